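"""Spectral containers, I/O, resampling, anchor normalization and peak ratios.

Single-channel SRS acquires intensity at a handful of stated wavenumbers
(CH2 2845, CH3 2940 cm^-1, ...); hSRS sweeps a grid.  Quantification here is
anchor normalization (default 2908 cm^-1, the zero crossing of the first
deviation constraint in lipid-droplet spectra) and windowed peak ratios such
as CE 2974/2908 and unsaturated-lipid 3022/2908.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Default anchor wavenumber (cm^-1) for normalization.
DEFAULT_ANCHOR = 2908.0

#: Default half-window (cm^-1) for peak quantification: half of the 8 cm^-1
#: spectral resolution.
DEFAULT_HALF_WINDOW = 4.0

#: Values below this fraction of the matrix maximum are raised to the floor
#: before taking logarithms.
PSEUDOCOUNT_FRACTION = 1e-6


@dataclass(frozen=True)
class Spectrum:
    """A single spectrum on a strictly ascending wavenumber axis."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    label: str = ""
    group: str = ""

    def __post_init__(self):
        w = np.asarray(self.wavenumbers, dtype=float)
        x = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or x.ndim != 1 or w.size != x.size:
            raise ValueError("wavenumbers and intensities must be 1-D and equal length")
        if w.size >= 2 and not np.all(np.diff(w) > 0):
            raise ValueError("wavenumbers must be strictly ascending")
        if not np.all(np.isfinite(x)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", x)

    def nearest_index(self, wavenumber: float) -> int:
        """Index of the grid point closest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.wavenumbers - wavenumber)))

    def at(self, wavenumber: float) -> float:
        """Intensity at the nearest grid point."""
        return float(self.intensities[self.nearest_index(wavenumber)])


@dataclass
class SpectraMatrix:
    """Strictly positive feature x sample matrix with per-sample group labels.

    ``features`` are wavenumbers (as floats) or gene symbols; ``values`` has
    one column per sample.  ``floor()`` applies the pseudocount policy so the
    matrix supports the log transform required by surprisal analysis.
    """

    features: list
    samples: list[str]
    values: np.ndarray
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.features), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.features)} features x {len(self.samples)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix entries must be finite")
        if len(set(map(str, self.features))) != len(self.features):
            raise ValueError("duplicate feature identifiers")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def floor(self, pseudocount_fraction: float = PSEUDOCOUNT_FRACTION) -> "SpectraMatrix":
        """Raise entries below ``fraction * max`` to that floor (log-safety)."""
        floor = pseudocount_fraction * float(self.values.max())
        if floor <= 0:
            raise ValueError("matrix maximum must be positive to apply the floor")
        return SpectraMatrix(
            features=list(self.features),
            samples=list(self.samples),
            values=np.maximum(self.values, floor),
            groups=dict(self.groups),
        )

    def group_of(self, sample: str) -> str:
        return self.groups.get(sample, "")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.features, columns=self.samples)

    def spectrum(self, sample: str) -> Spectrum:
        """Extract one sample as a :class:`Spectrum` (features must be numeric)."""
        j = self.samples.index(sample)
        return Spectrum(
            wavenumbers=np.asarray(self.features, dtype=float),
            intensities=self.values[:, j],
            label=sample,
            group=self.group_of(sample),
        )


def read_spectra_table(path, sep: str = "\t", group_row: bool = True) -> SpectraMatrix:
    """Read a delimited spectra/expression table.

    Layout: first column holds feature ids (wavenumbers or gene symbols),
    remaining columns one sample each.  When ``group_row`` is true and the
    second file row is tagged ``group`` in its first cell, it supplies the
    per-sample group labels.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    groups: dict[str, str] = {}
    if group_row and len(df.index) and str(df.index[0]).lower() == "group":
        groups = {s: str(v) for s, v in df.iloc[0].items()}
        df = df.iloc[1:]
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric intensity in {path}: {exc}") from exc
    if df.isna().any().any():
        raise ValueError(f"missing/ragged values in {path}")
    feats = list(df.index)
    counts = pd.Index(feats).value_counts()
    dups = counts[counts > 1]
    if len(dups):
        raise ValueError(f"duplicate feature id(s) in {path}: {list(dups.index)}")
    try:
        feats = [float(f) for f in feats]
        order = np.argsort(feats)
        df = df.iloc[order]
        feats = [feats[i] for i in order]
    except (TypeError, ValueError):
        feats = [str(f) for f in feats]
    return SpectraMatrix(
        features=feats,
        samples=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        groups=groups,
    )


def write_spectra_table(matrix: SpectraMatrix, path, sep: str = "\t") -> None:
    """Write a matrix in the layout :func:`read_spectra_table` expects."""
    df = matrix.to_frame()
    if matrix.groups:
        header = pd.DataFrame(
            [[matrix.group_of(s) for s in matrix.samples]],
            index=["group"],
            columns=matrix.samples,
        )
        df = pd.concat([header, df.astype(object)])
    df.to_csv(path, sep=sep, index_label="feature")


def resample_to_grid(spectrum: Spectrum, grid) -> Spectrum:
    """Linearly interpolate a spectrum onto a new ascending grid.

    No extrapolation: the grid must lie within the spectrum's support.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or not np.all(np.diff(grid) > 0) and grid.size > 1:
        raise ValueError("grid must be non-empty and strictly ascending")
    lo, hi = spectrum.wavenumbers[0], spectrum.wavenumbers[-1]
    if grid[0] < lo or grid[-1] > hi:
        raise ValueError(
            f"grid [{grid[0]}, {grid[-1]}] extends beyond support [{lo}, {hi}]"
        )
    vals = np.interp(grid, spectrum.wavenumbers, spectrum.intensities)
    return replace(spectrum, wavenumbers=grid, intensities=vals)


def normalize_to_anchor(spectrum: Spectrum, anchor: float = DEFAULT_ANCHOR) -> Spectrum:
    """Divide all intensities by the intensity at the grid point nearest ``anchor``."""
    ref = spectrum.at(anchor)
    if ref <= 0:
        raise ValueError(f"nonpositive intensity {ref} at anchor {anchor} cm^-1")
    return replace(spectrum, intensities=spectrum.intensities / ref)


def _window_mean(spectrum: Spectrum, center: float, half_window: float) -> float:
    if half_window == 0:
        return spectrum.at(center)
    w = spectrum.wavenumbers
    sel = (w >= center - half_window) & (w <= center + half_window)
    if not sel.any():
        sel = np.zeros_like(w, dtype=bool)
        sel[spectrum.nearest_index(center)] = True
    return float(spectrum.intensities[sel].mean())


def peak_ratio(
    spectrum: Spectrum,
    numerator: float,
    denominator: float,
    half_window: float = DEFAULT_HALF_WINDOW,
) -> float:
    """Windowed mean intensity at ``numerator`` over that at ``denominator``.

    ``half_window = 0`` uses the single nearest grid point, matching
    single-channel acquisition at the stated wavenumber.
    """
    lo, hi = spectrum.wavenumbers[0], spectrum.wavenumbers[-1]
    for w in (numerator, denominator):
        if not lo <= w <= hi:
            raise ValueError(f"wavenumber {w} outside support [{lo}, {hi}]")
    den = _window_mean(spectrum, denominator, half_window)
    if den <= 0:
        raise ValueError(f"nonpositive denominator window mean at {denominator}")
    return _window_mean(spectrum, numerator, half_window) / den


def summarize_ratio_by_group(ratios, groups) -> pd.DataFrame:
    """Per-group mean and SEM (sample sd / sqrt(n)); group order of first appearance.

    SEM is reported as NaN for singleton groups.
    """
    ratios = np.asarray(ratios, dtype=float)
    groups = list(groups)
    if len(ratios) != len(groups):
        raise ValueError("ratios and groups must align")
    order = list(dict.fromkeys(groups))
    rows = []
    for g in order:
        vals = ratios[[i for i, gg in enumerate(groups) if gg == g]]
        if vals.size == 0:
            raise ValueError(f"empty group {g!r}")
        sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else float("nan")
        rows.append({"group": g, "n": int(vals.size), "mean": float(vals.mean()), "sem": sem})
    return pd.DataFrame(rows).set_index("group")
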