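"""Synthetic inputs with known ground truth for every pipeline stage.

Generates (a) C–H region Raman spectra as positive mixtures of Gaussian
bands (CH2 2845, CH3 2940, =C–H 3022 cm^-1 and the cholesteryl-ester
doublet near 2965/2985 cm^-1) whose lipid fraction varies with a
differentiation-like group axis, (b) SRS image fields containing elliptical
cells with bright sub-micron lipid droplets, optionally as hyperspectral
stacks, (c) FPKM-like expression matrices with four phenotype clusters and
genes planted to correlate with a latent lipid/protein ratio, and
(d) lipidomics tables of six lipid classes with a desaturase-inhibition
treatment effect (saturated species up, TAG 18:1 down).

Every generator is a pure function of its parameters and seed, and every
returned :class:`SyntheticTruth` carries enough ground truth to score
downstream recovery without re-inspecting generator internals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ramanmet.imaging import ImageChannel
from ramanmet.spectra import SpectraMatrix

FWHM_DEFAULT = 8.0  # cm^-1, the stated spectral resolution
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

PHENOTYPES = ("melanocytic", "transitory", "neural-crest", "undifferentiated")

LIPID_CLASSES = ("TAG", "DAG", "CE", "FFA", "PC", "PE")

#: Acyl chains used in the synthetic lipidome (xx:yy = carbons:double bonds).
_ACYL_POOL = ("14:0", "16:0", "16:1", "18:0", "18:1", "18:2", "20:4")

#: Treated/control fold changes of the membrane-lipid class totals, the
#: PC +40.2% / PE +38.6% remodeling that accompanies desaturase inhibition.
MEMBRANE_CLASS_FOLD = {"PC": 1.402, "PE": 1.386}

#: Relative class abundances of the control lipidome: membrane
#: phospholipids dominate, storage lipids (TAG, CE) are minor residents.
CLASS_ABUNDANCE = {"TAG": 0.03, "DAG": 0.08, "CE": 0.02, "FFA": 0.12, "PC": 0.47, "PE": 0.28}


@dataclass(frozen=True)
class BandComponent:
    """One Gaussian Raman band."""

    center: float  # cm^-1
    width: float  # FWHM, cm^-1
    amplitude: float
    label: str = ""

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")

    def profile(self, grid: np.ndarray) -> np.ndarray:
        """Evaluate the band on a wavenumber grid."""
        sigma = self.width * _FWHM_TO_SIGMA
        return self.amplitude * np.exp(-0.5 * ((np.asarray(grid) - self.center) / sigma) ** 2)


#: The C–H region band set: (center, relative amplitude, label).
_CH_BANDS = (
    (2845.0, 1.0, "CH2"),
    (2940.0, 1.0, "CH3"),
    (2965.0, 0.10, "CE_a"),
    (2985.0, 0.10, "CE_b"),
    (3022.0, 0.15, "=C-H"),
)


@dataclass
class SyntheticTruth:
    """Ground truth recorded by a generator run."""

    seed: int
    lipid_fraction: dict = field(default_factory=dict)  # sample -> f in [0, 1]
    phenotype_label: dict = field(default_factory=dict)  # sample -> phenotype
    droplet_centers: list = field(default_factory=list)  # (row, col, radius)
    planted_gene_sign: dict = field(default_factory=dict)  # gene -> -1/0/+1
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=float)


def make_component_bands(range_lo: float, range_hi: float, step: float = 2.0) -> list[BandComponent]:
    """Gaussian band definitions for the simulated range (FWHM 8 cm^-1).

    Only bands whose centers fall inside [range_lo, range_hi] are returned,
    so a fingerprint-region request excludes the C–H bands.
    """
    if not range_lo < range_hi:
        raise ValueError("empty spectral range")
    if step <= 0:
        raise ValueError("step must be positive")
    return [
        BandComponent(center=c, width=FWHM_DEFAULT, amplitude=a, label=lab)
        for c, a, lab in _CH_BANDS
        if range_lo <= c <= range_hi
    ]


def _band(label: str, bands) -> BandComponent:
    for b in bands:
        if b.label == label:
            return b
    raise KeyError(label)


def spectrum_model(grid: np.ndarray, lipid_fraction: float, bands=None) -> np.ndarray:
    """Noise-free spectral model: f*CH2 + (1-f)*CH3 + minor bands.

    The minor =C–H and CE bands scale with the lipid fraction (they ride on
    the lipid pool), keeping every component nonnegative.
    """
    if bands is None:
        bands = make_component_bands(float(grid[0]), float(grid[-1]))
    f = float(lipid_fraction)
    out = f * _band("CH2", bands).profile(grid) + (1 - f) * _band("CH3", bands).profile(grid)
    for lab in ("CE_a", "CE_b", "=C-H"):
        out = out + (0.25 + 0.75 * f) * _band(lab, bands).profile(grid)
    return out


def simulate_spectra_matrix(
    n_groups: int = 5,
    n_per_group: int = 10,
    lipid_fraction_by_group=(0.6, 0.5, 0.4, 0.3, 0.2),
    noise_sd: float = 0.02,
    seed: int = 0,
    range_lo: float = 2800.0,
    range_hi: float = 3050.0,
    step: float = 2.0,
    baseline: float = 0.3,
):
    """Simulate grouped single-cell Raman spectra in the C–H region.

    Groups mimic cell lines ordered by differentiation; the default lipid
    fractions decrease along the group axis, as the lipid/protein ratio does
    with de-differentiation.  ``noise_sd`` is Gaussian noise as a fraction
    of the maximum model intensity; ``baseline`` is a flat offset (same
    fraction) standing in for the residual background of real acquisitions
    — it also keeps the log transform well conditioned off the peaks.
    Intensities are floored at a small positive value so logarithms exist.

    Returns ``(SpectraMatrix, SyntheticTruth)``.
    """
    fracs = list(lipid_fraction_by_group)
    if len(fracs) != n_groups:
        raise ValueError("lipid_fraction_by_group length must equal n_groups")
    if any(not 0 <= f <= 1 for f in fracs):
        raise ValueError("lipid fractions must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    grid = np.arange(range_lo, range_hi + step / 2, step)
    bands = make_component_bands(range_lo, range_hi)

    cols, samples, groups, truth_f = [], [], [], {}
    scale = max(spectrum_model(grid, f, bands).max() for f in fracs)
    for g, f in enumerate(fracs):
        for i in range(n_per_group):
            name = f"group{g}_cell{i}"
            base = spectrum_model(grid, f, bands) + baseline * scale
            noisy = base + rng.normal(0.0, noise_sd * scale, size=grid.size)
            cols.append(np.maximum(noisy, 1e-6 * scale))
            samples.append(name)
            groups.append(f"group{g}")
            truth_f[name] = f
    matrix = SpectraMatrix(
        features=[float(w) for w in grid],
        samples=samples,
        values=np.column_stack(cols),
        groups=dict(zip(samples, groups)),
    )
    truth = SyntheticTruth(seed=seed, lipid_fraction=truth_f)
    return matrix, truth


def _render_disc(img: np.ndarray, r0: float, c0: float, radius: float, value: float) -> None:
    rr, cc = np.ogrid[: img.shape[0], : img.shape[1]]
    img[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2] += value


def simulate_srs_field(
    n_cells: int = 4,
    droplets_per_cell: int = 3,
    image_size: int = 256,
    seed: int = 0,
    hyperspectral: bool = False,
    droplet_radius_range: tuple[float, float] = (2.0, 6.0),
    ul_ratio: float = 0.35,
    ce_ratio: float = 0.3,
):
    """Simulate a CH2/CH3 SRS image pair with cells and lipid droplets.

    Cells are smooth elliptical regions with per-cell CH2/CH3 levels drawn
    so the planted pixel ratio varies from cell to cell; droplets are bright
    discs in the CH2 channel, placed fully inside a cell.  With
    ``hyperspectral=True`` a (wavenumber, row, col) stack over 2800–3050
    cm^-1 is also returned, in which droplet pixels carry a lipid-droplet
    spectrum with planted 3022/2908 (``ul_ratio``) and 2974/2908
    (``ce_ratio``) anchor ratios.

    Returns ``(ch2, ch3, stack_or_None, wavenumbers_or_None, truth)``.
    """
    if image_size < 64:
        raise ValueError("image_size must be at least 64")
    rng = np.random.default_rng(seed)
    shape = (image_size, image_size)
    ch2 = np.zeros(shape)
    ch3 = np.zeros(shape)
    cell_labels = np.zeros(shape, dtype=int)

    r_lo, r_hi = droplet_radius_range
    if n_cells > 0:
        # cells on a jittered grid so they never overlap
        per_side = int(np.ceil(np.sqrt(n_cells)))
        pitch = image_size / per_side
        axis_max = 0.38 * pitch
        if axis_max < 4 * r_hi:
            raise ValueError("impossible packing: cells too small for requested droplets")
        centers = []
        for k in range(n_cells):
            gr, gc = divmod(k, per_side)
            centers.append(
                (
                    (gr + 0.5) * pitch + rng.uniform(-0.05, 0.05) * pitch,
                    (gc + 0.5) * pitch + rng.uniform(-0.05, 0.05) * pitch,
                )
            )
        rr, cc = np.ogrid[:image_size, :image_size]
        ratios, ch3_levels = {}, {}
        for k, (r0, c0) in enumerate(centers, start=1):
            a = rng.uniform(0.75, 1.0) * axis_max
            b = rng.uniform(0.75, 1.0) * axis_max
            theta = rng.uniform(0, np.pi)
            dr, dc = rr - r0, cc - c0
            u = dr * np.cos(theta) + dc * np.sin(theta)
            v = -dr * np.sin(theta) + dc * np.cos(theta)
            inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            ch3_level = rng.uniform(0.8, 1.2)
            ratio = rng.uniform(0.15, 0.45)  # planted per-cell CH2/CH3
            ch3[inside] = ch3_level
            ch2[inside] = ratio * ch3_level
            cell_labels[inside] = k
            ratios[k] = ratio
            ch3_levels[k] = ch3_level
    else:
        ratios, ch3_levels, centers = {}, {}, []

    droplet_truth = []
    droplet_mask = np.zeros(shape, dtype=bool)
    if droplets_per_cell > 0 and n_cells == 0:
        raise ValueError("droplets require at least one cell")
    for k, (r0, c0) in enumerate(centers, start=1):
        placed = 0
        attempts = 0
        while placed < droplets_per_cell:
            attempts += 1
            if attempts > 2000:
                raise ValueError("impossible packing: could not place droplets inside cell")
            rad = rng.uniform(r_lo, r_hi)
            dr = rng.uniform(-0.6, 0.6) * axis_max
            dc = rng.uniform(-0.6, 0.6) * axis_max
            pr, pc = r0 + dr, c0 + dc
            ir, ic = int(round(pr)), int(round(pc))
            pad = int(np.ceil(rad)) + 2
            if not (pad <= ir < image_size - pad and pad <= ic < image_size - pad):
                continue
            patch = cell_labels[ir - pad : ir + pad + 1, ic - pad : ic + pad + 1]
            if not np.all(patch == k):  # droplet (plus margin) must stay inside this cell
                continue
            # keep droplets separated so detections are unambiguous
            if any((pr - tr) ** 2 + (pc - tc) ** 2 < (rad + trad + 2) ** 2 for tr, tc, trad in droplet_truth):
                continue
            _render_disc(ch2, pr, pc, rad, 4.0)
            rr2, cc2 = np.ogrid[:image_size, :image_size]
            droplet_mask |= (rr2 - pr) ** 2 + (cc2 - pc) ** 2 <= rad**2
            droplet_truth.append((pr, pc, rad))
            placed += 1

    noise = 0.01
    ch2 = np.maximum(ch2 + rng.normal(0, noise, shape), 0)
    ch3 = np.maximum(ch3 + rng.normal(0, noise, shape), 0)

    stack = wavenumbers = None
    if hyperspectral:
        wavenumbers = np.arange(2800.0, 3052.0, 2.0)
        bands = make_component_bands(2800.0, 3050.0)
        cell_spec = spectrum_model(wavenumbers, 0.4, bands)
        cell_spec = cell_spec + 0.3 * cell_spec.max()  # residual background
        ld_spec = _band("CH2", bands).profile(wavenumbers).astype(float)
        # pin the anchor ratios: set 2908 to a fixed pedestal, then scale
        # the =C-H and CE bands to the planted ratios
        anchor_idx = int(np.argmin(np.abs(wavenumbers - 2908.0)))
        ld_spec += 0.25  # pedestal so the anchor is nonzero
        anchor_val = ld_spec[anchor_idx]
        ul_idx = int(np.argmin(np.abs(wavenumbers - 3022.0)))
        ce_idx = int(np.argmin(np.abs(wavenumbers - 2974.0)))
        ul_b = BandComponent(3022.0, FWHM_DEFAULT, 1.0, "=C-H").profile(wavenumbers)
        ce_b = BandComponent(2974.0, FWHM_DEFAULT, 1.0, "CE").profile(wavenumbers)
        ld_spec = ld_spec + (ul_ratio * anchor_val - ld_spec[ul_idx]) / ul_b[ul_idx] * ul_b
        ld_spec = ld_spec + (ce_ratio * anchor_val - ld_spec[ce_idx]) / ce_b[ce_idx] * ce_b
        # match the bright CH2-channel disc so droplet pixels dominate noise
        ld_spec = np.maximum(ld_spec, 0) * 4.0
        stack = np.zeros((wavenumbers.size, image_size, image_size))
        stack[:, cell_labels > 0] = cell_spec[:, None]
        stack[:, droplet_mask] = ld_spec[:, None]
        stack += rng.normal(0, noise, stack.shape)
        stack = np.maximum(stack, 0)

    truth = SyntheticTruth(
        seed=seed,
        droplet_centers=[(float(r), float(c), float(rad)) for r, c, rad in droplet_truth],
        extras={
            "cell_ratio": {str(k): float(v) for k, v in ratios.items()},
            "cell_ch3_level": {str(k): float(v) for k, v in ch3_levels.items()},
            "ul_ratio": ul_ratio,
            "ce_ratio": ce_ratio,
        },
    )
    truth.extras["cell_labels"] = cell_labels
    ch2_img = ImageChannel(ch2, wavenumber=2845.0)
    ch3_img = ImageChannel(ch3, wavenumber=2940.0)
    return ch2_img, ch3_img, stack, wavenumbers, truth


def simulate_expression_matrix(
    n_genes: int = 2000,
    n_samples_per_phenotype: int = 8,
    n_planted: int = 40,
    effect_size: float = 2.0,
    noise_sd: float = 0.25,
    seed: int = 0,
):
    """Simulate an FPKM-like matrix with four phenotype clusters.

    Samples sit at four equidistant positions on a latent differentiation
    axis; a latent lipid/protein ratio decreases along it.  The first
    ``n_planted`` genes respond to that ratio (alternating sign) with
    log-scale slope ``effect_size``; a second block of genes separates the
    clusters; the rest is noise.  All values are strictly positive.

    Returns ``(SpectraMatrix, SyntheticTruth)``.
    """
    if n_planted > n_genes:
        raise ValueError("n_planted cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    n_samples = 4 * n_samples_per_phenotype
    axis = np.repeat(np.linspace(-1.5, 1.5, 4), n_samples_per_phenotype)
    lipid_ratio = 0.5 - 0.25 * axis / 1.5  # latent CH2/CH3, decreasing with de-differentiation

    genes = [f"GENE{i:05d}" for i in range(n_genes)]
    samples = [
        f"{PHENOTYPES[p]}_{i}" for p in range(4) for i in range(n_samples_per_phenotype)
    ]
    groups = dict(zip(samples, np.repeat(PHENOTYPES, n_samples_per_phenotype)))

    logX = rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    logX += rng.normal(2.0, 0.5, size=(n_genes, 1))  # per-gene baseline
    signs = {}
    centered = lipid_ratio - lipid_ratio.mean()
    for i in range(n_planted):
        s = 1 if i % 2 == 0 else -1
        logX[i] += s * effect_size * centered / np.abs(centered).max()
        signs[genes[i]] = s
    # phenotype-structure block so clusters separate beyond the planted axis
    n_struct = min(200, max(0, n_genes - n_planted))
    struct_load = rng.normal(0.0, 1.0, size=(n_struct, 2))
    pheno_coord = np.column_stack([axis, np.sign(np.abs(axis) - 1.0)])
    logX[n_planted : n_planted + n_struct] += 0.8 * struct_load @ pheno_coord.T
    for g in genes[n_planted:]:
        signs[g] = 0

    matrix = SpectraMatrix(
        features=genes, samples=samples, values=np.exp(logX), groups=groups
    )
    truth = SyntheticTruth(
        seed=seed,
        phenotype_label=groups,
        planted_gene_sign=signs,
        extras={"lipid_ratio": {s: float(v) for s, v in zip(samples, lipid_ratio)}},
    )
    return matrix, truth


def simulate_lipidomics_table(
    n_species_per_class: int = 6,
    treatment_effect: float = 0.8,
    noise_sd: float = 0.02,
    n_replicates: int = 3,
    seed: int = 0,
):
    """Simulate control and desaturase-inhibitor-treated lipidomics tables.

    Six lipid classes (TAG, DAG, CE, FFA, PC, PE) with acyl chains in
    xx:yy notation.  Treatment scales every saturated species up by
    ``1 + treatment_effect`` and TAG 18:1 down by the same factor,
    reproducing the SFA-up / oleate-down signature of SCD1 inhibition.
    Membrane classes PC and PE are additionally rescaled as whole classes
    so their treated totals exceed control by the stated +40.2% / +38.6%
    (a uniform per-class factor, so within-class saturation ratios are
    untouched); applied only when ``treatment_effect > 0``.  Replicate
    columns carry multiplicative Gaussian noise.

    Returns ``(control, treated)`` long-format DataFrames with columns
    class, species, carbons, double_bonds, condition, replicate,
    concentration.
    """
    if treatment_effect < 0:
        raise ValueError("treatment_effect must be nonnegative")
    if not 1 <= n_species_per_class <= len(_ACYL_POOL):
        raise ValueError(f"n_species_per_class must be in [1, {len(_ACYL_POOL)}]")
    rng = np.random.default_rng(seed)
    rows_ct, rows_tx = [], []
    for cls in LIPID_CLASSES:
        chains = _ACYL_POOL[:n_species_per_class]
        bases, folds = [], []
        for chain in chains:
            dbs = int(chain.split(":")[1])
            bases.append(CLASS_ABUNDANCE[cls] * float(rng.lognormal(mean=3.0, sigma=0.25)))
            fold = 1.0
            if dbs == 0:
                fold *= 1.0 + treatment_effect
            if cls == "TAG" and chain == "18:1":
                fold /= 1.0 + treatment_effect
            folds.append(fold)
        if treatment_effect > 0 and cls in MEMBRANE_CLASS_FOLD:
            # uniform class rescale pinning the treated/control total ratio
            total_ct = sum(bases)
            total_tx = sum(b * f for b, f in zip(bases, folds))
            adj = MEMBRANE_CLASS_FOLD[cls] * total_ct / total_tx
            folds = [f * adj for f in folds]
        for chain, base, fold in zip(chains, bases, folds):
            carbons, dbs = (int(x) for x in chain.split(":"))
            for rep in range(n_replicates):
                eps_ct = float(rng.normal(1.0, noise_sd))
                eps_tx = float(rng.normal(1.0, noise_sd))
                rows_ct.append((cls, chain, carbons, dbs, "control", rep, base * max(eps_ct, 0.01)))
                rows_tx.append((cls, chain, carbons, dbs, "treated", rep, base * fold * max(eps_tx, 0.01)))
    cols = ["lipid_class", "species", "carbons", "double_bonds", "condition", "replicate", "concentration"]
    return pd.DataFrame(rows_ct, columns=cols), pd.DataFrame(rows_tx, columns=cols)
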