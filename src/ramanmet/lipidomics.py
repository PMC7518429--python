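"""Fatty-acid and lipid-class analytics.

Works on long-format lipidomics tables (one row per lipid species x
replicate) covering the six major intracellular classes — TAG, DAG, CE,
FFA, PC, PE — with acyl chains in xx:yy (carbons:double-bonds) notation.
Provides relative fatty-acid abundances, SFA/UFA and 18:0/18:1 saturation
ratios, class percentages, per-column Z-scored heatmap matrices and
treatment percent changes of class totals.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

LIPID_CLASSES = ("TAG", "DAG", "CE", "FFA", "PC", "PE")

#: The six dominant fatty acids quantified by GC-MS, in reporting order.
MAJOR_FATTY_ACIDS = ("16:0", "16:1", "18:0", "18:1", "18:2", "20:4")

_SPECIES_RE = re.compile(r"^\s*([A-Za-z]+)\s+(\d+):(\d+)\s*$")


@dataclass(frozen=True)
class LipidSpecies:
    """One lipid species: class plus acyl-chain composition."""

    lipid_class: str
    carbons: int
    double_bonds: int

    def __post_init__(self):
        if self.lipid_class not in LIPID_CLASSES:
            raise ValueError(
                f"unknown lipid class {self.lipid_class!r}; expected one of {LIPID_CLASSES}"
            )
        if self.carbons <= 0:
            raise ValueError("carbons must be positive")
        if self.double_bonds < 0:
            raise ValueError("double_bonds must be nonnegative")

    @property
    def saturated(self) -> bool:
        return self.double_bonds == 0

    @property
    def chain(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"

    def __str__(self) -> str:
        return f"{self.lipid_class} {self.chain}"


def parse_species(text: str) -> LipidSpecies:
    """Parse ``"<class> <xx>:<yy>"`` (e.g. ``"TAG 18:1"``) into a species."""
    m = _SPECIES_RE.match(text)
    if not m:
        raise ValueError(f"malformed lipid species {text!r}; expected '<class> xx:yy'")
    return LipidSpecies(m.group(1), int(m.group(2)), int(m.group(3)))


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"lipid_class", "species", "replicate", "concentration"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"lipidomics table missing columns {sorted(missing)}")
    if len(table) == 0:
        raise ValueError("empty lipidomics table")
    if (table["concentration"] < 0).any():
        raise ValueError("concentrations must be nonnegative")
    out = table.copy()
    if "double_bonds" not in out.columns:
        parsed = out["species"].map(lambda s: s.split(":"))
        out["double_bonds"] = parsed.map(lambda p: int(p[1]))
    return out


def read_lipidomics_table(path, sep: str = "\t") -> pd.DataFrame:
    """Read a long-format lipidomics table and validate it."""
    return _validate_table(pd.read_csv(path, sep=sep))


def fa_relative_abundance(peak_areas) -> pd.Series:
    """Relative abundance of the six major fatty acids.

    Each peak area divided by the sum over all six species; input is a
    length-6 sequence ordered as :data:`MAJOR_FATTY_ACIDS` or a mapping
    keyed by chain.  Output fractions sum to 1.
    """
    if isinstance(peak_areas, dict):
        areas = np.array([float(peak_areas[fa]) for fa in MAJOR_FATTY_ACIDS])
    else:
        areas = np.asarray(peak_areas, dtype=float)
    if areas.shape != (6,):
        raise ValueError("expected exactly six peak areas")
    if (areas < 0).any():
        raise ValueError("peak areas must be nonnegative")
    total = areas.sum()
    if total <= 0:
        raise ValueError("zero total peak area")
    return pd.Series(areas / total, index=list(MAJOR_FATTY_ACIDS))


def _replicate_mean_total(table: pd.DataFrame, sel) -> float:
    """Mean over replicates of the summed concentration of selected rows."""
    sub = table[sel]
    per_rep = sub.groupby("replicate")["concentration"].sum()
    # replicates in which no selected species was measured count as zero
    n_reps = table["replicate"].nunique()
    return float(per_rep.sum() / n_reps)


def saturation_ratios(
    table: pd.DataFrame, by_class: bool = True, mode: str = "replicate_mean"
) -> pd.DataFrame:
    """SFA/UFA and 18:0/18:1 concentration ratios, per class and overall.

    SFA = species with zero double bonds; everything else UFA.  With the
    default ``mode="replicate_mean"`` each ratio is formed from
    replicate-averaged totals; ``mode="per_replicate"`` averages the
    per-replicate ratios instead.
    """
    t = _validate_table(table)
    groups = [(c, t["lipid_class"] == c) for c in LIPID_CLASSES if (t["lipid_class"] == c).any()]
    if by_class:
        groups.append(("all", t["lipid_class"].notna()))
    else:
        groups = [("all", t["lipid_class"].notna())]

    rows = []
    for name, sel in groups:
        sfa_sel = sel & (t["double_bonds"] == 0)
        ufa_sel = sel & (t["double_bonds"] > 0)
        st_sel = sel & (t["species"] == "18:0")
        oa_sel = sel & (t["species"] == "18:1")
        if mode == "replicate_mean":
            ufa = _replicate_mean_total(t, ufa_sel)
            if ufa == 0:
                raise ValueError(f"zero UFA total in class {name!r}")
            sfa_ufa = _replicate_mean_total(t, sfa_sel) / ufa
            oa = _replicate_mean_total(t, oa_sel)
            st_oa = _replicate_mean_total(t, st_sel) / oa if oa > 0 else np.nan
        elif mode == "per_replicate":
            per = []
            per_so = []
            for _, rep in t[sel].groupby("replicate"):
                u = rep.loc[rep["double_bonds"] > 0, "concentration"].sum()
                if u == 0:
                    raise ValueError(f"zero UFA total in class {name!r}")
                per.append(rep.loc[rep["double_bonds"] == 0, "concentration"].sum() / u)
                o = rep.loc[rep["species"] == "18:1", "concentration"].sum()
                s = rep.loc[rep["species"] == "18:0", "concentration"].sum()
                per_so.append(s / o if o > 0 else np.nan)
            sfa_ufa = float(np.mean(per))
            st_oa = float(np.nanmean(per_so)) if per_so else np.nan
        else:
            raise ValueError(f"unknown mode {mode!r}")
        rows.append({"group": name, "sfa_ufa": sfa_ufa, "st_oa": st_oa})
    return pd.DataFrame(rows).set_index("group")


def class_percentages(table: pd.DataFrame) -> pd.Series:
    """Per-class totals as percent of the summed concentration (sums to 100)."""
    t = _validate_table(table)
    totals = t.groupby("lipid_class")["concentration"].sum()
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("total concentration must be positive")
    pct = 100.0 * totals / grand
    return pct.reindex([c for c in LIPID_CLASSES if c in pct.index])


def column_zscore_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column across samples (sample sd, ddof=1).

    Constant columns map to zeros (with a warning) so heatmaps stay
    complete.  Rows are sample replicates, columns acyl chains.
    """
    df = matrix.astype(float)
    means = df.mean(axis=0)
    sds = df.std(axis=0, ddof=1)
    flat = sds == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant column(s) mapped to zeros")
    out = (df - means) / sds.replace(0, np.nan)
    return out.fillna(0.0)


def acyl_heatmap_matrix(table: pd.DataFrame, lipid_class: str) -> pd.DataFrame:
    """Replicate x acyl-chain abundance matrix for one class, Z-scored per column.

    Rows are ``condition/replicate`` pairs, columns acyl chains ordered by
    carbon count then double bonds — the standard heatmap layout.
    """
    t = _validate_table(table)
    t = t[t["lipid_class"] == lipid_class]
    if len(t) == 0:
        raise ValueError(f"no rows for class {lipid_class!r}")
    if "condition" in t.columns:
        t = t.assign(row=t["condition"].astype(str) + "/" + t["replicate"].astype(str))
    else:
        t = t.assign(row=t["replicate"].astype(str))
    wide = t.pivot_table(index="row", columns="species", values="concentration", aggfunc="sum")
    order = sorted(wide.columns, key=lambda s: (int(s.split(":")[0]), int(s.split(":")[1])))
    return column_zscore_matrix(wide[order])


def percent_change_totals(
    control: pd.DataFrame,
    treated: pd.DataFrame,
    lipid_class: str,
    mode: str = "replicate_mean",
) -> float:
    """Percent change of a class's total concentration, treated vs control.

    ``replicate_mean`` (default): 100 * (mean treated total - mean control
    total) / mean control total, totals taken per replicate then averaged.
    ``pooled``: the same on summed totals (identical when replicate counts
    match).
    """
    ct = _validate_table(control)
    tx = _validate_table(treated)
    ct_sel = ct["lipid_class"] == lipid_class
    tx_sel = tx["lipid_class"] == lipid_class
    if not ct_sel.any() or not tx_sel.any():
        raise ValueError(f"class {lipid_class!r} absent from a condition")
    if mode == "replicate_mean":
        ct_total = _replicate_mean_total(ct, ct_sel)
        tx_total = _replicate_mean_total(tx, tx_sel)
    elif mode == "pooled":
        ct_total = float(ct.loc[ct_sel, "concentration"].sum())
        tx_total = float(tx.loc[tx_sel, "concentration"].sum())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if ct_total == 0:
        raise ValueError("zero control class total")
    return 100.0 * (tx_total - ct_total) / ct_total
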