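"""Gene–ratio correlation screening and minimal pre-ranked enrichment.

Screens every gene's expression against an imaging-derived CH2/CH3
lipid-to-protein ratio with Spearman correlation (|rho| > 0.95 by default,
matching a five-cell-line screen where only near-perfect monotone
relations survive), converts Pearson coefficients to two-sided t-test
p-values, and computes a weighted running-sum (pre-ranked) gene-set
enrichment score with a gene-set permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ramanmet.spectra import SpectraMatrix


@dataclass(frozen=True)
class CorrelationResult:
    gene: str
    rho: float  # Spearman
    r: float  # Pearson
    n: int
    p: float  # two-sided, from the Pearson t statistic


@dataclass(frozen=True)
class EnrichmentResult:
    gene_set: str
    ES: float
    NES: float
    p_perm: float
    n_perm: int


def spearman_screen(
    expression: SpectraMatrix,
    ratios,
    cutoff: float = 0.95,
):
    """Screen genes for monotone association with a per-sample ratio.

    Spearman rho (average ranks for ties) per gene against ``ratios``
    (aligned with ``expression.samples``, or a mapping sample -> value).
    Returns ``(positive, negative, results)``: genes with rho > cutoff,
    genes with rho < -cutoff, and the full per-gene results table.
    Constant-expression genes are excluded with a warning.
    """
    if isinstance(ratios, dict):
        missing = [s for s in expression.samples if s not in ratios]
        if missing:
            raise ValueError(f"ratio missing for samples {missing}")
        y = np.array([float(ratios[s]) for s in expression.samples])
    else:
        y = np.asarray(ratios, dtype=float)
        if y.shape != (len(expression.samples),):
            raise ValueError("ratios must align with expression samples")
    if y.size < 3:
        raise ValueError("need at least 3 paired samples")

    X = expression.values
    const = X.std(axis=1) == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant gene(s) excluded from the screen")

    rank_y = stats.rankdata(y)
    rank_X = np.apply_along_axis(stats.rankdata, 1, X)
    # Spearman as Pearson on ranks, vectorized across genes
    ry = rank_y - rank_y.mean()
    rX = rank_X - rank_X.mean(axis=1, keepdims=True)
    denom = np.sqrt((rX**2).sum(axis=1) * (ry**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rX @ ry) / denom

    results = []
    n = y.size
    for g, gene in enumerate(expression.features):
        if const[g]:
            continue
        xc = X[g] - X[g].mean()
        yc = y - y.mean()
        denom_p = np.sqrt((xc**2).sum() * (yc**2).sum())
        r = float((xc @ yc) / denom_p) if denom_p > 0 else np.nan
        p = pearson_r_pvalue(min(max(r, -1.0), 1.0), n) if np.isfinite(r) else np.nan
        results.append(CorrelationResult(gene=str(gene), rho=float(rho[g]), r=r, n=n, p=p))
    table = pd.DataFrame([r.__dict__ for r in results]).set_index("gene")
    positive = list(table.index[table["rho"] > cutoff])
    negative = list(table.index[table["rho"] < -cutoff])
    return positive, negative, table


def pearson_r_pvalue(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson coefficient under the t reference.

    t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom.  |r| = 1 is
    reported as the lower bound 0 (with a warning); for n-2 = 2 the closed
    form reduces to p = 1 - |r|.
    """
    if n < 3:
        raise ValueError("need n >= 3 paired observations")
    if not -1.0 <= r <= 1.0:
        raise ValueError("|r| cannot exceed 1")
    if abs(r) == 1.0:
        warnings.warn("|r| = 1: p-value reported as its lower bound 0")
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted q-values (optional add-on; the screen itself filters on rho)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q


def _running_es(hit_mask: np.ndarray, metric: np.ndarray, weight: float) -> np.ndarray:
    N = hit_mask.size
    n_hits = int(hit_mask.sum())
    w = np.abs(metric) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit weights zero: fall back to unweighted hits
        hit_w = hit_mask.astype(float)
        total = hit_w.sum()
    step = hit_w / total - (~hit_mask) / (N - n_hits)
    return np.cumsum(step)


def preranked_enrichment(
    ranked_genes,
    metric_values,
    gene_set,
    name: str = "",
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentResult:
    """Weighted running-sum enrichment of a gene set in a ranked list.

    ``ranked_genes`` are ordered by the ranking metric (descending);
    hits advance the running sum by |metric|^weight normalized over the
    set, misses decrement it by 1/(N - set size); ES is the extreme
    deviation.  The null is ``n_perm`` random same-size gene sets
    (pre-ranked permutation scheme); p is one-sided toward the observed
    sign, NES the ES over the mean |null ES| of that sign.
    """
    ranked = list(ranked_genes)
    N = len(ranked)
    sset = set(gene_set)
    if not sset or len(sset) >= N:
        raise ValueError("gene set must be a nonempty strict subset of the ranked list")
    unknown = sset - set(ranked)
    if unknown:
        raise ValueError(f"gene set members absent from ranking: {sorted(unknown)}")
    metric = np.asarray(metric_values, dtype=float)
    if metric.shape != (N,):
        raise ValueError("metric_values must align with ranked_genes")

    hit = np.array([g in sset for g in ranked])
    run = _running_es(hit, metric, weight)
    ES = float(run[np.argmax(np.abs(run))])

    rng = np.random.default_rng(seed)
    k = len(sset)
    null = np.empty(n_perm)
    for b in range(n_perm):
        idx = rng.choice(N, size=k, replace=False)
        mask = np.zeros(N, dtype=bool)
        mask[idx] = True
        r = _running_es(mask, metric, weight)
        null[b] = r[np.argmax(np.abs(r))]
    same_sign = null >= 0 if ES >= 0 else null <= 0
    extreme = (null >= ES) if ES >= 0 else (null <= ES)
    p_perm = float((extreme.sum() + 1) / (n_perm + 1))
    denom = np.abs(null[same_sign]).mean() if same_sign.any() else np.nan
    NES = float(ES / denom) if denom and np.isfinite(denom) and denom > 0 else np.nan
    return EnrichmentResult(gene_set=name or "gene_set", ES=ES, NES=NES, p_perm=p_perm, n_perm=n_perm)


def read_gene_sets(path) -> dict[str, list[str]]:
    """Read gene sets: one per line, tab-separated ``name<TAB>gene1<TAB>gene2...``."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0]:
                sets[parts[0]] = [g for g in parts[1:] if g]
    return sets
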