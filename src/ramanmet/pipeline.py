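"""End-to-end orchestration of the analysis on synthetic or user data.

Stage order follows the study flow: single-cell spectra -> surprisal
analysis -> SRS ratio imaging and droplet spectroscopy -> gene-ratio
correlation screen and enrichment -> lipidomics saturation analytics.
Every stage writes delimited-text outputs plus a run manifest recording
the seed and parameters, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ramanmet import assoc, imaging, lipidomics, spectra, surprisal, synthetic
from ramanmet.spectra import read_spectra_table, write_spectra_table

log = logging.getLogger("ramanmet")


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    With the default ``synthetic=True`` every input is generated; otherwise
    the ``*_path`` fields must point at existing files in the package's
    delimited-text layouts.
    """

    out_dir: str = "ramanmet_out"
    seed: int = 0
    synthetic: bool = True

    # synthetic-run parameters (the study-like defaults)
    n_groups: int = 5
    n_per_group: int = 10
    lipid_fraction_by_group: tuple = (0.6, 0.5, 0.4, 0.3, 0.2)
    spectra_noise_sd: float = 0.02
    n_cells: int = 4
    droplets_per_cell: int = 3
    image_size: int = 256
    n_genes: int = 2000
    n_samples_per_phenotype: int = 8
    n_planted: int = 40
    expression_effect_size: float = 2.0
    lipid_treatment_effect: float = 0.8

    # analysis parameters
    anchor_wavenumber: float = spectra.DEFAULT_ANCHOR
    half_window: float = spectra.DEFAULT_HALF_WINDOW
    n_constraints: int = 5
    screen_cutoff: float = 0.95
    n_perm: int = 1000
    min_droplet_radius: float = 1.5
    max_droplet_radius: float = 8.0

    # real-data inputs (used when synthetic is False)
    spectra_path: str | None = None
    expression_path: str | None = None
    ch2_tiff: str | None = None
    ch3_tiff: str | None = None
    lipidomics_control_path: str | None = None
    lipidomics_treated_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "lipid_fraction_by_group" in raw:
            raw["lipid_fraction_by_group"] = tuple(raw["lipid_fraction_by_group"])
        return cls(**raw)


def _stage_spectra(cfg: PipelineConfig, out: Path) -> dict:
    if cfg.synthetic:
        matrix, truth = synthetic.simulate_spectra_matrix(
            n_groups=cfg.n_groups,
            n_per_group=cfg.n_per_group,
            lipid_fraction_by_group=cfg.lipid_fraction_by_group,
            noise_sd=cfg.spectra_noise_sd,
            seed=cfg.seed,
        )
    else:
        matrix, truth = read_spectra_table(cfg.spectra_path), None
    write_spectra_table(matrix, out / "spectra.tsv")

    decomp = surprisal.fit_surprisal(matrix, n_constraints=cfg.n_constraints, pin_feature=2845.0)
    surprisal.write_decomposition(decomp, out / "spectra_sa")
    corr = surprisal.reconstruction_correlation(decomp, decomp.n_constraints)

    ratios = [
        spectra.peak_ratio(matrix.spectrum(s), 2845.0, 2940.0, cfg.half_window)
        for s in matrix.samples
    ]
    groups = [matrix.group_of(s) for s in matrix.samples]
    summary = spectra.summarize_ratio_by_group(ratios, groups)
    summary.to_csv(out / "peak_ratio_by_group.tsv", sep="\t")

    metrics = {"reconstruction_correlation": corr}
    if truth is not None:
        f = np.array([truth.lipid_fraction[s] for s in matrix.samples])
        lam1 = decomp.weight_of(1)
        metrics["lambda1_lipid_fraction_corr"] = float(abs(np.corrcoef(lam1, f)[0, 1]))
        i2845 = int(np.argmin(np.abs(np.asarray(matrix.features, float) - 2845)))
        i2940 = int(np.argmin(np.abs(np.asarray(matrix.features, float) - 2940)))
        metrics["lambda1_opposite_signs"] = bool(
            decomp.G[i2845, 1] * decomp.G[i2940, 1] < 0
        )
    log.info("spectra stage: matrix %s, reconstruction r=%.6f", matrix.shape, corr)
    return metrics


def _stage_imaging(cfg: PipelineConfig, out: Path) -> dict:
    if cfg.synthetic:
        ch2, ch3, stack, wns, truth = synthetic.simulate_srs_field(
            n_cells=cfg.n_cells,
            droplets_per_cell=cfg.droplets_per_cell,
            image_size=cfg.image_size,
            seed=cfg.seed,
            hyperspectral=True,
        )
    else:
        ch2 = imaging.ImageChannel.from_tiff(cfg.ch2_tiff, wavenumber=2845.0)
        ch3 = imaging.ImageChannel.from_tiff(cfg.ch3_tiff, wavenumber=2940.0)
        stack = wns = truth = None
    ch2.to_tiff(out / "ch2.tiff")
    ch3.to_tiff(out / "ch3.tiff")

    mask = imaging.huang_threshold_mask(ch3)
    rimg = imaging.ratio_image(ch2, ch3, mask)
    labels = imaging.label_cells(mask)
    rows = []
    for lab in range(1, labels.max() + 1):
        region = labels == lab
        rows.append(
            {"cell": lab, "n_px": int(region.sum()), "mean_ratio": imaging.region_mean(rimg, region)}
        )
    cells = pd.DataFrame(rows)
    cells.to_csv(out / "cell_ratios.tsv", sep="\t", index=False)

    droplets = imaging.detect_lipid_droplets(
        ch2, mask, min_radius=cfg.min_droplet_radius, max_radius=cfg.max_droplet_radius
    )
    drows = [
        {"droplet": i, "row": r.centroid[0], "col": r.centroid[1], "radius": r.radius}
        for i, r in enumerate(droplets.regions)
    ]
    metrics: dict = {"n_cells_detected": int(labels.max()), "n_droplets": len(droplets)}

    if stack is not None and len(droplets):
        ul, ce = [], []
        for i, reg in enumerate(droplets.regions):
            spec = imaging.extract_region_spectrum(stack, wns, reg.pixels, label=f"LD{i}")
            anchored = spectra.normalize_to_anchor(spec, cfg.anchor_wavenumber)
            ul.append(spectra.peak_ratio(anchored, 3022.0, cfg.anchor_wavenumber, 0.0))
            ce.append(spectra.peak_ratio(anchored, 2974.0, cfg.anchor_wavenumber, 0.0))
            drows[i]["ul_ratio"], drows[i]["ce_ratio"] = ul[-1], ce[-1]
        metrics["mean_ul_ratio"] = float(np.mean(ul))
        metrics["mean_ce_ratio"] = float(np.mean(ce))
    pd.DataFrame(drows).to_csv(out / "droplets.tsv", sep="\t", index=False)

    if truth is not None:
        true_centers = truth.droplet_centers
        matched = 0
        for tr, tc, trad in true_centers:
            if len(droplets) and np.min(
                np.hypot(droplets.centroids[:, 0] - tr, droplets.centroids[:, 1] - tc)
            ) <= max(2.0, trad):
                matched += 1
        metrics["droplet_sensitivity"] = matched / len(true_centers) if true_centers else np.nan
        extra = len(droplets) - matched
        metrics["droplet_fdr"] = extra / len(droplets) if len(droplets) else 0.0
    log.info("imaging stage: %d cells, %d droplets", metrics["n_cells_detected"], len(droplets))
    return metrics


def _stage_screen(cfg: PipelineConfig, out: Path) -> dict:
    if cfg.synthetic:
        matrix, truth = synthetic.simulate_expression_matrix(
            n_genes=cfg.n_genes,
            n_samples_per_phenotype=cfg.n_samples_per_phenotype,
            n_planted=cfg.n_planted,
            effect_size=cfg.expression_effect_size,
            seed=cfg.seed,
        )
        ratios = truth.extras["lipid_ratio"]
    else:
        matrix, truth = read_spectra_table(cfg.expression_path), None
        ratios = None
    write_spectra_table(matrix, out / "expression.tsv")

    decomp = surprisal.fit_surprisal(matrix, n_constraints=min(6, len(matrix.samples)))
    coords, loadings = surprisal.sample_projection_2d(decomp)
    coords.to_csv(out / "projection_2d.tsv", sep="\t", index_label="sample")
    scores = surprisal.phenotype_contribution_scores(loadings)
    scores.to_csv(out / "phenotype_scores.tsv", sep="\t", index_label="gene")
    for pheno in surprisal.PHENOTYPES:
        top = surprisal.top_phenotype_genes(scores, pheno, n=min(100, len(scores)))
        (out / f"top_{pheno.replace('-', '_')}.txt").write_text("\n".join(top) + "\n")

    metrics: dict = {}
    if ratios is not None:
        pos, neg, table = assoc.spearman_screen(matrix, ratios, cutoff=cfg.screen_cutoff)
        table.to_csv(out / "screen.tsv", sep="\t")
        planted_pos = [g for g, s in truth.planted_gene_sign.items() if s > 0]
        planted_neg = [g for g, s in truth.planted_gene_sign.items() if s < 0]
        metrics["screen_pos_recall"] = (
            len(set(pos) & set(planted_pos)) / len(planted_pos) if planted_pos else np.nan
        )
        metrics["screen_neg_recall"] = (
            len(set(neg) & set(planted_neg)) / len(planted_neg) if planted_neg else np.nan
        )
        ranked = table.sort_values("rho", ascending=False)
        enr = assoc.preranked_enrichment(
            list(ranked.index),
            ranked["rho"].to_numpy(),
            planted_pos,
            name="planted_positive",
            n_perm=cfg.n_perm,
            seed=cfg.seed,
        )
        pd.DataFrame([enr.__dict__]).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        metrics["enrichment_es"] = enr.ES
        metrics["enrichment_p"] = enr.p_perm
    log.info("screen stage: %d genes x %d samples", *matrix.shape)
    return metrics


def _stage_lipidomics(cfg: PipelineConfig, out: Path) -> dict:
    if cfg.synthetic:
        control, treated = synthetic.simulate_lipidomics_table(
            treatment_effect=cfg.lipid_treatment_effect, seed=cfg.seed
        )
    else:
        control = lipidomics.read_lipidomics_table(cfg.lipidomics_control_path)
        treated = lipidomics.read_lipidomics_table(cfg.lipidomics_treated_path)
    control.to_csv(out / "lipidomics_control.tsv", sep="\t", index=False)
    treated.to_csv(out / "lipidomics_treated.tsv", sep="\t", index=False)

    ct = lipidomics.saturation_ratios(control)
    tx = lipidomics.saturation_ratios(treated)
    both = ct.join(tx, lsuffix="_control", rsuffix="_treated")
    both.to_csv(out / "saturation_ratios.tsv", sep="\t")
    lipidomics.class_percentages(control).to_csv(
        out / "class_percent_control.tsv", sep="\t", header=["percent"]
    )
    changes = {
        cls: lipidomics.percent_change_totals(control, treated, cls)
        for cls in lipidomics.LIPID_CLASSES
    }
    pd.Series(changes, name="percent_change").to_csv(out / "class_percent_change.tsv", sep="\t")
    metrics = {
        "pc_percent_change": changes["PC"],
        "pe_percent_change": changes["PE"],
        "tag_sfa_ufa_fold": float(tx.loc["TAG", "sfa_ufa"] / ct.loc["TAG", "sfa_ufa"]),
    }
    log.info("lipidomics stage: %d control rows", len(control))
    return metrics


_STAGES = {
    "spectra": _stage_spectra,
    "imaging": _stage_imaging,
    "screen": _stage_screen,
    "lipidomics": _stage_lipidomics,
}


def run_pipeline(config: PipelineConfig, stages=None) -> dict:
    """Run the pipeline; returns the metrics report (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}
    for name in stages or _STAGES:
        try:
            report["stages"][name] = _STAGES[name](config, out)
        except Exception:
            log.exception("stage %r failed", name)
            raise
    manifest = {
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "metrics": report["stages"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=float)
    return report
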