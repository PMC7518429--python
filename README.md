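# ramanmet

Raman-guided subcellular metabolic phenotyping: a Python library for
analyzing how cellular lipid metabolism varies across cancer-cell
differentiation states, combining single-cell Raman / stimulated Raman
scattering (SRS) spectroscopy, bulk transcriptomics and lipidomics in one
reproducible pipeline.

## The problem

De-differentiating melanoma cells remodel their metabolism. That remodeling
is visible in several complementary data types: single-cell Raman spectra
(the lipid CH2 band at 2845 cm⁻¹ vs the protein CH3 band at 2940 cm⁻¹),
SRS ratio images (per-pixel CH2/CH3 as a lipid-to-protein map), the
composition of individual lipid droplets (unsaturated lipids at 3022 cm⁻¹
and cholesteryl esters near 2974 cm⁻¹, both referenced to the 2908 cm⁻¹
anchor), phenotype-clustered expression matrices, and lipid-class
saturation profiles. `ramanmet` implements the shared analysis core for
all of them, plus a synthetic-data generator that produces every input
with known ground truth so the whole pipeline is testable end to end.

## The model

The central statistic is **surprisal analysis** of a positive data matrix
X (features i × samples c): the log-intensities are decomposed as

    ln X_i(c) = Σ_j G_ij · λ_j(c)

where constraint j = 0 is the steady state shared by all samples and the
remaining constraints are deviations, each the product of a
sample-independent feature pattern G_ij and a sample-dependent weight
λ_j(c). The decomposition is fitted by thin SVD of ln X without centering:
G holds the orthonormal left singular vectors, λ_j(c) the singular value
times the right singular vector entry, so the full-rank sum reproduces
ln X exactly and the rank-k truncation is the optimal rank-k fit.

On Raman spectra, λ₁ is the lipid/protein axis (positive CH2 loading,
negative CH3 loading). On expression matrices, samples are mapped to
(λ₁, λ₂) and each gene's loadings (G1, G2) are turned into phenotype
contribution scores

    S_melanocytic = −G1 − G2    S_transitory      = −G1 + G2
    S_neural-crest =  G1 + G2    S_undifferentiated =  G1 − G2

so S_melanocytic ≡ −S_neural-crest and S_transitory ≡ −S_undifferentiated.

Around this core sit: Huang fuzzy-entropy thresholding and CH2/CH3 ratio
imaging (with the 5·CH2 − 0.4·CH3 lipid channel), lipid-droplet detection
and per-droplet hyperspectral quantification, a Spearman |ρ| > 0.95
gene–ratio screen with t-based Pearson p-values and a minimal pre-ranked
running-sum enrichment statistic, and lipidomics analytics (SFA/UFA and
18:0/18:1 ratios, class percentages, Z-scored acyl-chain heatmaps,
treatment percent changes).

## Worked example

```bash
python examples/01_surprisal_raman.py
```

prints

```
full-rank reconstruction max |error|: 9.10e-15
corr(lambda_1 weight, planted lipid fraction) = 0.9986
lambda_1 loading at 2845 cm^-1 (CH2, lipid):   +0.3637
lambda_1 loading at 2940 cm^-1 (CH3, protein): -0.2911
```

Fifty synthetic single-cell spectra (five groups whose lipid fraction
descends 0.6 → 0.2, 2% noise) are decomposed; the reconstruction is exact
to machine precision, and the first deviation constraint both points from
lipid (positive 2845) to protein (negative 2940) and ranks the cells by
their planted lipid fraction with r ≈ 0.999 — the spectroscopic
differentiation axis. The other examples (`examples/02`–`05`) walk through
ratio imaging and droplet spectroscopy, phenotype projection, the
gene–ratio screen, and lipidomics saturation analytics the same way.

A thin CLI mirrors the stages:

```bash
ramanmet run-all --out out_dir --seed 0     # full synthetic pipeline
ramanmet simulate --out inputs --seed 0     # just the synthetic inputs
ramanmet lipidomics control.tsv treated.tsv
```

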