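# Methods

## Surprisal analysis

A positive feature × sample matrix X is floored (entries below
`1e-6 × max(X)` are raised to that floor) and log-transformed; the model

    ln X_i(c) = Σ_j G_ij λ_j(c)

is fitted by thin SVD of ln X **without centering**. The dominant
component then plays the steady-state role (it captures what all samples
share), and the deviations are the subsequent constraints. G_ij are the
left singular vectors (orthonormal columns); λ_j(c) absorbs the singular
value, so the full-rank sum reproduces ln X exactly and the rank-k
truncation is, by the Eckart–Young theorem, the best rank-k approximation
in the Frobenius norm — the test suite verifies this against an
independent eigendecomposition of the Gram matrix LᵀL.

Sign conventions: an SVD's column signs are arbitrary, so each constraint
is flipped to make its largest-|loading| feature positive. For Raman data
an override (`pin_feature=2845`) pins the CH2 loading positive in
constraint 1, orienting the lipid direction "up" so that λ₁ weights read
directly as lipid/protein balance. Equal singular values keep the
factorization's output order; that order is not stable under exact ties.
An iterative refinement of the steady state is sometimes layered on top
of the SVD initial estimate in the surprisal-analysis literature; it is
not implemented here — plain SVD is the documented estimator.

The 2-D sample map uses (λ₁, λ₂), the two dominant deviation constraints:
λ₀ is sample-invariant up to scale and cannot separate phenotypes. The
four phenotype contribution scores are exact linear forms of the (G1, G2)
loadings (see README); because IEEE negation is exact, the identities
S_melanocytic = −S_neural-crest and S_transitory = −S_undifferentiated
hold to the bit, and the tests assert them with `==`.

Hierarchical clustering of score/expression rows uses average linkage on
Euclidean distances (SciPy). Leaf order is made platform-independent by a
fixed rule: at every merge, the subtree containing the smaller minimum
original row index goes left.

## Spectra

Quantification is windowed peak ratios after optional anchor
normalization at 2908 cm⁻¹ (the zero crossing of the droplet λ₁ pattern,
so it is insensitive to the lipid-composition axis being measured).
Defaults: `half_window = 4 cm⁻¹`, half the 8 cm⁻¹ spectral resolution;
`half_window = 0` selects the single nearest grid point, matching
single-channel acquisition at a stated wavenumber. Peak ratios are
invariant to overall intensity scale; anchor normalization is idempotent.
Resampling between grids is linear interpolation with no extrapolation.
Baseline correction is not performed (acquisitions are assumed
baseline-corrected upstream); a flat-background term is instead part of
the synthetic generator (below).

## Imaging

The cell mask minimizes Huang–Wang fuzziness: intensities are min–max
rescaled onto a 256-bin histogram and, for every candidate threshold, the
histogram-weighted Shannon entropy of the fuzzy memberships
µ = 1/(1 + |g − m_side|/C) is computed exhaustively; foreground is
strictly above the minimizing threshold. A constant image has no
separable histogram and errors.

The ratio image divides CH2 by CH3 per pixel inside the mask; pixels
outside the mask, and in-mask pixels with zero CH3, map to 0 so the image
stays displayable and averageable (stored values are not clamped; any
0–0.5 display range is rendering only). The per-cell statistic is the
mean of per-pixel ratios within the cell (not the ratio of channel
means); both agree for flat cells, and the alternative is one line of
user code on the returned arrays. The lipid channel is 5·CH2 − 0.4·CH3
with negatives clipped to zero.

Droplet detection: Gaussian smoothing (σ = 1 px), local maxima above the
in-mask mean + 2 SD, flood growth to each peak's half-maximum, then
radius ∈ [min, max] (defaults 1.5–8 px) and circularity ≥ 0.7 filters,
claiming pixels brightest-first so regions are disjoint. These detector
parameters are package defaults chosen for sub-resolution bright discs;
they are tunable. Droplet spectra are the per-wavenumber mean over the
detected region; no erosion is applied — with realistically bright
droplets the boundary dilution is within the quantification tolerance,
and eroding small regions loses more to noise than it gains.

## Association screen

Spearman ρ (average ranks) is computed per gene against the per-sample
ratio, vectorized as Pearson on ranks; constant genes are excluded with a
warning. The screen filters on |ρ| > 0.95 — with five cell lines this
admits only (near-)perfect monotone relations, which is the intended
behavior, and no multiplicity adjustment is applied (a Benjamini–Hochberg
helper is available). Pearson p-values use the exact t reference
t = r√(n−2)/√(1−r²) on n−2 df; for n = 4 this reduces to p = 1 − |r|, and
|r| = 1 is reported as the lower bound 0 with a warning.

The pre-ranked enrichment statistic is the classic weighted running sum:
hits advance by |metric|^weight normalized over the set, misses decrement
by 1/(N − |S|); ES is the extreme deviation. The null permutes gene-set
membership (random same-size sets), matching the pre-ranked scheme; p is
one-sided toward the observed sign with the +1 correction, and NES
divides ES by the mean |null ES| of the same sign. At weight 0 the ES of
a set and of its complement are exact negatives.

## Lipidomics

Tables are long-format rows (class, species xx:yy, condition, replicate,
concentration). SFA means zero double bonds; everything else is UFA.
Ratios are computed on replicate-averaged totals by default ("overall
concentration ratios"); a per-replicate mode averages ratios instead.
Percent changes of class totals likewise default to replicate means, with
a pooled mode (identical when replicate counts match). Z-scoring is per
column with sample SD (ddof = 1); constant columns map to zeros with a
warning so heatmaps render complete.

## Synthetic data

The generators define the test conditions:

- **Spectra**: each cell's spectrum is f·CH2 + (1−f)·CH3 + minor bands
  (=C–H 3022, CE 2965/2985, scaled 0.25 + 0.75·f so they ride on the
  lipid pool), all Gaussian with FWHM 8 cm⁻¹ on a 2800–3050 cm⁻¹ grid at
  2 cm⁻¹ steps, plus a flat background of 30% of the peak intensity and
  Gaussian noise (default 2% of peak). Five groups of ten spectra with
  lipid fractions 0.6 → 0.2 mimic five cell lines ordered by
  differentiation. The background level matters: cellular Raman spectra
  never drop to zero between bands, and without the offset the log
  transform turns off-peak noise into the dominant variance component,
  which no real C–H-region spectrum exhibits. Recovery of the lipid axis
  is insensitive to the exact level (r ≈ 0.998 anywhere in 20–40%).
- **SRS fields**: non-overlapping elliptical cells on a jittered grid
  with per-cell CH3 level and planted CH2/CH3 ratio (0.15–0.45); droplets
  are discs (radius 2–6 px) adding 4.0 to CH2, kept fully inside a cell
  and mutually separated; background noise SD 0.01. The hyperspectral
  variant assigns cell pixels a lipid-fraction-0.4 spectrum (plus 30%
  background) and droplet pixels a CH2-dominated spectrum whose 3022/2908
  and 2974/2908 anchor ratios are pinned to the planted values, scaled to
  the bright-disc amplitude.
- **Expression**: 2000 genes × 32 samples (four phenotypes × 8) on a
  latent differentiation axis with a lipid/protein ratio descending along
  it; 40 planted genes respond monotonically (alternating sign,
  log-slope 2), 200 genes carry phenotype cluster structure, the rest is
  log-normal noise. Values are strictly positive (FPKM-like).
- **Lipidomics**: six classes × six acyl chains × three replicates, class
  abundances weighted so membrane phospholipids dominate and TAG + CE
  stay a minor (~5%) fraction, as in an untreated lipidome. Treatment
  multiplies saturated species by 1 + effect, divides TAG 18:1 by the
  same factor, and rescales PC/PE uniformly so their class totals rise by
  the reference +40.2% / +38.6%; replicates get 2% multiplicative noise.

Every generator is a pure function of (parameters, seed); identical seeds
give identical outputs, and the returned truth objects carry everything
needed to score recovery.

What the generators do **not** emulate: instrument drift, fluorescence
backgrounds with spectral shape, cosmic rays, cell-to-cell spectral
heterogeneity beyond the lipid fraction, optical sectioning or
point-spread blur beyond the droplet smoothing, library-size or batch
effects in expression, and isotope or adduct structure in lipidomics.
Passing tests therefore demonstrate that the analysis recovers the
planted statistical structure under the stated noise, not that it would
be robust to every artifact of real acquisitions.

## Problem sizes and determinism

Default test/report sizes — 50 spectra × 126 wavenumbers, 256² images
with 12 droplets, 2000 × 32 expression, 50 random 6 × 4 matrices for the
truncation oracle, 1000 enrichment permutations — run the whole suite in
seconds while leaving every recovery margin wide (e.g. λ₁ correlation
≈ 0.998 against the 0.95 requirement). All randomness flows from a single
integer seed per run; reruns are byte-identical.

## Known limitations

- The Huang threshold is histogram-based; images whose dynamic range is
  dominated by a few hot pixels compress the histogram and can shift the
  threshold.
- The droplet detector assumes bright, round, well-separated droplets;
  touching droplets merge into one half-maximum basin and are counted
  once (the circularity filter then often rejects the pair).
- Surprisal constraints beyond λ₁ on Raman data are noise-dominated at
  the default noise level, as expected for a one-axis generative model.
- The enrichment statistic implements only the pre-ranked running sum
  with gene-set permutations — no collapse to symbols, FDR across
  collections, or leading-edge reports.
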