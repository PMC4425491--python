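# Methods

This note documents the models, estimators, default parameters and design
choices behind `cohortcna`, and what the synthetic-data validation does and
does not demonstrate.

## Signal model

A SNP array reports, per probe, a Log R Ratio `r` (log2 total-intensity
ratio against a diploid reference; a compressed proxy for total copy
number) and a B-allele frequency `b` in [0, 1]. A tumour specimen is
modelled as a mixture of a fraction ρ of tumour cells with integer local
allele copies (n_A, n_B) and 1−ρ normal cells with one copy of each allele:

    r = γ · log2( (2(1−ρ) + ρ(n_A+n_B)) / (2(1−ρ) + ρψ) )
    b = (g_B(1−ρ) + ρ t_B) / (2(1−ρ) + ρ(n_A+n_B))

with ψ the tumour ploidy (probe-weighted mean total copy number), γ the
platform compression factor, g_B ∈ {0,1,2} the germline B-allele count and
t_B the tumour B count (n_B at germline-heterozygous probes). The inverse
map from segment-mean (r, b) to continuous allele copies is closed-form
(`ascat.invert_signal`) and exact on the model's domain. A homozygous
deletion in a pure tumour leaves no DNA: `predict_signal` returns NaN BAF
and a −8.0 LRR sentinel (a −∞ surrogate).

## Preprocessing

*GC correction* (tumour LRR only): a least-squares line of LRR on
window-smoothed local GC (running mean over 1 Mb, probes' `gc_fraction`
supplied by the manifest) is subtracted and the result re-centred to the
input median. This removes the slow GC-correlated "wave" without touching
copy-number structure; the full multi-window regression of dedicated wave
tools is deliberately not reimplemented.

*Quantile normalization*: order statistics are mapped onto
Φ⁻¹((i−0.5)/n)·scale, with scale anchored to the median per-sample germline
LRR standard deviation so thresholds are comparable across arrays. It is a
rank-only transform intended to remove technical skew in real arrays; the
synthetic generator produces no such artifact and the rank-to-Gaussian map
would distort true segment amplitudes, so validation runs leave it off
(`apply_quantile=False`, the pipeline default; switch it on for real data).

*Winsorization*: values outside running-median (25-probe window) ± k·MAD
(scaled by 1.4826, k = 2.5) are clamped per chromosome before single-track
segmentation. On noise-free input the MAD is 0 and any probe off its
running median collapses onto it — a single spike is still removed.

## Segmentation

`pcf` computes the exact minimizer of Σ(y−fit)² + γ_pcf·(#breakpoints)
subject to ≥ kmin probes per segment by an O(n²) dynamic program
(vectorized inner loop; ties broken toward fewer segments, then the
leftmost final breakpoint). Defaults γ_pcf = 80 on MAD-standardized data,
kmin = 10. An optional coarsening pre-step (block candidates plus local
refinement) exists for very long tracks but is not needed at the default
chromosome sizes. Correctness is checked against an independent
segment-count dynamic program on thousands of random signals.

`aspcf` segments LRR and mirrored BAF (|b−0.5|+0.5 at germline-het probes)
jointly with shared breakpoints constrained to the het-probe grid; each
track's SSE is divided by its robust variance (squared MAD of first
differences / √2) so the two tracks are commensurable. The breakpoint
penalty (0.80) is interpreted on the raw squared-error scale of the LRR
track and converted internally (penalty/var_LRR); a variance-standardized
penalty of 0.8 would sit below the ~1σ² chance gain of a spurious
breakpoint and over-segment any realistic track. When the measured noise is
at the numerical floor the penalty stays on the raw scale, which is
negligible against the floor-standardized cost of any true step — so on
noise-free input every real breakpoint is taken and exactly flat stretches
are never split.

*Folded-mean correction.* Mirroring folds BAF noise upward: a balanced
segment's mirrored mean is biased to 0.5 + σ√(2/π) rather than 0.5, and the
1/ρ amplification of the inversion turns this into a systematic pull toward
ρ = 1. With x = b−0.5 ~ N(δ, σ), the mirrored data give E|x| in closed form
and E[x²] = δ² + σ² exactly, so each segment's band offset δ is recovered
from its first two mirrored moments alone (`folded_mean_correct`). The
correction is the identity at zero noise and for bands far from 0.5.

## Purity and ploidy

The grid search (ρ: 0.10–1.00 step 0.01; ψ: 1.0–5.5 step 0.05; γ = 0.40)
inverts each het-bearing segment's means at every grid cell and scores

    D(ρ, ψ) = Σ_seg w_seg [ (n_A_raw − [n_A_raw]₊)² + (n_B_raw − [n_B_raw]₊)² ]

with w_seg the het-probe count and [·]₊ the nearest non-negative integer
(half-up). Segments without het probes receive copy numbers from LRR alone
(total split evenly) and contribute only to the reported ploidy.

The raw distance alone does not identify the solution:

* **Noise bias.** The inversion amplifies probe noise by 1/ρ, so D is
  systematically cheapest at ρ = 1 whatever the data. With measured
  per-probe noise (estimated from first differences), D is debiased by its
  propagated expectation (capped at the 1/12 variance of a rounding
  residual); cells whose debiased distance exceeds 50 null standard
  deviations, or whose variances are mostly capped (no allele resolution),
  are infeasible. The generous threshold absorbs systematic
  breakpoint-placement error that propagated probe noise does not cover.
* **Ghost solutions.** The model admits exact alternative interpretations:
  (n_A+k, n_B+k) at ρ/(1−ρ)-type remappings, doubling (2n_A, 2n_B) at
  ρ/(2−ρ) with ψ′ = 2ψ, and an all-odd mid-map. These fit the data
  identically, so selection is by parsimony: among feasible cells the
  lowest ploidy wins (then the best debiased fit, then the higher ρ).
  Candidate genomes that are implausible as tumours — more than 60% of het
  weight in LOH (the genome-wide-LOH ghost of a triploid) or more than 5%
  homozygously deleted — are vetoed.
* **Grid quantization.** The ψ grid step (0.05) lets the optimum trade a ψ
  offset against a ρ shift of up to ~0.05 along the valley
  2(1−ρ)+ρψ ≈ const. After cell selection, (ρ, ψ) is polished by
  multi-scale coordinate descent in (ρ, denominator) space, where the
  valley is axis-aligned, re-deriving the integer assignment each round.
  On noise-free input the exact-match path refines each ψ column's best
  cell and compares refined distances.

The reported ψ is the probe-weighted mean of the fitted integer totals.
Goodness of fit is 1 − D_selected / (95th percentile of D over the grid);
profiles under 0.80 are rejected, which reproduces the handful of
unfittable tumours seen in real cohorts. The 0.80 gate and the veto
fractions are policy defaults, exposed in `AscatParams`.

Identifiability has hard limits: a genome whose truth is all-even
(balanced tetraploid without odd or LOH segments) is exactly equivalent to
its halved diploid, and an all-odd genome to its mid-mapped version; no
estimator can resolve these from (LRR, BAF) alone.
`simulate.truth_identifiable` encodes this predicate and the validation
excludes such samples (about 2 of 113 in the default cohort).

## Calling, recurrence, annotation

Threshold mode: segment mean > 0.05 is a gain, < −0.05 a loss (strict, as
the thresholds are exclusive bounds). Allele-specific mode compares each
segment's total with the tumour's rounded ploidy; LOH requires n_B = 0 and
at least one germline-het probe in the segment (so uninformative segments
cannot drive LOH); copy-neutral LOH additionally requires a neutral total;
homozygous deletion is total 0. Frequencies are exact counts over samples;
recurrence is inclusive (≥ 20% of tumours, or ≥ 20 tumours in
allele-specific mode) over maximal probe runs. Gene annotation intersects
half-open intervals (≥ 1 bp overlap) against a user-supplied BED.

## Permutation significance

The statistic at probe j is G_j = Σ_samples segmented value, optionally
split into positive/negative part sums. Each of n_perm (default 1000)
replicates permutes every sample's per-probe segmented values across
genomic locations independently within the sample, preserving each
sample's value multiset while destroying genomic alignment, and the
pointwise p-value is (1 + #{|null| ≥ |observed|}) / (1 + n_perm) (add-one:
p > 0 always). Benjamini–Hochberg step-up (implemented directly,
cross-checked against statsmodels) controls FDR at 5%; in the split mode
the amplification and deletion statistics are adjusted separately, as
their peak regions are reported separately. For cohorts with several
tumours per animal, `split_by_dog` builds two analysis sets with one
tumour per animal each (singles in both; triples 2/1, seeded random) plus
the all-tumours set. Probe-level permutation was chosen as the unit
because the statistic itself is defined per location; the permutation
preserves per-sample marginals but not segment-length autocorrelation,
which makes the pointwise null slightly conservative for long-segment
samples.

## Group contrasts

For each of six histopathological malignancy parameters (solid growth,
myoepithelial cells, nuclear pleomorphism, mitotic index, invasive growth,
necrosis) the per-probe aberration frequency of the low subgroup is
subtracted from the high subgroup (the myoepithelial contrast is reversed:
absence of myoepithelial cells is the malignancy-associated level), plus
hyperplasia-vs-malignant and benign-vs-malignant. Ordinal scores map 0 vs
{2,3} for pleomorphism and mitotic index — the intermediate score 1
belongs to neither level rather than being binned arbitrarily — and 0 vs
≥1 for the others. Runs with a difference ≥ 20 percentage points are
reported per direction; the contrasts are descriptive (no test), matching
their screening role.

## Synthetic cohorts

The generator emulates a matched tumour/germline SNP-array cohort:
default 113 tumours in three malignancy groups (12/55/46) on 4 chromosomes
× 5,000 evenly spaced probes (a full-scale 39-chromosome ~170K layout is
available but not exercised routinely); germline genotypes AB with
probability 0.33, else AA/BB equally; purity Uniform(0.24, 1.00) rounded
to 0.01 (the analysis grid step); ploidy mixture 74% diploid, 9%
tetraploid, 13% triploid-like, 2% hypodiploid, 2% highly polyploid.
Genome-doubled baselines carry two pre-doubling LOH regions and one
post-doubling single-copy event — the standard signatures of
whole-genome duplication, without which balanced tetraploids are
unidentifiable in principle. Group-structured recurrent events mirror the
motivating cohort's anchors (an oncogene-like amplicon at 16.7%/9.1%/30.4%
across groups, a rare tumour-suppressor-like homozygous deletion,
telomeric losses enriched with malignancy, a cnLOH region), and every
tumour receives ≥ 1 private event (1 + Poisson(1.5)), since a tumour with
no aberration has unidentifiable purity. Observed signals come from the
forward model plus reflected Gaussian noise (LRR sd 0.15, BAF sd 0.03) and
a GC-tied LRR wave (amplitude 0.08); at a pure-tumour homozygous deletion
the array reports noise around BAF 0.5, which the generator emulates. The
noise-free configuration also places het probes at truth-segment
boundaries, making every boundary identifiable at probe resolution so
exactness checks isolate algorithmic correctness from boundary
unobservability.

What passing the synthetic validation shows: the estimators recover the
generating model's parameters and calls under realistic noise levels and
cohort structure. What it does not show: robustness to features the
generator omits — probe-specific biases, genotyping-cluster artifacts,
subclonal (non-integer) copy number, segmental noise autocorrelation
beyond the GC wave, and platform-specific BAF asymmetries. Results on real
arrays depend on those.

## Numerical choices and degenerate inputs

Robust scale estimates use median(|Δy|)·1.4826/√2 with a 1e-4 floor;
chromosomes with fewer probes than kmin become single segments (warned);
chromosomes without het probes are flagged and skipped by the
allele-specific fit; a sample with no het-bearing segments yields no
profile (logged, as in real cohorts). BAF read from disk is clamped into
[0, 1] within 1e-3 (warned) and rejected beyond. All randomness flows
through explicit seeds; reruns of the pipeline with the same config and
seed are bit-identical.

## Validation problem sizes

The bundled validation uses the default 113-sample cohort at 4 × 5,000
probes for parameter recovery, 200 random signals (n ≤ 60) against the
segmentation oracle across penalty/kmin grids, and 20 null plus 20 spiked
40 × 2,000-probe cohorts at 200 permutation replicates for the
significance test, with the spiked region spanning 300 probes — sized so
that the add-one p-value floor at 200 replicates can pass the 5% FDR
step-up (a smaller region cannot reach significance at this replicate
count regardless of effect size).
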