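# cohortcna

Allele-specific copy-number aberration (CNA) analysis of SNP-array tumour
cohorts: preprocessing of Log R Ratio (LRR) and B-allele frequency (BAF)
tracks, penalized piecewise-constant segmentation, purity/ploidy estimation
with integer allele-specific copy numbers, aberration/LOH calling and
recurrence analysis, a permutation test for recurrent aberrations, and
frequency contrasts between histopathological subgroups. A bundled
synthetic-cohort generator with full ground truth exercises every stage.

The package is aimed at cancer-genomics analysts working with matched
tumour/germline SNP-array cohorts — the motivating setting is canine mammary
tumour cohorts profiled on ~170K BeadChips (38 autosomes + X, mixed
diploid/aneuploid tumours, purities from ~24% to 100%), but nothing is
species-specific.

## The model

At a germline-heterozygous SNP, a tumour with aberrant cell fraction ρ,
ploidy ψ (mean copy number over the tumour genome) and local allele-specific
copy numbers (n_A, n_B) is expected to show

    r = γ · log2( (2(1−ρ) + ρ(n_A+n_B)) / (2(1−ρ) + ρψ) )        (LRR)
    b = (1 − ρ + ρ n_B) / (2(1−ρ) + ρ(n_A+n_B))                  (BAF)

where γ is the platform compression factor (0.40 by default). The pipeline:

1. **Preprocess** tumour LRR: GC-wave removal (linear regression on
   window-smoothed local GC), optional quantile normalization to a Gaussian
   reference, and winsorization at running-median ± 2.5·MAD.
2. **Segment**: single-track PCF (exact dynamic program minimizing
   SSE + γ_pcf·breakpoints, γ_pcf = 80, ≥ 10 probes per segment) for
   threshold calls; joint allele-specific PCF (shared breakpoints on LRR +
   mirrored BAF, penalty 0.80) for the allele-specific stage.
3. **Fit purity/ploidy**: grid search over (ρ, ψ) inverting segment means to
   continuous allele copies and scoring their distance to non-negative
   integers, with noise debiasing, plausibility vetoes, lowest-ploidy
   selection among exactly equivalent interpretations, and continuous
   polishing. Ploidy classes: hypodiploid < 1.8, diploid 1.8–2.2,
   tetraploid 3.8–4.2, highly polyploid > 4.2.
4. **Call**: gains/losses relative to segment mean ±0.05 (threshold mode) or
   to the rounded tumour ploidy (allele-specific mode), plus LOH (n_B = 0),
   copy-neutral LOH and homozygous deletions; cohort frequency tracks;
   recurrent regions (≥ 20% of tumours, or ≥ 20 tumours in allele-specific
   mode); gene annotation against a user-supplied BED.
5. **Significance**: per-location sums of segmented values across samples
   compared with a within-sample permutation null (1000 replicates by
   default), Benjamini–Hochberg FDR at 5%, significant regions per
   direction, and the split-pairs/all-tumours three-set design for cohorts
   with multiple tumours per animal.
6. **Contrast**: aberration-frequency differences (≥ 20 percentage points)
   between subgroups of six histopathological malignancy parameters and
   between malignancy groups.

## Worked example

```python
from cohortcna import ascat, calls, preprocess
from cohortcna.simulate import SimConfig, simulate_cohort

cfg = SimConfig(n_per_group={"hyperplasia": 2, "benign": 4, "malignant": 4},
                probes_per_chrom={"chr1": 1500, "chr2": 1500,
                                  "chr3": 1500, "chr4": 1500},
                seed=42)
tracks, metadata, truths = simulate_cohort(cfg)
tracks.tumour_lrr = preprocess.preprocess_tumour_lrr(
    tracks.tumour_lrr, tracks.manifest, apply_quantile=False)
profiles = ascat.fit_cohort(tracks)

ascat_calls = [calls.call_ascat(p, tracks.manifest.n_probes)
               for p in profiles.values()]
freq = calls.cohort_frequencies(ascat_calls)["all"]
regions = calls.recurrent_regions(freq, tracks.manifest, mode="fraction",
                                  threshold=0.20)
```

prints (comparing estimates with the generator's truth):

```
profiles obtained for 9 of 10 tumours

  sample true rho  est rho true psi  est psi  ploidy class
 hyp_001     0.69     0.68     2.00     2.00  diploid
 ben_000     0.73     0.67     3.90     3.90  tetraploid
 ben_001     0.83     0.78     2.96     2.96  aneuploid_other
 ben_002     0.35     0.34     2.97     2.96  aneuploid_other
 ben_003     0.59     0.56     2.09     2.08  diploid

13 recurrent regions (>=20% of tumours); first three:
  chr1:32840000-39720000  gain  peak 0.22
  chr4:27060000-47220000  gain  peak 0.33
  chr1:61560000-82200000  loss  peak 0.33
```

One tumour is rejected at the goodness-of-fit gate (a small failure rate is
expected and mirrors real cohorts); estimated purity and ploidy track the
truth closely, and the group-structured gains/losses built into the cohort
design surface as recurrent regions.

The same analysis is available from the shell:

```bash
cohortcna run-all --outdir demo_run --seed 42      # built-in synthetic demo
cohortcna simulate --seed 1 --outdir cohort/       # write a cohort as TSVs
cohortcna ascat --indir cohort/ --outdir out/      # purity/ploidy per sample
```

## Layout

| module | contents |
|---|---|
| `cohortcna.io` / `datatypes` | manifest/track/metadata containers, TSV/BED/bedGraph I/O |
| `cohortcna.preprocess` | GC correction, quantile normalization, winsorization |
| `cohortcna.segmentation` | exact PCF, mirrored BAF, joint ASPCF |
| `cohortcna.ascat` | forward model, inversion, purity/ploidy grid fit |
| `cohortcna.calls` | call rules, frequencies, recurrence, gene annotation |
| `cohortcna.significance` | permutation test, BH FDR, significant regions |
| `cohortcna.contrast` | histopathology subgroup contrasts |
| `cohortcna.simulate` | synthetic cohorts with ground truth |
| `cohortcna.pipeline` / `cli` | YAML-configured end-to-end runs, subcommands |

See `docs/methods.md` for the statistical methods, default parameters and
known limitations.
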