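# Methods

## Scope and data model

The pipeline starts from per-sample CpG count data (Bismark-style cytosine
reports: chrom, 1-based position, strand, methylated count, unmethylated
count) for two groups of replicates, labelled CD8 (reference) and DN
(case).  CpGs are kept strand-specific as reported; the two cytosines of a
CpG dyad are never merged.  Cytosine reports use 1-based positions; all
interval work (BED, bedGraph, peaks, shuffles) is 0-based half-open, and a
DML point is `pos - 1` in interval space.

## Coverage filter

A CpG is retained when its coverage, summed over each group's replicates,
is at least `min_cov` (default 10) in both groups.  The pooled-per-group
reading was chosen over per-sample because the filter is stated per group,
and pooled filtering is the common practice for replicate bisulfite designs;
a strict per-sample mode is available (`per_sample=True`).  The filter is
idempotent and monotone in `min_cov` (property-tested).

## Conversion-efficiency QC

Bisulfite conversion is estimated from spike-in control cytosines in an
unmethylated context: efficiency = converted / total, pooled per sample,
with a configurable pass threshold (default 0.99).

## Beta-binomial Wald test

Counts are modelled beta-binomially with per-CpG dispersion `phi`:
`Var(X) = N mu (1-mu) (1 + (N-1) phi)`.

*Dispersion estimation.*  For each group the sample variance of replicate
proportions around the pooled group mean has expectation
`mu(1-mu) * mean_r[1/N_r + phi (N_r-1)/N_r]`; solving for `phi` and pooling
numerator and denominator over the two groups (weights `n_g - 1`) gives a
method-of-moments estimate, clamped at 0.  Estimates are shrunk on the log
scale toward the genome-wide prior `(m0, r0^2)` — the mean and variance of
`log phi_hat` over CpGs with finite positive estimates — with weight
`w_i = r0^2 / (r0^2 + s_i^2)` and sampling variance approximated as
`s_i^2 = 2/(n_eff - 1)`, `n_eff` the number of covered replicates.  CpGs
with undefined or zero raw estimates receive `exp(m0)`.  When no finite
positive estimate exists at all, the weakly informative fallback prior
`(log 0.01, 1)` is used.  Conditioning the prior on positive raw estimates
biases `m0` upward slightly (zero/negative moment estimates, which indicate
small dispersion, are excluded); this makes the test mildly conservative,
never anticonservative, and is accepted as the price of a closed-form
estimator.

*Test.*  With pooled group proportions `mu_g = sum X / sum N` and

    Var_g = mu_g (1 - mu_g) * sum_r N_gr (1 + (N_gr - 1) phi_i) / (sum_r N_gr)^2

the statistic is `t = (mu_DN - mu_CD8) / sqrt(Var_CD8 + Var_DN)` with a
two-sided standard-normal p-value (no small-sample t correction; Wald
convention).  When both group means are degenerate (0 or 1) the variance is
recomputed with the continuity-corrected mean `(sum X + 0.5)/(sum N + 1)` so
the statistic stays finite and keeps its sign.  P-values are floored at
1e-300 to stay in (0, 1].

*Calling.*  Benjamini–Hochberg FDR (step-up with monotonicity enforcement)
across all tested CpGs; a DML requires `FDR < 0.05` **and**
`|delta| > 0.20`, both strict, so ties at a threshold are not significant.
The source study's text states the effect threshold once as "<20%" and once
as ">20%"; the ">20% required" reading is implemented, since a
significance rule that demands a *small* effect is not meaningful.

No spatial smoothing is applied: dispersion shrinkage plus the Wald test is
a self-contained single-CpG procedure, and equivalence with any particular
published implementation is not claimed — calibration and power are instead
established by simulation (see below).

## Annotation and expression integration

Each DML is assigned to the gene with the nearest TSS on its chromosome by
absolute point distance, strand-ignored (the minimal assumption when only
"nearest TSS" is specified); the signed distance `pos - tss` is reported.
Equidistant ties go to the lexicographically smallest gene id; a
configurable maximum distance cap exists but is off by default.  Integration
reports the genes both upregulated and carrying hypomethylated DML, the DML
mapping to significantly changed genes (split by direction), quadrant counts
of the (Δmethylation, Δexpression) plane, and genes ranked by their count of
hypomethylated DML (ties by gene id).

## Interval enrichment

Peak sets are merged with overlapping *and* book-ended intervals coalesced
(the behaviour of the standard merge tools).  A DML "overlaps" a peak at
window `w` when the peak extended by `w` on both sides contains the DML
point; each DML counts once.  The permutation null re-places every peak
uniformly across the genome — chromosome chosen with probability
proportional to its length, start uniform on the feasible range, overlaps
among shuffled peaks permitted, lengths preserved exactly.  The empirical
p-value is the fraction of permutations whose overlap count is *strictly
greater* than observed; `0/n` is reported as `<1/n` rather than using an
add-one correction, matching the convention of reporting `p < 0.001` at
1000 permutations.  Signal aggregation around anchors uses
coverage-weighted means over equal bins in `[pos - flank, pos + flank)`
(default flank 2 kb), zero-filling gaps and zero-padding windows truncated
at chromosome edges (flagged).  Naive-vs-effector accessibility at DML is
compared by an equal-variance two-tailed two-sample t test on per-anchor
window means.

## Motif analysis

Windows of 400 bp total (±200) around hypomethylated DMLs are scanned on
both strands with log-odds PWMs (`log2((p + 0.01)/(1 + 0.04) / 0.25)`,
uniform background); a position is a hit at ≥ 0.8 of the maximum score
(configurable).  Enrichment per PWM is a one-sided binomial test of the
foreground hit-window count against the background hit fraction; background
windows are CpG-anchored, sampled at twice the foreground count away from
foreground windows, and matched to foreground GC content in quintile bins.
CpG-anchored backgrounds deliberately *preserve* the restriction-site
composition of enzyme-digest (MspI/TaqI) libraries, so the CCGG and TCGA
"motifs" shipped in the bundled PWM library act as positive controls rather
than being masked.  The bundled MEME-format library also carries AP-1
(TGACTCA), a T-box motif and an EGR zinc-finger motif.

## Synthetic data

The generator emulates the statistical structure of a two-subset RRBS study
with three purifications per subset:

- **Genome** — Bernoulli-placed CpG dyads (density 0.01 by default) on one
  or more chromosomes; optional random background sequence with `CG` written
  at every catalogued position.
- **Baselines** — a two-component Beta mixture with modes 0.05 and 0.95
  (weights 0.45/0.55, concentration 12), mimicking the strongly bimodal
  genome-wide methylation distribution of CpG-enriched libraries.
- **DMRs** — non-overlapping clusters of 10 consecutive CpGs, covering ~5%
  of CpGs, hypo:hyper 96:4 by default; inside a DMR the DN mean is
  `baseline + delta` (delta constrained so means stay in [0, 1]).  All CpGs
  inside DMRs form the emitted truth table.
- **Counts** — coverage is a shifted negative binomial (minimum 1, mean 20,
  size 5 — overdispersed, creating realistic loss at the ≥10 filter);
  methylated counts are beta-binomial with dispersion `phi = 0.02`
  (`phi = 0` degenerates to plain binomial, moment-tested).
- **Spike-in** — converted counts `Binomial(depth, 0.995)` per control site.
- **Peaks/signal** — effector peaks placed so a configurable fraction
  (default 0.9) of truth DMLs lie within 500 bp of a peak, plus uniform
  background peaks for both conditions; binned signal tracks are elevated
  inside each condition's peaks.
- **Expression** — genes whose TSS is nearest to a hypo truth DML are
  upregulated with probability `coupling` (default 0.8); others draw from a
  zero-centred null; flags use `p < 0.05` and `logFC > 1`.
- **Motif planting** — a consensus is written at a uniform offset within
  ±200 bp of an anchor with a given probability, never overwriting a
  catalogued CpG dyad (infeasible anchors are skipped and logged).

All randomness derives from one master seed through named substreams (CRC32
of the stage name), so any stage regenerates independently and the whole
pipeline is byte-reproducible.  What the generator does **not** emulate:
read-level error, fragment-based coverage correlation along the genome,
CpG-island structure, strand asymmetry, batch effects, and mapping artefacts
— so passing tests demonstrate correctness of the statistical machinery
under the stated model, not robustness to those real-data phenomena.

## Calibration and known limitations

- On null simulations at the defaults (3v3, 20x, phi 0.02, ~50k CpGs),
  essentially no CpGs are called significant, and the raw p<0.05 fraction is
  ~0.013 — conservative.  The conservatism is concentrated at the ~74% of
  CpGs with methylation near 0 or 1 (the bimodal baseline), where a Wald
  statistic on discrete counts cannot reach nominal size; CpGs with
  intermediate methylation calibrate at 0.03–0.07.  Fixing the dispersion
  at its true value changes this only marginally, i.e. the effect is
  structural, not an estimation artefact.
- With spiked `|delta| = 0.5` at 30x coverage, sensitivity on truth DML is
  ~0.96 and precision ~0.99 across seeds, and the called hypo fraction
  tracks the realized spiked mixture within 3 points.
- Problem sizes used in the test and acceptance runs (5k–50k CpGs, 1000
  permutations, 10–20 calibration seeds) were chosen as the smallest scales
  at which the binomial/Monte-Carlo error bands in the assertions are
  meaningful.
- Single-factor two-group designs only; no smoothing-based DMR segmentation,
  no paired tests, no covariates.  The shuffle null is genome-wide and
  unmatched (no GC/blacklist constraints).  The permutation p-value
  resolution is `1/n_perm`.
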