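# Methods

## Problem and data model

RT-qPCR quantifies a transcript through its quantification cycle Cq: the
PCR cycle at which fluorescence crosses threshold, one cycle lower per
doubling of template. Comparing a target gene across samples therefore
requires removing per-sample differences in cDNA input. That removal is
done by dividing by one or more *reference genes*, and the whole point of
this package is to decide which candidates deserve that role for a given
experiment — here modelled on muscle satellite cells sampled in a
proliferation phase (GM) and at two differentiation time points (DM1,
DM5), with three biological replicates per phase measured in technical
triplicate.

The central container is a genes × samples Cq matrix with per-sample
metadata (group, biological replicate, technical replicate). Validation is
strict: unique gene symbols, Cq ∈ (0, 45], no silent missing values.
Technical replicates are averaged arithmetically on the Cq scale before
any stability analysis (all four algorithms assume one observation per
biological sample); replicate sets whose SD exceeds 0.5 cycles — an
ordinary wet-lab QC bound, configurable — are flagged but never dropped
automatically. Missing Cq values are a hard error by default; the optional
complete-case mode removes the affected sample column entirely and never
imputes, because every algorithm here needs a complete matrix.

## Relative quantities

Per gene, ΔCq = Cq − Cq(min over samples) and Q = 2^(−ΔCq), so Q ∈ (0, 1]
with the most abundant sample at exactly 1. Base 2 assumes perfect
doubling; measured per-assay efficiencies are deliberately *not* folded
into Q in the default pipeline (the validation workflow this mirrors does
not efficiency-correct), but `relative_quantity` accepts per-gene
efficiencies and then uses (1+E)^(−ΔCq) for users who want correction.
Because the anchor is per-gene, Q is invariant to per-gene additive Cq
shifts; that invariance and the per-sample loading-shift invariance of the
stability statistics are asserted to 1e-9 in the test suite.

## Stability algorithms

**geNorm.** For genes j,k: V_jk = SD_s[log₂(Q_j(s)/Q_k(s))] (sample SD,
n−1 denominator, as throughout), and M_j = mean_{k≠j} V_jk. Ranking is by
stepwise exclusion: remove the argmax-M gene (ties broken
lexicographically and recorded in the trace), recompute, stop at two
genes. The final pair is inseparable by construction (both genes of a
two-gene set share one M), yet a total order is wanted; we order the pair
by full-panel M, ties again lexicographic, and record this choice in the
result. The pairwise-variation curve uses NF_n(s), the geometric mean of
the n most stable genes' quantities, and V_{n/n+1} = SD_s[log₂(NF_n/NF_{n+1})];
the optimal reference count is the smallest n with V_{n/n+1} < 0.15
(strict, configurable), falling back to k with a warning when no V clears
the threshold.

**NormFinder-style.** On y = log₂ Q with k genes, G groups, n_g samples
per group, the model splits a gene's variation into intragroup variance
σ²_ig and a systematic gene-by-group interaction d_ig. Sample-centering
(subtracting each sample's gene-mean) removes loading effects exactly but
biases the naive within-group variances: E[s²_ig] = σ²_ig(1−2/k) + σ̄²_g/k.
With σ̄²_g estimated as (k/(k−1))·mean_i s²_ig, inversion gives the
unbiased σ̂²_ig = max(0, (s²_ig − σ̄²_g/k)/(1−2/k)) — whence the k ≥ 3
requirement (the factor vanishes at k = 2). The intergroup variance γ̂²_i
comes from a moment estimator on the d_ig, group differences are shrunk by
γ̂²/(γ̂² + σ̂²/n_g), and the stability value is
ρ_i = mean_g[|d̃_ig| + sqrt(γ̂²·(σ̂²/n_g)/(γ̂² + σ̂²/n_g))], lower = more
stable. All variance estimates are clamped at zero and the shrinkage terms
defined as 0 when their denominator vanishes, so degenerate (constant)
panels yield ρ = 0 rather than NaN. With a single group the interaction
vanishes and the stability value reduces to the pooled intragroup SD; the
grouped entry point falls back to this mode with a warning. The derivation
fixes the constants; the acceptance study verifies them empirically (mean
σ̂² within 15% of the generating variance at k = 10, n_g = 10 over 200
simulations — observed relative error well under 1%).

**BestKeeper.** Deliberately on raw Cq, not Q: per gene the arithmetic
mean Cq, the sample SD (a mean-absolute-deviation mode is available, since
the original spreadsheet tool used a MAD-like dispersion), CV =
100·SD/mean, and Pearson r against the BestKeeper index (per-sample
geometric mean Cq over the panel, always recomputed from the data being
analysed). Ranking is by SD ascending, ties by CV then gene symbol; r is
reported but kept out of the ranking key — the published dispersion table
for this panel contains two gene pairs whose SD and CV orders disagree,
and its printed ranks follow SD both times, which pins the key.

**Comparative ΔCt.** Gene j's statistic is mean_{k≠j} SD_s(Cq_j − Cq_k).
Since per-gene constants cancel inside an SD, this is algebraically the
geNorm M computed on unanchored Cq, and the test suite asserts that
identity; it is kept as a separate method because the four-method
consensus treats it as an independent vote, as comprehensive-ranking tools
conventionally do.

## Consensus and validation

Each method contributes integer ranks 1..k; the mean rank is the geometric
mean (arithmetic offered behind a flag), reported at 2 decimals in CSVs
and kept at full precision internally. The comprehensive rank sorts by
mean rank, ties broken by the gene's best single-method rank, then
lexicographically. Aggregation is symmetric in method order and
monotone in each method's rank — both property-tested. The published
three-method rank triplets for the ten-gene MuSC panel reproduce their
published mean ranks exactly at 2-decimal rounding under this definition,
which is what fixes geometric over arithmetic mean.

Target-gene validation uses 2^(−ΔΔCt): ΔCt_s = Cq_target,s − mean of the
reference genes' Cq in sample s (arithmetic mean on the Cq scale, i.e.
geometric mean of quantities — the standard multi-reference combination),
ΔΔCt_s = ΔCt_s − mean(ΔCt over calibrator-group samples). Centering on the
calibrator's mean ΔCt makes the calibrator group's *geometric* mean fold
exactly 1 (its arithmetic mean is ≥ 1 by Jensen's inequality); the
contract tests assert the geometric form. Group patterns are compared by
one-way ANOVA on fold changes with Tukey-HSD pairwise labels at α =
0.05/0.01. Tukey HSD stands in for Duncan's multiple range test: it is the
standard familywise-error-controlled pairwise procedure in scipy, and only
the qualitative significance pattern is part of this package's claims.

## Synthetic data generator

The generator defines the study conditions: Cq[g, well] = base_g +
effect_g(group) + loading_b + ε, with loading_b ~ N(0, loading_sd) drawn
once per biological sample and shared by all genes and technical
replicates of that sample, and ε ~ N(0, noise_sd) independent per well.
Group effects are additive in Cq (multiplicative in abundance), which is
how stage-dependent regulation manifests; the shared loading term is
precisely the nuisance normalization must remove, making the cancellation
invariants exact rather than approximate. All random draws are made before
effects are applied, so a fixed seed yields the identical noise
realisation under different effect sizes — this is what makes the
monotone-degradation checks (inflating a gene's group effect never
improves its M, ρ, or BestKeeper SD) well-posed.

The default ten-gene panel uses base Cq between 15.6 and 19.8 (abundant
transcripts, matching the observed 15–21 band for such panels), eight
genes with zero group effect, one GAPDH-like gene shifting 0.25/0.5 cycles
at DM1/DM5, and one ACTB-like gene shifting 0.7/1.4 cycles; loading SD 0.3
and technical noise SD 0.15 cycles (typical qPCR technical noise). The
FPKM generator draws mean-preserving log-normal expression profiles and
redraws each gene until its realised sample statistics respect its
designed class (candidate / low-expression / high-CV), so screening truth
labels are exact. The dilution-series generator inverts the standard-curve
relation Cq = intercept − log₁₀(input)/log₁₀(1+E).

What the generator does *not* emulate: amplification-curve shape and Cq
calling, inter-plate effects, efficiency differences between genes (Cq
noise is homoskedastic and Gaussian), primer-dimer artefacts, and any
correlation structure among genes beyond the shared loading term. Passing
the recovery tests therefore demonstrates that the algorithms identify
designed instability under realistic noise magnitudes, not that they are
robust to every pathology of real plates.

## Numerical and design choices

- SDs use the n−1 denominator everywhere; logs are base 2 throughout.
- Screening inequalities are strict (FPKM > 100, CV < 10); "FPKM > 100" is
  read as *mean* FPKM across samples, with min/median selectable.
- Efficiency fits flag, never drop: slope ≥ 0 marks the fit invalid,
  efficiencies outside 90–110% are marked out-of-band.
- Zero-mean genes in screening are excluded with a recorded reason rather
  than propagating NaN.
- Ties anywhere in ranking keys resolve lexicographically by gene symbol,
  so all outputs are deterministic and rerun-stable byte for byte.
- Problem sizes in the test and acceptance studies (100 random 5×6 oracle
  panels, 100 seeded ten-gene panels, 200 variance-recovery simulations)
  are chosen to make the Monte-Carlo rates sharp at desk scale; all
  complete in seconds.

## Known limitations

- The published per-gene M values, NormFinder stability values, and V
  curve for the motivating panel cannot be reproduced numerically because
  the underlying per-well Cq data are unpublished; the exact anchors are
  the published summary tables (rank aggregation, dispersion sort) and all
  algorithmic claims are established by oracle equivalence, invariance,
  and designed-truth recovery instead.
- NormFinder estimator variants differ in third-decimal details across
  implementations; ranks are robust to this, absolute ρ values are not.
- The stepwise geNorm trace asserts non-increase of the *mean* M across
  exclusion steps; individual surviving genes' M values can move either
  way, which is inherent to the algorithm, not an implementation artefact.
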