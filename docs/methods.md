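# Methods

## Problem and model

Somatic mutations in UV-exposed skin tumours are not uniformly distributed:
beyond per-sample load differences and megabase-scale regional rate
variation, some short (motif-sized) intervals are mutated recurrently in
many patients — the signal of interest here. The package treats each
sample's SNVs as a point set on the genome, merges all samples onto one
axis, and asks two questions at two levels of rigour:

1. **Heuristic scan**: which width-*w* windows hold at least *k* mutation
   events across all samples? This counts *events*, not distinct samples,
   because the classic promoter hotspots include single positions mutated
   recurrently in different patients; a position hit in four samples must
   clear a k = 4 threshold on its own. Window starts step by 1 bp (maximal
   sensitivity for an unstated step) and overlapping above-threshold
   windows are merged, so a reported interval is the exact union of all
   qualifying windows (oracle-tested against per-start enumeration).

2. **Background-corrected scan statistic**: for every run of k = 4 adjacent
   merged events ("4-scan") with spanned width W and local density c
   (events per sample per Mb in sliding 1 Mb windows, step 100 kb, nearest
   window-centre assignment),

       log(W + 0.5) = β₀ + β₁ log(c + 0.5) + β₂ log²(c + 0.5) + ε

   is fitted by OLS over all scans jointly; p = Φ(ε̂/σ̂) (one-sided: only
   abnormally *tight* scans are interesting) with σ̂ from residuals at
   n − 3 df; BH q-values; scans with q < 0.01 sharing at least one genomic
   position are merged into disjoint hotspots.

### Threshold calibration

Per-sample window-hit probabilities are p_i = n_i·w/G with G = 3×10⁹ bp and
n_i the sample's genome-wide SNV count; the cross-sample hit count is
Poisson-binomial. The tail P(X ≥ k) is computed by the exact O(n·k) dynamic
programme with an additive absorbing bucket at k (no 1 − Σ cancellation, so
tails of order 10⁻⁹ remain accurate; verified to 10⁻¹² against 2ⁿ
enumeration). Cohorts are tens of samples, so the exact computation is
always affordable and no normal/Poisson approximation is used. The
Bonferroni multiplier for the reported adjusted tail is caller-supplied:
the number of tested windows is a property of the scan, not the rate model.

### UV spectrum

A mutation is UV-consistent iff it is C→T with a pyrimidine neighbour on
the strand carrying the mutated C — or, mirrored, G→A with a purine
neighbour — the dipyrimidine substrate of CPD/6-4 photoproducts; neighbours
on either side qualify. Tandem CC→TT (GG→AA) pairs are same-sample SNVs at
adjacent positions on a CC (GG) reference run, paired greedily left to
right in runs of ≥ 3. Reported fractions are per mutational *event*: a
tandem pair arises from a single photoproduct, so it counts once in the UV
numerator, once in the event denominator, and once in the dinucleotide
numerator. This makes the generator parameters (`uv_fraction`,
`dinuc_fraction`, both Bernoulli fractions over events) exactly the
quantities the summary estimates; counting records instead would bias the
recovered UV fraction upward by ~0.3 pp at the default parameters.
Unknown-context (N) sites are excluded from denominators.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| w (exome / genome window) | 5 / 15 bp | TF motif width / two adjacent motifs |
| k (events per window / scan) | 4 | calibrated: P(X ≥ 4) < 10⁻⁶ at melanoma loads |
| α (calibration level) | 10⁻⁶ | tail bound for threshold choice |
| background window / step | 1 Mb / 100 kb | regional density estimator granularity |
| c and width offsets | 0.5 | keep log finite at c = 0 and W small; response offset mirrored onto the predictor |
| q cutoff | 0.01 | BH FDR level for significant scans |
| DHS flank | 50 bp | heuristic-promoter proximity |
| min distinct ChIP peaks | 3 | multi-factor support (distinct by source label, not interval) |
| promoter span (fallback) | TSS −1000/+100 | used only when gene models lack explicit promoters |
| panel filters | depth > 50; AF > 0.1; 30/20 amplicons < 100 reads | printed panel stringency rules |

## Synthetic cohorts: what they emulate, and what they do not

The generator reproduces the *structure* the detection methods key on:
heterogeneous per-sample loads (log-normal, default median 10⁵ SNVs per
3 Gb genome scaled to the simulated size — a chronically UV-exposed
melanoma-like load — log-SD 0.5), piecewise-constant per-Mb rate
multipliers (gamma, mean 1, shape 3; piecewise-constant deliberately
matches the 1 Mb background estimator granularity), i.i.d. reference
sequence at GC 0.41, the UV spectrum (97% dipyrimidine C→T/G→A events, 12%
of UV events emitted as adjacent same-sample record pairs, exactly how
callers report CC→TT), planted cross-sample clusters with independent
per-sample Bernoulli hits, and a track layer that overlays DHS plus ≥ 3
distinct-label ChIP peaks on promoter-flagged clusters only.

Two generator rules go beyond the obvious sampling scheme, both to keep
ground truth exact rather than approximate: (a) independently placed events
within a sample keep ≥ 2 bp separation, so no accidental same-sample
adjacent C→T pair can masquerade as a planted dinucleotide; (b) non-UV
background substitutions are rejection-sampled to be literally non-UV.
Random track intervals (decoys, blacklist, mappability gaps) stay ≥ 2 kb
from planted spans so planted truth is never silently filtered away.

Not emulated: trinucleotide (96-channel) signature structure, transcription-
coupled repair strand asymmetry, real DHS/ChIP track geometry, indels and
copy number, correlated hotspot occupancy across samples, and sequencing
noise. Passing tests therefore demonstrate correctness of the *statistics
and bookkeeping* under the stated generative model, not robustness to every
artefact of real call sets.

A positions-only mode (no reference) supports scan-statistic tests cheaply;
spectrum analyses require the sequence mode.

Randomness: one root seed; `SeedSequence.spawn` children per component
(reference, loads, positions, planted hits, tracks), so changing track
counts never perturbs cohort draws. Identical config + seed gives
byte-identical outputs.

## Numerical and design choices

- Internal coordinates are 0-based half-open; SNV positions are 1-based
  (VCF) and converted once on entry. "chr" prefixes are stripped on read.
- Duplicate SNV rows (same sample/position/alt) collapse with a warning;
  conflicting alts at one site in one sample raise.
- Natural logarithms throughout the width model; the base cancels in the
  residual z-scores.
- The width regression is fitted genome-wide with per-scan local density;
  a per-chromosome fit is available by scanning chromosomes separately
  (the joint fit pools information and is the default because σ̂ is shared).
- Recurrent same-position events are retained on the merged axis: a 4×
  recurrent position yields a width-1 scan, the strongest possible signal.
- Ties in event position order by sample id; widths depend only on
  positions, so ties cannot change any statistic.
- σ̂ can optionally be the scaled MAD (`robust=True`) to resist inflation by
  a handful of extreme true-cluster scans; OLS σ̂ is the default and is what
  the null-calibration figures below describe.
- Hotspot merging uses strict position sharing (connected components of the
  interval-overlap graph), matching an independent graph oracle in tests.
- Empty cohorts, empty subsets and constant covariates return explicit
  flagged results (`None` fractions, `no_variance`) rather than NaNs.

## Calibration behaviour and known limitations

Under a homogeneous Poisson null a 4-scan width is the sum of three
i.i.d. gaps, i.e. ~Gamma(shape 3), and log(W + 0.5) is left-skewed
(skewness ψ''(3)/ψ'(3)^{3/2} ≈ −0.62). The normal approximation to the
residuals is therefore imperfect in a way no sample size fixes: the pooled
null p-value distribution sits a Kolmogorov–Smirnov distance of ≈ 0.04 from
uniform (an Edgeworth estimate |γ₁|/6·φ(0) ≈ 0.041 matches what
`scripts/acceptance.py` measures as `null_pvalue_ks`). The practical
consequence is a mildly anti-conservative extreme left tail; at q < 0.01
the measured false-hotspot yield on null cohorts is ≈ 5 per 10⁴ scans
(`null_hotspots_per_10k_scans`), well below the 1% of scans that the
nominal FDR level would tolerate, but not zero. Interpretation of marginal
hotspots should lean on the regulatory-track filters, as the hotspot lists
themselves do.

Other limitations: the background estimator assumes density is roughly
constant at the 1 Mb scale; the heuristic promoter definition inherits
whatever biases the supplied DHS/ChIP tracks carry; association tests are
univariate with pairwise missing-data exclusion; and the panel-call filter
implements the stricter reading of the depth rule (every supporting
replicate must exceed the depth cutoff — configurable).

## Problem sizes used in the test suite

Oracle-equivalence suites run at exhaustive-enumeration scale (n ≤ 12 for
the 2ⁿ Poisson-binomial oracle; 20 kb chromosomes for per-start window
enumeration; 10 kb masks for interval oracles). End-to-end scan tests use
40 samples on a 10 Mb chromosome (~13–16k merged events, matching the
per-Mb density of a 10⁵-SNV melanoma genome), 50 replicates for null
calibration, and 20 planted hotspots at hit probability 0.25 for recovery
— sizes at which every statistic of interest is estimated with comfortable
margin while the full suite stays fast.
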