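# Methods

## Problem and model

`cnvaccord` tests whether copy-number variation (CNV) is associated with
case status in two independent SNP-array case-control cohorts, and
whether the association *replicates* between them. The analysis
substrate is the per-individual, per-SNP integer copy-number state
s ∈ {0, 1, 2, 3, 4} (2 = normal diploid) over an ordered autosomal SNP
map; probe intensities enter only through an optional decoding stage.
The workflow is a funnel:

1. **SNP-based testing** (per cohort). At each site the 2×5
   case/control-by-state table is tested under three carrier
   hypotheses — loss (states {0,1}), gain ({3,4}) and abnormal
   ({0,1,3,4}) — by two-sided Fisher exact tests on the collapsed 2×2
   tables, alongside a Pearson chi-square on the observed-state columns
   and a Cochran-Armitage trend test with copy numbers (0…4) as scores.
   The selection statistic is S_snp = −log10 of the smallest of the
   three hypothesis p-values.
2. **Window-based testing.** For each candidate the statistic
   S_w = Σ_j −log10 p_h(j) sums the focal site's best-hypothesis
   p-value over the window of `half_width` consecutive SNPs on each
   side, truncated at any inter-SNP gap above `max_gap` and never
   crossing a chromosome.
3. **Cross-cohort accordance.** With the larger cohort as Reference and
   the smaller as Testing, four model p-values compare state
   distributions between groups across cohorts (M00 cases/cases, M10
   Testing-controls/Reference-cases, M01 Testing-cases/
   Reference-controls, M11 controls/controls; each a Pearson chi-square
   on the 2×K group-by-state table). The relative factor

       Rf = P(M00) · P(M11) / (P(M01) · P(M10))

   is large when the case/case and control/control distributions agree
   while the cross comparisons differ, i.e. when the association
   pattern replicates. Risk loci are the window-passing sites whose Rf
   clears a data-driven cutoff (below).
4. **CNV summarization.** Maximal chains of ≥ `min_loci` risk loci with
   successive gaps ≤ 30 kb become CNV records spanning the first to the
   last member position; size in kb is (end − start)/1000 rounded
   half-up to one decimal (integer arithmetic, so 30 395 bp → 30.4 kb).
5. **Recombination context.** Each SNP's recombination level is log10
   of the maximum map rate within a 10 kb region around it; levels are
   compared across the funnel groups (not_sig / snp_based / window /
   window_Rf, each site labelled by the furthest stage passed), and
   summarized CNVs are intersected with hotspot intervals under closed
   1-based coordinates.

## Significance calibration

All FDRs are permutation-based: case/control labels are permuted
`t_pm` times (default 100) within each cohort, preserving cohort sizes,
and one shared permutation set serves the SNP-based, window-based and
Rf stages. The raw estimate at a statistic threshold t is

    FDR(t) = [Σ_m #{i : S_i^(m) ≥ t}] / (t_pm · #{i : S_i ≥ t}),

clamped to [0, 1], with ties counted by "≥". The raw ratio is not
monotone in t, so per-site FDRs are reported as q-values — each site
receives the minimum raw FDR over all thresholds it still passes —
which makes the estimate non-increasing in the statistic. Candidate
selection uses q ≤ 0.15 at the SNP stage; window selection reuses the
same ceiling (0.15) since only the attained FDRs, not the cutoff rule,
are fixed by the study design this package emulates.

For Rf the accordance (high-Rf) tail is counted by default; the low
tail is available via `tail="le"`. The final joint rule selects
window-passing sites with Rf ≥ t\*, where t\* is the smallest attained
threshold at which the permutation-expected count of null sites jointly
passing (window criterion, Rf ≥ t) drops below `fp_budget` (default 1
expected false positive genome-wide). If no threshold satisfies the
budget the selection is empty, with a warning rather than an error.

## Numerical choices

- Model p-values are floored at 1e-12 before forming the Rf ratio;
  window p-values at 1/(2·10⁶) before −log10. Recombination rates are
  floored at 1e-4 cM/Mb before log10.
- Fisher exact p-values are computed two ways that are pinned against
  each other in the tests: scipy's `fisher_exact` on the single-site
  path, and an exact vectorized hypergeometric enumeration (log-gamma
  lookup, scipy's tie tolerance of 1e-7) on the batch path that makes
  ~10⁶ permutation tests per run affordable.
- The Cochran-Armitage statistic uses the standard N·r² form and is
  cross-checked against R's `prop.trend.test` convention (χ²₁).
- Degenerate tables — a zero-variance margin, fewer than two observed
  state columns, or an empty carrier class — return p = 1 throughout.
- Ties between hypotheses are broken in the order loss, gain, abnormal.

## Locus typing

Testing and selection use the three-way best hypothesis, but CNV
records are typed from the *directional* per-locus call (loss vs gain,
whichever Fisher p is smaller; unanimity required, mixed chains →
Abnormal). The abnormal hypothesis nests the directional ones, so at a
clean deletion site sampling noise lets it win the three-way argmin
with appreciable probability; typing records by that label would flip
true deletions to "Abnormal" at random. The directional rule keeps
Abnormal for genuinely mixed amplification/deletion regions.

## Hidden Markov model

The optional decoding stage models normalized intensities with a
5-state Gaussian HMM: homogeneous, distance-independent transitions
with a sticky diagonal (default 0.999), a strong prior on the diploid
state, and per-state normal emissions. Training is Baum-Welch
(per-step scaled forward-backward; emission sds floored at 1e-3) on a
designated reference panel; the fitted parameters are frozen before
study cohorts are decoded with per-individual, per-chromosome Viterbi
in log space. Posterior-marginal decoding, B-allele frequency, GC-wave
correction and distance-dependent transitions are out of scope. Before
decoding, cohorts are quantile-normalized to one baseline: all
individuals are pooled, the reference quantile vector is the mean of
the per-individual sorted intensity vectors, and each individual's
values are replaced by reference quantiles at their ranks (idempotent,
rank-preserving). Because the association layers consume only integer
states, pipelines may bypass this stage entirely and ingest state
matrices directly (`use_hmm_path=False`, the default).

## Synthetic cohorts: what they emulate and what they do not

The generator emulates the *structure* the analysis needs: an ordered
autosomal SNP map (exponential spacing, configurable fraction of
> 30 kb gaps so the consecutiveness rule is exercised), a discovery and
a smaller validation cohort (defaults 400/400 and 160/170 over 2,000
SNPs, mirroring the discovery > validation size asymmetry of the
emulated study at desk scale), case-enriched risk regions carried
whole-region in a single state (3 for amplification, 1 for deletion),
and sporadic background CNVs: Poisson-count segments per individual
(rate 2), geometric lengths with mean 5 SNPs truncated at ≥ 3 (the
smallest detectable scale under the ≥ 3-SNP rule), uniform abnormal
state, identical process in cases and controls. The recombination map
is a step function: a uniform background rate (0.5 cM/Mb) with short
(2 kb) hotspot intervals at an elevated rate (10 cM/Mb).

It deliberately does **not** simulate linkage disequilibrium,
genotypes, population stratification, batch or GC artefacts, partial
region overlap (available as ground truth would be ambiguous), or
distance-dependent CNV breakpoints. Passing tests therefore show that
the statistics behave as designed under clean carrier-frequency
signals and exchangeable noise — not that real array data meet those
assumptions. The true carrier-frequency contrast at the emulated
study's loci is unknown; the default 0.15 cases / 0.03 controls for a
5-SNP deletion was chosen once as a moderate, detectable effect at
desk-scale cohort sizes.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `t_pm` | 100 | label permutations shared by all FDR stages |
| `candidate_fdr` | 0.15 | q-value ceiling after SNP-based testing |
| `window_fdr` | 0.15 | q-value ceiling after window-based testing |
| `half_width` | 2 | window = 5 consecutive SNPs |
| `max_gap` | 30 000 bp | consecutiveness limit for windows and chains |
| `min_loci` | 3 | minimum chain length for a CNV record |
| `fp_budget` | 1 | expected null sites allowed through the joint rule |
| `recomb_window` | 10 000 bp | total span for the recombination level |
| `background_rate` | 2 | sporadic CNV segments per individual |

The 10 kb recombination region is read as a total span (± 5 kb); the
"sum of log10(maximum rate)" arises at group level, as per-group sums
of per-SNP levels. Both choices are configurable.

## Problem sizes used in validation

The test suite and the acceptance script run the full study at 2,000
SNPs with 400/400 and 160/170 individuals, 100 permutations and 25
replicate studies; null calibration uses 5,000 sites at 400/400; the
HMM benchmark decodes 10,000 entries at 6-sd emission separation.
These sizes were chosen as the smallest at which every stage of the
funnel (including the 30 kb chaining rule) operates on non-trivial
inputs.

## Known limitations

- Exact equivalence with the original upstream CNV caller is not
  claimed: its emission/transition parameterization and its window
  statistic are not recoverable from the study this package emulates,
  and S_w as defined here is a documented stand-in.
- Pearson chi-square on very sparse state tables relies on an
  asymptotic null; the null-calibration test shows it is conservative
  under the simulated background, not under arbitrary real-data noise.
- The permutation FDR shares one ensemble across stages; with very few
  permutations (t_pm ≲ 20) the q-values are coarse.
- Cytogenetic band assignment for CNV records requires an external
  band file and is left as optional metadata.
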