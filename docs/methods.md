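# Methods

This note documents the generative model behind the synthetic cohorts, the
gating and scoring procedures, the statistical conventions, and the design
choices made where more than one reasonable option existed.

## Synthetic cohort model

Each donor in a diagnosis group is generated independently from a seeded
RNG (`numpy` PCG64; donor seed = master seed + donor index, so a cohort is
reproducible byte for byte and any donor can be regenerated in isolation).
The per-donor draw order is identical for every group, so a given donor
seed yields the same age/concentration/composition stream regardless of
group parameters.

**Metadata.** Age ~ Uniform over the group's age range (the ranges of the
motivating pediatric cohorts, e.g. 2.6–19.4 y for non-inflammatory
controls); sex ~ Bernoulli(0.5) (unused downstream); a treatment flag
~ Bernoulli(0.5) for the demyelinating groups (recorded but not used by any
analysis here); CSF cell concentration ~ lognormal with the group median
(0.63 cells/µL for NIND) and a natural-log sd of 0.9 for NIND and 0.5
elsewhere. The NIND spread is wide enough that 33 draws span roughly the
0.2–6 cells/µL range observed clinically; the inflammatory groups use a
moderate spread so that the medians of small groups (n = 4–15) remain
representative of their configured centers.

**Event count.** `round(concentration × volume × 1000)` events for a
simulated 3 mL draw, clamped to [200, 50 000]. A typical NIND donor
contributes ~1 900 events; the more cellular ADS donors contribute more,
mirroring clinical cellularity.

**Composition.** The leukocyte composition over
{T, CD14 myeloid, NK, DC, B, PMN, unassigned} is group-specific; the NIND
values are the published cohort medians (67.3 / 12.9 / 4.3 / 1.6 / 0.6 /
0.3 %) with the remainder (13.0 %) assigned to an `unassigned` CD45+
lineage-negative pool so that the named lineages keep their anchor values.
Lineage frequencies are interpreted as fractions of CD45+ leukocytes.
Donor-level variability is a Dirichlet draw with total concentration 200.
The Dirichlet is *median-centered*: its parameters are calibrated
numerically (bisection on the Beta marginal median) so that each marginal's
median — not its mean — equals the configured composition. Mean-centering
would push the cohort medians of rare populations well below their anchors
(a 0.6 % mean B-cell component has a marginal median near 0.44 %), because
small-α Beta marginals are strongly right-skewed; since every composition
anchor here *is* a cohort median, median-centering is the faithful choice.

**T-cell structure.** CD4/CD8/DN/DP fractions of T cells are 0.672 / 0.236
/ 0.084 / 0.008 (published medians, renormalized). The memory fraction of
CD4+ T cells is fixed at 0.978 and age-independent, matching the absence of
an age trend in CD4 cells. The naive fraction of CD8+ (and DN/DP) T cells
follows a clamped decreasing line in age,
`clamp(0.74 − 0.0467·age, 0.02, 0.95)` — a deliberately simple, testable
stand-in for the observed age trend, calibrated so that a cohort with
median age ≈ 11 y has a median CD8 memory fraction ≈ 77 %. Memory cells
split CM/EM/TEMRA at 0.80/0.18/0.02 (CD4) and 0.55/0.35/0.10 (CD8),
CM-dominant as observed. Memory CD4 cells carry Th chemokine-receptor
states (CXCR3+CCR6− 0.60, CCR6+CXCR3− 0.15, double-positive 0.10,
double-negative 0.15; Th1-like dominant); activation (CD38+HLA-DR+) marks
2 % of memory CD4 and 5 % of memory CD8; 5 % of CD4 T cells are Tregs
(CD25+CD127lo); 5 % of T cells carry CD56 (NKT overlay). The NKT fraction
is a generator parameter because the coNCS divides by the NKT frequency —
a cohort without NKT events would force every coNCS to 0 through the score's
zero rule.

**B cells and ASC.** The ASC fraction of B cells is 2–3 % in control
groups, 10 % in MOGAD/otherADS and 12 % in MS. MOGAD and otherADS donors
are zero-inflated: with probability 0.5 a donor has no ASCs at all,
mirroring the frequent absence of ASCs in those diseases (5/10 samples
each) versus their near-ubiquity in MS.

**Marker expression.** Intensities are generated directly on a transformed
(arcsinh-like) scale: state locations μ_neg = 0, μ_pos = 4, μ_hi = 6 with
shared σ = 0.5 (SSC: low 0, high 6, σ 0.5). The 8σ pos/neg separation
guarantees that fixed mid-way thresholds misassign < 0.01 % of events per
channel, which is what makes latent-label validation of the gating exact to
0.1 %. No raw-scale fluorescence, spillover, doublets or debris are
simulated — the generator exists to exercise gating logic and downstream
statistics, not instrument physics.

**Direction-constrained disease groups.** PIND/AIE/IDWM are mild
perturbations of NIND; otherADS/MOGAD have high cellularity (4–5 cells/µL),
elevated CD14+ myeloid (22–24 %), modest B (4 %) and appreciable PMN
(3–3.5 %); MS has high cellularity (3 cells/µL), strongly elevated B
(12 %), depleted CD14+ myeloid (5 %) and near-absent PMN (0.2 %). These
defaults encode the qualitative orderings that the analyses should
recover: ADS cellularity above controls, >10× B-cell enrichment in ADS,
and an MS profile separable from MOGAD/otherADS by ASC and CD14 measures.

## Gating

Thresholding is hard (binary); a value exactly at a boundary counts as
positive. Predicate semantics per channel: `pos`/`neg` compare to the
primary threshold, `hi` to the high threshold, and `lo` means below the
high threshold where one exists (SSC-low) and below the primary otherwise
(CD127-low). Default fixed thresholds are 2.0 for all fluorescence
channels, high thresholds 5.0 for CD27/CD38, and 3.0 for the SSC low/high
boundary — midpoints of the expression-model states.

`midpoint-mixture` estimation fits a two-component spherical Gaussian
mixture per channel (deterministically thinned to ≤ 5 000 events,
`random_state=0`) and takes the midpoint of the component locations as the
primary threshold; CD27/CD38 high thresholds sit at a fixed +3.0 offset
(three-state channels are too sparse in their high state to re-estimate),
and on SSC the midpoint is assigned to the low/high boundary, which is what
the two SSC modes actually straddle. A fit whose component locations are
closer than 3.0 units (well under the 4-unit spacing of genuine states) or
whose minor component weight is < 0.002 is treated as unimodal — typical
for CD45 (all positive) or for channels whose positive population is absent
in a small donor — and falls back to the default fixed threshold with a
logged warning. This fallback is deliberately the safe path: the defaults
are matched to the expression model.

Three node kinds close the tree under the operations the analysis needs:
conjunction gates, disjoint unions (memory = CM ∪ EM ∪ TEMRA; lymphocytes
= T ∪ B ∪ NK), and remainders (`unassigned` = non-myeloid minus
T/B/NK/DC; non-ASC B = B minus ASC). Sibling quadrant sets partition their
parent exactly by construction, which the tests assert as an exact integer
identity. The DC gate sits inside the SSC-low non-myeloid parent; NKT is an
overlay on T (it does not perturb the CD4/CD8/DN/DP partition). The
lymphocyte denominator excludes DCs (conventional definition).

Gate trees serialize to YAML; counts to long-format CSV.

## Metrics and scores

Frequencies are percentages of parent, of CD45+ leukocytes, of lymphocytes
(populations inside T ∪ B ∪ NK) and of CD3+ T cells (T subsets). A zero
denominator yields a frequency of 0 with a logged warning rather than a
missing value, so the composite scores' zero rules apply without
special-casing. Absolute counts are
cells/mL = %leukocytes/100 × cells/µL × 1000. Medians use the
mean-of-central-pair convention for even n.

The AMR expresses both ASC and CD14 as % of leukocytes; the ratio is
invariant to that choice as long as both use the same denominator. With
ASC > 0 and CD14 = 0 the AMR is an infinite sentinel that ranks above all
finite values (preserving classifier ordering) rather than an error; with
ASC = 0 it is 0 regardless of the denominator. The coNCS follows
`(cells/µL + 1) · B% · 100 / (CD14% · NKT%)` with multiplication binding
before division; the full NCS divides additionally by the blood CD56dim
NK %, and is reported absent — never imputed to 0 — when no blood value
exists. The PMN rule is strict: flagged iff PMN% > 2 × mean NIND PMN%,
with the NIND mean computed from the NIND donors of the same analysis run
(or supplied explicitly when no NIND donors are present).

## Statistics

Wilcoxon rank-sum: U counts (x, y) pairs with x > y, ties ½. The exact
null distribution (scipy's counting recursion) is used when
n₁·n₂ ≤ 400 and no ties are present; otherwise the tie-corrected normal
approximation. Fully tied inputs short-circuit to p = 1. The test suite
verifies the exact path against full enumeration of all C(n₁+n₂, n₁)
assignments for n ≤ 5, and documents that exact and approximate p-values
agree on the 0.05 side in ≥ 95 % of random instances. Group comparisons
report raw p-values with the conventional star notation; Benjamini-Hochberg
adjustment is available behind a flag but off by default, matching how such
panels are usually presented.

The age trend uses Spearman rank correlation (robust to the unknown
functional form of the age effect), with an exact permutation p-value for
n ≤ 9 (vectorized enumeration of all n! rank permutations) and the
t-approximation otherwise; constant inputs yield NaN with no error.

ROC curves place one threshold at every distinct score value; tied blocks
collapse to a single point, so the trapezoidal AUC equals the Mann-Whitney
pair fraction (ties ½) to machine precision — the package computes both and
the tests require agreement to 1e-9 on a thousand random instances,
including tied and infinite-sentinel scores. Score orientation is fixed a
priori (higher AMR/coNCS ⇒ MS); no direction is fitted.

## Problem sizes and determinism

The default cohorts (33 NIND; 15 MS, 10 MOGAD, 10 otherADS; 85 donors over
all seven groups) with ~0.6–50 k events per donor keep a full
simulate→estimate→gate→summarize→score→ROC pass to a few seconds on one
CPU. All randomness flows from the single master seed; mixture fits are
deterministic given the data; CSV outputs are byte-stable across reruns.

## What the synthetic validation does and does not show

Passing the recovery suites demonstrates that the pipeline is
self-consistent: the gating recovers the generator's latent populations to
< 0.1 %, the summarization reproduces the configured cohort medians through
estimated thresholds, and the scores separate groups whose compositions
differ in the configured directions. It does not validate the biology of
real CSF: the generator has no spillover/compensation structure, no
continuum between marker states, no doublets or debris, no correlation
between subset fractions and disease activity, and its group differences
are built in rather than discovered. AUCs on synthetic cohorts (≈ 1.0 at
the defaults) are upper bounds set by the configured effect sizes, not
estimates of clinical performance; the published bound they are checked
against (> 0.7) is the claim the defaults are designed to satisfy.

## Known limitations

- The CD8 memory-fraction cohort median inherits the variance of the
  sampled age median (~7 pp sd at n = 33 under a uniform age draw), so it
  is the least stable of the recovered medians across seeds.
- The expected ADS-over-AIE B-cell fold change sits near 10 under the
  default AIE parameters (B 1.5 % of a 1.2 cells/µL CSF, n = 6), so that
  comparison can dip below tenfold for unlucky seeds; the other three
  control comparisons have wide margins.
- The mixture-midpoint estimator assumes two well-separated location
  states; on real (compensated, arcsinh-transformed) data with smeared or
  trimodal channels it will frequently fall back to the fixed defaults,
  which were chosen for the synthetic scale and would need recalibration.
- The FCS reader covers plain list-mode float/integer exports only (no
  bit-masked integers, no multi-dataset files, no compensation).
- The companion "MS score" used alongside composite scores in the clinical
  literature requires IgG synthesis rates and is out of scope.
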