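# Methods

This note documents the models and procedures implemented in `fcgroups`,
the parameters that matter, what the synthetic cohort does and does not
emulate, and the design decisions taken where the method was genuinely
open.

## 1. Synthetic cohort generator

### Connectivity model

Each subject's node timeseries are T i.i.d. draws from N(0, Σ), where Σ is
a correlation matrix over N nodes partitioned into 16 canonical networks
(four top-down prefrontal networks DMN, CON, FPN, DAN; two bottom-up
networks VAN, SAL; ten sensory/motor/subcortical modules). The baseline is
block-structured: `rho_within = 0.35` inside a network, `rho_between =
0.10` across networks. A planted group shifts the blocks of its signature
additively: `delta = 0.12` (correlation units) for ordinary deviations and
`delta_bold = 0.20` for the strongest ("bold") ones, positive or negative
per network. Entries are clipped to ±0.95; if the edits break positive
semidefiniteness, eigenvalues are floored at 1e−6 and the matrix rescaled
to unit diagonal (logged). `delta`/`delta_bold` are calibration choices in
correlation units — no published effect sizes exist for them; they were
fixed once so that bold block shifts are roughly four control-sampling SDs
at T = 400 (Fisher-z sampling SD ≈ 1/√(T−3) ≈ 0.05).

Group signatures are defined per network; they are lifted to network-pair
blocks as follows: a within-network block takes the network's sign; a
between-network block deviates only when both networks deviate in the same
direction (bold only when both are bold). This is the weakest lifting
consistent with per-network annotations — it never invents a cross-network
deviation that the annotations do not imply.

### Membership structure

The default cohort is 30 controls + 27 SZ + 35 BP patients with five
planted groups of sizes 11, 27, 10, 35 and 16 (per-diagnosis counts 5/6,
10/17, 4/6, 17/18, 8/8) — 99 memberships over 62 patients, so groups
overlap and every patient belongs to at least one group. Assignment is
deterministic: group "cores" (unique members) partition the patient list
proportionally to group size; remaining slots are filled from a sharable
pool. Because block shifts add across a subject's groups, a subject
belonging to two groups with *opposite* signs for the same network would
express neither signature (the shifts cancel); overlap members are
therefore drawn preferentially between sign-compatible groups (cosine
affinity of the planted block patterns, worst current membership deciding).
A handful of mildly conflicting co-memberships remain — with 99 memberships
over 62 patients they are unavoidable — and they are the main reason
recovery of the two broadest groups saturates below a perfect Jaccard of 1.

### Phenotypes

TCI scores (NS, HA, RD, PS, SD, CO, ST) and three symptom composites are
unit-variance Gaussians; a group member's scores are shifted by
`tci_effect = 1.5` SD times the *mean* profile over their memberships
(averaging prevents effect stacking for multi-group members). Controls are
centred at zero. Demographics (age, sex, ethnicity, handedness, illness
duration, medication flags) are drawn independently of membership, so
demographic confounder tests are null by construction. The generator writes
the planted memberships to a ground-truth file that the pipeline never
reads.

### What the generator does not emulate

No hemodynamics, no temporal autocorrelation, no head motion, no scanner
artifacts, no site effects, and no voxel level (node timeseries are
simulated directly). Deviations are homogeneous within a network block,
whereas real group effects are graded across node pairs. Passing tests
therefore demonstrate that the pipeline recovers block-structured,
control-referenced group signal at realistic SNR — not that it is robust to
fMRI preprocessing artifacts.

## 2. Feature construction

Pearson correlations per subject; Fisher z (atanh, |r| clipped at
0.999999 with a warning) for variance stabilization before averaging and
differencing; deviations are patient z minus the control mean z per
upper-triangle node pair (row-major, i < j, 0-based; a network-block-mean
mode exists as an option). Features undefined for any subject (constant
node) are dropped listwise and logged. The nonnegative encoding is
two-channel: `pos = max(d, 0)`, `neg = max(−d, 0)` — an exact, invertible
representation of the signed deviations (`pos − neg = d`,
`pos · neg = 0`). An optional noise floor `tau_noise` (default 0) zeroes
sub-threshold deviations in both channels.

## 3. Multilevel fuzzy NMF and bicluster dissection

Frobenius-norm NMF by Lee–Seung multiplicative updates (denominators
floored at 1e−12 against zero-locking), random-uniform initialization by
default (an NNDSVD-style initializer is available), stopping at relative
objective change < 1e−6 or 500 iterations. The multiplicative update
guarantees a nonincreasing objective, asserted in the tests on every run.
Ranks 2..10 are fitted with 5 restarts each (restart seeds derived from the
master seed by fixed offsets; best final objective kept), giving a
multilevel family from broad groups (low rank: many subjects, few shared
features) to specific ones.

Dissection of factor j into a candidate bicluster must resolve the scale
ambiguity W H = (W D)(D⁻¹ H): subject loadings are first rescaled by their
factor's feature-loading norm. Membership uses a relative threshold α = 0.5
against the *minimum* of (a) the subject's own best loading and (b) the
factor's top subject loading. Rule (a) alone would strike subjects
expressing several patterns from all but their dominant group; rule (b)
alone truncates broad groups with graded expression; the union supports
fuzzy overlap across group breadths. Both pure rules remain available
(`membership_rule`). Features use the within-factor relative threshold
β = 0.5.

Each candidate carries three scores:

* **sensitivity** — mean of V[s, f] normalized by the column maximum over
  the bicluster's cells (coherence; 1 for a perfect block);
* **specificity** — logistic(d), d the pooled-SD Cohen's d of the
  bicluster-feature mean between members and non-member patients (chance
  level 0.5; rank-based fallback when the pooled SD degenerates);
* **deviation strength** — mean member deviation on the bicluster's
  features in units of the per-feature control SD. Control connectivity
  estimates fluctuate by one unit of this scale through sampling alone, so
  strength ≤ 1 marks noise. This score is essential: on structure-free
  data NMF *overfits* coherent noise, producing biclusters whose
  specificity is far above chance (≈ 0.9 empirically), and only the
  absolute deviation scale separates them from real effects (planted
  groups sit at 3–14).

## 4. Selection

Candidates from all ranks compete under a quality-weighted
facility-location objective. Quality
`q(B) = spec_excess^λ_spec · sens^λ_sens · max(0, 1 − 1/strength)` with
`spec_excess = max(0, 2(specificity − ½))`; coverage
`C(Sel) = mean over patients of max_{B ∋ s} q(B)` (subject facet weight 1;
a feature facet exists with default weight 0 — low-rank candidates that
blend two groups carry bloated feature sets that would otherwise buy
selection without adding subject information; feature coverage is still
computed and reported). Greedy forward selection adds the candidate with
the best marginal gain, prunes near-duplicate views of an accepted
bicluster (subject Jaccard ≥ `tau_dup` = 0.6, logged), and stops when the
best gain falls below `epsilon_gain` = 0.02. A deterministic local search
(drop/swap/add passes on the penalized objective `C − ε·|Sel|`, at most 20
sweeps) then corrects the greedy tendency to take broad low-quality
candidates before sharp ones. Ties break by higher specificity, then
smaller subject set, then provenance (rank, factor). An exhaustive
optimizer (≤ 15 candidates) is the oracle in tests. No number of groups is
ever imposed; the gain threshold decides, and on structure-free data the
strength gate drives every gain to ≈ 0, so selection terminates empty.

Accounting per selected group: connection count, subject count, SZ/BP/
control counts, risk = patient fraction, and SZ%/BP% among patients,
rounded half away from zero. Coverage is the percentage of patients in at
least one selected group (full precision and nearest integer).

## 5. Validation

All validation consumes data the clustering never used. Per group:

* **Direction classification** — per-subject within-network mean deviation
  (from the control mean); Welch t of members vs controls per network,
  Bonferroni over the 16 networks; Positive/Negative when the adjusted
  p < 0.05 with the corresponding mean ordering, bold when p < 0.001
  (0.001 is a declared choice for "highly significant"); members vs other
  patients reported side by side, and a three-way ANOVA
  (members/others/controls) per network. Degenerate ANOVA input resolves
  by exact equality (identical constants → F = 0, p = 1; distinct
  constants → F = ∞, p = 0; both logged).
* **TCI explanatory power** — forward-stepwise logistic regression of
  group membership (vs all other patients) on the seven TCI dimensions;
  predictors enter while AIC improves by ≥ 2. Under (quasi-)separation a
  small-ridge penalized fit substitutes (logged). The reported R² (percent
  scale), F, p and RMSE come from an OLS of the 0/1 membership on the
  fitted probabilities — invariant to affine rescaling of the predictors.
  Groups with fewer than 5 members (or non-members) are marked not
  applicable.
* **Diagnosis contrasts** — per-feature Welch t of SZ vs BP members,
  counted in the weak (0.01 < p < 0.05) and strong (p < 0.01) bands.
* **Confounders** — Welch t (plus members/others/controls ANOVA) for
  continuous demographics, chi-squared (Fisher exact fallback for sparse
  2×2 tables) for categorical ones; effect sizes on the correlation scale
  (r = √(t²/(t²+df)), Cramér's V).

Welch (unequal-variance) t-tests are the default throughout; the Bonferroni
family is the set of tests in the group's own table.

## 6. Problem sizes and reproducibility

The analysis scripts, test suite and acceptance script run the pipeline at
48 nodes (3 per network; 1128 node pairs, 2256 channels) and T = 400,
cohort 30 + 62 — small enough that a ten-seed full-pipeline study completes
in a few minutes on one CPU while preserving within- and between-network
pair structure. `SimConfig` defaults to 160 nodes (10 per network) and
scales to atlas size; node count is fully configurable because published
ROI counts for such atlases vary. All randomness flows from one master
seed through fixed per-stage offsets; a rerun with the same configuration
and seed reproduces byte-identical outputs (asserted via the run manifest's
SHA-256 digests).

## 7. Known limitations

* Recovery of broad groups saturates around Jaccard 0.8–0.9: members
  shared with a sign-conflicting group express attenuated signatures and
  are genuinely ambiguous under additive planting.
* The NMF membership construction and the selection objective are declared
  stand-ins for procedures whose exact published form is unavailable; both
  are parameterized and documented rather than hidden.
* The explanatory-power simulation shows that a 1.5-SD two-dimensional
  personality profile yields R² values whose spread (≈ 30–75%) brackets
  the 35–67% range reported for real cohorts; with overlapping groups
  sharing profile dimensions the full-cohort values are lower.
* Network-block planting means per-connection statistics inside a block
  are exchangeable; real data would grade them.
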