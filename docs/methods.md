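# Methods

This note documents the statistical model behind `rbclink`, the design of
the synthetic-cohort generator, and the numerical choices made where the
procedure left room for judgement.  It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Study design and data model

The pipeline targets longitudinal donor/storage designs: each donor is
measured once at donation (baseline, timepoint `NS`, the *in vivo*
compartment) and the packed RBC unit prepared from that donation is
sampled weekly during refrigerated storage (`D7`…`D42`, the *ex vivo*
compartment).  Donors belong to one of two groups (`deficient` /
`sufficient`, e.g. by G6PD genotype).  The emulated design has 6 deficient
and 3 sufficient donors, ~45 baseline hematological/physiological
parameters and ~293 stored-unit metabolites.

`LongitudinalDataset` holds a variables × samples matrix with a
four-level sample key (donor, group, timepoint, compartment) and
variable-level metadata (compartment: `in_vivo`, `ex_vivo` or `both`;
free-text class tag used for sub-network grouping).  Missing cells are NaN
and are never imputed: every test uses pairwise-complete observations, and
a pair at a timepoint is untestable (and kills its candidate edge) if
fewer than 3 paired donors remain — the minimum for a defined p-value.
Variables assayed only at a subset of storage days (e.g. end-of-storage
enzyme activity) are supported: the repeated filter applies to the days
where data exist and the edge is annotated `partial`.

## The adaptive correlation test

For one pair of series (donor-aligned), with significance accepted at
p < 0.01 throughout:

1. **Normality screen.** Shapiro–Wilk on each series at
   `normality_alpha = 0.05`; both must pass for the Pearson branch.  The
   screen is applied per (group, timepoint) stratum — the series actually
   being correlated — not pooled across storage.
2. **Outlier rule.** A value is an outlier if it lies outside
   mean ± 2·SD of its own series, with the sample (n−1) SD computed on the
   full series including candidates.  Detection runs once (no iterative
   re-detection after exclusion).
3. **Re-test loop.** If either series carries an outlier, Pearson is run
   with and without the flagged donor(s) (exclusion is pairwise: the donor
   leaves both series).  The *outcome* is "unchanged" when the re-test
   lands on the same side of α **and** the sign of r is unchanged — the
   minimal reading that affects downstream edges; magnitudes are not
   compared.  Unchanged → outliers are included back and the full-data
   Pearson result is reported (the flagged donors stay recorded in
   `outliers_excluded` and the re-test in `decision_trace`).  Changed →
   the full-data Spearman result is preferred.  If exclusion would leave
   n < 3 or a constant series, the re-test is infeasible and Spearman is
   used directly.

Every branch taken is recorded as an ordered `decision_trace`, so the
choice of test for any edge can be audited after the fact.

Pearson p-values come from the t distribution with n−2 df.  Spearman rho
is Pearson on average ranks (ties → mean rank); its two-sided p is exact
for n ≤ 8 — the proportion of the n! equally likely rank permutations
with |rho| at least as extreme, computed by vectorised enumeration, which
handles ties correctly — and the t approximation otherwise.  With 6–9
donors per group the exact path is the one that actually runs, and its
granularity matters: the smallest attainable p at n = 6 is 2/720 ≈ 0.0028,
so a single week of n = 6 Spearman can clear α = 0.01 only near-perfect
concordance.

The selection between tests perturbs the size of the combined procedure
slightly; the suite checks empirically (10,000 null replicates) that the
type-I error at α = 0.01 stays ≤ 0.015.

## Repeated filter, correction, interactome

All in-vivo × ex-vivo pairs are tested at every storage week (baseline
values against that week's stored values).  An edge `passes_raw` iff
p < α at **every** tested week with a constant sign of r.  Repetition
across weeks is the primary guard against the false-discovery rate a
small cohort invites: under independence the per-pair null pass rate is
≈ α^T; empirically (weeks are positively dependent through shared donors)
it is still ~10⁻⁴ per pair at T = 6.  Sign consistency is required by
default (networks draw one sign per edge) and can be disabled.

The family-wise correction is applied on top of the repeated filter.  The
family size m is the number of pairs actually scanned (callers supply
it).  Three variants are implemented because the combining rule across
weeks is a genuine design choice; the variant used is recorded in run
manifests:

- `max-p` (default, most conservative): worst per-week p ≤ family_α / m;
- `per-tp`: every per-week p ≤ family_α / (m·T);
- `fisher`: Fisher-combined p across weeks ≤ family_α / m.

Surviving edges form an undirected bipartite graph (networkx).  The
representative r is the latest tested day (day 42 in the full design);
edge length is exported as 1/|r| so stronger correlations draw shorter.
A variable measured in both compartments appears as two nodes
("X (in vivo)", "X (ex vivo)"), keeping the graph bipartite and
self-loop-free.  Within-compartment pairs are excluded from this scan —
they belong to the linkage analysis.  SIF export writes
`nodeA <pos|neg> nodeB`; GraphML carries all node/edge attributes.

## Linkage and rewiring

Within one group, metabolite–metabolite correlations are computed on all
(donor, storage week) observations pooled ("independently of storage
age").  This pools repeated measures per donor — pseudo-replication
accepted deliberately for fidelity to the emulated analysis; a
`timepoint_mean` collapse (one averaged point per donor) is available for
the statistically purer alternative.  Baseline samples are excluded from
pooling by default.  The rewiring score between groups A and B is
Δ = ||r_A| − |r_B|| (absolute difference of magnitudes, i.e. "Δ|r| > 30%"
read as 0.30 in absolute r units, not a relative change); pairs with
Δ > 0.30 are flagged.  A `signed` mode (Δ = |r_A − r_B|) exists because a
sign flip at equal magnitude is invisible to the default score; sign flips
with both |r| ≥ 0.2 are flagged separately in either mode.

The intra-parameter scan correlates each both-compartment variable's
baseline with its own stored level, week by week, and flags variables
significant at every tested week (the "donor-signature" effect: storage
shifts the variable but preserves donor ordering).

## Two-way ANOVA screen

Per ex-vivo variable: fixed-effects group × week ANOVA with interaction.
Balanced designs use the exact Type I sums-of-squares decomposition
(SS_total = SS_group + SS_time + SS_interaction + SS_error, checked to
1e-9 relative in the suite and against statsmodels `anova_lm`).
Unbalanced cells — the normal case with 6 vs 3 donors — use the
unweighted (cell-mean) analysis with the harmonic mean cell size; the
factor SS then live on the cell-mean scale and no longer sum to SS_total,
which the result object marks via `balanced=False`.  Empty cells raise,
naming the cell.  Significance flags default to α = 0.01, the package's
blanket threshold; the screen's α is configurable.

## The synthetic-cohort generator

The generator exists so that every downstream stage can be tested against
known truth without any external data.  It is a Gaussian copula: every
variable owns a latent standard-normal donor score, and a target
correlation matrix C over all latent scores encodes the planted structure
(cross-compartment persistent edges, within-baseline correlations — used
e.g. to make feasible hubs — group-specific rewired ex-vivo pairs, and
baseline→storage signatures for both-compartment variables, which
internally own one latent per compartment).

Baseline observations are the baseline-block latents X.  Storage
observations at week t are

    V_t = M·X + sqrt(1−k)·P + sqrt(k)·W_t,   M = C_sb·C_bb⁻¹,

with P (persistent) and W_t (weekly refresh) i.i.d. draws from the
conditional covariance C_ss − C_sb·C_bb⁻¹·C_bs, and k = noise_sd² the
refreshed share of the residual variance.  This conditional construction
makes every per-timepoint cross-sectional correlation *exactly* equal to
the target in C — planted edges are not attenuated by the weekly noise —
while week-to-week sample correlations still fluctuate, which is what the
repeated filter experiences on real data.  Infeasible targets (C not
positive semidefinite, e.g. a hub with too many strong independent
partners) raise an explicit error naming the planted pairs.

On top of the latent values:

- **Storage drift** (the storage lesion): each ex-vivo variable's mean
  moves by `drift_per_week` (default 0.15 SD) per week, direction random
  per variable, linear by default with a U-shaped option.  Drift shifts
  per-week means and therefore never affects cross-donor correlations at
  a fixed week.  Variables in planted rewired pairs stay drift-free so the
  pooled between-group delta measures the planted rewiring and not a
  shared time trend.
- **Non-normal marginals**: a random `nonnormal_fraction` (default 0.25,
  a realistic share of right-skewed metabolites) of variables is
  exponentiated — a strictly monotone map that preserves Spearman but not
  Pearson correlation, exactly the contrast the adaptive test must handle.
- **Outliers**: each observed cell is shifted with probability
  `outlier_rate` (default 0.01) by `outlier_magnitude` (default 5) SDs of
  its (variable, group, week) stratum — comfortably beyond the 2·SD
  detection rule.

Defaults mirror the emulated design (6 + 3 donors, 45 + 293 variables,
weekly sampling days 7–42).  Planted edge strengths in tests are high
(0.9–0.98) by necessity: at n = 6 and α = 0.01 the two-sided Pearson
detection limit is |r| ≈ 0.917, and the generator warns when a planted
edge is undetectable at the configured n.  `noise_sd = 0.5` (k = 0.25)
keeps three quarters of the residual variance persistent per donor —
storage weeks of one unit resemble each other, as repeated measures do —
while leaving enough weekly wobble that the six weekly tests are not one
test in disguise.  A single integer seed fully determines the output.

What the generator does **not** emulate: mass-spectral acquisition
artefacts, batch effects, missingness mechanisms, heavy-tailed error
beyond the lognormal transform, or the biochemical content of the
metabolic phases.  Passing tests therefore demonstrate that the pipeline
recovers planted dependence structure under realistic noise, skew,
outliers and drift — not that any particular biological claim holds on
real cohorts.

## Numerical and design details

- Sample SD (n−1) everywhere.
- Exact Spearman enumeration is capped at n = 8 (40,320 permutations,
  vectorised and cached per n); beyond that the t approximation is
  standard and accurate.
- Q–Q-plot-based outlier calls are a visual aid in the emulated workflow;
  the implementable rule is mean ± 2·SD, and only that is implemented.
- Degenerate inputs raise typed errors rather than returning NaN:
  constant series (`ZeroVarianceError`), n < 3 (`InsufficientDataError`),
  malformed tables (`DatasetFormatError`), non-PSD plant
  (`InfeasibleCorrelationError`).
- Tie-break in hub ranking: degree descending, then node name
  lexicographically (stable, documented).
- The pipeline's master seed fans out to per-stage child seeds via
  `SeedSequence([seed, stage_index])`, so stages can be rerun
  independently; the derivation is recorded in the run manifest.
- Problem sizes in the validation suite and acceptance script — 20
  donors/group for power analyses, 200 candidate null pairs, 500 null
  replicates for the family-wise error estimate — were chosen to give
  stable Monte-Carlo estimates at desk scale (binomial SE ≈ 1% on the
  FWER) while keeping a full run in the minutes range on one CPU.

## Known limitations

- The pooled linkage correlations treat repeated measures as independent
  observations; their p-values are optimistic.  The rewiring delta has no
  permutation significance attached (a natural extension, not
  implemented).
- The max-p correction is conservative under positive dependence of
  per-week p-values.
- The unweighted-means ANOVA is approximate for severely unbalanced
  designs; a mixed/repeated-measures model is out of scope.
- With 6 donors per group, only near-deterministic correlations
  (|r| ≳ 0.92) are detectable at α = 0.01 — a property of the design, not
  the implementation; the generator makes this limit explicit.
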