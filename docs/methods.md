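# Methods

This note documents the models and procedures implemented in
`bloodsift`, the parameters that matter with their defaults and units,
the design choices made where the design was genuinely open, what the
synthetic-data generator does and does not emulate, and known
limitations.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. Presence calling (`profiles`)

Species-level taxonomic profiles are read either from standard 6-column
Kraken2 reports (one per sample) or from a samples × species integer
TSV.  For Kraken2 reports only rank-`S` rows are used, and the
**clade-level** read count (column 2) is taken, so subspecies/strain
assignments roll up into their species — the standard species-level
aggregation of such reports.  Classifier reports do not state whether a
study used clade-rolled or direct-assigned counts; clade-rolled is the
defensible default and is documented here rather than inferred.

*Sample QC.* Samples with fewer than `min_total = 100` microbial read
pairs are removed ("fewer than" — a total of exactly 100 is kept).

*Relative abundance.* `RA[i, s] = count[i, s] / total[i]`, with the
denominator fixed to the sample's total species-level microbial reads
**before** any zeroing.  Re-calling presence on a zeroed matrix with the
original totals is a no-op (idempotence, property-tested).

*Presence rule.* An entry is **absent** when `RA ≤ 0.005` **or**
`reads ≤ 10`; equivalently, present requires `RA > 0.005` AND
`reads > 10` (both boundaries exclusive for presence).  The two
thresholds are described jointly as defining absence, so the conjunctive
(strictest) reading is the default; a permissive `rule="either"` is one
config key away for sensitivity analyses.  The abundance threshold
0.005 is taken as a parameter — it was originally calibrated with
read-level simulation, which is out of scope here; the count-level
generator (§7) plants its signal relative to whatever thresholds are
configured.

## 2. Decontamination (`decontam`)

Four filters run sequentially, each on the survivor set of the previous
one; a species called anywhere is removed **globally** (the pipeline
tracks a single shrinking species list, so one batch's contaminant
cannot survive as another batch's "signal").

1. **Prevalence filter** (`prev_threshold = 0.25`, `fold = 2`,
   `min_batch_size = 100`).  For every batch variable and every batch
   with ≥ 100 samples: species `s` is called in batch `b` iff
   `prev(s, b) > 0.25` and `prev(s, b) > 2 · prev(s, b′)` for **every**
   other eligible batch `b′` of the same variable.  Batches under 100
   samples are excluded from both sides of the comparison; variables
   with fewer than two eligible batches are skipped with a warning.
   `x > 2·0` holds for any `x > 0`, so a species exclusive to one large
   batch at > 25% prevalence is called.  Comparisons are within-variable
   only ("any other batch" of that variable).
2. **Correlation filter** (`rho_threshold = 0.7`).  Candidates are the
   current survivors; seeds are exclusively the prevalence-filter calls.
   For each seed call (contaminant `c`, batch `b`), Spearman's ρ
   (mid-rank convention) is computed between CLR-transformed abundances
   of each candidate and `c` over exactly the samples of `b`; a
   candidate is called when ρ strictly exceeds 0.7 for any seed.
   Batches with < 3 samples are skipped (ρ degenerate).  The abundances
   used are the post-presence zeroed counts over the original totals —
   the matrix the rest of the pipeline sees.
3. **Batch filter** (`excluded_variables = ("library_kit",)`).  A
   species must be detected in ≥ 2 batches of **every** non-excluded
   reagent variable; detection in ≤ 1 batch of any variable calls it.
   Species present in zero samples are called as the degenerate case.
   Library-preparation kit type is excluded by default because kit types
   are typically few and heavily skewed toward one type, making the
   two-batch requirement uninformative for that variable.
4. **Read-count filter** (`min_max_reads = 100`).  A species never
   assigned ≥ 100 reads in any single sample is an analysis artefact
   ("at least 100" — a maximum of exactly 100 survives).

*CLR and zero replacement.* `clr(x)_s = ln x_s − mean_s ln x` per
sample.  Zeros are replaced multiplicatively by
`0.65 × (smallest nonzero value of the matrix)` before the log.  The
replacement strategy is not dictated by the filter definition; since the
filter consumes only ranks, any monotone replacement below the smallest
observed value gives identical calls — the constant is recorded for
reproducibility, not because results are sensitive to it.  Samples with
no present species become constant CLR rows (all-zero after centring);
`clr_transform` treats such rows as an error unless explicitly allowed,
which the correlation filter does (they carry no rank information and
cannot reach ρ > 0.7).

*Auditability.* Every call stores the numbers that justified it
(prevalences and batch size, ρ and partner, batches detected, max
reads); a test re-evaluates each filter's rule from the stored evidence
alone.

## 3. Enrichment randomization test (`annotate`)

Given the species list before filtering (size `N`) and the survivor
list (size `k`), the test draws `n_iter = 1000` uniform size-`k`
subsets of the pre-list without replacement and computes, per draw, the
proportion annotated to the category of interest.  The p-value is the
plain fraction of draws at least as extreme as the observed survivor
proportion (`≥` for direction *greater*, `≤` for *less*; no +1
smoothing); an exact zero is additionally rendered as `< 1/n_iter`.
Defaults test *likely contaminant* with direction *less* (filters
should deplete it) and *blood-culture* / *human-associated* with
*greater*.  Species missing from the annotation table count as
category-negative but stay in the denominator, keeping proportions
comparable across lists.

Because draws are uniform without replacement, the null distribution of
the category count is exactly hypergeometric `HG(N, K, k)`; the test
suite checks the empirical null against this closed form (total
variation < 0.05) and uses the hypergeometric tail as an oracle for
enriched subsets.  One calibration caveat, verified exactly: with small
draw sizes the attainable proportions are coarse and inclusive-tail
p-values are conservative, so `P(p < 0.05)` under a random survivor
list is 0.034, not 0.05 — approximately, not exactly, uniform.

## 4. SparCC co-occurrence (`cooccur`)

Counts are compositional, so correlations are estimated from log-ratio
variances, which are invariant to per-sample totals:

* fractions per draw: Dirichlet resample with prior `counts + 1`
  (pseudocount 1.0); `n_draws = 20`, or the deterministic posterior
  mean with `n_draws = 0`;
* `t_ij = var(ln(x_i/x_j))` (unbiased, ddof 1);
* sparsity approximation: with
  `t_ij = w_i + w_j − 2 ρ_ij √(w_i w_j)` and most `ρ_ij ≈ 0`, row sums
  give the linear system
  `Σ_{j∈S_i} t_ij = |S_i| w_i + Σ_{j∈S_i} w_j`, solved for the basis
  variances `w` (clipped below at 1e-12);
* `ρ_ij = (w_i + w_j − t_ij) / (2 √(w_i w_j))`, clipped to [−1, 1];
* iterative exclusion: up to `n_exclusion_iters = 10` times, the
  strongest pair with `|ρ|` above `exclusion_threshold = 0.1` is
  removed from the row sums and the system re-solved (no component is
  reduced below two partners);
* final ρ is averaged over draws, symmetrised, with unit diagonal.

These internals (pseudocount, draw count, exclusion schedule) follow
the published algorithm's conventions and are all exposed in config.
With `n_draws = 0` and no exclusions the estimate is reproduced to
1e-6 by an independent brute-force solve of the full linear system,
which the tests use as an oracle on 4–6-species instances.  At the
default study size (500 samples, 20 species) the null sampling noise of
the estimator puts the maximum off-diagonal `|ρ|` around 0.12–0.15.

Networks: edges are unordered species pairs with `|ρ|` **strictly**
above the threshold (defaults 0.05 / 0.2 / 0.3 for the pooled network,
0.2 per cohort); isolated nodes are kept.  Network samples are those
with ≥ 2 present species after decontamination.  Cohort networks
exclude configured cohorts (e.g. an infant birth cohort of distinct
demography); the pooled network includes all cohorts by default.  Edge
intersection across cohorts uses pair identity only — sign and
magnitude are ignored because each cohort's ρ is estimated on different
samples — and reports the per-network correlations on surviving edges.

## 5. Replication rates and GC skew (`replication`)

*Coverage model.* In a population of replicating cells, copy number
decays log-linearly from Ori to Ter along both arcs of the circular
chromosome.  Depth is averaged in `bin_size = 10 kb` bins and smoothed
with an 11-bin **circular** running median (window wraps the origin) —
median smoothing because single-bin spikes from mobile elements or
mismapping must not set the peak.  Bin size and window are configurable;
the genome must cover at least `2 × bin_size × window` bp.

*PTR.* Peak = global maximum of the smoothed bins (Ori at its bin
midpoint), trough = global minimum (Ter); `PTR = peak / trough ≥ 1` by
construction, invariant to uniform depth rescaling and equivariant
under genome rotation (property-tested).  Argmax/argmin is used instead
of sinusoid fitting, but an R² of the two-arc piecewise-linear
log2-coverage model is attached so callers can reject tracks whose
extremes are not part of a coherent gradient.  All-equal bins yield
PTR = 1 with a degeneracy flag (first-occurrence positions).  A zero
trough is an error (insufficient coverage).

*Replication call.* A species/sample pair is *eligible* with
≥ `min_assigned_reads = 1000` assigned read pairs and a non-degenerate
track; *replicating* iff additionally `PTR > ptr_threshold`.  The
default threshold 1.1 keeps a guard band above the literal "> 1"
because Poisson noise on flat coverage yields ratios slightly above 1
even after smoothing; the literal 1.0 rule is one config key away, and
the two agree on any clearly replicating genome (the guard band only
affects the 1.0–1.1 sliver).

*GC skew.* Per `10 kb` window, `skew = (G − C)/(G + C)` (0 for windows
without G or C; non-ACGT ignored; trailing partial window dropped).
The cumulative sum is detrended by the straight line through its
endpoints (the circular closure constraint), then Ori = the boundary of
the window attaining the cumulative minimum and Ter = the maximum.
Degeneracy: under a skew-free sequence the detrended series is a random
walk bridge with per-step variance ≈ `1/(G+C per window)`; the result
is flagged unreliable when the detrended range is below
`4 · sqrt(n_windows) · sqrt(mean 1/(G+C))`.  The factor 4 puts the
false-positive rate of the flag well below 1% while a planted amplitude
of 0.3 over a 2 Mb genome exceeds the floor by more than an order of
magnitude.  Coverage breadth (fraction of positions with depth ≥ 1)
requires per-position input and is reported alongside.

## 6. Association screen (`assoc`)

Per cohort, per species (present in ≥ `min_present = 50` samples
overall), per phenotype; samples with missing phenotype values are
excluded test-wise.

* **Categorical** (sex; ancestry as a single 2 × 4 table, not
  pairwise): two-sided Fisher's exact test.  The p-value sums the
  probabilities of all tables with the observed margins that are no
  more probable than the observed table (the `fisher.test` convention).
  2 × 2 tables and small 2 × k tables are enumerated exactly
  (vectorised multivariate-hypergeometric log-probabilities); tables
  with more than 20,000 candidate top rows use a seeded
  multivariate-hypergeometric Monte Carlo (20,000 draws) of the same
  functional.  No statistic is reported for Fisher tests (the statistic
  column is blank by convention for r × c exact tests).
* **Continuous** (age, BMI, TC, TG, SBP, DBP in mmol/l / mmHg):
  two-sided Mann-Whitney U.  When both groups are < 20 the exact
  permutation distribution is computed by a rank-sum dynamic program
  that handles ties via mid-ranks (doubled ranks keep it integral); the
  two-sided p counts labelings whose U deviates from `n₁n₂/2` at least
  as much as observed (the permutation distribution of U is symmetric
  about that mean).  Larger groups use the tie-corrected normal
  approximation with continuity correction.  Both branches are verified
  against exhaustive enumeration for ≤ 8 observations, and the
  asymptotic branch against a 400k-draw permutation at the far tail.
* **Correction**: Benjamini-Hochberg step-up (statsmodels), applied
  once over the pooled p-values of both tests and all cohorts.  Derived
  phenotypes — elderly (age ≥ 65), obese (BMI > 30), high TG (> 2.3
  mmol/l), high TC (≥ 6.3 mmol/l), high BP (SBP ≥ 130 **and**
  DBP ≥ 80) — are screened with Fisher tests in a second family with
  its own BH pass.  Significant hits are annotated with the number of
  cohorts in which the same (species, phenotype) pair is significant,
  since cross-cohort replication, not pooled significance, is the
  relevant evidence standard.

Calibration note: BH's global-null probability of any rejection within
one family equals the Simes level (~α) for continuous p-values, so "no
significant hits under the null" holds in ~95% of screens per family —
an expectation, not a guarantee; pooling the two separately-corrected
families compounds to ~90%.  The KS-uniformity check of null p-values
is applied to the Mann-Whitney family only: exact conditional tests on
sparse binary presence are discrete and conservative, so their p-values
are not uniform by construction and a KS test against the uniform would
reject a perfectly correct implementation.

## 7. Synthetic data (`synth`)

The generator defines the study conditions for all planted-truth tests;
every generator is bit-reproducible given (config, seed) and the truth
object round-trips through JSON.

*Cohort counts* (defaults): 2,000 samples in 4 cohorts; four batch
variables (extraction kit, library kit, SBS lot, flow cell) with 4
batches each, assigned in contiguous blocks rotated per variable so
variables are partially confounded — mimicking nested laboratory
processing — with an independent-assignment mode for ablation.
Per-sample totals are lognormal (median 6,000 read pairs, σ = 1).  The
30 contaminants each have a home (variable, batch) assigned round-robin;
within the home batch presence probability is 0.4, tied across
co-resident contaminants by a shared per-sample standard-normal factor
under a Gaussian copula with correlation 0.8 (chosen because the
correlation filter consumes ranks — any monotone dependence suffices);
conditional on presence, the relative abundance is log-uniform on
[0.01, 0.3] and increases with the latent load.  Background presence
elsewhere is independent at 0.05.  The 20 genuine taxa are present
independently of batch at prevalences uniform on [0.001, 0.05], with
log-uniform abundance on [0.01, 0.3] — high enough that ≥ 90% of
occurrences clear the presence thresholds at the median total (the
failures are real: low-total samples lose their genuine signal, as in
real data).  If a sample's planted abundances sum past 0.8 they are
rescaled to leave room for background.  Residual reads are spread over
1,500 noise species by a per-study Dirichlet(1) propensity multinomial,
capped at 10 reads per entry: noise species never clear the presence
thresholds and are removed by the read-count filter, emulating the long
misclassification tail.  1,500 species is the smallest tail that can
absorb a median residual of several thousand reads under the 10-read
cap without the cap binding often (which would depress totals).

What the generator does **not** emulate: read-level error profiles and
reference-database artefacts (counts are planted directly, so the 0.005
threshold is exercised, not re-derived); contaminants shared across
*all* batches of a variable (undetectable by design by these filters);
taxonomic mis-assignment between related genuine species; negative
controls (the filters assume none exist).  Passing tests therefore show
the chain recovers batch-structured contamination of the planted form,
not that these thresholds are optimal for any particular laboratory.

*Phenotypes*: age ~ U(21, 80) years; BMI ~ N(24, 4²) kg/m² truncated
> 14; TC ~ N(5.2, 1.1²), TG ~ N(1.5, 0.8²) mmol/l; SBP ~ N(125, 15²),
DBP ~ N(75, 10²) mmHg (all truncated at physiological floors); sex
50/50; ancestry Chinese/Malay/Indian/Others at 57/22/16/5% — marginals
plausible for an adult Southeast-Asian population survey.  A planted
effect re-draws the source column for carriers so that the derived
condition's odds shift by the requested log-odds while the conditional
distribution within each side of the threshold is preserved (supported
for elderly/obese/high_tg/high_tc; high_bp involves two columns and is
not plantable).  Optional missingness is injected completely at random.

*Coverage*: expected log2 depth is piecewise linear on the circle
(maximum at Ori, minimum at Ter, range log2 PTR), scaled to the target
mean depth; per-bin observed depth is Poisson(expected × bin size)/bin
size.  *Genomes*: i.i.d. bases at the target GC content with
`P(G | GC) = (1 ± amplitude)/2` on the Ori→Ter / Ter→Ori arcs, putting
the cumulative-skew minimum at Ori and maximum at Ter by construction.

*Basis counts for correlation benchmarks*: lognormal basis abundances
(per-species means ~ N(0,1), σ = 1) with specified pairwise log-scale
correlations, closed to fractions and multinomially sampled at 50,000
reads/sample.

## 8. Pipeline, configuration, determinism

`PipelineConfig` is a flat typed dataclass loadable from YAML; unknown
keys are rejected by name, all range violations are reported at once,
and every default equals the stage defaults above.  `run_pipeline`
executes profiles → decontamination → enrichment → networks →
replication (if coverage inputs are given) → associations (if
phenotypes are given), writes each stage's artefacts (TSV/JSON/GraphML)
and a `report.json` that is byte-identical across runs with identical
inputs, config and seed (no timestamps; JSON keys sorted).  The CLI
exposes the stages as checkpointed subcommands (`simulate`, `qc`,
`presence`, `decontam`, `enrich`, `network`, `ptr`, `assoc`,
`run-all`); exit codes are 0 (success), 2 (config error), 3 (data
error).  All randomness flows from explicit seeds through
`numpy.random.default_rng`.

Problem sizes used by the test suite and acceptance script — 2,000
samples for decontamination recovery, 500 samples × 20 species for
correlation benchmarks, 1–2 Mb genomes for replication, n = 5,000 for
the planted association, 50 replicate screens for null calibration —
are the package's benchmark conditions, chosen to make the planted
signals' recovery statistically unambiguous at desk scale.

## 9. Known limitations

* The filters are heuristics: a contaminant present in every batch of
  every variable at similar prevalence is indistinguishable from a
  genuine ubiquitous taxon by design (no negative-control or
  frequency-based modelling is attempted).
* Global removal means a species that is a contaminant in one cohort
  and genuine in another is lost everywhere.
* PTR estimation assumes a single circular replicon and complete
  references; draft-genome (fragment-sorted) modes and GC-bias
  correction of coverage are out of scope.
* The Fisher Monte-Carlo fallback estimates, rather than bounds, the
  exact p (standard error ≤ 0.0035 at 20,000 draws).
* Randomization and permutation p-values are discrete; their
  granularity is 1/n_iter.
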