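# Methods

## Cluster definition and detection

An S/T-Q motif is a serine or threonine immediately followed by a
glutamine.  An SCD under definition (k, W) is a region containing at
least k motifs whose span — from the S/T of the first motif through the
Q of the last, inclusive — is at most W residues.  Defaults are k = 3,
W = 50; the definition is valid for k ≥ 2 and W ≥ 2k (k non-overlapping
dipeptides must fit in the span).

Detection enumerates **all** motif occurrences (no greedy or
first-match semantics), tests every window of k *consecutive*
occurrences against the span rule, and transitively merges qualifying
windows that share occurrences into maximal regions.  Consecutive
windows suffice: occurrences are position-sorted, so any k-subset
spanning ≤ W contains k consecutive occurrences spanning ≤ W, and the
chain of consecutive windows inside a qualifying subset covers its full
interval.  The test suite checks this equivalence against a brute-force
oracle that enumerates all k-subsets.  Coordinates are 1-based
inclusive throughout; only the BED export converts to 0-based
half-open.  Ambiguity characters (B, Z, X, U, O) are retained in
sequences and never match the motif; splice variants are independent
records; each FASTA entry counts once toward a census.

A regex-style scan with greedy gap matching can miss overlapping
clusters on pathological sequences; exhaustive enumeration is a
deterministic superset of such behaviour, which is why the census here
may be a strict superset of what a pattern-server query would return on
the same input.

## Null model

Protein i of length L_i is modelled as a Bernoulli trial that contains
an SCD with probability p_i; the expected census size is Σ p_i and the
census size under the null is Poisson-binomial.  Its exact tail is
computed by O(n²) convolution (`exact_dp`); a normal approximation with
continuity correction (μ = Σp_i, σ² = Σp_i(1−p_i)) is available for
very large proteomes.  p-values below 1e−15 are displayed as "< 1e−15".

### Rate estimation

Three λ estimators are provided because the appropriate choice depends
on the question asked:

* `per_protein` (default): λ_i = m_i / L_i — conditions on each
  protein's own motif count, appropriate when asking whether motifs are
  *clustered* beyond chance given their abundance;
* `global_mean_per_protein`: λ_i = mean(m) / L_i — the mean motif count
  per protein divided by each length;
* `global_per_residue`: λ = Σm / ΣL — one pooled per-residue rate,
  appropriate when asking whether a proteome has more SCD proteins than
  its overall composition predicts.

### Event models

`p_i` is the probability that ≥ k motif events fall within some window
of ≤ W residues.  Two event laws are implemented:

* **indicator** — independent per-residue Bernoulli(λ) events, the
  discrete analogue of a Poisson process.  Exact enumeration over all
  2^L indicator vectors is available for L ≤ 25 and is the oracle for
  the Monte Carlo path.
* **dipeptide** (default) — the law of actual S/T-Q occurrences in an
  i.i.d. residue sequence.  A motif occupies two residues, so motifs at
  adjacent positions are impossible (the Q of one would have to be the
  S/T of the next), while any non-adjacent position set S has
  probability λ^|S| of being jointly occupied.  These "at least"
  probabilities determine the full joint law of the occurrence vector
  by inclusion–exclusion, and they depend on the composition only
  through λ.  Simulating residue classes with P(S/T) = P(Q) = √λ
  therefore reproduces the law of *any* composition with that rate
  exactly (it requires λ ≤ 0.25, far above any biological rate).  Exact
  enumeration over 3^L class sequences is available for L ≤ 14.

The indicator idealization permits adjacent events and therefore
overstates clustering: at (k=3, W=50) and a yeast-like rate the event
probability is inflated by roughly the fraction of motif triples
containing an adjacent pair, 1 − C(48,3)/C(50,3) ≈ 6–12% relative,
an effect we measured directly by simulation (ratio ≈ 0.94 at L = 400).
This is why the dipeptide model is the default for census-level
expectations and for comparisons against sequence-level simulation;
a regression test asserts dipeptide ≤ indicator on exact enumerations.

### Monte Carlo

The Monte Carlo estimator simulates the chosen event law and records,
per replicate, the completion position of the *first* qualifying
cluster.  The cumulative histogram of completion positions yields p(L)
for every L up to L_max from a single simulation batch ("first-passage
curve"), monotone in L by construction; a whole proteome sharing one
rate costs one batch.  Default 10^5 replicates, seeded; per-protein
calls are deduplicated by (L, λ) class.  Standard errors are binomial.
Shared seeds couple estimates across λ, W and k, so the monotonicity
properties (p_i non-decreasing in λ, L, W; non-increasing in k) hold
exactly in the coupled estimates and are asserted in tests.

### Approximation

The closed-form path uses a product-type scan-statistic approximation:
P(no W-window holds ≥ k) ≈ q_W · r^(L−W) with q_w the binomial
probability of < k events in a w-window and r = q_{W+1}/q_W the
per-step no-new-cluster factor.  It is adequate at small λ·W and
degrades at high rates; Monte Carlo is authoritative and the
approximation is only validated against it.

## Overlap, enrichment and length fit

Overlap tests use the exact hypergeometric upper tail, inclusive
(P(X ≥ x)); the inclusive convention is stated because published
analyses often leave it implicit.  Ids outside the declared universe
are dropped with a logged count; the universe defaults to the scanned
proteome's id set.  Term enrichment tests every term annotating at
least `min_term_size` (default 2) universe proteins, applies Bonferroni
over exactly the tested terms and Benjamini–Hochberg FDR over the same
set, and flags rows with Bonferroni-corrected p ≤ 0.01 by default.
Annotation maps are used exactly as given — no ontology-graph
propagation.

The length fit estimates (μ, σ) of a log-normal by maximum likelihood
on natural-log lengths, partitions the fitted distribution into 20
equal-probability bins, merges adjacent bins until every expected count
is ≥ 5, and refers Pearson's X² to chi-square with df = bins − 3
(two estimated parameters).  Estimating parameters from raw data
rather than from binned counts makes this df choice slightly
conservative in theory (Chernoff–Lehmann); with 20 equal-probability
bins the effect is negligible, and a 500-replicate calibration in the
test suite confirms the p-values are uniform to a Kolmogorov–Smirnov
check at the 1% level.

## Flank profiles

Profiles pool counts per offset over all sites (offsets −5..+5, S/T at
0).  Offsets that fall outside a protein are dropped from that offset's
denominator rather than dropping the whole site or padding — this
maximizes data use and keeps every populated offset column-stochastic.
Only sites whose following residue is Q are profiled by default (the
pS/T-Q definition); others are excluded with a count.  Non-standard
residues at a flanking position are excluded from that offset's total.
Background comparison reports per-cell log2((f+ε)/(g+ε)) with
ε = 1/(2·max total) and delta-method binomial standard errors; cells at
offsets with zero totals are missing, not zero.

## Synthetic data

The generator emulates the features the pipeline's statistics depend
on, with full determinism per seed:

* **lengths** — log-normal(μ = 6.0, σ = 0.55) truncated to
  [50, 3000] by rejection, giving a median of ~400 residues, the scale
  of a typical proteome;
* **composition** — i.i.d. residues; the bundled yeast-like preset
  (S 9.0%, T 5.9%, Q 3.9%, remainder uniform) implies a background
  motif rate λ = P(S∪T)·P(Q) ≈ 5.8 × 10⁻³ per residue;
* **planted SCDs** — k S/T-Q dipeptides overwritten at positions
  spanning ≤ W in distinct proteins.  Overwriting (not inserting)
  keeps the length model exact, and an S/T-then-Q write can never
  create a motif outside the planted set, so scanner recall of plants
  is 1.0 by construction;
* **phosphosites** — sampled from S/T-Q positions, optionally
  preferring planted regions, spaced ≥ 2·flank+2 apart so flank
  rewrites never collide; an offset bias (residue r, probability q)
  rewrites the flank so the marginal frequency of r at that offset is
  exactly q;
* **annotations** — background terms assigned independently of census
  membership, plus an optional planted term with separate inside- and
  outside-census rates.

What the generator does **not** emulate: real domain architecture,
compositional heterogeneity along sequences, homology between
proteins, or database-specific redundancy.  Passing tests therefore
demonstrate the correctness and calibration of the algorithms under
the stated stochastic model, not the biological census counts of any
particular database release — which is why census numbers on real
proteomes are commands to run, not values the suite asserts.

## Problem sizes and numerical choices

The statistical checks run at: 1,000 random sequences (lengths
10–2,000) for scanner/oracle equivalence; 500 clusters planted in a
10,000-protein proteome for recall; 200 replicate 100-protein proteomes
(max length 1,200, 4 × 10⁵ Monte Carlo replicates for the probability
curve) for generative consistency of Σp_i, with the Monte Carlo error
folded conservatively (fully correlated) into the comparison's standard
error; a 54-point (L ≤ 20, λ, k, W) lattice against exhaustive
enumeration; 200 replicates for enrichment calibration/power and 500
for length-fit calibration.  These sizes were chosen so each property
is measured with comfortable margin while the whole suite stays quick
on a laptop.

Ties and degenerate inputs: detection is deterministic, so no
tie-breaking is needed; an empty proteome yields an empty census;
proteins shorter than 2k have p_i = 0; λ = 0 gives p_i = 0; λ > 1 is
rejected; identical lengths make the log-normal fit degenerate and
raise an error; a census disjoint from all terms is an empty result,
not an error.

## Known limitations

* The motif pattern language covers fixed-length residue-class
  patterns only (e.g. `[ST]Q`); general PROSITE syntax is out of scope.
* The continuous-time scan-statistic literature offers exact formulas
  for the indicator model; we deliberately use enumeration + Monte
  Carlo instead, trading closed forms for oracle-checkable code.
* Per-protein λ mode on a large proteome implies many (L, λ) classes
  and thus many Monte Carlo batches; pooled modes reuse one
  first-passage curve and are much faster.
* Annotation enrichment treats terms independently (no graph
  structure) and the census/universe ids must share a namespace with
  the annotation file.
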