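# Methods

## Model and assumptions

A sequenced clone from an asexual evolution experiment is separated from
the ancestor by a known number of generations `t_g`. Under neutrality,
synonymous substitutions of mutation type `c` (six strand-collapsed
categories: A:T→G:C, A:T→C:G, A:T→T:A, G:C→A:T, G:C→T:A, G:C→C:G)
accumulate along that lineage as a Poisson process with mean
`mu_c · t_g · S_gc`, where `S_gc` counts the clone's callable synonymous
opportunities of type `c`. The assumptions are:

* most synonymous mutations are selectively neutral (selection elsewhere
  in the genome does not change the expected neutral accumulation in an
  asexual lineage — it is a chain of replication events);
* mutation rates are homogeneous along the genome within a type and
  constant in time (no mutator lineages in the data);
* substitutions are rare enough that a site is hit at most once.

`mu_c` is expressed per ancestral base pair of the matching type per
generation, so the overall per-bp rate is the composition-weighted sum
`mu = f_AT·Σ_AT mu_c + f_GC·Σ_GC mu_c` with `f_AT`, `f_GC` the genomic
base-pair frequencies.

## Synonymous opportunity counting

For every coding position and each of its three possible changes, the
change counts as an opportunity of its type iff it leaves the amino acid
unchanged in **every** CDS containing the position (translation with the
bacterial/archaeal code, NCBI table 11; start codons translated as
ordinary codons). Changes that create or destroy stop codons are never
synonymous; stop-to-stop changes are. Positions inside overlapping CDS
contribute to the coding length once. Features whose span is not a whole
number of codons (or marked pseudo, or with unsupported compound
locations) are skipped with a logged count. Circular genomes are
supported; origin-wrapping features are handled by coordinate rotation.
The implementation is vectorised through a precomputed 64×3×4
codon/offset/alternative-base lookup, with a scalar fallback for
positions under overlapping CDS; it is checked exactly against an
independent brute-force enumeration (all `3L` changes, full
retranslation) on genomes up to 10 kb.

Two site conventions coexist deliberately. The *simple* count — one
third of the protein-coding length, since three changes are possible
from any base — feeds the cross-study estimator, where comparability and
robustness to annotation detail matter more than precision. The *full*
per-type enumeration feeds the likelihood and the spectrum statistics,
where base-composition effects are the object of interest.

## Estimators

**Simple pooled estimator.** `rate = m / (G · S)` with `G` cumulative
generations and `S` the simple site count. Its confidence interval is
the exact Clopper–Pearson binomial interval on the per-trial probability
with `G·S` trials, evaluated through beta quantiles (valid for
non-integral trial counts). At the trial counts involved (≥10¹⁰) it is
numerically indistinguishable from the exact Poisson interval; the test
suite asserts agreement to 4 significant figures.

**Blocked maximum likelihood.** The log likelihood sums over types and
clones, but clone contributions are *averaged within population blocks*:

```
l(mu) = Σ_p (1/n_p) Σ_{g∈p} Σ_c [ m_gc·ln(mu_c t_g S_gc) − mu_c t_g S_gc − ln(m_gc!) ]
```

with the `0·ln 0 = 0` convention, and `−∞` when some type has zero rate
but a positive count. Averaging, rather than summing, is the
pseudo-replication correction: sequencing a second clone from the same
population adds information about the population's shared branch only,
and the block average prevents it from being double-counted as if
independent. Duplicating every clone within a block provably leaves the
likelihood (and so the estimates) unchanged, which the tests assert.

Differentiating per type gives the closed-form maximiser

```
mu_c = [Σ_p (1/n_p) Σ_g m_gc] / [Σ_p (1/n_p) Σ_g t_g·S_gc]
```

used by default; a bounded one-dimensional numeric maximisation (the
likelihood separates by type; optimisation in log-rate, floor 10⁻¹⁸ per
bp per generation, relative tolerance 10⁻¹²) is kept as a cross-check
and must agree to 6 significant figures on random instances. Types never
observed get rate 0, reported together with the likelihood-based
one-sided upper bound for a Poisson process observed to produce zero
events, `−ln(1−level)/T_c`, where `T_c` is the block-weighted exposure.

**Jackknife.** Confidence limits for the combined rate use Tukey's
delete-one jackknife over *populations*: dropping block `i` gives
`theta_(−i)`, pseudo-values `n·theta − (n−1)·theta_(−i)`, and the
interval is their mean ± `t_{1−alpha/2, n−1}` × SE, truncated below at 0.
The Student-t reference with `n−1` degrees of freedom is the standard
Tukey procedure (7 df for eight populations). We jackknife the combined
rate, not each per-type rate, since the overall rate is the quantity
interval estimates are wanted for. In rare unbalanced configurations the
pseudo-value interval can exclude the full-data estimate; the pipeline
widens the interval minimally to include it. Zero-mutation clones are
included in the likelihood — their Poisson zeros are informative.

The headline analysis of the real experiment used per-genome
callable-site tables produced by a resequencing pipeline; such tables
are accepted as input (TSV of clone, type, sites) but are not published,
so the blocked-ML stage is validated by simulation with known truth
rather than by reproducing the published interval.

## Spectrum statistics

Raw counts confound mutation pressure with site availability, so every
ratio normalises counts by the per-type synonymous opportunities `S_c`
("sites at risk"): the corrected transition:transversion ratio is
`[Σ_ts m_c/S_c] : [Σ_tv m_c/S_c]`, reported as 1:x (expectation 1:2
under a uniform per-site probability of all six types — two transition
types against four transversion types), and the G:C→A:T fold bias is
`(m_a/S_a)/(m_b/S_b)`. Both are invariant under joint rescaling of the
opportunities, so callable-site proportionality drops out.

Significance uses the exact two-tailed binomial test with the
minimum-likelihood rule: the p-value sums null probabilities of all
outcomes no more probable than the observed one (a 10⁻¹² relative guard
admits floating-point ties, e.g. the symmetric outcome at p₀ = ½). Nulls
are opportunity-implied and recorded in the report: transitions among
all events with `p₀ = S_ts/S_total`; G:C→A:T among the two transition
types with `p₀ = S_GC>AT/(S_GC>AT + S_AT>GC)`. Exactness is verified
against an exhaustive rational-arithmetic oracle for all totals ≤ 50.
The calibration check uses the real study's scale — 35 events, null
p₀ = 1/3 — a design chosen because its exact attainable size at the
nominal 5% level is 0.0477; exact tests on small discrete supports can
otherwise be far more conservative than nominal (e.g. 0.032 at n = 35,
p₀ = 0.35), which would say nothing about the implementation.

## dN/dS

Per-clone dN/dS uses unweighted fractional site counting: each coding
position contributes the fraction of its three changes that are
synonymous to `S_sites` and the remainder to `N_sites` (totals sum to
the coding length), and the ratio is `(N_obs/N_sites)/(S_obs/S_sites)`.
Nonsense changes count as nonsynonymous. No multiple-hit correction is
applied: per-clone substitution counts here are far below one per gene,
where corrected and uncorrected estimators coincide. Clones with no
synonymous substitution get an undefined (not infinite) ratio. The
principal calibration is neutrality: mutations placed uniformly over all
coding changes yield a mean per-clone dN/dS within three standard errors
of 1.0 across replicates.

## Simulator

`SimulationConfig` defaults mirror the real study's design: 8
populations, two clones per population sampled at 40,000 generations,
half of each clone's history on the population's shared lineage
(`alpha = 0.5`), genome GC 0.508 and coding fraction 0.87 (the ancestral
*E. coli* B values), with the true spectrum AT-biased (G:C→A:T 14.5×
A:T→G:C, corrected ts:tv 1:1.99 — the measured values) and the combined
rate 8.9 × 10⁻¹¹ per bp per generation. To keep simulation affordable
the default genome is 46 kb — 1/100 of the real 4.6 Mb — with rates
scaled up 100-fold, preserving all expected counts; `calibrate_rates`
additionally rescales rates so the expected number of independent
synonymous events matches a target (35 by default, the real dataset's
information content). Validation runs use 200 replicates for recovery
and coverage, 120 for the dN/dS calibration; the whole suite runs in
seconds.

Genomes are generated gene-by-gene: ATG start, body codons drawn iid
from the base composition restricted to sense codons, one terminal stop,
random strand, exponential intergenic gaps sized for the coding
fraction. Excluding the AT-rich stop codons would pull coding GC about
one point above target, so the codon-sampling composition is adjusted by
a fixed-point iteration; realised GC lands within 0.1 point of target at
100 kb. The genealogy is star-like — a single shared prefix per
population — which induces the pseudo-replication structure the
estimator corrects for without the cost of a full coalescent. Mutations
are placed uniformly over positions carrying the matching ancestral
pair, with collisions resampled (infinite sites; a warning fires if over
1% of placements collide). Selection, mutator phenotypes, sequencing
error and calling error are not simulated: passing recovery tests shows
the estimator is correct under its own model, not that real pipelines
introduce no biases upstream.

## Degenerate inputs and numerical conventions

* Ambiguity codes in sequences are rejected at load; mutation tables are
  validated row-wise with all problems reported together.
* A mutation table may legitimately collapse to fewer events than
  records; identical positions in different populations never merge.
* `S_gc = 0` with `m_gc > 0` is rejected at construction (a mutation
  cannot be observed where it cannot be called).
* All randomness flows from a single seed through spawned child
  generators; repeated calls are bit-identical.
* Rates are reported in full precision internally and rounded to 2
  significant figures only at the reporting boundary, matching the
  convention for such estimates.

## Known limitations

* The corrected-spectrum ratios for the real dataset require the full
  4.6-Mb REL606 annotation, which cannot ship with the package; the
  counting machinery is instead verified exactly against brute-force
  oracles on small genomes.
* Spliced CDS, selenocysteine recoding and programmed frameshifts are
  out of scope; such features are skipped.
* No codon-usage or GC-equilibrium modelling; the spectrum statistics
  describe mutation pressure, not its long-term compositional
  consequences.
* The jackknife interval is approximate for very sparse data (few
  events spread over few populations); coverage at the real study's
  scale is validated by simulation at ≥ 0.85 for the nominal 95% level.
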