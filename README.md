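# synrate

Spontaneous base-substitution rates from synonymous substitutions
accumulated in evolution experiments.

When replicate bacterial populations are propagated for thousands of
generations and clones are whole-genome sequenced, the synonymous
substitutions they carry measure the point-mutation rate directly: most
synonymous changes are selectively neutral, so a clone's lineage
accumulates them as a simple chain of replication events, unaffected by
the pervasive positive selection that inflates nonsynonymous counts.
`synrate` is for researchers analysing such resequencing data (and for
anyone who wants calibrated simulations of it): it turns an annotated
ancestral genome plus a table of clone-level substitutions into per-type
and overall mutation-rate estimates with honest confidence limits, a
composition-corrected mutational spectrum, and per-clone dN/dS.

## The model

Synonymous substitutions of mutation type *c* (one of the six
strand-collapsed base-pair changes, e.g. G:C→A:T) accumulate in the
lineage of clone *g* as a Poisson process:

```
E[m_gc] = mu_c · t_g · S_gc
```

where `t_g` is elapsed generations and `S_gc` the clone's callable
synonymous opportunities of type *c* — the number of (position, change)
combinations in the ancestral annotation at which that change would leave
every encoded amino acid unchanged (bacterial code, NCBI table 11).
Clones from the same population share part of their history and are not
independent; the log likelihood therefore **averages** clone
contributions within population blocks, so each population counts once
no matter how many of its clones were sequenced. Per-type maxima have a
closed form (block-weighted counts over block-weighted exposures), and
the overall per-bp rate weights them by the ancestral base-pair
composition:

```
mu = f_AT · (mu_AT>GC + mu_AT>CG + mu_AT>TA) + f_GC · (mu_GC>AT + mu_GC>TA + mu_GC>CG)
```

Confidence limits come from Tukey's jackknife, deleting one whole
population at a time. A simpler cross-study estimator — observed
synonymous mutations over (cumulative generations × one-third of the
protein-coding length), with exact Clopper–Pearson binomial limits — is
also provided, as are composition-corrected spectrum ratios
(transition:transversion, G:C→A:T fold bias) with exact two-tailed
binomial tests, Nei–Gojobori-style fractional site counting for dN/dS,
and a forward simulator with known true rates.

## Worked example

The long-term *E. coli* dataset ships with the package: 52 clone-level
synonymous substitutions in 19 clones from 8 populations, collapsing to
35 independent events.

```python
from synrate import (load_ltee_records, collapse_events, spectrum_counts,
                     point_estimate_simple, binomial_rate_ci)

records = load_ltee_records()
events = collapse_events(records)
counts, ts, tv = spectrum_counts(events)
print(len(records), len(events), ts, tv)   # 52 35 19 16

est = point_estimate_simple(25, 300_000, 941_000)
lo, hi = binomial_rate_ci(25, 300_000 * 941_000)
print(f"{est.rate:.3g} [{lo:.2g}, {hi:.2g}]")
# 8.86e-11 [5.7e-11, 1.3e-10]   per bp per generation
```

The same numbers from the shell:

```
$ synrate estimate-simple --mutations 25 --generations 300000 --sites 941000
{
  "method": "simple",
  "rate": 8.85582713425434e-11,
  "ci_lower": 5.7310243882583954e-11,
  "ci_upper": 1.307294782031604e-10,
  ...
}
```

i.e. 8.9 × 10⁻¹¹ per bp per generation with 95% limits [5.7–13] × 10⁻¹¹,
or about 0.00041 mutations per genome per generation for a 4.6-Mb genome.

The blocked-ML route needs per-type opportunity tables from an annotated
genome, so the end-to-end demonstration uses the simulator (an
experiment at 1/100 genome scale with rates scaled up by 100, true
combined rate 8.9 × 10⁻⁹):

```
$ synrate simulate --seed 7 --out sim/
$ synrate estimate-ml --mutations sim/mutations.tsv --clones sim/clones.tsv \
      --genome sim/genome.gff3 --fasta sim/genome.fasta
{
  "method": "blocked_ml",
  "rate": 8.71559351451267e-09,
  "ci": {"lower": 5.164920043480166e-09, "upper": 1.2266266985545174e-08, ...}
  ...
}
```

The estimate (8.7 × 10⁻⁹) recovers the known truth within its jackknife
interval. Averaged over many replicates the estimator is unbiased:

```python
from synrate import SimulationConfig, recovery_experiment
rep = recovery_experiment(SimulationConfig(seed=3), replicates=200, seed=42)
print(f"{rep.relative_bias:+.2%}  coverage {rep.coverage:.2f}")
# -0.41%  coverage 0.95
```

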