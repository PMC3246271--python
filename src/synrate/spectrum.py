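"""Mutational-spectrum statistics corrected for sequence composition.

Raw counts of synonymous substitutions confound the mutation process with
the availability of sites at which each change *can* be synonymous. The
statistics here normalise each type's count by its synonymous opportunity
count S_c before forming ratios, so a genome rich in fourfold-degenerate
G:C third positions, say, does not masquerade as a G:C-biased mutation
process. Two headline quantities:

* the corrected transition:transversion ratio, reported as 1:x — under a
  uniform per-site probability of all six substitution types the
  expectation is 1:2 (two transition types versus four transversion types);
* the fold bias between two types, e.g. G:C->A:T versus A:T->G:C, the
  classic AT-ward mutation-pressure measure.

Significance is assessed with exact two-tailed binomial tests using the
minimum-likelihood rule (the two-sided p-value sums the probabilities of
all outcomes no more probable than the observed one).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .catalog import MutationEvent, spectrum_counts
from .genome import MutationType, SiteOpportunityTable, expected_spectrum

__all__ = [
    "BinomialTestResult",
    "SpectrumReport",
    "corrected_ts_tv",
    "fold_bias",
    "two_tailed_binomial_test",
    "spectrum_report",
]


@dataclass(frozen=True)
class BinomialTestResult:
    """An exact two-tailed binomial test and the null it was built from."""

    statistic: str          # what "successes" counts
    successes: int
    total: int
    null_probability: float
    p_value: float


@dataclass
class SpectrumReport:
    """Observed versus expected synonymous mutational spectrum."""

    observed: dict[MutationType, int]
    opportunities: dict[MutationType, int]
    expected_proportions: dict[MutationType, float]
    normalized_rates: dict[MutationType, float]   # count_c / S_c
    ts_tv: float                                   # the x of "1:x"
    gc_at_fold_bias: float
    ts_tv_test: BinomialTestResult
    bias_test: BinomialTestResult

    @property
    def n_events(self) -> int:
        return sum(self.observed.values())


def corrected_ts_tv(observed: Mapping[MutationType, int],
                    table: SiteOpportunityTable) -> float:
    """Composition-corrected transition:transversion ratio, as the x of 1:x.

    Each type's count is divided by its synonymous opportunities; the ratio
    of summed transversion rates to summed transition rates is returned, so
    a value of 2.0 means transversions are twice as frequent per site at
    risk (the uniform-probability expectation, given four transversion
    types and two transition types).
    """
    ts_rate = 0.0
    tv_rate = 0.0
    for t in MutationType:
        s = table.opportunities[t]
        if s <= 0:
            raise ValueError(f"zero synonymous opportunities for {t.value}")
        r = observed.get(t, 0) / s
        if t.is_transition:
            ts_rate += r
        else:
            tv_rate += r
    if ts_rate == 0:
        raise ValueError("no transitions observed; 1:x ratio undefined")
    return tv_rate / ts_rate


def fold_bias(observed: Mapping[MutationType, int],
              table: SiteOpportunityTable,
              type_a: MutationType, type_b: MutationType) -> float:
    """Per-opportunity rate of ``type_a`` over that of ``type_b``.

    Returns ``inf`` when ``type_b`` was never observed but ``type_a`` was.
    """
    s_a, s_b = table.opportunities[type_a], table.opportunities[type_b]
    if s_a <= 0 or s_b <= 0:
        raise ValueError("both types need positive synonymous opportunities")
    rate_a = observed.get(type_a, 0) / s_a
    rate_b = observed.get(type_b, 0) / s_b
    if rate_b == 0:
        return float("inf") if rate_a > 0 else float("nan")
    return rate_a / rate_b


def two_tailed_binomial_test(successes: int, total: int,
                             null_probability: float) -> float:
    """Exact two-tailed binomial p-value by the minimum-likelihood rule.

    The p-value is the total null probability of every outcome whose
    probability does not exceed that of the observed outcome (with a tiny
    relative guard for floating-point ties, so e.g. the symmetric outcome
    under p0 = 1/2 is always included). Observing the modal outcome gives
    p = 1.
    """
    if not 0 <= successes <= total:
        raise ValueError(f"need 0 <= successes <= total, got {successes}/{total}")
    if not 0 < null_probability < 1:
        raise ValueError("null probability must be strictly inside (0, 1)")
    k = np.arange(total + 1)
    pmf = stats.binom.pmf(k, total, null_probability)
    threshold = pmf[successes] * (1 + 1e-12)
    return float(min(1.0, pmf[pmf <= threshold].sum()))


def spectrum_report(events: Sequence[MutationEvent],
                    table: SiteOpportunityTable) -> SpectrumReport:
    """Assemble the full observed-versus-expected spectrum analysis.

    Two tests are run, each against the opportunity-implied null (the
    chance that a synonymous event falls in the focal class when every
    possible substitution is equally likely per site):

    * transitions versus transversions, null p = S_ts / S_total;
    * G:C->A:T versus A:T->G:C among transitions, null
      p = S_GC>AT / (S_GC>AT + S_AT>GC).
    """
    if not events:
        raise ValueError("no events supplied")
    observed, ts, tv = spectrum_counts(events)
    expected = expected_spectrum(table)
    rates = {}
    for t in MutationType:
        s = table.opportunities[t]
        rates[t] = observed[t] / s if s > 0 else float("nan")

    s_total = table.total
    p_ts = table.transition_total() / s_total
    ts_test = BinomialTestResult(
        statistic="transitions among all events", successes=ts,
        total=ts + tv, null_probability=p_ts,
        p_value=two_tailed_binomial_test(ts, ts + tv, p_ts),
    )

    n_gc_at = observed[MutationType.GC_AT]
    n_at_gc = observed[MutationType.AT_GC]
    s_pair = (table.opportunities[MutationType.GC_AT]
              + table.opportunities[MutationType.AT_GC])
    p_bias = table.opportunities[MutationType.GC_AT] / s_pair
    bias_test = BinomialTestResult(
        statistic="GC>AT among GC>AT + AT>GC events",
        successes=n_gc_at, total=n_gc_at + n_at_gc, null_probability=p_bias,
        p_value=(
            two_tailed_binomial_test(n_gc_at, n_gc_at + n_at_gc, p_bias)
            if n_gc_at + n_at_gc > 0 else float("nan")
        ),
    )

    return SpectrumReport(
        observed=observed,
        opportunities=dict(table.opportunities),
        expected_proportions=expected,
        normalized_rates=rates,
        ts_tv=corrected_ts_tv(observed, table),
        gc_at_fold_bias=fold_bias(observed, table,
                                  MutationType.GC_AT, MutationType.AT_GC),
        ts_tv_test=ts_test,
        bias_test=bias_test,
    )
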