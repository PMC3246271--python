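"""Base-substitution rate estimation from synonymous substitution counts.

Two estimators are provided.

*Simple estimator.* The rate is the number of observed synonymous
mutations divided by (cumulative generations x synonymous target sites),
with an exact (Clopper-Pearson) binomial confidence interval on the
per-site-per-generation probability. This is the cross-study comparison
estimator: it pools clones and uses the one-third site approximation.

*Blocked Poisson maximum likelihood.* Synonymous substitutions of each
mutation type accumulate along a clone's lineage as a Poisson process with
expectation ``mu_c * t_g * S_{g,c}`` (rate x generations x callable
synonymous opportunities of that type). Clones sampled from the same
population share part of their history and are therefore not independent;
the likelihood corrects for this pseudo-replication by *averaging* the
per-clone log likelihoods within population blocks, so each population
contributes one clone's worth of information regardless of how many of its
clones were sequenced. Per-type rates have a closed-form maximum
(block-weighted counts over block-weighted exposures), cross-checked here
by bounded numeric maximisation. The overall per-base-pair rate weights
the per-type rates by the genomic frequency of the matching ancestral base
pair, and confidence limits come from Tukey's jackknife over populations
(delete one whole population at a time).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, special, stats

from .genome import MutationType, SiteOpportunityTable

__all__ = [
    "CloneObservation",
    "PopulationBlock",
    "ConfidenceInterval",
    "RateEstimate",
    "JackknifeResult",
    "group_blocks",
    "point_estimate_simple",
    "binomial_rate_ci",
    "blocked_loglik",
    "closed_form_blocked_ml",
    "fit_blocked_ml",
    "combine_rates",
    "genomic_rate",
    "jackknife_ci",
    "estimate_rate_blocked",
]

_RATE_FLOOR = 1e-18  # lower bound for numeric maximisation, avoids log(0)


@dataclass(frozen=True)
class CloneObservation:
    """Per-clone synonymous mutation counts and exposures.

    ``counts[c]`` is the number of synonymous substitutions of type ``c``
    observed in the clone; ``sites[c]`` the callable synonymous
    opportunities of that type (ancestral opportunities when no per-clone
    callable table is available); ``generations`` the elapsed generations
    since the ancestor.
    """

    clone: str
    population: str
    generations: int
    counts: dict[MutationType, int]
    sites: dict[MutationType, float]

    def __post_init__(self) -> None:
        if self.generations <= 0:
            raise ValueError("generations must be > 0")
        for t in MutationType:
            m = self.counts.get(t, 0)
            s = self.sites.get(t, 0.0)
            if m < 0 or int(m) != m:
                raise ValueError(f"count for {t.value} must be a non-negative "
                                 f"integer, got {m}")
            if s < 0:
                raise ValueError(f"sites for {t.value} must be >= 0, got {s}")
            if s == 0 and m > 0:
                raise ValueError(
                    f"clone {self.clone}: {m} mutations of type {t.value} "
                    "but zero callable sites"
                )


@dataclass(frozen=True)
class PopulationBlock:
    """All sequenced clones of one replicate population."""

    population: str
    observations: tuple[CloneObservation, ...]

    def __post_init__(self) -> None:
        if not self.observations:
            raise ValueError("a block must contain at least one observation")
        if any(o.population != self.population for o in self.observations):
            raise ValueError("block members must share the population id")

    @property
    def n(self) -> int:
        return len(self.observations)


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    level: float
    method: str


@dataclass
class RateEstimate:
    """A point-mutation rate estimate.

    ``rate`` is per base pair per generation; ``per_type`` (blocked-ML
    only) maps each mutation type to its rate per ancestral base pair of
    the matching type per generation.
    """

    rate: float
    method: str
    per_type: dict[MutationType, float] | None = None
    per_type_upper: dict[MutationType, float] | None = None
    genomic: float | None = None
    ci: ConfidenceInterval | None = None

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.ci is not None and not (
            self.ci.lower <= self.rate <= self.ci.upper
        ):
            raise ValueError("point estimate outside its confidence interval")


@dataclass
class JackknifeResult:
    """Tukey's delete-one jackknife over population blocks."""

    estimate: float                 # full-data estimate
    leave_one_out: np.ndarray       # delete-one estimates, one per block
    pseudo_values: np.ndarray       # n*theta - (n-1)*theta_(-i)
    n: int
    point: float                    # mean of pseudo-values
    se: float
    df: int
    ci: ConfidenceInterval


def group_blocks(observations: Iterable[CloneObservation]) -> list[PopulationBlock]:
    """Group clone observations into population blocks, sorted by population."""
    by_pop: dict[str, list[CloneObservation]] = {}
    for o in observations:
        by_pop.setdefault(o.population, []).append(o)
    return [PopulationBlock(p, tuple(obs)) for p, obs in sorted(by_pop.items())]


# ---------------------------------------------------------------------------
# simple estimator

def point_estimate_simple(m: int, generations: float, sites: float) -> RateEstimate:
    """Rate = observed synonymous mutations / (generations x target sites)."""
    if generations <= 0 or sites <= 0:
        raise ValueError("generations and sites must both be positive")
    if m < 0 or int(m) != m:
        raise ValueError(f"mutation count must be a non-negative integer, got {m}")
    return RateEstimate(rate=m / (generations * sites), method="simple")


def binomial_rate_ci(m: int, trials: float, level: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided limits on the per-trial probability.

    ``trials`` is generations x sites; it may be non-integral (site counts
    are effective numbers), in which case the beta-quantile form of the
    Clopper-Pearson limits is evaluated at the fractional total.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if m < 0 or m > trials:
        raise ValueError(f"need 0 <= m <= trials, got m={m}, trials={trials}")
    alpha = 1.0 - level
    lower = 0.0 if m == 0 else float(stats.beta.ppf(alpha / 2, m, trials - m + 1))
    upper = 1.0 if m == trials else float(
        stats.beta.ppf(1 - alpha / 2, m + 1, trials - m))
    return lower, upper


def genomic_rate(mu: float, genome_size: float) -> float:
    """Per-genome per-generation rate: per-bp rate x genome size."""
    if mu < 0 or genome_size < 0:
        raise ValueError("rate and genome size must be non-negative")
    return mu * genome_size


# ---------------------------------------------------------------------------
# blocked Poisson likelihood

def blocked_loglik(blocks: Sequence[PopulationBlock],
                   rates: Mapping[MutationType, float]) -> float:
    """Block-averaged Poisson log likelihood of per-type rates.

    l(mu) = sum over blocks of (1/n_p) * sum over member clones of
    sum over types of [ m*ln(mu*t*S) - mu*t*S - ln(m!) ], with the
    0*ln(0) = 0 convention. Returns -inf when some type has rate 0 but a
    positive count somewhere.
    """
    for t in MutationType:
        if rates.get(t, 0.0) < 0:
            raise ValueError(f"rate for {t.value} must be >= 0")
    total = 0.0
    for block in blocks:
        block_sum = 0.0
        for obs in block.observations:
            for t in MutationType:
                m = obs.counts.get(t, 0)
                lam = rates.get(t, 0.0) * obs.generations * obs.sites.get(t, 0.0)
                if lam == 0.0:
                    if m > 0:
                        return -math.inf
                    continue  # 0*ln(0) - 0 = 0
                block_sum += m * math.log(lam) - lam - special.gammaln(m + 1)
        total += block_sum / block.n
    return total


def closed_form_blocked_ml(
    blocks: Sequence[PopulationBlock],
) -> dict[MutationType, float]:
    """Closed-form maximiser of :func:`blocked_loglik`.

    Differentiating the block-averaged likelihood gives, per type,
    mu_c = [sum_p (1/n_p) sum_g m_{g,c}] / [sum_p (1/n_p) sum_g t_g S_{g,c}].
    Types with zero weighted counts get rate 0; a type with zero total
    exposure but positive counts is impossible (guarded at construction).
    """
    rates = {}
    for t in MutationType:
        num = 0.0
        den = 0.0
        for block in blocks:
            num += sum(o.counts.get(t, 0) for o in block.observations) / block.n
            den += sum(o.generations * o.sites.get(t, 0.0)
                       for o in block.observations) / block.n
        rates[t] = num / den if den > 0 else 0.0
    return rates


def _numeric_blocked_ml(blocks: Sequence[PopulationBlock],
                        xtol: float = 1e-12) -> dict[MutationType, float]:
    """Bounded per-type numeric maximisation (the likelihood separates by
    type, so six one-dimensional problems)."""
    rates: dict[MutationType, float] = {}
    start = closed_form_blocked_ml(blocks)
    for t in MutationType:
        num = sum(sum(o.counts.get(t, 0) for o in b.observations) / b.n
                  for b in blocks)
        den = sum(sum(o.generations * o.sites.get(t, 0.0)
                      for o in b.observations) / b.n for b in blocks)
        if num == 0.0 or den == 0.0:
            rates[t] = 0.0
            continue

        def neg_ll(log_mu: float, t=t) -> float:
            mu = math.exp(log_mu)
            test = dict(start)
            test[t] = mu
            return -blocked_loglik(blocks, test)

        centre = math.log(max(start[t], _RATE_FLOOR))
        res = optimize.minimize_scalar(
            neg_ll, bracket=(centre - 1.0, centre, centre + 1.0),
            options={"xtol": xtol},
        )
        rates[t] = math.exp(float(res.x))
    return rates


def fit_blocked_ml(observations: Sequence[CloneObservation],
                   blocks: Sequence[PopulationBlock] | None = None,
                   method: str = "closed_form",
                   level: float = 0.95) -> RateEstimate:
    """Blocked maximum-likelihood per-type rates.

    ``method`` is ``"closed_form"`` (default) or ``"numeric"`` (bounded
    maximisation, used as a cross-check of the closed form). Types never
    observed get rate 0 and a one-sided upper bound derived from the
    likelihood of observing zero events over the block-weighted exposure.
    """
    if blocks is None:
        if not observations:
            raise ValueError("no observations supplied")
        blocks = group_blocks(observations)
    if not blocks:
        raise ValueError("no population blocks supplied")
    for t in MutationType:
        if all(o.sites.get(t, 0.0) == 0 for b in blocks for o in b.observations):
            raise ValueError(f"zero total exposure for type {t.value}")

    if method == "closed_form":
        per_type = closed_form_blocked_ml(blocks)
    elif method == "numeric":
        per_type = _numeric_blocked_ml(blocks)
    else:
        raise ValueError(f"unknown method {method!r}")

    upper: dict[MutationType, float] = {}
    for t in MutationType:
        if per_type[t] == 0.0:
            exposure = sum(
                sum(o.generations * o.sites.get(t, 0.0) for o in b.observations)
                / b.n
                for b in blocks
            )
            # P(0 events) = exp(-mu * T) = 1 - level at the bound
            upper[t] = -math.log(1.0 - level) / exposure if exposure > 0 else math.inf
    return RateEstimate(
        rate=0.0, method=f"blocked_ml[{method}]", per_type=per_type,
        per_type_upper=upper or None,
    )


def combine_rates(per_type: Mapping[MutationType, float],
                  table: SiteOpportunityTable | tuple[float, float]) -> float:
    """Overall per-bp rate: per-type rates weighted by ancestral base-pair
    frequencies.

    mu = f_AT * (mu_AT>GC + mu_AT>CG + mu_AT>TA)
       + f_GC * (mu_GC>AT + mu_GC>TA + mu_GC>CG)

    ``table`` may be a :class:`SiteOpportunityTable` or a bare
    ``(f_at, f_gc)`` pair.
    """
    if isinstance(table, SiteOpportunityTable):
        f_at, f_gc = table.f_at, table.f_gc
    else:
        f_at, f_gc = table
    if abs(f_at + f_gc - 1.0) > 1e-9:
        raise ValueError("base-pair frequencies must sum to 1")
    at_sum = sum(per_type.get(t, 0.0) for t in MutationType
                 if t.ancestral_pair == "AT")
    gc_sum = sum(per_type.get(t, 0.0) for t in MutationType
                 if t.ancestral_pair == "GC")
    return f_at * at_sum + f_gc * gc_sum


def jackknife_ci(estimator: Callable[[Sequence[PopulationBlock]], float],
                 blocks: Sequence[PopulationBlock],
                 level: float = 0.95) -> JackknifeResult:
    """Tukey's delete-one jackknife over population blocks.

    Each resampled dataset drops all clones of one population. Pseudo-values
    are ``n*theta - (n-1)*theta_(-i)``; the interval is their mean +/- a
    Student-t quantile (n-1 degrees of freedom) times their standard error,
    truncated below at 0 (rates cannot be negative).
    """
    blocks = list(blocks)
    n = len(blocks)
    if n < 2:
        raise ValueError("jackknife needs at least 2 population blocks")
    theta = float(estimator(blocks))
    loo = np.array([
        float(estimator(blocks[:i] + blocks[i + 1:])) for i in range(n)
    ])
    pseudo = n * theta - (n - 1) * loo
    point = float(pseudo.mean())
    se = float(pseudo.std(ddof=1) / math.sqrt(n))
    tq = float(stats.t.ppf(1 - (1 - level) / 2, df=n - 1))
    lower = max(0.0, point - tq * se)
    upper = point + tq * se
    return JackknifeResult(
        estimate=theta, leave_one_out=loo, pseudo_values=pseudo, n=n,
        point=point, se=se, df=n - 1,
        ci=ConfidenceInterval(lower, upper, level, "tukey_jackknife"),
    )


def estimate_rate_blocked(observations: Sequence[CloneObservation],
                          table: SiteOpportunityTable | tuple[float, float],
                          genome_size: float | None = None,
                          level: float = 0.95) -> RateEstimate:
    """Full blocked-ML pipeline: per-type rates, composition-weighted
    combined rate, and a jackknife interval on the combined rate."""
    blocks = group_blocks(observations)

    def combined(bs: Sequence[PopulationBlock]) -> float:
        return combine_rates(closed_form_blocked_ml(bs), table)

    fit = fit_blocked_ml(observations, blocks)
    rate = combined(blocks)
    ci = None
    if len(blocks) >= 2:
        jk = jackknife_ci(combined, blocks, level)
        lo = min(jk.ci.lower, rate)
        hi = max(jk.ci.upper, rate)
        ci = ConfidenceInterval(lo, hi, level, "tukey_jackknife")
    return RateEstimate(
        rate=rate, method="blocked_ml", per_type=fit.per_type,
        per_type_upper=fit.per_type_upper,
        genomic=None if genome_size is None else genomic_rate(rate, genome_size),
        ci=ci,
    )
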