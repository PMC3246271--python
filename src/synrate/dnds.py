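"""Per-clone dN/dS from observed substitutions and the ancestral genome.

The ratio of nonsynonymous changes per nonsynonymous site to synonymous
changes per synonymous site screens for selection: values near 1 are the
neutral expectation, values above 1 indicate positive selection on
amino-acid-changing mutations. In an evolution experiment this screen
justifies (or forbids) using nonsynonymous changes for rate estimation —
clones under pervasive positive selection must be analysed through their
synonymous changes only.

Sites are counted with unweighted fractional opportunities: each coding
position contributes the fraction of its three possible changes that are
synonymous to the synonymous site total, and the remainder to the
nonsynonymous total. No multiple-hit correction is applied — per-clone
substitution counts in mutation-accumulation settings are far below one
per gene, so corrected and uncorrected estimates coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .catalog import MutationRecord
from .genome import AnnotatedGenome, GenomeContentError, classify_change, \
    synonymous_opportunities

__all__ = ["DnDsResult", "count_sites_ng", "dnds", "dnds_per_clone"]


@dataclass(frozen=True)
class DnDsResult:
    """Per-clone dN/dS with its ingredients.

    ``ratio`` is None (undefined) when the clone carries no synonymous
    substitution — an absent denominator, not an infinite ratio. Nonsense
    changes count as nonsynonymous: they alter the protein.
    """

    clone: str
    n_obs: int
    s_obs: int
    n_sites: float
    s_sites: float
    dn: float
    ds: float
    ratio: float | None

    @property
    def defined(self) -> bool:
        return self.ratio is not None


def count_sites_ng(genome: AnnotatedGenome) -> tuple[float, float]:
    """(nonsynonymous sites, synonymous sites) by fractional counting.

    Each coding position splits its one site into a synonymous fraction
    (the share of its three changes that are synonymous, under the
    every-containing-CDS rule) and a nonsynonymous remainder; totals sum
    to the coding length.
    """
    if not genome.features:
        raise GenomeContentError("genome has no coding sequence")
    table = synonymous_opportunities(genome)
    s_sites = table.total / 3.0
    n_sites = table.coding_length - s_sites
    return n_sites, s_sites


def dnds(records: Sequence[MutationRecord], genome: AnnotatedGenome,
         sites: tuple[float, float] | None = None) -> DnDsResult:
    """dN/dS for the substitutions of a single clone.

    Records lacking a coding classification are classified against the
    genome; noncoding records are ignored. ``sites`` can carry a
    precomputed (N_sites, S_sites) pair to avoid re-enumerating the genome
    per clone.
    """
    clones = {(r.population, r.clone) for r in records}
    if len(clones) > 1:
        raise ValueError(f"records span multiple clones: {sorted(clones)}")
    clone = records[0].clone if records else "?"
    if sites is None:
        sites = count_sites_ng(genome)
    n_sites, s_sites = sites
    if n_sites <= 0 or s_sites <= 0:
        raise ValueError("site counts must be positive")

    n_obs = s_obs = 0
    for r in records:
        cls = r.coding_class or classify_change(genome, r.position, r.alt)
        if cls == "synonymous":
            s_obs += 1
        elif cls in ("nonsynonymous", "nonsense"):
            n_obs += 1
    dn = n_obs / n_sites
    ds = s_obs / s_sites
    ratio = None if ds == 0 else dn / ds
    return DnDsResult(clone=clone, n_obs=n_obs, s_obs=s_obs,
                      n_sites=n_sites, s_sites=s_sites,
                      dn=dn, ds=ds, ratio=ratio)


def dnds_per_clone(records: Sequence[MutationRecord],
                   genome: AnnotatedGenome) -> list[DnDsResult]:
    """dN/dS for every clone present in a mutation table."""
    sites = count_sites_ng(genome)
    by_clone: dict[tuple[str, str], list[MutationRecord]] = {}
    for r in records:
        by_clone.setdefault((r.population, r.clone), []).append(r)
    return [dnds(rs, genome, sites) for _, rs in sorted(by_clone.items())]
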