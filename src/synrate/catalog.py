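"""Clone-level substitution records and population-collapsed events.

Evolution-experiment resequencing yields one list of base substitutions per
sequenced clone. Clones sampled from the same population share part of
their history, so the same mutation can appear in several genomes while
representing a single mutational event; collapsing identical
(population, position, base-change) records recovers the independent
events, which is what the spectrum analysis must count. Rate estimation,
by contrast, keeps clone-level observations and corrects for the shared
history in the likelihood (see :mod:`synrate.rates`).

The 35-event / 52-record mutation table from the 40,000-generation
*E. coli* long-term evolution experiment ships as a packaged fixture,
together with the manifest of its 19 sequenced clones (clones that carry
no synonymous mutation still contribute informative Poisson zeros).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome import AnnotatedGenome, MutationType, SiteOpportunityTable
from .rates import CloneObservation

__all__ = [
    "MutationRecord",
    "MutationEvent",
    "MutationTableError",
    "read_mutation_table",
    "write_mutation_table",
    "read_clone_manifest",
    "read_callable_sites",
    "collapse_events",
    "classify_type",
    "spectrum_counts",
    "build_clone_observations",
    "load_ltee_records",
    "load_ltee_clones",
    "load_published_studies",
]

_VALID_BASES = set("ACGT")
_CODING_CLASSES = {"synonymous", "nonsynonymous", "nonsense", "noncoding"}

REQUIRED_COLUMNS = ("population", "clone", "generation", "position", "ref", "alt")


class MutationTableError(ValueError):
    """A mutation table failed validation; carries per-row messages."""

    def __init__(self, messages: Sequence[str]):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


@dataclass(frozen=True)
class MutationRecord:
    """One substitution observed in one sequenced clone."""

    population: str
    clone: str
    generation: int
    position: int
    ref: str
    alt: str
    gene: str = ""
    coding_class: str | None = None

    @property
    def mutation_type(self) -> MutationType:
        return MutationType.from_bases(self.ref, self.alt)


@dataclass(frozen=True)
class MutationEvent:
    """An independent mutational event within one population.

    ``carriers`` lists the (clone, generation) pairs in which the event was
    observed; multiple carriers mean the mutation arose on the population's
    shared lineage.
    """

    population: str
    position: int
    ref: str
    alt: str
    gene: str = ""
    carriers: frozenset[tuple[str, int]] = field(default_factory=frozenset)

    @property
    def mutation_type(self) -> MutationType:
        return MutationType.from_bases(self.ref, self.alt)


def classify_type(ref: str, alt: str) -> MutationType:
    """Strand-collapsed substitution category of a directional change."""
    return MutationType.from_bases(ref, alt)


def read_mutation_table(path: str | Path,
                        genome: AnnotatedGenome | None = None) -> list[MutationRecord]:
    """Read and validate a tab-separated mutation table.

    Required columns: population, clone, generation, position, ref, alt;
    optional: gene, coding_class. Lines starting with ``#`` are comments.
    Row-level problems are collected and raised together as
    :class:`MutationTableError`; when a genome is supplied, each record's
    ref base is checked against the sequence.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MutationTableError([f"missing required column(s): {missing}"])
    records: list[MutationRecord] = []
    problems: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header
        try:
            generation = int(getattr(row, "generation"))
            position = int(getattr(row, "position"))
            ref = getattr(row, "ref").upper()
            alt = getattr(row, "alt").upper()
            if generation <= 0:
                raise ValueError(f"generation must be > 0, got {generation}")
            if position <= 0:
                raise ValueError(f"position must be >= 1, got {position}")
            if ref not in _VALID_BASES or alt not in _VALID_BASES:
                raise ValueError(f"invalid base(s) {ref!r}->{alt!r}")
            if ref == alt:
                raise ValueError(f"ref equals alt ({ref})")
            coding = getattr(row, "coding_class", "") or None
            if coding is not None and coding not in _CODING_CLASSES:
                raise ValueError(f"unknown coding_class {coding!r}")
            if genome is not None:
                if position > len(genome.sequence):
                    raise ValueError(f"position {position} beyond genome end")
                gref = genome.sequence[position - 1]
                if gref != ref:
                    raise ValueError(
                        f"ref {ref} does not match genome base {gref} at {position}"
                    )
            records.append(MutationRecord(
                population=getattr(row, "population"),
                clone=getattr(row, "clone"),
                generation=generation, position=position,
                ref=ref, alt=alt,
                gene=getattr(row, "gene", ""),
                coding_class=coding,
            ))
        except (ValueError, TypeError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise MutationTableError(problems)
    return records


def write_mutation_table(records: Iterable[MutationRecord],
                         path: str | Path) -> None:
    """Write records back to the TSV dialect read by :func:`read_mutation_table`."""
    rows = [
        {
            "population": r.population, "clone": r.clone,
            "generation": r.generation, "position": r.position,
            "gene": r.gene, "ref": r.ref, "alt": r.alt,
            "coding_class": r.coding_class or "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_clone_manifest(path: str | Path) -> list[tuple[str, str, int]]:
    """Read a (population, clone, generation) manifest TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    needed = {"population", "clone", "generation"}
    if not needed <= set(df.columns):
        raise MutationTableError(
            [f"clone manifest must have columns {sorted(needed)}"])
    return [(r.population, r.clone, int(r.generation))
            for r in df.itertuples(index=False)]


def read_callable_sites(path: str | Path) -> dict[str, dict[MutationType, float]]:
    """Read a per-clone per-type callable-sites TSV (clone, type, sites)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    needed = {"clone", "type", "sites"}
    if not needed <= set(df.columns):
        raise MutationTableError(
            [f"callable-sites table must have columns {sorted(needed)}"])
    out: dict[str, dict[MutationType, float]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(r.clone, {})[MutationType(r.type)] = float(r.sites)
    return out


def collapse_events(records: Sequence[MutationRecord]) -> list[MutationEvent]:
    """Collapse clone-level records into independent events.

    Records are grouped by (population, position, ref, alt); the carriers of
    an event are the union of clones in which it was seen. Identical
    positions in *different* populations remain separate events — replicate
    populations evolve independently.
    """
    grouped: dict[tuple[str, int, str, str], dict] = {}
    for r in records:
        key = (r.population, r.position, r.ref, r.alt)
        entry = grouped.setdefault(key, {"gene": r.gene, "carriers": set()})
        entry["carriers"].add((r.clone, r.generation))
        if not entry["gene"]:
            entry["gene"] = r.gene
    events = [
        MutationEvent(population=k[0], position=k[1], ref=k[2], alt=k[3],
                      gene=v["gene"], carriers=frozenset(v["carriers"]))
        for k, v in grouped.items()
    ]
    events.sort(key=lambda e: (e.population, e.position, e.alt))
    return events


def spectrum_counts(
    events: Sequence[MutationEvent],
) -> tuple[dict[MutationType, int], int, int]:
    """Per-type event counts plus (transitions, transversions)."""
    if not events:
        raise ValueError("no events to tally")
    counts = {t: 0 for t in MutationType}
    for e in events:
        counts[e.mutation_type] += 1
    ts = sum(v for t, v in counts.items() if t.is_transition)
    return counts, ts, len(events) - ts


def build_clone_observations(
    records: Sequence[MutationRecord],
    clones: Sequence[tuple[str, str, int]] | None = None,
    callable_sites: Mapping[str, Mapping[MutationType, float]] | None = None,
    fallback: SiteOpportunityTable | None = None,
) -> list[CloneObservation]:
    """Assemble per-clone Poisson observations for rate estimation.

    Only records classified synonymous (or unclassified) enter the counts.
    ``clones`` supplies the full clone universe so that clones carrying no
    synonymous mutation still contribute zero-count observations; when
    omitted, it is derived from the records. Per-clone callable synonymous
    opportunities come from ``callable_sites`` when available, otherwise
    from the ancestral ``fallback`` table.
    """
    if clones is None:
        seen: dict[tuple[str, str], int] = {}
        for r in records:
            seen[(r.population, r.clone)] = r.generation
        clones = [(p, c, g) for (p, c), g in sorted(seen.items())]
    universe = {(p, c) for p, c, _ in clones}
    for r in records:
        if (r.population, r.clone) not in universe:
            raise ValueError(
                f"clone {r.clone} of population {r.population} present in the "
                "mutation table but absent from the clone manifest"
            )

    counts: dict[tuple[str, str], dict[MutationType, int]] = {
        (p, c): {t: 0 for t in MutationType} for p, c, _ in clones
    }
    for r in records:
        if r.coding_class not in (None, "synonymous"):
            continue
        counts[(r.population, r.clone)][r.mutation_type] += 1

    observations = []
    for population, clone, generation in clones:
        if callable_sites is not None and clone in callable_sites:
            sites = {t: float(callable_sites[clone].get(t, 0.0))
                     for t in MutationType}
        elif fallback is not None:
            sites = {t: float(fallback.opportunities[t]) for t in MutationType}
        else:
            raise ValueError(
                f"no callable-site table for clone {clone} and no ancestral "
                "fallback opportunity table supplied"
            )
        observations.append(CloneObservation(
            clone=clone, population=population, generations=generation,
            counts=dict(counts[(population, clone)]), sites=sites,
        ))
    return observations


# ---------------------------------------------------------------------------
# packaged fixtures

def _data_path(name: str):
    return importlib.resources.files("synrate.data").joinpath(name)


def load_ltee_records() -> list[MutationRecord]:
    """The packaged long-term evolution experiment synonymous-substitution
    table: 52 clone-level records over 35 events in 8 populations."""
    with importlib.resources.as_file(_data_path("ltee_synonymous_mutations.tsv")) as p:
        return read_mutation_table(p)


def load_ltee_clones() -> list[tuple[str, str, int]]:
    """Manifest of the 19 sequenced non-mutator clones."""
    with importlib.resources.as_file(_data_path("ltee_clones.tsv")) as p:
        return read_clone_manifest(p)


def load_published_studies() -> pd.DataFrame:
    """Published whole-genome evolution-experiment datasets: clone counts,
    cumulative generations, simple synonymous target sites, and observed
    synonymous mutation counts, one row per study."""
    with importlib.resources.as_file(_data_path("published_studies.tsv")) as p:
        return pd.read_csv(p, sep="\t", comment="#")
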