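"""Annotated genomes and synonymous target-site counting.

A spontaneous-rate estimate from accumulated synonymous substitutions needs
to know, for every mutation type, how many genomic "opportunities" there are
for a synonymous change: the number of (position, base-change) combinations
inside protein-coding genes that leave every encoded amino acid unchanged.
This module represents a (possibly circular) annotated genome, classifies
single-base changes against the bacterial genetic code, and tallies the
per-type synonymous opportunity table together with the genome's A:T / G:C
base-pair composition.

Two site-counting conventions are exposed:

* the *simple* approximation, one-third of the protein-coding length
  (three changes are possible from any ancestral base, so a fully
  degenerate position would contribute one synonymous site);
* the *full enumeration*, which translates every possible change and
  tallies synonymous opportunities per mutation type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "MutationType",
    "CdsFeature",
    "AnnotatedGenome",
    "SiteOpportunityTable",
    "GenomeInputError",
    "GenomeContentError",
    "load_genome",
    "simple_synonymous_sites",
    "classify_change",
    "synonymous_opportunities",
    "expected_spectrum",
]

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

# NCBI translation table 11 (bacterial/archaeal); start codons are read as
# ordinary codons.
_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_CODON_AA = dict(_TABLE11.forward_table)
for _stop in _TABLE11.stop_codons:
    _CODON_AA[_stop] = "*"


class GenomeInputError(ValueError):
    """The genome file could not be read or parsed."""


class GenomeContentError(ValueError):
    """The parsed content violates a structural requirement (e.g. no CDS)."""


class MutationType(Enum):
    """The six strand-collapsed base-pair substitution categories.

    Each of the 12 directional single-base changes maps onto exactly one
    category; complementary changes (e.g. C->T and G->A) collapse together
    because a substitution mutates a base *pair*.
    """

    AT_GC = "AT>GC"
    AT_CG = "AT>CG"
    AT_TA = "AT>TA"
    GC_AT = "GC>AT"
    GC_TA = "GC>TA"
    GC_CG = "GC>CG"

    @property
    def is_transition(self) -> bool:
        return self in (MutationType.AT_GC, MutationType.GC_AT)

    @property
    def ancestral_pair(self) -> str:
        """``"AT"`` or ``"GC"`` — the unordered ancestral base pair."""
        return self.value[:2]

    @classmethod
    def from_bases(cls, ref: str, alt: str) -> "MutationType":
        """Map a directional change (genome-strand ref -> alt) to its category."""
        ref, alt = ref.upper(), alt.upper()
        if ref not in _BASE_INDEX or alt not in _BASE_INDEX:
            raise ValueError(f"bases must be one of A/C/G/T, got {ref!r}->{alt!r}")
        if ref == alt:
            raise ValueError(f"ref and alt are identical: {ref!r}")
        # normalise to the A/C representative of the base pair
        if ref in "TG":
            ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        key = {"AG": cls.AT_GC, "AC": cls.AT_CG, "AT": cls.AT_TA,
               "CT": cls.GC_AT, "CA": cls.GC_TA, "CG": cls.GC_CG}
        return key[ref + alt]


@dataclass(frozen=True)
class CdsFeature:
    """A protein-coding feature, 1-based inclusive coordinates.

    ``start > end`` is the wrap convention for a feature spanning the
    origin of a circular genome.
    """

    gene_name: str
    start: int
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise ValueError("coordinates are 1-based and must be >= 1")

    def span_length(self, genome_length: int) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return genome_length - self.start + 1 + self.end

    def positions(self, genome_length: int) -> np.ndarray:
        """0-based genome positions in forward genome order (5'->3' of the
        + strand), following the wrap for origin-spanning features."""
        if self.start <= self.end:
            return np.arange(self.start - 1, self.end)
        head = np.arange(self.start - 1, genome_length)
        tail = np.arange(0, self.end)
        return np.concatenate([head, tail])

    def reading_positions(self, genome_length: int) -> np.ndarray:
        """0-based genome positions in reading order (first codon first)."""
        pos = self.positions(genome_length)
        return pos if self.strand == "+" else pos[::-1]


@dataclass
class AnnotatedGenome:
    """A genome sequence with its protein-coding annotation."""

    id: str
    sequence: str
    circular: bool = False
    features: list[CdsFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise GenomeContentError("genome sequence is empty")
        if set(self.sequence) - set(_BASES):
            bad = sorted(set(self.sequence) - set(_BASES))
            raise GenomeContentError(
                f"sequence contains non-ACGT characters: {bad} "
                "(ambiguity codes are rejected at load)"
            )
        L = len(self.sequence)
        for f in self.features:
            if f.start > L or f.end > L:
                raise GenomeContentError(
                    f"feature {f.gene_name} exceeds genome length {L}"
                )
            if f.start > f.end and not self.circular:
                raise GenomeContentError(
                    f"feature {f.gene_name} wraps the origin of a linear genome"
                )
            if f.span_length(L) % 3:
                raise GenomeContentError(
                    f"feature {f.gene_name} span not divisible by 3"
                )
            if f.span_length(L) < 6:
                raise GenomeContentError(
                    f"feature {f.gene_name} shorter than two codons"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def encoded(self) -> np.ndarray:
        """Sequence as uint8 indices (A=0, C=1, G=2, T=3); cached."""
        enc = getattr(self, "_encoded", None)
        if enc is None:
            enc = np.frombuffer(self.sequence.encode(), dtype=np.uint8)
            lut = np.zeros(256, dtype=np.uint8)
            for b, i in _BASE_INDEX.items():
                lut[ord(b)] = i
            enc = lut[enc]
            self._encoded = enc
        return enc

    def base_pair_counts(self) -> tuple[int, int]:
        """(#A:T pairs, #G:C pairs) over the whole genome."""
        enc = self.encoded
        n_at = int(np.count_nonzero((enc == 0) | (enc == 3)))
        return n_at, len(self.sequence) - n_at

    def coding_mask(self) -> np.ndarray:
        """Boolean mask of positions inside at least one CDS."""
        mask = np.zeros(len(self.sequence), dtype=bool)
        for f in self.features:
            mask[f.positions(len(self.sequence))] = True
        return mask

    def coding_length(self) -> int:
        """Protein-coding bp, counting positions in overlapping CDS once."""
        return int(self.coding_mask().sum())

    def features_at(self, position: int) -> list[CdsFeature]:
        """CDS features containing a 1-based position."""
        L = len(self.sequence)
        hits = []
        for f in self.features:
            if f.start <= f.end:
                if f.start <= position <= f.end:
                    hits.append(f)
            elif position >= f.start or position <= f.end:
                hits.append(f)
        return hits

    def reverse_complemented(self) -> "AnnotatedGenome":
        """Strand-flipped copy (used by symmetry checks)."""
        L = len(self.sequence)
        seq = str(Seq(self.sequence).reverse_complement())
        feats = []
        for f in self.features:
            # the same formula covers wrapped features: start > end persists
            new_start, new_end = L - f.end + 1, L - f.start + 1
            feats.append(
                CdsFeature(f.gene_name, new_start, new_end,
                           "-" if f.strand == "+" else "+")
            )
        return AnnotatedGenome(self.id, seq, self.circular, feats)


@dataclass
class SiteOpportunityTable:
    """Per-type synonymous opportunities and genome composition.

    ``opportunities[c]`` counts (position, change) combinations of mutation
    type ``c`` that are synonymous in every CDS containing the position; the
    unit is sites x changes, so a fully degenerate third codon position
    contributes up to 3 across the types. ``n_at`` / ``n_gc`` count base
    pairs over the whole genome.
    """

    opportunities: dict[MutationType, int]
    coding_length: int
    n_at: int
    n_gc: int

    @property
    def total(self) -> int:
        return sum(self.opportunities.values())

    @property
    def s_simple(self) -> float:
        """The one-third-of-coding-length approximation."""
        return self.coding_length / 3.0

    @property
    def f_at(self) -> float:
        return self.n_at / (self.n_at + self.n_gc)

    @property
    def f_gc(self) -> float:
        return self.n_gc / (self.n_at + self.n_gc)

    @property
    def weights(self) -> dict[MutationType, float]:
        """w_c: frequency of the ancestral base pair of type c."""
        return {
            t: (self.f_at if t.ancestral_pair == "AT" else self.f_gc)
            for t in MutationType
        }

    def transition_total(self) -> int:
        return sum(v for t, v in self.opportunities.items() if t.is_transition)

    def transversion_total(self) -> int:
        return sum(v for t, v in self.opportunities.items() if not t.is_transition)

    def scaled(self, factor: float) -> "SiteOpportunityTable":
        """Opportunity counts multiplied by ``factor`` (callable-site scaling)."""
        return SiteOpportunityTable(
            {t: v * factor for t, v in self.opportunities.items()},
            self.coding_length, self.n_at, self.n_gc,
        )

    def write(self, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
        """TSV of per-type opportunities plus a JSON composition sidecar."""
        import json

        tsv_path = Path(tsv_path)
        with open(tsv_path, "w") as fh:
            fh.write("type\topportunities\n")
            for t in MutationType:
                fh.write(f"{t.value}\t{self.opportunities[t]}\n")
        if json_path is None:
            json_path = tsv_path.with_suffix(".json")
        with open(json_path, "w") as fh:
            json.dump(
                {
                    "coding_length": self.coding_length,
                    "s_simple": self.s_simple,
                    "n_at": self.n_at,
                    "n_gc": self.n_gc,
                    "f_at": self.f_at,
                    "f_gc": self.f_gc,
                },
                fh, indent=2,
            )
            fh.write("\n")


# ---------------------------------------------------------------------------
# loading

def _features_from_genbank(record) -> tuple[list[CdsFeature], int]:
    feats, skipped = [], 0
    L = len(record.seq)
    for sf in record.features:
        if sf.type != "CDS":
            continue
        quals = sf.qualifiers
        if "pseudo" in quals or "pseudogene" in quals:
            skipped += 1
            continue
        name = (quals.get("gene") or quals.get("locus_tag") or ["?"])[0]
        parts = sf.location.parts
        strand = "+" if sf.location.strand != -1 else "-"
        if len(parts) == 1:
            start, end = int(parts[0].start) + 1, int(parts[0].end)
        elif (
            len(parts) == 2
            and int(parts[0].end) == L
            and int(parts[1].start) == 0
        ):
            # two-part join across the origin of a circular genome
            start, end = int(parts[0].start) + 1, int(parts[1].end)
        else:
            skipped += 1
            continue
        span = end - start + 1 if start <= end else L - start + 1 + end
        if span % 3 or span < 6:
            skipped += 1
            continue
        feats.append(CdsFeature(name, start, end, strand))
    if skipped:
        logger.warning("skipped %d CDS features (pseudo, compound, or bad span)",
                       skipped)
    return feats, skipped


def _features_from_gff3(path: Path, genome_length: int) -> tuple[list[CdsFeature], int]:
    feats, skipped = [], 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8 or cols[2] != "CDS":
                continue
            start, end = int(cols[3]), int(cols[4])
            strand = cols[6] if cols[6] in "+-" else "+"
            attrs = {}
            if len(cols) > 8:
                for item in cols[8].split(";"):
                    if "=" in item:
                        k, v = item.split("=", 1)
                        attrs[k.strip()] = v.strip()
            name = attrs.get("gene") or attrs.get("locus_tag") or attrs.get("ID", "?")
            span = end - start + 1
            if span % 3 or span < 6:
                logger.warning("skipping CDS %s: span %d not a whole number "
                               "of codons (>= 2)", name, span)
                skipped += 1
                continue
            feats.append(CdsFeature(name, start, end, strand))
    return feats, skipped


def load_genome(path: str | Path, fasta: str | Path | None = None,
                circular: bool | None = None) -> AnnotatedGenome:
    """Load an annotated genome from GenBank, or from GFF3 + FASTA.

    Parameters
    ----------
    path : GenBank flat file (single record), or a GFF3 file when ``fasta``
        is also given.
    fasta : FASTA with the genome sequence, for the GFF3 route.
    circular : override the topology; by default GenBank topology is used
        and GFF3 genomes are treated as linear.

    CDS features whose span is not a whole number of codons (or marked
    pseudo, or with unsupported compound locations) are skipped with a
    logged count. A genome with no usable CDS raises
    :class:`GenomeContentError`.
    """
    path = Path(path)
    if not path.exists():
        raise GenomeInputError(f"no such file: {path}")
    if fasta is None:
        try:
            record = SeqIO.read(str(path), "genbank")
        except Exception as exc:  # malformed file
            raise GenomeInputError(f"could not parse GenBank file {path}: {exc}")
        seq = str(record.seq).upper()
        topo = record.annotations.get("topology", "linear")
        is_circ = (topo == "circular") if circular is None else circular
        feats, _ = _features_from_genbank(record)
        gid = record.id or path.stem
    else:
        fasta = Path(fasta)
        if not fasta.exists():
            raise GenomeInputError(f"no such file: {fasta}")
        try:
            record = SeqIO.read(str(fasta), "fasta")
        except Exception as exc:
            raise GenomeInputError(f"could not parse FASTA file {fasta}: {exc}")
        seq = str(record.seq).upper()
        is_circ = bool(circular)
        feats, _ = _features_from_gff3(path, len(seq))
        gid = record.id or fasta.stem
    if not feats:
        raise GenomeContentError(f"no usable CDS features in {path}")
    return AnnotatedGenome(gid, seq, is_circ, feats)


# ---------------------------------------------------------------------------
# classification

def _codon_at(genome: AnnotatedGenome, feature: CdsFeature,
              position0: int) -> tuple[str, int]:
    """(reading-frame codon, offset within codon) for a 0-based position."""
    L = len(genome.sequence)
    pos = feature.reading_positions(L)
    # index of position0 along the reading direction
    if feature.strand == "+":
        if feature.start <= feature.end:
            idx = position0 - (feature.start - 1)
        else:
            idx = (position0 - (feature.start - 1)) % L
    else:
        if feature.start <= feature.end:
            idx = (feature.end - 1) - position0
        else:
            idx = ((feature.end - 1) - position0) % L
    codon_i, off = divmod(idx, 3)
    bases = [genome.sequence[pos[3 * codon_i + k]] for k in range(3)]
    if feature.strand == "-":
        bases = [_COMPLEMENT[b] for b in bases]
    return "".join(bases), off


def classify_change(genome: AnnotatedGenome, position: int, alt: str) -> str:
    """Classify a single-base change at a 1-based position.

    Returns one of ``"synonymous"``, ``"nonsynonymous"``, ``"nonsense"``,
    ``"noncoding"``. A change is synonymous only if it leaves the amino
    acid unchanged in *every* CDS containing the position; a change that
    creates a stop codon in any CDS is nonsense.
    """
    alt = alt.upper()
    if alt not in _BASE_INDEX:
        raise ValueError(f"alt base must be one of A/C/G/T, got {alt!r}")
    if not 1 <= position <= len(genome.sequence):
        raise ValueError(f"position {position} outside genome of length "
                         f"{len(genome.sequence)}")
    ref = genome.sequence[position - 1]
    if alt == ref:
        raise ValueError(f"alt equals the reference base {ref!r} at {position}")
    feats = genome.features_at(position)
    if not feats:
        return "noncoding"
    any_nonsense = False
    all_syn = True
    for f in feats:
        codon, off = _codon_at(genome, f, position - 1)
        frame_alt = alt if f.strand == "+" else _COMPLEMENT[alt]
        mutated = codon[:off] + frame_alt + codon[off + 1:]
        aa_ref, aa_alt = _CODON_AA[codon], _CODON_AA[mutated]
        if aa_alt == "*" and aa_ref != "*":
            any_nonsense = True
        if aa_alt != aa_ref:
            all_syn = False
    if any_nonsense:
        return "nonsense"
    return "synonymous" if all_syn else "nonsynonymous"


# ---------------------------------------------------------------------------
# opportunity enumeration

def _syn_lookup() -> np.ndarray:
    """SYN[codon_index, offset, alt_base] — synonymous flags for all single
    changes of all 64 codons (frame coordinates)."""
    syn = np.zeros((64, 3, 4), dtype=bool)
    for ci in range(64):
        b = [(ci >> 4) & 3, (ci >> 2) & 3, ci & 3]
        codon = "".join(_BASES[x] for x in b)
        aa = _CODON_AA[codon]
        for off in range(3):
            for a in range(4):
                if a == b[off]:
                    continue
                mb = list(b)
                mb[off] = a
                mcodon = "".join(_BASES[x] for x in mb)
                syn[ci, off, a] = _CODON_AA[mcodon] == aa
    return syn


_SYN = _syn_lookup()

_TYPE_ORDER = list(MutationType)
_TYPE_IDX = np.full((4, 4), -1, dtype=np.int8)
for _r in range(4):
    for _a in range(4):
        if _r != _a:
            t = MutationType.from_bases(_BASES[_r], _BASES[_a])
            _TYPE_IDX[_r, _a] = _TYPE_ORDER.index(t)


def simple_synonymous_sites(genome: AnnotatedGenome) -> float:
    """Synonymous target sites by the one-third-of-coding-bp approximation.

    Positions inside overlapping CDS are counted once.
    """
    return genome.coding_length() / 3.0


def synonymous_opportunities(genome: AnnotatedGenome) -> SiteOpportunityTable:
    """Enumerate per-type synonymous opportunities over all coding positions.

    For every coding position and each of its three possible changes, the
    opportunity count of the corresponding strand-collapsed mutation type is
    incremented iff the change is synonymous (in all containing CDS).
    Whole-genome base-pair composition is tallied alongside.
    """
    L = len(genome.sequence)
    enc = genome.encoded
    counts = np.zeros(6, dtype=np.int64)

    coverage = np.zeros(L, dtype=np.int16)
    for f in genome.features:
        coverage[f.positions(L)] += 1

    for f in genome.features:
        gpos = f.reading_positions(L)
        fb = enc[gpos]
        if f.strand == "-":
            fb = 3 - fb  # complement in the 0..3 encoding
        n = len(fb)
        ci = 16 * fb[0::3] + 4 * fb[1::3] + fb[2::3]
        ci = np.repeat(ci, 3)
        off = np.tile(np.array([0, 1, 2], dtype=np.int64), n // 3)
        single = coverage[gpos] == 1
        for d in (1, 2, 3):
            fa = (fb + d) % 4  # one of the three frame-alternative bases
            is_syn = _SYN[ci, off, fa] & single
            # mutation types are strand-collapsed, so frame bases suffice
            np.add.at(counts, _TYPE_IDX[fb[is_syn], fa[is_syn]], 1)

    # positions inside more than one CDS: the all-CDS rule, counted once
    multi = np.nonzero(coverage > 1)[0]
    for p0 in multi:
        ref = genome.sequence[p0]
        for alt in _BASES:
            if alt == ref:
                continue
            if classify_change(genome, p0 + 1, alt) == "synonymous":
                counts[_TYPE_IDX[_BASE_INDEX[ref], _BASE_INDEX[alt]]] += 1

    n_at, n_gc = genome.base_pair_counts()
    return SiteOpportunityTable(
        {t: int(counts[i]) for i, t in enumerate(_TYPE_ORDER)},
        genome.coding_length(), n_at, n_gc,
    )


def expected_spectrum(table: SiteOpportunityTable) -> dict[MutationType, float]:
    """Expected share of each mutation type among synonymous changes, were
    every possible change equally likely: S_c / sum(S)."""
    total = table.total
    if total <= 0:
        raise GenomeContentError("opportunity table is all zero")
    return {t: table.opportunities[t] / total for t in MutationType}
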