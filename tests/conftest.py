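"""Shared fixtures and independent oracles.

The oracles deliberately avoid the package's counting code paths: they
enumerate every possible single-base change and translate codons through
Biopython, so agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pytest
from Bio.Data import CodonTable

from synrate import AnnotatedGenome, CdsFeature, MutationType

_T11 = CodonTable.unambiguous_dna_by_id[11]
_AA = dict(_T11.forward_table)
for _s in _T11.stop_codons:
    _AA[_s] = "*"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def oracle_classify(genome: AnnotatedGenome, position: int, alt: str) -> str:
    """Brute-force classification of a change, independent of the package.

    Rebuilds every containing CDS sequence from scratch, applies the
    change, and compares full translations.
    """
    L = len(genome.sequence)
    verdicts = []
    for f in genome.features:
        if f.start <= f.end:
            pos = list(range(f.start - 1, f.end))
        else:
            pos = list(range(f.start - 1, L)) + list(range(0, f.end))
        if (position - 1) not in pos:
            continue
        ref_cds = [genome.sequence[p] for p in pos]
        alt_cds = list(ref_cds)
        alt_cds[pos.index(position - 1)] = alt
        if f.strand == "-":
            ref_cds = [_COMP[b] for b in reversed(ref_cds)]
            alt_cds = [_COMP[b] for b in reversed(alt_cds)]
        ref_aa = [_AA["".join(ref_cds[i:i + 3])] for i in range(0, len(pos), 3)]
        alt_aa = [_AA["".join(alt_cds[i:i + 3])] for i in range(0, len(pos), 3)]
        if ref_aa == alt_aa:
            verdicts.append("synonymous")
        elif any(a == "*" and r != "*" for r, a in zip(ref_aa, alt_aa)):
            verdicts.append("nonsense")
        else:
            verdicts.append("nonsynonymous")
    if not verdicts:
        return "noncoding"
    if "nonsense" in verdicts:
        return "nonsense"
    if all(v == "synonymous" for v in verdicts):
        return "synonymous"
    return "nonsynonymous"


def oracle_opportunities(genome: AnnotatedGenome) -> dict[MutationType, int]:
    """Exhaustive tally of synonymous single-base changes by type."""
    coding = set()
    L = len(genome.sequence)
    for f in genome.features:
        if f.start <= f.end:
            coding.update(range(f.start, f.end + 1))
        else:
            coding.update(range(f.start, L + 1))
            coding.update(range(1, f.end + 1))
    tally: Counter = Counter()
    for position in sorted(coding):
        ref = genome.sequence[position - 1]
        for alt in "ACGT":
            if alt == ref:
                continue
            if oracle_classify(genome, position, alt) == "synonymous":
                tally[MutationType.from_bases(ref, alt)] += 1
    return {t: tally.get(t, 0) for t in MutationType}


def random_genome(rng: np.random.Generator, length: int = 600,
                  n_genes: int = 3) -> AnnotatedGenome:
    """A small random genome with non-overlapping CDS on both strands."""
    seq = "".join(rng.choice(list("ACGT"), size=length))
    features = []
    gene_len = 3 * int(rng.integers(4, 12))
    gap = max(3, (length - n_genes * gene_len) // (n_genes + 1))
    pos = gap
    for i in range(n_genes):
        if pos + gene_len > length:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(CdsFeature(f"g{i}", pos + 1, pos + gene_len, strand))
        pos += gene_len + gap
    return AnnotatedGenome("rand", seq, circular=False, features=features)


@pytest.fixture
def toy_genome() -> AnnotatedGenome:
    """A single + strand gene, ATG AAA TAA."""
    return AnnotatedGenome("toy", "ATGAAATAA",
                           features=[CdsFeature("toy", 1, 9, "+")])


@pytest.fixture(scope="session")
def ltee_records():
    from synrate import load_ltee_records
    return load_ltee_records()


@pytest.fixture(scope="session")
def ltee_clones():
    from synrate import load_ltee_clones
    return load_ltee_clones()
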