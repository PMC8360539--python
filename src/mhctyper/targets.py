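"""Domain types shared across the pipeline: amplicon targets, sample metadata,
pedigree triads.

The four targets are MHC class II exons amplified with locus-specific primers:
DRB exon 2 (the classical peptide-binding-region exon), DRB exon 3, DQA exon 3
and DQB exon 3.  ``exon_length`` is the full exon size in the genome;
``expected_recovered_lengths`` are the insert sizes actually produced by the
primer pair (DRB exon 3 segregates two in-frame length variants, 214 and
217 bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

#: IUPAC nucleotide code -> set of concrete bases it stands for.
IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}

EXON_NAMES = ("DRBe2", "DRBe3", "DQAe3", "DQBe3")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ExonTarget:
    """One amplified exon locus: primers and the insert lengths they yield."""

    name: str
    exon_length: int
    expected_recovered_lengths: frozenset
    fwd_primer: str
    rev_primer: str

    def __post_init__(self):
        if self.name not in EXON_NAMES:
            raise ValueError(f"unknown exon name {self.name!r}")
        if not self.fwd_primer or not self.rev_primer:
            raise ValueError("primers must be non-empty")
        for p in (self.fwd_primer, self.rev_primer):
            bad = set(p) - set(IUPAC)
            if bad:
                raise ValueError(f"non-IUPAC characters in primer: {sorted(bad)}")
        lens = sorted(self.expected_recovered_lengths)
        if not lens or any(l <= 0 for l in lens):
            raise ValueError("expected recovered lengths must be positive")
        base = lens[0]
        if any((l - base) % 3 for l in lens):
            raise ValueError("expected lengths must differ by multiples of 3")

    @property
    def canonical_length(self) -> int:
        """Reference length for reading-frame checks (smallest recovered)."""
        return min(self.expected_recovered_lengths)


#: Primer pairs and lengths for the four class II exon amplicons.
DEFAULT_TARGETS = {
    "DRBe2": ExonTarget(
        "DRBe2", 267, frozenset({248}),
        "CGGATCGTTCGTGTYCCCACAG", "CTCTCCGCTGCACTGTGAAGCT"),
    "DRBe3": ExonTarget(
        "DRBe3", 282, frozenset({214, 217}),
        "TGACTGTGTATCCTGCMAAGACCCAG", "ATTGCACTGTGRKAGGGCTCRTCA"),
    "DQAe3": ExonTarget(
        "DQAe3", 279, frozenset({229}),
        "CCTCACCRCAGAGGTTCCTGAGG", "TCCAGGCCCCAGTGCTCC"),
    "DQBe3": ExonTarget(
        "DQBe3", 279, frozenset({254}),
        "GTCTTTCCCTGTCTGTTACTGCCCT", "GTGATGGGGCTCTGGAGGCT"),
}


@dataclass(frozen=True)
class SampleMeta:
    """One sequenced library: an individual (optionally a replicate PCR)."""

    individual_id: str
    species: str
    genus: str
    population: str
    replicate_id: Optional[str] = None
    fastq_fwd: Optional[str] = None
    fastq_rev: Optional[str] = None

    @property
    def key(self):
        """Unique library key (individual, replicate)."""
        return (self.individual_id, self.replicate_id)


@dataclass(frozen=True)
class PedigreeTriad:
    """A known offspring-mother-father trio used for Mendelian validation."""

    offspring_id: str
    mother_id: str
    father_id: str

    def __post_init__(self):
        ids = {self.offspring_id, self.mother_id, self.father_id}
        if len(ids) != 3:
            raise ValueError("triad ids must be pairwise distinct")
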