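"""Readers and writers for the pipeline's file formats.

FASTQ is Phred+33 only (modern Illumina); anything that looks like Phred+64
is rejected outright rather than silently mis-scaled.  Tables are plain TSV.
All coordinates are 0-based half-open internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, List, Optional, Tuple

import pandas as pd

from .targets import PedigreeTriad, SampleMeta

#: Highest quality character accepted as Phred+33 (Q41, MiSeq ceiling).
_MAX_PHRED33_CHAR = 33 + 41


class FastqFormatError(ValueError):
    """Malformed or truncated FASTQ record."""


class PairingError(ValueError):
    """Forward/reverse FASTQ files with unequal record counts."""


@dataclass(frozen=True)
class Read:
    """A single read: id, sequence and integer Phred qualities."""

    id: str
    seq: str
    quals: Tuple[int, ...]

    def __post_init__(self):
        if len(self.seq) != len(self.quals):
            raise FastqFormatError(
                f"read {self.id!r}: sequence and quality lengths differ")


ReadPair = Tuple[Read, Read]


def _parse_fastq(path) -> Iterator[Read]:
    with open(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise FastqFormatError(
                    f"{path}: truncated FASTQ record at record index {idx}")
            header, seq, plus, qual = (s.rstrip("\n") for s in (header, seq, plus, qual))
            if not header.startswith("@") or not plus.startswith("+"):
                raise FastqFormatError(
                    f"{path}: malformed FASTQ record at record index {idx}")
            if len(seq) != len(qual):
                raise FastqFormatError(
                    f"{path}: sequence/quality length mismatch at record index {idx}")
            quals = []
            for ch in qual:
                o = ord(ch)
                if o < 33:
                    raise FastqFormatError(
                        f"{path}: quality character below '!' at record index {idx}")
                if o > _MAX_PHRED33_CHAR:
                    raise FastqFormatError(
                        f"{path}: quality character {ch!r} above Q41 at record "
                        f"index {idx}; looks like Phred+64, which is not supported")
                quals.append(o - 33)
            yield Read(header[1:].split()[0] if header[1:] else "", seq.upper(),
                       tuple(quals))
            idx += 1


def read_fastq_pairs(path_fwd, path_rev) -> List[ReadPair]:
    """Read two FASTQ files as mate pairs, paired by record order."""
    fwd = list(_parse_fastq(path_fwd))
    rev = list(_parse_fastq(path_rev))
    if len(fwd) != len(rev):
        raise PairingError(
            f"mate count mismatch: {len(fwd)} forward vs {len(rev)} reverse reads")
    return list(zip(fwd, rev))


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n"
                     + "".join(chr(q + 33) for q in r.quals) + "\n")


# ---------------------------------------------------------------------------
# sample sheet / pedigree

SAMPLE_SHEET_COLUMNS = ["individual_id", "species", "genus", "population",
                        "fastq_fwd", "fastq_rev"]


def read_sample_sheet(path) -> List[SampleMeta]:
    """Parse the TSV sample sheet; ``replicate_id`` column is optional."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet missing required columns: {missing}")
    metas = []
    seen = set()
    for _, row in df.iterrows():
        rep = row.get("replicate_id") or None
        meta = SampleMeta(
            individual_id=row["individual_id"], species=row["species"],
            genus=row["genus"], population=row["population"],
            replicate_id=rep, fastq_fwd=row["fastq_fwd"] or None,
            fastq_rev=row["fastq_rev"] or None)
        if meta.key in seen:
            raise ValueError(f"duplicate sample sheet key {meta.key}")
        seen.add(meta.key)
        metas.append(meta)
    return metas


def write_sample_sheet(metas: Iterable[SampleMeta], path) -> None:
    rows = [{"individual_id": m.individual_id, "species": m.species,
             "genus": m.genus, "population": m.population,
             "replicate_id": m.replicate_id or "",
             "fastq_fwd": m.fastq_fwd or "", "fastq_rev": m.fastq_rev or ""}
            for m in metas]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> List[PedigreeTriad]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("offspring_id", "mother_id", "father_id")
               if c not in df.columns]
    if missing:
        raise ValueError(f"pedigree file missing required columns: {missing}")
    return [PedigreeTriad(r.offspring_id, r.mother_id, r.father_id)
            for r in df.itertuples()]


def write_pedigree(triads: Iterable[PedigreeTriad], path) -> None:
    pd.DataFrame([{"offspring_id": t.offspring_id, "mother_id": t.mother_id,
                   "father_id": t.father_id} for t in triads]
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genotype table + allele FASTA

@dataclass(frozen=True)
class GenotypeRow:
    """One called allele in one individual at one exon."""

    individual_id: str
    exon: str
    allele_seq: str
    within_rf: Optional[float] = None
    status: str = "allele"


def assign_allele_ids(rows: Iterable[GenotypeRow]) -> dict:
    """Stable allele ids per exon: zero-padded index by descending carrier
    count, ties broken lexicographically by sequence.

    Deterministic and permutation-invariant given the same multiset of rows.
    """
    counts = {}
    for r in rows:
        counts[(r.exon, r.allele_seq)] = counts.get((r.exon, r.allele_seq), 0) + 1
    ids = {}
    by_exon = {}
    for (exon, seq), n in counts.items():
        by_exon.setdefault(exon, []).append((-n, seq))
    for exon, entries in by_exon.items():
        for i, (_, seq) in enumerate(sorted(entries), start=1):
            key = (exon, seq)
            allele_id = f"{exon}-{i:03d}"
            if allele_id in ids.values():  # pragma: no cover - impossible
                raise RuntimeError(f"allele id collision: {allele_id}")
            ids[key] = allele_id
    return ids


def write_genotype_table(rows: List[GenotypeRow], path) -> Path:
    """Write the genotype TSV plus a FASTA of unique alleles alongside.

    Returns the FASTA path.
    """
    path = Path(path)
    ids = assign_allele_ids(rows)
    records = [{"individual_id": r.individual_id, "exon": r.exon,
                "allele_id": ids[(r.exon, r.allele_seq)],
                "allele_seq": r.allele_seq,
                "within_rf": "" if r.within_rf is None else f"{r.within_rf:.6f}",
                "status": r.status}
               for r in sorted(rows, key=lambda r: (r.individual_id, r.exon,
                                                    ids[(r.exon, r.allele_seq)]))]
    pd.DataFrame(records, columns=["individual_id", "exon", "allele_id",
                                   "allele_seq", "within_rf", "status"]
                 ).to_csv(path, sep="\t", index=False)
    fasta_path = path.with_suffix(".alleles.fasta")
    with open(fasta_path, "w") as fh:
        for (exon, seq), allele_id in sorted(ids.items(), key=lambda kv: kv[1]):
            fh.write(f">{allele_id}\n{seq}\n")
    return fasta_path


def read_genotype_table(path) -> List[GenotypeRow]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [GenotypeRow(r.individual_id, r.exon, r.allele_seq,
                        float(r.within_rf) if r.within_rf else None, r.status)
            for r in df.itertuples()]


def genotype_sets(rows: Iterable[GenotypeRow]) -> dict:
    """Collapse genotype rows to ``{individual: {exon: frozenset(seqs)}}``
    keeping only confirmed alleles."""
    geno = {}
    for r in rows:
        if r.status != "allele":
            continue
        geno.setdefault(r.individual_id, {}).setdefault(r.exon, set()).add(r.allele_seq)
    return {ind: {e: frozenset(s) for e, s in ex.items()}
            for ind, ex in geno.items()}


def load_config(path) -> dict:
    """Load a JSON or YAML config mapping of threshold names to values."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml
        return yaml.safe_load(text)
    return json.loads(text)
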