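"""Allelic diversity summaries across populations, species and genera.

Counts unique DNA and amino-acid alleles per group, per-individual allele
statistics, per-site means (PSM) across sampling localities and the mean
additional unique alleles gained per added locality (MAA), allele sharing
between groups, and per-site amino-acid variability profiles (the matrix
behind a sequence logo).

Rounding convention throughout: round half up to one decimal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq

Genotype = Dict[str, FrozenSet[str]]  # exon -> allele sequences

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"-"}


def round1(x: float) -> float:
    """Round half up to 1 decimal (the tables' dominant behavior)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _round_int(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# translation

def translate(dna_seq: str, frame: int = 0) -> Tuple[str, bool]:
    """Translate with the standard code; flag sequences containing a stop
    codon (a pseudogene indicator for an internal exon fragment)."""
    trimmed = dna_seq[frame:]
    if len(trimmed) % 3:
        raise ValueError(
            f"length {len(trimmed)} not divisible by 3 (frame={frame})")
    aa = str(Seq(trimmed).translate())
    return aa, "*" in aa


# ---------------------------------------------------------------------------
# group summaries

@dataclass
class DiversitySummary:
    group: str
    exon: str
    n_unique_dna: int
    n_unique_aa: int
    per_individual_mean: float
    per_individual_min: int
    per_individual_max: int
    per_individual_mode: Optional[int]
    psm: Optional[float] = None
    maa_per_locality: Optional[float] = None


def _mode_if_unique(values: Sequence[int]) -> Optional[int]:
    counts: Dict[int, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    top = max(counts.values())
    modes = [v for v, n in counts.items() if n == top]
    return modes[0] if len(modes) == 1 else None


def summarize_group(genotypes: Dict[str, Genotype], members: Iterable[str],
                    exon: str, group_name: str = "") -> DiversitySummary:
    """Unique allele counts and per-individual statistics over one group."""
    members = [m for m in members if m in genotypes and exon in genotypes[m]]
    if not members:
        raise ValueError(f"group {group_name!r} has no genotyped members "
                         f"for {exon}")
    union = set()
    counts = []
    for m in members:
        alleles = genotypes[m][exon]
        union |= alleles
        counts.append(len(alleles))
    aas = {translate(s[:len(s) - len(s) % 3])[0] for s in union}
    return DiversitySummary(
        group=group_name, exon=exon,
        n_unique_dna=len(union), n_unique_aa=len(aas),
        per_individual_mean=round1(sum(counts) / len(counts)),
        per_individual_min=min(counts), per_individual_max=max(counts),
        per_individual_mode=_mode_if_unique(counts))


def psm(per_locality_unique_counts: Sequence[int]) -> float:
    """Per-site mean: arithmetic mean of per-locality unique allele counts."""
    if not per_locality_unique_counts:
        raise ValueError("need at least one locality")
    return round1(sum(per_locality_unique_counts)
                  / len(per_locality_unique_counts))


def maa_per_locality(total_unique: int, psm_value: float,
                     n_localities: int) -> Optional[float]:
    """Mean additional unique alleles gained per added locality:
    (total - round(PSM)) / (n_localities - 1); None for a single locality."""
    if n_localities < 1:
        raise ValueError("n_localities must be >= 1")
    if n_localities == 1:
        return None
    base = _round_int(psm_value)
    if total_unique < base:
        raise ValueError("total unique alleles below rounded per-site mean")
    return round1((total_unique - base) / (n_localities - 1))


# ---------------------------------------------------------------------------
# sharing

@dataclass
class SharingTable:
    groups: List[str]
    allele_groups: Dict[str, FrozenSet[str]]  # allele -> groups carrying it
    n_shared: int  # alleles in >= 2 groups
    pct_unique_single_group: float
    pairwise: pd.DataFrame  # groups x groups shared-allele counts


def sharing_table(allele_sets: Dict[str, Iterable[str]]) -> SharingTable:
    """Allele sharing between >= 2 groups (populations, species or genera)."""
    if len(allele_sets) < 2:
        raise ValueError("need at least two groups")
    groups = sorted(allele_sets)
    sets = {g: frozenset(allele_sets[g]) for g in groups}
    alleles = sorted(set().union(*sets.values()))
    carrier = {a: frozenset(g for g in groups if a in sets[g]) for a in alleles}
    n_shared = sum(1 for a in alleles if len(carrier[a]) >= 2)
    pct_unique = (100.0 * (len(alleles) - n_shared) / len(alleles)
                  if alleles else 0.0)
    mat = pd.DataFrame(
        [[len(sets[g1] & sets[g2]) for g2 in groups] for g1 in groups],
        index=groups, columns=groups)
    return SharingTable(groups, carrier, n_shared, pct_unique, mat)


# ---------------------------------------------------------------------------
# amino-acid alignment metrics

def align_protein_set(aa_seqs: Sequence[str]) -> List[str]:
    """Gap-pad same-frame exon fragments of slightly different lengths.

    Shorter sequences receive one contiguous gap placed at the position
    minimizing mismatches against the first longest sequence (leftmost on
    ties); full-length sequences pass through unchanged.
    """
    if not aa_seqs:
        return []
    target = max(len(s) for s in aa_seqs)
    ref = next(s for s in aa_seqs if len(s) == target)
    out = []
    for s in aa_seqs:
        d = target - len(s)
        if d == 0:
            out.append(s)
            continue
        best, best_mm = None, None
        for pos in range(len(s) + 1):
            padded = s[:pos] + "-" * d + s[pos:]
            mm = sum(1 for a, b in zip(padded, ref) if a != b)
            if best_mm is None or mm < best_mm:
                best, best_mm = padded, mm
        out.append(best)
    return out


def _check_rectangular(alignment: Sequence[str]) -> int:
    lengths = {len(s) for s in alignment}
    if len(lengths) > 1:
        raise ValueError("ragged alignment")
    return lengths.pop() if lengths else 0


def polymorphic_fraction(aa_alignment: Sequence[str]) -> float:
    """Percent of alignment columns with >= 2 distinct residues (gaps count
    as a state)."""
    ncol = _check_rectangular(aa_alignment)
    if ncol == 0 or len(aa_alignment) < 2:
        return 0.0
    poly = sum(1 for i in range(ncol)
               if len({s[i] for s in aa_alignment}) >= 2)
    return 100.0 * poly / ncol


def mean_pairwise_identity(aa_sequences: Sequence[str]) -> Optional[float]:
    """Mean percent identical columns over unordered sequence pairs."""
    if len(aa_sequences) < 2:
        return None
    ncol = _check_rectangular(aa_sequences)
    idents = []
    for i in range(len(aa_sequences)):
        for j in range(i + 1, len(aa_sequences)):
            same = sum(1 for a, b in zip(aa_sequences[i], aa_sequences[j])
                       if a == b)
            idents.append(100.0 * same / ncol)
    return float(np.mean(idents))


def shared_polymorphism_proportion(alignment_a: Sequence[str],
                                   alignment_b: Sequence[str]) -> float:
    """Proportion of (column, residue) variant states at jointly polymorphic
    columns that occur in both groups.

    Over columns polymorphic in the combined alignment, collect every
    (column, residue) state seen in either group; the result is
    |states in both| / |states in either|.
    """
    na, nb = _check_rectangular(alignment_a), _check_rectangular(alignment_b)
    if na != nb:
        raise ValueError("alignments are over different column coordinates")
    states_a, states_b = set(), set()
    for col in range(na):
        combined = {s[col] for s in alignment_a} | {s[col] for s in alignment_b}
        if len(combined) < 2:
            continue
        states_a |= {(col, s[col]) for s in alignment_a}
        states_b |= {(col, s[col]) for s in alignment_b}
    union = states_a | states_b
    if not union:
        return 1.0
    return len(states_a & states_b) / len(union)


@dataclass
class SiteProfile:
    """Per-column residue frequencies plus information content in bits."""

    columns: List[Dict[str, float]]
    information: List[float]
    n_sequences: int

    def to_frame(self) -> pd.DataFrame:
        residues = sorted({r for col in self.columns for r in col})
        return pd.DataFrame(
            [[col.get(r, 0.0) for r in residues] for col in self.columns],
            columns=residues)


def site_profile(aa_alignment: Sequence[str]) -> SiteProfile:
    """Column-wise residue frequency matrix (the data behind a sequence logo)
    with per-column information content log2(20) - entropy."""
    if not aa_alignment:
        raise ValueError("empty alignment")
    ncol = _check_rectangular(aa_alignment)
    n = len(aa_alignment)
    columns, info = [], []
    for i in range(ncol):
        freqs: Dict[str, float] = {}
        for s in aa_alignment:
            freqs[s[i]] = freqs.get(s[i], 0.0) + 1.0 / n
        entropy = -sum(p * math.log2(p) for p in freqs.values())
        columns.append(freqs)
        info.append(math.log2(20) - entropy)
    return SiteProfile(columns, info, n)


# ---------------------------------------------------------------------------
# table assembly

def diversity_table(genotypes: Dict[str, Genotype],
                    population_of: Dict[str, str],
                    exons: Sequence[str]) -> pd.DataFrame:
    """Per-exon species summary with per-locality counts, PSM and MAA."""
    rows = []
    members = sorted(genotypes)
    localities = sorted({population_of[m] for m in members})
    for exon in exons:
        typed = [m for m in members if exon in genotypes.get(m, {})]
        if not typed:
            continue
        total = summarize_group(genotypes, typed, exon, "all")
        loc_counts = []
        for loc in localities:
            here = [m for m in typed if population_of[m] == loc]
            if here:
                loc_counts.append(
                    summarize_group(genotypes, here, exon, loc).n_unique_dna)
        p = psm(loc_counts)
        maa = maa_per_locality(total.n_unique_dna, p, len(loc_counts))
        rows.append({"exon": exon, "n_unique_dna": total.n_unique_dna,
                     "n_unique_aa": total.n_unique_aa,
                     "mean_alleles_per_individual": total.per_individual_mean,
                     "min": total.per_individual_min,
                     "max": total.per_individual_max,
                     "mode": total.per_individual_mode,
                     "psm": p, "maa_per_locality": maa})
    return pd.DataFrame(rows)
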