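"""Mendelian validation of multicopy genotypes and haplotype-block inference.

Genotypes here are unphased per-exon allele *sets*.  Validation checks that
every allele in an offspring occurs in at least one parent.  Because the four
exons sit in one tightly linked MHC region, the allele sets across all exons
are transmitted together as a block; block inference searches for a minimal
set of four-exon blocks such that every individual's genotype is the union of
two blocks (homozygotes: the same block twice).  Minimum gene copy number per
exon follows from the largest per-individual allele count: a diploid with m
distinct alleles needs at least ceil(m / 2) gene copies.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .targets import PedigreeTriad

Genotype = Dict[str, FrozenSet[str]]  # exon -> allele sequences
Block = Tuple[Tuple[str, FrozenSet[str]], ...]  # canonical ((exon, seqs), ...)


def _canon(alleles: Dict[str, FrozenSet[str]]) -> Block:
    return tuple(sorted((e, frozenset(s)) for e, s in alleles.items()))


def _block_key(block: Block) -> tuple:
    return tuple((e, tuple(sorted(s))) for e, s in block)


@dataclass
class TriadReport:
    triad: PedigreeTriad
    per_exon: Dict[str, dict]  # exon -> {comparable, consistent, orphans}

    @property
    def consistent(self) -> Optional[bool]:
        flags = [d["consistent"] for d in self.per_exon.values()
                 if d["comparable"]]
        return all(flags) if flags else None


def validate_triad(genotypes: Dict[str, Genotype],
                   triad: PedigreeTriad) -> TriadReport:
    """Check that each offspring allele occurs in at least one parent,
    per exon.  Symmetric in mother and father."""
    off = genotypes.get(triad.offspring_id, {})
    mom = genotypes.get(triad.mother_id, {})
    dad = genotypes.get(triad.father_id, {})
    exons = sorted(set(off) | set(mom) | set(dad))
    per_exon = {}
    for exon in exons:
        if exon not in off or exon not in mom or exon not in dad:
            per_exon[exon] = {"comparable": False, "consistent": None,
                              "orphans": frozenset()}
            continue
        orphans = off[exon] - (mom[exon] | dad[exon])
        per_exon[exon] = {"comparable": True, "consistent": not orphans,
                          "orphans": frozenset(orphans)}
    return TriadReport(triad, per_exon)


def flag_triad_inconsistent_alleles(genotypes: Dict[str, Genotype],
                                    triads: Sequence[PedigreeTriad],
                                    min_triads: int = 2
                                    ) -> Dict[Tuple[str, str], List[PedigreeTriad]]:
    """Advisory flag: alleles orphaned in >= ``min_triads`` distinct triads.

    Returns ``{(exon, allele_seq): [triads with the orphan]}``.  The caller
    decides removal; nothing is deleted silently.
    """
    evidence: Dict[Tuple[str, str], List[PedigreeTriad]] = {}
    for triad in triads:
        report = validate_triad(genotypes, triad)
        for exon, d in report.per_exon.items():
            for seq in d["orphans"]:
                evidence.setdefault((exon, seq), []).append(triad)
    return {key: tr for key, tr in evidence.items() if len(tr) >= min_triads}


# ---------------------------------------------------------------------------
# haplotype blocks

def _explains(genotype: Genotype, b1: Block, b2: Block) -> bool:
    d1, d2 = dict(b1), dict(b2)
    if set(d1) != set(genotype) or set(d2) != set(genotype):
        return False
    return all(d1[e] | d2[e] == genotype[e] for e in genotype)


def _candidate_blocks(genotypes: Dict[str, Genotype], exons: Sequence[str],
                      triads: Sequence[PedigreeTriad]) -> List[Block]:
    """Seed candidates from (i) whole genotypes (homozygote hypothesis),
    (ii) parental contributions inferred from triads, and (iii) set-difference
    complements of existing candidates within each genotype."""
    complete = {ind: g for ind, g in genotypes.items()
                if set(g) == set(exons)}
    seen: Set[tuple] = set()
    candidates: List[Block] = []

    def add(alleles: Dict[str, FrozenSet[str]]):
        if any(not s for s in alleles.values()) or set(alleles) != set(exons):
            return
        block = _canon(alleles)
        key = _block_key(block)
        if key not in seen:
            seen.add(key)
            candidates.append(block)

    for ind in sorted(complete):
        add({e: frozenset(s) for e, s in complete[ind].items()})
    for t in triads:
        if not all(x in complete for x in (t.offspring_id, t.mother_id,
                                           t.father_id)):
            continue
        off, mom, dad = (complete[t.offspring_id], complete[t.mother_id],
                         complete[t.father_id])
        maternal = {e: off[e] & mom[e] for e in exons}
        paternal = {e: off[e] & dad[e] for e in exons}
        if all(maternal[e] | paternal[e] == off[e] for e in exons):
            add(maternal)
            add(paternal)
    # complements: if b covers part of a genotype, the rest must be the
    # other block (falling back to b's own alleles at homozygous exons)
    for ind in sorted(complete):
        g = complete[ind]
        for block in list(candidates):
            d = dict(block)
            if all(d[e] <= g[e] for e in exons):
                add({e: (g[e] - d[e]) or d[e] for e in exons})
    return candidates


@dataclass
class BlockInference:
    blocks: List[Block]
    assignment: Dict[str, Optional[Tuple[int, int]]]  # indices into blocks
    unexplained: List[str]


def infer_haplotype_blocks(genotypes: Dict[str, Genotype],
                           triads: Sequence[PedigreeTriad] = (),
                           exhaustive_limit: int = 12) -> BlockInference:
    """Find a minimal block set explaining each fully genotyped individual as
    the union of two blocks.

    Exhaustive subset search when there are <= ``exhaustive_limit`` candidate
    blocks, otherwise a deterministic greedy cover (candidates ordered by how
    many genotypes contain them, then lexicographically).  Individuals no
    candidate pair explains are reported unexplained, never forced.
    """
    exons = sorted({e for g in genotypes.values() for e in g})
    complete = {ind: g for ind, g in genotypes.items() if set(g) == set(exons)}
    if not complete:
        return BlockInference([], {}, [])
    candidates = _candidate_blocks(genotypes, exons, triads)
    # deterministic candidate order: containment frequency desc, then lex
    freq = {i: sum(1 for g in complete.values()
                   if all(dict(c)[e] <= g[e] for e in exons))
            for i, c in enumerate(candidates)}
    order = sorted(range(len(candidates)),
                   key=lambda i: (-freq[i], _block_key(candidates[i])))
    candidates = [candidates[i] for i in order]

    pairs_for: Dict[str, List[Tuple[int, int]]] = {}
    for ind, g in sorted(complete.items()):
        opts = [(i, j)
                for i in range(len(candidates))
                for j in range(i, len(candidates))
                if _explains(g, candidates[i], candidates[j])]
        pairs_for[ind] = opts
    explainable = [ind for ind, opts in pairs_for.items() if opts]
    unexplained = sorted(set(complete) - set(explainable))

    chosen: Optional[Tuple[int, ...]] = None
    if len(candidates) <= exhaustive_limit:
        for size in range(1, len(candidates) + 1):
            for subset in itertools.combinations(range(len(candidates)), size):
                sset = set(subset)
                if all(any(i in sset and j in sset for i, j in pairs_for[ind])
                       for ind in explainable):
                    chosen = subset
                    break
            if chosen is not None:
                break
    else:
        picked: Set[int] = set()
        covered: Set[str] = set()
        while True:
            best, best_gain = None, 0
            for i in range(len(candidates)):
                if i in picked:
                    continue
                trial = picked | {i}
                gain = sum(1 for ind in explainable if ind not in covered
                           and any(a in trial and b in trial
                                   for a, b in pairs_for[ind]))
                if gain > best_gain:
                    best, best_gain = i, gain
            if best is None:
                break
            picked.add(best)
            covered = {ind for ind in explainable
                       if any(a in picked and b in picked
                              for a, b in pairs_for[ind])}
        chosen = tuple(sorted(picked))
    chosen = chosen or ()

    index_map = {old: new for new, old in enumerate(chosen)}
    blocks = [candidates[i] for i in chosen]
    assignment: Dict[str, Optional[Tuple[int, int]]] = {}
    sset = set(chosen)
    for ind in sorted(complete):
        usable = sorted((index_map[i], index_map[j])
                        for i, j in pairs_for[ind]
                        if i in sset and j in sset)
        assignment[ind] = usable[0] if usable else None
    unexplained = sorted(ind for ind, a in assignment.items() if a is None)
    return BlockInference(blocks, assignment, unexplained)


def classify_zygosity(inference: BlockInference) -> Dict[str, dict]:
    """Per individual: per-exon homozygosity flags and the overall class
    (homozygous_all / heterozygous_all / mixed / unknown)."""
    out = {}
    for ind, pair in sorted(inference.assignment.items()):
        if pair is None:
            out[ind] = {"class": "unknown", "per_exon": {}}
            continue
        b1, b2 = (dict(inference.blocks[pair[0]]),
                  dict(inference.blocks[pair[1]]))
        per_exon = {e: b1[e] == b2[e] for e in sorted(b1)}
        if all(per_exon.values()):
            cls = "homozygous_all"
        elif not any(per_exon.values()):
            cls = "heterozygous_all"
        else:
            cls = "mixed"
        out[ind] = {"class": cls, "per_exon": per_exon}
    return out


def min_copy_number(allele_counts: Sequence[int]) -> int:
    """Minimum diploid gene copy number consistent with the largest
    per-individual allele count: ceil(max / 2)."""
    if not allele_counts:
        raise ValueError("no allele counts supplied")
    if any(c < 1 for c in allele_counts):
        raise ValueError("allele counts must be >= 1")
    return math.ceil(max(allele_counts) / 2)
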