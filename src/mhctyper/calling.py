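"""Distinguishing putative alleles from artifacts in multicopy amplicons.

The decision tree per amplicon: the most frequent variant is automatically a
putative allele; remaining variants must exceed a 1% relative-frequency floor
(strict); surviving variants are screened for two-parent PCR chimeras (a
sequence is discarded only when it is chimeric in every individual carrying
it); variants within 1-2 bp of a more frequent variant are putative artifacts
while those >2 bp from every more frequent variant are putative alleles.
Population-level thresholds then confirm or reject: mean relative frequency
across carriers >= 0.07, within-individual relative frequency >= 0.04
(0.025 for DRBe3 whose high copy number depresses per-allele frequencies),
a DIS score (minimum edit distance to the individual's four most frequent
variants) > 1 for variants outside the top four, and - for well-sampled
species - at least two qualifying carriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

import edlib

from .qc import AmpliconSet, Variant

STATUSES = ("allele", "artifact_lowfreq", "artifact_near", "chimera",
            "failed_population_qc", "triad_removed")


@dataclass(frozen=True)
class CallingConfig:
    floor_frac: float = 0.01
    near_diff_max: int = 2
    mean_rsf_min: float = 0.07
    within_rf_min: float = 0.04
    within_rf_min_by_exon: Tuple[Tuple[str, float], ...] = (("DRBe3", 0.025),)
    top_k: int = 4
    dis_min_exclusive: int = 1
    min_individuals_well_sampled: int = 2
    well_sampled_min_individuals: int = 21  # species with >20 genotyped individuals
    assumed_min_copies: int = 2
    chimera_abundance_skew: float = 2.0

    def __post_init__(self):
        if not self.floor_frac < self.within_rf_min:
            raise ValueError("floor_frac must be below within_rf_min")

    def exon_threshold(self, exon: str) -> float:
        return dict(self.within_rf_min_by_exon).get(exon, self.within_rf_min)


@dataclass
class AlleleCall:
    """One variant's classification within one individual's amplicon."""

    seq: str
    individual_id: str
    exon: str
    status: str
    within_rf: float
    rank: int
    dis: Optional[int] = None
    mean_rsf: Optional[float] = None
    n_carriers: int = 0


def edit_distance(a: str, b: str) -> int:
    """Unit-cost edit distance (substitutions + indels)."""
    return edlib.align(a, b, task="distance")["editDistance"]


# ---------------------------------------------------------------------------
# per-amplicon steps

def floor_filter(amplicon: AmpliconSet, config: CallingConfig
                 ) -> Tuple[List[Variant], List[Variant]]:
    """Keep the rank-1 variant unconditionally; others must strictly exceed
    the 1% relative-frequency floor ("more than 1%")."""
    kept, discarded = [], []
    for i, v in enumerate(amplicon.variants):
        if i == 0 or v.rel_freq > config.floor_frac:
            kept.append(v)
        else:
            discarded.append(v)
    return kept, discarded


def _lcp(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[i] == b[i]:
        i += 1
    return i


def _lcs(a: str, b: str) -> int:
    n = min(len(a), len(b))
    i = 0
    while i < n and a[-1 - i] == b[-1 - i]:
        i += 1
    return i


def detect_chimera(candidate: Variant, parent_pool: Sequence[Variant]
                   ) -> Optional[Tuple[str, str, int]]:
    """Exact two-parent crossover test: candidate == A[0:p) + B[p:len).

    ``parent_pool`` holds variants strictly more abundant than
    ``candidate x chimera_abundance_skew`` from the same amplicon.  Returns
    the first ordered pair by parent abundance (ties by sequence) with the
    smallest interior breakpoint, or None.
    """
    pool = [v for v in sorted(parent_pool, key=lambda v: (-v.count, v.seq))
            if v.seq != candidate.seq]
    if len(pool) < 2:
        return None
    n = len(candidate.seq)
    for a in pool:
        lcp = _lcp(candidate.seq, a.seq)
        if lcp < 1:
            continue
        for b in pool:
            if b.seq == a.seq or len(b.seq) != n:
                continue
            lcs = _lcs(candidate.seq, b.seq)
            p_min = max(1, n - lcs)
            p_max = min(lcp, len(a.seq), n - 1)
            if p_min <= p_max:
                return (a.seq, b.seq, p_min)
    return None


def chimera_parent_pool(kept: Sequence[Variant], candidate: Variant,
                        skew: float) -> List[Variant]:
    return [v for v in kept
            if v.count > candidate.count * skew and v.seq != candidate.seq]


def apply_global_chimera_rule(flags: Dict[str, Dict[str, bool]]) -> Set[str]:
    """A sequence is discarded as chimeric only when flagged chimeric in 100%
    of the individuals carrying it."""
    return {seq for seq, per_ind in flags.items()
            if per_ind and all(per_ind.values())}


def dis_score(seq: str, individual_top: Sequence[str]) -> int:
    """Smallest edit distance from ``seq`` to the individual's most frequent
    variants (up to four; fewer allowed)."""
    if not individual_top:
        raise ValueError("top variant set must be non-empty")
    return min(edit_distance(seq, t) for t in individual_top)


def classify_variants(kept: Sequence[Variant], individual_id: str, exon: str,
                      config: CallingConfig) -> List[AlleleCall]:
    """Provisional classification of floor/chimera-surviving variants.

    Rank 1 is a putative allele; a variant more than ``near_diff_max`` bp
    (unit edit distance) from every more frequent kept variant is a putative
    allele; one within 1-2 bp of any more frequent variant is a putative
    artifact pending rescue by population QC.
    """
    top_seqs = [v.seq for v in kept[:config.top_k]]
    calls = []
    for rank0, v in enumerate(kept):
        rank = rank0 + 1
        dis = dis_score(v.seq, top_seqs) if rank > config.top_k else None
        if rank == 1:
            status = "allele"
        else:
            dmin = min(edit_distance(v.seq, u.seq) for u in kept[:rank0])
            status = "allele" if dmin > config.near_diff_max else "artifact_near"
        calls.append(AlleleCall(v.seq, individual_id, exon, status,
                                within_rf=v.rel_freq, rank=rank, dis=dis))
    return calls


# ---------------------------------------------------------------------------
# population-level QC

def population_qc(calls: Sequence[AlleleCall], species_of: Dict[str, str],
                  config: CallingConfig,
                  well_sampled_species: Optional[Set[str]] = None
                  ) -> List[AlleleCall]:
    """Confirm or reject provisional calls against population thresholds.

    A sequence is a confirmed allele in an individual iff its mean
    within-amplicon relative frequency over all carriers of the species is
    >= ``mean_rsf_min``; its frequency in this individual meets the exon
    threshold; and, when outside the individual's top four, its DIS exceeds
    ``dis_min_exclusive``.  For well-sampled species at least
    ``min_individuals_well_sampled`` carriers must qualify.  Rank-1 variants
    remain alleles regardless (the most frequent variant is automatically a
    putative allele).  Putative near artifacts are rescued by the same
    criteria, otherwise rejected.  Iteration order never affects the result.
    """
    if well_sampled_species is None:
        n_by_species: Dict[str, Set[str]] = {}
        for c in calls:
            n_by_species.setdefault(species_of[c.individual_id], set()).add(
                c.individual_id)
        well_sampled_species = {
            sp for sp, inds in n_by_species.items()
            if len(inds) >= config.well_sampled_min_individuals}

    groups: Dict[Tuple[str, str, str], List[AlleleCall]] = {}
    for c in calls:
        key = (species_of[c.individual_id], c.exon, c.seq)
        groups.setdefault(key, []).append(c)

    def qualifies(c: AlleleCall) -> bool:
        if c.within_rf < config.exon_threshold(c.exon):
            return False
        if c.rank > config.top_k:
            return c.dis is not None and c.dis > config.dis_min_exclusive
        return True

    out: List[AlleleCall] = []
    for (species, exon, seq) in sorted(groups):
        # fixed summation order so the result is bit-identical however the
        # input calls were ordered
        members = sorted(groups[(species, exon, seq)],
                         key=lambda c: (c.individual_id, c.rank))
        mean_rsf = sum(c.within_rf for c in members) / len(members)
        n_qual = sum(1 for c in members if qualifies(c))
        required = (config.min_individuals_well_sampled
                    if species in well_sampled_species else 1)
        group_pass = mean_rsf >= config.mean_rsf_min and n_qual >= required
        for c in members:
            if c.rank == 1:
                status = "allele"
            elif group_pass and qualifies(c):
                status = "allele"
            else:
                status = "failed_population_qc"
            out.append(replace(c, status=status, mean_rsf=mean_rsf,
                               n_carriers=len(members)))
    out.sort(key=lambda c: (c.individual_id, c.exon, c.rank))
    return out


# ---------------------------------------------------------------------------
# whole-run driver

@dataclass
class CallingResult:
    calls: List[AlleleCall]
    genotypes: Dict[str, Dict[str, FrozenSet[str]]]  # individual -> exon -> seqs
    chimera_report: List[Tuple[str, str, str, str, int]]  # ind, seq, parentA, parentB, p
    gate_failures: List[Tuple[str, str, str]] = field(default_factory=list)


def call_population(amplicons: Sequence[AmpliconSet],
                    species_of: Dict[str, str],
                    config: CallingConfig,
                    min_reads_final: int = 120) -> CallingResult:
    """Run the full decision tree over every amplicon of a study.

    After the first pass, amplicons whose confirmed allele count exceeds two
    are re-gated at ``min_reads_final`` reads (the multi-allele depth
    threshold) and dropped from the genotype table if too shallow.
    """
    amplicons = sorted(amplicons, key=lambda a: (a.individual_id, a.exon))
    kept_by_amp: Dict[Tuple[str, str], List[Variant]] = {}
    for amp in amplicons:
        if not amp.variants:
            continue
        kept, _ = floor_filter(amp, config)
        kept_by_amp[(amp.individual_id, amp.exon)] = kept

    # chimera flags for every carrier of any flagged sequence (per exon)
    flags: Dict[Tuple[str, str], Dict[str, bool]] = {}
    chimera_hits: Dict[Tuple[str, str, str], Tuple[str, str, int]] = {}
    for (ind, exon), kept in sorted(kept_by_amp.items()):
        for v in kept[1:]:  # rank-1 exempt from the chimera check
            pool = chimera_parent_pool(kept, v, config.chimera_abundance_skew)
            hit = detect_chimera(v, pool) if len(pool) >= 2 else None
            if hit is not None:
                flags.setdefault((exon, v.seq), {})[ind] = True
                chimera_hits[(ind, exon, v.seq)] = hit
    # fill in non-flagged carriers (including rank-1 carriers)
    for (exon, seq) in list(flags):
        for (ind, e2), kept in kept_by_amp.items():
            if e2 == exon and any(v.seq == seq for v in kept):
                flags[(exon, seq)].setdefault(ind, False)
    discard_by_exon: Dict[str, Set[str]] = {}
    for (exon, seq), per_ind in flags.items():
        if all(per_ind.values()):
            discard_by_exon.setdefault(exon, set()).add(seq)

    chimera_report = [(ind, seq, a, b, p)
                      for (ind, exon, seq), (a, b, p) in sorted(chimera_hits.items())
                      if seq in discard_by_exon.get(exon, ())]

    provisional: List[AlleleCall] = []
    for (ind, exon), kept in sorted(kept_by_amp.items()):
        surviving = [v for v in kept
                     if v.seq not in discard_by_exon.get(exon, ())]
        if not surviving:
            continue
        provisional.extend(classify_variants(surviving, ind, exon, config))

    final = population_qc(provisional, species_of, config)

    totals = {(a.individual_id, a.exon): a.total_reads for a in amplicons}
    genotypes: Dict[str, Dict[str, FrozenSet[str]]] = {}
    gate_failures = []
    for c in final:
        if c.status != "allele":
            continue
        genotypes.setdefault(c.individual_id, {}).setdefault(c.exon, set()).add(c.seq)
    for ind in list(genotypes):
        for exon in list(genotypes[ind]):
            alleles = genotypes[ind][exon]
            if len(alleles) > 2 and totals[(ind, exon)] < min_reads_final:
                del genotypes[ind][exon]
                gate_failures.append((ind, exon, "below_final_depth_gate"))
        if not genotypes[ind]:
            del genotypes[ind]
    genotypes = {ind: {e: frozenset(s) for e, s in ex.items()}
                 for ind, ex in genotypes.items()}
    return CallingResult(final, genotypes, chimera_report, gate_failures)


# ---------------------------------------------------------------------------
# replicate concordance

def replicate_concordance(genotype_r1: Dict[str, FrozenSet[str]],
                          genotype_r2: Dict[str, FrozenSet[str]]) -> Dict[str, dict]:
    """Per-exon agreement between duplicate PCRs of the same individual."""
    report = {}
    for exon in sorted(set(genotype_r1) | set(genotype_r2)):
        if exon not in genotype_r1 or exon not in genotype_r2:
            report[exon] = {"comparable": False}
            continue
        a, b = genotype_r1[exon], genotype_r2[exon]
        report[exon] = {"comparable": True,
                        "n_shared": len(a & b),
                        "n_discordant": len(a ^ b),
                        "full_match": a == b}
    return report
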