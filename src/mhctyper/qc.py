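"""Post-sequencing quality control for multicopy amplicons.

Stage order is fixed: demultiplex by primer -> merge mates -> length/quality
filter -> dereplicate and drop singletons -> homopolymer-indel correction ->
reading-frame filter -> read-depth gate.  Every stage is a pure function of
its input so it can be re-applied idempotently, and the pipeline records
in/out counts for a funnel report.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import binom

from .io import Read, ReadPair
from .targets import IUPAC, ExonTarget, revcomp

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCConfig:
    """Thresholds for read-level quality control.

    ``min_reads_initial``/``min_reads_final`` are the depth gates for the
    one-copy and multi-allele genotyping passes (25 and 120 reads).  They are
    literal constants used for gating; ``coverage_probability`` below is a
    transparent utility for inspecting what such gates buy under a multinomial
    read-allocation model with one poorly amplifying allele.
    """

    max_primer_mismatch: int = 1
    min_len: int = 150
    max_len: int = 400
    q_threshold: int = 20
    max_frac_lowq: float = 0.05
    min_overlap: int = 20
    max_overlap_mismatch_frac: float = 0.1
    homopolymer_min_run: int = 3
    min_reads_initial: int = 25
    min_reads_final: int = 120
    assumed_efficiency: float = 0.7
    min_reads_per_allele: int = 3
    confidence: float = 0.999

    def __post_init__(self):
        if not self.min_len < self.max_len:
            raise ValueError("min_len must be < max_len")
        for frac in (self.max_frac_lowq, self.max_overlap_mismatch_frac):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.min_reads_initial > self.min_reads_final:
            raise ValueError("min_reads_initial must be <= min_reads_final")


@dataclass(frozen=True)
class Variant:
    """A unique merged sequence with its read count within one amplicon."""

    seq: str
    count: int
    rel_freq: float

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("variant count must be >= 1")
        if not 0 < self.rel_freq <= 1:
            raise ValueError("rel_freq must lie in (0, 1]")


@dataclass(frozen=True)
class AmpliconSet:
    """All variants for one individual x exon, sorted by descending count
    (ties broken lexicographically by sequence)."""

    individual_id: str
    exon: str
    variants: Tuple[Variant, ...]
    total_reads: int

    def __post_init__(self):
        if sum(v.count for v in self.variants) != self.total_reads:
            raise ValueError("variant counts must sum to total_reads")
        order = [(-v.count, v.seq) for v in self.variants]
        if order != sorted(order):
            raise ValueError("variants must be sorted by descending count")


def make_amplicon(individual_id: str, exon: str,
                  counts: Dict[str, int]) -> AmpliconSet:
    """Build a sorted AmpliconSet from a ``{seq: count}`` mapping."""
    total = sum(counts.values())
    variants = tuple(
        Variant(seq, n, n / total)
        for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    return AmpliconSet(individual_id, exon, variants, total)


# ---------------------------------------------------------------------------
# primer matching / demultiplexing

def match_primer(seq: str, primer_iupac: str,
                 max_mismatch: int) -> Tuple[bool, str]:
    """Compare a read prefix to an IUPAC primer; trim the primer on match.

    A read base matches when it belongs to the IUPAC set of the primer code;
    anything outside ACGTN counts as a mismatch, never an error.
    """
    if len(primer_iupac) > len(seq):
        return False, seq
    mismatches = 0
    for base, code in zip(seq, primer_iupac):
        if base not in IUPAC.get(code, ()):  # non-IUPAC read base: mismatch
            mismatches += 1
            if mismatches > max_mismatch:
                return False, seq
    return True, seq[len(primer_iupac):]


def _primer_mismatches(seq: str, primer: str, limit: int) -> Optional[int]:
    if len(primer) > len(seq):
        return None
    mism = 0
    for base, code in zip(seq, primer):
        if base not in IUPAC.get(code, ()):
            mism += 1
            if mism > limit:
                return None
    return mism


def demultiplex(pairs: Iterable[ReadPair],
                targets: Dict[str, ExonTarget],
                config: QCConfig) -> Tuple[Dict[str, List[ReadPair]],
                                           List[Tuple[ReadPair, str]]]:
    """Assign read pairs to exons by both primers and trim the primers.

    A pair is assigned when the forward mate matches the forward primer and
    the reverse mate matches the reverse primer, each within
    ``max_primer_mismatch``.  When more than one exon matches, the pair goes
    to the fewest-mismatch exon; exact ties are discarded as ambiguous.
    """
    assigned: Dict[str, List[ReadPair]] = {name: [] for name in targets}
    discards: List[Tuple[ReadPair, str]] = []
    order = sorted(targets)
    for pair in pairs:
        fwd, rev = pair
        hits = []
        for name in order:
            t = targets[name]
            mf = _primer_mismatches(fwd.seq, t.fwd_primer, config.max_primer_mismatch)
            if mf is None:
                continue
            mr = _primer_mismatches(rev.seq, t.rev_primer, config.max_primer_mismatch)
            if mr is None:
                continue
            hits.append((mf + mr, name))
        if not hits:
            discards.append((pair, "no_primer_match"))
            continue
        hits.sort()
        if len(hits) > 1 and hits[0][0] == hits[1][0]:
            discards.append((pair, "ambiguous_primer_match"))
            continue
        name = hits[0][1]
        t = targets[name]
        nf, nr = len(t.fwd_primer), len(t.rev_primer)
        trimmed = (Read(fwd.id, fwd.seq[nf:], fwd.quals[nf:]),
                   Read(rev.id, rev.seq[nr:], rev.quals[nr:]))
        assigned[name].append(trimmed)
    return assigned, discards


# ---------------------------------------------------------------------------
# mate merging

def _to_arrays(read: Read) -> Tuple[np.ndarray, np.ndarray]:
    return (np.frombuffer(read.seq.encode(), dtype=np.uint8),
            np.asarray(read.quals, dtype=np.int16))


def merge_pair(fwd: Read, rev_rc: Read, config: QCConfig) -> Optional[Read]:
    """Merge a primer-trimmed pair (reverse mate already reverse-complemented).

    Chooses the overlap length ``o >= min_overlap`` maximizing the number of
    matching bases subject to a mismatch fraction <= max_overlap_mismatch_frac
    (larger overlap wins ties).  Disagreements resolve to the higher-quality
    base (forward on quality ties); merged quality is the max of the two.
    Returns None when no admissible overlap exists - failure is a value.
    """
    f_seq, f_q = _to_arrays(fwd)
    r_seq, r_q = _to_arrays(rev_rc)
    nf, nr = len(f_seq), len(r_seq)
    max_o = min(nf, nr)
    if max_o < config.min_overlap:
        return None
    best_o, best_matches = 0, -1
    # matches(o) <= o, so scanning o downward can stop once o <= best_matches
    for o in range(max_o, config.min_overlap - 1, -1):
        if o <= best_matches:
            break
        matches = int(np.count_nonzero(f_seq[nf - o:] == r_seq[:o]))
        if (o - matches) / o <= config.max_overlap_mismatch_frac \
                and matches > best_matches:
            best_o, best_matches = o, matches
    if best_matches < 0:
        return None
    o = best_o
    f_tail, r_head = f_seq[nf - o:], r_seq[:o]
    fq_tail, rq_head = f_q[nf - o:], r_q[:o]
    take_rev = (f_tail != r_head) & (rq_head > fq_tail)
    cons = np.where(take_rev, r_head, f_tail)
    cons_q = np.maximum(fq_tail, rq_head)
    seq = fwd.seq[:nf - o] + cons.tobytes().decode() + rev_rc.seq[o:]
    quals = tuple(f_q[:nf - o]) + tuple(int(q) for q in cons_q) + tuple(r_q[o:])
    return Read(fwd.id, seq, quals)


def revcomp_read(read: Read) -> Read:
    return Read(read.id, revcomp(read.seq), tuple(reversed(read.quals)))


# ---------------------------------------------------------------------------
# merged-read filters

def length_quality_filter(read: Read, config: QCConfig) -> Optional[str]:
    """Return a discard reason, or None to keep.

    Keeps reads with min_len <= length <= max_len whose fraction of bases
    below the Phred threshold does not exceed ``max_frac_lowq`` (strictly
    more than 5% low-quality bases is discarded).
    """
    n = len(read.seq)
    if n < config.min_len or n > config.max_len:
        return "length"
    n_lowq = sum(1 for q in read.quals if q < config.q_threshold)
    if n_lowq / n > config.max_frac_lowq:
        return "low_quality"
    return None


def dereplicate(reads: Sequence[Read], individual_id: str,
                exon: str) -> AmpliconSet:
    """Collapse identical sequences into counted variants; singletons
    (count 1) are discarded as presumptive errors."""
    counts: Dict[str, int] = {}
    for r in reads:
        counts[r.seq] = counts.get(r.seq, 0) + 1
    counts = {s: n for s, n in counts.items() if n >= 2}
    if not counts:
        return AmpliconSet(individual_id, exon, (), 0)
    return make_amplicon(individual_id, exon, counts)


# ---------------------------------------------------------------------------
# homopolymer-indel correction

def _single_indel_site(longer: str, shorter: str) -> Optional[int]:
    """If ``longer`` equals ``shorter`` plus one inserted base, return an
    insertion index in ``longer`` (the longest-common-prefix position, which
    is always a valid placement when one exists); otherwise None."""
    if len(longer) != len(shorter) + 1:
        return None
    lp = 0
    n = len(shorter)
    while lp < n and longer[lp] == shorter[lp]:
        lp += 1
    return lp if longer[lp + 1:] == shorter[lp:] else None


def _run_length_at(seq: str, pos: int, base: str) -> int:
    """Length of the homopolymer run of ``base`` in ``seq`` touching ``pos``."""
    if pos >= len(seq) or seq[pos] != base:
        if pos > 0 and seq[pos - 1] == base:
            pos -= 1
        else:
            return 0
    i = pos
    while i > 0 and seq[i - 1] == base:
        i -= 1
    j = pos
    while j + 1 < len(seq) and seq[j + 1] == base:
        j += 1
    return j - i + 1


def is_homopolymer_indel(frequent: str, rare: str, min_run: int) -> bool:
    """True when ``rare`` differs from ``frequent`` by exactly one single-base
    indel lying inside a homopolymer run of length >= min_run in ``frequent``."""
    if abs(len(frequent) - len(rare)) != 1:
        return False
    longer, shorter = (frequent, rare) if len(frequent) > len(rare) else (rare, frequent)
    pos = _single_indel_site(longer, shorter)
    if pos is None:
        return False
    base = longer[pos]
    return _run_length_at(frequent, min(pos, len(frequent) - 1), base) >= min_run


def correct_homopolymer_indels(amplicon: AmpliconSet,
                               min_run: int = 3) -> AmpliconSet:
    """Merge variants that differ from a strictly more frequent variant only
    by one single-base indel inside a homopolymer run (length >= min_run in
    the more frequent variant), most-frequent-first, until fixpoint.

    Read counts are conserved: merged counts are added to the absorber.
    """
    counts = {v.seq: v.count for v in amplicon.variants}
    changed = True
    while changed:
        changed = False
        ordered = sorted(counts, key=lambda s: (-counts[s], s))
        for u in ordered:
            if u not in counts:
                continue
            for v in ordered:
                if v == u or v not in counts or u not in counts:
                    continue
                if counts[v] < counts[u] and is_homopolymer_indel(u, v, min_run):
                    counts[u] += counts.pop(v)
                    changed = True
            if changed:
                break
    if not counts:
        return AmpliconSet(amplicon.individual_id, amplicon.exon, (), 0)
    return make_amplicon(amplicon.individual_id, amplicon.exon, counts)


# ---------------------------------------------------------------------------
# reading frame and depth

def frame_filter(amplicon: AmpliconSet, target: ExonTarget) -> AmpliconSet:
    """Keep variants whose length offset from the expected recovered length
    is a multiple of 3 (negative offsets allowed)."""
    expected = target.canonical_length
    counts = {v.seq: v.count for v in amplicon.variants
              if (len(v.seq) - expected) % 3 == 0}
    if not counts:
        return AmpliconSet(amplicon.individual_id, amplicon.exon, (), 0)
    return make_amplicon(amplicon.individual_id, amplicon.exon, counts)


def depth_gate(amplicon: AmpliconSet, stage: str, config: QCConfig) -> bool:
    """Read-depth gate: >= 25 reads on the initial pass, >= 120 on the final
    pass once first-pass genotyping reveals more than two alleles."""
    if stage == "initial":
        return amplicon.total_reads >= config.min_reads_initial
    if stage == "final":
        return amplicon.total_reads >= config.min_reads_final
    raise ValueError(f"unknown depth gate stage {stage!r}")


def coverage_probability(total_reads: int, n_alleles: int,
                         worst_efficiency: float = 0.7,
                         min_reads_per_allele: int = 3) -> float:
    """P(every allele receives >= min_reads_per_allele reads) when reads are
    allocated multinomially with one allele at weight ``worst_efficiency``
    and the remaining ``n_alleles - 1`` at weight 1.

    Exact sequential-binomial dynamic program.  Utility only: depth gating
    uses the literal 25/120 read constants.
    """
    if n_alleles < 1:
        raise ValueError("n_alleles must be >= 1")
    if not 0 < worst_efficiency <= 1:
        raise ValueError("worst_efficiency must lie in (0, 1]")
    r = min_reads_per_allele
    if total_reads < n_alleles * r:
        return 0.0
    if n_alleles == 1:
        return 1.0
    weights = [worst_efficiency] + [1.0] * (n_alleles - 1)
    # dp maps reads-remaining -> probability, constraining each count >= r
    dp = {total_reads: 1.0}
    for i, w in enumerate(weights[:-1]):
        w_rest = sum(weights[i + 1:])
        p = w / (w + w_rest)
        nxt: Dict[int, float] = {}
        reserve = (n_alleles - 1 - i) * r  # reads the remaining alleles need
        for n_rem, prob in dp.items():
            ks = np.arange(r, n_rem - reserve + 1)
            if len(ks) == 0:
                continue
            pmf = binom.pmf(ks, n_rem, p)
            for k, pk in zip(ks, pmf):
                key = n_rem - int(k)
                nxt[key] = nxt.get(key, 0.0) + prob * float(pk)
        dp = nxt
    return float(sum(prob for n_rem, prob in dp.items() if n_rem >= r))


# ---------------------------------------------------------------------------
# per-amplicon QC pipeline

@dataclass
class Funnel:
    """In/out read counts per QC stage for one individual x exon."""

    counts: Dict[str, int] = field(default_factory=dict)

    def record(self, stage: str, n: int) -> None:
        self.counts[stage] = n
        log.info("funnel %s: %d", stage, n)


def qc_amplicon(pairs: Sequence[ReadPair], individual_id: str,
                target: ExonTarget, config: QCConfig) -> Tuple[AmpliconSet, Funnel]:
    """Run the post-demultiplex QC chain for one amplicon's trimmed pairs."""
    funnel = Funnel()
    funnel.record("input_pairs", len(pairs))
    merged: List[Read] = []
    merge_cache: Dict[Tuple[str, str, Tuple[int, ...], Tuple[int, ...]], Optional[Read]] = {}
    for fwd, rev in pairs:
        key = (fwd.seq, rev.seq, fwd.quals, rev.quals)
        if key in merge_cache:
            hit = merge_cache[key]
            if hit is not None:
                merged.append(Read(fwd.id, hit.seq, hit.quals))
            continue
        m = merge_pair(fwd, revcomp_read(rev), config)
        merge_cache[key] = m
        if m is not None:
            merged.append(m)
    funnel.record("merged", len(merged))
    kept = [r for r in merged if length_quality_filter(r, config) is None]
    funnel.record("length_quality", len(kept))
    amplicon = dereplicate(kept, individual_id, target.name)
    funnel.record("dereplicated_nonsingleton", amplicon.total_reads)
    amplicon = correct_homopolymer_indels(amplicon, config.homopolymer_min_run)
    funnel.record("homopolymer_corrected", amplicon.total_reads)
    amplicon = frame_filter(amplicon, target)
    funnel.record("frame_filtered", amplicon.total_reads)
    return amplicon, funnel
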