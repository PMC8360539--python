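"""Ground-truthed amplicon read simulator.

Emulates the artifact processes the genotyping procedure is designed to
defeat: multicopy loci (3 DQ / 5 DRB gene copies per haplotype), diploid
genotypes drawn from a founder haplotype pool, parent-offspring block
transmission, per-allele PCR amplification efficiency skew (lower bound 0.7),
per-base substitution errors, single-base homopolymer indels, two-parent PCR
chimeras, unique singleton noise reads, and optional allelic dropout.

Everything is driven by one ``numpy.random.Generator`` so a seed fixes pools,
pedigree, reads and qualities byte-for-byte.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io import Read, ReadPair
from .targets import (DEFAULT_TARGETS, EXON_NAMES, IUPAC, ExonTarget,
                      PedigreeTriad, SampleMeta, revcomp)

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class GenerationError(RuntimeError):
    """Raised when a pool or population cannot be realized."""


@dataclass
class SimConfig:
    """Simulation parameters.

    Defaults are the study conditions the pipeline is validated under:
    sequencing depth 500 read pairs per amplicon, 0.002/base substitution
    error, 3% chimeric reads, 1%/run homopolymer indels, 0.5% noise
    singletons, no dropout, and per-allele amplification efficiencies drawn
    from [0.7, 1.0] (0.7 being the assumed worst-case average efficiency).
    """

    seed: int = 0
    n_copies_per_haplotype: Dict[str, int] = field(
        default_factory=lambda: {"DRBe2": 5, "DRBe3": 5, "DQAe3": 3, "DQBe3": 3})
    allele_pool_size: int = 12
    pool_divergence: float = 0.05
    n_founder_haplotypes: int = 6
    n_individuals: int = 30
    n_triads: int = 20
    reads_per_amplicon: int = 500
    efficiency_range: Tuple[float, float] = (0.7, 1.0)
    sub_error_rate: float = 0.002
    homopolymer_indel_rate: float = 0.01
    homopolymer_min_run: int = 3
    chimera_rate: float = 0.03
    noise_singleton_rate: float = 0.005
    dropout_rate: float = 0.0
    p_low_quality: float = 0.02
    q_high: int = 37
    q_low: int = 15
    couple_errors_to_quality: bool = False
    species: str = "Cebus simulatus"
    genus: str = "Cebus"
    n_localities: int = 1

    def __post_init__(self):
        for name in ("pool_divergence", "sub_error_rate", "homopolymer_indel_rate",
                     "chimera_rate", "noise_singleton_rate", "dropout_rate",
                     "p_low_quality"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.reads_per_amplicon <= 0:
            raise ValueError("reads_per_amplicon must be > 0")
        lo, hi = self.efficiency_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("efficiency_range must be an interval within (0, 1]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class HaplotypeBlock:
    """The four-exon allele-set unit transmitted from one parent."""

    id: str
    alleles: Tuple[Tuple[str, frozenset], ...]  # ((exon, seqs), ...) sorted

    def exon_alleles(self, exon: str) -> frozenset:
        return dict(self.alleles)[exon]

    @staticmethod
    def make(block_id: str, alleles: Dict[str, frozenset]) -> "HaplotypeBlock":
        if not alleles or any(not s for s in alleles.values()):
            raise ValueError("every exon must carry a non-empty allele set")
        return HaplotypeBlock(block_id, tuple(sorted(
            (e, frozenset(s)) for e, s in alleles.items())))


@dataclass
class SimTruth:
    """Ground truth for a simulated run."""

    blocks: Dict[str, HaplotypeBlock]
    diplotypes: Dict[str, Tuple[str, str]]  # individual -> (block id, block id)
    true_genotypes: Dict[Tuple[str, str], frozenset]  # (individual, exon) -> seqs
    read_provenance: Dict[str, tuple] = field(default_factory=dict)

    def genotype(self, individual: str, exon: str) -> frozenset:
        return self.true_genotypes[(individual, exon)]


# ---------------------------------------------------------------------------
# allele pools

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate_sites(seq: str, rng: np.random.Generator, p: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < p)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def generate_pool(config: SimConfig, exon: str,
                  rng: Optional[np.random.Generator] = None,
                  target: Optional[ExonTarget] = None) -> List[str]:
    """Generate ``allele_pool_size`` distinct allele sequences for one exon.

    Alleles descend from a common ancestral sequence with per-site
    substitution probability ``pool_divergence / 2`` each, so any two pool
    alleles differ per site with probability ~``pool_divergence``.  Lengths
    are drawn from the target's expected recovered lengths; shorter length
    variants delete whole codons at a fixed interior position.
    """
    rng = rng if rng is not None else config.rng()
    target = target or DEFAULT_TARGETS[exon]
    if config.allele_pool_size < config.n_copies_per_haplotype.get(exon, 1):
        raise GenerationError("pool smaller than copies per haplotype")
    lengths = sorted(target.expected_recovered_lengths)
    max_len = lengths[-1]
    ancestor = _random_seq(rng, max_len)
    del_pos = 3 * (max_len // 6)  # codon-aligned interior deletion point
    pool: List[str] = []
    seen = set()
    for _ in range(config.allele_pool_size):
        for _attempt in range(100):
            length = int(rng.choice(lengths))
            seq = ancestor
            if length < max_len:
                seq = seq[:del_pos] + seq[del_pos + (max_len - length):]
            seq = _mutate_sites(seq, rng, config.pool_divergence / 2)
            if seq not in seen:
                seen.add(seq)
                pool.append(seq)
                break
        else:
            raise GenerationError(
                f"could not realize {config.allele_pool_size} distinct alleles "
                f"for {exon} at divergence {config.pool_divergence}")
    return pool


# ---------------------------------------------------------------------------
# population and pedigree

def generate_population(config: SimConfig, pools: Dict[str, List[str]],
                        rng: Optional[np.random.Generator] = None
                        ) -> Tuple[List[SampleMeta], SimTruth, List[PedigreeTriad]]:
    """Draw founder haplotype blocks, assign diplotypes, and breed triads.

    Founders receive two blocks drawn with replacement from the founder block
    pool (homozygotes are possible); each triad offspring receives exactly one
    block from each parent, chosen uniformly.
    """
    rng = rng if rng is not None else config.rng()
    if config.n_founder_haplotypes < 1:
        raise GenerationError("need at least 1 founder haplotype")
    exons = sorted(pools)
    blocks: Dict[str, HaplotypeBlock] = {}
    for b in range(config.n_founder_haplotypes):
        alleles = {}
        for exon in exons:
            k = config.n_copies_per_haplotype.get(exon, 1)
            idx = rng.choice(len(pools[exon]), size=k, replace=False)
            alleles[exon] = frozenset(pools[exon][i] for i in sorted(idx))
        block = HaplotypeBlock.make(f"H{b + 1:02d}", alleles)
        blocks[block.id] = block
    block_ids = sorted(blocks)

    diplotypes: Dict[str, Tuple[str, str]] = {}
    founders = [f"F{i + 1:03d}" for i in range(config.n_individuals)]
    for ind in founders:
        pair = rng.choice(len(block_ids), size=2, replace=True)
        diplotypes[ind] = (block_ids[pair[0]], block_ids[pair[1]])

    parent_pairs = list(itertools.combinations(founders, 2))
    if config.n_triads > len(parent_pairs):
        raise GenerationError(
            f"n_triads={config.n_triads} exceeds available parent pairs "
            f"({len(parent_pairs)})")
    chosen = rng.choice(len(parent_pairs), size=config.n_triads, replace=False)
    triads: List[PedigreeTriad] = []
    for j, pi in enumerate(sorted(int(i) for i in chosen)):
        mother, father = parent_pairs[pi]
        child = f"O{j + 1:03d}"
        mb = diplotypes[mother][int(rng.integers(2))]
        fb = diplotypes[father][int(rng.integers(2))]
        diplotypes[child] = (mb, fb)
        triads.append(PedigreeTriad(child, mother, father))

    true_genotypes = {}
    for ind, (b1, b2) in diplotypes.items():
        for exon in exons:
            true_genotypes[(ind, exon)] = (blocks[b1].exon_alleles(exon)
                                           | blocks[b2].exon_alleles(exon))

    localities = [f"SiteA{i + 1}" for i in range(max(1, config.n_localities))]
    mother_of = {t.offspring_id: t.mother_id for t in triads}
    loc = {}
    for i, ind in enumerate(founders):
        loc[ind] = localities[i % len(localities)]
    metas = []
    for ind in sorted(diplotypes):
        population = loc[ind] if ind in loc else loc[mother_of[ind]]
        metas.append(SampleMeta(ind, config.species, config.genus, population))
    truth = SimTruth(blocks=blocks, diplotypes=diplotypes,
                     true_genotypes=true_genotypes)
    return metas, truth, triads


# ---------------------------------------------------------------------------
# read simulation

def _resolve_iupac(primer: str) -> str:
    """Concrete template-strand realization of a degenerate primer."""
    return "".join(sorted(IUPAC[c])[0] for c in primer)


def _homopolymer_runs(seq: str, min_run: int) -> List[Tuple[int, int, str]]:
    runs = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j + 1 < n and seq[j + 1] == seq[i]:
            j += 1
        if j - i + 1 >= min_run:
            runs.append((i, j - i + 1, seq[i]))
        i = j + 1
    return runs


def _apply_errors(seq: str, rng: np.random.Generator, rate: float
                  ) -> Tuple[str, np.ndarray]:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        arr[i] = rng.choice(_BASES[_BASES != arr[i]])
    return arr.tobytes().decode(), hits


def simulate_amplicon(individual_id: str, exon: str, config: SimConfig,
                      truth: SimTruth, rng: np.random.Generator,
                      target: Optional[ExonTarget] = None,
                      efficiencies: Optional[Sequence[float]] = None
                      ) -> Tuple[List[ReadPair], Dict[str, tuple]]:
    """Emit ``reads_per_amplicon`` read pairs for one individual x exon.

    Templates are chosen proportionally to per-allele efficiency weights
    drawn once per allele per amplicon from ``efficiency_range``; chimeric
    fragments splice two distinct true alleles at a uniform interior
    breakpoint; noise fragments are unique 3-5-substitution mutants.  Each
    fragment yields a fully overlapping pair (forward: primer+template;
    reverse: reverse complement with the reverse primer prepended) so that
    merging reconstructs the template exactly in the absence of errors.
    """
    target = target or DEFAULT_TARGETS[exon]
    alleles = sorted(truth.genotype(individual_id, exon))
    k = len(alleles)
    lo, hi = config.efficiency_range
    if efficiencies is not None:
        weights = np.asarray(efficiencies, dtype=float).copy()
        if len(weights) != k:
            raise ValueError("one efficiency per true allele required")
    else:
        weights = rng.uniform(lo, hi, size=k)
    dropped = rng.random(k) < config.dropout_rate
    weights[dropped] = 0.0
    if weights.sum() == 0:
        weights = np.ones(k)
    probs = weights / weights.sum()

    fp = _resolve_iupac(target.fwd_primer)
    rp = _resolve_iupac(target.rev_primer)
    run_cache: Dict[str, List[Tuple[int, int, str]]] = {}
    noise_seen = set(alleles)
    pairs: List[ReadPair] = []
    provenance: Dict[str, tuple] = {}

    for i in range(config.reads_per_amplicon):
        read_id = f"{individual_id}|{exon}|{i:05d}"
        u = rng.random()
        if u < config.noise_singleton_rate:
            src = alleles[int(rng.integers(k))]
            for _ in range(50):
                nsub = int(rng.integers(3, 6))
                pos = rng.choice(len(src), size=nsub, replace=False)
                arr = np.frombuffer(src.encode(), dtype=np.uint8).copy()
                for p in pos:
                    arr[p] = rng.choice(_BASES[_BASES != arr[p]])
                template = arr.tobytes().decode()
                if template not in noise_seen:
                    break
            noise_seen.add(template)
            prov = ("noise", template)
        elif u < config.noise_singleton_rate + config.chimera_rate and k >= 2:
            a, b = rng.choice(k, size=2, replace=False)
            sa, sb = alleles[a], alleles[b]
            p = int(rng.integers(1, min(len(sa), len(sb))))
            template = sa[:p] + sb[p:]
            prov = ("chimera", sa, sb, p)
        else:
            if u < config.noise_singleton_rate + config.chimera_rate and k < 2:
                log.debug("chimera requested with <2 alleles; emitting allele read")
            src = alleles[int(rng.choice(k, p=probs))]
            template = src
            prov = ("allele", src)

        # fragment-level homopolymer indels (one gained/lost base per run)
        if config.homopolymer_indel_rate > 0:
            if template not in run_cache:
                run_cache[template] = _homopolymer_runs(
                    template, config.homopolymer_min_run)
            runs = run_cache[template]
            if runs:
                events = np.nonzero(rng.random(len(runs))
                                    < config.homopolymer_indel_rate)[0]
                for ri in reversed(events):
                    start, length, base = runs[ri]
                    if rng.random() < 0.5:
                        template = template[:start] + base + template[start:]
                    else:
                        template = template[:start] + template[start + 1:]

        fwd_seq = fp + template
        rev_seq = rp + revcomp(template)
        fwd_seq, fwd_err = _apply_errors(fwd_seq, rng, config.sub_error_rate)
        rev_seq, rev_err = _apply_errors(rev_seq, rng, config.sub_error_rate)
        mates = []
        for seq, err in ((fwd_seq, fwd_err), (rev_seq, rev_err)):
            quals = np.where(rng.random(len(seq)) < config.p_low_quality,
                             config.q_low, config.q_high)
            if config.couple_errors_to_quality and len(err):
                quals[err] = config.q_low
            mates.append(Read(read_id, seq, tuple(quals.tolist())))
        pairs.append((mates[0], mates[1]))
        provenance[read_id] = prov
    return pairs, provenance


def simulate_individual(individual_id: str, config: SimConfig, truth: SimTruth,
                        rng: np.random.Generator,
                        targets: Optional[Dict[str, ExonTarget]] = None
                        ) -> Tuple[List[ReadPair], Dict[str, tuple]]:
    """All four exon amplicons for one individual, concatenated."""
    targets = targets or DEFAULT_TARGETS
    pairs: List[ReadPair] = []
    prov: Dict[str, tuple] = {}
    for exon in sorted(targets):
        p, pr = simulate_amplicon(individual_id, exon, config, truth, rng,
                                  targets[exon])
        pairs.extend(p)
        prov.update(pr)
    truth.read_provenance.update(prov)
    return pairs, prov


def simulate_study(config: SimConfig,
                   targets: Optional[Dict[str, ExonTarget]] = None
                   ) -> Tuple[List[SampleMeta], SimTruth, List[PedigreeTriad],
                              Dict[str, List[ReadPair]]]:
    """Full study: pools, population, pedigree and reads for every individual.

    Returns (sample metadata, truth, triads, reads keyed by individual id).
    """
    targets = targets or DEFAULT_TARGETS
    rng = config.rng()
    pools = {exon: generate_pool(config, exon, rng, targets[exon])
             for exon in sorted(targets)}
    metas, truth, triads = generate_population(config, pools, rng)
    reads = {}
    for meta in metas:
        pairs, _ = simulate_individual(meta.individual_id, config, truth, rng,
                                       targets)
        reads[meta.individual_id] = pairs
    return metas, truth, triads, reads
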