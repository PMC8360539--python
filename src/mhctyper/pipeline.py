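"""End-to-end orchestration: reads -> QC -> allele calls -> genotypes.

Works either from FASTQ files listed in a sample sheet or from in-memory read
pairs (as produced by the simulator), one library at a time so memory stays
proportional to a single individual's reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from . import io as mio
from .calling import AlleleCall, CallingConfig, CallingResult, call_population
from .qc import AmpliconSet, Funnel, QCConfig, demultiplex, depth_gate, qc_amplicon
from .targets import DEFAULT_TARGETS, ExonTarget, SampleMeta

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    amplicons: List[AmpliconSet]
    calling: CallingResult
    funnel: Dict[Tuple[str, str], Dict[str, int]]  # (library, exon) -> stage counts
    depth_failures: List[Tuple[str, str]] = field(default_factory=list)

    @property
    def genotypes(self) -> Dict[str, Dict[str, FrozenSet[str]]]:
        return self.calling.genotypes

    def genotype_rows(self) -> List[mio.GenotypeRow]:
        rows = []
        for c in self.calling.calls:
            ind, exon = c.individual_id, c.exon
            if c.status == "allele" and exon in self.genotypes.get(ind, {}) \
                    and c.seq in self.genotypes[ind][exon]:
                rows.append(mio.GenotypeRow(ind, exon, c.seq, c.within_rf,
                                            "allele"))
        return rows


def qc_library(pairs, library_id: str, targets: Dict[str, ExonTarget],
               qc_config: QCConfig) -> Tuple[List[AmpliconSet],
                                             Dict[Tuple[str, str], Dict[str, int]],
                                             List[Tuple[str, str]]]:
    """Demultiplex one library's read pairs and QC each exon's amplicon."""
    assigned, discards = demultiplex(pairs, targets, qc_config)
    log.info("%s: %d pairs demultiplexed, %d discarded",
             library_id, sum(len(v) for v in assigned.values()), len(discards))
    amplicons, funnels, failures = [], {}, []
    for exon in sorted(targets):
        amp, funnel = qc_amplicon(assigned[exon], library_id, targets[exon],
                                  qc_config)
        funnel.record("demultiplexed", len(assigned[exon]))
        funnels[(library_id, exon)] = funnel.counts
        if not depth_gate(amp, "initial", qc_config):
            failures.append((library_id, exon))
            continue
        amplicons.append(amp)
    return amplicons, funnels, failures


def run_pipeline(reads_by_library: Dict[str, Sequence],
                 species_of: Dict[str, str],
                 targets: Optional[Dict[str, ExonTarget]] = None,
                 qc_config: Optional[QCConfig] = None,
                 calling_config: Optional[CallingConfig] = None) -> PipelineResult:
    """Full pipeline over in-memory read pairs keyed by library id."""
    targets = targets or DEFAULT_TARGETS
    qc_config = qc_config or QCConfig()
    calling_config = calling_config or CallingConfig()
    amplicons: List[AmpliconSet] = []
    funnel: Dict[Tuple[str, str], Dict[str, int]] = {}
    depth_failures: List[Tuple[str, str]] = []
    for library_id in sorted(reads_by_library):
        amps, fns, fails = qc_library(reads_by_library[library_id], library_id,
                                      targets, qc_config)
        amplicons.extend(amps)
        funnel.update(fns)
        depth_failures.extend(fails)
    calling = call_population(amplicons, species_of, calling_config,
                              min_reads_final=qc_config.min_reads_final)
    return PipelineResult(amplicons, calling, funnel, depth_failures)


def run_from_sample_sheet(sheet_path, targets=None, qc_config=None,
                          calling_config=None) -> PipelineResult:
    """Run the pipeline from a sample sheet pointing at paired FASTQ files.

    Replicate libraries are genotyped independently under the key
    ``individual_id#replicate_id``.
    """
    metas = mio.read_sample_sheet(sheet_path)
    targets = targets or DEFAULT_TARGETS
    qc_config = qc_config or QCConfig()
    calling_config = calling_config or CallingConfig()
    amplicons: List[AmpliconSet] = []
    funnel: Dict[Tuple[str, str], Dict[str, int]] = {}
    depth_failures: List[Tuple[str, str]] = []
    species_of: Dict[str, str] = {}
    for meta in metas:
        library_id = meta.individual_id + (
            f"#{meta.replicate_id}" if meta.replicate_id else "")
        species_of[library_id] = meta.species
        pairs = mio.read_fastq_pairs(meta.fastq_fwd, meta.fastq_rev)
        amps, fns, fails = qc_library(pairs, library_id, targets, qc_config)
        amplicons.extend(amps)
        funnel.update(fns)
        depth_failures.extend(fails)
    calling = call_population(amplicons, species_of, calling_config,
                              min_reads_final=qc_config.min_reads_final)
    return PipelineResult(amplicons, calling, funnel, depth_failures)


def recovery_rate(result: PipelineResult, truth,
                  individuals: Sequence[str],
                  exons: Sequence[str]) -> Tuple[float, int, int]:
    """Fraction of individual x exon amplicons whose called allele set equals
    the simulator's true set.  Returns (fraction, n_exact, n_total)."""
    n_total = n_exact = 0
    for ind in individuals:
        for exon in exons:
            n_total += 1
            called = result.genotypes.get(ind, {}).get(exon)
            if called is not None and called == truth.genotype(ind, exon):
                n_exact += 1
    return (n_exact / n_total if n_total else 0.0), n_exact, n_total
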