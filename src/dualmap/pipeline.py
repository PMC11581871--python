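"""End-to-end orchestration of the read-separation benchmark.

One call simulates a genome pair and a merged dual RNA-seq library, runs the
sequential strategy in both orders plus the combined strategy, labels every
read against the encoded truth, computes the four separation metrics per
organism and run, and performs the one-side / two-side cross-mapping analysis
(including the relaxed remapping of one-side reads).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from . import crossmap_analysis as cx
from .aligner import HitSet, MapperParams, SeedIndex, build_index
from .evaluation import (AssignmentLabel, MetricSet, confusion_counts,
                         compute_metrics, label_assignments)
from .report import RunRow, flow_table, tabulate_run
from .strategy import (AssignmentOutcome, Order, Strategy, assign_combined,
                       assign_sequential, build_concat_index, concat_genomes)
from .synthetic_data import (GenomePair, GenomePairSpec, HOST, LibrarySpec,
                             PARASITE, ReadPairRecord, generate_genome_pair,
                             merge_libraries, simulate_library, truth_map)

logger = logging.getLogger(__name__)


@dataclass
class RunResult:
    """One (strategy, order) run: outcomes, labels, metrics, table row."""

    strategy: Strategy
    order: Order
    outcomes: list[AssignmentOutcome]
    labels: list[AssignmentLabel]
    metrics: dict[str, MetricSet]
    row: RunRow
    hits: dict[str, HitSet]


@dataclass
class PipelineResult:
    pair: GenomePair
    merged: list[ReadPairRecord]
    truth: dict[str, str]
    runs: dict[tuple[Strategy, Order], RunResult]
    crossmap: cx.CrossMapReport

    def run(self, strategy: Strategy, order: Order = Order.NA) -> RunResult:
        return self.runs[(strategy, order)]


def run_pipeline(genome_spec: GenomePairSpec,
                 host_lib_spec: LibrarySpec,
                 parasite_lib_spec: LibrarySpec,
                 params: MapperParams,
                 seed: int = 0,
                 relaxed_max_mismatch: int = 10,
                 interaction: str = "synthetic",
                 replicate: str = "1") -> PipelineResult:
    """Simulate, separate, evaluate and analyze cross-mapping in one pass.

    ``seed`` drives the library merge shuffle; the genome and library specs
    carry their own seeds so the same genomes can be reused across replicates.
    """
    pair = generate_genome_pair(genome_spec)
    host_lib = simulate_library(pair.host, pair.annotations_host,
                                host_lib_spec, HOST)
    parasite_lib = simulate_library(pair.parasite, pair.annotations_parasite,
                                    parasite_lib_spec, PARASITE)
    merged = merge_libraries(host_lib, parasite_lib, seed=seed)
    truth = truth_map(merged)
    logger.info("merged library: %d host + %d parasite = %d read pairs",
                len(host_lib), len(parasite_lib), len(merged))

    host_index = build_index(pair.host, params.k, tag=HOST)
    parasite_index = build_index(pair.parasite, params.k, tag=PARASITE)
    concat_index = build_concat_index(concat_genomes(pair.host, pair.parasite),
                                      params.k)

    runs: dict[tuple[Strategy, Order], RunResult] = {}

    def add_run(strategy: Strategy, order: Order,
                outcomes: list[AssignmentOutcome], hits: dict[str, HitSet]):
        labels = label_assignments(outcomes, truth)
        metrics = {org: compute_metrics(confusion_counts(labels, org))
                   for org in (HOST, PARASITE)}
        row = tabulate_run(outcomes, interaction=interaction, replicate=replicate)
        runs[(strategy, order)] = RunResult(strategy=strategy, order=order,
                                            outcomes=outcomes, labels=labels,
                                            metrics=metrics, row=row, hits=hits)
        logger.info("%s/%s: %s", strategy.value, order.value, row)

    hits_hf: dict[str, HitSet] = {}
    add_run(Strategy.SEQUENTIAL, Order.HOST_FIRST,
            assign_sequential(merged, host_index, parasite_index, params,
                              Order.HOST_FIRST, collect_hits=hits_hf), hits_hf)
    hits_pf: dict[str, HitSet] = {}
    add_run(Strategy.SEQUENTIAL, Order.PARASITE_FIRST,
            assign_sequential(merged, parasite_index, host_index, params,
                              Order.PARASITE_FIRST, collect_hits=hits_pf), hits_pf)
    hits_com: dict[str, HitSet] = {}
    add_run(Strategy.COMBINED, Order.NA,
            assign_combined(merged, concat_index, params, collect_hits=hits_com),
            hits_com)

    crossmap = _analyze_crossmapping(
        pair, merged, truth, runs, host_index, parasite_index,
        params.relaxed(relaxed_max_mismatch), interaction)

    return PipelineResult(pair=pair, merged=merged, truth=truth, runs=runs,
                          crossmap=crossmap)


def _analyze_crossmapping(pair, merged, truth, runs, host_index, parasite_index,
                          relaxed_params, interaction) -> cx.CrossMapReport:
    by_id = {r.read_id: r for r in merged}
    labels_hf = runs[(Strategy.SEQUENTIAL, Order.HOST_FIRST)].labels
    labels_pf = runs[(Strategy.SEQUENTIAL, Order.PARASITE_FIRST)].labels
    combined_run = runs[(Strategy.COMBINED, Order.NA)]

    one_host, one_para = cx.extract_one_side(
        Strategy.SEQUENTIAL, labels_host_first=labels_hf,
        labels_parasite_first=labels_pf)
    rate_host = cx.relaxed_remap([by_id[i] for i in sorted(one_host)],
                                 host_index, relaxed_params)
    rate_para = cx.relaxed_remap([by_id[i] for i in sorted(one_para)],
                                 parasite_index, relaxed_params)

    two_host, two_para = cx.intersect_two_side_sequential(labels_hf, labels_pf)

    # locus summaries use the combined run's hits over the concatenated genome,
    # restricted to the organism's own annotation (namespaced chromosomes)
    ns_host_ann = [replace_chrom(g, f"{HOST}::{g.chromosome}")
                   for g in pair.annotations_host]
    ns_para_ann = [replace_chrom(g, f"{PARASITE}::{g.chromosome}")
                   for g in pair.annotations_parasite]
    com_two_host, com_two_para = cx.two_side_roster_combined(
        combined_run.outcomes, truth)
    locus_host = cx.summarize_loci(com_two_host, combined_run.hits, ns_host_ann)
    locus_para = cx.summarize_loci(com_two_para, combined_run.hits, ns_para_ann)

    return cx.CrossMapReport(
        interaction=interaction, strategy=Strategy.SEQUENTIAL,
        one_side_host=one_host, one_side_parasite=one_para,
        one_side_remap_rate_host=rate_host,
        one_side_remap_rate_parasite=rate_para,
        two_side_host=two_host, two_side_parasite=two_para,
        locus_counts_host=locus_host, locus_counts_parasite=locus_para)


def replace_chrom(gene, chromosome: str):
    return replace(gene, chromosome=chromosome)
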