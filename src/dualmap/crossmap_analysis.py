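"""One-side and two-side cross-mapped read analysis.

One-side cross-mapped reads originate in organism X but map only to organism
Y's genome — typically a symptom of incompleteness of X's assembly.  They are
pulled out of the label sets and remapped to their own genome under relaxed
filters (mismatch cap 10 instead of 5); the recovered fraction separates
"too-stringent filters" from "locus genuinely absent".

Two-side cross-mapped reads map validly in both genomes (conserved,
insufficiently diverged loci).  In the sequential design they are found by
intersecting the step-1 label sets of the two run orders; in the combined
design they fall out of a single run as the TWO_SIDE category.  Their loci
are summarized per gene with union-mode feature counting and the ``product``
annotation attribute is carried along.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

from .aligner import HitSet, MapperParams, SeedIndex, find_hits
from .errors import ConfigurationError, DataError
from .evaluation import AssignmentLabel
from .strategy import AssignmentOutcome, Category, Strategy
from .synthetic_data import GeneModel, HOST, PARASITE, ReadPairRecord

NO_FEATURE = "no_feature"
AMBIGUOUS = "ambiguous"


@dataclass
class CrossMapReport:
    """Everything the cross-mapping analysis produces for one run set."""

    interaction: str
    strategy: Strategy
    one_side_host: set[str] = field(default_factory=set)
    one_side_parasite: set[str] = field(default_factory=set)
    one_side_remap_rate_host: float | None = None
    one_side_remap_rate_parasite: float | None = None
    two_side_host: set[str] = field(default_factory=set)
    two_side_parasite: set[str] = field(default_factory=set)
    locus_counts_host: list[tuple[str, str, int]] = field(default_factory=list)
    locus_counts_parasite: list[tuple[str, str, int]] = field(default_factory=list)


def _ids_with(labels: list[AssignmentLabel], side: str, name: str) -> set[str]:
    attr = "host_label" if side == HOST else "parasite_label"
    return {lab.read_id for lab in labels if getattr(lab, attr) == name}


def extract_one_side(strategy: Strategy,
                     labels_host_first: list[AssignmentLabel] | None = None,
                     labels_parasite_first: list[AssignmentLabel] | None = None,
                     labels_combined: list[AssignmentLabel] | None = None,
                     two_side_ids: set[str] | None = None
                     ) -> tuple[set[str], set[str]]:
    """Read-id sets of one-side cross-mapped reads, (host set, parasite set).

    Sequential: host set = reads labeled ``S-FN_h2`` in the host-first run
    (host reads that failed on the host genome but mapped to the parasite in
    step 2); parasite set = ``S-FN_p2`` in the parasite-first run.  Combined:
    the ``C-FN_h``/``C-FN_p`` sets (total cross-mapped) minus the TWO_SIDE
    roster, leaving only reads that hit the wrong genome exclusively.
    """
    if strategy == Strategy.SEQUENTIAL:
        if labels_host_first is None:
            raise ConfigurationError("sequential extraction needs the "
                                     "host-first run labels")
        if labels_parasite_first is None:
            raise ConfigurationError("sequential extraction needs the "
                                     "parasite-first run labels")
        host_set = _ids_with(labels_host_first, HOST, "S-FN_h2")
        parasite_set = _ids_with(labels_parasite_first, PARASITE, "S-FN_p2")
        return host_set, parasite_set
    if labels_combined is None:
        raise ConfigurationError("combined extraction needs the combined run labels")
    if two_side_ids is None:
        raise ConfigurationError("combined extraction needs the TWO_SIDE roster")
    host_set = _ids_with(labels_combined, HOST, "C-FN_h") - two_side_ids
    parasite_set = _ids_with(labels_combined, PARASITE, "C-FN_p") - two_side_ids
    return host_set, parasite_set


def relaxed_remap(one_side_reads: list[ReadPairRecord], own_genome_index: SeedIndex,
                  relaxed_params: MapperParams,
                  strict_params: MapperParams | None = None) -> float | None:
    """Fraction of one-side cross-mapped reads that map to their own genome
    under relaxed filters; ``None`` (missing) for an empty input set."""
    if strict_params is not None and (
            relaxed_params.max_mismatch < strict_params.max_mismatch):
        raise ConfigurationError(
            "relaxed max_mismatch must be >= the strict max_mismatch")
    if not one_side_reads:
        return None
    n_recovered = sum(
        1 for pair in one_side_reads
        if find_hits(pair, own_genome_index, relaxed_params).is_mapped)
    return n_recovered / len(one_side_reads)


def two_side_roster_combined(outcomes: list[AssignmentOutcome],
                             truth: dict[str, str]
                             ) -> tuple[set[str], set[str]]:
    """TWO_SIDE reads of a combined run, split by true origin."""
    host_set, parasite_set = set(), set()
    for o in outcomes:
        if o.category == Category.TWO_SIDE:
            (host_set if truth[o.read_id] == HOST else parasite_set).add(o.read_id)
    return host_set, parasite_set


def intersect_two_side_sequential(labels_host_first: list[AssignmentLabel],
                                  labels_parasite_first: list[AssignmentLabel]
                                  ) -> tuple[set[str], set[str]]:
    """Two-side cross-mapped reads from the two sequential run orders.

    A host read that maps validly in both genomes is captured in step 1 of
    *both* orders: correctly (``S-TP_h1``) host-first and wrongly
    (``S-FN_h1``) parasite-first — the intersection is exactly the two-side
    set.  Parasite reads symmetrically.
    """
    universe_hf = {lab.read_id for lab in labels_host_first}
    universe_pf = {lab.read_id for lab in labels_parasite_first}
    if universe_hf != universe_pf:
        raise DataError("the two run orders label different read universes")
    host_set = (_ids_with(labels_host_first, HOST, "S-TP_h1")
                & _ids_with(labels_parasite_first, HOST, "S-FN_h1"))
    parasite_set = (_ids_with(labels_parasite_first, PARASITE, "S-TP_p1")
                    & _ids_with(labels_host_first, PARASITE, "S-FN_p1"))
    return host_set, parasite_set


class _GeneLocator:
    """Interval lookup over non-overlapping gene models, per chromosome."""

    def __init__(self, annotations: list[GeneModel]):
        self.by_chrom: dict[str, tuple[list[int], list[GeneModel]]] = {}
        per_chrom: dict[str, list[GeneModel]] = {}
        for gene in annotations:
            per_chrom.setdefault(gene.chromosome, []).append(gene)
        for chrom, genes in per_chrom.items():
            genes.sort(key=lambda g: g.start)
            self.by_chrom[chrom] = ([g.start for g in genes], genes)

    def overlapping(self, chrom: str, start0: int, end0: int) -> set[str]:
        """Gene ids overlapping the 0-based half-open interval [start0, end0)."""
        if chrom not in self.by_chrom:
            return set()
        starts, genes = self.by_chrom[chrom]
        lo1, hi1 = start0 + 1, end0  # 1-based inclusive query
        out = set()
        # rightmost gene starting at or before the query end, then walk left
        # until genes end before the query start (genes are non-overlapping)
        i = bisect_right(starts, hi1) - 1
        while i >= 0:
            g = genes[i]
            if g.end < lo1:
                break
            out.add(g.gene_id)
            i -= 1
        return out


def summarize_loci(read_set: set[str], hit_source: dict[str, HitSet],
                   annotations: list[GeneModel],
                   chromosomes: set[str] | None = None
                   ) -> list[tuple[str, str, int]]:
    """Union-mode per-gene counts for a read set (htseq-count defaults).

    For each read pair the gene sets overlapped by every retained hit (both
    mates) are unioned: exactly one gene -> counted for it; none ->
    ``no_feature``; more than one (within a locus or across multimapped
    loci) -> ``ambiguous``.  The returned counts partition the read set.
    """
    locator = _GeneLocator(annotations)
    known_chroms = chromosomes if chromosomes is not None else None
    products = {g.gene_id: g.product for g in annotations}
    counts: dict[str, int] = {}
    for read_id in sorted(read_set):
        hs = hit_source.get(read_id)
        if hs is None:
            raise DataError(f"no hits supplied for read {read_id!r}")
        genes: set[str] = set()
        for hit in hs.hits:
            if known_chroms is not None and hit.chromosome not in known_chroms:
                raise DataError(
                    f"hit chromosome {hit.chromosome!r} absent from annotation "
                    "genome")
            genes |= locator.overlapping(hit.chromosome, hit.start,
                                         hit.start + hs.mate1_len)
            genes |= locator.overlapping(hit.chromosome, hit.mate2_start,
                                         hit.mate2_start + hs.mate2_len)
        if not genes:
            key = NO_FEATURE
        elif len(genes) == 1:
            key = genes.pop()
        else:
            key = AMBIGUOUS
        counts[key] = counts.get(key, 0) + 1
    return [(gid, products.get(gid, ""), n)
            for gid, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
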