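"""Sequential and combined read-assignment strategies over a merged library.

*Sequential*: map the merged reads to the first genome; only the reads that
fail there (no qualifying locus, or over the multimap cap) are forwarded to
the second genome.  A read captured in step 1 never consults the second
genome — this greedy order is exactly what produces the order-dependent
cross-mapping the label taxonomy quantifies.  Both orders are supported.

*Combined*: map each read once against a single concatenated genome holding
both references (chromosomes namespaced ``host::``/``parasite::``).  The
multimap cap then applies to the *total* locus count across both genomes, as
a single aligner invocation on a concatenated reference would; retained hits
falling on both sides make the read TWO_SIDE (two-side cross-mapped).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .aligner import HitSet, MapperParams, SeedIndex, Status, build_index, find_hits
from .errors import ConfigurationError, DataError
from .synthetic_data import HOST, PARASITE, ReadPairRecord

NAMESPACE_SEP = "::"


class Strategy(str, Enum):
    SEQUENTIAL = "SEQUENTIAL"
    COMBINED = "COMBINED"


class Order(str, Enum):
    HOST_FIRST = "HOST_FIRST"
    PARASITE_FIRST = "PARASITE_FIRST"
    NA = "NA"


class Category(str, Enum):
    UNIQUE_HOST = "UNIQUE_HOST"
    MULTI_HOST = "MULTI_HOST"
    UNIQUE_PARASITE = "UNIQUE_PARASITE"
    MULTI_PARASITE = "MULTI_PARASITE"
    TWO_SIDE = "TWO_SIDE"
    UNMAPPED = "UNMAPPED"


#: categories meaning "assigned to this organism"
HOST_CATEGORIES = {Category.UNIQUE_HOST, Category.MULTI_HOST}
PARASITE_CATEGORIES = {Category.UNIQUE_PARASITE, Category.MULTI_PARASITE}


@dataclass(frozen=True)
class AssignmentOutcome:
    read_id: str
    strategy: Strategy
    order: Order
    category: Category
    hits_host: int
    hits_parasite: int

    @property
    def assigned_organism(self) -> str | None:
        if self.category in HOST_CATEGORIES:
            return HOST
        if self.category in PARASITE_CATEGORIES:
            return PARASITE
        return None


@dataclass
class ConcatenatedGenome:
    """Both genomes under one roof, with disjoint namespaced chromosome names."""

    sequences: dict[str, str]

    @staticmethod
    def tag_of(chromosome: str) -> str:
        tag = chromosome.split(NAMESPACE_SEP, 1)[0]
        if tag not in (HOST, PARASITE):
            raise DataError(f"chromosome {chromosome!r} carries no genome namespace")
        return tag


def concat_genomes(host_genome: dict[str, str],
                   parasite_genome: dict[str, str]) -> ConcatenatedGenome:
    """Prefix every chromosome with ``host::`` / ``parasite::`` (sequences
    unchanged); the prefix rule is exactly inverted by ``tag_of``."""
    sequences: dict[str, str] = {}
    for chrom, seq in host_genome.items():
        sequences[f"{HOST}{NAMESPACE_SEP}{chrom}"] = seq
    for chrom, seq in parasite_genome.items():
        sequences[f"{PARASITE}{NAMESPACE_SEP}{chrom}"] = seq
    return ConcatenatedGenome(sequences=sequences)


def build_concat_index(concat: ConcatenatedGenome, k: int) -> SeedIndex:
    return build_index(concat.sequences, k, tag_of=ConcatenatedGenome.tag_of)


def _category_for(status: Status, organism: str) -> Category:
    unique = Category.UNIQUE_HOST if organism == HOST else Category.UNIQUE_PARASITE
    multi = Category.MULTI_HOST if organism == HOST else Category.MULTI_PARASITE
    return unique if status == Status.UNIQUE else multi


def assign_sequential(merged_reads: list[ReadPairRecord],
                      first_index: SeedIndex, second_index: SeedIndex,
                      params: MapperParams, order: Order,
                      collect_hits: dict[str, HitSet] | None = None
                      ) -> list[AssignmentOutcome]:
    """Greedy two-step assignment.  ``first_index``/``second_index`` must carry
    genome tags consistent with ``order``; step-1-captured reads never consult
    the second genome.  ``collect_hits`` optionally receives the HitSet of the
    genome each read was finally assigned to (for locus summarization)."""
    if order == Order.HOST_FIRST:
        expected = (HOST, PARASITE)
    elif order == Order.PARASITE_FIRST:
        expected = (PARASITE, HOST)
    else:
        raise ConfigurationError("sequential assignment needs HOST_FIRST or "
                                 "PARASITE_FIRST")
    if (first_index.tag, second_index.tag) != expected:
        raise ConfigurationError(
            f"order {order.value} inconsistent with index tags "
            f"({first_index.tag!r}, {second_index.tag!r})")

    outcomes: list[AssignmentOutcome] = []
    for pair in merged_reads:
        hs1 = find_hits(pair, first_index, params)
        if hs1.is_mapped:
            org = expected[0]
            n = len(hs1.hits)
            outcomes.append(AssignmentOutcome(
                read_id=pair.read_id, strategy=Strategy.SEQUENTIAL, order=order,
                category=_category_for(hs1.status, org),
                hits_host=n if org == HOST else 0,
                hits_parasite=n if org == PARASITE else 0))
            if collect_hits is not None:
                collect_hits[pair.read_id] = hs1
            continue
        hs2 = find_hits(pair, second_index, params)
        if hs2.is_mapped:
            org = expected[1]
            n = len(hs2.hits)
            outcomes.append(AssignmentOutcome(
                read_id=pair.read_id, strategy=Strategy.SEQUENTIAL, order=order,
                category=_category_for(hs2.status, org),
                hits_host=n if org == HOST else 0,
                hits_parasite=n if org == PARASITE else 0))
            if collect_hits is not None:
                collect_hits[pair.read_id] = hs2
        else:
            outcomes.append(AssignmentOutcome(
                read_id=pair.read_id, strategy=Strategy.SEQUENTIAL, order=order,
                category=Category.UNMAPPED, hits_host=0, hits_parasite=0))
    return outcomes


def assign_combined(merged_reads: list[ReadPairRecord], concat_index: SeedIndex,
                    params: MapperParams,
                    collect_hits: dict[str, HitSet] | None = None
                    ) -> list[AssignmentOutcome]:
    """Single competitive mapping pass over the concatenated genome.

    The multimap cap applies to the total hit count; retained hits are then
    partitioned by genome: all-host or all-parasite reads get the usual
    unique/multi categories, hits on both sides make the read TWO_SIDE, and
    none (or over the cap) leaves it UNMAPPED.
    """
    outcomes: list[AssignmentOutcome] = []
    for pair in merged_reads:
        hs = find_hits(pair, concat_index, params)
        if collect_hits is not None:
            collect_hits[pair.read_id] = hs
        n_host = sum(1 for h in hs.hits if h.genome_tag == HOST)
        n_para = len(hs.hits) - n_host
        if not hs.is_mapped:
            category = Category.UNMAPPED
        elif n_host and n_para:
            category = Category.TWO_SIDE
        elif n_host:
            category = Category.UNIQUE_HOST if n_host == 1 else Category.MULTI_HOST
        else:
            category = (Category.UNIQUE_PARASITE if n_para == 1
                        else Category.MULTI_PARASITE)
        outcomes.append(AssignmentOutcome(
            read_id=pair.read_id, strategy=Strategy.COMBINED, order=Order.NA,
            category=category, hits_host=n_host, hits_parasite=n_para))
    return outcomes
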