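"""Deterministic paired-end read mapping with multimap and mismatch caps.

The mapper reproduces the two filters that matter for cross-mapping accounting
in a splice-free setting: a cap on the number of reported loci per read pair
(``max_multimap``, default 10) and a cap on the total number of mismatches per
pair (``max_mismatch``, default 5; relaxed remapping uses 10).  Alignment is
contiguous and Hamming-based: candidate loci are generated from exact k-mer
anchors of either mate (on both strands) and verified by direct comparison, so
with error-free reads every true placement carries a clean anchor and the hit
set equals exhaustive enumeration.  No "best hit" selection exists anywhere:
all qualifying placements are retained up to the cap.

A valid placement puts both mates in FR orientation on one chromosome with an
outer fragment span within ``[insert_min, insert_max]``.  A locus is a
distinct mate-1 placement (chromosome, position): fragment-length variants and
the two strand readings of a palindromic pair at one position collapse to a
single locus, keeping the locus count interpretable against the multimap cap.

Read-pair status follows the usual aligner report columns: UNIQUE (one locus),
MULTI (2..cap loci), UNMAPPED (none — including pairs where only one mate has
any qualifying placement, which are discarded whole), TOO_MANY (over the cap;
the hit list is emptied and the pair is counted as unmapped downstream).
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pysam
from Bio.Seq import reverse_complement
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, DataError

HOST = "host"
PARASITE = "parasite"


class Status(str, Enum):
    UNMAPPED = "UNMAPPED"
    UNIQUE = "UNIQUE"
    MULTI = "MULTI"
    TOO_MANY = "TOO_MANY"


@dataclass(frozen=True)
class MapperParams:
    """Mapping filters; ``max_multimap``/``max_mismatch`` mirror the aligner
    options -outFilterMultimapNmax / -outFilterMismatchNmax."""

    k: int = 15
    max_multimap: int = 10
    max_mismatch: int = 5
    insert_min: int = 100
    insert_max: int = 600

    def validate(self) -> None:
        if self.k < 8:
            raise ConfigurationError(f"k must be >= 8, got {self.k}")
        if self.max_multimap < 1:
            raise ConfigurationError("max_multimap must be >= 1")
        if self.max_mismatch < 0:
            raise ConfigurationError("max_mismatch must be >= 0")
        if self.insert_min > self.insert_max:
            raise ConfigurationError("insert_min must be <= insert_max")

    def relaxed(self, max_mismatch: int = 10) -> "MapperParams":
        if max_mismatch < self.max_mismatch:
            raise ConfigurationError(
                "relaxed max_mismatch must be >= the strict value")
        return MapperParams(k=self.k, max_multimap=self.max_multimap,
                            max_mismatch=max_mismatch,
                            insert_min=self.insert_min, insert_max=self.insert_max)


@dataclass(frozen=True)
class AlignmentHit:
    """One retained placement of a read pair. ``start`` is the 0-based genome
    position of mate 1; ``mate2_start`` that of mate 2."""

    genome_tag: str | None
    chromosome: str
    start: int
    strand: str
    mismatches_pair: int
    mate2_start: int


@dataclass
class HitSet:
    read_id: str
    hits: list[AlignmentHit]
    status: Status
    mate1_len: int = 0
    mate2_len: int = 0

    @property
    def is_mapped(self) -> bool:
        return self.status in (Status.UNIQUE, Status.MULTI)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class SeedIndex:
    """Exact k-mer -> position table over a genome (forward strand stored;
    minus-strand occurrences are served by looking up the reverse complement)."""

    def __init__(self, genome: dict[str, str], k: int, tag: str | None = None,
                 tag_of=None):
        if k < 8:
            raise ConfigurationError(f"k must be >= 8, got {k}")
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise DataError("cannot index an empty genome")
        for chrom, seq in genome.items():
            bad = next((i for i, b in enumerate(seq) if b not in "ACGT"), None)
            if bad is not None:
                raise DataError(
                    f"non-ACGT character {seq[bad]!r} in {chrom} at position {bad}")
        self.k = k
        self.genome = dict(genome)
        self.tag = tag
        self._tag_of = tag_of
        self.arrays = {c: _encode(s) for c, s in genome.items()}
        table: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom in sorted(genome):
            seq = genome[chrom]
            for i in range(len(seq) - k + 1):
                table[seq[i:i + k]].append((chrom, i))
        self._table = dict(table)

    def tag_of(self, chromosome: str) -> str | None:
        if self._tag_of is not None:
            return self._tag_of(chromosome)
        return self.tag

    def positions(self, kmer: str, strand: str = "+") -> list[tuple[str, int]]:
        """Occurrences of ``kmer``; on '-' the reverse complement is matched
        against the forward strand (position of its leftmost base)."""
        if len(kmer) != self.k:
            raise ConfigurationError(f"query length {len(kmer)} != k={self.k}")
        if strand == "-":
            kmer = reverse_complement(kmer)
        return list(self._table.get(kmer, ()))


def build_index(genome: dict[str, str], k: int, tag: str | None = None,
                tag_of=None) -> SeedIndex:
    return SeedIndex(genome, k, tag=tag, tag_of=tag_of)


def _anchor_positions(read: str, index: SeedIndex, max_mismatch: int
                      ) -> dict[tuple[str, int], int]:
    """Verified candidate positions of ``read`` on the forward strand, from all
    error-free k-mer anchors; values are mismatch counts (<= max_mismatch)."""
    k = index.k
    L = len(read)
    rarr = _encode(read)
    candidates: set[tuple[str, int]] = set()
    for off in range(L - k + 1):
        for chrom, i in index._table.get(read[off:off + k], ()):
            p = i - off
            if 0 <= p <= len(index.genome[chrom]) - L:
                candidates.add((chrom, p))
    verified: dict[tuple[str, int], int] = {}
    for chrom, p in candidates:
        mism = int(np.count_nonzero(index.arrays[chrom][p:p + L] != rarr))
        if mism <= max_mismatch:
            verified[(chrom, p)] = mism
    return verified


def _window_scan(garr: np.ndarray, lo: int, hi: int, rarr: np.ndarray,
                 budget: int) -> list[tuple[int, int]]:
    """All positions q in [lo, hi] where ``rarr`` matches ``garr`` with at most
    ``budget`` mismatches."""
    L = len(rarr)
    lo = max(lo, 0)
    hi = min(hi, len(garr) - L)
    if hi < lo or budget < 0:
        return []
    windows = sliding_window_view(garr[lo:hi + L], L)
    mism = np.count_nonzero(windows != rarr, axis=1)
    return [(lo + int(i), int(mism[i])) for i in np.flatnonzero(mism <= budget)]


def find_hits(pair, index: SeedIndex, params: MapperParams) -> HitSet:
    """Map one read pair, returning all qualifying placements up to the cap.

    The fragment span must satisfy ``insert_min <= span <= insert_max`` and the
    fragment must contain both mates, so the effective lower bound is
    ``max(insert_min, len(mate1), len(mate2))``.
    """
    params.validate()
    m1, m2 = pair.mate1_seq, pair.mate2_seq
    L1, L2 = len(m1), len(m2)
    if min(L1, L2) < params.k:
        raise ConfigurationError(
            f"mate lengths ({L1},{L2}) must be >= k={params.k}")
    cap = params.max_mismatch
    ins_lo = max(params.insert_min, L1, L2)
    ins_hi = params.insert_max
    rc1, rc2 = reverse_complement(m1), reverse_complement(m2)
    m1a, m2a = _encode(m1), _encode(m2)
    rc1a, rc2a = _encode(rc1), _encode(rc2)

    # a locus is a distinct mate-1 placement: key (chrom, mate1_start); a
    # palindromic pair matching both strands there is still one locus
    best: dict[tuple[str, int], tuple[int, str, int]] = {}

    def record(chrom: str, strand: str, p: int, q: int, mism: int) -> None:
        # '+': mate1 at p (fragment start), mate2 ends at q+L2 (fragment end)
        # '-': mate1 (rc) at p with fragment end p+L1, mate2 at q = fragment start
        span = (q + L2 - p) if strand == "+" else (p + L1 - q)
        if not ins_lo <= span <= ins_hi:
            return
        key = (chrom, p)
        cand = (mism, strand, q)
        prev = best.get(key)
        if prev is None or cand < prev:
            best[key] = cand

    def sweep(read_fwd_arr, read_fwd_str, other_arr, other_str, strand):
        """One strand: the forward-matching mate anchors positions p, the other
        mate is sought in the span window; and symmetrically."""
        P = _anchor_positions(read_fwd_str, index, cap)
        Q = _anchor_positions(other_str, index, cap)
        for (chrom, p), e1 in P.items():
            garr = index.arrays[chrom]
            if strand == "+":
                lo, hi = p + ins_lo - L2, p + ins_hi - L2
            else:
                lo, hi = p + L1 - ins_hi, p + L1 - ins_lo
            for q, e2 in _window_scan(garr, lo, hi, other_arr, cap - e1):
                record(chrom, strand, p, q, e1 + e2)
        for (chrom, q), e2 in Q.items():
            garr = index.arrays[chrom]
            if strand == "+":
                lo, hi = q + L2 - ins_hi, q + L2 - ins_lo
            else:
                lo, hi = q - L1 + ins_lo, q - L1 + ins_hi
            for p, e1 in _window_scan(garr, lo, hi, read_fwd_arr, cap - e2):
                record(chrom, strand, p, q, e1 + e2)

    # '+' strand: mate1 forward at p, revcomp(mate2) at q downstream
    sweep(m1a, m1, rc2a, rc2, "+")
    # '-' strand: revcomp(mate1) at p, mate2 forward at q upstream
    sweep(rc1a, rc1, m2a, m2, "-")

    hits = [AlignmentHit(genome_tag=index.tag_of(chrom), chromosome=chrom,
                         start=p, strand=strand, mismatches_pair=mism,
                         mate2_start=q)
            for (chrom, p), (mism, strand, q) in sorted(best.items())]

    if not hits:
        status = Status.UNMAPPED
    elif len(hits) == 1:
        status = Status.UNIQUE
    elif len(hits) <= params.max_multimap:
        status = Status.MULTI
    else:
        status, hits = Status.TOO_MANY, []
    return HitSet(read_id=pair.read_id, hits=hits, status=status,
                  mate1_len=L1, mate2_len=L2)


# ---------------------------------------------------------------------------
# SAM output / ingestion
# ---------------------------------------------------------------------------

def write_sam(hitsets: list[HitSet], genome: dict[str, str], path: str) -> None:
    """Minimal SAM output of the built-in mapper: full-length M CIGARs,
    MAPQ 255, NM = pair mismatch total, NH = retained loci, HI = hit index."""
    refs = sorted(genome)
    header = {"HD": {"VN": "1.6", "SO": "queryname"},
              "SQ": [{"SN": c, "LN": len(genome[c])} for c in refs]}
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for hs in hitsets:
            if not hs.hits:
                for first in (True, False):
                    a = pysam.AlignedSegment(out.header)
                    a.query_name = hs.read_id
                    a.flag = (0x1 | 0x4 | 0x8 | (0x40 if first else 0x80))
                    a.reference_id = -1
                    out.write(a)
                continue
            nh = len(hs.hits)
            for hi, hit in enumerate(hs.hits, start=1):
                for first in (True, False):
                    a = pysam.AlignedSegment(out.header)
                    a.query_name = hs.read_id
                    mate1_fwd = hit.strand == "+"
                    this_fwd = mate1_fwd if first else not mate1_fwd
                    flag = 0x1 | 0x2 | (0x40 if first else 0x80)
                    if not this_fwd:
                        flag |= 0x10
                    if this_fwd:  # the other mate is then reverse
                        flag |= 0x20
                    if hi > 1:
                        flag |= 0x100
                    a.flag = flag
                    a.reference_id = refs.index(hit.chromosome)
                    a.reference_start = hit.start if first else hit.mate2_start
                    a.mapping_quality = 255
                    length = hs.mate1_len if first else hs.mate2_len
                    a.cigarstring = f"{length}M"
                    a.next_reference_id = a.reference_id
                    a.next_reference_start = hit.mate2_start if first else hit.start
                    a.set_tags([("NM", hit.mismatches_pair), ("NH", nh), ("HI", hi)])
                    out.write(a)


def ingest_alignments(path: str, tag_rule=None) -> list[HitSet]:
    """Build HitSets from an externally produced SAM/BAM file.

    The file must be name-collated (all records of one pair adjacent);
    secondary records (NH/HI-tagged multimappers) are collapsed into a single
    hit list per pair.  ``tag_rule`` maps a chromosome name to a genome tag
    (e.g. the ``host::``/``parasite::`` namespacing rule); by default names
    with such a prefix are recognized and anything else is left untagged.
    """
    if tag_rule is None:
        def tag_rule(chrom):
            return chrom.split("::", 1)[0] if "::" in chrom else None

    hitsets: list[HitSet] = []
    seen: set[str] = set()
    with pysam.AlignmentFile(path, check_sq=True) as fh:
        for qname, group_iter in itertools.groupby(fh, key=lambda r: r.query_name):
            if qname in seen:
                raise DataError(
                    f"read {qname!r} occurs in non-adjacent blocks: input must be "
                    "name-collated (samtools collate/sort -n)")
            seen.add(qname)
            group = list(group_iter)
            r1 = {r.get_tag("HI") if r.has_tag("HI") else 1: r
                  for r in group if r.is_read1 and not r.is_unmapped}
            r2 = {r.get_tag("HI") if r.has_tag("HI") else 1: r
                  for r in group if r.is_read2 and not r.is_unmapped}
            if not r1 or not r2:
                lens = [r.infer_query_length() or r.query_length or 0 for r in group]
                hitsets.append(HitSet(read_id=qname, hits=[], status=Status.UNMAPPED,
                                      mate1_len=max(lens, default=0),
                                      mate2_len=max(lens, default=0)))
                continue
            hits = []
            for hi in sorted(r1):
                a, b = r1[hi], r2.get(hi)
                if b is None:
                    raise DataError(f"read {qname!r}: mate 2 missing for hit {hi}")
                if a.reference_name not in fh.references:
                    raise DataError(f"unknown reference {a.reference_name!r}")
                nm = int(a.get_tag("NM")) if a.has_tag("NM") else 0
                hits.append(AlignmentHit(
                    genome_tag=tag_rule(a.reference_name),
                    chromosome=a.reference_name,
                    start=a.reference_start,
                    strand="-" if a.is_reverse else "+",
                    mismatches_pair=nm,
                    mate2_start=b.reference_start))
            status = Status.UNIQUE if len(hits) == 1 else Status.MULTI
            first1 = next(iter(r1.values()))
            first2 = next(iter(r2.values()))
            hitsets.append(HitSet(
                read_id=qname, hits=hits, status=status,
                mate1_len=first1.infer_query_length() or first1.query_length or 0,
                mate2_len=first2.infer_query_length() or first2.query_length or 0))
    return hitsets
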