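"""Shared fixtures and the independent brute-force alignment oracle.

The oracle enumerates *every* placement of a read pair by exhaustive
sliding-window comparison (numpy), with no k-mer seeding, and is therefore an
independent check of the seed-and-extend mapper under the error-free
condition where the mapper guarantees exhaustiveness.
"""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from dualmap import (GenomePairSpec, LibrarySpec, MapperParams,
                     generate_genome_pair, merge_libraries, simulate_library)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _mismatch_profile(genome_arr: np.ndarray, read: str) -> np.ndarray:
    """mismatches of ``read`` at every start position of the forward strand."""
    r = _encode(read)
    L = len(r)
    if len(genome_arr) < L:
        return np.empty(0, dtype=int)
    windows = np.lib.stride_tricks.sliding_window_view(genome_arr, L)
    return np.count_nonzero(windows != r, axis=1)


def oracle_loci(pair, genome: dict[str, str], params: MapperParams
                ) -> dict[tuple[str, int], int]:
    """All qualifying loci of a read pair, by exhaustive enumeration.

    A locus is a distinct mate-1 placement (chrom, 0-based position); the
    value is the minimal pair mismatch total over fragment lengths and strand
    readings at that position.  Placement rules mirror the mapper's contract:
    FR orientation, fragment span within [max(insert_min, L1, L2), insert_max],
    total mismatches <= max_mismatch.
    """
    m1, m2 = pair.mate1_seq, pair.mate2_seq
    L1, L2 = len(m1), len(m2)
    cap = params.max_mismatch
    lo_span = max(params.insert_min, L1, L2)
    hi_span = params.insert_max
    loci: dict[tuple[str, int], int] = {}
    for chrom, seq in genome.items():
        g = _encode(seq)
        for strand in "+-":
            if strand == "+":
                prof_a = _mismatch_profile(g, m1)                 # mate1 at p
                prof_b = _mismatch_profile(g, reverse_complement(m2))
            else:
                prof_a = _mismatch_profile(g, reverse_complement(m1))
                prof_b = _mismatch_profile(g, m2)
            for p in np.flatnonzero(prof_a <= cap):
                p = int(p)
                if strand == "+":
                    qlo, qhi = p + lo_span - L2, p + hi_span - L2
                else:
                    qlo, qhi = p + L1 - hi_span, p + L1 - lo_span
                qlo, qhi = max(qlo, 0), min(qhi, len(prof_b) - 1)
                if qhi < qlo:
                    continue
                best_b = int(prof_b[qlo:qhi + 1].min())
                total = int(prof_a[p]) + best_b
                if total <= cap:
                    key = (chrom, p)
                    loci[key] = min(loci.get(key, cap + 1), total)
    return loci


def oracle_hitset_summary(pair, genome, params) -> tuple[set, str]:
    """(locus set, status) per the mapper's cap semantics."""
    loci = oracle_loci(pair, genome, params)
    n = len(loci)
    if n == 0:
        return set(), "UNMAPPED"
    if n == 1:
        return set(loci), "UNIQUE"
    if n <= params.max_multimap:
        return set(loci), "MULTI"
    return set(), "TOO_MANY"


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def default_params() -> MapperParams:
    return MapperParams()


@pytest.fixture(scope="session")
def small_pair():
    """A compact genome pair with every homology class present."""
    spec = GenomePairSpec(seed=11, n_chromosomes_host=1, n_chromosomes_parasite=1,
                          n_genes_per_chromosome=8, gene_length=500,
                          intergenic_length=120, divergence=0.10,
                          paralog_fraction=0.125, conserved_fraction=0.125,
                          host_private_fraction=0.25,
                          parasite_private_fraction=0.25)
    return generate_genome_pair(spec)


@pytest.fixture(scope="session")
def small_merged(small_pair):
    """A merged library over the small pair, error-free for determinism."""
    host = simulate_library(small_pair.host, small_pair.annotations_host,
                            LibrarySpec(n_pairs=150, read_length=120,
                                        fragment_length_mean=250.0,
                                        fragment_length_sd=25.0,
                                        error_rate=0.0, seed=21), "host")
    para = simulate_library(small_pair.parasite, small_pair.annotations_parasite,
                            LibrarySpec(n_pairs=120, read_length=100,
                                        fragment_length_mean=250.0,
                                        fragment_length_sd=25.0,
                                        error_rate=0.0, seed=22), "parasite")
    return merge_libraries(host, para, seed=23)
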