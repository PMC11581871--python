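"""One-side/two-side cross-mapping extraction, relaxed remapping, locus counts."""

import numpy as np
import pytest
from Bio.Seq import reverse_complement

from dualmap import (Category, ConfigurationError, GeneModel, MapperParams,
                     Order, ReadPairRecord, Strategy, build_concat_index,
                     build_index, assign_combined, assign_sequential,
                     concat_genomes, extract_one_side, find_hits,
                     intersect_two_side_sequential, label_assignments,
                     relaxed_remap, summarize_loci, two_side_roster_combined)
from dualmap.crossmap_analysis import AMBIGUOUS, NO_FEATURE


def rand_seq(n, seed):
    return "".join(np.random.default_rng(seed).choice(list("ACGT"), n))


def pair_from(seq, start, frag, read_len, read_id):
    fragment = seq[start:start + frag]
    return ReadPairRecord(read_id, fragment[:read_len],
                          reverse_complement(fragment[-read_len:]))


PARAMS = MapperParams(k=15, insert_min=100, insert_max=400)


@pytest.fixture(scope="module")
def gap_scenario():
    """Host reads from a locus present only in the parasite genome, emulating
    a host assembly gap: the classic one-side cross-mapping situation."""
    missing = rand_seq(400, 50)          # absent from host, present in parasite
    host = {"hchr": rand_seq(600, 51)}
    para = {"pchr": rand_seq(200, 52) + missing + rand_seq(200, 53)}
    gap_reads = [pair_from(missing, 10 * i, 250, 100, f"read{i:06d}|host|gap|1")
                 for i in range(10)]
    host_reads = [pair_from(host["hchr"], 40 * i, 250, 100,
                            f"read{i + 100:06d}|host|hg|1") for i in range(5)]
    para_reads = [pair_from(para["pchr"][200:600], 12 * i, 250, 100,
                            f"read{i + 200:06d}|parasite|pg|1") for i in range(5)]
    merged = gap_reads + host_reads + para_reads
    truth = {r.read_id: r.read_id.split("|")[1] for r in merged}
    return host, para, merged, truth, {r.read_id for r in gap_reads}


class TestExtractOneSide:
    def _labels(self, host, para, merged, truth):
        hidx = build_index(host, 15, tag="host")
        pidx = build_index(para, 15, tag="parasite")
        hf = label_assignments(
            assign_sequential(merged, hidx, pidx, PARAMS, Order.HOST_FIRST),
            truth)
        pf = label_assignments(
            assign_sequential(merged, pidx, hidx, PARAMS, Order.PARASITE_FIRST),
            truth)
        return hf, pf

    def test_planted_gap_reads_are_the_host_one_side_set(self, gap_scenario):
        host, para, merged, truth, gap_ids = gap_scenario
        hf, pf = self._labels(host, para, merged, truth)
        host_set, para_set = extract_one_side(
            Strategy.SEQUENTIAL, labels_host_first=hf, labels_parasite_first=pf)
        assert host_set == gap_ids
        assert para_set == set()

    def test_combined_extraction_subtracts_two_side(self, gap_scenario):
        host, para, merged, truth, gap_ids = gap_scenario
        cidx = build_concat_index(concat_genomes(host, para), 15)
        outcomes = assign_combined(merged, cidx, PARAMS)
        labels = label_assignments(outcomes, truth)
        two_h, two_p = two_side_roster_combined(outcomes, truth)
        host_set, para_set = extract_one_side(
            Strategy.COMBINED, labels_combined=labels,
            two_side_ids=two_h | two_p)
        assert host_set == gap_ids          # gap reads hit only the parasite
        assert para_set == set()

    def test_missing_required_run_is_named(self):
        with pytest.raises(ConfigurationError, match="parasite-first"):
            extract_one_side(Strategy.SEQUENTIAL, labels_host_first=[])
        with pytest.raises(ConfigurationError, match="TWO_SIDE"):
            extract_one_side(Strategy.COMBINED, labels_combined=[])


class TestRelaxedRemap:
    def _own_genome(self):
        genome = {"chr1": rand_seq(2000, 60)}
        return genome, build_index(genome, 15, tag="host")

    def _read_with_mismatches(self, seq, start, n_mm, read_id):
        pair = pair_from(seq, start, 250, 100, read_id)
        m1 = list(pair.mate1_seq)
        for i in range(n_mm):   # clustered at the tail, clean anchor remains
            pos = 99 - i
            m1[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[m1[pos]]
        return ReadPairRecord(read_id, "".join(m1), pair.mate2_seq)

    def test_reads_with_seven_mismatches_all_recover(self):
        genome, index = self._own_genome()
        reads = [self._read_with_mismatches(genome["chr1"], 30 * i, 7, f"r{i}")
                 for i in range(10)]
        strict = MapperParams(k=15, max_mismatch=5, insert_min=100,
                              insert_max=400)
        for r in reads:  # by construction none map strictly
            assert not find_hits(r, index, strict).is_mapped
        assert relaxed_remap(reads, index, strict.relaxed(10),
                             strict_params=strict) == 1.0

    def test_reads_with_no_own_locus_never_recover(self):
        genome, index = self._own_genome()
        reads = [ReadPairRecord(f"r{i}", rand_seq(100, 70 + i),
                                rand_seq(100, 80 + i)) for i in range(5)]
        relaxed = MapperParams(k=15, max_mismatch=10, insert_min=100,
                               insert_max=400)
        assert relaxed_remap(reads, index, relaxed) == 0.0

    def test_planted_mixture_yields_exact_fraction(self):
        genome, index = self._own_genome()
        recoverable = [self._read_with_mismatches(genome["chr1"], 25 * i, 7,
                                                  f"ok{i}") for i in range(6)]
        lost = [ReadPairRecord(f"no{i}", rand_seq(100, 90 + i),
                               rand_seq(100, 95 + i)) for i in range(4)]
        relaxed = MapperParams(k=15, max_mismatch=10, insert_min=100,
                               insert_max=400)
        assert relaxed_remap(recoverable + lost, index, relaxed) == 0.60

    def test_empty_set_is_missing_not_zero(self):
        genome, index = self._own_genome()
        assert relaxed_remap([], index, MapperParams()) is None

    def test_relaxed_params_must_not_tighten(self):
        genome, index = self._own_genome()
        with pytest.raises(ConfigurationError):
            relaxed_remap([ReadPairRecord("r", "A" * 100, "T" * 100)], index,
                          MapperParams(max_mismatch=3),
                          strict_params=MapperParams(max_mismatch=5))


class TestTwoSideIntersection:
    def test_sequential_intersection_equals_combined_roster(self, small_pair,
                                                            small_merged):
        """With generous caps every two-side read is found identically by the
        sequential intersection and the combined TWO_SIDE roster."""
        hidx = build_index(small_pair.host, 15, tag="host")
        pidx = build_index(small_pair.parasite, 15, tag="parasite")
        cidx = build_concat_index(
            concat_genomes(small_pair.host, small_pair.parasite), 15)
        truth = {r.read_id: r.origin_organism for r in small_merged}
        hf = label_assignments(assign_sequential(
            small_merged, hidx, pidx, PARAMS, Order.HOST_FIRST), truth)
        pf = label_assignments(assign_sequential(
            small_merged, pidx, hidx, PARAMS, Order.PARASITE_FIRST), truth)
        seq_host, seq_para = intersect_two_side_sequential(hf, pf)
        outcomes = assign_combined(small_merged, cidx, PARAMS)
        over_cap = {o.read_id for o in outcomes
                    if o.category == Category.UNMAPPED
                    and (o.hits_host + o.hits_parasite) > 0}
        com_host, com_para = two_side_roster_combined(outcomes, truth)
        assert seq_host - over_cap == com_host
        assert seq_para - over_cap == com_para
        assert com_host or com_para  # the conserved class must cross-map

    def test_host_only_read_absent_from_two_side_set(self):
        host = {"hchr": rand_seq(1500, 61)}
        para = {"pchr": rand_seq(1500, 62)}
        read = pair_from(host["hchr"], 100, 250, 100, "read000001|host|g|1")
        truth = {read.read_id: "host"}
        hidx = build_index(host, 15, tag="host")
        pidx = build_index(para, 15, tag="parasite")
        hf = label_assignments(assign_sequential(
            [read], hidx, pidx, PARAMS, Order.HOST_FIRST), truth)
        pf = label_assignments(assign_sequential(
            [read], pidx, hidx, PARAMS, Order.PARASITE_FIRST), truth)
        host_set, para_set = intersect_two_side_sequential(hf, pf)
        assert host_set == set() and para_set == set()

    def test_mismatched_universes_rejected(self):
        from dualmap.errors import DataError
        with pytest.raises(DataError, match="universe"):
            intersect_two_side_sequential(
                label_assignments([], {}), label_assignments(
                    [], {}) or [type("L", (), {"read_id": "x"})()])


class TestSummarizeLoci:
    def _setup(self):
        gene_seq = rand_seq(500, 70)
        genome = {"chr1": rand_seq(200, 71) + gene_seq + rand_seq(400, 72)}
        genes = [GeneModel("G", "chr1", 201, 700, "+",
                           "conserved ribosomal protein")]
        index = build_index(genome, 15, tag="host")
        return genome, genes, index, gene_seq

    def test_reads_inside_one_gene_counted_for_it(self):
        genome, genes, index, gene_seq = self._setup()
        reads = [pair_from(gene_seq, 10 * i, 250, 100, f"r{i}")
                 for i in range(5)]
        hits = {r.read_id: find_hits(r, index, PARAMS) for r in reads}
        table = summarize_loci({r.read_id for r in reads}, hits, genes)
        assert table == [("G", "conserved ribosomal protein", 5)]

    def test_intergenic_read_is_no_feature(self):
        genome, genes, index, _ = self._setup()
        read = pair_from(genome["chr1"], 720, 250, 100, "rI")
        hits = {"rI": find_hits(read, index, PARAMS)}
        table = summarize_loci({"rI"}, hits, genes)
        assert table == [(NO_FEATURE, "", 1)]

    def test_counts_partition_the_read_set(self):
        genome, genes, index, gene_seq = self._setup()
        reads = ([pair_from(gene_seq, 5 * i, 250, 100, f"g{i}") for i in range(4)]
                 + [pair_from(genome["chr1"], 720, 250, 100, "i0")]
                 # straddles the gene 3' end into intergenic space: still gene G
                 + [pair_from(genome["chr1"], 550, 250, 100, "s0")])
        hits = {r.read_id: find_hits(r, index, PARAMS) for r in reads}
        table = summarize_loci({r.read_id for r in reads}, hits, genes)
        assert sum(n for _, _, n in table) == len(reads)

    def test_read_spanning_two_genes_is_ambiguous(self):
        seq = rand_seq(1000, 75)
        genome = {"chr1": seq}
        genes = [GeneModel("A", "chr1", 1, 400, "+", "first"),
                 GeneModel("B", "chr1", 401, 800, "+", "second")]
        index = build_index(genome, 15, tag="host")
        read = pair_from(seq, 300, 250, 100, "rA")
        hits = {"rA": find_hits(read, index, PARAMS)}
        table = summarize_loci({"rA"}, hits, genes)
        assert table == [(AMBIGUOUS, "", 1)]

    def test_unknown_chromosome_rejected(self):
        genome, genes, index, gene_seq = self._setup()
        read = pair_from(gene_seq, 0, 250, 100, "rX")
        hits = {"rX": find_hits(read, index, PARAMS)}
        from dualmap.errors import DataError
        with pytest.raises(DataError, match="absent"):
            summarize_loci({"rX"}, hits, genes, chromosomes={"other_chr"})


def test_two_side_size_shrinks_with_divergence():
    """Over a few seeds the mean two-side count is non-increasing in the
    homolog divergence (no conserved class)."""
    from dualmap import (GenomePairSpec, LibrarySpec, generate_genome_pair,
                         merge_libraries, simulate_library)
    means = []
    for div in (0.01, 0.05, 0.10):
        counts = []
        for seed in (1, 2, 3):
            spec = GenomePairSpec(seed=seed, n_chromosomes_host=1,
                                  n_chromosomes_parasite=1,
                                  n_genes_per_chromosome=5, gene_length=400,
                                  intergenic_length=100, divergence=div,
                                  conserved_fraction=0.0, paralog_fraction=0.0,
                                  host_private_fraction=0.0,
                                  parasite_private_fraction=0.0)
            pair = generate_genome_pair(spec)
            lib_kw = dict(n_pairs=80, read_length=100,
                          fragment_length_mean=200.0, fragment_length_sd=20.0,
                          error_rate=0.0)
            merged = merge_libraries(
                simulate_library(pair.host, pair.annotations_host,
                                 LibrarySpec(seed=seed + 10, **lib_kw), "host"),
                simulate_library(pair.parasite, pair.annotations_parasite,
                                 LibrarySpec(seed=seed + 20, **lib_kw),
                                 "parasite"), seed=seed)
            cidx = build_concat_index(concat_genomes(pair.host, pair.parasite),
                                      15)
            outcomes = assign_combined(merged, cidx,
                                       MapperParams(k=15, insert_min=100,
                                                    insert_max=400))
            counts.append(sum(1 for o in outcomes
                              if o.category == Category.TWO_SIDE))
        means.append(np.mean(counts))
    assert means[0] >= means[1] >= means[2]
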