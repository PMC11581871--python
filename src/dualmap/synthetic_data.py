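"""Synthetic host/parasite genome pairs and paired-end read libraries with ground truth.

A dual RNA-seq sample mixes transcripts of two interacting plants (e.g. a host
stem and the parasite's haustorium).  Separating the mixed reads in silico is
hard exactly where the two genomes are similar, so this module builds genome
pairs whose homology structure is *known by construction*:

* homologous single-exon gene pairs with a tunable per-base divergence,
* an "organelle-like" class of ultra-conserved genes copied verbatim into both
  genomes (the source of two-side cross-mapping),
* within-genome paralog copies (the source of multimapping),
* private genes with no homolog in the other genome (random sequence).

Every simulated read pair encodes its true origin in its name
(``readNNNNNN|<organism>|<gene_id>|<start>``), so downstream assignment can be
scored against the truth without sidecar files.

Coordinates are 0-based half-open internally; GFF3 output is 1-based inclusive.
Divergence and sequencing error are substitution-only (no indels), matching the
contiguous Hamming-distance mapper in :mod:`dualmap.aligner`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import reverse_complement

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

_BASES = "ACGT"
_OTHER = {b: _BASES.replace(b, "") for b in _BASES}

HOST = "host"
PARASITE = "parasite"

#: minimum retained read length, as after adapter/quality trimming of real libraries
MIN_READ_LENGTH = 75


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def mutate_sequence(seq: str, p: float, rng: np.random.Generator) -> tuple[str, float]:
    """Substitute each position independently with probability ``p``.

    Substitutions always change the base, so the returned realized divergence is
    exactly the Hamming fraction between input and output.
    """
    if p <= 0.0:
        return seq, 0.0
    flags = rng.random(len(seq)) < p
    out = list(seq)
    for i in np.flatnonzero(flags):
        out[i] = _OTHER[out[i]][rng.integers(0, 3)]
    return "".join(out), float(flags.sum()) / len(seq)


# ---------------------------------------------------------------------------
# genome pair
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """A single-exon gene feature (GFF3 convention: 1-based inclusive)."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    product: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConfigurationError(f"gene {self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ConfigurationError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomePairSpec:
    """Parameters controlling the simulated host/parasite genome pair.

    ``divergence`` is the per-base substitution probability between homologous
    gene copies; ``conserved_fraction`` is the share of genes copied verbatim
    into both genomes (divergence exactly 0); the private fractions are shares
    of genes with no homolog at all.
    """

    seed: int = 0
    n_chromosomes_host: int = 2
    n_chromosomes_parasite: int = 2
    n_genes_per_chromosome: int = 10
    gene_length: int = 600
    intergenic_length: int = 200
    divergence: float = 0.05
    paralog_fraction: float = 0.1
    paralog_divergence: float = 0.02
    conserved_fraction: float = 0.1
    host_private_fraction: float = 0.2
    parasite_private_fraction: float = 0.2

    def validate(self) -> None:
        for name in ("n_chromosomes_host", "n_chromosomes_parasite",
                     "n_genes_per_chromosome", "gene_length", "intergenic_length"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("divergence", "paralog_fraction", "paralog_divergence",
                     "conserved_fraction", "host_private_fraction",
                     "parasite_private_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.conserved_fraction + self.host_private_fraction > 1.0:
            raise ConfigurationError(
                "conserved_fraction + host_private_fraction must be <= 1")
        if self.conserved_fraction + self.parasite_private_fraction > 1.0:
            raise ConfigurationError(
                "conserved_fraction + parasite_private_fraction must be <= 1")


@dataclass
class GenomePair:
    """Two genomes plus the complete homology/paralogy ground truth."""

    host: dict[str, str]
    parasite: dict[str, str]
    annotations_host: list[GeneModel]
    annotations_parasite: list[GeneModel]
    #: (host gene id, parasite gene id, realized per-base divergence)
    homology_map: set[tuple[str, str, float]]
    #: (source gene id, copy gene id) pairs within one genome
    paralog_map: set[tuple[str, str]]
    spec: GenomePairSpec | None = None

    def genome(self, organism: str) -> dict[str, str]:
        if organism == HOST:
            return self.host
        if organism == PARASITE:
            return self.parasite
        raise ConfigurationError(f"unknown organism {organism!r}")

    def annotations(self, organism: str) -> list[GeneModel]:
        return self.annotations_host if organism == HOST else self.annotations_parasite


def transcript_sequence(genome: dict[str, str], gene: GeneModel) -> str:
    """The transcript of a single-exon gene: genomic interval, minus-strand genes
    are reverse-complemented."""
    seq = genome[gene.chromosome][gene.start - 1:gene.end]
    return reverse_complement(seq) if gene.strand == "-" else seq


def _gene_counts(n: int, private_fraction: float, spec: GenomePairSpec) -> tuple[int, int, int]:
    n_private = round(private_fraction * n)
    n_paralog = min(round(spec.paralog_fraction * n), n - n_private)
    n_shared_cap = n - n_private - n_paralog
    return n_private, n_paralog, n_shared_cap


def generate_genome_pair(spec: GenomePairSpec) -> GenomePair:
    """Generate a host/parasite genome pair with full truth maps.

    Deterministic for a fixed ``spec.seed``.  Homologous gene pairs differ at
    each position independently with probability ``spec.divergence``; conserved
    pairs are copied verbatim; paralog copies are placed at distinct loci of
    the same genome; private genes are i.i.d. uniform nucleotide sequences.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    n_host = spec.n_chromosomes_host * spec.n_genes_per_chromosome
    n_para = spec.n_chromosomes_parasite * spec.n_genes_per_chromosome
    hp, hpar, hcap = _gene_counts(n_host, spec.host_private_fraction, spec)
    pp, ppar, pcap = _gene_counts(n_para, spec.parasite_private_fraction, spec)

    n_shared = min(hcap, pcap)
    n_conserved = min(round(spec.conserved_fraction * n_host),
                      round(spec.conserved_fraction * n_para), n_shared)
    n_diverged = n_shared - n_conserved

    # ancestral sequences for the shared gene classes
    conserved_anc = [random_sequence(spec.gene_length, rng) for _ in range(n_conserved)]
    diverged_anc = [random_sequence(spec.gene_length, rng) for _ in range(n_diverged)]

    homology_map: set[tuple[str, str, float]] = set()
    paralog_map: set[tuple[str, str]] = set()

    def build_side(org: str, n_genes: int, n_private: int, n_paralog: int,
                   prefix: str) -> tuple[list[str], list[str], list[str]]:
        """Return (gene ids, sequences, products) for one genome, pre-placement."""
        ids, seqs, prods = [], [], []
        realized: dict[str, float] = {}
        for i, anc in enumerate(conserved_anc):
            ids.append(f"{prefix}gene{i + 1:04d}")
            seqs.append(anc)  # verbatim copy: realized divergence exactly 0
            prods.append(f"ultra-conserved ribosomal protein L{i + 1}")
            realized[ids[-1]] = 0.0
        for i, anc in enumerate(diverged_anc):
            ids.append(f"{prefix}gene{n_conserved + i + 1:04d}")
            if org == HOST:
                seqs.append(anc)
                realized[ids[-1]] = 0.0
            else:
                mut, r = mutate_sequence(anc, spec.divergence, rng)
                seqs.append(mut)
                realized[ids[-1]] = r
            prods.append(f"homologous metabolic enzyme {n_conserved + i + 1}")
        n_shared_here = len(ids)
        n_priv_here = n_genes - n_shared_here - n_paralog
        priv_ids = []
        for i in range(n_priv_here):
            gid = f"{prefix}gene{n_shared_here + i + 1:04d}"
            ids.append(gid)
            priv_ids.append(gid)
            seqs.append(random_sequence(spec.gene_length, rng))
            prods.append(f"lineage-specific protein {n_shared_here + i + 1}")
        # paralog copies duplicate an existing gene of the same genome; private
        # sources are preferred so the cross-genome truth stays clean
        source_pool = priv_ids if priv_ids else ids[:n_shared_here]
        for i in range(n_paralog):
            src_idx = ids.index(source_pool[int(rng.integers(0, len(source_pool)))])
            gid = f"{prefix}gene{n_genes - n_paralog + i + 1:04d}"
            copy, _ = mutate_sequence(seqs[src_idx], spec.paralog_divergence, rng)
            paralog_map.add((ids[src_idx], gid))
            ids.append(gid)
            seqs.append(copy)
            prods.append(prods[src_idx] + " paralog")
        return ids, seqs, prods, realized

    h_ids, h_seqs, h_prods, h_real = build_side(HOST, n_host, hp, hpar, "h")
    p_ids, p_seqs, p_prods, p_real = build_side(PARASITE, n_para, pp, ppar, "p")

    for i in range(n_shared):
        # realized divergence of the pair is carried by the mutated (parasite) copy
        homology_map.add((h_ids[i], p_ids[i], p_real[p_ids[i]]))

    def place(org: str, n_chrom: int, ids: list[str], seqs: list[str],
              prods: list[str]) -> tuple[dict[str, str], list[GeneModel]]:
        order = rng.permutation(len(ids))
        genome: dict[str, str] = {}
        annotations: list[GeneModel] = []
        idx = 0
        for c in range(n_chrom):
            parts = [random_sequence(spec.intergenic_length, rng)]
            pos = spec.intergenic_length
            chrom = f"{org}_chr{c + 1}"
            for _ in range(spec.n_genes_per_chromosome):
                j = order[idx]
                idx += 1
                strand = "+" if rng.random() < 0.5 else "-"
                gseq = seqs[j] if strand == "+" else reverse_complement(seqs[j])
                parts.append(gseq)
                annotations.append(GeneModel(
                    gene_id=ids[j], chromosome=chrom,
                    start=pos + 1, end=pos + spec.gene_length,
                    strand=strand, product=prods[j]))
                pos += spec.gene_length
                parts.append(random_sequence(spec.intergenic_length, rng))
                pos += spec.intergenic_length
            genome[chrom] = "".join(parts)
        return genome, annotations

    host_genome, host_ann = place(HOST, spec.n_chromosomes_host, h_ids, h_seqs, h_prods)
    para_genome, para_ann = place(PARASITE, spec.n_chromosomes_parasite,
                                  p_ids, p_seqs, p_prods)

    return GenomePair(host=host_genome, parasite=para_genome,
                      annotations_host=host_ann, annotations_parasite=para_ann,
                      homology_map=homology_map, paralog_map=paralog_map, spec=spec)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LibrarySpec:
    """Parameters of one paired-end library.

    Defaults mirror a typical short-read dual RNA-seq design: 150 nt host reads
    (100 nt for the parasite side), ~300 bp fragments, and a small per-base
    substitution error rate.
    """

    n_pairs: int = 1000
    read_length: int = 150
    fragment_length_mean: float = 300.0
    fragment_length_sd: float = 30.0
    error_rate: float = 0.002
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 0:
            raise ConfigurationError(f"n_pairs must be >= 0, got {self.n_pairs}")
        if self.read_length < MIN_READ_LENGTH:
            raise ConfigurationError(
                f"read_length must be >= {MIN_READ_LENGTH} nt, got {self.read_length}")
        if self.read_length > self.fragment_length_mean:
            raise ConfigurationError(
                "read_length must not exceed fragment_length_mean "
                f"({self.read_length} > {self.fragment_length_mean})")
        if not 0.0 <= self.error_rate < 0.1:
            raise ConfigurationError(
                f"error_rate must lie in [0, 0.1), got {self.error_rate}")
        if self.fragment_length_sd < 0:
            raise ConfigurationError("fragment_length_sd must be >= 0")


@dataclass(frozen=True)
class ReadPairRecord:
    """A simulated read pair whose name encodes its true origin."""

    read_id: str
    mate1_seq: str
    mate2_seq: str

    @staticmethod
    def make_id(serial: int, organism: str, gene_id: str, start: int) -> str:
        return f"read{serial:06d}|{organism}|{gene_id}|{start}"

    def _fields(self) -> list[str]:
        parts = self.read_id.split("|")
        if len(parts) != 4:
            raise DataError(f"read id {self.read_id!r} does not encode an origin")
        return parts

    @property
    def origin_organism(self) -> str:
        return self._fields()[1]

    @property
    def origin_gene(self) -> str:
        return self._fields()[2]

    @property
    def origin_start(self) -> int:
        """1-based start of the fragment on the source transcript."""
        return int(self._fields()[3])


def simulate_library(genome: dict[str, str], annotations: list[GeneModel],
                     spec: LibrarySpec, organism: str,
                     abundance: dict[str, float] | None = None,
                     id_prefix: str = "") -> list[ReadPairRecord]:
    """Simulate ``spec.n_pairs`` FR-oriented read pairs from gene bodies.

    Fragments are drawn from transcripts (minus-strand genes are read on the
    reverse complement); mate 1 is the transcript-forward end of the fragment
    and mate 2 the reverse complement of the other end.  Per-base substitution
    errors are applied independently at ``spec.error_rate``.  Genes shorter
    than the read length are excluded with a logged warning.  ``abundance``
    optionally weights genes; the default is uniform.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    eligible = []
    for gene in annotations:
        if gene.length < spec.read_length:
            logger.warning("gene %s (%d bp) shorter than read length %d nt: excluded",
                           gene.gene_id, gene.length, spec.read_length)
            continue
        eligible.append(gene)
    if not eligible and spec.n_pairs > 0:
        raise DataError("no gene long enough to support the requested read length")

    weights = np.ones(len(eligible))
    if abundance is not None:
        weights = np.array([abundance.get(g.gene_id, 1.0) for g in eligible], float)
        if weights.sum() <= 0:
            raise ConfigurationError("abundance weights sum to zero")
    probs = weights / weights.sum() if len(eligible) else None

    reads: list[ReadPairRecord] = []
    for serial in range(spec.n_pairs):
        gene = eligible[int(rng.choice(len(eligible), p=probs))]
        transcript = transcript_sequence(genome, gene)
        flen = int(round(rng.normal(spec.fragment_length_mean, spec.fragment_length_sd)))
        flen = max(spec.read_length, min(flen, len(transcript)))
        start0 = int(rng.integers(0, len(transcript) - flen + 1))
        fragment = transcript[start0:start0 + flen]
        mate1 = fragment[:spec.read_length]
        mate2 = reverse_complement(fragment[-spec.read_length:])
        mate1, _ = mutate_sequence(mate1, spec.error_rate, rng)
        mate2, _ = mutate_sequence(mate2, spec.error_rate, rng)
        rid = ReadPairRecord.make_id(serial, organism, gene.gene_id, start0 + 1)
        if id_prefix:
            rid = id_prefix + rid
        reads.append(ReadPairRecord(read_id=rid, mate1_seq=mate1, mate2_seq=mate2))
    return reads


def merge_libraries(host_lib: list[ReadPairRecord], parasite_lib: list[ReadPairRecord],
                    seed: int = 0) -> list[ReadPairRecord]:
    """Merge two libraries into one dual RNA-seq sample, shuffled by ``seed``.

    The output is a content-preserving permutation of the concatenation; read
    ids must be globally unique.
    """
    ids_h = {r.read_id for r in host_lib}
    collisions = sorted(ids_h & {r.read_id for r in parasite_lib})
    if len(ids_h) != len(host_lib):
        raise DataError("duplicate read ids within host library")
    if collisions:
        raise DataError(f"duplicate read ids across libraries: {collisions[:10]}")
    merged = list(host_lib) + list(parasite_lib)
    rng = np.random.default_rng(seed)
    return [merged[i] for i in rng.permutation(len(merged))]


def truth_map(reads: list[ReadPairRecord]) -> dict[str, str]:
    """read_id -> origin organism, parsed from the encoded names."""
    return {r.read_id: r.origin_organism for r in reads}
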