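"""File round trips: FASTA genomes, GFF3 gene models, paired FASTQ, truth TSV,
assignment and metrics tables.

FASTQ qualities are written as constant 'I' (Phred 40): quality modeling is
out of scope and the mapper is quality-blind.
"""

from __future__ import annotations

import os
import tempfile

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError
from .evaluation import AssignmentLabel
from .strategy import AssignmentOutcome, Category, Order, Strategy
from .synthetic_data import GeneModel, GenomePair, ReadPairRecord


def write_fasta(genome: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="")
               for chrom, seq in genome.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_gff3(annotations: list[GeneModel], path: str, source: str = "dualmap") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(annotations, key=lambda g: (g.chromosome, g.start)):
            attrs = f"ID={g.gene_id};product={g.product}"
            fh.write("\t".join([g.chromosome, source, "gene", str(g.start),
                                str(g.end), ".", g.strand, ".", attrs]) + "\n")


def read_gff3(path: str) -> list[GeneModel]:
    db = gffutils.create_db(path, ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    out = []
    for feat in db.features_of_type("gene"):
        product = feat.attributes.get("product", [""])[0]
        out.append(GeneModel(gene_id=feat.id, chromosome=feat.seqid,
                             start=feat.start, end=feat.end,
                             strand=feat.strand, product=product))
    return out


def write_fastq_pair(reads: list[ReadPairRecord], prefix: str) -> tuple[str, str]:
    """Write ``<prefix>_R1.fastq`` / ``<prefix>_R2.fastq``; returns the paths."""
    paths = (f"{prefix}_R1.fastq", f"{prefix}_R2.fastq")
    for path, attr in zip(paths, ("mate1_seq", "mate2_seq")):
        records = []
        for r in reads:
            seq = getattr(r, attr)
            rec = SeqRecord(Seq(seq), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            records.append(rec)
        SeqIO.write(records, path, "fastq")
    return paths


def read_fastq_pair(r1_path: str, r2_path: str) -> list[ReadPairRecord]:
    reads = []
    for rec1, rec2 in zip(SeqIO.parse(r1_path, "fastq"),
                          SeqIO.parse(r2_path, "fastq"), strict=True):
        if rec1.id != rec2.id:
            raise DataError(f"mate name mismatch: {rec1.id!r} vs {rec2.id!r}")
        reads.append(ReadPairRecord(read_id=rec1.id, mate1_seq=str(rec1.seq),
                                    mate2_seq=str(rec2.seq)))
    return reads


def write_truth_tsv(reads: list[ReadPairRecord], pair: GenomePair, path: str) -> None:
    strands = {g.gene_id: g.strand
               for g in pair.annotations_host + pair.annotations_parasite}
    df = pd.DataFrame({
        "read_id": [r.read_id for r in reads],
        "organism": [r.origin_organism for r in reads],
        "gene_id": [r.origin_gene for r in reads],
        "start": [r.origin_start for r in reads],
        "strand": [strands.get(r.origin_gene, ".") for r in reads],
    })
    df.to_csv(path, sep="\t", index=False)


def read_truth_tsv(path: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["read_id"], df["organism"]))


def write_outcomes_tsv(outcomes: list[AssignmentOutcome], path: str) -> None:
    pd.DataFrame({
        "read_id": [o.read_id for o in outcomes],
        "strategy": [o.strategy.value for o in outcomes],
        "order": [o.order.value for o in outcomes],
        "category": [o.category.value for o in outcomes],
        "hits_host": [o.hits_host for o in outcomes],
        "hits_parasite": [o.hits_parasite for o in outcomes],
    }).to_csv(path, sep="\t", index=False)


def read_outcomes_tsv(path: str) -> list[AssignmentOutcome]:
    df = pd.read_csv(path, sep="\t")
    return [AssignmentOutcome(read_id=rec["read_id"],
                              strategy=Strategy(rec["strategy"]),
                              order=Order(rec["order"]),
                              category=Category(rec["category"]),
                              hits_host=int(rec["hits_host"]),
                              hits_parasite=int(rec["hits_parasite"]))
            for rec in df.to_dict("records")]


def write_labels_tsv(labels: list[AssignmentLabel], path: str) -> None:
    pd.DataFrame({
        "read_id": [l.read_id for l in labels],
        "strategy": [l.strategy.value for l in labels],
        "order": [l.order.value for l in labels],
        "host_label": [l.host_label for l in labels],
        "parasite_label": [l.parasite_label for l in labels],
    }).to_csv(path, sep="\t", index=False)
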