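# dualmap

Benchmarking in-silico read separation for **dual RNA-seq** of host–parasite
plant systems.

When a parasitic plant (e.g. dodder, *Cuscuta*) feeds on a host through its
haustorium, the interface tissue yields a mixed transcriptome. Dual RNA-seq
separates the mixture computationally by mapping reads against both reference
genomes — which works exactly as well as the two genomes are divergent. Two
standard designs exist:

* **sequential**: map all reads to genome A, forward only the unmapped
  leftovers to genome B (repeatable with the order swapped);
* **combined**: map all reads once against a single concatenated reference
  `A + B` and assign each read by which side its retained hits fall on.

Both suffer from **multimapping** (paralogs within one genome) and
**cross-mapping** (homologous loci between genomes): *one-side* cross-mapping
(a read from X maps only to Y, typically an assembly-gap symptom) and
*two-side* cross-mapping (a read maps validly in both genomes — conserved,
insufficiently diverged loci).

`dualmap` makes these effects measurable by construction. It simulates a
host/parasite genome pair whose homology structure is fully known (homologous
gene pairs at a tunable per-base divergence *d*, ultra-conserved
"organelle-like" genes, within-genome paralogs, private genes), generates
paired-end read libraries whose names encode their true origin, runs both
separation strategies with a deterministic Hamming-distance mapper under the
two standard filters (multimap cap `N_loci ≤ 10`, mismatch cap
`N_mm ≤ 5`; relaxed remapping uses 10), labels every read against the truth,
and reports the four separation metrics per organism:

```
precision   = TP / (TP + FP)
sensitivity = TP / (TP + FN)
specificity = TN / (TN + FP)
accuracy    = (TP + TN) / (TP + TN + FP + FN)
```

where, for the host reference, TP = host reads assigned to the host,
FP = parasite reads assigned to the host, and so on; every assignment event
carries a dual label (a host-reference and a parasite-reference name, e.g.
`S-TP_h1` / `S-TN_p1` for a host read captured correctly at step 1 of a
host-first sequential run), so TP_host ≡ TN_parasite by construction.
Reads mapped in neither genome stay outside the four cells.

## Worked example

```python
import dualmap as dm

res = dm.run_pipeline(
    dm.GenomePairSpec(seed=7, n_chromosomes_host=1, n_chromosomes_parasite=1,
                      n_genes_per_chromosome=10, divergence=0.05,
                      conserved_fraction=0.1),
    dm.LibrarySpec(n_pairs=1000, read_length=150, seed=8),   # host library
    dm.LibrarySpec(n_pairs=800, read_length=100, seed=9),    # parasite library
    dm.MapperParams(), seed=10)

for (strategy, order), run in res.runs.items():
    r = run.row
    print(strategy.value, order.value, r.unique_host, r.multi_host,
          r.unique_parasite, r.multi_parasite, r.two_side, r.unmapped,
          f"{r.mapped_percent:.2f}%")
```

prints (reformatted):

```
SEQUENTIAL HOST_FIRST     uniq_h=1112 multi_h= 13 uniq_p= 574 multi_p=101 two_side=  0 unmapped=  0 mapped=100.00%
SEQUENTIAL PARASITE_FIRST uniq_h= 885 multi_h= 13 uniq_p= 801 multi_p=101 two_side=  0 unmapped=  0 mapped=100.00%
COMBINED   NA             uniq_h= 885 multi_h= 13 uniq_p= 574 multi_p=101 two_side=227 unmapped=  0 mapped=87.39%
combined host:     precision=0.8778 sensitivity=0.8980 accuracy=0.8739
two-side reads (sequential intersection): host=102 parasite=125
top two-side locus: ('hgene0001', 'ultra-conserved ribosomal protein L1', 98)
```

Reading it: whichever genome is mapped *first* in the sequential design
captures the ~227 two-side cross-mapping reads (1112 vs 885 unique-host reads
between the two orders — the difference is exactly the host-side two-side
set). The combined design isolates those reads in a single pass as the
`TWO_SIDE` category, and their loci trace back to the planted ultra-conserved
genes via the GFF3 `product` attribute. With 5% homolog divergence everything
else separates cleanly.

Cross-mapping analysis lives in `res.crossmap`: one-side read sets and their
relaxed-remap recovery rates (mismatch cap lifted 5 → 10), two-side rosters
from both designs (they provably coincide whenever total hit counts stay
within the multimap cap), and per-gene union-mode locus counts.

## Command line

```bash
dualmap run-all --config config.yaml --seed 1 --outdir out/
```

writes the genomes (FASTA), annotations (GFF3), merged library (paired
FASTQ + truth TSV), per-strategy assignment and label tables, the run table,
metrics, cross-mapping summaries and a Sankey-style flow edge list. The
verbs `simulate`, `map`, `assign`, `evaluate`, `crossmap` and `report` expose
the individual stages; `dualmap map` also writes SAM readable by samtools,
and externally produced name-collated SAM/BAM can be ingested with
`dualmap.ingest_alignments`.

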