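# Methods

## The problem being modeled

Dual RNA-seq of a host plant and a parasitic plant samples the haustorial
interface as one library; reads must then be assigned to their source
organism by mapping against both reference genomes. Assignment fails in two
characteristic ways: *multimapping* within one genome (gene duplication) and
*cross-mapping* between genomes (homologous loci that have not diverged
enough for the mismatch filter to tell apart). `dualmap` reproduces this
situation with synthetic genome pairs in which every read's true origin and
every homologous relationship is known, so both failure modes can be counted
exactly rather than estimated.

## Synthetic genome pairs

`generate_genome_pair` builds two genomes from four gene classes laid out as
non-overlapping single-exon genes separated by random intergenic sequence:

* **diverged homologs** — an ancestral sequence is copied into both genomes
  and one copy is substituted at each position independently with probability
  `divergence` (substitutions always change the base, so the recorded
  realized divergence is exactly the Hamming fraction of the pair);
* **ultra-conserved genes** (`conserved_fraction`) — copied verbatim into
  both genomes, emulating organelle-like and ribosomal loci; these are the
  designed source of two-side cross-mapping;
* **paralogs** (`paralog_fraction`) — within-genome duplicates at a separate
  `paralog_divergence`, the designed source of multimapping; copies prefer
  private genes as templates so they do not confound the cross-genome truth;
* **private genes** — i.i.d. random sequence with no homolog, the cleanly
  separable background.

Class counts are rounded per genome; shared classes are capped at the
smaller genome's capacity and leftover slots become private. Genes are
single-exon by design: contiguous alignment is then exact and splicing is
orthogonal to the cross-mapping question being studied. Divergence and
sequencing error are substitution-only — the mapper is Hamming-based, and
indel realism is a non-goal.

Coordinates are 0-based half-open internally; GFF3 output is 1-based
inclusive with `ID` and `product` attributes (the `product` text is what the
two-side locus tables report).

## Read simulation

`simulate_library` draws fragments uniformly from gene transcripts
(minus-strand genes read on the reverse complement), with Normal fragment
lengths clipped to `[read_length, transcript_length]`. Mate 1 is the
transcript-forward end of the fragment, mate 2 the reverse complement of the
other end (FR orientation); per-base errors are applied independently.
Defaults emulate the benchmark's library design: 150 nt host reads and
100 nt parasite reads (both well above the 75 nt post-trimming floor),
~300 ± 30 bp fragments, and a 0.2% substitution error rate typical of
quality-trimmed short-read data. Expression heterogeneity is uniform per
gene (an abundance weighting hook exists but defaults to uniform). The true
origin is encoded in the read name (`readNNNNNN|organism|gene|start`) so it
survives FASTQ round trips without sidecar files; FASTQ qualities are
constant `I` because the mapper is quality-blind.

`merge_libraries` concatenates the two libraries and shuffles them with a
seeded permutation; it is content-preserving and rejects colliding read ids.

## The mapper

`find_hits` is a deterministic seed-and-extend Hamming mapper with the two
filters that drive all downstream accounting: a per-pair mismatch cap
(default 5; the relaxed remapping mode uses 10) and a multimap cap on
retained loci (default 10). Design choices:

* The mismatch cap applies to the **pair total** (sum over mates) — one
  consistent knob; whether the emulated aligner option is per-mate or
  per-pair is not observable from the outside, and per-pair is the stricter,
  simpler reading.
* Candidates are generated from **every error-free k-mer** (default k = 15)
  of either mate on either strand and verified by direct comparison, with
  the partner mate sought by an exhaustive scan of the fragment-span window.
  With error-free reads every true placement contains a clean anchor, so the
  hit set is provably exhaustive (the test suite checks it against a
  sliding-window enumeration oracle); with errors, placements whose two
  mates both lack a clean k-mer can be missed — declared, not hidden.
* A **locus** is a distinct mate-1 placement `(chromosome, position)`:
  fragment-length variants and the two strand readings of a palindromic pair
  at one position collapse to one locus, keeping locus counts interpretable
  against the multimap cap. Among collapsed placements the lowest mismatch
  count is kept.
* A valid placement is FR-oriented with outer span in
  `[max(insert_min, L1, L2), insert_max]` (defaults 100–600 bp).
* **No best-hit selection exists**: all qualifying loci are retained up to
  the cap. Over-cap pairs (`TOO_MANY`) have their hits discarded and are
  counted as unmapped in every report, which keeps the report columns
  (unique / multiple / unmapped) a partition of processed reads. A pair in
  which only one mate has any qualifying placement is discarded whole.

`write_sam` / `ingest_alignments` provide a minimal SAM round trip (MAPQ
255, full-length `M` CIGARs, `NM`/`NH`/`HI` tags) so externally produced
name-collated alignments can flow through the same downstream accounting.

## Assignment strategies

*Sequential* (`assign_sequential`) is greedy by order: reads captured by the
first genome (unique or multi) never consult the second; only unmapped and
over-cap reads are forwarded. *Combined* (`assign_combined`) maps once
against the concatenated genome (chromosomes namespaced `host::` /
`parasite::`, a separator that survives SAM reference names) with the
multimap cap applied to the **joint** hit count — that is what a single
aligner invocation on a concatenated reference does. Reads with retained
hits on both sides are `TWO_SIDE`. The joint cap produces a documented
boundary effect: a read with, say, 6 valid loci per genome is `MULTI` for
the sequential first genome but over-cap (hence unmapped) for the combined
run. Away from that boundary the two designs provably agree: a read is
`TWO_SIDE` under the combined design iff both sequential orders capture it
in step 1 (property-tested).

## Labels, metrics and their conventions

Each assignment event carries a host-reference and a parasite-reference
label simultaneously (`S-TP_h1`/`S-TN_p1`, `S-FP_h1`/`S-FN_p1`, …, with the
numeric suffix recording the capture step; `C-…` for combined), so the
dualities TP_host = TN_parasite and FP_host = FN_parasite hold by
construction and are re-verified at tally time. Conventions, each isolated
and documented:

* The counting unit is the **read pair**; a discarded-mate pair is one
  unmapped unit.
* Reads unmapped in every genome are excluded from all four confusion
  cells — the metrics grade the separation of the reads that were mapped,
  and are thereby insensitive to overall mapping completeness.
* Combined-run `TWO_SIDE` reads count as FN for their origin organism and FP
  for the other (they reached the wrong genome). This is the single
  genuinely open convention; the `two_side_as_error` switch on
  `label_assignments` flips them out of the cells instead.
* 0/0 metric ratios are reported as missing (`None`), never as 0 or 1.

## Cross-mapping analysis

One-side sets: `S-FN_h2` reads of the host-first run (host reads rescued by
the parasite genome at step 2) and symmetrically `S-FN_p2`; for the combined
design, the `C-FN` sets minus the `TWO_SIDE` roster. These are remapped to
their own genome with the mismatch cap relaxed to 10; the recovery rate
distinguishes filter stringency from genuine absence of the locus (the
assembly-gap scenario). Empty sets yield a missing rate, not 0.

Two-side sets: sequential `S-TP_?1 ∩ S-FN_?1` intersections across the two
orders, and the combined `TWO_SIDE` roster split by true origin. Locus
summarization emulates union-mode feature counting with defaults as in
htseq-count: the union of annotated genes overlapped by all retained hits
(both mates) of a pair — exactly one gene counts for that gene, none is
`no_feature`, several is `ambiguous`; the three classes partition the read
set.

## Reports

Run tables carry the six category counts per (interaction, replicate,
strategy, order); the row sums equal processed reads by construction, and
"mapped" excludes `TWO_SIDE` (those reads are not assigned to a single
organism). Replicate averages recompute percentages as mean count / mean
processed — the only convention under which averaged counts and percentages
stay mutually consistent — with a 2-decimal "millions" rendering.
Per-replicate percentages print with 2 decimals, per-category columns as
whole numbers; both precisions are exposed. The flow table is a Sankey-style
edge list conserving totals at every node; rendering is out of scope.

## Problem sizes and numerical choices

The default study conditions (2 + 2 chromosomes × 10 genes × 600 bp,
divergence 0.05, conserved fraction 0.1, paralog fraction 0.1, private
fractions 0.2; 2000 + 1500 read pairs) are chosen so that every phenomenon
of interest — multimapping, both cross-mapping kinds, the cap boundary — is
present with counts large enough to be stable across seeds, while a full
pipeline run stays in the seconds range. The conserved fraction is
deliberately generous compared with real plant genomes: at desk scale the
organelle-like class must be visible in thousands, not tens of millions, of
reads. Consequently the absolute cross-mapping percentages are properties
of the synthetic design, not predictions for real genome pairs; what does
transfer are the structural results — the order-dependence of sequential
capture, the equivalence of the two designs within the cap, the monotone
decline of two-side cross-mapping with divergence, and the bit-exact table
arithmetic.

All randomness flows through `numpy.random.default_rng` from explicit seeds
carried in the spec objects; identical specs produce byte-identical FASTA,
GFF3, FASTQ and TSV outputs.

## Known limitations

* No indels, no splicing, no quality modeling, no expression heterogeneity
  beyond the optional per-gene weights.
* With sequencing errors the seed-and-extend search can miss placements in
  which both mates lack an error-free k-mer; exhaustiveness is only
  guaranteed (and only claimed) for error-free reads.
* The Hamming model cannot represent alignment-score gaps, so a real
  aligner's score-based suppression of a worse hit in the other genome has
  no analogue here; combined-run retention is purely mismatch-count-based.
* Homology structure is i.i.d. per class; real genomes have correlated
  divergence along genes and families, which the generator does not emulate.
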