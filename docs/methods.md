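# Methods

## Problem setting

3' expression arrays measure transcript abundance through sets of 25-mer
probes designed from EST consensus sequences that predate current genome
assemblies. Re-annotating the probes against an up-to-date, multi-database
transcript catalogue changes which probes are trustworthy and which
transcripts they interrogate. `remapkit` implements that re-annotation as a
deterministic pipeline: integrate annotations, define genes, classify and
regroup probes, and score alternative splicing from the regrouped probe
sets.

## Coordinate and identity conventions

All genomic coordinates are 0-based half-open, the native convention of
genePred and PSL; every output file states this in its header. PSL base
identity is computed as `matches / (matches + misMatches + repMatches)`,
with insertions excluded from the denominator. The alignment filter keeps
placements with identity ≥ `min_identity` (default 0.96); transcripts with
multiple surviving placements keep those within a per-source near-best
window of the best placement (defaults: RefSeq 0.001, GenBank 0.005, all
others 0, in identity fraction). Collections supplied directly as genePred
(Ensembl-style, pre-reconciled with the assembly) are exempt from the
identity filter unless alignments are given.

## Gene definitions

Genes are connected components of a pairwise linkage relation; clustering
is the transitive closure, so the result is independent of input order.
Four rules are implemented:

* **exlink** — some CDS-clipped exon interval of one transcript overlaps
  (≥ 1 base) a CDS-clipped exon of the other. Non-coding transcripts
  (encoded as `cds_start == cds_end`) contribute nothing and become
  singletons under this rule.
* **overlap_0** — same test on full exons; the coarsest rule.
* **exbd** — the two transcripts share an exon with both boundaries
  identical; the most stringent rule.
* **itbd** — the transcripts share a splice-site coordinate. Splice sites
  are *polarity-typed*: an intron's left edge only matches another
  intron's left edge (likewise right edges). A donor and an acceptor that
  happen to share a coordinate are distinct splice sites; typing also makes
  "overlap_0 is coarsest" a theorem, because two exons ending (or starting)
  at the same coordinate necessarily overlap. A stricter variant requiring
  one fully shared intron (both edges) is available via
  `itbd_shared_intron=True`. Single-exon transcripts have no splice sites
  and are always itbd singletons.

Linkage is strand-restricted in every rule: overlapping antisense loci are
biologically distinct genes, and probe sense classification depends on the
distinction. Gene IDs are assigned by sorting clusters on
(chromosome, span start, span end, smallest member ID) and numbering
sequentially (`g000001`, ...), so IDs are reproducible and input-order
independent.

The optimized clustering uses hashing (exbd: exact exon keys; itbd: typed
splice-site keys) and a sorted interval sweep (exlink/overlap_0: transcripts
sharing a merged-overlap interval blob are exactly the connected components
of the interval-overlap graph). A brute-force all-pairs union-find oracle
(`synthetic_fixtures.naive_cluster`) is kept for cross-checking.

## Probe classification

Matching is exact 25-mer identity against either strand; probes containing
non-ACGT characters are unmatchable. Probes with no genomic placement are
offered junction rescue: each transcript's spliced sequence is assembled
from its exons (reverse-complemented on the minus strand) and scanned for
the probe and its reverse complement; matches name the transcripts they
occur in.

Classification applies a fixed precedence; the seven categories are
exhaustive and mutually exclusive, and their counts always sum to the
input probe total:

1. ≥ 2 genomic placements → **multiple genome matches**;
2. no placement after rescue → **no genome match**;
3. transcript signature spans ≥ 2 genes (including mixed-sense signatures,
   which under strand-restricted gene definitions always span two genes)
   → **multiple genes**;
4. empty signature but inside some gene span (either strand) →
   **intronic**;
5. empty signature otherwise → **intergenic**;
6. signature group smaller than `min_probes` → **under-populated set**;
7. otherwise → **good**.

A probe's signature is the set of transcripts whose exons *fully contain*
the 25-base interval; a probe partially overlapping an exon interrogates no
transcript. The minimum probe-set size defaults to 3 and means "keep sets
with ≥ 3 probes": the source protocol states the rule both as "more than 3"
and as removing "< 3 per set", and the accounting semantics are keyed to
the latter. Reverse-complement (antisense) probe sets are retained, flagged
`_RC`, and counted good by default; `drop_antisense` filters them through
the under-populated bucket (the "failed set formation" category) so that
the conservation invariant is preserved.

Probe sets are named `{gene_id}_{k}`, with `k` numbering a gene's sets by
the genomic start of each set's leftmost probe and `_RC` appended for
antisense sets. Outputs are byte-identical across runs and across input
orderings.

Two remappings of the same probe universe are compared gene-by-gene: genes
sharing ≥ 1 good probe are paired; a 1-1 pair is *Same* iff its good probes
are partitioned into identical sets (labels ignored), else *Diff*;
one-sided genes are *UniqueA*/*UniqueB*; a many-to-many component counts
once as *Diff* (the counting unit for such components is a design choice —
the source material does not define it).

## Splicing Index

For a gene with probe sets *i* and conditions *x* ∈ {1, 2}:
`NI_{i,x} = P_{i,x} / G_x` with `G_x` the unweighted mean of the gene's
probe-set condition means, and `SI_i = log2(NI_{i,1} / NI_{i,2})`. A gene
with ≥ 2 probe sets is called alternatively spliced when any
|SI_i| ≥ 0.5. Replicates are averaged per condition before normalization.
Consequences used as test invariants: mean of NI over a gene's sets is 1
per condition; SI is antisymmetric under condition swap; SI is invariant to
condition-wide rescaling; single-set genes have SI ≡ 0 and are ineligible.

Intensities are linear-scale and strictly positive at the interface
(the ratio form forces a convention); `from_log2`/`--log2-input` accept
log2 matrices and exponentiate. Gene-level signal weights each probe set
equally — weighting by probe count was rejected to keep "probe-set
expressions averaged" literal. The moderated t-test is out of scope:
`select_de` consumes externally computed p-values, adjusts them with
Benjamini–Hochberg (via statsmodels), and applies adjusted p < 0.05
(strict) with fold change ≥ 2 or ≤ 0.5 (inclusive).

## Synthetic worlds

The generator's defaults are a stated world, not tuning knobs. The default
world has 12 genes on one chromosome with 2–3 transcripts per gene, 3–5
exons of 120–240 bp, introns of 80–300 bp, and 400 bp intergenic gaps —
compact but proportioned like real vertebrate loci at toy scale. Five
probes are planted per filter category, with 3–4 probes per retained set,
mirroring the order of magnitude a per-gene slice of a real array would
show. Per-database dropout rates (GenBank 0.4, RefSeq 0.6, Ensembl 0.3)
reproduce the rank order of database completeness seen in real multi-source
catalogues (RefSeq smallest, the union largest). Expression uses baseline
log2 intensities ~ N(8, 1) (mid-range scanner signal), three replicates per
condition (the usual design for such experiments), multiplicative
log-normal noise with σ = 0.1 on the natural-log scale, a planted fold of 4
on one probe set of each alternatively spliced gene, and 30% of
multi-probe-set genes spliced.

Planted categories are constructed, not rejection-sampled: probes are cut
from the genome (or from junction flanks, or generated as random 25-mers),
then *verified* — every single-copy probe must occur exactly once in the
genome, duplicated-block probes exactly twice, junction and random probes
never (random probes also must not occur in any spliced sequence).
Violations raise rather than resample, so truth counts are exact and the
seed fully determines the output. Junction probes are planted on plus-strand
genes only (rescue itself is strand-agnostic and is tested on minus-strand
transcripts separately).

What a green fixture test does **not** establish: the generator uses
uniform random sequence (no repeat families, no GC structure, no
cross-hybridisation), perfect probe identity (no mismatch/thermodynamics
model), clean planted categories (no boundary-ambiguous probes), and
noise-free category construction. Published-scale numbers (a 249,752-probe
array against a real assembly) are checked only through their arithmetic:
the accounting and ratio semantics reproduce the printed totals,
percentages and per-gene averages when fed the printed category counts.

## Numerical and degenerate-input choices

* Good-probe percentages are reported to three decimals of a percentage.
* `filter_transcript_alignments` keeps multi-placement survivors under
  `@2`, `@3`… suffixes; integration resolves cross-database ID collisions
  by source-prefixing both colliding records.
* Empty inputs are legal everywhere they can be (empty PSL → empty list;
  integrating nothing → empty collection; zero genes → empty world).
* Zero or negative intensities, p-values outside [0, 1], mismatched vector
  lengths, arity errors in genePred, and hits referencing unknown probes
  are errors, not warnings.
* PSL blocks that abut on the target are merged into one exon (abutting
  alignment blocks are not introns).

## Known limitations

* The exact matcher scans the genome per 25-mer window; it is meant for
  desk-scale genomes (≤ a few Mb), not a full vertebrate assembly — real
  probe alignments can be supplied as precomputed hits instead.
* GTF/GFF3 ingestion is not implemented (genePred and PSL only).
* Binary chip-definition containers are out of scope; probe sets are
  emitted as flat TSVs.
* Comparison counts for many-to-many gene pairings are a convention (one
  *Diff* per component); alternative conventions would change the Diff
  column, not Same/Unique.
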