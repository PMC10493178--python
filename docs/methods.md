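# Methods

## Variant model and normalization

Every variant is one (chrom, pos, ref, alt) allele observation in VCF
coordinates (1-based, inclusive) with a class in {SNV, INSERTION, DELETION,
MNV}. Multi-allelic VCF records are split into one observation per ALT
allele before anything else runs, so every downstream count is per allele,
not per site. Alleles are reduced to minimal representation by trimming
shared trailing bases, then shared leading bases, always retaining one
anchor base when an allele would otherwise become empty; the position
advances by the number of leading bases removed. This is deliberately a
pure string operation — it never consults the reference, so a deletion
whose minimal form would require left-extension beyond the record
(e.g. REF `AG`, ALT `G`) is kept as given rather than re-anchored. The
operation is idempotent and preserves the placed genomic change, which the
suite verifies by applying both representations to embedding sequences.

Variant identity for all overlap and membership computations is the full
allele-aware key (chrom, pos, ref, alt). Position-only matching would merge
distinct ALT alleles at one site and was rejected; the choice matters for
replicate-concordance numbers and is therefore stated here.

FILTER semantics: `PASS` and `.` pass, anything else fails; by default only
passing records are kept (an explicit flag includes all). Multi-sample VCFs
attribute a variant to each sample column with a non-reference genotype
call. Symbolic and breakend ALTs are skipped and counted in the log —
structural variants are out of scope.

## Feature annotation

Gene models load from GTF (Ensembl dialect) or GFF3 via `gffutils` into an
interval-tree index; UTRs are derived from CDS vs. exon extents, so
explicit UTR lines are unnecessary. A variant's category is decided by
fixed precedence:

    exonic > splicing > UTR5 > UTR3 > intronic > upstream > downstream > intergenic

with these conventions:

- *exonic* = inside an exon and within the CDS span (any exon of a
  non-coding transcript is exonic);
- *splicing* = intronic and within `splice_window_bp` (default 2) of an
  exon/intron boundary;
- *upstream/downstream* = within `upstream_downstream_bp` (default 1000)
  of the transcript span, oriented by the transcript's strand;
- indels and MNVs are categorized by their anchor (leftmost) position, not
  by span overlap — deterministic and cheap, at the cost of occasionally
  labeling a boundary-spanning deletion by its start;
- when transcripts disagree, the highest-precedence category wins and all
  gene names achieving it are reported sorted; intergenic calls carry the
  nearest flanking gene(s) and distance.

The same precedence is implemented twice on purpose: once as interval-tree
queries (the production path) and once as whole-chromosome array painting
in the fixture generator. The two routes share no code, so their exact
agreement on random probes and exhaustive 1-bp scans is a meaningful check.

If VCF INFO already carries Annovar-style keys (`Func.refGene`,
`Gene.refGene`), a parse mode maps the Annovar vocabulary onto the one
above through a fixed table (`ncRNA_exonic` → exonic, etc.) instead of
re-annotating.

Known-sites membership (dbSNP-style) accepts BED (0-based half-open,
position match) or 1-based TSV (3 columns: position match; 5 columns:
position + allele match), auto-detected by extension.

## Summaries

All summaries are long-format tables with within-sample frequencies
(`count / sample total`); frequencies are never pooled across groups. Zero
denominators emit frequency 0. Replicate overlap enumerates all non-empty
subsets of a group's replicates and counts keys present in *exactly* that
subset; counts therefore sum to the union size. Plotting of overlap uses a
labelled region-count bar chart (counting itself has no set-size cap).
Driver-gene tallies count only variants whose category places them inside
the gene body (exonic/splicing/UTR/intronic) — upstream, downstream and
intergenic calls name nearby genes without the variant being in them.
Default indel bins are {1, 2, 3, 4–5, 6–10, >10}; default genome windows
are 1 Mb, with chromosome sizes from a chrom.sizes file or the FASTA index.

## SBS96 and signature extraction

Channels follow the conventional substitution-major, context-lexicographic
order (`A[C>A]A` … `T[T>G]T`). Purine-reference SNVs are reverse-
complemented so the reported reference base is a pyrimidine. SNVs at the
first or last base of a chromosome, or with an N in the trinucleotide
context, are dropped and counted per sample; column sums plus drops always
equal the sample's SNV total.

De-novo extraction minimizes the generalized Kullback–Leibler divergence
D(V‖WH) by multiplicative updates, the standard choice for count data.
Defaults: 10 random restarts (best objective kept), 2000 iterations
maximum, relative objective tolerance 1e-8 checked every 10 iterations, all
randomness from one seeded generator so results are bit-reproducible.
Signatures are rescaled column-stochastic with the scale absorbed into
exposures, so exposures are attributed mutation counts. NMF (rather than a
topic-model formulation) was chosen as the simplest estimator matching the
count likelihood; the suite cross-checks the attained objective against an
independent KL-NMF implementation. Rank `k` is user-supplied; a scan mode
reports reconstruction error and restart stability per candidate rank
without auto-selecting, since rank choice is a judgment call. Refitting
against a fixed catalog is per-sample non-negative least squares; no
hypermutator filtering or sample exclusion is applied.

## Synthetic fixtures: what they emulate and what they do not

The generator emulates the *structure* of a replicated cancer-cohort
analysis at desk scale: a uniform-random ACGT genome (default 2 × 150 kb),
12 non-overlapping coding genes with 1–3 transcripts and 2–6 exons each
(UTRs on both ends), and cohorts of 2 groups × 3 replicates × 2000
variants. Study conditions are planted, not sampled: the class mix
(78% SNV / 10% insertion / 10% deletion / 2% MNV), 6-class spectrum
(C>T-dominated, 0.40/0.25/…), indel-length distribution (heavy at 1–3 bp
with a >10 bp tail) and feature-category placement are realized by
largest-remainder exact allocation, and each group is built as a 1400-key
shared core plus 600 private keys per replicate. The manifest records every
planted quantity, which makes count-level summaries testable with zero
tolerance. Only the signature studies sample: planted mixtures of 4
block-separated synthetic signatures (pairwise cosine ≤ 0.3, 30 samples,
5000 mutations each) are Poisson-noised at the SBS96-matrix level.

What passing these tests does **not** show about real data: real genomes
have repeats, N runs, GC structure and overlapping genes; real cohorts have
representation-dependent indel calls, caller-specific FILTER vocabularies,
and replicate overlap that is nowhere near clean core-plus-private; real
signatures are far less separated than the synthetic catalog, and NMF
recovery at cosine ≥ 0.95 under these favorable conditions is an upper
bound on what noisy, collinear real catalogs allow.

Problem sizes throughout (2 × 150 kb genome, 2000 variants/sample, 30
samples for signature studies) were chosen as the smallest at which every
planted structure is comfortably feasible and sampling error is small; all
are parameters, not constants.

## Numerical and degenerate-input choices

- Frequencies: exact integer counts divided by totals; tables assert
  per-sample sums of 1 within 1e-9.
- NMF guards: entries floored at 1e-12 inside updates; all-zero matrices
  are a degenerate-input error; `k` must not exceed min(96, n_samples).
- Ties: gene rankings break count ties lexicographically; equal-precedence
  gene names are sorted; largest-remainder ties resolve in dictionary
  insertion order (deterministic).
- Atomic output: every CLI table is written to a temp file and renamed, so
  failed runs leave no partial outputs; exit status 2 = configuration
  error, 1 = data error.

## Known limitations

No BCF, no phased genotypes, no structural variants, no amino-acid
consequence calling, no ID/DBS signature channels, no transcription-strand
bias, no built-in COSMIC catalog (catalogs are user-supplied files), and no
between-group statistical testing. Deletion annotation by anchor position
can differ from span-overlap annotation at feature boundaries.
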