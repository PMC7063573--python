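# Methods

## Scope and data model

The package starts from aligned reads (plain-text SAM with CIGAR strings);
alignment itself is out of scope. All coordinates are 1-based inclusive.
Gene models carry one transcript per gene (exon intervals in genomic order,
transcript-relative CDS bounds); on the minus strand exon ordinal 1 is the
genomically last exon. Hard clips consume neither query nor reference, soft
clips consume query only.

## Edit genotyping

A read *spans* a guide site when its reference footprint (outer aligned
span; deletions still cover the reference) contains the window
`[cut − w, cut + w]`. The default half-width `w = 15` bp covers the indel
spread around a Cas9 cut while staying inside one exon of the toy genes; it
is configurable per site. Walking the CIGAR over the window yields an
allele: I/D ops intersecting the window and contiguous mismatch runs are
collected into a canonical allele string (`ins@pos:SEQ`, `del@a-b`,
`sub@pos:REF>ALT`, joined for compound alleles). A read spliced (N op)
across the window carries no sequence evidence there and is excluded from
calling but still counted as spanning.

Calls aggregate per identical allele string. A site is **edited** when some
allele reaches `min_support` reads. `min_support` applies per allele, not
to the pooled deviant count: two different single-read discrepancies are
not replicated evidence of one editing event. The default
`min_support = 1` keeps the any-deviant-read behaviour of manual read
inspection.

`max_error_frac` (default 0, i.e. off) addresses sequencing error:
substitution-only alleles supported by at most that fraction of spanning
reads are attributed to base-call error and ignored. Indel-containing
alleles are never filtered this way because base-call errors are
substitutions. Under the error-rate study condition (1% per-base error,
depth 30) the analysis uses `min_support = 2, max_error_frac = 0.1`: a
false edited call then requires ≥ 4 reads with the same error position and
base, which has negligible probability, while true alleles are carried by
essentially all spanning reads.

**Large deletions** (> 10 kb between two cut sites) are called from split
alignments: a query whose records place one aligned block entirely at or
before the upstream cut and another at or after the downstream cut, with no
block in between. Single-record N gaps never qualify — those are spliced
reads. Both flanking sites are marked edited.

Cohort summaries exclude `no_coverage` samples from every denominator; the
overall row counts a sample edited if edited at any site. For whole-animal
bulk RNA-seq the read-level measure (deviant spanning reads over callable
spanning reads) is provided separately.

## ORF consequence

Genomic allele ops are projected onto the wildtype transcript
(strand-aware; inserted/substituted bases reverse-complemented on minus
strands; intronic pieces dropped with a warning) and applied in descending
transcript order. Translation uses the standard nuclear code
(stops TAA/TAG/TGA) from the wildtype start-codon position as projected
into the edited sequence. If the start codon is destroyed (edit or exon-1
skip) the next downstream ATG is used and the report flagged
`alternative_start`; with no ATG at all the protein length is 0
(`no_start`). `frameshift` is net inserted − deleted coding bases ≢ 0
(mod 3). `premature_stop` compares the first stop's offset with the
expected stop position (wildtype CDS length plus the net coding indel);
with an alternative start it degrades to "shorter than wildtype". A
transcript with no in-frame stop is flagged `ran_off_end` and not called
premature. Protein lengths exclude the stop codon, so for in-frame,
whole-codon deletions `relative_length = (3·aa_wt + net)/(3·aa_wt)`
exactly.

## Splice quantification

Every N op overlapping a gene produces a junction keyed by
`(donor_end, acceptor_start)`; a multi-gap read contributes one count per
gap. Canonical means an exact match to a consecutive-exon boundary pair
(a `tolerance_bp` flag exists, default 0, since simulated and short-read
aligned junctions are base-precise). `from_exon(k)` mode restricts the
denominator to reads leaving exon k's donor; since a read has at most one
gap at that donor, junction-count arithmetic equals per-read counting
there. Genomic-amplicon reads carry no N ops and therefore never enter
splicing denominators. Zero denominators return NaN with a warning. The
inclusion rule for splice-informative samples (spliced evidence at more
than one junction) is implemented as ≥ 1 read at ≥ 2 distinct junctions, both thresholds
exposed.

## Expression quantification

A read counts for a gene when ≥ 1 aligned (M) base lands on a retained
exon; D/N segments are not overlap, supplementary records are skipped so a
split query counts once. Masking the guide-site exons (amplified from
genomic DNA) removes amplicon molecules from mRNA counts. Library size is
the per-sample count over the full, unmasked annotation — the text's
"sample library size" refers to the library, not the gene (switchable by
passing a different denominator). The effective length
`r·len_skip + (1 − r)·len_full` is applied only to genes with a declared
skip isoform; FPKM for masked genes is refused unless an effective length
is supplied explicitly.

## Single-cell QC, markers, statistics

MADs use the 1.4826 normal-consistency scaling on raw (not log) values.
Thresholds: library size and detected genes fail below
`median − 3·MAD`; spike-in count fraction fails above `median + 3·MAD`.
All three medians are taken over the whole dataset jointly (the filters are
not applied sequentially, which would change the medians). A zero MAD
degenerates the threshold to the median; this is warned and applied as
stated. At least 4 samples are required. Gene filtering keeps mean count
≥ 0.1 across all cells and drops exclusion-listed genes (unknown names
warn, not error). Empty wells are ordinary samples expected to fail QC.

Marker positivity defaults to FPKM > 0: with deep-well zero-inflated
libraries, any detected expression is the natural cut; the threshold is a
parameter. The log2 display transform uses offset 1 and is never used for
classification. Welch's t statistic and Satterthwaite df are computed
directly; p-values are two-sided from the t distribution. When both groups
have zero variance the comparison degenerates (t = 0, p = 1 for equal
means) with a warning.

## Synthetic data generator

The generator emulates targeted single-cell libraries: per sample, spliced
mRNA reads (75 bp, junction reads carrying N ops) plus genomic-amplicon
reads over each guide site (contiguous), with programmable per-site editing
probability, allele classes (indel 1–12 bp, substitution 1–3 bp by
default, or fixed specs including > 10 kb deletions emitted as split read
pairs), per-read aberrant-splice ratio, base-error rate (substitutions
only, never on allele-derived bases, so truth/call discordance is
attributable to the caller), lognormal library-size factors and a spike-in
read fraction. Default depths: 30 amplicon reads per site and an expected
60 mRNA reads per gene per sample, matching a deep-well protocol's
per-locus coverage at toy scale. Reads are emitted pre-aligned with
perfect alignment of the simulated allele.

The aberrant-splice ratio `r` is defined **per junction read**: a read
crossing the skip-donor boundary follows the aberrant acceptor with
probability `r`. Defining `r` per molecule instead would bias the
read-level estimator through isoform-length differences (for the toy
1342/1224-bp pair, a per-molecule 0.20 would be measured as ≈ 0.216); the
per-read definition keeps the read-level normalisation unbiased.
A consequence is that reads wholly inside the skipped exon are slightly
overrepresented relative to a physical isoform mixture.

Amplicon reads are placed so that every read spans the guide window —
modelling a targeted amplicon whose primers flank the site — so coverage of
the window never limits genotyping at the configured depth. Large-deletion
samples emit split reads instead of amplicons at the flanking sites, and
their mRNA lacks the exons inside the deleted span (aligned across the gap
with an N op, which is how an aligner reports cDNA across a genomic
deletion; these surface as aberrant junctions).

What the generator does **not** model: quality scores, PCR duplicates,
paired-end insert-size structure, alignment ambiguity or soft-clip noise at
indel edges, allele-specific expression, and minus-strand genes (toy genes
are plus-strand; strand handling elsewhere is tested on small fixtures).
Passing tests therefore demonstrate correctness of the CIGAR-level
arithmetic and the estimators under clean alignments, not robustness to
aligner artefacts on real data.

The companion count-matrix generator (for the QC/marker stages) draws
Poisson counts with lognormal per-cell size factors, constant-input
spike-ins (so low-content wells show high spike fractions), mitochondrial
genes, three groups with preset marker-combination probabilities (only the
first group contains triple-positive cells) and empty wells at ~1% depth.

## Determinism and numerics

A single integer seed fixes the entire simulation byte-for-byte
(per-sample generators are spawned as `default_rng([seed, i])`). Pipeline
tables are plain TSVs written in sorted order; reruns with the same config
are byte-identical. Junction matching and allele keys are exact string/
integer comparisons — no floating-point tolerances enter any call. Problem
sizes in the analysis drivers (24-sample cohort, 10,000 junction reads,
200-sample recovery cohorts) were chosen as the smallest sizes at which
binomial scatter is clearly separated from the effects being measured.

## Known limitations

- One transcript per gene; no isoform-aware quantification (no TPM, no EM).
- Substitution evidence cannot be separated from systematic sequencing
  error beyond the support-fraction heuristic; no base-quality model.
- The premature-stop call after an alternative start is heuristic (shorter
  than wildtype), since the wildtype stop position loses meaning there.
- `from_exon` splice mode expects plus-strand models (the minus-strand
  donor convention is not implemented; `all_junctions` mode is
  strand-agnostic).
- Paired-end mates are treated as independent evidence reads; there is no
  fragment-level deduplication beyond the SAM duplicate flag.
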