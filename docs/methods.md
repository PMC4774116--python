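# Methods

## Pipeline model

The profiler estimates the composition of the eukaryotic viral community in
a shotgun metagenome by assigning individual reads to known viral genomes.
Its core assumption is shared by all read-mapping profilers: a virus is
only detectable if a sufficiently similar genome is in the reference. The
stage order — candidate screening *before* any filtering — is a deliberate
performance choice: on real metagenomes the viral fraction is tiny, so an
inclusive first mapping pass reduces the working set to a small percentage
of the input and every subsequent stage operates on candidates only.

Reads are the counting unit throughout: paired-end input is consumed as two
parallel FASTQ files whose mates are processed independently, each
contributing one count. Quality encoding is fixed to Phred+33.

## Mapping

Both mapping stages use one internal seed-and-extend mapper:

- **Index** — canonical 21-mers (lexicographic min of k-mer and reverse
  complement) at every offset of every reference genome, both strands
  covered by canonicalization; windows containing N are skipped.
- **Extension** — each distinct seeded locus (accession, implied start,
  strand) is verified by an end-to-end alignment of the read against the
  reference window padded by 5 bp, computed with the bounded
  edit-distance routine of `edlib` (unit-cost substitutions and indels).
- **Acceptance** — a hit is kept when its error count is at most
  `max_error_rate × read_length` (default rate 0.1). Score is read length
  minus errors; all hits tied at the best score are reported.
- **Modes** — SCREEN (candidate selection) relaxes the error budget ×1.5 so
  screening can never discard a read the final assignment could place;
  ASSIGN picks exactly one genome per read, breaking multi-mapping ties by
  smallest accession. Tie-breaking by accession rather than at random keeps
  the whole pipeline deterministic: identical inputs give byte-identical
  outputs, and read order cannot change any count.

The seed size (21) makes the screen blind to reads whose best alignment
retains no exact 21 bp stretch — with a 10 % error budget on 100 bp reads
this is the regime above ~4–5 evenly spread errors. The error-rate
threshold is a tunable surfaced on the CLI.

## Quality trimming

End bases with Phred quality ≤ 2 are unreliable under Illumina's EAMMS
(End Anchored Max Scoring Segments) convention. Trimming removes the
maximal contiguous run of such bases from the 5′ and the 3′ end (interior
low-quality bases are kept), and discards reads left shorter than 60 bp.
The operation is idempotent and equivalent to keeping the longest window
whose terminal bases exceed the threshold; the test suite checks it against
a window-enumeration oracle. Whether trimming should touch the 5′ end at
all is genuinely ambiguous in the HMP-style protocols this mirrors
(BWA-style trimmers are 3′-only); the symmetric reading was chosen and is
the documented behavior.

## Decontamination

Human and bacterial reads are removed by the same two-stage tagger with
different reference sets:

- **Stage 1** — the fraction of the read's canonical 18-mers present in the
  contaminant index. Fraction ≥ 0.8: contaminant (fast accept). Fraction 0:
  clean, no second stage. The 0.8 threshold is a design choice: one
  mutation on a 100 bp read shadows at most 18 of its 83 18-mers
  (fraction ≈ 0.78), so near-identical reads are accepted without
  alignment while anything with a single divergent site falls through to
  verification.
- **Stage 2** — every matching 18-mer implies a reference window; the read
  is aligned end-to-end against each distinct window (±3 bp padding, enough
  for two indels) and tagged if any alignment has ≤ 2 errors. Because any
  read within 2 edits of a reference necessarily shares an exact 18-mer
  with it (pigeonhole on a 100 bp read), stage 2 decides exactly the rule
  "minimum edit distance to any contaminant window ≤ 2", which the tests
  verify against an exhaustive dynamic-programming oracle. The error type
  is not restricted: substitutions and indels both count one.

Reads shorter than 18 bp carry no k-mers and are reported clean; they
cannot occur after the 60 bp length filter.

## Mock-community simulator

The simulator is the validation harness's backbone and defines the study
conditions under which accuracy is measured:

- 100 bp reads drawn with replacement: source genome by normalized member
  weight, start position uniform, strand equiprobable.
- Reads are error-free by default; a per-base substitution rate and a
  configurable fraction of quality-2 tails (to exercise trimming) are off
  by default and enabled explicitly in robustness tests.
- Read IDs encode provenance (`accession|start|strand|serial`), so every
  downstream assignment can be audited against the truth.
- The ground truth is the *realized* per-source composition of the emitted
  reads, not the nominal weights — accuracy metrics therefore measure the
  pipeline, not multinomial sampling noise.

Synthetic genomes are i.i.d. base sequences at a chosen GC content. The
validation study uses 20 viral genomes of 8–25 kb at GC 0.45 across 6
genera and 3 families, a 150 kb human surrogate (GC 0.41) and three 100 kb
bacterial surrogates (GC 0.50); communities hold 50 000 reads with viral
weights spread unevenly over 2–10× (every species ≥ 1 % of viral reads)
and ≥ 60 % contaminant reads. These sizes keep a full five-community study
under a minute on one CPU while leaving every per-read decision (seeding,
extension, tagging) at full scale; real genomes are larger, which raises
index size and time roughly linearly but does not change any decision
rule. What synthetic data cannot show: homology *between* references and
contaminants (real viral and host genomes share repeats and integrated
elements; i.i.d. genomes share essentially nothing, so cross-tagging and
multi-mapping are rarer here than in practice), platform error profiles,
and coverage bias. Accuracy on these mocks is therefore an upper bound on
real-sample accuracy, exactly as mock-community validations generally are.

## Metrics

All metrics are computed over the union of predicted and true taxa with
absent entries as zero, making them symmetric in their two arguments.
"Within 1 % deviation" means absolute deviation ≤ 0.01 in relative-
abundance units (the comparison is inclusive, with a 1e-12 guard for float
rounding). RMSE is reported per community and as the mean over
communities. Sample clustering uses 1 − Spearman correlation as the
dissimilarity and Ward linkage directly on it; at species level only
species reaching 0.5 % abundance in ≥ 25 % of samples enter as features,
at family level all detected families do. Samples are sorted by identifier
before distance computation so leaf order is reproducible.

## Numerical and degenerate-input choices

- Relative abundances must sum to 1 within 1e-9 per level; zero totals
  yield empty tables rather than NaNs.
- Pearson correlation on a zero-variance vector is undefined and returned
  as NaN with a warning; a constant profile vector in clustering is fatal
  and names the sample.
- Abundance tables are written with 6 decimal places, rows ordered by
  descending count with lexicographic tie-break, so output files are
  byte-stable across runs.
- Zip input archives: only the first entry is read, with a warning if the
  archive holds more.

## Known limitations

- No SAM/BAM output, no local (soft-clipped) alignment, no adapter
  trimming, no Phred+64 autodetection.
- The screen cannot recover reads whose best alignment lacks an exact
  21-mer seed; deeply diverged viruses are invisible, as for any
  closed-reference profiler.
- Counting is at species resolution; strain-level records collapse to
  their species.
- The contaminant references bundled with the tests are synthetic
  surrogates; real analyses must supply genuine human/bacterial FASTA
  references (any FASTA is accepted).
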