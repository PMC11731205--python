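# Methods

## Model and assumptions

`tissense` treats initiation profiling in transcript space: every
coordinate is 0-based, half-open, on the sense strand of a spliced
transcript. Reads are assumed to come from an aligner run against a
transcriptome reference (one SAM reference per transcript); antisense,
secondary, supplementary and unmapped records are skipped and counted.
Splicing, genome-space coordinates and alignment itself are out of scope.

The signal model is the standard harringtonine picture: an initiating
ribosome is arrested with its P-site on the start codon, so a footprint's
5' end sits a read-length-dependent offset upstream of the TIS. Counts at
a nucleotide are modeled as negative binomial, NB(μ, k) with variance
μ + μ²/k, which absorbs the overdispersion of footprint coverage relative
to Poisson.

## P-site offsets

For each read length L with at least `min_reads_per_length` (default 100)
reads, the offset is the argmax over the search window (default 10–15 nt)
of the number of reads whose shifted 5' end lands on any of the three
nucleotides of an annotated CDS start codon, aggregated over coding
transcripts. The 3-nt target makes the score robust to ±1 nuclease-
trimming jitter; exact ties break deterministically to the smaller offset.
The per-length score profile is retained for audit. Offsets are global
per read length (not per transcript or per sample): standard practice, and
the quantity is a property of the nuclease digestion, not of the
transcript.

## TIS test

Candidates are all positions whose 3-mer is ATG or a near-cognate (the
nine single-substitution neighbours; configurable, near-cognates on by
default because uORFs frequently initiate at them). The tested statistic
is the 3-nt P-site sum over the codon — again tolerating ±1 jitter. A
candidate is reported when this sum reaches `min_count` (default 5), which
bounds the list size without changing the statistics (see below).

The background for a transcript is fitted on codon-binned counts after
masking every start-codon position ± `exclusion_radius` codons (default
1). Masking is defined by sequence alone — not by observed counts — so
under the null hypothesis the retained bins are an unbiased sample of the
elongation background; masking by count (e.g. only candidates passing
`min_count`) would preferentially remove high-count bins and bias μ
downward. For transcripts so dense in start codons that fewer than
`min_codons` (default 20) bins survive, the pipeline falls back to fitting
on all bins: unbiased under the null, and only conservative otherwise
(initiation signal then inflates the background mean).

Dispersion: the per-transcript moment estimate k = μ²/(var − μ) (floored
at 0.1; Poisson when var ≤ μ) is far too noisy at a few dozen bins to set
far-tail probabilities — calibration runs with per-transcript k gave a
family-wise null error rate of 0.12–0.20 at α = 0.05, versus 0.025 with
the true background. The pipeline therefore shares one robust size across
transcripts, the median of the per-transcript moment estimates, while
keeping the mean per transcript (`pool_dispersion`; the same information-
sharing idea that count-based differential-expression tools use). With
sharing, the measured null family-wise error is 0.01–0.05 depending on
scale. `fit_background` itself remains per-transcript so an alternative
GLM-style background can be substituted without touching the callers.

P-values are upper tails, p = P(X ≥ x) evaluated as the NB survival
function at x − 1 (so x = 0 gives p = 1). Benjamini–Hochberg runs across
the pooled candidates of a sample with the testing burden `n_tests` set to
the *total number of scanned start-codon positions*, not just the
candidates that passed `min_count`: the filtered-out positions necessarily
carry large p-values, so counting them in the multiplicity keeps the
procedure equivalent to testing everything while avoiding the cost.
Significance is q < α (default 0.05).

## ORF building, classification, resolution

A called TIS is extended codon-by-codon to the first TAA/TAG/TGA;
translation uses the standard genetic code with the initiator reported as
M regardless of a near-cognate start. ORFs that run off the transcript
without a stop are retained, flagged incomplete, counted in TIS tallies
but excluded from mean-length summaries. No minimum ORF length is imposed
by default.

Classes partition all calls by TIS position relative to the annotated CDS:
`lncRNA` (no CDS), `annotated` (TIS = CDS start), `upstream`,
`downstream`, and internal in/out-of-frame separated by
(TIS − cds_start) mod 3. An upstream-initiating ORF that overlaps the CDS
is still classed `upstream` by its TIS, with the overlap and relative
frame recorded separately — antigen catalogs sometimes label such ORFs
"out-of-frame", which is why matching never requires label equality.
When one TIS yields calls on several transcripts of a gene, the in-frame
ORF (annotated or internal in-frame) wins, then the longest peptide, then
the lexicographically smallest transcript id; grouping is by
(gene, TIS position), the transcript-space proxy for a shared genomic TIS.

## Antigen matching and sensitivity

The default detection criterion is peptide containment at gene level: an
antigen is detected in a sample when some significant ORF call on its gene
contains the epitope as a substring of the called peptide. This is
deliberately lenient about the exact initiating nucleotide (isoform and
near-cognate ambiguity); a strict `exact_tis` mode (expected TIS ±
tolerance on the stated transcript) is also exposed, and its detections
are a subset of containment's whenever the expected TIS initiates an
epitope-containing ORF. Antigens genotypically absent from a sample are
never detected there; the matrix constructor enforces detection ⇒
presence. Antigens sharing an encoding ORF collapse to one ORF-level row.

Sensitivity is 100 · detected/total per class and pooled, under
`any_sample` scope (detected in ≥1 sample, denominator = present in ≥1)
or `all_samples` (detected in all, denominator = present in all).
Percentages round half-away-from-zero to one decimal, matching how such
figures are conventionally printed. Expression strata default to bins
(<1, 1–10, >10 RPKM): 10 RPKM is the threshold at which detection of
conventional antigen ORFs saturates in published data, and 1 RPKM adds a
low-expression bin; ORFs whose gene lacks an expression value are tallied
separately rather than dropped.

## Synthetic data

The generator emulates the study design the pipeline targets: a
transcriptome of coding and lncRNA transcripts carrying planted ORFs of
every class with recorded coordinates, peptides and stops, and
harringtonine-style footprints over it.

* Architecture defaults: 40 coding + 8 lncRNA transcripts, 5'UTR 90–240
  nt, CDS 300–900 nt (multiples of 3), 3'UTR 60–240 nt — deliberately
  compact transcripts so the default study runs in seconds; planted ORF
  peptides 12–40 aa.
* Plants: upstream, downstream and lncRNA ORFs are self-contained
  cassettes (start codon, non-stop body, stop) placed at disjoint
  positions, so their peptides do not depend on surrounding random
  sequence; internal in-frame ORFs flip one CDS codon to ATG and share the
  CDS stop; internal out-of-frame ORFs write an ATG across a codon
  boundary under the constraint that the canonical frame stays stop-free,
  with the shifted frame terminating wherever it naturally terminates.
  Options: near-cognate starts for UTR cassettes, and uORFs overlapping
  the CDS out-of-frame.
* Expression is log-normal, 10^N(0.8, 0.8) RPKM-like (median ≈ 6, spanning
  roughly 0.1–1000). Footprint intensity per nucleotide is proportional to
  expression times `elongation_scale` (run-off is modeled only as this
  flat down-scaling; no positional decay); the three nucleotides of each
  active TIS codon get expression times `initiation_enrichment` instead.
  The enrichment magnitude is not quantified in the literature this
  emulates; the default of 20-fold is a plausible arrest strength and is a
  free parameter. Intensities are scaled to `total_reads` (default 100k),
  counts drawn NB with `nb_dispersion` = 5, read lengths 28–31 nt with
  offsets {28:12, 29:12, 30:12, 31:13}, and 5' ends that would fall before
  the transcript start are dropped and counted.

What the generator does *not* emulate: sequencing errors, UMIs, multi-
isoform genes, positional run-off decay, codon-level periodicity of
elongation signal, and reads from unannotated transcripts. Passing tests
therefore demonstrate correctness of the statistical machinery and
bookkeeping under the stated model, not robustness to alignment artifacts
or model misspecification in real libraries.

## Numerical and procedural choices

* NB survival functions come from scipy; an independent pmf-summation
  oracle agrees to 1e-9 across a (μ, k, x) grid.
* BH is implemented directly (to support `n_tests` larger than the list)
  and agrees with statsmodels on shared cases.
* Degenerate inputs: empty footprint sets give all-zero tracks and no
  candidates; a transcript shorter than one codon, or with too few
  background bins even unmasked, is skipped and logged; offset estimation
  with no sufficiently supported read length is an error advising deeper
  input; conservation (retained + dropped = input reads) is asserted on
  every track build.
* Determinism: generation and simulation are pure functions of the seed;
  per-sample seeds derive from the study seed; two runs of
  `tis-sense run-all` with the same config produce byte-identical TSVs.
  The `--threads` flag never affects results.

## Problem sizes used in validation

The test-bench study conditions are the generator defaults above; the
null-calibration study uses 8 coding + 2 lncRNA transcripts at 15k reads
per replicate × 200 replicates, and the oracle-equivalence sweep uses 100
transcripts. These sizes make the whole validation run in seconds while
leaving every per-class and per-stage check populated.

## Known limitations

* Out-of-frame ORF detection inherits the convolved-frame problem of
  initiation profiling; the simulator plants clean signals, so measured
  sensitivity there is optimistic relative to real data.
* The NB background is flat per transcript; structured elongation signal
  (pause sites, codon periodicity) would locally violate it.
* `exact_tis` matching requires the catalog's transcript choice to match
  the caller's; in transcript space there is no liftover to reconcile
  isoforms.
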