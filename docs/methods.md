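# Methods

`trnamod` detects tRNA modifications from nanopore direct-RNA sequencing by
analysing the per-read, per-position modification prediction scores that
pre-trained neural modification callers emit, rather than the neural models
themselves.  This note records the statistical procedures, the parameter
choices, the numerical conventions, and what the synthetic-data generator
does and does not emulate.

## Input model

A modification caller assigns, at every basecalled position of its
canonical base (e.g. U for the pseudouridine model), a discretized
probability score `floor(255*p)` on the integer scale 0-255.  Only scores
at or above an emission threshold — 12, i.e. `floor(255*0.05)` — are written
to the MM/ML base-modification tags, so a matched position may carry no
score; absence is itself informative (probability below 5%).  `trnamod`
decodes MM/ML tags through pysam's base-modification machinery and also
accepts a plain TSV sidecar (read_id, read_pos, mod_code, score) for
tag-free inputs.

References are mature tRNA sequences with the library's 5'/3' splint
adapters attached.  Adapters are user configuration (they are
ligation-protocol specific and never built in).  All reported coordinates
are 1-based positions on the tRNA body; adapters are excluded.  U and T are
accepted interchangeably and canonicalized to a DNA alphabet internally.

## Alignment and filtering

Reads are aligned all-against-all to the references with an affine-gap
Smith–Waterman–Gotoh local aligner and filtered by three rules: (i) per
read, only the reference(s) tied at the read's maximal alignment score are
kept (ties are flagged `multi_reference` and contribute to every tied
reference by default); (ii) reads with AS < 50 are excluded; (iii) only
full-length reads are kept.

Choices the procedure leaves open, fixed here:

- **Scoring scheme**: match +2, mismatch −1, gap open −2, gap extend −1,
  configurable.  A length-L gap costs `open + (L−1)·extend`.  The AS ≥ 50
  cutoff is scheme-relative and exposed in configuration.
- **Full length** is defined as the alignment's reference span covering the
  entire tRNA body (a configurable number of uncovered body bases is
  tolerated at each end, default 0).  Truncated nanopore tRNA reads
  otherwise bias per-site coverage.
- **Determinism**: the traceback starts at the maximal DP cell with the
  smallest reference end, then smallest read end, and prefers
  stop > diagonal > deletion > insertion at equal scores, so outputs are
  byte-reproducible.
- Direct RNA is single-stranded: reverse-strand alignments in pre-aligned
  input are discarded with a warning.

The aligner is validated against an independently written plain-Python DP
oracle and against Biopython's `PairwiseAligner` scores.

## Score extraction

Basecalled reads contain errors, so per-read scores are projected onto
reference coordinates through the filtered alignment and only *matched*
positions count: a mismatched read base carries no prediction score for the
reference canonical base, and insertions/deletions have no site.  Per site
the table records `n_matched` (filtered reads with a sequence match) and
the emitted scores (`n_scored <= n_matched`).

## On-label pseudouridine calling

The per-site modification fraction is

    f = N(reads with score > 204) / N(reads),     204 = 255 * 0.80,

a proxy for modification stoichiometry; sites with `f >= 0.2` are called
modified.  Conventions fixed here:

- The high-score comparison is strictly greater-than; the call boundary is
  inclusive (`>=` 0.2).  Both are configurable.
- **Denominator**: "all reads" is taken as all matched reads
  (`n_matched`), counting matched-but-unscored reads as unmodified, since
  an absent score means probability below 5%.  A `scored` mode
  (emitted scores only) is available because the choice is genuinely
  ambiguous; the operating characteristics differ and output metadata
  records the mode used.
- Minimum per-site coverage for a fraction record: 20 matched reads by
  default (configurable); fractions from a handful of reads are noise.

A threshold-selection curve (percentage of annotated vs non-annotated sites
detected as the cutoff varies) and a midrank ROC AUC support cutoff
calibration and benchmarking.

## Off-label detection by symmetric KL divergence

For any modification that perturbs a caller's score distribution — whether
or not the caller was trained for it — two samples (wild type vs knockout,
or wild type vs unmodified IVT RNA) are compared per site:

1. Emitted scores are binned into 10 equal-width half-open bins on
   [11, 256) (width 24.5).
2. Bins receive an additive pseudocount (default 1) before normalization:
   `probs = (counts + 1) / (n + 10)`.  The KL divergence is undefined on
   zero bins; the pseudocount is the minimal standard regularizer and its
   effect vanishes as counts grow (regression-tested at pseudocounts 1,
   0.1, 0.01).
3. The statistic is the symmetrized divergence
   `sym_KL = Σ P ln(P/Q) + Σ Q ln(Q/P)` in natural-log units (nats).  The
   log base scales all values uniformly; rankings and normalized values are
   base-independent.
4. Coverage gating is per tRNA per sample: sites are only compared on tRNAs
   with ≥ 100 filtered full-length reads in both samples, and each site
   needs ≥ 1 emitted score on both sides.  Gated-out sites are reported
   with `passed_coverage = False` rather than silently dropped.
5. For cross-tRNA or cross-model display, values are min-max normalized,
   by default per model across the compared tRNA set (per-tRNA grouping by
   flag).  A constant group normalizes to zeros with a warning.

Multi-model integration assigns each body position the divergence of the
model matching its canonical base (U → pseudouridine model, A → m6A,
C → m5C); G positions carry no score because no G-base model exists.

## Error-score outliers

An external per-position basecalling-error score table (one non-negative
score per reference position) is thresholded with Tukey's fences:
`score > Q3 + k·IQR` with `k = 1.5`, quantiles by linear interpolation
between order statistics (the common "type 7" estimator; the estimator is
configurable since the convention is not universal).  Reported calls must
also clear an absolute floor (`score >= 10`), which suppresses the tail of
ordinary error fluctuation.  The fence population is global across all
positions by default; a per-canonical-base scope is available because error
baselines differ by base identity, and the scope used is recorded in the
output.  The external error statistic itself is not reimplemented; a
clearly labelled non-equivalent internal fallback (arcsine-stabilized
per-site error-rate difference between two samples) exists so the caller
can run self-contained.

## Signal comparison

The basecaller's move table assigns each basecalled base a contiguous block
of raw signal samples whose length is a multiple of the model stride (6).
Per base, six values at indices `floor(i·L/6)`, i = 0..5 are subsampled, so
dwell-time variation cancels and every base contributes equally.  Only
aligned reference positions (matches and mismatches) enter the per-position
track; insertions have no reference position and deleted positions receive
nothing from that read.  Two samples are overlaid after one scalar vertical
shift per tRNA: the median across positions of the per-position difference
in median signal, computed as reference-sample minus shifted-sample and
*added to the second (mutant) sample*.  The sign convention is explicit in
the API and recorded in output metadata.  Signals are passed through in
arbitrary units; no picoampere calibration or further normalization is
applied.  Signals arrive as NPZ/TSV sidecars of (signal array, move
vector) per read.

## Synthetic data

The generator emulates every upstream input so the full pipeline runs
without sequencing data:

- **References**: random bodies of 65-95 nt (the mature tRNA length range)
  with random splint adapters of 24/30 nt.
- **Reads**: independent per-base substitution (0.03), insertion (0.01) and
  deletion (0.015) errors, and with probability 0.15 a 5' truncation that
  removes part of the body (truncated molecules are the principal artefact
  of direct tRNA sequencing and the target of the full-length rule).  These
  rates are fixed, direct-RNA-realistic defaults chosen once; they are not
  fitted to any dataset.
- **Scores**: discretized Beta mixtures.  Unmodified positions draw from
  Beta(1, 20) (mass near 0), on-label pseudouridine from Beta(20, 1) (mass
  near 1), and off-label "abnormal" modifications from
  0.5·Beta(4, 4) + 0.5·Beta(8, 2) (bimodal-intermediate).  The shapes
  reproduce the qualitative score-distribution classes of annotated,
  unannotated and otherwise-modified sites; they are deliberately not fits.
  Modification status is drawn per read with probability equal to the
  site's stoichiometry; optional neighbor interference redraws
  canonical-base neighbors' scores within a configurable offset when the
  site is modified, emulating cross-talk between adjacent modifications.
  Scores below the emission threshold are withheld from the emitted track
  but retained in the truth.
- **Tags**: MM/ML encoding (with '?' skip semantics) is hand-rolled in the
  generator, so the decode path (pysam) round-trips against an independent
  implementation.
- **Signals**: per-reference-position levels ~ N(100, 12) a.u. shared
  across reads, per-base dwell = stride × geometric(0.5) blocks, Gaussian
  noise (sd 3), optional per-site level shifts.

What the generator does **not** emulate: k-mer-dependent pore levels,
homopolymer-specific error modes, context-dependent caller biases,
base-quality correlation, or carrier/adapter chemistry artefacts.  Passing
tests therefore demonstrate the correctness and statistical behaviour of
the *procedures* under controlled conditions, not performance on real
sequencing runs.

## Problem sizes

Simulation-based tests and the acceptance script run at desk scale chosen
as the package's own test conditions: 1-3 references, 60-150 reads per
sample for pipeline runs, 500 reads for stoichiometry-recovery checks
(3 binomial standard errors), and 100 seeded replicates for the off-label
ranking study.  Oracle-equivalence checks use 500-1000 random cases each
plus exhaustive enumeration for small ROC inputs.

## Known limitations

- The AS ≥ 50 cutoff is reused as a default without re-deriving its
  calibration; it is only meaningful relative to the default scoring
  scheme.
- The fraction denominator ambiguity (matched vs scored) changes absolute
  fractions at sites with many sub-threshold reads; comparisons across
  samples should fix one mode.
- `sym_kl` has no significance calibration; it is a ranking statistic.
  Permutation p-values are an extension hook, not implemented.
- No G-base modification model exists, so G positions are blind spots of
  the integrated map.
- pod5 raw-signal files are not read directly; signals are supplied as
  NPZ/TSV sidecars.
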