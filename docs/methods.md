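# Methods

## Coordinates and harmonization

All internal coordinates are 0-based half-open `[start, end)`; every
dialect conversion happens at the reader boundary. A VCF `POS`/`END` pair
(both 1-based inclusive) maps to `(POS - 1, END)`; DGV-style 1-based
inclusive start/end maps to `(start - 1, end)`; BED enters verbatim. The
inverted length is therefore always `end - start`, and the two breakpoints
are operationalized as the first and the last inverted base (`start` and
`end - 1`).

SV producers disagree on whether `POS` anchors the first inverted base or
the base before the event. The default is first-base anchoring
(`start = POS - 1`), which matches how gnomAD-SV prints inversion
coordinates; `pos_anchor="preceding_base"` switches per reader. When
`INFO/END` is missing the reader falls back to `SVLEN`; a record with
neither is a hard error rather than a guess. The VCF reader is built on
cyvcf2 because it exposes `INFO/END` verbatim; htslib-based record objects
recompute the end from `SVLEN` for symbolic alleles, which silently shifts
the bound by one under first-base anchoring.

Records on contigs other than chr1–22, chrX, chrY are dropped and counted,
as are records failing the FILTER policy (default: keep `PASS` and `.`,
which the parser reports as one class) and non-inversion types. Exact
duplicate `(chrom, start, end)` triples within one callset are collapsed
to the first record, since the downstream redundancy analysis assumes set
semantics. The counters partition the input: kept + dropped-by-type +
dropped-by-contig + dropped-by-filter + dropped-by-duplicate + malformed =
total; this is asserted in tests and recorded in a JSON provenance sidecar.

## Intersection categories

For a gene span `[g.start, g.end)` and inversion breakpoints
`b1 = start`, `b2 = end - 1`, a breakpoint is *inside* the gene when
`g.start <= b <= g.end - 1` (closed on the base level, so a breakpoint on
the gene's first or last base counts as inside — a deterministic edge
policy). For every pair with at least one shared base:

* both breakpoints inside → **intragenic** (equivalently, inversion ⊆ gene);
* exactly one inside → **gene-disrupting**;
* neither inside → **gene-spanning**, which with positive overlap forces
  gene ⊆ inversion under half-open geometry.

The trichotomy is exhaustive and exclusive; the containment equivalences
are asserted as invariants. Pairs are evaluated per gene independently: an
inversion intragenic in gene A may simultaneously be gene-disrupting for
an overlapping gene B, and a single inversion spanning three genes yields
three records.

Intragenic events get exon/intron context against the canonical
transcript's blocks: counts of exon and intron blocks overlapped, a
`single_intron` flag (true iff the inversion is confined to one intron —
the class that can alter splicing while leaving every exon intact), and
the ordinals of overlapped introns numbered 5′→3′ in transcription
orientation (strand-aware; geometry itself is strand-agnostic).

Choosing breakpoints as first/last inverted base rather than the flanking
junction positions makes "intragenic ⇔ contained" exact; junction-anchored
definitions differ by one base on each side and would need a separate
containment rule.

## Fractional overlap and redundancy

`overlaps_fraction(a, b, f)` is true iff `overlap_length(a, b) >= f * |a|`.
The requirement applies to the query interval only (directional, mirroring
the `-f` semantics of the standard intersection tool); a reciprocal mode
is available behind a flag. The boundary uses `>=` and is evaluated in
exact rational arithmetic — `overlap * q >= p * |a|` with `f = p/q` — so a
50-base overlap of a 100-base query at f = 0.5 passes bit-stably. A float
`f` is interpreted as the decimal it prints as (0.05 means 1/20; the
nearest binary double is slightly larger and would silently fail exact
boundaries).

Cross-dataset redundancy supports two criteria: `exact` (identical
`(chrom, start, end)`) and `fraction` (≥ f of the query's length, default
0.5). Matching is existential — one partner suffices, no one-to-one
assignment — so `percent[a][b]` is the share of a's inversions with at
least one match in b. The matrix is generally asymmetric under the
fractional criterion (a short call half-covered by a long one does not
half-cover it back); exact matches are a subset of fractional matches for
any f ≤ 1. An inversion is *dataset-specific* when unmatched in every
other callset under the active criterion.

The indexed implementations (per-chromosome interval trees) are required
by the test suite to agree exactly, case by case, with brute-force
all-pairs scans kept in the package for that purpose.

## Frequency strata and the candidate cascade

Calls split at an allele-frequency threshold (default 0.05) into rare
(AF < t) and common (AF ≥ t, boundary inclusive on the common side);
calls without AF form an `unknown` stratum that is reported but excluded
from the rare/common percentage denominator, so missing data never
inflates the rare class.

The recessive-candidate cascade keeps (inversion, gene) pairs that are
(i) gene-disrupting or intragenic, (ii) in an OMIM phenotype-linked gene,
(iii) rare; it then flags pairs never observed homozygous (`n_homalt = 0`;
missing counts stay missing rather than defaulting either way) and
finally requires an AR inheritance mode. The funnel is reported at pair,
distinct-inversion and distinct-gene granularity because the interesting
claims mix the two (inversion counts vs gene counts); counts are
non-increasing down the stages by construction.

OMIM statuses partition genes into phenotype-linked, cataloged-without-
phenotype and not-in-OMIM. Free-text inheritance strings normalize through
a synonym map to {AR, AD, XLR, XLD, other}; a gene with phenotypes of
different modes carries the union of modes, counts once per mode in
distributions, and counts as an AR gene iff AR is among its modes. The
union rule is the permissive choice for multi-phenotype genes; the
alternative (per-phenotype records) would need phenotype-level input the
tables do not reliably carry.

## Statistics

* **Length summaries** are six-number summaries in kb with quantiles by
  linear interpolation (the "type 7" definition, the default of mainstream
  statistical environments); "type 6" is available behind a flag because
  published quartiles are definition-dependent.
* **Wilcoxon rank-sum** enumerates the exact null distribution of the
  rank sum (dynamic program over n-subsets of ranks) when there are no
  ties and n·m ≤ 10,000; otherwise it uses the tie-corrected normal
  approximation with continuity correction. Two-sided p is
  `min(1, 2·min(P≤, P≥))`.
* **Binomial tests** are exact; the two-sided p follows the
  minimum-likelihood ("small-P") rule — the sum of all outcome
  probabilities no larger than the observed one — matching the common
  default of statistical environments; central and one-sided alternatives
  are flags. One- vs two-sidedness is not always stated alongside
  published p-values, so the default is the documented choice here.
* **Over-representation** is a one-sided Fisher exact (hypergeometric
  upper tail) per gene set with Benjamini–Hochberg step-up adjustment
  across sets, as a self-contained stand-in for web enrichment services.
* **Inheritance distributions** count distinct phenotype-linked genes per
  mode within a category and test the AR gene count against the AR
  proportion of the full phenotype-linked background with the exact
  binomial test.

All of these are implemented from first principles (only the normal CDF
comes from scipy) and are cross-checked in the test suite against
independent oracles: full combinatorial enumeration for the rank-sum test,
closed forms for binomial/Fisher/BH, and scipy/statsmodels as external
references.

## Synthetic data generator

The generator emulates the statistical shape of the public callsets, not
their content:

* **Lengths.** Each built-in profile anchors the length quantile function
  at a published five-number summary (min, Q1, median, Q3, max in kb) and
  samples by inverse transform through a monotone cubic (PCHIP)
  interpolation in log space. The cubic passes exactly through the anchors
  while keeping the slope continuous; a piecewise-linear quantile function
  would put a slope discontinuity at Q3 (the jump toward the Mb-scale
  maxima) and make empirical quartiles needlessly noisy. A two-parameter
  log-normal (`mu = ln(median)`, `sigma = (ln Q3 - ln Q1)/(2·0.6745)`)
  remains for profiles specified only by quartiles — note the published
  quartiles are not log-symmetric, so no log-normal can match all three at
  once; that is why the anchored model is the default.
* **Allele frequencies.** A rare/common mixture: with probability
  `prop_rare` (default 0.989, the observed rare share) a log-uniform draw
  below the 5% threshold, else uniform on [0.05, 0.5]. Homozygote counts
  are zero with probability `prop_homalt_zero` (default 0.9). Profiles of
  sources that publish no frequencies set `with_af = False`.
* **Genes.** Non-overlapping multi-exon genes laid left to right with
  random intergenic gaps; exon counts uniform on a range, exon lengths
  uniform on 80–300 bp, intron lengths log-normal (clamped at 50 bp).
  OMIM status and inheritance-mode mixes are configurable synthetic
  defaults, not published constants.
* **Planted truth.** Category quotas are realized by construction: e.g. a
  single-intron intragenic event places both ends strictly inside one
  intron; a gene-disrupting event places one end in the gene and one in
  the adjacent intergenic gap, clipped so no second gene is touched. The
  intended labels are returned and must be recovered by classification
  with 100% accuracy — the pipeline's primary acceptance property.
  Background calls are placed uniformly (lengths truncated at the contig
  size by redrawing, so oversized draws do not pile up as identical
  whole-contig duplicates).
* **Determinism.** One numpy Generator per call, seeded explicitly;
  identical seeds give byte-identical outputs, including the emitted
  VCF/TSV files.

What the generator does *not* model: sequence context (no repeats, no
NAHR mechanism, no breakpoint microhomology), overlapping genes, real
chromosome lengths, linkage between frequency and length, or per-population
frequencies. Passing tests therefore demonstrate the correctness of the
interval logic, bookkeeping and statistics — not caller performance on
real reads.

## Problem sizes and numerical choices

The test suite and the acceptance script run oracle comparisons on ~1,000
random interval instances, classification oracles on a few hundred calls
against tens of genes, planted-truth recovery on 130 planted events, and
length-model calibration at n = 10,000 draws — sizes chosen so the whole
suite completes in seconds while keeping quantile sampling error a few
percent. Empty callsets, zero-length intervals, missing AF/homozygote
fields and degenerate test inputs (all-tied samples, empty gene universes)
are either handled with documented semantics or rejected with hard errors;
none are silently defaulted.

## Known limitations

* Gene models assume one canonical transcript per gene; isoform-level
  effects are out of scope.
* The FILTER policy cannot distinguish `PASS` from `.` (parser limitation,
  both mean "kept" under the default policy anyway).
* Breakpoint uncertainty (confidence intervals on POS/END) is ignored;
  matching is purely positional.
* The OMIM/Orphanet join is symbol/id-based; genes whose symbols collide
  resolve deterministically (lowest id) with a warning rather than a
  curated disambiguation.
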