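# Methods

## Cassette deconvolution

A pegRNA-ST cassette read pair is sliced at fixed offsets derived from the
library's (uniform) element lengths: read 1 carries protospacer, scaffold
and 3′ extension; read 2 carries the 55-nt surrogate target (ST), the 16-nt
pegRNA barcode and the 10-nt library barcode. Optional anchor search (exact
match of a fixed sequence, e.g. the shared scaffold, within a small window)
absorbs small indel offsets at the read start; reads whose anchor is absent
or that are too short are rejected with an explicit reason.

Each element is matched against the distinct library sequences for that
element by substitution (Hamming) distance, allowing up to
`floor(0.10 × length)` mismatches — "up to 10%" read as an inclusive bound.
`N` always counts as a mismatch. A match is *confident* only if the minimal
distance is within tolerance and achieved by a single distinct sequence;
ties never guess an identity. The ST is matched only by its 3′ suffix
(15 nt by default) so edited STs are not discarded — the programmed edit
sits away from the ST 3′ end in the supported designs.

A read is **assigned** to a pegRNA only when every element confidently
matches and all matches are consistent with exactly one library member.
When two or more confidently matched elements implicate *different*
pegRNAs the read is a **recombinant** (lentiviral template switching or
synthesis chimera) and is discarded; anything else is **unassigned**. The
four fates partition the input reads exactly. The spec-level rule
"all confidently matched elements agree" is implemented in this stricter
all-elements form because a read identified by a single element (e.g. only
its spacer) cannot be distinguished from a chimera whose remaining elements
are unreadable; this also matches how the processing is described for the
original screens.

ST editing is exact containment of the intended edit plus its two 5-nt
flanks (≥ 11 nt); the editing percentage is defined only for pegRNAs with at
least 10 ST reads. A sequencing error inside the core therefore undercounts
editing slightly — an accepted, conservative bias. Reads matching a pegRNA
whose ST is neither reference nor edited still count in the editing
denominator. No base-quality filtering is applied to cassette reads.
pegRNAs with > 5% "editing" in the negative-control sample (library without
prime editor) are excluded; a control percentage undefined for lack of
reads retains the pegRNA and logs a warning.

## Scoring

Counts from replicate samples of the same condition/timepoint are summed
before frequency computation; ST editing percentages are averaged across
replicates (each replicate weighs equally regardless of depth). Frequencies
are pseudocounted over all library pegRNAs surviving the negative-control
exclusion — the frequency/activity filters apply afterwards, as flags.
Default thresholds are 6×10⁻⁵ pre-selection frequency and 75% ST editing
(negative-selection configuration); enrichment-style screens typically run
at 1.0–1.4×10⁻⁴ and 5–25% depending on cell line, via `ScreenConfig`.

Two aggregation modes exist because one-condition and multi-condition
screens normalize at different levels:

* **single** — pegRNA scores are normalized to the neutral-pegRNA median,
  then averaged per variant;
* **multi** — per-condition variant means of unnormalized pegRNA scores are
  normalized to the per-condition neutral median, averaged across the
  conditions in which the variant scored (at least two required,
  unweighted), and normalized once more. Cell-line-specific scores average
  only the conditions of one cell line before the final normalization.

Any neutral-median normalization requires at least `min_neutral = 5`
defined neutral entries and errors otherwise. After the final
normalization the neutral median is exactly zero by construction.

## LoF classification and diagnostics

The null is a normal distribution fitted by moments (mean, SD with ddof 1)
to the neutral function scores; identical neutral scores (SD 0) are an
error. p-values are one-sided in the screen's selection direction by
default (a two-sided option exists); whether the original analyses were
one- or two-sided is not documented, and one-sided matches the directional
design of both depletion and enrichment screens. Benjamini-Hochberg runs
over all variants receiving a final function score; LoF requires q strictly
below the cutoff (0.05 default, 0.01 for stringent screens).

AUC is the rank-based probability that a random putative-LoF variant
outscores a random putative-neutral variant in the selection direction,
ties counting one half (equivalent to the Mann–Whitney statistic; verified
against exhaustive pairwise comparison and scikit-learn). The threshold
sweep re-filters, re-scores and re-measures AUC at each grid value; the
retained-pegRNA count is non-increasing in the threshold by construction.
The high-stringency search returns the smallest grid value of *mean
per-variant ST editing* above which the pLoF and pNeut score ranges are
disjoint ([min, max] intervals, both classes non-empty), or none.

## Endogenous-target analysis

ET count tables (variant × {ctrl, pre, post}, including a wildtype row so
per-sample frequencies have their natural denominator) are consumed as
produced by external amplicon counters; no alignment or variant calling is
done here. Exclusion precedence: not programmed by the library → control
frequency above 4×10⁻⁴ (site-specific error hotspot) → zero pre-selection
frequency → insufficient editing gain (log2 pre/ctrl below 1, inclusive
keep at exactly 1; enabled per config). Background subtraction floors at
zero; no pseudocounts are applied at the ET level, so a zero denominator
excludes the variant rather than inventing a ratio. Endogenous function
scores follow the same normalize–average–renormalize chain as pegRNA-based
scores. Duplicate samples are combined by averaging per-sample frequencies
(`mean_duplicate_frequencies`), not by summing counts. ST variant
frequencies use the whole-sample ST total as denominator (the fraction of
*all* STs carrying the variant).

## Synthetic screens

The generator emulates the structure the analysis assumes, with defaults
chosen once as representative study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_variants`, `pegrnas_per_variant` | 200, 4 (cap 9) | library layout |
| `mixture_weights/shapes` | 0.45 Beta(0.3, 3) + 0.55 Beta(5, 1.5) | bimodal per-pegRNA editing at day `t_ref` |
| `growth`, `t_ref` | 1.05/day, day 10 | editing accumulates as `min(1, e₀·growth^(t−t_ref))` |
| `fraction_lof` / `fraction_intermediate` | 0.25 / 0.15 | true-LoF (\|s\| = 2) and intermediate (\|s\| = 1) variant fractions |
| `selection_time` | 3 | effective selection doublings: edited cells grow by `2^(s·τ)` |
| `depth_per_sample`, `et_depth` | 5×10⁵, 10⁶ | sequencing depths |
| `recombination_frac` | 0.02 | ST + pegRNA-barcode block swapped with a random cassette (no measured value exists; free parameter) |
| `seq_error_rate` | 0.001/base | substitution errors only |
| `background_edit_rate` | 0.001 | negative-control "editing" |
| `abundance_sigma`, `growth_noise_sd` | 0.5, 0.2 (log2) | library skew; per-pegRNA clonal drift |

Selection acts multiplicatively on the *edited* subpopulation only —
unedited cells carry the pegRNA neutrally, which is exactly why the
analysis must filter on ST activity: an inactive pegRNA encoding a lethal
variant scores neutrally. The class fractions emulate a saturation screen
of essential coding regions, where a substantial minority of variants
(nonsense, canonical splice, some missense) is deleterious. Clonal drift is
drawn once per pegRNA per post-selection sample and shared between the
cassette counts and the ET counts, because both readouts sequence the same
cell population; this is what makes the two score sets correlate within the
neutral class, as they do in real data. The ET tables use the negative
control as the editing-gain baseline (the non-coding-screen form): with
editing clamped at 1, a day-over-day baseline would spuriously fail the
most active variants.

Same seed ⇒ byte-identical FASTQ (gzip headers are written with a zeroed
timestamp). Recombinant cassettes are emitted with the partner's unedited
ST. Not modeled: PCR duplicates, GC bias, indel errors, quality-score
variation (constant 'I').

Calibration studies (effect recovery, type-I error, power, threshold
monotonicity) run the generator at its defaults through the count-level
interface (`simulate_counts` / `analyze_simulated_screen`), the same
generative model without read rendering; read-level fidelity is checked
separately by emitting FASTQ with and without noise and requiring exact
reconstruction of emitted counts in the noiseless case. Problem sizes used
in the test suite and acceptance script (200 variants × 4 pegRNAs at depth
5×10⁵ for calibration; 10³–2×10⁴ reads for read-level checks) were chosen
as the package's own desk-scale defaults.

## What passing tests do and do not show

The simulator draws independent multinomial/binomial counts around a clean
abundance model. Real screens add PCR jackpotting, uneven coverage,
bottleneck drift beyond the lognormal term, position-dependent sequencing
error and pegRNA-specific editing artifacts. Recovery at the defaults
therefore demonstrates correctness of the estimators and calibration of the
statistics under the stated model, not performance guarantees on any
particular dataset. Known limitations: scores do not weight pegRNAs by
editing strength; hypomorphic alleles are not modeled as a separate class
in classification (they surface as intermediate scores); element extraction
assumes uniform element lengths per library; and the HGVS variant
identifiers are treated as opaque strings, with consequence classes taken
from the input annotation.
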