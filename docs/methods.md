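# Methods

## The scoring model

The screen encodes three sequence hallmarks of the yeast E3 ligase
San1 — pervasive intrinsic disorder, short embedded binding stretches,
and lysine suppression — into per-protein scores. Disorder and binding
propensity are consumed as per-residue input tracks in [0, 1] (a
consensus disorder annotation such as MobiDB's, and ANCHOR scores); the
package never predicts them from sequence, so results are conditional
on the predictor versions that produced the tracks.

**Thresholding.** A residue is disorder-positive or ANCHOR-positive
when its track value is strictly greater than the threshold (default
0.5 for both). Values exactly at the threshold are negative. All
downstream counts inherit this convention.

**Qualifying stretches.** Maximal runs of consecutive ANCHOR-positive
residues are detected first; a run qualifies as a binding stretch when
its length lies within the inclusive bounds `stretch_min..stretch_max`
(default 15–40, the lengths of San1's experimentally supported binding
regions). Qualification is a property of the *maximal* run: a maximal
run of, say, 150 positive residues contributes nothing, because no
15–40 sub-window of it is itself a maximal run. The alternative
(counting sub-windows) would let every long positive region contribute
and erase the upper bound's effect. No requirement is placed on the
disorder status of a stretch.

**Whole-protein statistics.** The disorder fraction and
ANCHOR-positive fraction are positive-residue counts divided by protein
length; the ANCHOR stretch score is the number of residues inside
qualifying stretches divided by protein length. The *initial score*
ranks proteins by `disorder_fraction × anchor_stretch_score`. This
global product requires high disorder over the whole chain and
therefore misses large proteins with one or more ordered domains —
the motivation for the windowed score.

**The sliding-window similarity score.** For window width `w`
(default 150, even by construction) and 0-based center `i`, the window
spans `[i − w/2, i + w/2)` and three quantities are computed over it:
the disorder-positive fraction `D(i)`; the fraction of window residues
covered by qualifying stretches `A(i)`; and the longest lysine-free
run within the window divided by `w`, `L(i)`. The per-position score
is the product `D·A·L` and the protein's similarity score is the
maximum over all valid centers. Stretch qualification is computed once
on the full protein and then intersected with each window, so a
stretch straddling a window boundary contributes its in-window
residues and its status cannot flicker with window placement.

**Window edge convention.** Valid centers are `i ∈ [w/2, n − w/2)`:
the score is undefined at exactly the first and last `w/2` positions
(75 for the default window), giving `n − w` valid centers. A protein
with no valid center (`n ≤ w`) is assigned score 0 with no best
window. With an even window a symmetric 75/75 edge rule and a defined
center at `n = w` are mutually exclusive; this package keeps the
symmetric edge rule, accepting that a protein of exactly window length
is not scored.

**Ties and determinism.** The best window is the leftmost center
achieving the maximum. Ranking is competition-style (tied scores share
the better rank, subsequent ranks are skipped) with protein id as the
deterministic secondary sort. Top-N cutoffs include all ids tied at
the boundary rank, and the realized set size is recorded, so overlap
counts remain well-defined under ties (an identical-parameter scan
preserves exactly N whenever the boundary is tie-free). Identical
inputs give bitwise-identical outputs; the sliding profile is computed
with prefix sums over integer counts, so it is exactly — not
approximately — equal to per-window recomputation, which the tests
enforce against an independent brute-force oracle.

**Monotonicity (tested properties).** Mutating any residue to lysine
never increases a protein's similarity score; raising any disorder
track value never decreases it; widening the stretch bounds never
decreases the ANCHOR stretch score.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `disorder_threshold` | 0.5 | strict cutoff on the consensus disorder track |
| `anchor_threshold` | 0.5 | strict cutoff on the ANCHOR track |
| `stretch_min`, `stretch_max` | 15, 40 | inclusive length bounds (residues) for qualifying stretches |
| `window` | 150 | sliding-window width (residues), even |

The window size trades sensitivity to long lysine-free stretches
(smaller windows dilute `L`) against the exclusion of small proteins
(anything of window length or shorter scores zero). The sensitivity
scan (`sensitivity_scan`) quantifies robustness: it rescores the whole
dataset under variant stretch bounds / window sizes and reports the
top-N overlap with the base parameterization.

## The synthetic generator

`generate_dataset(SyntheticSpec)` produces labeled datasets for
testing and benchmarking. Background proteins have: sequences drawn
i.i.d. with lysine probability 0.058 (approximate natural abundance)
and the other 19 residues uniform; a disorder track of
moving-average-smoothed Gaussian noise (width 11, sd 0.1) around a
baseline mean of 0.2, clipped to [0, 1]; and an ANCHOR track of
smoothed noise around 0.15 clipped to [0, 0.5] — deliberately capped
at the threshold so that the supra-threshold plateau runs planted on
top of it (Poisson-placed at 1 run per 100 residues, lengths uniform
in 5–50, values uniform in 0.6–0.95) are recovered by maximal-run
detection with their exact planted boundaries.

San1-like proteins additionally carry exactly one planted region
(default 150 residues): disorder mean raised to 0.9, ANCHOR plateaus
of lengths 20, 25 and 30 separated by sub-threshold gaps of at least
two residues, and a lysine-free sequence segment spanning the region.
By construction a window centered in the region has `D ≳ 0.9`,
`A = 0.5` and `L = 1`, so planted proteins score ≥ 0.4 while
background proteins — whose smoothed disorder essentially never
crosses 0.5 — score 0. Protein lengths are uniform in 200–600
residues so every planted region fits with margin.

`evaluate_recovery` measures how well ranking separates planted from
background proteins: the pairwise rank statistic (AUC; ties count one
half) and the fraction of planted proteins within the top `n_planted`
competition ranks.

**What the generator does and does not emulate.** It reproduces the
*track-level* structure the score reads — smooth disorder profiles
with region-level contrast, plateau-like binding-propensity runs,
controllable lysine composition — but not realistic amino-acid
composition beyond lysine frequency, no domain architecture, no
correlation between disorder and ANCHOR tracks, and background
disorder never reaches the levels of genuinely half-disordered real
proteins. Consequently the synthetic discrimination task is easier
than the real one: background proteins score exactly zero, and perfect
recovery on synthetic data demonstrates correctness of the scoring
machinery, not discriminative power on real proteomes. Scoring real
datasets additionally depends on the disorder/ANCHOR predictor
versions used to build the input tracks.

## Numerical and I/O conventions

- Internal coordinates are 0-based half-open; all files use 1-based
  inclusive positions. Conversion happens only in `io_tables`.
- Track tables round-trip bitwise (`%.17g` serialization, correctly
  rounded parsing); result tables round-trip to 6 significant digits.
- Sequences may contain `X`; it is never a lysine and carries whatever
  track values the input provides. The 20 standard residues plus `X`
  are the accepted alphabet; anything else is an input error naming
  the offending position.
- An interval consisting entirely of lysine has no lysine-free run;
  the longest-run search returns a documented zero-length sentinel at
  the interval start (making the window score 0) rather than raising.
- The annotated E3 table reader is driven by a column-mapping config
  (id, position, disorder, ANCHOR, optional residue/organism/name
  columns) so any long-format export dialect can be ingested; when no
  per-row residue column exists, sequences come from a companion
  FASTA.

## Problem sizes used in the test suite

The shipped tests run entirely on generated data: brute-force oracle
comparisons use 500 random proteins of length 100–400 (every window of
every protein checked exactly), each monotonicity property uses at
least 1000 random mutations, and the recovery benchmark uses the
default 200-protein study. The published-dataset statistics (80 yeast
and 563 human E3 ligases; San1 disorder fraction 0.78 and
ANCHOR-positive fraction 0.53; top-20 preservation of 17/20 under
5–35 stretch bounds) can be reproduced with the externally hosted
annotated E3 table placed at `data/e3_table_s1.xlsx`; that table is
not redistributed here, so the corresponding test reports failure in
its absence rather than silently passing.

## Known limitations

- The score is a screen, not a classifier: it has no null model and
  no significance calibration; overlap counts in the sensitivity scan
  are raw counts.
- Proteins of window length or shorter are invisible to the windowed
  score (by design; use the initial score for small proteins).
- The strict-inequality threshold convention means input tracks
  quantized exactly at 0.5 contribute nothing; shift the threshold
  slightly if a predictor emits exact 0.5 plateaus.
- SUMO-interacting motifs, domain annotations and ortholog
  conservation — all informative for interpreting candidates — are
  outside the score.
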