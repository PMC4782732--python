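# san1score

Screening protein datasets for San1-like sequence signatures.

San1 is a nuclear E3 ubiquitin-protein ligase of *Saccharomyces
cerevisiae* that recognizes misfolded substrates directly through its
own intrinsically disordered regions, without delegating recognition to
chaperones. Its sequence shows three hallmarks: pervasive intrinsic
disorder, short (15–40 residue) embedded stretches predicted by ANCHOR
to mediate binding within disordered regions, and remarkably long
segments containing no lysine — the residue most commonly targeted by
ubiquitination, whose absence is thought to protect the ligase from
auto-ubiquitination.

`san1score` turns these hallmarks into a quantitative screen. It
consumes protein sequences (FASTA) together with per-residue consensus
disorder and ANCHOR score tracks (the package does not re-implement the
predictors), and computes:

- **whole-protein statistics** — disorder fraction, ANCHOR-positive
  fraction, the *ANCHOR stretch score* (residues inside maximal
  ANCHOR-positive runs of qualifying length, normalized by protein
  length), and the initial ranking product `disorder × stretch score`;
- **the San1 similarity score** — for every residue *i* with a full
  `w = 150` window inside the protein, the product of three window
  quantities

  ```
  S(i) = D(i) · A(i) · L(i)
  D(i) = fraction of window residues with consensus disorder > 0.5
  A(i) = fraction of window residues inside ANCHOR-positive stretches of length 15–40
  L(i) = longest lysine-free run in the window / w
  ```

  summarized per protein as `max_i S(i)`. The score is undefined at the
  first and last `w/2 = 75` positions; proteins without a valid window
  center score 0;
- **ranking and sensitivity** — competition-ranked candidate tables,
  top-N extraction with tie-aware cutoffs, and a parameter-sensitivity
  scan reporting how many top-N candidates are preserved when the
  stretch bounds or window size change;
- **synthetic benchmarks** — labeled datasets with planted San1-like
  regions (high disorder, qualifying ANCHOR plateaus, lysine-free
  segments) over realistic background, so the whole pipeline is
  testable without any external data.

Intended users: computational biologists screening E3-ligase (or other
protein) datasets for disorder-mediated substrate-recognition
candidates, and anyone needing a reproducible sliding-window
disorder/binding/composition score.

## Worked example

Generate a small labeled benchmark, score it, and rank the candidates:

```
$ san1score simulate --out-dir data --n-background 30 --n-san1-like 3 --seed 4
wrote 33 proteins to data

$ san1score score --fasta data/sequences.fasta --tracks data/tracks.tsv --out-dir out
scored 33 proteins -> out/scores.tsv

$ head -5 out/scores.tsv
protein_id      score   center  window_start    window_end      disorder_frac   anchor_stretch_frac     kfree_frac
planted01       0.5     393     318     467     1       0.5     1
planted02       0.5     201     126     275     1       0.5     1
planted03       0.5     162     87      236     1       0.5     1
background01    0       76      1       150     0       0       0.3
```

Each row gives a protein's similarity score, the 1-based coordinates of
its best window, and the three component values there. `planted01`
scores 0.5: its best window is fully disordered (`disorder_frac 1`),
half-covered by qualifying ANCHOR stretches (`0.5` — the planted 20-,
25- and 30-residue plateaus), and entirely lysine-free (`kfree_frac 1`).
Background proteins score 0 because their windows contain no residues
above the disorder threshold, so at least one factor vanishes.

```
$ san1score rank --fasta data/sequences.fasta --tracks data/tracks.tsv --out-dir out --top-n 5
$ head -6 out/ranks.tsv
protein_id      score   rank
planted01       0.5     1
planted02       0.5     1
planted03       0.5     1
background01    0       4
background02    0       4
```

Ranking is competition-style (ties share the better rank; the next rank
is skipped), and all three planted proteins rank above every
background protein. `rank` also writes `scatter.tsv` with each
protein's whole-sequence disorder fraction and ANCHOR stretch score for
two-dimensional candidate plots, and

```
$ san1score sensitivity --fasta data/sequences.fasta --tracks data/tracks.tsv \
      --out overlaps.tsv --top-n 5 --variant stretch_min=5,stretch_max=35
```

reports how many of the top-N candidates survive a change of stretch
bounds. `san1score profile --protein-id planted01 ...` renders a
per-protein figure (disorder and ANCHOR curves, lysine tick marks,
best-window bar) plus the TSV of the plotted per-position scores.

All commands accept `--params params.yaml` and/or individual flags
(`--window`, `--stretch-min`, `--stretch-max`, `--disorder-threshold`,
`--anchor-threshold`) mirroring the `ScoreParams` fields.

The same operations are available as a library:

```python
from san1score import ScoreParams, SyntheticSpec, generate_dataset, \
    san1_similarity, evaluate_recovery

proteins, labels = generate_dataset(SyntheticSpec(seed=1))
results = [san1_similarity(p, ScoreParams()) for p in proteins]
print(evaluate_recovery(results, labels))
# RecoveryReport(separation=1.0, top_fraction=1.0, n_planted=20,
#                n_background=180, top_set_size=20)
```

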