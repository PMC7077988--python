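# cisgrammar

Tools for designing, quantifying and modeling massively parallel reporter
assay (MPRA) libraries built from combinations of pluripotency
transcription-factor binding sites (OCT4, SOX2, KLF4, ESRRB — O, S, K, E).

The scientific question is *cis*-regulatory grammar: do binding sites act
as independent, additive "billboard" contributions, or does the order,
orientation and spacing of sites change an enhancer's output?  The package
implements the complete computational workflow for attacking that question
with paired synthetic and genomic reporter libraries:

- **Library design** — exhaustive enumeration of every ordered arrangement
  of 2–4 distinct oriented sites (48 + 192 + 384 = 624 elements, id'd as
  e.g. `S-O-k-e`, capital = forward strand), oligo assembly into a 150-bp
  barcoded scaffold, restriction-site screening, barcode generation, and a
  "mini-spacer" library that swaps the constant sequence flanking the
  sites.
- **Genomic element selection** — PWM scanning with *exact* score
  p-values (dynamic programming over the discretized null score
  distribution), merging of nearby hits into clusters, selection of
  81–82-bp elements carrying exactly one site for each of three factors,
  and matched mutants that kill every site with two substitutions at its
  highest-information positions.
- **Biophysical predicted occupancy** — energy weight matrices
  ε(b, i) = RT·ln(f(consensus, i)/f(b, i)) and total occupancy
  P(Occ) = Σ_windows 1/(1 + e^{ΔG−μ}) over both strands, with saturation
  analysis over a grid of chemical potentials μ.
- **MPRA quantification** — barcode count filters (RNA ≥ 3 in every
  replicate, DNA ≥ 10), reads-per-million scaling, per-barcode RNA/DNA
  expression, basal normalization, and per-replicate Wilcoxon rank-sum
  activity calls with Bonferroni correction (exact conditional null for
  small samples, tie-corrected normal approximation otherwise).
- **Grammar features and models** — presence ("independent", 4 features)
  and positional ("independent + position", 20 features) encodings, a
  configurable genomic feature set (site affinities, spacings,
  occupancies, track overlaps), activity logos, spacing histograms,
  ChIP-overlap binning, and **iteratively reweighted random forests**
  (iRF): forests whose trees sample candidate features with probability
  proportional to the previous iteration's Gini importances, starting from
  uniform 1/p weights, for four iterations.
- **Synthetic data** — a first-class generator producing ground-truth
  grammars (additive log-activity with positional modifiers), barcode
  counts with log-normal library representation and negative-binomial
  noise (RNA mean ∝ DNA abundance × activity), and synthetic chromosomes
  with planted site clusters, so every stage is testable end to end.

The library is used from Python; the scripts in `examples/` are the tour.

## Worked example

`examples/06_irf_models.py` simulates the full 624-element library under a
planted grammar (site-count main effect; ESRRB favored, SOX2 penalized in
the last position), quantifies it, and compares the two encodings:

```
split: 312 train / 312 test

independent (4 features): held-out R^2 = 0.12
  top importances: S=0.68, O=0.27, K=0.04, E=0.01

independent_position (20 features): held-out R^2 = 0.84
  top importances: E@4=0.60, K@4=0.19, S@1=0.09, S@4=0.06
```

The independent encoding cannot distinguish between 4-mers (identical
composition), so its held-out R² is low; the positional encoding recovers
the planted effects — `E@4` (ESRRB in the last slot) dominates the
importance ranking — and predicts expression well.  That gap is the
signature of a positional grammar.

`examples/05_quantify_mpra.py` shows the quantification half:

```
simulated 5104 barcodes x (1 DNA + 3 RNA replicates)
barcodes surviving count filters: 5104/5104
basal normalized expression (by construction): 1.000
Spearman(planted activity, estimated expression) = 0.992
elements called active vs basal in all replicates: 607/624 (97%)
```

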