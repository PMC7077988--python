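# Methods

This note documents the models, conventions and numerical choices behind
`cisgrammar`, and what the synthetic-data generator does and does not
emulate.

## Motif models

A motif is stored as a position frequency matrix (PFM) over A, C, G, T.
Columns are normalized, a pseudocount (default 1e-3) is added to every
frequency, and columns are renormalized; the pseudocount exists because
the energy formula divides by per-base frequencies that can be zero in
count matrices.  Derived quantities:

- **PWM** (log-odds, bits): log2(f(b,i)/q(b)) against a background q
  (default uniform; overridable, since scanning tools differ here).
- **EWM** (energies, RT units with RT ≡ 1): ε(b,i) =
  ln(f(consensus,i)/f(b,i)).  The consensus base has energy 0 at every
  position and all entries are ≥ 0.  Working in dimensionless RT units
  lets energies be compared directly with the chemical-potential grid
  (0.5–12), which is likewise unitless.
- **Information content** (bits): 2 + Σ_b f·log2 f per position, in
  [0, 2]; 2 bits is approached but never attained with a positive
  pseudocount.

**Exact score p-values.** The null distribution of a window's log-odds
score under the background is computed by dynamic programming: each PWM
entry is rounded to a 1e-3-bit grid, and the per-position 4-point score
distributions are convolved.  Tail lookups are therefore exact up to the
discretization (a summed word score can move by at most L/2 bins relative
to its float value; tests budget for exactly that).  Scores above the
maximum attainable return the probability of the top word set — never 0 —
and scores below the minimum return 1.  Scanning applies the same binned
arithmetic to window scores, so threshold decisions and reported p-values
are mutually consistent.  The DP table is bounded by requiring motif
length ≤ 30.

Windows containing N are skipped when scanning (masked-genome input) and
assigned +∞ energy in occupancy (never occupied).  Coordinates are
0-based half-open everywhere in memory and in BED output.

## Predicted occupancy

Every window on both strands gets an energy ΔG (sum of EWM entries) and a
binding probability 1/(1 + e^{ΔG−μ}), where μ is the TF's chemical
potential — a proxy for active protein concentration.  Total P(Occ) sums
over all windows and both strands: it estimates the expected number of
bound molecules, so a three-site element saturates near P(Occ) = 3.
Design choices:

- Both strands are summed rather than max-collapsed.  A single physical
  site thus contributes a negligible second-strand term; the simple sum
  keeps occupancy strictly monotone in μ and reverse-complement
  invariant.
- Overlapping windows are all counted (no exclusion process).  With
  sharp, high-information matrices this does not affect saturation
  behavior.
- Per-factor defaults μ = 8 for SOX2/KLF4/ESRRB and μ = 10 for OCT4 (the
  shorter motif saturates later).
- The wild-type/mutant occupancy contrast (mutants strictly lower) holds
  at and below the working potentials.  Above saturation the logistic
  flattens: a doubly substituted site whose total penalty is below μ is
  still mostly bound, so at μ = 12 the contrast can collapse or invert
  for the softest matrix.  This is a property of the model, not an
  implementation artifact, and the tests pin μ ≤ 10.

"Predicted affinity" for the total-primary-affinity summary is the
scanner's log-odds score of each annotated site (an EWM-energy alternative
is available behind a flag).

## Library design

Element ids are orientation-aware strings (`S-O-k-e`); enumeration is
deterministic (k ascending, canonical TF order O, S, K, E, forward before
reverse), and counts follow Σ_k P(4,k)·2^k = 624.  Oligos are assembled
from a scaffold template with `[SEQ]`, `[FILL]`, `[BC]` slots; `[FILL]`
pads to the scaffold's fixed total length (150 bp; 161 bp for the
mini-spacer scaffold, which has no fill).  Restriction screening allows
the scaffold's intended cloning sites but rejects any occurrence (either
strand) touching a variable segment; barcodes whose junction context
creates a site are discarded and redrawn.  Barcodes are uniform random
9-mers screened for homopolymers ≥ 5, restriction sites, and pairwise
Hamming distance < 2.

**Site-killing mutations.** The two positions with the highest
information content (ties broken 5'-most) are changed to the
lowest-frequency base of that column (ties alphabetical; if the site
already carries that base, the next rarest is used so exactly two
positions always change).  Reverse-orientation sites are mutated through
the reverse-complement mapping.  Every mutant is rescanned at the
selection threshold; a surviving hit flags the result for review instead
of passing silently.  The tie-break conventions are this package's own.

**Mini-spacer library.** Alternative spacers are composition-preserving
shuffles of each block's flanks, screened so the shuffle neither destroys
the intended site nor creates a new one, block-pair junctions included.
Six elements × (4 alternatives + original) × 5 barcodes = 150 oligos.

**Bundled defaults are synthetic.** The shipped PFMs
(`data/synthetic_*.jaspar`) and 20-bp blocks are stand-ins built around
the field-standard consensus sites, with near-zero minor counts at core
positions (mismatch penalties ≈ 5–7 RT, IC ≈ 1.7 bits/position) so that
occupancy is site-dominated at the working potentials, as it is for real
pluripotency PWMs.  The synthetic KLF4 matrix uses an aperiodic G-rich
consensus (`GGGGCAAGA`) rather than a pure G-run: a G-run's shifted
self-alignments scan as overlapping hits at p ≤ 1e-3, which the selection
pipeline's overlap-exclusion rule then (correctly) rejects, so a pure-run
stand-in would make planted-cluster fixtures unrecoverable.  The KLF4
block applies the fifth-position-to-T cloning variant.  All operations
take user-supplied motifs/blocks/scaffolds via the config loader.

## Genomic selection

Hits (all four motifs, p ≤ 1e-3) are optionally restricted to within
100 bp of anchor peaks, merged single-linkage at edge-to-edge gaps
< 20 bp, and any cluster containing two overlapping hits is excluded
outright.  Clusters with exactly three sites for three distinct TFs are
expanded symmetrically about the motif span: equal pads on both sides,
giving 81 bp when the parity works out and 82 bp otherwise, so the span
stays exactly centered (this choice reproduces the 81–82-bp range
naturally).  Expanded sequences are rescanned and must return exactly
their three sites; elements containing restriction sites are dropped.
Selection is deterministic given the inputs.  Repeat/blacklist masking is
delegated to an optional input mask; anchor peaks are an input BED
(ChIP-seq processing is out of scope).

## MPRA quantification

Pipeline order: filter barcodes (every RNA replicate ≥ 3 raw counts, DNA
≥ 10 — "less than" removal, boundaries retained) → scale each column to
reads per million → per-barcode expression = RNA RPM / DNA RPM per
replicate → per-element mean over barcodes → divide by the basal
barcodes' mean in that replicate (so basal ≡ 1) → average replicates.
Ratios are averaged arithmetically and log2 applied only at reporting
time.  Elements that lose every barcode are reported as missing, not
dropped.  Expression is invariant to uniform rescaling of any single
column by construction.

The Wilcoxon rank-sum test uses midranks; for n1 + n2 ≤ 20 the exact
conditional null is computed by a subset-sum dynamic program over the
observed (doubled) ranks — identical to full enumeration, valid under
ties — and otherwise a tie-corrected normal approximation with continuity
correction.  Two-sided p-values count outcomes at least as far from the
null mean as observed.  Activity calls test each element's barcodes
against the basal barcodes per replicate, Bonferroni-correct with
n_tests = number of elements tested (overridable), and require
significance in **all** replicates (per-replicate-then-intersect, rather
than pooling barcodes across replicates).  Paired wild-type/mutant calls
test the matched barcode sets the same way.

## Grammar features and models

The `independent` encoding is 4 presence bits; `independent_position`
adds 16 TF × position indicators (20 columns, always).  The genomic
feature set is configuration-driven (the exact published column set is
not enumerable from the text): per-TF site affinities with the
`OSKE_TotalAffinity` sum, pairwise edge-to-edge spacings (−1 when a pair
is absent, keeping the matrix dense for tree models), wild-type and
mutant occupancies, additional-TF motif counts, and per-track overlap
indicators.  Quantile subsets (activity logos, labeled FASTA export) rank
by expression with ties broken by element id and take round(q·n) members,
so 25% of 384 four-site elements is exactly 96.

**iRF.** Feature reweighting is realized as weighted sampling of each
tree's candidate-feature subspace: every tree gets a bootstrap row sample
and an mtry-sized feature subset drawn without replacement with
probability proportional to the current weights (uniform 1/p in iteration
1); trees are standard CART (Gini for classification, variance reduction
for regression; mtry defaults ⌈√p⌉ / max(1, p/3)).  Per-iteration Gini
importances (total impurity decrease, mapped back to the full feature
space) are renormalized to become the next weights, for four iterations;
predictions come from the final forest.  Sampling per tree rather than
per split is the closest realization scikit-learn's tree API allows and
preserves the reweighting dynamics (uniform start, weight conservation,
concentration on stable predictors, no runaway on null features at
realistic forest sizes).  Classification labels use the
expression ≥ 3rd-quartile rule (linear-interpolation quantile, computed
from the data at hand, not a hard-coded cutoff).  All stochastic
operations take explicit seeds; evaluation reports R² (regression) or
trapezoidal AUROC and step-wise AUPRC with the underlying curves.

## Synthetic-data generator

**Truth model.** log activity = Σ β(TF) + Σ γ(TF, position) +
Σ δ(adjacent pair) + ε, ε ~ N(0, σ²); basal = 1.  The default preset
(site-count main effect β ≈ 0.45–0.6; γ(S,1) = +0.5, γ(E,4) = +1.0,
γ(S,4) = −1.0, γ(K,4) = +0.3; σ = 0.25) plants the qualitative pattern
the exhaustive 4-mer libraries reveal — more sites drive more expression,
with early-S/late-E positional bonuses — so model-recovery tests are
meaningful.  It is additive on the log scale by design; it does not
emulate thresholding/saturation of real enhancers, promoter-specific
effects, or sequence-level context.

**Count model.** Each barcode draws a log-normal abundance (library
representation bias, σ = 0.5); DNA counts are negative-binomial at the
DNA depth and RNA replicate counts at the RNA depth with mean ∝
abundance × activity (Var = m + φm², φ = 0.05; φ = 0 gives Poisson).
Defaults represent a realistically sized campaign: 8 barcodes/element, 112 basal
barcodes, 3 replicates, 20M DNA / 13M RNA reads.  The representation bias
is deliberately planted so that DNA normalization has something real to
remove.  The generator does not simulate reads (no sequencing errors, no
PCR jackpots), so barcode-rescue and error-tolerant matching are
untestable here — and exact-match counting is the contract anyway.

**Genome fixtures.** Three-site clusters (random TF triples, orientations
and gaps) are planted at well-separated offsets in random background.  In
clean mode the background is iteratively re-randomized wherever it (or
the deterministic all-mutant version of the genome) produces spurious
motif hits or restriction sites, touching only non-site bases — so
truth-aware recovery and mutant-verification tests are exact rather than
probabilistic.  Dirty mode (`clean_background=False`) leaves the
background untouched for false-positive-rate checks against the analytic
expectation ≈ 2·(L−w+1)·p per motif.

**What passing tests show.** Recovery of planted activities (Spearman
≥ 0.99 at full depths), calibrated false-positive rates after
Bonferroni, ≥ 90% power on 10-fold wild-type/mutant contrasts, and a
positional-vs-independent iRF gap ≥ 0.2 held-out R² demonstrate that the
pipeline's inference machinery is correct and well-calibrated under its
own generative assumptions.  They do not certify performance on real
MPRA data, where noise is heavier-tailed, activities are not log-additive
in site content, and real genomic context (chromatin, additional TFs)
drives most of the variance.

## Problem sizes

Default test and acceptance runs use the full 624-element synthetic
library at experiment-scale depths, 10-cluster synthetic genomes of 20 kb, and
50 wild-type/mutant pairs; forests use 500 trees (150+ in tests where
only weight stability matters).  These sizes were chosen so every check
runs in seconds while keeping the library and depth at full experimental
scale.

## Known limitations

- Single-motif energetics only: no TF–TF cooperativity, no dinucleotide
  background, no concentration fitting from data.
- The p-value DP is exact only up to its discretization bin; two words
  whose float scores straddle a bin edge can swap order.
- Gapped-k-mer SVM training is external by design; the package only
  exports labeled FASTA for such tools.
- The bundled motifs/blocks are synthetic; results on them characterize
  the pipeline, not any particular biological TF.
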