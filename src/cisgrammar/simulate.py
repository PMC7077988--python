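"""Synthetic-data generation for end-to-end pipeline testing.

Generates (i) ground-truth element activities from an additive log-linear
grammar (per-TF effects, positional modifiers, optional adjacent-pair
interactions, log-normal context noise), (ii) barcode-level DNA/RNA count
tables with log-normal library representation and negative-binomial
sequencing noise in which the expected RNA count is proportional to DNA
abundance × element activity, and (iii) a synthetic genome with planted
three-site clusters for exercising the genomic selection pipeline.  The
defaults represent a realistic full-scale campaign: 8 barcodes per element, 112 basal
barcodes, 3 RNA replicates, sequencing depths of ~20M (DNA) and ~13M (RNA),
and a grammar preset with a site-count main effect plus early-S / late-E
positional bonuses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import BASES, revcomp
from .library_design import FORWARD, SynElement
from .motifs import MotifModel


# ------------------------------------------------------------------- truth


@dataclass
class GrammarTruth:
    """An additive log-scale grammar: activity = exp(Σβ + Σγ + Σδ + ε).

    ``beta`` holds per-TF main effects, ``gamma`` positional modifiers
    keyed by (TF, position), ``delta`` adjacent-pair interactions keyed by
    (left TF, right TF).  ``noise_sd`` is the context noise on the log
    scale; basal activity is 1 (all terms zero).
    """

    beta: dict[str, float] = field(default_factory=dict)
    gamma: dict[tuple[str, int], float] = field(default_factory=dict)
    delta: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_sd: float = 0.0

    def log_activity(self, element: SynElement) -> float:
        """Deterministic part of the element's log activity."""
        tfs = [tf for tf, _ in element.sites]
        total = sum(self.beta.get(tf, 0.0) for tf in tfs)
        total += sum(self.gamma.get((tf, p), 0.0) for p, tf in enumerate(tfs, start=1))
        total += sum(self.delta.get((a, b), 0.0) for a, b in zip(tfs, tfs[1:]))
        return total


def default_grammar(noise_sd: float = 0.25) -> GrammarTruth:
    """Preset planting the canonical qualitative grammar.

    Site count dominates (β ≈ 0.45-0.6 per site, slightly TF-specific);
    positionally, S is favored early and penalized in the last position
    while E is strongly favored in position 4 — the pattern seen in the
    top/bottom activity logos of exhaustive 4-mer libraries.
    """
    return GrammarTruth(
        beta={"O": 0.60, "S": 0.55, "K": 0.50, "E": 0.45},
        gamma={("S", 1): 0.5, ("O", 1): 0.2, ("E", 4): 1.0, ("S", 4): -1.0, ("K", 4): 0.3},
        delta={},
        noise_sd=noise_sd,
    )


def simulate_truth(
    elements: Sequence[SynElement],
    grammar: GrammarTruth,
    seed: int = 0,
) -> pd.DataFrame:
    """Planted activities with the generative decomposition recorded.

    Returns a frame indexed by element_id with columns ``log_main``
    (deterministic part), ``log_noise``, and ``activity`` =
    exp(log_main + log_noise) > 0.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    known = set(grammar.beta)
    rows = []
    for el in elements:
        for tf, _ in el.sites:
            if grammar.beta and tf not in known:
                raise ValueError(f"element TF {tf!r} outside the grammar's TF set")
        main = grammar.log_activity(el)
        noise = rng.normal(0.0, grammar.noise_sd) if grammar.noise_sd > 0 else 0.0
        rows.append((el.element_id, main, noise, float(np.exp(main + noise))))
    return pd.DataFrame(
        rows, columns=["element_id", "log_main", "log_noise", "activity"]
    ).set_index("element_id")


# ------------------------------------------------------------------- counts


@dataclass
class CountSimConfig:
    """Full-experiment-scale defaults for the barcode-count generator."""

    barcodes_per_element: int = 8
    basal_barcodes: int = 112
    replicates: int = 3
    dna_depth: float = 20e6
    rna_depth: float = 13e6
    dna_dispersion: float = 0.05
    rna_dispersion: float = 0.05
    representation_sd: float = 0.5  # log-normal spread of barcode abundance
    seed: int = 0

    def __post_init__(self):
        if self.dna_depth <= 0 or self.rna_depth <= 0:
            raise ValueError("depths must be > 0")
        if self.dna_dispersion < 0 or self.rna_dispersion < 0:
            raise ValueError("dispersion must be >= 0 (0 = Poisson)")


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with Var = m + dispersion·m²; 0 = Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    activities: pd.Series | Mapping[str, float],
    config: CountSimConfig | None = None,
    roles: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Barcode-level CountTable for planted element activities.

    Each barcode gets a log-normal DNA abundance (library representation
    bias); DNA counts are negative-binomial at the DNA depth, RNA replicate
    counts at the RNA depth with mean proportional to abundance × element
    activity.  ``basal_barcodes`` extra barcodes with activity 1 and role
    ``basal`` are appended.  Identical config (incl. seed) reproduces the
    table exactly.
    """
    if config is None:
        config = CountSimConfig()
    acts = pd.Series(activities, dtype=float)
    if (acts <= 0).any():
        raise ValueError("activities must be > 0")
    rng = np.random.default_rng(config.seed)

    element_ids = list(acts.index) + ["basal"]
    n_bc = [config.barcodes_per_element] * len(acts) + [config.basal_barcodes]
    act_values = list(acts.values) + [1.0]

    rows_element, rows_barcode, rows_role, rows_act = [], [], [], []
    for eid, nb, a in zip(element_ids, n_bc, act_values):
        role = "basal" if eid == "basal" else (roles or {}).get(eid, "syn")
        for j in range(nb):
            rows_element.append(eid)
            rows_barcode.append(f"{eid}|bc{j + 1}")
            rows_role.append(role)
            rows_act.append(a)
    abundance = rng.lognormal(0.0, config.representation_sd, size=len(rows_barcode))
    act_arr = np.asarray(rows_act)

    dna_mean = abundance / abundance.sum() * config.dna_depth
    if dna_mean.min() < 1:
        import warnings

        warnings.warn("DNA depth too low to expect >=1 count per barcode", stacklevel=2)
    out = pd.DataFrame(
        {"barcode": rows_barcode, "element_id": rows_element, "role": rows_role}
    )
    out["dna"] = _nb_sample(rng, dna_mean, config.dna_dispersion)
    rna_weight = abundance * act_arr
    rna_mean = rna_weight / rna_weight.sum() * config.rna_depth
    for rep in range(1, config.replicates + 1):
        out[f"rna_{rep}"] = _nb_sample(rng, rna_mean, config.rna_dispersion)
    return out


# ------------------------------------------------------------------- genome


def simulate_genome(
    n_clusters: int,
    motifs: Mapping[str, MotifModel],
    background_length: int = 20000,
    seed: int = 0,
    gap_range: tuple[int, int] = (5, 15),
    site_sequences: Mapping[str, str] | None = None,
    clean_background: bool = True,
    p_threshold: float = 1e-3,
    chrom: str = "chrS",
) -> tuple[dict[str, str], pd.DataFrame, pd.DataFrame]:
    """A synthetic chromosome with planted three-site clusters.

    Clusters of three distinct TF sites (random orientation, edge-to-edge
    gaps drawn from ``gap_range``, below the 20-bp merge threshold by
    default) are planted at well-separated offsets in random background.
    ``site_sequences`` defaults to each motif's consensus.  With
    ``clean_background`` the background is iteratively re-randomized
    wherever it produces spurious motif hits, so truth-aware recovery tests
    are exact.  Returns (sequences, truth sites frame, anchor-peak frame).
    """
    rng = np.random.default_rng(seed)
    tf_names = sorted(motifs)
    sites = {tf: (site_sequences or {}).get(tf, motifs[tf].consensus) for tf in tf_names}
    max_cluster = 3 * max(len(s) for s in sites.values()) + 2 * gap_range[1]
    slot = background_length // max(n_clusters, 1) if n_clusters else background_length
    if n_clusters and slot < max_cluster + 40:
        raise ValueError(
            f"{n_clusters} clusters do not fit in {background_length} bp of background"
        )
    seq = list("".join(BASES[c] for c in rng.integers(0, 4, size=background_length)))
    truth_rows = []
    anchor_rows = []
    planted_spans: list[tuple[int, int]] = []
    for ci in range(n_clusters):
        tfs = list(rng.choice(tf_names, size=3, replace=False))
        gaps = [int(rng.integers(gap_range[0], gap_range[1] + 1)) for _ in range(2)]
        cluster_len = sum(len(sites[tf]) for tf in tfs) + sum(gaps)
        offset = ci * slot + int(rng.integers(20, slot - cluster_len - 20))
        pos = offset
        for i, tf in enumerate(tfs):
            word = sites[tf]
            strand = "+" if rng.random() < 0.5 else "-"
            planted = word if strand == "+" else revcomp(word)
            seq[pos : pos + len(word)] = list(planted)
            truth_rows.append((chrom, pos, pos + len(word), tf, strand, ci))
            pos += len(word)
            if i < 2:
                pos += gaps[i]
        planted_spans.append((offset, pos))
        anchor_rows.append((chrom, max(0, offset - 50), min(background_length, pos + 50)))

    genome = "".join(seq)
    if clean_background:
        # a parallel genome carrying the deterministic site-killing mutants;
        # scrubbing against both guarantees mutant rescans also come up empty
        from .library_design import REVERSE, design_mutant_site

        seq_mut = list(seq)
        for _, s, e, tf, strand, _ in truth_rows:
            mut = design_mutant_site(
                genome[s:e], motifs[tf],
                orientation=FORWARD if strand == "+" else REVERSE,
                p_threshold=p_threshold,
            )
            seq_mut[s:e] = list(mut.sequence)
        site_spans = [(s, e) for _, s, e, _, _, _ in truth_rows]
        expected = {(s, e, tf) for _, s, e, tf, _, _ in truth_rows}
        genome = _scrub_background(
            seq, seq_mut, motifs, site_spans, expected, rng, p_threshold
        )
    sequences = {chrom: genome}
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "start", "end", "tf", "strand", "cluster"]
    )
    anchors = pd.DataFrame(anchor_rows, columns=["chrom", "start", "end"])
    return sequences, truth, anchors


def _scrub_background(
    seq: list[str],
    seq_mut: list[str],
    motifs: Mapping[str, MotifModel],
    site_spans: Sequence[tuple[int, int]],
    expected: set[tuple[int, int, str]],
    rng: np.random.Generator,
    p_threshold: float,
    max_rounds: int = 50,
) -> str:
    """Re-randomize background bases that create spurious motif hits.

    Only bases outside the planted site intervals are touched, so hits that
    span a site/background junction are broken without disturbing the
    planted sites.  Background edits are mirrored into the parallel
    mutant-site genome, and hits in either genome trigger scrambling, so a
    downstream mutant rescan is guaranteed to come up empty.  Restriction
    sites are cleared from the background as well (they would disqualify
    otherwise valid elements downstream).
    """
    from .library_design import DEFAULT_RESTRICTION_SITES

    protected = np.zeros(len(seq), dtype=bool)
    for s, e in site_spans:
        protected[s:e] = True

    def scramble(start: int, end: int) -> bool:
        free = [i for i in range(start, end) if not protected[i]]
        for i in free:
            base = BASES[rng.integers(0, 4)]
            seq[i] = base
            seq_mut[i] = base
        return bool(free)

    for _ in range(max_rounds):
        dirty = False
        for variant, exp in (("".join(seq), expected), ("".join(seq_mut), set())):
            for m in motifs.values():
                for h in m.scan(variant, p_threshold):
                    if (h.start, h.end, h.tf) in exp:
                        continue
                    if not scramble(h.start, h.end):
                        raise RuntimeError(
                            f"spurious {h.tf} hit at {h.start} lies entirely within planted sites"
                        )
                    dirty = True
            for site in DEFAULT_RESTRICTION_SITES.values():
                for probe in {site, revcomp(site)}:
                    start = variant.find(probe)
                    while start != -1:
                        if scramble(start, start + len(probe)):
                            dirty = True
                        start = variant.find(probe, start + 1)
        if not dirty:
            return "".join(seq)
    raise RuntimeError("could not scrub spurious hits from the background")


def simulate_paired_library(
    n_pairs: int,
    wt_activity: float = 10.0,
    mut_activity: float = 1.0,
    config: CountSimConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Matched wild-type/mutant count table for power analyses.

    Wild-type elements get ``wt_activity``, their matched mutants
    ``mut_activity`` (basal level), emulating genomic elements whose
    activity depends entirely on the planted sites.  Returns the CountTable
    and the wt -> mut pairing map.
    """
    acts = {}
    roles = {}
    paired = {}
    for i in range(1, n_pairs + 1):
        wt, mut = f"gwt_{i}", f"gmut_{i}"
        acts[wt] = wt_activity
        acts[mut] = mut_activity
        roles[wt] = "gwt"
        roles[mut] = "gmut"
        paired[wt] = mut
    table = simulate_counts(pd.Series(acts), config=config, roles=roles)
    return table, paired


def write_truth_table(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)
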