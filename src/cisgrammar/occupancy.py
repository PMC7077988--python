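"""Biophysical predicted occupancy of sequences by transcription factors.

Each window of a sequence is assigned a binding energy ΔG, the sum of the
motif's energy-weight-matrix entries for the bases in that window (the
consensus word scores 0, mismatches add non-negative penalties in RT units).
At chemical potential μ (a proxy for active protein concentration, also in
RT units) the equilibrium binding probability of a window is the logistic
1/(1 + exp(ΔG − μ)).  Total predicted occupancy P(Occ) sums this over all
windows on both strands, so it estimates the expected number of bound
molecules; a sequence with three strong sites saturates near P(Occ) ≅ 3 as
μ grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import encode, revcomp
from .motifs import MotifModel

#: per-factor defaults for the chemical potential: the short OCT4 motif
#: saturates later than the others
DEFAULT_MU = {"O": 10.0, "S": 8.0, "K": 8.0, "E": 8.0}

#: the μ grid used for saturation analysis
MU_GRID = (0.5, 1.0, 2.0, 4.0, 5.0, 8.0, 10.0, 12.0)


@dataclass
class OccupancyResult:
    """Predicted occupancy of one sequence by one TF at one μ."""

    sequence_id: str
    tf: str
    mu: float
    per_position: dict[str, np.ndarray]  # strand -> per-window probabilities
    total: float


def energy_landscape(motif: MotifModel, seq: str) -> dict[str, np.ndarray]:
    """Per-window binding energies ΔG (RT units) on both strands.

    ``result["+"][i]`` is the energy of ``seq[i:i+L]`` read forward;
    ``result["-"][i]`` of the same window read as its reverse complement.
    Windows containing N get +inf (never occupied).  The consensus word has
    energy exactly 0.
    """
    L = motif.length
    codes = encode(seq)
    if len(codes) < L:
        return {"+": np.zeros(0), "-": np.zeros(0)}
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    valid = (win >= 0).all(axis=1)
    safe = np.where(win >= 0, win, 0)
    fwd = motif.ewm[safe, np.arange(L)].sum(axis=1)
    fwd[~valid] = np.inf

    rc = encode(revcomp(seq))
    win_rc = np.lib.stride_tricks.sliding_window_view(rc, L)
    valid_rc = (win_rc >= 0).all(axis=1)
    safe_rc = np.where(win_rc >= 0, win_rc, 0)
    rev_scores = motif.ewm[safe_rc, np.arange(L)].sum(axis=1)
    rev_scores[~valid_rc] = np.inf
    # window i of the rc sequence covers seq[n-L-i : n-i]; re-index so that
    # rev[i] is the energy of the reverse-complement read of seq[i:i+L]
    rev = rev_scores[::-1].copy()
    return {"+": fwd, "-": rev}


def predicted_occupancy(
    motif: MotifModel, seq: str, mu: float, sequence_id: str = "seq"
) -> OccupancyResult:
    """Logistic occupancy per window and the total P(Occ) over both strands."""
    if not np.isfinite(mu):
        raise ValueError("mu must be finite")
    energies = energy_landscape(motif, seq)
    per_position = {
        strand: 1.0 / (1.0 + np.exp(dg - mu)) for strand, dg in energies.items()
    }
    total = float(sum(p.sum() for p in per_position.values()))
    return OccupancyResult(sequence_id, motif.name, float(mu), per_position, total)


def occupancy_table(
    sequences: Mapping[str, str],
    motifs: Sequence[MotifModel],
    mu: Mapping[str, float] | float | None = None,
) -> pd.DataFrame:
    """Tidy table of total P(Occ) per (sequence, TF).

    ``mu`` may be a scalar, a per-TF mapping, or None for the per-factor
    defaults (μ = 8 for S/K/E, 10 for O; TFs without a default require an
    explicit value).
    """
    rows = []
    for m in motifs:
        if mu is None:
            if m.name not in DEFAULT_MU:
                raise ValueError(f"no default mu for TF {m.name!r}; pass mu explicitly")
            tf_mu = DEFAULT_MU[m.name]
        elif isinstance(mu, Mapping):
            tf_mu = mu[m.name]
        else:
            tf_mu = float(mu)
        for sid, seq in sequences.items():
            occ = predicted_occupancy(m, seq, tf_mu, sequence_id=sid)
            rows.append((sid, m.name, tf_mu, occ.total))
    return pd.DataFrame(rows, columns=["sequence_id", "tf", "mu", "total_occupancy"])


def saturation_scan(
    sequences: Mapping[str, str],
    motifs: Sequence[MotifModel],
    mu_grid: Sequence[float] = MU_GRID,
    site_count: int = 3,
    tol: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """P(Occ) over a μ grid and the saturation point per (sequence, TF).

    The saturation point is the smallest μ at which total occupancy is
    within ``tol`` of ``site_count`` (the number of planted sites, so
    saturation means every site is nearly always bound).  Returns the tidy
    occupancy table and a (sequence_id, tf, saturation_mu) frame with NaN
    where the grid never saturates.
    """
    if len(mu_grid) == 0 or list(mu_grid) != sorted(mu_grid):
        raise ValueError("mu_grid must be non-empty and sorted")
    frames = [occupancy_table(sequences, motifs, mu=m) for m in mu_grid]
    table = pd.concat(frames, ignore_index=True)
    rows = []
    for (sid, tf), grp in table.groupby(["sequence_id", "tf"], sort=True):
        grp = grp.sort_values("mu")
        sat = grp.loc[(grp.total_occupancy - site_count).abs() <= tol, "mu"]
        rows.append((sid, tf, float(sat.iloc[0]) if len(sat) else np.nan))
    sat_df = pd.DataFrame(rows, columns=["sequence_id", "tf", "saturation_mu"])
    return table, sat_df


def total_primary_affinity(element, motifs=None, mode: str = "logodds") -> float:
    """Sum of the primary sites' affinity scores for a genomic element.

    ``mode="logodds"`` (default) sums the scanner log-odds scores attached
    to the element's sites; ``mode="energy"`` sums the negated EWM energies
    of the site words instead (higher = better, 0 penalty = consensus), and
    requires ``motifs`` (mapping TF -> MotifModel) plus a wt_sequence.
    """
    sites = getattr(element, "sites", None)
    if not sites:
        raise ValueError("element has no annotated sites")
    if mode == "logodds":
        return float(sum(h.score for h in sites))
    if mode == "energy":
        if motifs is None:
            raise ValueError("mode='energy' requires motifs")
        total = 0.0
        for h in sites:
            m = motifs[h.tf]
            word = element.wt_sequence[h.start : h.end]
            if h.strand == "-":
                word = revcomp(word)
            codes = encode(word)
            total += -float(m.ewm[codes, np.arange(m.length)].sum())
        return total
    raise ValueError(f"unknown mode {mode!r}")
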