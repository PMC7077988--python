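"""Grammar feature construction and descriptive analyses.

Encodes elements into the feature sets used for modeling — ``independent``
(4 binary presence columns, one per TF), ``independent_position`` (those 4
plus 16 TF x position indicators = 20 columns), and a configurable
``genomic`` set (site affinities, total primary affinity, pairwise
spacings, predicted occupancies, additional-TF site counts and annotation-
track overlaps) — and provides the descriptive analyses: activity logos
over expression quantiles, edge-to-edge spacing histograms, binning by
ChIP-peak overlap count, and matching of genomic site configurations to
their synthetic counterparts.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .genome_select import GenomicElement
from .library_design import TF_ORDER, SynElement

POSITIONS = (1, 2, 3, 4)


# ----------------------------------------------------------------- encoding


def _as_elements(elements: Sequence[SynElement | str]) -> list[SynElement]:
    return [e if isinstance(e, SynElement) else SynElement.from_id(e) for e in elements]


def encode_features(
    elements: Sequence[SynElement | str],
    mode: str = "independent",
    tf_order: Sequence[str] = TF_ORDER,
    annotations: Mapping[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Feature matrix for a set of elements.

    ``independent``: one binary presence column per TF (4 columns).
    ``independent_position``: presence plus ``TF@pos`` indicators for
    positions 1-4 (20 columns).  ``genomic``: delegates to
    :func:`encode_genomic_features` with the ``annotations`` mapping.
    An element carrying the same TF twice is rejected.
    """
    if mode == "genomic":
        if annotations is None:
            raise ValueError("mode='genomic' requires annotations")
        return encode_genomic_features(**annotations)
    els = _as_elements(elements)
    rows = []
    for el in els:
        tfs = [tf for tf, _ in el.sites]
        if len(set(tfs)) != len(tfs):
            raise ValueError(f"TF present twice in element {el.element_id}")
        presence = {tf: int(tf in tfs) for tf in tf_order}
        if mode == "independent":
            rows.append({"element_id": el.element_id, **presence})
        elif mode == "independent_position":
            pos = {
                f"{tf}@{p}": int(p <= el.k and el.sites[p - 1][0] == tf)
                for tf in tf_order
                for p in POSITIONS
            }
            rows.append({"element_id": el.element_id, **presence, **pos})
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows).set_index("element_id")


def encode_genomic_features(
    site_scores: pd.DataFrame | None = None,
    spacings: pd.DataFrame | None = None,
    occupancy_wt: pd.DataFrame | None = None,
    occupancy_mut: pd.DataFrame | None = None,
    extra_motif_counts: pd.DataFrame | None = None,
    track_overlaps: pd.DataFrame | None = None,
    tf_order: Sequence[str] = TF_ORDER,
) -> pd.DataFrame:
    """Configurable genomic feature set, column groups concatenated.

    Each input frame is indexed by element_id.  ``site_scores`` (one column
    per TF, NaN where the TF is absent) yields per-TF affinity columns
    (absent -> 0) plus the summary ``OSKE_TotalAffinity`` (the summed
    primary-site affinities, a strong summary feature for classification).
    ``spacings`` columns are pairwise edge-to-edge gaps (absent pair -> -1).
    Occupancy frames add ``Occ_<TF>_wt`` / ``Occ_<TF>_mut`` columns; the
    other two groups are passed through with ``nSites_`` / ``Track_``
    prefixes.
    """
    pieces = []
    if site_scores is not None:
        aff = site_scores.reindex(columns=list(tf_order)).astype(float)
        total = aff.sum(axis=1, skipna=True)
        aff = aff.fillna(0.0).rename(columns={tf: f"Affinity_{tf}" for tf in tf_order})
        aff["OSKE_TotalAffinity"] = total
        pieces.append(aff)
    if spacings is not None:
        sp = spacings.astype(float).fillna(-1.0)
        sp.columns = [f"Spacing_{c}" for c in sp.columns]
        pieces.append(sp)
    if occupancy_wt is not None:
        occ = occupancy_wt.astype(float)
        occ.columns = [f"Occ_{c}_wt" for c in occ.columns]
        pieces.append(occ)
    if occupancy_mut is not None:
        occ = occupancy_mut.astype(float)
        occ.columns = [f"Occ_{c}_mut" for c in occ.columns]
        pieces.append(occ)
    if extra_motif_counts is not None:
        cnt = extra_motif_counts.astype(float)
        cnt.columns = [f"nSites_{c}" for c in cnt.columns]
        pieces.append(cnt)
    if track_overlaps is not None:
        tr = track_overlaps.astype(float)
        tr.columns = [f"Track_{c}" for c in tr.columns]
        pieces.append(tr)
    if not pieces:
        raise ValueError("no annotation groups supplied")
    out = pd.concat(pieces, axis=1)
    if out.isna().any().any():
        raise ValueError("genomic feature matrix contains missing values")
    return out


# -------------------------------------------------------------- activity logo


def _quantile_subset(
    expression: pd.Series, quantile: float, side: str
) -> pd.Index:
    """Top/bottom-quantile element ids, ties broken by element_id."""
    n_sub = int(round(quantile * len(expression)))
    df = expression.rename("expression").rename_axis("element_id").reset_index()
    if side == "top":
        df = df.sort_values(["expression", "element_id"], ascending=[False, True])
    elif side == "bottom":
        df = df.sort_values(["expression", "element_id"], ascending=[True, True])
    else:
        raise ValueError(f"side must be 'top' or 'bottom', got {side!r}")
    return pd.Index(df.element_id.head(n_sub))


def activity_logo(
    elements: Sequence[SynElement | str],
    expression: pd.Series,
    quantile: float = 0.25,
    side: str = "top",
    tf_order: Sequence[str] = TF_ORDER,
) -> pd.DataFrame:
    """Position x TF site-frequency matrix over an expression quantile.

    All elements must share the same number of sites k (positions are not
    comparable across k).  Returns a k x |TF| frame whose rows sum to 1;
    letter heights of the published activity logos are these frequencies.
    """
    els = _as_elements(elements)
    ks = {el.k for el in els}
    if len(ks) != 1:
        raise ValueError(f"elements must share one k; got k = {sorted(ks)}")
    k = ks.pop()
    expr = expression.loc[[el.element_id for el in els]]
    chosen = set(_quantile_subset(expr, quantile, side))
    subset = [el for el in els if el.element_id in chosen]
    freq = pd.DataFrame(0.0, index=pd.RangeIndex(1, k + 1, name="position"), columns=list(tf_order))
    for el in subset:
        for p, (tf, _) in enumerate(el.sites, start=1):
            freq.loc[p, tf] += 1
    return freq / len(subset)


def quantile_fasta_export(
    sequences: Mapping[str, str],
    expression: pd.Series,
    path_high,
    path_low,
    quantile: float = 0.25,
) -> tuple[int, int]:
    """Labeled FASTA export of top/bottom expression quantiles.

    For handing to external gapped-k-mer SVM tools; returns the subset
    sizes.
    """
    expr = expression.loc[[sid for sid in sequences]]
    high = _quantile_subset(expr, quantile, "top")
    low = _quantile_subset(expr, quantile, "bottom")
    for ids, path in ((high, path_high), (low, path_low)):
        with open(path, "w") as fh:
            for sid in ids:
                fh.write(f">{sid}\n{sequences[sid]}\n")
    return len(high), len(low)


# ------------------------------------------------------------------ spacing


def spacing_histogram(
    elements: Sequence[GenomicElement],
    groups: Mapping[str, str],
) -> pd.DataFrame:
    """Edge-to-edge distance frequencies for every TF pair, per group.

    Distance is the gap in bp between the nearest edges of two sites
    (0 = adjacent); overlapping sites are an upstream design violation and
    raise.  Returns a tidy frame (pair, distance, group, count); the counts
    for a pair sum to the number of elements containing that pair.
    """
    rows = []
    for el in elements:
        group = groups.get(el.element_id)
        if group is None:
            continue
        ordered = sorted(el.sites, key=lambda h: h.start)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                gap = b.start - a.end
                if gap < 0:
                    raise ValueError(f"overlapping sites in element {el.element_id}")
                pair = "-".join(sorted((a.tf, b.tf)))
                rows.append((pair, gap, group))
    df = pd.DataFrame(rows, columns=["pair", "distance", "group"])
    return (
        df.groupby(["pair", "distance", "group"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )


# ----------------------------------------------------------- overlap binning


def _count_track_overlaps(
    elements: pd.DataFrame, track: pd.DataFrame
) -> pd.Series:
    """Binary per-element indicator of >=1 bp overlap with a peak track."""
    out = pd.Series(0, index=elements.index)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for row in track.itertuples():
        by_chrom.setdefault(str(row.chrom), []).append((int(row.start), int(row.end)))
    for idx, row in elements.iterrows():
        peaks = by_chrom.get(str(row.chrom), [])
        if any(row.start < pe and row.end > ps for ps, pe in peaks):
            out.loc[idx] = 1
    return out


def chip_overlap_bins(
    elements: pd.DataFrame,
    tracks: Mapping[str, pd.DataFrame],
    expression: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bin elements by how many peak tracks they intersect.

    ``elements`` is BED-like (index = element_id; chrom/start/end columns);
    each track counts at most once per element regardless of how many of
    its peaks overlap.  Returns (per-element frame with ``n_tracks`` and
    expression, per-bin summary with count/mean/median expression).
    """
    if not tracks:
        raise ValueError("at least one track is required")
    indicators = pd.DataFrame(
        {name: _count_track_overlaps(elements, track) for name, track in tracks.items()}
    )
    per_element = pd.DataFrame(
        {"n_tracks": indicators.sum(axis=1), "expression": expression.reindex(elements.index)}
    )
    summary = (
        per_element.groupby("n_tracks")["expression"]
        .agg(n="size", mean="mean", median="median")
        .reset_index()
    )
    return per_element, summary


# ------------------------------------------------------------- SYN matching


def match_configurations(
    syn_expression: pd.Series,
    genomic_configurations: Mapping[str, str],
    genomic_expression: pd.Series,
) -> tuple[pd.DataFrame, float]:
    """Match genomic site configurations to SYN elements; report R².

    ``genomic_configurations`` maps element_id to an orientation-aware
    configuration string (e.g. ``"O-k-E"``).  A genomic element is matched
    to the SYN element with the identical id when one exists; otherwise to
    the mean expression of the SYN family sharing the same 5'→3' TF order
    regardless of orientation; configurations with no counterpart are
    reported unmatched.  R² is from the least-squares linear fit of SYN on
    genomic expression over matched pairs.
    """
    syn_by_order: dict[str, list[str]] = {}
    for sid in syn_expression.index:
        order = sid.upper()
        syn_by_order.setdefault(order, []).append(sid)
    rows = []
    for gid, config in genomic_configurations.items():
        if gid not in genomic_expression.index:
            continue
        g_expr = genomic_expression.loc[gid]
        if config in syn_expression.index:
            rows.append((gid, config, "exact", g_expr, syn_expression.loc[config]))
            continue
        family = syn_by_order.get(config.upper())
        if family:
            rows.append((gid, config, "order", g_expr, syn_expression.loc[family].mean()))
        else:
            rows.append((gid, config, "unmatched", g_expr, np.nan))
    pairs = pd.DataFrame(
        rows, columns=["element_id", "configuration", "match_type", "genomic_expression", "syn_expression"]
    )
    matched = pairs.dropna(subset=["syn_expression"])
    if len(matched) < 3 or matched.genomic_expression.nunique() < 2:
        return pairs, float("nan")
    fit = linregress(matched.genomic_expression, matched.syn_expression)
    return pairs, float(fit.rvalue**2)
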