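"""Barcode-count quantification of massively parallel reporter assays.

A count table holds one row per barcode with its element assignment, one
DNA column and one RNA column per biological replicate.  Quantification
follows the standard MPRA recipe: drop barcodes with fewer than 3 raw
counts in any RNA replicate or fewer than 10 in the DNA pool, scale every
column to reads per million (RPM), compute per-barcode expression as
RNA RPM / DNA RPM per replicate, average barcodes within each element,
divide by the basal (minimal-promoter-only) mean in that replicate, and
average across replicates.  Activity calls compare an element's barcode
expressions to the basal barcodes with a Wilcoxon rank-sum test per
replicate, Bonferroni-corrected; an element is active only if it is
significant in every replicate.  Matched wild-type/mutant pairs are tested
the same way against each other.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import comb
from scipy.stats import norm, rankdata

DEFAULT_RNA_MIN = 3
DEFAULT_DNA_MIN = 10

ID_COLUMNS = ["barcode", "element_id", "role"]


def rna_columns(counts: pd.DataFrame) -> list[str]:
    """The RNA replicate columns of a count table, in order."""
    return [c for c in counts.columns if c.startswith("rna")]


def validate_count_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Check the count-table contract (unique barcodes, counts >= 0)."""
    missing = [c for c in ID_COLUMNS + ["dna"] if c not in counts.columns]
    if missing:
        raise ValueError(f"count table missing columns: {missing}")
    if not rna_columns(counts):
        raise ValueError("count table has no rna replicate columns")
    if counts.barcode.duplicated().any():
        dup = counts.barcode[counts.barcode.duplicated()].iloc[0]
        raise ValueError(f"duplicate barcode in count table: {dup}")
    numeric = counts[["dna"] + rna_columns(counts)]
    if (numeric < 0).any().any():
        raise ValueError("negative counts")
    return counts


# ----------------------------------------------------------------- counting


def count_barcodes(
    reads: Iterable[str],
    manifest: pd.DataFrame,
    extract: Callable[[str], str] | tuple[int, int] = (0, 9),
) -> tuple[pd.Series, int]:
    """Exact-match barcode counting for one sample.

    ``extract`` is either a ``(start, length)`` slice locating the barcode
    in each read or a callable.  Reads whose extracted barcode does not
    perfectly match a manifest barcode are tallied separately, so
    counted + rejected equals the number of reads.  Returns
    (counts indexed by manifest barcode, n_rejected).
    """
    if manifest.barcode.duplicated().any():
        raise ValueError("manifest has duplicate barcodes")
    if isinstance(extract, tuple):
        start, length = extract
        extract = lambda read: read[start : start + length]  # noqa: E731
    counts = dict.fromkeys(manifest.barcode, 0)
    rejected = 0
    for read in reads:
        bc = extract(read)
        if bc in counts:
            counts[bc] += 1
        else:
            rejected += 1
    return pd.Series(counts, name="count"), rejected


def build_count_table(
    manifest: pd.DataFrame,
    dna_reads: Iterable[str],
    rna_reads: Sequence[Iterable[str]],
    extract: Callable[[str], str] | tuple[int, int] = (0, 9),
) -> pd.DataFrame:
    """Assemble a CountTable from raw read streams (DNA + RNA replicates)."""
    out = manifest[ID_COLUMNS].copy()
    dna, _ = count_barcodes(dna_reads, manifest, extract)
    out["dna"] = dna.values
    for i, reads in enumerate(rna_reads, start=1):
        rep, _ = count_barcodes(reads, manifest, extract)
        out[f"rna_{i}"] = rep.values
    return validate_count_table(out)


# ---------------------------------------------------------------- filtering


def filter_barcodes(
    counts: pd.DataFrame,
    rna_min: int = DEFAULT_RNA_MIN,
    dna_min: int = DEFAULT_DNA_MIN,
) -> pd.DataFrame:
    """Drop barcodes with low raw counts.

    A barcode survives iff its DNA count is >= ``dna_min`` and every RNA
    replicate count is >= ``rna_min`` (the "less than" removal rule, so the
    boundary values are retained).
    """
    validate_count_table(counts)
    keep = counts.dna >= dna_min
    for c in rna_columns(counts):
        keep &= counts[c] >= rna_min
    return counts.loc[keep].reset_index(drop=True)


# ------------------------------------------------------------ normalization


def rpm(column: pd.Series) -> pd.Series:
    """Scale a count column to reads per million."""
    total = column.sum()
    if total == 0:
        raise ValueError("cannot RPM-scale an all-zero column")
    return column * (1e6 / total)


def barcode_expression(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-barcode expression: RNA RPM / DNA RPM, one column per replicate."""
    validate_count_table(counts)
    if (counts.dna == 0).any():
        raise ValueError("zero DNA counts present; filter_barcodes first")
    out = counts[ID_COLUMNS].copy()
    dna_rpm = rpm(counts.dna)
    for c in rna_columns(counts):
        out[f"expr_{c}"] = rpm(counts[c]) / dna_rpm
    return out


def expr_columns(bc_expr: pd.DataFrame) -> list[str]:
    return [c for c in bc_expr.columns if c.startswith("expr_")]


def normalize_expression(
    counts: pd.DataFrame,
    basal_role: str = "basal",
    all_elements: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Element-level normalized expression table.

    Per replicate: mean barcode expression per element, divided by the
    basal barcodes' mean in that replicate (so basal normalized expression
    is 1 by construction); replicate values are then averaged.  Elements in
    ``all_elements`` that lost every barcode to the filters are reported
    with missing expression rather than dropped silently.
    """
    bc_expr = barcode_expression(counts)
    basal = bc_expr[bc_expr.role == basal_role]
    if basal.empty:
        raise ValueError(f"no surviving barcodes with role {basal_role!r}")
    cols = expr_columns(bc_expr)
    per_element = bc_expr.groupby("element_id", sort=True).agg(
        role=("role", "first"), n_barcodes=("barcode", "size"), **{c: (c, "mean") for c in cols}
    )
    basal_means = basal[cols].mean()
    norm_cols = {}
    for c in cols:
        norm_cols[c.replace("expr_", "norm_")] = per_element[c] / basal_means[c]
    normed = pd.DataFrame(norm_cols, index=per_element.index)
    result = pd.concat([per_element, normed], axis=1)
    result["expression"] = normed.mean(axis=1)
    if all_elements is not None:
        result = result.reindex(pd.Index(all_elements, name="element_id").union(result.index))
        result["n_barcodes"] = result["n_barcodes"].fillna(0).astype(int)
    return result


# ------------------------------------------------------------------- tests


def _rank_sum(x: np.ndarray, pooled: np.ndarray) -> float:
    ranks = rankdata(pooled)  # midranks for ties
    return float(ranks[: len(x)].sum())


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
    exact_limit: int = 20,
) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Uses midranks for ties.  ``mode="exact"`` enumerates all assignments of
    the pooled values to the two groups (the exact conditional null, valid
    with ties); ``mode="normal"`` uses the tie-corrected normal
    approximation with continuity correction; ``mode="auto"`` picks exact
    when n1 + n2 <= ``exact_limit``.  Identical constant samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    if mode == "auto":
        mode = "exact" if n <= exact_limit else "normal"
    ranks = rankdata(pooled)
    w = float(ranks[:n1].sum())
    mean_w = n1 * (n + 1) / 2.0

    if mode == "exact":
        # exact conditional null: distribution of the rank sum over all
        # C(n, n1) assignments of the observed (mid)ranks, via subset-sum DP
        # on doubled ranks (midranks are half-integers)
        scaled = np.round(ranks * 2).astype(np.int64)
        total_sum = int(scaled.sum())
        dp = np.zeros((n1 + 1, total_sum + 1))
        dp[0, 0] = 1.0
        for r in scaled:
            for k in range(n1, 0, -1):
                dp[k, r:] += dp[k - 1, : total_sum + 1 - r]
        counts = dp[n1]
        total = comb(n, n1, exact=True)
        values = np.arange(total_sum + 1) / 2.0
        dev = abs(w - mean_w)
        hits = counts[np.abs(values - mean_w) >= dev - 1e-9].sum()
        return float(hits / total)
    if mode != "normal":
        raise ValueError(f"unknown mode {mode!r}")
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return 1.0
    z = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)
    return float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))


def bonferroni(p: float, n_tests: int) -> float:
    return min(1.0, p * n_tests)


def call_activity(
    bc_expr: pd.DataFrame,
    basal_role: str = "basal",
    n_tests: int | None = None,
    alpha: float = 0.05,
    paired: Mapping[str, str] | None = None,
    min_barcodes_warn: int = 2,
) -> pd.DataFrame:
    """Per-element activity calls versus basal (or versus matched mutants).

    For every non-basal element and every replicate, the element's barcode
    expressions are tested against the basal barcodes (or, in paired mode,
    the wild-type element's barcodes against its mutant partner's) with the
    rank-sum test.  Bonferroni correction uses ``n_tests`` (default: the
    number of elements tested; a fixed family size such as 637 can be
    supplied instead).  An element is called active iff the adjusted
    p-value is below ``alpha`` in every replicate.
    """
    cols = expr_columns(bc_expr)
    if not cols:
        raise ValueError("bc_expr must carry expr_* columns from barcode_expression")
    groups = {eid: grp for eid, grp in bc_expr.groupby("element_id", sort=True)}
    if paired is None:
        basal = bc_expr[bc_expr.role == basal_role]
        if basal.empty:
            raise ValueError(f"no barcodes with role {basal_role!r}")
        tested = [e for e in groups if (groups[e].role != basal_role).all()]
        reference = {e: basal for e in tested}
    else:
        unknown = [e for pair in paired.items() for e in pair if e not in groups]
        if unknown:
            raise ValueError(f"paired map references unknown element(s): {sorted(set(unknown))}")
        tested = sorted(paired)
        reference = {e: groups[paired[e]] for e in tested}
    m = n_tests if n_tests is not None else len(tested)
    rows = []
    for eid in tested:
        grp = groups[eid]
        ref = reference[eid]
        if len(grp) < min_barcodes_warn:
            import warnings

            warnings.warn(f"element {eid} has only {len(grp)} barcode(s)", stacklevel=2)
        pvals = [wilcoxon_rank_sum(grp[c].to_numpy(), ref[c].to_numpy(), mode="normal")
                 if len(grp) + len(ref) > 20
                 else wilcoxon_rank_sum(grp[c].to_numpy(), ref[c].to_numpy(), mode="exact")
                 for c in cols]
        padj = [bonferroni(p, m) for p in pvals]
        rows.append([eid, *pvals, *padj, all(q < alpha for q in padj)])
    out = pd.DataFrame(
        rows,
        columns=["element_id"]
        + [f"p_{c.removeprefix('expr_')}" for c in cols]
        + [f"padj_{c.removeprefix('expr_')}" for c in cols]
        + ["active"],
    ).set_index("element_id")
    return out
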