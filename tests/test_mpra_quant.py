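"""MPRA quantification: counting, filtering, normalization, the rank-sum
test, and activity calls."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu, rankdata

from cisgrammar import mpra_quant as mq, simulate as sim


def make_counts(rows, n_reps=3):
    """rows: (barcode, element_id, role, dna, rna...) tuples."""
    cols = ["barcode", "element_id", "role", "dna"] + [f"rna_{i+1}" for i in range(n_reps)]
    return pd.DataFrame(rows, columns=cols)


# ----------------------------------------------------------------- counting


def test_exact_match_counting_and_conservation():
    manifest = pd.DataFrame({"barcode": ["AAACCCTTT", "GGGTTTAAA"], "element_id": ["e1", "e2"], "role": ["syn", "syn"]})
    reads = ["AAACCCTTT" + "X" * 5] * 3 + ["GGGTTTAAC" + "X" * 5] + ["AAACCCTTA"]
    counts, rejected = mq.count_barcodes(reads, manifest, extract=(0, 9))
    assert counts["AAACCCTTT"] == 3
    assert counts["GGGTTTAAA"] == 0  # 1-mismatch read is NOT counted
    assert counts.sum() + rejected == len(reads)


def test_duplicate_manifest_barcode_rejected():
    manifest = pd.DataFrame({"barcode": ["AAACCCTTT", "AAACCCTTT"], "element_id": ["a", "b"], "role": ["syn", "syn"]})
    with pytest.raises(ValueError, match="duplicate"):
        mq.count_barcodes([], manifest)


# ---------------------------------------------------------------- filtering


def test_filter_rules():
    counts = make_counts(
        [
            ("b1", "e1", "syn", 100, 2, 50, 50),   # rna below min in one rep -> removed
            ("b2", "e1", "syn", 10, 3, 3, 3),      # boundary values -> retained
            ("b3", "e1", "syn", 9, 50, 50, 50),    # dna below min -> removed
            ("b4", "e1", "syn", 1000, 100, 100, 100),
        ]
    )
    kept = mq.filter_barcodes(counts)
    assert list(kept.barcode) == ["b2", "b4"]


def test_filter_monotone_in_thresholds():
    rng = np.random.default_rng(0)
    counts = make_counts(
        [(f"b{i}", "e", "syn", rng.integers(0, 30), *rng.integers(0, 10, 3)) for i in range(200)]
    )
    sizes = [
        len(mq.filter_barcodes(counts, rna_min=r, dna_min=d))
        for r in range(0, 6)
        for d in range(0, 20, 4)
    ]
    # raising either threshold never increases the surviving count
    for r in range(0, 6):
        prev = None
        for d in range(0, 20, 4):
            n = len(mq.filter_barcodes(counts, rna_min=r, dna_min=d))
            if prev is not None:
                assert n <= prev
            prev = n


# ------------------------------------------------------------ normalization


def test_rpm_scaling():
    col = pd.Series([1, 1, 2])
    np.testing.assert_allclose(mq.rpm(col), [250000.0, 250000.0, 500000.0])
    assert mq.rpm(pd.Series([5, 5])).sum() == pytest.approx(1e6)


def test_identity_expression_is_one():
    # every barcode has RNA RPM == DNA RPM, basal included -> all expression 1
    counts = make_counts(
        [
            ("b1", "e1", "syn", 10, 10, 20, 10),
            ("b2", "basal", "basal", 30, 30, 60, 30),
            ("b3", "basal", "basal", 60, 60, 120, 60),
        ]
    )
    expr = mq.normalize_expression(counts)
    assert expr.loc["basal", "expression"] == pytest.approx(1.0)
    assert expr.loc["e1", "expression"] == pytest.approx(1.0)


def test_rescaling_invariance():
    """Uniformly rescaling any single column's counts leaves normalized
    expression unchanged (verified by recomputation on a random table)."""
    rng = np.random.default_rng(1)
    rows = []
    for i in range(40):
        role = "basal" if i < 10 else "syn"
        eid = "basal" if i < 10 else f"e{i % 7}"
        rows.append((f"b{i}", eid, role, rng.integers(10, 1000), *rng.integers(3, 1000, 3)))
    counts = make_counts(rows)
    base = mq.normalize_expression(counts)

    doubled = counts.copy()
    doubled["dna"] = doubled["dna"] * 2
    doubled["rna_2"] = doubled["rna_2"] * 5
    again = mq.normalize_expression(doubled)
    pd.testing.assert_frame_equal(
        base[["expression"]], again[["expression"]], check_exact=False, rtol=1e-9
    )


def test_basal_required_and_missing_elements_reported():
    counts = make_counts([("b1", "e1", "syn", 10, 5, 5, 5)])
    with pytest.raises(ValueError, match="basal"):
        mq.normalize_expression(counts)
    counts2 = make_counts(
        [("b1", "e1", "syn", 10, 5, 5, 5), ("b2", "basal", "basal", 10, 5, 5, 5)]
    )
    expr = mq.normalize_expression(counts2, all_elements=["e1", "e_lost"])
    assert np.isnan(expr.loc["e_lost", "expression"])
    assert expr.loc["e_lost", "n_barcodes"] == 0


# ------------------------------------------------------------------ wilcoxon


def brute_force_wilcoxon(x, y):
    """Exact two-sided rank-sum p-value by full enumeration (oracle)."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1, n = len(x), len(pooled)
    w = ranks[:n1].sum()
    mean_w = n1 * (n + 1) / 2
    dev = abs(w - mean_w)
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mean_w) >= dev - 1e-9:
            hits += 1
    return hits / total


def test_wilcoxon_known_values():
    assert mq.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == 1.0
    # extreme separation: 2/20 per tail -> p = 0.1
    assert mq.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact") == pytest.approx(0.1)
    assert mq.wilcoxon_rank_sum([5.0], [5.0]) == 1.0


def test_wilcoxon_matches_enumeration_oracle():
    """DP-based exact p equals full enumeration for all splits with
    n1 + n2 <= 12, including ties."""
    rng = np.random.default_rng(2)
    for n1 in range(1, 7):
        for n2 in range(n1, 13 - n1):
            vals = rng.integers(0, 5, size=n1 + n2).astype(float)  # many ties
            x, y = vals[:n1], vals[n1:]
            assert mq.wilcoxon_rank_sum(x, y, mode="exact") == pytest.approx(
                brute_force_wilcoxon(x, y), abs=1e-12
            )
            cont = rng.normal(size=n1 + n2)
            assert mq.wilcoxon_rank_sum(cont[:n1], cont[n1:], mode="exact") == pytest.approx(
                brute_force_wilcoxon(cont[:n1], cont[n1:]), abs=1e-12
            )


def test_wilcoxon_matches_scipy_without_ties():
    rng = np.random.default_rng(3)
    x, y = rng.normal(size=6), rng.normal(size=8)
    ours = mq.wilcoxon_rank_sum(x, y, mode="exact")
    ref = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
    assert ours == pytest.approx(ref, abs=1e-12)


def test_exact_and_normal_agree_at_moderate_n():
    rng = np.random.default_rng(4)
    for _ in range(10):
        x = rng.normal(size=8)
        y = rng.normal(size=12)
        p_exact = mq.wilcoxon_rank_sum(x, y, mode="exact")
        p_norm = mq.wilcoxon_rank_sum(x, y, mode="normal")
        assert abs(p_exact - p_norm) < 0.02


# ------------------------------------------------------------ activity calls


def test_bonferroni_arithmetic():
    assert mq.bonferroni(0.049 / 637, 637) == pytest.approx(0.049)
    assert mq.bonferroni(0.5, 637) == 1.0


def test_element_equal_to_basal_is_inactive():
    rows = []
    for i in range(8):
        rows.append((f"e{i}", "e1", "syn", 100, 100, 100, 100))
    for i in range(20):
        rows.append((f"b{i}", "basal", "basal", 100, 100, 100, 100))
    bc = mq.barcode_expression(make_counts(rows))
    calls = mq.call_activity(bc, n_tests=637)
    assert not calls.loc["e1", "active"]
    assert calls.loc["e1", "padj_rna_1"] == 1.0


def test_planted_activations_are_detected():
    """10-fold activations at deep coverage: >= 95% of planted-active and
    <= 5% of planted-null elements are called active."""
    acts = {f"on_{i}": 10.0 for i in range(40)}
    acts.update({f"null_{i}": 1.0 for i in range(40)})
    counts = sim.simulate_counts(pd.Series(acts), sim.CountSimConfig(seed=9))
    bc = mq.barcode_expression(mq.filter_barcodes(counts))
    calls = mq.call_activity(bc)
    on = calls.loc[[e for e in calls.index if e.startswith("on_")], "active"]
    null = calls.loc[[e for e in calls.index if e.startswith("null_")], "active"]
    assert on.mean() >= 0.95
    assert null.mean() <= 0.05


def test_paired_calls_and_unknown_element():
    table, paired = sim.simulate_paired_library(20, config=sim.CountSimConfig(seed=10))
    bc = mq.barcode_expression(mq.filter_barcodes(table))
    calls = mq.call_activity(bc, paired=paired)
    assert calls.active.mean() >= 0.9  # power at 10-fold ratios
    with pytest.raises(ValueError, match="unknown"):
        mq.call_activity(bc, paired={"nonesuch": "gmut_1"})
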