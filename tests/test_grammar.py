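"""Grammar features: encodings, activity logos, spacing, overlap binning
and SYN-genomic configuration matching."""

import numpy as np
import pandas as pd
import pytest

from cisgrammar import grammar as gr
from cisgrammar.genome_select import GenomicElement
from cisgrammar.library_design import SynElement, enumerate_syn_elements
from cisgrammar.motifs import SiteHit


# ----------------------------------------------------------------- encoding


def test_feature_counts_exact(syn_elements):
    X4 = gr.encode_features(syn_elements, mode="independent")
    assert X4.shape == (624, 4)
    assert set(X4.columns) == {"O", "S", "K", "E"}
    X20 = gr.encode_features(syn_elements, mode="independent_position")
    assert X20.shape == (624, 20)
    assert X4.isin([0, 1]).all().all() and X20.isin([0, 1]).all().all()


def test_positional_encoding_values():
    X = gr.encode_features(["S-O-K-E"], mode="independent_position")
    row = X.loc["S-O-K-E"]
    assert row[["O", "S", "K", "E"]].tolist() == [1, 1, 1, 1]
    on = {c for c in X.columns if "@" in c and row[c] == 1}
    assert on == {"S@1", "O@2", "K@3", "E@4"}

    X2 = gr.encode_features(["O-s"], mode="independent_position")
    row2 = X2.loc["O-s"]
    assert row2[["O", "S", "K", "E"]].tolist() == [1, 1, 0, 0]
    assert {c for c in X2.columns if "@" in c and row2[c] == 1} == {"O@1", "S@2"}


def test_duplicate_tf_rejected():
    el = SynElement.__new__(SynElement)  # bypass validation to build a bad element
    object.__setattr__(el, "sites", (("O", "forward"), ("O", "reverse")))
    with pytest.raises(ValueError, match="twice"):
        gr.encode_features([el], mode="independent")


def test_genomic_encoding_total_affinity():
    scores = pd.DataFrame(
        {"O": [5.1], "S": [3.2], "K": [4.0], "E": [np.nan]}, index=["g1"]
    )
    X = gr.encode_features([], mode="genomic", annotations={"site_scores": scores})
    assert X.loc["g1", "OSKE_TotalAffinity"] == pytest.approx(12.3)
    assert X.loc["g1", "Affinity_E"] == 0.0


# -------------------------------------------------------------------- logos


def test_top_quartile_of_4mers_is_96(syn_elements):
    four = [e for e in syn_elements if e.k == 4]
    rng = np.random.default_rng(0)
    expr = pd.Series(rng.normal(size=384), index=[e.element_id for e in four])
    logo = gr.activity_logo(four, expr, quantile=0.25, side="top")
    assert logo.shape == (4, 4)
    np.testing.assert_allclose(logo.sum(axis=1), 1.0)
    assert len(gr._quantile_subset(expr, 0.25, "top")) == 96
    assert len(gr._quantile_subset(expr, 0.25, "bottom")) == 96


def test_degenerate_subset_gives_indicator_logo():
    els = ["S-O-K-E"] * 5
    expr = pd.Series(1.0, index=["S-O-K-E"])
    logo = gr.activity_logo(els, expr.reindex(["S-O-K-E"] * 5).set_axis(["S-O-K-E"] * 5), quantile=1.0)
    assert logo.loc[1, "S"] == 1.0 and logo.loc[4, "E"] == 1.0
    assert logo.loc[1, ["O", "K", "E"]].sum() == 0.0


def test_full_4mer_set_frequencies_are_uniform(syn_elements):
    """Pooled over all 384 4-mers, each TF occupies each position with
    frequency exactly 1/4 (exhaustive-enumeration symmetry)."""
    four = [e for e in syn_elements if e.k == 4]
    expr = pd.Series(0.0, index=[e.element_id for e in four])
    logo = gr.activity_logo(four, expr, quantile=1.0, side="top")
    np.testing.assert_allclose(logo.to_numpy(), 0.25)


def test_mixed_k_rejected(syn_elements):
    expr = pd.Series(0.0, index=[e.element_id for e in syn_elements])
    with pytest.raises(ValueError, match="k"):
        gr.activity_logo(syn_elements, expr)


# ------------------------------------------------------------------ spacing


def element_with_sites(eid, spans):
    sites = [
        SiteHit(eid, s, e, "+", tf, 1.0, 1e-4) for (s, e, tf) in spans
    ]
    return GenomicElement(eid, "chr", 0, 81, sites, "A" * 81)


def test_edge_to_edge_distances():
    el = element_with_sites("g1", [(10, 20, "O"), (25, 35, "S")])
    hist = gr.spacing_histogram([el], {"g1": "high"})
    assert hist.iloc[0].distance == 5
    el2 = element_with_sites("g2", [(10, 20, "O"), (20, 30, "S")])
    hist2 = gr.spacing_histogram([el2], {"g2": "high"})
    assert hist2.iloc[0].distance == 0  # adjacency


def test_overlapping_sites_error():
    el = element_with_sites("g1", [(10, 20, "O"), (15, 25, "S")])
    with pytest.raises(ValueError, match="overlap"):
        gr.spacing_histogram([el], {"g1": "high"})


def test_histogram_row_sums_match_recount():
    rng = np.random.default_rng(5)
    els, groups = [], {}
    for i in range(30):
        tfs = rng.choice(["O", "S", "K", "E"], size=3, replace=False)
        pos = 5
        spans = []
        for tf in tfs:
            spans.append((pos, pos + 9, tf))
            pos += 9 + int(rng.integers(0, 15))
        eid = f"g{i}"
        els.append(element_with_sites(eid, spans))
        groups[eid] = "high" if i % 2 else "low"
    hist = gr.spacing_histogram(els, groups)
    # counts for a pair sum to the number of elements containing that pair
    for pair, sub in hist.groupby("pair"):
        a, b = pair.split("-")
        n_brute = sum(
            1 for el in els if {a, b} <= {h.tf for h in el.sites}
        )
        assert sub["count"].sum() == n_brute


# ----------------------------------------------------------- overlap binning


def make_track(*spans):
    return pd.DataFrame(spans, columns=["chrom", "start", "end"])


def test_overlap_counting_rules():
    elements = pd.DataFrame(
        {"chrom": ["c1"], "start": [100], "end": [181]}, index=["g1"]
    )
    expr = pd.Series({"g1": 2.0})
    tracks = {
        "t1": make_track(("c1", 150, 200)),
        "t2": make_track(("c1", 0, 101)),
        "t3": make_track(("c1", 120, 130), ("c1", 140, 150)),  # overlaps twice: counts once
        "t4": make_track(("c1", 181, 300)),                    # abuts: no overlap
        "t5": make_track(("c2", 100, 181)),                    # wrong chrom
    }
    per_element, summary = gr.chip_overlap_bins(elements, tracks, expr)
    assert per_element.loc["g1", "n_tracks"] == 3
    assert summary.loc[summary.n_tracks == 3, "n"].iloc[0] == 1


def test_overlap_invariant_to_track_order_and_splitting():
    elements = pd.DataFrame(
        {"chrom": ["c1", "c1"], "start": [0, 500], "end": [81, 581]},
        index=["g1", "g2"],
    )
    expr = pd.Series({"g1": 1.0, "g2": 2.0})
    whole = {"t": make_track(("c1", 40, 560))}
    split = {"t": make_track(("c1", 40, 300), ("c1", 300, 560))}
    a, _ = gr.chip_overlap_bins(elements, whole, expr)
    b, _ = gr.chip_overlap_bins(elements, split, expr)
    pd.testing.assert_frame_equal(a, b)


def test_zero_tracks_error():
    with pytest.raises(ValueError, match="track"):
        gr.chip_overlap_bins(pd.DataFrame(), {}, pd.Series(dtype=float))


# ------------------------------------------------------------- SYN matching


def test_configuration_matching_and_r2(syn_elements):
    syn_expr = pd.Series(
        np.arange(624, dtype=float), index=[e.element_id for e in syn_elements]
    )
    configs = {"g1": "O-K-E", "g2": "O-k-E", "g3": "Q-X-Z"}
    gen_expr = pd.Series({"g1": 1.0, "g2": 2.0, "g3": 3.0})
    pairs, r2 = gr.match_configurations(syn_expr, configs, gen_expr)
    assert pairs.set_index("element_id").loc["g1", "match_type"] == "exact"
    assert pairs.set_index("element_id").loc["g1", "syn_expression"] == syn_expr["O-K-E"]
    assert pairs.set_index("element_id").loc["g3", "match_type"] == "unmatched"

    # identical expression vectors give R^2 = 1
    ids = [e.element_id for e in syn_elements if e.k == 3][:50]
    syn2 = pd.Series(np.linspace(0, 5, 50), index=ids)
    configs2 = {f"g{i}": eid for i, eid in enumerate(ids)}
    gen2 = pd.Series({f"g{i}": syn2[eid] for i, eid in enumerate(ids)})
    _, r2_perfect = gr.match_configurations(syn2, configs2, gen2)
    assert r2_perfect == pytest.approx(1.0)


def test_independent_simulations_have_no_correlation(syn_elements):
    """Independently simulated genomic and SYN activities: R^2 below 0.05."""
    rng = np.random.default_rng(6)
    three = [e.element_id for e in syn_elements if e.k == 3]
    syn_expr = pd.Series(rng.lognormal(0, 1, len(three)), index=three)
    configs = {f"g{i}": rng.choice(three) for i in range(150)}
    gen_expr = pd.Series(rng.lognormal(0, 1, 150), index=[f"g{i}" for i in range(150)])
    pairs, r2 = gr.match_configurations(syn_expr, configs, gen_expr)
    assert len(pairs.dropna(subset=["syn_expression"])) == 150
    assert r2 < 0.05
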