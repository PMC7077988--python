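"""Synthetic library design: enumeration, oligo assembly, barcodes,
site-killing mutations, and the mini-spacer library."""

import numpy as np
import pytest

import cisgrammar as cg
from cisgrammar._seq import hamming, revcomp
from cisgrammar.library_design import (
    MINI_SPACER,
    SYN,
    OligoDesignError,
    SynElement,
    assemble_oligo,
    build_mini_spacer_library,
    build_syn_pool,
    design_mutant_site,
    element_insert,
    enumerate_syn_elements,
    find_restriction_violations,
    generate_barcodes,
    generate_spacer_alternatives,
)
from cisgrammar.motifs import MotifModel


# -------------------------------------------------------------- enumeration


@pytest.mark.parametrize(
    "k_values,expected",
    [({2}, 48), ({3}, 192), ({4}, 384), ({2, 3, 4}, 624)],
)
def test_enumeration_counts(k_values, expected):
    els = enumerate_syn_elements(k_values=k_values)
    assert len(els) == expected
    ids = [e.element_id for e in els]
    assert len(set(ids)) == expected  # all unique


def test_enumeration_canonical_and_input_order_invariant():
    a = enumerate_syn_elements(("O", "S", "K", "E"))
    b = enumerate_syn_elements(("E", "K", "S", "O"))
    assert [e.element_id for e in a] == [e.element_id for e in b]


def test_element_id_roundtrip(syn_elements):
    for el in syn_elements:
        assert SynElement.from_id(el.element_id).sites == el.sites


def test_duplicate_tf_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        enumerate_syn_elements(("O", "O", "K", "E"))
    with pytest.raises(ValueError, match="duplicate"):
        SynElement.from_id("O-o")


# ----------------------------------------------------------------- assembly


def test_oligo_lengths_and_fill_arithmetic(blocks):
    el4 = SynElement.from_id("O-S-K-E")
    insert = element_insert(el4, blocks)
    assert len(insert) == 80
    # 150 = fixed scaffold + [SEQ] + [FILL] + 9 bp barcode
    assert SYN.fill_length(len(insert)) == 150 - SYN.fixed_length - 80 - 9 == 0
    rec = assemble_oligo("O-S-K-E", insert, "ACGTACGTA", rng=np.random.default_rng(0))
    assert len(rec.oligo) == 150

    # basal record: empty [SEQ], all padding in [FILL]
    basal = assemble_oligo("basal", "", "ACGTACGTC", rng=np.random.default_rng(0), role="basal")
    assert len(basal.oligo) == 150


def test_reverse_orientation_uses_block_revcomp(blocks):
    el = SynElement.from_id("o-S")
    insert = element_insert(el, blocks)
    assert insert == revcomp(blocks["O"].sequence) + blocks["S"].sequence


def test_oversized_insert_rejected():
    with pytest.raises(OligoDesignError, match="too long"):
        assemble_oligo("x", "A" * 100, "ACGTACGTA", rng=np.random.default_rng(0))


def test_restriction_screen_applies_to_variable_segments():
    # a barcode carrying an EcoRI site must be rejected
    with pytest.raises(OligoDesignError):
        assemble_oligo("x", "", "GAATTCAAA", rng=np.random.default_rng(0))
    # the scaffold's own cloning sites are allowed
    rec = assemble_oligo("x", "", "ACGTACGTA", rng=np.random.default_rng(0))
    assert "AAGCTT" in rec.oligo  # fixed HindIII arm is present and legal


def test_full_syn_pool_composition(syn_elements, blocks):
    pool = build_syn_pool(syn_elements, blocks, seed=0)
    assert len(pool) == 624 * 8 + 112
    barcodes = [r.barcode for r in pool]
    assert len(set(barcodes)) == len(barcodes)
    roles = {r.role for r in pool}
    assert roles == {"syn", "basal"}
    assert sum(r.role == "basal" for r in pool) == 112
    assert all(len(r.oligo) == 150 for r in pool)


# ----------------------------------------------------------------- barcodes


def test_barcode_screens():
    bcs = generate_barcodes(500, seed=1)
    assert len(set(bcs)) == 500
    for bc in bcs:
        assert len(bc) == 9
        for b in "ACGT":
            assert b * 5 not in bc
        for site in ("GGGCCC", "GAGCTC", "AAGCTT", "GAATTC", "TCTAGA", "ACTAGT"):
            assert site not in bc and revcomp(site) not in bc
    # pairwise Hamming distance >= 2 (spot-check a subset)
    for i in range(0, 100, 7):
        for j in range(i + 1, 100, 7):
            assert hamming(bcs[i], bcs[j]) >= 2


# ----------------------------------------------------------------- mutation


def test_mutation_targets_two_highest_ic_positions():
    """Positions with the top-2 information content are mutated (computed by
    brute force on a toy PFM with a known IC ordering)."""
    # IC order: position 0 sharpest, then 2; 1 and 3 near-uniform
    pfm = np.array(
        [
            [97.0, 26.0, 90.0, 28.0],
            [1.0, 25.0, 4.0, 24.0],
            [1.0, 25.0, 3.0, 24.0],
            [1.0, 24.0, 3.0, 24.0],
        ]
    )
    m = MotifModel("toy", pfm)
    ic_brute = 2.0 + (m.pfm * np.log2(m.pfm)).sum(axis=0)
    assert list(np.argsort(-ic_brute)[:2]) == [0, 2]
    mut = design_mutant_site("AAAA", m)
    assert mut.positions == (0, 2)
    assert hamming("AAAA", mut.sequence) == 2
    # substituted base is the lowest-frequency base of the column
    assert mut.sequence[0] == "ACGT"[int(np.argmin(m.pfm[:, 0]))]


def test_mutation_reverse_orientation_symmetry(motifs):
    """Mutating a reverse-orientation site equals mutating the forward
    reading and reverse-complementing."""
    for m in motifs.values():
        site_fwd = m.consensus
        mut_fwd = design_mutant_site(site_fwd, m, "forward")
        mut_rev = design_mutant_site(revcomp(site_fwd), m, "reverse")
        assert mut_rev.sequence == revcomp(mut_fwd.sequence)
        assert hamming(revcomp(site_fwd), mut_rev.sequence) == 2


def test_mutants_never_rescan_as_hits(motifs, blocks):
    """Every accepted mutant has exactly 2 substitutions and zero hits at
    the selection threshold, for all four factors."""
    for tf, m in motifs.items():
        site = blocks[tf].site
        mut = design_mutant_site(site, m)
        assert mut.status == "ok"
        assert hamming(site, mut.sequence) == 2
        for other in motifs.values():
            assert other.scan(mut.sequence, 1e-3) == []


def test_short_motif_rejected():
    pfm = np.array([[97.0], [1.0], [1.0], [1.0]])
    m = MotifModel("tiny", pfm)
    with pytest.raises(ValueError, match="at least 2"):
        design_mutant_site("A", m)


# -------------------------------------------------------------- mini spacer


@pytest.fixture(scope="module")
def spacer_alts(motifs, blocks):
    return generate_spacer_alternatives(blocks, motifs, n_alternatives=4, seed=0)


def test_mini_spacer_library_counts(motifs, blocks, spacer_alts):
    elements = [e for e in enumerate_syn_elements(k_values={4})][:6]
    lib = build_mini_spacer_library(elements, blocks, spacer_alts, motifs=motifs, seed=0)
    assert lib.n_constructs == 30          # 6 elements x (4 + 1) spacers
    assert len(lib.records) == 150         # x 5 barcodes
    assert lib.rejected == []
    assert all(len(r.oligo) == 161 for r in lib.records)
    assert all(r.scaffold is MINI_SPACER for r in lib.records)


def test_mini_spacer_empty_input(blocks, spacer_alts):
    lib = build_mini_spacer_library([], blocks, spacer_alts, seed=0)
    assert lib.records == [] and lib.n_constructs == 0


def test_spacer_alternatives_preserve_site_and_composition(blocks, spacer_alts):
    for name, table in spacer_alts.items():
        for tf, block in table.items():
            orig = blocks[tf]
            assert block.site == orig.site  # binding site untouched
            assert sorted(block.sequence) == sorted(orig.sequence)  # same composition
            assert block.sequence != orig.sequence
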