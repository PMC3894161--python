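"""Alignment/tree IO, the JTT model, pruning likelihoods and the rate cache."""

import itertools

import numpy as np
import pytest

import phylogp as pg
from phylogp.phylo_core import AMINO_ACIDS, FormatError, GAP_CODE, loglik_matrix


# ---------------------------------------------------------------------- IO


def test_fasta_round_trip(tmp_path):
    p = tmp_path / "a.fasta"
    p.write_text(">s1\nACDEFGHIKL\n>s2\nACDEFGHIKM\n>s3\nACDEFGH-KL\n>s4\nACDEFGHXKL\n")
    aln = pg.read_alignment(p)
    assert aln.n_sites == 10 and aln.n_taxa == 4
    assert aln.sequence("s3") == "ACDEFGH-KL"
    out = tmp_path / "out.fasta"
    aln.to_fasta(out)
    assert pg.read_alignment(out).sequence("s1") == "ACDEFGHIKL"


def test_mixed_case_and_unknown_normalized(tmp_path, quartet, jtt):
    up = tmp_path / "up.fasta"
    lo = tmp_path / "lo.fasta"
    up.write_text(">A\nKQR\n>B\nKQR\n>C\nKXR\n>D\nKQR\n")
    lo.write_text(">A\nkqr\n>B\nkqr\n>C\nkJr\n>D\nkqr\n")  # J is non-canonical
    a_up, a_lo = pg.read_alignment(up), pg.read_alignment(lo)
    ll_up = loglik_matrix(a_up, quartet, jtt, np.array([1.0]))
    ll_lo = loglik_matrix(a_lo, quartet, jtt, np.array([1.0]))
    np.testing.assert_allclose(ll_up, ll_lo, rtol=0, atol=0)


def test_ragged_alignment_rejected(tmp_path):
    p = tmp_path / "bad.fasta"
    p.write_text(">s1\nACDEF\n>s2\nACD\n")
    with pytest.raises(FormatError):
        pg.read_alignment(p)


def test_empty_file_rejected(tmp_path):
    p = tmp_path / "empty.fasta"
    p.write_text("")
    with pytest.raises(FormatError):
        pg.read_alignment(p)


def test_phylip_reading(tmp_path):
    p = tmp_path / "a.phy"
    p.write_text(" 2 6\nseq_one    ACDEFG\nseq_two    ACDEFH\n")
    aln = pg.read_alignment(p)
    assert aln.taxon_names == ["seq_one", "seq_two"]
    assert aln.n_sites == 6


def test_canonical_tree_total_branch_length():
    tree = pg.read_newick("((A:0.2,B:0.2):0.2,C:0.2,D:0.2);")
    assert tree.total_branch_length == pytest.approx(1.0, abs=1e-15)
    assert sorted(tree.taxon_names) == ["A", "B", "C", "D"]


def test_zero_length_branches_allowed():
    tree = pg.read_newick("(A:0.0,B:0.0);")
    assert tree.total_branch_length == 0.0


def test_malformed_newick_rejected():
    with pytest.raises(FormatError):
        pg.read_newick("((A:0.1,B:0.2;")


def test_missing_branch_length_needs_default():
    with pytest.raises(FormatError):
        pg.read_newick("(A:0.1,B);")
    tree = pg.read_newick("(A:0.1,B);", default_branch_length=0.3)
    assert tree.total_branch_length == pytest.approx(0.4)


# ------------------------------------------------------------------- JTT


def test_jtt_normalization(jtt):
    assert jtt.equilibrium_freqs.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.abs(jtt.rate_matrix.sum(axis=1)).max() < 1e-12
    mean_rate = -float(jtt.equilibrium_freqs @ np.diag(jtt.rate_matrix))
    assert mean_rate == pytest.approx(1.0, abs=1e-10)


def test_jtt_detailed_balance(jtt):
    flux = jtt.equilibrium_freqs[:, None] * jtt.rate_matrix
    np.testing.assert_allclose(flux, flux.T, atol=1e-14)


def test_transition_matrix_identity_at_zero(jtt):
    np.testing.assert_allclose(jtt.transition_matrix(0.0), np.eye(20), atol=1e-12)


def test_transition_matrix_rows_are_distributions(jtt):
    for t in (0.01, 0.2, 1.0, 10.0):
        p = jtt.transition_matrix(t)
        assert p.min() >= 0
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)


# ------------------------------------------------- pruning likelihood


def _brute_force_loglik(column, tree, model, rate):
    """Sum the joint likelihood over all internal-node state assignments."""
    pi = model.equilibrium_freqs
    internals = tree.postorder
    pmats = {}
    for _parent, child, bl in tree.edges():
        pmats[child] = model.transition_matrix(bl * rate)
    leaf_codes = {
        i: AMINO_ACIDS.index(column[t]) if column[t] in AMINO_ACIDS else None
        for i, t in enumerate(tree.taxon_names)
    }
    total = 0.0
    for assign in itertools.product(range(20), repeat=len(internals)):
        states = dict(zip(internals, assign))
        term = pi[states[tree.root]]
        for parent, child, _bl in tree.edges():
            p = pmats[child]
            if child in states:
                term *= p[states[parent], states[child]]
            else:
                code = leaf_codes[child]
                term *= 1.0 if code is None else p[states[parent], code]
        total += term
    return np.log(total)


def test_two_taxon_matches_direct_sum(jtt):
    tree = pg.read_newick("(A:0.13,B:0.41);")
    rng = np.random.default_rng(7)
    for _ in range(5):
        a, b = rng.choice(list(AMINO_ACIDS), size=2)
        rate = float(rng.uniform(0.05, 5.0))
        col = {"A": a, "B": b}
        expected = _brute_force_loglik(col, tree, jtt, rate)
        assert pg.site_log_likelihood(col, tree, jtt, rate) == pytest.approx(
            expected, abs=1e-10
        )


def test_four_taxon_matches_exhaustive_sum(quartet, jtt):
    rng = np.random.default_rng(11)
    for _ in range(3):
        col = dict(zip("ABCD", rng.choice(list(AMINO_ACIDS + "-"), size=4)))
        rate = float(rng.uniform(0.1, 3.0))
        expected = _brute_force_loglik(col, quartet, jtt, rate)
        assert pg.site_log_likelihood(col, quartet, jtt, rate) == pytest.approx(
            expected, abs=1e-8
        )


def test_matches_independent_r_reference(quartet, jtt):
    """Frozen values computed with R phangorn's pml on the same tree/model."""
    ll = pg.site_log_likelihood({"A": "K", "B": "Q", "C": "K", "D": "L"}, quartet, jtt, 1.0)
    assert ll == pytest.approx(-12.899603252701, abs=1e-6)
    ll2 = pg.site_log_likelihood({"A": "A", "B": "A", "C": "G", "D": "-"}, quartet, jtt, 1.0)
    assert ll2 == pytest.approx(-6.252060120703, abs=1e-6)


def test_gap_only_column_gives_zero(quartet, jtt):
    for rate in (0.01, 1.0, 19.0):
        col = {"A": "-", "B": "-", "C": "X", "D": "-"}
        assert abs(pg.site_log_likelihood(col, quartet, jtt, rate)) < 1e-12


def test_nonpositive_rate_rejected(quartet, jtt):
    with pytest.raises(ValueError):
        pg.site_log_likelihood({"A": "K", "B": "K", "C": "K", "D": "K"}, quartet, jtt, 0.0)


def test_likelihood_invariant_to_rooting(jtt):
    """Pulley principle: rerooting a reversible model changes nothing."""
    variants = [
        "((A:0.2,B:0.2):0.2,C:0.2,D:0.2);",
        "((C:0.2,D:0.2):0.2,A:0.2,B:0.2);",
        "(A:0.2,B:0.2,(C:0.2,D:0.2):0.2);",
        "((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);",
    ]
    col = {"A": "K", "B": "Q", "C": "K", "D": "L"}
    lls = [pg.site_log_likelihood(col, pg.read_newick(v), jtt, 1.3) for v in variants]
    assert max(lls) - min(lls) < 1e-9


# ------------------------------------------------------------- rate cache


def test_cache_grid_spacing(quartet, jtt):
    aln = pg.Alignment.from_sequences(list("ABCD"), ["K", "Q", "K", "L"])
    cache = pg.build_cache(aln, quartet, jtt, grid_size=4000, rate_max=20.0)
    assert cache.rate_min == pytest.approx(0.005)
    assert cache.spacing == pytest.approx((20.0 - 0.005) / 3999)
    assert cache.table.shape == (1, 4000)


def test_cache_values_equal_direct_pruning(quartet, jtt):
    aln = pg.Alignment.from_sequences(list("ABCD"), ["KA", "QA", "KG", "LG"])
    cache = pg.build_cache(aln, quartet, jtt, grid_size=16, rate_max=4.0, rate_min=0.25)
    for site in range(2):
        for g in (0, 7, 15):
            direct = pg.site_log_likelihood(
                aln.column(site), quartet, jtt, float(cache.rate_grid[g])
            )
            assert cache.table[site, g] == pytest.approx(direct, abs=1e-12)


def test_cache_invalid_bounds(quartet, jtt):
    aln = pg.Alignment.from_sequences(list("ABCD"), ["K", "Q", "K", "L"])
    with pytest.raises(ValueError):
        pg.build_cache(aln, quartet, jtt, rate_min=-1.0)
    with pytest.raises(ValueError):
        pg.build_cache(aln, quartet, jtt, grid_size=1)


def test_interp_exact_on_grid_and_midpoint(quartet, jtt):
    aln = pg.Alignment.from_sequences(list("ABCD"), ["K", "Q", "K", "L"])
    cache = pg.build_cache(aln, quartet, jtt, grid_size=100, rate_max=10.0, rate_min=0.1)
    g = 30
    on_grid = pg.interp_log_likelihood(cache, 0, np.log(cache.rate_grid[g]))
    assert on_grid == pytest.approx(cache.table[0, g], abs=1e-12)
    mid = 0.5 * (cache.rate_grid[g] + cache.rate_grid[g + 1])
    expected = 0.5 * (cache.table[0, g] + cache.table[0, g + 1])
    assert pg.interp_log_likelihood(cache, 0, np.log(mid)) == pytest.approx(expected, abs=1e-12)


def test_interp_clamps_out_of_range(quartet, jtt):
    aln = pg.Alignment.from_sequences(list("ABCD"), ["K", "Q", "K", "L"])
    cache = pg.build_cache(aln, quartet, jtt, grid_size=50, rate_max=20.0)
    assert pg.interp_log_likelihood(cache, 0, np.log(50.0)) == pytest.approx(
        cache.table[0, -1]
    )
    assert pg.interp_log_likelihood(cache, 0, -50.0) == pytest.approx(cache.table[0, 0])


def test_interp_accuracy_on_default_grid(quartet, jtt):
    """Linear interpolation on the 4000-point grid is within 0.01 log units
    of exact pruning across the working rate range."""
    rng = np.random.default_rng(3)
    field = pg.RateField(rng.uniform(0.2, 1.8, size=20), np.zeros(20, dtype=bool))
    aln = pg.simulate_alignment(pg.canonical_tree(), jtt, field, rng)
    cache = pg.build_cache(aln, quartet, jtt)
    rates = np.concatenate([[0.01, 18.9], rng.uniform(0.01, 19.0, size=30)])
    exact = loglik_matrix(aln, quartet, jtt, rates)
    for j, rho in enumerate(rates):
        approx = cache.interp_all(np.full(20, np.log(rho)))
        assert np.max(np.abs(approx - exact[:, j])) < 0.01


def test_gap_columns_constant_in_rate(quartet, jtt):
    aln = pg.Alignment.from_sequences(list("ABCD"), ["-K", "-Q", "-K", "-L"])
    cache = pg.build_cache(aln, quartet, jtt, grid_size=64, rate_max=20.0)
    assert np.max(np.abs(cache.table[0])) < 1e-12
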