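"""Joint overhang tables, rank correlation and the independence null model."""

import numpy as np
import pytest
from _oracles import exact_spearman_permutation_p, grid_search_independence

from mirfoot import (
    boundary_base_frequencies,
    fit_independence_model,
    joint_overhang_table,
    rank_correlation,
    restrict_near_canonical,
)
from mirfoot.overhang_stats import class_counts, overhang_correlation
from mirfoot.simulate import coherent_mixture, independent_joint

from conftest import make_record


def _sample_joint(joint, n, seed):
    rng = np.random.default_rng(seed)
    keys = list(joint)
    probs = np.array([joint[k] for k in keys])
    idx = rng.choice(len(keys), size=n, p=probs / probs.sum())
    return [keys[i] for i in idx]


class TestJointTable:
    def test_counting(self):
        table = joint_overhang_table([(2, 2), (2, 2), (1, 3)])
        assert table.counts == {(2, 2): 2, (1, 3): 1}
        assert table.n_total == 3
        assert table.basal_margin() == {2: 2, 1: 1}

    def test_empty(self):
        table = joint_overhang_table([])
        assert table.counts == {} and table.n_total == 0

    def test_sampled_margins_match_generating_marginals(self):
        """Product-distribution sample: margins within multinomial error."""
        pairs = _sample_joint(independent_joint(0.2, 0.1), 10_000, seed=0)
        table = joint_overhang_table(pairs)
        q = {1: 0.2, 2: 0.7, 3: 0.1}
        for margin in (table.basal_margin(), table.apical_margin()):
            for k, target in q.items():
                assert margin[k] / table.n_total == pytest.approx(target, abs=0.02)


class TestRestrictNearCanonical:
    def test_filter_and_fraction(self):
        subset, fraction = restrict_near_canonical([(2, 2), (1, 3), (0, 2), (4, 2)])
        assert subset == [(2, 2), (1, 3)]
        assert fraction == 0.5

    def test_all_canonical(self):
        _, fraction = restrict_near_canonical([(2, 2)] * 5)
        assert fraction == 1.0


class TestRankCorrelation:
    def test_perfect_monotone(self):
        assert rank_correlation([1, 2, 3], [10, 20, 30]).rho == pytest.approx(1.0)

    def test_perfect_antitone(self):
        assert rank_correlation([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)

    def test_antisymmetric_under_reversal(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        assert rank_correlation(x, y).rho == pytest.approx(
            -rank_correlation(x, -y).rho
        )

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rank_correlation([1, 1, 1], [1, 2, 3])

    @pytest.mark.parametrize(
        "x,y",
        [
            ([1, 2, 3, 4], [2, 1, 4, 3]),
            ([1, 2, 3, 4, 5], [5, 3, 1, 2, 4]),
            ([3, 1, 4, 1, 5, 9], [2, 7, 1, 8, 2, 8]),  # with ties
        ],
    )
    def test_small_n_permutation_p_equals_exact_enumeration(self, x, y):
        result = rank_correlation(x, y, method="permutation")
        assert result.method == "permutation(exact)"
        assert result.p_value == pytest.approx(exact_spearman_permutation_p(x, y))
        assert 0 < result.p_value <= 1

    def test_permutation_p_close_to_asymptotic_at_moderate_n(self, rng):
        x = rng.normal(size=40)
        y = x + rng.normal(size=40)
        asym = rank_correlation(x, y)
        perm = rank_correlation(x, y, method="permutation", seed=1)
        assert perm.p_value < 0.01 and asym.p_value < 0.01


class TestIndependenceFit:
    def test_exact_product_table_zero_residual(self):
        q = np.array([0.25, 0.5, 0.25])
        counts = 400 * np.outer(q, q)
        fit = fit_independence_model(counts)
        assert fit.p_short == pytest.approx(0.25)
        assert fit.p_long == pytest.approx(0.25)
        assert fit.obs_over_exp == pytest.approx(np.ones((3, 3)))
        assert fit.gof_stat == pytest.approx(0.0, abs=1e-9)

    def test_matches_grid_search_oracle_on_diagonal_enriched_table(self):
        """Closed-form ML equals an independent zoomed grid search."""
        q = np.array([0.25, 0.5, 0.25])
        counts = 400 * np.outer(q, q)
        counts[0, 0] *= 2
        counts[2, 2] *= 2
        fit = fit_independence_model(counts)
        ps, pl = grid_search_independence(counts)
        assert fit.p_short == pytest.approx(ps, abs=2e-4)
        assert fit.p_long == pytest.approx(pl, abs=2e-4)
        # doubled cells: exactly 2x the generating product model, and still
        # enriched (>1) against the refitted marginals, which absorb part of
        # the excess; every off-diagonal cell is depleted under the fit
        generating_exp = 400 * np.outer(q, q)
        assert counts[0, 0] / generating_exp[0, 0] == pytest.approx(2.0)
        assert counts[2, 2] / generating_exp[2, 2] == pytest.approx(2.0)
        assert fit.obs_over_exp[0, 0] > 1 and fit.obs_over_exp[2, 2] > 1
        off_diag = ~np.eye(3, dtype=bool)
        assert np.all(fit.obs_over_exp[off_diag] < 1)

    def test_least_squares_agrees_on_model_data(self):
        q = np.array([0.2, 0.7, 0.1])
        counts = 1000 * np.outer(q, q)
        fit = fit_independence_model(counts, method="ls")
        assert fit.p_short == pytest.approx(0.2, abs=1e-3)
        assert fit.p_long == pytest.approx(0.1, abs=1e-3)

    def test_per_site_variant_uses_row_and_column_margins(self):
        counts = np.array([[10, 5, 1], [20, 40, 8], [2, 6, 8]], dtype=float)
        fit = fit_independence_model(counts, shared=False)
        n = counts.sum()
        assert fit.q_basal == pytest.approx(tuple(counts.sum(axis=1) / n))
        assert fit.q_apical == pytest.approx(tuple(counts.sum(axis=0) / n))
        assert fit.gof_df == 4

    def test_depletion_factor_consistency(self):
        """canonical/long and canonical/short ratios follow from q exactly."""
        pairs = _sample_joint(independent_joint(0.2, 0.1), 5000, seed=2)
        fit = fit_independence_model(joint_overhang_table(pairs))
        c_over_s, c_over_l = fit.depletion_factors()
        assert c_over_s == pytest.approx(fit.q[1] / fit.p_short)
        assert c_over_l == pytest.approx(fit.q[1] / fit.p_long)

    def test_coupled_mixture_shows_coherence(self):
        """80/20 independent/coherent mixture: positive rank correlation and
        enriched short/short and long/long cells."""
        pairs = _sample_joint(coherent_mixture(0.2, 0.1, 0.2), 10_000, seed=3)
        table = joint_overhang_table(pairs)
        fit = fit_independence_model(table)
        assert fit.obs_over_exp[0, 0] > 1
        assert fit.obs_over_exp[2, 2] > 1
        corr = overhang_correlation(pairs)
        assert corr.rho > 0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fit_independence_model(np.zeros((3, 3)))


class TestBoundaryBaseFrequencies:
    def test_counting_example(self):
        structure = "." * 12
        seqs = ["AAAAAAGAAAAA", "AAAAAACAAAAA", "AAAAAACAAAAA", "AAAAAACAAAAA"]
        records = [
            make_record(structure, matures=[("three_prime", 7, 12)],
                        hairpin_id=f"hsa-{i}", sequence=s)
            for i, s in enumerate(seqs)
        ]
        freqs = boundary_base_frequencies(records, "3p_start")
        assert freqs.loc["G", 0] == pytest.approx(0.25)
        assert freqs.loc["C", 0] == pytest.approx(0.75)

    def test_offsets_outside_hairpin_dropped(self):
        records = [
            make_record("." * 10, matures=[("five_prime", 1, 6)],
                        hairpin_id="hsa-a", sequence="GAAAAAAAAA")
        ]
        freqs = boundary_base_frequencies(records, "5p_start")
        assert np.isnan(freqs.loc["G", -1])  # position 0 does not exist
        assert freqs.loc["G", 0] == 1.0

    def test_uniform_sequences_near_quarter(self, rng):
        n = 2000
        records = []
        for i in range(n):
            seq = "".join(rng.choice(list("ACGU"), size=12))
            records.append(
                make_record("." * 12, matures=[("five_prime", 3, 9)],
                            hairpin_id=f"hsa-{i}", sequence=seq)
            )
        freqs = boundary_base_frequencies(records, "5p_start")
        # binomial 3-sigma band around 0.25 at n=2000
        assert ((freqs - 0.25).abs() < 3 * np.sqrt(0.25 * 0.75 / n)).all().all()
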