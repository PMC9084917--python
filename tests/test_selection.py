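"""Ranking, selection, paired statistics and error stratification."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

import decoyrank as dr
from decoyrank.features import FeatureMatrix
from decoyrank.regression import SvrHyperparams, fit_model, fit_svr
from decoyrank.selection import (
    DecoyEnsemble,
    DegenerateEnsembleWarning,
    compare_methods,
    paired_t,
    rank_decoys,
    select_optimal,
    spearman,
    stratify_errors,
    wilcoxon_signed_rank,
)


def ensemble_from_values(values, energies=None, target_id="t0"):
    n = len(values)
    ids = [f"{target_id}:d{i:03d}" for i in range(n)]
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"p1_a": rng.normal(size=n)}, index=ids)
    fm = FeatureMatrix(
        data=df, column_meta=[(1, "a")],
        energy=None if energies is None else pd.Series(energies, index=ids),
    )
    return DecoyEnsemble(
        target_id=target_id, features=fm,
        true_ha_rmsd=np.asarray(values, dtype=float),
    )


class TestRankDecoys:
    def test_hand_example(self):
        ens = ensemble_from_values([0.5, 1.5, 1.0])
        res = rank_decoys(ens, "true_ha_rmsd")
        assert list(res.ranks) == [1, 3, 2]

    def test_degenerate_constant_criterion(self):
        ens = ensemble_from_values([1.4] * 6)
        with pytest.warns(DegenerateEnsembleWarning):
            res = rank_decoys(ens, "true_ha_rmsd")
        assert np.allclose(res.ranks, 3.5)  # (N+1)/2
        assert np.isnan(res.spearman_vs_true)

    def test_matches_bruteforce_sort_with_tie_averaging(self):
        rng = np.random.default_rng(1)
        values = np.round(rng.normal(size=40), 1)  # induce ties
        ens = ensemble_from_values(np.abs(values))
        res = rank_decoys(ens, "true_ha_rmsd")
        assert np.allclose(res.ranks, rankdata(np.abs(values)))


class TestSpearman:
    def test_perfect_and_reversed(self):
        a = np.array([0.3, 1.1, 2.2, 2.9, 4.0])
        assert spearman(a, a) == pytest.approx(1.0)
        assert spearman(a, -a) == pytest.approx(-1.0)

    def test_hand_rank_formula_example(self):
        assert spearman([1, 2, 3, 4, 5], [1, 3, 2, 5, 4]) == pytest.approx(0.8)

    def test_constant_is_nan_with_warning(self):
        with pytest.warns(DegenerateEnsembleWarning):
            assert np.isnan(spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))


class TestSelectOptimal:
    def test_perfect_model_matches_best_true(self):
        # noiseless plant away from the zero clip: OLS is an oracle
        # predictor, so its argmin equals the true-best decoy everywhere
        suite = dr.generate_feature_suite(
            dr.EnsembleSpec(
                n_targets=6, n_decoys=60, noise_sd=0.0, seed=3,
                rmsd_lognormal_median=2.0, rmsd_lognormal_sigma=0.15,
                rmsd_range=(1.2, 3.2), per_target_variance=0.04,
            )
        )
        model = fit_model("ols", suite.pooled())
        for ens in suite.ensembles:
            d_true, _, _ = select_optimal(ens, "best_true")
            d_model, _, _ = select_optimal(ens, model)
            assert d_true == d_model

    def test_tie_breaks_to_lexically_first_id(self):
        ens = ensemble_from_values([1.0, 1.0, 2.0])
        did, _, ha = select_optimal(ens, "best_true")
        assert did == "t0:d000"
        assert ha == 1.0

    def test_empty_ensemble_rejected(self):
        ens = ensemble_from_values([1.0, 2.0])
        ens.features.data = ens.features.data.iloc[:0]
        with pytest.raises(ValueError, match="empty"):
            select_optimal(ens, "best_true")

    def test_decorrelated_energy_selects_like_random(self):
        """When energy carries no RMSD information, energy selection's mean
        true RMSD sits near the ensemble mean, far above the oracle."""
        rng = np.random.default_rng(2)
        sel_energy, sel_best, ens_means = [], [], []
        for t in range(100):
            y = rng.uniform(0.5, 3.5, 50)
            e = rng.normal(size=50)  # independent of y
            ens = ensemble_from_values(y, energies=e, target_id=f"t{t:03d}")
            _, _, ha_e = select_optimal(ens, "lowest_total_energy")
            _, _, ha_b = select_optimal(ens, "best_true")
            sel_energy.append(ha_e)
            sel_best.append(ha_b)
            ens_means.append(y.mean())
        assert np.mean(sel_energy) == pytest.approx(np.mean(ens_means), abs=0.15)
        assert np.mean(sel_best) < np.mean(sel_energy) - 1.0


class TestWilcoxon:
    def test_all_positive_n6_exact(self):
        stat, p = wilcoxon_signed_rank([0.3, 1.2, 0.7, 2.0, 0.9, 1.4], "greater")
        assert p == pytest.approx(1 / 64)

    def test_symmetric_pairs_two_sided_p_one(self):
        _, p = wilcoxon_signed_rank([1.0, -1.0, 2.0, -2.0, 3.0, -3.0], "two_sided")
        assert p == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank([0.0, 0.0, 0.0, 0.0, 0.0])

    @pytest.mark.parametrize("n", [5, 6, 7, 8, 9, 10])
    def test_matches_exact_sign_enumeration(self, n):
        """Independent oracle: enumerate all 2^n sign assignments of the
        rank magnitudes to build the exact null distribution of W+."""
        rng = np.random.default_rng(n)
        d = rng.normal(scale=2.0, size=n)
        d[d == 0] = 0.5
        ranks = rankdata(np.abs(d))
        w_plus = ranks[d > 0].sum()
        null = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=n)
        ]
        null = np.asarray(null, dtype=float)
        expected = {
            "greater": np.mean(null >= w_plus),
            "less": np.mean(null <= w_plus),
        }
        expected["two_sided"] = min(
            1.0, 2 * min(expected["greater"], expected["less"])
        )
        for alt in ("greater", "less", "two_sided"):
            _, p = wilcoxon_signed_rank(d, alt)
            assert p == pytest.approx(expected[alt], abs=1e-12), alt


class TestPairedT:
    def test_hand_example(self):
        t, p = paired_t(np.array([1.0, 2.0, 3.0]))
        assert t == pytest.approx(2 * np.sqrt(3), abs=1e-9)
        assert p == pytest.approx(0.0742, abs=2e-4)

    def test_zero_variance_rejected(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t(x, x)

    def test_matches_t_cdf_integration(self):
        """p agrees with numerical integration of the t density."""
        from scipy.integrate import quad
        from scipy.special import gamma as G
        d = np.array([0.4, 1.1, -0.2, 0.8, 0.9, 1.5, 0.1])
        t, p = paired_t(d, alternative="greater")
        df = len(d) - 1

        def density(x):
            return (
                G((df + 1) / 2) / (np.sqrt(df * np.pi) * G(df / 2))
                * (1 + x * x / df) ** (-(df + 1) / 2)
            )

        tail, _ = quad(density, t, np.inf)
        assert p == pytest.approx(tail, abs=1e-6)

    def test_direction_agrees_with_wilcoxon(self):
        """On random paired data both tests land on the same side of 0.5."""
        rng = np.random.default_rng(0)
        agreements = 0
        for _ in range(100):
            d = rng.normal(loc=rng.normal(scale=0.5), size=12)
            if np.all(d == 0) or np.ptp(d) == 0:
                continue
            _, pw = wilcoxon_signed_rank(d, "greater")
            _, pt = paired_t(d, alternative="greater")
            agreements += (pw - 0.5) * (pt - 0.5) > 0 or abs(pw - pt) < 0.1
        assert agreements >= 95


class TestCompareMethods:
    def test_identical_selections_give_null_result(self, small_suite):
        comp = compare_methods(
            small_suite.ensembles,
            {"best_true": "best_true", "also_best": "best_true"},
            tests=[(("best_true", "also_best"), "ttest", "two_sided")],
        )
        row = comp.tests.iloc[0]
        assert row["statistic"] == 0.0
        assert row["p"] == 1.0

    def test_summary_sorted_ascending_with_best_first(self, small_suite):
        pool = small_suite.pooled()
        model = fit_model("ols", pool)
        comp = compare_methods(
            small_suite.ensembles,
            {"best_true": "best_true", "model": model,
             "energy": "lowest_total_energy"},
        )
        assert comp.summary.index[0] == "best_true"
        assert comp.summary["mean"].is_monotonic_increasing

    def test_unevaluated_method_in_test_rejected(self, small_suite):
        with pytest.raises(ValueError, match="unevaluated"):
            compare_methods(
                small_suite.ensembles, {"best_true": "best_true"},
                tests=[(("best_true", "energy"), "ttest", "two_sided")],
            )


class TestEndToEndBenchmark:
    def test_trained_selection_beats_energy(self):
        """Planted linear map, decorrelated energy: a trained linSVR ranks
        and selects near-oracle decoys while energy selection does not,
        and a deliberately degraded OLS sits in between."""
        suite = dr.generate_feature_suite(
            dr.EnsembleSpec(n_targets=20, n_decoys=100, seed=4)
        )
        pool = suite.pooled()
        linsvr = fit_svr(pool, kernel="linear", hp=SvrHyperparams(C=0.5))
        rng = np.random.default_rng(0)
        noisy_y = pool.target.to_numpy() + rng.normal(0, 1.0, pool.n_decoys)
        ols_noisy = fit_model("ols", pool, noisy_y)
        comp = compare_methods(
            suite.ensembles,
            {"best_true": "best_true", "linsvr": linsvr,
             "ols_noisy": ols_noisy, "energy": "lowest_total_energy"},
            tests=[(("linsvr", "energy"), "wilcoxon", "less")],
        )
        means = comp.summary["mean"]
        assert means["best_true"] <= means["linsvr"]
        assert means["linsvr"] < means["ols_noisy"]
        assert means["ols_noisy"] < means["energy"]
        assert comp.tests.iloc[0]["p"] < 0.05


class TestStratifyErrors:
    def test_min_count_cells_absent_and_zero_baseline(self, toy_complex):
        from decoyrank.geometry import stratified_rmsd
        # three identical-to-crystal "selected decoys"
        reports = {
            f"t{i}": stratified_rmsd(toy_complex, toy_complex)
            for i in range(3)
        }
        seqs = {"t0": "AVGSYVYSV", "t1": "AVGSYVYSV", "t2": "KLGSYVYAA"}
        table = stratify_errors(reports, seqs, min_count=3)
        assert np.allclose(
            table.by_position[["backbone", "heavy"]].to_numpy(), 0.0
        )
        cells = set(
            zip(table.by_position_aa["position"], table.by_position_aa["amino_acid"])
        )
        assert (3, "G") in cells  # G at position 3 in all three peptides
        assert (1, "A") not in cells  # only 2 peptides have A at position 1
        assert (1, "K") not in cells

    def test_localized_perturbation_shows_at_position_five(self, toy_complex):
        from decoyrank.geometry import stratified_rmsd
        reports, seqs = {}, {}
        for i in range(4):
            decoy = toy_complex.copy()
            m = decoy.chain_mask("P") & (decoy.res_id == 5)
            decoy.coord[m] += np.array([0.4, 0.1, 0.2])
            reports[f"t{i}"] = stratified_rmsd(toy_complex, decoy, superpose=False)
            seqs[f"t{i}"] = "AVGSYVYSV"
        table = stratify_errors(reports, seqs, min_count=3)
        heavy = table.by_position["heavy"]
        assert heavy.loc[5] > 0.1
        assert np.allclose(heavy.drop(5), 0.0, atol=1e-12)
        # marginal means match direct recomputation
        manual = np.mean([r.per_position["heavy"][4] for r in reports.values()])
        assert heavy.loc[5] == pytest.approx(manual, abs=1e-12)

    def test_wrong_sequence_length_rejected(self, toy_complex):
        from decoyrank.geometry import stratified_rmsd
        reports = {"t0": stratified_rmsd(toy_complex, toy_complex)}
        with pytest.raises(ValueError, match="length"):
            stratify_errors(reports, {"t0": "SHORT"}, min_count=1)


# -- property tests ---------------------------------------------------------

from hypothesis import given, settings, strategies as st

finite_floats = st.floats(
    min_value=0.0, max_value=10.0, allow_nan=False, allow_infinity=False
)


@settings(max_examples=50, derandomize=True)
@given(st.lists(finite_floats, min_size=3, max_size=40))
def test_ranks_are_midrank_permutation(values):
    """Ranks always sum to n(n+1)/2 and respect the value ordering."""
    ens = ensemble_from_values(values)
    res = rank_decoys(ens, "true_ha_rmsd")
    n = len(values)
    assert res.ranks.sum() == pytest.approx(n * (n + 1) / 2)
    order = np.argsort(values, kind="stable")
    ranked = res.ranks[order]
    assert np.all(np.diff(ranked) >= -1e-12)


@settings(max_examples=50, derandomize=True)
@given(st.lists(finite_floats, min_size=3, max_size=25),
       st.integers(min_value=0, max_value=2**31 - 1))
def test_spearman_bounded_and_symmetric(values, seed):
    a = np.asarray(values)
    b = np.random.default_rng(seed).permutation(a)
    if np.ptp(a) == 0:
        return
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateEnsembleWarning)
        r1, r2 = spearman(a, b), spearman(b, a)
    if not np.isnan(r1):
        assert -1.0 - 1e-12 <= r1 <= 1.0 + 1e-12
        assert r1 == pytest.approx(r2, abs=1e-12)
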