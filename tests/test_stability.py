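"""Stability algorithms against brute-force oracles, consensus ranking,
imputation semantics and reference selection."""

import numpy as np
import pandas as pd
import pytest

from censq import (
    aggregate_ranks,
    apply_well_qc,
    bestkeeper_stats,
    comparative_deltact,
    genorm,
    hemolysis_check,
    impute_censored,
    normfinder_stability,
    select_references,
    simulate_cohort,
    stability_table,
)

from conftest import small_config


def _genorm_bruteforce(df):
    """Literal double-loop geNorm M: mean over j≠i of SD(Cq_i − Cq_j)."""
    out = {}
    for i in df.index:
        sds = [np.std(df.loc[i] - df.loc[j], ddof=1) for j in df.index if j != i]
        out[i] = float(np.mean(sds))
    return pd.Series(out)


def _random_panel(rng, k=10, n=20):
    return pd.DataFrame(
        rng.normal(28, 2, (k, n)),
        index=[f"g{i}" for i in range(k)],
        columns=[f"s{j}" for j in range(n)],
    )


class TestGeNorm:
    def test_matches_bruteforce_and_deltact_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            panel = _random_panel(rng)
            m, _ = genorm(panel)
            oracle = _genorm_bruteforce(panel)
            assert np.allclose(m, oracle[m.index], atol=1e-12)
            # comparative ΔCt is exactly the first geNorm pass
            np.testing.assert_allclose(
                comparative_deltact(panel).to_numpy(), m.to_numpy(), atol=1e-12
            )

    def test_co_stable_pair_survives_elimination(self):
        rng = np.random.default_rng(1)
        panel = _random_panel(rng, k=6)
        panel.loc["g1"] = panel.loc["g0"] + 3.0  # SD(g0 − g1) = 0
        _, ranks = genorm(panel)
        assert ranks["g0"] == ranks["g1"] == 1.5

    def test_per_sample_constant_invariance(self):
        rng = np.random.default_rng(2)
        panel = _random_panel(rng)
        shifted = panel + rng.normal(0, 5, panel.shape[1])  # same shift all genes
        m1, _ = genorm(panel)
        m2, _ = genorm(shifted)
        np.testing.assert_allclose(m1, m2, atol=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        panel = _random_panel(rng, k=6)
        perm = panel.sample(frac=1, random_state=1)
        m1, _ = genorm(panel)
        m2, _ = genorm(perm)
        np.testing.assert_allclose(m1.sort_index(), m2.sort_index(), atol=1e-12)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            genorm(_random_panel(np.random.default_rng(0), k=2))


class TestComparativeDeltaCt:
    def test_two_gene_symmetry(self):
        rng = np.random.default_rng(4)
        panel = _random_panel(rng, k=2)
        scores = comparative_deltact(panel)
        sd = np.std(panel.iloc[0] - panel.iloc[1], ddof=1)
        assert scores.iloc[0] == pytest.approx(sd, abs=1e-12)
        assert scores.iloc[1] == pytest.approx(sd, abs=1e-12)

    def test_constant_gene_wins_only_without_covariation(self):
        # flat gene vs two *independently* noisy genes: flat wins
        rng = np.random.default_rng(11)
        indep = pd.DataFrame(
            [[25.0] * 6, rng.normal(30, 2, 6), rng.normal(20, 2, 6)],
            index=["flat", "noisy1", "noisy2"], columns=list("abcdef"),
        )
        scores = comparative_deltact(indep)
        assert scores.idxmin() == "flat"
        # but when the noisy genes co-vary strongly, their mutual pairwise
        # SD vanishes and the flat gene loses — a known ΔCt-method trait
        co = indep.copy()
        co.loc["noisy2"] = co.loc["noisy1"] - 10.0 + rng.normal(0, 0.05, 6)
        co_scores = comparative_deltact(co)
        assert co_scores.idxmin() != "flat"
        # both regimes agree with the brute-force double loop
        for panel in (indep, co):
            oracle = _genorm_bruteforce(panel)
            np.testing.assert_allclose(
                comparative_deltact(panel), oracle[panel.index], atol=1e-12
            )


class TestBestKeeper:
    def test_hand_computation_toy(self):
        panel = pd.DataFrame(
            [[20.0, 21.0, 22.0, 23.0, 24.0],
             [30.0, 30.0, 30.0, 30.0, 30.0],
             [25.0, 26.0, 24.0, 27.0, 23.0]],
            index=["a", "flat", "c"], columns=list("vwxyz"),
        )
        out = bestkeeper_stats(panel)
        assert out.loc["a", "bestkeeper_sd"] == pytest.approx(np.std([20, 21, 22, 23, 24], ddof=1))
        assert out.loc["a", "bestkeeper_cv"] == pytest.approx(100 * out.loc["a", "bestkeeper_sd"] / 22.0)
        assert out.loc["flat", "bestkeeper_sd"] == 0.0
        assert out.loc["flat", "bestkeeper_cv"] == 0.0
        assert out.loc["flat", "bestkeeper_r"] == 1.0  # convention for zero variance
        assert out["bestkeeper_sd"].rank()["flat"] == 1.0

    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(5)
        g = rng.normal(25, 1, 10)
        panel = pd.DataFrame([g, g + 4.0], index=["a", "b"])
        out = bestkeeper_stats(panel)
        assert out["bestkeeper_r"].to_numpy() == pytest.approx([1.0, 1.0])


def _normfinder_bruteforce(df, groups):
    """Loop implementation of the model-based decomposition."""
    k = df.shape[0]
    labels = sorted(set(groups))
    var_hat, d_hat, n_per = {}, {}, {}
    for g in labels:
        cols = [c for c, lab in zip(df.columns, groups) if lab == g]
        sub = df[cols]
        n = len(cols)
        n_per[g] = n
        grand = sub.to_numpy().mean()
        z = {}
        for i in df.index:
            rss = 0.0
            for c in cols:
                r = (sub.loc[i, c] - sub.loc[i].mean()
                     - sub[c].mean() + grand)
                rss += r * r
            z[i] = rss / (n - 1)
        zsum = sum(z.values())
        var_hat[g] = {i: max(0.0, k / (k - 2) * (z[i] - zsum / (k * (k - 1))))
                      for i in df.index}
        centred = {i: sub.loc[i].mean() - np.mean([sub.loc[j].mean() for j in df.index])
                   for i in df.index}
        d_hat[g] = centred
    # centre the biases across groups per gene
    for i in df.index:
        mean_g = np.mean([d_hat[g][i] for g in labels])
        for g in labels:
            d_hat[g][i] -= mean_g
    stab = {}
    d_tilde = {g: {} for g in labels}
    for g in labels:
        samp_var = {i: var_hat[g][i] / n_per[g] for i in df.index}
        gamma2 = max(0.0, sum(d_hat[g][i] ** 2 for i in df.index) / (k - 1)
                     - np.mean(list(samp_var.values())))
        for i in df.index:
            shrink = gamma2 / (gamma2 + samp_var[i]) if gamma2 > 0 else 0.0
            d_tilde[g][i] = d_hat[g][i] * shrink
    for i in df.index:
        stab[i] = (np.mean([abs(d_tilde[g][i]) for g in labels])
                   + np.mean([np.sqrt(var_hat[g][i] / n_per[g]) for g in labels]))
    return pd.Series(stab)


class TestNormFinder:
    @pytest.fixture()
    def fixture_5x12(self):
        rng = np.random.default_rng(6)
        df = _random_panel(rng, k=5, n=12)
        groups = ["A"] * 6 + ["B"] * 6
        return df, groups

    def test_pinned_against_bruteforce(self, fixture_5x12):
        df, groups = fixture_5x12
        ours = normfinder_stability(df, pd.Series(groups, index=df.columns))
        oracle = _normfinder_bruteforce(df, groups)
        np.testing.assert_allclose(ours, oracle[ours.index], atol=1e-10)

    def test_location_invariance(self, fixture_5x12):
        df, groups = fixture_5x12
        g = pd.Series(groups, index=df.columns)
        base = normfinder_stability(df, g)
        shifted = df.copy()
        shifted.loc[df.index[2]] += 7.0  # same constant in all samples/groups
        moved = normfinder_stability(shifted, g)
        np.testing.assert_allclose(base, moved, atol=1e-10)

    def test_planted_stable_gene_wins(self):
        rng = np.random.default_rng(7)
        wins = 0
        for _ in range(100):
            k, n = 6, 20
            df = pd.DataFrame(
                rng.normal(28, 1.0, (k, 2 * n)),
                index=[f"g{i}" for i in range(k)],
            )
            df.iloc[0] = rng.normal(28, 0.1, 2 * n)  # tiny variance, no group effect
            # group biases drawn from the model: they sum to zero across
            # genes, the planted gene holding exactly zero
            effects = rng.normal(0, 1.0, k - 1)
            effects -= effects.mean()
            for i in range(1, k):
                df.iloc[i, n:] += effects[i - 1]
            groups = pd.Series(["A"] * n + ["B"] * n, index=df.columns)
            stab = normfinder_stability(df, groups)
            wins += stab.idxmin() == "g0"
        assert wins >= 95

    def test_single_group_fallback(self, fixture_5x12):
        df, _ = fixture_5x12
        one = normfinder_stability(df, pd.Series("A", index=df.columns))
        assert (one > 0).all()


class TestAggregation:
    def test_geometric_mean_exact(self):
        ranks = pd.DataFrame(
            {"a": [1.0, 1.0], "b": [2.0, 1.0], "c": [2.0, 1.0], "d": [4.0, 1.0]},
            index=["x", "y"],
        )
        score = aggregate_ranks(ranks)
        assert score["x"] == pytest.approx((1 * 2 * 2 * 4) ** 0.25, abs=1e-12)  # = 2
        assert score["x"] == pytest.approx(2.0, abs=1e-12)
        assert score["y"] == pytest.approx(1.0, abs=1e-12)

    def test_column_order_invariance(self):
        rng = np.random.default_rng(8)
        ranks = pd.DataFrame(rng.integers(1, 10, (6, 4)).astype(float),
                             columns=list("abcd"))
        s1 = aggregate_ranks(ranks)
        s2 = aggregate_ranks(ranks[["d", "b", "a", "c"]])
        np.testing.assert_allclose(s1, s2, atol=1e-12)


class TestImputation:
    def test_complete_matrix_unchanged(self, toy_matrix, toy_samples):
        m = toy_matrix.copy()
        m.values.loc["miR-x", "s3"] = 31.5  # fill the only hole
        complete, excluded = impute_censored(m, toy_samples, seed=0)
        pd.testing.assert_frame_equal(complete, m.values, check_names=False)
        assert excluded == []

    def test_censored_cells_at_or_beyond_limit_and_deterministic(self, small_cohort):
        matrix, samples, _ = small_cohort
        matrix, _ = apply_well_qc(matrix)
        samples = hemolysis_check(matrix, samples)
        c1, _ = impute_censored(matrix, samples, seed=3)
        c2, _ = impute_censored(matrix, samples, seed=3)
        pd.testing.assert_frame_equal(c1, c2)
        cens = matrix.censored_mask[c1.columns].loc[c1.index]
        assert (c1.to_numpy()[cens.to_numpy()] >= matrix.detection_limit).all()
        # observed cells never modified
        obs = matrix.values[c1.columns].loc[c1.index].notna()
        np.testing.assert_array_equal(
            c1.to_numpy()[obs.to_numpy()],
            matrix.values[c1.columns].loc[c1.index].to_numpy()[obs.to_numpy()],
        )

    def test_imputed_mean_matches_truncated_normal(self):
        # one gene, heavy censoring, many samples: mean of imputed cells
        # approaches the analytic truncated mean of the fitted parameters
        from censq import CtMatrix, fit_censored_normal, truncated_normal_mean
        rng = np.random.default_rng(9)
        n = 4000
        raw = rng.normal(38.0, 2.0, n)
        vals = np.where(raw > 40.0, np.nan, raw)
        cols = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
        idx = pd.Index(["g1", "g2", "g3"], name="target_id")
        values = pd.DataFrame(
            np.vstack([vals, rng.normal(30, 1, n), rng.normal(25, 1, n)]),
            index=idx, columns=cols,
        )
        matrix = CtMatrix(values=values,
                          amp_score=pd.DataFrame(1.5, index=idx, columns=cols),
                          cq_confidence=pd.DataFrame(0.9, index=idx, columns=cols))
        samples = pd.DataFrame({"group": ["CNT"] * (n // 2) + ["OMA"] * (n // 2)},
                               index=cols)
        complete, _ = impute_censored(matrix, samples, seed=1)
        hole = values.loc["g1"].isna()
        imputed = complete.loc["g1", hole]
        fit = fit_censored_normal(values.loc["g1"].fillna(40).to_numpy()[: n // 2],
                                  hole.to_numpy()[: n // 2], 40.0)
        expected = truncated_normal_mean(fit.mu, fit.sigma, 40.0)
        assert imputed.mean() == pytest.approx(expected, abs=0.1)


class TestSelection:
    def test_constant_detected_gene_selected_k1(self):
        table = pd.DataFrame(
            {
                "overall_rank_score": [1.0, 2.5, 3.0],
                "genorm_m": [0.1, 0.5, 0.9],
                "tost_p": [1e-6, 1e-3, 0.2],
                "detected_frac": [1.0, 0.97, 1.0],
            },
            index=["flat", "ok", "unstable"],
        )
        refs = select_references(table, k=1)
        assert refs.reference_ids == ["flat"]

    def test_too_few_candidates_informative_error(self):
        table = pd.DataFrame(
            {"overall_rank_score": [1.0], "genorm_m": [0.1],
             "tost_p": [0.5], "detected_frac": [1.0]},
            index=["g"],
        )
        with pytest.raises(ValueError, match="TOST"):
            select_references(table, k=1)

    def test_full_selection_on_cohort(self, small_cohort):
        matrix, samples, truth = small_cohort
        matrix, _ = apply_well_qc(matrix)
        samples = hemolysis_check(matrix, samples)
        complete, _ = impute_censored(matrix, samples, seed=2)
        stab = stability_table(complete, samples, matrix)
        refs = select_references(stab, k=3, matrix=matrix, samples=samples)
        assert set(refs.reference_ids) == set(truth.reference_ids)
        assert (stab.loc[refs.reference_ids, "detected_frac"] >= 0.95).all()
        # norm factor = arithmetic mean of the three reference Cqs
        s = refs.norm_factor.index[0]
        manual = matrix.values.loc[refs.reference_ids, s].mean()
        assert refs.norm_factor[s] == pytest.approx(manual)
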