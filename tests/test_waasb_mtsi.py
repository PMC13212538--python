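"""WAASB stability, WAASBY blending, factor analysis and MTSI selection."""

import numpy as np
import pandas as pd
import pytest

from metstab import (
    AmmiModel,
    FactorModel,
    GamemModel,
    SyntheticConfig,
    cell_means,
    mtsi,
    selection_differentials,
    simulate_met,
    waasb,
    waasb_scores,
    waasby,
)
from metstab.exceptions import DomainError, InputError, UnsupportedDesignError
from metstab.waasb import interaction_scores


class TestWaasb:
    def test_brute_force_weighted_mean(self, default_sim):
        data, _ = default_sim
        res = GamemModel(data, "Y").fit()
        scores, ep = interaction_scores(res.blup_ge)
        w = waasb_scores(res.blup_ge)
        brute = np.zeros(len(scores))
        for k in range(scores.shape[1]):
            brute += np.abs(scores.iloc[:, k].to_numpy()) * ep[k]
        brute /= ep.sum()
        assert np.allclose(w.to_numpy(), brute, atol=1e-12)

    def test_weighted_mean_example(self):
        """Scores (|2|, |1|) with explained proportions (0.9, 0.1) -> 1.9."""
        assert 2 * 0.9 + 1 * 0.1 == pytest.approx(1.9)
        # and via the implementation on a matrix engineered to have those
        # scores: brute-force identity already pins the formula, so the
        # arithmetic example is asserted directly on the weights
        ep = np.array([0.9, 0.1])
        s = np.array([[2.0, -1.0]])
        assert (np.abs(s) * ep).sum() / ep.sum() == pytest.approx(1.9)

    def test_single_axis_equals_abs_score(self):
        cfg = SyntheticConfig(
            n_genotypes=7, n_environments=4, n_replicates=2,
            ge_rank=1, var_residual=0.0, seed=13,
        )
        data, _ = simulate_met(cfg)
        z = cell_means(data, "Y").interaction()
        scores, _ = interaction_scores(z)
        w = waasb_scores(z)
        assert scores.shape[1] == 1
        assert np.allclose(w, scores.iloc[:, 0].abs(), atol=1e-10)

    def test_zero_matrix_gives_zero(self):
        z = pd.DataFrame(np.zeros((4, 3)), index=list("ABCD"))
        assert np.allclose(waasb_scores(z), 0.0)

    def test_fixed_and_blup_variants(self, default_sim):
        data, _ = default_sim
        waas = waasb(AmmiModel(data, "Y").fit())
        wb = waasb(GamemModel(data, "Y").fit())
        assert waas.name == "WAAS" and wb.name == "WAASB"
        # BLUP shrinkage: WAASB no larger than WAAS on average
        assert wb.mean() <= waas.mean() + 1e-9


class TestWaasby:
    def _series(self, vals, name="x"):
        return pd.Series(vals, index=[f"G{i+1}" for i in range(len(vals))],
                         name=name, dtype=float)

    def test_best_both_is_100(self):
        out = waasby(self._series([10, 5, 1]), self._series([0.1, 1.0, 2.0]))
        assert out.loc["G1", "WAASBY"] == pytest.approx(100.0)

    def test_best_mean_worst_stability_65(self):
        out = waasby(self._series([10, 5, 1]), self._series([2.0, 1.0, 0.1]))
        assert out.loc["G1", "WAASBY"] == pytest.approx(65.0)

    def test_weight_100_matches_mean_order(self):
        rng = np.random.default_rng(0)
        means = self._series(rng.normal(size=8))
        w = self._series(rng.uniform(size=8))
        out = waasby(means, w, mean_weight=100.0)
        assert (out["WAASBY"].rank() == means.rank()).all()

    def test_constant_column_rejected(self):
        with pytest.raises(DomainError):
            waasby(self._series([1, 1, 1]), self._series([0.1, 0.2, 0.3]))

    def test_lower_better_direction_reverses(self):
        means = self._series([10, 5, 1])
        w = self._series([1.0, 1.5, 2.0])
        hi = waasby(means, w, direction="higher")
        lo = waasby(means, w, direction="lower")
        assert hi.loc["G1", "rY"] == 100.0 and lo.loc["G1", "rY"] == 0.0

    def test_monotone_in_mean(self):
        rng = np.random.default_rng(1)
        means = self._series(rng.normal(50, 5, size=10))
        w = self._series(rng.uniform(0.5, 2.0, size=10))
        base = waasby(means, w)
        bumped = means.copy()
        bumped["G4"] += 1.0
        out = waasby(bumped, w)
        assert out.loc["G4", "WAASBY"] >= base.loc["G4", "WAASBY"] - 1e-9

    def test_quadrant_iv_high_mean_low_waasb(self):
        means = self._series([10, 9, 2, 1])
        w = self._series([0.1, 2.0, 0.1, 2.0])
        out = waasby(means, w)
        assert list(out["quadrant"]) == ["IV", "II", "III", "I"]


class TestEfa:
    def _two_factor_table(self, n=40, seed=5, noise=0.0):
        rng = np.random.default_rng(seed)
        f = rng.standard_normal((n, 2))
        loadings = np.array(
            [[0.9, 0.0], [0.85, 0.0], [0.8, 0.0],
             [0.0, 0.9], [0.0, 0.85], [0.0, 0.8]]
        )
        x = f @ loadings.T + noise * rng.standard_normal((n, 6))
        return (
            pd.DataFrame(x, columns=[f"T{i}" for i in range(6)],
                         index=[f"G{i}" for i in range(n)]),
            loadings,
        )

    def test_recovers_planted_two_factor_structure(self):
        table, true_l = self._two_factor_table()
        fm = FactorModel(table).fit(ideal=table.max())
        assert fm.n_factors == 2
        assert fm.cumulative_explained[1] > 99.0
        est = fm.loadings.to_numpy()
        congr = np.abs(
            (est / np.linalg.norm(est, axis=0)).T
            @ (true_l / np.linalg.norm(true_l, axis=0))
        )
        assert (congr.max(axis=0) > 0.99).all()

    def test_varimax_preserves_communality_and_total(self):
        table, _ = self._two_factor_table(noise=0.4)
        fm = FactorModel(table).fit(ideal=table.max())
        h_rot = (fm.loadings.to_numpy() ** 2).sum(axis=1)
        h_unrot = (fm.unrotated_loadings.to_numpy() ** 2).sum(axis=1)
        assert np.allclose(h_rot, h_unrot, atol=1e-8)
        assert np.allclose(h_rot.sum(), h_unrot.sum(), atol=1e-8)

    def test_simple_structure_is_fixed_point(self):
        table, true_l = self._two_factor_table()
        fm = FactorModel(table).fit(ideal=table.max())
        # rotated solution for data that already has simple structure keeps
        # one dominant loading per trait
        top = np.sort(np.abs(fm.loadings.to_numpy()), axis=1)
        assert (top[:, -1] > 0.95).all()
        assert (top[:, 0] < 0.12).all()

    def test_fewer_than_three_traits_rejected(self):
        t = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 2)))
        with pytest.raises(UnsupportedDesignError):
            FactorModel(t)

    def test_communality_in_unit_interval(self):
        table, _ = self._two_factor_table(noise=0.8)
        fm = FactorModel(table).fit(ideal=table.max())
        assert ((fm.communality >= 0) & (fm.communality <= 1 + 1e-9)).all()
        assert np.allclose(fm.communality + fm.uniqueness, 1.0)


class TestMtsi:
    def _manual_result(self):
        """Hand-built factor scores around a (0, 0) ideotype."""
        from metstab.mtsi import FactorResults

        scores = pd.DataFrame(
            [[0.0, 0.0], [3.0, 4.0], [1.0, 1.0]],
            index=["ideal-like", "far", "near"], columns=["FA1", "FA2"],
        )
        fm = FactorResults(
            traits=["a", "b", "c"],
            eigenvalues=np.array([2.0, 1.0, 0.0]),
            explained=np.array([66.7, 33.3, 0.0]),
            loadings=pd.DataFrame(np.eye(3, 2), index=["a", "b", "c"],
                                  columns=["FA1", "FA2"]),
            unrotated_loadings=pd.DataFrame(np.eye(3, 2), index=["a", "b", "c"],
                                            columns=["FA1", "FA2"]),
            rotation=np.eye(2),
            communality=pd.Series([1.0, 1.0, 0.0], index=["a", "b", "c"]),
            scores=scores,
            ideotype_scores=pd.Series([0.0, 0.0], index=["FA1", "FA2"]),
            ideal=pd.Series(100.0, index=["a", "b", "c"]),
        )
        return mtsi(fm)

    def test_distances_and_contributions(self):
        res = self._manual_result()
        assert res.mtsi["ideal-like"] == pytest.approx(0.0)
        assert res.mtsi["far"] == pytest.approx(5.0)  # 3-4-5 triangle
        assert res.contributions.loc["far"].to_numpy() == pytest.approx([36.0, 64.0])
        sums = res.contributions.loc[["far", "near"]].sum(axis=1)
        assert np.allclose(sums, 100.0)

    def test_selection_counts_and_ties(self):
        base = self._manual_result()
        # 30 genotypes, 15%, no ties -> ceil(4.5) = 5 selected
        m = pd.Series(np.arange(30, dtype=float) + 1, index=[f"G{i}" for i in range(30)])
        res = base
        res = mtsi_like(res, m)
        sel = res.select(15.0)
        assert len(sel.selected) == 5
        assert sel.cutpoint == 5.0
        # all selected at 100%
        assert len(res.select(100.0).selected) == 30
        # three-way tie at the cutpoint all included
        m2 = m.copy()
        m2.iloc[4] = m2.iloc[5] = m2.iloc[6] = 5.0
        assert len(mtsi_like(res, m2).select(15.0).selected) == 7

    def test_bad_intensity_rejected(self):
        res = self._manual_result()
        with pytest.raises(InputError):
            res.select(0.0)
        with pytest.raises(InputError):
            res.select(120.0)


def mtsi_like(res, new_mtsi):
    """Clone an MtsiResult with replaced distances (selection-rule testing)."""
    from metstab.mtsi import MtsiResult

    contrib = pd.DataFrame(
        50.0, index=new_mtsi.index, columns=res.contributions.columns
    )
    return MtsiResult(mtsi=new_mtsi, contributions=contrib, factors=res.factors)


class TestSelectionDifferentials:
    def test_basic_numbers(self):
        tab = pd.DataFrame(
            {"T1": [40.0, 60.0, 50.0], "T2": [1.0, 3.0, 2.0]},
            index=["A", "B", "C"],
        )
        out = selection_differentials(tab, ["B"], h2=1.0)
        assert out.loc["T1", "Xo"] == pytest.approx(50.0)
        assert out.loc["T1", "Xs"] == pytest.approx(60.0)
        assert out.loc["T1", "SD"] == pytest.approx(10.0)
        assert out.loc["T1", "SDperc"] == pytest.approx(20.0)
        assert out.loc["T1", "SG"] == pytest.approx(10.0)  # h2 = 1 -> SG = SD

    def test_select_all_zero_differential(self):
        tab = pd.DataFrame({"T1": [1.0, 2.0]}, index=["A", "B"])
        out = selection_differentials(tab, ["A", "B"])
        assert out["SD"].to_numpy() == pytest.approx([0.0])

    def test_heritability_scales_gain(self):
        tab = pd.DataFrame({"T1": [40.0, 60.0]}, index=["A", "B"])
        out = selection_differentials(tab, ["B"], h2=pd.Series({"T1": 0.5}))
        assert out.loc["T1", "SG"] == pytest.approx(out.loc["T1", "SD"] * 0.5)

    def test_empty_selection_rejected(self):
        tab = pd.DataFrame({"T1": [1.0, 2.0]}, index=["A", "B"])
        with pytest.raises(InputError):
            selection_differentials(tab, [])
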