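"""GGE model fitting and biplot-view geometry."""

import numpy as np
import pandas as pd
import pytest

from metstab import GgeModel, SyntheticConfig, cell_means, simulate_met
from metstab.data import GEMatrix
from metstab.exceptions import DomainError


def _gem(arr, genotypes=None, environments=None):
    arr = np.asarray(arr, dtype=float)
    g, e = arr.shape
    means = pd.DataFrame(
        arr,
        index=genotypes or [f"G{i+1}" for i in range(g)],
        columns=environments or [f"E{j+1}" for j in range(e)],
    )
    return GEMatrix("t", means, means * 0 + 1, True)


def _rank2_sim(seed, g=10, e=5):
    cfg = SyntheticConfig(
        n_genotypes=g, n_environments=e, n_replicates=2,
        ge_rank=1, var_residual=0.0, var_rep_within_env=0.0, seed=seed,
    )
    data, _ = simulate_met(cfg)
    return cell_means(data, "Y")


class TestFit:
    def test_environment_centering(self, default_sim):
        data, _ = default_sim
        gem = cell_means(data, "Y")
        res = GgeModel(gem).fit()
        assert np.allclose(res.centered.mean(axis=0), 0.0, atol=1e-9)

    def test_rank2_two_axes_explain_all(self):
        res = GgeModel(_rank2_sim(0)).fit()
        assert res.explained[:2].sum() == pytest.approx(100.0, abs=1e-8)

    def test_translation_invariance(self, default_sim):
        data, _ = default_sim
        gem = cell_means(data, "Y")
        res1 = GgeModel(gem).fit()
        shifted = gem.means.copy()
        shifted["E2"] += 1000.0
        gem2 = GEMatrix("t", shifted, gem.rep_counts, True)
        res2 = GgeModel(gem2).fit()
        assert np.allclose(
            res1.genotype_scores, res2.genotype_scores, atol=1e-8
        )

    def test_genotype_svp_distance_identity(self):
        gem = _rank2_sim(3)
        res = GgeModel(gem, svp="genotype").fit()
        pts = res.genotype_scores.iloc[:, :2].to_numpy()
        rows = res.centered.to_numpy()
        for i in range(3):
            for j in range(i + 1, 4):
                d_scores = np.linalg.norm(pts[i] - pts[j])
                d_rows = np.linalg.norm(rows[i] - rows[j])
                assert d_scores == pytest.approx(d_rows, rel=1e-8)

    def test_inner_product_identity_rank2(self):
        res = GgeModel(_rank2_sim(5)).fit()
        gen, env = (
            res.genotype_scores.iloc[:, :2].to_numpy(),
            res.environment_scores.iloc[:, :2].to_numpy(),
        )
        assert np.allclose(gen @ env.T, res.centered.to_numpy(), atol=1e-8)

    def test_sd_scaling_constant_column_rejected(self):
        arr = np.column_stack([np.arange(4.0), np.full(4, 2.0)])
        arr = np.column_stack([arr, np.arange(4.0) ** 2])
        with pytest.raises(DomainError):
            GgeModel(_gem(arr), scaling="sd").fit()


class TestWhichWonWhere:
    def test_dominant_genotype_wins_everywhere(self):
        rng = np.random.default_rng(2)
        arr = rng.normal(0, 0.5, size=(6, 4))
        arr[2] += 20.0  # overwhelming main effect
        res = GgeModel(_gem(arr)).fit()
        www = res.which_won_where()
        assert all(www.winner_for(e) == "G3" for e in res.centered.columns)

    def test_winners_match_argmax_of_centered_means(self):
        agree = total = 0
        for seed in range(50):
            gem = _rank2_sim(seed)
            res = GgeModel(gem).fit()
            www = res.which_won_where()
            argmax = gem.means.sub(gem.means.mean(axis=0), axis=1).idxmax()
            for e in gem.environments:
                total += 1
                agree += www.winner_for(e) == argmax[e]
        assert agree == total

    def test_square_symmetry_four_sectors(self):
        # four symmetric genotype points plus one interior point
        pts = {"N": (0, 2), "E": (2, 0), "S": (0, -2), "W": (-2, 0)}
        arr = np.array([[0.0, 2.0], [2.0, 0.0], [0.0, -2.0], [-2.0, 0.0],
                        [0.1, 0.1]])
        # fabricate scores directly through a results object
        from metstab.gge import GgeResults

        res = GgeResults(
            trait="t",
            centered=pd.DataFrame(np.zeros((5, 4))),
            singular_values=np.array([2.0, 2.0]),
            explained=np.array([50.0, 50.0]),
            genotype_scores=pd.DataFrame(
                arr, index=list(pts) + ["mid"], columns=["PC1", "PC2"]
            ),
            environment_scores=pd.DataFrame(
                [[1.0, 1.0], [1.0, -1.0], [-1.0, -1.0], [-1.0, 1.0]],
                index=["E1", "E2", "E3", "E4"], columns=["PC1", "PC2"],
            ),
            svp="environment",
        )
        www = res.which_won_where()
        assert set(www.hull_vertices) == {"N", "E", "S", "W"}
        assert len(www.sector_boundaries) == 4
        diffs = np.diff(np.sort(www.sector_boundaries))
        assert np.allclose(diffs, np.pi / 2)
        winners = {e: www.winner_for(e) for e in ["E1", "E2", "E3", "E4"]}
        assert winners == {"E1": "N", "E2": "E", "E3": "S", "E4": "W"}

    def test_collinear_points_degenerate(self):
        from metstab.gge import GgeResults

        res = GgeResults(
            trait="t",
            centered=pd.DataFrame(np.zeros((3, 2))),
            singular_values=np.array([1.0, 0.0]),
            explained=np.array([100.0, 0.0]),
            genotype_scores=pd.DataFrame(
                [[1.0, 0.0], [2.0, 0.0], [3.0, 0.0]],
                index=["A", "B", "C"], columns=["PC1", "PC2"],
            ),
            environment_scores=pd.DataFrame(
                [[1.0, 0.0]], index=["E1"], columns=["PC1", "PC2"]
            ),
            svp="environment",
        )
        with pytest.raises(DomainError):
            res.which_won_where()


class TestMeanVsStability:
    def test_parallel_point_zero_deviation(self):
        res = GgeModel(_rank2_sim(7)).fit()
        a = res.aea_direction
        ms = res.mean_vs_stability()
        # a synthetic point exactly on the AEA has zero deviation: check the
        # identity for the projection decomposition of every genotype
        gen = res.genotype_scores.iloc[:, :2].to_numpy()
        recon = np.outer(ms["mean_projection"], a)
        assert np.allclose(
            np.linalg.norm(gen - recon, axis=1),
            ms["stability_deviation"],
            atol=1e-10,
        )

    def test_projection_order_matches_means_at_rank2(self):
        gem = _rank2_sim(9)
        res = GgeModel(gem).fit()
        ms = res.mean_vs_stability()
        raw_order = gem.means.mean(axis=1).rank()
        proj_order = ms["mean_projection"].rank()
        assert (raw_order == proj_order).all()

    def test_pc2_reflection_leaves_mean_projection(self):
        res = GgeModel(_rank2_sim(11)).fit()
        ms1 = res.mean_vs_stability()
        res.genotype_scores["PC2"] *= -1
        res.environment_scores["PC2"] *= -1
        ms2 = res.mean_vs_stability()
        assert np.allclose(ms1["mean_projection"], ms2["mean_projection"])
        assert np.allclose(
            ms1["stability_deviation"], ms2["stability_deviation"]
        )


class TestRankVsIdeal:
    def test_planted_dominant_ranks_first(self):
        rng = np.random.default_rng(4)
        arr = rng.normal(0, 0.3, size=(8, 4))
        arr[5] += 10.0
        res = GgeModel(_gem(arr)).fit()
        out = res.rank_vs_ideal()
        assert out["distance_to_ideal"].idxmin() == "G6"
        assert out.loc["G6", "rank"] == 1.0

    def test_symmetric_pair_ties(self):
        from metstab.gge import GgeResults

        res = GgeResults(
            trait="t",
            centered=pd.DataFrame(np.zeros((3, 2))),
            singular_values=np.array([1.0, 1.0]),
            explained=np.array([60.0, 40.0]),
            genotype_scores=pd.DataFrame(
                [[1.0, 0.5], [1.0, -0.5], [2.0, 0.0]],
                index=["A", "B", "C"], columns=["PC1", "PC2"],
            ),
            environment_scores=pd.DataFrame(
                [[1.0, 0.0], [2.0, 0.0]], index=["E1", "E2"],
                columns=["PC1", "PC2"],
            ),
            svp="environment",
        )
        out = res.rank_vs_ideal()
        assert out.loc["A", "distance_to_ideal"] == pytest.approx(
            out.loc["B", "distance_to_ideal"]
        )


class TestDiscrimVsRepr:
    def test_proportional_environment_cosine_one(self):
        from metstab.gge import GgeResults

        res = GgeResults(
            trait="t",
            centered=pd.DataFrame(np.zeros((3, 3))),
            singular_values=np.array([1.0, 1.0]),
            explained=np.array([60.0, 40.0]),
            genotype_scores=pd.DataFrame(
                np.eye(3, 2), index=["A", "B", "C"], columns=["PC1", "PC2"]
            ),
            environment_scores=pd.DataFrame(
                [[1.0, 1.0], [2.0, 2.0], [1.0, -1.0]],
                index=["E1", "E2", "E3"], columns=["PC1", "PC2"],
            ),
            svp="environment",
        )
        out = res.discrim_vs_repr()
        # AEA here points along (mean of env vectors) = (4/3, 2/3)
        a = res.aea_direction
        assert out.loc["E2", "vector_length"] == pytest.approx(
            2 * out.loc["E1", "vector_length"]
        )
        assert out.loc["E1", "aea_cosine"] == pytest.approx(
            np.dot([1, 1] / np.sqrt(2), a)
        )

    def test_orthogonal_environment_cosine_zero(self):
        from metstab.gge import GgeResults

        res = GgeResults(
            trait="t",
            centered=pd.DataFrame(np.zeros((2, 2))),
            singular_values=np.array([1.0, 1.0]),
            explained=np.array([60.0, 40.0]),
            genotype_scores=pd.DataFrame(
                np.eye(2), index=["A", "B"], columns=["PC1", "PC2"]
            ),
            environment_scores=pd.DataFrame(
                [[1.0, 0.0], [1.0, 0.0001], [0.0, 5.0]],
                index=["E1", "E2", "E3"], columns=["PC1", "PC2"],
            ),
            svp="environment",
        )
        out = res.discrim_vs_repr()
        a = res.aea_direction
        expected = np.dot([0, 1], a)
        assert out.loc["E3", "aea_cosine"] == pytest.approx(expected, abs=1e-6)

    def test_discriminating_environment_longer_vector(self):
        # under environment-metric svp an environment with more genotype
        # spread carries a longer vector
        rng = np.random.default_rng(8)
        base = rng.normal(0, 1, size=(10, 3))
        arr = np.column_stack([base[:, 0], base[:, 1] * 4.0, base[:, 2]])
        res = GgeModel(_gem(arr)).fit()
        out = res.discrim_vs_repr()
        assert out["vector_length"].idxmax() == "E2"
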