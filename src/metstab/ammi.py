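"""Additive main effects and multiplicative interaction (AMMI) model.

AMMI combines the additive two-way ANOVA of a genotype × environment means
table with a principal-component decomposition of its interaction:

    X_ij = mu + g_i + e_j + sum_k lam_k gamma_ik delta_jk + eps_ij

where Z = X double-centered and Z = U diag(lam) V' is its SVD.  The k-th
axis (IPCA k) carries a share theta_k = lam_k^2 / sum lam^2 of the
interaction sum of squares and, for replicate-level data, Gollob degrees
of freedom g + e - 1 - 2k.

Usage::

    fit = AmmiModel(dataset, "GY").fit()
    fit.anova()           # combined ANOVA with IPCA partition
    fit.ammi1_coords()    # (mean, IPCA1) biplot coordinates
    fit.significant_axes()

Biplot scores default to symmetric singular-value scaling (each side gets
lam^0.5); genotype- and environment-metric scalings are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import GEMatrix, MetDataset, cell_means
from .exceptions import UnsupportedDesignError

__all__ = ["AmmiModel", "AmmiResults", "gollob_df"]

_SCALINGS = ("symmetric", "genotype", "environment")


def gollob_df(g: int, e: int, k: int) -> int:
    """Gollob degrees of freedom of the k-th interaction axis."""
    return g + e - 1 - 2 * k


class AmmiModel:
    """AMMI model for one trait of a balanced MET dataset.

    Accepts either replicate-level data (``MetDataset``; enables the
    combined ANOVA) or a bare complete means matrix (``GEMatrix``; biplot
    geometry and stability indices only).
    """

    def __init__(self, data: MetDataset | GEMatrix, trait: str | None = None):
        if isinstance(data, GEMatrix):
            self.gem = data
            self.trait = data.trait
            self._long = None
            self.rep_count = int(data.rep_counts.to_numpy().max(initial=1))
        else:
            if trait is None:
                raise ValueError("trait is required when fitting from a MetDataset")
            self.trait = trait
            self.gem = cell_means(data, trait)
            if not self.gem.balanced:
                raise UnsupportedDesignError(
                    f"AMMI needs balanced data; trait {trait!r} has missing or "
                    f"unequal cells {self.gem.missing_cells}"
                )
            self._long = data.trait_frame(trait)
            self.rep_count = int(self.gem.rep_counts.iloc[0, 0])
        self.gem.require_complete()

    def fit(self) -> "AmmiResults":
        gem = self.gem
        x = gem.means.to_numpy(dtype=float)
        g, e = x.shape
        mu = x.mean()
        gen_eff = x.mean(axis=1) - mu
        env_eff = x.mean(axis=0) - mu
        z = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + mu
        kstar = min(g, e) - 1
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        u, s, vt = u[:, :kstar], s[:kstar], vt[:kstar]
        # sign convention: largest-|.| element of each genotype eigenvector positive
        for k in range(kstar):
            i = np.argmax(np.abs(u[:, k]))
            if u[i, k] < 0:
                u[:, k] = -u[:, k]
                vt[k] = -vt[k]
        ss_int = float(np.sum(s**2))
        theta = 100.0 * s**2 / ss_int if ss_int > 0 else np.zeros(kstar)

        residual_ms = residual_df = None
        if self._long is not None:
            y = self._long["value"].to_numpy(dtype=float)
            r = self.rep_count
            cell = self._long.groupby(["genotype", "environment"])["value"].mean()
            ss_total = float(np.sum((y - y.mean()) ** 2))
            ss_env = g * r * float(np.sum(env_eff**2))
            ss_gen = e * r * float(np.sum(gen_eff**2))
            ss_ge = r * ss_int
            rep_means = self._long.groupby(["environment", "replicate"])["value"].mean()
            env_means = self._long.groupby("environment")["value"].mean()
            ss_rep = g * float(
                np.sum((rep_means - env_means.reindex(
                    rep_means.index.get_level_values(0)).to_numpy()) ** 2)
            )
            cell_expanded = cell.reindex(
                pd.MultiIndex.from_frame(self._long[["genotype", "environment"]])
            ).to_numpy()
            ss_res = float(np.sum((y - cell_expanded) ** 2))
            residual_df = e * (g - 1) * (r - 1)
            residual_ms = ss_res / residual_df if residual_df > 0 else np.nan
            self._ss = dict(
                total=ss_total, env=ss_env, gen=ss_gen, ge=ss_ge,
                rep=ss_rep, res=ss_res,
            )
        return AmmiResults(
            trait=self.trait,
            grand_mean=float(mu),
            genotype_effects=pd.Series(gen_eff, index=gem.genotypes, name="effect"),
            environment_effects=pd.Series(env_eff, index=gem.environments, name="effect"),
            singular_values=s,
            genotype_eigenvectors=pd.DataFrame(
                u, index=gem.genotypes,
                columns=[f"PC{k + 1}" for k in range(kstar)],
            ),
            environment_eigenvectors=pd.DataFrame(
                vt.T, index=gem.environments,
                columns=[f"PC{k + 1}" for k in range(kstar)],
            ),
            proportion_explained=theta,
            residual_ms=residual_ms,
            residual_df=residual_df,
            rep_count=self.rep_count,
            model=self,
        )


@dataclass
class AmmiResults:
    """Fitted AMMI decomposition of one trait."""

    trait: str
    grand_mean: float
    genotype_effects: pd.Series
    environment_effects: pd.Series
    singular_values: np.ndarray
    genotype_eigenvectors: pd.DataFrame     # g × K*, unit-norm columns
    environment_eigenvectors: pd.DataFrame  # e × K*, unit-norm columns
    proportion_explained: np.ndarray        # percent, sums to 100
    residual_ms: float | None
    residual_df: int | None
    rep_count: int
    model: AmmiModel

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_effects)

    @property
    def n_environments(self) -> int:
        return len(self.environment_effects)

    @property
    def n_axes(self) -> int:
        return len(self.singular_values)

    @property
    def interaction_ss(self) -> float:
        """Interaction SS of the means matrix (sum of squared singular values)."""
        return float(np.sum(self.singular_values**2))

    def reconstruct(self) -> pd.DataFrame:
        """Full-rank reconstruction mu + g_i + e_j + sum_k lam_k gamma delta; equals cell means."""
        z = (self.genotype_eigenvectors.to_numpy() * self.singular_values) @ \
            self.environment_eigenvectors.to_numpy().T
        x = (
            self.grand_mean
            + self.genotype_effects.to_numpy()[:, None]
            + self.environment_effects.to_numpy()[None, :]
            + z
        )
        return pd.DataFrame(
            x, index=self.genotype_effects.index, columns=self.environment_effects.index
        )

    def scores(self, scaling: str = "symmetric") -> tuple[pd.DataFrame, pd.DataFrame]:
        """(genotype scores, environment scores) under a singular-value scaling."""
        if scaling not in _SCALINGS:
            raise ValueError(f"scaling must be one of {_SCALINGS}")
        s = self.singular_values
        u = self.genotype_eigenvectors
        v = self.environment_eigenvectors
        if scaling == "symmetric":
            return u * np.sqrt(s), v * np.sqrt(s)
        if scaling == "genotype":
            return u * s, v.copy()
        return u.copy(), v * s

    # ------------------------------------------------------------------ ANOVA

    def anova(self) -> pd.DataFrame:
        """Combined ANOVA with the IPCA partition of the interaction.

        Rows: ENV, REP(ENV), GEN, GEN:ENV, PC1..PCK*, Residuals, Total.
        ``Proportion`` is percent of the total SS for main rows and percent
        of the interaction SS for IPCA rows (with an accumulated column).
        The ENV mean square is tested against REP(ENV); everything else
        against the pooled residual.  This denominator convention is
        recorded in ``DataFrame.attrs['env_f_denominator']``.
        """
        if self.residual_ms is None:
            raise UnsupportedDesignError(
                "combined ANOVA needs replicate-level data (fit from a MetDataset)"
            )
        ss = self.model._ss
        g, e, r = self.n_genotypes, self.n_environments, self.rep_count
        if r < 2:
            raise UnsupportedDesignError("combined ANOVA needs >= 2 replicates")
        df_env, df_rep, df_gen = e - 1, e * (r - 1), g - 1
        df_ge, df_res = (g - 1) * (e - 1), self.residual_df
        ms_rep = ss["rep"] / df_rep
        ms_res = self.residual_ms
        rows = []

        def frow(source, df, ssval, f_den, f_den_df, prop, acc=np.nan):
            ms = ssval / df
            if f_den is None or f_den <= 0:
                f = p = np.nan
            else:
                f = ms / f_den
                p = stats.f.sf(f, df, f_den_df)
            rows.append((source, df, ssval, ms, f, p, prop, acc))

        total_ss = ss["total"] + ss["ge"]  # IPCA rows re-list the interaction SS
        frow("ENV", df_env, ss["env"], ms_rep, df_rep, 100 * ss["env"] / ss["total"])
        frow("REP(ENV)", df_rep, ss["rep"], ms_res, df_res, 100 * ss["rep"] / ss["total"])
        frow("GEN", df_gen, ss["gen"], ms_res, df_res, 100 * ss["gen"] / ss["total"])
        frow("GEN:ENV", df_ge, ss["ge"], ms_res, df_res, 100 * ss["ge"] / ss["total"])
        acc = 0.0
        for k in range(self.n_axes):
            ss_k = r * self.singular_values[k] ** 2
            prop = 100 * ss_k / ss["ge"] if ss["ge"] > 0 else 0.0
            acc += prop
            frow(f"PC{k + 1}", gollob_df(g, e, k + 1), ss_k, ms_res, df_res, prop, acc)
        rows.append(
            ("Residuals", df_res, ss["res"], ms_res, np.nan, np.nan, np.nan, np.nan)
        )
        df_listed = df_env + df_rep + df_gen + df_ge + df_res + sum(
            gollob_df(g, e, k + 1) for k in range(self.n_axes)
        )
        rows.append(
            ("Total", df_listed, total_ss, total_ss / df_listed,
             np.nan, np.nan, np.nan, np.nan)
        )
        out = pd.DataFrame(
            rows,
            columns=["Source", "df", "SS", "MS", "F", "p", "Proportion", "Accumulated"],
        )
        out.attrs["env_f_denominator"] = "REP(ENV) mean square"
        return out

    def significant_axes(self, alpha: float = 0.05) -> int:
        """Number of IPCAs significant by F-test with Gollob df against residual MS."""
        tab = self.anova()
        pcs = tab[tab["Source"].str.startswith("PC")]
        n = 0
        for _, row in pcs.iterrows():
            if np.isfinite(row["p"]) and row["p"] < alpha:
                n += 1
            else:
                break
        return n

    def n_axes_for_rule(self, axes_rule: str = "all", alpha: float = 0.05) -> int:
        """Resolve an axes-retention rule to a number of IPCAs."""
        if axes_rule == "first":
            return 1
        if axes_rule == "all":
            return self.n_axes
        if axes_rule == "f-significant":
            return self.significant_axes(alpha)
        raise ValueError(f"unknown axes rule {axes_rule!r}")

    # ----------------------------------------------------------------- biplots

    def ammi1_coords(self, scaling: str = "symmetric") -> pd.DataFrame:
        """(mean, IPCA1 score) coordinates for genotypes and environments."""
        gs, es = self.scores(scaling)
        gen = pd.DataFrame({
            "type": "genotype",
            "id": self.genotype_effects.index,
            "mean": self.grand_mean + self.genotype_effects.to_numpy(),
            "ipca1": gs.iloc[:, 0].to_numpy(),
        })
        env = pd.DataFrame({
            "type": "environment",
            "id": self.environment_effects.index,
            "mean": self.grand_mean + self.environment_effects.to_numpy(),
            "ipca1": es.iloc[:, 0].to_numpy(),
        })
        return pd.concat([gen, env], ignore_index=True)

    def ammi2_coords(self, scaling: str = "symmetric") -> pd.DataFrame:
        """(IPCA1, IPCA2) coordinates with distance from the origin."""
        if self.n_axes < 2:
            raise UnsupportedDesignError("AMMI2 biplot needs at least two axes")
        gs, es = self.scores(scaling)
        frames = []
        for kind, sc, ids in (
            ("genotype", gs, self.genotype_effects.index),
            ("environment", es, self.environment_effects.index),
        ):
            xy = sc.iloc[:, :2].to_numpy()
            frames.append(pd.DataFrame({
                "type": kind,
                "id": ids,
                "ipca1": xy[:, 0],
                "ipca2": xy[:, 1],
                "origin_distance": np.hypot(xy[:, 0], xy[:, 1]),
            }))
        return pd.concat(frames, ignore_index=True)
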