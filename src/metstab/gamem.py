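"""Fully random mixed model for balanced MET data ("gamem" analysis).

The model for a replicate-level observation is

    Y_ijr = mu + g_i + env_j + rep_r(j) + ge_ij + eps_ijr

with every effect random and independent:  g ~ N(0, s2_g), env ~ N(0,
s2_env), rep-within-environment ~ N(0, s2_rep), interaction ~ N(0, s2_ge)
and residual ~ N(0, s2_e).  Only the intercept is fixed.

For a balanced trial the five classical ANOVA strata (GEN, ENV, REP(ENV),
GEN:ENV, residual) are orthogonal eigenspaces of the marginal covariance,
with stratum variances

    th_GEN = s2_e + r s2_ge + e r s2_g
    th_ENV = s2_e + r s2_ge + g s2_rep + g r s2_env
    th_REP = s2_e + g s2_rep
    th_GE  = s2_e + r s2_ge
    th_RES = s2_e

so the restricted log-likelihood decomposes exactly as

    -2 lR = sum_s [ df_s ln th_s + SS_s / th_s ] + const.

REML therefore reduces to a five-parameter bounded maximisation that
equals the expected-mean-squares closed form whenever that solution is
interior (all components positive).  BLUPs come from Henderson's
mixed-model equations evaluated at the REML estimates.

Usage::

    res = GamemModel(dataset, "GY").fit()
    res.variance_components      # s2_g, s2_env, s2_rep, s2_ge, s2_e
    res.heritability             # broad-sense H2 on an entry-mean basis
    res.blup_ge                  # shrunken interaction matrix (for WAASB)
    res.blup_indices()           # HMGV / RPGV / HMRPGV
    res.lrt()                    # likelihood-ratio tests for s2_g, s2_ge
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import GEMatrix, MetDataset, cell_means
from .exceptions import ConvergenceError, DomainError, UnsupportedDesignError

__all__ = ["GamemModel", "GamemResults", "heritability", "blup_indices"]

_COMPONENTS = ("genotype", "environment", "rep", "ge", "residual")


def _stratum_stats(long: pd.DataFrame) -> dict:
    """Sums of squares and df of the five orthogonal strata of a balanced trial."""
    y = long["value"].to_numpy(dtype=float)
    g = long["genotype"].nunique()
    e = long["environment"].nunique()
    r = long["replicate"].nunique()
    mu = y.mean()
    gm = long.groupby("genotype")["value"].mean()
    em = long.groupby("environment")["value"].mean()
    cm = long.groupby(["genotype", "environment"])["value"].mean()
    rm = long.groupby(["environment", "replicate"])["value"].mean()
    ss_gen = e * r * float(((gm - mu) ** 2).sum())
    ss_env = g * r * float(((em - mu) ** 2).sum())
    ss_rep = g * float(
        ((rm - em.reindex(rm.index.get_level_values(0)).to_numpy()) ** 2).sum()
    )
    z = (
        cm
        - gm.reindex(cm.index.get_level_values(0)).to_numpy()
        - em.reindex(cm.index.get_level_values(1)).to_numpy()
        + mu
    )
    ss_ge = r * float((z**2).sum())
    ss_tot = float(((y - mu) ** 2).sum())
    ss_res = ss_tot - ss_gen - ss_env - ss_rep - ss_ge
    return dict(
        g=g, e=e, r=r,
        ss=np.array([ss_gen, ss_env, ss_rep, ss_ge, max(ss_res, 0.0)]),
        df=np.array([g - 1, e - 1, e * (r - 1), (g - 1) * (e - 1),
                     e * (g - 1) * (r - 1)], dtype=float),
    )


def _theta(v: np.ndarray, g: int, e: int, r: int) -> np.ndarray:
    """Stratum variances for components (s2_g, s2_env, s2_rep, s2_ge, s2_e)."""
    s2g, s2env, s2rep, s2ge, s2e = v
    return np.array([
        s2e + r * s2ge + e * r * s2g,
        s2e + r * s2ge + g * s2rep + g * r * s2env,
        s2e + g * s2rep,
        s2e + r * s2ge,
        s2e,
    ])


def _neg2_reml(v: np.ndarray, st: dict) -> float:
    th = _theta(v, st["g"], st["e"], st["r"])
    if np.any(th <= 0):
        return np.inf
    return float(np.sum(st["df"] * np.log(th) + st["ss"] / th))


def _reml_fit(st: dict, fixed_zero: tuple[int, ...] = ()) -> tuple[np.ndarray, float]:
    """Maximise the restricted likelihood; optionally pin components to zero.

    Returns (estimates, restricted log-likelihood up to a constant).
    """
    g, e, r = st["g"], st["e"], st["r"]
    ms = st["ss"] / np.where(st["df"] > 0, st["df"], 1.0)
    start = np.array([
        (ms[0] - ms[3]) / (e * r),
        (ms[1] - ms[3] - ms[2] + ms[4]) / (g * r),
        (ms[2] - ms[4]) / g,
        (ms[3] - ms[4]) / r,
        ms[4],
    ])
    start = np.clip(start, 0.0, None)
    start[4] = max(start[4], 1e-10)
    free = [i for i in range(5) if i not in fixed_zero]

    def obj(x: np.ndarray) -> float:
        v = np.zeros(5)
        v[free] = x
        return _neg2_reml(v, st)

    x0 = start[free]
    res = optimize.minimize(
        obj, x0, method="L-BFGS-B",
        bounds=[(0.0, None)] * (len(free) - 1) + [(1e-12, None)],
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    if not res.success and not np.isfinite(res.fun):
        raise ConvergenceError(f"REML failed: {res.message} (after {res.nit} iterations)")
    v = np.zeros(5)
    v[free] = np.clip(res.x, 0.0, None)
    return v, -0.5 * float(res.fun)


class GamemModel:
    """Fully random genotype × environment mixed model for one trait."""

    def __init__(self, data: MetDataset, trait: str):
        self.trait = trait
        self.long = data.trait_frame(trait)
        self.gem = cell_means(data, trait)
        if not self.gem.balanced:
            raise UnsupportedDesignError(
                f"gamem REML here covers balanced trials; trait {trait!r} is unbalanced"
            )
        for col, need in (("genotype", 2), ("environment", 2)):
            if self.long[col].nunique() < need:
                raise UnsupportedDesignError(f"need >= {need} levels of {col}")
        self._single_rep = self.long["replicate"].nunique() < 2
        if self._single_rep:
            warnings.warn(
                "single replicate: rep-within-environment variance inestimable, dropped",
                stacklevel=2,
            )

    def fit(self) -> "GamemResults":
        st = _stratum_stats(self.long)
        fixed = (2,) if self._single_rep else ()
        v, loglik = _reml_fit(st, fixed_zero=fixed)
        blups = self._solve_mme(v)
        return GamemResults(
            trait=self.trait,
            model=self,
            components=pd.Series(v, index=_COMPONENTS, name="variance"),
            loglik=loglik,
            stratum_stats=st,
            **blups,
        )

    def _solve_mme(self, v: np.ndarray) -> dict:
        """Henderson's mixed-model equations at the given variance components."""
        long = self.long
        gens = sorted(long["genotype"].unique())
        envs = sorted(long["environment"].unique())
        reps = sorted(
            set(zip(long["environment"], long["replicate"]))
        )
        ges = [(gn, en) for gn in gens for en in envs]
        n = len(long)
        gi = {x: i for i, x in enumerate(gens)}
        ei = {x: i for i, x in enumerate(envs)}
        ri = {x: i for i, x in enumerate(reps)}
        cj = {x: i for i, x in enumerate(ges)}
        y = long["value"].to_numpy(dtype=float)

        blocks = []   # (design matrix, variance) for each non-null factor
        s2g, s2env, s2rep, s2ge, s2e = v
        specs = [
            ("genotype", gens, s2g,
             [gi[x] for x in long["genotype"]]),
            ("environment", envs, s2env,
             [ei[x] for x in long["environment"]]),
            ("rep", reps, s2rep,
             [ri[x] for x in zip(long["environment"], long["replicate"])]),
            ("ge", ges, s2ge,
             [cj[x] for x in zip(long["genotype"], long["environment"])]),
        ]
        zs, variances, labels = [], [], []
        for name, levels, s2, idx in specs:
            if s2 <= 0:
                continue
            zmat = np.zeros((n, len(levels)))
            zmat[np.arange(n), idx] = 1.0
            zs.append(zmat)
            variances.append(np.full(len(levels), s2))
            labels.append((name, levels))
        x = np.ones((n, 1))
        if zs:
            z = np.hstack(zs)
            dinv = s2e / np.concatenate(variances)
            lhs = np.block([
                [x.T @ x, x.T @ z],
                [z.T @ x, z.T @ z + np.diag(dinv)],
            ])
            rhs = np.concatenate([x.T @ y, z.T @ y])
            sol = np.linalg.solve(lhs, rhs)
            mu = sol[0]
            u = sol[1:]
        else:
            mu = y.mean()
            u = np.array([])
        out = {
            "grand_mean_hat": float(mu),
            "blup_genotype": pd.Series(0.0, index=gens, name="blup"),
            "blup_environment": pd.Series(0.0, index=envs, name="blup"),
            "blup_rep": pd.Series(
                0.0, index=pd.MultiIndex.from_tuples(reps or [("", "")]), name="blup"
            ),
            "blup_ge": pd.DataFrame(0.0, index=gens, columns=envs),
        }
        pos = 0
        for name, levels in labels:
            vals = u[pos: pos + len(levels)]
            pos += len(levels)
            if name == "genotype":
                out["blup_genotype"] = pd.Series(vals, index=levels, name="blup")
            elif name == "environment":
                out["blup_environment"] = pd.Series(vals, index=levels, name="blup")
            elif name == "rep":
                out["blup_rep"] = pd.Series(
                    vals, index=pd.MultiIndex.from_tuples(levels), name="blup"
                )
            else:
                mat = np.array(vals).reshape(len(gens), len(envs))
                out["blup_ge"] = pd.DataFrame(mat, index=gens, columns=envs)
        return out


@dataclass
class GamemResults:
    """REML variance components, BLUPs and derived indices for one trait."""

    trait: str
    model: GamemModel
    components: pd.Series         # s2 for genotype, environment, rep, ge, residual
    loglik: float                 # restricted log-likelihood (constant dropped)
    stratum_stats: dict
    grand_mean_hat: float
    blup_genotype: pd.Series
    blup_environment: pd.Series
    blup_rep: pd.Series
    blup_ge: pd.DataFrame
    _lrt_cache: dict = field(default_factory=dict, repr=False)

    @property
    def n_environments(self) -> int:
        return self.stratum_stats["e"]

    @property
    def n_replicates(self) -> int:
        return self.stratum_stats["r"]

    @property
    def heritability(self) -> float:
        """Broad-sense heritability on an entry-mean basis."""
        return heritability(
            self.components["genotype"], self.components["ge"],
            self.components["residual"], self.n_environments, self.n_replicates,
        )

    @property
    def component_se(self) -> pd.Series:
        """Asymptotic standard errors of the variance components.

        From the expected Fisher information of the stratum likelihood:
        I(theta) = diag(df_s / (2 theta_s^2)) mapped through the linear
        stratum-variance coefficients.  Components estimated at the zero
        boundary get NaN (the asymptotic approximation does not apply).
        """
        st = self.stratum_stats
        g, e, r = st["g"], st["e"], st["r"]
        a = np.array([
            [e * r, 0,     0, r, 1],
            [0,     g * r, g, r, 1],
            [0,     0,     g, 0, 1],
            [0,     0,     0, r, 1],
            [0,     0,     0, 0, 1],
        ], dtype=float)
        theta = _theta(self.components.to_numpy(), g, e, r)
        info = a.T @ np.diag(st["df"] / (2.0 * theta**2)) @ a
        se = np.sqrt(np.diag(np.linalg.inv(info)))
        se = np.where(self.components.to_numpy() > 0, se, np.nan)
        return pd.Series(se, index=_COMPONENTS, name="se")

    @property
    def phenotypic_proportions(self) -> pd.Series:
        """Each component's share of the summed variance components."""
        total = float(self.components.sum())
        return (self.components / total).rename("proportion")

    def genotypic_values(self) -> pd.DataFrame:
        """GV_ij = mu + g_i + env_j + ge_ij (all effects at their BLUPs)."""
        return (
            self.grand_mean_hat
            + self.blup_genotype.to_numpy()[:, None]
            + self.blup_environment.to_numpy()[None, :]
            + self.blup_ge
        )

    def blup_indices(self, gem: GEMatrix | None = None) -> pd.DataFrame:
        """Per-genotype HMGV, RPGV and HMRPGV (higher = better)."""
        gem = gem if gem is not None else self.model.gem
        return blup_indices(self.genotypic_values(), gem)

    def lrt(self, component: str = "ge", boundary_correction: bool = False) -> dict:
        """Likelihood-ratio test that one variance component is zero.

        Twice the restricted-log-likelihood difference between the full fit
        and the fit with the component removed, against chi-square(1).
        ``boundary_correction=True`` halves the p-value (50:50 mixture).
        """
        which = {"genotype": 0, "ge": 3}
        if component not in which:
            raise ValueError("component must be 'genotype' or 'ge'")
        if component not in self._lrt_cache:
            fixed = (which[component],)
            if self.model._single_rep:
                fixed = fixed + (2,)
            _, ll0 = _reml_fit(self.stratum_stats, fixed_zero=fixed)
            stat = max(2.0 * (self.loglik - ll0), 0.0)
            p = float(stats.chi2.sf(stat, df=1)) if stat > 0 else 1.0
            self._lrt_cache[component] = (stat, p)
        stat, p = self._lrt_cache[component]
        return {"statistic": stat, "p": 0.5 * p if boundary_correction else p}

    def summary(self) -> pd.DataFrame:
        rows = [
            *[(f"sigma2_{k}", v) for k, v in self.components.items()],
            ("H2", self.heritability),
            ("restricted_loglik", self.loglik),
        ]
        return pd.DataFrame(rows, columns=["parameter", "value"])


def heritability(s2g: float, s2ge: float, s2e: float, e: int, r: int) -> float:
    """Broad-sense heritability H2 = s2g / (s2g + s2ge/e + s2e/(r e))."""
    den = s2g + s2ge / e + s2e / (r * e)
    if den == 0:
        raise DomainError("zero phenotypic variance: heritability undefined")
    return float(s2g / den)


def blup_indices(gv: pd.DataFrame, gem: GEMatrix) -> pd.DataFrame:
    """Harmonic/relative-performance indices of genotypic values.

    HMGV   = E / sum_j (1 / GV_ij)                harmonic mean
    RPGV   = (1/E) sum_j GV_ij / mu_j             relative performance
    HMRPGV = E / sum_j (mu_j / GV_ij)             harmonic mean of the ratios

    mu_j is the observed mean of environment j.  All three require strictly
    positive genotypic values.
    """
    vals = gv.to_numpy(dtype=float)
    if np.any(vals <= 0):
        bad = [
            (g, e)
            for i, g in enumerate(gv.index)
            for j, e in enumerate(gv.columns)
            if vals[i, j] <= 0
        ]
        raise DomainError(f"non-positive genotypic values at {bad[:5]}")
    mu_j = gem.means.mean(axis=0).reindex(gv.columns).to_numpy()
    e = vals.shape[1]
    hmgv = e / (1.0 / vals).sum(axis=1)
    rpgv = (vals / mu_j).mean(axis=1)
    hmrpgv = e / (mu_j / vals).sum(axis=1)
    return pd.DataFrame(
        {"HMGV": hmgv, "RPGV": rpgv, "HMRPGV": hmrpgv}, index=gv.index
    )
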