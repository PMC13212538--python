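"""Multi-trait stability index (MTSI) via exploratory factor analysis.

Pipeline: a genotypes × traits table of WAASBY values (each column already
on the 0-100 "higher is better" scale) is standardized and its correlation
matrix eigen-decomposed.  Factors with eigenvalue >= 1 are retained
(Kaiser rule, overridable), loadings are varimax-rotated, and genotype
scores are obtained by the regression method, F = Z R^{-1} L.  The
ideotype is the hypothetical genotype scoring 100 on every trait,
projected through the same score weights.  Then

    MTSI_i = sqrt( sum_k (F_ik - F_k^ideo)^2 )

is the genotype-ideotype Euclidean distance in factor space; the lowest
MTSI genotypes (a chosen selection intensity, default 15%, ties at the
cutpoint included) form the selected set.  Per-factor squared-distance
contributions show which trait groups pull a genotype away from the
ideotype, and selection differentials quantify what the selected set
gains per trait.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor_rotation import rotate_factors

from .exceptions import DomainError, InputError, UnsupportedDesignError

__all__ = [
    "FactorModel",
    "FactorResults",
    "MtsiResult",
    "mtsi",
    "selection_differentials",
]


class FactorModel:
    """Exploratory factor analysis of a genotypes × traits matrix."""

    def __init__(self, table: pd.DataFrame, n_factors: int | None = None):
        if table.shape[1] < 3:
            raise UnsupportedDesignError("factor analysis needs at least 3 traits")
        if table.isna().any().any():
            raise InputError("factor-analysis input contains missing values")
        self.table = table.astype(float)
        self.n_factors = n_factors

    def fit(self, ideal: pd.Series | None = None) -> "FactorResults":
        """Fit the EFA; ``ideal`` is the ideotype's trait vector
        (default: 100 for every trait, the best rescaled WAASBY)."""
        x = self.table.to_numpy()
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = list(self.table.columns[sd == 0])
            raise DomainError(f"constant trait columns {bad}: correlation undefined")
        z = (x - mean) / sd
        corr = np.corrcoef(z, rowvar=False)
        if not np.all(np.isfinite(corr)):
            raise DomainError("degenerate trait correlation matrix")
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        f = self.n_factors if self.n_factors is not None else int(np.sum(evals >= 1.0))
        f = max(f, 1)
        if f >= self.table.shape[0]:
            raise UnsupportedDesignError("need more genotypes than retained factors")
        loadings = evecs[:, :f] * np.sqrt(np.clip(evals[:f], 0.0, None))
        if f > 1:
            # a fixed pre-rotation breaks the symmetric saddle the gradient
            # rotation can stall on (e.g. exact two-block structures)
            q0, _ = np.linalg.qr(
                np.eye(f) + 0.1 * np.random.default_rng(0).standard_normal((f, f))
            )
            rotated, t = rotate_factors(loadings @ q0, "varimax")
            rotation = q0 @ t
        else:
            rotated, rotation = loadings.copy(), np.eye(1)
        # sign convention: each factor's dominant loading positive
        for k in range(f):
            j = np.argmax(np.abs(rotated[:, k]))
            if rotated[j, k] < 0:
                rotated[:, k] = -rotated[:, k]
                rotation[:, k] = -rotation[:, k]
        communality = (rotated**2).sum(axis=1)
        # regression score weights; pinv keeps exactly collinear traits
        # (e.g. noiseless latent structure) well-defined via minimum norm
        weights = np.linalg.pinv(corr, rcond=1e-10) @ rotated
        scores = z @ weights
        if ideal is None:
            ideal = pd.Series(100.0, index=self.table.columns)
        z_ideal = (ideal.reindex(self.table.columns).to_numpy() - mean) / sd
        ideal_scores = z_ideal @ weights
        cols = [f"FA{k + 1}" for k in range(f)]
        return FactorResults(
            traits=list(self.table.columns),
            eigenvalues=evals,
            explained=100.0 * evals / evals.sum(),
            loadings=pd.DataFrame(rotated, index=self.table.columns, columns=cols),
            unrotated_loadings=pd.DataFrame(
                loadings, index=self.table.columns, columns=cols
            ),
            rotation=rotation,
            communality=pd.Series(communality, index=self.table.columns, name="h2"),
            scores=pd.DataFrame(scores, index=self.table.index, columns=cols),
            ideotype_scores=pd.Series(ideal_scores, index=cols, name="ideotype"),
            ideal=ideal,
        )


@dataclass
class FactorResults:
    """Rotated EFA solution plus genotype and ideotype factor scores."""

    traits: list[str]
    eigenvalues: np.ndarray          # all eigenvalues, descending
    explained: np.ndarray            # percent per component
    loadings: pd.DataFrame           # varimax-rotated, traits × f
    unrotated_loadings: pd.DataFrame
    rotation: np.ndarray
    communality: pd.Series
    scores: pd.DataFrame             # genotypes × f
    ideotype_scores: pd.Series
    ideal: pd.Series

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    @property
    def uniqueness(self) -> pd.Series:
        return (1.0 - self.communality).rename("uniqueness")

    @property
    def cumulative_explained(self) -> np.ndarray:
        return np.cumsum(self.explained)


@dataclass
class MtsiResult:
    """Genotype-ideotype distances, factor contributions and the selected set."""

    mtsi: pd.Series                   # per genotype, ascending = closer to ideal
    contributions: pd.DataFrame       # genotypes × factors, rows sum to 100
    factors: FactorResults
    intensity: float | None = None
    selected: list[str] = field(default_factory=list)
    cutpoint: float = math.nan

    def select(self, intensity: float = 15.0) -> "MtsiResult":
        """Select the ceil(intensity% · g) lowest-MTSI genotypes, ties included.

        Ties exactly at the cutpoint are all included, so the selected set
        can exceed the nominal count.
        """
        if not (0.0 < intensity <= 100.0):
            raise InputError("selection intensity must be in (0, 100]")
        ordered = self.mtsi.sort_values(kind="mergesort")
        n_sel = math.ceil(intensity * len(ordered) / 100.0)
        cut = float(ordered.iloc[n_sel - 1])
        chosen = list(ordered.index[ordered.to_numpy() <= cut])
        return MtsiResult(
            mtsi=self.mtsi,
            contributions=self.contributions,
            factors=self.factors,
            intensity=intensity,
            selected=chosen,
            cutpoint=cut,
        )


def mtsi(fm: FactorResults) -> MtsiResult:
    """Genotype-ideotype Euclidean distance in rotated factor space."""
    diff = fm.scores.to_numpy() - fm.ideotype_scores.to_numpy()
    d2 = diff**2
    dist = np.sqrt(d2.sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(
            dist[:, None] > 0, 100.0 * d2 / d2.sum(axis=1, keepdims=True), 0.0
        )
    return MtsiResult(
        mtsi=pd.Series(dist, index=fm.scores.index, name="MTSI"),
        contributions=pd.DataFrame(
            contrib, index=fm.scores.index, columns=fm.scores.columns
        ),
        factors=fm,
    )


def selection_differentials(
    trait_table: pd.DataFrame,
    selected: list[str],
    h2: pd.Series | float | None = None,
) -> pd.DataFrame:
    """Per-trait selection differentials of a selected genotype set.

    Xo original mean, Xs selected mean, SD = Xs - Xo, SDperc = 100 SD/Xo;
    with heritabilities the expected gains SG = SD h2, SGperc = 100 SG/Xo.
    """
    if len(selected) == 0:
        raise InputError("selected set is empty")
    missing = [g for g in selected if g not in trait_table.index]
    if missing:
        raise KeyError(f"selected genotypes not in table: {missing}")
    xo = trait_table.mean(axis=0)
    xs = trait_table.loc[selected].mean(axis=0)
    sd = xs - xo
    with np.errstate(divide="ignore", invalid="ignore"):
        sdp = np.where(xo != 0, 100.0 * sd / xo, np.nan)
    out = pd.DataFrame({"Xo": xo, "Xs": xs, "SD": sd, "SDperc": sdp})
    if h2 is not None:
        h2v = (
            h2.reindex(trait_table.columns)
            if isinstance(h2, pd.Series)
            else pd.Series(float(h2), index=trait_table.columns)
        )
        out["h2"] = h2v
        out["SG"] = out["SD"] * h2v
        with np.errstate(divide="ignore", invalid="ignore"):
            out["SGperc"] = np.where(xo != 0, 100.0 * out["SG"] / xo, np.nan)
    return out
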