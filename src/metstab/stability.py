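"""Per-genotype stability statistics: parametric and AMMI-based families.

Parametric measures work directly on the genotype × environment means
matrix (ecovalence, Shukla's stability variance, Lin–Binns superiority,
joint regression, Annicchiarico's risk index).  The AMMI family re-uses a
fitted AMMI decomposition: every statistic combines the genotype
eigenvectors gamma_in, the singular values lam_n and/or the explained
proportions theta_n over the first N retained axes.  N is set by an axes
rule: ``"first"`` (one axis), ``"f-significant"`` (axes passing the
Gollob-df F-test) or ``"all"``.

All of these are "lower = more stable" except the mean itself, R^2 and
the Annicchiarico index.  ``stability_table`` assembles everything, adds
average-tie ranks, and computes the genotype stability index
GSI = rank(ASV) + rank(mean).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ammi import AmmiModel, AmmiResults
from .data import GEMatrix, MetDataset
from .exceptions import DomainError, UnsupportedDesignError

__all__ = [
    "ecovalence",
    "shukla_variance",
    "superiority_pi",
    "joint_regression",
    "annicchiarico",
    "genotype_cv",
    "ammi_index_family",
    "asv_family",
    "gsi",
    "stability_table",
]


# ---------------------------------------------------------------- parametric


def ecovalence(gem: GEMatrix) -> pd.Series:
    """Wricke's ecovalence W^2: each genotype's summed squared interaction cells.

    The W^2 values partition the interaction SS: sum_i W2_i = SS(GxE).
    """
    z = gem.interaction().to_numpy()
    return pd.Series((z**2).sum(axis=1), index=gem.genotypes, name="W2")


def shukla_variance(gem: GEMatrix) -> pd.Series:
    """Shukla's stability variance, an affine transform of ecovalence.

    sigma2_i = p W2_i / ((p-2)(q-1)) - sum(W2) / ((p-1)(p-2)(q-1))
    with p genotypes and q environments.  May be negative.
    """
    p = len(gem.genotypes)
    q = len(gem.environments)
    if p < 3:
        raise UnsupportedDesignError("Shukla's variance needs at least 3 genotypes")
    w2 = ecovalence(gem)
    sigma = p * w2 / ((p - 2) * (q - 1)) - w2.sum() / ((p - 1) * (p - 2) * (q - 1))
    return sigma.rename("shukla")


def superiority_pi(gem: GEMatrix, variant: str = "superiority") -> pd.Series:
    """Superiority measure Pi (Lin–Binns): mean squared distance from the
    environment-wise best genotype, Pi = sum_j (X_ij - M_j)^2 / (2q).

    ``variant="mean"`` instead returns the plain across-environment mean
    (the literal printed form of the source formula, kept for comparison).
    """
    gem.require_complete()
    x = gem.means.to_numpy(dtype=float)
    if variant == "mean":
        return pd.Series(x.mean(axis=1), index=gem.genotypes, name="Pi")
    if variant != "superiority":
        raise ValueError(f"unknown Pi variant {variant!r}")
    q = x.shape[1]
    best = x.max(axis=0, keepdims=True)
    pi = ((x - best) ** 2).sum(axis=1) / (2 * q)
    return pd.Series(pi, index=gem.genotypes, name="Pi")


def joint_regression(gem: GEMatrix) -> pd.DataFrame:
    """Finlay–Wilkinson-type regression of each genotype on the environmental index.

    Returns per-genotype slope ``bi``, deviation variance ``S2di`` and
    Pinthus coefficient of determination ``R2`` (the share of a genotype's
    across-environment variation explained by its linear response).
    """
    gem.require_complete()
    x = gem.means.to_numpy(dtype=float)
    q = x.shape[1]
    if q < 3:
        raise UnsupportedDesignError("joint regression needs at least 3 environments")
    idx = x.mean(axis=0) - x.mean()          # environmental index
    sxx = float(np.sum(idx**2))
    if sxx == 0:
        raise DomainError("zero environmental variance: slopes undefined")
    xc = x - x.mean(axis=1, keepdims=True)
    b = xc @ idx / sxx
    resid = xc - np.outer(b, idx)
    s2d = (resid**2).sum(axis=1) / (q - 2)
    ss_gen = (xc**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_gen > 0, b**2 * sxx / ss_gen, np.nan)
    return pd.DataFrame({"bi": b, "S2di": s2d, "R2": r2}, index=gem.genotypes)


def annicchiarico(gem: GEMatrix, alpha: float = 0.25) -> pd.Series:
    """Annicchiarico's risk index on the percent-of-environment-mean scale.

    AEI_i = mean_j(100 X_ij / Xbar_j) - z_{1-alpha} * sd_j(100 X_ij / Xbar_j).
    A genotype exceeding its environments' means with little dispersion
    scores above 100; higher is better.
    """
    gem.require_complete()
    x = gem.means.to_numpy(dtype=float)
    col = x.mean(axis=0)
    if np.any(col == 0):
        raise DomainError("an environment mean is zero: percent scale undefined")
    pct = 100.0 * x / col
    z = stats.norm.ppf(1 - alpha)
    aei = pct.mean(axis=1) - z * pct.std(axis=1, ddof=1)
    return pd.Series(aei, index=gem.genotypes, name="AEI")


def genotype_cv(gem: GEMatrix) -> pd.Series:
    """Coefficient of variation (%) of each genotype across environment means."""
    gem.require_complete()
    x = gem.means.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = 100.0 * x.std(axis=1, ddof=1) / x.mean(axis=1)
    return pd.Series(cv, index=gem.genotypes, name="CV")


# ------------------------------------------------------------- AMMI family


def _resolve_axes(fit: AmmiResults, axes_rule: str, alpha: float) -> int:
    n = fit.n_axes_for_rule(axes_rule, alpha)
    if n == 0:
        raise UnsupportedDesignError(
            "axes rule retained no IPCA axis (no significant axis at "
            f"alpha={alpha}); choose 'first' or 'all'"
        )
    return n


def ammi_index_family(
    fit: AmmiResults, axes_rule: str = "all", alpha: float = 0.05
) -> pd.DataFrame:
    """The AMMI stability-index family over the first N retained axes.

    EV     mean squared genotype-eigenvector element
    SIPC   sum of absolute symmetric-scaled scores |lam^0.5 gamma|
    AMGE   summed modelled interaction over environments
    AVAMGE summed absolute modelled interaction
    Da     Euclidean length of (lam_n gamma_in)
    Dz     Euclidean length of (gamma_in)
    ASTAB  sum lam_n gamma_in^2
    FA     sum lam_n^2 gamma_in^2
    Za     sum |theta_n gamma_in| (theta as fractions)

    The result records N in ``DataFrame.attrs['n_axes']``.
    """
    n = _resolve_axes(fit, axes_rule, alpha)
    lam = fit.singular_values[:n]
    gamma = fit.genotype_eigenvectors.to_numpy()[:, :n]
    delta = fit.environment_eigenvectors.to_numpy()[:, :n]
    theta = fit.proportion_explained[:n] / 100.0
    # a zero-singular-value axis carries no interaction: its (arbitrary)
    # eigenvectors must not contribute to eigenvector-only statistics
    mask = lam > (lam[0] if lam.size and lam[0] > 0 else 1.0) * 1e-12
    gamma = gamma * mask
    delta = delta * mask
    modelled = np.einsum("k,ik,jk->ijk", lam, gamma, delta)
    out = pd.DataFrame(
        {
            "EV": (gamma**2).sum(axis=1) / n,
            "SIPC": np.abs(gamma * np.sqrt(lam)).sum(axis=1),
            "AMGE": modelled.sum(axis=(1, 2)),
            "AVAMGE": np.abs(modelled).sum(axis=(1, 2)),
            "Da": np.sqrt(((lam * gamma) ** 2).sum(axis=1)),
            "Dz": np.sqrt((gamma**2).sum(axis=1)),
            "ASTAB": (lam * gamma**2).sum(axis=1),
            "FA": (lam**2 * gamma**2).sum(axis=1),
            "Za": np.abs(theta * gamma).sum(axis=1),
        },
        index=fit.genotype_eigenvectors.index,
    )
    out.attrs["n_axes"] = n
    return out


def asv_family(
    fit: AmmiResults,
    axes_rule: str = "all",
    alpha: float = 0.05,
    scaling: str = "symmetric",
) -> pd.DataFrame:
    """ASV, ASI and their multi-axis generalisations MASV, MASI.

    ASV_i  = sqrt[((SS1/SS2) s_i1)^2 + s_i2^2]
    ASI_i  = sqrt[(s_i1 th1)^2 + (s_i2 th2)^2]
    MASV_i = sqrt[sum_{n<N} ((SS_n/SS_{n+1}) s_in)^2 + s_iN^2]
    MASI_i = sqrt[sum_{n<=N} s_in^2 th_n^2]

    with s the scaled genotype scores, SS_n = lam_n^2 (axis interaction SS
    up to the replicate factor) and th_n the explained fractions.  With
    N = 2 the modified statistics collapse to ASV and ASI.
    """
    if fit.n_axes < 2:
        raise UnsupportedDesignError("ASV family needs at least two IPCA axes")
    if fit.singular_values[1] == 0:
        raise DomainError("second axis has zero SS: ASV ratio degenerate")
    n = _resolve_axes(fit, axes_rule, alpha)
    s = fit.scores(scaling)[0].to_numpy()
    lam2 = fit.singular_values**2
    theta = fit.proportion_explained / 100.0
    asv = np.sqrt(((lam2[0] / lam2[1]) * s[:, 0]) ** 2 + s[:, 1] ** 2)
    asi = np.sqrt((s[:, 0] * theta[0]) ** 2 + (s[:, 1] * theta[1]) ** 2)
    masi = np.sqrt(np.sum((s[:, :n] * theta[:n]) ** 2, axis=1))
    if n == 1:
        masv = np.abs(s[:, 0])
    else:
        ratios = lam2[: n - 1] / lam2[1:n]
        masv = np.sqrt(
            np.sum((ratios * s[:, : n - 1]) ** 2, axis=1) + s[:, n - 1] ** 2
        )
    out = pd.DataFrame(
        {"ASV": asv, "ASI": asi, "MASI": masi, "MASV": masv},
        index=fit.genotype_eigenvectors.index,
    )
    out.attrs["n_axes"] = n
    return out


def gsi(mean_ranks: pd.Series, asv_ranks: pd.Series) -> pd.Series:
    """Genotype stability index: GSI = rank(ASV) + rank(mean); lower is better."""
    if set(mean_ranks.index) != set(asv_ranks.index):
        raise KeyError("mean and ASV rank vectors cover different genotype sets")
    return (asv_ranks + mean_ranks.reindex(asv_ranks.index)).rename("GSI")


# ------------------------------------------------------------- full table


def stability_table(
    data: MetDataset,
    trait: str,
    axes_rule: str = "all",
    alpha: float = 0.05,
    aei_alpha: float = 0.25,
    direction: str = "higher",
    pi_variant: str = "superiority",
) -> pd.DataFrame:
    """Assemble every parametric and AMMI-based index with ranks for one trait.

    ``direction`` states whether a larger trait mean is desirable; it only
    affects the mean rank (and hence GSI).  Rank columns (``rank_*``) use
    average ties; lower-is-better statistics are ranked ascending.
    """
    fit = AmmiModel(data, trait).fit()
    gem = fit.model.gem
    reg = joint_regression(gem)
    fam = ammi_index_family(fit, axes_rule, alpha)
    asv = asv_family(fit, axes_rule, alpha)
    tab = pd.DataFrame(index=gem.genotypes)
    tab["mean"] = gem.means.mean(axis=1)
    tab["CV"] = genotype_cv(gem)
    tab["W2"] = ecovalence(gem)
    tab["shukla"] = shukla_variance(gem)
    tab["Pi"] = superiority_pi(gem, pi_variant)
    tab[["bi", "S2di", "R2"]] = reg
    tab["AEI"] = annicchiarico(gem, aei_alpha)
    tab[fam.columns] = fam
    tab[asv.columns] = asv

    ascending_better = direction == "lower"
    rank_mean = tab["mean"].rank(ascending=ascending_better, method="average")
    lower_better = [
        "CV", "W2", "shukla", "Pi", "S2di", "EV", "SIPC", "AVAMGE", "Da", "Dz",
        "ASTAB", "FA", "Za", "ASV", "ASI", "MASI", "MASV",
    ]
    for col in lower_better:
        tab[f"rank_{col}"] = tab[col].rank(ascending=True, method="average")
    tab["rank_mean"] = rank_mean
    tab["rank_AEI"] = tab["AEI"].rank(ascending=False, method="average")
    tab["GSI"] = gsi(rank_mean, tab["rank_ASV"])
    tab.attrs["trait"] = trait
    tab.attrs["n_axes"] = fam.attrs["n_axes"]
    tab.attrs["direction"] = direction
    return tab
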