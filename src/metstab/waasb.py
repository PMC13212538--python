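"""WAASB stability and the WAASBY mean-performance/stability blend.

WAASB is the weighted average of a genotype's absolute interaction
principal-component scores, with weights equal to each axis's explained
proportion of the interaction variance:

    WAASB_i = sum_k |IPCA_ik| EP_k / sum_k EP_k.

Computed from the SVD of the BLUP genotype × environment interaction
matrix it is the (BLUP-based) WAASB; from the double-centered matrix of
fixed-effect cell means it is the fixed-AMMI WAAS.  Lower = more stable.

WAASBY blends mean performance and stability: both are rescaled to 0-100
(100 = best mean, 100 = lowest WAASB) and combined with user weights,
by default 65% mean / 35% stability.  Genotypes are also classed into
the four mean × stability quadrants (IV = desirable mean and low WAASB).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ammi import AmmiResults
from .exceptions import DomainError, InputError

__all__ = ["interaction_scores", "waasb_scores", "waasb", "waasby"]


def interaction_scores(matrix: pd.DataFrame, scaling: str = "symmetric"):
    """SVD scores and explained proportions of a g × e interaction-effect matrix.

    Returns (genotype scores DataFrame, explained-proportion array in [0,1]).
    Axes with zero singular value are dropped.
    """
    z = matrix.to_numpy(dtype=float)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    keep = s > max(s[0], 1.0) * 1e-12 if s.size and s[0] > 0 else s > 0
    u, s = u[:, keep], s[keep]
    if s.size == 0:
        return (
            pd.DataFrame(index=matrix.index, dtype=float),
            np.array([]),
        )
    if scaling == "symmetric":
        scores = u * np.sqrt(s)
    elif scaling == "genotype":
        scores = u * s
    elif scaling == "environment":
        scores = u.copy()
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    ep = s**2 / np.sum(s**2)
    cols = [f"PC{k + 1}" for k in range(s.size)]
    return pd.DataFrame(scores, index=matrix.index, columns=cols), ep


def waasb_scores(matrix: pd.DataFrame, scaling: str = "symmetric") -> pd.Series:
    """Weighted average of absolute SVD scores of an interaction matrix.

    An all-zero matrix yields zero for every genotype (no interaction,
    perfectly stable).
    """
    scores, ep = interaction_scores(matrix, scaling)
    if ep.size == 0:
        return pd.Series(0.0, index=matrix.index, name="WAASB")
    w = (np.abs(scores.to_numpy()) * ep).sum(axis=1) / ep.sum()
    return pd.Series(w, index=matrix.index, name="WAASB")


def waasb(source, scaling: str = "symmetric") -> pd.Series:
    """WAASB/WAAS from a fitted model.

    ``source`` is either GamemResults (BLUP interaction matrix -> WAASB)
    or AmmiResults (double-centered fixed-effect means -> WAAS).
    """
    from .gamem import GamemResults  # local import to avoid a cycle

    if isinstance(source, GamemResults):
        return waasb_scores(source.blup_ge, scaling).rename("WAASB")
    if isinstance(source, AmmiResults):
        z = source.model.gem.interaction()
        return waasb_scores(z, scaling).rename("WAAS")
    raise TypeError("source must be GamemResults or AmmiResults")


def _rescale(x: np.ndarray, higher_better: bool) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise DomainError(
            "constant column: cannot rescale to 0-100 (all values equal)"
        )
    r = 100.0 * (x - lo) / (hi - lo)
    return r if higher_better else 100.0 - r


def waasby(
    means: pd.Series,
    waasb_values: pd.Series,
    mean_weight: float = 65.0,
    direction: str = "higher",
) -> pd.DataFrame:
    """Blend rescaled mean performance and rescaled WAASB stability.

    Returns per-genotype ``rY`` (0-100, 100 = best mean under the trait's
    desired direction), ``rW`` (100 = lowest WAASB), ``WAASBY`` and the
    mean × stability ``quadrant`` (I low/unstable, II high/unstable,
    III low/stable, IV high/stable, judged against the across-genotype
    averages).
    """
    if not (0.0 <= mean_weight <= 100.0):
        raise InputError("mean_weight must be in [0, 100]")
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")
    w = waasb_values.reindex(means.index)
    if w.isna().any():
        raise KeyError("means and WAASB cover different genotype sets")
    ry = _rescale(means.to_numpy(dtype=float), higher_better=(direction == "higher"))
    rw = _rescale(w.to_numpy(dtype=float), higher_better=False)
    blend = (mean_weight * ry + (100.0 - mean_weight) * rw) / 100.0
    good_mean = (
        means > means.mean() if direction == "higher" else means < means.mean()
    )
    stable = w < w.mean()
    quadrant = np.where(
        good_mean, np.where(stable, "IV", "II"), np.where(stable, "III", "I")
    )
    out = pd.DataFrame(
        {
            "mean": means,
            "WAASB": w,
            "rY": ry,
            "rW": rw,
            "WAASBY": blend,
            "quadrant": quadrant,
        },
        index=means.index,
    )
    out.attrs["mean_weight"] = mean_weight
    out.attrs["stability_weight"] = 100.0 - mean_weight
    out.attrs["direction"] = direction
    return out
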