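"""Site-regression (GGE) model and the geometry of its biplot views.

GGE removes only the environment main effect from the genotype ×
environment means table and decomposes the rest (genotype + interaction)
by SVD:

    X_ij - mu_j = sum_k lam_k gamma_ik delta_jk.

The first two axes carry the biplot.  Singular-value partitioning (SVP)
decides which side absorbs lam: ``"environment"`` (column-metric, the
default, matching the convention "partitioning = 2"), ``"genotype"``
(row-metric) or ``"symmetric"``.

Four standard views are computed as coordinates, not pictures:

* which-won-where — convex hull of genotype points, perpendicular sector
  rays, per-environment winning genotype (the inner-product argmax);
* mean vs stability — projections onto the average-environment axis (AEA)
  and the perpendicular deviation from it;
* genotype ranking — distance to the "ideal" point on the AEA;
* discriminativeness vs representativeness — environment vector length
  and its angle cosine with the AEA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .data import GEMatrix
from .exceptions import DomainError, UnsupportedDesignError

__all__ = ["GgeModel", "GgeResults", "WhichWonWhere"]

_TWO_PI = 2.0 * np.pi


class GgeModel:
    """GGE (genotype + G×E) model of a complete genotype × environment matrix."""

    def __init__(
        self,
        gem: GEMatrix,
        scaling: str = "none",
        svp: str = "environment",
    ):
        gem.require_complete()
        if scaling not in ("none", "sd"):
            raise ValueError("scaling must be 'none' or 'sd'")
        if svp not in ("genotype", "environment", "symmetric"):
            raise ValueError("svp must be 'genotype', 'environment' or 'symmetric'")
        self.gem = gem
        self.scaling = scaling
        self.svp = svp

    def fit(self) -> "GgeResults":
        x = self.gem.means.to_numpy(dtype=float)
        centered = x - x.mean(axis=0, keepdims=True)   # environment-centered
        if self.scaling == "sd":
            sd = x.std(axis=0, ddof=1)
            if np.any(sd == 0):
                bad = [
                    e for e, s in zip(self.gem.environments, sd) if s == 0
                ]
                raise DomainError(f"constant environment columns {bad} under sd scaling")
            centered = centered / sd
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        # deterministic orientation: largest-|.| genotype element of each axis positive
        for k in range(len(s)):
            i = np.argmax(np.abs(u[:, k]))
            if u[i, k] < 0:
                u[:, k] = -u[:, k]
                vt[k] = -vt[k]
        total = float(np.sum(s**2))
        explained = 100.0 * s**2 / total if total > 0 else np.zeros_like(s)
        if self.svp == "environment":
            gs, es = u, vt.T * s
        elif self.svp == "genotype":
            gs, es = u * s, vt.T
        else:
            gs, es = u * np.sqrt(s), vt.T * np.sqrt(s)
        cols = [f"PC{k + 1}" for k in range(len(s))]
        return GgeResults(
            trait=self.gem.trait,
            centered=pd.DataFrame(
                centered, index=self.gem.genotypes, columns=self.gem.environments
            ),
            singular_values=s,
            explained=explained,
            genotype_scores=pd.DataFrame(gs, index=self.gem.genotypes, columns=cols),
            environment_scores=pd.DataFrame(
                es, index=self.gem.environments, columns=cols
            ),
            svp=self.svp,
        )


@dataclass
class WhichWonWhere:
    """Polygon (hull) structure of the which-won-where view."""

    hull_vertices: list[str]                  # counterclockwise genotype ids
    sector_boundaries: np.ndarray             # ray angles, radians in [0, 2pi)
    environment_sector: dict[str, int]
    sector_winner: dict[int, str]

    def winner_for(self, environment: str) -> str:
        return self.sector_winner[self.environment_sector[environment]]


@dataclass
class GgeResults:
    """Fitted GGE decomposition with its biplot-view geometry."""

    trait: str
    centered: pd.DataFrame
    singular_values: np.ndarray
    explained: np.ndarray
    genotype_scores: pd.DataFrame
    environment_scores: pd.DataFrame
    svp: str

    def _points2d(self) -> tuple[np.ndarray, np.ndarray]:
        if self.genotype_scores.shape[1] < 2:
            raise UnsupportedDesignError("GGE biplot views need at least two axes")
        return (
            self.genotype_scores.iloc[:, :2].to_numpy(),
            self.environment_scores.iloc[:, :2].to_numpy(),
        )

    @property
    def aea_direction(self) -> np.ndarray:
        """Unit vector of the average-environment axis in the PC1/PC2 plane."""
        _, env = self._points2d()
        mean_env = env.mean(axis=0)
        norm = np.linalg.norm(mean_env)
        if norm == 0:
            raise DomainError("zero average-environment vector: AEA undefined")
        return mean_env / norm

    # ------------------------------------------------------- which-won-where

    def which_won_where(self) -> WhichWonWhere:
        """Hull vertices, perpendicular sector rays and per-sector winners.

        Sectors are half-open angle intervals [boundary_k, boundary_{k+1})
        counterclockwise; an environment belongs to the sector containing
        its vector's angle, and the sector winner is the hull vertex
        maximising the biplot inner product there.
        """
        gen, env = self._points2d()
        if gen.shape[0] < 3:
            raise UnsupportedDesignError("which-won-where needs >= 3 genotypes")
        try:
            hull = ConvexHull(gen)
        except QhullError as exc:
            raise DomainError("genotype points are collinear: degenerate hull") from exc
        verts = list(hull.vertices)  # counterclockwise for 2-D qhull
        names = list(self.genotype_scores.index)
        vpts = gen[verts]
        m = len(verts)
        boundaries = []
        for a in range(m):
            b = (a + 1) % m
            edge = vpts[b] - vpts[a]
            # qhull returns 2-D vertices counterclockwise, so the outward
            # normal of each edge is the edge vector rotated by -90 degrees
            d = np.array([edge[1], -edge[0]])
            boundaries.append(np.arctan2(d[1], d[0]) % _TWO_PI)
        boundaries = np.sort(np.array(boundaries))
        sector_winner = {}
        for k in range(len(boundaries)):
            lo = boundaries[k]
            hi = boundaries[(k + 1) % len(boundaries)]
            span = (hi - lo) % _TWO_PI or _TWO_PI
            mid = (lo + span / 2.0) % _TWO_PI
            probe = np.array([np.cos(mid), np.sin(mid)])
            sector_winner[k] = names[verts[int(np.argmax(vpts @ probe))]]
        env_sector = {}
        env_names = list(self.environment_scores.index)
        for j, w in enumerate(env):
            ang = np.arctan2(w[1], w[0]) % _TWO_PI
            k = int(np.searchsorted(boundaries, ang, side="right") - 1) % len(boundaries)
            env_sector[env_names[j]] = k
        return WhichWonWhere(
            hull_vertices=[names[v] for v in verts],
            sector_boundaries=boundaries,
            environment_sector=env_sector,
            sector_winner=sector_winner,
        )

    def environment_winners(self) -> pd.Series:
        """Per-environment winning genotype by the biplot inner product."""
        gen, env = self._points2d()
        names = np.array(self.genotype_scores.index)
        return pd.Series(
            names[np.argmax(env @ gen.T, axis=1)],
            index=self.environment_scores.index,
            name="winner",
        )

    # ---------------------------------------------------- mean vs stability

    def mean_vs_stability(self) -> pd.DataFrame:
        """Per-genotype signed AEA projection (mean axis) and unsigned deviation."""
        gen, _ = self._points2d()
        a = self.aea_direction
        proj = gen @ a
        perp = gen - np.outer(proj, a)
        return pd.DataFrame(
            {
                "mean_projection": proj,
                "stability_deviation": np.linalg.norm(perp, axis=1),
            },
            index=self.genotype_scores.index,
        )

    def rank_vs_ideal(self) -> pd.DataFrame:
        """Distance of each genotype to the ideal point on the AEA, with ranks."""
        gen, _ = self._points2d()
        a = self.aea_direction
        ideal = a * float(np.max(gen @ a))
        dist = np.linalg.norm(gen - ideal, axis=1)
        out = pd.DataFrame(
            {"distance_to_ideal": dist}, index=self.genotype_scores.index
        )
        out["rank"] = out["distance_to_ideal"].rank(method="average")
        out.attrs["ideal_point"] = ideal
        return out

    def discrim_vs_repr(self) -> pd.DataFrame:
        """Environment vector length (discriminativeness) and AEA cosine
        (representativeness); zero-length vectors get NaN cosine."""
        _, env = self._points2d()
        a = self.aea_direction
        length = np.linalg.norm(env, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cosine = np.where(length > 0, env @ a / length, np.nan)
        return pd.DataFrame(
            {"vector_length": length, "aea_cosine": cosine},
            index=self.environment_scores.index,
        )
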