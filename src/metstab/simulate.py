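"""Synthetic multi-environment trial generator with known ground truth.

The generator draws data from the same model family the analysis fits: a
balanced randomized-complete-block trial in every environment, with random
genotype, environment, replicate-within-environment and residual effects,
and a bilinear (rank-constrained) genotype × environment interaction

    Y_ijr = mu + g_i + e_j + b_r(j) + sum_k sqrt(lam_k) u_ik v_jk + eps_ijr.

The bilinear score vectors u_k, v_k are column-centred and orthonormalised
(QR of centred Gaussians), so the generator's interaction has an exactly
known singular-value spectrum — AMMI, which-won-where and WAASB behaviour
on the generated data can therefore be checked against construction.  The
eigenvalues lam_k decay geometrically (ratio 1/2) and are scaled so that
the mean squared interaction cell equals the configured ``var_ge``.

Multi-trait panels share genotype effects through a trait × factor loading
matrix, so that factor analysis of the generated traits has a known target
structure.  The default panel mirrors a rice culm-strength/yield trial: 30
genotypes × 4 environments × 3 replicates and 19 correlated traits in six
latent groups, with realistic trait means (e.g. breaking resistance ~847 g,
grain yield ~528 g/m^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GEMatrix, MetDataset
from .exceptions import InputError

__all__ = ["SyntheticConfig", "TruthTables", "simulate_met", "toy_matrix", "study_config"]


#: trait panel of the emulated trial: name -> (mean, phenotypic scale, desired direction)
STUDY_TRAITS: dict[str, tuple[float, float, str]] = {
    "PH":   (105.76, 13.3, "higher"),
    "IL":   (11.18,  1.6,  "lower"),
    "CL":   (76.24,  11.0, "higher"),
    "TN":   (12.5,   1.3,  "higher"),
    "PR":   (21.26,  2.6,  "higher"),
    "CD":   (6.13,   0.47, "higher"),
    "CT":   (1.83,   0.23, "higher"),
    "SM":   (17.28,  3.2,  "higher"),
    "BS":   (48.22,  7.6,  "higher"),
    "M":    (824.56, 210.0, "higher"),
    "BR":   (847.05, 114.0, "higher"),
    "CLSW": (10.57,  1.4,  "higher"),
    "DFF":  (122.25, 4.8,  "lower"),
    "PN":   (10.17,  1.4,  "higher"),
    "PL":   (21.78,  2.2,  "higher"),
    "GN":   (218.31, 25.4, "higher"),
    "PW":   (4.14,   0.72, "higher"),
    "TW":   (20.31,  3.4,  "higher"),
    "GY":   (527.66, 47.9, "higher"),
}

#: latent-factor group of each default trait (six groups)
_STUDY_FACTOR_OF = {
    "PR": 0, "BS": 0, "DFF": 0,
    "CD": 1, "CT": 1, "SM": 1, "M": 1, "BR": 1, "GY": 1,
    "PH": 2, "IL": 2, "CL": 2,
    "TN": 3, "PN": 3,
    "GN": 4, "PW": 4, "CLSW": 4,
    "PL": 5, "TW": 5,
}


@dataclass
class SyntheticConfig:
    """Parameters of the generative MET model.

    Variances are on the standardized effect scale; each trait's draws are
    multiplied by its entry in ``trait_scales`` (default 1), so the realised
    variance for trait t is ``trait_scales[t]**2`` times the configured one.
    """

    n_genotypes: int = 30
    n_environments: int = 4
    n_replicates: int = 3
    grand_mean: float = 0.0
    var_genotype: float = 100.0
    var_environment: float = 50.0
    var_rep_within_env: float = 10.0
    var_ge: float = 50.0
    ge_rank: int = 3
    var_residual: float = 25.0
    n_traits: int = 1
    trait_names: list[str] | None = None
    trait_means: list[float] | None = None
    trait_scales: list[float] | None = None
    trait_factor_loadings: np.ndarray | None = None  # traits × factors, row norms <= 1
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        g, e = self.n_genotypes, self.n_environments
        if g < 2 or e < 2 or self.n_replicates < 1:
            raise InputError("need >=2 genotypes, >=2 environments, >=1 replicate")
        kmax = min(g, e) - 1
        if not (1 <= self.ge_rank <= kmax):
            raise InputError(f"ge_rank must be in [1, {kmax}], got {self.ge_rank}")
        for name in ("var_genotype", "var_environment", "var_rep_within_env",
                     "var_ge", "var_residual"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise InputError("dropout_rate must be in [0, 1)")
        if self.trait_names is None:
            self.trait_names = (
                ["Y"] if self.n_traits == 1
                else [f"T{i + 1}" for i in range(self.n_traits)]
            )
        if len(self.trait_names) != self.n_traits:
            raise InputError("trait_names length must equal n_traits")
        if self.trait_means is None:
            self.trait_means = [self.grand_mean] * self.n_traits
        if self.trait_scales is None:
            self.trait_scales = [1.0] * self.n_traits
        if self.trait_factor_loadings is not None:
            lam = np.asarray(self.trait_factor_loadings, dtype=float)
            if lam.shape[0] != self.n_traits:
                raise InputError("trait_factor_loadings must have n_traits rows")
            if np.any(np.linalg.norm(lam, axis=1) > 1.0 + 1e-9):
                raise InputError("trait_factor_loadings row norms must be <= 1")
            self.trait_factor_loadings = lam


@dataclass
class TruthTables:
    """Every effect drawn by the generator, for recovery tests."""

    genotype_effects: pd.DataFrame        # genotypes × traits
    environment_effects: pd.DataFrame     # environments × traits
    rep_effects: pd.DataFrame             # (environment, replicate) × traits
    interaction: dict[str, pd.DataFrame]  # trait -> genotypes × environments
    singular_values: dict[str, np.ndarray]
    genotype_scores: dict[str, np.ndarray]     # trait -> g × K orthonormal
    environment_scores: dict[str, np.ndarray]  # trait -> e × K orthonormal
    config: SyntheticConfig


def _centered_orthonormal(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """n × k matrix with orthonormal columns, each orthogonal to the ones vector."""
    ones = np.ones((n, 1)) / np.sqrt(n)
    m = rng.standard_normal((n, k))
    m -= ones @ (ones.T @ m)          # project out the mean direction
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))          # deterministic sign convention
    return q


def simulate_met(cfg: SyntheticConfig) -> tuple[MetDataset, TruthTables]:
    """Draw a balanced MET dataset (plus truth tables) from the config."""
    rng = np.random.default_rng(cfg.seed)
    g, e, r, t = cfg.n_genotypes, cfg.n_environments, cfg.n_replicates, cfg.n_traits
    gen_ids = [f"G{i + 1:02d}" for i in range(g)]
    env_ids = [f"E{j + 1}" for j in range(e)]
    rep_ids = [f"R{k + 1}" for k in range(r)]

    # genotype effects, optionally factor-structured across traits
    sd_g = np.sqrt(cfg.var_genotype)
    if cfg.trait_factor_loadings is not None:
        lam = cfg.trait_factor_loadings
        nf = lam.shape[1]
        scores = rng.standard_normal((g, nf))
        unique = rng.standard_normal((g, t))
        psi = np.sqrt(np.clip(1.0 - np.sum(lam**2, axis=1), 0.0, None))
        g_eff = sd_g * (scores @ lam.T + unique * psi)
    else:
        g_eff = sd_g * rng.standard_normal((g, t))

    e_eff = np.sqrt(cfg.var_environment) * rng.standard_normal((e, t))
    b_eff = np.sqrt(cfg.var_rep_within_env) * rng.standard_normal((e * r, t))

    # Interaction per trait.  An iid N(0, s2_ge) matrix decomposes into four
    # independent orthogonal parts: grand mean, centred row means, centred
    # column means, and the double-centered core.  The first three are drawn
    # at their iid-implied variances (so the classical expected mean squares
    # hold and REML recovers s2_ge without bias), while the double-centered
    # core is built as a rank-K bilinear form with a KNOWN singular-value
    # spectrum (geometric decay, total SS = (g-1)(e-1) s2_ge): AMMI and GGE
    # see only this core, so their oracles are exact.
    k = cfg.ge_rank
    weights = 0.5 ** np.arange(k)
    lam2 = (
        cfg.var_ge * (g - 1) * (e - 1) * weights / weights.sum()
        if cfg.var_ge > 0
        else np.zeros(k)
    )  # squared singular values of the double-centered interaction core
    interaction, svals, uscores, vscores = {}, {}, {}, {}
    sd_ge = np.sqrt(cfg.var_ge)
    for name in cfg.trait_names:
        u = _centered_orthonormal(rng, g, k)
        v = _centered_orthonormal(rng, e, k)
        core = (u * np.sqrt(lam2)) @ v.T
        c0 = sd_ge / np.sqrt(g * e) * rng.standard_normal()
        row = sd_ge / np.sqrt(e) * rng.standard_normal(g)
        row -= row.mean()
        col = sd_ge / np.sqrt(g) * rng.standard_normal(e)
        col -= col.mean()
        z = c0 + row[:, None] + col[None, :] + core
        interaction[name] = pd.DataFrame(z, index=gen_ids, columns=env_ids)
        svals[name] = np.sqrt(lam2)
        uscores[name] = u
        vscores[name] = v

    eps = np.sqrt(cfg.var_residual) * rng.standard_normal((g, e, r, t))

    rows = []
    for ti, name in enumerate(cfg.trait_names):
        scale = cfg.trait_scales[ti]
        base = cfg.trait_means[ti]
        z = interaction[name].to_numpy()
        for i in range(g):
            for j in range(e):
                for rep in range(r):
                    val = base + scale * (
                        g_eff[i, ti] + e_eff[j, ti] + b_eff[j * r + rep, ti]
                        + z[i, j] + eps[i, j, rep, ti]
                    )
                    rows.append((gen_ids[i], env_ids[j], rep_ids[rep], name, val))
    df = pd.DataFrame(rows, columns=["genotype", "environment", "replicate", "trait", "value"])

    if cfg.dropout_rate > 0:
        keep_cell = rng.random((g, e)) >= cfg.dropout_rate
        keep_cell[0, :] = True  # never empty a full genotype/environment margin
        keep_cell[:, 0] = True
        cell_ok = {
            (gen_ids[i], env_ids[j])
            for i in range(g) for j in range(e) if keep_cell[i, j]
        }
        mask = [
            (row.genotype, row.environment) in cell_ok for row in df.itertuples()
        ]
        df = df[mask].reset_index(drop=True)

    truth = TruthTables(
        genotype_effects=pd.DataFrame(g_eff, index=gen_ids, columns=cfg.trait_names),
        environment_effects=pd.DataFrame(e_eff, index=env_ids, columns=cfg.trait_names),
        rep_effects=pd.DataFrame(
            b_eff,
            index=pd.MultiIndex.from_product([env_ids, rep_ids]),
            columns=cfg.trait_names,
        ),
        interaction=interaction,
        singular_values=svals,
        genotype_scores=uscores,
        environment_scores=vscores,
        config=cfg,
    )
    return MetDataset(records=df), truth


def study_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Config emulating the reference trial: 30 × 4 × 3 with the 19-trait panel.

    Genotype effects share six latent factors (loading 0.85 on the trait's
    group), giving strong within-group trait correlations; per-trait means
    and scales are set to realistic field magnitudes.
    """
    names = list(STUDY_TRAITS)
    nf = 6
    lam = np.zeros((len(names), nf))
    for i, name in enumerate(names):
        lam[i, _STUDY_FACTOR_OF[name]] = 0.85
    defaults = dict(
        n_genotypes=30,
        n_environments=4,
        n_replicates=3,
        var_genotype=1.0,
        var_environment=0.25,
        var_rep_within_env=0.05,
        var_ge=0.6,
        ge_rank=3,
        var_residual=0.3,
        n_traits=len(names),
        trait_names=names,
        trait_means=[STUDY_TRAITS[n][0] for n in names],
        trait_scales=[STUDY_TRAITS[n][1] for n in names],
        trait_factor_loadings=lam,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


def simulate_elite_panel(
    seed: int = 0,
    n_genotypes: int = 30,
    n_environments: int = 4,
    n_replicates: int = 2,
    n_traits: int = 6,
    n_elite: int = 5,
    elite_effect: float = 2.5,
) -> tuple[MetDataset, list[str]]:
    """Multi-trait panel with a planted set of unambiguously superior genotypes.

    The first ``n_elite`` genotypes get a top-decile main effect
    (``elite_effect`` standard deviations, all traits) and exactly zero
    interaction; the remaining genotypes have standard-normal effects and a
    bilinear interaction.  Used to verify that multi-trait selection
    (WAASBY → factor analysis → MTSI) recovers known winners.

    Returns the dataset and the elite genotype ids.
    """
    rng = np.random.default_rng(seed)
    g, e, r = n_genotypes, n_environments, n_replicates
    gen_ids = [f"G{i + 1:02d}" for i in range(g)]
    env_ids = [f"E{j + 1}" for j in range(e)]
    rep_ids = [f"R{k + 1}" for k in range(r)]
    traits = [f"T{t + 1}" for t in range(n_traits)]
    rows = []
    for name in traits:
        g_eff = rng.standard_normal(g)
        g_eff[:n_elite] = elite_effect
        e_eff = 0.7 * rng.standard_normal(e)
        z = 0.8 * rng.standard_normal((g, e))
        z -= z.mean(axis=1, keepdims=True)
        z[:n_elite] = 0.0
        eps = 0.3 * rng.standard_normal((g, e, r))
        for i in range(g):
            for j in range(e):
                for k in range(r):
                    rows.append((
                        gen_ids[i], env_ids[j], rep_ids[k], name,
                        10.0 + g_eff[i] + e_eff[j] + z[i, j] + eps[i, j, k],
                    ))
    df = pd.DataFrame(
        rows, columns=["genotype", "environment", "replicate", "trait", "value"]
    )
    return MetDataset(records=df), gen_ids[:n_elite]


def toy_matrix() -> GEMatrix:
    """Fixed 3 × 3 means matrix used as an exact hand-checkable fixture.

    Its double-centered interaction is [[-1,0,1],[-1,1,0],[2,-1,-1]] with
    interaction SS 10, singular values (3, 1, 0) and per-genotype
    ecovalences (2, 2, 6).
    """
    means = pd.DataFrame(
        [[10.0, 12.0, 14.0], [10.0, 13.0, 13.0], [13.0, 11.0, 12.0]],
        index=["G1", "G2", "G3"],
        columns=["E1", "E2", "E3"],
    )
    counts = pd.DataFrame(1, index=means.index, columns=means.columns)
    return GEMatrix(trait="toy", means=means, rep_counts=counts, balanced=True)
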