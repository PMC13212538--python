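"""Pipeline orchestration: run the requested analyses and write a report bundle.

Every analysis table lands as one CSV in the output directory (per-trait
tables under a subdirectory named after the trait); a ``manifest.json``
records the package version, seed, configuration hash and artifact list,
so identical configuration and input reproduce byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .ammi import AmmiModel
from .data import MetDataset, cell_means, environment_summary, read_met_table
from .exceptions import InputError
from .gamem import GamemModel
from .gge import GgeModel
from .mtsi import FactorModel, mtsi, selection_differentials
from .stability import stability_table
from .waasb import waasb_scores, waasby

logger = logging.getLogger("metstab")

KNOWN_MODULES = ("ammi", "indices", "blup", "waasb", "gge", "mtsi")
_DEPENDS = {
    "indices": ("ammi",),
    "waasb": ("blup",),
    "mtsi": ("waasb",),
}
_ALIASES = {"parametric": "indices"}


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_path: str
    traits: list[str]
    modules: list[str] = field(default_factory=lambda: list(KNOWN_MODULES))
    output_dir: str = "metstab_out"
    mean_weight: float = 65.0
    intensity: float = 15.0
    axes_rule: str = "all"
    alpha: float = 0.05
    svp: str = "environment"
    gge_scaling: str = "none"
    trait_directions: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.modules = [_ALIASES.get(m, m) for m in self.modules]
        unknown = [m for m in self.modules if m not in KNOWN_MODULES]
        if unknown:
            raise InputError(f"unknown modules {unknown}; choose from {KNOWN_MODULES}")
        for mod in self.modules:
            for dep in _DEPENDS.get(mod, ()):
                if dep not in self.modules:
                    raise InputError(
                        f"module {mod!r} requires {dep!r} to run first; add it"
                    )
        if not (0.0 < self.intensity <= 100.0):
            raise InputError("intensity must be in (0, 100]")
        if not (0.0 <= self.mean_weight <= 100.0):
            raise InputError("mean_weight must be in [0, 100]")

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.__dict__.items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_pipeline(cfg: RunConfig, data: MetDataset | None = None) -> dict:
    """Execute the requested modules in dependency order; returns the manifest."""
    t0 = time.time()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if data is None:
        data = read_met_table(cfg.input_path, cfg.traits)
    missing = [t for t in cfg.traits if t not in data.traits]
    if missing:
        raise InputError(f"requested traits {missing} not in input")
    artifacts: list[str] = []

    def save(df: pd.DataFrame, relpath: str, index_label: str | None = None) -> None:
        path = out / relpath
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=index_label is not None, index_label=index_label)
        artifacts.append(relpath)

    waasby_tables: dict[str, pd.DataFrame] = {}
    h2: dict[str, float] = {}

    for trait in cfg.traits:
        tdir = trait
        direction = cfg.trait_directions.get(trait, "higher")
        gem = cell_means(data, trait)
        env_sum = pd.DataFrame(
            [vars(s) for s in environment_summary(gem)]
        )
        save(env_sum, f"{tdir}/environment_summary.csv")

        ammi_fit = None
        if "ammi" in cfg.modules:
            logger.info("AMMI: %s", trait)
            ammi_fit = AmmiModel(data, trait).fit()
            save(ammi_fit.anova(), f"{tdir}/anova.csv")
            eff = pd.DataFrame({
                "genotype_effect": ammi_fit.genotype_effects,
            })
            eff = pd.concat([eff, ammi_fit.genotype_eigenvectors], axis=1)
            save(eff, f"{tdir}/ammi_fit.csv", index_label="GEN")
            save(ammi_fit.ammi1_coords(), f"{tdir}/biplot_ammi1.csv")
            save(ammi_fit.ammi2_coords(), f"{tdir}/biplot_ammi2.csv")

        if "indices" in cfg.modules:
            logger.info("stability indices: %s", trait)
            tab = stability_table(
                data, trait,
                axes_rule=cfg.axes_rule, alpha=cfg.alpha, direction=direction,
            )
            save(tab, f"{tdir}/stability.csv", index_label="GEN")

        gamem_res = None
        if "blup" in cfg.modules:
            logger.info("REML/BLUP: %s", trait)
            gamem_res = GamemModel(data, trait).fit()
            save(gamem_res.summary(), f"{tdir}/variance_components.csv")
            save(
                pd.DataFrame({"blup": gamem_res.blup_genotype}),
                f"{tdir}/blups.csv", index_label="GEN",
            )
            save(gamem_res.blup_indices(), f"{tdir}/blup_indices.csv", index_label="GEN")
            h2[trait] = gamem_res.heritability
            diag = {
                "trait": trait,
                "restricted_loglik": gamem_res.loglik,
                "lrt_genotype": gamem_res.lrt("genotype"),
                "lrt_ge": gamem_res.lrt("ge"),
            }
            path = out / tdir / "reml_diagnostics.json"
            path.write_text(json.dumps(diag, indent=2, default=float))
            artifacts.append(f"{tdir}/reml_diagnostics.json")

        if "waasb" in cfg.modules:
            logger.info("WAASB: %s", trait)
            wb = waasb_scores(gamem_res.blup_ge)
            table = waasby(
                gem.means.mean(axis=1), wb,
                mean_weight=cfg.mean_weight, direction=direction,
            )
            save(table, f"{tdir}/waasb.csv", index_label="GEN")
            waasby_tables[trait] = table

        if "gge" in cfg.modules:
            logger.info("GGE: %s", trait)
            gge_res = GgeModel(gem, scaling=cfg.gge_scaling, svp=cfg.svp).fit()
            coords = pd.concat([
                gge_res.genotype_scores.iloc[:, :2].assign(type="genotype"),
                gge_res.environment_scores.iloc[:, :2].assign(type="environment"),
            ])
            save(coords, f"{tdir}/gge_coords.csv", index_label="id")
            www = gge_res.which_won_where()
            rows = [
                {
                    "environment": e,
                    "sector": s,
                    "winner": www.sector_winner[s],
                }
                for e, s in www.environment_sector.items()
            ]
            save(pd.DataFrame(rows), f"{tdir}/which_won_where.csv")
            save(gge_res.mean_vs_stability(), f"{tdir}/mean_vs_stability.csv",
                 index_label="GEN")
            save(gge_res.rank_vs_ideal(), f"{tdir}/rank_vs_ideal.csv",
                 index_label="GEN")
            save(gge_res.discrim_vs_repr(), f"{tdir}/discrim_vs_repr.csv",
                 index_label="ENV")

    if "mtsi" in cfg.modules:
        logger.info("MTSI across %d traits", len(waasby_tables))
        wmat = pd.DataFrame(
            {t: tab["WAASBY"] for t, tab in waasby_tables.items()}
        )
        save(wmat, "waasby_matrix.csv", index_label="GEN")
        fm = FactorModel(wmat).fit()
        save(fm.loadings, "factor_loadings.csv", index_label="trait")
        eig = pd.DataFrame({
            "eigenvalue": fm.eigenvalues,
            "explained_pct": fm.explained,
            "cumulative_pct": fm.cumulative_explained,
        })
        save(eig, "factor_eigen.csv")
        save(fm.scores, "factor_scores.csv", index_label="GEN")
        res = mtsi(fm).select(cfg.intensity)
        rank_tab = pd.DataFrame({
            "MTSI": res.mtsi,
            "selected": [g in res.selected for g in res.mtsi.index],
        }).sort_values("MTSI")
        save(rank_tab, "mtsi.csv", index_label="GEN")
        save(res.contributions, "mtsi_factor_contributions.csv", index_label="GEN")
        sd = selection_differentials(
            wmat, res.selected,
            h2=pd.Series(h2).reindex(wmat.columns) if h2 else None,
        )
        save(sd, "selection_differentials.csv", index_label="trait")

    manifest = {
        "package": "metstab",
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "traits": cfg.traits,
        "modules": cfg.modules,
        "artifacts": sorted(artifacts),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline finished in %.2fs", time.time() - t0)
    return manifest
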