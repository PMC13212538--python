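"""Core data containers for multi-environment trial (MET) phenotypes.

A MET evaluates a set of genotypes in several environments (location ×
season combinations) with replication, typically as a randomized complete
block design within each environment.  The universal input here is a
long-format table of replicate-level observations: one row per
(genotype, environment, replicate, trait).  Every downstream model —
AMMI, GGE, the mixed model — consumes either this table or the genotype ×
environment matrix of cell means derived from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError, IntegrityError, SchemaError, UnsupportedDesignError

__all__ = [
    "MetDataset",
    "GEMatrix",
    "EnvironmentSummary",
    "read_met_table",
    "cell_means",
    "environment_summary",
    "trait_correlations",
]

#: default column names for the identifier columns of a MET table
DEFAULT_ID_COLS = ("GEN", "ENV", "REP")

_LONG_COLS = ["genotype", "environment", "replicate", "trait", "value"]


@dataclass
class MetDataset:
    """Replicate-level MET phenotypes in long format.

    Parameters
    ----------
    records : pandas.DataFrame
        Columns ``genotype``, ``environment``, ``replicate``, ``trait``
        (strings) and ``value`` (float).  One row per observation
        :math:`Y_{ijr}` of one trait.
    trait_units : dict
        Optional map trait name -> unit string, for reporting only.
    """

    records: pd.DataFrame
    trait_units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in _LONG_COLS if c not in df.columns]
        if missing:
            raise SchemaError(f"MetDataset records missing columns: {missing}")
        if len(df) == 0:
            raise InputError("MetDataset has no records")
        df = df.copy()
        for c in _LONG_COLS[:4]:
            df[c] = df[c].astype(str)
        values = pd.to_numeric(df["value"], errors="coerce")
        bad = ~np.isfinite(values.to_numpy(dtype=float))
        if bad.any():
            first = df.index[bad][0]
            raise InputError(
                f"non-finite or non-numeric trait value at row {first} "
                f"(trait {df.loc[first, 'trait']!r})"
            )
        df["value"] = values.astype(float)
        key = ["genotype", "environment", "replicate", "trait"]
        dup = df.duplicated(subset=key)
        if dup.any():
            first = df.loc[dup.idxmax(), key].tolist()
            raise IntegrityError(f"duplicated observation key {tuple(first)}")
        for trait, sub in df.groupby("trait"):
            if sub["genotype"].nunique() < 2 or sub["environment"].nunique() < 2:
                raise IntegrityError(
                    f"trait {trait!r} needs at least 2 genotypes and 2 environments"
                )
        self.records = df.reset_index(drop=True)

    # -- convenient accessors -------------------------------------------------

    @property
    def traits(self) -> list[str]:
        return sorted(self.records["trait"].unique())

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.records["genotype"].unique())

    @property
    def environments(self) -> list[str]:
        return sorted(self.records["environment"].unique())

    def trait_frame(self, trait: str) -> pd.DataFrame:
        """Long-format rows for one trait (genotype, environment, replicate, value)."""
        if trait not in set(self.records["trait"]):
            raise KeyError(f"trait {trait!r} not in dataset")
        return self.records[self.records["trait"] == trait].reset_index(drop=True)

    def to_wide(self) -> pd.DataFrame:
        """Wide table: one row per (genotype, environment, replicate), one column per trait."""
        wide = self.records.pivot_table(
            index=["genotype", "environment", "replicate"],
            columns="trait",
            values="value",
            aggfunc="first",
        ).reset_index()
        wide.columns.name = None
        return wide.rename(
            columns={"genotype": "GEN", "environment": "ENV", "replicate": "REP"}
        )

    @classmethod
    def from_wide(
        cls,
        df: pd.DataFrame,
        trait_columns: list[str],
        genotype_col: str = "GEN",
        environment_col: str = "ENV",
        replicate_col: str = "REP",
        trait_units: dict[str, str] | None = None,
    ) -> "MetDataset":
        for col in (genotype_col, environment_col, replicate_col, *trait_columns):
            if col not in df.columns:
                raise SchemaError(f"required column {col!r} missing from table")
        key_cols = [genotype_col, environment_col, replicate_col]
        dup = df.duplicated(subset=key_cols)
        if dup.any():
            first = df.loc[dup.idxmax(), key_cols].tolist()
            raise IntegrityError(
                f"duplicated (genotype, environment, replicate) row {tuple(first)}"
            )
        for col in trait_columns:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = ~np.isfinite(vals.to_numpy(dtype=float))
            if bad.any():
                row = df.index[bad][0]
                raise InputError(f"non-numeric value in column {col!r} at row {row}")
        long = df.melt(
            id_vars=key_cols,
            value_vars=list(trait_columns),
            var_name="trait",
            value_name="value",
        ).rename(
            columns={
                genotype_col: "genotype",
                environment_col: "environment",
                replicate_col: "replicate",
            }
        )
        return cls(records=long, trait_units=dict(trait_units or {}))


@dataclass
class GEMatrix:
    """Genotype × environment matrix of cell means :math:`X_{ij}` for one trait."""

    trait: str
    means: pd.DataFrame          # genotypes (rows) × environments (columns)
    rep_counts: pd.DataFrame     # same shape, integer replicate counts
    balanced: bool
    missing_cells: list[tuple[str, str]] = field(default_factory=list)

    @property
    def genotypes(self) -> list[str]:
        return list(self.means.index)

    @property
    def environments(self) -> list[str]:
        return list(self.means.columns)

    @property
    def grand_mean(self) -> float:
        return float(np.nanmean(self.means.to_numpy()))

    def require_complete(self) -> None:
        if self.missing_cells or self.means.isna().any().any():
            raise UnsupportedDesignError(
                f"GEMatrix for {self.trait!r} has empty cells {self.missing_cells}; "
                "fixed-effect methods need a complete matrix"
            )

    def interaction(self) -> pd.DataFrame:
        """Double-centered matrix Z: X_ij − row mean − column mean + grand mean."""
        self.require_complete()
        x = self.means.to_numpy(dtype=float)
        z = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + x.mean()
        return pd.DataFrame(z, index=self.means.index, columns=self.means.columns)

    def to_csv(self, path) -> None:
        self.means.to_csv(path, index_label="GEN")


@dataclass
class EnvironmentSummary:
    """Environment mean, centred environmental index, and favorability class.

    The environmental index (environment mean minus grand mean) classifies
    an environment as favorable when genotypes on average perform above the
    grand mean there; strictly positive index required (ties unfavorable).
    """

    environment: str
    mean: float
    environmental_index: float
    favorability: str  # "favorable" | "unfavorable"


def read_met_table(
    path,
    trait_columns: list[str],
    genotype_col: str = "GEN",
    environment_col: str = "ENV",
    replicate_col: str = "REP",
) -> MetDataset:
    """Read a delimited MET table (CSV, or TSV by ``.tsv``/``.txt`` extension).

    The file must have a header row with the three identifier columns and the
    named trait columns.  Duplicate (genotype, environment, replicate) rows
    and non-numeric trait cells are rejected.
    """
    sep = "\t" if str(path).lower().endswith((".tsv", ".txt")) else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"empty input file {path}") from exc
    if len(df) == 0:
        raise InputError(f"no data rows in {path}")
    return MetDataset.from_wide(
        df,
        trait_columns,
        genotype_col=genotype_col,
        environment_col=environment_col,
        replicate_col=replicate_col,
    )


def cell_means(data: MetDataset, trait: str) -> GEMatrix:
    """Genotype × environment cell means for one trait.

    ``balanced`` is true when every cell holds the same number of replicates;
    empty cells are flagged in ``missing_cells`` and left as NaN.
    """
    sub = data.trait_frame(trait)
    means = sub.pivot_table(
        index="genotype", columns="environment", values="value", aggfunc="mean"
    )
    counts = sub.pivot_table(
        index="genotype", columns="environment", values="value", aggfunc="count"
    ).fillna(0).astype(int)
    means = means.reindex(index=sorted(means.index), columns=sorted(means.columns))
    counts = counts.reindex(index=means.index, columns=means.columns).fillna(0).astype(int)
    missing = [
        (g, e)
        for g in means.index
        for e in means.columns
        if counts.loc[g, e] == 0
    ]
    nonzero = counts.to_numpy()[counts.to_numpy() > 0]
    balanced = len(missing) == 0 and nonzero.size > 0 and (nonzero == nonzero[0]).all()
    return GEMatrix(
        trait=trait,
        means=means,
        rep_counts=counts,
        balanced=bool(balanced),
        missing_cells=missing,
    )


def environment_summary(gem: GEMatrix) -> list[EnvironmentSummary]:
    """Per-environment mean, environmental index, and favorability.

    The index is the environment mean minus the grand mean; indices sum to
    zero over environments.  Environments with a strictly positive index are
    classed favorable.
    """
    gem.require_complete()
    col_means = gem.means.mean(axis=0)
    grand = float(gem.means.to_numpy().mean())
    out = []
    for env in gem.environments:
        idx = float(col_means[env] - grand)
        out.append(
            EnvironmentSummary(
                environment=env,
                mean=float(col_means[env]),
                environmental_index=idx,
                favorability="favorable" if idx > 0 else "unfavorable",
            )
        )
    return out


def trait_correlations(data: MetDataset, traits: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlations among traits over genotype means pooled across environments.

    Each trait is first reduced to one mean per genotype (pooling environments
    and replicates); correlations are then computed across genotypes.  A
    zero-variance trait yields NaN entries with a warning.
    """
    traits = list(traits) if traits is not None else data.traits
    for t in traits:
        if t not in data.traits:
            raise KeyError(f"trait {t!r} not in dataset")
    sub = data.records[data.records["trait"].isin(traits)]
    gm = sub.pivot_table(index="genotype", columns="trait", values="value", aggfunc="mean")
    gm = gm[traits]
    if len(gm) < 3:
        raise UnsupportedDesignError("trait correlations need at least 3 genotypes")
    zero_var = gm.std(ddof=1) == 0
    if zero_var.any():
        warnings.warn(
            f"zero-variance traits {list(gm.columns[zero_var])}: correlations undefined",
            stacklevel=2,
        )
    corr = gm.corr(method="pearson")
    arr = corr.to_numpy(dtype=float).copy()
    zv = zero_var.to_numpy()
    arr[zv, :] = np.nan
    arr[:, zv] = np.nan
    np.fill_diagonal(arr, np.where(zv, np.nan, 1.0))
    return pd.DataFrame(arr, index=corr.index, columns=corr.columns)
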