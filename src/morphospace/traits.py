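"""Species x trait tables over mixed measurement scales.

The trait model follows a five-trait morphological schema for ferns:
rhizome type (categorical), laminar dissection and laminar texture
(ordinal, scored on integer class codes), laminar length (continuous,
cm) and presence of hydathodes (binary).  Every trait carries a scale
tag so downstream dissimilarity code can dispatch on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCALES = ("categorical", "ordinal", "binary", "continuous")


class TraitValidationError(ValueError):
    """A trait value, column, or species id violates the declared schema."""


@dataclass(frozen=True)
class TraitSchema:
    """Declares, per trait, its measurement scale and admissible values.

    ``levels`` lists the admissible integer codes for categorical,
    ordinal, and binary traits; ``bounds`` gives the (open) lower /
    upper limits for continuous traits.
    """

    scales: dict[str, str]
    levels: dict[str, tuple[int, ...]] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, scale in self.scales.items():
            if scale not in SCALES:
                raise TraitValidationError(f"unknown scale {scale!r} for trait {name!r}")
            if scale == "continuous":
                if name not in self.bounds:
                    raise TraitValidationError(f"continuous trait {name!r} needs bounds")
            elif name not in self.levels:
                raise TraitValidationError(f"trait {name!r} needs declared levels")
            if scale == "binary" and set(self.levels.get(name, ())) != {0, 1}:
                raise TraitValidationError(f"binary trait {name!r} must have levels (0, 1)")

    @property
    def trait_names(self) -> list[str]:
        return list(self.scales)


#: Default schema for the fern morphological trait set.
FERN_SCHEMA = TraitSchema(
    scales={
        "rhizome_type": "categorical",
        "laminar_dissection": "ordinal",
        "laminar_texture": "ordinal",
        "laminar_length": "continuous",
        "hydathodes": "binary",
    },
    levels={
        "rhizome_type": (0, 1, 2, 3),
        "laminar_dissection": (0, 1, 2),
        "laminar_texture": (1, 2, 3),
        "hydathodes": (0, 1),
    },
    bounds={"laminar_length": (0.0, np.inf)},
)


@dataclass
class TraitTable:
    """Validated species x trait matrix.

    ``data`` is indexed by species id with one column per trait in the
    schema's order.  Construction validates uniqueness of ids, absence
    of missing values, and membership of every value in its trait's
    declared domain.
    """

    data: pd.DataFrame
    schema: TraitSchema = FERN_SCHEMA

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise TraitValidationError(f"duplicated species ids: {dups}")
        missing = [c for c in self.schema.trait_names if c not in df.columns]
        if missing:
            raise TraitValidationError(f"missing trait columns: {missing}")
        unknown = [c for c in df.columns if c not in self.schema.scales]
        if unknown:
            raise TraitValidationError(f"unknown trait columns: {unknown}")
        df = df[self.schema.trait_names]
        if df.isna().any().any():
            bad = df.index[df.isna().any(axis=1)].tolist()
            raise TraitValidationError(f"missing trait values for species {bad}")
        for name in self.schema.trait_names:
            col = df[name]
            if self.schema.scales[name] == "continuous":
                lo, hi = self.schema.bounds[name]
                vals = col.astype(float)
                bad = col.index[(vals <= lo) | (vals >= hi) | ~np.isfinite(vals)]
                if len(bad):
                    raise TraitValidationError(
                        f"trait {name!r} out of bounds ({lo}, {hi}) for species "
                        f"{bad.tolist()} (values {col.loc[bad].tolist()})"
                    )
                df[name] = vals
            else:
                allowed = set(self.schema.levels[name])
                vals = col.astype(int)
                if not (vals == col).all():
                    raise TraitValidationError(f"non-integer codes in trait {name!r}")
                bad = col.index[~vals.isin(allowed)]
                if len(bad):
                    raise TraitValidationError(
                        f"trait {name!r} value outside domain {sorted(allowed)} for "
                        f"species {bad.tolist()} (values {col.loc[bad].tolist()})"
                    )
                df[name] = vals
        self.data = df

    @property
    def species_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def n_species(self) -> int:
        return len(self.data)

    def subset(self, species: list[str]) -> "TraitTable":
        missing = [s for s in species if s not in self.data.index]
        if missing:
            raise KeyError(f"species not in trait table: {missing}")
        return TraitTable(self.data.loc[species].copy(), self.schema)

    def relabel(self, new_ids: list[str]) -> "TraitTable":
        """Return a table with the same trait rows under permuted ids."""
        if sorted(new_ids) != sorted(self.species_ids):
            raise TraitValidationError("relabel must permute the existing species ids")
        df = self.data.copy()
        df.index = pd.Index(new_ids, name=df.index.name)
        return TraitTable(df, self.schema)


def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_trait_table(path: str, schema: TraitSchema = FERN_SCHEMA) -> TraitTable:
    """Read a CSV/TSV trait table (one row per species) and validate it.

    The first column is taken as the species id.  Raises
    :class:`TraitValidationError` naming the offending species and trait
    on any domain violation.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    return TraitTable(df, schema)


def write_trait_table(table: TraitTable, path: str) -> None:
    df = table.data.copy()
    df.index.name = "species_id"
    df.to_csv(path, sep=_sep_for(path), float_format="%.10g")


def read_schema(path: str) -> TraitSchema:
    """Read a flat ``key: value`` schema file.

    Lines look like ``laminar_texture: ordinal 1,2,3`` or
    ``laminar_length: continuous 0,inf``.
    """
    scales: dict[str, str] = {}
    levels: dict[str, tuple[int, ...]] = {}
    bounds: dict[str, tuple[float, float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, _, rest = line.partition(":")
            parts = rest.split()
            scale = parts[0]
            scales[name.strip()] = scale
            if scale == "continuous":
                lo, hi = parts[1].split(",")
                bounds[name.strip()] = (float(lo), float(hi))
            else:
                levels[name.strip()] = tuple(int(v) for v in parts[1].split(","))
    return TraitSchema(scales, levels, bounds)
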