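"""Data model, readers/writers and validation shared by all analysis stages.

Cell tables are plain :class:`pandas.DataFrame` objects with the canonical
columns ``cell_id, image_id, x, y, lineage`` (coordinates in micrometres,
1 pixel = 1 um) plus optional per-marker intensity columns.  Image metadata
is a second frame keyed by ``image_id`` carrying ``patient_id``,
``primary_site`` (lung / breast / melanoma / other), ``region``
(core / margin) and ``pattern`` (MI = minimally invasive, HI = highly
invasive growth pattern).  Validation is total: every input either yields a
valid table or a located error, never a silent drop.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "CellTableParseError",
    "UnknownLineageError",
    "GmtError",
    "LineageSet",
    "AnalysisConfig",
    "CELL_COLUMNS",
    "META_COLUMNS",
    "read_cell_table",
    "write_cell_table",
    "read_image_meta",
    "write_image_meta",
    "validate_cells",
    "read_gmt",
    "write_gmt",
    "write_manifest",
]

CELL_COLUMNS = ("cell_id", "image_id", "x", "y", "lineage")
META_COLUMNS = ("image_id", "patient_id", "primary_site", "region", "pattern")

REGIONS = ("core", "margin")
PATTERNS = ("MI", "HI")
PRIMARY_SITES = ("lung", "breast", "melanoma", "other")


class SchemaError(ValueError):
    """A required column is missing or the schema mapping is inconsistent."""


class CellTableParseError(ValueError):
    """A cell-table value could not be parsed; the message carries the row index."""


class UnknownLineageError(ValueError):
    """A lineage label is not part of the declared :class:`LineageSet`."""


class GmtError(ValueError):
    """A GMT gene-set file is malformed; the message carries the line number."""


#: The default 20-lineage palette used by the segmented imaging-mass-cytometry
#: tables: one cancer lineage, eighteen resolvable stromal lineages, and an
#: "Undefined" bucket for cells the antibody panel cannot classify.
DEFAULT_LINEAGES = (
    "Cancer",
    "B cell",
    "Plasma cell",
    "T helper",
    "T cytotoxic",
    "T regulatory",
    "Other T",
    "NK cell",
    "Dendritic cell",
    "Macrophage",
    "Monocyte",
    "Microglia",
    "Neutrophil",
    "Mast cell",
    "Astrocyte",
    "Oligodendrocyte",
    "Neuron",
    "Endothelial",
    "Fibroblast",
    "Undefined",
)


@dataclass(frozen=True)
class LineageSet:
    """Ordered lineage palette with cancer / stroma flags.

    Exactly one lineage is the cancer lineage.  Every non-cancer lineage is
    stromal unless listed in ``non_stroma``; the "Undefined" bucket counts as
    stroma by default (``undefined_is_stroma``) because it is reported among
    the stromal populations.
    """

    names: tuple[str, ...] = DEFAULT_LINEAGES
    cancer: str = "Cancer"
    non_stroma: frozenset[str] = frozenset()
    undefined_is_stroma: bool = True

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("lineage names must be unique")
        if self.cancer not in self.names:
            raise ValueError(f"cancer lineage {self.cancer!r} not in palette")
        if not self.stroma:
            raise ValueError("stroma lineage set is empty")

    def is_cancer(self, name: str) -> bool:
        return name == self.cancer

    def counts_as_stroma(self, name: str) -> bool:
        if name == self.cancer or name in self.non_stroma:
            return False
        if name == "Undefined" and not self.undefined_is_stroma:
            return False
        return name in self.names

    @property
    def stroma(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if self.counts_as_stroma(n))

    def codes(self) -> dict[str, int]:
        """Stable integer coding used by the permutation engine."""
        return {n: i for i, n in enumerate(self.names)}

    def validate_labels(self, labels: Sequence[str]) -> None:
        unknown = sorted(set(labels) - set(self.names))
        if unknown:
            raise UnknownLineageError(
                f"unknown lineage label(s): {', '.join(map(repr, unknown))}"
            )


@dataclass
class AnalysisConfig:
    """Shared analysis parameters.

    radius_um
        Interaction radius: cells within this distance are neighbours (6 um,
        i.e. 6 pixels at the 1 px = 1 um convention).
    n_perm
        Label permutations per image for the interaction test.
    score_cutoff
        Interaction/avoidance score above which a pair is classified
        (default half of ``n_perm``).
    k_neighborhoods, window_size
        K clusters and N nearest neighbours for cellular-neighborhood
        discovery.
    """

    radius_um: float = 6.0
    n_perm: int = 50_000
    score_cutoff: int = 25_000
    k_neighborhoods: int = 9
    window_size: int = 10
    alpha: float = 0.05
    padj_threshold: float = 0.1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius_um must be > 0")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0 <= self.score_cutoff <= self.n_perm:
            raise ValueError("score_cutoff must lie in [0, n_perm]")
        if self.k_neighborhoods < 2:
            raise ValueError("k_neighborhoods must be >= 2")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","


def validate_cells(cells: pd.DataFrame, lineages: LineageSet | None = None) -> pd.DataFrame:
    """Validate a canonical-column cell table in place and return it.

    Checks column presence, coordinate parsability/finiteness (reporting the
    offending row index), (image_id, cell_id) uniqueness, and lineage labels
    against ``lineages`` when given.
    """
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    for col in ("x", "y"):
        vals = pd.to_numeric(cells[col], errors="coerce")
        bad = vals.index[~np.isfinite(vals.to_numpy(dtype=float))]
        if len(bad):
            raise CellTableParseError(
                f"non-numeric or non-finite {col!r} at row index {bad[0]}"
            )
        cells[col] = vals.astype(float)
    dup = cells.duplicated(subset=["image_id", "cell_id"])
    if dup.any():
        i = cells.index[dup][0]
        raise CellTableParseError(f"duplicate (image_id, cell_id) at row index {i}")
    if lineages is not None:
        lineages.validate_labels(cells["lineage"].astype(str))
    return cells


def read_cell_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    lineages: LineageSet | None = None,
    sep: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Read a delimited per-cell table; return ``(cells, meta_or_None)``.

    ``schema`` maps canonical names (``cell_id`` ...) to the file's column
    names for tables in a foreign dialect.  If the file also carries the
    image-metadata columns they are split off into a per-image frame
    (one row per image; conflicting metadata is an error).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep or _sep_for(path))
    if schema:
        rename = {v: k for k, v in schema.items()}
        absent = [v for v in schema.values() if v not in df.columns]
        if absent:
            raise SchemaError(
                f"schema names column(s) absent from file: {', '.join(absent)}"
            )
        df = df.rename(columns=rename)
    cells = validate_cells(df, lineages)
    meta = None
    meta_cols = [c for c in META_COLUMNS if c != "image_id" and c in cells.columns]
    if meta_cols:
        meta = cells[["image_id", *meta_cols]].drop_duplicates().reset_index(drop=True)
        if meta["image_id"].duplicated().any():
            raise SchemaError("conflicting image metadata: >1 metadata row per image")
        cells = cells.drop(columns=meta_cols)
    return cells, meta


def write_cell_table(cells: pd.DataFrame, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    cells.to_csv(path, sep=sep or _sep_for(path), index=False)


def read_image_meta(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    path = Path(path)
    meta = pd.read_csv(path, sep=sep or _sep_for(path))
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise SchemaError(f"image metadata missing column(s): {', '.join(missing)}")
    if meta["image_id"].duplicated().any():
        raise SchemaError("image metadata has duplicate image_id rows")
    return meta


def write_image_meta(meta: pd.DataFrame, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    meta.to_csv(path, sep=sep or _sep_for(path), index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT gene sets: ``name<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a set are dropped (first occurrence kept); a set
    with no genes is an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtError(f"line {lineno}: expected name, description, >=1 gene")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise GmtError(f"line {lineno}: gene set {name!r} is empty")
            seen: dict[str, None] = {}
            for g in genes:
                seen.setdefault(g, None)
            sets[name] = list(seen)
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def write_manifest(path: str | Path, config: AnalysisConfig, seed: int | None = None,
                   extra: Mapping | None = None) -> None:
    """Write the JSON run manifest: config, seed and library versions."""
    import sklearn
    import scipy

    payload = {
        "config": dataclasses.asdict(config),
        "seed": config.rng_seed if seed is None else seed,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
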