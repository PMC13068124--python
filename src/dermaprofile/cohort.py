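"""Categorical cohort tables with a column-role manifest.

A cohort is a subjects x features table of integer category codes. Every
column carries a :class:`FeatureSpec` declaring its modality (``genetics``,
``lifestyle`` or ``phenotype``), its scale (``nominal``, ``ordinal`` or
``binary``) and the admissible integer levels. Genetics columns hold
per-gene mutation burden: 0 (wild type), 1 (heterozygous), 2 (homozygous or
compound heterozygous).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MODALITIES = ("genetics", "lifestyle", "phenotype")
SCALES = ("nominal", "ordinal", "binary")

#: burden code -> group label (bijection)
BURDEN_LABELS = {0: "none", 1: "single", 2: "double"}


class ManifestError(ValueError):
    """The manifest is malformed or inconsistent with the table."""


class CohortValidationError(ValueError):
    """A table value violates its feature's declared levels."""


@dataclass(frozen=True)
class FeatureSpec:
    """Declared role and coding of one cohort column."""

    name: str
    modality: str
    scale: str
    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ManifestError(
                f"feature {self.name!r}: unknown modality {self.modality!r}"
            )
        if self.scale not in SCALES:
            raise ManifestError(f"feature {self.name!r}: unknown scale {self.scale!r}")
        levels = tuple(int(v) for v in self.levels)
        object.__setattr__(self, "levels", levels)
        if len(set(levels)) != len(levels) or len(levels) < 2:
            raise ManifestError(f"feature {self.name!r}: levels must be >=2 and unique")
        if self.modality == "genetics" and levels != (0, 1, 2):
            raise ManifestError(
                f"feature {self.name!r}: genetics features code burden as (0, 1, 2)"
            )
        if self.scale == "binary" and tuple(sorted(levels)) != (0, 1):
            raise ManifestError(f"feature {self.name!r}: binary features use levels (0, 1)")
        if self.modality == "phenotype":
            if self.scale != "ordinal" or levels != tuple(range(len(levels))):
                raise ManifestError(
                    f"feature {self.name!r}: phenotype features are ordinal with "
                    "consecutive levels starting at 0"
                )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "modality": self.modality,
            "scale": self.scale,
            "levels": list(self.levels),
        }


class CohortTable:
    """Validated subjects x features table of integer category codes."""

    def __init__(self, data: pd.DataFrame, manifest: Sequence[FeatureSpec]):
        manifest = list(manifest)
        names = [f.name for f in manifest]
        if len(set(names)) != len(names):
            raise ManifestError("duplicate feature names in manifest")
        missing = set(names) - set(data.columns)
        if missing:
            raise ManifestError(f"table lacks manifest columns: {sorted(missing)}")
        extra = set(data.columns) - set(names)
        if extra:
            raise ManifestError(f"columns absent from manifest: {sorted(extra)}")
        data = data[names]  # manifest order is canonical
        present = {f.modality for f in manifest}
        if set(MODALITIES) - present:
            raise ManifestError(
                f"cohort must contain every modality; missing {sorted(set(MODALITIES) - present)}"
            )
        self.manifest = manifest
        self._by_name = {f.name: f for f in manifest}
        self.data = data.astype(np.int64)
        self._validate()

    # -- construction -----------------------------------------------------
    def _validate(self) -> None:
        for spec in self.manifest:
            col = self.data[spec.name]
            bad = ~col.isin(spec.levels)
            if bad.any():
                row = self.data.index[bad.to_numpy().argmax()]
                raise CohortValidationError(
                    f"value {col.loc[row]} at row {row!r}, column {spec.name!r} "
                    f"is not in levels {list(spec.levels)}"
                )

    # -- basic accessors ---------------------------------------------------
    @property
    def subjects(self) -> list:
        return list(self.data.index)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.manifest]

    def spec(self, name: str) -> FeatureSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise ManifestError(f"unknown feature {name!r}") from None

    def columns_for(self, modalities: Iterable[str]) -> list[str]:
        modalities = set(modalities)
        unknown = modalities - set(MODALITIES)
        if unknown:
            raise ManifestError(f"unknown modalities: {sorted(unknown)}")
        return [f.name for f in self.manifest if f.modality in modalities]

    def to_array(self, columns: Sequence[str] | None = None) -> np.ndarray:
        frame = self.data if columns is None else self.data[list(columns)]
        return frame.to_numpy(dtype=np.int64)

    def subset_rows(self, indices: Sequence[int]) -> "CohortTable":
        return CohortTable(self.data.iloc[list(indices)], self.manifest)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.data)


def select_modalities(cohort: CohortTable, modalities: Iterable[str]) -> CohortTable:
    """Column-subset view of the cohort restricted to the given modalities.

    Subject order is unchanged. An empty resulting feature set is an error.
    """
    modalities = set(modalities)
    if not modalities:
        raise ManifestError("requested modality set is empty")
    names = cohort.columns_for(modalities)
    if not names:
        raise ManifestError(f"no features with modality in {sorted(modalities)}")
    specs = [cohort.spec(n) for n in names]
    # bypass the all-modalities invariant for deliberate views
    table = CohortTable.__new__(CohortTable)
    table.manifest = specs
    table._by_name = {f.name: f for f in specs}
    table.data = cohort.data[names]
    return table


def load_manifest(path: str | Path) -> list[FeatureSpec]:
    """Load a manifest (YAML or JSON list of feature dicts)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, list):
        raise ManifestError("manifest must be a list of feature entries")
    specs = []
    for entry in raw:
        try:
            specs.append(
                FeatureSpec(
                    name=str(entry["name"]),
                    modality=entry["modality"],
                    scale=entry["scale"],
                    levels=tuple(entry["levels"]),
                )
            )
        except (KeyError, TypeError) as exc:
            raise ManifestError(f"malformed manifest entry {entry!r}") from exc
    return specs


def write_manifest(manifest: Sequence[FeatureSpec], path: str | Path) -> None:
    path = Path(path)
    payload = [f.to_dict() for f in manifest]
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def _read_table(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep, index_col=0)
    frame.index.name = None  # write_cohort labels it "subject"; keep round-trips exact
    return frame


def read_cohort(
    table_path: str | Path,
    manifest_path: str | Path,
    missing: str = "error",
) -> CohortTable:
    """Read and validate a cohort table against its manifest.

    Parameters
    ----------
    missing:
        ``"error"`` (default) rejects any missing cell; ``"drop_rows"``
        removes affected rows and logs how many were dropped.
    """
    if missing not in ("error", "drop_rows"):
        raise ValueError(f"unknown missing-data policy {missing!r}")
    manifest = load_manifest(manifest_path)
    frame = _read_table(Path(table_path))
    has_na = frame.isna().any(axis=1)
    if has_na.any():
        if missing == "drop_rows":
            n_drop = int(has_na.sum())
            logger.warning("dropping %d row(s) with missing values", n_drop)
            frame = frame.loc[~has_na]
        else:
            row = frame.index[has_na.to_numpy().argmax()]
            raise CohortValidationError(
                f"missing value(s) at row {row!r}; use missing='drop_rows' to discard"
            )
    # reject non-integer codes before casting silently truncates them
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any() or (numeric != numeric.round()).any().any():
        raise CohortValidationError("table contains non-integer category codes")
    return CohortTable(numeric.astype(np.int64), manifest)


def write_cohort(
    cohort: CohortTable, table_path: str | Path, manifest_path: str | Path | None = None
) -> None:
    table_path = Path(table_path)
    sep = "\t" if table_path.suffix.lower() in {".tsv", ".tab"} else ","
    cohort.data.to_csv(table_path, sep=sep, index_label="subject")
    if manifest_path is not None:
        write_manifest(cohort.manifest, manifest_path)
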