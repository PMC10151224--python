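"""Reading, writing, and validation of 2-D landmark datasets.

Two interchange formats are supported: the TPS dialect used by most landmark
digitizing tools (``LM=``, ``ID=``, ``IMAGE=``, ``SCALE=`` keys) and a flat
delimited table with one specimen per row.  Coordinates are Cartesian with y
increasing upward; the TPS reader applies ``SCALE=`` so that stored
coordinates are in mm, but never flips axes — image-pixel sources must be
flipped upstream.
"""

from __future__ import annotations

import csv
import io
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_SEXES = ("male", "female", "unknown")

METADATA_COLUMNS = ["specimen_id", "species", "sex", "site", "user_id", "replicate"]


class LandmarkFormatError(ValueError):
    """Raised when a landmark file violates its format contract."""


@dataclass
class LandmarkConfiguration:
    """One specimen's landmark configuration plus metadata.

    ``coords`` is a (k, 2) float array in mm.  Landmark order is homologous:
    index i corresponds to the same anatomical point in every specimen.
    """

    specimen_id: str
    coords: np.ndarray
    species: str = "unknown"
    sex: str = "unknown"
    site: str = "unknown"
    user_id: str = "unknown"
    replicate: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(
                f"coords must be (k, 2), got {self.coords.shape} for {self.specimen_id!r}"
            )
        if self.coords.shape[0] < 3:
            raise ValueError(f"need k >= 3 landmarks, got {self.coords.shape[0]}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates in {self.specimen_id!r}")
        if self.sex not in VALID_SEXES:
            raise ValueError(f"sex must be one of {VALID_SEXES}, got {self.sex!r}")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")

    @property
    def k(self) -> int:
        return self.coords.shape[0]

    @property
    def group(self) -> tuple[str, str]:
        """(species, sex) factor level used throughout the pipeline."""
        return (self.species, self.sex)


@dataclass
class LandmarkDataset:
    """An ordered collection of configurations sharing one landmark scheme."""

    configurations: list[LandmarkConfiguration]

    def __post_init__(self) -> None:
        if not self.configurations:
            raise ValueError("dataset must contain at least one configuration")
        ks = {c.k for c in self.configurations}
        if len(ks) > 1:
            raise LandmarkFormatError(f"inconsistent landmark counts across records: {sorted(ks)}")

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self) -> Iterator[LandmarkConfiguration]:
        return iter(self.configurations)

    def __getitem__(self, i: int) -> LandmarkConfiguration:
        return self.configurations[i]

    @property
    def k(self) -> int:
        return self.configurations[0].k

    @property
    def group_labels(self) -> list[tuple[str, str]]:
        return [c.group for c in self.configurations]

    @property
    def groups(self) -> list[tuple[str, str]]:
        """Distinct (species, sex) levels in sorted order."""
        return sorted(set(self.group_labels))

    def coords_array(self) -> np.ndarray:
        """(n, k, 2) coordinate stack."""
        return np.stack([c.coords for c in self.configurations])

    def subset(self, indices: Sequence[int]) -> "LandmarkDataset":
        return LandmarkDataset([self.configurations[i] for i in indices])


# ---------------------------------------------------------------------------
# TPS


def read_tps(path: str | Path) -> LandmarkDataset:
    """Read a TPS landmark file.

    Each record starts with ``LM=<count>`` followed by that many ``x y``
    lines, then optional ``ID=``, ``IMAGE=``, ``SCALE=`` lines.  If SCALE is
    present the coordinates are multiplied by it (yielding mm); otherwise
    coordinates are taken as already metric and a warning is logged.
    """
    path = Path(path)
    records: list[LandmarkConfiguration] = []
    lines = path.read_text(encoding="utf-8").splitlines()
    i = 0
    rec_index = 0
    any_unscaled = False
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise LandmarkFormatError(f"{path}: expected LM= at line {i + 1}, got {line!r}")
        rec_index += 1
        try:
            k = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise LandmarkFormatError(f"{path}: bad LM count in record {rec_index}") from exc
        i += 1
        coords = []
        while i < len(lines) and len(coords) < k:
            row = lines[i].strip()
            if not row or "=" in row:
                break
            parts = row.split()
            if len(parts) != 2:
                raise LandmarkFormatError(
                    f"{path}: record {rec_index}: expected 'x y' at line {i + 1}"
                )
            try:
                coords.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise LandmarkFormatError(
                    f"{path}: record {rec_index}: non-numeric coordinate at line {i + 1}"
                ) from exc
            i += 1
        if len(coords) != k:
            raise LandmarkFormatError(
                f"{path}: record {rec_index} declares LM={k} but provides {len(coords)} coordinate lines"
            )
        meta: dict[str, str] = {}
        while i < len(lines):
            row = lines[i].strip()
            if not row:
                i += 1
                continue
            if row.upper().startswith("LM="):
                break
            if "=" not in row:
                raise LandmarkFormatError(
                    f"{path}: record {rec_index}: unexpected line {i + 1}: {row!r}"
                )
            key, value = row.split("=", 1)
            meta[key.strip().upper()] = value.strip()
            i += 1
        arr = np.array(coords, dtype=float)
        if "SCALE" in meta:
            arr = arr * float(meta["SCALE"])
        else:
            any_unscaled = True
        records.append(
            LandmarkConfiguration(
                specimen_id=meta.get("ID", f"record_{rec_index}"),
                coords=arr,
            )
        )
    if not records:
        raise LandmarkFormatError(f"{path}: no TPS records found")
    if any_unscaled:
        logger.warning(
            "%s: one or more records lack SCALE=; coordinates taken as already metric", path
        )
    return LandmarkDataset(records)


def write_tps(ds: LandmarkDataset, path: str | Path) -> None:
    """Write a dataset as TPS (coordinates already in mm; no SCALE line)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for c in ds:
            fh.write(f"LM={c.k}\n")
            for x, y in c.coords:
                fh.write(f"{x:.17g} {y:.17g}\n")
            fh.write(f"ID={c.specimen_id}\n")


# ---------------------------------------------------------------------------
# Delimited table


def _coordinate_columns(k: int) -> list[str]:
    cols = []
    for j in range(1, k + 1):
        cols.extend([f"x{j}", f"y{j}"])
    return cols


def read_landmark_table(path: str | Path) -> LandmarkDataset:
    """Read a delimited landmark table (comma or tab, auto-detected).

    Expected header: specimen_id, species, sex, site, user_id, replicate,
    x1, y1, ..., xk, yk.
    """
    path = Path(path)
    sample = path.read_text(encoding="utf-8")
    if not sample.strip():
        raise LandmarkFormatError(f"{path}: empty file")
    delimiter = "\t" if "\t" in sample.splitlines()[0] else ","
    df = pd.read_csv(
        io.StringIO(sample), sep=delimiter, dtype={"specimen_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise LandmarkFormatError(f"{path}: missing metadata columns {missing}")
    coord_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    if len(coord_cols) % 2:
        raise LandmarkFormatError(f"{path}: odd number of coordinate columns ({len(coord_cols)})")
    k = len(coord_cols) // 2
    expected = _coordinate_columns(k)
    if coord_cols != expected:
        raise LandmarkFormatError(
            f"{path}: coordinate columns must be x1,y1,...,x{k},y{k}; got {coord_cols}"
        )
    configs = []
    for row_i, row in df.iterrows():
        vals = row[expected]
        bad = vals.index[pd.to_numeric(vals, errors="coerce").isna()]
        if len(bad):
            raise LandmarkFormatError(
                f"{path}: non-numeric coordinate at row {row_i + 2}, column {bad[0]!r}"
            )
        configs.append(
            LandmarkConfiguration(
                specimen_id=str(row["specimen_id"]),
                coords=np.asarray(vals, dtype=float).reshape(k, 2),
                species=str(row["species"]),
                sex=str(row["sex"]),
                site=str(row["site"]),
                user_id=str(row["user_id"]),
                replicate=int(row["replicate"]),
            )
        )
    return LandmarkDataset(configs)


def write_landmark_table(ds: LandmarkDataset, path: str | Path, delimiter: str = "\t") -> None:
    """Write a dataset as a delimited table; round-trips with the reader."""
    path = Path(path)
    cols = METADATA_COLUMNS + _coordinate_columns(ds.k)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(cols)
        for c in ds:
            writer.writerow(
                [c.specimen_id, c.species, c.sex, c.site, c.user_id, c.replicate]
                + [f"{v:.17g}" for v in c.coords.ravel()]
            )


def attach_metadata(ds: LandmarkDataset, metadata: pd.DataFrame) -> LandmarkDataset:
    """Join sidecar metadata (exact match on specimen_id) onto a dataset."""
    if "specimen_id" not in metadata.columns:
        raise ValueError("metadata table must have a specimen_id column")
    meta = metadata.set_index(metadata["specimen_id"].astype(str))
    configs = []
    for c in ds:
        if c.specimen_id in meta.index:
            row = meta.loc[c.specimen_id]
            kwargs = {
                f: (int(row[f]) if f == "replicate" else str(row[f]))
                for f in METADATA_COLUMNS[1:]
                if f in meta.columns and not pd.isna(row[f])
            }
            configs.append(replace(c, **kwargs))
        else:
            configs.append(c)
    return LandmarkDataset(configs)


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationReport:
    duplicate_ids: list[str] = field(default_factory=list)
    small_groups: list[tuple[tuple[str, str], int]] = field(default_factory=list)
    degenerate_ids: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.duplicate_ids or self.small_groups or self.degenerate_ids)

    def problems(self) -> list[str]:
        out = [f"duplicate specimen_id: {s}" for s in self.duplicate_ids]
        out += [f"group {g} has only {n} specimens" for g, n in self.small_groups]
        out += [f"degenerate configuration: {s}" for s in self.degenerate_ids]
        return out


def _is_degenerate(coords: np.ndarray) -> bool:
    centered = coords - coords.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    # coincident: everything at one point; collinear: rank-1 geometry
    return sv[0] < 1e-12 or sv[1] < 1e-9 * sv[0]


def validate_dataset(ds: LandmarkDataset, min_per_group: int = 3) -> ValidationReport:
    """Report duplicate ids, undersized groups, and degenerate configurations.

    Report-only: the dataset is never modified; callers decide whether to
    escalate.  A specimen digitized in replicates shares its id across
    replicates, so duplication is judged on (specimen_id, replicate).
    """
    report = ValidationReport()
    seen: set[tuple[str, int]] = set()
    for c in ds:
        key = (c.specimen_id, c.replicate)
        if key in seen:
            report.duplicate_ids.append(c.specimen_id)
        seen.add(key)
        if _is_degenerate(c.coords):
            report.degenerate_ids.append(c.specimen_id)
    counts: dict[tuple[str, str], int] = {}
    for g in ds.group_labels:
        counts[g] = counts.get(g, 0) + 1
    for g, n in sorted(counts.items()):
        if n < min_per_group:
            report.small_groups.append((g, n))
    return report
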