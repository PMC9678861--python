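"""Feature-table containers and on-disk formats.

A whole-slide image (WSI) is represented here by a single real-valued
feature vector, typically the mean of patch-level deep features (MFV).
Every sample carries two categorical labels -- its primary diagnosis
(cancer subtype) and its source institution (the acquisition site whose
classifiability defines the bias indicator) -- plus a tumor-type grouping
and a train/validation/test split assignment.

On-disk contracts
-----------------
Delimited format: CSV, UTF-8, header mandatory. Reserved columns
``sample_id, diagnosis, site, tumor_type, split`` come first; every other
column is a feature, in file order.

Binary format: a single HDF5 file holding the feature matrix, parallel
label arrays and a JSON metadata block (format version, feature names,
free-text provenance). Bit-exact round trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

RESERVED_COLUMNS = ("sample_id", "diagnosis", "site", "tumor_type", "split")
SPLITS = ("train", "validation", "test")
BINARY_FORMAT_VERSION = 1


class FeatureTableError(ValueError):
    """Raised when a feature table violates its schema or invariants."""


@dataclass(frozen=True)
class PatchFeatureSet:
    """Patch-level deep features of one WSI: a P x D matrix."""

    wsi_id: str
    patches: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.patches, dtype=np.float64)
        if p.ndim != 2 or p.shape[0] < 1 or p.shape[1] < 1:
            raise FeatureTableError(
                f"patches of {self.wsi_id!r} must be a P x D matrix with P, D >= 1"
            )
        if not np.isfinite(p).all():
            raise FeatureTableError(f"non-finite patch feature in {self.wsi_id!r}")
        object.__setattr__(self, "patches", p)


@dataclass(frozen=True)
class MetadataRecord:
    """Slide-level metadata used for rare-group filtering."""

    morphology: str
    primary_diagnosis: str
    tissue_or_organ: str
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key in ("morphology", "primary_diagnosis", "tissue_or_organ"):
            if not getattr(self, key):
                raise FeatureTableError(f"metadata field {key!r} must be non-empty")

    @property
    def group_key(self) -> tuple[str, str, str]:
        return (self.morphology, self.primary_diagnosis, self.tissue_or_organ)


@dataclass(frozen=True)
class FeatureTable:
    """N samples x D features with diagnosis, site, tumor-type, split labels.

    ``X`` is always float64 internally regardless of on-disk width, so
    distance computations are platform-stable.
    """

    sample_ids: tuple[str, ...]
    X: np.ndarray
    diagnosis: tuple[str, ...]
    site: tuple[str, ...]
    tumor_type: tuple[str, ...]
    split: tuple[str, ...]
    feature_names: tuple[str, ...] = ()
    provenance: str = ""

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=np.float64)
        if X.ndim != 2:
            raise FeatureTableError("X must be a 2-D matrix")
        object.__setattr__(self, "X", X)
        n = X.shape[0]
        for name in ("sample_ids", "diagnosis", "site", "tumor_type", "split"):
            vals = tuple(str(v) for v in getattr(self, name))
            object.__setattr__(self, name, vals)
            if len(vals) != n:
                raise FeatureTableError(
                    f"{name} has {len(vals)} entries but X has {n} rows"
                )
        if len(set(self.sample_ids)) != n:
            dupes = {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
            raise FeatureTableError(f"duplicate sample ids: {sorted(dupes)[:5]}")
        if not np.isfinite(X).all():
            bad = np.argwhere(~np.isfinite(X))[0]
            raise FeatureTableError(
                f"non-finite feature value at row {bad[0]}, feature column {bad[1]}"
            )
        bad_splits = set(self.split) - set(SPLITS)
        if bad_splits:
            raise FeatureTableError(f"unknown split labels: {sorted(bad_splits)}")
        if not self.feature_names:
            object.__setattr__(
                self, "feature_names", tuple(f"f{j}" for j in range(X.shape[1]))
            )
        if len(self.feature_names) != X.shape[1]:
            raise FeatureTableError("feature_names length does not match D")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def rows(self, indices: Sequence[int]) -> "FeatureTable":
        """Row subset preserving all labels and feature columns."""
        idx = list(indices)
        return replace(
            self,
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            X=self.X[idx],
            diagnosis=tuple(self.diagnosis[i] for i in idx),
            site=tuple(self.site[i] for i in idx),
            tumor_type=tuple(self.tumor_type[i] for i in idx),
            split=tuple(self.split[i] for i in idx),
        )

    def split_indices(self, split: str) -> np.ndarray:
        if split not in SPLITS:
            raise FeatureTableError(f"unknown split {split!r}")
        return np.flatnonzero(np.asarray(self.split) == split)

    def with_split(self, split: Sequence[str]) -> "FeatureTable":
        return replace(self, split=tuple(split))


def aggregate_mfv(patchset: PatchFeatureSet) -> np.ndarray:
    """Mean of feature vectors (MFV): the per-WSI representation.

    Element j is the arithmetic mean of feature j over all patches;
    permutation-invariant in the patches.
    """
    return patchset.patches.mean(axis=0)


def filter_rare_groups(
    records: Sequence[MetadataRecord], min_count: int = 20
) -> list[MetadataRecord]:
    """Drop records whose (morphology, diagnosis, tissue) group has < min_count members.

    Order of surviving records is preserved; idempotent.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts: dict[tuple[str, str, str], int] = {}
    for r in records:
        counts[r.group_key] = counts.get(r.group_key, 0) + 1
    return [r for r in records if counts[r.group_key] >= min_count]


def subset_by_tumor_type(table: FeatureTable, tumor_type: str) -> FeatureTable:
    """Restrict rows to one tumor type; feature columns and splits untouched."""
    if tumor_type not in set(table.tumor_type):
        raise FeatureTableError(f"tumor type {tumor_type!r} not present in table")
    idx = [i for i, t in enumerate(table.tumor_type) if t == tumor_type]
    return table.rows(idx)


def split_dataset(
    table: FeatureTable,
    fractions: tuple[float, float, float],
    seed: int,
    stratify_on: str = "diagnosis",
) -> FeatureTable:
    """Assign train/validation/test splits, stratified per diagnosis.

    Counts per class are allocated by largest remainder so each split's
    per-class proportion is within one sample of its target. Deterministic
    for a fixed seed. Stratification is on diagnosis only -- never on site,
    which would artificially balance the confounder the method must face.
    """
    if stratify_on != "diagnosis":
        raise ValueError("only stratification on diagnosis is supported")
    fr = np.asarray(fractions, dtype=float)
    if fr.shape != (3,) or (fr < 0).any() or abs(fr.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be 3 nonnegative values summing to 1")
    n_splits_needed = int((fr > 0).sum())
    rng = np.random.default_rng(seed)
    new_split = [""] * table.n_samples
    diag = np.asarray(table.diagnosis)
    for cls in sorted(set(table.diagnosis)):
        idx = np.flatnonzero(diag == cls)
        if len(idx) < n_splits_needed:
            raise FeatureTableError(
                f"diagnosis {cls!r} has {len(idx)} samples, fewer than the "
                f"{n_splits_needed} non-empty splits"
            )
        rng.shuffle(idx)
        exact = fr * len(idx)
        counts = np.floor(exact).astype(int)
        remainder = exact - counts
        for _ in range(len(idx) - counts.sum()):
            j = int(np.argmax(remainder))
            counts[j] += 1
            remainder[j] = -1.0
        start = 0
        for split_name, c in zip(SPLITS, counts):
            for i in idx[start : start + c]:
                new_split[i] = split_name
            start += c
    return table.with_split(new_split)


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------


def write_feature_table(table: FeatureTable, path: str | Path, format: str = "delimited") -> None:
    """Write a table as CSV (``delimited``) or HDF5 (``binary``)."""
    path = Path(path)
    if format == "delimited":
        df = pd.DataFrame(
            {
                "sample_id": table.sample_ids,
                "diagnosis": table.diagnosis,
                "site": table.site,
                "tumor_type": table.tumor_type,
                "split": table.split,
            }
        )
        feats = pd.DataFrame(table.X, columns=list(table.feature_names))
        pd.concat([df, feats], axis=1).to_csv(path, index=False, float_format="%.17g")
    elif format == "binary":
        with h5py.File(path, "w") as f:
            f.create_dataset("X", data=table.X)
            str_dt = h5py.string_dtype(encoding="utf-8")
            for name in ("sample_ids", "diagnosis", "site", "tumor_type", "split"):
                f.create_dataset(name, data=list(getattr(table, name)), dtype=str_dt)
            f.attrs["format_version"] = BINARY_FORMAT_VERSION
            f.attrs["metadata"] = json.dumps(
                {
                    "feature_names": list(table.feature_names),
                    "provenance": table.provenance,
                }
            )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_feature_table(path: str | Path, format: str = "delimited") -> FeatureTable:
    """Read a table written by :func:`write_feature_table`.

    Raises a descriptive :class:`FeatureTableError` on a malformed header,
    a non-numeric feature cell, a duplicate sample id or a missing label
    column, naming the offending row or column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited":
        df = pd.read_csv(path, dtype={c: str for c in RESERVED_COLUMNS})
        missing = [c for c in RESERVED_COLUMNS if c not in df.columns]
        if missing:
            raise FeatureTableError(
                f"{path}: missing required label column(s) {missing}"
            )
        feature_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
        X = np.empty((len(df), len(feature_cols)), dtype=np.float64)
        for j, col in enumerate(feature_cols):
            try:
                X[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(np.float64)
            except (ValueError, TypeError) as exc:
                raise FeatureTableError(
                    f"{path}: non-numeric value in feature column {col!r}"
                ) from exc
        return FeatureTable(
            sample_ids=tuple(df["sample_id"]),
            X=X,
            diagnosis=tuple(df["diagnosis"]),
            site=tuple(df["site"]),
            tumor_type=tuple(df["tumor_type"]),
            split=tuple(df["split"]),
            feature_names=tuple(feature_cols),
        )
    elif format == "binary":
        with h5py.File(path, "r") as f:
            version = int(f.attrs.get("format_version", -1))
            if version != BINARY_FORMAT_VERSION:
                raise FeatureTableError(
                    f"{path}: unsupported binary format version {version}"
                )
            meta = json.loads(f.attrs["metadata"])
            decode = lambda ds: tuple(s.decode() if isinstance(s, bytes) else str(s) for s in ds[()])
            return FeatureTable(
                sample_ids=decode(f["sample_ids"]),
                X=f["X"][()],
                diagnosis=decode(f["diagnosis"]),
                site=decode(f["site"]),
                tumor_type=decode(f["tumor_type"]),
                split=decode(f["split"]),
                feature_names=tuple(meta.get("feature_names", ())),
                provenance=meta.get("provenance", ""),
            )
    else:
        raise ValueError(f"unknown format {format!r}")
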