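"""Shared domain types for structured medical-image hashing.

The label space of a dataset has three characteristic axes — imaging
*modality*, *organ*, and *disease* — with cardinalities ``lam`` (λ), ``mu``
(μ), ``nu`` (ν).  Only a subset of the λ·μ·ν conceivable triples occurs in
real archives (a brain is not imaged with breast ultrasound), so a
:class:`LabelSpace` carries an explicit set of valid combinations.

A structured hash code is the horizontal concatenation of three binary
sub-codes of lengths ``K1`` (modality), ``K2`` (organ), ``K3`` (disease),
in that fixed order.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

CHARACTERISTICS = ("modality", "organ", "disease")
SPLITS = ("train", "gallery", "query")


# ---------------------------------------------------------------------------
# Label space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelSpace:
    """Category names per characteristic plus the valid-combination set.

    Parameters
    ----------
    modalities, organs, diseases
        Category names; indices into these tuples are the canonical label
        encoding used everywhere else.
    valid_combinations
        Set of ``(modality, organ, disease)`` index triples that occur in
        the dataset.
    """

    modalities: tuple[str, ...]
    organs: tuple[str, ...]
    diseases: tuple[str, ...]
    valid_combinations: frozenset[tuple[int, int, int]]

    def __post_init__(self) -> None:
        if not self.valid_combinations:
            raise ValueError("valid_combinations must be non-empty")
        for m, o, d in self.valid_combinations:
            if not (0 <= m < self.lam and 0 <= o < self.mu and 0 <= d < self.nu):
                raise ValueError(f"combination {(m, o, d)} out of range")

    @property
    def lam(self) -> int:
        """Number of modalities (λ)."""
        return len(self.modalities)

    @property
    def mu(self) -> int:
        """Number of organs (μ)."""
        return len(self.organs)

    @property
    def nu(self) -> int:
        """Number of diseases (ν)."""
        return len(self.diseases)

    @property
    def cardinalities(self) -> tuple[int, int, int]:
        return (self.lam, self.mu, self.nu)

    def names_of(self, labels: "CharacteristicLabels") -> tuple[str, str, str]:
        return (
            self.modalities[labels.modality],
            self.organs[labels.organ],
            self.diseases[labels.disease],
        )

    def labels_from_names(self, modality: str, organ: str, disease: str) -> "CharacteristicLabels":
        try:
            triple = (
                self.modalities.index(modality),
                self.organs.index(organ),
                self.diseases.index(disease),
            )
        except ValueError as exc:
            raise ValueError(f"unknown category name: {exc}") from exc
        return CharacteristicLabels(*triple)

    def is_valid(self, labels: "CharacteristicLabels") -> bool:
        return labels.as_tuple() in self.valid_combinations

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "modalities": list(self.modalities),
            "organs": list(self.organs),
            "diseases": list(self.diseases),
            "valid_combinations": sorted(list(c) for c in self.valid_combinations),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LabelSpace":
        return cls(
            modalities=tuple(d["modalities"]),
            organs=tuple(d["organs"]),
            diseases=tuple(d["diseases"]),
            valid_combinations=frozenset(tuple(c) for c in d["valid_combinations"]),
        )

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "LabelSpace":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class CharacteristicLabels:
    """A (modality, organ, disease) category-index triple.

    Indices are the storage form; one-hot vectors are produced on demand.
    """

    modality: int
    organ: int
    disease: int

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.modality, self.organ, self.disease)

    def one_hot(self, characteristic: str, cardinality: int) -> np.ndarray:
        idx = getattr(self, characteristic)
        if not 0 <= idx < cardinality:
            raise ValueError(
                f"{characteristic} index {idx} out of range [0, {cardinality})"
            )
        v = np.zeros(cardinality, dtype=np.int64)
        v[idx] = 1
        return v


def pair_similarity(a: CharacteristicLabels, b: CharacteristicLabels) -> int:
    """Binary semantic similarity of an image pair.

    Returns 1 iff modality, organ and disease all agree, else 0.
    """
    return int(a.as_tuple() == b.as_tuple())


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

@dataclass
class Image:
    """A single-channel intensity image with values in [0, 1]."""

    pixels: np.ndarray
    id: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"expected a single-channel 2-D grid, got shape {px.shape}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError(f"image must be at least 8x8, got {px.shape}")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError("pixel intensities must lie in [0, 1]")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


# ---------------------------------------------------------------------------
# Code structure and codes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodeStructure:
    """Sub-code bit lengths (K1, K2, K3) for modality, organ, disease."""

    k1: int
    k2: int
    k3: int

    def __post_init__(self) -> None:
        for name, k in zip(("K1", "K2", "K3"), (self.k1, self.k2, self.k3)):
            if not (isinstance(k, (int, np.integer)) and k > 0):
                raise ValueError(f"{name} must be a positive integer, got {k!r}")

    @property
    def total(self) -> int:
        """Full code length K = K1 + K2 + K3."""
        return self.k1 + self.k2 + self.k3

    def slices(self) -> dict[str, slice]:
        """Index ranges of the three sub-codes within the full code."""
        return {
            "modality": slice(0, self.k1),
            "organ": slice(self.k1, self.k1 + self.k2),
            "disease": slice(self.k1 + self.k2, self.total),
        }

    def slice_for(self, characteristic: str) -> slice:
        try:
            return self.slices()[characteristic]
        except KeyError:
            raise ValueError(f"unknown characteristic {characteristic!r}") from None

    def lengths(self) -> tuple[int, int, int]:
        return (self.k1, self.k2, self.k3)


def validate_code_structure(lam: int, mu: int, nu: int, cs: CodeStructure) -> None:
    """Check the sub-code length constraints against class counts.

    Each sub-code must carry more bits than needed to enumerate its
    categories: ``K1 > ceil(log2 λ)``, ``K2 > ceil(log2 μ)``,
    ``K3 > ceil(log2 ν)``.  Raises :class:`ValueError` naming the offending
    sub-code.
    """
    for count, name in ((lam, "λ (modalities)"), (mu, "μ (organs)"), (nu, "ν (diseases)")):
        if count < 2:
            raise ValueError(f"need at least 2 categories for {name}, got {count}")
    bounds = (
        ("K1", cs.k1, lam, "modality"),
        ("K2", cs.k2, mu, "organ"),
        ("K3", cs.k3, nu, "disease"),
    )
    for kname, k, count, char in bounds:
        floor = math.ceil(math.log2(count))
        if not k > floor:
            raise ValueError(
                f"{kname}={k} ({char} sub-code) must be > ceil(log2({count})) = {floor}"
            )


@dataclass
class StructuredHashCode:
    """A binary code b ∈ {−1, +1}^K split as (modality, organ, disease) sub-codes."""

    bits: np.ndarray
    structure: CodeStructure

    def __post_init__(self) -> None:
        b = np.asarray(self.bits, dtype=np.int8).ravel()
        if b.size != self.structure.total:
            raise ValueError(
                f"code length {b.size} does not match structure K={self.structure.total}"
            )
        if not np.all(np.abs(b) == 1):
            raise ValueError("every bit must be exactly -1 or +1")
        self.bits = b

    def subcode(self, characteristic: str) -> np.ndarray:
        return self.bits[self.structure.slice_for(characteristic)]

    def to_string(self) -> str:
        """Render as a '+'/'-' string, one symbol per bit."""
        return "".join("+" if b > 0 else "-" for b in self.bits)

    @classmethod
    def from_string(cls, s: str, structure: CodeStructure) -> "StructuredHashCode":
        if set(s) - {"+", "-"}:
            raise ValueError("bit string may contain only '+' and '-'")
        bits = np.array([1 if c == "+" else -1 for c in s], dtype=np.int8)
        return cls(bits=bits, structure=structure)


@dataclass
class RelaxedHashCode:
    """A continuous code h ∈ [−1, 1]^K used during training (tanh relaxation)."""

    values: np.ndarray
    structure: CodeStructure

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64).ravel()
        if v.size != self.structure.total:
            raise ValueError(
                f"code length {v.size} does not match structure K={self.structure.total}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("relaxed code entries must be finite")
        if v.min() < -1.0 or v.max() > 1.0:
            raise ValueError("relaxed code entries must lie in [-1, 1]")
        self.values = v

    def subcode(self, characteristic: str) -> np.ndarray:
        return self.values[self.structure.slice_for(characteristic)]


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ["id", "path", "modality", "organ", "disease", "split"]


@dataclass
class DatasetManifest:
    """Image records with labels and train/gallery/query split membership.

    ``records`` is a DataFrame with columns ``id, path, modality, organ,
    disease, split``; labels are stored as human-readable category names and
    mapped through ``label_space``.
    """

    records: pd.DataFrame
    label_space: LabelSpace

    def __post_init__(self) -> None:
        missing = set(MANIFEST_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        self.records = self.records[MANIFEST_COLUMNS].reset_index(drop=True)

    def split(self, name: str) -> pd.DataFrame:
        if name not in SPLITS:
            raise ValueError(f"unknown split {name!r}")
        return self.records[self.records["split"] == name].reset_index(drop=True)

    @property
    def counts(self) -> tuple[int, int, int]:
        """(U1, U2, U3) = sizes of the train, gallery, query splits."""
        return tuple(int((self.records["split"] == s).sum()) for s in SPLITS)

    def labels_of(self, row: pd.Series) -> CharacteristicLabels:
        return self.label_space.labels_from_names(
            row["modality"], row["organ"], row["disease"]
        )

    def split_labels(self, name: str) -> list[CharacteristicLabels]:
        return [self.labels_of(row) for _, row in self.split(name).iterrows()]

    # -- I/O ---------------------------------------------------------------

    def save(self, csv_path: str | os.PathLike, label_space_path: str | os.PathLike) -> None:
        self.records.to_csv(csv_path, index=False)
        self.label_space.save(label_space_path)

    @classmethod
    def load(
        cls, csv_path: str | os.PathLike, label_space_path: str | os.PathLike
    ) -> "DatasetManifest":
        records = pd.read_csv(csv_path, dtype=str, comment="#")
        return cls(records=records, label_space=LabelSpace.load(label_space_path))


def validate_manifest(
    manifest: DatasetManifest, check_files: bool = True
) -> tuple[int, int, int]:
    """Validate split disjointness, label ranges and (optionally) file existence.

    Returns the per-split counts (U1, U2, U3) on success.
    """
    df = manifest.records
    bad_split = set(df["split"]) - set(SPLITS)
    if bad_split:
        raise ValueError(f"unknown split values: {sorted(bad_split)}")

    for s1, s2 in (("train", "gallery"), ("train", "query"), ("gallery", "query")):
        ids1 = set(df.loc[df["split"] == s1, "id"])
        ids2 = set(df.loc[df["split"] == s2, "id"])
        common = ids1 & ids2
        if common:
            raise ValueError(
                f"overlapping splits: ids {sorted(common)[:5]} appear in both "
                f"{s1} and {s2}"
            )
    if df["id"].duplicated().any():
        dupes = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate ids within a split: {dupes[:5]}")

    space = manifest.label_space
    for _, row in df.iterrows():
        labels = space.labels_from_names(row["modality"], row["organ"], row["disease"])
        if not space.is_valid(labels):
            raise ValueError(
                f"label out of range / invalid combination for id {row['id']}: "
                f"{(row['modality'], row['organ'], row['disease'])}"
            )

    if check_files:
        for _, row in df.iterrows():
            if not os.path.exists(row["path"]):
                raise FileNotFoundError(f"missing image file for id {row['id']}: {row['path']}")

    return manifest.counts
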