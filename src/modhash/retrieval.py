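"""Hamming-distance ranking of gallery codes against a query.

Case-I ranks by the full-code distance; Case-II by a single
characteristic's sub-code distance.  Distances are exact integer mismatch
counts (computed from the ±1 bit representation); ties are broken stably
by gallery insertion order, so rankings are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_types import CharacteristicLabels, CodeStructure, StructuredHashCode

MODES = ("full", "modality", "organ", "disease")


def hamming_distance(b1: StructuredHashCode, b2: StructuredHashCode) -> int:
    """Number of differing bit positions; integer in [0, K]."""
    if b1.structure != b2.structure:
        raise ValueError("codes have different structures")
    return int(np.count_nonzero(b1.bits != b2.bits))


@dataclass
class GalleryIndex:
    """Parallel arrays of gallery codes, labels and ids (one CodeStructure)."""

    codes: list[StructuredHashCode]
    labels: list[CharacteristicLabels]
    ids: list[str]

    def __post_init__(self) -> None:
        if not (len(self.codes) == len(self.labels) == len(self.ids)):
            raise ValueError("codes, labels and ids must be parallel arrays")
        if not self.codes:
            raise ValueError("gallery must be non-empty")
        self.structure: CodeStructure = self.codes[0].structure
        if any(c.structure != self.structure for c in self.codes):
            raise ValueError("all gallery codes must share one CodeStructure")
        # (U2, K) ±1 matrix for vectorized distance computation
        self._bits = np.stack([c.bits for c in self.codes]).astype(np.int32)

    def __len__(self) -> int:
        return len(self.codes)

    def distances(self, query: StructuredHashCode, mode: str = "full") -> np.ndarray:
        """Integer distances from `query` to every gallery item."""
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
        if query.structure != self.structure:
            raise ValueError("query code structure does not match gallery")
        if mode == "full":
            g = self._bits
            q = query.bits.astype(np.int32)
        else:
            sl = self.structure.slice_for(mode)
            g = self._bits[:, sl]
            q = query.bits[sl].astype(np.int32)
        k = g.shape[1]
        return (k - g @ q) // 2


@dataclass
class RetrievalResult:
    query_id: str
    ranked_ids: list[str]
    distances: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        d = np.asarray(self.distances)
        if np.any(np.diff(d) < 0):
            raise ValueError("distances must be non-decreasing")
        self.distances = d


def rank_gallery(query_code: StructuredHashCode, index: GalleryIndex,
                 p: int, mode: str = "full",
                 query_id: str = "query") -> RetrievalResult:
    """Top-p gallery items by ascending Hamming distance.

    ``mode="full"`` uses the whole code (Case-I); a characteristic name
    uses only that sub-code (Case-II).  Stable sort: at equal distance the
    earlier-inserted gallery item ranks first.
    """
    if p <= 0:
        raise ValueError("p must be positive")
    if p > len(index):
        raise ValueError(f"p={p} exceeds gallery size {len(index)}")
    dists = index.distances(query_code, mode=mode)
    order = np.argsort(dists, kind="stable")[:p]
    return RetrievalResult(
        query_id=query_id,
        ranked_ids=[index.ids[i] for i in order],
        distances=dists[order],
        mode=mode,
    )


def rank_order(query_code: StructuredHashCode, index: GalleryIndex,
               p: int, mode: str = "full") -> np.ndarray:
    """Indices (into the gallery) of the top-p ranked items."""
    dists = index.distances(query_code, mode=mode)
    return np.argsort(dists, kind="stable")[:p]
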