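"""Characteristic-specific retrieval metrics: mAP@p and nDCG@p.

Relevance is evaluated under a *characteristic spec* — a non-empty subset
of {modality, organ, disease}, giving seven cases M, O, D, MO, MD, OD,
MOD.  For mAP the relevance of a retrieved item is binary: 1 iff *all*
characteristics in the spec match the query.  For nDCG the gain is graded:
the number V of spec characteristics that match, scored as (2^V − 1)
with a log2(r + 1) position discount and normalized by the ideal
(descending-gain) ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_types import CharacteristicLabels, CHARACTERISTICS
from .retrieval import GalleryIndex, rank_order
from .core_types import StructuredHashCode

SPEC_NAMES = {
    "M": ("modality",),
    "O": ("organ",),
    "D": ("disease",),
    "MO": ("modality", "organ"),
    "MD": ("modality", "disease"),
    "OD": ("organ", "disease"),
    "MOD": ("modality", "organ", "disease"),
}


@dataclass(frozen=True)
class CharacteristicSpec:
    """A non-empty subset of the three characteristics."""

    required: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.required:
            raise ValueError("spec must require at least one characteristic")
        unknown = set(self.required) - set(CHARACTERISTICS)
        if unknown:
            raise ValueError(f"unknown characteristics: {sorted(unknown)}")
        # canonical order, no duplicates
        canon = tuple(c for c in CHARACTERISTICS if c in self.required)
        object.__setattr__(self, "required", canon)

    @classmethod
    def from_name(cls, name: str) -> "CharacteristicSpec":
        try:
            return cls(SPEC_NAMES[name.upper()])
        except KeyError:
            raise ValueError(f"unknown spec name {name!r}; expected one of "
                             f"{sorted(SPEC_NAMES)}") from None

    @property
    def name(self) -> str:
        initials = {"modality": "M", "organ": "O", "disease": "D"}
        return "".join(initials[c] for c in self.required)


def relevance_map(y_r: CharacteristicLabels, y_q: CharacteristicLabels,
                  spec: CharacteristicSpec) -> int:
    """Binary mAP relevance: 1 iff every spec characteristic matches."""
    return int(all(getattr(y_r, c) == getattr(y_q, c) for c in spec.required))


def relevance_ndcg(y_r: CharacteristicLabels, y_q: CharacteristicLabels,
                   spec: CharacteristicSpec) -> int:
    """Graded nDCG gain V = number of spec characteristics that match."""
    return sum(getattr(y_r, c) == getattr(y_q, c) for c in spec.required)


def average_precision_at_p(relevances: Sequence[int]) -> float:
    """AP over a binary relevance sequence of the top-p ranking.

    AP = Σ_r P(r)·R(r) / Σ_r R(r) with P(r) the precision of the top-r
    prefix; defined as 0 when no retrieved item is relevant (the 0/0 case).
    """
    rel = np.asarray(relevances, dtype=np.float64)
    if rel.size == 0:
        return 0.0
    if np.any((rel != 0) & (rel != 1)):
        raise ValueError("mAP relevances must be binary")
    n_rel = rel.sum()
    if n_rel == 0:
        return 0.0
    ranks = np.arange(1, rel.size + 1)
    precision = np.cumsum(rel) / ranks
    return float((precision * rel).sum() / n_rel)


def dcg_at_p(gains: Sequence[int]) -> float:
    """DCG = Σ_r (2^{V(r)} − 1) / log2(r + 1)."""
    g = np.asarray(gains, dtype=np.float64)
    if g.size == 0:
        return 0.0
    if np.any(g < 0):
        raise ValueError("gains must be non-negative")
    ranks = np.arange(1, g.size + 1)
    return float(((2.0 ** g - 1.0) / np.log2(ranks + 1)).sum())


def ndcg_at_p(gains: Sequence[int]) -> float:
    """DCG normalized by the ideal (descending) ordering's DCG.

    When the ideal DCG is 0 (no relevant item at all in the top-p), any
    ordering is ideal and the value is defined as 1.
    """
    g = np.asarray(gains, dtype=np.float64)
    ideal = dcg_at_p(np.sort(g)[::-1])
    if ideal == 0.0:
        return 1.0
    return dcg_at_p(g) / ideal


@dataclass
class EvaluationReport:
    """mAP@p and nDCG@p per characteristic spec, with per-query details."""

    map_at: dict[tuple[str, int], float]
    ndcg_at: dict[tuple[str, int], float]
    per_query_ap: dict[tuple[str, int], np.ndarray]
    per_query_ndcg: dict[tuple[str, int], np.ndarray]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (spec, p), v in sorted(self.map_at.items()):
            rows.append({"spec": spec, "p": p, "metric": "mAP", "value": v})
        for (spec, p), v in sorted(self.ndcg_at.items()):
            rows.append({"spec": spec, "p": p, "metric": "nDCG", "value": v})
        return pd.DataFrame(rows, columns=["spec", "p", "metric", "value"])

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def evaluate(
    query_codes: Sequence[StructuredHashCode],
    query_labels: Sequence[CharacteristicLabels],
    gallery: GalleryIndex,
    specs: Iterable[CharacteristicSpec | str] = tuple(SPEC_NAMES),
    p_list: Sequence[int] = (10,),
    mode: str = "full",
) -> EvaluationReport:
    """Mean AP@p and nDCG@p over the query set for each spec.

    Each query is ranked against the gallery once (at max(p_list)) in the
    requested mode; relevances are then scored per spec and cutoff.
    """
    if len(query_codes) == 0:
        raise ValueError("query set must be non-empty")
    if len(query_codes) != len(query_labels):
        raise ValueError("query codes and labels must be parallel")
    specs = [s if isinstance(s, CharacteristicSpec) else CharacteristicSpec.from_name(s)
             for s in specs]
    p_list = sorted(set(int(p) for p in p_list))
    if p_list[0] <= 0:
        raise ValueError("p values must be positive")
    p_max = min(p_list[-1], len(gallery))

    ap_acc: dict[tuple[str, int], list[float]] = {
        (s.name, p): [] for s in specs for p in p_list}
    ndcg_acc: dict[tuple[str, int], list[float]] = {
        (s.name, p): [] for s in specs for p in p_list}

    for code, y_q in zip(query_codes, query_labels):
        top = rank_order(code, gallery, p_max, mode=mode)
        ranked_labels = [gallery.labels[i] for i in top]
        for spec in specs:
            rel = np.array([relevance_map(y_r, y_q, spec) for y_r in ranked_labels])
            gains = np.array([relevance_ndcg(y_r, y_q, spec) for y_r in ranked_labels])
            for p in p_list:
                cut = min(p, p_max)
                ap_acc[(spec.name, p)].append(average_precision_at_p(rel[:cut]))
                ndcg_acc[(spec.name, p)].append(ndcg_at_p(gains[:cut]))

    return EvaluationReport(
        map_at={k: float(np.mean(v)) for k, v in ap_acc.items()},
        ndcg_at={k: float(np.mean(v)) for k, v in ndcg_acc.items()},
        per_query_ap={k: np.array(v) for k, v in ap_acc.items()},
        per_query_ndcg={k: np.array(v) for k, v in ndcg_acc.items()},
    )
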