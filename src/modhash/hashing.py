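"""Relaxation, binarization and structured concatenation of hash codes.

During training the network emits continuous code features ``z`` which are
squashed to ``h = tanh(z)`` in (−1, 1) so gradients flow; at encoding time
``b = sign(h)`` gives the binary code, with the tie ``sign(0) := +1`` so
encoding is deterministic.  Full codes are the concatenation of the
(modality, organ, disease) sub-codes, in that order.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import yaml

from .core_types import CodeStructure, RelaxedHashCode, StructuredHashCode


def relax(z: np.ndarray) -> np.ndarray:
    """Elementwise tanh of code features; rejects non-finite input."""
    z = np.asarray(z, dtype=np.float64)
    if not np.all(np.isfinite(z)):
        raise ValueError("code features must be finite")
    return np.tanh(z)


def binarize_bits(h: np.ndarray) -> np.ndarray:
    """Elementwise sign with sign(0) := +1; output in {-1, +1}."""
    h = np.asarray(h, dtype=np.float64)
    return np.where(h >= 0.0, 1, -1).astype(np.int8)


def binarize(h: RelaxedHashCode) -> StructuredHashCode:
    """Relaxed code -> binary structured code (idempotent on binary input)."""
    return StructuredHashCode(bits=binarize_bits(h.values), structure=h.structure)


def concat_codes(h1: np.ndarray, h2: np.ndarray, h3: np.ndarray,
                 structure: CodeStructure) -> np.ndarray:
    """Concatenate (modality, organ, disease) sub-codes into a full code."""
    parts = [np.asarray(p).ravel() for p in (h1, h2, h3)]
    for part, k, name in zip(parts, structure.lengths(), ("K1", "K2", "K3")):
        if part.size != k:
            raise ValueError(f"sub-code length {part.size} does not match {name}={k}")
    return np.concatenate(parts)


def subcode_slice(code: StructuredHashCode | RelaxedHashCode,
                  characteristic: str) -> np.ndarray:
    """The modality [0,K1), organ [K1,K1+K2) or disease [K1+K2,K) segment."""
    return code.subcode(characteristic)


# ---------------------------------------------------------------------------
# Hash-code store
# ---------------------------------------------------------------------------
# One CSV per split with header `id,bits` (bits as a '+'/'-' string) plus a
# sidecar YAML recording (K1, K2, K3); round-trips are bit-exact.

def save_codes(path: str | os.PathLike, ids: list[str],
               codes: list[StructuredHashCode]) -> None:
    if len(ids) != len(codes):
        raise ValueError("ids and codes must be parallel")
    if codes:
        structure = codes[0].structure
        if any(c.structure != structure for c in codes):
            raise ValueError("all codes in a store must share one CodeStructure")
    else:
        raise ValueError("refusing to write an empty code store")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("id,bits\n")
        for i, c in zip(ids, codes):
            fh.write(f"{i},{c.to_string()}\n")
    sidecar = path.with_suffix(path.suffix + ".structure.yml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump({"K1": structure.k1, "K2": structure.k2, "K3": structure.k3}, fh)


def load_codes(path: str | os.PathLike) -> tuple[list[str], list[StructuredHashCode]]:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".structure.yml")
    with open(sidecar) as fh:
        d = yaml.safe_load(fh)
    structure = CodeStructure(d["K1"], d["K2"], d["K3"])
    ids: list[str] = []
    codes: list[StructuredHashCode] = []
    with open(path) as fh:
        header = fh.readline().strip()
        if header != "id,bits":
            raise ValueError(f"unexpected code store header: {header!r}")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            img_id, bits = line.split(",", 1)
            ids.append(img_id)
            codes.append(StructuredHashCode.from_string(bits, structure))
    return ids, codes
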