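"""End-to-end training: batch sampling, pairwise similarity, loss
minimization with Adam + reduce-on-plateau scheduling, and dataset
encoding.

The combined objective is L = L1 + L2 + α·L3 over each mini-batch:
classification cross-entropy summed over samples, Cauchy cross-entropy
averaged over all unordered within-batch pairs, and the quantization
penalty summed over samples.  Ablation runs activate a subset of terms.

Training is fully seeded and single-threaded: the same configuration and
seed reproduce the final parameters bitwise.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._nn import Adam, ReduceLROnPlateau
from .core_types import (
    CharacteristicLabels,
    DatasetManifest,
    StructuredHashCode,
    pair_similarity,
)
from .hashing import binarize_bits, save_codes
from .losses import (
    LossConfig,
    batch_cauchy_loss,
    batch_classification_loss,
    batch_quantization_loss,
)
from .model import HEADS, MODHashModel, ModelConfig
from .synthetic import load_images


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults are the CPU desk-scale profile (batch 64); at full scale the
    reference settings are batch 256 and learning rate 1e-4.
    """

    model: ModelConfig
    loss: LossConfig = field(default_factory=LossConfig)
    batch_size: int = 64
    learning_rate: float = 1e-3
    scheduler_patience: int = 10
    scheduler_factor: float = 0.1
    max_epochs: int = 30
    seed: int = 0
    # saturation stop: no improvement of the best epoch loss by min_delta
    # for `saturation_patience` consecutive epochs
    early_stop_min_delta: float = 1e-4
    early_stop_patience: int = 25

    def __post_init__(self) -> None:
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (pairs must exist)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


def sample_pairs(labels: Sequence[CharacteristicLabels]
                 ) -> list[tuple[int, int, int]]:
    """All unordered within-batch pairs (i, j, s_ij) with i < j."""
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 samples to form pairs")
    return [
        (i, j, pair_similarity(labels[i], labels[j]))
        for i in range(n) for j in range(i + 1, n)
    ]


def similarity_matrix(labels: Sequence[CharacteristicLabels]) -> np.ndarray:
    """(B, B) ground-truth 0/1 similarity matrix (all characteristics equal)."""
    n = len(labels)
    s = np.zeros((n, n))
    for i, j, sij in sample_pairs(labels):
        s[i, j] = s[j, i] = sij
    np.fill_diagonal(s, 1.0)
    return s


def characteristic_similarity_matrix(
    labels: Sequence[CharacteristicLabels], characteristic: str
) -> np.ndarray:
    """(B, B) 0/1 matrix of single-characteristic label agreement."""
    vals = np.array([getattr(l, characteristic) for l in labels])
    return np.equal.outer(vals, vals).astype(np.float64)


@dataclass
class TrainResult:
    model: MODHashModel
    step_log: pd.DataFrame    # step, epoch, L1, L2, L3, L
    epoch_log: pd.DataFrame   # epoch, L1, L2, L3, L, lr


def train(manifest: DatasetManifest, cfg: TrainConfig,
          out_dir: str | os.PathLike | None = None,
          verbose: bool = False) -> TrainResult:
    """Train the hashing network on the manifest's train split.

    Writes ``loss_log.tsv`` (per step) and ``model.npz`` under ``out_dir``
    when given.  Aborts with a diagnostic if the loss becomes non-finite.
    """
    images, labels, _ids = load_images(manifest, "train")
    if len(images) == 0:
        raise ValueError("train split is empty")

    model = MODHashModel(cfg.model)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    sched = ReduceLROnPlateau(opt, patience=cfg.scheduler_patience,
                              factor=cfg.scheduler_factor)
    gamma = cfg.loss.resolve_gamma(cfg.model.code_structure.total)
    active = cfg.loss.loss_subset
    rng = np.random.default_rng(cfg.seed)

    step_rows = []
    epoch_rows = []
    best = np.inf
    stale = 0
    step = 0
    n = len(images)

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_terms = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            if idx.size < 2:
                continue  # a singleton batch has no pairs
            batch = images[idx]
            batch_labels = [labels[i] for i in idx]

            outputs, h = model.forward_all(batch)
            logits = {name: outputs[name][0] for name in HEADS}

            terms = {}
            total = None
            if "L1" in active:
                terms["L1"] = batch_classification_loss(logits, batch_labels)
                total = terms["L1"]
            if "L2" in active:
                s = similarity_matrix(batch_labels)
                l2 = batch_cauchy_loss(h, s, gamma)
                if cfg.loss.structured_pairs:
                    # score each sub-code's distance against its own
                    # characteristic's label match, so every sub-code
                    # carries exactly its characteristic's similarity
                    cs = cfg.model.code_structure
                    for char, k in zip(HEADS, cs.lengths()):
                        sk = characteristic_similarity_matrix(batch_labels, char)
                        sub_gamma = (cfg.loss.gamma if cfg.loss.gamma is not None
                                     else k / 4.0)
                        l2 = l2 + batch_cauchy_loss(
                            h[:, cs.slice_for(char)], sk, sub_gamma)
                terms["L2"] = l2
                total = terms["L2"] if total is None else total + terms["L2"]
            if "L3" in active:
                terms["L3"] = batch_quantization_loss(h)
                scaled = terms["L3"] * cfg.loss.alpha
                total = scaled if total is None else total + scaled
            if total is None:
                raise ValueError("loss_subset selected no loss terms")

            value = total.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}, step {step}: "
                    f"loss={value}; try a lower learning rate"
                )
            opt.zero_grad()
            total.backward()
            opt.step()

            row = {
                "step": step, "epoch": epoch,
                "L1": terms["L1"].item() if "L1" in terms else 0.0,
                "L2": terms["L2"].item() if "L2" in terms else 0.0,
                "L3": terms["L3"].item() if "L3" in terms else 0.0,
                "L": value,
            }
            step_rows.append(row)
            epoch_terms.append(row)
            step += 1

        mean = {k: float(np.mean([r[k] for r in epoch_terms]))
                for k in ("L1", "L2", "L3", "L")}
        epoch_rows.append({"epoch": epoch, **mean, "lr": opt.lr})
        if verbose:
            print(f"epoch {epoch:3d}  L={mean['L']:.4f}  L1={mean['L1']:.4f}  "
                  f"L2={mean['L2']:.4f}  L3={mean['L3']:.4f}  lr={opt.lr:g}")
        sched.step(mean["L"])

        if mean["L"] < best - cfg.early_stop_min_delta:
            best = mean["L"]
            stale = 0
        else:
            stale += 1
            if stale >= cfg.early_stop_patience:
                break

    step_log = pd.DataFrame(step_rows, columns=["step", "epoch", "L1", "L2", "L3", "L"])
    epoch_log = pd.DataFrame(epoch_rows, columns=["epoch", "L1", "L2", "L3", "L", "lr"])

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        step_log[["step", "L1", "L2", "L3", "L"]].to_csv(
            out / "loss_log.tsv", sep="\t", index=False)
        model.save(out / "model.npz")

    return TrainResult(model=model, step_log=step_log, epoch_log=epoch_log)


def encode_dataset(
    model: MODHashModel, manifest: DatasetManifest, split: str,
    out_path: str | os.PathLike | None = None, batch_size: int = 128,
) -> tuple[list[str], list[StructuredHashCode], list[CharacteristicLabels]]:
    """Map every image of a split to its binary structured hash code."""
    images, labels, ids = load_images(manifest, split)
    structure = model.cfg.code_structure
    codes: list[StructuredHashCode] = []
    for start in range(0, len(images), batch_size):
        h = model.relaxed_codes(images[start:start + batch_size])
        bits = binarize_bits(h)
        codes.extend(StructuredHashCode(bits=row, structure=structure) for row in bits)
    if out_path is not None:
        save_codes(out_path, ids, codes)
    return ids, codes, labels


def classification_accuracy(
    model: MODHashModel, manifest: DatasetManifest, split: str,
    batch_size: int = 128,
) -> dict[str, float]:
    """Per-characteristic argmax accuracy of the heads on a split."""
    images, labels, _ids = load_images(manifest, split)
    correct = {name: 0 for name in HEADS}
    for start in range(0, len(images), batch_size):
        chunk = slice(start, start + batch_size)
        logits = model.predict_logits(images[chunk])
        for name in HEADS:
            pred = logits[name].argmax(axis=1)
            truth = np.array([getattr(l, name) for l in labels[chunk]])
            correct[name] += int((pred == truth).sum())
    n = len(images)
    return {name: correct[name] / n for name in HEADS}
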