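"""Encoder and characteristic heads of the structured hashing network.

The encoder maps a single-channel image to a feature vector ``f``.  At
``scale="paper"`` it is the truncated-AlexNet stack (five convolutions,
three overlapping max-pools, one final Linear:1024); at ``scale="tiny"``
a reduced three-block stack suited to small images and CPU training.

Three identically shaped heads (modality, organ, disease) each apply
Linear:512 followed by two parallel linear maps: one producing class
logits (widths λ, μ, ν) and one producing the sub-code features
``z`` (widths K1, K2, K3).  Class count and sub-code length are
independent knobs.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._nn import Conv2d, Linear, Module, Tensor, concatenate, max_pool2d
from .core_types import CodeStructure, validate_code_structure

_SCALES = ("paper", "tiny")
HEADS = ("modality", "organ", "disease")


@dataclass
class ModelConfig:
    input_size: int
    lam: int
    mu: int
    nu: int
    code_structure: CodeStructure
    feature_dim: int = 1024
    scale: str = "paper"
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.scale not in _SCALES:
            raise ValueError(f"scale must be one of {_SCALES}, got {self.scale!r}")
        if self.feature_dim < max(self.code_structure.lengths()):
            raise ValueError("feature_dim must be >= max sub-code length")
        validate_code_structure(self.lam, self.mu, self.nu, self.code_structure)

    def to_dict(self) -> dict:
        return {
            "input_size": self.input_size,
            "lam": self.lam,
            "mu": self.mu,
            "nu": self.nu,
            "code_structure": list(self.code_structure.lengths()),
            "feature_dim": self.feature_dim,
            "scale": self.scale,
            "init_seed": self.init_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["code_structure"] = CodeStructure(*d["code_structure"])
        return cls(**d)


def _conv_out(size: int, kernel: int, stride: int, padding: int) -> int:
    out = (size + 2 * padding - kernel) // stride + 1
    if out <= 0:
        raise ValueError(f"feature map collapsed (size {size}, kernel {kernel})")
    return out


class _Encoder(Module):
    """Convolutional feature extractor ending in Linear(feature_dim)."""

    # (out_channels, kernel, stride, padding, relu_after, pool_kernel, pool_stride)
    _PAPER_PLAN = (
        (64, 11, 4, 2, True, 3, 2),
        (192, 5, 1, 2, True, 3, 2),
        (384, 3, 1, 1, True, 0, 0),
        (256, 3, 1, 1, True, 0, 0),
        (256, 3, 1, 1, False, 3, 2),
    )
    _TINY_PLAN = (
        (8, 3, 1, 1, True, 2, 2),
        (16, 3, 1, 1, True, 2, 2),
        (32, 3, 1, 1, True, 2, 2),
    )

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        plan = self._PAPER_PLAN if cfg.scale == "paper" else self._TINY_PLAN
        self.plan = plan
        self.convs: list[Conv2d] = []
        in_ch, size = 1, cfg.input_size
        for out_ch, k, s, p, _relu, pk, ps in plan:
            self.convs.append(Conv2d(in_ch, out_ch, k, s, p, rng))
            size = _conv_out(size, k, s, p)
            if pk:
                size = _conv_out(size, pk, ps, 0)
            in_ch = out_ch
        self.flat_dim = in_ch * size * size
        self.fc = Linear(self.flat_dim, cfg.feature_dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        for conv, (_oc, _k, _s, _p, relu, pk, ps) in zip(self.convs, self.plan):
            x = conv(x)
            if relu:
                x = x.relu()
            if pk:
                x = max_pool2d(x, pk, ps)
        x = x.reshape(x.shape[0], -1)
        return self.fc(x)


class _Head(Module):
    """Linear:512 (+ReLU) -> (Linear:classes, Linear:code_bits).

    The rectification after the 512-wide trunk makes the trunk a real
    representational bottleneck shared by the logits and the sub-code
    features — this is what lets each sub-code inherit its
    characteristic's structure from the classification signal.
    """

    def __init__(self, feature_dim: int, n_classes: int, code_bits: int,
                 rng: np.random.Generator):
        self.trunk = Linear(feature_dim, 512, rng)
        self.cls = Linear(512, n_classes, rng)
        self.code = Linear(512, code_bits, rng)

    def __call__(self, f: Tensor) -> tuple[Tensor, Tensor]:
        t = self.trunk(f).relu()
        return self.cls(t), self.code(t)


class MODHashModel(Module):
    """Encoder plus three characteristic heads.

    ``forward_all`` returns, for a batch of images, the three heads'
    (logits, code-feature) pairs and the concatenated tanh-relaxed code
    ``h`` of shape (batch, K1+K2+K3) in sub-code order
    (modality, organ, disease).
    """

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.init_seed)
        self.encoder = _Encoder(cfg, rng)
        cs = cfg.code_structure
        self.heads: list[_Head] = [
            _Head(cfg.feature_dim, cfg.lam, cs.k1, rng),
            _Head(cfg.feature_dim, cfg.mu, cs.k2, rng),
            _Head(cfg.feature_dim, cfg.nu, cs.k3, rng),
        ]

    # -- forward -----------------------------------------------------------

    def encode_features(self, images: np.ndarray | Tensor) -> Tensor:
        """Images (B, 1, H, W) -> features (B, feature_dim)."""
        x = Tensor.as_tensor(images)
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (B, 1, H, W) input, got {x.shape}")
        if x.shape[2] != self.cfg.input_size or x.shape[3] != self.cfg.input_size:
            raise ValueError(
                f"image size {x.shape[2:]} does not match configured "
                f"input_size {self.cfg.input_size}"
            )
        return self.encoder(x)

    def head_forward(self, f: Tensor, head: str) -> tuple[Tensor, Tensor]:
        """(logits, code features) of one characteristic head."""
        try:
            idx = HEADS.index(head)
        except ValueError:
            raise ValueError(f"unknown head {head!r}; expected one of {HEADS}") from None
        return self.heads[idx](f)

    def forward_all(self, images: np.ndarray | Tensor
                    ) -> tuple[dict[str, tuple[Tensor, Tensor]], Tensor]:
        """Full forward pass: per-head outputs and the relaxed code h."""
        f = self.encode_features(images)
        outputs = {name: self.heads[i](f) for i, name in enumerate(HEADS)}
        h = concatenate([outputs[name][1].tanh() for name in HEADS], axis=1)
        return outputs, h

    # -- inference conveniences --------------------------------------------

    def relaxed_codes(self, images: np.ndarray) -> np.ndarray:
        """(B, K) relaxed codes in [-1, 1], no gradient tracking."""
        _, h = self.forward_all(np.asarray(images, dtype=np.float64))
        return h.data

    def predict_logits(self, images: np.ndarray) -> dict[str, np.ndarray]:
        outputs, _ = self.forward_all(np.asarray(images, dtype=np.float64))
        return {name: logits.data for name, (logits, _z) in outputs.items()}

    # -- checkpointing -----------------------------------------------------

    def save(self, path: str | os.PathLike) -> None:
        params = self.parameters()
        arrays = {f"param_{i:04d}": p.data for i, p in enumerate(params)}
        np.savez(path, config=np.array(json.dumps(self.cfg.to_dict())), **arrays)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "MODHashModel":
        with np.load(path, allow_pickle=False) as archive:
            cfg = ModelConfig.from_dict(json.loads(str(archive["config"])))
            model = cls(cfg)
            params = model.parameters()
            for i, p in enumerate(params):
                stored = archive[f"param_{i:04d}"]
                if stored.shape != p.data.shape:
                    raise ValueError("checkpoint does not match model architecture")
                p.data = stored.astype(np.float64)
        return model


def tiny_config(lam: int = 5, mu: int = 4, nu: int = 13,
                code_structure: CodeStructure | None = None,
                input_size: int = 32, init_seed: int = 0) -> ModelConfig:
    """CPU-scale model configuration for 32-pixel synthetic images."""
    cs = code_structure or CodeStructure(8, 8, 8)
    return ModelConfig(
        input_size=input_size, lam=lam, mu=mu, nu=nu, code_structure=cs,
        feature_dim=128, scale="tiny", init_seed=init_seed,
    )
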