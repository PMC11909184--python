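"""Seeded synthetic grayscale datasets with three independent visual factors.

Real multi-source radiology archives couple three label axes: the *organ*
determines gross anatomy (shape), the imaging *modality* determines
acquisition appearance (background pattern, contrast curve, noise texture),
and the *disease* appears as a local pathology motif inside the organ.  The
renderer here mirrors that factorization so that each characteristic
carries an independent, learnable signal:

* organ   -> base shape (disc / rectangle / annulus / cross), centred;
* modality-> global appearance (background level and bands, gamma curve,
             noise texture scale);
* disease -> a class-constant local stamp overlaid inside the organ mask,
             with per-image position jitter.

Everything is deterministic given the configuration seed: identical seeds
yield bitwise-identical manifests and pixels.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image as PILImage

from .core_types import (
    CharacteristicLabels,
    DatasetManifest,
    Image,
    LabelSpace,
    MANIFEST_COLUMNS,
    SPLITS,
)

# -- default label space ----------------------------------------------------
# Five modalities, four organs, thirteen diseases, fifteen valid
# (modality, organ, disease) combinations.  "normal" is organ-specific
# (a normal chest X-ray and a normal breast ultrasound are distinct
# categories), which is what makes the disease count come out at thirteen.

_MODALITIES = ("MRI", "X-ray", "CT", "US", "OCT")
_ORGANS = ("brain", "chest", "breast", "retina")
_DISEASES = (
    "glioma", "meningioma", "pituitary",          # brain MRI
    "pneumonia", "covid", "normal_chest",          # chest X-ray / CT
    "benign", "malignant", "normal_breast",        # breast US
    "cnv", "dme", "drusen", "normal_retina",       # retina OCT
)

_VALID_COMBINATIONS = frozenset(
    [
        (0, 0, 0), (0, 0, 1), (0, 0, 2),           # MRI brain
        (1, 1, 3), (1, 1, 4), (1, 1, 5),           # X-ray chest
        (2, 1, 4), (2, 1, 5),                      # CT chest
        (3, 2, 6), (3, 2, 7), (3, 2, 8),           # US breast
        (4, 3, 9), (4, 3, 10), (4, 3, 11), (4, 3, 12),  # OCT retina
    ]
)


def default_label_space() -> LabelSpace:
    """The 5-modality / 4-organ / 13-disease space with 15 valid triples."""
    return LabelSpace(
        modalities=_MODALITIES,
        organs=_ORGANS,
        diseases=_DISEASES,
        valid_combinations=_VALID_COMBINATIONS,
    )


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic dataset.

    ``n_per_combination`` is the total number of images per valid triple,
    divided between splits according to ``split_fractions`` (largest-
    remainder rounding, stratified per combination).
    """

    label_space: LabelSpace = field(default_factory=default_label_space)
    image_size: int = 32
    n_per_combination: int = 133
    split_fractions: tuple[float, float, float] = (0.75, 0.15, 0.10)
    seed: int = 0
    noise_level: float = 0.05

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if any(f <= 0 for f in self.split_fractions):
            raise ValueError("split fractions must be positive")
        if self.image_size < 8:
            raise ValueError("image_size must be at least 8")
        used = {c[i] for c in self.label_space.valid_combinations for i in range(3)}
        for axis, card in enumerate(self.label_space.cardinalities):
            present = {c[axis] for c in self.label_space.valid_combinations}
            if present != set(range(card)):
                raise ValueError(
                    f"every category of axis {axis} must appear in at least one "
                    f"valid combination; missing {set(range(card)) - present}"
                )

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "label_space": self.label_space.to_dict(),
            "image_size": self.image_size,
            "n_per_combination": self.n_per_combination,
            "split_fractions": list(self.split_fractions),
            "seed": self.seed,
            "noise_level": self.noise_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "label_space" in d:
            d["label_space"] = LabelSpace.from_dict(d["label_space"])
        if "split_fractions" in d:
            d["split_fractions"] = tuple(d["split_fractions"])
        return cls(**d)

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "SyntheticConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_paperlike_config(seed: int = 0) -> SyntheticConfig:
    """Desk-scale dataset emulating the combined radiology archive structure:
    λ=5 modalities, μ=4 organs, ν=13 diseases, 15 valid combinations."""
    return SyntheticConfig(seed=seed)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

# per-modality appearance: (background level, organ fill level,
#                           band pattern, gamma, texture noise scale)
_MODALITY_STYLE = (
    {"bg": 0.10, "fg": 0.60, "bands": None, "gamma": 1.00, "tex": 0.5},
    {"bg": 0.30, "fg": 0.78, "bands": "horizontal", "gamma": 0.80, "tex": 1.0},
    {"bg": 0.05, "fg": 0.52, "bands": "vertical", "gamma": 1.30, "tex": 0.7},
    {"bg": 0.22, "fg": 0.68, "bands": None, "gamma": 1.00, "tex": 1.5},
    {"bg": 0.16, "fg": 0.72, "bands": "radial", "gamma": 0.90, "tex": 1.3},
)


def organ_mask(organ: int, size: int, seed: int) -> np.ndarray:
    """Boolean anatomy mask for one image.

    The mask depends only on (organ, size, seed) — never on modality or
    disease — so two renders differing only in disease share it exactly.
    """
    rng = np.random.default_rng([seed, 11, organ])
    scale = 1.0 + 0.08 * rng.uniform(-1, 1)
    cy = 0.05 * rng.uniform(-1, 1)
    cx = 0.05 * rng.uniform(-1, 1)
    lin = np.linspace(-1.0, 1.0, size)
    yy, xx = np.meshgrid(lin, lin, indexing="ij")
    yy = (yy - cy) / scale
    xx = (xx - cx) / scale
    rr = np.sqrt(yy ** 2 + xx ** 2)
    if organ == 0:          # disc
        return rr < 0.62
    if organ == 1:          # rectangle
        return (np.abs(xx) < 0.66) & (np.abs(yy) < 0.48)
    if organ == 2:          # annulus
        return (rr > 0.28) & (rr < 0.64)
    if organ == 3:          # cross
        return ((np.abs(xx) < 0.22) | (np.abs(yy) < 0.22)) & (rr < 0.85)
    raise ValueError(f"invalid organ index {organ}")


def _disease_stamp(disease: int, size: int) -> tuple[np.ndarray, float]:
    """Class-constant lesion motif: a coarse binary pattern and its
    intensity offset.  Deterministic in the disease index alone."""
    rng = np.random.default_rng([101, disease])
    grid = rng.random((5, 5)) < 0.5
    if not grid.any():
        grid[2, 2] = True
    stamp_px = max(2 * size // 5, 8)
    reps = int(np.ceil(stamp_px / 5))
    stamp = np.kron(grid, np.ones((reps, reps), dtype=bool))[:stamp_px, :stamp_px]
    sign = 1.0 if disease % 2 == 0 else -1.0
    delta = sign * (0.33 + 0.04 * (disease % 3))
    return stamp, delta


# nominal lesion anchor per organ, in the normalized [-1, 1] frame; snapped
# to the nearest organ-interior pixel so the motif always overlays tissue
_ORGAN_ANCHOR = ((0.0, 0.0), (0.0, 0.0), (0.46, 0.0), (0.0, 0.0))


def _anchor_pixel(mask: np.ndarray, organ: int) -> tuple[int, int]:
    size = mask.shape[0]
    ay, ax = _ORGAN_ANCHOR[organ]
    ty = (ay + 1.0) / 2.0 * (size - 1)
    tx = (ax + 1.0) / 2.0 * (size - 1)
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return size // 2, size // 2
    d2 = (ys - ty) ** 2 + (xs - tx) ** 2
    i = int(np.argmin(d2))
    return int(ys[i]), int(xs[i])


def render_image(modality: int, organ: int, disease: int,
                 size: int = 32, seed: int = 0,
                 noise_level: float = 0.05) -> Image:
    """Render one synthetic image; deterministic in all arguments.

    Raises :class:`ValueError` for out-of-range indices.
    """
    if not 0 <= modality < len(_MODALITY_STYLE):
        raise ValueError(f"invalid modality index {modality}")
    if not 0 <= organ < 4:
        raise ValueError(f"invalid organ index {organ}")
    if disease < 0:
        raise ValueError(f"invalid disease index {disease}")

    style = _MODALITY_STYLE[modality]
    lin = np.linspace(-1.0, 1.0, size)
    yy, xx = np.meshgrid(lin, lin, indexing="ij")

    img = np.full((size, size), style["bg"], dtype=np.float64)
    if style["bands"] == "horizontal":
        img += 0.08 * np.sin(2 * np.pi * 3 * yy)
    elif style["bands"] == "vertical":
        img += 0.08 * np.sin(2 * np.pi * 3 * xx)
    elif style["bands"] == "radial":
        img += 0.15 * (1.0 - np.sqrt(yy ** 2 + xx ** 2))

    mask = organ_mask(organ, size, seed)
    img[mask] = style["fg"]

    # local pathology motif, jittered but class-constant in shape; anchored
    # to an organ-interior point so it always overlays tissue
    stamp, delta = _disease_stamp(disease, size)
    jrng = np.random.default_rng([seed, 19, disease])
    jitter = 1
    cy, cx = _anchor_pixel(mask, organ)
    sy = cy - stamp.shape[0] // 2 + int(jrng.integers(-jitter, jitter + 1))
    sx = cx - stamp.shape[1] // 2 + int(jrng.integers(-jitter, jitter + 1))
    sy = int(np.clip(sy, 0, size - stamp.shape[0]))
    sx = int(np.clip(sx, 0, size - stamp.shape[1]))
    region = np.zeros_like(mask)
    region[sy:sy + stamp.shape[0], sx:sx + stamp.shape[1]] = stamp
    region &= mask
    img[region] += delta

    # modality contrast curve
    img = np.clip(img, 0.0, 1.0) ** style["gamma"]

    # modality-scaled texture + global additive noise, truncated to [0, 1]
    nrng = np.random.default_rng([seed, 23, modality, organ, disease])
    img += noise_level * style["tex"] * nrng.standard_normal((size, size))
    img = np.clip(img, 0.0, 1.0)

    return Image(pixels=img, id=f"m{modality}o{organ}d{disease}s{seed}")


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _split_counts(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Largest-remainder allocation of n images to (train, gallery, query)."""
    exact = [n * f for f in fractions]
    base = [int(np.floor(e)) for e in exact]
    remainder = n - sum(base)
    order = sorted(range(3), key=lambda i: (-(exact[i] - base[i]), i))
    for i in order[:remainder]:
        base[i] += 1
    return tuple(base)


def generate_dataset(cfg: SyntheticConfig, out_dir: str | os.PathLike) -> DatasetManifest:
    """Write PNG images plus manifest/label-space files; return the manifest.

    Splits are stratified per valid combination and pairwise disjoint.
    Fully reproducible from ``cfg.seed``.
    """
    out = Path(out_dir)
    images_dir = out / "images"
    images_dir.mkdir(parents=True, exist_ok=True)

    space = cfg.label_space
    combos = sorted(space.valid_combinations)
    counts = _split_counts(cfg.n_per_combination, cfg.split_fractions)

    ss = np.random.SeedSequence(cfg.seed)
    per_image_seeds = ss.generate_state(len(combos) * cfg.n_per_combination) & 0x7FFFFFFF

    rows = []
    k = 0
    for m, o, d in combos:
        split_of = []
        for split, c in zip(SPLITS, counts):
            split_of.extend([split] * c)
        for j, split in enumerate(split_of):
            img_seed = int(per_image_seeds[k])
            k += 1
            img = render_image(m, o, d, size=cfg.image_size, seed=img_seed,
                               noise_level=cfg.noise_level)
            img_id = f"m{m}o{o}d{d}_{j:04d}"
            rel = f"images/{img_id}.png"
            px8 = np.round(img.pixels * 255.0).astype(np.uint8)
            PILImage.fromarray(px8, mode="L").save(out / rel)
            rows.append(
                {
                    "id": img_id,
                    "path": str(out / rel),
                    "modality": space.modalities[m],
                    "organ": space.organs[o],
                    "disease": space.diseases[d],
                    "split": split,
                }
            )

    records = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest = DatasetManifest(records=records, label_space=space)

    csv_path = out / "manifest.csv"
    with open(csv_path, "w") as fh:
        fh.write("# split rule: stratified per (modality, organ, disease) combination\n")
        records.to_csv(fh, index=False)
    space.save(out / "label_space.yml")
    cfg.save(out / "synthetic_config.yml")
    return manifest


def load_images(manifest: DatasetManifest, split: str) -> tuple[np.ndarray, list[CharacteristicLabels], list[str]]:
    """Load one split as (N, 1, H, W) float64 pixels in [0,1], labels, ids."""
    df = manifest.split(split)
    pixels = []
    labels = []
    ids = []
    for _, row in df.iterrows():
        with PILImage.open(row["path"]) as im:
            px = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
        pixels.append(px[None])
        labels.append(manifest.labels_of(row))
        ids.append(row["id"])
    return np.stack(pixels), labels, ids
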