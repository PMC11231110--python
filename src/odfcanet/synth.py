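"""Synthetic chest-radiograph-like image generation, splitting and loading.

Three deterministic class recipes mimic the gross radiographic appearance of
the task's categories on a bright mediastinum background:

* ``normal`` — two dark elliptical lung fields with mild Gaussian noise;
* ``pneumonia`` — the normal anatomy plus one focal bright consolidation
  blob inside a lung field;
* ``covid`` — the normal anatomy plus several diffuse, low-contrast
  opacities in the peripheral lung zones (bilateral ground-glass pattern).

The recipes are intentionally easy to separate so that training-based checks
of the full pipeline are fast and robust; they are a stand-in for real CXR
data, not a radiological simulation.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

CLASS_NAMES = ("covid", "pneumonia", "normal")

__all__ = [
    "CLASS_NAMES",
    "SyntheticSpec",
    "SplitIndices",
    "render_image",
    "generate_dataset",
    "split_dataset",
    "load_and_preprocess",
    "load_image_folder",
]


@dataclass
class SyntheticSpec:
    """Generation parameters: counts, geometry jitter and noise level."""

    per_class: int = 50
    image_size: int = 224
    noise_sigma: float = 8.0
    background: float = 170.0
    lung_intensity: float = 60.0
    consolidation_boost: float = 100.0
    opacity_boost: float = 45.0
    seed: int = 0

    def __post_init__(self):
        if self.per_class < 1:
            raise ValueError(f"per_class must be >= 1, got {self.per_class}")
        if self.image_size < 32:
            raise ValueError(f"image_size must be >= 32, got {self.image_size}")


@dataclass
class SplitIndices:
    """Disjoint train/val/test index lists covering a dataset."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def __iter__(self):
        return iter((self.train, self.val, self.test))


def _lung_params(rng: np.random.Generator, size: int) -> dict:
    """Randomised ellipse geometry for the two lung fields."""
    s = size / 224.0
    jit = lambda scale: rng.normal(0, scale * s)
    return {
        "left_center": (112 * s + jit(3), 68 * s + jit(3)),
        "right_center": (112 * s + jit(3), 156 * s + jit(3)),
        "semi_axes": (62 * s + jit(3), 36 * s + jit(2)),
        "tilt": rng.normal(0, 0.06),
    }


def _ellipse_mask(size: int, center, semi, tilt: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy, cx = center
    a, b = semi
    y = (yy - cy) * np.cos(tilt) + (xx - cx) * np.sin(tilt)
    x = -(yy - cy) * np.sin(tilt) + (xx - cx) * np.cos(tilt)
    return (y / a) ** 2 + (x / b) ** 2 <= 1.0


def _gaussian_blob(size: int, center, sigma: float, amplitude: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy, cx = center
    return amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))


def render_image(label: str, spec: SyntheticSpec, rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Render one image; returns (uint8 image, lung-field mask, parameters)."""
    if label not in CLASS_NAMES:
        raise ValueError(f"unknown class {label!r}; expected one of {CLASS_NAMES}")
    size = spec.image_size
    geom = _lung_params(rng, size)
    left = _ellipse_mask(size, geom["left_center"], geom["semi_axes"], geom["tilt"])
    right = _ellipse_mask(size, geom["right_center"], geom["semi_axes"], -geom["tilt"])
    lungs = left | right
    img = np.full((size, size), spec.background, dtype=float)
    img[lungs] = spec.lung_intensity

    params = {"label": label, **{k: np.asarray(v).tolist() for k, v in geom.items()}}
    s = size / 224.0
    if label == "pneumonia":
        # one focal consolidation inside a randomly chosen lung field
        # sampled well inside the ellipse so the lung mask never clips it away
        side = "left_center" if rng.random() < 0.5 else "right_center"
        cy, cx = geom[side]
        a, b = geom["semi_axes"]
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.0, 0.45)
        cy += rad * a * np.sin(ang)
        cx += rad * b * np.cos(ang)
        sigma = (9 + 3 * rng.random()) * s
        img += _gaussian_blob(size, (cy, cx), sigma, spec.consolidation_boost) * lungs
        params["consolidation"] = {"center": [cy, cx], "sigma": sigma}
    elif label == "covid":
        # diffuse low-contrast opacities near the periphery of BOTH lung
        # fields (bilateral ground-glass pattern, unlike the unilateral
        # focal consolidation of the pneumonia recipe)
        blobs = []
        for side in ("left_center", "right_center"):
            for _ in range(int(rng.integers(2, 4))):
                cy, cx = geom[side]
                a, b = geom["semi_axes"]
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0.55, 0.95)
                by = cy + rad * a * np.sin(ang)
                bx = cx + rad * b * np.cos(ang)
                sigma = (13 + 5 * rng.random()) * s
                img += _gaussian_blob(size, (by, bx), sigma, spec.opacity_boost) * lungs
                blobs.append({"center": [by, bx], "sigma": sigma})
        params["opacities"] = blobs

    img += rng.normal(0, spec.noise_sigma, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, lungs, params


def generate_dataset(spec: SyntheticSpec, out_dir) -> Path:
    """Write a folder-per-class PNG dataset plus a CSV manifest.

    Deterministic given ``spec.seed``: the same spec written twice yields
    byte-identical files. Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for label in CLASS_NAMES:
        class_dir = out / label
        class_dir.mkdir(exist_ok=True)
        for i in range(spec.per_class):
            img, _, params = render_image(label, spec, rng)
            name = f"{label}_{i:04d}.png"
            Image.fromarray(img, mode="L").save(class_dir / name)
            rows.append({
                "path": f"{label}/{name}",
                "label": label,
                "seed": spec.seed,
                "params": json.dumps(params),
            })
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["path", "label", "seed", "params"])
        writer.writeheader()
        writer.writerows(rows)
    return manifest


def split_dataset(n_items: int, ratio: tuple[int, int, int] = (7, 2, 1),
                  seed: int = 0, labels=None) -> SplitIndices:
    """Shuffled train/val/test partition by largest-remainder apportionment.

    With ``labels`` given, the split is stratified: each class is apportioned
    separately, so per-split class proportions match the global ratio to
    within one item.
    """
    if any(r < 0 for r in ratio) or sum(ratio) <= 0:
        raise ValueError(f"degenerate ratio {ratio}")
    if n_items < sum(ratio):
        raise ValueError(f"need at least {sum(ratio)} items for ratio {ratio}, got {n_items}")
    rng = np.random.default_rng(seed)

    def apportion(n: int) -> list[int]:
        total = sum(ratio)
        quotas = [n * r / total for r in ratio]
        sizes = [int(q) for q in quotas]
        remainders = [q - s for q, s in zip(quotas, sizes)]
        for i in sorted(range(3), key=lambda i: -remainders[i])[: n - sum(sizes)]:
            sizes[i] += 1
        return sizes

    if labels is None:
        perm = rng.permutation(n_items)
        sizes = apportion(n_items)
        a, b = sizes[0], sizes[0] + sizes[1]
        return SplitIndices(np.sort(perm[:a]), np.sort(perm[a:b]), np.sort(perm[b:]))

    labels = np.asarray(labels)
    if len(labels) != n_items:
        raise ValueError(f"{n_items} items but {len(labels)} labels")
    parts: list[list[np.ndarray]] = [[], [], []]
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        sizes = apportion(len(idx))
        a, b = sizes[0], sizes[0] + sizes[1]
        parts[0].append(idx[:a])
        parts[1].append(idx[a:b])
        parts[2].append(idx[b:])
    return SplitIndices(*(np.sort(np.concatenate(p)) for p in parts))


def load_and_preprocess(path, size: int = 224, standardize: bool = False) -> np.ndarray:
    """Decode an image to a (3, size, size) float array in [0, 1].

    Grayscale conversion, bilinear resize, [0,1] scaling, channel
    replication; optional per-channel standardization to zero mean / unit
    variance.
    """
    try:
        with Image.open(path) as im:
            gray = im.convert("L")
            if gray.size != (size, size):
                gray = gray.resize((size, size), Image.BILINEAR)
            arr = np.asarray(gray, dtype=np.float64) / 255.0
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    out = np.repeat(arr[None, :, :], 3, axis=0)
    if standardize:
        mean = out.mean(axis=(1, 2), keepdims=True)
        std = out.std(axis=(1, 2), keepdims=True)
        out = (out - mean) / np.maximum(std, 1e-8)
    return out


def load_image_folder(root, size: int = 224, standardize: bool = False
                      ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Load a folder-per-class dataset into (images, labels, class_names).

    images: (N, 3, size, size) float64; labels: integer indices into the
    sorted class-name list.
    """
    root = Path(root)
    classes = sorted(d.name for d in root.iterdir() if d.is_dir())
    if not classes:
        raise OSError(f"no class folders under {root}")
    images, labels = [], []
    for ci, cls in enumerate(classes):
        for p in sorted((root / cls).glob("*.png")) + sorted((root / cls).glob("*.jpg")):
            images.append(load_and_preprocess(p, size=size, standardize=standardize))
            labels.append(ci)
    if not images:
        raise OSError(f"no images found under {root}")
    return np.stack(images), np.asarray(labels), classes
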