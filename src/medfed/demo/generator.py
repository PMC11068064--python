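"""Synthetic multi-site lesion-imaging generator.

Emulates the raw data a participating site would hold: 8-bit greyscale
images containing bright, roughly circular "lesions" on a darker
background, with per-site Gaussian acquisition noise, plus binary label
masks and a CSV case manifest.  The default configuration — 20 cases of
64×64 pixels, 1–3 lesions of radius 3–8, foreground level 0.9 vs
background 0.1, noise σ = 0.05 — keeps a clear intensity separation so a
simple threshold model is a meaningful reference, while the noise level
and per-site seed give sites realistically different intensity statistics.

A dataset is fully determined by its :class:`GeneratorConfig` (one seeded
generator consumed in case order → whole-dataset determinism; individual
cases are not reproducible independently of ``n_cases``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from ..errors import ValidationError


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one site's synthetic raw dataset."""

    n_cases: int = 20
    image_height: int = 64
    image_width: int = 64
    lesions_min: int = 1
    lesions_max: int = 3
    radius_min: int = 3
    radius_max: int = 8
    foreground_level: float = 0.9
    background_level: float = 0.1
    noise_sigma: float = 0.05
    site_id: str = "site"
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases <= 0:
            raise ValidationError("n_cases must be positive")
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValidationError("image dimensions must be positive")
        if not (0 <= self.lesions_min <= self.lesions_max):
            raise ValidationError("lesion count range invalid")
        if not (1 <= self.radius_min <= self.radius_max):
            raise ValidationError("lesion radius range invalid")
        for name in ("foreground_level", "background_level"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.foreground_level <= self.background_level:
            raise ValidationError("foreground_level must exceed background_level")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be non-negative")


def _disk_mask(h: int, w: int, row: int, col: int, radius: int) -> np.ndarray:
    rr, cc = np.ogrid[:h, :w]
    return (rr - row) ** 2 + (cc - col) ** 2 <= radius**2


def quantize(values: np.ndarray) -> np.ndarray:
    """Clip to [0, 1] and quantize to 8 bits (round-half-even, as numpy)."""
    return np.rint(np.clip(values, 0.0, 1.0) * 255.0).astype(np.uint8)


def synthesize_case(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """One (image, mask) pair as uint8 image and {0,1} mask arrays."""
    h, w = config.image_height, config.image_width
    mask = np.zeros((h, w), dtype=bool)
    n_lesions = int(rng.integers(config.lesions_min, config.lesions_max + 1))
    for _ in range(n_lesions):
        row = int(rng.integers(0, h))
        col = int(rng.integers(0, w))
        radius = int(rng.integers(config.radius_min, config.radius_max + 1))
        mask |= _disk_mask(h, w, row, col, radius)
    levels = np.where(mask, config.foreground_level, config.background_level)
    if config.noise_sigma > 0:
        levels = levels + rng.normal(0.0, config.noise_sigma, size=(h, w))
    return quantize(levels), mask.astype(np.uint8)


def generate_raw_dataset(config: GeneratorConfig, out_dir: Path | str) -> Path:
    """Write a raw site dataset: ``images/``, ``labels/``, ``manifest.csv``.

    ``out_dir`` must be empty or absent; the layout is byte-reproducible
    from the config (including the seed).
    """
    config.validate()
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        raise ValidationError(f"output directory {out_dir} is not empty")
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "labels").mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(config.seed)
    rows = []
    for k in range(config.n_cases):
        case_id = f"{config.site_id}_case_{k:04d}"
        image, mask = synthesize_case(config, rng)
        image_rel = f"images/{case_id}.png"
        label_rel = f"labels/{case_id}.png"
        Image.fromarray(image, mode="L").save(out_dir / image_rel)
        Image.fromarray(mask * np.uint8(255), mode="L").save(out_dir / label_rel)
        rows.append((case_id, image_rel, label_rel, config.site_id))

    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["case_id", "image_path", "label_path", "site_id"])
        writer.writerows(rows)
    return out_dir
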