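"""Synthetic nodule-box generator with controllable boundary morphology.

Real malignant nodules tend to show spiculated (spiky) boundaries while
benign ones are smoother; the generator emulates exactly this contrast.  A
nodule is a star-shaped solid whose per-slice boundary radius is

    r(theta, z) = R(z) * (1 + a * h(theta)),

with R(z) an ellipsoidal axial profile, h a unit-normalized sum of random
angular harmonics, and a the class-dependent spiculation amplitude (0.05
benign, 0.35 malignant by default).  Interior voxels are bright soft-tissue
gray (~200) and the exterior dark parenchyma (~40), with additive Gaussian
texture noise, mimicking lung-windowed CT contrast.  Everything is seeded:
the dataset manifest records one seed per sample, and regeneration from the
manifest is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import NoduleBox

LABELS = ("benign", "malignant")


@dataclass(frozen=True)
class SynthConfig:
    n_per_class: int = 10
    box_size: int = 32
    base_radius_range: tuple[float, float] = (6.0, 10.0)
    benign_amplitude: float = 0.05
    malignant_amplitude: float = 0.35
    spiculation_lobes: int = 6
    texture_noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        for a in (self.benign_amplitude, self.malignant_amplitude):
            if not (0 <= a < 1):
                raise ValueError("amplitudes must lie in [0, 1)")
        rmax = self.base_radius_range[1] * (1 + self.malignant_amplitude)
        if rmax >= self.box_size / 2 - 1:
            raise ValueError(
                f"max radius {rmax:.1f} does not fit in a "
                f"{self.box_size}-voxel box"
            )

    def amplitude(self, label: str) -> float:
        return (self.benign_amplitude if label == "benign"
                else self.malignant_amplitude)


def gen_nodule_volume(cfg: SynthConfig, label: str, seed: int) -> NoduleBox:
    """One seeded nodule box of the requested class."""
    if label not in LABELS:
        raise ValueError(f"label must be one of {LABELS}")
    rng = np.random.default_rng(seed)
    s = cfg.box_size
    cz = cy = cx = (s - 1) / 2.0

    r0 = rng.uniform(*cfg.base_radius_range)
    half_len = r0 * rng.uniform(1.0, 1.25)
    half_len = min(half_len, s / 2 - 1.5)
    amp = cfg.amplitude(label)

    # random angular harmonics, normalized so max |h| = 1
    freqs = rng.integers(3, 9, size=cfg.spiculation_lobes)
    phases = rng.uniform(0, 2 * np.pi, size=cfg.spiculation_lobes)
    weights = rng.uniform(0.5, 1.0, size=cfg.spiculation_lobes)
    theta_grid = np.linspace(0, 2 * np.pi, 720, endpoint=False)

    def h(theta):
        return np.sum(
            weights[:, None] * np.cos(np.multiply.outer(freqs, theta)
                                      + phases[:, None]),
            axis=0,
        )

    norm = np.abs(h(theta_grid)).max()
    if norm == 0:
        norm = 1.0

    yy, xx = np.mgrid[0:s, 0:s]
    dy = yy - cy
    dx = xx - cx
    # package angle convention: theta CCW from +col axis, y = -row
    theta = np.arctan2(-dy, dx)
    rho = np.hypot(dy, dx)
    h_theta = h(theta.ravel()).reshape(theta.shape) / norm

    gray = np.empty((s, s, s), dtype=np.float64)
    for z in range(s):
        u = (z - cz) / half_len
        rz = r0 * np.sqrt(max(0.0, 1.0 - u * u))
        inside = rho <= rz * (1.0 + amp * h_theta)
        slab = np.where(inside, 200.0, 40.0)
        slab = slab + rng.normal(0.0, cfg.texture_noise_sd, size=slab.shape)
        gray[z] = slab
    gray = np.clip(gray, 0.0, 255.0)
    return NoduleBox(gray=gray, spacing=(1.0, 1.0, 1.0), label=label,
                     center_voxel=(s // 2, s // 2, s // 2))


def gen_dataset(
    cfg: SynthConfig,
    imbalance: tuple[int, int] | None = None,
) -> tuple[list[NoduleBox], pd.DataFrame]:
    """A labeled dataset of nodule boxes plus its manifest.

    By default ``n_per_class`` boxes per label; ``imbalance=(n_benign,
    n_malignant)`` overrides the class counts (e.g. (616, 281) emulates the
    archive's class ratio).  The manifest records (sample_id, label, seed)
    and suffices to regenerate the dataset exactly.
    """
    if imbalance is not None:
        counts = {"benign": int(imbalance[0]), "malignant": int(imbalance[1])}
    else:
        counts = {lab: cfg.n_per_class for lab in LABELS}
    ss = np.random.SeedSequence(cfg.seed)
    seeds = [int(s) for s in
             ss.generate_state(sum(counts.values())) % (2 ** 31)]
    boxes: list[NoduleBox] = []
    rows = []
    i = 0
    for lab in LABELS:
        for _ in range(counts[lab]):
            boxes.append(gen_nodule_volume(cfg, lab, seeds[i]))
            rows.append({"sample_id": i, "label": lab, "seed": seeds[i]})
            i += 1
    manifest = pd.DataFrame(rows)
    return boxes, manifest


def regen_from_manifest(cfg: SynthConfig, manifest: pd.DataFrame) -> list[NoduleBox]:
    """Rebuild the exact dataset a manifest describes."""
    return [
        gen_nodule_volume(cfg, row.label, int(row.seed))
        for row in manifest.itertuples()
    ]
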