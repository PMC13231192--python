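"""Synthetic ultrasound-like cohorts with instance-level ground truth.

Real thyroid ultrasound cohorts carry only patient-level histopathology
labels, so nothing at desk scale can validate instance attention.  This
module plants the signal explicitly: every image is a speckle-textured
"nodule" (a bright ellipse on a darker background); malignant instances get
an irregular, Fourier-perturbed boundary plus a handful of punctate
high-intensity spots (a microcalcification proxy).  A patient's bag is
malignant iff it contains at least one malignant instance — the standard
multiple-instance assumption — and the generator records which instances
those are.

Nodule size, position and echogenicity are randomised identically for both
classes, so global image brightness is uninformative and the planted signal
lives in boundary shape and punctate texture; a pixel-mean classifier stays
near chance while a small CNN can learn the task.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from ._rng import stream
from .bags import Bag

__all__ = ["SynthConfig", "CohortRecord", "generate_instance", "generate_bag",
           "generate_cohort"]

_RAYLEIGH_MEAN = np.sqrt(np.pi / 2.0)  # mean of a unit-scale Rayleigh variate


@dataclass
class SynthConfig:
    """Study conditions for a synthetic cohort.

    ``witness_rate`` is the fraction of truly malignant instances inside a
    positive bag (at least one is always planted); ``speckle_scale`` blends
    between a noise-free render (0) and full multiplicative Rayleigh speckle
    (1); ``irregularity`` is the relative amplitude of the malignant boundary
    perturbation.
    """

    n_patients: int = 200
    prevalence: float = 0.5
    bag_size_range: tuple[int, int] = (3, 12)
    witness_rate: float = 0.3
    image_size: int = 64
    speckle_scale: float = 0.6
    irregularity: float = 0.18
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.bag_size_range[0] < 1 or self.bag_size_range[0] > self.bag_size_range[1]:
            raise ValueError("invalid bag_size_range")
        if not 0 < self.witness_rate <= 1:
            raise ValueError("witness_rate must be in (0, 1]")
        if self.speckle_scale < 0:
            raise ValueError("speckle_scale must be nonnegative")


@dataclass
class CohortRecord:
    """Generator bookkeeping for a written cohort."""

    out_dir: Path
    manifest_path: Path
    truth_path: Path
    patient_ids: list[str]
    labels: list[int]
    bag_sizes: list[int]
    instance_labels: dict[str, list[int]] = field(default_factory=dict)


def generate_instance(instance_class: int, config: SynthConfig,
                      rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Render one nodule image; returns (float image in [0,1], class).

    Benign (0): smooth-boundary bright ellipse over a darker background with
    multiplicative speckle.  Malignant (1): the ellipse boundary radius is
    modulated by a low-order random Fourier series and 3-8 punctate
    high-intensity spots are planted inside; same background and speckle
    model, so only shape and spots discriminate.
    """
    if instance_class not in (0, 1):
        raise ValueError("instance_class must be 0 or 1")
    s = config.image_size
    px_scale = s / 64.0

    background = rng.uniform(0.10, 0.18)
    brightness = rng.uniform(0.35, 0.55)
    cx, cy = (s / 2.0 + rng.uniform(-0.1 * s, 0.1 * s, size=2))
    rx = rng.uniform(0.16 * s, 0.30 * s)
    ry = rng.uniform(0.16 * s, 0.30 * s)
    tilt = rng.uniform(0.0, np.pi)

    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    dx, dy = xx - cx, yy - cy
    u = dx * np.cos(tilt) + dy * np.sin(tilt)
    v = -dx * np.sin(tilt) + dy * np.cos(tilt)
    rho = np.sqrt((u / rx) ** 2 + (v / ry) ** 2)
    theta = np.arctan2(v / ry, u / rx)

    edge = np.ones_like(rho)
    if instance_class == 1:
        for k in range(2, 6):
            amp = rng.uniform(-config.irregularity / 2.0, config.irregularity / 2.0)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            edge += amp * np.cos(k * theta + phase)

    # soft edge ~1.2 px wide in units of the mean radius
    r_mean = 0.5 * (rx + ry)
    interior = 1.0 / (1.0 + np.exp(-(edge - rho) * r_mean / 1.2))
    clean = background + (brightness - background) * interior

    if instance_class == 1:
        n_spots = int(rng.integers(3, 9))
        centers: list[tuple[float, float]] = []
        attempts = 0
        while len(centers) < n_spots and attempts < 200:
            attempts += 1
            ang = rng.uniform(0.0, 2.0 * np.pi)
            rad = rng.uniform(0.0, 0.65)
            su = rad * np.cos(ang) * rx
            sv = rad * np.sin(ang) * ry
            px = cx + su * np.cos(tilt) - sv * np.sin(tilt)
            py = cy + su * np.sin(tilt) + sv * np.cos(tilt)
            if all((px - qx) ** 2 + (py - qy) ** 2 >= (4.0 * px_scale) ** 2
                   for qx, qy in centers):
                centers.append((px, py))
        for px, py in centers:
            r_spot = rng.uniform(1.0, 2.0) * px_scale
            peak = rng.uniform(0.85, 0.95)
            d2 = (xx - px) ** 2 + (yy - py) ** 2
            clean = np.maximum(clean, peak * np.exp(-d2 / (2.0 * r_spot**2)))

    if config.speckle_scale > 0:
        # correlated speckle: smooth the Rayleigh multiplier over ~1-px
        # speckle cells, renormalised to unit mean
        mult = rng.rayleigh(scale=1.0, size=(s, s)) / _RAYLEIGH_MEAN
        mult = gaussian_filter(mult, sigma=1.0 * px_scale, mode="reflect")
        mult /= mult.mean()
        img = clean * (1.0 + config.speckle_scale * (mult - 1.0))
    else:
        img = clean
    return np.clip(img, 0.0, 1.0), instance_class


def generate_bag(bag_label: int, config: SynthConfig, rng: np.random.Generator,
                 patient_id: str = "P0000") -> tuple[Bag, list[np.ndarray]]:
    """Draw a bag: size uniform on ``bag_size_range``; positive bags contain
    exactly ``max(1, round(witness_rate * n))`` malignant instances.

    Returns the bag (instance paths are the file names a cohort writer would
    use) and the raw float images.
    """
    if bag_label not in (0, 1):
        raise ValueError("bag_label must be 0 or 1")
    n_min, n_max = config.bag_size_range
    n = int(rng.integers(n_min, n_max + 1))
    inst_labels = np.zeros(n, dtype=int)
    if bag_label == 1:
        n_pos = max(1, int(np.floor(config.witness_rate * n + 0.5)))
        pos_idx = rng.choice(n, size=min(n_pos, n), replace=False)
        inst_labels[pos_idx] = 1
    frames = []
    for j in range(n):
        img, _ = generate_instance(int(inst_labels[j]), config, rng)
        frames.append(img)
    bag = Bag(
        patient_id=patient_id,
        instances=[f"images/{patient_id}_{j:02d}.png" for j in range(n)],
        label=bag_label,
        instance_labels=[int(x) for x in inst_labels],
    )
    return bag, frames


def generate_cohort(config: SynthConfig, out_dir: str | Path,
                    overwrite: bool = False) -> CohortRecord:
    """Write a full cohort (images/, manifest.csv, truth.csv) to ``out_dir``.

    ``round(prevalence * n_patients)`` bags are positive; patient order and
    every image are reproducible bit-for-bit from ``config.seed``.
    """
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True")
    (out_dir / "images").mkdir(parents=True, exist_ok=True)

    rng = stream(config.seed, "cohort")
    n_pos = int(np.floor(config.prevalence * config.n_patients + 0.5))
    labels = np.zeros(config.n_patients, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)

    width = max(4, len(str(config.n_patients)))
    rows = []
    record = CohortRecord(out_dir=out_dir, manifest_path=manifest_path,
                          truth_path=out_dir / "truth.csv",
                          patient_ids=[], labels=[], bag_sizes=[])
    for i in range(config.n_patients):
        pid = f"P{i:0{width}d}"
        bag, frames = generate_bag(int(labels[i]), config, rng, patient_id=pid)
        for rel_path, frame, inst_label in zip(bag.instances, frames,
                                               bag.instance_labels):
            img8 = np.clip(np.round(frame * 255.0), 0, 255).astype(np.uint8)
            Image.fromarray(img8, mode="L").save(out_dir / rel_path)
            rows.append({"patient_id": pid, "image_path": rel_path,
                         "label": bag.label, "instance_label": inst_label})
        record.patient_ids.append(pid)
        record.labels.append(bag.label)
        record.bag_sizes.append(bag.n)
        record.instance_labels[pid] = list(bag.instance_labels)

    df = pd.DataFrame(rows)
    df.to_csv(manifest_path, index=False)
    df[["patient_id", "image_path", "instance_label"]].to_csv(
        record.truth_path, index=False)
    return record
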