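"""Patient-level bags of ultrasound images: loading, labelling, splitting, batching.

The unit of analysis is the *bag*: all images acquired for one patient,
carrying a single patient-level label (1 = malignant).  Weak supervision
means instance (per-image) labels are never used for training; the optional
``instance_label`` manifest column exists only so synthetic cohorts can carry
ground truth for attention evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from ._rng import stream, substream_seed

__all__ = [
    "Bag",
    "CohortSplit",
    "PaddedBatch",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "assign_patient_label",
    "load_manifest",
    "split_patients",
    "preprocess_image",
    "augment",
    "collate_batch",
    "load_bag_images",
]

# Channel statistics of the ImageNet training corpus, the de-facto standard
# normalisation for transfer-learning backbones.
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass
class Bag:
    """One patient's set of image instances with its patient-level label."""

    patient_id: str
    instances: list[str]
    label: int
    instance_labels: list[int] | None = None
    images: list[np.ndarray] | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.instances)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"bag {self.patient_id} has no instances")
        if self.label not in (0, 1):
            raise ValueError(f"bag {self.patient_id} label must be 0 or 1")
        if self.instance_labels is not None:
            if len(self.instance_labels) != self.n:
                raise ValueError(f"bag {self.patient_id}: instance label count mismatch")
            if self.label != max(self.instance_labels):
                raise ValueError(
                    f"bag {self.patient_id}: label must equal max of instance labels"
                )


@dataclass
class CohortSplit:
    """Patient-level held-out test set plus K disjoint cross-validation folds."""

    test_patients: set[str]
    folds: list[tuple[set[str], set[str]]]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "k": self.k,
            "counts": {
                "test": len(self.test_patients),
                "folds_val": [len(v) for _, v in self.folds],
            },
            "test": sorted(self.test_patients),
            "folds": [
                {"train": sorted(tr), "val": sorted(va)} for tr, va in self.folds
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSplit":
        payload = json.loads(Path(path).read_text())
        return cls(
            test_patients=set(payload["test"]),
            folds=[(set(f["train"]), set(f["val"])) for f in payload["folds"]],
            seed=int(payload["seed"]),
        )


@dataclass
class PaddedBatch:
    """Zero-padded rank-5 image block with a validity mask.

    ``images``: [B, n_max, 3, H, W]; ``mask``: [B, n_max] with 1 marking real
    instances (row sums equal true bag sizes); ``labels``: length-B 0/1.
    """

    images: np.ndarray
    mask: np.ndarray
    labels: np.ndarray
    patient_ids: list[str]


def assign_patient_label(nodule_diagnoses: list[int]) -> int:
    """Patient label from per-nodule diagnoses: malignant if any nodule is.

    The patient-level label is the most severe histopathological diagnosis
    among the patient's nodules, i.e. the OR of the binary diagnoses.
    """
    if len(nodule_diagnoses) == 0:
        raise ValueError("no diagnoses")
    if any(d not in (0, 1) for d in nodule_diagnoses):
        raise ValueError("diagnoses must be binary")
    return int(max(nodule_diagnoses))


def load_manifest(path: str | Path) -> list[Bag]:
    """Read a cohort manifest CSV into a deterministically ordered bag list.

    Required columns: ``patient_id``, ``image_path``, ``label``; optional
    ``instance_label``.  Image paths are resolved relative to the manifest's
    directory and must exist.  Bags are sorted by patient id; within a bag,
    instances keep manifest row order.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = {"patient_id", "image_path", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    base = path.parent
    bags = []
    for pid, group in df.groupby("patient_id", sort=True):
        labels = group["label"].unique()
        if len(labels) != 1:
            raise ValueError(f"conflicting labels for patient {pid}: {sorted(labels)}")
        paths = []
        for p in group["image_path"]:
            full = base / p
            if not full.is_file():
                raise FileNotFoundError(f"image not found: {full}")
            paths.append(str(full))
        inst = None
        if "instance_label" in group.columns and group["instance_label"].notna().all():
            inst = [int(v) for v in group["instance_label"]]
        bags.append(Bag(patient_id=str(pid), instances=paths,
                        label=int(labels[0]), instance_labels=inst))
    return bags


def split_patients(bags: list[Bag], test_frac: float = 0.1, k: int = 5,
                   seed: int = 0) -> CohortSplit:
    """Patient-level stratified 90/10-style split plus K-fold partition.

    ``round(test_frac * P)`` patients (ties rounded toward more test
    patients) form the held-out test set; the remainder is partitioned into
    ``k`` label-stratified folds whose validation sets are pairwise disjoint
    and together cover the train-val pool.  Fully reproducible from ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not 0 < test_frac < 1:
        raise ValueError("test_frac must be in (0, 1)")
    pids = np.array([b.patient_id for b in bags])
    if len(np.unique(pids)) != len(pids):
        raise ValueError("duplicate patient ids")
    labels = np.array([b.label for b in bags])
    p_total = len(bags)
    if p_total < k + 1:
        raise ValueError(f"need at least {k + 1} patients for a {k}-fold split")
    n_test = int(np.floor(test_frac * p_total + 0.5))
    n_test = max(1, n_test)

    sss = StratifiedShuffleSplit(n_splits=1, test_size=n_test,
                                 random_state=substream_seed(seed, "split/test"))
    (pool_idx, test_idx), = sss.split(pids, labels)
    test_patients = set(pids[test_idx])

    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=substream_seed(seed, "split/folds"))
    folds = []
    pool_pids, pool_labels = pids[pool_idx], labels[pool_idx]
    for tr_idx, va_idx in skf.split(pool_pids, pool_labels):
        folds.append((set(pool_pids[tr_idx]), set(pool_pids[va_idx])))
    return CohortSplit(test_patients=test_patients, folds=folds, seed=seed)


def preprocess_image(image, size: int = 256) -> np.ndarray:
    """Resize, replicate grayscale to 3 channels, standardise with ImageNet stats.

    Accepts an ``ndarray`` (H,W) or (H,W,3), with uint8 or float values, or a
    PIL image; returns float32 [3, size, size].  Grayscale inputs are
    channel-replicated so an ImageNet-style backbone and its normalisation
    statistics apply.
    """
    if isinstance(image, Image.Image):
        arr = np.asarray(image)
    else:
        arr = np.asarray(image)
    if arr.ndim not in (2, 3) or arr.size == 0 or min(arr.shape[:2]) == 0:
        raise ValueError(f"unreadable image of shape {arr.shape}")
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float32) / 255.0
    else:
        arr = arr.astype(np.float32)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.shape[2] == 1:
        arr = np.repeat(arr, 3, axis=2)
    elif arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.shape[:2] != (size, size):
        # bilinear resize per channel via PIL (float mode)
        resized = np.empty((size, size, 3), dtype=np.float32)
        for c in range(3):
            im = Image.fromarray(arr[:, :, c], mode="F")
            resized[:, :, c] = np.asarray(
                im.resize((size, size), resample=Image.BILINEAR)
            )
        arr = resized
    arr = (arr - IMAGENET_MEAN) / IMAGENET_STD
    return np.ascontiguousarray(arr.transpose(2, 0, 1))


def augment(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Training-time augmentation: horizontal flip (p=0.5) then a right-angle
    rotation drawn uniformly from {0, 90, 180, 270} degrees.

    ``image`` is a [C, H, W] array; the evaluation path applies neither
    transform.  Flip-then-rotate and rotate-then-flip generate the same
    dihedral group, so the order is a pure convention.
    """
    out = image
    if rng.random() < 0.5:
        out = out[:, :, ::-1]
    rot = int(rng.integers(0, 4))
    if rot:
        out = np.rot90(out, k=rot, axes=(1, 2))
    return np.ascontiguousarray(out)


def load_bag_images(bag: Bag, size: int = 256) -> Bag:
    """Read and preprocess a bag's image files into memory (idempotent)."""
    if bag.images is not None:
        return bag
    images = []
    for p in bag.instances:
        with Image.open(p) as im:
            images.append(preprocess_image(im, size=size))
    bag.images = images
    return bag


def collate_batch(bags: list[Bag]) -> PaddedBatch:
    """Zero-pad a list of loaded bags to the batch's maximum bag size."""
    if not bags:
        raise ValueError("empty batch")
    for b in bags:
        if b.images is None:
            raise ValueError(f"bag {b.patient_id} has no loaded images; "
                             "call load_bag_images first")
    n_max = max(b.n for b in bags)
    c, h, w = bags[0].images[0].shape
    images = np.zeros((len(bags), n_max, c, h, w), dtype=np.float32)
    mask = np.zeros((len(bags), n_max), dtype=np.float32)
    labels = np.zeros(len(bags), dtype=np.int64)
    for i, b in enumerate(bags):
        for j, img in enumerate(b.images):
            images[i, j] = img
        mask[i, : b.n] = 1.0
        labels[i] = b.label
    return PaddedBatch(images=images, mask=mask, labels=labels,
                       patient_ids=[b.patient_id for b in bags])


def _augment_stream(seed: int, epoch: int) -> np.random.Generator:
    """Per-epoch augmentation substream (reproducible regardless of order)."""
    return stream(seed, f"augment/epoch{epoch}")
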