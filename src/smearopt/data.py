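"""Image dataset handling: loading, merging, augmentation, split, metrics.

Datasets are folders with one subdirectory per class (``healthy/`` and
``all/`` by convention; ``all`` maps to the positive "diseased" label).
Two source sets can be merged into one hybrid bundle; the hybrid set is
enlarged six-fold by horizontal/vertical reflection and rotations by 90
and +/-45 degrees; images are resized bilinearly to the network input
size; and an 80/10/10 stratified split produces the train/validation/test
partitions.  Binary evaluation uses sensitivity (diseased recall),
specificity (healthy recall) and accuracy with diseased as the positive
class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize
from skimage.transform import rotate as _sk_rotate

__all__ = [
    "HEALTHY",
    "DISEASED",
    "TRANSFORMS",
    "LabeledImage",
    "DatasetBundle",
    "ConfusionCounts",
    "merge_datasets",
    "augment",
    "resize_images",
    "split_dataset",
    "confusion_counts",
    "sensitivity_specificity_accuracy",
    "load_image_folder",
    "write_image_folder",
    "bundle_to_arrays",
]

HEALTHY = "healthy"
DISEASED = "diseased"
TRANSFORMS = ("identity", "reflect_h", "reflect_v", "rot90", "rot45", "rot_neg45")

# folder name <-> label mapping for on-disk layouts
_FOLDER_TO_LABEL = {"healthy": HEALTHY, "all": DISEASED}
_LABEL_TO_FOLDER = {v: k for k, v in _FOLDER_TO_LABEL.items()}


@dataclass
class LabeledImage:
    """An RGB image with its class label and provenance."""

    pixels: np.ndarray  # (H, W, 3) uint8
    label: str  # HEALTHY | DISEASED
    source_id: str
    transform: str = "identity"

    def __post_init__(self) -> None:
        if self.label not in (HEALTHY, DISEASED):
            raise ValueError(f"unknown label {self.label!r}")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class DatasetBundle:
    """A list of labeled images, optionally partitioned."""

    images: list[LabeledImage]
    partitions: dict[str, list[int]] | None = None

    def __len__(self) -> int:
        return len(self.images)

    def class_counts(self) -> dict[str, int]:
        counts = {HEALTHY: 0, DISEASED: 0}
        for im in self.images:
            counts[im.label] += 1
        return counts

    def labels(self) -> np.ndarray:
        return np.array([im.label for im in self.images])


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix entries with diseased as positive."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def merge_datasets(set1: DatasetBundle, set2: DatasetBundle) -> DatasetBundle:
    """Concatenate two bundles into one hybrid set (provenance preserved)."""
    vocab1 = {im.label for im in set1.images}
    vocab2 = {im.label for im in set2.images}
    if vocab1 and vocab2 and not (vocab1 <= {HEALTHY, DISEASED} and vocab2 <= {HEALTHY, DISEASED}):
        raise ValueError("label vocabularies differ between bundles")
    return DatasetBundle(images=list(set1.images) + list(set2.images))


def _apply_transform(pixels: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return pixels
    if transform == "reflect_h":
        return np.ascontiguousarray(pixels[:, ::-1])
    if transform == "reflect_v":
        return np.ascontiguousarray(pixels[::-1, :])
    if transform == "rot90":
        return np.ascontiguousarray(np.rot90(pixels))
    if transform in ("rot45", "rot_neg45"):
        angle = 45.0 if transform == "rot45" else -45.0
        out = _sk_rotate(
            pixels.astype(np.float64) / 255.0,
            angle,
            resize=False,
            mode="reflect",
            order=1,
        )
        return (np.clip(out, 0.0, 1.0) * 255.0).round().astype(np.uint8)
    raise ValueError(f"unknown transform {transform!r}")


def augment(bundle: DatasetBundle) -> DatasetBundle:
    """Six-fold enlargement: identity + reflections + 90/+45/-45 rotations.

    Rotations by +/-45 degrees keep the original frame, filling exposed
    corners by border reflection; reflections and the 90-degree rotation
    are pixel-lossless.  Input images must carry the identity transform
    (augmenting twice is refused).
    """
    if not bundle.images:
        raise ValueError("cannot augment an empty bundle")
    out: list[LabeledImage] = []
    for im in bundle.images:
        if im.transform != "identity":
            raise ValueError(
                f"image {im.source_id!r} already transformed ({im.transform}); "
                "refusing to augment twice"
            )
        for t in TRANSFORMS:
            out.append(
                LabeledImage(
                    pixels=_apply_transform(im.pixels, t),
                    label=im.label,
                    source_id=im.source_id,
                    transform=t,
                )
            )
    return DatasetBundle(images=out)


def resize_images(bundle: DatasetBundle, height: int = 64, width: int = 64) -> DatasetBundle:
    """Bilinear resize of every image to (height, width); no-op sizes pass through."""
    if height < 1 or width < 1:
        raise ValueError("target dimensions must be positive")
    out = []
    for im in bundle.images:
        if im.pixels.shape[:2] == (height, width):
            out.append(replace(im))
            continue
        resized = _sk_resize(
            im.pixels.astype(np.float64),
            (height, width),
            order=1,
            anti_aliasing=False,
            preserve_range=True,
        )
        out.append(
            replace(im, pixels=np.clip(resized, 0, 255).round().astype(np.uint8))
        )
    return DatasetBundle(images=out, partitions=bundle.partitions)


def split_dataset(
    bundle: DatasetBundle,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    by_source: bool = False,
) -> DatasetBundle:
    """Stratified train/validation/test split by seeded permutation.

    Validation and test take ``floor(f_val * N)`` and ``floor(f_test * N)``
    images overall, apportioned across the classes by largest remainder so
    the split is stratified; the remainder trains.  With
    ``by_source=True`` whole source-image groups (all augmented variants
    of one original) are assigned together, preventing leakage across
    partitions.
    """
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError("fractions must sum to 1")
    _, f_val, f_test = fractions
    n = len(bundle)
    if n < 10:
        import warnings

        warnings.warn(
            f"only {n} images: partition sizes will be degenerate", stacklevel=2
        )
    rng = np.random.default_rng(seed)
    parts: dict[str, list[int]] = {"train": [], "val": [], "test": []}
    class_idx = {
        label: [i for i, im in enumerate(bundle.images) if im.label == label]
        for label in (HEALTHY, DISEASED)
    }
    class_idx = {k: v for k, v in class_idx.items() if v}
    if by_source:
        for label, idx in class_idx.items():
            sources = sorted({bundle.images[i].source_id for i in idx})
            order = rng.permutation(len(sources))
            n_val = int(f_val * len(sources))
            n_test = int(f_test * len(sources))
            val_src = {sources[i] for i in order[:n_val]}
            test_src = {sources[i] for i in order[n_val : n_val + n_test]}
            for i in idx:
                src = bundle.images[i].source_id
                key = "val" if src in val_src else "test" if src in test_src else "train"
                parts[key].append(i)
    else:
        sizes = [len(v) for v in class_idx.values()]
        val_quota = _apportion(int(f_val * n), sizes)
        test_quota = _apportion(int(f_test * n), sizes)
        for (label, idx), nv, nt in zip(class_idx.items(), val_quota, test_quota):
            order = rng.permutation(len(idx))
            parts["val"] += [idx[i] for i in order[:nv]]
            parts["test"] += [idx[i] for i in order[nv : nv + nt]]
            parts["train"] += [idx[i] for i in order[nv + nt :]]
    for key in parts:
        parts[key].sort()
    return DatasetBundle(images=bundle.images, partitions=parts)


def _apportion(total: int, sizes: list[int]) -> list[int]:
    """Split ``total`` across groups proportionally (largest remainder)."""
    n = sum(sizes)
    quotas = [total * s / n for s in sizes]
    counts = [int(q) for q in quotas]
    order = sorted(
        range(len(sizes)), key=lambda i: (quotas[i] - counts[i], sizes[i]),
        reverse=True,
    )
    for i in order[: total - sum(counts)]:
        counts[i] += 1
    return counts


def confusion_counts(predictions, labels) -> ConfusionCounts:
    """Tally the binary confusion matrix (diseased = positive class)."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    pos_pred = predictions == DISEASED
    pos_true = labels == DISEASED
    return ConfusionCounts(
        tp=int(np.sum(pos_pred & pos_true)),
        fp=int(np.sum(pos_pred & ~pos_true)),
        tn=int(np.sum(~pos_pred & ~pos_true)),
        fn=int(np.sum(~pos_pred & pos_true)),
    )


def sensitivity_specificity_accuracy(c: ConfusionCounts) -> tuple[float, float, float]:
    """SN = TP/(TP+FN), SP = TN/(TN+FP), AC = (TP+TN)/total.

    An undefined ratio (empty positive or negative class) is reported as
    NaN rather than silently zero.
    """
    sn = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else float("nan")
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else float("nan")
    ac = (c.tp + c.tn) / c.total if c.total > 0 else float("nan")
    return sn, sp, ac


# ---- disk I/O -------------------------------------------------------------


def load_image_folder(root, manifest: str | None = None) -> DatasetBundle:
    """Load a folder-per-class tree (``healthy/``, ``all/``) of RGB images.

    With ``manifest`` given, a CSV of (path, label, source_id) columns is
    read instead of inferring labels from folder membership.
    """
    root = Path(root)
    images: list[LabeledImage] = []
    if manifest is not None:
        df = pd.read_csv(root / manifest)
        for _, row in df.iterrows():
            pixels = _read_rgb(root / row["path"])
            images.append(
                LabeledImage(pixels, row["label"], str(row["source_id"]))
            )
        return DatasetBundle(images=images)
    for folder, label in _FOLDER_TO_LABEL.items():
        class_dir = root / folder
        if not class_dir.is_dir():
            continue
        for path in sorted(class_dir.iterdir()):
            if path.suffix.lower() not in (".png", ".jpg", ".jpeg", ".tif", ".tiff"):
                continue
            images.append(LabeledImage(_read_rgb(path), label, path.stem))
    if not images:
        raise FileNotFoundError(f"no class folders with images under {root}")
    return DatasetBundle(images=images)


def _read_rgb(path) -> np.ndarray:
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise OSError(f"could not read image {path}") from exc
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return np.ascontiguousarray(arr[..., :3]).astype(np.uint8)


def write_image_folder(bundle: DatasetBundle, root, manifest: str = "manifest.csv"):
    """Write PNGs into per-class folders plus a provenance manifest CSV."""
    root = Path(root)
    rows = []
    for i, im in enumerate(bundle.images):
        folder = _LABEL_TO_FOLDER[im.label]
        (root / folder).mkdir(parents=True, exist_ok=True)
        name = f"{im.source_id}_{im.transform}_{i:05d}.png"
        iio.imwrite(root / folder / name, im.pixels)
        partition = ""
        if bundle.partitions:
            for key, idxs in bundle.partitions.items():
                if i in idxs:
                    partition = key
                    break
        rows.append(
            {
                "path": f"{folder}/{name}",
                "label": im.label,
                "source_id": im.source_id,
                "transform": im.transform,
                "partition": partition,
            }
        )
    pd.DataFrame(rows).to_csv(root / manifest, index=False)


def bundle_to_arrays(
    bundle: DatasetBundle, partition: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stack images as (N, 3, H, W) float32 in [0, 1] with integer labels.

    Labels: healthy -> 0, diseased -> 1.
    """
    if partition is not None:
        if not bundle.partitions or partition not in bundle.partitions:
            raise KeyError(f"partition {partition!r} not present")
        images = [bundle.images[i] for i in bundle.partitions[partition]]
    else:
        images = bundle.images
    if not images:
        raise ValueError("empty partition")
    X = np.stack([im.pixels for im in images]).astype(np.float32) / 255.0
    X = X.transpose(0, 3, 1, 2)
    y = np.array([0 if im.label == HEALTHY else 1 for im in images], dtype=np.int64)
    return X, y
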