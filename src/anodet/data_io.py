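"""Image I/O, preprocessing, and the dataset-splitting protocol.

Images are square grayscale grids normalized to [-1, 1] (the range of the
generator's tanh output).  Normalization maps the format's full bit-depth
range onto [-1, 1] rather than per-image statistics, so that globally dark,
bright, or intensity-inverted images remain anomalous after preprocessing.

The splitting protocol trains on normal images only: 70% of the Normal
records (floor) are sampled for training, and the remaining records are
split 1:2 into validation and test, stratified within the Normal remainder
and within the pooled abnormal records (validation takes floor(group/3) of
each group).  Monte Carlo cross-validation repeats this with independent
derived seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import ContractViolationError, FormatError, InvalidSpecError, ShapeError

LABEL_NORMAL = "Normal"
LABEL_OPACITY = "Opacity"
LABEL_NOT_NORMAL = "NoOpacityNotNormal"
LABELS = (LABEL_NORMAL, LABEL_OPACITY, LABEL_NOT_NORMAL)

TRAIN_FRACTION = 0.7   # fraction of Normal records used for training
VAL_TEST_RATIO = 3     # validation takes floor(group / 3); test takes the rest


@dataclass
class ImageRecord:
    """One image: id, pixel grid in [-1, 1] (possibly unmaterialized), label."""

    id: str
    pixels: np.ndarray | None
    label: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.label not in LABELS:
            raise InvalidSpecError(f"unknown label {self.label!r}")


@dataclass
class Manifest:
    """Ordered collection of image records; the unit of dataset splitting."""

    records: list[ImageRecord]

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise InvalidSpecError("manifest ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def label_counts(self) -> dict[str, int]:
        counts = {label: 0 for label in LABELS}
        for r in self.records:
            counts[r.label] += 1
        return counts

    def by_id(self, record_id: str) -> ImageRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(record_id)

    def subset(self, ids) -> list[ImageRecord]:
        wanted = set(ids)
        return [r for r in self.records if r.id in wanted]

    def labels_by_id(self) -> dict[str, str]:
        return {r.id: r.label for r in self.records}

    def to_csv(self, path) -> None:
        rows = []
        for r in self.records:
            row = {"id": r.id, "label": r.label}
            for key in ("path", "anomaly_kind", "seed", "resolution",
                        "age", "sex", "view"):
                if key in r.metadata:
                    row[key] = r.metadata[key]
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)

    @staticmethod
    def from_csv(path) -> "Manifest":
        frame = pd.read_csv(path)
        records = []
        for _, row in frame.iterrows():
            meta = {k: row[k] for k in row.index
                    if k not in ("id", "label") and pd.notna(row[k])}
            records.append(ImageRecord(id=str(row["id"]), pixels=None,
                                       label=str(row["label"]), metadata=meta))
        return Manifest(records)


@dataclass
class SplitResult:
    """Disjoint train/validation/test id sets; train is Normal-only."""

    seed: int
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def to_json(self, path) -> None:
        payload = {"seed": int(self.seed), "train_ids": list(self.train_ids),
                   "val_ids": list(self.val_ids), "test_ids": list(self.test_ids)}
        Path(path).write_text(json.dumps(payload))

    @staticmethod
    def from_json(path) -> "SplitResult":
        payload = json.loads(Path(path).read_text())
        return SplitResult(seed=payload["seed"],
                           train_ids=tuple(payload["train_ids"]),
                           val_ids=tuple(payload["val_ids"]),
                           test_ids=tuple(payload["test_ids"]))


# ---------------------------------------------------------------------------
# image loading and preprocessing
# ---------------------------------------------------------------------------

def load_image(path) -> np.ndarray:
    """Load a grayscale PNG/TIFF (or DICOM) as a 2-D float array of raw intensities."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    if path.suffix.lower() in (".dcm", ".dicom"):
        try:
            import pydicom
        except ImportError as exc:  # pragma: no cover
            raise FormatError("DICOM support requires pydicom") from exc
        return np.asarray(pydicom.dcmread(path).pixel_array, dtype=np.float64)
    try:
        img = Image.open(path)
    except Exception as exc:
        raise FormatError(f"unreadable image file: {path}") from exc
    if img.mode in ("RGB", "RGBA", "P", "CMYK", "YCbCr"):
        raise FormatError(f"expected grayscale image, got mode {img.mode}: {path}")
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise FormatError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    return arr.astype(np.float64)


def resample_lanczos(pixels: np.ndarray, target: int) -> np.ndarray:
    """Resample a square grid to target x target with a Lanczos (a=3) kernel."""
    pixels = np.asarray(pixels, dtype=np.float32)
    if pixels.ndim != 2 or pixels.shape[0] != pixels.shape[1]:
        raise ShapeError(f"expected a square grid, got shape {pixels.shape}")
    if target < 1:
        raise ShapeError("target side must be >= 1")
    if pixels.shape[0] == target:
        return pixels.copy()
    img = Image.fromarray(pixels, mode="F")
    out = img.resize((target, target), Image.Resampling.LANCZOS)
    return np.asarray(out, dtype=np.float32)


def normalize_intensity(pixels: np.ndarray,
                        source_range: tuple[float, float] | None = None) -> np.ndarray:
    """Affinely map [source_min, source_max] onto [-1, 1].

    The source range comes from the image format's bit depth (inferred from an
    integer dtype when not given), never from per-image statistics.
    """
    pixels = np.asarray(pixels)
    if pixels.size == 0:
        raise ShapeError("empty pixel grid")
    if source_range is None:
        if not np.issubdtype(pixels.dtype, np.integer):
            raise InvalidSpecError(
                "source_range is required for non-integer pixel data")
        info = np.iinfo(pixels.dtype)
        source_range = (float(info.min), float(info.max))
    lo, hi = map(float, source_range)
    if hi <= lo:
        raise InvalidSpecError("source range must have max > min")
    return (pixels.astype(np.float64) - lo) / (hi - lo) * 2.0 - 1.0


def denormalize_to_uint16(pixels: np.ndarray) -> np.ndarray:
    """Inverse of normalize_intensity for writing 16-bit grayscale PNGs."""
    scaled = (np.clip(pixels, -1.0, 1.0) + 1.0) / 2.0 * 65535.0
    return np.round(scaled).astype(np.uint16)


# ---------------------------------------------------------------------------
# dataset splitting
# ---------------------------------------------------------------------------

def split_dataset(manifest: Manifest, seed: int) -> SplitResult:
    """Sample floor(70%) of Normal for training; split the rest 1:2 (val:test).

    The 1:2 split is stratified within the leftover Normal group and within
    the pooled abnormal group, validation taking floor(group/3) of each.
    """
    if len(manifest) == 0:
        raise InvalidSpecError("cannot split an empty manifest")
    rng = np.random.default_rng(seed)
    normal_ids = [r.id for r in manifest if r.label == LABEL_NORMAL]
    abnormal_ids = [r.id for r in manifest if r.label != LABEL_NORMAL]

    n_train = int(np.floor(TRAIN_FRACTION * len(normal_ids)))
    perm = rng.permutation(len(normal_ids))
    train = [normal_ids[i] for i in perm[:n_train]]
    rest_normal = [normal_ids[i] for i in perm[n_train:]]

    val: list[str] = []
    test: list[str] = []
    for group in (rest_normal, abnormal_ids):
        gperm = rng.permutation(len(group))
        n_val = len(group) // VAL_TEST_RATIO
        val.extend(group[i] for i in gperm[:n_val])
        test.extend(group[i] for i in gperm[n_val:])

    return SplitResult(seed=int(seed), train_ids=tuple(train),
                       val_ids=tuple(val), test_ids=tuple(test))


def monte_carlo_splits(manifest: Manifest, repeats: int,
                       master_seed: int) -> list[SplitResult]:
    """Independent random splits for Monte Carlo cross-validation."""
    if repeats < 1:
        raise InvalidSpecError("repeats must be >= 1")
    seeds = np.random.SeedSequence(master_seed).generate_state(repeats).tolist()
    if len(set(seeds)) != len(seeds):  # pragma: no cover - astronomically rare
        seeds = [int(s) + i for i, s in enumerate(seeds)]
    return [split_dataset(manifest, int(s)) for s in seeds]


def check_training_purity(records) -> None:
    """Raise unless every record is labeled Normal."""
    for r in records:
        if r.label != LABEL_NORMAL:
            raise ContractViolationError(
                f"abnormal record {r.id!r} (label {r.label}) in training set")
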