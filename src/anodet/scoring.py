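"""Per-image anomaly scores.

Two scores, both computed from a model trained on normal images only:

* reconstruction error: the pixelwise L1 norm ||x - Gen(Enc(x))||_1, an
  unnormalized sum over pixels.  Its per-pixel terms form an error map that
  localizes what the normal-only model could not reproduce.
* code norm: ||Enc(x)||_2, the Euclidean distance of the latent code from
  the origin.  Codes of normal images are trained toward a standard
  Gaussian, so unusually large norms flag out-of-distribution inputs.

Higher values mean more anomalous for both methods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ImageRecord
from .exceptions import ShapeError

METHOD_RECON = "reconstruction_error"
METHOD_CODE = "code_norm"
METHODS = (METHOD_RECON, METHOD_CODE)


@dataclass
class AnomalyScore:
    image_id: str
    method: str
    value: float
    error_map: np.ndarray | None = None


def _check_resolution(image: ImageRecord, model) -> np.ndarray:
    pixels = image.pixels
    if pixels is None:
        raise ShapeError(f"record {image.id!r} has no materialized pixels")
    res = model.current_resolution
    if pixels.shape != (res, res):
        raise ShapeError(
            f"record {image.id!r} has shape {pixels.shape}, "
            f"model resolution is {res}")
    return np.asarray(pixels, dtype=np.float32)


def reconstruction_error(image: ImageRecord, model) -> AnomalyScore:
    """L1 reconstruction error with its per-pixel error map."""
    pixels = _check_resolution(image, model)
    rec = model.reconstruct_images(pixels[None])[0]
    error_map = np.abs(pixels.astype(np.float64) - rec.astype(np.float64))
    return AnomalyScore(image_id=image.id, method=METHOD_RECON,
                        value=float(error_map.sum()), error_map=error_map)


def code_norm(image: ImageRecord, model) -> AnomalyScore:
    """Euclidean norm of the latent code."""
    pixels = _check_resolution(image, model)
    code = model.encode_images(pixels[None])[0]
    return AnomalyScore(image_id=image.id, method=METHOD_CODE,
                        value=float(np.linalg.norm(code.astype(np.float64))))


def score_manifest(records, model, method: str,
                   batch_size: int = 16) -> list[AnomalyScore]:
    """Score a collection of records, order-preserving, batched for throughput."""
    if method not in METHODS:
        raise ValueError(f"unknown scoring method {method!r}")
    records = list(records)
    scores: list[AnomalyScore] = []
    for start in range(0, len(records), batch_size):
        chunk = records[start:start + batch_size]
        batch = np.stack([_check_resolution(r, model) for r in chunk])
        if method == METHOD_CODE:
            codes = model.encode_images(batch).astype(np.float64)
            for r, c in zip(chunk, codes):
                scores.append(AnomalyScore(r.id, METHOD_CODE,
                                           float(np.linalg.norm(c))))
        else:
            recs = model.reconstruct_images(batch).astype(np.float64)
            for r, rec in zip(chunk, recs):
                emap = np.abs(r.pixels.astype(np.float64) - rec)
                scores.append(AnomalyScore(r.id, METHOD_RECON,
                                           float(emap.sum()), error_map=emap))
    return scores


def scores_to_frame(scores: list[AnomalyScore]) -> pd.DataFrame:
    return pd.DataFrame([{"image_id": s.image_id, "method": s.method,
                          "value": s.value} for s in scores])
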