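"""Per-slide stain calibration and morphometric fibrosis quantification.

The measurement implemented here — morphometric interstitial fibrosis, mIF
— is the percentage of an annotated cortical section whose pixels classify
as Sirius-Red-positive collagen.  Classification is a two-class Gaussian
model in a hue/saturation/value-derived color space, trained per slide
from operator-drawn reference patches of positive (red collagen) and
negative (counterstained tissue) regions on that same slide.  Because the
model is refit per slide from internal references, slides stained in
different batches — with different overall intensity or hue — remain
comparable: a global shift moves both reference classes and the decision
boundary with them.

The working color space embeds hue cyclically as
``(cos(2*pi*h) * s, sin(2*pi*h) * s, v)`` so that the red hue's wraparound
at 0/1 does not split the positive class, and so that desaturated pixels
(where hue is meaningless) collapse toward the origin of the chromatic
plane.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.color import rgb2hsv

from .errors import (
    CalibrationError,
    PreconditionError,
    QuantificationError,
)
from .image_io import (
    AnnotationSet,
    LabelMask,
    RasterImage,
    rasterize,
    read_annotations,
    read_image,
    extract_pixels,
)

#: Minimum reference pixels per class for a stable covariance estimate.
MIN_CALIBRATION_PIXELS = 100

#: Ridge added to covariance diagonals (channels are unit-scaled).
COVARIANCE_RIDGE = 1e-3


def rgb_to_features(rgb: np.ndarray) -> np.ndarray:
    """Map 8-bit RGB rows to the cyclic-hue working color space.

    Parameters
    ----------
    rgb:
        ``(N, 3)`` uint8 (or float in [0, 255]) array.

    Returns
    -------
    ``(N, 3)`` float array ``(cos(2*pi*h)*s, sin(2*pi*h)*s, v)`` with every
    channel in [-1, 1].
    """
    rgb = np.asarray(rgb, dtype=np.float64) / 255.0
    hsv = rgb2hsv(rgb.reshape(1, -1, 3)).reshape(-1, 3)
    h, s, v = hsv[:, 0], hsv[:, 1], hsv[:, 2]
    ang = 2.0 * np.pi * h
    return np.column_stack([np.cos(ang) * s, np.sin(ang) * s, v])


@dataclass
class StainCalibration:
    """Two-class Gaussian color model learned from reference patches."""

    pos_mean: np.ndarray
    neg_mean: np.ndarray
    pos_cov: np.ndarray
    neg_cov: np.ndarray
    n_pos_pixels: int
    n_neg_pixels: int
    slide_id: str = ""
    color_space: str = "hsv-cyclic"
    llr_offset: float = 0.0
    degenerate: bool = False

    def log_likelihood_ratio(self, features: np.ndarray) -> np.ndarray:
        """log N(x; pos) - log N(x; neg) for each feature row."""
        return _gaussian_logpdf(features, self.pos_mean, self.pos_cov) - (
            _gaussian_logpdf(features, self.neg_mean, self.neg_cov)
        )

    def classify(self, features: np.ndarray) -> np.ndarray:
        """Boolean positive/negative decision; ties break negative."""
        return self.log_likelihood_ratio(features) > self.llr_offset


def _gaussian_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    # cov is 3x3 and ridge-regularized, so Cholesky always succeeds
    chol = np.linalg.cholesky(cov)
    diff = x - mean
    sol = np.linalg.solve(chol, diff.T)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    d = x.shape[1]
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def fit_calibration(
    pos_pixels: np.ndarray,
    neg_pixels: np.ndarray,
    slide_id: str = "",
    min_calibration_pixels: int = MIN_CALIBRATION_PIXELS,
    ridge: float = COVARIANCE_RIDGE,
    llr_offset: float = 0.0,
) -> StainCalibration:
    """Fit the per-slide two-class color model from reference pixel samples.

    Each class gets a mean and a ridge-regularized covariance in the
    working color space.  After fitting, the training pixels themselves are
    classified: if either class fails to win a majority of its own training
    sample the calibration is flagged ``degenerate`` (classes inseparable)
    but still returned.

    Raises
    ------
    CalibrationError
        If either sample has fewer than ``min_calibration_pixels`` rows.
    """
    pos_pixels = np.atleast_2d(np.asarray(pos_pixels))
    neg_pixels = np.atleast_2d(np.asarray(neg_pixels))
    if len(pos_pixels) < min_calibration_pixels:
        raise CalibrationError(
            f"positive reference has {len(pos_pixels)} pixels; "
            f"need at least {min_calibration_pixels}"
        )
    if len(neg_pixels) < min_calibration_pixels:
        raise CalibrationError(
            f"negative reference has {len(neg_pixels)} pixels; "
            f"need at least {min_calibration_pixels}"
        )
    pos_f = rgb_to_features(pos_pixels)
    neg_f = rgb_to_features(neg_pixels)
    eye = np.eye(3)
    calib = StainCalibration(
        pos_mean=pos_f.mean(axis=0),
        neg_mean=neg_f.mean(axis=0),
        pos_cov=np.cov(pos_f, rowvar=False) + ridge * eye,
        neg_cov=np.cov(neg_f, rowvar=False) + ridge * eye,
        n_pos_pixels=len(pos_f),
        n_neg_pixels=len(neg_f),
        slide_id=slide_id,
        llr_offset=llr_offset,
    )
    pos_ok = calib.classify(pos_f).mean() > 0.5
    neg_ok = (~calib.classify(neg_f)).mean() > 0.5
    if not (pos_ok and neg_ok):
        calib.degenerate = True
    return calib


def calibration_from_annotations(
    image: RasterImage,
    annotations: AnnotationSet,
    llr_offset: float = 0.0,
) -> StainCalibration:
    """Convenience: harvest ref_positive/ref_negative patches and fit."""
    pos_polys = annotations.by_role("ref_positive")
    neg_polys = annotations.by_role("ref_negative")
    if not pos_polys or not neg_polys:
        raise CalibrationError(
            "calibration requires at least one ref_positive and one "
            "ref_negative polygon"
        )
    pos = extract_pixels(image, pos_polys)
    neg = extract_pixels(image, neg_polys)
    return fit_calibration(
        pos, neg, slide_id=annotations.slide_id or image.slide_id,
        llr_offset=llr_offset,
    )


@dataclass
class BackgroundPolicy:
    """How luminal white space enters the mIF denominator.

    ``entire_section`` (default) counts every cortical pixel — lumens and
    white space included — matching a denominator defined as the whole
    cortical surface.  ``tissue_only`` removes near-white low-saturation
    pixels from numerator candidates and denominator alike.
    """

    mode: str = "entire_section"
    saturation_min: float = 0.08
    value_max: float = 0.85

    def __post_init__(self) -> None:
        if self.mode not in ("entire_section", "tissue_only"):
            raise PreconditionError(
                f"unknown background policy mode {self.mode!r}"
            )
        for name in ("saturation_min", "value_max"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise PreconditionError(f"{name} must lie in [0, 1]")


@dataclass
class FibrosisResult:
    """Pixel bookkeeping and mIF percent for one slide."""

    slide_id: str
    n_cortex_px: int
    n_evaluated_px: int
    n_positive_px: int
    mif_percent: float
    policy: BackgroundPolicy
    calibration_id: str = ""
    degenerate_calibration: bool = False

    def to_dict(self) -> dict:
        d = {
            "slide_id": self.slide_id,
            "n_cortex_px": self.n_cortex_px,
            "n_evaluated_px": self.n_evaluated_px,
            "n_positive_px": self.n_positive_px,
            "mif_percent": self.mif_percent,
            "policy": {
                "mode": self.policy.mode,
                "saturation_min": self.policy.saturation_min,
                "value_max": self.policy.value_max,
            },
            "calibration_id": self.calibration_id,
        }
        if self.degenerate_calibration:
            d["degenerate_calibration"] = True
        return d


def classify_pixels(
    image: RasterImage, mask: LabelMask, calibration: StainCalibration
) -> np.ndarray:
    """Binary Sirius-Red-positive mask over the evaluation region.

    A pixel is positive iff its log-likelihood ratio (positive vs negative
    class) strictly exceeds ``calibration.llr_offset``; ties and all pixels
    outside ``mask`` are negative.
    """
    if mask.grid.shape != image.shape:
        raise PreconditionError(
            f"mask shape {mask.grid.shape} does not match image {image.shape}"
        )
    out = np.zeros(image.shape, dtype=bool)
    sel = mask.grid
    if not sel.any():
        return out
    feats = rgb_to_features(image.pixels[sel])
    out[sel] = calibration.classify(feats)
    return out


def detect_background(
    image: RasterImage, policy: BackgroundPolicy
) -> np.ndarray:
    """Near-white background mask (saturation below and value above cutoffs)."""
    rgb = image.pixels.astype(np.float64) / 255.0
    hsv = rgb2hsv(rgb)
    return (hsv[:, :, 1] < policy.saturation_min) & (
        hsv[:, :, 2] > policy.value_max
    )


def compute_mif(
    image: RasterImage,
    annotations: AnnotationSet,
    calibration: StainCalibration,
    policy: BackgroundPolicy | None = None,
) -> FibrosisResult:
    """Quantify one slide: percent Sirius-Red-positive cortical area.

    The evaluation mask is the rasterized cortex minus exclusions.  Under
    ``entire_section`` the denominator is every evaluated cortical pixel;
    under ``tissue_only`` background pixels are removed from numerator and
    denominator alike.
    """
    if policy is None:
        policy = BackgroundPolicy()
    h, w = image.shape
    mask = rasterize(annotations, h, w)
    n_cortex = mask.n_set
    if n_cortex == 0:
        raise QuantificationError("evaluation mask is empty")
    eval_grid = mask.grid
    if policy.mode == "tissue_only":
        eval_grid = eval_grid & ~detect_background(image, policy)
        if not eval_grid.any():
            raise QuantificationError(
                "no evaluated pixels remain after background removal"
            )
    positive = classify_pixels(
        image, LabelMask(grid=eval_grid), calibration
    )
    n_eval = int(eval_grid.sum())
    n_pos = int(positive.sum())
    return FibrosisResult(
        slide_id=annotations.slide_id or image.slide_id,
        n_cortex_px=n_cortex,
        n_evaluated_px=n_eval,
        n_positive_px=n_pos,
        mif_percent=100.0 * n_pos / n_eval,
        policy=policy,
        calibration_id=calibration.slide_id,
        degenerate_calibration=calibration.degenerate,
    )


@dataclass
class ManifestEntry:
    """One row of a batch manifest."""

    slide_id: str
    image_path: str
    annotation_path: str
    adequate: bool = True
    adequacy_reason: str = ""


@dataclass
class BatchResult:
    """Quantified slides plus exclusions for one batch run."""

    results: list[FibrosisResult] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)
    rater_id: str = ""


def read_manifest(path: str | Path) -> list[ManifestEntry]:
    """Load a manifest CSV (slide_id, image_path, annotation_path, adequate,
    adequacy_reason)."""
    entries = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            entries.append(
                ManifestEntry(
                    slide_id=row["slide_id"],
                    image_path=row["image_path"],
                    annotation_path=row["annotation_path"],
                    adequate=str(row.get("adequate", "1")).strip() in ("1", "true", "True"),
                    adequacy_reason=row.get("adequacy_reason", "") or "",
                )
            )
    return entries


def batch_quantify(
    manifest: Sequence[ManifestEntry],
    policy: BackgroundPolicy | None = None,
    rater_id: str = "",
    fail_fast: bool = False,
    llr_offset: float = 0.0,
) -> BatchResult:
    """Quantify a batch of slides, routing failures to the exclusion list.

    Slides flagged inadequate in the manifest (the adequacy rule — fewer
    than 7 glomeruli and/or no artery — is applied upstream by the
    pathologist, not computed here) go straight to ``excluded`` with their
    stated reason.  Per-slide errors are captured as exclusions rather than
    raised, unless ``fail_fast`` is set.
    """
    batch = BatchResult(rater_id=rater_id)
    for entry in manifest:
        if not entry.adequate:
            batch.excluded.append(
                (entry.slide_id, entry.adequacy_reason or "inadequate specimen")
            )
            continue
        try:
            image = read_image(entry.image_path)
            annotations = read_annotations(entry.annotation_path)
            if not annotations.slide_id:
                annotations.slide_id = entry.slide_id
            calib = calibration_from_annotations(
                image, annotations, llr_offset=llr_offset
            )
            result = compute_mif(image, annotations, calib, policy)
            result.slide_id = entry.slide_id
            batch.results.append(result)
        except Exception as exc:
            if fail_fast:
                raise
            batch.excluded.append((entry.slide_id, f"read-error: {exc}"))
    return batch


def write_result_json(result: FibrosisResult, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)


def write_batch_csv(batch: BatchResult, path: str | Path) -> None:
    """Write a batch as CSV, one row per quantified or excluded slide."""
    cols = [
        "slide_id", "rater_id", "n_cortex_px", "n_evaluated_px",
        "n_positive_px", "mif_percent", "excluded_reason",
    ]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for res in batch.results:
            writer.writerow(
                {
                    "slide_id": res.slide_id,
                    "rater_id": batch.rater_id,
                    "n_cortex_px": res.n_cortex_px,
                    "n_evaluated_px": res.n_evaluated_px,
                    "n_positive_px": res.n_positive_px,
                    "mif_percent": f"{res.mif_percent:.4f}",
                    "excluded_reason": "",
                }
            )
        for slide_id, reason in batch.excluded:
            writer.writerow(
                {"slide_id": slide_id, "rater_id": batch.rater_id,
                 "excluded_reason": reason}
            )
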