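"""Synthetic Sirius-Red renal-cortex slides with known ground truth.

Real picrosirius-red slides of transplant biopsies cannot be redistributed,
so the quantification pipeline is exercised end to end on procedurally
rendered cortex images whose fibrosis fraction is known exactly.  A
generated slide contains:

* a cortical region bounded by a polygon (the rest of the canvas is
  unstained background, as outside the tissue section);
* tubule cross-sections — counterstained epithelial rings around white
  lumens — and glomerular discs, placed without mutual overlap;
* interstitial collagen painted where a seeded Gaussian-smoothed noise
  field is highest, thresholded so the realized positive fraction of the
  evaluation region matches the requested ``fibrosis_fraction`` to within
  0.002 (the threshold is the exact order statistic of the field over the
  paintable interstitium, which is at least as tight as iterative
  bisection would be);
* per-class colors plus Gaussian pixel noise, then a global batch
  transform (intensity gain and hue rotation) emulating slide-to-slide
  staining variation between Sirius-Red batches;
* auto-generated annotations: the cortex polygon, exclusion circles over
  glomeruli, and reference patches — the largest axis-aligned rectangles
  wholly inside pure positive / pure negative truth regions (capped at
  40x40 px) — standing in for the operator's hand-drawn internal controls.

Truth masks are recorded from the geometry, before noise, so classifier
output can be scored against them pixel by pixel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb, rgb2hsv

from .errors import GenerationError, PreconditionError
from .image_io import (
    AnnotationSet,
    RasterImage,
    RoiPolygon,
    rasterize,
    write_annotations,
    write_image,
)

_REF_PATCH_CAP = 40  # max side of an auto-drawn reference patch, px
_MIN_REF_SIDE = 10   # below this the patch cannot reach 100 calibration px


@dataclass
class SynthConfig:
    """Parameters of one synthetic slide.

    ``fibrosis_fraction`` is the target positive fraction of the
    *evaluation region* (cortex minus glomerular exclusions).  Colors are
    generator parameters approximating bright-field picrosirius red:
    collagen red, pale yellow-tan counterstain, near-white lumens and
    background; they make no claim about any particular scanner or stain
    lot.  ``batch_gain`` and ``batch_hue_shift_deg`` emulate staining-batch
    variation; the internal calibration patches see the same transform, as
    they would on a real slide.
    """

    height: int = 192
    width: int = 192
    fibrosis_fraction: float = 0.15
    n_tubules: int = 40
    n_glomeruli: int = 3
    stain_pos_rgb: tuple[int, int, int] = (190, 45, 45)
    stain_neg_rgb: tuple[int, int, int] = (235, 215, 170)
    background_rgb: tuple[int, int, int] = (250, 250, 250)
    batch_gain: float = 1.0
    batch_hue_shift_deg: float = 0.0
    noise_sd: float = 4.0
    field_smoothness: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 64 or self.width < 64:
            raise PreconditionError("canvas must be at least 64x64")
        if not 0.0 <= self.fibrosis_fraction <= 1.0:
            raise PreconditionError("fibrosis_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise PreconditionError("noise_sd must be non-negative")
        if self.field_smoothness <= 0:
            raise PreconditionError("field_smoothness must be positive")
        if self.n_tubules < 0 or self.n_glomeruli < 0:
            raise PreconditionError("structure counts must be non-negative")


@dataclass
class SynthSlide:
    """A rendered slide with its ground truth and auto-annotations."""

    image: RasterImage
    truth_fibrosis_mask: np.ndarray
    truth_cortex_mask: np.ndarray
    truth_glomeruli_mask: np.ndarray
    truth_background_mask: np.ndarray
    annotations: AnnotationSet
    realized_fraction: float
    config: SynthConfig = field(repr=False, default=None)


def _circle_polygon(cx: float, cy: float, r: float, n: int = 24) -> list[tuple[float, float]]:
    ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return [(cx + r * np.cos(a), cy + r * np.sin(a)) for a in ang]


def _disc_mask(h: int, w: int, cx: float, cy: float, rx: float, ry: float) -> np.ndarray:
    ys, xs = np.ogrid[:h, :w]
    return ((xs + 0.5 - cx) / rx) ** 2 + ((ys + 0.5 - cy) / ry) ** 2 <= 1.0


def _largest_rectangle(mask: np.ndarray) -> tuple[int, int, int, int] | None:
    """Largest all-true axis-aligned rectangle as (r0, c0, height, width).

    Classic maximal-rectangle-in-histogram sweep, O(H*W).
    """
    h, w = mask.shape
    heights = np.zeros(w, dtype=int)
    best = (0, 0, 0, 0)
    best_area = 0
    for r in range(h):
        heights = np.where(mask[r], heights + 1, 0)
        # monotonic stack over the histogram
        stack: list[int] = []
        for c in range(w + 1):
            cur = heights[c] if c < w else 0
            while stack and heights[stack[-1]] >= cur:
                top = stack.pop()
                rect_h = heights[top]
                left = stack[-1] + 1 if stack else 0
                rect_w = c - left
                area = rect_h * rect_w
                if area > best_area:
                    best_area = area
                    best = (r - rect_h + 1, left, rect_h, rect_w)
            stack.append(c)
    if best_area == 0:
        return None
    return best


def _clip_rect(rect: tuple[int, int, int, int], cap: int) -> tuple[int, int, int, int]:
    r0, c0, rh, rw = rect
    if rh > cap:
        r0 += (rh - cap) // 2
        rh = cap
    if rw > cap:
        c0 += (rw - cap) // 2
        rw = cap
    return r0, c0, rh, rw


def _rect_polygon(rect: tuple[int, int, int, int], role: str, label: str) -> RoiPolygon:
    r0, c0, rh, rw = rect
    return RoiPolygon(
        vertices=[(c0, r0), (c0 + rw, r0), (c0 + rw, r0 + rh), (c0, r0 + rh)],
        role=role,
        label=label,
    )


def _best_clear_window(
    paintable: np.ndarray, field_noise: np.ndarray, side: int
) -> tuple[int, int] | None:
    """Top-left corner of the side x side all-paintable window with the
    highest mean field value, or None if no clear window exists."""
    h, w = paintable.shape
    if h < side or w < side:
        return None
    ones = np.lib.stride_tricks.sliding_window_view(
        paintable.astype(np.int32), (side, side)
    ).sum(axis=(2, 3))
    clear = ones == side * side
    if not clear.any():
        return None
    score = np.lib.stride_tricks.sliding_window_view(
        field_noise, (side, side)
    ).sum(axis=(2, 3))
    score = np.where(clear, score, -np.inf)
    flat = int(np.argmax(score))
    return flat // score.shape[1], flat % score.shape[1]


def generate_slide(config: SynthConfig) -> SynthSlide:
    """Render one synthetic slide; identical config => bit-identical output.

    Raises :class:`GenerationError` when the paintable interstitium cannot
    hold the requested fibrosis fraction (too many tubules/glomeruli for
    the canvas).
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width

    # --- cortex outline: an irregular octagon inset from the canvas edge
    margin = 0.06 * min(h, w)
    cx, cy = w / 2.0, h / 2.0
    ang = np.linspace(0.0, 2.0 * np.pi, 8, endpoint=False)
    ang = ang + rng.uniform(-0.1, 0.1, size=8)
    rad_x = (w / 2.0 - margin) * rng.uniform(0.92, 1.0, size=8)
    rad_y = (h / 2.0 - margin) * rng.uniform(0.92, 1.0, size=8)
    cortex_vertices = [
        (cx + rx * np.cos(a), cy + ry * np.sin(a))
        for a, rx, ry in zip(ang, rad_x, rad_y)
    ]
    cortex_poly = RoiPolygon(vertices=cortex_vertices, role="cortex", label="cortex")
    cortex_mask = rasterize(
        AnnotationSet(polygons=[cortex_poly]), h, w
    ).grid

    # --- glomeruli: non-overlapping discs inside the cortex
    glom_mask = np.zeros((h, w), dtype=bool)
    exclusion_polys: list[RoiPolygon] = []
    glom_r = 0.055 * min(h, w)
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    while len(placed) < config.n_glomeruli and attempts < 2000:
        attempts += 1
        gx = rng.uniform(margin + glom_r, w - margin - glom_r)
        gy = rng.uniform(margin + glom_r, h - margin - glom_r)
        if any(np.hypot(gx - px, gy - py) < glom_r + pr + 3 for px, py, pr in placed):
            continue
        disc = _disc_mask(h, w, gx, gy, glom_r, glom_r)
        if not (disc <= cortex_mask).all():
            continue
        placed.append((gx, gy, glom_r))
        glom_mask |= disc
        exclusion_polys.append(
            RoiPolygon(
                vertices=_circle_polygon(gx, gy, glom_r + 1.5),
                role="exclusion",
                label="glomerulus",
            )
        )

    annotations = AnnotationSet(
        slide_id=f"synth-{config.seed}",
        polygons=[cortex_poly] + exclusion_polys,
    )
    eval_mask = rasterize(annotations, h, w).grid
    n_eval = int(eval_mask.sum())
    if n_eval == 0:
        raise GenerationError("evaluation region is empty")
    n_target = int(round(config.fibrosis_fraction * n_eval))

    # the fibrosis field is drawn before tubule placement so a solid
    # calibration band can be reserved where the field is highest
    field_noise = gaussian_filter(
        rng.standard_normal((h, w)), config.field_smoothness
    )
    # Reserve one clear window for a pure collagen reference patch (the
    # operator's positive internal control): tubules will avoid it.  At
    # least 100 pure pixels are needed for calibration; skipped when the
    # target fraction is too small to spend that many pixels on a band.
    reserved: np.ndarray | None = None
    clear = cortex_mask & eval_mask
    for side in (12, 10):
        if n_target >= 2 * side * side:
            win = _best_clear_window(clear, field_noise, side)
            if win is not None:
                r0, c0 = win
                reserved = np.zeros((h, w), dtype=bool)
                reserved[r0 : r0 + side, c0 : c0 + side] = True
                break

    # --- tubules: counterstain rings with white lumens, avoiding glomeruli
    tubule_full = np.zeros((h, w), dtype=bool)
    lumen_mask = np.zeros((h, w), dtype=bool)
    occupied = glom_mask.copy()
    if reserved is not None:
        occupied |= reserved
    n_placed = 0
    attempts = 0
    while n_placed < config.n_tubules and attempts < 40 * max(config.n_tubules, 1):
        attempts += 1
        rx = rng.uniform(4.0, 9.0)
        ry = rng.uniform(4.0, 9.0)
        tx = rng.uniform(rx, w - rx)
        ty = rng.uniform(ry, h - ry)
        full = _disc_mask(h, w, tx, ty, rx, ry)
        if not (full <= cortex_mask).all() or (full & occupied).any():
            continue
        lumen = _disc_mask(h, w, tx, ty, 0.55 * rx, 0.55 * ry)
        tubule_full |= full
        lumen_mask |= lumen & full
        occupied |= full
        n_placed += 1

    # --- fibrosis: top-of-field pixels of the paintable interstitium
    interstitium = cortex_mask & ~glom_mask & ~tubule_full
    paintable = interstitium & eval_mask
    n_paintable = int(paintable.sum())
    if n_target > n_paintable:
        raise GenerationError(
            f"fibrosis fraction {config.fibrosis_fraction} needs {n_target} "
            f"interstitial pixels but only {n_paintable} are free; "
            "reduce n_tubules/n_glomeruli or the fraction"
        )
    fibrosis_mask = np.zeros((h, w), dtype=bool)
    if n_target > 0:
        if reserved is not None:
            fibrosis_mask |= reserved
        remaining = n_target - int(fibrosis_mask.sum())
        if remaining > 0:
            pool = paintable & ~fibrosis_mask
            vals = field_noise[pool]
            order = np.argsort(vals)[::-1][:remaining]
            idx_r, idx_c = np.nonzero(pool)
            fibrosis_mask[idx_r[order], idx_c[order]] = True
    realized = fibrosis_mask.sum() / n_eval

    # --- render
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = config.background_rgb
    neg = np.asarray(config.stain_neg_rgb, dtype=np.float64)
    pos = np.asarray(config.stain_pos_rgb, dtype=np.float64)
    img[cortex_mask] = neg
    # glomerular tufts carry some collagen: a pos/neg blend distinct from
    # both classes, so excluding them actually matters
    img[glom_mask] = 0.65 * neg + 0.35 * pos
    img[lumen_mask] = config.background_rgb
    img[fibrosis_mask] = pos
    truth_background = ~cortex_mask | lumen_mask

    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    img = np.clip(img * config.batch_gain, 0.0, 255.0)
    if config.batch_hue_shift_deg != 0.0:
        hsv = rgb2hsv(img / 255.0)
        hsv[:, :, 0] = (hsv[:, :, 0] + config.batch_hue_shift_deg / 360.0) % 1.0
        img = np.clip(hsv2rgb(hsv) * 255.0, 0.0, 255.0)
    image = RasterImage(
        pixels=img.round().astype(np.uint8),
        slide_id=f"synth-{config.seed}",
    )

    # --- reference patches from pure truth regions
    pure_neg = interstitium & ~fibrosis_mask
    for role, region, label in (
        ("ref_positive", fibrosis_mask, "collagen"),
        ("ref_negative", pure_neg, "counterstain"),
    ):
        rect = _largest_rectangle(region)
        if rect is not None:
            rect = _clip_rect(rect, _REF_PATCH_CAP)
            if rect[2] * rect[3] >= _MIN_REF_SIDE**2:
                annotations.polygons.append(_rect_polygon(rect, role, label))

    return SynthSlide(
        image=image,
        truth_fibrosis_mask=fibrosis_mask,
        truth_cortex_mask=cortex_mask,
        truth_glomeruli_mask=glom_mask,
        truth_background_mask=truth_background,
        annotations=annotations,
        realized_fraction=float(realized),
        config=config,
    )


def derive_seed(base_seed: int, index: int) -> int:
    """Stable per-slide seed below 2**31 derived from (base seed, index)."""
    return int(
        np.random.SeedSequence([int(base_seed), int(index)]).generate_state(1)[0]
        % (2**31)
    )


def generate_batch(
    base: SynthConfig,
    fractions: Sequence[float],
    batch_gains: Sequence[float],
    seed: int,
) -> list[SynthSlide]:
    """One slide per (fraction, gain) pair of the cartesian product.

    Per-slide seeds are derived from ``seed`` and the slide index, so the
    batch is reproducible as a whole while each slide gets an independent
    noise field.
    """
    if len(fractions) == 0 or len(batch_gains) == 0:
        raise PreconditionError("fractions and batch_gains must be non-empty")
    slides = []
    idx = 0
    for frac in fractions:
        for gain in batch_gains:
            cfg = SynthConfig(
                **{
                    **asdict(base),
                    "fibrosis_fraction": float(frac),
                    "batch_gain": float(gain),
                    "seed": derive_seed(seed, idx),
                }
            )
            slides.append(generate_slide(cfg))
            idx += 1
    return slides


DEFAULT_BATCH_FRACTIONS = (0.05, 0.15, 0.25)
DEFAULT_BATCH_GAINS = (0.9, 1.0, 1.1)


def default_batch(base: SynthConfig | None = None, seed: int = 0) -> list[SynthSlide]:
    """The standard 9-slide validation batch: 3 fractions x 3 gains."""
    if base is None:
        base = SynthConfig()
    return generate_batch(base, DEFAULT_BATCH_FRACTIONS, DEFAULT_BATCH_GAINS, seed)


def write_slide(slide: SynthSlide, out_dir: str | Path) -> None:
    """Write image (PNG), truth masks (0/255 PNGs), GeoJSON and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_image(slide.image, out / "image.png")
    for name in (
        "truth_fibrosis_mask",
        "truth_cortex_mask",
        "truth_glomeruli_mask",
        "truth_background_mask",
    ):
        mask = getattr(slide, name).astype(np.uint8) * 255
        write_image(
            RasterImage(pixels=np.repeat(mask[:, :, None], 3, axis=2)),
            out / f"{name}.png",
        )
    write_annotations(slide.annotations, out / "annotations.geojson")
    truth = {
        "realized_fraction": slide.realized_fraction,
        "config": asdict(slide.config),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
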