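"""Scorer-annotation handling and chance-corrected agreement.

Each scorer outlines their SOZ opinion as one or more polygons on a fixed
raster view; the polygons are rasterised (even-odd fill, pixel-centre rule)
into binary masks. Agreement between two masks is unweighted Cohen's kappa
over *all* pixels in the raster: each pixel is classified in/out by each
scorer, observed agreement is corrected for the agreement expected from the
two marginal in-rates. The full-raster denominator means kappa depends on
the view size — padding a raster changes the chance-agreement term — so all
masks entering a comparison must share the same raster.

Kappa is undefined when the expected agreement is 1 (both masks empty, or
both full): such comparisons are recorded as missing, never coerced to 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "AnnotationMask",
    "KappaResult",
    "AgreementError",
    "UndefinedKappaError",
    "rasterize_polygons",
    "cohen_kappa",
    "pairwise_kappa",
    "kappa_matrix",
    "intra_rater_kappa",
    "overlaps_clinical",
    "scorer_mean_kappa",
    "save_mask",
    "load_mask",
]


class AgreementError(ValueError):
    pass


class UndefinedKappaError(AgreementError):
    """Expected agreement is 1; kappa has no defined value."""


@dataclass(frozen=True)
class AnnotationMask:
    """One scorer's binary SOZ raster for one seizure view."""

    pixels: np.ndarray
    raster_spec: str = "surface-800x600"
    scorer_id: str = ""
    seizure_id: str = ""
    condition: str = ""  # "HD" | "LD" | "" for ground truth
    confidence: int = 3
    multifocal: bool = False

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise AgreementError("pixels must be a 2D raster")
        if not np.isin(px, (0, 1)).all():
            raise AgreementError("pixels must be binary")
        if not 1 <= int(self.confidence) <= 5:
            raise AgreementError("confidence must be a Likert value 1-5")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class KappaResult:
    scorer_a: str
    scorer_b: str
    seizure_id: str
    condition: str
    kappa: float | None  # None = undefined (pe == 1)


def _points_in_ring(ring: np.ndarray, px: np.ndarray, py: np.ndarray) -> np.ndarray:
    """Even-odd (ray casting) point-in-polygon test, vectorised over points."""
    x0, y0 = ring[:, 0], ring[:, 1]
    x1, y1 = np.roll(x0, -1), np.roll(y0, -1)
    inside = np.zeros(px.shape, dtype=bool)
    for ax, ay, bx, by in zip(x0, y0, x1, y1):
        crosses = (ay > py) != (by > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = ax + (py - ay) * (bx - ax) / (by - ay)
        inside ^= crosses & (px < xint)
    return inside


def rasterize_polygons(
    polygons: Sequence[np.ndarray],
    raster_shape: tuple[int, int] = (600, 800),
    **mask_meta,
) -> AnnotationMask:
    """Rasterise polygon rings into a binary mask.

    Rings are ``(k, 2)`` arrays of ``(x, y)`` vertices in raster pixel
    coordinates, 0-based with origin at the top-left. A pixel ``(r, c)``
    is set when its centre ``(c + 0.5, r + 0.5)`` lies inside a ring under
    the even-odd rule; multiple rings (multifocal annotations) are OR-ed.
    Self-intersecting rings are filled even-odd with a warning; vertices
    outside the raster are clipped to its bounds.
    """
    h, w = raster_shape
    mask = np.zeros((h, w), dtype=bool)
    cy, cx = np.mgrid[0:h, 0:w]
    px = cx + 0.5
    py = cy + 0.5
    for ring in polygons:
        ring = np.asarray(ring, dtype=float)
        if ring.ndim != 2 or ring.shape[1] != 2 or len(ring) < 3:
            raise AgreementError("each ring needs >= 3 (x, y) vertices")
        if _ring_self_intersects(ring):
            warnings.warn("self-intersecting ring; applying even-odd fill",
                          stacklevel=2)
        clipped = np.column_stack(
            [np.clip(ring[:, 0], 0, w), np.clip(ring[:, 1], 0, h)]
        )
        mask |= _points_in_ring(clipped, px, py)
    return AnnotationMask(mask.astype(np.uint8), **mask_meta)


def _ring_self_intersects(ring: np.ndarray) -> bool:
    try:
        from shapely.geometry import LinearRing

        return not LinearRing(ring).is_simple
    except Exception:
        return False


def cohen_kappa(a: AnnotationMask, b: AnnotationMask) -> float:
    """Unweighted Cohen's kappa of two binary masks over the full raster.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with ``p_o = (n11 + n00) / N`` and
    ``p_e = p_a p_b + (1 - p_a)(1 - p_b)``.
    """
    if a.shape != b.shape or a.raster_spec != b.raster_spec:
        raise AgreementError("masks must share a raster to be compared")
    n = a.pixels.size
    n11 = int((a.pixels & b.pixels).sum())
    pa = a.area_px / n
    pb = b.area_px / n
    n00 = n - a.area_px - b.area_px + n11
    po = (n11 + n00) / n
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe >= 1.0:
        raise UndefinedKappaError(
            "both masks empty or both full: chance agreement is 1"
        )
    return (po - pe) / (1 - pe)


def _kappa_or_none(a: AnnotationMask, b: AnnotationMask) -> float | None:
    try:
        return cohen_kappa(a, b)
    except UndefinedKappaError:
        return None


def pairwise_kappa(masks: Sequence[AnnotationMask]) -> list[KappaResult]:
    """Kappa for every unordered scorer pair on one seizure + condition
    (C(n, 2) results; undefined kappas propagate as missing)."""
    if len(masks) < 2:
        raise AgreementError("need >= 2 scorers")
    out = []
    for ma, mb in combinations(masks, 2):
        out.append(
            KappaResult(
                ma.scorer_id, mb.scorer_id, ma.seizure_id, ma.condition,
                _kappa_or_none(ma, mb),
            )
        )
    return out


def kappa_matrix(masks: Sequence[AnnotationMask]) -> np.ndarray:
    """Symmetric pairwise matrix with unit diagonal (display form)."""
    n = len(masks)
    mat = np.full((n, n), np.nan)
    np.fill_diagonal(mat, 1.0)
    for i, j in combinations(range(n), 2):
        k = _kappa_or_none(masks[i], masks[j])
        if k is not None:
            mat[i, j] = mat[j, i] = k
    return mat


def intra_rater_kappa(hd_mask: AnnotationMask, ld_mask: AnnotationMask) -> KappaResult:
    """Same scorer, same seizure, HD vs LD conditions."""
    if hd_mask.scorer_id != ld_mask.scorer_id:
        raise AgreementError("intra-rater kappa needs the same scorer twice")
    return KappaResult(
        hd_mask.scorer_id, hd_mask.scorer_id, hd_mask.seizure_id, "HDvsLD",
        _kappa_or_none(hd_mask, ld_mask),
    )


def overlaps_clinical(mask: AnnotationMask, clinical_region: AnnotationMask) -> bool:
    """Any-pixel intersection with the clinically determined SOZ region."""
    if mask.shape != clinical_region.shape:
        raise AgreementError("masks must share a raster")
    return bool((mask.pixels & clinical_region.pixels).any())


def scorer_mean_kappa(results: Sequence[KappaResult], scorer_id: str) -> float:
    """Mean of one scorer's pairwise kappas with all other scorers
    (missing entries excluded)."""
    vals = [
        r.kappa
        for r in results
        if r.kappa is not None and scorer_id in (r.scorer_a, r.scorer_b)
        and r.scorer_a != r.scorer_b
    ]
    if not vals:
        raise AgreementError(f"no defined kappas for scorer {scorer_id!r}")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Mask I/O: PNG raster (0/255) + JSON sidecar with the metadata

def save_mask(mask: AnnotationMask, path: str | Path) -> None:
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, mask.pixels * np.uint8(255))
    meta = dict(
        raster_spec=mask.raster_spec, scorer_id=mask.scorer_id,
        seizure_id=mask.seizure_id, condition=mask.condition,
        confidence=int(mask.confidence), multifocal=bool(mask.multifocal),
    )
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_mask(path: str | Path) -> AnnotationMask:
    import imageio.v3 as iio

    path = Path(path)
    px = (np.asarray(iio.imread(path)) > 127).astype(np.uint8)
    meta = json.loads(path.with_suffix(".json").read_text())
    return AnnotationMask(px, **meta)
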