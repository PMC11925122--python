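"""Seizure-intensity heatmaps: line-length transform, baseline z-scoring,
and blinded anatomical projection.

Seizure intensity is summarised per channel by the line-length transform —
the sum of absolute consecutive-sample differences over a trailing window —
z-scored against a pre-ictal baseline. Intensity is painted onto anatomy
(surface-mesh vertices or omni-planar slice pixels) by a distance-based
Gaussian drop-off, taking the *maximum* weighted contribution over nearby
electrodes rather than their sum: an additive rule would brighten simply
because more electrodes are present, unblinding the density condition,
whereas the max of ``z_e * exp(-d^2 / 2 sigma^2)`` is invariant to contact
duplication and monotone under contact removal. (Monotonicity is exact on
the displayed heat, where negatives are clamped to zero: an uncovered
target scores 0, which could exceed a negative raw max.)

Blinded rendering draws no electrode glyphs and no condition metadata; only
the heat colour map and a time axis remain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import OmniplanarPlane, SurfaceMesh
from .preprocess import Recording

__all__ = [
    "LineLengthSeries",
    "HeatmapFrame",
    "HeatmapError",
    "line_length",
    "zscore_to_baseline",
    "project_max_gaussian",
    "render_surface_frame",
    "render_omniplanar_frame",
]

#: Defaults for the trailing line-length window and the projection kernel.
DEFAULT_WINDOW_S = 1.0
DEFAULT_HOP_S = 0.1
DEFAULT_SIGMA_MM = 5.0
DEFAULT_CUTOFF_MM = 15.0


class HeatmapError(ValueError):
    pass


@dataclass(frozen=True)
class LineLengthSeries:
    """Per-channel, per-frame line length (channels x frames)."""

    values: np.ndarray
    window_s: float
    hop_s: float
    frame_times_s: np.ndarray
    channel_labels: tuple[str, ...]
    zscored: bool = False

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def frames_in(self, t0_s: float, t1_s: float) -> np.ndarray:
        """Column indices of frames with time in [t0_s, t1_s)."""
        return np.nonzero((self.frame_times_s >= t0_s) & (self.frame_times_s < t1_s))[0]


@dataclass(frozen=True)
class HeatmapFrame:
    """Scalar heat per projection target (mesh vertex or slice pixel) at
    one time point. Values are z-units; negatives are retained here and
    clamped to zero only at display time."""

    values: np.ndarray
    frame_time_s: float
    vmin: float = 0.0
    vmax: float = 8.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.isfinite(v).all():
            raise HeatmapError("heatmap values must be finite")
        object.__setattr__(self, "values", v)


def line_length(
    rec: Recording,
    window_s: float = DEFAULT_WINDOW_S,
    hop_s: float = DEFAULT_HOP_S,
) -> LineLengthSeries:
    """Trailing-window line length per channel.

    Frame at time ``t`` sums ``|x[i] - x[i-1]|`` over the window ``(t -
    window_s, t]``; the transform is causal, so the first full frame sits at
    ``t = window_s``.
    """
    win = int(round(window_s * rec.fs_hz))
    hop = max(1, int(round(hop_s * rec.fs_hz)))
    if win < 2:
        raise HeatmapError("window must cover >= 2 samples")
    if win > rec.n_samples:
        raise HeatmapError("window longer than the recording")
    absdiff = np.abs(np.diff(rec.data, axis=1))
    csum = np.concatenate(
        [np.zeros((rec.n_channels, 1)), np.cumsum(absdiff, axis=1)], axis=1
    )
    # frame ending at sample e sums absdiff[e-win+1 .. e-1] -> win-1 diffs
    ends = np.arange(win, rec.n_samples + 1, hop)
    values = csum[:, ends - 1] - csum[:, ends - win]
    times = ends / rec.fs_hz
    return LineLengthSeries(values, window_s, hop_s, times, rec.channel_labels)


def zscore_to_baseline(
    ll: LineLengthSeries,
    baseline_window_s: tuple[float, float],
    min_baseline_frames: int = 10,
) -> LineLengthSeries:
    """Per-channel z-score against frames inside the pre-ictal baseline."""
    idx = ll.frames_in(*baseline_window_s)
    if len(idx) < min_baseline_frames:
        raise HeatmapError(
            f"baseline covers {len(idx)} frames; need >= {min_baseline_frames}"
        )
    base = ll.values[:, idx]
    mu = base.mean(axis=1, keepdims=True)
    sd = base.std(axis=1, ddof=1, keepdims=True)
    dead = np.nonzero(sd.ravel() == 0)[0]
    if len(dead):
        labels = [ll.channel_labels[i] for i in dead]
        raise HeatmapError(
            f"zero baseline variability on channels {labels}; exclude them first"
        )
    return LineLengthSeries(
        (ll.values - mu) / sd,
        ll.window_s,
        ll.hop_s,
        ll.frame_times_s,
        ll.channel_labels,
        zscored=True,
    )


def project_max_gaussian(
    z: np.ndarray,
    contacts: np.ndarray,
    targets: np.ndarray,
    sigma_mm: float = DEFAULT_SIGMA_MM,
    cutoff_mm: float = DEFAULT_CUTOFF_MM,
    frame_time_s: float = 0.0,
) -> HeatmapFrame:
    """Max-of-weighted Gaussian projection of per-electrode intensity.

    ``value(t) = max_{e : d(e,t) <= cutoff} z_e * exp(-d^2 / (2 sigma^2))``;
    targets with no contact within the cutoff get 0. Applying the drop-off
    *before* the max keeps distance informative while staying monotone under
    contact removal (LD heat never exceeds HD heat on shared channels).
    """
    z = np.asarray(z, dtype=float).ravel()
    contacts = np.atleast_2d(np.asarray(contacts, dtype=float))
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    if contacts.size == 0:
        raise HeatmapError("empty contact list")
    if len(z) != len(contacts):
        raise HeatmapError("one intensity value per contact required")
    if sigma_mm <= 0:
        raise HeatmapError("sigma_mm must be positive")
    d = cdist(targets, contacts)
    w = np.exp(-(d**2) / (2 * sigma_mm**2))
    contrib = z[None, :] * w
    contrib[d > cutoff_mm] = -np.inf
    values = contrib.max(axis=1)
    values[~np.isfinite(values)] = 0.0
    return HeatmapFrame(values, frame_time_s)


def render_surface_frame(
    mesh: SurfaceMesh,
    frame: HeatmapFrame,
    blinded: bool = True,
    contacts: np.ndarray | None = None,
    view_axis: int = 0,
    cmap: str = "hot",
):
    """Colour-map a heatmap frame onto a brain surface.

    Returns ``(figure, layer_manifest)``: the manifest lists the layers
    drawn, so a blinded render can be checked to contain no electrode layer
    and no condition text. The 3D surface is shown as an orthographic 2D
    projection along ``view_axis`` (0 = sagittal view).
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    import matplotlib.tri as mtri

    if len(frame.values) != mesh.n_vertices:
        raise HeatmapError("frame length must match mesh vertex count")
    keep = [ax for ax in range(3) if ax != view_axis]
    xy = mesh.vertices[:, keep]
    heat = np.clip(frame.values, frame.vmin, None)  # display clamp only
    fig, ax = plt.subplots(figsize=(5, 4))
    tri = mtri.Triangulation(xy[:, 0], xy[:, 1], mesh.faces)
    ax.tripcolor(tri, heat, shading="gouraud", cmap=cmap,
                 vmin=frame.vmin, vmax=frame.vmax)
    manifest = ["surface_heat"]
    if not blinded:
        if contacts is not None:
            ax.plot(contacts[:, keep[0]], contacts[:, keep[1]], "k.", ms=3)
            manifest.append("electrodes")
    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(f"t = {frame.frame_time_s:.1f} s")
    manifest.append("time_axis")
    return fig, manifest


def render_omniplanar_frame(
    plane: OmniplanarPlane,
    contacts: np.ndarray,
    z: np.ndarray,
    sigma_mm: float = DEFAULT_SIGMA_MM,
    cutoff_mm: float = DEFAULT_CUTOFF_MM,
    anatomy_field=None,
    frame_time_s: float = 0.0,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Heat raster on an omni-planar slice.

    Every slice pixel centre is a 3D point; heat comes from the same
    max-Gaussian projection as the surface view. ``anatomy_field``, if
    given, is a callable mapping (n, 3) positions to a grey-matter scalar
    background sampled on the same grid. Returns ``(heat, background)``
    rasters of shape (nu, nv).
    """
    pix = plane.pixel_positions()
    if pix.size == 0:
        raise HeatmapError("plane has zero resolution")
    nu, nv, _ = pix.shape
    flat = pix.reshape(-1, 3)
    frame = project_max_gaussian(
        z, contacts, flat, sigma_mm, cutoff_mm, frame_time_s
    )
    heat = frame.values.reshape(nu, nv)
    background = None
    if anatomy_field is not None:
        background = np.asarray(anatomy_field(flat), dtype=float).reshape(nu, nv)
    return heat, background
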