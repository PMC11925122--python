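"""Synthetic inputs with known ground truth for every pipeline stage.

Real seizure recordings of this kind are not redistributable, so this
module emulates them: referential recordings at 3052 Hz with a stationary
pre-ictal baseline and a focal ictal oscillation whose amplitude decays
exponentially with distance from a focus. The model is deliberately the
simplest one that makes the line-length transform spatially informative —
a distance-attenuated sinusoid plus white noise — and makes no attempt to
mimic real ictal morphology (LVFA spectra, spiking).

It also simulates the human side of the study with controllable truth:
scorer annotation masks jittered around a true SOZ region with a known
HD-vs-LD log-area effect, balanced crossover schedules, and score tables
drawn from the exact mixed models the inference module fits (the
parameter-recovery harness).

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage import measure

from .agreement import AnnotationMask, rasterize_polygons
from .geometry import ElectrodeArray
from .preprocess import Recording

__all__ = [
    "SeizureSimConfig",
    "ScorerSimConfig",
    "CrossoverSchedule",
    "SyntheticError",
    "generate_seizure_recording",
    "generate_true_soz_mask",
    "simulate_scorer_annotations",
    "generate_crossover_schedule",
    "generate_score_table",
    "DEFAULT_AREA_BETA",
    "DEFAULT_CONFIDENCE_BETA",
]

# Fixed-effect defaults for the score-table generator: the density effect on
# log area (HD annotations ~25% larger) and the multifocality effect on
# confidence (multifocal SOZs rated ~0.9 Likert points less confidently).
DEFAULT_AREA_BETA = dict(
    intercept=7.0, density=0.227, multifocal=0.2, overlaps_clinical=1.606,
    confidence=0.05,
)
DEFAULT_CONFIDENCE_BETA = dict(
    intercept=3.5, density=0.0, multifocal=-0.873, overlaps_clinical=0.0,
    scorer_mean_kappa=0.0,
)


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SeizureSimConfig:
    """Parameters of the simulated focal seizure.

    The ictal component on a channel at distance ``d`` (mm) from the focus
    is ``amplitude_uv * exp(-d / amplitude_decay_mm) * ramp(t) *
    sin(2 pi f t)``, ramping linearly over ``ramp_s`` after onset, on top
    of white noise of SD ``noise_sd`` everywhere.
    """

    focus: tuple[float, float, float] = (0.0, 0.0, 0.0)
    onset_s: float = 10.0
    # fast (LVFA-like) oscillation: line length grows with both amplitude
    # and frequency, so a fast rhythm is what makes the transform light up
    ictal_freq_hz: float = 80.0
    amplitude_uv: float = 300.0
    amplitude_decay_mm: float = 10.0
    ramp_s: float = 2.0
    noise_sd: float = 20.0
    fs_hz: float = 3052.0
    duration_s: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.focus)):
            raise SyntheticError("focus coordinates must be finite")
        if not 0 < self.onset_s < self.duration_s:
            raise SyntheticError("onset must lie inside the recording")
        if self.amplitude_decay_mm <= 0:
            raise SyntheticError("decay constant must be positive")
        if self.fs_hz <= 2 * self.ictal_freq_hz:
            raise SyntheticError("fs must exceed twice the ictal frequency")


@dataclass(frozen=True)
class ScorerSimConfig:
    """Simulated scorer behaviour.

    ``area_log_multiplier_hd`` is the expected difference in log annotated
    area between HD and LD presentations of the same seizure;
    ``scorer_bias_sd`` / ``seizure_effect_sd`` are SDs of per-scorer and
    per-seizure log-area intercepts. Confidence is a base Likert level,
    reduced for multifocal annotations and noisier boundaries.
    """

    n_scorers: int = 6
    boundary_jitter_px: float = 2.0
    area_log_multiplier_hd: float = 0.227
    scorer_bias_sd: float = 0.1
    seizure_effect_sd: float = 0.0
    confidence_base: float = 4.0
    confidence_multifocal_shift: float = -0.873
    confidence_noise_sd: float = 0.7
    seed: int = 0
    retry_cap: int = 10

    def __post_init__(self) -> None:
        if self.n_scorers < 2:
            raise SyntheticError("need >= 2 scorers")
        if self.boundary_jitter_px < 0:
            raise SyntheticError("jitter must be >= 0")


@dataclass(frozen=True)
class CrossoverSchedule:
    """Blocked crossover schedule: per-seizure first condition, balanced
    (half HD-first); the second pass shows every seizure in the opposite
    condition."""

    first_condition: tuple[str, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.first_condition)
        n_hd = sum(c == "HD" for c in self.first_condition)
        if n_hd * 2 != n:
            raise SyntheticError("schedule must be balanced (half HD-first)")

    @property
    def n_seizures(self) -> int:
        return len(self.first_condition)

    @property
    def second_condition(self) -> tuple[str, ...]:
        return tuple("LD" if c == "HD" else "HD" for c in self.first_condition)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                seizure_id=[f"sz{i:02d}" for i in range(self.n_seizures)],
                first_condition=self.first_condition,
                second_condition=self.second_condition,
            )
        )


def generate_seizure_recording(
    arrays: list[ElectrodeArray], cfg: SeizureSimConfig
) -> Recording:
    """Focal seizure on the supplied electrode geometry.

    Pre-onset: stationary white noise. Post-onset: each channel adds a
    sinusoid at ``ictal_freq_hz`` whose amplitude decays exponentially with
    the contact's distance from the focus and ramps up linearly over
    ``ramp_s``. Deterministic under a fixed seed.
    """
    if not arrays:
        raise SyntheticError("need at least one electrode array")
    contacts = np.vstack([a.contacts for a in arrays])
    labels = tuple(lab for a in arrays for lab in a.channel_labels)
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs_hz))
    t = np.arange(n) / cfg.fs_hz
    data = rng.normal(0.0, cfg.noise_sd, size=(len(contacts), n))
    d = np.linalg.norm(contacts - np.asarray(cfg.focus), axis=1)
    amp = cfg.amplitude_uv * np.exp(-d / cfg.amplitude_decay_mm)
    rel = t - cfg.onset_s
    ramp = np.clip(rel / cfg.ramp_s, 0.0, 1.0) * (rel >= 0)
    osc = np.sin(2 * np.pi * cfg.ictal_freq_hz * rel) * ramp
    data += amp[:, None] * osc[None, :]
    onset = int(round(cfg.onset_s * cfg.fs_hz))
    b1 = max(1, onset - int(round(1.0 * cfg.fs_hz)))
    b0 = max(0, b1 - int(round(min(30.0, cfg.onset_s - 2.0) * cfg.fs_hz)))
    return Recording(
        data=data, fs_hz=cfg.fs_hz, channel_labels=labels,
        onset_sample=onset, baseline_window=(b0, b1),
    )


def generate_true_soz_mask(
    raster_shape: tuple[int, int] = (200, 200),
    shape: str = "disc",
    center: tuple[float, float] | None = None,
    radius_px: float = 30.0,
    polygon: np.ndarray | None = None,
    seizure_id: str = "sz00",
) -> AnnotationMask:
    """Ground-truth SOZ region as a disc or explicit polygon on the raster."""
    h, w = raster_shape
    if shape == "disc":
        if radius_px <= 0:
            raise SyntheticError("disc radius must be positive")
        cx, cy = center if center is not None else (w / 2, h / 2)
        yy, xx = np.mgrid[0:h, 0:w]
        mask = ((xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2) <= radius_px**2
        out = AnnotationMask(mask.astype(np.uint8), seizure_id=seizure_id)
    elif shape == "polygon":
        if polygon is None:
            raise SyntheticError("polygon shape needs vertices")
        out = rasterize_polygons([polygon], raster_shape, seizure_id=seizure_id)
    else:
        raise SyntheticError(f"unknown SOZ shape {shape!r}")
    if out.area_px == 0:
        raise SyntheticError("true SOZ mask is empty")
    return out


def _mask_contour(mask: np.ndarray, max_vertices: int = 72) -> np.ndarray:
    """Largest closed iso-contour of the mask as (k, 2) (x, y) vertices,
    decimated to ``max_vertices`` for smooth jittering."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise SyntheticError("mask has no contour")
    ring = max(contours, key=len)  # rows, cols
    step = max(1, len(ring) // max_vertices)
    return ring[::step, ::-1].copy()  # -> x, y


def _jitter_and_scale(
    ring: np.ndarray,
    jitter_px: float,
    log_area_shift: float,
    rng: np.random.Generator,
    n_modes: int = 6,
) -> np.ndarray:
    """Displace boundary vertices along the outward normal by smooth noise,
    then rescale about the centroid so polygon area changes by exactly
    ``exp(log_area_shift)``."""
    c = ring.mean(axis=0)
    rel = ring - c
    radii = np.linalg.norm(rel, axis=1)
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    if jitter_px > 0:
        # low-order Fourier field in boundary angle -> smooth displacement
        amp = rng.normal(0.0, jitter_px, size=(n_modes, 2)) / np.sqrt(n_modes)
        disp = np.zeros_like(theta)
        for m in range(1, n_modes + 1):
            disp += amp[m - 1, 0] * np.cos(m * theta) + amp[m - 1, 1] * np.sin(m * theta)
        radii = np.maximum(radii + disp, 0.5)
    ring = c + np.column_stack([radii * np.cos(theta), radii * np.sin(theta)])
    area = _polygon_area(ring)
    if area <= 0:
        raise SyntheticError("degenerate jittered ring")
    ring = c + (ring - c) * np.sqrt(np.exp(log_area_shift))
    return ring


def _polygon_area(ring: np.ndarray) -> float:
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def simulate_scorer_annotations(
    true_mask: AnnotationMask,
    condition: str,
    cfg: ScorerSimConfig,
    multifocal: bool = False,
    seizure_effect: float | None = None,
) -> list[AnnotationMask]:
    """One jittered annotation per scorer for a given density condition.

    Each scorer's mask is the true region's boundary displaced by smooth
    normal noise (SD ``boundary_jitter_px``) and rescaled so the polygon
    log-area equals ``log(true area) + multiplier*[HD] + scorer bias +
    seizure effect`` — the jitter perturbs shape, not expected area. A mask
    that rasterises to empty is regenerated up to ``retry_cap`` times.
    """
    if true_mask.area_px == 0:
        raise SyntheticError("true mask is empty")
    if condition not in ("HD", "LD"):
        raise SyntheticError("condition must be HD or LD")
    rng = np.random.default_rng(cfg.seed)
    ring0 = _mask_contour(true_mask.pixels)
    base_log_area = np.log(true_mask.area_px)
    if seizure_effect is None:
        seizure_effect = (
            rng.normal(0.0, cfg.seizure_effect_sd) if cfg.seizure_effect_sd else 0.0
        )
    out: list[AnnotationMask] = []
    for s in range(cfg.n_scorers):
        bias = rng.normal(0.0, cfg.scorer_bias_sd) if cfg.scorer_bias_sd else 0.0
        shift = (cfg.area_log_multiplier_hd if condition == "HD" else 0.0)
        shift += bias + seizure_effect
        target_log_area = base_log_area + shift
        conf_noise = rng.normal(0.0, cfg.confidence_noise_sd)
        if cfg.boundary_jitter_px == 0 and shift == 0:
            # identity limit: no jitter, no area effect -> the annotation
            # is the truth itself
            conf = cfg.confidence_base + (
                cfg.confidence_multifocal_shift if multifocal else 0.0
            ) + conf_noise
            out.append(
                replace(
                    true_mask, scorer_id=f"scorer{s}", condition=condition,
                    multifocal=multifocal,
                    confidence=int(np.clip(round(conf), 1, 5)),
                )
            )
            continue
        mask = None
        for _ in range(cfg.retry_cap):
            ring = _jitter_and_scale(
                ring0.copy(), cfg.boundary_jitter_px,
                target_log_area - np.log(max(_polygon_area(ring0), 1.0)),
                rng,
            )
            # correct for the jittered ring's own area so the polygon area
            # hits the target exactly
            a = _polygon_area(ring)
            ring = ring.mean(axis=0) + (ring - ring.mean(axis=0)) * np.sqrt(
                np.exp(target_log_area) / a
            )
            cand = rasterize_polygons(
                [ring], true_mask.shape,
                raster_spec=true_mask.raster_spec,
                scorer_id=f"scorer{s}",
                seizure_id=true_mask.seizure_id,
                condition=condition,
                multifocal=multifocal,
            )
            if cand.area_px > 0:
                mask = cand
                break
        if mask is None:
            raise SyntheticError(
                f"scorer {s}: mask empty after {cfg.retry_cap} retries"
            )
        conf = (
            cfg.confidence_base
            + (cfg.confidence_multifocal_shift if multifocal else 0.0)
            - 0.1 * cfg.boundary_jitter_px
            + conf_noise
        )
        conf_i = int(np.clip(round(conf), 1, 5))
        out.append(replace(mask, confidence=conf_i))
    return out


def generate_crossover_schedule(
    n_seizures: int = 10, seed: int = 0
) -> CrossoverSchedule:
    """Balanced blocked randomisation: exactly half the seizures show HD
    first, uniformly over arrangements."""
    if n_seizures % 2:
        raise SyntheticError("balanced crossover needs an even seizure count")
    rng = np.random.default_rng(seed)
    conds = np.array(["HD"] * (n_seizures // 2) + ["LD"] * (n_seizures // 2))
    rng.shuffle(conds)
    return CrossoverSchedule(tuple(conds), seed=seed)


def generate_score_table(
    area_beta: dict | None = None,
    confidence_beta: dict | None = None,
    scorer_sd: float = 0.3,
    seizure_sd: float = 0.4,
    resid_sd: float = 0.3,
    conf_scorer_sd: float = 0.3,
    conf_seizure_sd: float = 0.3,
    conf_resid_sd: float = 0.7,
    n_scorers: int = 6,
    n_seizures: int = 10,
    p_multifocal: float = 0.3,
    p_overlap: float = 0.917,
    seed: int = 0,
    discretise_confidence: bool = False,
) -> pd.DataFrame:
    """Score table drawn from the exact mixed models the inference module
    fits, with known fixed effects and variance components.

    The default design — every scorer, every seizure, both conditions —
    yields ``n_scorers * n_seizures * 2`` rows (120 for the study design).
    Both outcomes are generated: log area from the area model (confidence
    enters it as the *generated* confidence covariate) and confidence from
    the confidence model. When ``discretise_confidence`` the confidence
    outcome is rounded and clipped to the Likert range, which biases naive
    recovery; the continuous default is the clean recovery harness.
    """
    ab = {**DEFAULT_AREA_BETA, **(area_beta or {})}
    cb = {**DEFAULT_CONFIDENCE_BETA, **(confidence_beta or {})}
    rng = np.random.default_rng(seed)
    sched = generate_crossover_schedule(
        n_seizures if n_seizures % 2 == 0 else n_seizures + 1, seed=seed
    )
    first = dict(zip(range(n_seizures), sched.first_condition))
    u_sc_area = rng.normal(0, scorer_sd, n_scorers)
    u_sz_area = rng.normal(0, seizure_sd, n_seizures)
    u_sc_conf = rng.normal(0, conf_scorer_sd, n_scorers)
    u_sz_conf = rng.normal(0, conf_seizure_sd, n_seizures)
    rows = []
    for sc in range(n_scorers):
        for sz in range(n_seizures):
            mean_kappa = float(np.clip(rng.normal(0.47, 0.15), -1, 1))
            for cond in ("HD", "LD"):
                hd = int(cond == "HD")
                mf = int(rng.random() < p_multifocal)
                ov = int(rng.random() < p_overlap)
                conf = (
                    cb["intercept"] + cb["density"] * hd + cb["multifocal"] * mf
                    + cb["overlaps_clinical"] * ov
                    + cb["scorer_mean_kappa"] * mean_kappa
                    + u_sc_conf[sc] + u_sz_conf[sz]
                    + rng.normal(0, conf_resid_sd)
                )
                if discretise_confidence:
                    conf = float(np.clip(round(conf), 1, 5))
                log_area = (
                    ab["intercept"] + ab["density"] * hd + ab["multifocal"] * mf
                    + ab["overlaps_clinical"] * ov + ab["confidence"] * conf
                    + u_sc_area[sc] + u_sz_area[sz]
                    + rng.normal(0, resid_sd)
                )
                rows.append(
                    dict(
                        scorer_id=f"scorer{sc}", seizure_id=f"sz{sz:02d}",
                        condition=cond, order_first=first.get(sz, "HD"),
                        area_px=int(max(1, round(np.exp(log_area)))),
                        log_area=log_area, confidence=conf, multifocal=mf,
                        overlaps_clinical=ov, scorer_mean_kappa=mean_kappa,
                    )
                )
    return pd.DataFrame(rows)
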