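"""Baseline heading models: motion pooling and differential motion.

Both baselines estimate heading frame by frame with no temporal state: the
flow field (motion pooling) or a field of opponent difference vectors
(differential motion) is matched against center-weighted radial expansion
templates tiling the image, and the heading is the preferred FoE of the
most active template on the horizontal cross-section through the true
heading.

The differential-motion front end filters the flow with odd-symmetric
(rectified) Gabor operators along each direction axis: the two lobes
average the projected speed on either side of the receptive field, and the
rectified lobe difference signals a sharp speed change along the preferred
direction, as at a depth discontinuity.  Uniform (parallax-free) flow
yields no opponent signal, so the model is undefined on such input and the
trace reports the no-estimate sentinel.

Pooling widths follow the printed overrides (sigma = 25 px for motion
pooling, 19 px for differential motion, template grid every 2 px, 7x7
opponent kernels, all at the reference display scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .dynamics import N_DIRECTIONS, direction_vector
from .mstd import HeadingTrace, temporal_smooth
from .stimulus import CameraModel, FlowField

__all__ = [
    "BaselineParams",
    "opponent_motion_field",
    "radial_match_map",
    "heading_from_templates",
    "run_baseline",
]


@dataclass(frozen=True)
class BaselineParams:
    """Printed parameter overrides (px at the working resolution)."""

    sigma_pooling: float = 25.0
    sigma_differential: float = 19.0
    grid_spacing: int = 2
    gabor_size: int = 7
    min_support: float = 1e-6  # minimum pooled validity weight per template


# ---------------------------------------------------------------------------
# center-weighted radial template match (shared by both baselines)
# ---------------------------------------------------------------------------


def _radial_kernels(sigma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(Kx, Ky, G): Gaussian-weighted unit radial field and its weight."""
    r = int(np.ceil(3 * sigma))
    ax = np.arange(-r, r + 1, dtype=float)
    dy, dx = np.meshgrid(ax, ax, indexing="ij")
    rad = np.hypot(dx, dy)
    g = np.exp(-(rad**2) / (2 * sigma * sigma))
    with np.errstate(invalid="ignore", divide="ignore"):
        kx = np.where(rad > 0, dx / np.maximum(rad, 1e-12), 0.0) * g
        ky = np.where(rad > 0, dy / np.maximum(rad, 1e-12), 0.0) * g
    return kx, ky, g


def _corr(arr: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return fftconvolve(arr, kernel[::-1, ::-1], mode="same")


def radial_match_map(
    u: np.ndarray,
    v: np.ndarray,
    valid: np.ndarray,
    sigma: float,
    min_support: float = 1e-6,
) -> np.ndarray:
    """Center-weighted radial template match at every pixel.

    Each template scores the Gaussian-weighted mean cosine between the local
    motion direction and the radial direction from its preferred FoE; motion
    near the preferred FoE therefore contributes more than peripheral
    motion.  Pixels without any support in the pooling window score 0.
    """
    mag = np.hypot(u, v)
    ok = valid & (mag > 1e-12)
    with np.errstate(invalid="ignore", divide="ignore"):
        uh = np.where(ok, u / np.maximum(mag, 1e-12), 0.0)
        vh = np.where(ok, v / np.maximum(mag, 1e-12), 0.0)
    kx, ky, g = _radial_kernels(sigma)
    num = _corr(uh, kx) + _corr(vh, ky)
    den = _corr(ok.astype(float), g)
    return np.where(den > min_support, num / np.maximum(den, min_support), 0.0)


def heading_from_templates(
    score: np.ndarray,
    camera: CameraModel,
    grid_spacing: int = 2,
    active_floor: float = 1e-9,
) -> float:
    """Heading (deg) from a template score map: argmax on the heading row.

    Templates sit every ``grid_spacing`` px; ties go to the template nearer
    the image center; an empty/silent cross-section returns NaN.
    """
    row = int(round(camera.cy))
    xs = score[row, ::grid_spacing]
    if not np.any(np.isfinite(xs)) or np.nanmax(xs) <= active_floor:
        return float("nan")
    center = camera.cx / grid_spacing
    best = np.nanmax(xs)
    cand = np.flatnonzero(xs >= best - 1e-12)
    col = cand[np.argmin(np.abs(cand - center))]
    return float(camera.px_to_deg(col * grid_spacing))


# ---------------------------------------------------------------------------
# differential motion front end
# ---------------------------------------------------------------------------


def _odd_gabor(size: int, d: int) -> np.ndarray:
    """Odd-symmetric Gabor with the positive lobe displaced along +d."""
    r = size // 2
    ax = np.arange(-r, r + 1, dtype=float)
    dy, dx = np.meshgrid(ax, ax, indexing="ij")
    ex, ey = direction_vector(d)
    proj = dx * ex + dy * ey
    env = np.exp(-(dx * dx + dy * dy) / (2 * (size / 3.0) ** 2))
    return np.sin(2 * np.pi * proj / size) * env


def opponent_motion_field(
    flow: FlowField, params: BaselineParams = BaselineParams()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Difference-vector field from MT-like opponent operators.

    For each direction axis the projected speed is averaged separately over
    the positive and negative Gabor lobes (normalized by the dot support
    under each lobe, so dot density does not masquerade as motion
    contrast), and the rectified lobe difference contributes a vector along
    that direction.  Returns (Du, Dv, responded) at display resolution.
    A depth-flat (parallax-free) field produces no response; a warning is
    emitted because the model is undefined there.
    """
    du = np.zeros(flow.shape)
    dv = np.zeros(flow.shape)
    valid = flow.valid.astype(float)
    # each operator sees only motion along its preferred direction
    # (rectified projection) and compares the two Gabor lobes, the positive
    # lobe displaced along +d: a positive difference means the preferred
    # motion is faster ahead, so the difference vector points toward the
    # faster (nearer) surface, away from the focus of expansion
    for d in range(N_DIRECTIONS):
        ex, ey = direction_vector(d)
        proj = np.where(
            flow.valid, np.maximum(flow.u * ex + flow.v * ey, 0.0), 0.0
        )
        k = _odd_gabor(params.gabor_size, d)
        kp, kn = np.maximum(k, 0.0), np.maximum(-k, 0.0)
        sp = _corr(valid, kp)
        sn = _corr(valid, kn)
        ok = (sp > params.min_support) & (sn > params.min_support)
        mean_p = np.where(ok, _corr(proj, kp) / np.maximum(sp, 1e-12), 0.0)
        mean_n = np.where(ok, _corr(proj, kn) / np.maximum(sn, 1e-12), 0.0)
        resp = np.maximum(mean_p - mean_n, 0.0)
        du += resp * ex
        dv += resp * ey
    responded = np.hypot(du, dv) > 1e-9
    if not np.any(responded):
        warnings.warn(
            "no opponent motion response (depth-flat flow?); the differential "
            "motion model is undefined on parallax-free input",
            stacklevel=2,
        )
    return du, dv, responded


# ---------------------------------------------------------------------------
# per-trial driver
# ---------------------------------------------------------------------------


def run_baseline(
    model: str,
    flows: list[FlowField],
    camera: CameraModel,
    params: BaselineParams = BaselineParams(),
    epochs: np.ndarray | None = None,
    smoothing_window: int | None = None,
) -> HeadingTrace:
    """Frame-independent heading estimates for one trial.

    ``model`` is ``"pooling"`` or ``"differential"``.  The optional moving
    average (the temporal-smoothing control) is applied to the per-frame
    template activation maps before the argmax readout; it is the only
    temporal coupling either baseline ever has.
    """
    if model not in ("pooling", "differential"):
        raise ValueError("model must be 'pooling' or 'differential'")
    sigma = params.sigma_pooling if model == "pooling" else params.sigma_differential
    maps = []
    for flow in flows:
        if model == "pooling":
            score = radial_match_map(
                flow.u, flow.v, flow.valid, sigma, params.min_support
            )
        else:
            du, dvv, responded = opponent_motion_field(flow, params)
            score = radial_match_map(du, dvv, responded, sigma, params.min_support)
        maps.append(score)
    maps = np.asarray(maps)
    if smoothing_window is not None and smoothing_window > 1:
        maps = temporal_smooth(maps, smoothing_window)
    n_t = maps.shape[0]
    est = np.array(
        [heading_from_templates(maps[k], camera, params.grid_spacing) for k in range(n_t)]
    )
    t = (np.arange(n_t) + 1) / camera.frame_rate
    if epochs is None:
        epochs = np.array(["before"] * n_t)
    return HeadingTrace(
        time_s=t,
        estimate_deg=est,
        error_deg=est.copy(),
        pop_variance=np.full(n_t, np.nan),
        epoch=np.asarray(epochs),
        model=f"{model}",
    )
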