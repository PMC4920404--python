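"""Heading estimation in MSTd: radial templates and recurrent competition.

MSTd units are tuned to radial expansion (+) or contraction (-) with a
focus-of-expansion / focus-of-contraction preference at every node of a
spatial grid.  The motion stage's direction-channel output is matched
against each unit's template (an ideal unit-length radial field decomposed
into the eight direction channels by rectified cosine projection and
center-weighted by a Gaussian around the preferred singularity), normalized
by the template energy.  Units then compete in an on-center/off-surround
recurrent shunting network across 2D space and across polarity; soft
winner-take-all dynamics sharpen the population code over time, and the
heading readout is the preferred azimuth of the most active expansion unit
on the horizontal cross-section through the true heading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .dynamics import (
    N_DIRECTIONS,
    direction_vector,
    gaussian_kernel,
    shunting_exp_step,
    sigmoid,
    threshold,
)
from .stimulus import CameraModel

__all__ = [
    "MstdParams",
    "TemplateBank",
    "build_templates",
    "template_match",
    "MstdState",
    "read_heading",
    "population_variance",
    "temporal_smooth",
    "HeadingTrace",
]


@dataclass(frozen=True)
class MstdParams:
    """Constants of the MSTd competitive field.

    ``sigma_surround`` and ``sigma_template`` are in *node-grid* units (the
    caller converts from pixels at the working resolution); the surround
    radius is in nodes.
    """

    eps: float = 2.0  # inverse time constant, 1/s
    gamma: float = 0.3  # firing threshold before the recurrent sigmoid
    #: gain on the bottom-up template match.  The absolute scale of the
    #: match depends on the motion front end; this gain places the peak
    #: match just above the printed firing threshold (calibrated once on the
    #: static-environment display) so that recurrent competition operates in
    #: its intended regime: strongly supported units recruit self-excitation,
    #: weakly supported ones stay subthreshold and are suppressed.
    v_gain: float = 0.3
    f0: float = 0.001  # recurrent sigmoid inflection
    sigma_surround: float = 10.0
    surround_radius: int = 7
    sigma_template: float = 15.0
    lesioned: bool = False
    #: strength of the off-surround relative to a unit's self-excitation.
    #: The surround kernel is normalized (border-compensated, so edge units
    #: are not under-inhibited) and scaled by this gain: with gain > 1 the
    #: pooled recurrent inhibition can outweigh the saturated self-excitation
    #: of weakly supported units, which is what makes the population sharpen
    #: into a soft winner-take-all bump instead of saturating everywhere.
    #: gain of the local Gaussian-windowed surround.  An established
    #: activity peak thereby suppresses competing peaks that try to form
    #: nearby, which is what keeps the heading estimate from drifting with
    #: transient radial-like structure (e.g. a pseudo focus of expansion)
    #: in its neighborhood.
    surround_gain: float = 0.0
    #: gain of a network-wide mean-field inhibition term (every unit
    #: inhibits every other, as in the generic recurrent competitive
    #: field).  This normalizes total activity and keeps weakly supported
    #: peripheral units from self-igniting outside the local window.
    global_gain: float = 20.0


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------


@dataclass
class TemplateBank:
    """Direction-channel kernels of the radial templates.

    ``kernels[d]`` holds, for expansion templates, the weight that a motion
    signal in channel ``d`` at node offset (dr, dc) from the preferred FoE
    contributes to the match.  Contraction templates are the same fields
    with every vector negated, i.e. ``kernels[(d + 4) % 8]``.  ``energy`` is
    the per-node template energy (total template weight falling inside the
    grid), used to normalize the match.
    """

    kernels: np.ndarray  # (8, 2*nh-1, 2*nw-1)
    energy: np.ndarray  # (nh, nw)
    node_shape: tuple[int, int]

    def contraction_kernel(self, d: int) -> np.ndarray:
        return self.kernels[(d + N_DIRECTIONS // 2) % N_DIRECTIONS]


def build_templates(
    node_shape: tuple[int, int], sigma_template: float
) -> TemplateBank:
    """Radial expansion templates for every node of the heading grid.

    The template for a node is the unit radial field emanating from that
    node, weighted by a Gaussian of ``sigma_template`` (node units) around
    the singularity and decomposed into the 8 direction channels by
    rectified cosine projection.  Because the field depends only on the
    offset from the singularity, one translation-invariant kernel per
    channel serves every node; per-node energy differs only through grid
    cropping.
    """
    nh, nw = node_shape
    dr = np.arange(-(nh - 1), nh)[:, None]
    dc = np.arange(-(nw - 1), nw)[None, :]
    rad = np.hypot(dr, dc)
    w = np.exp(-(rad**2) / (2.0 * sigma_template**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        rx = np.where(rad > 0, dc / np.maximum(rad, 1e-12), 0.0)
        ry = np.where(rad > 0, dr / np.maximum(rad, 1e-12), 0.0)
    kernels = np.zeros((N_DIRECTIONS, 2 * nh - 1, 2 * nw - 1))
    for d in range(N_DIRECTIONS):
        ex, ey = direction_vector(d)
        kernels[d] = np.maximum(rx * ex + ry * ey, 0.0) * w
    # template energy: one unit-length vector per location, weighted by w,
    # restricted to the part of the template that falls inside the grid
    energy = _corr(np.ones(node_shape), w)
    if np.any(energy <= 0):
        raise ValueError("degenerate template energy")
    return TemplateBank(kernels=kernels, energy=energy, node_shape=node_shape)


def _corr(arr: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """out(ij) = sum_off kernel(off) * arr(ij + off), zero padded."""
    return fftconvolve(arr, kernel[::-1, ::-1], mode="same")


def template_match(n_d: np.ndarray, bank: TemplateBank) -> np.ndarray:
    """Energy-normalized template match, shape (2, nh, nw) = (V+, V-).

    Linear in the motion signal ``n_d`` (shape (8, nh, nw)); V- uses the
    vector-negated (contraction) templates.
    """
    if n_d.shape != (N_DIRECTIONS,) + bank.node_shape:
        raise ValueError("motion signal shape does not match the template grid")
    v_exp = np.zeros(bank.node_shape)
    v_con = np.zeros(bank.node_shape)
    for d in range(N_DIRECTIONS):
        v_exp += _corr(n_d[d], bank.kernels[d])
        v_con += _corr(n_d[d], bank.contraction_kernel(d))
    return np.stack([v_exp / bank.energy, v_con / bank.energy])


# ---------------------------------------------------------------------------
# recurrent competitive field
# ---------------------------------------------------------------------------


@dataclass
class MstdState:
    """Expansion/contraction unit activities P (2, nh, nw) plus kernels."""

    p: np.ndarray
    params: MstdParams
    _g: np.ndarray = field(init=False, repr=False)
    _den: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        par = self.params
        self._g = gaussian_kernel(par.sigma_surround, par.surround_radius)
        from scipy.ndimage import correlate

        self._den = np.maximum(
            correlate(np.ones(self.p.shape[1:]), self._g, mode="constant"),
            1e-12,
        )

    @classmethod
    def zeros(cls, node_shape: tuple[int, int], params: MstdParams | None = None):
        return cls(p=np.zeros((2,) + node_shape), params=params or MstdParams())

    def step(self, v: np.ndarray, dt: float) -> None:
        """One Euler step under bottom-up match ``v`` (2, nh, nw).

        On-center: recurrent self-excitation f(g(P)) plus V.  Off-surround:
        Gaussian-weighted recurrent signals from every other unit of both
        polarities (only the unit itself is excluded).  The lesioned variant
        drops every recurrent term, leaving pure leaky integration of V.
        """
        par = self.params
        from scipy.ndimage import correlate

        v = par.v_gain * v
        if par.lesioned:
            self.p = shunting_exp_step(self.p, v, 0.0, dt, eps=par.eps)
            return
        fg = sigmoid(threshold(self.p, par.gamma), par.f0)
        both = fg.sum(axis=0)
        pooled = correlate(both, self._g, mode="constant") / self._den
        g00 = self._g[par.surround_radius, par.surround_radius]
        local = pooled[None, :, :] - (g00 / self._den)[None, :, :] * fg
        n_units = fg.size
        glob = (fg.sum() - fg) / (n_units - 1)
        inh = par.surround_gain * local + par.global_gain * glob
        self.p = shunting_exp_step(
            self.p, fg + v, np.maximum(inh, 0.0), dt, eps=par.eps
        )


# ---------------------------------------------------------------------------
# readout
# ---------------------------------------------------------------------------


def node_azimuths(camera: CameraModel, node_spacing: int, n_cols: int) -> np.ndarray:
    """Preferred-FoE azimuth (deg) of each node column."""
    cols_px = np.arange(n_cols) * node_spacing
    return camera.px_to_deg(cols_px)


def node_elevations(camera: CameraModel, node_spacing: int, n_rows: int) -> np.ndarray:
    rows_px = np.arange(n_rows) * node_spacing
    return np.degrees(np.arctan2(camera.cy - rows_px, camera.focal_px))


def read_heading(
    p_exp: np.ndarray,
    camera: CameraModel,
    node_spacing: int,
    active_floor: float = 1e-9,
) -> float:
    """Heading estimate (deg azimuth) from the expansion population.

    Argmax along the horizontal cross-section through the true heading row;
    ties go to the node nearer the image center.  Returns NaN ("no
    estimate") when the cross-section is silent.
    """
    nh, nw = p_exp.shape
    row = int(round(camera.cy / node_spacing))
    row = min(max(row, 0), nh - 1)
    xs = p_exp[row]
    if np.max(xs) <= active_floor:
        return float("nan")
    center = camera.cx / node_spacing
    best = np.max(xs)
    cand = np.flatnonzero(xs >= best - 1e-12)
    col = cand[np.argmin(np.abs(cand - center))]
    return float(camera.px_to_deg(col * node_spacing))


def population_variance(
    p_exp: np.ndarray,
    az_deg: np.ndarray,
    el_deg: np.ndarray | None = None,
) -> float:
    """Activity-weighted variance of preferred-FoE positions (deg^2).

    Treats the normalized expansion activity as a weight distribution over
    the template space.  With ``el_deg`` given the variance is the trace of
    the 2D positional covariance; otherwise it is computed along azimuth
    only.  Returns NaN for an all-zero population.
    """
    w = np.asarray(p_exp, dtype=float)
    tot = w.sum()
    if tot <= 0:
        return float("nan")
    w = w / tot
    az = np.broadcast_to(az_deg[None, :], w.shape)
    mu_az = float((w * az).sum())
    var = float((w * (az - mu_az) ** 2).sum())
    if el_deg is not None:
        el = np.broadcast_to(el_deg[:, None], w.shape)
        mu_el = float((w * el).sum())
        var += float((w * (el - mu_el) ** 2).sum())
    return var


def temporal_smooth(series: np.ndarray, window: int) -> np.ndarray:
    """Causal moving average along axis 0 (identity for ``window == 1``).

    Used only for the smoothing control applied to the baseline models'
    per-frame MSTd arrays.
    """
    series = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > series.shape[0]:
        raise ValueError("window longer than the series")
    out = np.empty_like(series)
    for t in range(series.shape[0]):
        out[t] = series[max(0, t - window + 1) : t + 1].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# per-trial result container
# ---------------------------------------------------------------------------


@dataclass
class HeadingTrace:
    """Per-frame heading estimate and diagnostics for one trial.

    Signed error follows the moving-object convention: the object always
    travels rightward, so positive error = deviation in the direction of
    object motion, negative = opposite.
    """

    time_s: np.ndarray
    estimate_deg: np.ndarray
    error_deg: np.ndarray
    pop_variance: np.ndarray
    epoch: np.ndarray  # "before" / "during" / "after"
    model: str = ""
    condition: str = ""
    seed: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": np.arange(len(self.time_s)),
                "time_s": self.time_s,
                "estimate_deg": self.estimate_deg,
                "error_deg": self.error_deg,
                "epoch": self.epoch,
                "pop_variance": self.pop_variance,
                "model": self.model,
                "condition": self.condition,
                "seed": self.seed,
            }
        )
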