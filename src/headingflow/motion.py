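"""Motion detection: V1 simple and complex cells and MT+ pooling.

Simple cells detect motion with a correlation (Reichardt-style) mechanism:
each speed/direction channel sums the present LGN signal with the previous
frame's signal displaced opposite the preferred direction, thresholds and
squares the sum, and averages over the active offsets.  Complex cells pool
simple cells anisotropically parallel to the preferred direction, receive
shunting inhibition from the orthogonal axis and from other directions, and
are suppressed by direction-discrepant feedback from MT+.  MT+ units pool
complex-cell output over a larger elongated receptive field; their
speed-collapsed, collinearly pooled output feeds the heading stage.

Two input routes drive the pathway:

* ``frames`` — the image-computable route (LGN transients in, integer
  pixel-per-frame speed channels), used for rendered video;
* ``flow`` — an analytic-flow drive that encodes each flow vector into the
  same speed/direction channels with rectified-cosine direction tuning and
  band-limited speed tuning that mirrors the offset-inclusive correlation
  detector.  This is the route used for the dot-world experiments at
  reduced resolution, where dot displacements fall below one pixel per
  frame and a pixel-offset correlation detector would be blind to them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate, map_coordinates, uniform_filter

from .dynamics import (
    N_DIRECTIONS,
    anisotropic_kernel,
    direction_vector,
    gaussian_kernel,
    shunting_exp_step,
    sigmoid,
    threshold,
)
from .stimulus import FlowField

__all__ = ["MotionParams", "MotionPathway", "phi_offsets", "v1_simple_drive", "flow_drive"]


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotionParams:
    """Constants of the V1/MT motion circuit.

    Speed channels are indexed 1..3; in frames mode they are literal pixel
    offsets per frame, in flow mode channel ``s`` is centered on
    ``s * speed_unit`` px/frame.  ``sigma_y_factor`` fixes the absolute
    cross-axis width of the anisotropic kernels (only the elongation ratio
    is prescribed), as sigma_y = sigma_y_factor * radius.
    """

    n_speeds: int = 3
    gamma_lgn: float = 0.45  # simple-cell correlation threshold
    eps_s: float = 5.0  # simple-cell inverse time constant, 1/s
    gamma_c: float = 0.01  # complex-cell input threshold
    eps_c: float = 30.0  # complex-cell inverse time constant, 1/s
    eps_mt: float = 30.0  # MT inverse time constant, 1/s
    gamma_v1mt: float = 0.01  # complex-cell output threshold
    f_v1mt: float = 0.01  # complex-cell output sigmoid inflection
    sigma_v1: float = 0.5  # MT->V1 feedback Gaussian width, px
    sigma_ratio: float = 15.0  # anisotropy sigma_x / sigma_y
    sigma_y_factor: float = 1.0 / 3.0
    gamma_mt: float = 1e-3  # MT output threshold
    out_pool_radius: int = 2  # collinear pooling radius on the heading grid
    diag_scale_by_speed: bool = True  # scale diagonal offsets by s, as printed
    mt_spacings: tuple[int, ...] = (1, 2, 3)  # MT grid spacing per speed channel
    printed_mt_form: bool = False  # dM/dt = -M(1-M)I exactly as printed
    # flow-drive encoding
    speed_unit: float = 1.0  # px/frame per speed-channel index
    flow_gain: float = 6.0  # drive amplitude of a fully matched flow vector


# ---------------------------------------------------------------------------
# V1 simple cells
# ---------------------------------------------------------------------------


def phi_offsets(s: int, d: int) -> list[tuple[int, int]]:
    """Integer pixel offsets (drow, dcol) implicating speed ``s`` along ``d``.

    All offsets of Chebyshev length 1..s along the direction ray: a channel
    tuned to speed 3 also receives the shorter-offset correlations.
    """
    if s < 1:
        raise ValueError("speed index must be >= 1")
    dx, dy = direction_vector(d)
    step_c = int(round(dx))
    step_r = int(round(dy))
    if step_c == 0 and step_r == 0:
        raise ValueError("bad direction")
    return [(k * step_r, k * step_c) for k in range(1, s + 1)]


def _shift(arr: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Shift with zero fill: out[r, c] = arr[r - dr, c - dc]."""
    out = np.zeros_like(arr)
    h, w = arr.shape
    r0, r1 = max(dr, 0), min(h + dr, h)
    c0, c1 = max(dc, 0), min(w + dc, w)
    out[r0:r1, c0:c1] = arr[r0 - dr : r1 - dr, c0 - dc : c1 - dc]
    return out


def v1_simple_drive(
    l_now: np.ndarray,
    l_prev: np.ndarray,
    s: int,
    d: int,
    params: MotionParams = MotionParams(),
) -> np.ndarray:
    """Correlation drive B for one (speed, direction) channel.

    For each offset in ``phi_offsets(s, d)`` the present signal is summed
    with the previous-frame signal displaced *opposite* the preferred
    direction, thresholded and squared; contributions are averaged over the
    offsets that are active, and diagonal contributions are scaled by ``s``.
    """
    diag = d % 2 == 1
    acc = np.zeros_like(l_now)
    count = np.zeros_like(l_now)
    for dr, dc in phi_offsets(s, d):
        a = threshold(l_now + _shift(l_prev, dr, dc), params.gamma_lgn) ** 2
        if diag and params.diag_scale_by_speed:
            a = a * s
        acc += a
        count += a > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(count > 0, acc / np.maximum(count, 1), 0.0)
    return b


def flow_drive(flow: FlowField, params: MotionParams) -> np.ndarray:
    """Encode a flow field into channel drives, shape (n_speeds, 8, H, W).

    Direction tuning is rectified cosine (broad, 90 deg half-width at zero).
    Speed tuning mirrors the offset-inclusive correlation detector: channel
    ``s`` pools all pixel offsets up to ``s``, so it responds to any speed
    from ``speed_unit`` up to ``s * speed_unit`` (ramping up below one
    channel unit), cuts off above its own preferred speed, and the fastest
    channel stays open-ended.  Invalid pixels contribute nothing.
    """
    h, w = flow.shape
    mag = np.hypot(flow.u, flow.v)
    out = np.zeros((params.n_speeds, N_DIRECTIONS, h, w))
    valid = flow.valid & (mag > 1e-9)
    if not np.any(valid):
        return out
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(valid, flow.u / np.maximum(mag, 1e-12), 0.0)
        uy = np.where(valid, flow.v / np.maximum(mag, 1e-12), 0.0)
    m = mag / params.speed_unit  # speed in channel units
    for s in range(1, params.n_speeds + 1):
        ws = np.minimum(m, 1.0)  # sub-unit speeds drive all channels weakly
        # cut off above the preferred speed: a correlation detector with
        # offsets up to s px cannot match faster motion, so the fastest
        # channel is a band edge, not open-ended
        ws = ws * np.clip(1.0 - (m - s), 0.0, 1.0)
        ws = np.where(valid, ws, 0.0)
        for d in range(N_DIRECTIONS):
            ex, ey = direction_vector(d)
            wd = np.maximum(0.0, ux * ex + uy * ey)
            out[s - 1, d] = params.flow_gain * ws * wd
    return out


# ---------------------------------------------------------------------------
# grid resampling helpers (display <-> speed grids <-> heading grid)
# ---------------------------------------------------------------------------


def _from_display(arr: np.ndarray, spacing: int) -> np.ndarray:
    """Downsample a display-resolution array to a grid spaced ``spacing`` px."""
    if spacing == 1:
        return arr
    size = spacing if spacing % 2 == 1 else spacing + 1
    return uniform_filter(arr, size=size, mode="constant")[::spacing, ::spacing]


def _to_display(arr: np.ndarray, spacing: int, shape: tuple[int, int]) -> np.ndarray:
    """Bilinear upsample from a ``spacing``-px grid back to display resolution."""
    if spacing == 1:
        return arr
    h, w = shape
    rows = np.arange(h) / spacing
    cols = np.arange(w) / spacing
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return map_coordinates(arr, [rr, cc], order=1, mode="nearest")


def _grid_to_nodes(
    arr: np.ndarray, spacing: int, node_spacing: int, node_shape: tuple[int, int]
) -> np.ndarray:
    """Resample from a speed grid onto the heading (MSTd) node grid."""
    ratio = node_spacing / spacing
    if ratio >= 2:
        size = int(round(ratio))
        if size % 2 == 0:
            size += 1  # odd support keeps the filter mirror-symmetric
        arr = uniform_filter(arr, size=size, mode="constant")
    nh, nw = node_shape
    rows = np.arange(nh) * ratio
    cols = np.arange(nw) * ratio
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return map_coordinates(arr, [rr, cc], order=1, mode="nearest")


def _norm_correlate(arr: np.ndarray, kernel: np.ndarray, denom: np.ndarray) -> np.ndarray:
    """Zero-padded correlation with border renormalization."""
    return correlate(arr, kernel, mode="constant") / denom


def _border_denom(shape: tuple[int, int], kernel: np.ndarray) -> np.ndarray:
    d = correlate(np.ones(shape), kernel, mode="constant")
    return np.maximum(d, 1e-12)


# ---------------------------------------------------------------------------
# the full V1 <-> MT circuit
# ---------------------------------------------------------------------------


class MotionPathway:
    """Stateful V1 simple / complex / MT+ circuit on one image grid.

    Holds the layer states S (simple, per polarity), C (complex) and M (MT),
    advances them by one stimulus frame per call, and returns the
    speed-collapsed MT output N on the heading node grid.
    """

    def __init__(
        self,
        shape: tuple[int, int],
        node_spacing: int,
        params: MotionParams | None = None,
        frame_rate: float = 30.0,
        substeps: int = 1,
    ):
        self.params = params or MotionParams()
        self.shape = shape
        self.node_spacing = node_spacing
        h, w = shape
        self.node_shape = ((h - 1) // node_spacing + 1, (w - 1) // node_spacing + 1)
        self.substeps = substeps
        self.dt = 1.0 / (frame_rate * substeps)
        p = self.params
        ns = p.n_speeds
        self.S = np.zeros((2, ns, N_DIRECTIONS, h, w))  # polarity, speed, dir
        self.C = np.zeros((ns, N_DIRECTIONS, h, w))
        self.M = [
            np.zeros(
                (
                    N_DIRECTIONS,
                    (h - 1) // p.mt_spacings[s] + 1,
                    (w - 1) // p.mt_spacings[s] + 1,
                )
            )
            for s in range(ns)
        ]
        self._build_kernels()

    def _build_kernels(self) -> None:
        p = self.params
        h, w = self.shape
        self.k_par = {}
        self.k_orth = {}
        self.den_par = {}
        self.den_orth = {}
        self.k_fb = {}
        self.den_fb = {}
        for s in range(1, p.n_speeds + 1):
            sy = max(p.sigma_y_factor * s, 0.3)
            for d in range(N_DIRECTIONS):
                kp = anisotropic_kernel(sy, s, d, p.sigma_ratio)
                ko = anisotropic_kernel(sy, s, (d + 2) % N_DIRECTIONS, p.sigma_ratio)
                self.k_par[(s, d)] = kp
                self.k_orth[(s, d)] = ko
                self.den_par[(s, d)] = _border_denom((h, w), kp)
                self.den_orth[(s, d)] = _border_denom((h, w), ko)
            kf = gaussian_kernel(p.sigma_v1, 3 * s)
            self.k_fb[s] = kf
            self.den_fb[s] = _border_denom((h, w), kf)
        # collinear pooling of the MT output on the node grid
        self.k_out = {}
        self.den_out = {}
        for d in range(N_DIRECTIONS):
            ko = anisotropic_kernel(
                max(p.sigma_y_factor * p.out_pool_radius, 0.3),
                p.out_pool_radius,
                d,
                p.sigma_ratio,
            )
            self.k_out[d] = ko
            self.den_out[d] = _border_denom(self.node_shape, ko)

    # -- one stimulus frame ------------------------------------------------

    def step_flow(self, flow: FlowField) -> np.ndarray:
        """Advance one frame driven by an analytic flow field; return N."""
        b = flow_drive(flow, self.params)
        return self._advance(b[None, ...])

    def step_frames(
        self,
        l_on: np.ndarray,
        l_on_prev: np.ndarray,
        l_off: np.ndarray,
        l_off_prev: np.ndarray,
    ) -> np.ndarray:
        """Advance one frame driven by gated LGN signals; return N."""
        p = self.params
        b = np.zeros_like(self.S)
        for pol, (now, prev) in enumerate(((l_on, l_on_prev), (l_off, l_off_prev))):
            for s in range(1, p.n_speeds + 1):
                for d in range(N_DIRECTIONS):
                    b[pol, s - 1, d] = v1_simple_drive(now, prev, s, d, p)
        return self._advance(b)

    def _advance(self, b: np.ndarray) -> np.ndarray:
        """Sub-stepped joint update of S, C, M under constant frame drive ``b``."""
        p = self.params
        dt = self.dt
        n_pol = b.shape[0]
        for _ in range(self.substeps):
            for pol in range(n_pol):
                self.S[pol] = shunting_exp_step(
                    self.S[pol], b[pol], 0.0, dt, eps=p.eps_s
                )
            s_sum = self.S[:n_pol].sum(axis=0)
            q = threshold(s_sum, p.gamma_c) ** 2
            # MT feedback, per speed/direction, in display coordinates
            y = np.empty_like(self.C)
            for si in range(p.n_speeds):
                sp = p.mt_spacings[si]
                for d in range(N_DIRECTIONS):
                    md = _to_display(self.M[si][d], sp, self.shape)
                    y[si, d] = _norm_correlate(
                        md, self.k_fb[si + 1], self.den_fb[si + 1]
                    )
            c2 = self.C**2
            c2_tot = c2.sum(axis=1, keepdims=True)
            y_tot = y.sum(axis=1, keepdims=True)
            new_c = np.empty_like(self.C)
            mt_in = np.empty_like(self.C)
            for si in range(p.n_speeds):
                s = si + 1
                for d in range(N_DIRECTIONS):
                    qpar = _norm_correlate(
                        q[si, d], self.k_par[(s, d)], self.den_par[(s, d)]
                    )
                    qorth = _norm_correlate(
                        q[si, d], self.k_orth[(s, d)], self.den_orth[(s, d)]
                    )
                    exc = c2[si, d] + qpar
                    inh = (
                        (c2_tot[si, 0] - c2[si, d])
                        + (y_tot[si, 0] - y[si, d])
                        + qorth
                    )
                    new_c[si, d] = shunting_exp_step(
                        self.C[si, d], exc, inh, dt, eps=p.eps_c
                    )
            self.C = new_c
            o = sigmoid(threshold(self.C, p.gamma_v1mt) ** 2, p.f_v1mt)
            for si in range(p.n_speeds):
                s = si + 1
                sp = p.mt_spacings[si]
                for d in range(N_DIRECTIONS):
                    pooled = _norm_correlate(
                        o[si, d], self.k_par[(s, d)], self.den_par[(s, d)]
                    )
                    mt_in[si, d] = pooled
                    drive = _from_display(pooled, sp)
                    if p.printed_mt_form:
                        m = self.M[si][d]
                        self.M[si][d] = m + dt * p.eps_mt * (
                            -m * (1.0 - m) * drive
                        )
                    else:
                        self.M[si][d] = shunting_exp_step(
                            self.M[si][d], drive, 0.0, dt, eps=p.eps_mt
                        )
        return self._mt_output()

    def _mt_output(self) -> np.ndarray:
        """Speed-collapsed, collinearly pooled MT output N on the node grid."""
        p = self.params
        n = np.zeros((N_DIRECTIONS,) + self.node_shape)
        for d in range(N_DIRECTIONS):
            acc = np.zeros(self.node_shape)
            for si in range(p.n_speeds):
                acc += _grid_to_nodes(
                    self.M[si][d],
                    p.mt_spacings[si],
                    self.node_spacing,
                    self.node_shape,
                )
            pooled = _norm_correlate(acc, self.k_out[d], self.den_out[d])
            n[d] = threshold(pooled, p.gamma_mt) ** 2
        return n

    def decode_direction(self) -> np.ndarray:
        """Population-vector decode of MT activity, shape (2, H', W') = (u, v).

        Diagnostic readout: sums unit vectors weighted by the first speed
        channel's MT activity at each grid point.
        """
        m = self.M[0]
        u = np.zeros(m.shape[1:])
        v = np.zeros(m.shape[1:])
        for d in range(N_DIRECTIONS):
            ex, ey = direction_vector(d)
            u += m[d] * ex
            v += m[d] * ey
        return np.stack([u, v])
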