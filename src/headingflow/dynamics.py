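"""Numerical primitives shared by all model areas.

Every neural layer in the model obeys membrane-style shunting dynamics

    dx/dt = eps * ( -x + (1 - x) * E - x * I )

with excitatory drive ``E`` and inhibitory drive ``I`` (both nonnegative).
The multiplicative gating bounds activity in [0, 1] and implements divisive
normalization.  This module provides the forward-Euler integrator for that
equation, the sigmoid / threshold nonlinearities used for recurrent signals,
and the normalized isotropic and anisotropic Gaussian kernels that define
inter-layer connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "N_DIRECTIONS",
    "direction_angle",
    "direction_vector",
    "mirror_direction",
    "sigmoid",
    "threshold",
    "gaussian_kernel",
    "anisotropic_kernel",
    "shunting_step",
    "ShuntingParams",
    "StabilityError",
]

#: number of motion-direction channels (cardinals + diagonals)
N_DIRECTIONS = 8


class StabilityError(ValueError):
    """Raised when an Euler step would violate the documented stability bound."""


def direction_angle(d: int) -> float:
    """Angle (rad, math convention, y up) of direction channel ``d``.

    The eight channels are spaced 45 deg apart; ``d = 0`` is rightward and the
    index increases counter-clockwise, so ``d`` and ``d + 4`` are opponent.
    """
    return d * np.pi / 4.0


def direction_vector(d: int) -> tuple[float, float]:
    """Unit vector ``(dx, dy_screen)`` for channel ``d`` in image coordinates.

    Image rows increase downward, so the screen y component is the negative
    sine of the math-convention angle.
    """
    th = direction_angle(d)
    return float(np.cos(th)), float(-np.sin(th))


def mirror_direction(d: int) -> int:
    """Direction channel of the left-right mirrored stimulus (theta -> pi - theta)."""
    return (4 - d) % N_DIRECTIONS


def sigmoid(w, f0: float):
    """Faster-than-linear sigmoid ``w^2 / (w^2 + f0^2)``.

    Reaches its half-maximum 0.5 at ``w = f0``; saturates at 1.  Used for
    recurrent signals, where its expansive lower branch produces soft
    winner-take-all competition.
    """
    if f0 <= 0:
        raise ValueError("sigmoid inflection f0 must be positive")
    w = np.asarray(w, dtype=float)
    w2 = w * w
    return w2 / (w2 + f0 * f0)


def threshold(w, gamma: float):
    """Half-wave rectification about ``gamma``: ``max(w - gamma, 0)``."""
    return np.maximum(np.asarray(w, dtype=float) - gamma, 0.0)


def gaussian_kernel(sigma: float, radius: int) -> np.ndarray:
    """Normalized isotropic Gaussian on a ``(2*radius+1)**2`` support.

    Entries sum to exactly 1; ``sigma`` is in pixels of the grid the kernel is
    applied to.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    ax = np.arange(-radius, radius + 1, dtype=float)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    k = np.exp(-(xx * xx + yy * yy) / (2.0 * sigma * sigma))
    return k / k.sum()


def anisotropic_kernel(
    sigma_y: float, radius: int, d: int, sigma_ratio: float
) -> np.ndarray:
    """Normalized anisotropic Gaussian elongated along direction channel ``d``.

    ``sigma_ratio`` = sigma_x / sigma_y sets the elongation parallel to the
    preferred direction; ``sigma_y`` is the absolute cross-axis width.  The
    support is rotated by the channel angle.  With ``sigma_ratio == 1`` the
    kernel reduces to :func:`gaussian_kernel`.
    """
    if sigma_y <= 0 or sigma_ratio <= 0:
        raise ValueError("kernel widths must be positive")
    th = direction_angle(d)
    sx = sigma_ratio * sigma_y
    ax = np.arange(-radius, radius + 1, dtype=float)
    # screen coords: row = -y
    yy, xx = np.meshgrid(-ax, ax, indexing="ij")
    # rotate offsets into the kernel frame (x' along the preferred direction)
    xr = np.cos(th) * xx + np.sin(th) * yy
    yr = -np.sin(th) * xx + np.cos(th) * yy
    k = np.exp(-0.5 * ((xr / sx) ** 2 + (yr / sigma_y) ** 2))
    return k / k.sum()


@dataclass
class ShuntingParams:
    """Integration parameters for one shunting layer.

    eps
        Inverse time constant in 1/s.  Layers whose equation carries no
        explicit rate use ``eps = 1``.
    dt
        Euler step in seconds (frame interval divided by ``substeps``).
    substeps
        Euler sub-steps per stimulus frame.
    """

    eps: float = 1.0
    dt: float = 1.0 / 60.0
    substeps: int = 2

    def __post_init__(self):
        if self.eps <= 0 or self.dt <= 0 or self.substeps < 1:
            raise ValueError("eps, dt must be positive and substeps >= 1")


def shunting_step(x, exc, inh, dt: float, eps: float = 1.0, check: bool = True):
    """One forward-Euler update of the shunting equation.

    ``x' = x + dt*eps*(-x + (1 - x)*exc - x*inh)``.

    The update provably stays in [0, 1] whenever
    ``dt * eps * (1 + exc + inh) <= 1`` pointwise; with ``check`` on, a step
    that violates that bound raises :class:`StabilityError` rather than
    silently clipping.
    """
    x = np.asarray(x, dtype=float)
    exc = np.asarray(exc, dtype=float)
    inh = np.asarray(inh, dtype=float)
    if check:
        lim = dt * eps * (1.0 + exc + inh)
        m = np.max(lim) if lim.size else 0.0
        if m > 1.0:
            raise StabilityError(
                f"Euler step unstable: dt*eps*(1+E+I) = {m:.3f} > 1; "
                "reduce dt or increase substeps"
            )
    return x + dt * eps * (-x + (1.0 - x) * exc - x * inh)


def shunting_exp_step(x, exc, inh, dt: float, eps: float = 1.0):
    """Exponential-Euler update of the shunting equation.

    Holding the drives constant over the step, the equation is linear,
    ``dx/dt = -a x + b`` with ``a = eps*(1 + exc + inh)`` and
    ``b = eps*exc``, and the update ``x' = b/a + (x - b/a) * exp(-a dt)``
    is exact.  Unconditionally stable and bounded in [0, 1], which makes it
    the integrator of choice for the fast cortical layers whose rates would
    otherwise force very small Euler steps.
    """
    x = np.asarray(x, dtype=float)
    exc = np.asarray(exc, dtype=float)
    inh = np.asarray(inh, dtype=float)
    a = eps * (1.0 + exc + inh)
    xeq = eps * exc / a
    return xeq + (x - xeq) * np.exp(-a * dt)
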