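"""Change sensitivity: retinal ON/OFF transients and habituative LGN gating.

The retina converts a luminance sequence into rectified frame-to-frame
increment (ON) and decrement (OFF) signals.  LGN units leakily integrate
those transients and are multiplicatively gated by a slow habituative
transmitter: sustained input depletes the gate, so the LGN output responds
well to motion and only weakly to anything stationary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import shunting_step

__all__ = ["retina_transients", "LgnParams", "LgnState"]


def retina_transients(
    frame_t: np.ndarray, frame_prev: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Rectified luminance increments (ON) and decrements (OFF).

    ``frame_prev = None`` pairs the first frame with a blank (zero) frame.
    The two signals are complementary: at any pixel at most one is nonzero.
    """
    frame_t = np.asarray(frame_t, dtype=float)
    if frame_prev is None:
        frame_prev = np.zeros_like(frame_t)
    frame_prev = np.asarray(frame_prev, dtype=float)
    if frame_prev.shape != frame_t.shape:
        raise ValueError("frame shapes differ")
    d = frame_t - frame_prev
    return np.maximum(d, 0.0), np.maximum(-d, 0.0)


@dataclass(frozen=True)
class LgnParams:
    """LGN rates: integration (1/s), gate recovery (1/s), depletion gain."""

    eps_r: float = 2.0
    eps_z: float = 0.01
    lam: float = 10.0
    #: use the gate law exactly as printed, dZ/dt = eps*(1 - R - lam*R*Z).
    #: The printed form grows without bound when R = 0, contradicting the
    #: described recovery toward full capacity, so the standard habituative
    #: form dZ/dt = eps*((1 - Z) - lam*R*Z) is the default.
    printed_gate_form: bool = False


@dataclass
class LgnState:
    """ON/OFF drive ``r`` and transmitter gates ``z`` (full at rest)."""

    r_on: np.ndarray
    r_off: np.ndarray
    z_on: np.ndarray
    z_off: np.ndarray
    params: LgnParams = field(default_factory=LgnParams)

    @classmethod
    def zeros(cls, shape, params: LgnParams | None = None) -> "LgnState":
        p = params or LgnParams()
        return cls(
            r_on=np.zeros(shape),
            r_off=np.zeros(shape),
            z_on=np.ones(shape),
            z_off=np.ones(shape),
            params=p,
        )

    def step(self, j_on: np.ndarray, j_off: np.ndarray, dt: float) -> None:
        """Advance one Euler step of duration ``dt`` (s) under retinal drive."""
        p = self.params
        for r_name, z_name, j in (
            ("r_on", "z_on", j_on),
            ("r_off", "z_off", j_off),
        ):
            r = getattr(self, r_name)
            z = getattr(self, z_name)
            r_new = shunting_step(r, j, 0.0, dt, eps=p.eps_r)
            if p.printed_gate_form:
                dz = p.eps_z * (1.0 - r - p.lam * r * z)
            else:
                dz = p.eps_z * ((1.0 - z) - p.lam * r * z)
            setattr(self, r_name, r_new)
            setattr(self, z_name, np.maximum(z + dt * dz, 0.0))

    @property
    def l_on(self) -> np.ndarray:
        """Gated ON output [R+ Z+]^+."""
        return np.maximum(self.r_on * self.z_on, 0.0)

    @property
    def l_off(self) -> np.ndarray:
        """Gated OFF output [R- Z-]^+."""
        return np.maximum(self.r_off * self.z_off, 0.0)
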