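"""End-to-end competitive dynamics model: change sensitivity -> motion ->
recurrent heading competition.

The model is a single coupled dynamical system integrated at the stimulus
frame rate with Euler sub-steps: each frame's input (rendered video through
the retina/LGN front end, or an analytic flow field through the flow drive)
updates V1 simple cells, the V1-complex/MT+ feedback loop, and the MSTd
recurrent competitive field.  The heading estimate at every frame is the
preferred azimuth of the most active expansion-tuned MSTd unit on the
horizontal cross-section through the true heading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .frontend import LgnParams, LgnState, retina_transients
from .motion import MotionParams, MotionPathway
from .mstd import (
    HeadingTrace,
    MstdParams,
    MstdState,
    build_templates,
    node_azimuths,
    node_elevations,
    population_variance,
    read_heading,
    template_match,
)
from .stimulus import CameraModel, FlowField

__all__ = ["CompetitiveModelConfig", "CompetitiveDynamicsModel"]


@dataclass(frozen=True)
class CompetitiveModelConfig:
    camera: CameraModel = field(default_factory=CameraModel)
    node_spacing: int = 2
    motion: MotionParams = field(default_factory=MotionParams)
    mstd: MstdParams = field(default_factory=MstdParams)
    lgn: LgnParams = field(default_factory=LgnParams)
    substeps: int = 1


class CompetitiveDynamicsModel:
    """Stateful model instance; build one per trial (fresh network state)."""

    def __init__(self, config: CompetitiveModelConfig | None = None):
        self.config = config or CompetitiveModelConfig()
        cfg = self.config
        cam = cfg.camera
        self.pathway = MotionPathway(
            (cam.height, cam.width),
            cfg.node_spacing,
            params=cfg.motion,
            frame_rate=cam.frame_rate,
            substeps=cfg.substeps,
        )
        self.bank = build_templates(
            self.pathway.node_shape, cfg.mstd.sigma_template
        )
        self.mstd = MstdState.zeros(self.pathway.node_shape, cfg.mstd)
        self._az = node_azimuths(cam, cfg.node_spacing, self.pathway.node_shape[1])
        self._el = node_elevations(cam, cfg.node_spacing, self.pathway.node_shape[0])
        self._dt = 1.0 / (cam.frame_rate * cfg.substeps)

    # -- per-frame core ----------------------------------------------------

    def _finish_frame(self, n: np.ndarray) -> None:
        v = template_match(n, self.bank)
        # the competitive field is the stiffest layer (total-activity
        # inhibition); integrate it on a twice-finer grid, which is cheap
        # relative to the convolutional motion stages
        for _ in range(self.config.substeps * 2):
            self.mstd.step(v, self._dt / 2.0)

    def _readout(self) -> tuple[float, float]:
        cam = self.config.camera
        est = read_heading(self.mstd.p[0], cam, self.config.node_spacing)
        var = population_variance(self.mstd.p[0], self._az, self._el)
        return est, var

    # -- public runs -------------------------------------------------------

    def run_flow(
        self,
        flows: list[FlowField],
        epochs: np.ndarray | None = None,
        record_mstd: bool = False,
    ) -> HeadingTrace:
        """Integrate a trial from analytic flow fields (one per frame pair)."""
        cam = self.config.camera
        n_t = len(flows)
        est = np.full(n_t, np.nan)
        var = np.full(n_t, np.nan)
        self.mstd_history = [] if record_mstd else None
        for k, flow in enumerate(flows):
            n = self.pathway.step_flow(flow)
            self._finish_frame(n)
            est[k], var[k] = self._readout()
            if record_mstd:
                self.mstd_history.append(self.mstd.p.copy())
        t = (np.arange(n_t) + 1) / cam.frame_rate
        if epochs is None:
            epochs = np.array(["before"] * n_t)
        return HeadingTrace(
            time_s=t,
            estimate_deg=est,
            error_deg=est.copy(),
            pop_variance=var,
            epoch=np.asarray(epochs),
            model="competitive_dynamics",
        )

    def run_frames(
        self, frames: np.ndarray, epochs: np.ndarray | None = None
    ) -> HeadingTrace:
        """Integrate a trial from grayscale video frames (T, H, W) in [0, 1]."""
        cam = self.config.camera
        frames = np.asarray(frames, dtype=float)
        n_t = frames.shape[0]
        lgn = LgnState.zeros(frames.shape[1:], self.config.lgn)
        l_on_prev = np.zeros(frames.shape[1:])
        l_off_prev = np.zeros(frames.shape[1:])
        prev_frame = None
        est = np.full(n_t, np.nan)
        var = np.full(n_t, np.nan)
        for k in range(n_t):
            j_on, j_off = retina_transients(frames[k], prev_frame)
            lgn.step(j_on, j_off, cam.dt)
            l_on, l_off = lgn.l_on, lgn.l_off
            n = self.pathway.step_frames(l_on, l_on_prev, l_off, l_off_prev)
            self._finish_frame(n)
            est[k], var[k] = self._readout()
            l_on_prev, l_off_prev = l_on, l_off
            prev_frame = frames[k]
        t = (np.arange(n_t) + 1) / cam.frame_rate
        if epochs is None:
            epochs = np.array(["before"] * n_t)
        return HeadingTrace(
            time_s=t,
            estimate_deg=est,
            error_deg=est.copy(),
            pop_variance=var,
            epoch=np.asarray(epochs),
            model="competitive_dynamics",
        )
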