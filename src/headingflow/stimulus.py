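"""Dot-world stimulus generation and analytic optic flow.

The simulated scenes reproduce the displays used in moving-object heading
experiments: an observer translating straight ahead at 200 cm/s toward two
frontoparallel planes of random dots (3000 dots each, initially 800 and
1000 cm away), with an optional rectangular moving object (150 x 150 cm,
320 dots) that crosses the observer's future path.  Trials last 1.5 s
rendered at 30 frames/s (45 frames).

The module produces three synchronized views of each trial:

* a 3D :class:`DotWorld` per frame (camera-frame coordinates, cm),
* analytic optic flow via pinhole projection (:func:`project_flow`), both as
  per-dot samples and rasterized onto the image grid, and
* rendered grayscale dot frames (:func:`render_frames`) for the image-computable
  motion pathway.

Object trajectories follow the printed condition table.  Positive trajectory
angles denote approach and are measured in world coordinates from the
observer's line of travel (so equal object/observer speeds place the
object-region focus of expansion at half the trajectory angle).  Negative
angles denote retreat and are read as observer-relative velocities, which
makes the retreating object recede in depth as described; the fixed-depth
condition clamps the object's depth-rate to the observer's so relative depth
stays constant.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CameraModel",
    "ObjectTrajectory",
    "BlankObject",
    "TrialConfig",
    "DotWorld",
    "FlowField",
    "TABLE1",
    "OBSERVER_SPEED",
    "object_relative_velocity",
    "object_foe_azimuth",
    "build_scene",
    "advance_world",
    "simulate_worlds",
    "project_flow",
    "flow_sequence",
    "render_frames",
    "apply_laminar_perturbation",
    "horn_schunck",
    "write_flo",
    "read_flo",
    "write_flow_text",
]

#: observer translation speed, cm/s, straight ahead
OBSERVER_SPEED = 200.0


# ---------------------------------------------------------------------------
# camera
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera.

    The image is indexed (row, col) with the origin top-left; the optical
    axis pierces the image at ``(cy, cx)`` = ((height-1)/2, (width-1)/2),
    which corresponds to the 0 deg straight-ahead heading.  ``fov_deg`` is
    the full horizontal field of view; the focal length in pixels follows
    from it.  Default view geometry is a 100 deg horizontal field, wide
    enough to contain every object trajectory in the condition table.
    """

    width: int = 129
    height: int = 97
    fov_deg: float = 100.0
    frame_rate: float = 30.0

    def __post_init__(self):
        if self.width < 3 or self.height < 3:
            raise ValueError("image must be at least 3x3")
        if not (0 < self.fov_deg < 180):
            raise ValueError("fov_deg must be in (0, 180)")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def focal_px(self) -> float:
        return (self.width / 2.0) / np.tan(np.radians(self.fov_deg) / 2.0)

    @property
    def cx(self) -> float:
        return (self.width - 1) / 2.0

    @property
    def cy(self) -> float:
        return (self.height - 1) / 2.0

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    def project(self, pos: np.ndarray) -> np.ndarray:
        """Project (N, 3) camera-frame points (cm) to (N, 2) pixel (x, y).

        World axes: x right, y up, z forward (depth).  Image y grows
        downward.  Points at or behind the camera plane produce NaN.
        """
        pos = np.asarray(pos, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            x = self.cx + self.focal_px * pos[:, 0] / pos[:, 2]
            y = self.cy - self.focal_px * pos[:, 1] / pos[:, 2]
        bad = pos[:, 2] <= 1e-6
        x = np.where(bad, np.nan, x)
        y = np.where(bad, np.nan, y)
        return np.stack([x, y], axis=1)

    def px_to_deg(self, x_px) -> np.ndarray:
        """Azimuth (deg, rightward positive) of an image column."""
        return np.degrees(np.arctan2(np.asarray(x_px, float) - self.cx, self.focal_px))

    def deg_to_px(self, az_deg) -> np.ndarray:
        """Image column of an azimuth (inverse of :meth:`px_to_deg`)."""
        return self.cx + self.focal_px * np.tan(np.radians(np.asarray(az_deg, float)))

    def in_bounds(self, xy: np.ndarray) -> np.ndarray:
        x, y = xy[:, 0], xy[:, 1]
        return (
            np.isfinite(x)
            & np.isfinite(y)
            & (x >= 0)
            & (x <= self.width - 1)
            & (y >= 0)
            & (y <= self.height - 1)
        )


# ---------------------------------------------------------------------------
# trial configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ObjectTrajectory:
    """Initial position and motion of the moving object.

    lateral_offset
        Starting lateral distance (cm) left of the observer's path; the
        object always starts on the left and moves rightward.
    depth
        Starting depth (cm).
    speed
        Object speed (cm/s) along its trajectory.
    angle_deg
        Trajectory angle; positive = approach (world-frame, measured from the
        line of travel), negative = retreat (observer-relative).
    fixed_depth
        Clamp the object's world depth-rate to the observer's speed so the
        relative depth never changes.
    """

    lateral_offset: float
    depth: float
    speed: float
    angle_deg: float
    fixed_depth: bool = False

    def __post_init__(self):
        if self.depth <= 0 or self.speed < 0 or self.lateral_offset < 0:
            raise ValueError("invalid object trajectory")


@dataclass(frozen=True)
class BlankObject:
    """Textureless opaque rectangle: occludes dots but emits none."""

    lateral: float  # center x, cm (signed)
    depth: float  # cm
    width: float = 150.0
    height: float = 150.0
    # observer-relative velocity (cm/s); default stationary in the scene
    vx: float = 0.0
    vz: float = -OBSERVER_SPEED


#: printed condition table: lateral offset (cm), depth (cm), speed (cm/s), angle (deg)
TABLE1: dict[str, dict] = {
    "approach_15": dict(lateral_offset=100, depth=900, speed=200, angle_deg=15),
    "approach_70": dict(lateral_offset=400, depth=600, speed=200, angle_deg=70),
    "fixed_depth": dict(
        lateral_offset=200, depth=250, speed=200, angle_deg=-45, fixed_depth=True
    ),
    "retreating": dict(lateral_offset=150, depth=100, speed=300, angle_deg=-56),
    "pseudo_foe_sweep": dict(lateral_offset=150, depth=400, speed=200, angle_deg=70),
    "pseudo_foe": dict(lateral_offset=170, depth=600, speed=200, angle_deg=45),
}


@dataclass(frozen=True)
class TrialConfig:
    """Everything needed to regenerate one trial deterministically."""

    camera: CameraModel = field(default_factory=CameraModel)
    obj: ObjectTrajectory | None = None
    blank: BlankObject | None = None
    observer_speed: float = OBSERVER_SPEED
    n_frames: int = 45
    plane_depths: tuple[float, ...] = (800.0, 1000.0)
    dots_per_plane: int = 3000
    object_dots: int = 320
    object_size: float = 150.0
    object_opaque: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.obj is not None:
            v = object_relative_velocity(self.obj, self.observer_speed)
            t = np.arange(self.n_frames) * self.camera.dt
            z = self.obj.depth + v[2] * t
            if np.any(z <= 0):
                raise ValueError("object depth reaches zero during the trial")


def object_relative_velocity(
    obj: ObjectTrajectory, observer_speed: float = OBSERVER_SPEED
) -> np.ndarray:
    """Object velocity (cm/s) in the observer's reference frame.

    Approach (positive angle): world velocity (s*sin a, 0, -s*cos a) minus
    the observer's forward translation.  Retreat (negative angle): read
    directly as an observer-relative velocity receding in depth.
    Fixed-depth: purely lateral relative motion.
    """
    a = np.radians(abs(obj.angle_deg))
    s = obj.speed
    if obj.fixed_depth:
        return np.array([s * np.sin(a), 0.0, 0.0])
    if obj.angle_deg >= 0:
        return np.array([s * np.sin(a), 0.0, -s * np.cos(a) - observer_speed])
    return np.array([s * np.sin(a), 0.0, s * np.cos(a)])


def object_foe_azimuth(
    obj: ObjectTrajectory, observer_speed: float = OBSERVER_SPEED
) -> float:
    """Azimuth (deg, signed) of the object-region focus of expansion.

    The flow of a rigidly translating object vanishes along the direction of
    its relative velocity; for relative velocity (vx, vy, vz) with vz < 0
    (approach) the image singularity sits at azimuth atan(vx / vz), i.e. on
    the side *opposite* the lateral motion.  For equal object and observer
    speeds at trajectory angle theta this reduces to the half-angle
    theta / 2 in magnitude.
    """
    v = object_relative_velocity(obj, observer_speed)
    if v[2] >= 0:
        raise ValueError("object is not approaching: no focus of expansion")
    return float(np.degrees(np.arctan(v[0] / v[2])))


# ---------------------------------------------------------------------------
# scene construction and kinematics
# ---------------------------------------------------------------------------


@dataclass
class DotWorld:
    """Camera-frame dot positions (cm) for one instant of a trial.

    ``owner`` codes the surface each dot belongs to: 0.. for the background
    planes, -1 for the moving object.  The object's occluding rectangle is
    tracked analytically (center + size) so occlusion does not depend on the
    random dot sample.
    """

    pos: np.ndarray  # (N, 3) float
    owner: np.ndarray  # (N,) int
    object_center: np.ndarray | None = None  # (3,) cm
    object_size: float = 150.0
    object_opaque: bool = True
    blank_center: np.ndarray | None = None
    blank_size: tuple[float, float] = (150.0, 150.0)

    @property
    def n_dots(self) -> int:
        return self.pos.shape[0]


def build_scene(config: TrialConfig, rng: np.random.Generator | None = None) -> DotWorld:
    """Random dot placement for frame 0 of a trial.

    Background dots are uniform on each frontoparallel plane, spanning the
    full field of view at the plane's depth; object dots are uniform on the
    object rectangle.  Deterministic given ``config.seed``.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cam = config.camera
    half_fov_x = np.radians(cam.fov_deg) / 2.0
    half_fov_y = np.arctan2(cam.height / 2.0, cam.focal_px)
    pos_list, owner_list = [], []
    for k, z in enumerate(config.plane_depths):
        hw = z * np.tan(half_fov_x)
        hh = z * np.tan(half_fov_y)
        x = rng.uniform(-hw, hw, config.dots_per_plane)
        y = rng.uniform(-hh, hh, config.dots_per_plane)
        pos_list.append(np.stack([x, y, np.full_like(x, z)], axis=1))
        owner_list.append(np.full(config.dots_per_plane, k, dtype=int))
    object_center = None
    if config.obj is not None:
        object_center = np.array(
            [-config.obj.lateral_offset, 0.0, config.obj.depth]
        )
        h = config.object_size / 2.0
        x = rng.uniform(-h, h, config.object_dots) + object_center[0]
        y = rng.uniform(-h, h, config.object_dots) + object_center[1]
        pos_list.append(
            np.stack([x, y, np.full_like(x, object_center[2])], axis=1)
        )
        owner_list.append(np.full(config.object_dots, -1, dtype=int))
    blank_center = None
    blank_size = (150.0, 150.0)
    if config.blank is not None:
        blank_center = np.array(
            [config.blank.lateral, 0.0, config.blank.depth]
        )
        blank_size = (config.blank.width, config.blank.height)
    return DotWorld(
        pos=np.concatenate(pos_list, axis=0),
        owner=np.concatenate(owner_list, axis=0),
        object_center=object_center,
        object_size=config.object_size,
        object_opaque=config.object_opaque,
        blank_center=blank_center,
        blank_size=blank_size,
    )


def advance_world(world: DotWorld, config: TrialConfig, frame_index: int) -> DotWorld:
    """World one frame interval later (observer translation applied as scene motion)."""
    if frame_index >= config.n_frames:
        raise ValueError("frame_index beyond the trial")
    dt = config.camera.dt
    pos = world.pos.copy()
    bg = world.owner >= 0
    pos[bg, 2] -= config.observer_speed * dt
    object_center = world.object_center
    if config.obj is not None and object_center is not None:
        v = object_relative_velocity(config.obj, config.observer_speed)
        pos[world.owner == -1] += v * dt
        object_center = object_center + v * dt
    blank_center = world.blank_center
    if config.blank is not None and blank_center is not None:
        blank_center = blank_center + np.array(
            [config.blank.vx, 0.0, config.blank.vz]
        ) * dt
    return replace(world, pos=pos, object_center=object_center, blank_center=blank_center)


def simulate_worlds(config: TrialConfig) -> list[DotWorld]:
    """The full per-frame world sequence for one trial (length ``n_frames``)."""
    worlds = [build_scene(config)]
    for k in range(1, config.n_frames):
        worlds.append(advance_world(worlds[-1], config, k))
    return worlds


def _occluded(world: DotWorld) -> np.ndarray:
    """Mask of dots hidden behind the opaque object or the blank occluder."""
    hidden = np.zeros(world.n_dots, dtype=bool)
    occluders: list[tuple[np.ndarray, float, float, int | None]] = []
    if world.object_center is not None and world.object_opaque:
        occluders.append(
            (world.object_center, world.object_size, world.object_size, -1)
        )
    if world.blank_center is not None:
        occluders.append((world.blank_center, *world.blank_size, None))
    for center, w, h, own in occluders:
        if center[2] <= 0:
            continue
        z = world.pos[:, 2]
        behind = z > center[2]
        if own is not None:
            behind &= world.owner != own
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = center[2] / z
            xi = world.pos[:, 0] * scale
            yi = world.pos[:, 1] * scale
        inside = (np.abs(xi - center[0]) <= w / 2.0) & (
            np.abs(yi - center[1]) <= h / 2.0
        )
        hidden |= behind & inside
    return hidden


def _visible(world: DotWorld, cam: CameraModel):
    """(projection, visibility mask) for one world."""
    xy = cam.project(world.pos)
    vis = cam.in_bounds(xy) & (world.pos[:, 2] > 1e-6) & ~_occluded(world)
    return xy, vis


# ---------------------------------------------------------------------------
# analytic optic flow
# ---------------------------------------------------------------------------


@dataclass
class FlowField:
    """Optic flow for one frame transition.

    Dense image-grid arrays ``u, v`` (px/frame, v positive downward) with a
    validity mask, plus the underlying per-dot samples.  The dense raster is
    nearest-pixel with a z-buffer (nearest dot wins a contested pixel).
    """

    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    sample_xy: np.ndarray  # (M, 2) px at frame t
    sample_uv: np.ndarray  # (M, 2) px/frame
    sample_depth: np.ndarray  # (M,) cm
    sample_owner: np.ndarray  # (M,) int
    frame_index: int = 0

    @property
    def shape(self):
        return self.u.shape

    def mirrored(self) -> "FlowField":
        """Left-right mirror (x -> W-1-x, u -> -u)."""
        w = self.u.shape[1]
        sxy = self.sample_xy.copy()
        sxy[:, 0] = (w - 1) - sxy[:, 0]
        suv = self.sample_uv.copy()
        suv[:, 0] = -suv[:, 0]
        return FlowField(
            u=-self.u[:, ::-1].copy(),
            v=self.v[:, ::-1].copy(),
            valid=self.valid[:, ::-1].copy(),
            sample_xy=sxy,
            sample_uv=suv,
            sample_depth=self.sample_depth.copy(),
            sample_owner=self.sample_owner.copy(),
            frame_index=self.frame_index,
        )


def project_flow(
    world_t: DotWorld,
    world_t1: DotWorld,
    cam: CameraModel,
    frame_index: int = 0,
) -> FlowField:
    """Per-dot image displacement between two consecutive worlds.

    A dot contributes a flow sample when it is visible (in bounds, in front
    of the camera, not occluded) at frame t and projects to a finite position
    at t+1.  Background dots geometrically behind the opaque object (or the
    blank occluder) are excluded.
    """
    if world_t.n_dots != world_t1.n_dots:
        raise ValueError("worlds must contain the same dots")
    xy0, vis0 = _visible(world_t, cam)
    xy1 = cam.project(world_t1.pos)
    ok = vis0 & np.isfinite(xy1).all(axis=1)
    uv = xy1[ok] - xy0[ok]
    sxy = xy0[ok]
    depth = world_t.pos[ok, 2]
    owner = world_t.owner[ok]

    h, w = cam.height, cam.width
    u = np.zeros((h, w))
    v = np.zeros((h, w))
    valid = np.zeros((h, w), dtype=bool)
    zbuf = np.full((h, w), np.inf)
    cols = np.clip(np.round(sxy[:, 0]).astype(int), 0, w - 1)
    rows = np.clip(np.round(sxy[:, 1]).astype(int), 0, h - 1)
    # nearest dot wins each pixel
    order = np.argsort(-depth)
    for i in order:
        r, c = rows[i], cols[i]
        if depth[i] < zbuf[r, c]:
            zbuf[r, c] = depth[i]
            u[r, c] = uv[i, 0]
            v[r, c] = uv[i, 1]
            valid[r, c] = True
    return FlowField(
        u=u,
        v=v,
        valid=valid,
        sample_xy=sxy,
        sample_uv=uv,
        sample_depth=depth,
        sample_owner=owner,
        frame_index=frame_index,
    )


def flow_sequence(config: TrialConfig) -> list[FlowField]:
    """Analytic flow for every frame transition of a trial (length n_frames - 1)."""
    worlds = simulate_worlds(config)
    return [
        project_flow(worlds[k], worlds[k + 1], config.camera, frame_index=k)
        for k in range(len(worlds) - 1)
    ]


def apply_laminar_perturbation(
    flows: list[FlowField],
    n_frames: int,
    onset: int,
    u: float = 2.0,
    v: float = 0.0,
) -> list[FlowField]:
    """Replace ``n_frames`` contiguous flow fields with uniform laminar flow.

    Every valid vector in the affected frames is set to ``(u, v)`` px/frame
    (default rightward at a mid-range detectable speed); other frames are
    returned untouched.  ``n_frames = 0`` is the identity.
    """
    if n_frames < 0:
        raise ValueError("n_frames must be nonnegative")
    if n_frames and (onset < 0 or onset + n_frames > len(flows)):
        raise ValueError("perturbation window outside the trial")
    out = []
    for k, f in enumerate(flows):
        if n_frames and onset <= k < onset + n_frames:
            uu = np.where(f.valid, u, 0.0)
            vv = np.where(f.valid, v, 0.0)
            suv = np.tile([u, v], (f.sample_uv.shape[0], 1)).astype(float)
            out.append(
                replace(f, u=uu, v=vv, sample_uv=suv)
            )
        else:
            out.append(f)
    return out


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def render_frames(
    worlds: list[DotWorld], cam: CameraModel, dot_radius: float = 1.0
) -> np.ndarray:
    """Grayscale frames (T, H, W) in [0, 1]: white dots on black.

    Dots are splatted as small Gaussians at sub-pixel positions so that slow
    motion produces graded luminance change.  The blank occluder region
    contains no texture (it renders black, like the background).
    """
    sig = max(0.5, 0.6 * dot_radius)
    r = int(np.ceil(3 * sig))
    frames = np.zeros((len(worlds), cam.height, cam.width))
    for t, world in enumerate(worlds):
        xy, vis = _visible(world, cam)
        img = frames[t]
        for x, y in xy[vis]:
            c0, r0 = int(np.floor(x)) - r, int(np.floor(y)) - r
            cols = np.arange(c0, c0 + 2 * r + 2)
            rows = np.arange(r0, r0 + 2 * r + 2)
            cc = cols[(cols >= 0) & (cols < cam.width)]
            rr = rows[(rows >= 0) & (rows < cam.height)]
            if cc.size == 0 or rr.size == 0:
                continue
            g = np.exp(
                -(
                    (rr[:, None] - y) ** 2 + (cc[None, :] - x) ** 2
                )
                / (2 * sig * sig)
            )
            img[np.ix_(rr, cc)] += g
        np.clip(img, 0.0, 1.0, out=img)
    return frames


# ---------------------------------------------------------------------------
# Horn-Schunck optical flow (for feeding the baselines from video)
# ---------------------------------------------------------------------------


def horn_schunck(
    frames: np.ndarray, alpha: float = 1.0, n_iter: int = 100
) -> list[FlowField]:
    """Classic global-smoothness optical flow on a grayscale frame stack.

    Minimizes the brightness-constancy residual plus ``alpha``-weighted
    smoothness with Jacobi iterations.  Returns one dense :class:`FlowField`
    per frame pair; all pixels are marked valid (the estimate is dense by
    construction).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a (T, H, W) stack with at least 2 frames")
    from scipy.ndimage import correlate

    lap = np.array(
        [[1 / 12, 1 / 6, 1 / 12], [1 / 6, 0.0, 1 / 6], [1 / 12, 1 / 6, 1 / 12]]
    )
    kx = np.array([[-1, 1], [-1, 1]]) * 0.25
    ky = np.array([[-1, -1], [1, 1]]) * 0.25
    kt = np.ones((2, 2)) * 0.25
    out = []
    for k in range(frames.shape[0] - 1):
        a, b = frames[k], frames[k + 1]
        ix = correlate(a, kx) + correlate(b, kx)
        iy = correlate(a, ky) + correlate(b, ky)
        it = correlate(b, kt) - correlate(a, kt)
        u = np.zeros_like(a)
        v = np.zeros_like(a)
        denom = alpha * alpha + ix * ix + iy * iy
        for _ in range(n_iter):
            ubar = correlate(u, lap)
            vbar = correlate(v, lap)
            t = (ix * ubar + iy * vbar + it) / denom
            u = ubar - ix * t
            v = vbar - iy * t
        h, w = a.shape
        yy, xx = np.mgrid[0:h, 0:w]
        out.append(
            FlowField(
                u=u,
                v=v,
                valid=np.ones_like(a, dtype=bool),
                sample_xy=np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float),
                sample_uv=np.stack([u.ravel(), v.ravel()], axis=1),
                sample_depth=np.full(a.size, np.nan),
                sample_owner=np.zeros(a.size, dtype=int),
                frame_index=k,
            )
        )
    return out


# ---------------------------------------------------------------------------
# flow file I/O (Middlebury .flo + columnar text dump)
# ---------------------------------------------------------------------------

_FLO_MAGIC = 202021.25


def write_flo(path, flow: FlowField) -> None:
    """Write dense flow in the Middlebury .flo binary layout."""
    h, w = flow.shape
    with open(path, "wb") as fh:
        fh.write(struct.pack("<f", _FLO_MAGIC))
        fh.write(struct.pack("<ii", w, h))
        inter = np.empty((h, w, 2), dtype="<f4")
        inter[..., 0] = flow.u
        inter[..., 1] = flow.v
        fh.write(inter.tobytes())


def read_flo(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a Middlebury .flo file; returns (u, v)."""
    with open(path, "rb") as fh:
        (magic,) = struct.unpack("<f", fh.read(4))
        if abs(magic - _FLO_MAGIC) > 1e-3:
            raise ValueError("not a .flo file")
        w, h = struct.unpack("<ii", fh.read(8))
        data = np.frombuffer(fh.read(h * w * 2 * 4), dtype="<f4").reshape(h, w, 2)
    return data[..., 0].astype(float), data[..., 1].astype(float)


def write_flow_text(path, flow: FlowField) -> None:
    """Columnar text dump: row, col, u, v, valid."""
    h, w = flow.shape
    yy, xx = np.mgrid[0:h, 0:w]
    cols = np.stack(
        [yy.ravel(), xx.ravel(), flow.u.ravel(), flow.v.ravel(), flow.valid.ravel()],
        axis=1,
    )
    np.savetxt(
        path,
        cols,
        fmt=["%d", "%d", "%.6f", "%.6f", "%d"],
        header="row col u v valid",
    )
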