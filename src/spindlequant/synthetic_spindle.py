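"""Ground-truth spindle models and their rendering into noisy image stacks.

The simulator provides the known-truth substrate for every measurement module:
a geometric/photometric spindle description (:class:`SpindleModel`), a forward
renderer producing calibrated multi-channel z-stacks, an anaphase trajectory
generator with planted segregation errors, and a photoactivation time series
with a mark fluxing poleward at a planted speed.

Photometry is strictly linear: a fiber deposits ``mt_count × unit_brightness``
a.u. per µm of centerline before PSF convolution, so background-subtracted
intensity ratios equal microtubule-number ratios by construction.  Microtubule
numbers default to the electron-tomography-calibrated values for RPE1 cells
(k-fiber 12.6, bridging fiber 3.8, astral 1.0).

Axial geometry emulates the refractive-index mismatch of an oil objective on
an aqueous sample: a source at true depth z is placed at stage-plane index
z / (axial_scale · z_step), so a downstream analysis that multiplies plane
offsets by 0.81 recovers true axial distances.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import (
    ImageStack,
    InvalidParameterError,
    OpticsParams,
    OutOfBoundsError,
)

__all__ = [
    "FiberClass",
    "FiberSpec",
    "KinetochorePair",
    "SpindleModel",
    "AnaphaseKinetics",
    "DEFAULT_MT_COUNTS",
    "DEFAULT_DEPLETION_RETAINED",
    "DEFAULT_BRIDGING_REMOVAL_FRACTION",
    "make_spindle_model",
    "apply_depletion",
    "render",
    "ground_truth_table",
    "make_anaphase_timelapse",
    "make_photoactivation_series",
]


class FiberClass(str, enum.Enum):
    K_FIBER = "k_fiber"
    BRIDGING = "bridging"
    ASTRAL = "astral"
    INTERPOLAR_NO_KC = "interpolar_no_kc"


#: Microtubule numbers per fiber class measured in untreated RPE1 cells.
DEFAULT_MT_COUNTS = {
    FiberClass.K_FIBER: 12.6,
    FiberClass.BRIDGING: 3.8,
    FiberClass.ASTRAL: 1.0,
    FiberClass.INTERPOLAR_NO_KC: 3.8,
}

#: Retained-intensity fractions reproducing the augmin-depletion bookkeeping:
#: bridging 3.8 -> 1.2 microtubules, k-fiber 12.6 -> 9.6 microtubules.
DEFAULT_DEPLETION_RETAINED = {
    FiberClass.BRIDGING: 1.2 / 3.8,
    FiberClass.K_FIBER: 9.6 / 12.6,
}

#: Fraction of kinetochore pairs losing their bridging fiber entirely.
DEFAULT_BRIDGING_REMOVAL_FRACTION = 0.41


@dataclass
class FiberSpec:
    """One microtubule bundle: class, brightness-equivalent count, geometry."""

    fiber_class: FiberClass
    mt_count: float
    centerline: np.ndarray  # (N, 3) world µm, N >= 2
    linked_pair_id: int | None = None

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[0] < 2:
            raise InvalidParameterError("centerline needs >= 2 points")
        if not np.isfinite(self.mt_count) or self.mt_count < 0:
            raise InvalidParameterError("mt_count must be finite and >= 0")


@dataclass
class KinetochorePair:
    pair_id: int
    sister1: np.ndarray  # (3,) world µm
    sister2: np.ndarray
    tilt_deg: float
    separation: float

    def __post_init__(self) -> None:
        self.sister1 = np.asarray(self.sister1, dtype=float)
        self.sister2 = np.asarray(self.sister2, dtype=float)
        if self.separation <= 0:
            raise InvalidParameterError("separation must be > 0")

    @property
    def midpoint(self) -> np.ndarray:
        return 0.5 * (self.sister1 + self.sister2)


@dataclass
class SpindleModel:
    """Ground-truth description of one simulated bipolar spindle."""

    pole_positions: np.ndarray  # (2, 3) world µm
    kinetochore_pairs: list
    fibers: list
    depletion_factors: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.pole_positions = np.asarray(self.pole_positions, dtype=float)
        if self.pole_positions.shape != (2, 3):
            raise InvalidParameterError("exactly 2 poles required")
        pair_ids = {p.pair_id for p in self.kinetochore_pairs}
        for f in self.fibers:
            if (f.fiber_class is FiberClass.BRIDGING
                    and f.linked_pair_id is not None
                    and f.linked_pair_id not in pair_ids):
                raise InvalidParameterError(
                    f"bridging fiber links unknown pair {f.linked_pair_id}"
                )

    @property
    def spindle_length(self) -> float:
        return float(np.linalg.norm(self.pole_positions[1] - self.pole_positions[0]))

    def bridging_pair_ids(self) -> set:
        return {
            f.linked_pair_id
            for f in self.fibers
            if f.fiber_class is FiberClass.BRIDGING
        }

    def all_points(self) -> np.ndarray:
        pts = [self.pole_positions]
        for p in self.kinetochore_pairs:
            pts.append(np.stack([p.sister1, p.sister2]))
        for f in self.fibers:
            pts.append(f.centerline)
        return np.concatenate(pts, axis=0)


def _arc(p0, p1, sag_vector, n=15) -> np.ndarray:
    """Quadratic Bezier from p0 to p1 bulging by sag_vector at mid-chord."""
    t = np.linspace(0.0, 1.0, n)[:, None]
    # control point at chord mid + 2*sag so the curve apex sits at chord mid + sag
    ctrl = 0.5 * (p0 + p1) + 2.0 * np.asarray(sag_vector)
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * ctrl + t**2 * p1


def _radial_unit(point) -> np.ndarray:
    """Unit vector away from the x (pole-to-pole) axis at ``point``."""
    r = np.array([0.0, point[1], point[2]])
    n = np.linalg.norm(r)
    if n < 1e-12:
        return np.array([0.0, 1.0, 0.0])
    return r / n


def make_spindle_model(
    n_pairs: int = 20,
    spindle_length: float = 12.0,
    spindle_width: float = 9.0,
    mean_separation: float = 0.98,
    tilt_spread_deg: float = 10.0,
    bridging_fraction: float = 1.0,
    mt_counts: dict | None = None,
    seed: int = 0,
    n_astral_per_pole: int = 3,
    astral_length: float = 3.0,
    plate_spread: float = 0.4,
    tilt_deg: float | None = None,
) -> SpindleModel:
    """Build a bipolar metaphase spindle with known geometry and photometry.

    Poles sit on the x axis at ±spindle_length/2.  Kinetochore-pair midpoints
    populate a transverse disk of diameter ~spindle_width around the plate
    (x ~ N(0, plate_spread)).  Sister axes make angles drawn from a half-normal
    distribution of scale ``tilt_spread_deg`` with the pole axis (or exactly
    ``tilt_deg`` when given), with uniform random azimuth.  K-fiber arcs run
    pole -> kinetochore; a fraction ``bridging_fraction`` of pairs receives a
    bridging arc joining its sisters, sagging 0.1 µm toward the spindle axis;
    astral fibers radiate outward from each pole with 1 microtubule by default.
    """
    if n_pairs < 1:
        raise InvalidParameterError("n_pairs must be >= 1")
    if not (0.0 <= bridging_fraction <= 1.0):
        raise InvalidParameterError("bridging_fraction must be in [0, 1]")
    if spindle_length <= 0 or spindle_width <= 0 or mean_separation <= 0:
        raise InvalidParameterError("dimensions must be > 0")
    if spindle_length <= mean_separation:
        raise InvalidParameterError("spindle_length must exceed mean_separation")

    counts = dict(DEFAULT_MT_COUNTS)
    if mt_counts:
        counts.update({FiberClass(k): float(v) for k, v in mt_counts.items()})

    rng = np.random.default_rng(seed)
    half_len = spindle_length / 2.0
    poles = np.array([[-half_len, 0.0, 0.0], [half_len, 0.0, 0.0]])

    pairs: list = []
    fibers: list = []
    for pid in range(n_pairs):
        x_mid = float(np.clip(rng.normal(0.0, plate_spread), -1.5, 1.5))
        radius = 0.45 * spindle_width * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        mid = np.array([x_mid, radius * np.cos(phi), radius * np.sin(phi)])

        if tilt_deg is not None:
            theta = np.deg2rad(tilt_deg)
        else:
            theta = np.deg2rad(abs(rng.normal(0.0, tilt_spread_deg))) if tilt_spread_deg > 0 else 0.0
        psi = rng.uniform(0, 2 * np.pi)
        direction = np.array(
            [np.cos(theta), np.sin(theta) * np.cos(psi), np.sin(theta) * np.sin(psi)]
        )
        s1 = mid - 0.5 * mean_separation * direction
        s2 = mid + 0.5 * mean_separation * direction
        pairs.append(
            KinetochorePair(
                pair_id=pid,
                sister1=s1,
                sister2=s2,
                tilt_deg=float(np.rad2deg(theta)),
                separation=float(mean_separation),
            )
        )
        # k-fiber arcs bow slightly outward, away from the pole-to-pole axis;
        # s1 (lower x, since direction_x >= 0) attaches to pole A, s2 to pole B
        for sister, pole in ((s1, poles[0]), (s2, poles[1])):
            sag = 0.3 * _radial_unit(mid)
            fibers.append(
                FiberSpec(
                    fiber_class=FiberClass.K_FIBER,
                    mt_count=counts[FiberClass.K_FIBER],
                    centerline=_arc(pole, sister, sag, n=25),
                    linked_pair_id=pid,
                )
            )

    n_bridge = int(round(bridging_fraction * n_pairs))
    bridge_ids = rng.choice(n_pairs, size=n_bridge, replace=False) if n_bridge else []
    for pid in sorted(int(i) for i in np.atleast_1d(bridge_ids)):
        p = pairs[pid]
        sag = -0.1 * _radial_unit(p.midpoint)  # sag toward the spindle axis
        fibers.append(
            FiberSpec(
                fiber_class=FiberClass.BRIDGING,
                mt_count=counts[FiberClass.BRIDGING],
                centerline=_arc(p.sister1, p.sister2, sag, n=9),
                linked_pair_id=pid,
            )
        )

    for pole, outward in ((poles[0], -1.0), (poles[1], 1.0)):
        for _ in range(n_astral_per_pole):
            theta = rng.uniform(np.deg2rad(20), np.deg2rad(70))
            psi = rng.uniform(0, 2 * np.pi)
            d = np.array(
                [outward * np.cos(theta), np.sin(theta) * np.cos(psi), np.sin(theta) * np.sin(psi)]
            )
            fibers.append(
                FiberSpec(
                    fiber_class=FiberClass.ASTRAL,
                    mt_count=counts[FiberClass.ASTRAL],
                    centerline=np.stack([pole, pole + astral_length * d]),
                )
            )

    return SpindleModel(
        pole_positions=poles,
        kinetochore_pairs=pairs,
        fibers=fibers,
        depletion_factors={},
        seed=seed,
    )


def apply_depletion(
    model: SpindleModel,
    retained: dict | None = None,
    bridging_removal_fraction: float = 0.0,
    seed: int = 0,
) -> SpindleModel:
    """Scale fiber brightness per class and delete a fraction of bridges.

    ``retained`` maps fiber class -> retained-intensity fraction in [0, 1]
    (default: the augmin-depletion preset, bridging 3.8->1.2 and k-fiber
    12.6->9.6).  Exactly ``round(fraction × n_bridging)`` bridging fibers,
    chosen at random, are removed entirely; the ground truth flags their pairs
    as bridging-absent.
    """
    if retained is None:
        retained = DEFAULT_DEPLETION_RETAINED
    retained = {FiberClass(k): float(v) for k, v in retained.items()}
    for cls, frac in retained.items():
        if not (0.0 <= frac <= 1.0):
            raise InvalidParameterError(f"retained fraction for {cls} not in [0, 1]")
    if not (0.0 <= bridging_removal_fraction <= 1.0):
        raise InvalidParameterError("bridging_removal_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    bridges = [f for f in model.fibers if f.fiber_class is FiberClass.BRIDGING]
    n_remove = int(round(bridging_removal_fraction * len(bridges)))
    removed_pairs: set = set()
    if n_remove:
        chosen = rng.choice(len(bridges), size=n_remove, replace=False)
        removed_pairs = {bridges[i].linked_pair_id for i in chosen}

    new_fibers = []
    for f in model.fibers:
        if f.fiber_class is FiberClass.BRIDGING and f.linked_pair_id in removed_pairs:
            continue
        scale = retained.get(f.fiber_class, 1.0)
        new_fibers.append(
            FiberSpec(
                fiber_class=f.fiber_class,
                mt_count=f.mt_count * scale,
                centerline=f.centerline.copy(),
                linked_pair_id=f.linked_pair_id,
            )
        )
    return SpindleModel(
        pole_positions=model.pole_positions.copy(),
        kinetochore_pairs=[replace(p) for p in model.kinetochore_pairs],
        fibers=new_fibers,
        depletion_factors={c.value: retained.get(c, 1.0) for c in FiberClass},
        seed=model.seed,
    )


def ground_truth_table(model: SpindleModel) -> pd.DataFrame:
    """One row per simulated object (pair or fiber) with its planted truth."""
    bridging_ids = model.bridging_pair_ids()
    axis_p0, axis_p1 = model.pole_positions
    axis_dir = axis_p1 - axis_p0
    axis_dir = axis_dir / np.linalg.norm(axis_dir)
    rows = []
    for p in model.kinetochore_pairs:
        rel = p.midpoint - axis_p0
        c = float(np.linalg.norm(rel - np.dot(rel, axis_dir) * axis_dir))
        rows.append(
            dict(
                object="pair",
                pair_id=p.pair_id,
                fiber_class="",
                mt_count=np.nan,
                separation_um=p.separation,
                tilt_deg=p.tilt_deg,
                axis_distance_um=c,
                bridging_present=p.pair_id in bridging_ids,
            )
        )
    for f in model.fibers:
        rows.append(
            dict(
                object="fiber",
                pair_id=-1 if f.linked_pair_id is None else f.linked_pair_id,
                fiber_class=f.fiber_class.value,
                mt_count=f.mt_count,
                separation_um=np.nan,
                tilt_deg=np.nan,
                axis_distance_um=np.nan,
                bridging_present=pd.NA,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rendering


def _resample_polyline(points: np.ndarray, step: float) -> tuple[np.ndarray, float]:
    """Equal-arclength resampling; returns samples and the per-sample length."""
    seg = np.diff(points, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    total = float(seg_len.sum())
    if total <= 0:
        return points[:1], 0.0
    n = max(int(np.ceil(total / step)), 2)
    s = np.linspace(0.0, total, n)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(s, cum, points[:, k])
    return out, total / n


def _deposit(vol: np.ndarray, prc: np.ndarray, weights: np.ndarray) -> None:
    """Trilinear additive deposition of point masses at fractional voxels."""
    base = np.floor(prc).astype(int)
    frac = prc - base
    nz, ny, nx = vol.shape
    if np.any(base < 0) or np.any(base + 1 >= np.array([nz, ny, nx])):
        raise OutOfBoundsError("model extends outside the rendered volume")
    for dz in (0, 1):
        wz = np.where(dz, frac[:, 0], 1 - frac[:, 0])
        for dy in (0, 1):
            wy = np.where(dy, frac[:, 1], 1 - frac[:, 1])
            for dx in (0, 1):
                wx = np.where(dx, frac[:, 2], 1 - frac[:, 2])
                np.add.at(
                    vol,
                    (base[:, 0] + dz, base[:, 1] + dy, base[:, 2] + dx),
                    weights * wz * wy * wx,
                )


def _auto_origin(model: SpindleModel, optics: OpticsParams, shape) -> tuple:
    pts = model.all_points()
    center = 0.5 * (pts.min(axis=0) + pts.max(axis=0))
    nz, ny, nx = shape
    return (
        center[0] - (nx - 1) / 2.0 * optics.pixel_size_xy,
        center[1] - (ny - 1) / 2.0 * optics.pixel_size_xy,
        center[2] - (nz - 1) / 2.0 * optics.z_sample_step,
    )


def _apply_noise(data: np.ndarray, optics: OpticsParams, rng) -> np.ndarray:
    out = data
    if optics.poisson_gain > 0:
        out = rng.poisson(np.clip(out, 0, None) * optics.poisson_gain) / optics.poisson_gain
    if optics.read_noise_sigma > 0:
        out = out + rng.normal(0.0, optics.read_noise_sigma, size=out.shape)
    return out.astype(float)


def render(
    model: SpindleModel,
    optics: OpticsParams | None = None,
    shape: tuple | None = None,
    seed: int = 0,
    noise: bool = True,
    origin: tuple | None = None,
    prc1_overlap_length: float = 1.5,
) -> ImageStack:
    """Rasterize a spindle model into a 3-channel (tubulin/kinetochore/PRC1)
    calibrated z-stack.

    Each fiber centerline deposits ``mt_count × unit_brightness`` a.u. per µm
    (trilinear, sub-voxel), the volume is convolved with the anisotropic
    Gaussian PSF, and sources at true depth z sit at plane z/(axial_scale ×
    z_step).  Kinetochores render as puncta in channel 2; bridging and
    interpolar fibers render (clipped to ``prc1_overlap_length`` around their
    arc midpoint) into the PRC1 channel.  Background is always added; Poisson
    shot noise and Gaussian read noise only when ``noise`` is true.
    """
    optics = optics or OpticsParams()
    if shape is None:
        pts = model.all_points()
        span = pts.max(axis=0) - pts.min(axis=0) + 2.0
        nx = int(np.ceil(span[0] / optics.pixel_size_xy))
        ny = int(np.ceil(span[1] / optics.pixel_size_xy))
        nz = int(np.ceil(span[2] / optics.z_sample_step)) + 4
        shape = (nz, ny, nx)
    if origin is None:
        origin = _auto_origin(model, optics, shape)

    stack = ImageStack(
        data=np.zeros((3,) + tuple(shape), dtype=float),
        optics=optics,
        origin=origin,
    )
    step = min(optics.pixel_size_xy, optics.z_sample_step) / 2.0

    tub = stack.data[0]
    kc = stack.data[1]
    prc1 = stack.data[2]
    for f in model.fibers:
        samples, ds = _resample_polyline(f.centerline, step)
        if ds == 0:
            continue
        w = np.full(len(samples), f.mt_count * optics.unit_brightness * ds)
        prc = stack.world_to_voxel(samples)
        _deposit(tub, prc, w)
        if f.fiber_class in (FiberClass.BRIDGING, FiberClass.INTERPOLAR_NO_KC):
            seg = _clip_to_central_length(f.centerline, prc1_overlap_length)
            s2, ds2 = _resample_polyline(seg, step)
            if ds2 > 0:
                _deposit(
                    prc1,
                    stack.world_to_voxel(s2),
                    np.full(len(s2), f.mt_count * optics.unit_brightness * ds2),
                )
    for p in model.kinetochore_pairs:
        for sister in (p.sister1, p.sister2):
            prc = stack.world_to_voxel(sister[None, :])
            _deposit(kc, prc, np.array([optics.punctum_brightness]))

    sigma_vox = (
        optics.psf_sigma_z / optics.z_sample_step,
        optics.psf_sigma_xy / optics.pixel_size_xy,
        optics.psf_sigma_xy / optics.pixel_size_xy,
    )
    for c in range(3):
        stack.data[c] = gaussian_filter(stack.data[c], sigma_vox)

    stack.data += optics.background_level
    if noise:
        rng = np.random.default_rng(seed)
        stack.data = _apply_noise(stack.data, optics, rng)
    return stack


def _clip_to_central_length(points: np.ndarray, length: float) -> np.ndarray:
    """Central sub-polyline of the given arclength (whole line if shorter)."""
    seg_len = np.linalg.norm(np.diff(points, axis=0), axis=1)
    total = float(seg_len.sum())
    if total <= length:
        return points
    dense, _ = _resample_polyline(points, total / 200.0)
    n = len(dense)
    keep = max(int(round(n * length / total)), 2)
    lo = (n - keep) // 2
    return dense[lo : lo + keep]


# ---------------------------------------------------------------------------
# anaphase time-lapse


@dataclass(frozen=True)
class AnaphaseKinetics:
    """Planted anaphase speeds (µm/min) and the onset frame index."""

    anaphase_A_speed: float = 1.0
    anaphase_B_speed: float = 0.8
    onset_frame: int = 4

    def __post_init__(self) -> None:
        if self.anaphase_A_speed < 0 or self.anaphase_B_speed < 0:
            raise InvalidParameterError("anaphase speeds must be >= 0")


def make_anaphase_timelapse(
    model: SpindleModel,
    error_spec: list | None = None,
    kinetics: AnaphaseKinetics | None = None,
    n_frames: int = 16,
    dt: float = 30.0,
    seed: int = 0,
    position_noise: float = 0.02,
    plate_half_thickness: float = 1.2,
    lagging_elongation: float = 2.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate kinetochore and pole trajectories through anaphase.

    ``error_spec`` lists (pair_id, error_class, missegregates) with classes in
    {"normal", "misaligned", "lagging", "other"}; unlisted pairs are normal.
    Frame interval ``dt`` is in seconds (default 30 s, the anaphase imaging
    cadence).  Returns a trajectory table (one row per object per frame with
    columns frame, time_s, object, track_id, sister, x/y/z µm, elongation) and
    a ground-truth table of planted labels and speeds.

    Normal pairs split at onset; each sister moves along the straight line to
    its pole so that the kinetochore-pole distance shrinks at exactly
    ``anaphase_A_speed`` while poles separate at ``anaphase_B_speed``.
    Misaligned pairs sit wholly outside the metaphase-plate slab before onset;
    lagging pairs leave one sister near the equator with a stretched punctum;
    "other" pairs never separate.  ``position_noise`` adds Gaussian jitter (µm).
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    kinetics = kinetics or AnaphaseKinetics()
    if kinetics.onset_frame >= n_frames:
        raise InvalidParameterError("onset_frame must be < n_frames")

    spec = {pid: ("normal", False) for pid in range(len(model.kinetochore_pairs))}
    for pid, klass, missg in error_spec or []:
        if klass not in ("normal", "misaligned", "lagging", "other"):
            raise InvalidParameterError(f"unknown planted class {klass!r}")
        spec[pid] = (klass, bool(missg))

    rng = np.random.default_rng(seed)
    vA = kinetics.anaphase_A_speed
    vB = kinetics.anaphase_B_speed
    onset = kinetics.onset_frame
    half_len = model.spindle_length / 2.0

    rows = []
    times = np.arange(n_frames) * dt

    def pole_pos(frame, sign):
        tau = max(times[frame] - times[onset], 0.0) / 60.0
        return np.array([sign * (half_len + 0.5 * vB * tau), 0.0, 0.0])

    for frame in range(n_frames):
        for sign, name in ((-1.0, "pole_A"), (1.0, "pole_B")):
            p = pole_pos(frame, sign)
            rows.append(
                dict(frame=frame, time_s=times[frame], object="pole",
                     track_id=name, sister=-1,
                     x=p[0], y=p[1], z=p[2], elongation=1.0)
            )

    for pair in model.kinetochore_pairs:
        klass, missg = spec[pair.pair_id]
        mid0 = pair.midpoint.copy()
        if klass == "misaligned":
            side = 1.0 if rng.uniform() < 0.5 else -1.0
            mid0[0] = side * (plate_half_thickness + 1.5)
        sep_dir = pair.sister2 - pair.sister1
        sep_dir = sep_dir / np.linalg.norm(sep_dir)
        s_init = {
            1: mid0 - 0.5 * pair.separation * sep_dir,
            2: mid0 + 0.5 * pair.separation * sep_dir,
        }
        # pole assignment by x coordinate of each sister at onset
        pole_sign = {
            s: (-1.0 if s_init[s][0] <= s_init[3 - s][0] else 1.0) for s in (1, 2)
        }
        if klass == "misaligned" and missg:
            near = -1.0 if mid0[0] < 0 else 1.0
            pole_sign = {1: near, 2: near}
        lag_sister = 2 if klass == "lagging" else None
        lag_side = np.sign(s_init.get(2, mid0)[0] - 0.0) or 1.0

        for frame in range(n_frames):
            tau = max(times[frame] - times[onset], 0.0) / 60.0
            for s in (1, 2):
                elong = 1.0
                if klass == "other" or frame <= onset:
                    pos = s_init[s].copy()
                elif klass == "lagging" and s == lag_sister:
                    # stalls centrally, stretched; resolves in the last quarter
                    late = frame >= n_frames - max(n_frames // 4, 1)
                    if late:
                        dest_sign = -lag_side if missg else lag_side
                        pole = pole_pos(frame, dest_sign)
                        u = s_init[s] - pole_pos(onset, dest_sign)
                        d0 = np.linalg.norm(u)
                        d = max(d0 - 2.0 * vA * tau, 1.0)
                        pos = pole + (u / d0) * d
                    else:
                        pos = s_init[s] + np.array([0.0, 0.0, 0.0])
                        elong = lagging_elongation
                else:
                    sign = pole_sign[s]
                    pole = pole_pos(frame, sign)
                    u = s_init[s] - pole_pos(onset, sign)
                    d0 = np.linalg.norm(u)
                    d = max(d0 - vA * tau, 0.8)
                    pos = pole + (u / d0) * d
                noisy = pos + rng.normal(0.0, position_noise, 3)
                rows.append(
                    dict(frame=frame, time_s=times[frame], object="kinetochore",
                         track_id=pair.pair_id, sister=s,
                         x=noisy[0], y=noisy[1], z=noisy[2], elongation=elong)
                )

    traj = pd.DataFrame(rows)
    truth = pd.DataFrame(
        [
            dict(
                pair_id=pid,
                error_class=(klass if klass != "normal" else "none"),
                missegregates=missg,
                onset_frame=onset,
                anaphase_A_speed=vA,
                anaphase_B_speed=vB,
            )
            for pid, (klass, missg) in sorted(spec.items())
        ]
    )
    return traj, truth


# ---------------------------------------------------------------------------
# photoactivation


def make_photoactivation_series(
    spindle_length: float = 12.0,
    flux_speed: float = 1.0,
    mark_width: float = 0.5,
    n_frames: int = 8,
    dt: float = 10.0,
    optics: OpticsParams | None = None,
    seed: int = 0,
    noise: bool = True,
    mark_start_offset: float = 3.0,
    mark_amplitude: float = 500.0,
    spindle_amplitude: float = 300.0,
    pole_amplitude: float = 600.0,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render a 2D+t photoactivation experiment with a poleward-fluxing mark.

    A transverse Gaussian stripe (FWHM ``mark_width``) is activated at
    ``mark_start_offset`` µm from the spindle midpoint toward pole A and moves
    toward that (nearer) pole at ``flux_speed`` µm/min over a static tubulin
    intensity field with bright poles.  Frame interval ``dt`` defaults to 10 s.
    Returns the 2-channel (photoactivation, tubulin) time series and a
    ground-truth table of mark and pole positions per frame.
    """
    optics = optics or OpticsParams()
    if flux_speed < 0:
        raise InvalidParameterError("flux_speed must be >= 0")
    if dt <= 0:
        raise InvalidParameterError("dt must be > 0")
    half = spindle_length / 2.0
    x0 = -abs(mark_start_offset)
    travel = flux_speed * (n_frames - 1) * dt / 60.0
    if abs(x0) + travel > half + 0.5:
        raise InvalidParameterError("mark leaves the spindle during the series")

    px = optics.pixel_size_xy
    nx = int(np.ceil((spindle_length + 4.0) / px))
    ny = int(np.ceil(6.0 / px))
    xs = (np.arange(nx) - (nx - 1) / 2.0) * px
    ys = (np.arange(ny) - (ny - 1) / 2.0) * px
    X, Y = np.meshgrid(xs, ys)

    body = np.exp(-(Y**2) / (2 * 1.2**2)) * (np.abs(X) < half + 0.3)
    tub = spindle_amplitude * body
    for sx in (-half, half):
        tub = tub + pole_amplitude * np.exp(-((X - sx) ** 2 + Y**2) / (2 * 0.4**2))

    sigma_mark = mark_width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    rng = np.random.default_rng(seed)
    data = np.zeros((n_frames, 2, 1, ny, nx), dtype=float)
    truth_rows = []
    for t in range(n_frames):
        xm = x0 - flux_speed * t * dt / 60.0
        pa = mark_amplitude * np.exp(-((X - xm) ** 2) / (2 * sigma_mark**2)) * body
        frame_pa = pa + optics.background_level
        frame_tub = tub + optics.background_level
        if noise:
            frame_pa = _apply_noise(frame_pa, optics, rng)
            frame_tub = _apply_noise(frame_tub, optics, rng)
        data[t, 0, 0] = frame_pa
        data[t, 1, 0] = frame_tub
        truth_rows.append(
            dict(frame=t, time_s=t * dt, mark_x=xm,
                 pole_a_x=-half, pole_b_x=half,
                 mark_pole_distance=xm - (-half))
        )

    stack = ImageStack(
        data=data,
        optics=optics,
        channel_names=("photoactivation", "tubulin"),
        origin=(xs[0], ys[0], 0.0),
        frame_interval_s=dt,
    )
    return stack, pd.DataFrame(truth_rows)
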