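"""3D kinetochore geometry with axial correction.

Point annotations live in voxel units (x_px, y_px, z_plane).  All distances
are computed after converting to µm, with axial (plane) offsets multiplied by
z_step × axial_scale: the 0.81 factor corrects the apparent depth compression
of an oil objective imaging an aqueous sample.  The interkinetochore distance
(a tension proxy), the distance of a pair from the pole-to-pole axis (the
Pythagorean c = sqrt(a² + b²) of an in-plane component a and a corrected
axial component b), the sister-axis tilt and whole-spindle dimensions are
derived from these corrected coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core import DegenerateGeometryError, ImageStack, InvalidParameterError


class Region(str, Enum):
    INNER = "inner"
    OUTER = "outer"


@dataclass(frozen=True)
class VoxelCalibration:
    """Pixel pitch, z-step and axial correction shared by a dataset."""

    pixel_size: float = 0.083
    z_step: float = 0.5
    axial_scale: float = 0.81

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.z_step <= 0:
            raise InvalidParameterError("pixel_size and z_step must be > 0")
        if not (0 < self.axial_scale <= 1):
            raise InvalidParameterError("axial_scale must be in (0, 1]")

    def to_um(self, points) -> np.ndarray:
        """(x_px, y_px, z_plane) -> fully scaled (x, y, z) µm coordinates."""
        p = np.asarray(points, dtype=float)
        scale = np.array([self.pixel_size, self.pixel_size, self.z_step * self.axial_scale])
        return p * scale


@dataclass
class KinetochorePairRecord:
    pair_id: int
    separation: float          # µm
    axis_distance: float       # c, µm
    in_plane_component: float  # a, µm
    axial_component: float     # b, µm
    tilt: float                # degrees in [0, 90]
    region: Region | None = None
    bridging_detected: bool | None = None


@dataclass
class SpindleDimensions:
    length: float
    width: float
    plate_diameter: float


def corrected_displacement(p1, p2, pixel_size: float = 0.083, z_step: float = 0.5,
                           axial_scale: float = 0.81) -> float:
    """3D distance in µm between two (x_px, y_px, z_plane) points.

    sqrt(Δx² + Δy² + (Δplane × z_step × axial_scale)²) with Δx, Δy in µm.
    """
    cal = VoxelCalibration(pixel_size, z_step, axial_scale)
    d = cal.to_um(p2) - cal.to_um(p1)
    return float(np.linalg.norm(d))


def interkinetochore_distance(sister1, sister2, calibration: VoxelCalibration,
                              mode: str = "3d",
                              frame1: int | None = None, frame2: int | None = None) -> float:
    """Distance between sister-kinetochore signal centres, µm.

    ``mode='2d'`` drops the axial term (used when all tracked pairs sit within
    2 µm of the central z-plane); ``mode='3d'`` applies the full corrected
    Pythagoras.  Identical points yield 0.0 (degenerate but legal).
    """
    if frame1 is not None and frame2 is not None and frame1 != frame2:
        raise InvalidParameterError("sisters annotated on different frames")
    a = calibration.to_um(sister1)
    b = calibration.to_um(sister2)
    if mode == "2d":
        a, b = a[:2], b[:2]
    elif mode != "3d":
        raise InvalidParameterError("mode must be '2d' or '3d'")
    return float(np.linalg.norm(b - a))


def axis_distance(pair_midpoint, poles, calibration: VoxelCalibration,
                  central_plane: float | None = None) -> tuple[float, float, float]:
    """Distance of a pair midpoint from the pole-to-pole axis: (a, b, c).

    a: in-plane distance, within the midpoint's z-plane, from the midpoint to
    the axis projected into the xy plane; b: axial offset from the central
    z-plane × z_step × axial_scale; c = sqrt(a² + b²).  The central plane
    defaults to the mean of the two pole planes.
    """
    poles = np.asarray(poles, dtype=float)
    mid = np.asarray(pair_midpoint, dtype=float)
    p0_xy = poles[0, :2] * calibration.pixel_size
    p1_xy = poles[1, :2] * calibration.pixel_size
    axis_xy = p1_xy - p0_xy
    norm = np.linalg.norm(axis_xy)
    if norm < 1e-12:
        raise DegenerateGeometryError("coincident poles: spindle axis undefined")
    m_xy = mid[:2] * calibration.pixel_size
    rel = m_xy - p0_xy
    a = float(abs(axis_xy[0] * rel[1] - axis_xy[1] * rel[0]) / norm)
    if central_plane is None:
        central_plane = 0.5 * (poles[0, 2] + poles[1, 2])
    b = float(abs(mid[2] - central_plane) * calibration.z_step * calibration.axial_scale)
    return a, b, float(np.hypot(a, b))


def classify_region_metaphase(axis_distances) -> list[Region]:
    """Inner/outer split of metaphase pairs about the cell-mean axis distance.

    A pair is inner iff its distance c is strictly below the mean over all
    tracked pairs of the cell; ties classify as outer.
    """
    c = np.asarray(axis_distances, dtype=float)
    if c.size < 2:
        raise InvalidParameterError("metaphase region split needs >= 2 pairs")
    mean = c.mean()
    return [Region.INNER if ci < mean else Region.OUTER for ci in c]


def classify_region_anaphase(axis_distance_um: float, spindle_half_width: float) -> Region:
    """Inner iff c / half-width < 0.5; the boundary value 0.5 is outer."""
    if spindle_half_width <= 0:
        raise InvalidParameterError("spindle_half_width must be > 0")
    return Region.INNER if axis_distance_um / spindle_half_width < 0.5 else Region.OUTER


def kinetochore_tilt(sister1, sister2, poles, calibration: VoxelCalibration) -> float:
    """Angle (degrees, folded into [0, 90]) between the sister-sister axis and
    the pole-to-pole axis, in fully scaled 3D coordinates."""
    s = calibration.to_um(sister2) - calibration.to_um(sister1)
    poles = np.asarray(poles, dtype=float)
    p = calibration.to_um(poles[1]) - calibration.to_um(poles[0])
    ns, np_ = np.linalg.norm(s), np.linalg.norm(p)
    if ns < 1e-12 or np_ < 1e-12:
        raise DegenerateGeometryError("degenerate sister or pole vector")
    cosang = abs(np.dot(s, p)) / (ns * np_)
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def spindle_dimensions(poles, outermost_bundle_lines, plate_annotations,
                       calibration: VoxelCalibration,
                       mode: str = "kinetochore") -> SpindleDimensions:
    """Whole-spindle dimensions from maximum-projection annotations.

    length: pole-to-pole distance (in-plane); width: separation of two lines
    parallel to the spindle axis bounding the outermost bundles (given as two
    points each, (x_px, y_px)); plate diameter: distance between the two
    outermost kinetochore pairs (mode 'kinetochore') or chromosome ends
    (mode 'dna') annotated at the plate edges.
    """
    if poles is None or outermost_bundle_lines is None or plate_annotations is None:
        raise InvalidParameterError("poles, bundle lines and plate annotations all required")
    if mode not in ("kinetochore", "dna"):
        raise InvalidParameterError("mode must be 'kinetochore' or 'dna'")
    px = calibration.pixel_size
    poles = np.asarray(poles, dtype=float)[:, :2] * px
    length = float(np.linalg.norm(poles[1] - poles[0]))
    if length < 1e-12:
        raise DegenerateGeometryError("coincident poles")
    axis = (poles[1] - poles[0]) / length

    def line_offset(line_pts):
        pt = np.asarray(line_pts, dtype=float)[0, :2] * px
        rel = pt - poles[0]
        return axis[0] * rel[1] - axis[1] * rel[0]  # signed transverse offset

    offs = [line_offset(line) for line in outermost_bundle_lines]
    if len(offs) != 2:
        raise InvalidParameterError("exactly two outermost bundle lines required")
    width = float(abs(offs[0] - offs[1]))

    plate = np.asarray(plate_annotations, dtype=float)[:, :2] * px
    if plate.shape[0] != 2:
        raise InvalidParameterError("exactly two plate-edge annotations required")
    diameter = float(np.linalg.norm(plate[1] - plate[0]))
    return SpindleDimensions(length=length, width=width, plate_diameter=diameter)


# ---------------------------------------------------------------------------
# sub-voxel localization of puncta on rendered or real stacks


def localize_pair(
    stack: ImageStack,
    channel,
    seed_voxel_1,
    seed_voxel_2,
    box_radius_px: int = 5,
    box_radius_planes: int = 3,
    iterations: int = 15,
) -> tuple[np.ndarray, np.ndarray]:
    """Jointly localize two nearby puncta with mutual-contribution removal.

    Sister kinetochores sit ~1 µm apart, within a few axial PSF widths of
    each other, so a plain centroid of either punctum is pulled toward its
    sister.  Here each punctum is localized on the image minus a Gaussian
    (PSF-shaped) model of the other, re-estimating both positions and
    amplitudes alternately; this removes the mutual bias for separations
    down to ~2 PSF widths.  Returns both refined (plane, row, col) positions.
    """
    from scipy.ndimage import map_coordinates

    vol = stack.channel(channel).astype(float)
    o = stack.optics
    sig = np.array([
        max(o.psf_sigma_z / o.z_sample_step, 0.5),
        max(o.psf_sigma_xy / o.pixel_size_xy, 0.5),
        max(o.psf_sigma_xy / o.pixel_size_xy, 0.5),
    ])
    bg = float(np.median(vol))
    positions = [np.asarray(seed_voxel_1, float).copy(),
                 np.asarray(seed_voxel_2, float).copy()]

    def raw_amplitude(p):
        val = map_coordinates(vol, p[:, None], order=1, mode="nearest")[0]
        return max(val - bg, 0.0)

    def solve_amplitudes(p1, p2):
        # peak values are a1 + a2·g and a2 + a1·g with g the mutual Gaussian
        # overlap; invert the 2x2 system for the uncontaminated amplitudes
        v1, v2 = raw_amplitude(p1), raw_amplitude(p2)
        g = float(np.exp(-0.5 * np.sum(((p1 - p2) / sig) ** 2)))
        det = 1.0 - g * g
        if det < 1e-6:
            return v1, v2
        return max((v1 - g * v2) / det, 0.0), max((v2 - g * v1) / det, 0.0)

    amps = list(solve_amplitudes(*positions))
    for _ in range(iterations):
        new_pos = []
        for j in (0, 1):
            other, a_other = positions[1 - j], amps[1 - j]
            p = positions[j]
            nz, ny, nx = vol.shape
            z0 = int(np.clip(round(p[0]) - box_radius_planes, 0, nz - 1))
            z1 = int(np.clip(round(p[0]) + box_radius_planes + 1, 1, nz))
            y0 = int(np.clip(round(p[1]) - box_radius_px, 0, ny - 1))
            y1 = int(np.clip(round(p[1]) + box_radius_px + 1, 1, ny))
            x0 = int(np.clip(round(p[2]) - box_radius_px, 0, nx - 1))
            x1 = int(np.clip(round(p[2]) + box_radius_px + 1, 1, nx))
            box = vol[z0:z1, y0:y1, x0:x1] - bg
            zz, yy, xx = np.meshgrid(
                np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
            )
            model_other = a_other * np.exp(
                -((zz - other[0]) ** 2) / (2 * sig[0] ** 2)
                - ((yy - other[1]) ** 2) / (2 * sig[1] ** 2)
                - ((xx - other[2]) ** 2) / (2 * sig[2] ** 2)
            )
            clean = np.clip(box - model_other, 0, None)
            w = clean * np.exp(
                -((zz - p[0]) ** 2) / (2 * (1.5 * sig[0]) ** 2)
                - ((yy - p[1]) ** 2) / (2 * (1.5 * sig[1]) ** 2)
                - ((xx - p[2]) ** 2) / (2 * (1.5 * sig[2]) ** 2)
            )
            total = w.sum()
            if total <= 0:
                new_pos.append(p)
                continue
            new_pos.append(
                np.array([(w * zz).sum(), (w * yy).sum(), (w * xx).sum()]) / total
            )
        shift = max(np.linalg.norm(n - p) for n, p in zip(new_pos, positions))
        positions = new_pos
        amps = list(solve_amplitudes(*positions))
        if shift < 1e-4:
            break
    return positions[0], positions[1]


def localize_centroid(
    stack: ImageStack,
    channel,
    seed_voxel,
    box_radius_px: int = 5,
    box_radius_planes: int = 3,
    iterations: int = 12,
) -> np.ndarray:
    """Refine an annotation to the punctum centre: iterative Gaussian-masked,
    background-subtracted intensity centroid.

    Returns fractional voxel coordinates (plane, row, col).  The mask σ equals
    the PSF σ in voxel units, which keeps the centroid near-unbiased for
    sub-voxel positions and suppresses the pull of neighbouring puncta.
    """
    vol = stack.channel(channel)
    o = stack.optics
    sz = max(o.psf_sigma_z / o.z_sample_step, 0.5)
    sxy = max(o.psf_sigma_xy / o.pixel_size_xy, 0.5)

    pos = np.asarray(seed_voxel, dtype=float).copy()
    nz, ny, nx = vol.shape
    for _ in range(iterations):
        z0 = int(np.clip(round(pos[0]) - box_radius_planes, 0, nz - 1))
        z1 = int(np.clip(round(pos[0]) + box_radius_planes + 1, 1, nz))
        y0 = int(np.clip(round(pos[1]) - box_radius_px, 0, ny - 1))
        y1 = int(np.clip(round(pos[1]) + box_radius_px + 1, 1, ny))
        x0 = int(np.clip(round(pos[2]) - box_radius_px, 0, nx - 1))
        x1 = int(np.clip(round(pos[2]) + box_radius_px + 1, 1, nx))
        box = vol[z0:z1, y0:y1, x0:x1].astype(float)
        # local background: median of the box faces
        edge = np.concatenate([box[0].ravel(), box[-1].ravel(),
                               box[:, 0].ravel(), box[:, -1].ravel()])
        box = np.clip(box - np.median(edge), 0, None)
        zz, yy, xx = np.meshgrid(
            np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
        )
        w = box * np.exp(
            -((zz - pos[0]) ** 2) / (2 * (1.5 * sz) ** 2)
            - ((yy - pos[1]) ** 2) / (2 * (1.5 * sxy) ** 2)
            - ((xx - pos[2]) ** 2) / (2 * (1.5 * sxy) ** 2)
        )
        total = w.sum()
        if total <= 0:
            break
        new = np.array([(w * zz).sum(), (w * yy).sum(), (w * xx).sum()]) / total
        if np.linalg.norm(new - pos) < 1e-4:
            pos = new
            break
        pos = new
    return pos
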