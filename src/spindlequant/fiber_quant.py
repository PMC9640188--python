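"""Fiber-intensity measurement and ratiometric microtubule counting.

Two measurement schemes are implemented.  The square-ROI scheme measures the
mean tubulin intensity in a small square placed on a bridging fiber (between
the two sister kinetochores), on each sister k-fiber (pole side of the
kinetochore) or on an astral microtubule, subtracts a background estimated
from empty in-spindle areas, and converts intensities to microtubule numbers
with the k-fiber calibration

    n_x = I_x * n_k / I_k,        n_k = 12.6 microtubules (RPE1 k-fiber).

The line-profile scheme pools a tubulin intensity profile along the contour
of the two sister k-fibers and their bridging fiber; the profile minimum
marks the bridge centre, I_b is the mean in a window around the centre, I_bk
the mean of two flanking windows, and I_k = I_bk - I_b.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core import ImageStack, InvalidParameterError, OutOfBoundsError

N_K_REFERENCE = 12.6  # microtubules per k-fiber (electron tomography, RPE1)

#: Background-ROI counts required in strict mode, per modality.
BACKGROUND_ROI_COUNT = {"sted": 10, "confocal": 2}


class RoiMethod(str, Enum):
    SQUARE_ROI = "square_roi"
    LINE_PROFILE = "line_profile"


@dataclass
class RoiMeasurement:
    """A single background-subtracted square-ROI intensity."""

    raw_mean: float
    background_mean: float
    roi_size_px: int
    z_plane: int
    method: RoiMethod = RoiMethod.SQUARE_ROI

    @property
    def corrected(self) -> float:
        return self.raw_mean - self.background_mean


@dataclass
class ProfileMeasurement:
    """Result of the pooled contour-profile scheme."""

    positions: np.ndarray      # arclength, µm, zero at the bridge centre
    contour_profile: np.ndarray  # background-subtracted intensity
    midzone_min: float         # background level subtracted
    bridge_center: float       # arclength of the profile minimum, µm
    I_b: float
    I_bk: float
    degenerate_center: bool = False

    @property
    def I_k(self) -> float:
        return self.I_bk - self.I_b


@dataclass
class MtCountEstimate:
    """Microtubule-number estimates for one kinetochore pair or fiber."""

    n_b: float = np.nan
    n_k_ref: float = N_K_REFERENCE
    n_a: float = np.nan
    bridging_detected: bool | None = None


def _roi_block(plane: np.ndarray, center_rc, roi_size_px: int) -> np.ndarray:
    if roi_size_px < 1:
        raise InvalidParameterError("roi_size_px must be >= 1")
    r0 = int(round(center_rc[0])) - roi_size_px // 2
    c0 = int(round(center_rc[1])) - roi_size_px // 2
    r1, c1 = r0 + roi_size_px, c0 + roi_size_px
    if r0 < 0 or c0 < 0 or r1 > plane.shape[0] or c1 > plane.shape[1]:
        raise OutOfBoundsError("ROI crosses the image border")
    return plane[r0:r1, c0:c1]


def measure_square_roi(
    stack: ImageStack, channel, center, roi_size_px: int = 25
) -> float:
    """Mean intensity of a roi_size × roi_size pixel square on one z-plane.

    ``center`` is (z_plane, row, col) in voxels.  25×25 px is the STED
    convention (0.5 µm at 20 nm pixels), 5×5 px the confocal one.
    """
    vol = stack.channel(channel)
    z = int(round(center[0]))
    if not (0 <= z < vol.shape[0]):
        raise OutOfBoundsError("z-plane outside the stack")
    return float(_roi_block(vol[z], center[1:], roi_size_px).mean())


def background_square(
    stack: ImageStack,
    channel,
    points,
    roi_size_px: int = 25,
    modality: str | None = None,
    strict: bool = False,
) -> float:
    """Mean of per-ROI means over empty areas: the background estimate I_bcg.

    In strict mode the number of background points must match the modality
    convention (10 random empty areas for STED, 2 areas just above and below
    the bridging fiber for confocal).
    """
    points = list(points)
    if not points:
        raise InvalidParameterError("at least one background point required")
    if strict:
        if modality not in BACKGROUND_ROI_COUNT:
            raise InvalidParameterError("strict mode needs modality 'sted' or 'confocal'")
        need = BACKGROUND_ROI_COUNT[modality]
        if len(points) != need:
            raise InvalidParameterError(
                f"{modality} strict mode requires {need} background ROIs, got {len(points)}"
            )
    means = [measure_square_roi(stack, channel, p, roi_size_px) for p in points]
    return float(np.mean(means))


def corrected_fiber_intensity(raw, background: float):
    """Background-subtract raw ROI means.

    ``raw`` is either a single measurement (bridging or astral fiber: returns
    I_x = I_x+bcg − I_bcg) or a pair of sister k-fiber measurements (returns
    I_k = mean(sisters) − I_bcg).  Negative results are allowed and flow into
    bridging detection.
    """
    arr = np.atleast_1d(np.asarray(raw, dtype=float))
    if arr.size not in (1, 2):
        raise InvalidParameterError("raw must be one value or a sister pair")
    return float(arr.mean() - background)


def estimate_mt_number(I_x: float, I_k: float, n_k_ref: float = N_K_REFERENCE) -> float:
    """Ratiometric microtubule number: n_x = I_x × n_k / I_k.

    Requires a positive k-fiber calibration intensity I_k.
    """
    if I_k <= 0:
        raise InvalidParameterError("undefined calibration: I_k must be > 0")
    return I_x * n_k_ref / I_k


def detect_bridging(I_b: float, noise_floor: float = 0.0, sigma_bcg: float | None = None,
                    z_threshold: float = 0.0) -> bool:
    """Bridging fiber detected iff its background-subtracted signal exceeds
    the noise floor (strictly).  Optional z-score mode: I_b > z·σ_background.
    """
    floor = noise_floor
    if sigma_bcg is not None and z_threshold > 0:
        floor = max(floor, z_threshold * sigma_bcg)
    return bool(I_b > floor)


def line_profile_method(
    stack: ImageStack,
    channel,
    contour,
    z_plane: int,
    midzone_line,
    line_width_px: int = 5,
    window_halfwidth: float = 0.25,
    flank_offset: float = 1.5,
) -> ProfileMeasurement:
    """Pooled contour-profile measurement of I_b, I_bk and I_k.

    ``contour`` and ``midzone_line`` are polylines in world µm (x, y) on the
    given z-plane, the contour running along one k-fiber, across the bridge
    and along the sister k-fiber.  The minimum of the midzone profile is the
    background and is subtracted; the minimum of the subtracted contour
    profile defines the bridge centre (arclength zero).  I_b is the mean
    intensity within ±window_halfwidth of the centre (default ±0.25 µm, i.e.
    a 500 nm window); I_bk averages the two windows centred ±flank_offset
    (default 1.5 µm) from it; I_k = I_bk − I_b.
    """
    positions, profile = _sample_profile(stack, channel, contour, z_plane, line_width_px)
    if positions[-1] < 2 * flank_offset:
        raise InvalidParameterError(
            "contour shorter than twice the flank offset; cannot place k-fiber windows"
        )
    _, mz_profile = _sample_profile(stack, channel, midzone_line, z_plane, line_width_px)
    background = float(np.min(mz_profile))
    profile = profile - background

    # restrict the centre search away from the ends (the k-fiber flanks);
    # a flat-bottomed dip centres on the midpoint of its minimal plateau
    interior = (positions > flank_offset / 2) & (positions < positions[-1] - flank_offset / 2)
    interior_idx = np.flatnonzero(interior)
    vmin = profile[interior_idx].min()
    at_min = interior_idx[profile[interior_idx] <= vmin + 1e-9]
    center = float(positions[at_min].mean())

    spread = float(profile.max() - profile.min())
    degenerate = spread < 1e-9 or np.isclose(spread, 0.0)

    def window_mean(c):
        m = np.abs(positions - c) <= window_halfwidth
        if not m.any():
            raise InvalidParameterError("profile sampling too coarse for window")
        return float(profile[m].mean())

    I_b = window_mean(center)
    I_bk = 0.5 * (window_mean(center - flank_offset) + window_mean(center + flank_offset))
    return ProfileMeasurement(
        positions=positions - center,
        contour_profile=profile,
        midzone_min=background,
        bridge_center=center,
        I_b=I_b,
        I_bk=I_bk,
        degenerate_center=bool(degenerate),
    )


def _sample_profile(stack, channel, polyline_um, z_plane, line_width_px):
    """Intensity profile along a world-µm (x, y) polyline on one z-plane."""
    from skimage.measure import profile_line

    vol = stack.channel(channel)
    if not (0 <= z_plane < vol.shape[0]):
        raise OutOfBoundsError("z-plane outside the stack")
    plane = vol[z_plane]
    pts = np.asarray(polyline_um, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise InvalidParameterError("polyline needs >= 2 points")
    px = stack.optics.pixel_size_xy
    rc = np.stack(
        [(pts[:, 1] - stack.origin[1]) / px, (pts[:, 0] - stack.origin[0]) / px], axis=1
    )
    chunks, offsets = [], [0.0]
    for a, b in zip(rc[:-1], rc[1:]):
        seg = profile_line(plane, a, b, linewidth=line_width_px, mode="reflect")
        chunks.append(seg)
        offsets.append(offsets[-1] + np.linalg.norm(b - a) * px)
    profile = np.concatenate(chunks)
    positions = np.concatenate(
        [
            np.linspace(offsets[i], offsets[i + 1], len(chunks[i]))
            for i in range(len(chunks))
        ]
    )
    return positions, profile


def depletion_summary(control_n_b, control_n_k, depleted_n_b, depleted_n_k) -> dict:
    """Bookkeeping of microtubule loss between control and depleted spindles.

    Percent reduction per fiber class is 100 × (1 − mean_depleted /
    mean_control); the depleted means are the augmin-independent (remaining)
    counts and control − remaining the augmin-dependent counts.
    """
    out = {}
    for name, ctrl, depl in (
        ("bridging", np.asarray(control_n_b, float), np.asarray(depleted_n_b, float)),
        ("k", np.asarray(control_n_k, float), np.asarray(depleted_n_k, float)),
    ):
        if ctrl.size == 0 or depl.size == 0:
            raise InvalidParameterError("control and depleted lists must be non-empty")
        mc, md = float(np.nanmean(ctrl)), float(np.nanmean(depl))
        if mc == 0:
            raise InvalidParameterError(f"zero control mean for {name}-fiber class")
        out[f"percent_reduction_{name}"] = 100.0 * (1.0 - md / mc)
        out[f"n_{'b' if name == 'bridging' else 'k'}_remaining"] = md
        out[f"n_{'b' if name == 'bridging' else 'k'}_augmin"] = mc - md
    return out


def remaining_from_reduction(control_count: float, percent_reduction: float) -> float:
    """Remaining microtubule count implied by a printed percent reduction."""
    return control_count * (1.0 - percent_reduction / 100.0)
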