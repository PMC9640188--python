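"""Closed-loop simulation -> measurement experiments.

Each experiment plants known truth with the synthetic-spindle generator,
renders it, runs the corresponding measurement module, and returns planted
and recovered values side by side.  They are the package's validation
harness: the astral one-microtubule calibration check, end-on bundle
counting, interkinetochore-distance and tilt recovery, and the
depletion-bookkeeping pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import OpticsParams
from . import fiber_quant
from .fiber_quant import (
    N_K_REFERENCE,
    background_square,
    corrected_fiber_intensity,
    estimate_mt_number,
    measure_square_roi,
)
from .kc_geometry import (
    VoxelCalibration,
    corrected_displacement,
    kinetochore_tilt,
    localize_pair,
)
from .end_on_view import count_bundles, rotate_to_end_on, sum_projection
from .synthetic_spindle import (
    FiberClass,
    FiberSpec,
    KinetochorePair,
    SpindleModel,
    render,
)

__all__ = [
    "astral_calibration_experiment",
    "bundle_count_experiment",
    "pair_recovery_experiment",
    "fiber_recovery_experiment",
    "roi_annotations_from_model",
]


def _parallel_fiber_model(fiber_defs, length: float = 3.6) -> SpindleModel:
    """Straight fibers parallel to x at given (y, mt_count, class), all z=0."""
    half = length / 2.0
    fibers = [
        FiberSpec(
            fiber_class=cls,
            mt_count=mt,
            centerline=np.array([[-half, y, 0.0], [half, y, 0.0]]),
        )
        for (y, mt, cls) in fiber_defs
    ]
    poles = np.array([[-half, 0.0, 0.0], [half, 0.0, 0.0]])
    return SpindleModel(pole_positions=poles, kinetochore_pairs=[], fibers=fibers)


def astral_calibration_experiment(
    n_spindles: int = 30,
    seed: int = 0,
    optics: OpticsParams | None = None,
    noise: bool = True,
    astral_mt: float = 1.0,
    k_mt: float = N_K_REFERENCE,
) -> pd.DataFrame:
    """Recover the astral single-microtubule calibration on STED phantoms.

    Each phantom spindle carries two straight sister k-fibers (``k_mt``
    microtubules each) and three astral microtubules (``astral_mt``), imaged
    with STED optics.  Intensities are measured with 25×25 px square ROIs;
    the k-fiber background comes from 10 randomly placed empty areas and the
    astral background from the empty area between two astral fibers, then
    n_a = I_a × n_k / I_k.  Returns one row per astral fiber with planted and
    estimated counts.
    """
    optics = optics or OpticsParams.sted()
    rng = np.random.default_rng(seed)
    roi = 25

    # fiber lanes (y, µm); empty lanes in between host background ROIs
    k_ys = (-2.4, -1.4)
    astral_ys = (0.6, 1.6, 2.6)
    between_astral_ys = (1.1, 2.1)
    empty_ys = (-2.9, -1.9, -0.6, 0.1, 1.1, 2.1, 3.0)

    defs = [(y, k_mt, FiberClass.K_FIBER) for y in k_ys] + [
        (y, astral_mt, FiberClass.ASTRAL) for y in astral_ys
    ]
    rows = []
    for s in range(n_spindles):
        model = _parallel_fiber_model(defs)
        nz = 7
        ny = int(6.8 / optics.pixel_size_xy)
        nx = int(4.4 / optics.pixel_size_xy)
        origin = (
            -nx / 2 * optics.pixel_size_xy,
            -ny / 2 * optics.pixel_size_xy,
            -(nz // 2) * optics.z_sample_step,
        )
        stack = render(model, optics, shape=(nz, ny, nx), seed=seed * 1009 + s,
                       noise=noise, origin=origin)
        zc = nz // 2

        def vox(x, y):
            p = stack.world_to_voxel((x, y, 0.0))
            return (zc, p[1], p[2])

        # k-fiber calibration: ROI on each sister at a random x along the fiber
        xk = rng.uniform(-1.0, 1.0)
        raw_k = [measure_square_roi(stack, "tubulin", vox(xk, y), roi) for y in k_ys]
        bcg_pts = [vox(rng.uniform(-1.2, 1.2), empty_ys[i % len(empty_ys)])
                   for i in rng.permutation(10 * len(empty_ys))[:10]]
        i_bcg = background_square(stack, "tubulin", bcg_pts, roi,
                                  modality="sted", strict=True)
        I_k = corrected_fiber_intensity(raw_k, i_bcg)

        for y in astral_ys:
            xa = rng.uniform(-1.0, 1.0)
            raw_a = measure_square_roi(stack, "tubulin", vox(xa, y), roi)
            between = background_square(
                stack, "tubulin", [vox(xa, by) for by in between_astral_ys], roi
            )
            I_a = raw_a - between
            rows.append(
                dict(spindle=s, planted_mt=astral_mt,
                     I_a=I_a, I_k=I_k,
                     n_a=estimate_mt_number(I_a, I_k, N_K_REFERENCE))
            )
    return pd.DataFrame(rows)


def _ring_layout(n_bundles: int = 28, rotation: float = 0.0) -> np.ndarray:
    """(y, z) bundle positions on concentric rings, NN spacing ~1 µm >= 0.4."""
    radii = [0.0, 1.0, 1.9, 2.8]
    counts = [1, 6, 9, 12]
    offsets = [0.0, 0.0, np.deg2rad(20.0), np.deg2rad(35.0)]
    pts = []
    for r, n, off in zip(radii, counts, offsets):
        if r == 0:
            pts.append((0.0, 0.0))
            continue
        ang = off + rotation + np.arange(n) * 2 * np.pi / n
        pts.extend(zip(r * np.cos(ang), r * np.sin(ang)))
    pts = np.asarray(pts)
    if n_bundles > len(pts):
        raise ValueError("ring layout supports at most 28 bundles")
    return pts[:n_bundles]


def bundle_count_experiment(
    n_bundles: int = 28,
    n_seeds: int = 10,
    seed: int = 0,
    optics: OpticsParams | None = None,
    noise: bool = True,
) -> pd.DataFrame:
    """Plant PRC1 overlap bundles, reslice end-on, count spots.

    ``n_bundles`` bundles run parallel to the spindle axis at cross-section
    positions with >= 0.4 µm spacing; the PRC1 channel is rendered as a
    z-stack, transformed end-on with the 0.81 axial correction, sum-projected
    over 10 central slices and fed to the peak counter.  One row per seed
    with planted and recovered counts.
    """
    optics = optics or OpticsParams()
    rows = []
    for i in range(n_seeds):
        rng = np.random.default_rng(seed * 7919 + i)
        yz = _ring_layout(n_bundles, rotation=rng.uniform(0, 2 * np.pi))
        fibers = [
            FiberSpec(
                fiber_class=FiberClass.INTERPOLAR_NO_KC,
                mt_count=3.8,
                centerline=np.array([[-2.0, y, z], [2.0, y, z]]),
            )
            for y, z in yz
        ]
        model = SpindleModel(
            pole_positions=np.array([[-2.0, 0.0, 0.0], [2.0, 0.0, 0.0]]),
            kinetochore_pairs=[],
            fibers=fibers,
        )
        nx = int(5.6 / optics.pixel_size_xy)
        ny = int(7.2 / optics.pixel_size_xy)
        nz = int(7.2 / optics.z_sample_step)
        origin = (
            -nx / 2 * optics.pixel_size_xy,
            -ny / 2 * optics.pixel_size_xy,
            -nz / 2 * optics.z_sample_step,
        )
        stack = render(model, optics, shape=(nz, ny, nx), seed=seed * 7919 + i,
                       noise=noise, origin=origin, prc1_overlap_length=4.0)
        end_on = rotate_to_end_on(stack.channel("prc1"), optics)
        proj = sum_projection(end_on, n_central=10)
        count, _ = count_bundles(proj, end_on.pixel_size)
        rows.append(dict(seed=i, planted=n_bundles, counted=count))
    return pd.DataFrame(rows)


def pair_recovery_experiment(
    n_pairs: int = 120,
    separation: float = 0.98,
    tilt_deg: float | None = None,
    seed: int = 0,
    optics: OpticsParams | None = None,
    noise: bool = True,
) -> pd.DataFrame:
    """Recover interkinetochore distance and tilt from rendered puncta pairs.

    Each pair is placed in its own small volume at the planted ``separation``
    with either a uniformly random 3D orientation or, when ``tilt_deg`` is
    given, a sister axis at exactly that angle to the pole (x) axis with a
    random azimuth.  Sisters are localized by iterative Gaussian-masked
    centroid and distances/tilts computed in 0.81-corrected coordinates.
    """
    optics = optics or OpticsParams()
    rng = np.random.default_rng(seed)
    cal = VoxelCalibration(optics.pixel_size_xy, optics.z_step, optics.axial_scale)
    nz, ny, nx = 11, 40, 40

    rows = []
    for i in range(n_pairs):
        if tilt_deg is None:
            v = rng.normal(size=3)
            direction = v / np.linalg.norm(v)
        else:
            th = np.deg2rad(tilt_deg)
            psi = rng.uniform(0, 2 * np.pi)
            direction = np.array(
                [np.cos(th), np.sin(th) * np.cos(psi), np.sin(th) * np.sin(psi)]
            )
        # random sub-voxel phase of the pair midpoint
        mid = rng.uniform(-0.2, 0.2, size=3)
        s1 = mid - 0.5 * separation * direction
        s2 = mid + 0.5 * separation * direction
        pair = KinetochorePair(pair_id=i, sister1=s1, sister2=s2,
                               tilt_deg=0.0 if tilt_deg is None else tilt_deg,
                               separation=separation)
        model = SpindleModel(
            pole_positions=np.array([[-3.0, 0.0, 0.0], [3.0, 0.0, 0.0]]),
            kinetochore_pairs=[pair],
            fibers=[],
        )
        origin = (
            -nx / 2 * optics.pixel_size_xy,
            -ny / 2 * optics.pixel_size_xy,
            -nz / 2 * optics.z_sample_step,
        )
        stack = render(model, optics, shape=(nz, ny, nx), seed=seed * 65537 + i,
                       noise=noise, origin=origin)
        loc = localize_pair(
            stack, "kinetochore",
            stack.world_to_voxel(s1), stack.world_to_voxel(s2),
        )
        # voxel (plane,row,col) -> annotation order (x_px, y_px, z_plane)
        a1 = (loc[0][2], loc[0][1], loc[0][0])
        a2 = (loc[1][2], loc[1][1], loc[1][0])
        meas_sep = corrected_displacement(a1, a2, cal.pixel_size, cal.z_step, cal.axial_scale)
        pole_ann = [
            (p[2], p[1], p[0])
            for p in stack.world_to_voxel(model.pole_positions)
        ]
        meas_tilt = kinetochore_tilt(a1, a2, pole_ann, cal)
        rows.append(
            dict(pair=i, planted_separation=separation,
                 planted_tilt=np.nan if tilt_deg is None else tilt_deg,
                 measured_separation=meas_sep, measured_tilt=meas_tilt)
        )
    return pd.DataFrame(rows)


def fiber_recovery_experiment(
    mt_counts: dict | None = None,
    seed: int = 0,
    optics: OpticsParams | None = None,
    noise: bool = False,
) -> pd.DataFrame:
    """Square-ROI microtubule-count recovery for every fiber class on
    parallel straight-fiber phantoms (noiseless by default)."""
    optics = optics or OpticsParams.sted()
    mt_counts = mt_counts or {"k_fiber": 12.6, "bridging": 3.8, "astral": 1.0}
    lanes = [
        (-2.2, mt_counts["k_fiber"], FiberClass.K_FIBER),
        (-1.2, mt_counts["k_fiber"], FiberClass.K_FIBER),
        (0.0, mt_counts["bridging"], FiberClass.BRIDGING),
        (1.2, mt_counts["astral"], FiberClass.ASTRAL),
    ]
    model = _parallel_fiber_model(lanes)
    nz, roi = 7, 25
    ny = int(6.0 / optics.pixel_size_xy)
    nx = int(4.4 / optics.pixel_size_xy)
    origin = (
        -nx / 2 * optics.pixel_size_xy,
        -(ny / 2 + int(0.5 / optics.pixel_size_xy)) * optics.pixel_size_xy,
        -(nz // 2) * optics.z_sample_step,
    )
    stack = render(model, optics, shape=(nz, ny, nx), seed=seed, noise=noise,
                   origin=origin)
    zc = nz // 2

    def vox(x, y):
        p = stack.world_to_voxel((x, y, 0.0))
        return (zc, p[1], p[2])

    bcg = background_square(stack, "tubulin",
                            [vox(x, -2.9) for x in (-1.2, -0.4, 0.4, 1.2)], roi)
    I_k = corrected_fiber_intensity(
        [measure_square_roi(stack, "tubulin", vox(0.0, y), roi) for y in (-2.2, -1.2)],
        bcg,
    )
    rows = []
    for y, mt, cls in lanes[1:]:
        I_x = measure_square_roi(stack, "tubulin", vox(0.0, y), roi) - bcg
        rows.append(
            dict(fiber_class=cls.value, planted_mt=mt,
                 estimated_mt=estimate_mt_number(I_x, I_k, N_K_REFERENCE))
        )
    return pd.DataFrame(rows)


def roi_annotations_from_model(model: SpindleModel, stack) -> pd.DataFrame:
    """Square-ROI annotations (bridging / k-fiber / background) derived from
    a simulated spindle's known geometry, in the annotation CSV schema."""
    rng = np.random.default_rng(model.seed + 12345)
    rows = []

    def ann(structure, pair_id, world):
        p = stack.world_to_voxel(np.asarray(world))
        rows.append(
            dict(structure=structure, pair_id=pair_id,
                 x_px=float(p[2]), y_px=float(p[1]), z_plane=int(round(p[0])))
        )

    bridge_pairs = model.bridging_pair_ids()
    for f in model.fibers:
        if f.fiber_class is FiberClass.BRIDGING:
            mid = f.centerline[len(f.centerline) // 2]
            ann("bridging", f.linked_pair_id, mid)
        elif f.fiber_class is FiberClass.K_FIBER:
            # pole-side of the kinetochore: 90% along the pole->kinetochore arc
            idx = int(0.9 * (len(f.centerline) - 1))
            ann("k_fiber", f.linked_pair_id, f.centerline[idx])
    # pairs whose bridge was removed still get a bridging ROI between sisters
    for p in model.kinetochore_pairs:
        if p.pair_id not in bridge_pairs:
            ann("bridging", p.pair_id, p.midpoint)
    # background: random empty-ish points near the volume faces
    shape = stack.channel(0).shape
    for _ in range(10):
        rows.append(
            dict(structure="background", pair_id=-1,
                 x_px=float(rng.uniform(3, shape[2] - 4)),
                 y_px=float(rng.choice([4.0, shape[1] - 5.0])),
                 z_plane=int(rng.integers(0, shape[0]))))
    return pd.DataFrame(rows)
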