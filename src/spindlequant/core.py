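"""Core containers: optical calibration, calibrated image stacks, errors.

All world coordinates are in micrometres (µm) with axes (x, y, z), where x is
the in-plane axis the spindle is aligned to, y the transverse in-plane axis and
z the optical (stage) axis.  Voxel coordinates follow the numpy axis order of
the stored arrays, (plane, row, col) = (z, y, x).

Axial distances recorded as stage z-steps underestimate true sample depth when
an oil objective images an aqueous sample; the ``axial_scale`` factor (default
0.81) converts stage z-distance to true z-distance.  The simulator places
sources at plane index z_true / (axial_scale * z_step) so that measurements
applying the same correction recover true axial distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

CHANNELS = ("tubulin", "kinetochore", "prc1")


class InvalidParameterError(ValueError):
    """A parameter violates its documented range or units."""


class OutOfBoundsError(ValueError):
    """A ROI, line or model extends beyond the image volume."""


class DegenerateGeometryError(ValueError):
    """Coincident points / zero-length vectors where geometry is required."""


class SchemaError(ValueError):
    """A tabular input does not match the documented schema."""


class DependencyError(RuntimeError):
    """A pipeline stage is missing an input produced by an earlier stage."""


@dataclass(frozen=True)
class OpticsParams:
    """Acquisition and rendering parameters of one imaging modality.

    Parameters
    ----------
    pixel_size_xy : float
        In-plane pixel size, µm/pixel.
    z_step : float
        Stage step between acquired planes, µm.
    psf_sigma_xy, psf_sigma_z : float
        Gaussian PSF standard deviations (true sample space), µm.
    background_level : float
        Additive background, arbitrary units (a.u.).
    unit_brightness : float
        Line brightness of a single microtubule, a.u. per µm of length.
    punctum_brightness : float
        Integrated brightness of one kinetochore punctum, a.u.
    poisson_gain : float
        Photons per a.u.; 0 disables shot noise.
    read_noise_sigma : float
        Additive Gaussian read noise, a.u.; 0 disables.
    axial_scale : float
        True-z per stage-z correction factor (oil objective, aqueous sample).
    """

    pixel_size_xy: float = 0.083
    z_step: float = 0.5
    psf_sigma_xy: float = 0.11
    psf_sigma_z: float = 0.35
    background_level: float = 20.0
    unit_brightness: float = 3000.0
    punctum_brightness: float = 5000.0
    poisson_gain: float = 1.0
    read_noise_sigma: float = 2.0
    axial_scale: float = 0.81

    def __post_init__(self) -> None:
        for name in ("pixel_size_xy", "z_step", "psf_sigma_xy", "psf_sigma_z"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if not (0.0 < self.axial_scale <= 1.0):
            raise InvalidParameterError("axial_scale must be in (0, 1]")
        if self.background_level < 0:
            raise InvalidParameterError("background_level must be >= 0")

    @property
    def z_sample_step(self) -> float:
        """True sample-depth distance between adjacent planes, µm."""
        return self.z_step * self.axial_scale

    @classmethod
    def confocal(cls, **overrides) -> "OpticsParams":
        """Spinning-disk confocal preset: 83 nm pixels, 0.5 µm z-steps."""
        return cls(**overrides)

    @classmethod
    def sted(cls, **overrides) -> "OpticsParams":
        """STED preset: 20 nm pixels, 0.3 µm z-steps, narrow lateral PSF."""
        params = dict(
            pixel_size_xy=0.020,
            z_step=0.3,
            psf_sigma_xy=0.035,
            psf_sigma_z=0.35,
            unit_brightness=20000.0,
        )
        params.update(overrides)
        return cls(**params)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ImageStack:
    """A calibrated multi-channel voxel volume, optionally time-resolved.

    ``data`` has axes (C, Z, Y, X) for a single time point or (T, C, Z, Y, X)
    for a time-lapse.  ``origin`` is the world position (x, y, z) in µm of the
    centre of voxel (plane 0, row 0, col 0).
    """

    data: np.ndarray
    optics: OpticsParams
    channel_names: tuple = CHANNELS
    origin: tuple = (0.0, 0.0, 0.0)
    frame_interval_s: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (4, 5):
            raise InvalidParameterError(
                "ImageStack data must be (C, Z, Y, X) or (T, C, Z, Y, X)"
            )

    @property
    def is_timelapse(self) -> bool:
        return self.data.ndim == 5

    @property
    def n_channels(self) -> int:
        return self.data.shape[1] if self.is_timelapse else self.data.shape[0]

    def channel_index(self, channel) -> int:
        if isinstance(channel, (int, np.integer)):
            return int(channel)
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise InvalidParameterError(
                f"unknown channel {channel!r}; have {self.channel_names}"
            ) from None

    def channel(self, channel, frame: int | None = None) -> np.ndarray:
        """Return the (Z, Y, X) volume of one channel (and frame if 4D+t)."""
        c = self.channel_index(channel)
        if self.is_timelapse:
            if frame is None:
                raise InvalidParameterError("time-lapse stack: frame required")
            return self.data[frame, c]
        return self.data[c]

    def world_to_voxel(self, xyz) -> np.ndarray:
        """World (x, y, z) µm -> fractional voxel (plane, row, col).

        The plane index uses stage z: plane = (z - z0) / (axial_scale·z_step),
        i.e. true depth compressed exactly as the microscope records it.
        """
        x, y, z = np.asarray(xyz, dtype=float).T
        o = self.optics
        plane = (z - self.origin[2]) / o.z_sample_step
        row = (y - self.origin[1]) / o.pixel_size_xy
        col = (x - self.origin[0]) / o.pixel_size_xy
        return np.stack([plane, row, col], axis=-1)

    def voxel_to_world(self, prc) -> np.ndarray:
        """Fractional voxel (plane, row, col) -> world (x, y, z) µm."""
        prc = np.asarray(prc, dtype=float)
        plane, row, col = prc.T if prc.ndim > 1 else prc
        o = self.optics
        x = self.origin[0] + col * o.pixel_size_xy
        y = self.origin[1] + row * o.pixel_size_xy
        z = self.origin[2] + plane * o.z_sample_step
        return np.stack([x, y, z], axis=-1)
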