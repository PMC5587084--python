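"""Shared domain types: imaging configuration, images, movies, ROIs, geometry.

Conventions
-----------
* Physical coordinates are in micrometres (μm), image origin top-left,
  ``y`` increasing downward.  A pixel with index ``(row, col)`` has its
  centre at ``((col + 0.5) * px, (row + 0.5) * px)`` where ``px`` is the
  pixel size in μm.  All pixel-space intervals are half-open.
* Time is in seconds for imaging/photobleaching and minutes for the
  slow NE-accumulation kinetics (field names carry the unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np


class ErneticsError(Exception):
    """Base class for package errors."""


class NoNucleusFound(ErneticsError):
    """Nucleus segmentation produced no component above the area cutoff."""


class BandDegenerate(ErneticsError):
    """Inward erosion emptied the nuclear mask; no NE band can be built."""


class NoSignal(ErneticsError):
    """Integrated intensity is zero after background subtraction."""


class FitFailure(ErneticsError):
    """Curve fit failed to converge from every starting point."""


class NoAccumulation(ErneticsError):
    """Accumulation curve is flat relative to its noise level."""


class PlanarityError(ErneticsError):
    """A graph expected to be planar has crossing edges."""


class ConfigError(ErneticsError):
    """A run configuration failed schema validation."""


@dataclass(frozen=True)
class ImagingConfig:
    """Synthetic acquisition parameters.

    Parameters
    ----------
    pixel_size_nm : float
        Physical length of one pixel side, nm.
    frame_interval_s : float
        Time between consecutive frames, s.
    psf_sigma_nm : float
        Gaussian point-spread-function sigma, nm (0 disables blurring).
    photon_scale : float
        Multiplicative gain from expected density to expected photons.
    read_noise_sd : float
        Additive Gaussian read noise, photon units (0 disables).
    width_px, height_px : int
        Frame dimensions.
    shot_noise : bool
        Apply Poisson shot noise to the expected photon field (disable
        together with ``read_noise_sd=0`` for noiseless renders).
    """

    pixel_size_nm: float = 100.0
    frame_interval_s: float = 4.0
    # diffraction-limited Gaussian sigma for a 63x/1.4 NA objective at
    # 488 nm (FWHM ~235 nm)
    psf_sigma_nm: float = 100.0
    photon_scale: float = 1.0
    read_noise_sd: float = 1.0
    width_px: int = 256
    height_px: int = 256
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_nm and frame_interval_s must be > 0")
        if self.psf_sigma_nm < 0 or self.read_noise_sd < 0:
            raise ValueError("psf_sigma_nm and read_noise_sd must be >= 0")
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be > 0")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("frame dimensions must be > 0")

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0

    @property
    def field_um(self) -> tuple[float, float]:
        """(width, height) of the field of view in μm."""
        return (self.width_px * self.pixel_size_um,
                self.height_px * self.pixel_size_um)

    def to_dict(self) -> dict:
        return {
            "pixel_size_nm": self.pixel_size_nm,
            "frame_interval_s": self.frame_interval_s,
            "psf_sigma_nm": self.psf_sigma_nm,
            "photon_scale": self.photon_scale,
            "read_noise_sd": self.read_noise_sd,
            "width_px": self.width_px,
            "height_px": self.height_px,
            "shot_noise": self.shot_noise,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ImagingConfig":
        return cls(**d)


@dataclass
class MicroImage:
    """A single multi-channel frame.

    ``data`` has shape ``(n_channels, height, width)``; ``channels`` holds
    one label per channel (e.g. ``("dapi", "gfp")``).
    """

    data: np.ndarray
    channels: tuple[str, ...]
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("MicroImage data must be (channels, H, W)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel labels must match data channels")

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channels.index(label)]

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0


@dataclass
class Movie:
    """A time series of multi-channel frames: ``data`` is (T, C, H, W)."""

    data: np.ndarray
    channels: tuple[str, ...]
    pixel_size_nm: float
    frame_interval_s: float
    times_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("Movie data must be (T, C, H, W)")
        if len(self.channels) != self.data.shape[1]:
            raise ValueError("channel labels must match data channels")
        if self.times_s is None:
            self.times_s = np.arange(self.data.shape[0]) * self.frame_interval_s
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.shape[0] != self.data.shape[0]:
            raise ValueError("times_s must have one entry per frame")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def channel(self, label: str) -> np.ndarray:
        """(T, H, W) stack for one channel."""
        return self.data[:, self.channels.index(label)]

    def frame(self, t: int) -> MicroImage:
        return MicroImage(self.data[t], self.channels, self.pixel_size_nm)

    @property
    def pixel_size_um(self) -> float:
        return self.pixel_size_nm / 1000.0


@dataclass(frozen=True)
class Roi:
    """A circular, rectangular or annular ROI in physical (μm) coordinates.

    ``dims_um`` is ``(radius,)`` for circles, ``(width, height)`` for
    rectangles and ``(r_inner, r_outer)`` for annuli (the FLIP "donut");
    ``center_um`` is the ROI centre ``(x, y)``.
    """

    shape: str
    center_um: tuple[float, float]
    dims_um: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.shape not in ("circle", "rectangle", "annulus"):
            raise ValueError("shape must be 'circle', 'rectangle' or 'annulus'")
        if self.shape == "circle" and len(self.dims_um) != 1:
            raise ValueError("circle dims_um is (radius,)")
        if self.shape == "rectangle" and len(self.dims_um) != 2:
            raise ValueError("rectangle dims_um is (width, height)")
        if self.shape == "annulus":
            if len(self.dims_um) != 2:
                raise ValueError("annulus dims_um is (r_inner, r_outer)")
            if self.dims_um[0] >= self.dims_um[1]:
                raise ValueError("annulus needs r_inner < r_outer")
        if any(d <= 0 for d in self.dims_um):
            raise ValueError("ROI dimensions must be > 0")

    @property
    def area_um2(self) -> float:
        if self.shape == "circle":
            return float(np.pi * self.dims_um[0] ** 2)
        if self.shape == "annulus":
            return float(np.pi * (self.dims_um[1] ** 2 - self.dims_um[0] ** 2))
        return float(self.dims_um[0] * self.dims_um[1])

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized point-membership test in μm coordinates."""
        cx, cy = self.center_um
        if self.shape == "circle":
            return (x - cx) ** 2 + (y - cy) ** 2 <= self.dims_um[0] ** 2
        if self.shape == "annulus":
            d2 = (x - cx) ** 2 + (y - cy) ** 2
            return (d2 >= self.dims_um[0] ** 2) & (d2 <= self.dims_um[1] ** 2)
        w, h = self.dims_um
        return ((np.abs(x - cx) <= w / 2.0) & (np.abs(y - cy) <= h / 2.0))

    def mask(self, height_px: int, width_px: int, pixel_size_um: float) -> np.ndarray:
        """Boolean pixel mask (pixel centres inside the ROI)."""
        yy, xx = np.mgrid[0:height_px, 0:width_px]
        x = (xx + 0.5) * pixel_size_um
        y = (yy + 0.5) * pixel_size_um
        return self.contains(x, y)

    def bounds_um(self) -> tuple[float, float, float, float]:
        cx, cy = self.center_um
        if self.shape in ("circle", "annulus"):
            r = self.dims_um[-1]
            return (cx - r, cy - r, cx + r, cy + r)
        w, h = self.dims_um
        return (cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)

    def to_dict(self) -> dict:
        return {"shape": self.shape, "center_um": list(self.center_um),
                "dims_um": list(self.dims_um)}

    @classmethod
    def from_dict(cls, d: dict) -> "Roi":
        return cls(d["shape"], tuple(d["center_um"]), tuple(d["dims_um"]))


@dataclass(frozen=True)
class CellGeometry:
    """Nucleus ellipse plus the polygonal cell boundary containing the ER."""

    nucleus_center_um: tuple[float, float]
    nucleus_radii_um: tuple[float, float]
    cell_boundary_um: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if min(self.nucleus_radii_um) <= 0:
            raise ValueError("nucleus semi-axes must be > 0")
        from shapely.geometry import Point, Polygon

        poly = Polygon(self.cell_boundary_um)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("cell boundary must be a valid polygon")
        ellipse = Point(self.nucleus_center_um).buffer(1.0, quad_segs=32)
        import shapely.affinity as aff

        ellipse = aff.scale(ellipse, *self.nucleus_radii_um,
                            origin=self.nucleus_center_um)
        if not poly.contains(ellipse):
            raise ValueError("nucleus must lie strictly inside the cell boundary")

    @classmethod
    def boxed(cls, width_um: float, height_um: float,
              nucleus_center_um: tuple[float, float] | None = None,
              nucleus_radii_um: tuple[float, float] = (5.0, 4.0)) -> "CellGeometry":
        """Rectangular cell boundary spanning the field, nucleus near centre."""
        if nucleus_center_um is None:
            nucleus_center_um = (width_um / 2.0, height_um / 2.0)
        box = ((0.0, 0.0), (width_um, 0.0), (width_um, height_um), (0.0, height_um))
        return cls(nucleus_center_um, nucleus_radii_um, box)

    def nucleus_polygon(self, quad_segs: int = 64):
        from shapely.geometry import Point
        import shapely.affinity as aff

        circ = Point(self.nucleus_center_um).buffer(1.0, quad_segs=quad_segs)
        return aff.scale(circ, *self.nucleus_radii_um, origin=self.nucleus_center_um)

    def nucleus_mask(self, height_px: int, width_px: int,
                     pixel_size_um: float) -> np.ndarray:
        """Analytic filled-ellipse mask over pixel centres."""
        yy, xx = np.mgrid[0:height_px, 0:width_px]
        x = (xx + 0.5) * pixel_size_um
        y = (yy + 0.5) * pixel_size_um
        cx, cy = self.nucleus_center_um
        rx, ry = self.nucleus_radii_um
        return ((x - cx) / rx) ** 2 + ((y - cy) / ry) ** 2 <= 1.0


@dataclass(frozen=True)
class BleachSchedule:
    """Photobleach protocol: pre-bleach frame count plus timed events.

    Each event is ``(time_s, roi, depletion_factor)``: at ``time_s`` every
    fluorescent particle inside ``roi`` stays fluorescent with probability
    ``depletion_factor`` (0 = complete bleach within the ROI).
    """

    events: tuple[tuple[float, Roi, float], ...]
    pre_frames: int = 3

    def __post_init__(self) -> None:
        times = [e[0] for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("bleach event times must be non-decreasing")
        if any(not (0.0 <= e[2] <= 1.0) for e in self.events):
            raise ValueError("depletion_factor must be in [0, 1]")
        if self.pre_frames < 0:
            raise ValueError("pre_frames must be >= 0")

    @classmethod
    def frap(cls, roi: Roi, bleach_time_s: float, pre_frames: int = 3,
             depletion_factor: float = 0.0) -> "BleachSchedule":
        """Single-bleach schedule (3 pre-bleach frames by default)."""
        return cls(((bleach_time_s, roi, depletion_factor),), pre_frames)

    @classmethod
    def flip(cls, roi: Roi, start_s: float, interval_s: float = 4.5,
             duration_s: float = 720.0, pre_frames: int = 2,
             depletion_factor: float = 0.0) -> "BleachSchedule":
        """Repeated-bleach schedule: spot bleached every ``interval_s``
        from ``start_s`` to ``duration_s`` (12-min course by default)."""
        times = np.arange(start_s, duration_s, interval_s)
        return cls(tuple((float(t), roi, depletion_factor) for t in times),
                   pre_frames)


@dataclass
class GroundTruth:
    """Generator-side record of the true parameters behind a synthetic dataset."""

    seed: int
    ne_fraction_true: float | None = None
    diffusion_um2_s: float | None = None
    immobile_fraction: float | None = None
    attach_success_p: float | None = None
    kinetic_params: dict | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("ne_fraction_true", "immobile_fraction", "attach_success_p"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.diffusion_um2_s is not None and self.diffusion_um2_s < 0:
            raise ValueError("diffusion_um2_s must be >= 0")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "ne_fraction_true": self.ne_fraction_true,
            "diffusion_um2_s": self.diffusion_um2_s,
            "immobile_fraction": self.immobile_fraction,
            "attach_success_p": self.attach_success_p,
            "kinetic_params": self.kinetic_params,
            "extra": self.extra,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(**d)
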