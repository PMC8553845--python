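"""Image-side stage: pseudopupil centre detection, intensity profiles,
width/offset measurements, pixel-to-lattice registration and facet-diameter
measurement.

Pixel coordinates are ``(row, col)`` with row 0 at the top of the image, as
stored; the lattice registration (:func:`pixel_to_lattice`) converts to the
y-up planar basis internally so that image and visual-field handedness agree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import (
    ConfigurationError,
    InvalidInputError,
    NoSignalError,
    RegistrationError,
    UnboundedProfileError,
)
from .hexlattice import LatticeCoord, LatticeFrame, cart_to_lattice, lattice_to_cart

__all__ = [
    "ImageFrame",
    "IntensityProfile",
    "DetectionResult",
    "detect_centre",
    "line_profile",
    "profile_peak",
    "profile_fwhm",
    "centre_offset",
    "pixel_to_lattice",
    "solve_lattice_frame",
    "facet_diameter_line",
]


@dataclass(frozen=True)
class ImageFrame:
    """2-D non-negative intensity raster with a physical pixel scale.

    Synthetic frames carry generator metadata (exact lattice registration,
    landmark positions, true pseudopupil centre); frames read from disk have
    these set to their defaults.
    """

    intensities: np.ndarray
    pixel_scale_um: float
    lattice_frame: LatticeFrame | None = None
    landmarks_px: tuple[tuple[float, float], ...] = ()
    landmarks_lattice: tuple[LatticeCoord, ...] = ()
    true_centre_px: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 2 or min(arr.shape) < 8:
            raise InvalidInputError(f"frame must be 2-D and at least 8x8, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)) or arr.min() < 0:
            raise InvalidInputError("frame intensities must be finite and non-negative")
        if not self.pixel_scale_um > 0:
            raise InvalidInputError("pixel_scale_um must be > 0")
        object.__setattr__(self, "intensities", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass(frozen=True)
class IntensityProfile:
    """Sampled relative-intensity profile along a line.

    ``positions`` are monotone, in the unit recorded in ``unit`` (µm when the
    frame's pixel scale was applied); ``values`` are min–max normalized to
    [0, 1]. A profile sampled from a constant region is all-zero and flagged
    ``flat``.
    """

    positions: np.ndarray
    values: np.ndarray
    unit: str = "um"
    flat: bool = False

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        val = np.asarray(self.values, dtype=float)
        if pos.shape != val.shape or pos.ndim != 1:
            raise InvalidInputError("positions and values must be equal-length 1-D arrays")
        if np.any(np.diff(pos) <= 0):
            raise InvalidInputError("positions must be strictly increasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "values", val)

    def inverted(self) -> "IntensityProfile":
        """The profile flipped about its maximum (for dark-pupil callers)."""
        if self.flat:
            return self
        v = self.values.max() - self.values
        rng = v.max() - v.min()
        return IntensityProfile(self.positions, v / rng if rng > 0 else v, self.unit, self.flat)


@dataclass(frozen=True)
class DetectionResult:
    """Sub-pixel pseudopupil centre plus the support used to compute it."""

    centre_px: tuple[float, float]
    n_pixels: int
    peak_value: float


def detect_centre(
    frame: ImageFrame,
    threshold_frac: float = 0.5,
    mode: str = "bright",
) -> DetectionResult:
    """Locate the pseudopupil centre as a thresholded intensity centroid.

    Pixels at or above ``min + threshold_frac * (max - min)`` are segmented
    into connected components; the component containing the global maximum is
    kept and its background-subtracted, intensity-weighted centroid returned.
    ``mode="dark"`` runs the identical estimator on the inverted frame, the
    convention adopted here for the broad incident-light pseudopupil. The
    estimator is invariant to affine rescaling of the intensities.
    """
    if not (0.0 < threshold_frac < 1.0):
        raise InvalidInputError(f"threshold_frac must be in (0, 1), got {threshold_frac}")
    if mode not in ("bright", "dark"):
        raise InvalidInputError(f"unknown mode {mode!r}")
    arr = frame.intensities
    if mode == "dark":
        arr = arr.max() - arr
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise NoSignalError("flat frame: no pseudopupil signal")
    level = lo + threshold_frac * (hi - lo)
    mask = arr >= level
    labels = measure.label(mask, connectivity=2)
    peak_idx = np.unravel_index(int(np.argmax(arr)), arr.shape)
    component = labels == labels[peak_idx]
    weights = np.where(component, arr - level, 0.0)
    total = weights.sum()
    rows, cols = np.nonzero(component)
    if total > 0:
        r = float((weights[rows, cols] * rows).sum() / total)
        c = float((weights[rows, cols] * cols).sum() / total)
    else:  # single-pixel or razor-thin component: unweighted centroid
        r, c = float(rows.mean()), float(cols.mean())
    return DetectionResult(centre_px=(r, c), n_pixels=int(component.sum()), peak_value=hi)


def line_profile(
    frame: ImageFrame,
    p0_px: tuple[float, float],
    p1_px: tuple[float, float],
    n_samples: int = 101,
) -> IntensityProfile:
    """Bilinear intensity profile between two pixel positions.

    Positions are distances along the line in µm (``pixel_scale_um`` applied);
    values are min–max normalized.
    """
    if n_samples < 3:
        raise InvalidInputError("n_samples must be >= 3")
    h, w = frame.shape
    for name, (r, c) in (("p0_px", p0_px), ("p1_px", p1_px)):
        if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
            raise InvalidInputError(f"{name}={p0_px if name == 'p0_px' else p1_px} outside frame {frame.shape}")
    t = np.linspace(0.0, 1.0, n_samples)
    rows = p0_px[0] + t * (p1_px[0] - p0_px[0])
    cols = p0_px[1] + t * (p1_px[1] - p0_px[1])
    vals = ndimage.map_coordinates(frame.intensities, [rows, cols], order=1, mode="nearest")
    length_um = float(np.hypot(p1_px[0] - p0_px[0], p1_px[1] - p0_px[1])) * frame.pixel_scale_um
    positions = t * length_um if length_um > 0 else t
    rng = vals.max() - vals.min()
    if rng > 0:
        vals = (vals - vals.min()) / rng
        flat = False
    else:
        vals = np.zeros_like(vals)
        flat = True
    return IntensityProfile(positions=positions, values=vals, unit="um", flat=flat)


def profile_peak(profile: IntensityProfile) -> float:
    """Position of the profile maximum; ties broken by the smallest position."""
    if profile.flat:
        raise NoSignalError("flat profile: no peak")
    return float(profile.positions[int(np.argmax(profile.values))])


def profile_fwhm(profile: IntensityProfile) -> float:
    """Full width at half maximum of the profile's main peak.

    The half level is midway between the profile's extremes; the two
    crossings nearest the peak are linearly interpolated between samples.
    """
    if profile.flat:
        raise NoSignalError("flat profile: no peak")
    pos, val = profile.positions, profile.values
    i_peak = int(np.argmax(val))
    half = 0.5 * (val.max() + val.min())

    def crossing(direction: int) -> float:
        i = i_peak
        while 0 <= i + direction < len(val):
            j = i + direction
            if val[j] < half <= val[i]:
                frac = (val[i] - half) / (val[i] - val[j])
                return float(pos[i] + frac * (pos[j] - pos[i]))
            i = j
        raise UnboundedProfileError(
            "profile does not cross half-maximum on the "
            + ("right" if direction > 0 else "left")
        )

    return crossing(+1) - crossing(-1)


def centre_offset(
    r1: DetectionResult, r2: DetectionResult, pixel_scale_um: float
) -> float:
    """Euclidean distance between two detected centres, in µm."""
    d = np.hypot(r1.centre_px[0] - r2.centre_px[0], r1.centre_px[1] - r2.centre_px[1])
    return float(d) * pixel_scale_um


def pixel_to_lattice(centre_px: tuple[float, float], frame_ref: LatticeFrame) -> LatticeCoord:
    """Map a pixel position to fractional lattice coordinates.

    Inverse of the registration: translate to the lattice origin, flip row to
    y-up, rotate by ``-orientation_deg``, scale to facet units, convert to
    axial coordinates.
    """
    if frame_ref.pitch_px <= 0:
        raise ConfigurationError("lattice frame pitch must be positive")
    row0, col0 = frame_ref.origin_px
    x_px = centre_px[1] - col0
    y_px = row0 - centre_px[0]
    th = -np.radians(frame_ref.orientation_deg)
    x = (np.cos(th) * x_px - np.sin(th) * y_px) / frame_ref.pitch_px
    y = (np.sin(th) * x_px + np.cos(th) * y_px) / frame_ref.pitch_px
    return cart_to_lattice((x, y))


def solve_lattice_frame(
    landmark_px: list[tuple[float, float]],
    landmark_lattice: list,
    pixel_scale_um: float | None = None,
) -> tuple[LatticeFrame, float]:
    """Least-squares similarity registration from landmark correspondences.

    Fits rotation + uniform scale + translation mapping integer lattice
    positions onto their pixel positions, as a complex linear least squares
    (planar point ``x + iy`` against pixel ``col - i*row``). Requires at
    least two distinct landmarks. Returns the solved frame and the RMS pixel
    residual.
    """
    if len(landmark_px) != len(landmark_lattice):
        raise RegistrationError("landmark lists differ in length")
    if len(landmark_px) < 2:
        raise RegistrationError("at least 2 landmark correspondences required")
    z = np.array([complex(*lattice_to_cart(c)) for c in landmark_lattice])
    q = np.array([complex(col, -row) for row, col in landmark_px])
    if np.allclose(z, z[0]):
        raise RegistrationError("degenerate landmark set: all lattice points coincide")
    a_mat = np.column_stack([z, np.ones_like(z)])
    coef, *_ = np.linalg.lstsq(a_mat, q, rcond=None)
    a, b = coef
    if abs(a) < 1e-12:
        raise RegistrationError("degenerate solution: zero scale")
    resid = a_mat @ coef - q
    rms = float(np.sqrt(np.mean(np.abs(resid) ** 2)))
    frame = LatticeFrame(
        pitch_px=float(abs(a)),
        orientation_deg=float(np.degrees(np.angle(a))),
        origin_px=(-b.imag, b.real),
        pixel_scale_um=pixel_scale_um,
    )
    return frame, rms


def facet_diameter_line(
    p0_px: tuple[float, float],
    p1_px: tuple[float, float],
    n_facets: int,
    pixel_scale_um: float,
) -> float:
    """Mean facet diameter from a straight line drawn across ``n_facets``.

    Mirrors the manual measurement of drawing a line through several in-focus
    ommatidia and dividing its length by their count; 5–8 facets give stable
    averages, other counts trigger a warning.
    """
    if n_facets < 2:
        raise InvalidInputError("n_facets must be >= 2")
    if not 5 <= n_facets <= 8:
        warnings.warn(
            f"facet count {n_facets} outside the recommended 5-8 range", stacklevel=2
        )
    length = np.hypot(p1_px[0] - p0_px[0], p1_px[1] - p0_px[1])
    if length == 0:
        raise InvalidInputError("zero-length measurement line")
    return float(length) * pixel_scale_um / n_facets
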