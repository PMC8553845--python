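"""Synthetic compound-eye generator: ground-truth gaze field, goniometer
scans, and rendered pseudopupil image frames.

The generator stands in for raw goniometer imagery of a real eye. It builds a
per-facet *gaze field* — the visual-field direction (azimuth, elevation)
viewed by each ommatidium — by integrating a parametric interommatidial-angle
(acuity) field over the hexagonal lattice, then

* inverts that field to produce pseudopupil-centre observations for any
  goniometer pose (the facet looking straight back at the observer), and
* renders phenomenological epifluorescence / incident-light frames in which
  facet brightness follows a Gaussian envelope around the viewing axis.

The gaze field is a flat chart over (azimuth, elevation) in degrees: moving
one facet pitch horizontally advances azimuth by the local field value, one
pitch vertically advances elevation likewise. Because the acuity field is
piecewise linear, both the integral (planar position -> gaze) and its inverse
are evaluated in closed form, so observation generation is exact to machine
precision rather than to an ODE tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Iterator, Literal, NamedTuple

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, InvalidInputError, PoseOutOfRangeError
from .hexlattice import LatticeCoord, LatticeFrame, cart_to_lattice, lattice_to_cart
from .pupil_detect import ImageFrame

__all__ = [
    "AcuityField",
    "EyeModel",
    "GonioPose",
    "Observation",
    "OpticsParams",
    "HONEYBEE_FIELD",
    "honeybee_eye",
    "uniform_eye",
    "eval_acuity",
    "build_eye",
    "observe",
    "scan",
    "render_frame",
]

DEFAULT_LAT_RANGE = (-40.0, 40.0)
DEFAULT_LON_RANGE = (-10.0, 60.0)
DEFAULT_STEP_DEG = 10.0


@dataclass(frozen=True)
class AcuityField:
    r"""Parametric interommatidial-angle field over the visual field.

    The local angle (degrees between neighbouring ommatidial axes) is

    .. math::

        \Delta\varphi(az, el) = \Delta\varphi_{min}
            + s_{az}\,\max(|az| - w, 0)
            + s_{d}\,\max(el - w, 0)
            + s_{v}\,\max(-el - w, 0)

    i.e. a flat acute-zone plateau of half-width ``w`` around the frontal
    axis, with independent linear fall-off of resolution towards lateral,
    dorsal and ventral visual fields. Continuous, and everywhere at least
    ``dphi_min_deg``.
    """

    dphi_min_deg: float
    plateau_halfwidth_deg: float = 0.0
    slope_az: float = 0.0
    slope_dorsal: float = 0.0
    slope_ventral: float = 0.0

    def __post_init__(self) -> None:
        if not (self.dphi_min_deg > 0):
            raise InvalidInputError("dphi_min_deg must be > 0")
        for name in ("plateau_halfwidth_deg", "slope_az", "slope_dorsal", "slope_ventral"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")

    def __call__(self, az_deg, el_deg):
        return eval_acuity(self, az_deg, el_deg)


#: Constructed honeybee-forager preset. The numbers are *derived constants*,
#: not anatomical measurements: they are chosen so that 10-degree-step finite
#: differencing of the resulting gaze field (which recovers the harmonic mean
#: of the field across each step) reproduces the forager acute-zone figures —
#: minimum 1.3 deg on the frontal axis, below 1.7 deg along the equator to
#: 40 deg azimuth, below 1.9 deg down to -30 deg elevation, above 2 deg by
#: +20 deg elevation. The plateau half-width of 10 deg makes the recovered
#: frontal minimum equal 1.30 exactly.
HONEYBEE_FIELD = AcuityField(
    dphi_min_deg=1.30,
    plateau_halfwidth_deg=10.0,
    slope_az=0.00875,
    slope_dorsal=0.10,
    slope_ventral=0.015,
)


def eval_acuity(field: AcuityField, az_deg, el_deg):
    """Evaluate the acuity field; degrees in, interommatidial degrees out."""
    az = np.asarray(az_deg, dtype=float)
    el = np.asarray(el_deg, dtype=float)
    if not (np.all(np.isfinite(az)) and np.all(np.isfinite(el))):
        raise InvalidInputError("angles must be finite")
    w = field.plateau_halfwidth_deg
    out = (
        field.dphi_min_deg
        + field.slope_az * np.maximum(np.abs(az) - w, 0.0)
        + field.slope_dorsal * np.maximum(el - w, 0.0)
        + field.slope_ventral * np.maximum(-el - w, 0.0)
    )
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# closed-form integration of d(angle)/d(position) = base + slope*max(|a|-w, 0)
# ---------------------------------------------------------------------------

def _pos_of_angle(angle: float, base: float, slope: float, w: float) -> float:
    """Planar position whose integrated angle equals `angle` (odd in angle)."""
    a = abs(angle)
    if a <= w or slope == 0.0:
        pos = a / base if a <= w else w / base + (a - w) / base
    else:
        pos = w / base + np.log1p(slope * (a - w) / base) / slope
    return float(np.copysign(pos, angle))


def _angle_of_pos(pos: float, base: float, slope: float, w: float) -> float:
    """Inverse of :func:`_pos_of_angle`."""
    p = abs(pos)
    pw = w / base
    if p <= pw or slope == 0.0:
        a = p * base
    else:
        a = w + base * np.expm1(slope * (p - pw)) / slope
    return float(np.copysign(a, pos))


class GonioPose(NamedTuple):
    """One goniometer pose: latitude = elevation axis, longitude = azimuth."""

    latitude_deg: float
    longitude_deg: float


@dataclass(frozen=True)
class Observation:
    """Pseudopupil centre seen at one goniometer pose."""

    pose: GonioPose
    centre: LatticeCoord
    facet_diameter_um: float
    frame_id: str | None = None


@dataclass(frozen=True)
class EyeModel:
    """Ground-truth synthetic eye: acuity field + gaze field over the lattice.

    ``extent`` gives inclusive integer ranges for the two lattice axes; the
    facet at (0, 0) gazes along (0, 0) by construction. Elevation is assigned
    along the vertical planar axis by integrating the frontal-meridian acuity
    per unit planar y; azimuth along each horizontal row by integrating the
    row's acuity per unit planar x. Both integrals are closed-form.
    """

    field: AcuityField
    extent: tuple[tuple[int, int], tuple[int, int]]
    pitch_um: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        (u0, u1), (v0, v1) = self.extent
        if u0 >= u1 or v0 >= v1:
            raise ConfigurationError(f"degenerate extent {self.extent}")
        if not self.pitch_um > 0:
            raise ConfigurationError("pitch_um must be > 0")

    # -- elevation along the central column ------------------------------
    def _el_base(self) -> tuple[float, float, float, float]:
        f = self.field
        return f.dphi_min_deg, f.plateau_halfwidth_deg, f.slope_dorsal, f.slope_ventral

    def _y_of_el(self, el: float) -> float:
        c0, w, sd, sv = self._el_base()
        slope = sd if el >= 0 else sv
        return _pos_of_angle(el, c0, slope, w)

    def _el_of_y(self, y: float) -> float:
        c0, w, sd, sv = self._el_base()
        slope = sd if y >= 0 else sv
        return _angle_of_pos(y, c0, slope, w)

    # -- azimuth along a row at fixed elevation --------------------------
    def _row_base(self, el: float) -> float:
        # elevation-dependent plateau value of the row's acuity profile
        return eval_acuity(self.field, 0.0, el)

    def _x_of_az(self, az: float, el: float) -> float:
        f = self.field
        return _pos_of_angle(az, self._row_base(el), f.slope_az, f.plateau_halfwidth_deg)

    def _az_of_x(self, x: float, el: float) -> float:
        f = self.field
        return _angle_of_pos(x, self._row_base(el), f.slope_az, f.plateau_halfwidth_deg)

    # -- public gaze field ----------------------------------------------
    def gaze_at_planar(self, x: float, y: float) -> tuple[float, float]:
        """Gaze direction (azimuth_deg, elevation_deg) at a planar position."""
        el = self._el_of_y(y)
        az = self._az_of_x(x, el)
        return az, el

    def gaze(self, coord) -> tuple[float, float]:
        """Gaze direction of a (possibly fractional) lattice coordinate."""
        x, y = lattice_to_cart(coord)
        return self.gaze_at_planar(x, y)

    def planar_of_gaze(self, az_deg: float, el_deg: float) -> tuple[float, float]:
        """Planar position of the facet gazing along (az, el); exact inverse."""
        y = self._y_of_el(el_deg)
        x = self._x_of_az(az_deg, el_deg)
        return x, y

    def contains_planar(self, x: float, y: float) -> bool:
        u, v = cart_to_lattice((x, y))
        (u0, u1), (v0, v1) = self.extent
        return (u0 <= u <= u1) and (v0 <= v <= v1)

    def gaze_range_contains(self, pose: GonioPose) -> bool:
        x, y = self.planar_of_gaze(pose.longitude_deg, pose.latitude_deg)
        return self.contains_planar(x, y)


def build_eye(
    field: AcuityField,
    extent: tuple[tuple[int, int], tuple[int, int]] | None = None,
    pitch_um: float = 20.0,
    seed: int = 0,
    *,
    scan_lat: tuple[float, float] = DEFAULT_LAT_RANGE,
    scan_lon: tuple[float, float] = DEFAULT_LON_RANGE,
    margin: int = 3,
) -> EyeModel:
    """Construct an :class:`EyeModel`, checking the extent covers the scan.

    With ``extent=None`` a minimal extent covering the requested scan ranges
    (plus ``margin`` facets — raise it when rendering frames, so the mosaic
    fills the field of view at edge poses) is derived from the field itself.
    """
    probe = EyeModel(field, ((-1, 1), (-1, 1)), pitch_um, seed)
    corners = [
        probe.planar_of_gaze(lon, lat)
        for lat in scan_lat
        for lon in scan_lon
    ]
    uv = np.array([cart_to_lattice(p) for p in corners])
    if extent is None:
        extent = (
            (int(np.floor(uv[:, 0].min())) - margin, int(np.ceil(uv[:, 0].max())) + margin),
            (int(np.floor(uv[:, 1].min())) - margin, int(np.ceil(uv[:, 1].max())) + margin),
        )
    model = EyeModel(field, extent, pitch_um, seed)
    for lat in scan_lat:
        for lon in scan_lon:
            if not model.gaze_range_contains(GonioPose(lat, lon)):
                raise ConfigurationError(
                    f"extent {extent} too small: pose (lat {lat}, lon {lon}) "
                    "falls outside the eye"
                )
    return model


def honeybee_eye(pitch_um: float = 20.0, seed: int = 0) -> EyeModel:
    """The honeybee-forager preset eye covering the default scan grid."""
    return build_eye(HONEYBEE_FIELD, pitch_um=pitch_um, seed=seed)


def uniform_eye(g_deg: float = 2.0, pitch_um: float = 20.0, seed: int = 0) -> EyeModel:
    """An eye with spatially uniform interommatidial angle ``g_deg``."""
    return build_eye(AcuityField(dphi_min_deg=g_deg), pitch_um=pitch_um, seed=seed)


def observe(
    model: EyeModel,
    pose: GonioPose,
    noise_sd_facets: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Observation:
    """Pseudopupil-centre observation for one goniometer pose.

    The centre is the (fractional) lattice coordinate whose gaze equals the
    pose, from the closed-form inverse of the gaze field. Localization noise,
    when requested, is zero-mean Gaussian applied independently to the two
    planar components (centre-detection error is a distance in facets).
    """
    pose = GonioPose(*pose)
    if not model.gaze_range_contains(pose):
        raise PoseOutOfRangeError(
            f"pose (lat {pose.latitude_deg}, lon {pose.longitude_deg}) outside eye gaze range"
        )
    x, y = model.planar_of_gaze(pose.longitude_deg, pose.latitude_deg)
    if noise_sd_facets > 0:
        if rng is None:
            rng = np.random.default_rng(model.seed)
        x += rng.normal(0.0, noise_sd_facets)
        y += rng.normal(0.0, noise_sd_facets)
    return Observation(
        pose=pose,
        centre=cart_to_lattice((x, y)),
        facet_diameter_um=model.pitch_um,
    )


def _grid_axis(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def scan(
    model: EyeModel,
    lat_range: tuple[float, float] = DEFAULT_LAT_RANGE,
    lon_range: tuple[float, float] = DEFAULT_LON_RANGE,
    step_deg: float = DEFAULT_STEP_DEG,
    noise_sd_facets: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[Observation]:
    """Goniometer scan: one observation per grid node, latitude-major order."""
    if step_deg <= 0:
        raise ConfigurationError("step_deg must be > 0")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    out = []
    for lat in _grid_axis(lat_range[0], lat_range[1], step_deg):
        for lon in _grid_axis(lon_range[0], lon_range[1], step_deg):
            out.append(observe(model, GonioPose(lat, lon), noise_sd_facets, rng))
    return out


# ---------------------------------------------------------------------------
# frame rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticsParams:
    """Phenomenological imaging parameters for rendered frames.

    ``na`` is the numerical aperture of the objective; the angular width of
    the pseudopupil envelope is ``sigma_deg = pupil_sigma_deg_per_na * na``
    (the default factor, 180/pi, makes sigma equal the NA acceptance
    half-angle in degrees for small NA). The incident-light ("dark") pupil
    shares the same centre but is broader by ``dark_width_factor``. Rendered
    facets are flat discs convolved with a Gaussian imaging blur of half a
    facet pitch, which washes out mosaic ripple without shifting the
    envelope; landmark facets saturate, emulating fluorescent crystals
    sprinkled on the cornea for registration.
    """

    na: float = 0.15
    pupil_sigma_deg_per_na: float = 180.0 / np.pi
    dark_width_factor: float = 1.6
    landmark_count: int = 0
    noise_sd: float = 0.0
    pixel_scale_um: float = 2.5
    image_size_px: tuple[int, int] = (384, 384)

    def __post_init__(self) -> None:
        if not (0.0 < self.na < 1.0):
            raise ConfigurationError("na must be in (0, 1)")
        if self.pupil_sigma_deg_per_na <= 0 or self.pixel_scale_um <= 0:
            raise ConfigurationError("scale parameters must be positive")
        if self.dark_width_factor <= 1.0:
            raise ConfigurationError("dark_width_factor must exceed 1")
        if self.landmark_count < 0 or self.noise_sd < 0:
            raise ConfigurationError("counts and noise must be non-negative")

    @property
    def sigma_deg(self) -> float:
        return self.pupil_sigma_deg_per_na * self.na


def render_frame(
    model: EyeModel,
    pose: GonioPose,
    optics: OpticsParams = OpticsParams(),
    mode: Literal["fluorescent", "dark"] = "fluorescent",
    rng: np.random.Generator | None = None,
    orientation_deg: float = 0.0,
) -> ImageFrame:
    """Render a synthetic eye-surface frame at one goniometer pose.

    Facet brightness in fluorescent mode is ``exp(-theta^2 / 2 sigma^2)``
    with ``theta`` the angular distance between the facet's gaze and the
    pose; dark mode renders the inverted envelope ``B0 (1 - c exp(...))``
    with the broader sigma. The image is centred on the true pseudopupil
    centre, so its lattice registration (returned in ``frame.lattice_frame``)
    and landmark list are exact generator metadata.
    """
    pose = GonioPose(*pose)
    h, w = optics.image_size_px
    pitch_px = model.pitch_um / optics.pixel_scale_um
    if min(h, w) < 7 * pitch_px:
        raise ConfigurationError(
            f"image {optics.image_size_px} smaller than 7 facet pitches ({7 * pitch_px:.0f} px)"
        )
    if not model.gaze_range_contains(pose):
        raise PoseOutOfRangeError(f"pose {pose} outside eye gaze range")
    if rng is None:
        rng = np.random.default_rng(model.seed)

    cx, cy = model.planar_of_gaze(pose.longitude_deg, pose.latitude_deg)
    theta = np.radians(orientation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    centre_px = np.array([(w - 1) / 2.0, (h - 1) / 2.0])  # (col, y-up row)

    def planar_to_px(x: float, y: float) -> tuple[float, float]:
        dx, dy = rot @ np.array([x - cx, y - cy])
        col = centre_px[0] + pitch_px * dx
        row = (h - 1) - (centre_px[1] + pitch_px * dy)
        return row, col

    # facets whose disc could intersect the frame
    half_diag_facets = np.hypot(h, w) / (2 * pitch_px) + 1
    (u0, u1), (v0, v1) = model.extent
    img = np.zeros((h, w), dtype=float)
    sigma = optics.sigma_deg
    if mode == "dark":
        sigma *= optics.dark_width_factor
    b0, contrast = 0.85, 0.9

    visible: list[tuple[LatticeCoord, tuple[float, float]]] = []
    r_px = 0.5 * pitch_px
    yy, xx = np.mgrid[0:h, 0:w]
    for u in range(u0, u1 + 1):
        for v in range(v0, v1 + 1):
            x, y = lattice_to_cart((u, v))
            if np.hypot(x - cx, y - cy) > half_diag_facets:
                continue
            row, col = planar_to_px(x, y)
            if not (-r_px <= row < h + r_px and -r_px <= col < w + r_px):
                continue
            az, el = model.gaze_at_planar(x, y)
            t2 = (az - pose.longitude_deg) ** 2 + (el - pose.latitude_deg) ** 2
            envelope = np.exp(-t2 / (2.0 * sigma**2))
            bright = envelope if mode == "fluorescent" else b0 * (1.0 - contrast * envelope)
            visible.append((LatticeCoord(u, v), (row, col)))
            rlo, rhi = max(int(row - r_px) - 1, 0), min(int(row + r_px) + 2, h)
            clo, chi = max(int(col - r_px) - 1, 0), min(int(col + r_px) + 2, w)
            patch = (yy[rlo:rhi, clo:chi] - row) ** 2 + (xx[rlo:rhi, clo:chi] - col) ** 2
            img[rlo:rhi, clo:chi][patch <= r_px**2] = bright

    landmarks_px: list[tuple[float, float]] = []
    landmarks_lattice: list[LatticeCoord] = []
    if optics.landmark_count > 0:
        idx = rng.choice(len(visible), size=min(optics.landmark_count, len(visible)), replace=False)
        for i in sorted(idx):
            coord, (row, col) = visible[i]
            if 0 <= row < h and 0 <= col < w:
                patch = (yy - row) ** 2 + (xx - col) ** 2
                img[patch <= r_px**2] = 1.0
                landmarks_px.append((row, col))
                landmarks_lattice.append(coord)

    # imaging blur: half a facet pitch suppresses mosaic ripple in profiles
    img = ndimage.gaussian_filter(img, sigma=0.5 * pitch_px, mode="nearest")
    if optics.noise_sd > 0:
        img = img + rng.normal(0.0, optics.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    prow, pcol = planar_to_px(cx, cy)  # = image centre by construction
    origin_row, origin_col = planar_to_px(0.0, 0.0)
    return ImageFrame(
        intensities=img,
        pixel_scale_um=optics.pixel_scale_um,
        lattice_frame=LatticeFrame(
            pitch_px=pitch_px,
            orientation_deg=orientation_deg,
            origin_px=(origin_row, origin_col),
            pixel_scale_um=optics.pixel_scale_um,
        ),
        landmarks_px=tuple(landmarks_px),
        landmarks_lattice=tuple(landmarks_lattice),
        true_centre_px=(prow, pcol),
    )
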