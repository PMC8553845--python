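"""Core estimation: pseudopupil displacement per goniometer rotation ->
local interommatidial angles -> acuity map of the visual field.

At each goniometer grid node the pseudopupil centre's planar displacement per
degree of rotation forms a 2x2 displacement matrix ``M`` (facets/degree);
its inverse ``J`` (degrees/facet) gives the local angular step of the gaze
field. The horizontal and vertical interommatidial angles are the planar
norms of ``J``'s action on unit steps, and the three-row average follows the
hexagonal axes. Because a 10-degree goniometer step spans about five facets,
the finite-difference estimate is inherently a local average over the
equivalent of a 5x5-facet rhomboid of eye surface; no extra smoothing is
applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DegenerateNodeError, InvalidInputError, MapInputError, NoSignalError
from .hexlattice import hex_axes, lattice_to_cart
from .synthetic_eye import Observation

__all__ = [
    "ObservationGrid",
    "MapNode",
    "AcuityMap",
    "MapSummary",
    "displacement_matrix",
    "local_jacobian",
    "dphi_components",
    "dphi_three_axis",
    "hex_combine",
    "build_map",
    "summarize",
]

_DET_TOL = 1e-9


@dataclass(frozen=True)
class ObservationGrid:
    """Observations arranged on the rectangular goniometer grid.

    ``x``/``y`` are planar facet coordinates of the pseudopupil centre,
    NaN where an observation is missing; axes are sorted ascending.
    """

    latitudes: np.ndarray  # (n_lat,)
    longitudes: np.ndarray  # (n_lon,)
    x: np.ndarray  # (n_lat, n_lon)
    y: np.ndarray
    facet_diameter_um: np.ndarray

    @classmethod
    def from_observations(cls, observations: list[Observation]) -> "ObservationGrid":
        if not observations:
            raise MapInputError("no observations")
        lats = np.array(sorted({o.pose.latitude_deg for o in observations}))
        lons = np.array(sorted({o.pose.longitude_deg for o in observations}))
        shape = (len(lats), len(lons))
        x = np.full(shape, np.nan)
        y = np.full(shape, np.nan)
        d = np.full(shape, np.nan)
        seen = np.zeros(shape, dtype=bool)
        for o in observations:
            i = int(np.argmin(np.abs(lats - o.pose.latitude_deg)))
            j = int(np.argmin(np.abs(lons - o.pose.longitude_deg)))
            # tolerate NaN centres (failed detections) instead of erroring:
            # they surface as invalid nodes after differencing
            u, v = o.centre
            x[i, j], y[i, j] = u + 0.5 * v, v * np.sqrt(3.0) / 2.0
            d[i, j] = o.facet_diameter_um
            seen[i, j] = True
        if not seen.all():
            missing = [
                (float(lats[i]), float(lons[j]))
                for i, j in zip(*np.nonzero(~seen))
            ]
            raise MapInputError(
                f"observations do not form a rectangular grid; missing nodes "
                f"(lat, lon): {missing}"
            )
        for name, ax in (("latitude", lats), ("longitude", lons)):
            if len(ax) > 1 and not np.allclose(np.diff(ax), np.diff(ax)[0]):
                raise MapInputError(f"{name} axis is not uniformly spaced: {ax}")
        return cls(lats, lons, x, y, d)

    def node_index(self, node: tuple[float, float]) -> tuple[int, int]:
        """Grid indices of a (latitude, longitude) node."""
        lat, lon = node
        i = int(np.argmin(np.abs(self.latitudes - lat)))
        j = int(np.argmin(np.abs(self.longitudes - lon)))
        if abs(self.latitudes[i] - lat) > 1e-9 or abs(self.longitudes[j] - lon) > 1e-9:
            raise MapInputError(f"node (lat {lat}, lon {lon}) not on the grid")
        return i, j


def _axis_derivative(values: np.ndarray, coords: np.ndarray, axis: int) -> np.ndarray:
    """Finite difference along one axis: central interior, one-sided edges.

    Exactly ``np.gradient`` semantics; NaN neighbours propagate so nodes with
    missing observations come out invalid rather than silently interpolated.
    """
    if values.shape[axis] < 2:
        return np.full_like(values, np.nan)
    return np.gradient(values, coords, axis=axis)


def displacement_matrix(
    grid: ObservationGrid,
    node: tuple[float, float],
    cos_lat_correction: bool = False,
) -> np.ndarray:
    """2x2 pseudopupil displacement per degree of rotation at one grid node.

    Column 1 is the finite difference of the planar centre with respect to
    longitude (divided by ``cos(latitude)`` when the correction is enabled,
    turning the longitude step into an effective visual-field step); column 2
    the same with respect to latitude. Central differences at interior nodes,
    one-sided at edges. Units: facets/degree.
    """
    i, j = grid.node_index(node)
    m = _displacement_field(grid, cos_lat_correction)[i, j]
    if not np.all(np.isfinite(m)):
        raise DegenerateNodeError(
            f"node (lat {node[0]}, lon {node[1]}) lacks the neighbours needed "
            "for finite differences"
        )
    return m


def _displacement_field(grid: ObservationGrid, cos_lat_correction: bool) -> np.ndarray:
    """(n_lat, n_lon, 2, 2) displacement matrices for every node."""
    dx_dlon = _axis_derivative(grid.x, grid.longitudes, axis=1)
    dy_dlon = _axis_derivative(grid.y, grid.longitudes, axis=1)
    dx_dlat = _axis_derivative(grid.x, grid.latitudes, axis=0)
    dy_dlat = _axis_derivative(grid.y, grid.latitudes, axis=0)
    if cos_lat_correction:
        cos_lat = np.cos(np.radians(grid.latitudes))[:, None]
        dx_dlon = dx_dlon / cos_lat
        dy_dlon = dy_dlon / cos_lat
    m = np.empty(grid.x.shape + (2, 2))
    m[..., 0, 0] = dx_dlon
    m[..., 1, 0] = dy_dlon
    m[..., 0, 1] = dx_dlat
    m[..., 1, 1] = dy_dlat
    return m


def local_jacobian(m: np.ndarray) -> np.ndarray:
    """Invert a displacement matrix: degrees of gaze rotation per facet step."""
    m = np.asarray(m, dtype=float)
    if m.shape != (2, 2) or not np.all(np.isfinite(m)):
        raise InvalidInputError(f"expected a finite 2x2 matrix, got {m!r}")
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    if abs(det) <= _DET_TOL:
        raise DegenerateNodeError(f"near-singular displacement matrix (det={det:g})")
    return np.array([[m[1, 1], -m[0, 1]], [-m[1, 0], m[0, 0]]]) / det


def dphi_components(j: np.ndarray) -> tuple[float, float, float]:
    """Horizontal/vertical interommatidial angles and their average.

    The angles are the gaze-rotation magnitudes produced by unit planar facet
    steps along x and y: the norms of the Jacobian's columns.
    """
    j = np.asarray(j, dtype=float)
    dphi_h = float(np.hypot(j[0, 0], j[1, 0]))
    dphi_v = float(np.hypot(j[0, 1], j[1, 1]))
    return dphi_h, dphi_v, 0.5 * (dphi_h + dphi_v)


def dphi_three_axis(j: np.ndarray) -> float:
    """Interommatidial angle averaged over the three hexagonal row directions."""
    j = np.asarray(j, dtype=float)
    norms = []
    for axis in hex_axes():
        ex, ey = lattice_to_cart(axis)
        norms.append(np.hypot(j[0, 0] * ex + j[0, 1] * ey, j[1, 0] * ex + j[1, 1] * ey))
    return float(np.mean(norms))


def hex_combine(dphi_h: float, dphi_v: float) -> float:
    """Quadrature combination of horizontal and vertical components.

    The allowance for the hexagonal lattice: ``sqrt(dphi_h^2 + dphi_v^2)``.
    Note the horizontal component here is the per-facet horizontal angle —
    half the horizontal row separation, since adjacent rows are staggered by
    half a facet; that halving is the caller's responsibility.
    """
    if dphi_h < 0 or dphi_v < 0:
        raise InvalidInputError("components must be non-negative")
    return float(np.hypot(dphi_h, dphi_v))


@dataclass(frozen=True)
class MapNode:
    """One visual-field node of the acuity map."""

    azimuth_deg: float
    elevation_deg: float
    dphi_h_deg: float
    dphi_v_deg: float
    dphi_mean_deg: float
    dphi_3axis_deg: float
    facet_diameter_um: float
    valid: bool
    edge: bool


@dataclass(frozen=True)
class AcuityMap:
    """Rectangular grid of acuity-map nodes plus scan metadata."""

    nodes: tuple[MapNode, ...]
    latitudes: np.ndarray
    longitudes: np.ndarray
    step_deg: float

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.latitudes) * len(self.longitudes):
            raise InvalidInputError("node count does not match grid shape")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.latitudes), len(self.longitudes)

    def node_at(self, azimuth_deg: float, elevation_deg: float) -> MapNode:
        for n in self.nodes:
            if (
                abs(n.azimuth_deg - azimuth_deg) < 1e-9
                and abs(n.elevation_deg - elevation_deg) < 1e-9
            ):
                return n
        raise MapInputError(f"no map node at (az {azimuth_deg}, el {elevation_deg})")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "azimuth_deg": [n.azimuth_deg for n in self.nodes],
                "elevation_deg": [n.elevation_deg for n in self.nodes],
                "dphi_h_deg": [n.dphi_h_deg for n in self.nodes],
                "dphi_v_deg": [n.dphi_v_deg for n in self.nodes],
                "dphi_mean_deg": [n.dphi_mean_deg for n in self.nodes],
                "dphi_3axis_deg": [n.dphi_3axis_deg for n in self.nodes],
                "facet_diameter_um": [n.facet_diameter_um for n in self.nodes],
                "valid": [int(n.valid) for n in self.nodes],
                "edge_flag": [int(n.edge) for n in self.nodes],
            }
        )

    def field(self, name: str) -> np.ndarray:
        """A node attribute as an (n_lat, n_lon) array (NaN where invalid)."""
        vals = np.array(
            [getattr(n, name) if n.valid else np.nan for n in self.nodes]
        )
        return vals.reshape(self.shape)


def build_map(
    observations: list[Observation],
    cos_lat_correction: bool = False,
    median_filter: bool = False,
) -> AcuityMap:
    """Assemble the acuity map from a rectangular goniometer scan.

    Per node: displacement matrix -> local Jacobian -> horizontal/vertical
    and three-axis interommatidial angles; facet diameters are copied from
    the observations. Map azimuth is goniometer longitude, elevation is
    latitude. Nodes with missing neighbours or singular displacement are
    flagged invalid, never interpolated. ``median_filter`` applies an
    optional 3x3 node median to the angle fields (off by default).
    """
    grid = ObservationGrid.from_observations(observations)
    m_field = _displacement_field(grid, cos_lat_correction)
    n_lat, n_lon = grid.x.shape
    fields = {k: np.full((n_lat, n_lon), np.nan) for k in ("h", "v", "mean", "ax3")}
    valid = np.zeros((n_lat, n_lon), dtype=bool)
    for i in range(n_lat):
        for j in range(n_lon):
            m = m_field[i, j]
            # a node missing its own centre is invalid even though central
            # differences would not consume it: no silent interpolation
            if not (np.isfinite(grid.x[i, j]) and np.isfinite(grid.y[i, j])):
                continue
            if not np.all(np.isfinite(m)):
                continue
            try:
                jac = local_jacobian(m)
            except DegenerateNodeError:
                continue
            h, v, mean = dphi_components(jac)
            fields["h"][i, j] = h
            fields["v"][i, j] = v
            fields["mean"][i, j] = mean
            fields["ax3"][i, j] = dphi_three_axis(jac)
            valid[i, j] = True
    if median_filter:
        for k, arr in fields.items():
            filt = ndimage.median_filter(arr, size=3, mode="nearest")
            fields[k] = np.where(valid, filt, arr)
    edge = np.zeros((n_lat, n_lon), dtype=bool)
    edge[0, :] = edge[-1, :] = True
    edge[:, 0] = edge[:, -1] = True
    steps = np.diff(grid.latitudes) if n_lat > 1 else np.diff(grid.longitudes)
    nodes = tuple(
        MapNode(
            azimuth_deg=float(grid.longitudes[j]),
            elevation_deg=float(grid.latitudes[i]),
            dphi_h_deg=float(fields["h"][i, j]),
            dphi_v_deg=float(fields["v"][i, j]),
            dphi_mean_deg=float(fields["mean"][i, j]),
            dphi_3axis_deg=float(fields["ax3"][i, j]),
            facet_diameter_um=float(grid.facet_diameter_um[i, j]),
            valid=bool(valid[i, j]),
            edge=bool(edge[i, j]),
        )
        for i in range(n_lat)
        for j in range(n_lon)
    )
    return AcuityMap(
        nodes=nodes,
        latitudes=grid.latitudes,
        longitudes=grid.longitudes,
        step_deg=float(steps[0]) if len(steps) else 0.0,
    )


@dataclass(frozen=True)
class MapSummary:
    """Headline numbers of an acuity map at a given threshold."""

    dphi_min_deg: float
    argmin: tuple[float, float]  # (azimuth_deg, elevation_deg)
    threshold_deg: float
    equator_extent_deg: float
    frontal_meridian_extent_deg: float
    region_node_count: int


#: slack added to the threshold when delimiting the sub-threshold region, so
#: that a node sitting numerically on the contour still counts as inside it
_THRESHOLD_SLACK = 0.05


def summarize(acuity_map: AcuityMap, threshold_deg: float = 2.0) -> MapSummary:
    """Acute-zone summary: minimum, its location, and sub-threshold extents.

    The minimum is over valid nodes' ``dphi_mean``; ties resolve toward the
    frontal axis (smallest |elevation|, then |azimuth|, then signed values).
    Extents are azimuth span of qualifying equatorial nodes and elevation
    span of qualifying frontal-meridian nodes, where qualifying means
    ``dphi_mean <= threshold + 0.05``.
    """
    if threshold_deg <= 0:
        raise InvalidInputError("threshold_deg must be > 0")
    valid_nodes = [n for n in acuity_map.nodes if n.valid]
    if not valid_nodes:
        raise NoSignalError("map has no valid nodes")
    best = min(
        valid_nodes,
        key=lambda n: (
            n.dphi_mean_deg,
            abs(n.elevation_deg),
            abs(n.azimuth_deg),
            n.elevation_deg,
            n.azimuth_deg,
        ),
    )
    cutoff = threshold_deg + _THRESHOLD_SLACK

    def span(values: list[float]) -> float:
        return max(values) - min(values) if len(values) >= 2 else 0.0

    eq_el = min((abs(n.elevation_deg) for n in valid_nodes))
    eq_az = [
        n.azimuth_deg
        for n in valid_nodes
        if abs(abs(n.elevation_deg) - eq_el) < 1e-9 and n.dphi_mean_deg <= cutoff
    ]
    mer_az = min((abs(n.azimuth_deg) for n in valid_nodes))
    mer_el = [
        n.elevation_deg
        for n in valid_nodes
        if abs(abs(n.azimuth_deg) - mer_az) < 1e-9 and n.dphi_mean_deg <= cutoff
    ]
    count = sum(1 for n in valid_nodes if n.dphi_mean_deg <= threshold_deg)
    return MapSummary(
        dphi_min_deg=best.dphi_mean_deg,
        argmin=(best.azimuth_deg, best.elevation_deg),
        threshold_deg=threshold_deg,
        equator_extent_deg=span(eq_az),
        frontal_meridian_extent_deg=span(mer_el),
        region_node_count=count,
    )
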