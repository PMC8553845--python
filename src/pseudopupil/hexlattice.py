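"""Geometry of the hexagonal ommatidial lattice.

Facet centres live on a two-axis ("axial") coordinate system: the ``u`` axis is
horizontal and the ``v`` axis runs at +60 degrees to it, both in facet units
(centre-to-centre pitch = 1). Integer ``(u, v)`` pairs are facet centres;
fractional values address sub-facet positions, e.g. a pseudopupil centre read
off in facet-row coordinates. An orthogonal planar basis (``x`` horizontal,
``y`` vertical, still in facet units) is used for all metric computations.

The honeybee's true anatomical row orientation relative to the image is *not*
encoded here: it is carried by :class:`LatticeFrame.orientation_deg` during
pixel registration, so the ``u``-horizontal convention is purely internal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import InvalidInputError

__all__ = [
    "LatticeCoord",
    "PlanarPoint",
    "LatticeFrame",
    "lattice_to_cart",
    "cart_to_lattice",
    "hex_axes",
    "nearest_facet",
    "facet_neighbors",
]

#: sin(60 deg); vertical spacing of lattice rows in facet units.
_SQRT3_2 = np.sqrt(3.0) / 2.0


class LatticeCoord(NamedTuple):
    """Position on the facet lattice, in facet units along the two row axes."""

    u: float
    v: float


class PlanarPoint(NamedTuple):
    """Position in the orthogonal working basis, in facet units."""

    x: float
    y: float


@dataclass(frozen=True)
class LatticeFrame:
    """Similarity transform registering lattice coordinates to image pixels.

    Parameters
    ----------
    pitch_px:
        Facet centre-to-centre spacing in pixels (> 0).
    orientation_deg:
        Angle of the lattice u-axis relative to the image horizontal
        (counter-clockwise positive, with image ``y`` taken upward).
    origin_px:
        ``(row, col)`` pixel coordinates of the lattice origin facet.
    pixel_scale_um:
        Physical pixel size; lets :attr:`pitch_um` report the facet pitch in µm.
    """

    pitch_px: float
    orientation_deg: float
    origin_px: tuple[float, float]
    pixel_scale_um: float | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.pitch_px) and self.pitch_px > 0):
            raise InvalidInputError(f"pitch_px must be positive, got {self.pitch_px}")

    @property
    def pitch_um(self) -> float | None:
        if self.pixel_scale_um is None:
            return None
        return self.pitch_px * self.pixel_scale_um


def _check_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"{name} must be finite, got {arr!r}")


def lattice_to_cart(coord) -> PlanarPoint:
    """Embed an axial lattice coordinate into the orthogonal planar basis.

    ``x = u + v/2``, ``y = v * sqrt(3)/2``: the u-axis is a planar unit vector
    along x and the v-axis a planar unit vector at +60 degrees. Linear and
    invertible (see :func:`cart_to_lattice`). Accepts any ``(u, v)`` pair.
    """
    u, v = np.asarray(coord, dtype=float)
    _check_finite(np.array([u, v]), "lattice coordinate")
    return PlanarPoint(float(u + 0.5 * v), float(v * _SQRT3_2))


def cart_to_lattice(point) -> LatticeCoord:
    """Exact inverse of :func:`lattice_to_cart`."""
    x, y = np.asarray(point, dtype=float)
    _check_finite(np.array([x, y]), "planar point")
    v = y / _SQRT3_2
    return LatticeCoord(float(x - 0.5 * v), float(v))


def hex_axes() -> tuple[LatticeCoord, LatticeCoord, LatticeCoord]:
    """The three hexagonal row directions as lattice step vectors.

    Steps along ``(1, 0)``, ``(0, 1)`` and ``(1, -1)`` traverse the three
    facet rows of a hexagonal mosaic; each maps to a planar unit vector, the
    pairwise planar angles being 60 or 120 degrees.
    """
    return (LatticeCoord(1, 0), LatticeCoord(0, 1), LatticeCoord(1, -1))


def facet_neighbors(coord) -> list[LatticeCoord]:
    """The six nearest facet centres around an integer lattice point."""
    u, v = (int(round(c)) for c in coord)
    steps = [(1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1)]
    return [LatticeCoord(u + du, v + dv) for du, dv in steps]


def nearest_facet(coord) -> LatticeCoord:
    """Integer facet centre closest (in planar distance) to a lattice position.

    Ties are broken by the smallest ``u``, then the smallest ``v``.
    """
    u, v = np.asarray(coord, dtype=float)
    _check_finite(np.array([u, v]), "lattice coordinate")
    x, y = lattice_to_cart((u, v))
    best: tuple[float, float, float] | None = None
    best_c: LatticeCoord | None = None
    for cu in (np.floor(u) - 1, np.floor(u), np.floor(u) + 1, np.floor(u) + 2):
        for cv in (np.floor(v) - 1, np.floor(v), np.floor(v) + 1, np.floor(v) + 2):
            cx, cy = lattice_to_cart((cu, cv))
            d2 = (cx - x) ** 2 + (cy - y) ** 2
            key = (round(d2, 12), cu, cv)
            if best is None or key < best:
                best = key
                best_c = LatticeCoord(float(cu), float(cv))
    assert best_c is not None
    return LatticeCoord(int(best_c.u), int(best_c.v))
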