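"""Parametric geometry of the corneal plate and the three incision families.

The model domain is a large thin square plate of corneal tissue containing a
single pre-cut incision of total arc length ``2a`` at its center.  Three
incision families are supported:

``straight``
    a horizontal segment of length ``2a``;
``chevron``
    two straight arms of length ``a`` meeting at an apex with included angle
    ``alpha`` (degrees); the apex points up (+y) and sits at the plate center;
``frown``
    a circular arc of arc length ``2a`` subtending a central angle ``beta``
    (degrees), bowing up (+y), with the arc midpoint at the plate center.

For the isotropic material studied here the up/down orientation of the bow or
apex is immaterial (a frown and a smile load identically), so a single
orientation convention is fixed once and for all.

Coordinates are SI meters; the incision midpoint (apex / arc midpoint /
segment center) is the coordinate origin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlateSpec",
    "IncisionShape",
    "CrackPath",
    "make_crack_path",
    "chord_span",
    "GeometryError",
]

FAMILIES = ("straight", "chevron", "frown")

CHEVRON_ANGLE_RANGE = (120.0, 180.0)
FROWN_ANGLE_RANGE = (0.0, 50.0)  # open at 0

#: incision chord / plate size ratio beyond which the large-plate (near
#: infinite-plate) assumption is considered dubious
PLATE_RATIO_WARN = 0.2


class GeometryError(ValueError):
    """Invalid incision or plate geometry."""


@dataclass(frozen=True)
class PlateSpec:
    """Rectangular tissue sample, dimensions in meters (default 60 x 60 mm)."""

    width: float = 0.060
    height: float = 0.060

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise GeometryError(
                f"plate dimensions must be positive, got {self.width} x {self.height}"
            )

    def check_incision(self, shape: "IncisionShape") -> None:
        """Warn if the incision span is not small relative to the plate.

        The comparison with infinite-plate closed forms assumes the incision
        is much shorter than the plate edge.
        """
        ratio = chord_span(shape) / min(self.width, self.height)
        if ratio >= PLATE_RATIO_WARN:
            warnings.warn(
                f"incision chord is {ratio:.2f} of the plate size; the "
                "large-plate assumption is questionable",
                stacklevel=2,
            )


@dataclass(frozen=True)
class IncisionShape:
    """One member of the straight / chevron / frown incision families.

    Parameters
    ----------
    family:
        ``"straight"``, ``"chevron"`` or ``"frown"``.
    half_length:
        ``a`` in meters; the total incision arc length is ``2a``.
    chevron_angle:
        Included angle ``alpha`` between the two chevron arms, degrees,
        in [120, 180].  ``alpha = 180`` degenerates to a straight incision.
    frown_angle:
        Central angle ``beta`` of the frown arc, degrees, in (0, 50].
        ``beta -> 0`` degenerates to a straight incision.
    """

    family: str
    half_length: float
    chevron_angle: float | None = None
    frown_angle: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise GeometryError(f"unknown incision family {self.family!r}")
        if not self.half_length > 0:
            raise GeometryError(f"half_length must be positive, got {self.half_length}")
        if self.family == "chevron":
            lo, hi = CHEVRON_ANGLE_RANGE
            if self.chevron_angle is None or not (lo <= self.chevron_angle <= hi):
                raise GeometryError(
                    f"chevron angle must lie in [{lo}, {hi}] degrees, "
                    f"got {self.chevron_angle}"
                )
        elif self.chevron_angle is not None:
            raise GeometryError("chevron_angle only applies to the chevron family")
        if self.family == "frown":
            lo, hi = FROWN_ANGLE_RANGE
            if self.frown_angle is None or not (lo < self.frown_angle <= hi):
                raise GeometryError(
                    f"frown central angle must lie in ({lo}, {hi}] degrees, "
                    f"got {self.frown_angle}"
                )
        elif self.frown_angle is not None:
            raise GeometryError("frown_angle only applies to the frown family")

    # -- constructors ------------------------------------------------------
    @classmethod
    def straight(cls, half_length: float) -> "IncisionShape":
        return cls("straight", half_length)

    @classmethod
    def chevron(cls, half_length: float, alpha_deg: float) -> "IncisionShape":
        return cls("chevron", half_length, chevron_angle=alpha_deg)

    @classmethod
    def frown(cls, half_length: float, beta_deg: float) -> "IncisionShape":
        return cls("frown", half_length, frown_angle=beta_deg)

    @property
    def total_length(self) -> float:
        """Total incision arc length ``2a`` [m]."""
        return 2.0 * self.half_length

    def describe(self) -> str:
        if self.family == "chevron":
            return f"chevron(alpha={self.chevron_angle:g} deg, 2a={self.total_length:g} m)"
        if self.family == "frown":
            return f"frown(beta={self.frown_angle:g} deg, 2a={self.total_length:g} m)"
        return f"straight(2a={self.total_length:g} m)"

    # -- analytic parameterization by arc length ---------------------------
    def point_at(self, s) -> np.ndarray:
        """Point(s) on the incision at arc length ``s`` from the left tip.

        ``s`` may be a scalar or array in ``[0, 2a]``.  Returns shape
        ``(..., 2)``.
        """
        s = np.asarray(s, dtype=float)
        a = self.half_length
        if self.family == "straight":
            x = s - a
            y = np.zeros_like(s)
        elif self.family == "chevron":
            gam = self._half_kink_angle
            cg, sg = math.cos(gam), math.sin(gam)
            # left arm rises toward the apex at the origin, right arm descends
            x = (s - a) * cg
            y = np.where(s <= a, (s - a) * sg, (a - s) * sg)
        else:  # frown: circle center at (0, -R) puts the arc midpoint at the origin
            R, beta = self._arc_radius, math.radians(self.frown_angle)
            phi = math.pi / 2 + beta / 2 - s / R
            x = R * np.cos(phi)
            y = R * np.sin(phi) - R
        return np.stack(np.broadcast_arrays(x, y), axis=-1)

    def tangent_at(self, s) -> np.ndarray:
        """Unit tangent(s) in the direction of increasing arc length."""
        s = np.asarray(s, dtype=float)
        if self.family == "straight":
            t = np.stack(np.broadcast_arrays(np.ones_like(s), np.zeros_like(s)), axis=-1)
        elif self.family == "chevron":
            gam = self._half_kink_angle
            cg, sg = math.cos(gam), math.sin(gam)
            on_left = s <= self.half_length
            tx = np.full_like(s, cg)
            ty = np.where(on_left, sg, -sg)
            t = np.stack(np.broadcast_arrays(tx, ty), axis=-1)
        else:
            R, beta = self._arc_radius, math.radians(self.frown_angle)
            phi = math.pi / 2 + beta / 2 - s / R
            t = np.stack(np.broadcast_arrays(np.sin(phi), -np.cos(phi)), axis=-1)
        return t

    @property
    def _half_kink_angle(self) -> float:
        """Chevron arm inclination (180 - alpha)/2 in radians."""
        return math.radians(180.0 - self.chevron_angle) / 2.0

    @property
    def _arc_radius(self) -> float:
        return self.total_length / math.radians(self.frown_angle)

    def tip_y(self) -> float:
        """Common y-coordinate of the two tips (both tips share it)."""
        return float(self.point_at(0.0)[1])


@dataclass(frozen=True)
class CrackPath:
    """Polyline discretization of an incision, plus tip metadata.

    ``vertices`` runs from the left tip to the right tip; the incision
    midpoint is always a vertex (``midpoint_index``).  ``tip_tangents`` point
    *outward* (the direction of self-similar crack extension at each tip).
    """

    shape: IncisionShape
    vertices: np.ndarray  # (n+1, 2)
    arclengths: np.ndarray  # (n+1,), from the left tip
    tip_left: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    tip_right: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    tip_tangents: dict = field(repr=False, default=None)  # type: ignore[assignment]
    midpoint: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    midpoint_index: int = 0

    @property
    def n_segments(self) -> int:
        return len(self.vertices) - 1

    def polyline_length(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)))

    def to_csv(self, path) -> None:
        np.savetxt(path, self.vertices, delimiter=",", header="x,y", comments="")


def make_crack_path(shape: IncisionShape, n_segments: int = 256) -> CrackPath:
    """Discretize an incision into a polyline with ``n_segments`` segments.

    ``n_segments`` must be even so the incision midpoint is a vertex.
    Vertices are spaced uniformly in arc length.
    """
    if n_segments < 2 or n_segments % 2:
        raise GeometryError(f"n_segments must be even and >= 2, got {n_segments}")
    s = np.linspace(0.0, shape.total_length, n_segments + 1)
    verts = shape.point_at(s)
    tl = shape.tangent_at(0.0)
    tr = shape.tangent_at(shape.total_length)
    return CrackPath(
        shape=shape,
        vertices=verts,
        arclengths=s,
        tip_left=verts[0],
        tip_right=verts[-1],
        tip_tangents={"left": -tl, "right": tr},
        midpoint=verts[n_segments // 2],
        midpoint_index=n_segments // 2,
    )


def chord_span(shape: IncisionShape) -> float:
    """Straight tip-to-tip distance [m] (closed form per family)."""
    a = shape.half_length
    if shape.family == "straight":
        return 2.0 * a
    if shape.family == "chevron":
        return 2.0 * a * math.cos(shape._half_kink_angle)
    beta = math.radians(shape.frown_angle)
    R = 2.0 * a / beta
    return 2.0 * R * math.sin(beta / 2.0)
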