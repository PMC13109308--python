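"""Measurement geometry for goniometer-style leaf reflectance scans.

The instrument holds the light source fixed and rotates (a) the leaf holder,
which sets the illumination incidence on the leaf, and (b) a detection ring
carrying a collimation lens, which sets the viewing direction.  A right-handed
Cartesian frame is used with the illumination travelling along +Y (so the
*surface-to-source* direction is ``L = (0, -1, 0)``), the Z axis pointing
vertically downward, and X completing the frame.

All public functions take degrees at the I/O boundary and work in radians
internally.  Every constructed direction is unit-norm to within 1e-9.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

#: Holder scale reading that corresponds to perpendicular illumination.
HOLDER_PERPENDICULAR_DEG = 95.0

#: Detection-ring coverage in degrees (zenith), i.e. -pi/36 .. 35*pi/36.
RING_COVERAGE_DEG = (-5.0, 175.0)

UNIT_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when a configuration cannot form a valid reflection frame."""


@dataclass(frozen=True)
class Direction:
    """A unit vector in the instrument frame."""

    x: float
    y: float
    z: float

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @staticmethod
    def from_array(v: np.ndarray, normalize: bool = False) -> "Direction":
        v = np.asarray(v, dtype=float)
        n = float(np.linalg.norm(v))
        if n == 0.0:
            raise DegenerateGeometryError("cannot build a direction from the zero vector")
        if normalize:
            v = v / n
        elif abs(n - 1.0) > UNIT_TOL:
            raise ValueError(f"direction is not unit-norm (|v| = {n!r})")
        return Direction(float(v[0]), float(v[1]), float(v[2]))

    def dot(self, other: "Direction") -> float:
        return self.x * other.x + self.y * other.y + self.z * other.z

    @property
    def norm(self) -> float:
        return math.sqrt(self.x**2 + self.y**2 + self.z**2)


@dataclass(frozen=True)
class InstrumentAngles:
    """Raw mechanical-scale readings for one measurement configuration.

    Either ``holder_scale_deg`` (the leaf-holder scale, perpendicular at 95)
    or ``incident_zenith_deg`` (the already-reduced leaf inclination) may be
    given; the holder scale wins when both are present.
    """

    view_zenith_deg: float
    view_azimuth_deg: float = 0.0
    holder_scale_deg: float | None = None
    incident_zenith_deg: float | None = None
    incident_azimuth_deg: float = 0.0

    def leaf_angle_deg(self) -> float:
        if self.holder_scale_deg is not None:
            return leaf_angle_from_holder(self.holder_scale_deg)
        if self.incident_zenith_deg is not None:
            return float(self.incident_zenith_deg)
        raise ValueError("need holder_scale_deg or incident_zenith_deg")


@dataclass(frozen=True)
class GeometryFrame:
    """Unit vectors and derived angles for one measurement configuration.

    ``H`` is the normalized bisector of ``L`` and ``V``; ``alpha`` is the
    angle between the surface normal and ``H``; ``theta_h`` is half the phase
    angle between ``L`` and ``V`` (computed as arccos(L·H)).
    """

    L: Direction
    N: Direction
    V: Direction
    H: Direction
    cos_LN: float
    cos_NV: float
    cos_NH: float
    cos_VH: float
    cos_theta_h: float
    alpha: float
    theta_h: float
    degenerate: bool = field(default=False)


def leaf_angle_from_holder(holder_scale_deg: float) -> float:
    """Leaf inclination (degrees) from the holder scale reading.

    The holder scale reads 95 when the leaf is perpendicular to the beam, so
    the inclination is ``95 - reading``.  Out-of-range results pass through
    with a warning rather than erroring (scans occasionally log overshoots).
    """
    if not math.isfinite(holder_scale_deg):
        raise ValueError("holder scale reading must be finite")
    angle = HOLDER_PERPENDICULAR_DEG - float(holder_scale_deg)
    if not -90.0 <= angle <= 90.0:
        warnings.warn(
            f"leaf angle {angle:.1f} deg is outside [-90, 90]; passing through",
            stacklevel=2,
        )
    return angle


def illumination_vector() -> Direction:
    """Surface-to-source direction ``L``; the source is fixed on the -Y side."""
    return Direction(0.0, -1.0, 0.0)


def normal_vector(theta_leaf_deg: float, phi_i_deg: float = 0.0) -> Direction:
    """Leaf normal ``N = (sin θ·cos φ, -cos θ, sin θ·sin φ)``.

    At ``θ = 0`` the leaf faces the source (``N = L``).  A nonzero holder
    azimuth rotates the tilt out of the XY plane; the instrument never uses
    it in practice but the frame supports it.
    """
    t = math.radians(theta_leaf_deg)
    p = math.radians(phi_i_deg)
    return Direction.from_array(
        np.array([math.sin(t) * math.cos(p), -math.cos(t), math.sin(t) * math.sin(p)]),
        normalize=True,
    )


def viewing_vector(
    view_zenith_deg: float, view_azimuth_deg: float = 0.0, form: str = "corrected"
) -> Direction:
    """Surface-to-detector direction ``V`` from the ring scales.

    ``form="corrected"`` uses the spherical parameterization
    ``(sin θv·cos φv, -cos θv, sin θv·sin φv)``, which is unit-norm and
    coincides with ``L`` at ``θv = 0``.  ``form="as_printed"`` keeps the
    middle component as ``-sin θv`` and renormalizes; it cannot represent
    ``θv = 0`` and errors there.
    """
    t = math.radians(view_zenith_deg)
    p = math.radians(view_azimuth_deg)
    if form == "corrected":
        v = np.array([math.sin(t) * math.cos(p), -math.cos(t), math.sin(t) * math.sin(p)])
    elif form == "as_printed":
        v = np.array([math.sin(t) * math.cos(p), -math.sin(t), math.sin(t) * math.sin(p)])
        if np.linalg.norm(v) < 1e-12:
            raise DegenerateGeometryError(
                "as_printed viewing vector is the zero vector at theta_v = 0"
            )
    else:
        raise ValueError(f"unknown viewing-vector form {form!r}")
    return Direction.from_array(v, normalize=True)


def half_vector(L: Direction, V: Direction) -> Direction:
    """Normalized bisector ``H = (L+V)/|L+V|``; symmetric in its arguments."""
    s = L.as_array() + V.as_array()
    n = float(np.linalg.norm(s))
    if n < 1e-12:
        raise DegenerateGeometryError("L and V are antiparallel; half-vector undefined")
    return Direction.from_array(s / n)


def frame_from_vectors(L: Direction, N: Direction, V: Direction) -> GeometryFrame:
    """Assemble a full frame from explicit unit vectors."""
    H = half_vector(L, V)
    cos_LN = L.dot(N)
    cos_NV = N.dot(V)
    cos_NH = N.dot(H)
    cos_VH = V.dot(H)
    cos_th = min(1.0, max(-1.0, L.dot(H)))
    alpha = math.acos(min(1.0, max(-1.0, cos_NH)))
    theta_h = math.acos(cos_th)
    degenerate = cos_LN <= 0.0 or cos_NV <= 0.0
    return GeometryFrame(
        L=L, N=N, V=V, H=H,
        cos_LN=cos_LN, cos_NV=cos_NV, cos_NH=cos_NH, cos_VH=cos_VH,
        cos_theta_h=cos_th, alpha=alpha, theta_h=theta_h, degenerate=degenerate,
    )


def geometry_frame(angles: InstrumentAngles, v_form: str = "corrected") -> GeometryFrame:
    """Build the (L, N, V, H) frame and derived angles for one configuration.

    Frames where the source or detector sits behind the leaf plane
    (``L·N <= 0`` or ``N·V <= 0``) are returned with ``degenerate=True`` so
    callers can exclude them from fitting rather than clamp them.
    """
    L = illumination_vector()
    N = normal_vector(angles.leaf_angle_deg(), angles.incident_azimuth_deg)
    V = viewing_vector(angles.view_zenith_deg, angles.view_azimuth_deg, form=v_form)
    return frame_from_vectors(L, N, V)


def scan_frame_arrays(
    theta_leaf_deg: np.ndarray,
    view_zenith_deg: np.ndarray,
    view_azimuth_deg: np.ndarray | float = 0.0,
    v_form: str = "corrected",
) -> dict[str, np.ndarray]:
    """Vectorized frame construction for whole scans.

    Returns the cosine/angle arrays the BRDF kernel needs plus a boolean
    ``usable`` mask (non-degenerate frames).  Shapes follow numpy
    broadcasting of the three inputs.
    """
    tl = np.radians(np.asarray(theta_leaf_deg, dtype=float))
    tv = np.radians(np.asarray(view_zenith_deg, dtype=float))
    pv = np.radians(np.asarray(view_azimuth_deg, dtype=float))
    tl, tv, pv = np.broadcast_arrays(tl, tv, pv)

    L = np.array([0.0, -1.0, 0.0])
    N = np.stack([np.sin(tl), -np.cos(tl), np.zeros_like(tl)], axis=-1)
    if v_form == "corrected":
        V = np.stack([np.sin(tv) * np.cos(pv), -np.cos(tv), np.sin(tv) * np.sin(pv)], axis=-1)
    elif v_form == "as_printed":
        V = np.stack([np.sin(tv) * np.cos(pv), -np.sin(tv), np.sin(tv) * np.sin(pv)], axis=-1)
        nv = np.linalg.norm(V, axis=-1, keepdims=True)
        if np.any(nv < 1e-12):
            raise DegenerateGeometryError("as_printed form degenerates at theta_v = 0")
        V = V / nv
    else:
        raise ValueError(f"unknown viewing-vector form {v_form!r}")

    S = L + V
    ns = np.linalg.norm(S, axis=-1, keepdims=True)
    antiparallel = ns[..., 0] < 1e-12
    ns = np.where(ns < 1e-12, 1.0, ns)
    H = S / ns

    cos_LN = N @ L
    cos_NV = np.einsum("...i,...i->...", N, V)
    cos_NH = np.einsum("...i,...i->...", N, H)
    cos_VH = np.einsum("...i,...i->...", V, H)
    cos_th = np.clip(H @ L, -1.0, 1.0)
    alpha = np.arccos(np.clip(cos_NH, -1.0, 1.0))
    usable = (cos_LN > 0.0) & (cos_NV > 0.0) & ~antiparallel
    return {
        "cos_LN": cos_LN,
        "cos_NV": cos_NV,
        "cos_NH": cos_NH,
        "cos_VH": cos_VH,
        "cos_theta_h": cos_th,
        "alpha": alpha,
        "theta_h": np.arccos(cos_th),
        "usable": usable,
    }
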