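"""Shared vector-geometry kernels (all vectorised over leading axes)."""

from __future__ import annotations

import numpy as np

__all__ = ["angle_at", "dihedral", "wrap_180", "to_watchface"]


def angle_at(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Angle a-b-c at vertex b, in degrees. Broadcasts over leading axes."""
    u = a - b
    v = c - b
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    cosang = np.einsum("...i,...i->...", u, v) / np.where(nu * nv == 0, np.inf,
                                                          nu * nv)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral angle of the planes (p0,p1,p2) and (p1,p2,p3).

    IUPAC sign convention, degrees in (-180, 180].  Uses the atan2 form,
    which is numerically stable near 0 and 180 degrees.
    """
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1, axis=-1, keepdims=True))
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", m1, n2)
    return wrap_180(-np.degrees(np.arctan2(y, x)))


def wrap_180(angles) -> np.ndarray:
    """Map angles in degrees to the interval (-180, 180]."""
    a = np.asarray(angles, dtype=float)
    wrapped = ((-a + 180.0) % 360.0)
    return 180.0 - wrapped  # maps -180 -> 180, keeps (-180, 180]


def to_watchface(angles) -> np.ndarray:
    """Display mode: map degrees to [0, 360) as on circular dial plots."""
    return np.asarray(angles, dtype=float) % 360.0
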