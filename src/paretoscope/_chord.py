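"""Knee localisation on a normalized curve by distance from the first-last chord.

Operationalizes the 45-degree-line elbow construction: both axes are scaled
to [0, 1] and the knee is the point where a line of slope -1 touches the
curve.  For a curve bending on the concave side of the chord that is the
point of maximum perpendicular distance above the chord; for a convex
(cliff-shaped) curve the tangent touches from below, and on a discrete
noisy curve the tangent point can slide a few points past the corner, so
the knee is snapped to the dominant value gap in the neighbourhood of the
tangent point — the discrete analogue of the corner where the extrapolated
horizontal and vertical lines meet.  The two branches coincide with the
geometric construction for curves with a single sharp bend.
"""

from __future__ import annotations

import numpy as np

_TOL = 1e-12
# minimum normalized chord distance for the curve to count as concave-side;
# below this the bend is treated as cliff-shaped
_CONCAVE_MIN = 0.02


def chord_knee(values: np.ndarray) -> tuple[int, float]:
    """Return (knee index, knee strength) for a non-increasing 1-D curve.

    The knee index is the last point *included* on the high side of the
    bend.  Strength is the maximum absolute normalized chord distance;
    values near zero indicate an essentially straight curve without a
    meaningful knee.  Ties resolve to the earliest index.  Raises on
    constant input.
    """
    v = np.asarray(values, dtype=float)
    m = v.size
    if m < 3:
        raise ValueError("need at least 3 points to locate a knee")
    vmin, vmax = float(v.min()), float(v.max())
    if vmax - vmin <= _TOL * max(1.0, abs(vmax)):
        raise ValueError("constant input has no knee")
    x = np.linspace(0.0, 1.0, m)
    y = (v - vmin) / (vmax - vmin)
    signed_above = x + y - 1.0  # prop. to perpendicular distance above the chord
    strength = float(np.max(np.abs(signed_above)))
    if strength <= 1e-9:
        return 0, strength  # essentially straight: earliest index by convention
    if signed_above.max() > _CONCAVE_MIN:
        return int(np.argmax(signed_above)), strength
    # convex branch: tangent point from below, then snap to the largest
    # value gap near it (the corner of the idealized right angle)
    tangent = max(int(np.argmax(-signed_above)) - 1, 0)
    lo = tangent // 2
    hi = min(2 * tangent + 3, m - 1)
    gaps = v[lo:hi] - v[lo + 1 : hi + 1]
    knee = lo + int(np.argmax(gaps))
    return knee, strength
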