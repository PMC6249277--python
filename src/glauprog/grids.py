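"""The Humphrey 24-2 test-point grid in right-eye (OD) field coordinates.

Coordinates are degrees of visual angle: x positive temporal (toward the
blind spot for OD), y positive superior.  The full 24-2 pattern has 54
locations on a 6-degree lattice; the two locations at (15, +/-3) fall on the
physiologic blind spot and are excluded everywhere in this package, leaving
the 52 analyzed points.
"""

from __future__ import annotations

#: Blind-spot locations (OD frame), always excluded.
BLIND_SPOT = ((15, 3), (15, -3))


def _build_grid():
    pts = []
    rows = {
        21: range(-9, 10, 6),
        15: range(-15, 16, 6),
        9: range(-21, 22, 6),
        3: range(-27, 22, 6),
    }
    for y, xs in rows.items():
        for x in xs:
            for yy in (y, -y):
                if (x, yy) not in BLIND_SPOT:
                    pts.append((x, yy))
    # deterministic ordering: superior to inferior, nasal to temporal
    pts.sort(key=lambda p: (-p[1], p[0]))
    return tuple(pts)


#: The 52 analyzed 24-2 locations, OD frame, ordered top row first.
GRID_24_2 = _build_grid()

assert len(GRID_24_2) == 52


def point_key(x: int, y: int) -> str:
    """Canonical column-name fragment for a grid point: signed ``<x>_<y>``.

    (-27, 3) -> ``-27_3``; (9, -15) -> ``9_-15``.  Used to build the
    ``thr_<x>_<y>`` / ``td_<x>_<y>`` CSV column names.
    """
    return f"{x}_{y}"


def mirror_x(points):
    """Mirror field x-coordinates (OS <-> OD frame)."""
    return [(-x, y) for x, y in points]
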