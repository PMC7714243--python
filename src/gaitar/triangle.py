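"""AR(2) stationarity triangle: membership, centroid distance, and plotting.

A second-order autoregressive process ``y_t = δ + φ1 y_{t-1} + φ2 y_{t-2} + ε_t``
is (weakly) stationary iff both roots of its characteristic polynomial
``m² − φ1 m − φ2`` have modulus < 1, which in the (φ1, φ2) plane is the open
triangle with vertices (−2, −1), (2, −1), (0, 1):

    φ2 + φ1 < 1,   φ2 − φ1 < 1,   |φ2| < 1.

Fitted coefficient pairs are plotted in this plane; their Euclidean distance
from the triangle centroid (0, −1/3) is used as a scalar gait-pattern
stability statistic — larger distance means the fitted dynamics sit closer to
the non-stationary boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

#: Vertices of the AR(2) stationarity triangle in the (φ1, φ2) plane.
VERTICES: tuple[tuple[float, float], ...] = ((-2.0, -1.0), (2.0, -1.0), (0.0, 1.0))

#: Half-width of the band around the triangle edges treated as "on the boundary".
BOUNDARY_TOL = 1e-9

_CENTROID = (0.0, -1.0 / 3.0)


class StationarityError(ValueError):
    """Raised when AR coefficients outside the stationarity region are rejected."""


class TriangleMembership(NamedTuple):
    inside: bool
    boundary: bool


def centroid() -> tuple[float, float]:
    """Centroid (0, −1/3) of the stationarity triangle (mean of the vertices)."""
    return _CENTROID


def is_stationary(phi1: float, phi2: float, tol: float = BOUNDARY_TOL) -> TriangleMembership:
    """Strict-inequality membership test for the stationarity triangle.

    Points whose smallest edge margin lies within ``tol`` of zero are flagged
    ``boundary=True`` and reported ``inside=False`` (a unit root is not
    stationary).
    """
    margin = min(1.0 - (phi2 + phi1), 1.0 - (phi2 - phi1), 1.0 - abs(phi2))
    if abs(margin) <= tol:
        return TriangleMembership(inside=False, boundary=True)
    return TriangleMembership(inside=margin > 0.0, boundary=False)


def distance_from_centroid(phi1: float, phi2: float) -> float:
    """Euclidean distance of (φ1, φ2) from the triangle centroid (0, −1/3).

    Defined for points outside the triangle as well.
    """
    return math.hypot(phi1 - _CENTROID[0], phi2 - _CENTROID[1])


@dataclass(frozen=True)
class TrianglePoint:
    """A fitted (φ1, φ2) pair located on the stationarity triangle.

    ``labels`` carries free-form tags (participant, limb, condition).
    """

    phi1: float
    phi2: float
    inside: bool
    boundary: bool
    distance: float
    labels: dict = field(default_factory=dict)


def classify(phi1: float, phi2: float, **labels: object) -> TrianglePoint:
    """Build a :class:`TrianglePoint` with membership and centroid distance."""
    member = is_stationary(phi1, phi2)
    return TrianglePoint(
        phi1=float(phi1),
        phi2=float(phi2),
        inside=member.inside,
        boundary=member.boundary,
        distance=distance_from_centroid(phi1, phi2),
        labels=dict(labels),
    )


def points_table(points: Sequence[TrianglePoint]):
    """Tabulate triangle points as a DataFrame (one row per point)."""
    import pandas as pd

    rows = []
    for p in points:
        row = {
            "participant": p.labels.get("participant", ""),
            "limb": p.labels.get("limb", ""),
            "condition": p.labels.get("condition", ""),
            "phi1": p.phi1,
            "phi2": p.phi2,
            "inside": p.inside,
            "distance": p.distance,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def render_triangle(
    points: Sequence[TrianglePoint],
    out_path,
    zoom: tuple[tuple[float, float], tuple[float, float]] | None = None,
    title: str | None = None,
) -> None:
    """Plot triangle edges, centroid, and labelled coefficient points to a file.

    Points are grouped (glyph/colour) by their ``condition`` label. SVG output
    is byte-deterministic for identical input: the hash salt is pinned and the
    date metadata suppressed.

    Parameters
    ----------
    points : non-empty sequence of TrianglePoint
    out_path : path ending in ``.svg`` or ``.png``
    zoom : optional ((xmin, xmax), (ymin, ymax)) axis window
    """
    if not points:
        raise ValueError("render_triangle requires a non-empty point list")

    import matplotlib

    from matplotlib.figure import Figure

    with matplotlib.rc_context({"svg.hashsalt": "gaitar"}):
        fig = Figure(figsize=(6.0, 5.0))
        ax = fig.add_subplot(111)
        tri_x = [v[0] for v in VERTICES] + [VERTICES[0][0]]
        tri_y = [v[1] for v in VERTICES] + [VERTICES[0][1]]
        ax.plot(tri_x, tri_y, color="black", lw=1.2, zorder=1)
        cx, cy = centroid()
        ax.plot([cx], [cy], marker="+", color="black", ms=10, mew=1.5, zorder=2)

        markers = ["x", "o", "^", "s", "D", "v", "P", "*"]
        conditions: list[str] = []
        for p in points:
            c = str(p.labels.get("condition", ""))
            if c not in conditions:
                conditions.append(c)
        for i, cond in enumerate(conditions):
            xs = [p.phi1 for p in points if str(p.labels.get("condition", "")) == cond]
            ys = [p.phi2 for p in points if str(p.labels.get("condition", "")) == cond]
            ax.scatter(xs, ys, marker=markers[i % len(markers)], s=30,
                       label=cond or "points", zorder=3)
        ax.set_xlabel(r"$\phi_1$")
        ax.set_ylabel(r"$\phi_2$")
        if title:
            ax.set_title(title)
        if zoom is not None:
            ax.set_xlim(*zoom[0])
            ax.set_ylim(*zoom[1])
        else:
            ax.set_xlim(-2.3, 2.3)
            ax.set_ylim(-1.3, 1.3)
        ax.legend(loc="upper right", fontsize=8)
        fig.tight_layout()
        out_path = str(out_path)
        if out_path.endswith(".svg"):
            fig.savefig(out_path, format="svg", metadata={"Date": None})
        else:
            fig.savefig(out_path)


def max_root_modulus(phi1: float, phi2: float) -> float:
    """Largest characteristic-root modulus, via the quadratic formula.

    Convenience wrapper used for membership cross-checks; see
    :func:`gaitar.ar.characteristic_roots` for the root computation itself.
    """
    disc = phi1 * phi1 + 4.0 * phi2
    if disc >= 0.0:
        s = math.sqrt(disc)
        return max(abs((phi1 + s) / 2.0), abs((phi1 - s) / 2.0))
    return math.hypot(phi1 / 2.0, math.sqrt(-disc) / 2.0)
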