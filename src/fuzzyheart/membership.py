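"""Piecewise-linear membership functions and polyline geometry.

Every fuzzy set in the model is either a piecewise-linear curve
(triangle, trapezoid, or a shoulder that saturates at 1 toward one end
of the universe) or a crisp interval (degree 1 inside, 0 outside).
Piecewise-linear curves are stored as ordered ``(x, degree)``
breakpoints; evaluation is exact at breakpoints and linear between
them, with the first/last degree extended beyond the breakpoint range
so shoulders saturate naturally.

The module also provides exact integration of piecewise-linear
polylines (area, first moment, centroid) and clipping of a polyline at
a height ``h`` — the geometric primitives behind Mamdani implication
and the area-based defuzzifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

SHAPES = ("triangular", "trapezoidal", "crisp", "left-shoulder", "right-shoulder")

#: Degrees below this are treated as exactly zero (float dust from
#: subtractions at breakpoint edges must not fire rules).
DEGREE_EPS = 1e-12

Polyline = list[tuple[float, float]]


@dataclass(frozen=True)
class MembershipFunction:
    """One named fuzzy set of a linguistic variable.

    Parameters
    ----------
    term : str
        The linguistic label, e.g. ``"VeryHealthy"``.
    shape : str
        One of ``triangular``, ``trapezoidal``, ``crisp``,
        ``left-shoulder`` (saturates at 1 toward low x),
        ``right-shoulder`` (saturates at 1 toward high x).
    vertices : tuple of (x, degree)
        Breakpoints of the piecewise-linear curve, strictly increasing
        in x.  For ``crisp`` shapes exactly two vertices give the
        interval bounds (both with degree 1).
    right_closed : bool
        Crisp intervals are half-open ``[lo, hi)`` by default so that
        adjacent intervals tile the universe without overlap; the last
        interval of a variable sets this flag to include its upper bound.
    """

    term: str
    shape: str
    vertices: tuple[tuple[float, float], ...]
    right_closed: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ConfigurationError(
                f"term {self.term!r}: unknown shape {self.shape!r}; expected one of {SHAPES}"
            )
        xs = [v[0] for v in self.vertices]
        ds = [v[1] for v in self.vertices]
        if len(xs) < 2:
            raise ConfigurationError(f"term {self.term!r}: needs at least 2 vertices")
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ConfigurationError(
                f"term {self.term!r}: vertex x-coordinates must be strictly increasing, got {xs}"
            )
        if any(not (0.0 <= d <= 1.0) for d in ds):
            raise ConfigurationError(
                f"term {self.term!r}: degrees must lie in [0, 1], got {ds}"
            )
        if self.shape == "crisp":
            if len(self.vertices) != 2 or ds != [1.0, 1.0]:
                raise ConfigurationError(
                    f"term {self.term!r}: crisp shape takes exactly two vertices with degree 1"
                )
        elif self.shape in ("triangular", "trapezoidal"):
            if ds[0] != 0.0 or ds[-1] != 0.0:
                raise ConfigurationError(
                    f"term {self.term!r}: interior shapes must start and end at degree 0"
                )
        elif self.shape == "left-shoulder" and ds[0] != 1.0:
            raise ConfigurationError(
                f"term {self.term!r}: left-shoulder must start at degree 1"
            )
        elif self.shape == "right-shoulder" and ds[-1] != 1.0:
            raise ConfigurationError(
                f"term {self.term!r}: right-shoulder must end at degree 1"
            )

    def degree(self, x: float) -> float:
        """Membership degree of crisp value ``x`` in this fuzzy set."""
        if self.shape == "crisp":
            lo, hi = self.vertices[0][0], self.vertices[1][0]
            if self.right_closed:
                inside = lo <= x <= hi
            else:
                inside = lo <= x < hi
            return 1.0 if inside else 0.0
        xs = [v[0] for v in self.vertices]
        ds = [v[1] for v in self.vertices]
        # endpoint degrees extend outward: shoulders saturate, interior
        # shapes (which end at 0) vanish outside their support
        d = float(np.interp(x, xs, ds, left=ds[0], right=ds[-1]))
        return 0.0 if d < DEGREE_EPS else d

    def support(self, universe: tuple[float, float]) -> tuple[float, float]:
        """Closed interval outside which the degree is 0.

        Shoulders saturate toward one end of the universe, so their
        support extends to that universe bound.
        """
        lo, hi = self.vertices[0][0], self.vertices[-1][0]
        if self.shape == "left-shoulder":
            lo = universe[0]
        elif self.shape == "right-shoulder":
            hi = universe[1]
        return (lo, hi)

    def peak(self, universe: tuple[float, float]) -> float:
        """Representative point: midpoint of the x-region of maximal degree."""
        if self.shape == "crisp":
            lo, hi = self.vertices[0][0], self.vertices[1][0]
            return 0.5 * (lo + hi)
        top = max(d for _, d in self.vertices)
        xs_at_top = [x for x, d in self.vertices if d == top]
        lo, hi = xs_at_top[0], xs_at_top[-1]
        if self.shape == "left-shoulder":
            lo = universe[0]
        elif self.shape == "right-shoulder":
            hi = universe[1]
        return 0.5 * (lo + hi)

    def polyline(self, universe: tuple[float, float]) -> Polyline:
        """Breakpoints as an explicit polyline covering the support."""
        pts = [(float(x), float(d)) for x, d in self.vertices]
        if self.shape == "crisp":
            lo, hi = pts[0][0], pts[1][0]
            return [(lo, 1.0), (hi, 1.0)]
        if self.shape == "left-shoulder" and pts[0][0] > universe[0]:
            pts.insert(0, (float(universe[0]), pts[0][1]))
        if self.shape == "right-shoulder" and pts[-1][0] < universe[1]:
            pts.append((float(universe[1]), pts[-1][1]))
        return pts


# ---------------------------------------------------------------------------
# polyline geometry


def clip_polyline(points: Polyline, h: float) -> Polyline:
    """Pointwise ``min(y, h)`` of a piecewise-linear curve.

    Crossing points with the level ``h`` are inserted exactly, so the
    result is again an exact polyline (Mamdani implication by clipping).
    """
    if h < 0:
        raise ValueError(f"clip height must be non-negative, got {h}")
    out: Polyline = []
    for i, (x1, y1) in enumerate(points):
        if i > 0:
            x0, y0 = points[i - 1]
            # insert the crossing if the segment traverses the level h
            if (y0 - h) * (y1 - h) < 0:
                t = (h - y0) / (y1 - y0)
                out.append((x0 + t * (x1 - x0), h))
        out.append((x1, min(y1, h)))
    # drop collinear interior points so plateaus are canonical segments
    simplified = [out[0]]
    for i in range(1, len(out) - 1):
        x0, y0 = simplified[-1]
        x1, y1 = out[i]
        x2, y2 = out[i + 1]
        if abs((x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)) > 1e-12:
            simplified.append(out[i])
    simplified.append(out[-1])
    return simplified


def polyline_area(points: Polyline) -> float:
    """Exact area under a piecewise-linear curve (trapezoid formula)."""
    return sum(
        (x2 - x1) * (y1 + y2) / 2.0
        for (x1, y1), (x2, y2) in zip(points, points[1:])
    )


def polyline_moment(points: Polyline) -> float:
    """Exact first moment ∫ x·y(x) dx of a piecewise-linear curve."""
    return sum(
        (x2 - x1) * (y1 * (2 * x1 + x2) + y2 * (x1 + 2 * x2)) / 6.0
        for (x1, y1), (x2, y2) in zip(points, points[1:])
    )


def polyline_centroid(points: Polyline) -> float:
    """x-coordinate of the centroid of the region under the curve."""
    area = polyline_area(points)
    if area <= 0:
        raise ZeroDivisionError("centroid of zero-area polyline is undefined")
    return polyline_moment(points) / area


def eval_polyline(points: Polyline, x: np.ndarray | float) -> np.ndarray | float:
    """Evaluate a polyline at x (0 outside its breakpoint range)."""
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    return np.interp(x, xs, ys, left=0.0, right=0.0)
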