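"""Topological triangle fit of a persistence diagram.

The point cloud D of a tachogram's persistence diagram typically fills
a triangular region above the diagonal {x = y} of the (birth, death)
plane: births cannot exceed deaths, the global pair sits at the apex
(min birth, max death), and short-lived components hug the diagonal.
The topological triangle T(D) = ABC encloses D tightly, with base AB on
the diagonal and apex C above it, and yields five scalar descriptors:
width |AB|, height h (distance from C to the diagonal), location (the
x-coordinate of the midpoint of AB), proportion |AC|/|BC|, and
misalignment (the minimised fitting objective).

The sides are fitted by a grid search over two angles measured against
the diagonal: phi in [-pi/2, 0) for the left side k = AC and psi in
(0, pi/2] for the right side l = BC.  For each candidate angle the line
is anchored so that a fixed outer fraction (default 10%) of the points
of D lies on its outer side; among all angle pairs, the fit minimises

    sum of squared point-line distances over the "10-75% zone" of each
    line (the outer points plus the inner points closest to that line,
    75% of D in total)
  + |A - p(c)|^2 + |B - p(c)|^2      (c = centroid of D, p = projection
                                      onto the diagonal)
  + h^2.

Repeated diagram points are counted with multiplicity throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

from .persistence import PersistenceDiagram

__all__ = [
    "TriangleConfig",
    "TriangleFit",
    "TriangleDescriptors",
    "fit_triangle",
    "triangle_descriptors",
    "line_normal",
    "anchored_offset",
    "TRIANGLE_FEATURE_COLUMNS",
]

TRIANGLE_FEATURE_COLUMNS = [
    "triangle_width",
    "triangle_height",
    "triangle_location",
    "triangle_proportion",
    "triangle_misalignment",
]

_SQRT2 = math.sqrt(2.0)
#: unit direction of the diagonal {x = y}
_U = np.array([1.0, 1.0]) / _SQRT2


@dataclass(frozen=True)
class TriangleConfig:
    """Grid-search settings for the triangle fit."""

    n_angle_candidates: int = 50
    outer_fraction: float = 0.10
    zone_fraction: float = 0.75

    def phi_grid(self) -> np.ndarray:
        """Candidates for the left-line angle: [-pi/2, 0), 0 excluded."""
        n = self.n_angle_candidates
        return -math.pi / 2 + (math.pi / 2) * np.arange(n) / n

    def psi_grid(self) -> np.ndarray:
        """Candidates for the right-line angle: (0, pi/2], 0 excluded."""
        n = self.n_angle_candidates
        return (math.pi / 2) * np.arange(1, n + 1) / n


@dataclass(frozen=True)
class TriangleFit:
    """Fitted triangle: angles, vertices, centroid data and objective."""

    phi: float
    psi: float
    A: tuple[float, float]
    B: tuple[float, float]
    C: tuple[float, float]
    centroid: tuple[float, float]
    centroid_projection: tuple[float, float]
    height: float
    objective: float
    degenerate: bool = False


@dataclass(frozen=True)
class TriangleDescriptors:
    """The five scalar descriptors of the topological triangle."""

    triangle_width: float
    triangle_height: float
    triangle_location: float
    triangle_proportion: float
    triangle_misalignment: float

    def as_dict(self) -> dict[str, float]:
        return {
            "triangle_width": self.triangle_width,
            "triangle_height": self.triangle_height,
            "triangle_location": self.triangle_location,
            "triangle_proportion": self.triangle_proportion,
            "triangle_misalignment": self.triangle_misalignment,
        }


def _rot(theta: float) -> np.ndarray:
    c, s = math.cos(theta), math.sin(theta)
    return np.array([[c, -s], [s, c]])


def line_normal(angle: float) -> np.ndarray:
    """Outward unit normal of the candidate line at ``angle``.

    The line direction is the diagonal rotated counterclockwise by
    ``-angle`` (so phi < 0 rotates counterclockwise toward the left
    side, psi > 0 clockwise toward the right side); the normal is the
    direction rotated by +90 degrees and points to the outer side: the
    low-birth side for the left line, the high-death / late-diagonal
    side for the right line.
    """
    direction = _rot(-angle) @ _U
    return _rot(math.pi / 2) @ direction


def anchored_offset(points: np.ndarray, normal: np.ndarray, m: int) -> float:
    """Offset c of the line {n . x = c} through the m-th outermost point.

    Projections s_i = n . p_i are sorted descending (outer side first);
    the line runs through the projection foot of the m-th point, so m
    points (the anchor included) lie on or outside the line.
    """
    s = points @ normal
    return float(np.sort(s)[::-1][m - 1])


def _zone_ssq(signed: np.ndarray, m: int, zone_size: int) -> float:
    """Sum of squared distances over the 10-75% zone of one line.

    ``signed`` are signed distances (positive = outer side).  The zone
    consists of the m outermost points plus the ``zone_size - m`` inner
    points closest to the line.
    """
    order = np.argsort(signed)[::-1]  # outermost first
    outer = order[:m]
    inner = order[m:]
    take = max(zone_size - m, 0)
    if take and inner.size:
        closest = inner[np.argsort(np.abs(signed[inner]))[:take]]
        idx = np.concatenate([outer, closest])
    else:
        idx = outer
    return float(np.square(signed[idx]).sum())


def _diag_intersection(normal: np.ndarray, offset: float) -> np.ndarray | None:
    denom = normal[0] + normal[1]
    if abs(denom) < 1e-12:
        return None  # line parallel to the diagonal
    t = offset / denom
    return np.array([t, t])


def fit_triangle(
    diagram: PersistenceDiagram | np.ndarray,
    config: TriangleConfig | None = None,
) -> TriangleFit:
    """Fit the topological triangle to a persistence diagram.

    Performs the full grid search over angle pairs (phi, psi); for each
    pair the two anchored lines give A (left line meets the diagonal),
    B (right line meets the diagonal) and C (the lines' intersection),
    and the objective described in the module docstring is evaluated.
    The minimising pair is returned (ties broken by the smallest grid
    indices).

    Diagrams with fewer than 3 points, or with all points coincident,
    yield a flagged degenerate fit of zero width and height.
    """
    config = config or TriangleConfig()
    pts = diagram.points() if isinstance(diagram, PersistenceDiagram) else np.asarray(
        diagram, dtype=float
    )
    n = pts.shape[0]
    centroid = pts.mean(axis=0) if n else np.zeros(2)
    proj = 0.5 * (centroid[0] + centroid[1])
    p_c = np.array([proj, proj])
    if n < 3 or np.allclose(pts, pts[0]):
        loc = float(centroid[0]) if n else math.nan
        v = (loc, loc)
        return TriangleFit(
            phi=math.nan, psi=math.nan, A=v, B=v, C=v,
            centroid=(float(centroid[0]), float(centroid[1])),
            centroid_projection=(float(p_c[0]), float(p_c[1])),
            height=0.0, objective=0.0, degenerate=True,
        )

    m = math.ceil(config.outer_fraction * n)
    zone = math.floor(config.zone_fraction * n)

    phis = config.phi_grid()
    psis = config.psi_grid()

    # per-angle quantities (each line depends on one angle only)
    def line_data(angles: np.ndarray):
        normals, offsets, ssqs, diag_pts = [], [], [], []
        for a in angles:
            nrm = line_normal(float(a))
            off = anchored_offset(pts, nrm, m)
            signed = pts @ nrm - off
            normals.append(nrm)
            offsets.append(off)
            ssqs.append(_zone_ssq(signed, m, zone))
            diag_pts.append(_diag_intersection(nrm, off))
        return normals, offsets, ssqs, diag_pts

    k_norm, k_off, k_ssq, k_A = line_data(phis)
    l_norm, l_off, l_ssq, l_B = line_data(psis)

    best = None
    for i in range(len(phis)):
        A = k_A[i]
        if A is None:
            continue
        a_term = float(np.square(A - p_c).sum())
        for j in range(len(psis)):
            B = l_B[j]
            if B is None:
                continue
            M = np.array([k_norm[i], l_norm[j]])
            det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
            if abs(det) < 1e-12:
                continue  # parallel lines: no apex
            C = np.linalg.solve(M, np.array([k_off[i], l_off[j]]))
            h = abs(C[1] - C[0]) / _SQRT2
            obj = (
                k_ssq[i] + l_ssq[j] + a_term
                + float(np.square(B - p_c).sum()) + h * h
            )
            if best is None or obj < best[0] - 1e-15:
                best = (obj, i, j, A, B, C, h)
    if best is None:
        raise ValueError("all candidate angle pairs are ill-conditioned")
    obj, i, j, A, B, C, h = best
    return TriangleFit(
        phi=float(phis[i]), psi=float(psis[j]),
        A=(float(A[0]), float(A[1])),
        B=(float(B[0]), float(B[1])),
        C=(float(C[0]), float(C[1])),
        centroid=(float(centroid[0]), float(centroid[1])),
        centroid_projection=(float(p_c[0]), float(p_c[1])),
        height=float(h), objective=float(obj),
    )


def triangle_descriptors(fit: TriangleFit) -> TriangleDescriptors:
    """The five descriptors of a fitted triangle.

    Degenerate fits report zero width and height, the common coordinate
    as location, NaN proportion and zero misalignment.
    """
    A = np.asarray(fit.A)
    B = np.asarray(fit.B)
    C = np.asarray(fit.C)
    width = float(np.linalg.norm(B - A))
    if fit.degenerate:
        return TriangleDescriptors(
            triangle_width=0.0, triangle_height=0.0,
            triangle_location=float(A[0]),
            triangle_proportion=math.nan, triangle_misalignment=0.0,
        )
    bc = float(np.linalg.norm(C - B))
    proportion = float(np.linalg.norm(C - A)) / bc if bc > 0 else math.nan
    return TriangleDescriptors(
        triangle_width=width,
        triangle_height=float(fit.height),
        triangle_location=float(0.5 * (A[0] + B[0])),
        triangle_proportion=proportion,
        triangle_misalignment=float(fit.objective),
    )


def plot_triangle(diagram: PersistenceDiagram, fit: TriangleFit, path: str) -> None:
    """Write a persistence-diagram scatter with the fitted triangle."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pts = diagram.points()
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(pts[:, 0], pts[:, 1], s=12, alpha=0.7, label="diagram")
    tri = np.array([fit.A, fit.B, fit.C, fit.A])
    ax.plot(tri[:, 0], tri[:, 1], "r-", lw=1.2, label="T(D)")
    lo = min(pts.min(), min(fit.A[0], fit.B[0]))
    hi = max(pts.max(), fit.C[1])
    pad = 0.05 * (hi - lo + 1)
    ax.plot([lo - pad, hi + pad], [lo - pad, hi + pad], "k--", lw=0.8)
    ax.set_xlabel("birth [ms]")
    ax.set_ylabel("death [ms]")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
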