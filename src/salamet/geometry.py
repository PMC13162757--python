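"""Habitat-outline geometry: contour area, minimum enclosing circle, circularity.

A spawning-site outline is a closed simple polygon in planar units (or a
binary raster mask traced into one).  The shape statistic used downstream is
the *circularity similarity*

    similarity(%) = 100 * contour_area / circle_area

where ``circle_area`` is the area of the minimum enclosing circle of the
outline.  A perfect disc scores 100; elongated ditches and channels score
low.  The statistic is scale invariant: both areas grow with the square of
any uniform rescaling.

The minimum enclosing circle is computed with Welzl's randomized incremental
algorithm (expected linear time, exact up to floating point); the shuffle is
seeded so results are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from shapely.geometry import MultiPoint, Polygon

from .errors import ParseError, ValidationError

__all__ = [
    "CircularityResult",
    "polygon_area",
    "min_enclosing_circle",
    "circularity",
    "mask_to_outline",
    "read_polygon",
    "write_polygon",
    "read_mask",
]

# relative slack for "point inside circle" tests; the final certificate is
# checked at 1e-9 relative tolerance
_EPS = 1e-12


@dataclass(frozen=True)
class CircularityResult:
    """Area, enclosing circle and circularity of one site outline."""

    contour_area: float
    circle_center: tuple[float, float]
    circle_radius: float
    similarity_pct: float
    degenerate: bool = False


def _as_vertices(outline) -> np.ndarray:
    v = np.asarray(outline, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ValidationError("outline must be an (n, 2) array of vertices")
    # drop an explicit closing vertex and consecutive duplicates
    if len(v) > 1 and np.allclose(v[0], v[-1]):
        v = v[:-1]
    keep = np.ones(len(v), dtype=bool)
    keep[1:] = ~np.all(np.isclose(v[1:], v[:-1]), axis=1)
    v = v[keep]
    if len(v) < 3:
        raise ValidationError(f"outline needs >= 3 distinct vertices, got {len(v)}")
    return v


def polygon_area(outline) -> float:
    """Absolute polygon area by the shoelace formula.

    Orientation independent; the outline is closed implicitly.
    """
    v = _as_vertices(outline)
    x, y = v[:, 0], v[:, 1]
    return abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0


def _validate_simple(v: np.ndarray) -> None:
    poly = Polygon(v)
    if not poly.is_valid:
        raise ValidationError("outline is self-intersecting; a simple polygon is required")


def _inside(c: np.ndarray, r: float, p: np.ndarray) -> bool:
    return float(np.hypot(*(p - c))) <= r * (1.0 + _EPS) + _EPS


def _circle_two_points(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, float]:
    c = (p + q) / 2.0
    return c, float(np.hypot(*(p - c)))


def _circumcircle(a, b, c) -> tuple[np.ndarray, float] | None:
    ax, ay = a
    bx, by = b
    cx, cy = c
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if d == 0.0:  # collinear
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay)
          + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx)
          + (cx**2 + cy**2) * (bx - ax)) / d
    center = np.array([ux, uy])
    return center, float(np.hypot(*(a - center)))


def _circle_with_two(points: np.ndarray, p: np.ndarray, q: np.ndarray):
    c, r = _circle_two_points(p, q)
    for k in range(len(points)):
        if not _inside(c, r, points[k]):
            cc = _circumcircle(p, q, points[k])
            if cc is None:
                # collinear triple: the diameter circle of the extreme pair
                trio = np.array([p, q, points[k]])
                best = (None, -1.0)
                for i in range(3):
                    for j in range(i + 1, 3):
                        ci, ri = _circle_two_points(trio[i], trio[j])
                        if ri > best[1]:
                            best = (ci, ri)
                c, r = best
            else:
                c, r = cc
    return c, r


def _circle_with_one(points: np.ndarray, q: np.ndarray):
    c, r = q.copy(), 0.0
    for j in range(len(points)):
        if not _inside(c, r, points[j]):
            c, r = _circle_with_two(points[:j], points[j], q)
    return c, r


def min_enclosing_circle(points, seed: int = 0) -> tuple[tuple[float, float], float]:
    """Smallest circle enclosing all points (Welzl, randomized incremental).

    Parameters
    ----------
    points : (n, 2) array-like, n >= 1
    seed : int
        Seed for the internal shuffle; the result is deterministic given it.

    Returns
    -------
    (center, radius) : ((float, float), float)
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValidationError("min_enclosing_circle requires at least one point")
    if pts.shape[1] != 2:
        raise ValidationError("points must be an (n, 2) array")
    rng = np.random.default_rng(seed)
    P = pts[rng.permutation(len(pts))]
    c, r = P[0].copy(), 0.0
    for i in range(1, len(P)):
        if not _inside(c, r, P[i]):
            c, r = _circle_with_one(P[:i], P[i])
    # certificate: every input point inside at 1e-9 relative tolerance
    dmax = float(np.max(np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])))
    if dmax > r * (1 + 1e-9) + 1e-9:
        raise RuntimeError("enclosing-circle certificate failed")  # pragma: no cover
    return (float(c[0]), float(c[1])), r


def circularity(outline, seed: int = 0) -> CircularityResult:
    """Circularity similarity of a site outline.

    Combines the shoelace contour area with the minimum enclosing circle of
    the vertices; result in [0, 100].  A zero-area (collinear) outline is
    reported with ``similarity_pct=0`` and ``degenerate=True`` rather than
    raising.
    """
    v = _as_vertices(outline)
    area = polygon_area(v)
    (cx, cy), radius = min_enclosing_circle(v, seed=seed)
    # degenerate = vertices (near-)collinear: the convex hull carries no area
    hull_area = MultiPoint(v).convex_hull.area
    if hull_area <= 1e-9 * max(1.0, radius**2):
        return CircularityResult(0.0, (cx, cy), radius, 0.0, degenerate=True)
    _validate_simple(v)
    sim = 100.0 * area / (math.pi * radius**2)
    return CircularityResult(area, (cx, cy), radius, min(sim, 100.0))


# ---------------------------------------------------------------------------
# raster masks

def mask_to_outline(mask, cell_size: float = 1.0, connectivity: int = 4) -> np.ndarray:
    """Trace the outer boundary of a single-component binary mask.

    The boundary follows pixel edges (so a single foreground pixel yields its
    unit-cell square), returned as an (n, 2) vertex array in physical units
    with x = column * cell_size, y = row * cell_size.  Interior holes are
    ignored.  Raises if the mask holds zero or more than one foreground
    component under the requested connectivity.
    """
    from scipy import ndimage

    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise ValidationError("mask must be a 2-D array")
    if connectivity not in (4, 8):
        raise ValidationError("connectivity must be 4 or 8")
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4 else 2)
    _, n_comp = ndimage.label(m, structure=structure)
    if n_comp != 1:
        raise ValidationError(f"mask must contain exactly one component, found {n_comp} components")

    # directed pixel edges with the foreground on the left; shared edges of
    # neighbouring foreground pixels cancel by omission
    padded = np.pad(m, 1)
    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def add(a, b):
        edges.setdefault(a, []).append(b)

    rows, cols = np.nonzero(m)
    for r, c in zip(rows.tolist(), cols.tolist()):
        if not padded[r, c + 1]:       # north neighbour background
            add((c, r), (c + 1, r))
        if not padded[r + 1, c + 2]:   # east
            add((c + 1, r), (c + 1, r + 1))
        if not padded[r + 2, c + 1]:   # south
            add((c + 1, r + 1), (c, r + 1))
        if not padded[r + 1, c]:       # west
            add((c, r + 1), (c, r))

    loops: list[list[tuple[int, int]]] = []
    while edges:
        start = next(iter(edges))
        loop = [start]
        prev = None
        cur = start
        while True:
            outs = edges[cur]
            if len(outs) == 1 or prev is None:
                nxt = outs[0]
            else:
                # checkerboard (pinch) vertex: two outgoing edges.
                # 4-connectivity pinches the corner apart, 8-connectivity
                # carries the walk across into the diagonal neighbour.
                dx, dy = cur[0] - prev[0], cur[1] - prev[1]

                def cross(nb):
                    return dx * (nb[1] - cur[1]) - dy * (nb[0] - cur[0])

                nxt = (max if connectivity == 4 else min)(outs, key=cross)
            outs.remove(nxt)
            if not outs:
                del edges[cur]
            prev, cur = cur, nxt
            # a loop may pass through its start vertex more than once (pinch
            # at the start); close only when start has no edges left
            if cur == start and start not in edges:
                break
            loop.append(cur)
        loops.append(loop)

    outer = max(loops, key=lambda lp: polygon_area(np.asarray(lp, float)))
    return np.asarray(outer, dtype=float) * float(cell_size)


# ---------------------------------------------------------------------------
# file formats

def read_polygon(path) -> np.ndarray:
    """Read a polygon file: one ``x<TAB>y`` vertex per line, closed implicitly."""
    verts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'x<TAB>y', got {line!r}")
            try:
                verts.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric vertex {line!r}") from exc
    if len(verts) < 3:
        raise ParseError(f"{path}: polygon needs >= 3 vertices, got {len(verts)}")
    return np.asarray(verts, dtype=float)


def write_polygon(path, outline) -> None:
    v = _as_vertices(outline)
    with open(path, "w") as fh:
        for x, y in v:
            fh.write(f"{x:.10g}\t{y:.10g}\n")


def read_mask(path) -> tuple[np.ndarray, float]:
    """Read a binary mask: PGM (P2/P5, nonzero = foreground, cell size 1) or a
    text grid whose first line is ``cell_size<TAB><value>`` followed by rows
    of 0/1 digits (whitespace optional)."""
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic in (b"P2", b"P5"):
        return _read_pgm(path), 1.0
    cell_size = 1.0
    rows = []
    with open(path) as fh:
        first = fh.readline().strip()
        if first.lower().startswith("cell_size"):
            cell_size = float(first.split()[1])
        elif first:
            rows.append([int(ch) for ch in first.replace(" ", "").replace("\t", "")])
        for line in fh:
            line = line.strip()
            if line:
                rows.append([int(ch) for ch in line.replace(" ", "").replace("\t", "")])
    if not rows:
        raise ParseError(f"{path}: empty mask")
    if len({len(r) for r in rows}) != 1:
        raise ParseError(f"{path}: ragged mask rows")
    return np.asarray(rows, dtype=bool), cell_size


def _read_pgm(path) -> np.ndarray:
    with open(path, "rb") as fh:
        data = fh.read()
    tokens: list[bytes] = []
    i = 0
    # header: magic, width, height, maxval (comments allowed)
    while len(tokens) < 4:
        while i < len(data) and data[i : i + 1].isspace():
            i += 1
        if data[i : i + 1] == b"#":
            while i < len(data) and data[i : i + 1] != b"\n":
                i += 1
            continue
        j = i
        while j < len(data) and not data[j : j + 1].isspace():
            j += 1
        tokens.append(data[i:j])
        i = j
    magic, w, h = tokens[0], int(tokens[1]), int(tokens[2])
    if magic == b"P2":
        vals = np.array(data[i:].split(), dtype=int)
    else:
        vals = np.frombuffer(data[i + 1 : i + 1 + w * h], dtype=np.uint8).astype(int)
    if vals.size != w * h:
        raise ParseError(f"{path}: PGM payload size mismatch")
    return (vals.reshape(h, w) > 0)
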