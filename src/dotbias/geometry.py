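"""Random dot-pattern stimuli for the connectedness numerosity illusion.

Stimuli are clouds of small black and white disks scattered in a circular
patch.  In the *connected* condition a fixed fraction of the dots is cast
in pairs joined by a thin line of the pair's colour, producing dumbbell-like
figures that perceptually group the two dots into one unit; the remaining
dots are cast afterwards, avoiding both the dots and the connecting lines.

All coordinates are degrees of visual angle, origin at the patch centre,
y pointing up.  Physical sizes are specified in millimetres and converted
through the viewing distance (at 57 cm, 1 cm on the screen subtends 1 deg,
and the conversion is kept linear in that small-angle regime).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "GeometryConfig",
    "DotPattern",
    "PlacementError",
    "place_isolated",
    "place_connected",
    "segments_intersect",
    "render_pattern",
    "check_pattern",
]


class PlacementError(RuntimeError):
    """Rejection sampling exhausted: the field cannot hold the requested
    number of elements at the configured spacing."""


@dataclass(frozen=True)
class GeometryConfig:
    """Physical layout of one stimulus patch.

    Parameters
    ----------
    viewing_distance : float
        Eye-to-screen distance in cm.  57 cm makes 1 cm = 1 deg.
    dot_diameter : float
        Disk diameter in mm (default 2.5 mm = 0.25 deg at 57 cm).
    min_spacing : float
        Minimum centre-to-centre dot distance in mm; two items can never
        be closer than this.
    connector_length_range : tuple of float
        (min, max) connector line length in mm.
    connector_width : float
        Connector line width in mm.
    connect_fraction : float
        Fraction of dots cast as connected pairs (0.4 = 40%).
    field_radius : float
        Radius of the circular patch in deg.
    clearance_margin : float
        Extra clearance (deg) between a loose dot's ink and a connector's
        ink beyond strict non-overlap.
    max_attempts : int
        Rejection-sampling cap per element before raising PlacementError.
    """

    viewing_distance: float = 57.0
    dot_diameter: float = 2.5
    min_spacing: float = 2.5
    connector_length_range: tuple[float, float] = (10.0, 15.0)
    connector_width: float = 0.5
    connect_fraction: float = 0.4
    field_radius: float = 6.0
    clearance_margin: float = 0.0
    max_attempts: int = 10_000

    def __post_init__(self):
        if self.viewing_distance <= 0 or self.dot_diameter <= 0:
            raise ValueError("lengths must be positive")
        if self.min_spacing <= 0 or self.connector_width <= 0:
            raise ValueError("lengths must be positive")
        lo, hi = self.connector_length_range
        if not (0 < lo < hi):
            raise ValueError("connector_length_range must satisfy 0 < min < max")
        if not 0.0 <= self.connect_fraction <= 1.0:
            raise ValueError("connect_fraction must lie in [0, 1]")
        if self.field_radius <= 0:
            raise ValueError("field_radius must be positive")

    # -- unit conversion -------------------------------------------------
    def mm_to_deg(self, mm: float) -> float:
        """Millimetres on screen to degrees of visual angle (linear)."""
        return (mm / 10.0) * (57.0 / self.viewing_distance)

    @property
    def dot_radius_deg(self) -> float:
        return self.mm_to_deg(self.dot_diameter) / 2.0

    @property
    def min_spacing_deg(self) -> float:
        return self.mm_to_deg(self.min_spacing)

    @property
    def connector_length_deg(self) -> tuple[float, float]:
        lo, hi = self.connector_length_range
        return self.mm_to_deg(lo), self.mm_to_deg(hi)

    @property
    def connector_width_deg(self) -> float:
        return self.mm_to_deg(self.connector_width)

    @property
    def dot_connector_clearance_deg(self) -> float:
        """Minimum distance between a loose dot's centre and a connector
        segment so that their ink does not overlap."""
        return (self.dot_radius_deg + self.connector_width_deg / 2.0
                + self.clearance_margin)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["connector_length_range"] = list(self.connector_length_range)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class DotPattern:
    """One stimulus cloud: dot centres (deg), dot colours, connector pairs."""

    xy: np.ndarray                    # (n, 2) float
    colours: np.ndarray               # (n,) str, "black" or "white"
    connectors: list[tuple[int, int]] = field(default_factory=list)

    @property
    def numerosity(self) -> int:
        return len(self.xy)

    def connector_segments(self) -> np.ndarray:
        """(k, 2, 2) array of connector endpoint coordinates."""
        if not self.connectors:
            return np.empty((0, 2, 2))
        idx = np.asarray(self.connectors)
        return self.xy[idx]

    # -- serialization ---------------------------------------------------
    def to_json(self, cfg: GeometryConfig | None = None) -> str:
        obj = {
            "numerosity": self.numerosity,
            "dots": [
                {"x": float(x), "y": float(y), "colour": str(c)}
                for (x, y), c in zip(self.xy, self.colours)
            ],
            "connectors": [[int(a), int(b)] for a, b in self.connectors],
        }
        if cfg is not None:
            obj["config_hash"] = cfg.config_hash()
        return json.dumps(obj)

    @classmethod
    def from_json(cls, text: str) -> "DotPattern":
        obj = json.loads(text)
        dots = obj["dots"]
        xy = np.array([[d["x"], d["y"]] for d in dots], float).reshape(-1, 2)
        colours = np.array([d["colour"] for d in dots], dtype="<U5")
        conns = [tuple(c) for c in obj["connectors"]]
        return cls(xy=xy, colours=colours, connectors=conns)


# ---------------------------------------------------------------------------
# low-level geometry
# ---------------------------------------------------------------------------

def _orient(p, q, r):
    """Sign of the cross product (q-p) x (r-p)."""
    v = (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])
    return 0 if v == 0 else (1 if v > 0 else -1)


def _on_segment(p, q, r):
    """Assuming p, q, r collinear: does r lie on closed segment pq?"""
    return (min(p[0], q[0]) <= r[0] <= max(p[0], q[0])
            and min(p[1], q[1]) <= r[1] <= max(p[1], q[1]))


def segments_intersect(s1: Sequence, s2: Sequence) -> bool:
    """True iff the closed segments share at least one point.

    Classic orientation test; collinear overlap (including a shared
    endpoint) counts as intersecting.
    """
    p1, q1 = s1
    p2, q2 = s2
    d1 = _orient(p1, q1, p2)
    d2 = _orient(p1, q1, q2)
    d3 = _orient(p2, q2, p1)
    d4 = _orient(p2, q2, q1)
    if d1 != d2 and d3 != d4:
        return True
    if d1 == 0 and _on_segment(p1, q1, p2):
        return True
    if d2 == 0 and _on_segment(p1, q1, q2):
        return True
    if d3 == 0 and _on_segment(p2, q2, p1):
        return True
    if d4 == 0 and _on_segment(p2, q2, q1):
        return True
    return False


def point_segment_distance(points: np.ndarray, a, b) -> np.ndarray:
    """Distance from each point to the closed segment a-b (vectorized)."""
    points = np.atleast_2d(points)
    a = np.asarray(a, float)
    d = np.asarray(b, float) - a
    denom = float(d @ d)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ d / denom, 0.0, 1.0)
    proj = a + t[:, None] * d
    return np.linalg.norm(points - proj, axis=1)


def _round_to_even(x: float) -> int:
    """Nearest even integer (pairs must be whole)."""
    return int(2 * round(x / 2.0))


# ---------------------------------------------------------------------------
# colour assignment
# ---------------------------------------------------------------------------

def _assign_colours(n: int, n_pairs: int, rng: np.random.Generator) -> np.ndarray:
    """Colours for ``2*n_pairs`` pair dots followed by loose dots.

    Pairs alternate colour (a pair and its connector share one colour);
    loose dots fill the remaining quota so that black and white counts
    differ by at most one.  Loose colour order is shuffled.
    """
    cols = np.empty(n, dtype="<U5")
    pair_cols = ["black" if i % 2 == 0 else "white" for i in range(n_pairs)]
    for i, c in enumerate(pair_cols):
        cols[2 * i] = c
        cols[2 * i + 1] = c
    n_black_pairs = 2 * sum(c == "black" for c in pair_cols)
    n_loose = n - 2 * n_pairs
    # total black must land on n//2 or ceil(n/2) so |black - white| <= 1
    lo, hi = n_black_pairs, n_black_pairs + n_loose
    for target in (n // 2, (n + 1) // 2):
        if lo <= target <= hi:
            break
    else:
        target = int(np.clip(n // 2, lo, hi))
    loose_black = target - n_black_pairs
    loose = np.array(["black"] * loose_black + ["white"] * (n_loose - loose_black),
                     dtype="<U5")
    rng.shuffle(loose)
    cols[2 * n_pairs:] = loose
    return cols


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------

def _sample_in_disk(rng: np.random.Generator, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random())
    th = 2 * np.pi * rng.random()
    return np.array([r * np.cos(th), r * np.sin(th)])


def place_isolated(n: int, cfg: GeometryConfig, rng: np.random.Generator) -> DotPattern:
    """Cast ``n`` isolated dots with the minimum-spacing constraint.

    Dots are placed one at a time by rejection sampling inside the circular
    field (centres kept ``dot_radius`` inside the rim); each candidate must
    keep ``min_spacing`` from every dot already placed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pat = _cast(n, 0, cfg, rng)
    return pat


def place_connected(n: int, cfg: GeometryConfig, rng: np.random.Generator) -> DotPattern:
    """Two-stage cast: connected pairs first, then the remaining loose dots.

    Stage 1 places ``round_to_even(connect_fraction * n) / 2`` pairs: the
    first dot of a pair is cast like an isolated dot, the second at a
    uniform-random direction and a uniform-random connector length from the
    first.  Connectors may not cross each other and keep clear of all dots.
    Stage 2 casts the loose dots avoiding both dots and connector lines.
    """
    if n < 2:
        raise ValueError("n must be >= 2 for connected patterns")
    n_paired = _round_to_even(cfg.connect_fraction * n)
    n_pairs = n_paired // 2
    if cfg.connect_fraction > 0 and n_pairs < 1:
        raise ValueError("connect_fraction * n rounds to fewer than one pair")
    return _cast(n, n_pairs, cfg, rng)


def _cast(n: int, n_pairs: int, cfg: GeometryConfig,
          rng: np.random.Generator) -> DotPattern:
    inner = cfg.field_radius - cfg.dot_radius_deg
    if inner <= 0:
        raise PlacementError("field smaller than a single dot")
    spacing = cfg.min_spacing_deg
    len_lo, len_hi = cfg.connector_length_deg
    clearance = cfg.dot_connector_clearance_deg

    xy: list[np.ndarray] = []
    segs: list[tuple[np.ndarray, np.ndarray]] = []
    connectors: list[tuple[int, int]] = []

    def far_from_dots(p, exclude_from=None):
        if not xy:
            return True
        pts = np.asarray(xy)
        d = np.linalg.norm(pts - p, axis=1)
        return bool(np.all(d >= spacing))

    def clear_of_segments(p, margin):
        return all(point_segment_distance(p[None, :], a, b)[0] >= margin
                   for a, b in segs)

    # stage 1: pairs ----------------------------------------------------
    for _ in range(n_pairs):
        for attempt in range(cfg.max_attempts):
            p = _sample_in_disk(rng, inner)
            theta = 2 * np.pi * rng.random()
            length = rng.uniform(len_lo, len_hi)
            q = p + length * np.array([np.cos(theta), np.sin(theta)])
            if np.linalg.norm(q) > inner:
                continue
            if not (far_from_dots(p) and far_from_dots(q)):
                continue
            # keep the new connector clear of existing dots and vice versa
            if not (clear_of_segments(p, clearance) and clear_of_segments(q, clearance)):
                continue
            if xy and np.any(point_segment_distance(np.asarray(xy), p, q) < clearance):
                continue
            if any(segments_intersect((p, q), s) for s in segs):
                continue
            i = len(xy)
            xy.append(p)
            xy.append(q)
            segs.append((p, q))
            connectors.append((i, i + 1))
            break
        else:
            raise PlacementError(
                f"could not place pair {len(connectors) + 1} of {n_pairs} "
                f"after {cfg.max_attempts} attempts")

    # stage 2: loose dots ------------------------------------------------
    for _ in range(n - 2 * n_pairs):
        for attempt in range(cfg.max_attempts):
            p = _sample_in_disk(rng, inner)
            if not far_from_dots(p):
                continue
            if not clear_of_segments(p, clearance):
                continue
            xy.append(p)
            break
        else:
            raise PlacementError(
                f"could not place dot {len(xy) + 1} of {n} after "
                f"{cfg.max_attempts} attempts")

    colours = _assign_colours(n, n_pairs, rng)
    return DotPattern(xy=np.asarray(xy), colours=colours, connectors=connectors)


# ---------------------------------------------------------------------------
# invariant checklist
# ---------------------------------------------------------------------------

def check_pattern(p: DotPattern, cfg: GeometryConfig) -> list[str]:
    """Run the full invariant checklist; return a list of violations
    (empty when the pattern is valid)."""
    errs: list[str] = []
    n = p.numerosity
    if len(p.colours) != n:
        errs.append("colour array length mismatch")
    used = [i for ab in p.connectors for i in ab]
    if any(not (0 <= i < n) for i in used):
        errs.append("connector references a missing dot")
    if any(a == b for a, b in p.connectors):
        errs.append("connector joins a dot to itself")
    if len(set(used)) != len(used):
        errs.append("a dot appears in more than one connector")
    nb = int(np.sum(p.colours == "black"))
    nw = int(np.sum(p.colours == "white"))
    if nb + nw != n:
        errs.append("colours other than black/white present")
    if abs(nb - nw) > 1:
        errs.append(f"colour imbalance: {nb} black vs {nw} white")
    if n > 1:
        d = np.linalg.norm(p.xy[:, None, :] - p.xy[None, :, :], axis=-1)
        iu = np.triu_indices(n, k=1)
        if np.min(d[iu]) < cfg.min_spacing_deg - 1e-9:
            errs.append("pairwise distance below min_spacing")
    lo, hi = cfg.connector_length_deg
    for a, b in p.connectors:
        length = float(np.linalg.norm(p.xy[a] - p.xy[b]))
        if not (lo - 1e-9 <= length <= hi + 1e-9):
            errs.append(f"connector length {length:.3f} outside [{lo:.3f}, {hi:.3f}]")
        col_a, col_b = p.colours[a], p.colours[b]
        if col_a != col_b:
            errs.append("pair dots differ in colour")
    segs = p.connector_segments()
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            if segments_intersect(segs[i], segs[j]):
                errs.append(f"connectors {i} and {j} intersect")
    if len(segs):
        loose = np.setdiff1d(np.arange(n), np.asarray(used))
        clearance = cfg.dot_connector_clearance_deg
        for a, b in segs:
            if len(loose) and np.any(
                    point_segment_distance(p.xy[loose], a, b) < clearance - 1e-9):
                errs.append("loose dot overlaps a connector line")
    rim = np.linalg.norm(p.xy, axis=1) + cfg.dot_radius_deg
    if np.any(rim > cfg.field_radius + 1e-9):
        errs.append("dot ink extends beyond the field")
    return errs


# ---------------------------------------------------------------------------
# rasterisation
# ---------------------------------------------------------------------------

def render_pattern(p: DotPattern, cfg: GeometryConfig,
                   px_per_deg: float = 40.0) -> np.ndarray:
    """Rasterise a pattern onto a mid-grey background without anti-aliasing.

    Returns a 2D float array with background 0.5, black ink 0.0 and white
    ink 1.0; row 0 is the top of the image.
    """
    if px_per_deg <= 0:
        raise ValueError("px_per_deg must be positive")
    half = cfg.field_radius + cfg.dot_radius_deg
    npx = int(np.ceil(2 * half * px_per_deg))
    ax = (np.arange(npx) + 0.5) / px_per_deg - half
    X, Y = np.meshgrid(ax, -ax)       # y axis up
    img = np.full((npx, npx), 0.5)

    half_w = cfg.connector_width_deg / 2.0
    pix = np.column_stack([X.ravel(), Y.ravel()])
    for a, b in p.connectors:
        d = point_segment_distance(pix, p.xy[a], p.xy[b]).reshape(npx, npx)
        img[d <= half_w] = 0.0 if p.colours[a] == "black" else 1.0
    r2 = cfg.dot_radius_deg ** 2
    for (x, y), c in zip(p.xy, p.colours):
        mask = (X - x) ** 2 + (Y - y) ** 2 <= r2
        img[mask] = 0.0 if c == "black" else 1.0
    return img


def count_components(img: np.ndarray, background: float = 0.5) -> int:
    """Number of 8-connected ink components in a rendered pattern."""
    from scipy import ndimage

    mask = img != background
    _, n = ndimage.label(mask, structure=np.ones((3, 3), int))
    return int(n)
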