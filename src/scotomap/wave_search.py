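"""Wave-based adaptive search for the blind-spot/angioscotoma boundary.

The search presents a single fixed contrast at locations on concentric
circles of increasing radius (0.5 deg steps) around the blind-spot center,
with about 1 deg spacing along each circle.  Wave 1 tests the innermost
circle exhaustively (two presentations per location).  Each later wave
opens only those locations on the next circle that are Voronoi neighbors of
an already-tested location with at least one miss; before advancing, any
untested location on the current circle that neighbors a >=1-miss tested
location is tested too.  The search ends when a wave opens no new
locations (every boundary location was seen on both presentations —
``edges_closed``) or when an opened location falls outside the rectangular
test area (``out_of_range``).

The procedure is deliberately specific to the blind spot: it assumes the
search starts inside a deep scotoma whose edge it walks outward to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np
import pandas as pd
from scipy.spatial import QhullError, Voronoi

from scotomap.field_geometry import FieldLocation, TestGrid
from scotomap.psychometrics import PsychometricParams, detection_probability

__all__ = [
    "WaveSearchConfig",
    "WaveSearchTrace",
    "ring_locations",
    "voronoi_neighbors",
    "run_wave_search",
    "simulated_observer_from_map",
]


def ring_locations(center: FieldLocation, radius: float, spacing: float = 1.0) -> np.ndarray:
    """Evenly spaced points on a circle, ~``spacing`` apart along the arc.

    The count is ``max(4, round(2*pi*r / spacing))``; the first point is at
    angle 0 (temporal direction) and the rest proceed counterclockwise.
    Returns an (n, 2) array.
    """
    if radius <= 0 or spacing <= 0:
        raise ValueError("radius and spacing must be > 0")
    n = max(4, int(np.rint(2.0 * np.pi * radius / spacing)))
    ang = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack(
        [center.x + radius * np.cos(ang), center.y + radius * np.sin(ang)]
    )


def voronoi_neighbors(points: np.ndarray) -> dict[int, set[int]]:
    """Adjacency over points: neighbors iff their Voronoi cells share an edge.

    Cells that touch only at a vertex (the perfect-square tie case) are not
    neighbors.  Requires at least 4 points in general position; collinear
    input raises ``ValueError``.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 4:
        raise ValueError("Voronoi adjacency needs at least 4 points")
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("degenerate geometry: points are collinear")
    try:
        vor = Voronoi(pts)
    except QhullError as exc:  # pragma: no cover - rank check catches most
        raise ValueError(f"degenerate geometry for Voronoi tessellation: {exc}") from exc
    adj: dict[int, set[int]] = {i: set() for i in range(len(pts))}
    for i, j in vor.ridge_points:
        adj[int(i)].add(int(j))
        adj[int(j)].add(int(i))
    return adj


ObserverCallback = Callable[[FieldLocation, float], bool]


@dataclass
class WaveSearchConfig:
    """Configuration of one boundary-search run (single fixed contrast)."""

    center: FieldLocation
    contrast: float
    bounds: tuple[float, float, float, float]  # x_min, x_max, y_min, y_max
    ring_step: float = 0.5
    along_ring_spacing: float = 1.0
    presentations_per_location: int = 2
    wave_cap: int = 60

    def __post_init__(self):
        if self.ring_step <= 0:
            raise ValueError("ring_step must be > 0")
        if self.presentations_per_location < 1:
            raise ValueError("presentations_per_location must be >= 1")
        x_min, x_max, y_min, y_max = self.bounds
        if not (x_min <= self.center.x <= x_max and y_min <= self.center.y <= y_max):
            raise ValueError("center must lie within bounds")


@dataclass
class WaveSearchTrace:
    """Full record of a search: every presentation plus the final state."""

    status: str                              # edges_closed | out_of_range | wave_cap
    presentations: pd.DataFrame = field(repr=False)
    tested: dict = field(repr=False, default_factory=dict)  # loc idx -> (n_seen, n_missed)
    points: np.ndarray = field(repr=False, default=None)
    rings: np.ndarray = field(repr=False, default=None)     # ring index per point
    waves: dict = field(default_factory=dict)               # wave -> n locations tested

    @property
    def n_locations_tested(self) -> int:
        return len(self.tested)

    @property
    def n_presentations(self) -> int:
        return len(self.presentations)

    def summary(self) -> dict:
        return {
            "status": self.status,
            "n_locations_tested": self.n_locations_tested,
            "n_presentations": self.n_presentations,
            "per_wave_counts": {int(k): int(v) for k, v in self.waves.items()},
        }


def run_wave_search(
    config: WaveSearchConfig,
    observer: ObserverCallback,
    seed: Optional[int] = None,
) -> WaveSearchTrace:
    """Run the wave-based boundary search against an observer callback.

    ``observer(location, contrast) -> bool`` is consulted for each
    presentation (``seed`` is accepted for symmetry with stochastic
    observers but the search itself is deterministic given the responses).
    """
    x_min, x_max, y_min, y_max = config.bounds

    points: list[np.ndarray] = []   # all candidate points generated so far
    rings: list[int] = []           # ring index (1-based) per point
    tested: dict[int, list[int]] = {}  # idx -> [n_seen, n_missed]
    opened_oob: set[int] = set()    # opened but outside the test area: never tested
    records: list[dict] = []
    waves: dict[int, int] = {}
    pres_id = 0
    status = None

    def in_bounds(p) -> bool:
        return x_min <= p[0] <= x_max and y_min <= p[1] <= y_max

    def test_location(idx: int, wave: int, ring_idx: int) -> None:
        nonlocal pres_id
        p = points[idx]
        loc = FieldLocation(float(p[0]), float(p[1]))
        counts = tested.setdefault(idx, [0, 0])
        for _ in range(config.presentations_per_location):
            try:
                seen = bool(observer(loc, config.contrast))
            except Exception as exc:
                raise RuntimeError(f"observer failed at {loc}") from exc
            counts[0 if seen else 1] += 1
            records.append(
                dict(presentation_id=pres_id, wave=wave,
                     x_deg=loc.x, y_deg=loc.y,
                     ring_radius_deg=ring_idx * config.ring_step,
                     contrast_log=config.contrast, seen=seen))
            pres_id += 1

    def add_ring(k: int) -> list[int]:
        ring = ring_locations(config.center, k * config.ring_step, config.along_ring_spacing)
        idxs = []
        for p in ring:
            idxs.append(len(points))
            points.append(p)
            rings.append(k)
        return idxs

    # Wave 1: the innermost circle, tested exhaustively.
    went_oob = False
    for i in add_ring(1):
        if in_bounds(points[i]):
            test_location(i, wave=1, ring_idx=1)
        else:
            opened_oob.add(i)
            went_oob = True
    waves[1] = len(tested)

    k = 1
    while status is None:
        k += 1
        if k > config.wave_cap:
            status = "wave_cap"
            break
        add_ring(k)
        adj = voronoi_neighbors(np.asarray(points))
        opened_any = False
        # Open ring-k locations adjacent to >=1-miss tested locations; repeat
        # within the wave so locations neighboring newly found misses on the
        # same circle are tested before advancing.  Locations opened outside
        # the test area are never presented; reaching the boundary marks the
        # run out-of-range but does not stop expansion elsewhere.
        while True:
            miss_idx = {i for i, (_, m) in tested.items() if m >= 1}
            to_open = sorted(
                i for i in range(len(points))
                if rings[i] == k and i not in tested and i not in opened_oob
                and adj[i] & miss_idx
            )
            if not to_open:
                break
            for i in to_open:
                if not in_bounds(points[i]):
                    opened_oob.add(i)
                    went_oob = True
                    continue
                test_location(i, wave=k, ring_idx=k)
                opened_any = True
        waves[k] = sum(
            1 for r in records if r["wave"] == k
        ) // config.presentations_per_location
        if not opened_any:
            # Every scotoma edge was closed (seen on both presentations with
            # no new neighbors opened), unless the frontier left the area.
            status = "out_of_range" if went_oob else "edges_closed"

    df = pd.DataFrame(
        records,
        columns=["presentation_id", "wave", "x_deg", "y_deg",
                 "ring_radius_deg", "contrast_log", "seen"],
    )
    return WaveSearchTrace(
        status=status,
        presentations=df,
        tested={i: tuple(c) for i, c in tested.items()},
        points=np.asarray(points),
        rings=np.asarray(rings),
        waves=waves,
    )


def simulated_observer_from_map(
    source,
    gamma: float = 0.02,
    lam: float = 0.02,
    seed: Optional[int] = 0,
) -> ObserverCallback:
    """Stochastic observer driven by a fitted or ground-truth sensitivity field.

    ``source`` is either a :class:`~scotomap.maps_and_slices.ThresholdMap`
    (local alpha/beta looked up at the nearest defined lattice point) or a
    :class:`~scotomap.synthetic_observer.SensitivitySurface`.  Each call
    draws a uniform random number and responds *seen* when it falls below
    the local frequency-of-seeing value; reproducible under ``seed``.
    Queries outside the source's region raise ``ValueError``.
    """
    rng = np.random.default_rng(seed)

    from scotomap.synthetic_observer import SensitivitySurface, surface_alpha

    if isinstance(source, SensitivitySurface):
        def lookup(loc: FieldLocation) -> tuple[float, float]:
            return float(surface_alpha(source, loc.x, loc.y)), source.beta_field
        region = None
    else:
        tmap = source
        lat = tmap.lattice
        defined = np.isfinite(tmap.threshold_log)
        if not defined.any():
            raise ValueError("threshold map has no defined points")
        from scipy.spatial import cKDTree
        tree = cKDTree(lat.locations[defined])
        alphas = tmap.threshold_log[defined]
        betas = np.where(np.isfinite(tmap.slope[defined]), tmap.slope[defined], 3.5)
        region = lat

        def lookup(loc: FieldLocation) -> tuple[float, float]:
            if not region.contains(loc.x, loc.y):
                raise ValueError(f"query {loc} outside the map region")
            _, i = tree.query([loc.x, loc.y])
            return float(alphas[i]), float(betas[i])

    def observer(loc: FieldLocation, contrast: float) -> bool:
        alpha, beta = lookup(loc)
        p = detection_probability(
            PsychometricParams(alpha=alpha, beta=beta, gamma=gamma, lam=lam), contrast
        )
        return bool(rng.random() < p)

    return observer
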