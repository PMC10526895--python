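"""Visual-field coordinate conventions, test grids, and the contrast ladder.

Coordinates are degrees of visual angle in a single field-space frame of the
right eye: temporal is +x, superior is +y.  The study region is a rectangle
of 13 columns x 19 rows (11-17 deg horizontally, -3 to +6 deg vertically at
0.5 deg spacing, 247 locations) that covers part of the optic nerve head and
several major retinal vessels.

Stimulus strength is log10 Weber contrast.  The default ladder spans -0.9 to
+0.6 log units (74 levels); +0.6 log units corresponds to the device maximum
of 400% Weber contrast (an 80 cd/m^2 increment on a 20 cd/m^2 background).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "FieldLocation",
    "TestGrid",
    "ContrastLadder",
    "build_grid",
    "build_estimation_lattice",
    "build_ladder",
    "weber_contrast",
]

#: Extents and spacing of the study's nominal test grid (degrees).
PAPER_GRID_EXTENTS = (11.0, 17.0, -3.0, 6.0)
PAPER_GRID_SPACING = 0.5
PAPER_LATTICE_SPACING = 0.05

_DIV_TOL = 1e-9


class FieldLocation(NamedTuple):
    """A point in visual-field coordinates (degrees; temporal +x, superior +y)."""

    x: float
    y: float


def _axis_count(lo: float, hi: float, spacing: float, axis: str) -> int:
    span = hi - lo
    n_steps = round(span / spacing)
    if abs(n_steps * spacing - span) > _DIV_TOL:
        raise ValueError(
            f"{axis} range [{lo}, {hi}] is not divisible by spacing {spacing}"
        )
    return n_steps + 1


@dataclass(frozen=True)
class TestGrid:
    """A rectangular grid of test locations over an inclusive extent.

    ``locations`` is an (n, 2) array in row-major order: y varies in the
    outer loop (from y_min upward), x in the inner loop.  This ordering is
    fixed so trial sequencing is reproducible.
    """

    x_min: float
    x_max: float
    y_min: float
    y_max: float
    spacing: float
    locations: np.ndarray = field(repr=False)

    @property
    def n_x(self) -> int:
        return _axis_count(self.x_min, self.x_max, self.spacing, "x")

    @property
    def n_y(self) -> int:
        return _axis_count(self.y_min, self.y_max, self.spacing, "y")

    def __len__(self) -> int:
        return len(self.locations)

    def __iter__(self):
        for x, y in self.locations:
            yield FieldLocation(float(x), float(y))

    @property
    def extents(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.x_max, self.y_min, self.y_max)

    def contains(self, x, y) -> np.ndarray:
        """Vectorized point-in-extent test (inclusive boundaries)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.x_min) & (x <= self.x_max)
            & (y >= self.y_min) & (y <= self.y_max)
        )

    def locations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "loc_id": np.arange(len(self.locations)),
                "x_deg": self.locations[:, 0],
                "y_deg": self.locations[:, 1],
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "x_min": self.x_min,
                "x_max": self.x_max,
                "y_min": self.y_min,
                "y_max": self.y_max,
                "spacing": self.spacing,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TestGrid":
        d = json.loads(text)
        return build_grid(d["x_min"], d["x_max"], d["y_min"], d["y_max"], d["spacing"])


def build_grid(
    x_min: float, x_max: float, y_min: float, y_max: float, spacing: float
) -> TestGrid:
    """Build an inclusive rectangular grid of test locations.

    The location count is ``(round((x_max-x_min)/spacing)+1) *
    (round((y_max-y_min)/spacing)+1)``; the study grid (11, 17, -3, 6, 0.5)
    yields 13 x 19 = 247 locations.  Each axis range must be an integer
    multiple of the spacing (tolerance 1e-9), otherwise a ``ValueError``
    names the offending axis.
    """
    if not all(np.isfinite(v) for v in (x_min, x_max, y_min, y_max, spacing)):
        raise ValueError("grid extents and spacing must be finite")
    if x_max < x_min:
        raise ValueError("x_max must be >= x_min")
    if y_max < y_min:
        raise ValueError("y_max must be >= y_min")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    n_x = _axis_count(x_min, x_max, spacing, "x")
    n_y = _axis_count(y_min, y_max, spacing, "y")
    xs = x_min + spacing * np.arange(n_x)
    ys = y_min + spacing * np.arange(n_y)
    yy, xx = np.meshgrid(ys, xs, indexing="ij")  # y outer, x inner
    locations = np.column_stack([xx.ravel(), yy.ravel()])
    return TestGrid(x_min, x_max, y_min, y_max, spacing, locations)


def build_estimation_lattice(grid: TestGrid, spacing: float) -> TestGrid:
    """A finer lattice over the same extents, for local threshold estimation.

    At the study extents and 0.05 deg spacing this gives 121 x 181 = 21,901
    estimation points.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    return build_grid(grid.x_min, grid.x_max, grid.y_min, grid.y_max, spacing)


def paper_grid() -> TestGrid:
    """The study's 247-location nominal test grid."""
    return build_grid(*PAPER_GRID_EXTENTS, PAPER_GRID_SPACING)


@dataclass(frozen=True)
class ContrastLadder:
    """The discrete set of log10 Weber contrasts the device can present."""

    levels: np.ndarray = field(repr=False)

    def __post_init__(self):
        lv = np.asarray(self.levels, dtype=float)
        if lv.ndim != 1 or len(lv) < 1:
            raise ValueError("ladder must be a non-empty 1-d level set")
        if np.any(np.diff(lv) <= 0):
            raise ValueError("ladder levels must be strictly increasing")
        object.__setattr__(self, "levels", lv)

    @property
    def min(self) -> float:
        return float(self.levels[0])

    @property
    def max(self) -> float:
        return float(self.levels[-1])

    def __len__(self) -> int:
        return len(self.levels)

    def snap(self, contrast: float) -> float:
        """Nearest ladder level; ties broken toward the lower contrast."""
        d = np.abs(self.levels - contrast)
        idx = int(np.flatnonzero(d <= d.min() + 1e-12)[0])
        return float(self.levels[idx])

    def to_json(self) -> str:
        return json.dumps(
            {"levels": self.levels.tolist(), "min": self.min, "max": self.max}
        )

    @classmethod
    def from_json(cls, text: str) -> "ContrastLadder":
        return cls(levels=np.asarray(json.loads(text)["levels"], dtype=float))


def build_ladder(
    min_log: float = -0.9,
    max_log: float = 0.6,
    n_levels: int = 74,
    scale: str = "linear",
) -> ContrastLadder:
    """Build the contrast ladder spanning [min_log, max_log] log units.

    Parameters
    ----------
    scale
        ``"linear"`` (default): levels are uniform in linear Weber contrast
        between ``10**min_log`` and ``10**max_log``, which reproduces a
        non-uniform spacing in log units like a device's native luminance
        steps.  ``"log"``: uniform spacing in log units.
    """
    if not min_log < max_log:
        raise ValueError("min_log must be < max_log")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if scale == "linear":
        levels = np.log10(np.linspace(10.0**min_log, 10.0**max_log, n_levels))
        # Endpoints exact in log units despite the round trip through linear.
        levels[0], levels[-1] = min_log, max_log
    elif scale == "log":
        levels = np.linspace(min_log, max_log, n_levels)
    else:
        raise ValueError(f"unknown ladder scale {scale!r}")
    return ContrastLadder(levels=levels)


def weber_contrast(increment: float, background: float) -> float:
    """Weber contrast in percent: 100 * (luminance increment / background).

    The study device: 80 cd/m^2 maximum increment on a 20 cd/m^2 background
    gives the 400% maximum contrast (+0.6 log units).
    """
    if background <= 0:
        raise ValueError("background luminance must be > 0")
    if increment < 0:
        raise ValueError("luminance increment must be >= 0")
    return 100.0 * increment / background
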