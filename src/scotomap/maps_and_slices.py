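"""The three result displays for high-density perimetry.

1. *Conventional threshold map*: log contrast sensitivity (the negative of
   the log threshold) plotted at each nominal grid location, ignoring eye
   position.
2. *Locally weighted maximum-likelihood map*: at each point of a fine
   estimation lattice (0.05 deg spacing over the test region), a weighted
   maximum-likelihood Quick-Weibull fit to all presentations whose inferred
   retinal location lies within 0.5 deg, with Gaussian kernel weights
   (SD 0.5 deg) on Euclidean distance and false-positive/false-negative
   rates fixed at 0.02.
3. *Slice display*: for an adjustable display threshold C0, show only the
   crossover trials — seen below C0, or not seen at or above C0 — and sweep
   C0 from 0.5 down to -0.5 log units in 0.01 steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.spatial import cKDTree

from scotomap.field_geometry import FieldLocation, TestGrid

__all__ = [
    "FitResult",
    "ThresholdMap",
    "SliceSelection",
    "MlMapSettings",
    "conventional_map",
    "gaussian_kernel_weight",
    "weighted_ml_fit",
    "ml_threshold_map",
    "slice_select",
    "slice_sweep",
    "render_map",
]

#: Display range for rendered sensitivity maps, relative log units.
DISPLAY_RANGE_LOG = (-0.5, 1.0)


@dataclass(frozen=True)
class ThresholdMap:
    """Per-lattice-point threshold/slope estimates; sensitivity = -threshold."""

    lattice: TestGrid
    threshold_log: np.ndarray = field(repr=False)   # NaN where undefined
    slope: np.ndarray = field(repr=False)
    n_trials: np.ndarray = field(repr=False)
    fit_status: np.ndarray = field(repr=False)      # ok|boundary|insufficient|no_converge|missing

    @property
    def sensitivity_log(self) -> np.ndarray:
        return -self.threshold_log

    def to_frame(self) -> pd.DataFrame:
        locs = self.lattice.locations
        return pd.DataFrame(
            {
                "point_id": np.arange(len(locs)),
                "x_deg": locs[:, 0],
                "y_deg": locs[:, 1],
                "alpha_log": self.threshold_log,
                "beta": self.slope,
                "sensitivity_log": self.sensitivity_log,
                "n_trials_in_radius": self.n_trials,
                "fit_status": self.fit_status,
            }
        )


def conventional_map(estimates: pd.DataFrame, grid: TestGrid) -> ThresholdMap:
    """Sensitivity at nominal locations: -threshold_log, no interpolation.

    ``estimates`` carries loc_id and threshold_log for the grid's locations;
    missing locations are flagged with status ``"missing"`` (NaN threshold),
    never silently dropped.
    """
    n = len(grid.locations)
    thr = np.full(n, np.nan)
    status = np.full(n, "missing", dtype=object)
    ids = estimates["loc_id"].to_numpy()
    if np.any(ids < 0) or np.any(ids >= n):
        raise ValueError("estimate loc_id outside grid")
    thr[ids] = estimates["threshold_log"].to_numpy()
    status[ids] = "ok"
    return ThresholdMap(
        lattice=grid,
        threshold_log=thr,
        slope=np.full(n, np.nan),
        n_trials=np.where(status == "ok", 6, 0),
        fit_status=status,
    )


def gaussian_kernel_weight(distance: float, kernel_sd: float = 0.5) -> float:
    """Relative weight of a presentation at the given distance from the
    estimation point: exp(-d^2 / (2 sd^2)); 1 at distance 0, exp(-0.5) at
    one SD (the 0.5 deg inclusion cutoff)."""
    return float(np.exp(-(distance**2) / (2.0 * kernel_sd**2)))


class FitResult(NamedTuple):
    alpha: float   # NaN if undefined
    beta: float
    n_trials: int
    status: str    # ok | boundary | insufficient | no_converge


def _weighted_nll(
    params: np.ndarray,
    contrasts: np.ndarray,
    responses: np.ndarray,
    weights: np.ndarray,
    gamma: float,
    lam: float,
) -> float:
    alpha, beta = params
    with np.errstate(over="ignore", under="ignore"):
        t = np.power(10.0, (contrasts - alpha) * beta)
        psi = gamma + (1.0 - gamma - lam) * (1.0 - np.exp2(-t))
    # psi in [gamma, 1-lam] with gamma, lam > 0, so the logs are finite.
    ll = weights * (responses * np.log(psi) + (1.0 - responses) * np.log(1.0 - psi))
    return -float(ll.sum())


_BETA_BOUNDS = (0.5, 20.0)


def weighted_ml_fit(
    xy: np.ndarray,
    contrasts: np.ndarray,
    responses: np.ndarray,
    point: FieldLocation,
    radius: float = 0.5,
    kernel_sd: float = 0.5,
    gamma: float = 0.02,
    lam: float = 0.02,
    min_trials: int = 4,
    alpha_bounds: tuple[float, float] = (-1.2, 0.9),
    beta_bounds: tuple[float, float] = _BETA_BOUNDS,
) -> FitResult:
    """Weighted ML Quick-Weibull fit of (alpha, beta) at one estimation point.

    Presentations with inferred location within ``radius`` of ``point`` enter
    the fit, weighted by a Gaussian kernel of SD ``kernel_sd`` on Euclidean
    distance (the kernel is truncated at the inclusion radius).  Returns an
    undefined fit (``status="insufficient"``) when fewer than ``min_trials``
    fall inside the radius, and ``status="boundary"`` when the threshold
    estimate is pinned at an alpha bound (e.g. an all-seen neighborhood,
    which carries no crossing information).  Optimizer failure yields
    ``status="no_converge"``, never an exception.
    """
    if radius <= 0 or kernel_sd <= 0:
        raise ValueError("radius and kernel_sd must be > 0")
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    d = np.hypot(xy[:, 0] - point.x, xy[:, 1] - point.y)
    inside = d <= radius
    n_in = int(inside.sum())
    if n_in < min_trials:
        return FitResult(np.nan, np.nan, n_in, "insufficient")
    c = np.asarray(contrasts, dtype=float)[inside]
    r = np.asarray(responses, dtype=float)[inside]
    w = np.exp(-(d[inside] ** 2) / (2.0 * kernel_sd**2))

    args = (c, r, w, gamma, lam)
    c_lo, c_hi = float(c.min()), float(c.max())
    starts = [
        (np.clip(c_lo, *alpha_bounds), 2.0),
        (np.clip(c_hi, *alpha_bounds), 2.0),
        (np.clip(0.5 * (c_lo + c_hi), *alpha_bounds), 6.0),
        (np.clip(float(np.average(c, weights=w)), *alpha_bounds), 3.5),
    ]
    best = None
    for x0 in starts:
        try:
            res = optimize.minimize(
                _weighted_nll, x0=np.asarray(x0), args=args,
                method="L-BFGS-B", bounds=[alpha_bounds, beta_bounds],
            )
        except Exception:
            continue
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        # coarse grid-search fallback over the bounded box
        aa = np.linspace(*alpha_bounds, 43)
        bb = np.geomspace(*beta_bounds, 16)
        vals = np.array([[_weighted_nll(np.array([a, b]), *args) for b in bb] for a in aa])
        if not np.isfinite(vals).any():
            return FitResult(np.nan, np.nan, n_in, "no_converge")
        ia, ib = np.unravel_index(np.nanargmin(vals), vals.shape)
        alpha, beta = float(aa[ia]), float(bb[ib])
    else:
        alpha, beta = float(best.x[0]), float(best.x[1])
    tol = 1e-6
    at_bound = alpha <= alpha_bounds[0] + tol or alpha >= alpha_bounds[1] - tol
    return FitResult(alpha, beta, n_in, "boundary" if at_bound else "ok")


@dataclass
class MlMapSettings:
    """Settings for the locally weighted ML threshold map."""

    radius: float = 0.5
    kernel_sd: float = 0.5
    gamma: float = 0.02
    lam: float = 0.02
    min_trials: int = 4
    alpha_bounds: tuple[float, float] = (-1.2, 0.9)
    beta_bounds: tuple[float, float] = _BETA_BOUNDS
    location_columns: tuple[str, str] = ("inferred_x_deg", "inferred_y_deg")


def ml_threshold_map(
    trials: pd.DataFrame,
    lattice: TestGrid,
    settings: Optional[MlMapSettings] = None,
) -> ThresholdMap:
    """Evaluate :func:`weighted_ml_fit` at every lattice point.

    ``trials`` are valid presentations with inferred retinal locations
    (columns from ``settings.location_columns``; set them to the nominal
    columns for data without gaze frames), log_contrast, and seen.  Points
    with undefined fits appear as NaN gaps with a diagnostic status.
    """
    s = settings or MlMapSettings()
    n = len(lattice.locations)
    thr = np.full(n, np.nan)
    slope = np.full(n, np.nan)
    ntr = np.zeros(n, dtype=int)
    status = np.full(n, "insufficient", dtype=object)
    if len(trials) == 0:
        return ThresholdMap(lattice, thr, slope, ntr, status)
    xcol, ycol = s.location_columns
    xy = trials[[xcol, ycol]].to_numpy(dtype=float)
    contrasts = trials["log_contrast"].to_numpy(dtype=float)
    responses = trials["seen"].to_numpy(dtype=float)
    tree = cKDTree(xy)
    neighbor_lists = tree.query_ball_point(lattice.locations, r=s.radius)
    for i, idx in enumerate(neighbor_lists):
        if len(idx) < s.min_trials:
            ntr[i] = len(idx)
            continue
        idx = np.asarray(idx)
        res = weighted_ml_fit(
            xy[idx], contrasts[idx], responses[idx],
            FieldLocation(*lattice.locations[i]),
            radius=s.radius, kernel_sd=s.kernel_sd, gamma=s.gamma, lam=s.lam,
            min_trials=s.min_trials, alpha_bounds=s.alpha_bounds,
            beta_bounds=s.beta_bounds,
        )
        thr[i], slope[i], ntr[i], status[i] = res.alpha, res.beta, res.n_trials, res.status
    return ThresholdMap(lattice, thr, slope, ntr, status)


@dataclass(frozen=True)
class SliceSelection:
    """Partition of the valid trials at one display threshold C0.

    crossover_seen: contrast strictly below C0 yet the subject responded;
    crossover_notseen: contrast at or above C0 yet no response; concordant:
    everything else.  The three subsets are disjoint and exhaustive.
    """

    display_threshold: float
    trials: pd.DataFrame = field(repr=False)  # adds a 'subset' column

    @property
    def crossover_seen(self) -> pd.DataFrame:
        return self.trials[self.trials["subset"] == "crossover_seen"]

    @property
    def crossover_notseen(self) -> pd.DataFrame:
        return self.trials[self.trials["subset"] == "crossover_notseen"]

    @property
    def concordant(self) -> pd.DataFrame:
        return self.trials[self.trials["subset"] == "concordant"]

    def counts(self) -> dict:
        c = self.trials["subset"].value_counts().to_dict()
        return {
            "display_threshold": float(self.display_threshold),
            "crossover_seen": int(c.get("crossover_seen", 0)),
            "crossover_notseen": int(c.get("crossover_notseen", 0)),
            "concordant": int(c.get("concordant", 0)),
        }


def slice_select(trials: pd.DataFrame, display_threshold: float) -> SliceSelection:
    """Partition trials into crossover and concordant subsets at C0.

    The boundary is exact: strictly-less for crossover seen trials,
    at-or-above (inclusive) for crossover not-seen trials.
    """
    out = trials.copy()
    c = out["log_contrast"].to_numpy(dtype=float)
    seen = out["seen"].to_numpy(dtype=bool)
    subset = np.full(len(out), "concordant", dtype=object)
    subset[(c < display_threshold) & seen] = "crossover_seen"
    subset[(c >= display_threshold) & ~seen] = "crossover_notseen"
    out["subset"] = subset
    out["display_threshold"] = display_threshold
    return SliceSelection(display_threshold=float(display_threshold), trials=out)


def slice_sweep(
    trials: pd.DataFrame,
    start: float = 0.5,
    stop: float = -0.5,
    step: float = -0.01,
) -> list[SliceSelection]:
    """Sweep the display threshold over an inclusive range.

    Defaults reproduce the study sweep: 0.5 down to -0.5 log units in steps
    of -0.01, i.e. 101 selections.
    """
    if step == 0:
        raise ValueError("step must be nonzero")
    if (stop - start) * step < 0:
        raise ValueError("step direction inconsistent with start/stop")
    n = int(round((stop - start) / step)) + 1
    thresholds = start + step * np.arange(n)
    return [slice_select(trials, float(np.round(c0, 10))) for c0 in thresholds]


def render_map(
    tmap: ThresholdMap,
    path: str,
    relative_to: float = 0.0,
    vmin: float = DISPLAY_RANGE_LOG[0],
    vmax: float = DISPLAY_RANGE_LOG[1],
) -> None:
    """Render a sensitivity map as a PNG (diverging palette over the fixed
    relative display range; red = less sensitive, blue = more sensitive).
    Rendering is a thin layer — the CSV/JSON outputs are the contract."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = tmap.lattice
    sens = np.clip(tmap.sensitivity_log - relative_to, vmin, vmax)
    img = sens.reshape(g.n_y, g.n_x)
    fig, ax = plt.subplots(figsize=(6, 6 * g.n_y / max(g.n_x, 1)))
    m = ax.imshow(
        img, origin="lower", cmap="RdYlBu", vmin=vmin, vmax=vmax,
        extent=[g.x_min, g.x_max, g.y_min, g.y_max], aspect="equal",
    )
    fig.colorbar(m, ax=ax, label="relative log sensitivity")
    ax.set_xlabel("x (deg, temporal +)")
    ax.set_ylabel("y (deg, superior +)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
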