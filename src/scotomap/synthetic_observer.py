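"""Synthetic observers: ground-truth sensitivity surfaces and full sessions.

The surface emulates the temporal visual field of a healthy right eye around
the optic nerve head: a uniform baseline threshold, a deep elliptical
blind-spot scotoma (unseeable at any ladder contrast), and narrow, shallow
angioscotomas — depressions about half a degree wide and ~0.3 log units
deep cast by retinal vessels leaving the disc.

The session simulator drives the ZEST procedure against this surface while
emulating fixational eye movement: per-trial drift, occasional
microsaccades that make the three eye-position frames disagree (triggering
the downstream 0.5 deg exclusion rule), and blinks that obscure a frame.
It emits the same trial/gaze CSV contracts the analysis modules consume,
plus a ground-truth record including the true per-trial displacement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from scotomap.field_geometry import FieldLocation, TestGrid
from scotomap.gaze_filter import PIXEL_SCALE_ARCMIN
from scotomap.psychometrics import (
    PsychometricParams,
    ZestConfig,
    detection_probability,
    zest_estimate,
    zest_init,
    zest_next_stimulus,
    zest_update,
)

__all__ = [
    "Ellipse",
    "Vessel",
    "SensitivitySurface",
    "EyeMovementModel",
    "SessionResult",
    "surface_alpha",
    "simulate_session",
    "make_paper_like_subject",
]


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse (degrees): the blind-spot outline."""

    center_x: float
    center_y: float
    semi_x: float
    semi_y: float

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return ((x - self.center_x) / self.semi_x) ** 2 + (
            (y - self.center_y) / self.semi_y
        ) ** 2 <= 1.0


@dataclass(frozen=True)
class Vessel:
    """A retinal vessel shadow: a polyline with width and depression depth.

    The threshold elevation has a Gaussian cross-section across the
    polyline with scale ``width / 2``, so the full width of the depression
    is about the vessel width (default 0.5 deg, depth 0.3 log units);
    ``profile="rect"`` gives a hard-edged shadow instead.
    """

    path: np.ndarray  # (m, 2) polyline vertices, degrees
    width: float = 0.5
    depth: float = 0.3
    profile: str = "gaussian"

    def elevation(self, x, y) -> np.ndarray:
        d = self.distance(x, y)
        if self.profile == "gaussian":
            return self.depth * np.exp(-(d**2) / (2.0 * (self.width / 2.0) ** 2))
        if self.profile == "rect":
            return np.where(d <= self.width / 2.0, self.depth, 0.0)
        raise ValueError(f"unknown vessel profile {self.profile!r}")

    def distance(self, x, y) -> np.ndarray:
        """Euclidean distance from (x, y) to the polyline (vectorized)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        p = np.column_stack([x, y])[:, None, :]            # (n, 1, 2)
        a = self.path[:-1][None, :, :]                     # (1, m-1, 2)
        b = self.path[1:][None, :, :]
        ab = b - a
        denom = (ab**2).sum(-1)
        t = np.clip(((p - a) * ab).sum(-1) / np.where(denom > 0, denom, 1.0), 0, 1)
        proj = a + t[..., None] * ab
        d = np.sqrt(((p - proj) ** 2).sum(-1)).min(axis=1)
        return d


@dataclass(frozen=True)
class SensitivitySurface:
    """Ground-truth log-threshold field alpha(x, y) over the test region."""

    baseline_alpha: float = -0.35
    blind_spot: Optional[Ellipse] = None
    vessels: tuple = ()
    beta_field: float = 3.5
    gamma: float = 0.02
    lam: float = 0.02

    def params_at(self, x: float, y: float) -> PsychometricParams:
        return PsychometricParams(
            alpha=float(surface_alpha(self, x, y)),
            beta=self.beta_field, gamma=self.gamma, lam=self.lam,
        )

    def to_dict(self) -> dict:
        d = {
            "baseline_alpha": self.baseline_alpha,
            "beta_field": self.beta_field,
            "gamma": self.gamma,
            "lam": self.lam,
            "blind_spot": asdict(self.blind_spot) if self.blind_spot else None,
            "vessels": [
                {"path": v.path.tolist(), "width": v.width, "depth": v.depth,
                 "profile": v.profile}
                for v in self.vessels
            ],
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SensitivitySurface":
        bs = Ellipse(**d["blind_spot"]) if d.get("blind_spot") else None
        vessels = tuple(
            Vessel(path=np.asarray(v["path"], dtype=float), width=v["width"],
                   depth=v["depth"], profile=v.get("profile", "gaussian"))
            for v in d.get("vessels", ())
        )
        return cls(
            baseline_alpha=d["baseline_alpha"], blind_spot=bs, vessels=vessels,
            beta_field=d["beta_field"], gamma=d["gamma"], lam=d["lam"],
        )


def surface_alpha(surface: SensitivitySurface, x, y) -> np.ndarray:
    """Ground-truth log threshold at (x, y); ``inf`` inside the blind spot.

    Threshold elevations from overlapping vessels add; everything is
    deterministic in the coordinates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    scalar = x.ndim == 0 and y.ndim == 0
    alpha = np.full(np.broadcast(x, y).shape or (1,), surface.baseline_alpha)
    for v in surface.vessels:
        alpha = alpha + v.elevation(x, y)
    if surface.blind_spot is not None:
        inside = np.atleast_1d(surface.blind_spot.contains(x, y))
        alpha = np.where(inside, np.inf, alpha)
    return float(alpha[0]) if scalar else alpha


@dataclass(frozen=True)
class EyeMovementModel:
    """Fixational eye movement and frame-corruption model.

    Within a trial the eye displacement is constant across the three frames
    unless a microsaccade fires mid-trial, in which case the frames after
    its onset jump — producing the inter-frame disagreement the exclusion
    rules are designed to catch.  Microsaccade occurrence per trial is
    rate x window (0.8/s x 120 ms ~ 10%).
    """

    drift_sd: float = 0.15                 # deg, per-axis SD of per-trial drift
    microsaccade_rate: float = 0.8         # per second
    microsaccade_amplitude_sd: float = 0.4 # deg, per-axis SD of the jump
    blink_prob: float = 0.05               # per trial
    frame_interval_ms: float = 40.0
    frames_per_trial: int = 3

    def __post_init__(self):
        if min(self.drift_sd, self.microsaccade_rate,
               self.microsaccade_amplitude_sd, self.blink_prob) < 0:
            raise ValueError("eye-movement rates must be >= 0")
        if self.frames_per_trial != 3:
            raise ValueError("the acquisition protocol uses exactly 3 frames")

    @property
    def window_s(self) -> float:
        return self.frames_per_trial * self.frame_interval_ms / 1000.0


@dataclass
class SessionResult:
    trials: pd.DataFrame
    gaze: pd.DataFrame
    estimates: pd.DataFrame
    truth: dict

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(out / "trials.csv", index=False, float_format="%.6g")
        self.gaze.to_csv(out / "gaze.csv", index=False, float_format="%.6g")
        self.estimates.to_csv(out / "thresholds.csv", index=False, float_format="%.6g")
        (out / "truth.json").write_text(json.dumps(self.truth, indent=1))


def simulate_session(
    surface: SensitivitySurface,
    grid: TestGrid,
    eye_model: Optional[EyeMovementModel] = None,
    zest_config: Optional[ZestConfig] = None,
    seed: int = 0,
) -> SessionResult:
    """Simulate a full ZEST session with fixational eye movement.

    For each presentation a per-trial drift displacement is drawn; the
    response is drawn from the frequency-of-seeing curve at the *displaced*
    retinal location (nominal + displacement).  Three gaze frames are
    emitted per trial; blinks blank a random frame and mid-trial
    microsaccades shift the later frames.  All randomness flows from
    ``seed``, so identical seeds give identical outputs.
    """
    em = eye_model or EyeMovementModel()
    cfg = zest_config or ZestConfig()
    rng = np.random.default_rng(seed)
    px = 60.0 / PIXEL_SCALE_ARCMIN  # pixels per degree

    p_saccade = em.microsaccade_rate * em.window_s
    trial_rows, gaze_rows, est_rows = [], [], []
    true_disp = {}
    trial_id = 0
    for loc_id, loc in enumerate(grid):
        state = zest_init(cfg.ladder, cfg.prior, cfg.n_presentations)
        for _ in range(cfg.n_presentations):
            contrast = zest_next_stimulus(state, cfg.placement)
            drift = rng.normal(0.0, em.drift_sd, 2) if em.drift_sd > 0 else np.zeros(2)
            frames = np.tile(drift, (3, 1))
            if p_saccade > 0 and rng.random() < p_saccade:
                onset = int(rng.integers(1, 3))  # frame index where the jump lands
                jump = rng.normal(0.0, em.microsaccade_amplitude_sd, 2)
                frames[onset:] += jump
            blink_frame = int(rng.integers(0, 3)) if (
                em.blink_prob > 0 and rng.random() < em.blink_prob
            ) else -1

            landed = FieldLocation(loc.x + drift[0], loc.y + drift[1])
            p_seen = detection_probability(surface.params_at(*landed), contrast)
            seen = bool(rng.random() < p_seen)
            state = zest_update(state, contrast, seen, cfg.likelihood())

            trial_rows.append(
                dict(trial_id=trial_id, loc_id=loc_id, nominal_x_deg=loc.x,
                     nominal_y_deg=loc.y, log_contrast=contrast, seen=seen,
                     is_catch=False, block_id=loc_id % cfg.n_blocks))
            for fi in range(3):
                if fi == blink_frame:
                    gaze_rows.append(
                        dict(trial_id=trial_id, frame_idx=fi + 1, dx_px=np.nan,
                             dy_px=np.nan, missing_reason="blink"))
                else:
                    gaze_rows.append(
                        dict(trial_id=trial_id, frame_idx=fi + 1,
                             dx_px=frames[fi, 0] * px, dy_px=frames[fi, 1] * px,
                             missing_reason="none"))
            true_disp[trial_id] = [float(drift[0]), float(drift[1])]
            trial_id += 1
        est_rows.append(
            dict(loc_id=loc_id, x_deg=loc.x, y_deg=loc.y,
                 threshold_log=zest_estimate(state), n_trials=state.n_presented))

    truth = {
        "surface": surface.to_dict(),
        "eye_model": asdict(em),
        "seed": int(seed),
        "true_displacement_deg": true_disp,
    }
    return SessionResult(
        trials=pd.DataFrame(trial_rows),
        gaze=pd.DataFrame(gaze_rows),
        estimates=pd.DataFrame(est_rows),
        truth=truth,
    )


def _arc(p0, p1, bulge, n=24) -> np.ndarray:
    """Quadratic Bezier polyline from p0 to p1 bowed sideways by ``bulge``."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    mid = 0.5 * (p0 + p1)
    d = p1 - p0
    normal = np.array([-d[1], d[0]])
    nrm = np.linalg.norm(normal)
    ctrl = mid + bulge * normal / (nrm if nrm > 0 else 1.0)
    t = np.linspace(0, 1, n)[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * ctrl + t**2 * p1


def make_paper_like_subject(seed: int = 0) -> SensitivitySurface:
    """A default synthetic subject mimicking the study region's anatomy.

    A blind-spot ellipse centered near (15, 1.5) deg with semi-axes around
    (2.5, 3.5) deg, and three vessel shadows (0.5 deg wide, 0.3 log units
    deep) arcing away from the disc across the 11-17 x -3-+6 deg region.
    Deterministic for a given seed; the seed jitters the geometry slightly.
    """
    rng = np.random.default_rng(seed)
    cx = 15.0 + rng.uniform(-0.2, 0.2)
    cy = 1.5 + rng.uniform(-0.2, 0.2)
    sx = 2.5 + rng.uniform(-0.15, 0.15)
    sy = 3.5 + rng.uniform(-0.15, 0.15)
    disc = Ellipse(cx, cy, sx, sy)
    # Superior and inferior arcades plus a nasal branch, leaving the disc edge.
    top = _arc((cx - 0.3, cy + sy - 0.3), (11.0, 5.5 + rng.uniform(-0.3, 0.3)), bulge=-0.8)
    bottom = _arc((cx - 0.3, cy - sy + 0.3), (11.0, -2.0 + rng.uniform(-0.3, 0.3)), bulge=0.8)
    nasal = _arc((cx - sx + 0.3, cy + rng.uniform(-0.3, 0.3)), (11.0, 1.0 + rng.uniform(-0.5, 0.5)), bulge=0.4)
    vessels = tuple(Vessel(path=p) for p in (top, bottom, nasal))
    return SensitivitySurface(blind_spot=disc, vessels=vessels)
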