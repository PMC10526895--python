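"""Quick-Weibull frequency-of-seeing model and the ZEST adaptive procedure.

The psychometric (frequency-of-seeing) function is Quick's form of the
Weibull,

    Psi(c) = gamma + (1 - gamma - lambda) * (1 - 2**(-(C / A)**beta)),

with C = 10**c the linear Weber contrast of the stimulus, A = 10**alpha the
linear threshold, beta the slope, gamma the false-positive (guess) rate and
lambda the false-negative (lapse) rate.  With gamma = lambda the function
passes through 0.5 exactly at c = alpha, matching the standard definition of
threshold as the contrast seen 50% of the time.

ZEST maintains a probability mass function over candidate thresholds (the
ladder levels), places each stimulus at the posterior mean (snapped to the
nearest ladder level), updates by Bayes' rule after each response, and
reports the posterior mean after a fixed number of presentations (six per
location in the study protocol).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from scotomap.field_geometry import ContrastLadder, FieldLocation, TestGrid, build_ladder

__all__ = [
    "PsychometricParams",
    "detection_probability",
    "ZestState",
    "ZestConfig",
    "zest_init",
    "zest_next_stimulus",
    "zest_update",
    "zest_estimate",
    "run_zest_session",
]


@dataclass(frozen=True)
class PsychometricParams:
    """Quick-Weibull parameters.

    alpha : log10 Weber contrast threshold (log units)
    beta  : slope (dimensionless, > 0)
    gamma : false-positive rate in [0, 1)
    lam   : false-negative (lapse) rate in [0, 1)
    """

    alpha: float
    beta: float = 3.5
    gamma: float = 0.02
    lam: float = 0.02

    def __post_init__(self):
        if not self.beta > 0:
            raise ValueError("beta must be > 0")
        if not (0 <= self.gamma < 1 and 0 <= self.lam < 1):
            raise ValueError("gamma and lam must be in [0, 1)")
        if self.gamma + self.lam >= 1:
            raise ValueError("gamma + lam must be < 1")


def detection_probability(params: PsychometricParams, contrast) -> Union[float, np.ndarray]:
    """Probability of reporting the stimulus at the given log contrast.

    Vectorized over ``contrast``.  An infinite ``alpha`` encodes an
    unseeable location (inside the blind spot): the probability is the
    false-positive floor ``gamma`` at any contrast.
    """
    contrast = np.asarray(contrast, dtype=float)
    with np.errstate(over="ignore", under="ignore"):
        # (C/A)**beta = 10**((c - alpha) * beta); overflow saturates to inf,
        # for which 2**-inf = 0 is the correct limit.
        t = np.power(10.0, (contrast - params.alpha) * params.beta)
        p = params.gamma + (1.0 - params.gamma - params.lam) * (1.0 - np.exp2(-t))
    if p.ndim == 0:
        return float(p)
    return p


def _psi_over_domain(domain: np.ndarray, contrast: float, params: PsychometricParams) -> np.ndarray:
    """Psi(contrast) for each candidate threshold in ``domain``."""
    with np.errstate(over="ignore", under="ignore"):
        t = np.power(10.0, (contrast - domain) * params.beta)
        return params.gamma + (1.0 - params.gamma - params.lam) * (1.0 - np.exp2(-t))


@dataclass(frozen=True)
class ZestState:
    """Posterior state of one ZEST run at one location."""

    domain: np.ndarray = field(repr=False)
    pdf: np.ndarray = field(repr=False)
    n_presented: int = 0
    history: tuple = ()
    max_presentations: int = 6

    @property
    def terminated(self) -> bool:
        return self.n_presented >= self.max_presentations


def zest_init(
    domain: Union[ContrastLadder, np.ndarray, Sequence[float]],
    prior: Union[str, np.ndarray, tuple] = "uniform",
    max_presentations: int = 6,
) -> ZestState:
    """Initialize a ZEST posterior over the ladder domain.

    ``prior`` may be ``"uniform"`` (default), an explicit weight vector, or
    ``("gaussian", mean, sd)`` for a broad Gaussian centered on a prior
    guess.  The pdf is always renormalized to sum to 1.
    """
    levels = domain.levels if isinstance(domain, ContrastLadder) else np.asarray(domain, dtype=float)
    if levels.size == 0:
        raise ValueError("ZEST domain must be non-empty")
    if isinstance(prior, str):
        if prior != "uniform":
            raise ValueError(f"unknown prior spec {prior!r}")
        pdf = np.full(levels.size, 1.0 / levels.size)
    elif isinstance(prior, tuple) and len(prior) == 3 and prior[0] == "gaussian":
        _, mean, sd = prior
        pdf = np.exp(-0.5 * ((levels - mean) / sd) ** 2)
        pdf /= pdf.sum()
    else:
        pdf = np.asarray(prior, dtype=float)
        if pdf.shape != levels.shape or np.any(pdf < 0) or pdf.sum() <= 0:
            raise ValueError("prior weights must be nonnegative and match the domain")
        pdf = pdf / pdf.sum()
    return ZestState(domain=levels, pdf=pdf, max_presentations=max_presentations)


def zest_estimate(state: ZestState) -> float:
    """Threshold estimate: the mean of the current pdf over the domain."""
    return float(np.dot(state.pdf, state.domain))


def zest_next_stimulus(state: ZestState, placement: str = "mean") -> float:
    """Next stimulus contrast: posterior mean (or mode) snapped to the ladder.

    Ties snap toward the lower contrast; deterministic given the state.
    """
    if state.terminated:
        raise ValueError("ZEST run already terminated")
    if placement == "mean":
        target = zest_estimate(state)
    elif placement == "mode":
        target = float(state.domain[int(np.argmax(state.pdf))])
    else:
        raise ValueError(f"unknown placement rule {placement!r}")
    d = np.abs(state.domain - target)
    idx = int(np.flatnonzero(d <= d.min() + 1e-12)[0])
    return float(state.domain[idx])


def zest_update(
    state: ZestState,
    contrast: float,
    seen: bool,
    likelihood_params: PsychometricParams,
) -> ZestState:
    """Bayes update of the threshold pdf after one response.

    The likelihood of a *seen* response under candidate threshold ``a`` is
    Psi(contrast | alpha=a); of a *not seen* response, 1 - Psi.
    """
    if state.terminated:
        raise ValueError("ZEST run already terminated")
    p_seen = _psi_over_domain(state.domain, contrast, likelihood_params)
    like = p_seen if seen else 1.0 - p_seen
    post = state.pdf * like
    z = post.sum()
    if not z > 0:
        raise ValueError("zero posterior mass in ZEST update")
    return replace(
        state,
        pdf=post / z,
        n_presented=state.n_presented + 1,
        history=state.history + ((float(contrast), bool(seen)),),
    )


ObserverCallback = Callable[[FieldLocation, float], bool]


@dataclass
class ZestConfig:
    """Session configuration for :func:`run_zest_session`.

    Timing fields (stimulus duration, mean inter-stimulus interval) are
    carried as metadata for downstream eye-movement simulation and are not
    enforced here.
    """

    ladder: ContrastLadder = field(default_factory=build_ladder)
    n_presentations: int = 6
    beta: float = 3.5
    gamma: float = 0.02
    lam: float = 0.02
    prior: Union[str, tuple] = "uniform"
    placement: str = "mean"
    catch_fp_rate: float = 0.0
    catch_fn_rate: float = 0.0
    n_blocks: int = 8
    stimulus_duration_ms: float = 60.0
    mean_isi_ms: float = 1200.0
    seed: Optional[int] = None

    def likelihood(self, alpha: float = 0.0) -> PsychometricParams:
        return PsychometricParams(alpha=alpha, beta=self.beta, gamma=self.gamma, lam=self.lam)


def run_zest_session(
    grid: TestGrid,
    observer: ObserverCallback,
    config: Optional[ZestConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run a full ZEST session over a test grid against an observer callback.

    The observer is called as ``observer(location, log_contrast) -> bool``
    once per threshold presentation (exactly ``n_presentations`` per grid
    location).  Optional catch trials — blank presentations probing false
    positives and maximum-contrast presentations probing false negatives —
    are inserted at the configured per-trial rates, recorded with
    ``is_catch=True``, and never fed to the ZEST posterior.

    Returns ``(trials, estimates)`` DataFrames.  Trial columns: trial_id,
    loc_id, nominal_x_deg, nominal_y_deg, log_contrast (NaN for blank catch
    trials), seen, is_catch, block_id.  Estimate columns: loc_id, x_deg,
    y_deg, threshold_log, n_trials.
    """
    cfg = config or ZestConfig()
    rng = np.random.default_rng(cfg.seed)
    trials: list[dict] = []
    estimates: list[dict] = []
    trial_id = 0
    for loc_id, loc in enumerate(grid):
        block_id = loc_id % cfg.n_blocks
        state = zest_init(cfg.ladder, cfg.prior, cfg.n_presentations)
        for _ in range(cfg.n_presentations):
            if cfg.catch_fp_rate > 0 and rng.random() < cfg.catch_fp_rate:
                trials.append(
                    dict(trial_id=trial_id, loc_id=loc_id, nominal_x_deg=loc.x,
                         nominal_y_deg=loc.y, log_contrast=np.nan,
                         seen=bool(rng.random() < cfg.gamma), is_catch=True,
                         block_id=block_id))
                trial_id += 1
            if cfg.catch_fn_rate > 0 and rng.random() < cfg.catch_fn_rate:
                c_max = cfg.ladder.max
                try:
                    seen = bool(observer(loc, c_max))
                except Exception as exc:  # pragma: no cover - passthrough context
                    raise RuntimeError(f"observer failed at {loc} (catch trial)") from exc
                trials.append(
                    dict(trial_id=trial_id, loc_id=loc_id, nominal_x_deg=loc.x,
                         nominal_y_deg=loc.y, log_contrast=c_max, seen=seen,
                         is_catch=True, block_id=block_id))
                trial_id += 1
            contrast = zest_next_stimulus(state, cfg.placement)
            try:
                seen = bool(observer(loc, contrast))
            except Exception as exc:
                raise RuntimeError(f"observer failed at {loc}, contrast {contrast}") from exc
            state = zest_update(state, contrast, seen, cfg.likelihood())
            trials.append(
                dict(trial_id=trial_id, loc_id=loc_id, nominal_x_deg=loc.x,
                     nominal_y_deg=loc.y, log_contrast=contrast, seen=seen,
                     is_catch=False, block_id=block_id))
            trial_id += 1
        estimates.append(
            dict(loc_id=loc_id, x_deg=loc.x, y_deg=loc.y,
                 threshold_log=zest_estimate(state), n_trials=state.n_presented))
    return pd.DataFrame(trials), pd.DataFrame(estimates)
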