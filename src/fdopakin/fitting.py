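"""Weighted nonlinear least-squares fitting, AICc model selection and Logan
graphical analysis of frame-binned time-activity curves.

The fit minimises Σᵢ wᵢ (TACᵢ − bin(model(θ))ᵢ)² over the model's free
parameters; the model curve is always binned with the TAC's own schedule
before residuals are formed, so the objective compares like with like.
Optimisation uses a bounded trust-region least-squares solver (the bounded
analogue of Levenberg–Marquardt), with a small multi-start jitter fallback
when the first attempt fails to converge.

Model comparison uses the small-sample-corrected Akaike criterion for
Gaussian residuals,

    AICc = n·ln(SS/n) + 2k + 2k(k+1)/(n − k − 1),

and Logan graphical analysis estimates the total distribution volume Vt as
the slope of the late linear segment of the Logan plot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from . import kinetic_models as km
from .input_function import InputFunction
from .kinetic_models import KineticParams
from .schedules import ContinuousCurve, SampledTAC, bin_curve

# Default initialisation and bounds (per-minute units). Multi-start jitters
# are log-normal perturbations of the initial point.
DEFAULT_INIT = {"K1": 0.1, "k2": 0.1, "k3": 0.05, "k4": 0.01, "VB": 0.05}
DEFAULT_BOUNDS = {"K1": (0.0, 2.0), "k2": (0.0, 2.0), "k3": (0.0, 2.0),
                  "k4": (0.0, 2.0), "VB": (0.0, 0.5)}
N_MULTISTART = 3
LOGAN_T_STAR_S = 600.0


class UnderdeterminedError(ValueError):
    """More free parameters than frames."""


class InsufficientPointsError(ValueError):
    """Too few usable points for a linear fit."""


class LoganDomainError(ValueError):
    """Non-positive tissue activity inside the Logan fit window."""


@dataclass(frozen=True)
class FitResult:
    """One model fitted to one TAC."""

    params: KineticParams
    ss: float              # weighted residual sum of squares
    n_frames: int
    n_params: int
    aicc: float
    converged: bool
    n_iter: int

    @property
    def model_id(self) -> str:
        return self.params.model_id


@dataclass(frozen=True)
class LoganResult:
    """Logan-plot linear fit over the late frames."""

    vt: float              # mL/ccm, slope
    intercept: float       # min
    t_star_s: float
    n_points: int
    r2: float


# ---------------------------------------------------------------------------
# nonlinear fitting

def fit_model(
    tac: SampledTAC,
    input_function: InputFunction,
    model_id: str = km.MODEL_1T2K,
    init: KineticParams | None = None,
    bounds: dict | None = None,
    weights: np.ndarray | str = "uniform",
    model_eval: str = "bin",
    max_nfev: int = 400,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Fit one compartment model to a frame-binned TAC.

    ``weights`` is either an explicit per-frame array, ``"uniform"`` or
    ``"duration"`` (wᵢ = frame duration, emphasising long late frames).

    ``model_eval`` chooses how the continuous model curve is reduced to
    frame values before residuals are formed:

    * ``"bin"`` (default) — time-average the model over each frame, the
      same reduction that produced the data; statistically consistent, so
      noiseless data refit exactly.
    * ``"midpoint"`` — sample the model at frame mid-times, the convention
      of conventional kinetic-analysis software. Cheap and adequate for
      slowly varying curves, but systematically wrong over the bolus peak
      when early frames are coarse — the very effect the schedule
      comparison experiment measures, which is why the Monte Carlo module
      fits in this mode.

    Non-convergence is reported via ``converged=False`` after exhausting
    the multi-start fallback, never raised.
    """
    if model_eval not in ("bin", "midpoint"):
        raise ValueError(f"unknown model_eval {model_eval!r}")
    n_free = km.N_PARAMS[model_id]
    n = tac.schedule.n_frames
    if n <= n_free:
        raise UnderdeterminedError(
            f"{n} frames cannot constrain {n_free} parameters"
        )
    w = _resolve_weights(weights, tac)
    sw = np.sqrt(w)
    duration = tac.schedule.total_duration_s
    free_names = km._FREE_PARAMS[model_id]
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    lo = np.array([b[name][0] for name in free_names])
    hi = np.array([b[name][1] for name in free_names])
    if init is None:
        theta0 = np.array([DEFAULT_INIT[name] for name in free_names])
    else:
        theta0 = km.as_model(init, model_id).free_values()
    theta0 = np.clip(theta0, lo + 1e-12, hi)

    mids = tac.frame_mid_s

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = KineticParams.from_free_values(model_id, theta)
        model = km.simulate(p, input_function, duration)
        if model_eval == "bin":
            pred = bin_curve(model, tac.schedule).values
        else:
            pred = model.interp(mids)
        return sw * (tac.values - pred)

    rng = rng or np.random.default_rng(0)
    best = None
    starts = [theta0]
    for _ in range(N_MULTISTART - 1):
        jitter = np.exp(rng.normal(0.0, 0.5, size=theta0.size))
        starts.append(np.clip(theta0 * jitter, lo + 1e-12, hi))
    for attempt, start in enumerate(starts):
        sol = least_squares(residuals, start, bounds=(lo, hi),
                            method="trf", max_nfev=max_nfev)
        converged = bool(sol.status > 0)
        ss = float(2.0 * sol.cost)
        cand = (not converged, ss, sol, converged)
        if best is None or cand[:2] < best[:2]:
            best = cand
        if converged and attempt == 0:
            break
    _, ss, sol, converged = best
    params = KineticParams.from_free_values(model_id, sol.x)
    score = aicc(max(ss, 1e-300), n, n_free) if n > n_free + 1 else np.inf
    return FitResult(params=params, ss=ss, n_frames=n, n_params=n_free,
                     aicc=score, converged=converged, n_iter=int(sol.nfev))


def _resolve_weights(weights, tac: SampledTAC) -> np.ndarray:
    if isinstance(weights, str):
        if weights == "uniform":
            return np.ones(tac.schedule.n_frames)
        if weights == "duration":
            return tac.durations_s.astype(float)
        raise ValueError(f"unknown weighting scheme {weights!r}")
    w = np.asarray(weights, dtype=float)
    if w.size != tac.schedule.n_frames or np.any(w < 0):
        raise ValueError("weights must be non-negative, one per frame")
    return w


# ---------------------------------------------------------------------------
# model scoring and selection

def aicc(ss: float, n: int, k: int) -> float:
    """Small-sample Akaike criterion for Gaussian residuals.

    ``n ln(SS/n) + 2k + 2k(k+1)/(n−k−1)``; requires n > k + 1 and SS > 0.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    if ss <= 0:
        raise ValueError("SS must be positive")
    return float(n * np.log(ss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1))


def select_model(fits: list[FitResult], tie_tol: float = 1e-9) -> FitResult:
    """Fit with minimal AICc; ties (|ΔAICc| < tol) go to fewer parameters."""
    if not fits:
        raise ValueError("no fits to select from")
    best_aicc = min(f.aicc for f in fits)
    tied = [f for f in fits if f.aicc - best_aicc < tie_tol]
    return min(tied, key=lambda f: f.n_params)


# ---------------------------------------------------------------------------
# Logan graphical analysis

def logan_vt(
    tac: SampledTAC,
    plasma: ContinuousCurve,
    t_star_s: float = LOGAN_T_STAR_S,
) -> LoganResult:
    """Total distribution volume from the Logan plot's late linear segment.

    Ordinary least squares of y = ∫₀ᵗ C dτ / C(t) against
    x = ∫₀ᵗ C_p dτ / C(t) over the frame midpoints with t ≥ ``t_star_s``;
    the slope is Vt (mL/ccm). For reversible single-tissue kinetics the
    relation is exactly linear with slope K1/k2 and intercept −1/k2.
    """
    mids = tac.frame_mid_s
    sel = mids >= t_star_s - 1e-9
    if int(sel.sum()) < 3:
        raise InsufficientPointsError(
            f"only {int(sel.sum())} frame midpoints at or after t*={t_star_s} s"
        )
    c = tac.values[sel]
    if np.any(c <= 0):
        raise LoganDomainError("non-positive TAC values inside the Logan window")
    cum_tac = tac.cumulative_at_mid()[sel]
    cum_plasma = np.interp(mids[sel], plasma.t_s, plasma.cumulative())
    x = cum_plasma / c / 60.0   # min: integral seconds·(kBq/mL) over kBq/mL
    y = cum_tac / c / 60.0
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return LoganResult(vt=float(slope), intercept=float(intercept),
                       t_star_s=t_star_s, n_points=int(sel.sum()), r2=r2)


def logan_auto_t_star(
    tac: SampledTAC,
    plasma: ContinuousCurve,
    max_rel_dev: float = 0.10,
    min_points: int = 3,
) -> LoganResult:
    """Logan fit with t* chosen automatically.

    Takes the earliest t* (scanning frame midpoints from late to early) such
    that every point in the tail window deviates from the window's own linear
    fit by at most ``max_rel_dev`` of the fitted value; the largest such
    window wins.
    """
    mids = tac.frame_mid_s
    best: LoganResult | None = None
    for i in range(tac.schedule.n_frames - min_points, -1, -1):
        t_star = float(mids[i])
        try:
            res = logan_vt(tac, plasma, t_star)
        except (InsufficientPointsError, LoganDomainError):
            continue
        sel = mids >= t_star - 1e-9
        c = tac.values[sel]
        y = tac.cumulative_at_mid()[sel] / c / 60.0
        x = np.interp(mids[sel], plasma.t_s, plasma.cumulative()) / c / 60.0
        yhat = res.vt * x + res.intercept
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = np.abs((y - yhat) / np.where(yhat != 0, yhat, np.nan))
        if np.nanmax(dev) <= max_rel_dev:
            best = res
        else:
            break
    if best is None:
        raise InsufficientPointsError("no linear tail window found")
    return best
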