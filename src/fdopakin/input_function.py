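"""Plasma input functions: synthetic bolus generator and blood corrections.

The kinetic models need the concentration of unmetabolised tracer in arterial
plasma, C_p(t). In the imaging workflow this comes from an image-derived
input function (IDIF) drawn on a large artery, then corrected for

* hematocrit — the tracer is carried in plasma, so whole-blood activity is
  divided by (1 − Hct), and
* metabolites — only the parent fraction f(t) of plasma activity is still
  the tracer; f(t) declines from 1 toward a plateau as peripheral
  metabolism proceeds.

This module provides a synthetic whole-blood bolus generator (gamma-variate
first pass plus a bi-exponential recirculation tail) standing in for a
measured IDIF, the correction step, and the population-mean construction
used to build one representative input curve from many subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedules import GRID_STEP_S, ContinuousCurve

# Parent-fraction model f(t) = f_inf + (1 - f_inf) * exp(-lambda_pf * t):
# monoexponential decay from 1 toward a plateau f_inf. Defaults are plausible
# for an amino-acid tracer with peripheral O-methylation, not measured values.
PF_F_INF = 0.5
PF_LAMBDA_PER_MIN = 0.03

HEMATOCRIT_DEFAULT = 0.42

# Synthetic whole-blood bolus defaults (kBq/mL peak, seconds).
BOLUS_AMPLITUDE_KBQ_ML = 30.0
BOLUS_T_PEAK_S = 35.0
BOLUS_SHAPE = {
    "onset_s": 15.0,       # appearance time of activity in the artery
    "alpha": 3.0,          # gamma-variate shape (rise sharpness)
    "tail_fracs": (0.12, 0.08),          # tail amplitudes as fractions of peak
    "tail_lambdas_per_min": (0.5, 0.02),  # fast and slow tail decay rates
    "tail_rise_per_min": 3.0,            # recirculation appearance rate
}


class InputValidationError(ValueError):
    """Non-physical input-function parameters."""


def parent_fraction(t_s: np.ndarray, f_inf: float = PF_F_INF,
                    lambda_per_min: float = PF_LAMBDA_PER_MIN) -> np.ndarray:
    """Fraction of plasma activity that is unmetabolised tracer at time t.

    ``f(t) = f_inf + (1 - f_inf) * exp(-lambda * t)`` with t in seconds and
    lambda given per minute; bounded in (0, 1] and non-increasing for
    lambda >= 0.
    """
    if not (0.0 < f_inf <= 1.0):
        raise InputValidationError(f"f_inf must be in (0, 1], got {f_inf}")
    if lambda_per_min < 0:
        raise InputValidationError("parent-fraction decay rate must be >= 0")
    t_min = np.asarray(t_s, dtype=float) / 60.0
    return f_inf + (1.0 - f_inf) * np.exp(-lambda_per_min * t_min)


@dataclass(frozen=True)
class InputFunction:
    """Whole-blood curve plus its metabolite/hematocrit-corrected plasma curve."""

    whole_blood: ContinuousCurve
    plasma_parent: ContinuousCurve
    hematocrit: float
    parent_fraction_params: tuple[float, float]  # (f_inf, lambda per min)

    def __post_init__(self) -> None:
        if not (0.0 <= self.hematocrit < 1.0):
            raise InputValidationError(
                f"hematocrit must be in [0, 1), got {self.hematocrit}"
            )
        if self.whole_blood.values.size != self.plasma_parent.values.size:
            raise InputValidationError("whole-blood and plasma grids differ")


def synth_bolus(
    amplitude_kbq_ml: float = BOLUS_AMPLITUDE_KBQ_ML,
    t_peak_s: float = BOLUS_T_PEAK_S,
    shape_params: dict | None = None,
    grid_step_s: float = GRID_STEP_S,
    duration_s: float = 1500.0,
) -> ContinuousCurve:
    """Synthetic arterial whole-blood bolus on the fine grid.

    Zero before ``onset_s``, a gamma-variate first pass peaking near
    ``t_peak_s``, and a slowly varying bi-exponential recirculation tail.
    The curve is rescaled at the end so its maximum equals
    ``amplitude_kbq_ml`` exactly.

    The raw (pre-rescaling) parameterisation, with t' = t − onset:

        g(t')    = (t'/tp)^alpha * exp(alpha * (1 − t'/tp))        (peak 1 at tp)
        tail(t') = sum_j a_j * (exp(−lam_j t') − exp(−mu t'))

    both of which integrate in closed form (incomplete-gamma and exponentials
    respectively), which the tests use as an analytic oracle.
    """
    if amplitude_kbq_ml <= 0:
        raise InputValidationError("amplitude must be positive")
    if not (0 < t_peak_s < duration_s):
        raise InputValidationError("peak time must lie inside the duration")
    p = dict(BOLUS_SHAPE)
    if shape_params:
        p.update(shape_params)
    if p["alpha"] <= 0 or p["tail_rise_per_min"] <= 0:
        raise InputValidationError("shape parameters must be positive")
    if any(lam <= 0 for lam in p["tail_lambdas_per_min"]):
        raise InputValidationError("tail decay rates must be positive")
    onset = float(p["onset_s"])
    if not (0 <= onset < t_peak_s):
        raise InputValidationError("onset must precede the peak")

    t = np.arange(0.0, duration_s + grid_step_s / 2, grid_step_s)
    raw = _raw_bolus(t, onset, t_peak_s, p)
    peak = raw.max()
    if peak <= 0:
        raise InputValidationError("degenerate bolus shape")
    return ContinuousCurve(values=raw * (amplitude_kbq_ml / peak),
                           grid_step_s=grid_step_s)


def _raw_bolus(t_s: np.ndarray, onset_s: float, t_peak_s: float, p: dict) -> np.ndarray:
    tp = t_peak_s - onset_s
    tprime = np.clip(t_s - onset_s, 0.0, None)
    alpha = float(p["alpha"])
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(
            tprime > 0,
            np.exp(alpha * (np.log(tprime / tp + 1e-300) + 1.0 - tprime / tp)),
            0.0,
        )
    mu = p["tail_rise_per_min"] / 60.0
    tail = np.zeros_like(tprime)
    for a, lam_min in zip(p["tail_fracs"], p["tail_lambdas_per_min"]):
        lam = lam_min / 60.0
        tail += a * (np.exp(-lam * tprime) - np.exp(-mu * tprime))
    tail[tprime <= 0] = 0.0
    return g + tail


def bolus_integral_closed_form(
    amplitude_kbq_ml: float,
    t_peak_s: float,
    shape_params: dict | None,
    duration_s: float,
    peak_scale: float,
) -> float:
    """Closed-form time integral of the synthetic bolus over [0, duration].

    ``peak_scale`` is the rescaling factor applied by :func:`synth_bolus`
    (amplitude / raw peak); pass ``amplitude / raw_max`` measured on the raw
    curve. Used as the analytic oracle for the grid integral.
    """
    from scipy.special import gammainc, gamma as gamma_fn

    p = dict(BOLUS_SHAPE)
    if shape_params:
        p.update(shape_params)
    onset = float(p["onset_s"])
    tp = t_peak_s - onset
    alpha = float(p["alpha"])
    T = duration_s - onset
    # ∫0^T (t/tp)^a e^{a(1-t/tp)} dt = e^a (tp/a)^{a+1} / tp^a * γ(a+1, aT/tp)
    g_int = (
        np.exp(alpha) * tp / alpha ** (alpha + 1)
        * gamma_fn(alpha + 1) * gammainc(alpha + 1, alpha * T / tp)
    )
    mu = p["tail_rise_per_min"] / 60.0
    tail_int = 0.0
    for a, lam_min in zip(p["tail_fracs"], p["tail_lambdas_per_min"]):
        lam = lam_min / 60.0
        tail_int += a * ((1 - np.exp(-lam * T)) / lam - (1 - np.exp(-mu * T)) / mu)
    return peak_scale * (g_int + tail_int)


def apply_corrections(
    whole_blood: ContinuousCurve,
    hematocrit: float = HEMATOCRIT_DEFAULT,
    pf_params: tuple[float, float] = (PF_F_INF, PF_LAMBDA_PER_MIN),
) -> InputFunction:
    """Metabolite- and hematocrit-correct a whole-blood curve.

    plasma_parent(t) = whole_blood(t) / (1 − Hct) · f(t) with f the parent
    fraction. Hct = 0 and f ≡ 1 make plasma_parent identical to whole blood.
    """
    if not (0.0 <= hematocrit < 1.0):
        raise InputValidationError(
            f"hematocrit must be in [0, 1), got {hematocrit}"
        )
    f_inf, lam = pf_params
    f = parent_fraction(whole_blood.t_s, f_inf, lam)
    plasma = ContinuousCurve(
        values=whole_blood.values / (1.0 - hematocrit) * f,
        grid_step_s=whole_blood.grid_step_s,
    )
    return InputFunction(
        whole_blood=whole_blood,
        plasma_parent=plasma,
        hematocrit=hematocrit,
        parent_fraction_params=(f_inf, lam),
    )


def population_mean_input(curves: list[ContinuousCurve],
                          grid_step_s: float = GRID_STEP_S) -> ContinuousCurve:
    """Pointwise mean of several input curves on a common fine grid.

    Curves are linearly resampled to the requested grid and truncated to the
    shortest duration before averaging — the construction used to form one
    representative arterial curve from a cohort.
    """
    if not curves:
        raise InputValidationError("need at least one curve")
    t_end = min(c.duration_s for c in curves)
    t = np.arange(0.0, t_end + grid_step_s / 2, grid_step_s)
    stack = np.vstack([c.interp(t) for c in curves])
    return ContinuousCurve(values=stack.mean(axis=0), grid_step_s=grid_step_s)
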