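"""Forward simulation of the three compartment models on the fine grid.

Models (tissue concentration C(t), plasma input C_p(t), fractional blood
volume VB):

* 1T2k+VB, reversible single tissue compartment:

      C(t) = VB·C_p(t) + (1 − VB)·K1·e^(−k2·t) ⊗ C_p(t)

* 2T3k+VB (irreversible, k4 = 0) and 2T4k+VB (reversible) two-tissue models:

      dC1/dt = K1·C_p − (k2 + k3)·C1 + k4·C2
      dC2/dt = k3·C1 − k4·C2
      C(t)   = VB·C_p(t) + (1 − VB)·(C1(t) + C2(t))

Rate constants are user-facing per-minute (K1 in mL/ccm/min, k2..k4 in
min⁻¹, matching how they are reported clinically) and converted to
per-second at this boundary. All convolutions are trapezoid-weighted
discrete convolutions on the 1-s grid, evaluated by an exact O(n)
recursion for exponential kernels; the same discretisation is the single
source of forward-model truth for both simulation and fitting, so
fit/simulate asymmetries cannot masquerade as schedule bias.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .input_function import InputFunction
from .schedules import ContinuousCurve

MODEL_1T2K = "1T2k+VB"
MODEL_2T3K = "2T3k+VB"
MODEL_2T4K = "2T4k+VB"
MODEL_IDS = (MODEL_1T2K, MODEL_2T3K, MODEL_2T4K)

#: free parameters per model (K1,k2,VB / +k3 / +k3,k4)
N_PARAMS = {MODEL_1T2K: 3, MODEL_2T3K: 4, MODEL_2T4K: 5}


class ParamError(ValueError):
    """Kinetic parameter outside its physical range."""


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of one compartment model, per-minute units."""

    model_id: str
    K1: float          # mL/ccm/min, blood -> tissue
    k2: float          # min^-1, tissue -> blood
    k3: float = 0.0    # min^-1, free -> bound pool (2T only)
    k4: float = 0.0    # min^-1, bound -> free pool (2T4k only)
    VB: float = 0.0    # fractional blood volume in [0, 1)

    def __post_init__(self) -> None:
        if self.model_id not in MODEL_IDS:
            raise ParamError(f"unknown model {self.model_id!r}")
        for name in ("K1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise ParamError(f"{name} must be >= 0")
        if not (0.0 <= self.VB <= 1.0):
            raise ParamError("VB must be in [0, 1]")
        if self.model_id == MODEL_1T2K and (self.k3 or self.k4):
            raise ParamError("1T2k+VB has no k3/k4")
        if self.model_id == MODEL_2T3K and self.k4:
            raise ParamError("2T3k+VB is irreversible: k4 = 0")

    @property
    def distribution_volume(self) -> float:
        """DV = K1/k2 of the single-tissue model (mL/ccm)."""
        if self.k2 <= 0:
            raise ParamError("DV undefined for k2 = 0")
        return self.K1 / self.k2

    def free_values(self) -> np.ndarray:
        order = _FREE_PARAMS[self.model_id]
        return np.array([getattr(self, name) for name in order])

    @classmethod
    def from_free_values(cls, model_id: str, theta: np.ndarray) -> "KineticParams":
        return cls(model_id=model_id,
                   **dict(zip(_FREE_PARAMS[model_id], np.asarray(theta, float))))


_FREE_PARAMS = {
    MODEL_1T2K: ("K1", "k2", "VB"),
    MODEL_2T3K: ("K1", "k2", "k3", "VB"),
    MODEL_2T4K: ("K1", "k2", "k3", "k4", "VB"),
}


# ---------------------------------------------------------------------------
# exponential convolution primitive

def exp_conv(values: np.ndarray, rate_per_s: float, step_s: float) -> np.ndarray:
    """Trapezoid-weighted discrete convolution of ``values`` with e^(−rate·t).

    Equals ``step · Σ_j w_j · values[j] · exp(−rate·(i−j)·step)`` with
    endpoint weights ½ (so y[0] = 0), computed by the exact recursion

        y[i+1] = e^(−rate·step)·y[i] + step/2·(values[i+1] + e^(−rate·step)·values[i])

    which is O(n) and bit-equivalent to the quadratic-cost sum.
    """
    from scipy.signal import lfilter

    v = np.asarray(values, dtype=float)
    a = float(np.exp(-rate_per_s * step_s))
    b = [0.5 * step_s, 0.5 * step_s * a]
    y = lfilter(b, [1.0, -a], v)
    # the filter seeds y[0] with b0·v[0]; the true convolution starts at 0
    y -= 0.5 * step_s * v[0] * a ** np.arange(v.size)
    return y


# ---------------------------------------------------------------------------
# model solutions

def simulate_1t2k_vb(params: KineticParams, input_function: InputFunction,
                     duration_s: float) -> ContinuousCurve:
    """Tissue curve of the reversible single-tissue model with blood volume."""
    if params.model_id != MODEL_1T2K:
        raise ParamError(f"expected {MODEL_1T2K}, got {params.model_id}")
    cp = _input_values(input_function, duration_s)
    step = input_function.plasma_parent.grid_step_s
    k1_s = params.K1 / 60.0
    k2_s = params.k2 / 60.0
    tissue = k1_s * exp_conv(cp, k2_s, step)
    return ContinuousCurve(
        values=params.VB * cp + (1.0 - params.VB) * tissue, grid_step_s=step
    )


def simulate_2t(params: KineticParams, input_function: InputFunction,
                duration_s: float) -> ContinuousCurve:
    """Tissue curve of the two-tissue model (irreversible when k4 = 0).

    Solved via the analytic bi-exponential impulse response

        h(t) = K1/(α2−α1) · [(k3+k4−α1)e^(−α1 t) + (α2−k3−k4)e^(−α2 t)]

    with α1,2 the eigen-rates of the two-compartment system, convolved with
    the input by the same trapezoid rule as the single-tissue model.
    """
    if params.model_id not in (MODEL_2T3K, MODEL_2T4K):
        raise ParamError(f"expected a two-tissue model, got {params.model_id}")
    cp = _input_values(input_function, duration_s)
    step = input_function.plasma_parent.grid_step_s
    k1, k2, k3, k4 = (params.K1 / 60.0, params.k2 / 60.0,
                      params.k3 / 60.0, params.k4 / 60.0)
    s = k2 + k3 + k4
    disc = max(s * s - 4.0 * k2 * k4, 0.0)
    root = np.sqrt(disc)
    a1 = 0.5 * (s - root)
    a2 = 0.5 * (s + root)
    if root > 1e-12 * max(s, 1e-30):
        c1 = k1 * (k3 + k4 - a1) / (a2 - a1)
        c2 = k1 * (a2 - k3 - k4) / (a2 - a1)
        tissue = c1 * exp_conv(cp, a1, step) + c2 * exp_conv(cp, a2, step)
    else:
        # degenerate repeated eigen-rate: h(t) = K1·(1 + (k3+k4−α)t)·e^(−αt);
        # realised by a central-difference limit of the generic branch
        eps = 1e-7 * max(a1, 1e-6)
        lo = exp_conv(cp, a1 - eps, step)
        hi = exp_conv(cp, a1 + eps, step)
        tissue = k1 * (0.5 * (lo + hi)
                       + (k3 + k4 - a1) * (lo - hi) / (2.0 * eps))
    return ContinuousCurve(
        values=params.VB * cp + (1.0 - params.VB) * tissue, grid_step_s=step
    )


def simulate(params: KineticParams, input_function: InputFunction,
             duration_s: float) -> ContinuousCurve:
    """Dispatch to the model named in ``params.model_id``."""
    if params.model_id == MODEL_1T2K:
        return simulate_1t2k_vb(params, input_function, duration_s)
    return simulate_2t(params, input_function, duration_s)


def _input_values(input_function: InputFunction, duration_s: float) -> np.ndarray:
    plasma = input_function.plasma_parent
    if plasma.duration_s + 1e-9 < duration_s:
        raise ParamError(
            f"input covers {plasma.duration_s} s, model needs {duration_s} s"
        )
    n = int(round(duration_s / plasma.grid_step_s)) + 1
    return plasma.values[:n]


def as_model(params: KineticParams, model_id: str) -> KineticParams:
    """Re-tag parameters under a (nesting-compatible) different model id."""
    kwargs = {"model_id": model_id}
    if model_id == MODEL_1T2K:
        return KineticParams(model_id=model_id, K1=params.K1, k2=params.k2,
                             VB=params.VB)
    if model_id == MODEL_2T3K:
        return KineticParams(model_id=model_id, K1=params.K1, k2=params.k2,
                             k3=params.k3, VB=params.VB)
    return replace(params, **kwargs)
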