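"""Two-state population-shift model for ligand dose-response.

The trigger's aptamer interconverts between a non-binding and a
binding-competent conformation, and only the competent one binds ligand:

    non-binding  <-- K -->  competent  <-- L/Kd -->  competent:ligand

with conformational equilibrium constant K = exp(-ddg_conf / rt) set by
the lower-stem penalty ddg_conf (kcal/mol), and ligand dissociation
constant Kd (molar). The fraction of triggers in a competent state
(free or ligand-bound) at ligand concentration L is

    f(L) = K (1 + L/Kd) / (1 + K (1 + L/Kd)),

rising from f(0) = K/(1+K) to 1 at saturation. The half-rise point has
the closed form EC50 = Kd (1 + K) / K: weaker stems (larger ddg_conf,
smaller K) shift the operational range to higher ligand concentrations.

Reporter output is affine in the competent fraction,

    r(L) = basal + span * (f(L) - f(0)) / (1 - f(0)),

which reduces exactly to a one-site binding curve in L with midpoint
EC50. A single dose-response curve therefore determines only the
combination Kd (1+K)/K, not Kd and K separately: fitting recovers one of
them with the other held fixed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .params import default_parameters

__all__ = [
    "TwoStateResponseModel",
    "DoseResponseCurve",
    "FitError",
    "fraction_active",
    "ec50",
    "predict_dose_response",
    "fit_two_state",
]

RT = default_parameters().rt  # kcal/mol at 37 C


class FitError(RuntimeError):
    """Dose-response fitting failed (degenerate or non-identifiable data)."""


@dataclass(frozen=True)
class TwoStateResponseModel:
    """Population-shift equilibrium parameters for one apta-trigger.

    ``ddg_conf`` is the free-energy penalty (kcal/mol) of the competent
    state, typically a stem variant's ddG plus a calibration offset
    (identity by default). ``basal`` and ``span`` are reporter output at
    zero ligand and the output amplitude, in arbitrary fluorescence units.
    """

    ddg_conf: float
    kd: float
    basal: float = 1.0
    span: float = 10.0

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError(f"kd must be positive, got {self.kd}")
        if self.basal < 0:
            raise ValueError(f"basal must be >= 0, got {self.basal}")
        if self.span <= 0:
            raise ValueError(f"span must be positive, got {self.span}")

    @property
    def k_conf(self) -> float:
        """Conformational equilibrium constant [competent]/[non-binding]."""
        return math.exp(-self.ddg_conf / RT)

    @classmethod
    def from_k_conf(cls, k_conf: float, kd: float, basal: float = 1.0,
                    span: float = 10.0) -> "TwoStateResponseModel":
        if k_conf <= 0:
            raise ValueError(f"k_conf must be positive, got {k_conf}")
        return cls(ddg_conf=-RT * math.log(k_conf), kd=kd, basal=basal, span=span)

    @property
    def fold_change(self) -> float:
        """(basal + span) / basal; infinite for basal = 0."""
        return math.inf if self.basal == 0 else (self.basal + self.span) / self.basal


@dataclass(frozen=True)
class DoseResponseCurve:
    concentrations: np.ndarray
    responses: np.ndarray
    ec50: float


def fraction_active(model: TwoStateResponseModel, conc) -> "float | np.ndarray":
    """Fraction of triggers in the binding-competent state at ligand conc."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("ligand concentration must be >= 0")
    k = model.k_conf
    x = k * (1.0 + conc / model.kd)
    f = x / (1.0 + x)
    return float(f) if f.ndim == 0 else f


def ec50(model: TwoStateResponseModel) -> float:
    """Ligand concentration at half-rise between f(0) and f(infinity).

    Closed form EC50 = Kd (1 + K) / K, cross-checked against numeric
    bisection in the test-suite. Emits a warning for degenerate models
    whose basal competent fraction already exceeds 0.99 (nothing left to
    switch).
    """
    k = model.k_conf
    f0 = k / (1.0 + k)
    if f0 > 0.99:
        warnings.warn(
            f"degenerate response model: f(0) = {f0:.4f} > 0.99, the trigger "
            "is almost fully competent without ligand",
            stacklevel=2,
        )
    return model.kd * (1.0 + k) / k


def predict_dose_response(
    model: TwoStateResponseModel, grid
) -> DoseResponseCurve:
    """Reporter output over a concentration grid (sorted, non-negative)."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("concentration grid must be non-empty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("concentration grid must be sorted ascending")
    f = fraction_active(model, grid)
    f0 = model.k_conf / (1.0 + model.k_conf)
    responses = model.basal + model.span * (f - f0) / (1.0 - f0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mid = ec50(model)
    return DoseResponseCurve(grid, responses, mid)


def _response(log_kd: float, log_k: float, basal: float, span: float,
              conc: np.ndarray) -> np.ndarray:
    # clamp to keep the degenerate (jointly free) fit from overflowing
    # while walking the Kd*(1+K)/K ridge
    kd = math.exp(min(max(log_kd, -60.0), 60.0))
    # |log K| <= 30 keeps 1 - f0 representable in double precision
    k = math.exp(min(max(log_k, -30.0), 30.0))
    x = k * (1.0 + conc / kd)
    f = x / (1.0 + x)
    f0 = k / (1.0 + k)
    return basal + span * (f - f0) / (1.0 - f0)


def fit_two_state(
    points: "list[tuple[float, float]]",
    fixed: dict | None = None,
    seed: int = 0,
) -> tuple[TwoStateResponseModel, dict]:
    """Least-squares fit of the two-state model to (conc, response) points.

    Requires >= 4 points spanning at least two decades of (positive)
    concentration. ``fixed`` may pin ``kd`` or ``k_conf``; with neither
    fixed only the compound midpoint Kd (1+K)/K is identifiable and the
    diagnostics flag the degeneracy. Deterministic for a fixed seed
    (seeded multi-start).
    """
    fixed = dict(fixed or {})
    unknown = set(fixed) - {"kd", "k_conf"}
    if unknown:
        raise ValueError(f"fixed accepts only 'kd'/'k_conf', got {sorted(unknown)}")
    conc = np.asarray([p[0] for p in points], dtype=float)
    resp = np.asarray([p[1] for p in points], dtype=float)
    if conc.size < 4:
        raise FitError("need at least 4 dose-response points")
    pos = conc[conc > 0]
    if pos.size < 2 or math.log10(pos.max() / pos.min()) < 2.0:
        raise FitError("concentrations must span at least two decades")
    if np.ptp(resp) <= 1e-12 * max(1.0, abs(resp).max()):
        raise FitError("all responses are equal; model is not identifiable")

    rng = np.random.default_rng(seed)
    span0 = max(np.ptp(resp), 1e-6)
    basal0 = float(resp.min())
    # crude midpoint guess: concentration nearest the half-rise
    half = basal0 + span0 / 2.0
    mid0 = float(pos[np.argmin(np.abs(resp[conc > 0] - half))])

    free: list[str] = []
    if "kd" not in fixed:
        free.append("log_kd")
    if "k_conf" not in fixed:
        free.append("log_k")
    free += ["basal", "span"]

    def unpack(theta: np.ndarray) -> tuple[float, float, float, float]:
        t = list(theta)
        log_kd = math.log(fixed["kd"]) if "kd" in fixed else t.pop(0)
        log_k = math.log(fixed["k_conf"]) if "k_conf" in fixed else t.pop(0)
        basal, span = t
        return log_kd, log_k, basal, span

    def residuals(theta: np.ndarray) -> np.ndarray:
        log_kd, log_k, basal, span = unpack(theta)
        return _response(log_kd, log_k, basal, span, conc) - resp

    best = None
    for start in range(4):
        theta0 = []
        jitter = 0.0 if start == 0 else rng.normal(0.0, 0.5)
        if "kd" not in fixed:
            k_guess = fixed.get("k_conf", 1.0)
            theta0.append(math.log(mid0 * k_guess / (1.0 + k_guess)) + jitter)
        if "k_conf" not in fixed:
            if "kd" in fixed:
                # midpoint = kd (1+K)/K  =>  K = kd / (mid - kd)
                ratio = max(mid0 / fixed["kd"] - 1.0, 1e-3)
                theta0.append(math.log(1.0 / ratio) + jitter)
            else:
                theta0.append(0.0 + jitter)
        theta0 += [basal0, span0]
        res = least_squares(residuals, np.asarray(theta0), method="lm",
                            max_nfev=2000)
        if best is None or res.cost < best.cost - 1e-15:
            best = res
    assert best is not None

    log_kd, log_k, basal, span = unpack(best.x)
    if span <= 0:
        raise FitError("fit collapsed to non-positive span; data not switch-like")
    model = TwoStateResponseModel(
        ddg_conf=-RT * log_k, kd=math.exp(log_kd), basal=max(basal, 0.0), span=span
    )
    # Gauss-Newton covariance approximation
    jac = best.jac
    dof = max(conc.size - len(best.x), 1)
    s2 = 2.0 * best.cost / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
    except np.linalg.LinAlgError:
        cov = np.full((len(best.x), len(best.x)), np.nan)
    diagnostics = {
        "residual_norm": float(np.sqrt(2.0 * best.cost)),
        "covariance": cov,
        "free_parameters": free,
        "identifiable": bool(fixed),
        "n_points": int(conc.size),
    }
    return model, diagnostics
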