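"""1:1 Langmuir binding-kinetics utilities.

The binding of a soluble analyte A to an immobilized ligand B is modeled as
single-site reversible binding, A + B <-> AB, with association rate ``ka``
(1/(M s)), dissociation rate ``kd`` (1/s) and affinity ``KD = kd/ka`` (M).
During association at analyte concentration C the response follows

    R(t) = Req * (1 - exp(-(ka*C + kd) * t)),   Req = Rmax * C / (C + KD)

and after the injection stops at ``t_assoc`` the complex decays as

    R(t) = R(t_assoc) * exp(-kd * (t - t_assoc)).

``fit_1to1`` estimates (ka, kd, Rmax) by nonlinear least squares jointly over
sensorgrams at several concentrations, which is the standard global-fit
protocol for surface plasmon resonance data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .types import KineticParams, ParameterError, Sensorgram

__all__ = ["kd_from_rates", "langmuir_response", "fit_1to1", "FitDiagnostics"]


def kd_from_rates(ka: float, kd: float) -> float:
    """Equilibrium dissociation constant KD = kd / ka, in molar units."""
    if ka <= 0:
        raise ParameterError("ka: must be positive")
    if kd < 0:
        raise ParameterError("kd: must be >= 0")
    return kd / ka


def langmuir_response(t: np.ndarray, conc: float, ka: float, kd: float,
                      Rmax: float, t_assoc: float) -> np.ndarray:
    """Noise-free 1:1 model response at times ``t`` (association then
    dissociation; ``t`` may span both phases)."""
    t = np.asarray(t, dtype=float)
    kobs = ka * conc + kd
    req = Rmax * ka * conc / kobs  # == Rmax * C / (C + KD)
    r_assoc = req * (1.0 - np.exp(-kobs * np.minimum(t, t_assoc)))
    r_end = req * (1.0 - np.exp(-kobs * t_assoc))
    r = np.where(t <= t_assoc, r_assoc,
                 r_end * np.exp(-kd * np.maximum(t - t_assoc, 0.0)))
    return r


@dataclass
class FitDiagnostics:
    rms_residual: float
    condition_number: float
    ill_conditioned: bool
    n_points: int
    success: bool
    message: str = ""
    per_curve_rms: list[float] = field(default_factory=list)


def _initial_guess(sensorgrams: list[Sensorgram]) -> tuple[float, float, float]:
    """Heuristic start: kd from the log-linear dissociation tail of the
    highest-concentration curve; (KD, Rmax) from a coarse plateau scan."""
    sg = max(sensorgrams, key=lambda s: s.conc)
    mask = sg.t > sg.t_assoc
    kd0 = 1e-3
    if mask.sum() >= 3:
        td = sg.t[mask] - sg.t_assoc
        rd = sg.response[mask]
        pos = rd > max(1e-6, 0.01 * np.max(np.abs(sg.response)))
        if pos.sum() >= 3:
            slope = np.polyfit(td[pos], np.log(rd[pos]), 1)[0]
            if slope < 0:
                kd0 = -slope
    plateaus = np.array([np.max(s.response[s.t <= s.t_assoc]) for s in sensorgrams])
    concs = np.array([s.conc for s in sensorgrams])
    best = (np.inf, concs.mean(), max(plateaus.max(), 1e-6))
    for kd_guess in np.geomspace(concs.min() / 100, concs.max() * 100, 60):
        w = concs / (concs + kd_guess)
        rmax = float(plateaus @ w / (w @ w))
        sse = float(np.sum((plateaus - rmax * w) ** 2))
        if sse < best[0] and rmax > 0:
            best = (sse, kd_guess, rmax)
    _, KD0, rmax0 = best
    ka0 = kd0 / KD0 if KD0 > 0 else 1e4
    return max(ka0, 1e-2), max(kd0, 1e-8), rmax0


def fit_1to1(sensorgrams: list[Sensorgram],
             x0: tuple[float, float, float] | None = None,
             ) -> tuple[KineticParams, FitDiagnostics]:
    """Global nonlinear least-squares fit of (ka, kd, Rmax) to sensorgrams.

    Parameters are optimized in log space for ka and kd (positivity).  The
    fit is deterministic given the data and starting values; diagnostics
    carry the residual RMS and the Jacobian condition number, with
    ``ill_conditioned`` set when the normal equations are numerically
    degenerate (e.g. a single concentration far below KD with kd ~ 0).
    """
    if not sensorgrams:
        raise ParameterError("sensorgrams: at least one required")
    ka0, kd0, rmax0 = x0 if x0 is not None else _initial_guess(sensorgrams)

    def residuals(x):
        ka, kd, rmax = np.exp(x[0]), np.exp(x[1]), x[2]
        res = [s.response - langmuir_response(s.t, s.conc, ka, kd, rmax, s.t_assoc)
               for s in sensorgrams]
        return np.concatenate(res)

    x_start = np.array([np.log(ka0), np.log(kd0), rmax0])
    sol = least_squares(residuals, x_start, method="lm", xtol=1e-14, ftol=1e-14,
                        gtol=1e-14, max_nfev=5000)
    ka, kd, rmax = float(np.exp(sol.x[0])), float(np.exp(sol.x[1])), float(sol.x[2])
    if not sol.success or not np.isfinite([ka, kd, rmax]).all() or rmax <= 0:
        raise RuntimeError(
            f"1:1 fit did not converge: {sol.message}; "
            f"last iterate ka={ka:.4g}, kd={kd:.4g}, Rmax={rmax:.4g}")

    n = sum(len(s.t) for s in sensorgrams)
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    sv = np.linalg.svd(sol.jac, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    per_rms = []
    i = 0
    for s in sensorgrams:
        per_rms.append(float(np.sqrt(np.mean(sol.fun[i:i + len(s.t)] ** 2))))
        i += len(s.t)
    diag = FitDiagnostics(rms_residual=rms, condition_number=cond,
                          ill_conditioned=bool(cond > 1e6), n_points=n,
                          success=bool(sol.success), message=sol.message,
                          per_curve_rms=per_rms)
    return KineticParams(ka=ka, kd=kd, Rmax=rmax), diag
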