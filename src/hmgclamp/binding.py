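"""Equilibrium and kinetic analysis of protein-DNA binding.

Equilibrium titrations are fit with the single-site ligand-binding
isotherm in its ligand-depletion ("quadratic") form, appropriate when
the fixed DNA concentration is comparable to the dissociation constant
(the usual regime for tight HMG-box/DNA complexes monitored by FRET at
~25 nM DNA):

    dF(S) = dF0 * { 0.5*(1 + S/D0 + Kd/D0)
                    - sqrt( 0.25*(1 + S/D0 + Kd/D0)**2 - S/D0 ) }

where ``S`` is total protein, ``D0`` total DNA, ``Kd`` the dissociation
constant and ``dF0`` the fluorescence change of the saturated 1:1
complex.

Dissociation kinetics from stopped-flow chase experiments (labelled
complex mixed with excess unlabelled competitor) are fit with single- or
double-exponential decays; the complex lifetime is ``1/koff``.  Rate
ratios between variants translate into free-energy-barrier differences
via ``ddG = R*T*ln(fold)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "GAS_CONSTANT_KCAL",
    "TitrationSeries",
    "BindingFit",
    "KineticTrace",
    "DissociationFit",
    "RateComparison",
    "predict_delta_f",
    "fit_kd",
    "fit_koff",
    "ddg_from_fold",
    "kon_from",
    "celsius_to_kelvin",
]

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.987e-3


def celsius_to_kelvin(t_celsius: float) -> float:
    """Convert a Celsius temperature to kelvin."""
    return t_celsius + 273.15


@dataclass(frozen=True)
class TitrationSeries:
    """A protein-into-DNA titration monitored by a fluorescence change.

    Parameters
    ----------
    protein_conc : array-like
        Total protein concentrations ``S`` in molar units.
    delta_f : array-like
        Observed fluorescence changes, same length as ``protein_conc``.
    dna_conc : float
        Fixed total DNA concentration ``D0`` in molar units.
    temperature : float
        Temperature in kelvin (metadata; not used by the fit).
    """

    protein_conc: np.ndarray
    delta_f: np.ndarray
    dna_conc: float
    temperature: float = 298.15

    def __post_init__(self) -> None:
        object.__setattr__(self, "protein_conc",
                           np.asarray(self.protein_conc, dtype=float))
        object.__setattr__(self, "delta_f",
                           np.asarray(self.delta_f, dtype=float))
        if self.dna_conc <= 0:
            raise ValueError("dna_conc must be positive")
        if np.any(self.protein_conc < 0):
            raise ValueError("protein concentrations must be non-negative")
        if self.protein_conc.shape != self.delta_f.shape:
            raise ValueError("protein_conc and delta_f must have equal length")

    def __len__(self) -> int:
        return self.protein_conc.size


@dataclass(frozen=True)
class BindingFit:
    """Result of fitting a titration with the depletion isotherm."""

    kd: float
    dF0: float
    se_kd: float
    se_dF0: float
    rss: float
    converged: bool
    n_points: int = 0

    def to_dict(self) -> dict:
        return {
            "kd_M": self.kd, "dF0": self.dF0,
            "se_kd_M": self.se_kd, "se_dF0": self.se_dF0,
            "rss": self.rss, "converged": self.converged,
            "n_points": self.n_points,
        }


@dataclass(frozen=True)
class KineticTrace:
    """A stopped-flow dissociation trace.

    ``chase_excess`` records the fold excess of unlabelled competitor in
    the chase syringe (metadata only).
    """

    time: np.ndarray
    signal: np.ndarray
    temperature: float = 298.15
    chase_excess: float = 20.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "signal", np.asarray(self.signal, dtype=float))
        if self.time.shape != self.signal.shape:
            raise ValueError("time and signal must have equal length")
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class DissociationFit:
    """Exponential fit of a dissociation trace.

    ``lifetime`` is the mean complex lifetime ``1/koff`` (dominant phase
    for a double-exponential fit).  ``aic`` allows explicit comparison of
    the single- and double-exponential models; model order is never
    selected silently.
    """

    koff: float
    amplitude: float
    baseline: float
    se_koff: float
    lifetime: float
    converged: bool
    model: str = "single"
    rss: float = math.nan
    aic: float = math.nan
    # second phase, populated only for model == "double"
    koff2: float | None = None
    amplitude2: float | None = None

    def to_dict(self) -> dict:
        out = {
            "koff_per_s": self.koff, "amplitude": self.amplitude,
            "baseline": self.baseline, "se_koff_per_s": self.se_koff,
            "lifetime_s": self.lifetime, "converged": self.converged,
            "model": self.model, "rss": self.rss, "aic": self.aic,
        }
        if self.model == "double":
            out["koff2_per_s"] = self.koff2
            out["amplitude2"] = self.amplitude2
        return out


@dataclass(frozen=True)
class RateComparison:
    """Off-rate ratio between a variant and a reference complex."""

    fold: float
    temperature: float
    ddg: float = field(init=False)
    gas_constant: float = GAS_CONSTANT_KCAL

    def __post_init__(self) -> None:
        object.__setattr__(self, "ddg",
                           ddg_from_fold(self.fold, self.temperature,
                                         gas_constant=self.gas_constant))


def predict_delta_f(S, D0: float, Kd: float, dF0: float):
    """Fluorescence change of the single-site depletion isotherm.

    Evaluates the quadratic binding model (see module docstring) for
    total protein ``S`` (scalar or array), total DNA ``D0``, dissociation
    constant ``Kd`` and saturation amplitude ``dF0``.  The discriminant
    is analytically non-negative; tiny negative values from floating
    error are clamped to zero, while substantially negative values raise.
    """
    S = np.asarray(S, dtype=float)
    if D0 <= 0:
        raise ValueError("D0 must be positive")
    if Kd < 0:
        raise ValueError("Kd must be non-negative")
    if np.any(S < 0):
        raise ValueError("protein concentrations must be non-negative")
    s = S / D0
    h = 0.5 * (1.0 + s + Kd / D0)
    disc = h * h - s
    bad = disc < -1e-9 * np.maximum(h * h, 1.0)
    if np.any(bad):
        raise FloatingPointError("negative discriminant in binding isotherm")
    disc = np.clip(disc, 0.0, None)
    bound = h - np.sqrt(disc)
    out = dF0 * bound
    return out.item() if out.ndim == 0 else out


def _kd_residuals(params, series: TitrationSeries):
    kd, df0 = params
    return predict_delta_f(series.protein_conc, series.dna_conc, kd, df0) \
        - series.delta_f


def fit_kd(series: TitrationSeries, init: tuple[float, float] | None = None
           ) -> BindingFit:
    """Least-squares fit of (Kd, dF0) to a titration series.

    Uses bounded nonlinear least squares with Kd >= 0, initialised at
    Kd = D0 and dF0 = max(delta_f) unless ``init`` is given.  Standard
    errors come from the Jacobian at the optimum.  A flat series (all
    delta_f ~ 0) is non-identifiable and returns ``converged=False``
    rather than raising.
    """
    if len(series) < 4:
        raise ValueError("need at least 4 titration points to fit")
    scale = float(np.max(np.abs(series.delta_f))) if len(series) else 0.0
    if scale == 0.0 or not np.isfinite(scale):
        return BindingFit(math.nan, math.nan, math.nan, math.nan,
                          math.nan, False, len(series))
    if init is None:
        init = (series.dna_conc, float(np.max(series.delta_f)))
    k0 = max(init[0], 1e-30)
    try:
        res = least_squares(
            _kd_residuals, x0=[k0, init[1]],
            bounds=([0.0, -np.inf], [np.inf, np.inf]),
            args=(series,), x_scale=[max(k0, series.dna_conc), abs(init[1]) or 1.0],
            xtol=1e-14, ftol=1e-14, gtol=1e-14)
    except FloatingPointError:
        return BindingFit(math.nan, math.nan, math.nan, math.nan,
                          math.nan, False, len(series))
    rss = float(2.0 * res.cost)
    se = _se_from_jacobian(res.jac, rss, len(series))
    return BindingFit(kd=float(res.x[0]), dF0=float(res.x[1]),
                      se_kd=se[0], se_dF0=se[1], rss=rss,
                      converged=bool(res.success), n_points=len(series))


def _se_from_jacobian(jac: np.ndarray, rss: float, n: int) -> np.ndarray:
    """Standard errors from local curvature at a least-squares optimum."""
    p = jac.shape[1]
    dof = max(n - p, 1)
    try:
        cov = np.linalg.inv(jac.T @ jac) * rss / dof
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)


def fit_koff(trace: KineticTrace, model: str = "single") -> DissociationFit:
    """Fit a dissociation trace with an exponential decay.

    model="single" fits ``F(t) = baseline + A*exp(-koff*t)``;
    model="double" adds a second exponential phase and reports the
    dominant (larger-amplitude) phase as ``koff``.  Both AICs are worth
    comparing before trusting the double fit.  A non-decaying signal
    yields ``converged=False``.
    """
    if model not in ("single", "double"):
        raise ValueError("model must be 'single' or 'double'")
    if len(trace) < 10:
        raise ValueError("need at least 10 points to fit a kinetic trace")
    t, y = trace.time, trace.signal
    t0 = t - t[0]
    span = float(y[0] - y[-1])
    base0 = float(y[-1])
    amp0 = span if span != 0 else (float(np.ptp(y)) or 1.0)
    k0 = 3.0 / max(t0[-1], 1e-12)

    if model == "single":
        def resid(p):
            k, a, b = p
            return b + a * np.exp(-np.clip(k * t0, None, 700.0)) - y
        x0 = [k0, amp0, base0]
        lb = [1e-12, -np.inf, -np.inf]
        ub = [np.inf, np.inf, np.inf]
    else:
        def resid(p):
            k1, a1, k2, a2, b = p
            return (b + a1 * np.exp(-np.clip(k1 * t0, None, 700.0))
                    + a2 * np.exp(-np.clip(k2 * t0, None, 700.0)) - y)
        x0 = [k0, 0.7 * amp0, k0 / 10.0, 0.3 * amp0, base0]
        lb = [1e-12, -np.inf, 1e-12, -np.inf, -np.inf]
        ub = [np.inf, np.inf, np.inf, np.inf, np.inf]

    res = least_squares(resid, x0=x0, bounds=(lb, ub),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    rss = float(2.0 * res.cost)
    n = len(trace)
    n_par = len(x0)
    aic = n * math.log(max(rss / n, 1e-300)) + 2 * n_par
    se = _se_from_jacobian(res.jac, rss, n)

    if model == "single":
        k, a, b = (float(v) for v in res.x)
        ok = bool(res.success) and k > 0 and a > 0
        return DissociationFit(koff=k, amplitude=a, baseline=b,
                               se_koff=float(se[0]),
                               lifetime=1.0 / k if k > 0 else math.inf,
                               converged=ok, model="single", rss=rss, aic=aic)
    k1, a1, k2, a2, b = (float(v) for v in res.x)
    # dominant phase = larger absolute amplitude
    if abs(a2) > abs(a1):
        (k1, a1), (k2, a2) = (k2, a2), (k1, a1)
        se = se[[2, 3, 0, 1, 4]]
    ok = bool(res.success) and k1 > 0 and a1 > 0
    return DissociationFit(koff=k1, amplitude=a1, baseline=b,
                           se_koff=float(se[0]),
                           lifetime=1.0 / k1 if k1 > 0 else math.inf,
                           converged=ok, model="double", rss=rss, aic=aic,
                           koff2=k2, amplitude2=a2)


def ddg_from_fold(fold: float, temperature: float, *,
                  gas_constant: float = GAS_CONSTANT_KCAL) -> float:
    """Free-energy-barrier change implied by an off-rate ratio.

    ``ddG = R * T * ln(fold)`` in kcal/mol; a fourfold acceleration at
    310.15 K corresponds to ~0.85 kcal/mol barrier reduction.
    """
    if fold <= 0:
        raise ValueError("fold ratio must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    return gas_constant * temperature * math.log(fold)


def kon_from(Kd: float, koff: float) -> float:
    """Association rate from Kd = koff/kon, i.e. kon = koff/Kd."""
    if Kd <= 0 or koff <= 0:
        raise ValueError("Kd and koff must be positive")
    return koff / Kd
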