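"""Least-squares estimation of synapse parameters and sigmoid gain fits.

Synapse parameters (U, tau_in, tau_rec, tau_facil) are estimated from
normalized EPSC amplitude curves by bounded multi-start least squares; the
absolute strength A scales out of normalized data and is never a free
parameter.  Spike-probability vs conductance curves are fitted with the
three-parameter sigmoid y = a / (1 + b * exp(-c * x)).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .stp import STPParams, train_amplitudes

__all__ = [
    "FitSpec",
    "FitResult",
    "SigmoidFit",
    "FitFailureError",
    "DEFAULT_BOUNDS",
    "fit_stp",
    "compare_scenarios",
    "fit_sigmoid",
]

PARAM_NAMES = ("U", "tau_in", "tau_rec", "tau_facil")

DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "U": (1e-3, 1.0),
    "tau_in": (0.05, 20.0),
    "tau_rec": (1.0, 1000.0),
    "tau_facil": (1.0, 2000.0),
}

#: Number of deterministic starting points per free parameter axis.
N_STARTS = 8


class FitFailureError(RuntimeError):
    """Raised when the optimizer fails to converge from every start."""


@dataclass(frozen=True)
class FitSpec:
    """Specification of a synapse-parameter fit.

    ``observations`` is a list of ``(frequency_hz, normalized_amplitudes)``
    pairs; ``fixed`` supplies values for the parameters not being fitted.
    """

    free_parameters: tuple[str, ...]
    fixed: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    observations: list[tuple[float, np.ndarray]] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.free_parameters) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        for name in PARAM_NAMES:
            if name not in self.free_parameters and name not in self.fixed:
                raise ValueError(f"parameter {name} is neither free nor fixed")
        for name, (lo, hi) in self.effective_bounds().items():
            if not (0 < lo < hi) or not np.isfinite(hi):
                raise ValueError(f"bounds for {name} must be finite and positive")

    def effective_bounds(self) -> dict[str, tuple[float, float]]:
        return {name: self.bounds.get(name, DEFAULT_BOUNDS[name]) for name in self.free_parameters}

    def n_observations(self) -> int:
        return int(sum(len(a) for _, a in self.observations))


@dataclass(frozen=True)
class FitResult:
    params: dict[str, float]
    sse: float
    residuals: np.ndarray
    label: str = ""


def model_curve(params: STPParams, frequency_hz: float, n_pulses: int) -> np.ndarray:
    """Normalized per-pulse amplitude curve predicted by the synapse model."""
    _, normalized = train_amplitudes(params, n_pulses, frequency_hz)
    return normalized


def _residuals(values: np.ndarray, spec: FitSpec) -> np.ndarray:
    kw = dict(spec.fixed)
    kw.update({name: v for name, v in zip(spec.free_parameters, values)})
    kw.pop("A", None)
    p = STPParams(A=1.0, **kw)
    res = []
    for freq, obs in spec.observations:
        obs = np.asarray(obs, dtype=float)
        res.append(model_curve(p, freq, len(obs)) - obs)
    return np.concatenate(res)


def _start_grid(spec: FitSpec) -> list[np.ndarray]:
    """Deterministic multi-start grid: linear in U, log-spaced in the time
    constants; the full Cartesian product is capped at 64 starts."""
    axes = []
    for name in spec.free_parameters:
        lo, hi = spec.effective_bounds()[name]
        if name == "U":
            axes.append(np.linspace(max(lo, 0.05), min(hi, 0.95), N_STARTS))
        else:
            axes.append(np.geomspace(lo, hi, N_STARTS))
    starts = list(itertools.product(*axes))
    if len(starts) > 64:
        step = len(starts) // 64 + 1
        starts = starts[::step]
    return [np.asarray(s) for s in starts]


def fit_stp(spec: FitSpec) -> FitResult:
    """Fit the free synapse parameters by bounded least squares.

    Runs a trust-region reflective optimization from every point of a fixed
    deterministic start grid and keeps the best solution; the result is
    exactly reproducible for a given spec.
    """
    if not spec.free_parameters:
        raise ValueError("at least one free parameter is required")
    if spec.n_observations() < len(spec.free_parameters):
        raise ValueError("need at least as many observation points as free parameters")
    bounds = spec.effective_bounds()
    lo = np.array([bounds[n][0] for n in spec.free_parameters])
    hi = np.array([bounds[n][1] for n in spec.free_parameters])
    best = None
    failures = []
    for x0 in _start_grid(spec):
        try:
            sol = optimize.least_squares(_residuals, x0, bounds=(lo, hi), args=(spec,), method="trf")
        except Exception as exc:  # noqa: BLE001 - collected for diagnostics
            failures.append(str(exc))
            continue
        if not sol.success:
            failures.append(sol.message)
            continue
        sse = float(np.sum(sol.fun**2))
        if best is None or sse < best[0]:
            best = (sse, sol)
    if best is None:
        raise FitFailureError(f"all {len(_start_grid(spec))} starts failed: {failures[:3]}")
    sse, sol = best
    fitted = dict(spec.fixed)
    fitted.update({name: float(v) for name, v in zip(spec.free_parameters, sol.x)})
    return FitResult(params=fitted, sse=sse, residuals=sol.fun, label=spec.label)


def evaluate_sse(params: STPParams, observations) -> float:
    """Sum of squared differences between a model curve and observations."""
    sse = 0.0
    for freq, obs in observations:
        obs = np.asarray(obs, dtype=float)
        sse += float(np.sum((model_curve(params, freq, len(obs)) - obs) ** 2))
    return sse


def compare_scenarios(reference_observations, scenarios: list[FitSpec]) -> pd.DataFrame:
    """Fit each scenario to a common reference curve and rank by SSE.

    ``reference_observations`` is a list of ``(frequency, normalized
    amplitudes)`` pairs shared by all scenarios (a scenario's own
    observations are ignored).  Scenarios with no free parameters are
    evaluated directly.  Returns a table sorted by SSE with the fitted
    values per scenario.
    """
    rows = []
    for i, scen in enumerate(scenarios):
        label = scen.label or f"scenario_{i}"
        if scen.free_parameters:
            spec = FitSpec(
                free_parameters=scen.free_parameters,
                fixed=scen.fixed,
                bounds=scen.bounds,
                observations=list(reference_observations),
                label=label,
            )
            result = fit_stp(spec)
            params, sse = result.params, result.sse
        else:
            params = dict(scen.fixed)
            kw = {k: v for k, v in params.items() if k != "A"}
            sse = evaluate_sse(STPParams(A=1.0, **kw), reference_observations)
        row = {"scenario": label, "sse": sse}
        row.update(params)
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("sse", kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


@dataclass(frozen=True)
class SigmoidFit:
    """Sigmoid y = a / (1 + b exp(-c x)) fitted to spike-probability data.

    ``a`` is the saturation asymptote (%), ``b`` the offset factor and ``c``
    the slope factor (per nS).
    """

    a: float
    b: float
    c: float

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a / (1.0 + self.b * np.exp(-self.c * x))


def fit_sigmoid(x, y, a_fixed: float | None = None) -> SigmoidFit:
    """Least-squares sigmoid fit of spike probability (%) vs conductance (nS).

    With ``a_fixed`` the asymptote is pinned (e.g. at the empirical
    saturating probability) and only ``b`` and ``c`` are fitted.  Degenerate
    inputs (constant y, so the slope is unidentifiable) raise
    :class:`FitFailureError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    min_points = 2 if a_fixed is not None else 3
    if x.size < min_points:
        raise ValueError(f"need at least {min_points} points")
    if np.ptp(y) < 1e-9:
        raise FitFailureError("constant spike probability: sigmoid slope unidentifiable")
    span = np.ptp(x) if np.ptp(x) > 0 else 1.0
    c0 = 4.0 / span
    a0 = a_fixed if a_fixed is not None else max(y.max(), 1e-3)
    x_mid = np.interp(0.5 * a0, np.sort(y), x[np.argsort(y)])
    b0 = max(np.exp(c0 * x_mid), 1e-3)
    try:
        if a_fixed is not None:
            popt, _ = optimize.curve_fit(
                lambda xx, b, c: a_fixed / (1.0 + b * np.exp(-c * xx)),
                x, y, p0=[b0, c0], bounds=([1e-9, 1e-9], [np.inf, np.inf]), maxfev=20000,
            )
            return SigmoidFit(a=float(a_fixed), b=float(popt[0]), c=float(popt[1]))
        popt, _ = optimize.curve_fit(
            lambda xx, a, b, c: a / (1.0 + b * np.exp(-c * xx)),
            x, y, p0=[a0, b0, c0], bounds=([1e-9, 1e-9, 1e-9], [100.0, np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitFailureError(f"sigmoid fit did not converge: {exc}") from None
    return SigmoidFit(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]))
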