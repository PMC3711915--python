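"""In-silico experiments: sweeps, parameter variations and fit comparisons.

Concentration sweeps record the observed turnover (per wild-type subunit)
against total particle number and attach a Michaelis-Menten fit with
residual diagnostics; mutant titrations hold the wild-type number fixed
(typically 1000) and sweep the number of catalytically dead subunits under
a chosen inhibition scheme.  Every run's seed is derived deterministically
from (base seed, grid index, replicate index), so sweeps are reproducible
bit for bit.

"Systematic deviation" of a fit is operationalized as a one-sided
Wald-Wolfowitz runs test on the signs of the residuals (clustered signs
mean fewer runs than chance): p < 0.05 flags the fit as structurally
wrong for the data, a quantitative stand-in for judging residual panels
by eye.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .fitting import MODELS, FitResult, TitrationCurve, fit
from .network import RateTable, build_network
from .ssa import (
    SimulationConfig,
    hexamer_census,
    kobs_from_trace,
    oligomer_census,
    run,
    steady_state_window,
)

__all__ = [
    "SweepSpec",
    "SweepResult",
    "derive_seed",
    "sweep_concentration",
    "sweep_mutant",
    "parameter_variation",
    "generate_synthetic_curve",
    "compare_fits",
    "residual_runs_pvalue",
]


def derive_seed(base_seed: int, grid_index: int, replicate_index: int) -> int:
    """Deterministic per-run seed below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), int(grid_index), int(replicate_index)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class SweepSpec:
    """One sweep: variable, grid, replicates, base run and scenario."""

    variable: str  # 'n_total' or 'n_Mut'
    grid: tuple[int, ...]
    base: SimulationConfig
    replicates: int = 10
    rate_multipliers: Mapping[str, float] = field(default_factory=dict)
    rate_overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variable not in ("n_total", "n_Mut"):
            raise ValueError("variable must be 'n_total' or 'n_Mut'")
        grid = tuple(int(v) for v in self.grid)
        if not grid or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("grid must be non-empty and strictly increasing")
        object.__setattr__(self, "grid", grid)
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def effective_rates(self) -> RateTable:
        rates = self.base.rates
        if self.rate_overrides:
            rates = replace(rates, **dict(self.rate_overrides))
        if self.rate_multipliers:
            rates = rates.scaled(self.rate_multipliers)
        return rates


@dataclass
class SweepResult:
    """Per (grid point, replicate) outcomes plus attached curve fits."""

    spec: SweepSpec
    table: pd.DataFrame
    fits: dict[str, FitResult] = field(default_factory=dict)
    diagnostics: dict[str, float | bool] = field(default_factory=dict)

    def mean_curve(self) -> TitrationCurve:
        g = self.table.groupby("x")["k_obs"].mean()
        return TitrationCurve(g.index.to_numpy(float), g.to_numpy())

    def pooled_curve(self) -> TitrationCurve:
        return TitrationCurve(
            self.table["x"].to_numpy(float),
            self.table["k_obs"].to_numpy(float),
            self.table["replicate"].to_numpy(),
        )


def _sweep(spec: SweepSpec) -> pd.DataFrame:
    rates = spec.effective_rates()
    network = build_network(spec.base.pathway, rates, spec.base.scheme)
    mut_ratio = spec.base.n_Mut / spec.base.n_Wt if spec.base.n_Wt else 0.0
    rows = []
    for gi, x in enumerate(spec.grid):
        if spec.variable == "n_total":
            n_wt = max(int(round(x / (1.0 + mut_ratio))), 1)
            n_mut = x - n_wt if mut_ratio else 0
        else:
            n_wt, n_mut = spec.base.n_Wt, x
        for ri in range(spec.replicates):
            cfg = replace(
                spec.base, n_Wt=n_wt, n_Mut=n_mut, rates=rates,
                seed=derive_seed(spec.base.seed, gi, ri),
            )
            trace = run(cfg, network=network)
            window = steady_state_window(trace)
            row = {
                "x": x, "grid_index": gi, "replicate": ri, "seed": cfg.seed,
                "n_Wt": n_wt, "n_Mut": n_mut,
                "k_obs": kobs_from_trace(trace, window=window),
                "warning": window.warning,
                "absorbed": trace.absorbed,
            }
            census = oligomer_census(trace)
            mask = census.index >= trace.times[window.start]
            means = census[mask].mean() if mask.any() else census.mean()
            for kind, frac in means.items():
                row[f"frac_{kind}"] = float(frac)
            rows.append(row)
    return pd.DataFrame(rows)


def residual_runs_pvalue(residuals: np.ndarray) -> float:
    """One-sided runs-test p-value for sign clustering of *residuals*."""
    from statsmodels.sandbox.stats.runs import runstest_1samp

    residuals = np.asarray(residuals, dtype=float)
    if len(residuals) < 4 or np.allclose(residuals, 0):
        return 1.0
    z, p_two = runstest_1samp(residuals, cutoff=0, correction=False)
    return float(p_two / 2.0) if z < 0 else float(1.0 - p_two / 2.0)


def _attach_mm_fit(result: SweepResult) -> None:
    curve = result.mean_curve()
    mm = fit("mm", curve)
    result.fits["mm"] = mm
    p = residual_runs_pvalue(mm.residuals)
    result.diagnostics["mm_runs_p"] = p
    result.diagnostics["mm_systematic_deviation"] = bool(p < 0.05)


def sweep_concentration(spec: SweepSpec) -> SweepResult:
    """Turnover vs total particle number, with a Michaelis-Menten fit.

    The grid value is the total subunit number; a mixed base configuration
    keeps its wild-type:mutant ratio along the sweep.
    """
    if spec.variable != "n_total":
        raise ValueError("concentration sweep needs variable='n_total'")
    result = SweepResult(spec, _sweep(spec))
    _attach_mm_fit(result)
    return result


def sweep_mutant(spec: SweepSpec) -> SweepResult:
    """Turnover per wild-type subunit vs mutant number at fixed n_Wt."""
    if spec.variable != "n_Mut":
        raise ValueError("mutant sweep needs variable='n_Mut'")
    return SweepResult(spec, _sweep(spec))


def parameter_variation(
    base: SweepSpec, multipliers: Mapping[str, float]
) -> dict[str, SweepResult]:
    """One concentration sweep per varied rate (plus the unmodified base).

    *multipliers* maps a rate field name (e.g. ``'k12_f'``) to its factor;
    each variation is swept independently and reported with its
    Michaelis-Menten Vmax and half-saturation constant.
    """
    results = {"default": sweep_concentration(base)}
    for name, factor in multipliers.items():
        if factor <= 0:
            raise ValueError(f"multiplier for {name} must be positive")
        varied = replace(base, rate_multipliers={**dict(base.rate_multipliers), name: factor})
        results[f"{factor:g}x {name}"] = sweep_concentration(varied)
    return results


def generate_synthetic_curve(
    model: str,
    params: Mapping[str, float],
    grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TitrationCurve:
    """Noisy synthetic titration curve: model(x) + Gaussian(0, noise_sd)."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    x = np.asarray(grid, dtype=float)
    y = np.asarray(MODELS[model].func(x, dict(params)), dtype=float)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(x))
    return TitrationCurve(x, y)


def compare_fits(
    curve: TitrationCurve,
    models: Sequence[str],
    fixed: Mapping[str, float] | None = None,
) -> tuple[list[FitResult], pd.DataFrame]:
    """Fit several models to one curve and rank them by SSR.

    *fixed* bindings are applied to each model that has the parameter.
    Returns the ranked fit results and a diagnostics table with SSR and
    the residual-sign runs-test p-value per model.
    """
    if len(models) < 2:
        raise ValueError("need at least two models to compare")
    fixed = dict(fixed or {})
    results = []
    for model in models:
        sub = {k: v for k, v in fixed.items() if k in MODELS[model].names}
        results.append(fit(model, curve, fixed=sub))
    ranked = sorted(results, key=lambda r: (not r.success, r.ssr))
    diag = pd.DataFrame(
        {
            "model": [r.model for r in ranked],
            "ssr": [r.ssr for r in ranked],
            "runs_p": [residual_runs_pvalue(r.residuals) for r in ranked],
            "converged": [r.success for r in ranked],
        }
    )
    diag["systematic_deviation"] = diag["runs_p"] < 0.05
    return ranked, diag
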