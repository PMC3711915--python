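"""Analysis models for titration curves of ring enzymes.

Four fit functions for steady-state turnover data, plus a mechanistic
pseudo-first-order chain prediction:

* :func:`michaelis_menten` — hyperbolic activation vs total enzyme.
* :func:`binomial_activity` — a mixture model for mutant titrations: rings
  are sampled binomially from the wild-type/mutant pool (mutant counts
  weighted by an incorporation factor ``d``), all-mutant rings are excluded
  from the readout, mutant-free rings turn over at k_cat,WW and mutant-
  containing rings at the basal k_cat,WM.
* :func:`noncompetitive_rate` — textbook non-competitive inhibition
  generalized to a non-zero turnover of the inhibited complex.
* :func:`exponential_decay` — a purely empirical single exponential.
* :func:`pseudo_first_order_kobs` / :func:`pseudo_first_order_K` — the
  steady-state turnover of a linear enzyme-state chain in which only the
  first step depends on substrate concentration, and its half-saturation
  constant.

:func:`fit` wraps nonlinear least squares with optional parameter fixing
(e.g. pinning k_cat,WW at an independently measured value).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

__all__ = [
    "TitrationCurve",
    "FitResult",
    "ChainRates",
    "michaelis_menten",
    "binomial_activity",
    "noncompetitive_rate",
    "exponential_decay",
    "pseudo_first_order_kobs",
    "pseudo_first_order_K",
    "fit",
    "MODELS",
]


@dataclass(frozen=True)
class TitrationCurve:
    """Observed turnover (1/s) vs particle number (total or mutant)."""

    x: np.ndarray
    y: np.ndarray
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        if np.any(self.x < 0):
            raise ValueError("particle numbers must be non-negative")


@dataclass
class FitResult:
    """Parameter estimates with residuals; fixed parameters pass through."""

    model: str
    params: dict[str, float]
    fixed: dict[str, float] = field(default_factory=dict)
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))
    ssr: float = np.nan
    success: bool = False
    message: str = ""

    def predict(self, x: np.ndarray) -> np.ndarray:
        return MODELS[self.model].func(np.asarray(x, dtype=float), self.params)


# --- closed-form models ----------------------------------------------------

def michaelis_menten(S, Vmax: float, K: float):
    """Hyperbolic saturation Vmax*S/(K+S)."""
    if K <= 0:
        raise ValueError("K must be positive")
    S = np.asarray(S, dtype=float)
    return Vmax * S / (K + S)


def binomial_activity(n_W, n_M, kcat_WW: float, kcat_WM: float, d: float = 1.0):
    """Per-wild-type-subunit turnover of a binomially assembled ring pool.

    With effective mutant number ``m = d*n_M``, ``p = m/(n_W+m)`` and
    ``q = 1-p``, the fraction of mutant-free rings among rings containing
    at least one wild-type subunit is ``q**6/(1-p**6)``; those rings turn
    over at *kcat_WW*, all other wild-type-containing rings at *kcat_WM*.
    """
    if np.any(np.asarray(n_W) <= 0):
        raise ValueError("n_W must be positive")
    if d <= 0:
        raise ValueError("d must be positive")
    n_M = np.asarray(n_M, dtype=float)
    m = d * n_M
    p = m / (n_W + m)
    q = 1.0 - p
    p6 = p**6
    p_nomut = q**6 / (1.0 - p6)
    p_mut = (1.0 - q**6 - p6) / (1.0 - p6)
    return kcat_WW * p_nomut + kcat_WM * p_mut


def noncompetitive_rate(S, I, kcat_WW: float, kcat_WM: float, Km: float, Ki: float):
    """Generalized non-competitive inhibition.

    ``(S/(Km+S)) * (kcat_WW*Ki + kcat_WM*I)/(Ki+I)`` — at I=0 this is a
    Michaelis-Menten curve with Vmax=kcat_WW; at saturating inhibitor the
    complex still turns over at kcat_WM.
    """
    if Km <= 0 or Ki <= 0:
        raise ValueError("Km and Ki must be positive")
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    return (S / (Km + S)) * (kcat_WW * Ki + kcat_WM * I) / (Ki + I)


def exponential_decay(I, A: float, lam: float, c: float):
    """Empirical single exponential A*exp(-I/lam) + c."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    I = np.asarray(I, dtype=float)
    return A * np.exp(-I / lam) + c


# --- pseudo-first-order chain ----------------------------------------------

@dataclass(frozen=True)
class ChainRates:
    """Rates of a linear enzyme-state chain E1 <-> E2 <-> ... <-> Em -> E1.

    ``forward[0]`` is the only substrate-dependent rate (multiplied by S);
    the catalytic step recycles the last state to the first.
    """

    forward: tuple[float, ...]
    reverse: tuple[float, ...]
    kcat: float

    def __post_init__(self) -> None:
        if len(self.forward) != len(self.reverse) or not self.forward:
            raise ValueError("need equal, non-empty forward/reverse rate lists")
        if any(k < 0 for k in self.forward + self.reverse) or self.kcat < 0:
            raise ValueError("rates must be non-negative")

    @property
    def n_states(self) -> int:
        return len(self.forward) + 1


def _chain_stationary(forward: Sequence[float], reverse: Sequence[float],
                      kcat: float, recycle_to: int = 0) -> np.ndarray:
    m = len(forward) + 1
    A = np.zeros((m, m))
    for i, (kf, kr) in enumerate(zip(forward, reverse)):
        A[i + 1, i] += kf
        A[i, i] -= kf
        A[i, i + 1] += kr
        A[i + 1, i + 1] -= kr
    A[recycle_to, m - 1] += kcat
    A[m - 1, m - 1] -= kcat
    A[-1, :] = 1.0  # normalization replaces one redundant balance row
    b = np.zeros(m)
    b[-1] = 1.0
    try:
        x = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"degenerate chain (singular steady state): {exc}") from exc
    if not np.all(np.isfinite(x)):
        raise ValueError("degenerate chain (non-finite steady state)")
    return x


def pseudo_first_order_kobs(S: float, chain: ChainRates) -> float:
    """Steady-state turnover per total enzyme at substrate number *S*.

    Only the first forward rate is multiplied by S; the stationary
    occupancies solve the linear balance equations of the chain and the
    turnover is kcat times the occupancy of the last state.
    """
    if S < 0:
        raise ValueError("S must be non-negative")
    forward = (chain.forward[0] * S,) + chain.forward[1:]
    x = _chain_stationary(forward, chain.reverse, chain.kcat)
    return chain.kcat * x[-1]


def _kobs_saturating(chain: ChainRates) -> float:
    """S -> infinity limit: the first state drains instantly into the second."""
    if chain.n_states == 2:
        return chain.kcat  # everything sits in the last state
    # reduced chain over states 2..m; the back-step to state 1 returns
    # immediately (a null transition), and catalysis recycles into state 2.
    forward = chain.forward[1:]
    reverse = chain.reverse[1:]
    x = _chain_stationary(forward, reverse, chain.kcat)
    return chain.kcat * x[-1]


def pseudo_first_order_K(chain: ChainRates) -> float:
    """Substrate number at which the chain runs at half its saturating rate."""
    if chain.forward[0] <= 0:
        raise ValueError("first forward rate must be positive")
    k_inf = _kobs_saturating(chain)
    if k_inf <= 0:
        raise ValueError("chain does not saturate (zero limiting turnover)")
    f = lambda S: pseudo_first_order_kobs(S, chain) - 0.5 * k_inf
    hi = 1.0
    while f(hi) < 0:
        hi *= 10.0
        if hi > 1e15:
            raise ValueError("half-saturation point not bracketed below 1e15")
    return float(brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-14))


# --- least-squares fitting -------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    names: tuple[str, ...]
    func: Callable[[np.ndarray, Mapping[str, float]], np.ndarray]
    guess: Callable[[TitrationCurve], dict[str, float]]
    lower: Mapping[str, float]


def _mm_guess(data: TitrationCurve) -> dict[str, float]:
    return {"Vmax": float(data.y.max()) or 1.0,
            "K": float(np.median(data.x[data.x > 0])) if np.any(data.x > 0) else 1.0}


def _binomial_guess(data: TitrationCurve) -> dict[str, float]:
    return {"kcat_WW": float(data.y.max()) or 1.0,
            "kcat_WM": max(float(data.y.min()), 1e-3),
            "d": 1.0,
            "n_W": max(float(data.x.max()), 1.0)}


def _noncomp_guess(data: TitrationCurve) -> dict[str, float]:
    xpos = data.x[data.x > 0]
    mid = float(np.median(xpos)) if len(xpos) else 1.0
    return {"kcat_WW": 2.0 * float(data.y.max()) or 1.0,
            "kcat_WM": max(float(data.y.min()), 1e-3),
            "Km": mid, "Ki": mid,
            "S": max(float(data.x.max()), 1.0)}


def _exp_guess(data: TitrationCurve) -> dict[str, float]:
    xpos = data.x[data.x > 0]
    return {"A": float(data.y.max() - data.y.min()) or 1.0,
            "lam": float(np.median(xpos)) if len(xpos) else 1.0,
            "c": float(data.y.min())}


MODELS: dict[str, ModelSpec] = {
    "mm": ModelSpec(
        ("Vmax", "K"),
        lambda x, p: michaelis_menten(x, p["Vmax"], p["K"]),
        _mm_guess,
        {"Vmax": 0.0, "K": 1e-12},
    ),
    "binomial": ModelSpec(
        ("kcat_WW", "kcat_WM", "d", "n_W"),
        lambda x, p: binomial_activity(p["n_W"], x, p["kcat_WW"], p["kcat_WM"], p["d"]),
        _binomial_guess,
        {"kcat_WW": 0.0, "kcat_WM": 0.0, "d": 1e-9, "n_W": 1e-9},
    ),
    "noncompetitive": ModelSpec(
        ("kcat_WW", "kcat_WM", "Km", "Ki", "S"),
        lambda x, p: noncompetitive_rate(p["S"], x, p["kcat_WW"], p["kcat_WM"], p["Km"], p["Ki"]),
        _noncomp_guess,
        {"kcat_WW": 0.0, "kcat_WM": 0.0, "Km": 1e-9, "Ki": 1e-9, "S": 1e-9},
    ),
    "exponential": ModelSpec(
        ("A", "lam", "c"),
        lambda x, p: exponential_decay(x, p["A"], p["lam"], p["c"]),
        _exp_guess,
        {"A": -np.inf, "lam": 1e-12, "c": -np.inf},
    ),
}


def fit(
    model: str,
    data: TitrationCurve,
    fixed: Mapping[str, float] | None = None,
    p0: Mapping[str, float] | None = None,
) -> FitResult:
    """Nonlinear least squares with optional fixed parameter bindings.

    Fixed parameters are honoured exactly and returned unchanged in the
    result.  Non-convergence is reported through ``success``/``message``
    rather than an exception.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(MODELS)}")
    spec = MODELS[model]
    fixed = dict(fixed or {})
    unknown = set(fixed) - set(spec.names)
    if unknown:
        raise ValueError(f"fixed parameters {sorted(unknown)} not in model {model!r}")
    free = [n for n in spec.names if n not in fixed]
    if len(data.x) < len(free):
        raise ValueError(f"need >= {len(free)} data points for {len(free)} free parameters")
    guess = spec.guess(data)
    if p0:
        guess.update(p0)

    def assemble(theta: np.ndarray) -> dict[str, float]:
        params = dict(fixed)
        params.update(zip(free, theta))
        return params

    def resid(theta: np.ndarray) -> np.ndarray:
        return spec.func(data.x, assemble(theta)) - data.y

    if not free:
        params = dict(fixed)
        residuals = spec.func(data.x, params) - data.y
        return FitResult(model, params, fixed, residuals,
                         float(residuals @ residuals), True, "all parameters fixed")
    theta0 = np.array([max(guess[n], MODELS[model].lower[n]) for n in free])
    lower = np.array([spec.lower[n] for n in free])
    try:
        sol = least_squares(resid, theta0, bounds=(lower, np.inf), method="trf",
                            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=20_000)
        params = assemble(sol.x)
        residuals = sol.fun
        return FitResult(model, params, fixed, residuals,
                         float(residuals @ residuals), bool(sol.success), sol.message)
    except Exception as exc:  # flagged, not silent
        return FitResult(model, assemble(theta0), fixed,
                         np.full_like(data.y, np.nan), np.nan, False, str(exc))
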