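"""Joint fitting of the HGT network model to empirical MLDs.

The rank-1 + hub model has n + 3 free parameters (n transferabilities, the
hub transferability, and the two mobilome sizes L_d, L_h) and must explain
all 2^n - n - 1 MLDs at once.  Fitting minimizes the trimmed mean squared
log10-difference between empirical and predicted densities over populated
bins: per genus set, the worst 15% of bins are dropped (robustness against
outlier bins), and the retained squared residuals of all sets are averaged.
Parameters are searched in log10 space (positivity plus wide dynamic range)
with a seeded population-based global stage (differential evolution)
followed by bounded quasi-Newton (L-BFGS-B) refinement.

Episodic MLDs — sets so large that only a handful of transfer events
contribute — are instead fitted by a small mixture of exponentials
A_k exp(-tau_k r); the crossover lengths where consecutive components are
equal separate the length classes attributable to individual events.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import differential_evolution, least_squares, minimize

from .match_core import InputError
from .mld_stats import MLD
from .hgt_model import TaxonNetwork, total_mld

__all__ = [
    "FitError",
    "FitConfig",
    "FitResult",
    "ExpMixture",
    "objective",
    "fit_network",
    "fit_exp_mixture",
]

# Squared-log penalty assigned where the model is zero on a populated bin;
# large enough to dominate, small enough to keep the objective finite, and
# trimmable like any other residual.
_ZERO_MODEL_PENALTY = 1e4


class FitError(RuntimeError):
    """Raised when a fit cannot be performed on the given data."""


@dataclass
class FitConfig:
    """Optimizer settings; bounds apply to log10 of the parameters."""

    trim_fraction: float = 0.15
    log_gamma_bounds: tuple[float, float] = (-6.0, 2.0)
    log_L_bounds: tuple[float, float] = (2.0, 8.0)
    popsize: int = 15
    maxiter: int = 200
    tol: float = 1e-10
    local_gtol: float = 1e-12
    reading: str = "pair_in_remaining"

    def __post_init__(self) -> None:
        if not 0 <= self.trim_fraction < 0.5:
            raise InputError("trim_fraction must be in [0, 0.5)")


@dataclass
class FitResult:
    """Fitted network parameters plus diagnostics."""

    taxa: tuple[str, ...]
    gamma: np.ndarray
    hub_gamma: float
    L_direct: float
    L_hub: float
    hub_mode: str
    objective: float
    residuals: dict[tuple[str, ...], np.ndarray]
    seed: int
    n_iterations: int

    def network(self) -> TaxonNetwork:
        return TaxonNetwork(
            taxa=self.taxa,
            gamma=self.gamma,
            hub_gamma=self.hub_gamma,
            L_direct=self.L_direct,
            L_hub=self.L_hub,
            hub_mode=self.hub_mode,
        )

    def to_dict(self) -> dict:
        return {
            "taxa": list(self.taxa),
            "gamma": self.gamma.tolist(),
            "hub_gamma": self.hub_gamma,
            "L_direct": self.L_direct,
            "L_hub": self.L_hub,
            "hub_mode": self.hub_mode,
            "objective": self.objective,
            "seed": self.seed,
            "n_iterations": self.n_iterations,
            "residual_rms_per_set": {
                ",".join(k): float(np.sqrt(np.mean(v))) for k, v in self.residuals.items()
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    def report(self) -> str:
        lines = ["taxon            transferability"]
        for t, g in zip(self.taxa, self.gamma):
            lines.append(f"{t:<16s} {g:.4g}")
        lines.append(f"{'hub':<16s} {self.hub_gamma:.4g}")
        lines.append(f"L_direct = {self.L_direct:.4g} bp")
        lines.append(f"L_hub    = {self.L_hub:.4g} bp")
        lines.append(f"objective (trimmed mean sq log10 diff) = {self.objective:.4g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Objective
# ---------------------------------------------------------------------------


def _network_from_params(params: np.ndarray, taxa: Sequence[str], hub_mode: str) -> TaxonNetwork:
    n = len(taxa)
    vals = 10.0 ** np.asarray(params, dtype=float)
    return TaxonNetwork(
        taxa=tuple(taxa),
        gamma=vals[:n],
        hub_gamma=float(vals[n]),
        L_direct=float(vals[n + 1]),
        L_hub=float(vals[n + 2]),
        hub_mode=hub_mode,
    )


def _set_residuals(
    mld: MLD,
    network: TaxonNetwork,
    reading: str,
) -> np.ndarray:
    """Squared log10 differences on populated bins (unsorted, untrimmed)."""
    mask = mld.populated
    centers = mld.bin_centers[mask]
    data = mld.density[mask]
    model = total_mld(network, mld.genus_set, centers, reading=reading).m_total
    d = np.full(centers.shape, _ZERO_MODEL_PENALTY)
    ok = model > 0
    d[ok] = (np.log10(data[ok]) - np.log10(model[ok])) ** 2
    return d


def _trim(d: np.ndarray, trim_fraction: float) -> np.ndarray:
    """Drop the floor(trim * B) largest squared residuals of one set."""
    k = int(np.floor(trim_fraction * d.size))
    if k == 0:
        return d
    return np.sort(d)[: d.size - k]


def objective(
    params: np.ndarray,
    mlds: Sequence[MLD],
    taxa: Sequence[str],
    trim_fraction: float = 0.15,
    hub_mode: str = "bidirectional",
    reading: str = "pair_in_remaining",
) -> float:
    """Trimmed mean squared log10-difference over all sets' populated bins.

    ``params`` holds log10 of (gamma_1..gamma_n, gamma_0, L_d, L_h).
    Trimming is one-sided and per set.  Invariant to the order of sets and
    bins; a model density of zero on a populated bin incurs a large,
    trimmable penalty.
    """
    network = _network_from_params(params, taxa, hub_mode)
    retained: list[np.ndarray] = []
    for mld in mlds:
        if mld.is_empty:
            continue
        d = _set_residuals(mld, network, reading)
        if d.size:
            retained.append(_trim(d, trim_fraction))
    if not retained:
        raise FitError("no populated bins in any MLD")
    return float(np.mean(np.concatenate(retained)))


# ---------------------------------------------------------------------------
# Joint network fit: global evolutionary search + local refinement
# ---------------------------------------------------------------------------


def fit_network(
    mlds: Sequence[MLD],
    taxa: Sequence[str],
    config: FitConfig | None = None,
    seed: int = 0,
    hub_mode: str = "bidirectional",
) -> FitResult:
    """Jointly fit gamma_1..gamma_n, gamma_0, L_d, L_h to the given MLDs.

    Deterministic for a given seed.  ``mlds`` should cover at least the
    pairwise sets; every genus appearing in a set must be listed in ``taxa``.
    """
    config = config or FitConfig()
    taxa = tuple(taxa)
    n = len(taxa)
    if n < 2:
        raise InputError("need at least two taxa")
    usable = [m for m in mlds if not m.is_empty]
    if not usable:
        raise FitError("all MLDs are empty")
    for m in usable:
        for t in m.genus_set:
            if t not in taxa:
                raise InputError(f"genus {t!r} in an MLD but not in taxa")

    bounds = [config.log_gamma_bounds] * (n + 1) + [config.log_L_bounds] * 2

    def f(x: np.ndarray) -> float:
        return objective(
            x, usable, taxa,
            trim_fraction=config.trim_fraction,
            hub_mode=hub_mode,
            reading=config.reading,
        )

    global_res = differential_evolution(
        f,
        bounds=bounds,
        seed=seed,
        popsize=config.popsize,
        maxiter=config.maxiter,
        tol=config.tol,
        init="sobol",
        polish=False,
    )
    local_res = minimize(
        f,
        global_res.x,
        method="L-BFGS-B",
        bounds=bounds,
        options={"gtol": config.local_gtol, "ftol": 1e-15, "maxiter": 2000},
    )
    best = local_res.x if local_res.fun <= global_res.fun else global_res.x

    network = _network_from_params(best, taxa, hub_mode)
    residuals = {
        m.genus_set: _set_residuals(m, network, config.reading) for m in usable
    }
    vals = 10.0**best
    return FitResult(
        taxa=taxa,
        gamma=vals[:n],
        hub_gamma=float(vals[n]),
        L_direct=float(vals[n + 1]),
        L_hub=float(vals[n + 2]),
        hub_mode=hub_mode,
        objective=float(min(local_res.fun, global_res.fun)),
        residuals=residuals,
        seed=seed,
        n_iterations=int(global_res.nit) + int(local_res.nit),
    )


# ---------------------------------------------------------------------------
# Exponential mixtures for episodic MLDs
# ---------------------------------------------------------------------------


@dataclass
class ExpMixture:
    """Mixture sum_k A_k exp(-tau_k r), components ordered by decreasing tau.

    With decreasing tau, successive components dominate at successively
    larger r; ``crossovers[k]`` is the length where components k and k+1 have
    equal density: r* = ln(A_k / A_{k+1}) / (tau_k - tau_{k+1}).
    """

    amplitudes: np.ndarray
    rates: np.ndarray
    cost: float = 0.0

    @property
    def K(self) -> int:
        return self.amplitudes.size

    @property
    def crossovers(self) -> np.ndarray:
        A, tau = self.amplitudes, self.rates
        return np.array(
            [
                np.log(A[k] / A[k + 1]) / (tau[k] - tau[k + 1])
                for k in range(self.K - 1)
            ]
        )

    def __call__(self, r) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return (self.amplitudes[:, None] * np.exp(-np.outer(self.rates, r))).sum(axis=0)


def fit_exp_mixture(
    mld: MLD,
    K: int,
    seed: int = 0,
    n_restarts: int = 10,
    trim_fraction: float = 0.0,
) -> ExpMixture:
    """Least-squares (log10 space) fit of K exponentials to an MLD.

    Multistart over ``n_restarts`` seeded initializations with decay rates
    log-spaced across [1/r_max, 1/r_min]; the best local optimum is kept.
    """
    if K < 1:
        raise InputError("K must be >= 1")
    if mld.is_empty:
        raise FitError("empty MLD")
    mask = mld.populated
    r = mld.bin_centers[mask]
    y = np.log10(mld.density[mask])
    if r.size <= 2 * K:
        raise FitError(f"{r.size} populated bins cannot constrain {K} exponentials")

    log_tau_lo = np.log10(0.1 / r.max())
    log_tau_hi = np.log10(10.0 / r.min())

    def residual(x: np.ndarray) -> np.ndarray:
        A = 10.0 ** x[:K]
        tau = 10.0 ** x[K:]
        model = (A[:, None] * np.exp(-np.outer(tau, r))).sum(axis=0)
        res = y - np.log10(np.maximum(model, 1e-300))
        if trim_fraction > 0:
            k = int(np.floor(trim_fraction * res.size))
            if k:
                keep = np.argsort(np.abs(res))[: res.size - k]
                res = res[keep]
        return res

    rng = np.random.default_rng(seed)
    best: ExpMixture | None = None
    for attempt in range(n_restarts):
        log_tau0 = np.linspace(log_tau_hi - 0.5, log_tau_lo + 0.5, K)
        if attempt:
            log_tau0 = log_tau0 + rng.uniform(-0.5, 0.5, size=K)
        tau0 = 10.0**log_tau0
        # amplitude guesses: each component matched to the data at the length
        # where its decay argument is ~1
        A0 = np.empty(K)
        for k in range(K):
            r_k = np.clip(1.0 / tau0[k], r.min(), r.max())
            y_k = np.interp(r_k, r, y)
            A0[k] = y_k + tau0[k] * r_k / np.log(10.0)
        x0 = np.concatenate([A0, log_tau0])
        lb = np.concatenate([np.full(K, -40.0), np.full(K, log_tau_lo - 1)])
        ub = np.concatenate([np.full(K, 40.0), np.full(K, log_tau_hi + 1)])
        try:
            res = least_squares(residual, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14)
        except ValueError:
            continue
        cost = float(res.cost)
        if best is None or cost < best.cost:
            A = 10.0 ** res.x[:K]
            tau = 10.0 ** res.x[K:]
            order = np.argsort(tau)[::-1]
            best = ExpMixture(A[order], tau[order], cost)
    if best is None:
        raise FitError("all mixture fits failed")
    return best
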