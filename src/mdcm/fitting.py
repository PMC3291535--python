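"""Parameterization of the mDCM against experimental heat-capacity data.

The fitting parameters are {u_sol, v_nat, delta_nat}; v_dis, delta_dis and
the gamma_hb(u_hb) coefficients stay fixed.  Two modes are supported:
``three_param`` fits all three, ``two_param`` holds the entropic parameter
delta_nat fixed (default 1.24) and fits only {u_sol, v_nat} — the entropic
parameter is related to the protein fold and can be shared across a
dataset.

The residual is the mean squared difference between the model Cp(T) and the
data after subtracting the best constant baseline offset (DSC baselines
make an offset term necessary; Cp is a temperature derivative, so a
constant offset is the natural nuisance).  Minimization uses simulated
annealing: Gaussian proposals reflected at the parameter bounds, Metropolis
acceptance, geometric cooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from .ensemble import LandscapeBuilder
from .network import ConstraintNetwork, DCMParameters, R_GAS

__all__ = ["AnnealingSchedule", "FitResult", "fit_cp", "model_cp"]


@dataclass(frozen=True)
class AnnealingSchedule:
    """Geometric-cooling schedule for the annealer."""

    n_steps: int = 200
    proposals_per_step: int = 20
    cooling: float = 0.95
    t0_factor: float = 10.0       # initial temperature ~ t0_factor * initial residual
    proposal_scale: float = 0.08  # Gaussian sd as a fraction of each bound range
    n_restarts: int = 3           # short exploratory anneals before the main run


DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "u_sol": (-4.0, -0.5),
    "v_nat": (-1.2, -0.02),
    "delta_nat": (0.6, 2.2),
}


@dataclass
class FitResult:
    params: DCMParameters
    objective: float
    tm_model: float
    baseline_offset: float
    n_evaluations: int
    seed: int
    mode: str
    bounds: dict[str, tuple[float, float]]
    history: list[float] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "seed": self.seed,
            "objective": self.objective,
            "tm_model": self.tm_model,
            "baseline_offset": self.baseline_offset,
            "n_evaluations": self.n_evaluations,
            "u_sol": self.params.u_sol,
            "v_nat": self.params.v_nat,
            "delta_nat": self.params.delta_nat,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
        }


def model_cp(builder: LandscapeBuilder, T: np.ndarray, grid_points=None) -> np.ndarray:
    """Model Cp on the data grid: d<U>/dT by centered differences."""
    grid_points = grid_points or builder.all_grid_points()
    g, u = builder.grid_thermo(np.asarray(T, float), grid_points)
    logp = -g / (R_GAS * np.asarray(T, float)[:, None])
    logp -= logp.max(axis=1, keepdims=True)
    pz = np.exp(logp)
    pz /= pz.sum(axis=1, keepdims=True)
    mean_u = np.sum(pz * u, axis=1)
    return np.gradient(mean_u, T)


def _objective(cp_data: np.ndarray, cp_model: np.ndarray) -> tuple[float, float]:
    offset = float(np.mean(cp_data - cp_model))
    resid = cp_data - cp_model - offset
    return float(np.mean(resid**2)), offset


def fit_cp(
    net: ConstraintNetwork,
    cp_data: tuple[Sequence[float], Sequence[float]],
    mode: str = "two_param",
    bounds: dict[str, tuple[float, float]] | None = None,
    schedule: AnnealingSchedule | None = None,
    seed: int = 0,
    delta_nat_fixed: float = 1.24,
    base_params: DCMParameters | None = None,
    start: dict[str, float] | None = None,
) -> FitResult:
    """Fit mDCM parameters to a (T, Cp) table by simulated annealing.

    ``cp_data`` must span a single Cp peak.  The network must be small
    enough for exact enumeration of its macrostates (the fit re-evaluates
    the landscape thousands of times; framework-level rigidity results are
    cached, so each evaluation is pure arithmetic).
    """
    if mode not in ("two_param", "three_param"):
        raise ValueError(f"unknown mode {mode!r}")
    bounds = dict(DEFAULT_BOUNDS, **(bounds or {}))
    schedule = schedule or AnnealingSchedule()
    base = base_params or DCMParameters()
    # keep proposals inside the model's ordering invariants
    if bounds["v_nat"][1] >= base.v_dis:
        raise ValueError("v_nat bounds must keep v_nat < v_dis")
    lo_d, hi_d = bounds["delta_nat"]
    bounds["delta_nat"] = (lo_d, min(hi_d, base.delta_dis - 1e-6))

    T = np.asarray(cp_data[0], float)
    cp = np.asarray(cp_data[1], float)
    if T.ndim != 1 or T.shape != cp.shape or len(T) < 5:
        raise ValueError("cp_data must be matching (T, Cp) vectors with >= 5 points")
    order = np.argsort(T)
    T, cp = T[order], cp[order]

    names = ["u_sol", "v_nat"] + (["delta_nat"] if mode == "three_param" else [])
    rng = np.random.default_rng(seed)

    fixed_delta = delta_nat_fixed if mode == "two_param" else None

    def make_params(theta: np.ndarray) -> DCMParameters:
        kw = dict(zip(names, theta))
        if fixed_delta is not None:
            kw["delta_nat"] = fixed_delta
        return replace(base, **kw)

    builder = LandscapeBuilder(net, make_params(np.array([np.mean(bounds[n]) for n in names])),
                               exhaustive_only=True)

    n_eval = 0
    any_interior_peak = False

    def evaluate(theta: np.ndarray) -> tuple[float, float, float]:
        nonlocal n_eval, any_interior_peak
        builder.params = make_params(theta)
        cp_m = model_cp(builder, T)
        n_eval += 1
        imax = int(np.argmax(cp_m))
        if 0 < imax < len(T) - 1:
            any_interior_peak = True
        obj, off = _objective(cp, cp_m)
        tmx = float(T[imax])
        return obj, off, tmx

    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    base_scales = np.array(
        [schedule.proposal_scale * (bounds[n][1] - bounds[n][0]) for n in names]
    )
    history: list[float] = []

    def anneal(theta0, n_steps, shrink_floor=0.02, t0_factor=None, scale_mult=1.0):
        theta = theta0.copy()
        obj, off, tmx = evaluate(theta)
        best = (obj, theta.copy(), off, tmx)
        temp = (schedule.t0_factor if t0_factor is None else t0_factor) * max(obj, 1e-12)
        for step in range(n_steps):
            # proposal width shrinks with the annealing temperature so late
            # steps polish the minimum instead of re-exploring the box
            scales = base_scales * scale_mult * max(schedule.cooling ** (0.5 * step), shrink_floor)
            for _ in range(schedule.proposals_per_step):
                prop = theta + rng.normal(size=len(names)) * scales
                prop = np.where(prop < lo, 2 * lo - prop, prop)  # reflect
                prop = np.where(prop > hi, 2 * hi - prop, prop)
                prop = np.clip(prop, lo, hi)
                obj_p, off_p, tmx_p = evaluate(prop)
                if obj_p <= obj or rng.random() < np.exp(-(obj_p - obj) / max(temp, 1e-300)):
                    theta, obj, off, tmx = prop, obj_p, off_p, tmx_p
                    if obj < best[0]:
                        best = (obj, theta.copy(), off, tmx)
            history.append(obj)
            temp *= schedule.cooling
        return best

    # exploratory restarts, then the full schedule from the best start
    candidates = []
    if start is not None:
        candidates.append(np.array([start[n] for n in names]))
    for _ in range(max(schedule.n_restarts - len(candidates), 1)):
        candidates.append(np.array([rng.uniform(*bounds[n]) for n in names]))
    probe_steps = max(schedule.n_steps // 6, 10)
    probes = [anneal(theta0, probe_steps, shrink_floor=0.25) for theta0 in candidates]
    best_probe = min(probes, key=lambda b: b[0])
    best = anneal(best_probe[1], schedule.n_steps)
    if best_probe[0] < best[0]:
        best = best_probe
    # cold greedy polish: near-zero temperature, narrow proposals
    polish = anneal(
        best[1], max(schedule.n_steps // 3, 20),
        shrink_floor=0.05, t0_factor=1e-6, scale_mult=0.08,
    )
    if polish[0] < best[0]:
        best = polish

    if not any_interior_peak:
        raise ValueError(
            "model Cp peak fell outside the data range for every sampled parameter "
            "set; widen the parameter bounds or the data temperature range"
        )

    obj_b, theta_b, off_b, tm_b = best
    return FitResult(
        params=make_params(theta_b),
        objective=obj_b,
        tm_model=tm_b,
        baseline_offset=off_b,
        n_evaluations=n_eval,
        seed=seed,
        mode=mode,
        bounds=bounds,
        history=history,
    )
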