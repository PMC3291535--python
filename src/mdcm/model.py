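"""Model/Results interface to the minimal Distance Constraint Model.

:class:`DistanceConstraintModel` is built from a constraint network (or
directly from a prepared PDB structure) plus an experimental heat-capacity
curve; ``fit()`` runs the simulated-annealing parameterization and returns
a :class:`DCMResults` carrying the fitted parameters, their restart spread,
the thermodynamic curves (Cp(T), Tm), the native-basin QSFR observables
(per-residue flexibility index and the cooperativity-correlation matrix)
and a ``summary()`` table.  Simulation (synthetic Cp) and plotting hooks
hang off the two objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import structure as sio
from .ensemble import LandscapeBuilder, Landscape, _landscape_at, heat_capacity
from .fitting import AnnealingSchedule, FitResult, fit_cp
from .network import ConstraintNetwork, DCMParameters, NetworkConfig, build_network
from .qsfr import QSFRProfile, ensemble_qsfr

__all__ = ["DistanceConstraintModel", "DCMResults"]


class DistanceConstraintModel:
    """Minimal Distance Constraint Model for one structure.

    Parameters
    ----------
    network : ConstraintNetwork
        The body-bar framework (covalent bonds, candidate H-bonds, torsions).
    cp_data : (T, Cp) pair, optional
        Experimental heat-capacity curve; temperatures in K, Cp in
        kcal/(mol K).  Required for :meth:`fit`.
    params : DCMParameters, optional
        Starting/fixed parameter set (fixed constants are taken from here).
    """

    def __init__(
        self,
        network: ConstraintNetwork,
        cp_data: tuple[Sequence[float], Sequence[float]] | None = None,
        params: DCMParameters | None = None,
        config: NetworkConfig | None = None,
    ):
        network.validate()
        self.network = network
        self.cp_data = None
        if cp_data is not None:
            T = np.asarray(cp_data[0], float)
            cp = np.asarray(cp_data[1], float)
            order = np.argsort(T)
            self.cp_data = (T[order], cp[order])
        self.params = params or DCMParameters()
        self.config = config or NetworkConfig()

    @classmethod
    def from_structure(
        cls,
        path_or_atoms,
        cp_data=None,
        params: DCMParameters | None = None,
        config: NetworkConfig | None = None,
    ) -> "DistanceConstraintModel":
        """Build the maximal constraint graph from a prepared PDB structure
        (protonated, minimized) or a list of AtomRecords."""
        params = params or DCMParameters()
        config = config or NetworkConfig()
        if isinstance(path_or_atoms, (str,)) or hasattr(path_or_atoms, "__fspath__"):
            atoms = sio.read_structure(path_or_atoms)
        else:
            atoms = list(path_or_atoms)
        net = build_network(atoms, params, config)
        model = cls(net, cp_data=cp_data, params=params, config=config)
        model.atoms = atoms
        return model

    # ------------------------------------------------------------------
    def fit(
        self,
        mode: str = "two_param",
        seed: int = 0,
        schedule: AnnealingSchedule | None = None,
        bounds: dict | None = None,
        delta_nat_fixed: float = 1.24,
        n_restarts_spread: int = 0,
        qsfr: bool = True,
        grid_stride: int = 1,
        n_samples: int = 300,
    ) -> "DCMResults":
        """Fit {u_sol, v_nat[, delta_nat]} to the Cp curve, then solve the
        landscape at Tm and average FI/CC over the native basin.

        ``n_restarts_spread`` > 0 repeats the fit from different seeds and
        reports the parameter spread as an uncertainty estimate.
        """
        if self.cp_data is None:
            raise ValueError("cp_data is required to fit the model")
        fit = fit_cp(
            self.network, self.cp_data, mode=mode, bounds=bounds,
            schedule=schedule, seed=seed, delta_nat_fixed=delta_nat_fixed,
            base_params=self.params,
        )
        spread = {}
        if n_restarts_spread > 0:
            others = [
                fit_cp(
                    self.network, self.cp_data, mode=mode, bounds=bounds,
                    schedule=schedule, seed=seed + 1 + k,
                    delta_nat_fixed=delta_nat_fixed, base_params=self.params,
                )
                for k in range(n_restarts_spread)
            ]
            allfits = [fit] + others
            for name in ("u_sol", "v_nat", "delta_nat"):
                vals = np.array([getattr(f.params, name) for f in allfits])
                spread[name] = float(vals.std(ddof=0))
        return self.solve(fit.params, fit=fit, param_spread=spread, seed=seed,
                          qsfr=qsfr, grid_stride=grid_stride, n_samples=n_samples)

    def solve(
        self,
        params: DCMParameters | None = None,
        fit: FitResult | None = None,
        param_spread: dict | None = None,
        seed: int = 0,
        qsfr: bool = True,
        grid_stride: int = 1,
        n_samples: int = 300,
        T_grid: Sequence[float] | None = None,
    ) -> "DCMResults":
        """Solve the landscape at given (or previously fitted) parameters."""
        params = params or self.params
        if T_grid is None:
            if self.cp_data is not None:
                T_grid = self.cp_data[0]
            else:
                raise ValueError("provide T_grid when no cp_data is attached")
        builder = LandscapeBuilder(self.network, params, n_samples=n_samples, seed=seed)
        Ts, cp, tm = heat_capacity(builder, T_grid)
        landscape = _landscape_at(builder, tm, grid_stride, mech=qsfr, tm=tm, cp_curve=(Ts, cp))
        profile = None
        if qsfr and landscape.native_basin:
            profile = ensemble_qsfr(landscape, self.network)
        return DCMResults(
            model=self,
            params=params,
            fit=fit,
            param_spread=param_spread or {},
            tm=tm,
            cp_curve=(Ts, cp),
            landscape=landscape,
            qsfr=profile,
        )


@dataclass
class DCMResults:
    """Fitted mDCM: parameters, thermodynamics and mechanical observables."""

    model: DistanceConstraintModel
    params: DCMParameters
    tm: float
    cp_curve: tuple[np.ndarray, np.ndarray]
    landscape: Landscape
    fit: FitResult | None = None
    param_spread: dict = field(default_factory=dict)
    qsfr: QSFRProfile | None = None

    # -- accessors ------------------------------------------------------
    @property
    def fi_residue(self) -> dict[int, float] | None:
        return self.qsfr.fi_residue if self.qsfr else None

    @property
    def cc_residue(self) -> np.ndarray | None:
        return self.qsfr.cc_residue if self.qsfr else None

    def summary(self) -> str:
        """Plain-text summary table in the spirit of a regression results
        summary: parameters (with restart spread when available),
        thermodynamic outputs and basin diagnostics."""
        net = self.model.network
        lines = []
        push = lines.append
        push("Minimal Distance Constraint Model results")
        push("=" * 57)
        push(f"{'bodies':<28}{net.n_bodies:>10d}")
        push(f"{'a-priori rotatable bonds':<28}{net.n_tor:>10d}")
        push(f"{'candidate H-bonds':<28}{net.n_hb_max:>10d}")
        if self.fit is not None:
            push(f"{'fit mode':<28}{self.fit.mode:>10s}")
            push(f"{'fit objective (MSE)':<28}{self.fit.objective:>10.3e}")
            push(f"{'fit evaluations':<28}{self.fit.n_evaluations:>10d}")
        push("-" * 57)
        for name in ("u_sol", "v_nat", "delta_nat"):
            val = getattr(self.params, name)
            sd = self.param_spread.get(name)
            unit = "kcal/mol" if name != "delta_nat" else ""
            if sd is not None:
                push(f"{name:<14}{val:>12.4f}  +/- {sd:<8.4f}{unit}")
            else:
                push(f"{name:<14}{val:>12.4f}  {'':<12}{unit}")
        push("-" * 57)
        push(f"{'Tm (Cp argmax)':<28}{self.tm:>10.1f} K")
        cpmax = float(np.max(self.cp_curve[1]))
        push(f"{'max Cp':<28}{cpmax:>10.4f} kcal/(mol K)")
        push(f"{'native basin size':<28}{len(self.landscape.native_basin):>10d}")
        if self.landscape.basin_min is not None:
            push(f"{'basin minimum (Nnat, Nhb)':<28}{str(self.landscape.basin_min):>10s}")
        if self.qsfr is not None:
            fi = self.qsfr.fi_bond
            push(f"{'mean bond FI':<28}{float(np.mean(fi)):>10.4f}")
            push(f"{'FI range':<28}" + f"[{fi.min():.3f}, {fi.max():.3f}]".rjust(10))
        return "\n".join(lines)

    # -- simulation and plotting ---------------------------------------
    def simulate_cp(self, T_grid=None, noise_sd: float = 0.0, seed: int = 0):
        """Synthetic Cp from this fitted model (see synthetic.make_synthetic_cp)."""
        from .synthetic import make_synthetic_cp

        T_grid = T_grid if T_grid is not None else self.cp_curve[0]
        return make_synthetic_cp(self.model.network, self.params, T_grid,
                                 noise_sd=noise_sd, seed=seed)

    def plot_cp(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        T, cp = self.cp_curve
        ax.plot(T, cp, label="model Cp")
        if self.model.cp_data is not None:
            ax.plot(*self.model.cp_data, ".", ms=4, label="data")
        ax.axvline(self.tm, ls="--", color="grey", lw=0.8)
        ax.set_xlabel("T (K)")
        ax.set_ylabel("Cp (kcal/mol/K)")
        ax.legend()
        return ax

    def plot_fi(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.fi_residue:
            res = sorted(self.fi_residue)
            ax.plot(res, [self.fi_residue[r] for r in res], "-o", ms=3)
            ax.set_xlabel("residue")
        elif self.qsfr is not None:
            ax.plot(self.qsfr.bond_ids, self.qsfr.fi_bond, "-o", ms=3)
            ax.set_xlabel("rotatable bond")
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_ylabel("flexibility index")
        return ax
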