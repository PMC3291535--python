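"""Free-energy landscape over (N_nat, N_hb) macrostates.

The mDCM ensemble is organised by two order parameters: the number of
engaged native torsions N_nat and the number of engaged H-bonds N_hb.  The
free energy of a macrostate is

    G(N_nat, N_hb) = U - T (S_mix + S_conf)

with the enthalpy bracket

    U = <sum of engaged u_hb> + (N_hb_max - N_hb) u_sol
        + N_nat v_nat + (N_tor - N_nat) v_dis,

the mixing entropy S_mix = R [ln C(N_tor, N_nat) + ln C(N_hb_max, N_hb)]
counting the placements consistent with the order parameters, and the
conformational entropy

    S_conf = R [ sum_i pi_i q_i gamma_i  +  q_nat N_nat delta_nat
                 +  q_dis (N_tor - N_nat) delta_dis ],

where pi_i is the probability that H-bond i is present in the macrostate,
and the q's are the conditional probabilities for a constraint to be
*independent* when present, measured by the pebble game.  Attenuating each
entropy component by its q restores the usefulness of a free-energy
decomposition: were all q = 1 the sum would revert to a plain additive
scheme.

Within a macrostate, frameworks are distributed with per-bond Gibbs factors
g_i = exp(-(u_i - u_sol)/RT) for the H-bond pattern (a conditional-Bernoulli
law over patterns with exactly N_hb bonds) and uniformly over native-torsion
placements.  Because the selection weights do not depend on the q's, the
mean-field self-consistency loop converges at its first update; the loop is
retained for generality and its tolerance is configurable.  Small systems
are enumerated exhaustively (flagged in metadata); larger ones are sampled
by Monte Carlo with exact conditional-Bernoulli draws, which makes the
sampling path an unbiased estimator of the enumeration path.

Heat capacity is computed as Cp(T) = d<U>/dT by centered finite differences
of the landscape-averaged enthalpy (stabler under sampling noise than a
second derivative of G), and the melting temperature Tm is the Cp argmax
refined by quadratic interpolation.  Near Tm the landscape shows two basins
separated by a saddle; mechanical observables are Gibbs-averaged over the
native (high-engagement) basin at Tm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .network import ConstraintNetwork, DCMParameters, R_GAS
from .pebble import run_pebble_game

__all__ = [
    "Macrostate",
    "Landscape",
    "LandscapeBuilder",
    "sample_macrostate",
    "mixing_entropy",
    "conformational_entropy",
    "free_energy",
    "build_landscape",
    "heat_capacity",
    "native_basin_average",
]


def log_binomial(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -np.inf
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


@dataclass
class Macrostate:
    """One point of the order-parameter grid with its conditional averages."""

    n_nat: int
    n_hb: int
    q: np.ndarray                  # per-H-bond conditional independence prob
    q_nat: float
    q_dis: float
    pi: np.ndarray                 # per-H-bond presence probability
    mean_enthalpy: float           # kcal/mol, includes solvent/torsion bracket
    s_mix: float                   # kcal/(mol K)
    s_conf: float                  # kcal/(mol K)
    free_energy: float             # kcal/mol at the evaluation temperature
    temperature: float
    exhaustive: bool
    n_samples: int
    mech: dict | None = None       # {"fi": (n_bonds,), "fpair": (n_bonds, n_bonds)}


@dataclass
class Landscape:
    """2D free-energy landscape at one temperature."""

    temperature: float
    n_tor: int
    n_hb_max: int
    grid_points: list[tuple[int, int]]
    macrostates: dict[tuple[int, int], Macrostate]
    tm: float | None = None
    cp_curve: tuple[np.ndarray, np.ndarray] | None = None
    native_basin: dict[tuple[int, int], float] = field(default_factory=dict)
    basin_min: tuple[int, int] | None = None
    saddle_free_energy: float | None = None
    metadata: dict = field(default_factory=dict)

    def free_energy_grid(self) -> np.ndarray:
        g = np.full((self.n_tor + 1, self.n_hb_max + 1), np.nan)
        for (j, k), mac in self.macrostates.items():
            g[j, k] = mac.free_energy
        return g


# ---------------------------------------------------------------------------
# Per-pattern statistics (pebble game results, cached)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _PatternStats:
    u_hb_sum: float
    indep_frac: tuple[float, ...]    # per H-bond, 0.0 when absent
    nat_indep: int
    dis_indep: int
    fi: tuple[float, ...] | None
    cluster_of: tuple[int, ...] | None
    cluster_f: tuple[float, ...] | None


class LandscapeBuilder:
    """Evaluates macrostates and landscapes for one network + parameter set.

    Framework-level pebble results are cached by engagement pattern, so the
    thermodynamic arithmetic (which is all that changes with T or with the
    fitting parameters) stays cheap.  Exhaustive enumeration is used when
    the macrostate holds at most ``exhaustive_cutoff`` patterns, otherwise
    ``n_samples`` Monte-Carlo draws.
    """

    def __init__(
        self,
        net: ConstraintNetwork,
        params: DCMParameters,
        n_samples: int = 300,
        exhaustive_cutoff: int = 4096,
        exhaustive_only: bool = False,
        seed: int = 0,
        mf_tolerance: float = 1e-4,
        mf_max_iter: int = 50,
    ):
        net.validate()
        self.net = net
        self.params = params
        self.n_samples = int(n_samples)
        self.exhaustive_cutoff = int(exhaustive_cutoff)
        self.exhaustive_only = bool(exhaustive_only)
        self.seed = int(seed)
        self.mf_tolerance = mf_tolerance
        self.mf_max_iter = mf_max_iter

        self.hb_ids = [c.id for c in net.hbonds]
        self.hb_u = np.array([c.enthalpy for c in net.hbonds], float)
        self.hb_gamma = np.array([c.entropy_weight for c in net.hbonds], float)
        self.bond_ids = [b.id for b in net.rotatable_bonds]
        self.n_hb_max = len(self.hb_ids)
        self.n_tor = len(self.bond_ids)
        self._pattern_cache: dict[tuple[frozenset, frozenset], _PatternStats] = {}
        self._mech_cache: dict[tuple[frozenset, frozenset], _PatternStats] = {}

    # -- pattern-level pebble statistics ------------------------------------
    def _pattern_stats(self, hb_pat: frozenset, nat_pat: frozenset, mech: bool) -> _PatternStats:
        cache = self._mech_cache if mech else self._pattern_cache
        key = (hb_pat, nat_pat)
        hit = self._mech_cache.get(key) or (None if mech else self._pattern_cache.get(key))
        if hit is not None:
            return hit
        decomp = run_pebble_game(self.net, engaged_hbonds=hb_pat, native_torsions=nat_pat)
        idx_of = {cid: i for i, cid in enumerate(self.hb_ids)}
        indep = [0.0] * self.n_hb_max
        for cid in hb_pat:
            indep[idx_of[cid]] = decomp.constraint_independence(cid)
        u_sum = float(sum(self.hb_u[idx_of[cid]] for cid in hb_pat))
        if mech:
            fi = tuple(decomp.bond_f(b) for b in self.bond_ids)
            cl = tuple(decomp.bond_cluster[b] for b in self.bond_ids)
            cf = tuple(c.f for c in decomp.clusters)
        else:
            fi = cl = cf = None
        stats = _PatternStats(
            u_hb_sum=u_sum,
            indep_frac=tuple(indep),
            nat_indep=decomp.n_nat_indep,
            dis_indep=decomp.n_dis_indep,
            fi=fi,
            cluster_of=cl,
            cluster_f=cf,
        )
        cache[key] = stats
        return stats

    # -- pattern generation --------------------------------------------------
    def _n_patterns(self, n_nat: int, n_hb: int) -> float:
        return math.comb(self.n_tor, n_nat) * math.comb(self.n_hb_max, n_hb)

    def _enumerate_patterns(self, n_nat: int, n_hb: int) -> list[tuple[frozenset, frozenset]]:
        from itertools import combinations

        hb_pats = [frozenset(c) for c in combinations(self.hb_ids, n_hb)]
        nat_pats = [frozenset(c) for c in combinations(self.bond_ids, n_nat)]
        return [(h, t) for h in hb_pats for t in nat_pats]

    def _sample_patterns(
        self, n_nat: int, n_hb: int, T: float, n_samples: int, rng: np.random.Generator
    ) -> list[tuple[frozenset, frozenset]]:
        logw = -(self.hb_u - self.params.u_sol) / (R_GAS * T)
        chooser = _ConditionalBernoulli(logw, n_hb)
        out = []
        bond_arr = np.array(self.bond_ids)
        for _ in range(n_samples):
            hb_pat = frozenset(self.hb_ids[i] for i in chooser.draw(rng))
            nat_pat = frozenset(
                int(x) for x in rng.choice(bond_arr, size=n_nat, replace=False)
            ) if n_nat else frozenset()
            out.append((hb_pat, nat_pat))
        return out

    # -- macrostate evaluation ----------------------------------------------
    def evaluate(self, n_nat: int, n_hb: int, T: float, mech: bool = False) -> Macrostate:
        if not (0 <= n_nat <= self.n_tor and 0 <= n_hb <= self.n_hb_max):
            raise ValueError("order parameters out of range")
        exhaustive = self.exhaustive_only or self._n_patterns(n_nat, n_hb) <= self.exhaustive_cutoff
        if exhaustive:
            patterns = self._enumerate_patterns(n_nat, n_hb)
            # exact conditional-Bernoulli weights over patterns
            logw = np.array(
                [-self._pattern_stats(h, t, False).u_hb_sum / (R_GAS * T) for h, t in patterns]
            )
            w = np.exp(logw - logsumexp(logw))
            n_used = len(patterns)
        else:
            rng = np.random.default_rng([self.seed, n_nat, n_hb, int(T * 1000)])
            patterns = self._sample_patterns(n_nat, n_hb, T, self.n_samples, rng)
            w = np.full(len(patterns), 1.0 / len(patterns))
            n_used = self.n_samples

        stats = [self._pattern_stats(h, t, mech) for h, t in patterns]
        u_sums = np.array([s.u_hb_sum for s in stats])
        indep = np.array([s.indep_frac for s in stats]) if self.n_hb_max else np.zeros((len(stats), 0))
        present = indep_present_matrix(patterns, self.hb_ids)
        nat_ind = np.array([s.nat_indep for s in stats], float)
        dis_ind = np.array([s.dis_indep for s in stats], float)

        p = self.params
        n_dis = self.n_tor - n_nat
        pi = w @ present if self.n_hb_max else np.zeros(0)
        qn = w @ indep if self.n_hb_max else np.zeros(0)
        with np.errstate(invalid="ignore", divide="ignore"):
            q = np.where(pi > 0, qn / np.maximum(pi, 1e-300), 1.0)
        q_nat = float(w @ nat_ind) / n_nat if n_nat else 1.0
        q_dis = float(w @ dis_ind) / n_dis if n_dis else 1.0

        mean_u = (
            float(w @ u_sums)
            + (self.n_hb_max - n_hb) * p.u_sol
            + n_nat * p.v_nat
            + n_dis * p.v_dis
        )
        s_mix = mixing_entropy(n_nat, n_hb, self.n_tor, self.n_hb_max)
        s_conf = R_GAS * (
            float(qn @ self.hb_gamma)
            + q_nat * n_nat * p.delta_nat
            + q_dis * n_dis * p.delta_dis
        )
        g = mean_u - T * (s_mix + s_conf)

        mech_out = None
        if mech:
            fi_mat = np.array([s.fi for s in stats])
            fbar = w @ fi_mat
            n_bonds = self.n_tor
            fpair = np.zeros((n_bonds, n_bonds))
            for wk, s in zip(w, stats):
                cl = np.asarray(s.cluster_of)
                cf = np.asarray(s.cluster_f)
                fvals = cf[cl]
                same = cl[:, None] == cl[None, :]
                fpair += wk * np.where(same, fvals[:, None], 0.0)
            mech_out = {"fi": fbar, "fpair": fpair}

        return Macrostate(
            n_nat=n_nat,
            n_hb=n_hb,
            q=q,
            q_nat=q_nat,
            q_dis=q_dis,
            pi=pi,
            mean_enthalpy=mean_u,
            s_mix=s_mix,
            s_conf=s_conf,
            free_energy=g,
            temperature=T,
            exhaustive=exhaustive,
            n_samples=n_used,
            mech=mech_out,
        )

    # -- fast enthalpy/free-energy grids (for Cp scans and fitting) ----------
    def grid_thermo(
        self,
        T_arr: np.ndarray,
        grid_points: Sequence[tuple[int, int]],
        sample_T: float | None = None,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized G and <U> of shape (n_T, n_grid), without building
        Macrostate objects.  All pattern-level rigidity results are cached,
        so this is pure array arithmetic.

        For macrostates too large to enumerate, patterns are Monte-Carlo
        sampled once at ``sample_T`` (default: the median of ``T_arr``) and
        reweighted to every other temperature by self-normalized importance
        weights — the sampled and target conditional-Bernoulli laws differ
        only through exp(-beta * sum u)."""
        p = self.params
        T_arr = np.atleast_1d(np.asarray(T_arr, float))
        beta = 1.0 / (R_GAS * T_arr)
        if sample_T is None:
            sample_T = float(np.median(T_arr))
        g_out = np.empty((len(T_arr), len(grid_points)))
        u_out = np.empty((len(T_arr), len(grid_points)))
        for idx, (n_nat, n_hb) in enumerate(grid_points):
            u_sums, I_gamma, nat_ind, dis_ind, log_prop = self._grid_cache_entry(
                n_nat, n_hb, sample_T
            )
            logw = -np.outer(beta, u_sums) - log_prop[None, :]   # (n_T, F)
            logw -= logw.max(axis=1, keepdims=True)
            w = np.exp(logw)
            w /= w.sum(axis=1, keepdims=True)
            n_dis = self.n_tor - n_nat
            mean_u = (
                w @ u_sums
                + (self.n_hb_max - n_hb) * p.u_sol
                + n_nat * p.v_nat
                + n_dis * p.v_dis
            )
            q_nat_n = (w @ nat_ind) if n_nat else np.full(len(T_arr), 0.0)
            q_dis_n = (w @ dis_ind) if n_dis else np.full(len(T_arr), 0.0)
            s_mix = mixing_entropy(n_nat, n_hb, self.n_tor, self.n_hb_max)
            s_conf = R_GAS * (
                (w @ I_gamma)
                + q_nat_n * p.delta_nat
                + q_dis_n * p.delta_dis
            )
            g_out[:, idx] = mean_u - T_arr * (s_mix + s_conf)
            u_out[:, idx] = mean_u
        return g_out, u_out

    def _grid_arrays(self, T: float, grid_points: Sequence[tuple[int, int]]):
        g, u = self.grid_thermo(np.array([T]), grid_points)
        return g[0], u[0]

    def _grid_cache_entry(self, n_nat: int, n_hb: int, T: float):
        """Per-macrostate arrays for the fast path.  Exhaustive macrostates
        carry a zero log-proposal (every pattern present once); sampled ones
        record the sampling temperature's log-weights so other temperatures
        can importance-reweight."""
        if not hasattr(self, "_fast_cache"):
            self._fast_cache = {}
        exhaustive = self.exhaustive_only or self._n_patterns(n_nat, n_hb) <= self.exhaustive_cutoff
        key = (n_nat, n_hb) if exhaustive else (n_nat, n_hb, round(float(T), 9))
        if key in self._fast_cache:
            return self._fast_cache[key]
        if exhaustive:
            patterns = self._enumerate_patterns(n_nat, n_hb)
        else:
            rng = np.random.default_rng([self.seed, n_nat, n_hb, int(T * 1000)])
            patterns = self._sample_patterns(n_nat, n_hb, T, self.n_samples, rng)
        stats = [self._pattern_stats(h, t, False) for h, t in patterns]
        u_sums = np.array([s.u_hb_sum for s in stats])
        if self.n_hb_max:
            I = np.array([s.indep_frac for s in stats])
            I_gamma = I @ self.hb_gamma
        else:
            I_gamma = np.zeros(len(stats))
        nat_ind = np.array([s.nat_indep for s in stats], float)
        dis_ind = np.array([s.dis_indep for s in stats], float)
        log_prop = (
            np.zeros(len(stats)) if exhaustive else -u_sums / (R_GAS * float(T))
        )
        entry = (u_sums, I_gamma, nat_ind, dis_ind, log_prop)
        self._fast_cache[key] = entry
        return entry

    def all_grid_points(self, stride: int = 1) -> list[tuple[int, int]]:
        js = sorted(set(list(range(0, self.n_tor + 1, stride)) + [self.n_tor]))
        ks = sorted(set(list(range(0, self.n_hb_max + 1, stride)) + [self.n_hb_max]))
        return [(j, k) for j in js for k in ks]

    def invalidate(self) -> None:
        """Drop parameter-independent caches (pebble stats are kept)."""
        if hasattr(self, "_fast_cache"):
            del self._fast_cache


def indep_present_matrix(patterns, hb_ids) -> np.ndarray:
    idx_of = {cid: i for i, cid in enumerate(hb_ids)}
    out = np.zeros((len(patterns), len(hb_ids)))
    for r, (hb_pat, _) in enumerate(patterns):
        for cid in hb_pat:
            out[r, idx_of[cid]] = 1.0
    return out


class _ConditionalBernoulli:
    """Exact sampling of k-subsets with probability proportional to the
    product of per-item weights, via the elementary-symmetric-polynomial
    recursion (sequential conditional draws)."""

    def __init__(self, logw: np.ndarray, k: int):
        n = len(logw)
        if not 0 <= k <= n:
            raise ValueError("k out of range")
        self.logw = np.asarray(logw, float)
        self.n, self.k = n, k
        logE = np.full((n + 1, k + 1), -np.inf)
        logE[:, 0] = 0.0
        for m in range(n - 1, -1, -1):
            for j in range(1, k + 1):
                logE[m, j] = np.logaddexp(logE[m + 1, j], self.logw[m] + logE[m + 1, j - 1])
        self.logE = logE

    def draw(self, rng: np.random.Generator) -> list[int]:
        chosen: list[int] = []
        j = self.k
        for m in range(self.n):
            if j == 0:
                break
            p = math.exp(self.logw[m] + self.logE[m + 1][j - 1] - self.logE[m][j])
            if rng.random() < p:
                chosen.append(m)
                j -= 1
        return chosen


# ---------------------------------------------------------------------------
# Module-level operations
# ---------------------------------------------------------------------------

def mixing_entropy(n_nat: int, n_hb: int, n_tor: int, n_hb_max: int) -> float:
    """S_mix = R [ln C(N_tor, N_nat) + ln C(N_hb_max, N_hb)], via log-gamma."""
    return R_GAS * (log_binomial(n_tor, n_nat) + log_binomial(n_hb_max, n_hb))


def conformational_entropy(mac: Macrostate, params: DCMParameters, gamma: np.ndarray, n_tor: int) -> float:
    """S_conf from a macrostate's conditional independence probabilities.

    Reverts to the additive sum of all engaged entropy components when every
    q equals 1."""
    n_dis = n_tor - mac.n_nat
    hb_term = float(np.sum(mac.pi * mac.q * gamma)) if gamma.size else 0.0
    return R_GAS * (
        hb_term + mac.q_nat * mac.n_nat * params.delta_nat + mac.q_dis * n_dis * params.delta_dis
    )


def free_energy(mac: Macrostate, T: float, params: DCMParameters) -> float:
    """G = U - T (S_mix + S_conf); linear in T for fixed entropies."""
    return mac.mean_enthalpy - T * (mac.s_mix + mac.s_conf)


def sample_macrostate(
    net: ConstraintNetwork,
    n_nat: int,
    n_hb: int,
    n_samples: int = 300,
    seed: int = 0,
    params: DCMParameters | None = None,
    T: float = 300.0,
    mech: bool = False,
) -> Macrostate:
    """Evaluate one macrostate (exhaustively for tiny networks, else MC)."""
    params = params or DCMParameters()
    builder = LandscapeBuilder(net, params, n_samples=n_samples, seed=seed)
    return builder.evaluate(n_nat, n_hb, T, mech=mech)


def heat_capacity(
    builder: LandscapeBuilder, T_grid: Sequence[float]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Cp(T) = d<U>/dT over the full landscape; Tm = interpolated argmax.

    Raises if the grid has fewer than 5 points or the maximum sits on an
    endpoint (grid too narrow to bracket the transition).
    """
    T = np.asarray(sorted(T_grid), float)
    if len(T) < 5:
        raise ValueError("need at least 5 temperatures spanning the transition")
    grid_points = builder.all_grid_points()
    g, u = builder.grid_thermo(T, grid_points)       # (n_T, n_grid)
    logp = -g / (R_GAS * T[:, None])
    logp -= logp.max(axis=1, keepdims=True)
    pz = np.exp(logp)
    pz /= pz.sum(axis=1, keepdims=True)
    mean_u = np.sum(pz * u, axis=1)
    cp = np.gradient(mean_u, T)
    imax = int(np.argmax(cp))
    if imax in (0, len(T) - 1):
        raise ValueError(
            f"heat-capacity maximum at grid endpoint T = {T[imax]:.1f} K; widen the grid"
        )
    # quadratic interpolation around the discrete maximum
    t0, t1, t2 = T[imax - 1 : imax + 2]
    c0, c1, c2 = cp[imax - 1 : imax + 2]
    denom = (t0 - t1) * (t0 - t2) * (t1 - t2)
    a = (t2 * (c1 - c0) + t1 * (c0 - c2) + t0 * (c2 - c1)) / denom
    b = (t2**2 * (c0 - c1) + t1**2 * (c2 - c0) + t0**2 * (c1 - c2)) / denom
    tm = float(-b / (2 * a)) if a < 0 else float(T[imax])
    return T, cp, tm


def build_landscape(
    net: ConstraintNetwork,
    params: DCMParameters | None = None,
    T: float | None = None,
    T_grid: Sequence[float] | None = None,
    grid_stride: int = 1,
    n_samples: int = 300,
    seed: int = 0,
    mech: bool = False,
    exhaustive_cutoff: int = 4096,
) -> Landscape:
    """Evaluate the landscape; if ``T`` is None it is set to Tm from ``T_grid``.

    Basin/saddle structure is detected by flooding the free-energy grid; the
    native basin is the lake draining the fully-engaged corner, the unfolded
    basin the lake draining (0, 0), and the saddle is the level at which the
    two lakes merge.
    """
    params = params or DCMParameters()
    builder = LandscapeBuilder(
        net, params, n_samples=n_samples, seed=seed, exhaustive_cutoff=exhaustive_cutoff
    )
    tm = None
    cp_curve = None
    if T is None:
        if T_grid is None:
            raise ValueError("provide either T or T_grid")
        Ts, cp, tm = heat_capacity(builder, T_grid)
        cp_curve = (Ts, cp)
        T = tm
    return _landscape_at(builder, T, grid_stride, mech, tm=tm, cp_curve=cp_curve)


def _landscape_at(
    builder: LandscapeBuilder,
    T: float,
    grid_stride: int = 1,
    mech: bool = False,
    tm: float | None = None,
    cp_curve=None,
    mech_basin_only: bool = True,
) -> Landscape:
    grid_points = builder.all_grid_points(grid_stride)
    macs = {
        (j, k): builder.evaluate(j, k, T, mech=mech and not mech_basin_only)
        for (j, k) in grid_points
    }
    scape = Landscape(
        temperature=T,
        n_tor=builder.n_tor,
        n_hb_max=builder.n_hb_max,
        grid_points=grid_points,
        macrostates=macs,
        tm=tm,
        cp_curve=cp_curve,
        metadata={
            "n_samples": builder.n_samples,
            "seed": builder.seed,
            "grid_stride": grid_stride,
            "exhaustive": all(m.exhaustive for m in macs.values()),
        },
    )
    _detect_basins(scape)
    if mech and mech_basin_only:
        for point in scape.native_basin:
            macs[point] = builder.evaluate(point[0], point[1], T, mech=True)
    return scape


def _detect_basins(scape: Landscape) -> None:
    """Watershed flood of the free-energy grid: find the native lake, the
    unfolded lake, and their merging saddle; fill Gibbs weights rho over the
    native basin truncated at the saddle."""
    points = scape.grid_points
    g = {p: scape.macrostates[p].free_energy for p in points}
    js = sorted({p[0] for p in points})
    ks = sorted({p[1] for p in points})
    jpos = {j: i for i, j in enumerate(js)}
    kpos = {k: i for i, k in enumerate(ks)}

    def neighbors(p):
        j, k = p
        ji, ki = jpos[j], kpos[k]
        for dj, dk in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            nj, nk = ji + dj, ki + dk
            if 0 <= nj < len(js) and 0 <= nk < len(ks):
                yield (js[nj], ks[nk])

    order = sorted(points, key=lambda p: (g[p], p))
    label: dict[tuple[int, int], int] = {}
    lake_alias: dict[int, int] = {}
    lake_of_seed: dict[tuple[int, int], int] = {}

    def resolve(l):
        while lake_alias.get(l, l) != l:
            l = lake_alias[l]
        return l

    next_lake = 0
    native_corner = (scape.n_tor, scape.n_hb_max)
    unfolded_corner = (0, 0)
    merges: list[tuple[float, int, int]] = []
    for p in order:
        nbr_lakes = {resolve(label[q]) for q in neighbors(p) if q in label}
        if not nbr_lakes:
            label[p] = next_lake
            lake_of_seed[p] = next_lake
            next_lake += 1
        elif len(nbr_lakes) == 1:
            label[p] = nbr_lakes.pop()
        else:
            lakes = sorted(nbr_lakes)
            keep = lakes[0]
            for other in lakes[1:]:
                merges.append((g[p], other, keep))
                lake_alias[other] = keep
            label[p] = keep

    def drain(p):
        # steepest descent to the local minimum this cell drains into
        while True:
            best = min(list(neighbors(p)) + [p], key=lambda q: (g[q], q))
            if best == p:
                return p
            p = best

    orig_native = lake_of_seed[drain(native_corner)]
    orig_unfolded = lake_of_seed[drain(unfolded_corner)]
    if orig_native == orig_unfolded:
        # single basin at this temperature
        scape.basin_min = min(points, key=lambda p: g[p])
        scape.native_basin = {}
        scape.saddle_free_energy = None
        return

    # replay merges to find when the two original lakes join
    parent = {l: l for l in range(next_lake)}

    def find(l):
        while parent[l] != l:
            parent[l] = parent[parent[l]]
            l = parent[l]
        return l

    saddle_g = None
    for glevel, a, b in sorted(merges):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
        if find(orig_native) == find(orig_unfolded):
            saddle_g = glevel
            break
    scape.saddle_free_energy = saddle_g

    # native basin: cells whose original lake merges into the native side
    # before the saddle, with G strictly below the saddle level
    parent = {l: l for l in range(next_lake)}
    for glevel, a, b in sorted(merges):
        if saddle_g is not None and glevel >= saddle_g:
            break
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    native_side = find(orig_native)
    cells = [
        p
        for p in points
        if find(label[p]) == native_side and (saddle_g is None or g[p] < saddle_g)
    ]
    if not cells:
        cells = [min(points, key=lambda p: g[p])]
    gmin_p = min(cells, key=lambda p: g[p])
    scape.basin_min = gmin_p
    beta = 1.0 / (R_GAS * scape.temperature)
    gvals = np.array([g[p] for p in cells])
    logrho = -beta * (gvals - g[gmin_p])
    rho = np.exp(logrho - logsumexp(logrho))
    basin = {p: float(r) for p, r in zip(cells, rho) if r >= 1e-9}
    z = sum(basin.values())
    scape.native_basin = {p: r / z for p, r in basin.items()}


def native_basin_average(
    landscape: Landscape, quantity: Callable[[Macrostate], np.ndarray] | str
) -> np.ndarray | float:
    """Gibbs average of a per-macrostate field over the native basin.

    ``quantity`` is either an attribute/mech-key name or a callable mapping
    a Macrostate to an array/scalar.  Raises when no two-basin structure was
    found at this temperature.
    """
    if not landscape.native_basin:
        raise ValueError(
            f"no native basin (single-basin landscape) at T = {landscape.temperature:.1f} K"
        )
    total = None
    for point, rho in landscape.native_basin.items():
        mac = landscape.macrostates[point]
        if callable(quantity):
            val = quantity(mac)
        elif mac.mech is not None and quantity in mac.mech:
            val = mac.mech[quantity]
        else:
            val = getattr(mac, quantity)
        val = np.asarray(val, float)
        total = rho * val if total is None else total + rho * val
    return float(total) if np.ndim(total) == 0 else total
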