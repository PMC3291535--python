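"""Mutant-versus-wild-type response statistics.

A set of wild-type profiles (FI vectors or CC matrices computed from
independently solved crystal structures) defines a positionwise baseline:
mean and standard deviation at every residue or pixel.  A mutant value is
compared to that baseline as a z-score; values within +/-1 sigma are
background noise ("no change"), 1-2 sigma are moderate changes, and beyond
2 sigma large changes.  The normalized delta used for difference maps is

    delta_n = 0                          for |z| <= 1,
    delta_n = sign(z) min(|z| - 1, 1)    otherwise,

so background is exactly zero, the moderate band is linear, and all large
changes saturate at +/-1.  Observed five-bin histograms are tested against
the standard-normal null expectation (2.3 / 13.6 / 68.2 / 13.6 / 2.3 %)
with a Pearson chi-square.  Further statistics stratify responses by
distance to the mutation site, solvent accessibility tertile, secondary
structure and subdomain, and summarize each stratum by the ratio of changed
to unchanged positions.  Alpha-carbon B-factors are median-normalized for
the flexibility-versus-mobility comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .structure import ResidueAnnotation

__all__ = [
    "BaselineProfile",
    "ResponseTable",
    "BIN_LABELS",
    "baseline",
    "normalized_delta",
    "classify_bins",
    "null_expectation",
    "chisq_vs_null",
    "response_ratio",
    "stratify",
    "normalize_bfactors_median",
    "cc_strip",
    "compare_to_baseline",
]

#: bin order used throughout (matches increasing z)
BIN_LABELS = ["large_rigid", "moderate_rigid", "no_change", "moderate_flex", "large_flex"]


@dataclass
class BaselineProfile:
    """Positionwise mean/sigma over an aligned wild-type profile set."""

    mean: np.ndarray
    sigma: np.ndarray
    n_structures: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float)
        self.sigma = np.asarray(self.sigma, float)
        if self.mean.shape != self.sigma.shape:
            raise ValueError("mean/sigma shape mismatch")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be nonnegative")


@dataclass
class ResponseTable:
    """Per-position normalized deltas, z-scores and bin labels."""

    delta_n: np.ndarray
    z: np.ndarray
    bins: list[str]
    positions: list[int] = field(default_factory=list)
    sigma_zero: np.ndarray | None = None  # mask of positions with sigma == 0


def baseline(profiles: Sequence[np.ndarray], ddof: int = 0) -> BaselineProfile:
    """Positionwise mean and (population, ddof=0) standard deviation.

    All profiles must share one shape; at least two are required.
    """
    arrays = [np.asarray(p, float) for p in profiles]
    if len(arrays) < 2:
        raise ValueError("need at least 2 profiles for a baseline")
    shape = arrays[0].shape
    for i, a in enumerate(arrays):
        if a.shape != shape:
            raise ValueError(f"profile {i} has shape {a.shape}, expected {shape}")
    stack = np.stack(arrays)
    return BaselineProfile(
        mean=stack.mean(axis=0), sigma=stack.std(axis=0, ddof=ddof), n_structures=len(arrays)
    )


def _zscores(value: np.ndarray, base: BaselineProfile) -> tuple[np.ndarray, np.ndarray]:
    value = np.asarray(value, float)
    sigma_zero = base.sigma == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (value - base.mean) / base.sigma
    # sigma = 0: zero when equal to the mean, saturated sign otherwise
    diff = value - base.mean
    if np.any(sigma_zero):
        saturated = np.where(diff == 0, 0.0, np.where(diff > 0, np.inf, -np.inf))
        z = np.where(sigma_zero, saturated, z)
    return z, sigma_zero


def normalized_delta(value, base: BaselineProfile):
    """Eq.-style normalized response: zero inside the noise band, linear in
    the moderate band, saturating at +/-1 beyond 2 sigma; odd in z."""
    z, _ = _zscores(np.asarray(value, float), base)
    mag = np.clip(np.abs(z) - 1.0, 0.0, 1.0)
    out = np.sign(z) * mag
    return out


def classify_bins(z) -> list[str] | str:
    """Five-bin classification of signed z-scores; boundary values (|z|
    exactly 1 or 2) fall in the outer bin."""
    scalar = np.ndim(z) == 0
    z = np.atleast_1d(np.asarray(z, float))
    out = np.full(z.shape, "no_change", dtype=object)
    out[z <= -2] = "large_rigid"
    out[(z > -2) & (z <= -1)] = "moderate_rigid"
    out[(z >= 1) & (z < 2)] = "moderate_flex"
    out[z >= 2] = "large_flex"
    return str(out[0]) if scalar else list(out)


def null_expectation() -> np.ndarray:
    """Standard-normal band probabilities for the five bins, in BIN_LABELS
    order; sums to 1."""
    from scipy.stats import norm

    p_large = norm.cdf(-2.0)
    p_mod = norm.cdf(-1.0) - norm.cdf(-2.0)
    p_center = norm.cdf(1.0) - norm.cdf(-1.0)
    return np.array([p_large, p_mod, p_center, p_mod, p_large])


def chisq_vs_null(observed: Sequence[float]) -> tuple[float, float]:
    """Pearson chi-square of an observed five-bin histogram against the
    Gaussian null, 4 degrees of freedom."""
    obs = np.asarray(observed, float)
    if obs.shape != (5,):
        raise ValueError("observed must have 5 bins")
    total = obs.sum()
    if total <= 0:
        raise ValueError("observed histogram is empty")
    expected = total * null_expectation()
    if np.any(expected <= 0):  # cannot happen with the analytic null; guard anyway
        raise ValueError("expected count of zero")
    stat = float(np.sum((obs - expected) ** 2 / expected))
    p = float(sps.chi2.sf(stat, df=4))
    return stat, p


def response_ratio(bins: Iterable[str]) -> float:
    """(# changed positions) / (# no-change positions)."""
    bins = list(bins)
    n_no = sum(1 for b in bins if b == "no_change")
    n_changed = len(bins) - n_no
    if n_no == 0:
        raise ZeroDivisionError("no 'no_change' positions; ratio undefined")
    return n_changed / n_no


def compare_to_baseline(
    value: np.ndarray, base: BaselineProfile, positions: Sequence[int] | None = None
) -> ResponseTable:
    """Full response table for one mutant profile against the baseline."""
    value = np.asarray(value, float)
    z, sigma_zero = _zscores(value, base)
    delta = normalized_delta(value, base)
    flat_z = z.ravel()
    return ResponseTable(
        delta_n=delta,
        z=z,
        bins=classify_bins(flat_z),
        positions=list(positions) if positions is not None else list(range(flat_z.size)),
        sigma_zero=sigma_zero,
    )


# ---------------------------------------------------------------------------
# Stratification
# ---------------------------------------------------------------------------

DISTANCE_STRATA = [(0.0, 8.0), (8.0, 16.0), (16.0, np.inf)]


def _stratum_name(lo: float, hi: float) -> str:
    return f"{lo:g}-{hi:g}A" if np.isfinite(hi) else f">={lo:g}A"


def stratify(
    bins: dict[int, str],
    mutation_site: int,
    ca_coords: dict[int, np.ndarray],
    annotations: Sequence[ResidueAnnotation] | None = None,
    accessibility_classes: dict[int, str] | None = None,
    exclude_window: int = 0,
) -> dict[tuple[str, str], dict[str, int]]:
    """Cross-tabulate per-residue response bins.

    Counts responses per (distance stratum x class x bin), with distance
    measured between alpha-carbons of the mutation site and the responding
    residue.  The mutated residue itself is excluded (optionally a window of
    ``exclude_window`` residues on each side).  Classes come from
    ``accessibility_classes`` (buried/moderate/exposed) and, when
    annotations are given, secondary structure and subdomain.
    """
    if mutation_site not in ca_coords:
        raise ValueError(f"no alpha-carbon for mutation site {mutation_site}")
    ann_by_res = {a.residue_index: a for a in annotations} if annotations else {}
    out: dict[tuple[str, str], dict[str, int]] = {}

    def bump(stratum: str, cls: str, b: str) -> None:
        cell = out.setdefault((stratum, cls), {lbl: 0 for lbl in BIN_LABELS})
        cell[b] += 1

    for res, b in sorted(bins.items()):
        if abs(res - mutation_site) <= exclude_window:
            continue
        if res not in ca_coords:
            raise ValueError(f"no alpha-carbon for residue {res}")
        d = float(np.linalg.norm(np.asarray(ca_coords[res]) - np.asarray(ca_coords[mutation_site])))
        stratum = next(
            _stratum_name(lo, hi) for lo, hi in DISTANCE_STRATA if lo <= d < hi
        )
        bump(stratum, "all", b)
        if accessibility_classes and res in accessibility_classes:
            bump(stratum, accessibility_classes[res], b)
        if res in ann_by_res:
            bump("all", ann_by_res[res].ss_class, b)
            bump("all", ann_by_res[res].subdomain, b)
    return out


# ---------------------------------------------------------------------------
# B-factors and CC strips
# ---------------------------------------------------------------------------

def normalize_bfactors_median(b: Sequence[float] | dict[int, float]):
    """Median-based robust normalization of alpha-carbon B-factors:
    (B - median) / (1.4826 * median absolute deviation).

    Affine-invariant: a*B + c normalizes identically to B (a > 0).  When the
    spread is zero the values are centered only (with a warning).  All
    B-factors must be positive.
    """
    if isinstance(b, dict):
        keys = sorted(b)
        vals = normalize_bfactors_median([b[k] for k in keys])
        return dict(zip(keys, vals))
    arr = np.asarray(list(b), float)
    if len(arr) < 3:
        raise ValueError("need at least 3 B-factors")
    if np.any(arr <= 0):
        raise ValueError("B-factors must be positive")
    med = np.median(arr)
    mad = np.median(np.abs(arr - med))
    if mad == 0:
        warnings.warn("zero median spread; centering only", stacklevel=2)
        return arr - med
    return (arr - med) / (1.4826 * mad)


def cc_strip(cc_delta: np.ndarray, reference: int) -> np.ndarray:
    """Extract the reference residue's row of a symmetric delta-CC matrix."""
    cc_delta = np.asarray(cc_delta, float)
    if cc_delta.ndim != 2 or cc_delta.shape[0] != cc_delta.shape[1]:
        raise ValueError("cc_delta must be square")
    if not 0 <= reference < cc_delta.shape[0]:
        raise IndexError(f"reference {reference} out of range")
    return cc_delta[reference].copy()
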