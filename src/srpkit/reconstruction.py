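"""Stepwise reconstruction of species richness patterns (SRPs).

Species are added one by one to an initially empty assemblage, either in
range-ascending order (rarest, i.e. smallest-MLE species first) or
range-descending order (commonest first).  After each addition the
subset's per-cell richness is correlated (Kendall tau-b) with the overall
per-cell richness.  Species tied on MLE — notably the single-site block at
MLE = 0 — are ordered at random within their tie block, and the curve is
summarized as the per-step median over many tie randomizations.  A null
model built from fully random addition orders provides per-step envelopes
and two-sided empirical p-values.

The cumulative information content (CI) of a subset,
``CI = sum_i p_i * (1 - p_i)`` with ``p_i`` the proportion of analysis
cells occupied by species i, re-expresses the x-axis in units of the
expected binomial variance each species contributes, so that a single-site
endemic (tiny p) counts for almost nothing while a half-prevalent species
counts the most (0.25).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "kendall_tau_b",
    "addition_order",
    "stepwise_curve",
    "median_curve",
    "null_model",
    "empirical_p",
    "cumulative_information",
    "crossing_point",
    "SubsetCurve",
    "NullModel",
]


# ---------------------------------------------------------------------------
# Kendall tau-b
# ---------------------------------------------------------------------------

def kendall_tau_b(x, y) -> float:
    """Kendall's tau-b rank correlation with tie correction.

    tau_b = (C - D) / sqrt((n0 - n1) * (n0 - n2)) where C/D are the
    concordant/discordant pair counts, n0 = n(n-1)/2 and n1, n2 the
    numbers of pairs tied in x and in y.  Suited to integer richness
    vectors with many ties.

    Returns NaN (the "undefined" flag) when all x or all y are tied, so a
    degenerate comparison is never silently reported as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("kendall_tau_b requires length >= 3")
    iu = np.triu_indices(n, 1)
    sx = np.sign(x[:, None] - x[None, :])[iu]
    sy = np.sign(y[:, None] - y[None, :])[iu]
    n0 = n * (n - 1) // 2
    n1 = int(np.count_nonzero(sx == 0))
    n2 = int(np.count_nonzero(sy == 0))
    if n1 == n0 or n2 == n0:
        return float("nan")
    cd = float(np.sum(sx * sy))
    return cd / math.sqrt((n0 - n1) * (n0 - n2))


class _TauEngine:
    """Repeated tau-b against one fixed vector (the overall richness)."""

    def __init__(self, y: np.ndarray):
        y = np.asarray(y, dtype=float)
        n = y.size
        if n < 3:
            raise ValueError("need >= 3 cells")
        self.n = n
        self.n0 = n * (n - 1) // 2
        self._iu = np.triu_indices(n, 1)
        self.sy = np.sign(y[:, None] - y[None, :])[self._iu]
        self.n2 = int(np.count_nonzero(self.sy == 0))

    def tau(self, x: np.ndarray) -> float:
        sx = np.sign(x[:, None] - x[None, :])[self._iu]
        n1 = int(np.count_nonzero(sx == 0))
        if n1 == self.n0 or self.n2 == self.n0:
            return float("nan")
        cd = float(np.sum(sx * self.sy))
        return cd / math.sqrt((self.n0 - n1) * (self.n0 - self.n2))


# ---------------------------------------------------------------------------
# Addition orders and raw curves
# ---------------------------------------------------------------------------

def addition_order(
    profiles: pd.DataFrame,
    direction: str,
    rng: np.random.Generator,
    tie_policy: str = "all",
) -> np.ndarray:
    """One species permutation for stepwise addition.

    Species are sorted by ``mle_km`` ascending ("rarest first") or
    descending ("commonest first").  Within every block of species tied on
    MLE the order is randomized by ``rng``; with
    ``tie_policy="single_site_only"`` only the MLE = 0 block is shuffled
    and other ties keep a stable (input-order) arrangement.
    """
    if direction not in ("ascending", "descending"):
        raise ValueError(f"direction must be ascending/descending, got {direction!r}")
    ids = profiles["species_id"].to_numpy()
    mles = profiles["mle_km"].to_numpy(dtype=float)
    order = np.argsort(mles, kind="stable")
    out = []
    start = 0
    n = len(order)
    while start < n:
        stop = start
        while stop < n and mles[order[stop]] == mles[order[start]]:
            stop += 1
        block = order[start:stop].copy()
        if len(block) > 1 and (
            tie_policy == "all"
            or (tie_policy == "single_site_only" and mles[block[0]] == 0)
        ):
            block = rng.permutation(block)
        out.append(block)
        start = stop
    perm = np.concatenate(out)
    if direction == "descending":
        perm = perm[::-1]
    return ids[perm]


def stepwise_curve(
    order,
    species_cells: dict,
    overall: np.ndarray,
    cells: str = "all",
) -> np.ndarray:
    """Per-step tau-b between subset and overall richness.

    Parameters
    ----------
    order : sequence of species ids covering the assemblage
    species_cells : dict species_id -> integer indices of occupied cells
        (positions into the analysis-cell vector)
    overall : per-cell overall richness over the taxon's occupied cells
    cells : "all" correlates over all occupied cells of the taxon with
        subset richness 0 where the subset is absent (default);
        "subset" restricts each step to cells the subset already occupies.

    Returns an array of length n_species; entries are NaN where tau-b is
    undefined (constant vector, or < 3 cells under ``cells="subset"``).

    The subset richness is updated incrementally; adding species k only
    increments its own cells.
    """
    overall = np.asarray(overall, dtype=float)
    sub = np.zeros(overall.size)
    taus = np.empty(len(order))
    engine = _TauEngine(overall) if cells == "all" else None
    for k, sp in enumerate(order):
        sub[species_cells[sp]] += 1
        if cells == "all":
            taus[k] = engine.tau(sub)
        elif cells == "subset":
            m = sub > 0
            if int(m.sum()) < 3:
                taus[k] = float("nan")
            else:
                taus[k] = kendall_tau_b(sub[m], overall[m])
        else:
            raise ValueError(f"cells must be 'all' or 'subset', got {cells!r}")
    return taus


# ---------------------------------------------------------------------------
# Median curves, null model, empirical p
# ---------------------------------------------------------------------------

@dataclass
class SubsetCurve:
    """A stepwise addition curve.

    points are parallel arrays over k = 1..n: percentage of species added,
    percentage of cumulative information content, the (median) tau-b, and
    optionally the per-step two-sided empirical p against a null model.
    """

    direction: str
    k: np.ndarray
    pct_species: np.ndarray
    pct_ci: np.ndarray
    tau_b: np.ndarray
    p_empirical: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "direction": self.direction,
                "k": self.k,
                "pct_species": self.pct_species,
                "pct_ci": self.pct_ci,
                "tau_b": self.tau_b,
            }
        )
        if self.p_empirical is not None:
            df["p_empirical"] = self.p_empirical
        return df


@dataclass
class NullModel:
    """Per-step summary of fully random addition orders."""

    taus: np.ndarray  # (R, n) replicate tau matrix
    median: np.ndarray = field(init=False)
    lo95: np.ndarray = field(init=False)
    hi95: np.ndarray = field(init=False)

    def __post_init__(self):
        with np.errstate(all="ignore"):
            self.median = np.nanmedian(self.taus, axis=0)
            self.lo95 = np.nanpercentile(self.taus, 2.5, axis=0)
            self.hi95 = np.nanpercentile(self.taus, 97.5, axis=0)

    @property
    def n_replicates(self) -> int:
        return self.taus.shape[0]

    def to_frame(self) -> pd.DataFrame:
        n = self.taus.shape[1]
        return pd.DataFrame(
            {
                "k": np.arange(1, n + 1),
                "null_median": self.median,
                "null_lo95": self.lo95,
                "null_hi95": self.hi95,
            }
        )


def _ci_for_order(order, species_cells: dict, n_cells: int) -> np.ndarray:
    p = np.array([len(species_cells[sp]) / n_cells for sp in order], dtype=float)
    if np.any(p <= 0):
        raise ValueError("every species must occupy at least one analysis cell")
    return np.cumsum(p * (1 - p))


def median_curve(
    profiles: pd.DataFrame,
    species_cells: dict,
    overall: np.ndarray,
    direction: str,
    n_randomizations: int = 10_000,
    rng: np.random.Generator | None = None,
    tie_policy: str = "all",
    cells: str = "all",
) -> SubsetCurve:
    """Median stepwise curve over tie randomizations.

    Runs ``n_randomizations`` replicates of :func:`addition_order` (ties
    reshuffled each time) through :func:`stepwise_curve` and keeps the
    per-step median tau-b and median %CI.  With no ties in MLE every
    replicate is identical, so the median equals the single deterministic
    curve for any R.
    """
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    n = len(profiles)
    n_cells = np.asarray(overall).size
    taus = np.empty((n_randomizations, n))
    cis = np.empty((n_randomizations, n))
    for r in range(n_randomizations):
        order = addition_order(profiles, direction, rng, tie_policy=tie_policy)
        taus[r] = stepwise_curve(order, species_cells, overall, cells=cells)
        cis[r] = _ci_for_order(order, species_cells, n_cells)
    with np.errstate(all="ignore"):
        med_tau = np.nanmedian(taus, axis=0)
        med_ci = np.median(cis, axis=0)
    k = np.arange(1, n + 1)
    return SubsetCurve(
        direction=direction,
        k=k,
        pct_species=100.0 * k / n,
        pct_ci=100.0 * med_ci / med_ci[-1],
        tau_b=med_tau,
    )


def null_model(
    profiles: pd.DataFrame,
    species_cells: dict,
    overall: np.ndarray,
    n_replicates: int = 10_000,
    rng: np.random.Generator | None = None,
    cells: str = "all",
) -> NullModel:
    """Null distribution of curves from fully random addition orders.

    Each replicate permutes all species uniformly at random, ignoring MLE,
    and is run through :func:`stepwise_curve`.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    ids = profiles["species_id"].to_numpy()
    n = len(ids)
    taus = np.empty((n_replicates, n))
    for r in range(n_replicates):
        order = ids[rng.permutation(n)]
        taus[r] = stepwise_curve(order, species_cells, overall, cells=cells)
    return NullModel(taus=taus)


def empirical_p(tau_obs: float, null_taus_at_k: np.ndarray) -> float:
    """Two-sided empirical p of an observed tau against null replicates.

    Measures the probability of lying at least as far from the null
    median as the observation:
    ``p = (1 + #{ |tau_r - med| >= |tau_obs - med| }) / (R + 1)``.
    The +1 correction keeps p in (0, 1].
    """
    null_taus_at_k = np.asarray(null_taus_at_k, dtype=float)
    null_taus_at_k = null_taus_at_k[np.isfinite(null_taus_at_k)]
    if null_taus_at_k.size == 0 or not np.isfinite(tau_obs):
        return float("nan")
    med = float(np.median(null_taus_at_k))
    r = null_taus_at_k.size
    obs_dev = abs(tau_obs - med)
    count = int(np.sum(np.abs(null_taus_at_k - med) >= obs_dev - 1e-12))
    return (1 + count) / (r + 1)


def attach_empirical_p(curve: SubsetCurve, null: NullModel) -> SubsetCurve:
    """Fill the per-step empirical p of a curve from a null model."""
    n = curve.tau_b.size
    if null.taus.shape[1] != n:
        raise ValueError("curve and null model differ in number of steps")
    curve.p_empirical = np.array(
        [empirical_p(curve.tau_b[k], null.taus[:, k]) for k in range(n)]
    )
    return curve


def cumulative_information(order, species_cells: dict, n_cells: int):
    """Cumulative information content along an addition order.

    CI_k = sum_{i<=k} p_i (1 - p_i) with p_i the proportion of the
    taxon's ``n_cells`` analysis cells occupied by species i (fixed
    denominator, so total CI is order-independent).  Returns
    ``(ci, pct_ci)`` arrays of length n.
    """
    ci = _ci_for_order(order, species_cells, n_cells)
    return ci, 100.0 * ci / ci[-1]


def crossing_point(curve: SubsetCurve, threshold: float = 0.5):
    """First step at which tau-b exceeds a threshold.

    Returns a dict with ``k``, ``pct_species`` and ``pct_ci`` at the
    smallest k with tau_b > threshold, or None if the curve never
    exceeds it.
    """
    above = np.flatnonzero(curve.tau_b > threshold)
    if above.size == 0:
        return None
    i = int(above[0])
    return {
        "k": int(curve.k[i]),
        "pct_species": float(curve.pct_species[i]),
        "pct_ci": float(curve.pct_ci[i]),
    }
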