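"""Wavelength selection: spectral binning, backward variable selection, annealing.

Three stages turn a 2048-wavelength transmission spectrum into a handful of
informative variables:

1. **Binning** — the grid is partitioned into contiguous groups of ``n``
   adjacent wavelengths (``w = m x n`` exactly) and each group is represented by
   the sum of its intensities, e.g. widths 32/16/8 give 64/128/256 variables.
   Adjacent wavelengths carry nearly identical chemical information, so summing
   sacrifices little signal while collapsing collinearity.
2. **BVS-PLS** — backward group elimination. At every iteration each remaining
   variable's removal is evaluated by cross-validated RMSECV of a PLS model on
   the rest; the removal producing the largest RMSECV decrease is committed.
   Iteration stops when no single removal decreases RMSECV further.
3. **Simulated annealing** — fixed-size subset refinement. From a random
   size-``k`` subset, each move swaps one selected variable for an unselected
   one; better subsets are always accepted and worse ones with probability
   ``exp(-dC/T)`` (Metropolis), with the temperature started at the initial
   RMSECV and lowered each iteration. Accepting occasional uphill moves lets the
   search escape local minima that greedy elimination cannot.

The combined selector runs binning, then BVS, then annealing on the survivors,
and maps the chosen variables back to index ranges on the original grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import pls
from .containers import SpectrumSet

__all__ = [
    "GroupingMap",
    "SelectionResult",
    "AnnealingConfig",
    "RmsecvObjective",
    "bin_matrix",
    "bin_spectrum",
    "bvs_pls",
    "sa_select",
    "combined_select",
    "CombinedResult",
]


# -- binning -------------------------------------------------------------


@dataclass
class GroupingMap:
    """Partition of a ``w``-point grid into ``m`` contiguous bins of width ``n``."""

    w: int
    n: int
    m: int
    group_ranges: list[tuple[int, int]]  # [start, end) on the original grid

    def original_indices(self, bins) -> np.ndarray:
        """Original-grid indices covered by the given bin indices."""
        parts = [np.arange(*self.group_ranges[b]) for b in np.asarray(bins, dtype=int)]
        return np.concatenate(parts) if parts else np.array([], dtype=int)

    def ranges_for(self, bins) -> list[tuple[int, int]]:
        return [self.group_ranges[int(b)] for b in bins]


def _divisors(w: int) -> list[int]:
    return [d for d in range(1, w + 1) if w % d == 0]


def bin_matrix(X: np.ndarray, width: int) -> np.ndarray:
    """Sum adjacent columns in groups of ``width`` (requires exact divisibility)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    w = X.shape[1]
    if width < 1 or w % width != 0:
        raise ValueError(
            f"bin width {width} does not divide {w} wavelengths; "
            f"valid widths include {_divisors(w)[:12]} ..."
        )
    return X.reshape(X.shape[0], w // width, width).sum(axis=2)


def bin_spectrum(sset: SpectrumSet, width: int) -> tuple[SpectrumSet, GroupingMap]:
    """Bin a SpectrumSet; each binned variable is labelled by its range midpoint (nm)."""
    binned = bin_matrix(sset.intensities, width)
    w = sset.n_wavelengths
    m = w // width
    ranges = [(i * width, (i + 1) * width) for i in range(m)]
    mids = np.array([(sset.wavelengths[lo] + sset.wavelengths[hi - 1]) / 2.0
                     for lo, hi in ranges])
    gmap = GroupingMap(w=w, n=width, m=m, group_ranges=ranges)
    return sset.with_data(binned, f"bin(width={width})", wavelengths=mids), gmap


# -- shared result type --------------------------------------------------


@dataclass
class SelectionResult:
    """Outcome of one selection stage on the current variable space."""

    selected: np.ndarray  # unique, sorted variable indices
    rmsecv_trace: list[float]  # per-iteration objective, % SSC
    elimination_order: list[int] = field(default_factory=list)  # BVS only
    accepted_moves: list[tuple] = field(default_factory=list)  # SA only: (iter, out, in, C)
    objective_final: float = float("nan")
    provenance: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "selected": self.selected.tolist(),
            "rmsecv_trace": list(self.rmsecv_trace),
            "elimination_order": list(self.elimination_order),
            "accepted_moves": [list(m) for m in self.accepted_moves],
            "objective_final": self.objective_final,
            "provenance": self.provenance,
        }


# -- objective -----------------------------------------------------------


class RmsecvObjective:
    """Fitness ``C(subset) = min RMSECV`` of a PLS model on the subset columns.

    Deterministic for a fixed subset and data: the CV folds are frozen at
    construction. The LV count is re-selected (capped at ``max_lv``) for every
    subset unless ``fixed_lv`` pins it. Evaluations are cached.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, cv: str | tuple = "loo",
                 max_lv: int = 20, fixed_lv: int | None = None, cv_seed: int = 0):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=float).ravel()
        self.cv = cv
        self.cv_seed = cv_seed
        self.max_lv = max_lv
        self.fixed_lv = fixed_lv
        self._cache: dict[tuple, float] = {}
        folds = pls._folds(self.y.size, cv, cv_seed)
        self._min_train = self.y.size - max(f.size for f in folds)

    def _cap(self, n_vars: int) -> int:
        cap = min(self.max_lv, self._min_train - 1, n_vars)
        return max(cap, 1)

    def __call__(self, subset) -> float:
        subset = np.asarray(subset, dtype=int)
        key = (frozenset(subset.tolist()), self.fixed_lv)
        if key in self._cache:
            return self._cache[key]
        cap = self._cap(subset.size)
        lv = min(self.fixed_lv, cap) if self.fixed_lv is not None else cap
        cv = pls.rmsecv(self.X[:, subset], self.y, lv, cv=self.cv, seed=self.cv_seed)
        value = (float(cv.rmsecv_by_lv[lv - 1]) if self.fixed_lv is not None
                 else float(cv.rmsecv_by_lv[cv.chosen_lv - 1]))
        if not math.isfinite(value):
            raise ValueError("non-finite RMSECV objective")
        self._cache[key] = value
        return value

    def chosen_lv(self, subset) -> int:
        subset = np.asarray(subset, dtype=int)
        cap = self._cap(subset.size)
        if self.fixed_lv is not None:
            return min(self.fixed_lv, cap)
        return pls.rmsecv(self.X[:, subset], self.y, cap, cv=self.cv,
                          seed=self.cv_seed).chosen_lv


# -- backward variable selection -----------------------------------------


def bvs_pls(X: np.ndarray, y: np.ndarray, cv: str | tuple = "loo", min_groups: int = 2,
            max_lv: int = 20, fast_lv: bool = False, cv_seed: int = 0) -> SelectionResult:
    """Backward group elimination driven by cross-validated RMSECV.

    At each iteration every remaining variable's single removal is evaluated;
    the one whose removal lowers RMSECV the most is discarded (ties break to the
    lowest index). Stops when no removal decreases RMSECV or ``min_groups``
    variables remain. With ``fast_lv`` the LV count is re-selected once per
    outer iteration (on the current set) instead of per candidate.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    m = X.shape[1]
    prov = {
        "method": "bvs_pls", "cv": pls._scheme_name(cv), "min_groups": min_groups,
        "max_lv": max_lv, "fast_lv": fast_lv,
    }
    if min_groups >= m or m < 2:
        return SelectionResult(np.arange(m), [], [], [], float("nan"), prov)
    objective = RmsecvObjective(X, y, cv=cv, max_lv=max_lv, cv_seed=cv_seed)
    current = list(range(m))
    current_val = objective(current)
    trace = [current_val]
    order: list[int] = []
    while len(current) > min_groups:
        if fast_lv:
            objective.fixed_lv = None
            lv_now = objective.chosen_lv(current)
            objective.fixed_lv = lv_now
        best_g, best_val = None, current_val
        for g in current:
            candidate = [v for v in current if v != g]
            val = objective(candidate)
            if val < best_val:  # strict: ties keep the earlier (lower-index) removal
                best_g, best_val = g, val
        if best_g is None:
            break
        current = [v for v in current if v != best_g]
        order.append(best_g)
        current_val = best_val
        trace.append(current_val)
    if fast_lv:
        objective.fixed_lv = None
        current_val = objective(current)
    return SelectionResult(
        selected=np.array(sorted(current)),
        rmsecv_trace=trace,
        elimination_order=order,
        objective_final=current_val,
        provenance=prov,
    )


# -- simulated annealing -------------------------------------------------


@dataclass
class AnnealingConfig:
    """Annealing schedule for fixed-size subset search.

    ``T0`` defaults to the initial subset's RMSECV. Two cooling rules are
    available: ``adaptive_decrement`` lowers T by ``decrement_fraction`` (0.5%
    by default) of the best RMSE found so far at every iteration, so the cooling
    step shrinks as the fit improves; ``geometric`` multiplies by ``alpha``.
    ``Te`` defaults to ``1e-8 * T0`` (effectively zero).
    """

    k: int
    T0: float | None = None
    cooling_rule: str = "adaptive_decrement"
    alpha: float = 0.95
    decrement_fraction: float = 0.005
    L: int = 500
    Te: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.T0 is not None and self.T0 <= 0:
            raise ValueError("T0 must be > 0")
        if self.cooling_rule not in ("adaptive_decrement", "geometric"):
            raise ValueError("cooling_rule must be 'adaptive_decrement' or 'geometric'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.decrement_fraction < 1:
            raise ValueError("decrement_fraction must be in (0, 1)")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.Te is not None and self.Te < 0:
            raise ValueError("Te must be >= 0")


def sa_select(X: np.ndarray, y: np.ndarray, config: AnnealingConfig,
              objective: RmsecvObjective | None = None) -> SelectionResult:
    """Simulated-annealing search for the best size-``k`` variable subset.

    One objective evaluation per iteration; temperature updated every iteration;
    runs for ``L`` iterations total. ``Te`` acts as the temperature floor: once
    the schedule cools to ``Te`` (effectively zero by default) the walk becomes
    greedy — worse moves are essentially never accepted — and the remaining
    budget is spent refining, so the search has both an exploratory hot phase
    and a descent phase. The best subset ever visited is returned together with
    the best-so-far objective trace.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n_vars = X.shape[1]
    if config.k > n_vars:
        raise ValueError(f"k={config.k} exceeds {n_vars} available variables")
    if objective is None:
        objective = RmsecvObjective(X, y)
    prov = {
        "method": "sa_select", "k": config.k, "cooling_rule": config.cooling_rule,
        "alpha": config.alpha, "decrement_fraction": config.decrement_fraction,
        "L": config.L, "seed": config.seed, "cv": pls._scheme_name(objective.cv),
    }
    if config.k == n_vars:
        final = objective(np.arange(n_vars))
        return SelectionResult(np.arange(n_vars), [final], [], [], final,
                               prov | {"note": "k equals variable count; single subset"})
    rng = np.random.default_rng(config.seed)
    current = rng.choice(n_vars, size=config.k, replace=False)
    c_current = objective(current)
    best, c_best = current.copy(), c_current
    T = config.T0 if config.T0 is not None else c_current
    if T <= 0:
        T = max(c_current, 1e-12)
    Te = config.Te if config.Te is not None else 1e-8 * T
    in_set = np.zeros(n_vars, dtype=bool)
    in_set[current] = True
    trace = [c_best]
    moves: list[tuple] = []
    for it in range(config.L):
        T = max(T, Te)
        pos = rng.integers(config.k)
        out_var = int(current[pos])
        outside = np.flatnonzero(~in_set)
        in_var = int(outside[rng.integers(outside.size)])
        candidate = current.copy()
        candidate[pos] = in_var
        c_new = objective(candidate)
        dC = c_new - c_current
        accept = dC < 0 or (T > 0 and rng.random() < math.exp(-min(dC / T, 700.0)))
        if accept:
            current = candidate
            c_current = c_new
            in_set[out_var] = False
            in_set[in_var] = True
            moves.append((it, out_var, in_var, c_new))
            if c_new < c_best:
                best, c_best = current.copy(), c_new
        trace.append(c_best)
        if config.cooling_rule == "adaptive_decrement":
            T -= config.decrement_fraction * c_best
        else:
            T *= config.alpha
    return SelectionResult(
        selected=np.array(sorted(best)),
        rmsecv_trace=trace,
        accepted_moves=moves,
        objective_final=c_best,
        provenance=prov,
    )


# -- combined pipeline ---------------------------------------------------


@dataclass
class CombinedResult:
    """BVS -> SA selection mapped back to the original wavelength grid."""

    original_ranges: list[tuple[int, int]]  # [start, end) index ranges, original grid
    wavelength_ranges_nm: list[tuple[float, float]]
    selected_bins: np.ndarray  # bin indices on the binned grid
    grouping: GroupingMap
    bvs: SelectionResult
    sa: SelectionResult
    provenance: dict = field(default_factory=dict)

    @property
    def original_indices(self) -> np.ndarray:
        return self.grouping.original_indices(self.selected_bins)

    def to_json_dict(self) -> dict:
        return {
            "original_ranges": [list(r) for r in self.original_ranges],
            "wavelength_ranges_nm": [list(r) for r in self.wavelength_ranges_nm],
            "selected_bins": self.selected_bins.tolist(),
            "bin_width": self.grouping.n,
            "bvs": self.bvs.to_json_dict(),
            "sa": self.sa.to_json_dict(),
            "provenance": self.provenance,
        }


def combined_select(sset: SpectrumSet, y: np.ndarray, bin_width: int, k: int,
                    sa_config: AnnealingConfig | None = None, cv: str | tuple = "loo",
                    max_lv: int = 20, min_groups: int | None = None,
                    fast_lv: bool = False, cv_seed: int = 0) -> CombinedResult:
    """Bin, eliminate backwards, refine by annealing; report original-grid ranges.

    BVS acts as a coarse screen that removes uninformative bins; SA then picks
    the best ``k`` of the survivors (skipped as an identity when ``k`` equals
    the survivor count). Because single removals keep lowering a cross-validated
    objective slightly even among pure-noise bins, BVS is floored at
    ``min_groups`` survivors — by default half the bins, but never fewer than
    ``k`` — and the subset refinement is left to the annealing stage.
    """
    binned, gmap = bin_spectrum(sset, bin_width)
    if min_groups is None:
        min_groups = max(k, gmap.m // 2)
    y = np.asarray(y, dtype=float).ravel()
    bvs_res = bvs_pls(binned.intensities, y, cv=cv, min_groups=min_groups,
                      max_lv=max_lv, fast_lv=fast_lv, cv_seed=cv_seed)
    survivors = bvs_res.selected
    if k > survivors.size:
        raise ValueError(f"k={k} exceeds {survivors.size} BVS survivors")
    if sa_config is None:
        sa_config = AnnealingConfig(k=k)
    elif sa_config.k != k:
        raise ValueError("sa_config.k must equal k")
    X_surv = binned.intensities[:, survivors]
    objective = RmsecvObjective(X_surv, y, cv=cv, max_lv=max_lv, cv_seed=cv_seed)
    sa_res = sa_select(X_surv, y, sa_config, objective)
    selected_bins = np.sort(survivors[sa_res.selected])
    ranges = gmap.ranges_for(selected_bins)
    wl_ranges = [(float(sset.wavelengths[lo]), float(sset.wavelengths[hi - 1]))
                 for lo, hi in ranges]
    return CombinedResult(
        original_ranges=ranges,
        wavelength_ranges_nm=wl_ranges,
        selected_bins=selected_bins,
        grouping=gmap,
        bvs=bvs_res,
        sa=sa_res,
        provenance={
            "bin_width": bin_width, "k": k, "cv": pls._scheme_name(cv),
            "max_lv": max_lv, "fast_lv": fast_lv, "sa_seed": sa_config.seed,
        },
    )
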