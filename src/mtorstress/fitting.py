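"""Weighted least-squares calibration in log10 parameter space.

The objective is the standard weighted sum of squared residuals,

    chi2(theta) = sum_i ((y_sim_i(theta) - y_i) / max(SEM_i, floor))^2,

over all fitted (condition, readout, time) means.  Because immunoblot
intensities are relative, each replicate of the data is normalised to the
average of its own readout across the time course; simulated readouts are
normalised the same way before comparison (no per-observable scale or
offset parameters — the condition-specific initial concentrations absorb
scale).  Artificial no-stress companion conditions are normalised with
the constant of their parent stressed condition, since their constant
records live on the parent's normalised scale.

Optimisation runs in log10 space with box bounds, multistarted from a
Latin hypercube; each start is refined by a trust-region-reflective
least-squares solver with finite-difference gradients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from scipy.stats import qmc

from .data import TimeCourseDataset
from .network import OBSERVABLE_NAMES, InputProfile, ModelSpec, RateParameter
from .simulate import (
    Condition,
    IntegrationError,
    _integrate,
    condition_init_params,
    initial_state,
    pool_totals,
)
from .simulate import _OBS_IDX

__all__ = [
    "FitProblem",
    "FitResult",
    "chi2_objective",
    "lhs_starts",
    "fit_multistart",
    "extent_of_inhibition",
    "PENALTY_CHI2",
]

#: chi2 assigned to a start whose integration fails (the start is kept,
#: flagged unconverged, so multistart bookkeeping stays complete)
PENALTY_CHI2 = 1e12


@dataclass
class FitResult:
    """Outcome of one local optimisation start."""

    log10_params: np.ndarray
    chi2: float
    n_datapoints: int
    converged: bool
    start_index: int
    seed: int
    free_names: tuple[str, ...] = ()

    def params_mapping(self, problem: "FitProblem") -> dict[str, float]:
        return problem.full_mapping(self.log10_params)


class FitProblem:
    """A model, its datasets and the free/fixed parameter bookkeeping.

    Parameters are the model's kinetic and input-strength parameters plus
    one initial-concentration block per condition label appearing in the
    datasets.  ``free`` restricts which parameters are optimised; the
    rest are held at ``fixed_values`` (defaulting to their stored values).
    """

    def __init__(
        self,
        model: ModelSpec,
        datasets: Sequence[TimeCourseDataset],
        conditions: Mapping[str, Condition],
        sigma_floor: float = 0.05,
        free: Optional[Iterable[str]] = None,
        fixed_values: Optional[Mapping[str, float]] = None,
        rtol: float = 1e-6,
        atol: float = 1e-8,
    ):
        if sigma_floor <= 0:
            raise ValueError("sigma_floor must be positive")
        self.model = model
        self.datasets = list(datasets)
        self.sigma_floor = float(sigma_floor)
        self.rtol = float(rtol)
        self.atol = float(atol)

        used_labels = []
        for ds in self.datasets:
            for lab in ds.conditions:
                if lab not in conditions:
                    raise ValueError(f"no Condition defined for dataset label {lab!r}")
                if lab not in used_labels:
                    used_labels.append(lab)
        self.conditions: dict[str, Condition] = {
            lab: conditions[lab] for lab in used_labels
        }

        # full parameter table: model params then per-block initials
        specs: list[RateParameter] = list(model.parameters)
        seen_blocks: set[str] = set()
        for lab in used_labels:
            cond = self.conditions[lab]
            if cond.block in seen_blocks:
                continue
            seen_blocks.add(cond.block)
            specs.extend(condition_init_params(cond))
        self.param_specs: tuple[RateParameter, ...] = tuple(specs)
        self._spec_by_name = {p.name: p for p in specs}

        # entries of fixed_values not naming a problem parameter are ignored,
        # so one truth mapping can season problems over several variants
        values = {p.name: p.value for p in specs}
        if fixed_values:
            values.update({k: v for k, v in fixed_values.items() if k in values})
        self._values = values

        default_free = [p.name for p in specs if not p.fixed]
        if free is None:
            self.free_names: tuple[str, ...] = tuple(default_free)
        else:
            free = list(free)
            unknown = set(free) - set(values)
            if unknown:
                raise ValueError(f"free names not in problem: {sorted(unknown)}")
            always_fixed = {p.name for p in specs if p.fixed}
            bad = set(free) & always_fixed
            if bad:
                raise ValueError(f"cannot free structurally fixed parameters: {sorted(bad)}")
            self.free_names = tuple(n for n in default_free if n in set(free))

        self._free_idx = {n: i for i, n in enumerate(self.free_names)}
        lo = np.array([self._spec_by_name[n].log10_lower for n in self.free_names])
        hi = np.array([self._spec_by_name[n].log10_upper for n in self.free_names])
        self.bounds = (lo, hi)

        self._build_data_tables()

    # -- construction helpers ---------------------------------------------

    def _build_data_tables(self):
        """Pre-extract per-condition times and record indices."""
        self._cond_tables = []  # (label, times, list of (readout_col, t_idx, mean, sig))
        n = 0
        for ds in self.datasets:
            for lab in ds.conditions:
                sub = ds.frame[ds.frame["condition"] == lab]
                times = np.sort(sub["time_min"].unique())
                if times[0] != 0.0:
                    times = np.concatenate([[0.0], times])
                t_index = {t: i for i, t in enumerate(times)}
                recs = []
                for _, r in sub.iterrows():
                    col = OBSERVABLE_NAMES.index(r["readout"])
                    sig = max(r["sem"], self.sigma_floor)
                    recs.append((col, t_index[r["time_min"]], r["mean"], sig))
                self._cond_tables.append((lab, times, recs))
                n += len(recs)
        self.n_datapoints = n
        # parent conditions must be simulated before their dependants
        labels = [t[0] for t in self._cond_tables]
        for lab in labels:
            parent = self.conditions[lab].normalize_with
            if parent is not None and parent not in labels:
                raise ValueError(
                    f"condition {lab!r} normalises with {parent!r}, "
                    "which is not part of the problem"
                )
        self._cond_tables.sort(
            key=lambda t: 1 if self.conditions[t[0]].normalize_with else 0
        )

    # -- parameter plumbing ------------------------------------------------

    @property
    def k_free(self) -> int:
        return len(self.free_names)

    def default_x0(self) -> np.ndarray:
        """log10 of the stored values of the free parameters, clipped to bounds."""
        x = np.array(
            [math.log10(max(self._values[n], 1e-300)) for n in self.free_names]
        )
        return np.clip(x, self.bounds[0], self.bounds[1])

    def full_mapping(self, x_log10: Sequence[float]) -> dict[str, float]:
        x = np.asarray(x_log10, dtype=float)
        if x.shape != (len(self.free_names),):
            raise ValueError(
                f"expected {len(self.free_names)} free values, got {x.shape}"
            )
        vals = dict(self._values)
        for n, xi in zip(self.free_names, x):
            vals[n] = 10.0**xi
        return vals

    def with_fixed(self, fixed: Mapping[str, float]) -> "FitProblem":
        """A copy with some parameters pinned (removed from the free set)."""
        new_values = dict(self._values)
        new_values.update(fixed)
        prob = FitProblem.__new__(FitProblem)
        prob.__dict__.update(self.__dict__)
        prob._values = new_values
        prob.free_names = tuple(n for n in self.free_names if n not in fixed)
        prob._free_idx = {n: i for i, n in enumerate(prob.free_names)}
        lo = np.array([prob._spec_by_name[n].log10_lower for n in prob.free_names])
        hi = np.array([prob._spec_by_name[n].log10_upper for n in prob.free_names])
        prob.bounds = (lo, hi)
        return prob

    # -- objective ---------------------------------------------------------

    def _simulate_condition(self, cond: Condition, vals, kvec, times):
        x0 = initial_state(self.model, cond, vals)
        inputs = InputProfile(
            stress=1.0 if cond.stress_present else 0.0,
            aa=cond.aa_level,
            insulin=cond.insulin_level,
            wortmannin=cond.wortmannin_present,
            mk2206=cond.mk2206_present,
            pool_totals=pool_totals(x0),
        )
        states = _integrate(
            self.model, kvec, x0, inputs, times, self.rtol, self.atol, cond.label
        )
        # readout matrix (n_t, 9)
        return np.column_stack(
            [states[:, _OBS_IDX[name]].sum(axis=1) for name in OBSERVABLE_NAMES]
        )

    def residuals(self, x_log10: Sequence[float]) -> np.ndarray:
        """Weighted residual vector; penalty-filled on integration failure."""
        vals = self.full_mapping(x_log10)
        kvec = np.array(
            [vals.get(p.name, p.value) for p in self.model.parameters]
        )
        res = np.empty(self.n_datapoints)
        norms: dict[str, np.ndarray] = {}
        try:
            pos = 0
            obs_cache: dict[str, np.ndarray] = {}
            for lab, times, recs in self._cond_tables:
                cond = self.conditions[lab]
                obs = self._simulate_condition(cond, vals, kvec, times)
                obs_cache[lab] = obs
                if cond.normalize_with is not None:
                    norm = norms.get(cond.normalize_with)
                    if norm is None:
                        raise ValueError(
                            f"normalisation source {cond.normalize_with!r} "
                            f"was not simulated before {lab!r}"
                        )
                else:
                    m = obs.mean(axis=0)
                    norm = np.where(m > 1e-12, m, 1.0)
                    norms[lab] = norm
                scaled = obs / norm
                for col, ti, mean, sig in recs:
                    res[pos] = (scaled[ti, col] - mean) / sig
                    pos += 1
        except (IntegrationError, ValueError):
            res.fill(math.sqrt(PENALTY_CHI2 / max(self.n_datapoints, 1)))
        return res

    def chi2(self, x_log10: Sequence[float]) -> float:
        r = self.residuals(x_log10)
        return float(r @ r)


def chi2_objective(problem: FitProblem, log10_params: Sequence[float]) -> float:
    """Weighted sum of squared residuals at one log10 parameter vector."""
    x = np.asarray(log10_params, dtype=float)
    lo, hi = problem.bounds
    if np.any(x < lo - 1e-9) or np.any(x > hi + 1e-9):
        raise ValueError("parameters outside bounds")
    return problem.chi2(x)


def lhs_starts(
    bounds: "tuple[np.ndarray, np.ndarray] | Sequence[tuple[float, float]]",
    n: int,
    seed: int,
) -> np.ndarray:
    """Latin hypercube sample of ``n`` log10 start vectors.

    Stratified per dimension: the n draws of each parameter occupy the n
    equal-width bins of its range exactly once.  Degenerate dimensions
    (lower == upper) are held constant and excluded from stratification.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(bounds, tuple) and len(bounds) == 2 and np.ndim(bounds[0]) == 1:
        lo = np.asarray(bounds[0], dtype=float)
        hi = np.asarray(bounds[1], dtype=float)
    else:
        arr = np.asarray(bounds, dtype=float)
        lo, hi = arr[:, 0], arr[:, 1]
    if np.any(hi < lo):
        raise ValueError("upper bounds below lower bounds")
    d = len(lo)
    active = hi > lo
    out = np.tile(lo, (n, 1))
    n_active = int(active.sum())
    if n_active:
        sampler = qmc.LatinHypercube(d=n_active, seed=seed)
        u = sampler.random(n)
        out[:, active] = lo[active] + u * (hi[active] - lo[active])
    return out


def fit_multistart(
    problem: FitProblem,
    n_starts: int,
    seed: int,
    x0_extra: Optional[Sequence[np.ndarray]] = None,
    max_nfev: Optional[int] = None,
    xtol: float = 1e-8,
    ftol: float = 1e-8,
) -> list[FitResult]:
    """LHS-multistart bound-constrained least squares; best chi2 first.

    Every start is retained (failed starts carry the penalty chi2 and a
    False convergence flag) so downstream cluster filtering sees the full
    multistart distribution.  ``x0_extra`` prepends user-chosen starts,
    e.g. the previous best for warm-started refits.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    lo, hi = problem.bounds
    starts = list(x0_extra or []) + list(lhs_starts((lo, hi), n_starts, seed))
    results: list[FitResult] = []
    for i, x0 in enumerate(starts):
        x0 = np.clip(np.asarray(x0, dtype=float), lo, hi)
        try:
            sol = least_squares(
                problem.residuals,
                x0,
                bounds=(lo, hi),
                method="trf",
                xtol=xtol,
                ftol=ftol,
                max_nfev=max_nfev,
            )
            chi2 = float(sol.fun @ sol.fun)
            converged = bool(sol.success) and chi2 < PENALTY_CHI2 / 2
            x_best = sol.x
        except Exception:
            chi2, converged, x_best = PENALTY_CHI2, False, x0
        results.append(
            FitResult(
                log10_params=np.asarray(x_best, dtype=float),
                chi2=chi2,
                n_datapoints=problem.n_datapoints,
                converged=converged,
                start_index=i,
                seed=seed,
                free_names=problem.free_names,
            )
        )
    if not any(r.converged for r in results):
        # keep contract: all results returned, flagged; caller decides
        pass
    results.sort(key=lambda r: r.chi2)
    return results


# ---------------------------------------------------------------------------
# Extent of inhibition
# ---------------------------------------------------------------------------


def _slope(times: np.ndarray, means: np.ndarray) -> float:
    return float(np.polyfit(times, means, 1)[0])


def _anova_from_summary(
    means: np.ndarray, sems: np.ndarray, ns: np.ndarray
) -> float:
    """One-way ANOVA p-value across time points from summary statistics."""
    k = len(means)
    N = int(ns.sum())
    if k < 2 or N <= k:
        return 0.0  # cannot test; treat induction as significant
    grand = float((ns * means).sum() / N)
    ss_between = float((ns * (means - grand) ** 2).sum())
    sds = sems * np.sqrt(ns)
    ss_within = float(((ns - 1) * sds**2).sum())
    df_b, df_w = k - 1, N - k
    if ss_within <= 0:
        return 0.0 if ss_between > 0 else 1.0
    F = (ss_between / df_b) / (ss_within / df_w)
    return float(stats.f.sf(F, df_b, df_w))


def _readout_series(ds: TimeCourseDataset, readout: str):
    sub = ds.frame[ds.frame["readout"] == readout]
    if sub.empty:
        raise ValueError(f"readout {readout!r} absent from dataset")
    if sub["condition"].nunique() != 1:
        raise ValueError(
            f"dataset holds multiple conditions for {readout!r}; pass one condition"
        )
    sub = sub.sort_values("time_min")
    return (
        sub["time_min"].to_numpy(),
        sub["mean"].to_numpy(),
        sub["sem"].to_numpy(),
        sub["n_reps"].to_numpy(),
    )


def extent_of_inhibition(
    control: TimeCourseDataset,
    treated: TimeCourseDataset,
    readout: str,
    alpha: float = 0.05,
) -> float:
    """Fractional inhibition of a readout's induction by a drug.

    Fits ordinary least-squares slopes of mean intensity versus time in
    the control and treated datasets.  If the treated time course shows
    no significant change by one-way ANOVA across time points (at level
    ``alpha``), inhibition is complete and 1.0 is returned (the rule used
    to classify wortmannin as a full, Boolean inhibitor).  Otherwise the
    extent is 1 - slope_treated / slope_control, clipped to [0, 1] (83%
    for MK-2206 in the calibration data).
    """
    tc, mc, _, _ = _readout_series(control, readout)
    tt, mt, st, nt = _readout_series(treated, readout)
    slope_c = _slope(tc, mc)
    if slope_c <= 0:
        raise ValueError(
            f"control slope for {readout!r} is non-positive ({slope_c:.3g}); "
            "no induction to compare against"
        )
    p = _anova_from_summary(mt, st, nt)
    if p > alpha:
        return 1.0
    slope_t = _slope(tt, mt)
    return float(np.clip(1.0 - slope_t / slope_c, 0.0, 1.0))
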