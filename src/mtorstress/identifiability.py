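"""Practical identifiability by profile likelihood and iterative fixing.

A parameter's profile is traced by stepping its log10 value away from
the optimum and re-optimising all other free parameters at each step.
If the profile chi2 exceeds the optimum by more than a chi2 quantile
threshold (3.84, the 95% point for one degree of freedom) on a side
before hitting the bound, the parameter is identifiable on that side.

The iterative fixing loop mirrors the calibration procedure: multistart
fit, profile the free parameters, fix the identifiable ones at their
optima; when profiling fixes nothing, run a fresh multistart, keep the
better of two k-means chi2 clusters, and fix every parameter whose
retained sample distribution is unimodal at the mode of a Gaussian
kernel density estimate; repeat until no free parameters remain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import gaussian_kde
from sklearn.cluster import KMeans

from .fitting import PENALTY_CHI2, FitProblem, FitResult, fit_multistart

__all__ = [
    "LikelihoodProfile",
    "FixingLedger",
    "profile_likelihood",
    "filter_fits_by_cluster",
    "kde_mode",
    "is_unimodal",
    "iterative_fixing",
]


@dataclass
class LikelihoodProfile:
    """Profile of one parameter: grid, re-optimised chi2, and status."""

    parameter: str
    grid: np.ndarray
    chi2: np.ndarray
    best_value: float
    best_chi2: float
    status: str  # identifiable | non_identifiable_lower/upper/both
    flagged_points: list[float] = field(default_factory=list)

    def lower_bound_95(self) -> Optional[float]:
        """Profile-based interval edge on the lower side, if crossed."""
        return self._edge(side=-1)

    def upper_bound_95(self) -> Optional[float]:
        return self._edge(side=+1)

    def _edge(self, side: int) -> Optional[float]:
        thr = self.best_chi2 + 3.84
        sel = self.grid < self.best_value if side < 0 else self.grid > self.best_value
        g, c = self.grid[sel], self.chi2[sel]
        order = np.argsort(g)[::-1] if side < 0 else np.argsort(g)
        for gi, ci in zip(g[order], c[order]):
            if ci > thr:
                return float(gi)
        return None


@dataclass
class FixingRecord:
    iteration: int
    parameter: str
    fixed_value: float  # linear scale
    method: str  # "ple" or "kde_mode"
    evidence: str


@dataclass
class FixingLedger:
    """Replayable record of every parameter fixing decision."""

    records: list[FixingRecord] = field(default_factory=list)
    status: str = "running"

    def add(self, rec: FixingRecord):
        if any(r.parameter == rec.parameter for r in self.records):
            raise ValueError(f"parameter {rec.parameter} fixed twice")
        self.records.append(rec)

    def as_mapping(self) -> dict[str, float]:
        return {r.parameter: r.fixed_value for r in self.records}

    def replay(self, problem: FitProblem) -> dict[str, float]:
        """Apply the ledger to a fresh problem; returns the final vector."""
        vals = {n: problem._values[n] for n in problem.free_names}
        vals.update(self.as_mapping())
        return vals


def _reoptimise(
    problem: FitProblem, x0: np.ndarray, max_nfev: Optional[int] = None
) -> tuple[float, np.ndarray, bool]:
    lo, hi = problem.bounds
    if len(x0) == 0:
        return problem.chi2(np.array([])), np.array([]), True
    try:
        sol = least_squares(
            problem.residuals,
            np.clip(x0, lo, hi),
            bounds=(lo, hi),
            method="trf",
            xtol=1e-8,
            ftol=1e-8,
            max_nfev=max_nfev,
        )
        return float(sol.fun @ sol.fun), sol.x, bool(sol.success)
    except Exception:
        return PENALTY_CHI2, x0, False


def profile_likelihood(
    problem: FitProblem,
    best: FitResult,
    parameter: str,
    delta_chi2: float = 3.84,
    max_steps: int = 50,
    init_step: float = 0.1,
    max_nfev: Optional[int] = None,
) -> LikelihoodProfile:
    """Trace the profile likelihood of one free parameter.

    Adaptive stepping targets chi2 increments of ~0.1 * delta_chi2 per
    step (step size halved when the increment overshoots, grown when the
    profile is flat), up to ``max_steps`` per direction.  A direction is
    identifiable when the profile crosses best_chi2 + delta_chi2 before
    the bound; re-optimisation failures flag the point and continue.
    """
    if not best.converged:
        raise ValueError("profile requires a converged best fit")
    if parameter not in problem.free_names:
        raise ValueError(f"{parameter!r} is not free in this problem")
    i = problem.free_names.index(parameter)
    lo, hi = problem.bounds
    x_best = np.asarray(best.log10_params, dtype=float)
    v_best = x_best[i]
    chi2_best = best.chi2
    target = 0.1 * delta_chi2

    grid = [v_best]
    chis = [chi2_best]
    flagged: list[float] = []
    crossed = {+1: False, -1: False}

    others = [j for j in range(len(x_best)) if j != i]
    sub_free = tuple(problem.free_names[j] for j in others)

    for direction in (+1, -1):
        step = init_step
        v = v_best
        x_warm = x_best[others].copy()
        bound = hi[i] if direction > 0 else lo[i]
        last_chi2 = chi2_best
        for _ in range(max_steps):
            v_next = v + direction * step
            hit_bound = (direction > 0 and v_next >= bound) or (
                direction < 0 and v_next <= bound
            )
            if hit_bound:
                v_next = bound
            sub = problem.with_fixed({parameter: 10.0**v_next})
            assert sub.free_names == sub_free
            chi2_v, x_opt, ok = _reoptimise(sub, x_warm, max_nfev=max_nfev)
            if not ok and chi2_v >= PENALTY_CHI2 / 2:
                flagged.append(v_next)
                v = v_next
                if hit_bound:
                    break
                continue
            grid.append(v_next)
            chis.append(chi2_v)
            x_warm = x_opt
            inc = chi2_v - last_chi2
            last_chi2 = chi2_v
            if chi2_v > chi2_best + delta_chi2:
                crossed[direction] = True
                break
            if hit_bound:
                break
            if inc > 4 * target:
                step = max(step / 2, 1e-3)
            elif inc < 0.2 * target:
                step = min(step * 1.6, 0.5)
            v = v_next

    if crossed[+1] and crossed[-1]:
        status = "identifiable"
    elif crossed[+1]:
        status = "non_identifiable_lower"
    elif crossed[-1]:
        status = "non_identifiable_upper"
    else:
        status = "non_identifiable_both"

    order = np.argsort(grid)
    return LikelihoodProfile(
        parameter=parameter,
        grid=np.asarray(grid)[order],
        chi2=np.asarray(chis)[order],
        best_value=v_best,
        best_chi2=chi2_best,
        status=status,
        flagged_points=flagged,
    )


def filter_fits_by_cluster(results: Sequence[FitResult]) -> list[FitResult]:
    """Keep the multistart solutions in the better of two chi2 clusters.

    One-dimensional k-means with two clusters on the chi2 values of the
    converged fits; the cluster with the lower mean chi2 is returned.
    Degenerate inputs (all chi2 identical) return everything.
    """
    conv = [r for r in results if r.converged]
    if len(conv) < 2:
        raise ValueError("need at least two converged fits to cluster")
    chi2s = np.array([r.chi2 for r in conv]).reshape(-1, 1)
    if np.allclose(chi2s, chi2s[0]):
        return list(conv)
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(chi2s)
    means = [chi2s[km.labels_ == c].mean() for c in (0, 1)]
    keep = int(np.argmin(means))
    return [r for r, lab in zip(conv, km.labels_) if lab == keep]


def kde_mode(samples: Sequence[float]) -> float:
    """Mode of a Gaussian kernel density over log10 parameter samples.

    Scott's reference rule sets the bandwidth; the mode is the argmax on
    a fine grid spanning the sample range, so it always lies within
    [min(samples), max(samples)].  Deterministic.
    """
    s = np.asarray(samples, dtype=float)
    if len(s) < 5:
        raise ValueError("kde_mode needs at least 5 samples")
    if np.ptp(s) < 1e-12:
        return float(s.mean())
    kde = gaussian_kde(s)
    grid = np.linspace(s.min(), s.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def is_unimodal(samples: Sequence[float], window: float = 0.5, frac: float = 0.8) -> bool:
    """Heuristic unimodality: most optima end in one value range.

    True iff at least ``frac`` of the samples lie within ``window`` log10
    units of the KDE mode (boundary inclusive).  Mirrors the qualitative
    criterion that a parameter "ends nearly always in the same value
    range regardless of the starting point".
    """
    s = np.asarray(samples, dtype=float)
    if len(s) < 5:
        raise ValueError("is_unimodal needs at least 5 samples")
    mode = kde_mode(s)
    inside = np.abs(s - mode) <= window + 1e-12
    return bool(inside.mean() >= frac - 1e-12)


def iterative_fixing(
    problem: FitProblem,
    n_starts: int,
    seed: int,
    max_iterations: int = 20,
    delta_chi2: float = 3.84,
    max_nfev: Optional[int] = None,
) -> tuple[dict[str, float], FixingLedger]:
    """Run the PLE / multistart-cluster-KDE parameter fixing loop.

    Per iteration: multistart fit; profile every free parameter and fix
    the identifiable ones at their optimum values.  If profiling fixes
    nothing, filter the multistart solutions by two-cluster chi2 k-means
    and fix each free parameter whose retained sample distribution is
    unimodal at its KDE mode.  Terminates when no free parameters remain
    ("complete"), when an iteration makes no progress ("stalled"), or at
    ``max_iterations``.  Returns the final full parameter mapping (all
    originally-free parameters at their fixed values) and the ledger.
    """
    ledger = FixingLedger()
    current = problem
    rng_seq = np.random.SeedSequence(seed)
    for iteration in range(1, max_iterations + 1):
        if not current.free_names:
            ledger.status = "complete"
            break
        sub_seed = int(rng_seq.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
        results = fit_multistart(current, n_starts, sub_seed, max_nfev=max_nfev)
        best = results[0]
        if not best.converged:
            ledger.status = "stalled"
            break

        fixed_now: dict[str, float] = {}
        for pname in current.free_names:
            prof = profile_likelihood(
                current, best, pname, delta_chi2=delta_chi2, max_nfev=max_nfev
            )
            if prof.status == "identifiable":
                i = current.free_names.index(pname)
                val = 10.0 ** best.log10_params[i]
                fixed_now[pname] = val
                ledger.add(
                    FixingRecord(
                        iteration,
                        pname,
                        val,
                        "ple",
                        f"profile crossed both sides (chi2* = {best.chi2:.4g})",
                    )
                )

        if not fixed_now:
            kept = filter_fits_by_cluster(results)
            if len(kept) >= 5:
                samples = np.array([r.log10_params for r in kept])
                for j, pname in enumerate(current.free_names):
                    col = samples[:, j]
                    if is_unimodal(col):
                        val = 10.0 ** kde_mode(col)
                        fixed_now[pname] = val
                        ledger.add(
                            FixingRecord(
                                iteration,
                                pname,
                                val,
                                "kde_mode",
                                f"unimodal over {len(col)} retained fits",
                            )
                        )

        if not fixed_now:
            ledger.status = "stalled"
            break
        current = current.with_fixed(fixed_now)
    else:
        ledger.status = "max_iterations" if current.free_names else "complete"
    if not current.free_names and ledger.status == "running":
        ledger.status = "complete"

    final = {n: problem._values[n] for n in problem.free_names}
    final.update(ledger.as_mapping())
    return final, ledger
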