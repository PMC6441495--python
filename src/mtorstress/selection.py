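"""Information criteria and the systematic second-stress-input search.

Candidate models are scored with chi2-based criteria (the data2dynamics
convention): chi2 stands in for -2 log L up to an additive constant that
is shared by all models fitted to the same data with the same weights,
so rankings and differences are unaffected:

    AIC  = chi2 + 2k
    AICc = AIC + 2k(k+1)/(n - k - 1)      (undefined when n <= k + 1)
    BIC  = chi2 + k ln(n)

with k the number of free parameters and n the number of fitted means.
A candidate model counts as an improvement over the incumbent when it
reduces the AIC by at least 5%.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .data import TimeCourseDataset
from .fitting import FitProblem, fit_multistart
from .network import ModelSpec, enumerate_candidate_inputs, with_stress_input
from .simulate import Condition

__all__ = [
    "information_criteria",
    "is_improvement",
    "second_input_search",
    "compare_models",
]


def information_criteria(chi2: float, k: int, n: int) -> dict[str, float]:
    """AIC, AICc and BIC from a chi2 fit value.

    AICc is reported as NaN when the small-sample correction is undefined
    (n <= k + 1); the other criteria are still returned.
    """
    if not (math.isfinite(chi2) and chi2 >= 0):
        raise ValueError(f"chi2 must be finite and non-negative, got {chi2}")
    if k < 0 or n < 1:
        raise ValueError("k must be >= 0 and n >= 1")
    aic = chi2 + 2.0 * k
    if n > k + 1:
        aicc = aic + 2.0 * k * (k + 1) / (n - k - 1)
    else:
        aicc = math.nan
    bic = chi2 + k * math.log(n)
    return {"AIC": aic, "AICc": aicc, "BIC": bic}


def is_improvement(aic_old: float, aic_new: float, threshold: float = 0.05) -> bool:
    """True iff the AIC drops by at least ``threshold`` (relative).

    The 5% default is the acceptance rule of the stepwise input search:
    a candidate stress input is only adopted when it lowers the AIC of
    the incumbent model by 5% or more.
    """
    if not (math.isfinite(aic_old) and math.isfinite(aic_new)):
        raise ValueError("AIC values must be finite")
    if aic_old <= 0:
        raise ValueError("aic_old must be positive for a relative threshold")
    return (aic_old - aic_new) / aic_old >= threshold


def _candidate_seed(seed: int, index: int) -> int:
    return int(
        np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31 - 1)
    )


def second_input_search(
    base: ModelSpec,
    datasets: Sequence[TimeCourseDataset],
    conditions: Mapping[str, Condition],
    n_starts: int,
    seed: int,
    free: Optional[Iterable[str]] = None,
    fixed_values: Optional[Mapping[str, float]] = None,
    sigma_floor: float = 0.05,
    max_nfev: Optional[int] = None,
) -> pd.DataFrame:
    """Rank every candidate second stress input by information criteria.

    For each of the 37 candidate conversions of the single-input model, a
    model with the extra input is built and fitted by LHS multistart; the
    best chi2 and the criteria are tabulated.  Per-candidate seeds are
    derived from (seed, candidate index), so the table is reproducible
    and independent of evaluation order.  ``free`` optionally restricts
    the fitted parameters (the candidate's input-strength parameter is
    always free); a candidate whose every start fails is flagged, not
    dropped.  Returns the table sorted ascending by AIC.
    """
    if base.variant.tag != "II":
        raise ValueError("the second-input search starts from model II")
    candidates = enumerate_candidate_inputs(base)
    rows = []
    for idx, cand in enumerate(candidates):
        model_c = with_stress_input(base, cand)
        stress_name = f"k_stress_{cand.substrate}__to__{cand.product}"
        free_c = None if free is None else list(free) + [stress_name]
        problem = FitProblem(
            model_c,
            datasets,
            conditions,
            sigma_floor=sigma_floor,
            free=free_c,
            fixed_values=fixed_values,
        )
        results = fit_multistart(
            problem, n_starts, _candidate_seed(seed, idx), max_nfev=max_nfev
        )
        best = results[0]
        ok = any(r.converged for r in results)
        crit = information_criteria(best.chi2, problem.k_free, problem.n_datapoints)
        rows.append(
            {
                "substrate": cand.substrate,
                "product": cand.product,
                "chi2": best.chi2,
                "k": problem.k_free,
                "n": problem.n_datapoints,
                "AIC": crit["AIC"],
                "AICc": crit["AICc"],
                "BIC": crit["BIC"],
                "all_starts_failed": not ok,
            }
        )
    table = pd.DataFrame(rows)
    return table.sort_values("AIC", kind="mergesort").reset_index(drop=True)


def compare_models(
    fits: Mapping[str, tuple[float, int, int]]
) -> pd.DataFrame:
    """Criteria table for named models given (chi2, k, n) triples."""
    rows = []
    for name, (chi2, k, n) in fits.items():
        crit = information_criteria(chi2, k, n)
        rows.append({"model": name, "chi2": chi2, "k": k, "n": n, **crit})
    return pd.DataFrame(rows).sort_values("AIC", kind="mergesort").reset_index(drop=True)
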