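"""Profile-likelihood identifiability of the stress-input strengths.

Profiles re-optimise all other free parameters while stepping one
parameter away from its optimum; a parameter is practically identifiable
when the profile chi2 crosses the 95% threshold (3.84) on both sides
before hitting the bounds.
"""

from mtorstress import build_model, generate_dataset, ground_truth_params
from mtorstress.data import NoiseModel
from mtorstress.fitting import FitProblem, fit_multistart
from mtorstress.identifiability import profile_likelihood
from mtorstress.simulate import DEFAULT_TIMES, standard_conditions

model = build_model("V")
truth = ground_truth_params("V")
conds = standard_conditions()
datasets = [
    generate_dataset(model, truth, c, DEFAULT_TIMES, 1, NoiseModel(cv=0.0, seed=0))
    for c in conds.values()
]
problem = FitProblem(
    model, datasets, conds,
    free=["k_stress_PI3K", "k_stress_Akt_pS473", "k_TSC2_T1462"],
    fixed_values=truth,
)
best = fit_multistart(problem, 1, seed=0, x0_extra=[problem.default_x0()])[0]
print(f"optimum chi2 {best.chi2:.3g}\n")
for pname in problem.free_names:
    prof = profile_likelihood(problem, best, pname, max_nfev=30)
    lo, hi = prof.lower_bound_95(), prof.upper_bound_95()
    span = (f"log10 in ({lo:.2f}, {hi:.2f})" if lo is not None and hi is not None
            else "unbounded on one side")
    print(f"{pname:22s} {prof.status:25s} {span}")
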