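"""Build the three-input model and simulate the arsenite response.

Prints the fold change of each phospho-readout after 60 min of stress.
Values above 1 mean the readout is induced; the strong rises in
Akt-pT308/pS473, p70-S6K-pT389 and 4E-BP1-pT37/46 are the signature of
stress-activated PI3K/Akt/mTORC1 signalling.
"""

from mtorstress import build_model, ground_truth_params, simulate, standard_conditions
from mtorstress.simulate import observable_matrix
from mtorstress.network import OBSERVABLE_NAMES

model = build_model("V")
params = ground_truth_params("V")
print(f"model V: {len(model.species)} species, {len(model.reactions)} reactions, "
      f"{sum(1 for p in model.parameters if not p.fixed)} free model parameters")

for label in ("arsenite", "arsenite_wortmannin"):
    cond = standard_conditions()[label]
    traj = simulate(model, params, cond)
    obs = observable_matrix(traj)
    print(f"\n{label}: fold change at 60 min vs t = 0")
    for j, name in enumerate(OBSERVABLE_NAMES):
        print(f"  {name:15s} {obs[-1, j] / obs[0, j]:5.2f}")
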