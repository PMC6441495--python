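"""Generate the synthetic three-condition immunoblot study.

Writes one CSV per condition (plus the constant no-stress companions the
calibration uses to penalise spurious dynamics) and prints the dataset
shapes.  Each record is a (condition, readout, time) mean relative
intensity with its SEM over replicates, exactly the structure of
quantified immunoblot time courses.
"""

from pathlib import Path

from mtorstress import build_model, generate_study, ground_truth_params, write_dataset
from mtorstress.data import NoiseModel
from mtorstress.simulate import DEFAULT_TIMES, standard_conditions

out = Path("scratch_example_data")
out.mkdir(exist_ok=True)

model = build_model("V")
params = ground_truth_params("V")
datasets = generate_study(
    model, params, standard_conditions().values(), DEFAULT_TIMES,
    n_reps=4, noise=NoiseModel(cv=0.2, seed=0),
)
for ds in datasets:
    label = ds.conditions[0]
    write_dataset(ds, out / f"{label}.csv")
    print(f"{label}: {ds.n_records()} records "
          f"({len(ds.readouts)} readouts x {len(ds.times(label))} times)")
print(f"\nCSV files in {out}/")
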