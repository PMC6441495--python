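"""Time-course datasets: the study's CSV schema and synthetic generation.

A :class:`TimeCourseDataset` holds tidy records of
(condition, readout, time, mean relative intensity, SEM, replicate count),
the structure of the quantified immunoblot data the model is calibrated
on.  The generator emulates how such data arise: each biological
replicate is a model trajectory corrupted by multiplicative log-normal
noise and then normalised to the average intensity of its own readout
across the time course, mimicking per-membrane normalisation of band
intensities; means and SEMs are taken across replicates.

Two artificial constructions used during calibration are provided:
constant no-stress companion datasets (each readout frozen at its t = 0
value, to penalise spurious dynamics in the absence of stress) and the
wortmannin residual dataset (the four readouts whose remaining signal
under PI3K inhibition is attributed to additional stress inputs).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .network import OBSERVABLE_NAMES, ModelSpec
from .simulate import Condition, observable_matrix, simulate

__all__ = [
    "TimeCourseDataset",
    "NoiseModel",
    "generate_dataset",
    "generate_study",
    "make_constant_dataset",
    "make_wortmannin_residual_dataset",
    "read_dataset",
    "write_dataset",
    "WORTMANNIN_RESIDUAL_READOUTS",
]

_COLUMNS = ["condition", "readout", "time_min", "mean", "sem", "n_reps"]

#: readouts with residual signal under PI3K inhibition
WORTMANNIN_RESIDUAL_READOUTS: tuple[str, ...] = (
    "Akt_pS473",
    "p70_S6K_pT389",
    "4EBP1_pT37_46",
    "PRAS40_pS183",
)


@dataclass
class TimeCourseDataset:
    """Tidy per-(condition, readout, time) summary records."""

    frame: pd.DataFrame
    tag: Optional[str] = None

    def __post_init__(self):
        df = self.frame
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        df = df[_COLUMNS].copy()
        df["time_min"] = df["time_min"].astype(float)
        df["mean"] = df["mean"].astype(float)
        df["sem"] = df["sem"].astype(float)
        df["n_reps"] = df["n_reps"].astype(int)
        bad = ~df["readout"].isin(OBSERVABLE_NAMES)
        if bad.any():
            raise ValueError(
                f"unknown readout names: {sorted(df.loc[bad, 'readout'].unique())}"
            )
        if (df["sem"] < 0).any():
            row = int(np.argmax(df["sem"].to_numpy() < 0))
            raise ValueError(f"negative sem at row {row}")
        if (df["n_reps"] < 1).any():
            raise ValueError("n_reps must be positive")
        if (df["mean"] < 0).any():
            raise ValueError("negative mean relative intensity")
        key = df[["condition", "readout", "time_min"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(
                "duplicate record for "
                f"({dup['condition']}, {dup['readout']}, {dup['time_min']})"
            )
        self.frame = df.reset_index(drop=True)

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.frame["condition"]))

    @property
    def readouts(self) -> list[str]:
        return list(dict.fromkeys(self.frame["readout"]))

    def times(self, condition: str) -> np.ndarray:
        sub = self.frame[self.frame["condition"] == condition]
        return np.sort(sub["time_min"].unique())

    def n_records(self) -> int:
        return len(self.frame)

    def equals(self, other: "TimeCourseDataset", tol: float = 0.0) -> bool:
        a = self.frame.sort_values(["condition", "readout", "time_min"]).reset_index(
            drop=True
        )
        b = other.frame.sort_values(["condition", "readout", "time_min"]).reset_index(
            drop=True
        )
        if len(a) != len(b):
            return False
        if not (
            (a["condition"] == b["condition"]).all()
            and (a["readout"] == b["readout"]).all()
        ):
            return False
        num = ["time_min", "mean", "sem"]
        return bool(
            np.allclose(a[num], b[num], rtol=0, atol=tol)
            and (a["n_reps"] == b["n_reps"]).all()
        )


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative log-normal replicate noise with a given CV.

    ``additive`` switches to additive Gaussian noise of the same standard
    deviation scale (kept behind a flag; band intensities are positive
    and roughly scale-proportional, so multiplicative is the default).
    """

    cv: float = 0.2
    seed: int = 0
    additive: bool = False

    def __post_init__(self):
        if not (0 <= self.cv < 1):
            raise ValueError("cv must be in [0, 1) for sane generation")


def _replicate_factors(rng: np.random.Generator, noise: NoiseModel, shape) -> np.ndarray:
    if noise.cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(noise.cv**2))
    # mean-one log-normal factors
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=shape)


def generate_dataset(
    model: ModelSpec,
    params: Mapping[str, float],
    condition: Condition,
    times: Sequence[float],
    n_reps: int,
    noise: NoiseModel,
) -> TimeCourseDataset:
    """Synthesise one condition's immunoblot-style summary dataset.

    Each replicate multiplies the simulated readout trajectories by
    i.i.d. mean-one log-normal factors (or adds Gaussian noise when the
    noise model says so) and is then normalised to its own readout
    average across the time course.  Deterministic given ``noise.seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    traj = simulate(model, params, condition, times)
    obs = observable_matrix(traj)  # (n_t, 9)
    rng = np.random.default_rng(noise.seed)
    reps = np.empty((n_reps,) + obs.shape)
    for r in range(n_reps):
        if noise.additive:
            scale = noise.cv * np.maximum(obs, 0.0)
            rep = obs + rng.normal(0.0, 1.0, size=obs.shape) * scale
            rep = np.maximum(rep, 0.0)
        else:
            rep = obs * _replicate_factors(rng, noise, obs.shape)
        m = rep.mean(axis=0)
        reps[r] = np.where(m > 0, rep / np.where(m > 0, m, 1.0), rep)
    mean = reps.mean(axis=0)
    if n_reps > 1:
        sem = reps.std(axis=0, ddof=1) / np.sqrt(n_reps)
    else:
        sem = np.zeros_like(mean)
    if noise.cv == 0:
        sem = np.zeros_like(mean)
    rows = []
    for j, name in enumerate(OBSERVABLE_NAMES):
        for i, t in enumerate(traj.times):
            rows.append((condition.label, name, t, mean[i, j], sem[i, j], n_reps))
    return TimeCourseDataset(pd.DataFrame(rows, columns=_COLUMNS))


def make_constant_dataset(template: TimeCourseDataset) -> TimeCourseDataset:
    """Artificial no-stress companion: all records frozen at t = 0 values.

    Conditions are relabelled with a ``_no_stress`` suffix.  Applying the
    construction twice is idempotent.
    """
    df = template.frame.copy()
    out = []
    for (cond, readout), grp in df.groupby(["condition", "readout"], sort=False):
        t0 = grp[grp["time_min"] == 0.0]
        if len(t0) != 1:
            raise ValueError(
                f"missing t = 0 record for ({cond}, {readout}); "
                "cannot build the constant companion"
            )
        g = grp.copy()
        g["mean"] = float(t0["mean"].iloc[0])
        g["sem"] = float(t0["sem"].iloc[0])
        g["n_reps"] = int(t0["n_reps"].iloc[0])
        suffix = "" if cond.endswith("_no_stress") else "_no_stress"
        g["condition"] = cond + suffix
        out.append(g)
    return TimeCourseDataset(pd.concat(out, ignore_index=True))


def make_wortmannin_residual_dataset(
    wortmannin_ds: TimeCourseDataset,
) -> TimeCourseDataset:
    """Restrict the wortmannin dataset to the four residual-signal readouts.

    The remaining signal of these readouts under PI3K inhibition is, by
    construction of the calibration, attributed to the non-PI3K stress
    inputs; the returned dataset is tagged so fitting setups can use it
    to constrain the stress-input strength parameters only.
    """
    df = wortmannin_ds.frame
    keep_cond = [c for c in df["condition"].unique() if "wortmannin" in c]
    if not keep_cond:
        raise ValueError("no wortmannin condition present")
    sub = df[df["condition"].isin(keep_cond)]
    missing = [r for r in WORTMANNIN_RESIDUAL_READOUTS if r not in set(sub["readout"])]
    if missing:
        raise ValueError(f"wortmannin dataset lacks readouts: {missing}")
    sub = sub[sub["readout"].isin(WORTMANNIN_RESIDUAL_READOUTS)]
    return TimeCourseDataset(sub.reset_index(drop=True), tag="wortmannin_residual")


def generate_study(
    model: ModelSpec,
    params: Mapping[str, float],
    conditions: Iterable[Condition],
    times: Sequence[float],
    n_reps: int = 4,
    noise: Optional[NoiseModel] = None,
    with_companions: bool = True,
) -> list[TimeCourseDataset]:
    """Generate the multi-condition synthetic study.

    One dataset per condition (seeds derived per condition so the study
    is reproducible yet conditions are independently noisy), plus the
    constant no-stress companions when requested.
    """
    noise = noise if noise is not None else NoiseModel()
    datasets: list[TimeCourseDataset] = []
    for i, cond in enumerate(conditions):
        sub_seed = int(
            np.random.SeedSequence([noise.seed, i]).generate_state(1)[0] % (2**31 - 1)
        )
        nm = NoiseModel(cv=noise.cv, seed=sub_seed, additive=noise.additive)
        ds = generate_dataset(model, params, cond, times, n_reps, nm)
        datasets.append(ds)
        if with_companions:
            datasets.append(make_constant_dataset(ds))
    return datasets


def write_dataset(ds: TimeCourseDataset, path: "str | Path") -> None:
    ds.frame.to_csv(path, index=False, float_format="%.17g")


def read_dataset(path: "str | Path") -> TimeCourseDataset:
    try:
        df = pd.read_csv(path)
    except Exception as e:  # pragma: no cover - pandas message passthrough
        raise ValueError(f"cannot read dataset CSV {path}: {e}") from e
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return TimeCourseDataset(df)
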