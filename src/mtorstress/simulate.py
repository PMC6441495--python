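"""Condition handling, ODE integration and immunoblot observables.

A :class:`Condition` describes one experimental regime (stress step on or
off, inhibitors present or not) and names the block of condition-specific
initial-concentration parameters that set the t = 0 state.  Trajectories
are mapped to the nine phospho-readouts quantified by immunoblotting; a
readout is the summed concentration of every species carrying the probed
phosphosite (e.g. Akt_pS473 + Akt_pT308_pS473 for the S473 antibody).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import (
    DOUBLE_PHOSPHO,
    OBSERVABLE_NAMES,
    POOLS,
    SPECIES,
    SPECIES_INDEX,
    InputProfile,
    ModelSpec,
    RateParameter,
)

__all__ = [
    "Condition",
    "Trajectory",
    "OBSERVABLE_SUMMANDS",
    "DEFAULT_TIMES",
    "STANDARD_CONDITIONS",
    "standard_conditions",
    "initial_state",
    "condition_init_params",
    "pool_totals",
    "simulate",
    "compute_observables",
    "trajectory_to_tidy",
    "IntegrationError",
]

#: default sampling grid (minutes): dense early response, out to one hour
DEFAULT_TIMES: tuple[float, ...] = (0.0, 2.5, 5.0, 15.0, 30.0, 60.0)

#: summands of each immunoblot observable
OBSERVABLE_SUMMANDS: dict[str, tuple[str, ...]] = {
    "Akt_pT308": ("Akt_pT308", "Akt_pT308_pS473"),
    "Akt_pS473": ("Akt_pS473", "Akt_pT308_pS473"),
    "TSC2_pT1462": ("TSC2_pT1462",),
    "PRAS40_pS183": ("PRAS40_pS183", "PRAS40_pT246_pS183"),
    "PRAS40_pT246": ("PRAS40_pT246", "PRAS40_pT246_pS183"),
    "p70_S6K_pT389": ("p70_S6K_pT389", "p70_S6K_pT229_pT389"),
    "p70_S6K_pT229": ("p70_S6K_pT229", "p70_S6K_pT229_pT389"),
    "4EBP1_pT37_46": ("4EBP1_pT37_46",),
    "IRS1_pS636": ("IRS1_loc_pS636",),
}

_OBS_IDX = {
    name: np.array([SPECIES_INDEX[s] for s in summands])
    for name, summands in OBSERVABLE_SUMMANDS.items()
}

#: species whose initial concentration is never a free parameter:
#: double-phosphos start at zero (baseline network activity) and
#: IR-beta-pY1146 starts at zero (overnight serum starvation, no insulin).
_FIXED_ZERO_INITIALS: tuple[str, ...] = DOUBLE_PHOSPHO + ("IR_beta_pY1146",)


class IntegrationError(RuntimeError):
    """ODE integration failed; carries the offending condition label."""

    def __init__(self, message: str, condition: Optional[str] = None):
        super().__init__(message)
        self.condition = condition


@dataclass(frozen=True)
class Condition:
    """One experimental regime.

    ``init_label`` keys the initial-concentration parameter block; the
    artificial no-stress companions share the block of their parent
    condition (set ``normalize_with`` to the parent's label so their
    simulated readouts are scaled with the parent's normalisation
    constant during fitting).  ``reference_label`` names the dataset whose
    Akt_pT308 initial the wortmannin fraction parameter multiplies.
    """

    label: str
    stress_present: bool = True
    wortmannin_present: bool = False
    mk2206_present: bool = False
    insulin_level: float = 0.0
    aa_level: float = 1.0
    init_label: Optional[str] = None
    reference_label: str = "arsenite"
    normalize_with: Optional[str] = None

    @property
    def block(self) -> str:
        return self.init_label if self.init_label is not None else self.label

    def no_stress_companion(self) -> "Condition":
        """The artificial constant-value companion regime (stress off)."""
        return Condition(
            label=f"{self.label}_no_stress",
            stress_present=False,
            wortmannin_present=self.wortmannin_present,
            mk2206_present=self.mk2206_present,
            insulin_level=self.insulin_level,
            aa_level=self.aa_level,
            init_label=self.block,
            reference_label=self.reference_label,
            normalize_with=self.label,
        )


def standard_conditions() -> dict[str, Condition]:
    """The three perturbation regimes of the calibration study."""
    return {
        "arsenite": Condition("arsenite"),
        "arsenite_wortmannin": Condition("arsenite_wortmannin", wortmannin_present=True),
        "arsenite_mk2206": Condition("arsenite_mk2206", mk2206_present=True),
    }


STANDARD_CONDITIONS = standard_conditions()


def condition_init_params(condition: Condition) -> list[RateParameter]:
    """Parameter definitions of one condition's initial-concentration block.

    Every species except the zero-pinned ones gets a parameter
    ``init_<species>__<block>``.  Under wortmannin, PI3K_p additionally
    starts at zero (30-min pre-inhibition) and the Akt_pT308 initial is
    replaced by a fraction of the reference (arsenite) dataset's value.
    """
    block = condition.block
    out: list[RateParameter] = []
    for sp in SPECIES:
        if sp in _FIXED_ZERO_INITIALS:
            continue
        if condition.wortmannin_present and sp == "PI3K_p":
            continue
        if condition.wortmannin_present and sp == "Akt_pT308":
            out.append(
                RateParameter(f"frac_Akt_pT308__{block}", 0.5, "fraction")
            )
            continue
        out.append(
            RateParameter(f"init_{sp}__{block}", 0.1, "initial_concentration")
        )
    return out


def initial_state(
    model: ModelSpec, condition: Condition, params: Mapping[str, float]
) -> np.ndarray:
    """Assemble the t = 0 state vector from a condition's parameter block."""
    block = condition.block
    x = np.zeros(len(SPECIES))
    for i, sp in enumerate(SPECIES):
        if sp in _FIXED_ZERO_INITIALS:
            continue
        if condition.wortmannin_present and sp == "PI3K_p":
            continue
        if condition.wortmannin_present and sp == "Akt_pT308":
            fkey = f"frac_Akt_pT308__{block}"
            rkey = f"init_Akt_pT308__{condition.reference_label}"
            if fkey not in params or rkey not in params:
                raise KeyError(
                    f"missing {fkey!r} or {rkey!r} for condition {condition.label!r}"
                )
            x[i] = params[fkey] * params[rkey]
            continue
        key = f"init_{sp}__{block}"
        if key not in params:
            raise KeyError(
                f"missing initial-concentration parameter {key!r} "
                f"for condition {condition.label!r}"
            )
        x[i] = params[key]
    if np.any(x < 0):
        raise ValueError("negative initial concentrations")
    return x


def pool_totals(state: Sequence[float]) -> np.ndarray:
    """Conserved totals, one per pool, summed from a state vector."""
    x = np.asarray(state, dtype=float)
    return np.array([x[list(p.member_indices)].sum() for p in POOLS])


@dataclass(frozen=True)
class Trajectory:
    """Integrated time course: times (min) by 25-species states (a.u.)."""

    times: np.ndarray
    states: np.ndarray
    condition: Optional[str] = None

    def species(self, name: str) -> np.ndarray:
        return self.states[:, SPECIES_INDEX[name]]


def _kinetic_vector(model: ModelSpec, params: Mapping[str, float]) -> np.ndarray:
    vals = []
    for p in model.parameters:
        vals.append(params.get(p.name, p.value))
    return np.array(vals, dtype=float)


def _integrate(
    model: ModelSpec,
    kvals: np.ndarray,
    x0: np.ndarray,
    inputs: InputProfile,
    times: np.ndarray,
    rtol: float,
    atol: float,
    condition_label: Optional[str] = None,
) -> np.ndarray:
    f = model.compiled().rhs_factory(kvals, inputs)
    sol = solve_ivp(
        f,
        (times[0], times[-1]),
        x0,
        method="LSODA",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"integrator failed for condition {condition_label!r}: {sol.message}",
            condition=condition_label,
        )
    states = sol.y.T
    if np.any(states < -1e-6):
        raise IntegrationError(
            f"trajectory went negative beyond tolerance for {condition_label!r}",
            condition=condition_label,
        )
    return np.maximum(states, 0.0)


def simulate(
    model: ModelSpec,
    params: Mapping[str, float],
    condition: Condition,
    times: Sequence[float] = DEFAULT_TIMES,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate ``model`` under ``condition`` over ``times``.

    ``params`` maps parameter names to values and must cover the
    condition's initial-concentration block; kinetic parameters missing
    from the mapping fall back to the model's stored defaults.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0) or t[0] != 0.0:
        raise ValueError("times must be strictly increasing and start at 0")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")
    x0 = initial_state(model, condition, params)
    inputs = InputProfile(
        stress=1.0 if condition.stress_present else 0.0,
        aa=condition.aa_level,
        insulin=condition.insulin_level,
        wortmannin=condition.wortmannin_present,
        mk2206=condition.mk2206_present,
        pool_totals=pool_totals(x0),
    )
    kvals = _kinetic_vector(model, params)
    states = _integrate(model, kvals, x0, inputs, t, rtol, atol, condition.label)
    return Trajectory(times=t, states=states, condition=condition.label)


def compute_observables(model: ModelSpec, traj: Trajectory) -> pd.DataFrame:
    """Tidy table of the nine readouts: (observable, time, value)."""
    rows = []
    for name in OBSERVABLE_NAMES:
        vals = traj.states[:, _OBS_IDX[name]].sum(axis=1)
        for t, v in zip(traj.times, vals):
            rows.append((name, t, v))
    return pd.DataFrame(rows, columns=["observable", "time_min", "value"])


def observable_matrix(traj: Trajectory) -> np.ndarray:
    """Readout values as an (n_times, 9) array in OBSERVABLE_NAMES order."""
    return np.column_stack(
        [traj.states[:, _OBS_IDX[name]].sum(axis=1) for name in OBSERVABLE_NAMES]
    )


def trajectory_to_tidy(model: ModelSpec, traj: Trajectory) -> pd.DataFrame:
    """Species and observable series as one tidy frame for CSV export."""
    rows = []
    label = traj.condition or ""
    for j, sp in enumerate(SPECIES):
        for t, v in zip(traj.times, traj.states[:, j]):
            rows.append((label, "species", sp, t, v))
    obs = compute_observables(model, traj)
    for _, r in obs.iterrows():
        rows.append((label, "observable", r["observable"], r["time_min"], r["value"]))
    return pd.DataFrame(
        rows, columns=["condition", "series_type", "name", "time_min", "value"]
    )
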