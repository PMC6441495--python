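"""Reaction network of stress signalling through PI3K/Akt/TSC2 to mTORC1.

The model tracks 25 phosphorylation/localisation states of nine proteins
(IR-beta, IRS1, PI3K, PDK1, Akt, TSC2, PRAS40, p70-S6K, 4E-BP1).  Each
protein forms a conserved pool: its states interconvert by first-order
mass-action reactions but their summed concentration never changes.  The
kinases mTORC1 and mTORC2 are not explicit species; they act through
activity expressions attached to the phosphorylation of their substrates.
Inhibition by TSC2 and PRAS40 is concentration dependent — the inhibitory
efficiency scales with the inhibitor's concentration relative to its pool
total — while the drugs wortmannin and MK-2206 follow a Boolean-like
scheme (full inhibition of PI3K activation, partial inhibition of Akt
activity, only while present).

Five model variants differ solely in where the acute-stress step input
(arsenite at t = 0) enters and in whether Akt phosphorylated at S473
alone contributes to Akt activity:

    I   no stress input
    II  stress on PI3K activation
    III II + stress on Akt -> Akt_pS473
    IV  III, but Akt_pS473 alone cannot activate mTORC1 substrates
    V   IV + stress drive directly on mTORC1

Concentrations are in arbitrary units (a.u.), time in minutes, rate
constants per minute (activity factors are dimensionless fractions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SPECIES",
    "POOLS",
    "OBSERVABLE_NAMES",
    "MK2206_EXTENT",
    "ConservationPool",
    "RateParameter",
    "Reaction",
    "ModelVariant",
    "ModelSpec",
    "InputProfile",
    "build_model",
    "enumerate_candidate_inputs",
    "with_stress_input",
    "evaluate_rhs",
    "model_summary",
]

# ---------------------------------------------------------------------------
# Species and conserved pools
# ---------------------------------------------------------------------------

#: Canonical state ordering.  All state vectors use this order.
SPECIES: tuple[str, ...] = (
    "IR_beta",
    "IR_beta_pY1146",
    "IRS1",
    "IRS1_loc",
    "IRS1_loc_pS636",
    "PI3K",
    "PI3K_p",
    "PDK1_cyt",
    "PDK1_mem",
    "Akt",
    "Akt_pT308",
    "Akt_pS473",
    "Akt_pT308_pS473",
    "TSC2",
    "TSC2_pT1462",
    "PRAS40",
    "PRAS40_pT246",
    "PRAS40_pS183",
    "PRAS40_pT246_pS183",
    "p70_S6K",
    "p70_S6K_pT229",
    "p70_S6K_pT389",
    "p70_S6K_pT229_pT389",
    "4EBP1",
    "4EBP1_pT37_46",
)

SPECIES_INDEX: dict[str, int] = {name: i for i, name in enumerate(SPECIES)}

#: Species that start doubly phosphorylated and are pinned to zero at t = 0
#: (baseline mTOR network activity after overnight serum starvation).
DOUBLE_PHOSPHO: tuple[str, ...] = (
    "Akt_pT308_pS473",
    "PRAS40_pT246_pS183",
    "p70_S6K_pT229_pT389",
)


@dataclass(frozen=True)
class ConservationPool:
    """A protein whose phospho/localisation states share a constant total."""

    name: str
    members: tuple[str, ...]

    @property
    def member_indices(self) -> tuple[int, ...]:
        return tuple(SPECIES_INDEX[m] for m in self.members)


POOLS: tuple[ConservationPool, ...] = (
    ConservationPool("IR", ("IR_beta", "IR_beta_pY1146")),
    ConservationPool("IRS1", ("IRS1", "IRS1_loc", "IRS1_loc_pS636")),
    ConservationPool("PI3K", ("PI3K", "PI3K_p")),
    ConservationPool("PDK1", ("PDK1_cyt", "PDK1_mem")),
    ConservationPool("Akt", ("Akt", "Akt_pT308", "Akt_pS473", "Akt_pT308_pS473")),
    ConservationPool("TSC2", ("TSC2", "TSC2_pT1462")),
    ConservationPool(
        "PRAS40", ("PRAS40", "PRAS40_pT246", "PRAS40_pS183", "PRAS40_pT246_pS183")
    ),
    ConservationPool(
        "p70_S6K",
        ("p70_S6K", "p70_S6K_pT229", "p70_S6K_pT389", "p70_S6K_pT229_pT389"),
    ),
    ConservationPool("4EBP1", ("4EBP1", "4EBP1_pT37_46")),
)

POOL_INDEX: dict[str, int] = {p.name: i for i, p in enumerate(POOLS)}

#: pool index of every species (species are partitioned by the pools)
SPECIES_POOL: tuple[int, ...] = tuple(
    next(POOL_INDEX[p.name] for p in POOLS if s in p.members) for s in SPECIES
)

OBSERVABLE_NAMES: tuple[str, ...] = (
    "Akt_pT308",
    "Akt_pS473",
    "TSC2_pT1462",
    "PRAS40_pS183",
    "PRAS40_pT246",
    "p70_S6K_pT389",
    "p70_S6K_pT229",
    "4EBP1_pT37_46",
    "IRS1_pS636",
)

#: Fractional inhibition of Akt activity by MK-2206 (partial inhibition,
#: derived from the slope ratio of TSC2-pT1462 induction with/without drug).
MK2206_EXTENT: float = 0.83

# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

#: default log10 bounds per parameter class
_KLASS_BOUNDS: dict[str, tuple[float, float]] = {
    "generic": (-5.0, 3.0),
    "mass_action": (-5.0, 1.0),
    "pi3k_activation": (-5.0, -2.0),
    "input_strength": (-5.0, 3.0),
    "initial_concentration": (-5.0, 1.0),
    "fraction": (-5.0, 0.0),
}


@dataclass(frozen=True)
class RateParameter:
    """A model parameter with log10 box bounds used during estimation."""

    name: str
    value: float
    klass: str = "generic"
    log10_lower: Optional[float] = None
    log10_upper: Optional[float] = None
    fixed: bool = False

    def __post_init__(self):
        if self.klass not in _KLASS_BOUNDS:
            raise ValueError(f"unknown parameter class {self.klass!r}")
        lo, hi = _KLASS_BOUNDS[self.klass]
        if self.log10_lower is None:
            object.__setattr__(self, "log10_lower", lo)
        if self.log10_upper is None:
            object.__setattr__(self, "log10_upper", hi)
        if self.value < 0:
            raise ValueError(f"parameter {self.name}: negative value {self.value}")
        if not self.fixed and self.value > 0:
            lv = math.log10(self.value)
            if not (self.log10_lower - 1e-9 <= lv <= self.log10_upper + 1e-9):
                raise ValueError(
                    f"parameter {self.name}: log10({self.value}) = {lv:.3f} "
                    f"outside [{self.log10_lower}, {self.log10_upper}]"
                )


# ---------------------------------------------------------------------------
# Reactions
# ---------------------------------------------------------------------------

#: activity-expression codes usable as reaction modifiers
_MODIFIERS = (
    "none",
    "insulin",
    "A_IR",
    "A_IRS1",
    "A_PI3K",
    "A_PDK1",
    "A_Akt",
    "A_S6K",
    "A_mTORC1",
    "A_mTORC2",
)
_MOD_CODE = {m: i for i, m in enumerate(_MODIFIERS)}


@dataclass(frozen=True)
class Reaction:
    """One first-order conversion substrate -> product.

    ``multiplicity`` is 2 for the six second-phosphorylation steps of the
    doubly phosphorylated proteins, which share their rate constant with
    the corresponding first phosphorylation and proceed twice as fast.
    ``stress_param`` names an input-strength parameter whose flux
    k_stress * u_stress(t) * [substrate] adds to the mass-action term.
    """

    substrate: str
    product: str
    rate_param: str
    modifier: str = "none"
    multiplicity: int = 1
    wortmannin_sensitive: bool = False
    mk2206_sensitive: bool = False
    stress_param: Optional[str] = None

    def __post_init__(self):
        if self.substrate not in SPECIES_INDEX or self.product not in SPECIES_INDEX:
            raise ValueError(f"unknown species in {self.substrate}->{self.product}")
        if SPECIES_POOL[SPECIES_INDEX[self.substrate]] != SPECIES_POOL[
            SPECIES_INDEX[self.product]
        ]:
            raise ValueError(
                f"{self.substrate}->{self.product} crosses conservation pools"
            )
        if self.modifier not in _MOD_CODE:
            raise ValueError(f"unknown modifier {self.modifier!r}")
        if self.multiplicity not in (1, 2):
            raise ValueError("multiplicity must be 1 or 2")

    @property
    def key(self) -> tuple[str, str]:
        return (self.substrate, self.product)


# The 37 convertible reactions, in the canonical ranking-table order used by
# the systematic second-stress-input search, followed by PI3K activation
# (which carries the primary stress input and is therefore never a search
# candidate).
_REACTION_TABLE: tuple[Reaction, ...] = (
    Reaction("Akt", "Akt_pS473", "k_Akt_S473", "A_mTORC2"),
    Reaction("Akt_pT308", "Akt_pT308_pS473", "k_Akt_S473", "A_mTORC2", 2),
    Reaction("PDK1_cyt", "PDK1_mem", "k_PDK1_mem", "A_PI3K"),
    Reaction("Akt", "Akt_pT308", "k_Akt_T308", "A_PDK1"),
    Reaction("TSC2", "TSC2_pT1462", "k_TSC2_T1462", "A_Akt", mk2206_sensitive=True),
    Reaction("PRAS40", "PRAS40_pT246", "k_PRAS40_T246", "A_Akt", mk2206_sensitive=True),
    Reaction("PRAS40", "PRAS40_pS183", "k_PRAS40_S183", "A_mTORC1"),
    Reaction("p70_S6K", "p70_S6K_pT389", "k_S6K_T389", "A_mTORC1"),
    Reaction(
        "PRAS40_pS183",
        "PRAS40_pT246_pS183",
        "k_PRAS40_T246",
        "A_Akt",
        2,
        mk2206_sensitive=True,
    ),
    Reaction("p70_S6K", "p70_S6K_pT229", "k_S6K_T229", "A_PDK1"),
    Reaction("IR_beta", "IR_beta_pY1146", "k_IR_act", "insulin"),
    Reaction("IRS1", "IRS1_loc_pS636", "k_IRS1_S636_cyt", "A_S6K"),
    Reaction("IRS1", "IRS1_loc", "k_IRS1_loc", "A_IR"),
    Reaction("4EBP1", "4EBP1_pT37_46", "k_4EBP1_T37_46", "A_mTORC1"),
    Reaction("PRAS40_pS183", "PRAS40", "kd_PRAS40_S183"),
    Reaction("p70_S6K_pT229", "p70_S6K_pT229_pT389", "k_S6K_T389", "A_mTORC1", 2),
    Reaction("p70_S6K_pT389", "p70_S6K_pT229_pT389", "k_S6K_T229", "A_PDK1", 2),
    Reaction("Akt_pT308_pS473", "Akt_pT308", "kd_Akt_S473"),
    Reaction("Akt_pT308_pS473", "Akt_pS473", "kd_Akt_T308"),
    Reaction("PRAS40_pT246", "PRAS40_pT246_pS183", "k_PRAS40_S183", "A_mTORC1", 2),
    Reaction("IRS1_loc", "IRS1_loc_pS636", "k_IRS1_S636_loc", "A_S6K"),
    Reaction("TSC2_pT1462", "TSC2", "kd_TSC2_T1462"),
    Reaction("PI3K_p", "PI3K", "kd_PI3K"),
    Reaction("PDK1_mem", "PDK1_cyt", "kd_PDK1"),
    Reaction("p70_S6K_pT229", "p70_S6K", "kd_S6K_T229"),
    Reaction("IR_beta_pY1146", "IR_beta", "kd_IR"),
    Reaction("Akt_pS473", "Akt_pT308_pS473", "k_Akt_T308", "A_PDK1", 2),
    Reaction("PRAS40_pT246", "PRAS40", "kd_PRAS40_T246"),
    Reaction("PRAS40_pT246_pS183", "PRAS40_pS183", "kd_PRAS40_T246"),
    Reaction("4EBP1_pT37_46", "4EBP1", "kd_4EBP1"),
    Reaction("PRAS40_pT246_pS183", "PRAS40_pT246", "kd_PRAS40_S183"),
    Reaction("p70_S6K_pT229_pT389", "p70_S6K_pT389", "kd_S6K_T229"),
    Reaction("Akt_pS473", "Akt", "kd_Akt_S473"),
    Reaction("Akt_pT308", "Akt", "kd_Akt_T308"),
    Reaction("IRS1_loc_pS636", "IRS1", "kd_IRS1"),
    Reaction("p70_S6K_pT389", "p70_S6K", "kd_S6K_T389"),
    Reaction("p70_S6K_pT229_pT389", "p70_S6K_pT229", "kd_S6K_T389"),
    Reaction(
        "PI3K", "PI3K_p", "k_PI3K_act", "A_IRS1", wortmannin_sensitive=True
    ),
)

_PI3K_ACTIVATION_KEY = ("PI3K", "PI3K_p")

#: kinetic rate parameters shared by every variant (name, klass).
#: k_IR_act is the insulin input strength; the cells are serum starved so the
#: insulin drive is zero and the parameter is fixed (not counted as free).
_KINETIC_PARAMS: tuple[tuple[str, str, bool], ...] = (
    ("k_IR_act", "input_strength", True),
    ("kd_IR", "mass_action", False),
    ("k_IRS1_loc", "mass_action", False),
    ("k_IRS1_S636_cyt", "mass_action", False),
    ("k_IRS1_S636_loc", "mass_action", False),
    ("kd_IRS1", "mass_action", False),
    ("k_PI3K_act", "pi3k_activation", False),
    ("kd_PI3K", "mass_action", False),
    ("k_PDK1_mem", "mass_action", False),
    ("kd_PDK1", "mass_action", False),
    ("k_Akt_T308", "mass_action", False),
    ("k_Akt_S473", "mass_action", False),
    ("kd_Akt_T308", "mass_action", False),
    ("kd_Akt_S473", "mass_action", False),
    ("k_TSC2_T1462", "mass_action", False),
    ("kd_TSC2_T1462", "mass_action", False),
    ("k_PRAS40_T246", "mass_action", False),
    ("k_PRAS40_S183", "mass_action", False),
    ("kd_PRAS40_T246", "mass_action", False),
    ("kd_PRAS40_S183", "mass_action", False),
    ("k_S6K_T229", "mass_action", False),
    ("k_S6K_T389", "mass_action", False),
    ("kd_S6K_T229", "mass_action", False),
    ("kd_S6K_T389", "mass_action", False),
    ("k_4EBP1_T37_46", "mass_action", False),
    ("kd_4EBP1", "mass_action", False),
    ("k_aa", "input_strength", False),
)

# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelVariant:
    """Where stress enters and whether Akt-pS473 alone carries activity."""

    tag: str
    stress_on_PI3K: bool
    stress_on_AktS473: bool
    stress_on_mTORC1: bool
    aktS473_alone_activates: bool


_VARIANTS: dict[str, ModelVariant] = {
    "I": ModelVariant("I", False, False, False, True),
    "II": ModelVariant("II", True, False, False, True),
    "III": ModelVariant("III", True, True, False, True),
    "IV": ModelVariant("IV", True, True, False, False),
    "V": ModelVariant("V", True, True, True, False),
}


@dataclass(frozen=True)
class InputProfile:
    """Time-independent drive and drug context for one simulated condition.

    ``stress`` is the amplitude of the unit-step arsenite input (0 or 1),
    active for all t >= 0.  ``pool_totals`` are the conserved totals, in
    pool order, computed from the condition's initial state.
    """

    stress: float = 0.0
    aa: float = 1.0
    insulin: float = 0.0
    wortmannin: bool = False
    mk2206: bool = False
    pool_totals: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# ModelSpec
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """A concrete, simulatable instance of one network variant."""

    variant: ModelVariant
    reactions: tuple[Reaction, ...]
    parameters: tuple[RateParameter, ...]
    species: tuple[str, ...] = SPECIES
    pools: tuple[ConservationPool, ...] = POOLS
    #: name of the parameter driving mTORC1 under stress (variant V route)
    mtorc1_stress_param: Optional[str] = None

    def __post_init__(self):
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise ValueError("duplicate parameter names")

    @property
    def param_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.parameters)

    @property
    def param_index(self) -> dict[str, int]:
        return {p.name: i for i, p in enumerate(self.parameters)}

    def default_values(self) -> np.ndarray:
        return np.array([p.value for p in self.parameters])

    def n_stress_inputs(self) -> int:
        n = sum(1 for r in self.reactions if r.stress_param is not None)
        if self.mtorc1_stress_param is not None:
            n += 1
        return n

    # -- compiled form -----------------------------------------------------

    def compiled(self) -> "_CompiledModel":
        c = getattr(self, "_compiled_cache", None)
        if c is None:
            c = _CompiledModel(self)
            object.__setattr__(self, "_compiled_cache", c)
        return c


class _CompiledModel:
    """Index arrays so the right-hand side is a handful of numpy ops."""

    def __init__(self, model: ModelSpec):
        pidx = model.param_index
        n_r = len(model.reactions)
        self.sub = np.array([SPECIES_INDEX[r.substrate] for r in model.reactions])
        self.prod = np.array([SPECIES_INDEX[r.product] for r in model.reactions])
        self.kidx = np.array([pidx[r.rate_param] for r in model.reactions])
        self.mult = np.array([float(r.multiplicity) for r in model.reactions])
        self.mod = np.array([_MOD_CODE[r.modifier] for r in model.reactions])
        self.wort = np.array([r.wortmannin_sensitive for r in model.reactions])
        self.mk = np.array([r.mk2206_sensitive for r in model.reactions])
        srows, skidx = [], []
        for i, r in enumerate(model.reactions):
            if r.stress_param is not None:
                srows.append(i)
                skidx.append(pidx[r.stress_param])
        self.stress_rows = np.array(srows, dtype=int)
        self.stress_kidx = np.array(skidx, dtype=int)
        self.k_aa = pidx["k_aa"]
        self.k_c1 = (
            pidx[model.mtorc1_stress_param]
            if model.mtorc1_stress_param is not None
            else -1
        )
        self.s_flag = 1.0 if model.variant.aktS473_alone_activates else 0.0
        # stoichiometry (25 x n_r)
        S = np.zeros((len(SPECIES), n_r))
        S[self.sub, np.arange(n_r)] -= 1.0
        S[self.prod, np.arange(n_r)] += 1.0
        self.S = S

    def rhs_factory(self, kvals: np.ndarray, inputs: InputProfile):
        """Return f(t, x) -> dx/dt for a fixed parameter vector and inputs."""
        C = inputs.pool_totals
        if C is None:
            raise ValueError("InputProfile.pool_totals is required for simulation")
        C = np.asarray(C, dtype=float)
        if C.shape != (len(POOLS),) or np.any(C <= 0):
            raise ValueError("pool_totals must be 9 positive totals")
        k = np.asarray(kvals, dtype=float)
        if not np.all(np.isfinite(k)):
            raise ValueError("non-finite parameter values")
        base = k[self.kidx] * self.mult
        mk_scale = (1.0 - MK2206_EXTENT) if inputs.mk2206 else 1.0
        drive = k[self.k_aa] * inputs.aa
        if self.k_c1 >= 0:
            drive = drive + k[self.k_c1] * inputs.stress
        stress_k = (
            k[self.stress_kidx] * inputs.stress if len(self.stress_rows) else None
        )
        sub, prod, mod = self.sub, self.prod, self.mod
        S = self.S
        wort_off = inputs.wortmannin
        wort_mask = self.wort
        mk_mask = self.mk
        s_flag = self.s_flag
        ins = inputs.insulin
        n_r = len(sub)
        act = np.empty(len(_MODIFIERS))

        def f(t: float, x: np.ndarray) -> np.ndarray:
            act[0] = 1.0
            act[1] = ins
            act[2] = x[1] / C[0]               # A_IR
            act[3] = x[3] / C[1]               # A_IRS1
            a_pi3k = x[6] / C[2]
            act[4] = a_pi3k                    # A_PI3K
            act[5] = x[8] / C[3]               # A_PDK1
            act[6] = mk_scale * (x[10] + s_flag * x[11] + 2.0 * x[12]) / C[4]  # A_Akt
            act[7] = (x[21] + x[22]) / C[7]    # A_S6K
            f_tsc2 = 1.0 - x[13] / C[5]
            f_pras = 1.0 - x[15] / C[6]
            if f_tsc2 < 0.0:
                f_tsc2 = 0.0
            if f_pras < 0.0:
                f_pras = 0.0
            act[8] = drive * f_tsc2 * f_pras   # A_mTORC1
            act[9] = a_pi3k                    # A_mTORC2 (driven by PI3K)
            v = base * x[sub] * act[mod]
            if stress_k is not None:
                v[self.stress_rows] += stress_k * x[sub[self.stress_rows]]
            if wort_off:
                v[wort_mask] = 0.0
            return S @ v

        return f


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------


def _default_kinetic_value(name: str, klass: str) -> float:
    # neutral mid-range starting values; calibrated regimes live elsewhere
    if klass == "pi3k_activation":
        return 1e-3
    return 0.1


def build_model(variant: "str | ModelVariant") -> ModelSpec:
    """Assemble a complete ModelSpec for variant I..V.

    The reaction set is identical across variants; variants differ only in
    which reactions carry a stress input and in the Akt activity formula.
    """
    if isinstance(variant, ModelVariant):
        tag = variant.tag
    else:
        tag = str(variant)
    if tag not in _VARIANTS:
        raise ValueError(
            f"unknown model variant {tag!r}; valid tags are I, II, III, IV, V"
        )
    var = _VARIANTS[tag]

    params = [
        RateParameter(name, _default_kinetic_value(name, klass), klass, fixed=fixed)
        for name, klass, fixed in _KINETIC_PARAMS
    ]
    reactions = list(_REACTION_TABLE)

    def attach(key: tuple[str, str], pname: str):
        for i, r in enumerate(reactions):
            if r.key == key:
                reactions[i] = replace(r, stress_param=pname)
                return
        raise ValueError(f"no reaction {key}")

    mtorc1_param = None
    if var.stress_on_PI3K:
        params.append(RateParameter("k_stress_PI3K", 1e-3, "pi3k_activation"))
        attach(_PI3K_ACTIVATION_KEY, "k_stress_PI3K")
    if var.stress_on_AktS473:
        params.append(RateParameter("k_stress_Akt_pS473", 0.01, "input_strength"))
        attach(("Akt", "Akt_pS473"), "k_stress_Akt_pS473")
    if var.stress_on_mTORC1:
        params.append(RateParameter("k_stress_mTORC1", 0.01, "input_strength"))
        mtorc1_param = "k_stress_mTORC1"

    return ModelSpec(
        variant=var,
        reactions=tuple(reactions),
        parameters=tuple(params),
        mtorc1_stress_param=mtorc1_param,
    )


def enumerate_candidate_inputs(model: ModelSpec) -> list[Reaction]:
    """All conversions that can receive an additional stress input.

    Defined for the single-input model (variant II): every reaction except
    the already-stressed PI3K activation, in the canonical table order.
    """
    if model.n_stress_inputs() >= 2:
        raise ValueError(
            "candidate enumeration is defined for the single-input model; "
            f"this model already carries {model.n_stress_inputs()} stress inputs"
        )
    return [r for r in model.reactions if r.key != _PI3K_ACTIVATION_KEY]


def with_stress_input(
    model: ModelSpec, target: "Reaction | tuple[str, str] | str"
) -> ModelSpec:
    """Return a copy of ``model`` with one extra stress input on ``target``.

    ``target`` is a candidate reaction (or its (substrate, product) pair),
    or the sentinel ``"mTORC1"`` to add the direct stress drive on mTORC1
    substrates.  Adds exactly one free input-strength parameter.
    """
    params = list(model.parameters)
    if isinstance(target, str):
        if target != "mTORC1":
            raise ValueError("string target must be 'mTORC1'")
        if model.mtorc1_stress_param is not None:
            raise ValueError("model already carries a stress input on mTORC1")
        pname = "k_stress_mTORC1"
        params.append(RateParameter(pname, 0.01, "input_strength"))
        var = replace(model.variant, tag=model.variant.tag, stress_on_mTORC1=True)
        return ModelSpec(
            variant=var,
            reactions=model.reactions,
            parameters=tuple(params),
            mtorc1_stress_param=pname,
        )

    key = target.key if isinstance(target, Reaction) else tuple(target)
    candidates = {r.key for r in model.reactions if r.key != _PI3K_ACTIVATION_KEY}
    if key not in candidates:
        raise ValueError(f"{key} is not a candidate reaction of this model")
    reactions = []
    pname = f"k_stress_{key[0]}__to__{key[1]}"
    for r in model.reactions:
        if r.key == key:
            if r.stress_param is not None:
                raise ValueError(f"reaction {key} already carries a stress input")
            reactions.append(replace(r, stress_param=pname))
        else:
            reactions.append(r)
    klass = "input_strength"
    params.append(RateParameter(pname, 0.01, klass))
    return ModelSpec(
        variant=model.variant,
        reactions=tuple(reactions),
        parameters=tuple(params),
        mtorc1_stress_param=model.mtorc1_stress_param,
    )


# ---------------------------------------------------------------------------
# Right-hand side
# ---------------------------------------------------------------------------


def evaluate_rhs(
    model: ModelSpec,
    state: Sequence[float],
    params: Sequence[float],
    inputs: InputProfile,
    t: float = 0.0,
) -> np.ndarray:
    """Time derivative of the 25-species state vector (a.u./min).

    Validating wrapper around the compiled right-hand side; inner loops
    (the integrator, the fit objective) use the compiled closure directly.
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (len(SPECIES),):
        raise ValueError(f"state must have length {len(SPECIES)}")
    if np.any(x < -1e-8):
        raise ValueError("negative state entries beyond tolerance")
    p = np.asarray(params, dtype=float)
    if p.shape != (len(model.parameters),):
        raise ValueError(
            f"expected {len(model.parameters)} parameter values, got {p.shape}"
        )
    if not np.all(np.isfinite(p)):
        raise ValueError("NaN/Inf in parameter vector")
    f = model.compiled().rhs_factory(p, inputs)
    return f(t, np.maximum(x, 0.0))


def model_summary(model: ModelSpec) -> str:
    """Plain-text summary: species, reactions, parameters with bounds."""
    lines = [f"Model variant {model.variant.tag}"]
    lines.append(f"  species ({len(model.species)}):")
    for p in model.pools:
        lines.append(f"    pool {p.name}: " + ", ".join(p.members))
    lines.append(f"  reactions ({len(model.reactions)}):")
    for r in model.reactions:
        extra = []
        if r.modifier != "none":
            extra.append(f"x {r.modifier}")
        if r.multiplicity == 2:
            extra.append("x2")
        if r.stress_param:
            extra.append(f"+ stress({r.stress_param})")
        if r.wortmannin_sensitive:
            extra.append("[wortmannin]")
        if r.mk2206_sensitive:
            extra.append("[MK-2206]")
        lines.append(
            f"    {r.substrate} -> {r.product}  (k = {r.rate_param}"
            + (", " + ", ".join(extra) if extra else "")
            + ")"
        )
    if model.mtorc1_stress_param:
        lines.append(f"  mTORC1 stress drive: {model.mtorc1_stress_param}")
    lines.append(f"  parameters ({len(model.parameters)}):")
    for p in model.parameters:
        tag = " (fixed)" if p.fixed else ""
        lines.append(
            f"    {p.name:24s} {p.value:.4g}  [{p.log10_lower}, {p.log10_upper}] "
            f"{p.klass}{tag}"
        )
    return "\n".join(lines)
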