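"""Sender/reporter consortium assembly: logic gates, preconditioning, scoring.

A gate couples one or two sender populations to one or two reporter
populations through a single shared medium alpha-factor pool.  Each
sender population contributes ``k33*[prepro_Alpha]/dilution(t)`` to the
pool; reporters read the pool without depleting it (the dilution factor
makes per-cell consumption negligible).  A reporter population is
GFP-positive when cytoplasmic mature GFP at the readout time reaches
the common 4.5 uM threshold.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .cells import (
    CellModel,
    CultureConfig,
    DEFAULT_CULTURE,
    GalCell,
    InputSignal,
    ReporterCell,
    SaltCell,
    make_cell,
)
from .deterministic import Trajectory, integrate
from .units import DEFAULT_GEOMETRY, UM, CellGeometry

#: common GFP-positive threshold, uM cytoplasmic mature GFP
GFP_THRESHOLD_UM = 4.5


@dataclass(frozen=True)
class GateSpec:
    """Declarative description of a logic gate built from cell populations."""

    name: str
    senders: tuple[tuple[str, float], ...]        # (cell type, density)
    reporters: tuple[tuple[str, float], ...]      # (variant, density)
    input_names: tuple[str, ...]                  # logical inputs, in order
    threshold_um: float = GFP_THRESHOLD_UM
    readout_h: float = 4.0

    def with_(self, **kw) -> "GateSpec":
        return replace(self, **kw)


def _d(density=None):
    """Population density in a GateSpec; None defers to the CultureConfig."""
    return density


BUILTIN_GATES: dict[str, GateSpec] = {
    # single-input gates
    "identity": GateSpec("identity", (("salt", _d()),), (("wildtype", _d()),),
                         ("nacl",)),
    "not": GateSpec("not", (("dox", _d()),), (("wildtype", _d()),), ("dox",)),
    # two-input gates
    "or": GateSpec("or", (("salt", _d()), ("gal", _d())), (("wildtype", _d()),),
                   ("nacl", "gal")),
    "implies": GateSpec("implies", (("dox", _d()), ("gal", _d())),
                        (("wildtype", _d()),), ("dox", "gal")),
    # reprogrammed gates: glucose replaces galactose as the named input
    "nand": GateSpec("nand", (("dox", _d()), ("gal", _d())),
                     (("wildtype", _d()),), ("dox", "glucose")),
    "or-implies": GateSpec("or-implies", (("salt", _d()), ("gal", _d())),
                           (("wildtype", _d()),), ("nacl", "glucose")),
    # three-value identity: second reporter population with the
    # half-affinity Ste2 mutant, read out at 5 h
    "three-value": GateSpec("three-value", (("salt", _d()),),
                            (("wildtype", _d()), ("mutant", _d())),
                            ("nacl",), readout_h=5.0),
}

#: preculture defaults: senders grown overnight before the gate experiment
PRECULTURED_SENDERS = ("dox", "gal")


def map_inputs(gate: GateSpec, logical_inputs: dict[str, float]) -> InputSignal:
    """Translate named logical inputs (lab units) to chemical signals.

    NaCl in M, doxycycline in ug/ml, galactose in % w/v.  For the
    reprogrammed gates the input "glucose" represses GAL transcription:
    glucose present means no galactose induction, glucose absent means
    full (2 %) galactose.
    """
    unknown = set(logical_inputs) - set(gate.input_names)
    if unknown:
        raise ValueError(
            f"unknown input(s) {sorted(unknown)} for gate {gate.name!r}; "
            f"expected {list(gate.input_names)}"
        )
    levels = {n: float(logical_inputs.get(n, 0.0)) for n in gate.input_names}
    gal_percent = levels.get("gal", 0.0)
    if "glucose" in levels:
        gal_percent = 0.0 if levels["glucose"] > 0 else 2.0
    return InputSignal.from_lab_units(
        nacl_m=levels.get("nacl", 0.0),
        dox_ug_ml=levels.get("dox", 0.0),
        gal_percent=gal_percent,
    )


class GateAssembly:
    """Coupled ODE system of all populations plus the shared alpha pool.

    Species are prefixed with the population name
    (``salt.Hog1ppn``, ``reporter.mature_GFP``); the pool is
    ``Alpha_in_medium``.
    """

    def __init__(
        self,
        gate: GateSpec,
        culture: CultureConfig = DEFAULT_CULTURE,
        geometry: CellGeometry = DEFAULT_GEOMETRY,
        preculture: str = "simulated",
        preculture_hours: float = 16.0,
        handling_delay_min: float = 0.0,
    ):
        if preculture not in ("simulated", "zero", "none"):
            raise ValueError(f"unknown preculture mode {preculture!r}")
        self.gate = gate
        self.geometry = geometry
        self.name = gate.name
        self.senders: list[tuple[CellModel, CultureConfig]] = []
        for cell_type, density in gate.senders:
            kw = {"precultured": True} if (
                cell_type == "gal" and preculture != "none") else {}
            cell = make_cell(cell_type, geometry=geometry, **kw)
            cult = culture if density is None else replace(culture, density=density)
            self.senders.append((cell, cult))
        self.reporters = [
            ReporterCell(geometry=geometry, variant=v) for v, _ in gate.reporters
        ]
        self.preculture_mode = preculture
        self.preculture_hours = preculture_hours
        self.handling_delay_min = handling_delay_min

        self.species: list[str] = []
        self._slices: list[slice] = []
        i = 0
        for cell, _ in self.senders:
            self.species += [f"{cell.name}.{s}" for s in cell.species]
            self._slices.append(slice(i, i + len(cell.species)))
            i += len(cell.species)
        self.alpha_index = i
        self.species.append("Alpha_in_medium")
        i += 1
        self._rep_slices: list[slice] = []
        for rep in self.reporters:
            self.species += [f"{rep.name}.{s}" for s in rep.species]
            self._rep_slices.append(slice(i, i + len(rep.species)))
            i += len(rep.species)
        self.n_species = i

    # -- initial conditions -------------------------------------------------

    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(self.n_species)
        for (cell, _), sl in zip(self.senders, self._slices):
            y0[sl] = cell.initial_state()
            if cell.name in PRECULTURED_SENDERS and self.preculture_mode != "none":
                pre = precondition(
                    cell,
                    duration_h=self.preculture_hours,
                    mode=self.preculture_mode,
                    handling_delay_min=self.handling_delay_min,
                )
                for j, s in enumerate(cell.species):
                    if s in pre:
                        y0[sl][j] = pre[s]
        for rep, sl in zip(self.reporters, self._rep_slices):
            y0[sl] = rep.initial_state()
        return y0

    # -- dynamics -----------------------------------------------------------

    def assembly_rhs(self, t: float, y: np.ndarray, inputs: InputSignal) -> np.ndarray:
        d = np.empty_like(y)
        alpha = y[self.alpha_index]
        d_alpha = 0.0
        t_h = t / 3600.0
        for (cell, cult), sl in zip(self.senders, self._slices):
            d[sl] = cell.rhs(t, y[sl], inputs)
            d_alpha += cell.alpha_export_rate(y[sl]) / cult.dilution_factor(t_h)
        d[self.alpha_index] = d_alpha
        for rep, sl in zip(self.reporters, self._rep_slices):
            d[sl] = rep.rhs_alpha(t, y[sl], alpha)
        return d

    def segment_times_s(self, t_end_s: float, inputs: InputSignal) -> list[float]:
        out: list[float] = []
        for cell, _ in self.senders:
            out += cell.segment_times_s(t_end_s, inputs)
        return out

    def reporter_gfp_um(self, traj: Trajectory, t_h: float | None = None):
        """Mature GFP (uM) per reporter population at a readout time."""
        t_s = (t_h if t_h is not None else self.gate.readout_h) * 3600.0
        return {
            rep.name: traj.at(t_s, f"{rep.name}.mature_GFP") / UM
            for rep in self.reporters
        }


def precondition(
    cell: CellModel,
    duration_h: float = 16.0,
    mode: str = "simulated",
    handling_delay_min: float = 0.0,
    preculture_inputs: InputSignal | None = None,
) -> dict[str, float]:
    """Intracellular state of a sender after overnight pre-culturing.

    Gal-cells are pre-cultured in 2 % galactose (no induction delay),
    dox-cells in plain medium (no doxycycline); the pre-simulation runs
    ``duration_h`` hours.  Medium alpha-factor accumulated during
    pre-culture is discarded (cells are pelleted and resuspended in
    fresh medium), but the intracellular mRNA and prepro-alpha pools
    remain.  ``mode='zero'`` instead resets both pools to zero
    (idealized instantaneous-handling control).  A positive
    ``handling_delay_min`` lets the pools decay exponentially
    (rates k31_deg and k33) between pelleting and the start of the gate.
    """
    if duration_h <= 0:
        raise ValueError("preculture duration must be positive")
    if mode == "zero":
        return {"MFalpha1_mRNA": 0.0, "prepro_Alpha": 0.0}
    if mode != "simulated":
        raise ValueError(f"unknown preculture mode {mode!r}")
    if isinstance(cell, SaltCell):
        warnings.warn(
            "pre-culturing a salt-cell is a no-op: without osmostress its "
            "expression species converge to zero",
            stacklevel=2,
        )
        return {"MFalpha1_mRNA": 0.0, "prepro_Alpha": 0.0}

    if preculture_inputs is None:
        preculture_inputs = (
            InputSignal.from_lab_units(gal_percent=2.0)
            if isinstance(cell, GalCell)
            else InputSignal()
        )
    if isinstance(cell, GalCell) and not cell.precultured:
        cell = GalCell(cell.params, cell.geometry, precultured=True)
    traj = integrate(cell, preculture_inputs, t_end_h=duration_h, report_dt_s=300.0)
    state = traj.final()
    out = {s: state[s] for s in ("MFalpha1_mRNA", "prepro_Alpha")}
    if handling_delay_min > 0:
        tau = handling_delay_min * 60.0
        out["MFalpha1_mRNA"] *= math.exp(-cell.params["k31_deg"] * tau)
        out["prepro_Alpha"] *= math.exp(-cell.params["k33"] * tau)
    return out


@dataclass
class GateResult:
    """Trajectory plus threshold verdicts of a deterministic gate run."""

    gate: GateSpec
    inputs: dict[str, float]
    trajectory: Trajectory
    gfp_um: dict[str, float]
    positive: dict[str, bool]

    @property
    def verdict(self) -> bool:
        """Gate-level verdict: the (first) wild-type reporter population."""
        return self.positive["reporter"]

    def to_json(self) -> str:
        return json.dumps(
            {
                "gate": self.gate.name,
                "inputs": self.inputs,
                "gfp_uM": {k: round(v, 6) for k, v in self.gfp_um.items()},
                "positive": self.positive,
            },
            indent=2,
        )


def get_gate(gate: str | GateSpec) -> GateSpec:
    if isinstance(gate, GateSpec):
        return gate
    try:
        return BUILTIN_GATES[gate.lower()]
    except KeyError:
        raise ValueError(
            f"unknown gate {gate!r}; built-ins: {sorted(BUILTIN_GATES)}"
        ) from None


def run_gate(
    gate: str | GateSpec,
    logical_inputs: dict[str, float] | None = None,
    culture: CultureConfig = DEFAULT_CULTURE,
    preculture: str = "simulated",
    handling_delay_min: float = 0.0,
    t_end_h: float | None = None,
    report_dt_s: float = 60.0,
) -> GateResult:
    """Integrate a gate and score its output against the GFP threshold."""
    spec = get_gate(gate)
    inputs_dict = dict(logical_inputs or {})
    signal = map_inputs(spec, inputs_dict)
    asm = GateAssembly(
        spec, culture=culture, preculture=preculture,
        handling_delay_min=handling_delay_min,
    )
    horizon = t_end_h if t_end_h is not None else spec.readout_h
    traj = integrate(asm, signal, t_end_h=horizon, report_dt_s=report_dt_s,
                     y0=asm.initial_state())
    traj.metadata["gate"] = spec.name
    traj.metadata["logical_inputs"] = inputs_dict
    gfp = {k: float(v)
           for k, v in asm.reporter_gfp_um(traj, min(spec.readout_h, horizon)).items()}
    positive = {k: bool(v >= spec.threshold_um) for k, v in gfp.items()}
    return GateResult(spec, inputs_dict, traj, gfp, positive)


def truth_table(
    gate: str | GateSpec,
    input_levels: dict[str, list[float]],
    **run_kw,
):
    """Verdict for every combination of the given input levels.

    Returns a :class:`pandas.DataFrame` with one row per combination,
    the readout GFP (uM) and the boolean verdict.
    """
    import pandas as pd

    spec = get_gate(gate)
    names = list(input_levels)
    if not names or any(len(v) == 0 for v in input_levels.values()):
        raise ValueError("input_levels must be a non-empty grid")
    rows = []
    for combo in itertools.product(*(input_levels[n] for n in names)):
        res = run_gate(spec, dict(zip(names, combo)), **run_kw)
        rows.append(
            {**dict(zip(names, combo)), "gfp_uM": res.gfp_um["reporter"],
             "positive": res.verdict}
        )
    return pd.DataFrame(rows)


def three_value_gate(
    salt_levels_m: tuple[float, ...] = (0.0, 0.1, 0.4),
    readout_h: float = 5.0,
    culture: CultureConfig = DEFAULT_CULTURE,
) -> dict[float, dict]:
    """Deterministic three-value identity gate (wild-type + mutant reporters).

    Returns, per NaCl level, the mature-GFP concentration (uM) and the
    threshold verdict of each reporter population at the readout time.
    """
    spec = BUILTIN_GATES["three-value"].with_(readout_h=readout_h)
    out = {}
    for salt in salt_levels_m:
        res = run_gate(spec, {"nacl": salt}, culture=culture)
        out[salt] = {"gfp_um": res.gfp_um, "positive": res.positive}
    return out
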