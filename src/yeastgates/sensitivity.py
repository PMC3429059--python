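"""Finite-difference parameter sensitivity of gate output (mature GFP).

Scaled (relative) sensitivity coefficients S_p(t) =
(p / GFP(t)) * (GFP_{p+h}(t) - GFP(t)) / h, i.e. dlnGFP/dlnp by forward
differences with h = max(delta*|p|, min_delta), one full re-integration
of the coupled gate per perturbed quantity.  Scanned quantities are all
kinetic parameters of the participating cells, every non-zero initial
concentration, the dilution coefficient, and the culture doubling time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cells import CultureConfig, DEFAULT_CULTURE
from .deterministic import integrate
from .gates import GateAssembly, GateSpec, get_gate, map_inputs

#: default report times, minutes (nine points in the 15-240 min range)
DEFAULT_TIMES_MIN = (15, 30, 60, 90, 120, 150, 180, 210, 240)

#: non-kinetic entries of the parameter dictionaries, never scanned
_EXCLUDED_PARAMS = {"gal_delay_h"}


@dataclass
class SensitivityTable:
    """Scaled sensitivity coefficients: rows = quantities, cols = times."""

    frame: pd.DataFrame  # index: quantity name, columns: time in minutes
    gate: str
    inputs: dict
    delta: float

    @property
    def times_min(self) -> list[float]:
        return list(self.frame.columns)

    def coefficient(self, name: str, t_min: float) -> float:
        return float(self.frame.at[name, t_min])

    def rank(self, t_min: float) -> list[str]:
        return rank_parameters(self, t_min)

    def write_csv(self, path) -> None:
        self.frame.rename_axis("parameter").to_csv(path)


def _gfp_at(asm: GateAssembly, signal, times_s: np.ndarray,
            t_end_h: float, y0=None) -> np.ndarray:
    traj = integrate(asm, signal, t_end_h=t_end_h,
                     y0=asm.initial_state() if y0 is None else y0)
    gfp = traj[f"{asm.reporters[0].name}.mature_GFP"]
    idx = [int(np.argmin(np.abs(traj.times_s - t))) for t in times_s]
    return gfp[idx]


def _all_cells(asm: GateAssembly):
    return [c for c, _ in asm.senders] + list(asm.reporters)


def _scan_quantities(asm: GateAssembly, y0: np.ndarray,
                     culture: CultureConfig) -> list[tuple[str, float]]:
    out: list[tuple[str, float]] = []
    seen = set()
    for cell in _all_cells(asm):
        for pname, val in cell.params.items():
            if pname in _EXCLUDED_PARAMS or pname in seen:
                continue
            seen.add(pname)
            out.append((pname, val))
    for i, sname in enumerate(asm.species):
        if y0[i] > 0:
            out.append((f"init.{sname}", y0[i]))
    out.append(("dilution_factor", culture.dilution_coeff))
    out.append(("doubling_time", culture.doubling_time_h))
    return out


def sensitivity_scan(
    gate: str | GateSpec,
    logical_inputs: dict[str, float],
    times_min=DEFAULT_TIMES_MIN,
    delta: float = 1e-3,
    min_delta: float = 1e-12,
    culture: CultureConfig = DEFAULT_CULTURE,
    parameters: list[str] | None = None,
    preculture: str = "simulated",
) -> SensitivityTable:
    """Time-dependent scaled sensitivities of mature GFP for a gate.

    ``parameters`` restricts the scan to a subset of quantity names
    (useful for convergence checks).  Requires a non-zero baseline GFP
    at the last report time; coefficients at times where GFP is still
    zero are reported as 0.
    """
    spec = get_gate(gate)
    signal = map_inputs(spec, logical_inputs)
    times_s = np.asarray(times_min, dtype=float) * 60.0
    t_end_h = float(times_s[-1]) / 3600.0

    def build(pname=None, h=0.0, cult=culture):
        asm = GateAssembly(spec, culture=cult, preculture=preculture)
        if pname is not None:
            for cell in _all_cells(asm):
                if pname in cell.params:
                    cell.params[pname] += h
        return asm

    base_asm = build()
    y0 = base_asm.initial_state()
    baseline = _gfp_at(base_asm, signal, times_s, t_end_h, y0=y0)
    if baseline[-1] < 1e-15:  # below integration round-off: gate is inactive
        raise ValueError(
            "baseline mature GFP is zero at the last report time; "
            "sensitivities are undefined for an inactive gate"
        )

    quantities = _scan_quantities(base_asm, y0, culture)
    if parameters is not None:
        wanted = set(parameters)
        quantities = [(n, v) for n, v in quantities if n in wanted]
        missing = wanted - {n for n, _ in quantities}
        if missing:
            raise ValueError(f"unknown quantities: {sorted(missing)}")

    rows = {}
    for name, value in quantities:
        h = max(delta * abs(value), min_delta)
        if name.startswith("init."):
            y0p = y0.copy()
            y0p[base_asm.species.index(name[5:])] += h
            pert = _gfp_at(base_asm, signal, times_s, t_end_h, y0=y0p)
        elif name == "dilution_factor":
            asm = build(cult=replace(culture,
                                     dilution_coeff=culture.dilution_coeff + h))
            pert = _gfp_at(asm, signal, times_s, t_end_h)
        elif name == "doubling_time":
            asm = build(cult=replace(culture,
                                     doubling_time_h=culture.doubling_time_h + h))
            pert = _gfp_at(asm, signal, times_s, t_end_h)
        else:
            asm = build(pname=name, h=h)
            pert = _gfp_at(asm, signal, times_s, t_end_h)
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(baseline > 0, value / baseline * (pert - baseline) / h, 0.0)
        rows[name] = s

    frame = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=list(times_min))
    return SensitivityTable(frame, spec.name, dict(logical_inputs), delta)


def rank_parameters(table: SensitivityTable, t_min: float) -> list[str]:
    """Quantity names sorted by |S(t)| descending; ties broken by name."""
    if t_min not in table.frame.columns:
        raise ValueError(f"t={t_min} min is not a report time of this table")
    col = table.frame[t_min]
    if (col.abs() < 1e-300).all():
        warnings.warn(f"all sensitivities are zero at t={t_min} min",
                      stacklevel=2)
        return []
    order = pd.DataFrame({"mag": col.abs(), "name": col.index}, index=col.index)
    order = order.sort_values(["mag", "name"], ascending=[False, True])
    return list(order.index)
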