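"""Stochastic simulation of reporter cells.

Two model levels, both driven by the exact Gillespie direct method:

* **Full reporter model** (molecule counts, published propensity table):
  the ligand-bound receptor is held at its quasi-steady-state count
  (QSSA), the Ste5-complex activation cycle and the GFP expression
  module are simulated event-by-event, and the fast, closed Fus3
  phosphorylation/shuttling cycle (relaxation time < 1 s, ~1e6
  events/s) is treated in quasi-equilibrium: each Fus3 molecule
  occupies one of four states (cytoplasmic/nuclear x un/phosphorylated)
  with the analytic stationary distribution conditional on the current
  active-Ste5 count.  Nuclear Fus3-PP is recorded as a binomial draw
  from that conditional occupancy, and drives transcription through its
  conditional mean.

* **Hybrid model**: only the GFP expression module is stochastic; the
  nuclear Fus3-PP count is a birth-only process whose time-varying
  birth propensity is the (clamped) derivative of a smooth fit to the
  deterministic trajectory.  Used for whole-gate population
  predictions, where alpha-factor rises during the experiment.

Cell-to-cell variation is summarized as the coefficient of variation,
100 * sd / mean across trajectories at a report time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.interpolate import InterpolatedUnivariateSpline

from .deterministic import Trajectory
from .parameters import (
    INITIAL_CONDITIONS,
    REPORTER_PARAMS,
    STOCHASTIC_REPORTER_PARAMS,
)
from .units import (
    DEFAULT_GEOMETRY,
    NM,
    CellGeometry,
    concentration_to_count,
)

#: GFP-positive threshold in molecule counts (4.5 uM in the cytoplasm)
GFP_THRESHOLD_COUNT = concentration_to_count(4500.0, DEFAULT_GEOMETRY.v_cyt_fl)

#: Per-molecule Fus3 transport propensities for the full stochastic model.
#: Unimolecular transport rates are invariant under the concentration ->
#: molecule-count conversion, so the deterministic constants carry over
#: unchanged; this keeps the stochastic mean on the deterministic
#: trajectory and reproduces the published population CVs.  (The printed
#: stochastic table's nuclear import/export pair does not satisfy this
#: consistency and is kept only as the verbatim record.)
FULL_MODEL_TRANSPORT = {
    "k_nuc_imp": REPORTER_PARAMS["k_nuc_imp"],
    "k_nuc_exp": REPORTER_PARAMS["k_nuc_exp"],
    "k_small": REPORTER_PARAMS["k_small"],
}


def _subseeds(seed: int, n: int) -> np.ndarray:
    """Independent per-trajectory sub-seeds from one master seed."""
    ss = np.random.SeedSequence(seed)
    return (ss.generate_state(n, dtype=np.uint32) & 0x7FFFFFFF).astype(np.int64)


# ---------------------------------------------------------------------------
# Generic exact SSA (direct method)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reaction:
    """Mass-action reaction with a per-molecule propensity constant (1/s)."""

    rate: float
    reactants: tuple[str, ...] = ()
    products: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("propensity constants must be non-negative")
        if len(self.reactants) > 2:
            raise ValueError("at most bimolecular reactions are supported")


@dataclass
class StochasticModel:
    """Species in molecule counts plus a mass-action reaction list."""

    species: list[str]
    reactions: list[Reaction]
    initial_counts: dict[str, int] = field(default_factory=dict)

    def _compiled(self):
        idx = {s: i for i, s in enumerate(self.species)}
        nr = len(self.reactions)
        c = np.array([r.rate for r in self.reactions])
        r1 = np.full(nr, -1, dtype=np.int64)
        r2 = np.full(nr, -1, dtype=np.int64)
        stoich = np.zeros((nr, len(self.species)), dtype=np.int64)
        for i, r in enumerate(self.reactions):
            if len(r.reactants) > 0:
                r1[i] = idx[r.reactants[0]]
            if len(r.reactants) > 1:
                r2[i] = idx[r.reactants[1]]
            for s in r.reactants:
                stoich[i, idx[s]] -= 1
            for s in r.products:
                stoich[i, idx[s]] += 1
        x0 = np.zeros(len(self.species), dtype=np.int64)
        for s, v in self.initial_counts.items():
            if v < 0 or v != int(v):
                raise ValueError("initial counts must be non-negative integers")
            x0[idx[s]] = int(v)
        return x0, c, r1, r2, stoich


@njit(cache=True)
def _ssa_generic(seed, x0, c, r1, r2, stoich, report_times):  # pragma: no cover
    np.random.seed(seed)
    x = x0.astype(np.float64)
    nr = c.shape[0]
    nt = report_times.shape[0]
    out = np.zeros((nt, x.shape[0]))
    props = np.empty(nr)
    t = 0.0
    ir = 0
    while ir < nt:
        tot = 0.0
        for i in range(nr):
            a = c[i]
            if r1[i] >= 0:
                a *= x[r1[i]]
            if r2[i] >= 0:
                if r2[i] == r1[i]:
                    a *= 0.5 * (x[r2[i]] - 1.0)
                else:
                    a *= x[r2[i]]
            if a < 0.0:
                a = 0.0
            props[i] = a
            tot += a
        if tot <= 0.0:
            t_next = np.inf
        else:
            t_next = t + np.random.exponential(1.0 / tot)
        while ir < nt and report_times[ir] < t_next:
            out[ir] = x
            ir += 1
        if t_next == np.inf:
            break
        t = t_next
        u = np.random.random() * tot
        acc = 0.0
        k = nr - 1
        for i in range(nr):
            acc += props[i]
            if u < acc:
                k = i
                break
        for j in range(x.shape[0]):
            x[j] += stoich[k, j]
    return out


def gillespie_direct(
    model,
    t_end_s: float,
    seed: int,
    report_dt_s: float = 60.0,
) -> np.ndarray:
    """One exact direct-method trajectory, recorded on a fixed grid.

    Works for a :class:`StochasticModel` or for any object exposing
    ``simulate(seed, report_times)`` (the full-reporter and hybrid
    models).  Returns an array of shape (n_times, n_species); with zero
    total propensity the state is frozen to ``t_end_s``.
    """
    report = _report_grid(t_end_s, report_dt_s)
    if hasattr(model, "simulate"):
        return model.simulate(seed, report)
    x0, c, r1, r2, stoich = model._compiled()
    return _ssa_generic(int(seed), x0, c, r1, r2, stoich, report)


def _report_grid(t_end_s: float, report_dt_s: float) -> np.ndarray:
    grid = np.arange(0.0, t_end_s + 0.5 * report_dt_s, report_dt_s)
    if grid[-1] > t_end_s:
        grid[-1] = t_end_s
    return grid


# ---------------------------------------------------------------------------
# Receptor QSSA and the Fus3 conditional occupancy
# ---------------------------------------------------------------------------


def ste2_qssa(
    alpha_mmol_ml: float,
    params: dict | None = None,
    geometry: CellGeometry = DEFAULT_GEOMETRY,
) -> int:
    """Quasi-steady-state ligand-bound receptor count at constant alpha.

    Solves the receptor synthesis/binding/degradation balance of the
    deterministic model in closed form and converts to molecules.
    Saturates at v_Ste2_production/k5 for large alpha.
    """
    if alpha_mmol_ml < 0:
        raise ValueError("alpha must be non-negative")
    p = params or REPORTER_PARAMS
    kon = p["k1"] * alpha_mmol_ml
    koff = p["k2"] + p["k5"]
    ste2 = p["v_Ste2_production"] / (p["k4"] + kon * p["k5"] / koff)
    ste2_ph = kon * ste2 / koff
    return concentration_to_count(ste2_ph / NM, geometry.v_cyt_fl)


def _fus3_stationary_table(n_ste5: int, s_params: dict) -> np.ndarray:
    """pi_ppn[a]: stationary nuclear-Fus3-PP occupancy per active-Ste5 count.

    Each Fus3 molecule hops on a 4-state chain (c, ppc, n, ppn) with
    pseudo-first-order phosphorylation rate k8*a; the chain is closed
    and linear, so the occupancy is its stationary distribution.
    """
    p = s_params
    kimp, kexp = p["k_nuc_imp"], p["k_nuc_exp"]
    kexp_pp = p["k_small"] * kexp
    pi = np.empty(n_ste5 + 1)
    for a in range(n_ste5 + 1):
        kphos = p["k8"] * a
        #      c      ppc     n      ppn
        Q = np.array([
            [-(kphos + kimp), kphos, kimp, 0.0],
            [p["k9"], -(p["k9"] + kimp), 0.0, kimp],
            [kexp, 0.0, -kexp, 0.0],
            [0.0, kexp_pp, p["k10"], -(kexp_pp + p["k10"])],
        ])
        A = np.vstack([Q.T, np.ones(4)])
        b = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
        sol, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi[a] = sol[3]
    # round-off guard: occupancies are probabilities
    return np.clip(pi, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Full reporter model (QSSA receptor, quasi-equilibrium Fus3 cycle)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _ssa_reporter_full(seed, report_times, n_ste5, a0, s2ph, n_fus3, pi_ppn,
                       c6, k7, c34, k34deg, k35, k36):  # pragma: no cover
    np.random.seed(seed)
    a = a0
    m = 0.0
    nas = 0.0
    mat = 0.0
    nt = report_times.shape[0]
    out = np.zeros((nt, 5))
    t = 0.0
    ir = 0
    while ir < nt:
        p1 = c6 * (n_ste5 - a) * s2ph
        p2 = k7 * a
        p3 = c34 * n_fus3 * pi_ppn[a]
        p4 = k34deg * m
        p5 = k35 * m
        p6 = k36 * nas
        tot = p1 + p2 + p3 + p4 + p5 + p6
        if tot <= 0.0:
            t_next = np.inf
        else:
            t_next = t + np.random.exponential(1.0 / tot)
        while ir < nt and report_times[ir] < t_next:
            out[ir, 0] = np.random.binomial(n_fus3, pi_ppn[a])
            out[ir, 1] = a
            out[ir, 2] = m
            out[ir, 3] = nas
            out[ir, 4] = mat
            ir += 1
        if t_next == np.inf:
            break
        t = t_next
        u = np.random.random() * tot
        if u < p1:
            a += 1
        elif u < p1 + p2:
            a -= 1
        elif u < p1 + p2 + p3:
            m += 1.0
        elif u < p1 + p2 + p3 + p4:
            m -= 1.0
        elif u < p1 + p2 + p3 + p4 + p5:
            nas += 1.0
        else:
            nas -= 1.0
            mat += 1.0
    return out


class FullReporterModel:
    """Stochastic reporter cell at constant medium alpha-factor (nM)."""

    recorded = ("Fus3ppn", "active_Ste5complex", "GFP_mRNA",
                "nascent_GFP", "mature_GFP")

    def __init__(
        self,
        alpha_nm: float,
        params: dict | None = None,
        geometry: CellGeometry = DEFAULT_GEOMETRY,
    ):
        self.alpha_nm = float(alpha_nm)
        if params is None:
            params = {**STOCHASTIC_REPORTER_PARAMS, **FULL_MODEL_TRANSPORT}
        self.params = dict(params)
        self.geometry = geometry
        self.n_ste5 = INITIAL_CONDITIONS["inactive_Ste5complex"][2]
        self.n_fus3 = (INITIAL_CONDITIONS["Fus3c"][2]
                       + INITIAL_CONDITIONS["Fus3n"][2])
        self.s2ph = ste2_qssa(alpha_nm * NM, geometry=geometry)
        self.pi_ppn = _fus3_stationary_table(self.n_ste5, self.params)

    def simulate(self, seed: int, report_times: np.ndarray) -> np.ndarray:
        p = self.params
        return _ssa_reporter_full(
            int(seed), np.asarray(report_times, dtype=float),
            self.n_ste5, 0, float(self.s2ph), self.n_fus3, self.pi_ppn,
            p["k6"], p["k7"], p["k34"], p["k34_deg"], p["k35"], p["k36"],
        )


# ---------------------------------------------------------------------------
# Hybrid drive and hybrid GFP-module model
# ---------------------------------------------------------------------------


@dataclass
class HybridDrive:
    """Time-varying nuclear-Fus3-PP birth propensity from a deterministic run.

    ``b[j]`` is the propensity (molecules/s) on the 1-s bin starting at
    ``t0_s + j*bin_dt_s``; before the onset time ``t0_s`` the propensity
    is zero and the stochastic clock has not started.
    """

    t0_s: float
    bin_dt_s: float
    b: np.ndarray
    metadata: dict = field(default_factory=dict)

    def propensity(self, t_s: float) -> float:
        if t_s < self.t0_s or len(self.b) == 0:
            return 0.0
        j = min(int((t_s - self.t0_s) / self.bin_dt_s), len(self.b) - 1)
        return float(self.b[j])


def hybrid_drive(
    det_trajectory: Trajectory,
    species: str = "reporter.Fus3ppn",
    geometry: CellGeometry = DEFAULT_GEOMETRY,
    bin_dt_s: float = 1.0,
    onset_count: float = 1.0,
) -> HybridDrive:
    """Fit a smooth curve to deterministic nuclear Fus3-PP and differentiate.

    The concentration series (nM, nuclear) is converted to molecule
    counts, interpolated with a cubic spline (exact at every report
    point, so the <1 % fit-error contract holds by construction), and
    the clamped-non-negative derivative becomes the birth propensity.
    The stochastic clock starts when the deterministic count first
    reaches ``onset_count`` molecules (dead-time handling).
    """
    t = det_trajectory.times_s
    conc_nm = det_trajectory.series_nm(species)
    counts = conc_nm * NM * (geometry.avogadro * 1e-3) * (geometry.v_nuc_fl * 1e-12)

    above = counts >= onset_count
    if not above.any():
        return HybridDrive(t[-1], bin_dt_s, np.zeros(0),
                           {"species": species, "onset_count": onset_count})
    i = int(np.argmax(above))
    if i == 0:
        t0 = float(t[0])
    else:  # linear refinement between grid points
        f = (onset_count - counts[i - 1]) / (counts[i] - counts[i - 1])
        t0 = float(t[i - 1] + f * (t[i] - t[i - 1]))

    spline = InterpolatedUnivariateSpline(t, counts, k=3)
    deriv = spline.derivative()
    edges = np.arange(t0, t[-1] + bin_dt_s, bin_dt_s)
    mids = edges[:-1] + 0.5 * bin_dt_s
    raw = deriv(np.minimum(mids, t[-1]))
    b = np.clip(raw, 0.0, None)

    clipped = -np.sum(raw[raw < 0]) * bin_dt_s
    total = np.sum(b) * bin_dt_s
    # warn only when clamping removes a material number of molecules
    if clipped > max(0.01 * total, 1.0):
        warnings.warn(
            f"non-monotone fit: clamping removed {100 * clipped / total:.1f}% "
            f"of the integrated drive for {species}",
            stacklevel=2,
        )
    return HybridDrive(t0, bin_dt_s, b,
                       {"species": species, "onset_count": onset_count})


@njit(cache=True)
def _ssa_hybrid(seed, t0, bin_dt, b, report_times,
                c34, k34deg, k35, k36):  # pragma: no cover
    np.random.seed(seed)
    n = 0.0
    m = 0.0
    nas = 0.0
    mat = 0.0
    nt = report_times.shape[0]
    out = np.zeros((nt, 4))
    ir = 0
    while ir < nt and report_times[ir] < t0:
        ir += 1  # before onset everything is zero
    t = t0
    nbins = b.shape[0]
    j = 0
    while ir < nt:
        p0 = b[j] if nbins > 0 else 0.0
        p3 = c34 * n
        p4 = k34deg * m
        p5 = k35 * m
        p6 = k36 * nas
        tot = p0 + p3 + p4 + p5 + p6
        if tot <= 0.0:
            t_next = np.inf
        else:
            t_next = t + np.random.exponential(1.0 / tot)
        bin_end = t0 + (j + 1) * bin_dt
        if t_next > bin_end and j < nbins - 1:
            # propensity changes at the bin boundary: advance and redraw
            while ir < nt and report_times[ir] <= bin_end:
                out[ir, 0] = n
                out[ir, 1] = m
                out[ir, 2] = nas
                out[ir, 3] = mat
                ir += 1
            t = bin_end
            j += 1
            continue
        while ir < nt and report_times[ir] < t_next:
            out[ir, 0] = n
            out[ir, 1] = m
            out[ir, 2] = nas
            out[ir, 3] = mat
            ir += 1
        if t_next == np.inf:
            break
        t = t_next
        u = np.random.random() * tot
        if u < p0:
            n += 1.0
        elif u < p0 + p3:
            m += 1.0
        elif u < p0 + p3 + p4:
            m -= 1.0
        elif u < p0 + p3 + p4 + p5:
            nas += 1.0
        else:
            nas -= 1.0
            mat += 1.0
    return out


class HybridGFPModel:
    """Stochastic GFP expression module driven by a :class:`HybridDrive`."""

    recorded = ("Fus3ppn", "GFP_mRNA", "nascent_GFP", "mature_GFP")

    def __init__(self, drive: HybridDrive, params: dict | None = None):
        self.drive = drive
        self.params = dict(params or STOCHASTIC_REPORTER_PARAMS)

    def simulate(self, seed: int, report_times: np.ndarray) -> np.ndarray:
        p = self.params
        return _ssa_hybrid(
            int(seed), self.drive.t0_s, self.drive.bin_dt_s,
            np.asarray(self.drive.b, dtype=float),
            np.asarray(report_times, dtype=float),
            p["k34"], p["k34_deg"], p["k35"], p["k36"],
        )


# ---------------------------------------------------------------------------
# Ensembles and noise quantification
# ---------------------------------------------------------------------------


@dataclass
class Ensemble:
    """n stochastic trajectories on a common report grid (molecule counts)."""

    times_s: np.ndarray
    species: list[str]
    counts: np.ndarray  # (n, n_times, n_species)
    seed: int
    sub_seeds: np.ndarray

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    def _sidx(self, species: str) -> int:
        return self.species.index(species)

    def _tidx(self, t_s: float) -> int:
        i = int(np.argmin(np.abs(self.times_s - t_s)))
        if abs(self.times_s[i] - t_s) > 1e-6:
            raise ValueError(f"t={t_s} s is not on the report grid")
        return i

    def mean(self, species: str) -> np.ndarray:
        return self.counts[:, :, self._sidx(species)].mean(axis=0)

    def sd(self, species: str) -> np.ndarray:
        return self.counts[:, :, self._sidx(species)].std(axis=0, ddof=1)

    def cv_percent(self, species: str) -> np.ndarray:
        m, s = self.mean(species), self.sd(species)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = np.where(m > 0, 100.0 * s / m, 0.0)
        return cv

    def frac_above(self, species: str, threshold_count: float) -> np.ndarray:
        x = self.counts[:, :, self._sidx(species)]
        return (x >= threshold_count).mean(axis=0)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.species:
            m, sd, cv = self.mean(s), self.sd(s), self.cv_percent(s)
            fp = self.frac_above(s, GFP_THRESHOLD_COUNT)
            for i, t in enumerate(self.times_s):
                rows.append({
                    "time_s": int(t), "species": s, "mean": m[i], "sd": sd[i],
                    "cv_percent": cv[i], "frac_positive": fp[i],
                })
        return pd.DataFrame(rows)


def run_ensemble(
    model,
    n: int,
    t_end_h: float,
    seed: int,
    report_dt_s: float = 60.0,
) -> Ensemble:
    """n independent trajectories with per-trajectory sub-seeds."""
    if n < 2:
        raise ValueError("an ensemble needs at least 2 trajectories")
    report = _report_grid(t_end_h * 3600.0, report_dt_s)
    subs = _subseeds(seed, n)
    if hasattr(model, "simulate"):
        species = list(model.recorded)
        sim = model.simulate
    else:
        species = list(model.species)
        x0, c, r1, r2, stoich = model._compiled()
        sim = lambda s, rt: _ssa_generic(int(s), x0, c, r1, r2, stoich, rt)
    counts = np.empty((n, len(report), len(species)))
    for i, s in enumerate(subs):
        counts[i] = sim(int(s), report)
    return Ensemble(report, species, counts, seed, subs)


def coefficient_of_variation(ensemble: Ensemble, species: str, t_h: float) -> float:
    """100*sd/mean across trajectories at time ``t_h`` (0 when mean is 0)."""
    i = ensemble._tidx(t_h * 3600.0)
    return float(ensemble.cv_percent(species)[i])


# ---------------------------------------------------------------------------
# Gate-level conveniences
# ---------------------------------------------------------------------------


def hybrid_gate_ensemble(
    gate,
    logical_inputs: dict[str, float],
    n: int = 1000,
    seed: int = 1,
    t_end_h: float | None = None,
    reporter: str = "reporter",
    **run_gate_kw,
) -> tuple[Ensemble, "object"]:
    """Deterministic gate run -> hybrid drive -> stochastic GFP ensemble.

    Returns the ensemble and the underlying deterministic gate result.
    """
    from .gates import get_gate, run_gate

    spec = get_gate(gate)
    horizon = t_end_h if t_end_h is not None else spec.readout_h
    res = run_gate(spec, logical_inputs, t_end_h=horizon, **run_gate_kw)
    drive = hybrid_drive(res.trajectory, species=f"{reporter}.Fus3ppn")
    model = HybridGFPModel(drive)
    ens = run_ensemble(model, n, horizon, seed)
    return ens, res


def three_value_stochastic(
    salt_levels_m=(0.0, 0.1, 0.4),
    n_per_population: int = 1000,
    seed: int = 1,
    readout_h: float = 5.0,
) -> dict[float, dict]:
    """Population response of the three-value gate at the 5-h readout.

    For each NaCl level, runs a hybrid ensemble per reporter population
    (wild-type and Ste2-mutant) and reports the fraction of cells at or
    above the GFP threshold, per population and pooled.
    """
    from .gates import BUILTIN_GATES, run_gate

    spec = BUILTIN_GATES["three-value"].with_(readout_h=readout_h)
    out = {}
    for k, salt in enumerate(salt_levels_m):
        res = run_gate(spec, {"nacl": salt}, t_end_h=readout_h)
        fracs = {}
        for j, rep in enumerate(("reporter", "reporter_mut")):
            drive = hybrid_drive(res.trajectory, species=f"{rep}.Fus3ppn")
            ens = run_ensemble(HybridGFPModel(drive), n_per_population,
                               readout_h, seed + 1000 * k + j)
            i = ens._tidx(readout_h * 3600.0)
            fracs[rep] = float(
                ens.frac_above("mature_GFP", GFP_THRESHOLD_COUNT)[i])
        fracs["pooled"] = 0.5 * (fracs["reporter"] + fracs["reporter_mut"])
        out[salt] = fracs
    return out
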