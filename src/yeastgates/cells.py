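"""ODE models of the four engineered cell types.

Senders (salt-, dox-, gal-cell) secrete alpha-factor into the shared
medium; the reporter cell transduces medium alpha-factor through the
pheromone pathway into GFP expression.  All states are concentrations in
mmol/ml; time is in seconds.  Compartment bridging uses the
nucleus/cytoplasm volume ratio so that volume-weighted totals of the
shuttling kinases are conserved exactly.

Mature GFP and medium alpha-factor have no sinks: degradation and
photobleaching are slow on the 4-6 h horizon of a gate experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .parameters import (
    DOX_CELL_PARAMS,
    GAL_CELL_PARAMS,
    REPORTER_PARAMS,
    SALT_CELL_PARAMS,
    INITIAL_CONDITIONS,
)
from .units import (
    DEFAULT_GEOMETRY,
    NM,
    CellGeometry,
    dox_ug_ml_to_canonical,
    gal_percent_to_canonical,
    nacl_molar_to_canonical,
)

#: Reference culture density for which the default dilution coefficient holds.
REFERENCE_DENSITY = 5e6  # cells/ml


@dataclass(frozen=True)
class InputSignal:
    """Constant chemical inputs over one simulation segment (mmol/ml).

    ``alpha`` is an externally imposed medium alpha-factor concentration,
    used when the reporter cell is driven directly (outside a gate).
    """

    nacl: float = 0.0
    dox: float = 0.0
    gal: float = 0.0
    alpha: float = 0.0

    def __post_init__(self) -> None:
        for name in ("nacl", "dox", "gal", "alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def from_lab_units(
        cls,
        nacl_m: float = 0.0,
        dox_ug_ml: float = 0.0,
        gal_percent: float = 0.0,
        alpha_nm: float = 0.0,
    ) -> "InputSignal":
        return cls(
            nacl=nacl_molar_to_canonical(nacl_m),
            dox=dox_ug_ml_to_canonical(dox_ug_ml),
            gal=gal_percent_to_canonical(gal_percent),
            alpha=alpha_nm * NM,
        )


@dataclass(frozen=True)
class CultureConfig:
    """Culture density and growth settings controlling the dilution law."""

    density: float = REFERENCE_DENSITY   # cells/ml of this population
    doubling_time_h: float = 4.0
    dilution_coeff: float = 13800.0      # at the reference density

    def __post_init__(self) -> None:
        if self.density <= 0 or self.doubling_time_h <= 0 or self.dilution_coeff <= 0:
            raise ValueError("culture settings must be positive")

    @property
    def dilution_rate_per_h(self) -> float:
        """ln 2 / doubling time (0.173 1/h at the default 4 h)."""
        return math.log(2.0) / self.doubling_time_h

    def dilution_factor(self, t_h: float) -> float:
        """Factor by which per-cell export flux is diluted into the medium.

        Halves every doubling time as the culture grows; scales inversely
        with the initial density.
        """
        if t_h < 0:
            raise ValueError("time must be non-negative")
        coeff = self.dilution_coeff * (REFERENCE_DENSITY / self.density)
        return coeff * math.exp(-self.dilution_rate_per_h * t_h)


DEFAULT_CULTURE = CultureConfig()


def osmostress(salt: float, int_osmo: float, w: float) -> float:
    """Effective osmotic stress: max(w*salt - internal osmolytes, 0)."""
    if salt < 0 or int_osmo < 0:
        raise ValueError("inputs must be non-negative")
    return max(w * salt - int_osmo, 0.0)


def dilution_factor(t_h: float, culture: CultureConfig = DEFAULT_CULTURE) -> float:
    """Module-level convenience wrapper around the culture's dilution law."""
    return culture.dilution_factor(t_h)


class CellModel:
    """Base: named species + intracellular RHS + optional alpha export."""

    name: str = "cell"
    species: tuple[str, ...] = ()
    is_sender: bool = False

    def __init__(self, params: dict[str, float], geometry: CellGeometry):
        self.params = dict(params)
        self.geometry = geometry

    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(len(self.species))
        for i, s in enumerate(self.species):
            if s in INITIAL_CONDITIONS:
                y0[i] = INITIAL_CONDITIONS[s][0] * NM
        return y0

    def rhs(self, t: float, y: np.ndarray, inputs: InputSignal) -> np.ndarray:
        raise NotImplementedError

    def alpha_export_rate(self, y: np.ndarray) -> float:
        """Per-cell cytoplasmic export flux k33*[prepro_Alpha] (senders only)."""
        raise NotImplementedError

    def segment_times_s(self, t_end_s: float, inputs: InputSignal) -> list[float]:
        """Interior time points where the RHS changes discontinuously."""
        return []


_EXPRESSION = ("MFalpha1_mRNA", "prepro_Alpha")


class _SenderCell(CellModel):
    """Shared alpha-factor expression module: translation and export."""

    is_sender = True

    def _expression_rhs(self, transcription: float, y: np.ndarray, i0: int):
        p = self.params
        mrna, prepro = y[i0], y[i0 + 1]
        d_mrna = transcription - p["k31_deg"] * mrna
        d_prepro = p["k32"] * mrna - p["k33"] * prepro
        return d_mrna, d_prepro

    def alpha_export_rate(self, y: np.ndarray) -> float:
        return self.params["k33"] * y[self.species.index("prepro_Alpha")]


class SaltCell(_SenderCell):
    """HOG-pathway salt sensor: NaCl -> Hog1-PP -> MFalpha1 expression."""

    name = "salt"
    species = (
        "Pbs2", "Pbs2pp", "Hog1c", "Hog1ppc", "Hog1n", "Hog1ppn",
        "Int_osmo",
    ) + _EXPRESSION

    def __init__(self, params=None, geometry: CellGeometry = DEFAULT_GEOMETRY):
        super().__init__(params or SALT_CELL_PARAMS, geometry)

    def rhs(self, t, y, inputs):
        p = self.params
        g = self.geometry
        pbs2, pbs2pp, hog1c, hog1ppc, hog1n, hog1ppn, osmo = y[:7]
        stress = osmostress(inputs.nacl, osmo, p["w"])

        d = np.empty_like(y)
        act = p["k20"] * pbs2 * stress
        deact = p["k21"] * pbs2pp
        d[0] = -act + deact
        d[1] = act - deact

        phos = p["k22"] * hog1c * pbs2pp
        r = g.nuc_over_cyt
        d[2] = -phos + p["k23"] * hog1ppc - p["k27"] * hog1c + p["k28"] * hog1n * r
        d[3] = phos - p["k23"] * hog1ppc - p["k26"] * hog1ppc + p["k25"] * hog1ppn * r
        d[4] = p["k24"] * hog1ppn + p["k27"] * hog1c / r - p["k28"] * hog1n
        d[5] = -p["k24"] * hog1ppn + p["k26"] * hog1ppc / r - p["k25"] * hog1ppn

        d[6] = p["k29"] * hog1ppc - p["k30"] * osmo / (1.0 + p["Ki30"] * stress)

        d[7], d[8] = self._expression_rhs(p["k31"] * hog1ppn, y, 7)
        return d


class DoxCell(_SenderCell):
    """Tet-Off constitutive sender, repressed by doxycycline."""

    name = "dox"
    species = _EXPRESSION

    def __init__(self, params=None, geometry: CellGeometry = DEFAULT_GEOMETRY):
        super().__init__(params or DOX_CELL_PARAMS, geometry)

    def rhs(self, t, y, inputs):
        p = self.params
        transcription = p["k38"] / (1.0 + p["Ki38"] * inputs.dox)
        d = np.empty_like(y)
        d[0], d[1] = self._expression_rhs(transcription, y, 0)
        return d


class GalCell(_SenderCell):
    """GAL1-promoter sender.

    After a glucose-to-galactose shift, GAL transcription only starts
    after a 3 h induction delay; cells pre-cultured in galactose
    (``precultured=True``) transcribe from t = 0.
    """

    name = "gal"
    species = _EXPRESSION

    def __init__(self, params=None, geometry: CellGeometry = DEFAULT_GEOMETRY,
                 precultured: bool = False):
        super().__init__(params or GAL_CELL_PARAMS, geometry)
        self.precultured = precultured

    def k_gal(self, t_s: float) -> float:
        if not self.precultured and t_s < self.params["gal_delay_h"] * 3600.0:
            return 0.0
        return self.params["k37"]

    def rhs(self, t, y, inputs):
        transcription = self.k_gal(t) * inputs.gal
        d = np.empty_like(y)
        d[0], d[1] = self._expression_rhs(transcription, y, 0)
        return d

    def segment_times_s(self, t_end_s, inputs):
        delay = self.params["gal_delay_h"] * 3600.0
        if not self.precultured and 0.0 < delay < t_end_s:
            return [delay]
        return []


class ReporterCell(CellModel):
    """Pheromone pathway + GFP expression, driven by medium alpha-factor.

    ``variant='mutant'`` swaps in the half-affinity Ste2 receptor
    (binding constant halved), used by the three-value gate.
    """

    name = "reporter"
    species = (
        "Ste2", "Ste2_Ph", "inactive_Ste5complex", "active_Ste5complex",
        "Fus3c", "Fus3ppc", "Fus3n", "Fus3ppn",
        "GFP_mRNA", "nascent_GFP", "mature_GFP",
    )

    def __init__(self, params=None, geometry: CellGeometry = DEFAULT_GEOMETRY,
                 variant: str = "wildtype"):
        super().__init__(params or REPORTER_PARAMS, geometry)
        if variant not in ("wildtype", "mutant"):
            raise ValueError(f"unknown reporter variant {variant!r}")
        self.variant = variant
        if variant == "mutant":
            from .parameters import STE2_MUTANT_K1

            self.params["k1"] = STE2_MUTANT_K1
            self.name = "reporter_mut"

    def rhs(self, t, y, inputs):
        return self.rhs_alpha(t, y, inputs.alpha)

    def rhs_alpha(self, t: float, y: np.ndarray, alpha: float) -> np.ndarray:
        p = self.params
        r = self.geometry.nuc_over_cyt
        (ste2, ste2ph, i5, a5, f3c, f3ppc, f3n, f3ppn,
         mrna, nascent, _mature) = y

        d = np.empty_like(y)
        bind = p["k1"] * ste2 * alpha
        d[0] = p["v_Ste2_production"] - bind + p["k2"] * ste2ph - p["k4"] * ste2
        d[1] = bind - p["k2"] * ste2ph - p["k5"] * ste2ph

        act = p["k6"] * i5 * ste2ph
        d[3] = act - p["k7"] * a5
        d[2] = -act + p["k7"] * a5

        phos = p["k8"] * f3c * a5
        kexp_pp = p["k_small"] * p["k_nuc_exp"]
        d[4] = (-p["k_nuc_imp"] * f3c + p["k_nuc_exp"] * f3n * r
                - phos + p["k9"] * f3ppc)
        d[5] = (kexp_pp * f3ppn * r - p["k_nuc_imp"] * f3ppc
                + phos - p["k9"] * f3ppc)
        d[6] = p["k_nuc_imp"] * f3c / r - p["k_nuc_exp"] * f3n + p["k10"] * f3ppn
        d[7] = -kexp_pp * f3ppn + p["k_nuc_imp"] * f3ppc / r - p["k10"] * f3ppn

        d[8] = p["k34"] * f3ppn - p["k34_deg"] * mrna
        d[9] = p["k35"] * mrna - p["k36"] * nascent
        d[10] = p["k36"] * nascent
        return d


SENDER_TYPES = {"salt": SaltCell, "dox": DoxCell, "gal": GalCell}


def make_cell(name: str, geometry: CellGeometry = DEFAULT_GEOMETRY, **kw) -> CellModel:
    """Factory for built-in cell types ('salt', 'dox', 'gal', 'reporter')."""
    if name in SENDER_TYPES:
        return SENDER_TYPES[name](geometry=geometry, **kw)
    if name == "reporter":
        return ReporterCell(geometry=geometry, **kw)
    raise ValueError(f"unknown cell type {name!r}")
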