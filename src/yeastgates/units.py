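"""Unit system and deterministic/stochastic parameter conversions.

Canonical internal units are mmol/ml (numerically equal to mol/L) for
concentrations and seconds for time.  User-facing values (nM, uM, M,
ug/ml, % w/v) are converted at the boundaries.

The stochastic framework works in molecule counts per cell compartment;
the conversions here make the deterministic rate constants, the initial
concentrations, and the per-molecule propensity constants mutually
consistent for the compartment volumes of an average haploid yeast cell.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Avogadro constant, 1/mol, fixed to 4 significant figures so that the
#: published per-cell molecule numbers are reproduced by rounding.
AVOGADRO = 6.022e23

#: nM -> mmol/ml (= mol/L)
NM = 1e-9
#: uM -> mmol/ml
UM = 1e-6

#: Doxycycline molar mass, g/mol.
DOX_MW_G_PER_MOL = 444.4

#: Galactose: "2% w/v" corresponds to 0.11 mmol/ml in this model.
GAL_MMOL_ML_PER_PERCENT = 0.055


@dataclass(frozen=True)
class CellGeometry:
    """Compartment volumes (fL) of the modeled yeast cell.

    The whole cell is 58 fL, of which the cytoplasm occupies 50 %
    (29 fL) and the nucleus 7 % (4.06 fL).
    """

    v_cell_fl: float = 58.0
    v_cyt_fl: float = 29.0
    v_nuc_fl: float = 4.06
    avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        if not (0 < self.v_nuc_fl < self.v_cyt_fl < self.v_cell_fl):
            raise ValueError(
                "compartment volumes must satisfy 0 < nucleus < cytoplasm < cell"
            )

    @property
    def nuc_over_cyt(self) -> float:
        """Volume ratio V_nucleus / V_cytoplasm used in shuttling terms."""
        return self.v_nuc_fl / self.v_cyt_fl

    @property
    def cyt_over_nuc(self) -> float:
        return self.v_cyt_fl / self.v_nuc_fl


DEFAULT_GEOMETRY = CellGeometry()


@dataclass(frozen=True)
class RateConstant:
    """A kinetic constant with its reaction order and compartment.

    ``value`` is in canonical units: ml/(mmol s) for order 2,
    1/s for order 1 and mmol/(ml s) for order 0.
    """

    value: float
    order: int
    units: str = ""
    compartment: str = "cytoplasm"

    def __post_init__(self) -> None:
        if self.order not in (0, 1, 2):
            raise ValueError(f"unsupported reaction order {self.order}")
        if self.value < 0:
            raise ValueError("rate constants must be non-negative")


def _molecules_per_unit_conc(volume_fl: float, avogadro: float = AVOGADRO) -> float:
    # molecules per (mmol/ml) of concentration in a compartment of volume_fl
    # = N_A[1/mmol] * V[ml] = (avogadro*1e-3) * (volume_fl*1e-12)
    return avogadro * 1e-3 * volume_fl * 1e-12


def concentration_to_count(
    conc_nm: float, volume_fl: float, avogadro: float = AVOGADRO
) -> int:
    """Convert a concentration in nM to a molecule count in a compartment.

    Parameters
    ----------
    conc_nm : concentration in nM.
    volume_fl : compartment volume in fL.

    Returns
    -------
    int
        ``round(conc * V * N_A)`` molecules.
    """
    if conc_nm < 0:
        raise ValueError("concentration must be non-negative")
    if volume_fl <= 0:
        raise ValueError("volume must be positive")
    return round(conc_nm * NM * _molecules_per_unit_conc(volume_fl, avogadro))


def count_to_concentration(
    count: float, volume_fl: float, avogadro: float = AVOGADRO
) -> float:
    """Inverse of :func:`concentration_to_count`; returns nM."""
    if count < 0:
        raise ValueError("molecule count must be non-negative")
    if volume_fl <= 0:
        raise ValueError("volume must be positive")
    return count / _molecules_per_unit_conc(volume_fl, avogadro) / NM


def det_to_stoch_rate(
    k: RateConstant,
    geometry: CellGeometry = DEFAULT_GEOMETRY,
    source_volume_fl: float | None = None,
    target_volume_fl: float | None = None,
) -> float:
    """Convert a deterministic rate constant to a per-molecule propensity (1/s).

    Rules:

    * order 2: ``k / (N_A * V)`` with V the reaction compartment volume
      (bimolecular concentration constant -> per-molecule-pair propensity);
    * order 0: ``k * N_A * V`` (concentration flux -> molecules/s);
    * order 1 within one compartment: unchanged;
    * order 1 crossing compartments (e.g. a nuclear species driving a
      cytoplasmic synthesis rate): ``k * V_target / V_source``, because the
      deterministic constant multiplies a source-compartment concentration
      while the propensity multiplies a source-compartment molecule count.
    """
    src = source_volume_fl if source_volume_fl is not None else geometry.v_cyt_fl
    tgt = target_volume_fl if target_volume_fl is not None else src
    if k.order == 2:
        return k.value / _molecules_per_unit_conc(tgt, geometry.avogadro)
    if k.order == 0:
        return k.value * _molecules_per_unit_conc(tgt, geometry.avogadro)
    # first order
    return k.value * tgt / src


def nacl_molar_to_canonical(nacl_m: float) -> float:
    """NaCl: mol/L is numerically mmol/ml."""
    if nacl_m < 0:
        raise ValueError("NaCl concentration must be non-negative")
    return float(nacl_m)


def dox_ug_ml_to_canonical(dox_ug_ml: float) -> float:
    """Doxycycline ug/ml -> mmol/ml via molar mass 444.4 g/mol."""
    if dox_ug_ml < 0:
        raise ValueError("doxycycline concentration must be non-negative")
    # g/ml / (g/mol) = mol/ml; *1e3 -> mmol/ml
    return dox_ug_ml * 1e-6 / DOX_MW_G_PER_MOL * 1e3


def gal_percent_to_canonical(gal_percent: float) -> float:
    """Galactose % w/v -> mmol/ml (2 % == 0.11 mmol/ml)."""
    if gal_percent < 0:
        raise ValueError("galactose concentration must be non-negative")
    return gal_percent * GAL_MMOL_ML_PER_PERCENT
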