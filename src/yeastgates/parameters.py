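"""Built-in kinetic parameter sets and initial conditions.

All deterministic constants are in canonical units (mmol/ml, s):
second-order constants in ml/(mmol s), first-order in 1/s, zeroth-order
in mmol/(ml s).  The stochastic table holds per-molecule propensity
constants (1/s) for the reporter-cell model in molecule counts.

The nuclear import/export pair of the stochastic table (21.423 / 8.4)
is not a volume-scaling of the deterministic pair (16.8 / 85.7); both
pairs are used verbatim in their respective frameworks.
"""

from __future__ import annotations

from .units import DEFAULT_GEOMETRY, RateConstant, det_to_stoch_rate

# ---------------------------------------------------------------------------
# Deterministic parameter sets
# ---------------------------------------------------------------------------

#: HOG-pathway salt sensor driving MFalpha1 expression.
SALT_CELL_PARAMS: dict[str, float] = {
    "w": 2.39,            # osmostress gain per mmol/ml NaCl
    "k20": 758.0,         # Pbs2 activation, ml/(mmol s)
    "k21": 235.0,         # Pbs2 deactivation, 1/s
    "k22": 113543.0,      # Hog1 phosphorylation, ml/(mmol s)
    "k23": 8.84e-5,       # cytoplasmic Hog1 dephosphorylation, 1/s
    "k24": 0.0148,        # nuclear Hog1 dephosphorylation, 1/s
    "k25": 34.5,          # nuclear export of Hog1-PP, 1/s
    "k26": 87.8,          # nuclear import of Hog1-PP, 1/s
    "k27": 5.76,          # nuclear import of Hog1, 1/s
    "k28": 45.2,          # nuclear export of Hog1, 1/s
    "k29": 8170.0,        # osmolyte synthesis, 1/s
    "k30": 0.0035,        # osmolyte leakage, 1/s
    "Ki30": 100.0,        # osmostress inhibition of leakage, ml/mmol
    "k31": 1.5e-6,        # STL1-promoter transcription, 1/s
    "k31_deg": 0.00231,   # MFalpha1-mRNA degradation (t1/2 = 5 min), 1/s
    "k32": 3.0,           # prepro-alpha translation, 1/s
    "k33": 0.00315,       # processing and export of alpha, 1/s
}

#: Tet-Off constitutive sender, repressed by doxycycline.
DOX_CELL_PARAMS: dict[str, float] = {
    "k38": 2e-12,         # Tet-Off transcription, mmol/(ml s)
    "Ki38": 1e7,          # doxycycline repression, ml/mmol
    "k31_deg": 0.00231,
    "k32": 3.0,
    "k33": 0.00315,
}

#: GAL1-promoter sender (3 h induction delay after a glucose shift).
GAL_CELL_PARAMS: dict[str, float] = {
    "k37": 1.2e-11,       # GAL1 transcription, ml/(mmol s) on galactose
    "gal_delay_h": 3.0,
    "k31_deg": 0.00231,
    "k32": 3.0,
    "k33": 0.00315,
}

#: Basal Ste2 steady state (nM); synthesis is pinned so that at zero
#: pheromone the receptor rests exactly at this level.
STE2_BASAL_NM = 378.0

#: Pheromone pathway + GFP expression module of the reporter cell.
REPORTER_PARAMS: dict[str, float] = {
    "k1": 8e11,           # Ste2-alpha binding, ml/(mmol s)
    "k2": 3250.0,         # alpha release from Ste2, 1/s
    "v_Ste2_production": STE2_BASAL_NM * 1e-9 * 1.84e-5,  # = Ste2_0 * k4
    "k4": 1.84e-5,        # Ste2 degradation, 1/s
    "k5": 2.1e-5,         # Ste2-alpha degradation, 1/s
    "k6": 18000.0,        # Ste5-complex activation, ml/(mmol s)
    "k7": 0.0042,         # Ste5-complex inactivation, 1/s
    "k8": 3.2e10,         # Fus3 phosphorylation, ml/(mmol s)
    "k9": 680.0,          # cytoplasmic Fus3 dephosphorylation, 1/s
    "k10": 0.28,          # nuclear Fus3 dephosphorylation, 1/s
    "k_nuc_imp": 16.8,    # nuclear import of Fus3 / Fus3-PP, 1/s
    "k_nuc_exp": 85.7,    # nuclear export of Fus3, 1/s
    "k_small": 0.5,       # Fus3-PP export = k_small * k_nuc_exp
    "k34": 4e-6,          # FUS1-promoter transcription, 1/s
    "k34_deg": 0.00214,   # GFP-mRNA degradation (t1/2 = 5.4 min), 1/s
    "k35": 2.0,           # GFP translation, 1/s
    "k36": 9.625e-5,      # GFP folding/maturation (t1/2 = 120 min), 1/s
}

#: Receptor-binding constant of the half-affinity Ste2 mutant used by the
#: second reporter population of the three-value gate.
STE2_MUTANT_K1 = 4e11

# ---------------------------------------------------------------------------
# Initial conditions (Table of measured per-cell abundances)
# ---------------------------------------------------------------------------

#: species -> (concentration nM, compartment, published per-cell count)
INITIAL_CONDITIONS: dict[str, tuple[float, str, int]] = {
    "Pbs2": (123.7, "cytoplasm", 2160),
    "Hog1n": (340.5, "nucleus", 832),
    "Hog1c": (340.5, "cytoplasm", 5948),
    "Ste2": (378.0, "cytoplasm", 6600),
    "inactive_Ste5complex": (38.5, "cytoplasm", 672),
    "Fus3n": (568.4, "nucleus", 1390),
    "Fus3c": (406.0, "cytoplasm", 7090),
}

# ---------------------------------------------------------------------------
# Stochastic reporter-cell propensity constants (per-molecule, 1/s)
# ---------------------------------------------------------------------------

#: Published propensity table, used verbatim in the stochastic model.
#: k3 is the zeroth-order Ste2 synthesis propensity (molecules/s).
STOCHASTIC_REPORTER_PARAMS: dict[str, float] = {
    "k1": 45.82,
    "k2": 3250.0,
    "k3": 0.12144,
    "k4": 1.84e-5,
    "k5": 2.1e-5,
    "k6": 1.031e-6,
    "k7": 0.0042,
    "k8": 1.833,
    "k9": 680.0,
    "k10": 0.28,
    "k_nuc_imp": 21.423,
    "k_nuc_exp": 8.4,
    "k_small": 0.5,
    "k34": 2.86e-5,
    "k34_deg": 0.00214,
    "k35": 2.0,
    "k36": 9.625e-5,
}


def derive_stochastic_params(geometry=DEFAULT_GEOMETRY) -> dict[str, float]:
    """Recompute the stochastic table from the deterministic constants.

    Applies the volume conversion rules of :func:`~yeastgates.units.
    det_to_stoch_rate`; covers every row except the anomalous nuclear
    import/export pair, which has no simple volume derivation and is
    taken verbatim from :data:`STOCHASTIC_REPORTER_PARAMS`.
    """
    p = REPORTER_PARAMS
    cyt, nuc = geometry.v_cyt_fl, geometry.v_nuc_fl
    second = lambda v: det_to_stoch_rate(RateConstant(v, 2), geometry, cyt)
    first = lambda v: v
    return {
        "k1": second(p["k1"]),
        "k2": first(p["k2"]),
        "k3": det_to_stoch_rate(RateConstant(p["v_Ste2_production"], 0), geometry, cyt),
        "k4": first(p["k4"]),
        "k5": first(p["k5"]),
        "k6": second(p["k6"]),
        "k7": first(p["k7"]),
        "k8": second(p["k8"]),
        "k9": first(p["k9"]),
        "k10": first(p["k10"]),
        # nuclear Fus3-PP (count) drives cytoplasmic transcription
        "k34": det_to_stoch_rate(RateConstant(p["k34"], 1), geometry, nuc, cyt),
        "k34_deg": first(p["k34_deg"]),
        "k35": first(p["k35"]),
        "k36": first(p["k36"]),
        "k_nuc_imp": STOCHASTIC_REPORTER_PARAMS["k_nuc_imp"],
        "k_nuc_exp": STOCHASTIC_REPORTER_PARAMS["k_nuc_exp"],
        "k_small": STOCHASTIC_REPORTER_PARAMS["k_small"],
    }
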