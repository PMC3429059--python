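"""Gate assembly: preconditioning, truth tables, thresholds, invariants."""

import numpy as np
import pytest

from yeastgates.cells import CultureConfig, DoxCell, GalCell, SaltCell
from yeastgates.gates import (
    BUILTIN_GATES,
    get_gate,
    map_inputs,
    precondition,
    run_gate,
    three_value_gate,
    truth_table,
)
from yeastgates.units import NM


def test_precondition_gal_matches_published_pools():
    pre = precondition(GalCell(precultured=True), duration_h=16)
    assert pre["MFalpha1_mRNA"] / NM == pytest.approx(0.571, rel=1e-2)
    assert pre["prepro_Alpha"] / NM == pytest.approx(544, rel=1e-2)


def test_precondition_dox_matches_published_pools():
    pre = precondition(DoxCell(), duration_h=16)
    assert pre["MFalpha1_mRNA"] / NM == pytest.approx(0.866, rel=1e-2)
    assert pre["prepro_Alpha"] / NM == pytest.approx(825, rel=1e-2)


def test_precondition_zero_mode_and_salt_noop():
    assert precondition(DoxCell(), mode="zero") == {
        "MFalpha1_mRNA": 0.0, "prepro_Alpha": 0.0}
    with pytest.warns(UserWarning, match="no-op"):
        pre = precondition(SaltCell(), duration_h=16)
    assert pre["prepro_Alpha"] == 0.0
    with pytest.raises(ValueError):
        precondition(DoxCell(), duration_h=0)


def test_precondition_handling_delay_decays_pools():
    full = precondition(DoxCell(), duration_h=16)
    delayed = precondition(DoxCell(), duration_h=16, handling_delay_min=15)
    k31_deg, k33 = DoxCell().params["k31_deg"], DoxCell().params["k33"]
    assert delayed["MFalpha1_mRNA"] == pytest.approx(
        full["MFalpha1_mRNA"] * np.exp(-k31_deg * 900), rel=1e-9)
    assert delayed["prepro_Alpha"] == pytest.approx(
        full["prepro_Alpha"] * np.exp(-k33 * 900), rel=1e-9)


def test_identity_without_stimulus_is_negative_with_zero_gfp():
    res = run_gate("identity", {"nacl": 0.0})
    assert not res.verdict
    assert res.gfp_um["reporter"] == pytest.approx(0.0, abs=1e-12)


def test_identity_output_monotone_in_salt_dose():
    gfp = [run_gate("identity", {"nacl": s}).gfp_um["reporter"]
           for s in (0.0, 0.1, 0.2, 0.4)]
    assert all(b >= a for a, b in zip(gfp, gfp[1:]))


def test_not_gate_leaky_under_full_repression():
    # pre-accumulated mRNA/prepro pools still generate >2 uM GFP
    res = run_gate("not", {"dox": 10.0})
    assert 2.0 < res.gfp_um["reporter"] < 4.5
    assert not res.verdict
    res0 = run_gate("not", {"dox": 0.0})
    assert res0.verdict
    assert res0.gfp_um["reporter"] > res.gfp_um["reporter"]


def test_not_gate_dose_response_non_increasing():
    gfp = [run_gate("not", {"dox": d}).gfp_um["reporter"]
           for d in (0.0, 0.5, 10.0)]
    assert all(b <= a for a, b in zip(gfp, gfp[1:]))


def test_not_gate_zero_preculture_removes_leak():
    res = run_gate("not", {"dox": 10.0}, preculture="zero")
    assert res.gfp_um["reporter"] < 0.1


def test_or_gate_truth_table():
    df = truth_table("or", {"nacl": [0.0, 0.4], "gal": [0.0, 2.0]})
    verdicts = {(r.nacl, r.gal): r.positive for r in df.itertuples()}
    assert not verdicts[(0.0, 0.0)]
    assert verdicts[(0.4, 0.0)]
    assert verdicts[(0.0, 2.0)]
    assert verdicts[(0.4, 2.0)]


def test_implies_gate_truth_table():
    df = truth_table("implies", {"dox": [0.0, 10.0], "gal": [0.0, 2.0]})
    verdicts = {(r.dox, r.gal): r.positive for r in df.itertuples()}
    assert verdicts[(0.0, 0.0)]
    assert verdicts[(0.0, 2.0)]
    assert verdicts[(10.0, 2.0)]
    assert not verdicts[(10.0, 0.0)]


def test_nand_gate_via_glucose_relabeling():
    df = truth_table("nand", {"dox": [0.0, 10.0], "glucose": [0.0, 1.0]})
    verdicts = {(r.dox, r.glucose): r.positive for r in df.itertuples()}
    # output false only when both inputs are on
    assert verdicts[(0.0, 0.0)]
    assert verdicts[(0.0, 1.0)]
    assert verdicts[(10.0, 0.0)]
    assert not verdicts[(10.0, 1.0)]


def test_truth_table_rejects_empty_grid():
    with pytest.raises(ValueError):
        truth_table("identity", {"nacl": []})


def test_unknown_gate_and_input_names_rejected():
    with pytest.raises(ValueError, match="unknown gate"):
        get_gate("xor")
    with pytest.raises(ValueError, match="unknown input"):
        map_inputs(BUILTIN_GATES["identity"], {"dox": 1.0})


def test_three_value_gate_discriminates_three_salt_levels():
    out = three_value_gate()
    p0 = out[0.0]["positive"]
    p1 = out[0.1]["positive"]
    p4 = out[0.4]["positive"]
    assert not p0["reporter"] and not p0["reporter_mut"]
    assert p1["reporter"] and not p1["reporter_mut"]
    assert p4["reporter"] and p4["reporter_mut"]
    # mutant responds more slowly than wild type at every level
    assert out[0.1]["gfp_um"]["reporter_mut"] < out[0.1]["gfp_um"]["reporter"]


def test_or_gate_alpha_superposition(identity_result):
    """Medium alpha with both senders on dominates either alone."""
    both = run_gate("or", {"nacl": 0.4, "gal": 2.0}).trajectory
    only_salt = run_gate("or", {"nacl": 0.4, "gal": 0.0}).trajectory
    only_gal = run_gate("or", {"nacl": 0.0, "gal": 2.0}).trajectory
    a_both = both["Alpha_in_medium"]
    assert np.all(a_both >= only_salt["Alpha_in_medium"] - 1e-18)
    assert np.all(a_both >= only_gal["Alpha_in_medium"] - 1e-18)


def test_halving_density_halves_initial_alpha_flux():
    full = run_gate("not", {"dox": 0.0}).trajectory
    half = run_gate("not", {"dox": 0.0},
                    culture=CultureConfig(density=2.5e6)).trajectory
    # compare early medium alpha accumulation (prepro pools identical)
    r = half["Alpha_in_medium"][5] / full["Alpha_in_medium"][5]
    assert r == pytest.approx(0.5, rel=2e-2)


def test_monotone_outputs_and_conservation(identity_result):
    tr = identity_result.trajectory
    for name in ("reporter.mature_GFP", "Alpha_in_medium"):
        assert np.all(np.diff(tr[name]) >= -1e-18)
    vc, vn = 29.0, 4.06
    hog = (tr["salt.Hog1c"] + tr["salt.Hog1ppc"]) * vc \
        + (tr["salt.Hog1n"] + tr["salt.Hog1ppn"]) * vn
    fus = (tr["reporter.Fus3c"] + tr["reporter.Fus3ppc"]) * vc \
        + (tr["reporter.Fus3n"] + tr["reporter.Fus3ppn"]) * vn
    ste5 = tr["reporter.inactive_Ste5complex"] + tr["reporter.active_Ste5complex"]
    pbs2 = tr["salt.Pbs2"] + tr["salt.Pbs2pp"]
    for total in (hog, fus, ste5, pbs2):
        assert np.max(np.abs(total - total[0])) / total[0] < 1e-6


def test_all_species_stay_non_negative(identity_result):
    assert identity_result.trajectory.values.min() >= 0.0


def test_verdict_monotone_in_threshold(identity_result):
    spec_lo = BUILTIN_GATES["identity"].with_(threshold_um=2.0)
    spec_hi = BUILTIN_GATES["identity"].with_(threshold_um=6.0)
    lo = run_gate(spec_lo, {"nacl": 0.4})
    hi = run_gate(spec_hi, {"nacl": 0.4})
    # raising the threshold can only flip positives to negatives
    assert lo.verdict or not hi.verdict
    assert lo.verdict and not hi.verdict  # 4.46 uM sits between 2 and 6
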