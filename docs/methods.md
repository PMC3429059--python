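# Methods

## Scope and model structure

`yeastgates` simulates consortium logic gates built from four engineered
yeast cell types. Three sender cells secrete alpha-factor in response
to chemical inputs; one reporter cell converts medium alpha-factor into
GFP. All intracellular kinetics are mass-action ODEs in canonical
units (concentrations in mmol/ml ≡ mol/L, time in seconds); the
built-in rate constants and initial concentrations ship in
`yeastgates.parameters`.

**Salt cell.** A minimal HOG-pathway model: osmostress
`max(w·Salt − Int_osmo, 0)` activates Pbs2, which phosphorylates Hog1;
Hog1 shuttles between cytoplasm and nucleus with
phosphorylation-state-dependent rates, and cytoplasmic active Hog1
drives osmolyte synthesis (adaptation: osmolytes quench osmostress, and
osmostress inhibits osmolyte leakage through the Fps1 channel term
`k30·Int_osmo/(1 + Ki30·osmostress)`). Nuclear Hog1-PP drives *MFα1*
transcription. At 0.4 M NaCl the model peaks near 50 % Hog1
phosphorylation — the calibration point of the underlying parameter
fits — and adapts within ~30 min to a plateau.

**Dox cell.** Constitutive Tet-Off transcription `k38/(1 + Ki38·DOX)`.

**Gal cell.** Transcription `k_Gal(t)·Gal` with `k_Gal = 0` for the
first 3 h after a glucose→galactose shift (GAL induction delay) and
`k37` afterwards; cells pre-cultured in galactose have no delay.

**Shared expression module.** mRNA degradation (t½ = 5 min),
translation (k32 = 3/s), processing/export (k33, t½ = 3.67 min). The
per-cell export flux enters the medium divided by the dilution factor
(below). Medium alpha-factor is **not** depleted by receptor binding:
with ~10⁴-fold dilution per cell the per-cell consumption is
negligible, and reporters are bar1Δ so no extracellular protease
degrades the pheromone.

**Reporter cell.** Ste2 synthesis is pinned to `v = Ste2₀·k4`
(Ste2₀ = 378 nM), so the unstimulated receptor level is exactly its
steady state. Bound receptor activates the Ste5 complex (a single
species standing in for the scaffolded MAPK cascade), active Ste5
phosphorylates Fus3, and Fus3/Fus3-PP shuttle between cytoplasm and
nucleus with import rate `k_nuc_imp` and export `k_nuc_exp`
(`k_small·k_nuc_exp` for the phosphorylated form — stronger nuclear
retention). The import/export pair is chosen so the basal
nuclear/cytoplasmic Fus3 concentration ratio is 1.4. Nuclear Fus3-PP
drives GFP transcription; translation and slow chromophore maturation
(t½ = 120 min) complete the output. Mature GFP has no sink.

Where the source equations carry duplicated left-hand sides, the
assignments used here are the unique ones that conserve the Ste5 and
Fus3 totals (volume-weighted, matching the structure of the Hog1
equations); conservation of Hog1, Fus3, Ste5, and Pbs2 totals is
asserted by the test suite to a relative drift < 10⁻⁶ over 6 h.

## Compartments and units

Cell 58 fL, cytoplasm 29 fL (50 %), nucleus 4.06 fL (7 %);
N_A = 6.022×10²³ (4 significant figures, which reproduces the published
per-cell molecule numbers by rounding). Cross-compartment shuttling
terms carry V_nuc/V_cyt factors so volume-weighted totals are
conserved. mRNA and proteins are referenced to the cytoplasm volume;
the transcription constants driven by nuclear MAPK concentrations are
used as printed, with compartment bridging absorbed into the fitted
constants.

Input conventions (the boundary between lab units and canonical units):
NaCl M ↔ mmol/ml 1:1; galactose 0.055 mmol/ml per % w/v (so "2 %" is
0.11 mmol/ml, the value that makes the gal-cell pre-culture pool come
out at 0.571 nM mRNA exactly); doxycycline μg/ml via molar mass
444.4 g/mol. At 1 μg/ml the Tet-Off term represses transcription
~23-fold.

## Dilution law and culture settings

`dilution(t) = 13 800·(5×10⁶/density)·exp(−(ln2/T_d)·t[h])`, default
density 5×10⁶ cells/ml per population and doubling time T_d = 4 h
(rate 0.173 1/h). The 13 800 coefficient is kept configurable; only
its link to doubling time and density is asserted (halving the density
doubles the coefficient and halves the initial alpha-factor flux).
Intracellular species are not diluted by growth — an accepted
simplification for a ≤ 6 h horizon.

## Gate assembly and scoring

A gate couples sender populations and reporter populations through one
shared `Alpha_in_medium` pool (sum of the senders' export fluxes, each
with its own dilution factor). Gal- and dox-senders are pre-conditioned
by a 16-h pre-simulation (gal: 2 % galactose, pre-cultured mode; dox: no
drug), which leaves mRNA/prepro-alpha pools of 0.571/544 nM (gal) and
0.866/825 nM (dox); medium alpha accumulated during pre-culture is
discarded at t = 0 (cells are washed into fresh medium). An optional
handling delay decays the two pools exponentially (k31_deg, k33) before
the gate starts — translation during handling is neglected, consistent
with treating handling as a perturbation of the stored pools. A
`zero` pre-culture mode resets both pools, the idealized control that
removes the NOT/OR/IMPLIES leak.

Verdicts compare mature GFP at the readout time (default 4 h; 5 h for
the three-value gate) against 4.5 μM cytoplasmic GFP; the comparison is
`≥` (a cell exactly at threshold counts positive). NAND and the
reprogrammed IMPLIES come from the same assemblies with glucose
relabeling: "glucose present" simply sets galactose induction to zero
(no catabolite-repression kinetics). At a strict 4.0-h readout the
IDENTITY gate at 0.4 M NaCl sits at 4.46 μM, ~1 % under the threshold,
and crosses it minutes later — a reminder that binary calls near the
threshold are sensitive to the exact readout time.

## Deterministic engine

LSODA (`scipy.integrate.solve_ivp`) with rtol 10⁻⁸ and atol 10⁻¹²
mmol/ml, reported on a 60-s grid; the GAL induction switch is handled
by segmenting the integration at t = 3 h, not by event detection.
Tightening the tolerances tenfold changes GFP(4 h) by < 0.1 %.
`steady_state` integrates in 8-h chunks until the state stops changing,
then polishes with a damped least-squares Newton step on the RHS, which
reaches max|dy/dt| < 10⁻¹⁵ mmol/ml/s (long integration alone bottoms
out at the atol noise floor). Pure accumulators (mature GFP, medium
alpha) are excluded from the residual — they grow linearly whenever
their source is active. The dilution factor makes coupled gates
non-autonomous, so steady states are only offered for single cells.

## Stochastic engine

Molecule counts use the initial-condition table verbatim (e.g. 7090
cytoplasmic + 1390 nuclear Fus3, 672 Ste5 complexes); propensity
constants come from the deterministic values by the standard
conversions (order 2: k/(N_A·V); order 0: k·N_A·V; order 1: unchanged;
a nuclear concentration driving a cytoplasmic synthesis rate picks up
V_cyt/V_nuc). `gillespie_direct` is the exact direct method:
exponential waiting times from the total propensity, linear-scan
selection, state frozen to the horizon when the total propensity
reaches zero. Kernels are numba-compiled.

**Full reporter model** (constant alpha-factor): the bound receptor is
held at its closed-form quasi-steady-state count (QSSA; validated in
the tests against the deterministic steady state). The Fus3
phosphorylation/dephosphorylation cycle is extremely fast at the fitted
constants (k9 = 680/s; ~10⁶ events/s per cell), which makes a literal
event-by-event simulation of it computationally useless. Because that
cycle is a *closed linear* four-state hop process for each Fus3
molecule, it is treated in quasi-equilibrium: conditional on the
current active-Ste5 count a, each molecule independently occupies
(cyt, cyt-PP, nuc, nuc-PP) with the analytic stationary distribution
π(a); Ste5 activation/deactivation and the GFP module are simulated
exactly; transcription uses the conditional mean N·π_ppn(a); recorded
nuclear Fus3-PP values are binomial draws from the conditional
occupancy. The approximation error is the neglected contribution of
sub-second Fus3-PP fluctuations to transcription noise,
≈ 2σ²τ_c/λ ~ 10⁻⁵ in relative variance (correlation time τ_c ≲ 0.2 s
against mean transcription intervals of ~10 s) — far below Monte-Carlo
resolution at 100 trajectories. The slower, noise-dominating Ste5
fluctuations (τ ≈ 2–4 min) are simulated exactly.

The per-molecule nuclear transport rates in the full model are the
deterministic constants themselves (16.8, 85.7, 0.5·85.7 1/s):
unimolecular rates are invariant under the count conversion, which
keeps the stochastic mean on the deterministic trajectory and
reproduces the published population CVs. The published stochastic
parameter table's import/export pair (21.423/8.4) does not satisfy this
consistency and is stored only as the verbatim record.

**Hybrid model** (whole gates, time-varying alpha-factor): the
deterministic nuclear Fus3-PP trajectory is converted to counts, fitted
with an interpolating cubic spline (exact at every 60-s report point,
so the < 1 % fit-error contract holds by construction), and its
derivative, clamped at ≥ 0, becomes the birth propensity of a
birth-only Fus3-PP counting process (hence Poisson:
CV = 100/√mean, an invariant the tests assert). The stochastic clock
starts at the dead time where the deterministic count first reaches one
molecule (≈ 5 min for the IDENTITY gate at 0.4 M). The time-varying
propensity is evaluated on 1-s piecewise-constant bins with
boundary-redraw — exact for piecewise-constant hazards by memorylessness.
If clamping removes > 1 % of the integrated drive (and more than one
molecule), a non-monotone-fit warning is raised. The GFP module
(transcription ∝ Fus3-PP count, mRNA decay, translation, maturation) is
simulated exactly; because the module is linear in its drive, the
ensemble mean reproduces the deterministic trajectory (asserted within
3·SEM).

**Ensembles and noise.** One master seed per ensemble spawns
per-trajectory sub-seeds through `numpy.random.SeedSequence`; seeds are
recorded in output metadata. Default sizes follow the study design:
100 trajectories for the full model, 1000 for hybrid ensembles, 60-s
report grid, CVs quoted at 1, 2, 4 h. CV is 100·sd/mean across
trajectories (sample sd, ddof = 1) and defined as 0 when the mean is 0.
"Mean" is the ensemble mean at the report time; the hybrid Fus3-PP
noise feeds the GFP drive (the sampled count multiplies the
transcription propensity), so pathway and expression noise are coupled.

## Sensitivity analysis

Scaled coefficients S_p(t) = (p/GFP)·ΔGFP/Δp (≈ ∂lnGFP/∂ln p) by
forward finite differences, Δp = max(10⁻³·|p|, 10⁻¹²), one full gate
re-integration per quantity; nine report times between 15 and 240 min.
Scanned: every kinetic parameter of the participating cells, every
non-zero initial concentration, the dilution coefficient, and the
doubling time. Halving Δp changes the top-ranked coefficients by
< 1 %. Two analytic identities anchor the scan: GFP is exactly linear
in the transcription and translation constants, so S = 1 for both at
all times. For the IDENTITY gate the GFP expression module dominates
the ranking, the HOG module contributes little, and the dilution
factor far outranks the doubling time on a 4-h horizon (doubling-time
changes only differentiate the dilution trajectories after ~2 h).

## Synthetic fixtures

`yeastgates fixtures` regenerates all reference data programmatically
(sender pre-cultures, basal reporter, salt-cell response, coupled
IDENTITY gate, a 50-cell hybrid mini-ensemble); regeneration with the
same seed is byte-identical. No measured data ships with the package —
passing tests demonstrate internal consistency with the published model
constants, not agreement with new experiments.

## Problem sizes

The shipped test-suite and acceptance runs use the study's own
replicate counts (100 full-model and 1000 hybrid trajectories, 2000
cells for the three-value gate), 4–6 h horizons, and the default report
grids; deterministic runs take well under a second each and the
stochastic ensembles seconds to ~2 min.

## Known limitations

- Single shared doubling time and translation rate for all cells and
  transcripts; no growth dilution of intracellular species.
- No receptor-level depletion of medium alpha-factor, no Bar1
  degradation, no pheromone-induced cell-cycle arrest.
- The 13 800 dilution coefficient is taken as given rather than derived
  from first principles (it is ~2× the naive 1/(density·V_cyt)).
- Sender-cell gene expression is deterministic even in population
  simulations; only reporter-cell noise is modeled.
- Binary verdicts near the 4.5 μM threshold are sensitive to the exact
  readout time (see the IDENTITY example above).
- The quasi-equilibrium treatment of the Fus3 cycle assumes its
  relaxation (< 1 s) is fast against Ste5 flips (~0.4 s mean interval;
  each flip moves the conditional occupancy by < 1 %, so the
  assumption is mild), and omits an O(10⁻⁵) noise term (above).
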