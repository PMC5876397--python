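# Methods

`placentrans` analyzes Transwell translocation experiments of the kind used
to probe the human placental barrier in vitro: a donor (apical, "maternal")
chamber is dosed with a test compound at concentration C₀, the receiver
(basolateral, "fetal") chamber is sampled at scheduled times, and each draw
is replaced with fresh medium. This note records the model, the estimators,
the synthetic-data generator, the numerical choices, and what the
validation results do and do not show.

## Transport model and estimators

**Cumulative transported mass.** Because each basolateral draw removes
analyte and replaces it with blank medium, the raw concentration Cₙ
understates transport. The sampling-corrected cumulative mass is

    ΔQₙ = Cₙ·V_w + Σ_{j=1}^{n−1} V_s·C_j

with V_w the basolateral volume and V_s the draw volume. Under
sample-and-replace with instantaneous mixing this correction is *exact*:
the simulator's event-driven bookkeeping shows ΔQₙ equals the true net
transported mass at every draw to 1e-9 relative (it is an identity, so
agreement is at machine precision). Results are reported as % of the
initial dose ID = C₀·V_apical.

**Equilibrium ceiling.** A passively equilibrating two-chamber system
splits mass by volume: the basolateral chamber can hold at most
V_b/(V_a+V_b) of the dose — 75% for the default 0.5/1.5 ml insert. The
*cumulative* ΔQ may legitimately exceed this ceiling because withdrawn
mass keeps the basolateral side below equilibrium; readings that push %ID
past the ceiling are flagged (`over_equilibrium`), never clipped, since
with noise they may also indicate an inflated reading.

**Permeability.** P = (ΔQ(t)/Δt)/(A·C₀), the secant from dosing to the
named timepoint, in cm s⁻¹. Two conventions required a decision:

- *Time anchor.* Δt is the elapsed time since dosing (secant from the
  origin), so "P at 2 h" means ΔQ(2 h)/7200 s normalized by A·C₀. This
  reads the subscripted reporting convention (P₁ₕ, Pₑ,₂ₕ) literally.
- *Constant C₀.* No apical-depletion correction is applied in the
  estimator. The simulator does deplete the apical chamber, so the induced
  bias is measured rather than hidden: the 0.25 h secant underestimates a
  true P of 1e-7/1e-6/1e-5 cm s⁻¹ by <0.02%/0.14%/1.34%, and the bias
  grows monotonically with P (≈12% at 1e-4 cm s⁻¹). Estimates at later
  timepoints are progressively more biased by back-flux; the test suite
  pins this bias curve.

**Membrane correction.** The blank insert membrane is itself a barrier in
series with the cells, so the cell-layer-only apparent permeability is
Pₑ = 1/(1/P_c − 1/P_m). At the pole P_c ≥ P_m (possible with noisy
estimates) Pₑ would be infinite or negative, which is unphysical; the
package returns a not-computable marker plus a `pe_undefined` flag.
P_m defaults to the pooled median over the blank-membrane replicates of
the same compound and regime (`pm_mode = "pooled"`); per-replicate pairing
(`per_replicate`) is available, falling back to the pooled value when a
replicate has no matched control.

**Additivity diagnostic.** If barrier layers act as independent series
resistances, 1/P_combined = Σ 1/Pᵢ. The diagnostic ratio
(1/Pₑ,co)/Σ(1/Pₑ,layer) is 1.0 for perfectly additive layers and 0.5 when
a bilayer is no tighter than one of two identical layers — a compact way
to ask whether a trophoblast/endothelial co-culture retains more than its
monolayers predict. On a simulated truly-additive barrier the full
estimator chain returns 1.0007.

**TEER.** Barrier tightness is (R_total − R_blank) × A in Ω·cm². Negative
values (cells reading below the blank) are returned with a warning flag,
not clamped — they usually indicate a bad blank.

**Nanoparticle dosimetry.** For monodisperse spheres,
N = C_mass/(ρ·(π/6)·d³). Nominal manufacturer diameters are used, not
hydrodynamic ones: the hydrodynamic size includes the solvent shell and
agglomerates, and only nominal diameters reproduce stock particle counts
from mass concentrations. Reporting uses 3 significant figures in
scientific notation.

## Statistics

Replicate counts of 3–4 rule out asymptotics, so condition contrasts use
the exact Mann–Whitney U test: all C(n₁+n₂, n₁) assignments of the pooled
midranks are enumerated (ties therefore remain exact) and the two-sided p
is the doubled smaller tail, capped at 1. At n = 4 vs 4 the attainable
p-values make complete separation p = 2/70 ≈ 0.029 and one overlapping
pair p = 4/70 ≈ 0.057; at 3 vs 3 the floor is 0.1. Enumeration is used up
to n₁+n₂ = 12 (70 ≤ C(12,6) = 924 assignments, microseconds); beyond that
the tie-corrected normal approximation (scipy) takes over. Summaries are
the median with either the replicate min/max ("error range") or the
unscaled median absolute deviation; "error range" is interpreted as
replicate min/max, the only definition consistent with upper-and-lower
limits at n = 3–4. No multiplicity correction is applied.

The exact test's type-I error on simulated identical-kinetics arms
(CV = 0.1 noise, 4 vs 4, 2000 studies) measures ≈0.027, matching the
attainable level 2/70 just below α = 0.05 — small-sample exactness comes
at the price of conservatism.

## Synthetic-data generator

The simulator advances well-mixed two-compartment diffusion exactly
between draws,

    M_b(t) = M_eq + (M_b(0) − M_eq)·e^(−P·A·(1/V_a+1/V_b)·t),
    M_eq = (M_a(0)+M_b(0))·V_b/(V_a+V_b),

and at each scheduled draw records C = M_b/V_b, withdraws V_s·C, and
refills with analyte-free medium (event order: read, withdraw, replace —
the reading is pre-replacement). Mass is conserved to 1e-12 relative at
every event. Multi-layer barriers compose harmonically. Measurement noise
is multiplicative Gaussian (CV × value), truncated at zero, applied only
to recorded concentrations — plate-reader error is approximately
proportional to signal, and keeping the truth noiseless lets estimators be
held to exact tolerances. Each (compound, condition, regime, replicate)
cell gets a deterministic RNG stream derived from the study seed.

The default study design mirrors the assay's structure: 6
compounds × 4 barrier conditions (blank membrane; trophoblast monolayer;
endothelial monolayer; co-culture) × static/shaken × 4 replicates, with
the 7-point 24 h schedule (50 µl draws) for fluorescent analytes and the
5-point 6 h schedule (200 µl draws) for the HPLC analytes. Doses are the
applied concentrations (5 µM Na-F and 40 kDa FITC-dextran, 100 µM
antipyrine and indomethacin, 0.5 mg/ml 49 nm and 50 µg/ml 70 nm PS
particles, converted to mg/ml). Static and shaken arms share identical
kinetics by default — the empirical finding this class of experiment
supports — with an optional permeability multiplier to break that null.

Per-layer permeabilities (cm s⁻¹) are design choices fixed to reproduce
the qualitative transport pattern, not any specific experiment's numbers:

| compound      | membrane | trophoblast | endothelium | LOD (mg/ml) |
|---------------|---------:|------------:|------------:|------------:|
| antipyrine    |   1.5e-4 |      1.1e-4 |      8.5e-5 |        1e-5 |
| indomethacin  |   8.0e-5 |      4.0e-5 |      2.0e-5 |        1e-5 |
| Na-F          |   6.0e-5 |      1.5e-6 |      9.0e-6 |        1e-7 |
| FITC-dextran  |   3.0e-5 |      1.0e-9 |      3.5e-7 |        1e-4 |
| 49 nm PS NP   |   3.8e-6 |      5.0e-8 |      1.0e-7 |        1e-5 |
| 70 nm PS NP   |   1.2e-6 |      1.0e-9 |      1.5e-9 |        1e-5 |

These encode: fast transcellular transport with modest cell retention
(antipyrine > indomethacin); strong size dependence of the paracellular
route, with the trophoblast layer much tighter than the endothelium for
Na-F and FITC-dextran; the membrane itself becoming a major barrier for
particulates; and 70 nm particles below detection across every cell-bearing
condition, which the pipeline renders as "n.t." when every replicate's
final reading sits under the compound's LOD.

What the generator does *not* model: unstirred water layers or any
static-vs-shaken hydrodynamic difference, particle sedimentation and
agglomeration dosimetry, carrier-mediated (e.g. OATP) transport, cellular
uptake/accumulation as a separate compartment, apical sampling or
evaporation, and instrument drift or additive background beyond a constant
t = 0 blank. Passing tests therefore demonstrate correctness of the
estimator chain under passive well-mixed diffusion with proportional
noise — not that real barrier data obey that model.

## Pipeline and I/O conventions

Readings travel as tidy CSV (`condition, regime, compound, replicate,
time_h, reading, unit`), hours and ml at the boundary, cm/s/mg/cm³
internally. The t = 0 draw is a pre-dose blank: nonzero t = 0 readings are
subtracted from the whole series (optional, on by default) because no
analyte can have crossed by then. Readings at or below the per-compound
LOD are stored as 0 and flagged rather than left as unreliable small
numbers; a condition is reported "n.t." when *every* replicate's final
reading is censored. A linear calibration coefficient per compound converts
instrument units (e.g. fluorescence) to mg/ml when readings are not
already concentrations. Outputs are four tidy CSVs (per-timepoint results,
Pₑ summary as median ± MAD with n.t. markers, %ID curves as median ±
error range, pairwise exact tests) plus a JSON-lines run log with package
version and config hash; reruns are byte-identical.

## Validation summary (computed by the suite and `scripts/acceptance.py`)

- Sphere dosimetry reproduces the stock particle counts (7.73e12 and
  2.65e11 particles/ml) to 3 significant figures.
- ΔQ ≡ simulated net transported mass across randomized noiseless
  configurations (100 in the acceptance test).
- Noiseless 0.25 h secant recovers P ∈ {1e-7, 1e-6, 1e-5} within 1.4%;
  with CV = 0.1 noise and 4 replicates the median recovered Pₑ over 500
  studies is within ~0.3% of truth (membrane and cell biases largely
  cancel in the series correction).
- Exact Mann–Whitney matches a brute-force permutation oracle for all
  n₁, n₂ ≤ 5 and scipy's exact mode on tie-free data.
- The default synthetic study, run end to end through CSV and pipeline,
  yields the expected ordering antipyrine > indomethacin > Na-F > 49 nm PS
  across cell-bearing barriers with FITC-dextran and 70 nm PS below
  detection (problem sizes: 500 recovery studies, 2000 null studies,
  192-series default study — all in seconds on one core).

## Known limitations

- The secant P estimator inherits a P-dependent downward bias from apical
  depletion/back-flux; comparisons between conditions at matched times are
  unaffected in rank, but absolute values at high P (≳3e-5 cm s⁻¹ at 2 h)
  should be read as lower bounds.
- The Pₑ correction amplifies noise as P_c approaches P_m; the
  `pe_undefined` marker makes the failure explicit, but values near the
  pole remain high-variance (a known pathology of the series-resistance
  correction).
- The exact test's doubled-tail convention can differ from
  sum-of-equally-extreme two-sided definitions in asymmetric tie
  configurations; the doubled tail was chosen for reproducibility of the
  standard small-sample anchor values.
- LOD censoring to zero biases very-low-transport %ID toward zero; the
  flags preserve censoring information for any downstream survival-style
  treatment.
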