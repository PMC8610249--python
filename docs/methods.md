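# Methods

## The model

`clotfilm` simulates tissue-factor-triggered coagulation under venous
flow inside a thin porous "core" layer (thickness δ = 15 µm, porosity
0.5) of platelets and fibrin deposited over a collagen/TF surface.  Two
physical simplifications make the system a set of ordinary differential
equations rather than a transport PDE:

1. **Zymogens are clamped at plasma levels.**  The layer is thin enough
   that the zymogen substrates (FX, FIX, FII, FXI, fibrinogen) are
   replenished by diffusion from flowing blood.  Each Michaelis–Menten
   step therefore linearizes to a first-order reaction in its enzyme
   with rate α = k_cat·[S]₀/(K_m + [S]₀), attenuated by an
   effectiveness factor η ∈ (0, 1] absorbing residual transport limits.
   Substrates are never depleted; fibrin can exceed the plasma
   fibrinogen concentration because flow keeps delivering substrate.
2. **Well-mixed film.**  Concentrations are uniform across the layer;
   wall fluxes are volumetric rates times the effective depth
   δ·porosity.

Eight dynamic species (µM internally): active tissue factor TF\*
(TF:VIIa), FIXa, FXa, FXIa, free thrombin, thrombin bound to the weak
fibrin E-domain site, thrombin bound to the high-affinity γ′-chain site,
and fibrin monomer.  Seven reactions connect them — extrinsic tenase
activating FX and FIX, intrinsic tenase (FIXa:VIIIa) activating FX,
prothrombinase (FXa:Va) producing thrombin, thrombin cleaving fibrinogen
to fibrin, thrombin activating FXI on platelets, and FXIa activating FIX
(the feedback loop an FXIa inhibitor removes).  Cofactors (FVIIa, FVa,
FVIIIa) are assumed non-limiting; the contact pathway (FXIIa) is
excluded, matching assays run under corn trypsin inhibitor.

Thrombin binds fibrin reversibly at two site classes ("antithrombin-I"
activity): a weak E-domain site (K_d = k_r/k_f = 2.8 µM) and a strong
site on the γ′-fibrinogen splice variant (K_d = 0.1 µM).  Sites are
generated in proportion to fibrin formed (`sites_per_fibrin` per site
class); bound thrombin is protected from inactivation and elution but
can re-dissociate, so fibrin acts as a thrombin buffer that first damps
and later sustains free thrombin.

Removal processes: every free active protease is inactivated by plasma
inhibitors with a 1-minute half-life; TF\* activity decays with a 3-minute
half-life; soluble species additionally elute from the film with a
2-second half-life under flow.  **Which species elute is a modelling
choice** (`ModelConfig.eluting_species`).  The default applies elution
to FXa and free thrombin only: FIXa acts within the platelet-membrane
intrinsic-tenase complex and FXIa is generated and held on activated
platelets, so both are treated as retained in the layer.  This choice is
load-bearing.  If the feedback enzymes washed out on the 2-s timescale,
the FXI loop gain would be ~10⁻³ and an FXIa knockout would change
fibrin by < 1%, contradicting the observed 30–70% reductions.  With FIXa
and FXIa retained, the loop
FXIa → FIXa → FXa → thrombin → FXIa is slightly supercritical at
baseline and is stabilized by the growing fibrin-site sink, which is
precisely the regime that reproduces the FIX superlinearity, the strong
γ′-site sensitivity, and the fibrinogen insensitivity simultaneously.

Cumulative bookkeeping integrals (thrombin produced, inactivated,
eluted) ride along with the state; by construction
produced = free + bound + inactivated + eluted, which the simulator
checks as a mass balance at every output time.  Effluent observables:
F1.2 flux equals the thrombin production rate (one fragment per thrombin
generated); TAT flux is 70% (`tat_fraction`) of the thrombin removal
rate.  By default TAT accounts for eluted plus inhibitor-complexed
thrombin (`tat_includes_inactivation = True`); the elution-only variant
is a switch.

## Parameters

The seven (k_cat, K_m, [S]₀, η) rows and both binding-site kinetic pairs
are taken verbatim from the published kinetics table and shipped as
`data/default_parameters.yaml`.  Rates are recomputed from the formula
rather than read from the published α column — required anyway for
variant scaling.  For reactions 2, 4, 6, 7 the recomputed α matches the
published value to two significant figures; for reactions 1, 3 and 5 it
does not (reaction 5 by ~10×).  `alpha_discrepancy_report` documents the
gap, and `use_printed_alpha` switches to the published column; nothing
is silently patched.

Three quantities are **not** published as absolute values and are
calibrated once against published anchors:

| parameter | meaning | calibrated default |
|---|---|---|
| `tf_active_fraction` | fraction of wall TF (1/µm²) present as active TF:VIIa | 0.07 |
| `weak_E.sites_per_fibrin` | weak E-domain sites per µM fibrin | 1.0 |
| `gamma_prime.sites_per_fibrin` | γ′ sites per µM fibrin | 0.25 |

Anchors: ensemble-mean end-time free thrombin ≈ 50 nM and the
one-at-a-time FIX response (peak total thrombin +100% at FIX = 150%),
with the knockout-potency ordering and the fibrinogen insensitivity
(< 10% fibrin loss at half fibrinogen) as consistency checks.  The wall
TF density conversion itself is exact
(1 molecule/µm² over 7.5 µm effective depth = 0.2214 nM); only the
active fraction is calibrated.  `calibrate_stoichiometry` reproduces the
two-stoichiometry search (deterministic nested grid over a seeded
mini-ensemble) and writes a calibrated parameter file.  The γ′ value of
0.25 sites per fibrin monomer is an *effective* density; the γA/γ′
heterodimer is 12–16% of fibrinogen, and the excess absorbs unmodelled
avidity (bivalent binding, entrapment).

## Numerics

LSODA (via `scipy.integrate.odeint`) with the analytic Jacobian;
rtol = 1e-8, atol = 1e-12 µM.  The binding reactions (rates up to
~10⁴/s) make the system stiff against the 800-s horizon.  Output every
1 s on [0, 800]; large ensembles and knockout re-simulations evaluate
only the endpoint (`t_eval=[0, t_end]`), which changes end values only
within solver tolerance.  Halving tolerances moves end-time fibrin by
< 0.01%.  Identical inputs give bitwise-identical trajectories; CSVs are
written with 17 significant digits so determinism checks can be
byte-level.  Tiny negative excursions are clipped at output; anything
below −10⁻⁶ µM aborts the run as an integration failure, which ensembles
log (with the offending variant) and skip, aborting only if > 1% of runs
fail.

Peak ("maximum over 800 s") statistics are taken over the dense 1-s
output grid, not solver-internal steps.  "Final" fibrin is the 800-s
value; distributions are also recorded at 780 s.  Ensemble envelopes are
pointwise mean/SD (streamed, Welford) and pointwise min/max.  Histograms
default to 50 equal-width bins over the observed range.  Subset
membership is by rank on end-time fibrin with ties broken by variant
index; the middle band is 50% of variants rank-centered on the median.
Subset inhibitor potency is the mean over members of the per-member
percent fibrin reduction (median also reported).

## The synthetic-input generator

The Monte Carlo "data" are variant vectors: independent multipliers,
uniform on [0.5, 1.5], for FXI, FIX, FX, FII, fibrinogen and the two
binding-site densities — i.e. every input varied ±50% around consensus
plasma values, the span of normal inter-individual variation.  The
generator emulates population variability only in these seven levels; it
does not emulate measurement noise, correlated co-variation of clotting
factors (e.g. vitamin-K-dependent factors co-varying), or intra-assay
drift.  Passing tests therefore show that the *model pipeline*
reproduces the published sensitivity structure under the stated sampling
assumptions, not that real donor plasmas are distributed this way.
Multiplier 0 is deliberately outside the variant range; knockouts are
configuration flags so the sampling contract stays tight.

## Problem sizes used by the shipped tests and acceptance script

The acceptance script and the study-level tests run the full published
design: 10,000 Monte Carlo variants, knockout re-simulation of the
top/bottom 2% (200 each) and middle 50% (5,000), and 11-level OAT scans.
One simulation takes ~7 ms, so the whole pipeline completes in about two
minutes.  The scale-down check uses 500-variant ensembles; its Monte
Carlo error is estimated from replicate ensembles because the spread of
a tail-conditional mean includes threshold randomness that member-level
standard errors miss.

## Known limitations

* No spatial resolution: a single well-mixed compartment; no boundary
  layers, no intrathrombus gradients.
* No platelet deposition dynamics, no contact pathway, no cofactor
  limitation, no fibrinogen depletion.
* The elution assignment for FIXa/FXIa, the active-TF fraction and the
  site stoichiometries are modelling choices constrained only by
  published aggregate outputs; different combinations could fit the same
  anchors.
* The published α column disagrees with the α formula for three
  reactions; results use the formula, so absolute fibrin levels inherit
  that choice (percent-change results are insensitive to it).
* Percent reductions and fold changes are robust; absolute bound
  thrombin and fibrin concentrations depend directly on the calibrated
  stoichiometries and should be read as order-of-magnitude.
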