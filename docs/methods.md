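# Methods

## The system and the two model families

`crtox` models a two-species bacterial batch co-culture — *Agrobacterium
tumefaciens* (`At`) and *Comamonas testosteroni* (`Ct`) — growing on linoleic
acid (LA) as the only added carbon source. LA is a nutrient for both species
but becomes toxic to `At` at high concentration; the toxicity is carried by
reactive oxygen species (ROS) generated spontaneously as LA oxidises, and
`Ct` can remove ROS. Two consumer–resource ODE families capture this, and
the difference between them is the package's central question: does it
matter whether the nutrient and the toxin are one compound or two?

**Model 1 — implicit toxicity.** For each species *i* with abundance
*B<sub>i</sub>* (CFU/ml) and LA concentration *C* (au, 1 au = 1 % v/v):

    dB_i/dt = r_i B_i C/(C+K_i) − (β_i + γ_i t) C B_i
    dC/dt   = − Σ_i (1/Y_i) r_i B_i C/(C+K_i)

Growth is Monod (rate *r*, half-saturation *K*, yield *Y*); the per-capita
death rate (β+γt)·C is proportional to LA and rises linearly with the age
*t* of the batch, a reduced-form stand-in for progressive medium oxidation.
Unlike a Haldane/Type-IV response, the net growth rate can go negative,
which is what hump-shaped growth-then-death curves require. The batch clock
resets at every serial transfer: fresh medium has not yet oxidised.

**Model 2 — explicit ROS.** LA is only a nutrient; a third state *R* (ROS
proxy, au) carries the toxicity:

    dB_i/dt = r_i B_i C/(C+K_i) − β_i R B_i
    dC/dt   = − Σ_i (1/Y_i) r_i B_i C/(C+K_i) − (1/m)(d + eR) C
    dR/dt   = (d + eR) C − l R − Σ_i α_i B_i R

ROS is generated from LA spontaneously (*d*) and autocatalytically (*e*,
the lipid-peroxidation chain reaction), decays at rate *l*, and is removed
by cells at per-capita rate *α* (here α<sub>Ct</sub> > 0 = α<sub>At</sub>).
The conversion factor *m* (au LA consumed per au ROS produced) couples the
ROS channel back to the substrate. The cell-free subsystem (*B* = 0) has
the fixed point R\* = dC/(l − eC) when l > eC: ROS rises and then
stabilises, which is exactly the observed cell-free proxy behaviour and
what makes the abiotic constants separately estimable.

The death term in model 2 is per-capita in *B* and proportional to *R*
(−βRB), the direct analogue of model 1's −(β+γt)CB.

Variant flags reproduce the standard simplifications: `no_toxicity_accumulation`
(γ=0, model 1), `linear_ros` (e=0, model 2), and `ros_free` (d=e=l=0 with
R(0)=0), the last mimicking continuous antioxidant (TBHQ) dosing. An
optional second Monod channel on an unspecified minimal-medium nutrient
*N* (N₀ = 0.01 au) accounts for the residual growth seen with no added
carbon; it is off by default and on in the compound-screen generator, whose
carbon-free controls must grow.

## Reference parameter set (synthetic)

The package does not redistribute fitted estimates from any external
dataset. Instead `crtox.reference` ships one synthetic parameter set per
family, calibrated once so the simulated system reproduces the reported
phenomenology of the real co-culture and then frozen:

| quantity | model 2 | model 1 |
|---|---|---|
| At: r, K, Y | 0.12 /h, 0.02 au, 4·10⁹ | 0.2 /h, 0.05 au, 4·10⁹ |
| At: toxicity | β = 0.8 /(au·h) | β = 0.04, γ = 0.012 |
| Ct: r, K, Y | 0.14 /h, 0.01 au, 10¹⁰ | same |
| Ct: detox | α = 3·10⁻¹⁰ ml/(CFU·h) | — |
| abiotic | d = 0.02, e = 0.05, m = 50, l = 0.1 | — |

Calibration targets, in order of priority: (i) growth transients spanning
several days, as in daily plate counts (growth rates ~0.1/h, doubling ~6 h);
(ii) `At` mono-culture hump at 0.75 au with washout of 100-fold/72 h serial
transfers within a few transfers, but indefinite persistence at ≤ 0.5 au;
(iii) co-culture `At` extinction at 0.75 au falling in transfers 6–10 —
later than mono-culture (facilitation) yet eventually excluded; (iv)
competitive exclusion of `At` at low LA; (v) a strictly larger 5-transfer
coexistence region for model 2 than model 1 on a matched grid (23 vs 20 of
28 cells on the default 7×4 grid). `Ct` is the stronger competitor at every
LA level (smaller K), which is what drives exclusion at low LA; facilitation
at high LA comes entirely from α<sub>Ct</sub>.

Two calibration trade-offs are worth knowing. First, with saturating
kinetics (K ≪ C) extra LA adds ROS without adding growth, so the co-culture
extinction transfer *decreases* mildly with C0 on the high-LA limb; a
monotone increase would require unsaturated kinetics (large K with large r)
that contradict the multi-day growth transients. The facilitation claim the
package tests is therefore the co-vs-mono comparison at each concentration,
not monotonicity across concentrations. Second, in model 1 a γ large enough
to keep its coexistence region clearly smaller than model 2's also makes
its mono-culture `At` wash out slowly even at low LA; the model-1 reference
set favours the coexistence-region contrast, as the single-batch
phenomenology (hump, weak rescue) is unaffected.

## Simulation

Batches are integrated with LSODA (`scipy.integrate.solve_ivp`), default
rtol 10⁻⁸ and per-channel atol (10⁻⁴ CFU/ml for abundances, 10⁻¹² au for
chemicals); states are clipped at zero after solving, since strictly
positive trajectories can undershoot numerically. The right-hand side also
clips its input, so adaptive steps probing slightly negative states see a
consistent vector field. Serial transfer: integrate 72 h, zero any species
below the extinction threshold (default 1 CFU/ml ≈ 4 cells in a 4 ml tube),
record the end state, dilute. The default carryover policy `dilute_all`
transfers 1/D of everything (cells, residual LA, ROS, nutrient) into fresh
medium, matching a whole-culture aliquot; `biomass_only` is available for
sensitivity analysis. Fresh medium contributes no ROS.

Phase diagrams run one co-culture serial-transfer simulation per (C0, D)
cell and classify the horizon state from the per-species extinction
indices; everything is deterministic, and the survived sentinel is −1.
Long-horizon sweeps default to 40–60 transfers in the shipped analyses
(extinction times of interest are < 30; the horizon only bounds the
sentinel), with 300 available for exploratory use.

## Fitting

The objective is the vector of log₁₀ residuals between observation and
model, floored at 1 CFU/ml for counts (or at the generator's detection
limit when fitting censored data — the default synthetic datasets are
left-censored at 10² CFU/ml) and at 10⁻³ au for the ROS proxy. Bounded
least squares uses the trust-region reflective algorithm
(`scipy.optimize.least_squares`, box [0, 10¹⁰]), searching log₁₀-scale by
default; linear scale is available and agrees on noise-free data.

Because the objective is multi-modal, each fit is multi-start: 20
log-uniform draws within the box (fixed seed 1789) plus a handful of
data-driven starts (growth rate from the steepest log-slope, yield from
the plateau, several Monod-K guesses, small toxicity). Every start is
probed with one residual evaluation and the best eight are fully
optimised — the rest converge to the same basins. Parameters ending at a
bound are reported in `FitResult.pinned` with a warning.

The model-2 workflow is two-stage, as in the underlying experimental
design: first `fit_cellfree_ros` estimates (d, e, m, l) from cell-free
proxy series at ≥ 2 LA concentrations; these are then fixed while
`fit_monoculture` estimates each species' (r, K, Y, β | α) jointly across
its mono-cultures, with the species' ROS series entering the objective at
equal per-point weight. α<sub>At</sub> is fixed at 0 (At does not detoxify).
Model-1 fits use all four LA concentrations; model-2 fits use two plus the
ROS series. Co-culture trajectories are then *predicted* from the
mono-culture estimates with no refitting; `goodness_scores` reports the
summed squared log₁₀ error on mono data (goodness of fit) and co data
(goodness of prediction) separately.

Inside the fitting loop all of one species' mono-culture conditions are
stacked into a single block-diagonal ODE solve — identical dynamics,
several-fold faster than per-condition solves (a unit test pins the
equivalence).

**Identifiability.** From daily samples of an At-type curve, (r, K) and
(β, γ) form a compensation ridge: the global optimum under CV ≈ 0.3 count
noise can sit 40–60 % away from the generating r even when the fit is
visually perfect, and even truth-started local optima err ~30 %. This is a
property of the design (9 time points per curve), not of the optimiser.
Noise-free data recover all parameters to < 1 %; under realistic noise the
growth side (r, K, Y) is reliably recovered for the detox-insensitive
species, whose curves carry no death signal, and the package's recovery
benchmark measures exactly that. Formal identifiability analysis beyond
bound-pinning warnings is out of scope.

## Synthetic data

The generators integrate the chosen "truth" model on the experimental
design (4 LA concentrations × {mono At, mono Ct, co, cell-free}, daily
sampling 0–192 h, triplicate, inoculum 5·10⁵ CFU/ml) and add measurement
noise: multiplicative lognormal noise on CFU (default CV 0.3 — plate counts
at these densities are dilution-pipetting dominated, so multiplicative
rather than Poisson; the value is an order-of-magnitude choice, not a claim
about any real dataset), left-censored at the detection limit (10²
CFU/ml); additive Gaussian noise on the MDA-TBA2 proxy (default sd 0.01 au,
clipped at 0); Gaussian noise on the linear calibration standards (8 MDA
concentrations 0–160 μM, triplicate). Identical seeds give identical
datasets; the CFU and ROS noise streams are decoupled.

What the generators do *not* emulate: plate-count dilution-series
mechanics, OD measurements, replicate-level batch effects, day effects in
the TBARS assay, or any cross-feeding between the species. Tests passing
on this synthetic data therefore validate the estimation and simulation
machinery under the stated noise model — they do not certify performance
on real plate counts, whose error structure is richer.

The compound screen generator reuses model 1 with per-compound parameters
(plus the MM nutrient channel so carbon-free controls grow): an inert
profile, a pure toxin (r = 0, β > 0), and an LA-like nutrient-then-toxin
profile reproduce the three signature heatmap rows (flat, monotone
negative, positive-then-negative).

## Assay analysis

Growth curves are summarised by trapezoid AUC on the linear CFU/ml scale
over the observed grid (log-scale AUC is available but not default; no
integration rule is canonical for this assay, and trapezoid on the
measured grid is the least-assumption choice). Fold change per replicate
is log₂(AUC / mean of the control triplicate); significance per condition
is a two-sided Welch two-sample t-test against the control AUCs (Welch
because n = 3 triplicates give no basis for assuming equal variances),
starred at 0.05 / 0.01 / 0.001. Fold changes and t statistics are invariant
to a global rescaling of all AUCs. Identical condition and control groups
report p = 1 rather than a 0/0 t-statistic.

TBARS calibration fits an ordinary least-squares line to blank-subtracted
absorbance versus standard concentration; sample concentrations come from
the inverse (A − blank − intercept)/slope, clamped at 0 μM with a flag.
Tukey-style multiple-comparison corrections are deliberately left to
standard statistics packages.

## Problem sizes in the shipped tests and analyses

The default suite and the acceptance script size their simulation studies
as: 100 random parameter draws for the fixed-step-oracle comparison (24 h
horizon, dt 10⁻³ h); 50 noise seeds for the noisy-recovery study; 7×4
(C0 × dilution) grids at a 5-transfer horizon for the phase-diagram
comparison; 15–60-transfer horizons for extinction windows. These sizes
give stable medians and counts while keeping any single study in the
minutes range on one core.

## Known limitations

* The reference parameter set is a calibrated synthetic stand-in, not a
  fit to any published dataset; quantities derived from it (extinction
  windows, coexistence counts) characterise the reference system.
* Model 1's reference set sacrifices low-LA mono-culture persistence for
  the coexistence-region contrast (see above).
* ROS suppression in co-culture is partial at the reference α; systems
  with near-total suppression are reachable by raising α and are exercised
  in tests, but are not the default.
* Toxicity parameters of the sensitive species are not identifiable to
  high precision from daily counts at CV 0.3 noise (ridge, above).
* No spatial structure, stochastic birth–death, pH/temperature dependence,
  chemostat mode, or > 2 species.
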