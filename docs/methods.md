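# Methods

## Model structure

The simulator couples a steady-state community flux balance LP to
extracellular batch mass balances (direct embedding: the LP is solved at
every right-hand-side evaluation of the ODE system).

**Community LP.** Member networks are assembled block-diagonally, so the
combined stoichiometry has no coefficients coupling the reactions of
different species; the objective is the *sum* of the members' growth rates.
This encodes the assumption that the two yeasts grow independently and
interact only through the shared extracellular pools (glucose, oxygen,
ethanol), whose availability enters as kinetic caps on the exchange-flux
bounds. No multi-level or altruistic community objective is used. Solving
with all fluxes of one member fixed to zero reproduces the single-species
problem, which is how pure cultures are simulated.

**Sign convention.** Uptake is a negative exchange flux. Kinetic caps are
magnitudes; a cap `c` sets the exchange lower bound to `-c`.

**Alternate optima.** FBA optima can be degenerate. After the primary
solve, the growth rate is pinned at its optimum and the sum of absolute
fluxes is minimized (a parsimonious second pass), making the exchange
fluxes handed to the ODE layer unique and reproducible. The two passes
share one persistent GLPK problem whose simplex is warm-started between
right-hand-side evaluations; a batch integration performs thousands of
solves at ~0.1 ms each. Simplex feasibility/optimality tolerances are
1e-10; on hand-sized networks the LP agrees with exhaustive vertex
enumeration to better than 1e-12.

**Extracellular balances.** State is (X_c, X_s, G, Z, E, O): biomass
densities in gdw/L, sugars and ethanol in g/L, dissolved oxygen in mM.
Exchange fluxes (mmol/gdw/h) are converted to g/L/h with fixed molar
masses: glucose 0.18016, xylose 0.15013, ethanol 0.04607 g/mmol. Oxygen
needs no conversion. Oxygen transfer follows a film model
`kLa (O* - O)` with `O* = 0.24 mM` (saturation of water at 30 °C, 1 atm);
the sparge-rate-to-kLa map is the straight line through the two gassing-out
calibration points (25 cc/min → 5.5 1/h, 50 cc/min → 10.1 1/h). Runs with
kLa above 10.1 1/h emit a warning: ethanol reassimilation, which appears at
high aeration, is deliberately outside this model's envelope, and ethanol
exchange is otherwise left free.

**Maintenance toggle.** Glucose-only members (the respiratory-deficient
*S. cerevisiae*) cannot pay their non-growth ATP maintenance once glucose
is exhausted, which would make the entire community LP infeasible and zero
out the partner's fluxes too. In co-culture context the simulator locates
the glucose-depletion event (G crossing 1e-6 g/L, chosen as "depleted" at
numerical level) and restarts integration with that member's maintenance
lower bound at zero. The right-hand side also applies the toggle reactively
whenever the LP is infeasible before the event has been located (the
maintenance demand can become unpayable slightly before G reaches the
threshold); if the LP is infeasible even after the toggle, growth and all
exchange fluxes are zero for that evaluation.

**Integration.** The oxygen balance equilibrates orders of magnitude
faster than the sugar balances, so the system is stiff; `solve_ivp` with
the BDF method is used (default rtol 1e-6, atol 1e-8). Depleted pools are
protected by the continuity of the kinetic caps (they vanish with the
substrate), a derivative clamp at zero, and event-based phase switching.
Output is reported on a uniform 0.1 h grid plus event points. Halving the
tolerances moves the final titer by well under 0.1% on the study system.

## Uptake kinetics and parameters

Units are exactly those of the kinetic expressions: sugars/ethanol g/L,
oxygen mM, rates mmol/gdw/h. Defaults (selected per species and context,
never inferred silently):

| parameter | *S. cerevisiae* | *S. stipitis* | meaning |
|---|---|---|---|
| v_g,max | 21.5 pure / 18.5 co-culture | 6.5 | max glucose uptake |
| K_g | 0.5 | 1 | glucose saturation, g/L |
| v_z,max | — | 5.5 | max xylose uptake |
| K_z | — | 0.25 | xylose saturation, g/L |
| K_igz | — | 0.5 | glucose repression of xylose uptake, g/L |
| K_ieg / K_iez | 10 / — | 10 / 4.5 | ethanol inhibition, g/L |
| v_o,max | 2.5 | 11 | max oxygen uptake |
| K_o | 0.005 | 0.0125 | oxygen saturation, mM |

Ethanol inhibition with K_ieg = 10 g/L applies to the glucose uptake of
both species (the expression is generic even though only one species'
variant is usually written out). The reduced co-culture v_g,max of
*S. cerevisiae* reflects the competitive disadvantage of the
respiratory-deficient strain against a Crabtree-negative partner and is a
context flag chosen explicitly by the caller. A missing capability (no
xylose system in *S. cerevisiae*) is a null parameter and yields an
identically zero bound; an infinite inhibition constant disables that
inhibition factor (used for the diauxy-removal scenario).

## The synthetic study system

`synthetic_data` builds small networks whose FBA optimum is computable by
hand: glucose can be fermented (2 ATP + 2 ethanol per glucose) or respired
(26 ATP, 6 O2, mitochondrial), xylose catabolism yields 4 ATP + 1.5 ethanol
and needs 0.5 O2 (oxygen-facilitated xylose use), optional ethanol
respiration yields 13 ATP for 3 O2 (mitochondrial), biomass costs 100 mmol
ATP/gdw, and a 1 mmol/gdw/h ATP maintenance must always be paid.
Integer-friendly yields keep the test oracles exact; every optimum is a
greedy allocation of the oxygen cap across routes ranked by ATP per O2.

The default community pairs a glucose-only member with its respiration
knocked out (the respiratory-deficient strain) with a glucose+xylose member
carrying the published transport parameters. Simulated batches reproduce
the qualitative study phenotypes: an initial respiratory transient while
dissolved oxygen is drawn down, fermentative (Crabtree) glucose overflow,
the diauxic switch to xylose, an oxygen-transfer-limited xylose phase whose
rate scales with kLa, rising titer and a batch-time minimum as the
fermenter's share of a fixed 1 g/L inoculum grows — hence an interior
productivity optimum at a fermenter-lean inoculum — and a positive but
modest sensitivity to the xylose transport parameters with a large gain
from removing glucose repression entirely.

What the toys do **not** emulate: real biomass composition (growth is a
pure ATP sink), byproducts (glycerol, xylitol, acetate), redox/cofactor
balancing, ethanol reassimilation dynamics, pH/temperature effects, and
measurement artifacts beyond i.i.d. multiplicative Gaussian noise. Passing
tests therefore validate the machinery (LP assembly, kinetics coupling,
stiff integration, event logic, estimation, optimization) and the direction
of the study's qualitative conclusions, not genome-scale quantitative
predictions; those require the published reconstructions loaded via SBML.

Synthetic datasets are sampled on a uniform grid (default 1 h) with
per-series multiplicative Gaussian noise, clipped at zero, fully
reproducible from a seed recorded in the metadata along with the generating
parameters.

## Calibration

The original uptake parameters were tuned by trial and error; this package
replaces that with staged, bounded Nelder-Mead minimization of a weighted
SSE between simulated and measured profiles (optionally multistart, seeded,
so results are reproducible). Stages run in order and later stages inherit
earlier results as fixed values — the intended protocol is glucose
parameters from anaerobic data first (kLa = 0, O(0) = 0), then oxygen
parameters from aerated data with the glucose values frozen. Residual
weighting defaults to the inverse squared per-series data maximum, so
g/L-scale sugars and mM-scale dissolved oxygen contribute comparably; unit
weights can be supplied instead. Simulated values are interpolated to the
sample times with monotone piecewise-cubic (PCHIP) interpolation.

Identifiability is a property of the experiment, not the optimizer: in a
gas-transfer-limited batch the oxygen flux equals supply/biomass and stops
depending on v_o,max, so that parameter cannot be estimated from such data.
The recovery experiments therefore estimate v_o,max from a small-inoculum
aerated batch, where uptake is limited by the cell kinetics, with the sugar
parameters fixed from the co-culture stage.
Calibration simulations default to relaxed integrator tolerances
(rtol 1e-4) and skip the parsimony pass for speed — mirroring the common
practice of fitting with a fast solver and reporting with a tight one —
and the recovery tests confirm this does not bias the estimates at the 5%
level. Non-convergence is flagged in the fit report; best-so-far values
are returned.

## Study analyses

Productivity is the final ethanol titer divided by the batch time, the
first (linearly interpolated) crossing of xylose below a 0.5 g/L cutoff;
designs that never cross are flagged undefined and excluded from argmax
with a deterministic tie-break (smallest fermenter inoculum, then smallest
kLa). The optimization is an exhaustive grid scan (default inoculum
fraction step 0.05, kLa in {5.5, 7.6, 10.1}, total inoculum 1 g/L,
16/8 g/L glucose/xylose) rather than a gradient method, matching the
study's protocol and keeping every evaluated design inspectable in the
response table. For grid scans the integration stops once xylose falls
safely below the cutoff (0.25 g/L) to save time.

Scaled sensitivities use one forward perturbation per parameter,
S = (p̄/ȳ)·(Δy/Δp); the Δ is configurable, and the scan reports both the
perturbed productivities and the coefficients. The diauxy-removal scenario
sets K_igz → ∞, which is algebraically identical to deleting the glucose
repression factor.

The ethanol-growth threshold bisects kLa over feasibility of the FBA
problem with maintenance enforced, ethanol as sole carbon source, and the
oxygen cap set by the quasi-steady balance between the kinetic uptake bound
(increasing in O) and film supply kLa(O*−O)/X (decreasing in O). The
assumed biomass density is a required input (default 1 gdw/L) because the
threshold scales with it.

## Knockout screen

Respiratory deficiency induced by mitochondrial DNA damage is modelled by
screening single and paired knockouts among mitochondrial-compartment
reactions only. A candidate is accepted when, on a fixed reference medium,
its FBA phenotype moves strictly in the required direction for biomass
yield (μ per glucose uptake), ethanol yield (ethanol secretion per glucose
uptake) and oxygen demand (oxygen uptake magnitude) relative to the wild
type, and shows no growth on a non-fermentable (ethanol) medium when
required. Candidates are reported in sorted, deterministic order. On the
toy system with an ethanol-respiring wild type, the screen returns exactly
the pair of mitochondrial oxidative reactions — the analogue of the two
electron-transport-chain enzyme deletions that reproduce the
respiratory-deficient phenotype.

## Numerical choices and degenerate inputs

- LP tolerances 1e-10 (simplex bound/reduced-cost); oracle agreement is
  asserted at 1e-9 on toy problems.
- Kinetic caps are evaluated on concentrations clamped at zero; negative
  inputs raise.
- Zero inoculum, zero-capability members, empty knockout lists, grids with
  a single point, xylose already below the cutoff, and maintenance-free
  networks are all defined degenerate cases with tested behaviour rather
  than errors.
- The constant-dissolved-oxygen comparison mode (no oxygen balance) is not
  a separate code path: pass a kLa of zero with a chosen fixed O(0), or
  simply bound oxygen uptake externally; the reported DO value used in such
  comparisons is a parameter, never a constant baked into the package.
- `bruteforce_lp` is exponential by construction and refuses networks with
  more than 12 reactions; it exists as a testing oracle only.

## Problem sizes

The bundled study system is exercised at modest scale: batches of 14–120 h
with ~8 reactions per species, grid scans of ≤ 63 designs, recovery
experiments with 10 noisy replicates of 15 samples each, and 50+ randomized
networks for the oracle check. These sizes keep the full test suite and the
acceptance script comfortably reproducible on a laptop-class single CPU
while exercising every code path; all of them are plain function arguments
and scale up unchanged.

## Known limitations

- Batch operation only; no fed-batch or continuous modes, no pH/T/CO2.
- Ethanol reassimilation at high aeration is out of scope; the model warns
  beyond kLa = 10.1 1/h instead of predicting it.
- Two species maximum in the dynamic layer (the LP layer itself is
  n-species).
- The knockout screen uses yield directions, not quantitative fits, to
  accept candidates; mapping accepted reaction sets back to genes requires
  annotation not carried by the network container (an explicit mapping can
  be supplied in configuration).
- Identifiability checking in the fitting report is a cheap local
  sensitivity probe, not a formal analysis.
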