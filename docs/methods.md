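# Methods

## The modelling problem

Large multi-tissue kinetic models of metabolism founder on parameter
estimation: in-vitro kinetic constants are scarce, noisy and rarely valid
in vivo.  `hepanet` implements a formalism that sidesteps measured
constants entirely.  A network is declared through four kinds of
*independent* parameters —

| symbol | meaning | domain | default |
|---|---|---|---|
| `r` | reverse/forward flux ratio of each reaction step at the reference state | [0, 1) | 0 (irreversible); 0.5 for reactions known reversible but unquantified |
| `f` | fraction of a metabolite's efflux routed into each consuming branch | (0, 1], Σ = 1 | declared per branch |
| `w` | enzyme–substrate complex / free enzyme ratio at the reference state | > 0 | 1 |
| `φ` | normalized boundary influxes | > 0 | 1 |

— and every kinetic rate constant is *derived* from them so that the
normalized reference state (every pool at 1, complexes at `w`) is an exact
equilibrium.  Simulated outputs are therefore fold-changes, not molar
concentrations; the model is semi-quantitative by design.

## Reaction mechanism and derived constants

Each enzymatic reaction is the reversible two-step mechanism
`S + E ⇌ C → E + P`, with the product step reversible through `k_PR`:

```
dS/dt = φ_in − v1              v1 = k_C·E·ΠS − k_CR·C
dC/dt = v1 − v2                v2 = k_P·C − k_PR·E·ΠP
dE/dt = φ_EI − k_dE·E − v1 + v2
dP/dt = v2 − φ_out
```

Given the baseline throughput `F` (the branch fraction times the parent's
total efflux, obtained from a global linear flux-balance solve), the unique
constants realizing net flux `F` and reverse/forward ratio `r` on *both*
elementary steps at the normalized state are

```
k_C = F/(1−r)      k_CR = rF/((1−r)w)
k_P = F/((1−r)w)   k_PR = rF/(1−r)
```

The printed equations of the source formalism are not machine-recoverable
(they survive only as images), so this algebra is the package's own
reconstruction from the stated contracts: the all-ones fixed point, the
per-step ratio `r`, `C = w` at baseline, and the closed-form
new-steady-state relations below.  The test suite pins those contracts, not
any particular typography.

**Closed form.**  For one reaction whose influx is scaled by `a` and whose
first-order product demand by `d`, the new steady state is

```
E* = 1      P* = a/d      C* = w·(a(1−r) + r·P*)      S* = a(1−r²) + r²·P*
```

— the `r²` term is where reversibility couples a reaction to its
downstream state; nothing depends on the absolute flux scale.  A linear
chain iterates `X_i = a(1−r_i²) + r_i²·X_{i+1}` upstream from the terminal
product `a`.  These are the oracles used against full numerical
integration.

**Multi-substrate / multi-product reactions.**  Complex formation is
proportional to the product of all normalized substrate concentrations
(each 1 at baseline, so the initialization is unchanged); the reverse of
the product step uses the product of the product concentrations.
Per-connector stoichiometric multipliers scale consumption/production
relative to the reaction's throughput.

**Flux-balance initialization.**  Baseline throughputs solve a linear
least-squares system: per-metabolite influx and efflux balances plus one
equation per declared branch fraction.  Cycles are handled naturally.  A
branch child may carry a *balance* fraction (`*`) when its flux is pinned
elsewhere — the canonical case is the secondary substrate of a
multi-substrate reaction, whose consumption is fixed by the primary side.
A residual above 1e-9 means the declared fractions are inconsistent and is
a validation error, as is any non-positive reaction throughput.

## Regulation layer

All regulation laws are normalized so that every node contributes zero net
rate when its drivers sit at 1: adding regulation never moves the global
fixed point.

- **Transcription** (mRNA pool `Q`, degradation `k_d`, transcription flux
  `φ_O = k_d`): production is `k_d · Π g(q_i)`, capped at `Q_max`.
  Repression uses the hyperbola `g⁻(q) = Q_max/(1 + (Q_max−1)q)` (equal to
  1 at q = 1, `Q_max` at q = 0, asymptote 0).  Activation uses a clamped
  ramp `g⁺(q) = clip(1 + (Q_max−1)(q−1)/(Q̂_C−1), 0, Q_max)` which reaches
  `Q_max` *exactly* at the saturating regulator level `Q̂_C`.  These are
  contract-faithful reconstructions of the published sigmoidal control
  (bounds, monotonicity, baseline neutrality, saturation at `Q̂_C`);
  multiple regulators combine multiplicatively.
- **Translation**: `dQ_P/dt = k_t·Q_mRNA − k_d·Q_P` with `k_t = k_d`.
- **Switches** (active/inactive pools `A`, `I`): activation transfers mass
  at `k_a·D_act·I`, inactivation at `k_i·D_inact·A`; both pools degrade at
  `k_d` and the inactive pool receives synthesis `2k_d`.  Enforcing
  `k_a = k_i + k_d` makes the all-ones partition exact.  With only an
  activating driver at level `D` the active pool settles at `2D/(1+D)` —
  a saturating (max 2), baseline-neutral transducer.

Defaults: `Q_max = 10`, `Q̂_C = 10`, mRNA/protein/switch `k_d = 0.01` per
time unit, enzyme turnover `φ_EI = k_dE = 0.01`.  The source publishes no
values for these; the defaults give a wide expression range and regulation
dynamics roughly 100× slower than metabolic relaxation, and every one is
overridable per node.  Steady states are unaffected by the turnover
magnitudes (only response speed changes), which is why the time-rescaling
invariance test multiplies them together with the fluxes.

## Perturbations, integration, steady-state detection

Perturbations are piecewise-constant fold multipliers: source influx,
sink demand, degradation of enzymes/genes/proteins/switches (knockout =
×1000), and clamping of a switch's active pool (constant activation, used
for receptor agonism).  Multiple actions on one parameter multiply.

Integration uses SciPy's BDF (the reference used a DASSL-family
integrator) at `rtol 1e-9`, `atol 1e-12`, restarted exactly at each
perturbation start time.  Within a phase the run proceeds in geometrically
expanding chunks and exits once both the derivative max-norm and the
relative state change over the last chunk fall below `ε_ss` (default
1e-7; the source states only the integrator tolerance, so `ε_ss` is this
package's declared criterion, surfaced as a keyword everywhere).
Divergence (any state beyond 1e6), negativity (below −1e-9) or reaching
the horizon (default 1e6 time units) yield a *result* with a failure mode,
never an exception — tolerance analysis consumes these modes.

## Sensitivity analysis

The concentration control coefficient of a branch fraction `f` with
respect to a target `TG` is `C = ((TG*−TG)/(f*−f))·(f/TG)`, with both
steady states computed under the same background (the high-calorie
background scales glucose and triglyceride influx 10-fold).  The perturbed
system re-derives its constants at `f(1+δ)` with siblings renormalized
proportionally (the unique symmetric complement rule); `f*` is the
realized fraction at the perturbed steady state, falling back to the
imposed difference when the realized one is unchanged by construction.
One-sided differences at δ = 10% are the default.  Impact classes use
|C|: `> 1` high, `0.1–0.99` moderate, `< 0.1` low; the printed bounds
leave (0.99, 1) unassigned and this package classes that gap as high (the
conservative screening choice).  Tolerance ranges sweep `f` over a grid
and report the maximal contiguous stable interval around the baseline
with the instability mode at each end (`infeasible` is added to the
published modes for grid points whose re-parameterization has no positive
flux solution).

A consequence of re-normalizing at every `f` worth stating explicitly:
in a purely linear unregulated network every rebuilt baseline is again
all-ones and responses scale exactly, so all coefficients are zero.
Nonzero sensitivity is carried by the nonlinearities — multi-substrate
coupling, saturating switches, clamped expression — exactly as in the
full regulated model.  The co-substrate toy (`make_cosubstrate_toy`)
isolates this: with supply fold `s` of the co-substrate, the target has
the closed form `Y1*(f) = (1−f)/(s−f)`, giving analytic coefficients and
an analytic stability boundary at `f = s` (beyond it the condensation
step is starved and the intermediate accumulates without bound).

## The bundled multi-tissue fixture

`make_liver_adipose_network()` is a reduced liver–adipose–blood network
(27 metabolites, 33 reactions, 25 enzymes, 17 genes, 3 proteins, 4
switches; 105 states) spanning dietary glucose/TG/cholesterol input,
hepatic glycolysis, glycogen turnover, gluconeogenesis, hepatic glucose
output, de-novo lipogenesis (ACC1→FAS→SCD→GPAT, with glycerol-3-P as
GPAT's co-substrate), β-oxidation to ketone bodies, ceramide turnover,
VLDL/LDL/HDL routing, and the adipose TG storage/lipolysis/oxidation
cycle.  Regulators: insulin and glucagon (driven by blood glucose),
PPARα (driven by hepatic fatty acids), AMPK (driven by adiponectin),
SREBP-1c, TNFα and adiponectin.

Its regulatory topology was calibrated qualitatively — edges and modest
per-gene dynamic ranges (e.g. cytokine `Q_max = 3`, adipose ketone
utilization `Q_max = 1.5`) chosen so the network reproduces well-known
physiology — mirroring the iterative literature-driven assembly of the
original whole-body model.  Two structural choices matter: chylomicron-
remnant TG is hydrolyzed on hepatic uptake into fatty acids plus glycerol
backbone (making SCD/GPAT the gatekeepers of hepatic TG synthesis, which
is what renders the desaturase knockout protective on both diets), and
surplus unsaturated FA escapes to membrane-lipid use so a steady state
exists when glycerol-3-P is scarce.

What a green validation matrix does and does not establish: the fixture
reproduces *directions* of change of ~27 variables across four classic
experiments (fasting; SCD knockout on lipogenic and high-fat diets;
adiponectin overexpression under fasting; PPARα agonism on a steatotic
background) at a 5% fold margin.  It does not reproduce the original
model's quantitative coefficients, its 159-metabolite coverage (no urea
cycle, amino-acid or detailed cholesterol-ester chemistry), real
transient shapes (all `w` = 1, turnover defaults), or inter-individual
variability.  The random-network generator likewise tests the
initialization algebra (layered topologies, r ∈ [0, 0.9], log-uniform
w ∈ [0.1, 10], Dirichlet fractions), not biological realism.

## Numerical choices and degenerate inputs

- Flux solve: `numpy.linalg.lstsq`, consistency residual < 1e-9.
- Baseline fixed-point acceptance: derivative max-norm < 1e-10.
- Branch re-declaration renormalizes sibling fractions and divides by the
  exact sum to suppress float drift; fractions at 0 or 1 are rejected
  (a zero-throughput reaction has no derivable constants).
- Scenario phases chain: each phase integrates from the previous end
  state with the union of perturbations in force; clamped pools snap to
  their target at the phase boundary.
- Direction margin 5%: folds in [0.95, 1.05] count as unchanged.
- `detect_steady_state` window: trailing 10% of elapsed time.

## Known limitations

- No molar units, thermodynamic constraints, or spatial structure.
- The Modelica importer targets the object-class subset (component
  declarations + connects) and was built against handcrafted fixtures;
  it does not execute equations or algorithms and will report — not
  interpret — constructs outside the subset.
- Sensitivity coefficients are local (one-sided finite differences under
  one background); no global sensitivity or summation theorems.
- Stiff systems with clamped states use derivative-zeroing, which is
  exact at events but makes a clamped pool insensitive to later
  degradation perturbations.
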