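# Methods

## The model

`landpop` implements a globally aggregated coupled human–environment
system with four state variables: productive natural / 'semi-natural'
land N, intensive agricultural land A, degraded/unproductive land D (all
in billions of hectares, Gha) and the human population H (billions of
individuals). Land is conserved: N + A + D = L, with L the Earth's
terrestrial area (default 13 Gha).

Land moves between pools through

* **natural fluxes** — regeneration of degraded land (r·D), natural
  disturbance of N (δ_N·N) and natural degradation of A (δ_A·A);
* **human-driven degradation** — d_N·H·N and d_A·exp(−N/N_th)·H·A, the
  latter accelerating once natural land falls below the
  ecosystem-service threshold N_th; and
* **perception-driven conversion** — fluxes of the form c·u·H·(source
  pool), where the perceived value u blends the supply–demand imbalance
  of a land type with a perception bias. With weights p_N = p_A = 0 the
  values reduce to pure supply–demand imbalances; at 1, decisions rest
  entirely on perceived value. All u are clamped at zero (no reverse
  conversion from negative demand).

The degraded-land equation is not integrated independently: the
implementation sets dD = −(dN + dA), which keeps conservation exact to
machine precision. Written out, this is equivalent to adding a −r·D
sink to the D balance so that regeneration has a source pool — without
it the three land equations would not sum to zero. For the same reason
the D→A conversion term uses the agricultural perception value
u_A(A, H) in both the A gain and the D loss.

Population follows a recruitment–mortality balance:

* recruitment b·exp(−β·η_N)·(1 − exp(−q_N·N − q_A·A)) — a base rate
  damped by the demographic transition (with natural-resource demand
  η_N as the affluence proxy) and collapsing if both land resources
  vanish;
* mortality m·exp(q·(η_N·H + η_A·H − E_N·N − ε_A(N)·A)) — rising
  exponentially with the gap between total per-capita demand and what
  the land supplies. Agricultural efficiency ε_A(N) = max(0, E_A −
  φ·(N_th − N)) falls linearly with the shortfall of natural land below
  the threshold; as written it exceeds E_A when N > N_th, and an
  opt-in `cap` flag saturates it at E_A for users who prefer a bounded
  efficiency (the default keeps the unbounded form).

## Baseline parameterization

The packaged `default.yaml` is built in two stages, reproduced by
`analysis/01_calibrate_baseline.py`:

1. **Land-side rates fixed by magnitude arguments.** The historical
   record constrains the land trajectories only coarsely (N ≈ 7.5 → 7.0
   Gha and A ≈ 1.36 → 1.56 Gha over 1960–2016, from forest + permanent
   meadow/pasture and arable + permanent-crop areas). Requiring the
   model's fluxes to reproduce those paths at the observed population
   fixes the conversion and degradation scales: c_AN = 6.5e-4,
   c_ND = 5e-4, c_AD = 2e-4, c_NA = 5e-5, d_N = 1.5e-4, d_A = 5e-4
   (per billion individuals per year), δ_N = 0.001, δ_A = 0.005,
   r = 0.001 (per year). Demands η_N = 1.0 and η_A = 1.2 Gha per
   billion people put the combined footprint at ≈ 2.2 ha per person;
   efficiencies E_N = 0.5, E_A = 1.2 make supply exceed demand in 1960
   and cross below it as N approaches N_th. N_th = 5.2 Gha is 40% of L.
   Perception weights default to the neutral midpoint p_N = p_A = 0.5.
   q_N = q_A = 2.0 /Gha keep the labour term ≈ 1 except near total land
   collapse. m = 0.010/yr is the adult crude death rate scale; β = 0.25
   gives a mild demographic transition.

2. **{b, q} calibrated by trajectory matching.** The recruitment rate b
   and the resource–mortality coupling q are the two parameters the
   population series actually identifies (q in particular cannot be
   measured independently). They are fit by bounded multi-start least
   squares on relative residuals against the 1960–2016 global
   population series (`data/history_world_1960_2016.csv`, a coarse
   public-statistics compilation), giving b = 0.039095/yr and
   q = 0.071602/Gha with a 0.3% RMS residual.

An earlier design that freed six land-side parameters against H and A
was rejected: those directions are unidentified by the data, and the
optimizer drifted to corners with physically impossible land histories
(N collapsing below 1 Gha by 2016). Identifiability, not fit quality,
dictated the two-parameter free set; `fit_parameters` supports any 1–8
free parameters (including the initial natural land, name `"N0"`) for
users with richer data.

Under this baseline the business-as-usual run peaks at 9.6 billion
around 2086, begins sustained decline with N at 5.0 Gha (≈ 39% of L),
and over 2016–2120 roughly doubles A (+93%) while N falls 32% and D
rises 12% (`analysis/02_bau_projection.py` prints the exact values).

## Numerics

* **Integration** uses adaptive Runge–Kutta 4(5) (`scipy.solve_ivp`,
  rtol 1e-8, atol 1e-10), sampled yearly by default. The max(0, ·)
  kinks in the perception and efficiency terms are continuous in the
  state, so no event location is needed. Inside the right-hand side,
  pools are clamped at zero for evaluation: every sink is proportional
  to its own pool, so the exact solution stays non-negative and tiny
  solver undershoots must not inject mass. Output states more negative
  than 100·(atol + rtol·L) abort with a diagnostic; smaller excursions
  are clipped. A fixed-step classical RK4 integrator
  (`integrate_rk4`) provides an independent cross-check; the two agree
  to ~1e-6 relative over the 160-year baseline run.
* **Peak detection** takes the first interior local maximum and refines
  it with a quadratic through the three bracketing samples; monotone
  series report the boundary extremum with `exists_interior_peak =
  False`. The post-peak decline is measured 50 years after the refined
  peak by linear interpolation.
* **Tipping onset** is operationalized as the first interior maximum of
  H followed by strictly decreasing samples for at least 5 years (the
  window adapts to the output step). The onset year agrees within one
  year when the trajectory is resampled at half the step.
* **Equilibria** are roots of the reduced (N, A, H) system with
  D = L − N − A eliminated, found by Powell's hybrid method from
  user-supplied starts, deduplicated within 1e-6·L, and labelled by
  the dominant eigenvalue of a finite-difference Jacobian (one-sided at
  domain boundaries; |Re λ| < 1e-8 counts as marginal). Out-of-domain
  probes are evaluated at the clipped state plus a continuous restoring
  term, so boundary equilibria (empty pools) remain reachable roots.
  Parameter planes report the state at a long fixed horizon (default
  1000 years) as the equilibrium proxy instead of a root, because some
  cells are still drifting at century scale; the two agree where the
  root finder converges.
* **Calibration** minimizes the weighted sum of squared *relative*
  residuals (H and A differ in scale) with trust-region-reflective
  least squares from a Latin-hypercube multi-start (deterministic per
  seed). Failed integrations map to a large finite penalty residual so
  optimizers never see an exception. Initial H and A come from the
  first observed row; initial N is a configuration input (60% of the
  non-agricultural remainder when nothing better is known) since it is
  not directly observed.

## The synthetic-data generator

`generate_observed` integrates a scenario with known parameters,
samples it at observation years, and applies independent multiplicative
lognormal noise per variable and year (x·exp(ε), ε ~ N(0, sd²)).
Multiplicative noise keeps observations positive and matches the
roughly constant relative accuracy of national statistics; the default
fixture uses 1% noise, annual 1960–2016 sampling and a fixed seed, and
ships its generating truth alongside. What the generator does **not**
emulate: autocorrelated revisions, reporting-definition changes, or any
structural mismatch between the model and the real world. Passing
recovery tests therefore demonstrate that the pipeline is self-
consistent and informative under the model's own assumptions — not that
the real historical series identifies the parameters. Recovery of d_N
at 2% noise is notably weak (its median bias across replicate sets
varies by several percent with the noise draw), which is the same
flat direction that motivated the two-parameter baseline fit.

## Study sizes and horizons

The baseline projection runs 1960–2160 (the extra 40 years make the
50-year post-peak decline measurable); land-cover changes are reported
over the 2016–2120 projection window. Perception planes use a
1000-year horizon; proactive/reactive grids use 160 years with corner
values d_N ∈ {1e-4, 1e-2} and c_ND ∈ {1e-4, 2e-3}; the recovery study
uses 20 replicates with three free parameters. The key-factor
divergence diagnostic flags the first year a swept trajectory departs
from the baseline by more than 5% in H — the threshold is a reporting
convention, not a model quantity.

## Known limitations

* Globally aggregated: no spatial structure, no trade, no regional
  heterogeneity in demands or land quality.
* No age structure; recruitment and mortality are population-wide
  rates, and technology (E_N, E_A) is static within a run.
* Deterministic: no demographic or environmental stochasticity in the
  core equations (noise enters only as observation error in the
  synthetic-data module).
* The baseline's projection-era behavior (peak size and timing, tipping
  area) inherits the uncertainty of the weakly identified land-side
  rates; the scenario analyses should be read as orderings and
  envelopes, not point forecasts.
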