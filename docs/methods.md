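# Methods

## Model definition

The simulator implements a continuous-time Markov jump process over a
population of compartments. A compartment is an integer vector
`(n_cis, n_medial, n_trans)` with total size `n ≥ 1`; a size-1 compartment
is a vesicle. All rates are expressed in units of the fusion rate constant
`K_f` between identical compartments, so time is measured in `1/K_f` and
three dimensionless parameters remain:

| parameter | meaning | default |
|---|---|---|
| `kb` | budding rate / fusion rate | 1 |
| `km` | conversion rate / fusion rate | 1 |
| `j`  | vesicle injection rate / fusion rate | derived from `n_target` |
| `n_target` | target mean total size (patches) | 300 |
| `alpha_er`, `alpha_tgn` | homotypic fraction of the ER / TGN boundary | 1 |
| `budding_mode` | `saturated` (`kb·n` per present identity) or `linear` (`kb·n_i`) | saturated |
| `inter_compartment_fusion` | pair-fusion toggle (boundary fusion always on) | on |

Event classes and rates:

* injection: rate `j`, creates a pure cis vesicle (the ER buds vesicles at
  a constant rate);
* pair fusion: rate `Σ_i φ_i(a)·φ_i(b)` for each unordered pair — the
  probability that two compartments present the same identity at the
  contact site; merged compartments add counts and cargo;
* boundary fusion: rate `α_ER·φ_cis(a)` (ER) and `α_TGN·φ_trans(a)` (TGN)
  per compartment; the compartment and its cargo leave the system;
* budding (compartments with `n ≥ 2` only): the emitted vesicle is pure —
  the budding machinery is assumed perfectly identity-specific. Saturated
  kinetics (`kb·n` for every identity present, independent of its
  abundance) describe budding factors that bind membrane non-specifically
  and find their partner patch by diffusion; linear kinetics (`kb·n_i`)
  are the mass-action alternative. A size-2 compartment may bud, leaving a
  vesicle behind;
* conversion: each cis patch → medial and each medial patch → trans at rate
  `km` per patch, irreversibly; trans is terminal. Free vesicles convert
  too, which at very high `kb` lets vesicles change identity between
  budding and fusion.

Cargo are passive, indistinguishable labels (stored as per-compartment
counts). On budding, each cargo in the donor joins the vesicle
independently with probability `1/n` (donor size before the bud); several
cargo may ride one vesicle. Cargo never modify propensities.

The injection rate is fixed at initialisation from the well-sorted
steady-state balance, `j = N(α_ER + km)α_TGN / (2α_TGN + km)`, and never
adjusted during a run.

## Exact simulation

The production engine is a Gillespie (direct-method) sampler in a
numba-compiled kernel. Class propensities are maintained in O(1) with
running sums (`S_i = Σ_a φ_i(a)`, `Q_i = Σ_a φ_i(a)²`, per-identity patch
totals, and budding weights); the total pair-fusion propensity is
`Σ_i (S_i² − Q_i)/2`. Given a class, the concrete compartment (or pair) is
chosen by an O(M) weighted scan; pairs are drawn per-identity with
rejection of self-pairs, which reproduces the pair law exactly. The running
sums are rebuilt from scratch at every observer interval, so floating-point
drift cannot accumulate beyond a few thousand events. A validation mode
rechecks patch and cargo conservation after every event.

Correctness is established against an independent pure-Python reference
that enumerates every addressable event at O(M²) cost
(`engine.total_propensity` / `engine.step`): on frozen states, 10⁴
single-event draws from the kernel must match the enumerated event-class
probabilities (chi-square) and waiting times must be exponential with the
enumerated total rate (Kolmogorov–Smirnov). Donor selection within a class
is tested the same way.

Randomness is a self-contained xoshiro256++ stream seeded from the run
seed via splitmix64 expansion; identical parameters + seed + observer
schedule give bit-identical trajectories in any process. (A pure splitmix64
stream is not used as the generator itself: its serial correlations produce
a small but systematic waiting-time bias under the event loop's
value-dependent draw consumption.)

Observers sample scalar series (sizes, counts, purity, cargo) every
Δt = 0.1 and full compartment tables every 1.0 time units by default; both
intervals are configurable. Event logs and cargo-transport logs are
streamed out of preallocated buffers.

## Mean-field companions

Two asymptotic closures accompany the simulator:

* **well-sorted limit** (`kb ≫ km`): per-species balance
  `dN_cis/dt = j − N_cis(α_ER + km)`, `dN_medial/dt = km(N_cis − N_medial)`,
  `dN_trans/dt = km·N_medial − α_TGN·N_trans`, solved in closed form at
  steady state and numerically (RK45, rtol 1e-8 — the system is linear and
  non-stiff) for de-novo growth; the typical compartment size per species
  is `N_species/(1 + kb)`;
* **maturation-dominated regime** (`kb ≪ 1`): a compartment born as a cis
  vesicle and growing from a symmetric vesicle pool has composition
  `φ(t) = (e^{−km t}, km·t·e^{−km t}, 1 − (1 + km·t)e^{−km t})`, whose
  medial component peaks at `km·t = 1` with value `1/e ≈ 0.368`.

Validity caveats, measured with the simulator itself: at `kb/km = 100`
(kb = 10, km = 0.1) the steady-state cis and trans totals agree with the
closure within statistical error, but the medial total sits ~3% below it —
a real leak the closure ignores, because medial patches ride exiting
mixed compartments (and medial vesicles fuse into cis-rich compartments
that then exit through the ER). Likewise the early de-novo growth of the
medial and trans species deviates from the ODEs while the system is still
sorting; the total size and the dominant cis species follow them closely.
These are limitations of the closure, not of the sampler.

The same caveat applies to the size-calibration formula: far from the
well-sorted limit (kb = 0.01, km = 1) the realised mean size sits ~9–13%
below the target N = 300 (injected cis vesicles can re-fuse with the ER
before joining a compartment), and the total size fluctuates with a
relative SD of ~0.40 (long-run estimate 0.407, autocorrelation time
≈ 1.2/K_f) because the system then consists of a few large, transient
compartments whose whole-compartment exits dominate the variance.

## Observables

* **typical size**: ⟨n²⟩/⟨n⟩ over all compartments, vesicles included
  (the size distribution starts at size 1); for a `n^{-3/2} e^{−n/n₀}`
  scission–aggregation law this is ≈ n₀/2.
* **system purity**: size-weighted mean of
  `P = sqrt(3/2·Σ(φ_i − 1/3)²)` over compartments with `n ≥ 2` — vesicles
  are excluded by definition since they are trivially pure. Undefined
  (NaN, with a warning) when only vesicles exist.
* **enrichment vector**: for every cargo-carrying budding → fusion episode
  the composition difference Δφ_i = φ_i(acceptor) − φ_i(donor) is recorded
  (donor composition at budding time, acceptor immediately before fusion,
  since conversion can change both in between). E is the cargo-weighted
  mean (a vesicle carrying two cargo counts twice; switchable to
  event-weighted), normalised so Σ|E_i| = 1. Back-fusion episodes
  (acceptor = original donor) are included by default — every
  budding/fusion event counts — and boundary exits are excluded by
  default; both are flags. Directionality: anterograde if `E_cis < 0 <
  E_trans`, retrograde if `E_trans < 0 < E_cis`, centripetal if medial is
  the only positive gain, otherwise mixed.
* **composition-simplex maps**: compartments are binned to the nearest
  center of a triangular barycentric grid (default 20 bins per edge; the
  brute-force nearest-center rule *is* the implementation, ties resolved
  to the lower flat index). Occupancy maps time-average total patch
  content and compartment count per bin; flux arrows point from a donor
  bin to the cargo-weighted mean acceptor composition, weighted by cargo
  flux, with back-fusion always excluded. Maps are exported as CSV;
  rendering is out of scope.
* **exit kinetics**: pulse-chase decay fitted as log(remaining) vs time by
  least squares over an ensemble of ≥ 20 seeded replicates (single-run
  curves are too noisy at pulse sizes of tens of cargo); returns the decay
  rate (units K_f) and R².

## Problem sizes and defaults

Study conditions follow the reference setup throughout: N = 300,
α_ER = α_TGN = 1, horizons t_max = 200 with burn-in 50 for steady-state
statistics, 5 seeds for size/purity estimates, 10 seeds for mean-field
comparisons, 20 replicates for pulse statistics. Pulse size for
directionality estimates is 300 cargo (one system size; a 50-cargo pulse
yields only a handful of transport events per run in the low-budding
regime, far too few for stable sign estimates). Phase-diagram sweeps
default to 9×9 log-spaced grids over `kb, km ∈ [10⁻², 10²]` with 3 seeds —
a desk-scale rendering of the full diagrams.

## What the tests do and do not show

All inputs are synthetic by construction (the model defines its own
universe; there is no external data format). Passing tests demonstrate
internal exactness of the sampler, agreement with closed forms in their
regimes of validity, and reproduction of the published regime phenomenology
(purity levels, fluctuation scale, directionality transition, exponential
exit kinetics). They do not calibrate the model against biological
measurements — mapping `kb, km` to a real organism's rates. Space,
cisternal stacking, membrane mechanics, tubular connections and
composition-dependent feedback on the rates are outside the model.
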