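# Methods

This note records the modelling assumptions, parameter choices and
numerical decisions behind the three engines, in the order a user meets
them.

## Grid-world ABM

**World.** A `height x width` grid (default 50 x 50) whose columns wrap
into a cylinder. Hunters take one uniformly random Moore step (8
directions) per tick and bounce off the top and bottom rows; prey enter
at a uniformly random top-row cell and march one row per tick toward
the absorbing bottom edge, so at inflow `F = 1` per species the
standing stock equilibrates near `F x height` animals of each kind.
Cells hold any number of occupants; "adjacent" always means Chebyshev
distance <= 1 under the wrapped-column metric, including co-occupancy.
Grid dimensions, hunter movement at the rim and the adjacency radius
are modelling choices of this package — the system being modelled pins
down only the absorbing bottom edge for prey.

**Tick order.** prey advance -> agent movement -> pair formation ->
capture resolution -> metabolism & mortality -> reproduction. Deaths
are resolved synchronously after the energy decay; each phase draws
only from its own named random stream (see *Reproducibility*).

**Encounters.** Unpaired agents with at least one unpaired neighbour
interact once per tick, processed in uniformly random order with
uniform tie-breaks. Stag+Stag form a hunting pair that thereafter moves
as a unit; Hare+Hare separate immediately; Stag+Hare form a "nuisance"
pair in which the stag member is locked in with no possible payoff —
unless communication is on, in which case the stag-hunter queries the
partner's intention and walks away, both agents forfeiting that tick's
pairing opportunity (the qualitative time cost of the query; no
explicit energy surcharge is modelled).

**Captures.** Hunting units — stag-hunter (SS) pairs and individual
hare-hunters, whether solo or trapped in a nuisance pair — act in
uniformly random order. An SS pair takes one stag from the union of its
members' neighbourhoods; both members are credited `r x 1.0` energy
units, capped at `E_max`. A hare-hunter takes one hare for 1.0 unit.
Captured prey vanish immediately; inflow continues at `F` regardless.
Solo stag-hunters never capture (a stag needs two committed hunters),
and a stag-hare pair ends exactly when its hare member catches a hare
or a member dies. SS partnerships persist across captures by default:
the game's rules state an end condition only for stag-hare pairs, and
dissolving SS pairs on every catch makes re-pairing diffusion-limited
at low density, starving sparse stag populations that demonstrably
persist under the persistent-pair reading.
`WorldConfig(ss_pairs_dissolve_on_capture=True)` restores the
resolve-on-catch behaviour assumed by the mean-field ODE model.

**Energy, death, reproduction.** Every agent starts at `E_s = 20`,
stores at most `E_max = 20`, and pays `E_r` per tick (the harshness
dial; the survey grid spans 0.02–0.12). An agent whose account drops
below `1e-9` units starves that tick — the epsilon absorbs float
rounding from repeated decay subtraction so that, e.g., a never-fed
agent at `E_r = 0.1` dies at exactly tick `ceil(E_s/E_r) = 200`; its
surviving partner decouples with its energy intact. Every agent whose
last reproduction lies `R = 1000` ticks back (birth counts) produces
one unpaired offspring of its own phenotype with energy `E_s` in a
neighbouring cell. Phenotypes never change within a lifetime.

**Survival sweeps.** A sweep cell `(E_r, ratio, communication)` runs
`runs` independent simulations; the survival probability of a phenotype
is the fraction of runs with at least one such agent alive at the
horizon. The full-scale protocol (11 harshness levels x 5 ratios x 2
modes x 100 runs x 50 000 ticks) is available as the `full` preset but
takes hours; the default `desk` preset (corner-and-centre grid
{0.02, 0.07, 0.12} x {1, 3, 5}, 20 runs, 5 000 ticks) reproduces the
qualitative structure — hare survival non-increasing in harshness,
communication never hurting stag-hunters, and a positive stag advantage
in the harshest cell at 5:1 — in a few minutes on one CPU, and is the
scale exercised by the test suite and acceptance script. Per-run seeds
are hashes of (master seed, cell indices, run index), so any cell can
be recomputed alone, in any order, with identical results.

## Pair-formation ODE model

Thirteen compartments: food `Fs`, `Fh`; free hunters `S+`, `S-`, `H+`,
`H-`; stag pairs `S2++`, `S2+-`, `S2--`; mixed pairs `B++`, `B+-`,
`B-+`, `B--` (stag member's status first). All processes are
mass-action: pairing at `k` (homotypic pairing carries the 1/2 symmetry
factor; hare-hunters do not pair together), food provision `F`,
departure `l3`, catching `ke`, reproduction at `1/R` per individual
(offspring well-fed, unpaired, of the parent's phenotype; a
reproduction event frees a paired parent), well-fed -> poorly-fed
transitions at `alpha*l1` (stag; `alpha < 1` encodes the stag's higher
nutritional value) and `l2` (hare), and poorly-fed death at `l1`/`l2`.
A pair's catch resolves it: an S2 pair yields two well-fed free
stag-hunters; a B pair's hare member emerges well-fed while the freed
stag member keeps its status.

Reference rates: `F = 10`, `R = 2`, `k = 0.6`, `alpha = 0.75`,
`l1 = 1.2`, `l2 = 1.05`, `l3 = 30`; initial state
`Fs = Fh = S+ = H+ = 10`, all else 0. `ke` is the swept harshness dial
(small = harsh); its default 0.63 is the worked-example value of twice
the critical threshold.

Because pairing changes neither a hare-hunter's feeding nor its
mortality, the total hare-hunter dynamics close on themselves, giving
the steady state `H_TOT = F/(l2(l2R-2)) - l3/ke` (when positive), the
extinction threshold `ke* = l3*l2*(l2R-2)/F = 0.315` at the reference
rates, and unbounded growth when `l2*R < 2`. The sign convention of the
closed form is fixed by requiring it to vanish exactly at `ke*`; the
test suite verifies it by bracketing the numeric extinction boundary.

**Numerics.** Integration uses `scipy.integrate.solve_ivp` with LSODA
(`rtol 1e-8`, `atol 1e-10` by default). Trajectories from non-negative
states are clipped at zero only within integrator error; a genuine
negative excursion raises. `steady_state` integrates in chunks
(default 50 time units) until the derivative infinity-norm falls below
`1e-8` or a horizon (default 500 time units) is reached, reporting the
residual either way. Near the extinction threshold the slow mode decays
at ~1e-3 per time unit, so threshold-bracketing computations use
horizons of 20 000–30 000 time units and a tighter residual tolerance;
totals count each member of a pair once (`S2` contributes 2 to
`S_TOT`, `B` contributes 1 to each total).

The derivative transcription is defended in the test suite by a second,
independently structured implementation (a reaction list of rate laws
and stoichiometries) compared at hundreds of random states and
parameter sets to 1e-10.

## Decision lab

`simulate_session` replays the avatar game: six trials per participant
with per-tick bar decay drawn from {0.02, 0.025, 0.03, 0.035, 0.04}
(shuffled; the sixth repeats a random rate), a 20-unit energy bar
starting full, a certain 1-unit reward for hare hunting versus 2 units
with probability 1/2 for stag (the 2:1 classic ratio; 100 calories in
the on-screen game = 1 unit here), starvation ending the trial. Trials
with decay <= 0.025 are "good times", >= 0.03 "hard times". Two rates
the on-screen game does not publish are free parameters here: capture
opportunities arrive at 0.03 per tick (so hard-times trials genuinely
drift toward starvation while good-times trials hold steady) and
switch-decision points at 0.06 per tick — chosen once so that a median
trial yields ~4 recorded switches, the order of magnitude of the
decisions-per-trial in the human dataset the game emulates. At a
decision point the policy hunts stag with probability
`sigmoid(beta0 + beta1*energy)`; a strategy change emits one record.

`generate_decisions` is the clean synthetic surface for the regression:
energies drawn from a stated distribution (default uniform on the bar),
direction Bernoulli with the same logistic law. Session data, by
contrast, yield *conditional* switch sequences (an avatar already
hunting stag cannot switch to stag), so fitted session slopes need not
equal the generating policy slope; parameter-recovery claims are made
on `generate_decisions` output only.

`fit_switch_logit` maximises the Bernoulli likelihood by
Newton/IRLS from a zero start, declaring separation when the linear
predictor escapes +-40 or the weights vanish; standard errors come from
the inverse observed information, the LR statistic is
`2*(ll - ll_null)` against the analytic intercept-only fit, CIs are
Wald intervals exponentiated to the odds-ratio scale, and
`Cox-Snell = 1 - exp(2(ll0-ll)/n)`, `Nagelkerke = CS / (1 - exp(2 ll0 / n))`.
Records are treated as independent (no participant-level clustering),
matching the headline analysis this module reproduces.

## Reproducibility

One master seed per run expands through `numpy` `SeedSequence` into
named PCG64 sub-streams (`prey`, `movement`, `pairing`, `capture`,
`reproduction`, `lab`), so subsystems can be tested in isolation and
identical (config, seed) pairs replay bit-identically, including output
files (only `manifest.json` carries a timestamp). The two
order-sensitive ABM phases consume pre-drawn uniforms inside numba
kernels, keeping results independent of compiler internals. The
optional event log records every birth, death, capture (with the
credited, cap-adjusted energy), pairing, dissolution and refused query;
`replay_energy_audit` re-derives every agent's energy from the log and
asserts bit-exact agreement, which the test suite runs on every audited
configuration.

## Limitations

The ABM omits spatial exclusion, prey flight, strategy mutation and any
N-player generalisation; harshness enters only through `E_r`. The ODE
model is well-mixed and maps to the ABM only qualitatively (`1/ke`
plays the role of `E_r`); no quantitative bridge between the two
harshness scales is attempted. The decision lab's capture and decision
rates are calibration choices, not measured quantities, and the
synthetic decision records are independent by construction — passing
recovery tests demonstrates correctness of the estimator, not
robustness to the clustering present in real per-participant data.
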