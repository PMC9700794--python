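# Methods

## Model and scope

The package analyses repeated binary-choice social-dilemma experiments in
which each participant's per-round record carries an action (cooperate C /
defect D), a response time (RT, seconds), and the decision context `c` —
the number of co-players who cooperated in the previous round. Three game
structures are supported: pairwise play (1 co-player), a Moore-lattice
game (8 neighbours) and a von Neumann-lattice game (4 neighbours), under
fixed or per-round-shuffled partner assignment. Lattices use periodic
boundaries so every node has exactly its nominal degree on a finite grid.

Two per-participant quantities are computed and then related:

1. the Relative Allocation angle RA°, a social-preference proxy, and
2. the drift-diffusion parameters (a, v, z, t0) of the decision process,

plus a derived rationality index R. The statistical layer reports
Spearman rank correlations of RA° with each parameter, per-treatment OLS
regressions with adjusted R², and two-sample Kolmogorov–Smirnov
comparisons between treatments.

## Relative Allocation angle

Payoff matrices (T, R, P, S) are min–max normalized over the four values,
which preserves their ordering and proportions and makes allocations
comparable across treatments with different stakes. For a decision with
action x in context c out of n co-players, the *planned allocation*
assumes the co-players repeat their previous action: c of them play C and
n−c play D. Then

- a_self = mean over the n pairwise games of the normalized payoff to the
  focal player,
- a_other = mean of the normalized payoff received by the co-players.

a_other is a mean, not a sum, so that ā_other shares the [0,1] scale of
ā_self and the 45° equality line means the same thing in every topology.
Averaging over the first 20 *scoreable* rounds (round 1 has no previous
round, hence no context, and never enters the score; at least 10 scoreable
rounds are required) gives (ā_self, ā_other), and RA° = atan2(ā_other,
ā_self) in degrees. atan2 maps ā_self = 0 to exactly 90°; the corner
(0, 0) — reachable only under the weak matrix whose P normalizes to 0 —
is reported undefined and flagged rather than imputed, because imputing
45° would contaminate the conditional-behaviour cluster.

Planned allocations are evaluated against *assumed-repeated* previous
actions rather than realized same-round actions: the context is the
information the participant actually holds when deciding, so the measure
reflects intention rather than outcome.

## Drift-diffusion model

Evidence accumulates as a Wiener process with drift v between absorbing
boundaries 0 (defect) and a (cooperate), starting at z·a, diffusion
coefficient fixed at 1 for identifiability; a non-decision time t0 adds
to the decision time. Inter-trial variability parameters (sv, sz, st)
are not modelled. Parameters, units and bounds used for fitting and as
uniform prior box:

| parameter | meaning | bounds |
|---|---|---|
| a | boundary separation (perceived difficulty), noise units | (0.3, 5) |
| v | drift rate (evidence-accumulation speed), signed toward C | (−5, 5) |
| z | relative starting point (a-priori bias; 0.5 = none) | (0.05, 0.95) |
| t0 | non-decision time, seconds | (0.05, min observed RT) |

**Likelihood.** The Wiener first-passage-time density at the lower
boundary is evaluated as exp(−v·a·w − v²·t/2)/a² · f0(t/a², w) with
w = z, where f0 is the zero-drift unit-boundary density computed by the
small-time image expansion or the large-time Fourier sine series —
whichever needs fewer terms for a truncation error of 1e−9 per point.
The upper-boundary density uses (v, w) → (−v, 1−z). Evaluation is done
in log space so extreme drifts and long times cannot overflow; times at
or below t0 get density 0.

Closed forms used as oracles and for the rationality index: the upper
absorption probability p = (1 − e^{−2vza})/(1 − e^{−2va}) (p = z at
v = 0), and the unconditional mean decision time a(p − z)/v
(a²z(1−z) at v = 0), which reduces to (a/2v)·tanh(av/2) at z = 0.5.

**Simulator.** Euler–Maruyama with step dt = 1e−3 s and a
Brownian-bridge within-step crossing check: after each step the
probability exp(−2·d_prev·d_new/dt) of having touched each boundary
inside the step is evaluated and Bernoulli-sampled. The bridge check
removes the O(√dt) boundary-overshoot bias of the bare Euler scheme,
which at dt = 1e−3 would bias mean decision times upward by several
percent at small a; with it, simulated choice shares and mean decision
times agree with the closed forms to within sampling error (< 2% on the
mean at n = 10⁴). If both boundary bridges fire in one step (rare), the
larger crossing probability wins. Walks not absorbed within 30 s are
flagged truncated; the generator re-draws them up to 5 times.

**Fitting.** Default is per-participant maximum likelihood: bounded
L-BFGS-B from four starting points (two moment-based heuristics — z and
v initialized from the observed cooperation share, t0 from 0.9·min RT —
plus seeded jitter), keeping the best optimum. Log densities are floored
at −690 per trial so the optimizer can recover from zero-density regions.
Degenerate inputs (fewer than 20 trials by default, all RTs identical, or
min RT at/below the 0.05 s non-decision floor) raise a fit error with a
diagnostic; the pipeline records such participants as unconverged rows
rather than dropping them. Only boundary separation is weakly identified
when drift is strong toward one boundary (the far boundary is almost
never reached, leaving a likelihood ridge in a); recovery errors
concentrate in that corner of the parameter space.

**Sampler.** An optional random-walk Metropolis sampler with uniform
priors on the box above mirrors the protocol of drawing 10,000 posterior
samples per chain and discarding the first 200; the point estimate is the
posterior mean, and convergence is gated by the Gelman–Rubin potential
scale reduction factor R̂ < 1.1 computed across chains (4 by default).
R̂ is the classic between/within-variance construction; on literally
identical chains it returns √((n−1)/n), i.e. 1 to within 1/2n.
Unconverged results are returned flagged, never silently used.

**Rationality.** R = |p − z| / (|p − z| + |z − 0.5|), with p the upper
absorption probability; R = 0 when the choice probability is fully
explained by the starting bias (v = 0), R = 1 when the bias is neutral
and drift does everything, and R = 0.5 by convention in the doubly
degenerate case v = 0, z = 0.5. This operationalization satisfies the
published endpoint semantics of the index; the original's exact formula
is defined in earlier work and may differ in the interior.

## Synthetic cohorts

Agents decide *by* the diffusion process — the absorbing boundary is the
action and the first-passage time (plus t0) is the RT — so choices and
RTs are jointly coherent, which real data are assumed to satisfy. Three
archetypes, with parameters drawn per agent from truncated normals inside
the fitting box:

| archetype | round-1 P(C) | drift | a | z |
|---|---|---|---|---|
| ALL_C | 0.9 | v ~ N(+1.5, 0.3²) | N(1.2, 0.2²) | N(0.55, 0.05²) |
| ALL_D | 0.1 | v ~ N(−1.5, 0.3²) | N(2.0, 0.3²) | N(0.45, 0.05²) |
| CONDITIONAL | 0.5 | g·(2f_C − 1), g ~ N(1.0, 0.2²) | N(1.6, 0.25²) | N(0.50, 0.05²) |

f_C = context/n_coplayers, so conditional agents drift toward what their
neighbourhood did last round and average near-zero drift over balanced
contexts. ALL_D carries the widest boundary, encoding the finding that
individualistic participants perceive the task as harder; non-decision
times are N(0.3, 0.05²) s for all types. Round-1 actions are drawn from
the archetype cooperation probability, with RTs taken from diffusion
trials rejection-matched to the drawn action (cap 20 attempts, then the
action is forced) so every record has a valid RT. Shuffled schemes
re-draw the pairwise matching, or the assignment of participants to
lattice nodes, every round from the cohort's seeded generator; all
generation is reproducible from a single integer seed.

Six ready-made configurations mirror the source experiments (pairwise
fixed n=58 / shuffled n=96 with the strong matrix (4,3,1,0); Moore
fixed/shuffled n=169 with the weak matrix (10,7,0,0); von Neumann
informed/uninformed with the strong matrix (6,5,1,0), sizes 50→49 and
59→64 rounded to perfect squares for the periodic lattice, noted in the
config). Mixtures are chosen to reproduce the qualitative RA° shapes:
pairwise-fixed concentrated near 45°, Moore treatments piling defectors
near 0°, von Neumann centred.

What the generator does *not* emulate: learning or strategy updating
across rounds, payment incentives, within-participant parameter drift,
and any dependence of t0 or a on round number. Passing tests therefore
show that the pipeline recovers structure that is present and
DDM-generated; they do not validate the DDM as a model of any specific
real cohort.

## Design choices and numerics

- The end-to-end sign-recovery check uses a *shuffled* pairwise cohort
  (n = 100, 40 scoreable decisions each, 30% ALL_C / 30% ALL_D / 40%
  CONDITIONAL). Under fixed pairing, conditional pairs lock into mutual
  cooperation or mutual defection, so a conditional agent's realized
  drift is ±g rather than the context-averaged ≈ 0 and the RA°–v̂ rank
  correlation is diluted; shuffling keeps contexts mixed, the regime
  where the strongest RA°–drift correlations are expected.
- Spearman p-values: exact permutation for n ≤ 10 (vectorised over all
  orderings of the ranks), t approximation above. KS p-values use the
  asymptotic Kolmogorov distribution; on a seeded null (1000 reps,
  n = 50) both tests reject at 3–5.5%, consistent with the nominal 5%
  (KS is conservative at this n because D is discrete). No
  multiple-testing correction is applied; all p-values are reported so
  users can correct post hoc.
- Density normalization (upper + lower mass = 1) holds to < 1e−6 by
  quadrature across the test grid; the acceptance checks use a 1e−3 band.
- Canonical record CSV: comma-separated, UTF-8 header row, RT in seconds
  with shortest round-tripping float representation, so
  load → write is byte-identical and seeded pipeline runs produce
  byte-identical outputs.
- Problem sizes used by the shipped checks: 27-point closed-form grid at
  10⁴ trials per point; 20 prior-box recovery draws at 2000 trials;
  pipeline cohort n = 100 × 41 rounds; calibration 1000 reps of n = 50;
  sampler checks at 4 × 1500 samples on 400 trials. The full test suite
  runs in ~2 minutes on one CPU.

## Known limitations

- No hierarchical (group-level) model: each participant is fitted
  independently, so estimates at ~20–40 trials per participant are
  noisier than a partially-pooled fit would give; rank correlations are
  attenuated accordingly.
- The rationality index is an endpoint-faithful fallback, not the
  original interior formula.
- Truncated-walk handling (classify by nearer boundary at 30 s) is a
  pragmatic tie-break; with the shipped parameter ranges truncation
  essentially never occurs.
- The Euler–Maruyama bridge simulator has O(dt) residual bias; halve dt
  for applications needing sub-0.1% moments.
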