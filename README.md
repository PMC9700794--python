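# socialdrift

Behavioural-game-theory experiments show that people differ widely in how
they allocate resources between themselves and others. `socialdrift` asks
whether those differences are visible in the *deliberation process* itself:
it links a social-preference proxy computed from iterated Prisoner's
Dilemma (IPD) play to the parameters of a drift-diffusion model (DDM)
fitted to each participant's choices and response times. It is intended
for researchers analysing repeated binary-choice experiments (pairwise
games or games on lattices) who record actions and reaction times.

## The two measures

**Relative Allocation angle (RA°).** Each decision, taken in context
`c` (the number of co-players that cooperated in the previous round),
implies a planned allocation of min–max-normalized payoff to self and to
the co-players, assuming co-players repeat their last action. Averaging
over the first 20 scoreable rounds gives a point (ā_self, ā_other), and

    RA° = arctan(ā_other / ā_self)

places each participant on a 0–90° scale: near 0° — defecting against
cooperators (individualistic); near 45° — conditional play with equal
allocation; near 90° — cooperating against defectors (unconditionally
cooperative).

**Drift-diffusion parameters.** Each choice is modelled as a Wiener
process with drift `v` (signed toward cooperation) between absorbing
boundaries at 0 (defect) and `a` (cooperate), starting at `z·a`, plus a
non-decision time `t0`. `a` measures perceived difficulty, `v` the speed
of evidence accumulation, `z` the a-priori bias. The likelihood is the
Wiener first-passage-time density; fitting is per-participant maximum
likelihood (or random-walk posterior sampling gated by the Gelman–Rubin
R̂ diagnostic). A rationality index `R ∈ [0,1]` summarises how much a
choice is driven by drift (deliberation) versus starting bias (intuition).

The package ships a synthetic-cohort generator whose agents *decide by
diffusion* (archetypes: unconditional cooperators, unconditional
defectors, and conditional reciprocators whose drift follows the context),
so the full pipeline — context derivation → RA° → DDM fits → rank
correlations, KS comparisons and regressions — runs end-to-end with known
ground truth and no external data.

## Worked example

```python
from socialdrift import (
    TreatmentSpec, PIPD_MATRIX, CohortConfig,
    generate_cohort, build_cohort_table,
)
from socialdrift.pipeline import analyze_cohort

spec = TreatmentSpec("DEMO", "pairwise", "shuffled", PIPD_MATRIX, n_rounds=25)
config = CohortConfig(
    treatment=spec,
    mixture={"ALL_C": 0.3, "ALL_D": 0.3, "CONDITIONAL": 0.4},
    n_participants=20, n_rounds=25, seed=3,
)
data = generate_cohort(config)                      # records + ground truth
table, excl = build_cohort_table(data.records, spec, seed=3)
corr, reg = analyze_cohort(table)
print(corr.to_string(index=False))
```

prints

```
treatment_id parameter       rho      p_value  n
        DEMO         a -0.393985 8.564648e-02 20
        DEMO         v  0.918797 1.082773e-08 20
        DEMO         z  0.681203 9.435725e-04 20
        DEMO         R  0.136842 5.650958e-01 20
```

Read: across the 20 synthetic participants, RA° correlates strongly and
positively with the fitted drift rate (ρ = 0.92 — cooperative agents
accumulate evidence toward cooperation, defectors toward defection),
positively with the starting bias, and negatively (here not significantly
at n = 20) with the decision threshold, since the defector archetype
carries the widest boundaries.

The same workflow is available from a shell:

```sh
socialdrift run --config config.yaml --out out/ --seed 3
```

which writes per-treatment record/ground-truth/cohort CSVs, correlation,
regression and KS-comparison tables, figures (allocation scatter, RA°
histogram, parameter-vs-RA° panels), and a run log. Subcommands
`simulate`, `fit`, `ra`, `analyze`, and `report` expose the individual
stages; see `socialdrift --help`.

A config file names one or more cohorts:

```yaml
cohorts:
  - treatment:
      treatment_id: DEMO
      topology: pairwise        # pairwise | moore | von_neumann
      partner_scheme: shuffled  # fixed | shuffled
      payoffs: {T: 4, R: 3, P: 1, S: 0}
      rounds: 25
    simulate:
      n_participants: 20
      n_rounds: 25
      mixture: {ALL_C: 0.3, ALL_D: 0.3, CONDITIONAL: 0.4}
fit:
  mode: mle                     # mle | sampler
```

`socialdrift.cohort.default_experiment_configs()` returns six ready-made
treatment configurations (pairwise fixed/shuffled, Moore-lattice
fixed/shuffled with a weak payoff matrix, von Neumann informed/uninformed)
matching the three experiments the analysis was designed around.
Real per-round records can be loaded through
`socialdrift.pipeline.load_external_records`, which maps a deposited CSV
schema onto the canonical one.

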