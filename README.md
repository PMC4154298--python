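# fatekinetics

Kinetic modelling of early mouse embryonic stem (ES) cell fate adoption.

When ES cells leave self-renewal they face a choice between an anterior
neural fate (neuroectoderm, NECT, reported experimentally by Sox1::GFP)
and a posterior primitive-streak fate (PS, reported by Brachyury/T::GFP)
that seeds endoderm and mesoderm. Flow-cytometry time courses show that
NECT is the primary outcome of neutral differentiation, while PS can win
only inside a transient competence window a couple of days after
differentiation starts — if a cell does not become PS in that window, it
becomes NECT. `fatekinetics` implements a minimal kinetic model of this
race and the analysis pipeline around it, for modellers and quantitative
stem-cell biologists who want to fit, simulate and stress-test such
fraction time-course data.

## The model

Four compartments — pluripotent $P$, differentiating/uncommitted $D$,
committed NECT $N$ and committed PS $M$ — with linear kinetics and no
death or division:

$$
\dot P = -\lambda_D P,\qquad
\dot D = \lambda_D P - (\lambda_N + \lambda_M)D,\qquad
\dot N = \lambda_N D,\qquad
\dot M = \lambda_M D .
$$

A population-level signal $s(t)$ builds up as cells lose pluripotency
(default law $s = 1 - P$). The PS rate $\lambda_M$ is piecewise
constant: $0$ in neutral medium (N2B27), and in PS-permissive medium
(AC: Activin 100 ng/ml + CHIR99021 3 µM) it is $\lambda_{M,\text{low}}$
(default $0$) until $s$ crosses the threshold $\theta$ and
$\lambda_{M,\text{high}} \gg \lambda_N$ afterwards. Because the system
is linear with piecewise-constant rates, the exact solution is built by
gluing closed-form constant-rate segments at protocol boundaries and at
the signal-crossing time $t^* = \ln\!\frac{1}{1-\theta} / \lambda_D$.

The package provides:

- `model` — exact piecewise solver plus an independent adaptive
  numerical oracle (`simulate_protocol` / `numeric_oracle`);
- `protocols` — condition registry, pulse-chase designs (single 1-day
  AC pulses on a 6-day N2B27 background), endpoint response tables and
  the NECT/PS fate correlation;
- `fitting` — two-stage least-squares estimation:
  $(\lambda_D, \lambda_N)$ from neutral time courses with
  $\lambda_M = 0$, then $(\lambda_{M,\text{high}}, \theta)$ from
  pulse-chase endpoints;
- `stochastic` — per-cell Markov simulation with exact exponential exit
  times, for mean-field validation and commitment-time records;
- `synthetic` — synthetic flow-cytometry datasets (binomial sampling +
  misclassification noise) and the calibrated default parameter set
  `paper_like_params()`;
- a `fatekinetics` CLI with subcommands `simulate`, `pulsechase`,
  `fit-neutral`, `fit-switch`, `synth`, `stochastic`.

## Worked example

```python
import fatekinetics as fk

params = fk.paper_like_params()          # lambda_D=0.9/d, lambda_N=0.5/d,
                                         # lambda_M_high=8/d, theta=0.8946
print(fk.crossing_time(params))          # 2.499991825416527  (days)

# 5 days of neutral medium: most cells end up NECT
traj = fk.simulate_protocol(fk.Protocol([(5.0, fk.N2B27)]), params,
                            output_grid=[5.0])
print(traj.n[-1])                        # 0.8291949987690306

# pulse-chase: 1-day AC pulses on days 0..5 of a 6-day N2B27 course
table = fk.pulse_response(fk.PulseChaseDesign(), params)
print(table.frame.round(3))
#    pulse_start_day  n_final  m_final  uncommitted_final
# 0              0.0    0.894    0.000              0.106
# 1              1.0    0.894    0.000              0.106
# 2              2.0    0.562    0.407              0.031
# 3              3.0    0.617    0.365              0.018
# 4              4.0    0.747    0.243              0.010
# 5              5.0    0.839    0.156              0.005
print(fk.fate_correlation(table))        # -0.9763178252237644
```

Pulses before the signal crossing (~2.5 days) produce no PS because the
threshold has not been reached; the day-2 pulse straddles the crossing
and yields the most PS (41%); later pulses find the uncommitted pool
already drained into NECT, so the yield declines and the NECT and PS
endpoint fractions are strongly anticorrelated — the model's "window of
opportunity" for the PS fate.

The same run from the shell:

```sh
fatekinetics pulsechase --out run1 --seed 1
cat run1/pulse_response.csv
```

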