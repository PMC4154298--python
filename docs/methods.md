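# Methods

## Model and assumptions

The population is partitioned into pluripotent ($P$), uncommitted
differentiating ($D$), NECT-committed ($N$) and PS-committed ($M$)
fractions with $P+D+N+M=1$. Transitions are first-order and
irreversible: $P \to D$ at $\lambda_D$, then a race $D \to N$ at
$\lambda_N$ versus $D \to M$ at an effective rate $\lambda_M$.
Commitment is absorbing, and death and division are assumed to balance
across compartments, so total mass is conserved. All times are in days
and rates per day.

The effective PS rate is gated twice: by the culture condition (zero
unless the medium is PS-permissive, i.e. supplies Activin/Wnt agonism)
and by a population-level signal $s(t)$ with threshold $\theta$. In
permissive media $\lambda_M = \lambda_{M,\text{low}}$ (default 0)
before the crossing and $\lambda_{M,\text{high}}$ after. The switch is
irreversible: once crossed, always crossed.

### Signal law

The signal "builds up as cells lose pluripotency". The default
(`instantaneous`) law identifies it with the non-pluripotent fraction,
$s(t) = 1 - P(t) = 1 - p_0 e^{-\lambda_D t}$, which is monotone,
bounded by 1, and gives the closed-form crossing time
$t^* = \ln(p_0/(1-\theta))/\lambda_D$ ($t^*=0$ if $\theta=0$;
$t^*=\infty$ if $\theta=1$ or $\lambda_D=0$). A `cumulative`
alternative, $s(t) = \int_0^t (1-P)\,du$, is available behind the
`signal_law` switch; it is unbounded and its crossing is found by
bracketed root-finding. The instantaneous law is the simplest monotone
choice consistent with the biology; nothing downstream depends on the
specific form beyond monotonicity.

Because $\lambda_D$ is condition-independent and the initial population
is taken fully pluripotent (configurable for sorted-subpopulation
scenarios), $P(t)$ — and hence $s(t)$ and $t^*$ — do not depend on the
protocol. The pulse condition therefore does not advance the signal
differently from the base medium.

### Exact piecewise solution

Within a piece of constant rates ($\Lambda = \lambda_N + \lambda_M$):

- $p(t) = p_0 e^{-\lambda_D t}$;
- $d(t) = d_0 e^{-\Lambda t} + \frac{\lambda_D p_0}{\Lambda-\lambda_D}
  \left(e^{-\lambda_D t} - e^{-\Lambda t}\right)$, with the confluent
  branch $d(t) = (d_0 + \lambda_D p_0 t)e^{-\Lambda t}$ used when
  $|\Lambda - \lambda_D| < 10^{-9}\max(\Lambda, \lambda_D, 1)$;
- $n$ and $m$ grow by $\lambda_N \int d$ and $\lambda_M \int d$, with
  the integral in closed form in both branches (and in the separate
  $\Lambda = 0$ and $\lambda_D = 0$ limits, which are handled without
  0/0 expressions).

A full trajectory glues these solutions at the protocol segment
boundaries and at $t^*$, with state continuity at every joint. Segments
are half-open $[t_0, t_1)$; a grid time exactly at a joint reports the
regime of the piece that starts there, and the protocol end reports the
final piece.

### Numerical oracle

`numeric_oracle` solves the same piecewise system with an adaptive
high-order Runge–Kutta scheme (DOP853, rtol $10^{-9}$, atol
$10^{-12}$), locating the crossing by bisection on the signal to
$10^{-10}$ days instead of using the closed form. It exists purely as
an independent check; the test suite and acceptance script require
agreement with the analytic solver to better than $10^{-6}$ in every
state component over randomized parameters, protocols and degenerate
$\Lambda \approx \lambda_D$ draws.

## Fitting

The objective is unweighted SSE on the fraction scale (binomial
variance weighting is available via `FitOptions(weighting="binomial")`).
Observables map as NECT reporter $\to n$, PS reporter $\to m$,
pluripotency reporter $\to p$; the neutral fit accepts either or both
of the NECT/pluripotency reporters.

Optimisation is bounded multi-start nonlinear least squares
(trust-region reflective), 20 starts drawn log-uniformly from the
bounds — rates in $[10^{-4}, 10]$ per day, $\theta \in [0.01, 0.99]$ —
best loss wins, ties broken by first found. Convergence tolerances:
loss change $<10^{-10}$ or step $<10^{-8}$. Identical
(dataset, options, seed) triples give identical results.

Stage 1 (`fit_neutral`) requires non-PS-permissive protocols, at least
two distinct time points, and fixes $\lambda_M \equiv 0$. Stage 2
(`fit_switch`) fixes $(\lambda_D, \lambda_N)$, holds
$\lambda_{M,\text{low}} = 0$, and flags whether the recovered
$\lambda_{M,\text{high}}$ exceeds $\lambda_N$ (the switch-regime
consistency check). Pulse-chase data in which every PS fraction is zero
leave $\theta$ unconstrained and raise an identifiability error.

## Stochastic counterpart

Cells are independent Markov chains advanced in fixed steps of at most
0.05 day, aligned to protocol segment boundaries. Per step, a
pluripotent cell exits with probability $1-e^{-\lambda_D h}$; on exit,
the exit time is drawn exactly from the exponential law conditioned on
the step, so the marginal exit-time distribution is exactly
exponential (no grid discretization artefact). An uncommitted cell
resolves one categorical draw with
$p_X = \frac{\lambda_X}{\Lambda}(1-e^{-\Lambda h})$ for $X \in \{N,M\}$.
Cells that exit within a step become eligible to commit from the next
step on, and commitment times are recorded at step end — both are
$O(h)$ approximations, negligible at the default $h = 0.02$ day.

The signal is computed from the *realized* pluripotent fraction by
default (self-consistent population coupling); a `deterministic`
variant uses the closed-form signal. The dt cap keeps single-step
transition probabilities below ~0.4 at the supported rate bounds.

## Synthetic data

Each measurement is one binomial draw of `n_sampled` cells (default
10,000, typical of flow-cytometry acquisitions) with success
probability $q = f(1-\epsilon_{fn}) + (1-f)\epsilon_{fp}$ (default
$\epsilon = 0.01$ each way). `n_sampled=None` disables sampling and
records the model fractions exactly. Generated datasets embed the
generating truth, noise settings and seed in their metadata and are
byte-reproducible given the seed.

What the generator does *not* emulate: instrument drift, day-to-day
culture variability, reporter maturation delays, fluorescence-intensity
distributions and gating, or a persistently pluripotent subpopulation
under PS-permissive media. Passing recovery tests therefore demonstrate
correctness of the estimation machinery under the model's own
statistical assumptions, not robustness to real-world systematics.

## Calibrated defaults

The fitted rate values for this system are not publicly tabulated, so
`paper_like_params()` is calibrated, not transcribed. A coarse grid
search over $(\lambda_D, \lambda_N, \lambda_{M,\text{high}}, \theta)$
selected the simplest round values satisfying four constraints at once:
NECT fraction after 5 days of N2B27 in $[0.70, 0.90]$; signal crossing
between days 2 and 3; $\lambda_{M,\text{high}} \ge 10\lambda_N$; and a
PS pulse response peaking on pulse day 2 or 3 and declining thereafter.
The frozen defaults are $\lambda_D = 0.9$, $\lambda_N = 0.5$,
$\lambda_{M,\text{low}} = 0$, $\lambda_{M,\text{high}} = 8$ per day and
$\theta = 0.8946$ (crossing at 2.50 days), giving a day-5 NECT fraction
of 0.829 and a peak PS yield at pulse day 2.

A consequence worth noting: with $\theta = 0$ the pulse response is
*not* monotonically declining in pulse day — the uncommitted pool $d$
must first build up from $P$, so the yield is unimodal, peaking where
$d$ peaks ($t = \ln(\lambda_D/\Lambda)/(\lambda_D-\Lambda)$) and
declining only afterwards. The monotone decline seen for late pulses is
the NECT-absorption effect.

## Problem sizes and numerical choices

Randomized solver cross-validation uses 200 instances; recovery studies
use 6 daily time points, 20 noise seeds at 10,000 cells per
measurement; stochastic validation uses 10,000 cells at $h = 0.02$ day
over 6 days. Mass conservation is asserted to $10^{-9}$; the exact
closed forms conserve to machine precision in practice. State
validation tolerates fractions in $[-10^{-9}, 1+10^{-9}]$ to absorb
floating-point residue at glue points.

## Known limitations

No spatial structure, cell–cell heterogeneity in signalling, division,
death or reversible commitment; $\lambda_D$ and $\lambda_N$ are global
(condition effects enter only through the $\lambda_M$ gate); media are
constant within segments (daily medium replacement is idealised away);
the signal law is a documented reconstruction, not a measured quantity.
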