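# Methods

## The model

`epifate` simulates a homeostatic epithelial sheet as a fully occupied
periodic square lattice of `N = L**2` cells, each of type A (self-renewing,
spin `c_i = +1`) or type B (licensed/committed to differentiation,
`c_i = -1`). Two event classes drive the dynamics, both constrained by
crowding control (a cell divides only into space freed by the loss of a
neighbour, so the sheet never develops vacancies):

* **Division-coupled replacement** (rate λ): an adjacent (A, B) pair is
  replaced by (A, A) with probability `p_A` or by (B, B) with probability
  `p_B = 1 - p_A` — the B cell is extruded and both daughters of the
  dividing cell adopt a common fate. Same-type pairs cannot divide
  (asymmetric divisions leave the configuration unchanged and are not
  represented).
* **Division-independent fate switch** (rate ω): a single cell redraws its
  type, becoming A with probability `p_A` evaluated on its own
  neighbourhood. Because `p_A + p_B = 1`, drawing the new type afresh
  (memoryless) is equivalent to the A→B / B→A event-rate formulation.

Juxtacrine signalling enters through `p_A(n)`, a function of the neighbour
field `n = n_A - n_B` (excess of type-A neighbours). Two sigmoidal forms
are available, both odd around `p_A(0) = 1/2` so that A/B competition is
neutral, as homeostasis requires:

* logistic: `p_A(n) = (1 + tanh(J n)) / 2`
* Hill:     `p_A(n) = (1 + J n / (1 + |J n|)) / 2`

`J > 0` is lateral induction, `J < 0` lateral inhibition, `J = 0` no
interaction. The logistic form is exactly the heat-bath (Glauber)
acceptance probability of a 2D Ising model with coupling `J`.

Two biological hypotheses are encoded as parameter choices:

* **Variant C** (fate committed at division): ω = 0, so `q = λ/(λ+ω) = 1`;
  the interaction governs division outcomes, evaluated on the six exterior
  neighbours of the dividing pair. Uniform lattices are absorbing.
* **Variant R** (reversible, division-independent fate): division outcomes
  are unbiased (`p_A^div = 1/2`) and the interaction governs fate switches,
  evaluated on the four neighbours of the switching site. For `q < 1`
  nothing is absorbing.

Rates are normalized to `λ + ω = 1`, so `q` is the only rate parameter and
one Monte Carlo step (MCS) is one time unit; absolute rates would only
rescale time.

## Update algorithm

The continuous-time Markov process is realized by random sequential update:
one MCS performs `N` elementary updates, each drawing a site `i` uniformly,
a neighbour `j` uniformly among the four von Neumann neighbours (periodic
boundaries), a branch uniform (division attempt with probability `q`, fate
switch otherwise), and an outcome uniform. Both uniforms are consumed even
for blocked updates, so a trajectory is a pure function of (initial grid,
parameters, seed); the compiled multi-step kernel and the single-update
Python path replay the same `numpy.random.Generator` stream bit-exactly.

Design points worth stating:

* The division branch updates **both** members of the pair in one event.
  A given site can be hit either as `i` or as `j`, which realizes the
  factor 2 in the per-site rate
  `γ_A(n) = f_A · 2λ · p_A^div + ω · p_A^switch`, with `f_A = (n+4)/8`
  the probability that a random neighbour is type A. The rate-oracle tests
  exploit this exactly: `N ×` (probability that a tagged site on a frozen
  grid ends `+1` after one uniformly random elementary update) `= γ_A(n)`.
* The simulator's division outcome uses the six-site pair field; the MSUM
  theory below uses the four-neighbour approximation. These intentionally
  differ; a forced-pair test verifies the six-site path directly.
* Early exit on a uniform grid is an optimization valid only when uniform
  grids are absorbing (variant C, or variant R at q = 1); it is off by
  default and rejected otherwise.
* Observables are computed on the final configuration only (endpoint
  protocol); optional time series sampling at a stride is additional.

## Observables

`phi = |N_A - N_B| / N` detects macroscopic single-type patches;
`phi~` is `phi` of the staggered lattice `c~_i = (-1)^(k_i+l_i) c_i` and
detects macroscopic checkerboard order. Both are in [0, 1]; for an i.i.d.
fair-coin grid `E[phi] = E|2K - N|/N` with `K ~ Binomial(N, 1/2)`,
approximately `sqrt(2/(π N))`, which the neutral reversible model
(`q = 0, J = 0`) must and does reproduce. Even `L` is required throughout
so the checkerboard mask is consistent across the periodic seam.

## MSUM mapping

A memoryless spin-update model (MSUM) updates a random site to `+1` with a
probability `p_+(n)` independent of the site's prior state, with
`p_+(-n) = 1 - p_+(n)`; it is characterized by `(p1, p2) = (p_+(2), p_+(4))`,
and the `(p1, p2)` plane has an Ising-universality order/disorder transition
except at the voter point `(3/4, 1)`.

* Variant R maps exactly per MCS: `p_+(n) = q (n+4)/8 + (1-q) p_A(n)`,
  so `p1 = 3q/4 + (1-q) p_A(2)` and `p2 = q + (1-q) p_A(4)`.
* Variant C maps in steady state (four-neighbour approximation):
  `p_+(n) = (n+4) p_A(n) / [(n+4) p_A(n) + (4-n) p_A(-n)]`, which pins
  `p2 = 1` for every `J` and both forms and puts `J = 0` exactly on the
  voter point — hence variant C at `J = 0` coarsens to consensus
  (`phi = 1`) on any finite lattice.
* Staggered order: symmetric divisions inside a checkerboard region act on
  the staggered lattice as forced flips against a fully aligned
  neighbourhood, shifting `(p1, p2) → (p1, p2 - q)`; a shifted `p2 < 0` is
  reported as invalid rather than clamped.
* At `q = 0` with the logistic form, `p_+(n)` is the 2D Ising heat-bath
  rule, so the order/disorder transition of the simulation must bracket the
  exact critical coupling `J_c = ln(1+sqrt(2))/2 ≈ 0.4407`. The phase
  transition *line* elsewhere in the plane has no closed form and is not
  computed.

## Experiments and problem sizes

`run_sweep` runs `R` independent replicates per `(J, q, L)` point
(replicate `r` seeds its own generator with `base_seed + r`; the same
derived seeds are reused across points, i.e. common random numbers, which
reduces the variance of differences along a parameter axis) and reports
mean and SEM (`sd/sqrt(R)`, unbiased variance) of the endpoint `phi` and
`phi~`. `run_scaling` uses runtimes of `L**2/2` MCS so equilibration grows
with the system.

The reference protocol is `L = 80`, `R = 80`, 4000 MCS per run. The
package's default desk-scale protocol is `L = 40`, `R = 20`, 800 MCS
(scaling checks use `L ∈ {10, 20}` at `L**2/2` MCS), which resolves the
same qualitative phase behaviour in tens of seconds on one CPU; all
statistical acceptance checks are phrased in pooled-SEM units or as
calibrated inequality thresholds, never as exact values, because the
underlying quantities are stochastic order parameters.

## What the simulations do and do not show

The generator of study conditions is the model itself (random 50/50 initial
lattices and the parameter grids above); there is no external data. The
square lattice with fourfold symmetry, fixed cell positions, and
nearest-neighbour-only signalling are idealizations: real epithelia have
irregular (roughly hexagonal) cell packings where exact checkerboards are
impossible, cells can intercalate, and signalling may reach beyond direct
contacts via protrusions or diffusible ligands. Passing tests therefore
validate the phase structure of the idealized model — patch order,
checkerboard order, their thresholds in `(J, q)`, and the spin-model
correspondences — not quantitative predictions for tissue. Critical values
(`J_c`, `J~_c`, `q_c`) are bracketed qualitatively, not estimated; no
finite-size-scaling collapse or critical exponents are attempted.

## Numerical choices

* Spins are int8; the inner loop is numba-compiled and consumes exactly
  four RNG draws per elementary update (site, neighbour, branch, outcome).
* `tanh`-based probabilities saturate safely for arbitrarily large `|J|`;
  `J` is never clamped.
* `p_B` is never stored — always `1 - p_A` — making the neutrality
  symmetry unviolable by construction.
* Ties/degenerate inputs: `L` must be even and ≥ 2; odd neighbour fields
  are rejected where the theory requires even ones; an empty replicate list
  cannot be summarized, and a single replicate reports SEM as missing.
* Absorption runs cap at 1e6 MCS and fail loudly rather than return an
  unabsorbed grid as if converged.
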