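# Methods

## Model structure

The population is structured by plasmid copy number `z ∈ {0, …, ẑ}` and
evolves linearly (no density dependence): the model describes per-capita
rates, so all long-term statements are about exponential growth rates and
compositions, not absolute numbers. The plasmid-bearing block
(`z = 1..ẑ`) is closed under the dynamics except for the flux of
plasmid-free daughters, which is collected in the vector `B` rather than in
the generator `A`; the plasmid-free class `x₀` is a scalar equation driven
by `Bᵀy`. This split mirrors the biology — a cell that loses its last
plasmid can never regain one without horizontal transfer, which is outside
the scope of this package.

Assembly of `A` combines three terms per column `z₀`: logistic replication
(loss `−b·z₀(1−z₀/ẑ)` on the diagonal, gain on the subdiagonal), division
loss `−β(z₀)`, and division inflow `k(z; z₀)·β(z₀)` into every row
`z ≤ z₀`. Because the kernel has total mass 2 and the replication terms
telescope, every column satisfies `column_sum(A) + B = β` exactly — each
division removes one cell and adds two. The test suite asserts this
identity to machine precision, and the generator is additionally pinned
against a hand-assembled three-state matrix.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| `ẑ` | plasmid carrying capacity per cell | 50 | plasmids |
| `b` | logistic plasmid replication parameter | 1.2 | 1/h |
| `β₀` | maximal cell division rate | 1 | 1/h |
| `μ₀` | death rate of unprotected cells under antibiotics | 5 | 1/h |
| `c` | burden scale in `β(z) = β₀(1 − c·z/ẑ)₊` | 1 | — |

Time is measured in units of the plasmid-free division time (`β₀ = 1/h`
without loss of generality); the ESSS depends only on `b/β₀`, `ẑ` and `c`.
The linear burden with `c = 1` makes division stop exactly at the carrying
capacity and costs `100·c/ẑ` percent of the division rate per plasmid (2%
at `ẑ = 50`). The positive-part clamp keeps `β ≥ 0` for any `c`. `c`
multiplies only the division-rate burden, not the plasmid replication term:
it is meant as a knob on the metabolic cost of carrying plasmids, while the
replication cap is a property of copy-number control.

## Spectral computations

`ẑ` is at most a few hundred, so the dominant eigenpair of `A` is computed
by a dense `scipy.linalg.eig` with left and right eigenvectors; the right
eigenvector is normalised to sum 1 (a distribution over copy numbers) and
the left one scaled so `wᵀv = 1`. An independent power-iteration oracle
(on the non-negative shift `A + sI`) cross-checks the eigenvalue in the
tests. With full burden the top state `z = ẑ` neither divides nor
replicates, so its column of `A` vanishes and `A` is reducible; the
dominant eigenvalue of the remaining dynamics is still simple and positive
for the parameter ranges used here, and the eigenvector remains strictly
positive because the top state is fed from below.

A useful exact identity follows from the column sums:
`λ₁ = Σ_z (β(z) − B_z)·ŷ_z` — growth equals the mean division rate minus
the plasmid-loss flux under the stationary composition. One consequence
worth flagging: even with no burden (`c = 0`) the growth rate stays
strictly below `β₀`, because single-plasmid mothers hand one daughter to
the plasmid-free class with certainty (`B₁ = β(1)`), and the stationary
distribution keeps mass at `z = 1` whenever divisions outpace replication
at low copy number. The suite asserts the identity rather than the naive
`λ₁ = β₀` limit.

Forward integration of the switching-environment system uses exact matrix
exponentials segment by segment (the environment is piecewise constant),
which sidesteps stiffness entirely and reproduces `λ₁` from trajectory
slopes to ~1e-14.

## ESSS optimisation

The optimiser follows the steepest-ascent flow `dp/ds = ∇λ₁(p)` by a
projected Euler scheme with a backtracking step (only improving steps are
accepted, so `λ₁` is monotone along the trajectory), projection onto
`[0, 0.5]^ẑ` and a convergence test on the sup-norm of the projected
gradient (default 1e-6). The gradient of the simple eigenvalue is
`∂λ₁/∂p_{z₀} = wᵀ(∂A/∂p_{z₀})v / (wᵀv)`, where `∂A/∂p_{z₀}` touches only
column `z₀` through the derivative of the binomial kernel, computed with
the exact shift identity `∂g(z;n,p)/∂p = n·(g(z−1;n−1,p) − g(z;n−1,p))`
(well defined at the box corners). A central finite-difference route is
kept as a cross-check; the two agree to ~1e-9 at interior points.

Two trait coordinates are structurally unidentifiable and are frozen at
0.5 and excluded from convergence norms, agreement checks and feature
extraction: `z = 1` (the kernel of a single-plasmid mother is `(1, 1)`
regardless of `p`) and any `z` with `β(z) = 0` (that mother never
divides; `z = ẑ` at full burden).

Because the kernel is even in each `p_z` about 0.5, `λ₁` is too, so the
uniform-0.5 strategy is always a stationary point — a saddle whenever
high-copy asymmetry pays. Stationary points are therefore probed before
convergence is declared: each identifiable coordinate is displaced by
±0.01 (plus a batch of random full-vector probes), and the ascent restarts
from any improving point. Coordinate probes are essential here: random
full-vector perturbations almost never improve `λ₁` at the saddle because
second-order losses on the many plateau coordinates dominate the gains of
the few tail coordinates. The local-maximum verifier uses the same
coordinate-plus-random probing, which is also what makes it correctly
reject the uniform-0.5 point.

Multi-start uses uniform 0.5, uniform 0.25 and seeded uniform-random
initials and reports how many runs agree with the best within 0.02
sup-norm over identifiable coordinates. At the default parameters all
starts converge to the same optimum (sup-norm differences below 1e-5 at
tolerance 1e-8).

### The shape of the optimum, and a flat tail

At the defaults the optimum keeps `p_z = 1/2` up to `z ≈ 28`, departs from
equality at `z = 29` (deviation band 0.05) and declines monotonically to
`min p_z ≈ 0.156` at `z = 49`. The objective is extremely flat in the
tail: clamping the optimised tail at 0.2 costs only ~3e-5 in `λ₁`
(0.5459168 vs 0.5458886). Loosely converged ascents therefore stall with a
tail near 0.2 rather than 0.156; the package reports the fully converged
optimum, verified by per-coordinate scans, and treats "roughly an 80/20
split" as the coarse summary of this regime rather than as the precise
minimiser. The onset and plateau are insensitive to this flatness.

## Two-generation model

The conceptual module treats copy numbers as continuous and one division
cycle as deterministic: division after `T(z₀) = 1/(β₀(1 − z₀/ẑ))`, load
growth by the logistic solution, end-of-cycle load
`F(z₀) = z₀ẑ/(z₀ + (ẑ−z₀)e^{−(b/β₀)/(1−z₀/ẑ)})`. The implementation uses
this closed form and pins it against direct ODE integration to 1e-8 — the
oracle also fixes the intended reading of the formula, which is easy to
mistype. Concavity of `F` makes the second-generation average fitness
increase with the asymmetry `a`, while weighting first-generation fitness
by the concave protection factor `q(z) = z/(K+z)` makes it decrease in
`a`; the package verifies both monotonicity claims numerically on
parameter grids rather than symbolically.

## Lineage simulator

The stochastic realisation is exact and event-driven: each cell carries
competing exponential clocks for replication, division and death, with the
environment piecewise constant (simulation windows never straddle a
schedule segment). At division the selected daughter draws
`Binomial(z, p_z)`; the records keep the selected daughter identified
(analyses that must be label-blind — share histograms, rank plots — use
ordered pairs instead). Population growth would be exponential, so when
the live population exceeds `max_cells` it is uniformly subsampled and a
scalar weight accumulates the removed factor; weighted censuses estimate
the unbounded population, and growth rates are read off their log-slope.
By default plasmid-free daughters are recorded but not followed, making
the census directly comparable to `ŷ`.

The fluorescence proxy is deliberately simple — `f = gain·z` plus additive
Gaussian noise truncated at zero. It emulates the monotone reporter
relationship that justifies using fluorescence as a copy-number surrogate,
but none of the real nuisances: maturation delays, cell-size dependence,
bleaching, segregation of the reporter protein itself. Passing the
pipeline tests therefore shows that the *procedures* (stratified share
histograms, rank plots, strategy re-estimation) recover what they should
from data generated by the model's own assumptions; it does not validate
those assumptions against microscopy.

Share histograms include both `f₁/(f₁+f₂)` and `f₂/(f₁+f₂)` per division,
so they are symmetric about 0.5 by construction; shares falling exactly on
an interior bin edge are split half-and-half between the adjacent bins so
the symmetry is bin-exact even for noiseless integer data. Mother strata
are by default bins of fluorescence relative to the observed maximum; an
empirical-quantile mode is provided as well, since for skewed copy-number
distributions the two stratifications differ substantially. Strategy
re-estimation pools all plasmid draws per mother copy number
(`p̂_z = Σd₁/Σz`, Clopper-Pearson intervals via the beta quantiles) and
reflects estimates into the canonical band `[0, 0.5]`.

## Problem sizes and numerical settings

The shipped tests run the full optimisation at `ẑ = 50` (three starts,
tolerance 1e-8, a few hundred eigen-decompositions of a 50×50 matrix),
exhaustive grid-search oracles at `ẑ ∈ {2, 3}` with resolution 0.025,
stochastic runs of ~10⁴ cells over ~20 h of simulated time (~10⁵
divisions), and forward integration to 200 h. These sizes make every
statistical assertion comfortably resolvable (e.g. total-variation
distance between a 10⁴-cell census and `ŷ` has sampling noise ~0.03
against a bound of 0.1) while keeping the whole suite under a minute.
Degenerate inputs are defined rather than rejected where a sensible limit
exists: `ẑ = 1` yields `A = [[0]]`, `F(ẑ) = ẑ`, `division_time(ẑ)`
raises.

## Known limitations

* Deterministic/linear theory only: no finite-population extinction
  probabilities, no demographic stochasticity in the persistence verdicts.
* No horizontal plasmid transfer, spatial structure, or explicit
  antibiotic pharmacokinetics; the environment is a given binary schedule.
* The ESSS is a local maximum certified by probing and multi-start
  agreement; global optimality over `[0, 0.5]^ẑ` is not (and cannot be)
  certified for large `ẑ`.
* The simulator's fluorescence model is a validation harness, not an
  instrument model (see above).
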