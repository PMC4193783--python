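# Methods

## Model

`pottsort` implements a two-dimensional Cellular Potts Model (CPM) of
tissue patterning by cell sorting. The tissue is a bounded lattice whose
interior sites each carry a cell identity σ(x) ∈ {1..N}; a one-site
boundary ring is inaccessible to cells (reflecting wall). Each cell has a
fixed type τ ∈ {1..n_t} (n_t = 4). The Hamiltonian is

    H = Σ_<x,x'> J(τ(σ(x)), τ(σ(x'))) · (1 − δ_{σ(x),σ(x')})
      + λ Σ_i (a_i − A)²
      − Σ_x μ(τ(σ(x))) · C(x)

with the three terms:

* **Contact (surface) energy.** Neighbor pairs are counted once over the
  4-connected graph; contacts inside a cell cost nothing (Kronecker
  delta). Differential adhesion enters through the type-pair matrix:
  in *graded* mode J(τ,τ') = J_same + j·|τ−τ'| (types that end up farther
  apart after sorting dislike each other more), in *uniform* mode every
  unlike pair costs J_same + j. Contact with the boundary ring costs
  J_bnd.
* **Area constraint.** Quadratic penalty about the target area A,
  identical for all types.
* **Chemotaxis.** Each site contributes −μ(τ)·C(x), so positive-μ types
  lower their energy by occupying high-concentration sites (attraction
  toward the source) and negative-μ types are repelled. This is the
  conservative (Hamiltonian) form of CPM chemotaxis: the energy change of
  a copy is exactly the difference of H, which the test suite verifies by
  path-independence. The bipolar potential vector is
  μ = μ₀·(−2, −1, +1, +2); attract-only and repel-only variants
  (μ₀·(1..4) and μ₀·(−4..−1)) keep the strictly increasing order so the
  sorted arrangement away from the source is always 1|2|3|4.

Dynamics are Metropolis Monte Carlo: pick a uniform random interior site
and a uniform random 4-neighbor, propose copying the neighbor's identity,
accept if ΔH ≤ 0 and with probability exp(−ΔH/T) otherwise. One Monte
Carlo step (MCS) is as many attempts as interior sites. Copies from the
boundary ring are rejected, as are flips that would annihilate a cell
(cells persist; the metrics assume a fixed census). Cells may fragment
transiently; no connectivity constraint is imposed.

## Parameters

| parameter | value | units | origin |
|---|---|---|---|
| grid | 142 × 37 (interior 140 × 35) | sites | 100 cells of 7×7; source column at x = 142 |
| large variant | 212 × 51 (210 cells) | sites | grid-size control |
| A (target area) | 49 | sites | fixed |
| λ | 0.2 | energy/site² | fixed |
| T | 1 | energy | fixed |
| J_same, J_bnd | 1, 1 | energy/contact | reference scale, config-exposed |
| j | 0–4 | energy/contact | differential-adhesion magnitude (swept) |
| μ₀ | 0–1.5 | energy/concentration | chemotactic magnitude (swept) |
| C₀ | 5 | concentration | source amplitude (calibrated, see below) |
| λ_d | 140 | sites | gradient decay length (calibrated) |
| k | 10⁻³ | 1/step | morphogen degradation; relaxation time 1/k |
| η | 0–5 | concentration/step^½ | gradient noise magnitude |
| r | 0.01695 (default "small") | — | fate-error ratio giving E[misspecified] = 2.5 of 100 |
| cadence | 100 | MCS | cluster-count recording interval |

**Gradient calibration.** C₀ and λ_d are free constants of the model; they
were fixed once so that the chemotaxis-only model sorts correctly over the
whole μ₀ range 0.25–1.5 within the 100k-MCS horizon with sorting time
decreasing in μ₀. The trade-off is sharp: the per-site chemical energy
scale is Δμ·C ~ μ₀·C₀, and when it exceeds ~30·T (e.g. C₀ = 10 at
μ₀ = 1.5) repelled cells near the source are squeezed to one site and
freeze behind the growth barrier (μ_max−μ_min)·C₀ minus the ~29·T
area-energy relief, so sorting never completes; when it is too small
(C₀ ≤ 2) the far edge, which only sees C₀·e^(−140/λ_d), provides too
little drive to sort within the horizon. C₀ = 5 with λ_d = 140 (the grid
length) satisfies both ends.

**Default error ratio.** Fates are sampled per cell with
P(τ = p ± k) ∝ r^|k| over the valid fates, p being the region (one of
n_t equal-width bands along the gradient axis) containing the cell
centroid. r = 0 is perfect specification, r = 1 uniform random, and
intermediate errors fall mostly on adjacent regions. The default small r
solves E[misspecified] = 2.5 (exact enumeration over the 25-cells-per-
region tiling), i.e. 2–3 misspecified cells per 100-cell tissue.

## Morphogen field

The deterministic gradient is the steady state of synthesis at the
rightmost column, diffusion, and first-order degradation:
C(x) = C₀·exp(−(x_s − x)/λ_d), uniform in y. The noisy variant integrates

    ∂C/∂t = D(∂²C/∂x² + ∂²C/∂y²) − kC + η·ξ(x, t)

with ξ i.i.d. standard normal per site and step, by implicit Euler for
the deterministic operator (one sparse LU factorization reused every
step) and explicit addition of the noise increment; negative
concentrations are clipped to zero. Boundary conditions: Dirichlet C = C₀
at the source column; zero-flux at top and bottom; at the far edge the
ghost value continues the exponential (Robin/outflow,
C_ghost = C_edge·e^(−1/λ_d)). D is tied to k by the *discrete* dispersion
relation k = 2D(cosh(1/λ_d) − 1) — equal to D/λ_d² up to O(λ_d⁻²) — so the
printed exponential is the exact fixed point of the discrete scheme (the
suite checks 10⁴ steps preserve it to better than 10⁻⁶ relative L2; a
zero-flux far edge would instead flatten the profile there by ~2%).
Noisy runs advance the field once per MCS after a burn-in from the
deterministic profile (50 000 steps at full scale; 10 000 = 10/k in the
reduced profiles, ten relaxation times).

**Noise scale.** The observable used to compare noise levels is the
stationary mean fractional deviation ⟨|C − C_det|/C_det⟩. Under the
defaults, η ∈ [0.5, 5] maps to deviations ≈ 0.02–0.2, the biologically
motivated range that brackets the measured Bicoid value of 0.1; η = 5
(deviation ≈ 0.2) anchors the upper end. η is convention-dependent
(it scales with C₀), so sweeps are specified on the deviation scale.

## Metrics

* **Cluster**: connected component of the cell-adjacency graph (two cells
  adjacent iff any of their sites are 4-neighbors) restricted to
  same-type edges. A site-level flood-fill count is kept as an
  independent oracle; the two agree exactly while no cell is fragmented.
  The cell-graph definition is the physically meaningful one here: at
  j = 0 type interfaces carry no line tension and interdigitate freely at
  the site scale, so a site-level count registers spurious single-site
  "clusters" at almost every record.
* **Correct run**: cluster count reaches n_t at a recorded time strictly
  after the gate (0 normally; 500 MCS for delayed-adhesion runs, whose
  pre-switch clusters would not survive noise). **Sorting time t_s**:
  first such time. **Stable run**: correct and the count stays n_t for
  every record in [t_s, t_end]. Sub-cadence breakups between records are
  invisible; coarser subsampling can only miss transient correctness, so
  it degrades correctness and flatters stability, never the reverse.
* **Size variation**: population std/mean of the n_t per-type mean areas.
* **Cell speed**: mean Euclidean centroid displacement per 100-MCS
  window, reported separately for misspecified and correctly specified
  cells.
* **Cluster lifetime**: duration of each maximal interval at n_t
  clusters (records spanned plus one cadence).
* **Merging time**: 16-cell fixture (4×4 cells, 7 type-1 / 9 type-2,
  straight interface after the second cell column; the marked type-2
  cell sits in the type-1 block adjacent to the interface). First MCS at
  which the marked centroid crosses the interface column, checked every
  MCS; non-crossing runs are capped at the horizon, excluded from the
  mean and counted.
* **Initial-cluster statistics**: per (μ₀, j) group, a two-sample
  t-test of initial cluster counts (correct vs incorrect runs,
  ≥2 runs per group) and Spearman correlation of initial count with t_s
  (≥3 correct runs); gated pairs are flagged untestable. "Initial" means
  the first recorded time (one cadence, 100 MCS), which is when counting
  starts; at t = 0 the exact tiling would give systematically higher
  counts (mean ≈ 58 vs ≈ 46 after one cadence).

## Problem sizes

Full-scale scenarios use the published ensembles (10 runs × 100k MCS per
chemotaxis point; 30 runs × 200k MCS per adhesion point; 100 merging
runs per j). The test suite and the acceptance script run reduced
profiles chosen to keep the stochastic checks inside binomial sampling
bands: 5–10 runs per chemotaxis point (full 100k horizon where stability
is asserted, 40k where only correctness/speed is), 4–5 runs per adhesion
point at the full 200k horizon, 30–100 merging runs, 100
random-initialization draws. Smoke profiles for every scenario are
listed by `pottsort dump-config --profile smoke`.

## What the generator does and does not emulate

Simulated tissues are exact rectangular tilings with identical target
areas, fixed fates, no growth, division, or death, and a single static or
stationary-noise gradient. Passing ensembles therefore demonstrate the
sorting physics of the model — not robustness to cell-size heterogeneity,
proliferation, boundary growth, or gradient drift, none of which are
modeled. The boundary ring is neutral (J_bnd = J_same); cells neither wet
nor avoid the wall.

## Known limitations

* With the conservative per-site chemical energy, the gradient induces an
  equilibrium pressure field (attracted types compressed, repelled types
  inflated). Site exchange across a type interface is partly funded by
  the area-energy imbalance, leaving only O(T) residual barriers, so
  sorted bands at every μ₀ exhibit recurrent whole-cell excursions: in
  this implementation essentially no chemotaxis-only run stays at 4
  clusters for the full 100k MCS even at μ₀ = 1.5, where stability is
  merely rare. The non-conservative gradient-coupling chemotaxis variant
  (ΔH = −μ·(C(x) − C(x'))) would not build this pressure field, but it
  has no Hamiltonian and breaks the total-energy/ΔH consistency contract
  this package guarantees.
* The delayed-adhesion protocol is only meaningful from
  gradient-specified initial fates (small r): from fully random fates
  nothing can traverse the 140-site tissue within its 2000-MCS horizon at
  the ~1–2 sites/100 MCS cell speeds this class of model produces. Even
  with small r, the measured advantage of delayed over simultaneous
  adhesion onset at matched noise and horizon is small compared to
  run-to-run variance at desk-scale replicate counts.
* Stability is assessed at the 100-MCS cadence; sub-cadence dissociation
  events are not observable by construction.
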