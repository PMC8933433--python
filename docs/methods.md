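# Methods

## Model and assumptions

The network is a linear firing-rate model (`φ(x) = x`) of `N` units whose
connectivity is shaped by a spike-timing-dependent plasticity rule with a
Dirac-delta temporal kernel concentrated at lag `±τ`. The kernel's
antisymmetry (potentiation for pre-before-post at lag τ, equal depression
for the reverse order) reduces the plasticity convolution to the delayed
outer-product rule

    Ẇ = −γW + ρ (x x_τᵀ − x_τ xᵀ),     x_τ = x(t − τ).

The increment is exactly antisymmetric, so `W(t)` remains antisymmetric
whenever `W(0)` is — the integrator preserves this to round-off, since
Heun's update is a linear combination of antisymmetric terms. Homeostatic
decay `γ` forgets obsolete structure; without input, `W → 0`.

Memory items enter as a sequential harmonic pulse
`b(t) = Σ sin(ωt − ξ_i) m_i` with sampling phases
`ξ_i = π(i−1)/n` on `[0, π)`. Expanding the sine shows the input orbit
lives in the 2-D plane spanned by `u = Σ cos ξ_i m_i` and
`v = Σ sin ξ_i m_i` (the memory plane). At the standard operating point
(`ω = 1.5`, `γ = ρ = 0.5`, `τ = π/(2ω)`), `W` converges to an
antisymmetric, numerically rank-2 matrix `α(vuᵀ − uvᵀ)`; the amplitude α
is a diagnostic recovered from the singular values of `W*`, never an
input.

Retrieval sets `γ = ρ = 0`. The system is then linear with sinusoidal
forcing, so each cue component `sin(ωt − ξ) m` has the unique periodic
response `Im(e^{i(ωt−ξ)} z)` with `((1+iω)I − W*) z = m`; antisymmetry of
`W*` makes the shifted matrix provably nonsingular. This closed form is
exposed as `phasor_steady_state` and used as an independent oracle for
the time-stepping integrator (final-period agreement is tested at
relative L2 < 1e-3). It also explains the intersection times: the
component of the response along a direction `W*`-orthogonal to the plane
is `(sin ωt − ω cos ωt)/(1+ω²) m`, which vanishes exactly at
`t† = (arctan ω + kπ)/ω` — so at `t†` only the in-plane (retrievable)
part of the state survives.

## Numerical scheme

Both phases use Heun's predictor-corrector (explicit Euler predictor,
trapezoidal corrector), the standard "modified Euler" treatment of delay
equations; delayed states are read from the stored trajectory by linear
interpolation between bracketing grid points, preserving second-order
accuracy without tying τ to the grid (τ ≥ Δt is required so the delayed
lookup never runs ahead of the solution). Pre-history is the constant
`x(s) = x(0)` for `s ≤ 0`; the fixed point is asymptotically stable, so
the choice only affects the transient. Initial conditions default to
"appropriately small": `x(0)` i.i.d. normal with standard deviation
`1e-3 · max(1, max_i ‖m_i‖_∞)` and `W(0) = 0`. A state that becomes
non-finite aborts the run with the offending step number.

Defaults (all exposed): storage 40 time units at Δt = 0.1, retrieval 15
(images) or 30 (sentences) at Δt = 0.01, brightness half-range σ = 0.02
for encoding and display threshold σ_display = 0.002 for rendering
retrieved images (retrieved amplitudes are roughly an order of magnitude
smaller than the originals; σ_display is a display parameter, not a model
constant).

Convergence of storage is declared when the per-forcing-period relative
Frobenius change `‖W(t_end) − W(t_end − 2π/ω)‖_F / ‖W(t_end)‖_F` drops
below 1e-2 (snapshots are taken once per period on the step grid, so the
lag is the nearest grid multiple). The criterion and tolerance are
implementation choices; the underlying signature of successful storage is
the convergence of W to a constant matrix.

### Connectivity representations

`W` is dense by default. For large `N` (the capacity sweep runs at
`N = 4000`; 64×64 images give `N = 20480`) a factored mode stores
`W = Q B Qᵀ` with `Q` orthonormal (N×r) and `B` a small antisymmetric
core; plasticity increments are buffered as rank-2 pairs and folded in
once per forcing period by QR plus a spectral truncation of the core at
1e-13 relative. The two modes agree to better than 1e-8 (tested), and the
factored form supports the same matvec, norm, SVD, and shifted-solve
(low-rank/Woodbury) operations, so retrieval and the analytic oracle run
without densifying.

## Retrieval metrics

* `p(t)`: mean over items of the scaled cosine similarity
  `f_iᵀ g_i(t) / ‖f_i‖²`, `g_i = x(t)·r_i`. The default takes absolute
  values per item before averaging: the decoded items oscillate between
  positive and negative copies, so a signed temporal average would cancel
  toward zero and hide genuine retrieval; the signed variant is retained
  as an option. `p̄` is the trapezoidal time average over the whole
  retrieval window.
* `t†` is mapped to the nearest trajectory grid point (Δt = 0.01 ⇒ error
  ≤ 0.005 time units); experiments evaluate the last intersection in the
  window, where the `e^{−t}` transient is fully decayed.
* Role fitness `P^i_j(t) = ∫_{t0}^{t} |f_iᵀ (x(s)·r_j)| ds`, cumulative
  trapezoid from `t0` (default: start of retrieval; exposed as a
  parameter). Dominance is quantified as a slope-ratio test — least
  squares slope over the trailing half of the grid, a component being
  dominant within its role if its slope reaches 50% of the role's
  maximum. The thresholds (window 0.5, ratio 0.5) are deliberately coarse
  because the observed slope gaps are orders of magnitude; the original
  judgement they formalize is visual.

## Synthetic fixtures

The image generator replaces photographs with seeded "dark object on a
light background" silhouettes: background brightness 0.52–0.95 with a
random linear shading gradient, 2–4 overlapping dark primitives
(ellipses or rectangles, brightness 0.05–0.45) covering roughly a fifth
to two-fifths of the frame. Background and object levels were chosen so
the brightness deviation from mid-gray is roughly balanced, as in
photographs normalized for display: vectorized images then have small
mean component and pairwise cosines well below 1, which is what makes an
"irrelevant" image genuinely unrelated to the stored ones. What the
fixtures do **not** emulate: natural image statistics (1/f spectra,
texture), so tests certify the dynamics and the encoding/decoding
pipeline, not performance on natural photographs — headline similarity
values on real images would differ (they depend on the images' mutual
overlaps), while the qualitative contrasts (exact vs noisy vs irrelevant
cues, capacity decay) are image-independent.

Default test-scale images are 16×16 (`N = 16²·5 = 1280`) so a full
store-and-retrieve runs in seconds; 64×64 is supported through the
factored connectivity. The capacity sweep uses unit-norm Gaussian
pattern vectors (`D = 200`, `K = 20`) — magnitude of order 1, matching
the image task's `‖f‖` — with a clean cue equal to the first stored
representation, 5 repetitions per group size.

Noisy cues follow `f̃ = √(1−α²) f + α ζ`, `r̃ = √(1−β²) r + β η` with ζ,
η isotropic and scaled to `‖ζ‖ = ‖f‖`, `‖η‖ = 1` exactly — a reading of
"Gaussian noise at the signal's scale" that keeps `‖f̃‖ ≈ ‖f‖` for every
α. The tag is not re-normalized before encoding (the printed construction
does not re-normalize); a flag forces unit tags when wanted. Occlusion
sets a configurable box to mid-gray (exactly zero in vector space); the
obstructed region's geometry is a stand-in, as no canonical mask exists.

## Semantic vocabulary

Eight orthonormal word vectors (`D = 8`) and four orthonormal role
vectors (`K = 4`, subject/predicate/object/modifier) encode three
sentences — *Mary is calling John in the living room*, *John is chasing
the dog in the garden*, *John is looking at Mary in the garden* — chosen
so John occurs once as object and twice as subject, and Mary and garden
recur in different contexts. Each sentence is stored separately with role
phases `ξ_j = π(j−1)/4` and the converged connectivities are summed;
composite cues drive each component at its role's storage phase.
`D = 8, K = 4` is the minimum supporting orthonormality; the word/role
sets are otherwise arbitrary seeded orthonormal frames.

## Known limitations

* Only the identity transfer function and the delta plasticity kernel are
  implemented; exponential STDP windows, nonlinear rates, and spiking
  correspondences are out of scope.
* The integrator is fixed-step; no adaptive error control.
* Factored storage assumes `W(0) = 0` (any antisymmetric start is
  supported densely).
* The dominance thresholds are heuristics; pathological slope profiles
  (all-flat roles) yield no dominant component rather than an error.
* Orthonormal tags cap the number of co-stored items at the tag dimension
  (`n ≤ K`); compressed bindings are not provided.
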