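# Methods

## Model and assumptions

The ODE system tracks a single satellite array through three continuous
variables: lncRNA transcripts `x1`, methylated repeat copies `x2` (M) and
total copies `x3` (CN). The model deliberately collapses the silencing
marks of pericentromeric chromatin (H3K9 methylation, DNA methylation and
their readers) into one binary per-copy state, M vs U, because these marks
are strongly correlated and redundantly maintained at satellite arrays.
Assumptions worth keeping in mind:

* every U copy transcribes independently; repression by methylation is a
  Hill-1 factor `1/(1 + x2/κ)` acting in trans through total M;
* cooperative methylation saturates in M (`(x2/κ2)/(1+x2/κ2)`) and is
  proportional to both M and U — a mean-field stand-in for read-write
  spreading by mark-binding methyltransferases;
* insertion converts transcripts to new copies (reverse transcription) and
  deletion is recombination between copies, hence the `x3²` mass action;
* time is measured in generations; no absolute unit is attached, and no
  fitting to experimental measurements is attempted. All qualitative
  claims are about regime structure, which is dimensionless.

The inequality `x2 ≤ x3` is biologically necessary but not structurally
preserved by the equations (deletion removes total mass while M decays
only through μ). The integrator therefore *monitors* the inequality and
logs excursions instead of clamping them; transient violations of a few
percent of the state scale do occur when a mostly-methylated array shrinks
quickly, and hiding them would misrepresent the model. The same policy
applies to small negative excursions (reported when beyond 100× the
absolute solver tolerance).

## Steady states via the QSSA

RNA turnover (minutes) is far faster than chromatin change (hours–days) or
copy-number change (days), so RNA is set to its quasi-steady value
`x1* = α·x3/(δ(1+x2/κ1))`. Setting dx2 = 0 and dx3 = 0 under the QSSA
yields the M and CN nullclines in the (x2, x3) plane; their intersections
are *exactly* the fixed points of the full 3D system (the QSSA is an
approximation for trajectories, not for equilibria, since dx1 = 0 holds at
any fixed point). Intersections are located by bracketing sign changes of
the nullcline difference on a 2000-point log-spaced x2 grid (1e-6·K to
10·K, K = σα/(γδ) being the copy-number scale) refined by Brent's method;
local minima of |difference| without a sign change trigger a 200-point
local refinement so near-tangent fold pairs are not missed, and roots with
a vanishing difference-derivative are flagged "marginal" rather than
duplicated. Stability comes from the eigenvalues of the full 3×3
Jacobian, computed by complex-step differentiation (exact to machine
precision for this rational vector field). The origin is always reported;
it is a saddle for every positive parameter set because the
transcription–insertion loop (`ασ > 0`) gives the (x1, x3) block a
positive eigenvalue, and for x2 > 0 the M nullcline lies strictly above
the diagonal so the x3 = 0 branch carries no other intersection.

## Fold geometry and the calibrated reference set

Writing the M nullcline as `x3 = x2 + μx2(1+x2/κ2)/(η(1+x2/κ2)+φx2²/κ2)`
shows it rises from the origin with slope (η+μ)/η, turns over near
`x2 ≈ √(ηκ2/φ)`, falls, and rejoins the diagonal near `x2 ≈ √(μκ2/φ)`;
the ratio of fold-top to fold-bottom heights grows like `√(μ/η)/4`, so a
large μ/η produces a wide fold. The CN nullcline is a decreasing hump of
height K on the scale of κ1 and κ3 (κ4 only relieves deletion at large
x2). Where the hump passes relative to the fold decides the regime:
above → monostably silenced, through → bistable, below → monostably
desilenced. This single picture fixes every sensitivity direction: rates
that raise the CN nullcline (α, σ, κ1, κ3) or lower the fold (φ, η)
silence at high values; their antagonists (δ, γ, μ, κ2) desilence; κ4
only ever lifts the CN nullcline further above the fold, which is why it
alone shows no three-regime structure.

`calibrate_reference_parameters` encodes this: it picks η = 2e-4,
μ = 0.25 (wide fold), φ = 0.5, κ2 = 1000 (fold location at tens of
copies), κ1 = κ3 = κ2/20, κ4 = 10κ2, α = δ = 2, σ = 1, then sets γ so
that K sits a factor 1.8 above the fold (monostably silenced wild type,
K ≈ 731). Every constraint — silenced reference; φ↓ crossing bistable
then desilenced; δ↑ crossing bistable then desilenced; σ showing
desilenced → bistable → silenced from low to high with the reference in
the silenced regime — is then verified by steady-state analysis on 25-point
log scans; a seeded random search around the template stands by in case a
modified template fails. The shipped `reference` preset is the verified
template output, and `bistable` moves φ to the geometric middle of the
verified bistable window (φ ≈ 0.0734).

The seven default initial conditions probe the basins deterministically:
copy number at K·{0.1, 1, 3} crossed with methylated fractions
{0.05, 0.5, 0.95} (low/high × low/high plus intermediates), RNA at its
QSSA value.

## Integration and steady-state detection

The default solver is LSODA (adaptive, automatic stiffness switching),
with the low-order explicit pair available as `method="RK23"`. The
explicit pair is not the default for a measured reason: near an attractor
its local-error noise (≈ rtol·|y|·λ_fast) can exceed any practical
steady-state detection threshold while its stability bound caps the step
size, so slow final approaches take hundreds of thousands of steps; LSODA
reaches the same attractors in a few hundred. Integration stops early
when |f(y)| < 1e-5·(1+|y|); the endpoint is then Newton-polished (hybrid
Powell with the complex-step Jacobian, accepted on its achieved residual)
and declared converged only when the polished residual is below
1e-9·(1+|y|). Converged endpoints are deduplicated as the same attractor
when closer than 1e-4 (relative) in (x2/x3, log x3) coordinates — the
space in which the silenced and desilenced branches are well separated at
any copy-number scale.

Bifurcation diagrams integrate the seven starts per grid point and
cross-validate the stable-state count against the nullcline
intersections. Near a fold one basin shrinks below the reach of seven
starts; such points are flagged in `BifurcationResult.flagged` rather
than silently misclassified (the flag is asserted, at regime boundaries
only, in the tests). Branch labels come from 1D k-means (k = 2) on the
methylated fraction pooled over the whole sweep — pooling keeps labels
consistent along the diagram — with the lower-methylation cluster as the
desilenced branch and a 0.05 centroid-gap floor below which the sweep is
declared single-branch and labeled against 0.5. Hysteresis scans are
continuation-style: each converged state seeds the next grid value,
forward then backward.

Sensitivity scans default to 41 log-spaced points spanning 1e-2–1e2 times
the reference value (tests and examples use 13–17 points to keep the
default run short); non-convergent cells are reported as "undetermined",
never merged into a regime — the jointly-low (α, σ) corner, where the
copy-number scale collapses to a fraction of a copy and the dynamics
become arbitrarily slow, is the one place this occurs in practice.

## Spatial chain model

The chain is a boolean array (True = M) updated synchronously once per
generation from the current configuration only: M → U with probability
μ = 0.1; U → M with probability η = 0.01, or 1−(1−η)(1−φ) with φ = 0.2
when at least one M lies within two positions (independent-chance
composition keeps the probability below 1; eligibility, not dosage — more
neighboring Ms do not raise it further). The transcript level is
`α·CN/(δ(1+nM/κ))`; insertions are Poisson with mean
`σ·n_transcript/(1+nM/κ3)`, each a new **U** monomer placed left or right
(fair coin) of a uniformly chosen U site; deletions are Poisson with mean
`γ·CN²/(1+nM/κ4)`, removing uniformly chosen U sites without replacement,
capped at the available U count. Sub-step order is fixed (flips computed
from the pre-update chain; insertions, then deletions, applied after) and
all randomness comes from the chain's own seeded stream, so runs are
bit-reproducible; the stream position is part of the serialized form.
Insertion with no U host is skipped and logged; a zero-length chain is an
absorbing, flagged extinction state.

Only η, φ, μ are rate constants with externally specified values; the
transcript/insertion/deletion constants were calibrated here (α=1, δ=1,
κ=1000, σ=0.5, κ3=1000, γ=4.5e-7, κ4=1e4) so that the demonstration
chain — 15,000 repeats, 68% methylated — holds a quasi-steady copy number
of order 1.5×10⁴ with fraction ≈ 0.67 over thousands of generations.
Silenced-domain statistics use a greedy left-to-right merge of M runs:
a run joins the current domain while the merged span's U fraction stays
≤ 20%; the domain size is the merged span length.

With `neighborhood_radius="global"` (every U eligible whenever any M
exists) the model admits an analytic mean field: E[ΔCN] per generation is
*algebraically identical* to the ODE copy-number equation at the
quasi-steady RNA level, and E[ΔnM] = (CN−nM)·[1−(1−η)(1−φ)] − μ·nM,
which reduces exactly to the ODE methylation equation when φ = 0. The
cooperative term itself cannot match the ODE term-by-term — the chain
gives each eligible U a constant probability φ while the ODE's
cooperative rate per U grows with M — so the correspondence is tested
where it is exact (copy-number equation; φ = 0 methylation) plus
Monte-Carlo agreement of the simulator with the analytic mean field.

## What the synthetic conditions do and do not show

All inputs are parameter sets and seeds; there is no external data. The
calibrated presets reproduce the *regime structure* (monostable silenced
wild type, bistable windows in every rate except κ4, hysteresis, the
antagonistic φ–μ and synergistic α–σ phase boundaries) but not any
particular literal rate table, so absolute copy numbers and bifurcation
thresholds here (e.g. the bistable φ window [0.034, 0.16]) characterize
this calibration, not a measured genome. The chain model emulates
local mark spreading and stochastic indels but not sequence heterogeneity,
3D organization, replication timing, or distinct mark layers — passing
tests show the mechanism is coherent, not that real HSATII arrays sit in
any particular regime.

## Known limitations

* The regime classifier depends on the seven-start protocol; attractors
  with basins smaller than the probe grid near folds are flagged, not
  found. Unstable branches come only from the nullcline analysis.
* No two-parameter fold tracking / arclength continuation; bistable
  windows are found by scanning.
* The spatial model's insertion placement ("adjacent to a uniformly
  chosen U") is one reading of insertion at active repeats; appending at
  array ends or replacement are plausible alternatives that would change
  domain statistics.
* Domain merging is greedy left-to-right; a globally optimal merge could
  differ on contrived gap patterns.
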