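# Methods

## Thin-film flow model

All hydrodynamics in `shearpick` rest on the lubrication closure: in a gap
that is thin relative to its lateral extent, the local velocity profile is
parabolic (plane Poiseuille), so for a channel of width `w` and height `h`
carrying flow `Q` the wall shear stress is `WSS = 6Qμ/(h²w)`, and for an
axisymmetric film of gap `h(r)` draining into a central sink at `Q`, the
per-circumference flux is `q(r) = Q/(2πr)` (continuity), the pressure
gradient is `dp/dr = 12μq/h³`, and the wall shear is
`τ(r) = 6μq/h² = 3μQ/(πr h(r)²)`.

The design insight is that choosing the pin-tip contour `h(r) = √(r₀/r)·h₀`
makes `r·h(r)² = r₀·h₀²` an exact algebraic constant, so `τ` is independent
of `r`: one flow-rate setting applies one well-defined stress to every cell
under the footprint. Flow-rate sizing is the inversion
`Q = τ·πr₀h₀²/(3μ)`; at the reference geometry (`r₀ = 500 µm`,
`h₀ = 50 µm`) a 500 Pa pulse needs 654.5 µl/s.

Assumptions: steady Stokes flow, Newtonian fluid, no entrance/rim effects,
no coupling between the field and cell topography. The numerical solver
(`lubrication.solve_radial`, trapezoid quadrature on a log-spaced grid,
outer boundary `p(r₀) = 0` gauge) evaluates the same physics for arbitrary
gap profiles and serves as the cross-check that the closed forms and the
grid plumbing agree to ~1e-15; a full Navier–Stokes treatment is out of
scope.

### Radial gradient of the shear field

For the contour-plus-offset gap family `h(r) = √(r₀/r)·h₀ + δ` the identity
`h + 2rh' = δ` holds exactly, giving the analytic gradient
`dτ/dr = −3μQδ/(πr²h³)`. `ShearField.gradient` uses this form rather than a
finite difference of the `τ` array: at `δ = 0` the gradient is exactly zero,
whereas differencing floating-point `τ` values would report spurious
~1e-6 Pa/m noise over µm-scale grid steps.

### Offset sensitivity

A vertical offset `δ` (positive = pin farther from the surface) perturbs the
field to `τ(r)/τ_nom = 1/(1 + (δ/h₀)√(r/r₀))²`, worst at the rim. The model
therefore predicts: widening the gap lowers the stress, narrowing raises it,
the magnitude grows with `|δ|`, and the narrow-gap branch is the more severe
(`|Δ(−δ)| > |Δ(+δ)|`). Only these qualitative facts are asserted; the
package's rim-ratio percentages are much larger than what a CFD treatment of
the full pin geometry reports for the same offsets (e.g. −17.4% vs a few
percent at `δ = +5 µm`), because the appropriate variation metric over an
unspecified bore/inlet geometry is not reproducible from the thin film
alone.

### Parameter defaults

| parameter | default | why |
|---|---|---|
| `r0` | 500 µm | rim radius of the reference pin |
| `h0` | 50 µm | standoff gap at the rim |
| `bore_radius` | 150 µm | not a published quantity; chosen so ideal coverage `1−(rᵢ/r₀)² = 91%` is consistent with the >90% footprint-coverage behaviour of the device |
| viscosity `μ` | 1.0e-3 Pa·s | water-like culture medium; the exact medium viscosity is not published, so every WSS↔Q conversion is conditional on this configurable value |
| coverage tolerance | 5% relative | "constant shear" needs an explicit band; exposed as a parameter |
| radial grid | 2048 log-spaced points | resolves the steep inner contour; pump pressure converges to <1e-6 between 2048 and 4096 points |

## Detachment simulator

Each cell carries a critical WSS `τ_c` drawn log-normally around its lineage
median with log-scale dispersion `σ` (default 0.15): adhesion strengths are
positive and right-skewed, and only point thresholds (medians) are measured,
so the distributional family and spread are modelling choices. Medians:
NPC 124 Pa, iPSC 248 Pa, UC 744 Pa; pre-neuron-1/2 are tied to the NPC
median (same weakly adherent stacked phenotype); cell-cycle cells and the
small uncharacterised remainder sit at the NPC/iPSC geometric mean
(~175 Pa) as an intermediate default. All are configurable.

During a pulse at stress `τ` for duration `t` a cell detaches with
probability `P = 1 − exp(−k·t·((τ/τ_c − 1)₊)^m)`: no detachment below
threshold, hazard growing with relative excess stress. Defaults `k = 1/s`,
`m = 1` make a single 1-s, 250 Pa pass remove `1 − e^{−(250/124−1)} ≈ 64%`
of NPCs, consistent with the observed ~60% first-run elimination of the
NPC/pre-neuron population; `k` remains a free kinetic calibration because
the 1-s pick pulse and the minutes-long chamber dissociation experiments
are not unified by a single published rate.

Stacking shields: cells are binned into 20 µm (x, y) neighbourhoods and only
the topmost retained layer of each bin is exposed; a step sweeps top-down
until no newly exposed cell detaches. Each cell draws a single uniform per
step (common random numbers), which makes the detached set — and hence every
reported fraction — monotone in `τ`, `t` and pass count for a fixed seed,
and bit-reproducible.

Colony construction assigns lineages multinomially (default: the
reprogramming mixture of 4.8% iPSC, 56.5% NPC, 12.5%/5.4% pre-neurons,
19.5% cell-cycle, 1.3% other), positions uniformly on a disc, and layers
from a (0.5, 0.3, 0.2) bottom-to-top distribution with the iPSC layer-0
probability boosted by the `layering` parameter (default 0.8), emulating the
bottom-monolayer localisation of pluripotent cells. The reported peripheral
enrichment of iPSCs is *not* modelled — no simulated behaviour depends on
radial position — and neither are cohesive-patch mechanics, proliferation
between runs, or field–cell coupling (the applied stress is uniform over
the footprint, which is exactly what the constant-WSS contour is for).

`ExposureStep` warns rather than errors above the 1000 Pa pump envelope:
the envelope is a hardware property, and characterising the UC response
curve (median 744 Pa) requires simulated sweeps beyond it.

### Threshold estimation from selected-area curves

The "selection threshold" of a lineage is operationalised as the first
stress at which the mean selected-area fraction exceeds 1% (the onset
criterion is not otherwise defined). For parameter recovery the monolayer
selected-area curve is fitted with a log-logistic sigmoid
`F(τ) = 1/(1 + (τ/α)^{−β})`; under the hazard model the half-detachment
point sits at `τ₅₀ = median·(1 + (ln2/(k·t))^{1/m})`, so the median
estimate is `α` divided by that kinetic factor. At the defaults
(`σ = 0.15`, `n_rep = 50`, 25-point grids spanning 0.05–3× the median) this
recovers 124/248/744 Pa with ~4% relative error; the residual bias comes
from the log-normal smearing of the curve, which the two-parameter sigmoid
absorbs into `β`.

## Vision pipeline

Synthetic plates are 16-bit grayscale frames (default 2048² px at
3.25 µm/px, a 6.7 mm field) with Gaussian background noise and textured
bright discs placed by rejection sampling under a minimum edge-separation
constraint; ground truth (centres, radii) is returned alongside. The
generator emulates contrast and placement geometry only — not bright-field
texture, focus drift, uneven illumination or colony morphology — so
perfect precision/recall on these fixtures demonstrates the geometry
plumbing and rule logic, not robustness on real microscopy.

Segmentation: Gaussian smoothing (σ = 2 px) → Otsu threshold → hole filling
→ connected components → minimum-area filter. A foreground/background
contrast floor (2000 counts) prevents Otsu from hallucinating structure on
blank plates. Qualification flags each colony with every failed rule: area
bounds, solidity (merged-blob proxy), pairwise edge-to-edge distance
≥ `2r₀ + clearance` (default 200 µm), and well-edge clearance
≥ `edge margin` (default `r₀ + 100 µm`). The solidity threshold is 0.90,
not lower: the union of two equal discs has solidity between ~0.88
(tangent) and 1 (coincident), so any cut below 0.88 can never flag a fused
pair, while isolated noisy discs measure ≥0.97 — 0.90 separates the two
populations cleanly. Pick lists convert pixel centroids to stage µm
(`px × pixel_size + offset`, origin top-left, x right, y down) and order
targets serpentine by 1000 µm y-bands to shorten arm travel.

## Proportion statistics

Purity comparisons use the exact hypergeometric construction: for each cell
type, `x` of `n` sampled cells against `K` of `N` pooled cells, upper tail
for enrichment, lower for depletion, `2·min(tails)` capped at 1 for the
(default) two-sided report — sidedness of the original analyses is not
specified, so the conservative choice is surfaced. P-values are
Benjamini–Hochberg adjusted across types (`statsmodels`), and
`scipy.stats.hypergeom` supplies the tails; both are verified in the test
suite against hand-rolled enumeration and step-up oracles. Fold ratios and
combined percentages are rounded half-up to one decimal, matching the
precision at which such results are reported.

## Problem sizes

The test suite and acceptance script run on desk-scale problems chosen as
sufficient for their statistical claims: colonies of 500–2000 cells,
200 paired replicates for the dual-vs-single purity comparison (one-sided
paired t-test), 50 replicates per point for threshold recovery, 1024² px
image fixtures, and 2048-point radial grids. The design-math identities are
exact and independent of problem size.

## Known limitations

- The lubrication model omits the pin's internal bore flow, rim free-surface
  effects, and inertia; offset-sensitivity magnitudes are therefore
  qualitative (signs and orderings only).
- Detachment is per-cell independent given the shielding rule; collective
  (cadherin-mediated) patch detachment is not modelled.
- The empirical purity percentages of the two selection modes (18.2%/8.3%,
  10.84%/2.38%) are measurement inputs used for ratio arithmetic, not
  quantities the simulator reproduces.
- The synthetic imaging fixtures do not exercise illumination or texture
  variation; segmentation defaults are tuned for high-contrast inputs.
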