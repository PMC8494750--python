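# Methods

## The model

Cells are point particles with an interaction radius r₀ on a flat square
substrate of side L, observed in two dimensions. Three mechanisms act:

- **Motility.** Discrete-time Brownian motion with per-axis displacement
  √(2 τᵢ D Δt)·ξ, ξ ~ N(0,1). D is the free diffusivity of a cell.
- **Adhesion.** A cell in *contact* — some other cell strictly within 2r₀ —
  moves with the reduced factor τᵢ = τ(N) ≤ 1; isolated cells have τᵢ = 1.
  Contact reduces motility only; there is no repulsive force, and cells may
  transiently overlap while diffusing (interpreted as cells crawling over
  each other).
- **Proliferation.** Each cell divides in a step with probability λΔt.
  The offspring site is drawn at distance exactly 2r₀ from the parent at a
  uniform angle, one proposal per attempt, and is accepted only if its
  centre distance to every cell — including offspring already accepted in
  the same step, processed in cell-index order — is at least 2r₀. This
  non-overlap rule is the only excluded-volume constraint in the model and
  encodes contact inhibition of proliferation. There is no cell death, so
  N is non-decreasing.

The density-dependent adhesion law

    τ(N) = τ₀                        N ≤ N₀
    τ(N) = 1 − (1−τ₀)·e^{−T(N−N₀)}   N > N₀

is exactly continuous at N₀ (the code branches on N ≤ N₀ so this holds in
floating point too) and rises to 1 as the colony densifies; T (1/cells)
sets how fast adhesion is lost. T = 0 recovers the constant-τ model. τ(N)
is evaluated from N at the start of each step, before that step's
divisions.

### Default parameters

| symbol | meaning | default | why |
| --- | --- | --- | --- |
| r₀ | interaction radius | 10 μm | ~40% above a typical GBM nucleus radius; sets the contact and division scale d = 2r₀ = 20 μm |
| D | free diffusivity | 500 μm²/h | experimental motility estimate for GBM cells, taken as a fixed constant |
| λ | division rate | 0.2 /h | the stage-1 fitted operating point |
| τ₀ | low-density adhesion factor | 0.52 | the stage-1 fitted operating point |
| T | adhesion-loss rate | 1.8×10⁻³ /cell | the stage-2 fitted operating point |
| N₀ | threshold count | 98 | lowest density with usable statistics in the emulated assay |
| L | domain side | 1000 μm | L² = 10⁻² cm², one microscope field |
| Δt | time step | 0.01 h | rms step √(2DΔt) ≈ 3.2 μm ≪ r₀ and λΔt ≪ 1 |
| N_init | initial cells | 50 | 10⁴ seeded cells × (10⁻² cm² / 1.93 cm² well) ≈ 52 |

Boundaries are periodic by default (no edge depletion to bias K);
reflecting boundaries are available. Note an interaction-radius ambiguity
in the source material (10 vs 15 μm); 10 μm is the default here because it
is consistent with the 20 μm division distance and analysis scale, and
results are insensitive to small changes in it.

### Numerical design

Two integration engines share one `numpy.random.Generator` stream and are
tested to agree bit-for-bit: plain numpy step functions (the readable
reference) and a fused numba kernel (~20× faster, used by `run_until`).
The per-step draw order is fixed (2N normals, N division uniforms, one
angle per divider) and independent of positions, which also makes periodic
trajectories exactly translation-equivariant under a shifted initial
condition with the same seed. Ties are strict: distance exactly 2r₀ is
neither contact nor overlap.

## Ripley's K

K(r) = area/(N(N−1)) · Σ_{i≠j} w_ij·1(d_ij ≤ r). Simulated (toroidal)
patterns use minimum-image distances (exact); bounded windows can use
translation weights w_ij = A/((Lx−|dx|)(Ly−|dy|)) or no correction. The
analysis grid is r = 15…100 μm in 5 μm steps: below 15 μm two nucleus
centroids cannot be distinguished reliably, and the grid also defines the
Q sum in inference. g(r) uses plain central differences (one-sided at the
ends, no smoothing) — it is reported for interpretation only. K(20 μm)/r²
is the single-scale summary used for the density analysis; 20 μm lies on
the grid so no interpolation is involved.

## Inference

**Stage 1 (λ, τ₀).** For each grid cell the constant-adhesion model runs
from 50 cells until N = N₀, K/r² of the final patterns is averaged, and
Q = Σᵣ(K_mod/r² − K_ref/r²)² is minimised over λ ∈ [0.15, 1.0] (step 0.05)
× τ ∈ [0.0, 1.5] (step 0.05). The Q valley is diagonal — faster division
trades against weaker adhesion — and one coarse step along the valley
changes Q by less than the replicate noise at 50 runs/cell (~0.5 vs ~0.85
measured at the operating point), so a plain 50-run argmin is unstable.
The search therefore uses three passes, all with **common random numbers**
(each cell replays the same replicate seeds, cancelling shared noise from
Q differences and making the result independent of evaluation order):

1. screen every cell at 50 runs;
2. re-evaluate the cells within a Q margin (default 1.0, ≲ the screening
   noise floor; typically ~10 cells) at 200 runs — the replicate count of
   the full-scale procedure — and take their minimiser;
3. refine on a ±0.02 neighbourhood at step 0.01, again at 200 runs.

Ties break toward smaller λ, then smaller τ; a boundary argmin raises a
warning. With a 200-run reference a single fit recovers (0.2, 0.52) to within one
coarse step in roughly four cases out of five; the residual scatter
(≈ ±0.02–0.06, diagonal) is the honest sampling uncertainty of the
procedure, dominated by the reference curve's own replicate noise, which
tilts the valley. Headline numbers are therefore reported as the median of
three independent replications of the whole fit.

**Stage 2 (T).** With (λ, τ₀) frozen, density-dependent runs continue past
N₀ until 6·N₀ or 24 h, sampled every 0.5 h; the samples of K(20)/r² vs N
with N ≥ N₀ (below N₀ the law is inert, so those samples carry no
information about T) are averaged in 8 equal-width N bins on the reference's
bin edges, and Σ_bins(model − reference)² is scanned over
T ∈ {0} ∪ [10⁻⁴, 10⁻¹] (12 log-spaced candidates, ratio 10^{3/11} ≈ 1.87).
Run seeds depend only on the base seed and run index, so all candidates
share noise realisations and the T = 0 candidate reproduces the constant-τ
curves *exactly*. Bins populated by only one side of the comparison are
skipped. Under the default parameters the growth cap 6·N₀ ≈ 588 is reached
around 13 h, so the scan compares the full N₀…6N₀ range.

No confidence intervals are attached to (λ̂, τ̂₀, T̂): the procedure is a
point estimate by design, and the scan/grid step is the resolution claimed.

## Synthetic experiments

`synthetic_data.generate_experiment` emulates the imaging assay:
replicate fields (default 10) run with the truth parameters, snapshotted at
experimental times {2, 4, 6, 8, 12, 24} h. Simulation t = 0 corresponds to
the 2 h time point (deposition is assumed complete by then). Detection
noise is iid Gaussian centroid jitter (default 1 μm, re-wrapped into the
periodic window) and independent misses (default 2%, which leaves Ripley's
K unbiased — binomial thinning preserves K in expectation). What it does
**not** emulate: nucleus size/shape heterogeneity, segmentation merge
errors at high density (unless patterns are round-tripped through the
imaging module), uneven illumination, or any departure of real cells from
the model dynamics — so a green recovery test establishes the internal
consistency of the pipeline, not the truth of the model for real colonies.

The micrograph stand-in renders isotropic Gaussian blobs (σ = 3.5 μm,
nucleus radius ≈ 7 μm) on a 1 μm/px raster plus iid pixel noise; the
detector chain is Gaussian blur (1 px) → Otsu threshold → 8-connected
components → area filter → intensity-weighted centroids. The real
experiment's segmentation algorithm is unspecified; this chain was chosen
for determinism and testability, and nuclei closer than ~2σ merge — the
round-trip tests report rather than hide this.

## Known limitations

- Division can stall near close packing; `run_until` raises after a step
  cap rather than looping forever when a count target is unreachable.
- The λ–τ₀ ridge means single-seed fits at reduced replication can land one
  grid step off along the valley; treat the grid step as the resolution.
- K edge corrections other than periodic are provided for bounded
  experimental windows but the package's own analyses run on periodic
  domains where the minimum-image estimator is exact.
- The imaging stand-in is deliberately minimal; it is a harness for the
  detector contract, not a microscope model.
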