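# Methods

This note documents the models and numerical choices behind `nirselect`: what
the synthetic generator simulates and why its defaults look the way they do,
how each algorithmic stage is defined, and what validation on synthetic data
does and does not establish.

## The calibration problem

A full-transmission Vis-NIR instrument records the light that passes entirely
through a fruit on a conveyor — 2048 wavelengths between 560 and 1072 nm at
0.25 nm spacing — while a refractometer measures the reference soluble solids
content (SSC, %) of the juiced fruit. The calibration task is a linear inverse
problem: predict SSC from the spectrum, using as few wavelengths as possible so
the deployed model can run at line speed. The obstacles are the usual ones of
transmission spectroscopy: large fruit-to-fruit intensity differences (optical
path, skin, positioning), detector noise, strongly collinear adjacent
wavelengths, and occasional aberrant samples.

## Synthetic data generator

No public transmission dataset of this kind exists, so the package generates
its own with known ground truth. The signal model for sample *i* is

    I_i(λ) = path_factor · m_i · I0(λ) · 10^(−A_i(λ)) + b_i + ε_i(λ)
    A_i(λ) = t_i · Σ_j c_ij · a_j · exp( −(λ − μ_j)² / 2σ_j² )

* `I0(λ)` — smooth broad-Gaussian lamp envelope (peak 40 000 counts at 800 nm,
  width 600 nm). A halogen source filtered through the instrument optics is
  smooth and nearly flat over this range; the exact shape is configurable.
* Gaussian absorption bands at 675, 840 and 960 nm (σ = 12, 18, 22 nm; unit-
  concentration peak absorbance 0.45, 0.35, 0.55) — a chlorophyll-like visible
  band, an SSC-linked carbohydrate band in the short NIR, and a water band.
  Per-sample concentrations `c_ij` are normal around 1 (sd 0.2, truncated at
  0.2).
* `t_i` — log-normal per-sample optical path length (sd 0.08) multiplying the
  whole absorbance, as Beer–Lambert prescribes for fruit of varying diameter.
  This term matters: it is the slope-type variation MSC exists to correct.
  Without it, the only source of per-spectrum "scale" is the band absorbance
  itself, and a scatter correction then transfers concentration information
  into every wavelength — baseline regions become spuriously predictive and
  wavelength selection loses its meaning.
* `m_i`, `b_i`, `ε` — log-normal multiplicative scatter (sd 0.15, the large
  curve-to-curve intensity differences a multi-point transmission measurement
  shows), a per-sample additive offset (sd 300 counts) and i.i.d. detector
  noise (sd 150 counts).
* SSC is affine in the designated band-1 concentration plus refractometer
  noise (sd 0.1 %): mean 4.5 %, sd 1.0 % — a ripe-tomato range.

Noise magnitudes were fixed at design time so that a full-spectrum PLSR model
on GF+MSC-preprocessed absorbance attains prediction R ≈ 0.80–0.92 on a held-
out quarter, the accuracy regime reported for instruments of this type; the
reference-noise ceiling is R ≈ 0.99. Ground truth records the per-band and
merged index ranges of band support (center ± 3σ), the concentrations, and the
affine SSC law, so selection methods can be scored by how many of their chosen
wavelengths fall inside true band support.

Multi-frame acquisition is emulated by `generate_multiframe`: each fruit
yields `frames_per_sample` noisy realizations of its spectrum, and when there
are at least three frames the first and last are scaled by `edge_frame_gain`
(2.5) to mimic frames where the beam grazed only pericarp tissue — these are
removed by truncation (threshold: frame total > 1.5 × median frame total)
before averaging. With one frame the stack is bit-identical to `generate`.

What the generator does **not** model: radiative transfer in heterogeneous
tissue, the locule cavity geometry, detector nonlinearity and wavelength-
dependent noise, temperature drift, and non-Gaussian band shapes. Passing the
synthetic benchmarks therefore demonstrates correctness of the algorithms and
their behavior under realistic noise structure, not instrument-ready accuracy
on real fruit.

## Preprocessing

* **Gaussian filter** — normalized Gaussian weights on an odd window
  (default 11 points, σ = window/5 in index units), reflect padding so smooth
  spectra do not droop at the edges. The kernel sums to exactly 1, so constants
  are preserved and the filter is linear.
* **SNV** — per-spectrum (x − mean)/sd with the sample (n−1) denominator, the
  common chemometrics convention; configurable. Constant spectra are rejected.
* **MSC** — least-squares fit s ≈ a·r + b per spectrum; corrected = (s − b)/a.
  The reference r defaults to the mean spectrum of the set being corrected,
  but the pipeline always fits the reference on the calibration set and passes
  it explicitly when correcting the prediction set, to avoid leakage. A fitted
  slope of ~0 (degenerate spectrum) is an error naming the sample.
* **GF+MSC** — smoothing first, then scatter correction; the combination used
  by the final pipeline.
* Absorbance conversion (−log10 I) precedes preprocessing by default so that
  Beer–Lambert concentration-signal linearity holds; scatter and lamp terms
  become additive/multiplicative nuisances that SNV/MSC remove.

Whether to preprocess per frame or after averaging is ambiguous in practice;
the pipeline averages first (the variance-reducing order) — preprocessing
operates on one spectrum per sample.

## PLS regression

NIPALS PLS1 with mean centering only: scatter correction already normalizes
the intensity scale, so autoscaling of wavelengths is not applied. With a
single response the inner NIPALS loop is non-iterative; successive score
vectors are orthogonal by construction, and with as many components as the
rank of centered X the fit equals ordinary least squares (both properties are
tested, the latter against the normal equations and scikit-learn). The
per-LV regression vectors are accumulated through the orthogonalized weights
r_i = w_i − Σ_j<i (p_jᵀw_i) r_j, so one pass yields the coefficient path for
every LV count — cross-validation fits each fold once, not once per LV.

RMSECV uses leave-one-out folds by default (k-fold available, seeded and
frozen); the chosen LV count is the **first** minimum of the curve, favoring
parsimony on ties, and is capped at 20. Metrics follow the printed convention
R = 1 − SSE/SST — algebraically a coefficient of determination even though
calibration papers commonly label it a correlation coefficient; a Pearson
variant is available behind a flag (`method="pearson"`) but is not the
default. The calibration/prediction split is random at 3:1 (96 → 72/24),
deterministic under its seed.

## Monte-Carlo outlier detection

Defaults: 500 runs, 25% validation fraction, inner LV selection by seeded
5-fold RMSECV capped at 15 (the cap and the 5-fold inner loop keep the scan
fast; the final calibration re-selects its LV count freely, and LOO is
available). Absolute errors are aggregated — the mean/STD plane is then
directly interpretable (bias vs volatility) — with a signed option. Every
sample must be held out at least 20 times or the scan aborts with advice to
raise `n_runs`. The flag rule is a documented surrogate for the unpublished
cut: flag when mean error > mean + 2.5·sd of mean errors OR error-STD exceeds
the analogous bound; errors below 1e−9 % SSC are treated as numerically zero
so a perfectly fitted dataset yields no flags. The pipeline removes outliers
before the split by default (matching how sample counts are reported in this
literature); a strict mode restricts the scan to the calibration set.

## Wavelength selection

**Binning** requires the width to divide the wavelength count (2048 with
widths 32/16/8 → 64/128/256 variables); each binned variable is the *sum* of
its members (total intensity is conserved) and is labelled by the nm midpoint
of its range.

**BVS-PLS** re-evaluates every single-group removal per iteration by RMSECV
(LV re-selected per candidate, capped at 20; a fast mode re-selects once per
iteration) and removes the best, breaking ties toward the lower group index
for determinism. The standalone stopping rule is "no removal decreases
RMSECV". Inside `combined_select` an additional floor is applied — BVS never
eliminates below max(k, m/2) groups — because among ~100 noise variables a
greedy search almost always finds a chance decrease and would otherwise run
all the way down, usurping the role of the annealing stage; BVS is used as a
coarse screen and the subset refinement is left to SA, mirroring the
division of labor the combined method intends (e.g. 128 → 64 survivors → 20).

**Simulated annealing** searches fixed-size-k subsets with single-swap moves
and Metropolis acceptance exp(−ΔC/T), C being the RMSECV of a PLS model on the
subset (deterministic: folds and LV policy frozen per run; evaluations are
cached). The initial temperature defaults to the initial subset's RMSECV.
Cooling defaults to an adaptive decrement — T decreases by 0.5% of the best
RMSE found so far at every iteration, so cooling slows as the fit improves —
with a geometric rule (α = 0.95) available. The termination temperature Te
(default 1e−8·T0) acts as a **floor**, not a stop: since objective differences
between neighboring subsets are orders of magnitude smaller than the RMSE
scale of T0, the hot phase is an exploratory random walk, and stopping the
moment T reaches ~0 would spend the entire budget exploring; instead the
remaining iterations run effectively greedily and refine the best region
found. L (default 500) is the total iteration budget, one objective
evaluation per iteration. The best subset ever visited is returned with its
best-so-far trace (non-increasing by construction) and the accepted-move log.

**Combined selection** maps the SA-chosen bins back to original-grid index
ranges through the grouping map and records the full provenance chain
(traces, seeds, parameters) in the result.

## Pipeline and reproducibility

Every stochastic stage draws a named seed derived from one master seed via
SHA-256 (`derive_seed(master, name)`, < 2³¹), so stages are independent and
the whole run is reproducible; reports contain no timestamps and identical
configs produce byte-identical JSON. All data-dependent statistics are
calibration-only. Stage failures abort with the stage name; intermediates
written before the failure are retained.

## Known limitations

* Synthetic validation only — see the generator caveats above.
* BVS cost grows as O(m²) RMSECV evaluations; the LOO objective on large n is
  the faithful-but-slow path, and the seeded 5-fold objective with fast LV
  mode is the practical one for 96 × 128 problems.
* The SA schedule inherits the ambiguity of its published description; both
  implemented cooling rules are logged in the provenance so runs are
  comparable.
* PLS1 only (single response); no autoscaling, derivatives, or orthogonal
  signal correction.
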