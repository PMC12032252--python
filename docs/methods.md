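# Methods

`hbscreen` re-implements, as a tested library, the computational analysis
of a multi-dose 3D drug screen on hepatoblastoma (HB) spheroid models:
control-based normalization, four-parameter logistic (4PL) dose–response
fitting, drug-sensitivity scoring (DSS/sDSS), Z′-factor plate QC, hit
selection, single-cell Cell-Painting-style morphological profiling, and the
study-endpoint formulas (tumor volume, T/C ratio, 2^−ΔΔCt, Student's t).
Because the raw screen plates and images of such studies are typically not
released, every stage is validated on synthetic data with planted ground
truth; this note records the models, the defaults and why, and what the
synthetic validation does and does not establish.

## Screen scoring

**Normalization.** Each 384-well plate carries one cell model, a column of
DMSO negative controls (no effect) and a column of benzethonium-chloride
positive controls (full kill). Viability is an ATP-proxy luminescence
signal. Percent inhibition of well *w* is its position on the plate's own
control axis, PI(w) = 100·(μ_neg − S_w)/(μ_neg − μ_pos). Normalization is
strictly per plate — plates are the batch unit — and PI is not clamped
before fitting; the fit constraints do the clamping. Replicate wells at a
dose are averaged on the PI scale so per-plate normalization stays
coherent.

**Dose–response model.** Responses on the log10-molar axis follow the
ascending 4PL y(x) = d + (a − d)/(1 + 10^{b(c−x)}) with top asymptote
a ∈ [0, 100] % inhibition, Hill slope b ∈ (0, 10], inflection c = log10
EC50, and bottom d fixed at 0 (the inhibition scale is anchored at the
DMSO level; d is configurable for diagnostics). Fitting is bounded
least squares (`scipy.optimize.least_squares`, trf, analytic Jacobian)
over a deterministic multi-start grid — slopes {0.5, 1, 2, 5} crossed
with the dose-grid midpoints for c — ranked by initial residual and
polished from the best four starts; equal-RSS ties resolve toward the
smaller slope (the smoother curve), and the exactly flat no-response
curve is always a candidate. A series whose PI range is under 10
percentage points (the DSS activity threshold) is flagged
*unidentifiable*: its potency parameters are not supported by the data.
Absolute IC50 is the 50 %-crossing 10^{c − log10(a/50 − 1)/b}, reported
only when a > 50; EC50 is 10^c.

**DSS.** The drug sensitivity score is the normalized area of the fitted
curve above a minimum-activity threshold t (default 10 % inhibition) over
the tested log-concentration window [x_min, x_max] (defaults to each
series' own range, 4 log-units for a 5-point ten-fold dilution series).
With d = 0 the area has a closed form via the antiderivative
(a/b)·log10(1 + 10^{b(x−c)}); the implementation is checked against a
trapezoid-rule oracle (`dss_numeric`) to 1e−6. DSS1 normalizes the area by
(100 − t)(x_max − x_min); the default DSS2 = DSS1/log10(a) additionally
divides out the top asymptote's magnitude, keeping scores on the ~0–50
scale on which the DSS ≥ 10 effectiveness cutoff operates (for a ≤ 1.01
DSS2 is defined as 0; that region is below any sensible threshold anyway).
Negative fitted responses never contribute: the integrand is (y − t) over
the region y ≥ t only. The selective score is the plain difference
sDSS = DSS_tumor − DSS_control against the healthy-hepatocyte control
model; both scores must come from identical configurations (threshold,
window, variant) — the package errors on mismatched windows rather than
harmonizing silently. Negative sDSS flags control-toxic compounds.

**QC.** Z′ = 1 − 3(σ_pos + σ_neg)/|μ_pos − μ_neg| per plate with sample
SDs; screens are conventionally usable at Z′ > 0.5. The simulator at its
default noise level produces plates comfortably above that bar.

**Hit calling.** Effective ⇔ DSS ≥ 10 and selective ⇔ sDSS ≥ 10, both
inclusive. Low-dose toxicity is operationalized as a parameterized rule —
control-model PI ≥ 50 % at any tested dose strictly below the top
concentration (scope and threshold configurable) — and reported as a flag,
never as silent removal, since the underlying screening practice is a
judgment call with no published numeric criterion. Summaries give
per-model effective/selective counts, union and intersection of selective
sets across models, and a top-N ranking by sDSS with ties broken by
compound id so rankings are reproducible.

## Screen simulator

The generator mirrors the screened library design: 527 compounds plus one
combination entry (modeled as an ordinary compound with its own id), five
ten-fold dilutions from a 10 µM top dose, six tumor models plus one
healthy-control model, ≥16 negative and ≥16 positive control wells per
plate in fixed flanking columns, compounds laid out columnwise. Defaults
chosen once as study conditions where the design leaves them open:
baseline 10 000 and floor 400 luminescence units; multiplicative lognormal
signal noise with CV 5 % (luminescence is positive and right-skewed; an
optional additive row/column drift can stress QC but is off by default);
a quarter of the library active (top 65–100 %, slope 0.8–2.5, EC50 inside
the window), of which 70 % spare the control model — hit-rate scales
matching what such screens report (tens to ~150 effective compounds of
527 per model, ~70 control-toxic). A well at true inhibition PI reads
S = (floor + (baseline − floor)(1 − PI/100))·ε, so DMSO wells sit at
baseline, fully inhibited wells at the positive-control floor, and the
zero-noise pipeline reproduces the planted closed-form DSS to ~1e−13.
All randomness flows from a single named generator seed.

`make_fixture_screen` is a deterministic zero-noise 24-compound fixture
whose planted composition (inactive / shared-selective / single-model /
control-toxic / low-dose-toxic / sub-threshold compounds) is documented in
its docstring; hit calling recovers every planted set exactly, which pins
the whole scoring path end to end.

## Image synthesis and profiling

**Fields.** Four channels (DNA, ER, membrane–actin–nucleic-acid composite
"AGP", mitochondria) of ellipse-shaped cells on a dark background. Nuclei
are single ellipses (normal) or 3–8 disjoint chromatin fragments sharing
the cell's label (fragmented — the mitotic-catastrophe morphology seen
under spindle-poison treatment). Cells are the nucleus ellipse scaled
1.7×; placements are non-overlapping, largest-first, with bounded retries
(a `PlacementError` signals an infeasible density). Rendering adds
per-pixel texture, Gaussian PSF blur (σ 1.5 px), Poisson shot noise and
Gaussian read noise; truth masks are the pre-blur, pre-noise labels.
Fields are 2-D, standing in for the maximum-projection-style planes the
analysis consumes; physically realistic optics and 3-D spheroid rendering
are out of scope.

**Segmentation.** The DNA channel is binarized by minimum-cross-entropy
thresholding — implemented exactly, as the argmin of the cross-entropy
criterion over all observed gray levels (images with >4096 distinct values
are first requantized), and tested against a brute-force oracle. Nuclei:
Euclidean distance transform of the binary, local maxima (min separation
30 px by default) as markers, watershed on the negated distance restricted
to the foreground, then an equivalent-circular-diameter filter discarding
objects outside 40–240 px ("diameter" is defined from area, √(4A/π), since
the filter's source leaves it unspecified). Cells grow from nuclei into
the MCE-thresholded ER foreground by geodesic propagation: a 4-connected
step from p to q costs λ + |I_q − I_p| (λ = 0.05), each pixel joins the
nucleus of minimal accumulated cost, ties break toward the lower label,
and nucleus pixels always belong to their own cell. The implementation is
a deterministic Dijkstra checked against `scipy.sparse.csgraph` shortest
paths.

**Features.** 306 named features per cell over three compartments
(nucleus, cell, cytoplasm = cell∖nucleus) — 13 intensity statistics ×
4 channels × 3 compartments, 10 shape descriptors × 3 compartments
(including an object count that directly separates intact from fragmented
nuclei), and 5 gray-level co-occurrence statistics (contrast, correlation,
energy, homogeneity, entropy) at offsets {1, 5} px, direction-averaged,
per channel per compartment. Texture is computed on intensities
requantized to 16 gray levels within the compartment, with co-occurrence
pairs touching background dropped — this makes the features deterministic
across platforms. Empty cytoplasm yields zeroed features plus a flag
column. The catalog is a documented superset-style stand-in for the
unpublished feature list of the original analysis; only its size (≥300),
naming stability and determinism are contractual.

**Profiling.** Features are standardized per plate against that plate's
DMSO cells (z = (f − μ_DMSO)/σ_DMSO, population SD; constant features are
zeroed and flagged). Embedding is UMAP with a fixed `random_state`
(single-threaded, hence reproducible); it is a pluggable stage whose only
contract here is determinism and row preservation — its internals are not
re-implemented. Treatment-level profiles are group means of normalized
features, clustered agglomeratively with Euclidean distance and average
linkage (the linkage method is unstated in the source practice; average is
the declared choice), groups pre-sorted by name for reproducible
tie-breaks.

Passing the synthetic checks shows the operators are implemented correctly
and the pipeline separates a planted morphological phenotype; it does not
show that real Cell-Painting images — with uneven illumination, touching
cells, debris and focus drift — would segment at the same accuracy.
Illumination correction and 3-D segmentation are explicitly out of scope.
Note that sub-40 px chromatin fragments are, correctly, discarded by the
diameter filter; profiling validation therefore extracts features on the
simulator's truth masks, while segmentation accuracy is validated on
intact-nucleus fields.

## Endpoints

Tumor volume TV = length·width²/2 (mm³), swapping measurements with a
warning if width > length. T/C is the ratio of group mean volumes at a
timepoint. Relative viability/caspase readouts are treated/control mean
fractions with the complementary percent decrease. qPCR fold change is
2^−ΔΔCt with ΔCt = Ct_target − mean(Ct_refs) over the reference genes
(Cyclophilin, GAPDH, PPIB by default); the arithmetic mean of reference
Cts equals the log of the geometric mean of the linear quantities, which
is the standard multi-reference normalization, and fold changes are
invariant to per-plate Ct offsets. The two-sample t-test is Student's
pooled-variance form by default (Welch behind a flag), implemented
directly and cross-checked against `scipy.stats.ttest_ind` to 1e−10;
identical groups define t = 0, p = 1.

## Problem sizes and numerical choices

Validation sizes were chosen so the full suite exercises every path at
desk scale: 1,000 random parameter draws for the DSS oracle equivalence;
200 five-point series at 5 % CV for EC50 recovery; a 100-compound,
3-tumor-model screen for noisy hit recovery (F1 ≥ 0.9); a 1024² field with
20 nuclei of 60–120 px for segmentation (exact count, per-object
IoU ≥ 0.8); and 2 models × 2 treatments × 8 cells on 512² fields for
profiling. Quadrature uses 1e5-point trapezoids; fit tolerances are 1e−10
with at most 300 function evaluations per start; ties and leaf orders are
broken lexicographically everywhere a library does not already guarantee
determinism.

## Known limitations

* The exact inhibition formula, fit constraints and DSS variant of the
  original screen's analytics tool are unpublished; the conventions here
  (formula isolated in one operation, declared constraints, variant as a
  reported config knob) are substitutable by design.
* sDSS requires identical scoring configurations for tumor and control
  rather than harmonizing differing concentration ranges.
* The simulator's noise is purely multiplicative per well; it does not
  model edge effects (beyond the optional linear drift), dispensing
  artifacts, or spheroid-size confounders.
* UMAP coordinates are reproducible only for a fixed seed and library
  version; no meaning is attached to their absolute values.
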