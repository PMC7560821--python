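# Methods

`phenolstm` classifies agricultural land use from one agronomic year of
multispectral satellite image time series with a stacked bidirectional LSTM,
and then interrogates the trained network: which spectral predictors and
which acquisition dates carry the information, how the class probability of
a pixel evolves through the year, and how the hidden-state activations
distribute over time.  Because operational ground-truth data of this kind
(regional in-situ parcel inspections) are not publicly distributable, the
package ships a synthetic scene generator that reproduces the statistical
structure the analysis depends on, so every stage runs end to end and every
interpretability claim can be checked against signal that was planted on
purpose.

## The classification model

Each pixel is a sequence of `T = 30` acquisition dates × 14 predictors: the
12 Sentinel-2-style surface-reflectance bands (B1, B2, B3, B4, B5, B6, B7,
B8, B8a, B9, B11, B12), the vegetation index NDVI = (B8 − B4)/(B8 + B4),
and E_NDVI, the Shannon entropy of NDVI in a local spatial window (a texture
measure).  The recurrent unit is the standard LSTM cell: a tanh-modulated
candidate memory, logistic input/forget/output gates,

    c̃_t = tanh(W_c x_t + U_c h_{t-1} + b_c)
    i_t  = σ(W_i x_t + U_i h_{t-1} + b_i)
    f_t  = σ(W_f x_t + U_f h_{t-1} + b_f)
    c_t  = i_t ⊙ c̃_t + f_t ⊙ c_{t-1}
    o_t  = σ(W_o x_t + U_o h_{t-1} + b_o)
    h_t  = o_t ⊙ tanh(c_t)

A bidirectional layer runs one LSTM forward over the dates and one backward,
concatenating the aligned hidden states; layers are stacked (default two,
100 units per direction) with inverted dropout (default 50%) on each layer's
output in training mode.  The sequence-level representation fed to the
fully-connected softmax head is the concatenation of each direction's final
state — forward after the last date, backward after the first — so both
halves have consumed the entire year.  Initial states are zero.

The forward pass, backpropagation through time and the Adam optimizer are
implemented in NumPy inside the package; the input projections of all
timesteps are batched into one matrix product per layer and direction, so a
CPU run at these problem sizes takes seconds to minutes.  Gradient
correctness is verified against central finite differences in the test
suite, and the forward pass against a fully-unrolled pure-Python scalar
implementation to 1e-12.

### Training defaults and why

| parameter | default | rationale |
|---|---|---|
| layers × hidden units | 2 × 100 | the reference architecture; 1–4 layers supported for sweeps |
| dropout | 0.5, inverted, on every BiLSTM layer's output | regularization between layers and after the last |
| optimizer | Adam, lr 1e-3, batch 256 | common recipe; exposed in `TrainingConfig` |
| epochs | ≤ 50, early stopping patience 8 on a 10% internal validation slice | stops long runs once the validation loss plateaus; best weights restored |
| weight init | uniform ±1/√hidden, forget-gate bias 1, seeded | standard recipe favouring long memory at the start |
| class weighting | off (optional inverse-frequency) | survey class counts are heavily imbalanced and the default mirrors training on raw pixel counts |

Features are z-scored per feature across samples and timesteps; the
statistics are fitted on the training split only and reused for the test
split, which prevents train/test leakage through normalization.

## The synthetic scene generator

Each land-use class is a `PhenologyProfile`: a double-logistic NDVI
trajectory over the agronomic year (day 0 = September 1),

    ndvi(d) = base + amp · [ 1/(1+e^{−r_g (d−d_g)}) − 1/(1+e^{−r_s (d−d_s)}) ],

the standard remote-sensing greenness curve, plus spectral rules that turn
NDVI into 12 bands: B4 and B8 are solved so that (B8−B4)/(B8+B4) equals the
curve exactly before noise (with B4+B8 fixed to the profile's `band_sum`),
every other informative band is a class-specific affine function of NDVI,
non-informative bands (B1 aerosols and B9 water vapour by default) get
class-independent constants, and i.i.d. Gaussian noise per pixel/date/band
is added and clipped to [0, 1].  Parcels are square blocks tiling the grid,
one class per parcel, apportioned by largest remainder on the configured
class proportions; the default 16 classes mirror a Mediterranean survey's
composition — rice and sunflower with strong summer cycles, four winter
cereals with overlapping winter–spring cycles, and permanent/natural classes
(forest, pastures, shrubs, citrus, olive, fruit) with flat, mutually similar
trajectories and survey-like imbalanced proportions down to ~0.2% for the
rarest cereal.  Dates default to 30 evenly spaced days over one
September→August year.

What the generator does *not* emulate: clouds and atmospheric effects (the
analysis assumes cloud-free acquisitions), real parcel geometry, spatial
autocorrelation of noise within parcels beyond the shared class curve,
sensor resampling of the 20 m/60 m bands, and label noise.  Passing tests
therefore demonstrate correctness of the pipeline and recoverability of
planted structure, not performance on real imagery.

Splits are stratified 70/30 at pixel level, or parcel-based (all pixels of
a parcel on one side, stratified by the parcel's class) to expose spatial
leakage; a class owning a single parcel triggers a warning because it must
then be absent from one side.

## Interpretability procedures

**Added-noise permutation relevance.** Gaussian white noise N(0, σ²) with
σ² equal to 3% of the perturbed signal's amplitude is added to one predictor
at all dates (predictor mode) or to all predictors at one date (date mode);
the relevance of the item is the drop in overall accuracy from the
unperturbed baseline, averaged over `n_repeats` draws (default 10), clipped
at zero and normalized to the most relevant item.  Two readings of the 3%
rule exist; the default takes *variance* = 0.03 × amplitude, with amplitude
= max − min of the targeted values over the evaluation set, measured on the
standardized representation the network consumes (which keeps the rule
scale-free).  Relevance is computed on the test split.  A practical caveat
found during development: a classifier that is saturated (≈100% accuracy)
shows no measurable drop for any item, so relevance demonstrations use
scene-noise settings that leave the classifier headroom (~95% baseline).

**Probability evolution.** The per-timestep class-probability trajectory of
one pixel is computed incrementally: at step t the network is evaluated on
the truncated series x_1..x_t, i.e. the probability the classifier would
assign having seen the year only up to that acquisition.  This trajectory
tracks phenology — a rice-like pixel's probability is near-uniform through
winter and rises sharply through the summer cycle.  An alternative
(`method="aligned"`) applies the softmax head to the aligned bidirectional
output at each t; since the backward half has then already consumed the
whole series, those curves are nearly flat and mostly restate the final
decision, which is why the incremental definition is the default.

**Hidden-state activations.** The last BiLSTM layer's outputs in eval mode
are summarized as (i) a units × dates heatmap of mean activations, (ii) the
mean over units and samples of squared activations per date, and (iii) the
same series per class, which recombine exactly (weighted by class counts)
to the pooled series.

A negative result worth documenting: on scenes whose class signal is
confined to a planted date window, the pooled mean-squared-activation curve
does **not** reliably peak inside that window.  Two mechanisms oppose the
localization.  First, with a final-state readout both directions must carry
the class signal from the window to their respective sequence ends, so the
signal's magnitude contribution spreads over all dates.  Second, each unit
integrates its inputs over roughly ten steps from the zero initial state,
producing a mid-sequence bulge (forward ramp plus backward ramp), and after
global z-scoring even the uninformative off-season baseline drives the
units with a constant offset.  This was verified across window placements
(sequence end, middle, narrow spike), 1–4 layers, hidden sizes 8–48,
dropout 0–0.5 and both readings of "mean squared" (square-then-average and
average-then-square).  Per-class curves of strong summer classes do
sometimes peak inside their activity window, matching the qualitative
expectation for annual crops; the corresponding pooled-localization test in
the acceptance suite is kept as stated and fails, recording the finding
rather than weakening the check.

## Numerical choices and degenerate inputs

- NDVI of a pixel with B8 + B4 = 0 is defined as 0, keeping the pipeline
  total on clipped dark pixels.
- E_NDVI: Shannon entropy, base-2 logarithm, 5×5 window, 16 equal-width bins
  on [−1, 1], reflection padding — the entropy's window/binning are a design
  choice (common texture practice at 10 m resolution); a co-occurrence
  (GLCM) entropy is a plausible alternative and is noted, not implemented.
- Zero-variance features standardize with scale 1 and a warning.
- Zero-amplitude perturbation targets are no-ops with a warning; if no
  perturbation reduces accuracy, all relevance scores are 0 and a flag is
  set instead of dividing by zero.
- Softmax probability sums are asserted to 1 within 1e-9; non-finite
  activations or losses abort with explicit errors.
- Prediction ties break toward the lowest class index (argmax convention).
- One master seed derives all stage seeds via `numpy.random.SeedSequence`,
  so full runs, stagewise CLI runs and reruns agree bit for bit.

## Problem sizes

The package's standard demonstrations are desk-scale by design: scenes of
48×48 pixels (four classes, 8×8-pixel parcels) for the relevance and
phenology demonstrations, and an 80×80-pixel, 16-class scene
(6 400 pixels, 4 480 training samples) with a 2×32-unit network for the
end-to-end reproduction script.  These sizes keep a full
train-plus-interpret cycle in the minutes range on one CPU while preserving
every structural property the analyses measure; grid size, parcel size,
class set, dates and noise are all configuration fields for larger runs.

## Known limitations

- No GPU path; very large scenes (10⁶+ pixels) would need minibatched
  streaming of the feature cube and hours of CPU time.
- The GeoTIFF ingestion adapter reads pixel arrays only (nearest-neighbour
  resampling to the label grid); georeferencing metadata is ignored and
  parcel ids default to one parcel per pixel, so parcel-based splits on
  ingested rasters require external parcel information.
- The relevance procedure inherits permutation-importance caveats:
  correlated predictors (NDVI vs B4/B8) share credit, and a redundant
  feature can score near zero even though the information it carries is
  used — the ranking identifies the information family, not unique causal
  contributions.
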