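# Methods

`phenomass` implements a plot-level sorghum fresh-biomass prediction
framework for UAV high-throughput phenotyping campaigns: feature
extraction from hyperspectral spectra, LiDAR point clouds and daily
weather; PCA-loading feature-importance pruning; genotype clustering from
a marker matrix; a stacked-LSTM regression model that fuses the
time-series features with a static genotype-cluster input; and two
transfer-learning strategies that select informative target-trial plots
for fine-tuning. Because no public breeding-trial dataset carries all of
these modalities together, the package ships a synthetic trial generator
whose statistical structure mirrors such a campaign; every empirical claim
in the test suite is made on that generator.

## Synthetic breeding trials

The generator (`trialsim`) emulates a two-panel breeding experiment: a
large testcross ("Tc") panel (default 630 hybrids x 2 replicates) and a
small calibration ("Cal") panel (default 72 hybrids, a stratified subset
of the Tc hybrids), observed on 4 dates per season.

**Genetics.** Hybrids belong to one of `n_subpops` (default 5) latent
subpopulations. Marker dosages (coded 0/1/2) are Binomial(2, p) draws
from subpopulation allele-frequency profiles scattered around a common
ancestral frequency with strong differentiation (Balding–Nichols-style
spread, Fst ≈ 0.25), wide enough that the subpopulations are separable by
PCA. Marker width defaults to 2,000 columns: genotype clustering operates
on the 10 leading principal components, which are insensitive to the raw
width.

**Growth.** Each hybrid carries intrinsic parameters (maximum height `K`,
rate `r`, thermal-time midpoint `m`, and an additive biomass deviation),
shared across trials. Canopy height follows a logistic curve in
cumulative growing-degree days. Subpopulations carry a modest phenology
and stature signature (±80 GDD in `m`, ±5% in `K`), so genotype clusters
are partially visible to the sensors — as photoperiod-sensitive hybrid
groups are in real trials — while the dominant subpopulation biomass
effect (an additive ±`subpop_effect` g/m² term, default 300) is applied
to biomass only and is *not* expressed in the canopy signal. This is the
mechanism behind the genotype-information experiment: a genotype-blind
model can explain the growth-driven share of biomass but systematically
under-predicts the high-yield cluster.

**Biomass.** Fresh biomass (g/m²) is an affine function of end-of-season
relative height plus the subpopulation effect, a hybrid deviation, a
year-keyed environment effect (`env_effect`, default 150 g/m²), a
year-keyed hybrid-by-environment term (`gxe_scale`, default 80), and
plot-level observation noise (`biomass_noise`, default 100). Environment
and GxE substreams are keyed by *year*, not by panel, so two panels grown
the same year share their environment — and two same-year trials with the
domain shift disabled are draws from the same distribution.

**Spectra.** Reflectance on the native 272-band 400–1000 nm grid is a
two-endmember mixture: canopy cover (Beer–Lambert light interception,
`1 − exp(−0.9 h)`) weights a vegetation endmember (pigment-darkened
visible baseline, green peak, and a red-edge sigmoid whose inflection
shifts with vigor) against a field-specific soil line. Noise has three
components with distinct spatial/temporal structure: smooth band-correlated
noise, a fine-scale white-noise floor with a per-date band-dependent
envelope, and per-plot soil-brightness heterogeneity whose amplitude is
drawn per acquisition date (surface moisture varies day to day). Trial-
level draws (soil optics, red-edge gain, canopy-profile coefficients)
make the relative variance of individual features reshuffle between
trials, which is what real campaigns show and what the majority-vote
pruning rule needs to be meaningful.

**Planted redundancy.** Four NIR sub-ranges (905–925, 930–950, 955–975,
980–1000 nm) are reserved: their reflectance is replaced by a baseline
plus one latent factor shared within each pair, decoupled from the canopy
signal. The default catalog integrates exactly these ranges, so the four
resulting features are (i) near-duplicates within each pair (|r| > 0.95)
and (ii) carriers of no between-plot information — the ground truth for
the importance-pruning experiment. A duplicate of a *strong* feature
would not have low PCA-loading importance, so redundancy is planted as
low-information duplication, which is also what the screening rule is
designed to remove. `n_planted_redundant_features` must be even (pairs)
and defaults to 4.

**Point clouds.** Each plot-date segment has 200 ground returns
(z ~ N(0, 1.5 cm)) and 1,000 canopy returns at heights
`h · (0.15 + 0.85 u^e)` over a deterministic grid `u`, with the profile
exponent `e` increasing with maturity (crops get top-heavy) plus per-plot
architecture jitter scaled by `structural_noise`. The deterministic grid
makes the 95th-percentile height exactly monotone in `h` when structural
noise is zero. The 0.15·h floor reflects that canopy returns do not reach
the ground under a closed canopy, and keeps low height percentiles
height-informative.

**Domain shift.** The target trial applies an affine shift to reflectance
(`×1.10 + 0.02` by default), a multiplicative height shift (×1.15) and a
multiplicative biomass shift (×1.25), plus whatever environment difference
its year implies. One knob family spans both the same-year/different-field
and the different-year transfer regimes.

What the generator does **not** emulate: within-plot spatial variability
(a plot is one homogeneous unit per date), georeferencing and
orthorectification artifacts, atmospheric effects, multi-row plot geometry
and border effects, moisture/dry-weight partitioning, and real linkage
disequilibrium structure in the markers. Passing tests therefore
demonstrate that the pipeline recovers the structure it assumes, at
realistic sizes and noise levels — not performance on any particular real
field.

## Feature extraction

The catalog is data (YAML), defaulting to 44 features: 22 hyperspectral
(8 normalised-difference indices, 2 simple ratios, 8 integration ranges,
4 first-derivative red-edge samples), 19 LiDAR (11 height percentiles,
mean, SD, skewness, CV, canopy volume on a 0.1 m planimetric grid, cover
at 0.5/1.0/2.0 m), and 3 cumulative weather features (precipitation,
radiation, GDD at base 10 °C — the sorghum standard). Band lookups are
nearest-wavelength; integration is trapezoidal on the native grid;
derivatives are central differences on the native grid. The default
derivative features are first-order only: second-order central differences
on a ~2.2 nm grid are noise-dominated at any realistic sensor SNR
(order-2 remains available through the catalog). Heights are normalised
to the median ground elevation per segment, which is robust to
ground-classification errors. Missing LiDAR dates are imputed by carrying
the nearest available date's LiDAR block (ties toward the earlier date)
and flagged; this preserves the fixed number of time steps without
inventing growth dynamics. Cumulative weather features use the closed
day interval from sowing to the observation date.

## Importance pruning

For each trial and date, features are column-standardised (hyperspectral
and LiDAR features have incommensurate units) and decomposed by PCA; the
importance of feature *i* is `I_i = Σ_n |W_in| V_n` over the top `n_pcs`
components (default 5), with unit-norm loadings and explained-variance
ratios, and a deterministic sign convention. Each remote-sensing source
(hyperspectral, LiDAR) is screened as its own matrix — the two sensors'
catalogs are independent instruments — and weather features are excluded
(they are constant across the plots of a trial-date). A feature is
flagged within a trial only if it sits among the smallest `⌈qF⌉`
importances at *every* date (default q = 0.25; an all-tied date vetoes
all flags), and removed only if flagged in strictly more than half of the
trials. The `⌈qF⌉`-order-statistic reading of "bottom-q" behaves sensibly
at both ends (one flag slot for small q and F; all features as q → 1).

## Genotype clustering

Markers are column-centred (not variance-scaled — biallelic codings share
a scale) and projected onto 10 principal components; k-means
(k-means++-style seeding, best of 10 restarts) is run for k = 1…k_max and
the within-cluster sum of squares curve is screened by a formalised elbow
rule: the k whose curve point lies farthest from the chord joining the
endpoints, ties toward smaller k, with a flag for numerically straight
curves. The WCSS curve is post-hoc monotonised (a larger k can always
reproduce a smaller k's partition, so any increase is a local-optimum
artifact). Final cluster IDs are relabelled canonically — descending
cluster size, ties by centroid norm — so equal partitions always serialise
identically.

## The recurrent prediction model

The network consumes the per-date feature vector sequence through 2
stacked LSTM cells (hidden size 64 by default); the final hidden state is
concatenated with the encoded genotype cluster and mapped to scalar
biomass by one fully connected layer. It is implemented directly in
NumPy — forward pass, full backpropagation through time, Adam — which
keeps training bit-deterministic under a seed and lets the test suite
verify every gradient against central finite differences (tolerance
1e−6).

Training minimises MSE with Adam at learning rate 5e−4 for up to 1,000
epochs (defaults follow the training protocol the architecture was
designed for); features and the target are z-scored with statistics from
the training split only, and the weights with the lowest validation loss
are retained — the validation split exists, so using it to pick the
snapshot is the standard choice and the only regulariser. The protocol is
3-fold cross-validation: disjoint test thirds, remaining plots split
90/10 into train/validation; reported metrics pool the three folds' test
predictions before computing R²_ref, RMSE and the ranking R²_ref (the
same metric applied to per-hybrid mean biomass).

Two numerical choices matter at desk scale and are deliberate:

* **Output layer zero-initialised.** Epoch-0 predictions then equal the
  scaled target mean; a random output layer applied to a scaled one-hot
  otherwise injects a spurious cluster offset that short training budgets
  never fully unlearn.
* **Static gain.** The one-hot cluster encoding is scaled by
  `static_gain` (default 8). Adam's per-parameter step is capped near the
  learning rate, so an O(1) one-hot would require more optimisation steps
  than short runs provide before the output-layer cluster coefficients
  reach their O(1) targets; the gain divides that requirement by 8.
  At full-protocol step counts the gain is harmless; at reduced epochs it
  is the difference between using and ignoring the genotype input.

The cluster encoding is one-hot by default; an integer encoding is
supported but imposes a false ordinal structure on cluster IDs. The
genotype-blind model variant ("model A") is requested explicitly via
`use_genotype=False`; `n_clusters = 0` is rejected otherwise.

`r2_ref` returns a structured `None` when the reference values are
constant (zero denominator) rather than a number.

## Transfer learning

One third of the target-trial plots is held out as the shared test set;
all four models (source-only, target-trained, and one fine-tuned model
per strategy) are evaluated on it. The **genomic** strategy selects every
non-test target plot whose hybrid is in the calibration panel. The
**phenotype** strategy z-scores the pool's flattened (features × dates)
matrices, clusters them by k-means with k chosen by the same elbow rule
as genotype clustering, and takes the `n_per_cluster` plots nearest each
centre (Euclidean distance; undersized clusters contribute everything
they have, logged). The per-cluster quota defaults to
`ceil(budget / k)` with the budget equal to the calibration-panel hybrid
count, which lands the phenotype selection near half the genomic
selection's plot count at two replicates.

Fine-tuning continues optimisation from the pre-trained weights on the
selected plots only, with all layers trainable at a reduced learning rate
(1e−4, i.e. 0.2× the pre-training rate; an optional freeze-recurrent mode
exists), a 10% validation split of the selection defining the retained
weights, and normalisation statistics refit on the selection — the
fine-tuned model is allowed to see the target domain's scale, the
source-only baseline is not (that asymmetry is the point of the
comparison).

## Study drivers and problem sizes

`phenomass.study` packages the named experiments at desk scale, used by
both the test suite and `scripts/acceptance.py`: redundancy recovery (6
trials × 120 plots, q ∈ {0.15, 0.25, 0.35}), cluster recovery (150
hybrids × 400 markers, 10 seeds), the genotype-information comparison
(100 hybrids × 2 replicates, strong cluster effect of 500 g/m², 100
epochs, batch 32, pooled 3-fold CV), and the transfer comparison (130-
hybrid target with 2 replicates, 20-hybrid calibration source, 150
epochs pre-training, 300-step fine-tuning). These sizes keep a full run
in tens of seconds per seed while leaving every effect detectable;
multi-seed claims use ten consecutive seeds.

## Known limitations

* The simulator's feature redundancy is planted in fixed NIR regions tied
  to the default catalog; a user-supplied catalog that does not integrate
  those regions will not see the planted features (the hidden truth
  records the regions, not catalog names).
* The elbow rule is a formalisation of a visual method; on unstructured
  data it still returns *a* k (smooth curves have a maximal-distance
  point), so the no-elbow flag only fires on numerically straight curves.
* Empty clusters after k-means convergence are handled by scikit-learn's
  initialisation; the degenerate k > distinct-points case reports the
  zero-WCSS solution with a flag.
* Fine-tuning selections below 10 plots are rejected (no validation split
  can be formed) rather than fine-tuned without early stopping.
* The NumPy LSTM is single-threaded and intended for the panel sizes
  above (thousands of plots train in minutes, not seconds).
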