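# phenomass

Plot-level sorghum fresh-biomass prediction from UAV high-throughput
phenotyping data — hyperspectral reflectance, LiDAR point clouds, daily
weather and genetic markers — with transfer-learning sample selection for
breeding programs.

Breeding trials measure end-of-season fresh biomass by destructive
harvest, which caps how many testcross hybrids can be phenotyped. This
package implements a framework that predicts per-plot biomass from
remote sensing instead: per-date features are screened by PCA-loading
importance, high-dimensional markers are compressed to genotype-cluster
IDs, and a stacked-LSTM network consumes the feature time series together
with the static cluster input. Two strategies then transfer a model
trained on a small calibration panel to a large testcross panel using a
small fraction of its plots: the *genomic* strategy fine-tunes on the
target plots whose hybrids appear in the calibration panel; the
*phenotype* strategy clusters the target panel's remote-sensing features
and fine-tunes on the plots nearest each cluster centre.

Because no public dataset carries all of these modalities, the package
includes a synthetic breeding-trial simulator (`phenomass.trialsim`) with
the same statistical structure — subpopulation-structured markers,
logistic growth in thermal time, a soil/vegetation spectral mixing model,
planted-redundant features, and a configurable between-trial domain
shift — so the entire pipeline is testable end to end.

## The model

For plot *i* with feature matrix X_i (N_f features × N_t dates) and
genotype cluster g_i:

    h_i = LSTM₂(LSTM₁(x_i,1 … x_i,N_t))        # 2 stacked cells
    ŷ_i = W [h_i,N_t ; onehot(g_i)] + b        # g/m² fresh biomass

trained by Adam on MSE with 3-fold cross-validation (test thirds;
remaining plots split 90/10 train/validation; best-validation weights
retained). Feature importance for pruning is

    I_f = Σ_n |W_fn| · V_n   over the top 5 PCs,

with W the PCA loadings and V the explained-variance ratios; a feature is
removed if it is low-importance at every date within a trial, in a strict
majority of trials. Accuracy is reported as the reference R²,

    R²_ref = 1 − Σ(y_i − ŷ_i)² / Σ(y_i − ȳ)²,

which is negative for biased predictors, plus RMSE (g/m²) and a ranking
R²_ref on per-hybrid mean biomass.

## Worked example

```python
import phenomass as pm
from phenomass import rnng

cfg = pm.SimConfig(n_hybrids=100, n_markers=400, n_cal_hybrids=20,
                   subpop_effect=500.0, seed=5)
markers = pm.simulate_markers(cfg)
weather = pm.simulate_weather(cfg, year="2019")
trial = pm.simulate_trial(cfg, markers, weather, trial_id="Tc", year="2019")

tensor = pm.extract_trial_features(trial, weather, pm.default_catalog())
clusters = pm.cluster_markers(markers, n_components=10, k_max=10, seed=5)
print("chosen k:", clusters.k)

config = rnng.RNNGConfig(hidden_size=64, epochs=100, batch_size=32, seed=5)
static = rnng.encode_static(
    trial.records["hybrid_id"].map(clusters.assignment), clusters.k, config)
biomass = trial.biomass.set_index("plot_id")["biomass"]
report, models = rnng.fit_cv(tensor, static, biomass, trial.records,
                             config, clusters.k, seed=5)
print(f"pooled test R2_ref: {report.r2_prediction:.3f}")
print(f"RMSE: {report.rmse_prediction:.1f} g/m2")
print(f"ranking R2_ref: {report.r2_ranking:.3f}")
```

prints

```
chosen k: 5
pooled test R2_ref: 0.797
RMSE: 210.1 g/m2
ranking R2_ref: 0.850
```

The elbow rule recovers the five simulated marker subpopulations, and the
cluster-aware model explains ~0.8 of the plot-level biomass variance on
held-out plots; the genotype-blind variant of the same network
(`use_genotype=False`) reaches ~0.43 on the same folds because the
high-yield genotype cluster's biomass advantage is not visible in the
canopy signal.

There is also a command-line surface over the same pipeline:

```sh
phenomass run --config demo.yaml --out runs/demo --seed 7
phenomass cluster --markers markers.csv --out runs/clust --seed 7
phenomass validate --data runs/demo/simulate/target
```

Every stage writes a `manifest.json` with input/output hashes; rerunning
with the same configuration and seed reproduces the manifests byte for
byte.

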