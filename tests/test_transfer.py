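"""Transfer-learning sample selection invariants and fine-tuning
contracts; brute-force oracles for the distance-minimal selection."""

import numpy as np
import pandas as pd
import pytest

import phenomass as pm
from phenomass import rnng
from phenomass.features import FeatureTensor
from phenomass.rnng import RNNGConfig
from phenomass.transfer import (FineTuneConfig, fine_tune, select_genomic,
                                select_phenotype)


def records_for(plots, hybrids):
    return pd.DataFrame({"trial": "T", "year": "2020", "plot_id": plots,
                         "hybrid_id": hybrids,
                         "replicate": [1] * len(plots)})


def tensor_for(X_flat, plots, T=2):
    P, FT = X_flat.shape
    F = FT // T
    vals = X_flat.reshape(P, T, F).transpose(0, 2, 1)
    return FeatureTensor(vals, list(plots), [f"f{i}" for i in range(F)],
                         ["hyperspectral"] * F, list(range(T)), [0.0] * T,
                         np.zeros((P, F, T), dtype=bool))


class TestGenomicSelection:
    def test_all_hybrids_in_cal_selects_whole_pool(self):
        rec = records_for([f"p{i}" for i in range(10)],
                          [f"h{i % 5}" for i in range(10)])
        sel = select_genomic(rec, {f"h{i}" for i in range(5)})
        assert set(sel.plot_ids) == set(rec["plot_id"])

    def test_replicate_counting(self):
        # 72 cal hybrids x 2 replicates, nothing held out -> 144 plots
        hybrids = [f"h{i}" for i in range(100) for _ in range(2)]
        plots = [f"p{i}" for i in range(200)]
        rec = records_for(plots, hybrids)
        cal = {f"h{i}" for i in range(72)}
        sel = select_genomic(rec, cal)
        assert len(sel.plot_ids) == 144
        assert set(sel.hybrid_ids) == cal

    def test_test_plots_excluded(self):
        rec = records_for([f"p{i}" for i in range(6)], ["h0"] * 6)
        sel = select_genomic(rec, {"h0"}, test_plots={"p0", "p1"})
        assert set(sel.plot_ids) == {"p2", "p3", "p4", "p5"}

    def test_selected_hybrids_subset_of_cal_exactly(self, trial):
        cal = set(trial.truth.cal_hybrids)
        sel = select_genomic(trial.records, cal)
        assert set(sel.hybrid_ids) <= cal

    def test_disjoint_panels_rejected(self):
        rec = records_for(["p0"], ["h0"])
        with pytest.raises(ValueError, match="disjoint"):
            select_genomic(rec, {"other"})

    def test_empty_cal_rejected(self):
        rec = records_for(["p0"], ["h0"])
        with pytest.raises(ValueError, match="empty"):
            select_genomic(rec, set())


class TestPhenotypeSelection:
    def test_k1_single_most_central_plot(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 8))
        plots = [f"p{i}" for i in range(12)]
        tens = tensor_for(X, plots)
        rec = records_for(plots, [f"h{i}" for i in range(12)])
        sel = select_phenotype(tens, rec, k=1, n_per_cluster=1, seed=0)
        # oracle: z-score, then nearest to the grand mean
        Z = (X - X.mean(0)) / X.std(0)
        oracle = plots[int(np.argmin(np.linalg.norm(Z - Z.mean(0), axis=1)))]
        assert sel.plot_ids == [oracle]

    def test_two_point_masses(self):
        X = np.vstack([np.zeros((5, 4)), np.full((5, 4), 3.0)])
        X += np.random.default_rng(1).normal(scale=0.01, size=X.shape)
        plots = [f"p{i}" for i in range(10)]
        tens = tensor_for(X, plots)
        rec = records_for(plots, plots)
        sel = select_phenotype(tens, rec, k=2, n_per_cluster=1, seed=0)
        labels = [sel.cluster_of_plot[p] for p in plots]
        assert len(sel.plot_ids) == 2
        assert labels[:5] != labels[5:]

    def test_distance_minimality_against_brute_force(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(loc=c, size=(15, 6))
                       for c in (0.0, 5.0, 10.0)])
        plots = [f"p{i}" for i in range(45)]
        tens = tensor_for(X, plots)
        rec = records_for(plots, plots)
        sel = select_phenotype(tens, rec, k=3, n_per_cluster=3, seed=0)
        for c in range(1, (sel.k or 0) + 1):
            members = [p for p in plots if sel.cluster_of_plot[p] == c]
            chosen = [p for p in sel.plot_ids if sel.cluster_of_plot[p] == c]
            d = {p: sel.distances[p] for p in members}
            max_chosen = max(d[p] for p in chosen)
            for p in set(members) - set(chosen):
                assert d[p] >= max_chosen - 1e-12

    def test_small_cluster_shortfall_logged(self):
        X = np.vstack([np.zeros((2, 4)), np.full((10, 4), 5.0)])
        X += np.random.default_rng(3).normal(scale=0.01, size=X.shape)
        plots = [f"p{i}" for i in range(12)]
        sel = select_phenotype(tensor_for(X, plots),
                               records_for(plots, plots),
                               k=2, n_per_cluster=4, seed=0)
        assert len(sel.shortfall_clusters) == 1
        assert len(sel.plot_ids) == 6  # 2 + 4

    def test_auto_k_covers_phenotypic_regimes(self, small_config, markers):
        """k="auto" selection reaches every hidden genotype cluster present
        in the pool (the regimes differ in growth, hence in features)."""
        hits = 0
        for seed in range(10):
            cfg = pm.SimConfig(n_hybrids=60, n_markers=300, n_cal_hybrids=20,
                               seed=seed)
            m = pm.simulate_markers(cfg)
            w = pm.simulate_weather(cfg)
            tr = pm.simulate_trial(cfg, m, w)
            tens = pm.extract_trial_features(tr, w, pm.default_catalog())
            sel = select_phenotype(tens, tr.records, k="auto",
                                   n_per_cluster=4, seed=seed)
            subpop = {h: s for h, s in tr.truth.subpop_of_hybrid.items()}
            present = {subpop[h] for h in tr.records["hybrid_id"]}
            covered = {subpop[h] for h in sel.hybrid_ids}
            hits += covered == present
        assert hits >= 9


def _packed_study(seed, replicates=2, n_hybrids=80, hidden=32, epochs=120):
    """Simulate a source/target pair and pack it for the transfer runner."""
    cfg = pm.SimConfig(n_hybrids=n_hybrids, n_markers=300, n_cal_hybrids=20,
                       replicates=replicates, seed=seed)
    study = pm.simulate_study(cfg)
    cat = pm.default_catalog()
    asn = pm.cluster_markers(study["markers"], 10, 10, seed=seed)
    c = RNNGConfig(hidden_size=hidden, epochs=epochs, batch_size=32,
                   seed=seed)

    def pack(trial, w):
        tens = pm.extract_trial_features(trial, w, cat)
        cl = trial.records["hybrid_id"].map(asn.assignment)
        return {"tensor": tens,
                "static": rnng.encode_static(cl, asn.k, c),
                "biomass": trial.biomass.set_index("plot_id")["biomass"],
                "records": trial.records}

    return (pack(study["source"], study["weather_source"]),
            pack(study["target"], study["weather_target"]), c, asn)


class TestTransferExperiments:
    def test_phenotype_strategy_sample_efficiency(self):
        """At three replicates and the default per-cluster budget, the
        phenotype strategy uses at most 60% of the plots the genomic
        strategy uses while matching its accuracy (median gap within
        0.05 of the genomic strategy or better)."""
        from phenomass.transfer import run_transfer_experiment
        gaps = []
        for seed in range(1, 6):
            src, tgt, c, asn = _packed_study(seed, replicates=3, hidden=64)
            rep = run_transfer_experiment(src, tgt, c, n_clusters=asn.k,
                                          seed=seed)
            ng = rep.n_training_samples["fine-tuned-genomic"]
            np_ = rep.n_training_samples["fine-tuned-phenotype"]
            assert np_ <= 0.6 * ng, (np_, ng)
            gaps.append(rep.reports["fine-tuned-phenotype"].r2_prediction
                        - rep.reports["fine-tuned-genomic"].r2_prediction)
        assert np.median(gaps) >= -0.05, gaps

    def test_full_pool_fine_tuning_matches_scratch_training(self):
        """Fine-tuning on the entire target training pool is equivalent
        (within noise) to training on the target from scratch."""
        diffs = []
        for seed in range(1, 6):
            src, tgt, c, asn = _packed_study(seed)
            rng = np.random.default_rng(seed)
            plots = tgt["records"]["plot_id"].tolist()
            order = list(np.array(plots)[rng.permutation(len(plots))])
            test = set(order[:len(order) // 3])
            pool = [p for p in plots if p not in test]
            hybrid_of = tgt["records"].set_index("plot_id")["hybrid_id"]

            def fit(pack_, split):
                net = rnng.build_model(c, pack_["tensor"].n_features, 4,
                                       asn.k)
                return rnng.train(net, pack_["tensor"], pack_["static"],
                                  pack_["biomass"], split, c,
                                  n_clusters=asn.k)

            s_plots = src["records"]["plot_id"].tolist()
            nv = max(1, round(0.1 * len(s_plots)))
            src_model = fit(src, {"train": s_plots[nv:],
                                  "val": s_plots[:nv], "test": []})
            nv = max(1, round(0.1 * len(pool)))
            scratch = fit(tgt, {"train": pool[nv:], "val": pool[:nv],
                                "test": sorted(test)})
            sel = pm.SelectionResult("genomic", pool,
                                     hybrid_of.loc[pool].tolist())
            tuned = fine_tune(src_model, tgt["tensor"], tgt["static"],
                              tgt["biomass"], sel,
                              FineTuneConfig(epochs=200, seed=seed))
            pos = {p: i for i, p in enumerate(tgt["tensor"].plot_ids)}
            t_tens = tgt["tensor"].subset_plots(sorted(test))
            t_static = tgt["static"][[pos[p] for p in sorted(test)]]
            r_scratch = rnng.evaluate(scratch, t_tens, t_static,
                                      tgt["biomass"], hybrid_of)
            r_tuned = rnng.evaluate(tuned, t_tens, t_static,
                                    tgt["biomass"], hybrid_of)
            diffs.append(r_tuned.r2_prediction - r_scratch.r2_prediction)
        assert abs(np.median(diffs)) <= 0.1, diffs


class TestFineTune:
    def _pretrained(self, seed=0):
        rng = np.random.default_rng(seed)
        P, F, T = 40, 5, 3
        vals = rng.normal(size=(P, F, T))
        plots = [f"p{i}" for i in range(P)]
        tens = FeatureTensor(vals, plots, [f"f{i}" for i in range(F)],
                             ["hyperspectral"] * F, list(range(T)),
                             [0.0] * T, np.zeros((P, F, T), dtype=bool))
        y = pd.Series(rng.normal(1000, 100, P), index=plots)
        cfg = RNNGConfig(hidden_size=6, epochs=10, batch_size=8,
                         use_genotype=False, seed=seed)
        split = {"train": plots[:30], "val": plots[30:34], "test": plots[34:]}
        net = rnng.build_model(cfg, F, T, 0)
        trained = rnng.train(net, tens, np.zeros((P, 0)), y, split, cfg,
                             n_clusters=0)
        return trained, tens, y, plots

    def test_zero_epochs_is_identity(self):
        trained, tens, y, plots = self._pretrained()
        sel = pm.SelectionResult("genomic", plots[:12], plots[:12])
        out = fine_tune(trained, tens, np.zeros((len(plots), 0)), y, sel,
                        FineTuneConfig(epochs=0))
        for k in trained.params:
            assert np.array_equal(out.params[k], trained.params[k])

    def test_small_selection_rejected(self):
        trained, tens, y, plots = self._pretrained()
        sel = pm.SelectionResult("genomic", plots[:5], plots[:5])
        with pytest.raises(ValueError, match="10"):
            fine_tune(trained, tens, np.zeros((len(plots), 0)), y, sel)

    def test_fine_tuning_changes_weights_and_refits_norm(self):
        trained, tens, y, plots = self._pretrained()
        sel = pm.SelectionResult("genomic", plots[:20], plots[:20])
        out = fine_tune(trained, tens, np.zeros((len(plots), 0)), y, sel,
                        FineTuneConfig(epochs=5, seed=1))
        assert any(not np.array_equal(out.params[k], trained.params[k])
                   for k in trained.params)
        assert out.norm["y_mean"] != trained.norm["y_mean"]

    def test_freeze_recurrent_keeps_lstm_weights(self):
        trained, tens, y, plots = self._pretrained()
        sel = pm.SelectionResult("genomic", plots[:20], plots[:20])
        out = fine_tune(trained, tens, np.zeros((len(plots), 0)), y, sel,
                        FineTuneConfig(epochs=5, freeze_recurrent=True,
                                       seed=1))
        for k in ("Wx0", "Wh0", "b0", "Wx1", "Wh1", "b1"):
            assert np.array_equal(out.params[k], trained.params[k])
        assert not np.array_equal(out.params["Wo"], trained.params["Wo"])
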