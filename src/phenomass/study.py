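"""Reproducible study drivers: the named experiments of the framework run
end to end on simulated breeding trials at desk scale.

Each driver simulates its own inputs from a seed, runs the relevant slice
of the pipeline, and returns plain dicts of measured quantities, so the
same code backs the acceptance tests and the reproduction script.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from . import rnng, transfer, trialsim
from .features import default_catalog, extract_trial_features
from .genoclust import cluster_markers
from .importance import majority_vote_redundant, trial_importance
from .trialsim import SimConfig

__all__ = [
    "PLANTED_FEATURES",
    "redundancy_recovery_study",
    "cluster_recovery_study",
    "genotype_effect_study",
    "transfer_ordering_study",
    "selection_invariant_study",
]

#: Integration features over the reserved no-signal NIR regions; the
#: default catalog maps each planted region to exactly one of these.
PLANTED_FEATURES = frozenset(
    f"aud_{int(lo)}_{int(hi)}" for lo, hi in trialsim.REDUNDANT_REGIONS)


def redundancy_recovery_study(seed: int, n_trials: int = 6,
                              qs=(0.15, 0.25, 0.35), n_pcs: int = 5,
                              n_hybrids: int = 60) -> dict:
    """Plant 4 redundant features across ``n_trials`` year-replicated
    trials; recover them with the low-at-all-dates rule + majority vote.

    Returns per-q: whether the planted set was fully recovered and the
    list of false positives.
    """
    cfg = SimConfig(n_hybrids=n_hybrids, n_markers=300, n_cal_hybrids=20,
                    seed=seed)
    markers = trialsim.simulate_markers(cfg)
    catalog = default_catalog()
    tensors = []
    for i in range(n_trials):
        year = str(2016 + i)
        w = trialsim.simulate_weather(cfg, year=year)
        tr = trialsim.simulate_trial(cfg, markers, w, trial_id=f"T{i}",
                                     year=year)
        tensors.append(extract_trial_features(tr, w, catalog))
    out = {}
    for q in qs:
        flags = {f"T{i}": trial_importance(t, n_pcs, q).flags
                 for i, t in enumerate(tensors)}
        red = majority_vote_redundant(flags)
        out[q] = {"recovered": PLANTED_FEATURES <= red,
                  "false_positives": sorted(red - PLANTED_FEATURES),
                  "n_plots": len(tensors[0].plot_ids)}
    return out


def cluster_recovery_study(seed: int, n_hybrids: int = 150,
                           n_markers: int = 400, n_subpops: int = 5) -> dict:
    """Simulate markers with known subpopulations; cluster via PCA (10
    components) + WCSS elbow; score k and label agreement."""
    cfg = SimConfig(n_hybrids=n_hybrids, n_markers=n_markers,
                    n_subpops=n_subpops, n_cal_hybrids=20, seed=seed)
    markers = trialsim.simulate_markers(cfg)
    out = cluster_markers(markers, n_components=10, k_max=10, seed=seed)
    ari = adjusted_rand_score(markers.subpop_truth, out.labels)
    return {"k": out.k, "ari": float(ari), "n_hybrids": n_hybrids}


def genotype_effect_study(seed: int, n_hybrids: int = 100,
                          subpop_effect: float = 500.0, epochs: int = 100,
                          hidden_size: int = 64,
                          batch_size: int = 32) -> dict:
    """Single-trial comparison of the genotype-blind model (A) and the
    genotype-cluster model (B) under a strong cluster biomass effect.

    Metrics are pooled over the 3 cross-validation folds; the signed error
    on the top-decile-biomass plots quantifies model A's under-prediction
    of high-yielding hybrids.
    """
    cfg = SimConfig(n_hybrids=n_hybrids, n_markers=400, n_cal_hybrids=20,
                    subpop_effect=subpop_effect, seed=seed)
    markers = trialsim.simulate_markers(cfg)
    w = trialsim.simulate_weather(cfg, year="2019")
    tr = trialsim.simulate_trial(cfg, markers, w, trial_id="Tc", year="2019")
    tensor = extract_trial_features(tr, w, default_catalog())
    assignment = cluster_markers(markers, 10, 10, seed=seed)
    biomass = tr.biomass.set_index("plot_id")["biomass"]
    reports = {}
    for name, use_genotype in (("A", False), ("B", True)):
        c = rnng.RNNGConfig(hidden_size=hidden_size, epochs=epochs,
                            batch_size=batch_size,
                            use_genotype=use_genotype, seed=seed)
        static = rnng.encode_static(
            tr.records["hybrid_id"].map(assignment.assignment),
            assignment.k, c)
        rep, _ = rnng.fit_cv(tensor, static, biomass, tr.records, c,
                             assignment.k if use_genotype else 0, seed=seed)
        reports[name] = rep
    df = reports["A"].predictions
    top = df[df["y"] >= df["y"].quantile(0.9)]
    return {
        "r2_a": reports["A"].r2_prediction,
        "r2_b": reports["B"].r2_prediction,
        "rmse_a": reports["A"].rmse_prediction,
        "rmse_b": reports["B"].rmse_prediction,
        "ranking_r2_b": reports["B"].r2_ranking,
        "top_decile_bias_a": float((top["yhat"] - top["y"]).mean()),
        "n_plots": len(tr.records),
    }


def transfer_ordering_study(seed: int, n_hybrids: int = 130,
                            n_cal_hybrids: int = 20, epochs: int = 150,
                            hidden_size: int = 64,
                            batch_size: int = 32) -> dict:
    """Four-model transfer comparison between a small calibration source
    trial and a domain-shifted testcross target trial."""
    cfg = SimConfig(n_hybrids=n_hybrids, n_markers=400,
                    n_cal_hybrids=n_cal_hybrids, seed=seed)
    study = trialsim.simulate_study(cfg)
    catalog = default_catalog()
    assignment = cluster_markers(study["markers"], 10, 10, seed=seed)
    c = rnng.RNNGConfig(hidden_size=hidden_size, epochs=epochs,
                        batch_size=batch_size, seed=seed)

    def pack(trial, weather):
        tensor = extract_trial_features(trial, weather, catalog)
        cl = trial.records["hybrid_id"].map(assignment.assignment)
        return {"tensor": tensor,
                "static": rnng.encode_static(cl, assignment.k, c),
                "biomass": trial.biomass.set_index("plot_id")["biomass"],
                "records": trial.records}

    report = transfer.run_transfer_experiment(
        pack(study["source"], study["weather_source"]),
        pack(study["target"], study["weather_target"]),
        c, n_clusters=assignment.k, seed=seed)
    r2 = {k: rep.r2_prediction for k, rep in report.reports.items()}
    pool = report.n_training_samples["target-trained"]
    out = {
        "r2": r2,
        "rmse": {k: rep.rmse_prediction for k, rep in report.reports.items()},
        "ranking_r2": {k: rep.r2_ranking for k, rep in report.reports.items()},
        "n_training_samples": report.n_training_samples,
        "n_training_hybrids": report.n_training_hybrids,
        "pool_fraction": {
            k: report.n_training_samples[k] / pool
            for k in ("fine-tuned-genomic", "fine-tuned-phenotype")},
        "ordered": (r2["target-trained"] >= r2["fine-tuned-genomic"]
                    and r2["target-trained"] >= r2["fine-tuned-phenotype"]
                    and r2["fine-tuned-genomic"] > r2["source-only"]
                    and r2["fine-tuned-phenotype"] > r2["source-only"]),
        "report": report,
    }
    return out


def selection_invariant_study(seed: int, n_hybrids: int = 60) -> dict:
    """Check both selection strategies' invariants on one simulated trial:
    genomic hybrids within the calibration set, phenotype selection
    distance-minimal per cluster, and genotype-cluster coverage."""
    cfg = SimConfig(n_hybrids=n_hybrids, n_markers=300, n_cal_hybrids=20,
                    seed=seed)
    markers = trialsim.simulate_markers(cfg)
    w = trialsim.simulate_weather(cfg)
    tr = trialsim.simulate_trial(cfg, markers, w)
    tensor = extract_trial_features(tr, w, default_catalog())
    cal = set(tr.truth.cal_hybrids)
    subpop = tr.truth.subpop_of_hybrid
    present = {subpop[h] for h in tr.records["hybrid_id"]}

    gen = transfer.select_genomic(tr.records, cal)
    gen_ok = set(gen.hybrid_ids) <= cal

    phe = transfer.select_phenotype(tensor, tr.records, k="auto",
                                    n_per_cluster=4, seed=seed)
    minimal = True
    for c in range(1, (phe.k or 0) + 1):
        members = [p for p, cl in phe.cluster_of_plot.items() if cl == c]
        chosen = [p for p in phe.plot_ids if phe.cluster_of_plot[p] == c]
        if not chosen:
            continue
        max_chosen = max(phe.distances[p] for p in chosen)
        for p in set(members) - set(chosen):
            if phe.distances[p] < max_chosen - 1e-12:
                minimal = False
    coverage = {
        "genomic": {subpop[h] for h in gen.hybrid_ids} == present,
        "phenotype": {subpop[h] for h in phe.hybrid_ids} == present,
    }
    return {"genomic_subset": gen_ok, "phenotype_minimal": minimal,
            "coverage": coverage, "n_plots": len(tr.records)}
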