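"""Transfer learning across trials: informative-sample selection and
fine-tuning of a pre-trained biomass model in a new (target) trial.

Two selection strategies pick target-domain training plots:

* **genomic** — all non-test target plots whose hybrid also appears in the
  calibration (source) panel;
* **phenotype** — k-means over the z-scored, flattened remote-sensing
  feature matrices of the target pool (k chosen by the same WCSS elbow rule
  as genotype clustering when "auto"); the ``n_per_cluster`` plots nearest
  each cluster centre are selected.

``run_transfer_experiment`` trains the four-model comparison (source-only,
target-trained, and one fine-tuned model per strategy), evaluating all
models on one shared held-out target test third.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import rnng
from .features import FeatureTensor
from .genoclust import _kmeans, elbow_select, wcss_curve
from .rnng import EvalReport, RNNGConfig, TrainedModel

__all__ = [
    "SelectionResult",
    "FineTuneConfig",
    "TransferReport",
    "select_genomic",
    "select_phenotype",
    "fine_tune",
    "run_transfer_experiment",
]


@dataclass
class SelectionResult:
    """Plots chosen by a transfer strategy, with per-cluster provenance."""

    strategy: str                   # "genomic" | "phenotype"
    plot_ids: list[str]
    hybrid_ids: list[str]
    seed: int = 0
    k: int | None = None
    cluster_of_plot: dict[str, int] = field(default_factory=dict)
    centers: np.ndarray | None = None
    per_cluster_counts: dict[int, int] = field(default_factory=dict)
    distances: dict[str, float] = field(default_factory=dict)
    shortfall_clusters: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "plot_id": self.plot_ids,
            "hybrid_id": self.hybrid_ids,
            "cluster": [self.cluster_of_plot.get(p, 0) for p in self.plot_ids],
            "distance": [self.distances.get(p, float("nan"))
                         for p in self.plot_ids],
        })


def select_genomic(records: pd.DataFrame, cal_hybrids: set[str],
                   test_plots: set[str] = frozenset()) -> SelectionResult:
    """All non-test target plots whose hybrid belongs to the calibration
    panel."""
    if not cal_hybrids:
        raise ValueError("calibration hybrid set is empty")
    pool = records[~records["plot_id"].isin(test_plots)]
    sel = pool[pool["hybrid_id"].isin(cal_hybrids)]
    if sel.empty:
        raise ValueError("disjoint panels: no target plot carries a "
                         "calibration-panel hybrid")
    return SelectionResult("genomic", sel["plot_id"].tolist(),
                           sel["hybrid_id"].tolist())


def select_phenotype(tensor: FeatureTensor, records: pd.DataFrame,
                     k: int | str = "auto", n_per_cluster: int = 1,
                     seed: int = 0, k_max: int = 10,
                     test_plots: set[str] = frozenset()) -> SelectionResult:
    """Nearest-to-centroid selection over k-means clusters of the pool's
    remote-sensing features.

    The tensor is restricted to non-test plots, flattened over (features x
    dates), z-scored pool-wide, and clustered.  From each cluster the
    ``n_per_cluster`` plots with the smallest Euclidean distance to the
    centre are selected; clusters smaller than the quota contribute all
    their members (logged in ``shortfall_clusters``).
    """
    pool_ids = [p for p in tensor.plot_ids if p not in test_plots]
    pool = tensor.subset_plots(pool_ids)
    X = pool.values.reshape(len(pool_ids), -1)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    if k == "auto":
        ks, wcss, _ = wcss_curve(Z, range(1, min(k_max, len(pool_ids)) + 1),
                                 seed=seed)
        k, _ = elbow_select(ks, wcss)
    k = int(k)
    if len(pool_ids) < k:
        raise ValueError("pool smaller than k")
    if k == 1:
        centers = Z.mean(axis=0, keepdims=True)
        labels = np.zeros(len(pool_ids), dtype=int)
    else:
        labels, centers, _ = _kmeans(Z, k, seed, n_init=10)
    dist = np.linalg.norm(Z - centers[labels], axis=1)

    hybrid_of = records.set_index("plot_id")["hybrid_id"]
    chosen, shortfall = [], []
    for c in range(centers.shape[0]):
        members = np.flatnonzero(labels == c)
        if len(members) < n_per_cluster:
            shortfall.append(c + 1)
        order = members[np.lexsort((members, dist[members]))]
        chosen.extend(order[:n_per_cluster])
    chosen = sorted(chosen)
    sel_ids = [pool_ids[i] for i in chosen]
    return SelectionResult(
        strategy="phenotype",
        plot_ids=sel_ids,
        hybrid_ids=[str(hybrid_of.loc[p]) for p in sel_ids],
        seed=seed,
        k=int(centers.shape[0]),
        cluster_of_plot={pool_ids[i]: int(labels[i]) + 1 for i in range(len(pool_ids))},
        centers=centers,
        per_cluster_counts={c + 1: int(np.sum(labels[chosen] == c))
                            for c in range(centers.shape[0])},
        distances={pool_ids[i]: float(dist[i]) for i in range(len(pool_ids))},
        shortfall_clusters=shortfall,
    )


@dataclass
class FineTuneConfig:
    """Fine-tuning schedule: reduced learning rate, short run, 10% val."""

    learning_rate: float = 1e-4
    epochs: int = 300
    val_fraction: float = 0.1
    batch_size: int = 32
    freeze_recurrent: bool = False
    seed: int = 0


def fine_tune(pretrained: TrainedModel, tensor: FeatureTensor,
              static: np.ndarray, biomass: pd.Series,
              selection: SelectionResult,
              ft_config: FineTuneConfig | None = None) -> TrainedModel:
    """Continue optimisation from the pre-trained weights on the selected
    plots only; normalisation statistics are refitted on the selection.

    ``epochs=0`` returns the pre-trained model unchanged.
    """
    ft = ft_config or FineTuneConfig()
    if ft.epochs == 0:
        return pretrained
    if len(selection.plot_ids) < 10:
        raise ValueError("selection smaller than 10 plots: cannot form a "
                         "validation split")
    sel = list(selection.plot_ids)
    rng = np.random.default_rng(ft.seed)
    order = list(np.array(sel)[rng.permutation(len(sel))])
    n_val = max(1, round(ft.val_fraction * len(order)))
    split = {"train": order[n_val:], "val": order[:n_val], "test": []}

    cfg = RNNGConfig(
        n_stacked_cells=pretrained.config.n_stacked_cells,
        hidden_size=pretrained.config.hidden_size,
        learning_rate=ft.learning_rate,
        epochs=ft.epochs,
        batch_size=ft.batch_size,
        static_encoding=pretrained.config.static_encoding,
        use_genotype=pretrained.config.use_genotype,
        seed=ft.seed,
    )
    fp = pretrained.fingerprint
    net = rnng.build_model(cfg, len(fp["feature_names"]), fp["n_timesteps"],
                           fp["n_clusters"])
    rnng._check_fingerprint(fp, tensor, static, cfg)
    freeze: tuple[str, ...] = ()
    if ft.freeze_recurrent:
        freeze = tuple(f"{w}{l}" for l in range(cfg.n_stacked_cells)
                       for w in ("Wx", "Wh", "b"))
    return rnng.train(net, tensor, static, biomass, split, cfg,
                      n_clusters=fp["n_clusters"],
                      initial_params=pretrained.params, freeze=freeze)


@dataclass
class TransferReport:
    """Four-model comparison evaluated on one shared target test third."""

    reports: dict[str, EvalReport]
    n_training_samples: dict[str, int]
    n_training_hybrids: dict[str, int]
    test_plots: list[str]
    selections: dict[str, SelectionResult]

    def to_markdown(self) -> str:
        keys = list(self.reports)
        lines = ["| Model | " + " | ".join(keys) + " |",
                 "|---" * (len(keys) + 1) + "|"]

        def fmt(v):
            return "nan" if v is None else f"{v:.2f}"

        lines.append("| Training samples from target panel | " +
                     " | ".join(str(self.n_training_samples[k]) for k in keys) + " |")
        lines.append("| Training hybrids from target panel | " +
                     " | ".join(str(self.n_training_hybrids[k]) for k in keys) + " |")
        lines.append("| R2_ref of prediction | " +
                     " | ".join(fmt(self.reports[k].r2_prediction) for k in keys) + " |")
        lines.append("| RMSE of prediction (g/m2) | " +
                     " | ".join(fmt(self.reports[k].rmse_prediction) for k in keys) + " |")
        lines.append("| R2_ref of ranking | " +
                     " | ".join(fmt(self.reports[k].r2_ranking) for k in keys) + " |")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "metrics": {k: r.to_dict() for k, r in self.reports.items()},
            "n_training_samples": self.n_training_samples,
            "n_training_hybrids": self.n_training_hybrids,
            "n_test_plots": len(self.test_plots),
        }


def run_transfer_experiment(
    source: dict, target: dict, config: RNNGConfig,
    strategies: tuple[str, ...] = ("genomic", "phenotype"),
    ft_config: FineTuneConfig | None = None,
    n_clusters: int = 1,
    cal_hybrids: set[str] | None = None,
    phenotype_budget: int | None = None,
    phenotype_k: int | str = "auto",
    seed: int = 0,
) -> TransferReport:
    """Train and compare the four transfer models.

    ``source`` and ``target`` are dicts with keys ``tensor`` (FeatureTensor,
    same post-pruning catalog), ``static`` (plots x C), ``biomass``
    (pd.Series by plot), ``records`` (plot metadata).  One third of the
    target plots is held out as the shared test set; the target-trained
    baseline and both selections use only the remaining pool.
    """
    if list(source["tensor"].feature_names) != list(target["tensor"].feature_names):
        raise ValueError("source and target must share the feature catalog")
    ft = ft_config or FineTuneConfig(seed=seed)
    rng = np.random.default_rng(seed)
    t_records = target["records"]
    t_plots = t_records["plot_id"].tolist()
    order = list(np.array(t_plots)[rng.permutation(len(t_plots))])
    n_test = round(len(order) / 3)
    test_plots = sorted(order[:n_test])
    pool_plots = [p for p in t_plots if p not in set(test_plots)]
    hybrid_of = t_records.set_index("plot_id")["hybrid_id"]

    pos_t = {p: i for i, p in enumerate(target["tensor"].plot_ids)}

    def static_for(plots):
        return target["static"][[pos_t[p] for p in plots]]

    # --- source-only baseline ----------------------------------------------
    s_records = source["records"]
    s_plots = s_records["plot_id"].tolist()
    s_order = list(np.array(s_plots)[rng.permutation(len(s_plots))])
    n_val = max(1, round(0.1 * len(s_order)))
    s_split = {"train": s_order[n_val:], "val": s_order[:n_val], "test": []}
    net = rnng.build_model(config, source["tensor"].n_features,
                           source["tensor"].values.shape[2], n_clusters)
    source_model = rnng.train(net, source["tensor"], source["static"],
                              source["biomass"], s_split, config,
                              n_clusters=n_clusters)

    # --- target-trained baseline -------------------------------------------
    p_order = list(np.array(pool_plots)[rng.permutation(len(pool_plots))])
    n_val = max(1, round(0.1 * len(p_order)))
    t_split = {"train": p_order[n_val:], "val": p_order[:n_val],
               "test": list(test_plots)}
    net = rnng.build_model(config, target["tensor"].n_features,
                           target["tensor"].values.shape[2], n_clusters)
    target_model = rnng.train(net, target["tensor"], target["static"],
                              target["biomass"], t_split, config,
                              n_clusters=n_clusters)

    # --- selections + fine-tuned models -------------------------------------
    selections: dict[str, SelectionResult] = {}
    models = {"source-only": source_model, "target-trained": target_model}
    if "genomic" in strategies:
        if cal_hybrids is None:
            cal_hybrids = set(s_records["hybrid_id"])
        selections["genomic"] = select_genomic(t_records, set(cal_hybrids),
                                               set(test_plots))
    if "phenotype" in strategies:
        if phenotype_budget is None:
            phenotype_budget = len(set(cal_hybrids or
                                       s_records["hybrid_id"]))
        pool_tensor = target["tensor"].subset_plots(pool_plots)
        # choose k first so the per-cluster quota can honour the budget
        tmp = select_phenotype(pool_tensor, t_records, k=phenotype_k,
                               n_per_cluster=1, seed=seed)
        k_found = tmp.k or 1
        n_per = max(1, math.ceil(phenotype_budget / k_found))
        selections["phenotype"] = select_phenotype(
            pool_tensor, t_records, k=k_found, n_per_cluster=n_per, seed=seed)

    for name, sel in selections.items():
        assert not (set(sel.plot_ids) & set(test_plots)), \
            f"{name} selection leaked into the test set"
        models[f"fine-tuned-{name}"] = fine_tune(
            source_model, target["tensor"], target["static"],
            target["biomass"], sel, ft)

    # --- shared evaluation ---------------------------------------------------
    test_tensor = target["tensor"].subset_plots(test_plots)
    st_test = static_for(test_plots)
    reports, n_samp, n_hyb = {}, {}, {}
    for name, model in models.items():
        reports[name] = rnng.evaluate(model, test_tensor, st_test,
                                      target["biomass"], hybrid_of, fold=name)
        if name == "source-only":
            n_samp[name], n_hyb[name] = 0, 0
        elif name == "target-trained":
            n_samp[name] = len(pool_plots)
            n_hyb[name] = hybrid_of.loc[pool_plots].nunique()
        else:
            sel = selections[name.replace("fine-tuned-", "")]
            n_samp[name] = len(sel.plot_ids)
            n_hyb[name] = len(set(sel.hybrid_ids))
    return TransferReport(reports, n_samp, n_hyb, test_plots, selections)
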