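"""PCA-based feature-importance pruning.

For each trial and observation date, features are column-standardised and a
PCA is run on the plots x features matrix; the importance of feature *i* is

    I_i = sum_n |W_in| * V_n      (n over the top ``n_pcs`` components)

with W the unit-norm loading vectors and V the explained-variance ratios.
A feature is flagged within a trial only if its importance falls in the
bottom-q quantile at *every* observation date; features flagged in strictly
more than half of the trials are declared redundant and removed.

Weather features are excluded by the trial-level driver by default: they
are identical for every plot of a trial-date, so their variance carries no
between-plot information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .features import FeatureTensor

__all__ = [
    "PCAImportance",
    "TrialImportance",
    "pca_importance",
    "flag_low_within_trial",
    "majority_vote_redundant",
    "drop_features",
    "trial_importance",
]


@dataclass
class PCAImportance:
    """Loadings, variance ratios and aggregated importance for one matrix."""

    importance: np.ndarray        # (F,)
    loadings: np.ndarray          # (F, n_pcs), |W| not applied
    variance_ratio: np.ndarray    # (n_pcs,)
    constant_features: np.ndarray  # (F,) bool


def pca_importance(X: np.ndarray, n_pcs: int) -> PCAImportance:
    """Per-feature importance from the top ``n_pcs`` principal components.

    Columns are standardised to zero mean and unit variance (correlation
    PCA); constant columns are excluded from the decomposition, given
    importance 0 and flagged.  The sign of each component is fixed by making
    its largest-magnitude loading positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a plots x features matrix")
    n, F = X.shape
    if n < 2:
        raise ValueError("need at least 2 plots for PCA importance")
    if n_pcs > F:
        raise ValueError(f"n_pcs={n_pcs} exceeds the number of features {F}")

    sd = X.std(axis=0, ddof=0)
    const = sd == 0
    Z = (X[:, ~const] - X[:, ~const].mean(axis=0)) / sd[~const]
    k = min(n_pcs, Z.shape[1], n - 1)
    if k < 1:
        raise ValueError("matrix has no non-constant features")
    pca = PCA(n_components=k, svd_solver="full")
    pca.fit(Z)
    W = pca.components_.T.copy()       # (F', k), unit-norm columns
    V = pca.explained_variance_ratio_.copy()
    # deterministic sign: largest-|loading| entry of each PC made positive
    for j in range(W.shape[1]):
        i = int(np.argmax(np.abs(W[:, j])))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]
    imp_active = np.abs(W) @ V

    importance = np.zeros(F)
    loadings = np.zeros((F, k))
    importance[~const] = imp_active
    loadings[~const] = W
    return PCAImportance(importance, loadings, V, const)


def flag_low_within_trial(per_date_importance: np.ndarray, q: float) -> np.ndarray:
    """Flag features whose importance is in the bottom-q quantile at every
    date of the trial.

    ``per_date_importance`` is (n_dates, n_features).  A date on which all
    importances are equal flags nothing (conservative tie-breaking), so a
    degenerate date vetoes every flag.
    """
    imp = np.asarray(per_date_importance, dtype=float)
    if imp.ndim != 2 or imp.shape[0] < 1:
        raise ValueError("need a (n_dates, n_features) importance array")
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    flags = np.ones(imp.shape[1], dtype=bool)
    n_low = int(np.ceil(q * imp.shape[1]))  # bottom-q = smallest ceil(qF)
    for row in imp:
        if np.all(row == row[0]):
            return np.zeros(imp.shape[1], dtype=bool)
        cutoff = np.sort(row)[n_low - 1]
        flags &= row <= cutoff
    return flags


def majority_vote_redundant(per_trial_flags: dict[str, dict[str, bool]]) -> set[str]:
    """Features flagged in strictly more than half of the trials.

    ``per_trial_flags`` maps trial id -> {feature name: flag}; all trials
    must share the same feature catalog.
    """
    if not per_trial_flags:
        raise ValueError("need at least one trial")
    trials = list(per_trial_flags.values())
    names = set(trials[0])
    for tid, flags in per_trial_flags.items():
        diff = names.symmetric_difference(flags)
        if diff:
            raise ValueError(f"trial {tid!r} catalog mismatch: {sorted(diff)}")
    n = len(trials)
    return {f for f in names if sum(fl[f] for fl in trials) > n / 2}


def drop_features(tensor: FeatureTensor, redundant: set[str]) -> FeatureTensor:
    """Remove redundant feature slabs, preserving survivor order."""
    return tensor.drop_features(redundant)


@dataclass
class TrialImportance:
    """Per-date importance and low-importance flags for one trial."""

    feature_names: list[str]
    per_date: np.ndarray          # (n_dates, n_features)
    per_date_pca: list[PCAImportance]
    flags: dict[str, bool] = field(default_factory=dict)


def _block_importance(tensor: FeatureTensor, features: list[str],
                      n_pcs: int, q: float) -> TrialImportance:
    T = len(tensor.dates)
    per_date = np.empty((T, len(features)))
    pcas = []
    for t in range(T):
        res = pca_importance(tensor.matrix_for_date(t, features),
                             min(n_pcs, len(features)))
        per_date[t] = res.importance
        pcas.append(res)
    flags = flag_low_within_trial(per_date, q)
    return TrialImportance(list(features), per_date, pcas,
                           dict(zip(features, map(bool, flags))))


def trial_importance(tensor: FeatureTensor, n_pcs: int = 5, q: float = 0.25,
                     features: list[str] | None = None) -> TrialImportance:
    """Run the per-date importance analysis over one trial's tensor.

    By default each remote-sensing source (hyperspectral, LiDAR) is
    analysed as its own plots x features matrix — mirroring how the two
    sensors' feature sets are screened independently — and the flags are
    concatenated.  Weather features are excluded: they are constant across
    the plots of a trial-date and carry no between-plot variance.  Passing
    an explicit ``features`` list runs a single joint analysis instead.
    """
    if features is not None:
        return _block_importance(tensor, list(features), n_pcs, q)
    blocks = []
    for source in ("hyperspectral", "lidar"):
        names = [n for n, s in zip(tensor.feature_names, tensor.feature_sources)
                 if s == source]
        if names:
            blocks.append(_block_importance(tensor, names, n_pcs, q))
    if not blocks:
        raise ValueError("tensor has no remote-sensing features")
    feature_names = [n for b in blocks for n in b.feature_names]
    per_date = np.concatenate([b.per_date for b in blocks], axis=1)
    pcas = [p for b in blocks for p in b.per_date_pca]
    flags = {n: f for b in blocks for n, f in b.flags.items()}
    return TrialImportance(feature_names, per_date, pcas, flags)
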