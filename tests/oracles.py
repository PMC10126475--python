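"""Independent numerical oracles used by the test suite."""

import numpy as np


def eigen_oracle_importance(X, n_pcs, iters=5000):
    """Loading-magnitude importance computed via power iteration with
    deflation on the correlation matrix — an eigendecomposition path
    independent of the implementation's SVD."""
    X = np.asarray(X, dtype=float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    C = (Z.T @ Z) / len(Z)
    total_var = np.trace(C)
    F = C.shape[0]
    rng = np.random.default_rng(0)
    vecs, vals = [], []
    M = C.copy()
    for _ in range(min(n_pcs, F)):
        v = rng.normal(size=F)
        for _ in range(iters):
            v_new = M @ v
            norm = np.linalg.norm(v_new)
            if norm == 0:
                break
            v_new /= norm
            if np.linalg.norm(v_new - v) < 1e-14 or \
               np.linalg.norm(v_new + v) < 1e-14:
                v = v_new
                break
            v = v_new
        lam = float(v @ M @ v)
        vecs.append(v)
        vals.append(max(lam, 0.0))
        M = M - lam * np.outer(v, v)
    W = np.column_stack(vecs)
    V = np.array(vals) / total_var
    return np.abs(W) @ V
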