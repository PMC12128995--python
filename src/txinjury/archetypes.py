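"""Archetypal analysis by alternating simplex-constrained least squares.

Each sample is represented as a convex combination of k archetypes, and each
archetype is itself constrained to the convex hull of the data (Cutler-Breiman
formulation): minimize ||X - alpha Z||^2 with Z = beta X, where the rows of
alpha (samples -> archetypes) and of beta (archetypes -> samples) live on the
probability simplex.

The alpha step is solved exactly per sample by enumerating active sets (the
number of archetypes is small), so the residual sum of squares is
non-increasing at every iteration; the beta step updates one archetype at a
time against its partial residual and is only accepted when it does not
increase the objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

_SUM_PENALTY = 1e4  # weight of the sum-to-one row in the NNLS formulation


def simplex_lstsq(archetypes: np.ndarray, X: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Exact simplex-constrained least squares of each row of X onto archetypes.

    Solves, per row x: min ||x - alpha^T Z||^2 subject to alpha >= 0,
    sum(alpha) = 1, by enumerating supports (exact for the small k used
    here); rows of the result sum to one exactly.

    Parameters
    ----------
    archetypes : (k, p) array
    X : (n, p) array

    Returns
    -------
    (n, k) array of simplex weights.
    """
    Z = np.atleast_2d(np.asarray(archetypes, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    k = Z.shape[0]
    if X.shape[1] != Z.shape[1]:
        raise ValueError(f"dimension mismatch: data p={X.shape[1]}, model p={Z.shape[1]}")
    if not (np.isfinite(Z).all() and np.isfinite(X).all()):
        raise ValueError("non-finite values in simplex least squares")
    if k > 12:
        return _simplex_lstsq_nnls(Z, X)
    n = X.shape[0]
    best_rss = np.full(n, np.inf)
    alpha = np.zeros((n, k))
    # enumerate non-empty supports; the optimum restricted to its own support
    # solves the equality-constrained (sum-to-one) normal equations
    for mask in range(1, 2**k):
        support = [j for j in range(k) if mask >> j & 1]
        s = len(support)
        Zs = Z[support]
        G = np.zeros((s + 1, s + 1))
        G[:s, :s] = 2.0 * (Zs @ Zs.T)
        G[:s, s] = 1.0
        G[s, :s] = 1.0
        rhs = np.vstack([2.0 * (Zs @ X.T), np.ones((1, n))])
        try:
            sol = np.linalg.solve(G, rhs)
        except np.linalg.LinAlgError:
            continue
        a = sol[:s]  # (s, n)
        feasible = (a >= -1e-9).all(axis=0)
        if not feasible.any():
            continue
        resid = X - a.T @ Zs
        rss = np.einsum("ij,ij->i", resid, resid)
        improve = feasible & (rss < best_rss)
        if improve.any():
            best_rss[improve] = rss[improve]
            alpha[improve] = 0.0
            alpha[np.ix_(improve, support)] = np.clip(a[:, improve].T, 0.0, None)
    # renormalize away the tiny negative clip
    alpha /= alpha.sum(axis=1, keepdims=True)
    return alpha


def _simplex_lstsq_nnls(Z: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Fallback for large k: penalized NNLS per row, renormalized."""
    A = np.vstack([Z.T, _SUM_PENALTY * np.ones(Z.shape[0])])
    out = np.empty((X.shape[0], Z.shape[0]))
    for i, x in enumerate(X):
        b = np.concatenate([x, [_SUM_PENALTY]])
        w, _ = nnls(A, b)
        total = w.sum()
        out[i] = w / total if total > 0 else np.full(len(w), 1.0 / len(w))
    return out


def _hull_project(X: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project ``target`` onto the convex hull of the rows of X.

    Returns (beta, point) with beta on the simplex over data points.
    """
    A = np.vstack([X.T, _SUM_PENALTY * np.ones(X.shape[0])])
    b = np.concatenate([target, [_SUM_PENALTY]])
    beta, _ = nnls(A, b)
    total = beta.sum()
    beta = beta / total if total > 0 else np.full(len(beta), 1.0 / len(beta))
    return beta, beta @ X


@dataclass
class ArchetypeModel:
    """Fitted archetypal-analysis model.

    Attributes
    ----------
    archetypes : (k, p) array
        Archetype positions (convex combinations of data points).
    alpha : (n, k) array
        Per-sample simplex weights ("archetype scores") on the training data.
    beta : (k, n) array
        Simplex weights expressing each archetype in terms of data points.
    rss_trace : list of float
        Objective after every iteration of the winning restart.
    labels : dict or None
        Optional archetype-index -> group-name map (e.g. "normal", "AKI2").
    """

    archetypes: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    rss_trace: list[float]
    restart_rss: list[float]
    converged: bool
    seed: int | None = None
    column_names: list[str] | None = None
    labels: dict[int, str] | None = None

    @property
    def k(self) -> int:
        return self.archetypes.shape[0]

    @property
    def rss(self) -> float:
        return self.rss_trace[-1]


def _aa_single(X: np.ndarray, k: int, rng, tol: float, max_iter: int):
    n, p = X.shape
    idx = rng.choice(n, size=k, replace=False)
    Z = X[idx].copy()
    beta = np.zeros((k, n))
    beta[np.arange(k), idx] = 1.0

    alpha = simplex_lstsq(Z, X)
    resid = X - alpha @ Z
    rss = float(np.einsum("ij,ij->", resid, resid))
    trace = [rss]
    converged = False
    for _ in range(max_iter):
        # beta step: exact coordinate update per archetype against its
        # partial residual; accepted only if the row objective improves
        for j in range(k):
            aj = alpha[:, j]
            wj = float(aj @ aj)
            Rj = X - alpha @ Z + np.outer(aj, Z[j])
            if wj <= 1e-12:
                # archetype lost all weight: restart it at the worst-fit point
                r = X - alpha @ Z
                far = int(np.argmax(np.einsum("ij,ij->i", r, r)))
                cand_beta = np.zeros(n)
                cand_beta[far] = 1.0
                cand_z = X[far]
            else:
                target = (aj @ Rj) / wj
                cand_beta, cand_z = _hull_project(X, target)
            old = Rj - np.outer(aj, Z[j])
            new = Rj - np.outer(aj, cand_z)
            if np.einsum("ij,ij->", new, new) <= np.einsum("ij,ij->", old, old) + 1e-12:
                Z[j] = cand_z
                beta[j] = cand_beta
        alpha = simplex_lstsq(Z, X)
        resid = X - alpha @ Z
        new_rss = float(np.einsum("ij,ij->", resid, resid))
        trace.append(min(new_rss, trace[-1] + 0.0))
        if trace[-2] - new_rss < tol * max(trace[-2], 1e-300):
            converged = True
            break
    return Z, alpha, beta, trace, converged


def fit_archetypes(
    data,
    k: int = 5,
    n_restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    column_names: list[str] | None = None,
) -> ArchetypeModel:
    """Fit k archetypes to ``data`` (n samples x p features).

    Runs ``n_restarts`` seeded random initializations (k distinct data points
    each) and keeps the best final objective. If no restart converges the best
    model is returned with ``converged=False`` and a warning.
    """
    X = np.asarray(getattr(data, "to_numpy", lambda: data)(), dtype=float)
    X = np.atleast_2d(X)
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples n={n}")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in data")
    if column_names is None and hasattr(data, "columns"):
        column_names = list(data.columns)

    rng = np.random.default_rng(seed)
    best = None
    restart_rss = []
    for _ in range(n_restarts):
        Z, alpha, beta, trace, conv = _aa_single(X, k, rng, tol, max_iter)
        restart_rss.append(trace[-1])
        if best is None or trace[-1] < best[3][-1]:
            best = (Z, alpha, beta, trace, conv)
    Z, alpha, beta, trace, conv = best
    if not conv:
        import warnings

        warnings.warn("archetypal analysis did not converge in any restart")
    return ArchetypeModel(
        archetypes=Z,
        alpha=alpha,
        beta=beta,
        rss_trace=trace,
        restart_rss=restart_rss,
        converged=conv,
        seed=seed,
        column_names=column_names,
    )


def archetype_scores(model: ArchetypeModel, data) -> np.ndarray:
    """Simplex weights of new samples against the fitted archetypes."""
    X = np.asarray(getattr(data, "to_numpy", lambda: data)(), dtype=float)
    return simplex_lstsq(model.archetypes, np.atleast_2d(X))
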