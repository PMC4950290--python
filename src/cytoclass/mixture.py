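"""Diagonal-covariance Gaussian mixtures fitted by EM on discretized codes.

The responder profiles (ordinal codes, treated as numeric) are modelled as
a k-component Gaussian mixture with diagonal covariance. Parameters are
estimated by expectation–maximization from multiple random restarts; the
number of components is chosen by v-fold cross-validation with a forward
search that stops as soon as the mean held-out log-likelihood stops
improving. Subjects are assigned to their highest-posterior class, with
the a-priori nonresponder class kept as a fixed label 0 outside the fit,
so a k-component responder model yields k+1 analysis classes.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.model_selection import KFold

from cytoclass.discretize import codes_matrix

_LOG_2PI = np.log(2.0 * np.pi)


@dataclasses.dataclass
class MixtureModel:
    """Fitted mixture: weights plus per-component, per-feature mean/sd.

    Components are stored in canonical order (ascending by mean of feature
    1 then feature 0 — IL-13 then IL-5 in the pipeline's feature space),
    so the last component is reproducibly the high-Th2 class.
    ``loglik_trace`` records the total training log-likelihood after every
    EM iteration of the winning restart; it is non-decreasing up to
    floating-point tolerance.
    """

    k: int
    weights: np.ndarray          # (k,)
    means: np.ndarray            # (k, d)
    sds: np.ndarray              # (k, d)
    loglik: float
    loglik_trace: np.ndarray
    n_iter: int
    seed: int
    sd_floor: float = 1e-6

    def log_joint(self, X: np.ndarray) -> np.ndarray:
        """(n, k) matrix of log w_j + log N(x_i | mu_j, diag sd_j^2)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return _log_joint(X, X ** 2, self.weights, self.means, self.sds, X.shape[1])

    def log_likelihood(self, X: np.ndarray) -> float:
        """Total log-likelihood of X under the model."""
        return float(logsumexp(self.log_joint(X), axis=1).sum())

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """(n, k) component posteriors (softmax-normalized log joints)."""
        lj = self.log_joint(X)
        return np.exp(lj - logsumexp(lj, axis=1, keepdims=True))

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loglik": self.loglik,
            "loglik_trace": np.asarray(self.loglik_trace).tolist(),
            "n_iter": self.n_iter,
            "seed": self.seed,
            "sd_floor": self.sd_floor,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureModel":
        return cls(
            k=int(d["k"]),
            weights=np.asarray(d["weights"], dtype=float),
            means=np.asarray(d["means"], dtype=float),
            sds=np.asarray(d["sds"], dtype=float),
            loglik=float(d["loglik"]),
            loglik_trace=np.asarray(d["loglik_trace"], dtype=float),
            n_iter=int(d["n_iter"]),
            seed=int(d["seed"]),
            sd_floor=float(d.get("sd_floor", 1e-6)),
        )

    @classmethod
    def from_json(cls, path) -> "MixtureModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _canonical_order(means: np.ndarray) -> np.ndarray:
    """Sort components ascending by (feature 1, feature 0, rest) means."""
    d = means.shape[1]
    if d >= 2:
        keys = [means[:, j] for j in range(d - 1, 1, -1)] + [means[:, 0], means[:, 1]]
    else:
        keys = [means[:, 0]]
    return np.lexsort(keys)


def _log_joint(X, X2, weights, means, sds, d):
    """(n, k) log w_j + log N(x | mu_j, diag sd_j^2).

    Uses a two-GEMM expansion of the quadratic form for speed; when any
    sd is near the floor the expansion cancels catastrophically (terms
    ~1/sd^2), so the exact centered form is used instead.
    """
    const = np.log(sds).sum(axis=1) + 0.5 * d * _LOG_2PI
    with np.errstate(divide="ignore"):
        log_w = np.where(weights > 0, np.log(np.maximum(weights, 1e-300)), -np.inf)
    if sds.min() < 1e-3:
        z = (X[:, None, :] - means[None, :, :]) / sds[None, :, :]
        quad = 0.5 * (z ** 2).sum(axis=2)
    else:
        inv2 = 0.5 / (sds ** 2)                   # (k, d)
        quad = X2 @ inv2.T - X @ (2.0 * means * inv2).T + (means ** 2 * inv2).sum(axis=1)
    return log_w - const - quad


def _em_single(X: np.ndarray, k: int, rng, tol: float, max_iter: int, sd_floor: float):
    n, d = X.shape
    X2 = X ** 2
    # k-means++-style init: first center uniform, then data points drawn
    # with probability proportional to squared distance from the nearest
    # chosen center (jittered so duplicate code vectors stay distinct)
    centers = [X[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min([((X - c) ** 2).sum(axis=1) for c in centers], axis=0)
        total = d2.sum()
        if total <= 0:
            centers.append(X[rng.integers(n)])
        else:
            centers.append(X[rng.choice(n, p=d2 / total)])
    means = np.asarray(centers) + rng.normal(scale=1e-3, size=(k, d))
    # diffuse start: global per-feature sd and uniform weights let the
    # E-step apportion responsibility before the components localize
    global_sd = np.maximum(X.std(axis=0), 0.5)
    sds = np.tile(global_sd, (k, 1))
    weights = np.full(k, 1.0 / k)

    trace = []
    prev_ll = -np.inf
    for it in range(max_iter):
        lj = _log_joint(X, X2, weights, means, sds, d)
        norm = logsumexp(lj, axis=1, keepdims=True)
        ll = float(norm.sum())
        resp = np.exp(lj - norm)
        trace.append(ll)
        if ll - prev_ll < tol and it > 0:
            break
        prev_ll = ll
        # M-step
        nk = resp.sum(axis=0)
        safe_nk = np.maximum(nk, 1e-12)
        weights = nk / n
        new_means = (resp.T @ X) / safe_nk[:, None]
        sq = (resp.T @ X2) / safe_nk[:, None]
        var = np.maximum(sq - new_means ** 2, sd_floor ** 2)
        # components that lost all responsibility keep their parameters
        dead = nk < 1e-12
        means = np.where(dead[:, None], means, new_means)
        sds = np.where(dead[:, None], sds, np.sqrt(var))
    return weights, means, sds, trace


def em_fit(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_restarts: int = 10,
    sd_floor: float = 1e-6,
) -> MixtureModel:
    """Fit a k-component diagonal Gaussian mixture by EM.

    Runs ``n_restarts`` random initializations (k distinct data points as
    starting means) and returns the fit with the best final training
    log-likelihood, with components renumbered into canonical order.
    Standard deviations are floored at ``sd_floor`` to keep degenerate
    (point-mass) components finite.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"need at least k={k} observations, got {n}")
    if not np.all(np.isfinite(X)):
        raise ValueError("codes must be finite")

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        weights, means, sds, trace = _em_single(X, k, rng, tol, max_iter, sd_floor)
        if best is None or trace[-1] > best[3][-1]:
            best = (weights, means, sds, trace)
    weights, means, sds, trace = best
    arr = np.asarray(trace)
    if len(arr) > 1:
        drops = np.diff(arr) + 1e-8 * np.maximum(1.0, np.abs(arr[:-1]))
        if np.any(drops < 0):
            raise AssertionError("EM log-likelihood decreased beyond tolerance")
    order = _canonical_order(means)
    model = MixtureModel(
        k=k,
        weights=weights[order],
        means=means[order],
        sds=sds[order],
        loglik=trace[-1],
        loglik_trace=np.asarray(trace),
        n_iter=len(trace),
        seed=seed,
        sd_floor=sd_floor,
    )
    return model


def select_k_cv(
    X: np.ndarray,
    k_max: int = 8,
    folds: int = 10,
    seed: int = 0,
    min_improvement: float = 1e-6,
    n_restarts: int = 3,
    **em_kwargs,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of components by forward cross-validated search.

    For k = 1, 2, …: the mean held-out log-likelihood per observation over
    ``folds`` CV folds is computed; k keeps increasing while the CV score
    improves by more than ``min_improvement`` and stops at the first
    non-improving k (capped at ``k_max``). Returns the selected k together
    with the per-k CV table (reported even for the k that ended the
    search). Fold fits default to fewer random restarts (3) than a final
    fit, since the score averages over folds.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = len(X)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError("need at least `folds` observations")

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed % (2 ** 32))
    splits = list(kf.split(X))
    rows = []
    best_score = -np.inf
    selected = 1
    for k in range(1, k_max + 1):
        scores = []
        for f, (tr, te) in enumerate(splits):
            if len(tr) < k:
                scores.append(-np.inf)
                continue
            m = em_fit(X[tr], k, seed=seed + 1009 * k + f, n_restarts=n_restarts, **em_kwargs)
            scores.append(m.log_likelihood(X[te]) / len(te))
        score = float(np.mean(scores))
        improved = score > best_score + min_improvement
        rows.append({"k": k, "cv_loglik": score, "improved": improved})
        if improved:
            best_score = score
            selected = k
        else:
            break
    table = pd.DataFrame(rows)
    return selected, table


def assign(
    model: MixtureModel,
    codes: pd.DataFrame,
    class0_ids=(),
) -> pd.DataFrame:
    """Max-posterior class assignment for all subjects.

    Responders (rows of ``codes``) receive the model posterior over the k
    fitted components, renumbered 1..k, and a hard label equal to the
    argmax (ties broken toward the lowest class index). Subjects in
    ``class0_ids`` — the a-priori nonresponders — get the fixed label 0
    with a degenerate posterior. Columns: ``subject_id``, ``p_class0`` …
    ``p_class<k>``, ``hard_label``.
    """
    k = model.k
    X = codes_matrix(codes)
    post = model.posterior(X) if len(X) else np.zeros((0, k))
    resp_ids = list(codes["subject_id"])
    overlap = set(resp_ids) & set(class0_ids)
    if overlap:
        raise ValueError(f"subjects appear both as responders and Class 0: {sorted(overlap)[:5]}")

    n0 = len(class0_ids)
    ids = list(class0_ids) + resp_ids
    p = np.zeros((len(ids), k + 1))
    p[:n0, 0] = 1.0
    p[n0:, 1:] = post
    hard = np.concatenate([np.zeros(n0, dtype=int), post.argmax(axis=1) + 1 if len(X) else np.empty(0, dtype=int)])
    out = pd.DataFrame({"subject_id": ids})
    for j in range(k + 1):
        out[f"p_class{j}"] = p[:, j]
    out["hard_label"] = hard.astype(int)
    return out
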