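"""Chemometric layer: PCA, single-response PLS with LOOCV, validation, ANOVA.

The PLS implementation is the classical single-response NIPALS algorithm
with X- and y-deflation; for one response the inner power iteration
converges in a single pass, so each factor is extracted directly.  Factors
are nested, which LOOCV exploits: one fit at max_factors per left-out
sample yields held-out predictions at every smaller factor count.

Validation follows standard chemometric practice: RMSEC / R_cal^2 on the
calibration fit, RMSECV / R_cv^2 from leave-one-out held-out predictions,
RPD = SD(reference) / RMSECV, and per-group recovery (measured/predicted
x 100) with its coefficient of variation on independent prediction sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "PCAResult",
    "PLSModel",
    "CVReport",
    "GroupValidation",
    "PredictionReport",
    "pca",
    "pls_fit",
    "pls_predict",
    "pls_loocv",
    "predict_and_validate",
    "recovery_percent",
    "anova_cld",
]


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PCAResult:
    scores: np.ndarray        # samples x components
    loadings: np.ndarray      # variables x components, orthonormal columns
    explained_pct: np.ndarray  # % of total variance per component
    mean: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.loadings.T + self.mean


def pca(X: np.ndarray, n_components: int | None = None) -> PCAResult:
    """Column-mean-centered principal component analysis via SVD.

    Sign convention: in each loading column the entry of largest magnitude
    is made positive.  explained_pct is relative to the total variance of
    the centered matrix, so it sums to 100 only when all components are
    kept.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be 2-D with at least 2 samples")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_components is None:
        n_components = max_rank
    if not 1 <= n_components <= max_rank:
        raise ValueError(f"n_components must be in 1..{max_rank}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float((s**2).sum())
    explained = (
        100.0 * s[:n_components] ** 2 / total_var
        if total_var > 0
        else np.zeros(n_components)
    )
    loadings = Vt[:n_components].T
    scores = U[:, :n_components] * s[:n_components]
    for j in range(n_components):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_pct=explained,
        mean=mean,
    )


# --------------------------------------------------------------------------
# PLS (single response, NIPALS)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PLSModel:
    n_factors: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray      # variables x factors (unit norm columns)
    x_loadings: np.ndarray   # variables x factors
    y_loadings: np.ndarray   # factors
    coefficients: np.ndarray  # variables, for centered X -> centered y
    degenerate: bool = False  # zero-variance response


def _nipals_factors(Xc: np.ndarray, yc: np.ndarray, n_factors: int, tol: float = 1e-12):
    """Extract NIPALS weight/loading sequences from centered data."""
    n, p = Xc.shape
    W = np.zeros((p, n_factors))
    P = np.zeros((p, n_factors))
    q = np.zeros(n_factors)
    X_work = Xc.copy()
    y_work = yc.copy()
    k_eff = 0
    for k in range(n_factors):
        w = X_work.T @ y_work
        norm = np.linalg.norm(w)
        if norm < tol * max(1.0, np.linalg.norm(Xc)):
            break
        w /= norm
        t = X_work @ w
        tt = float(t @ t)
        if tt < tol:
            break
        p_k = X_work.T @ t / tt
        q_k = float(y_work @ t) / tt
        X_work -= np.outer(t, p_k)
        y_work = y_work - q_k * t
        W[:, k] = w
        P[:, k] = p_k
        q[k] = q_k
        k_eff += 1
    return W[:, :k_eff], P[:, :k_eff], q[:k_eff]


def _coefficients(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    if W.shape[1] == 0:
        return np.zeros(W.shape[0])
    return W @ np.linalg.solve(P.T @ W, q)


def pls_fit(X: np.ndarray, y: np.ndarray, n_factors: int) -> PLSModel:
    """Fit a single-response PLS model by NIPALS with deflation.

    With n_factors equal to the rank of centered X the fit coincides with
    least squares.  A zero-variance response yields a degenerate model
    whose predictions are the constant mean (flagged, not an error).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y must have the same number of samples")
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    if np.allclose(yc, 0.0):
        p = X.shape[1]
        return PLSModel(
            n_factors=0,
            x_mean=x_mean,
            y_mean=y_mean,
            weights=np.zeros((p, 0)),
            x_loadings=np.zeros((p, 0)),
            y_loadings=np.zeros(0),
            coefficients=np.zeros(p),
            degenerate=True,
        )
    W, P, q = _nipals_factors(Xc, yc, n_factors)
    return PLSModel(
        n_factors=W.shape[1],
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coefficients=_coefficients(W, P, q),
    )


def pls_predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return (X - model.x_mean) @ model.coefficients + model.y_mean


# --------------------------------------------------------------------------
# Leave-one-out cross-validation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CVReport:
    per_factor_rmsecv: np.ndarray
    chosen_factors: int
    r2_cal: float
    rmsec: float
    r2_cv: float
    rmsecv: float
    rpd: float
    model: PLSModel = field(repr=False, compare=False, default=None)


def _loo_prediction_matrix(X: np.ndarray, y: np.ndarray, max_factors: int) -> np.ndarray:
    """Held-out predictions, samples x factor counts (1..max_factors)."""
    n = X.shape[0]
    preds = np.empty((n, max_factors))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        X_train, y_train = X[mask], y[mask]
        x_mean = X_train.mean(axis=0)
        y_mean = float(y_train.mean())
        W, P, q = _nipals_factors(X_train - x_mean, y_train - y_mean, max_factors)
        xc = X[i] - x_mean
        for k in range(1, max_factors + 1):
            k_eff = min(k, W.shape[1])
            coef = _coefficients(W[:, :k_eff], P[:, :k_eff], q[:k_eff])
            preds[i, k - 1] = xc @ coef + y_mean
    return preds


def pls_loocv(X: np.ndarray, y: np.ndarray, max_factors: int) -> CVReport:
    """Leave-one-out cross-validated PLS calibration.

    RMSECV is computed per factor count from held-out predictions; the
    factor count minimizing RMSECV (ties broken toward fewer factors)
    is selected, RMSEC / R_cal^2 come from the full-data refit at that
    count, and RPD = SD(y, ddof=1) / RMSECV.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for LOOCV")
    if max_factors < 1:
        raise ValueError("max_factors must be >= 1")
    if max_factors > n - 2:
        raise ValueError("max_factors must be <= n_samples - 2")
    preds = _loo_prediction_matrix(X, y, max_factors)
    errors = preds - y[:, None]
    per_factor_rmsecv = np.sqrt(np.mean(errors**2, axis=0))
    chosen = int(np.argmin(per_factor_rmsecv)) + 1
    rmsecv = float(per_factor_rmsecv[chosen - 1])
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2_cv = 1.0 - float(np.sum(errors[:, chosen - 1] ** 2)) / ss_tot if ss_tot else 0.0
    model = pls_fit(X, y, chosen)
    fitted = pls_predict(model, X)
    rmsec = float(np.sqrt(np.mean((fitted - y) ** 2)))
    r2_cal = 1.0 - float(np.sum((fitted - y) ** 2)) / ss_tot if ss_tot else 0.0
    sd_y = float(np.std(y, ddof=1))
    rpd = sd_y / rmsecv if rmsecv > 0 else np.inf
    return CVReport(
        per_factor_rmsecv=per_factor_rmsecv,
        chosen_factors=chosen,
        r2_cal=r2_cal,
        rmsec=rmsec,
        r2_cv=r2_cv,
        rmsecv=rmsecv,
        rpd=rpd,
        model=model,
    )


# --------------------------------------------------------------------------
# Prediction-set validation (recovery / CV)
# --------------------------------------------------------------------------

def recovery_percent(predicted: float, measured: float) -> float:
    """Recovery in % as measured / predicted x 100."""
    if predicted == 0:
        raise ZeroDivisionError("recovery undefined for zero predicted value")
    return measured / predicted * 100.0


@dataclass(frozen=True)
class GroupValidation:
    label: str
    n_rep: int
    predicted_mean: float
    predicted_sd: float
    measured_mean: float
    measured_sd: float
    recovery_pct: float
    recovery_sd: float
    cv_pct: float


@dataclass(frozen=True)
class PredictionReport:
    groups: tuple[GroupValidation, ...]

    def as_rows(self) -> list[dict]:
        return [vars(g).copy() for g in self.groups]


def predict_and_validate(
    model: PLSModel,
    X_new: np.ndarray,
    y_ref: np.ndarray,
    group_labels: list[str],
    n_rep: int,
) -> PredictionReport:
    """Per-group recovery and CV of PLS predictions on an external set.

    Each group must contain exactly n_rep replicates.  Per replicate,
    recovery = measured / predicted x 100; the group CV is the SD/mean of
    those replicate recoveries (in %).
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    if not (X_new.shape[0] == y_ref.size == len(group_labels)):
        raise ValueError("X_new, y_ref and group_labels must be parallel")
    predicted = pls_predict(model, X_new)
    order: list[str] = []
    for lab in group_labels:
        if lab not in order:
            order.append(lab)
    groups = []
    labels_arr = np.asarray(group_labels)
    for lab in order:
        idx = np.flatnonzero(labels_arr == lab)
        if idx.size != n_rep:
            raise ValueError(
                f"group {lab!r} has {idx.size} replicates, expected {n_rep}"
            )
        pred = predicted[idx]
        meas = y_ref[idx]
        if np.any(pred == 0):
            raise ZeroDivisionError(
                f"recovery undefined: zero predicted value in group {lab!r}"
            )
        rec = meas / pred * 100.0
        rec_mean = float(rec.mean())
        rec_sd = float(np.std(rec, ddof=1)) if n_rep > 1 else 0.0
        groups.append(
            GroupValidation(
                label=lab,
                n_rep=n_rep,
                predicted_mean=float(pred.mean()),
                predicted_sd=float(np.std(pred, ddof=1)) if n_rep > 1 else 0.0,
                measured_mean=float(meas.mean()),
                measured_sd=float(np.std(meas, ddof=1)) if n_rep > 1 else 0.0,
                recovery_pct=rec_mean,
                recovery_sd=rec_sd,
                cv_pct=rec_sd / rec_mean * 100.0 if rec_mean != 0 else np.nan,
            )
        )
    return PredictionReport(groups=tuple(groups))


# --------------------------------------------------------------------------
# One-way ANOVA with compact letter display
# --------------------------------------------------------------------------

def anova_cld(groups: dict[str, np.ndarray], alpha: float = 0.05) -> dict[str, str]:
    """One-way ANOVA + Tukey HSD all-pairs test, summarized as letters.

    Groups that are not significantly different at ``alpha`` share at
    least one letter; the highest-mean group's first letter is "a".
    Letters follow from the maximal cliques of the not-significantly-
    different graph, ordered by descending clique maximum mean.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    names = list(groups)
    arrays = {k: np.asarray(v, dtype=float).ravel() for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs at least 2 values")
    values = np.concatenate([arrays[k] for k in names])
    labels = np.concatenate([[k] * arrays[k].size for k in names])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    # adjacency of "not significantly different"
    nsd = {k: {k} for k in names}
    res = tukey.summary().data[1:]
    for row in res:
        g1, g2, reject = str(row[0]), str(row[1]), bool(row[6])
        if not reject:
            nsd[g1].add(g2)
            nsd[g2].add(g1)
    cliques = _maximal_cliques(names, nsd)
    means = {k: float(arrays[k].mean()) for k in names}
    cliques.sort(key=lambda c: (-max(means[k] for k in c), -len(c), sorted(c)))
    letters = {k: "" for k in names}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i)
        for k in clique:
            letters[k] += letter
    # order letters within each group alphabetically
    return {k: "".join(sorted(v)) for k, v in letters.items()}


def _maximal_cliques(names: list[str], adj: dict[str, set]) -> list[set]:
    """Bron-Kerbosch maximal cliques of the NSD graph (tiny inputs)."""
    cliques: list[set] = []

    def expand(R: set, P: set, X: set) -> None:
        if not P and not X:
            cliques.append(R)
            return
        for v in sorted(P):
            expand(
                R | {v},
                P & (adj[v] - {v}),
                X & (adj[v] - {v}),
            )
            P = P - {v}
            X = X | {v}

    expand(set(), set(names), set())
    return cliques
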