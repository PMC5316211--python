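"""Multivariate discrimination of the T0 vs T1 metabolome.

Unsupervised exploration (PCA, interclass Monte-Carlo test) and supervised
orthogonal projections to latent structures (OPLS): a NIPALS PLS component
fitted after removal of ``n_ortho`` components of X-variation orthogonal to
the class response (orthogonal signal correction). Internal validation
follows the classical chemometrics protocol — stratified 10-fold cross
validation for R2/Q2/RMSEP, label-permutation testing, and jack-knife
confidence intervals on the predictive loadings for discriminant-variable
selection. A univariate ANOVA with Bonferroni correction complements the
multivariate models.

Class coding is y in {-1, +1} with T0 = -1 and T1 = +1, so a positive
predictive loading means the variable is higher at T1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PeakTable

__all__ = [
    "PCAModel", "fit_pca", "MonteCarloResult", "interclass_pca_test",
    "OPLS", "OPLSResults", "fit_opls", "CVResult", "cross_validate",
    "PermutationResult", "permutation_validate",
    "select_discriminant_variables", "anova_bonferroni", "encode_classes",
]


# --------------------------------------------------------------------------
# preprocessing

def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])


def _preprocess(X: pd.DataFrame, scale: str | None):
    """Center and optionally scale columns. Returns (array, center, scale)."""
    A = X.to_numpy(dtype=float)
    center = A.mean(axis=0)
    A = A - center
    if scale is None:
        s = np.ones(A.shape[1])
    else:
        sd = A.std(axis=0, ddof=1) if A.shape[0] > 1 else np.zeros(A.shape[1])
        if (sd == 0).any():
            bad = [str(c) for c, z in zip(X.columns, sd == 0) if z]
            raise ValueError(f"constant variable(s) under scaling: {bad}")
        if scale == "uv":
            s = sd
        elif scale == "pareto":
            s = np.sqrt(sd)
        else:
            raise ValueError(f"unknown scale mode {scale!r}")
    return A / s, center, s


def encode_classes(labels) -> tuple[np.ndarray, dict]:
    """Encode a two-class label vector as -1/+1 (sorted order: first -> -1).

    T0/T1 labels therefore map to T0 = -1, T1 = +1.
    """
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    y = np.where(labels == classes[1], 1.0, -1.0)
    return y, {classes[0]: -1.0, classes[1]: 1.0}


# --------------------------------------------------------------------------
# PCA

@dataclass
class PCAModel:
    """Principal component model (scores = centered X @ loadings)."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance: np.ndarray        # eigenvalues of the covariance
    explained_variance_ratio: np.ndarray
    center: np.ndarray
    scale: np.ndarray

    def reconstruct(self) -> np.ndarray:
        """Back-transform scores to the original variable space."""
        return (self.scores.to_numpy() @ self.loadings.to_numpy().T) * self.scale + self.center


def fit_pca(X, scale_mode: str | None = None, n_components: int | None = None) -> PCAModel:
    """PCA by singular value decomposition of the centered (scaled) matrix."""
    X = _as_frame(X)
    n, p = X.shape
    if n < 2 or p < 1:
        raise ValueError("PCA needs at least 2 samples and 1 variable")
    A, center, s = _preprocess(X, scale_mode)
    U, sv, Vt = np.linalg.svd(A, full_matrices=False)
    k = min(n_components or len(sv), len(sv))
    eig = sv**2 / max(n - 1, 1)
    total = eig.sum()
    ratio = eig / total if total > 0 else np.zeros_like(eig)
    comps = [f"PC{i + 1}" for i in range(k)]
    return PCAModel(
        scores=pd.DataFrame(U[:, :k] * sv[:k], index=X.index, columns=comps),
        loadings=pd.DataFrame(Vt[:k].T, index=X.columns, columns=comps),
        explained_variance=eig[:k],
        explained_variance_ratio=ratio[:k],
        center=center,
        scale=s,
    )


# --------------------------------------------------------------------------
# interclass PCA Monte-Carlo test

@dataclass
class MonteCarloResult:
    statistic: float          # between-class inertia / total inertia
    p_value: float
    permuted: np.ndarray
    n_perm: int


def _inertia_ratio(A: np.ndarray, y01: np.ndarray) -> float:
    total = float((A**2).sum())
    if total == 0:
        return 0.0
    between = 0.0
    for g in (0, 1):
        rows = A[y01 == g]
        between += len(rows) * float((rows.mean(axis=0) ** 2).sum())
    return between / total

def _permute_labels(y: np.ndarray, rng: np.random.Generator,
                    group_idx: list[np.ndarray] | None) -> np.ndarray:
    """Permute a label vector; within groups only when a grouping is given
    (the design-aware scheme for paired samples: swaps within each horse)."""
    if group_idx is None:
        return y[rng.permutation(len(y))]
    out = y.copy()
    for idx in group_idx:
        out[idx] = out[idx[rng.permutation(len(idx))]]
    return out


def _group_indices(groups) -> list[np.ndarray] | None:
    if groups is None:
        return None
    groups = np.asarray(groups)
    return [np.flatnonzero(groups == g) for g in pd.unique(groups)]


def interclass_pca_test(X, labels, n_perm: int = 999, seed: int | None = None,
                        scale_mode: str | None = None,
                        groups=None) -> MonteCarloResult:
    """Monte-Carlo test of class separation on the (centered) data cloud.

    The statistic is the fraction of total inertia carried between the two
    class centroids; its null distribution is obtained by permuting the
    class labels ``n_perm`` times (999 by default). With ``groups`` (e.g.
    horse ids in a paired design) labels are permuted within groups only,
    which keeps the permutation distribution valid when samples are
    correlated within group. The p-value is
    ``(1 + #{perm >= observed}) / (n_perm + 1)``.
    """
    X = _as_frame(X)
    y, _ = encode_classes(labels)
    y01 = (y > 0).astype(int)
    if min(np.bincount(y01)) < 2:
        raise ValueError("both classes need at least 2 samples")
    A, _, _ = _preprocess(X, scale_mode)
    obs = _inertia_ratio(A, y01)
    rng = np.random.default_rng(seed)
    gidx = _group_indices(groups)
    permuted = np.empty(n_perm)
    for i in range(n_perm):
        permuted[i] = _inertia_ratio(A, _permute_labels(y01, rng, gidx))
    p = (1 + int((permuted >= obs - 1e-15).sum())) / (n_perm + 1)
    return MonteCarloResult(statistic=obs, p_value=p, permuted=permuted, n_perm=n_perm)


# --------------------------------------------------------------------------
# OPLS

@dataclass
class _OPLSComponents:
    w: np.ndarray            # predictive weights (unit norm)
    t: np.ndarray            # predictive scores
    p: np.ndarray            # predictive loadings
    q: float                 # y loading
    W_o: np.ndarray          # p_vars x n_ortho orthogonal weights
    T_o: np.ndarray          # n x n_ortho orthogonal scores
    P_o: np.ndarray          # p_vars x n_ortho orthogonal loadings


def _nipals_opls(Xc: np.ndarray, y: np.ndarray, n_ortho: int) -> _OPLSComponents:
    """One predictive + ``n_ortho`` orthogonal components (NIPALS O-PLS)."""
    n, p = Xc.shape
    Xr = Xc.copy()
    yy = float(y @ y)
    W_o, T_o, P_o = [], [], []
    for _ in range(n_ortho):
        w = Xr.T @ y / yy
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w = w / nw
        t = Xr @ w
        pl = Xr.T @ t / float(t @ t)
        w_o = pl - float(w @ pl) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-10 * max(1.0, np.linalg.norm(pl)):
            break  # no y-orthogonal structure left to strip
        w_o = w_o / n_wo
        t_o = Xr @ w_o
        tt_o = float(t_o @ t_o)
        if tt_o < 1e-24:
            break
        p_o = Xr.T @ t_o / tt_o
        Xr = Xr - np.outer(t_o, p_o)
        W_o.append(w_o)
        T_o.append(t_o)
        P_o.append(p_o)
    w = Xr.T @ y / yy
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        raise ValueError("X carries no covariance with y")
    w = w / nw
    t = Xr @ w
    tt = float(t @ t)
    pl = Xr.T @ t / tt
    q = float(y @ t) / tt
    stack = (lambda L: np.column_stack(L) if L else np.zeros((p, 0)))
    stack_n = (lambda L: np.column_stack(L) if L else np.zeros((n, 0)))
    return _OPLSComponents(w=w, t=t, p=pl, q=q,
                           W_o=stack(W_o), T_o=stack_n(T_o), P_o=stack(P_o))


class OPLS:
    """Orthogonal PLS discriminant model.

    Parameters
    ----------
    X : DataFrame or array, samples x variables
    y : two-class label vector (T0/T1) or numeric -1/+1 vector
    n_ortho : number of y-orthogonal components to strip (default 1;
        0 makes the model identical to single-component PLS)
    scale : "uv" (unit variance, default), "pareto" or None; X is always
        mean-centered
    """

    def __init__(self, X, y, n_ortho: int = 1, scale: str | None = "uv"):
        self.X = _as_frame(X)
        if np.issubdtype(np.asarray(y).dtype, np.number):
            self.y = np.asarray(y, dtype=float)
            if len(set(self.y.tolist())) != 2:
                raise ValueError("y must contain exactly two classes")
            self.class_map = None
        else:
            self.y, self.class_map = encode_classes(y)
        if n_ortho < 0:
            raise ValueError("n_ortho must be >= 0")
        self.n_ortho = n_ortho
        self.scale = scale

    def fit(self) -> "OPLSResults":
        A, center, s = _preprocess(self.X, self.scale)
        rank = np.linalg.matrix_rank(A)
        if self.n_ortho >= rank:
            raise ValueError(f"n_ortho={self.n_ortho} >= rank(X)={rank}")
        yc = self.y - self.y.mean()
        comp = _nipals_opls(A, yc, self.n_ortho)
        fitted = comp.q * comp.t + self.y.mean()
        ss_res = float(((self.y - fitted) ** 2).sum())
        ss_tot = float((yc**2).sum())
        r2 = 1.0 - ss_res / ss_tot
        return OPLSResults(model=self, components=comp, center=center,
                           scale_vec=s, y_mean=self.y.mean(), fitted=fitted, r2=r2)


@dataclass
class OPLSResults:
    """Fitted OPLS model: predictive/orthogonal components and fit metrics.

    Cross-validation metrics (Q2, RMSEP) and jack-knife loading intervals
    are attached by :meth:`cross_validate`.
    """

    model: OPLS
    components: _OPLSComponents
    center: np.ndarray
    scale_vec: np.ndarray
    y_mean: float
    fitted: np.ndarray
    r2: float
    cv_: "CVResult | None" = field(default=None, repr=False)

    # ---- accessors ----
    @property
    def predictive_scores(self) -> pd.Series:
        return pd.Series(self.components.t, index=self.model.X.index, name="t")

    @property
    def predictive_loadings(self) -> pd.Series:
        return pd.Series(self.components.p, index=self.model.X.columns, name="p")

    @property
    def predictive_weights(self) -> pd.Series:
        return pd.Series(self.components.w, index=self.model.X.columns, name="w")

    @property
    def y_loading(self) -> float:
        return self.components.q

    @property
    def orthogonal_scores(self) -> pd.DataFrame:
        cols = [f"to{i + 1}" for i in range(self.components.T_o.shape[1])]
        return pd.DataFrame(self.components.T_o, index=self.model.X.index, columns=cols)

    # ---- prediction ----
    def transform(self, X_new) -> np.ndarray:
        """Orthogonal-corrected predictive scores for new samples."""
        A = (np.asarray(_as_frame(X_new), dtype=float) - self.center) / self.scale_vec
        c = self.components
        for k in range(c.W_o.shape[1]):
            t_o = A @ c.W_o[:, k]
            A = A - np.outer(t_o, c.P_o[:, k])
        return A @ c.w

    def predict(self, X_new) -> np.ndarray:
        """Continuous class prediction (threshold at 0 for a hard call)."""
        return self.components.q * self.transform(X_new) + self.y_mean

    def cross_validate(self, k: int = 10, seed: int | None = None) -> "CVResult":
        cv = cross_validate(self.model.X, self.model.y, n_ortho=self.model.n_ortho,
                            scale=self.model.scale, k=k, seed=seed)
        self.cv_ = cv
        return cv

    def permutation_test(self, n: int = 1000, seed: int | None = None,
                         k: int = 10, groups=None) -> "PermutationResult":
        return permutation_validate(self.model.X, self.model.y, n=n, seed=seed,
                                    n_ortho=self.model.n_ortho,
                                    scale=self.model.scale, k=k, groups=groups)

    def summary(self) -> str:
        lines = [
            "OPLS discriminant model",
            f"  samples: {self.model.X.shape[0]}  variables: {self.model.X.shape[1]}",
            f"  orthogonal components: {self.components.W_o.shape[1]}",
            f"  R2 = {self.r2:.4f}",
        ]
        if self.cv_ is not None:
            lines.append(f"  Q2 = {self.cv_.q2:.4f}  RMSEP = {self.cv_.rmsep:.4f} "
                         f"({self.cv_.k}-fold CV)")
        return "\n".join(lines)


def fit_opls(X, y, n_ortho: int = 1, scale: str | None = "uv") -> OPLSResults:
    """Convenience wrapper: build and fit an :class:`OPLS` model."""
    return OPLS(X, y, n_ortho=n_ortho, scale=scale).fit()


# --------------------------------------------------------------------------
# cross validation & permutation testing

@dataclass
class CVResult:
    r2: float                 # training R2 of the full-data fit
    q2: float                 # 1 - PRESS/TSS over held-out predictions
    rmsep: float              # sqrt(PRESS / n)
    k: int
    predictions: pd.Series    # stacked held-out predictions, sample-indexed
    fold_loadings: np.ndarray  # k x p predictive loadings per training fold
    folds: list[np.ndarray]


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Class-stratified fold assignment; every fold keeps both classes
    whenever class sizes allow."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds if len(f)]


def cross_validate(X, y, n_ortho: int = 1, scale: str | None = "uv",
                   k: int = 10, seed: int | None = None) -> CVResult:
    """Stratified k-fold cross validation of the OPLS model.

    The orthogonal signal correction is refitted inside every training fold
    (no leakage). ``Q2 = 1 - PRESS/TSS`` with TSS the total centered sum of
    squares of y; ``RMSEP = sqrt(PRESS/n)``.
    """
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(y, k, rng)
    press = 0.0
    preds = pd.Series(np.nan, index=X.index, dtype=float)
    fold_loadings = []
    full = fit_opls(X, y, n_ortho=n_ortho, scale=scale)
    for test_idx in folds:
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        if len(set(y[train_mask].tolist())) < 2:
            warnings.warn("fold with single-class training set skipped", stacklevel=2)
            continue
        res = fit_opls(X.iloc[train_mask], y[train_mask], n_ortho=n_ortho, scale=scale)
        y_hat = res.predict(X.iloc[test_idx])
        press += float(((y[test_idx] - y_hat) ** 2).sum())
        preds.iloc[test_idx] = y_hat
        fold_loadings.append(res.components.p)
    tss = float(((y - y.mean()) ** 2).sum())
    return CVResult(
        r2=full.r2,
        q2=1.0 - press / tss,
        rmsep=float(np.sqrt(press / n)),
        k=len(folds),
        predictions=preds,
        fold_loadings=np.vstack(fold_loadings),
        folds=folds,
    )


@dataclass
class PermutationResult:
    """Observed vs label-permuted model quality (R2, Q2, RMSEP)."""

    observed: tuple[float, float, float]
    permuted: pd.DataFrame     # n x (r2, q2, rmsep)
    p_value: float             # (1 + #{perm Q2 >= observed Q2}) / (n + 1)

    def summary(self) -> str:
        o = self.observed
        m, s = self.permuted.mean(), self.permuted.std(ddof=1)
        return (
            "OPLS permutation validation "
            f"(n = {len(self.permuted)})\n"
            f"  observed:  R2 = {o[0]:.3f}  Q2 = {o[1]:.3f}  RMSEP = {o[2]:.3f}\n"
            f"  permuted:  R2 = {m['r2']:.2f} ± {s['r2']:.2f}  "
            f"Q2 = {m['q2']:.2f} ± {s['q2']:.2f}  "
            f"RMSEP = {m['rmsep']:.2f} ± {s['rmsep']:.2f}\n"
            f"  p = {self.p_value:.4g}"
        )


def permutation_validate(X, y, n: int = 1000, seed: int | None = None,
                         n_ortho: int = 1, scale: str | None = "uv",
                         k: int = 10, groups=None) -> PermutationResult:
    """Label-permutation validation of the cross-validated OPLS model.

    Each replicate shuffles y over the samples (within groups when a
    paired-design grouping is given; the identity permutation is excluded)
    and re-runs the full cross validation. The p-value compares the
    observed Q2 with the permuted Q2 distribution.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    gidx = _group_indices(groups)
    obs = cross_validate(X, y, n_ortho=n_ortho, scale=scale, k=k,
                         seed=int(rng.integers(2**31)))
    rows = []
    for _ in range(n):
        for _attempt in range(1000):
            yp = _permute_labels(y, rng, gidx)
            if not np.array_equal(yp, y):
                break
        cvp = cross_validate(X, yp, n_ortho=n_ortho, scale=scale, k=k,
                             seed=int(rng.integers(2**31)))
        rows.append((cvp.r2, cvp.q2, cvp.rmsep))
    permuted = pd.DataFrame(rows, columns=["r2", "q2", "rmsep"])
    p = (1 + int((permuted["q2"].to_numpy() >= obs.q2 - 1e-15).sum())) / (n + 1)
    return PermutationResult(observed=(obs.r2, obs.q2, obs.rmsep),
                             permuted=permuted, p_value=p)


# --------------------------------------------------------------------------
# discriminant-variable selection

def select_discriminant_variables(results: OPLSResults,
                                  ci_level: float = 0.95) -> pd.DataFrame:
    """Variables whose predictive loading differs from zero.

    Uses jack-knife confidence intervals of the predictive loadings across
    the stored cross-validation rounds: a variable is selected when its
    interval excludes zero. The reported sign follows the T0=-1/T1=+1
    coding: positive means higher at T1.
    """
    if results.cv_ is None:
        raise ValueError("model has no stored CV rounds; run cross_validate() first")
    L = results.cv_.fold_loadings.copy()            # k x p
    full = results.components.p
    # sign-align folds with the full-model loading vector
    signs = np.sign(L @ full)
    signs[signs == 0] = 1.0
    L = L * signs[:, None]
    kf = L.shape[0]
    mean = L.mean(axis=0)
    var_jk = (kf - 1) / kf * ((L - mean) ** 2).sum(axis=0)
    se = np.sqrt(var_jk)
    tq = stats.t.ppf(0.5 + ci_level / 2, df=kf - 1)
    lo, hi = mean - tq * se, mean + tq * se
    q_sign = np.sign(results.components.q) or 1.0
    signed = full * q_sign
    out = pd.DataFrame({
        "variable": results.model.X.columns,
        "loading": signed,
        "ci_low": lo * q_sign if q_sign > 0 else hi * q_sign,
        "ci_high": hi * q_sign if q_sign > 0 else lo * q_sign,
        "selected": (lo > 0) | (hi < 0),
        "direction": np.where(signed > 0, "up_at_T1", "down_at_T1"),
    })
    return out.set_index("variable")


# --------------------------------------------------------------------------
# univariate check

def anova_bonferroni(peaks, labels) -> pd.DataFrame:
    """Per-peak one-way ANOVA with Bonferroni-corrected p-values.

    ``p_corrected = min(1, p * m)`` with m the number of peaks tested;
    significance at corrected p < 0.05. For exactly two groups the F
    statistic equals the squared equal-variance two-sample t statistic.
    Zero within-group variance yields p = 0 and a degenerate flag.
    """
    table = peaks.intensities if isinstance(peaks, PeakTable) else _as_frame(peaks)
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    m = table.shape[1]
    rows = []
    for col in table.columns:
        vals = [table[col].to_numpy()[labels == g] for g in groups]
        degenerate = all(np.var(v) == 0 for v in vals)
        if degenerate:
            means = [v.mean() for v in vals]
            f = np.inf if len(set(means)) > 1 else 0.0
            p = 0.0 if len(set(means)) > 1 else 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f, p = stats.f_oneway(*vals)
        rows.append((col, float(f), float(p), min(1.0, float(p) * m), degenerate))
    out = pd.DataFrame(rows, columns=["peak", "F", "p", "p_corrected", "degenerate"])
    out["significant"] = out["p_corrected"] < 0.05
    return out.set_index("peak")
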