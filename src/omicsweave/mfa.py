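"""Multiple factor analysis across omic tables measured on the same samples.

MFA proceeds in three steps: (1) each table is column-centered (and, by
default, unit-variance scaled) and divided by the first singular value of
its own PCA, equalizing the tables' dominant variances; (2) the weighted
tables are concatenated into a grand table analyzed by a plain
(non-normalized) PCA, giving global factor scores and variable loadings;
(3) each table is projected separately onto the global axes (partial
scores, scaled by the number of tables so that their barycenter equals the
global score). The RV coefficient quantifies co-structure between two
centered tables: total co-inertia over the geometric mean of the tables'
squared total inertias, in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

__all__ = ["MFA", "MFAResults", "fit_mfa", "rv_coefficient",
           "high_weight_variables", "group_contributions", "group_differences"]


def _prep_table(df: pd.DataFrame, center: bool, scale: bool) -> np.ndarray:
    A = df.to_numpy(dtype=float)
    if center:
        A = A - A.mean(axis=0)
    if scale:
        sd = A.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = [str(c) for c, z in zip(df.columns, sd == 0) if z]
            raise ValueError(f"constant column(s) under scaling: {bad}")
        A = A / sd
    return A


def rv_coefficient(X, Y) -> float:
    """RV coefficient between two column-centered tables on the same samples.

    ``rv = trace(X Xt Y Yt) / sqrt(trace((X Xt)^2) * trace((Y Yt)^2))``;
    1 for identical configurations (up to rotation/scale), 0 for orthogonal
    co-inertia.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("tables must share the sample dimension")
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    Sxy = X.T @ Y
    Sxx = X.T @ X
    Syy = Y.T @ Y
    num = float((Sxy**2).sum())                 # trace(X Xt Y Yt)
    den = float(np.sqrt((Sxx**2).sum() * (Syy**2).sum()))
    if den == 0:
        raise ValueError("RV undefined for an all-zero table")
    return num / den


class MFA:
    """Multiple factor analysis model.

    Parameters
    ----------
    tables : mapping of table name -> DataFrame (samples x variables); all
        tables must share the same sample index and order
    center, scale : within-table column preprocessing before the 1/sigma1
        weighting (defaults follow the quantitative-group convention:
        center and unit-variance scale)
    """

    def __init__(self, tables: dict[str, pd.DataFrame], center: bool = True,
                 scale: bool = True):
        names = list(tables)
        if not names:
            raise ValueError("need at least one table")
        index = tables[names[0]].index
        for name in names[1:]:
            if not tables[name].index.equals(index):
                raise ValueError(f"table {name!r} has a mismatched sample set/order")
        self.tables = {n: t.copy() for n, t in tables.items()}
        self.center = center
        self.scale = scale

    def fit(self, n_components: int | None = None) -> "MFAResults":
        names = list(self.tables)
        index = self.tables[names[0]].index
        prepped: dict[str, np.ndarray] = {}
        weights: dict[str, float] = {}
        for name in names:
            A = _prep_table(self.tables[name], self.center, self.scale)
            if np.linalg.matrix_rank(A) < 1 or not A.any():
                raise ValueError(f"table {name!r} has rank 0")
            sigma1 = float(np.linalg.svd(A, compute_uv=False)[0])
            weights[name] = 1.0 / sigma1
            prepped[name] = A * weights[name]

        Z = np.concatenate([prepped[n] for n in names], axis=1)
        U, sv, Vt = np.linalg.svd(Z, full_matrices=False)
        rank = int((sv > sv[0] * 1e-10).sum())  # axes beyond rank are arbitrary
        k = min(n_components or rank, rank)
        dims = [f"dim{i + 1}" for i in range(k)]
        global_scores = pd.DataFrame(U[:, :k] * sv[:k], index=index, columns=dims)

        # per-table slices of the global loadings
        offsets, start = {}, 0
        for n in names:
            p = prepped[n].shape[1]
            offsets[n] = (start, start + p)
            start += p
        V = Vt.T  # variables x dims

        n_tables = len(names)
        partial_scores = {}
        contributions = np.zeros((n_tables, k))
        var_rows = []
        for i, name in enumerate(names):
            a, b = offsets[name]
            Vk = V[a:b, :k]
            partial_scores[name] = pd.DataFrame(
                n_tables * prepped[name] @ Vk, index=index, columns=dims)
            contributions[i] = (Vk**2).sum(axis=0)
            # correlation of each (preprocessed) variable with the global axes
            A = prepped[name]
            sd_a = A.std(axis=0)
            sd_f = global_scores.to_numpy().std(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                corr = ((A - A.mean(axis=0)).T @
                        (global_scores.to_numpy() - global_scores.to_numpy().mean(axis=0))
                        ) / len(index) / np.outer(sd_a, sd_f)
            corr[~np.isfinite(corr)] = np.nan
            for j, var in enumerate(self.tables[name].columns):
                var_rows.append({"variable": var, "table": name,
                                 **{d: corr[j, m] for m, d in enumerate(dims)}})

        rv = pd.DataFrame(np.eye(n_tables), index=names, columns=names)
        for i, a in enumerate(names):
            for j in range(i + 1, n_tables):
                b = names[j]
                rv.loc[a, b] = rv.loc[b, a] = rv_coefficient(prepped[a], prepped[b])

        return MFAResults(
            group_weights=pd.Series(weights),
            eigenvalues=sv[:k] ** 2,
            global_scores=global_scores,
            partial_scores=partial_scores,
            variable_correlations=pd.DataFrame(var_rows).set_index("variable"),
            group_contributions=pd.DataFrame(contributions, index=names, columns=dims),
            rv=rv,
        )


@dataclass
class MFAResults:
    """Fitted MFA: weights, scores, loadings-derived contributions, RV matrix."""

    group_weights: pd.Series
    eigenvalues: np.ndarray
    global_scores: pd.DataFrame
    partial_scores: dict[str, pd.DataFrame]
    variable_correlations: pd.DataFrame
    group_contributions: pd.DataFrame  # rows: tables, cols: dims; sums to 1
    rv: pd.DataFrame

    def summary(self) -> str:
        total = self.eigenvalues.sum()
        lines = ["Multiple factor analysis",
                 f"  tables: {list(self.group_weights.index)}",
                 f"  samples: {len(self.global_scores)}"]
        for i, ev in enumerate(self.eigenvalues[:3]):
            lines.append(f"  dim{i + 1}: eigenvalue {ev:.3f} "
                         f"({100 * ev / total:.1f}% of variance)")
        off = [f"{a}-{b}: {self.rv.loc[a, b]:.3f}"
               for i, a in enumerate(self.rv.index)
               for b in self.rv.index[i + 1:]]
        if off:
            lines.append("  RV: " + ", ".join(off))
        return "\n".join(lines)


def fit_mfa(tables: dict[str, pd.DataFrame], center: bool = True,
            scale: bool = True, n_components: int | None = None) -> MFAResults:
    """Fit an MFA over the given tables (functional surface)."""
    return MFA(tables, center=center, scale=scale).fit(n_components=n_components)


def high_weight_variables(m: MFAResults, dim: int = 1,
                          threshold: float = 0.80) -> pd.DataFrame:
    """Variables whose |correlation| with global axis ``dim`` strictly
    exceeds the threshold, sorted by |correlation| descending."""
    col = f"dim{dim}"
    if col not in m.variable_correlations.columns:
        raise ValueError(f"dimension {dim} not fitted")
    corr = m.variable_correlations[[col, "table"]].rename(columns={col: "correlation"})
    out = corr[corr["correlation"].abs() > threshold].copy()
    out["abs_correlation"] = out["correlation"].abs()
    out = out.sort_values("abs_correlation", ascending=False).drop(columns="abs_correlation")
    out.attrs["dim"] = dim
    out.attrs["threshold"] = threshold
    return out


def group_contributions(m: MFAResults) -> pd.DataFrame:
    """Per-dimension fraction of variance contributed by each table
    (columns sum to 1)."""
    return m.group_contributions / m.group_contributions.sum(axis=0)


def group_differences(values: pd.DataFrame, labels) -> pd.DataFrame:
    """Two-sample t-test per variable between two sample groups, with BH
    correction — the check applied to high-weight variables when comparing
    finishers against eliminated horses at baseline."""
    labels = np.asarray(labels)
    groups = sorted(set(labels.tolist()))
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    a = values.loc[labels == groups[0]]
    b = values.loc[labels == groups[1]]
    t, p = stats.ttest_ind(a, b, axis=0)
    out = pd.DataFrame({"t": t, "p": p, "q": bh_adjust(np.asarray(p))},
                       index=values.columns)
    out["mean_" + str(groups[0])] = a.mean(axis=0)
    out["mean_" + str(groups[1])] = b.mean(axis=0)
    return out
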