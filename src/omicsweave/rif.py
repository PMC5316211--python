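"""Regulatory impact factors: scoring TF and miRNA regulators by
differential co-expression with the differentially expressed genes.

The two conditions are T0 (condition 1) and T1 (condition 2). For a
regulator f and the DE genes j = 1..n_de, with per-condition means
``e1_j``/``e2_j`` and per-condition Pearson correlations ``r1(f,j)`` /
``r2(f,j)``:

* phenotype impact factor ``PIF_j = a_j * d_j`` with ``a_j = (e1_j+e2_j)/2``
  and ``d_j = e1_j - e2_j`` (positive d = higher at T0);
* differential co-expression ``dCo_fj = r1(f,j) - r2(f,j)``;
* ``RIF1_f = (1/n_de) * sum_j PIF_j * dCo_fj^2`` — regulators consistently
  differentially co-expressed with abundant, strongly changing genes;
* ``RIF2_f = (1/n_de) * sum_j [(e1_j*r1)^2 - (e2_j*r2)^2]`` — regulators
  with the most altered ability to predict DE-gene abundance.

Raw scores are z-standardized across regulators (both columns emitted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix

__all__ = ["compute_pif", "RegulatoryImpact", "RIFResults", "compute_rif"]


def compute_pif(expr_c1: pd.DataFrame, expr_c2: pd.DataFrame, gene: str) -> float:
    """Phenotype impact factor of one gene: mean abundance times the
    between-condition difference of the condition means."""
    for df in (expr_c1, expr_c2):
        if gene not in df.columns:
            raise KeyError(f"gene {gene!r} missing from a condition")
    e1 = float(expr_c1[gene].mean())
    e2 = float(expr_c2[gene].mean())
    return (e1 + e2) / 2.0 * (e1 - e2)


def _corr_matrix(R: np.ndarray, E: np.ndarray, label: str) -> np.ndarray:
    """Pearson correlations between regulator columns (R) and gene columns
    (E) over the same samples; constant columns correlate as 0."""
    n = R.shape[0]
    sr = R.std(axis=0)
    se = E.std(axis=0)
    const = sr == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant regulator(s) in {label}: "
                      "correlations set to 0", stacklevel=3)
    Rz = np.where(const[None, :], 0.0, (R - R.mean(axis=0)) / np.where(sr == 0, 1.0, sr))
    Ez = np.where((se == 0)[None, :], 0.0,
                  (E - E.mean(axis=0)) / np.where(se == 0, 1.0, se))
    return (Rz.T @ Ez) / n


def _zscore(x: np.ndarray) -> np.ndarray:
    if len(x) < 2:
        return np.zeros_like(x)
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


@dataclass
class RIFResults:
    """Per-regulator RIF scores (raw and z-standardized)."""

    table: pd.DataFrame  # regulator x (kind, rif1_raw, rif2_raw, rif1_z, rif2_z)
    n_de: int

    def top(self, n: int = 10, metric: str = "rif1_z") -> pd.DataFrame:
        return self.table.reindex(
            self.table[metric].abs().sort_values(ascending=False).index).head(n)

    def summary(self) -> str:
        lead = self.top(5)
        lines = [f"Regulatory impact factors over {self.n_de} DE genes, "
                 f"{len(self.table)} regulators",
                 "  top |RIF1 z|:"]
        for rid, row in lead.iterrows():
            lines.append(f"    {rid} ({row['kind']}): RIF1 = {row['rif1_z']:+.2f}, "
                         f"RIF2 = {row['rif2_z']:+.2f}")
        return "\n".join(lines)

    def write(self, path) -> None:
        out = self.table.copy()
        out.index.name = "regulator"
        out.to_csv(path, sep="\t")


class RegulatoryImpact:
    """RIF model for a set of candidate regulators against the DE genes.

    Parameters
    ----------
    expr_c1, expr_c2 : samples x features log2 matrices for condition 1
        (T0) and condition 2 (T1). Gene and miRNA matrices may be joined
        beforehand (see :meth:`from_layers`); regulators may themselves be
        DE genes.
    de_genes : ids of the differentially expressed genes to score against
    regulators : candidate regulator ids (TFs and/or miRNAs)
    kinds : optional regulator -> kind ("tf"/"mirna") mapping for reporting
    """

    def __init__(self, expr_c1: pd.DataFrame, expr_c2: pd.DataFrame,
                 de_genes: set[str], regulators: set[str],
                 kinds: dict[str, str] | None = None):
        if len(expr_c1) < 3 or len(expr_c2) < 3:
            raise ValueError("need >= 3 samples per condition for correlations")
        genes = sorted(set(de_genes) & set(expr_c1.columns) & set(expr_c2.columns))
        if not genes:
            raise ValueError("no DE genes present in both conditions")
        regs = sorted(set(regulators) & set(expr_c1.columns) & set(expr_c2.columns))
        if not regs:
            raise ValueError("no regulators present in both conditions")
        self.expr_c1, self.expr_c2 = expr_c1, expr_c2
        self.de_genes, self.regulators = genes, regs
        self.kinds = kinds or {}

    @classmethod
    def from_layers(cls, genes: ExpressionMatrix, mirnas: ExpressionMatrix,
                    metadata: pd.DataFrame, de_genes: set[str],
                    regulators: set[str]) -> "RegulatoryImpact":
        """Join the gene and miRNA layers on shared samples and split by
        timepoint (T0 = condition 1, T1 = condition 2)."""
        shared = genes.values.index.intersection(mirnas.values.index)
        joined = pd.concat([genes.values.loc[shared], mirnas.values.loc[shared]], axis=1)
        tp = metadata.set_index("sample_id")["timepoint"].reindex(shared)
        kinds = {f: "gene" for f in genes.values.columns}
        kinds.update({f: "mirna" for f in mirnas.values.columns})
        return cls(expr_c1=joined[tp == "T0"], expr_c2=joined[tp == "T1"],
                   de_genes=de_genes, regulators=regulators, kinds=kinds)

    def fit(self) -> RIFResults:
        genes, regs = self.de_genes, self.regulators
        E1 = self.expr_c1[genes].to_numpy(dtype=float)
        E2 = self.expr_c2[genes].to_numpy(dtype=float)
        R1 = self.expr_c1[regs].to_numpy(dtype=float)
        R2 = self.expr_c2[regs].to_numpy(dtype=float)
        e1, e2 = E1.mean(axis=0), E2.mean(axis=0)
        pif = (e1 + e2) / 2.0 * (e1 - e2)
        r1 = _corr_matrix(R1, E1, "condition 1")
        r2 = _corr_matrix(R2, E2, "condition 2")
        dco = r1 - r2
        rif1 = (dco**2 * pif[None, :]).mean(axis=1)
        rif2 = ((e1[None, :] * r1) ** 2 - (e2[None, :] * r2) ** 2).mean(axis=1)
        table = pd.DataFrame({
            "kind": [self.kinds.get(r, "tf") for r in regs],
            "rif1_raw": rif1,
            "rif2_raw": rif2,
            "rif1_z": _zscore(rif1),
            "rif2_z": _zscore(rif2),
        }, index=pd.Index(regs, name="regulator"))
        return RIFResults(table=table, n_de=len(genes))


def compute_rif(expr_c1: pd.DataFrame, expr_c2: pd.DataFrame,
                de_genes: set[str], regulators: set[str],
                kinds: dict[str, str] | None = None) -> RIFResults:
    """Functional surface over :class:`RegulatoryImpact`."""
    return RegulatoryImpact(expr_c1, expr_c2, de_genes, regulators, kinds=kinds).fit()
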