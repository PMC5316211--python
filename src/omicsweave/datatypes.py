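"""Shared data containers for the multi-omic integration pipeline.

All containers are thin, validated wrappers around pandas DataFrames (matrices)
or plain Python collections (sets, graphs), with plain-text round-trip I/O:
CSV for peak tables, TSV for expression matrices and metadata, JSON for the
pathway database and ground truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

PPM_WINDOW = (0.0, 12.0)  # plausible 1H chemical-shift window


@dataclass
class PeakTable:
    """NMR peak table: samples x peaks with per-peak chemical shifts.

    Parameters
    ----------
    intensities
        samples x peaks matrix of non-negative normalized intensities (a.u.).
    ppm
        Chemical shift (ppm) of each peak, indexed by peak id.
    ppm_range
        Optional per-peak ``(low, high)`` ppm window, columns
        ``ppm_low``/``ppm_high``, used for trapezoidal peak areas.
    """

    intensities: pd.DataFrame
    ppm: pd.Series
    ppm_range: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        peaks = self.intensities.columns
        if peaks.duplicated().any():
            raise ValueError("duplicate peak ids")
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("peak intensities must be non-negative")
        self.ppm = self.ppm.reindex(peaks)
        if self.ppm.isna().any():
            raise ValueError("every peak needs a ppm position")
        lo, hi = PPM_WINDOW
        if ((self.ppm <= lo) | (self.ppm >= hi)).any():
            raise ValueError(f"ppm values must lie strictly within {PPM_WINDOW}")
        if self.ppm_range is not None:
            self.ppm_range = self.ppm_range.reindex(peaks)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def peak_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def write(self, path: str | Path, meta_path: str | Path | None = None) -> None:
        """Write ``peaks.csv`` plus a ``peaks_meta.csv`` sidecar."""
        path = Path(path)
        out = self.intensities.copy()
        out.index.name = "sample_id"
        out.to_csv(path)
        meta = pd.DataFrame({"peak_id": self.peak_ids, "ppm": self.ppm.to_numpy()})
        if self.ppm_range is not None:
            meta["ppm_low"] = self.ppm_range["ppm_low"].to_numpy()
            meta["ppm_high"] = self.ppm_range["ppm_high"].to_numpy()
        meta_path = Path(meta_path) if meta_path else path.with_name(path.stem + "_meta.csv")
        meta.to_csv(meta_path, index=False)

    @classmethod
    def read(cls, path: str | Path, meta_path: str | Path | None = None) -> "PeakTable":
        path = Path(path)
        intens = pd.read_csv(path, index_col="sample_id")
        meta_path = Path(meta_path) if meta_path else path.with_name(path.stem + "_meta.csv")
        meta = pd.read_csv(meta_path).set_index("peak_id")
        ppm_range = None
        if {"ppm_low", "ppm_high"}.issubset(meta.columns):
            ppm_range = meta[["ppm_low", "ppm_high"]]
        return cls(intensities=intens, ppm=meta["ppm"], ppm_range=ppm_range)


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values, samples x features.

    ``feature_kind`` distinguishes gene from miRNA matrices so downstream
    stages can tag node types without guessing from identifiers.
    """

    values: pd.DataFrame
    feature_kind: str = "gene"  # "gene" | "mirna"

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate feature ids")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        vals = self.values.to_numpy()
        if not pd.notna(vals).all() or not np_isfinite_all(vals):
            raise ValueError("expression values must be finite")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def write(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path, feature_kind: str = "gene",
             orient: str = "samples_by_features") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if orient == "features_by_samples":
            df = df.T
        elif orient != "samples_by_features":
            raise ValueError(f"unknown orient {orient!r}")
        df.index.name = "sample_id"
        return cls(values=df, feature_kind=feature_kind)


REQUIRED_METADATA_COLUMNS = ("sample_id", "horse_id", "timepoint", "status")


def validate_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    """Check the sample sheet: one row per sample, T0/T1 timepoints."""
    missing = set(REQUIRED_METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in metadata")
    bad = set(meta["timepoint"]) - {"T0", "T1"}
    if bad:
        raise ValueError(f"unknown timepoints: {sorted(bad)}")
    return meta


def read_metadata(path: str | Path) -> pd.DataFrame:
    return validate_metadata(pd.read_csv(path, sep="\t"))


def write_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    validate_metadata(meta).to_csv(path, sep="\t", index=False)


@dataclass
class ReferenceShiftTable:
    """Reference chemical shifts for peak assignment.

    Columns: ``metabolite``, ``reference_ppm``, ``multiplicity``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"metabolite", "reference_ppm"}
        if not need.issubset(self.table.columns):
            raise ValueError("reference table needs metabolite and reference_ppm columns")
        if "multiplicity" not in self.table.columns:
            self.table = self.table.assign(multiplicity="")
        if self.table.duplicated(["metabolite", "reference_ppm"]).any():
            raise ValueError("duplicate (metabolite, reference_ppm) pairs")

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def read(cls, path: str | Path) -> "ReferenceShiftTable":
        return cls(pd.read_csv(path))


@dataclass
class Pathway:
    name: str
    genes: set[str]
    metabolites: set[str]
    graph: nx.DiGraph = field(default_factory=nx.DiGraph)


@dataclass
class PathwayDB:
    """Metabolite -> pathway -> metabolic-gene mapping with directed
    metabolite graphs per pathway (metabolic networks are directed)."""

    pathways: dict[str, Pathway]

    def __post_init__(self) -> None:
        for pid, pw in self.pathways.items():
            extra = set(pw.graph.nodes) - pw.metabolites
            if extra:
                raise ValueError(f"pathway {pid}: graph nodes not in metabolite set: {sorted(extra)}")

    @property
    def metabolite_index(self) -> dict[str, list[str]]:
        idx: dict[str, list[str]] = {}
        for pid, pw in self.pathways.items():
            for m in sorted(pw.metabolites):
                idx.setdefault(m, []).append(pid)
        return idx

    def to_json(self, path: str | Path) -> None:
        payload = {
            pid: {
                "name": pw.name,
                "genes": sorted(pw.genes),
                "metabolites": sorted(pw.metabolites),
                "edges": sorted([list(e) for e in pw.graph.edges]),
            }
            for pid, pw in self.pathways.items()
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PathwayDB":
        payload = json.loads(Path(path).read_text())
        pathways = {}
        for pid, rec in payload.items():
            g = nx.DiGraph()
            g.add_nodes_from(rec["metabolites"])
            g.add_edges_from([tuple(e) for e in rec["edges"]])
            pathways[pid] = Pathway(
                name=rec["name"], genes=set(rec["genes"]),
                metabolites=set(rec["metabolites"]), graph=g,
            )
        return cls(pathways)


@dataclass
class TargetDB:
    """miRNA-target interaction table: (mirna_id, gene_id, support)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"mirna_id", "gene_id", "support"}
        if not need.issubset(self.table.columns):
            raise ValueError("target table needs mirna_id, gene_id, support columns")
        bad = set(self.table["support"]) - {"validated", "predicted"}
        if bad:
            raise ValueError(f"unknown support classes: {sorted(bad)}")
        if self.table.duplicated(["mirna_id", "gene_id", "support"]).any():
            raise ValueError("duplicate (mirna, gene) pairs within a support class")

    def targets_of(self, mirna: str, support: str | None = "validated") -> set[str]:
        t = self.table
        if support is not None:
            t = t[t["support"] == support]
        return set(t.loc[t["mirna_id"] == mirna, "gene_id"])

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "TargetDB":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort, recorded exactly."""

    active_metabolites: set[str] = field(default_factory=set)
    de_genes: set[str] = field(default_factory=set)
    de_mirnas: set[str] = field(default_factory=set)
    active_regulators: set[str] = field(default_factory=set)
    metabolite_gene_pairs: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        coupled = {g for _, g in self.metabolite_gene_pairs}
        if not coupled <= self.de_genes:
            raise ValueError("coupled pathway genes must all be differentially expressed")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "active_metabolites": sorted(self.active_metabolites),
            "de_genes": sorted(self.de_genes),
            "de_mirnas": sorted(self.de_mirnas),
            "active_regulators": sorted(self.active_regulators),
            "metabolite_gene_pairs": sorted([list(p) for p in self.metabolite_gene_pairs]),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            active_metabolites=set(payload["active_metabolites"]),
            de_genes=set(payload["de_genes"]),
            de_mirnas=set(payload["de_mirnas"]),
            active_regulators=set(payload["active_regulators"]),
            metabolite_gene_pairs={tuple(p) for p in payload["metabolite_gene_pairs"]},
        )


def np_isfinite_all(a) -> bool:
    import numpy as np

    return bool(np.isfinite(a).all())


def read_tf_list(path: str | Path) -> set[str]:
    """One TF gene id per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    if not out:
        warnings.warn("TF list is empty", stacklevel=2)
    return out


def write_tf_list(tfs: set[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(tfs)) + "\n")
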