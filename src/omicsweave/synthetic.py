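"""Synthetic paired two-timepoint multi-omic cohorts with known ground truth.

The generator emulates the design of an endurance-exercise cohort: each horse
is sampled at baseline (T0) and immediately post-competition (T1), and three
omic layers are measured on the same samples — an NMR metabolite peak table,
a gene expression matrix and a miRNA expression matrix (both log2 scale).

Planted structure, all recorded exactly in :class:`~omicsweave.datatypes.GroundTruth`:

* *active metabolites* shift by a standardized effect at T1 and share a
  per-sample latent factor with the genes of their pathway, so that the
  sample-wise Pearson correlation of each planted (metabolite, gene) pair has
  expectation at least ``latent_coupling``;
* *differentially expressed genes/miRNAs* shift by a standardized log2 effect
  at T1 (random sign; coupled pathway genes follow their metabolite's sign);
* *active regulators* (miRNAs, or TF genes) have their residual signal mixed
  into the DE genes at T1 only, producing condition-dependent co-expression
  (high at T1, ~0 at T0) that the regulatory-impact-factor metrics recover;
* everything else is exchangeable noise with a per-horse random intercept
  shared across the two timepoints (the paired structure).

Expression values are Gaussian on the log2 scale; metabolite peak intensities
are log-normal (exponentiated scaled Gaussian), mimicking microarray and NMR
conventions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GroundTruth,
    Pathway,
    PathwayDB,
    PeakTable,
    ReferenceShiftTable,
    TargetDB,
    validate_metadata,
    write_metadata,
    write_tf_list,
)

# log-normal scale factor for peak intensities: small enough that Pearson
# correlations on the intensity scale track the latent (log-scale) coupling
_LOGNORMAL_SCALE = 0.25
_PPM_LOW, _PPM_HIGH = 0.8, 9.5


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the emulated study design: 10 horses sampled at T0 and
    T1, 54 metabolite peaks, a custom microarray with 362 miRNAs, 11 planted
    differential metabolites and 5 planted miRNA regulators; gene count and
    pathway sizes are desk-scale stand-ins for a genome-wide platform.
    """

    n_horses: int = 10
    n_metabolites: int = 54
    n_genes: int = 2000
    n_mirnas: int = 362
    n_pathways: int = 20
    genes_per_pathway: int = 25
    n_active_metabolites: int = 11
    effect_size_metab: float = 1.5     # standardized mean difference at T1
    latent_coupling: float = 0.7       # target metabolite-gene Pearson r
    n_active_regulators: int = 5
    frac_de_genes: float = 0.35
    noise_sd: float = 1.0
    seed: int = 0
    # mechanism parameters the planted structure needs
    effect_size_gene: float = 2.0      # log2 shift of DE genes at T1
    effect_size_mirna: float = 1.5     # log2 shift of DE miRNAs at T1
    regulator_strength: float = 1.0    # mixing weight of regulator residual into DE genes at T1
    horse_sd: float = 0.5              # per-horse random-intercept sd (pairing)
    pathway_overlap: float = 0.0       # target mean pairwise Jaccard of pathway gene sets
    decoy_target_rate: float = 0.05    # Bernoulli rate of decoy miRNA-target pairs
    frac_eliminated: float = 0.3       # horses failing a vet gate
    regulator_kind: str = "mirna"      # "mirna" | "tf" | "mixed"

    def __post_init__(self) -> None:
        for name in ("n_horses", "n_metabolites", "n_genes", "n_mirnas",
                     "n_pathways", "genes_per_pathway"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.n_active_metabolites <= self.n_metabolites:
            raise ValueError("n_active_metabolites must be in [0, n_metabolites]")
        if not 0.0 <= self.frac_de_genes < 1.0:
            raise ValueError("frac_de_genes must be in [0, 1)")
        if not 0.0 <= self.latent_coupling <= 1.0:
            raise ValueError("latent_coupling must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.regulator_kind not in ("mirna", "tf", "mixed"):
            raise ValueError("regulator_kind must be mirna, tf or mixed")
        if self.regulator_kind in ("mirna", "mixed") and self.n_active_regulators > self.n_mirnas:
            raise ValueError("n_active_regulators exceeds n_mirnas")
        if not 0.0 <= self.pathway_overlap < 1.0:
            raise ValueError("pathway_overlap must be in [0, 1)")


@dataclass
class CohortBundle:
    """Everything one simulated cohort produces, ready for the pipeline."""

    peaks: PeakTable
    genes: ExpressionMatrix
    mirnas: ExpressionMatrix
    metadata: pd.DataFrame
    truth: GroundTruth
    pathway_db: PathwayDB
    target_db: TargetDB
    reference: ReferenceShiftTable
    tf_list: set[str]
    config: SyntheticConfig


def _ids(prefix: str, n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _metabolite_ids(cfg: SyntheticConfig) -> list[str]:
    return _ids("metab_", cfg.n_metabolites)


def _gene_ids(cfg: SyntheticConfig) -> list[str]:
    return _ids("gene_", cfg.n_genes)


def _mirna_ids(cfg: SyntheticConfig) -> list[str]:
    return _ids("mir_", cfg.n_mirnas)


def _residuals(rng: np.random.Generator, cfg: SyntheticConfig,
               n_features: int, horse_of_sample: np.ndarray) -> np.ndarray:
    """Unit-variance residual matrix (samples x features) with per-horse
    random intercepts shared across the two timepoints."""
    b = rng.standard_normal((cfg.n_horses, n_features))  # horse x feature
    e = rng.standard_normal((len(horse_of_sample), n_features))
    tau, sd = cfg.horse_sd, cfg.noise_sd
    scale = math.sqrt(tau * tau + sd * sd)
    return (tau * b[horse_of_sample, :] + sd * e) / scale


def generate_pathway_db(config: SyntheticConfig) -> PathwayDB:
    """Build the metabolite -> pathway -> metabolic-gene database.

    Planted (active) metabolites occupy dedicated single-metabolite pathways
    whenever enough pathways exist; the remaining metabolites are spread
    round-robin over the remaining pathways.  ``pathway_overlap`` sets a
    target mean pairwise Jaccard similarity between pathway gene sets via a
    shared gene core (0 -> disjoint partition).
    """
    rng = np.random.default_rng([config.seed, 1])
    metabolites = _metabolite_ids(config)
    genes = _gene_ids(config)
    P, G = config.n_pathways, config.genes_per_pathway
    if P * G > config.n_genes:
        raise ValueError("n_pathways * genes_per_pathway exceeds n_genes")

    # shared core size from target Jaccard J: core fraction c = 2J/(1+J)
    J = config.pathway_overlap
    core_size = int(round(G * 2 * J / (1 + J))) if J > 0 else 0
    uniq = G - core_size
    pool = rng.permutation(config.n_genes)
    core = [genes[i] for i in pool[:core_size]]
    cursor = core_size

    dedicated = P > config.n_active_metabolites > 0
    assignment: dict[int, list[str]] = {p: [] for p in range(P)}
    for i, m in enumerate(metabolites):
        if dedicated and i < config.n_active_metabolites:
            assignment[i].append(m)
        elif dedicated:
            k = config.n_active_metabolites
            assignment[k + (i - k) % (P - k)].append(m)
        else:
            assignment[i % P].append(m)

    pathways: dict[str, Pathway] = {}
    for p in range(P):
        members = [genes[i] for i in pool[cursor:cursor + uniq]]
        cursor += uniq
        gset = set(core) | set(members)
        mets = assignment[p]
        g = nx.DiGraph()
        g.add_nodes_from(mets)
        # a directed chain with a few random forward shortcuts
        for a, b in zip(mets, mets[1:]):
            g.add_edge(a, b)
        if len(mets) > 3:
            n_extra = max(1, len(mets) // 3)
            for _ in range(n_extra):
                i, j = sorted(rng.choice(len(mets), size=2, replace=False))
                if j > i + 1:
                    g.add_edge(mets[i], mets[j])
        pathways[f"pw_{p + 1:03d}"] = Pathway(
            name=f"pathway {p + 1}", genes=gset, metabolites=set(mets), graph=g)
    return PathwayDB(pathways)


def _planted_structure(config: SyntheticConfig, db: PathwayDB):
    """Choose active metabolites, coupled genes, DE genes and regulators."""
    rng = np.random.default_rng([config.seed, 4])
    metabolites = _metabolite_ids(config)
    genes = _gene_ids(config)
    mirnas = _mirna_ids(config)
    active_metabs = metabolites[: config.n_active_metabolites]

    coupled: dict[str, list[str]] = {}
    idx = db.metabolite_index
    for m in active_metabs:
        gs: set[str] = set()
        for pid in idx.get(m, []):
            gs |= db.pathways[pid].genes
        coupled[m] = sorted(gs)

    coupled_genes = sorted({g for gs in coupled.values() for g in gs})
    n_de_target = int(round(config.frac_de_genes * config.n_genes))
    extra_needed = max(0, n_de_target - len(coupled_genes))
    free = [g for g in genes if g not in set(coupled_genes)]
    extra = list(rng.choice(free, size=min(extra_needed, len(free)), replace=False))
    de_genes = sorted(set(coupled_genes) | set(extra))

    # regulators
    K = config.n_active_regulators
    reg_mirnas: list[str] = []
    reg_tfs: list[str] = []
    if K > 0:
        if config.regulator_kind == "mirna":
            n_mir = K
        elif config.regulator_kind == "tf":
            n_mir = 0
        else:
            n_mir = (K + 1) // 2
        reg_mirnas = mirnas[:n_mir]
        non_de = [g for g in genes if g not in set(de_genes)]
        reg_tfs = list(rng.choice(non_de, size=K - n_mir, replace=False))

    # DE miRNAs: regulators plus a background fraction
    n_de_mir = int(round(config.frac_de_genes * config.n_mirnas))
    others = [m for m in mirnas if m not in set(reg_mirnas)]
    extra_mir = list(rng.choice(others, size=max(0, min(n_de_mir - len(reg_mirnas), len(others))),
                                replace=False))
    de_mirnas = sorted(set(reg_mirnas) | set(extra_mir))

    return active_metabs, coupled, de_genes, de_mirnas, reg_mirnas, reg_tfs


def generate_cohort(config: SyntheticConfig):
    """Generate one paired cohort.

    Returns
    -------
    (PeakTable, ExpressionMatrix, ExpressionMatrix, DataFrame, GroundTruth)
        Peaks, genes, miRNAs, sample metadata and the planted ground truth.
        Same config (same seed) gives bit-identical outputs.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 0])
    db = generate_pathway_db(cfg)
    (active_metabs, coupled, de_genes, de_mirnas,
     reg_mirnas, reg_tfs) = _planted_structure(cfg, db)

    horses = _ids("H", cfg.n_horses)
    sample_ids, horse_of_sample, t1 = [], [], []
    for h, horse in enumerate(horses):
        for tp in ("T0", "T1"):
            sample_ids.append(f"{horse}_{tp}")
            horse_of_sample.append(h)
            t1.append(tp == "T1")
    horse_of_sample = np.asarray(horse_of_sample)
    t1 = np.asarray(t1, dtype=float)
    n_samples = len(sample_ids)

    status = np.array(["finished"] * cfg.n_horses, dtype=object)
    n_elim = int(round(cfg.frac_eliminated * cfg.n_horses))
    elim = rng.choice(cfg.n_horses, size=n_elim, replace=False)
    status[elim] = "eliminated"
    metadata = pd.DataFrame({
        "sample_id": sample_ids,
        "horse_id": [horses[h] for h in horse_of_sample],
        "timepoint": ["T1" if x else "T0" for x in t1],
        "status": [status[h] for h in horse_of_sample],
    })
    validate_metadata(metadata)

    metabolites = _metabolite_ids(cfg)
    genes = _gene_ids(cfg)
    mirnas = _mirna_ids(cfg)
    rho = cfg.latent_coupling

    # per-active-metabolite latent factor, shared with its pathway genes
    latents = {m: rng.standard_normal(n_samples) for m in active_metabs}
    metab_dir = {m: float(rng.choice([-1.0, 1.0])) for m in active_metabs}

    # --- metabolome ---------------------------------------------------------
    resid_m = _residuals(rng, cfg, cfg.n_metabolites, horse_of_sample)
    baselines_m = rng.uniform(0.5, 2.5, size=cfg.n_metabolites)
    Z = resid_m.copy()
    for j, m in enumerate(metabolites):
        if m in latents:
            Z[:, j] = (metab_dir[m] * cfg.effect_size_metab * t1
                       + math.sqrt(rho) * latents[m]
                       + math.sqrt(1 - rho) * resid_m[:, j])
    intens = np.exp(baselines_m[None, :] + _LOGNORMAL_SCALE * Z)
    ppm = np.linspace(_PPM_LOW, _PPM_HIGH, cfg.n_metabolites)
    peaks = PeakTable(
        intensities=pd.DataFrame(intens, index=sample_ids, columns=_ids("peak_", cfg.n_metabolites)),
        ppm=pd.Series(ppm, index=_ids("peak_", cfg.n_metabolites)),
    )

    # --- regulators' residual signals (mixed into DE genes at T1 only) -----
    resid_mir = _residuals(rng, cfg, cfg.n_mirnas, horse_of_sample)
    resid_g = _residuals(rng, cfg, cfg.n_genes, horse_of_sample)
    mir_index = {m: j for j, m in enumerate(mirnas)}
    gene_index = {g: j for j, g in enumerate(genes)}
    reg_signals = [resid_mir[:, mir_index[m]] for m in reg_mirnas]
    reg_signals += [resid_g[:, gene_index[g]] for g in reg_tfs]
    K = len(reg_signals)
    reg_mix = np.zeros(n_samples)
    if K:
        reg_mix = (cfg.regulator_strength / math.sqrt(K)) * np.sum(reg_signals, axis=0) * t1

    # --- transcriptome ------------------------------------------------------
    gene_of_metab = {g: m for m, gs in coupled.items() for g in gs}
    de_set = set(de_genes)
    baselines_g = rng.uniform(6.0, 12.0, size=cfg.n_genes)
    gene_dir = {g: float(rng.choice([-1.0, 1.0])) for g in de_genes}
    for g in gene_of_metab:  # coupled genes follow their metabolite's sign
        gene_dir[g] = metab_dir[gene_of_metab[g]]
    Xg = baselines_g[None, :] + resid_g.copy()
    for j, g in enumerate(genes):
        if g in gene_of_metab:
            # coupled genes carry the latent factor but no regulator mix,
            # preserving the latent_coupling expectation exactly
            m = gene_of_metab[g]
            Xg[:, j] = (baselines_g[j]
                        + gene_dir[g] * cfg.effect_size_gene * t1
                        + math.sqrt(rho) * latents[m]
                        + math.sqrt(1 - rho) * resid_g[:, j])
        elif g in de_set:
            Xg[:, j] = (baselines_g[j] + gene_dir[g] * cfg.effect_size_gene * t1
                        + resid_g[:, j] + reg_mix)
    gene_mat = ExpressionMatrix(
        values=pd.DataFrame(Xg, index=sample_ids, columns=genes), feature_kind="gene")

    # --- miRNome ------------------------------------------------------------
    baselines_mi = rng.uniform(4.0, 10.0, size=cfg.n_mirnas)
    mir_dir = {m: float(rng.choice([-1.0, 1.0])) for m in de_mirnas}
    Xm = baselines_mi[None, :] + resid_mir.copy()
    for j, m in enumerate(mirnas):
        if m in mir_dir:
            Xm[:, j] = (baselines_mi[j] + mir_dir[m] * cfg.effect_size_mirna * t1
                        + resid_mir[:, j])
    mirna_mat = ExpressionMatrix(
        values=pd.DataFrame(Xm, index=sample_ids, columns=mirnas), feature_kind="mirna")

    truth = GroundTruth(
        active_metabolites=set(active_metabs),
        de_genes=set(de_genes),
        de_mirnas=set(de_mirnas),
        active_regulators=set(reg_mirnas) | set(reg_tfs),
        metabolite_gene_pairs={(m, g) for m, gs in coupled.items() for g in gs},
    )
    return peaks, gene_mat, mirna_mat, metadata, truth


def generate_target_db(config: SyntheticConfig, ground_truth: GroundTruth) -> TargetDB:
    """miRNA-target table: planted regulators get >= 10 metabolic-gene targets
    each; decoy pairs are added at ``decoy_target_rate``."""
    rng = np.random.default_rng([config.seed, 2])
    db = generate_pathway_db(config)
    pathway_genes = sorted({g for pw in db.pathways.values() for g in pw.genes})
    coupled_genes = sorted({g for _, g in ground_truth.metabolite_gene_pairs})
    mirnas = _mirna_ids(config)
    reg_mirnas = sorted(ground_truth.active_regulators & set(mirnas))

    rows: list[tuple[str, str, str]] = []
    planted: set[tuple[str, str]] = set()
    pool = coupled_genes if coupled_genes else pathway_genes
    for m in reg_mirnas:
        n_t = min(len(pool), int(rng.integers(10, 21)))
        if n_t < 10:
            warnings.warn(f"regulator {m}: only {n_t} metabolic genes available "
                          "for targeting (< 10)", stacklevel=2)
        for g in rng.choice(pool, size=n_t, replace=False):
            rows.append((m, str(g), "validated"))
            planted.add((m, str(g)))

    if config.decoy_target_rate > 0:
        for m in mirnas:
            hits = rng.random(len(pathway_genes)) < config.decoy_target_rate
            support = rng.random(len(pathway_genes)) < 0.5
            for g, hit, val in zip(pathway_genes, hits, support):
                if hit and (m, g) not in planted:
                    rows.append((m, g, "validated" if val else "predicted"))

    table = pd.DataFrame(rows, columns=["mirna_id", "gene_id", "support"])
    table = table.drop_duplicates(["mirna_id", "gene_id", "support"]).reset_index(drop=True)
    return TargetDB(table)


def generate_reference_shifts(config: SyntheticConfig) -> ReferenceShiftTable:
    """Reference chemical-shift table naming every generated peak."""
    ppm = np.linspace(_PPM_LOW, _PPM_HIGH, config.n_metabolites)
    return ReferenceShiftTable(pd.DataFrame({
        "metabolite": _metabolite_ids(config),
        "reference_ppm": ppm,
        "multiplicity": "s",
    }))


def generate_tf_list(config: SyntheticConfig, ground_truth: GroundTruth) -> set[str]:
    """TF catalogue stand-in: a deterministic 5% subset of genes plus any
    planted TF regulators."""
    rng = np.random.default_rng([config.seed, 3])
    genes = _gene_ids(config)
    n_tf = max(10, config.n_genes // 20)
    tfs = set(rng.choice(genes, size=min(n_tf, config.n_genes), replace=False).tolist())
    tfs |= ground_truth.active_regulators - set(_mirna_ids(config))
    return tfs


def simulate(config: SyntheticConfig) -> CohortBundle:
    """Generate the full cohort bundle (cohort + databases + TF list)."""
    peaks, genes, mirnas, metadata, truth = generate_cohort(config)
    db = generate_pathway_db(config)
    targets = generate_target_db(config, truth)
    reference = generate_reference_shifts(config)
    tfs = generate_tf_list(config, truth)
    return CohortBundle(peaks=peaks, genes=genes, mirnas=mirnas, metadata=metadata,
                        truth=truth, pathway_db=db, target_db=targets,
                        reference=reference, tf_list=tfs, config=config)


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> dict[str, Path]:
    """Serialize every cohort artifact as plain text; returns path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "peaks": out / "peaks.csv",
        "peaks_meta": out / "peaks_meta.csv",
        "genes": out / "genes.tsv",
        "mirnas": out / "mirnas.tsv",
        "metadata": out / "metadata.tsv",
        "pathways": out / "pathways.json",
        "targets": out / "targets.tsv",
        "truth": out / "truth.json",
        "reference": out / "reference.csv",
        "tfs": out / "tfs.txt",
        "config": out / "config.json",
    }
    bundle.peaks.write(paths["peaks"], paths["peaks_meta"])
    bundle.genes.write(paths["genes"])
    bundle.mirnas.write(paths["mirnas"])
    write_metadata(bundle.metadata, paths["metadata"])
    bundle.pathway_db.to_json(paths["pathways"])
    bundle.target_db.write(paths["targets"])
    bundle.truth.to_json(paths["truth"])
    bundle.reference.write(paths["reference"])
    write_tf_list(bundle.tf_list, paths["tfs"])
    import json as _json
    paths["config"].write_text(_json.dumps(asdict(bundle.config), indent=1))
    return paths
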