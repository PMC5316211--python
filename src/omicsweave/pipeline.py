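"""End-to-end orchestration: prep -> chemometrics -> DE -> enrichment -> RIF -> MFA.

Every stage consumes plain-text inputs, writes plain TSV/JSON outputs into
the run directory, and records its parameters, consumed seeds and output
file hashes in a JSON manifest, so a rerun with the same configuration and
seed reproduces every artifact bit-identically and each stage can be rerun
standalone from the previous stage's serialized outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemometrics as chem
from . import enrichment as enr
from .datatypes import (
    ExpressionMatrix, PathwayDB, PeakTable, ReferenceShiftTable, TargetDB,
    read_metadata, read_tf_list,
)
from .de import paired_de_test
from .mfa import fit_mfa, high_weight_variables, group_contributions
from .peaks import assign_peaks, filter_peaks
from .rif import RegulatoryImpact


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Input paths, thresholds and the top-level seed of one pipeline run."""

    peaks: str
    peaks_meta: str
    genes: str
    mirnas: str
    metadata: str
    pathways: str
    targets: str
    reference: str
    tf_list: str
    out_dir: str
    # thresholds, as printed in the emulated protocol
    min_detect_frac: float = 0.5
    tol_ppm: float = 0.005
    r_thresh: float = 0.5
    p_thresh: float = 0.05
    de_q: float = 0.05
    enrich_fdr: float = 0.1
    mfa_threshold: float = 0.80
    min_targets: int = 10
    n_perm_interclass: int = 999
    n_perm_opls: int = 1000
    n_ortho: int = 1
    cv_folds: int = 10
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (("r_thresh", 0, 1), ("p_thresh", 0, 1),
                             ("de_q", 0, 1), ("enrich_fdr", 0, 1),
                             ("mfa_threshold", 0, 1), ("min_detect_frac", 0, 1)):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.tol_ppm <= 0:
            raise ValueError("tol_ppm must be positive")


@dataclass
class RunReport:
    """All stage outputs plus the provenance manifest."""

    manifest: dict
    out_dir: Path
    discriminant_metabolites: list[str] = field(default_factory=list)
    enrichment: list = field(default_factory=list)
    network: "enr.RegulatoryNetwork | None" = None
    flags: list[str] = field(default_factory=list)


def _stage_seed(seed: int, stage: int) -> int:
    """Deterministically derive a per-stage seed below 2**31."""
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % 2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full workflow; see the module docstring for the stage list."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "outputs": {}}
    log_path = out / "pipeline.log"
    log_lines: list[str] = []
    flags: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(f"[{time.strftime('%H:%M:%S')}] {msg}")

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        log(f"stage {stage}: " + json.dumps(info, default=str))

    def save(name: str, path: Path) -> None:
        manifest["outputs"][name] = {"path": path.name, "sha256": _sha256(path)}

    def finish() -> None:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True,
                                                      default=str))
        log_path.write_text("\n".join(log_lines) + "\n")

    stage = "load"
    try:
        peaks = PeakTable.read(config.peaks, config.peaks_meta)
        genes = ExpressionMatrix.read(config.genes, feature_kind="gene")
        mirnas = ExpressionMatrix.read(config.mirnas, feature_kind="mirna")
        metadata = read_metadata(config.metadata)
        db = PathwayDB.from_json(config.pathways)
        targets = TargetDB.read(config.targets)
        reference = ReferenceShiftTable.read(config.reference)
        tf_list = read_tf_list(config.tf_list)
        record(stage, n_samples=len(metadata), n_peaks=len(peaks.peak_ids),
               n_genes=len(genes.feature_ids), n_mirnas=len(mirnas.feature_ids))

        # ------------------------------------------------ metabolome prep
        stage = "prep"
        filtered = filter_peaks(peaks, min_detect_frac=config.min_detect_frac)
        assigned = assign_peaks(filtered, reference, tol_ppm=config.tol_ppm)
        abundance = pd.DataFrame({
            m: assigned.abundance_of(m) for m in assigned.assigned_metabolites})
        record(stage, peaks_surviving=len(filtered.peak_ids),
               assigned_metabolites=len(assigned.assigned_metabolites))

        # ------------------------------------------------ chemometrics
        stage = "chemometrics"
        seed_c = _stage_seed(config.seed, 1)
        md_ix = metadata.set_index("sample_id")
        labels = md_ix["timepoint"].reindex(filtered.intensities.index)
        horses = md_ix["horse_id"].reindex(filtered.intensities.index).to_numpy()
        ic = chem.interclass_pca_test(filtered.intensities, labels,
                                      n_perm=config.n_perm_interclass, seed=seed_c,
                                      groups=horses)
        opls = chem.fit_opls(filtered.intensities, labels, n_ortho=config.n_ortho)
        opls.cross_validate(k=config.cv_folds, seed=seed_c)
        perm = opls.permutation_test(n=config.n_perm_opls, seed=seed_c,
                                     k=config.cv_folds, groups=horses)
        selection = chem.select_discriminant_variables(opls, ci_level=config.ci_level)
        selection["metabolite"] = assigned.assignment.reindex(selection.index)
        selection.to_csv(out / "selected_peaks.tsv", sep="\t")
        save("selected_peaks", out / "selected_peaks.tsv")
        pca = chem.fit_pca(filtered.intensities, scale_mode="uv")
        pca.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        save("pca_scores", out / "pca_scores.tsv")
        validation = {
            "interclass_statistic": ic.statistic, "interclass_p": ic.p_value,
            "observed": {"r2": perm.observed[0], "q2": perm.observed[1],
                         "rmsep": perm.observed[2]},
            "permuted_mean": perm.permuted.mean().to_dict(),
            "permuted_sd": perm.permuted.std(ddof=1).to_dict(),
            "permutation_p": perm.p_value,
        }
        (out / "validation.json").write_text(json.dumps(validation, indent=1))
        save("validation", out / "validation.json")
        disc = selection[selection["selected"] & (selection["metabolite"] != "unassigned")]
        disc_metabs = sorted(set(disc["metabolite"]))
        metab_dir = {}
        for m in disc_metabs:
            sub = disc[disc["metabolite"] == m]
            metab_dir[m] = "up" if sub["loading"].mean() > 0 else "down"
        anova = chem.anova_bonferroni(filtered, labels.to_numpy())
        anova.to_csv(out / "anova.tsv", sep="\t")
        save("anova", out / "anova.tsv")
        record(stage, seed=seed_c, interclass_p=ic.p_value, r2=opls.r2,
               q2=opls.cv_.q2, permutation_p=perm.p_value,
               discriminant_metabolites=len(disc_metabs))

        # ------------------------------------------------ differential expression
        stage = "de"
        de_g = paired_de_test(genes, metadata, alpha=config.de_q)
        de_m = paired_de_test(mirnas, metadata, alpha=config.de_q)
        de_g.write(out / "de_genes.tsv")
        de_m.write(out / "de_mirnas.tsv")
        save("de_genes", out / "de_genes.tsv")
        save("de_mirnas", out / "de_mirnas.tsv")
        record(stage, n_de_genes=len(de_g.significant), n_de_mirnas=len(de_m.significant))

        # ------------------------------------------------ enrichment + network
        stage = "enrich"
        cand_abund = abundance[[m for m in disc_metabs if m in abundance.columns]]
        candidates = enr.enrich_metabolites(
            cand_abund, db, de_g, genes, r_thresh=config.r_thresh,
            p_thresh=config.p_thresh, fdr=config.enrich_fdr)
        enr.enrichment_table(candidates).to_csv(out / "enrichment.tsv", sep="\t")
        save("enrichment", out / "enrichment.tsv")
        enriched = [c for c in candidates if c.enriched]
        if not enriched:
            flags.append("no enriched metabolites")
        network_genes = set().union(*(c.overlap for c in enriched)) if enriched else set()
        edges = enr.mirna_overlay(network_genes, targets, de_m, alpha=config.de_q)
        network = enr.assemble_network(
            candidates, edges, tf_list, de_g, de_m,
            metabolite_directions=metab_dir, min_targets=config.min_targets)
        network.write_graphml(out / "network.graphml")
        network.write_sif(out / "network.sif")
        save("network_graphml", out / "network.graphml")
        save("network_sif", out / "network.sif")
        impacts = {
            pid: enr.pathway_impact(db, pid, set(m.metabolite_id for m in enriched)
                                    & db.pathways[pid].metabolites)
            for pid in sorted(db.pathways)
        }
        (out / "pathway_impact.json").write_text(json.dumps(impacts, indent=1))
        save("pathway_impact", out / "pathway_impact.json")
        record(stage, n_enriched=len(enriched),
               n_network_nodes=network.graph.number_of_nodes(),
               n_network_edges=network.graph.number_of_edges())

        # ------------------------------------------------ RIF
        stage = "rif"
        regulators = (tf_list & set(genes.feature_ids)) | set(mirnas.feature_ids)
        rif_res = None
        if de_g.significant:
            rif = RegulatoryImpact.from_layers(genes, mirnas, metadata,
                                               de_genes=de_g.significant,
                                               regulators=regulators)
            rif_res = rif.fit()
            rif_res.write(out / "rif.tsv")
            save("rif", out / "rif.tsv")
            record(stage, n_regulators=len(rif_res.table), n_de=rif_res.n_de)
        else:
            flags.append("no DE genes: RIF skipped")
            record(stage, skipped=True)

        # ------------------------------------------------ MFA per timepoint
        stage = "mfa"
        rv_out = {}
        for tp in ("T0", "T1"):
            samples = metadata.loc[metadata["timepoint"] == tp, "sample_id"]
            tables = {
                "metabolome": abundance.loc[samples],
                "transcriptome": genes.values.loc[samples],
                "mirnome": mirnas.values.loc[samples],
            }
            res = fit_mfa(tables)
            res.global_scores.to_csv(out / f"mfa_{tp}_scores.tsv", sep="\t")
            save(f"mfa_{tp}_scores", out / f"mfa_{tp}_scores.tsv")
            res.rv.to_csv(out / f"mfa_{tp}_rv.tsv", sep="\t")
            save(f"mfa_{tp}_rv", out / f"mfa_{tp}_rv.tsv")
            group_contributions(res).to_csv(out / f"mfa_{tp}_contributions.tsv", sep="\t")
            save(f"mfa_{tp}_contributions", out / f"mfa_{tp}_contributions.tsv")
            hw = high_weight_variables(res, dim=1, threshold=config.mfa_threshold)
            hw.to_csv(out / f"mfa_{tp}_high_weights.tsv", sep="\t")
            save(f"mfa_{tp}_high_weights", out / f"mfa_{tp}_high_weights.tsv")
            rv_out[tp] = res.rv.to_dict()
        record(stage, rv=rv_out)
    except Exception as e:
        manifest["failed_stage"] = stage
        manifest["error"] = str(e)
        finish()
        raise PipelineError(f"stage {stage!r} failed: {e}") from e

    manifest["flags"] = flags
    finish()
    return RunReport(manifest=manifest, out_dir=out,
                     discriminant_metabolites=disc_metabs,
                     enrichment=candidates, network=network, flags=flags)
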