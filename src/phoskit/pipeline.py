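"""End-to-end pipeline orchestration with manifests and reproducibility.

Two entry points: ``run_phospho_pipeline`` (simulate or read -> filter ->
aggregate -> ratio-normalize -> moderated differential testing -> site
localization -> motif matrices -> enrichment -> clustering) and
``run_dia_pipeline`` (simulate or read -> build -> impute/weight ->
per-stage weighted contrasts -> centered matrix for heatmaps).  Every
stage persists its TSV output and the manifest records seed, thresholds
and per-stage row counts, so a run is reproducible bit-for-bit from
(inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import diffstats, dia, enrich, norm, sites as sites_mod, synthdata
from .errors import ConfigError
from .ingest import (
    Design,
    filter_protein_groups,
    filter_psms,
    read_evidence,
    read_protein_groups,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One run's inputs, thresholds and output location.

    Exactly one of ``input_dir`` (pre-existing tables) or ``sim`` (a
    simulation config) must be provided.
    """

    outdir: str
    seed: int = 0
    input_dir: str | None = None
    sim: synthdata.SimConfig | None = None
    pep_max: float = 0.01
    alpha: float = 0.05
    lfc_min: float = 0.5
    rank_max: int = 10
    window: int = 7
    stages: list[str] = field(default_factory=lambda: ["MI", "MII"])
    n_bio: int = 2
    n_tech: int = 3
    gmt_path: str | None = None
    kinase_scores_path: str | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.input_dir is None) == (self.sim is None):
            raise ConfigError("exactly one of input_dir or sim must be set")
        if not 0.0 < self.pep_max <= 1.0:
            raise ConfigError(f"pep_max must lie in (0, 1], got {self.pep_max}")
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigError(f"alpha must lie in (0, 1], got {self.alpha}")
        if self.lfc_min < 0:
            raise ConfigError(f"lfc_min must be >= 0, got {self.lfc_min}")
        if self.rank_max < 1:
            raise ConfigError(f"rank_max must be >= 1, got {self.rank_max}")
        if self.window < 1:
            raise ConfigError(f"window must be >= 1, got {self.window}")
        if self.sim is not None:
            self.sim.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim_raw = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            if "pep_alpha_beta" in sim_raw:
                sim_raw["pep_alpha_beta"] = tuple(sim_raw["pep_alpha_beta"])
            for key in ("peptides_per_protein", "psms_per_peptide"):
                if key in sim_raw and isinstance(sim_raw[key], list):
                    sim_raw[key] = (sim_raw[key][0], sim_raw[key][1])
            cfg.sim = synthdata.SimConfig(**sim_raw)
        cfg.validate()
        return cfg


def _manifest_write(manifest: dict, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_phospho_pipeline(config: PipelineConfig) -> dict:
    """Execute the isobaric phospho pipeline; returns the manifest dict."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "pipeline": "phospho",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "pep_max": config.pep_max,
            "alpha": config.alpha,
            "rank_max": config.rank_max,
            "window": config.window,
        },
        "counts": {},
    }
    try:
        # --- inputs
        if config.sim is not None:
            dataset = synthdata.generate_phospho_dataset(config.sim)
            dataset.write(out / "simulated")
            psms, groups = dataset.psms, dataset.protein_groups
            proteins = dataset.protein_sequences
            design = dataset.design
        else:
            indir = Path(config.input_dir)
            psms = read_evidence(indir / "evidence.tsv")
            groups = read_protein_groups(indir / "protein_groups.tsv")
            fasta = indir / "proteins.fasta"
            proteins = sites_mod.read_fasta(fasta) if fasta.exists() else {}
            design = Design.two_group(3)
        manifest["counts"]["psms_input"] = len(psms)
        manifest["counts"]["protein_groups_input"] = len(groups)

        # --- confidence filtering
        kept, report = filter_psms(psms, pep_max=config.pep_max)
        report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
        groups_kept, greport = filter_protein_groups(groups)
        manifest["counts"]["psms_retained"] = report.n_retained
        manifest["counts"]["psms_removed"] = {
            "decoy": report.n_decoy,
            "contaminant": report.n_contaminant,
            "low_confidence": report.n_low_confidence,
        }
        manifest["counts"]["protein_groups_retained"] = greport.n_retained

        # --- aggregation and ratio normalization
        features = norm.aggregate_psms_to_features(kept)
        ratios = norm.compute_log_ratios(features, groups_kept, design)
        ratios.write(out / "ratio_matrix.tsv")
        manifest["counts"]["features"] = len(features)
        manifest["counts"]["features_matched"] = len(ratios.values)
        manifest["match_rate"] = ratios.match_rate

        # --- differential testing
        results, prior = diffstats.run_differential(
            ratios.values, design, alpha=config.alpha
        )
        results.to_csv(out / "differential_results.tsv", sep="\t")
        diffstats.volcano_table(results).to_csv(out / "volcano.tsv", sep="\t")
        n_sig = int(results["significant"].sum())
        manifest["counts"]["features_tested"] = len(results)
        manifest["counts"]["significant"] = n_sig
        manifest["counts"]["significant_down"] = int(
            (results["significant"] & (results["direction"] == "down")).sum()
        )
        manifest["counts"]["significant_up"] = int(
            (results["significant"] & (results["direction"] == "up")).sum()
        )
        manifest["prior"] = {
            "d0": prior.d0 if np.isfinite(prior.d0) else "inf",
            "s0_sq": prior.s0_sq,
        }

        # --- site localization
        localized, unloc = sites_mod.localize_sites(kept)
        if proteins:
            localized = sites_mod.map_to_protein(localized, proteins)
        sites_mod.sites_table(localized).to_csv(out / "sites.tsv", sep="\t", index=False)
        manifest["counts"]["localized_sites"] = len(localized)
        manifest["counts"]["unlocalizable_peptides"] = len(unloc)

        # --- motif matrices: foreground = significant down peptides,
        #     background = all tested dephosphorylated (log2fc < 0) peptides
        if proteins and len(results):
            meta = ratios.feature_meta
            sig_down = results.index[results["significant"] & (results["direction"] == "down")]
            bg_ids = results.index[results["log2fc"] < 0]
            fg_peps = set(meta.loc[meta.index.isin(sig_down), "peptide_sequence"])
            bg_peps = set(meta.loc[meta.index.isin(bg_ids), "peptide_sequence"])
            site_by_pep = {s.peptide_sequence: s for s in localized}
            fg_sites = [site_by_pep[p] for p in sorted(fg_peps) if p in site_by_pep]
            bg_sites = [site_by_pep[p] for p in sorted(bg_peps) if p in site_by_pep]
            if fg_sites and bg_sites:
                fg_windows = sites_mod.center_windows(fg_sites, proteins, w=config.window)
                bg_windows = sites_mod.center_windows(bg_sites, proteins, w=config.window)
                motif = sites_mod.motif_information_content(fg_windows, bg_windows)
                motif.write(out / "motif_matrix.tsv")
                manifest["counts"]["motif_foreground"] = len(fg_windows)
                manifest["counts"]["motif_background"] = len(bg_windows)
            if config.kinase_scores_path:
                scores = sites_mod.read_kinase_scores(config.kinase_scores_path)
                for kinase in sorted(scores["kinase"].unique()):
                    subset = sites_mod.select_kinase_subset(
                        fg_sites, scores, kinase, rank_max=config.rank_max
                    )
                    if subset and bg_sites:
                        kf = sites_mod.center_windows(subset, proteins, w=config.window)
                        km = sites_mod.motif_information_content(
                            kf, sites_mod.center_windows(bg_sites, proteins, w=config.window)
                        )
                        km.write(out / f"motif_{kinase}.tsv")

        # --- enrichment: any significant peptide puts its protein in the query
        if config.gmt_path:
            meta = ratios.feature_meta
            universe = set(meta["protein_group_id"])
            collection = enrich.GeneSetCollection.from_gmt(config.gmt_path, universe=universe)
            sig_ids = results.index[results["significant"]]
            query = set(meta.loc[meta.index.isin(sig_ids), "protein_group_id"])
            ora = enrich.hypergeometric_ora(query, collection, alpha=config.alpha)
            ora.to_csv(out / "enrichment.tsv", sep="\t", index=False)
            manifest["counts"]["enriched_terms"] = len(ora)

        # --- clustering of significant features (row-scaled ratios)
        sig_matrix = ratios.values.loc[results.index[results["significant"]]].dropna()
        if len(sig_matrix) >= 2:
            scaled, _flagged = enrich.scale_rows(sig_matrix)
            clust = enrich.ward_d2_cluster(scaled, axis="rows")
            clust.write(out / "cluster_merges.tsv", out / "cluster_leaf_order.tsv")
            clust.scaled.to_csv(out / "heatmap_matrix.tsv", sep="\t")
            manifest["counts"]["clustered_features"] = len(sig_matrix)
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _manifest_write(manifest, out / "manifest.json")
        raise
    _manifest_write(manifest, out / "manifest.json")
    return manifest


def run_dia_pipeline(config: PipelineConfig) -> dict:
    """Execute the DIA time-course pipeline; returns the manifest dict."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "pipeline": "dia",
        "version": __version__,
        "seed": config.seed,
        "thresholds": {"alpha": config.alpha, "lfc_min": config.lfc_min},
        "counts": {},
    }
    try:
        if config.sim is not None:
            dataset = synthdata.generate_dia_timecourse(
                config.sim, stages=config.stages, n_bio=config.n_bio, n_tech=config.n_tech
            )
            dataset.write(out / "simulated")
            quantities = dataset.quantities
            design = dia.TimeCourseDesign(dataset.run_design)
        else:
            indir = Path(config.input_dir)
            quantities = pd.read_csv(
                indir / "dia_protein_matrix.tsv", sep="\t", index_col=0
            )
            design = dia.TimeCourseDesign.read(indir / "dia_run_design.tsv")
        manifest["counts"]["proteins_input"] = len(quantities)
        manifest["counts"]["runs"] = quantities.shape[1]

        matrix = dia.build_matrix(quantities, design)
        complete = dia.impute_and_weight(matrix)
        manifest["counts"]["proteins_modeled"] = len(complete.values)
        manifest["counts"]["imputed_cells"] = int(complete.imputed.to_numpy().sum())
        complete.values.to_csv(out / "dia_log10_matrix.tsv", sep="\t")
        complete.centered().to_csv(out / "dia_centered_matrix.tsv", sep="\t")

        results = dia.differential_all_stages(
            complete, alpha=config.alpha, lfc_min=config.lfc_min
        )
        results.to_csv(out / "dia_differential.tsv", sep="\t")
        manifest["counts"]["called"] = int(results["called"].sum())
        manifest["counts"]["called_per_stage"] = {
            stage: int(results.loc[results["stage"] == stage, "called"].sum())
            for stage in design.stages
        }
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _manifest_write(manifest, out / "manifest.json")
        raise
    _manifest_write(manifest, out / "manifest.json")
    return manifest
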