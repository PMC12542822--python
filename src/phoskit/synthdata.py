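"""Ground-truth simulator for TMT phospho and DIA time-course experiments.

Two generators share one configuration:

``generate_phospho_dataset`` emulates a 6-plex isobaric phosphoproteomics
run contrasting kinase-inhibited against control oocytes, three biological
replicates per arm.  It emits an evidence-style PSM table, a protein-group
table, parent protein sequences, and a ground-truth table of planted
effects and phosphosites.  Reporter noise is multiplicative on the log2
scale (log-normal), the standard error structure of isobaric reporter
data.  Planted effects default to dephosphorylation (negative log2
fold change), matching the strong down/up asymmetry such inhibition
produces; the sign is configurable.

``generate_dia_timecourse`` emulates a label-free DIA protein-quantity
matrix over meiotic stages: two conditions x stages x biological x
technical replicates, with most proteins flat across stages, a designated
minority following stage-specific changes, and missingness enriched in
low-abundance proteins.

All randomness flows from the single seed in the config; identical config
and seed give byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .ingest import (
    Design,
    PsmRecord,
    ProteinGroupRecord,
    write_evidence,
    write_protein_groups,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
# residue frequencies roughly matching a vertebrate proteome, S/T/Y not rare
_AA_WEIGHTS = np.array(
    [7.4, 2.5, 5.9, 5.8, 4.0, 7.4, 2.9, 3.8, 7.2, 7.6, 1.8, 4.4, 5.0, 3.7, 4.2, 8.1, 6.2, 6.8, 1.3, 3.3]
)
_AA_WEIGHTS = _AA_WEIGHTS / _AA_WEIGHTS.sum()

# weight of the confident component of the PEP mixture; the remainder is a
# Beta(2, 8) low-confidence tail that exercises the PEP >= 0.01 filter
_PEP_CONFIDENT_WEIGHT = 0.9
_PEP_TAIL_AB = (2.0, 8.0)


# ---------------------------------------------------------------------------
# configuration


DistSpec = int | tuple[str, float]


def _sample_counts(rng: np.random.Generator, spec: DistSpec, size: int) -> np.ndarray:
    """Positive-integer counts: an int means a constant, ("poisson", m) a
    shifted Poisson 1 + Pois(m - 1)."""
    if isinstance(spec, int):
        if spec < 1:
            raise ConfigError(f"count distribution constant must be >= 1, got {spec}")
        return np.full(size, spec, dtype=int)
    kind, param = spec
    if kind == "const":
        return _sample_counts(rng, int(param), size)
    if kind == "poisson":
        if param < 1:
            raise ConfigError(f"poisson count mean must be >= 1, got {param}")
        return 1 + rng.poisson(param - 1.0, size=size)
    raise ConfigError(f"unknown count distribution kind {kind!r}")


@dataclass
class SimConfig:
    """Parameters of the simulated study design.

    Proportions live in [0, 1]; noise standard deviations are on the log2
    scale.  ``effect_log2fc`` is negative by default: the planted signal is
    dephosphorylation of a minority (``effect_fraction``) of features.
    ``site_prob_concentration`` is the Dirichlet concentration of the
    per-PSM localization vectors (larger = more peaked at the true site).
    ``between_replicate_sd`` adds biological variability shared by all
    channels of one replicate at the phosphopeptide level; the default 0
    reflects that replicate-level variance components are otherwise
    unconstrained.
    """

    seed: int
    n_proteins: int = 500
    peptides_per_protein: DistSpec = ("poisson", 3.0)
    psms_per_peptide: DistSpec = ("poisson", 2.0)
    n_channels_per_condition: int = 3
    effect_fraction: float = 0.1
    effect_log2fc: float = -1.0
    reporter_noise_sd: float = 0.25
    pep_alpha_beta: tuple[float, float] = (0.5, 500.0)
    decoy_fraction: float = 0.01
    contaminant_fraction: float = 0.01
    site_prob_concentration: float = 20.0
    missing_rate: float = 0.0
    between_replicate_sd: float = 0.0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigError(f"n_proteins must be >= 1, got {self.n_proteins}")
        if self.n_channels_per_condition < 1:
            raise ConfigError(
                f"n_channels_per_condition must be >= 1, got {self.n_channels_per_condition}"
            )
        for name in ("effect_fraction", "decoy_fraction", "contaminant_fraction", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.decoy_fraction + self.contaminant_fraction >= 1.0:
            raise ConfigError("decoy_fraction + contaminant_fraction must be < 1")
        if self.reporter_noise_sd <= 0:
            raise ConfigError(f"reporter_noise_sd must be > 0, got {self.reporter_noise_sd}")
        if self.site_prob_concentration <= 0:
            raise ConfigError(
                f"site_prob_concentration must be > 0, got {self.site_prob_concentration}"
            )
        a, b = self.pep_alpha_beta
        if a <= 0 or b <= 0:
            raise ConfigError(f"pep_alpha_beta must be positive, got {self.pep_alpha_beta}")
        if self.between_replicate_sd < 0:
            raise ConfigError(
                f"between_replicate_sd must be >= 0, got {self.between_replicate_sd}"
            )
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")


# ---------------------------------------------------------------------------
# phospho (isobaric 6-plex) dataset


@dataclass
class PhosphoDataset:
    """Simulator output bundle for the isobaric phospho experiment."""

    psms: list[PsmRecord]
    protein_groups: list[ProteinGroupRecord]
    truth: pd.DataFrame  # feature_id, parent_protein_id, peptide_sequence, true_effect, true_site_residue, true_site_position
    protein_sequences: dict[str, str]
    design: Design

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_evidence(self.psms, outdir / "evidence.tsv")
        write_protein_groups(self.protein_groups, outdir / "protein_groups.tsv")
        self.truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
        with open(outdir / "proteins.fasta", "w") as fh:
            for pid, seq in self.protein_sequences.items():
                fh.write(f">{pid}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")


def _random_peptide(rng: np.random.Generator) -> tuple[str, np.ndarray]:
    """A tryptic-looking peptide with at least one S/T/Y; returns the
    sequence and its 0-based S/T/Y positions."""
    length = int(rng.integers(8, 19))
    letters = rng.choice(AMINO_ACIDS, size=length, p=_AA_WEIGHTS)
    sty_pos = np.flatnonzero(np.isin(letters, ("S", "T", "Y")))
    if sty_pos.size == 0:
        forced = int(rng.integers(1, length - 1))
        letters[forced] = rng.choice(("S", "T", "Y"))
        sty_pos = np.array([forced])
    return "".join(letters), sty_pos


def _draw_pep(rng: np.random.Generator, n: int, ab: tuple[float, float]) -> np.ndarray:
    confident = rng.beta(*ab, size=n)
    tail = rng.beta(*_PEP_TAIL_AB, size=n)
    use_tail = rng.random(n) >= _PEP_CONFIDENT_WEIGHT
    return np.where(use_tail, tail, confident)


def generate_phospho_dataset(config: SimConfig) -> PhosphoDataset:
    """Simulate the 6-plex phospho experiment with known ground truth.

    Per-protein baselines are drawn on the log2 scale; protein-group
    reporter intensities are log-normal around the baseline.  Each
    phosphopeptide feature carries its parent protein's channel intensity
    times a peptide-level stoichiometry offset, log-normal reporter noise,
    and — for affected features — a shift of ``2**true_effect`` in the
    treated channels.  PSM intensities split each feature's channel
    intensities with channel-independent Dirichlet shares, so summing PSMs
    recovers the feature exactly.  Localization vectors are Dirichlet over
    the peptide's S/T/Y positions, peaked at the true site.  Decoy and
    contaminant rows are appended at the configured rates.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_cond = config.n_channels_per_condition
    n_chan = 2 * n_cond
    design = Design.two_group(n_cond)
    treated = np.array([design.conditions[str(i + 1)] == "treatment" for i in range(n_chan)])

    peptide_counts = _sample_counts(rng, config.peptides_per_protein, config.n_proteins)
    protein_ids = [f"P{i:05d}" for i in range(1, config.n_proteins + 1)]

    # peptides and concatenated parent-protein sequences
    feat_protein: list[str] = []
    feat_seq: list[str] = []
    feat_sty: list[np.ndarray] = []
    protein_sequences: dict[str, str] = {}
    seen_seqs: set[str] = set()
    for pid, k in zip(protein_ids, peptide_counts):
        parts = []
        for _ in range(int(k)):
            seq, sty = _random_peptide(rng)
            while seq in seen_seqs:  # features must be distinct peptides
                seq, sty = _random_peptide(rng)
            seen_seqs.add(seq)
            feat_protein.append(pid)
            feat_seq.append(seq)
            feat_sty.append(sty)
            parts.append(seq)
        protein_sequences[pid] = "".join(parts)

    n_feat = len(feat_seq)
    n_affected = int(round(config.effect_fraction * n_feat))
    affected = np.zeros(n_feat, dtype=bool)
    affected[rng.choice(n_feat, size=n_affected, replace=False)] = True
    true_effect = np.where(affected, config.effect_log2fc, 0.0)

    # true phosphosite per feature: one of the peptide's S/T/Y residues
    true_site_idx = np.array([sty[rng.integers(len(sty))] for sty in feat_sty])
    mod_seqs = [
        f"_{s[: i + 1]}(ph){s[i + 1 :]}_" for s, i in zip(feat_seq, true_site_idx)
    ]

    # protein-group reporter intensities: log-normal around per-protein baseline
    baseline = rng.normal(17.0, 1.5, size=config.n_proteins)
    prot_log2 = baseline[:, None] + rng.normal(
        0.0, config.reporter_noise_sd, size=(config.n_proteins, n_chan)
    )
    prot_intensity = np.power(2.0, prot_log2)
    prot_index = {pid: i for i, pid in enumerate(protein_ids)}

    # feature intensities ride on the parent protein's channel intensity so
    # protein-level noise cancels in the phospho/protein ratio
    stoich = rng.normal(-1.5, 0.8, size=n_feat)  # log2 phospho stoichiometry offset
    feat_noise = rng.normal(0.0, config.reporter_noise_sd, size=(n_feat, n_chan))
    if config.between_replicate_sd > 0:
        feat_noise = feat_noise + rng.normal(
            0.0, config.between_replicate_sd, size=(n_feat, n_chan)
        )
    feat_log2 = (
        np.log2(prot_intensity[[prot_index[p] for p in feat_protein], :])
        + stoich[:, None]
        + feat_noise
        + np.outer(true_effect, treated.astype(float))
    )
    feat_intensity = np.power(2.0, feat_log2)

    # split features into PSMs with channel-independent shares
    psm_counts = _sample_counts(rng, config.psms_per_peptide, n_feat)
    psms: list[PsmRecord] = []
    psm_id = 0
    for f in range(n_feat):
        m = int(psm_counts[f])
        shares = rng.dirichlet(np.full(m, 5.0)) if m > 1 else np.ones(1)
        sty = feat_sty[f]
        base_prob = np.full(len(sty), 0.15 / max(len(sty) - 1, 1))
        base_prob[np.searchsorted(sty, true_site_idx[f])] = 0.85
        if len(sty) == 1:
            base_prob = np.ones(1)
        peps = _draw_pep(rng, m, config.pep_alpha_beta)
        for j in range(m):
            probs = (
                rng.dirichlet(config.site_prob_concentration * base_prob)
                if len(sty) > 1
                else np.ones(1)
            )
            intensities = feat_intensity[f] * shares[j]
            if config.missing_rate > 0:
                drop = rng.random(n_chan) < config.missing_rate
                intensities = np.where(drop, np.nan, intensities)
            psm_id += 1
            psms.append(
                PsmRecord(
                    psm_id=str(psm_id),
                    peptide_sequence=feat_seq[f],
                    modified_sequence=mod_seqs[f],
                    protein_group_id=feat_protein[f],
                    pep=float(peps[j]),
                    reporter_intensities=intensities,
                    site_probabilities={
                        int(pos) + 1: round(float(pr), 6) for pos, pr in zip(sty, probs)
                    },
                )
            )

    # decoy / contaminant contamination of the PSM table
    n_real = len(psms)
    frac_extra = config.decoy_fraction + config.contaminant_fraction
    n_total = int(round(n_real / (1.0 - frac_extra))) if frac_extra > 0 else n_real
    n_extra = n_total - n_real
    n_decoy = int(round(n_total * config.decoy_fraction))
    extra_groups: list[ProteinGroupRecord] = []
    for j in range(n_extra):
        seq, _ = _random_peptide(rng)
        is_decoy = j < n_decoy
        gid = (f"REV__D{j:04d}" if is_decoy else f"CON__C{j:04d}")
        psm_id += 1
        psms.append(
            PsmRecord(
                psm_id=str(psm_id),
                peptide_sequence=seq,
                modified_sequence=f"_{seq}_",
                protein_group_id=gid,
                pep=float(rng.beta(*_PEP_TAIL_AB)),
                reporter_intensities=np.power(
                    2.0, rng.normal(12.0, 1.0, size=n_chan)
                ),
                site_probabilities={},
                is_decoy=is_decoy,
                is_contaminant=not is_decoy,
            )
        )
        extra_groups.append(
            ProteinGroupRecord(
                group_id=gid,
                member_accessions=[gid],
                gene_symbol=None,
                reporter_intensities=np.power(2.0, rng.normal(14.0, 1.0, size=n_chan)),
                is_decoy=is_decoy,
                is_contaminant=not is_decoy,
            )
        )

    groups = [
        ProteinGroupRecord(
            group_id=pid,
            member_accessions=[pid],
            gene_symbol=f"GENE{i + 1}",
            reporter_intensities=prot_intensity[i],
        )
        for i, pid in enumerate(protein_ids)
    ] + extra_groups

    truth = pd.DataFrame(
        {
            "feature_id": mod_seqs,
            "parent_protein_id": feat_protein,
            "peptide_sequence": feat_seq,
            "true_effect": true_effect,
            "true_site_residue": [s[i] for s, i in zip(feat_seq, true_site_idx)],
            "true_site_position": true_site_idx + 1,  # 1-based within peptide
        }
    )
    return PhosphoDataset(psms, groups, truth, protein_sequences, design)


# ---------------------------------------------------------------------------
# DIA time course


@dataclass
class DiaDataset:
    """Simulator output bundle for the DIA time-course experiment."""

    quantities: pd.DataFrame  # proteins x runs, raw (linear-scale) with NaN
    run_design: pd.DataFrame  # run_id, condition, stage, bio_replicate, tech_replicate
    truth: pd.DataFrame  # feature_id (=protein), true_effect, affected_stage

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.quantities.to_csv(outdir / "dia_protein_matrix.tsv", sep="\t")
        self.run_design.to_csv(outdir / "dia_run_design.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "dia_ground_truth.tsv", sep="\t", index=False)


def generate_dia_timecourse(
    config: SimConfig,
    stages: list[str],
    n_bio: int = 2,
    n_tech: int = 3,
) -> DiaDataset:
    """Simulate a DIA protein-quantity matrix over meiotic stages.

    Runs enumerate stages x {control, treatment} x biological x technical
    replicates.  Most proteins are flat across stages and conditions
    (abundances largely stable through meiosis); an ``effect_fraction``
    minority changes in the treatment arm at one designated stage by
    ``effect_log2fc``.  Missing values are injected at ``missing_rate``
    overall, enriched in low-abundance proteins.
    """
    config.validate()
    if not stages:
        raise ConfigError("stages must be a nonempty list")
    if n_bio < 1 or n_tech < 1:
        raise ConfigError(f"n_bio and n_tech must be >= 1, got {n_bio}, {n_tech}")
    rng = np.random.default_rng(config.seed)

    runs = []
    for stage in stages:
        for cond in ("control", "treatment"):
            for b in range(1, n_bio + 1):
                for t in range(1, n_tech + 1):
                    runs.append((f"{cond[:3]}_{stage}_b{b}_t{t}", cond, stage, b, t))
    run_design = pd.DataFrame(
        runs, columns=["run_id", "condition", "stage", "bio_replicate", "tech_replicate"]
    )
    n_runs = len(run_design)

    n_prot = config.n_proteins
    protein_ids = [f"P{i:05d}" for i in range(1, n_prot + 1)]
    baseline = rng.normal(6.5, 0.5, size=n_prot)  # log10 abundance

    n_affected = int(round(config.effect_fraction * n_prot))
    affected_idx = rng.choice(n_prot, size=n_affected, replace=False)
    affected_stage = np.array([""] * n_prot, dtype=object)
    affected_stage[affected_idx] = rng.choice(stages, size=n_affected)
    true_effect = np.zeros(n_prot)
    true_effect[affected_idx] = config.effect_log2fc

    log2_to_log10 = np.log10(2.0)
    sd10 = config.reporter_noise_sd * log2_to_log10
    bio_offsets = rng.normal(
        0.0, config.between_replicate_sd * log2_to_log10, size=(n_prot, len(stages) * 2 * n_bio)
    )

    values = np.empty((n_prot, n_runs))
    bio_col = 0
    col = 0
    for stage in stages:
        for cond in ("control", "treatment"):
            for _b in range(n_bio):
                shift = np.where(
                    (affected_stage == stage) & (cond == "treatment"),
                    true_effect * log2_to_log10,
                    0.0,
                )
                mean = baseline + shift + bio_offsets[:, bio_col]
                for _t in range(n_tech):
                    values[:, col] = mean + rng.normal(0.0, sd10, size=n_prot)
                    col += 1
                bio_col += 1

    quantities = np.power(10.0, values)
    if config.missing_rate > 0:
        # abundance-dependent missingness: probability decreases with rank
        pct = pd.Series(baseline).rank(pct=True).to_numpy()
        p_miss = np.clip(2.0 * config.missing_rate * (1.0 - pct), 0.0, 0.95)
        drop = rng.random((n_prot, n_runs)) < p_miss[:, None]
        quantities = np.where(drop, np.nan, quantities)

    qdf = pd.DataFrame(quantities, index=pd.Index(protein_ids, name="protein_group_id"),
                       columns=run_design["run_id"].tolist())
    truth = pd.DataFrame(
        {
            "feature_id": protein_ids,
            "true_effect": true_effect,
            "affected_stage": affected_stage,
        }
    )
    return DiaDataset(qdf, run_design, truth)
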