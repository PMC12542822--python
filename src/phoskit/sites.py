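"""Phosphosite localization aggregation and kinase-motif matrices.

Search engines report a per-residue S/T/Y localization probability for
each PSM.  Those vectors are mean-aggregated per peptide sequence across
all of the peptide's PSMs (a position absent from one PSM's vector
contributes 0 for that PSM, so every PSM enters the denominator), and the
position with the highest mean is taken as the peptide's phosphosite.

Motif matrices compare the residue composition around foreground
phosphosites (e.g. significantly dephosphorylated peptides) against a
background (e.g. all dephosphorylated peptides): per window position and
residue, the enrichment contribution is f*log2(f/b), clipped at zero and
scaled by log2(20) so values live in [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ConsistencyError
from .ingest import PsmRecord

logger = logging.getLogger(__name__)

AA20 = list("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"


@dataclass
class LocalizedSite:
    """A peptide's aggregated most-likely phosphosite."""

    peptide_sequence: str
    parent_protein_id: str
    residue: str
    peptide_position: int  # 1-based
    mean_probability: float
    n_psms: int
    protein_position: int | None = None  # 1-based, set once proteins are available


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# probability aggregation


def aggregate_site_probabilities(
    psms: list[PsmRecord],
) -> tuple[dict[int, float], LocalizedSite | None]:
    """Mean per-position localization probabilities over one peptide's PSMs.

    All PSMs must share the peptide sequence.  Returns the per-position
    means and the localized site (argmax of means, ties broken by the
    lowest position).  A group in which no PSM carries any probability is
    unlocalizable: the site is None.
    """
    if not psms:
        raise ValueError("PSM group is empty")
    seq = psms[0].peptide_sequence
    for r in psms:
        if r.peptide_sequence != seq:
            raise ConsistencyError(
                f"PSM group mixes peptide sequences {seq!r} and {r.peptide_sequence!r}"
            )
    positions = sorted({p for r in psms for p in r.site_probabilities})
    if not positions:
        return {}, None
    n = len(psms)
    means = {
        pos: sum(r.site_probabilities.get(pos, 0.0) for r in psms) / n for pos in positions
    }
    best = min(means, key=lambda pos: (-means[pos], pos))
    site = LocalizedSite(
        peptide_sequence=seq,
        parent_protein_id=psms[0].protein_group_id,
        residue=seq[best - 1],
        peptide_position=best,
        mean_probability=means[best],
        n_psms=n,
    )
    return means, site


def localize_sites(psms: list[PsmRecord]) -> tuple[list[LocalizedSite], list[str]]:
    """Aggregate per peptide sequence over a whole filtered PSM list.

    Returns localized sites and the peptide sequences flagged
    unlocalizable (no probability vector on any PSM).
    """
    groups: dict[str, list[PsmRecord]] = {}
    for r in psms:
        groups.setdefault(r.peptide_sequence, []).append(r)
    sites, unlocalizable = [], []
    for seq in sorted(groups):
        _, site = aggregate_site_probabilities(groups[seq])
        if site is None:
            unlocalizable.append(seq)
        else:
            sites.append(site)
    if unlocalizable:
        logger.info("%d peptides unlocalizable (no site probabilities)", len(unlocalizable))
    return sites, unlocalizable


def map_to_protein(sites: list[LocalizedSite], proteins: dict[str, str]) -> list[LocalizedSite]:
    """Fill protein_position via substring lookup of the peptide (first
    occurrence) in its parent protein sequence."""
    out = []
    for s in sites:
        seq = proteins.get(s.parent_protein_id)
        if seq is None:
            logger.warning("no protein sequence for %s; site dropped", s.parent_protein_id)
            continue
        start = seq.find(s.peptide_sequence)
        if start < 0:
            logger.warning(
                "peptide %s not found in protein %s; site dropped",
                s.peptide_sequence,
                s.parent_protein_id,
            )
            continue
        s.protein_position = start + s.peptide_position
        out.append(s)
    return out


# ---------------------------------------------------------------------------
# motif windows


def center_windows(
    sites: list[LocalizedSite], proteins: dict[str, str], w: int = 7
) -> list[str]:
    """(2w+1)-mers from the protein sequence centered on each phosphosite.

    Positions beyond the protein termini are padded with '-', which is
    excluded from frequency counts downstream.  A site whose recorded
    residue disagrees with the protein sequence raises ConsistencyError.
    """
    windows = []
    for s in sites:
        seq = proteins.get(s.parent_protein_id)
        if seq is None:
            raise ConsistencyError(f"no protein sequence for {s.parent_protein_id}")
        if s.protein_position is None:
            mapped = map_to_protein([s], proteins)
            if not mapped:
                raise ConsistencyError(
                    f"cannot place peptide {s.peptide_sequence} in {s.parent_protein_id}"
                )
        pos0 = s.protein_position - 1
        if not (0 <= pos0 < len(seq)) or seq[pos0] != s.residue:
            raise ConsistencyError(
                f"site {s.parent_protein_id}:{s.residue}{s.protein_position} does not match "
                f"protein residue {seq[pos0] if 0 <= pos0 < len(seq) else '?'}"
            )
        left = seq[max(0, pos0 - w) : pos0]
        right = seq[pos0 + 1 : pos0 + 1 + w]
        windows.append(GAP * (w - len(left)) + left + seq[pos0] + right + GAP * (w - len(right)))
    return windows


@dataclass
class MotifMatrix:
    """Scaled information-content matrix, positions x 20 residues."""

    values: pd.DataFrame  # index -w..+w, columns AA20, entries in [0, 1]
    counts: pd.Series  # contributing (non-gap) sequences per position

    def write(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "n", self.counts)
        out.to_csv(path, sep="\t", index_label="position")


def _frequencies(windows: list[str], w: int, pseudocount: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-position residue frequencies (gaps excluded) and non-gap counts."""
    L = 2 * w + 1
    counts = np.zeros((L, len(AA20)))
    aa_index = {a: i for i, a in enumerate(AA20)}
    for win in windows:
        if len(win) != L:
            raise ValueError(f"window {win!r} is not length {L}")
        for j, ch in enumerate(win):
            if ch == GAP:
                continue
            counts[j, aa_index[ch]] += 1
    n = counts.sum(axis=1)
    freq = (counts + pseudocount) / np.maximum(n + 20 * pseudocount, 1e-300)[:, None]
    return freq, n


def motif_information_content(
    foreground: list[str],
    background: list[str],
    pseudocount: float = 0.0,
) -> MotifMatrix:
    """Enrichment-only scaled information content of foreground vs background.

    Per cell: f*log2(f/b), clipped below at 0 and divided by log2(20), so
    a residue fixed in the foreground and uniform (1/20) in the background
    scores exactly 1.  A residue seen in the foreground but absent from
    the (unpseudocounted) background is scored against a floor frequency
    of 1/(n_background + 20), logged.
    """
    if not foreground or not background:
        raise ValueError("foreground and background must be nonempty")
    w = (len(foreground[0]) - 1) // 2
    f, _nf = _frequencies(foreground, w, pseudocount)
    b, nb = _frequencies(background, w, pseudocount)
    floor = 1.0 / (np.maximum(nb, 1) + 20.0)
    zero_b = (b <= 0) & (f > 0)
    if np.any(zero_b):
        logger.info(
            "%d motif cells had foreground residues absent from background; floored",
            int(zero_b.sum()),
        )
    b_eff = np.where(zero_b, floor[:, None], b)
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0) / np.where(b_eff > 0, b_eff, 1.0)), 0.0)
    contrib = np.clip(contrib, 0.0, None) / math.log2(20)
    contrib = np.minimum(contrib, 1.0)
    positions = list(range(-w, w + 1))
    values = pd.DataFrame(contrib, index=positions, columns=AA20)
    counts = pd.Series(_frequencies(foreground, w, 0.0)[1], index=positions)
    return MotifMatrix(values, counts)


# ---------------------------------------------------------------------------
# kinase-target subsetting


def read_kinase_scores(path) -> pd.DataFrame:
    """Kinase-prediction rank table: peptide_sequence, kinase, rank."""
    df = pd.read_csv(path, sep="\t")
    needed = {"peptide_sequence", "kinase", "rank"}
    missing = needed - set(df.columns)
    if missing:
        raise ConsistencyError(f"kinase-score table lacks column(s): {sorted(missing)}")
    return df


def select_kinase_subset(
    sites: list[LocalizedSite],
    kinase_scores: pd.DataFrame,
    kinase: str,
    rank_max: int = 10,
) -> list[LocalizedSite]:
    """Sites whose peptide has ``kinase`` among its top ``rank_max``
    predicted kinases (rank <= rank_max, inclusive)."""
    sub = kinase_scores[kinase_scores["kinase"] == kinase]
    if sub.empty:
        logger.warning("kinase %r absent from score table; empty subset", kinase)
        return []
    ranks = sub.set_index("peptide_sequence")["rank"]
    return [
        s
        for s in sites
        if s.peptide_sequence in ranks.index and ranks[s.peptide_sequence] <= rank_max
    ]


def sites_table(sites: list[LocalizedSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peptide_sequence": [s.peptide_sequence for s in sites],
            "parent_protein_id": [s.parent_protein_id for s in sites],
            "site": [f"{s.residue}{s.protein_position or s.peptide_position}" for s in sites],
            "peptide_position": [s.peptide_position for s in sites],
            "protein_position": [s.protein_position for s in sites],
            "mean_probability": [s.mean_probability for s in sites],
            "n_psms": [s.n_psms for s in sites],
        }
    )
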