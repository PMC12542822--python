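"""Phosphopeptide/parent-protein ratio normalization.

Quantification unit: the sequence-PTM combination (one modified sequence).
PSM reporter intensities are summed per combination and channel, then
divided by the parent protein group's corrected intensity and
log2-transformed.  Dividing by the parent protein separates phosphorylation
changes from protein-abundance changes; the log2 ratio matrix is the input
to the differential model.

A feature whose parent group has no intensity in any channel cannot be
normalized; it is excluded from the matrix but counted in the match-rate
denominator, so ``match_rate`` reports the fraction of phosphopeptide
features with a usable parent intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import Design, N_CHANNELS, PsmRecord, ProteinGroupRecord

logger = logging.getLogger(__name__)

INTENSITY_COLUMNS = [f"intensity_{i}" for i in range(1, N_CHANNELS + 1)]


def aggregate_psms_to_features(psms: list[PsmRecord]) -> pd.DataFrame:
    """Sum PSM reporter intensities per sequence-PTM combination.

    Returns a frame indexed by modified sequence with per-channel summed
    intensities (NaN where every contributing PSM is missing), the peptide
    sequence, the parent protein group id (the single leading/razor group
    carried on the PSMs), and the PSM multiplicity ``n_psms``.
    """
    rows = []
    for r in psms:
        rows.append(
            [r.modified_sequence, r.peptide_sequence, r.protein_group_id]
            + list(r.reporter_intensities)
        )
    df = pd.DataFrame(
        rows, columns=["feature_id", "peptide_sequence", "protein_group_id"] + INTENSITY_COLUMNS
    )
    grouped = df.groupby("feature_id", sort=True)
    intens = grouped[INTENSITY_COLUMNS].sum(min_count=1)  # all-NaN stays NaN
    meta = grouped[["peptide_sequence", "protein_group_id"]].first()
    out = meta.join(intens)
    out["n_psms"] = grouped.size()
    return out


@dataclass
class RatioMatrix:
    """Log2 phosphopeptide/parent-protein ratios, features x channels."""

    values: pd.DataFrame  # index feature_id, columns channel labels "1".."6"
    feature_meta: pd.DataFrame  # protein_group_id, peptide_sequence, n_psms
    match_rate: float
    n_unmatched: int = 0

    def write(self, path) -> None:
        out = self.feature_meta.join(self.values)
        out.to_csv(path, sep="\t")


def compute_log_ratios(
    features: pd.DataFrame,
    protein_groups: list[ProteinGroupRecord],
    design: Design,
) -> RatioMatrix:
    """Form log2(feature intensity / parent protein intensity) per channel.

    Ratios are computed per channel, never on channel-summed intensities,
    since the differential model compares per-channel ratios between
    conditions.  Cells where either intensity is missing or non-positive
    are NaN.  Features referencing an unknown protein group are excluded
    and logged, not fatal.
    """
    prot = {g.group_id: g.reporter_intensities for g in protein_groups}
    channels = design.channels
    chan_idx = [int(c) - 1 for c in channels]

    keep_rows = []
    ratio_rows = []
    n_total = len(features)
    n_unmatched = 0
    for fid, row in features.iterrows():
        gid = row["protein_group_id"]
        parent = prot.get(gid)
        if parent is None:
            logger.warning("feature %s references unknown protein group %s; excluded", fid, gid)
            n_unmatched += 1
            continue
        if not np.any(np.isfinite(parent) & (parent > 0)):
            n_unmatched += 1
            continue
        feat = np.asarray([row[f"intensity_{c}"] for c in channels], dtype=float)
        par = np.asarray([parent[i] for i in chan_idx], dtype=float)
        ok = np.isfinite(feat) & np.isfinite(par) & (feat > 0) & (par > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(ok, np.log2(feat) - np.log2(par), np.nan)
        keep_rows.append(fid)
        ratio_rows.append(ratios)

    values = pd.DataFrame(
        ratio_rows, index=pd.Index(keep_rows, name="feature_id"), columns=channels
    )
    meta = features.loc[keep_rows, ["protein_group_id", "peptide_sequence", "n_psms"]]
    match_rate = (n_total - n_unmatched) / n_total if n_total else 0.0
    logger.info(
        "%d/%d features matched to a parent protein intensity (match rate %.1f%%)",
        n_total - n_unmatched,
        n_total,
        100.0 * match_rate,
    )
    return RatioMatrix(values, meta, match_rate, n_unmatched)
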