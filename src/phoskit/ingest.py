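"""Reading search-output-style tables and applying confidence filters.

The evidence dialect mirrors a MaxQuant-style PSM table: one row per
peptide-spectrum match carrying six isobaric reporter intensities, a
posterior error probability (PEP), decoy/contaminant flags, and a
per-residue phospho-STY localization string such as ``"S3:0.9;T5:0.1"``.
Protein groups arrive in a companion table with the same six reporter
channels.

Filtering follows the standard confidence rules for such tables: decoy
matches, contaminants, and PSMs with PEP >= 0.01 are removed.  A record
failing several rules is counted once, with priority
decoy > contaminant > PEP, so the filter report is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError

N_CHANNELS = 6
STY = frozenset("STY")
PHOSPHO_MARK = "(ph)"  # appears after the modified residue in modified_sequence

#: column order of the evidence (PSM) dialect
EVIDENCE_COLUMNS = (
    ["id", "Sequence", "Modified sequence", "Protein group IDs", "PEP"]
    + [f"Reporter intensity corrected {i}" for i in range(1, N_CHANNELS + 1)]
    + ["Phospho (STY) Probabilities", "Reverse", "Potential contaminant"]
)

#: column order of the protein-group dialect
PROTEIN_GROUP_COLUMNS = (
    ["id", "Protein IDs", "Gene names"]
    + [f"Reporter intensity corrected {i}" for i in range(1, N_CHANNELS + 1)]
    + ["Reverse", "Potential contaminant"]
)

REPORTER_COLUMNS = [f"Reporter intensity corrected {i}" for i in range(1, N_CHANNELS + 1)]


# ---------------------------------------------------------------------------
# records


@dataclass
class PsmRecord:
    """One peptide-spectrum match.

    ``reporter_intensities`` holds six floats with NaN for missing values;
    a stored intensity of 0 is treated as missing (search engines emit 0
    for channels without signal, and a zero numerator/denominator would
    poison the downstream log-ratios).  ``site_probabilities`` maps 1-based
    peptide positions of S/T/Y residues to localization probabilities.
    """

    psm_id: str
    peptide_sequence: str
    modified_sequence: str
    protein_group_id: str
    pep: float
    reporter_intensities: np.ndarray
    site_probabilities: dict[int, float] = field(default_factory=dict)
    is_decoy: bool = False
    is_contaminant: bool = False

    @property
    def n_phospho(self) -> int:
        return self.modified_sequence.count(PHOSPHO_MARK)

    def validate(self) -> None:
        seq = self.peptide_sequence
        if not seq or not seq.isalpha() or not seq.isupper():
            raise FormatError(f"peptide_sequence {seq!r} is not an uppercase amino-acid string")
        if not 0.0 <= self.pep <= 1.0:
            raise FormatError(f"PEP {self.pep} outside [0, 1]")
        for pos, prob in self.site_probabilities.items():
            if not 1 <= pos <= len(seq):
                raise FormatError(f"site position {pos} outside peptide of length {len(seq)}")
            if seq[pos - 1] not in STY:
                raise FormatError(
                    f"site position {pos} is {seq[pos - 1]!r}, not S/T/Y, in {seq!r}"
                )
            if not 0.0 <= prob <= 1.0:
                raise FormatError(f"site probability {prob} at position {pos} outside [0, 1]")
        if self.site_probabilities:
            total = sum(self.site_probabilities.values())
            if total > max(self.n_phospho, 1) + 1e-6:
                raise FormatError(
                    f"site probabilities sum to {total:.6f}, exceeding the "
                    f"{self.n_phospho} phospho group(s) on {self.modified_sequence!r}"
                )


@dataclass
class ProteinGroupRecord:
    """One protein group with six corrected reporter intensities."""

    group_id: str
    member_accessions: list[str]
    gene_symbol: str | None
    reporter_intensities: np.ndarray
    is_decoy: bool = False
    is_contaminant: bool = False


@dataclass(frozen=True)
class Design:
    """Channel-to-condition assignment for a two-group isobaric experiment."""

    conditions: dict[str, str]  # channel -> "control" | "treatment"
    replicates: dict[str, str]  # channel -> replicate label

    def __post_init__(self) -> None:
        labels = set(self.conditions.values())
        if labels != {"control", "treatment"}:
            raise ConfigError(
                f"Design.conditions must use labels control/treatment, got {sorted(labels)}"
            )
        for label in ("control", "treatment"):
            n = sum(1 for v in self.conditions.values() if v == label)
            if n < 2:
                raise ConfigError(f"Design requires >= 2 channels per condition; {label} has {n}")

    @property
    def channels(self) -> list[str]:
        return list(self.conditions)

    def channels_of(self, condition: str) -> list[str]:
        return [c for c, v in self.conditions.items() if v == condition]

    @classmethod
    def two_group(cls, n_per_condition: int = 3) -> "Design":
        """Default layout: channels 1..n control, n+1..2n treatment."""
        cond, rep = {}, {}
        for i in range(1, 2 * n_per_condition + 1):
            c = str(i)
            cond[c] = "control" if i <= n_per_condition else "treatment"
            rep[c] = f"rep{(i - 1) % n_per_condition + 1}"
        return cls(cond, rep)


# ---------------------------------------------------------------------------
# site-probability string codec


def parse_site_string(text: str, peptide_sequence: str) -> dict[int, float]:
    """Parse ``"S3:0.9;T5:0.1"`` into ``{3: 0.9, 5: 0.1}``.

    Each entry is residue letter + 1-based position + ':' + probability.
    The residue letter must match the peptide sequence and be S, T or Y.
    """
    if text is None or (isinstance(text, float) and math.isnan(text)) or text == "":
        return {}
    out: dict[int, float] = {}
    for token in str(text).split(";"):
        token = token.strip()
        if not token:
            continue
        try:
            head, prob_s = token.split(":")
            residue, pos_s = head[0], head[1:]
            pos = int(pos_s)
            prob = float(prob_s)
        except (ValueError, IndexError) as exc:
            raise FormatError(f"malformed site-probability token {token!r}") from exc
        if residue not in STY:
            raise FormatError(f"site residue {residue!r} in token {token!r} is not S/T/Y")
        if not 1 <= pos <= len(peptide_sequence) or peptide_sequence[pos - 1] != residue:
            raise FormatError(
                f"token {token!r} does not match residue at position {pos} of "
                f"{peptide_sequence!r}"
            )
        if pos in out:
            raise FormatError(f"duplicate site position {pos} in {text!r}")
        out[pos] = prob
    return out


def format_site_string(sites: dict[int, float], peptide_sequence: str) -> str:
    return ";".join(
        f"{peptide_sequence[pos - 1]}{pos}:{prob:g}" for pos, prob in sorted(sites.items())
    )


# ---------------------------------------------------------------------------
# readers / writers


def _flag(value) -> bool:
    return str(value).strip() == "+"


def _read_intensities(row: pd.Series) -> np.ndarray:
    vals = np.asarray([row[c] for c in REPORTER_COLUMNS], dtype=float)
    vals[vals == 0.0] = np.nan  # zero reporter signal is absence, not a measurement
    return vals


def read_evidence(path) -> list[PsmRecord]:
    """Read the evidence-dialect TSV into PsmRecords.

    Missing intensities stay missing (NaN), never zero.  Malformed
    localization strings are rejected with the 1-based data row number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "Protein group IDs": str})
    missing_cols = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"evidence table {path} lacks mandatory column(s): {missing_cols}")
    records: list[PsmRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = pd.Series(row, index=df.columns)
        seq = str(row["Sequence"])
        try:
            sites = parse_site_string(row["Phospho (STY) Probabilities"], seq)
            rec = PsmRecord(
                psm_id=str(row["id"]),
                peptide_sequence=seq,
                modified_sequence=str(row["Modified sequence"]),
                protein_group_id=str(row["Protein group IDs"]),
                pep=float(row["PEP"]),
                reporter_intensities=_read_intensities(row),
                site_probabilities=sites,
                is_decoy=_flag(row["Reverse"]),
                is_contaminant=_flag(row["Potential contaminant"]),
            )
            rec.validate()
        except FormatError as exc:
            raise FormatError(f"evidence row {i}: {exc}") from exc
        records.append(rec)
    return records


def write_evidence(records: list[PsmRecord], path) -> None:
    rows = []
    for r in records:
        row = {
            "id": r.psm_id,
            "Sequence": r.peptide_sequence,
            "Modified sequence": r.modified_sequence,
            "Protein group IDs": r.protein_group_id,
            "PEP": r.pep,
            "Phospho (STY) Probabilities": format_site_string(
                r.site_probabilities, r.peptide_sequence
            ),
            "Reverse": "+" if r.is_decoy else "",
            "Potential contaminant": "+" if r.is_contaminant else "",
        }
        for i, col in enumerate(REPORTER_COLUMNS):
            v = r.reporter_intensities[i]
            row[col] = "" if not np.isfinite(v) else repr(float(v))
        rows.append(row)
    pd.DataFrame(rows, columns=EVIDENCE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_protein_groups(path) -> list[ProteinGroupRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing_cols = [c for c in PROTEIN_GROUP_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"protein-group table {path} lacks mandatory column(s): {missing_cols}")
    seen: set[str] = set()
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = pd.Series(row, index=df.columns)
        gid = str(row["id"])
        if gid in seen:
            raise FormatError(f"protein-group row {i}: duplicate group id {gid!r}")
        seen.add(gid)
        gene = row["Gene names"]
        records.append(
            ProteinGroupRecord(
                group_id=gid,
                member_accessions=str(row["Protein IDs"]).split(";"),
                gene_symbol=None if pd.isna(gene) or gene == "" else str(gene),
                reporter_intensities=_read_intensities(row),
                is_decoy=_flag(row["Reverse"]),
                is_contaminant=_flag(row["Potential contaminant"]),
            )
        )
    return records


def write_protein_groups(records: list[ProteinGroupRecord], path) -> None:
    rows = []
    for r in records:
        row = {
            "id": r.group_id,
            "Protein IDs": ";".join(r.member_accessions),
            "Gene names": r.gene_symbol or "",
            "Reverse": "+" if r.is_decoy else "",
            "Potential contaminant": "+" if r.is_contaminant else "",
        }
        for i, col in enumerate(REPORTER_COLUMNS):
            v = r.reporter_intensities[i]
            row[col] = "" if not np.isfinite(v) else repr(float(v))
        rows.append(row)
    pd.DataFrame(rows, columns=PROTEIN_GROUP_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filtering


@dataclass
class FilterReport:
    n_input: int = 0
    n_decoy: int = 0
    n_contaminant: int = 0
    n_low_confidence: int = 0
    n_retained: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reason": ["decoy", "contaminant", "low_confidence", "retained"],
                "count": [
                    self.n_decoy,
                    self.n_contaminant,
                    self.n_low_confidence,
                    self.n_retained,
                ],
            }
        )


def filter_psms(
    psms: list[PsmRecord], pep_max: float = 0.01
) -> tuple[list[PsmRecord], FilterReport]:
    """Remove decoys, contaminants, and PSMs with PEP >= ``pep_max``.

    The PEP bound is exclusive on the keep side: a record at exactly
    ``pep_max`` is removed.  Each removed record is counted under a single
    reason with priority decoy > contaminant > low-confidence.
    """
    if not 0.0 < pep_max <= 1.0:
        raise ConfigError(f"pep_max must lie in (0, 1], got {pep_max}")
    report = FilterReport(n_input=len(psms))
    retained: list[PsmRecord] = []
    for rec in psms:
        if rec.is_decoy:
            report.n_decoy += 1
        elif rec.is_contaminant:
            report.n_contaminant += 1
        elif rec.pep >= pep_max:
            report.n_low_confidence += 1
        else:
            retained.append(rec)
    report.n_retained = len(retained)
    return retained, report


def filter_protein_groups(
    groups: list[ProteinGroupRecord],
) -> tuple[list[ProteinGroupRecord], FilterReport]:
    """Drop decoy/contaminant protein groups; everything else passes.

    Protein groups are deliberately not post-filtered on peptide counts or
    q-values, so that as many phosphopeptides as possible keep a parent
    intensity for ratio normalization.
    """
    report = FilterReport(n_input=len(groups))
    retained = []
    for g in groups:
        if g.is_decoy:
            report.n_decoy += 1
        elif g.is_contaminant:
            report.n_contaminant += 1
        else:
            retained.append(g)
    report.n_retained = len(retained)
    return retained, report
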