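"""PSM and protein confidence handling: probability filtering and FDR estimation.

Identification confidence (PeptideProphet/ProteinProphet-style posterior
probabilities) is consumed from tab-separated tables; the statistical
models that produce the probabilities are upstream and out of scope here.
The false discovery rate of an accepted set is estimated as the mean of
(1 − p) over accepted entries, the standard reading of a posterior-derived
FDR; a target–decoy estimator is provided as an independent cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

PSM_COLUMNS = [
    "spectrum_id",
    "sample",
    "peptide",
    "modifications",
    "assigned_protein",
    "probability",
    "is_decoy",
]


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match.

    ``modifications`` is a tuple of (position, delta_mass) pairs with the
    position 1-based within the peptide; ``probability`` is the posterior
    probability the identification is correct.
    """

    spectrum_id: str
    sample: str
    peptide: str
    modifications: tuple[tuple[int, float], ...]
    assigned_protein: str | None
    probability: float
    is_decoy: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(
                f"spectrum {self.spectrum_id!r}: probability {self.probability} "
                "outside [0, 1]"
            )
        for pos, _ in self.modifications:
            if not 1 <= pos <= len(self.peptide):
                raise ValueError(
                    f"spectrum {self.spectrum_id!r}: modification position {pos} "
                    f"outside peptide of length {len(self.peptide)}"
                )


@dataclass(frozen=True)
class ProteinConfidence:
    accession: str
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"{self.accession}: probability outside [0, 1]")


def parse_modifications(text: str) -> tuple[tuple[int, float], ...]:
    """Parse 'pos:delta;pos:delta' (empty string → no modifications)."""
    text = text.strip()
    if not text:
        return ()
    mods = []
    for token in text.split(";"):
        pos_s, delta_s = token.split(":")
        mods.append((int(pos_s), float(delta_s)))
    return tuple(mods)


def format_modifications(mods: Sequence[tuple[int, float]]) -> str:
    return ";".join(f"{pos}:{delta:g}" for pos, delta in mods)


def read_psm_table(path: str | Path) -> list[PSMRecord]:
    """Read the PSM TSV dialect (see :data:`PSM_COLUMNS` for the header).

    Raises ``ValueError`` naming the missing column or the offending line
    number for unparseable rows.
    """
    path = Path(path)
    records: list[PSMRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for col in PSM_COLUMNS:
            if col not in header:
                raise ValueError(f"{path}: missing required column {col!r}")
        idx = {c: header.index(c) for c in PSM_COLUMNS}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                records.append(
                    PSMRecord(
                        spectrum_id=fields[idx["spectrum_id"]],
                        sample=fields[idx["sample"]],
                        peptide=fields[idx["peptide"]],
                        modifications=parse_modifications(fields[idx["modifications"]]),
                        assigned_protein=fields[idx["assigned_protein"]] or None,
                        probability=float(fields[idx["probability"]]),
                        is_decoy=fields[idx["is_decoy"]] == "1",
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_psm_table(records: Iterable[PSMRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PSM_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.spectrum_id,
                        r.sample,
                        r.peptide,
                        format_modifications(r.modifications),
                        r.assigned_protein or "",
                        f"{r.probability:.6g}",
                        "1" if r.is_decoy else "0",
                    ]
                )
                + "\n"
            )


def read_protein_confidence(path: str | Path) -> list[ProteinConfidence]:
    """Read a protein-confidence TSV with columns (accession, probability)."""
    out: list[ProteinConfidence] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["accession", "probability"]:
            raise ValueError(f"{path}: expected columns ['accession', 'probability']")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            acc, prob = line.rstrip("\n").split("\t")[:2]
            try:
                out.append(ProteinConfidence(acc, float(prob)))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def apply_probability_filter(records, threshold: float):
    """Keep non-decoy records with probability ≥ threshold, order preserved.

    Works on any sequence of objects carrying ``probability`` and
    ``is_decoy`` attributes (PSM or protein-level records).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return [
        r
        for r in records
        if not getattr(r, "is_decoy", False) and r.probability >= threshold
    ]


def estimate_fdr(accepted_probabilities: Sequence[float]) -> float:
    """FDR of an accepted set as mean(1 − p) over its posterior probabilities."""
    probs = np.asarray(list(accepted_probabilities), dtype=float)
    if probs.size == 0:
        raise ValueError("cannot estimate FDR of an empty accepted set")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean(1.0 - probs))


def target_decoy_fdr(records, threshold: float) -> float:
    """Target–decoy FDR: decoys above threshold over targets above threshold.

    With zero passing targets the raw decoy count is returned as-is and a
    warning is logged (degenerate denominator).
    """
    n_decoy = sum(1 for r in records if r.is_decoy and r.probability >= threshold)
    n_target = sum(1 for r in records if not r.is_decoy and r.probability >= threshold)
    if n_target == 0 and n_decoy > 0:
        logger.warning(
            "target_decoy_fdr: %d decoys but no targets above threshold %.3f",
            n_decoy,
            threshold,
        )
    return n_decoy / max(1, n_target)
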