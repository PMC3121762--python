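"""Spectral-count quantification.

A protein's relative abundance is the number of tandem mass spectra (PSMs)
assigned to it.  Counts are normalized for total mixture content by scaling
every sample to the mean per-sample spectrum total, fold changes are ratios
of pseudocounted normalized counts, and count differences are tested with
Fisher's exact test on the 2×2 table of (entity spectra, remaining spectra)
per group.  A two-model comparison partitions up-regulated entities into
common and model-specific sets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .confidence import PSMRecord
from .digestion import GENE_UNIQUE, ISOFORM_UNIQUE, PeptideIndex

ASSIGNMENT_POLICIES = ("assigned_column", "gene_level", "unique_only")


@dataclass
class SpectralCountMatrix:
    """Entity × sample spectral counts with per-sample totals.

    ``raw`` holds integer counts, ``totals`` the per-sample total accepted
    spectra (the normalization denominator), ``normalized`` the counts
    rescaled to the mean total, and ``dropped`` per-category tallies of
    spectra that no entity received under the assignment policy.
    """

    raw: pd.DataFrame
    totals: pd.Series
    normalized: pd.DataFrame | None = None
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def entities(self) -> list[str]:
        return list(self.raw.index)

    @property
    def samples(self) -> list[str]:
        return list(self.raw.columns)

    def n_dropped(self) -> int:
        return sum(self.dropped.values())


def assign_spectra(
    psms: Sequence[PSMRecord],
    index: PeptideIndex | None = None,
    policy: str = "gene_level",
) -> SpectralCountMatrix:
    """Count accepted spectra per entity and sample under an assignment policy.

    Policies:

    - ``assigned_column`` — trust each PSM's ``assigned_protein`` field;
      PSMs without one are dropped (tallied as ``no_assigned_protein``).
    - ``gene_level`` — count gene-unique and isoform-unique peptides toward
      their gene; multi-gene and unmapped peptides are dropped.
    - ``unique_only`` — count only isoform-unique peptides toward their
      isoform; everything else is dropped.

    Per-sample totals are the counts of *all* input PSMs per sample, so the
    column sums are ≤ totals with equality when nothing is dropped.
    """
    if policy not in ASSIGNMENT_POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected {ASSIGNMENT_POLICIES}")
    if policy != "assigned_column" and index is None:
        raise ValueError(f"policy {policy!r} requires a peptide index")

    counts: Counter[tuple[str, str]] = Counter()
    totals: Counter[str] = Counter()
    dropped: Counter[str] = Counter()
    for psm in psms:
        totals[psm.sample] += 1
        entity = _entity_for(psm, index, policy, dropped)
        if entity is not None:
            counts[(entity, psm.sample)] += 1

    samples = sorted(totals)
    entities = sorted({e for e, _ in counts})
    raw = pd.DataFrame(0, index=entities, columns=samples, dtype=int)
    for (entity, sample), n in counts.items():
        raw.loc[entity, sample] = n
    return SpectralCountMatrix(
        raw=raw,
        totals=pd.Series({s: totals[s] for s in samples}, dtype=float),
        dropped=dict(dropped),
    )


def _entity_for(
    psm: PSMRecord,
    index: PeptideIndex | None,
    policy: str,
    dropped: Counter,
) -> str | None:
    if policy == "assigned_column":
        if not psm.assigned_protein:
            dropped["no_assigned_protein"] += 1
            return None
        return psm.assigned_protein
    occs = index.lookup(psm.peptide)
    if not occs:
        dropped["unmapped"] += 1
        return None
    cls = index.uniqueness(psm.peptide)
    if policy == "gene_level":
        if cls in (ISOFORM_UNIQUE, GENE_UNIQUE):
            return index.gene_of[occs[0].accession]
        dropped["multi_gene" if cls == "multi_gene" else "unclassified"] += 1
        return None
    # unique_only
    if cls == ISOFORM_UNIQUE:
        return occs[0].accession
    dropped["not_isoform_unique"] += 1
    return None


def normalize_counts(matrix: SpectralCountMatrix) -> SpectralCountMatrix:
    """Scale each sample's counts by mean(totals)/total[sample].

    The reference scale is the mean per-sample total, so samples with equal
    totals are left unchanged and per-sample normalized totals agree across
    samples whenever the raw column sums equal the totals.
    """
    if (matrix.totals <= 0).any():
        zero = list(matrix.totals.index[matrix.totals <= 0])
        raise ValueError(f"samples with zero total spectra: {zero}")
    factor = matrix.totals.mean() / matrix.totals
    normalized = matrix.raw.astype(float).mul(factor, axis=1)
    return SpectralCountMatrix(
        raw=matrix.raw,
        totals=matrix.totals,
        normalized=normalized,
        dropped=dict(matrix.dropped),
    )


def fold_change(
    matrix: SpectralCountMatrix,
    group_a: str,
    group_b: str,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-entity fold change normalized_b / normalized_a with a pseudocount.

    Direction is ``group_b`` over ``group_a``; the pseudocount is added to
    both normalized values so undetected-in-one-group entities get a finite
    ratio, and 0 vs 0 gives exactly 1.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    for g in (group_a, group_b):
        if g not in matrix.raw.columns:
            raise KeyError(f"unknown group label {g!r}")
    norm = matrix.normalized
    if norm is None:
        norm = normalize_counts(matrix).normalized
    return (norm[group_b] + pseudocount) / (norm[group_a] + pseudocount)


def count_difference_test(
    matrix: SpectralCountMatrix, entity: str, group_a: str, group_b: str
) -> float:
    """Two-sided Fisher exact p-value for a count difference between groups.

    The 2×2 table contrasts the entity's raw spectra with the remaining
    spectra of each sample: [[count_a, total_a − count_a],
    [count_b, total_b − count_b]].
    """
    if entity not in matrix.raw.index:
        raise KeyError(f"unknown entity {entity!r}")
    a = int(matrix.raw.loc[entity, group_a])
    b = int(matrix.raw.loc[entity, group_b])
    ta = int(matrix.totals[group_a])
    tb = int(matrix.totals[group_b])
    table = [[a, ta - a], [b, tb - b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def upregulated_entities(
    matrix: SpectralCountMatrix,
    group_a: str,
    group_b: str,
    fc_threshold: float,
    p_threshold: float,
    pseudocount: float = 0.5,
) -> set[str]:
    """Entities with fold change ≥ fc_threshold and Fisher p ≤ p_threshold."""
    fc = fold_change(matrix, group_a, group_b, pseudocount)
    up = set()
    for entity in matrix.raw.index:
        if fc[entity] >= fc_threshold:
            p = count_difference_test(matrix, entity, group_a, group_b)
            if p <= p_threshold:
                up.add(entity)
    return up


def compare_models(
    quant_model1: SpectralCountMatrix,
    quant_model2: SpectralCountMatrix,
    group_a: str,
    group_b: str,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    pseudocount: float = 0.5,
) -> dict[str, set[str]]:
    """Partition up-regulated entities across two disease models.

    An entity is "up" in a model when its ``group_b``-over-``group_a`` fold
    change passes ``fc_threshold`` with Fisher p ≤ ``p_threshold``.  Returns
    the partition {common_up, model1_specific, model2_specific}.
    """
    up1 = upregulated_entities(
        quant_model1, group_a, group_b, fc_threshold, p_threshold, pseudocount
    )
    up2 = upregulated_entities(
        quant_model2, group_a, group_b, fc_threshold, p_threshold, pseudocount
    )
    return {
        "common_up": up1 & up2,
        "model1_specific": up1 - up2,
        "model2_specific": up2 - up1,
    }


def write_quant_tsv(
    matrix: SpectralCountMatrix,
    path: str | Path,
    contrasts: Sequence[tuple[str, str]] = (),
    pseudocount: float = 0.5,
) -> None:
    """Write entity × sample raw and normalized counts plus per-contrast
    fold-change and p-value columns."""
    norm = matrix.normalized
    if norm is None:
        norm = normalize_counts(matrix).normalized
    out = pd.DataFrame(index=matrix.raw.index)
    for s in matrix.samples:
        out[f"raw_{s}"] = matrix.raw[s]
    for s in matrix.samples:
        out[f"norm_{s}"] = norm[s].round(4)
    for a, b in contrasts:
        fc = fold_change(matrix, a, b, pseudocount)
        out[f"fc_{b}_vs_{a}"] = fc.round(4)
        out[f"p_{b}_vs_{a}"] = [
            count_difference_test(matrix, e, a, b) for e in matrix.raw.index
        ]
    out.index.name = "entity"
    out.to_csv(path, sep="\t")
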