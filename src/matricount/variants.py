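"""Evidence for post-transcriptional (splice/promoter) variants.

A variant isoform is supported when enough distinct isoform-unique
("variant-specific") peptides are observed among the accepted spectra.
Specificity is relative to the supplied sequence database: a peptide is
specific to an isoform iff its occurrence set is exactly that isoform.
Segment annotations (declared on protein coordinates) let a peptide be
placed on the variant's exon-level structure.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .confidence import PSMRecord
from .digestion import ISOFORM_UNIQUE, PeptideIndex, PeptideOccurrence


@dataclass
class VariantSupportRecord:
    gene: str
    accession: str
    variant_label: str
    n_specific_peptides_possible: int
    n_specific_peptides_observed: int
    specific_spectra: dict[str, int]  # per-group spectra on specific peptides
    supported: bool
    database_size: int  # specificity is database-relative

    def total_specific_spectra(self) -> int:
        return sum(self.specific_spectra.values())


def variant_specific_peptides(index: PeptideIndex, gene: str) -> dict[str, list[str]]:
    """Per-isoform lists of peptides occurring in exactly that isoform.

    Returns a mapping accession → sorted canonical peptides whose entire
    occurrence set lies on that single isoform.  Every isoform of the gene
    appears as a key, possibly with an empty list.
    """
    accessions = [a for a, g in index.gene_of.items() if g == gene]
    if not accessions:
        raise KeyError(f"unknown gene {gene!r}")
    out: dict[str, list[str]] = {a: [] for a in accessions}
    for pep, occs in index.occurrences.items():
        if index.classes[pep] != ISOFORM_UNIQUE:
            continue
        acc = occs[0].accession
        if acc in out:
            out[acc].append(pep)
    for acc in out:
        out[acc].sort()
    return out


def segment_overlap(
    occurrence: PeptideOccurrence, segments: Sequence[tuple[int, int, str]]
) -> set[str]:
    """Labels of annotated segments the peptide occurrence intersects.

    Overlap of ≥1 residue counts; junction-spanning peptides return the
    labels of every segment they touch.
    """
    return {
        label
        for start, end, label in segments
        if occurrence.start <= end and occurrence.end >= start
    }


def variant_support_table(
    psms: Sequence[PSMRecord],
    index: PeptideIndex,
    min_peptides: int = 1,
) -> list[VariantSupportRecord]:
    """Per-isoform variant support from observed isoform-specific peptides.

    For every isoform in the index, counts the distinct observed specific
    peptides and their spectra per group; ``supported`` is set when the
    distinct-peptide count reaches ``min_peptides`` (default 1: a single
    specific peptide is treated as variant evidence).
    """
    if min_peptides < 1:
        raise ValueError("min_peptides must be >= 1")
    specific_of: dict[str, set[str]] = {}
    for gene in index.genes():
        for acc, peps in variant_specific_peptides(index, gene).items():
            specific_of[acc] = set(peps)

    observed: dict[str, set[str]] = defaultdict(set)
    spectra: dict[str, Counter] = defaultdict(Counter)
    for psm in psms:
        pep = index.canonical(psm.peptide)
        if index.classes.get(pep) != ISOFORM_UNIQUE:
            continue
        acc = index.occurrences[pep][0].accession
        observed[acc].add(pep)
        spectra[acc][psm.sample] += 1

    db_size = len(index.isoforms)
    records = []
    for acc in sorted(index.isoforms):
        iso = index.isoforms[acc]
        n_obs = len(observed.get(acc, ()))
        records.append(
            VariantSupportRecord(
                gene=iso.gene,
                accession=acc,
                variant_label=iso.variant_label,
                n_specific_peptides_possible=len(specific_of.get(acc, ())),
                n_specific_peptides_observed=n_obs,
                specific_spectra=dict(spectra.get(acc, {})),
                supported=n_obs >= min_peptides,
                database_size=db_size,
            )
        )
    return records


def write_variant_tsv(
    records: Iterable[VariantSupportRecord], groups: Sequence[str], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene\taccession\tvariant_label\tn_specific_possible\t"
            "n_specific_observed\t"
            + "\t".join(f"spectra_{g}" for g in groups)
            + "\tsupported\tdatabase_size\n"
        )
        for r in records:
            counts = "\t".join(str(r.specific_spectra.get(g, 0)) for g in groups)
            fh.write(
                f"{r.gene}\t{r.accession}\t{r.variant_label}\t"
                f"{r.n_specific_peptides_possible}\t{r.n_specific_peptides_observed}\t"
                f"{counts}\t{int(r.supported)}\t{r.database_size}\n"
            )
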