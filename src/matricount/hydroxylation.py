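"""Lysine-hydroxylation site mapping and occupancy statistics.

Hydroxylysine carries the same +15.9949 Da delta as oxidation, so a
variable modification qualifies as lysine hydroxylation when its mass is
within tolerance of that delta AND the modified peptide residue is K
(oxidized methionine thereby never qualifies).  Sites are mapped onto
protein coordinates through the peptide index, inventoried per protein,
and summarized per group as the hydroxylation status: the percentage of a
protein's spectra whose peptide carries at least one qualifying
modification.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats

from .confidence import PSMRecord
from .digestion import (
    GENE_UNIQUE,
    ISOFORM_UNIQUE,
    PeptideIndex,
    PeptideOccurrence,
)

HYDROXYLATION_DELTA = 15.9949  # Da, monoisotopic +O
DEFAULT_MASS_TOLERANCE = 0.01  # Da

DENOMINATOR_POLICIES = ("all_psms", "k_containing_psms")


@dataclass
class ModSiteRecord:
    """A hydroxylated lysine at a protein position, with per-group spectra counts."""

    accession: str
    position: int  # 1-based protein coordinate
    residue: str
    spectra_count: dict[str, int]
    multi_isoform: bool = False  # peptide also occurs in sibling isoforms

    def total_spectra(self) -> int:
        return sum(self.spectra_count.values())


@dataclass
class OccupancyRecord:
    """Hydroxylation status of one protein in one sample group.

    ``percent`` is None when the denominator is zero (status undefined,
    reported as missing rather than 0).
    """

    accession: str
    group: str
    denominator: int
    modified: int
    percent: float | None

    @property
    def defined(self) -> bool:
        return self.percent is not None


def match_hydroxylation(
    psm: PSMRecord, mass_tolerance: float = DEFAULT_MASS_TOLERANCE
) -> list[int]:
    """Peptide positions (1-based) carrying a qualifying K hydroxylation.

    A modification qualifies iff |delta − 15.9949| ≤ tolerance and the
    peptide residue at its position is K.  Non-qualifying modifications
    pass through silently.
    """
    if mass_tolerance <= 0:
        raise ValueError("mass_tolerance must be positive")
    return [
        pos
        for pos, delta in psm.modifications
        if abs(delta - HYDROXYLATION_DELTA) <= mass_tolerance
        and psm.peptide[pos - 1] == "K"
    ]


def map_site_to_protein(occurrence: PeptideOccurrence, peptide_pos: int) -> int:
    """Protein coordinate of a peptide position: start + pos − 1 (both 1-based)."""
    if not 1 <= peptide_pos <= len(occurrence.peptide):
        raise ValueError(
            f"peptide position {peptide_pos} outside 1..{len(occurrence.peptide)}"
        )
    return occurrence.start + peptide_pos - 1


def _gene_occurrences(
    psm: PSMRecord, index: PeptideIndex, gene: str
) -> tuple[list[PeptideOccurrence], str | None]:
    """Occurrences of the PSM's peptide on isoforms of ``gene``, with its class.

    Multi-gene and unmapped/unclassified peptides return no occurrences.
    """
    cls = index.uniqueness(psm.peptide)
    if cls not in (ISOFORM_UNIQUE, GENE_UNIQUE):
        return [], cls
    occs = [o for o in index.lookup(psm.peptide) if index.gene_of[o.accession] == gene]
    return occs, cls


def site_inventory(
    psms: Sequence[PSMRecord],
    index: PeptideIndex,
    accession: str,
    mass_tolerance: float = DEFAULT_MASS_TOLERANCE,
) -> tuple[list[ModSiteRecord], int]:
    """Distinct hydroxylated lysine positions on ``accession``.

    Only isoform-unique and gene-unique peptides of the protein's gene are
    used; spectra on ambiguous (multi-gene) peptides are excluded and their
    count returned as the second element.  Each site carries per-group
    spectra counts; sites whose peptide also occurs in sibling isoforms are
    flagged ``multi_isoform``.
    """
    if accession not in index.isoforms:
        raise KeyError(f"unknown accession {accession!r}")
    gene = index.gene_of[accession]
    sequence = index.isoforms[accession].sequence
    per_site: dict[int, Counter] = defaultdict(Counter)
    multi_iso: set[int] = set()
    n_ambiguous = 0
    for psm in psms:
        positions = match_hydroxylation(psm, mass_tolerance)
        if not positions:
            continue
        occs, cls = _gene_occurrences(psm, index, gene)
        if not occs:
            if cls == "multi_gene":
                n_ambiguous += 1
            continue
        mine = [o for o in occs if o.accession == accession]
        for occ in mine:
            for pos in positions:
                prot_pos = map_site_to_protein(occ, pos)
                if sequence[prot_pos - 1] != "K":
                    continue  # I/L-canonicalized occurrence may shift identity
                per_site[prot_pos][psm.sample] += 1
                if any(o.accession != accession for o in occs):
                    multi_iso.add(prot_pos)
    records = [
        ModSiteRecord(
            accession=accession,
            position=pos,
            residue="K",
            spectra_count=dict(per_site[pos]),
            multi_isoform=pos in multi_iso,
        )
        for pos in sorted(per_site)
    ]
    return records, n_ambiguous


def hydroxylation_status(
    psms: Sequence[PSMRecord],
    index: PeptideIndex,
    accession: str,
    group: str,
    denominator_policy: str = "all_psms",
    mass_tolerance: float = DEFAULT_MASS_TOLERANCE,
    distinct_peptides: bool = False,
) -> OccupancyRecord:
    """Hydroxylation status of one protein in one group.

    The denominator is the protein's accepted spectra in the group (policy
    ``all_psms``) or only those whose peptide contains lysine
    (``k_containing_psms``); the numerator counts spectra whose peptide
    carries ≥1 qualifying hydroxylation.  With ``distinct_peptides`` the
    unit is distinct peptide sequences instead of spectra.
    """
    if denominator_policy not in DENOMINATOR_POLICIES:
        raise ValueError(
            f"unknown policy {denominator_policy!r}; expected {DENOMINATOR_POLICIES}"
        )
    if accession not in index.isoforms:
        raise KeyError(f"unknown accession {accession!r}")
    gene = index.gene_of[accession]
    denom_units: set | list = set() if distinct_peptides else []
    mod_units: set | list = set() if distinct_peptides else []
    for psm in psms:
        if psm.sample != group:
            continue
        occs, _cls = _gene_occurrences(psm, index, gene)
        if not any(o.accession == accession for o in occs):
            continue
        if denominator_policy == "k_containing_psms" and "K" not in psm.peptide:
            continue
        unit = index.canonical(psm.peptide) if distinct_peptides else psm.spectrum_id
        _add(denom_units, unit)
        if match_hydroxylation(psm, mass_tolerance):
            _add(mod_units, unit)
    denominator = len(denom_units)
    modified = len(mod_units)
    percent = 100.0 * modified / denominator if denominator > 0 else None
    return OccupancyRecord(accession, group, denominator, modified, percent)


def _add(container, item) -> None:
    container.add(item) if isinstance(container, set) else container.append(item)


def compare_status(
    record_a: OccupancyRecord, record_b: OccupancyRecord
) -> tuple[float, float]:
    """Difference in hydroxylation percent (b − a) with a Fisher exact p-value.

    The test contrasts [modified, unmodified] counts of the two records.
    """
    if not record_a.defined or not record_b.defined:
        raise ValueError("both occupancy records must have a defined percent")
    diff = record_b.percent - record_a.percent
    table = [
        [record_a.modified, record_a.denominator - record_a.modified],
        [record_b.modified, record_b.denominator - record_b.modified],
    ]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return diff, p


def write_sites_tsv(
    sites: Iterable[ModSiteRecord], groups: Sequence[str], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tposition\tresidue\t" + "\t".join(groups) + "\tmulti_isoform\n")
        for s in sites:
            counts = "\t".join(str(s.spectra_count.get(g, 0)) for g in groups)
            fh.write(
                f"{s.accession}\t{s.position}\t{s.residue}\t{counts}\t"
                f"{int(s.multi_isoform)}\n"
            )


def write_occupancy_tsv(records: Iterable[OccupancyRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\tgroup\tdenominator\tmodified\tpercent\n")
        for r in records:
            pct = "" if r.percent is None else f"{r.percent:.2f}"
            fh.write(f"{r.accession}\t{r.group}\t{r.denominator}\t{r.modified}\t{pct}\n")
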