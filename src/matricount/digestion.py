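"""In-silico tryptic digestion and peptide-to-isoform indexing.

Protein isoforms are digested with trypsin specificity (cleavage C-terminal
to K/R, optionally suppressed before proline) and the resulting peptides are
indexed against every isoform in the database.  Each peptide receives a
uniqueness class — ``isoform_unique``, ``gene_unique`` or ``multi_gene`` —
which downstream stages use to resolve shared-peptide ambiguity when
counting spectra, mapping modification sites and calling splice/promoter
variants.

Coordinates are 1-based inclusive throughout, matching the K(160)-style
site notation used for collagen hydroxylation sites.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

ISOFORM_UNIQUE = "isoform_unique"
GENE_UNIQUE = "gene_unique"
MULTI_GENE = "multi_gene"
UNCLASSIFIED = "unclassified"  # peptides containing X: identity is ambiguous


class FastaFormatError(ValueError):
    """Raised when a FASTA header does not follow the accession|gene|variant grammar."""


@dataclass(frozen=True)
class IsoformRecord:
    """One protein isoform.

    Parameters
    ----------
    accession : str
        Unique database accession.
    gene : str
        Gene symbol the isoform belongs to.
    variant_label : str
        Human-readable variant name, e.g. ``"canonical"`` or ``"NC1-301"``.
    sequence : str
        Uppercase amino-acid sequence (20-letter alphabet plus ``X``).
    segments : tuple of (start, end, label)
        Optional non-overlapping annotated segments in 1-based inclusive
        protein coordinates, sorted by start.
    """

    accession: str
    gene: str
    variant_label: str
    sequence: str
    segments: tuple[tuple[int, int, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"isoform {self.accession!r}: empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS + "X")
        if bad:
            raise ValueError(
                f"isoform {self.accession!r}: invalid residues {sorted(bad)}"
            )
        prev_end = 0
        for start, end, label in self.segments:
            if not (1 <= start <= end <= len(self.sequence)):
                raise ValueError(
                    f"isoform {self.accession!r}: segment {label!r} ({start}-{end}) "
                    f"outside [1, {len(self.sequence)}]"
                )
            if start <= prev_end:
                raise ValueError(
                    f"isoform {self.accession!r}: segments overlap or are unsorted "
                    f"at {label!r}"
                )
            prev_end = end


@dataclass(frozen=True)
class DigestParams:
    """Trypsin digestion settings.

    Defaults follow typical database-search practice: up to 2 missed
    cleavages, peptide length 6–50, cleavage suppressed before proline,
    and I/L treated as distinct residues for indexing.
    """

    max_missed_cleavages: int = 2
    min_length: int = 6
    max_length: int = 50
    proline_rule: bool = True
    il_equivalent: bool = False

    def __post_init__(self) -> None:
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be non-negative")
        if self.min_length < 1 or self.max_length < self.min_length:
            raise ValueError("require 1 <= min_length <= max_length")


@dataclass(frozen=True)
class PeptideOccurrence:
    """A peptide located on a parent isoform (1-based inclusive coordinates)."""

    peptide: str
    accession: str
    start: int
    end: int
    missed_cleavages: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.peptide):
            raise ValueError("coordinates inconsistent with peptide length")


def canonicalize(peptide: str, il_equivalent: bool = False) -> str:
    """Canonical form of a peptide string for index lookup (I→L if requested)."""
    return peptide.replace("I", "L") if il_equivalent else peptide


def _parse_header(description: str) -> tuple[str, str, str]:
    parts = description.strip().split("|")
    if len(parts) != 3 or not all(p.strip() for p in parts):
        raise FastaFormatError(description)
    return parts[0].strip(), parts[1].strip(), parts[2].strip()


def read_fasta(path: str | Path) -> list[IsoformRecord]:
    """Read isoform records from FASTA with ``>accession|gene|variant_label`` headers.

    Sequences are uppercased and ``*`` stop characters stripped.  Malformed
    headers raise :class:`FastaFormatError` naming the offending line;
    duplicate accessions raise ``ValueError``.
    """
    path = Path(path)
    records: list[IsoformRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            accession, gene, variant = _parse_header(rec.description)
        except FastaFormatError:
            lineno = _header_lineno(path, rec.description)
            raise FastaFormatError(
                f"{path}:{lineno}: header {rec.description!r} does not match "
                "'accession|gene|variant_label'"
            ) from None
        if accession in seen:
            raise ValueError(f"{path}: duplicate accession {accession!r}")
        seen.add(accession)
        sequence = str(rec.seq).upper().replace("*", "")
        records.append(IsoformRecord(accession, gene, variant, sequence))
    return records


def _header_lineno(path: Path, description: str) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">") and line[1:].strip() == description.strip():
                return i
    return 0


def write_fasta(records: Iterable[IsoformRecord], path: str | Path) -> None:
    """Write isoforms in the ``>accession|gene|variant_label`` dialect."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession}|{rec.gene}|{rec.variant_label}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def read_segments(path: str | Path) -> dict[str, list[tuple[int, int, str]]]:
    """Read a segment annotation TSV (accession, start, end, label)."""
    out: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["accession", "start", "end", "label"]
        if header != expected:
            raise ValueError(f"{path}: expected columns {expected}, got {header}")
        for line in fh:
            acc, start, end, label = line.rstrip("\n").split("\t")
            out[acc].append((int(start), int(end), label))
    for acc in out:
        out[acc].sort()
    return dict(out)


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """0-based indices i such that trypsin cuts between residue i and i+1."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and not (proline_rule and sequence[i + 1] == "P")
    ]


def digest(
    sequence: str,
    params: DigestParams = DigestParams(),
    accession: str = "",
) -> list[PeptideOccurrence]:
    """Tryptic peptides of ``sequence`` with 0..max_missed_cleavages missed cuts.

    Returns occurrences ordered by start coordinate then length, with
    1-based inclusive coordinates on the parent sequence.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    sites = cleavage_sites(sequence, params.proline_rule)
    # fragment boundaries as 0-based half-open intervals
    starts = [0] + [s + 1 for s in sites]
    ends = [s + 1 for s in sites] + [len(sequence)]
    n_frag = len(starts)
    out: list[PeptideOccurrence] = []
    for i in range(n_frag):
        for mc in range(min(params.max_missed_cleavages, n_frag - 1 - i) + 1):
            j = i + mc
            pep = sequence[starts[i] : ends[j]]
            if params.min_length <= len(pep) <= params.max_length:
                out.append(
                    PeptideOccurrence(pep, accession, starts[i] + 1, ends[j], mc)
                )
    return out


@dataclass
class PeptideIndex:
    """Canonical peptide → occurrences across a database of isoforms.

    Attributes
    ----------
    occurrences : dict
        Canonical peptide string → tuple of :class:`PeptideOccurrence`.
    classes : dict
        Canonical peptide → uniqueness class.  Peptides containing ``X``
        are ``unclassified`` (their identity is ambiguous).
    gene_of : dict
        Accession → gene symbol.
    isoforms : dict
        Accession → :class:`IsoformRecord`.
    params : DigestParams
        Settings the index was built with (canonicalization must match).
    """

    occurrences: dict[str, tuple[PeptideOccurrence, ...]]
    classes: dict[str, str]
    gene_of: dict[str, str]
    isoforms: dict[str, IsoformRecord]
    params: DigestParams

    def canonical(self, peptide: str) -> str:
        return canonicalize(peptide, self.params.il_equivalent)

    def lookup(self, peptide: str) -> tuple[PeptideOccurrence, ...]:
        return self.occurrences.get(self.canonical(peptide), ())

    def uniqueness(self, peptide: str) -> str | None:
        return self.classes.get(self.canonical(peptide))

    def genes(self) -> list[str]:
        return sorted(set(self.gene_of.values()))


def _classify(occs: Sequence[PeptideOccurrence], gene_of: Mapping[str, str]) -> str:
    accessions = {o.accession for o in occs}
    if len(accessions) == 1:
        return ISOFORM_UNIQUE
    genes = {gene_of[a] for a in accessions}
    return GENE_UNIQUE if len(genes) == 1 else MULTI_GENE


def build_peptide_index(
    isoforms: Sequence[IsoformRecord], params: DigestParams = DigestParams()
) -> PeptideIndex:
    """Digest every isoform and assign per-peptide uniqueness classes."""
    if not isoforms:
        raise ValueError("need at least one isoform to build an index")
    gene_of = {r.accession: r.gene for r in isoforms}
    occurrences: dict[str, list[PeptideOccurrence]] = defaultdict(list)
    for rec in isoforms:
        for occ in digest(rec.sequence, params, accession=rec.accession):
            occurrences[canonicalize(occ.peptide, params.il_equivalent)].append(occ)
    classes = {
        pep: (UNCLASSIFIED if "X" in pep else _classify(occs, gene_of))
        for pep, occs in occurrences.items()
    }
    return PeptideIndex(
        occurrences={p: tuple(o) for p, o in occurrences.items()},
        classes=classes,
        gene_of=gene_of,
        isoforms={r.accession: r for r in isoforms},
        params=params,
    )


def unique_peptide_counts(
    observed_peptides: Iterable[str], index: PeptideIndex, level: str = "gene"
) -> tuple[dict[str, int], set[str]]:
    """Count distinct observed peptides unique at ``level`` per entity.

    At ``level="isoform"`` only isoform-unique peptides count, toward their
    sole accession; at ``level="gene"`` both isoform-unique and gene-unique
    peptides count, toward their gene.  Peptides absent from the index are
    returned separately as the unmapped set.
    """
    if level not in ("gene", "isoform"):
        raise ValueError(f"unknown level {level!r}; expected 'gene' or 'isoform'")
    counts: dict[str, int] = defaultdict(int)
    unmapped: set[str] = set()
    for pep in {index.canonical(p) for p in observed_peptides}:
        occs = index.occurrences.get(pep)
        if not occs:
            unmapped.add(pep)
            continue
        cls = index.classes[pep]
        if level == "isoform":
            if cls == ISOFORM_UNIQUE:
                counts[occs[0].accession] += 1
        else:
            if cls in (ISOFORM_UNIQUE, GENE_UNIQUE):
                counts[index.gene_of[occs[0].accession]] += 1
    return dict(counts), unmapped


def write_index_tsv(index: PeptideIndex, path: str | Path) -> None:
    """Dump the index as TSV: peptide, class, 'accession:start-end;...'."""
    with open(path, "w") as fh:
        fh.write("peptide\tclass\toccurrences\n")
        for pep in sorted(index.occurrences):
            occs = ";".join(
                f"{o.accession}:{o.start}-{o.end}"
                for o in sorted(index.occurrences[pep], key=lambda o: (o.accession, o.start))
            )
            fh.write(f"{pep}\t{index.classes[pep]}\t{occs}\n")
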