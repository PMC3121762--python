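"""Synthetic data with known ground truth.

The generator emulates the statistical structure of a pooled-group,
label-free liver proteomics study of tumor-associated matrix remodeling:
multi-isoform gene families sharing a backbone with variant-private
segments, Poisson spectral counts per isoform per sample group with
planted tumor fold changes, per-spectrum lysine hydroxylation at planted
occupancies, calibrated posterior probabilities with reversed-sequence
decoys, and qPCR Ct tables with additive cycle noise.

Defaults mirror the study conditions: four sample groups per disease
model (control, fibrotic, tumor, adjacent), two models, tumor fold
changes cycling through the magnitudes reported for collagen transcripts
(3, 6.8, 10.8, 32.8) and hydroxylation occupancies spanning the reported
range (0.94 down to 0.05).  All randomness flows through one
``numpy.random.Generator``; a fixed seed gives byte-identical output
files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .confidence import PSMRecord, write_psm_table
from .digestion import DigestParams, IsoformRecord, digest, write_fasta
from .hydroxylation import HYDROXYLATION_DELTA
from .qpcr import QpcrRecord, write_qpcr_table

GROUPS = ("control", "fibrotic", "tumor", "adjacent")
DEFAULT_FOLDS = (3.0, 6.8, 10.8, 32.8)
DEFAULT_OCCUPANCIES = (0.94, 0.33, 0.15, 0.05)

# residues other than K/R for backbone filling; P appears so the
# cleavage-suppression rule is exercised
_OTHER_RESIDUES = "ACDEFGHILMNPQSTVWY"


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs for the synthetic generator.

    ``group_abundances`` maps each sample group to the expected number of
    spectra per expressed isoform before fold changes; ``planted_folds``
    maps genes to the tumor-over-control fold applied in the tumor group;
    ``occupancies`` maps accessions to the per-K-containing-spectrum
    hydroxylation probability.  Unset mappings are resolved from the
    defaults (folds and occupancies cycle through the reported magnitudes).
    """

    n_genes: int = 6
    isoforms_per_gene: int = 2
    backbone_length: int = 360
    variant_segment_length: int = 30
    k_frequency: float = 0.08
    groups: tuple[str, ...] = GROUPS
    group_abundances: Mapping[str, float] | None = None
    planted_folds: Mapping[str, float] | None = None
    occupancies: Mapping[str, float] | None = None
    designated_sites: Mapping[str, tuple[int, ...]] | None = None
    decoy_fraction: float = 0.1
    ct_noise_sd: float = 0.3
    n_qpcr_per_group: int = 5
    unexpressed_variant_genes: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.isoforms_per_gene < 1:
            raise ValueError("need at least one gene and one isoform per gene")
        if not 0 <= self.decoy_fraction <= 1:
            raise ValueError("decoy_fraction must lie in [0, 1]")
        if not 0 < self.k_frequency < 0.5:
            raise ValueError("k_frequency must lie in (0, 0.5)")

    def gene_names(self) -> list[str]:
        return [f"g{i:02d}" for i in range(self.n_genes)]

    def resolved_abundances(self) -> dict[str, float]:
        if self.group_abundances is not None:
            return dict(self.group_abundances)
        return {g: 150.0 for g in self.groups}

    def resolved_folds(self) -> dict[str, float]:
        if self.planted_folds is not None:
            return dict(self.planted_folds)
        return {
            gene: DEFAULT_FOLDS[i % len(DEFAULT_FOLDS)]
            for i, gene in enumerate(self.gene_names())
        }

    def resolved_occupancies(self, accessions: Sequence[str]) -> dict[str, float]:
        if self.occupancies is not None:
            return dict(self.occupancies)
        return {
            acc: DEFAULT_OCCUPANCIES[i % len(DEFAULT_OCCUPANCIES)]
            for i, acc in enumerate(sorted(accessions))
        }


def _random_backbone(config: GeneratorConfig, rng: np.random.Generator) -> str:
    n = config.backbone_length
    u = rng.random(n)
    other = rng.integers(0, len(_OTHER_RESIDUES), size=n)
    residues = []
    for i in range(n):
        if u[i] < config.k_frequency:
            residues.append("K")
        elif u[i] < 1.5 * config.k_frequency:
            residues.append("R")
        else:
            residues.append(_OTHER_RESIDUES[other[i]])
    residues[-1] = "K"  # clean tryptic boundary before any appended segment
    return "".join(residues)


def _private_segment(
    config: GeneratorConfig, backbone: str, rng: np.random.Generator
) -> str:
    # no internal K/R so the whole segment is one tryptic peptide; first
    # residue not P so cleavage after the flanking K is not suppressed
    pool = _OTHER_RESIDUES.replace("P", "")
    for _ in range(100):
        head = pool[rng.integers(0, len(pool))]
        body = "".join(
            _OTHER_RESIDUES[i]
            for i in rng.integers(0, len(_OTHER_RESIDUES), size=config.variant_segment_length - 1)
        )
        seg = head + body
        if seg not in backbone:
            return seg
    raise RuntimeError("could not draw a backbone-disjoint private segment")


def generate_isoform_family(
    config: GeneratorConfig, gene_index: int, rng: np.random.Generator
) -> list[IsoformRecord]:
    """One gene family: a canonical isoform plus variants with private segments.

    Variants append a distinct segment after the backbone's terminal K, so
    each variant's digest contains at least one isoform-unique peptide (the
    segment itself) while the backbone peptides stay shared (gene-unique).
    Segment annotations mark the shared backbone and each private segment.
    """
    gene = config.gene_names()[gene_index]
    backbone = _random_backbone(config, rng)
    length = len(backbone)
    records = [
        IsoformRecord(
            accession=f"{gene}_c",
            gene=gene,
            variant_label="canonical",
            sequence=backbone,
            segments=((1, length, "shared"),),
        )
    ]
    for j in range(1, config.isoforms_per_gene):
        seg = _private_segment(config, backbone, rng)
        records.append(
            IsoformRecord(
                accession=f"{gene}_v{j}",
                gene=gene,
                variant_label=f"ALT{j}-{len(seg)}",
                sequence=backbone + seg,
                segments=(
                    (1, length, "shared"),
                    (length + 1, length + len(seg), f"alt{j}"),
                ),
            )
        )
    return records


def generate_database(
    config: GeneratorConfig, rng: np.random.Generator
) -> list[IsoformRecord]:
    """All gene families of the configured database."""
    isoforms: list[IsoformRecord] = []
    for i in range(config.n_genes):
        isoforms.extend(generate_isoform_family(config, i, rng))
    return isoforms


def _draw_probability_high(rng: np.random.Generator) -> float:
    # correct-identification component: posterior concentrated near 1
    return float(np.clip(1.0 - rng.beta(0.6, 40.0), 0.0, 1.0))


def simulate_confidences(
    n: int, rng: np.random.Generator, correct_fraction: float = 0.9
) -> tuple[np.ndarray, np.ndarray]:
    """Calibrated protein/PSM confidence scores with ground-truth labels.

    Draws probabilities from a two-component mixture (a correct-like
    component concentrated near 1 and an incorrect-like component spread
    low) and then labels each entry correct with probability equal to its
    score — so the scores are perfectly calibrated by construction and
    mean(1 − p) over any acceptance set estimates its false fraction.
    """
    is_high = rng.random(n) < correct_fraction
    p = np.where(
        is_high,
        np.clip(1.0 - rng.beta(0.6, 40.0, size=n), 0.0, 1.0),
        rng.beta(1.5, 6.0, size=n),
    )
    is_correct = rng.random(n) < p
    return p, is_correct


def _expected_spectra(
    config: GeneratorConfig, iso: IsoformRecord, group: str
) -> float:
    if iso.gene in config.unexpressed_variant_genes and iso.variant_label != "canonical":
        return 0.0
    base = config.resolved_abundances()[group]
    if group == "tumor":
        base *= config.resolved_folds().get(iso.gene, 1.0)
    return base


def simulate_psms(
    config: GeneratorConfig,
    isoforms: Sequence[IsoformRecord],
    rng: np.random.Generator,
    digest_params: DigestParams = DigestParams(max_missed_cleavages=0),
) -> tuple[list[PSMRecord], dict]:
    """Poisson spectral counts per isoform per group, rendered as PSM records.

    Spectra are distributed uniformly over the isoform's tryptic peptides
    (fixed uniform detectability); each K-containing spectrum is
    hydroxylated with probability equal to the entity's occupancy, the
    modified position drawn uniformly among the peptide's lysines (or
    restricted to designated protein sites when configured).  Reversed-
    sequence decoys are appended at ``decoy_fraction`` with low scores.

    Returns the records and a truth document holding the emitted per-entity
    counts, folds, occupancies, modified protein sites, K-containing and
    modified spectrum tallies, and expressed variants.
    """
    occupancies = config.resolved_occupancies([r.accession for r in isoforms])
    records: list[PSMRecord] = []
    truth_counts: dict[str, dict[str, int]] = {}
    truth_sites: dict[str, set[int]] = {}
    truth_k_spectra: dict[str, dict[str, int]] = {}
    truth_mod_spectra: dict[str, dict[str, int]] = {}
    spectrum_no = 0

    for iso in sorted(isoforms, key=lambda r: r.accession):
        occs = digest(iso.sequence, digest_params, accession=iso.accession)
        if not occs:
            raise RuntimeError(f"{iso.accession}: digest produced no peptides")
        occupancy = occupancies.get(iso.accession, 0.0)
        designated = set(
            (config.designated_sites or {}).get(iso.accession, ())
        )
        truth_counts[iso.accession] = {}
        truth_k_spectra[iso.accession] = {}
        truth_mod_spectra[iso.accession] = {}
        truth_sites.setdefault(iso.accession, set())
        for group in config.groups:
            mean = _expected_spectra(config, iso, group)
            n = int(rng.poisson(mean)) if mean > 0 else 0
            truth_counts[iso.accession][group] = n
            n_k = 0
            n_mod = 0
            for _ in range(n):
                occ = occs[int(rng.integers(0, len(occs)))]
                mods: tuple[tuple[int, float], ...] = ()
                k_positions = [i + 1 for i, aa in enumerate(occ.peptide) if aa == "K"]
                if designated:
                    k_positions = [
                        p for p in k_positions if occ.start + p - 1 in designated
                    ]
                if "K" in occ.peptide:
                    n_k += 1
                if k_positions and rng.random() < occupancy:
                    pos = k_positions[int(rng.integers(0, len(k_positions)))]
                    mods = ((pos, HYDROXYLATION_DELTA),)
                    truth_sites[iso.accession].add(occ.start + pos - 1)
                    n_mod += 1
                spectrum_no += 1
                records.append(
                    PSMRecord(
                        spectrum_id=f"sp{spectrum_no:07d}",
                        sample=group,
                        peptide=occ.peptide,
                        modifications=mods,
                        assigned_protein=iso.accession,
                        probability=_draw_probability_high(rng),
                        is_decoy=False,
                    )
                )
            truth_k_spectra[iso.accession][group] = n_k
            truth_mod_spectra[iso.accession][group] = n_mod

    n_decoys = int(round(config.decoy_fraction * len(records)))
    targets = records[:]
    for _ in range(n_decoys):
        src = targets[int(rng.integers(0, len(targets)))]
        rev = src.peptide[::-1]
        if rev == src.peptide:  # palindromes excluded by convention
            continue
        spectrum_no += 1
        records.append(
            PSMRecord(
                spectrum_id=f"sp{spectrum_no:07d}",
                sample=src.sample,
                peptide=rev,
                modifications=(),
                assigned_protein=f"DECOY_{src.assigned_protein}",
                probability=float(rng.beta(1.5, 6.0)),
                is_decoy=True,
            )
        )

    truth = {
        "spectral_counts": truth_counts,
        "k_containing_spectra": truth_k_spectra,
        "modified_spectra": truth_mod_spectra,
        "planted_folds": config.resolved_folds(),
        "occupancies": occupancies,
        "modified_sites": {a: sorted(s) for a, s in truth_sites.items()},
        "expressed_variants": {
            gene: sorted(
                r.accession
                for r in isoforms
                if r.gene == gene
                and any(
                    _expected_spectra(config, r, g) > 0 for g in config.groups
                )
            )
            for gene in {r.gene for r in isoforms}
        },
    }
    return records, truth


def simulate_qpcr(
    config: GeneratorConfig,
    genes: Sequence[str],
    rng: np.random.Generator,
    qpcr_folds: Mapping[str, Mapping[str, float]] | None = None,
    baseline_dct: float = 7.0,
    reference_ct: float = 18.0,
) -> tuple[list[QpcrRecord], dict]:
    """Per-sample Ct tables with planted group fold changes.

    dCt = baseline − log2(true relative expression) + Normal(0, ct_noise_sd);
    the reference Ct is constant per well.  By default the tumor group gets
    the gene's planted fold and every other group fold 1.
    """
    folds = config.resolved_folds()
    records: list[QpcrRecord] = []
    truth: dict[str, dict[str, float]] = {}
    for gene in genes:
        truth[gene] = {}
        for group in config.groups:
            if qpcr_folds is not None:
                fold = float(qpcr_folds.get(gene, {}).get(group, 1.0))
            else:
                fold = folds.get(gene, 1.0) if group == "tumor" else 1.0
            truth[gene][group] = fold
            for i in range(config.n_qpcr_per_group):
                dct = (
                    baseline_dct
                    - np.log2(fold)
                    + rng.normal(0.0, config.ct_noise_sd)
                )
                records.append(
                    QpcrRecord(
                        sample_id=f"{group}{i + 1}",
                        group=group,
                        gene=gene,
                        ct_target=reference_ct + float(dct),
                        ct_reference=reference_ct,
                    )
                )
    return records, {"qpcr_folds": truth}


def comparative_study_design(
    seed: int, n_genes: int = 10, up_fold: float = 8.0
) -> tuple[GeneratorConfig, dict[str, GeneratorConfig], dict[str, set[str]]]:
    """A two-model study with planted common and model-specific up-regulation.

    The first gene is up-regulated in tumors of both models, the second in
    model 1 only, the third in model 2 only; the remaining genes form a
    flat background so mixture-content normalization leaves the planted
    signals detectable.  Returns the shared config, per-model overrides,
    and the expected gene-level partition.
    """
    genes = [f"g{i:02d}" for i in range(n_genes)]
    common, only1, only2 = genes[0], genes[1], genes[2]
    base = GeneratorConfig(n_genes=n_genes, seed=seed, planted_folds={})
    overrides = {
        "model1": replace(base, planted_folds={common: up_fold, only1: up_fold}),
        "model2": replace(base, planted_folds={common: up_fold, only2: up_fold}),
    }
    expected = {
        "common_up": {common},
        "model1_specific": {only1},
        "model2_specific": {only2},
    }
    return base, overrides, expected


def simulate_bundle(
    config: GeneratorConfig,
    out_dir: str | Path,
    models: Sequence[str] = ("model1", "model2"),
    model_overrides: Mapping[str, GeneratorConfig] | None = None,
) -> dict:
    """Write a complete synthetic study to ``out_dir`` and return its truth.

    Emits the isoform FASTA, segment TSV, one PSM TSV per disease model,
    one qPCR TSV, and ``truth.json``.  All models share the sequence
    database; per-model configs (e.g. different planted folds, emulating
    model-specific up-regulation) are supplied via ``model_overrides``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    isoforms = generate_database(config, rng)
    write_fasta(isoforms, out / "isoforms.fasta")
    with open(out / "segments.tsv", "w") as fh:
        fh.write("accession\tstart\tend\tlabel\n")
        for iso in isoforms:
            for start, end, label in iso.segments:
                fh.write(f"{iso.accession}\t{start}\t{end}\t{label}\n")

    truth: dict = {"seed": config.seed, "models": {}}
    for model in models:
        model_cfg = (model_overrides or {}).get(model, config)
        psms, model_truth = simulate_psms(model_cfg, isoforms, rng)
        write_psm_table(psms, out / f"psms_{model}.tsv")
        truth["models"][model] = model_truth

    qpcr_records, qpcr_truth = simulate_qpcr(config, config.gene_names(), rng)
    write_qpcr_table(qpcr_records, out / "qpcr.tsv")
    truth.update(qpcr_truth)
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return truth
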