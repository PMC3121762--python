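"""End-to-end orchestration: filter → index → quantify → PTM → variants → qPCR → compare.

The pipeline reads the documented TSV/FASTA dialects, runs every analysis
stage, writes per-stage TSV outputs plus a machine-readable
``summary.json``, and keeps full accounting of spectra: accepted and
dropped categories always sum to the input count.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .confidence import (
    PSMRecord,
    apply_probability_filter,
    estimate_fdr,
    read_psm_table,
    target_decoy_fdr,
)
from .digestion import (
    DigestParams,
    IsoformRecord,
    build_peptide_index,
    read_fasta,
    read_segments,
    unique_peptide_counts,
    write_index_tsv,
)
from .hydroxylation import (
    hydroxylation_status,
    site_inventory,
    write_occupancy_tsv,
    write_sites_tsv,
)
from .qpcr import group_fold_change, read_qpcr_table, write_fold_change_tsv
from .quant import (
    SpectralCountMatrix,
    assign_spectra,
    compare_models,
    normalize_counts,
    write_quant_tsv,
)
from .variants import variant_support_table, write_variant_tsv

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All run settings; see the CLI ``--help`` for the file dialects."""

    fasta: str
    psm_tables: dict[str, str]  # model name → PSM TSV path
    segments: str | None = None
    qpcr: str | None = None
    out_dir: str = "results"
    digest: DigestParams = field(default_factory=DigestParams)
    probability_threshold: float = 0.97
    assignment_policy: str = "gene_level"
    pseudocount: float = 0.5
    control_group: str = "control"
    test_group: str = "tumor"
    fc_threshold: float = 2.0
    p_threshold: float = 0.05
    denominator_policy: str = "all_psms"
    min_peptides: int = 1
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.probability_threshold <= 1.0:
            raise PipelineError(
                "config", f"probability_threshold {self.probability_threshold} outside [0, 1]"
            )
        if self.pseudocount <= 0:
            raise PipelineError("config", "pseudocount must be positive")
        if not 0 < self.p_threshold <= 1:
            raise PipelineError("config", "p_threshold must lie in (0, 1]")
        for path in [self.fasta, self.segments, self.qpcr, *self.psm_tables.values()]:
            if path is not None and not Path(path).exists():
                raise PipelineError("config", f"input path does not exist: {path}")

    @classmethod
    def from_json(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a JSON config file; keyword overrides win over file values."""
        with open(path) as fh:
            data = json.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        digest_kwargs = data.pop("digest", {})
        return cls(digest=DigestParams(**digest_kwargs), **data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the summary document (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": _config_doc(config),
        "models": {},
    }

    try:
        isoforms = read_fasta(config.fasta)
        if config.segments:
            seg_map = read_segments(config.segments)
            isoforms = [
                IsoformRecord(
                    r.accession,
                    r.gene,
                    r.variant_label,
                    r.sequence,
                    tuple(seg_map.get(r.accession, ())),
                )
                for r in isoforms
            ]
    except Exception as exc:
        raise PipelineError("read_fasta", str(exc)) from exc

    try:
        index = build_peptide_index(isoforms, config.digest)
        write_index_tsv(index, out / "peptide_index.tsv")
    except Exception as exc:
        raise PipelineError("index", str(exc)) from exc

    matrices: dict[str, SpectralCountMatrix] = {}
    for model, psm_path in sorted(config.psm_tables.items()):
        summary["models"][model] = _run_model(
            model, psm_path, index, config, out, matrices
        )

    if config.qpcr:
        try:
            records = read_qpcr_table(config.qpcr)
            genes = sorted({r.gene for r in records})
            groups = sorted(
                {r.group for r in records} - {config.control_group}
            )
            results = [
                group_fold_change(records, gene, group, config.control_group)
                for gene in genes
                for group in groups
            ]
            write_fold_change_tsv(results, out / "qpcr_folds.tsv")
            summary["qpcr"] = {
                f"{r.gene}:{r.contrast[0]}": {"fold": r.fold, "p": r.p_value}
                for r in results
            }
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("qpcr", str(exc)) from exc

    if len(matrices) == 2:
        try:
            (m1, q1), (m2, q2) = sorted(matrices.items())
            partition = compare_models(
                q1,
                q2,
                config.control_group,
                config.test_group,
                config.fc_threshold,
                config.p_threshold,
                config.pseudocount,
            )
            summary["comparison"] = {
                "models": [m1, m2],
                **{k: sorted(v) for k, v in partition.items()},
            }
        except Exception as exc:
            raise PipelineError("compare", str(exc)) from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary


def _run_model(
    model: str,
    psm_path: str,
    index,
    config: PipelineConfig,
    out: Path,
    matrices: dict,
) -> dict:
    try:
        psms = read_psm_table(psm_path)
    except Exception as exc:
        raise PipelineError("read_psms", f"{model}: {exc}") from exc

    try:
        accepted = apply_probability_filter(psms, config.probability_threshold)
        n_decoy = sum(1 for p in psms if p.is_decoy)
        n_below = len(psms) - n_decoy - len(accepted)
        fdr = estimate_fdr([p.probability for p in accepted]) if accepted else None
        td_fdr = target_decoy_fdr(psms, config.probability_threshold)
    except Exception as exc:
        raise PipelineError("filter", f"{model}: {exc}") from exc

    try:
        matrix = assign_spectra(accepted, index, config.assignment_policy)
        matrix = normalize_counts(matrix)
        contrasts = [(config.control_group, config.test_group)]
        write_quant_tsv(
            matrix, out / f"quant_{model}.tsv", contrasts, config.pseudocount
        )
        matrices[model] = matrix
    except Exception as exc:
        raise PipelineError("quant", f"{model}: {exc}") from exc

    groups = matrix.samples
    try:
        all_sites = []
        occupancy_records = []
        for acc in sorted(index.isoforms):
            sites, _ambig = site_inventory(accepted, index, acc)
            all_sites.extend(sites)
            for group in groups:
                occupancy_records.append(
                    hydroxylation_status(
                        accepted, index, acc, group, config.denominator_policy
                    )
                )
        write_sites_tsv(all_sites, groups, out / f"sites_{model}.tsv")
        write_occupancy_tsv(occupancy_records, out / f"occupancy_{model}.tsv")
    except Exception as exc:
        raise PipelineError("ptm", f"{model}: {exc}") from exc

    try:
        support = variant_support_table(accepted, index, config.min_peptides)
        write_variant_tsv(support, groups, out / f"variants_{model}.tsv")
    except Exception as exc:
        raise PipelineError("variants", f"{model}: {exc}") from exc

    gene_counts, unmapped = unique_peptide_counts(
        (p.peptide for p in accepted), index, level="gene"
    )

    assigned = int(matrix.raw.values.sum())
    accounting = {
        "input": len(psms),
        "decoy": n_decoy,
        "below_threshold": n_below,
        "assigned": assigned,
        "dropped": dict(matrix.dropped),
    }
    assert accounting["input"] == (
        n_decoy + n_below + assigned + sum(matrix.dropped.values())
    ), "spectrum accounting does not balance"

    return {
        "accounting": accounting,
        "estimated_fdr": fdr,
        "target_decoy_fdr": td_fdr,
        "entities": matrix.entities,
        "unique_peptides_per_gene": gene_counts,
        "n_unmapped_peptides": len(unmapped),
        "supported_variants": sorted(
            r.accession for r in support if r.supported
        ),
    }


def _config_doc(config: PipelineConfig) -> dict:
    doc = asdict(config)
    doc["digest"] = asdict(config.digest)
    return doc
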