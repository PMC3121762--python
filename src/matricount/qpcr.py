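"""Relative qPCR quantification by the 2^-ddCt method.

Each well's target-gene cycle threshold is normalized to a reference gene
(dCt = Ct_target − Ct_reference, here actin-style single-reference), and
expression relative to a control group is 2^−(dCt − mean control dCt).
Group fold changes use the geometric mean (i.e. the arithmetic mean on the
dCt scale), matching normalization to the mean of control-group expression;
significance is a two-sided Welch t-test on the dCt values.  Amplification
efficiency is assumed to be exactly 2 per cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

QPCR_COLUMNS = ["sample_id", "group", "gene", "ct_target", "ct_reference"]


@dataclass(frozen=True)
class QpcrRecord:
    sample_id: str
    group: str
    gene: str
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name, ct in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not math.isfinite(ct) or ct <= 0:
                raise ValueError(
                    f"sample {self.sample_id!r}: {name}={ct} must be finite and positive"
                )


@dataclass(frozen=True)
class FoldChangeResult:
    gene: str
    contrast: tuple[str, str]  # (group, control_group)
    fold: float
    p_value: float  # NaN when degenerate (zero variance in both groups)
    n_group: int
    n_control: int
    zero_variance: bool = False


def read_qpcr_table(path: str | Path) -> list[QpcrRecord]:
    """Read the qPCR TSV dialect (sample_id, group, gene, ct_target, ct_reference)."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for col in QPCR_COLUMNS:
            if col not in header:
                raise ValueError(f"{path}: missing required column {col!r}")
        idx = {c: header.index(c) for c in QPCR_COLUMNS}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            try:
                records.append(
                    QpcrRecord(
                        sample_id=f[idx["sample_id"]],
                        group=f[idx["group"]],
                        gene=f[idx["gene"]],
                        ct_target=float(f[idx["ct_target"]]),
                        ct_reference=float(f[idx["ct_reference"]]),
                    )
                )
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_qpcr_table(records: Iterable[QpcrRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(QPCR_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.sample_id}\t{r.group}\t{r.gene}\t"
                f"{r.ct_target:.4f}\t{r.ct_reference:.4f}\n"
            )


def delta_ct(record: QpcrRecord) -> float:
    """dCt = Ct_target − Ct_reference."""
    return record.ct_target - record.ct_reference


def fold_2ddct(sample_dct: float, control_dct_mean: float) -> float:
    """Relative expression 2^−(dCt − mean control dCt)."""
    return float(2.0 ** -(sample_dct - control_dct_mean))


def group_fold_change(
    records: Sequence[QpcrRecord],
    gene: str,
    group: str,
    control_group: str,
    geometric: bool = True,
) -> FoldChangeResult:
    """Fold change of a gene in ``group`` over ``control_group``.

    With ``geometric=True`` (default) the fold is the geometric mean of the
    per-sample 2^−ddCt values, i.e. 2^−(mean dCt_group − mean dCt_control);
    the arithmetic mean of per-sample folds is available as an alternative.
    The p-value is a two-sided Welch t-test on the dCt values; with zero
    variance in both groups it is returned as NaN and flagged.
    """
    dct_group = [delta_ct(r) for r in records if r.gene == gene and r.group == group]
    dct_ctrl = [
        delta_ct(r) for r in records if r.gene == gene and r.group == control_group
    ]
    if not dct_group or not dct_ctrl:
        missing = group if not dct_group else control_group
        raise KeyError(f"no qPCR records for gene {gene!r} in group {missing!r}")
    ctrl_mean = float(np.mean(dct_ctrl))
    if geometric:
        fold = fold_2ddct(float(np.mean(dct_group)), ctrl_mean)
    else:
        fold = float(np.mean([fold_2ddct(d, ctrl_mean) for d in dct_group]))

    zero_var = np.var(dct_group) == 0 and np.var(dct_ctrl) == 0
    if len(dct_group) < 2 or len(dct_ctrl) < 2 or zero_var:
        equal_means = zero_var and np.isclose(np.mean(dct_group), ctrl_mean)
        p = 1.0 if equal_means else float("nan")
    else:
        p = float(stats.ttest_ind(dct_group, dct_ctrl, equal_var=False).pvalue)
    return FoldChangeResult(
        gene=gene,
        contrast=(group, control_group),
        fold=fold,
        p_value=p,
        n_group=len(dct_group),
        n_control=len(dct_ctrl),
        zero_variance=zero_var,
    )


def write_fold_change_tsv(results: Iterable[FoldChangeResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tgroup\tcontrol_group\tfold\tp_value\tn_group\tn_control\n")
        for r in results:
            fh.write(
                f"{r.gene}\t{r.contrast[0]}\t{r.contrast[1]}\t{r.fold:.4f}\t"
                f"{r.p_value:.4g}\t{r.n_group}\t{r.n_control}\n"
            )
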