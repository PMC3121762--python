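"""Spectral-count assignment, normalization, fold changes and count tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from matricount import (
    DigestParams,
    IsoformRecord,
    SpectralCountMatrix,
    assign_spectra,
    build_peptide_index,
    compare_models,
    count_difference_test,
    fold_change,
    normalize_counts,
)

from .conftest import make_psm
from .oracles import oracle_fisher_two_sided


def matrix_from_raw(raw: dict, totals: dict) -> SpectralCountMatrix:
    df = pd.DataFrame(raw).T.astype(int)
    return SpectralCountMatrix(raw=df, totals=pd.Series(totals, dtype=float))


@pytest.fixture
def tiny_index():
    isos = [
        IsoformRecord("P1", "geneA", "canonical", "AAAWCK"),
        IsoformRecord("P2", "geneA", "alt", "AAAWCKDDDFGK"),
        IsoformRecord("P3", "geneB", "canonical", "MMMWHKAAAWCK"),
    ]
    return build_peptide_index(isos, DigestParams(0, 4, 50))


class TestAssignSpectra:
    def test_unique_only_counts_isoform_unique_peptides(self, tiny_index):
        psms = [make_psm("DDDFGK", sample="tumor") for _ in range(10)]
        m = assign_spectra(psms, tiny_index, "unique_only")
        assert m.raw.loc["P2", "tumor"] == 10
        assert m.n_dropped() == 0

    def test_multi_gene_peptides_dropped_at_gene_level(self, tiny_index):
        # AAAWCK occurs in geneA (P1, P2) and geneB (P3)
        psms = [make_psm("AAAWCK"), make_psm("DDDFGK")]
        m = assign_spectra(psms, tiny_index, "gene_level")
        assert m.raw.loc["geneA", "tumor"] == 1
        assert m.dropped == {"multi_gene": 1}

    def test_shared_within_gene_counts_toward_gene(self, tiny_index):
        # MMMWHK is unique to P3, hence to geneB
        psms = [make_psm("MMMWHK") for _ in range(4)]
        m = assign_spectra(psms, tiny_index, "gene_level")
        assert m.raw.loc["geneB", "tumor"] == 4

    def test_assigned_column_verbatim_and_missing_dropped(self, tiny_index):
        psms = [
            make_psm("AAAWCK", protein="P9"),
            make_psm("AAAWCK", protein=None),
        ]
        m = assign_spectra(psms, policy="assigned_column")
        assert m.raw.loc["P9", "tumor"] == 1
        assert m.dropped == {"no_assigned_protein": 1}

    def test_totals_count_all_input_spectra(self, tiny_index):
        psms = [make_psm("AAAWCK"), make_psm("DDDFGK"), make_psm("MMMWHK")]
        m = assign_spectra(psms, tiny_index, "gene_level")
        assert m.totals["tumor"] == 3
        assert m.raw["tumor"].sum() + m.n_dropped() == 3

    def test_unknown_policy_rejected(self, tiny_index):
        with pytest.raises(ValueError):
            assign_spectra([], tiny_index, "nsaf")


class TestNormalization:
    def test_mean_total_reference_scaling(self):
        m = matrix_from_raw({"P": {"A": 10, "B": 10}}, {"A": 100, "B": 200})
        n = normalize_counts(m)
        assert n.normalized.loc["P", "A"] == pytest.approx(15.0)
        assert n.normalized.loc["P", "B"] == pytest.approx(7.5)

    def test_equal_totals_leave_counts_unchanged(self):
        m = matrix_from_raw({"P": {"A": 7, "B": 3}}, {"A": 50, "B": 50})
        n = normalize_counts(m)
        assert (n.normalized == m.raw).all().all()

    def test_single_sample_unchanged(self):
        m = matrix_from_raw({"P": {"A": 7}}, {"A": 50})
        assert (normalize_counts(m).normalized == m.raw).all().all()

    def test_zero_total_rejected(self):
        m = matrix_from_raw({"P": {"A": 0, "B": 3}}, {"A": 0, "B": 50})
        with pytest.raises(ValueError, match="zero total"):
            normalize_counts(m)

    def test_conservation_on_random_matrices(self, rng):
        """When totals equal the column sums, normalized per-sample totals
        agree across samples to 1e-9 relative."""
        for _ in range(100):
            n_e = int(rng.integers(1, 30))
            n_s = int(rng.integers(2, 6))
            raw = pd.DataFrame(
                rng.integers(0, 200, size=(n_e, n_s)),
                index=[f"e{i}" for i in range(n_e)],
                columns=[f"s{j}" for j in range(n_s)],
            )
            totals = raw.sum(axis=0).astype(float)
            if (totals == 0).any():
                continue
            norm = normalize_counts(SpectralCountMatrix(raw, totals)).normalized
            sums = norm.sum(axis=0).to_numpy()
            assert np.allclose(sums, sums[0], rtol=1e-9)

    def test_scale_invariance_per_sample(self, rng):
        raw = pd.DataFrame({"A": [10, 5], "B": [4, 8]}, index=["P", "Q"])
        totals = pd.Series({"A": 40.0, "B": 30.0})
        n1 = normalize_counts(SpectralCountMatrix(raw, totals)).normalized
        scaled = raw.copy()
        scaled["A"] *= 3
        n2 = normalize_counts(
            SpectralCountMatrix(scaled, pd.Series({"A": 120.0, "B": 30.0}))
        ).normalized
        # sample A's normalized values depend only on count/total ratio, up to
        # the common mean-total reference; fold changes are unaffected
        assert np.allclose(
            n1["A"] / n1["A"].sum(), n2["A"] / n2["A"].sum()
        )


class TestFoldChange:
    def test_pseudocounted_ratio(self):
        m = matrix_from_raw({"P": {"A": 5, "B": 50}}, {"A": 100, "B": 100})
        fc = fold_change(m, "A", "B", pseudocount=0.5)
        assert fc["P"] == pytest.approx(50.5 / 5.5)

    def test_zero_vs_zero_is_one(self):
        m = matrix_from_raw({"P": {"A": 0, "B": 0}}, {"A": 100, "B": 100})
        assert fold_change(m, "A", "B")["P"] == pytest.approx(1.0)

    def test_unknown_group_rejected(self):
        m = matrix_from_raw({"P": {"A": 1, "B": 2}}, {"A": 10, "B": 10})
        with pytest.raises(KeyError):
            fold_change(m, "A", "C")

    def test_planted_fold_within_poisson_resampling_interval(self, rng):
        """A planted 6.8x ratio at ~300 expected spectra lands inside the
        central 95% interval of a Poisson-resampling oracle."""
        fold, mean_a = 6.8, 300.0
        bg = 20_000
        a = rng.poisson(mean_a)
        b = rng.poisson(mean_a * fold)
        m = matrix_from_raw(
            {"P": {"A": int(a), "B": int(b)}},
            {"A": float(a + bg), "B": float(b + bg)},
        )
        est = fold_change(m, "A", "B")["P"]
        sims = rng.poisson(mean_a * fold, size=4000) / np.maximum(
            rng.poisson(mean_a, size=4000), 1
        )
        lo, hi = np.quantile(sims, [0.025, 0.975])
        # widen slightly for the normalization factor's own variation
        assert 0.9 * lo <= est <= 1.1 * hi


class TestCountDifference:
    @pytest.mark.parametrize(
        "table",
        [
            [[10, 990], [40, 960]],
            [[3, 7], [9, 1]],
            [[0, 12], [5, 8]],
        ],
    )
    def test_matches_exact_hypergeometric_oracle(self, table):
        (a, b), (c, d) = table
        m = matrix_from_raw(
            {"P": {"A": a, "B": c}}, {"A": float(a + b), "B": float(c + d)}
        )
        p = count_difference_test(m, "P", "A", "B")
        assert p == pytest.approx(oracle_fisher_two_sided(table), rel=1e-9)

    def test_all_small_margin_tables_match_oracle(self):
        for row1 in range(0, 31, 6):
            for col1 in range(0, 31, 6):
                for a in range(0, min(row1, col1) + 1, 3):
                    table = [[a, row1 - a], [col1 - a, 30 - row1 - (col1 - a)]]
                    if min(min(r) for r in table) < 0:
                        continue
                    m = matrix_from_raw(
                        {"P": {"A": table[0][0], "B": table[1][0]}},
                        {
                            "A": float(sum(table[0])),
                            "B": float(sum(table[1])),
                        },
                    )
                    if m.totals.min() == 0:
                        continue
                    p = count_difference_test(m, "P", "A", "B")
                    assert p == pytest.approx(
                        oracle_fisher_two_sided(table), rel=1e-7
                    )

    def test_identical_rows_give_p_one(self):
        m = matrix_from_raw({"P": {"A": 10, "B": 10}}, {"A": 100, "B": 100})
        assert count_difference_test(m, "P", "A", "B") == pytest.approx(1.0)

    def test_empty_margins_give_p_one(self):
        m = matrix_from_raw({"P": {"A": 0, "B": 0}}, {"A": 1000, "B": 1000})
        assert count_difference_test(m, "P", "A", "B") == pytest.approx(1.0)

    def test_unknown_entity_rejected(self):
        m = matrix_from_raw({"P": {"A": 1, "B": 1}}, {"A": 10, "B": 10})
        with pytest.raises(KeyError):
            count_difference_test(m, "Q", "A", "B")


class TestCompareModels:
    def test_partition_by_membership(self):
        def mat(up_entities):
            raw = {
                e: {"control": 20, "tumor": 200 if e in up_entities else 20}
                for e in ["itga5", "itga8", "itgb1", "flat"]
            }
            totals = {
                "control": 10_000.0,
                "tumor": 10_000.0 + 180 * len(up_entities),
            }
            return matrix_from_raw(raw, totals)

        partition = compare_models(
            mat({"itga5", "itga8"}),
            mat({"itga5", "itgb1"}),
            "control",
            "tumor",
            fc_threshold=2.0,
            p_threshold=0.05,
        )
        assert partition["common_up"] == {"itga5"}
        assert partition["model1_specific"] == {"itga8"}
        assert partition["model2_specific"] == {"itgb1"}
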