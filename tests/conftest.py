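import numpy as np
import pytest

from matricount import (
    DigestParams,
    IsoformRecord,
    PSMRecord,
    build_peptide_index,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240131)


@pytest.fixture
def collagen_like_family():
    """Two isoforms of one gene (shared backbone + variant-private tail)
    plus a single-isoform second gene."""
    backbone = "MAAAGPKGDRGPPGSSKGEELTNKVVVDDKPPPGSSK"
    tail = "WWFFYYHHMMNNQQCCDDEE"
    return [
        IsoformRecord("colA_c", "colA", "canonical", backbone,
                      segments=((1, len(backbone), "shared"),)),
        IsoformRecord("colA_v1", "colA", "ALT-20", backbone + tail,
                      segments=((1, len(backbone), "shared"),
                                (len(backbone) + 1, len(backbone) + len(tail), "alt1"))),
        IsoformRecord("colB_c", "colB", "canonical",
                      "MMMTTTWWWKGGGHHHCCCRFFFYYYNNNK"),
    ]


@pytest.fixture
def family_index(collagen_like_family):
    return build_peptide_index(
        collagen_like_family,
        DigestParams(max_missed_cleavages=1, min_length=4, max_length=50),
    )


def make_psm(peptide, sample="tumor", mods=(), protein=None, probability=0.99,
             decoy=False, spectrum_id=None):
    make_psm._n = getattr(make_psm, "_n", 0) + 1
    return PSMRecord(
        spectrum_id=spectrum_id or f"s{make_psm._n:05d}",
        sample=sample,
        peptide=peptide,
        modifications=tuple(mods),
        assigned_protein=protein,
        probability=probability,
        is_decoy=decoy,
    )
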