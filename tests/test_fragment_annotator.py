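"""EI fragment pairs, spectral similarity scores, and candidate ranking."""

import math

import pytest

from iroakit.fragment_annotator import (
    CandidateSpectrum,
    dot_product_score,
    ei_pair_config,
    find_ei_pairs,
    jaccard_score,
    rank_candidates,
    read_candidates_csv,
    read_candidates_msp,
)
from iroakit.isotope_model import EnrichmentModel
from iroakit.spectra_io import CentroidSpectrum, Peak
from iroakit.synthetic_data import SimulationConfig, fixture_library, simulate_ei_spectrum


class TestFindEiPairs:
    def test_unknown_metabolite_spectrum(self, fig4_spectrum):
        """The 3-carbon and 2-carbon fragment pairs emerge from the background."""
        pairs = find_ei_pairs(fig4_spectrum)
        got = {(p.mz12, p.mz13, p.n_carbons) for p in pairs}
        assert (131.0883, 134.0991, 3) in got
        assert (292.1345, 294.1427, 2) in got
        assert len(pairs) == 2

    def test_isoleucine_fragments(self, enrichment, library, noiseless_config):
        ei = simulate_ei_spectrum(library["isoleucine_2tms"], enrichment,
                                  noiseless_config)
        pairs = find_ei_pairs(ei, enrichment)
        assert sorted(p.n_carbons for p in pairs) == [2, 5, 6]

    def test_background_ions_never_anchor(self):
        """Derivatization ions are barred from pairing even when a peak sits
        at a valid carbon spacing from them."""
        from iroakit.constants import DELTA_13C

        partner = 73.0468 + 8 * DELTA_13C
        spec = CentroidSpectrum(peaks=(Peak(73.0468, 1e5), Peak(partner, 9e4)))
        assert find_ei_pairs(spec) == []
        # the same spacing with non-excluded masses does pair
        shifted = CentroidSpectrum(
            peaks=(Peak(75.0468, 1e5), Peak(partner + 2.0, 9e4)))
        assert len(find_ei_pairs(shifted)) == 1

    def test_empty_spectrum(self):
        assert find_ei_pairs(CentroidSpectrum(peaks=())) == []


class TestSimilarityScores:
    def _toy(self):
        a = [(100.0, 400.0), (150.0, 100.0), (200.0, 900.0)]
        b = [(100.0, 400.0), (150.0, 100.0), (250.0, 900.0)]
        return a, b

    def test_identical_spectra(self):
        a, _ = self._toy()
        assert dot_product_score(a, a) == pytest.approx(1.0)
        assert jaccard_score(a, a) == pytest.approx(1.0)

    def test_disjoint_spectra(self):
        a = [(100.0, 1.0)]
        b = [(300.0, 1.0)]
        assert dot_product_score(a, b) == 0.0
        assert jaccard_score(a, b) == 0.0

    def test_hand_computed_cosine(self):
        """Partially matched 3-peak toy agrees with the hand-worked cosine."""
        a, b = self._toy()
        # sqrt weights: a=(20,10,30), b=(20,10,30); matched peaks 100 and 150
        expected = (20 * 20 + 10 * 10) / (
            math.sqrt(400 + 100 + 900) * math.sqrt(400 + 100 + 900)
        )
        assert dot_product_score(a, b) == pytest.approx(expected)
        assert jaccard_score(a, b) == pytest.approx(2 / 4)

    def test_symmetry_and_scale_invariance(self):
        a, b = self._toy()
        b10 = [(mz, i * 10) for mz, i in b]
        assert dot_product_score(a, b) == pytest.approx(dot_product_score(b, a))
        assert dot_product_score(a, b10) == pytest.approx(dot_product_score(a, b))
        assert jaccard_score(a, b) == pytest.approx(jaccard_score(b, a))

    def test_cosine_against_matchms(self):
        """Independent cross-check against the matchms CosineGreedy scorer."""
        import numpy as np
        from matchms import Spectrum
        from matchms.similarity import CosineGreedy

        a = [(100.0, 400.0), (150.0, 100.0), (200.3, 900.0), (310.0, 50.0)]
        b = [(100.0, 360.0), (150.004, 120.0), (200.3, 800.0), (250.0, 40.0)]
        ours = dot_product_score(a, b, mz_tol=0.005, weighting="none")
        sa = Spectrum(mz=np.array([p[0] for p in a]),
                      intensities=np.array([p[1] for p in a]),
                      metadata={"precursor_mz": 500.0})
        sb = Spectrum(mz=np.array([p[0] for p in b]),
                      intensities=np.array([p[1] for p in b]),
                      metadata={"precursor_mz": 500.0})
        theirs = float(CosineGreedy(tolerance=0.005).pair(sa, sb)["score"])
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_noise_peak_never_raises_jaccard(self):
        a, b = self._toy()
        base = jaccard_score(a, b)
        noisy = a + [(500.0, 10.0)]
        assert jaccard_score(noisy, b) <= base

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dot_product_score([], [(100.0, 1.0)])


def _dhiv_candidates():
    """Isomer candidates for the 5-carbon unknown; only two predict the
    3-carbon fragment at m/z 131."""
    formula = {"C": 14, "H": 34, "O": 4, "Si": 3}
    frag131 = {"C": 6, "H": 15, "O": 1, "Si": 1}     # 3 labeled carbons
    frag292 = {"C": 11, "H": 28, "O": 3, "Si": 3}    # 2 labeled carbons
    good_peaks = ((73.05, 999.0), (131.0887, 800.0), (292.135, 400.0))
    return [
        CandidateSpectrum(
            candidate_id="dihydroxyisovalerate_3tms",
            formula=formula,
            peaks=good_peaks,
            fragment_formulas={1: frag131, 2: frag292},
        ),
        CandidateSpectrum(
            candidate_id="dihydroxyvalerate_3tms",
            formula=formula,
            peaks=good_peaks,
            fragment_formulas={1: frag131, 2: frag292},
        ),
        CandidateSpectrum(
            candidate_id="deoxyribose_3tms",
            formula=formula,
            peaks=((73.05, 999.0), (103.0417, 500.0), (217.1073, 700.0)),
            fragment_formulas={1: {"C": 4, "H": 11, "O": 1, "Si": 1},
                               2: {"C": 9, "H": 21, "O": 2, "Si": 2}},
        ),
        CandidateSpectrum(
            candidate_id="wrong_formula_isomer",
            formula={"C": 14, "H": 34, "N": 1, "O": 4, "Si": 3},
            peaks=good_peaks,
            fragment_formulas={1: frag131, 2: frag292},
        ),
    ]


class TestRankCandidates:
    def test_isomers_with_matching_fragment_rank_top(
        self, enrichment, library, noiseless_config
    ):
        """Only candidates predicting the 131 fragment with 3 labeled
        carbons explain the observed pairs; the two that do tie at the top."""
        met = library["dihydroxyisovalerate_3tms"]
        ei = simulate_ei_spectrum(met, enrichment, noiseless_config)
        pairs = find_ei_pairs(ei, enrichment)
        scores = rank_candidates(
            ei, pairs, _dhiv_candidates(),
            formula_candidates=[{"C": 14, "H": 34, "O": 4, "Si": 3}],
            mz_tol=0.005,
        )
        by_id = {s.candidate_id: s for s in scores}
        top_two = {scores[0].candidate_id, scores[1].candidate_id}
        assert top_two == {"dihydroxyisovalerate_3tms", "dihydroxyvalerate_3tms"}
        assert by_id["dihydroxyisovalerate_3tms"].carbon_consistency == 1.0
        assert by_id["deoxyribose_3tms"].carbon_consistency == 0.0
        assert not by_id["wrong_formula_isomer"].formula_match
        assert by_id["wrong_formula_isomer"].rank == len(scores)

    def test_single_candidate_ranks_first(self, fig4_spectrum):
        cand = CandidateSpectrum(
            candidate_id="only", formula={}, peaks=((131.0887, 1.0),))
        scores = rank_candidates(fig4_spectrum, [], [cand])
        assert scores[0].rank == 1

    def test_no_fragment_formulas_reports_not_available(self, fig4_spectrum):
        pairs = find_ei_pairs(fig4_spectrum)
        cand = CandidateSpectrum(
            candidate_id="mz_only", formula={},
            peaks=((131.0883, 1.0), (292.1345, 0.5)))
        (score,) = rank_candidates(fig4_spectrum, pairs, [cand])
        assert score.carbon_consistency is None
        assert score.mz_match_fraction == 1.0

    def test_empty_candidates_rejected(self, fig4_spectrum):
        with pytest.raises(ValueError):
            rank_candidates(fig4_spectrum, [], [])


class TestCandidateIo:
    def test_csv_roundtrip(self, tmp_path):
        p = tmp_path / "cands.csv"
        p.write_text(
            "candidate_id,formula,mz,intensity,fragment_formula\n"
            "a,C14H34O4Si3,131.0887,800,C6H15OSi\n"
            "a,C14H34O4Si3,292.1350,400,C11H28O3Si3\n"
            "b,C14H34O4Si3,103.0417,500,\n"
        )
        cands = read_candidates_csv(p)
        assert [c.candidate_id for c in cands] == ["a", "b"]
        assert cands[0].formula == {"C": 14, "H": 34, "O": 4, "Si": 3}
        assert cands[0].fragment_formulas[0] == {"C": 6, "H": 15, "O": 1, "Si": 1}
        assert cands[1].fragment_formulas == {}

    def test_msp_candidates(self, tmp_path):
        p = tmp_path / "cands.msp"
        p.write_text(
            "Name: candA\nFormula: C6H12O6\nNum Peaks: 2\n"
            "100.0 50.0\n200.0 100.0\n\n"
        )
        (cand,) = read_candidates_msp(p)
        assert cand.candidate_id == "candA"
        assert cand.formula == {"C": 6, "H": 12, "O": 6}
        assert len(cand.peaks) == 2
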