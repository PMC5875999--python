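"""Pair detection: carbon-count inference, vetting, recovery and false positives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from iroakit.constants import DELTA_13C
from iroakit.isotope_model import DerivatizationSpec, EnrichmentModel
from iroakit.pair_finder import (
    PairSearchConfig,
    carbon_count,
    estimate_tms,
    find_pairs,
    find_pairs_cross,
    pairs_to_dataframe,
    score_pair,
)
from iroakit.spectra_io import CentroidSpectrum, Peak
from iroakit.synthetic_data import (
    GroundTruthMetabolite,
    SimulationConfig,
    simulate_spectrum,
)


class TestCarbonCount:
    def test_known_fragment_pairs(self):
        cfg = PairSearchConfig(mz_tol_ppm=15.0, n_min=1, n_max=20)
        n, res = carbon_count(131.0883, 134.0991, cfg)
        assert n == 3
        n, res = carbon_count(292.1345, 294.1427, cfg)
        assert n == 2

    def test_non_integer_spacing_rejected(self):
        n, _ = carbon_count(100.0, 100.5, PairSearchConfig())
        assert n is None

    @given(
        n=st.integers(min_value=1, max_value=30),
        m0=st.floats(min_value=80.0, max_value=900.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_roundtrip_with_pair_mz(self, n, m0):
        """carbon_count inverts pair_mz exactly for every n in range."""
        from iroakit.isotope_model import pair_mz

        cfg = PairSearchConfig(n_min=1, n_max=30)
        got, res = carbon_count(m0, pair_mz(m0, n), cfg)
        assert got == n
        assert res == pytest.approx(0.0, abs=1e-6)


def _one_metabolite_spectrum(enrichment, n=5, k=2, artifacts=20, seed=1,
                             jitter=0.0, **cfg_kw):
    met = GroundTruthMetabolite(
        name="t", n_carbons=n, k_tms=k, base_mz=274.1295, abundance=1e5
    )
    cfg = SimulationConfig(
        ppm_jitter_sd=jitter, intensity_sigma=0.0,
        artifact_count=artifacts, seed=seed, **cfg_kw,
    )
    return simulate_spectrum([met], enrichment, cfg)


class TestFindPairs:
    def test_single_metabolite_among_artifacts(self, enrichment):
        spec, _ = _one_metabolite_spectrum(enrichment, artifacts=20)
        pairs = find_pairs(spec, enrichment, PairSearchConfig())
        assert len(pairs) == 1
        assert pairs[0].n_carbons == 5
        assert pairs[0].est_tms == 2

    def test_artifact_only_spectrum_yields_nothing(self, enrichment):
        cfg = SimulationConfig(artifact_count=30, seed=3)
        spec, _ = simulate_spectrum([], enrichment, cfg)
        assert find_pairs(spec, enrichment, PairSearchConfig()) == []

    def test_empty_spectrum(self, enrichment):
        assert find_pairs(CentroidSpectrum(peaks=()), enrichment) == []

    def test_two_coeluting_metabolites(self, enrichment, noiseless_config):
        mets = [
            GroundTruthMetabolite(name="a", n_carbons=3, k_tms=1,
                                  base_mz=200.05, abundance=1e5),
            GroundTruthMetabolite(name="b", n_carbons=6, k_tms=2,
                                  base_mz=400.21, abundance=2e5),
        ]
        spec, _ = simulate_spectrum(mets, enrichment, noiseless_config)
        pairs = find_pairs(spec, enrichment, PairSearchConfig())
        assert sorted(p.n_carbons for p in pairs) == [3, 6]

    def test_each_peak_in_at_most_one_pair(self, enrichment):
        mets = [
            GroundTruthMetabolite(name=f"m{i}", n_carbons=3 + i, k_tms=i % 3,
                                  base_mz=150.0 + 37.1 * i, abundance=1e5)
            for i in range(5)
        ]
        cfg = SimulationConfig(ppm_jitter_sd=1.0, artifact_count=30, seed=7)
        spec, _ = simulate_spectrum(mets, enrichment, cfg)
        pairs = find_pairs(spec, enrichment, PairSearchConfig())
        anchors = [p.m0.mz for p in pairs] + [p.mn.mz for p in pairs]
        assert len(anchors) == len(set(anchors))
        for p in pairs:
            assert p.mn.mz > p.m0.mz
            assert abs(p.spacing_residual_ppm) <= 5.0

    def test_ratio_vetting_rejects_wrong_envelope(self, enrichment):
        """Anchor-like peaks with a grossly wrong M+1 ratio are not paired."""
        # planted spacing of 4 carbons but the 12C "M+1" is 3x too intense
        m0 = 300.0
        peaks = (
            Peak(m0, 1e5),
            Peak(m0 + DELTA_13C, 1e5 * 1.6),     # expected ~0.21-0.72 for n=4
            Peak(m0 + 4 * DELTA_13C, 9e4),
        )
        spec = CentroidSpectrum(peaks=peaks)
        assert find_pairs(spec, enrichment, PairSearchConfig()) == []

    def test_saturated_anchor_skips_ratio_check_and_flags(self, enrichment):
        spec, _ = _one_metabolite_spectrum(
            enrichment, artifacts=0, saturation_cap=5e4
        )
        assert any(p.saturated for p in spec.peaks)
        pairs = find_pairs(spec, enrichment, PairSearchConfig())
        assert len(pairs) == 1
        assert "saturated" in pairs[0].flags
        # clipping pushes the observed ratio above the model expectation
        assert pairs[0].obs_m0p1_ratio > 0.44

    def test_recovery_rate_at_orbitrap_jitter(self, enrichment):
        """>=95% of planted pairs recovered with exact n at 1 ppm jitter."""
        rng = np.random.default_rng(0)
        total = recovered = 0
        for seed in range(40):
            n = int(rng.integers(2, 12))
            k = int(rng.integers(0, 4))
            met = GroundTruthMetabolite(
                name="m", n_carbons=n, k_tms=k,
                base_mz=float(rng.uniform(120, 700)), abundance=1e5,
            )
            cfg = SimulationConfig(ppm_jitter_sd=1.0, intensity_sigma=0.05,
                                   artifact_count=20, seed=seed)
            spec, _ = simulate_spectrum([met], enrichment, cfg)
            pairs = find_pairs(spec, enrichment, PairSearchConfig())
            total += 1
            recovered += any(p.n_carbons == n for p in pairs)
        assert recovered / total >= 0.95

    def test_tof_tolerance_is_superset(self, enrichment):
        """Opening the tolerance can only keep or add accepted pairs."""
        spec, _ = _one_metabolite_spectrum(enrichment, artifacts=20, jitter=4.0,
                                           seed=11)
        narrow = find_pairs(spec, enrichment, PairSearchConfig.orbitrap())
        wide = find_pairs(spec, enrichment, PairSearchConfig.tof())
        assert len(wide) >= len(narrow)

    def test_cross_spectrum_mode(self, enrichment, noiseless_config):
        met = GroundTruthMetabolite(name="x", n_carbons=4, k_tms=1,
                                    base_mz=250.1, rt=7.5, abundance=1e5)
        mixed, _ = simulate_spectrum([met], enrichment, noiseless_config)
        # split the mixed spectrum into a 12C-only and a 13C-only view
        mid = met.m0_mz + met.n_carbons * DELTA_13C / 2
        s12 = CentroidSpectrum(
            peaks=tuple(p for p in mixed.peaks if p.mz < mid), rt=7.5)
        s13 = CentroidSpectrum(
            peaks=tuple(p for p in mixed.peaks if p.mz >= mid), rt=7.51)
        pairs = find_pairs_cross([s12], [s13], enrichment, PairSearchConfig())
        assert len(pairs) == 1 and pairs[0].n_carbons == 4
        # outside the co-elution window nothing matches
        s13_late = CentroidSpectrum(peaks=s13.peaks, rt=8.2)
        assert find_pairs_cross([s12], [s13_late], enrichment) == []


class TestEstimateTms:
    @pytest.mark.parametrize(
        "ratio, expected",
        [(0.171, 2), (0.26, 3), (0.0, 0), (None, None), (0.0854 * 5, 5)],
    )
    def test_inversion(self, ratio, expected):
        assert estimate_tms(ratio) == expected

    def test_clipping(self):
        assert estimate_tms(10.0) == 6
        assert estimate_tms(-0.2) == 0

    def test_mox_correction(self):
        deriv = DerivatizationSpec(m_mox=1)
        assert estimate_tms(2 * 0.0854 + 0.011, deriv) == 2


class TestScorePair:
    def test_exact_pair_scores_one(self):
        cfg = PairSearchConfig()
        assert score_pair(0.0, [], cfg) == 1.0
        assert score_pair(0.0, [0.0, 0.0], cfg) == 1.0

    def test_tolerance_edge_below_half(self):
        import math

        cfg = PairSearchConfig()
        edge = score_pair(cfg.mz_tol_ppm, [math.log(cfg.ratio_tol_factor)], cfg)
        assert edge < 0.5

    def test_monotone_in_each_deviation(self):
        cfg = PairSearchConfig()
        s = [score_pair(r, [0.1], cfg) for r in (0.0, 1.0, 2.0, 4.0)]
        assert all(b > a for a, b in zip(s[1:], s[:-1]))
        s = [score_pair(1.0, [d], cfg) for d in (0.0, 0.2, 0.5)]
        assert all(b > a for a, b in zip(s[1:], s[:-1]))


def test_report_dataframe_roundtrip(tmp_path, enrichment, noiseless_config):
    spec, _ = _one_metabolite_spectrum(enrichment, artifacts=0)
    pairs = find_pairs(spec, enrichment, PairSearchConfig())
    df = pairs_to_dataframe(pairs)
    assert list(df["n_carbons"]) == [5]
    out = tmp_path / "pairs.csv"
    df.to_csv(out, index=False)
    assert out.read_text().startswith("m0_mz,mn_mz,n_carbons")
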