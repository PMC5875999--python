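"""Synthetic mixed-sample IROA spectra with known ground truth.

Emulates what a derivatized extract of a culture grown half on 95% 12C and
half on 95% 13C glucose looks like to a centroiding GC/MS instrument: per
metabolite, the two binomial isotopologue envelopes anchored n*1.0033548 Da
apart, first-order derivatization M+1 carryover on both anchors, Gaussian
ppm mass jitter, multiplicative log-normal intensity noise, unpaired
chemical-background artifact peaks, and optional detector saturation
(intensity clipping), which is what makes observed satellite ratios exceed
their model expectation on TOF instruments.

Every simulated spectrum ships with a manifest of the planted pairs so
detection, carbon/TMS inference and formula ranking can be tested for exact
parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .constants import DELTA_13C, PROTON_MASS, monoisotopic_mass
from .isotope_model import (
    DerivatizationSpec,
    EnrichmentModel,
    binomial_envelope,
    m1_ratio,
    pair_mz,
)
from .spectra_io import CentroidSpectrum, Peak

__all__ = [
    "GroundTruthMetabolite",
    "SimulationConfig",
    "simulate_spectrum",
    "simulate_ei_spectrum",
    "fixture_library",
]

#: Unpaired derivatization background ions added to simulated EI spectra.
EI_BACKGROUND_IONS = ((73.0468, 1.0), (147.0654, 0.6))


@dataclass(frozen=True)
class GroundTruthMetabolite:
    """Simulator record for one planted metabolite.

    ``base_mz`` is the all-12C anchor ion m/z; it may be given directly or
    derived from ``ion_formula`` (atom counts of the intact even-electron
    ion, e.g. the [MH]+ of the silylated species).  ``ei_fragments`` lists
    (fragment m/z, labeled backbone carbons, relative intensity) triples for
    EI simulation; a fragment with 0 labeled carbons yields a single
    unpaired peak.
    """

    name: str
    n_carbons: int
    k_tms: int = 0
    m_mox: int = 0
    rt: float = 10.0
    abundance: float = 1e5
    base_mz: float | None = None
    ion_formula: dict[str, int] | None = None
    ei_fragments: tuple[tuple[float, int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.n_carbons < 1:
            raise ValueError("backbone carbon count must be >= 1")
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")
        if self.base_mz is None and self.ion_formula is None:
            raise ValueError("need base_mz or ion_formula")

    @property
    def m0_mz(self) -> float:
        if self.base_mz is not None:
            return self.base_mz
        return monoisotopic_mass(self.ion_formula)

    @property
    def mn_mz(self) -> float:
        return pair_mz(self.m0_mz, self.n_carbons)

    @property
    def deriv(self) -> DerivatizationSpec:
        return DerivatizationSpec(k_tms=self.k_tms, m_mox=self.m_mox)


@dataclass(frozen=True)
class SimulationConfig:
    """Noise, artifact and acquisition settings of a simulated run.

    ppm_jitter_sd: per-peak Gaussian m/z error in ppm (1 emulates an
        Orbitrap, 15 a TOF).
    intensity_sigma: sigma of the per-peak multiplicative log-normal
        intensity noise (0 disables it).
    artifact_count / artifact_intensity_scale / artifact_intensity_sigma:
        number of unpaired background peaks and the log-normal parameters of
        their intensities.
    saturation_cap: detector clipping level; peaks at the cap are flagged
        saturated (None disables clipping).
    mix_13c: 13C-channel abundance relative to the 12C channel (1.0 = the
        default 1:1 mix of the two cultures).
    adversarial_artifacts: when True, artifact m/z values are NOT kept away
        from accidental pair spacings (used to stress false-positive rates).
    """

    ppm_jitter_sd: float = 1.0
    intensity_sigma: float = 0.05
    artifact_count: int = 0
    artifact_intensity_scale: float = 1e4
    artifact_intensity_sigma: float = 1.0
    saturation_cap: float | None = None
    mix_13c: float = 1.0
    mz_range: tuple[float, float] = (80.0, 1000.0)
    envelope_floor: float = 1e-4
    adversarial_artifacts: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ppm_jitter_sd < 0 or self.intensity_sigma < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if self.mix_13c <= 0:
            raise ValueError("channel mixing ratio must be positive")

    @classmethod
    def orbitrap(cls, **kw) -> "SimulationConfig":
        return cls(ppm_jitter_sd=kw.pop("ppm_jitter_sd", 1.0), **kw)

    @classmethod
    def tof(cls, **kw) -> "SimulationConfig":
        kw.setdefault("saturation_cap", 1.8e4)
        return cls(ppm_jitter_sd=kw.pop("ppm_jitter_sd", 15.0), **kw)


def _envelope_peaks(
    met: GroundTruthMetabolite,
    enrichment: EnrichmentModel,
    config: SimulationConfig,
    deriv_carryover: bool = True,
) -> dict[int, float]:
    """Ideal intensity at each integer offset above the 12C anchor."""
    n = met.n_carbons
    out: dict[int, float] = {}
    env12 = binomial_envelope(n, enrichment.q12, config.envelope_floor)
    for j, rel in zip(env12.offsets, env12.rel_intensities):
        out[j] = out.get(j, 0.0) + met.abundance * rel
    env13 = binomial_envelope(n, enrichment.q13, config.envelope_floor)
    for j, rel in zip(env13.offsets, env13.rel_intensities):
        out[j] = out.get(j, 0.0) + met.abundance * config.mix_13c * rel
    if deriv_carryover:
        c = met.deriv.m1_carryover
        if c > 0:
            # first-order natural-abundance satellite of each channel's anchor
            out[1] = out.get(1, 0.0) + c * met.abundance
            out[n + 1] = out.get(n + 1, 0.0) + c * met.abundance * config.mix_13c
    return {j: v for j, v in out.items() if v > 0}


def _apply_noise_and_emit(
    ideal: list[tuple[float, float]],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[Peak]:
    peaks: list[Peak] = []
    for mz, inten in ideal:
        if config.intensity_sigma > 0:
            inten = inten * rng.lognormal(0.0, config.intensity_sigma)
        if config.ppm_jitter_sd > 0:
            mz = mz * (1.0 + rng.normal(0.0, config.ppm_jitter_sd) * 1e-6)
        saturated = False
        if config.saturation_cap is not None and inten > config.saturation_cap:
            inten = config.saturation_cap
            saturated = True
        peaks.append(Peak(mz, inten, saturated=saturated))
    return peaks


def _forms_accidental_pair(mz: float, existing: list[float], guard_da_ppm: float = 90.0) -> bool:
    """True when mz sits within a guard band of an IROA spacing from any peak."""
    guard = guard_da_ppm * 1e-6 * mz  # 3x the widest (TOF, 30 ppm) tolerance
    for other in existing:
        spacing = abs(mz - other)
        n = round(spacing / DELTA_13C)
        if 1 <= n <= 30 and abs(spacing - n * DELTA_13C) <= guard:
            return True
    return False


def _artifact_peaks(
    existing_mz: list[float],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    lo, hi = config.mz_range
    placed: list[float] = []
    out: list[tuple[float, float]] = []
    for _ in range(config.artifact_count):
        for _attempt in range(200):
            mz = float(rng.uniform(lo, hi))
            if config.adversarial_artifacts or not _forms_accidental_pair(
                mz, existing_mz + placed
            ):
                break
        inten = float(
            config.artifact_intensity_scale * rng.lognormal(0.0, config.artifact_intensity_sigma)
        )
        placed.append(mz)
        out.append((mz, inten))
    return out


def _merge_close(peaks: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Sum intensities of peaks the instrument could not resolve (<2e-6 Da)."""
    peaks = sorted(peaks)
    merged: list[tuple[float, float]] = []
    for mz, inten in peaks:
        if merged and mz - merged[-1][0] < 2e-6:
            merged[-1] = (merged[-1][0], merged[-1][1] + inten)
        else:
            merged.append((mz, inten))
    return merged


def simulate_spectrum(
    metabolites: list[GroundTruthMetabolite],
    enrichment: EnrichmentModel | None = None,
    config: SimulationConfig | None = None,
) -> tuple[CentroidSpectrum, dict]:
    """Simulate one mixed-sample CI spectrum plus its ground-truth manifest.

    The manifest records the seed and, per metabolite, the planted anchor
    m/z values, carbon and TMS counts, and the model-expected satellite
    ratios, enabling exact parameter-recovery tests downstream.
    """
    enrichment = enrichment or EnrichmentModel()
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)

    ideal: list[tuple[float, float]] = []
    planted = []
    for met in metabolites:
        offsets = _envelope_peaks(met, enrichment, config)
        for j in sorted(offsets):
            ideal.append((met.m0_mz + j * DELTA_13C, offsets[j]))
        planted.append(
            {
                "name": met.name,
                "n_carbons": met.n_carbons,
                "k_tms": met.k_tms,
                "m_mox": met.m_mox,
                "m0_mz": met.m0_mz,
                "mn_mz": met.mn_mz,
                "rt": met.rt,
                "abundance": met.abundance,
                "expected_m0p1_ratio": m1_ratio(
                    met.n_carbons, enrichment.q12, met.deriv
                ),
                "expected_mnp1_ratio": met.deriv.m1_carryover,
            }
        )
    artifacts = _artifact_peaks([mz for mz, _ in ideal], config, rng)
    peaks = _apply_noise_and_emit(_merge_close(ideal + artifacts), config, rng)
    rt = metabolites[0].rt if metabolites else None
    spectrum = CentroidSpectrum(
        peaks=tuple(peaks), rt=rt, ionization="CI", label="simulated_ci"
    )
    manifest = {
        "seed": config.seed,
        "enrichment": {"q12": enrichment.q12, "q13": enrichment.q13},
        "config": {
            "ppm_jitter_sd": config.ppm_jitter_sd,
            "intensity_sigma": config.intensity_sigma,
            "artifact_count": config.artifact_count,
            "saturation_cap": config.saturation_cap,
            "mix_13c": config.mix_13c,
        },
        "planted_pairs": planted,
        "artifact_mz": [mz for mz, _ in artifacts],
    }
    return spectrum, manifest


def simulate_ei_spectrum(
    metabolite: GroundTruthMetabolite,
    enrichment: EnrichmentModel | None = None,
    config: SimulationConfig | None = None,
) -> CentroidSpectrum:
    """Simulate the mixed-sample EI spectrum of one metabolite.

    Each fragment with a positive labeled-carbon count contributes a
    mirrored binomial pair (no derivatization carryover: a fragment's TMS
    complement is not modeled); zero-carbon fragments and the ubiquitous
    silylation background ions (73.0468, 147.0654) stay unpaired.
    """
    enrichment = enrichment or EnrichmentModel()
    config = config or SimulationConfig()
    if not metabolite.ei_fragments:
        raise ValueError(f"{metabolite.name}: no EI fragment list to simulate")
    rng = np.random.default_rng(config.seed)
    ideal: list[tuple[float, float]] = []
    for mz, nc, rel in metabolite.ei_fragments:
        height = metabolite.abundance * rel
        if nc < 1:
            ideal.append((mz, height))
            continue
        env12 = binomial_envelope(nc, enrichment.q12, config.envelope_floor)
        for j, r in zip(env12.offsets, env12.rel_intensities):
            ideal.append((mz + j * DELTA_13C, height * r))
        env13 = binomial_envelope(nc, enrichment.q13, config.envelope_floor)
        for j, r in zip(env13.offsets, env13.rel_intensities):
            ideal.append((mz + j * DELTA_13C, height * config.mix_13c * r))
    for mz, rel in EI_BACKGROUND_IONS:
        ideal.append((mz, metabolite.abundance * rel))
    peaks = _apply_noise_and_emit(_merge_close(ideal), config, rng)
    return CentroidSpectrum(
        peaks=tuple(peaks),
        rt=metabolite.rt,
        ionization="EI",
        label=f"simulated_ei_{metabolite.name}",
    )


def fixture_library() -> dict[str, GroundTruthMetabolite]:
    """Bundled ground-truth metabolites for the worked examples.

    All are TMS-derivatized species observed as [MH]+ CI ions; EI fragment
    m/z values are monoisotopic masses of the plausible fragment ions
    carrying the listed number of labeled (backbone) carbons.
    """
    return {
        "glutamate_3tms": GroundTruthMetabolite(
            name="glutamate_3tms",
            n_carbons=5,
            k_tms=3,
            rt=10.62,
            abundance=5e5,
            ion_formula={"C": 14, "H": 34, "N": 1, "O": 4, "Si": 3},  # [MH]+ 364.1796
        ),
        "oxoproline_2tms": GroundTruthMetabolite(
            name="oxoproline_2tms",
            n_carbons=5,
            k_tms=2,
            rt=9.80,
            abundance=8e5,
            ion_formula={"C": 11, "H": 24, "N": 1, "O": 3, "Si": 2},  # [MH]+ 274.1295
        ),
        "dihydroxyisovalerate_3tms": GroundTruthMetabolite(
            name="dihydroxyisovalerate_3tms",
            n_carbons=5,
            k_tms=3,
            rt=11.30,
            abundance=3e5,
            ion_formula={"C": 14, "H": 35, "O": 4, "Si": 3},  # [MH]+ 351.1843
            ei_fragments=(
                (131.0887, 3, 0.8),   # C6H15OSi+: 3 backbone C + one TMS
                (292.1350, 2, 0.4),   # C11H28O3Si3+: 2 backbone C + three TMS
            ),
        ),
        "isoleucine_2tms": GroundTruthMetabolite(
            name="isoleucine_2tms",
            n_carbons=6,
            k_tms=2,
            rt=8.45,
            abundance=6e5,
            ion_formula={"C": 12, "H": 30, "N": 1, "O": 2, "Si": 2},  # [MH]+ 276.18
            ei_fragments=(
                (158.1365, 5, 1.0),   # loss of the carboxyl-TMS arm
                (218.1027, 2, 0.3),
                (260.1497, 6, 0.5),   # loss of a methyl from a TMS
            ),
        ),
    }


def write_manifest(manifest: dict, path) -> None:
    """Write a simulation manifest as JSON."""
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
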