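"""Detection of mirrored IROA peak pairs in mixed 12C/13C spectra.

A biological metabolite grown on the two randomized-enrichment carbon
sources appears as two envelope anchors: the all-12C monoisotopic peak M0
and the all-13C peak Mn, spaced n * 1.0033548 Da apart where n is the
backbone carbon count.  Chemical background and derivatization artifacts
have no such partner, so pair detection separates biological signal from
noise while simultaneously reading out n.

Detection proceeds peak-pair-wise: every ordered candidate (m0, mn) whose
spacing sits within tolerance of an integer number of 13C-12C mass shifts
is vetted against the binomial envelope model (observed M0+1/M0 and
Mn-1/Mn satellite ratios, when those satellites exist), anchors must be
local envelope maxima, and surviving candidates are greedily assigned so
each peak joins at most one reported pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .constants import DELTA_13C
from .isotope_model import (
    DerivatizationSpec,
    EnrichmentModel,
    MOX_M1_CARRYOVER,
    TMS_M1_CARRYOVER,
)
from .spectra_io import CentroidSpectrum, Peak

__all__ = [
    "PairSearchConfig",
    "IroaPair",
    "carbon_count",
    "find_pairs",
    "find_pairs_cross",
    "estimate_tms",
    "score_pair",
    "pairs_to_dataframe",
    "write_pair_report",
]

#: Highest TMS count entertained when vetting / inverting M+1 ratios.
MAX_TMS = 6


@dataclass(frozen=True)
class PairSearchConfig:
    """Tunables of the pair search.

    mz_tol_ppm: spacing tolerance; 5 ppm suits Orbitrap data, 30 ppm TOF.
    n_min/n_max: backbone carbon-count search window.
    ratio_tol_factor: maximum fold-deviation between an observed satellite
        ratio and its model expectation before a candidate is rejected.
    intensity_floor: anchors below this intensity are not considered.
    rt_tol_min: co-elution window (minutes) for cross-spectrum pairing.
    require_deriv_ratio: vet the 12C-side M+1 against the TMS-carryover
        model (True for CI molecular ions; EI fragment search disables it).
    excluded_mz: m/z values never used as anchors (ubiquitous unpaired
        derivatization ions in EI mode), matched within ``excluded_tol`` Da.
    anchor_ratio_bounds: admissible I(Mn)/I(M0) window.  The two anchors
        measure the 12C:13C channel mixing, which the experimenter controls
        (1:1 by design), whereas an envelope satellite masquerading as an
        anchor yields an extreme ratio; widen for strongly unequal mixes.
    """

    mz_tol_ppm: float = 5.0
    n_min: int = 2
    n_max: int = 30
    ratio_tol_factor: float = 2.0
    intensity_floor: float = 0.0
    rt_tol_min: float = 0.03
    require_deriv_ratio: bool = True
    excluded_mz: tuple[float, ...] = ()
    excluded_tol: float = 0.01
    anchor_ratio_bounds: tuple[float, float] = (0.2, 5.0)

    def __post_init__(self) -> None:
        if self.mz_tol_ppm <= 0:
            raise ValueError("mz_tol_ppm must be positive")
        if self.n_min < 1 or self.n_max < self.n_min:
            raise ValueError("need 1 <= n_min <= n_max")
        if self.ratio_tol_factor <= 1:
            raise ValueError("ratio_tol_factor must exceed 1")

    @classmethod
    def orbitrap(cls, **kw) -> "PairSearchConfig":
        return cls(mz_tol_ppm=kw.pop("mz_tol_ppm", 5.0), **kw)

    @classmethod
    def tof(cls, **kw) -> "PairSearchConfig":
        return cls(mz_tol_ppm=kw.pop("mz_tol_ppm", 30.0), **kw)


@dataclass(frozen=True)
class IroaPair:
    """A matched (M0, Mn) IROA peak pair with its diagnostics.

    Observed satellite ratios are None when the corresponding peak is absent
    from the spectrum; ``est_tms`` is the silylation count inverted from the
    13C-side M+1 carryover; ``flags`` carries warnings such as "saturated".
    """

    m0: Peak
    mn: Peak
    n_carbons: int
    spacing_residual_ppm: float
    obs_m0p1_ratio: float | None = None
    obs_mnm1_ratio: float | None = None
    obs_mnp1_ratio: float | None = None
    est_tms: int | None = None
    score: float = 1.0
    rt: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mn.mz <= self.m0.mz:
            raise ValueError("Mn must sit above M0 in m/z")
        if self.n_carbons < 1:
            raise ValueError("pair carbon count must be >= 1")


def carbon_count(
    m0_mz: float, mn_mz: float, config: PairSearchConfig | None = None
) -> tuple[int | None, float]:
    """Backbone carbon count implied by a pair of anchor m/z values.

    Rounds the spacing to the nearest whole number of 13C-12C mass shifts
    and reports the residual in ppm of the heavy anchor.  Returns
    ``(None, residual)`` when the best integer lies outside the configured
    [n_min, n_max] window or the residual exceeds the tolerance.
    """
    if mn_mz <= m0_mz:
        raise ValueError("mn_mz must exceed m0_mz")
    config = config or PairSearchConfig()
    spacing = mn_mz - m0_mz
    n = round(spacing / DELTA_13C)
    residual_ppm = 1e6 * (spacing - n * DELTA_13C) / mn_mz
    if n < config.n_min or n > config.n_max or abs(residual_ppm) > config.mz_tol_ppm:
        return None, residual_ppm
    return n, residual_ppm


def _log_dev(observed: float, expected: float) -> float:
    """|log fold-change| between an observed and expected ratio."""
    if observed <= 0 or expected <= 0:
        return math.inf
    return abs(math.log(observed / expected))


def _ratio_ok(observed: float, expected: float, factor: float) -> bool:
    return _log_dev(observed, expected) <= math.log(factor)


def _satellite_ratio(
    spec: CentroidSpectrum, anchor: Peak, direction: int, tol_da: float
) -> float | None:
    """Intensity ratio of the satellite one 13C shift away from an anchor."""
    sat = spec.nearest_peak(anchor.mz + direction * DELTA_13C, tol_da)
    if sat is None or anchor.intensity <= 0:
        return None
    return sat.intensity / anchor.intensity


def score_pair(
    spacing_residual_ppm: float,
    ratio_log_devs: list[float],
    config: PairSearchConfig,
) -> float:
    """Deterministic pair-quality score in [0, 1].

    Each diagnostic contributes its squared deviation normalized by the
    configured tolerance; the score is ``0.5 ** sum``, so a pair that is
    exact on every diagnostic scores 1.0, a single diagnostic sitting at
    its tolerance edge halves the score, and the score decreases
    monotonically in every deviation.
    """
    q = (spacing_residual_ppm / config.mz_tol_ppm) ** 2
    log_tol = math.log(config.ratio_tol_factor)
    for dev in ratio_log_devs:
        q += (dev / log_tol) ** 2
    return 0.5 ** q


def estimate_tms(
    obs_mnp1_ratio: float | None,
    deriv_constants: DerivatizationSpec | None = None,
) -> int | None:
    """Silylation count inverted from the 13C-side M+1/Mn ratio.

    On the 13C side the M+1 satellite carries only derivatization natural
    abundance (the backbone is saturated with 13C), so the ratio divided by
    the per-TMS carryover yields the TMS count, rounded and clipped to
    [0, MAX_TMS].  Returns None when the satellite was absent.
    """
    if obs_mnp1_ratio is None:
        return None
    c_tms = deriv_constants.c_tms if deriv_constants else TMS_M1_CARRYOVER
    m_mox = deriv_constants.m_mox if deriv_constants else 0
    c_mox = deriv_constants.c_mox if deriv_constants else MOX_M1_CARRYOVER
    k = round((obs_mnp1_ratio - m_mox * c_mox) / c_tms)
    return max(0, min(MAX_TMS, k))


def _is_excluded(mz: float, config: PairSearchConfig) -> bool:
    return any(abs(mz - x) <= config.excluded_tol for x in config.excluded_mz)


#: A candidate 12C anchor is disqualified when a peak one 13C shift below it
#: reaches this fraction of its intensity (a true M0 has nothing below; a
#: satellite always has its anchor below).
_M0_BELOW_FRAC = 0.25

#: A candidate 13C anchor tolerates a peak above it up to this fraction (the
#: legitimate derivatization M+1 carryover reaches ~0.5 at 6 TMS).
_MN_ABOVE_FRAC = 0.7


def _expected_ratios(
    n: int,
    k_tms: int,
    enrichment: EnrichmentModel,
    r_mn_over_m0: float,
) -> tuple[float, float]:
    """Model (M0+1/M0, Mn-1/Mn) ratios for the mixed two-channel spectrum.

    For small n the interior satellites of the two channels coincide (at
    n=2, M0+1 and Mn-1 are the same peak), so each expectation includes the
    other channel's binomial contribution, scaled by the observed
    anchor-intensity ratio ``r_mn_over_m0 = I(Mn)/I(M0)``.
    """
    q12, q13 = enrichment.q12, enrichment.q13
    own_m0p1 = n * q12 / (1.0 - q12) + k_tms * TMS_M1_CARRYOVER
    cross_13 = n * ((1.0 - q13) / q13) ** (n - 1)  # 13C channel at offset 1
    exp_m0p1 = own_m0p1 + r_mn_over_m0 * cross_13
    own_mnm1 = n * (1.0 - q13) / q13
    cross_12 = n * (q12 / (1.0 - q12)) ** (n - 1)  # 12C channel at offset n-1
    if n == 2:
        cross_12 += k_tms * TMS_M1_CARRYOVER  # M0's carryover satellite
    exp_mnm1 = own_mnm1 + cross_12 / r_mn_over_m0
    return exp_m0p1, exp_mnm1


def _candidate_pairs(
    spec12: CentroidSpectrum,
    spec13: CentroidSpectrum,
    enrichment: EnrichmentModel,
    config: PairSearchConfig,
    rt: float | None,
) -> list[IroaPair]:
    """All vetted candidate pairs with M0 from spec12 and Mn from spec13.

    ``spec12 is spec13`` in the usual single-mixed-spectrum mode.
    """
    out: list[IroaPair] = []
    log_tol = math.log(config.ratio_tol_factor)
    for p0 in spec12.peaks:
        if p0.intensity <= 0 or p0.intensity < config.intensity_floor:
            continue
        if _is_excluded(p0.mz, config):
            continue
        tol0 = config.mz_tol_ppm * 1e-6 * p0.mz
        # anchor rule: M0 is the outermost peak of the 12C envelope, so any
        # substantial peak one shift below marks p0 as a satellite
        below = spec12.nearest_peak(p0.mz - DELTA_13C, tol0)
        if below is not None and below.intensity >= _M0_BELOW_FRAC * p0.intensity:
            continue
        for pn in spec13.peaks:
            if pn.mz <= p0.mz:
                continue
            if pn.intensity <= 0 or pn.intensity < config.intensity_floor:
                continue
            if _is_excluded(pn.mz, config):
                continue
            n, residual_ppm = carbon_count(p0.mz, pn.mz, config)
            if n is None:
                continue
            toln = config.mz_tol_ppm * 1e-6 * pn.mz
            above = spec13.nearest_peak(pn.mz + DELTA_13C, toln)
            if above is not None and above.intensity >= _MN_ABOVE_FRAC * pn.intensity:
                continue  # pn is itself a satellite of a heavier anchor
            r_lo, r_hi = config.anchor_ratio_bounds
            if not r_lo <= pn.intensity / p0.intensity <= r_hi:
                continue
            saturated = p0.saturated or pn.saturated
            flags: list[str] = ["saturated"] if saturated else []

            obs_m0p1 = _satellite_ratio(spec12, p0, +1, tol0)
            obs_mnm1 = _satellite_ratio(spec13, pn, -1, toln)
            obs_mnp1 = _satellite_ratio(spec13, pn, +1, toln)

            devs: list[float] = []
            ok = True
            if not saturated and (obs_m0p1 is not None or obs_mnm1 is not None):
                # unknown TMS count: take the hypothesis that best explains
                # both satellite ratios jointly
                r = pn.intensity / p0.intensity
                best: tuple[float, list[float]] | None = None
                for k in range(MAX_TMS + 1):
                    exp_a, exp_b = _expected_ratios(n, k, enrichment, r)
                    k_devs = []
                    if obs_m0p1 is not None:
                        k_devs.append(_log_dev(obs_m0p1, exp_a))
                    if obs_mnm1 is not None:
                        k_devs.append(_log_dev(obs_mnm1, exp_b))
                    if best is None or sum(k_devs) < sum(best[1]):
                        best = (k, k_devs)
                devs = best[1]
                if obs_mnm1 is not None:
                    # the 13C-side mirror check always applies
                    if devs[-1] > log_tol:
                        ok = False
                if config.require_deriv_ratio and obs_m0p1 is not None:
                    # the 12C-side M+1 check applies to molecular ions only
                    # (EI fragments may have shed derivatized carbons)
                    if devs[0] > log_tol:
                        ok = False
            if not ok:
                continue
            est_k = estimate_tms(obs_mnp1) if config.require_deriv_ratio else None
            score = score_pair(residual_ppm, devs, config)
            out.append(
                IroaPair(
                    m0=p0,
                    mn=pn,
                    n_carbons=n,
                    spacing_residual_ppm=residual_ppm,
                    obs_m0p1_ratio=obs_m0p1,
                    obs_mnm1_ratio=obs_mnm1,
                    obs_mnp1_ratio=obs_mnp1,
                    est_tms=est_k,
                    score=score,
                    rt=rt,
                    flags=tuple(flags),
                )
            )
    return out


def _greedy_assign(candidates: list[IroaPair]) -> list[IroaPair]:
    """One pair per peak: best score wins, ties broken deterministically.

    Ties on score prefer the smaller spacing residual, then the larger
    carbon count (a longer backbone explains more of the envelope).
    """
    candidates = sorted(
        candidates,
        key=lambda p: (-p.score, abs(p.spacing_residual_ppm), -p.n_carbons, p.m0.mz),
    )
    used: set[float] = set()
    accepted: list[IroaPair] = []
    for pair in candidates:
        if pair.m0.mz in used or pair.mn.mz in used:
            continue
        used.add(pair.m0.mz)
        used.add(pair.mn.mz)
        accepted.append(pair)
    return sorted(accepted, key=lambda p: -p.score)


def find_pairs(
    spectrum: CentroidSpectrum,
    enrichment: EnrichmentModel | None = None,
    config: PairSearchConfig | None = None,
) -> list[IroaPair]:
    """Detect IROA pairs within a single mixed 12C+13C spectrum.

    Returns accepted pairs sorted by descending score; each peak anchors at
    most one pair.  See the module docstring for the vetting rules.
    """
    enrichment = enrichment or EnrichmentModel()
    config = config or PairSearchConfig()
    if len(spectrum) == 0:
        return []
    cands = _candidate_pairs(spectrum, spectrum, enrichment, config, spectrum.rt)
    return _greedy_assign(cands)


def find_pairs_cross(
    spectra_12c: list[CentroidSpectrum],
    spectra_13c: list[CentroidSpectrum],
    enrichment: EnrichmentModel | None = None,
    config: PairSearchConfig | None = None,
) -> list[IroaPair]:
    """Detect IROA pairs across separate 12C and 13C runs matched by RT.

    Spectra are paired when their retention times agree within
    ``config.rt_tol_min``; within each matched pair of scans the same
    vetting as :func:`find_pairs` applies, with M0 drawn from the 12C run
    and Mn from the 13C run.
    """
    enrichment = enrichment or EnrichmentModel()
    config = config or PairSearchConfig()
    out: list[IroaPair] = []
    for s12 in spectra_12c:
        for s13 in spectra_13c:
            if s12.rt is None or s13.rt is None:
                continue
            if abs(s12.rt - s13.rt) > config.rt_tol_min:
                continue
            out.extend(_candidate_pairs(s12, s13, enrichment, config, s12.rt))
    return _greedy_assign(out)


def pairs_to_dataframe(pairs: list[IroaPair]) -> pd.DataFrame:
    """Tabulate pairs for reporting."""
    rows = [
        {
            "m0_mz": p.m0.mz,
            "mn_mz": p.mn.mz,
            "n_carbons": p.n_carbons,
            "residual_ppm": p.spacing_residual_ppm,
            "m0_intensity": p.m0.intensity,
            "mn_intensity": p.mn.intensity,
            "obs_m0p1_ratio": p.obs_m0p1_ratio,
            "obs_mnm1_ratio": p.obs_mnm1_ratio,
            "obs_mnp1_ratio": p.obs_mnp1_ratio,
            "est_tms": p.est_tms,
            "score": p.score,
            "rt": p.rt,
            "flags": ";".join(p.flags),
        }
        for p in pairs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "m0_mz", "mn_mz", "n_carbons", "residual_ppm", "m0_intensity",
            "mn_intensity", "obs_m0p1_ratio", "obs_mnm1_ratio",
            "obs_mnp1_ratio", "est_tms", "score", "rt", "flags",
        ],
    )


def write_pair_report(pairs: list[IroaPair], path) -> None:
    """Write the pair table as CSV."""
    pairs_to_dataframe(pairs).to_csv(path, index=False)
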