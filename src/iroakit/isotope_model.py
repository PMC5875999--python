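"""Binomial model of IROA isotopologue envelopes.

IROA labeling grows one culture on randomized 95% 12C glucose (5% 13C) and a
second on randomized 95% 13C glucose (5% 12C).  Every carbon position of a
biosynthesized metabolite is then an independent Bernoulli draw, so the
isotopologue intensities within each channel follow a binomial distribution
in the number of heavy carbons.  Mixing the two channels yields mirror-image
envelopes whose anchor peaks (all-12C M0 and all-13C Mn) are separated by
n times the 13C-12C mass difference, exposing the backbone carbon count n.

Derivatization for GC (trimethylsilylation, methoximation) adds carbons and
silicon of natural isotopic abundance.  To first order this contributes only
to the M+1 satellite of each anchor: 8.54% of the anchor intensity per TMS
group, and one natural-abundance carbon (1.1%) per methoxime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import DELTA_13C

__all__ = [
    "EnrichmentModel",
    "DerivatizationSpec",
    "IsotopologueEnvelope",
    "binomial_envelope",
    "m1_ratio",
    "mirror_envelope",
    "pair_mz",
    "tms_carryover_from_abundances",
    "TMS_M1_CARRYOVER",
    "MOX_M1_CARRYOVER",
]

#: Per-silylation-site M+1/M0 carryover fraction (workflow constant).
TMS_M1_CARRYOVER: float = 0.0854

#: Per-methoxime M+1/M0 carryover fraction (one natural-abundance carbon).
MOX_M1_CARRYOVER: float = 0.011


def tms_carryover_from_abundances(
    p_2h: float = 0.00015, p_29si: float = 0.0467, p_13c: float = 0.011
) -> float:
    """First-order M+1 carryover of one -Si(CH3)3 group from isotope abundances.

    Sums the single-substitution probabilities over the group's 9 hydrogens,
    1 silicon and 3 carbons: ``9*p(2H) + p(29Si) + 3*p(13C)`` (~= 0.081).
    The default workflow constant is the larger 0.0854; this abundance-derived
    alternative is exposed for users who prefer a value traceable to the
    elemental abundances.
    """
    return 9.0 * p_2h + p_29si + 3.0 * p_13c


@dataclass(frozen=True)
class EnrichmentModel:
    """13C fractions of the two IROA channels.

    q12 is the 13C fraction in the nominally-12C channel (default 0.05) and
    q13 the 13C fraction in the nominally-13C channel (default 0.95).
    """

    q12: float = 0.05
    q13: float = 0.95

    def __post_init__(self) -> None:
        if not (0.0 < self.q12 < 0.5 < self.q13 < 1.0):
            raise ValueError(
                f"enrichment must satisfy 0 < q12 < 0.5 < q13 < 1, "
                f"got q12={self.q12}, q13={self.q13}"
            )


@dataclass(frozen=True)
class DerivatizationSpec:
    """Derivatization state of one metabolite: TMS and methoxime counts.

    c_tms / c_mox are the per-group first-order M+1 carryover fractions.
    """

    k_tms: int = 0
    m_mox: int = 0
    c_tms: float = TMS_M1_CARRYOVER
    c_mox: float = MOX_M1_CARRYOVER

    def __post_init__(self) -> None:
        if self.k_tms < 0 or self.m_mox < 0:
            raise ValueError("derivatization group counts must be non-negative")
        if not (0.0 <= self.c_tms < 1.0 and 0.0 <= self.c_mox < 1.0):
            raise ValueError("carryover fractions must lie in [0, 1)")

    @property
    def m1_carryover(self) -> float:
        """Total first-order M+1/M0 contribution of the derivatization."""
        return self.k_tms * self.c_tms + self.m_mox * self.c_mox


@dataclass(frozen=True)
class IsotopologueEnvelope:
    """Relative isotopologue intensities of one labeled species.

    ``offsets[i]`` heavy carbons above the lightest isotopologue, with
    ``rel_intensities`` normalized so the most abundant peak equals 1.
    ``base_mz``, when set, is the m/z of that most abundant (base) peak.
    """

    n_carbons: int
    offsets: tuple[int, ...]
    rel_intensities: tuple[float, ...]
    base_mz: float | None = None

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.rel_intensities):
            raise ValueError("offsets and rel_intensities lengths differ")
        if any(b <= a for a, b in zip(self.offsets, self.offsets[1:])):
            raise ValueError("offsets must be strictly increasing")
        if any(i < 0 for i in self.rel_intensities):
            raise ValueError("intensities must be non-negative")
        if abs(max(self.rel_intensities) - 1.0) > 1e-12:
            raise ValueError("base peak must be normalized to 1.0")

    def intensity_at(self, offset: int) -> float:
        """Relative intensity at a given offset (0.0 if absent)."""
        try:
            return self.rel_intensities[self.offsets.index(offset)]
        except ValueError:
            return 0.0

    @property
    def base_offset(self) -> int:
        """Offset of the most abundant isotopologue."""
        return self.offsets[int(np.argmax(self.rel_intensities))]

    def isclose(self, other: "IsotopologueEnvelope", rel_tol: float = 1e-9) -> bool:
        """Numerical equality up to floating-point tolerance."""
        return (
            self.n_carbons == other.n_carbons
            and self.offsets == other.offsets
            and all(
                abs(a - b) <= rel_tol * max(abs(a), abs(b), 1.0)
                for a, b in zip(self.rel_intensities, other.rel_intensities)
            )
        )


def binomial_envelope(n: int, q: float, floor: float = 1e-4) -> IsotopologueEnvelope:
    """Isotopologue envelope of an n-carbon backbone at 13C fraction q.

    The probability of j heavy carbons is Binomial(n, q); intensities are
    renormalized so the most abundant isotopologue is 1.0 and offsets below
    ``floor`` (relative to the base peak) are trimmed from both tails.

    Parameters
    ----------
    n : backbone carbon count, >= 1.
    q : 13C fraction, in the open interval (0, 1).
    floor : relative-intensity cutoff for reporting an offset.
    """
    if n < 1:
        raise ValueError(f"carbon count must be >= 1, got {n}")
    if not 0.0 < q < 1.0:
        raise ValueError(f"13C fraction must lie in (0, 1), got {q}")
    j = np.arange(n + 1)
    pmf = stats.binom.pmf(j, n, q)
    rel = pmf / pmf.max()
    keep = rel >= floor
    # the binomial pmf is unimodal so the kept set is contiguous
    idx = np.flatnonzero(keep)
    lo, hi = idx[0], idx[-1]
    return IsotopologueEnvelope(
        n_carbons=n,
        offsets=tuple(int(x) for x in j[lo : hi + 1]),
        rel_intensities=tuple(float(x) for x in rel[lo : hi + 1]),
    )


def m1_ratio(n: int, q: float, deriv: DerivatizationSpec | None = None) -> float:
    """Predicted M+1/anchor intensity ratio for the low-13C channel.

    The backbone term is the exact first-order binomial ratio
    ``C(n,1) q (1-q)^(n-1) / (1-q)^n = n q/(1-q)``; derivatization adds
    ``k_tms*c_tms + m_mox*c_mox`` on top.

    With the defaults (q=0.05, c_tms=0.0854) this reproduces the canonical
    worked example: a 5-carbon, doubly silylated metabolite has
    5*0.05/0.95 + 2*0.0854 = 0.43.
    """
    if n < 1:
        raise ValueError(f"carbon count must be >= 1, got {n}")
    if not 0.0 < q < 1.0:
        raise ValueError(f"13C fraction must lie in (0, 1), got {q}")
    ratio = n * q / (1.0 - q)
    if deriv is not None:
        ratio += deriv.m1_carryover
    return ratio


def mirror_envelope(env: IsotopologueEnvelope) -> IsotopologueEnvelope:
    """Envelope of the complementary channel (q -> 1-q).

    By binomial symmetry the intensity at offset j of the mirrored envelope
    equals the input intensity at offset n-j; mirroring twice is the
    identity.  ``base_mz`` is dropped (the mirrored species sits n*delta_13C
    away and must be re-anchored by the caller).
    """
    n = env.n_carbons
    offsets = tuple(n - o for o in reversed(env.offsets))
    rel = tuple(reversed(env.rel_intensities))
    return IsotopologueEnvelope(n_carbons=n, offsets=offsets, rel_intensities=rel)


def pair_mz(m0: float, n: int) -> float:
    """m/z of the all-13C partner of an all-12C anchor at ``m0``.

    Simply ``m0 + n * DELTA_13C``; the mass spacing of an IROA pair encodes
    the backbone carbon count.
    """
    if m0 <= 0:
        raise ValueError(f"m/z must be positive, got {m0}")
    if n < 0:
        raise ValueError(f"carbon count must be non-negative, got {n}")
    return m0 + n * DELTA_13C
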