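"""Chemical formula generation (CFG) for accurate ion masses.

Enumerates every elemental composition over {C, H, N, O, Si, S} within
user-supplied per-element count ranges whose monoisotopic ion mass falls
inside a ppm window around the measured m/z, ranked by absolute ppm
deviation.  IROA evidence (backbone carbon count n and silylation count k)
tightens the ranges: each TMS group contributes exactly three
natural-abundance carbons and one silicon, so C spans
n + 3*k_min + m_mox ... n + 3*k_max + m_mox and Si spans k_min ... k_max.

Masses are plain sums of monoisotopic atomic masses with no electron-mass
correction; the measured m/z is taken to be the intact even-electron ion
([MH]+ for CI molecular ions), so callers working from neutral-molecule
hypotheses must add the proton's hydrogen themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import MONOISOTOPIC_MASS, SUPPORTED_ELEMENTS

__all__ = [
    "ElementRanges",
    "FormulaCandidate",
    "generate_formulas",
    "iroa_constrained_ranges",
    "theoretical_ion_mass",
    "hill_formula",
    "parse_formula",
]


@dataclass(frozen=True)
class ElementRanges:
    """Per-element (min, max) atom-count bounds for enumeration."""

    C: tuple[int, int] = (0, 0)
    H: tuple[int, int] = (0, 0)
    N: tuple[int, int] = (0, 0)
    O: tuple[int, int] = (0, 0)
    Si: tuple[int, int] = (0, 0)
    S: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        for el in SUPPORTED_ELEMENTS:
            lo, hi = getattr(self, el)
            if not (0 <= lo <= hi):
                raise ValueError(f"invalid range for {el}: ({lo}, {hi})")

    def bounds(self, el: str) -> tuple[int, int]:
        return getattr(self, el)


#: The element settings of the triple-silylated amino-acid worked example:
#: C 14-15, H 0-100, N 0-4, O 0-10, Si 2-3, S 0-2.
GLUTAMATE_EXAMPLE_RANGES = ElementRanges(
    C=(14, 15), H=(0, 100), N=(0, 4), O=(0, 10), Si=(2, 3), S=(0, 2)
)


@dataclass(frozen=True)
class FormulaCandidate:
    """One elemental composition consistent with a measured ion mass.

    ``ppm`` is the signed deviation 1e6*(measured - theoretical)/theoretical
    at full floating-point precision; :meth:`reported_ppm` reproduces the
    convention of vendor elemental-composition reports, which quote the
    theoretical mass rounded to 4 decimals.
    """

    counts: dict[str, int]
    theoretical_mz: float
    ppm: float
    rank: int

    @property
    def formula(self) -> str:
        return hill_formula(self.counts)

    def reported_ppm(self, mass_decimals: int = 4, ppm_decimals: int = 1) -> float:
        """ppm deviation as a report would print it (rounded theoretical mass)."""
        rounded = round(self.theoretical_mz, mass_decimals)
        measured = self.theoretical_mz * (1.0 + self.ppm * 1e-6)
        return round(1e6 * (measured - rounded) / rounded, ppm_decimals)


def hill_formula(counts: dict[str, int]) -> str:
    """Hill-order formula string: C first, H second, rest alphabetical."""
    parts: list[str] = []
    rest = sorted(el for el in counts if el not in ("C", "H") and counts[el] > 0)
    order = [el for el in ("C", "H") if counts.get(el, 0) > 0] + rest
    for el in order:
        n = counts[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a plain formula string ("C14H34NO4Si3") into atom counts."""
    import re

    counts: dict[str, int] = {}
    pos = 0
    for m in re.finditer(r"([A-Z][a-z]?)(\d*)", formula):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        el, num = m.group(1), m.group(2)
        if el not in MONOISOTOPIC_MASS:
            raise ValueError(f"unsupported element {el!r} in formula {formula!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


def theoretical_ion_mass(counts: dict[str, int]) -> float:
    """Monoisotopic ion mass: sum of atomic masses, no electron correction."""
    if any(n < 0 for n in counts.values()):
        raise ValueError("atom counts must be non-negative")
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.items() if n)


def _rdbe(counts: dict[str, int]) -> float:
    """Ring-plus-double-bond equivalents; Si counts as tetravalent carbon."""
    return (
        counts.get("C", 0)
        + counts.get("Si", 0)
        + 1.0
        + 0.5 * counts.get("N", 0)
        - 0.5 * counts.get("H", 0)
    )


def generate_formulas(
    measured_mz: float,
    ranges: ElementRanges,
    tol_ppm: float,
    rdbe_min: float | None = None,
) -> list[FormulaCandidate]:
    """Enumerate and rank formula candidates for a measured ion m/z.

    Returns exactly the compositions within ``ranges`` whose theoretical
    ion mass deviates at most ``tol_ppm`` (ppm of the theoretical mass)
    from ``measured_mz``, sorted ascending by |ppm| with ties broken by the
    Hill formula string.  ``rdbe_min`` optionally drops chemically
    implausible compositions (off by default; the pure mass-window
    enumeration reproduces vendor elemental-composition counts).

    The search recurses over elements heaviest-first with partial-mass
    pruning; hydrogen, the lightest, is resolved in a closed form at the
    bottom, so the cost is far below the full Cartesian product.
    """
    if not (50.0 < measured_mz < 2000.0):
        raise ValueError(f"measured m/z {measured_mz} outside supported (50, 2000)")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")

    heavy = [el for el in SUPPORTED_ELEMENTS if el != "H"]
    m_h = MONOISOTOPIC_MASS["H"]
    h_lo, h_hi = ranges.bounds("H")
    # window on theoretical mass m: |measured - m| <= tol*1e-6*m
    m_min = measured_mz / (1.0 + tol_ppm * 1e-6)
    m_max = measured_mz / (1.0 - tol_ppm * 1e-6)

    # remaining minimum/maximum heavy mass achievable from element i onward
    suffix_min = [0.0] * (len(heavy) + 1)
    suffix_max = [0.0] * (len(heavy) + 1)
    for i in range(len(heavy) - 1, -1, -1):
        lo, hi = ranges.bounds(heavy[i])
        suffix_min[i] = suffix_min[i + 1] + lo * MONOISOTOPIC_MASS[heavy[i]]
        suffix_max[i] = suffix_max[i + 1] + hi * MONOISOTOPIC_MASS[heavy[i]]

    found: list[tuple[float, str, dict[str, int], float, float]] = []

    def recurse(i: int, mass: float, counts: dict[str, int]) -> None:
        if mass + suffix_min[i] + h_lo * m_h > m_max:
            return
        if mass + suffix_max[i] + h_hi * m_h < m_min:
            return
        if i == len(heavy):
            for n_h in range(h_lo, h_hi + 1):
                m = mass + n_h * m_h
                if m < m_min:
                    continue
                if m > m_max:
                    break
                full = dict(counts, H=n_h)
                if rdbe_min is not None and _rdbe(full) < rdbe_min:
                    continue
                ppm = 1e6 * (measured_mz - m) / m
                found.append((abs(ppm), hill_formula(full), full, m, ppm))
            return
        el = heavy[i]
        lo, hi = ranges.bounds(el)
        for n_el in range(lo, hi + 1):
            recurse(i + 1, mass + n_el * MONOISOTOPIC_MASS[el], dict(counts, **{el: n_el}))

    recurse(0, 0.0, {})
    found.sort(key=lambda t: (t[0], t[1]))
    return [
        FormulaCandidate(counts=f, theoretical_mz=m, ppm=ppm, rank=r)
        for r, (_, _, f, m, ppm) in enumerate(found, start=1)
    ]


def iroa_constrained_ranges(
    n_backbone: int,
    k_tms_range: tuple[int, int],
    m_mox: int = 0,
    user_ranges: ElementRanges | None = None,
) -> ElementRanges:
    """Tighten element ranges using IROA-derived carbon and TMS evidence.

    The observed backbone carbon count fixes the biological carbons; each
    hypothesized TMS group adds 3 carbons and 1 silicon, each methoxime
    adds 1 carbon.  H, N, O and S bounds come from ``user_ranges``
    (defaulting to H 0-100, N 0-4, O 0-10, S 0-2).
    """
    if n_backbone < 1:
        raise ValueError("n_backbone must be >= 1")
    k_min, k_max = k_tms_range
    if not (0 <= k_min <= k_max):
        raise ValueError(f"invalid TMS range {k_tms_range}")
    user = user_ranges or ElementRanges(H=(0, 100), N=(0, 4), O=(0, 10), S=(0, 2))
    return ElementRanges(
        C=(n_backbone + 3 * k_min + m_mox, n_backbone + 3 * k_max + m_mox),
        H=user.bounds("H"),
        N=user.bounds("N"),
        O=user.bounds("O"),
        Si=(k_min, k_max),
        S=user.bounds("S"),
    )
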