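"""EI fragment-pair detection and candidate-structure scoring.

Electron ionization of the mixed 12C/13C sample fragments both labeling
channels identically, so each informative fragment appears as its own
mirrored pair whose spacing reveals the fragment's backbone carbon count.
Those per-fragment carbon counts are a structural fingerprint: an isomeric
candidate whose predicted fragments cannot produce the observed carbon
counts is inconsistent with the data regardless of how well the raw
intensities match.  This module detects the fragment pairs, scores observed
EI spectra against externally predicted candidate spectra (cosine/dot
product and Jaccard), and ranks candidates by formula consistency, fragment
carbon-count consistency, then spectral similarity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import pandas as pd

from .isotope_model import EnrichmentModel
from .pair_finder import IroaPair, PairSearchConfig, find_pairs
from .spectra_io import CentroidSpectrum

__all__ = [
    "FragmentPair",
    "CandidateSpectrum",
    "CandidateScore",
    "DEFAULT_EXCLUDED_IONS",
    "ei_pair_config",
    "find_ei_pairs",
    "dot_product_score",
    "jaccard_score",
    "rank_candidates",
    "scores_to_dataframe",
]

#: Ubiquitous unpaired silylation background ions excluded from EI anchoring:
#: the TMS cation (73.0468) and the pentamethyldisiloxane ion (147.0654).
DEFAULT_EXCLUDED_IONS: tuple[float, ...] = (73.0468, 147.0654)


@dataclass(frozen=True)
class FragmentPair:
    """An EI fragment pair: 12C anchor, 13C anchor, fragment carbon count."""

    mz12: float
    mz13: float
    n_carbons: int
    intensity12: float
    intensity13: float

    def __post_init__(self) -> None:
        if self.mz13 <= self.mz12:
            raise ValueError("13C anchor must sit above the 12C anchor")
        if self.n_carbons < 1:
            raise ValueError("fragment carbon count must be >= 1")


@dataclass(frozen=True)
class CandidateSpectrum:
    """An externally predicted EI spectrum for one candidate structure.

    ``peaks`` are (m/z, relative intensity); ``fragment_formulas`` maps the
    index of a predicted peak to that fragment's atom counts when the
    prediction source supplies per-fragment formulas (else empty).
    ``formula`` is the candidate's intact (derivatized) ion composition.
    """

    candidate_id: str
    formula: dict[str, int]
    peaks: tuple[tuple[float, float], ...]
    fragment_formulas: dict[int, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.peaks))
        object.__setattr__(self, "peaks", ordered)
        if any(i < 0 for _, i in ordered):
            raise ValueError("predicted intensities must be >= 0")


@dataclass(frozen=True)
class CandidateScore:
    """Scores of one candidate against the observed EI evidence.

    ``carbon_consistency`` is None when the prediction source supplied no
    per-fragment formulas (reported as not-available, never penalized as 0).
    """

    candidate_id: str
    spectral_score: float
    jaccard: float
    carbon_consistency: float | None
    mz_match_fraction: float
    formula_match: bool
    rank: int


def ei_pair_config(**overrides) -> PairSearchConfig:
    """Pair-search configuration tuned for EI fragment spectra.

    Fragments may have shed derivatized carbons, so the carbon window opens
    to [1, 20], the TMS-carryover vetting of the 12C-side M+1 is disabled,
    the spacing tolerance relaxes to 15 ppm (EI centroids of weak fragments
    sit a few ppm off), and the ubiquitous unpaired derivatization ions are
    barred from anchoring.
    """
    kw = dict(
        mz_tol_ppm=15.0,
        n_min=1,
        n_max=20,
        require_deriv_ratio=False,
        excluded_mz=DEFAULT_EXCLUDED_IONS,
    )
    kw.update(overrides)
    return PairSearchConfig(**kw)


def find_ei_pairs(
    ei_spectrum: CentroidSpectrum,
    enrichment: EnrichmentModel | None = None,
    config: PairSearchConfig | None = None,
) -> list[FragmentPair]:
    """Detect mirrored fragment pairs in a mixed-sample EI spectrum."""
    config = config or ei_pair_config()
    pairs: list[IroaPair] = find_pairs(ei_spectrum, enrichment, config)
    out = [
        FragmentPair(
            mz12=p.m0.mz,
            mz13=p.mn.mz,
            n_carbons=p.n_carbons,
            intensity12=p.m0.intensity,
            intensity13=p.mn.intensity,
        )
        for p in pairs
    ]
    return sorted(out, key=lambda f: f.mz12)


# ---------------------------------------------------------------------------
# spectral similarity
# ---------------------------------------------------------------------------

def _greedy_match(
    a: list[tuple[float, float]],
    b: list[tuple[float, float]],
    mz_tol: float,
) -> list[tuple[int, int]]:
    """Greedy closest-first 1:1 matching of peaks within an absolute Da window."""
    cands = [
        (abs(ma - mb), i, j)
        for i, (ma, _) in enumerate(a)
        for j, (mb, _) in enumerate(b)
        if abs(ma - mb) <= mz_tol
    ]
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((i, j))
    return matches


def _weight(x: float, weighting: str) -> float:
    if weighting == "sqrt":
        return math.sqrt(x)
    if weighting == "none":
        return x
    raise ValueError(f"unknown intensity weighting {weighting!r}")


def dot_product_score(
    observed: CentroidSpectrum | list[tuple[float, float]],
    predicted: CentroidSpectrum | list[tuple[float, float]],
    mz_tol: float = 0.005,
    weighting: str = "sqrt",
) -> float:
    """Cosine (dot-product) similarity over tolerance-matched peaks.

    Peaks are matched greedily closest-first within ``mz_tol`` Da;
    intensities are square-root transformed by default (standard GC-EI
    practice, dampens base-peak dominance).  Unmatched peaks of either
    spectrum count toward the norms, so the score is 1.0 only for
    effectively identical spectra and 0.0 when nothing matches.  Symmetric
    and invariant to global intensity scaling.
    """
    a = _as_peaklist(observed)
    b = _as_peaklist(predicted)
    if not a or not b:
        raise ValueError("both spectra must be non-empty")
    wa = [_weight(i, weighting) for _, i in a]
    wb = [_weight(i, weighting) for _, i in b]
    num = sum(wa[i] * wb[j] for i, j in _greedy_match(a, b, mz_tol))
    den = math.sqrt(sum(x * x for x in wa)) * math.sqrt(sum(x * x for x in wb))
    return num / den if den > 0 else 0.0


def jaccard_score(
    observed: CentroidSpectrum | list[tuple[float, float]],
    predicted: CentroidSpectrum | list[tuple[float, float]],
    mz_tol: float = 0.005,
) -> float:
    """Matched-peak Jaccard index: |matched| / |union| under tolerance matching."""
    a = _as_peaklist(observed)
    b = _as_peaklist(predicted)
    if not a or not b:
        raise ValueError("both spectra must be non-empty")
    m = len(_greedy_match(a, b, mz_tol))
    return m / (len(a) + len(b) - m)


def _as_peaklist(spec) -> list[tuple[float, float]]:
    if isinstance(spec, CentroidSpectrum):
        return [(p.mz, p.intensity) for p in spec.peaks]
    return [(float(mz), float(i)) for mz, i in spec]


# ---------------------------------------------------------------------------
# candidate ranking
# ---------------------------------------------------------------------------

def _labeled_carbons(counts: dict[str, int]) -> int:
    """Biological (labeled) carbons of a fragment: total C minus TMS carbons.

    Each silicon in a fragment implies an attached trimethylsilyl group
    whose 3 carbons are of natural abundance, not biosynthesized.
    """
    return counts.get("C", 0) - 3 * counts.get("Si", 0)


def _pair_explained(
    pair: FragmentPair, cand: CandidateSpectrum, mz_tol: float, use_formulas: bool
) -> bool:
    for idx, (mz, _) in enumerate(cand.peaks):
        if abs(mz - pair.mz12) > mz_tol:
            continue
        if not use_formulas:
            return True
        frag = cand.fragment_formulas.get(idx)
        if frag is not None and _labeled_carbons(frag) == pair.n_carbons:
            return True
    return False


def rank_candidates(
    observed_ei: CentroidSpectrum,
    fragment_pairs: list[FragmentPair],
    candidates: list[CandidateSpectrum],
    formula_candidates: list[dict[str, int]] | None = None,
    mz_tol: float = 0.005,
    weighting: str = "sqrt",
) -> list[CandidateScore]:
    """Rank isomeric candidate structures against the observed EI evidence.

    A candidate's intact-ion formula is checked against the IROA/CFG-derived
    ``formula_candidates`` (skipped when None); candidates failing that check
    are demoted below every passing one.  Among the rest, ordering is by
    fragment carbon-count consistency (fraction of observed fragment pairs
    explained by a predicted fragment of matching labeled-carbon count; m/z
    co-location alone when the source gives no fragment formulas), breaking
    ties by the spectral dot-product score.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    scored = []
    for cand in candidates:
        spectral = dot_product_score(observed_ei, list(cand.peaks), mz_tol, weighting)
        jac = jaccard_score(observed_ei, list(cand.peaks), mz_tol)
        has_formulas = bool(cand.fragment_formulas)
        if fragment_pairs:
            mz_frac = sum(
                _pair_explained(p, cand, mz_tol, use_formulas=False)
                for p in fragment_pairs
            ) / len(fragment_pairs)
            cc = (
                sum(
                    _pair_explained(p, cand, mz_tol, use_formulas=True)
                    for p in fragment_pairs
                )
                / len(fragment_pairs)
                if has_formulas
                else None
            )
        else:
            mz_frac, cc = 0.0, None
        fmatch = True
        if formula_candidates is not None:
            fmatch = any(
                all(cand.formula.get(el, 0) == fc.get(el, 0)
                    for el in set(cand.formula) | set(fc))
                for fc in formula_candidates
            )
        scored.append((cand.candidate_id, spectral, jac, cc, mz_frac, fmatch))
    # effective consistency for ordering: formula-aware when available,
    # plain m/z co-location otherwise
    scored.sort(
        key=lambda t: (
            not t[5],
            -(t[3] if t[3] is not None else t[4]),
            -t[1],
            t[0],
        )
    )
    return [
        CandidateScore(
            candidate_id=cid,
            spectral_score=sp,
            jaccard=jc,
            carbon_consistency=cc,
            mz_match_fraction=mf,
            formula_match=fm,
            rank=r,
        )
        for r, (cid, sp, jc, cc, mf, fm) in enumerate(scored, start=1)
    ]


def read_candidates_msp(path) -> list[CandidateSpectrum]:
    """Load candidate spectra from an MSP library.

    The record Name becomes the candidate id; a ``Formula:`` header, when
    present, supplies the intact-ion composition.  MSP carries no
    per-fragment formulas, so carbon-count matching for these candidates
    falls back to m/z co-location.
    """
    from .formula_gen import parse_formula
    from .spectra_io import read_msp

    out = []
    for spec in read_msp(path):
        formula = (
            parse_formula(spec.meta["formula"]) if "formula" in spec.meta else {}
        )
        out.append(
            CandidateSpectrum(
                candidate_id=spec.label,
                formula=formula,
                peaks=tuple((p.mz, p.intensity) for p in spec.peaks),
            )
        )
    return out


def read_candidates_csv(path) -> list[CandidateSpectrum]:
    """Load candidate spectra from a long-format CSV.

    Columns: ``candidate_id, formula, mz, intensity[, fragment_formula]``,
    one row per predicted peak; ``fragment_formula`` (optional) enables
    labeled-carbon matching of observed fragment pairs.
    """
    from .formula_gen import parse_formula

    df = pd.read_csv(path)
    required = {"candidate_id", "formula", "mz", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: candidate CSV needs columns {sorted(required)}, "
            f"found {list(df.columns)}"
        )
    out = []
    for cid, grp in df.groupby("candidate_id", sort=False):
        grp = grp.sort_values("mz").reset_index(drop=True)
        frag_formulas = {}
        if "fragment_formula" in grp.columns:
            for idx, val in enumerate(grp["fragment_formula"]):
                if isinstance(val, str) and val.strip():
                    frag_formulas[idx] = parse_formula(val.strip())
        out.append(
            CandidateSpectrum(
                candidate_id=str(cid),
                formula=parse_formula(str(grp["formula"].iloc[0])),
                peaks=tuple(zip(grp["mz"], grp["intensity"])),
                fragment_formulas=frag_formulas,
            )
        )
    return out


def scores_to_dataframe(scores: list[CandidateScore]) -> pd.DataFrame:
    """Tabulate the ranking report."""
    return pd.DataFrame(
        [
            {
                "rank": s.rank,
                "candidate_id": s.candidate_id,
                "formula_match": s.formula_match,
                "carbon_consistency": s.carbon_consistency,
                "mz_match_fraction": s.mz_match_fraction,
                "dot_product": s.spectral_score,
                "jaccard": s.jaccard,
            }
            for s in scores
        ]
    )
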