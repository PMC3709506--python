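"""Identification of BS3 d0/d4 cross-linked peptide pairs.

The search follows the isotope-pair strategy: tryptic peptides with an
internal (missed-cleavage) lysine are paired combinatorially, each pair is
considered in its light (d0) and heavy (d4) form, candidates are matched to
MS1 features by precursor mass and scored against MS2 spectra with a b/y-ion
matched-fraction score, and a hit is validated only if it scores well enough
and (optionally) its isotope doublet partner is present in MS1.  The final
FDR is the fraction of candidate hits rejected by validation.
"""

from __future__ import annotations

import itertools
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from pyteomics import mass as pmass

from .constants import (
    BS3_D0_MASS,
    BS3_D4_MASS,
    BS3_ISOTOPE_SHIFT,
    BS3_SPACER_A,
    CARBAMIDOMETHYL_C,
    OXIDATION_M,
    PROTON_MONO,
    WATER_MONO,
)
from .spectra import MassSpectrum

__all__ = [
    "LinkerSpec",
    "BS3_D0_D4",
    "Peptide",
    "CrossLinkCandidate",
    "ScoredHit",
    "ValidatedLink",
    "digest",
    "expand_variable_mods",
    "peptide_mass",
    "linkable_positions",
    "enumerate_candidates",
    "theoretical_fragments",
    "match_and_score",
    "detect_isotope_pair",
    "validate",
    "compute_fdr",
]

_AA_MASS = dict(pmass.std_aa_mass)


@dataclass(frozen=True)
class LinkerSpec:
    """Chemistry constants of an isotope-coded amine-reactive cross-linker."""

    name: str = "BS3"
    spacer: float = BS3_SPACER_A          # Angstrom
    mass_d0: float = BS3_D0_MASS          # Da added by the light bridge
    mass_d4: float = BS3_D4_MASS          # Da added by the heavy bridge
    reactive_residue: str = "K"

    def __post_init__(self) -> None:
        if self.spacer <= 0:
            raise ValueError("spacer must be > 0")
        if self.mass_d4 <= self.mass_d0:
            raise ValueError("heavy linker must be heavier than light")

    @property
    def isotope_shift(self) -> float:
        return self.mass_d4 - self.mass_d0

    def mass(self, isotope: str) -> float:
        if isotope == "d0":
            return self.mass_d0
        if isotope == "d4":
            return self.mass_d4
        raise ValueError(f"unknown isotope form {isotope!r}")


BS3_D0_D4 = LinkerSpec()


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide in 1-based protein coordinates."""

    protein: str
    sequence: str
    start: int
    end: int
    missed_cleavages: int
    mass: float
    #: variable modifications as (1-based position in peptide, name, delta Da)
    mods: tuple[tuple[int, str, float], ...] = ()

    def __len__(self) -> int:
        return len(self.sequence)


def peptide_mass(sequence: str, mods: Sequence[tuple[int, str, float]] = ()) -> float:
    """Monoisotopic neutral mass of a peptide with optional modifications."""
    try:
        total = sum(_AA_MASS[aa] for aa in sequence)
    except KeyError as exc:
        raise ValueError(f"unknown residue symbol {exc.args[0]!r}") from exc
    return total + WATER_MONO + sum(delta for _, _, delta in mods)


def digest(sequence: str, max_missed: int = 2, protein: str = "?") -> list[Peptide]:
    """Tryptic digest: cleave after K/R unless followed by P.

    Returns every peptide with 0..``max_missed`` internal missed cleavages.
    The zero-missed peptides partition the sequence.
    """
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence) - set(_AA_MASS)
    if bad:
        raise ValueError(f"unknown residue symbol(s): {sorted(bad)}")
    if not 0 <= max_missed <= 2:
        raise ValueError("missed cleavages must be within 0..2")

    cut_after = [
        i
        for i, aa in enumerate(sequence)
        if aa in "KR" and (i + 1 == len(sequence) or sequence[i + 1] != "P")
    ]
    # segment boundaries (0-based, exclusive end)
    ends = sorted(set(cut_after) | {len(sequence) - 1})
    starts = [0] + [e + 1 for e in ends[:-1]]

    peptides: list[Peptide] = []
    for i, s in enumerate(starts):
        for missed in range(max_missed + 1):
            j = i + missed
            if j >= len(ends):
                break
            e = ends[j]
            seq = sequence[s : e + 1]
            peptides.append(
                Peptide(
                    protein=protein,
                    sequence=seq,
                    start=s + 1,
                    end=e + 1,
                    missed_cleavages=missed,
                    mass=peptide_mass(seq),
                )
            )
    return peptides


def expand_variable_mods(
    peptides: Iterable[Peptide],
    mod_specs: Sequence[tuple[str, str, float]] = (CARBAMIDOMETHYL_C, OXIDATION_M),
    max_mods: int = 3,
) -> list[Peptide]:
    """Expand peptides with all combinations of <= ``max_mods`` variable mods."""
    out: list[Peptide] = []
    for pep in peptides:
        sites = [
            (pos + 1, name, delta)
            for pos, aa in enumerate(pep.sequence)
            for res, name, delta in mod_specs
            if aa == res
        ]
        out.append(pep)
        for r in range(1, min(max_mods, len(sites)) + 1):
            for combo in itertools.combinations(sites, r):
                out.append(
                    replace(
                        pep,
                        mods=combo,
                        mass=pep.mass + sum(d for _, _, d in combo),
                    )
                )
    return out


def linkable_positions(pep: Peptide, linker: LinkerSpec = BS3_D0_D4) -> list[int]:
    """1-based protein positions of cross-linkable residues in a peptide.

    A linkable lysine must be a missed-cleavage site: internal to the peptide
    (trypsin does not cleave after a cross-linked K, so the K cannot sit at
    the peptide C-terminus) and an actual cleavage site (not followed by P).
    """
    res = linker.reactive_residue
    return [
        pep.start + i
        for i, aa in enumerate(pep.sequence[:-1])
        if aa == res and pep.sequence[i + 1] != "P"
    ]


@dataclass(frozen=True)
class CrossLinkCandidate:
    """A peptide pair bridged by one cross-link, in one isotope form."""

    pep1: Peptide
    pep2: Peptide
    link1: tuple[str, int]   # (protein, 1-based residue)
    link2: tuple[str, int]
    isotope: str             # 'd0' | 'd4'
    mass: float              # theoretical neutral precursor mass, Da

    @property
    def key(self) -> tuple[tuple[str, int], tuple[str, int]]:
        """Unordered residue-pair key, canonically sorted."""
        return tuple(sorted((self.link1, self.link2)))  # type: ignore[return-value]

    @property
    def is_interprotein(self) -> bool:
        return self.link1[0] != self.link2[0]


def _canonical_pair(p1: Peptide, p2: Peptide) -> tuple[Peptide, Peptide]:
    k = lambda p: (p.protein, p.start, p.sequence, p.mods)
    return (p1, p2) if k(p1) <= k(p2) else (p2, p1)


def enumerate_candidates(
    peptides_by_protein: Mapping[str, Sequence[Peptide]],
    linker: LinkerSpec = BS3_D0_D4,
) -> list[CrossLinkCandidate]:
    """All cross-link candidates over all unordered peptide pairs.

    One candidate is emitted per (peptide pair, linked-K choice, isotope
    form); at most one cross-link per peptide.  The enumeration is invariant
    to protein input order.
    """
    linkable: list[tuple[Peptide, list[int]]] = []
    for protein in sorted(peptides_by_protein):
        for pep in peptides_by_protein[protein]:
            sites = linkable_positions(pep, linker)
            if sites:
                linkable.append((pep, sites))
    linkable.sort(key=lambda t: (t[0].protein, t[0].start, t[0].sequence, t[0].mods))

    candidates: list[CrossLinkCandidate] = []
    for (pa, sa), (pb, sb) in itertools.combinations_with_replacement(linkable, 2):
        if pa is pb:
            continue  # a peptide cannot be cross-linked to itself
        p1, p2 = _canonical_pair(pa, pb)
        s1 = sa if p1 is pa else sb
        s2 = sb if p1 is pa else sa
        for r1 in s1:
            for r2 in s2:
                for isotope in ("d0", "d4"):
                    candidates.append(
                        CrossLinkCandidate(
                            pep1=p1,
                            pep2=p2,
                            link1=(p1.protein, r1),
                            link2=(p2.protein, r2),
                            isotope=isotope,
                            mass=p1.mass + p2.mass + linker.mass(isotope),
                        )
                    )
    return candidates


def theoretical_fragments(
    candidate: CrossLinkCandidate, linker: LinkerSpec = BS3_D0_D4
) -> list[tuple[str, float]]:
    """Singly protonated b/y fragment m/z values of both peptides.

    Fragments that contain the linked residue carry the full partner peptide
    plus the linker bridge as a fixed mass addition.
    """
    linker_mass = linker.mass(candidate.isotope)
    frags: list[tuple[str, float]] = []
    pairs = (
        (candidate.pep1, candidate.link1[1], candidate.pep2, "A"),
        (candidate.pep2, candidate.link2[1], candidate.pep1, "B"),
    )
    for pep, link_protein_pos, partner, tag in pairs:
        link_idx = link_protein_pos - pep.start  # 0-based position in peptide
        residues = [_AA_MASS[aa] for aa in pep.sequence]
        for pos, _, delta in pep.mods:
            residues[pos - 1] += delta
        prefix = np.cumsum(residues)
        total = prefix[-1]
        xl_add = partner.mass + linker_mass
        n = len(residues)
        for i in range(1, n):  # b_i covers residues [0, i); y_i covers [n-i, n)
            b = prefix[i - 1] + PROTON_MONO
            if link_idx < i:
                b += xl_add
            frags.append((f"{tag}b{i}", b))
            y = total - prefix[n - i - 1] + WATER_MONO + PROTON_MONO
            if link_idx >= n - i:
                y += xl_add
            frags.append((f"{tag}y{i}", y))
    return frags


@dataclass
class ScoredHit:
    """A candidate matched to an MS1 feature and scored against its MS2."""

    candidate: CrossLinkCandidate
    feature: "object"        # Ms1Feature (duck-typed: mz, z, rt, intensity)
    score: float
    n_matched: int
    n_theoretical: int
    pair_found: bool | None = None
    pair_ratio: float = float("nan")


def score_spectrum(
    candidate: CrossLinkCandidate,
    spectrum: MassSpectrum,
    fragment_tol: float = 0.8,
    linker: LinkerSpec = BS3_D0_D4,
) -> tuple[float, int, int]:
    """Matched-fraction MS2 score in [0, 1].

    score = (matched / theoretical fragments) x (matched intensity fraction).
    """
    frags = theoretical_fragments(candidate, linker)
    if len(spectrum) == 0:
        return 0.0, 0, len(frags)
    matched = 0
    matched_idx: set[int] = set()
    mzs = spectrum.mz
    for _, fmz in frags:
        lo = int(np.searchsorted(mzs, fmz - fragment_tol, side="left"))
        hi = int(np.searchsorted(mzs, fmz + fragment_tol, side="right"))
        if hi > lo:
            matched += 1
            matched_idx.update(range(lo, hi))
    total_int = float(spectrum.intensity.sum())
    int_frac = (
        float(spectrum.intensity[sorted(matched_idx)].sum()) / total_int
        if total_int > 0
        else 0.0
    )
    frac = matched / len(frags)
    return frac * int_frac, matched, len(frags)


def match_and_score(
    candidates: Sequence[CrossLinkCandidate],
    ms1_features: Sequence,
    ms2_spectra: Mapping[str, MassSpectrum],
    precursor_tol_ppm: float = 10.0,
    fragment_tol: float = 0.8,
    linker: LinkerSpec = BS3_D0_D4,
    proton: float = PROTON_MONO,
) -> list[ScoredHit]:
    """Match candidates to MS1 features by neutral precursor mass, score MS2.

    Only features that carry an MS2 spectrum produce hits; a candidate
    without any matching spectrum is simply unmatched.
    """
    if precursor_tol_ppm <= 0 or fragment_tol <= 0:
        raise ValueError("tolerances must be > 0")
    feats = [f for f in ms1_features if getattr(f, "feature_id", None) in ms2_spectra]
    feats.sort(key=lambda f: f.z * (f.mz - proton))
    neutral = [f.z * (f.mz - proton) for f in feats]

    hits: list[ScoredHit] = []
    for cand in candidates:
        tol = cand.mass * precursor_tol_ppm * 1e-6
        lo = bisect_left(neutral, cand.mass - tol)
        hi = bisect_right(neutral, cand.mass + tol)
        for f in feats[lo:hi]:
            score, nm, nt = score_spectrum(
                cand, ms2_spectra[f.feature_id], fragment_tol, linker
            )
            hits.append(ScoredHit(cand, f, score, nm, nt))
    return hits


def detect_isotope_pair(
    hit: ScoredHit,
    ms1_features: Sequence,
    shift: float = BS3_ISOTOPE_SHIFT,
    mz_tol_ppm: float = 10.0,
    rt_tol: float = 1.0,
) -> tuple[bool, float]:
    """Look for the d0/d4 doublet partner of a hit in MS1.

    For a d0 hit the partner sits at m/z + shift/z, for a d4 hit at
    m/z - shift/z, co-eluting within ``rt_tol`` seconds.  Returns
    (found, d0:d4 intensity ratio); the ratio is NaN when not found.
    """
    f = hit.feature
    sign = +1 if hit.candidate.isotope == "d0" else -1
    target = f.mz + sign * shift / f.z
    tol = target * mz_tol_ppm * 1e-6
    best = None
    for g in ms1_features:
        if g is f or g.z != f.z:
            continue
        if abs(g.rt - f.rt) <= rt_tol and abs(g.mz - target) <= tol:
            if best is None or g.intensity > best.intensity:
                best = g
    if best is None:
        return False, float("nan")
    if sign > 0:
        ratio = f.intensity / best.intensity if best.intensity > 0 else float("inf")
    else:
        ratio = best.intensity / f.intensity if f.intensity > 0 else float("inf")
    return True, ratio


@dataclass
class ValidatedLink:
    """A unique residue-residue cross-link supported by validated hits."""

    key: tuple[tuple[str, int], tuple[str, int]]
    hits: list[ScoredHit] = field(default_factory=list)
    pair_detected: bool = False

    @property
    def is_interprotein(self) -> bool:
        return self.key[0][0] != self.key[1][0]

    @property
    def n_spectra(self) -> int:
        return len(self.hits)

    @property
    def best_score(self) -> float:
        return max((h.score for h in self.hits), default=0.0)


def validate(
    hits: Sequence[ScoredHit],
    min_score: float = 0.3,
    require_pair: bool = True,
) -> tuple[list[ValidatedLink], int, int]:
    """Apply the two validation criteria and deduplicate to unique links.

    A hit is accepted iff its MS2 score is >= ``min_score`` and, when
    ``require_pair``, its isotope doublet partner was detected.  Returns
    (links, n_candidate_hits, n_validated_hits).
    """
    n_candidates = len(hits)
    links: dict[tuple, ValidatedLink] = {}
    n_validated = 0
    for hit in hits:
        ok = hit.score >= min_score and (not require_pair or bool(hit.pair_found))
        if not ok:
            continue
        n_validated += 1
        link = links.setdefault(hit.candidate.key, ValidatedLink(hit.candidate.key))
        link.hits.append(hit)
        link.pair_detected = link.pair_detected or bool(hit.pair_found)
    ordered = sorted(links.values(), key=lambda l: l.key)
    return ordered, n_candidates, n_validated


def compute_fdr(n_candidates: int, n_validated: int) -> float:
    """Validation FDR, %: fraction of candidate hits rejected by validation."""
    if n_candidates <= 0:
        raise ValueError("n_candidates must be > 0")
    if not 0 <= n_validated <= n_candidates:
        raise ValueError("0 <= n_validated <= n_candidates required")
    return round(100.0 * (n_candidates - n_validated) / n_candidates, 2)
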