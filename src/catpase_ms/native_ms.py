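"""Native-MS inversion: masses, subcomplex compositions, occupancy, lipids.

A native spectrum of an intact complex shows one Gaussian peak per charge
state z at m/z = (M + z*1.00728)/z.  This module picks peaks, groups them
into charge series to recover neutral masses, explains each mass as a
bounded combination of subunit masses (plus lipids and nucleotides),
explains small mass shifts as PTM combinations, reads nucleotide occupancy
from integer-spaced peak splitting, and computes the lipid:protein
stoichiometry of the membrane-ring lipid plug.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .constants import ATP_AVG, PROTON_AVG, PTM_DELTAS
from .spectra import MassSpectrum

__all__ = [
    "SubunitMassTable",
    "SubunitEntry",
    "ChargeSeries",
    "ComplexAssignment",
    "OccupancyProfile",
    "DEFAULT_SUBUNIT_TABLE",
    "pick_peaks",
    "infer_charge",
    "deconvolute",
    "assign_composition",
    "explain_mass_shift",
    "lipid_stoichiometry",
    "call_occupancy",
]


@dataclass(frozen=True)
class SubunitEntry:
    name: str
    mass: float          # average mass, Da
    min_copies: int = 0
    max_copies: int = 1

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"{self.name}: mass must be > 0")
        if not 0 <= self.min_copies <= self.max_copies:
            raise ValueError(f"{self.name}: need 0 <= min <= max copies")


@dataclass
class SubunitMassTable:
    """Subunit masses with copy-number bounds, plus lipid/nucleotide masses."""

    entries: list[SubunitEntry]
    lipid_mass: float = 750.0
    nucleotide_mass: float = ATP_AVG

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("subunit names must be unique")
        if self.lipid_mass <= 0 or self.nucleotide_mass <= 0:
            raise ValueError("lipid and nucleotide masses must be > 0")


#: Approximate mature-subunit masses (Da) of the spinach chloroplast ATP
#: synthase.  These are rounded stand-ins consistent with the intact F1 mass
#: of ~400 kDa and a III14 membrane ring of ~112.3 kDa, not measured values.
DEFAULT_SUBUNIT_TABLE = SubunitMassTable(
    entries=[
        SubunitEntry("alpha", 55_500.0, 0, 3),
        SubunitEntry("beta", 53_900.0, 0, 3),
        SubunitEntry("gamma", 35_800.0, 0, 1),
        SubunitEntry("delta", 20_500.0, 0, 1),
        SubunitEntry("epsilon", 14_700.0, 0, 1),
        SubunitEntry("I", 21_000.0, 0, 1),
        SubunitEntry("II", 16_500.0, 0, 1),
        SubunitEntry("III", 8_021.0, 0, 14),
        SubunitEntry("IV", 27_000.0, 0, 1),
    ],
)


def pick_peaks(
    spectrum: MassSpectrum,
    snr_threshold: float = 5.0,
    smooth_sigma: float = 0.0,
) -> list[tuple[float, float]]:
    """Local maxima above an SNR threshold, apex-refined by a 3-point fit.

    The noise level is a robust MAD estimate of the intensity trace; the
    apex is refined with a parabola through log-intensity, which is exact
    for a Gaussian peak.  ``smooth_sigma`` (in grid points) optionally
    smooths the trace before picking.
    """
    if len(spectrum) == 0:
        raise ValueError("empty spectrum")
    y = spectrum.intensity
    if smooth_sigma > 0:
        y = gaussian_filter1d(y, smooth_sigma)
    mz = spectrum.mz
    med = np.median(y)
    noise = 1.4826 * np.median(np.abs(y - med))
    floor = max(snr_threshold * noise, 1e-9 * (y.max() if y.max() > 0 else 1.0))

    peaks: list[tuple[float, float]] = []
    for i in range(1, len(y) - 1):
        if y[i] <= floor or not (y[i] > y[i - 1] and y[i] >= y[i + 1]):
            continue
        y0, y1, y2 = y[i - 1], y[i], y[i + 1]
        if y0 > 0 and y2 > 0 and y1 > y0 and y1 > y2:
            l0, l1, l2 = np.log(y0), np.log(y1), np.log(y2)
            denom = l0 - 2 * l1 + l2
            delta = 0.5 * (l0 - l2) / denom if denom < 0 else 0.0
        else:
            delta = 0.0
        step = mz[i + 1] - mz[i]
        peaks.append((float(mz[i] + delta * step), float(y1)))
    return peaks


def infer_charge(
    m1: float, m2: float, proton: float = PROTON_AVG, max_residual: float = 0.2
) -> tuple[int, bool, float]:
    """Charge of the lower-m/z neighbour of an adjacent peak pair.

    For consecutive charge states z (at m1, the higher m/z) and z+1 (at m2),
    (m1 - proton)/(m1 - m2) = z + 1 exactly.  Returns (z+1, consistent,
    residual): a residual above ``max_residual`` flags the pair as not
    adjacent (for example a skipped charge state).
    """
    if m1 <= m2:
        raise ValueError("need m1 > m2")
    ratio = (m1 - proton) / (m1 - m2)
    z_plus_1 = int(round(ratio))
    residual = abs(ratio - z_plus_1)
    return z_plus_1, residual <= max_residual, residual


@dataclass
class ChargeSeries:
    """Peaks assigned to consecutive charge states of one species."""

    peaks: list[tuple[float, float, int]]   # (m/z, intensity, z)
    mass: float                             # abundance-weighted neutral mass
    mass_sd: float
    abundance: float                        # summed peak intensity

    @property
    def charges(self) -> list[int]:
        return sorted(z for _, _, z in self.peaks)


def _series_from_assignment(
    assigned: list[tuple[float, float, int]], proton: float
) -> ChargeSeries:
    mzs = np.array([p[0] for p in assigned])
    ints = np.array([p[1] for p in assigned])
    zs = np.array([p[2] for p in assigned])
    masses = zs * (mzs - proton)
    w = ints / ints.sum()
    mean = float(np.sum(w * masses))
    sd = float(np.sqrt(np.sum(w * (masses - mean) ** 2)))
    return ChargeSeries(assigned, mean, sd, float(ints.sum()))


def deconvolute(
    spectrum: MassSpectrum,
    snr_threshold: float = 5.0,
    smooth_sigma: float = 0.0,
    charge_range: tuple[int, int] = (1, 100),
    match_tol_ppm: float = 50.0,
    min_peaks: int = 3,
    merge_tol_rel: float = 5e-4,
    min_rel_abundance: float = 0.01,
    proton: float = PROTON_AVG,
) -> list[ChargeSeries]:
    """Group picked peaks into charge series and recover neutral masses.

    Greedy charge-hypothesis search: starting from the most intense
    unassigned peak, every charge hypothesis z predicts the full series of
    positions (M + k*proton)/k; the hypothesis matching the most unassigned
    peaks wins, with ties broken in favour of consecutive charge sets (this
    rejects z-harmonics, which only match every other peak) and then lower
    mass.  Series need >= ``min_peaks`` peaks; each peak joins at most one
    series; output is sorted by abundance.

    Post-processing: series whose masses agree within ``merge_tol_rel``
    (relative) are merged — under noise a species can split when a few
    apexes drift outside the match tolerance — and series weaker than
    ``min_rel_abundance`` times the base series are discarded as noise.
    """
    peaks = pick_peaks(spectrum, snr_threshold, smooth_sigma)
    if len(peaks) < min_peaks:
        raise ValueError(f"need at least {min_peaks} picked peaks, got {len(peaks)}")
    peaks = sorted(peaks)  # by m/z
    mzs = np.array([p[0] for p in peaks])
    ints = np.array([p[1] for p in peaks])
    unassigned = np.ones(len(peaks), dtype=bool)
    # seeds that produced no series (e.g. merged peaks of two species) are
    # skipped but stay available for matching by later hypotheses
    failed_seed = np.zeros(len(peaks), dtype=bool)
    zmin, zmax = charge_range
    series: list[ChargeSeries] = []

    while unassigned.sum() >= min_peaks:
        seedable = unassigned & ~failed_seed
        if not seedable.any():
            break
        seed = int(np.flatnonzero(seedable)[np.argmax(ints[seedable])])
        best: tuple | None = None
        for z in range(zmin, zmax + 1):
            mass = z * (mzs[seed] - proton)
            matched: list[tuple[int, int]] = []   # (peak index, charge)
            used: set[int] = set()
            for k in range(zmin, zmax + 1):
                pred = (mass + k * proton) / k
                if pred < mzs[0] - 1 or pred > mzs[-1] + 1:
                    continue
                i = int(np.searchsorted(mzs, pred))
                cand = [
                    j
                    for j in (i - 1, i)
                    if 0 <= j < len(mzs)
                    and unassigned[j]
                    and j not in used
                    and abs(mzs[j] - pred) <= pred * match_tol_ppm * 1e-6
                ]
                if cand:
                    j = min(cand, key=lambda j: abs(mzs[j] - pred))
                    matched.append((j, k))
                    used.add(j)
            if len(matched) < min_peaks:
                continue
            ks = sorted(k for _, k in matched)
            gaps = ks[-1] - ks[0] + 1 - len(ks)
            score = (len(matched), -gaps, -mass)
            if best is None or score > best[0]:
                best = (score, matched)
        if best is None:
            failed_seed[seed] = True
            continue
        _, matched = best
        assigned = [(float(mzs[j]), float(ints[j]), k) for j, k in matched]
        for j, _ in matched:
            unassigned[j] = False
        series.append(_series_from_assignment(assigned, proton))

    if not series:
        raise ValueError("no consistent charge series found")
    series.sort(key=lambda s: -s.abundance)
    merged: list[list[tuple[float, float, int]]] = []
    for s in series:
        for group in merged:
            ref = _series_from_assignment(group, proton).mass
            if abs(s.mass - ref) <= merge_tol_rel * ref:
                group.extend(s.peaks)
                break
        else:
            merged.append(list(s.peaks))
    series = [_series_from_assignment(g, proton) for g in merged]
    series.sort(key=lambda s: -s.abundance)
    cutoff = min_rel_abundance * series[0].abundance
    return [s for s in series if s.abundance >= cutoff]


# ---------------------------------------------------------------------------
# composition assignment
# ---------------------------------------------------------------------------


@dataclass
class ComplexAssignment:
    """One candidate composition for an observed mass."""

    composition: dict[str, int]
    lipids: int
    nucleotides: int
    theoretical_mass: float
    observed_mass: float
    rank: int = 0

    @property
    def error_da(self) -> float:
        return self.theoretical_mass - self.observed_mass

    @property
    def error_ppm(self) -> float:
        if self.observed_mass == 0:
            return 0.0
        return 1e6 * self.error_da / self.observed_mass

    @property
    def total_copies(self) -> int:
        return sum(self.composition.values()) + self.lipids + self.nucleotides

    @property
    def n_types(self) -> int:
        return sum(1 for v in self.composition.values() if v > 0) + (
            self.lipids > 0
        ) + (self.nucleotides > 0)


def assign_composition(
    observed_mass: float,
    table: SubunitMassTable,
    tol_da: float | None = None,
    tol_ppm: float | None = None,
    constraints: Sequence[Callable[[dict[str, int]], bool]] = (),
    lipid_bounds: tuple[int, int] = (0, 0),
    nucleotide_bounds: tuple[int, int] = (0, 0),
    max_results: int = 1_000_000,
) -> list[ComplexAssignment]:
    """Exhaustive bounded search for compositions matching an observed mass.

    Depth-first enumeration over copy-number ranges with branch-and-bound
    pruning on the remaining reachable mass.  Results are ranked by
    |mass error|, ties by fewer total components, then fewer distinct
    types, then lexicographically by composition.  Constraint callables
    (composition dict -> bool, lipid/nucleotide counts included under
    ``"lipid"``/``"nucleotide"``) filter candidates before ranking.

    The default tolerance is 0.2% of the observed mass, matching
    assignment of 0.1-0.55 MDa complexes to roughly the nearest kDa.
    """
    if observed_mass < 0:
        raise ValueError("observed mass must be >= 0")
    if not table.entries:
        raise ValueError("empty subunit table")
    if tol_da is None:
        tol_da = (
            observed_mass * tol_ppm * 1e-6
            if tol_ppm is not None
            else observed_mass * 0.002
        )
    if tol_da < 0:
        raise ValueError("tolerance must be >= 0")

    items = [(e.name, e.mass, e.min_copies, e.max_copies) for e in table.entries]
    items.append(("lipid", table.lipid_mass, *lipid_bounds))
    items.append(("nucleotide", table.nucleotide_mass, *nucleotide_bounds))
    items.sort(key=lambda t: -t[1])
    # max mass still addable from item i onward
    suffix_max = [0.0] * (len(items) + 1)
    for i in range(len(items) - 1, -1, -1):
        suffix_max[i] = suffix_max[i + 1] + items[i][1] * items[i][3]

    results: list[ComplexAssignment] = []
    counts: dict[str, int] = {}

    def dfs(i: int, mass: float) -> None:
        if mass > observed_mass + tol_da:
            return
        if mass + suffix_max[i] < observed_mass - tol_da:
            return
        if i == len(items):
            comp = dict(counts)
            if all(rule(comp) for rule in constraints):
                if len(results) >= max_results:
                    raise RuntimeError(
                        "more than %d compositions within tolerance; tighten the "
                        "tolerance or the copy-number bounds" % max_results
                    )
                results.append(
                    ComplexAssignment(
                        composition={
                            k: v
                            for k, v in comp.items()
                            if k not in ("lipid", "nucleotide") and v > 0
                        },
                        lipids=comp.get("lipid", 0),
                        nucleotides=comp.get("nucleotide", 0),
                        theoretical_mass=mass,
                        observed_mass=observed_mass,
                    )
                )
            return
        name, m, lo, hi = items[i]
        for c in range(lo, hi + 1):
            add = c * m
            if mass + add > observed_mass + tol_da:
                break
            counts[name] = c
            dfs(i + 1, mass + add)
        counts.pop(name, None)

    dfs(0, 0.0)
    results.sort(
        key=lambda a: (
            abs(a.error_da),
            a.total_copies,
            a.n_types,
            tuple(sorted(a.composition.items())),
            a.lipids,
            a.nucleotides,
        )
    )
    for rank, a in enumerate(results, start=1):
        a.rank = rank
    return results


def explain_mass_shift(
    delta: float,
    ptm_deltas: Sequence[tuple[str, float, int]] = PTM_DELTAS,
    tolerance: float = 0.05,
) -> list[tuple[dict[str, int], float]]:
    """Explain a protein mass shift as a bounded combination of PTMs.

    Returns (combination, residual) pairs with |residual| <= tolerance,
    ranked by |residual| then by fewer modifications.  An empty combination
    explains delta = 0.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    out: list[tuple[dict[str, int], float]] = []
    ranges = [range(maxc + 1) for _, _, maxc in ptm_deltas]
    for combo in itertools.product(*ranges):
        total = sum(c * d for c, (_, d, _) in zip(combo, ptm_deltas))
        residual = delta - total
        if abs(residual) <= tolerance:
            out.append(
                (
                    {
                        name: c
                        for c, (name, _, _) in zip(combo, ptm_deltas)
                        if c > 0
                    },
                    residual,
                )
            )
    out.sort(key=lambda t: (abs(t[1]), sum(t[0].values()), sorted(t[0])))
    return out


def lipid_stoichiometry(
    plug_mass: float, n_ring_subunits: int, avg_lipid_mass: float
) -> tuple[float, int, float]:
    """Lipids per ring subunit from the plug mass.

    Returns (lipids per subunit, nearest integer stoichiometry, residual).
    """
    if n_ring_subunits <= 0 or avg_lipid_mass <= 0 or plug_mass < 0:
        raise ValueError("inputs must be positive (plug mass may be 0)")
    per_subunit = plug_mass / (n_ring_subunits * avg_lipid_mass)
    nearest = int(round(per_subunit))
    return per_subunit, nearest, per_subunit - nearest


@dataclass
class OccupancyProfile:
    """Nucleotide occupancy read from integer-spaced mass splitting."""

    base_mass: float
    occupancies: list[tuple[int, float]]       # (k, normalized abundance)
    unassigned: list[tuple[float, float]]      # species fitting no integer k
    max_occupancy: int
    ratio: str


def _ratio_string(abundances: Sequence[float]) -> str:
    smallest = min(a for a in abundances if a > 0)
    parts = []
    for a in abundances:
        r = a / smallest
        parts.append(str(int(round(r))) if abs(r - round(r)) < 0.05 else f"{r:.1f}")
    return ":".join(parts)


def call_occupancy(
    species: Sequence[tuple[float, float]],
    nucleotide_mass: float = ATP_AVG,
    tolerance: float = 100.0,
    apo_mass: float | None = None,
) -> OccupancyProfile:
    """Assign integer nucleotide counts to deconvolved species.

    The base (apo) mass is anchored at the lightest detected species unless
    an explicit ``apo_mass`` override is given (for conditions where no apo
    population remains).  Each species gets the integer k minimising
    |M - base - k*nucleotide| and is reported unassigned if the residual
    exceeds ``tolerance``.  Abundances are normalised to sum to 1.
    """
    if not species:
        raise ValueError("at least one species required")
    if nucleotide_mass <= 0 or tolerance <= 0:
        raise ValueError("nucleotide mass and tolerance must be > 0")
    base = min(m for m, _ in species) if apo_mass is None else apo_mass
    total = sum(a for _, a in species)
    if total <= 0:
        raise ValueError("abundances must sum to > 0")

    assigned: dict[int, float] = {}
    unassigned: list[tuple[float, float]] = []
    for m, a in sorted(species):
        k = max(0, int(round((m - base) / nucleotide_mass)))
        if abs(m - base - k * nucleotide_mass) > tolerance:
            unassigned.append((m, a / total))
        else:
            assigned[k] = assigned.get(k, 0.0) + a / total
    occupancies = sorted(assigned.items())
    return OccupancyProfile(
        base_mass=base,
        occupancies=occupancies,
        unassigned=unassigned,
        max_occupancy=max(assigned) if assigned else 0,
        ratio=_ratio_string([a for _, a in occupancies]) if assigned else "",
    )
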