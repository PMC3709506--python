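"""Forward models that generate every input the pipeline consumes.

The generators emulate the data the analysis inverts: multi-charge-state
native-MS envelopes of 0.4-0.55 MDa complexes, peak splitting by integer
nucleotide masses, d0/d4 cross-link doublets with co-eluting Gaussian
chromatographic peaks at a defined light/heavy area ratio, b/y fragment
spectra of cross-linked peptides, and toy coordinate files with lysines at
analytically known positions.  Every generator is deterministic for a fixed
seed and records its ground truth so round-trip tests can compare exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np

from .constants import GAUSSIAN_FWHM, PROTON_AVG, PROTON_MONO
from .spectra import Chromatogram, MassSpectrum
from .xlink_search import (
    BS3_D0_D4,
    CrossLinkCandidate,
    LinkerSpec,
    Peptide,
    digest,
    theoretical_fragments,
)

__all__ = [
    "GroundTruth",
    "InstrumentModel",
    "Ms1Feature",
    "XlRun",
    "gen_native_spectrum",
    "gen_occupancy_spectrum",
    "gen_xl_run",
    "gen_toy_structure",
    "gen_protein_sequences",
    "write_truth_manifest",
]

_MAX_GRID_POINTS = 20_000_000


@dataclass
class GroundTruth:
    """The parameters a simulated experiment is built from.

    species
        (label, exact average mass Da, relative abundance) per complex.
    links
        (protein1, residue1, protein2, residue2, light/heavy area ratio)
        per true cross-link; residues are 1-based lysine positions.
    phosphosites
        (protein, residue) phosphorylated positions.
    """

    species: list[tuple[str, float, float]] = field(default_factory=list)
    links: list[tuple[str, int, str, int, float]] = field(default_factory=list)
    phosphosites: list[tuple[str, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for label, m, a in self.species:
            if m <= 0 or a <= 0:
                raise ValueError(f"species {label!r}: mass and abundance must be > 0")
        for p1, r1, p2, r2, ratio in self.links:
            if ratio <= 0:
                raise ValueError(f"link {p1}:{r1}-{p2}:{r2}: ratio must be > 0")


@dataclass
class InstrumentModel:
    """Instrument response parameters.

    resolution is m/dm at FWHM; the peak shape is Gaussian with
    sigma = m / (2.3548 * resolution).  noise_sd is additive Gaussian noise
    expressed relative to the maximum intensity, clipped at zero.
    """

    resolution: float = 1000.0
    charge_range: tuple[int, int] = (35, 55)
    noise_sd: float = 0.0
    proton_mass: float = PROTON_AVG

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        zmin, zmax = self.charge_range
        if zmin > zmax or zmin < 1:
            raise ValueError("charge range must be a non-empty positive interval")

    def sigma(self, m: float) -> float:
        return m / (GAUSSIAN_FWHM * self.resolution)


def gen_native_spectrum(
    truth: GroundTruth,
    model: InstrumentModel,
    mz_step: float | None = None,
    pad_sigmas: float = 6.0,
) -> MassSpectrum:
    """Simulate a native mass spectrum of intact complexes.

    Each species of neutral mass M contributes one Gaussian peak per charge
    z in the model's range, centred at (M + z*proton)/z, with equal
    abundance across charge states.
    """
    if not truth.species:
        raise ValueError("at least one species required")
    zmin, zmax = model.charge_range
    charges = np.arange(zmin, zmax + 1)
    centers = []
    for label, m, a in truth.species:
        for z in charges:
            c = (m + z * model.proton_mass) / z
            centers.append((c, a, model.sigma(c)))

    lo = min(c - pad_sigmas * s for c, _, s in centers)
    hi = max(c + pad_sigmas * s for c, _, s in centers)
    if mz_step is None:
        mz_step = min(s for _, _, s in centers) / 5.0
    n = int(np.ceil((hi - lo) / mz_step)) + 1
    if n > _MAX_GRID_POINTS:
        raise ValueError(
            f"m/z grid of {n} points is too fine; pass a coarser mz_step"
        )
    mz = lo + mz_step * np.arange(n)
    intensity = np.zeros_like(mz)
    for c, a, s in centers:
        win = np.abs(mz - c) < pad_sigmas * s
        intensity[win] += a * np.exp(-0.5 * ((mz[win] - c) / s) ** 2)

    if model.noise_sd > 0:
        rng = np.random.default_rng(truth.seed)
        intensity = intensity + rng.normal(
            0.0, model.noise_sd * intensity.max(), size=intensity.shape
        )
        np.clip(intensity, 0.0, None, out=intensity)
    return MassSpectrum(mz, intensity, spectrum_id="native", ms_level=1)


def gen_occupancy_spectrum(
    base_mass: float,
    nucleotide_mass: float,
    weights: Sequence[float],
    model: InstrumentModel,
    seed: int = 0,
) -> MassSpectrum:
    """Simulate peak splitting by integer numbers of bound nucleotides.

    weights[k] is the relative abundance of the species of mass
    base_mass + k * nucleotide_mass; zero weights produce no sub-series.
    """
    if any(w < 0 for w in weights):
        raise ValueError("weights must be >= 0")
    species = [
        (f"{k}xNUC", base_mass + k * nucleotide_mass, w)
        for k, w in enumerate(weights)
        if w > 0
    ]
    truth = GroundTruth(species=species, seed=seed)
    return gen_native_spectrum(truth, model)


# ---------------------------------------------------------------------------
# cross-linking run
# ---------------------------------------------------------------------------


@dataclass
class Ms1Feature:
    """One detected precursor ion in one MS1 scan."""

    feature_id: str
    mz: float
    z: int
    rt: float
    intensity: float


@dataclass
class XlRun:
    """A simulated cross-linking LC-MS/MS acquisition."""

    features: list[Ms1Feature]
    ms2: dict[str, MassSpectrum]
    chromatograms: dict[tuple, tuple[Chromatogram, Chromatogram]]
    manifest: dict


def _link_peptide(
    sequences: Mapping[str, str], protein: str, residue: int, linker: LinkerSpec
) -> Peptide:
    seq = sequences[protein]
    if residue < 1 or residue > len(seq) or seq[residue - 1] != linker.reactive_residue:
        raise ValueError(
            f"link residue {protein}:{residue} is not a {linker.reactive_residue}"
        )
    candidates = [
        p
        for p in digest(seq, max_missed=2, protein=protein)
        # linked K must be internal (a missed-cleavage site)
        if p.start <= residue < p.end
    ]
    if not candidates:
        raise ValueError(f"no tryptic peptide holds {protein}:{residue} internally")
    return min(candidates, key=lambda p: (p.missed_cleavages, len(p.sequence)))


def gen_xl_run(
    sequences: Mapping[str, str],
    truth: GroundTruth,
    linker: LinkerSpec = BS3_D0_D4,
    model: InstrumentModel | None = None,
    charge: int = 3,
    base_area: float = 1.0e5,
    rt_start: float = 300.0,
    rt_spacing: float = 60.0,
    rt_sigma: float = 4.0,
    rt_step: float = 1.0,
    d4_rt_shift: float = 0.0,
    n_decoys: int = 0,
    proton: float = PROTON_MONO,
) -> XlRun:
    """Simulate MS1 features, MS2 spectra and paired XICs for true links.

    Every true link yields a d0 and a d4 precursor separated by
    isotope_shift/z in m/z, co-eluting Gaussian chromatographic profiles
    whose areas stand in the link's light/heavy ratio, and one MS2 spectrum
    per isotope form containing every theoretical b/y fragment.  Decoy
    features (sequence-shuffled peptides, no doublet partner) are appended
    for FDR exercises and recorded in the manifest.
    """
    model = model or InstrumentModel()
    rng = np.random.default_rng(truth.seed)
    features: list[Ms1Feature] = []
    ms2: dict[str, MassSpectrum] = {}
    chromatograms: dict[tuple, tuple[Chromatogram, Chromatogram]] = {}
    manifest: dict = {"links": [], "decoys": [], "seed": truth.seed}

    offsets = np.arange(-4 * rt_sigma, 4 * rt_sigma + rt_step / 2, rt_step)
    shape = np.exp(-0.5 * (offsets / rt_sigma) ** 2)
    shape_area = np.trapezoid(shape, dx=rt_step)

    def add_profile(fid: str, mz: float, rt0: float, area: float) -> np.ndarray:
        amp = area / shape_area
        intens = amp * shape
        if model.noise_sd > 0:
            intens = intens * (
                1.0 + rng.normal(0.0, model.noise_sd, size=intens.shape)
            )
            intens = np.clip(intens, 0.0, None)
        for k, (dt, y) in enumerate(zip(offsets, intens)):
            features.append(Ms1Feature(f"{fid}_s{k}", mz, charge, rt0 + dt, y))
        return intens

    apex = len(offsets) // 2
    for i, (p1, r1, p2, r2, ratio) in enumerate(truth.links):
        pep1 = _link_peptide(sequences, p1, r1, linker)
        pep2 = _link_peptide(sequences, p2, r2, linker)
        mass_d0 = pep1.mass + pep2.mass + linker.mass_d0
        mz_d0 = (mass_d0 + charge * proton) / charge
        mz_d4 = mz_d0 + linker.isotope_shift / charge
        rt0 = rt_start + i * rt_spacing
        area_d0 = base_area
        area_d4 = base_area / ratio
        y0 = add_profile(f"L{i}_d0", mz_d0, rt0, area_d0)
        y4 = add_profile(f"L{i}_d4", mz_d4, rt0 + d4_rt_shift, area_d4)
        chromatograms[((p1, r1), (p2, r2))] = (
            Chromatogram(rt0 + offsets, y0),
            Chromatogram(rt0 + d4_rt_shift + offsets, y4),
        )
        for isotope, mz_prec in (("d0", mz_d0), ("d4", mz_d4)):
            cand = CrossLinkCandidate(
                pep1=pep1,
                pep2=pep2,
                link1=(p1, r1),
                link2=(p2, r2),
                isotope=isotope,
                mass=pep1.mass + pep2.mass + linker.mass(isotope),
            )
            frag_mz = sorted(mz for _, mz in theoretical_fragments(cand, linker))
            fid = f"L{i}_{isotope}_s{apex}"
            ms2[fid] = MassSpectrum(
                np.array(frag_mz),
                np.full(len(frag_mz), 100.0),
                spectrum_id=fid,
                ms_level=2,
                charge=charge,
                rt=rt0 + (d4_rt_shift if isotope == "d4" else 0.0),
            )
        manifest["links"].append(
            {
                "link": [p1, r1, p2, r2],
                "ratio": ratio,
                "peptides": [pep1.sequence, pep2.sequence],
                "mz_d0": mz_d0,
                "mz_d4": mz_d4,
                "z": charge,
                "rt": rt0,
                "area_d0": area_d0,
                "area_d4": area_d4,
            }
        )

    for j in range(n_decoys):
        p1, r1, p2, r2, _ = truth.links[int(rng.integers(len(truth.links)))]
        pep1 = _link_peptide(sequences, p1, r1, linker)
        pep2 = _link_peptide(sequences, p2, r2, linker)
        # shuffling preserves composition, hence the precursor mass
        shuf = lambda s: "".join(rng.permutation(list(s)))
        dseq1, dseq2 = shuf(pep1.sequence), shuf(pep2.sequence)
        mass_d0 = pep1.mass + pep2.mass + linker.mass_d0
        mz_d0 = (mass_d0 + charge * proton) / charge
        rt0 = rt_start + (len(truth.links) + j) * rt_spacing
        fid = f"D{j}_d0"
        features.append(Ms1Feature(f"{fid}_s{apex}", mz_d0, charge, rt0, base_area))
        dpep1 = Peptide(p1, dseq1, pep1.start, pep1.end, pep1.missed_cleavages, pep1.mass)
        dpep2 = Peptide(p2, dseq2, pep2.start, pep2.end, pep2.missed_cleavages, pep2.mass)
        k1 = dpep1.start + dseq1[:-1].index("K") if "K" in dseq1[:-1] else dpep1.start
        k2 = dpep2.start + dseq2[:-1].index("K") if "K" in dseq2[:-1] else dpep2.start
        dcand = CrossLinkCandidate(
            dpep1, dpep2, (p1, k1), (p2, k2), "d0", mass_d0
        )
        frag_mz = sorted(mz for _, mz in theoretical_fragments(dcand, linker))
        ms2[f"{fid}_s{apex}"] = MassSpectrum(
            np.array(frag_mz),
            np.full(len(frag_mz), 100.0),
            spectrum_id=f"{fid}_s{apex}",
            ms_level=2,
            charge=charge,
            rt=rt0,
        )
        manifest["decoys"].append(
            {"from_link": [p1, r1, p2, r2], "sequences": [dseq1, dseq2], "mz": mz_d0,
             "z": charge, "rt": rt0}
        )

    return XlRun(features, ms2, chromatograms, manifest)


# ---------------------------------------------------------------------------
# toy structures and sequences
# ---------------------------------------------------------------------------


def gen_toy_structure(
    n_residues: int,
    lysine_positions: Sequence[int],
    spacing: float = 3.8,
    chain_offsets: Sequence[tuple[float, float, float]] = ((0.0, 0.0, 0.0),),
    nz_offset: tuple[float, float, float] = (0.0, 1.5, 0.0),
) -> gemmi.Structure:
    """Build a toy structure with Calpha atoms on straight chains.

    Each chain holds ``n_residues`` residues with Calpha at
    offset + ((i-1)*spacing, 0, 0), so inter-residue distances are known in
    closed form.  Residues listed in ``lysine_positions`` become LYS and get
    an Nzeta atom displaced by ``nz_offset``; the rest are GLY.
    """
    for pos in lysine_positions:
        if pos < 1 or pos > n_residues:
            raise ValueError(f"lysine position {pos} out of range 1..{n_residues}")
    st = gemmi.Structure()
    st.name = "toy"
    mdl = gemmi.Model("1")
    for ci, (ox, oy, oz) in enumerate(chain_offsets):
        chain = gemmi.Chain(chr(ord("A") + ci))
        for i in range(1, n_residues + 1):
            res = gemmi.Residue()
            res.name = "LYS" if i in lysine_positions else "GLY"
            res.seqid = gemmi.SeqId(i, " ")
            ca = gemmi.Atom()
            ca.name = "CA"
            ca.element = gemmi.Element("C")
            ca.pos = gemmi.Position(ox + (i - 1) * spacing, oy, oz)
            res.add_atom(ca)
            if res.name == "LYS":
                nz = gemmi.Atom()
                nz.name = "NZ"
                nz.element = gemmi.Element("N")
                nz.pos = gemmi.Position(
                    ca.pos.x + nz_offset[0],
                    ca.pos.y + nz_offset[1],
                    ca.pos.z + nz_offset[2],
                )
                res.add_atom(nz)
            chain.add_residue(res)
        mdl.add_chain(chain)
    st.add_model(mdl)
    st.setup_entities()
    return st


_AA_POOL = "ADEFGHILNPQSTVWY"  # no K/R/C/M so placement below is explicit


def gen_protein_sequences(
    names: Sequence[str],
    length: int = 120,
    lysines: Mapping[str, Sequence[int]] | None = None,
    lysine_every: int = 12,
    seed: int = 0,
) -> dict[str, str]:
    """Random protein sequences with lysines at controlled positions.

    Lysines are placed either explicitly (``lysines[name]``, 1-based) or
    every ``lysine_every`` residues; an R is appended near the C-terminus so
    terminal peptides stay tryptic.  Positions 1 and ``length`` are never K,
    keeping every placed K an internal missed-cleavage site of some peptide.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for name in names:
        res = [
            _AA_POOL[i] for i in rng.integers(len(_AA_POOL), size=length)
        ]
        if lysines and name in lysines:
            positions = list(lysines[name])
        else:
            positions = list(range(lysine_every, length - 1, lysine_every))
        for pos in positions:
            if not 1 < pos < length:
                raise ValueError(f"lysine position {pos} out of 2..{length - 1}")
            res[pos - 1] = "K"
            if res[pos] == "P":  # keep every K a cleavage site
                res[pos] = "G"
        res[-1] = "R"
        out[name] = "".join(res)
    return out


def write_truth_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
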