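"""Structural validation of cross-links and lipid poses.

BS3 bridges two lysines whose Calpha atoms can be at most
spacer + 2 x side-chain reach apart (11.4 + 2*6.5 ~ 24.4 A); allowing for
conformational dynamics extends the acceptable distance to ~35 A.  This
module measures residue-residue distances in coordinate files, classifies
links against the (strict, dynamic) cutoff pair, screens docked lipid poses
against a distance restraint, and annotates links with phosphosite context.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import gemmi

from .constants import BS3_SPACER_A, LYSINE_SIDE_CHAIN_A

__all__ = [
    "DistanceRecord",
    "max_link_distance",
    "residue_distance",
    "classify_link",
    "map_links",
    "screen_poses",
    "annotate_phospho",
    "STRICT_CUTOFF_A",
    "DYNAMIC_CUTOFF_A",
]

STRICT_CUTOFF_A = BS3_SPACER_A + 2 * LYSINE_SIDE_CHAIN_A   # 24.4
DYNAMIC_CUTOFF_A = 35.0


def max_link_distance(spacer: float, side_chain: float) -> float:
    """Maximum Calpha-Calpha distance a cross-linker can bridge."""
    if spacer < 0 or side_chain < 0:
        raise ValueError("inputs must be >= 0")
    return spacer + 2 * side_chain


def _find_atom(
    structure: gemmi.Structure, chain: str, resnum: int, atom: str
) -> gemmi.Atom | None:
    for model in structure:
        ch = model.find_chain(chain)
        if ch is None:
            continue
        for res in ch:
            if res.seqid.num == resnum:
                a = res.find_atom(atom, "*")
                if a is not None:
                    return a
    return None


def residue_distance(
    structure: gemmi.Structure,
    a: tuple[str, int],
    b: tuple[str, int],
    atom_rule: str = "CA",
) -> tuple[float | None, str]:
    """Euclidean distance between two residues under an atom rule.

    Residues are addressed by (chain, author residue number).  With the
    'NZ' rule, an unresolved side chain falls back to Calpha with a note.
    Returns (distance, note); distance is None when a residue is absent
    from the coordinates (unresolved link).
    """
    if atom_rule not in ("CA", "NZ"):
        raise ValueError("atom_rule must be 'CA' or 'NZ'")
    notes = []
    atoms = []
    for chain, resnum in (a, b):
        atom = _find_atom(structure, chain, resnum, atom_rule)
        if atom is None and atom_rule == "NZ":
            atom = _find_atom(structure, chain, resnum, "CA")
            if atom is not None:
                notes.append(f"{chain}{resnum}: NZ unresolved, used CA")
        if atom is None:
            return None, f"{chain}{resnum}: residue not in coordinates"
        atoms.append(atom)
    return atoms[0].pos.dist(atoms[1].pos), "; ".join(notes)


def classify_link(
    distance: float | None,
    strict: float = STRICT_CUTOFF_A,
    dynamic: float = DYNAMIC_CUTOFF_A,
) -> str:
    """Classify a measured link distance against the cutoff pair."""
    if strict > dynamic:
        raise ValueError("need strict <= dynamic")
    if distance is None or (isinstance(distance, float) and math.isnan(distance)):
        return "unresolved"
    if distance <= strict:
        return "satisfied_strict"
    if distance <= dynamic:
        return "satisfied_dynamic"
    return "violated"


@dataclass
class DistanceRecord:
    key: tuple
    pair: tuple[tuple[str, int], tuple[str, int]]
    atom_rule: str
    distance: float | None
    link_class: str
    note: str = ""


def map_links(
    structure: gemmi.Structure,
    links: Sequence,
    chain_map: Mapping[str, str],
    atom_rule: str = "CA",
    strict: float = STRICT_CUTOFF_A,
    dynamic: float = DYNAMIC_CUTOFF_A,
) -> list[DistanceRecord]:
    """Measure and classify every link against one structure.

    ``links`` carry residue-pair keys ((protein, residue), (protein,
    residue)); ``chain_map`` translates protein names to chain ids.
    Proteins missing from the map give unresolved records.
    """
    records = []
    for link in links:
        key = link.key if hasattr(link, "key") else tuple(link)
        (pa, ra), (pb, rb) = key
        if pa not in chain_map or pb not in chain_map:
            records.append(
                DistanceRecord(key, key, atom_rule, None, "unresolved",
                               "protein not mapped to a chain")
            )
            continue
        pair = ((chain_map[pa], ra), (chain_map[pb], rb))
        dist, note = residue_distance(structure, *pair, atom_rule=atom_rule)
        records.append(
            DistanceRecord(key, pair, atom_rule, dist,
                           classify_link(dist, strict, dynamic), note)
        )
    return records


def screen_poses(
    poses: Sequence[tuple[str, gemmi.Structure]],
    donor: tuple[str, int, str],
    acceptor: tuple[str, int, str],
    cutoff: float = 5.0,
) -> list[tuple[str, float]]:
    """Keep poses whose donor-acceptor distance is below the restraint.

    ``donor`` and ``acceptor`` are (chain, residue number, atom name)
    selectors.  Poses where a selector does not resolve are excluded with a
    warning.  The result is sorted by ascending distance (best pose first),
    every entry strictly below ``cutoff``.
    """
    kept: list[tuple[str, float]] = []
    for pose_id, st in poses:
        da = _find_atom(st, *donor)
        aa = _find_atom(st, *acceptor)
        if da is None or aa is None:
            warnings.warn(f"pose {pose_id}: selector unresolved, excluded")
            continue
        d = da.pos.dist(aa.pos)
        if d < cutoff:
            kept.append((pose_id, d))
    kept.sort(key=lambda t: t[1])
    return kept


def annotate_phospho(
    links: Sequence,
    sites: Sequence[tuple[str, int]],
    structure: gemmi.Structure | None = None,
    chain_map: Mapping[str, str] | None = None,
    radius: float = 15.0,
    residue_extent: float = 3.8,
) -> list[tuple[tuple, bool]]:
    """Flag links with a linked residue within ``radius`` of a phosphosite.

    Distances are measured between Calpha atoms when both residues resolve
    in the structure; otherwise a sequence-distance fallback flags residues
    within radius / ``residue_extent`` positions on the same protein
    (an extended-chain upper bound of ~3.8 A per residue).
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    out = []
    max_seq_sep = radius / residue_extent
    for link in links:
        key = link.key if hasattr(link, "key") else tuple(link)
        flagged = False
        for protein, residue in key:
            for sprot, sres in sites:
                if sprot != protein and structure is None:
                    continue
                d = None
                if structure is not None and chain_map is not None:
                    if protein in chain_map and sprot in chain_map:
                        d, _ = residue_distance(
                            structure,
                            (chain_map[protein], residue),
                            (chain_map[sprot], sres),
                        )
                if d is not None:
                    flagged = d <= radius
                elif sprot == protein:
                    flagged = abs(residue - sres) <= max_seq_sep
                if flagged:
                    break
            if flagged:
                break
        out.append((key, flagged))
    return out
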