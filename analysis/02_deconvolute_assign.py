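#!/usr/bin/env python
"""Invert the simulated native spectra: masses, compositions, occupancy,
lipid stoichiometry, PTM mass shifts.

Reads the peak lists written by 01_simulate_native.py and writes
deconvolved masses, ranked subcomplex assignments, occupancy profiles and
the lipid-plug stoichiometry under results/native/.
"""

from pathlib import Path

import pandas as pd

from catpase_ms.native_ms import (
    DEFAULT_SUBUNIT_TABLE,
    assign_composition,
    call_occupancy,
    deconvolute,
    explain_mass_shift,
    lipid_stoichiometry,
)
from catpase_ms.spectra import read_peaklist

IN = Path(__file__).resolve().parents[1] / "scratch" / "sim" / "native"
OUT = Path(__file__).resolve().parents[1] / "results" / "native"

RING_MASS = 14 * 8_021.0   # III14 membrane ring
AVG_LIPID_MASS = 750.0
N_RING_SUBUNITS = 14

# plausibility rules for solution-phase complexes: the alpha3beta3 head is
# intact, the III ring is all-or-nothing with a stoichiometric lipid plug,
# and stators/IV attach only when the ring is present
RULES = [
    lambda c: c.get("alpha", 0) == 3 and c.get("beta", 0) == 3,
    lambda c: c.get("III", 0) in (0, 14),
    lambda c: c.get("lipid", 0) == c.get("III", 0),
    lambda c: c.get("I", 0) == 0 or c.get("III", 0) > 0,
    lambda c: c.get("II", 0) == 0 or c.get("III", 0) > 0,
    lambda c: c.get("IV", 0) == 0 or c.get("III", 0) > 0,
]


def deconvolve_file(name: str, smooth: float = 1.0, match_tol_ppm: float = 150.0):
    # the wide match tolerance absorbs noise-driven apex drift
    (spectrum,) = read_peaklist(IN / f"{name}.tsv")
    return deconvolute(spectrum, smooth_sigma=smooth, match_tol_ppm=match_tol_ppm)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    series = deconvolve_file("solution_mixture")
    rows = [
        {"species_rank": i + 1, "mass_da": s.mass, "mass_sd_da": s.mass_sd,
         "n_peaks": len(s.peaks), "z_min": s.charges[0], "z_max": s.charges[-1],
         "abundance": s.abundance}
        for i, s in enumerate(series)
    ]
    pd.DataFrame(rows).to_csv(OUT / "deconvolved_masses.csv", index=False)
    masses = sorted((s.mass for s in series), reverse=True)
    print("solution mixture deconvolves to:",
          ", ".join(f"{m/1000:.0f} kDa" for m in masses))

    # the species that survives incubation minus the one that disassembles
    after = sorted((s.mass for s in deconvolve_file("after_37C")), reverse=True)
    lost_ring_plug = masses[1] - after[-1]
    plug = lost_ring_plug - RING_MASS
    per_subunit, nearest, resid = lipid_stoichiometry(
        plug, N_RING_SUBUNITS, AVG_LIPID_MASS
    )
    print(f"523-400 kDa difference: {lost_ring_plug/1000:.1f} kDa; "
          f"after subtracting the {RING_MASS/1000:.1f} kDa ring the lipid plug "
          f"is {plug/1000:.2f} kDa -> {per_subunit:.2f} lipids per ring subunit "
          f"(nearest integer {nearest}:1)")

    assign_rows = []
    for s in series:
        assignments = assign_composition(
            s.mass, DEFAULT_SUBUNIT_TABLE, constraints=RULES,
            lipid_bounds=(0, 20), nucleotide_bounds=(0, 0),
        )
        for a in assignments[:5]:
            assign_rows.append({
                "observed_da": round(s.mass, 1),
                "rank": a.rank,
                "composition": " ".join(f"{k}{v}" for k, v in
                                        sorted(a.composition.items())),
                "lipids": a.lipids,
                "theoretical_da": round(a.theoretical_mass, 1),
                "error_da": round(a.error_da, 1),
            })
        best = assignments[0]
        print(f"  {s.mass/1000:7.1f} kDa -> "
              + " ".join(f"{k}{v}" for k, v in sorted(best.composition.items()))
              + f" +{best.lipids} lipids (err {best.error_da:+.0f} Da)")
    pd.DataFrame(assign_rows).to_csv(OUT / "assignments.csv", index=False)

    occ_rows = []
    apo_mass = deconvolve_file("apo_f1")[0].mass
    for name in ("untreated_atp", "untreated_gs_atp", "dephos_atp",
                 "dephos_gs_atp", "excess_atp"):
        nuc = 523.3 if "gs" in name else 507.2
        ss = deconvolve_file(name)
        profile = call_occupancy([(s.mass, s.abundance) for s in ss], nuc,
                                 apo_mass=apo_mass)
        occ_rows.append({"condition": name, "max_occupancy": profile.max_occupancy,
                         "ratio": profile.ratio,
                         "occupancies": [k for k, _ in profile.occupancies]})
        print(f"{name}: occupancies {[k for k, _ in profile.occupancies]} "
              f"ratio {profile.ratio} (max {profile.max_occupancy})")
    pd.DataFrame(occ_rows).to_csv(OUT / "occupancy.csv", index=False)

    # intact-subunit mass shifts explained as PTM combinations
    ptm_rows = []
    for subunit, delta in (("alpha", -89.03), ("beta", 0.00), ("III", 31.99)):
        combos = explain_mass_shift(delta, tolerance=0.05)
        top = combos[0][0] if combos else None
        ptm_rows.append({"subunit": subunit, "delta_da": delta,
                         "explanation": top, "n_explanations": len(combos)})
        print(f"{subunit}: {delta:+.2f} Da -> {top}")
    pd.DataFrame(ptm_rows).to_csv(OUT / "ptm_shifts.csv", index=False)


if __name__ == "__main__":
    main()
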