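#!/usr/bin/env python
"""Simulate the native-MS experiments: intact-complex envelopes and
nucleotide-occupancy splitting.

Writes peak-list TSVs plus a ground-truth manifest under scratch/sim/native/
(raw simulated spectra are bulky and regenerable, so they stay out of the
curated results/ tables).
The simulated conditions: a solution mixture of the 538/523/400 kDa
complexes; the post-incubation state in which the 523 kDa species has
disassembled; an apo F1 head; and the nucleotide-binding preparations
(untreated ATP and gamma-S-ATP preps, their dephosphorylated forms, and a
tenfold ATP excess).
"""

import json
from pathlib import Path

from catpase_ms.spectra import write_peaklist
from catpase_ms.synthetic_data import (
    GroundTruth,
    InstrumentModel,
    gen_native_spectrum,
    gen_occupancy_spectrum,
)

OUT = Path(__file__).resolve().parents[1] / "scratch" / "sim" / "native"

SEED = 20260927
ATP = 507.2
ATP_GAMMA_S = 523.3

# species masses derived from the subunit table so that composition
# assignment can be checked against a known ground truth
from catpase_ms.native_ms import DEFAULT_SUBUNIT_TABLE

_m = {e.name: e.mass for e in DEFAULT_SUBUNIT_TABLE.entries}
F1_MASS = 3 * _m["alpha"] + 3 * _m["beta"] + _m["gamma"] + _m["delta"] + _m["epsilon"]
RING_PLUG_MASS = 14 * _m["III"] + 14 * DEFAULT_SUBUNIT_TABLE.lipid_mass
WITH_RING_MASS = F1_MASS + RING_PLUG_MASS                      # ~522 kDa
WITH_STATORS_MASS = WITH_RING_MASS - _m["delta"] + _m["I"] + _m["II"]  # ~539 kDa

# occupancy weights per condition: index k = number of bound nucleotides
OCCUPANCY_CONDITIONS = {
    "apo_f1": (ATP, [1.0]),
    "untreated_atp": (ATP, [0, 0, 1, 1]),          # 2- and 3-bound at 1:1
    "untreated_gs_atp": (ATP_GAMMA_S, [0, 0, 1, 2]),
    "dephos_atp": (ATP, [1, 2, 4, 5]),
    "dephos_gs_atp": (ATP_GAMMA_S, [2, 4, 5, 4]),
    "excess_atp": (ATP, [0, 0, 1, 2]),             # pushed toward 3-bound
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    envelope_model = InstrumentModel(resolution=1000, charge_range=(35, 55),
                                     noise_sd=0.005)
    # peak resolution improves for the bare F1 head, resolving nucleotides
    split_model = InstrumentModel(resolution=5000, charge_range=(35, 55),
                                  noise_sd=0.005)

    manifest = {"seed": SEED, "spectra": {}}
    solution = GroundTruth(
        species=[
            ("head_base_stators", WITH_STATORS_MASS, 0.6),
            ("head_ring_plug", WITH_RING_MASS, 1.0),
            ("F1", F1_MASS, 0.8),
        ],
        seed=SEED,
    )
    after_37c = GroundTruth(
        species=[("head_base_stators", WITH_STATORS_MASS, 0.6), ("F1", F1_MASS, 1.0)],
        seed=SEED + 1,
    )
    for name, truth in (("solution_mixture", solution), ("after_37C", after_37c)):
        sp = gen_native_spectrum(truth, envelope_model)
        sp.spectrum_id = name
        write_peaklist([sp], OUT / f"{name}.tsv")
        manifest["spectra"][name] = {
            "species": truth.species,
            "resolution": envelope_model.resolution,
        }
        print(f"{name}: {len(truth.species)} species, {len(sp)} grid points")

    for i, (name, (nuc, weights)) in enumerate(OCCUPANCY_CONDITIONS.items()):
        sp = gen_occupancy_spectrum(F1_MASS, nuc, weights, split_model,
                                    seed=SEED + 10 + i)
        sp.spectrum_id = name
        write_peaklist([sp], OUT / f"{name}.tsv")
        manifest["spectra"][name] = {
            "base_mass": F1_MASS,
            "nucleotide_mass": nuc,
            "weights": weights,
            "resolution": split_model.resolution,
        }
        print(f"{name}: weights {weights} at nucleotide {nuc} Da")

    (OUT / "truth.json").write_text(json.dumps(manifest, indent=1))
    print(f"wrote {len(manifest['spectra'])} spectra to {OUT}")


if __name__ == "__main__":
    main()
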