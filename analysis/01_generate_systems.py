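#!/usr/bin/env python
"""Generate every synthetic input system used by the downstream drivers.

Writes to results/systems:
  trilayer.gro / trilayer.xtc   PL-bounded smectic trilayer trajectory
  trilayer.truth.json           planted observables implied by the generator spec
  defects_<i>.gro / .truth.tsv  single leaflets with planted defect patches
  pes_scan.txt / pes.truth.json synthetic dihedral potential-energy scan
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
from common import SEED, SYSTEMS, write_json, write_tsv

from ldtk import (
    SyntheticSpec,
    generate_defect_leaflet,
    generate_trilayer_trajectory,
    sample_defect_sizes,
    synthetic_pes,
    trilayer_ground_truth,
    write_gro,
    write_scan,
    write_xtc,
)

N_FRAMES = 12
DEFECT_PI = 15.0  # Å², planted size constant of the defect leaflets
DEFECT_LEAFLETS = 6
PATCHES_PER_TYPE = 25
DEFECT_TYPES = ("PL_ACYL", "TG_ACYL", "CHYO_SIDE")
PES_TRUTH = [(1, 1.2, 0.0), (2, 0.4, 180.0), (3, 2.1, 0.0)]


def main() -> None:
    SYSTEMS.mkdir(parents=True, exist_ok=True)

    spec = SyntheticSpec(seed=SEED, surf_tg_fraction=0.125)
    system, frames = generate_trilayer_trajectory(spec, n_frames=N_FRAMES, dt=1.0)
    write_gro(SYSTEMS / "trilayer.gro", system, frames[0])
    write_xtc(SYSTEMS / "trilayer.xtc", system, frames)
    print(f"wrote trilayer ({system.n_atoms} atoms, {len(frames)} frames)")
    write_json(SYSTEMS / "trilayer.truth.json", trilayer_ground_truth(spec))

    size_cap = int(round(8.0 * 10)) - 2
    for i in range(DEFECT_LEAFLETS):
        entries = []
        for t, dtype in enumerate(DEFECT_TYPES):
            sizes = sample_defect_sizes(DEFECT_PI, PATCHES_PER_TYPE,
                                        seed=SEED * 1000 + i * 10 + t)
            entries += [("TOP", dtype, int(s), 1)
                        for s in np.clip(sizes, 1, size_cap)]
        dspec = SyntheticSpec(seed=SEED + 500 + i, box=(8.0, 8.0, 5.0),
                              n_layers=1, core_half_thickness=1.0,
                              n_pl_per_leaflet=20, water_density_core=0.0,
                              water_density_slab=0.0, planted_defects=entries)
        dsys, dframe, truth = generate_defect_leaflet(dspec)
        write_gro(SYSTEMS / f"defects_{i}.gro", dsys, dframe)
        write_tsv(SYSTEMS / f"defects_{i}.truth.tsv",
                  ["defect_type", "size_A2"], [list(t) for t in truth])

    scan = synthetic_pes(PES_TRUTH, np.linspace(-180.0, 180.0, 24, endpoint=False))
    write_scan(SYSTEMS / "pes_scan.txt", scan)
    write_json(SYSTEMS / "pes.truth.json",
               {"terms": [{"multiplicity": n, "k": k, "phase": d}
                          for n, k, d in PES_TRUTH]})


if __name__ == "__main__":
    main()
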