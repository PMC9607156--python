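#!/usr/bin/env python
"""Fit periodic dihedral force constants to the synthetic scan.

Reads results/systems/pes_scan.txt (+ pes.truth.json); writes to
results/dihedrals:
  dihedral_fit.json fitted terms, RMSE, and planted-vs-fitted deltas
  charmm_block.txt  CHARMM-style parameter lines
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import SYSTEMS, outdir, write_json

from ldtk import format_charmm_block, mcsa_fit, read_scan

SEED = 0


def main() -> None:
    out = outdir("dihedrals")
    scan = read_scan(SYSTEMS / "pes_scan.txt")
    truth = json.loads((SYSTEMS / "pes.truth.json").read_text())["terms"]

    model, rmse = mcsa_fit(scan, multiplicities=[1, 2, 3, 6], seed=SEED)
    deltas = {t["multiplicity"]: model.k_of(t["multiplicity"]) - t["k"]
              for t in truth}
    write_json(out / "dihedral_fit.json", {
        "terms": [{"multiplicity": t.multiplicity, "k_kcal_mol": t.k,
                   "phase_deg": t.phase} for t in model.terms],
        "rmse_kcal_mol": rmse,
        "delta_k_vs_planted": deltas,
    })
    block = format_charmm_block(model, ("CTL2", "CTL2", "CTL2", "CTL3"))
    (out / "charmm_block.txt").write_text(block + "\n")
    print(block)
    print(f"RMSE = {rmse:.4f} kcal/mol; "
          f"max |delta k| = {max(abs(d) for d in deltas.values()):.4f}")


if __name__ == "__main__":
    main()
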