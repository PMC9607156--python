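#!/usr/bin/env python
"""Monolayer surface composition and area per lipid.

Reads results/systems/trilayer.{gro,xtc}; writes to results/surface:
  surface.json  residence-filtered SURF composition and APL per leaflet
  apl_series.tsv per-frame area per lipid (both denominators, TOP leaflet)
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import load_trilayer, outdir, write_json, write_tsv

from ldtk import Leaflet, apl, classify, monolayer_composition, residence_filter

EQUILIBRATION = 0.5
RESIDENCE_MIN = 5.0  # ns


def main() -> None:
    out = outdir("surface")
    system, frames = load_trilayer()
    labels = residence_filter(classify(system, frames), RESIDENCE_MIN)

    report = {}
    for lf in (Leaflet.TOP, Leaflet.BOTTOM):
        comp = monolayer_composition(labels, system, lf,
                                     equilibration=EQUILIBRATION)
        a = apl(system, frames, lf, "PL_ONLY", equilibration=EQUILIBRATION)
        report[lf.value] = {**comp, "apl_pl_only_nm2": a.mean,
                            "apl_pl_only_sd": a.sd}
    write_json(out / "surface.json", report)

    a_pl = apl(system, frames, Leaflet.TOP, "PL_ONLY", equilibration=0.0)
    a_ps = apl(system, frames, Leaflet.TOP, "PL_PLUS_SURF", labels=labels,
               equilibration=0.0)
    write_tsv(out / "apl_series.tsv",
              ["time_ns", "apl_pl_only_nm2", "apl_pl_plus_surf_nm2"],
              [[f"{fr.time:.2f}", f"{x:.5f}", f"{y:.5f}"]
               for fr, x, y in zip(frames, a_pl.values, a_ps.values)])
    top = report["TOP"]
    print(f"TOP: SURF fraction {top['fraction']:.4f}, "
          f"APL {top['apl_pl_only_nm2']:.3f} nm²")


if __name__ == "__main__":
    main()
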