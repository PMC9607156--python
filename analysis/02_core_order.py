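#!/usr/bin/env python
"""Orientational and positional order of the neutral-lipid core.

Reads results/systems/trilayer.{gro,xtc}; writes to results/order:
  order.json        S, layer spacing, per-layer up/down fractions
  ester_profile.tsv ester-oxygen number-density profile along z
  tail_scd.tsv      per-carbon acyl order parameter of the PL tails
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import load_trilayer, outdir, write_json, write_tsv

from ldtk import (
    MoleculeClass,
    Role,
    assign_layers,
    layer_spacing,
    molecular_axes,
    nematic_order,
    number_density_profile,
    tail_order,
    updown_fractions,
)


def main() -> None:
    out = outdir("order")
    system, frames = load_trilayer()

    axes = molecular_axes(system, frames, MoleculeClass.CHYO)
    order = nematic_order(axes, director="auto", window_fraction=0.5)
    ester = number_density_profile(system, frames, Role.ESTER_O,
                                   MoleculeClass.CHYO, 0.1)
    spacing, spacing_sd, peaks = layer_spacing(ester)
    layers = assign_layers(system, frames[-1], peaks)
    ud = updown_fractions(axes.vectors[-1], layers)

    write_json(out / "order.json", {
        "S": order.S,
        "S_converged_sd": order.converged_sd,
        "director": list(order.director),
        "layer_spacing_nm": spacing,
        "layer_spacing_sd_nm": spacing_sd,
        "layer_positions_nm": list(peaks),
        "updown_by_layer": {int(k): {"up": v[0], "down": v[1]}
                            for k, v in ud.items()},
    })
    write_tsv(out / "ester_profile.tsv", ["z_nm", "number_density_nm3"],
              [[f"{z:.4f}", f"{v:.6g}"]
               for z, v in zip(ester.centers, ester.values)])
    scd = tail_order(system, frames)
    write_tsv(out / "tail_scd.tsv", ["carbon_index", "S_CD"],
              [[i + 1, f"{s:.6f}"] for i, s in enumerate(scd)])
    print(f"S = {order.S:.3f}, layer spacing = {spacing:.3f} ± {spacing_sd:.3f} nm")


if __name__ == "__main__":
    main()
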