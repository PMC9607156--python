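"""Shared paths and small I/O helpers for the numbered analysis drivers.

Every driver reads the synthetic systems written by ``01_generate_systems.py``
from ``results/systems`` and writes its own outputs under ``results/``.
Generated trajectories and coordinate files are reproducible from the seed,
so ``results/`` is disposable and not version-controlled.
"""

from __future__ import annotations

import json
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SYSTEMS = RESULTS / "systems"

SEED = 0


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d


def write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, default=float) + "\n")
    print(f"wrote {path.relative_to(ROOT)}")


def write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    lines = ["\t".join(header)]
    lines += ["\t".join(str(v) for v in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    print(f"wrote {path.relative_to(ROOT)}")


def load_trilayer():
    """System + frames of the trilayer written by driver 01."""
    from ldtk import assign_leaflets, load_system, read_trajectory

    system = load_system(SYSTEMS / "trilayer.gro", "synthetic")
    frames = read_trajectory(SYSTEMS / "trilayer.xtc", system)
    return assign_leaflets(system, frames[0]), frames
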