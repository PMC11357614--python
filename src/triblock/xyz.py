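"""Minimal extended-XYZ trajectory I/O.

Frames are written with an orthorhombic ``Lattice`` entry, a ``Properties``
descriptor and a ``Time`` tag in the comment line, and one row per bead::

    <n_beads>
    Lattice="L 0 0 0 L 0 0 0 L" Properties=species:S:1:pos:R:3:chain:I:1 Time=12.5
    B 1.234 5.678 9.012 0
    ...

Species ``A``/``B`` map to the package's bead-type codes; the integer column
is the chain index.  The body of each frame is also valid plain XYZ, so
generic readers (e.g. MDAnalysis) can consume the coordinates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .forcefield import BEAD_A, BEAD_B

__all__ = ["XYZFrame", "write_extxyz", "read_extxyz"]

_SPECIES = {BEAD_A: "A", BEAD_B: "B"}
_CODES = {"A": BEAD_A, "B": BEAD_B}


@dataclass
class XYZFrame:
    """One trajectory frame: wrapped positions, cubic box edge, time stamp."""

    positions: np.ndarray  # (N, 3)
    box_edge: float
    time: float
    bead_type: np.ndarray  # (N,) uint8
    chain_index: np.ndarray  # (N,) int


def write_extxyz(path, frames, mode: str = "w") -> None:
    """Write frames (an iterable of :class:`XYZFrame`) to ``path``."""
    path = Path(path)
    with path.open(mode) as fh:
        for fr in frames:
            n = len(fr.positions)
            L = fr.box_edge
            fh.write(f"{n}\n")
            fh.write(
                f'Lattice="{L:.10g} 0 0 0 {L:.10g} 0 0 0 {L:.10g}" '
                f"Properties=species:S:1:pos:R:3:chain:I:1 Time={fr.time:.10g}\n"
            )
            for p, t, c in zip(fr.positions, fr.bead_type, fr.chain_index):
                fh.write(
                    f"{_SPECIES[int(t)]} {p[0]:.10g} {p[1]:.10g} {p[2]:.10g} {int(c)}\n"
                )


def read_extxyz(path) -> list[XYZFrame]:
    """Read all frames from an extended-XYZ file written by this package."""
    frames: list[XYZFrame] = []
    with Path(path).open() as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1]
        m = re.search(r'Lattice="([^"]+)"', comment)
        if m is None:
            raise ValueError(f"frame at line {i + 1}: missing Lattice entry")
        lat = np.fromstring(m.group(1), sep=" ")
        box_edge = float(lat[0])
        mt = re.search(r"Time=([0-9eE+.\-]+)", comment)
        time = float(mt.group(1)) if mt else 0.0
        pos = np.empty((n, 3))
        types = np.empty(n, dtype=np.uint8)
        chains = np.empty(n, dtype=np.int64)
        for j in range(n):
            parts = lines[i + 2 + j].split()
            types[j] = _CODES[parts[0]]
            pos[j] = [float(x) for x in parts[1:4]]
            chains[j] = int(parts[4]) if len(parts) > 4 else 0
        frames.append(
            XYZFrame(positions=pos, box_edge=box_edge, time=time, bead_type=types, chain_index=chains)
        )
        i += 2 + n
    return frames
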