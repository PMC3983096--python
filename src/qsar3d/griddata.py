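"""Plain-text OpenDX scalar-grid reading and writing.

The OpenDX format stores a regular lattice (counts, origin, per-axis
deltas) followed by the scalar values in z-fastest order — the same
ordering :meth:`qsar3d.fields.GridSpec.points` uses, so field and contour
grids round-trip without reshuffling.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .fields import FieldGrid, GridSpec

__all__ = ["write_dx", "read_dx"]


def write_dx(grid: FieldGrid, path: str | Path, name: str | None = None) -> None:
    spec = grid.spec
    nx, ny, nz = spec.dims
    lines = [
        f"# qsar3d field grid: {grid.kind}",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        "origin {:.6f} {:.6f} {:.6f}".format(*spec.origin),
        f"delta {spec.spacing:.6f} 0.000000 0.000000",
        f"delta 0.000000 {spec.spacing:.6f} 0.000000",
        f"delta 0.000000 0.000000 {spec.spacing:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {spec.n_points} data follows",
    ]
    vals = grid.values
    for i in range(0, len(vals), 3):
        lines.append(" ".join(f"{v:.10e}" for v in vals[i:i + 3]))
    lines += [
        'attribute "dep" string "positions"',
        f'object "{name or grid.kind}" class field',
        'component "positions" value 1',
        'component "connections" value 2',
        'component "data" value 3',
        "",
    ]
    Path(path).write_text("\n".join(lines))


def read_dx(path: str | Path) -> FieldGrid:
    dims = origin = None
    deltas: list[list[float]] = []
    values: list[float] = []
    n_items = None
    kind = "unknown"
    reading = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "field grid:" in line:
                kind = line.split("field grid:")[1].strip()
            continue
        if reading and n_items is not None and len(values) < n_items:
            values.extend(float(v) for v in line.split())
            continue
        if line.startswith("object 1"):
            dims = tuple(int(x) for x in line.split()[-3:])
        elif line.startswith("origin"):
            origin = tuple(float(x) for x in line.split()[1:4])
        elif line.startswith("delta"):
            deltas.append([float(x) for x in line.split()[1:4]])
        elif "data follows" in line:
            n_items = int(line.split("items")[1].split()[0])
            reading = True
    if dims is None or origin is None or len(deltas) != 3 or n_items is None:
        raise ValueError(f"{path}: not a recognisable OpenDX scalar grid")
    spacings = {deltas[0][0], deltas[1][1], deltas[2][2]}
    if len(spacings) != 1:
        raise ValueError(f"{path}: anisotropic grids not supported")
    spec = GridSpec(origin=origin, spacing=spacings.pop(), dims=dims)
    if len(values) != spec.n_points:
        raise ValueError(f"{path}: expected {spec.n_points} values, got {len(values)}")
    return FieldGrid(spec=spec, kind=kind, values=np.array(values))
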