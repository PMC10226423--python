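"""Outlier gates in the (pseudo-bulk, bulk) expression plane.

A gate is a named simple polygon in (x, y) space; the three canonical gates
select genes under-detected in scRNA-seq (upper_left: low x, high y), highly
expressed in both modalities (upper_right), and over-detected in scRNA-seq
(bottom: high x, near-zero y).  Gates can be loaded from JSON or derived
deterministically from the dot cloud's quantiles, shrunk away from
high-density histogram cells so they select genuine outliers.

Containment is boundary-inclusive so membership is stable under float
round-trips through TSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

__all__ = [
    "GateSpec",
    "RecurrenceTable",
    "density_grid",
    "point_in_gate",
    "auto_gates",
    "load_gates",
    "save_gates",
    "recurrence",
    "recurrent_genes",
    "top_frequent",
]


@dataclass(eq=False)
class GateSpec:
    """A named simple polygon; vertices are (x, y) in dot coordinates."""

    name: str
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self):
        self.vertices = tuple((float(x), float(y)) for x, y in self.vertices)
        if len(self.vertices) < 3:
            raise ValueError(f"gate {self.name!r}: need >= 3 vertices")
        poly = shapely.Polygon(self.vertices)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(f"gate {self.name!r}: polygon is degenerate or self-intersecting")
        self._poly = poly
        shapely.prepare(self._poly)

    def contains(self, x, y) -> np.ndarray:
        """Boundary-inclusive containment for arrays of coordinates."""
        return shapely.intersects_xy(self._poly, np.asarray(x, float), np.asarray(y, float))


def point_in_gate(point, gate: GateSpec) -> bool:
    """Boundary-inclusive test for a single (x, y) point."""
    x, y = point
    return bool(gate.contains(np.array([x]), np.array([y]))[0])


def density_grid(dots: pd.DataFrame, nx: int = 60, ny: int = 60):
    """2D histogram of the dot cloud; returns (counts, x_edges, y_edges)."""
    if nx < 2 or ny < 2:
        raise ValueError("nx and ny must be >= 2")
    if len(dots) == 0:
        raise ValueError("empty dot table")
    H, xe, ye = np.histogram2d(dots["x"], dots["y"], bins=(nx, ny))
    return H, xe, ye


@dataclass(frozen=True)
class GateParams:
    """Quantile thresholds of the automatic gates.

    The gates are axis-aligned rectangles at quantiles of the pooled dot
    cloud, then shrunk away from histogram cells whose count exceeds the
    ``density_clip`` quantile of occupied cells, so no gate overlaps the
    dense central mass.  upper_left uses the x-quantile of dots with y > 0
    (zero-bulk dots carry no under-detection signal).
    """

    upper_left_x_q: float = 0.08
    upper_left_y_q: float = 0.40
    upper_right_x_q: float = 0.97
    upper_right_y_q: float = 0.97
    bottom_x_q: float = 0.60
    bottom_y_q: float = 0.02
    grid: int = 60
    density_clip: float = 0.99
    pad: float = 1e-6


def _rect(name, x_lo, x_hi, y_lo, y_hi) -> GateSpec:
    return GateSpec(name, ((x_lo, y_lo), (x_hi, y_lo), (x_hi, y_hi), (x_lo, y_hi)))


def auto_gates(dots: pd.DataFrame, params: GateParams = GateParams()) -> list[GateSpec]:
    """Derive the three gates deterministically from the dot cloud."""
    x = dots["x"].to_numpy()
    y = dots["y"].to_numpy()
    pad = params.pad
    x_min, x_max = x.min() - pad, x.max() + pad
    y_min, y_max = y.min() - pad, y.max() + pad
    pos = y > 0
    ul_x = float(np.quantile(x[pos] if pos.any() else x, params.upper_left_x_q))
    ul_y = float(np.quantile(y, params.upper_left_y_q))
    ur_x = float(np.quantile(x, params.upper_right_x_q))
    ur_y = float(np.quantile(y, params.upper_right_y_q))
    bo_x = float(np.quantile(x, params.bottom_x_q))
    bo_y = float(np.quantile(y, params.bottom_y_q))

    H, xe, ye = density_grid(dots, params.grid, params.grid)
    occupied = H[H > 0]
    thresh = np.quantile(occupied, params.density_clip)
    hot = H > thresh
    hx, hy = np.nonzero(hot)
    cx = (xe[hx] + xe[hx + 1]) / 2
    cy = (ye[hy] + ye[hy + 1]) / 2

    # shrink each rectangle until it excludes all hot cell centers
    def clip(x_lo, x_hi, y_lo, y_hi, direction):
        inside = (cx >= x_lo) & (cx <= x_hi) & (cy >= y_lo) & (cy <= y_hi)
        while inside.any():
            if direction == "upper_left":      # retreat the right edge leftward
                x_hi = cx[inside].min() - (xe[1] - xe[0]) / 2
            elif direction == "upper_right":   # retreat the left edge rightward
                x_lo = cx[inside].max() + (xe[1] - xe[0]) / 2
            else:                               # bottom: retreat the top edge down
                y_hi = cy[inside].min() - (ye[1] - ye[0]) / 2
            inside = (cx >= x_lo) & (cx <= x_hi) & (cy >= y_lo) & (cy <= y_hi)
        return x_lo, x_hi, y_lo, y_hi

    gates = []
    for name, rect in (
        ("upper_left", clip(x_min, ul_x, ul_y, y_max, "upper_left")),
        ("upper_right", clip(ur_x, x_max, ur_y, y_max, "upper_right")),
        ("bottom", clip(bo_x, x_max, y_min, bo_y, "bottom")),
    ):
        x_lo, x_hi, y_lo, y_hi = rect
        if x_hi <= x_lo or y_hi <= y_lo:
            raise ValueError(f"gate {name!r} collapsed during density clipping")
        gates.append(_rect(name, x_lo, x_hi, y_lo, y_hi))
    return gates


def save_gates(gates: list[GateSpec], path):
    payload = [{"name": g.name, "vertices": list(map(list, g.vertices))} for g in gates]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_gates(path) -> list[GateSpec]:
    payload = json.loads(Path(path).read_text())
    gates = [GateSpec(d["name"], tuple(map(tuple, d["vertices"]))) for d in payload]
    names = [g.name for g in gates]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate gate names in {path}")
    return gates


@dataclass
class RecurrenceTable:
    """Per-gate recurrence: gene -> number of sample pairs inside the gate."""

    gate: str
    counts: pd.Series  # only genes with count >= 1
    total_dots: int

    def __post_init__(self):
        self.counts = self.counts[self.counts > 0].astype(int)
        assert int(self.counts.sum()) == self.total_dots


def recurrence(dots: pd.DataFrame, gate: GateSpec) -> RecurrenceTable:
    """Count, per gene, the sample pairs whose dot falls inside the gate."""
    inside = gate.contains(dots["x"].to_numpy(), dots["y"].to_numpy())
    counts = (
        dots.loc[inside].groupby("gene_id", sort=True).size()
        if inside.any()
        else pd.Series(dtype=int)
    )
    return RecurrenceTable(gate=gate.name, counts=counts, total_dots=int(inside.sum()))


def recurrent_genes(table: RecurrenceTable, min_count: int = 2) -> set[str]:
    """Genes inside the gate in at least ``min_count`` sample pairs."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return set(table.counts.index[table.counts >= min_count])


def top_frequent(table: RecurrenceTable, k: int = 15) -> list[tuple[str, int]]:
    """Top-k genes by recurrence count; ties break lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    items = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(g, int(c)) for g, c in items[:k]]
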