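"""SWC neuron reconstructions and branch/bifurcation-level morphometrics.

Nine features are computed separately for the basal (SWC type 3) and apical
(type 4) dendritic arbors of a reconstruction:

==============  =============  =====================================================
feature         units          definition
==============  =============  =====================================================
distance        micrometers    along-tree path length from the arbor's insertion
                               point at the soma to a bifurcation, averaged over
                               bifurcations
length          micrometers    sum of compartment lengths of a branch, averaged
                               over branches
tortuosity      dimensionless  branch length / chord between branch endpoints,
                               averaged over branches (>= 1)
angle           radians        shortest planar angle at a bifurcation between the
                               vectors to the daughter branches' end nodes,
                               averaged over bifurcations
diameter        micrometers    compartment-length-weighted mean diameter
                               (2 x radius) of a branch, averaged over branches
height/width/   micrometers    max - min of arbor node Y / X / Z coordinates
depth
total_length    micrometers    sum of all branch lengths
==============  =============  =====================================================

Branches run between topological events (soma insertion, bifurcation,
terminal) and partition the arbor's compartments; soma-attached segments are
excluded, so branch geometry starts at the first dendritic node.  Features
whose averaging population is empty (no bifurcation, missing arbor) are NaN,
and cells with NaN in an analyzed column are dropped downstream.  Apical
features carry an ``a.`` column prefix; the externally supplied normalized
cortical depth of the soma (``rel_depth``: 0 at the pia, 1 at the white
matter) is passed through unchanged.

Coordinates are taken as micrometers in the reconstruction frame: extents
are axis-dependent, every length feature scales linearly under uniform
scaling, and all features are translation-invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

SOMA, AXON, BASAL, APICAL = 1, 2, 3, 4
_ARBOR_CODES = {"basal": BASAL, "apical": APICAL}


class SwcParseError(ValueError):
    pass


class SwcNode(NamedTuple):
    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


class NeuronReconstruction:
    """A validated SWC tree (parents precede children; roots have parent -1)."""

    def __init__(self, nodes: Iterable[SwcNode]):
        self.nodes: list[SwcNode] = [SwcNode(*n) for n in nodes]
        if not self.nodes:
            raise SwcParseError("empty reconstruction")
        self._by_id: dict[int, SwcNode] = {}
        self._children: dict[int, list[SwcNode]] = {}
        for line_no, n in enumerate(self.nodes, start=1):
            if n.id <= 0:
                raise SwcParseError(f"node {line_no}: non-positive id {n.id}")
            if n.id in self._by_id:
                raise SwcParseError(f"node {line_no}: duplicate id {n.id}")
            if n.parent_id != -1:
                if n.parent_id not in self._by_id:
                    raise SwcParseError(
                        f"node {line_no}: parent {n.parent_id} missing or not yet defined"
                    )
                self._children.setdefault(n.parent_id, []).append(n)
            self._by_id[n.id] = n
        if not any(n.parent_id == -1 for n in self.nodes):
            raise SwcParseError("no root node (parent_id -1)")

    def node(self, node_id: int) -> SwcNode:
        return self._by_id[node_id]

    def children(self, node_id: int) -> list[SwcNode]:
        return self._children.get(node_id, [])

    def arbor_nodes(self, arbor_class: str) -> list[SwcNode]:
        code = _arbor_code(arbor_class)
        return [n for n in self.nodes if n.type_code == code]

    def to_swc_text(self) -> str:
        lines = ["# id type x y z radius parent"]
        for n in self.nodes:
            # shortest exact float repr so that write -> read round-trips
            lines.append(
                f"{n.id} {n.type_code} {n.x!r} {n.y!r} {n.z!r} {n.radius!r} {n.parent_id}"
            )
        return "\n".join(lines) + "\n"


def _arbor_code(arbor_class: str) -> int:
    try:
        return _ARBOR_CODES[arbor_class]
    except KeyError:
        raise ValueError(f"arbor_class must be 'basal' or 'apical', got {arbor_class!r}")


def parse_swc(text: str) -> NeuronReconstruction:
    nodes = []
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 7:
            raise SwcParseError(f"line {line_no}: expected 7 columns, got {len(parts)}")
        try:
            nodes.append(
                SwcNode(
                    int(parts[0]), int(parts[1]), float(parts[2]), float(parts[3]),
                    float(parts[4]), float(parts[5]), int(parts[6]),
                )
            )
        except ValueError as exc:
            raise SwcParseError(f"line {line_no}: {exc}") from None
    return NeuronReconstruction(nodes)


def read_swc(path) -> NeuronReconstruction:
    return parse_swc(Path(path).read_text())


def write_swc(recon: NeuronReconstruction, path) -> None:
    Path(path).write_text(recon.to_swc_text())


@dataclass(frozen=True)
class Branch:
    """Node path between two topological events; interior nodes are pass-through."""

    nodes: tuple[SwcNode, ...]

    @property
    def length(self) -> float:
        return float(
            sum(
                np.linalg.norm(b.xyz - a.xyz)
                for a, b in zip(self.nodes, self.nodes[1:])
            )
        )

    @property
    def chord(self) -> float:
        return float(np.linalg.norm(self.nodes[-1].xyz - self.nodes[0].xyz))

    @property
    def tortuosity(self) -> float:
        if self.chord == 0:
            raise ValueError("malformed branch: coincident endpoints")
        return self.length / self.chord

    @property
    def diameter(self) -> float:
        """Compartment-length-weighted mean diameter (2 x mean endpoint radius)."""
        num = den = 0.0
        for a, b in zip(self.nodes, self.nodes[1:]):
            seg = float(np.linalg.norm(b.xyz - a.xyz))
            num += seg * (a.radius + b.radius)  # 2 * mean radius
            den += seg
        if den == 0:
            return float(self.nodes[0].radius * 2)
        return num / den


def extract_branches(recon: NeuronReconstruction, arbor_class: str) -> list[Branch]:
    """Decompose one arbor class into branches (a partition of its compartments)."""
    code = _arbor_code(arbor_class)

    def arbor_children(n: SwcNode) -> list[SwcNode]:
        return [c for c in recon.children(n.id) if c.type_code == code]

    insertions = [
        n
        for n in recon.nodes
        if n.type_code == code
        and (n.parent_id == -1 or recon.node(n.parent_id).type_code != code)
    ]
    branches: list[Branch] = []
    stack = list(reversed(insertions))
    while stack:
        start = stack.pop()
        for first in arbor_children(start):
            path = [start, first]
            while True:
                nxt = arbor_children(path[-1])
                if len(nxt) == 1:
                    path.append(nxt[0])
                else:
                    break
            branches.append(Branch(tuple(path)))
            if len(arbor_children(path[-1])) >= 2:
                stack.append(path[-1])
    return branches


def _bifurcations(recon, arbor_class):
    code = _arbor_code(arbor_class)
    out = []
    for n in recon.nodes:
        if n.type_code != code:
            continue
        kids = [c for c in recon.children(n.id) if c.type_code == code]
        if len(kids) >= 2:
            out.append(n)
    return out


def mean_branch_length(branches: list[Branch]) -> float:
    if not branches:
        return math.nan
    return float(np.mean([b.length for b in branches]))


def mean_tortuosity(branches: list[Branch]) -> float:
    if not branches:
        return math.nan
    return float(np.mean([b.tortuosity for b in branches]))


def total_length(branches: list[Branch]) -> float:
    if not branches:
        return math.nan
    return float(sum(b.length for b in branches))


def mean_diameter(branches: list[Branch]) -> float:
    if not branches:
        return math.nan
    return float(np.mean([b.diameter for b in branches]))


def mean_path_distance(recon: NeuronReconstruction, arbor_class: str) -> float:
    """Mean along-tree distance from the arbor insertion point to a bifurcation."""
    code = _arbor_code(arbor_class)
    bifs = {n.id for n in _bifurcations(recon, arbor_class)}
    if not bifs:
        return math.nan
    dist: dict[int, float] = {}
    for n in recon.nodes:
        if n.type_code != code:
            continue
        parent_in_arbor = (
            n.parent_id != -1 and recon.node(n.parent_id).type_code == code
        )
        if parent_in_arbor:
            p = recon.node(n.parent_id)
            dist[n.id] = dist[p.id] + float(np.linalg.norm(n.xyz - p.xyz))
        else:
            dist[n.id] = 0.0  # insertion point
    return float(np.mean([dist[b] for b in bifs]))


def mean_remote_bifurcation_angle(recon: NeuronReconstruction, arbor_class: str) -> float:
    """Mean over bifurcations of the shortest angle between fork-to-daughter-end vectors."""
    branches = extract_branches(recon, arbor_class)
    by_start: dict[int, list[Branch]] = {}
    for b in branches:
        by_start.setdefault(b.nodes[0].id, []).append(b)
    angles = []
    for bif in _bifurcations(recon, arbor_class):
        daughters = by_start.get(bif.id, [])
        if len(daughters) < 2:
            continue
        vecs = []
        for d in daughters:
            v = d.nodes[-1].xyz - bif.xyz
            norm = np.linalg.norm(v)
            if norm == 0:
                raise ValueError(f"zero-length daughter vector at node {bif.id}")
            vecs.append(v / norm)
        best = min(
            math.acos(float(np.clip(np.dot(u, w), -1.0, 1.0)))
            for u, w in combinations(vecs, 2)
        )
        angles.append(best)
    if not angles:
        return math.nan
    return float(np.mean(angles))


def arbor_extent(recon: NeuronReconstruction, arbor_class: str) -> tuple[float, float, float]:
    """(height, width, depth) = per-axis max - min over arbor nodes (Y, X, Z)."""
    pts = np.array([n.xyz for n in recon.arbor_nodes(arbor_class)])
    if pts.size == 0:
        return (math.nan, math.nan, math.nan)
    ext = pts.max(axis=0) - pts.min(axis=0)
    return (float(ext[1]), float(ext[0]), float(ext[2]))


BASAL_FEATURES = (
    "distance", "length", "tortuosity", "angle", "diameter",
    "height", "width", "depth", "total_length",
)
APICAL_FEATURES = tuple("a." + f for f in BASAL_FEATURES)
ALL_MORPHO_COLUMNS = BASAL_FEATURES + APICAL_FEATURES + ("rel_depth",)


@dataclass(frozen=True)
class MorphoFeatures:
    values: dict[str, float]

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def to_dict(self) -> dict[str, float]:
        return dict(self.values)


def _arbor_features(recon: NeuronReconstruction, arbor_class: str) -> dict[str, float]:
    branches = extract_branches(recon, arbor_class)
    height, width, depth = arbor_extent(recon, arbor_class)
    return {
        "distance": mean_path_distance(recon, arbor_class),
        "length": mean_branch_length(branches),
        "tortuosity": mean_tortuosity(branches),
        "angle": mean_remote_bifurcation_angle(recon, arbor_class),
        "diameter": mean_diameter(branches),
        "height": height,
        "width": width,
        "depth": depth,
        "total_length": total_length(branches),
    }


def compute_features(recon: NeuronReconstruction, rel_depth: float) -> MorphoFeatures:
    """All 18 per-arbor features plus rel_depth for one cell.

    Missing arbors or empty averaging populations yield NaN entries.
    """
    if not (recon.arbor_nodes("basal") or recon.arbor_nodes("apical")):
        raise ValueError("reconstruction has no dendritic nodes")
    out: dict[str, float] = {}
    out.update(_arbor_features(recon, "basal"))
    for key, val in _arbor_features(recon, "apical").items():
        out["a." + key] = val
    out["rel_depth"] = float(rel_depth)
    return MorphoFeatures(out)


def features_table(
    swc_paths: dict[str, object], metadata: pd.DataFrame
) -> pd.DataFrame:
    """Feature table (one row per cell) from SWC files plus a metadata table.

    ``metadata`` needs columns cell_id, species, rel_depth; ``swc_paths`` maps
    cell_id to an SWC file path.
    """
    required = {"cell_id", "species", "rel_depth"}
    if not required.issubset(metadata.columns):
        raise ValueError(f"metadata must contain columns {sorted(required)}")
    if metadata["cell_id"].duplicated().any():
        raise ValueError("duplicate cell_id in metadata")
    rows = []
    for rec in metadata.itertuples(index=False):
        recon = read_swc(swc_paths[rec.cell_id])
        feats = compute_features(recon, rec.rel_depth).to_dict()
        feats["cell_id"] = rec.cell_id
        feats["species"] = rec.species
        rows.append(feats)
    df = pd.DataFrame(rows).set_index("cell_id")
    return df[["species", *ALL_MORPHO_COLUMNS]]
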