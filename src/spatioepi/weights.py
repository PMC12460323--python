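"""Areal spatial weights: neighbor lists, contiguity construction, standardization.

A :class:`SpatialWeights` object stores, for every areal unit, the list of its
neighbors and the associated weights w_ij.  Binary contiguity weights are the
raw material for both the global Moran statistic and the local Getis-Ord Gi*
statistic; row-standardized weights (each row summing to one) are the common
convention for Moran's I so that the spatial lag is a neighbor average.

Supported on-disk formats are the plain-text GAL neighbor list and GeoJSON
FeatureCollections of polygons, from which queen or rook contiguity is
derived with shapely.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SpatialWeights",
    "read_gal",
    "write_gal",
    "read_geojson",
    "read_weights",
    "row_standardize",
]


@dataclass
class SpatialWeights:
    """Neighbor structure and weights over an ordered set of areal units.

    Parameters
    ----------
    unit_ids
        Ordered unit identifiers; defines the row order of the dense matrix.
    neighbors
        Per-unit neighbor id lists, aligned with ``unit_ids``.
    weights
        Per-neighbor weights, aligned with ``neighbors``.  ``None`` means
        binary (all ones).
    standardization
        ``"binary"`` or ``"row"``.
    include_self
        Whether each unit is its own neighbor (used by the Gi* variant).
    """

    unit_ids: list
    neighbors: list[list]
    weights: list[list[float]] | None = None
    standardization: str = "binary"
    include_self: bool = False
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = [[1.0] * len(nb) for nb in self.neighbors]
        if len(self.unit_ids) != len(self.neighbors):
            raise ValueError("unit_ids and neighbors must be aligned")
        if len(self.neighbors) != len(self.weights):
            raise ValueError("neighbors and weights must be aligned")
        self._index = {u: i for i, u in enumerate(self.unit_ids)}
        if len(self._index) != len(self.unit_ids):
            raise ValueError("duplicate unit ids")
        for u, nbs, ws in zip(self.unit_ids, self.neighbors, self.weights):
            if len(nbs) != len(ws):
                raise ValueError(f"unit {u!r}: neighbor/weight length mismatch")
            for v in nbs:
                if v not in self._index:
                    raise ValueError(f"unit {u!r} references unknown neighbor {v!r}")
                if v == u and not self.include_self:
                    raise ValueError(f"unit {u!r} is its own neighbor")

    @property
    def n(self) -> int:
        return len(self.unit_ids)

    def index_of(self, unit) -> int:
        return self._index[unit]

    def degree(self, unit) -> int:
        return len(self.neighbors[self._index[unit]])

    @property
    def islands(self) -> list:
        """Units with no neighbors (beyond an optional self-loop)."""
        return [
            u
            for u, nbs in zip(self.unit_ids, self.neighbors)
            if all(v == u for v in nbs)
        ]

    def to_dense(self, dtype=float) -> np.ndarray:
        """Dense N x N weight matrix in ``unit_ids`` order."""
        W = np.zeros((self.n, self.n), dtype=dtype)
        for i, (nbs, ws) in enumerate(zip(self.neighbors, self.weights)):
            for v, w in zip(nbs, ws):
                W[i, self._index[v]] = w
        return W

    def check_symmetric(self) -> list[tuple]:
        """Return (i, j) pairs where j lists i but i does not list j."""
        nbset = {
            u: set(nbs) for u, nbs in zip(self.unit_ids, self.neighbors)
        }
        bad = []
        for u, nbs in nbset.items():
            for v in nbs:
                if v != u and u not in nbset[v]:
                    bad.append((u, v))
        return bad

    def with_self(self) -> "SpatialWeights":
        """Copy with a unit-weight self-loop added to every row (Gi* star form)."""
        if self.include_self:
            return self
        return SpatialWeights(
            unit_ids=list(self.unit_ids),
            neighbors=[[u] + list(nbs) for u, nbs in zip(self.unit_ids, self.neighbors)],
            weights=[[1.0] + list(ws) for ws in self.weights],
            standardization=self.standardization,
            include_self=True,
        )

    def subset(self, keep: list) -> "SpatialWeights":
        """Restrict to ``keep`` units, dropping edges to removed units."""
        keepset = set(keep)
        ids = [u for u in self.unit_ids if u in keepset]
        nbs, ws = [], []
        for u in ids:
            i = self._index[u]
            pair = [
                (v, w)
                for v, w in zip(self.neighbors[i], self.weights[i])
                if v in keepset
            ]
            nbs.append([v for v, _ in pair])
            ws.append([w for _, w in pair])
        return SpatialWeights(ids, nbs, ws, self.standardization, self.include_self)


def row_standardize(W: SpatialWeights) -> SpatialWeights:
    """Rescale each unit's weights to sum to one.

    Islands keep an all-zero row (a warning is emitted).  Applying the
    operation twice is a no-op.
    """
    new_weights = []
    for u, ws in zip(W.unit_ids, W.weights):
        s = float(sum(ws))
        if s == 0.0 or not ws:
            if not ws:
                warnings.warn(f"unit {u!r} is an island; zero row retained")
            new_weights.append(list(ws))
        else:
            new_weights.append([w / s for w in ws])
    return replace(
        W,
        weights=new_weights,
        standardization="row",
        _index=dict(W._index),
    )


# ---------------------------------------------------------------------------
# GAL neighbor-list format
# ---------------------------------------------------------------------------

def read_gal(path) -> SpatialWeights:
    """Read a GAL-style plain-text neighbor list.

    Header line holds the unit count (a leading "0" flag field is tolerated);
    then, per unit, a line ``id degree`` followed by a line of neighbor ids.
    Asymmetric lists are rejected; islands are kept with a warning.
    """
    with open(path) as fh:
        tokens_by_line = [ln.split() for ln in fh if ln.strip()]
    header = tokens_by_line[0]
    n = int(header[1] if len(header) >= 2 and header[0] == "0" else header[0])
    unit_ids: list = []
    neighbors: list[list] = []
    k = 1
    for _ in range(n):
        uid, deg = tokens_by_line[k][0], int(tokens_by_line[k][1])
        if deg == 0:
            nbs: list = []
            k += 1
        else:
            nbs = list(tokens_by_line[k + 1])
            if len(nbs) != deg:
                raise ValueError(f"unit {uid}: declared degree {deg}, found {len(nbs)}")
            k += 2
        unit_ids.append(uid)
        neighbors.append(nbs)
    W = SpatialWeights(unit_ids, neighbors)
    bad = W.check_symmetric()
    if bad:
        raise ValueError(f"asymmetric neighbor list; offending pairs: {bad}")
    for u in W.islands:
        warnings.warn(f"unit {u!r} has no neighbors (island); retained")
    return W


def write_gal(W: SpatialWeights, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{W.n}\n")
        for u, nbs in zip(W.unit_ids, W.neighbors):
            fh.write(f"{u} {len(nbs)}\n")
            if nbs:
                fh.write(" ".join(str(v) for v in nbs) + "\n")


# ---------------------------------------------------------------------------
# GeoJSON polygon contiguity
# ---------------------------------------------------------------------------

def read_geojson(path, id_property: str = "id", contiguity: str = "queen") -> SpatialWeights:
    """Derive binary contiguity weights from a GeoJSON FeatureCollection.

    Queen contiguity links polygons sharing at least one boundary point;
    rook requires a shared edge of positive length.  Queen is therefore a
    superset of rook on any polygon set.
    """
    from shapely.geometry import shape
    from shapely.strtree import STRtree

    with open(path) as fh:
        gj = json.load(fh)
    feats = gj["features"]
    ids = []
    geoms = []
    for i, f in enumerate(feats):
        props = f.get("properties") or {}
        if id_property not in props:
            raise ValueError(f"feature {i} lacks id property {id_property!r}")
        ids.append(props[id_property])
        geoms.append(shape(f["geometry"]))
    tree = STRtree(geoms)
    neighbors: list[list] = [[] for _ in ids]
    for i, g in enumerate(geoms):
        for j in tree.query(g):
            j = int(j)
            if j <= i:
                continue
            inter = g.boundary.intersection(geoms[j].boundary)
            if inter.is_empty:
                continue
            touch = (contiguity == "queen") or inter.length > 0
            if touch:
                neighbors[i].append(ids[j])
                neighbors[j].append(ids[i])
    W = SpatialWeights(ids, neighbors)
    for u in W.islands:
        warnings.warn(f"unit {u!r} has no neighbors (island); retained")
    return W


def read_weights(path, *, id_property: str = "id", contiguity: str = "queen") -> SpatialWeights:
    """Dispatch on file extension: ``.gal`` neighbor lists, ``.geojson``/``.json`` polygons."""
    p = str(path).lower()
    if p.endswith(".gal"):
        return read_gal(path)
    if p.endswith((".geojson", ".json")):
        return read_geojson(path, id_property=id_property, contiguity=contiguity)
    raise ValueError(f"unrecognized weights format: {path}")
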