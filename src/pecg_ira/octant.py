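"""VCG octant random-walk representation and its four feature groups.

The dipole trajectory is discretized into the 8 Cartesian octants of
(X, Y, Z) space; the sequence of visited octants is a random walk whose
transition structure forms a directed weighted 8-node network. Four
groups of scalar features summarize the walk:

I.   local octant statistics of the vector magnitude (48),
II.  residence / sojourn features and transition-rate statistics (12),
III. per-octant arrival and departure rates (16),
IV.  topology metrics of the transition network (85),

for 161 named features in total.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .records import VCGRecord

N_OCTANTS = 8

_STATS = ("Min", "Avg", "Var", "Max", "Elv", "Azm")
GROUP_I_NAMES = tuple(
    f"Oct{i}{s}" for s in _STATS for i in range(1, N_OCTANTS + 1)
)
GROUP_II_NAMES = tuple(
    [f"Oct{i}Num" for i in range(1, N_OCTANTS + 1)]
    + ["SlowTran", "FastTran", "MeanTran", "VarTran"]
)
GROUP_III_NAMES = tuple(
    [f"InOct{i}Rate" for i in range(1, N_OCTANTS + 1)]
    + [f"OutOct{i}Rate" for i in range(1, N_OCTANTS + 1)]
)
_NODE_METRICS = ("InDgr", "OutDgr", "Degr", "InStr", "OutStr", "Str", "Clust")
GROUP_IV_NAMES = tuple(
    [f"{m}{i}" for m in _NODE_METRICS for i in range(1, N_OCTANTS + 1)]
    + ["Jod", "Jid", "Jbl", "Rass", "Kden", "Nden", "K_den", "Transi",
       "Qmod", "LambdaNet", "EfficiencyNet"]
    + [f"Ecc{i}" for i in range(1, N_OCTANTS + 1)]
    + ["RadiusNet", "DiameterNet"]
    + [f"NodeBet{i}" for i in range(1, N_OCTANTS + 1)]
)
FEATURE_NAMES = GROUP_I_NAMES + GROUP_II_NAMES + GROUP_III_NAMES + GROUP_IV_NAMES
GROUP_SIZES = {
    "I": len(GROUP_I_NAMES),
    "II": len(GROUP_II_NAMES),
    "III": len(GROUP_III_NAMES),
    "IV": len(GROUP_IV_NAMES),
}

#: value reported for statistics of octants the trajectory never visits
FILL_VALUE = 0.0


@dataclass
class OctantSequence:
    """Per-sample octant index plus spherical coordinates of the dipole."""

    octant: np.ndarray     # int in 1..8
    magnitude: np.ndarray  # mV
    azimuth: np.ndarray    # degrees, atan2(Y, X)
    elevation: np.ndarray  # degrees, atan2(Z, sqrt(X^2+Y^2))
    fs: float

    @property
    def n_samples(self) -> int:
        return len(self.octant)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


def assign_octants(vcg: VCGRecord) -> OctantSequence:
    """Discretize the trajectory into octants by coordinate signs.

    Octant index = 1 + 4*[X<0] + 2*[Y<0] + [Z<0]: the all-positive
    octant is 1 and the all-negative octant is 8, so octants 1-4 share
    the X>=0 half-space and 5-8 the X<0 half-space. Exact zero vectors
    carry no direction and keep the previous sample's octant.
    """
    if vcg.n_samples == 0:
        raise ValueError("empty VCG record")
    x, y, z = vcg.x, vcg.y, vcg.z
    octant = 1 + 4 * (x < 0) + 2 * (y < 0) + (z < 0)
    octant = octant.astype(np.int64)
    zero = (x == 0) & (y == 0) & (z == 0)
    if zero.any():
        idx = np.arange(len(octant))
        last_nonzero = np.maximum.accumulate(np.where(~zero, idx, -1))
        carried = np.where(last_nonzero >= 0, octant[np.maximum(last_nonzero, 0)], 1)
        octant = np.where(zero, carried, octant)
    magnitude = np.sqrt(x**2 + y**2 + z**2)
    azimuth = np.degrees(np.arctan2(y, x))
    elevation = np.degrees(np.arctan2(z, np.hypot(x, y)))
    return OctantSequence(octant, magnitude, azimuth, elevation, fs=vcg.fs)


# --------------------------------------------------------------------------
# group I: local octant statistics
# --------------------------------------------------------------------------

def local_octant_features(seq: OctantSequence) -> dict[str, float]:
    """Magnitude statistics per octant plus the orientation of the
    maximal vector in each octant; unvisited octants take the fill value."""
    out = {name: FILL_VALUE for name in GROUP_I_NAMES}
    for i in range(1, N_OCTANTS + 1):
        mask = seq.octant == i
        if not mask.any():
            continue
        mags = seq.magnitude[mask]
        peak = int(np.argmax(mags))
        out[f"Oct{i}Min"] = float(mags.min())
        out[f"Oct{i}Avg"] = float(mags.mean())
        out[f"Oct{i}Var"] = float(mags.var())
        out[f"Oct{i}Max"] = float(mags.max())
        out[f"Oct{i}Elv"] = float(seq.elevation[mask][peak])
        out[f"Oct{i}Azm"] = float(seq.azimuth[mask][peak])
    return out


# --------------------------------------------------------------------------
# group II: residence features
# --------------------------------------------------------------------------

def residence_features(seq: OctantSequence, window: float = 1.0) -> dict[str, float]:
    """Sojourn time per octant (s) and sliding-window transition-rate
    statistics (transitions per second over ``window``-long windows)."""
    out: dict[str, float] = {}
    for i in range(1, N_OCTANTS + 1):
        out[f"Oct{i}Num"] = float(np.sum(seq.octant == i) / seq.fs)
    changes = (np.diff(seq.octant) != 0).astype(float)
    w = int(round(window * seq.fs))
    if len(changes) == 0 or changes.sum() == 0:
        rates = np.zeros(1)
    elif len(changes) <= w:
        rates = np.array([changes.sum() / seq.duration])
    else:
        counts = np.convolve(changes, np.ones(w), mode="valid")
        rates = counts / window
    out["SlowTran"] = float(rates.min())
    out["FastTran"] = float(rates.max())
    out["MeanTran"] = float(rates.mean())
    out["VarTran"] = float(rates.var())
    return out


# --------------------------------------------------------------------------
# group III: transition features
# --------------------------------------------------------------------------

def transition_features(seq: OctantSequence) -> dict[str, float]:
    """Arrival and departure rates per octant (events per second)."""
    out: dict[str, float] = {}
    src = seq.octant[:-1]
    dst = seq.octant[1:]
    moved = src != dst
    duration = seq.duration
    for i in range(1, N_OCTANTS + 1):
        out[f"InOct{i}Rate"] = float(np.sum(moved & (dst == i)) / duration)
    for i in range(1, N_OCTANTS + 1):
        out[f"OutOct{i}Rate"] = float(np.sum(moved & (src == i)) / duration)
    return out


# --------------------------------------------------------------------------
# the transition network
# --------------------------------------------------------------------------

@dataclass
class OctantNetwork:
    """Directed weighted transition graph on the 8 octants (no self loops)."""

    weights: np.ndarray  # (8, 8) integer transition counts, zero diagonal
    duration: float      # s of observation

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights)
        if self.weights.shape != (N_OCTANTS, N_OCTANTS):
            raise ValueError("weight matrix must be 8x8")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("self loops are not part of the octant network")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")

    @property
    def n_nodes(self) -> int:
        return N_OCTANTS

    @property
    def total_transitions(self) -> int:
        return int(self.weights.sum())

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(1, N_OCTANTS + 1))
        for i, j in zip(*np.nonzero(self.weights)):
            w = float(self.weights[i, j])
            g.add_edge(i + 1, j + 1, weight=w, length=1.0 / w)
        return g


def build_octant_network(seq: OctantSequence, duration: float | None = None) -> OctantNetwork:
    """Count consecutive-sample transitions between distinct octants."""
    w = np.zeros((N_OCTANTS, N_OCTANTS), dtype=np.int64)
    src = seq.octant[:-1]
    dst = seq.octant[1:]
    moved = src != dst
    np.add.at(w, (src[moved] - 1, dst[moved] - 1), 1)
    return OctantNetwork(w, duration if duration is not None else seq.duration)


# --------------------------------------------------------------------------
# group IV: network topology
# --------------------------------------------------------------------------

def _restricted_growth_strings(n: int):
    """All set partitions of range(n) as membership vectors."""
    a = [0] * n
    b = [1] * n
    while True:
        yield tuple(a)
        j = n - 1
        while j > 0 and a[j] == b[j - 1]:
            j -= 1
        if j == 0:
            return
        a[j] += 1
        b[j] = max(b[j - 1], a[j] + 1)
        for k in range(j + 1, n):
            a[k] = 0
            b[k] = max(b[j], a[k] + 1)


@lru_cache(maxsize=16)
def _all_partitions(n: int) -> np.ndarray:
    return np.array(list(_restricted_growth_strings(n)))


def max_modularity(weights: np.ndarray) -> float:
    """Exact maximized Newman modularity of the symmetrized network.

    Feasible here because the network never has more than 8 nodes
    (Bell(8) = 4140 partitions).
    """
    a = np.asarray(weights, float)
    a = a + a.T
    two_m = a.sum()
    if two_m == 0:
        return 0.0
    k = a.sum(axis=1)
    b = a / two_m - np.outer(k, k) / two_m**2
    # isolated nodes have zero degree and cannot affect Q: enumerate
    # partitions of the connected nodes only
    active = np.flatnonzero(k > 0)
    b = b[np.ix_(active, active)]
    parts = _all_partitions(len(active))
    best = -np.inf
    for p in parts:
        same = np.equal.outer(p, p)
        best = max(best, float(b[same].sum()))
    return best


def _shortest_paths(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths with edge length 1/weight."""
    w = np.asarray(weights, float)
    lengths = np.zeros_like(w)
    nz = w > 0
    lengths[nz] = 1.0 / w[nz]
    return dijkstra(lengths, directed=True, indices=None)


def topology_features(net: OctantNetwork) -> dict[str, float]:
    """The 85 topology metrics of the transition network.

    Conventions for degenerate inputs: path-based averages run over
    reachable ordered pairs only; eccentricity, radius and diameter are
    taken over the largest strongly connected component (nodes outside
    it report the fill value); an edgeless network yields zeros except
    Jbl = 8 (every octant has equal in- and out-degree).
    """
    w = np.asarray(net.weights, float)
    out: dict[str, float] = {}
    binary = w > 0
    in_dgr = binary.sum(axis=0).astype(float)
    out_dgr = binary.sum(axis=1).astype(float)
    in_str = w.sum(axis=0)
    out_str = w.sum(axis=1)
    g = net.to_networkx()
    clust = nx.clustering(g, weight="weight")
    for i in range(N_OCTANTS):
        out[f"InDgr{i+1}"] = in_dgr[i]
        out[f"OutDgr{i+1}"] = out_dgr[i]
        out[f"Degr{i+1}"] = in_dgr[i] + out_dgr[i]
        out[f"InStr{i+1}"] = float(in_str[i])
        out[f"OutStr{i+1}"] = float(out_str[i])
        out[f"Str{i+1}"] = float(in_str[i] + out_str[i])
        out[f"Clust{i+1}"] = float(clust[i + 1])

    out["Jod"] = float(np.sum(out_dgr > in_dgr))
    out["Jid"] = float(np.sum(in_dgr > out_dgr))
    out["Jbl"] = float(np.sum(in_dgr == out_dgr))

    # assortativity: Pearson correlation of (source out-degree,
    # target in-degree) across directed edges
    src, dst = np.nonzero(binary)
    if len(src) >= 2:
        xs, ys = out_dgr[src], in_dgr[dst]
        if np.std(xs) > 0 and np.std(ys) > 0:
            out["Rass"] = float(np.corrcoef(xs, ys)[0, 1])
        else:
            out["Rass"] = FILL_VALUE
    else:
        out["Rass"] = FILL_VALUE

    out["Kden"] = float(np.sum((in_dgr + out_dgr) > 0))
    out["Nden"] = float(binary.sum())
    out["K_den"] = float(binary.sum() / (N_OCTANTS * (N_OCTANTS - 1)))
    out["Transi"] = float(nx.transitivity(nx.Graph(g.to_undirected())))
    out["Qmod"] = max_modularity(w)

    d = _shortest_paths(w)
    off = ~np.eye(N_OCTANTS, dtype=bool)
    reachable = np.isfinite(d) & off
    out["LambdaNet"] = (
        float(d[reachable].mean()) if reachable.any() else FILL_VALUE
    )
    inv = np.zeros_like(d)
    inv[reachable] = 1.0 / d[reachable]
    out["EfficiencyNet"] = float(inv[off].sum() / (N_OCTANTS * (N_OCTANTS - 1)))

    # eccentricity on the largest strongly connected component
    n_comp, labels = _strongly_connected(binary)
    sizes = np.bincount(labels, minlength=n_comp)
    best = np.flatnonzero(sizes == sizes.max())
    # deterministic tie-break: component containing the lowest octant index
    comp = min(best, key=lambda c: int(np.flatnonzero(labels == c)[0]))
    members = np.flatnonzero(labels == comp)
    ecc = np.full(N_OCTANTS, FILL_VALUE)
    if len(members) > 1:
        sub = d[np.ix_(members, members)]
        ecc_vals = np.max(np.where(np.eye(len(members), dtype=bool), 0.0, sub), axis=1)
        ecc[members] = ecc_vals
        out["RadiusNet"] = float(ecc_vals.min())
        out["DiameterNet"] = float(ecc_vals.max())
    else:
        out["RadiusNet"] = FILL_VALUE
        out["DiameterNet"] = FILL_VALUE
    for i in range(N_OCTANTS):
        out[f"Ecc{i+1}"] = float(ecc[i])

    bet = nx.betweenness_centrality(g, weight="length", normalized=True)
    for i in range(N_OCTANTS):
        out[f"NodeBet{i+1}"] = float(bet[i + 1])
    return out


def _strongly_connected(binary: np.ndarray) -> tuple[int, np.ndarray]:
    from scipy.sparse.csgraph import connected_components

    return connected_components(
        binary.astype(float), directed=True, connection="strong"
    )


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------

def extract_all(vcg: VCGRecord) -> pd.Series:
    """All 161 named features of one VCG record, in frozen order."""
    seq = assign_octants(vcg)
    values: dict[str, float] = {}
    values.update(local_octant_features(seq))
    values.update(residence_features(seq))
    values.update(transition_features(seq))
    values.update(topology_features(build_octant_network(seq)))
    return pd.Series([values[n] for n in FEATURE_NAMES], index=list(FEATURE_NAMES))


class OctantFeatureExtractor:
    """sklearn-style transformer: list of VCG records -> feature matrix.

    Stateless (``fit`` is a no-op); ``transform`` returns a DataFrame
    with the 161 frozen feature columns.
    """

    def __init__(self, window: float = 1.0):
        self.window = window

    def get_params(self, deep: bool = True) -> dict:
        return {"window": self.window}

    def set_params(self, **params) -> "OctantFeatureExtractor":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "OctantFeatureExtractor":
        self.feature_names_ = list(FEATURE_NAMES)
        return self

    def transform(self, X) -> pd.DataFrame:
        rows = [extract_all(vcg) for vcg in X]
        return pd.DataFrame(rows).reset_index(drop=True)

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)
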