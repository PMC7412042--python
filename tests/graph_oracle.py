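"""Independent brute-force implementations of the octant-network topology
metrics, written from the definitions with explicit loops (no networkx,
no shared code with the package). Feasible because the network has at
most 8 nodes."""

from __future__ import annotations

import itertools
import math

N = 8


def _binary(w):
    return [[1 if w[i][j] > 0 else 0 for j in range(N)] for i in range(N)]


def degrees(w):
    b = _binary(w)
    in_d = [sum(b[j][i] for j in range(N)) for i in range(N)]
    out_d = [sum(b[i][j] for j in range(N)) for i in range(N)]
    return in_d, out_d


def strengths(w):
    in_s = [sum(w[j][i] for j in range(N)) for i in range(N)]
    out_s = [sum(w[i][j] for j in range(N)) for i in range(N)]
    return in_s, out_s


def fagiolo_clustering(w):
    """Directed weighted clustering (Fagiolo 2007), cube-root weights
    normalized by the maximum weight."""
    wmax = max((w[i][j] for i in range(N) for j in range(N)), default=0)
    if wmax == 0:
        return [0.0] * N
    cw = [[(w[i][j] / wmax) ** (1.0 / 3.0) for j in range(N)] for i in range(N)]
    b = _binary(w)
    in_d, out_d = degrees(w)
    out = []
    for i in range(N):
        t = 0.0
        for j in range(N):
            for h in range(N):
                t += (cw[i][j] + cw[j][i]) * (cw[i][h] + cw[h][i]) * (
                    cw[j][h] + cw[h][j]
                )
        t /= 2.0
        d_tot = in_d[i] + out_d[i]
        d_bi = sum(b[i][j] * b[j][i] for j in range(N))
        denom = float(d_tot * (d_tot - 1) - 2 * d_bi)
        out.append(t / denom if denom > 0 else 0.0)
    return out


def assortativity(w):
    """Pearson correlation of (source out-degree, target in-degree)
    over directed edges."""
    in_d, out_d = degrees(w)
    xs, ys = [], []
    for i in range(N):
        for j in range(N):
            if w[i][j] > 0:
                xs.append(out_d[i])
                ys.append(in_d[j])
    n = len(xs)
    if n < 2:
        return 0.0
    mx = sum(xs) / n
    my = sum(ys) / n
    sx = math.sqrt(sum((x - mx) ** 2 for x in xs) / n)
    sy = math.sqrt(sum((y - my) ** 2 for y in ys) / n)
    if sx == 0 or sy == 0:
        return 0.0
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys)) / n
    return cov / (sx * sy)


def transitivity(w):
    """3 * triangles / triads on the symmetrized unweighted graph."""
    sym = [[1 if (w[i][j] > 0 or w[j][i] > 0) and i != j else 0
            for j in range(N)] for i in range(N)]
    triangles = 0
    triads = 0
    for i in range(N):
        neighbors = [j for j in range(N) if sym[i][j]]
        for a, b in itertools.permutations(neighbors, 2):
            triads += 1
            if sym[a][b]:
                triangles += 1
    return triangles / triads if triads else 0.0


def _partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i, block in enumerate(part):
            yield part[:i] + [block + [first]] + part[i + 1 :]
        yield [[first]] + part


def max_modularity(w):
    """Exact maximum Newman modularity of the symmetrized weighted graph
    via recursive partition enumeration."""
    a = [[w[i][j] + w[j][i] for j in range(N)] for i in range(N)]
    two_m = sum(sum(row) for row in a)
    if two_m == 0:
        return 0.0
    k = [sum(a[i]) for i in range(N)]
    active = [i for i in range(N) if k[i] > 0]
    best = -math.inf
    for part in _partitions(active):
        q = 0.0
        for block in part:
            for i in block:
                for j in block:
                    q += a[i][j] / two_m - k[i] * k[j] / (two_m * two_m)
        best = max(best, q)
    return best


def shortest_paths(w):
    """Floyd-Warshall with edge length 1/weight."""
    inf = math.inf
    d = [[0.0 if i == j else inf for j in range(N)] for i in range(N)]
    for i in range(N):
        for j in range(N):
            if w[i][j] > 0 and i != j:
                d[i][j] = 1.0 / w[i][j]
    for k in range(N):
        for i in range(N):
            for j in range(N):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def path_metrics(w):
    d = shortest_paths(w)
    finite = [d[i][j] for i in range(N) for j in range(N)
              if i != j and math.isfinite(d[i][j])]
    lam = sum(finite) / len(finite) if finite else 0.0
    eff = sum(1.0 / d[i][j] for i in range(N) for j in range(N)
              if i != j and math.isfinite(d[i][j])) / (N * (N - 1))
    return lam, eff


def strongly_connected_components(w):
    reach = [[i == j or w[i][j] > 0 for j in range(N)] for i in range(N)]
    for k in range(N):
        for i in range(N):
            for j in range(N):
                reach[i][j] = reach[i][j] or (reach[i][k] and reach[k][j])
    comps = []
    assigned = [False] * N
    for i in range(N):
        if assigned[i]:
            continue
        comp = [j for j in range(N) if reach[i][j] and reach[j][i]]
        for j in comp:
            assigned[j] = True
        comps.append(comp)
    return comps


def eccentricity_metrics(w):
    """Eccentricity / radius / diameter over the largest SCC (tie broken
    toward the component containing the lowest node index)."""
    comps = strongly_connected_components(w)
    size = max(len(c) for c in comps)
    comp = next(c for c in comps if len(c) == size)
    ecc = [0.0] * N
    if len(comp) <= 1:
        return ecc, 0.0, 0.0
    d = shortest_paths(w)
    for i in comp:
        ecc[i] = max(d[i][j] for j in comp if j != i)
    vals = [ecc[i] for i in comp]
    return ecc, min(vals), max(vals)


def betweenness(w):
    """Betweenness centrality by exhaustive simple-path enumeration,
    normalized by (N-1)(N-2) as for directed graphs."""
    nodes = list(range(N))
    score = [0.0] * N
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            # enumerate all simple s->t paths
            best = math.inf
            paths = []
            stack = [(s, [s], 0.0)]
            while stack:
                node, path, length = stack.pop()
                if length > best:
                    continue
                if node == t:
                    if length < best - 1e-12:
                        best = length
                        paths = [path]
                    elif abs(length - best) <= 1e-12:
                        paths.append(path)
                    continue
                for nxt in nodes:
                    if w[node][nxt] > 0 and nxt not in path:
                        stack.append((nxt, path + [nxt], length + 1.0 / w[node][nxt]))
            if not paths:
                continue
            sigma = len(paths)
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                score[v] += through / sigma
    norm = (N - 1) * (N - 2)
    return [x / norm for x in score]


def all_features(w):
    """The full 85-metric dict, keyed like the package's output."""
    in_d, out_d = degrees(w)
    in_s, out_s = strengths(w)
    clust = fagiolo_clustering(w)
    out = {}
    for i in range(N):
        out[f"InDgr{i+1}"] = float(in_d[i])
        out[f"OutDgr{i+1}"] = float(out_d[i])
        out[f"Degr{i+1}"] = float(in_d[i] + out_d[i])
        out[f"InStr{i+1}"] = float(in_s[i])
        out[f"OutStr{i+1}"] = float(out_s[i])
        out[f"Str{i+1}"] = float(in_s[i] + out_s[i])
        out[f"Clust{i+1}"] = clust[i]
    out["Jod"] = float(sum(1 for i in range(N) if out_d[i] > in_d[i]))
    out["Jid"] = float(sum(1 for i in range(N) if in_d[i] > out_d[i]))
    out["Jbl"] = float(sum(1 for i in range(N) if in_d[i] == out_d[i]))
    out["Rass"] = assortativity(w)
    out["Kden"] = float(sum(1 for i in range(N) if in_d[i] + out_d[i] > 0))
    n_edges = sum(1 for i in range(N) for j in range(N) if w[i][j] > 0)
    out["Nden"] = float(n_edges)
    out["K_den"] = n_edges / (N * (N - 1))
    out["Transi"] = transitivity(w)
    out["Qmod"] = max_modularity(w)
    lam, eff = path_metrics(w)
    out["LambdaNet"] = lam
    out["EfficiencyNet"] = eff
    ecc, radius, diameter = eccentricity_metrics(w)
    for i in range(N):
        out[f"Ecc{i+1}"] = ecc[i]
    out["RadiusNet"] = radius
    out["DiameterNet"] = diameter
    bet = betweenness(w)
    for i in range(N):
        out[f"NodeBet{i+1}"] = bet[i]
    return out
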