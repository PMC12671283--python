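"""Independently coded O(n^2) Local Outlier Factor reference.

Pure-Python loops straight from the density-ratio definitions; shares no
code with the package implementation.  Used only as a test oracle.
"""

import math


def _dist(a, b):
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def _standardize(points):
    n = len(points)
    d = len(points[0])
    means = [sum(p[j] for p in points) / n for j in range(d)]
    scales = []
    for j in range(d):
        var = sum((p[j] - means[j]) ** 2 for p in points) / n
        s = math.sqrt(var)
        scales.append(s if s > 0 else 1.0)
    z = [[(p[j] - means[j]) / scales[j] for j in range(d)] for p in points]
    return z, means, scales


def _lof(lrd_p, lrds_o):
    if math.isinf(lrd_p):
        return sum(1.0 if math.isinf(l) else 0.0 for l in lrds_o) / len(lrds_o)
    return sum(lrds_o) / len(lrds_o) / lrd_p


def brute_force_lof(calibration, k, queries=()):
    """Leave-one-out LOF of every calibration point and novelty LOF of
    every query, after standardizing with the calibration moments.

    Returns (calibration_scores, query_scores) as plain lists.
    """
    z, means, scales = _standardize([list(p) for p in calibration])
    n = len(z)

    # calibration scoring: each point against all others
    kdists = []
    neighbourhoods = []
    for i in range(n):
        dists = {j: _dist(z[i], z[j]) for j in range(n) if j != i}
        kd, nb = _neighbourhood_from_map(dists, k)
        kdists.append(kd)
        neighbourhoods.append((dists, nb))
    lrds = [
        _lrd_from_map(kdists, dists, nb) for dists, nb in neighbourhoods
    ]
    cal_scores = [
        _lof(lrds[i], [lrds[o] for o in neighbourhoods[i][1]]) for i in range(n)
    ]

    query_scores = []
    for q in queries:
        zq = [(q[j] - means[j]) / scales[j] for j in range(len(q))]
        dists = {j: _dist(zq, z[j]) for j in range(n)}
        kd, nb = _neighbourhood_from_map(dists, k)
        lrd_q = _lrd_from_map(kdists, dists, nb)
        query_scores.append(_lof(lrd_q, [lrds[o] for o in nb]))
    return cal_scores, query_scores


def _neighbourhood_from_map(dists, k):
    ordered = sorted(dists.values())
    kdist = ordered[k - 1]
    return kdist, [j for j, dd in dists.items() if dd <= kdist]


def _lrd_from_map(kdists, dists, neighbours):
    reach = [max(kdists[o], dists[o]) for o in neighbours]
    mean_reach = sum(reach) / len(reach)
    return math.inf if mean_reach == 0 else 1.0 / mean_reach
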