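"""Independent reference implementations used to check the package.

These deliberately use the most literal, brute-force formulation of each
computation and share no code with the implementation under test.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import squareform, pdist


def brute_dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Textbook DBSCAN via explicit reachability graph and breadth-first
    flood fill.  Core point: >= min_pts points (itself included) within eps.
    Clusters are discovered in point-index order; border points keep the
    first label they receive.  Noise = -1."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    dist = squareform(pdist(pts)) if n > 1 else np.zeros((1, 1))
    neigh = [np.flatnonzero(dist[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neigh])
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cid
        queue = [i]
        while queue:
            j = queue.pop(0)
            for k in neigh[j]:
                if labels[k] == -1:
                    labels[k] = cid
                    if core[k]:
                        queue.append(k)
        cid += 1
    return labels


def canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Rename clusters by order of first appearance so labelings compare."""
    labels = np.asarray(labels)
    out = np.full(len(labels), -1, dtype=int)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab == -1:
            continue
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def balanced_three_way_anova(table, response: str) -> dict[str, tuple[int, float]]:
    """Sequential = marginal-means ANOVA for a balanced 3-factor design with
    one observation per cell.  Returns {term: (DF, SS)} including Residuals
    (the three-way stratum) and the corrected total."""
    df = table.copy()
    y = df[response].to_numpy(float)
    grand = y.mean()
    levels = {f: np.sort(df[f].unique()) for f in ("H", "S", "D")}
    a, b, c = (len(levels[f]) for f in ("H", "S", "D"))

    def marg(*factors):
        return df.groupby(list(factors))[response].mean()

    mH, mS, mD = marg("H"), marg("S"), marg("D")
    mHS, mHD, mSD = marg("H", "S"), marg("H", "D"), marg("S", "D")

    ss = {}
    ss["Heterogeneity"] = (a - 1, b * c * ((mH - grand) ** 2).sum())
    ss["Selection"] = (b - 1, a * c * ((mS - grand) ** 2).sum())
    ss["Dispersal"] = (c - 1, a * b * ((mD - grand) ** 2).sum())
    hs = ((mHS - grand).unstack()
          - (mH - grand).to_numpy()[:, None]
          - (mS - grand).to_numpy()[None, :])
    ss["Heterogeneity:Selection"] = ((a - 1) * (b - 1), c * (hs.to_numpy() ** 2).sum())
    hd = ((mHD - grand).unstack()
          - (mH - grand).to_numpy()[:, None]
          - (mD - grand).to_numpy()[None, :])
    ss["Heterogeneity:Dispersal"] = ((a - 1) * (c - 1), b * (hd.to_numpy() ** 2).sum())
    sd = ((mSD - grand).unstack()
          - (mS - grand).to_numpy()[:, None]
          - (mD - grand).to_numpy()[None, :])
    ss["Selection:Dispersal"] = ((b - 1) * (c - 1), a * (sd.to_numpy() ** 2).sum())
    total = ((y - grand) ** 2).sum()
    explained = sum(v for _, v in ss.values())
    ss["Residuals"] = ((a - 1) * (b - 1) * (c - 1), total - explained)
    ss["Total"] = (a * b * c - 1, total)
    return ss


def wright_fisher_mean_het(n_loci: int, n_diploid: int, gens: int,
                           n_reps: int, rng: np.random.Generator) -> np.ndarray:
    """Monte Carlo distribution of mean expected heterozygosity.

    Simulates ``n_reps`` independent populations of ``n_loci`` unlinked loci
    under pure binomial (Wright-Fisher) resampling of 2N allele copies,
    starting from binomially drawn initial counts at frequency 0.5, and
    returns an (n_reps, gens + 1) array of the across-locus mean of
    2 p (1 - p) per generation.
    """
    two_n = 2 * n_diploid
    counts = rng.binomial(two_n, 0.5, size=(n_reps, n_loci))
    out = np.empty((n_reps, gens + 1))
    p = counts / two_n
    out[:, 0] = (2 * p * (1 - p)).mean(axis=1)
    for t in range(1, gens + 1):
        counts = rng.binomial(two_n, counts / two_n)
        p = counts / two_n
        out[:, t] = (2 * p * (1 - p)).mean(axis=1)
    return out
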