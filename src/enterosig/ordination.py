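"""Beta diversity: Bray-Curtis / Jaccard distances, PCoA, and PERMANOVA.

Distances are computed on per-sample relative abundances (Bray-Curtis) or on
presence/absence (Jaccard).  PCoA is classical metric scaling (Gower
double-centering + eigendecomposition); PERMANOVA follows Anderson's
partition of squared dissimilarities with a seeded whole-label permutation
test, including pairwise sub-tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis, jaccard, pdist, squareform

from .tables import AbundanceTable


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.sum() + y.sum() <= 0:
        raise ValueError("both samples are all-zero")
    return x, y


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) on abundance vectors."""
    x, y = _check_pair(x, y)
    return float(braycurtis(x, y))


def jaccard_binary(x, y) -> float:
    """1 - |shared present taxa| / |union of present taxa|."""
    x, y = _check_pair(x, y)
    return float(jaccard(x > 0, y > 0))


def distance_matrix(table: AbundanceTable, metric: str = "bray") -> pd.DataFrame:
    """Square sample-by-sample dissimilarity matrix.

    ``bray`` uses per-sample proportions; ``jaccard`` uses presence/absence
    of raw counts.
    """
    if metric == "bray":
        data = table.relative_abundance().T.to_numpy()
        cond = pdist(data, metric="braycurtis")
    elif metric == "jaccard":
        data = (table.counts.T.to_numpy() > 0)
        cond = pdist(data, metric="jaccard")
    else:
        raise ValueError(f"unknown metric {metric!r}; expected 'bray' or 'jaccard'")
    return pd.DataFrame(squareform(cond), index=table.samples, columns=table.samples)


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class OrdinationResult:
    """Principal-coordinate embedding of a dissimilarity matrix."""

    coordinates: pd.DataFrame          # samples x retained axes
    eigenvalues: np.ndarray            # all eigenvalues, descending
    proportion_explained: np.ndarray   # per positive axis, vs sum of positives


def _as_square(dm) -> tuple[np.ndarray, list]:
    if isinstance(dm, pd.DataFrame):
        ids = list(dm.index)
        d = dm.to_numpy(dtype=float)
    else:
        d = np.asarray(dm, dtype=float)
        ids = list(range(d.shape[0]))
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix is not symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-8):
        raise ValueError("distance matrix diagonal is not zero")
    return d, ids


def pcoa(dm, lingoes: bool = False) -> OrdinationResult:
    """Classical metric scaling of a dissimilarity matrix.

    Negative eigenvalues (non-Euclidean input) are reported in
    ``eigenvalues`` but excluded from the proportion-explained denominator.
    With ``lingoes=True`` the constant -2*lambda_min is added to squared
    off-diagonal dissimilarities first, making the matrix Euclidean.
    """
    d, ids = _as_square(dm)
    n = d.shape[0]

    def _embed(dsq: np.ndarray):
        j = np.eye(n) - np.ones((n, n)) / n
        b = -0.5 * j @ dsq @ j
        vals, vecs = np.linalg.eigh((b + b.T) / 2)
        order = np.argsort(vals)[::-1]
        return vals[order], vecs[:, order]

    vals, vecs = _embed(d**2)
    if lingoes and vals[-1] < -1e-12:
        # Lingoes: d'^2 = d^2 + 2c for i != j, with c = -lambda_min of B
        dsq = d**2 + 2.0 * (-vals[-1])
        np.fill_diagonal(dsq, 0.0)
        vals, vecs = _embed(dsq)

    pos = vals > max(1e-12, 1e-10 * abs(vals[0]) if vals[0] > 0 else 1e-12)
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    prop = vals[pos] / vals[pos].sum() if pos.any() else np.array([])
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=axes),
        eigenvalues=vals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int | None
    groups: list
    pairwise: pd.DataFrame | None = None


def _ss_partition(dsq: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances, Anderson's identities."""
    n = dsq.shape[0]
    ss_total = dsq[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = dsq[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, k=1)].sum() / idx.size
    return float(ss_total), float(ss_within)


def _pseudo_f(dsq: np.ndarray, labels: np.ndarray, k: int) -> tuple[float, float]:
    n = dsq.shape[0]
    ss_total, ss_within = _ss_partition(dsq, labels)
    ss_among = ss_total - ss_within
    if ss_within == 0:  # perfect separation: infinite pseudo-F
        return float("inf"), ss_among / ss_total
    f = (ss_among / (k - 1)) / (ss_within / (n - k))
    r2 = ss_among / ss_total
    return f, r2


def _batch_f(dsq: np.ndarray, label_codes: np.ndarray, perms: np.ndarray, k: int) -> np.ndarray:
    """Vectorized pseudo-F for a batch of label permutations (rows of `perms`)."""
    n = dsq.shape[0]
    ss_total = dsq[np.triu_indices(n, k=1)].sum() / n
    permuted = label_codes[perms]  # (B, n)
    ss_within = np.zeros(perms.shape[0])
    for g in np.unique(label_codes):
        m = (permuted == g).astype(float)  # (B, n)
        n_g = m[0].sum()
        # sum over ordered pairs within group, minus diagonal (zero), halved
        ss_within += np.einsum("bi,ij,bj->b", m, dsq, m) / (2.0 * n_g)
    ss_among = ss_total - ss_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_among / (k - 1)) / (ss_within / (n - k))
    return np.where(ss_within == 0, np.inf, f)


def permanova(
    dm,
    groups,
    n_permutations: int = 9999,
    seed: int | None = None,
    pairwise: bool = False,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a dissimilarity matrix.

    R^2 is the between-group fraction of the total sum of squared
    dissimilarities; the p-value is (1 + #{F_perm >= F_obs}) / (1 + B) under
    whole-sample-label permutation.  Pairwise mode re-runs the test on each
    group pair's sub-matrix (p-values reported unadjusted).
    """
    d, ids = _as_square(dm)
    labels = pd.Series(groups)
    if isinstance(dm, pd.DataFrame) and set(labels.index) >= set(ids):
        labels = labels.reindex(ids)
    labels = labels.to_numpy()
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    small = uniq[counts < 2]
    if small.size:
        raise ValueError(f"groups with fewer than 2 samples: {list(small)}")

    k = uniq.size
    codes = np.searchsorted(uniq, labels)
    dsq = d**2
    f_obs, r2 = _pseudo_f(dsq, codes, k)

    rng = np.random.default_rng(seed)
    n = d.shape[0]
    perms = np.argsort(rng.random((n_permutations, n)), axis=1)
    f_perm = _batch_f(dsq, codes, perms, k)
    p = (1.0 + np.sum(f_perm >= f_obs - 1e-12)) / (1.0 + n_permutations)

    pw = None
    if pairwise:
        rows = []
        id_arr = np.arange(n)
        for i in range(k):
            for j in range(i + 1, k):
                sel = id_arr[(codes == i) | (codes == j)]
                sub = pd.DataFrame(
                    d[np.ix_(sel, sel)],
                    index=[ids[s] for s in sel],
                    columns=[ids[s] for s in sel],
                )
                res = permanova(
                    sub,
                    pd.Series(labels[sel], index=[ids[s] for s in sel]),
                    n_permutations=n_permutations,
                    seed=None if seed is None else seed + 1000 * (i * k + j + 1),
                    pairwise=False,
                )
                rows.append(
                    {
                        "group_1": uniq[i],
                        "group_2": uniq[j],
                        "pseudo_f": res.pseudo_f,
                        "r_squared": res.r_squared,
                        "p_value": res.p_value,
                    }
                )
        pw = pd.DataFrame(rows)

    return PermanovaResult(
        pseudo_f=float(f_obs),
        r_squared=float(r2),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
        groups=list(uniq),
        pairwise=pw,
    )
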