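"""Alpha diversity: Shannon entropy, Pielou evenness, rarefied Chao1 richness."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import AbundanceTable


def shannon(counts) -> tuple[float, float]:
    """Shannon index H (nats) and Pielou evenness J of one count vector.

    H = -sum(p_i * ln p_i) over taxa with positive counts; J = H / ln(S_obs)
    where S_obs is the number of positive taxa.  J is NaN when S_obs = 1
    (evenness is undefined for a single taxon).
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D count vector")
    if (x < 0).any():
        raise ValueError("negative counts")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero count vector")
    p = x[x > 0] / total
    h = float(-(p * np.log(p)).sum())
    s_obs = p.size
    j = h / np.log(s_obs) if s_obs >= 2 else float("nan")
    return h, j


def chao1(counts) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1))."""
    x = np.asarray(counts)
    pos = x[x > 0]
    s_obs = pos.size
    f1 = int((pos == 1).sum())
    f2 = int((pos == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def rarefy(counts, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Subsample `depth` reads without replacement from a count vector."""
    x = np.asarray(counts, dtype=np.int64)
    total = int(x.sum())
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    if depth > total:
        raise ValueError(f"rarefaction depth {depth} exceeds sample total {total}")
    return rng.multivariate_hypergeometric(x, depth)


def chao1_rarefied(counts, depth: int, reps: int = 100, seed: int | None = None) -> float:
    """Mean bias-corrected Chao1 over `reps` seeded rarefactions to `depth`."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    return float(np.mean([chao1(rarefy(counts, depth, rng)) for _ in range(reps)]))


def alpha_diversity(
    table: AbundanceTable,
    depth: int | None = None,
    reps: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-sample diversity profile of an abundance table.

    Columns: ``shannon_h`` (nats), ``evenness_j``, ``observed_richness``,
    ``chao1_rarefied``.  The rarefaction depth defaults to the minimum sample
    total so that every sample can be subsampled without replacement.
    """
    counts = table.counts
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        empty = list(totals.index[totals == 0])
        raise ValueError(f"samples with zero total counts: {empty}")
    if depth is None:
        depth = int(totals.min())
    rows = []
    for k, sample in enumerate(counts.columns):
        vec = counts[sample].to_numpy()
        h, j = shannon(vec)
        c1 = chao1_rarefied(
            vec, depth, reps=reps, seed=None if seed is None else seed + k
        )
        rows.append(
            {
                "sample": sample,
                "shannon_h": h,
                "evenness_j": j,
                "observed_richness": int((vec > 0).sum()),
                "chao1_rarefied": c1,
            }
        )
    out = pd.DataFrame(rows).set_index("sample")
    out.attrs.update({"depth": depth, "reps": reps, "seed": seed})
    return out
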