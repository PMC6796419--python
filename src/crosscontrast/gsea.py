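"""Preranked gene-set enrichment with leading-edge extraction.

Weighted Kolmogorov-Smirnov walk over a ranked gene list: walking down the
ranking, a gene in the set ("hit") increments the running sum by its
weighted score ``|score|^p / sum_hits |score|^p``; a miss decrements by
``1/(N - N_hit)``.  The enrichment score (ES) is the maximum-magnitude
deviation of the walk, and the leading edge is the hit genes at or before
(positive ES) / at or after (negative ES) the extremum.

Significance uses a gene-sampling permutation null (random sets of the same
size drawn from the ranking), the standard choice for preranked lists; NES
divides ES by the mean |null ES| of matching sign, and permutation p-values
carry the add-one correction so p is never exactly zero.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .diffexp import bh_adjust

__all__ = ["enrichment_score", "preranked_gsea", "rank_by_score", "GSEA_COLUMNS"]

GSEA_COLUMNS = ["size", "ES", "NES", "pval", "padj", "leadingEdge"]


def rank_by_score(scores: pd.Series, descending: bool = True) -> pd.Series:
    """Deterministically ordered ranking (ties broken by gene id)."""
    order = scores.reset_index()
    gene_col, score_col = order.columns
    order = order.sort_values([score_col, gene_col],
                              ascending=[not descending, True], kind="mergesort")
    return pd.Series(order[score_col].to_numpy(), index=order[gene_col].to_numpy(),
                     name=scores.name or "score")


def enrichment_score(ranking: pd.Series, gene_set, p: float = 1.0
                     ) -> tuple[float, list[str]]:
    """ES and leading edge of one gene set against a ranked list.

    ``ranking`` must already be ordered (see :func:`rank_by_score`); scores
    must be finite.  Raises if the set intersected with the ranking is empty
    or covers the whole ranking (the miss step would be undefined).
    """
    genes = ranking.index.to_numpy()
    scores = ranking.to_numpy(dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("ranking scores must be finite")
    hit_mask = np.isin(genes, list(gene_set))
    n = len(genes)
    n_hit = int(hit_mask.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranking")
    if n_hit == n:
        raise ValueError("gene set covers the entire ranking; ES undefined")
    weights = np.abs(scores) ** p
    hit_weights = weights[hit_mask]
    wsum = hit_weights.sum()
    if wsum == 0:
        # all hit scores are exactly 0 (possible with p>0): fall back to equal steps
        hit_weights = np.ones(n_hit)
        wsum = float(n_hit)
    step = np.where(hit_mask, 0.0, -1.0 / (n - n_hit))
    step[hit_mask] = hit_weights / wsum
    running = np.cumsum(step)
    i_ext = int(np.argmax(np.abs(running)))
    es = float(running[i_ext])
    if es >= 0:
        le_mask = hit_mask & (np.arange(n) <= i_ext)
    else:
        le_mask = hit_mask & (np.arange(n) >= i_ext)
    return es, genes[le_mask].tolist()


def _null_es(weights: np.ndarray, miss: float, k: int, n_perm: int,
             rng: np.random.Generator) -> np.ndarray:
    """Vectorized null ES for random k-subsets of an N-long ranking.

    Exploits that the walk is piecewise linear between hits: the maximum
    occurs just after a hit, the minimum just before a hit (or 0 at the
    end), so only the k hit positions per permutation are needed.
    """
    n = len(weights)
    # k smallest of n iid uniforms per row = a uniform k-subset of positions
    r = rng.random((n_perm, n))
    idx = np.argpartition(r, k, axis=1)[:, :k]
    idx.sort(axis=1)
    w = weights[idx]
    wsum = w.sum(axis=1, keepdims=True)
    zero = wsum[:, 0] == 0
    if zero.any():
        w[zero] = 1.0
        wsum[zero] = k
    cum_w = np.cumsum(w, axis=1) / wsum
    j = np.arange(k)[None, :]
    misses_before = idx - j            # misses before each hit
    after_hit = cum_w - miss * misses_before
    before_hit = after_hit - w / wsum  # value just before each hit
    max_dev = after_hit.max(axis=1)
    min_dev = np.minimum(before_hit.min(axis=1), 0.0)
    return np.where(max_dev >= -min_dev, max_dev, min_dev)


def preranked_gsea(ranking: pd.Series, sets: dict[str, list[str]],
                   n_perm: int = 10000, size_bounds: tuple[int, int] = (15, 500),
                   seed: int = 0, p: float = 1.0) -> pd.DataFrame:
    """Permutation GSEA over a collection; returns a result table.

    Sets are intersected with the ranking; those outside ``size_bounds``
    are excluded (and reported via a warning).  Null distributions are
    shared between sets of equal effective size.  NES = ES / mean(|null ES|
    of matching sign); p is the one-tailed permutation probability with the
    add-one correction, BH-adjusted across the tested sets.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranking = rank_by_score(ranking) if not ranking.index.is_unique else ranking
    genes = ranking.index
    lo, hi = size_bounds
    effective: dict[str, list[str]] = {}
    skipped = []
    for name, members in sets.items():
        inter = [g for g in members if g in genes]
        if lo <= len(inter) <= hi and len(inter) < len(genes):
            effective[name] = inter
        else:
            skipped.append(name)
    if skipped:
        warnings.warn(f"{len(skipped)} gene set(s) outside size bounds "
                      f"{size_bounds} or degenerate; excluded", stacklevel=2)
    if not effective:
        warnings.warn("no gene set within size bounds; empty result", stacklevel=2)
        return pd.DataFrame(columns=GSEA_COLUMNS)

    scores = ranking.to_numpy(dtype=float)
    weights = np.abs(scores) ** p
    n = len(scores)

    rows = {}
    es_obs = {}
    le = {}
    for name, members in effective.items():
        es_obs[name], le[name] = enrichment_score(ranking, members, p=p)

    rng = np.random.default_rng(seed)
    sizes = sorted({len(v) for v in effective.values()})
    null_by_size = {}
    for k in sizes:
        miss = 1.0 / (n - k)
        null_by_size[k] = _null_es(weights, miss, k, n_perm, rng)

    for name in effective:
        k = len(effective[name])
        null = null_by_size[k]
        es = es_obs[name]
        same_sign = null >= 0 if es >= 0 else null < 0
        null_same = np.abs(null[same_sign])
        n_same = len(null_same)
        if n_same == 0:
            nes = np.nan
            pval = 1.0 / (n_perm + 1)
        else:
            mean_mag = null_same.mean()
            nes = es / mean_mag if mean_mag > 0 else np.nan
            pval = (1.0 + (null_same >= abs(es)).sum()) / (n_same + 1.0)
        rows[name] = {"size": k, "ES": es, "NES": nes, "pval": pval,
                      "leadingEdge": le[name]}

    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "pathway"
    out["padj"] = bh_adjust(out["pval"])
    return out[GSEA_COLUMNS]


def write_gsea_table(results: pd.DataFrame, path) -> None:
    out = results.copy()
    out["leadingEdge"] = out["leadingEdge"].apply(",".join)
    out.to_csv(path, sep="\t", index_label="pathway")


def read_gsea_table(path) -> pd.DataFrame:
    out = pd.read_csv(path, sep="\t", index_col=0)
    out["leadingEdge"] = out["leadingEdge"].fillna("").apply(
        lambda s: s.split(",") if s else [])
    return out
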