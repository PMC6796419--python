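"""Per-gene negative-binomial Wald differential expression.

A deliberately simplified NB GLM in the DESeq2 mold: median-of-ratios size
factors enter as an offset, per-gene dispersions are method-of-moments
estimates (optionally shrunk toward the across-gene trend), and the
condition coefficient is tested with a Wald z.  Cox-Reid adjustment, LFC
priors, independent filtering and outlier replacement are intentionally
absent; downstream analyses consume only (l2fc, se, padj, n_total).

Results use DESeq2-compatible column names: ``baseMean``,
``log2FoldChange``, ``lfcSE``, ``stat``, ``pvalue``, ``padj`` plus
``n_total``, so externally produced tables can be dropped in.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .counts_io import ContrastSpec, compute_size_factors, filter_genes

__all__ = ["estimate_dispersions", "run_contrast", "bh_adjust",
           "read_de_table", "write_de_table", "DE_COLUMNS"]

logger = logging.getLogger(__name__)

DE_COLUMNS = ["baseMean", "log2FoldChange", "lfcSE", "stat", "pvalue", "padj", "n_total"]

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs propagate untouched."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def estimate_dispersions(counts: pd.DataFrame, design: pd.DataFrame,
                         size_factors: pd.Series, *, prior_df: float = 10.0,
                         n_bins: int = 20,
                         floor: float = DISPERSION_FLOOR) -> pd.Series:
    """Method-of-moments NB dispersions with shrinkage to the mean-dispersion trend.

    For each gene, fitted means come from a linear projection of the
    normalized counts onto the design; the moments estimator
    ``alpha = sum((y - m)^2 - m/s) / sum(m^2)`` (with an n/dof residual
    degrees-of-freedom correction) supplies the gene-wise evidence.  A
    mean-dispersion trend is estimated by averaging the raw (possibly
    negative, hence unbiased) gene-wise estimates within ``n_bins``
    expression bins, and each gene's log dispersion is a dof-weighted
    average of its own estimate and the trend:

        log alpha = (dof * log alpha_gene + prior_df * log alpha_trend)
                    / (dof + prior_df).

    With one or two residual degrees of freedom (tiny contrasts) the trend
    dominates, which is what makes the downstream Wald tests usable there;
    with many samples the gene-wise estimate dominates.  Genes with
    sub-Poisson residual variance get the floor as their gene-wise value.
    """
    X = design.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("dispersion estimation needs >= 2 samples")
    sf = size_factors.loc[counts.columns].to_numpy()
    y = counts.to_numpy(dtype=float) / sf[None, :]
    # hat matrix of the design; fitted means on the normalized scale
    hat = X @ np.linalg.pinv(X)
    m = np.maximum(y @ hat.T, 1e-8)
    dof = n - np.linalg.matrix_rank(X)
    if dof < 1:
        raise ValueError("design is saturated: no residual degrees of freedom "
                         "to estimate dispersions from")
    resid2 = (y - m) ** 2
    # on the normalized scale var(y_j) = m_j/s_j + alpha m_j^2
    num = (resid2 * (n / dof) - m / sf[None, :]).sum(axis=1)
    den = (m ** 2).sum(axis=1)
    alpha_raw = np.where(den > 0, num / den, 0.0)

    # mean-dispersion trend: binned means of the raw estimates over expression
    mu_bar = m.mean(axis=1)
    order = np.argsort(mu_bar, kind="mergesort")
    n_genes = len(mu_bar)
    bins = min(n_bins, max(1, n_genes // 10))
    edges = np.array_split(order, bins)
    trend = np.empty(n_genes)
    for chunk in edges:
        trend[chunk] = max(float(np.mean(alpha_raw[chunk])), floor)

    gene_wise = np.maximum(alpha_raw, floor)
    w = dof / (dof + prior_df)
    alpha = np.exp(w * np.log(gene_wise) + (1.0 - w) * np.log(trend))
    return pd.Series(np.maximum(alpha, floor), index=counts.index, name="alpha")


CONDITION_VIF_LIMIT = 5.0


def _condition_vif(cols: dict[str, np.ndarray]) -> float:
    """Variance inflation factor of the condition column given the others."""
    others = np.column_stack([v for k, v in cols.items() if k != "condition"])
    cond = cols["condition"]
    beta, *_ = np.linalg.lstsq(others, cond, rcond=None)
    resid = cond - others @ beta
    total = ((cond - cond.mean()) ** 2).sum()
    if total == 0:
        return np.inf
    r2 = 1.0 - (resid ** 2).sum() / total
    return np.inf if r2 >= 1 else 1.0 / (1.0 - r2)


def _build_design(meta: pd.DataFrame, a: list[str], b: list[str],
                  covariates: tuple[str, ...]) -> pd.DataFrame:
    """Design matrix: intercept, condition (1 for side A), then covariates.

    Age is z-scored; sex coded 0/1.  Covariates that are constant or
    collinear with the earlier columns are dropped with a warning, as are
    covariates confounded with the condition: if the condition column's
    variance inflation factor exceeds ``CONDITION_VIF_LIMIT`` (the usual
    VIF-5 convention), covariates are removed greedily, worst offender
    first, until it does not.  In a 2-vs-3 contrast an unlucky age or sex
    split can otherwise multiply the condition standard error severalfold.
    """
    samples = list(a) + list(b)
    sub = meta.loc[samples]
    cols: dict[str, np.ndarray] = {
        "intercept": np.ones(len(samples)),
        "condition": np.array([1.0] * len(a) + [0.0] * len(b)),
    }
    for cov in covariates:
        if cov not in sub.columns:
            raise ValueError(f"covariate column {cov!r} missing from metadata")
        col = sub[cov]
        if col.dtype == object or str(col.dtype) == "category":
            levels = sorted(col.astype(str).unique())
            if len(levels) > 2:
                raise ValueError(f"covariate {cov!r} has >2 levels; encode it numerically")
            vals = (col.astype(str) == levels[-1]).to_numpy(float)
        else:
            vals = col.to_numpy(float)
            sd = vals.std()
            vals = (vals - vals.mean()) / sd if sd > 0 else vals * 0.0
        X = np.column_stack(list(cols.values()))
        candidate = np.column_stack([X, vals])
        if np.linalg.matrix_rank(candidate) <= np.linalg.matrix_rank(X):
            logger.warning("dropping covariate %r: collinear with design", cov)
            continue
        cols[cov] = vals
    # a saturated design leaves no residual degrees of freedom to estimate
    # dispersion from: drop covariates (last added first) until >= 1 remains
    while len(cols) > 2 and len(samples) - len(cols) < 1:
        dropped = list(cols)[-1]
        logger.warning("dropping covariate %r: design would be saturated "
                       "(n=%d)", dropped, len(samples))
        del cols[dropped]
    # guard against covariates confounded with the condition
    while len(cols) > 2 and _condition_vif(cols) > CONDITION_VIF_LIMIT:
        candidates = [k for k in cols if k not in ("intercept", "condition")]
        vifs = {}
        for k in candidates:
            reduced = {kk: v for kk, v in cols.items() if kk != k}
            vifs[k] = _condition_vif(reduced)
        worst = min(candidates, key=lambda k: vifs[k])
        logger.warning("dropping covariate %r: confounded with condition "
                       "(VIF %.2f -> %.2f)", worst, _condition_vif(cols), vifs[worst])
        del cols[worst]
    return pd.DataFrame(cols, index=samples)


def run_contrast(counts: pd.DataFrame, meta: pd.DataFrame, spec: ContrastSpec,
                 *, size_factors: pd.Series | None = None,
                 dispersions: pd.Series | None = None) -> pd.DataFrame:
    """Fit the NB Wald model for one contrast; returns a DE table.

    ``size_factors`` should normally be computed once on the full study
    matrix (they are computed from ``counts`` if omitted).  The gene filter
    of ``spec.filter_rule`` is applied to the contrast's samples before
    fitting; BH adjustment runs over all tested genes.
    """
    a, b = spec.samples(meta)
    samples = a + b
    if size_factors is None:
        size_factors = compute_size_factors(counts)
    keep = filter_genes(counts, {"A": a, "B": b}, spec.filter_rule)
    sub = counts.loc[keep, samples]
    design = _build_design(meta, a, b, spec.covariates)
    sf = size_factors.loc[samples]
    if dispersions is None:
        dispersions = estimate_dispersions(sub, design, sf)
    X = design.to_numpy()
    offset = np.log(sf.to_numpy())
    cond_idx = design.columns.get_loc("condition")
    norm = sub.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    base_mean = norm.mean(axis=1)

    l2fc = np.full(len(keep), np.nan)
    se = np.full(len(keep), np.nan)
    wald = np.full(len(keep), np.nan)
    pval = np.full(len(keep), np.nan)
    y_all = sub.to_numpy()
    for i, gene in enumerate(keep):
        y = y_all[i]
        alpha = max(float(dispersions.loc[gene]), DISPERSION_FLOOR)
        try:
            model = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=alpha),
                           offset=offset)
            with warnings.catch_warnings():
                # saturated designs (tiny contrasts) emit harmless scale
                # warnings; separation is handled via the SE guard below
                warnings.simplefilter("ignore")
                fit = model.fit(maxiter=100, tol=1e-8)
            if not np.all(np.isfinite(fit.params)) or not np.all(np.isfinite(fit.bse)):
                raise ValueError("non-finite fit")
        except (PerfectSeparationError, ValueError, np.linalg.LinAlgError):
            logger.warning("contrast %s: gene %s did not converge", spec.name, gene)
            continue
        coef = fit.params[cond_idx]
        bse = fit.bse[cond_idx]
        if bse <= 0 or not np.isfinite(bse):
            continue
        if bse > 10.0:
            # quasi-separation (e.g. a condition cell with all-zero counts):
            # the MLE diverges and the estimate carries no information
            logger.warning("contrast %s: gene %s separated (se=%.3g); flagged",
                           spec.name, gene, bse)
            continue
        l2fc[i] = coef / LN2
        se[i] = bse / LN2
        wald[i] = coef / bse
        pval[i] = 2.0 * stats.norm.sf(abs(wald[i]))

    out = pd.DataFrame({
        "baseMean": base_mean,
        "log2FoldChange": l2fc,
        "lfcSE": se,
        "stat": wald,
        "pvalue": pval,
        "padj": bh_adjust(pval),
        "n_total": len(samples),
    }, index=pd.Index(keep, name="gene_id"))
    return out


def write_de_table(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index_label="gene_id")


def read_de_table(path) -> pd.DataFrame:
    """Read a DE table (ours or external DESeq2-style output plus n_total)."""
    de = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in DE_COLUMNS if c not in de.columns]
    if missing:
        raise ValueError(f"DE table missing column(s): {missing}")
    return de
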