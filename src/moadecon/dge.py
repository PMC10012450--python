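"""Factorial differential expression with within-gene FWER control and the
max-of-minima (p*) significance resolution rule.

Per gene, an ordinary least-squares treatment-by-timepoint cell-means
model (plus a plate covariate when more than one plate is present)
yields the within-timepoint treatment contrasts.  Family-wise error over
the contrasts within each gene is controlled by a single-step max-|t|
adjustment (Monte-Carlo from the joint multivariate t implied by the
contrast covariance); the per-gene minimum adjusted p-values are then
Benjamini-Hochberg corrected across genes, and the threshold p* — the
largest within-gene minimum among genes passing FDR — resolves which
individual contrasts are significant overall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class InputError(ValueError):
    """Invalid input table or design."""


# -- quantile normalisation -------------------------------------------------


def normalize_quantile(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalise samples (columns) of a log2 expression matrix.

    Every column receives the same sorted values: the row-wise mean of
    the per-column sorted values.  Ties within a column share the mean
    of the values at their would-be quantiles (average ranks are mapped
    by linear interpolation).
    """
    if matrix.shape[1] < 2:
        raise InputError("quantile normalisation needs at least 2 samples")
    x = matrix.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise InputError("expression matrix contains non-finite values")
    mean_sorted = np.sort(x, axis=0).mean(axis=1)
    n = x.shape[0]
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = stats.rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), mean_sorted)
    res = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    res.attrs.update(matrix.attrs)
    return res


# -- factorial model ---------------------------------------------------------


@dataclass
class ContrastFit:
    """Per-gene contrast estimates from the factorial OLS fit."""

    genes: list[str]
    contrasts: list[str]  # e.g. "compound_vs_vehicle@DIV14"
    estimate: np.ndarray  # genes x contrasts
    se: np.ndarray  # genes x contrasts
    tstat: np.ndarray  # genes x contrasts
    p_raw: np.ndarray  # genes x contrasts
    df_resid: float
    corr: np.ndarray  # contrasts x contrasts, shared across genes
    sigma2: np.ndarray  # per-gene residual variance
    metadata: dict


def _design_matrix(design: pd.DataFrame) -> tuple[np.ndarray, list[str], list[str]]:
    """Cell-means design for treatment x DIV plus plate dummies."""
    cells = (
        design["treatment"].astype(str) + "@DIV" + design["div"].astype(str)
    ).tolist()
    cell_levels = sorted(set(cells))
    cols = [[1.0 if c == lvl else 0.0 for c in cells] for lvl in cell_levels]
    names = list(cell_levels)
    plates = sorted(design["plate"].astype(str).unique())
    for p in plates[1:]:
        cols.append([1.0 if v == p else 0.0 for v in design["plate"].astype(str)])
        names.append(f"plate[{p}]")
    X = np.array(cols).T
    return X, names, cell_levels


def fit_factorial_model(matrix: pd.DataFrame, design: pd.DataFrame) -> ContrastFit:
    """OLS treatment x DIV factorial fit, one model per gene.

    Returns the within-DIV treatment contrasts (compound - vehicle at
    each DIV) with estimates, standard errors, residual df and the
    shared contrast correlation structure.
    """
    missing = set(matrix.columns) - set(design["sample"])
    if missing:
        raise InputError(f"design does not cover samples: {sorted(missing)}")
    design = design.set_index("sample").loc[list(matrix.columns)].reset_index()
    counts = design.groupby(["treatment", "div"]).size()
    if (counts < 1).any():  # pragma: no cover - groupby omits empty cells
        raise InputError("every treatment x DIV cell must be non-empty")

    X, names, cell_levels = _design_matrix(design)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the aliased columns via the QR diagonal
        _, R = np.linalg.qr(X)
        aliased = [names[i] for i in range(p) if abs(R[i, i]) < 1e-8]
        raise InputError(f"rank-deficient design; aliased terms: {aliased}")

    Y = matrix.to_numpy(dtype=float).T  # samples x genes
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y  # p x genes
    resid = Y - X @ B
    df = n - rank
    if df <= 0:
        raise InputError("no residual degrees of freedom")
    sigma2 = (resid**2).sum(axis=0) / df

    divs = sorted(design["div"].unique())
    treatments = sorted(design["treatment"].unique())
    if len(treatments) != 2:
        raise InputError("expected exactly two treatment levels")
    ref, alt = treatments[0], treatments[1]
    if alt == "vehicle" or ref == "compound":  # keep compound - vehicle direction
        ref, alt = alt, ref
    C = np.zeros((len(divs), p))
    labels = []
    for i, d in enumerate(divs):
        C[i, names.index(f"{alt}@DIV{d}")] = 1.0
        C[i, names.index(f"{ref}@DIV{d}")] = -1.0
        labels.append(f"{alt}_vs_{ref}@DIV{d}")

    est = (C @ B).T  # genes x contrasts
    covC = C @ XtX_inv @ C.T  # unit-variance contrast covariance
    d = np.sqrt(np.diag(covC))
    corr = covC / np.outer(d, d)
    se = np.sqrt(np.outer(sigma2, np.diag(covC)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / se
    t[np.isnan(t)] = 0.0  # 0/0: no effect, no noise
    p_raw = 2 * stats.t.sf(np.abs(t), df)
    return ContrastFit(
        genes=list(matrix.index),
        contrasts=labels,
        estimate=est,
        se=se,
        tstat=t,
        p_raw=p_raw,
        df_resid=float(df),
        corr=corr,
        sigma2=sigma2,
        metadata={
            "n_samples": n,
            "n_plates": int(design["plate"].nunique()),
            "plate_covariate": design["plate"].nunique() > 1,
            "note": "plate modelled as a fixed covariate (not a random effect)",
        },
    )


# -- within-gene FWER ---------------------------------------------------------


def adjust_within_gene(
    fit: ContrastFit,
    n_draws: int = 20_000,
    seed: int = 0,
    corr: np.ndarray | None = None,
) -> np.ndarray:
    """Single-step max-|t| FWER adjustment within each gene's contrast family.

    The adjusted p of contrast j is P(max over the family of |T| >= |t_j|)
    under the joint null, estimated by Monte-Carlo from the multivariate
    t distribution implied by the shared contrast correlation and the
    residual df.  The draw is shared across genes (the family structure
    is identical), and the result is floored at the raw p so that
    adjusted >= raw always holds.
    """
    if n_draws < 1000:
        logger.warning("n_draws=%d is below 1000; FWER adjustment will be noisy", n_draws)
    R = fit.corr if corr is None else corr
    m = R.shape[0]
    if m == 1:  # degenerate family: nothing to adjust for
        return fit.p_raw.copy()
    rng = np.random.default_rng(seed)
    # nearest-PSD safeguard for numerically indefinite correlation matrices
    w, V = np.linalg.eigh(R)
    L = V @ np.diag(np.sqrt(np.clip(w, 0, None)))
    Z = rng.standard_normal((n_draws, m)) @ L.T
    chi = rng.chisquare(fit.df_resid, size=n_draws)
    T = Z / np.sqrt(chi / fit.df_resid)[:, None]
    max_t = np.sort(np.abs(T).max(axis=1))
    abst = np.abs(fit.tstat)
    # P(maxT >= |t|) via binary search on the sorted null draws
    idx = np.searchsorted(max_t, abst, side="left")
    p_adj = (n_draws - idx) / n_draws
    p_adj = np.maximum(p_adj, fit.p_raw)
    p_adj[np.isinf(abst)] = 0.0
    fit.metadata["fwer"] = {"n_draws": n_draws, "seed": seed, "method": "max-|t| Monte-Carlo"}
    return np.minimum(p_adj, 1.0)


# -- p* resolution -------------------------------------------------------------


@dataclass
class PStarResult:
    p_star: float | None
    fdr_threshold: float
    gene_q: pd.Series  # per-gene BH q on the minimum FWER p
    table: pd.DataFrame  # gene x contrast rows with significance flags


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    return multipletests(p, method="fdr_bh")[1]


def contrast_table(fit: ContrastFit, p_fwer: np.ndarray) -> pd.DataFrame:
    """Long-format contrast table: one row per gene x contrast."""
    rows = []
    for i, g in enumerate(fit.genes):
        for j, c in enumerate(fit.contrasts):
            rows.append(
                {
                    "gene": g,
                    "contrast": c,
                    "log2fc": fit.estimate[i, j],
                    "se": fit.se[i, j],
                    "p_raw": fit.p_raw[i, j],
                    "p_fwer": p_fwer[i, j],
                }
            )
    return pd.DataFrame(rows)


def pstar_procedure(table: pd.DataFrame, fdr: float = 0.05) -> PStarResult:
    """Resolve contrast-level significance with the max-of-minima rule.

    Per gene the minimum FWER-adjusted p is taken; these minima are BH
    adjusted across genes; p* is the largest minimum among genes passing
    FDR < ``fdr``; a contrast is significant iff its FWER p <= p*.  The
    boundary is inclusive so the gene that defines p* is itself
    significant.  When no gene passes FDR, p* is undefined and nothing
    is significant.
    """
    if table.empty:
        raise InputError("empty contrast table")
    if table["p_fwer"].isna().any():
        raise InputError("FWER p-values must be present for all contrasts")
    minima = table.groupby("gene")["p_fwer"].min()
    q = pd.Series(benjamini_hochberg(minima.to_numpy()), index=minima.index)
    passing = q[q < fdr]
    out = table.copy()
    out["gene_q"] = q.loc[out["gene"]].to_numpy()
    if passing.empty:
        p_star = None
        out["significant"] = False
    else:
        p_star = float(minima.loc[passing.index].max())
        out["significant"] = out["p_fwer"] <= p_star
    return PStarResult(p_star=p_star, fdr_threshold=fdr, gene_q=q, table=out)


# -- DEG selection --------------------------------------------------------------


def select_degs(
    table: pd.DataFrame,
    lfc_min: float = 1.5,
    p_max: float = 0.05,
    p_col: str = "p_fwer",
) -> pd.DataFrame:
    """Differentially expressed genes: |log2FC| >= lfc_min and adjusted
    p <= p_max (both boundaries inclusive), with direction recorded."""
    keep = (table["log2fc"].abs() >= lfc_min) & (table[p_col] <= p_max)
    out = table.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


def run_dge(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    n_draws: int = 20_000,
    seed: int = 0,
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, PStarResult, ContrastFit]:
    """Quantile-normalise, fit, FWER-adjust and resolve significance.

    Convenience wrapper returning (contrast table with flags, p* result,
    underlying fit).
    """
    norm = normalize_quantile(matrix)
    fit = fit_factorial_model(norm, design)
    p_fwer = adjust_within_gene(fit, n_draws=n_draws, seed=seed)
    table = contrast_table(fit, p_fwer)
    res = pstar_procedure(table, fdr=fdr)
    return res.table, res, fit
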