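"""Transcription-factor activity and pathway scoring from gene statistics.

TF activity is a significance-gated weighted sum over the TF's regulon:
genes failing the p gate contribute 0, the rest their log2FC times the
regulon sign.  The raw score is normalised to a z-like NES against a
gene-label permutation null, and discretised to {-1, 0, +1} for use as
causal-reasoning input.  Pathway scores are plain weighted sums of gene
z-statistics with a coefficient matrix.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: minimum measured targets before a regulon score is considered reliable
LOW_CONFIDENCE_TARGETS = 3


class ActivityError(ValueError):
    pass


def tf_activity(
    measurements: pd.DataFrame,
    regulons: pd.DataFrame,
    p_gate: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    gene_col: str = "gene",
    lfc_col: str = "log2fc",
    p_col: str = "p_fwer",
) -> pd.DataFrame:
    """Permutation-normalised regulon activity scores per TF.

    ``measurements`` has one row per gene with log2FC and a p-value;
    ``regulons`` has columns (tf, target, sign).  The gene statistic is
    the log2FC where p <= ``p_gate`` and 0 otherwise; raw score(t) =
    sum over measured targets of sign * statistic; the NES is the raw
    score standardised against ``n_perm`` permutations of gene labels.
    Regulons with no measured target are omitted (logged); those with
    fewer than 3 are flagged low-confidence.
    """
    meas = measurements.set_index(gene_col)
    x = np.where(meas[p_col] <= p_gate, meas[lfc_col], 0.0)
    gene_index = {g: i for i, g in enumerate(meas.index)}

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(x) for _ in range(n_perm)])

    rows = []
    for tf, grp in regulons.groupby("tf", sort=True):
        grp = grp.drop_duplicates(subset=["tf", "target"])
        idx = [gene_index[t] for t in grp["target"] if t in gene_index]
        w = np.array(
            [s for t, s in zip(grp["target"], grp["sign"]) if t in gene_index],
            dtype=float,
        )
        if not idx:
            logger.info("regulon %s has no measured targets; omitted", tf)
            continue
        raw = float(w @ x[idx])
        null = perms[:, idx] @ w
        sd = null.std()
        nes = (raw - null.mean()) / sd if sd > 0 else 0.0
        rows.append(
            {
                "entity": tf,
                "raw": raw,
                "nes": float(nes),
                "n_targets": len(idx),
                "low_confidence": len(idx) < LOW_CONFIDENCE_TARGETS,
            }
        )
    return pd.DataFrame(rows, columns=["entity", "raw", "nes", "n_targets", "low_confidence"])


def pathway_scores(
    z: pd.Series,
    coefficients: pd.DataFrame,
) -> pd.DataFrame:
    """Pathway scores: score(p) = sum_g c_{p,g} * z_g.

    ``coefficients`` is pathways x genes; genes missing from ``z``
    contribute 0.  Raises when no coefficient gene is measured.
    """
    common = coefficients.columns.intersection(z.index)
    if common.empty:
        raise ActivityError("no overlap between coefficient genes and measurements")
    scores = coefficients[common].to_numpy() @ z.loc[common].to_numpy()
    return pd.DataFrame({"entity": coefficients.index, "raw": scores})


def discretize(
    activity: pd.DataFrame, z_thresh: float = 1.96, col: str = "nes"
) -> pd.DataFrame:
    """Discretise activity scores to {-1, 0, +1} at +-``z_thresh``
    (boundary inclusive): the causal-reasoning input encoding where +1
    is activation, -1 inactivation and 0 no change."""
    out = activity.copy()
    v = out[col].to_numpy()
    out["state"] = np.where(v >= z_thresh, 1, np.where(v <= -z_thresh, -1, 0))
    return out
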