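"""Cross-species identifier mapping with expansion and averaging rules.

A source-namespace measurement table (per-gene log2FC and p) is carried
into the target namespace through an ortholog map: a source gene mapping
to several targets is expanded to one row per target; several source
genes sharing a target are aggregated by the arithmetic mean of both the
log2FC and the p-value.  Averaging p-values is statistically improper
but is the convention this pipeline reproduces; a Fisher-combination
alternative is available behind a flag.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class MappingError(ValueError):
    pass


def map_measurements(
    table: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    gene_col: str = "gene",
    source_col: str = "rat_id",
    target_col: str = "human_id",
    combine_p: str = "mean",
) -> tuple[pd.DataFrame, dict]:
    """Map a per-gene measurement table into the target namespace.

    Expansion happens first (1:many source->target duplicates the row
    per target), aggregation second (many:1 rows are averaged), in a
    single pass.  Unmapped source ids are dropped and counted in the
    returned report.  ``combine_p`` is ``"mean"`` (the reproduced
    convention) or ``"fisher"``.

    Returns ``(mapped table keyed by target id, report dict)``.
    """
    if ortholog_map.empty:
        raise MappingError("empty ortholog map")
    omap = ortholog_map[[source_col, target_col]].drop_duplicates()
    merged = table.merge(omap, left_on=gene_col, right_on=source_col, how="left")
    unmapped = merged[merged[target_col].isna()][gene_col].unique().tolist()
    merged = merged.dropna(subset=[target_col])

    value_cols = [c for c in ("log2fc",) if c in table.columns]
    p_cols = [c for c in table.columns if c == "p" or c.startswith("p_")]

    def _combine_p(x: pd.Series) -> float:
        if combine_p == "fisher":
            stat = -2 * np.sum(np.log(np.clip(x, 1e-300, 1.0)))
            return float(stats.chi2.sf(stat, 2 * len(x)))
        return float(np.mean(x))

    agg = {c: "mean" for c in value_cols}
    agg.update({c: _combine_p for c in p_cols})
    out = (
        merged.groupby(target_col, sort=True)
        .agg(agg)
        .reset_index()
        .rename(columns={target_col: gene_col})
    )
    report = {
        "n_source": int(table[gene_col].nunique()),
        "n_unmapped": len(unmapped),
        "unmapped": sorted(unmapped),
        "n_target": int(out[gene_col].nunique()),
        "combine_p": combine_p,
    }
    if unmapped:
        logger.info("dropped %d unmapped source ids", len(unmapped))
    return out, report
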