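"""Evidence integration: reversal analysis, the three-stream evidence
matrix and process-hypothesis ranking.

A biological process collects evidence from up to three independent
streams — predicted compound targets, pooled causal-reasoning
regulators, and enriched pathways — through an explicit process map
(process -> associated genes and pathway ids).  The process map is a
versioned input so the integration is reproducible and auditable.
Processes are ranked by how many streams support them.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class IntegrationError(ValueError):
    pass


# -- reversal analysis ----------------------------------------------------------


def reversal_analysis(
    seed_signature: pd.DataFrame,
    treatment_signature: pd.DataFrame,
    gene_col: str = "gene",
) -> pd.DataFrame:
    """Classify genes by how a treatment signature relates to a disease
    (seed) signature at the same timepoint.

    Both inputs need columns (gene, log2fc, significant).  Genes
    significant in both with opposite log2FC signs are ``reversed-down``
    (seed-up, treated-down) or ``reversed-up``; same signs are
    ``concordant``; significant in exactly one are ``single-sided``.
    Genes significant in neither are omitted.
    """
    s = seed_signature.set_index(gene_col)
    t = treatment_signature.set_index(gene_col)
    genes = s.index.union(t.index)
    rows = []
    for g in genes:
        s_sig = g in s.index and bool(s.loc[g, "significant"])
        t_sig = g in t.index and bool(t.loc[g, "significant"])
        if not s_sig and not t_sig:
            continue
        s_fc = float(s.loc[g, "log2fc"]) if g in s.index else np.nan
        t_fc = float(t.loc[g, "log2fc"]) if g in t.index else np.nan
        if s_sig and t_sig:
            if s_fc > 0 and t_fc < 0:
                cls = "reversed-down"
            elif s_fc < 0 and t_fc > 0:
                cls = "reversed-up"
            else:
                cls = "concordant"
        else:
            cls = "single-sided"
        rows.append(
            {gene_col: g, "seed_log2fc": s_fc, "treatment_log2fc": t_fc, "class": cls}
        )
    return pd.DataFrame(rows, columns=[gene_col, "seed_log2fc", "treatment_log2fc", "class"])


# -- evidence matrix -------------------------------------------------------------


def build_evidence_matrix(
    predictions: pd.DataFrame,
    regulators: Iterable[str],
    enrichments: pd.DataFrame,
    process_map: Mapping[str, Mapping[str, Iterable[str]]],
    prob_min: float = 0.3,
    ad_min: float = 50.0,
) -> pd.DataFrame:
    """Assemble per-process evidence from the three analysis streams.

    ``process_map`` maps a process label to {"genes": ..., "pathways":
    ...}.  A process receives target-stream evidence when a predicted
    target with probability >= ``prob_min`` and applicability percentile
    >= ``ad_min`` is among its genes; regulator-stream evidence when a
    pooled causal-reasoning regulator is; pathway-stream evidence when a
    significantly enriched pathway id is among its pathways.
    """
    if not process_map:
        raise IntegrationError("empty process map")
    confident = predictions[
        (predictions["probability"] >= prob_min)
        & (predictions["ad_percentile"] >= ad_min)
    ]
    predicted = set(confident["target_id"])
    regulators = set(regulators)
    enriched = set(enrichments.loc[enrichments["significant"], "set_id"])
    rows = []
    for process in process_map:
        genes = set(process_map[process].get("genes", ()))
        pathways = set(process_map[process].get("pathways", ()))
        targets_hit = sorted(predicted & genes)
        regs_hit = sorted(regulators & genes)
        paths_hit = sorted(enriched & pathways)
        streams = sum(bool(x) for x in (targets_hit, regs_hit, paths_hit))
        rows.append(
            {
                "process": process,
                "predicted_targets": targets_hit,
                "consensus_regulators": regs_hit,
                "enriched_pathways": paths_hit,
                "stream_count": streams,
            }
        )
    return pd.DataFrame(rows)


def rank_process_hypotheses(matrix: pd.DataFrame) -> tuple[pd.DataFrame, str]:
    """Rank processes by stream count, then total evidence items, then label.

    Returns the headline table (zero-stream processes excluded) and a
    status string ("ok" or "no consensus" when nothing has evidence).
    """
    m = matrix.copy()
    m["n_items"] = (
        m["predicted_targets"].map(len)
        + m["consensus_regulators"].map(len)
        + m["enriched_pathways"].map(len)
    )
    m = m.sort_values(
        ["stream_count", "n_items", "process"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    headline = m[m["stream_count"] > 0].reset_index(drop=True)
    status = "ok" if not headline.empty else "no consensus"
    return headline, status
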