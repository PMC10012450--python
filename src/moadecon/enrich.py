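"""Over-representation analysis, cross-experiment overlap coefficients and
disease-gene overlap tests.

Enrichment is tested one-sided (over-representation only) against the
measured background with the hypergeometric upper tail, BH-adjusted
within each collection.  The overlap coefficient between two enriched-
pathway sets is |A n B| / min(|A|, |B|).  Disease association of a DEG
set is a two-sided Fisher exact test on the 2x2 table over the measured
background, after unioning the disease lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .dge import benjamini_hochberg


class EnrichmentError(ValueError):
    pass


def overrepresentation(
    query: set[str],
    background: set[str],
    sets: Mapping[str, Iterable[str]],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Sets are intersected with the background before testing; the
    background must contain the query.  Returns one row per set with
    overlap counts, the upper-tail p and the BH-adjusted p, sorted by p.
    """
    if not background:
        raise EnrichmentError("empty background")
    if not query <= background:
        raise EnrichmentError("query must be a subset of the background")
    M = len(background)
    N = len(query)
    rows = []
    for set_id in sets:
        members = set(sets[set_id]) & background
        n = len(members)
        k = len(members & query)
        # P(X >= k) for X ~ Hypergeom(M, n, N)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if N else 1.0
        rows.append(
            {"set_id": set_id, "set_size": n, "query_size": N, "overlap": k, "p_value": min(p, 1.0)}
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = benjamini_hochberg(df["p_value"].to_numpy())
    df["significant"] = df["p_adjusted"] <= fdr
    return df.sort_values(["p_value", "set_id"], kind="mergesort").reset_index(drop=True)


@dataclass
class OverlapStats:
    intersection: int
    coefficient: float
    undefined: bool = False

    @property
    def rounded(self) -> float:
        """Coefficient to two decimals, the reporting convention."""
        return round(self.coefficient, 2)


def overlap_coefficient(set_a: Iterable[str], set_b: Iterable[str]) -> OverlapStats:
    """Overlap (Szymkiewicz-Simpson) coefficient |A n B| / min(|A|, |B|).

    Undefined for an empty input set; reported as 0 with the
    ``undefined`` flag raised.
    """
    a, b = set(set_a), set(set_b)
    inter = len(a & b)
    if not a or not b:
        return OverlapStats(intersection=inter, coefficient=0.0, undefined=True)
    return OverlapStats(intersection=inter, coefficient=inter / min(len(a), len(b)))


def overlap_matrix(named_sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Pairwise intersection counts and overlap coefficients between
    experiments' significant-pathway sets."""
    rows = []
    names = list(named_sets)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            st = overlap_coefficient(named_sets[a], named_sets[b])
            rows.append(
                {
                    "experiment_1": a,
                    "experiment_2": b,
                    "shared": st.intersection,
                    "overlap_coefficient": st.rounded,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class DiseaseOverlap:
    table: np.ndarray  # 2x2: [[deg&dis, deg&~dis], [~deg&dis, ~deg&~dis]]
    odds_ratio: float
    p_value: float
    union_size: int
    haldane: bool = False


def disease_overlap(
    degs: set[str],
    disease_lists: Iterable[Iterable[str]],
    background: set[str],
) -> DiseaseOverlap:
    """Fisher exact overlap between a DEG set and unioned disease lists.

    All sets are intersected with the measured background.  The sample
    odds ratio uses a Haldane 0.5 continuity correction only when a cell
    is zero; the p-value is the two-sided Fisher exact test.
    """
    union: set[str] = set()
    for lst in disease_lists:
        union |= set(lst)
    if len(union) > len(background):
        raise EnrichmentError("background smaller than the union of disease lists")
    degs = degs & background
    disease = union & background
    a = len(degs & disease)
    b = len(degs - disease)
    c = len(disease - degs)
    d = len(background) - a - b - c
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    haldane = (table == 0).any()
    t = table + 0.5 if haldane else table.astype(float)
    oratio = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return DiseaseOverlap(
        table=table,
        odds_ratio=float(oratio),
        p_value=float(p),
        union_size=len(union),
        haldane=haldane,
    )


def collapse_redundant(
    sets: Mapping[str, set[str]], jaccard_min: float = 0.9
) -> dict[str, set[str]]:
    """Optional readability filter: greedily merge sets whose Jaccard
    similarity is at least ``jaccard_min`` (keeps the first id)."""
    kept: dict[str, set[str]] = {}
    for sid in sets:
        members = set(sets[sid])
        for existing in kept.values():
            j = len(members & existing) / len(members | existing) if members | existing else 1.0
            if j >= jaccard_min:
                existing |= members
                break
        else:
            kept[sid] = set(members)
    return kept
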