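"""Synthetic-data generation with planted ground truth.

Emulates a two-treatment (vehicle vs compound) by three-timepoint
(days in vitro 3, 7, 14) factorial expression experiment on a signed
protein network: planted upstream regulators perturb their downstream
genes, gene sets are built to be enriched in the perturbed genes, and
annotation inputs (ortholog map, disease gene list, TF regulons, pathway
coefficients, a bioactivity corpus) are generated consistently with the
network.  Everything downstream of the generators is therefore testable
against a known answer, offline.

Expression is generated directly on the log2 scale (Gaussian): the
analysis consumes log2 gene-level abundances, so a count-level generator
is deliberately out of scope.  Gene identifiers are synthetic strings
("G0001" in the source/rat namespace, "HG0001" in the target/human
namespace).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .causal import predict_downstream
from .network import SignedNetwork

#: effect size at DIV d is scaled by d / max(DIV): differential expression
#: builds up over time in culture, matching the qualitative pattern of DEG
#: counts growing with treatment duration.
DEFAULT_DIVS = (3, 7, 14)


class ParameterError(ValueError):
    """Invalid generator parameter."""


@dataclass
class GroundTruth:
    """Everything that was planted, for downstream verification."""

    planted_regulators: set[tuple[str, int]]
    effect_size: float
    perturbed_genes: dict[str, int]  # gene -> expected log2FC sign
    enriched_sets: list[str] = field(default_factory=list)
    active_targets: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        mio.write_run_log(
            {
                "planted_regulators": sorted(self.planted_regulators),
                "effect_size": self.effect_size,
                "perturbed_genes": self.perturbed_genes,
                "enriched_sets": self.enriched_sets,
                "active_targets": sorted(self.active_targets),
            },
            path,
        )


# -- network -------------------------------------------------------------


def simulate_network(
    n_nodes: int,
    mean_out_degree: float = 3.0,
    inhibitory_fraction: float = 0.3,
    seed: int = 0,
) -> SignedNetwork:
    """Random signed directed network.

    Every node gets out-degree ``1 + Poisson(mean_out_degree - 1)`` (so
    the expectation is ``mean_out_degree`` and every node has at least
    one target), targets drawn without replacement among the other
    nodes, and each edge is inhibitory with probability
    ``inhibitory_fraction``.  Deterministic for a fixed seed.
    """
    if n_nodes < 2:
        raise ParameterError(f"need at least 2 nodes, got {n_nodes}")
    if mean_out_degree < 1:
        raise ParameterError("mean_out_degree must be >= 1")
    if not 0 <= inhibitory_fraction <= 1:
        raise ParameterError("inhibitory_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    nodes = [f"G{i:04d}" for i in range(n_nodes)]
    net = SignedNetwork.from_edges([], nodes=nodes)
    idx = np.arange(n_nodes)
    for i, u in enumerate(nodes):
        k = 1 + rng.poisson(mean_out_degree - 1)
        k = min(k, n_nodes - 1)
        others = np.delete(idx, i)
        targets = rng.choice(others, size=k, replace=False)
        for j in targets:
            sign = -1 if rng.random() < inhibitory_fraction else 1
            net.add_edge(u, nodes[j], sign)
    return net


# -- design & expression ---------------------------------------------------


def make_design(
    replicates: int = 3,
    divs: tuple[int, ...] = DEFAULT_DIVS,
    treatments: tuple[str, str] = ("vehicle", "compound"),
    n_plates: int = 2,
    condition: str = "seeded",
) -> pd.DataFrame:
    """Factorial design table: one row per sample.

    Plates are assigned cyclically over replicates so the design stays
    balanced across the plate covariate.
    """
    if replicates < 2:
        raise ParameterError("need >= 2 replicates per treatment*DIV cell")
    rows = []
    i = 0
    for div in divs:
        for trt in treatments:
            for rep in range(1, replicates + 1):
                rows.append(
                    {
                        "sample": f"S{i:03d}",
                        "treatment": trt,
                        "condition": condition,
                        "div": div,
                        "plate": f"P{(rep - 1) % n_plates + 1}",
                        "replicate": rep,
                    }
                )
                i += 1
    return pd.DataFrame(rows)


def planted_effects(
    network: SignedNetwork,
    regulators: set[tuple[str, int]],
    depth: int = 2,
) -> dict[str, int]:
    """Expected perturbation sign per downstream gene.

    Signs are propagated along shortest paths to ``depth``; genes whose
    shortest-path signs conflict (within or across regulators) are
    ambiguous and receive no perturbation.  Regulator nodes themselves
    act at the protein level and are not transcriptionally perturbed.
    """
    combined: dict[str, set[int]] = {}
    for reg, sign in regulators:
        if reg not in network:
            raise ParameterError(f"regulator {reg!r} not in network")
        for node, state in predict_downstream(network, reg, sign, depth).items():
            combined.setdefault(node, set()).add(state)
    regs = {r for r, _ in regulators}
    return {
        g: next(iter(s))
        for g, s in combined.items()
        if len(s) == 1 and 0 not in s and g not in regs
    }


def simulate_experiment(
    network: SignedNetwork,
    regulators: set[tuple[str, int]],
    design: pd.DataFrame,
    effect_size: float = 2.0,
    noise_sd: float = 0.3,
    plate_sd: float = 0.1,
    seed: int = 0,
    depth: int = 2,
    n_background_genes: int = 0,
    baseline_mean: float = 5.0,
    baseline_sd: float = 1.5,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a log2 expression matrix with planted treatment effects.

    Genes downstream of the planted regulators (within ``depth`` steps)
    receive a treatment-dependent mean shift whose sign is the regulator
    sign times the product of edge signs along a shortest path and whose
    magnitude is ``effect_size`` scaled linearly by DIV (full size at
    the last timepoint).  Per-plate intercepts are drawn once per
    (gene, plate) with sd ``plate_sd``; residual noise is Gaussian with
    sd ``noise_sd``.
    """
    if noise_sd < 0 or plate_sd < 0:
        raise ParameterError("noise_sd and plate_sd must be non-negative")
    rng = np.random.default_rng(seed)
    perturbed = planted_effects(network, regulators, depth=depth)
    genes = list(network.nodes) + [
        f"B{i:04d}" for i in range(n_background_genes)
    ]
    samples = design["sample"].tolist()
    n_g, n_s = len(genes), len(samples)
    max_div = max(design["div"])
    div_scale = design["div"].to_numpy() / max_div
    treated = (design["treatment"] == "compound").to_numpy()

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_g)
    plates = sorted(design["plate"].unique())
    plate_fx = {p: rng.normal(0.0, plate_sd, size=n_g) for p in plates}

    effect = np.array([perturbed.get(g, 0) for g in genes], dtype=float)
    effect *= effect_size

    mat = np.empty((n_g, n_s))
    for j, (_, row) in enumerate(design.iterrows()):
        mu = baseline + plate_fx[row["plate"]]
        if treated[j]:
            mu = mu + effect * div_scale[j]
        mat[:, j] = mu
    mat += rng.normal(0.0, noise_sd, size=(n_g, n_s)) if noise_sd > 0 else 0.0

    matrix = pd.DataFrame(mat, index=genes, columns=samples)
    matrix.attrs["namespace"] = "rat"
    truth = GroundTruth(
        planted_regulators=set(regulators),
        effect_size=effect_size,
        perturbed_genes=perturbed,
    )
    return matrix, truth


# -- gene sets -------------------------------------------------------------


def simulate_genesets(
    perturbed_genes: set[str],
    all_genes: set[str],
    n_sets: int = 50,
    set_size_range: tuple[int, int] = (10, 40),
    enriched_fraction: float = 0.1,
    enriched_purity: float = 0.8,
    seed: int = 0,
) -> tuple[dict[str, list[str]], list[str]]:
    """Gene-set collection with a planted enriched subset.

    Enriched sets draw ``enriched_purity`` of their members from the
    perturbed genes, the remainder (and all background sets) uniformly
    from the gene universe.  Returns the collection (GMT-serialisable,
    deterministic member order for a fixed seed) and the ids of the
    truly enriched sets.
    """
    if not perturbed_genes <= all_genes:
        raise ParameterError("perturbed_genes must be a subset of all_genes")
    lo, hi = set_size_range
    if hi > len(all_genes):
        raise ParameterError("set_size_range exceeds the gene universe")
    if not 0 <= enriched_fraction <= 1:
        raise ParameterError("enriched_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    universe = sorted(all_genes)
    perturbed = sorted(perturbed_genes)
    n_enriched = round(n_sets * enriched_fraction)
    sets: dict[str, list[str]] = {}
    enriched_ids: list[str] = []
    for i in range(n_sets):
        set_id = f"SET{i:04d}"
        size = int(rng.integers(lo, hi + 1))
        if i < n_enriched and perturbed:
            k = min(round(size * enriched_purity), len(perturbed))
            core = list(rng.choice(perturbed, size=k, replace=False))
            pool = [g for g in universe if g not in set(core)]
            rest = list(rng.choice(pool, size=size - k, replace=False))
            sets[set_id] = sorted(core + rest)
            enriched_ids.append(set_id)
        else:
            sets[set_id] = sorted(rng.choice(universe, size=size, replace=False))
    return sets, enriched_ids


# -- annotation inputs ------------------------------------------------------


@dataclass
class Annotations:
    ortholog_map: pd.DataFrame  # rat_id, human_id
    disease_genes: pd.DataFrame  # gene (human), score in [0, 1]
    regulons: pd.DataFrame  # tf, target, sign
    pathway_coefficients: pd.DataFrame  # pathways x genes
    bioactivity: pd.DataFrame  # compound_id, fingerprint_hex, target_id, activity_uM
    query_fingerprint: "object"  # chemtarget.Fingerprint
    planted_target: str


def _human_id(rat_id: str) -> str:
    return "H" + rat_id


def simulate_annotations(
    network: SignedNetwork,
    perturbed_genes: dict[str, int],
    seed: int = 0,
    n_one2many: int = 3,
    n_many2one: int = 3,
    disease_odds_ratio: float = 3.0,
    disease_base_rate: float = 0.3,
    tf_min_out_degree: int = 3,
    n_pathways: int = 5,
    n_decoy_targets: int = 4,
    n_active_neighbours: int = 6,
    n_decoy_compounds: int = 24,
    neighbour_similarity: tuple[float, float] = (0.7, 0.9),
    fp_bits: int = 256,
    extra_genes: tuple[str, ...] = (),
) -> Annotations:
    """Annotation inputs consistent with the network and planted truth.

    * ortholog map: 1:1 for most genes, with ``n_one2many`` rat genes
      mapping to two human genes and ``n_many2one`` extra rat genes
      sharing a human target;
    * disease gene list drawn so overlap with the perturbed genes has
      the configured odds ratio (1.0 gives independence);
    * regulons: out-edges of every node with out-degree >=
      ``tf_min_out_degree``, signs from the network;
    * pathway coefficient matrix with one pathway aligned to the
      perturbed-gene signs and random decoys;
    * bioactivity corpus: one planted target whose actives are
      high-similarity neighbours of the query fingerprint, plus decoy
      targets held by low-similarity compounds with mixed activity.
    """
    from . import chemtarget as ct

    rng = np.random.default_rng(seed)
    genes = sorted(set(network.nodes) | set(extra_genes))
    n = len(genes)

    # --- ortholog map
    picks = rng.choice(n, size=n_one2many + n_many2one, replace=False)
    one2many = {genes[i] for i in picks[:n_one2many]}
    many2one = [genes[i] for i in picks[n_one2many:]]
    pairs = []
    for g in genes:
        pairs.append((g, _human_id(g)))
        if g in one2many:
            pairs.append((g, _human_id(g) + "b"))
    for g in many2one:
        # a second rat gene sharing this human target
        pairs.append((g + "x", _human_id(g)))
    ortho = pd.DataFrame(pairs, columns=["rat_id", "human_id"]).drop_duplicates()

    # --- disease gene list (human namespace), configurable association
    p0 = disease_base_rate
    odds0 = p0 / (1 - p0)
    odds1 = odds0 * disease_odds_ratio
    p1 = odds1 / (1 + odds1)
    rows = []
    for g in genes:
        p_in = p1 if g in perturbed_genes else p0
        if rng.random() < p_in:
            rows.append({"gene": _human_id(g), "score": float(rng.uniform(0, 1))})
    disease = pd.DataFrame(rows, columns=["gene", "score"])

    # --- regulons from the network
    reg_rows = [
        {"tf": u, "target": v, "sign": s}
        for u, v, s in sorted(network.edges())
        if network.graph.out_degree(u) >= tf_min_out_degree
    ]
    regulons = pd.DataFrame(reg_rows, columns=["tf", "target", "sign"])

    # --- pathway coefficients: one aligned with the planted signs
    coef = pd.DataFrame(0.0, index=[f"PW{i:02d}" for i in range(n_pathways)], columns=genes)
    for i in range(1, n_pathways):
        members = rng.choice(genes, size=min(30, n), replace=False)
        coef.loc[f"PW{i:02d}", members] = rng.normal(0, 0.3, size=len(members))
    for g, s in perturbed_genes.items():
        if g in coef.columns:
            coef.loc["PW00", g] = 0.5 * s

    # --- bioactivity corpus + query fingerprint (synthetic bit vectors)
    query = ct.random_fingerprint(fp_bits, density=0.12, rng=rng)
    planted_target = "T00"
    targets = [planted_target] + [f"T{i:02d}" for i in range(1, n_decoy_targets + 1)]
    bio_rows = []
    for i in range(n_active_neighbours):
        sim = float(rng.uniform(*neighbour_similarity))
        fp = ct.neighbour_fingerprint(query, sim, rng=rng)
        bio_rows.append(
            {
                "compound_id": f"CPD_NBR{i:02d}",
                "fingerprint_hex": fp.to_hex(),
                "target_id": planted_target,
                "activity_uM": 0.05,
            }
        )
    for i in range(n_decoy_compounds):
        fp = ct.random_fingerprint(fp_bits, density=0.12, rng=rng)
        tgt = targets[1 + i % max(n_decoy_targets, 1)] if n_decoy_targets else planted_target
        # alternate activity within each decoy target so every decoy ends
        # up with a mixed (about half active) training set
        within = i // max(n_decoy_targets, 1)
        bio_rows.append(
            {
                "compound_id": f"CPD_BG{i:03d}",
                "fingerprint_hex": fp.to_hex(),
                "target_id": tgt,
                "activity_uM": 0.05 if within % 2 == 0 else 500.0,
            }
        )
    bioactivity = pd.DataFrame(bio_rows)

    return Annotations(
        ortholog_map=ortho,
        disease_genes=disease,
        regulons=regulons,
        pathway_coefficients=coef,
        bioactivity=bioactivity,
        query_fingerprint=query,
        planted_target=planted_target,
    )
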