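"""Over-representation of a DEG list in gene sets, the overlap
coefficient between two experiments' significant pathways, and the
disease-list Fisher test.

The gene-set collection is generated with four sets deliberately built
from the perturbed genes; enrichment should rank exactly those first."""

from moadecon import enrich, synth

universe = {f"g{i:04d}" for i in range(1000)}
perturbed = {f"g{i:04d}" for i in range(40)}

sets, truly_enriched = synth.simulate_genesets(
    perturbed, universe, n_sets=40, enriched_fraction=0.1, seed=7
)
res = enrich.overrepresentation(perturbed, universe, sets)
print("top 5 sets by hypergeometric p (planted:", truly_enriched, ")")
print(res.head(5)[["set_id", "set_size", "overlap", "p_adjusted"]].to_string(index=False))

# overlap coefficient between two experiments' significant-pathway sets:
# |A n B| / min(|A|, |B|) -- 1.0 when one list nests inside the other.
sig_a = set(res.loc[res["significant"], "set_id"])
sig_b = set(truly_enriched[:2]) | {"SET0099"}
st = enrich.overlap_coefficient(sig_a, sig_b)
print(f"\nshared pathways: {st.intersection}, overlap coefficient {st.rounded}")

disjoint = enrich.overlap_coefficient({"PW1", "PW2"}, {"PW3", "PW4"})
print(f"disjoint pathway sets -> {disjoint.intersection} ({disjoint.rounded:.2f})")

# Fisher exact overlap of the DEGs with a disease-association list
disease = {f"g{i:04d}" for i in range(20)} | {f"g{i:04d}" for i in range(500, 800)}
ov = enrich.disease_overlap(perturbed, [disease], universe)
print(f"\ndisease overlap: OR = {ov.odds_ratio:.2f}, Fisher p = {ov.p_value:.2g} "
      f"(union of disease lists: {ov.union_size} genes)")
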