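"""The whole mechanism-of-action deconvolution chain on synthetic truth.

One call generates every input (network, factorial expression data,
ortholog map, gene sets, regulons, disease list, bioactivity corpus),
runs differential expression, identifier mapping, enrichment, TF
activity, causal reasoning under two input preparations, target
prediction, and integrates the three evidence streams.  The planted
process should surface with all three streams behind it."""

import moadecon as m

r = m.run_pipeline(seed=2)

(reg, sign), = r.truth.planted_regulators
print(f"planted: regulator {reg} (sign {sign:+d}), "
      f"{len(r.truth.perturbed_genes)} perturbed genes, "
      f"sets {r.truth.enriched_sets}, target {sorted(r.truth.active_targets)}")

print(f"\nday-14 DEGs: {r.degs_day14['gene'].nunique()}   p* = {r.pstar.p_star:.3g}")
print(f"significant pathways: "
      f"{int(r.enrichment['significant'].sum())} of {len(r.enrichment)}")
print(f"disease overlap: OR = {r.disease.odds_ratio:.2f}, p = {r.disease.p_value:.3g}")
print(f"pooled causal regulators: {sorted(r.pooled_regulators)}")
best = r.target_predictions.groupby('target_id')['probability'].max()
print(f"best predicted target: {best.idxmax()} (probability {best.max():.2f})")

print("\nevidence-ranked process hypotheses (streams = of 3 analysis types):")
print(r.headline[["process", "stream_count"]].to_string(index=False))
print(f"status: {r.status}")
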