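"""Whole-gene rare-variant burden testing against a reference population.

The discovery cohort has 67 probands; 6 of them carry a rare qualifying
variant in the candidate gene. The reference population (3000 individuals,
playing the role of a population browser such as ExAC) has 1 carrier.
Fisher's exact test asks whether carrier prevalence is enriched in cases.
"""

from famburden import ReferenceCounts, adjust_p, burden_test, fisher_exact_2x2

odds_ratio, p = fisher_exact_2x2(6, 61, 1, 2999, sidedness="enrichment")
print(f"candidate gene: 6/67 probands vs 1/3000 reference carriers")
print(f"  odds ratio = {odds_ratio:.1f}, one-sided exact p = {p:.3g}")
print()

reference = {
    "CAND": ReferenceCounts("CAND", ref_carriers=1, ref_total_individuals=3000),
    "OTHER1": ReferenceCounts("OTHER1", ref_carriers=120, ref_total_individuals=3000),
    "OTHER2": ReferenceCounts("OTHER2", ref_carriers=40, ref_total_individuals=3000),
}
counts = {"CAND": (6, 67), "OTHER1": (5, 67), "OTHER2": (2, 67)}
results = burden_test(counts, reference, n_segregating={"CAND": 6})
print("ranked candidates (Bonferroni over 3 genes):")
for r in results:
    print(f"  {r.rank}. {r.gene:<7} p={r.p_value:.3g}  p_adj={r.p_adjusted:.3g}")
print()
print("a Bonferroni-adjusted p below 0.05 flags the gene as significantly "
      "enriched for rare qualifying variants relative to the reference.")
print()
print("Bonferroni vs Benjamini-Hochberg on the same raw p-values:")
raw = [r.p_value for r in sorted(results, key=lambda r: r.gene)]
print("  bonferroni:", [f"{x:.3g}" for x in adjust_p(raw, "bonferroni")])
print("  BH        :", [f"{x:.3g}" for x in adjust_p(raw, "benjamini_hochberg")])
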