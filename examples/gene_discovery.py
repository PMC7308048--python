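"""End-to-end gene discovery on a synthetic family cohort.

Simulates 67 multigenerational families segregating a dominant trait, with
one causal gene spiked into 6 of them, then runs the full analysis: filter
cascade -> dominant co-segregation -> per-gene exact burden test against a
simulated reference population of 3000 individuals.
"""

from famburden import RunConfig, run_analysis, simulate_cohort

cohort = simulate_cohort(seed=1)
results, traces, summary = run_analysis(
    cohort.annotations,
    cohort.genotypes,
    cohort.pedigrees,
    cohort.reference,
    RunConfig(seed=1),
)

print(f"cohort: {summary.n_families} families, {summary.n_samples} sequenced samples, "
      f"{summary.n_variants} variants")
print("filter funnel:", summary.removed_by_filter,
      f"-> {summary.n_retained_variants} variants retained in "
      f"{len(summary.retained_genes)} genes")
print()
print("top candidates (rank, gene, carriers, reference carriers, p, p_adj, "
      "co-segregating families):")
for r in results[:5]:
    print(f"  {r.rank:>2}  {r.gene:<12} {r.cohort_alt:>2}/{r.cohort_total:<3} "
          f"{r.ref_alt:>4}/{r.ref_total:<5} p={r.p_value:<9.3g} "
          f"p_adj={r.p_adjusted:<9.3g} seg={r.n_segregating_families}")
print()
print(f"ground truth: the spiked gene is {cohort.params.causal_gene!r} — "
      f"a Bonferroni-adjusted p below 0.05 at rank 1 means the pipeline "
      f"recovered it against {len(results) - 1} background genes.")
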