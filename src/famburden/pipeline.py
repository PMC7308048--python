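"""End-to-end orchestration: filter -> segregate -> burden -> report.

`run_analysis` is the in-memory engine (used by the tests and the
simulation studies); `run_pipeline` wraps it with file input/output and a
machine-readable run summary.  Both are deterministic given their inputs
and the configured seed, and two runs in one process never share state.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .burden import GeneBurdenResult, aggregate_gene_counts, burden_test
from .filters import FilterTrace, run_cascade
from .io_formats import (
    CohortGenotypes,
    ReferenceCounts,
    RunConfig,
    VariantAnnotation,
    read_annotations,
    read_ped,
    read_reference_counts,
    read_vcf,
    write_filter_trace,
    write_report,
)
from .pedigree import FamilyIndex, Pedigree, build_pedigrees

__all__ = ["RunSummary", "run_analysis", "run_pipeline"]


@dataclass
class RunSummary:
    """Counts and top candidates of one pipeline run (the report funnel)."""

    config: dict
    n_variants: int
    n_samples: int
    n_families: int
    removed_by_filter: dict[str, int]
    n_retained_variants: int
    retained_genes: list[str]
    top_genes: list[dict]
    seed: int
    version: str = __version__

    def __post_init__(self) -> None:
        if sum(self.removed_by_filter.values()) + self.n_retained_variants != self.n_variants:
            raise ValueError("filter funnel does not conserve the variant count")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def run_analysis(
    annotations: list[VariantAnnotation],
    genotypes: CohortGenotypes,
    pedigrees: list[Pedigree],
    reference: dict[str, ReferenceCounts],
    config: RunConfig,
) -> tuple[list[GeneBurdenResult], list[FilterTrace], RunSummary]:
    """Filter the cohort, check segregation, and test per-gene burden."""
    retained_by_gene, traces = run_cascade(annotations, genotypes, pedigrees, config)

    findex = FamilyIndex(pedigrees, genotypes)
    n_segregating: dict[str, int] = {}
    for gene, anns in retained_by_gene.items():
        seg_families: set[str] = set()
        for ann in anns:
            verdicts = findex.verdicts(genotypes.calls[ann.key], config.segregation_mode)
            seg_families |= {f for f, v in verdicts.items() if v == "co_segregates"}
        n_segregating[gene] = len(seg_families)

    proband_ids = sorted(
        m.id
        for ped in pedigrees
        for m in ped.members
        if m.is_proband and m.id in genotypes._index
    )
    counts_by_gene = {
        gene: aggregate_gene_counts(
            [a.key for a in anns], genotypes, proband_ids, config.burden_unit
        )
        for gene, anns in retained_by_gene.items()
    }
    results = burden_test(
        counts_by_gene,
        reference,
        burden_unit=config.burden_unit,
        sidedness=config.test_sidedness,
        mtc_method=config.mtc_method,
        n_segregating=n_segregating,
    )

    removed: dict[str, int] = {}
    for t in traces:
        if t.disposition == "removed":
            removed[t.removed_by] = removed.get(t.removed_by, 0) + 1
    summary = RunSummary(
        config=json.loads(config.to_json()),
        n_variants=len(annotations),
        n_samples=len(genotypes.sample_ids),
        n_families=len(pedigrees),
        removed_by_filter=removed,
        n_retained_variants=sum(1 for t in traces if t.disposition == "retained"),
        retained_genes=sorted(retained_by_gene),
        top_genes=[
            {
                "rank": r.rank,
                "gene": r.gene,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "odds_ratio": None if r.odds_ratio != r.odds_ratio else r.odds_ratio,
                "n_segregating_families": r.n_segregating_families,
            }
            for r in results[:10]
        ],
        seed=config.seed,
    )
    return results, traces, summary


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    vcf: str | Path | None = None,
    ped: str | Path | None = None,
    annotations: str | Path | None = None,
    reference: str | Path | None = None,
    simulate: bool = False,
    sim_params=None,
) -> RunSummary:
    """Run the full analysis from files (or a fresh simulation) to reports.

    Writes ``trace.tsv``, ``report.tsv`` and ``summary.json`` under
    ``out_dir``; on any error the partial outputs are removed before the
    exception propagates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        if simulate:
            from .simulate import SimParams, simulate_cohort

            cohort = simulate_cohort(sim_params or SimParams(seed=config.seed))
            anns, genotypes = cohort.annotations, cohort.genotypes
            pedigrees, ref = cohort.pedigrees, cohort.reference
        else:
            for name, p in (("VCF", vcf), ("PED", ped), ("annotations", annotations), ("reference counts", reference)):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name} file missing: {p}")
            keys, genotypes = read_vcf(vcf)
            pedigrees = build_pedigrees(read_ped(ped))
            anns = read_annotations(annotations, known_keys=set(keys))
            ref = read_reference_counts(reference)
        results, traces, summary = run_analysis(anns, genotypes, pedigrees, ref, config)
        trace_path = out / "trace.tsv"
        written.append(trace_path)
        write_filter_trace(traces, trace_path, seed=config.seed)
        if results:
            report_path = out / "report.tsv"
            written.append(report_path)
            write_report(results, report_path, seed=config.seed)
        summary_path = out / "summary.json"
        written.append(summary_path)
        summary.to_json(summary_path)
        return summary
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
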