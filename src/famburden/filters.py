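"""The variant filter cascade.

Variant-level filters run in a fixed canonical order — quality control,
consequence class, minor allele frequency, case-control — followed by the
gene-level multiple-family filter.  Every input variant receives exactly one
audit record naming the first filter that removed it, or ``retained``.

The variant-level filters are pure predicates on independent annotation
fields, so any ordering yields the same surviving set; only the
``removed_by`` labels depend on the order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import CohortGenotypes, RunConfig, VariantAnnotation, VariantKey
from .pedigree import Pedigree

__all__ = [
    "FilterTrace",
    "qc_filter",
    "consequence_filter",
    "maf_filter",
    "consensus_filter",
    "case_control_filter",
    "multi_family_filter",
    "run_cascade",
]


@dataclass
class FilterTrace:
    """Per-variant audit record: the first filter that removed it, or retained."""

    key: VariantKey
    gene: str
    disposition: str  # retained / removed
    removed_by: str | None = None
    details: str | None = None

    def __post_init__(self) -> None:
        if (self.disposition == "removed") != (self.removed_by is not None):
            raise ValueError("removed_by must be set iff disposition is 'removed'")


def qc_filter(ann: VariantAnnotation, thresholds: dict[str, float]) -> bool:
    """Fail iff any QC field is present and below its threshold.

    Absent QC fields pass (permissive default: upstream variant-quality
    recalibration is assumed to have run).
    """
    for name, minimum in thresholds.items():
        value = ann.qc.get(name)
        if value is not None and value < minimum:
            return False
    return True


def consequence_filter(ann: VariantAnnotation, whitelist: frozenset[str]) -> bool:
    """Pass iff the consequence class is in the function-altering whitelist."""
    return ann.consequence in whitelist


def maf_filter(
    ann: VariantAnnotation,
    threshold: float,
    aggregation: str = "max_across_dbs",
) -> bool:
    """Pass iff the variant is rare in every reference database.

    The boundary is strict: a MAF exactly at the threshold fails.  A variant
    absent from every database is treated as novel and passes (distinct from
    a reported MAF of 0.0, which also passes).  ``max_across_dbs`` and
    ``all_dbs`` are equivalent (max < t  <=>  every MAF < t); both names are
    accepted for config clarity.
    """
    if aggregation not in ("max_across_dbs", "all_dbs"):
        raise ValueError(f"unknown maf aggregation {aggregation!r}")
    mafs = ann.maf_by_db.values()
    if not mafs:
        return True
    return max(mafs) < threshold


def consensus_filter(ann: VariantAnnotation, k: int, n: int) -> bool:
    """Pass iff >= k of n prediction tools call the variant deleterious.

    Missing tool calls count as non-deleterious.  By default the cascade
    reports this flag without removing (a variant failing the consensus can
    still be retained on segregation grounds); ``consensus_removes`` in the
    run config makes it a removing filter.
    """
    if not (1 <= k <= n):
        raise ValueError("consensus requires 1 <= k <= n")
    n_deleterious = sum(1 for call in ann.tool_calls.values() if call == "deleterious")
    return n_deleterious >= k


def case_control_filter(
    key: VariantKey,
    genotypes: CohortGenotypes,
    unaffected_ids: set[str],
    max_controls: int = 1,
) -> bool:
    """Fail iff more than ``max_controls`` unaffected individuals carry the variant."""
    return _count_unaffected_carriers(key, genotypes, unaffected_ids) <= max_controls


def _count_unaffected_carriers(
    key: VariantKey, genotypes: CohortGenotypes, unaffected_ids: set[str]
) -> int:
    arr = genotypes.calls[key]
    return sum(
        1
        for s in unaffected_ids
        if s in genotypes._index and arr[genotypes._index[s]] > 0
    )


def multi_family_filter(
    variants_by_gene: dict[str, list[VariantKey]],
    genotypes: CohortGenotypes,
    proband_ids: set[str],
    min_probands: int = 2,
) -> set[str]:
    """Retain genes whose surviving variants occur in >= ``min_probands`` probands.

    The unit is distinct probands carrying at least one qualifying variant in
    the gene — two variants in one proband do not qualify a gene.
    """
    proband_idx = np.array(
        [genotypes._index[s] for s in sorted(proband_ids) if s in genotypes._index],
        dtype=np.intp,
    )
    retained = set()
    for gene, keys in variants_by_gene.items():
        if not keys:
            continue
        mat = genotypes.matrix(keys)[:, proband_idx]
        n_carrying_probands = int(((mat > 0).any(axis=0)).sum())
        if n_carrying_probands >= min_probands:
            retained.add(gene)
    return retained


def run_cascade(
    annotations: list[VariantAnnotation],
    genotypes: CohortGenotypes,
    pedigrees: list[Pedigree],
    config: RunConfig,
) -> tuple[dict[str, list[VariantAnnotation]], list[FilterTrace]]:
    """Run every filter in canonical order, producing survivors and a full trace.

    Order: qc -> consequence -> maf -> [consensus if removing] ->
    case_control -> biological-relevance gene whitelist (if configured) ->
    gene-level multi_family.  ``removed_by`` names the first failing filter.
    Returns surviving annotations grouped by gene (only genes passing the
    multiple-family filter) and one trace record per input variant.
    """
    samples = {m.id: m for ped in pedigrees for m in ped.members}
    unaffected_ids = {s for s, m in samples.items() if m.status == "unaffected"}
    proband_ids = {s for s, m in samples.items() if m.is_proband}

    traces: dict[VariantKey, FilterTrace] = {}
    survivors: list[VariantAnnotation] = []
    for ann in annotations:
        removed_by = details = None
        if not qc_filter(ann, config.qc_thresholds):
            removed_by, details = "qc", "below a QC threshold"
        elif not consequence_filter(ann, config.consequence_whitelist):
            removed_by, details = "consequence", f"{ann.consequence} not in whitelist"
        elif not maf_filter(ann, config.maf_threshold, config.maf_aggregation):
            removed_by = "maf"
            details = f"max MAF {max(ann.maf_by_db.values()):.4g} >= {config.maf_threshold:g}"
        elif config.consensus_removes and not consensus_filter(
            ann, config.consensus_k, config.consensus_n
        ):
            removed_by = "consensus"
            details = f"< {config.consensus_k} of {config.consensus_n} tools deleterious"
        elif not case_control_filter(
            ann.key, genotypes, unaffected_ids, config.max_unaffected_controls_with_variant
        ):
            removed_by = "case_control"
            n = _count_unaffected_carriers(ann.key, genotypes, unaffected_ids)
            details = f"present in {n} unaffected controls"
        elif config.gene_whitelist is not None and ann.gene not in config.gene_whitelist:
            removed_by, details = "biological_relevance", "gene not in whitelist"
        if removed_by is None:
            consensus = consensus_filter(ann, config.consensus_k, config.consensus_n)
            traces[ann.key] = FilterTrace(
                key=ann.key,
                gene=ann.gene,
                disposition="retained",
                details=f"consensus_deleterious={'yes' if consensus else 'no'}",
            )
            survivors.append(ann)
        else:
            traces[ann.key] = FilterTrace(
                key=ann.key,
                gene=ann.gene,
                disposition="removed",
                removed_by=removed_by,
                details=details,
            )

    by_gene: dict[str, list[VariantAnnotation]] = {}
    for ann in survivors:
        by_gene.setdefault(ann.gene, []).append(ann)
    retained_genes = multi_family_filter(
        {g: [a.key for a in anns] for g, anns in by_gene.items()},
        genotypes,
        proband_ids,
        config.min_probands_per_gene,
    )
    for gene, anns in by_gene.items():
        if gene in retained_genes:
            continue
        for ann in anns:
            traces[ann.key] = FilterTrace(
                key=ann.key,
                gene=gene,
                disposition="removed",
                removed_by="multi_family",
                details=f"gene variants in < {config.min_probands_per_gene} probands",
            )
    retained_by_gene = {g: anns for g, anns in by_gene.items() if g in retained_genes}
    trace_list = [traces[ann.key] for ann in annotations]
    return retained_by_gene, trace_list
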