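"""Synthetic cohorts with the structure the discovery analysis assumes.

The generator emulates a family-based rare-variant study of a dominantly
inherited binary trait: multigenerational pedigrees ascertained through an
affected proband, a spiked causal gene whose rare variants segregate with
the trait in several unrelated families, a background of common and rare
non-causal exome variants transmitted Mendelianly, and a matching per-gene
reference-population count table.  Defaults mirror a cohort of 67
multigenerational families with the causal gene present in 6 of them.

Every family segregates a fully penetrant (by default) dominant trait
allele introduced through one founder; in the causal families that allele
*is* a variant of the causal gene, in the remaining families it is latent
(its gene is not among the simulated variants), so the trait has a genetic
architecture the analysis can only partially resolve — exactly the situation
a discovery cohort faces.  Only the proband, the affected relatives, and a
configurable number of unaffected relatives per family are "sequenced"
(appear in the VCF); the PED file describes everyone.

All randomness flows from ``SimParams.seed``; outputs are pure functions of
the parameters, and emitted files are byte-identical across reruns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    CohortGenotypes,
    ReferenceCounts,
    VariantAnnotation,
    VariantKey,
    write_annotations,
    write_reference_counts,
    write_vcf,
)
from .pedigree import FOUNDER, Pedigree, Sample, build_pedigrees

__all__ = [
    "SimParams",
    "SyntheticCohort",
    "simulate_pedigree",
    "spike_causal_variant",
    "simulate_cohort",
    "emit_cohort",
]

_TOOLS = ("sift", "polyphen2", "mutationtaster", "provean", "cadd")
_DBS = ("exac", "gnomad")
_BASES = ("A", "C", "G", "T")
_FUNCTIONAL = ("missense", "nonsense", "frameshift", "splice_site")
_FUNCTIONAL_W = (0.80, 0.08, 0.07, 0.05)
_NEUTRAL = ("synonymous", "other")
_NEUTRAL_W = (0.70, 0.30)
#: Deleterious-tool-call counts cycled over the spiked causal variants: two
#: clear a 3-of-5 consensus, one does not (a causal variant can look benign
#: in silico and still be retained on segregation grounds).
_CAUSAL_TOOL_PATTERN = (5, 4, 2)


@dataclass
class SimParams:
    """Study conditions for one synthetic cohort."""

    n_families: int = 67
    family_size_range: tuple[int, int] = (4, 12)
    generations: int = 3
    causal_gene: str = "GENE_CAUSAL"
    n_causal_families: int = 6
    n_causal_variants: int = 3
    causal_maf_in_reference: float = 1e-4
    penetrance: float = 1.0
    background_genes: int = 200
    background_sites_per_gene: tuple[int, int] = (8, 30)
    common_site_fraction: float = 0.25
    common_maf_range: tuple[float, float] = (0.10, 0.50)
    rare_maf_range: tuple[float, float] = (1e-4, 0.025)
    fraction_functional: float = 0.3
    reference_population_n: int = 3000
    controls_per_family: int = 1
    planted_control_carriers: int = 0
    annotation_maf_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_causal_families > self.n_families or self.n_causal_families < 0:
            raise ValueError("need 0 <= n_causal_families <= n_families")
        lo, hi = self.family_size_range
        if lo < 3 or hi < lo:
            raise ValueError("family_size_range must satisfy 3 <= lo <= hi")
        if self.generations not in (2, 3):
            raise ValueError("generations must be 2 or 3")
        if not (0.0 < self.penetrance <= 1.0):
            raise ValueError("penetrance must be in (0, 1]")
        for p in (self.common_site_fraction, self.fraction_functional):
            if not (0.0 <= p <= 1.0):
                raise ValueError("fractions must be in [0, 1]")
        if not (0.0 <= self.causal_maf_in_reference <= 1.0):
            raise ValueError("causal_maf_in_reference must be in [0, 1]")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


@dataclass
class SyntheticCohort:
    """In-memory view of one simulated cohort (what the emitted files contain)."""

    params: SimParams
    keys: list[VariantKey]
    genotypes: CohortGenotypes
    annotations: list[VariantAnnotation]
    ped_table: pd.DataFrame
    pedigrees: list[Pedigree]
    reference: dict[str, ReferenceCounts]
    truth: pd.DataFrame
    causal_keys: list[VariantKey]
    #: genotypes for *every* pedigree member (the VCF carries only the
    #: sequenced subset); used for Mendelian-consistency audits
    genotypes_all: CohortGenotypes | None = None


# ---------------------------------------------------------------------------
# Pedigree structure


def simulate_pedigree(
    params: SimParams, rng: np.random.Generator, family_id: str = "FAM001"
) -> Pedigree:
    """One multigenerational family: founder couple plus descendants.

    Members are created parents-before-children; married-in spouses are
    founders.  Sizes fall within ``family_size_range`` and the structure
    passes pedigree validation.  Statuses are unknown until a trait is
    assigned.
    """
    target = int(rng.integers(params.family_size_range[0], params.family_size_range[1] + 1))
    members: list[Sample] = []

    def new_member(sex: str, father: str = FOUNDER, mother: str = FOUNDER) -> Sample:
        m = Sample(
            id=f"{family_id}-{len(members) + 1}",
            family_id=family_id,
            father_id=father,
            mother_id=mother,
            sex=sex,
        )
        members.append(m)
        return m

    father = new_member("male")
    mother = new_member("female")
    children: list[Sample] = []
    spouses: dict[str, Sample] = {}
    # first child always exists
    children.append(
        new_member("male" if rng.random() < 0.5 else "female", father.id, mother.id)
    )
    while len(members) < target:
        room = target - len(members)
        unmarried = [c for c in children if c.id not in spouses]
        actions = ["child"]
        if params.generations == 3:
            if unmarried and room >= 2:
                actions.append("marry")
            if spouses:
                actions.append("grandchild")
        action = actions[int(rng.integers(len(actions)))]
        if action == "child":
            children.append(
                new_member("male" if rng.random() < 0.5 else "female", father.id, mother.id)
            )
        elif action == "marry":
            child = unmarried[int(rng.integers(len(unmarried)))]
            spouse = new_member("female" if child.sex == "male" else "male")
            spouses[child.id] = spouse
            pa, ma = (child, spouse) if child.sex == "male" else (spouse, child)
            new_member("male" if rng.random() < 0.5 else "female", pa.id, ma.id)
        else:  # grandchild of a random married couple
            child_id = sorted(spouses)[int(rng.integers(len(spouses)))]
            child, spouse = next(c for c in children if c.id == child_id), spouses[child_id]
            pa, ma = (child, spouse) if child.sex == "male" else (spouse, child)
            new_member("male" if rng.random() < 0.5 else "female", pa.id, ma.id)
    ped = Pedigree(family_id=family_id, members=members)
    ped.validate()
    return ped


def _topological_members(ped: Pedigree) -> list[Sample]:
    """Members ordered parents-before-children."""
    placed: set[str] = set()
    ordered: list[Sample] = []
    pending = list(ped.members)
    while pending:
        progressed = False
        rest = []
        for m in pending:
            ready = all(
                p == FOUNDER or p in placed or p not in {x.id for x in ped.members}
                for p in (m.father_id, m.mother_id)
            )
            if ready:
                ordered.append(m)
                placed.add(m.id)
                progressed = True
            else:
                rest.append(m)
        if not progressed:
            raise ValueError(f"family {ped.family_id}: cannot order members")
        pending = rest
    return ordered


def _transmit_dominant(
    ped: Pedigree, carrier_founder: str, rng: np.random.Generator
) -> dict[str, bool]:
    """Mendelian transmission of a het founder allele through the pedigree."""
    carrier: dict[str, bool] = {}
    for m in _topological_members(ped):
        if m.is_founder:
            carrier[m.id] = m.id == carrier_founder
        else:
            inherited = False
            for parent in (m.father_id, m.mother_id):
                if carrier.get(parent, False) and rng.random() < 0.5:
                    inherited = True
            carrier[m.id] = inherited
    return carrier


def spike_causal_variant(
    pedigree: Pedigree,
    params: SimParams,
    rng: np.random.Generator,
    max_retries: int = 200,
) -> tuple[dict[str, bool], dict[str, str], str]:
    """Introduce a het dominant allele through one founder and assign the trait.

    Returns (carrier flags, affection status, proband id).  Carriers are
    affected with probability ``penetrance``; non-carriers are never affected
    (phenocopies off).  The proband is the first affected carrier in member
    order.  Transmission is resampled (bounded) until an affected carrier
    exists.
    """
    parents = {p for m in pedigree.members for p in (m.father_id, m.mother_id)}
    eligible = [m.id for m in pedigree.members if m.is_founder and m.id in parents]
    if not eligible:
        raise ValueError(f"family {pedigree.family_id}: no founder with offspring")
    founder = eligible[int(rng.integers(len(eligible)))]
    for _ in range(max_retries):
        carrier = _transmit_dominant(pedigree, founder, rng)
        status = {
            m.id: (
                "affected"
                if carrier[m.id] and rng.random() < params.penetrance
                else "unaffected"
            )
            for m in pedigree.members
        }
        affected_carriers = [
            m.id for m in pedigree.members if status[m.id] == "affected" and carrier[m.id]
        ]
        if affected_carriers:
            return carrier, status, affected_carriers[0]
    raise RuntimeError(
        f"family {pedigree.family_id}: no affected carrier after {max_retries} resamples"
    )


def _ascertained_family(
    pedigree: Pedigree, params: SimParams, rng: np.random.Generator, max_retries: int = 500
) -> tuple[dict[str, bool], dict[str, str], str]:
    """Trait assignment conditional on the family being informative.

    The study design ascertains families through a proband and keeps those
    with multiple affected members, so transmission is resampled until at
    least two members are affected.
    """
    for _ in range(max_retries):
        carrier, status, proband = spike_causal_variant(pedigree, params, rng)
        if sum(1 for s in status.values() if s == "affected") >= 2:
            return carrier, status, proband
    raise RuntimeError(
        f"family {pedigree.family_id}: could not ascertain >=2 affected members"
    )


# ---------------------------------------------------------------------------
# Sites and annotations


def _chrom_of(gene_index: int) -> str:
    return str(gene_index % 22 + 1)


def _draw_sites(params: SimParams, rng: np.random.Generator):
    """Background gene/site layout with generating MAFs and annotations."""
    genes = [f"GENE{i:04d}" for i in range(1, params.background_genes + 1)]
    sites = []  # (key, gene, maf, consequence, tool_deleterious_count)
    per_chrom_slot: dict[str, int] = {}
    lo, hi = params.background_sites_per_gene
    for gi, gene in enumerate(genes):
        chrom = _chrom_of(gi)
        slot = per_chrom_slot.get(chrom, 0)
        per_chrom_slot[chrom] = slot + 1
        base_pos = 1_000_000 * (slot + 1)
        n_sites = int(rng.integers(lo, hi + 1))
        for j in range(n_sites):
            pos = base_pos + 1 + int(rng.integers(200)) + j * 250
            ref = _BASES[int(rng.integers(4))]
            alt = _BASES[(int(_BASES.index(ref)) + 1 + int(rng.integers(3))) % 4]
            if rng.random() < params.common_site_fraction:
                maf = float(rng.uniform(*params.common_maf_range))
            else:
                lo_f, hi_f = params.rare_maf_range
                maf = float(math.exp(rng.uniform(math.log(lo_f), math.log(hi_f))))
            if rng.random() < params.fraction_functional:
                consequence = str(rng.choice(_FUNCTIONAL, p=_FUNCTIONAL_W))
                p_del = 0.30
            else:
                consequence = str(rng.choice(_NEUTRAL, p=_NEUTRAL_W))
                p_del = 0.05
            n_del = int(rng.binomial(len(_TOOLS), p_del))
            sites.append((VariantKey(chrom, pos, ref, alt), gene, maf, consequence, n_del))
    return genes, sites


def _causal_sites(params: SimParams, rng: np.random.Generator):
    """The spiked gene's rare missense variants (one per causal-variant slot)."""
    chrom = "11"
    sites = []
    for v in range(params.n_causal_variants):
        pos = 50_000_000 + v * 1_000 + int(rng.integers(500))
        ref = _BASES[int(rng.integers(4))]
        alt = _BASES[(int(_BASES.index(ref)) + 1 + int(rng.integers(3))) % 4]
        n_del = _CAUSAL_TOOL_PATTERN[v % len(_CAUSAL_TOOL_PATTERN)]
        sites.append(
            (
                VariantKey(chrom, pos, ref, alt),
                params.causal_gene,
                params.causal_maf_in_reference,
                "missense",
                n_del,
            )
        )
    return sites


def _annotation_for(
    key: VariantKey,
    gene: str,
    maf: float,
    consequence: str,
    n_deleterious: int,
    params: SimParams,
    rng: np.random.Generator,
) -> VariantAnnotation:
    if params.annotation_maf_noise:
        chroms = 2 * params.reference_population_n
        maf_by_db = {
            db: float(rng.binomial(chroms, maf)) / chroms for db in _DBS
        }
    else:
        maf_by_db = {db: maf for db in _DBS}
    if maf == 0.0:
        maf_by_db = {}  # never observed in any database: a novel variant
    tool_calls = {
        tool: ("deleterious" if i < n_deleterious else "tolerated")
        for i, tool in enumerate(_TOOLS)
    }
    qc = {
        "site_quality": float(rng.uniform(200.0, 2000.0)),
        "mean_depth": float(rng.uniform(20.0, 120.0)),
        "call_rate": float(rng.uniform(0.95, 1.0)),
    }
    return VariantAnnotation(
        key=key,
        gene=gene,
        consequence=consequence,
        maf_by_db=maf_by_db,
        tool_calls=tool_calls,
        qc=qc,
    )


# ---------------------------------------------------------------------------
# Cohort assembly


def _carrier_frequency(maf: float) -> float:
    return 1.0 - (1.0 - maf) ** 2


def _reference_counts(
    genes_sites: dict[str, list[tuple[float, str]]],
    params: SimParams,
    rng: np.random.Generator,
) -> tuple[dict[str, ReferenceCounts], dict[str, float]]:
    """Binomial reference-population counts over each gene's qualifying sites.

    Qualifying means function-altering consequence and generating MAF below
    2.5% — the same definition of "rare deleterious" the cohort analysis
    applies, emulating a per-gene query against a population browser.
    """
    n_ind = params.reference_population_n
    n_chrom = 2 * n_ind
    counts: dict[str, ReferenceCounts] = {}
    true_q: dict[str, float] = {}
    from .io_formats import FUNCTIONAL_CONSEQUENCES

    for gene, site_list in genes_sites.items():
        qualifying = [
            maf for maf, csq in site_list if csq in FUNCTIONAL_CONSEQUENCES and maf < 0.025
        ]
        alt = int(sum(rng.binomial(n_chrom, maf) for maf in qualifying))
        q = 1.0 - math.prod(1.0 - _carrier_frequency(m) for m in qualifying)
        carriers = int(rng.binomial(n_ind, q)) if qualifying else 0
        counts[gene] = ReferenceCounts(
            gene=gene,
            ref_alt_alleles=min(alt, n_chrom),
            ref_total_alleles=n_chrom,
            ref_carriers=carriers,
            ref_total_individuals=n_ind,
        )
        true_q[gene] = q
    return counts, true_q


def simulate_cohort(params: SimParams | None = None, **overrides) -> SyntheticCohort:
    """Generate a full cohort: pedigrees, trait, genotypes, annotations, reference.

    Keyword overrides are applied on top of ``params`` (or the defaults), so
    ``simulate_cohort(seed=7, n_causal_families=0)`` is a null cohort.
    """
    params = replace(params or SimParams(), **overrides)
    rng = np.random.default_rng(params.seed)

    # --- variant layout -----------------------------------------------------
    genes, background = _draw_sites(params, rng)
    causal = _causal_sites(params, rng)
    all_sites = causal + background
    annotations_by_key = {}
    for key, gene, maf, csq, n_del in all_sites:
        annotations_by_key[key] = _annotation_for(key, gene, maf, csq, n_del, params, rng)
    order = sorted(
        range(len(all_sites)),
        key=lambda i: (int(all_sites[i][0].chrom), all_sites[i][0].pos),
    )
    keys = [all_sites[i][0] for i in order]
    key_row = {k: r for r, k in enumerate(keys)}
    causal_keys = [s[0] for s in causal]
    causal_rows = [key_row[k] for k in causal_keys]
    background_rows = np.array(
        [key_row[s[0]] for s in background], dtype=np.intp
    )
    background_mafs = np.array([s[2] for s in background])

    # --- families, trait, proband -------------------------------------------
    pedigrees: list[Pedigree] = []
    carriers: list[dict[str, bool]] = []
    statuses: list[dict[str, str]] = []
    probands: list[str] = []
    for f in range(params.n_families):
        ped = simulate_pedigree(params, rng, family_id=f"FAM{f + 1:03d}")
        carrier, status, proband = _ascertained_family(ped, params, rng)
        for m in ped.members:
            m.status = status[m.id]
            m.is_proband = m.id == proband
        pedigrees.append(ped)
        carriers.append(carrier)
        statuses.append(status)
        probands.append(proband)
    causal_families = list(range(params.n_causal_families))

    # --- genotypes ------------------------------------------------------------
    sample_ids: list[str] = []
    sample_index: dict[str, int] = {}
    topo: list[tuple[int, Sample]] = []  # (global index, member) parents first
    for ped in pedigrees:
        for m in _topological_members(ped):
            sample_index[m.id] = len(sample_ids)
            sample_ids.append(m.id)
            topo.append((sample_index[m.id], m))
    nv, ns = len(keys), len(sample_ids)
    G = np.zeros((nv, ns), dtype=np.int8)
    for gi, m in topo:
        if m.is_founder:
            G[background_rows, gi] = rng.binomial(2, background_mafs).astype(np.int8)
        else:
            gf = G[:, sample_index[m.father_id]]
            gm = G[:, sample_index[m.mother_id]]
            G[:, gi] = (rng.random(nv) < gf / 2.0).astype(np.int8) + (
                rng.random(nv) < gm / 2.0
            ).astype(np.int8)
    # causal-site rows carry the trait-allele transmission of the causal
    # families (the rows are zero elsewhere: the variants are private)
    for fi in causal_families:
        if not causal_rows:
            break
        ped = pedigrees[fi]
        row = causal_rows[fi % len(causal_rows)]
        for m in ped.members:
            G[row, sample_index[m.id]] = 1 if carriers[fi][m.id] else 0

    # --- sequenced subset ------------------------------------------------------
    sequenced: list[str] = []
    for fi, ped in enumerate(pedigrees):
        affected = [m.id for m in ped.members if m.status == "affected"]
        unaffected = [m.id for m in ped.members if m.status == "unaffected"]
        chosen_controls = [
            str(s)
            for s in rng.choice(
                unaffected,
                size=min(params.controls_per_family, len(unaffected)),
                replace=False,
            )
        ]
        sequenced.extend(affected + sorted(chosen_controls))

    # negative-control scenario: plant the causal variants into unaffected
    # sequenced controls of non-causal families (emulating carriers among the
    # reference-side relatives), so the case-control filter can catch them
    if params.planted_control_carriers > 0 and causal_rows:
        pool = []
        for fi, ped in enumerate(pedigrees):
            if fi in causal_families:
                continue
            for m in ped.members:
                if m.status == "unaffected" and m.id in set(sequenced):
                    pool.append(m.id)
        for row in causal_rows:
            take = min(params.planted_control_carriers, len(pool))
            chosen = rng.choice(pool, size=take, replace=False)
            for sid in chosen:
                G[row, sample_index[str(sid)]] = 1

    seq_idx = np.array([sample_index[s] for s in sequenced], dtype=np.intp)
    genotypes = CohortGenotypes(sample_ids=list(sequenced))
    genotypes_all = CohortGenotypes(sample_ids=list(sample_ids))
    for r, key in enumerate(keys):
        genotypes.calls[key] = G[r, seq_idx].copy()
        genotypes_all.calls[key] = G[r]

    # --- annotations, reference, truth -----------------------------------------
    annotations = [annotations_by_key[k] for k in keys]
    genes_sites: dict[str, list[tuple[float, str]]] = {}
    for key, gene, maf, csq, n_del in all_sites:
        genes_sites.setdefault(gene, []).append((maf, csq))
    reference, true_q = _reference_counts(genes_sites, params, rng)

    ped_rows = []
    for ped in pedigrees:
        for m in ped.members:
            ped_rows.append(
                (ped.family_id, m.id, m.father_id, m.mother_id, m.sex, m.status, m.is_proband)
            )
    ped_table = pd.DataFrame(
        ped_rows,
        columns=["family_id", "individual_id", "father_id", "mother_id", "sex", "status", "is_proband"],
    )

    truth_rows = []
    for fi, ped in enumerate(pedigrees):
        is_causal = fi in causal_families
        causal_key = (
            str(causal_keys[fi % len(causal_keys)]) if is_causal and causal_keys else "."
        )
        n_affected = sum(1 for s in statuses[fi].values() if s == "affected")
        n_carriers = sum(1 for v in carriers[fi].values() if v)
        truth_rows.append(
            (
                ped.family_id,
                params.causal_gene if is_causal else ".",
                causal_key,
                probands[fi],
                n_affected,
                n_carriers,
                len(ped.members),
            )
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "family_id",
            "causal_gene",
            "causal_variant",
            "proband_id",
            "n_affected",
            "n_trait_carriers",
            "n_members",
        ],
    )

    return SyntheticCohort(
        params=params,
        keys=keys,
        genotypes=genotypes,
        annotations=annotations,
        ped_table=ped_table,
        pedigrees=pedigrees,
        reference=reference,
        truth=truth,
        causal_keys=causal_keys,
        genotypes_all=genotypes_all,
    )


_SEX_OUT = {"male": "1", "female": "2", "unknown": "0"}
_STATUS_OUT = {"unaffected": "1", "affected": "2", "unknown": "0"}


def write_ped(ped_table: pd.DataFrame, path: str | Path) -> None:
    """Write the tidy pedigree table as a 7-column PED file."""
    with open(path, "w") as fh:
        for row in ped_table.itertuples(index=False):
            fh.write(
                " ".join(
                    [
                        str(row.family_id),
                        row.individual_id,
                        row.father_id,
                        row.mother_id,
                        _SEX_OUT[row.sex],
                        _STATUS_OUT[row.status],
                        "1" if row.is_proband else "0",
                    ]
                )
                + "\n"
            )


def emit_cohort(params: SimParams | None = None, out_dir: str | Path = ".", **overrides) -> dict[str, Path]:
    """Simulate a cohort and write it to disk.

    Emits ``cohort.vcf`` (sequenced samples), ``cohort.ped`` (all members),
    ``annotations.tsv``, ``reference_counts.tsv`` (with the generating
    carrier frequency as an extra column) and ``truth.tsv`` (causal gene,
    causal variant per family, proband, affected counts).  Identical
    parameters and seed produce byte-identical files.
    """
    cohort = simulate_cohort(params, **overrides)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "cohort.vcf",
        "ped": out / "cohort.ped",
        "annotations": out / "annotations.tsv",
        "reference": out / "reference_counts.tsv",
        "truth": out / "truth.tsv",
    }
    write_vcf(cohort.keys, cohort.genotypes, paths["vcf"])
    write_ped(cohort.ped_table, paths["ped"])
    write_annotations(cohort.annotations, paths["annotations"])
    write_reference_counts(cohort.reference, paths["reference"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
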