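"""Independent brute-force oracles used to validate the package's statistics.

Everything here is written directly from the mathematical definitions —
exact rational arithmetic for the hypergeometric tail, literal truth tables
for segregation, set comprehensions for the filter cascade, the textbook
step-up for Benjamini-Hochberg — and deliberately shares no code with the
implementation it checks.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


# ---------------------------------------------------------------------------
# Exact hypergeometric enumeration (rational arithmetic)

_TIE_FACTOR = 1 + Fraction(1, 10**7)  # the two-sided tie tolerance, exactly


def fisher_oracle(a: int, b: int, c: int, d: int, sidedness: str) -> float:
    """Fisher exact p by exhaustive enumeration with Fraction arithmetic."""
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    denom = comb(n, c1)

    def pmf(k: int) -> Fraction:
        return Fraction(comb(r1, k) * comb(r2, c1 - k), denom)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    if sidedness == "enrichment":
        total = sum(pmf(k) for k in range(a, hi + 1))
    elif sidedness == "depletion":
        total = sum(pmf(k) for k in range(lo, a + 1))
    else:  # two_sided
        cut = pmf(a) * _TIE_FACTOR
        total = sum(pmf(k) for k in range(lo, hi + 1) if pmf(k) <= cut)
    return float(min(Fraction(1), total))


# ---------------------------------------------------------------------------
# Segregation truth table

MISSING_GENO = None


def segregation_oracle(statuses: list[str], genotypes: list, mode: str) -> str:
    """Literal evaluation of the dominant co-segregation contract.

    ``genotypes`` holds dosages 0/1/2 or None for missing; ``statuses`` are
    affected/unaffected/unknown.  Unknown-status and missing-genotype
    members are ignored; < 2 genotyped affected members is uninformative;
    an affected genotyped non-carrier always violates; a genotyped
    unaffected carrier violates only in strict mode.
    """
    ids = range(len(statuses))
    genotyped = {i for i in ids if genotypes[i] is not None and genotypes[i] >= 0}
    affected = {i for i in genotyped if statuses[i] == "affected"}
    unaffected = {i for i in genotyped if statuses[i] == "unaffected"}
    carriers = {i for i in genotyped if genotypes[i] > 0}
    if len(affected) < 2:
        return "uninformative"
    if mode == "strict":
        ok = affected <= carriers and not (unaffected & carriers)
    else:
        ok = affected <= carriers
    return "co_segregates" if ok else "violates"


# ---------------------------------------------------------------------------
# Filter cascade by set comprehension


def cascade_oracle(annotations, genotypes, pedigrees, config):
    """Surviving (gene -> set of keys) by direct set comprehension.

    Applies the post-conditions literally and independently of order:
    variant-level predicates conjoined, then the gene-level proband rule.
    """
    members = {m.id: m for ped in pedigrees for m in ped.members}
    unaffected = {s for s, m in members.items() if m.status == "unaffected"}
    probands = {s for s, m in members.items() if m.is_proband}

    def carriers_of(key):
        arr = genotypes.calls[key]
        return {
            s
            for s in genotypes.sample_ids
            if arr[genotypes.sample_ids.index(s)] > 0
        }

    def variant_ok(ann):
        qc_ok = all(
            ann.qc.get(f) is None or ann.qc[f] >= t
            for f, t in config.qc_thresholds.items()
        )
        csq_ok = ann.consequence in config.consequence_whitelist
        maf_ok = all(v < config.maf_threshold for v in ann.maf_by_db.values())
        consensus_ok = (
            not config.consensus_removes
            or sum(1 for v in ann.tool_calls.values() if v == "deleterious")
            >= config.consensus_k
        )
        cc_ok = (
            len(carriers_of(ann.key) & unaffected)
            <= config.max_unaffected_controls_with_variant
        )
        gene_ok = config.gene_whitelist is None or ann.gene in config.gene_whitelist
        return qc_ok and csq_ok and maf_ok and consensus_ok and cc_ok and gene_ok

    survivors = [ann for ann in annotations if variant_ok(ann)]
    genes = {ann.gene for ann in survivors}
    result = {}
    for gene in genes:
        keys = {ann.key for ann in survivors if ann.gene == gene}
        carrying_probands = set()
        for key in keys:
            carrying_probands |= carriers_of(key) & probands
        if len(carrying_probands) >= config.min_probands_per_gene:
            result[gene] = keys
    return result


# ---------------------------------------------------------------------------
# Benjamini-Hochberg step-up


def bh_oracle(p_values: list[float]) -> list[float]:
    """Textbook BH adjusted values: q_(i) = min_{j >= i} (m * p_(j) / j)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, m * p_values[i] / rank_from_top)
        adjusted[i] = min(1.0, running_min)
    return adjusted


# ---------------------------------------------------------------------------
# Dominant-trait spiking with ascertainment, literal Monte-Carlo


def spike_oracle(pedigree, penetrance: float, rng, max_retries: int = 200):
    """Independent simulation of the trait-spiking contract.

    Picks a founder with offspring uniformly, transmits the het allele with
    fair coin flips parents-before-children, affects carriers with the given
    penetrance, and resamples (bounded) until an affected carrier exists.
    Returns (n_carriers, n_affected).
    """
    members = {m.id: m for m in pedigree.members}
    children_of = {m.id: (m.father_id, m.mother_id) for m in pedigree.members}
    parents = {p for pair in children_of.values() for p in pair}
    eligible = [m.id for m in pedigree.members if m.is_founder and m.id in parents]
    founder = eligible[int(rng.integers(len(eligible)))]

    order = []
    placed = set()
    pending = list(pedigree.members)
    while pending:
        rest = []
        for m in pending:
            if all(p == "0" or p in placed or p not in members for p in (m.father_id, m.mother_id)):
                order.append(m)
                placed.add(m.id)
            else:
                rest.append(m)
        pending = rest

    for _ in range(max_retries):
        carrier = {}
        for m in order:
            if m.is_founder:
                carrier[m.id] = m.id == founder
            else:
                carrier[m.id] = any(
                    carrier.get(p, False) and rng.random() < 0.5
                    for p in (m.father_id, m.mother_id)
                )
        affected = {m: c and rng.random() < penetrance for m, c in carrier.items()}
        if any(affected[m] and carrier[m] for m in carrier):
            return sum(carrier.values()), sum(affected.values())
    raise RuntimeError("no affected carrier")
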