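"""Multigenerational families and autosomal dominant co-segregation checks.

A variant co-segregates with a dominantly inherited trait in a family when
every genotyped affected member carries at least one alternate allele and
(in strict mode) no genotyped unaffected member carries it.  Members with
unknown phenotype or missing genotype never trigger violations; a family
with fewer than two genotyped affected members is uninformative.

All variants are treated as autosomal; X-linkage and hemizygosity are out
of model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, CohortGenotypes, VariantKey

__all__ = [
    "Sample",
    "Pedigree",
    "SegregationResult",
    "PedigreeError",
    "build_pedigrees",
    "check_segregation",
    "segregating_families",
]

FOUNDER = "0"


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, cross-family links)."""


@dataclass
class Sample:
    id: str
    family_id: str
    father_id: str = FOUNDER
    mother_id: str = FOUNDER
    sex: str = "unknown"
    status: str = "unknown"  # affected / unaffected / unknown
    is_proband: bool = False

    @property
    def is_founder(self) -> bool:
        return self.father_id == FOUNDER and self.mother_id == FOUNDER


@dataclass
class Pedigree:
    """One family: members plus child -> (father, mother) links."""

    family_id: str
    members: list[Sample] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {m.id: m for m in self.members}

    @property
    def edges(self) -> dict[str, tuple[str, str]]:
        return {
            m.id: (m.father_id, m.mother_id) for m in self.members if not m.is_founder
        }

    def member(self, sample_id: str) -> Sample:
        return self._by_id[sample_id]

    @property
    def proband(self) -> Sample | None:
        for m in self.members:
            if m.is_proband:
                return m
        return None

    def validate(self) -> None:
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            raise PedigreeError(f"family {self.family_id}: duplicate member ids")
        probands = [m for m in self.members if m.is_proband]
        if len(probands) > 1:
            raise PedigreeError(f"family {self.family_id}: more than one proband")
        for m in self.members:
            for parent in (m.father_id, m.mother_id):
                if parent != FOUNDER and parent not in self._by_id:
                    raise PedigreeError(
                        f"family {self.family_id}: parent {parent} of {m.id} not a member"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {m.id: WHITE for m in self.members}

        def visit(node: str) -> None:
            color[node] = GRAY
            m = self._by_id[node]
            for parent in (m.father_id, m.mother_id):
                if parent == FOUNDER or parent not in color:
                    continue
                if color[parent] == GRAY:
                    raise PedigreeError(
                        f"family {self.family_id}: ancestry cycle through {parent}"
                    )
                if color[parent] == WHITE:
                    visit(parent)
            color[node] = BLACK

        for m in self.members:
            if color[m.id] == WHITE:
                visit(m.id)


@dataclass
class SegregationResult:
    family_id: str
    key: VariantKey
    verdict: str  # co_segregates / violates / uninformative
    affected_carriers: int
    affected_noncarriers: int
    unaffected_carriers: int
    genotyped_members: int


def build_pedigrees(ped_table: pd.DataFrame) -> list[Pedigree]:
    """Assemble one validated :class:`Pedigree` per family in the PED table.

    A parent id that never appears as an individual in the file is recorded
    as an external founder placeholder (unknown sex and phenotype, no
    genotype).  A parent listed under a different family is an error.
    """
    family_of = dict(
        zip(ped_table["individual_id"], ped_table["family_id"])
    )
    pedigrees = []
    for fam, group in ped_table.groupby("family_id", sort=False):
        members = []
        present = set(group["individual_id"])
        for row in group.itertuples(index=False):
            for parent in (row.father_id, row.mother_id):
                if parent == FOUNDER:
                    continue
                if parent in family_of and family_of[parent] != fam:
                    raise PedigreeError(
                        f"family {fam}: parent {parent} of {row.individual_id} "
                        f"belongs to family {family_of[parent]}"
                    )
            members.append(
                Sample(
                    id=row.individual_id,
                    family_id=fam,
                    father_id=row.father_id,
                    mother_id=row.mother_id,
                    sex=row.sex,
                    status=row.status,
                    is_proband=bool(row.is_proband),
                )
            )
        # external founder placeholders for parents missing from the file
        for row in group.itertuples(index=False):
            for parent in (row.father_id, row.mother_id):
                if parent != FOUNDER and parent not in present:
                    members.append(Sample(id=parent, family_id=fam))
                    present.add(parent)
        ped = Pedigree(family_id=str(fam), members=members)
        ped.validate()
        pedigrees.append(ped)
    return pedigrees


def check_segregation(
    pedigree: Pedigree,
    genotypes: CohortGenotypes,
    key: VariantKey,
    mode: str = "strict",
) -> SegregationResult:
    """Test dominant co-segregation of ``key`` with the trait in one family.

    ``strict``: co-segregates iff every genotyped affected member carries at
    least one alt allele and no genotyped unaffected member carries it.
    ``allow_nonpenetrance``: unaffected carriers are counted but tolerated;
    only a genotyped affected non-carrier violates.  Members with unknown
    status or missing genotype are ignored.  A family with fewer than two
    genotyped affected members is uninformative.
    """
    if mode not in ("strict", "allow_nonpenetrance"):
        raise ValueError(f"unknown segregation mode {mode!r}")
    if key not in genotypes.calls:
        raise KeyError(f"variant {key} absent from cohort genotypes")
    arr = genotypes.calls[key]
    aff_car = aff_non = unaff_car = genotyped = 0
    for m in pedigree.members:
        idx = genotypes._index.get(m.id)
        if idx is None:
            continue  # unsequenced member
        g = int(arr[idx])
        if g == MISSING:
            continue
        genotyped += 1
        if m.status == "affected":
            if g > 0:
                aff_car += 1
            else:
                aff_non += 1
        elif m.status == "unaffected" and g > 0:
            unaff_car += 1
    n_genotyped_affected = aff_car + aff_non
    if n_genotyped_affected < 2:
        verdict = "uninformative"
    elif aff_non > 0:
        verdict = "violates"
    elif mode == "strict" and unaff_car > 0:
        verdict = "violates"
    else:
        verdict = "co_segregates"
    return SegregationResult(
        family_id=pedigree.family_id,
        key=key,
        verdict=verdict,
        affected_carriers=aff_car,
        affected_noncarriers=aff_non,
        unaffected_carriers=unaff_car,
        genotyped_members=genotyped,
    )


def segregating_families(
    pedigrees: list[Pedigree],
    genotypes: CohortGenotypes,
    key: VariantKey,
    mode: str = "strict",
) -> int:
    """Number of families in which ``key`` co-segregates with the trait."""
    return sum(
        1
        for ped in pedigrees
        if check_segregation(ped, genotypes, key, mode).verdict == "co_segregates"
    )


class FamilyIndex:
    """Precomputed per-family sample indices for fast sweeps over many variants."""

    def __init__(self, pedigrees: list[Pedigree], genotypes: CohortGenotypes):
        self.families = []
        for ped in pedigrees:
            idx, aff = [], []
            for m in ped.members:
                i = genotypes._index.get(m.id)
                if i is None:
                    continue
                idx.append(i)
                aff.append({"affected": 1, "unaffected": 0}.get(m.status, 2))
            self.families.append(
                (ped.family_id, np.array(idx, dtype=np.intp), np.array(aff, dtype=np.int8))
            )

    def verdicts(self, calls: np.ndarray, mode: str = "strict") -> dict[str, str]:
        """Segregation verdict per family for one variant's call array."""
        out = {}
        for family_id, idx, aff in self.families:
            g = calls[idx]
            seen = g != MISSING
            aff_mask = seen & (aff == 1)
            n_aff = int(aff_mask.sum())
            if n_aff < 2:
                out[family_id] = "uninformative"
                continue
            carrier = g > 0
            if int((aff_mask & ~carrier).sum()) > 0:
                out[family_id] = "violates"
            elif mode == "strict" and int((seen & (aff == 0) & carrier).sum()) > 0:
                out[family_id] = "violates"
            else:
                out[family_id] = "co_segregates"
        return out
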