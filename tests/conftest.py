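"""Shared fixtures: tiny literal VCF/PED texts and randomized cohort builders."""

from __future__ import annotations

import numpy as np
import pytest

from famburden.io_formats import CohortGenotypes, VariantAnnotation, VariantKey
from famburden.pedigree import Pedigree, Sample

TRIO_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
1\t100\t.\tA\tG\t50\tPASS\t.\tGT\t0/1\t0|0
1\t200\t.\tC\tT\t50\tPASS\t.\tGT\t1/1\t./.
1\t300\t.\tG\tA\t50\tPASS\t.\tGT\t0/0\t0/1
"""

MULTIALLELIC_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4\tS5
1\t500\t.\tC\tA,T\t50\tPASS\t.\tGT\t1/2\t0/2\t2/2\t0/0\t./.
"""

@pytest.fixture
def trio_vcf(tmp_path):
    path = tmp_path / "trio.vcf"
    path.write_text(TRIO_VCF)
    return path


@pytest.fixture
def multiallelic_vcf(tmp_path):
    path = tmp_path / "multi.vcf"
    path.write_text(MULTIALLELIC_VCF)
    return path


@pytest.fixture
def trio_ped(tmp_path):
    # father unaffected, mother affected, child affected proband
    path = tmp_path / "trio.ped"
    path.write_text(
        "FAM1 DAD 0 0 1 1\n"
        "FAM1 MOM 0 0 2 2\n"
        "FAM1 KID DAD MOM 1 2\n"
    )
    return path


def make_family(
    family_id: str,
    statuses: list[str],
    proband_index: int | None = None,
) -> Pedigree:
    """A flat family of unrelated members with given affection statuses."""
    members = [
        Sample(
            id=f"{family_id}-{i + 1}",
            family_id=family_id,
            status=status,
            is_proband=(i == proband_index),
        )
        for i, status in enumerate(statuses)
    ]
    ped = Pedigree(family_id=family_id, members=members)
    ped.validate()
    return ped


def random_cohort(rng: np.random.Generator, n_variants: int = 60, n_families: int = 8):
    """Randomized annotations + genotypes + flat pedigrees for oracle checks.

    Variants get adversarial annotation values (MAFs at and around the
    threshold, every consequence class, sparse QC fields) and random dosages
    including missing calls.
    """
    pedigrees = []
    for f in range(n_families):
        n = int(rng.integers(2, 6))
        statuses = [
            str(rng.choice(["affected", "unaffected", "unknown"], p=[0.45, 0.45, 0.1]))
            for _ in range(n)
        ]
        proband = int(rng.integers(n))
        pedigrees.append(make_family(f"F{f + 1}", statuses, proband))
    sample_ids = [m.id for ped in pedigrees for m in ped.members]
    genotypes = CohortGenotypes(sample_ids=sample_ids)
    annotations = []
    consequences = ["missense", "nonsense", "frameshift", "splice_site", "synonymous", "other"]
    maf_pool = [0.0, 1e-4, 0.01, 0.024999, 0.025, 0.0251, 0.1, 0.4]
    genes = [f"G{i}" for i in range(1, max(2, n_variants // 6))]
    for v in range(n_variants):
        key = VariantKey("1", 1000 + v, "A", "G")
        maf_by_db = {
            db: float(rng.choice(maf_pool))
            for db in ("exac", "gnomad")
            if rng.random() < 0.7
        }
        tool_calls = {
            t: str(rng.choice(["deleterious", "tolerated", "missing"]))
            for t in ("sift", "polyphen2", "mutationtaster", "provean", "cadd")
        }
        qc = {}
        if rng.random() < 0.5:
            qc["call_rate"] = float(rng.uniform(0.5, 1.0))
        if rng.random() < 0.5:
            qc["mean_depth"] = float(rng.uniform(2, 80))
        annotations.append(
            VariantAnnotation(
                key=key,
                gene=str(rng.choice(genes)),
                consequence=str(rng.choice(consequences)),
                maf_by_db=maf_by_db,
                tool_calls=tool_calls,
                qc=qc,
            )
        )
        genotypes.calls[key] = rng.choice(
            np.array([-1, 0, 0, 0, 1, 1, 2], dtype=np.int8), size=len(sample_ids)
        )
    return annotations, genotypes, pedigrees
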