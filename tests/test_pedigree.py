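"""Pedigree assembly and autosomal dominant co-segregation verdicts."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from famburden.io_formats import MISSING, CohortGenotypes, VariantKey
from famburden.pedigree import (
    Pedigree,
    PedigreeError,
    Sample,
    build_pedigrees,
    check_segregation,
    segregating_families,
)

from conftest import make_family
from oracles import segregation_oracle

KEY = VariantKey("1", 100, "A", "G")


def ped_df(rows):
    return pd.DataFrame(
        rows,
        columns=["family_id", "individual_id", "father_id", "mother_id", "sex", "status", "is_proband"],
    )


def family_genotypes(pedigree: Pedigree, dosages: dict[str, int]) -> CohortGenotypes:
    ids = [m.id for m in pedigree.members if m.id in dosages]
    g = CohortGenotypes(sample_ids=ids)
    g.calls[KEY] = np.array([dosages[s] for s in ids], dtype=np.int8)
    return g


class TestBuildPedigrees:
    def test_three_generation_family(self):
        rows = [
            ("F1", "GP1", "0", "0", "male", "affected", False),
            ("F1", "GM1", "0", "0", "female", "unaffected", False),
            ("F1", "DAD", "GP1", "GM1", "male", "affected", False),
            ("F1", "MOM", "0", "0", "female", "unaffected", False),
            ("F1", "C1", "DAD", "MOM", "male", "affected", True),
            ("F1", "C2", "DAD", "MOM", "female", "unaffected", False),
            ("F1", "C3", "DAD", "MOM", "female", "unknown", False),
            ("F1", "UNCLE", "GP1", "GM1", "male", "unaffected", False),
        ]
        (ped,) = build_pedigrees(ped_df(rows))
        assert len(ped.members) == 8
        assert ped.proband.id == "C1"
        assert ped.edges["C1"] == ("DAD", "MOM")

    def test_two_families(self):
        rows = [
            ("F1", "A", "0", "0", "male", "affected", True),
            ("F2", "B", "0", "0", "female", "affected", True),
        ]
        assert [p.family_id for p in build_pedigrees(ped_df(rows))] == ["F1", "F2"]

    def test_cross_family_parent_rejected(self):
        rows = [
            ("F1", "MOM", "0", "0", "female", "affected", False),
            ("F2", "KID", "0", "MOM", "male", "affected", True),
        ]
        with pytest.raises(PedigreeError, match="belongs to family"):
            build_pedigrees(ped_df(rows))

    def test_missing_parent_becomes_external_founder(self):
        rows = [("F1", "KID", "DAD", "0", "male", "affected", True)]
        (ped,) = build_pedigrees(ped_df(rows))
        dad = ped.member("DAD")
        assert dad.is_founder and dad.status == "unknown"

    def test_ancestry_cycle_rejected(self):
        # A and B are each other's parents
        members = [
            Sample(id="A", family_id="F1", father_id="B"),
            Sample(id="B", family_id="F1", father_id="A"),
        ]
        with pytest.raises(PedigreeError, match="cycle"):
            Pedigree(family_id="F1", members=members).validate()


class TestCheckSegregation:
    def family_of_four(self):
        return make_family(
            "F1", ["affected", "affected", "unaffected", "unknown"], proband_index=0
        )

    def test_clean_cosegregation(self):
        ped = self.family_of_four()
        g = family_genotypes(ped, {"F1-1": 1, "F1-2": 1, "F1-3": 0, "F1-4": MISSING})
        res = check_segregation(ped, g, KEY, "strict")
        assert res.verdict == "co_segregates"
        assert (res.affected_carriers, res.unaffected_carriers) == (2, 0)
        assert res.genotyped_members == 3

    def test_unaffected_carrier_mode_contrast(self):
        """An unaffected het violates strict mode but is tolerated when the
        model allows non-penetrance."""
        ped = self.family_of_four()
        g = family_genotypes(ped, {"F1-1": 1, "F1-2": 1, "F1-3": 1, "F1-4": MISSING})
        assert check_segregation(ped, g, KEY, "strict").verdict == "violates"
        res = check_segregation(ped, g, KEY, "allow_nonpenetrance")
        assert res.verdict == "co_segregates"
        assert res.unaffected_carriers == 1

    def test_affected_noncarrier_always_violates(self):
        ped = self.family_of_four()
        g = family_genotypes(ped, {"F1-1": 1, "F1-2": 0, "F1-3": 0, "F1-4": 0})
        for mode in ("strict", "allow_nonpenetrance"):
            assert check_segregation(ped, g, KEY, mode).verdict == "violates"

    def test_single_genotyped_affected_is_uninformative(self):
        ped = self.family_of_four()
        g = family_genotypes(ped, {"F1-1": 1, "F1-2": MISSING, "F1-3": 0, "F1-4": 0})
        assert check_segregation(ped, g, KEY).verdict == "uninformative"

    def test_unsequenced_members_ignored(self):
        ped = self.family_of_four()
        g = family_genotypes(ped, {"F1-1": 1, "F1-2": 1})  # others not in the VCF
        assert check_segregation(ped, g, KEY).verdict == "co_segregates"

    def test_absent_variant_rejected(self):
        ped = self.family_of_four()
        g = family_genotypes(ped, {"F1-1": 1, "F1-2": 1, "F1-3": 0, "F1-4": 0})
        with pytest.raises(KeyError):
            check_segregation(ped, g, VariantKey("9", 9, "A", "C"), "strict")

    @pytest.mark.parametrize("mode", ["strict", "allow_nonpenetrance"])
    def test_exhaustive_trio_matches_truth_table(self, mode):
        """Every genotype/status assignment of a trio agrees with the oracle."""
        statuses_pool = ["affected", "unaffected", "unknown"]
        geno_pool = [None, 0, 1, 2]
        ped = make_family("F1", ["unknown"] * 3, proband_index=0)
        for statuses in itertools.product(statuses_pool, repeat=3):
            for m, s in zip(ped.members, statuses):
                m.status = s
            for genos in itertools.product(geno_pool, repeat=3):
                dosages = {
                    f"F1-{i + 1}": (MISSING if g is None else g)
                    for i, g in enumerate(genos)
                }
                g = family_genotypes(ped, dosages)
                got = check_segregation(ped, g, KEY, mode).verdict
                assert got == segregation_oracle(list(statuses), list(genos), mode)

    def test_verdict_invariant_to_member_order_and_ids(self):
        rng = np.random.default_rng(7)
        for trial in range(50):
            n = int(rng.integers(3, 7))
            statuses = [str(rng.choice(["affected", "unaffected", "unknown"])) for _ in range(n)]
            genos = [int(rng.choice([-1, 0, 1, 2])) for _ in range(n)]
            ped = make_family("F1", statuses, proband_index=0)
            g = family_genotypes(ped, {f"F1-{i+1}": genos[i] for i in range(n)})
            base = check_segregation(ped, g, KEY, "strict").verdict
            # permuted members, relabeled ids
            perm = rng.permutation(n)
            members = [
                Sample(id=f"X{j}", family_id="F1", status=statuses[i], is_proband=(i == 0))
                for j, i in enumerate(perm)
            ]
            ped2 = Pedigree(family_id="F1", members=members)
            g2 = CohortGenotypes(sample_ids=[m.id for m in members])
            g2.calls[KEY] = np.array([genos[i] for i in perm], dtype=np.int8)
            assert check_segregation(ped2, g2, KEY, "strict").verdict == base

    def test_mode_monotonicity(self):
        """Families co-segregating strictly also co-segregate when
        non-penetrance is allowed (the lenient verdict set is a superset)."""
        rng = np.random.default_rng(13)
        for trial in range(200):
            n = int(rng.integers(3, 6))
            statuses = [str(rng.choice(["affected", "unaffected", "unknown"])) for _ in range(n)]
            genos = [int(rng.choice([-1, 0, 1, 2])) for _ in range(n)]
            ped = make_family("F1", statuses, proband_index=0)
            g = family_genotypes(ped, {f"F1-{i+1}": genos[i] for i in range(n)})
            strict = check_segregation(ped, g, KEY, "strict").verdict
            lenient = check_segregation(ped, g, KEY, "allow_nonpenetrance").verdict
            if strict == "co_segregates":
                assert lenient == "co_segregates"
            if strict == "uninformative":
                assert lenient == "uninformative"


class TestSegregatingFamilies:
    def test_mixed_verdict_count(self):
        peds, dosage_sets = [], []
        # two clean co-segregating families and one with an affected non-carrier
        for f, genos in enumerate([(1, 1, 0), (1, 2, 0), (1, 0, 0)]):
            ped = make_family(f"F{f+1}", ["affected", "affected", "unaffected"], 0)
            peds.append(ped)
            dosage_sets.append({f"F{f+1}-{i+1}": genos[i] for i in range(3)})
        ids = [s for d in dosage_sets for s in d]
        g = CohortGenotypes(sample_ids=ids)
        g.calls[KEY] = np.array(
            [d[s] for d in dosage_sets for s in d], dtype=np.int8
        )
        assert segregating_families(peds, g, KEY, "strict") == 2

    def test_no_genotyped_families(self):
        peds = [make_family("F1", ["affected", "affected"], 0)]
        g = CohortGenotypes(sample_ids=["OTHER"])
        g.calls[KEY] = np.array([1], dtype=np.int8)
        assert segregating_families(peds, g, KEY) == 0
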