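"""The filter cascade: individual predicates, ordering, and oracle equivalence."""

from __future__ import annotations

import numpy as np
import pytest

from famburden.filters import (
    case_control_filter,
    consensus_filter,
    consequence_filter,
    maf_filter,
    multi_family_filter,
    qc_filter,
    run_cascade,
)
from famburden.io_formats import (
    CohortGenotypes,
    RunConfig,
    VariantAnnotation,
    VariantKey,
)

from conftest import make_family, random_cohort
from oracles import cascade_oracle


def ann(consequence="missense", mafs=None, tools=0, qc=None, gene="G1", pos=100):
    return VariantAnnotation(
        key=VariantKey("1", pos, "A", "G"),
        gene=gene,
        consequence=consequence,
        maf_by_db=mafs or {},
        tool_calls={
            f"tool{i}": ("deleterious" if i < tools else "tolerated") for i in range(5)
        },
        qc=qc or {},
    )


class TestVariantFilters:
    def test_qc_pass_fail_and_permissive_default(self):
        assert qc_filter(ann(qc={"call_rate": 0.99}), {"call_rate": 0.9})
        assert not qc_filter(ann(qc={"mean_depth": 4.0}), {"mean_depth": 8.0})
        assert qc_filter(ann(qc={}), {"mean_depth": 8.0})  # absent fields pass

    @pytest.mark.parametrize(
        "consequence,expected",
        [("missense", True), ("splice_site", True), ("synonymous", False), ("other", False)],
    )
    def test_consequence_whitelist(self, consequence, expected):
        whitelist = RunConfig().consequence_whitelist
        assert consequence_filter(ann(consequence), whitelist) is expected

    def test_maf_below_threshold_passes(self):
        assert maf_filter(ann(mafs={"exac": 0.001, "gnomad": 0.002}), 0.025)

    def test_maf_above_threshold_fails(self):
        assert not maf_filter(ann(mafs={"g1000": 0.03}), 0.025)

    def test_maf_boundary_is_strict(self):
        """'rare' means strictly below the threshold: 2.5% exactly is removed."""
        assert not maf_filter(ann(mafs={"exac": 0.025}), 0.025)
        assert maf_filter(ann(mafs={"exac": 0.024999}), 0.025)

    def test_novel_variant_passes(self):
        assert maf_filter(ann(mafs={}), 0.025)  # absent everywhere = novel
        assert maf_filter(ann(mafs={"exac": 0.0}), 0.025)  # reported 0 also passes

    @pytest.mark.parametrize("k_del,expected", [(3, True), (2, False), (0, False)])
    def test_consensus_threshold(self, k_del, expected):
        assert consensus_filter(ann(tools=k_del), 3, 5) is expected

    def test_consensus_missing_calls_are_nondeleterious(self):
        a = ann()
        a.tool_calls = {f"tool{i}": "missing" for i in range(5)}
        assert not consensus_filter(a, 3, 5)

    @pytest.mark.parametrize("n_carrying,expected", [(0, True), (1, True), (2, False)])
    def test_case_control_boundary(self, n_carrying, expected):
        """'more than 1 unaffected control' removes: exactly 1 still passes."""
        g = CohortGenotypes(sample_ids=["U1", "U2", "U3", "A1"])
        key = VariantKey("1", 100, "A", "G")
        calls = np.zeros(4, dtype=np.int8)
        calls[:n_carrying] = 1
        calls[3] = 1  # an affected carrier never counts
        g.calls[key] = calls
        assert case_control_filter(key, g, {"U1", "U2", "U3"}, 1) is expected

    def test_multi_family_counts_probands_not_variants(self):
        key1, key2 = VariantKey("1", 1, "A", "G"), VariantKey("1", 2, "C", "T")
        g = CohortGenotypes(sample_ids=["P1", "P2"])
        # gene A: one variant in each proband; gene B: two variants, same proband
        g.calls[key1] = np.array([1, 0], dtype=np.int8)
        g.calls[key2] = np.array([1, 0], dtype=np.int8)
        assert multi_family_filter({"B": [key1, key2]}, g, {"P1", "P2"}, 2) == set()
        g.calls[key2] = np.array([0, 1], dtype=np.int8)
        assert multi_family_filter({"A": [key1, key2]}, g, {"P1", "P2"}, 2) == {"A"}


def surviving_keys(retained_by_gene):
    return {g: {a.key for a in anns} for g, anns in retained_by_gene.items()}


class TestRunCascade:
    def engineered_fixture(self):
        """Deterministic cohort where each filter removes known variants."""
        fams = [
            make_family("F1", ["affected", "unaffected"], 0),
            make_family("F2", ["affected", "unaffected"], 0),
            make_family("F3", ["unaffected", "unaffected"], 0),
        ]
        samples = [m.id for f in fams for m in f.members]
        g = CohortGenotypes(sample_ids=samples)
        anns = []

        def add(pos, gene, consequence="missense", mafs=None, qc=None, dosages=None):
            a = ann(consequence, mafs, tools=3, qc=qc, gene=gene, pos=pos)
            anns.append(a)
            g.calls[a.key] = np.array(dosages or [0] * 6, dtype=np.int8)

        both_probands = [1, 0, 1, 0, 0, 0]
        one_proband = [1, 0, 0, 0, 0, 0]
        add(1, "GOOD", dosages=both_probands)                                  # retained
        add(2, "GOOD", mafs={"exac": 0.01}, dosages=one_proband)               # retained
        add(3, "BADQC", qc={"mean_depth": 2.0}, dosages=both_probands)         # qc
        add(4, "SYN", consequence="synonymous", dosages=both_probands)         # consequence
        add(5, "COMMON", mafs={"exac": 0.3}, dosages=both_probands)            # maf
        add(6, "INCTRL", dosages=[1, 1, 1, 1, 1, 0])                           # case_control (2 controls)
        add(7, "LONE", dosages=one_proband)                                    # multi_family
        return anns, g, fams

    def test_engineered_counts_and_first_failing_filter(self):
        anns, g, fams = self.engineered_fixture()
        config = RunConfig(qc_thresholds={"mean_depth": 8.0})
        retained, traces = run_cascade(anns, g, fams, config)
        assert set(retained) == {"GOOD"}
        assert len(retained["GOOD"]) == 2
        removed_by = {t.key.pos: t.removed_by for t in traces}
        assert removed_by == {
            1: None, 2: None, 3: "qc", 4: "consequence", 5: "maf",
            6: "case_control", 7: "multi_family",
        }
        assert surviving_keys(retained) == cascade_oracle(anns, g, fams, config)

    def test_trace_covers_every_variant(self):
        anns, g, fams = self.engineered_fixture()
        retained, traces = run_cascade(anns, g, fams, RunConfig())
        assert len(traces) == len(anns)
        n_retained = sum(len(v) for v in retained.values())
        n_removed = sum(1 for t in traces if t.disposition == "removed")
        assert n_retained + n_removed == len(anns)

    def test_empty_input(self):
        retained, traces = run_cascade([], CohortGenotypes(sample_ids=["S"]), [], RunConfig())
        assert retained == {} and traces == []

    def test_all_synonymous_removed_by_consequence(self):
        fams = [make_family("F1", ["affected"], 0)]
        g = CohortGenotypes(sample_ids=["F1-1"])
        anns = []
        for pos in range(1, 6):
            a = ann("synonymous", pos=pos)
            anns.append(a)
            g.calls[a.key] = np.array([1], dtype=np.int8)
        _, traces = run_cascade(anns, g, fams, RunConfig())
        assert all(t.removed_by == "consequence" for t in traces)

    def test_consensus_annotate_only_vs_removing(self):
        fams = [make_family("F1", ["affected"], 0), make_family("F2", ["affected"], 0)]
        g = CohortGenotypes(sample_ids=["F1-1", "F2-1"])
        a = ann(tools=2)  # fails 3-of-5
        g.calls[a.key] = np.array([1, 1], dtype=np.int8)
        retained, traces = run_cascade([a], g, fams, RunConfig())
        assert traces[0].disposition == "retained"
        assert "consensus_deleterious=no" in traces[0].details
        retained, traces = run_cascade([a], g, fams, RunConfig(consensus_removes=True))
        assert traces[0].removed_by == "consensus"

    def test_matches_brute_force_on_randomized_cohorts(self):
        """Cascade output equals direct set comprehension of the contracts."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            anns, g, fams = random_cohort(rng, n_variants=int(rng.integers(20, 100)))
            config = RunConfig(
                qc_thresholds={"call_rate": 0.9, "mean_depth": 8.0},
                consensus_removes=bool(seed % 2),
                min_probands_per_gene=int(rng.integers(1, 3)),
            )
            retained, traces = run_cascade(anns, g, fams, config)
            assert surviving_keys(retained) == cascade_oracle(anns, g, fams, config)
            assert len(traces) == len(anns)

    def test_variant_filter_order_does_not_change_survivors(self):
        """The variant-level predicates commute: shuffled application orders
        give the same surviving set (only removed_by labels differ)."""
        rng = np.random.default_rng(3)
        anns, g, fams = random_cohort(rng)
        config = RunConfig(qc_thresholds={"call_rate": 0.9})
        members = {m.id: m for f in fams for m in f.members}
        unaffected = {s for s, m in members.items() if m.status == "unaffected"}
        predicates = {
            "qc": lambda a: qc_filter(a, config.qc_thresholds),
            "consequence": lambda a: consequence_filter(a, config.consequence_whitelist),
            "maf": lambda a: maf_filter(a, config.maf_threshold),
            "case_control": lambda a: case_control_filter(
                a.key, g, unaffected, config.max_unaffected_controls_with_variant
            ),
        }
        names = list(predicates)
        baseline = None
        for _ in range(6):
            order = [names[i] for i in rng.permutation(len(names))]
            survivors = {
                a.key for a in anns if all(predicates[n](a) for n in order)
            }
            baseline = survivors if baseline is None else baseline
            assert survivors == baseline
        # the shipped canonical order agrees (multi_family is gene-level)
        _, traces = run_cascade(anns, g, fams, config)
        cascade_survivors = {
            t.key for t in traces if t.removed_by in (None, "multi_family")
        }
        assert cascade_survivors == baseline

    def test_threshold_monotonicity(self):
        """Tightening thresholds never grows the surviving set."""
        rng = np.random.default_rng(4)
        anns, g, fams = random_cohort(rng, n_variants=120)
        loose = cascade_oracle(anns, g, fams, RunConfig(maf_threshold=0.05))
        tight = cascade_oracle(anns, g, fams, RunConfig(maf_threshold=0.01))
        loose_keys = {k for ks in loose.values() for k in ks}
        tight_keys = {k for ks in tight.values() for k in ks}
        assert tight_keys <= loose_keys
        few = set(cascade_oracle(anns, g, fams, RunConfig(min_probands_per_gene=1)))
        many = set(cascade_oracle(anns, g, fams, RunConfig(min_probands_per_gene=3)))
        assert many <= few
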