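"""Filter cascade: stage semantics, oracle equivalence, order invariance."""

import itertools

import pytest

from rettlike.cascade import (
    CascadeConfig,
    calls_by_key,
    carried_key_set,
    child_record_set,
    filter_functional_impact,
    filter_parental,
    filter_pooled_controls,
    filter_population_frequency,
    run_cascade,
)
from rettlike.model import ConfigurationError, GenotypeCall, VariantRecord


def rec(pos, consequence="missense_variant", af=None, gene="G1"):
    af_map = {} if af is None else {"dbSNP": af}
    return VariantRecord("1", pos, "A", "C", gene=gene,
                         consequence=consequence, af_map=af_map)


def het(sample="s"):
    return GenotypeCall(sample, (0, 1), depth=30, genotype_quality=99,
                        allele_depths=(15, 15))


def homref(sample="s"):
    return GenotypeCall(sample, (0, 0), depth=30, genotype_quality=99,
                        allele_depths=(30, 0))


class TestFunctionalImpact:
    def test_keeps_qualifying_and_drops_others(self):
        records = [rec(1), rec(2, "synonymous_variant"), rec(3, None)]
        kept = filter_functional_impact(records)
        assert [r.pos for r in kept] == [1]

    def test_empty_qualifying_set_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            filter_functional_impact([rec(1)], qualifying_consequences=())

    def test_count_matches_linear_scan_oracle(self):
        """1,000 annotated records with 47 qualifying: output size equals an
        independent linear scan."""
        records = [
            rec(i + 1, "missense_variant" if i < 47 else "synonymous_variant")
            for i in range(1000)
        ]
        kept = filter_functional_impact(records)
        oracle = sum(1 for r in records if r.consequence == "missense_variant")
        assert len(kept) == oracle == 47


class TestPopulationFrequency:
    def test_above_threshold_removed(self):
        assert filter_population_frequency([rec(1, af=0.02)]) == []

    def test_boundary_is_inclusive(self):
        # exactly 1% is the classic polymorphism definition: removed
        assert filter_population_frequency([rec(1, af=0.01)]) == []
        assert len(filter_population_frequency([rec(1, af=0.0099)])) == 1

    def test_novel_variant_survives(self):
        assert len(filter_population_frequency([rec(1)])) == 1

    def test_any_source_at_threshold_removes(self):
        r = VariantRecord("1", 5, "A", "C",
                          af_map={"dbSNP": 0.001, "1000G": 0.05})
        assert filter_population_frequency([r]) == []

    def test_unknown_source_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            filter_population_frequency(
                [rec(1)], af_sources=["gnomAD"], declared_sources=["dbSNP"]
            )


class TestParentalAndPool:
    def test_inherited_variant_removed(self):
        r = rec(1)
        kept = filter_parental([r], {r.key: het("fa")}, {})
        assert kept == []

    def test_de_novo_configuration_kept(self):
        r = rec(1)
        kept = filter_parental([r], {r.key: homref("fa")}, {r.key: homref("mo")})
        assert kept == [r]

    def test_parental_nocall_does_not_subtract(self):
        r = rec(1)
        nocall = GenotypeCall("fa", (None, None))
        assert filter_parental([r], {r.key: nocall}, {}) == [r]

    def test_pool_subtraction(self):
        r1, r2 = rec(1), rec(2)
        kept = filter_pooled_controls([r1, r2], {r1.key})
        assert kept == [r2]

    def test_empty_pool_warns_and_is_identity(self):
        r = rec(1)
        with pytest.warns(UserWarning, match="empty"):
            assert filter_pooled_controls([r], set()) == [r]


class TestRunCascade:
    def test_counts_equal_brute_force_oracle(self, small_cohort):
        """Per-stage counts equal an independent brute-force filter over the
        same records, for every family."""
        _, _, records_calls, pedigree = small_cohort
        cfg = CascadeConfig()
        pool_ids = pedigree.parent_ids
        for family in pedigree:
            report = run_cascade(family, records_calls, pedigree, cfg)

            # brute force, re-derived from first principles
            affected = [c.sample_id for c in family.affected_children]
            current = [
                r for r, calls in records_calls
                if any(calls[a].carries_alt for a in affected)
            ]
            sizes = [len(current)]
            current = [
                r for r in current
                if r.consequence in cfg.qualifying_consequences
            ]
            sizes.append(len(current))
            current = [
                r for r in current
                if not any(af >= cfg.af_threshold for af in r.af_map.values())
            ]
            sizes.append(len(current))
            fa = calls_by_key(records_calls, family.father_id)
            mo = calls_by_key(records_calls, family.mother_id)
            current = [
                r for r in current
                if not fa[r.key].carries_alt and not mo[r.key].carries_alt
            ]
            sizes.append(len(current))
            pool = carried_key_set(records_calls, pool_ids)
            current = [r for r in current if r.key not in pool]
            sizes.append(len(current))

            got = [report.stages[0].variants_in] + [s.variants_out for s in report.stages]
            assert got == sizes
            assert report.final_keys == {r.key for r in current}

    def test_monotone_shrinkage_and_chaining(self, small_cohort):
        _, _, records_calls, pedigree = small_cohort
        for family in pedigree:
            report = run_cascade(family, records_calls, pedigree)
            for prev, nxt in zip(report.stages, report.stages[1:]):
                assert nxt.variants_in == prev.variants_out
            for s in report.stages:
                assert s.variants_out <= s.variants_in
            assert report.final_gene_count <= len(report.final_keys)

    def test_stage_order_does_not_change_final_set(self, small_cohort):
        """Each stage is a pure predicate / set subtraction, so every
        permutation of the four filters yields the same final set."""
        _, _, records_calls, pedigree = small_cohort
        family = pedigree.families[0]
        fa = calls_by_key(records_calls, family.father_id)
        mo = calls_by_key(records_calls, family.mother_id)
        pool = carried_key_set(records_calls, pedigree.parent_ids)
        start = child_record_set(records_calls, family)

        stages = {
            "impact": lambda rs: filter_functional_impact(rs),
            "af": lambda rs: filter_population_frequency(rs),
            "parental": lambda rs: filter_parental(rs, fa, mo),
            "pool": lambda rs: filter_pooled_controls(rs, pool),
        }
        finals = set()
        for order in itertools.permutations(stages):
            current = start
            for name in order:
                current = stages[name](current)
            finals.add(frozenset(r.key for r in current))
        assert len(finals) == 1

    def test_family_with_zero_variants(self, small_cohort):
        _, _, _, pedigree = small_cohort
        family = pedigree.families[0]
        with pytest.warns(UserWarning, match="empty"):
            report = run_cascade(family, [], pedigree)
        assert all(s.variants_in == 0 and s.variants_out == 0 for s in report.stages)
        assert report.final_keys == set()

    def test_control_shared_variants_removed_at_pool_stage(self, small_cohort):
        """Planted control-shared variants survive the parental stage but
        all fall at the pooled-controls stage."""
        _, truth, records_calls, pedigree = small_cohort
        removed_at_pool = set()
        survived_parental = set()
        for family in pedigree:
            report = run_cascade(family, records_calls, pedigree)
            parental_out = report.stages[2]
            pool_stage = report.stages[3]
            # reconstruct the pool stage's full removal set
            fa = calls_by_key(records_calls, family.father_id)
            mo = calls_by_key(records_calls, family.mother_id)
            affected = [c.sample_id for c in family.affected_children]
            current = [
                r for r, calls in records_calls
                if any(calls[a].carries_alt for a in affected)
            ]
            current = filter_functional_impact(current)
            current = filter_population_frequency(current)
            current = filter_parental(current, fa, mo)
            survived_parental |= {r.key for r in current}
            pool = carried_key_set(records_calls, pedigree.parent_ids)
            removed_at_pool |= {r.key for r in current if r.key in pool}
        planted = truth.keys_with_label("control_shared")
        assert planted <= survived_parental
        assert planted <= removed_at_pool
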