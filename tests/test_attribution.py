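"""Rule resolution, componentwise attribution, aggregation, and burden I/O."""

import io

import pytest
from hypothesis import given
import hypothesis.strategies as st

from plastattr import (
    AttributionRule,
    OutcomeBurden,
    PRFLookupError,
    PRFTriple,
    RuleError,
    Triple,
    aggregate,
    attribute,
    attribute_table,
    read_burden_table,
    read_rules,
    resolve_prf,
    write_burden_table,
)
from plastattr.errors import BurdenParseError


def _row(cls="PFAS", outcome="Low birth weight", cost=(1.0, 0.5, 2.0), cases=None):
    return OutcomeBurden(
        chemical_class=cls,
        exposure_chemical="X",
        life_stage="Prenatal",
        outcome=outcome,
        cost=Triple(*cost),
        cases=None if cases is None else Triple(*cases),
    )


PFOA = PRFTriple(0.93, 0.8955, 0.9645, "PFOA")
PFOS = PRFTriple(0.317, 0.158, 0.475, "PFOS")


class TestResolvePRF:
    def test_envelope_substitution_spans_chemicals(self):
        """A PFOA-based outcome takes its low bound from PFOS: 93% (16%-96%)."""
        rules = [AttributionRule(match_class="PFAS", base_prf_chemical="PFOA",
                                 envelope_prf_chemicals=("PFOA", "PFOS"))]
        t = resolve_prf(_row(), rules, {"PFOA": PFOA, "PFOS": PFOS})
        assert t.as_tuple() == pytest.approx((0.93, 0.158, 0.9645), abs=1e-12)

    def test_single_chemical_rule_is_identity(self):
        rules = [AttributionRule(match_class="PFAS", base_prf_chemical="PFOA")]
        t = resolve_prf(_row(), rules, {"PFOA": PFOA})
        assert t.as_tuple() == PFOA.as_tuple()

    def test_most_specific_rule_wins(self):
        rules = [
            AttributionRule(base_prf_chemical="GENERIC"),
            AttributionRule(match_class="PFAS", base_prf_chemical="PFOA"),
            AttributionRule(match_class="PFAS", match_outcome="Low birth weight",
                            prf_override=PRFTriple(1.0, 0.71, 1.0)),
        ]
        prfs = {"PFOA": PFOA, "GENERIC": PFOS}
        assert resolve_prf(_row(), rules, prfs).as_tuple() == (1.0, 0.71, 1.0)
        assert resolve_prf(_row(outcome="Obesity"), rules, prfs).base == PFOA.base
        assert resolve_prf(_row(cls="BPA"), rules, prfs).base == PFOS.base

    def test_unmatched_and_ambiguous_rows_are_errors(self):
        with pytest.raises(RuleError, match="no attribution rule"):
            resolve_prf(_row(), [AttributionRule(match_class="BPA",
                                                 base_prf_chemical="BPA")], {})
        dup = [
            AttributionRule(match_class="PFAS", base_prf_chemical="PFOA"),
            AttributionRule(match_outcome="Low birth weight", base_prf_chemical="PFOS"),
        ]
        with pytest.raises(RuleError, match="ambiguous"):
            resolve_prf(_row(), dup, {"PFOA": PFOA, "PFOS": PFOS})

    def test_missing_prf_is_lookup_error(self):
        rules = [AttributionRule(match_class="PFAS", base_prf_chemical="PFOA",
                                 envelope_prf_chemicals=("PFOA", "PFOS"))]
        with pytest.raises(PRFLookupError, match="PFOS"):
            resolve_prf(_row(), rules, {"PFOA": PFOA})

    def test_rule_without_base_or_override_rejected(self):
        with pytest.raises(RuleError, match="base_prf_chemical or prf_override"):
            AttributionRule(match_class="PFAS")

    @given(st.lists(st.tuples(st.floats(0.1, 0.5), st.floats(0.5, 0.9)),
                    min_size=1, max_size=6))
    def test_envelope_equals_bruteforce_min_max_scan(self, bounds):
        prfs = {
            f"C{i}": PRFTriple(base=0.5, low=lo, high=hi, chemical_id=f"C{i}")
            for i, (lo, hi) in enumerate(bounds)
        }
        names = tuple(prfs)
        rules = [AttributionRule(match_class="PFAS", base_prf_chemical=names[0],
                                 envelope_prf_chemicals=names)]
        t = resolve_prf(_row(), rules, prfs)
        # direct loop oracle
        low, high = 1.0, 0.0
        for n in names:
            if prfs[n].low < low:
                low = prfs[n].low
            if prfs[n].high > high:
                high = prfs[n].high
        assert t.low == low and t.high == high and t.base == prfs[names[0]].base


class TestAttribute:
    @pytest.mark.parametrize(
        "cost_base, prf_base, expected",
        [
            (1.04, 0.98, 1.0192),   # childhood obesity worked example
            (24.1, 0.93, 22.413),   # PFAS class total
            (39.7, 0.98, 38.906),   # endometriosis
        ],
    )
    def test_base_attribution_is_exact_product(self, cost_base, prf_base, expected):
        row = _row(cost=(cost_base, cost_base, cost_base))
        prf = PRFTriple(prf_base, prf_base, prf_base)
        assert attribute(row, prf).attributable_cost.base == pytest.approx(
            expected, abs=1e-12
        )

    def test_zero_prf_gives_zero_burden(self):
        res = attribute(_row(cases=(10, 5, 20)), PRFTriple(0, 0, 0))
        assert res.attributable_cost == (0, 0, 0)
        assert res.attributable_cases == (0, 0, 0)

    def test_multiway_pairing_no_cross_terms(self):
        res = attribute(_row(cost=(2.0, 1.0, 4.0)), PRFTriple(0.5, 0.25, 0.75))
        assert res.attributable_cost == pytest.approx((1.0, 0.25, 3.0))

    @given(st.floats(0.01, 100), st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_attribution_is_linear_and_bounded(self, scale, b, lo, hi):
        low, base, high = sorted((b, lo, hi))
        prf = PRFTriple(base=base, low=low, high=high)
        row = _row(cost=(3.0, 2.0, 5.0), cases=(30, 20, 50))
        doubled = _row(cost=(6.0, 4.0, 10.0), cases=(60, 40, 100))
        res, res2 = attribute(row, prf), attribute(doubled, prf)
        for k in range(3):
            # attributable never exceeds the total (PRF <= 1) ...
            assert res.attributable_cost[k] <= row.cost[k] + 1e-12
            # ... scaling the input scales the output
            assert res2.attributable_cost[k] == pytest.approx(
                2 * res.attributable_cost[k], rel=1e-12
            )

    def test_cases_omitted_when_absent(self):
        assert attribute(_row(), PRFTriple(0.5, 0.5, 0.5)).attributable_cases is None


class TestAggregate:
    def test_printed_class_bases_sum_to_grand_total(self):
        results = [
            attribute(_row(cls=c, cost=(v, v, v)), PRFTriple(1, 1, 1))
            for c, v in [("PBDE", 159.0), ("PHTHALATE", 66.7), ("BPA", 1.02),
                         ("PFAS", 22.4)]
        ]
        table = aggregate(results)
        assert table.grand_total.base == pytest.approx(249.12, abs=1e-9)

    def test_single_result_table(self):
        res = attribute(_row(), PRFTriple(0.5, 0.5, 0.5))
        table = aggregate([res])
        assert table.class_subtotals == {"PFAS": res.attributable_cost}
        assert table.grand_total == res.attributable_cost

    @given(st.lists(st.tuples(st.sampled_from("ABC"), st.floats(0.1, 10)),
                    min_size=1, max_size=12))
    def test_aggregate_matches_loop_oracle_and_is_permutation_invariant(self, spec):
        results = [
            attribute(_row(cls=c, cost=(v, v / 2, 2 * v)), PRFTriple(0.9, 0.4, 0.95))
            for c, v in spec
        ]
        table = aggregate(results)
        # brute-force accumulation per component
        for k in range(3):
            expected = {}
            grand = 0.0
            for r in results:
                expected[r.burden.chemical_class] = (
                    expected.get(r.burden.chemical_class, 0.0) + r.attributable_cost[k]
                )
                grand += r.attributable_cost[k]
            for cls, tot in expected.items():
                assert table.class_subtotals[cls][k] == pytest.approx(tot, abs=1e-12)
            assert table.grand_total[k] == pytest.approx(grand, abs=1e-12)
        # permutation leaves totals unchanged (up to float reordering)
        reversed_table = aggregate(list(reversed(results)))
        assert reversed_table.grand_total == pytest.approx(table.grand_total, rel=1e-9)

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            aggregate([])


def test_cost_triples_validated():
    with pytest.raises(ValueError, match="low <= base <= high"):
        _row(cost=(1.0, 2.0, 3.0))
    with pytest.raises(ValueError, match="nonnegative"):
        _row(cost=(-1.0, -1.0, 1.0))


def test_burden_table_round_trip(tmp_path):
    rows = [
        _row(cost=(1.5, 1.0, 2.0), cases=(100, 50, 200)),
        _row(cls="BPA", outcome="Childhood obesity", cost=(1.04, 1.04, 1.04)),
    ]
    path = tmp_path / "burden.csv"
    write_burden_table(rows, path)
    assert read_burden_table(path) == rows


def test_burden_parse_errors():
    with pytest.raises(BurdenParseError, match="missing column"):
        read_burden_table(io.StringIO("chemical_class,outcome\nA,B\n"))
    header = ("chemical_class,exposure_chemical,life_stage,outcome,"
              "cost_base,cost_low,cost_high,cases_base,cases_low,cases_high\n")
    with pytest.raises(BurdenParseError, match="row 1.*all of base/low/high"):
        read_burden_table(io.StringIO(header + "A,X,All,O,1,1,1,5,,\n"))
    with pytest.raises(BurdenParseError, match="row 1.*not numbers"):
        read_burden_table(io.StringIO(header + "A,X,All,O,a,b,c,,,\n"))


def test_read_rules_yaml_and_validation(tmp_path):
    path = tmp_path / "rules.yaml"
    path.write_text(
        "- match: {chemical_class: PFAS}\n"
        "  base_prf_chemical: PFOA\n"
        "  envelope_prf_chemicals: [PFOA, PFOS]\n"
        "- prf_override: {base: 1.0, low: 0.71, high: 1.0}\n"
    )
    rules = read_rules(path)
    assert rules[0].match_class == "PFAS"
    assert rules[0].envelope_prf_chemicals == ("PFOA", "PFOS")
    assert rules[1].prf_override.low == 0.71
    with pytest.raises(RuleError, match="nonempty list"):
        read_rules(io.StringIO("{}"))


def test_attribute_table_end_to_end_smoke(burden_rows, reference_prfs):
    from plastattr import datasets

    table = attribute_table(burden_rows, datasets.default_rules(), reference_prfs)
    assert set(table.class_subtotals) == {"PBDE", "PHTHALATE", "BPA", "PFAS"}
    for res in table.results:
        for k in range(3):
            assert res.attributable_cost[k] <= res.burden.cost[k] + 1e-12
    assert table.grand_total.low <= table.grand_total.base <= table.grand_total.high
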