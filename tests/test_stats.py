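"""The e-Northern statistics: percent abundance, E_r, classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enorthern import (
    ClassifierConfig,
    GeneProfile,
    Status,
    StudyTable,
    ValidationError,
    classify,
    percent_abundance,
    ratio_ma_s,
    relative_expression,
    run_enorthern,
    stage_preference,
)
from enorthern._util import round_half_away

from _expected_panel import EXPECTED, UP_GENES

tpm = st.integers(min_value=0, max_value=10_000)
positive_tpm = st.integers(min_value=1, max_value=10_000)


def profiles_strategy(min_size=1, max_size=30):
    return st.builds(
        StudyTable,
        st.lists(
            st.builds(
                GeneProfile,
                gene_symbol=st.uuids().map(lambda u: f"G{u.hex[:8]}"),
                tpm_ma=tpm, tpm_s=tpm, tpm_mu=tpm,
            ),
            min_size=min_size, max_size=max_size,
            unique_by=lambda p: p.gene_symbol,
        ),
    )


class TestPanelReproduction:
    """Every derived cell of the bundled panel matches the reference values."""

    @pytest.mark.parametrize(
        "gene,pct,ratio,e_r,status", EXPECTED, ids=[row[0] for row in EXPECTED]
    )
    def test_derived_cells(self, panel_results, gene, pct, ratio, e_r, status):
        r = next(x for x in panel_results if x.gene_symbol == gene)
        assert round_half_away(r.pct_abundance, 3) == pytest.approx(pct, abs=1e-12)
        for got, want in ((r.ratio_ma_s, ratio), (r.e_r, e_r)):
            if want is None:
                assert got is None
            else:
                assert got is not None
                assert round_half_away(got, 3) == pytest.approx(want, abs=1e-12)
        assert r.status.name == status

    def test_status_counts(self, panel_results):
        counts = {s: 0 for s in Status}
        for r in panel_results:
            counts[r.status] += 1
        assert counts[Status.UP] == 13
        assert counts[Status.EXCLUDED] == 23
        assert counts[Status.DOWN] == 1
        assert counts[Status.NOT_DIFFERENTIAL] == 8

    def test_up_set_and_sole_down_gene(self, panel_results):
        assert sorted(
            r.gene_symbol for r in panel_results if r.status is Status.UP
        ) == UP_GENES
        assert [r.gene_symbol for r in panel_results if r.status is Status.DOWN] == [
            "SGPL1"
        ]


class TestPercentAbundance:
    def test_single_gene_takes_all(self):
        table = StudyTable([GeneProfile("A", 7, 0, 0)])
        assert percent_abundance(table) == {"A": 100.0}

    def test_denominator_includes_incomplete_genes(self):
        # one complete gene, one incomplete: both contribute mammary TPM
        table = StudyTable([GeneProfile("A", 75, 5, 5), GeneProfile("B", 25, 0, 0)])
        assert percent_abundance(table) == {"A": 75.0, "B": 25.0}

    def test_all_zero_mammary_column_is_an_error(self):
        table = StudyTable([GeneProfile("A", 0, 3, 4), GeneProfile("B", 0, 1, 2)])
        with pytest.raises(ValidationError):
            percent_abundance(table)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(profiles_strategy())
    def test_conservation_sums_to_100_unrounded(self, table):
        if all(p.tpm_ma == 0 for p in table):
            return
        pct = percent_abundance(table, decimals=None)
        assert math.isclose(sum(pct.values()), 100.0, abs_tol=1e-6)


class TestRelativeExpression:
    def test_identical_triple_is_unity(self):
        assert relative_expression(GeneProfile("A", 50, 50, 50)) == pytest.approx(1.0)

    def test_zero_numerator_gives_zero(self):
        assert relative_expression(GeneProfile("A", 0, 118, 51)) == 0.0

    def test_undefined_when_a_reference_tissue_is_zero(self):
        assert relative_expression(GeneProfile("A", 593, 29, 0)) is None
        assert relative_expression(GeneProfile("A", 593, 0, 29)) is None

    def test_log_space_oracle_equivalence(self):
        """E_r agrees with an independent log-space recomputation."""
        rng = np.random.default_rng(20171107)
        triples = rng.integers(0, 2001, size=(1000, 3))
        for ma, s, mu in triples:
            p = GeneProfile("A", int(ma), int(s), int(mu))
            got = relative_expression(p)
            if s == 0 or mu == 0:
                assert got is None
            elif ma == 0:
                assert got == 0.0
            else:
                oracle = math.exp(
                    math.log(ma) - 0.5 * (math.log(s) + math.log(mu))
                )
                assert got == pytest.approx(oracle, rel=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(ma=tpm, s=positive_tpm, mu=positive_tpm, delta=st.integers(1, 100))
    def test_strictly_increasing_in_mammary_tpm(self, ma, s, mu, delta):
        lo = relative_expression(GeneProfile("A", ma, s, mu))
        hi = relative_expression(GeneProfile("A", ma + delta, s, mu))
        assert hi > lo


class TestRatio:
    def test_defined_even_when_er_is_not(self):
        p = GeneProfile("AGPAT6", 593, 29, 0)
        assert ratio_ma_s(p) == pytest.approx(593 / 29)
        assert relative_expression(p) is None

    def test_undefined_for_zero_numerator_or_denominator(self):
        assert ratio_ma_s(GeneProfile("A", 0, 0, 0)) is None
        assert ratio_ma_s(GeneProfile("A", 0, 118, 51)) is None
        assert ratio_ma_s(GeneProfile("A", 10, 0, 51)) is None


class TestClassify:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((755, 29, 69), Status.UP),  # high E_r, mammary > skin
            ((194, 324, 17), Status.NOT_DIFFERENTIAL),  # E_r 2.6 but ma < s
            ((10, 177, 34), Status.DOWN),
            ((474, 295, 51), Status.UP),  # ratio 1.6 < 2 yet E_r 3.9: rule uses E_r
            ((593, 29, 0), Status.EXCLUDED),
            ((50, 50, 50), Status.NOT_DIFFERENTIAL),
        ],
    )
    def test_rule_cases(self, triple, expected):
        assert classify(GeneProfile("X", *triple)) is expected

    def test_thresholds_are_inclusive(self):
        # E_r exactly 2 with mammary > skin is UP; exactly 0.5 with ma < s is DOWN
        assert classify(GeneProfile("A", 8, 4, 4)) is Status.UP
        assert classify(GeneProfile("A", 2, 4, 4)) is Status.DOWN

    def test_custom_thresholds(self):
        strict = ClassifierConfig(up_threshold=4.0, down_threshold=0.25)
        assert classify(GeneProfile("A", 12, 4, 4), strict) is Status.NOT_DIFFERENTIAL
        assert classify(GeneProfile("A", 16, 4, 4), strict) is Status.UP

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            ClassifierConfig(up_threshold=1.0)
        with pytest.raises(ValidationError):
            ClassifierConfig(down_threshold=1.5)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(ma=tpm, s=tpm, mu=tpm)
    def test_partition_every_gene_gets_exactly_one_status(self, ma, s, mu):
        status = classify(GeneProfile("A", ma, s, mu))
        assert status in Status
        complete = ma > 0 and s > 0 and mu > 0
        assert (status is Status.EXCLUDED) == (not complete)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(ma=positive_tpm, s=positive_tpm, mu=positive_tpm,
           k=st.integers(min_value=2, max_value=50))
    def test_scale_invariance(self, ma, s, mu, k):
        """Multiplying all TPMs by k changes neither E_r nor the status."""
        base = GeneProfile("A", ma, s, mu)
        scaled = GeneProfile("A", k * ma, k * s, k * mu)
        assert relative_expression(scaled) == pytest.approx(
            relative_expression(base), rel=1e-12
        )
        assert classify(scaled) is classify(base)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(table=profiles_strategy(), k=st.integers(min_value=2, max_value=20))
    def test_percent_abundance_scale_invariance(self, table, k):
        if all(p.tpm_ma == 0 for p in table):
            return
        scaled = StudyTable(
            [
                GeneProfile(p.gene_symbol, k * p.tpm_ma, k * p.tpm_s, k * p.tpm_mu)
                for p in table
            ]
        )
        a = percent_abundance(table, decimals=None)
        b = percent_abundance(scaled, decimals=None)
        for gene in a:
            assert b[gene] == pytest.approx(a[gene], rel=1e-12, abs=1e-12)


class TestStagePreference:
    def test_strict_inequality(self):
        assert stage_preference(GeneProfile("A", 1, 1, 1, tpm_adult=100, tpm_young=40))
        assert not stage_preference(
            GeneProfile("A", 1, 1, 1, tpm_adult=40, tpm_young=40)
        )

    def test_absent_stage_tpms_give_absent_result(self):
        assert stage_preference(GeneProfile("A", 1, 1, 1)) is None
        assert stage_preference(GeneProfile("A", 1, 1, 1, tpm_adult=5)) is None

    def test_min_fold_margin(self):
        p = GeneProfile("A", 1, 1, 1, tpm_adult=60, tpm_young=40)
        assert stage_preference(p, min_fold=1.0)
        assert not stage_preference(p, min_fold=2.0)


def test_run_enorthern_preserves_order_and_composes(panel, panel_results):
    assert [r.gene_symbol for r in panel_results] == panel.gene_symbols
    for r in panel_results:
        assert r.complete == r.profile.complete
        assert (r.status is Status.EXCLUDED) == (not r.complete)
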