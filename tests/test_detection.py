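import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genecov.detection import (
    CANONICAL_RULES,
    CutoffRule,
    coverage_row_from_counts,
    coverage_table,
    cutoff_sweep,
    detect,
    format_percent,
    parse_rule,
    truncate_proportion,
)
from genecov.errors import ConfigurationError, ValidationError

from conftest import make_catalog, make_quant

SETTINGS = settings(max_examples=100, deadline=None, derandomize=True)


class TestDetect:
    def test_greater_than_is_strict_at_zero(self, chr18_catalog):
        quant = make_quant("illumina", {"G1": 0.0, "G2": 0.5, "G3": 10.0})
        s = detect(quant, CANONICAL_RULES["illumina"], chr18_catalog)
        assert s.genes == {"G2", "G3"}

    def test_greater_than_is_strict_at_boundary(self, chr18_catalog):
        quant = make_quant("illumina", {"G1": 0.0, "G2": 0.5, "G3": 10.0})
        s = detect(quant, CutoffRule("FPKM", "greater_than", 10.0), chr18_catalog)
        assert s.genes == set()

    def test_ct_limit_is_inclusive(self, chr18_catalog):
        """Ct <= 40 keeps a gene at exactly 40 cycles."""
        quant = make_quant(
            "qpcr", {"G1": 5.0, "G2": 1.0, "G3": 0.0},
            ct={"G1": 39.5, "G2": 40.0, "G3": 41.0},
        )
        s = detect(quant, CANONICAL_RULES["qpcr"], chr18_catalog)
        assert s.genes == {"G1", "G2"}

    def test_genes_outside_catalog_ignored(self, chr18_catalog):
        quant = make_quant("illumina", {"G1": 2.0, "NOT_IN_CATALOG": 9.0})
        s = detect(quant, CANONICAL_RULES["illumina"], chr18_catalog)
        assert s.genes == {"G1"}

    def test_metric_unit_mismatch_is_configuration_error(self, chr18_catalog):
        quant = make_quant("ont", {"G1": 2.0})
        with pytest.raises(ConfigurationError):
            detect(quant, CANONICAL_RULES["illumina"], chr18_catalog)


class TestSweep:
    def test_counts_from_hand_enumeration(self, chr18_catalog):
        quant = make_quant("illumina", {"G1": 1.0, "G2": 5.0, "G3": 20.0})
        assert cutoff_sweep(quant, chr18_catalog, [0, 4, 10]) == [(0, 3), (4, 2), (10, 1)]

    def test_empty_quant(self, chr18_catalog):
        quant = make_quant("illumina", {})
        assert cutoff_sweep(quant, chr18_catalog, [0]) == [(0, 0)]

    def test_unsorted_thresholds_rejected(self, chr18_catalog):
        quant = make_quant("illumina", {"G1": 1.0})
        with pytest.raises(ValidationError):
            cutoff_sweep(quant, chr18_catalog, [5, 1])
        with pytest.raises(ValidationError):
            cutoff_sweep(quant, chr18_catalog, [])

    @SETTINGS
    @given(
        abundances=st.lists(st.floats(0, 50, allow_nan=False), min_size=0, max_size=10),
        thresholds=st.lists(st.floats(0, 50, allow_nan=False), min_size=1, max_size=6),
    )
    def test_counts_match_brute_force_and_never_increase(self, abundances, thresholds):
        thresholds = sorted(thresholds)
        catalog = make_catalog({"1": [f"G{i}" for i in range(len(abundances))]})
        if not abundances:
            catalog = make_catalog({"1": ["G0"]})
        quant = make_quant("illumina", {f"G{i}": a for i, a in enumerate(abundances)})
        points = cutoff_sweep(quant, catalog, thresholds)
        brute = [sum(1 for a in abundances if a > t) for t in thresholds]
        assert [c for _, c in points] == brute
        assert all(b <= a for a, b in zip(brute, brute[1:]))


class TestTruncation:
    @pytest.mark.parametrize(
        "num, den, expected",
        [
            (453, 812, 0.55),  # rounding would print 0.56
            (186, 275, 0.67),
            (315, 326, 0.96),
            (268, 275, 0.97),
            (0, 10, 0.00),
        ],
    )
    def test_two_decimal_truncation(self, num, den, expected):
        assert truncate_proportion(num / den, 2) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            truncate_proportion(1.2)
        with pytest.raises(ValidationError):
            truncate_proportion(-0.1)

    @SETTINGS
    @given(st.floats(0, 1, allow_nan=False), st.integers(0, 4))
    def test_truncation_never_exceeds_value(self, x, d):
        t = truncate_proportion(x, d)
        assert 0 <= t <= x
        assert x - t < 10 ** -d + 1e-12

    @pytest.mark.parametrize(
        "num, den, decimals, expected",
        [
            (267, 275, 1, 97.0),
            (224, 275, 1, 81.4),  # rounding would print 81.5
            (186, 275, 1, 67.6),
            (63, 275, 0, 23.0),  # integer percents round half-up
        ],
    )
    def test_percent_formatting(self, num, den, decimals, expected):
        assert format_percent(num / den, decimals) == expected


class TestCoverageRows:
    @pytest.mark.parametrize(
        "n_genes, n_a, n_b, n_both, props",
        [
            (275, 267, 186, 185, (0.97, 0.67, 0.97)),
            (2022, 1951, 1361, 1330, (0.96, 0.67, 0.98)),
            (10, 0, 0, 0, (0.0, 0.0, 0.0)),
        ],
    )
    def test_row_from_counts(self, n_genes, n_a, n_b, n_both, props):
        row = coverage_row_from_counts("18", n_genes, n_a, n_b, n_both)
        assert (row.prop_a, row.prop_b, row.prop_union) == props

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValidationError):
            coverage_row_from_counts("1", 10, 12, 3, 1)
        with pytest.raises(ValidationError):
            coverage_row_from_counts("1", 10, 5, 3, 4)
        with pytest.raises(ValidationError):
            coverage_row_from_counts("1", 10, 9, 9, 2)  # union would be 16 > 10


def test_coverage_table_against_direct_union():
    """Inclusion-exclusion per chromosome equals a brute-force union, and the
    summary row sums the count columns."""
    rng = np.random.default_rng(42)
    genes = {c: [f"g{c}_{i}" for i in range(rng.integers(5, 40))] for c in ("1", "2", "X")}
    catalog = make_catalog(genes)
    universe = [g for gs in genes.values() for g in gs]
    set_a = {g for g in universe if rng.random() < 0.7}
    set_b = {g for g in universe if rng.random() < 0.4}
    quant_a = make_quant("illumina", {g: (1.0 if g in set_a else 0.0) for g in universe})
    quant_b = make_quant("ont", {g: (1.0 if g in set_b else 0.0) for g in universe})
    sets = {
        "illumina": detect(quant_a, CANONICAL_RULES["illumina"], catalog),
        "ont": detect(quant_b, CANONICAL_RULES["ont"], catalog),
    }
    df = coverage_table(sets, catalog)
    body = df[df["chromosome"] != "total"]
    for _, row in body.iterrows():
        chrom_genes = set(genes[row["chromosome"]])
        direct_union = len((set_a | set_b) & chrom_genes)
        assert row["n_illumina"] + row["n_ont"] - row["n_both"] == direct_union
        assert row["prop_union"] == truncate_proportion(direct_union / row["n_genes"])
    total = df[df["chromosome"] == "total"].iloc[0]
    for col in ("n_genes", "n_illumina", "n_ont", "n_both"):
        assert total[col] == body[col].sum()


def test_parse_rule_grammar():
    assert parse_rule("fpkm>0") == CutoffRule("FPKM", "greater_than", 0.0)
    assert parse_rule("ct<=40") == CutoffRule("Ct", "at_most", 40.0)
    with pytest.raises(ValidationError):
        parse_rule("banana=3")
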