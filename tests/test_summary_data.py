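"""Record I/O, SE reconstruction from (effect, P) pairs, and harmonization."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from mrpool.exceptions import (
    DegenerateInputError,
    HarmonizationError,
    RowError,
    SchemaError,
)
from mrpool.summary_data import (
    AssociationRecord,
    TableSchema,
    harmonize,
    impute_missing_se,
    read_association_table,
    read_instrument_table,
    reconstruct_se,
    write_instrument_table,
)

FIXTURE_SCHEMA = TableSchema(
    snp_id="snp", effect_allele="ea", other_allele="nea",
    effect="or_exposure", p_value="p_exposure", effect_is_or=True,
    locus="locus", trait_id="T2D",
)


def _fixture_path():
    from importlib import resources

    return resources.files("mrpool.data").joinpath("t2d_table1.tsv")


class TestReadAssociationTable:
    def test_reads_all_rows_in_order_with_log_or(self):
        records = read_association_table(str(_fixture_path()), FIXTURE_SCHEMA)
        assert len(records) == 37
        tcf7l2 = next(r for r in records if r.snp_id == "rs7903146")
        assert tcf7l2.effect == pytest.approx(math.log(1.39))
        assert tcf7l2.locus == "TCF7L2"
        # file order preserved
        assert records[0].locus == "ADCY5"

    def test_empty_file_with_header_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("snp\tea\tnea\tor_exposure\tp_exposure\tlocus\n")
        assert read_association_table(p, FIXTURE_SCHEMA) == []

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("snp\tea\tnea\tp_exposure\tlocus\n")
        with pytest.raises(SchemaError, match="or_exposure"):
            read_association_table(p, FIXTURE_SCHEMA)

    @pytest.mark.parametrize("bad_value, detail", [
        ("0", "p_value"),          # P must be > 0
        ("nope", "unparsable"),    # non-numeric
    ])
    def test_bad_rows_reported_with_row_numbers(self, tmp_path, bad_value, detail):
        p = tmp_path / "rows.tsv"
        p.write_text(
            "snp\tea\tnea\tor_exposure\tp_exposure\tlocus\n"
            "rs1\tA\tG\t1.10\t1e-8\tL1\n"
            f"rs2\tA\tG\t1.10\t{bad_value}\tL2\n"
        )
        with pytest.raises(RowError) as err:
            read_association_table(p, FIXTURE_SCHEMA)
        assert err.value.rows[0][0] == 2
        assert detail in str(err.value)


class TestReconstructSE:
    def test_unit_z_score(self):
        # two-sided P of z=1 is 0.3173105; SE must equal the effect
        assert reconstruct_se(0.693147, 0.3173105) == pytest.approx(0.693147, rel=1e-5)

    def test_zero_effect_is_undefined(self):
        assert math.isnan(reconstruct_se(0.0, 0.83))

    def test_p_of_one_is_undefined(self):
        assert math.isnan(reconstruct_se(0.2, 1.0))

    def test_nonpositive_p_raises(self):
        with pytest.raises(ValueError):
            reconstruct_se(0.1, 0.0)

    def test_matches_log_space_bisection_oracle(self):
        # independent inversion: bisect z such that ln(2*Phi(-z)) = ln(p)
        from scipy.stats import norm

        effect, p = math.log(1.11), 6.5e-14
        target = math.log(p)
        lo, hi = 0.0, 50.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if math.log(2.0) + norm.logsf(mid) > target:
                lo = mid
            else:
                hi = mid
        assert reconstruct_se(effect, p) == pytest.approx(effect / lo, rel=1e-10)

    @given(st.floats(min_value=-215.0, max_value=-0.00436))  # p in [1e-215, ~0.99]
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_p_round_trip_to_six_significant_digits(self, log10_p):
        from scipy.stats import norm

        p = 10.0 ** log10_p
        se = reconstruct_se(0.25, p)
        p_back = 2.0 * norm.sf(0.25 / se)
        assert p_back == pytest.approx(p, rel=1e-6)


class TestImputeMissingSE:
    def _rec(self, i, se):
        return AssociationRecord(
            snp_id=f"rs{i}", effect_allele="A", other_allele="G",
            effect=0.1, p_value=0.5, se=se,
        )

    def test_median_fills_and_preserves_defined(self):
        records = [self._rec(i, se) for i, se in enumerate([0.01, 0.02, 0.03, None])]
        out = impute_missing_se(records, policy="median")
        assert out[3].se == pytest.approx(0.02)
        assert [r.se for r in out[:3]] == [0.01, 0.02, 0.03]

    def test_no_missing_is_identity(self):
        records = [self._rec(i, 0.01 * (i + 1)) for i in range(3)]
        assert impute_missing_se(records, policy="mean") == records

    def test_drop_removes_exactly_the_or_one_rows(self, t2d_table):
        # oracle: count OR CHD printed as 1.00 among non-pleiotropic rows
        sub = t2d_table[t2d_table.pleiotropic == "No"]
        n_flat = int((sub.or_outcome == 1.00).sum())
        assert n_flat > 0
        from mrpool.datasets import load_t2d_instruments

        dropped = load_t2d_instruments(screened=True, se_policy="drop")
        assert len(dropped) == len(sub) - n_flat

    def test_all_undefined_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            impute_missing_se([self._rec(0, None)], policy="median")


def _assoc(snp="rs1", ea="A", og="G", effect=0.1, se=0.05, p=0.01):
    return AssociationRecord(snp_id=snp, effect_allele=ea, other_allele=og,
                             effect=effect, p_value=p, se=se)


class TestHarmonize:
    def test_identical_alleles_keep_signs(self):
        instr = harmonize(_assoc(), _assoc(effect=0.05))
        assert instr.gamma == 0.1
        assert instr.beta == 0.05

    def test_swapped_alleles_negate_beta(self):
        instr = harmonize(_assoc(), _assoc(ea="G", og="A", effect=0.05))
        assert instr.beta == -0.05

    def test_strand_complement_pairs_match(self):
        # A/G on exposure, T/C on outcome: same variant on opposite strands
        instr = harmonize(_assoc(ea="A", og="G"), _assoc(ea="T", og="C", effect=0.05))
        assert instr.beta == 0.05

    def test_swap_is_involutive_on_sign(self):
        outcome = _assoc(ea="G", og="A", effect=0.05)
        once = harmonize(_assoc(), outcome)
        # re-expressing the already-flipped beta against the swapped outcome
        # alleles flips it back to the original orientation
        twice = harmonize(
            _assoc(ea="G", og="A"),
            _assoc(ea="A", og="G", effect=once.beta),
        )
        assert twice.beta == outcome.effect

    def test_palindromic_drop_policy_excludes(self):
        assert harmonize(_assoc(ea="A", og="T"), _assoc(ea="A", og="T"),
                         palindrome_policy="drop") is None

    def test_palindromic_flag_policy_keeps(self):
        instr = harmonize(_assoc(ea="C", og="G"), _assoc(ea="C", og="G"),
                          palindrome_policy="flag")
        assert instr is not None

    def test_irreconcilable_alleles_raise_naming_snp(self):
        with pytest.raises(HarmonizationError, match="rs1"):
            harmonize(_assoc(ea="A", og="G"), _assoc(ea="A", og="C"))

    def test_snp_mismatch_raises(self):
        with pytest.raises(HarmonizationError):
            harmonize(_assoc(snp="rs1"), _assoc(snp="rs2"))


def test_instrument_table_round_trip(tmp_path, t2d_instruments):
    path = tmp_path / "instruments.tsv"
    write_instrument_table(t2d_instruments, path)
    assert read_instrument_table(path) == t2d_instruments
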