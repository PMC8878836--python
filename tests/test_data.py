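"""Data model, table IO, taxonomy and unit-conversion behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dgcmeta import (
    ArmSummary,
    StudyRecord,
    Taxonomy,
    TemperatureSeries,
    convert_rate_units,
    convert_water_loss_units,
    read_study_table,
    read_taxonomy,
    write_study_table,
)
from dgcmeta.data import ParseError, SchemaError, TaxonLookupError


def _hygric_records():
    arms = lambda m1, m2: (ArmSummary(m1, 0.4, 8, "mg/h"), ArmSummary(m2, 0.5, 9, "mg/h"))
    return [
        StudyRecord(f"st{i}", species=f"sp{i}", family="Blaberidae",
                    order="Blattodea", objective="hygric", arms=arms(2.0 + i, 1.0))
        for i in range(3)
    ]


class TestArmSummary:
    def test_se_to_sd_uses_row_n(self):
        arm = ArmSummary(mean=10.0, dispersion=0.5, n=16, units="mg/h",
                         dispersion_type="se")
        assert arm.sd == pytest.approx(2.0)
        assert arm.as_sd().dispersion == pytest.approx(2.0)
        assert arm.as_sd().dispersion_type == "sd"

    @pytest.mark.parametrize("kwargs", [
        dict(mean=float("nan"), dispersion=1.0, n=5, units="mg/h"),
        dict(mean=1.0, dispersion=-0.1, n=5, units="mg/h"),
        dict(mean=1.0, dispersion=1.0, n=0, units="mg/h"),
        dict(mean=1.0, dispersion=1.0, n=5, units="furlongs"),
    ])
    def test_invariants_rejected(self, kwargs):
        with pytest.raises((ValueError, SchemaError)):
            ArmSummary(**kwargs)


class TestStudyTableIO:
    def test_round_trip_two_arm(self, tmp_path):
        records = _hygric_records()
        path = tmp_path / "hygric.csv"
        write_study_table(records, path)
        back = read_study_table(path, "hygric")
        assert len(back) == 3
        for a, b in zip(records, back):
            assert a.study_id == b.study_id
            assert a.arms[0].mean == pytest.approx(b.arms[0].mean)
            assert a.arms[1].sd == pytest.approx(b.arms[1].sd)

    def test_round_trip_temperature(self, tmp_path):
        series = TemperatureSeries((15.0, 25.0, 35.0), (1.0, 2.0, 4.0),
                                   (0.1, 0.2, 0.4), (10, 10, 10))
        rec = StudyRecord("t1", species="sp", family="Acrididae",
                          order="Orthoptera", objective="temperature",
                          series=series)
        path = tmp_path / "temp.tsv"
        write_study_table([rec], path)
        back = read_study_table(path, "temperature")
        assert len(back) == 1
        assert back[0].series.means == pytest.approx(series.means)
        assert back[0].series.ns == series.ns

    def test_invalid_row_rejected_with_diagnostic(self, tmp_path):
        path = tmp_path / "bad.csv"
        write_study_table(_hygric_records(), path)
        text = path.read_text().replace("st1,", "bad_n,").splitlines()
        # corrupt row 1's reference n to 0
        cols = text[0].split(",")
        row = text[2].split(",")
        row[cols.index("n_ref")] = "0"
        text[2] = ",".join(row)
        path.write_text("\n".join(text))
        with pytest.warns(UserWarning, match="rejected"):
            records = read_study_table(path, "hygric")
        assert len(records) == 2

    def test_missing_column_names_it(self, tmp_path):
        path = tmp_path / "no_units.csv"
        write_study_table(_hygric_records(), path)
        lines = path.read_text().splitlines()
        cols = lines[0].split(",")
        drop = cols.index("units")
        out = ["," .join(c for i, c in enumerate(l.split(",")) if i != drop)
               for l in lines]
        path.write_text("\n".join(out))
        with pytest.raises(SchemaError, match="units"):
            read_study_table(path, "hygric")

    def test_non_numeric_cell_names_row(self, tmp_path):
        path = tmp_path / "nan.csv"
        write_study_table(_hygric_records(), path)
        path.write_text(path.read_text().replace("2.0,", "two,", 1))
        with pytest.raises(ParseError, match="row"):
            read_study_table(path, "hygric")

    def test_se_rows_stored_as_sd(self, tmp_path):
        path = tmp_path / "se.csv"
        recs = _hygric_records()
        # rewrite reference arm as SE-tagged
        import pandas as pd
        write_study_table(recs, path)
        df = pd.read_csv(path)
        df.loc[0, "disp_type_ref"] = "se"
        df.loc[0, "disp_ref"] = 0.5
        df.loc[0, "n_ref"] = 16
        df.to_csv(path, index=False)
        back = read_study_table(path, "hygric")
        assert back[0].arms[0].dispersion_type == "sd"
        assert back[0].arms[0].sd == pytest.approx(2.0)


class TestRateConversion:
    def test_worked_ratio_example(self):
        rate = ArmSummary(2.0, math.sqrt(0.04), 10, "ml/h")
        mass = ArmSummary(0.5, math.sqrt(0.0025), 10, "g")
        out = convert_rate_units(rate, mass)
        assert out.mean == pytest.approx(4.0)
        assert out.dispersion == pytest.approx(0.565685, rel=1e-5)
        assert out.units == "ml/g/h"

    def test_zero_variance_reductions(self):
        rate = ArmSummary(2.0, 0.0, 10, "ml/h")
        mass = ArmSummary(0.5, 0.0, 10, "g")
        assert convert_rate_units(rate, mass).dispersion == 0.0
        rate = ArmSummary(2.0, 0.3, 10, "ml/h")
        out = convert_rate_units(rate, mass)
        assert out.dispersion == pytest.approx(0.3 / 0.5)

    def test_nonpositive_mass_rejected(self):
        rate = ArmSummary(2.0, 0.1, 10, "ml/h")
        with pytest.raises(ValueError, match="mass"):
            convert_rate_units(rate, ArmSummary(0.0, 0.1, 10, "g"))
        with pytest.raises(ValueError, match="mass"):
            convert_rate_units(rate, ArmSummary(-0.5, 0.1, 10, "g"))

    @given(c=st.floats(0.1, 10.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_scale_consistency(self, c):
        rate = ArmSummary(2.0, 0.2, 10, "ml/h")
        mass = ArmSummary(0.5, 0.05, 10, "g")
        base = convert_rate_units(rate, mass)
        scaled = convert_rate_units(
            ArmSummary(2.0 * c, 0.2 * c, 10, "ml/h"),
            ArmSummary(0.5 * c, 0.05 * c, 10, "g"))
        assert scaled.mean == pytest.approx(base.mean)

    def test_matches_monte_carlo_propagation(self, rng):
        """Taylor SD agrees with simulated SD of A/B.

        The first-order expansion is accurate while the denominator CV stays
        small (here <= 0.1; the near-zero tail of the mass distribution
        inflates the exact ratio SD beyond first order at larger CVs).
        """
        for cv_a, cv_b in [(0.05, 0.05), (0.1, 0.1), (0.2, 0.05)]:
            a_mean, b_mean = 2.0, 0.5
            rate = ArmSummary(a_mean, cv_a * a_mean, 10, "ml/h")
            mass = ArmSummary(b_mean, cv_b * b_mean, 10, "g")
            out = convert_rate_units(rate, mass)
            a = rng.normal(a_mean, cv_a * a_mean, size=400_000)
            b = rng.normal(b_mean, cv_b * b_mean, size=400_000)
            mc_sd = np.std(a / b)
            assert out.dispersion == pytest.approx(mc_sd, rel=0.05)


class TestWaterLossConversion:
    @pytest.mark.parametrize("units,factor", [("mg/h", 1.0), ("ug/h", 1e-3),
                                              ("mg/min", 60.0)])
    def test_exact_factors(self, units, factor):
        out = convert_water_loss_units(ArmSummary(3.0, 0.6, 7, units))
        assert out.units == "mg/h"
        assert out.mean == pytest.approx(3.0 * factor)
        assert out.dispersion == pytest.approx(0.6 * factor)

    def test_rate_units_rejected(self):
        with pytest.raises(ValueError):
            convert_water_loss_units(ArmSummary(3.0, 0.6, 7, "ml/h"))


class TestTemperatureSeries:
    def test_sorted_and_validated(self):
        s = TemperatureSeries((35.0, 15.0, 25.0), (4.0, 1.0, 2.0),
                              (0.4, 0.1, 0.2), (5, 5, 5))
        assert s.temperatures == (15.0, 25.0, 35.0)
        assert s.means == (1.0, 2.0, 4.0)

    @pytest.mark.parametrize("means", [(0.0, 1.0), (-1.0, 2.0)])
    def test_nonpositive_means_rejected(self, means):
        with pytest.raises(ValueError):
            TemperatureSeries((15.0, 25.0), means, (0.1, 0.1), (5, 5))

    def test_single_temperature_rejected(self):
        with pytest.raises(ValueError):
            TemperatureSeries((25.0, 25.0), (1.0, 1.0), (0.1, 0.1), (5, 5))


class TestTaxonomy:
    def test_newick_round_trip(self, tmp_path):
        path = tmp_path / "orders.nwk"
        path.write_text("(Diptera,(Blattodea,Orthoptera));\n")
        tax = read_taxonomy(path)
        assert tax.orders == {"Diptera", "Blattodea", "Orthoptera"}

    def test_absent_order_is_lookup_error(self, tmp_path):
        path = tmp_path / "orders.nwk"
        path.write_text("(Diptera,(Blattodea,Orthoptera));\n")
        tax = read_taxonomy(path)
        with pytest.raises(TaxonLookupError, match="Coleoptera"):
            tax.resolve(("Coleoptera", "Carabidae", "sp1"))

    def test_nested_table_paths(self):
        """9 orders / 12 families / 23 species resolve as depth-3 paths."""
        import pandas as pd
        orders = [f"Order{i}" for i in range(9)]
        rows = []
        sp = 0
        fam = 0
        while sp < 23:
            o = orders[sp % 9]
            f = f"Family{fam % 12}"
            rows.append(dict(order=o, family=f, species=f"sp{sp}"))
            sp += 1
            fam += 1
        tax = Taxonomy.from_table(pd.DataFrame(rows))
        assert len(tax.paths) == 23
        assert all(len(p) == 3 for p in tax.paths)
        for p in tax.paths:
            assert tax.resolve(p) == p
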