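"""I/O round-trips, schema validation, normalization and complete-case
filtering."""

import numpy as np
import pandas as pd
import pytest

from proteoturn.errors import SchemaError
from proteoturn.tables import (
    AbundanceMatrix,
    filter_complete_cases,
    normalize_intersample,
    read_abundance_table,
    read_design,
    read_isotopomer_table,
    write_abundance_table,
    write_isotopomer_table,
)


def random_isotopomers(rng, n=100):
    return pd.DataFrame(
        {
            "peptide_id": [f"p{i}" for i in range(n)],
            "sequence": ["ACDK"] * n,
            "protein_accession": [f"P{i%7}" for i in range(n)],
            "sample_id": ["VC_r1_t12"] * n,
            "time_h": 12.0,
            "m0": rng.uniform(1, 1e7, n),
            "m1": rng.uniform(1, 1e7, n),
        }
    )


class TestIsotopomerIO:
    def test_round_trip_lossless(self, tmp_path, rng):
        df = random_isotopomers(rng)
        path = tmp_path / "iso.csv"
        write_isotopomer_table(df, path)
        back = read_isotopomer_table(path)
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True), df.reset_index(drop=True)
        )

    def test_well_formed_row_count(self, tmp_path, rng):
        path = tmp_path / "iso.csv"
        write_isotopomer_table(random_isotopomers(rng, n=3), path)
        assert len(read_isotopomer_table(path)) == 3

    def test_missing_column_named(self, tmp_path, rng):
        df = random_isotopomers(rng, n=3).drop(columns=["m1"])
        path = tmp_path / "iso.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="m1"):
            read_isotopomer_table(path)

    def test_non_numeric_intensity_reports_row(self, tmp_path, rng):
        df = random_isotopomers(rng, n=3).astype({"m0": object})
        df.loc[df.index[1], "m0"] = "oops"
        path = tmp_path / "iso.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="row 2"):
            read_isotopomer_table(path)

    def test_tsv_dialect(self, tmp_path, rng):
        df = random_isotopomers(rng, n=5)
        path = tmp_path / "iso.tsv"
        write_isotopomer_table(df, path)
        assert "\t" in path.read_text().splitlines()[0]
        assert len(read_isotopomer_table(path)) == 5


class TestDesign:
    def test_round_trip_and_validation(self, tmp_path, design_frame):
        path = tmp_path / "design.csv"
        design_frame.to_csv(path, index=False)
        back = read_design(path)
        assert len(back) == len(design_frame)
        assert back["labeled"].dtype == bool

    def test_duplicate_key_rejected(self, tmp_path, design_frame):
        df = pd.concat([design_frame, design_frame.iloc[[0]].assign(sample_id="dup")])
        path = tmp_path / "design.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="key not unique"):
            read_design(path)

    def test_unequal_replicates_rejected(self, tmp_path, design_frame):
        df = design_frame[
            ~((design_frame.condition == "PEA") & (design_frame.replicate == 3))
        ]
        path = tmp_path / "design.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="unequal replicate"):
            read_design(path)


class TestAbundanceIO:
    def make_table(self, rng, design, n=5):
        samples = design.loc[design.labeled, "sample_id"].tolist()
        values = pd.DataFrame(
            rng.uniform(1, 500, (n, len(samples))),
            index=[f"P{i}" for i in range(n)],
            columns=samples,
        )
        return AbundanceMatrix(
            values=values,
            descriptions=pd.Series([f"protein {i}" for i in range(n)], index=values.index),
        )

    def test_round_trip_full_precision(self, tmp_path, rng, design_frame):
        mat = self.make_table(rng, design_frame)
        path = tmp_path / "ab.csv"
        write_abundance_table(mat, path)
        back = read_abundance_table(path, design_frame)
        pd.testing.assert_frame_equal(back.values, mat.values, check_names=False)
        assert back.values.shape == (5, 18)

    def test_duplicate_accession_rejected(self, tmp_path, rng, design_frame):
        mat = self.make_table(rng, design_frame)
        df = mat.values.copy()
        df = pd.concat([df, df.iloc[[0]]])
        df.index.name = "protein_accession"
        path = tmp_path / "ab.csv"
        df.to_csv(path)
        with pytest.raises(SchemaError, match="duplicate"):
            read_abundance_table(path, design_frame)

    def test_unknown_sample_rejected(self, tmp_path, rng, design_frame):
        mat = self.make_table(rng, design_frame)
        df = mat.values.rename(columns={mat.values.columns[0]: "mystery"})
        df.index.name = "protein_accession"
        path = tmp_path / "ab.csv"
        df.to_csv(path)
        with pytest.raises(SchemaError, match="mystery"):
            read_abundance_table(path, design_frame)


class TestNormalization:
    def test_pure_scaling_removed(self, rng):
        a = rng.uniform(1, 100, 50)
        values = pd.DataFrame({"A": a, "B": 2 * a}, index=[f"P{i}" for i in range(50)])
        out = normalize_intersample(AbundanceMatrix(values=values))
        assert out.scaling_factors["B"] / out.scaling_factors["A"] == pytest.approx(0.5)
        np.testing.assert_allclose(out.values["A"], out.values["B"], rtol=1e-12)

    def test_equal_samples_unit_factors(self, rng):
        a = rng.uniform(1, 100, 30)
        values = pd.DataFrame({s: a for s in "ABC"})
        out = normalize_intersample(AbundanceMatrix(values=values))
        assert np.allclose(out.scaling_factors, 1.0)

    def test_median_ratio_to_reference_is_one(self, rng):
        values = pd.DataFrame(
            rng.lognormal(3, 1, (200, 6)), columns=list("ABCDEF")
        )
        out = normalize_intersample(AbundanceMatrix(values=values))
        ref = out.values[out.reference_sample]
        for col in values.columns:
            assert (out.values[col] / ref).median() == pytest.approx(1.0, abs=1e-12)

    def test_idempotent_with_recorded_reference(self, rng):
        values = pd.DataFrame(rng.lognormal(3, 1, (100, 4)), columns=list("ABCD"))
        out = normalize_intersample(AbundanceMatrix(values=values))
        again = normalize_intersample(out, reference=out.reference_sample)
        assert np.allclose(again.scaling_factors, 1.0)

    def test_renormalizing_without_reference_rejected(self, rng):
        values = pd.DataFrame(rng.lognormal(3, 1, (20, 3)), columns=list("ABC"))
        out = normalize_intersample(AbundanceMatrix(values=values))
        with pytest.raises(ValueError, match="already normalized"):
            normalize_intersample(out)

    def test_disjoint_sample_rejected(self):
        values = pd.DataFrame(
            {"A": [1.0, 2.0, np.nan, np.nan], "B": [np.nan, np.nan, 3.0, 4.0],
             "C": [1.0, 2.0, 3.0, 4.0]}
        )
        with pytest.raises(SchemaError, match="shares no nonzero proteins"):
            normalize_intersample(AbundanceMatrix(values=values), reference="A")


class TestCompleteCases:
    def grid(self, design):
        return design.loc[design.labeled, "sample_id"].tolist()

    def test_complete_retained_missing_dropped(self, rng, design_frame):
        cols = self.grid(design_frame)
        values = pd.DataFrame(
            rng.uniform(1, 10, (2, len(cols))), index=["full", "gap"], columns=cols
        )
        values.loc["gap", cols[3]] = np.nan
        kept, n = filter_complete_cases(values, design_frame)
        assert list(kept.index) == ["full"]
        assert n == 1

    def test_matches_brute_force_scan(self, rng, design_frame):
        cols = self.grid(design_frame)
        values = pd.DataFrame(
            rng.uniform(1, 10, (500, len(cols))),
            index=[f"P{i}" for i in range(500)],
            columns=cols,
        )
        mask = rng.random(values.shape) < 0.10
        values = values.mask(mask)
        kept, n = filter_complete_cases(values, design_frame)
        expected = [
            acc
            for acc in values.index
            if all(np.isfinite(values.at[acc, c]) for c in cols)
        ]
        assert list(kept.index) == expected
        assert n == len(expected)

    def test_order_invariant_and_never_grows(self, rng, design_frame):
        cols = self.grid(design_frame)
        values = pd.DataFrame(
            rng.uniform(1, 10, (50, len(cols))),
            index=[f"P{i}" for i in range(50)],
            columns=cols,
        ).mask(rng.random((50, len(cols))) < 0.2)
        kept, n = filter_complete_cases(values, design_frame)
        shuffled = values.sample(frac=1, random_state=1)
        kept2, n2 = filter_complete_cases(shuffled, design_frame)
        assert n == n2 <= len(values)
        assert set(kept.index) == set(kept2.index)

    def test_time_restriction(self, rng, design_frame):
        lab = design_frame[design_frame.labeled]
        t36 = lab.loc[np.isclose(lab.time_h, 36.0), "sample_id"].tolist()
        values = pd.DataFrame(
            rng.uniform(1, 10, (3, len(t36))), columns=t36,
            index=["a", "b", "c"],
        )
        values.iloc[0, 0] = np.nan
        kept, n = filter_complete_cases(values, design_frame, time_h=36.0)
        assert n == 2

    def test_missing_required_sample_column_rejected(self, rng, design_frame):
        values = pd.DataFrame({"VC_r1_t12": [1.0]}, index=["P0"])
        with pytest.raises(SchemaError, match="missing design sample"):
            filter_complete_cases(values, design_frame)
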