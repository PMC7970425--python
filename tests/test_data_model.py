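import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micronet.data_model import (
    FormatError,
    OtuTable,
    compute_relative_dose,
    filter_rare_otus,
    read_otu_table,
    read_trait_table,
    round_half_away,
    to_relative_abundance,
    transform_for_network,
    write_otu_table,
    write_trait_table,
)


class TestOtuTableIO:
    def test_tsv_round_trip_is_identity(self, tiny_table, tmp_path):
        path = tmp_path / "otus.tsv"
        write_otu_table(tiny_table, path)
        back = read_otu_table(path)
        pd.testing.assert_frame_equal(back.counts, tiny_table.counts)
        pd.testing.assert_series_equal(back.taxonomy, tiny_table.taxonomy)
        assert back.counts.shape == (3, 4)

    def test_subject_with_single_condition_is_dropped(self, tiny_counts, caplog):
        counts, tax = tiny_counts
        counts = counts.copy()
        counts["S03_PL"] = [1, 2, 3]  # S03 has no BR sample
        with caplog.at_level("WARNING"):
            table = OtuTable(counts=counts, taxonomy=tax)
        assert "S03" not in table.subjects
        assert table.n_dropped_samples == 1
        assert any("S03" in rec.message for rec in caplog.records)

    def test_duplicate_otu_id_is_format_error(self, tiny_counts):
        counts, tax = tiny_counts
        counts = counts.copy()
        counts.index = pd.Index(["OTU_1", "OTU_1", "OTU_3"], name="otu_id")
        tax.index = counts.index
        with pytest.raises(FormatError, match="duplicate"):
            OtuTable(counts=counts, taxonomy=tax)

    def test_negative_and_fractional_counts_rejected(self, tiny_counts):
        counts, tax = tiny_counts
        bad = counts.copy()
        bad.iloc[0, 0] = -1
        with pytest.raises(FormatError, match="non-negative"):
            OtuTable(counts=bad, taxonomy=tax)
        bad = counts.astype(float).copy()
        bad.iloc[0, 0] = 1.5
        with pytest.raises(FormatError, match="integer"):
            OtuTable(counts=bad, taxonomy=tax)

    def test_biom_json_matches_tsv(self, tiny_table, tmp_path):
        doc = {
            "format": "Biological Observation Matrix 1.0",
            "matrix_type": "sparse",
            "shape": [3, 4],
            "rows": [
                {"id": o, "metadata": {"taxonomy": tiny_table.taxonomy[o].split(";")}}
                for o in tiny_table.otu_ids
            ],
            "columns": [{"id": s, "metadata": None} for s in tiny_table.counts.columns],
            "data": [
                [i, j, int(v)]
                for i, row in enumerate(tiny_table.counts.to_numpy())
                for j, v in enumerate(row)
                if v
            ],
        }
        path = tmp_path / "otus.biom"
        path.write_text(json.dumps(doc))
        back = read_otu_table(path, format="biom-json")
        assert np.array_equal(back.counts.to_numpy(), tiny_table.counts.to_numpy())
        assert back.taxonomy.tolist() == tiny_table.taxonomy.tolist()


class TestTraitTableIO:
    def test_round_trip(self, tmp_path, small_dataset):
        path = tmp_path / "traits.tsv"
        write_trait_table(small_dataset.traits, path)
        back = read_trait_table(path)
        for cond in ("PL", "BR"):
            pd.testing.assert_frame_equal(
                back.values[cond], small_dataset.traits.values[cond], atol=1e-12
            )
        pd.testing.assert_frame_equal(
            back.baseline, small_dataset.traits.baseline, atol=1e-12
        )


class TestFiltering:
    @staticmethod
    def _table(rows: dict) -> OtuTable:
        counts = pd.DataFrame(
            rows, index=["S01_PL", "S01_BR", "S02_PL", "S02_BR"]
        ).T
        counts.index.name = "otu_id"
        tax = pd.Series("Bacteria;P;C;O;F;G;S", index=counts.index)
        return OtuTable(counts=counts, taxonomy=tax)

    def test_rule_outcomes_on_hand_enumerated_toy(self):
        # 4 samples; rule 1: max < 10 everywhere; rule 2: <5 in >= 50% of samples
        table = self._table(
            {
                "all_zero": [0, 0, 0, 0],          # rule 1
                "low_everywhere": [9, 9, 9, 9],     # survives rule 1 max<10? no: removed
                "one_big_rest_prevalent": [10, 6, 5, 0],  # >=10 once, >=5 in 3/4: kept
                "abundant": [50, 40, 30, 20],       # kept
                "one_big_rest_zero": [10, 0, 0, 0],  # rule 2: <5 in 3/4
            }
        )
        filtered, report = filter_rare_otus(table)
        assert set(filtered.otu_ids) == {"one_big_rest_prevalent", "abundant"}
        # rule 1 catches OTUs below 10 in every sample
        assert report.n_removed_rule1 == 2
        assert report.n_removed_rule2 == 1
        assert report.n_input_otus == 5
        assert "abundant" in report.surviving_otu_ids

    def test_rule2_boundary_is_inclusive(self):
        # exactly 50% of samples below 5 -> removed
        table = self._table({"edge": [10, 10, 4, 4], "keep": [10, 10, 5, 5]})
        filtered, _ = filter_rare_otus(table)
        assert list(filtered.otu_ids) == ["keep"]

    def test_filtering_is_idempotent_and_preserves_counts(self, study_scale_dataset):
        once, rep1 = filter_rare_otus(study_scale_dataset.otus)
        twice, rep2 = filter_rare_otus(once)
        pd.testing.assert_frame_equal(once.counts, twice.counts)
        assert rep2.n_removed_rule1 == rep2.n_removed_rule2 == 0
        # surviving counts are untouched
        orig = study_scale_dataset.otus.counts.loc[once.otu_ids]
        pd.testing.assert_frame_equal(once.counts, orig)

    def test_all_filtered_is_error(self):
        table = self._table({"a": [0, 1, 0, 1], "b": [2, 2, 2, 2]})
        with pytest.raises(ValueError, match="all OTUs filtered"):
            filter_rare_otus(table)


class TestRelativeAbundance:
    def test_hand_cases(self, tiny_counts):
        counts, tax = tiny_counts
        counts = counts.copy()
        counts["S01_PL"] = [2, 2, 0]
        counts["S01_BR"] = [1, 3, 0]
        rel = to_relative_abundance(OtuTable(counts=counts, taxonomy=tax))
        assert rel.fractions["S01_PL"].tolist() == [0.5, 0.5, 0.0]
        assert rel.fractions["S01_BR"].tolist() == [0.25, 0.75, 0.0]

    def test_columns_sum_to_one_on_random_table(self, small_dataset):
        rel = to_relative_abundance(small_dataset.otus)
        np.testing.assert_allclose(rel.fractions.sum(axis=0), 1.0, atol=1e-12)

    def test_all_zero_sample_error_names_sample(self, tiny_counts):
        counts, tax = tiny_counts
        counts = counts.copy()
        counts.loc[:, "S02_PL"] = 0
        with pytest.raises(ValueError, match="S02_PL"):
            to_relative_abundance(OtuTable(counts=counts, taxonomy=tax))


class TestNetworkTransform:
    def test_zero_fraction_maps_to_log_pseudocount(self, tiny_table):
        rel = to_relative_abundance(tiny_table)
        x = transform_for_network(rel, pseudocount=1e-6)
        # OTU_2 is all-zero, so its transformed value is log10(1e-6) = -6
        assert np.allclose(x["OTU_2"], -6.0)

    def test_monotone_and_invertible(self, small_dataset):
        rel = to_relative_abundance(small_dataset.otus)
        x = transform_for_network(rel, pseudocount=1e-6)
        recovered = 10.0 ** x.to_numpy() - 1e-6
        np.testing.assert_allclose(recovered, rel.fractions.to_numpy().T, atol=1e-12)
        col = rel.fractions.iloc[:, 0].to_numpy()
        order = np.argsort(col)
        assert (np.diff(x.iloc[0, :].to_numpy()[order]) >= 0).all()

    def test_zero_variance_columns_flagged(self, tiny_table):
        rel = to_relative_abundance(tiny_table)
        with pytest.warns(UserWarning, match="zero-variance"):
            x = transform_for_network(rel, pseudocount=1e-6)
        assert x.attrs["zero_variance_otus"] == ["OTU_2"]

    def test_nonpositive_pseudocount_rejected(self, tiny_table):
        rel = to_relative_abundance(tiny_table)
        with pytest.raises(ValueError):
            transform_for_network(rel, pseudocount=0.0)


class TestRelativeDose:
    def test_study_range_bounds(self):
        # heaviest and lightest participants at the 750 mg/day dose
        assert round_half_away(compute_relative_dose(750, 51.4)) == 0.24
        assert round_half_away(compute_relative_dose(750, 103.0)) == 0.12

    def test_zero_dose(self):
        assert compute_relative_dose(0, 70.0) == 0.0

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            compute_relative_dose(750, 0.0)

    @given(st.floats(0, 5000), st.floats(30, 150))
    @settings(max_examples=50, deadline=None)
    def test_scales_inversely_with_mass(self, dose, mass):
        assert compute_relative_dose(dose, mass) == pytest.approx(
            (dose / 62.004) / mass
        )
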