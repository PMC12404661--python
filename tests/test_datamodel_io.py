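"""Domain-type invariants and TSV round-tripping."""

import math

import pytest
from hypothesis import given, settings, strategies as st
from pydantic import ValidationError

from biphasix.datamodel import (
    Assay,
    CFUObservation,
    CFUTable,
    Culture,
    Habitat,
    ODCalibration,
    TableSchemaError,
    TableValidationError,
    TraitTable,
    Unit,
)
from biphasix.io import (
    read_cfu_table,
    read_trait_table,
    write_cfu_table,
    write_trait_table,
)
from biphasix.synthetic import generate_trait_table


def _growth_obs(species, cfu, rep=1, time_h=72.0):
    return CFUObservation(
        species_id=species,
        habitat=Habitat.plate,
        assay=Assay.growth,
        culture=Culture.co,
        time_h=time_h,
        replicate=rep,
        cfu=cfu,
        unit=Unit.per_plate,
    )


class TestObservationInvariants:
    def test_negative_cfu_rejected(self):
        with pytest.raises(ValidationError):
            _growth_obs("MYb11", -5.0)

    @pytest.mark.parametrize(
        "habitat,unit",
        [(Habitat.plate, Unit.per_worm), (Habitat.worm, Unit.per_plate)],
    )
    def test_habitat_unit_mismatch_rejected(self, habitat, unit):
        with pytest.raises(ValidationError):
            CFUObservation(
                species_id="MYb11",
                habitat=habitat,
                assay=Assay.growth if habitat is Habitat.plate else Assay.persistence,
                culture=Culture.co,
                time_h=0,
                replicate=1,
                cfu=10,
                unit=unit,
            )

    def test_worm_assay_requires_worm_habitat(self):
        with pytest.raises(ValidationError):
            CFUObservation(
                species_id="MYb71",
                habitat=Habitat.plate,
                assay=Assay.persistence,
                culture=Culture.co,
                time_h=1,
                replicate=1,
                cfu=10,
                unit=Unit.per_plate,
            )

    @given(
        cfu=st.floats(min_value=0, max_value=1e12, allow_nan=False),
        time_h=st.floats(min_value=0, max_value=200, allow_nan=False),
        rep=st.integers(min_value=1, max_value=10),
    )
    @settings(max_examples=50, derandomize=True)
    def test_valid_records_accepted(self, cfu, time_h, rep):
        obs = _growth_obs("sp", cfu, rep=rep, time_h=time_h)
        assert obs.cfu == cfu and obs.replicate == rep

    @given(
        cfu=st.floats(max_value=-1e-9, min_value=-1e12, allow_nan=False)
        | st.floats(allow_nan=True, allow_infinity=False).filter(
            lambda v: v != v
        ),
    )
    @settings(max_examples=25, derandomize=True)
    def test_invalid_cfu_rejected(self, cfu):
        with pytest.raises(ValidationError):
            _growth_obs("sp", cfu)


class TestCFUTable:
    def test_duplicate_key_rejected(self):
        obs = _growth_obs("MYb11", 10.0)
        with pytest.raises(TableValidationError, match="duplicate"):
            CFUTable(observations=[obs, obs])

    def test_incomplete_co_pairs_flagged(self):
        table = CFUTable(observations=[_growth_obs("MYb11", 10.0)])
        assert table.incomplete_co_groups() == [("plate", "growth", 72.0, 1)]
        paired = CFUTable(
            observations=[_growth_obs("MYb11", 10.0), _growth_obs("MYb71", 5.0)]
        )
        assert paired.incomplete_co_groups() == []


class TestCFUTableIO:
    def test_two_row_file_parses(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "species_id\thabitat\tassay\tculture\ttime_h\treplicate\tcfu\tunit\n"
            "MYb11\tplate\tgrowth\tco\t72\t1\t1.86e9\tper_plate\n"
            "MYb71\tplate\tgrowth\tco\t72\t1\t8.0e8\tper_plate\n"
        )
        table = read_cfu_table(path)
        assert len(table) == 2
        assert table.observations[0].cfu == 1.86e9  # scientific notation fidelity

    def test_missing_column_names_column(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("species_id\thabitat\tassay\n")
        with pytest.raises(TableSchemaError, match="culture"):
            read_cfu_table(path)

    def test_negative_cfu_cites_row(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "species_id\thabitat\tassay\tculture\ttime_h\treplicate\tcfu\tunit\n"
            "MYb11\tplate\tgrowth\tco\t72\t1\t-5\tper_plate\n"
        )
        with pytest.raises(TableValidationError, match="row 0"):
            read_cfu_table(path)

    def test_round_trip_identity(self, tmp_path, noiseless_co_table):
        path = tmp_path / "co.tsv"
        write_cfu_table(noiseless_co_table, path)
        again = read_cfu_table(path)
        assert again.observations == noiseless_co_table.observations

    def test_empty_table_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_cfu_table(CFUTable(), path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("species_id\t")
        assert len(read_cfu_table(path)) == 0


class TestTraitTable:
    def test_doubling_time_autofilled(self, tmp_path):
        path = tmp_path / "traits.tsv"
        table = generate_trait_table(4, seed=0)
        frame = table.frame.drop(columns=["doubling_time_h"]).reset_index()
        frame.loc[0, "max_growth_rate"] = 0.4
        frame.loc[1, "max_growth_rate"] = 0.12
        frame.to_csv(path, sep="\t", index=False)
        parsed = read_trait_table(path)
        assert parsed.frame["doubling_time_h"].iloc[0] == pytest.approx(1.733, abs=1e-3)
        assert parsed.frame["doubling_time_h"].iloc[1] == pytest.approx(5.776, abs=1e-3)

    def test_codon_usage_bias_range_enforced(self):
        table = generate_trait_table(4, seed=0)
        frame = table.frame.copy()
        frame.loc[frame.index[0], "codon_usage_bias"] = 1.2
        with pytest.raises(TableValidationError, match="codon_usage_bias"):
            TraitTable(frame)

    def test_inconsistent_doubling_time_rejected(self):
        table = generate_trait_table(4, seed=0)
        frame = table.frame.copy()
        frame.loc[frame.index[0], "doubling_time_h"] = (
            2.0 * math.log(2) / frame.loc[frame.index[0], "max_growth_rate"]
        )
        with pytest.raises(TableValidationError, match="inconsistent"):
            TraitTable(frame)

    def test_round_trip_identity(self, tmp_path):
        table = generate_trait_table(6, planted={"a": "ruderal"}, seed=5)
        path = tmp_path / "traits.tsv"
        write_trait_table(table, path)
        assert read_trait_table(path) == table


def test_od_calibration_rejects_nonpositive():
    with pytest.raises(ValidationError):
        ODCalibration(cfu_per_od={"MYb11": 0.0})
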