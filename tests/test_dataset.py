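"""Dataset schema, parsing, validation, design matrices and EDA."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qaop.dataset import (
    COLUMNS,
    DatasetValidationError,
    DNTDataset,
    ParseError,
    PredictorAssignment,
    SchemaError,
    build_design_matrices,
    explore_dataset,
    read_dataset,
    validate_dataset,
    write_dataset,
)
from qaop.synthetic import GeneratorConfig, apply_missingness, simulate_dataset

from conftest import make_record


def write_csv(tmp_path, rows, header=COLUMNS):
    path = tmp_path / "ds.csv"
    lines = [",".join(header)]
    lines += [",".join(r) for r in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def row(name, cas, dnt="1", bdnf="0"):
    r = dict.fromkeys(COLUMNS, "")
    r.update(
        compound_name=name,
        cas_rn=cas,
        dnt_label=dnt,
        bdnf_label=bdnf,
        logd="1.5",
        syn_label="1",
        syn_viability="80",
        syn_ec30_um="10",
        nnf_label="0",
        nnf_viability="75",
        nnf_ec50min_um="1",
        nnf_ec50max_um="5",
    )
    return [r[c] for c in COLUMNS]


class TestReadDataset:
    def test_missing_cell_becomes_none(self, tmp_path):
        rows = [row("a", "1-1"), row("b", "2-2", bdnf=""), row("c", "3-3")]
        ds = read_dataset(write_csv(tmp_path, rows))
        assert len(ds) == 3
        assert ds.records[1].bdnf_label is None
        assert ds.records[0].bdnf_label == 0
        assert [r.name for r in ds.records] == ["a", "b", "c"]

    def test_nonbinary_value_cites_row_and_column(self, tmp_path):
        rows = [row("a", "1-1"), row("b", "2-2", dnt="2")]
        with pytest.raises(ParseError, match=r"row 2.*dnt_label"):
            read_dataset(write_csv(tmp_path, rows))

    def test_missing_mandatory_column_named(self, tmp_path):
        header = [c for c in COLUMNS if c != "cas_rn"]
        path = write_csv(tmp_path, [], header=header)
        with pytest.raises(SchemaError, match="cas_rn"):
            read_dataset(path)

    def test_duplicate_cas_rejected(self, tmp_path):
        rows = [row("a", "1-1"), row("b", "1-1")]
        with pytest.raises(DatasetValidationError, match="duplicate CAS"):
            read_dataset(write_csv(tmp_path, rows))

    def test_complete_case_fixture_has_no_missing(self, complete_8, tmp_path):
        path = write_dataset(complete_8, tmp_path / "f.csv")
        ds = read_dataset(path)
        assert len(ds) == 8
        frame = ds.to_frame()
        numeric = frame.drop(columns=["smiles", "dtxsid"])
        assert not numeric.isna().any().any()


class TestRoundTrip:
    def test_write_read_identity_with_missingness(self, tmp_path):
        ds, _ = simulate_dataset(GeneratorConfig(n_compounds=50, seed=11))
        ds = apply_missingness(
            ds, {"logd": 0.3, "bdnf_label": 0.5, "syn_ec30_um": 0.2}, seed=3
        )
        back = read_dataset(write_dataset(ds, tmp_path / "rt.csv"))
        for a, b in zip(ds.records, back.records):
            for col in COLUMNS:
                va, vb = a.get(col), b.get(col)
                if va is None or vb is None:
                    assert va is None and vb is None, col
                elif isinstance(va, float):
                    assert math.isclose(va, vb, rel_tol=0, abs_tol=0), col
                else:
                    assert va == vb, col

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 12))
    def test_round_trip_property(self, tmp_path_factory, seed, n):
        ds, _ = simulate_dataset(GeneratorConfig(n_compounds=n, seed=seed))
        tmp = tmp_path_factory.mktemp("rt")
        back = read_dataset(write_dataset(ds, tmp / "p.csv"))
        assert back.to_frame().equals(ds.to_frame())


class TestValidateDataset:
    def test_clean_dataset_passes(self, clean_dataset):
        assert validate_dataset(clean_dataset) == []

    def test_violations_reported_with_index(self):
        recs = [
            make_record(0),
            make_record(1, syn_ec30=-1.0),
            make_record(2, nnf_ec50min=10.0, nnf_ec50max=1.0),
        ]
        v = validate_dataset(DNTDataset(recs))
        assert len(v) == 2
        assert any("record 1" in s and "non-positive EC" in s for s in v)
        assert any("record 2" in s and "ec50min > " in s.replace("nnf_", "") for s in v)

    def test_missing_ao_label_flagged(self):
        ds = DNTDataset([make_record(0), make_record(1, dnt_label=None)])
        v = validate_dataset(ds)
        assert len(v) == 1 and "AO label required" in v[0]


class TestBuildDesignMatrices:
    def test_zscore_uses_sample_sd(self):
        # logd {1, 3}: mean 2, sample sd sqrt(2) -> z = ±1/sqrt(2)
        ds = DNTDataset([make_record(0, logd=1.0), make_record(1, logd=3.0)])
        dm = build_design_matrices(ds)
        j = dm.columns["bdnf"].index("logd")
        np.testing.assert_allclose(
            dm.x_bdnf[:, j], [-1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-12
        )

    def test_ec_log10_then_zscore(self):
        # syn_ec30 {10, 1000}: log10 -> {1, 3} -> ±1/sqrt(2)
        ds = DNTDataset(
            [make_record(0, syn_ec30=10.0), make_record(1, syn_ec30=1000.0)]
        )
        dm = build_design_matrices(ds)
        j = dm.columns["syn"].index("syn_ec30_um")
        np.testing.assert_allclose(
            dm.x_syn[:, j], [-1 / np.sqrt(2), 1 / np.sqrt(2)], atol=1e-12
        )

    def test_observed_columns_standardized(self, complete_8):
        dm = build_design_matrices(complete_8)
        for block, x in dm.x_blocks().items():
            for j, col in enumerate(dm.columns[block]):
                if col in ("intercept",) or col not in dm.standardization:
                    continue
                if dm.standardization[col] == (0.0, 1.0):
                    continue  # binary columns stay 0/1
                assert abs(x[:, j].mean()) < 1e-9
                assert abs(x[:, j].std(ddof=1) - 1.0) < 1e-9

    def test_missing_cell_masked_not_imputed(self):
        recs = [make_record(i) for i in range(4)]
        recs[2].syn_ec30 = None
        dm = build_design_matrices(DNTDataset(recs))
        j = dm.columns["syn"].index("syn_ec30_um")
        assert dm.miss_syn[2, j] == 1
        assert dm.x_syn[2, j] == 0.0
        assert dm.miss_syn.sum() == 1

    def test_masked_count_equals_missing_fields(self):
        ds, _ = simulate_dataset(GeneratorConfig(n_compounds=40, seed=5))
        ds = apply_missingness(ds, {"logd": 0.3, "bbb": 0.2, "nnf_viability": 0.25}, seed=9)
        dm = build_design_matrices(ds)
        n_missing_raw = sum(
            1
            for r in ds.records
            for a in ("logd", "bbb", "nnf_viability")
            if getattr(r, a) is None
        )
        total_masked = int(dm.miss_bdnf.sum() + dm.miss_syn.sum() + dm.miss_nnf.sum())
        assert total_masked == n_missing_raw

    def test_standardization_invertible(self, complete_8):
        from qaop.dataset import destandardize

        dm = build_design_matrices(complete_8)
        raw = complete_8.column("syn_ec30_um")
        j = dm.columns["syn"].index("syn_ec30_um")
        np.testing.assert_allclose(
            destandardize(dm, "syn_ec30_um", dm.x_syn[:, j]), raw, rtol=1e-9
        )

    def test_entirely_missing_column_errors(self):
        recs = [make_record(i, logd=None) for i in range(3)]
        with pytest.raises(DatasetValidationError, match="logd"):
            build_design_matrices(DNTDataset(recs))

    def test_zero_variance_column_errors(self):
        recs = [make_record(i, logd=2.5) for i in range(3)]
        with pytest.raises(DatasetValidationError, match="zero-variance.*logd"):
            build_design_matrices(DNTDataset(recs))

    def test_intercept_disabled_by_config(self, complete_8):
        dm = build_design_matrices(
            complete_8, PredictorAssignment(include_intercept=False)
        )
        assert "intercept" not in dm.columns["bdnf"]
        assert dm.block_dims == (6, 2, 3)


class TestExploreDataset:
    def test_self_and_linear_correlations(self):
        recs = [
            make_record(i, logd=float(i + 1), cbrain_cblood=2.0 * (i + 1))
            for i in range(3)
        ]
        eda = explore_dataset(DNTDataset(recs))
        corr = eda.pearson_correlations
        assert corr.loc["logd", "logd"] == pytest.approx(1.0)
        assert corr.loc["logd", "cbrain_cblood"] == pytest.approx(1.0)
        assert np.allclose(corr.values, corr.values.T, equal_nan=True)

    def test_missing_fraction(self):
        recs = [make_record(i) for i in range(10)]
        for i in range(4):
            recs[i].bdnf_label = None
        eda = explore_dataset(DNTDataset(recs))
        assert eda.missing_fraction["bdnf_label"] == pytest.approx(0.4)

    def test_undefined_correlation_is_nan_not_zero(self):
        recs = [make_record(i) for i in range(4)]
        for i in (0, 1, 2):
            recs[i].logd = None
        eda = explore_dataset(DNTDataset(recs))
        assert np.isnan(eda.pearson_correlations.loc["logd", "cbrain_cblood"])

    def test_class_balance_over_observed_only(self):
        recs = [make_record(i, bdnf_label=1) for i in range(4)]
        recs[0].bdnf_label = None
        recs[1].bdnf_label = 0
        eda = explore_dataset(DNTDataset(recs))
        assert eda.class_balance["bdnf_label"] == pytest.approx(2 / 3)
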