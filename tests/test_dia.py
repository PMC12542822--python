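"""DIA time-course filtering, matrix building, imputation, contrasts."""

import numpy as np
import pandas as pd
import pytest

import phoskit.dia as dia
from phoskit import ConfigError, SimConfig, generate_dia_timecourse


def design_2x2x3(stages=("MI", "MII")):
    rows = []
    for stage in stages:
        for cond in ("control", "treatment"):
            for b in (1, 2):
                for t in (1, 2, 3):
                    rows.append([f"{cond[:3]}_{stage}_b{b}_t{t}", cond, stage, b, t])
    return dia.TimeCourseDesign(
        pd.DataFrame(
            rows, columns=["run_id", "condition", "stage", "bio_replicate", "tech_replicate"]
        )
    )


class TestFilterDia:
    def _rows(self):
        # 8 rows, 3 failing one or both thresholds -> 5 retained
        return pd.DataFrame(
            {
                "run_id": ["r1"] * 8,
                "protein_group_id": [f"P{i}" for i in range(8)],
                "precursor_id": [f"pre{i}" for i in range(8)],
                "psm_q": [0.001, 0.0005, 0.002, 0.0001, 0.001, 0.01, 0.0002, 0.0009],
                "pg_q": [0.05, 0.01, 0.01, 0.06, 0.04, 0.2, 0.05, 0.03],
                "quantity": [100.0] * 8,
            }
        )

    def test_boundaries_inclusive(self):
        rows = self._rows()
        kept, _ = dia.filter_dia(rows)
        # psm_q = 0.001 exactly and pg_q = 0.05 exactly are retained
        assert "P0" in set(kept["protein_group_id"])

    def test_above_threshold_removed(self):
        kept, _ = dia.filter_dia(self._rows())
        assert "P2" not in set(kept["protein_group_id"])  # psm_q = 0.002

    def test_fixture_retains_five(self):
        kept, report = dia.filter_dia(self._rows())
        assert report == {"n_input": 8, "n_retained": 5, "n_removed": 3}
        assert len(kept) == 5


class TestBuildMatrix:
    def test_log10_and_tech_averaging(self):
        des = design_2x2x3(stages=("MI",))
        q = pd.DataFrame(
            [[1000.0] * 3 + [10 ** 3.0, 10 ** 3.1, 10 ** 3.2] + [1000.0] * 6],
            index=pd.Index(["P1"], name="protein_group_id"),
            columns=des.table["run_id"].tolist(),
        )
        m = dia.build_matrix(q, des)
        assert m.values.loc["P1", "con_MI_b1"] == pytest.approx(3.0)
        assert m.values.loc["P1", "con_MI_b2"] == pytest.approx(3.1, abs=1e-9)

    def test_centering_subtracts_row_mean(self):
        des = design_2x2x3(stages=("MI",))
        vals = [10 ** 3, 10 ** 3, 10 ** 3, 10 ** 4, 10 ** 4, 10 ** 4,
                10 ** 5, 10 ** 5, 10 ** 5, 10 ** 4, 10 ** 4, 10 ** 4]
        q = pd.DataFrame([vals], index=pd.Index(["P1"], name="p"),
                         columns=des.table["run_id"].tolist())
        centered = dia.build_matrix(q, des).centered()
        np.testing.assert_allclose(centered.loc["P1"].to_numpy(), [-1, 0, 1, 0], atol=1e-12)

    def test_unknown_run_rejected(self):
        des = design_2x2x3(stages=("MI",))
        q = pd.DataFrame([[1.0]], index=["P1"], columns=["mystery_run"])
        with pytest.raises(ConfigError, match="mystery_run"):
            dia.build_matrix(q, des)


class TestImputeAndWeight:
    def _matrix(self, rows, stages=("MI",)):
        des = design_2x2x3(stages=stages)
        units = des.units()
        values = pd.DataFrame(rows, columns=units["unit_id"].tolist())
        values.index = [f"P{i}" for i in range(len(values))]
        weights = pd.DataFrame(
            np.where(np.isfinite(values.to_numpy()), 1.0, 0.0),
            index=values.index, columns=values.columns,
        )
        imputed = pd.DataFrame(False, index=values.index, columns=values.columns)
        return dia.ProteinQuantMatrix(values, weights, imputed, units)

    def test_group_minimum_rule_three_protein_fixture(self):
        # columns: con_b1, con_b2, tre_b1, tre_b2
        m = self._matrix(
            [
                [5.0, np.nan, 5.2, 5.3],  # missing control -> control min 5.0
                [4.0, 4.1, np.nan, np.nan],  # treatment empty -> protein-wide min 4.0
                [3.0, 3.1, 3.2, 3.3],  # complete -> untouched
            ]
        )
        out = dia.impute_and_weight(m)
        assert out.values.loc["P0", "con_MI_b2"] == pytest.approx(5.0)
        assert out.weights.loc["P0", "con_MI_b2"] == 0.05
        assert out.values.loc["P1", "tre_MI_b1"] == pytest.approx(4.0)
        assert out.values.loc["P1", "tre_MI_b2"] == pytest.approx(4.0)
        assert (out.weights.loc["P1", ["tre_MI_b1", "tre_MI_b2"]] == 0.05).all()
        assert (out.weights.loc["P2"] == 1.0).all()
        np.testing.assert_allclose(out.values.loc["P2"], [3.0, 3.1, 3.2, 3.3])

    def test_observed_cells_never_altered(self):
        m = self._matrix([[5.0, np.nan, 5.2, 5.3]])
        out = dia.impute_and_weight(m)
        obs = ~m.values.isna()
        np.testing.assert_array_equal(
            out.values.to_numpy()[obs.to_numpy()], m.values.to_numpy()[obs.to_numpy()]
        )

    def test_finite_cells_never_decrease(self):
        m = self._matrix([[5.0, np.nan, np.nan, 5.3], [np.nan, 2.0, 2.1, np.nan]])
        out = dia.impute_and_weight(m)
        assert np.isfinite(out.values.to_numpy()).sum() >= np.isfinite(
            m.values.to_numpy()
        ).sum()

    def test_fully_observed_matrix_is_noop(self):
        m = self._matrix([[1.0, 2.0, 3.0, 4.0]])
        out = dia.impute_and_weight(m)
        assert (out.weights.to_numpy() == 1.0).all()
        np.testing.assert_array_equal(out.values.to_numpy(), m.values.to_numpy())

    def test_never_observed_protein_dropped(self):
        m = self._matrix([[np.nan] * 4, [1.0, 2.0, 3.0, 4.0]])
        out = dia.impute_and_weight(m)
        assert list(out.values.index) == ["P1"]


class TestDifferential:
    def _pipeline(self, missing_rate, seed=5):
        cfg = SimConfig(seed=seed, n_proteins=150, missing_rate=missing_rate)
        ds = generate_dia_timecourse(cfg, stages=["MI", "MII"], n_bio=2, n_tech=3)
        des = dia.TimeCourseDesign(ds.run_design)
        complete = dia.impute_and_weight(dia.build_matrix(ds.quantities, des))
        return ds, dia.differential_all_stages(complete)

    def test_no_missingness_equals_unweighted_path(self):
        cfg = SimConfig(seed=5, n_proteins=120, missing_rate=0.0)
        ds = generate_dia_timecourse(cfg, stages=["MI"], n_bio=2, n_tech=3)
        des = dia.TimeCourseDesign(ds.run_design)
        built = dia.build_matrix(ds.quantities, des)
        weighted = dia.differential_dia(dia.impute_and_weight(built), "MI")

        from phoskit import Design, run_differential

        units = built.units
        cols = units["unit_id"].tolist()
        plain_design = Design(
            conditions=dict(zip(units["unit_id"], units["condition"])),
            replicates={u: str(b) for u, b in zip(units["unit_id"], units["bio_replicate"])},
        )
        plain, _ = run_differential(built.values[cols], plain_design)
        np.testing.assert_allclose(weighted["t_mod"], plain["t_mod"], atol=1e-12)
        np.testing.assert_allclose(weighted["p_adj"], plain["p_adj"], atol=1e-12)

    def test_recovers_planted_stage_specific_changes(self):
        ds, res = self._pipeline(missing_rate=0.1)
        truth = ds.truth.set_index("feature_id")
        called = res[res["called"]]
        assert len(called) > 0
        is_tp = [
            truth.loc[protein, "affected_stage"] == row["stage"]
            for protein, row in called.iterrows()
        ]
        fdp = 1.0 - sum(is_tp) / len(called)
        planted = (truth["affected_stage"] != "").sum()
        assert fdp <= 0.2
        assert sum(is_tp) >= 0.7 * planted

    def test_effect_size_threshold_applied_inclusively(self):
        """Re-running with lfc_min set to a called protein's own |log2fc|
        must keep that protein called: the bound is >=, not >."""
        cfg = SimConfig(seed=5, n_proteins=150, missing_rate=0.1)
        ds = generate_dia_timecourse(cfg, stages=["MI"], n_bio=2, n_tech=3)
        des = dia.TimeCourseDesign(ds.run_design)
        complete = dia.impute_and_weight(dia.build_matrix(ds.quantities, des))
        res = dia.differential_dia(complete, "MI")
        called = res[res["called"]]
        assert len(called) > 0
        v = float(called["log2fc"].abs().min())
        boundary = dia.differential_dia(complete, "MI", lfc_min=v)
        protein = called["log2fc"].abs().idxmin()
        assert bool(boundary.loc[protein, "called"])

    def test_unknown_stage_rejected(self):
        cfg = SimConfig(seed=5, n_proteins=30)
        ds = generate_dia_timecourse(cfg, stages=["MI"], n_bio=2, n_tech=3)
        des = dia.TimeCourseDesign(ds.run_design)
        complete = dia.impute_and_weight(dia.build_matrix(ds.quantities, des))
        with pytest.raises(ConfigError, match="GVBD"):
            dia.differential_dia(complete, "GVBD")
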