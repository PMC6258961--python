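"""Ensemble averaging, scoring pipeline, decision bands and persistence."""

import io
import json

import numpy as np
import pytest

from abps import (
    AbpsEnsemble,
    ClipWarning,
    CohortSpec,
    MARKERS,
    ModelFormatError,
    classify_band,
    clip_matrix,
    ensemble_average,
    generate_cohort_frame,
    load_model,
    read_profiles,
    save_model,
    score_profiles,
    train_ensemble,
    write_profiles,
)
from abps.persistence import model_from_dict, model_to_dict


class TestEnsembleAverage:
    def test_opposite_standardized_components_average_to_zero(self):
        # centers (2, 4), scales (1, 2): components 3 and 2 standardize to +1, -1
        assert ensemble_average(3.0, 2.0, (2.0, 4.0), (1.0, 2.0)) == 0.0

    def test_equal_standardized_components_average_to_themselves(self):
        z = ensemble_average(2.5, 2.5, (0.0, 0.0), (1.0, 1.0))
        assert z == 2.5

    def test_five_sample_hand_recomputation(self):
        nb = np.array([0.2, -1.1, 0.7, 2.0, -0.3])
        sv = np.array([1.5, 0.1, -0.4, 0.9, 0.6])
        centers = (nb.mean(), sv.mean())
        scales = (nb.std(ddof=1), sv.std(ddof=1))
        got = ensemble_average(nb, sv, centers, scales)
        expected = 0.5 * (nb - centers[0]) / scales[0] + 0.5 * (sv - centers[1]) / scales[1]
        assert np.allclose(got, expected, atol=1e-12)

    def test_zero_component_scale_is_hard_error(self):
        with pytest.raises(ValueError, match="zero component scale"):
            ensemble_average(1.0, 1.0, (0.0, 0.0), (0.0, 1.0))

    def test_weights_are_normalized(self):
        a = ensemble_average(1.0, 3.0, (0.0, 0.0), (1.0, 1.0), weights=(1, 1))
        b = ensemble_average(1.0, 3.0, (0.0, 0.0), (1.0, 1.0), weights=(2, 2))
        assert a == b == 2.0


class TestBands:
    @pytest.mark.parametrize(
        "score, band",
        [
            (0.5, "suspicion"),
            (1.2, "abnormal"),
            (-0.67, "typical"),
            (0.0, "suspicion"),
            (1.0, "suspicion"),
            (1.0000001, "abnormal"),
            (-1e-9, "typical"),
        ],
    )
    def test_band_boundaries(self, score, band):
        assert classify_band(score) == band

    def test_nonfinite_score_rejected(self):
        with pytest.raises(ValueError):
            classify_band(float("nan"))


class TestScoringPipeline:
    def test_scoring_calibration_population_recovers_reference_mean(self, default_model):
        from abps.workflow import reference_population

        ref = reference_population(0, 5_000)
        s = default_model.abps(ref[list(MARKERS)].to_numpy(float))
        assert s.mean() == pytest.approx(-0.67, abs=0.02)
        assert s.std(ddof=1) == pytest.approx(0.87, abs=0.02)

    def test_permuting_inputs_permutes_outputs(self, default_model, cohort_frame):
        df = cohort_frame.head(40)
        perm = np.random.default_rng(3).permutation(len(df))
        out1 = score_profiles(df, default_model)
        out2 = score_profiles(df.iloc[perm].reset_index(drop=True), default_model)
        by_id = {s.sample_id: s.abps for s in out1}
        assert all(s.abps == by_id[s.sample_id] for s in out2)
        assert [s.sample_id for s in out2] == df.iloc[perm]["sample_id"].tolist()

    def test_profile_and_clipped_copy_score_identically(self, default_model):
        X = np.array([[60.0, 19.5, 29.6, 34.0, 87.0, 4.9, 0.05]])  # out of range
        with pytest.warns(ClipWarning):
            import pandas as pd

            df = pd.DataFrame(X, columns=list(MARKERS))
            df.insert(0, "sample_id", ["raw"])
            s_raw = score_profiles(df, default_model)
        dfc = df.copy()
        dfc.loc[:, list(MARKERS)] = clip_matrix(X)
        s_clip = score_profiles(dfc, default_model)
        assert s_raw[0].abps == s_clip[0].abps

    def test_empty_input_gives_empty_output(self, default_model):
        import pandas as pd

        assert score_profiles(pd.DataFrame(columns=["sample_id", *MARKERS]), default_model) == []

    def test_uncalibrated_model_refuses_to_score(self, cohort_matrix):
        X, y = cohort_matrix
        m = AbpsEnsemble().fit(X, y)
        with pytest.raises(AttributeError, match="calibrat"):
            m.abps(X[:3])

    def test_training_is_deterministic(self, cohort_matrix):
        X, y = cohort_matrix
        m1 = train_ensemble(X, y).calibrate(X=X[y == "control"])
        m2 = train_ensemble(X, y).calibrate(X=X[y == "control"])
        probe = X[::5]
        assert np.array_equal(m1.abps(probe), m2.abps(probe))


class TestPersistence:
    def test_save_load_round_trip_is_bit_exact(self, default_model):
        probe = generate_cohort_frame(CohortSpec(n_control=60, n_doped=40, seed=42))
        X = probe[list(MARKERS)].to_numpy(float)
        s1 = default_model.abps(X)
        buf = io.StringIO()
        save_model(default_model, buf)
        buf.seek(0)
        s2 = load_model(buf).abps(X)
        assert np.array_equal(s1, s2)

    def test_empty_file_is_schema_error(self):
        with pytest.raises(ModelFormatError):
            load_model(io.StringIO(""))

    def test_unknown_schema_version_rejected(self, default_model):
        d = model_to_dict(default_model)
        d["schema_version"] = 99
        with pytest.raises(ModelFormatError, match="version"):
            model_from_dict(d)

    def test_truncated_file_rejected(self, default_model):
        buf = io.StringIO()
        save_model(default_model, buf)
        with pytest.raises(ModelFormatError):
            load_model(io.StringIO(buf.getvalue()[: len(buf.getvalue()) // 2]))

    def test_marker_order_is_canonicalized_on_load(self, default_model):
        probe = generate_cohort_frame(CohortSpec(n_control=30, n_doped=0, seed=9))
        X = probe[list(MARKERS)].to_numpy(float)
        s1 = default_model.abps(X)
        d = json.loads(json.dumps(model_to_dict(default_model)))
        perm = [6, 0, 5, 1, 4, 2, 3]
        d["markers"] = [list(MARKERS)[i] for i in perm]
        d["naive_bayes"]["kdes"] = [[row[i] for i in perm] for row in d["naive_bayes"]["kdes"]]
        for key in ("center", "scale"):
            d["svm"][key] = [d["svm"][key][i] for i in perm]
        d["svm"]["support_vectors"] = [[v[i] for i in perm] for v in d["svm"]["support_vectors"]]
        s2 = model_from_dict(d).abps(X)
        assert np.array_equal(s1, s2)


def test_csv_round_trip_through_scoring(default_model, cohort_frame, tmp_path):
    """Profiles written to CSV and read back score identically."""
    profiles = read_profiles(io.StringIO(cohort_frame.head(20).to_csv(index=False)))
    path = tmp_path / "p.csv"
    with open(path, "w") as fh:
        write_profiles(profiles, fh)
    reread = read_profiles(path)
    s1 = [s.abps for s in score_profiles(profiles, default_model)]
    s2 = [s.abps for s in score_profiles(reread, default_model)]
    assert s1 == s2
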