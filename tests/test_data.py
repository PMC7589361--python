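import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import constant_episode, make_episode
from recline.data import (
    Dataset,
    Episode,
    Recording,
    integrate_datasets,
    normalize_episode,
    posture_axis_summary,
    read_dataset,
    resegment_episode,
    segment_by_labels,
    write_dataset,
)
from recline.errors import (
    DegenerateInputError,
    ParseError,
    ValidationError,
)
from recline.synthetic import SimulationConfig, simulate_dataset


class TestEpisode:
    def test_valid_episode(self):
        ep = make_episode([[0, 0, 1], [0, 0, 1]])
        assert ep.n_samples == 2
        assert ep.duration_s == pytest.approx(2 / 25)

    def test_rejects_empty(self):
        with pytest.raises(ValidationError):
            make_episode(np.empty((0, 3)))

    def test_rejects_bad_shape(self):
        with pytest.raises(ValidationError):
            make_episode([[1, 2], [3, 4]])

    def test_rejects_nan(self):
        with pytest.raises(ValidationError):
            make_episode([[0, 0, np.nan]])

    def test_rejects_bad_rate(self):
        with pytest.raises(ValidationError):
            make_episode([[0, 0, 1]], rate=0)

    def test_rejects_unknown_site(self):
        with pytest.raises(ValidationError):
            make_episode([[0, 0, 1]], site="elbow")

    def test_dataset_rejects_label_outside_vocabulary(self):
        ep = make_episode([[0, 0, 1]], posture="supine")
        with pytest.raises(ValidationError):
            Dataset("d", [ep], label_vocabulary=("prone", "left"))


class TestIO:
    def test_empty_dataset_round_trip(self, tmp_path):
        manifest = write_dataset(Dataset("empty", []), tmp_path)
        ds = read_dataset(manifest)
        assert len(ds) == 0

    def test_three_sample_episode(self, tmp_path):
        (tmp_path / "ep.csv").write_text(
            "t,ax,ay,az\n0,0,0,1\n0.04,0,0,1\n0.08,0,0,1\n"
        )
        (tmp_path / "manifest.csv").write_text(
            "file,subject,site,posture,rate_hz\nep.csv,S1,chest,supine,25\n"
        )
        ds = read_dataset(tmp_path / "manifest.csv")
        ep = ds.episodes[0]
        assert ep.n_samples == 3
        assert ep.sampling_rate_hz == 25
        np.testing.assert_array_equal(ep.axis("z"), [1, 1, 1])

    def test_one_episode_manifest_row(self, tmp_path):
        ep = constant_episode([0, 0, 1], 5, subject="S9", site="wrist_L",
                              posture="prone", rate=30)
        manifest = write_dataset(Dataset("one", [ep]), tmp_path)
        lines = manifest.read_text().strip().splitlines()
        assert len(lines) == 2
        assert "S9" in lines[1] and "wrist_L" in lines[1] and "prone" in lines[1]

    @pytest.mark.parametrize("seed", range(10))
    def test_round_trip_random_dataset(self, tmp_path, seed):
        cfg = SimulationConfig(
            seed=seed, n_subjects=2, episodes_per_posture=1,
            sites=("chest", "wrist_R"), sampling_rate_hz=13.0,
            duration_mean_s=2.0, duration_sd_s=0.5,
        )
        original = simulate_dataset(cfg).dataset
        manifest = write_dataset(original, tmp_path / f"s{seed}")
        restored = read_dataset(manifest, label_vocabulary=original.label_vocabulary)
        assert len(restored) == len(original)
        for a, b in zip(original.episodes, restored.episodes):
            assert a.subject_id == b.subject_id
            assert a.body_site == b.body_site
            assert a.posture == b.posture
            assert a.sampling_rate_hz == b.sampling_rate_hz
            np.testing.assert_allclose(a.samples, b.samples, rtol=1e-11, atol=1e-14)

    def test_fifty_episode_round_trip_value_identical(self, tmp_path):
        cfg = SimulationConfig(
            seed=3, n_subjects=5, episodes_per_posture=1,
            sites=("chest", "thigh_L", "ankle_R"),
            duration_mean_s=1.5, duration_sd_s=0.2, sampling_rate_hz=11.0,
        )
        ds = simulate_dataset(cfg).dataset
        assert len(ds) >= 50
        manifest = write_dataset(ds, tmp_path)
        back = read_dataset(manifest)
        for a, b in zip(ds.episodes, back.episodes):
            np.testing.assert_allclose(a.samples, b.samples, rtol=1e-11, atol=1e-14)

    def test_missing_file_names_it(self, tmp_path):
        (tmp_path / "manifest.csv").write_text(
            "file,subject,site,posture,rate_hz\nnope.csv,S1,chest,supine,25\n"
        )
        with pytest.raises(FileNotFoundError, match="nope.csv"):
            read_dataset(tmp_path / "manifest.csv")

    def test_non_numeric_cell_reports_row(self, tmp_path):
        (tmp_path / "ep.csv").write_text("t,ax,ay,az\n0,0,0,1\n0.04,oops,0,1\n")
        (tmp_path / "manifest.csv").write_text(
            "file,subject,site,posture,rate_hz\nep.csv,S1,chest,supine,25\n"
        )
        with pytest.raises(ParseError, match="row 1"):
            read_dataset(tmp_path / "manifest.csv")

    def test_unknown_posture_label(self, tmp_path):
        (tmp_path / "ep.csv").write_text("t,ax,ay,az\n0,0,0,1\n")
        (tmp_path / "manifest.csv").write_text(
            "file,subject,site,posture,rate_hz\nep.csv,S1,chest,standing,25\n"
        )
        with pytest.raises(ValidationError, match="standing"):
            read_dataset(tmp_path / "manifest.csv")

    def test_scale_option_converts_units(self, tmp_path):
        (tmp_path / "ep.csv").write_text("t,ax,ay,az\n0,0,0,9.81\n")
        (tmp_path / "manifest.csv").write_text(
            "file,subject,site,posture,rate_hz\nep.csv,S1,chest,supine,25\n"
        )
        ds = read_dataset(tmp_path / "manifest.csv", scale=1 / 9.81)
        assert ds.episodes[0].samples[0, 2] == pytest.approx(1.0)


class TestNormalize:
    def test_identity_when_already_unit(self):
        ep = constant_episode([0, 0, 1.0], 10)
        out = normalize_episode(ep)
        np.testing.assert_array_equal(out.samples, ep.samples)

    def test_constant_981(self):
        ep = constant_episode([0, 0, 9.81], 4)
        out = normalize_episode(ep)
        np.testing.assert_allclose(out.samples, np.tile([0, 0, 1.0], (4, 1)))

    def test_scale_invariance(self, rng):
        samples = rng.normal([0, 0, 1], 0.1, size=(50, 3))
        ep = make_episode(samples)
        scaled = make_episode(samples * 3.7)
        np.testing.assert_allclose(
            normalize_episode(scaled).samples,
            normalize_episode(ep).samples,
            atol=1e-9,
        )

    def test_idempotent(self, rng):
        ep = make_episode(rng.normal([0.2, 0, 0.9], 0.05, size=(30, 3)))
        once = normalize_episode(ep)
        twice = normalize_episode(once)
        np.testing.assert_allclose(once.samples, twice.samples, atol=1e-12)

    def test_all_zero_is_degenerate(self):
        ep = constant_episode([0, 0, 0], 5)
        with pytest.raises(DegenerateInputError):
            normalize_episode(ep)


class TestSegmentByLabels:
    def _recording(self, n):
        samples = np.arange(3 * n, dtype=float).reshape(n, 3)
        return Recording("S1", "chest", 25.0, samples)

    def test_single_run(self):
        eps = segment_by_labels(self._recording(100), ["supine"] * 100)
        assert len(eps) == 1 and eps[0].n_samples == 100

    def test_null_gap_splits(self):
        labels = ["supine"] * 50 + [None] * 10 + ["prone"] * 40
        eps = segment_by_labels(self._recording(100), labels)
        assert [e.n_samples for e in eps] == [50, 40]
        assert [e.posture for e in eps] == ["supine", "prone"]

    def test_all_null_empty(self):
        assert segment_by_labels(self._recording(10), [None] * 10) == []

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            segment_by_labels(self._recording(10), ["supine"] * 9)

    def test_concatenation_reproduces_labeled_subsequence(self, rng):
        rec = self._recording(200)
        labels = [
            rng.choice(["supine", "prone", "left", "right", None])
            for _ in range(200)
        ]
        eps = segment_by_labels(rec, labels)
        kept = rec.samples[[i for i, l in enumerate(labels) if l is not None]]
        if eps:
            np.testing.assert_array_equal(
                np.concatenate([e.samples for e in eps]), kept
            )
        else:
            assert kept.size == 0

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.sampled_from(["supine", "prone", "left", "right", None]),
            min_size=1,
            max_size=60,
        )
    )
    def test_counting_oracle(self, labels):
        rec = self._recording(len(labels))
        eps = segment_by_labels(rec, labels)
        assert sum(e.n_samples for e in eps) == sum(
            1 for l in labels if l is not None
        )


class TestResegment:
    def test_das_episode_gives_15_segments(self):
        ep = constant_episode([0, 0, 1], 7500, rate=25)
        segs = resegment_episode(ep, 20)
        assert len(segs) == 15
        assert all(s.n_samples == 500 for s in segs)

    def test_single_segment(self):
        ep = constant_episode([0, 0, 1], 500, rate=25)
        assert len(resegment_episode(ep, 20)) == 1

    def test_remainder_dropped(self):
        ep = constant_episode([0, 0, 1], 7499, rate=25)
        assert len(resegment_episode(ep, 20)) == 14

    def test_too_short_gives_empty(self):
        ep = constant_episode([0, 0, 1], 10, rate=25)
        assert resegment_episode(ep, 20) == []

    def test_sub_sample_segment_invalid(self):
        ep = constant_episode([0, 0, 1], 10, rate=25)
        with pytest.raises(ValidationError):
            resegment_episode(ep, 0.01)

    @settings(max_examples=60, deadline=None)
    @given(n=st.integers(1, 400), seg=st.integers(1, 10))
    def test_sample_conservation(self, n, seg):
        ep = constant_episode([0, 0, 1], n, rate=5)
        segs = resegment_episode(ep, seg)
        seg_len = int(np.floor(seg * 5))
        total = sum(s.n_samples for s in segs)
        assert total == seg_len * len(segs)
        assert 0 <= n - total
        assert n - total < seg_len or not segs

    def test_metadata_inherited(self):
        ep = constant_episode([0, 0, 1], 100, rate=25, subject="S7",
                              site="thigh_L", posture="right")
        seg = resegment_episode(ep, 2)[0]
        assert (seg.subject_id, seg.body_site.value, seg.posture) == (
            "S7", "thigh_L", "right",
        )


class TestIntegrateDatasets:
    @staticmethod
    def _das_like():
        eps = []
        for i in range(8):
            eps.append(
                constant_episode([0.8, 0, 0], 7500, rate=25,
                                 subject=f"D{i}", posture="right")
            )
            eps.append(
                constant_episode([0, 0, 0.9], 7500, rate=25,
                                 subject=f"D{i}", posture="supine")
            )
        return Dataset("das", eps)

    @staticmethod
    def _primary(n_per_label=5):
        eps = []
        for posture in ("supine", "prone", "left"):
            for i in range(n_per_label):
                eps.append(
                    constant_episode([0, 0, 1], 300, rate=30,
                                     subject=f"C{i}", posture=posture)
                )
        return Dataset("classact", eps)

    def test_candidate_count_120_per_posture(self):
        out = integrate_datasets(
            self._primary(), self._das_like(), ["chest"], 20, {}, seed=0
        )
        counts = out.label_counts()
        assert counts["right"] == 120 and counts["supine"] == 5 + 120

    def test_subsample_counts_exact(self):
        out = integrate_datasets(
            self._primary(), self._das_like(), ["chest"], 20,
            {"right": 80, "supine": 8}, seed=0,
        )
        counts = out.label_counts()
        assert counts == {"supine": 5 + 8, "prone": 5, "left": 5, "right": 80}

    def test_deterministic_per_seed(self):
        args = (self._primary(), self._das_like(), ["chest"], 20,
                {"right": 80, "supine": 8})
        a = integrate_datasets(*args, seed=5)
        b = integrate_datasets(*args, seed=5)
        assert len(a) == len(b)
        for x, y in zip(a.episodes, b.episodes):
            np.testing.assert_array_equal(x.samples, y.samples)
        c = integrate_datasets(*args, seed=6)
        assert c.label_counts() == a.label_counts()

    def test_over_request_raises(self):
        with pytest.raises(ValidationError, match="right"):
            integrate_datasets(
                self._primary(), self._das_like(), ["chest"], 20,
                {"right": 121}, seed=0,
            )

    def test_counting_oracle_random_parameterization(self, rng):
        for _ in range(5):
            want = int(rng.integers(0, 120))
            out = integrate_datasets(
                self._primary(), self._das_like(), ["chest"], 20,
                {"right": want}, seed=int(rng.integers(1e6)),
            )
            assert out.label_counts()["right"] == want


class TestPostureAxisSummary:
    def test_single_constant_episode(self):
        ds = Dataset("d", [constant_episode([0, 0, 1], 10)])
        table = posture_axis_summary(ds, "chest")
        assert table.loc[("supine", "z"), "mean"] == pytest.approx(1.0)
        assert table.loc[("supine", "z"), "sd"] == 0.0

    def test_two_episode_symmetry(self):
        ds = Dataset(
            "d",
            [
                constant_episode([0, 0, 0], 10),
                constant_episode([0, 0, 2], 10),
            ],
        )
        table = posture_axis_summary(ds, "chest")
        assert table.loc[("supine", "z"), "mean"] == pytest.approx(1.0)

    def test_no_matching_site_empty(self):
        ds = Dataset("d", [constant_episode([0, 0, 1], 10)])
        assert posture_axis_summary(ds, "wrist_L").empty

    def test_noise_free_simulation_matches_orientation_table(
        self, noise_free_chest
    ):
        from recline.synthetic import PostureOrientationModel

        orientation = PostureOrientationModel()
        table = posture_axis_summary(noise_free_chest.dataset, "chest")
        for posture in ("supine", "prone", "left", "right"):
            expected = orientation.direction("chest", posture)
            for k, axis in enumerate("xyz"):
                assert table.loc[(posture, axis), "mean"] == pytest.approx(
                    expected[k], abs=1e-9
                )
                assert table.loc[(posture, axis), "sd"] == pytest.approx(
                    0.0, abs=1e-9
                )
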