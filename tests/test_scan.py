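"""Sliding-window scan: tiling, scoring, merging, tissue assignment."""

import numpy as np
import pytest

from enhancerscan import GenomicInterval, call_and_merge, make_windows, score_windows
from enhancerscan.mkl import MKLModel
from enhancerscan.scan import ScanWindow, assign_tissues
from enhancerscan.intervals import FeatureTrack, GenomeAssembly


def model_with(kernel_names, train_features, alphas, bias=0.0, families=None):
    n = len(alphas)
    betas = np.full(len(kernel_names), 1.0 / len(kernel_names))
    return MKLModel(
        alphas=np.asarray(alphas, dtype=float),
        betas=betas,
        bias=bias,
        labels=np.where(np.asarray(alphas) >= 0, 1, -1),
        kernel_names=list(kernel_names),
        kernel_families=families or ["linear"] * len(kernel_names),
        normalizers=[1.0] * len(kernel_names),
        train_refs=[f"r{i}" for i in range(n)],
        C=1.0,
        train_features=train_features,
    )


class TestMakeWindows:
    def test_enumerated_small_chromosome(self):
        windows = make_windows({"chr1": 2500})
        assert [(w.start, w.end) for w in windows] == [(0, 1500), (500, 2000), (1000, 2500)]

    def test_sub_window_chromosome_yields_nothing(self):
        assert make_windows({"chr1": 1499}) == []

    @pytest.mark.parametrize("length", [1500, 1999, 2000, 7321, 10_000])
    def test_count_closed_form_vs_enumeration(self, length):
        windows = make_windows({"c": length})
        assert len(windows) == (length - 1500) // 500 + 1
        # enumeration oracle
        count = sum(1 for s in range(0, length, 500) if s + 1500 <= length)
        assert len(windows) == count

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            make_windows({"c": 5000}, size=100, step=200)


class TestCallAndMerge:
    def _windows(self, spans_scores):
        return [
            ScanWindow(GenomicInterval("chr1", s, e), step1_score=v)
            for (s, e), v in spans_scores
        ]

    def test_overlapping_pair_merges(self):
        track = call_and_merge(
            self._windows([((0, 1500), 1.0), ((500, 2000), 2.0)]), threshold=0.5
        )
        assert [(iv.start, iv.end, iv.score) for iv in track] == [(0, 2000, 2.0)]

    def test_distant_windows_stay_separate(self):
        track = call_and_merge(
            self._windows([((0, 1500), 1.0), ((2000, 3500), 1.0)]), threshold=0.5
        )
        assert len(track) == 2

    def test_transitive_chain_merges_to_one_call(self):
        track = call_and_merge(
            self._windows([((0, 1500), 1.0), ((500, 2000), 3.0), ((1000, 2500), 2.0)]),
            threshold=0.5,
        )
        (iv,) = track.intervals
        assert (iv.start, iv.end) == (0, 2500) and len(iv) == 2500
        assert iv.score == 3.0  # max member score

    def test_book_ended_windows_merge(self):
        track = call_and_merge(
            self._windows([((0, 1000), 1.0), ((1000, 2000), 1.0)]), threshold=0.0
        )
        assert len(track) == 1

    def test_threshold_monotone_contraction(self):
        rng = np.random.default_rng(0)
        windows = self._windows(
            [((i * 500, i * 500 + 1500), float(rng.normal())) for i in range(100)]
        )
        prev_bp, prev_calls = None, None
        for threshold in (-1.0, 0.0, 0.5, 1.0, 2.0):
            track = call_and_merge(windows, threshold)
            bp = track.total_bp()
            if prev_bp is not None:
                assert bp <= prev_bp
                assert len(track) <= prev_calls or bp < prev_bp
            prev_bp, prev_calls = bp, len(track)

    def test_coverage_equals_union_of_passing_windows(self):
        rng = np.random.default_rng(1)
        windows = self._windows(
            [((i * 500, i * 500 + 1500), float(rng.normal())) for i in range(50)]
        )
        threshold = 0.3
        track = call_and_merge(windows, threshold)
        passing = FeatureTrack(
            "p", [w.interval for w in windows if w.step1_score >= threshold]
        )
        assert track.total_bp() == passing.total_bp()


class TestScoreWindows:
    def _genome(self, n=20_000):
        rng = np.random.default_rng(5)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
        return GenomeAssembly(sequences={"chr1": seq})

    def test_conservation_model_refused(self):
        genome = self._genome()
        model = model_with(
            ["spectrum", "conservation"],
            {"spectrum": np.zeros((2, 256)), "conservation": np.zeros((2, 1))},
            [0.5, -0.5],
            families=["spectrum", "linear"],
        )
        with pytest.raises(ValueError, match="conservation"):
            score_windows(make_windows(genome.sizes), model, genome, [])

    def test_scores_deterministic_and_bias_only_for_zero_alphas(self):
        genome = self._genome()
        track = FeatureTrack("t", [GenomicInterval("chr1", 0, 3000)])
        model = model_with(
            ["spectrum", "functional"],
            {"spectrum": np.zeros((2, 256)), "functional": np.zeros((2, 1))},
            [0.0, 0.0],
            bias=0.25,
            families=["spectrum", "linear"],
        )
        windows = make_windows(genome.sizes)
        s1 = score_windows(windows, model, genome, [track])
        s2 = score_windows(windows, model, genome, [track])
        assert [w.step1_score for w in s1] == [w.step1_score for w in s2]
        assert all(w.step1_score == pytest.approx(0.25) for w in s1)

    def test_all_n_window_scored_from_overlap_and_bias(self):
        genome = GenomeAssembly(sequences={"chr1": "N" * 3000})
        track = FeatureTrack("t", [GenomicInterval("chr1", 0, 3000)])
        # one training example with a functional bit set; spectrum empty
        model = model_with(
            ["spectrum", "functional"],
            {"spectrum": np.zeros((1, 256)), "functional": np.ones((1, 1))},
            [2.0],
            bias=-0.5,
            families=["spectrum", "linear"],
        )
        scored = score_windows(make_windows(genome.sizes), model, genome, [track])
        # spectrum contributes 0; functional block = 1*1, alpha=2, beta=1/2 each
        assert scored[0].step1_score == pytest.approx(0.5 * 2.0 * 1.0 - 0.5)


class TestPlantedEnhancerRecovery:
    def test_most_planted_enhancers_overlap_a_merged_call(self, small_dataset):
        from enhancerscan.evaluation import cross_validate
        from enhancerscan.features import build_feature_bundles, bundles_to_matrices
        from enhancerscan.kernels import gram_matrix, variance_normalize
        from enhancerscan.mkl import TrainConfig, train_mkl
        from enhancerscan.scan import run_scan
        from enhancerscan.trainsets import build_step1_set

        ds = small_dataset
        labeled = build_step1_set(ds.records, ds.genome, seed=1)
        bundles = {
            b.region_id: b
            for b in build_feature_bundles(
                labeled.intervals(), ds.genome, ds.tracks, ds.conservation,
                region_ids=labeled.ids,
            )
        }
        spec = ("spectrum", "functional")  # conservation excluded genome-wide
        cv = cross_validate(bundles, labeled, kernel_spec=spec, config=TrainConfig(seed=1))
        threshold = cv.threshold_at_fpr(0.05)
        mats = bundles_to_matrices([bundles[r] for r in labeled.ids])
        Ks, feats, fams = [], {}, []
        for name in spec:
            K = variance_normalize(gram_matrix(mats[name], name=name))
            Ks.append(K)
            feats[name] = mats[name]
            fams.append("spectrum" if name == "spectrum" else "linear")
        model = train_mkl(
            Ks, labeled.labels, TrainConfig(seed=1), families=fams,
            train_refs=labeled.ids, train_features=feats,
        )
        result = run_scan(ds.genome, ds.tracks, model, threshold)
        calls = result.merged["step1"]
        recovered = np.mean([calls.overlaps_any(iv) for iv in ds.truth])
        assert recovered >= 0.8


class TestAssignTissues:
    def _setup(self):
        genome = GenomeAssembly(sequences={"chr1": "ACGT" * 2000})
        heart_track = FeatureTrack("heart_mark", [GenomicInterval("chr1", 0, 4000)])
        limb_track = FeatureTrack("limb_mark", [GenomicInterval("chr1", 4000, 8000)])
        tracks = [heart_track, limb_track]

        def tissue_model(bit_index):
            feats = np.zeros((1, 2))
            feats[0, bit_index] = 1.0
            return model_with(
                ["functional"], {"functional": feats}, [1.0], bias=-0.5
            )

        return genome, tracks, {"heart": tissue_model(0), "limb": tissue_model(1)}

    def test_windows_gated_on_positive_step1_score(self):
        genome, tracks, models = self._setup()
        windows = [
            ScanWindow(GenomicInterval("chr1", 0, 1500), step1_score=-1.0),
            ScanWindow(GenomicInterval("chr1", 500, 2000), step1_score=1.0),
        ]
        out = assign_tissues(windows, models, {"heart": 0.0, "limb": 0.0}, genome, tracks)
        called = {iv.start for iv in out["heart"]}
        assert called == {500}
        assert windows[0].tissue_scores == {}

    def test_window_may_pass_multiple_tissues(self):
        genome, tracks, models = self._setup()
        window = ScanWindow(GenomicInterval("chr1", 3000, 4500), step1_score=1.0)
        out = assign_tissues([window], models, {"heart": 0.0, "limb": 0.0}, genome, tracks)
        assert len(out["heart"]) == 1 and len(out["limb"]) == 1

    def test_missing_threshold_errors(self):
        genome, tracks, models = self._setup()
        with pytest.raises(ValueError, match="limb"):
            assign_tissues([], models, {"heart": 0.0}, genome, tracks)
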