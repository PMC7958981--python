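"""The four behavioral worker metrics and their eligibility rules."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import crowdtrust as ct

CFG3 = ct.StudyConfig(M=3, levels=(4, 4, 4), min_videos_metrics=2)

answer3 = st.lists(st.integers(0, 3), min_size=3, max_size=3).map(tuple)


@pytest.mark.parametrize(
    "a, b, expected",
    [((1, 2, 3), (1, 2, 3), 0.0), ((0, 3, 1), (2, 0, 1), 5.0),
     (tuple(range(13)), tuple(v + 1 for v in range(13)), 13.0)],
)
def test_l1_distance(a, b, expected):
    assert ct.l1_distance(a, b) == expected


def test_l1_distance_length_mismatch():
    with pytest.raises(ct.DimensionError):
        ct.l1_distance((1, 2), (1, 2, 3))


@given(answer3, answer3, st.permutations(range(3)))
def test_l1_distance_symmetric_and_permutation_invariant(a, b, perm):
    d = ct.l1_distance(a, b)
    assert ct.l1_distance(b, a) == d
    assert ct.l1_distance([a[i] for i in perm], [b[i] for i in perm]) == d


def test_mscl1_pairs_by_video_and_averages(make_response):
    # per-video retest distances 3 and 5; a video rated once is excluded
    responses = [
        make_response(video="v1", answers=(0, 0, 0)),
        make_response(video="v1", attempt=2, answers=(1, 2, 0)),   # L1 = 3
        make_response(video="v2", answers=(3, 3, 3)),
        make_response(video="v2", attempt=2, answers=(0, 1, 3)),   # L1 = 5
        make_response(video="v3", answers=(1, 1, 1)),              # unpaired
    ]
    assert ct.compute_mscl1(responses) == pytest.approx(4.0)


def test_mscl1_identical_retest_is_zero(make_response):
    responses = [
        make_response(video=f"v{i}", attempt=k, answers=(1, 2, 3))
        for i in range(4) for k in (1, 2)
    ]
    assert ct.compute_mscl1(responses) == 0.0


def test_mscl1_requires_a_paired_video(make_response):
    with pytest.raises(ct.UndefinedMetricError):
        ct.compute_mscl1([make_response(video="v1"), make_response(video="v2")])


def test_mscl1_symmetric_under_attempt_swap(make_response):
    rng = np.random.default_rng(3)
    fwd, swapped = [], []
    for i in range(5):
        a1 = tuple(rng.integers(0, 4, 3))
        a2 = tuple(rng.integers(0, 4, 3))
        fwd += [make_response(video=f"v{i}", answers=a1),
                make_response(video=f"v{i}", attempt=2, answers=a2)]
        swapped += [make_response(video=f"v{i}", answers=a2),
                    make_response(video=f"v{i}", attempt=2, answers=a1)]
    assert ct.compute_mscl1(fwd) == ct.compute_mscl1(swapped)


def test_mpil1_two_and_three_videos(make_response):
    two = [
        make_response(video="v1", answers=(0, 0, 0)),
        make_response(video="v2", answers=(2, 1, 0)),  # single pair, distance 3
    ]
    assert ct.compute_mpil1(two) == pytest.approx(3.0)
    # pairwise distances 2, 4, 6 -> mean 4
    three = [
        make_response(video="v1", answers=(0, 0, 0)),
        make_response(video="v2", answers=(2, 0, 0)),
        make_response(video="v3", answers=(3, 3, 0)),
    ]
    assert ct.compute_mpil1(three) == pytest.approx(4.0)


def test_mpil1_copy_paste_is_exactly_zero(make_response):
    responses = [make_response(video=f"v{i}", answers=(1, 3, 2)) for i in range(10)]
    assert ct.compute_mpil1(responses) == 0.0


def test_mpil1_requires_two_videos(make_response):
    with pytest.raises(ct.UndefinedMetricError):
        ct.compute_mpil1([make_response(video="v1")])


@given(st.lists(answer3, min_size=2, max_size=8))
def test_mpil1_matches_explicit_pair_enumeration(vectors):
    """The pair formula equals the mean over all N(N-1)/2 unordered pairs."""
    responses = [
        ct.WorkerResponse("w", f"v{i}", 1, answers=v, t1_s=200.0)
        for i, v in enumerate(vectors)
    ]
    brute = [
        ct.l1_distance(vectors[i], vectors[j])
        for i in range(len(vectors)) for j in range(i + 1, len(vectors))
    ]
    assert ct.compute_mpil1(responses) == pytest.approx(np.mean(brute), abs=1e-12)
    # bounded by the maximal possible disagreement per pair
    assert 0.0 <= ct.compute_mpil1(responses) <= sum(L - 1 for L in CFG3.levels)


def test_rmscl1_mean_over_warned_revised_videos(make_response):
    responses = [
        make_response(video="v1", answers=(0, 0, 0), t1=60, warned=True,
                      revised=(1, 0, 0), t2=30),              # distance 1
        make_response(video="v2", answers=(0, 0, 0), t1=60, warned=True,
                      revised=(2, 0, 0), t2=30),              # distance 2
        make_response(video="v3", answers=(0, 0, 0), t1=60, warned=True,
                      revised=(3, 3, 0), t2=30),              # distance 6
        make_response(video="v4", answers=(0, 0, 0), t1=200),  # never warned
    ]
    assert ct.compute_rmscl1(responses) == pytest.approx(3.0)


def test_rmscl1_undefined_without_revisions(make_response):
    with pytest.raises(ct.UndefinedMetricError):
        ct.compute_rmscl1([make_response(video="v1", t1=60, warned=True)])


def test_pt_baseline_for_never_warned_worker(make_response):
    cfg = ct.StudyConfig(min_videos_metrics=2)
    responses = [
        make_response(video=f"v{i}", answers=(0,) * 13, t1=130.0 + i) for i in range(10)
    ]
    assert ct.compute_pt(responses, cfg) == 13.0


def test_pt_warned_worker_hand_computation(make_response):
    cfg = ct.StudyConfig(M=3, levels=(4,) * 3, min_videos_metrics=2, c=1.0)
    responses = [
        make_response(video="v1", answers=(0, 0, 0), t1=60.0, warned=True,
                      revised=(2, 0, 0), t2=30.0)  # RMSCL1 = 2
    ]
    # (60 + 30)/1 + 1.0 * 2 = 92
    assert ct.compute_pt(responses, cfg) == pytest.approx(92.0)
    # with c = 0 the revision term vanishes
    assert ct.compute_pt(responses, cfg, c=1e-12) == pytest.approx(90.0, abs=1e-9)


def test_pt_time_term_scales_with_time_revision_term_does_not(make_response):
    cfg = ct.StudyConfig(M=3, levels=(4,) * 3, min_videos_metrics=2, c=2.0)
    base = [
        make_response(video="v1", answers=(0, 0, 0), t1=50.0, warned=True,
                      revised=(1, 1, 0), t2=25.0),
        make_response(video="v2", answers=(0, 0, 0), t1=140.0),
    ]
    k = 0.5  # times halved but still under threshold on the warned video
    scaled = [
        make_response(video="v1", answers=(0, 0, 0), t1=25.0, warned=True,
                      revised=(1, 1, 0), t2=12.5),
        make_response(video="v2", answers=(0, 0, 0), t1=70.0),
    ]
    b0, s0 = ct.pt_components(base, cfg)
    b1, s1 = ct.pt_components(scaled, cfg)
    assert b1 == pytest.approx(k * b0)
    assert s1 == s0


def test_pt_undefined_for_warned_worker_without_revisions(make_response):
    cfg = ct.StudyConfig(M=3, levels=(4,) * 3, min_videos_metrics=2)
    with pytest.raises(ct.UndefinedMetricError):
        ct.compute_pt([make_response(video="v1", answers=(0, 0, 0), t1=60, warned=True)], cfg)


def test_mean_time_and_pilot_rescaling(make_response):
    responses = [
        make_response(video="v1", t1=100.0),
        make_response(video="v2", t1=140.0),
        make_response(video="v1", attempt=2, t1=999.0),  # attempt 2 excluded
    ]
    assert ct.compute_mean_time(responses) == pytest.approx(120.0)
    assert ct.compute_mean_time([make_response(t1=557.7)]) == pytest.approx(557.7)
    assert round(ct.rescale_mean_time(557.7, 31, 13), 1) == 233.9


def test_compute_all_metrics_eligibility_and_absences(make_response, scored, default_study):
    cfg = ct.StudyConfig(min_videos_metrics=10)
    # 9 videos -> excluded; 10 videos without retest -> reported, mscl1 absent
    responses = [
        make_response(worker="small", video=f"v{i}", answers=(0,) * 13, t1=130)
        for i in range(9)
    ] + [
        make_response(worker="big", video=f"v{i}", answers=(i % 4,) * 13, t1=130)
        for i in range(10)
    ]
    videos = {f"v{i}": ct.AUTISM for i in range(10)}
    pcc_df = ct.score_responses(responses, videos, ct.ClassifierSpec((0.0,) * 13, 0.0))
    metrics, report = ct.compute_all_metrics(responses, pcc_df, cfg)
    assert report["excluded"] == {"small": 9}
    (m,) = metrics
    assert m.worker_id == "big"
    assert m.mscl1 is None and m.rmscl1 is None and m.n_retest == 0
    assert m.mpil1 is not None and m.pt == 13.0 and m.mean_time_s == 130.0


def test_metrics_invariant_under_video_order_permutation(default_study, scored):
    """Shuffling response order never changes any worker's metrics."""
    rng = np.random.default_rng(0)
    shuffled = list(default_study.responses)
    rng.shuffle(shuffled)
    a, _ = ct.compute_all_metrics(default_study.responses, scored, default_study.study_config)
    b, _ = ct.compute_all_metrics(shuffled, scored, default_study.study_config)
    assert len(a) == len(b)
    for ma, mb in zip(a, b):
        assert ma.worker_id == mb.worker_id
        assert (ma.n_videos, ma.n_retest, ma.n_warned, ma.n_revised) == (
            mb.n_videos, mb.n_retest, mb.n_warned, mb.n_revised
        )
        for fa, fb in [(ma.mscl1, mb.mscl1), (ma.mpil1, mb.mpil1),
                       (ma.pt, mb.pt), (ma.rmscl1, mb.rmscl1),
                       (ma.mean_time_s, mb.mean_time_s), (ma.mean_pcc, mb.mean_pcc)]:
            if fa is None:
                assert fb is None
            else:
                # summation order may differ; agreement to floating-point level
                assert fb == pytest.approx(fa, rel=1e-12)
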