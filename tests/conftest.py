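import pytest
from hypothesis import HealthCheck, settings

import crowdtrust as ct

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_study() -> ct.SimulatedStudy:
    """A coupled-mode synthetic study at the default cohort size."""
    return ct.simulate_study(ct.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def scored(default_study):
    """Per-response PCC table for the default study."""
    return ct.score_responses(
        default_study.responses, default_study.videos, default_study.classifier
    )


@pytest.fixture(scope="session")
def metric_table(default_study, scored):
    """Worker-metric DataFrame for the default study."""
    worker_metrics, _ = ct.compute_all_metrics(
        default_study.responses, scored, default_study.study_config
    )
    return ct.metrics_frame(worker_metrics)


@pytest.fixture
def make_response():
    """Factory for hand-built WorkerResponse records with sane defaults."""

    def _make(
        worker="w1",
        video="v1",
        attempt=1,
        answers=(0,) * 13,
        t1=200.0,
        warned=False,
        revised=None,
        t2=None,
    ) -> ct.WorkerResponse:
        return ct.WorkerResponse(
            worker_id=worker,
            video_id=video,
            attempt=attempt,
            answers=tuple(answers),
            t1_s=t1,
            warned=warned,
            revised_answers=tuple(revised) if revised is not None else None,
            t2_s=t2,
        )

    return _make
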