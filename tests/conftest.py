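import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_suite():
    """The default generated case suite (10 cases x 14 days, GMI 6-9)."""
    import time

    from cgmkit.simulate import generate_suite

    t0 = time.perf_counter()
    suite = generate_suite()
    elapsed = time.perf_counter() - t0
    return suite, elapsed


@pytest.fixture(scope="session")
def suite_reports(default_suite):
    from cgmkit.metrics import metric_report

    suite, _ = default_suite
    return [(config, series, metric_report(series)) for config, series in suite]
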