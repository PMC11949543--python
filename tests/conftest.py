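import numpy as np
import pytest

from statedyn.synthetic import SynthStudyParams, simulate_study


def small_params(seed: int = 11, **overrides) -> SynthStudyParams:
    """A scaled-down study (16 nodes, short runs) that keeps the default
    statistical structure but runs in seconds."""
    base = dict(
        n_nodes=16,
        n_meditation_runs=10,
        n_control_runs=3,
        run_length_trs=120,
        control_length_trs=120,
        stage_plan=[(s, 15) for s in
                    ("AC", "J1", "J2", "J3", "J4", "J5", "J6-8", "afterglow")],
        seed=seed,
    )
    base.update(overrides)
    return SynthStudyParams(**base)


@pytest.fixture(scope="session")
def small_study():
    return simulate_study(small_params())


@pytest.fixture(scope="session")
def small_analysis(small_study):
    """Windows + fitted 3-state model + sequences for the small study."""
    from statedyn import clustering, windows

    taper = windows.make_taper()
    series = [windows.windowed_connectivity(tc, taper) for tc in small_study.runs]
    pooled, prov = clustering.pool_windows(series)
    runs_by_id = {tc.run_id: tc for tc in small_study.runs}
    model, seqs = clustering.fit_states(
        pooled, prov, 3, seed=0, n_replicates=10, runs_by_id=runs_by_id
    )
    return {
        "taper": taper,
        "series": series,
        "pooled": pooled,
        "provenance": prov,
        "model": model,
        "sequences": seqs,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
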