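import numpy as np
import pytest

import thermowrist as tw


@pytest.fixture(scope="session")
def small_cohort():
    """4 participants, default signatures, full-length segments."""
    return tw.generate_cohort(tw.default_config(n_participants=4, seed=11))


@pytest.fixture(scope="session")
def small_scaled(small_cohort):
    return tw.z_scale(small_cohort)


@pytest.fixture()
def make_segment():
    """Hand-built segment factory with explicit channel values."""

    def _make(
        values,
        label="nose",
        participant_id="P0",
        segment_id="s0",
        on_target=None,
    ):
        values = np.asarray(values, dtype=float)
        n = values.shape[0]
        if on_target is None:
            on_target = np.ones(n, dtype=bool) if label != tw.OFF_BODY else np.zeros(n, dtype=bool)
        return tw.Segment(
            participant_id=participant_id,
            segment_id=segment_id,
            label=label,
            t=np.arange(n, dtype=float) * 0.2,
            values=values,
            on_target=on_target,
        )

    return _make
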