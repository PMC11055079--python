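import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def indoor_frame():
    """Four days of clean indoor barn data."""
    from timetector.simulate import SimConfig, generate_barn_series

    return generate_barn_series(SimConfig(profile="indoor", n_days=4, seed=3))


@pytest.fixture(scope="session")
def tiny_trained():
    """A default-architecture model trained briefly on two days of data.

    Session-scoped: several detection/model tests reuse it.  Returns
    (model, feedback, train_ds, val_ds, scaler, scaled val frame).
    """
    from timetector.model import TTTBAD, TTTBADConfig, train
    from timetector.preprocess import (
        apply_scaler,
        chronological_split,
        fit_scaler,
        make_windows,
        with_corruption,
    )
    from timetector.simulate import SimConfig, generate_barn_series

    frame = generate_barn_series(SimConfig(profile="indoor", n_days=2, seed=11))
    train_f, val_f, _ = chronological_split(frame)
    scaler = fit_scaler(train_f)
    train_ds = with_corruption(make_windows(apply_scaler(train_f, scaler), split="train"), 0.1, 5)
    val_s = apply_scaler(val_f, scaler)
    val_ds = with_corruption(make_windows(val_s, split="val"), 0.1, 6)
    cfg = TTTBADConfig(features=5, max_epochs=3, seed=1)
    model, feedback = train(TTTBAD(cfg), train_ds, val_ds)
    return model, feedback, train_ds, val_ds, scaler, val_s


def rng(seed=0) -> np.random.Generator:
    return np.random.default_rng(seed)
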