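import numpy as np
import pytest

from popmodes import (
    Correctness,
    GeneratorConfig,
    InstructedType,
    Response,
    Trial,
    TrialAlignedSession,
    Unit,
    generate_session,
)


def make_units(n: int) -> list[Unit]:
    return [
        Unit(
            unit_id=f"u{i:03d}",
            mouse_id="m0",
            session_id="s0",
            depth_um=100.0 + 10.0 * i,
            spike_width_ms=0.6,
        )
        for i in range(n)
    ]


_COND_META = {
    "CR": (InstructedType.LICK_RIGHT, Response.RIGHT, Correctness.CORRECT),
    "CL": (InstructedType.LICK_LEFT, Response.LEFT, Correctness.CORRECT),
    "ER": (InstructedType.LICK_RIGHT, Response.LEFT, Correctness.ERROR),
    "EL": (InstructedType.LICK_LEFT, Response.RIGHT, Correctness.ERROR),
    "ignore": (InstructedType.LICK_RIGHT, Response.NONE, Correctness.IGNORE),
}


def make_rate_session(
    rate_fn,
    n_units: int,
    n_trials: dict[str, int],
    delay: float = 1.3,
    seed: int = 0,
    dt: float = 0.005,
) -> TrialAlignedSession:
    """Session with Poisson spikes from rate_fn(unit_index, condition, t)."""
    rng = np.random.default_rng(seed)
    units = make_units(n_units)
    t_lo, t_hi = -(0.5 + 1.3 + delay), 1.3
    t = np.arange(t_lo, t_hi, dt) + dt / 2
    trials, spikes = [], {}
    tid = 0
    for cond, n in n_trials.items():
        inst, resp, corr = _COND_META[cond]
        lam = np.stack([np.broadcast_to(rate_fn(i, cond, t), t.shape) for i in range(n_units)])
        for _ in range(n):
            counts = rng.poisson(np.maximum(lam, 0) * dt)
            rt = 150.0 if corr in (Correctness.CORRECT, Correctness.ERROR) else None
            trials.append(
                Trial(
                    trial_id=tid,
                    instructed_type=inst,
                    response=resp,
                    correctness=corr,
                    sample_start_s=-(1.3 + delay),
                    delay_start_s=-delay,
                    reaction_time_ms=rt,
                )
            )
            for i, u in enumerate(units):
                nz = np.nonzero(counts[i])[0]
                if nz.size:
                    st = np.repeat(t[nz] - dt / 2, counts[i][nz]) + rng.random(
                        counts[i][nz].sum()
                    ) * dt
                    spikes[(u.unit_id, tid)] = np.sort(st)
            tid += 1
    return TrialAlignedSession(
        units=units, trials=trials, spikes=spikes, delay_duration_s=delay
    )


@pytest.fixture(scope="session")
def clustered_session():
    """Default clustered-regime synthetic session with ground truth."""
    cfg = GeneratorConfig(n_units=80, seed=11)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def mixed_session():
    cfg = GeneratorConfig(n_units=80, mixing_regime="random_mixed", seed=12)
    return generate_session(cfg)
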