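import numpy as np
import pytest

from popmodes import (
    GeneratorConfig,
    ModeSet,
    PSTHMatrix,
    condition_averages,
    define_modes,
    generate_session,
    orthogonalize,
    project,
    selectivity_correlation_map,
    selectivity_vectors,
    split_trials,
    synthesize_mixture_population,
    variance_captured,
)
from popmodes.modes import MODE_ORDER
from conftest import make_rate_session


# ---------------------------------------------------------------------------
# selectivity algebra
# ---------------------------------------------------------------------------

def test_stimulus_only_coding_zeroes_choice_and_outcome():
    rng = np.random.default_rng(0)
    CR = rng.random((5, 3))
    CL = rng.random((5, 3))
    sel = selectivity_vectors({"CR": CR, "ER": CR, "CL": CL, "EL": CL})
    np.testing.assert_allclose(sel.choice, 0.0, atol=1e-12)
    np.testing.assert_allclose(sel.outcome, 0.0, atol=1e-12)


def test_choice_only_coding_zeroes_stimulus():
    rng = np.random.default_rng(1)
    R = rng.random((5, 3))  # lick-right activity
    L = rng.random((5, 3))
    sel = selectivity_vectors({"CR": R, "EL": R, "CL": L, "ER": L})
    np.testing.assert_allclose(sel.stimulus, 0.0, atol=1e-12)


def test_selectivity_hand_arithmetic():
    """Frozen hand computation from the defining formulas."""
    avgs = {
        "CR": np.array([2.0, 0.0]),
        "CL": np.array([0.0, 2.0]),
        "ER": np.array([1.0, 1.0]),
        "EL": np.array([1.0, 1.0]),
    }
    sel = selectivity_vectors(avgs)
    np.testing.assert_allclose(sel.stimulus, [1.0, -1.0])
    np.testing.assert_allclose(sel.choice, [1.0, -1.0])
    np.testing.assert_allclose(sel.outcome, [0.0, 0.0])


def test_selectivity_correlation_map_constant_and_splithalf():
    rng = np.random.default_rng(2)
    v = rng.standard_normal(20)
    sel = np.tile(v[:, None], (1, 15))
    C = selectivity_correlation_map(sel)
    np.testing.assert_allclose(C, 1.0, atol=1e-9)
    # noiseless split halves -> diagonal exactly 1
    C2 = selectivity_correlation_map(sel, sel_split=(sel, sel))
    np.testing.assert_allclose(np.diag(C2), 1.0, atol=1e-9)


def test_condition_averages_constant_rate():
    session = make_rate_session(
        lambda i, c, t: 10.0, 2, {"CR": 150, "CL": 150, "ER": 40, "EL": 40}, seed=3
    )
    avgs = condition_averages(session, session.unit_ids, step_ms=20.0)
    for cond in ("CR", "CL", "ER", "EL"):
        interior = (avgs.time_s > avgs.time_s[0] + 0.1)
        n_tr = len(avgs.trial_ids[cond])
        se = np.sqrt(10.0 / (0.1 * n_tr))  # Poisson SE of a 100-ms window mean
        assert np.abs(avgs[cond][:, interior] - 10.0).mean() < se


# ---------------------------------------------------------------------------
# mode definition & orthogonalization
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def planted_modes_session():
    cfg = GeneratorConfig(
        n_units=90,
        n_prototypes=7,
        gain_sd=0.0,
        n_trials_per_condition={"CR": 50, "CL": 50, "ER": 16, "EL": 16},
        seed=17,
    )
    return generate_session(cfg)


def test_mode_recovery_against_planted_weights(planted_modes_session):
    session, truth = planted_modes_session
    definition, _ = split_trials(session, seed=0)
    modeset = define_modes(session, session.unit_ids, definition)
    for j, name in enumerate(MODE_ORDER):
        w_true = truth.true_mode_weights[:, j]
        if np.linalg.norm(w_true) == 0:
            continue
        w_true = w_true / np.linalg.norm(w_true)
        cos = abs(float(modeset.mode(name) @ w_true))
        assert cos >= 0.7, f"{name}: |cos|={cos:.2f}"


def test_orthogonalize_gram_identity(planted_modes_session):
    session, _ = planted_modes_session
    definition, _ = split_trials(session, seed=0)
    ortho = orthogonalize(define_modes(session, session.unit_ids, definition))
    np.testing.assert_allclose(ortho.gram, np.eye(7), atol=1e-9)


def test_orthogonalize_random_modes_high_dim():
    rng = np.random.default_rng(4)
    W = rng.standard_normal((50, 7))
    ms = ModeSet(weights=W, unit_ids=[f"u{i}" for i in range(50)],
                 orthogonalized=False, definition_trial_ids={})
    out = orthogonalize(ms)
    np.testing.assert_allclose(out.gram, np.eye(7), atol=1e-9)


def test_orthogonalize_preserves_already_orthogonal_directions():
    Q, _ = np.linalg.qr(np.random.default_rng(5).standard_normal((30, 7)))
    ms = ModeSet(weights=Q, unit_ids=[f"u{i}" for i in range(30)],
                 orthogonalized=False, definition_trial_ids={})
    out = orthogonalize(ms)
    np.testing.assert_allclose(np.abs(np.sum(out.weights * Q, axis=0)), 1.0, atol=1e-9)


def test_orthogonalize_rejects_collinear_modes():
    rng = np.random.default_rng(6)
    W = rng.standard_normal((20, 7))
    W[:, 3] = 2.0 * W[:, 1]
    ms = ModeSet(weights=W, unit_ids=[f"u{i}" for i in range(20)],
                 orthogonalized=False, definition_trial_ids={})
    with pytest.raises(ValueError, match="collinear"):
        orthogonalize(ms)


def test_define_modes_requires_error_trials(planted_modes_session):
    session, _ = planted_modes_session
    definition, _ = split_trials(session, seed=0)
    definition["ER"] = []
    with pytest.raises(ValueError, match="stimulus, choice and outcome"):
        define_modes(session, session.unit_ids, definition)


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------

def test_projection_zero_mode_gives_zero(planted_modes_session):
    session, _ = planted_modes_session
    n = len(session.unit_ids)
    W = np.zeros((n, 7))
    W[:, 0] = 0.0
    ms = ModeSet(weights=W, unit_ids=session.unit_ids, orthogonalized=False,
                 definition_trial_ids={})
    prj = project(ms, session, {"CR": session.trials_of("CR")[:5]}, bootstrap_n=10)
    np.testing.assert_allclose(prj.values["stimulus"]["CR"], 0.0, atol=1e-12)


def test_defining_contrast_projects_positively(planted_modes_session):
    """The action mode is CR - CL after the go cue, so the CR-CL projection
    difference in its defining window is positive by construction."""
    session, _ = planted_modes_session
    definition, projection = split_trials(session, seed=0)
    modeset = define_modes(session, session.unit_ids, definition)
    prj = project(
        modeset, session,
        {"CR": projection["CR"], "CL": projection["CL"]},
        bootstrap_n=0,
    )
    win = (prj.time_s >= 0.1) & (prj.time_s < 0.3)
    diff = prj.values["action"]["CR"][win].mean() - prj.values["action"]["CL"][win].mean()
    assert diff > 0


def test_bootstrap_relative_se_shrinks_with_population_size():
    rng = np.random.default_rng(7)
    rel = {}
    for n in (50, 200):
        session = make_rate_session(
            lambda i, c, t: 8.0 + 2 * (i % 3), n, {"CR": 10}, seed=100 + n
        )
        W = np.zeros((n, 7))
        W[:, 0] = 1.0 / np.sqrt(n)
        ms = ModeSet(weights=W, unit_ids=session.unit_ids, orthogonalized=False,
                     definition_trial_ids={})
        prj = project(ms, session, {"CR": session.trials}, bootstrap_n=400, seed=1)
        v = prj.values["stimulus"]["CR"].mean()
        s = prj.se["stimulus"]["CR"].mean()
        rel[n] = s / v
    ratio = rel[50] / rel[200]
    assert 1.4 < ratio < 2.9  # ~ sqrt(200/50) = 2


# ---------------------------------------------------------------------------
# variance captured
# ---------------------------------------------------------------------------

def _orthonormal_modeset(n, rng):
    Q, _ = np.linalg.qr(rng.standard_normal((n, 7)))
    return ModeSet(weights=Q, unit_ids=[f"u{i}" for i in range(n)],
                   orthogonalized=True, definition_trial_ids={})


def test_variance_captured_inside_and_outside_subspace():
    rng = np.random.default_rng(8)
    ms = _orthonormal_modeset(40, rng)
    inside = ms.weights @ rng.standard_normal((7, 100))
    assert variance_captured(ms, inside)["activity"] == pytest.approx(1.0, abs=1e-9)
    # activity orthogonal to every mode
    x = rng.standard_normal((40, 100))
    outside = x - ms.weights @ (ms.weights.T @ x)
    assert variance_captured(ms, outside)["activity"] == pytest.approx(0.0, abs=1e-9)


def test_variance_captured_full_basis_is_one():
    rng = np.random.default_rng(9)
    data = rng.standard_normal((7, 60))  # rank-7 population of 7 neurons
    ms = ModeSet(weights=np.eye(7), unit_ids=[f"u{i}" for i in range(7)],
                 orthogonalized=True, definition_trial_ids={})
    out = variance_captured(ms, data, selectivity={"stimulus": data[:, :20]})
    assert out["activity"] == pytest.approx(1.0, abs=1e-6)
    assert out["stimulus"] == pytest.approx(1.0, abs=1e-6)


# ---------------------------------------------------------------------------
# random-mixture population
# ---------------------------------------------------------------------------

def test_mixture_population_preserves_component_energy():
    rng = np.random.default_rng(10)
    n, T = 2000, 150
    rows = rng.standard_normal((n, 10)) @ rng.standard_normal((10, T))
    rows /= np.linalg.norm(rows, axis=1, keepdims=True)
    mat = PSTHMatrix(matrix=rows, unit_ids=[f"u{i}" for i in range(n)],
                     time_s=np.arange(T // 2) * 0.01 - 3.1, conditions=("CR", "CL"),
                     delay_duration_s=1.3, dt_s=0.01)
    ms = ModeSet(weights=np.linalg.qr(rng.standard_normal((n, 7)))[0],
                 unit_ids=mat.unit_ids, orthogonalized=True, definition_trial_ids={})
    mix = synthesize_mixture_population(ms, mat, seed=0)
    # per-component energy preserved: recover the time courses and compare
    rec = np.linalg.lstsq(mix.all_weights, mix.rows, rcond=None)[0]
    energy = np.sum(rec**2, axis=1)
    ratio = energy / mix.component_energy
    assert np.all(np.abs(ratio - 1.0) < 0.05)


def test_mixture_population_preserves_population_projections():
    # data with well-separated (orthogonal) component time courses of distinct
    # energies, so the matched-filter projection isolates each component
    rng = np.random.default_rng(11)
    n, T = 400, 120
    Q, _ = np.linalg.qr(rng.standard_normal((T, 8)))
    energies = np.linspace(3.0, 0.5, 8)
    rows = rng.standard_normal((n, 8)) @ (energies[:, None] * Q.T)
    rows /= np.linalg.norm(rows, axis=1, keepdims=True)
    mat = PSTHMatrix(matrix=rows, unit_ids=[f"u{i}" for i in range(n)],
                     time_s=np.arange(T // 2) * 0.01 - 3.1, conditions=("CR", "CL"),
                     delay_duration_s=1.3, dt_s=0.01)
    ms = ModeSet(weights=np.linalg.qr(rng.standard_normal((n, 7)))[0],
                 unit_ids=mat.unit_ids, orthogonalized=True, definition_trial_ids={})
    mix = synthesize_mixture_population(ms, mat, seed=1)
    A = mix.component_timecourses
    # synthetic rows lie in the span of the original component time courses
    rec, res, *_ = np.linalg.lstsq(mix.all_weights, mix.rows, rcond=None)
    resid = mix.rows - mix.all_weights @ rec
    assert np.linalg.norm(resid) < 1e-8 * np.linalg.norm(mix.rows)
    # and each mode component re-enters with its original population r.m.s.
    for c in range(7):
        rms_ratio = np.sqrt(np.sum(rec[c] ** 2) / np.sum(A[c] ** 2))
        assert abs(rms_ratio - 1.0) < 0.1
    # total population energy preserved within sampling fluctuation
    assert np.sum(mix.rows**2) == pytest.approx(np.sum(mat.matrix**2), rel=0.15)


# ---------------------------------------------------------------------------
# session pooling & alignment
# ---------------------------------------------------------------------------

def test_session_offset_pooling_superimposes_offset_sessions():
    """Two sessions with the same signal but different baseline offsets pool
    onto superimposing traces after per-session offset removal; a single
    session equals its plain projection minus a constant."""
    from popmodes import session_offset_project

    def make(offset, seed):
        rate = lambda i, c, t: offset + 10.0 * (t > 0)
        return make_rate_session(rate, 12, {"CR": 30, "CL": 30}, seed=seed)

    entries = []
    for offset, seed in ((4.0, 0), (10.0, 1)):
        s = make(offset, seed)
        n = len(s.unit_ids)
        W = np.zeros((n, 7))
        W[:, 6] = 1.0 / np.sqrt(n)  # uniform "response" direction
        ms = ModeSet(weights=W, unit_ids=s.unit_ids, orthogonalized=True,
                     definition_trial_ids={})
        cr, cl = s.trials_of("CR"), s.trials_of("CL")
        defs = {"CR": cr[: len(cr) // 2], "CL": cl[: len(cl) // 2]}
        projs = {"CR": cr[len(cr) // 2 :], "CL": cl[len(cl) // 2 :]}
        entries.append((s, ms, defs, projs))

    pooled = session_offset_project(entries, min_units=10, min_trials=10)
    # single-session pooled result = plain projection minus its offset
    from popmodes import project
    single = session_offset_project(entries[:1], min_units=10, min_trials=10)
    plain = project(entries[0][1], entries[0][0], entries[0][3], bootstrap_n=0)
    diff = plain.values["response"]["CR"] - single.values["response"]["CR"]
    assert np.ptp(diff) < 1e-9  # constant shift only
    # sessions with different offsets superimpose after offset removal:
    # compare each session's own offset-corrected trace to the pooled mean
    per = []
    for e in (entries[0], entries[1]):
        p = session_offset_project([e], min_units=10, min_trials=10)
        per.append(p.values["response"]["CR"])
    resid = np.abs(per[0] - per[1]).mean()
    uncorrected = abs(
        project(entries[0][1], entries[0][0], entries[0][3], bootstrap_n=0)
        .values["response"]["CR"].mean()
        - project(entries[1][1], entries[1][0], entries[1][3], bootstrap_n=0)
        .values["response"]["CR"].mean()
    )
    assert resid < 0.25 * uncorrected  # offsets removed down to noise level
    assert pooled.values["response"]["CR"].shape == per[0].shape


def test_first_lick_alignment_shifts_response():
    """Aligning to the first lick moves a go-locked response earlier by the
    reaction time."""
    from dataclasses import replace as dc_replace
    from popmodes import project

    rate = lambda i, c, t: 2.0 + 30.0 * ((t > 0.2) & (t < 0.5))
    session = make_rate_session(rate, 10, {"CR": 60}, seed=9)
    session.trials = [dc_replace(t, reaction_time_ms=200.0) for t in session.trials]
    session.validate()
    n = 10
    W = np.zeros((n, 7)); W[:, 6] = 1.0 / np.sqrt(n)
    ms = ModeSet(weights=W, unit_ids=session.unit_ids, orthogonalized=True,
                 definition_trial_ids={})
    go = project(ms, session, {"CR": session.trials}, bootstrap_n=0, align="go")
    lick = project(ms, session, {"CR": session.trials}, bootstrap_n=0, align="first_lick")
    t_go = go.time_s[np.argmax(go.values["response"]["CR"] > go.values["response"]["CR"].max() / 2)]
    t_lick = lick.time_s[np.argmax(lick.values["response"]["CR"] > lick.values["response"]["CR"].max() / 2)]
    assert t_go - t_lick == pytest.approx(0.2, abs=0.05)
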