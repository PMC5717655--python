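"""Developmental driver: determinism, trace analyses, emergent contrasts."""

import numpy as np
import pandas as pd
import pytest

from huddlesim import (
    AssociationMatrix,
    LitterPartition,
    SimulationConfig,
    delta_update,
    detect_divergence_day,
    huddling_drive,
    mc_step,
    mean_group_size,
    run_development,
    steady_state_rho,
)
from huddlesim.simulate import compare_conditions


def small_config(**kw):
    base = dict(day_end=15, iters_per_day=100, replicates=3, seed=7)
    base.update(kw)
    return SimulationConfig(**base)


# -- configuration contract ------------------------------------------

@pytest.mark.parametrize(
    "kw",
    [
        dict(condition="osmotic"),
        dict(iters_per_day=0),
        dict(replicates=0),
        dict(day_start=5, day_end=3),
        dict(estimator="mode"),
    ],
)
def test_invalid_configuration_rejected(kw):
    with pytest.raises(ValueError):
        SimulationConfig(**kw)


def test_day_grid_is_inclusive():
    cfg = SimulationConfig(day_start=0, day_end=60)
    assert len(cfg.days) == 61


# -- determinism and reference equivalence ---------------------------

@pytest.mark.parametrize("condition", ["control", "learning"])
def test_same_seed_reproduces_bitwise(condition):
    cfg = small_config(condition=condition)
    r1 = run_development(cfg)
    r2 = run_development(cfg)
    assert np.array_equal(r1.group_size, r2.group_size)
    assert np.array_equal(r1.rho, r2.rho)
    if condition == "learning":
        assert np.array_equal(r1.alpha_history, r2.alpha_history)


@pytest.mark.parametrize("condition", ["control", "learning"])
def test_fast_loop_matches_stepwise_reference(condition):
    """The production inner loop must equal composing the elementary ops.

    Replays the identical random stream through mc_step + delta_update
    and demands bit-for-bit agreement of every statistic.
    """
    cfg = small_config(condition=condition, day_end=8, iters_per_day=60,
                       replicates=2)
    res = run_development(cfg)
    consts = cfg.constants
    n = consts.n
    learning = condition == "learning"
    for rep, stream in enumerate(np.random.SeedSequence(cfg.seed).spawn(cfg.replicates)):
        rng = np.random.default_rng(stream)
        part = LitterPartition.single_group(n)
        alpha = (
            AssociationMatrix.full(n, cfg.alpha_init)
            if learning
            else AssociationMatrix.ones(n)
        )
        for d_idx, day in enumerate(cfg.days):
            base = huddling_drive(float(day), consts)
            gs_acc = rho_acc = 0.0
            for _ in range(cfg.iters_per_day):
                part, rec = mc_step(
                    part, lambda a, b: alpha.alpha[b, a] * base, rng, inplace=True
                )
                if learning:
                    delta_update(alpha, rec.a, rec.b, 1 if rec.joined else 0, consts)
                gs_acc += mean_group_size(part, cfg.estimator)
                rho_acc += rec.rho
            assert res.group_size[rep, d_idx] == gs_acc / cfg.iters_per_day
            assert res.rho[rep, d_idx] == rho_acc / cfg.iters_per_day
            if learning:
                assert np.array_equal(res.alpha_history[rep, d_idx], alpha.alpha)


def test_disabled_learning_reproduces_control():
    """gamma = 0 with unit associations is the control condition exactly."""
    control = run_development(small_config(condition="control"))
    frozen = small_config(
        condition="learning",
        alpha_init=1.0,
        constants=small_config().constants.with_(gamma=0.0),
    )
    res = run_development(frozen)
    assert np.array_equal(res.group_size, control.group_size)
    assert np.array_equal(res.rho, control.rho)


# -- initial condition and daily statistics --------------------------

def test_litter_starts_as_a_single_huddle():
    """Day-0 statistics reflect relaxation from one group of n=7."""
    cfg = SimulationConfig(day_end=0, iters_per_day=1, replicates=300, seed=0)
    res = run_development(cfg)
    first = res.group_size[:, 0]
    # after one encounter the litter is either still whole (gs 7, prob
    # rho(0.6) ~ 0.65) or has shed one pup (gs 3.5)
    assert set(np.round(first, 6)) <= {7.0, 3.5}
    assert 5.0 < first.mean() < 7.0


def test_stats_frame_schema_and_bounds(dev_runs):
    control, learning = dev_runs
    n = control.config.constants.n
    for res in dev_runs:
        stats = res.stats
        assert list(stats.columns) == [
            "day", "condition", "mean_group_size", "sd", "mean_rho",
        ]
        assert ((stats.mean_group_size >= 1) & (stats.mean_group_size <= n)).all()
        assert ((stats.mean_rho > 0) & (stats.mean_rho < 1)).all()
    assert (control.stats.condition == "control").all()
    assert (learning.stats.condition == "learning").all()


def test_csv_round_trip(dev_runs, tmp_path):
    control, _ = dev_runs
    path = tmp_path / "stats.csv"
    control.to_csv(path)
    back = pd.read_csv(path)
    pd.testing.assert_frame_equal(back, control.stats, check_exact=False)


def test_summary_mentions_key_settings(dev_runs):
    control, _ = dev_runs
    text = control.summary()
    assert "control" in text
    assert "seed: 1" in text


# -- trace analyses ---------------------------------------------------

def _trace(days, values):
    return pd.DataFrame(
        {"day": days, "mean_group_size": values, "mean_rho": 0.5}
    )


def test_identical_traces_have_no_divergence():
    days = np.arange(61)
    t = _trace(days, np.full(61, 3.0))
    assert detect_divergence_day(t, t) is None


def test_step_divergence_found_at_the_step():
    days = np.arange(61)
    control = _trace(days, np.full(61, 3.0))
    learning_vals = np.full(61, 3.0)
    learning_vals[days >= 20] += 1.0
    assert detect_divergence_day(control, _trace(days, learning_vals)) == 20


def test_brief_crossing_is_ignored_by_persistence():
    days = np.arange(61)
    control = _trace(days, np.full(61, 3.0))
    vals = np.full(61, 3.0)
    vals[10:12] += 1.0  # two-day blip
    vals[30:] += 1.0  # persistent excess
    assert detect_divergence_day(control, _trace(days, vals), persistence=5) == 30


def test_divergence_requires_matching_grids():
    t1 = _trace(np.arange(61), np.full(61, 3.0))
    t2 = _trace(np.arange(60), np.full(60, 3.0))
    with pytest.raises(ValueError):
        detect_divergence_day(t1, t2)


def test_steady_state_rho_on_constant_trace():
    t = _trace(np.arange(61), np.full(61, 3.0))
    assert steady_state_rho(t) == 0.5
    with pytest.raises(ValueError):
        steady_state_rho(t, window=(100, 120))


# -- emergent developmental contrasts --------------------------------

def test_learning_exceeds_control_late_in_development(dev_runs):
    """Learnt preferences keep late huddles larger than control huddles."""
    control, learning = dev_runs
    late = (control.stats.day >= 40) & (control.stats.day <= 60)
    c = control.stats.loc[late, "mean_group_size"].mean()
    l = learning.stats.loc[late, "mean_group_size"].mean()
    assert l > c


def test_control_group_size_follows_drive_sign(dev_runs):
    """Days with positive thermal drive sustain larger control huddles."""
    control, _ = dev_runs
    drive = huddling_drive(control.stats.day.to_numpy().astype(float))
    gs = control.stats.mean_group_size.to_numpy()
    assert gs[drive > 0].mean() > gs[drive < 0].mean()


def test_association_heterogeneity_at_high_encounter_rate(high_rate_learning):
    """Littermates end development with strong positive AND negative
    associations when encounters are frequent enough for the
    behaviour-learning loop to amplify early differences."""
    res = high_rate_learning
    n = res.config.constants.n
    off = ~np.eye(n, dtype=bool)
    both_signs = 0
    for rep in range(res.config.replicates):
        final = res.alpha_history[rep, -1][off]
        both_signs += (final.min() < 0) and (final.max() > 0)
    assert both_signs >= 8


def test_alpha_snapshots_only_in_learning(dev_runs):
    control, learning = dev_runs
    assert control.alpha_history is None
    assert control.final_alpha() is None
    assert learning.alpha_history.shape == (10, 61, 7, 7)
    long = learning.alpha_long(replicate=0)
    assert list(long.columns) == ["day", "a", "b", "alpha"]
    assert len(long) == 61 * 42


def test_compare_conditions_report(dev_runs):
    control, learning = dev_runs
    report = compare_conditions(control, learning)
    assert set(report) == {
        "divergence_day", "persistence", "window",
        "steady_state_rho", "late_mean_group_size",
    }
    assert report["late_mean_group_size"]["learning"] > report[
        "late_mean_group_size"
    ]["control"]
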