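"""Session analyses: cross-correlation, z-scoring, split-half modes,
time-warping, onset-aligned projections, selectivity."""

import numpy as np
import pytest

from striatalrl.analysis import (
    NeuralSession,
    asymmetry_index,
    cross_correlation,
    cross_validated_onset_projection,
    mode_correlation_permutation_test,
    retained_inventory,
    selectivity_index,
    split_half_by_onset_parity,
    split_half_mode_correlation,
    syllable_mode_regression,
    time_warp_syllables,
    zscore_neurons,
)


def _toy_session(T=300, n=4, frame_rate=30.0, seed=0, labels=None):
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = np.repeat(np.arange(T // 10) % 3, 10)[:T]
    return NeuralSession(
        activity=rng.normal(size=(T, n)),
        pathway=np.array(["dSPN", "dSPN", "iSPN", "iSPN"]),
        syllables=np.asarray(labels),
        frame_rate=frame_rate,
    )


# -- cross-correlation -------------------------------------------------------


def test_cross_correlation_against_bruteforce(rng):
    a = rng.normal(size=2000)
    b = rng.normal(size=2000)
    b[3:] += 0.7 * a[:-3]
    xc = cross_correlation(a, b, 15)
    for i, lag in enumerate(range(-15, 16)):
        if lag >= 0:
            x, y = a[: len(a) - lag], b[lag:]
        else:
            x, y = a[-lag:], b[: len(b) + lag]
        assert xc[i] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-10)
    assert np.argmax(xc) - 15 == 3


def test_cross_correlation_identities(rng):
    a = rng.normal(size=500)
    xc = cross_correlation(a, a, 5)
    assert xc[5] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        cross_correlation(np.ones(100), a[:100], 5)
    with pytest.raises(ValueError):
        cross_correlation(a, a[:100], 5)


def test_white_noise_cross_correlation_is_null():
    rng = np.random.default_rng(123)
    T = 20_000
    xc = cross_correlation(rng.normal(size=T), rng.normal(size=T), 20)
    assert np.abs(xc).max() < 4.0 / np.sqrt(T)


def test_asymmetry_index():
    sym = np.array([0.1, 0.2, 1.0, 0.2, 0.1])
    assert asymmetry_index(sym) == 0.0
    skew = np.array([0.0, 0.1, 1.0, 0.3, 0.2])
    assert asymmetry_index(skew) == pytest.approx(0.25 - 0.05)
    with pytest.raises(ValueError):
        asymmetry_index(np.ones(4))


# -- preprocessing -----------------------------------------------------------


def test_zscore_neurons(rng):
    sess = _toy_session(seed=1)
    sess.activity[:, 2] *= 7.0
    z = zscore_neurons(sess)
    np.testing.assert_allclose(z.activity.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(z.activity.std(axis=0), 1.0, atol=1e-12)
    # idempotent up to numerics
    z2 = zscore_neurons(z)
    np.testing.assert_allclose(z2.activity, z.activity, atol=1e-10)


def test_zscore_excludes_constant_neuron():
    sess = _toy_session(seed=2)
    sess.activity[:, 1] = 3.14
    with pytest.warns(UserWarning, match="zero-variance"):
        z = zscore_neurons(sess)
    assert z.activity.shape[1] == 3
    assert list(z.pathway) == ["dSPN", "iSPN", "iSPN"]


def test_split_half_by_onset_parity():
    # onsets at frames 72 (2.4 s -> even), 78 (2.6 s -> odd), 102 (3.4 s -> odd)
    labels = np.full(150, -1)
    labels[72:78] = 0
    labels[78:102] = 1
    labels[102:120] = 0
    sess = _toy_session(T=150, labels=labels)
    even, odd = split_half_by_onset_parity(sess)
    assert [s for _, _, s in even] == [0]
    assert [(a, s) for a, _, s in odd] == [(78, 1), (102, 0)]
    # partition: no overlap, all instances covered
    assert len(even) + len(odd) == len(sess.instances())


def test_instances_and_inventory():
    labels = np.array([0, 0, 1, 1, 1, -1, -1, 0, 0, 2])
    sess = _toy_session(T=10, labels=labels)
    inst = sess.instances()
    assert inst == [(0, 2, 0), (2, 5, 1), (7, 9, 0), (9, 10, 2)]
    assert sess.instances(include_unlabeled=True)[2] == (5, 7, -1)
    assert retained_inventory(sess, min_count=2) == [0]


# -- syllable modes ----------------------------------------------------------


def test_single_syllable_mode_is_mean_change():
    labels = np.full(100, -1)
    labels[20:30] = 5
    labels[60:70] = 5
    sess = _toy_session(T=100, labels=labels, seed=3)
    modes = syllable_mode_regression(sess, sess.instances(), [5])
    expected = np.mean(
        [
            sess.activity[20:30].mean(axis=0) - sess.activity[10:20].mean(axis=0),
            sess.activity[60:70].mean(axis=0) - sess.activity[50:60].mean(axis=0),
        ],
        axis=0,
    )
    np.testing.assert_allclose(modes.modes[0], expected, atol=1e-12)


def test_missing_syllable_raises():
    sess = _toy_session(seed=4)
    with pytest.raises(ValueError, match="no instances for syllables \\[9\\]"):
        syllable_mode_regression(sess, sess.instances(), [0, 9])


def test_planted_mode_exact_recovery():
    """With transient-only structure confined to the instances and no
    noise, the regression recovers the planted modes exactly up to scale."""
    from striatalrl.synth import generate_neural_session

    # one-frame transients cannot bleed into the following instance, so the
    # per-instance mean is exactly proportional to the planted mode
    sess, truth = generate_neural_session(
        seed=8, noise_sd=0.0, ramp_amplitude=0.0, n_events=150,
        transient_frames=1,
    )
    modes = syllable_mode_regression(
        sess, sess.instances(), list(range(10)), baseline="none"
    )
    for s in range(10):
        md = modes.modes[s][modes.pathway == "dSPN"]
        cos = md @ truth.modes_dspn[s] / np.linalg.norm(md)
        assert cos > 0.999


def test_shuffled_labels_destroy_split_half_correlation(planted_session):
    sess, _ = planted_session
    obs, null, p = mode_correlation_permutation_test(
        sess, n_perm=30, rng=np.random.default_rng(5)
    )
    assert obs > 0.3
    assert np.abs(null).max() < obs
    assert p == pytest.approx(1.0 / 31.0)


# -- time warping ------------------------------------------------------------


def test_time_warp_identity_and_interpolation():
    labels = np.concatenate([np.full(10, 0), np.full(20, 1), np.full(1, 2)])
    rng = np.random.default_rng(6)
    act = rng.normal(size=(31, 2))
    sess = NeuralSession(activity=act, pathway=np.array(["dSPN", "iSPN"]),
                         syllables=labels)
    w = time_warp_syllables(sess, steps_per_syllable=10)
    assert w.activity.shape == (30, 2)
    # 10-frame instance: identity
    np.testing.assert_allclose(w.activity[:10], act[:10])
    # 20-frame instance: endpoints preserved, interior matches np.interp
    np.testing.assert_allclose(w.activity[10], act[10])
    np.testing.assert_allclose(w.activity[19], act[29])
    grid = np.linspace(0, 19, 10)
    for j in range(2):
        np.testing.assert_allclose(
            w.activity[10:20, j], np.interp(grid, np.arange(20), act[10:30, j])
        )
    # single-frame instance: constant
    np.testing.assert_allclose(w.activity[20:30], np.tile(act[30], (10, 1)))
    assert list(w.syllables[:10]) == [0] * 10


# -- onset-aligned projections ----------------------------------------------


def test_projection_invariant_to_neuron_rescaling(planted_session):
    from dataclasses import replace

    sess, _ = planted_session
    tr1 = cross_validated_onset_projection(sess, window=10)
    scale = np.linspace(0.5, 3.0, sess.activity.shape[1])
    rescaled = zscore_neurons(replace(sess, activity=sess.activity * scale))
    tr2 = cross_validated_onset_projection(rescaled, window=10)
    for key in tr1.traces:
        np.testing.assert_allclose(tr1.traces[key], tr2.traces[key], atol=1e-8)


def test_planted_onset_signatures(planted_session):
    sess, _ = planted_session
    tr = cross_validated_onset_projection(sess, window=20)
    w = 20
    assert tr.traces[("dSPN", "associated")][:w].mean() > 0
    assert tr.traces[("iSPN", "associated")][:w].mean() < 0
    assert tr.traces[("dSPN", "associated")][w:].mean() > 0
    assert tr.traces[("iSPN", "associated")][w:].mean() > 0
    # sum mode rises only after onset; difference mode leads it
    assert tr.traces[("sum", "associated")][w:].mean() > 3 * abs(
        tr.traces[("sum", "associated")][:w].mean()
    )
    assert tr.traces[("diff", "associated")][:w].mean() > 0
    # other-syllable alignments stay near zero
    peak = np.abs(tr.traces[("dSPN", "associated")]).max()
    assert np.abs(tr.traces[("dSPN", "other")]).max() < 0.3 * peak
    assert np.abs(tr.traces[("iSPN", "other")]).max() < 0.3 * peak


# -- selectivity -------------------------------------------------------------


@pytest.mark.parametrize(
    "tuning,expected",
    [
        (np.ones(7), 1.0),
        (np.eye(5)[0], 1.0 / 5.0),
        (np.array([1.0, 1.0, 0.0, 0.0]), 0.5),
        (np.zeros(4), 0.0),
    ],
)
def test_selectivity_closed_forms(tuning, expected):
    assert selectivity_index(tuning) == pytest.approx(expected)


def test_selectivity_rejects_negative():
    with pytest.raises(ValueError):
        selectivity_index(np.array([0.5, -0.1]))
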