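"""Factored HMM: state enumeration, factor stochasticity, and oracle
equivalence of the forward algorithm with exhaustive enumeration."""

from itertools import product

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fluorfit import ChannelModel, ErrorModel, parse_peptide
from fluorfit.hmm import (
    HmmState,
    build_state_space,
    emission_logpdf,
    forward_backward,
    forward_loglik,
)
from fluorfit.simulator import Read, simulate_reads

rates = st.floats(0.0, 1.0)


@pytest.fixture(scope="module")
def small_space():
    # one label at position 3 of 4 residues, 5 cycles
    return build_state_space(parse_peptide("NH2-AAK*A|"), 5)


def brute_force_state_count(label_pos: int, n_cycles: int) -> int:
    """Independent enumeration for a one-label peptide: Edman successes are
    capped at the label position, counts bounded by the labels left."""
    k_cap = min(n_cycles, label_pos)
    total = 0
    for k in range(k_cap + 1):
        remaining = 1 if label_pos > k else 0
        total += (remaining + 1) * 2  # counts 0..remaining, x blocked flag
    return total + 1  # detached


def test_state_count_one_label(small_space):
    assert small_space.n_states == brute_force_state_count(3, 5)


def test_state_count_two_label(two_label):
    space = build_state_space(two_label, 10)
    # positions 2 and 5: remaining labels 2,2,1,1,1,0 for k=0..5
    expected = sum((r + 1) * 2 for r in (2, 2, 1, 1, 1, 0)) + 1
    assert space.n_states == expected


def test_reachability_exhaustive(two_label):
    """Every enumerated state is reachable with positive probability under
    generic rates, and the factored support never leaves the state set."""
    space = build_state_space(two_label, 10)
    m = ErrorModel(0.1, [0.1], 0.1, [0.1], 0.1, 0.1)
    a = space.initial_distribution()
    for name, ch in space.initial_factor_names():
        a = a @ space.factor_matrix(name, m, ch)
    reached = a > 0
    for _ in range(space.n_cycles):
        for name, ch in space.cycle_factor_names():
            a = a @ space.factor_matrix(name, m, ch)
        reached |= a > 0
    assert reached.all()


@given(e=rates, loss=rates, det=rates, dud=rates, b=rates, c=rates)
def test_factor_rows_sum_to_one(e, loss, det, dud, b, c):
    space = build_state_space(parse_peptide("NH2-K*AK*|"), 4)
    m = ErrorModel(e, [loss], det, [dud], b, c)
    for (name, ch), F in space.all_factor_matrices(m).items():
        np.testing.assert_allclose(F.sum(axis=1), 1.0, atol=1e-12, err_msg=name)


def test_blocked_states_invariant_under_edman(two_label):
    space = build_state_space(two_label, 6)
    F = space.factor_matrix("edman", ErrorModel(0.1, [0.1], 0.0, [0.0]))
    blocked = np.flatnonzero(space.blocked)
    for i in blocked:
        assert F[i, i] == 1.0
        assert F[i].sum() == 1.0


def test_emission_logpdf_properties(channels):
    s0 = HmmState(0, (0,), False)
    s2 = HmmState(0, (2,), False)
    det = HmmState(0, (2,), False, detached=True)
    # background observation maximizes the zero-count density
    assert emission_logpdf(s0, [0.0], channels) > emission_logpdf(s0, [500.0], channels)
    # two-fluorophore mode sits at 2*mu
    assert emission_logpdf(s2, [12000.0], channels) > emission_logpdf(s2, [10000.0], channels)
    # detached emits like zero fluorophores
    assert emission_logpdf(det, [100.0], channels) == pytest.approx(
        emission_logpdf(s0, [100.0], channels)
    )


def test_emission_two_channels_sum():
    ch = ChannelModel(mu=[6000.0, 4000.0], sigma=[500.0, 400.0], bg_sigma=[300.0, 200.0])
    s = HmmState(0, (1, 2), False)
    total = emission_logpdf(s, [5800.0, 8100.0], ch)
    ch0 = ChannelModel(mu=[6000.0], sigma=[500.0], bg_sigma=[300.0])
    ch1 = ChannelModel(mu=[4000.0], sigma=[400.0], bg_sigma=[200.0])
    parts = emission_logpdf(HmmState(0, (1,), False), [5800.0], ch0) + emission_logpdf(
        HmmState(0, (2,), False), [8100.0], ch1
    )
    assert total == pytest.approx(parts, rel=1e-12)


# ---------------------------------------------------------------------------
# oracle equivalences


def _norm_logpdf(x, mean, var):
    return -0.5 * (np.log(2 * np.pi * var) + (x - mean) ** 2 / var)


def path_sum_loglik(label_pos, n_cycles, m: ErrorModel, ch: ChannelModel, obs):
    """Exhaustive enumeration over every error-event combination for a
    one-label peptide; the factored forward must match this sum."""
    e, loss, det, dud = m.edman_failure, m.dye_loss[0], m.detach, m.dud[0]
    b, c = m.initial_block, m.cyclic_block
    total = 0.0
    bools = (False, True)
    cycle_events = list(product(bools, repeat=4))  # detach, loss, block, edman-fail
    for is_dud in bools:
        for init_block in bools:
            p0 = (dud if is_dud else 1 - dud) * (b if init_block else 1 - b)
            for events in product(cycle_events, repeat=n_cycles):
                prob = p0
                alive = not is_dud
                blocked = init_block
                detached = False
                edman = 0
                counts = [1 if alive else 0]
                for (d_ev, l_ev, c_ev, f_ev) in events:
                    prob *= (det if d_ev else 1 - det)
                    prob *= (loss if l_ev else 1 - loss)
                    prob *= (c if c_ev else 1 - c)
                    prob *= (e if f_ev else 1 - e)
                    if prob == 0.0:
                        break
                    if d_ev:
                        detached = True
                    if l_ev and alive:
                        alive = False
                    if c_ev and not blocked:
                        blocked = True
                    if not blocked and not detached and not f_ev:
                        edman += 1
                        if edman >= label_pos:
                            alive = False
                    counts.append(1 if (alive and not detached) else 0)
                if prob == 0.0:
                    continue
                lik = prob
                for t, k in enumerate(counts):
                    mean = ch.count_mean(0, k)
                    var = ch.count_var(0, k)
                    lik *= np.exp(_norm_logpdf(obs[t], mean, var))
                total += lik
    return float(np.log(total))


def test_forward_matches_path_enumeration():
    m = ErrorModel(0.1, [0.07], 0.04, [0.15], 0.06, 0.03)
    ch = ChannelModel(mu=[6000.0], sigma=[900.0], bg_sigma=[900.0])
    p = parse_peptide("NH2-K*A|")  # label at position 1
    space = build_state_space(p, 3)
    rng = np.random.default_rng(0)
    for _ in range(4):
        obs = rng.normal([6000, 6000, 0, 0], 1200.0)
        ll_hmm = forward_loglik(space, m, ch, Read(obs[None, :]))
        ll_oracle = path_sum_loglik(1, 3, m, ch, obs)
        assert ll_hmm == pytest.approx(ll_oracle, abs=1e-10)


def test_forward_matches_dense_transition_matrix(two_label, channels):
    """Multiplying the factors into one dense per-cycle transition matrix and
    running a textbook forward pass gives the same likelihood."""
    m = ErrorModel(0.08, [0.05], 0.03, [0.12], 0.05, 0.02)
    space = build_state_space(two_label, 5)
    mats = space.all_factor_matrices(m)
    T = np.eye(space.n_states)
    for name, ch_i in space.cycle_factor_names():
        T = T @ mats[(name, ch_i)]
    init = space.initial_distribution()
    for name, ch_i in space.initial_factor_names():
        init = init @ mats[(name, ch_i)]

    rng = np.random.default_rng(1)
    rs = simulate_reads(two_label, m, channels, 5, 5, rng)
    for r in range(5):
        obs = rs.intensities[r].T  # [t, channel]
        log_e = space.state_log_emission(obs[None], channels)[0]
        alpha = init * np.exp(log_e[0] - log_e[0].max())
        ll = np.log(alpha.sum()) + log_e[0].max()
        alpha /= alpha.sum()
        for t in range(1, 6):
            alpha = (alpha @ T) * np.exp(log_e[t] - log_e[t].max())
            ll += np.log(alpha.sum()) + log_e[t].max()
            alpha /= alpha.sum()
        ll_factored = forward_loglik(space, m, channels, rs[r])
        assert ll_factored == pytest.approx(float(ll), abs=1e-10)


def test_truncation_irrelevance(channels):
    """Appending unlabeled C-terminal residues does not change likelihoods."""
    m = ErrorModel(0.08, [0.05], 0.03, [0.12], 0.05, 0.02)
    p_short = parse_peptide("NH2-AK*|")
    p_long = parse_peptide("NH2-AK*AAAA")
    rng = np.random.default_rng(2)
    rs = simulate_reads(p_short, m, channels, 5, 6, rng)
    s_short = build_state_space(p_short, 6)
    s_long = build_state_space(p_long, 6)
    for r in range(5):
        ll_a = forward_loglik(s_short, m, channels, rs[r])
        ll_b = forward_loglik(s_long, m, channels, rs[r])
        assert ll_a == pytest.approx(ll_b, rel=1e-12)


def test_forward_backward_consistency(two_label, truth, channels, reads_10k):
    space = build_state_space(two_label, 10)
    for r in range(3):
        post = forward_backward(space, truth, channels, reads_10k[r])
        ll = forward_loglik(space, truth, channels, reads_10k[r])
        assert post.log_likelihood == pytest.approx(ll, abs=1e-10)
        for occ in post.occupancy:
            assert occ.sum() == pytest.approx(1.0, abs=1e-9)
        # transition posteriors marginalize to occupancies on both sides
        for f, P in enumerate(post.transitions):
            np.testing.assert_allclose(P.sum(axis=1), post.occupancy[f], atol=1e-9)


def test_deterministic_model_posterior_on_true_path(two_label, channels):
    """With error rates ~0 and tiny noise the posterior concentrates on the
    error-free staircase path."""
    m = ErrorModel(1e-9, [1e-9], 1e-9, [1e-9], 1e-9, 1e-9)
    ch = ChannelModel(mu=[6000.0], sigma=[50.0], bg_sigma=[50.0])
    track = np.array([2, 2, 1, 1, 1, 0, 0]) * 6000.0
    space = build_state_space(two_label, 6)
    post = forward_backward(space, m, ch, Read(track[None, :]))
    final = post.occupancy[-1]
    idx = int(np.argmax(final))
    s = space.states[idx]
    assert final[idx] > 0.999
    assert s.edman_successes == 5 and s.fluor_counts == (0,)


def test_posterior_dye_loss_matches_simulation(two_label, channels):
    """Posterior-expected dye-loss events agree with the true simulated count
    (Edman disabled so every drop is a dye loss)."""
    from fluorfit.fit_bw import _estep_batch
    from fluorfit.simulator import simulate_reads

    m = ErrorModel(edman_failure=1.0 - 1e-9, dye_loss=[0.1], detach=0.0, dud=[0.0])
    rng = np.random.default_rng(3)
    n = 2000
    rs = simulate_reads(two_label, m, channels, n, 6, rng)
    space = build_state_space(two_label, 6)
    _, stats = _estep_batch(space, m, channels, rs.intensities)
    # with e ~ 1 and no duds/detach, true losses per read = 2 - final count;
    # recover the truth from the noise via the generating parameters
    rng2 = np.random.default_rng(3)
    from fluorfit.simulator import simulate_dye_tracks

    tracks = simulate_dye_tracks(two_label, m, n, 6, rng2)
    true_losses = (2 - tracks.counts[:, 0, -1]).sum()
    se = np.sqrt(n * 2 * 6 * 0.1 * 0.9)
    assert abs(stats.dye_loss_x[0] - true_losses) < 3 * se
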