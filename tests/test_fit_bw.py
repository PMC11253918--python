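"""Modified Baum-Welch: sufficient statistics, M-step, bias correction, and
parameter recovery."""

import numpy as np
import pytest

from fluorfit import ChannelModel, ErrorModel, parse_peptide, simulate_reads
from fluorfit.fit_bw import (
    SufficientStats,
    accumulate_stats,
    all_dud_probability,
    dud_bias_correction,
    fit_baum_welch,
    m_step,
    _estep_batch,
    _estep_kernel_path,
    _precompute_emissions,
)
from fluorfit.hmm import build_state_space, forward_backward
from fluorfit.simulator import Read

from conftest import rates_vector


def test_mstep_examples():
    cur = ErrorModel(0.5, [0.5], 0.5, [0.5], 0.5, 0.5)
    stats = SufficientStats(
        n_channels=1,
        edman_n=100.0, edman_x=0.0,        # clamps at the floor
        detach_n=100.0, detach_x=5.0,      # plain ratio
        block_n=0.0, block_x=0.0,          # no trials: unchanged
        init_block_n=10.0, init_block_x=2.0,
        dye_loss_n=np.array([50.0]), dye_loss_x=np.array([10.0]),
        dud_n=np.array([20.0]), dud_x=np.array([20.0]),  # clamps at the ceiling
    )
    new = m_step(stats, cur)
    assert new.edman_failure == pytest.approx(1e-9)
    assert new.detach == pytest.approx(0.05)
    assert new.cyclic_block == 0.5
    assert new.initial_block == pytest.approx(0.2)
    assert new.dye_loss[0] == pytest.approx(0.2)
    assert new.dud[0] == pytest.approx(1.0 - 1e-9)


def test_mstep_respects_mask():
    cur = ErrorModel(0.1, [0.1], 0.0, [0.1], 0.1, 0.1, fixed=frozenset({"detach"}))
    stats = SufficientStats(n_channels=1, detach_n=100.0, detach_x=50.0)
    assert m_step(stats, cur).detach == 0.0


def test_dud_bias_correction_printed_example(two_label):
    """100 observed reads of a two-label peptide at d = 0.5: all-dud
    probability 0.25, expected missing reads 100 * 0.25/0.75 = 33.33."""
    m = ErrorModel(0.0, [0.0], 0.0, [0.5])
    stats = SufficientStats(n_channels=1, dud_n=np.array([200.0]), dud_x=np.array([60.0]))
    corrected, missing = dud_bias_correction(stats, m, 100, two_label)
    assert missing == pytest.approx(100 * 0.25 / 0.75)
    assert corrected.dud_n[0] == pytest.approx(200.0 + missing * 2)
    assert corrected.dud_x[0] == pytest.approx(60.0 + missing * 2)


def test_dud_bias_correction_zero(two_label):
    m = ErrorModel(0.0, [0.0], 0.0, [0.0])
    stats = SufficientStats(n_channels=1, dud_n=np.array([10.0]))
    corrected, missing = dud_bias_correction(stats, m, 100, two_label)
    assert missing == 0.0
    assert corrected.dud_n[0] == 10.0


def test_all_dud_probability_multichannel():
    p = parse_peptide("NH2-K*AY*1|")
    m = ErrorModel(0.0, [0.0, 0.0], 0.0, [0.2, 0.5])
    assert all_dud_probability(m, p) == pytest.approx(0.1)


def test_accumulate_error_free_read(two_label, channels):
    """A noise-free staircase read under near-zero rates yields zero success
    counts but positive trial counts for every free parameter."""
    m = ErrorModel(1e-6, [1e-6], 1e-6, [1e-6], 1e-6, 1e-6)
    space = build_state_space(two_label, 6)
    track = np.array([2, 2, 1, 1, 1, 0, 0]) * 6000.0
    post = forward_backward(space, m, channels, Read(track[None, :]))
    stats = accumulate_stats(post, space)
    assert stats.edman_x < 1e-3 and stats.edman_n > 1
    assert stats.dye_loss_x[0] < 1e-3 and stats.dye_loss_n[0] > 1
    assert stats.detach_x < 1e-3 and stats.detach_n > 1
    assert stats.dud_x[0] < 1e-3 and stats.dud_n[0] == 2.0
    assert stats.init_block_n == 1.0


def test_single_drop_attributed_to_dye_loss(channels):
    """A mid-run drop before the label position can only be dye loss when
    detachment is masked off: its expected loss count is ~1."""
    p = parse_peptide("fmoc-AAAAK*|")  # label at position 5
    from fluorfit.error_model import fix_for_identifiability

    m = fix_for_identifiability(ErrorModel(0.01, [0.1], 0.0, [0.0], 0.01, 0.0), p)
    space = build_state_space(p, 3)  # 3 cycles < label position
    track = np.array([1, 1, 0, 0]) * 6000.0
    post = forward_backward(space, m, channels, Read(track[None, :]))
    stats = accumulate_stats(post, space)
    assert stats.dye_loss_x[0] == pytest.approx(1.0, abs=1e-2)


def test_stats_additive(two_label, truth, channels, reads_10k):
    space = build_state_space(two_label, 10)
    posts = [forward_backward(space, truth, channels, reads_10k[i]) for i in range(4)]
    parts = [accumulate_stats(po, space) for po in posts]
    total_ab = (parts[0] + parts[1]) + (parts[2] + parts[3])
    total_ba = (parts[3] + parts[2]) + (parts[1] + parts[0])
    assert total_ab.edman_x == pytest.approx(total_ba.edman_x, rel=1e-12)
    assert total_ab.dye_loss_n[0] == pytest.approx(total_ba.dye_loss_n[0], rel=1e-12)


def test_estep_paths_agree(two_label, truth, channels, reads_10k):
    """Per-read posteriors, the batched numpy E-step, and the compiled kernel
    produce identical statistics and likelihoods."""
    sub = reads_10k.subset(np.arange(25))
    space = build_state_space(two_label, 10)
    ll_np, st_np = _estep_batch(space, truth, channels, sub.intensities)
    em = _precompute_emissions(space, channels, sub.intensities)
    ll_k, st_k = _estep_kernel_path(space, truth, em)
    total = SufficientStats(n_channels=1)
    ll_ref = 0.0
    for i in range(25):
        post = forward_backward(space, truth, channels, sub[i])
        ll_ref += post.log_likelihood
        total = total + accumulate_stats(post, space)
    for ll in (ll_np, ll_k):
        assert ll == pytest.approx(ll_ref, abs=1e-6)
    for a, b in ((st_np, total), (st_k, total)):
        assert a.edman_x == pytest.approx(b.edman_x, rel=1e-9)
        assert a.detach_x == pytest.approx(b.detach_x, rel=1e-9)
        assert a.block_n == pytest.approx(b.block_n, rel=1e-9)
        np.testing.assert_allclose(a.dye_loss_x, b.dye_loss_x, rtol=1e-9)
        np.testing.assert_allclose(a.dud_x, b.dud_x, rtol=1e-9)


def test_weighted_estep_equals_duplication(two_label, truth, channels, reads_10k):
    rs = reads_10k.subset(np.arange(40))
    idx = np.random.default_rng(5).integers(0, 40, 40)
    uniq, cnt = np.unique(idx, return_counts=True)
    f_dup = fit_baum_welch(rs.subset(idx), two_label, channels, max_iter=4)
    f_w = fit_baum_welch(
        rs.subset(uniq), two_label, channels, max_iter=4, weights=cnt.astype(float)
    )
    assert f_w.log_likelihood[-1] == pytest.approx(f_dup.log_likelihood[-1], rel=1e-10)
    np.testing.assert_allclose(
        rates_vector(f_w.estimate), rates_vector(f_dup.estimate), rtol=1e-8
    )


def test_read_order_invariance(two_label, truth, channels, reads_10k):
    rs = reads_10k.subset(np.arange(60))
    perm = np.random.default_rng(6).permutation(60)
    f_a = fit_baum_welch(rs, two_label, channels, max_iter=3)
    f_b = fit_baum_welch(rs.subset(perm), two_label, channels, max_iter=3)
    np.testing.assert_allclose(
        rates_vector(f_a.estimate), rates_vector(f_b.estimate), atol=1e-10
    )


def test_one_label_estimate_masked(one_label, channels):
    m = ErrorModel(0.05, [0.04], 0.0, [0.0], 0.06, 0.0)
    rng = np.random.default_rng(7)
    rs = simulate_reads(one_label, m, channels, 1500, 6, rng)
    fit = fit_baum_welch(rs, one_label, channels)
    assert fit.estimate.detach == 0.0
    assert fit.estimate.dud[0] == 0.0
    assert fit.estimate.cyclic_block == 0.0
    assert fit.fixed == {"detach", "dud", "cyclic_block"}
    assert abs(fit.estimate.edman_failure - 0.05) < 0.02


def test_init_at_truth_converges_fast(two_label):
    """Starting at the generating parameters of an error-free dataset, EM
    stays there and stops almost immediately."""
    m = ErrorModel(1e-6, [1e-6], 1e-6, [1e-6], 1e-6, 1e-6)
    ch = ChannelModel(mu=[6000.0], sigma=[60.0], bg_sigma=[60.0])
    rs = simulate_reads(two_label, m, ch, 300, 6, np.random.default_rng(8))
    fit = fit_baum_welch(rs, two_label, ch, init=m, tol=1e-4)
    assert fit.converged and fit.n_iterations <= 3
    assert rates_vector(fit.estimate).max() < 1e-3


def test_em_monotone_and_recovers(two_label, truth, channels, bw_fit_10k):
    """On 10k simulated reads EM increases the censored log-likelihood every
    iteration and lands within 2pp of every generating rate."""
    traj = np.array(bw_fit_10k.log_likelihood)
    tol = 1e-8 * np.maximum(1.0, np.abs(traj[:-1]))
    assert np.all(np.diff(traj) >= -tol)
    assert bw_fit_10k.converged
    err = np.abs(rates_vector(bw_fit_10k.estimate) - rates_vector(truth))
    assert err.max() < 0.02
    assert bw_fit_10k.missing_reads > 0


def test_censoring_correction_unbiased_vs_naive(two_label, channels):
    """At dud = 0.2 the corrected estimator is centred on the truth while the
    uncorrected one is biased low (small replicate version of the full
    criterion test)."""
    m = ErrorModel(0.06, [0.05], 0.02, [0.2], 0.05, 0.02)
    diffs = []
    for seed in range(6):
        rs = simulate_reads(two_label, m, channels, 2000, 8, np.random.default_rng(100 + seed))
        d_corr = fit_baum_welch(rs, two_label, channels).estimate.dud[0]
        d_naive = fit_baum_welch(rs, two_label, channels, bias_correction=False).estimate.dud[0]
        diffs.append((d_corr, d_naive))
    d_corr = np.array([a for a, _ in diffs])
    d_naive = np.array([b for _, b in diffs])
    assert abs(d_corr.mean() - 0.2) < 0.01
    assert np.all(d_naive < d_corr)
    assert d_naive.mean() < 0.2 - 0.02
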