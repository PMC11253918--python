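"""Modified Baum-Welch estimation of the six sequencing-error rates.

Classical Baum-Welch re-estimates every transition probability of an HMM
independently.  Here the transition structure is generated by six scalar
rates, so the M-step instead computes a weighted maximum-likelihood
estimate of each rate directly: every sub-transition posterior from the
factored forward-backward pass is mapped to a number of Bernoulli trials
``n`` and successes ``x`` for the parameter that generated it, summed
over reads, and the update is simply ``x / n``.  This keeps the number of
fitted quantities at six (fewer with the one-label identifiability mask)
regardless of the size of the state space.

Censoring of all-dud molecules biases the naive dud-rate estimate low:
molecules whose fluorophores are all dark never appear as reads.  The
classical EM treatment of truncated data is applied: given current dud
rates, the expected number of unobserved molecules is ``N * x / (1 - x)``
with ``x`` the all-dud probability, and that many phantom all-dud
molecules are added to the dud sufficient statistics (only — an
unobserved molecule carries no information about the cycle-level rates)
before each M-step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .error_model import (
    RATE_EPS,
    ChannelModel,
    ErrorModel,
    fix_for_identifiability,
)
from .hmm import (
    HmmStateSpace,
    SubStepPosteriors,
    _build_schedule,
    _emission_slots,
    build_state_space,
    forward_pass,
)
from .peptide import LabeledPeptide, label_counts
from .simulator import ReadSet

__all__ = [
    "SufficientStats",
    "FitResult",
    "accumulate_stats",
    "dud_bias_correction",
    "m_step",
    "fit_baum_welch",
]


@dataclass
class SufficientStats:
    """Weighted Bernoulli-trial counts per error parameter.

    Per-fluorophore parameters (dye loss, dud) keep one ``(n, x)`` pair
    per channel.  Stats are additive over reads.
    """

    n_channels: int
    edman_n: float = 0.0
    edman_x: float = 0.0
    detach_n: float = 0.0
    detach_x: float = 0.0
    block_n: float = 0.0
    block_x: float = 0.0
    init_block_n: float = 0.0
    init_block_x: float = 0.0
    dye_loss_n: np.ndarray = field(default=None)
    dye_loss_x: np.ndarray = field(default=None)
    dud_n: np.ndarray = field(default=None)
    dud_x: np.ndarray = field(default=None)

    def __post_init__(self):
        for name in ("dye_loss_n", "dye_loss_x", "dud_n", "dud_x"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(self.n_channels))

    def __add__(self, other: "SufficientStats") -> "SufficientStats":
        if self.n_channels != other.n_channels:
            raise ValueError("channel count mismatch")
        return SufficientStats(
            n_channels=self.n_channels,
            edman_n=self.edman_n + other.edman_n,
            edman_x=self.edman_x + other.edman_x,
            detach_n=self.detach_n + other.detach_n,
            detach_x=self.detach_x + other.detach_x,
            block_n=self.block_n + other.block_n,
            block_x=self.block_x + other.block_x,
            init_block_n=self.init_block_n + other.init_block_n,
            init_block_x=self.init_block_x + other.init_block_x,
            dye_loss_n=self.dye_loss_n + other.dye_loss_n,
            dye_loss_x=self.dye_loss_x + other.dye_loss_x,
            dud_n=self.dud_n + other.dud_n,
            dud_x=self.dud_x + other.dud_x,
        )


@dataclass
class FitResult:
    """Outcome of a parameter fit (either estimator)."""

    estimate: ErrorModel
    log_likelihood: list[float]
    n_iterations: int
    converged: bool
    fixed: frozenset[str]
    missing_reads: float = 0.0
    method: str = "bw"
    objective: float | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "estimate": self.estimate.to_dict(),
            "log_likelihood": [float(v) for v in self.log_likelihood],
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "fixed": sorted(self.fixed),
            "missing_reads": float(self.missing_reads),
            "objective": None if self.objective is None else float(self.objective),
        }


def accumulate_stats(post: SubStepPosteriors, space: HmmStateSpace) -> SufficientStats:
    """Map one read's sub-step posteriors to per-parameter trial counts.

    Sub-transition-to-statistic mapping: a dye-loss factor contributes
    fluorophore-weighted occupancy to ``n`` and the posterior-expected
    count drop to ``x``; the Edman factor contributes unblocked,
    undetached occupancy to ``n`` and its self- (failure) transition mass
    to ``x``; detach and blocking factors contribute eligible occupancy
    and the corresponding transition mass; the dud factors contribute the
    per-channel label total to ``n`` and the expected number of initially
    dark fluorophores to ``x``.
    """
    stats = SufficientStats(n_channels=space.n_channels)
    counts = space.counts
    nondet = ~space.detached
    unblocked = nondet & ~space.blocked
    for f, (name, ch, _t) in enumerate(post.schedule):
        P = post.transitions[f]
        occ = post.occupancy[f]
        if name == "dud":
            stats.dud_n[ch] += float(space.label_totals[ch])
            drop = counts[:, ch][:, None] - counts[:, ch][None, :]
            stats.dud_x[ch] += float((P * drop).sum())
        elif name == "dye_loss":
            stats.dye_loss_n[ch] += float(occ @ counts[:, ch])
            drop = counts[:, ch][:, None] - counts[:, ch][None, :]
            stats.dye_loss_x[ch] += float((P * drop).sum())
        elif name == "detach":
            stats.detach_n += float(occ[nondet].sum())
            stats.detach_x += float(P[nondet, space.detached_index].sum())
        elif name == "cyclic_block":
            stats.block_n += float(occ[unblocked].sum())
            stats.block_x += float(P[np.ix_(unblocked, space.blocked)].sum())
        elif name == "initial_block":
            stats.init_block_n += 1.0
            stats.init_block_x += float(P[np.ix_(unblocked, space.blocked)].sum())
        elif name == "edman":
            elig = space.edman_eligible
            stats.edman_n += float(occ[elig].sum())
            stats.edman_x += float(np.diag(P)[elig].sum())
    return stats


def all_dud_probability(m: ErrorModel, p: LabeledPeptide) -> float:
    """Probability that every fluorophore on the peptide is a dud."""
    m = m.broadcast(p.n_channels)
    return float(np.prod([m.dud[ch] for _, ch in p.labels]))


def dud_bias_correction(
    stats: SufficientStats, current: ErrorModel, n_reads: int, p: LabeledPeptide
) -> tuple[SufficientStats, float]:
    """Augment the dud statistics with the expected censored molecules.

    With all-dud probability ``x``, an experiment that yielded ``N``
    observed reads is expected to have lost ``m = N * x / (1 - x)``
    molecules.  Each phantom molecule contributes all of its labels as
    dud trials *and* successes, to the dud statistics only.  Returns the
    corrected stats and ``m``.
    """
    x = all_dud_probability(current, p)
    if x >= 1.0 - 1e-9:
        raise ValueError("all-dud probability ~1; censoring correction diverges")
    missing = n_reads * x / (1.0 - x)
    if missing == 0.0:
        return stats, 0.0
    totals = label_counts(p).astype(float)
    corrected = replace_stats(stats)
    corrected.dud_n = stats.dud_n + missing * totals
    corrected.dud_x = stats.dud_x + missing * totals
    return corrected, missing


def replace_stats(stats: SufficientStats) -> SufficientStats:
    return stats + SufficientStats(n_channels=stats.n_channels)


def m_step(stats: SufficientStats, current: ErrorModel) -> ErrorModel:
    """Weighted-MLE update: each free rate becomes ``x / n`` clamped inside
    ``[1e-9, 1 - 1e-9]``; fixed parameters and parameters with no trials
    keep their current value."""

    def upd(name: str, x, n, cur):
        if name in current.fixed:
            return cur
        x, n, cur = np.asarray(x, float), np.asarray(n, float), np.asarray(cur, float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(n > 0, x / np.maximum(n, 1e-300), cur)
        return np.clip(rate, RATE_EPS, 1.0 - RATE_EPS)

    return ErrorModel(
        edman_failure=float(upd("edman_failure", stats.edman_x, stats.edman_n, current.edman_failure)),
        dye_loss=upd("dye_loss", stats.dye_loss_x, stats.dye_loss_n, current.dye_loss),
        detach=float(upd("detach", stats.detach_x, stats.detach_n, current.detach)),
        dud=upd("dud", stats.dud_x, stats.dud_n, current.dud),
        initial_block=float(
            upd("initial_block", stats.init_block_x, stats.init_block_n, current.initial_block)
        ),
        cyclic_block=float(upd("cyclic_block", stats.block_x, stats.block_n, current.cyclic_block)),
        fixed=current.fixed,
    )


def _stat_structures(space: HmmStateSpace, mats: dict):
    """Per-slot transition-statistic matrices and occupancy weights.

    For slot ``f`` applying factor ``F``, ``xmats[f]`` holds ``F``
    restricted (and weighted) to the sub-transitions that count as
    "successes" for that factor's parameter, and ``nvecs[f]`` the
    per-state weights whose posterior occupancy counts as "trials"
    (``None`` where trials are a per-read constant).
    """
    schedule = _build_schedule(space)
    counts = space.counts
    nondet = ~space.detached
    unblocked = nondet & ~space.blocked
    elig = space.edman_eligible

    xmats: list[np.ndarray] = []
    nvecs: list[np.ndarray | None] = []
    for name, chn, _t in schedule:
        F = mats[(name, chn)]
        if name in ("dud", "dye_loss"):
            drop = counts[:, chn][:, None] - counts[:, chn][None, :]
            xmats.append(F * drop)
            nvecs.append(counts[:, chn].astype(float) if name == "dye_loss" else None)
        elif name == "detach":
            M = np.zeros_like(F)
            M[nondet, space.detached_index] = F[nondet, space.detached_index]
            xmats.append(M)
            nvecs.append(nondet.astype(float))
        elif name in ("cyclic_block", "initial_block"):
            M = np.zeros_like(F)
            rows = np.flatnonzero(unblocked)
            cols = np.flatnonzero(space.blocked)
            M[np.ix_(rows, cols)] = F[np.ix_(rows, cols)]
            xmats.append(M)
            nvecs.append(unblocked.astype(float) if name == "cyclic_block" else None)
        elif name == "edman":
            M = np.zeros_like(F)
            idx = np.flatnonzero(elig)
            M[idx, idx] = F[idx, idx]
            xmats.append(M)
            nvecs.append(elig.astype(float))
        else:  # pragma: no cover - schedule only contains the above
            raise ValueError(name)
    return schedule, xmats, nvecs


def _estep_batch(
    space: HmmStateSpace,
    m: ErrorModel,
    ch: ChannelModel,
    intensities: np.ndarray,
    batch_size: int = 4096,
    weights: np.ndarray | None = None,
) -> tuple[float, SufficientStats]:
    """Vectorized numpy E-step over all reads.

    Runs the scaled forward pass storing pre-factor state distributions,
    then sweeps backward accumulating the per-parameter statistics of
    :func:`accumulate_stats` without materializing per-read posterior
    matrices.  Identical (to float tolerance) to summing
    ``accumulate_stats(forward_backward(read))`` over reads, and to the
    compiled kernel path used by :func:`fit_baum_welch`.
    """
    mats = space.all_factor_matrices(m)
    schedule, xmats_l, nvecs_l = _stat_structures(space, mats)
    emit_after = _emission_slots(space)
    xmats = dict(enumerate(xmats_l))
    nvecs = {f: v for f, v in enumerate(nvecs_l) if v is not None}

    total = SufficientStats(n_channels=space.n_channels)
    total_ll = 0.0
    n_reads = intensities.shape[0]
    n_obs = intensities.shape[2]
    if weights is None:
        weights = np.ones(n_reads)
    for start in range(0, n_reads, batch_size):
        chunk = intensities[start : start + batch_size]
        w = weights[start : start + batch_size]
        obs = np.transpose(chunk, (0, 2, 1))  # [r, t, channel]
        log_e = space.state_log_emission(obs, ch)
        loglik, alphas, log_e_scaled = forward_pass(space, mats, log_e, keep_alphas=True)
        total_ll += float(loglik @ w)
        e_scaled = np.exp(log_e_scaled)

        b = np.ones((chunk.shape[0], space.n_states))
        obs_t = n_obs - 1
        for f in range(len(schedule) - 1, -1, -1):
            if obs_t >= 0 and f == emit_after[obs_t]:
                b = b * e_scaled[:, obs_t, :]
                obs_t -= 1
            name, chn, _t = schedule[f]
            F = mats[(name, chn)]
            a_pre = alphas[f] * w[:, None]
            x_val = float(((a_pre @ xmats[f]) * b).sum())
            b_pre = b @ F.T
            if f in nvecs:
                n_val = float(((a_pre * b_pre) @ nvecs[f]).sum())
            b = b_pre
            if name == "dud":
                total.dud_n[chn] += float(space.label_totals[chn]) * float(w.sum())
                total.dud_x[chn] += x_val
            elif name == "dye_loss":
                total.dye_loss_n[chn] += n_val
                total.dye_loss_x[chn] += x_val
            elif name == "detach":
                total.detach_n += n_val
                total.detach_x += x_val
            elif name == "cyclic_block":
                total.block_n += n_val
                total.block_x += x_val
            elif name == "initial_block":
                total.init_block_n += float(w.sum())
                total.init_block_x += x_val
            elif name == "edman":
                total.edman_n += n_val
                total.edman_x += x_val
    return total_ll, total


def _precompute_emissions(
    space: HmmStateSpace, ch: ChannelModel, intensities: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Shifted linear emission densities, computed once per fit.

    Emissions depend only on the (held-fixed) channel model and the data,
    never on the error rates, so EM evaluates them a single time.
    Returns ``E[t, r, s] = exp(log_e - shift)`` and ``shifts[r, t]``.
    """
    obs = np.transpose(intensities, (0, 2, 1))
    log_e = space.state_log_emission(obs, ch)  # [r, t, s]
    shifts = log_e.max(axis=2)
    E = np.exp(log_e - shifts[:, :, None]).transpose(1, 0, 2).copy()
    return E, shifts


def _estep_kernel_path(
    space: HmmStateSpace,
    m: ErrorModel,
    emissions: tuple[np.ndarray, np.ndarray],
    weights: np.ndarray | None = None,
) -> tuple[float, SufficientStats]:
    """Compiled E-step; equivalent to :func:`_estep_batch`.

    ``weights`` are per-read multiplicities: a bootstrap resample is
    processed as its distinct reads with integer weights, which is
    mathematically identical to duplicating the reads.
    """
    from ._kernels import estep_kernel, pack_factors

    mats = space.all_factor_matrices(m)
    schedule, xmats, nvecs = _stat_structures(space, mats)
    mats_list = [mats[(name, chn)] for name, chn, _t in schedule]
    packed = pack_factors(mats_list, xmats, nvecs)

    emit_after = _emission_slots(space)
    emit_idx = np.full(len(schedule), -1, dtype=np.int64)
    for t, f in enumerate(emit_after):
        emit_idx[f] = t

    E, shifts = emissions
    if weights is None:
        weights = np.ones(E.shape[1])
    total_ll, xsum, nsum, bad = estep_kernel(
        *packed, emit_idx, E, shifts, space.intact_index, weights
    )
    if bad >= 0:
        raise FloatingPointError(f"non-finite forward likelihood at read {bad}")

    n_reads = float(weights.sum())
    total = SufficientStats(n_channels=space.n_channels)
    for f, (name, chn, _t) in enumerate(schedule):
        if name == "dud":
            total.dud_n[chn] += float(space.label_totals[chn]) * n_reads
            total.dud_x[chn] += xsum[f]
        elif name == "dye_loss":
            total.dye_loss_n[chn] += nsum[f]
            total.dye_loss_x[chn] += xsum[f]
        elif name == "detach":
            total.detach_n += nsum[f]
            total.detach_x += xsum[f]
        elif name == "cyclic_block":
            total.block_n += nsum[f]
            total.block_x += xsum[f]
        elif name == "initial_block":
            total.init_block_n += n_reads
            total.init_block_x += xsum[f]
        elif name == "edman":
            total.edman_n += nsum[f]
            total.edman_x += xsum[f]
    return float(total_ll), total


def _max_param_change(a: ErrorModel, b: ErrorModel) -> float:
    return float(
        max(
            abs(a.edman_failure - b.edman_failure),
            np.abs(a.dye_loss - b.dye_loss).max(),
            abs(a.detach - b.detach),
            np.abs(a.dud - b.dud).max(),
            abs(a.initial_block - b.initial_block),
            abs(a.cyclic_block - b.cyclic_block),
        )
    )


DEFAULT_INIT_RATE = 0.05


def default_init(p: LabeledPeptide) -> ErrorModel:
    """All free rates at 0.05, a weakly informative starting point."""
    n_ch = p.n_channels
    return ErrorModel(
        edman_failure=DEFAULT_INIT_RATE,
        dye_loss=np.full(n_ch, DEFAULT_INIT_RATE),
        detach=DEFAULT_INIT_RATE,
        dud=np.full(n_ch, DEFAULT_INIT_RATE),
        initial_block=DEFAULT_INIT_RATE,
        cyclic_block=DEFAULT_INIT_RATE,
    )


def fit_baum_welch(
    reads: ReadSet,
    p: LabeledPeptide,
    ch: ChannelModel,
    init: ErrorModel | None = None,
    tol: float = 1e-5,
    max_iter: int = 250,
    bias_correction: bool = True,
    batch_size: int = 4096,
    space: HmmStateSpace | None = None,
    use_kernel: bool = True,
    weights: np.ndarray | None = None,
) -> FitResult:
    """EM fit of the error model to a read set.

    The channel (emission) model is held fixed throughout.  Convergence
    is declared when the largest absolute parameter change in an
    iteration falls below ``tol``.  The recorded log-likelihood is the
    censored-data log-likelihood (per-read model likelihood adjusted for
    the probability of a molecule being observable at all), which EM must
    not decrease; a decrease beyond tolerance raises, as it indicates an
    implementation defect.
    """
    if reads.n_reads < 1:
        raise ValueError("need at least one read")
    if space is None:
        space = build_state_space(p, reads.n_observations - 1)
    if init is None:
        init = default_init(p)
    current = fix_for_identifiability(init.broadcast(p.n_channels), p)
    n_reads = reads.n_reads if weights is None else float(np.sum(weights))

    emissions = _precompute_emissions(space, ch, reads.intensities) if use_kernel else None

    trajectory: list[float] = []
    missing = 0.0
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        if use_kernel:
            ll, stats = _estep_kernel_path(space, current, emissions, weights=weights)
        else:
            ll, stats = _estep_batch(
                space, current, ch, reads.intensities, batch_size, weights=weights
            )
        x_cens = all_dud_probability(current, p)
        ll_censored = ll - n_reads * np.log(max(1.0 - x_cens, 1e-300))
        if trajectory and ll_censored < trajectory[-1] - 1e-8 * max(1.0, abs(trajectory[-1])):
            raise RuntimeError(
                f"log-likelihood decreased at iteration {iteration}: "
                f"{trajectory[-1]:.10g} -> {ll_censored:.10g}"
            )
        trajectory.append(ll_censored)
        if bias_correction and "dud" not in current.fixed:
            stats, missing = dud_bias_correction(stats, current, n_reads, p)
        new = m_step(stats, current)
        delta = _max_param_change(new, current)
        current = new
        if delta < tol:
            converged = True
            break
    return FitResult(
        estimate=current,
        log_likelihood=trajectory,
        n_iterations=iteration,
        converged=converged,
        fixed=current.fixed,
        missing_reads=missing,
        method="bw",
    )
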