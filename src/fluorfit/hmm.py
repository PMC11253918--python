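"""Factored hidden Markov model of fluorosequencing for a single peptide.

States are merged by (number of successful Edman cycles, surviving
fluorophore count per channel, N-terminal blocked flag), plus one
absorbing "detached" state.  Merging is exact because duds and dye loss
strike fluorophores i.i.d., so conditional on the counts the surviving
fluorophores are uniformly placed among the label positions that have not
yet been cleaved off; Edman removal of a labeled residue then lowers the
count hypergeometrically (probability ``count / remaining labels``).

The one-step transition matrix is never formed.  Each error type is a
separate sparse factor applied in a fixed within-cycle order shared with
the simulator (detach, per-channel dye loss, cyclic block, Edman), with
two pre-sequencing factors (per-channel dud thinning, then initial
block).  The factorization introduces *sub-steps* between factors;
:func:`forward_backward` exposes state occupancies and transition
posteriors at every sub-step, which is what lets the Baum-Welch M-step
attribute evidence to individual error parameters.

Edman cycles are capped at the last labeled position: beyond it every
fluorophore is gone and further chemistry is unobservable, which also
makes the likelihood invariant to unlabeled C-terminal residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from math import comb

import numpy as np

from .error_model import ChannelModel, ErrorModel
from .peptide import LabeledPeptide, label_counts
from .simulator import Read

__all__ = [
    "HmmState",
    "HmmStateSpace",
    "SubStepPosteriors",
    "build_state_space",
    "emission_logpdf",
    "forward_loglik",
    "forward_backward",
]

LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class HmmState:
    """One merged HMM state.  ``detached`` overrides everything else for
    emission purposes (zero fluorophores)."""

    edman_successes: int
    fluor_counts: tuple[int, ...]
    blocked: bool
    detached: bool = False


class HmmStateSpace:
    """Enumerated merged states plus per-error-type factor structure.

    Factor matrices are parameter-symbolic: :meth:`factor_matrix` binds an
    :class:`ErrorModel`'s rates at call time.  All matrices are dense
    (state spaces for single peptides are small); each is row-stochastic.
    """

    #: factor application order for the pre-sequencing step and for each cycle
    INITIAL_FACTORS = ("dud", "initial_block")

    def __init__(self, peptide: LabeledPeptide, n_cycles: int, max_states: int = 10**6):
        if n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        self.peptide = peptide
        self.n_cycles = n_cycles
        self.n_channels = peptide.n_channels
        self.label_totals = label_counts(peptide)
        self.k_cap = min(n_cycles, peptide.last_label_position)

        # labels remaining (per channel) after k successful Edman cycles
        self.remaining = np.array(
            [
                [
                    sum(1 for pos, c in peptide.labels if c == ch and pos > k)
                    for ch in range(self.n_channels)
                ]
                for k in range(self.k_cap + 1)
            ],
            dtype=np.int64,
        )

        states: list[HmmState] = []
        for k in range(self.k_cap + 1):
            rem = self.remaining[k]
            count_ranges = [range(int(r) + 1) for r in rem]
            for counts in product(*count_ranges):
                for blocked in (False, True):
                    states.append(HmmState(k, counts, blocked))
                    if len(states) > max_states:
                        raise ValueError(
                            f"state space exceeds {max_states} states; "
                            "consider fewer cycles or a pruned model"
                        )
        states.append(HmmState(self.k_cap, (0,) * self.n_channels, False, detached=True))
        self.states = states
        self.n_states = len(states)
        self.index = {s: i for i, s in enumerate(states)}
        self.detached_index = self.n_states - 1

        self.edman = np.array([s.edman_successes for s in states], dtype=np.int64)
        self.counts = np.array([s.fluor_counts for s in states], dtype=np.int64)
        self.blocked = np.array([s.blocked for s in states], dtype=bool)
        self.detached = np.array([s.detached for s in states], dtype=bool)
        # detached emits as zero fluorophores regardless of bookkeeping counts
        self.emission_counts = np.where(self.detached[:, None], 0, self.counts)

        # emission classes: states sharing a count vector share densities
        uniq, class_index = np.unique(self.emission_counts, axis=0, return_inverse=True)
        self.class_counts = uniq
        self.class_index = class_index

        # index of the intact starting state (all labels present, unblocked)
        intact = HmmState(0, tuple(int(v) for v in self.label_totals), False)
        self.intact_index = self.index[intact]

        # Edman factor is structurally identity once every label is cleaved
        # off (k == cap); such states carry no evidence about the failure rate.
        self.edman_eligible = (~self.blocked) & (~self.detached) & (self.edman < self.k_cap)

    # ---------------------------------------------------------------- factors

    def cycle_factor_names(self) -> tuple[tuple[str, int | None], ...]:
        """Per-cycle factor applications in order, as (name, channel) pairs."""
        names: list[tuple[str, int | None]] = [("detach", None)]
        names += [("dye_loss", ch) for ch in range(self.n_channels)]
        names += [("cyclic_block", None), ("edman", None)]
        return tuple(names)

    def initial_factor_names(self) -> tuple[tuple[str, int | None], ...]:
        names: list[tuple[str, int | None]] = [("dud", ch) for ch in range(self.n_channels)]
        names.append(("initial_block", None))
        return tuple(names)

    def factor_matrix(self, name: str, m: ErrorModel, channel: int | None = None) -> np.ndarray:
        """Dense row-stochastic matrix for one error-type factor with the
        rates of ``m`` bound."""
        m = m.broadcast(self.n_channels)
        S = self.n_states
        F = np.zeros((S, S))
        if name == "detach":
            rate = m.detach
            for i in range(S):
                if self.detached[i]:
                    F[i, i] = 1.0
                else:
                    F[i, self.detached_index] += rate
                    F[i, i] += 1.0 - rate
        elif name == "dye_loss" or name == "dud":
            rate = m.dye_loss[channel] if name == "dye_loss" else m.dud[channel]
            for i in range(S):
                if self.detached[i]:
                    F[i, i] = 1.0
                    continue
                s = self.states[i]
                v = s.fluor_counts[channel]
                if v == 0:
                    F[i, i] = 1.0
                    continue
                for w in range(v + 1):
                    prob = comb(v, w) * (1.0 - rate) ** w * rate ** (v - w)
                    tgt = list(s.fluor_counts)
                    tgt[channel] = w
                    j = self.index[HmmState(s.edman_successes, tuple(tgt), s.blocked)]
                    F[i, j] += prob
        elif name in ("cyclic_block", "initial_block"):
            # Acetylation is deliberately NOT folded in here: an acetylated
            # control peptide is fit with a free initial-block rate, which is
            # how the model detects that its N-terminus is blocked.
            rate = m.cyclic_block if name == "cyclic_block" else m.initial_block
            for i in range(S):
                s = self.states[i]
                if self.detached[i] or s.blocked:
                    F[i, i] = 1.0
                else:
                    j = self.index[HmmState(s.edman_successes, s.fluor_counts, True)]
                    F[i, j] += rate
                    F[i, i] += 1.0 - rate
        elif name == "edman":
            e = m.edman_failure
            for i in range(S):
                s = self.states[i]
                if not self.edman_eligible[i]:
                    F[i, i] = 1.0
                    continue
                F[i, i] += e
                k = s.edman_successes
                pos = k + 1  # 1-based position of the residue being removed
                labeled_ch = next(
                    (c for p_, c in self.peptide.labels if p_ == pos), None
                )
                if labeled_ch is None:
                    j = self.index[HmmState(k + 1, s.fluor_counts, s.blocked)]
                    F[i, j] += 1.0 - e
                else:
                    v = s.fluor_counts[labeled_ch]
                    rem = int(self.remaining[k, labeled_ch])
                    p_alive = v / rem if rem > 0 else 0.0
                    if p_alive > 0.0:
                        tgt = list(s.fluor_counts)
                        tgt[labeled_ch] = v - 1
                        j = self.index[HmmState(k + 1, tuple(tgt), s.blocked)]
                        F[i, j] += (1.0 - e) * p_alive
                    if p_alive < 1.0:
                        j = self.index[HmmState(k + 1, s.fluor_counts, s.blocked)]
                        F[i, j] += (1.0 - e) * (1.0 - p_alive)
        else:
            raise ValueError(f"unknown factor {name!r}")
        return F

    def all_factor_matrices(self, m: ErrorModel) -> dict[tuple[str, int | None], np.ndarray]:
        mats = {}
        for name, ch in self.initial_factor_names() + self.cycle_factor_names():
            mats[(name, ch)] = self.factor_matrix(name, m, ch)
        return mats

    def initial_distribution(self) -> np.ndarray:
        """Point mass on the intact, unblocked state; dud and initial-block
        factors are applied as the first sub-steps."""
        a = np.zeros(self.n_states)
        a[self.intact_index] = 1.0
        return a

    # --------------------------------------------------------------- emission

    def class_log_emission(self, obs: np.ndarray, ch: ChannelModel) -> np.ndarray:
        """Log emission density of each emission class for a batch of
        observations ``obs[..., channel]``; returns ``[..., n_classes]``."""
        obs = np.asarray(obs, dtype=float)
        out = np.zeros(obs.shape[:-1] + (self.class_counts.shape[0],))
        for c in range(self.n_channels):
            counts = self.class_counts[:, c]
            mean = ch.count_mean(c, counts)
            var = ch.count_var(c, counts)
            x = obs[..., c : c + 1]
            out += -0.5 * (LOG_2PI + np.log(var) + (x - mean) ** 2 / var)
        return out

    def state_log_emission(self, obs: np.ndarray, ch: ChannelModel) -> np.ndarray:
        return self.class_log_emission(obs, ch)[..., self.class_index]


def build_state_space(
    p: LabeledPeptide, n_cycles: int, max_states: int = 10**6
) -> HmmStateSpace:
    """Enumerate the merged state space and factor structure for one peptide."""
    return HmmStateSpace(p, n_cycles, max_states=max_states)


def emission_logpdf(s: HmmState, obs, ch: ChannelModel) -> float:
    """Log density of one observation vector (one value per channel) given a
    state; channels are independent Gaussians."""
    obs = np.atleast_1d(np.asarray(obs, dtype=float))
    counts = np.zeros_like(obs) if s.detached else np.asarray(s.fluor_counts)
    total = 0.0
    for c in range(obs.size):
        mean = ch.count_mean(c, counts[c])
        var = ch.count_var(c, counts[c])
        total += -0.5 * (LOG_2PI + np.log(var) + (obs[c] - mean) ** 2 / var)
    return float(total)


@dataclass
class SubStepPosteriors:
    """Forward-backward output for one read under the factored model.

    ``occupancy[slot]`` is the state distribution at sub-step ``slot``
    (slot order: before each factor application, in schedule order, with
    one extra slot after the final factor).  ``transitions[f]`` is the
    posterior joint over (source, target) for factor application ``f``.
    ``schedule[f]`` names the factor and the cycle it belongs to.
    """

    log_likelihood: float
    schedule: list[tuple[str, int | None, int]]
    occupancy: list[np.ndarray]
    transitions: list[np.ndarray] = field(repr=False)


def _build_schedule(space: HmmStateSpace) -> list[tuple[str, int | None, int]]:
    sched = [(name, ch, 0) for name, ch in space.initial_factor_names()]
    for t in range(1, space.n_cycles + 1):
        sched += [(name, ch, t) for name, ch in space.cycle_factor_names()]
    return sched


def _emission_slots(space: HmmStateSpace) -> list[int]:
    """Index into the schedule after which each observation is emitted:
    observation t is emitted after the last factor of cycle t."""
    n_init = len(space.initial_factor_names())
    n_cycle = len(space.cycle_factor_names())
    return [n_init - 1] + [n_init + (t + 1) * n_cycle - 1 for t in range(space.n_cycles)]


def forward_pass(
    space: HmmStateSpace,
    mats: dict,
    log_emission: np.ndarray,
    keep_alphas: bool = False,
):
    """Scaled forward pass for a batch.

    ``log_emission[r, t, s]`` is the per-state log density of observation
    ``t`` of read ``r``.  Returns ``(loglik[r], alphas)`` where ``alphas``
    (if kept) holds the normalized state distribution before every factor
    application, plus per-observation scaling data for the backward pass.
    """
    n_reads, n_obs, S = log_emission.shape
    if n_obs != space.n_cycles + 1:
        raise ValueError("read length does not match state space cycles")
    schedule = _build_schedule(space)
    emit_after = _emission_slots(space)

    a = np.tile(space.initial_distribution(), (n_reads, 1))
    loglik = np.zeros(n_reads)
    alphas = [] if keep_alphas else None
    log_e_scaled = np.empty_like(log_emission)
    obs_t = 0
    for f, (name, ch, _t) in enumerate(schedule):
        if keep_alphas:
            alphas.append(a)
        a = a @ mats[(name, ch)]
        if obs_t < n_obs and f == emit_after[obs_t]:
            log_e = log_emission[:, obs_t, :]
            shift = log_e.max(axis=1, keepdims=True)
            e_lin = np.exp(log_e - shift)
            log_e_scaled[:, obs_t, :] = log_e - shift
            a = a * e_lin
            norm = a.sum(axis=1)
            if np.any(norm <= 0.0) or not np.all(np.isfinite(norm)):
                bad = int(np.flatnonzero(~np.isfinite(norm) | (norm <= 0))[0])
                raise FloatingPointError(
                    f"non-finite forward likelihood at read {bad}, observation {obs_t}"
                )
            loglik += np.log(norm) + shift[:, 0]
            a = a / norm[:, None]
            log_e_scaled[:, obs_t, :] -= np.log(norm)[:, None]
            obs_t += 1
    return loglik, alphas, log_e_scaled


def forward_loglik(
    space: HmmStateSpace, m: ErrorModel, ch: ChannelModel, read: Read
) -> float:
    """Log-likelihood of one read under the factored model."""
    intens = read.intensities if isinstance(read, Read) else np.asarray(read)
    obs = np.transpose(intens)[None, :, :]  # [1, t, channel]
    log_e = space.state_log_emission(obs, ch)
    mats = space.all_factor_matrices(m)
    loglik, _, _ = forward_pass(space, mats, log_e)
    return float(loglik[0])


def forward_backward(
    space: HmmStateSpace, m: ErrorModel, ch: ChannelModel, read: Read
) -> SubStepPosteriors:
    """Full sub-step posteriors for one read.

    Occupancy distributions sum to one at every sub-step, and each
    factor's transition posterior marginalizes to the occupancies on
    either side of it.
    """
    intens = read.intensities if isinstance(read, Read) else np.asarray(read)
    obs = np.transpose(intens)[None, :, :]
    log_e = space.state_log_emission(obs, ch)
    mats = space.all_factor_matrices(m)
    loglik, alphas, log_e_scaled = forward_pass(space, mats, log_e, keep_alphas=True)

    schedule = _build_schedule(space)
    emit_after = _emission_slots(space)
    e_scaled = np.exp(log_e_scaled[0])  # [n_obs, S], includes 1/norm scaling

    n_obs = e_scaled.shape[0]
    S = space.n_states
    betas_post: list[np.ndarray] = [np.empty(0)] * len(schedule)
    b = np.ones(S)
    obs_t = n_obs - 1
    for f in range(len(schedule) - 1, -1, -1):
        if obs_t >= 0 and f == emit_after[obs_t]:
            b = b * e_scaled[obs_t]
            obs_t -= 1
        betas_post[f] = b
        name, chn, _t = schedule[f]
        b = mats[(name, chn)] @ b

    occupancy = []
    transitions = []
    for f, (name, chn, t) in enumerate(schedule):
        a_pre = alphas[f][0]
        F = mats[(name, chn)]
        P = a_pre[:, None] * F * betas_post[f][None, :]
        transitions.append(P)
        occupancy.append(P.sum(axis=1))
    occupancy.append(transitions[-1].sum(axis=0))
    return SubStepPosteriors(
        log_likelihood=float(loglik[0]),
        schedule=schedule,
        occupancy=occupancy,
        transitions=transitions,
    )
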