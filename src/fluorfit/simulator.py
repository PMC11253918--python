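"""Monte Carlo generative model of fluorosequencing reads.

A molecule is simulated fluorophore-by-fluorophore.  Before sequencing,
each label may be a dud and the N-terminus may be blocked; each Edman
cycle then applies, in a fixed order, peptide detachment, per-fluorophore
dye loss, cyclic N-terminal blocking and the Edman cleavage attempt
(which removes the current N-terminal residue, and with it any label it
carries, with probability ``1 - edman_failure`` and only when the
N-terminus is unblocked).

Observation 0 is imaged before any Edman chemistry, so a run of
``n_cycles`` cycles yields ``n_cycles + 1`` observations.  A molecule
whose fluorophores are all dark at observation 0 is never detected and is
censored from the read set; :func:`simulate_reads` keeps drawing until
the requested number of *observed* reads exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .error_model import ChannelModel, ErrorModel
from .peptide import LabeledPeptide

__all__ = [
    "EVENT_ORDER",
    "Read",
    "DyeTrack",
    "ReadSet",
    "DyeTrackSet",
    "simulate_molecule",
    "simulate_dye_tracks",
    "simulate_reads",
]

#: Within-cycle event order, shared verbatim with the HMM sub-step order so
#: that simulation and inference agree by construction.
EVENT_ORDER = ("detach", "dye_loss", "cyclic_block", "edman")


@dataclass(frozen=True)
class Read:
    """One molecule's fluorescence time series: ``intensities[ch, t]`` in
    arbitrary fluorescence units, ``t = 0`` imaged before Edman cycle 1."""

    intensities: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_observations(self) -> int:
        return self.intensities.shape[1]


@dataclass(frozen=True)
class DyeTrack:
    """Integer fluorophore-count time series, the noise-free twin of a
    :class:`Read`."""

    counts: np.ndarray

    def key(self) -> tuple[int, ...]:
        """Hashable flat representation used as a histogram key."""
        return tuple(int(v) for v in self.counts.ravel())


@dataclass
class ReadSet:
    """A homogeneous collection of reads, stored as one dense array
    ``intensities[read, ch, t]``."""

    intensities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("ReadSet intensities must be [n_reads, n_channels, n_obs]")

    @property
    def n_reads(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_observations(self) -> int:
        return self.intensities.shape[2]

    def __len__(self) -> int:
        return self.n_reads

    def __getitem__(self, i: int) -> Read:
        return Read(self.intensities[i])

    def subset(self, indices) -> "ReadSet":
        return ReadSet(self.intensities[np.asarray(indices)], meta=dict(self.meta))


@dataclass
class DyeTrackSet:
    """Dense collection of dye tracks: ``counts[read, ch, t]``."""

    counts: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return self.counts.shape[0]

    def __len__(self) -> int:
        return self.counts.shape[0]

    def __getitem__(self, i: int) -> DyeTrack:
        return DyeTrack(self.counts[i])


def _label_arrays(p: LabeledPeptide):
    positions = np.array([pos for pos, _ in p.labels], dtype=np.int64)
    channels = np.array([ch for _, ch in p.labels], dtype=np.int64)
    return positions, channels


def simulate_molecule(
    p: LabeledPeptide, m: ErrorModel, n_cycles: int, rng: np.random.Generator
) -> tuple[DyeTrack, bool]:
    """Simulate a single molecule; scalar reference implementation.

    Returns the true dye track (``counts[ch, t]`` for observations
    ``0..n_cycles``) and whether the molecule is observable (at least one
    functioning fluorophore at observation 0).
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    m = m.broadcast(p.n_channels)
    positions, channels = _label_arrays(p)
    n_ch = p.n_channels

    alive = rng.random(len(positions)) >= m.dud[channels]
    b = 1.0 if p.n_term_status == "acetylated" else m.initial_block
    blocked = rng.random() < b
    detached = False
    edman = 0

    counts = np.zeros((n_ch, n_cycles + 1), dtype=np.int64)
    np.add.at(counts[:, 0], channels[alive], 1)
    observed = counts[:, 0].sum() > 0

    for t in range(1, n_cycles + 1):
        if not detached and rng.random() < m.detach:
            detached = True
        loss_draw = rng.random(len(positions))
        alive &= ~(loss_draw < m.dye_loss[channels])
        if not blocked and rng.random() < m.cyclic_block:
            blocked = True
        if not blocked and not detached and edman < len(p.sequence):
            if rng.random() >= m.edman_failure:
                edman += 1
                alive &= positions > edman
        if not detached:
            np.add.at(counts[:, t], channels[alive], 1)
    return DyeTrack(counts), bool(observed)


def _simulate_tracks_vectorized(
    p: LabeledPeptide, m: ErrorModel, n: int, n_cycles: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n`` molecules at once; returns (counts[n, ch, t], observed[n])."""
    m = m.broadcast(p.n_channels)
    positions, channels = _label_arrays(p)
    n_ch, L = p.n_channels, len(positions)
    ch_onehot = np.zeros((L, n_ch))
    ch_onehot[np.arange(L), channels] = 1.0

    alive = rng.random((n, L)) >= m.dud[channels][None, :]
    b = 1.0 if p.n_term_status == "acetylated" else m.initial_block
    blocked = rng.random(n) < b
    detached = np.zeros(n, dtype=bool)
    edman = np.zeros(n, dtype=np.int64)

    counts = np.zeros((n, n_ch, n_cycles + 1), dtype=np.int64)
    counts[:, :, 0] = alive @ ch_onehot
    observed = counts[:, :, 0].sum(axis=1) > 0

    for t in range(1, n_cycles + 1):
        detached |= rng.random(n) < m.detach
        alive &= rng.random((n, L)) >= m.dye_loss[channels][None, :]
        blocked |= rng.random(n) < m.cyclic_block
        advance = (~blocked) & (~detached) & (rng.random(n) >= m.edman_failure)
        edman += advance & (edman < len(p.sequence))
        alive &= positions[None, :] > edman[:, None]
        counts[:, :, t] = (alive @ ch_onehot).astype(np.int64)
        counts[detached, :, t] = 0
    return counts, observed


def _observable_probability(p: LabeledPeptide, m: ErrorModel) -> float:
    m = m.broadcast(p.n_channels)
    _, channels = _label_arrays(p)
    return 1.0 - float(np.prod(m.dud[channels]))


def simulate_dye_tracks(
    p: LabeledPeptide,
    m: ErrorModel,
    n_reads: int,
    n_cycles: int,
    rng: np.random.Generator,
) -> DyeTrackSet:
    """Draw molecules until ``n_reads`` observable ones exist and return
    their true (noise-free) dye tracks.  Unobservable molecules (all
    labels dud) are censored, exactly as in a real experiment."""
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    p_obs = _observable_probability(p, m)
    if p_obs <= 1e-9:
        raise ValueError("all-dud probability ~1: no molecule would ever be observed")

    kept: list[np.ndarray] = []
    n_kept = 0
    n_drawn = 0
    while n_kept < n_reads:
        batch = max(64, int(1.2 * (n_reads - n_kept) / p_obs))
        counts, observed = _simulate_tracks_vectorized(p, m, batch, n_cycles, rng)
        n_drawn += batch
        keep = counts[observed]
        kept.append(keep)
        n_kept += keep.shape[0]
    counts = np.concatenate(kept, axis=0)[:n_reads]
    return DyeTrackSet(
        counts,
        meta={"peptide": p.render(), "n_drawn": n_drawn, "observable_prob": p_obs},
    )


def simulate_reads(
    p: LabeledPeptide,
    m: ErrorModel,
    ch: ChannelModel,
    n_reads: int,
    n_cycles: int,
    rng: np.random.Generator,
) -> ReadSet:
    """Simulate ``n_reads`` observed radiometry reads.

    Dye tracks are drawn with censoring via :func:`simulate_dye_tracks`;
    intensities are then Gaussian per channel and observation with mean
    ``bg_mu + count*mu`` and variance from the :class:`ChannelModel`
    (detached molecules emit pure background from the detachment cycle
    onward, since their counts are zero there).
    """
    if ch.n_channels != p.n_channels:
        raise ValueError(
            f"ChannelModel has {ch.n_channels} channels, peptide needs {p.n_channels}"
        )
    tracks = simulate_dye_tracks(p, m, n_reads, n_cycles, rng)
    counts = tracks.counts
    mean = ch.bg_mu[None, :, None] + counts * ch.mu[None, :, None]
    if ch.variance_mode == "linear":
        var = counts * ch.sigma[None, :, None] ** 2 + ch.bg_sigma[None, :, None] ** 2
    else:
        var = (
            np.where(counts > 0, ch.sigma[None, :, None] ** 2, 0.0)
            + ch.bg_sigma[None, :, None] ** 2
        )
    intensities = rng.normal(mean, np.sqrt(var))
    meta = dict(tracks.meta)
    meta["true_error_model"] = m.to_dict()
    return ReadSet(intensities, meta=meta)
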