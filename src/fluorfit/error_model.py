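"""Sequencing-error and emission-model parameters.

The generative model of a fluorosequencing run has six error parameters:

``edman_failure``
    Probability per cycle that Edman degradation fails to remove the
    N-terminal residue (chemistry failure; combined over TFA and PITC
    steps).
``dye_loss``
    Probability per cycle, per fluorophore, that a dye is destroyed
    (chemical destruction plus photobleaching, folded into one rate),
    per channel.
``detach``
    Probability per cycle that the whole peptide leaves the surface; the
    signal is pure background thereafter.
``dud``
    Probability that a fluorophore is dark from the start (missing or
    non-fluorescent label), per channel.  A molecule whose labels are all
    duds never appears as a read, which censors the data.
``initial_block``
    Probability that the N-terminus is chemically blocked before cycle 1.
``cyclic_block``
    Probability per cycle that the N-terminus acquires a blocking
    modification during sequencing.

Emissions are Gaussian per channel: a state with ``k`` surviving
fluorophores on channel ``ch`` emits ``Normal(bg_mu + k*mu, sqrt(k*sigma^2
+ bg_sigma^2))`` fluorescence units (variance options in
:class:`ChannelModel`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from math import comb

import numpy as np

from .peptide import LabeledPeptide

__all__ = [
    "ErrorModel",
    "ChannelModel",
    "PARAMETER_NAMES",
    "fix_for_identifiability",
    "kappa_distribution",
]

#: Canonical order of the six error parameters in vectors, reports and files.
PARAMETER_NAMES = (
    "edman_failure",
    "dye_loss",
    "detach",
    "dud",
    "initial_block",
    "cyclic_block",
)

# Fitters clamp free rates inside this open interval to avoid degenerate
# (zero-probability) likelihoods at the boundary.
RATE_EPS = 1e-9


def _as_channel_vector(value, n_channels: int, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1 and n_channels > 1:
        arr = np.repeat(arr, n_channels)
    if arr.size != n_channels:
        raise ValueError(f"{name} must be scalar or length {n_channels}, got {arr.size}")
    return arr


@dataclass(frozen=True)
class ErrorModel:
    """The six sequencing-error rates; per-fluorophore rates are per-channel.

    Scalars broadcast across channels.  ``fixed`` names parameters excluded
    from fitting (see :func:`fix_for_identifiability`).
    """

    edman_failure: float
    dye_loss: np.ndarray
    detach: float
    dud: np.ndarray
    initial_block: float = 0.0
    cyclic_block: float = 0.0
    fixed: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        dye_loss = np.atleast_1d(np.asarray(self.dye_loss, dtype=float))
        dud = np.atleast_1d(np.asarray(self.dud, dtype=float))
        if dye_loss.size != dud.size:
            n = max(dye_loss.size, dud.size)
            dye_loss = _as_channel_vector(dye_loss, n, "dye_loss")
            dud = _as_channel_vector(dud, n, "dud")
        dye_loss.flags.writeable = False
        dud.flags.writeable = False
        object.__setattr__(self, "dye_loss", dye_loss)
        object.__setattr__(self, "dud", dud)
        object.__setattr__(self, "fixed", frozenset(self.fixed))
        for name in ("edman_failure", "detach", "initial_block", "cyclic_block"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("dye_loss", "dud"):
            v = getattr(self, name)
            if np.any(v < 0.0) or np.any(v > 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        unknown = self.fixed - set(PARAMETER_NAMES)
        if unknown:
            raise ValueError(f"unknown fixed parameter names {sorted(unknown)}")

    @property
    def n_channels(self) -> int:
        return self.dye_loss.size

    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n in PARAMETER_NAMES if n not in self.fixed)

    def broadcast(self, n_channels: int) -> "ErrorModel":
        """Return a copy with per-channel vectors of the given length."""
        return replace(
            self,
            dye_loss=_as_channel_vector(self.dye_loss, n_channels, "dye_loss"),
            dud=_as_channel_vector(self.dud, n_channels, "dud"),
        )

    def to_dict(self) -> dict:
        return {
            "edman_failure": float(self.edman_failure),
            "dye_loss": [float(v) for v in self.dye_loss],
            "detach": float(self.detach),
            "dud": [float(v) for v in self.dud],
            "initial_block": float(self.initial_block),
            "cyclic_block": float(self.cyclic_block),
            "fixed": sorted(self.fixed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ErrorModel":
        return cls(
            edman_failure=d["edman_failure"],
            dye_loss=np.asarray(d["dye_loss"], dtype=float),
            detach=d["detach"],
            dud=np.asarray(d["dud"], dtype=float),
            initial_block=d.get("initial_block", 0.0),
            cyclic_block=d.get("cyclic_block", 0.0),
            fixed=frozenset(d.get("fixed", ())),
        )

    @classmethod
    def from_json(cls, path) -> "ErrorModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    # Flat parameter-vector view used by the derivative-free fitter: one
    # entry per scalar parameter, per-channel rates expanded.
    def parameter_vector(self) -> np.ndarray:
        out = []
        for name in PARAMETER_NAMES:
            v = getattr(self, name)
            out.extend(np.atleast_1d(v).tolist())
        return np.asarray(out, dtype=float)

    def parameter_labels(self) -> tuple[str, ...]:
        out = []
        for name in PARAMETER_NAMES:
            v = np.atleast_1d(getattr(self, name))
            if name in ("dye_loss", "dud") and v.size > 1:
                out.extend(f"{name}[{i}]" for i in range(v.size))
            else:
                out.append(name)
        return tuple(out)

    def with_parameter_vector(self, vec: np.ndarray) -> "ErrorModel":
        vec = np.asarray(vec, dtype=float)
        nch = self.n_channels
        e = vec[0]
        dye_loss = vec[1 : 1 + nch]
        det = vec[1 + nch]
        dud = vec[2 + nch : 2 + 2 * nch]
        b = vec[2 + 2 * nch]
        c = vec[3 + 2 * nch]
        return replace(
            self,
            edman_failure=e,
            dye_loss=dye_loss,
            detach=det,
            dud=dud,
            initial_block=b,
            cyclic_block=c,
        )


@dataclass(frozen=True)
class ChannelModel:
    """Per-channel fluorescence emission parameters (arbitrary fluorescence
    units).

    ``mu``/``sigma`` are the one-fluorophore intensity mean and s.d.;
    ``bg_sigma`` is the zero-count (background) s.d., ``bg_mu`` the
    background mean, which defaults to 0 because signal extraction
    subtracts a local background.  ``variance_mode`` selects whether the
    k-fluorophore variance is ``k*sigma^2 + bg_sigma^2`` (independent
    fluorophores, the default) or ``sigma^2 + bg_sigma^2`` for any k > 0.
    """

    mu: np.ndarray
    sigma: np.ndarray
    bg_sigma: np.ndarray
    bg_mu: np.ndarray | None = None
    variance_mode: str = "linear"

    def __post_init__(self):
        mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        n = mu.size
        sigma = _as_channel_vector(self.sigma, n, "sigma")
        bg_sigma = _as_channel_vector(self.bg_sigma, n, "bg_sigma")
        bg_mu = (
            np.zeros(n)
            if self.bg_mu is None
            else _as_channel_vector(self.bg_mu, n, "bg_mu")
        )
        for arr in (mu, sigma, bg_sigma, bg_mu):
            arr.flags.writeable = False
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "bg_sigma", bg_sigma)
        object.__setattr__(self, "bg_mu", bg_mu)
        if np.any(sigma <= 0) or np.any(bg_sigma <= 0):
            raise ValueError("sigma and bg_sigma must be positive")
        if self.variance_mode not in ("linear", "constant"):
            raise ValueError("variance_mode must be 'linear' or 'constant'")

    @property
    def n_channels(self) -> int:
        return self.mu.size

    def count_mean(self, channel: int, count) -> np.ndarray:
        return self.bg_mu[channel] + np.asarray(count) * self.mu[channel]

    def count_var(self, channel: int, count) -> np.ndarray:
        count = np.asarray(count)
        if self.variance_mode == "linear":
            return count * self.sigma[channel] ** 2 + self.bg_sigma[channel] ** 2
        return (
            np.where(count > 0, self.sigma[channel] ** 2, 0.0)
            + self.bg_sigma[channel] ** 2
        )

    def to_dict(self) -> dict:
        return {
            "mu": [float(v) for v in self.mu],
            "sigma": [float(v) for v in self.sigma],
            "bg_sigma": [float(v) for v in self.bg_sigma],
            "bg_mu": [float(v) for v in self.bg_mu],
            "variance_mode": self.variance_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelModel":
        return cls(
            mu=np.asarray(d["mu"], dtype=float),
            sigma=np.asarray(d["sigma"], dtype=float),
            bg_sigma=np.asarray(d["bg_sigma"], dtype=float),
            bg_mu=np.asarray(d["bg_mu"], dtype=float) if "bg_mu" in d else None,
            variance_mode=d.get("variance_mode", "linear"),
        )

    @classmethod
    def from_json(cls, path) -> "ChannelModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def fix_for_identifiability(m: ErrorModel, p: LabeledPeptide) -> ErrorModel:
    """Apply the one-fluorophore parameter-fixing rules.

    With a single label, fluorophore destruction and peptide detachment
    are visually indistinguishable, all-dud molecules are unobservable so
    the dud rate carries no data, and the cyclic block rate trades off
    against the Edman failure rate through the product ``e*(1-c)`` (see
    :func:`kappa_distribution`).  All three are therefore fixed at zero
    and excluded from fitting.  Peptides with two or more labels leave the
    mask unchanged.
    """
    if p.n_labels != 1:
        return m
    return replace(
        m,
        detach=0.0,
        dud=np.zeros_like(m.dud),
        cyclic_block=0.0,
        fixed=m.fixed | {"detach", "dud", "cyclic_block"},
    )


def kappa_distribution(r: int, b: float, e: float, c: float, i_max: int) -> np.ndarray:
    """Distribution of the last bright cycle for a single fluorophore.

    For a peptide whose only fluorophore sits at 1-based position ``r``,
    ``kappa[i]`` is the probability that the fluorophore's last cycle is
    cycle ``r + i`` under Edman failure rate ``e``, initial block rate
    ``b`` and cyclic block rate ``c`` (no dye loss, dud or detachment):

        kappa_i = (1-b) * C(i+r-1, i) * (1-e)^r * e^i * (1-c)^(r+i)

    Consecutive terms satisfy ``kappa_{i+1} = kappa_i * e*(1-c) *
    (i+r)/(i+1)``, so the data determine only the product ``e*(1-c)``:
    distinct ``(b, e, c)`` triples with equal ``e*(1-c)`` and matched
    ``kappa_0`` are observationally indistinguishable.
    """
    if r < 1:
        raise ValueError("fluorophore position r must be >= 1")
    i = np.arange(i_max + 1)
    if e == 0.0:
        kappa = np.zeros(i_max + 1)
        kappa[0] = (1.0 - b) * (1.0 - c) ** r
        return kappa
    log_binom = np.array([0.0] + [np.log(comb(int(j) + r - 1, int(j))) for j in i[1:]])
    log_kappa = (
        np.log1p(-b)
        + log_binom
        + r * np.log1p(-e)
        + i * np.log(e)
        + (r + i) * np.log1p(-c)
    )
    return np.exp(log_kappa)
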