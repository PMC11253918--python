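"""Labeled-peptide notation and the quantities the sequencing model needs.

Peptides are written the way fluorosequencing figures caption them: an
optional N-terminal prefix (``NH2-``, ``fmoc-`` or ``ac-``), a run of
residue tokens (single letters, or ``{...}`` for non-standard residues such
as azido-lysine ``{azK}``), each optionally followed by ``*`` marking a
fluorescent label, and an optional trailing ``|`` indicating the sequence
was truncated after the last labeled residue.  A label may carry an
explicit dye-channel index as ``*1``; a bare ``*`` means channel 0.

``fmoc-`` denotes the Fmoc protecting group, which is removed before
sequencing, so it is equivalent to a free N-terminus for modeling purposes.
``ac-`` denotes N-terminal acetylation, which permanently blocks Edman
degradation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabeledPeptide", "PeptideParseError", "parse_peptide", "label_counts"]


class PeptideParseError(ValueError):
    """Raised for malformed peptide notation; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at character {position})")
        self.position = position


_PREFIXES = {"NH2-": "free", "fmoc-": "free", "ac-": "acetylated"}


@dataclass(frozen=True)
class LabeledPeptide:
    """A peptide with fluorophore labels at known positions.

    Parameters
    ----------
    sequence:
        Residue codes, N- to C-terminal.  Positions are 1-based.
    labels:
        ``(position, channel)`` pairs, strictly increasing in position.
    n_term_status:
        ``"free"`` or ``"acetylated"`` (Fmoc counts as free since the
        protecting group is removed before sequencing).
    truncated:
        Whether the notation ended with ``|`` (sequence cut after the last
        labeled residue).
    """

    sequence: tuple[str, ...]
    labels: tuple[tuple[int, int], ...]
    n_term_status: str = "free"
    truncated: bool = False
    notation: str = field(default="", compare=False)

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise ValueError("empty peptide sequence")
        if len(self.labels) == 0:
            raise ValueError("peptide has no labels and would be unobservable")
        positions = [pos for pos, _ in self.labels]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("label positions must be strictly increasing")
        if positions[0] < 1 or positions[-1] > len(self.sequence):
            raise ValueError("label position outside sequence")
        channels = sorted({ch for _, ch in self.labels})
        if channels != list(range(len(channels))):
            raise ValueError(f"channel indices must be contiguous from 0, got {channels}")
        if self.n_term_status not in ("free", "acetylated"):
            raise ValueError(f"unknown N-terminal status {self.n_term_status!r}")

    @property
    def n_channels(self) -> int:
        return max(ch for _, ch in self.labels) + 1

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    @property
    def last_label_position(self) -> int:
        return self.labels[-1][0]

    def labels_on_channel(self, channel: int) -> tuple[int, ...]:
        """1-based positions of the labels on one channel."""
        return tuple(pos for pos, ch in self.labels if ch == channel)

    def render(self) -> str:
        """Canonical notation string; ``parse_peptide(render())`` round-trips."""
        prefix = "ac-" if self.n_term_status == "acetylated" else "NH2-"
        by_pos = {pos: ch for pos, ch in self.labels}
        parts = [prefix]
        for i, res in enumerate(self.sequence, start=1):
            parts.append(res if len(res) == 1 else "{" + res + "}")
            if i in by_pos:
                ch = by_pos[i]
                parts.append("*" if ch == 0 else f"*{ch}")
        if self.truncated:
            parts.append("|")
        return "".join(parts)


def parse_peptide(notation: str) -> LabeledPeptide:
    """Parse figure-style peptide notation into a :class:`LabeledPeptide`.

    >>> p = parse_peptide("NH2-G{azK}*AG{azK}*|")
    >>> len(p.sequence), p.labels
    (5, ((2, 0), (5, 0)))
    """
    text = notation.strip()
    n_term_status = "free"
    offset = 0
    for prefix, status in _PREFIXES.items():
        if text.startswith(prefix):
            n_term_status = status
            offset = len(prefix)
            break

    sequence: list[str] = []
    labels: list[tuple[int, int]] = []
    truncated = False
    i = offset
    while i < len(text):
        c = text[i]
        if c == "|":
            if i != len(text) - 1:
                raise PeptideParseError("'|' is only allowed at the end", i)
            truncated = True
            i += 1
        elif c == "{":
            end = text.find("}", i)
            if end < 0:
                raise PeptideParseError("unclosed '{'", i)
            token = text[i + 1 : end]
            if not token:
                raise PeptideParseError("empty '{}' residue token", i)
            sequence.append(token)
            i = end + 1
        elif c == "*":
            if not sequence:
                raise PeptideParseError("'*' must follow a residue", i)
            pos = len(sequence)
            if labels and labels[-1][0] == pos:
                raise PeptideParseError("residue labeled twice", i)
            i += 1
            j = i
            while j < len(text) and text[j].isdigit():
                j += 1
            channel = int(text[i:j]) if j > i else 0
            labels.append((pos, channel))
            i = j
        elif c.isalpha():
            sequence.append(c)
            i += 1
        else:
            raise PeptideParseError(f"unexpected character {c!r}", i)

    if not sequence:
        raise PeptideParseError("empty peptide sequence", len(text))
    if not labels:
        raise PeptideParseError("peptide has no labels and would be unobservable", len(text))
    try:
        return LabeledPeptide(
            sequence=tuple(sequence),
            labels=tuple(labels),
            n_term_status=n_term_status,
            truncated=truncated,
            notation=text,
        )
    except ValueError as exc:
        raise PeptideParseError(str(exc), len(text)) from exc


def label_counts(p: LabeledPeptide) -> np.ndarray:
    """Number of labels on each channel, as an integer vector of length
    ``p.n_channels``."""
    counts = np.zeros(p.n_channels, dtype=np.int64)
    for _, ch in p.labels:
        counts[ch] += 1
    return counts
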