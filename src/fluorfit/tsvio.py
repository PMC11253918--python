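"""Radiometry and dye-track TSV files.

The dialect is three bare header lines — number of observations per read,
number of channels, number of reads — followed by one row per read of
``n_observations * n_channels`` tab-separated values ordered
observation-major then channel (column ``t * n_channels + c``).  Floats
are written with Python's shortest round-trip representation, so a
write/read cycle is lossless; dye tracks use the same layout with plain
integers.
"""

from __future__ import annotations

import numpy as np

from .simulator import DyeTrackSet, ReadSet

__all__ = [
    "read_radiometry",
    "write_radiometry",
    "read_dye_tracks",
    "write_dye_tracks",
]


class TsvFormatError(ValueError):
    """Malformed radiometry/dye-track file; message carries the line number."""


def _write(path, data: np.ndarray, fmt) -> None:
    n_reads, n_channels, n_obs = data.shape
    with open(path, "w") as fh:
        fh.write(f"{n_obs}\n{n_channels}\n{n_reads}\n")
        for r in range(n_reads):
            row = data[r].T.ravel()  # observation-major, then channel
            fh.write("\t".join(fmt(v) for v in row))
            fh.write("\n")


def _read(path, cast, dtype) -> tuple[np.ndarray, int, int]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    header = []
    for i in range(3):
        if i >= len(lines):
            raise TsvFormatError(f"{path}: truncated header at line {i + 1}")
        try:
            header.append(int(lines[i].strip()))
        except ValueError as exc:
            raise TsvFormatError(
                f"{path}: non-integer header field at line {i + 1}: {lines[i]!r}"
            ) from exc
    n_obs, n_channels, n_reads = header
    if n_obs < 1 or n_channels < 1 or n_reads < 0:
        raise TsvFormatError(f"{path}: implausible header {header}")
    body = [ln for ln in lines[3:] if ln.strip() != ""]
    if len(body) != n_reads:
        raise TsvFormatError(
            f"{path}: header says {n_reads} reads, body has {len(body)} "
            f"(first problem at line {3 + min(len(body), n_reads) + 1})"
        )
    data = np.empty((n_reads, n_channels, n_obs), dtype=dtype)
    width = n_obs * n_channels
    for r, line in enumerate(body):
        fields = line.split("\t")
        if len(fields) != width:
            raise TsvFormatError(
                f"{path}: line {r + 4} has {len(fields)} fields, expected {width}"
            )
        try:
            row = np.array([cast(f) for f in fields], dtype=dtype)
        except ValueError as exc:
            raise TsvFormatError(f"{path}: non-numeric field at line {r + 4}") from exc
        data[r] = row.reshape(n_obs, n_channels).T
    return data, n_channels, n_obs


def write_radiometry(rs: ReadSet, path) -> None:
    _write(path, rs.intensities, lambda v: repr(float(v)))


def read_radiometry(path) -> ReadSet:
    data, _, _ = _read(path, float, float)
    return ReadSet(data, meta={"source": str(path)})


def write_dye_tracks(ts: DyeTrackSet, path) -> None:
    _write(path, ts.counts, lambda v: str(int(v)))


def read_dye_tracks(path) -> DyeTrackSet:
    data, _, _ = _read(path, int, np.int64)
    return DyeTrackSet(data, meta={"source": str(path)})
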