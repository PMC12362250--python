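"""Raw-signal extraction via the basecaller move table, for comparative plots.

The basecaller's move table assigns each basecalled nucleotide a contiguous
block of raw signal samples whose length is a positive multiple of the model
stride (6 for the RNA004 chemistry).  Per base, six data points with equal
spacing are subsampled so dwell-time variation cancels; only aligned
reference positions (matches and mismatches) enter the per-position track.
Two samples are overlaid after a single vertical shift: the median over
positions of the per-position difference in median signal, added to the
mutant sample's signals.  Signal units are passed through untransformed.

Signals arrive as NPZ/TSV sidecars mapping read_id -> (signal array, move
vector); reads lacking a complete move table are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .align import INSERTION, ReadAlignment
from .refio import ReferenceSet

logger = logging.getLogger(__name__)

STRIDE = 6
N_SUBSAMPLE = 6


@dataclass
class MoveSegmentation:
    """Per-base signal segments of one read, in basecall order."""

    read_id: str
    stride: int
    segments: list[tuple[int, int]]  # half-open [start, end) into the signal

    def __len__(self) -> int:
        return len(self.segments)


def segment_signal(
    moves: np.ndarray, signal: np.ndarray, stride: int = STRIDE, read_id: str = "read"
) -> MoveSegmentation:
    """Turn a move vector into per-base signal segments.

    ``moves`` has one 0/1 entry per stride-sized signal block; a 1 starts a
    new base.  Segment lengths are therefore positive multiples of the
    stride, and segments tile the signal contiguously.
    """
    moves = np.asarray(moves).astype(int)
    signal = np.asarray(signal)
    if moves.size == 0 or moves[0] != 1:
        raise ValueError("move vector must be non-empty and start with 1")
    if not np.isin(moves, (0, 1)).all():
        raise ValueError("move vector entries must be 0 or 1")
    if signal.size != moves.size * stride:
        raise ValueError(
            f"signal length {signal.size} != stride {stride} x {moves.size} moves"
        )
    starts = np.flatnonzero(moves == 1) * stride
    ends = np.append(starts[1:], signal.size)
    return MoveSegmentation(read_id, stride, list(zip(starts.tolist(), ends.tolist())))


def subsample_six(segment: np.ndarray) -> np.ndarray:
    """Six equally spaced values from a segment of length 6m: indices floor(i*L/6)."""
    segment = np.asarray(segment)
    L = segment.size
    if L <= 0 or L % N_SUBSAMPLE != 0:
        raise ValueError(f"segment length {L} is not a positive multiple of 6")
    idx = (np.arange(N_SUBSAMPLE) * L) // N_SUBSAMPLE
    return segment[idx]


@dataclass
class SignalTrack:
    """Per body-position subsampled signal values of one sample on one tRNA."""

    ref_id: str
    values: dict[int, list[np.ndarray]] = field(default_factory=dict)  # body_pos -> per-read arrays of 6

    def positions(self) -> list[int]:
        return sorted(self.values)

    def median(self, body_pos: int) -> float:
        return float(np.median(np.concatenate(self.values[body_pos])))

    def sd(self, body_pos: int) -> float:
        return float(np.std(np.concatenate(self.values[body_pos])))

    def summary(self) -> dict[int, tuple[float, float]]:
        return {p: (self.median(p), self.sd(p)) for p in self.positions()}


def build_signal_tracks(
    alns: Iterable[ReadAlignment],
    segmentations: Mapping[str, MoveSegmentation],
    signals: Mapping[str, np.ndarray],
    refs: ReferenceSet,
) -> dict[str, SignalTrack]:
    """Per-reference signal tracks from filtered alignments.

    For each aligned (match or mismatch) read position within the tRNA body,
    the read's signal segment is subsampled to six values.  Insertions are
    dropped (no reference position) and deleted reference positions receive
    nothing from that read.  Reads without a segmentation are skipped.
    """
    tracks: dict[str, SignalTrack] = {}
    for aln in alns:
        seg = segmentations.get(aln.read_id)
        sig = signals.get(aln.read_id)
        if seg is None or sig is None:
            logger.warning("read %s lacks signal/move data; skipped", aln.read_id)
            continue
        ref = refs[aln.ref_id]
        track = tracks.setdefault(aln.ref_id, SignalTrack(ref_id=aln.ref_id))
        for read_pos, ref_pos, op in aln.pairs:
            if op == INSERTION or ref_pos is None or read_pos is None:
                continue
            body = ref.full_to_body(ref_pos)
            if body is None:
                continue
            if read_pos >= len(seg.segments):
                raise ValueError(
                    f"read {aln.read_id}: position {read_pos} beyond move table"
                )
            start, end = seg.segments[read_pos]
            track.values.setdefault(body, []).append(subsample_six(sig[start:end]))
    return tracks


def vertical_shift(track_a: SignalTrack, track_b: SignalTrack) -> float:
    """Offset between two samples on one tRNA: the median over common
    positions of (median_a - median_b); add the result to sample b's signals
    for overlay."""
    common = sorted(set(track_a.positions()) & set(track_b.positions()))
    if not common:
        raise ValueError("no common covered positions between tracks")
    diffs = [track_a.median(p) - track_b.median(p) for p in common]
    return float(np.median(diffs))


# --- sidecar I/O -------------------------------------------------------------


def write_signal_npz(
    path: str | Path,
    signals: Mapping[str, np.ndarray],
    moves: Mapping[str, np.ndarray],
) -> None:
    """Bundle signals and move vectors into one NPZ sidecar."""
    arrays: dict[str, np.ndarray] = {}
    for read_id, sig in signals.items():
        arrays[f"signal/{read_id}"] = np.asarray(sig)
        arrays[f"moves/{read_id}"] = np.asarray(moves[read_id])
    np.savez(str(path), **arrays)


def read_signal_npz(path: str | Path) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    signals: dict[str, np.ndarray] = {}
    moves: dict[str, np.ndarray] = {}
    with np.load(str(path)) as data:
        for key in data.files:
            kind, _, read_id = key.partition("/")
            if kind == "signal":
                signals[read_id] = data[key]
            elif kind == "moves":
                moves[read_id] = data[key]
    return signals, moves


def plot_signal_overlay(
    track_a: SignalTrack,
    track_b: SignalTrack,
    label_a: str = "wt",
    label_b: str = "mutant",
    shift: float | None = None,
    ax=None,
):
    """Overlay two samples' per-position median signal with +-1 SD bands.

    The vertical shift (computed if not given) is added to sample b.
    """
    import matplotlib.pyplot as plt

    if shift is None:
        shift = vertical_shift(track_a, track_b)
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    for track, label, offset, color in (
        (track_a, label_a, 0.0, "tab:blue"),
        (track_b, label_b, shift, "tab:orange"),
    ):
        pos = np.array(track.positions())
        med = np.array([track.median(p) for p in pos]) + offset
        sd = np.array([track.sd(p) for p in pos])
        ax.plot(pos, med, label=label, color=color)
        ax.fill_between(pos, med - sd, med + sd, alpha=0.25, color=color)
    ax.set_xlabel("tRNA body position")
    ax.set_ylabel("signal (a.u.)")
    ax.legend()
    return ax
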