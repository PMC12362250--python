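"""Local read-to-reference alignment and the three-rule alignment filter.

Every read is aligned all-against-all to the adapter-flanked references with
an affine-gap Smith-Waterman-Gotoh local aligner, then filtered:

1. per read, keep only the reference(s) tied at the highest alignment score;
2. drop reads whose best score is below ``min_as`` (default 50);
3. keep full-length reads only, where full length means the alignment's
   reference span covers the whole tRNA body (configurable end slack).

A gap of length L costs ``gap_open + (L-1)*gap_extend`` (the first gapped
base pays the open penalty).  Tie-breaks are fixed so outputs are
reproducible: the traceback starts at the maximal cell with the smallest
reference end, then smallest read end, and prefers stop > diagonal >
deletion > insertion at equal scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from numba import njit

from .refio import Reference, ReferenceSet, canonicalize

logger = logging.getLogger(__name__)

MATCH, MISMATCH, INSERTION, DELETION = "=", "X", "I", "D"

NEG_INF = np.int32(-(2**30))


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap local-alignment scores; penalties are non-positive."""

    match: int = 2
    mismatch: int = -1
    gap_open: int = -2
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("penalties must be <= 0")


@dataclass
class ReadAlignment:
    """One read-to-reference local alignment.

    ``pairs`` holds (read_pos, ref_pos, op) with 0-based coordinates and
    ``None`` on the gapped side; ``ref_span``/``read_span`` are half-open.
    """

    read_id: str
    ref_id: str
    score: int
    pairs: list[tuple[int | None, int | None, str]]
    ref_span: tuple[int, int]
    read_span: tuple[int, int]
    full_length: bool = False
    multi_reference: bool = False

    @property
    def cigar(self) -> str:
        runs: list[tuple[str, int]] = []
        for _, _, op in self.pairs:
            if runs and runs[-1][0] == op:
                runs[-1] = (op, runs[-1][1] + 1)
            else:
                runs.append((op, 1))
        return "".join(f"{n}{op}" for op, n in runs)


@njit(cache=True)
def _gotoh_fill(read_c, ref_c, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n = read_c.shape[0]
    m = ref_c.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG_INF, dtype=np.int32)
    ptr_h = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 E, 3 F
    ptr_e = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 opened, 1 extended
    ptr_f = np.zeros((n + 1, m + 1), dtype=np.int8)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + gap_open
            e_ext = E[i, j - 1] + gap_extend
            if e_ext > e_open:
                E[i, j] = e_ext
                ptr_e[i, j] = 1
            else:
                E[i, j] = e_open
                ptr_e[i, j] = 0
            f_open = H[i - 1, j] + gap_open
            f_ext = F[i - 1, j] + gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                ptr_f[i, j] = 1
            else:
                F[i, j] = f_open
                ptr_f[i, j] = 0
            s = match if read_c[i - 1] == ref_c[j - 1] else mismatch
            diag = H[i - 1, j - 1] + s
            val = np.int32(0)
            p = np.int8(0)
            if diag > val:
                val = diag
                p = 1
            if E[i, j] > val:
                val = E[i, j]
                p = 2
            if F[i, j] > val:
                val = F[i, j]
                p = 3
            H[i, j] = val
            ptr_h[i, j] = p
            # best cell: maximal H, ties -> smallest ref end j, then read end i
            if val > best or (val == best and (j < bj or (j == bj and i < bi))):
                best = val
                bi = i
                bj = j
    return best, bi, bj, ptr_h, ptr_e, ptr_f


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def local_align(
    read: str,
    ref: str,
    scheme: ScoringScheme = ScoringScheme(),
    read_id: str = "read",
    ref_id: str = "ref",
) -> ReadAlignment:
    """Optimal affine-gap local alignment of ``read`` against ``ref``."""
    read = canonicalize(read)
    ref = canonicalize(ref)
    if not read or not ref:
        raise ValueError("cannot align empty sequences")
    best, bi, bj, ptr_h, ptr_e, ptr_f = _gotoh_fill(
        _encode(read),
        _encode(ref),
        np.int32(scheme.match),
        np.int32(scheme.mismatch),
        np.int32(scheme.gap_open),
        np.int32(scheme.gap_extend),
    )
    pairs: list[tuple[int | None, int | None, str]] = []
    i, j = bi, bj
    if best > 0:
        state = "H"
        while True:
            if state == "H":
                p = ptr_h[i, j]
                if p == 0:
                    break
                if p == 1:
                    op = MATCH if read[i - 1] == ref[j - 1] else MISMATCH
                    pairs.append((i - 1, j - 1, op))
                    i -= 1
                    j -= 1
                elif p == 2:
                    state = "E"
                else:
                    state = "F"
            elif state == "E":  # gap consuming reference (deletion from read)
                opened = ptr_e[i, j] == 0
                pairs.append((None, j - 1, DELETION))
                j -= 1
                if opened:
                    state = "H"
            else:  # F: gap consuming read (insertion)
                opened = ptr_f[i, j] == 0
                pairs.append((i - 1, None, INSERTION))
                i -= 1
                if opened:
                    state = "H"
    pairs.reverse()
    return ReadAlignment(
        read_id=read_id,
        ref_id=ref_id,
        score=int(best),
        pairs=pairs,
        ref_span=(j, bj),
        read_span=(i, bi),
    )


def rescore(pairs, read: str, ref: str, scheme: ScoringScheme = ScoringScheme()) -> int:
    """Re-score an alignment path; used to assert the AS invariant."""
    read = canonicalize(read)
    ref = canonicalize(ref)
    total = 0
    prev_op = None
    for rp, fp, op in pairs:
        if op in (MATCH, MISMATCH):
            total += scheme.match if read[rp] == ref[fp] else scheme.mismatch
        else:
            total += scheme.gap_extend if prev_op == op else scheme.gap_open
        prev_op = op
    return total


def is_full_length(
    aln: ReadAlignment, ref: Reference, end_slack: int = 0
) -> bool:
    """True when the alignment's reference span covers the whole tRNA body.

    ``end_slack`` allows up to that many uncovered body bases at each end
    (default 0: every body position must be consumed by the alignment).
    """
    body_start0 = ref.adapter5_len
    body_end0 = len(ref.sequence) - ref.adapter3_len  # half-open
    start, end = aln.ref_span
    return start <= body_start0 + end_slack and end >= body_end0 - end_slack


def align_all(
    reads: Mapping[str, str] | Iterable[tuple[str, str]],
    refs: ReferenceSet,
    scheme: ScoringScheme = ScoringScheme(),
    end_slack: int = 0,
) -> list[ReadAlignment]:
    """All-against-all read-to-reference alignments with full-length flags."""
    items = list(reads.items()) if isinstance(reads, Mapping) else list(reads)
    if not items or len(refs) == 0:
        raise ValueError("need at least one read and one reference")
    out: list[ReadAlignment] = []
    for read_id, seq in items:
        for ref in refs:
            aln = local_align(seq, ref.sequence, scheme, read_id=read_id, ref_id=ref.ref_id)
            aln.full_length = is_full_length(aln, ref, end_slack)
            out.append(aln)
    return out


def filter_alignments(
    alns: Iterable[ReadAlignment],
    min_as: int = 50,
    audit: list | None = None,
) -> list[ReadAlignment]:
    """Apply the three-rule filter: best-AS per read, AS >= min_as, full length.

    Reads tied at their maximal score on several references keep all tied
    alignments, flagged ``multi_reference``.  When ``audit`` is a list, one
    (read_id, ref_id, AS, rule_failed) tuple is appended per input alignment.
    """
    by_read: dict[str, list[ReadAlignment]] = {}
    for aln in alns:
        by_read.setdefault(aln.read_id, []).append(aln)
    kept: list[ReadAlignment] = []
    for read_id, group in by_read.items():
        best = max(a.score for a in group)
        tied = [a for a in group if a.score == best]
        multi = len(tied) > 1
        for a in group:
            if a.score < best:
                if audit is not None:
                    audit.append((a.read_id, a.ref_id, a.score, "not_best_as"))
                continue
            if a.score < min_as:
                if audit is not None:
                    audit.append((a.read_id, a.ref_id, a.score, "as_below_min"))
                continue
            if not a.full_length:
                if audit is not None:
                    audit.append((a.read_id, a.ref_id, a.score, "not_full_length"))
                continue
            a.multi_reference = multi
            if audit is not None:
                audit.append((a.read_id, a.ref_id, a.score, "pass"))
            kept.append(a)
    return kept


def audit_frame(audit: list) -> pd.DataFrame:
    return pd.DataFrame(audit, columns=["read_id", "ref_id", "AS", "rule_failed"])


# --- SAM interop -------------------------------------------------------------


def write_alignments_sam(
    alns: Iterable[ReadAlignment],
    reads: Mapping[str, str],
    refs: ReferenceSet,
    path: str | Path,
) -> None:
    """Write alignments as SAM records with CIGAR and AS tags."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": r.ref_id, "LN": len(r.sequence)} for r in refs],
    }
    tid = {r.ref_id: k for k, r in enumerate(refs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alns:
            a = pysam.AlignedSegment(out.header)
            a.query_name = aln.read_id
            seq = canonicalize(reads[aln.read_id])
            a.query_sequence = seq
            a.flag = 0
            a.reference_id = tid[aln.ref_id]
            a.reference_start = aln.ref_span[0]
            cigar = aln.cigar
            rs, re_ = aln.read_span
            pre = f"{rs}S" if rs else ""
            post = f"{len(seq) - re_}S" if len(seq) - re_ else ""
            a.cigarstring = pre + cigar + post
            a.mapping_quality = 60
            a.set_tag("AS", aln.score)
            out.write(a)


def load_alignments_sam(path: str | Path, refs: ReferenceSet, end_slack: int = 0) -> list[ReadAlignment]:
    """Load pre-aligned reads (CIGAR + AS tag); the stored AS is trusted.

    Reverse-strand records are discarded with a warning: direct RNA reads are
    single-stranded and only forward-orientation alignments are meaningful.
    """
    import pysam

    out: list[ReadAlignment] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as f:
        for rec in f.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            if rec.is_reverse:
                logger.warning("discarding reverse-strand read %s", rec.query_name)
                continue
            pairs: list[tuple[int | None, int | None, str]] = []
            for rp, fp in rec.get_aligned_pairs():
                if rp is None:
                    pairs.append((None, fp, DELETION))
                elif fp is None:
                    if rec.cigartuples and _pos_is_softclip(rec, rp):
                        continue
                    pairs.append((rp, None, INSERTION))
                else:
                    ref = refs[rec.reference_name]
                    op = MATCH if canonicalize(rec.query_sequence)[rp] == ref.sequence[fp] else MISMATCH
                    pairs.append((rp, fp, op))
            aln = ReadAlignment(
                read_id=rec.query_name,
                ref_id=rec.reference_name,
                score=int(rec.get_tag("AS")),
                pairs=pairs,
                ref_span=(rec.reference_start, rec.reference_end),
                read_span=(rec.query_alignment_start, rec.query_alignment_end),
            )
            aln.full_length = is_full_length(aln, refs[rec.reference_name], end_slack)
            out.append(aln)
    return out


def _pos_is_softclip(rec, read_pos: int) -> bool:
    start = rec.query_alignment_start
    end = rec.query_alignment_end
    return read_pos < start or read_pos >= end
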