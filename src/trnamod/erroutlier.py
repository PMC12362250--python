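"""Outlier calling on per-position basecalling-error scores.

An external error profiler (run on the two samples' aligned reads) reports a
single non-negative score per reference position; modified positions distort
basecalling and inflate it.  Calls use Tukey's fences: a position is an
outlier when its score strictly exceeds Q3 + k*IQR (k = 1.5 by default),
and is only reported when the score also clears an absolute floor
(>= 10 by default, calibrated on the error-score distribution of non-U
positions).  This module ingests the profiler's table; it does not
reimplement the error statistic.  A clearly non-equivalent internal
fallback score (arcsine-stabilized per-site error-rate difference between
two samples' alignments) is provided for self-contained runs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .align import INSERTION, MATCH, ReadAlignment
from .refio import ReferenceSet

logger = logging.getLogger(__name__)

TUKEY_K = 1.5
SCORE_FLOOR = 10.0


@dataclass(frozen=True)
class ErrorScore:
    ref_id: str
    body_position: int
    canonical_base: str
    score: float


@dataclass
class ErrorScoreTable:
    rows: list[ErrorScore]

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


def load_error_table(
    tsv_path: str | Path,
    refs: ReferenceSet,
    columns: dict[str, str] | None = None,
    positions_are_full: bool = False,
) -> ErrorScoreTable:
    """Load a per-position error-score TSV.

    ``columns`` maps the canonical names (ref_id, position, score) to the
    file's column names so arbitrary profiler outputs can be ingested.  With
    ``positions_are_full`` the file's positions are 1-based on the
    adapter-flanked sequence and are converted to body coordinates; adapter
    positions are excluded.  Malformed rows (unknown reference, negative or
    non-finite score, out-of-range position) are dropped with a log entry.
    """
    colmap = {"ref_id": "ref_id", "position": "position", "score": "score"}
    if columns:
        colmap.update(columns)
    df = pd.read_csv(tsv_path, sep="\t")
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ValueError(f"error table missing columns {missing}")
    rows: list[ErrorScore] = []
    seen: set[tuple[str, int]] = set()
    for rec in df.itertuples(index=False):
        ref_id = str(getattr(rec, colmap["ref_id"]))
        if ref_id not in refs:
            logger.warning("error row for unknown reference %s dropped", ref_id)
            continue
        ref = refs[ref_id]
        try:
            pos = int(getattr(rec, colmap["position"]))
            score = float(getattr(rec, colmap["score"]))
        except (TypeError, ValueError):
            logger.warning("malformed error row %r dropped", rec)
            continue
        if not math.isfinite(score) or score < 0:
            logger.warning("dropping %s:%d with invalid score %r", ref_id, pos, score)
            continue
        if positions_are_full:
            body = ref.full_to_body(pos - 1)
            if body is None:
                continue  # adapter region
            pos = body
        if not 1 <= pos <= ref.body_len:
            logger.warning("error row %s:%d outside body dropped", ref_id, pos)
            continue
        if (ref_id, pos) in seen:
            logger.warning("duplicate error row %s:%d dropped", ref_id, pos)
            continue
        seen.add((ref_id, pos))
        rows.append(ErrorScore(ref_id, pos, ref.body_base(pos), score))
    if not rows:
        raise ValueError(f"no parseable rows in {tsv_path}")
    return ErrorScoreTable(rows)


def tukey_threshold(scores, k: float = TUKEY_K) -> float:
    """Tukey's fence Q3 + k*(Q3 - Q1) with linear-interpolation quantiles."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 4:
        raise ValueError("Tukey threshold needs at least 4 values")
    q1, q3 = np.quantile(scores, [0.25, 0.75], method="linear")
    return float(q3 + k * (q3 - q1))


@dataclass(frozen=True)
class OutlierCall:
    ref_id: str
    body_position: int
    canonical_base: str
    score: float
    threshold: float
    is_outlier: bool
    passed_floor: bool

    @property
    def reported(self) -> bool:
        return self.is_outlier and self.passed_floor


def call_outliers(
    table: ErrorScoreTable,
    k: float = TUKEY_K,
    score_floor: float = SCORE_FLOOR,
    scope: Literal["global", "per_base"] = "global",
) -> list[OutlierCall]:
    """Tukey's-fences calls over the chosen score population.

    ``scope='global'`` pools every position of every tRNA into one fence;
    ``'per_base'`` computes a fence per canonical base identity.  A call is
    reported only when score > fence (strict) AND score >= score_floor.
    """
    if len(table) == 0:
        raise ValueError("empty error-score table")
    groups: dict[str, list[ErrorScore]] = {}
    for row in table:
        key = row.canonical_base if scope == "per_base" else "__all__"
        groups.setdefault(key, []).append(row)
    out: list[OutlierCall] = []
    for key, rows in groups.items():
        if len(rows) < 4:
            raise ValueError(f"scope population {key!r} has fewer than 4 scores")
        fence = tukey_threshold([r.score for r in rows], k=k)
        for r in rows:
            out.append(
                OutlierCall(
                    r.ref_id,
                    r.body_position,
                    r.canonical_base,
                    r.score,
                    fence,
                    is_outlier=r.score > fence,
                    passed_floor=r.score >= score_floor,
                )
            )
    out.sort(key=lambda c: (c.ref_id, c.body_position))
    return out


def outlier_frame(calls: Iterable[OutlierCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ref_id": c.ref_id,
                "body_pos": c.body_position,
                "base": c.canonical_base,
                "score": c.score,
                "threshold": c.threshold,
                "is_outlier": c.is_outlier,
                "passed_floor": c.passed_floor,
                "reported": c.reported,
            }
            for c in calls
        ]
    )


def write_outliers(calls: Iterable[OutlierCall], path: str | Path) -> None:
    outlier_frame(calls).to_csv(path, sep="\t", index=False)


# --- internal fallback error score ------------------------------------------


def fallback_error_scores(
    alns_a: Iterable[ReadAlignment],
    alns_b: Iterable[ReadAlignment],
    refs: ReferenceSet,
    scale: float = 100.0,
) -> ErrorScoreTable:
    """Self-contained per-site error score from two samples' alignments.

    For each body position the per-read error rate (mismatch + insertion +
    deletion over reads covering the position) is computed in both samples;
    the score is scale * |asin(sqrt(rate_a)) - asin(sqrt(rate_b))| (arcsine
    variance stabilization).  This is NOT equivalent to any external error
    profiler's statistic; it exists so the outlier caller can run without
    one.
    """

    def rates(alns) -> dict[tuple[str, int], tuple[int, int]]:
        acc: dict[tuple[str, int], tuple[int, int]] = {}
        for aln in alns:
            ref = refs[aln.ref_id]
            for read_pos, ref_pos, op in aln.pairs:
                if op == INSERTION:
                    continue  # no reference position to attribute
                body = ref.full_to_body(ref_pos)
                if body is None:
                    continue
                err, tot = acc.get((aln.ref_id, body), (0, 0))
                acc[(aln.ref_id, body)] = (err + (op != MATCH), tot + 1)
        return acc

    ra, rb = rates(alns_a), rates(alns_b)
    rows: list[ErrorScore] = []
    for key in sorted(set(ra) & set(rb)):
        ea, ta = ra[key]
        eb, tb = rb[key]
        if ta == 0 or tb == 0:
            continue
        score = scale * abs(
            math.asin(math.sqrt(ea / ta)) - math.asin(math.sqrt(eb / tb))
        )
        ref_id, body = key
        rows.append(ErrorScore(ref_id, body, refs[ref_id].body_base(body), score))
    return ErrorScoreTable(rows)
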