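"""De novo pseudouridine calling from per-site score distributions.

The on-label statistic is the per-site modification fraction: the share of
reads whose prediction score strictly exceeds a high-confidence threshold
(default 204 = 255*0.80), a proxy for modification stoichiometry.  Sites
with fraction >= 0.2 (default) are called modified.  The denominator is
configurable: ``matched`` counts all filtered reads matching the position
(treating matched-but-unscored reads, whose scores fell below the 5%
emission cutoff, as unmodified) while ``scored`` counts emitted scores only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .modscores import SiteScoreTable
from .refio import AnnotationTable

logger = logging.getLogger(__name__)

HIGH_THRESHOLD = 204  # 255 * 0.80
FRACTION_CUTOFF = 0.2
MIN_SITE_COVERAGE = 20

Denominator = Literal["matched", "scored"]


@dataclass(frozen=True)
class FractionRecord:
    ref_id: str
    body_position: int
    fraction: float
    n_high: int
    n_total: int
    call: bool = False


def site_fraction(
    ref_id: str,
    body_position: int,
    site,
    high_threshold: int = HIGH_THRESHOLD,
    denominator: Denominator = "matched",
) -> FractionRecord | None:
    """Modification fraction of one site: N(scores > threshold) / N(reads).

    The comparison is strictly greater-than.  Returns None (with a log
    entry) when the chosen denominator is zero.
    """
    n_high = sum(1 for s in site.scores if s > high_threshold)
    n_total = site.n_matched if denominator == "matched" else site.n_scored
    if n_total <= 0:
        logger.info("site %s:%d skipped: zero %s denominator", ref_id, body_position, denominator)
        return None
    return FractionRecord(ref_id, body_position, n_high / n_total, n_high, n_total)


def site_fractions(
    table: SiteScoreTable,
    high_threshold: int = HIGH_THRESHOLD,
    denominator: Denominator = "matched",
    min_coverage: int = MIN_SITE_COVERAGE,
) -> list[FractionRecord]:
    """Fractions for every canonical-base site with enough matched reads."""
    out: list[FractionRecord] = []
    for (ref_id, pos), site in sorted(table.sites.items()):
        if site.n_matched < min_coverage:
            continue
        rec = site_fraction(ref_id, pos, site, high_threshold, denominator)
        if rec is not None:
            out.append(rec)
    return out


def call_sites(
    fractions: Iterable[FractionRecord], cutoff: float = FRACTION_CUTOFF
) -> list[FractionRecord]:
    """Binary calls: modified when fraction >= cutoff (boundary inclusive)."""
    return [replace(r, call=r.fraction >= cutoff) for r in fractions]


@dataclass
class ThresholdCurve:
    """Detection percentages of annotated vs non-annotated sites per cutoff."""

    cutoffs: list[float]
    pct_annotated: list[float | None]
    pct_nonannotated: list[float | None]
    n_annotated: int = 0
    n_nonannotated: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cutoff": self.cutoffs,
                "pct_annotated": self.pct_annotated,
                "pct_nonannotated": self.pct_nonannotated,
            }
        )


def threshold_curve(
    fractions: Iterable[FractionRecord],
    annotations: AnnotationTable,
    mod_code: str,
    grid: Sequence[float] | None = None,
) -> ThresholdCurve:
    """Detection-rate curve over fraction cutoffs.

    At each cutoff, the percentage of annotated sites (for ``mod_code``) and
    of non-annotated sites whose fraction is >= cutoff.  An empty class
    yields None percentages.
    """
    if grid is None:
        grid = [round(c, 2) for c in np.arange(0.0, 1.01, 0.05)]
    annotated_sites = annotations.sites(mod_code)
    ann = [r.fraction for r in fractions if (r.ref_id, r.body_position) in annotated_sites]
    non = [r.fraction for r in fractions if (r.ref_id, r.body_position) not in annotated_sites]

    def pct(vals: list[float], cutoff: float) -> float | None:
        if not vals:
            return None
        return 100.0 * sum(v >= cutoff for v in vals) / len(vals)

    return ThresholdCurve(
        cutoffs=list(grid),
        pct_annotated=[pct(ann, c) for c in grid],
        pct_nonannotated=[pct(non, c) for c in grid],
        n_annotated=len(ann),
        n_nonannotated=len(non),
    )


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve of per-site scores against binary labels.

    Computed by the rank (Mann-Whitney) statistic with midrank tie handling;
    equivalent to the trapezoid area under the empirical ROC.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC AUC requires both classes present")
    return float(roc_auc_score(labels, scores))


def fraction_frame(records: Iterable[FractionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ref_id": r.ref_id,
                "body_pos": r.body_position,
                "n_high": r.n_high,
                "n_total": r.n_total,
                "fraction": r.fraction,
                "call": r.call,
            }
            for r in records
        ],
        columns=["ref_id", "body_pos", "n_high", "n_total", "fraction", "call"],
    )


def write_fractions(records: Iterable[FractionRecord], path: str | Path) -> None:
    fraction_frame(records).to_csv(path, sep="\t", index=False)


def fraction_matrix(records: Iterable[FractionRecord]) -> pd.DataFrame:
    """Wide (tRNA x position) fraction matrix for heatmap plotting."""
    df = fraction_frame(records)
    if df.empty:
        return pd.DataFrame()
    return df.pivot(index="ref_id", columns="body_pos", values="fraction")
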