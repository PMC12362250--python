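"""Off-label modification detection by comparing score distributions.

The core sample-comparison statistic: per site, the emitted per-read
prediction scores of two samples (e.g. wild type vs knockout, or wild type
vs fully unmodified IVT RNA) are smoothed into 10-bin frequency histograms
of equal spacing between 11 and 256, and compared with the symmetric
Kullback-Leibler divergence

    sym_KL = D_KL(P || Q) + D_KL(Q || P),    D_KL(P||Q) = sum_x P(x) ln(P(x)/Q(x)).

Any modification that perturbs a caller's score distribution is visible in
this statistic, whether or not the caller was trained for it.  Histograms
receive an additive pseudocount (default 1 per bin) so the divergence stays
finite; the logarithm is natural.  Sites are only compared on tRNAs where
both samples have at least ``min_coverage`` (default 100) filtered reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from .modscores import MOD_MODELS, SiteScoreTable
from .refio import AnnotationTable, ReferenceSet

logger = logging.getLogger(__name__)

N_BINS = 10
HIST_LO = 11.0
HIST_HI = 256.0
PSEUDOCOUNT = 1.0
MIN_COVERAGE = 100


@dataclass(frozen=True)
class ScoreHistogram:
    """A smoothed 10-bin score histogram on [11, 256) with half-open bins."""

    bin_edges: np.ndarray  # n_bins + 1 ascending edges
    counts: np.ndarray  # raw integer counts
    probs: np.ndarray  # smoothed probabilities, strictly positive, sum 1

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def smooth_histogram(
    scores: Sequence[int],
    n_bins: int = N_BINS,
    lo: float = HIST_LO,
    hi: float = HIST_HI,
    pseudocount: float = PSEUDOCOUNT,
) -> ScoreHistogram:
    """Bin scores into equal-width half-open bins and pseudocount-smooth.

    probs = (counts + pseudocount) / (n + n_bins * pseudocount); with the
    defaults every bin has width (256-11)/10 = 24.5 and strictly positive
    probability, which keeps KL divergences finite.
    """
    scores = np.asarray(scores)
    if scores.size == 0:
        raise ValueError("empty score list; gate coverage before building histograms")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if scores.min() < lo or scores.max() >= hi:
        raise ValueError(f"scores outside [{lo}, {hi})")
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(scores, bins=edges)
    probs = (counts + pseudocount) / (counts.sum() + n_bins * pseudocount)
    return ScoreHistogram(bin_edges=edges, counts=counts, probs=probs)


def kl_divergence(p: Sequence[float], q: Sequence[float]) -> float:
    """D_KL(P || Q) = sum P ln(P/Q) in nats; requires strictly positive inputs."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must have equal length")
    if (p <= 0).any() or (q <= 0).any():
        raise ValueError("distributions must be strictly positive (smooth first)")
    if not (np.isclose(p.sum(), 1.0) and np.isclose(q.sum(), 1.0)):
        raise ValueError("distributions must sum to 1")
    return float(rel_entr(p, q).sum())


def symmetric_kl(p: Sequence[float], q: Sequence[float]) -> float:
    """Symmetrized divergence D_KL(P||Q) + D_KL(Q||P)."""
    return kl_divergence(p, q) + kl_divergence(q, p)


@dataclass(frozen=True)
class KLRecord:
    ref_id: str
    body_position: int
    mod_code: str
    cov_a: int
    cov_b: int
    passed_coverage: bool
    d_pq: float | None = None
    d_qp: float | None = None

    @property
    def sym_kl(self) -> float | None:
        if self.d_pq is None or self.d_qp is None:
            return None
        return self.d_pq + self.d_qp


def compare_samples(
    table_a: SiteScoreTable,
    table_b: SiteScoreTable,
    min_coverage: int = MIN_COVERAGE,
    n_bins: int = N_BINS,
    pseudocount: float = PSEUDOCOUNT,
) -> list[KLRecord]:
    """Per-site symmetric KL divergence between two samples' score tables.

    The coverage gate is per tRNA per sample (filtered full-length reads);
    sites on under-covered tRNAs, or without at least one emitted score in
    both samples, are reported with ``passed_coverage=False`` and no
    divergence.  Sample order does not affect ``sym_kl``.
    """
    if table_a.mod_code != table_b.mod_code:
        raise ValueError(
            f"mod code mismatch: {table_a.mod_code} vs {table_b.mod_code}"
        )
    out: list[KLRecord] = []
    common = sorted(set(table_a.sites) & set(table_b.sites))
    for ref_id, pos in common:
        sa = table_a.sites[(ref_id, pos)]
        sb = table_b.sites[(ref_id, pos)]
        cov_a = table_a.coverage(ref_id)
        cov_b = table_b.coverage(ref_id)
        gated = cov_a >= min_coverage and cov_b >= min_coverage
        if not gated or sa.n_scored == 0 or sb.n_scored == 0:
            out.append(
                KLRecord(ref_id, pos, table_a.mod_code, cov_a, cov_b, passed_coverage=False)
            )
            continue
        ha = smooth_histogram(sa.scores, n_bins=n_bins, pseudocount=pseudocount)
        hb = smooth_histogram(sb.scores, n_bins=n_bins, pseudocount=pseudocount)
        out.append(
            KLRecord(
                ref_id,
                pos,
                table_a.mod_code,
                cov_a,
                cov_b,
                passed_coverage=True,
                d_pq=kl_divergence(ha.probs, hb.probs),
                d_qp=kl_divergence(hb.probs, ha.probs),
            )
        )
    return out


def min_max_normalize(
    values: Mapping[str, float] | Sequence[float],
    groups: Mapping[str, str] | None = None,
) -> dict[str, float] | list[float]:
    """Min-max normalize values to [0, 1], optionally within groups.

    A group with a single distinct value maps to all zeros with a warning
    (no spread to normalize).  Ranking within each group is preserved.
    """
    if not isinstance(values, Mapping):
        keys = list(range(len(values)))
        mapping = {k: float(v) for k, v in zip(keys, values)}
        result = min_max_normalize(mapping, None)
        return [result[k] for k in keys]
    by_group: dict[str, list] = {}
    for key, val in values.items():
        g = groups[key] if groups is not None else "__all__"
        by_group.setdefault(g, []).append(key)
    out: dict = {}
    for g, keys in by_group.items():
        vals = np.array([values[k] for k in keys], dtype=float)
        lo, hi = vals.min(), vals.max()
        if hi == lo:
            logger.warning("constant group %r in min-max normalization; emitting zeros", g)
            normed = np.zeros_like(vals)
        else:
            normed = (vals - lo) / (hi - lo)
        out.update(dict(zip(keys, normed.tolist())))
    return out


# --- multi-model integration -------------------------------------------------

#: canonical base (internal DNA alphabet) -> modification model used for it
BASE_MODEL: dict[str, str] = {"T": "psi", "A": "m6A", "C": "m5C"}
# G positions carry no score: no G-base modification model exists yet.


@dataclass
class MapCell:
    ref_id: str
    body_position: int
    canonical_base: str
    mod_code: str | None = None
    sym_kl: float | None = None
    sym_kl_norm: float | None = None
    annotation: str | None = None
    fraction: float | None = None
    call: bool | None = None


@dataclass
class ModificationMap:
    """Integrated per-tRNA, per-position call matrix across models."""

    cells: dict[tuple[str, int], MapCell]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ref_id": c.ref_id,
                    "body_pos": c.body_position,
                    "base": c.canonical_base,
                    "mod_code": c.mod_code,
                    "sym_kl": c.sym_kl,
                    "sym_kl_norm": c.sym_kl_norm,
                    "annotation": c.annotation,
                    "fraction": c.fraction,
                    "call": c.call,
                }
                for c in sorted(
                    self.cells.values(), key=lambda c: (c.ref_id, c.body_position)
                )
            ]
        )

    def to_matrix(self, value: str = "sym_kl_norm") -> pd.DataFrame:
        df = self.to_frame()
        if df.empty:
            return pd.DataFrame()
        return df.pivot(index="ref_id", columns="body_pos", values=value)


def integrate_models(
    kl_by_model: Mapping[str, Iterable[KLRecord]],
    refs: ReferenceSet,
    annotations: AnnotationTable | None = None,
    fractions: Iterable | None = None,
    normalize_per_ref: bool = False,
) -> ModificationMap:
    """Fuse per-model KL records into one A/U/C modification map.

    Each body position receives the symmetric KL of the model matching its
    canonical base (U -> pseudouridine model, A -> m6A, C -> m5C); G
    positions stay empty.  Values are min-max normalized per model (or per
    tRNA per model with ``normalize_per_ref``) for cross-model comparison.
    """
    cells: dict[tuple[str, int], MapCell] = {}
    for ref in refs:
        for pos in range(1, ref.body_len + 1):
            base = ref.body_base(pos)
            cells[(ref.ref_id, pos)] = MapCell(ref.ref_id, pos, base, BASE_MODEL.get(base))
    for mod_code, records in kl_by_model.items():
        model_base = MOD_MODELS[mod_code].canonical_base
        values: dict[tuple[str, int], float] = {}
        for rec in records:
            key = (rec.ref_id, rec.body_position)
            if key not in cells:
                continue
            cell = cells[key]
            if cell.canonical_base != model_base:
                continue  # model does not apply to this base
            if not rec.passed_coverage or rec.sym_kl is None:
                continue
            if cell.sym_kl is not None:
                raise ValueError(f"conflicting duplicate KL records at {key}")
            cell.sym_kl = rec.sym_kl
            values[key] = rec.sym_kl
        if values:
            groups = (
                {k: f"{mod_code}:{k[0]}" for k in values}
                if normalize_per_ref
                else {k: mod_code for k in values}
            )
            for key, v in min_max_normalize(values, groups).items():
                cells[key].sym_kl_norm = v
    if annotations is not None:
        for ann in annotations:
            if ann.position is not None and (ann.ref_id, ann.position) in cells:
                cells[(ann.ref_id, ann.position)].annotation = ann.mod_code
    if fractions is not None:
        for fr in fractions:
            key = (fr.ref_id, fr.body_position)
            if key in cells:
                cells[key].fraction = fr.fraction
                cells[key].call = fr.call
    return ModificationMap(cells=cells)


def kl_frame(records: Iterable[KLRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ref_id": r.ref_id,
                "body_pos": r.body_position,
                "mod_code": r.mod_code,
                "cov_a": r.cov_a,
                "cov_b": r.cov_b,
                "d_pq": r.d_pq,
                "d_qp": r.d_qp,
                "sym_kl": r.sym_kl,
                "passed_coverage": r.passed_coverage,
            }
            for r in records
        ],
        columns=[
            "ref_id",
            "body_pos",
            "mod_code",
            "cov_a",
            "cov_b",
            "d_pq",
            "d_qp",
            "sym_kl",
            "passed_coverage",
        ],
    )


def write_kl_records(records: Iterable[KLRecord], path: str | Path) -> None:
    kl_frame(records).to_csv(path, sep="\t", index=False)
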