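"""Seeded synthetic data: references, error-bearing reads, per-read
modification scores, and stride-6 segmented signals.

The generator emulates the upstream of the pipeline — adapter-flanked tRNA
references, direct-RNA reads with substitution/indel/truncation errors,
per-read discretized modification scores drawn from configurable
modified/unmodified mixtures (with optional neighbor interference), MM/ML
base-modification tags, and raw signals segmented by a move table — so the
whole downstream analysis is testable without sequencing data.  All
randomness flows from explicit seeds; identical seeds give identical
output.

Score mixtures are discretized Beta distributions.  Defaults: unmodified
sites draw from Beta(1, 20) (mass near 0), on-label pseudouridine sites
from Beta(20, 1) (mass near 1), and off-label "abnormal" uridine
modifications from the bimodal-intermediate mixture 0.5*Beta(4, 4) +
0.5*Beta(8, 2).  These reproduce the qualitative score-distribution shapes
seen for annotated, unannotated, and otherwise-modified sites; they are not
fits to any caller.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .align import DELETION, INSERTION, MATCH, MISMATCH
from .modscores import MOD_MODELS, EMISSION_THRESHOLD, ReadScoreTrack
from .refio import Reference, ReferenceSet

BASES = "ACGT"

# study conditions for read errors (direct-RNA-realistic; see docs/methods.md)
SUB_RATE = 0.03
INS_RATE = 0.01
DEL_RATE = 0.015
TRUNCATION_PROB = 0.15
DEFAULT_DEPTH = 150


# --- score distributions -----------------------------------------------------


@dataclass(frozen=True)
class BetaScoreDist:
    """Beta(a, b) on [0, 1], discretized to integer scores 0-255."""

    a: float
    b: float

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = rng.beta(self.a, self.b, size=size)
        return np.minimum((p * 256).astype(int), 255)

    def cdf_above(self, threshold: int, n: int = 200_000, seed: int = 0) -> float:
        """Monte Carlo P(score > threshold); used by recovery checks."""
        rng = np.random.default_rng(seed)
        return float((self.sample(rng, n) > threshold).mean())


@dataclass(frozen=True)
class MixtureScoreDist:
    """Weighted mixture of score distributions."""

    components: tuple[tuple[float, BetaScoreDist], ...]

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        weights = np.array([w for w, _ in self.components])
        choice = rng.choice(len(self.components), size=size, p=weights / weights.sum())
        out = np.empty(size, dtype=int)
        for k, (_, dist) in enumerate(self.components):
            mask = choice == k
            if mask.any():
                out[mask] = dist.sample(rng, int(mask.sum()))
        return out

    def cdf_above(self, threshold: int, n: int = 200_000, seed: int = 0) -> float:
        rng = np.random.default_rng(seed)
        return float((self.sample(rng, n) > threshold).mean())


@dataclass(frozen=True)
class PointScoreDist:
    """Degenerate distribution: every draw is the same score."""

    value: int

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.full(size, self.value, dtype=int)

    def cdf_above(self, threshold: int, n: int = 0, seed: int = 0) -> float:
        return float(self.value > threshold)


UNMODIFIED_DIST = BetaScoreDist(1, 20)
PSI_MODIFIED_DIST = BetaScoreDist(20, 1)
ABNORMAL_DIST = MixtureScoreDist(((0.5, BetaScoreDist(4, 4)), (0.5, BetaScoreDist(8, 2))))


@dataclass(frozen=True)
class NeighborInterference:
    """Score perturbation at canonical-base neighbors of a modified site."""

    max_offset: int
    dist: BetaScoreDist | MixtureScoreDist


@dataclass(frozen=True)
class SiteModel:
    """Ground-truth modification model of one site."""

    body_position: int
    stoichiometry: float
    modified_dist: BetaScoreDist | MixtureScoreDist = PSI_MODIFIED_DIST
    unmodified_dist: BetaScoreDist | MixtureScoreDist = UNMODIFIED_DIST
    neighbor_interference: NeighborInterference | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.stoichiometry <= 1.0:
            raise ValueError("stoichiometry must be in [0, 1]")


# --- truth bookkeeping -------------------------------------------------------


@dataclass
class SimRead:
    read_id: str
    seq: str
    source_ref: str
    truncated: bool
    pairs: list[tuple[int | None, int | None, str]]  # truth alignment to source ref
    mod_status: dict[int, bool] = field(default_factory=dict)  # body_pos -> modified
    true_scores: dict[int, int] = field(default_factory=dict)  # read_pos -> score (pre-threshold)


@dataclass
class SimTruth:
    refs: ReferenceSet
    reads: dict[str, SimRead] = field(default_factory=dict)
    site_models: dict[tuple[str, int], SiteModel] = field(default_factory=dict)
    level_table: dict[tuple[str, int], float] = field(default_factory=dict)  # (ref_id, full_pos) -> level

    def coverage(self, ref_id: str, full_length_only: bool = True) -> int:
        return sum(
            1
            for r in self.reads.values()
            if r.source_ref == ref_id and not (full_length_only and r.truncated)
        )


# --- generators --------------------------------------------------------------


def simulate_references(
    n: int,
    body_len_range: tuple[int, int] = (65, 95),
    adapter_lens: tuple[int, int] = (24, 30),
    seed: int = 0,
    gc: float = 0.5,
) -> ReferenceSet:
    """Random tRNA-body references with random splint adapters attached."""
    if n < 1:
        raise ValueError("need n >= 1 references")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    def rand_seq(length: int) -> str:
        return "".join(rng.choice(list(BASES), size=length, p=p))

    a5 = rand_seq(adapter_lens[0])
    a3 = rand_seq(adapter_lens[1])
    entries = []
    for k in range(n):
        body_len = int(rng.integers(body_len_range[0], body_len_range[1] + 1))
        body = rand_seq(body_len)
        entries.append(
            Reference(f"tRNA-sim-{k + 1:03d}", a5 + body + a3, len(a5), len(a3))
        )
    return ReferenceSet(entries)


def simulate_reads(
    refs: ReferenceSet,
    per_ref_depth: int = DEFAULT_DEPTH,
    sub_rate: float = SUB_RATE,
    ins_rate: float = INS_RATE,
    del_rate: float = DEL_RATE,
    truncation_prob: float = TRUNCATION_PROB,
    seed: int = 0,
) -> tuple[dict[str, str], SimTruth]:
    """Error-bearing reads from each reference, with a truth alignment.

    Substitutions, insertions and deletions are independent per base.
    Truncated reads (probability ``truncation_prob``) lose the 5' adapter
    plus a uniform number of 5' body bases of the source molecule, so they
    can never pass the full-length filter.
    """
    for rate in (sub_rate, ins_rate, del_rate):
        if not 0.0 <= rate < 1.0:
            raise ValueError("error rates must be in [0, 1)")
    if not 0.0 <= truncation_prob <= 1.0:
        raise ValueError("truncation_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = SimTruth(refs=refs)
    reads: dict[str, str] = {}
    counter = 0
    for ref in refs:
        for _ in range(per_ref_depth):
            counter += 1
            read_id = f"read-{counter:05d}"
            truncated = bool(rng.random() < truncation_prob)
            start = 0
            if truncated:
                body_cut = int(rng.integers(1, max(2, ref.body_len - 5)))
                start = ref.adapter5_len + body_cut
            seq_chars: list[str] = []
            pairs: list[tuple[int | None, int | None, str]] = []
            for ref_pos in range(start, len(ref.sequence)):
                if rng.random() < del_rate:
                    pairs.append((None, ref_pos, DELETION))
                    continue
                base = ref.sequence[ref_pos]
                if rng.random() < sub_rate:
                    base = BASES[(BASES.index(base) + int(rng.integers(1, 4))) % 4]
                    pairs.append((len(seq_chars), ref_pos, MISMATCH))
                else:
                    pairs.append((len(seq_chars), ref_pos, MATCH))
                seq_chars.append(base)
                if rng.random() < ins_rate:
                    pairs.append((len(seq_chars), None, INSERTION))
                    seq_chars.append(BASES[int(rng.integers(0, 4))])
            seq = "".join(seq_chars)
            if not seq:
                continue
            reads[read_id] = seq
            truth.reads[read_id] = SimRead(read_id, seq, ref.ref_id, truncated, pairs)
    return reads, truth


def simulate_scores(
    truth: SimTruth,
    site_models: Mapping[tuple[str, int], SiteModel],
    mod_code: str = "psi",
    baseline_dist: BetaScoreDist | MixtureScoreDist = UNMODIFIED_DIST,
    emission_threshold: int = EMISSION_THRESHOLD,
    seed: int = 0,
) -> dict[str, ReadScoreTrack]:
    """Per-read score tracks for one modification model.

    Every read position carrying the model's canonical base receives a true
    score: from the site's modified/unmodified mixture (modification status
    drawn per read with probability = stoichiometry) when the position
    matches a modeled body site, else from the baseline unmodified
    distribution.  Neighbor interference, when configured on a modified
    site, redraws the scores of canonical-base neighbors within the given
    offset after the primary draw.  Only scores >= ``emission_threshold``
    are emitted into the track; the full truth (all scores, modification
    statuses) is recorded on the SimRead.
    """
    rng = np.random.default_rng(seed)
    truth.site_models = dict(site_models)
    canonical = MOD_MODELS[mod_code].canonical_base
    tracks: dict[str, ReadScoreTrack] = {}
    for read_id in sorted(truth.reads):
        sim_read = truth.reads[read_id]
        ref = truth.refs[sim_read.source_ref]
        # body_pos -> read_pos for matched canonical-base positions
        matched: dict[int, int] = {}
        canonical_positions = [
            rp for rp, ch in enumerate(sim_read.seq) if ch == canonical
        ]
        for read_pos, ref_pos, op in sim_read.pairs:
            if op != MATCH or read_pos is None or ref_pos is None:
                continue
            if ref.sequence[ref_pos] != canonical:
                continue
            body = ref.full_to_body(ref_pos)
            if body is not None:
                matched[body] = read_pos
        # primary draws
        for read_pos in canonical_positions:
            sim_read.true_scores[read_pos] = int(baseline_dist.sample(rng, 1)[0])
        for body, read_pos in matched.items():
            model = site_models.get((sim_read.source_ref, body))
            if model is None:
                continue
            modified = bool(rng.random() < model.stoichiometry)
            sim_read.mod_status[body] = modified
            dist = model.modified_dist if modified else model.unmodified_dist
            sim_read.true_scores[read_pos] = int(dist.sample(rng, 1)[0])
        # neighbor interference after the primary draw
        for body, read_pos in matched.items():
            model = site_models.get((sim_read.source_ref, body))
            if model is None or model.neighbor_interference is None:
                continue
            if not sim_read.mod_status.get(body, False):
                continue
            ni = model.neighbor_interference
            for offset in range(-ni.max_offset, ni.max_offset + 1):
                if offset == 0:
                    continue
                neighbor = body + offset
                if neighbor in matched and (sim_read.source_ref, neighbor) not in site_models:
                    sim_read.true_scores[matched[neighbor]] = int(
                        ni.dist.sample(rng, 1)[0]
                    )
        track = ReadScoreTrack(read_id, mod_code)
        track.scores = {
            rp: s for rp, s in sorted(sim_read.true_scores.items()) if s >= emission_threshold
        }
        tracks[read_id] = track
    return tracks


def simulate_site_table(
    refs: ReferenceSet,
    site_models: Mapping[tuple[str, int], SiteModel],
    n_reads: int,
    mod_code: str = "psi",
    baseline_dist: BetaScoreDist | MixtureScoreDist = UNMODIFIED_DIST,
    emission_threshold: int = EMISSION_THRESHOLD,
    seed: int = 0,
):
    """Error-free fast path: a SiteScoreTable drawn directly per site.

    Emulates ``n_reads`` perfectly aligned full-length reads per reference:
    every canonical-base body position gets ``n_matched = n_reads`` and its
    emitted scores drawn from the site's mixture (or the baseline).  Useful
    for statistics-level experiments where read errors are irrelevant.
    """
    from .modscores import SiteScoreTable

    rng = np.random.default_rng(seed)
    canonical = MOD_MODELS[mod_code].canonical_base
    table = SiteScoreTable(mod_code=mod_code)
    for ref in refs:
        table.reads_per_ref[ref.ref_id] = n_reads
        for pos in range(1, ref.body_len + 1):
            if ref.body_base(pos) != canonical:
                continue
            model = site_models.get((ref.ref_id, pos))
            if model is None:
                scores = baseline_dist.sample(rng, n_reads)
            else:
                modified = rng.random(n_reads) < model.stoichiometry
                scores = np.where(
                    modified,
                    model.modified_dist.sample(rng, n_reads),
                    model.unmodified_dist.sample(rng, n_reads),
                )
            site = table.site(ref.ref_id, pos)
            site.n_matched = n_reads
            site.scores = sorted(int(s) for s in scores if s >= emission_threshold)
    return table


# --- MM/ML tag writing -------------------------------------------------------


def encode_mm_ml(seq: str, track: ReadScoreTrack) -> tuple[str, list[int]]:
    """Encode a score track as MM/ML tag values ('?' skip semantics).

    The MM delta list counts skipped canonical bases between scored
    positions, resolved against the read sequence; ML carries the scores in
    the same order.  This encoder is independent of any library decoder so
    round trips are a two-implementation check.
    """
    model = MOD_MODELS[track.mod_code]
    canonical_positions = [i for i, ch in enumerate(seq) if ch == model.canonical_base]
    index_of = {pos: k for k, pos in enumerate(canonical_positions)}
    deltas: list[int] = []
    scores: list[int] = []
    prev_index = -1
    for pos in sorted(track.scores):
        if pos not in index_of:
            raise ValueError(
                f"scored position {pos} is not a {model.canonical_base} in the read"
            )
        k = index_of[pos]
        deltas.append(k - prev_index - 1)
        prev_index = k
        scores.append(track.scores[pos])
    code = str(model.sam_code)
    mm = f"{model.canonical_base}+{code}?," + ",".join(map(str, deltas)) + ";"
    if not deltas:
        mm = f"{model.canonical_base}+{code}?;"
    return mm, scores


def write_tagged_sam(
    reads: Mapping[str, str],
    tracks: Mapping[str, ReadScoreTrack],
    path: str | Path,
) -> None:
    """Write unaligned SAM records carrying MM/ML base-modification tags."""
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "unknown"}}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read_id in sorted(reads):
            seq = reads[read_id]
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = read_id
            rec.query_sequence = seq
            rec.flag = 4
            rec.mapping_quality = 0
            track = tracks.get(read_id)
            if track is not None and track.scores:
                mm, ml = encode_mm_ml(seq, track)
                rec.set_tag("MM", mm)
                rec.set_tag("ML", array_to_ml(ml))
            out.write(rec)


def array_to_ml(scores: Sequence[int]):
    from array import array

    return array("B", scores)


# --- signals -----------------------------------------------------------------


def simulate_signals(
    truth: SimTruth,
    noise_sd: float = 3.0,
    stride: int = 6,
    mean_level: float = 100.0,
    level_sd: float = 12.0,
    dwell_p: float = 0.5,
    level_shift: Mapping[tuple[str, int], float] | None = None,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Raw signals plus move vectors for every simulated read.

    Each reference position receives a level ~ N(mean_level, level_sd)
    (shared across reads and recorded in the truth's level table);
    ``level_shift`` adds per-(ref_id, body_pos) offsets, emulating a
    modification-induced current shift in one sample.  Per base the dwell is
    ``stride`` times a geometric count (so segment lengths are positive
    multiples of the stride) and samples are Gaussian around the level.
    """
    rng = np.random.default_rng(seed)
    if not truth.level_table:
        for ref in truth.refs:
            for full_pos in range(len(ref.sequence)):
                truth.level_table[(ref.ref_id, full_pos)] = float(
                    rng.normal(mean_level, level_sd)
                )
    signals: dict[str, np.ndarray] = {}
    moves: dict[str, np.ndarray] = {}
    for read_id in sorted(truth.reads):
        sim_read = truth.reads[read_id]
        ref = truth.refs[sim_read.source_ref]
        ref_pos_of: dict[int, int | None] = {}
        for read_pos, ref_pos, op in sim_read.pairs:
            if read_pos is not None:
                ref_pos_of[read_pos] = ref_pos
        sig_parts: list[np.ndarray] = []
        mv: list[int] = []
        for read_pos in range(len(sim_read.seq)):
            ref_pos = ref_pos_of.get(read_pos)
            if ref_pos is None:  # insertion: unmodelled level
                level = float(rng.normal(mean_level, level_sd))
            else:
                level = truth.level_table[(sim_read.source_ref, ref_pos)]
                if level_shift and ref_pos is not None:
                    body = ref.full_to_body(ref_pos)
                    if body is not None:
                        level += level_shift.get((sim_read.source_ref, body), 0.0)
            blocks = int(rng.geometric(dwell_p))
            sig_parts.append(rng.normal(level, noise_sd, size=blocks * stride))
            mv.extend([1] + [0] * (blocks - 1))
        signals[read_id] = np.concatenate(sig_parts)
        moves[read_id] = np.array(mv, dtype=np.int8)
    return signals, moves


# --- manifest ----------------------------------------------------------------


def truth_manifest(truth: SimTruth) -> dict:
    """JSON-serializable summary of the simulation ground truth."""
    return {
        "references": {
            r.ref_id: {
                "length": len(r.sequence),
                "body_len": r.body_len,
                "adapter5_len": r.adapter5_len,
                "adapter3_len": r.adapter3_len,
            }
            for r in truth.refs
        },
        "n_reads": len(truth.reads),
        "n_truncated": sum(r.truncated for r in truth.reads.values()),
        "site_models": {
            f"{ref_id}:{pos}": {
                "stoichiometry": m.stoichiometry,
                "interference_offset": (
                    m.neighbor_interference.max_offset if m.neighbor_interference else 0
                ),
            }
            for (ref_id, pos), m in truth.site_models.items()
        },
    }


def write_manifest(truth: SimTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth_manifest(truth), indent=2, sort_keys=True))
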