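"""Per-read modification prediction scores and their projection onto sites.

Pre-trained modification callers emit, per read, a discretized probability
score (integer 0-255) at positions of the model's canonical base; only
scores at or above an emission threshold (default 12 = floor(255*0.05))
appear in the MM/ML base-modification tags.  This module decodes those tags,
projects scores through filtered alignments onto reference body coordinates,
and aggregates them into per-site score tables.  Only *matched* alignment
positions contribute: a mismatched read base carries no prediction score for
the reference canonical base, and insertions/deletions have no site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .align import MATCH, ReadAlignment
from .refio import ReferenceSet

logger = logging.getLogger(__name__)

EMISSION_THRESHOLD = 12  # floor(255 * 0.05), the caller's default emission cutoff


@dataclass(frozen=True)
class ModModel:
    """A modification caller: its code, canonical base, and SAM tag code."""

    mod_code: str
    canonical_base: str  # internal DNA alphabet (T for U)
    sam_code: str | int  # single-letter SAM code or ChEBI number


#: The four RNA modification models and their SAM base-modification codes.
MOD_MODELS: dict[str, ModModel] = {
    "psi": ModModel("psi", "T", 17802),
    "m6A": ModModel("m6A", "A", "a"),
    "m5C": ModModel("m5C", "C", "m"),
    "inosine": ModModel("inosine", "A", 17596),
}


def discretize_probability(p: float) -> int:
    """Map a modification probability in [0, 1] to the 0-255 integer scale.

    floor(255 * p); e.g. the 5% emission default maps to 12 and the 80%
    high-confidence threshold to 204.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    return min(int(255 * p), 255)


@dataclass
class ReadScoreTrack:
    """Emitted scores of one modification model on one read (read coordinates)."""

    read_id: str
    mod_code: str
    scores: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pos, s in self.scores.items():
            if not 0 <= s <= 255:
                raise ValueError(f"score {s} at read pos {pos} outside [0, 255]")


def decode_mod_tags(record, mod_code: str) -> ReadScoreTrack:
    """Decode MM/ML base-modification tags from a pysam record for one model.

    Skip-count resolution against the read's canonical-base occurrences and
    the '.'/'?' skipped-base semantics follow the SAM tag specification
    (delegated to pysam).  Positions are reported in the read's original
    sequencing orientation.  A record without tags, or without this model's
    code, yields an empty track.
    """
    model = MOD_MODELS[mod_code]
    track = ReadScoreTrack(record.query_name, mod_code)
    try:
        mods = record.modified_bases_forward
    except ValueError as exc:
        raise ValueError(f"malformed MM/ML tags on {record.query_name}: {exc}") from exc
    if not mods:
        return track
    found = False
    for (canonical, strand, code), entries in mods.items():
        if code != model.sam_code or strand != 0:
            continue
        found = True
        for pos, qual in entries:
            track.scores[int(pos)] = int(qual)
    if not found:
        logger.debug("no %s entries in tags of %s", mod_code, record.query_name)
    return track


def read_score_tracks(path: str | Path, mod_code: str) -> dict[str, ReadScoreTrack]:
    """Decode one model's tracks for every record of a SAM/BAM file."""
    import pysam

    tracks: dict[str, ReadScoreTrack] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as f:
        for rec in f.fetch(until_eof=True):
            tracks[rec.query_name] = decode_mod_tags(rec, mod_code)
    return tracks


def load_score_sidecar(path: str | Path, mod_code: str) -> dict[str, ReadScoreTrack]:
    """Tag-free alternative input: TSV of (read_id, read_pos, mod_code, score)."""
    df = pd.read_csv(path, sep="\t")
    tracks: dict[str, ReadScoreTrack] = {}
    for rec in df[df["mod_code"] == mod_code].itertuples(index=False):
        track = tracks.setdefault(str(rec.read_id), ReadScoreTrack(str(rec.read_id), mod_code))
        track.scores[int(rec.read_pos)] = int(rec.score)
    return tracks


def write_score_sidecar(tracks: Iterable[ReadScoreTrack], path: str | Path) -> None:
    rows = [
        {"read_id": t.read_id, "read_pos": p, "mod_code": t.mod_code, "score": s}
        for t in tracks
        for p, s in sorted(t.scores.items())
    ]
    pd.DataFrame(rows, columns=["read_id", "read_pos", "mod_code", "score"]).to_csv(
        path, sep="\t", index=False
    )


@dataclass
class SiteScores:
    """Aggregated per-site evidence for one model.

    ``n_matched`` counts filtered reads with a sequence match at the
    position; ``scores`` holds the emitted scores among them (n_scored =
    len(scores) <= n_matched, since sub-threshold scores are absent).
    """

    n_matched: int = 0
    scores: list[int] = field(default_factory=list)

    @property
    def n_scored(self) -> int:
        return len(self.scores)


@dataclass
class SiteScoreTable:
    """Per-(ref_id, body_position) score multisets for one modification model."""

    mod_code: str
    sites: dict[tuple[str, int], SiteScores] = field(default_factory=dict)
    reads_per_ref: dict[str, int] = field(default_factory=dict)

    def site(self, ref_id: str, body_pos: int) -> SiteScores:
        return self.sites.setdefault((ref_id, body_pos), SiteScores())

    def coverage(self, ref_id: str) -> int:
        """Filtered full-length reads assigned to this tRNA."""
        return self.reads_per_ref.get(ref_id, 0)


def project_scores(
    aln: ReadAlignment,
    track: ReadScoreTrack,
    refs: ReferenceSet,
) -> list[tuple[int, int | None]]:
    """Project one read's scores onto body positions of its reference.

    Returns (body_position, score-or-None) for every *matched* canonical-base
    position in the tRNA body: None marks matched-but-unscored positions
    (score below the emission threshold).  Mismatches, insertions and
    deletions contribute nothing.
    """
    if aln.read_id != track.read_id:
        raise ValueError(f"alignment read {aln.read_id} != track read {track.read_id}")
    model = MOD_MODELS[track.mod_code]
    ref = refs[aln.ref_id]
    out: list[tuple[int, int | None]] = []
    for read_pos, ref_pos, op in aln.pairs:
        if op != MATCH or ref_pos is None or read_pos is None:
            continue
        if ref.sequence[ref_pos] != model.canonical_base:
            continue
        body_pos = ref.full_to_body(ref_pos)
        if body_pos is None:  # adapter region
            continue
        out.append((body_pos, track.scores.get(read_pos)))
    return out


def build_site_table(
    alns: Iterable[ReadAlignment],
    tracks: Mapping[str, ReadScoreTrack],
    refs: ReferenceSet,
    mod_code: str,
    drop_multi_reference: bool = False,
) -> SiteScoreTable:
    """Aggregate filtered alignments and score tracks into a SiteScoreTable.

    Reads tied between references contribute to every tied reference unless
    ``drop_multi_reference``.  Per-site score lists are stored sorted so the
    result is independent of read input order.
    """
    table = SiteScoreTable(mod_code=mod_code)
    for aln in sorted(alns, key=lambda a: (a.read_id, a.ref_id)):
        if drop_multi_reference and aln.multi_reference:
            continue
        track = tracks.get(aln.read_id)
        if track is None:
            logger.warning("read %s has no score track; skipped", aln.read_id)
            continue
        table.reads_per_ref[aln.ref_id] = table.reads_per_ref.get(aln.ref_id, 0) + 1
        for body_pos, score in project_scores(aln, track, refs):
            site = table.site(aln.ref_id, body_pos)
            site.n_matched += 1
            if score is not None:
                site.scores.append(score)
    for site in table.sites.values():
        site.scores.sort()
    return table


def write_site_table(table: SiteScoreTable, path: str | Path) -> None:
    rows = [
        {
            "ref_id": ref_id,
            "body_pos": pos,
            "mod_code": table.mod_code,
            "n_matched": s.n_matched,
            "n_scored": s.n_scored,
            "ref_reads": table.coverage(ref_id),
            "scores": ",".join(map(str, s.scores)),
        }
        for (ref_id, pos), s in sorted(table.sites.items())
    ]
    pd.DataFrame(
        rows,
        columns=["ref_id", "body_pos", "mod_code", "n_matched", "n_scored", "ref_reads", "scores"],
    ).to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> SiteScoreTable:
    df = pd.read_csv(path, sep="\t", dtype={"scores": str})
    if df.empty:
        raise ValueError(f"empty site table {path}")
    mod_code = str(df["mod_code"].iloc[0])
    table = SiteScoreTable(mod_code=mod_code)
    for rec in df.itertuples(index=False):
        scores = [int(x) for x in str(rec.scores).split(",")] if isinstance(rec.scores, str) and rec.scores else []
        table.sites[(str(rec.ref_id), int(rec.body_pos))] = SiteScores(
            n_matched=int(rec.n_matched), scores=sorted(scores)
        )
        if hasattr(rec, "ref_reads"):
            table.reads_per_ref[str(rec.ref_id)] = int(rec.ref_reads)
    return table
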