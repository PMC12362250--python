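"""Convenience wiring of the pipeline stages.

These helpers chain align -> filter -> extract (and, for simulated inputs,
the generator before them) so examples, the CLI and the acceptance checks
do not repeat the plumbing.  Every stage remains available individually.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .align import ReadAlignment, ScoringScheme, align_all, filter_alignments
from .modscores import ReadScoreTrack, SiteScoreTable, build_site_table
from .refio import ReferenceSet
from .simulate import SimTruth, SiteModel, simulate_reads, simulate_scores


@dataclass
class Sample:
    """One sample's reads, truth, score tracks and aggregated site table."""

    reads: dict[str, str]
    truth: SimTruth
    tracks: dict[str, ReadScoreTrack]
    alignments: list[ReadAlignment]
    table: SiteScoreTable
    audit: list = field(default_factory=list)


def extract_site_table(
    reads: Mapping[str, str],
    tracks: Mapping[str, ReadScoreTrack],
    refs: ReferenceSet,
    mod_code: str,
    scheme: ScoringScheme = ScoringScheme(),
    min_as: int = 50,
    end_slack: int = 0,
    audit: list | None = None,
) -> tuple[SiteScoreTable, list[ReadAlignment]]:
    """Align all reads, apply the three-rule filter, aggregate site scores."""
    alns = align_all(reads, refs, scheme, end_slack=end_slack)
    kept = filter_alignments(alns, min_as=min_as, audit=audit)
    table = build_site_table(kept, tracks, refs, mod_code)
    return table, kept


def simulate_sample(
    refs: ReferenceSet,
    site_models: Mapping[tuple[str, int], SiteModel],
    seed: int,
    depth: int = 150,
    mod_code: str = "psi",
    **read_kwargs,
) -> Sample:
    """Simulate one sample end to end and push it through the pipeline."""
    reads, truth = simulate_reads(refs, per_ref_depth=depth, seed=seed, **read_kwargs)
    tracks = simulate_scores(truth, site_models, mod_code=mod_code, seed=seed + 1)
    audit: list = []
    table, kept = extract_site_table(reads, tracks, refs, mod_code, audit=audit)
    return Sample(reads=reads, truth=truth, tracks=tracks, alignments=kept, table=table, audit=audit)
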