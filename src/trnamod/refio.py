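"""Reference sequences and site annotations.

Mature tRNA references are sequenced with 5'/3' splint adapters ligated, so
every reference carried by :class:`ReferenceSet` is ``adapter5 + body +
adapter3``.  All reported coordinates in this package are 1-based, inclusive
positions on the tRNA *body* (adapters excluded); internal full-sequence
coordinates are 0-based.  Sequences are canonicalized to the DNA alphabet
internally (U -> T); writers can report RNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_IUPAC_DNA = set("ACGTRYSWKMBDHVN")


def canonicalize(seq: str) -> str:
    """Uppercase and map RNA to the internal DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class Reference:
    """One adapter-flanked reference sequence.

    ``sequence`` is the full adapter5+body+adapter3 string (DNA alphabet);
    body positions are 1-based on the body, i.e. body position ``p`` sits at
    full-sequence index ``adapter5_len + p - 1``.
    """

    ref_id: str
    sequence: str
    adapter5_len: int
    adapter3_len: int

    def __post_init__(self) -> None:
        if self.adapter5_len < 0 or self.adapter3_len < 0:
            raise ValueError("adapter lengths must be >= 0")
        if len(self.sequence) <= self.adapter5_len + self.adapter3_len:
            raise ValueError(
                f"{self.ref_id}: sequence length {len(self.sequence)} does not "
                f"exceed adapter lengths {self.adapter5_len}+{self.adapter3_len}"
            )

    @property
    def body(self) -> str:
        end = len(self.sequence) - self.adapter3_len
        return self.sequence[self.adapter5_len : end]

    @property
    def body_len(self) -> int:
        return len(self.sequence) - self.adapter5_len - self.adapter3_len

    @property
    def body_span(self) -> tuple[int, int]:
        """Body coordinates on the full sequence, 1-based inclusive."""
        return (self.adapter5_len + 1, len(self.sequence) - self.adapter3_len)

    def body_to_full(self, body_pos: int) -> int:
        """1-based body position -> 0-based full-sequence index."""
        if not 1 <= body_pos <= self.body_len:
            raise IndexError(f"body position {body_pos} outside [1, {self.body_len}]")
        return self.adapter5_len + body_pos - 1

    def full_to_body(self, full_idx: int) -> int | None:
        """0-based full-sequence index -> 1-based body position, or None in adapters."""
        p = full_idx - self.adapter5_len + 1
        if 1 <= p <= self.body_len:
            return p
        return None

    def body_base(self, body_pos: int) -> str:
        return self.sequence[self.body_to_full(body_pos)]


@dataclass
class ReferenceSet:
    entries: list[Reference] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.ref_id for r in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate reference ids: {dupes}")
        self._by_id = {r.ref_id: r for r in self.entries}

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, ref_id: str) -> Reference:
        return self._by_id[ref_id]

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self._by_id

    def ids(self) -> list[str]:
        return [r.ref_id for r in self.entries]


def build_references(
    bodies: dict[str, str], adapter5: str = "", adapter3: str = ""
) -> ReferenceSet:
    """Attach splint adapters to mature-tRNA bodies and assemble a ReferenceSet."""
    a5 = canonicalize(adapter5)
    a3 = canonicalize(adapter3)
    entries = [
        Reference(ref_id, a5 + canonicalize(body) + a3, len(a5), len(a3))
        for ref_id, body in bodies.items()
    ]
    return ReferenceSet(entries)


def load_references(
    fasta_path: str | Path, adapter5: str = "", adapter3: str = ""
) -> ReferenceSet:
    """Load mature tRNA bodies from FASTA and attach splint adapters.

    Adapter sequences are user configuration, never built in.  Records with
    non-IUPAC characters are rejected with a warning; duplicate sequences
    under distinct ids are allowed but warned; duplicate ids are an error.
    """
    bodies: dict[str, str] = {}
    seen_seqs: dict[str, str] = {}
    n_records = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        n_records += 1
        seq = canonicalize(str(rec.seq))
        if not seq:
            logger.warning("skipping empty record %s", rec.id)
            continue
        bad = set(seq) - _IUPAC_DNA
        if bad:
            logger.warning(
                "rejecting record %s: non-IUPAC characters %s", rec.id, sorted(bad)
            )
            continue
        if rec.id in bodies:
            raise ValueError(f"duplicate reference id {rec.id!r} in {fasta_path}")
        if seq in seen_seqs:
            logger.warning(
                "records %s and %s have identical sequences", seen_seqs[seq], rec.id
            )
        seen_seqs.setdefault(seq, rec.id)
        bodies[rec.id] = seq
    if n_records == 0:
        raise ValueError(f"no FASTA records in {fasta_path}")
    return build_references(bodies, adapter5, adapter3)


def write_references(
    refs: ReferenceSet, fasta_path: str | Path, bodies_only: bool = True, rna: bool = False
) -> None:
    """Write references to FASTA (bodies only by default, matching the loader)."""
    records = []
    for ref in refs:
        seq = ref.body if bodies_only else ref.sequence
        if rna:
            seq = to_rna(seq)
        records.append(SeqRecord(Seq(seq), id=ref.ref_id, description=""))
    SeqIO.write(records, str(fasta_path), "fasta-2line")


# --- annotations -------------------------------------------------------------


@dataclass(frozen=True)
class Annotation:
    ref_id: str
    position: int | None  # 1-based body position; None for insertion labels
    position_label: str  # original label, e.g. "55" or "20.1"
    mod_code: str
    canonical_base: str | None = None

    @property
    def is_insertion(self) -> bool:
        return self.position is None


@dataclass
class AnnotationTable:
    rows: list[Annotation] = field(default_factory=list)

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def sites(self, mod_code: str | None = None) -> set[tuple[str, int]]:
        """Integral (ref_id, body_position) pairs, optionally for one mod code."""
        return {
            (a.ref_id, a.position)
            for a in self.rows
            if a.position is not None and (mod_code is None or a.mod_code == mod_code)
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "ref_id": a.ref_id,
                    "position": a.position_label,
                    "mod_code": a.mod_code,
                    "canonical_base": a.canonical_base,
                }
                for a in self.rows
            ]
        )


def load_annotations(tsv_path: str | Path, refs: ReferenceSet) -> AnnotationTable:
    """Load a site-annotation TSV (columns ref_id, position, mod_code).

    Positions are 1-based body coordinates.  Insertion labels such as "20.1"
    (positions inserted relative to canonical tRNA numbering) are retained as
    opaque labels and excluded from coordinate arithmetic.  Rows referencing
    unknown references or out-of-body positions are dropped with a warning.
    """
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    required = {"ref_id", "position", "mod_code"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation TSV must have columns {sorted(required)}")
    rows: list[Annotation] = []
    seen: set[tuple[str, str, str]] = set()
    for rec in df.itertuples(index=False):
        ref_id = str(rec.ref_id)
        label = str(rec.position)
        mod_code = str(rec.mod_code)
        if ref_id not in refs:
            logger.warning("annotation for unknown reference %s dropped", ref_id)
            continue
        key = (ref_id, label, mod_code)
        if key in seen:
            raise ValueError(f"duplicate annotation row {key}")
        seen.add(key)
        ref = refs[ref_id]
        try:
            pos: int | None = int(label)
        except ValueError:
            pos = None  # insertion label like "20.1"
        base: str | None = None
        if pos is not None:
            if not 1 <= pos <= ref.body_len:
                logger.warning(
                    "annotation %s:%s outside body [1, %d], dropped",
                    ref_id,
                    label,
                    ref.body_len,
                )
                continue
            base = ref.body_base(pos)
        rows.append(Annotation(ref_id, pos, label, mod_code, base))
    return AnnotationTable(rows)


def write_annotations(table: AnnotationTable, tsv_path: str | Path) -> None:
    table.to_frame().to_csv(tsv_path, sep="\t", index=False)
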