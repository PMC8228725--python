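"""Acceptance cascade for predictor-output miRNA candidates.

A hairpin-discovery tool emits candidate records carrying a likelihood score,
the predicted mature/star/loop segments with their read support, and a flag
saying whether the precursor matched a known miRNA precursor in a reference
set. A candidate enters the accepted novel-miRNA set when

* its score is at least ``score_min`` (default 1.0),
* both a star and a loop sequence were predicted (a hairpin without them is
  not a credible precursor), and
* it has either a homolog hit or at least ``min_mature_reads`` (default 30)
  reads on the mature arm — homology and expression evidence are alternatives.

Rejections are labelled with the first failing rule, in the fixed order
score -> structure -> evidence, so reports are deterministic.

Star-dominant candidates (more reads on the star arm than the mature arm) are
flagged for inspection but never removed by the flag alone: arm assignment is
occasionally ambiguous, and such records stay in the set as long as both arms
clear the read cutoff or a homolog exists.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import pandas as pd

from ._seq import to_dna

DEFAULT_SCORE_MIN = 1.0
DEFAULT_MIN_MATURE_READS = 30

REASON_SCORE = "score"
REASON_STRUCTURE = "structure"
REASON_EVIDENCE = "evidence"


class CandidateValidationError(ValueError):
    """A candidate record is internally inconsistent."""


@dataclasses.dataclass
class CandidateRecord:
    candidate_id: str
    score: float
    precursor_seq: str
    mature_seq: str = ""
    star_seq: str = ""
    loop_seq: str = ""
    mature_reads: int = 0
    star_reads: int = 0
    loop_reads: int = 0
    homolog_hit: bool = False
    chromosome: str = ""
    start: int = -1
    end: int = -1
    strand: str = "+"

    def validate(self) -> None:
        for arm, seq in (
            ("mature", self.mature_seq),
            ("star", self.star_seq),
            ("loop", self.loop_seq),
        ):
            if seq and to_dna(seq) not in to_dna(self.precursor_seq):
                raise CandidateValidationError(
                    f"candidate {self.candidate_id}: {arm} sequence is not a "
                    f"substring of its precursor"
                )
        if min(self.mature_reads, self.star_reads, self.loop_reads) < 0:
            raise CandidateValidationError(
                f"candidate {self.candidate_id}: negative read count"
            )


def apply_filter_cascade(
    records: Sequence[CandidateRecord],
    score_min: float = DEFAULT_SCORE_MIN,
    min_mature_reads: int = DEFAULT_MIN_MATURE_READS,
) -> tuple[list[CandidateRecord], list[tuple[CandidateRecord, str]]]:
    """Split records into (accepted, rejected-with-reason).

    Accepted iff score >= score_min AND star and loop sequences are present
    AND (homolog hit OR mature reads >= min_mature_reads). The union of the
    two returned lists is the input; they never overlap.
    """
    accepted: list[CandidateRecord] = []
    rejected: list[tuple[CandidateRecord, str]] = []
    for rec in records:
        rec.validate()
        if rec.score < score_min:
            rejected.append((rec, REASON_SCORE))
        elif not (rec.star_seq and rec.loop_seq):
            rejected.append((rec, REASON_STRUCTURE))
        elif not (rec.homolog_hit or rec.mature_reads >= min_mature_reads):
            rejected.append((rec, REASON_EVIDENCE))
        else:
            accepted.append(rec)
    return accepted, rejected


def flag_star_dominant(records: Iterable[CandidateRecord]) -> list[CandidateRecord]:
    """Records whose star arm out-reads the mature arm (informational only)."""
    return [rec for rec in records if rec.star_reads > rec.mature_reads]


def dedupe_precursor_library(
    precursors: Mapping[str, str],
) -> tuple[dict[str, str], dict[str, str]]:
    """Keep one representative per distinct precursor sequence.

    The representative is the first id in sorted order among those sharing a
    sequence (U/T-insensitive). Returns ``(library, representative_of)`` where
    ``representative_of`` maps every input id (including representatives) to
    its representative. Idempotent.
    """
    seen: dict[str, str] = {}
    library: dict[str, str] = {}
    rep_of: dict[str, str] = {}
    for pid in sorted(precursors):
        key = to_dna(precursors[pid])
        if key not in seen:
            seen[key] = pid
            library[pid] = precursors[pid]
        rep_of[pid] = seen[key]
    return library, rep_of


# ---------------------------------------------------------------------------
# Tabular I/O — a plain TSV dialect mirroring the predictor's result table
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = [
    "candidate_id",
    "score",
    "precursor_seq",
    "mature_seq",
    "star_seq",
    "loop_seq",
    "mature_reads",
    "star_reads",
    "loop_reads",
    "homolog_hit",
    "chromosome",
    "start",
    "end",
    "strand",
]


def read_candidates(path: str | Path) -> list[CandidateRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str}, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            CandidateRecord(
                candidate_id=str(row.candidate_id),
                score=float(row.score),
                precursor_seq=str(row.precursor_seq),
                mature_seq=str(row.mature_seq),
                star_seq=str(row.star_seq),
                loop_seq=str(row.loop_seq),
                mature_reads=int(row.mature_reads),
                star_reads=int(row.star_reads),
                loop_reads=int(row.loop_reads),
                homolog_hit=_parse_bool(row.homolog_hit),
                chromosome=str(row.chromosome),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
            )
        )
    return records


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in {"1", "true", "yes"}


def write_candidates(records: Sequence[CandidateRecord], path: str | Path) -> None:
    rows = [dataclasses.asdict(rec) for rec in records]
    pd.DataFrame(rows, columns=CANDIDATE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_filter_report(
    accepted: Sequence[CandidateRecord],
    rejected: Sequence[tuple[CandidateRecord, str]],
    path: str | Path,
) -> None:
    rows = [{"candidate_id": r.candidate_id, "status": "accepted", "reason": ""} for r in accepted]
    rows += [
        {"candidate_id": r.candidate_id, "status": "rejected", "reason": why}
        for r, why in rejected
    ]
    df = pd.DataFrame(rows, columns=["candidate_id", "status", "reason"])
    df.sort_values("candidate_id").to_csv(path, sep="\t", index=False)


def write_accepted_fasta(records: Sequence[CandidateRecord], path: str | Path) -> None:
    """Accepted precursors with mature/star arms as a three-records-per-candidate
    FASTA (precursor, mature, star)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.candidate_id}\n{rec.precursor_seq}\n")
            if rec.mature_seq:
                fh.write(f">{rec.candidate_id}_mature\n{rec.mature_seq}\n")
            if rec.star_seq:
                fh.write(f">{rec.candidate_id}_star\n{rec.star_seq}\n")
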