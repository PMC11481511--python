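"""Quality control of prophage predictions.

A prediction table (CheckV-style columns) is parsed into records, filtered
by estimated completeness (strictly greater than the threshold) and contig
length (at least the threshold), and contigs carrying several prophage
signals are resolved deterministically: overlapping intervals are merged,
disjoint signals stay separate, and every touched contig is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional

import pandas as pd

from .errors import JoinError, RowError, TableFormatError

REQUIRED_COLUMNS = (
    "prophage_id", "genome_id", "contig_id", "contig_length",
    "start", "end", "completeness",
)


@dataclass(frozen=True)
class ProphageRecord:
    """One predicted prophage with provenance to its host genome.

    Coordinates are 1-based inclusive on the contig (GFF convention);
    ``completeness`` is a percentage in [0, 100]; ``sequence`` is optional
    until extraction.
    """

    prophage_id: str
    genome_id: str
    contig_id: str
    contig_length: int
    start: int
    end: int
    completeness: float
    sequence: Optional[str] = None

    def validate(self) -> Optional[str]:
        """Return a human-readable problem description, or None if valid."""
        if not (1 <= self.start <= self.end <= self.contig_length):
            return (
                f"coordinates violate 1 <= start <= end <= contig_length "
                f"({self.start}, {self.end}, {self.contig_length})"
            )
        if not 0.0 <= self.completeness <= 100.0:
            return f"completeness {self.completeness} outside [0, 100]"
        return None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def records_to_frame(records: Iterable[ProphageRecord]) -> pd.DataFrame:
    rows = [
        {c: getattr(r, c) for c in REQUIRED_COLUMNS} for r in records
    ]
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def parse_predictions(source, errors: str = "raise"):
    """Parse a tab-delimited prediction table into :class:`ProphageRecord`s.

    ``source`` is a path or file-like object. Malformed rows are reported
    with their 1-based line numbers (header is line 1). With
    ``errors="raise"`` (default) any malformed row raises :class:`RowError`;
    with ``errors="collect"`` the return value is ``(records, problems)``
    where ``problems`` is the list of ``(line, prophage_id, message)``.
    """
    if errors not in ("raise", "collect"):
        raise ValueError("errors must be 'raise' or 'collect'")
    try:
        df = pd.read_csv(source, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise TableFormatError("prediction table is empty (no header)") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"prediction table lacks column(s): {missing}")
    records: list[ProphageRecord] = []
    problems: list[tuple[int, str, str]] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header occupies line 1
        pid = str(row["prophage_id"])
        try:
            rec = ProphageRecord(
                prophage_id=pid,
                genome_id=str(row["genome_id"]),
                contig_id=str(row["contig_id"]),
                contig_length=int(row["contig_length"]),
                start=int(row["start"]),
                end=int(row["end"]),
                completeness=float(row["completeness"]),
            )
        except (TypeError, ValueError):
            problems.append((line, pid, "non-numeric coordinate or completeness"))
            continue
        msg = rec.validate()
        if msg is not None:
            problems.append((line, pid, msg))
            continue
        records.append(rec)
    if problems and errors == "raise":
        raise RowError(problems)
    if errors == "collect":
        return records, problems
    return records


def filter_predictions(
    records: Iterable[ProphageRecord],
    min_completeness: float = 50.0,
    min_contig: int = 30_000,
):
    """Keep reliable predictions; return ``(kept, dropped)``.

    A record is kept iff completeness is strictly greater than
    ``min_completeness`` and the contig length is at least ``min_contig``
    (the completeness rule is exclusive, the contig rule inclusive).
    ``dropped`` pairs each discarded record with the tuple of failed rules.
    """
    kept: list[ProphageRecord] = []
    dropped: list[tuple[ProphageRecord, tuple[str, ...]]] = []
    for rec in records:
        reasons = []
        if not rec.completeness > min_completeness:
            reasons.append(f"completeness {rec.completeness} <= {min_completeness}")
        if not rec.contig_length >= min_contig:
            reasons.append(f"contig_length {rec.contig_length} < {min_contig}")
        if reasons:
            dropped.append((rec, tuple(reasons)))
        else:
            kept.append(rec)
    return kept, dropped


def resolve_multicontig(records: Iterable[ProphageRecord]):
    """Resolve contigs carrying more than one prophage signal.

    Overlapping intervals on one contig are merged into a single record
    (coordinate union, maximum completeness, ids joined with ``+``);
    disjoint signals remain separate. Returns ``(records, report)`` where
    ``report`` maps every touched contig to a description of the action.
    The operation is idempotent and order-stable.
    """
    records = list(records)
    by_contig: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        by_contig.setdefault(rec.contig_id, []).append(i)
    out: list[ProphageRecord] = []
    report: dict[str, str] = {}
    for rec in records:
        idxs = by_contig.get(rec.contig_id)
        if idxs is None:
            continue  # already emitted with an earlier record of this contig
        del by_contig[rec.contig_id]
        group = [records[i] for i in idxs]
        if len(group) == 1:
            out.append(group[0])
            continue
        group.sort(key=lambda r: (r.start, r.end, r.prophage_id))
        merged: list[list[ProphageRecord]] = [[group[0]]]
        for r in group[1:]:
            cur = merged[-1]
            if r.start <= max(x.end for x in cur):
                cur.append(r)
            else:
                merged.append([r])
        actions = []
        for chunk in merged:
            if len(chunk) == 1:
                out.append(chunk[0])
            else:
                first = chunk[0]
                rec_m = replace(
                    first,
                    prophage_id="+".join(r.prophage_id for r in chunk),
                    start=min(r.start for r in chunk),
                    end=max(r.end for r in chunk),
                    completeness=max(r.completeness for r in chunk),
                    sequence=None,
                )
                out.append(rec_m)
                actions.append(
                    f"merged {len(chunk)} overlapping signals into {rec_m.prophage_id}"
                )
        if not actions:
            actions.append(f"kept {len(group)} disjoint signals separate")
        report[rec.contig_id] = "; ".join(actions)
    return out, report


def extract_sequences(
    records: Iterable[ProphageRecord],
    contigs: Mapping[str, str],
) -> list[ProphageRecord]:
    """Attach prophage sequences sliced from contig sequences.

    ``contigs`` maps contig id to nucleotide sequence. Slicing follows the
    1-based inclusive convention: positions ``start..end``.
    """
    records = list(records)
    missing = {r.contig_id for r in records if r.contig_id not in contigs}
    if missing:
        raise JoinError(missing, context="contig sequences")
    return [
        replace(r, sequence=contigs[r.contig_id][r.start - 1: r.end]) for r in records
    ]
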