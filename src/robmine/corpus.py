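"""Corpus input/output.

A corpus is a directory of plain-text manuscripts (``<doc_id>.txt``, UTF-8)
plus a metadata CSV (``doc_id,journal,record_date``) and, optionally, a gold
annotation CSV (``doc_id,randomization,blinding,samplesize``) produced by
manual ascertainment.  The corpus is defined by the metadata (the screening
record), not by the file system: text files without a metadata row are
reported and ignored, metadata rows without a text file are reported as
retrieval gaps.

Loading never alters text content except normalizing newlines to ``"\\n"``.
Dates must be ISO-8601 (``YYYY-MM-DD``) so that epoch binning is unambiguous.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime
import json
from pathlib import Path
from typing import Iterable, Sequence

ITEMS = ("randomization", "blinding", "samplesize")

_TRUE_TOKENS = {"true", "1", "yes", "y", "t"}
_FALSE_TOKENS = {"false", "0", "no", "n", "f"}


class CorpusError(ValueError):
    """Fatal problem with corpus, metadata, or annotation inputs."""


@dataclasses.dataclass(frozen=True)
class Document:
    """One manuscript: full text plus journal and record-date metadata."""

    doc_id: str
    text: str
    journal: str = ""
    record_date: datetime.date | None = None


@dataclasses.dataclass(frozen=True)
class GoldAnnotation:
    """Manual gold-standard call for all three risk-of-bias items."""

    doc_id: str
    randomization: bool
    blinding: bool
    samplesize: bool

    def __getitem__(self, item: str) -> bool:
        if item not in ITEMS:
            raise KeyError(item)
        return getattr(self, item)


@dataclasses.dataclass
class Corpus:
    """Loaded documents plus the load report.

    ``missing_text`` lists metadata doc_ids with no text file (the retrieval
    gap); ``unlisted_files`` lists ``.txt`` files absent from the metadata.
    """

    documents: list[Document]
    missing_text: list[str] = dataclasses.field(default_factory=list)
    unlisted_files: list[str] = dataclasses.field(default_factory=list)

    def __iter__(self):
        return iter(self.documents)

    def __len__(self) -> int:
        return len(self.documents)

    @property
    def doc_ids(self) -> list[str]:
        return [d.doc_id for d in self.documents]


def _parse_date(token: str, row_label: str) -> datetime.date:
    try:
        return datetime.date.fromisoformat(token.strip())
    except ValueError:
        raise CorpusError(
            f"unparseable record_date {token!r} in metadata row {row_label}; "
            "dates must be ISO-8601 (YYYY-MM-DD)"
        ) from None


def _parse_bool(token: str, row_label: str, column: str) -> bool:
    low = str(token).strip().lower()
    if low in _TRUE_TOKENS:
        return True
    if low in _FALSE_TOKENS:
        return False
    raise CorpusError(
        f"unrecognized boolean token {token!r} in row {row_label}, "
        f"column {column!r} (accepted: true/false, 1/0, yes/no)"
    )


def _read_table(path: Path, required: Sequence[str]) -> list[dict[str, str]]:
    path = Path(path)
    if not path.is_file():
        raise CorpusError(f"table not found: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CorpusError(f"empty table (no header): {path}")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise CorpusError(f"{path}: missing required column(s) {missing}")
        return list(reader)


def load_corpus(text_dir: str | Path, metadata_path: str | Path) -> Corpus:
    """Load documents listed in the metadata table from ``text_dir``.

    Returns one :class:`Document` per metadata row with a matching
    ``<doc_id>.txt`` file, sorted by ``doc_id``.  Rows without a file and
    files without a row are recorded on the returned :class:`Corpus` rather
    than silently dropped.
    """
    text_dir = Path(text_dir)
    if not text_dir.is_dir():
        raise CorpusError(f"corpus directory not found: {text_dir}")
    rows = _read_table(Path(metadata_path), ("doc_id", "journal", "record_date"))

    seen: set[str] = set()
    documents: list[Document] = []
    missing: list[str] = []
    for i, row in enumerate(rows, start=2):  # header is line 1
        doc_id = row["doc_id"].strip()
        if not doc_id:
            raise CorpusError(f"empty doc_id in metadata line {i}")
        if doc_id in seen:
            raise CorpusError(f"duplicate doc_id {doc_id!r} in metadata")
        seen.add(doc_id)
        date = _parse_date(row["record_date"], f"{i} (doc_id={doc_id})")
        txt_path = text_dir / f"{doc_id}.txt"
        if not txt_path.is_file():
            missing.append(doc_id)
            continue
        text = txt_path.read_text(encoding="utf-8")
        text = text.replace("\r\n", "\n").replace("\r", "\n")
        documents.append(
            Document(doc_id=doc_id, text=text, journal=row["journal"].strip(), record_date=date)
        )
    documents.sort(key=lambda d: d.doc_id)
    unlisted = sorted(
        p.name for p in text_dir.glob("*.txt") if p.stem not in seen
    )
    return Corpus(documents=documents, missing_text=sorted(missing), unlisted_files=unlisted)


def load_gold(path: str | Path) -> list[GoldAnnotation]:
    """Load gold-standard annotations; one row per document."""
    rows = _read_table(Path(path), ("doc_id",) + ITEMS)
    seen: set[str] = set()
    out: list[GoldAnnotation] = []
    for i, row in enumerate(rows, start=2):
        doc_id = row["doc_id"].strip()
        if doc_id in seen:
            raise CorpusError(f"duplicate doc_id {doc_id!r} in gold table")
        seen.add(doc_id)
        label = f"{i} (doc_id={doc_id})"
        out.append(
            GoldAnnotation(
                doc_id=doc_id,
                randomization=_parse_bool(row["randomization"], label, "randomization"),
                blinding=_parse_bool(row["blinding"], label, "blinding"),
                samplesize=_parse_bool(row["samplesize"], label, "samplesize"),
            )
        )
    out.sort(key=lambda a: a.doc_id)
    return out


# ---------------------------------------------------------------------------
# Result output.  CSV is the summary schema (stable column order, quoted as
# needed); the JSON variant is lossless and round-trips full evidence.
# ---------------------------------------------------------------------------

CALLS_CSV_COLUMNS = ("doc_id", "item", "call", "n_matches", "first_snippet")


def write_calls(calls: Iterable, path: str | Path) -> None:
    """Write detector calls; ``.json`` is lossless, ``.csv`` is the summary.

    The CSV schema is ``doc_id,item,call,n_matches,first_snippet``; the JSON
    variant additionally stores every evidence span and round-trips exactly
    through :func:`read_calls`.
    """
    path = Path(path)
    calls = list(calls)
    if path.suffix.lower() == ".json":
        payload = [
            {
                "doc_id": c.doc_id,
                "item": c.item,
                "call": c.call,
                "evidence": [dataclasses.asdict(e) for e in c.evidence],
            }
            for c in calls
        ]
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n", encoding="utf-8")
        return
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CALLS_CSV_COLUMNS)
        for c in calls:
            first = c.evidence[0].snippet if c.evidence else ""
            writer.writerow([c.doc_id, c.item, str(c.call).lower(), len(c.evidence), first])


def read_calls(path: str | Path):
    """Read calls written by :func:`write_calls` (either format)."""
    from .detect import MatchEvidence, RobCall  # local import: avoid cycle

    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        return [
            RobCall(
                doc_id=rec["doc_id"],
                item=rec["item"],
                call=bool(rec["call"]),
                evidence=tuple(MatchEvidence(**e) for e in rec["evidence"]),
            )
            for rec in payload
        ]
    rows = _read_table(path, CALLS_CSV_COLUMNS)
    return [
        {
            "doc_id": r["doc_id"],
            "item": r["item"],
            "call": _parse_bool(r["call"], str(i), "call"),
            "n_matches": int(r["n_matches"]),
            "first_snippet": r["first_snippet"],
        }
        for i, r in enumerate(rows, start=2)
    ]


def write_report(rows: Iterable[dict], path: str | Path, columns: Sequence[str]) -> None:
    """Write a generic delimited report with a fixed column order."""
    path = Path(path)
    rows = list(rows)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(rows, indent=1, sort_keys=True, default=str) + "\n",
                        encoding="utf-8")
        return
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(columns))
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row.get(k, "") for k in columns})
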