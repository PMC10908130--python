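"""Bibliographic corpus I/O and input-quality validation.

A corpus is an ordered set of title/abstract records with oracle relevance
labels (the simulated screener answers from these) and key-paper flags.
Garbage in, garbage out: screening prioritization degrades on corpora with
missing text or duplicates, so validation reports those before a run.

Formats: a simple CSV (record_id, title, abstract, year, label, key_paper)
and RIS for the bibliographic fields, with labels supplied as a separate
CSV keyed by record id.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

from .state import IRRELEVANT, RELEVANT, ScreeningState


class ValidationError(ValueError):
    """Input data violates a corpus invariant."""


# accepted spellings per label class, lowercased
_LABEL_MAP = {
    "1": RELEVANT,
    "relevant": RELEVANT,
    "included": RELEVANT,
    "0": IRRELEVANT,
    "irrelevant": IRRELEVANT,
    "excluded": IRRELEVANT,
}

_TRUTHY = {"1", "true", "yes"}
_FALSY = {"0", "false", "no", ""}

CSV_COLUMNS = ["record_id", "title", "abstract", "year", "label", "key_paper"]


@dataclass(frozen=True)
class Record:
    """One bibliographic item in the candidate set."""

    record_id: str
    title: str = ""
    abstract: str = ""
    year: int | None = None
    oracle_label: str | None = None
    is_key_paper: bool = False

    @property
    def text(self) -> str:
        return f"{self.title} {self.abstract}".strip()


@dataclass
class Corpus:
    """Ordered collection of records; ``T`` is the total record count."""

    records: list[Record]
    validation_report: list[str] = field(default_factory=list)

    @property
    def T(self) -> int:
        return len(self.records)

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValidationError(f"duplicate record_id {dup!r}")
        for r in self.records:
            if r.is_key_paper and r.oracle_label != RELEVANT:
                raise ValidationError(
                    f"key paper {r.record_id!r} must have a relevant oracle label"
                )
        self._by_id = {r.record_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, record_id: str) -> Record:
        return self._by_id[record_id]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._by_id

    def key_paper_ids(self) -> list[str]:
        return [r.record_id for r in self.records if r.is_key_paper]

    def relevant_ids(self) -> set[str]:
        return {r.record_id for r in self.records if r.oracle_label == RELEVANT}

    @property
    def n_relevant(self) -> int:
        return len(self.relevant_ids())


def _parse_label(raw: str, row: int) -> str:
    label = _LABEL_MAP.get(str(raw).strip().lower())
    if label is None:
        raise ValidationError(f"row {row}: unknown label value {raw!r}")
    return label


def _parse_year(raw: str) -> int | None:
    raw = str(raw).strip()
    return int(raw) if raw else None


def _parse_flag(raw: str, row: int) -> bool:
    v = str(raw).strip().lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise ValidationError(f"row {row}: unknown key_paper value {raw!r}")


def read_corpus(
    path: str | Path,
    format: str = "csv",
    label_column: str = "label",
    key_paper_ids: list[str] | None = None,
    labels_path: str | Path | None = None,
) -> Corpus:
    """Read a labeled corpus from CSV or RIS (+ separate label CSV).

    Record order equals file order.  Key papers may be flagged in-file
    (CSV ``key_paper`` column) or designated by ``key_paper_ids``; both are
    honored, and a designated id absent from the file, or carrying an
    irrelevant label, is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        records = _read_csv(path, label_column)
    elif format == "ris":
        records = _read_ris(path)
        if labels_path is not None:
            records = _attach_labels(records, Path(labels_path), label_column)
    else:
        raise ValueError(f"unknown format {format!r}")

    if key_paper_ids:
        present = {r.record_id for r in records}
        missing = [k for k in key_paper_ids if k not in present]
        if missing:
            raise ValidationError(f"key paper ids not in corpus: {missing}")
        key = set(key_paper_ids)
        records = [
            replace(r, is_key_paper=True) if r.record_id in key else r for r in records
        ]
    return Corpus(records)


def _read_csv(path: Path, label_column: str) -> list[Record]:
    records: list[Record] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "record_id" not in reader.fieldnames:
            raise ValidationError(f"{path}: missing header with record_id column")
        if label_column not in reader.fieldnames:
            raise ValidationError(f"{path}: missing label column {label_column!r}")
        for i, row in enumerate(reader, start=2):  # header is line 1
            records.append(
                Record(
                    record_id=row["record_id"].strip(),
                    title=row.get("title", "") or "",
                    abstract=row.get("abstract", "") or "",
                    year=_parse_year(row.get("year", "") or ""),
                    oracle_label=_parse_label(row[label_column], i),
                    is_key_paper=_parse_flag(row.get("key_paper", "") or "", i),
                )
            )
    return records


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Write the standard corpus CSV (UTF-8, header required on read)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in corpus:
            writer.writerow(
                [
                    r.record_id,
                    r.title,
                    r.abstract,
                    "" if r.year is None else r.year,
                    {RELEVANT: 1, IRRELEVANT: 0}.get(r.oracle_label, ""),
                    int(r.is_key_paper),
                ]
            )


# -- RIS ------------------------------------------------------------------
# Minimal line-tag reader for the subset of tags the framework uses
# (TY/ID/TI/AB/PY/ER).  Continuation lines extend the previous tag's value.

_RIS_TAG = re.compile(r"^([A-Z][A-Z0-9])  - ?(.*)$")


def _read_ris(path: Path) -> list[Record]:
    records: list[Record] = []
    fields: dict[str, str] = {}
    last_tag: str | None = None
    n = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            m = _RIS_TAG.match(line)
            if m:
                tag, value = m.group(1), m.group(2).strip()
                if tag == "ER":
                    n += 1
                    records.append(
                        Record(
                            record_id=fields.get("ID", f"ris{n:05d}"),
                            title=fields.get("TI", ""),
                            abstract=fields.get("AB", ""),
                            year=_parse_year(fields.get("PY", "")),
                        )
                    )
                    fields, last_tag = {}, None
                else:
                    fields[tag] = value
                    last_tag = tag
            elif line.strip() and last_tag is not None:
                fields[last_tag] += " " + line.strip()
    return records


def write_ris(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in corpus:
            fh.write("TY  - JOUR\n")
            fh.write(f"ID  - {r.record_id}\n")
            fh.write(f"TI  - {r.title}\n")
            if r.abstract:
                fh.write(f"AB  - {r.abstract}\n")
            if r.year is not None:
                fh.write(f"PY  - {r.year}\n")
            fh.write("ER  - \n")


def _attach_labels(records: list[Record], labels_path: Path, label_column: str) -> list[Record]:
    labels: dict[str, str] = {}
    key_flags: dict[str, bool] = {}
    with open(labels_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "record_id" not in reader.fieldnames:
            raise ValidationError(f"{labels_path}: missing record_id column")
        for i, row in enumerate(reader, start=2):
            rid = row["record_id"].strip()
            labels[rid] = _parse_label(row[label_column], i)
            if "key_paper" in row:
                key_flags[rid] = _parse_flag(row.get("key_paper", "") or "", i)
    missing = [r.record_id for r in records if r.record_id not in labels]
    if missing:
        raise ValidationError(f"labels missing for records: {missing}")
    return [
        replace(r, oracle_label=labels[r.record_id], is_key_paper=key_flags.get(r.record_id, False))
        for r in records
    ]


# -- validation -----------------------------------------------------------

_WS = re.compile(r"\s+")


def _norm_text_pair(r: Record) -> tuple[str, str]:
    return (_WS.sub(" ", r.title.lower()).strip(), _WS.sub(" ", r.abstract.lower()).strip())


def validate_corpus(corpus: Corpus, dedupe: bool = False, require_labels: bool = True) -> Corpus:
    """Quality-check a corpus; optionally drop exact text duplicates.

    Duplicate detection is exact equality on lowercased, whitespace-collapsed
    (title, abstract) pairs; deduplication keeps the first occurrence.
    Records missing text or year are retained with a warning — they are
    rankable on whatever text remains.  Idempotent: a clean, already
    deduplicated corpus passes through unchanged.
    """
    if corpus.T == 0:
        raise ValidationError("corpus has zero records")
    if require_labels:
        unlabeled = [r.record_id for r in corpus if r.oracle_label is None]
        if unlabeled:
            raise ValidationError(f"records without oracle label: {unlabeled[:5]} ...")
        if corpus.n_relevant == 0:
            raise ValidationError(
                "corpus has zero relevant records; the procedure is undefined with R=0"
            )

    report: list[str] = []
    seen: dict[tuple[str, str], str] = {}
    kept: list[Record] = []
    for r in corpus:
        if not r.title.strip() and not r.abstract.strip():
            report.append(f"{r.record_id}: empty title and abstract")
        elif not r.abstract.strip():
            report.append(f"{r.record_id}: missing abstract (ranked on title alone)")
        if r.year is None:
            report.append(f"{r.record_id}: missing year")
        key = _norm_text_pair(r)
        if key in seen and key != ("", ""):
            report.append(f"{r.record_id}: duplicate of {seen[key]}")
            if dedupe:
                continue
        else:
            seen[key] = r.record_id
        kept.append(r)
    return Corpus(kept, validation_report=report)


# -- screening-log serialization ------------------------------------------

LOG_COLUMNS = ["step", "record_id", "phase", "presented_rank", "label", "cumulative_relevant"]


def write_screening_log(state: ScreeningState, path: str | Path) -> None:
    """Persist the decision log; re-reading reconstructs the recall curve."""
    if len(state) == 0:
        raise ValueError("refusing to write an empty screening log")
    cum = 0
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LOG_COLUMNS)
        for e in state.log:
            cum += e.label == RELEVANT
            writer.writerow([e.step, e.record_id, e.phase, e.presented_rank, e.label, cum])


def read_screening_log(path: str | Path) -> ScreeningState:
    state = ScreeningState()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            state.append(
                row["record_id"], int(row["phase"]), int(row["presented_rank"]), row["label"]
            )
    return state
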