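"""Data model and I/O for clinical notes, span-level mention annotations and
admission-level ICD-9 code sets.

The unit of annotation is a *mention*: a possibly discontiguous text span in a
note, linked to a medical concept identifier (a CUI), to the special value
``CUI-less`` (the annotators found no concept), or to a non-concept marker.
Two mentions are synonyms when they link to the same concept with different
surface strings, so everything downstream (representation building, ranking,
evaluation) consumes the types defined here.

Offsets in the canonical dialects are 0-based, half-open.  The pipe-standoff
adapter declares its own offset base and end closure in its dialect config so
that external annotation layouts can be ingested without silent off-by-one
errors.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

CUI_LESS = "CUI-less"

CANONICAL_TSV_COLUMNS = ("mention_id", "doc_id", "spans", "surface", "concept", "fold")


class CorpusError(Exception):
    """Base class for corpus-layer failures."""


class ValidationError(CorpusError):
    """A row or annotation violates the data model invariants."""


class ConfigurationError(CorpusError):
    """An unknown dialect or an inconsistent reader configuration."""


class AlignmentError(CorpusError):
    """A mention could not be located inside a single sentence."""


class FormatError(CorpusError):
    """A file does not parse in the declared format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Span:
    """Character offsets, 0-based half-open: text[start:end]."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"span end must exceed start: {self.start}-{self.end}")
        if self.start < 0:
            raise ValidationError(f"negative span offset: {self.start}")

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class MentionAnnotation:
    """One annotated mention. ``spans`` is sorted and non-overlapping; more
    than one span encodes a discontiguous mention."""

    mention_id: str
    doc_id: str
    spans: tuple[Span, ...]
    surface: str
    concept: str
    fold: str = "all"

    def __post_init__(self) -> None:
        if not self.spans:
            raise ValidationError(f"{self.mention_id}: mention requires at least one span")
        spans = tuple(self.spans)
        for a, b in zip(spans, spans[1:]):
            if b.start < a.start:
                raise ValidationError(f"{self.mention_id}: spans not sorted")
            if a.overlaps(b):
                raise ValidationError(f"{self.mention_id}: overlapping spans")
        object.__setattr__(self, "spans", spans)
        if not self.surface.strip():
            raise ValidationError(f"{self.mention_id}: empty surface")


@dataclass(frozen=True)
class Document:
    doc_id: str
    text: str
    admission_id: str = ""

    def __post_init__(self) -> None:
        if not self.text:
            raise ValidationError(f"{self.doc_id}: empty document text")
        if not self.admission_id:
            object.__setattr__(self, "admission_id", self.doc_id)


@dataclass(frozen=True)
class Admission:
    admission_id: str
    icd_codes: frozenset[str] = frozenset()
    demographics: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "icd_codes", frozenset(self.icd_codes))


@dataclass(frozen=True)
class Sentence:
    """A tokenized sentence; each token carries its document-level span."""

    doc_id: str
    tokens: tuple[tuple[str, Span], ...]

    @property
    def words(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.tokens)

    @property
    def extent(self) -> Span:
        return Span(self.tokens[0][1].start, self.tokens[-1][1].end)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

_WS = re.compile(r"\s+")


def normalize_surface(s: str) -> str:
    """Canonical form used for every string-equality test: lowercase, internal
    whitespace collapsed to single spaces, ends stripped."""
    return _WS.sub(" ", s).strip().lower()


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

_SENT_BREAK = re.compile(r"[.!?](?=\s)|\n")
_TOKEN = re.compile(r"\w+|[^\w\s]+")


def tokenize(document: Document) -> list[Sentence]:
    """Deterministic, rule-based segmentation.

    Sentences break on newlines and on ``. ! ?`` followed by whitespace (the
    punctuation mark stays with the sentence it ends).  Tokens are maximal
    runs of word characters or of non-space punctuation, so every non-space
    character belongs to exactly one token and original offsets are kept.
    """
    text = document.text
    sentences: list[Sentence] = []
    start = 0
    boundaries = [m.end() for m in _SENT_BREAK.finditer(text)] + [len(text)]
    for end in boundaries:
        if end < start:
            continue
        chunk = text[start:end]
        tokens = tuple(
            (m.group(), Span(start + m.start(), start + m.end()))
            for m in _TOKEN.finditer(chunk)
        )
        if tokens:
            sentences.append(Sentence(doc_id=document.doc_id, tokens=tokens))
        start = end
    return sentences


def align_mention(
    mention: MentionAnnotation, sentences: Sequence[Sentence]
) -> tuple[Sentence, tuple[int, ...]]:
    """Locate a mention inside its sentence.

    Returns the containing sentence and the indices of every token that
    overlaps any mention span.  Mentions straddling a sentence boundary are
    rejected: the encoders are sentence-scoped by contract.
    """
    hits: dict[int, set[int]] = {}
    for si, sent in enumerate(sentences):
        if sent.doc_id != mention.doc_id:
            continue
        for ti, (_, tspan) in enumerate(sent.tokens):
            if any(tspan.overlaps(mspan) for mspan in mention.spans):
                hits.setdefault(si, set()).add(ti)
    if not hits:
        raise AlignmentError(f"{mention.mention_id}: spans cover no token")
    if len(hits) > 1:
        raise AlignmentError(
            f"{mention.mention_id}: spans cross sentences "
            f"{sorted(hits)} in doc {mention.doc_id}"
        )
    (si, indices), = hits.items()
    return sentences[si], tuple(sorted(indices))


def filter_mentions(
    mentions: Iterable[MentionAnnotation], allowed_concepts: Iterable[str]
) -> list[MentionAnnotation]:
    """Apply the concept allow-list.

    A mention is kept iff its concept is in the allow-list or is ``CUI-less``;
    every other value is treated as a non-concept marker and dropped.  The
    allow-list itself is a precomputed input (e.g. the disorder semantic
    group of an ontology); no ontology traversal happens here.
    """
    allowed = set(allowed_concepts)
    return [m for m in mentions if m.concept in allowed or m.concept == CUI_LESS]


# ---------------------------------------------------------------------------
# Mention table I/O
# ---------------------------------------------------------------------------


def _format_spans(spans: Sequence[Span]) -> str:
    return ";".join(f"{s.start}-{s.end}" for s in spans)


def _parse_spans(text: str, where: str) -> tuple[Span, ...]:
    spans = []
    for part in text.split(";"):
        m = re.fullmatch(r"(\d+)-(\d+)", part.strip())
        if not m:
            raise ValidationError(f"{where}: bad span field {part!r}")
        spans.append(Span(int(m.group(1)), int(m.group(2))))
    return tuple(spans)


def write_mention_table(mentions: Iterable[MentionAnnotation], path: str | Path) -> None:
    """Write the canonical TSV dialect (tab/newline in surfaces replaced by
    spaces; no further escaping)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(CANONICAL_TSV_COLUMNS) + "\n")
        for m in mentions:
            surface = m.surface.replace("\t", " ").replace("\n", " ")
            fh.write(
                "\t".join(
                    (m.mention_id, m.doc_id, _format_spans(m.spans), surface, m.concept, m.fold)
                )
                + "\n"
            )


def read_mention_table(
    path: str | Path,
    dialect: str = "canonical-tsv",
    *,
    dialect_config: Mapping | None = None,
    documents: Mapping[str, Document] | None = None,
) -> list[MentionAnnotation]:
    """Read a mention table.

    dialect is one of ``canonical-tsv``, ``canonical-jsonl`` or
    ``pipe-standoff``.  The pipe-standoff adapter needs the documents to
    assemble surfaces and a dialect config declaring the field order, offset
    base and end closure.  Malformed rows raise with their line number.
    """
    path = Path(path)
    if dialect == "canonical-tsv":
        return _read_canonical_tsv(path)
    if dialect == "canonical-jsonl":
        return _read_canonical_jsonl(path)
    if dialect == "pipe-standoff":
        return _read_pipe_standoff(path, dialect_config or {}, documents)
    raise ConfigurationError(f"unknown mention-table dialect: {dialect!r}")


def _read_canonical_tsv(path: Path) -> list[MentionAnnotation]:
    mentions = []
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != CANONICAL_TSV_COLUMNS:
            raise FormatError(f"{path}:1: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(CANONICAL_TSV_COLUMNS):
                raise FormatError(f"{path}:{lineno}: expected 6 fields, got {len(fields)}")
            mid, doc_id, spans, surface, concept, fold = fields
            try:
                mentions.append(
                    MentionAnnotation(
                        mention_id=mid,
                        doc_id=doc_id,
                        spans=_parse_spans(spans, f"{path}:{lineno}"),
                        surface=surface,
                        concept=concept,
                        fold=fold,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return mentions


def _read_canonical_jsonl(path: Path) -> list[MentionAnnotation]:
    mentions = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                row = json.loads(line)
                mentions.append(
                    MentionAnnotation(
                        mention_id=row["mention_id"],
                        doc_id=row["doc_id"],
                        spans=tuple(Span(int(a), int(b)) for a, b in row["spans"]),
                        surface=row["surface"],
                        concept=row["concept"],
                        fold=row.get("fold", "all"),
                    )
                )
            except (KeyError, ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return mentions


def write_mention_jsonl(mentions: Iterable[MentionAnnotation], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for m in mentions:
            fh.write(
                json.dumps(
                    {
                        "mention_id": m.mention_id,
                        "doc_id": m.doc_id,
                        "spans": [[s.start, s.end] for s in m.spans],
                        "surface": m.surface,
                        "concept": m.concept,
                        "fold": m.fold,
                    }
                )
                + "\n"
            )


_STANDOFF_DEFAULT = {
    "fields": ["doc_id", "type", "concept", "offsets"],
    "offset_base": 0,
    "end_exclusive": True,
    "fold": "all",
}


def _read_pipe_standoff(
    path: Path, config: Mapping, documents: Mapping[str, Document] | None
) -> list[MentionAnnotation]:
    if documents is None:
        raise ConfigurationError("pipe-standoff dialect requires the documents mapping")
    cfg = dict(_STANDOFF_DEFAULT)
    cfg.update(config)
    fields: list[str] = list(cfg["fields"])
    if "offsets" in fields and fields.index("offsets") != len(fields) - 1:
        raise ConfigurationError("'offsets' must be the trailing standoff field")
    base = int(cfg["offset_base"])
    excl = bool(cfg["end_exclusive"])
    mentions = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("||")
            named = dict(zip(fields[:-1], parts))
            offs = parts[len(fields) - 1 :]
            if len(offs) < 2 or len(offs) % 2:
                raise FormatError(f"{path}:{lineno}: expected start/end offset pairs")
            try:
                spans = tuple(
                    Span(int(offs[i]) - base, int(offs[i + 1]) - base + (0 if excl else 1))
                    for i in range(0, len(offs), 2)
                )
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
            doc_id = named.get("doc_id", "")
            doc = documents.get(doc_id)
            if doc is None:
                raise ValidationError(f"{path}:{lineno}: unknown doc_id {doc_id!r}")
            surface = " ".join(doc.text[s.start : s.end] for s in spans)
            mentions.append(
                MentionAnnotation(
                    mention_id=f"{doc_id}:{lineno}",
                    doc_id=doc_id,
                    spans=spans,
                    surface=surface,
                    concept=named.get("concept", CUI_LESS),
                    fold=str(cfg["fold"]),
                )
            )
    return mentions


# ---------------------------------------------------------------------------
# Notes and admissions I/O
# ---------------------------------------------------------------------------


def _escape_text(text: str) -> str:
    return text.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def _unescape_text(text: str) -> str:
    out, i = [], 0
    while i < len(text):
        c = text[i]
        if c == "\\" and i + 1 < len(text):
            nxt = text[i + 1]
            out.append({"t": "\t", "n": "\n", "\\": "\\"}.get(nxt, "\\" + nxt))
            i += 2
        else:
            out.append(c)
            i += 1
    return "".join(out)


def write_notes(documents: Iterable[Document], path: str | Path) -> None:
    """Two-column TSV (doc_id, text); newlines/tabs in text are escaped."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for d in documents:
            fh.write(f"{d.doc_id}\t{_escape_text(d.text)}\n")


def read_notes(path: str | Path) -> dict[str, Document]:
    """Read notes from a directory of one UTF-8 file per doc_id, or from a
    two-column TSV.  The admission key defaults to the doc_id."""
    path = Path(path)
    docs: dict[str, Document] = {}
    if path.is_dir():
        for f in sorted(path.iterdir()):
            if f.is_file():
                docs[f.stem] = Document(doc_id=f.stem, text=f.read_text(encoding="utf-8"))
        return docs
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                doc_id, text = line.rstrip("\n").split("\t", 1)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields") from exc
            docs[doc_id] = Document(doc_id=doc_id, text=_unescape_text(text))
    return docs


def write_admissions(admissions: Iterable[Admission], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for a in admissions:
            fh.write(f"{a.admission_id}\t{','.join(sorted(a.icd_codes))}\n")


def read_admissions(path: str | Path) -> dict[str, Admission]:
    admissions: dict[str, Admission] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) not in (1, 2):
                raise FormatError(f"{path}:{lineno}: expected 1-2 tab-separated fields")
            adm_id = parts[0]
            codes = frozenset(c for c in parts[1].split(",") if c) if len(parts) == 2 else frozenset()
            admissions[adm_id] = Admission(admission_id=adm_id, icd_codes=codes)
    return admissions
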