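"""Synthetic clinical-corpus generator.

Real evaluations of disorder-synonym discovery run on access-restricted data
(annotated clinical notes plus admission-level ICD-9 codes).  This module
plants the same statistical structure in synthetic text so the full pipeline
is exercisable and testable:

* concepts with several surface forms — lexically similar variants (single
  character edits, like "dilated RA"/"dilated RV"), lexically unrelated
  strings (like "cerebrovascular accident"/"stroke"), and initialisms;
* concept-specific context cues: each concept owns cue words that co-occur
  with its mentions inside the sentence, the signal a contextual encoder
  should exploit;
* document-level ICD codes statistically tied to the concepts mentioned.

No attempt is made at clinically realistic language — only the statistical
properties the method relies on.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import (
    Admission,
    Document,
    MentionAnnotation,
    Span,
    normalize_surface,
    write_admissions,
    write_mention_table,
    write_notes,
)

FOLDS = ("train", "tune", "test")

_CONSONANTS = "bcdfghjklmnpqrstvwz"
_VOWELS = "aeiou"
_SYLLABLES = tuple(c + v for c in _CONSONANTS for v in _VOWELS)


@dataclass(frozen=True)
class ConceptSpec:
    """Ground truth for one synthetic concept: its identifier, the surface
    forms its mentions use, its context-cue words and its ICD-9-like code."""

    concept_id: str
    surface_forms: tuple[str, ...]
    cue_tokens: tuple[str, ...]
    icd_code: str

    def __post_init__(self) -> None:
        normalized = [normalize_surface(s) for s in self.surface_forms]
        if len(set(normalized)) != len(normalized):
            raise ValueError(f"{self.concept_id}: surface forms collide after normalization")


@dataclass(frozen=True)
class GenConfig:
    """Study conditions for one synthetic corpus.

    ``frac_lexical_synonyms`` is the probability that a non-base surface form
    is a single-character edit of the base form rather than an unrelated
    string; ``abbreviation_rate`` the probability a multiword form is replaced
    by its initialism; ``cue_strength`` the probability a mention's sentence
    carries one of its concept's cue words; ``icd_noise`` the probability a
    mentioned concept's code is dropped from (or a random code added to) the
    document's admission.
    """

    n_concepts: int = 25
    forms_per_concept: int = 3
    frac_lexical_synonyms: float = 0.0
    abbreviation_rate: float = 0.1
    cue_strength: float = 0.9
    icd_noise: float = 0.1
    n_docs: int = 200
    sentences_per_doc: int = 5
    mentions_per_doc: int = 3
    concepts_per_doc: int = 2
    split: tuple[float, float, float] = (0.4, 0.3, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_lexical_synonyms", "abbreviation_rate", "cue_strength", "icd_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("n_concepts", "forms_per_concept", "n_docs", "sentences_per_doc",
                     "mentions_per_doc", "concepts_per_doc"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.mentions_per_doc > self.sentences_per_doc:
            raise ValueError("mentions_per_doc cannot exceed sentences_per_doc")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")


def _fresh_word(rng, syllables, n_syl, seen: set[str]) -> str:
    for _ in range(1000):
        w = "".join(syllables[i] for i in rng.integers(0, len(syllables), size=n_syl))
        if w not in seen:
            seen.add(w)
            return w
    raise RuntimeError("syllable inventory exhausted")


def _edit_one(rng: np.random.Generator, base: str, taken: set[str]) -> str:
    """Single character substitution of a letter, avoiding collisions."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    positions = [i for i, c in enumerate(base) if c != " "]
    for _ in range(1000):
        i = int(rng.choice(positions))
        c = letters[int(rng.integers(0, len(letters)))]
        if c == base[i]:
            continue
        cand = base[:i] + c + base[i + 1 :]
        if normalize_surface(cand) not in taken:
            return cand
    raise RuntimeError("could not produce a distinct single-edit variant")


def _initialism(form: str) -> str:
    return "".join(w[0] for w in form.split()).upper()


def generate_concepts(config: GenConfig) -> list[ConceptSpec]:
    """Build the synthetic concept inventory: surface forms, cue words, codes.

    Deterministic given ``config.seed``.  Dissimilar forms are drawn from a
    rotating slice of a shuffled syllable inventory so that distinct forms
    share as little character material as chance allows.
    """
    if config.forms_per_concept < 2:
        warnings.warn(
            "forms_per_concept < 2: no concept will have synonyms, so "
            "synonym evaluation downstream will have no eligible queries",
            stacklevel=2,
        )
    rng = np.random.default_rng([config.seed, 11])
    syl = list(_SYLLABLES)
    rng.shuffle(syl)
    seen_words: set[str] = set()
    concepts = []
    chunk = 12  # syllables available to each dissimilar form
    counter = 0
    for i in range(config.n_concepts):
        taken: set[str] = set()
        base = " ".join(
            _fresh_word(rng, syl, int(rng.integers(2, 4)), seen_words) for _ in range(2)
        )
        forms = [base]
        taken.add(normalize_surface(base))
        for _ in range(config.forms_per_concept - 1):
            if rng.random() < config.frac_lexical_synonyms:
                form = _edit_one(rng, base, taken)
            else:
                lo = (counter * chunk) % len(syl)
                counter += 1
                slice_ = syl[lo:] + syl[:lo]
                n_words = int(rng.integers(1, 3))
                form = " ".join(
                    _fresh_word(rng, slice_[:chunk], int(rng.integers(2, 5)), seen_words)
                    for _ in range(n_words)
                )
            forms.append(form)
            taken.add(normalize_surface(form))
        # abbreviation pass: multiword forms collapse to initialisms
        for j, form in enumerate(forms):
            if len(form.split()) >= 2 and rng.random() < config.abbreviation_rate:
                abbr = _initialism(form)
                if normalize_surface(abbr) not in taken and len(abbr) >= 2:
                    taken.discard(normalize_surface(form))
                    forms[j] = abbr
                    taken.add(normalize_surface(abbr))
        cues = tuple(_fresh_word(rng, syl, 3, seen_words) for _ in range(2))
        concepts.append(
            ConceptSpec(
                concept_id=f"C{i:04d}",
                surface_forms=tuple(forms),
                cue_tokens=cues,
                icd_code=f"{100 + i}.{i % 10}",
            )
        )
    return concepts


def _background_vocab(rng: np.random.Generator, size: int, seen: set[str]) -> list[str]:
    return [_fresh_word(rng, list(_SYLLABLES), int(rng.integers(1, 3)), seen) for _ in range(size)]


def generate_corpus(
    concepts: Sequence[ConceptSpec], config: GenConfig
) -> tuple[list[Document], list[MentionAnnotation], list[Admission]]:
    """Emit documents, the gold mention table, and per-document admissions.

    Each document samples a small concept subset; each mention sentence is
    Zipf-distributed filler plus the mention surface, and with probability
    ``cue_strength`` one cue token of the mention's concept placed adjacent
    to it.  One admission per document, carrying the codes of the mentioned
    concepts perturbed by ``icd_noise``.  Folds are assigned per document.
    """
    rng = np.random.default_rng([config.seed, 23])
    seen = {normalize_surface(w) for c in concepts for f in c.surface_forms for w in f.split()}
    seen |= {w for c in concepts for w in c.cue_tokens}
    background = _background_vocab(rng, 150, seen)
    zipf = 1.0 / np.arange(1, len(background) + 1)
    zipf /= zipf.sum()
    code_pool = [c.icd_code for c in concepts]

    documents, mentions, admissions = [], [], []
    for di in range(config.n_docs):
        doc_id = f"d{di:04d}"
        fold = FOLDS[int(rng.choice(3, p=list(config.split)))]
        subset = rng.choice(len(concepts), size=min(config.concepts_per_doc, len(concepts)),
                            replace=False)
        slots = set(rng.choice(config.sentences_per_doc, size=config.mentions_per_doc,
                               replace=False).tolist())
        lines: list[str] = []
        offset = 0
        mentioned: set[int] = set()
        mk = 0
        for si in range(config.sentences_per_doc):
            words = [background[i] for i in rng.choice(len(background), size=int(rng.integers(3, 7)), p=zipf)]
            if si in slots:
                ci = int(rng.choice(subset))
                mentioned.add(ci)
                concept = concepts[ci]
                form = concept.surface_forms[int(rng.integers(0, len(concept.surface_forms)))]
                pos = int(rng.integers(0, len(words) + 1))
                pieces = words[:pos] + [form] + words[pos:]
                mention_slot = pos
                if rng.random() < config.cue_strength:
                    cue = concept.cue_tokens[int(rng.integers(0, len(concept.cue_tokens)))]
                    before = bool(rng.integers(0, 2))
                    at = mention_slot if before else mention_slot + 1
                    pieces.insert(at, cue)
                    if before:
                        mention_slot += 1
                start = offset + sum(len(p) + 1 for p in pieces[:mention_slot])
                line = " ".join(pieces) + " ."
                mentions.append(
                    MentionAnnotation(
                        mention_id=f"m{di:04d}.{mk}",
                        doc_id=doc_id,
                        spans=(Span(start, start + len(form)),),
                        surface=form,
                        concept=concept.concept_id,
                        fold=fold,
                    )
                )
                mk += 1
            else:
                line = " ".join(words) + " ."
            lines.append(line)
            offset += len(line) + 1  # newline
        text = "\n".join(lines)
        documents.append(Document(doc_id=doc_id, text=text, admission_id=doc_id))
        codes = set()
        for ci in mentioned:
            if rng.random() >= config.icd_noise:
                codes.add(concepts[ci].icd_code)
            if rng.random() < config.icd_noise:
                codes.add(code_pool[int(rng.integers(0, len(code_pool)))])
        admissions.append(Admission(admission_id=doc_id, icd_codes=frozenset(codes)))
    return documents, mentions, admissions


def generate(config: GenConfig):
    """Concept inventory plus corpus in one call."""
    concepts = generate_concepts(config)
    documents, mentions, admissions = generate_corpus(concepts, config)
    return concepts, documents, mentions, admissions


def write_concepts(concepts: Sequence[ConceptSpec], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for c in concepts:
            fh.write(
                json.dumps(
                    {
                        "concept_id": c.concept_id,
                        "surface_forms": list(c.surface_forms),
                        "cue_tokens": list(c.cue_tokens),
                        "icd_code": c.icd_code,
                    }
                )
                + "\n"
            )


def read_concepts(path: str | Path) -> list[ConceptSpec]:
    concepts = []
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                row = json.loads(line)
                concepts.append(
                    ConceptSpec(
                        concept_id=row["concept_id"],
                        surface_forms=tuple(row["surface_forms"]),
                        cue_tokens=tuple(row["cue_tokens"]),
                        icd_code=row["icd_code"],
                    )
                )
    return concepts


def write_corpus(
    concepts: Sequence[ConceptSpec],
    documents: Sequence[Document],
    mentions: Sequence[MentionAnnotation],
    admissions: Sequence[Admission],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the canonical corpus files plus the ground-truth inventory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mentions": outdir / "mentions.tsv",
        "notes": outdir / "notes.tsv",
        "admissions": outdir / "admissions.tsv",
        "concepts": outdir / "concepts.jsonl",
    }
    write_mention_table(mentions, paths["mentions"])
    write_notes(documents, paths["notes"])
    write_admissions(admissions, paths["admissions"])
    write_concepts(concepts, paths["concepts"])
    return paths
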