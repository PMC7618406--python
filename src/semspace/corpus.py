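"""Corpus ingestion, labeling, lemmatization and vocabulary extraction.

A *corpus* here is a labeled collection of tokenized documents.  Documents
are classified as mathematical or not by scanning their raw text for portal
tag strings (the convention used for French Wikipedia, where a page's footer
names the portals it belongs to).  From a lemmatized corpus we extract a
frequency-ranked vocabulary, per-corpus log frequencies (log10 occurrences
per million tokens) and curricular annotations (grade of acquisition,
grammatical category, meta-math and polysemy flags).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GRADE_LEVELS",
    "GRADE_GROUPS",
    "GRADE_TO_GROUP",
    "EDUCATION_LEVELS",
    "EDUCATION_TO_GROUP",
    "DEFAULT_PORTAL_TAGS",
    "Document",
    "Corpus",
    "VocabularyEntry",
    "tokenize",
    "classify_documents",
    "merge_corpora",
    "lemmatize_corpus",
    "build_vocabulary",
    "compute_log_frequency",
    "add_reference_counts",
    "annotate_vocabulary",
    "experimental_subset",
    "vocabulary_frame",
]

#: Ordered school grades of acquisition (French curriculum convention).
GRADE_LEVELS: tuple[str, ...] = (
    "primary",
    "6-7th",
    "8-9th",
    "10th",
    "11-12th",
    "bachelor",
    "licence",
    "master",
)

#: Merged grade groups used in the behavioral design: middle-school grades,
#: high-school grades, and the two university graduate levels are pooled.
GRADE_GROUPS: tuple[str, ...] = (
    "primary",
    "6-9th",
    "10-12th",
    "bachelor",
    "licence+master",
)

GRADE_TO_GROUP: dict[str, str] = {
    "primary": "primary",
    "6-7th": "6-9th",
    "8-9th": "6-9th",
    "10th": "10-12th",
    "11-12th": "10-12th",
    "bachelor": "bachelor",
    "licence": "licence+master",
    "master": "licence+master",
}

#: Ordered self-reported math-education levels of participants.
EDUCATION_LEVELS: tuple[str, ...] = (
    "primary",
    "medium-school",
    "high-school",
    "college-1",
    "college-2",
    "college-3",
    "college-4",
    "master",
    "phd",
)

#: Highest grade group whose word pairs a participant of each education
#: level is shown (pairs at or below one's grade level).
EDUCATION_TO_GROUP: dict[str, str] = {
    "primary": "primary",
    "medium-school": "6-9th",
    "high-school": "10-12th",
    "college-1": "bachelor",
    "college-2": "bachelor",
    "college-3": "bachelor",
    "college-4": "bachelor",
    "master": "licence+master",
    "phd": "licence+master",
}

#: Portal footer strings marking a French Wikipedia page as mathematical.
DEFAULT_PORTAL_TAGS: tuple[str, ...] = (
    "Portail des mathématiques",
    "Portail de la géométrie",
    "Portail de l'analyse",
    "Portail de l'algèbre",
    "Portail des probabilités et de la statistique",
    "Arithmétique et théorie des nombres",
    "Portail de la logique",
    "Portail de l'informatique théorique",
)


@dataclass
class Document:
    """One tokenized document with its math/non-math label."""

    doc_id: str
    tokens: list[str]
    label: str | None = None


@dataclass
class Corpus:
    """A collection of documents from one corpus variant."""

    documents: list[Document]
    variant: str = "math"  # one of {math, nonmath, global}

    @property
    def token_count(self) -> int:
        return sum(len(d.tokens) for d in self.documents)

    def __len__(self) -> int:
        return len(self.documents)


@dataclass
class VocabularyEntry:
    """One vocabulary word with counts, log frequencies and annotations."""

    word: str
    rank: int
    count_math: int = 0
    count_nonmath: int = 0
    logfreq_math: float = float("nan")
    logfreq_nonmath: float = float("nan")
    grade: str | None = None
    category: frozenset[str] = field(default_factory=frozenset)
    meta_math_flag: bool = False
    polysemy_flag: bool = False
    annotation_missing: bool = True


def tokenize(text: str) -> list[str]:
    """Whitespace tokenization with lowercasing (test-corpus default).

    Real-corpus tokenizers are pluggable: any callable producing a token
    list can be passed wherever a raw text is ingested.
    """
    return text.lower().split()


def classify_documents(
    documents: Iterable[tuple[str, str]] | Mapping[str, str],
    portal_tags: Sequence[str] = DEFAULT_PORTAL_TAGS,
    tokenizer: Callable[[str], list[str]] = tokenize,
) -> tuple[Corpus, Corpus]:
    """Partition raw documents into a math and a non-math corpus.

    A document is labeled ``math`` iff its raw text contains at least one
    of the portal tag strings; all others are ``nonmath``.

    Parameters
    ----------
    documents : iterable of (doc_id, text) or mapping doc_id -> text
    portal_tags : tag strings searched verbatim in the raw text
    tokenizer : callable turning the raw text into tokens

    Returns
    -------
    (math_corpus, nonmath_corpus)
    """
    if isinstance(documents, Mapping):
        items = list(documents.items())
    else:
        items = list(documents)
    if not items:
        raise ValueError("no input documents to classify")
    if not portal_tags:
        raise ValueError("portal_tags must be non-empty")
    math_docs: list[Document] = []
    nonmath_docs: list[Document] = []
    for doc_id, text in items:
        label = "math" if any(tag in text for tag in portal_tags) else "nonmath"
        doc = Document(doc_id=str(doc_id), tokens=tokenizer(text), label=label)
        (math_docs if label == "math" else nonmath_docs).append(doc)
    return Corpus(math_docs, "math"), Corpus(nonmath_docs, "nonmath")


def merge_corpora(math: Corpus, nonmath: Corpus) -> Corpus:
    """Concatenate the math and non-math corpora into the global corpus."""
    return Corpus(list(math.documents) + list(nonmath.documents), "global")


def lemmatize_corpus(
    corpus: Corpus,
    lemmatizer: Mapping[str, str] | Callable[[str], str],
    passes: int = 2,
) -> Corpus:
    """Replace every token by its lemma, applying the lemmatizer ``passes``
    times (a second pass catches lemmas that are themselves inflected).

    Word forms unknown to the lemmatizer map to themselves (identity
    fallback), so the token count is always preserved.
    """
    if passes < 1:
        raise ValueError("passes must be >= 1")
    if callable(lemmatizer):
        apply_once = lemmatizer
    else:
        table = dict(lemmatizer)
        apply_once = lambda w: table.get(w, w)  # noqa: E731

    def lemma(word: str) -> str:
        for _ in range(passes):
            word = apply_once(word)
        return word

    docs = [
        Document(d.doc_id, [lemma(t) for t in d.tokens], d.label)
        for d in corpus.documents
    ]
    return Corpus(docs, corpus.variant)


def build_vocabulary(
    corpus: Corpus, max_size: int = 50_000, min_count: int = 5
) -> list[VocabularyEntry]:
    """Extract the frequency-ranked vocabulary of a (lemmatized) corpus.

    Words occurring fewer than ``min_count`` times are dropped; the rest
    are sorted by decreasing count (lexicographic tie-break for
    reproducible ranks) and truncated to ``max_size``.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    counts: Counter[str] = Counter()
    for doc in corpus.documents:
        counts.update(doc.tokens)
    total = corpus.token_count
    kept = sorted(
        ((w, c) for w, c in counts.items() if c >= min_count),
        key=lambda wc: (-wc[1], wc[0]),
    )[:max_size]
    entries = []
    for rank, (word, count) in enumerate(kept, start=1):
        entries.append(
            VocabularyEntry(
                word=word,
                rank=rank,
                count_math=count,
                logfreq_math=compute_log_frequency(count, total),
            )
        )
    return entries


def compute_log_frequency(count: int, total_tokens: int) -> float:
    """log10 occurrences per million tokens: ``log10(count/total * 1e6)``."""
    if total_tokens < 1:
        raise ValueError("total_tokens must be positive")
    if count < 1:
        raise ValueError("log frequency undefined for count < 1")
    return math.log10(count / total_tokens * 1e6)


def add_reference_counts(
    entries: Sequence[VocabularyEntry], reference: Corpus
) -> list[VocabularyEntry]:
    """Fill ``count_nonmath``/``logfreq_nonmath`` from a reference corpus.

    Words absent from the reference keep a missing (NaN) log frequency.
    """
    counts: Counter[str] = Counter()
    for doc in reference.documents:
        counts.update(doc.tokens)
    total = reference.token_count
    out = []
    for e in entries:
        c = counts.get(e.word, 0)
        lf = compute_log_frequency(c, total) if c >= 1 else float("nan")
        out.append(replace(e, count_nonmath=c, logfreq_nonmath=lf))
    return out


def annotate_vocabulary(
    entries: Sequence[VocabularyEntry],
    annotation_table: pd.DataFrame | Mapping[str, Mapping],
) -> list[VocabularyEntry]:
    """Join grade / category / flag annotations onto vocabulary entries.

    The join is outer on the vocabulary side: unannotated words keep
    ``annotation_missing=True`` and are never dropped.  Duplicate keys in
    the annotation table are an error.
    """
    if isinstance(annotation_table, pd.DataFrame):
        if annotation_table.index.name != "word" and "word" in annotation_table:
            annotation_table = annotation_table.set_index("word")
        if annotation_table.index.duplicated().any():
            dups = annotation_table.index[annotation_table.index.duplicated()]
            raise ValueError(f"duplicate annotation keys: {sorted(set(dups))}")
        records = {w: row.to_dict() for w, row in annotation_table.iterrows()}
    else:
        records = {k: dict(v) for k, v in annotation_table.items()}
    out = []
    for e in entries:
        rec = records.get(e.word)
        if rec is None:
            out.append(replace(e, annotation_missing=True))
            continue
        grade = rec.get("grade")
        if grade is not None and grade not in GRADE_LEVELS:
            raise ValueError(f"unknown grade {grade!r} for word {e.word!r}")
        cat = rec.get("category", frozenset())
        if isinstance(cat, str):
            cat = frozenset(cat.split("|")) if cat else frozenset()
        out.append(
            replace(
                e,
                grade=grade,
                category=frozenset(cat),
                meta_math_flag=bool(rec.get("meta_math_flag", False)),
                polysemy_flag=bool(rec.get("polysemy_flag", False)),
                annotation_missing=False,
            )
        )
    return out


def experimental_subset(entries: Sequence[VocabularyEntry]) -> list[VocabularyEntry]:
    """Words eligible for the behavioral experiment: annotated numbers,
    nouns or symbols that are neither meta-mathematical nor polysemic."""
    eligible = {"number", "noun", "symbol"}
    return [
        e
        for e in entries
        if not e.annotation_missing
        and e.category & eligible
        and not e.meta_math_flag
        and not e.polysemy_flag
    ]


def vocabulary_frame(entries: Sequence[VocabularyEntry]) -> pd.DataFrame:
    """Tabular view of the vocabulary (the TSV dialect written to disk)."""
    return pd.DataFrame(
        {
            "word": [e.word for e in entries],
            "rank": [e.rank for e in entries],
            "count_math": [e.count_math for e in entries],
            "count_nonmath": [e.count_nonmath for e in entries],
            "logfreq_math": [e.logfreq_math for e in entries],
            "logfreq_nonmath": [e.logfreq_nonmath for e in entries],
            "grade": [e.grade for e in entries],
            "category": ["|".join(sorted(e.category)) for e in entries],
            "meta_math_flag": [e.meta_math_flag for e in entries],
            "polysemy_flag": [e.polysemy_flag for e in entries],
        }
    )
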