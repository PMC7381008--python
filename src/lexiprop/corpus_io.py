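"""Reading, cleaning, filtering and tokenizing post-level corpora.

A corpus is an ordered list of :class:`Post` records (one social-media post
each).  Throughout the package one post is one document: TF-IDF document
frequencies, SO-PMI co-occurrence windows and label-propagation inputs all
count at the post level.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "Post",
    "Corpus",
    "ConfigurationError",
    "load_posts",
    "write_jsonl",
    "strip_emoji",
    "filter_unrelated",
    "tokenize",
    "whitespace_tokenizer",
    "DictionaryTokenizer",
]

GROUPS = ("depressed", "nondepressed", "unknown")


class ConfigurationError(ValueError):
    """Bad schema, pattern, or option supplied by the caller."""


@dataclass
class Post:
    """One social-media post.

    ``group`` marks the user cohort the post's author belongs to
    (``depressed`` / ``nondepressed`` / ``unknown``); it is a property of
    the user, so all posts of one user carry the same value.
    """

    user_id: str
    text: str
    timestamp: str | None = None
    group: str = "unknown"
    tokens: list[str] | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ConfigurationError(f"unknown group {self.group!r}; expected one of {GROUPS}")


@dataclass
class Corpus:
    """Ordered post collection with per-user index and drop bookkeeping."""

    posts: list[Post] = field(default_factory=list)
    n_dropped: int = 0
    n_duplicates: int = 0

    def __len__(self) -> int:
        return len(self.posts)

    @property
    def documents(self) -> list[list[str]]:
        """Per-post token sequences; requires :func:`tokenize` to have run."""
        docs = []
        for p in self.posts:
            if p.tokens is None:
                raise ValueError("corpus is not tokenized; call tokenize() first")
            docs.append(p.tokens)
        return docs

    @property
    def by_user(self) -> dict[str, list[int]]:
        index: dict[str, list[int]] = {}
        for i, p in enumerate(self.posts):
            index.setdefault(p.user_id, []).append(i)
        return index

    @property
    def user_groups(self) -> dict[str, str]:
        groups: dict[str, str] = {}
        for p in self.posts:
            prev = groups.setdefault(p.user_id, p.group)
            if prev != p.group:
                raise ValueError(f"user {p.user_id!r} has posts in more than one group")
        return groups

    def vocabulary(self) -> set[str]:
        vocab: set[str] = set()
        for doc in self.documents:
            vocab.update(doc)
        return vocab


# ---------------------------------------------------------------------------
# loading

_DEFAULT_SCHEMA = {"user_id": "user_id", "text": "text", "timestamp": "timestamp", "group": "group"}


def _iter_records(source, fmt: str | None):
    if isinstance(source, (str, Path)):
        path = Path(source)
        if fmt is None:
            fmt = "tsv" if path.suffix.lower() in {".tsv", ".tab"} else "jsonl"
        text = path.read_text(encoding="utf-8")
        if fmt == "jsonl":
            for line in text.splitlines():
                if line.strip():
                    yield json.loads(line)
        elif fmt == "tsv":
            reader = csv.DictReader(io.StringIO(text), delimiter="\t")
            yield from reader
        else:
            raise ConfigurationError(f"unknown corpus format {fmt!r}")
    else:
        yield from source


def load_posts(
    source: str | Path | Iterable[Mapping[str, object]],
    schema: Mapping[str, str] | None = None,
    fmt: str | None = None,
) -> Corpus:
    """Load post records into a :class:`Corpus`.

    Parameters
    ----------
    source
        Path to a UTF-8 JSONL or TSV file, or any iterable of dict-like
        records.
    schema
        Maps the canonical field names (``user_id``, ``text``, optionally
        ``timestamp`` and ``group``) to the keys used in the records.
    fmt
        ``"jsonl"`` or ``"tsv"``; inferred from the file suffix when omitted.

    Records with a missing or empty ``text`` are dropped and counted in
    ``Corpus.n_dropped``.  A post whose text is byte-identical to an earlier
    post of the same user is dropped as a duplicate.
    """
    schema = {**_DEFAULT_SCHEMA, **(schema or {})}
    for mandatory in ("user_id", "text"):
        if mandatory not in schema:
            raise ConfigurationError(f"schema must map the mandatory field {mandatory!r}")

    corpus = Corpus()
    seen: set[tuple[str, str]] = set()
    for rec in _iter_records(source, fmt):
        user = rec.get(schema["user_id"])
        text = rec.get(schema["text"])
        if user is None or text is None or not str(text).strip():
            corpus.n_dropped += 1
            continue
        user = str(user)
        text = str(text)
        if (user, text) in seen:
            corpus.n_duplicates += 1
            continue
        seen.add((user, text))
        timestamp = rec.get(schema.get("timestamp", "timestamp"))
        group = rec.get(schema.get("group", "group")) or "unknown"
        corpus.posts.append(Post(user_id=user, text=text, timestamp=timestamp, group=str(group)))
    return corpus


def write_jsonl(corpus: Corpus, path: str | Path) -> None:
    """Write posts back out as UTF-8 JSONL with canonical field names."""
    with open(path, "w", encoding="utf-8") as fh:
        for p in corpus.posts:
            rec = {"user_id": p.user_id, "text": p.text}
            if p.timestamp is not None:
                rec["timestamp"] = p.timestamp
            if p.group != "unknown":
                rec["group"] = p.group
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# cleaning

# Unicode blocks treated as emoji/pictographs. ASCII-art emoticons are not
# touched; only these code-point ranges are removed.
_EMOJI_RANGES = (
    (0x1F600, 0x1F64F),  # Emoticons
    (0x1F300, 0x1F5FF),  # Misc Symbols and Pictographs
    (0x1F680, 0x1F6FF),  # Transport and Map
    (0x1F900, 0x1F9FF),  # Supplemental Symbols and Pictographs
    (0x2600, 0x26FF),    # Miscellaneous Symbols
    (0x2700, 0x27BF),    # Dingbats
)
_JOINERS = {0xFE0E, 0xFE0F, 0x200D}  # variation selectors + ZWJ


def _is_emoji(cp: int) -> bool:
    return any(lo <= cp <= hi for lo, hi in _EMOJI_RANGES)


def strip_emoji(text: str) -> str:
    """Remove emoji code points; variation selectors and zero-width joiners
    are removed only when adjacent to a removed code point.  Idempotent."""
    n = len(text)
    remove = [_is_emoji(ord(c)) for c in text]
    for i, c in enumerate(text):
        if ord(c) in _JOINERS:
            left = remove[i - 1] if i > 0 else False
            right = remove[i + 1] if i + 1 < n and _is_emoji(ord(text[i + 1])) else False
            if left or right:
                remove[i] = True
    return "".join(c for c, r in zip(text, remove) if not r)


def filter_unrelated(corpus: Corpus, patterns: Sequence[str]) -> tuple[Corpus, int]:
    """Drop every post whose text matches any of the regular expressions.

    Returns a new corpus (the input is untouched) and the removal count.
    """
    compiled = []
    for pat in patterns:
        try:
            compiled.append(re.compile(pat))
        except re.error as exc:
            raise ConfigurationError(f"invalid pattern {pat!r}: {exc}") from exc
    kept = [p for p in corpus.posts if not any(rx.search(p.text) for rx in compiled)]
    removed = len(corpus.posts) - len(kept)
    out = Corpus(posts=list(kept), n_dropped=corpus.n_dropped, n_duplicates=corpus.n_duplicates)
    return out, removed


# ---------------------------------------------------------------------------
# tokenization

def whitespace_tokenizer(text: str) -> list[str]:
    return text.split()


class DictionaryTokenizer:
    """Wrap a base tokenizer so that user-dictionary entries are never split.

    Multi-token dictionary entries (e.g. ``"x y"``) are re-merged after base
    tokenization by greedy longest match over adjacent tokens.
    """

    def __init__(self, base: Callable[[str], list[str]] | None = None,
                 words: Iterable[str] = ()) -> None:
        self.base = base or whitespace_tokenizer
        self.words = set(words)
        self._max_parts = max((len(w.split()) for w in self.words), default=1)

    def __call__(self, text: str) -> list[str]:
        toks = self.base(text)
        if self._max_parts == 1:
            return toks
        out: list[str] = []
        i = 0
        while i < len(toks):
            for span in range(min(self._max_parts, len(toks) - i), 1, -1):
                joined = " ".join(toks[i : i + span])
                if joined in self.words:
                    out.append(joined)
                    i += span
                    break
            else:
                out.append(toks[i])
                i += 1
        return out


def _read_word_list(path: str | Path) -> list[str]:
    try:
        lines = Path(path).read_text(encoding="utf-8").splitlines()
    except OSError as exc:
        raise IOError(f"cannot read dictionary file {path}: {exc}") from exc
    return [ln.strip() for ln in lines if ln.strip()]


def tokenize(
    corpus: Corpus,
    tokenizer: Callable[[str], list[str]] | None = None,
    user_dicts: Sequence[str | Path] = (),
) -> Corpus:
    """Populate per-post token sequences in place (and return the corpus).

    Posts that tokenize to nothing are dropped and counted in ``n_dropped``.
    Words listed in ``user_dicts`` files (one per line) are protected from
    splitting.
    """
    words: set[str] = set()
    for path in user_dicts:
        words.update(_read_word_list(path))
    tok: Callable[[str], list[str]]
    if words:
        tok = DictionaryTokenizer(tokenizer, words)
    else:
        tok = tokenizer or whitespace_tokenizer

    kept: list[Post] = []
    for p in corpus.posts:
        tokens = [t for t in tok(p.text) if t]
        if not tokens:
            corpus.n_dropped += 1
            continue
        p.tokens = tokens
        kept.append(p)
    corpus.posts = kept
    return corpus
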