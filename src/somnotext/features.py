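"""Text preprocessing, lexicon sentiment, and the classifier input tensor.

A labeled dataset of n posts becomes a dense array of shape
``(n, kappa, xi)``: ``kappa`` is the maximum number of surviving
(in-vocabulary) tokens over the dataset, and ``xi = dim + 3`` stacks each
token's word vector with three whole-post features — sentiment polarity
in [-1, 1], subjectivity in [0, 1], and the clock hour of posting
(0..23).  Posts shorter than ``kappa`` are zero-padded, so a position is
padding exactly when its full xi-vector is zero.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .labeling import LABEL_DEPRIVED, LabeledPost
from .timeutil import hour_of

logger = logging.getLogger(__name__)

# URLs, @mentions and #hashtags survive as single tokens; everything else
# splits on whitespace/punctuation.  \w covers accented letters, so
# Spanish-adjacent text is tokenized rather than discarded.
_TOKEN_RE = re.compile(r"https?://\S+|www\.\S+|[@#]\w+|[\w'-]+")
_ASCII_ALNUM = set("abcdefghijklmnopqrstuvwxyz0123456789")


def _read_wordlist(name: str) -> frozenset[str]:
    text = resources.files("somnotext.data").joinpath(name).read_text("utf-8")
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


@lru_cache(maxsize=None)
def load_stopwords() -> frozenset[str]:
    """Union of the bundled English and Spanish stopword snapshots."""
    return _read_wordlist("stopwords_en.txt") | _read_wordlist("stopwords_es.txt")


@lru_cache(maxsize=None)
def _default_lexicon() -> dict[str, tuple[float, float]]:
    text = resources.files("somnotext.data").joinpath(
        "sentiment_lexicon.csv"
    ).read_text("utf-8")
    return _parse_lexicon(csv.DictReader(text.splitlines()))


def _parse_lexicon(reader) -> dict[str, tuple[float, float]]:
    lex: dict[str, tuple[float, float]] = {}
    for row in reader:
        pol = float(row["polarity"])
        subj = float(row["subjectivity"])
        if not (-1.0 <= pol <= 1.0 and 0.0 <= subj <= 1.0):
            raise ValueError(f"lexicon entry {row['word']!r} out of range")
        lex[row["word"].strip().lower()] = (pol, subj)
    return lex


def load_lexicon(path=None) -> dict[str, tuple[float, float]]:
    """Load a ``word,polarity,subjectivity`` CSV, or the bundled lexicon."""
    if path is None:
        return _default_lexicon()
    with open(path, encoding="utf-8") as fh:
        return _parse_lexicon(csv.DictReader(fh))


def preprocess(text: str) -> list[str]:
    """Lower-case, tokenize, and filter a post's text.

    Tokens found in the bundled stopword lists are removed, as are tokens
    with no ASCII letter or digit (pure emoji/symbol runs); accented Latin
    words are kept.  URLs, #hashtags and @mentions stay whole.
    """
    stop = load_stopwords()
    toks = _TOKEN_RE.findall(text.lower().replace("’", "'"))
    return [
        t
        for t in toks
        if t not in stop and any(c in _ASCII_ALNUM for c in t)
    ]


def sentiment_scores(
    text: str, lexicon: dict[str, tuple[float, float]] | None = None
) -> tuple[float, float]:
    """Whole-post (polarity, subjectivity): the mean of the lexicon scores
    of matched tokens, (0, 0) when nothing matches, clipped to range."""
    lex = _default_lexicon() if lexicon is None else lexicon
    hits = [lex[t] for t in preprocess(text) if t in lex]
    if not hits:
        return 0.0, 0.0
    pol = float(np.clip(np.mean([h[0] for h in hits]), -1.0, 1.0))
    subj = float(np.clip(np.mean([h[1] for h in hits]), 0.0, 1.0))
    return pol, subj


@dataclass(frozen=True)
class TensorSpec:
    """Dimensions of the input tensor: kappa tokens per post, word-vector
    length dim, per-token feature length xi = dim + 3."""

    kappa: int
    dim: int

    @property
    def xi(self) -> int:
        return self.dim + 3


@dataclass
class FeatureTensor:
    """values (n, kappa, xi), binary labels (1 = sleep deprived), post ids."""

    values: np.ndarray
    labels: np.ndarray
    post_ids: list[str]
    spec: TensorSpec

    def __len__(self) -> int:
        return self.values.shape[0]

    def subset(self, idx) -> "FeatureTensor":
        idx = np.asarray(idx)
        return FeatureTensor(
            self.values[idx],
            self.labels[idx],
            [self.post_ids[i] for i in idx],
            self.spec,
        )


def build_tensor(
    rows: list[LabeledPost],
    emb,
    lexicon: dict[str, tuple[float, float]] | None = None,
    dtype=np.float32,
) -> FeatureTensor:
    """Assemble the input tensor from labeled (non-dropped) posts.

    Tokens absent from the embedding vocabulary are skipped (mirroring
    rare-word removal before vectorization); ``kappa`` is the maximum
    surviving token count.  A post whose tokens are all out-of-vocabulary
    stays as an all-zero row (logged).
    """
    if not rows:
        raise ValueError("no rows to build a tensor from")
    for lp in rows:
        if lp.drop_reason != "none":
            raise ValueError(f"post {lp.post.post_id!r} was dropped; cannot featurize")
    lex = _default_lexicon() if lexicon is None else lexicon
    token_lists = [
        [t for t in preprocess(lp.post.text) if t in emb] for lp in rows
    ]
    kappa = max((len(ts) for ts in token_lists), default=0) or 1
    spec = TensorSpec(kappa=kappa, dim=emb.dim)
    values = np.zeros((len(rows), kappa, spec.xi), dtype=dtype)
    labels = np.zeros(len(rows), dtype=np.int64)
    n_empty = 0
    for i, (lp, toks) in enumerate(zip(rows, token_lists)):
        labels[i] = 1 if lp.label == LABEL_DEPRIVED else 0
        if not toks:
            n_empty += 1
            continue
        pol, subj = sentiment_scores(lp.post.text, lex)
        hour = float(hour_of(lp.post.timestamp))
        for j, t in enumerate(toks):
            values[i, j, : spec.dim] = emb[t]
            values[i, j, spec.dim :] = (pol, subj, hour)
    if n_empty:
        logger.warning("%d posts had no in-vocabulary tokens (all-zero rows)", n_empty)
    return FeatureTensor(values, labels, [lp.post.post_id for lp in rows], spec)
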