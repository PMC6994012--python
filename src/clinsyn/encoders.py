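"""Mention representations: type-level vector averaging, a desk-scale
reference bidirectional language model (BiLM) with contextual layers, ICD-9
patient-context vectors, and the fusion architectures that combine them.

The reference BiLM keeps the structural commitments of full-scale
contextual encoders while staying trainable on one CPU in seconds-to-minutes:

* a context-independent token representation ("layer 0"), either a word
  embedding or a character-CNN (so out-of-vocabulary words still get finite
  representations);
* two recurrent layers per direction ("layer 1", "layer 2"), forward and
  backward, whose per-direction states are concatenated (forward half first);
* a prediction softmax over the word vocabulary whose parameters, like the
  token representation, are shared between the two directions;
* two optional patient-context fusion sites: *input* fusion concatenates an
  admission-level ICD-code vector onto every layer-0 token representation
  before the recurrent layers; *output* fusion concatenates it onto the
  softmax input during training only, leaving the emitted token layers
  unchanged.

The training objective is cloze-style: token t_k is predicted from the
forward state at k-1 and the backward state at k+1, so the prediction input
is always the left⊕right (⊕ ICD) concatenation.  The contextual layers are
defined the same way: the layer-1/2 representation of token k concatenates
the forward state over t_1..t_{k-1} with the backward state over t_N..t_{k+1}
— the model's bidirectional *context* embedding of position k, which for
layer 2 is exactly the vector the trained softmax scores against the
vocabulary.  Keeping the token itself out of its contextual layers is what
lets lexically unrelated synonyms in interchangeable contexts meet in
representation space.  Recurrent cells are plain tanh units rather than
LSTMs, initialized input-dominant (recurrent weights scaled down) so the
state beside a mention is sharply driven by the nearest context words —
adequate for the short sentences and small vocabularies this reference model
targets.

Pretrained full-scale vectors (word2vec-style word vectors, Med2vec-style
code vectors) plug in as whitespace-delimited text tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .corpus import (
    Admission,
    AlignmentError,
    ConfigurationError,
    Document,
    FormatError,
    MentionAnnotation,
    Sentence,
    align_mention,
    normalize_surface,
    tokenize,
)

logger = logging.getLogger(__name__)

BOS = "<bos>"
EOS = "<eos>"
UNK = "<unk>"


# ---------------------------------------------------------------------------
# Vector tables
# ---------------------------------------------------------------------------


class VectorTable:
    """Immutable key → fixed-dimensional vector map.

    Lookup of a missing key returns None (absence is a value here: the
    out-of-vocabulary rule for type-level representations skips such tokens,
    it never substitutes a default vector).
    """

    def __init__(self, vectors: Mapping[str, np.ndarray]):
        if not vectors:
            raise ValueError("empty vector table")
        dims = {len(v) for v in vectors.values()}
        if len(dims) != 1:
            raise FormatError(f"inconsistent vector dimensionalities: {sorted(dims)}")
        self._vectors = {k: np.asarray(v, dtype=float) for k, v in vectors.items()}
        self.dim = dims.pop()

    def get(self, key: str) -> np.ndarray | None:
        return self._vectors.get(key)

    def __contains__(self, key: str) -> bool:
        return key in self._vectors

    def __len__(self) -> int:
        return len(self._vectors)

    def keys(self):
        return self._vectors.keys()


class WordVectorTable(VectorTable):
    """Type-level word vectors (word2vec text-format compatible)."""


class CodeVectorTable(VectorTable):
    """ICD-9 code vectors (Med2vec-style embeddings)."""


def read_vector_table(path: str | Path, kind: str = "word") -> VectorTable:
    """Read a whitespace-delimited text vector table.

    Format: one ``token v1 ... vd`` row per line, optionally preceded by a
    ``count dim`` header.  Ragged rows raise with their line number.
    """
    path = Path(path)
    cls = {"word": WordVectorTable, "code": CodeVectorTable}.get(kind)
    if cls is None:
        raise ConfigurationError(f"unknown vector-table kind {kind!r}")
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with path.open(encoding="utf-8") as fh:
        lines = [(i, ln) for i, ln in enumerate(fh, start=1) if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty vector table")
    first_fields = lines[0][1].split()
    start = 0
    if len(first_fields) == 2 and all(f.isdigit() for f in first_fields):
        dim = int(first_fields[1])
        start = 1
    for lineno, line in lines[start:]:
        fields = line.split()
        key, values = fields[0], fields[1:]
        if dim is None:
            dim = len(values)
        if len(values) != dim:
            raise FormatError(f"{path}:{lineno}: expected {dim} values, got {len(values)}")
        try:
            vectors[key] = np.array([float(v) for v in values])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric value") from exc
    return cls(vectors)


def write_vector_table(table: VectorTable, path: str | Path, header: bool = False) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        if header:
            fh.write(f"{len(table)} {table.dim}\n")
        for key in table.keys():
            vec = table.get(key)
            fh.write(key + " " + " ".join(repr(float(x)) for x in vec) + "\n")


def random_vector_table(keys: Iterable[str], dim: int, seed: int, kind: str = "code") -> VectorTable:
    """Gaussian random vector table — a synthetic stand-in for pretrained
    embeddings when only the fusion plumbing, not embedding quality, is under
    study."""
    rng = np.random.default_rng([seed, 5])
    cls = {"word": WordVectorTable, "code": CodeVectorTable}[kind]
    return cls({k: rng.normal(size=dim) / np.sqrt(dim) for k in sorted(set(keys))})


# ---------------------------------------------------------------------------
# Mention vectors and pooling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Provenance:
    encoder: str
    layer: int | None
    pooling: str | None
    fusion: str = "none"


@dataclass(frozen=True)
class MentionVector:
    mention_id: str
    vector: np.ndarray
    provenance: Provenance

    def __post_init__(self) -> None:
        vec = np.asarray(self.vector, dtype=float)
        if not np.all(np.isfinite(vec)):
            raise ValueError(f"{self.mention_id}: non-finite mention vector")
        object.__setattr__(self, "vector", vec)


@dataclass(frozen=True)
class TokenVectorSet:
    """Per-token, per-layer vectors for one sentence.  Layer 0 is the
    context-independent token representation; layers 1 and 2 concatenate the
    forward and backward recurrent states (forward half first)."""

    sentence_key: str
    layers: Mapping[int, np.ndarray]

    @property
    def n_tokens(self) -> int:
        return next(iter(self.layers.values())).shape[0]


def pool_tokens(matrix: np.ndarray, indices: Sequence[int], mode: str) -> np.ndarray:
    """Dimension-wise average or maximum over selected token vectors."""
    if mode not in ("avg", "max"):
        raise ConfigurationError(f"unknown pooling mode {mode!r}")
    if len(indices) == 0:
        raise ValueError("cannot pool an empty token index set")
    sel = np.asarray(matrix)[list(indices)]
    return sel.mean(axis=0) if mode == "avg" else sel.max(axis=0)


def pool_mention(
    token_vectors: TokenVectorSet,
    indices: Sequence[int],
    mode: str,
    *,
    layer: int = 2,
    mention_id: str = "",
    encoder: str = "bilm",
    fusion: str = "none",
) -> MentionVector:
    vec = pool_tokens(token_vectors.layers[layer], indices, mode)
    return MentionVector(
        mention_id=mention_id,
        vector=vec,
        provenance=Provenance(encoder=encoder, layer=layer, pooling=mode, fusion=fusion),
    )


def type_mention_vector(
    mention: MentionAnnotation, table: WordVectorTable
) -> MentionVector | None:
    """Type-level mention representation: the dimensional average of the
    in-vocabulary token vectors of the normalized surface.  Out-of-vocabulary
    tokens are excluded; a mention whose tokens are all out-of-vocabulary has
    no representation (returns None) and drops out of ranking entirely."""
    vecs = [table.get(tok) for tok in normalize_surface(mention.surface).split()]
    vecs = [v for v in vecs if v is not None]
    if not vecs:
        return None
    return MentionVector(
        mention_id=mention.mention_id,
        vector=np.mean(vecs, axis=0),
        provenance=Provenance(encoder="word-vector-table", layer=None, pooling="avg"),
    )


# ---------------------------------------------------------------------------
# Patient-context (ICD-9) vectors and fusion
# ---------------------------------------------------------------------------


def icd_context_vector(
    codes: Iterable[str], code_table: CodeVectorTable, mode: str = "max"
) -> np.ndarray:
    """Single admission-level context vector from a set of ICD-9 codes.

    Default aggregation is the dimension-wise maximum over the code vectors
    (the mean is exposed as an option).  Codes missing from the table are
    skipped with a logged count; an admission with no resolvable codes maps
    to the zero vector — the neutral element for concatenation-based fusion.
    """
    if mode not in ("max", "mean"):
        raise ConfigurationError(f"unknown ICD aggregation mode {mode!r}")
    vecs, missing = [], 0
    for code in sorted(set(codes)):
        v = code_table.get(code)
        if v is None:
            missing += 1
        else:
            vecs.append(v)
    if missing:
        logger.info("icd_context_vector: %d code(s) missing from table", missing)
    if not vecs:
        logger.warning("icd_context_vector: no resolvable codes; using zero vector")
        return np.zeros(code_table.dim)
    stack = np.stack(vecs)
    return stack.max(axis=0) if mode == "max" else stack.mean(axis=0)


def admission_icd_vectors(
    documents: Iterable[Document],
    admissions: Mapping[str, Admission],
    code_table: CodeVectorTable,
    mode: str = "max",
) -> dict[str, np.ndarray]:
    """doc_id → admission-level ICD context vector."""
    out = {}
    for doc in documents:
        adm = admissions.get(doc.admission_id)
        codes = adm.icd_codes if adm is not None else frozenset()
        out[doc.doc_id] = icd_context_vector(codes, code_table, mode=mode)
    return out


def c2v_fuse(
    left_context_vec: np.ndarray, right_context_vec: np.ndarray, icd_vector: np.ndarray
) -> np.ndarray:
    """Fused input for a context-MLP architecture: left LSTM state ⊕ right
    LSTM state ⊕ admission ICD vector, in that order."""
    return np.concatenate([left_context_vec, right_context_vec, icd_vector])


def output_fuse(
    left_top: np.ndarray, right_top: np.ndarray, icd_vector: np.ndarray | None = None
) -> np.ndarray:
    """Softmax input for output-site fusion: top-layer left ⊕ right states,
    with the ICD vector appended when fusion is enabled.  Used during BiLM
    training only; emitted token representations are unaffected."""
    parts = [left_top, right_top]
    if icd_vector is not None:
        parts.append(icd_vector)
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# Reference BiLM
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiLMConfig:
    """Hyperparameters of the reference BiLM.

    ``token_mode`` selects the layer-0 encoder: ``character-cnn`` (a small
    convolution over character embeddings with max-over-time pooling, so any
    string receives a representation) or ``word`` (embedding lookup with an
    unknown-word bucket).  ``n_layers`` is fixed at 2.
    """

    token_mode: str = "character-cnn"
    token_dim: int = 48
    hidden_dim: int = 48
    n_layers: int = 2
    epochs: int = 5
    lr: float = 0.02
    seed: int = 0
    fusion: str = "none"
    char_emb_dim: int = 12
    conv_width: int = 3
    recurrent_scale: float = 0.15
    heldout_fraction: float = 0.1
    grad_clip: float = 5.0

    def __post_init__(self) -> None:
        if self.token_mode not in ("character-cnn", "word"):
            raise ConfigurationError(f"unknown token mode {self.token_mode!r}")
        if self.fusion not in ("none", "input", "output"):
            raise ConfigurationError(f"unknown fusion mode {self.fusion!r}")
        if self.n_layers != 2:
            raise ConfigurationError("the reference BiLM is fixed at 2 recurrent layers")
        for name in ("token_dim", "hidden_dim", "char_emb_dim", "conv_width", "epochs"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")


_CHAR_UNK = "\x00"
_CHAR_PAD = "\x01"


class ReferenceBiLM:
    """Two-layer forward/backward tanh-RNN language model with a shared token
    representation and a shared cloze softmax.

    Training is plain backpropagation through time with Adagrad updates, one
    sentence per step, deterministic given the seed.  After training the
    model is frozen and encoding is pure: identical inputs give bitwise
    identical outputs.
    """

    def __init__(self, config: BiLMConfig, vocab: Sequence[str], chars: Sequence[str] = (),
                 d_c: int = 0):
        self.config = config
        self.d_c = int(d_c)
        if config.fusion != "none" and self.d_c == 0:
            raise ConfigurationError("fusion mode requires a code-vector dimensionality")
        self.vocab = list(dict.fromkeys([UNK, BOS, EOS] + list(vocab)))
        self.word_ids = {w: i for i, w in enumerate(self.vocab)}
        # BOS/EOS/UNK act as single dedicated "characters" in the char inventory
        self.chars = list(dict.fromkeys([_CHAR_UNK, _CHAR_PAD, BOS, EOS, UNK] + list(chars)))
        self.char_ids = {c: i for i, c in enumerate(self.chars)}
        self._rng = np.random.default_rng([config.seed, 3])
        self._frozen = False
        self._token_cache: dict[str, np.ndarray] = {}
        self.perplexity_history: list[float] = []
        self._init_params()

    # -- parameters ---------------------------------------------------------

    def _init_params(self) -> None:
        cfg = self.config
        rng = self._rng
        d0, H, V = cfg.token_dim, cfg.hidden_dim, len(self.vocab)
        din1 = d0 + (self.d_c if cfg.fusion == "input" else 0)
        dz = 2 * H + (self.d_c if cfg.fusion == "output" else 0)

        def mat(*shape):
            fan_in = shape[0]
            return rng.normal(size=shape) / np.sqrt(fan_in)

        p: dict[str, np.ndarray] = {}
        if cfg.token_mode == "word":
            p["E_w"] = rng.normal(size=(V, d0)) * 0.1
        else:
            p["E_c"] = rng.normal(size=(len(self.chars), cfg.char_emb_dim)) * 0.1
            p["W_conv"] = mat(cfg.conv_width * cfg.char_emb_dim, d0)
            p["b_conv"] = np.zeros(d0)
        # recurrent weights start small (input-dominant dynamics): the state
        # next to a mention is then dominated by the nearest context words,
        # and training refines rather than re-derives that structure
        for direction in ("f", "b"):
            p[f"Wx1{direction}"] = mat(din1, H)
            p[f"Wh1{direction}"] = mat(H, H) * cfg.recurrent_scale
            p[f"b1{direction}"] = np.zeros(H)
            p[f"Wx2{direction}"] = mat(H, H)
            p[f"Wh2{direction}"] = mat(H, H) * cfg.recurrent_scale
            p[f"b2{direction}"] = np.zeros(H)
        p["W_out"] = mat(dz, V)
        p["b_out"] = np.zeros(V)
        self.params = p
        self._adagrad = {k: np.zeros_like(v) for k, v in p.items()}

    # -- token representation (layer 0, context-independent) ----------------

    def _char_matrix(self, word: str) -> np.ndarray:
        if word in (BOS, EOS, UNK):
            ids = [self.char_ids.get(word, 0)]
        else:
            ids = [self.char_ids.get(c, 0) for c in word]
        width = self.config.conv_width
        pad = self.char_ids[_CHAR_PAD]
        while len(ids) < width:
            ids.append(pad)
        return np.array(ids)

    def _token_forward(self, word: str):
        """Layer-0 vector for one word, plus intermediates for backprop."""
        cfg = self.config
        if cfg.token_mode == "word":
            wid = self.word_ids.get(word, self.word_ids[UNK])
            return self.params["E_w"][wid], ("word", wid)
        ids = self._char_matrix(word)
        emb = self.params["E_c"][ids]  # (L, ce)
        w = cfg.conv_width
        L = len(ids)
        windows = np.stack([emb[i : i + w].ravel() for i in range(L - w + 1)])
        pre = windows @ self.params["W_conv"] + self.params["b_conv"]  # (nw, d0)
        arg = pre.argmax(axis=0)
        pooled = pre[arg, np.arange(pre.shape[1])]
        x = np.tanh(pooled)
        return x, ("char", ids, windows, arg, x)

    def token_vector(self, word: str) -> np.ndarray:
        if self._frozen:
            cached = self._token_cache.get(word)
            if cached is None:
                cached = self._token_forward(word)[0]
                self._token_cache[word] = cached
            return cached
        return self._token_forward(word)[0]

    # -- forward/backward pass ----------------------------------------------

    @staticmethod
    def _special(word: str) -> bool:
        return word in (BOS, EOS)

    def _forward(self, words: list[str], icd: np.ndarray | None):
        cfg = self.config
        p = self.params
        seq = [BOS] + list(words) + [EOS]
        T = len(seq)
        if self._frozen:
            toks = None  # intermediates not needed once training is done
            X0 = np.stack([self.token_vector(w) for w in seq])
        else:
            toks = [self._token_forward(w) for w in seq]
            X0 = np.stack([t[0] for t in toks])
        if cfg.fusion == "input":
            X = np.concatenate([X0, np.tile(icd, (T, 1))], axis=1)
        else:
            X = X0
        H = cfg.hidden_dim
        h1 = {"f": np.zeros((T, H)), "b": np.zeros((T, H))}
        h2 = {"f": np.zeros((T, H)), "b": np.zeros((T, H))}
        order = {"f": range(T), "b": range(T - 1, -1, -1)}
        for d in ("f", "b"):
            prev1 = np.zeros(H)
            prev2 = np.zeros(H)
            for t in order[d]:
                a1 = X[t] @ p[f"Wx1{d}"] + prev1 @ p[f"Wh1{d}"] + p[f"b1{d}"]
                h1[d][t] = np.tanh(a1)
                a2 = h1[d][t] @ p[f"Wx2{d}"] + prev2 @ p[f"Wh2{d}"] + p[f"b2{d}"]
                h2[d][t] = np.tanh(a2)
                prev1, prev2 = h1[d][t], h2[d][t]
        # cloze prediction at interior positions
        ks = np.arange(1, T - 1)
        Z = np.concatenate([h2["f"][ks - 1], h2["b"][ks + 1]], axis=1)
        if cfg.fusion == "output":
            Z = np.concatenate([Z, np.tile(icd, (len(ks), 1))], axis=1)
        logits = Z @ p["W_out"] + p["b_out"]
        return seq, toks, X, h1, h2, ks, Z, logits

    def _loss_and_grads(self, words: list[str], icd: np.ndarray | None):
        cfg = self.config
        p = self.params
        seq, toks, X, h1, h2, ks, Z, logits = self._forward(words, icd)
        T = len(seq)
        H = cfg.hidden_dim
        targets = np.array([self.word_ids.get(w, self.word_ids[UNK]) for w in words])
        shifted = logits - logits.max(axis=1, keepdims=True)
        expz = np.exp(shifted)
        probs = expz / expz.sum(axis=1, keepdims=True)
        nll = -np.log(probs[np.arange(len(targets)), targets] + 1e-12)
        loss = nll.mean()

        g = {k: np.zeros_like(v) for k, v in p.items()}
        dlogits = probs.copy()
        dlogits[np.arange(len(targets)), targets] -= 1.0
        dlogits /= len(targets)
        g["W_out"] = Z.T @ dlogits
        g["b_out"] = dlogits.sum(axis=0)
        dZ = dlogits @ p["W_out"].T
        dh2 = {"f": np.zeros((T, H)), "b": np.zeros((T, H))}
        dh2["f"][ks - 1] += dZ[:, :H]
        dh2["b"][ks + 1] += dZ[:, H : 2 * H]
        dh1 = {"f": np.zeros((T, H)), "b": np.zeros((T, H))}
        dX = np.zeros_like(X)
        # BPTT per direction: forward direction runs t = 0..T-1, so its
        # gradient runs in reverse; mirrored for the backward direction.
        for d, times in (("f", range(T - 1, -1, -1)), ("b", range(T))):
            step = -1 if d == "f" else 1
            carry2 = np.zeros(H)
            carry1 = np.zeros(H)
            for t in times:
                prev_t = t + step  # earlier in this direction's time order
                da2 = (dh2[d][t] + carry2) * (1.0 - h2[d][t] ** 2)
                g[f"Wx2{d}"] += np.outer(h1[d][t], da2)
                prev2 = h2[d][prev_t] if 0 <= prev_t < T else np.zeros(H)
                g[f"Wh2{d}"] += np.outer(prev2, da2)
                g[f"b2{d}"] += da2
                carry2 = da2 @ p[f"Wh2{d}"].T
                da1 = (dh1[d][t] + carry1 + da2 @ p[f"Wx2{d}"].T) * (1.0 - h1[d][t] ** 2)
                g[f"Wx1{d}"] += np.outer(X[t], da1)
                prev1 = h1[d][prev_t] if 0 <= prev_t < T else np.zeros(H)
                g[f"Wh1{d}"] += np.outer(prev1, da1)
                g[f"b1{d}"] += da1
                carry1 = da1 @ p[f"Wh1{d}"].T
                dX[t] += da1 @ p[f"Wx1{d}"].T
        # token-encoder gradients
        d0 = cfg.token_dim
        dX0 = dX[:, :d0]
        if cfg.token_mode == "word":
            for t, tok in enumerate(toks):
                _, (_, wid) = tok
                g["E_w"][wid] += dX0[t]
        else:
            for t, tok in enumerate(toks):
                x = tok[0]
                _, ids, windows, arg, _ = tok[1]
                dpooled = dX0[t] * (1.0 - x**2)
                dpre = np.zeros((windows.shape[0], d0))
                dpre[arg, np.arange(d0)] = dpooled
                g["W_conv"] += windows.T @ dpre
                g["b_conv"] += dpre.sum(axis=0)
                dwindows = dpre @ p["W_conv"].T
                w = cfg.conv_width
                ce = cfg.char_emb_dim
                for i in range(windows.shape[0]):
                    demb = dwindows[i].reshape(w, ce)
                    for j in range(w):
                        g["E_c"][ids[i + j]] += demb[j]
        return loss, g

    def _apply_grads(self, grads: dict[str, np.ndarray]) -> None:
        cfg = self.config
        total = np.sqrt(sum(float((v**2).sum()) for v in grads.values()))
        scale = cfg.grad_clip / total if total > cfg.grad_clip else 1.0
        for k, gk in grads.items():
            gk = gk * scale
            self._adagrad[k] += gk**2
            self.params[k] -= cfg.lr * gk / (np.sqrt(self._adagrad[k]) + 1e-8)

    # -- training ------------------------------------------------------------

    def sentence_nll(self, words: list[str], icd: np.ndarray | None = None) -> tuple[float, int]:
        *_, ks, Z, logits = self._forward(words, icd)
        targets = np.array([self.word_ids.get(w, self.word_ids[UNK]) for w in words])
        shifted = logits - logits.max(axis=1, keepdims=True)
        logprobs = shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))
        return float(-logprobs[np.arange(len(targets)), targets].sum()), len(targets)

    def perplexity(self, corpus: list[tuple[list[str], np.ndarray | None]]) -> float:
        total, n = 0.0, 0
        for words, icd in corpus:
            nll, count = self.sentence_nll(words, icd)
            total += nll
            n += count
        return float(np.exp(total / max(n, 1)))

    def fit(self, corpus: list[tuple[list[str], np.ndarray | None]]) -> "ReferenceBiLM":
        """Train on (words, icd_vector) pairs; records held-out perplexity
        before training and after each epoch."""
        rng = np.random.default_rng([self.config.seed, 7])
        perm = rng.permutation(len(corpus))
        n_held = max(1, int(round(self.config.heldout_fraction * len(corpus))))
        if len(corpus) <= n_held:
            n_held = 0
        held = [corpus[i] for i in perm[:n_held]]
        train = [corpus[i] for i in perm[n_held:]]
        eval_set = held if held else train
        self.perplexity_history = [self.perplexity(eval_set)]
        for epoch in range(self.config.epochs):
            order = rng.permutation(len(train))
            running = 0.0
            for i in order:
                words, icd = train[i]
                loss, grads = self._loss_and_grads(words, icd)
                self._apply_grads(grads)
                running += loss
            ppl = self.perplexity(eval_set)
            self.perplexity_history.append(ppl)
            logger.info(
                "epoch %d: train loss %.4f, held-out perplexity %.3f",
                epoch + 1, running / max(len(train), 1), ppl,
            )
        self._frozen = True
        self._token_cache = {}
        return self

    # -- encoding ------------------------------------------------------------

    def encode_sentence(
        self, sentence: Sentence | Sequence[str], icd_vector: np.ndarray | None = None,
        sentence_key: str | None = None,
    ) -> TokenVectorSet:
        """Per-token, per-layer vectors for one sentence.

        Layer 0 is the token's own (context-independent) representation;
        layers 1 and 2 are the bidirectional *context* states of each token:
        forward state over the tokens before it ⊕ backward state over the
        tokens after it (forward half first).  Input fusion concatenates the
        ICD vector onto every layer-0 token representation (so layer 0 widens
        by d_c); output fusion leaves all emitted layers unchanged.
        Deterministic and pure.
        """
        if self.config.fusion == "input" and icd_vector is None:
            raise ConfigurationError("encoder trained with input fusion requires an icd_vector")
        if self.config.fusion == "none" and icd_vector is not None:
            raise ConfigurationError("icd_vector supplied but encoder was trained without fusion")
        if isinstance(sentence, Sentence):
            words = list(sentence.words)
            key = sentence_key or (
                f"{sentence.doc_id}:{sentence.extent.start}-{sentence.extent.end}"
            )
        else:
            words = list(sentence)
            key = sentence_key or " ".join(words)
        icd = icd_vector if self.config.fusion != "none" else None
        _, toks, X, h1, h2, *_ = self._forward(words, icd)
        T = len(words) + 2  # with sentence boundary markers
        inner = slice(1, T - 1)
        left = slice(0, T - 2)   # forward state just before each token
        right = slice(2, T)      # backward state just after each token
        layers = {
            0: X[inner].copy(),
            1: np.concatenate([h1["f"][left], h1["b"][right]], axis=1),
            2: np.concatenate([h2["f"][left], h2["b"][right]], axis=1),
        }
        return TokenVectorSet(sentence_key=key, layers=layers)

    @property
    def layer_dims(self) -> dict[int, int]:
        d0 = self.config.token_dim + (self.d_c if self.config.fusion == "input" else 0)
        return {0: d0, 1: 2 * self.config.hidden_dim, 2: 2 * self.config.hidden_dim}

    @property
    def prediction_input_dim(self) -> int:
        return 2 * self.config.hidden_dim + (self.d_c if self.config.fusion == "output" else 0)


def train_reference_bilm(
    sentences: Sequence[Sentence | Sequence[str]],
    config: BiLMConfig,
    icd_vectors: Mapping[str, np.ndarray] | None = None,
) -> ReferenceBiLM:
    """Build vocabularies from the sentences and fit the reference BiLM.

    ``icd_vectors`` maps doc_id → admission-level ICD context vector and is
    required (and only allowed) when ``config.fusion`` is input or output.
    """
    if not sentences:
        raise ValueError("need at least one training sentence")
    if config.fusion != "none" and icd_vectors is None:
        raise ConfigurationError(f"fusion={config.fusion!r} requires icd_vectors")

    def words_of(s) -> list[str]:
        return list(s.words) if isinstance(s, Sentence) else list(s)

    def icd_of(s) -> np.ndarray | None:
        if config.fusion == "none":
            return None
        doc_id = s.doc_id if isinstance(s, Sentence) else None
        if doc_id is None or doc_id not in icd_vectors:
            raise ConfigurationError(f"no ICD vector for sentence of doc {doc_id!r}")
        return icd_vectors[doc_id]

    corpus = [(words_of(s), icd_of(s)) for s in sentences]
    vocab = sorted({w for words, _ in corpus for w in words})
    chars = sorted({c for w in vocab for c in w})
    d_c = len(next(iter(icd_vectors.values()))) if config.fusion != "none" else 0
    model = ReferenceBiLM(config, vocab=vocab, chars=chars, d_c=d_c)
    return model.fit(corpus)


# ---------------------------------------------------------------------------
# Corpus-level mention representation pipeline
# ---------------------------------------------------------------------------


def _merge_span_units(words: Sequence[str], indices: Sequence[int]) -> tuple[list[str], list[int]]:
    """Collapse each contiguous run of mention token indices into one unit.

    Returns the merged token sequence and the positions of the mention's
    units within it.  A contiguous mention becomes a single unit; a
    discontiguous mention yields one unit per contiguous run.
    """
    runs: list[list[int]] = [[indices[0]]]
    for i in indices[1:]:
        if i == runs[-1][-1] + 1:
            runs[-1].append(i)
        else:
            runs.append([i])
    run_starts = {r[0]: r for r in runs}
    merged: list[str] = []
    unit_pos: list[int] = []
    i = 0
    while i < len(words):
        run = run_starts.get(i)
        if run is not None:
            unit_pos.append(len(merged))
            merged.append(" ".join(words[run[0] : run[-1] + 1]))
            i = run[-1] + 1
        else:
            merged.append(words[i])
            i += 1
    return merged, unit_pos


def bilm_mention_vectors(
    encoder: ReferenceBiLM,
    documents: Mapping[str, Document] | Sequence[Document],
    mentions: Sequence[MentionAnnotation],
    layer: int = 1,
    pooling: str = "max",
    icd_vectors: Mapping[str, np.ndarray] | None = None,
    merge_spans: bool = True,
) -> dict[str, MentionVector | None]:
    """Encode every mention's sentence and pool its unit vectors.

    With ``merge_spans`` (the default) the mention span is treated as a
    single lexical unit when its sentence is encoded — gold spans are given,
    and the character-level token encoder represents any string — so the
    mention's contextual layers describe the sentence context around the
    whole span rather than around each word separately.  Discontiguous
    mentions yield one unit per contiguous run, pooled dimension-wise.
    With ``merge_spans=False`` the sentence is encoded as-is and pooling
    ranges over the mention's individual tokens.

    Mentions that cannot be aligned to a single sentence map to None (absent
    representation) with a logged diagnostic.
    """
    if not isinstance(documents, Mapping):
        documents = {d.doc_id: d for d in documents}
    sent_cache: dict[str, list[Sentence]] = {}
    tvs_cache: dict[tuple, TokenVectorSet] = {}
    out: dict[str, MentionVector | None] = {}
    for mention in mentions:
        doc = documents.get(mention.doc_id)
        if doc is None:
            logger.warning("%s: unknown document %s", mention.mention_id, mention.doc_id)
            out[mention.mention_id] = None
            continue
        sents = sent_cache.get(doc.doc_id)
        if sents is None:
            sents = tokenize(doc)
            sent_cache[doc.doc_id] = sents
        try:
            sentence, indices = align_mention(mention, sents)
        except AlignmentError as exc:
            logger.warning("alignment failed: %s", exc)
            out[mention.mention_id] = None
            continue
        si = sents.index(sentence)
        icd = icd_vectors.get(doc.doc_id) if icd_vectors is not None else None
        if merge_spans:
            units, pool_idx = _merge_span_units(list(sentence.words), list(indices))
            cache_key = (doc.doc_id, si, tuple(pool_idx), len(units))
        else:
            units, pool_idx = list(sentence.words), list(indices)
            cache_key = (doc.doc_id, si)
        tvs = tvs_cache.get(cache_key)
        if tvs is None:
            tvs = encoder.encode_sentence(units, icd_vector=icd,
                                          sentence_key=f"{doc.doc_id}:{si}")
            tvs_cache[cache_key] = tvs
        out[mention.mention_id] = pool_mention(
            tvs, pool_idx, pooling, layer=layer, mention_id=mention.mention_id,
            encoder=f"reference-bilm[{encoder.config.token_mode}]",
            fusion=encoder.config.fusion,
        )
    return out


def type_mention_vectors(
    mentions: Sequence[MentionAnnotation], table: WordVectorTable
) -> dict[str, MentionVector | None]:
    out = {}
    n_absent = 0
    for m in mentions:
        mv = type_mention_vector(m, table)
        if mv is None:
            n_absent += 1
        out[m.mention_id] = mv
    if n_absent:
        logger.info("type_mention_vectors: %d mention(s) entirely out of vocabulary", n_absent)
    return out


# ---------------------------------------------------------------------------
# Representation store (text format + provenance sidecar)
# ---------------------------------------------------------------------------


def write_mention_vectors(
    vectors: Mapping[str, MentionVector | None], path: str | Path,
    provenance_extra: Mapping | None = None,
) -> None:
    """Whitespace text store: mention_id then the vector entries, one row per
    represented mention; absent mentions and provenance go to a JSON sidecar."""
    path = Path(path)
    present = {k: v for k, v in vectors.items() if v is not None}
    with path.open("w", encoding="utf-8") as fh:
        for mid in sorted(present):
            vec = present[mid].vector
            fh.write(mid + " " + " ".join(repr(float(x)) for x in vec) + "\n")
    any_prov = next(iter(present.values())).provenance if present else None
    sidecar = {
        "absent": sorted(k for k, v in vectors.items() if v is None),
        "provenance": None
        if any_prov is None
        else {
            "encoder": any_prov.encoder,
            "layer": any_prov.layer,
            "pooling": any_prov.pooling,
            "fusion": any_prov.fusion,
        },
    }
    if provenance_extra:
        sidecar["provenance_extra"] = dict(provenance_extra)
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_mention_vectors(path: str | Path) -> dict[str, MentionVector | None]:
    path = Path(path)
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    prov = sidecar.get("provenance") or {}
    provenance = Provenance(
        encoder=prov.get("encoder", "unknown"),
        layer=prov.get("layer"),
        pooling=prov.get("pooling"),
        fusion=prov.get("fusion", "none"),
    )
    out: dict[str, MentionVector | None] = {mid: None for mid in sidecar.get("absent", [])}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            try:
                vec = np.array([float(x) for x in fields[1:]])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric vector entry") from exc
            out[fields[0]] = MentionVector(fields[0], vec, provenance)
    return out
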