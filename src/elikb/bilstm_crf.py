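"""Trainable BiLSTM-CRF sequence tagger for criterion entity recognition.

Architecture: each token is embedded as the concatenation of a learned
token-level embedding and a character-level convolutional feature (max-pooled
over character trigram windows).  The embedded sequence runs through a
bidirectional LSTM; a linear layer maps the concatenated hidden states to
per-tag emission scores; a linear-chain CRF on top scores whole tag
sequences, trained by maximum likelihood and decoded with Viterbi under a
structural mask that guarantees valid BIO output.

Everything is implemented directly in numpy (forward and backward passes),
updated per sentence with Adam.  With a fixed seed, training is
deterministic and bit-reproducible on the same machine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import crf
from .bio import BIOSequence, mentions_to_bio
from .ontology import AnnotatedCriterion
from .tokenizer import tokenize

UNK = "<unk>"
MAX_WORD_LEN = 20


class LabelCoverageError(ValueError):
    """A tag occurs in the evaluation split but never in the training split."""


@dataclass
class ModelConfig:
    """Hyperparameters of the tagger.

    ``train_fraction`` is the share of criteria used for training when a
    corpus is split internally (default 0.8, i.e. an 80/20 split).
    """

    char_embedding_dim: int = 12
    char_filters: int = 16
    token_embedding_dim: int = 32
    lstm_hidden: int = 32
    epochs: int = 4
    learning_rate: float = 0.01
    seed: int = 0
    train_fraction: float = 0.8
    grad_clip: float = 5.0

    def __post_init__(self) -> None:
        for name in ("char_embedding_dim", "char_filters", "token_embedding_dim", "lstm_hidden"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class _LSTM:
    """One direction of the LSTM; gates stacked as [i, f, o, g]."""

    def __init__(self, params: dict, prefix: str, hidden: int):
        self.p = params
        self.W = prefix + "W"
        self.U = prefix + "U"
        self.b = prefix + "b"
        self.H = hidden

    def forward(self, xs: np.ndarray):
        T = xs.shape[0]
        H = self.H
        W, U, b = self.p[self.W], self.p[self.U], self.p[self.b]
        hs = np.zeros((T, H))
        cache = []
        h = np.zeros(H)
        c = np.zeros(H)
        for t in range(T):
            z = W @ xs[t] + U @ h + b
            i = _sigmoid(z[:H])
            f = _sigmoid(z[H : 2 * H])
            o = _sigmoid(z[2 * H : 3 * H])
            g = np.tanh(z[3 * H :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((xs[t], h, c, i, f, o, g, tc))
            h, c = h_new, c_new
            hs[t] = h
        return hs, cache

    def backward(self, dhs: np.ndarray, cache, grads: dict) -> np.ndarray:
        T = dhs.shape[0]
        H = self.H
        W, U = self.p[self.W], self.p[self.U]
        dW = grads[self.W]
        dU = grads[self.U]
        db = grads[self.b]
        dxs = np.zeros((T, W.shape[1]))
        dh_next = np.zeros(H)
        dc_next = np.zeros(H)
        for t in range(T - 1, -1, -1):
            x, h_prev, c_prev, i, f, o, g, tc = cache[t]
            dh = dhs[t] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    do * o * (1.0 - o),
                    dg * (1.0 - g * g),
                ]
            )
            dW += np.outer(dz, x)
            dU += np.outer(dz, h_prev)
            db += dz
            dxs[t] = W.T @ dz
            dh_next = U.T @ dz
        return dxs


class BiLstmCrfTagger:
    """A trained (or trainable) BiLSTM-CRF tagger.

    Use :func:`train_bilstm_crf` for the standard corpus-in, model-out path;
    the class itself exposes ``fit`` / ``predict`` / ``save`` / ``load``.
    """

    def __init__(self, config: ModelConfig, vocab: dict, charset: dict, labels: list[str]):
        self.config = config
        self.vocab = vocab
        self.charset = charset
        self.labels = labels
        self.label_index = {lab: i for i, lab in enumerate(labels)}
        self.history: list[dict] = []
        rng = np.random.default_rng(config.seed)
        dw, dc, F, H = (
            config.token_embedding_dim,
            config.char_embedding_dim,
            config.char_filters,
            config.lstm_hidden,
        )
        din = dw + F
        L = len(labels)

        def init(*shape, scale=None):
            scale = scale if scale is not None else 1.0 / np.sqrt(shape[-1])
            return rng.uniform(-scale, scale, size=shape)

        self.params: dict[str, np.ndarray] = {
            "E_tok": init(len(vocab), dw, scale=0.1),
            "E_ch": init(len(charset), dc, scale=0.1),
            "Wc": init(F, 3 * dc),
            "bc": np.zeros(F),
            "fW": init(4 * H, din),
            "fU": init(4 * H, H),
            "fb": np.zeros(4 * H),
            "bW": init(4 * H, din),
            "bU": init(4 * H, H),
            "bb": np.zeros(4 * H),
            "Wo": init(L, 2 * H),
            "bo": np.zeros(L),
            "trans": np.zeros((L, L)),
            "start": np.zeros(L),
            "end": np.zeros(L),
        }
        self._fwd = _LSTM(self.params, "f", H)
        self._bwd = _LSTM(self.params, "b", H)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0
        self._bio_masks = _bio_transition_masks(labels)

    # ----- encoding -------------------------------------------------------

    def _token_ids(self, surfaces: list[str]) -> np.ndarray:
        unk = self.vocab[UNK]
        return np.array([self.vocab.get(s.lower(), unk) for s in surfaces], dtype=np.int64)

    def _char_ids(self, surface: str) -> np.ndarray:
        unk = self.charset[UNK]
        chars = [self.charset.get(ch, unk) for ch in surface[:MAX_WORD_LEN]]
        while len(chars) < 3:  # pad so one trigram window exists
            chars.append(self.charset["<pad>"])
        return np.array(chars, dtype=np.int64)

    # ----- forward / backward --------------------------------------------

    def _char_features(self, surfaces: list[str]):
        E, Wc, bc = self.params["E_ch"], self.params["Wc"], self.params["bc"]
        dc = self.config.char_embedding_dim
        feats = np.empty((len(surfaces), self.config.char_filters))
        caches = []
        for t, surf in enumerate(surfaces):
            ids = self._char_ids(surf)
            emb = E[ids]  # (W, dc)
            W_ = len(ids)
            windows = np.concatenate([emb[: W_ - 2], emb[1 : W_ - 1], emb[2:]], axis=1)
            conv = windows @ Wc.T + bc  # (W-2, F)
            arg = np.argmax(conv, axis=0)
            feats[t] = conv[arg, np.arange(conv.shape[1])]
            caches.append((ids, windows, arg))
        return feats, caches

    def _forward(self, surfaces: list[str]):
        tok_ids = self._token_ids(surfaces)
        x_tok = self.params["E_tok"][tok_ids]
        cfeat, ccache = self._char_features(surfaces)
        xs = np.concatenate([x_tok, cfeat], axis=1)
        hf, fcache = self._fwd.forward(xs)
        hb, bcache = self._bwd.forward(xs[::-1])
        hb = hb[::-1]
        hcat = np.concatenate([hf, hb], axis=1)
        emissions = hcat @ self.params["Wo"].T + self.params["bo"]
        cache = (tok_ids, ccache, xs, fcache, bcache, hcat)
        return emissions, cache

    def _backward(self, d_em: np.ndarray, cache, grads: dict) -> None:
        tok_ids, ccache, xs, fcache, bcache, hcat = cache
        grads["Wo"] += d_em.T @ hcat
        grads["bo"] += d_em.sum(axis=0)
        d_hcat = d_em @ self.params["Wo"]
        H = self.config.lstm_hidden
        dxs = self._fwd.backward(d_hcat[:, :H], fcache, grads)
        dxs += self._bwd.backward(d_hcat[::-1, H:], bcache, grads)[::-1]
        dw = self.config.token_embedding_dim
        np.add.at(grads["E_tok"], tok_ids, dxs[:, :dw])
        Wc = self.params["Wc"]
        dc = self.config.char_embedding_dim
        for t, (ids, windows, arg) in enumerate(ccache):
            dfeat = dxs[t, dw:]  # (F,)
            # route gradient through the max-pooled window of each filter
            dwindows = np.zeros_like(windows)
            for k, pos in enumerate(arg):
                grads["Wc"][k] += dfeat[k] * windows[pos]
                grads["bc"][k] += dfeat[k]
                dwindows[pos] += dfeat[k] * Wc[k]
            demb = np.zeros((len(ids), dc))
            demb[: len(ids) - 2] += dwindows[:, :dc]
            demb[1 : len(ids) - 1] += dwindows[:, dc : 2 * dc]
            demb[2:] += dwindows[:, 2 * dc :]
            np.add.at(grads["E_ch"], ids, demb)

    def _loss_and_grads(self, surfaces: list[str], gold: np.ndarray, grads: dict) -> float:
        emissions, cache = self._forward(surfaces)
        p = self.params
        node, edge, log_z = crf.forward_backward(emissions, p["trans"], p["start"], p["end"])
        gold_score = crf.path_score(emissions, p["trans"], p["start"], p["end"], gold)
        loss = log_z - gold_score
        d_em = node.copy()
        d_em[np.arange(len(gold)), gold] -= 1.0
        obs_edge = np.zeros_like(edge)
        for t in range(1, len(gold)):
            obs_edge[gold[t - 1], gold[t]] += 1.0
        grads["trans"] += edge - obs_edge
        d_start = node[0].copy()
        d_start[gold[0]] -= 1.0
        grads["start"] += d_start
        d_end = node[-1].copy()
        d_end[gold[-1]] -= 1.0
        grads["end"] += d_end
        self._backward(d_em, cache, grads)
        return loss

    def _adam_step(self, grads: dict) -> None:
        self._adam_t += 1
        lr, b1, b2, eps = self.config.learning_rate, 0.9, 0.999, 1e-8
        t = self._adam_t
        clip = self.config.grad_clip
        for k, g in grads.items():
            np.clip(g, -clip, clip, out=g)
            m = self._adam_m[k]
            v = self._adam_v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # ----- public API -----------------------------------------------------

    def fit(self, sentences: list[tuple[list[str], list[str]]]) -> "BiLstmCrfTagger":
        """Train on ``(surfaces, bio_labels)`` pairs; returns self.

        ``self.history`` records the mean per-sentence negative log
        likelihood for each epoch.
        """
        rng = np.random.default_rng(self.config.seed + 1)
        encoded = [
            (surfs, np.array([self.label_index[lab] for lab in labs], dtype=np.int64))
            for surfs, labs in sentences
        ]
        for epoch in range(self.config.epochs):
            order = rng.permutation(len(encoded))
            total = 0.0
            for idx in order:
                surfs, gold = encoded[idx]
                grads = {k: np.zeros_like(v) for k, v in self.params.items()}
                total += self._loss_and_grads(surfs, gold, grads)
                self._adam_step(grads)
            self.history.append({"epoch": epoch, "mean_nll": total / max(len(encoded), 1)})
        return self

    def predict(self, surfaces: list[str]) -> BIOSequence:
        """Viterbi-decode; the structural mask guarantees a valid BIO string."""
        emissions, _ = self._forward(surfaces)
        p = self.params
        mask, start_mask = self._bio_masks
        path = crf.viterbi(emissions, p["trans"], p["start"], p["end"], mask, start_mask)
        return BIOSequence([self.labels[i] for i in path])

    def predict_criterion(self, criterion: AnnotatedCriterion):
        """Tokenize a criterion and return (tokens, decoded mentions)."""
        from .bio import bio_to_mentions

        toks = tokenize(criterion.text, criterion.trial_id)
        bio = self.predict(toks.surfaces())
        return toks, bio_to_mentions(bio, toks)

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "weights.npz", **self.params)
        (d / "config.json").write_text(json.dumps(asdict(self.config), indent=1))
        (d / "vocab.json").write_text(
            json.dumps({"vocab": self.vocab, "charset": self.charset}, indent=1)
        )
        (d / "labels.json").write_text(json.dumps(self.labels, indent=1))

    @classmethod
    def load(cls, directory: str | Path) -> "BiLstmCrfTagger":
        d = Path(directory)
        config = ModelConfig(**json.loads((d / "config.json").read_text()))
        vv = json.loads((d / "vocab.json").read_text())
        labels = json.loads((d / "labels.json").read_text())
        model = cls(config, vv["vocab"], vv["charset"], labels)
        with np.load(d / "weights.npz") as w:
            for k in model.params:
                model.params[k] = w[k]
        model._fwd = _LSTM(model.params, "f", config.lstm_hidden)
        model._bwd = _LSTM(model.params, "b", config.lstm_hidden)
        return model


def _bio_transition_masks(labels: list[str]) -> tuple[np.ndarray, np.ndarray]:
    L = len(labels)
    mask = np.zeros((L, L))
    start_mask = np.zeros(L)
    for j, lab in enumerate(labels):
        if lab.startswith("I-"):
            body = lab[2:]
            start_mask[j] = -np.inf
            for i, prev in enumerate(labels):
                if prev == f"B-{body}" or prev == f"I-{body}":
                    continue
                mask[i, j] = -np.inf
    return mask, start_mask


# ---------------------------------------------------------------------------


def corpus_to_sentences(corpus: list[AnnotatedCriterion]) -> list[tuple[list[str], list[str]]]:
    """Tokenize and BIO-encode a gold corpus."""
    out = []
    for crit in corpus:
        toks = tokenize(crit.text, crit.trial_id)
        bio = mentions_to_bio(crit, toks)
        out.append((toks.surfaces(), bio.labels))
    return out


def split_corpus(
    corpus: list[AnnotatedCriterion],
    train_fraction: float,
    seed: int,
    stratify: bool = True,
) -> tuple[list[AnnotatedCriterion], list[AnnotatedCriterion]]:
    """Seed-controlled train/test split by criterion sentence.

    With ``stratify=True`` (default) every entity label present in the
    corpus is guaranteed at least one training example, by swapping a
    holder of a missing label from the test split into the training split.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    n_train = max(1, int(round(train_fraction * len(corpus))))
    n_train = min(n_train, len(corpus) - 1) if len(corpus) > 1 else n_train
    train_idx = list(order[:n_train])
    test_idx = list(order[n_train:])

    def labels_of(idx_list):
        labs = set()
        for i in idx_list:
            labs.update(m.label for m in corpus[i].mentions)
        return labs

    if stratify:
        missing = labels_of(test_idx) - labels_of(train_idx)
        for lab in sorted(missing):
            if lab in labels_of(train_idx):
                continue
            for j, ti in enumerate(test_idx):
                if any(m.label == lab for m in corpus[ti].mentions):
                    # swap with a random train item to preserve sizes
                    k = int(rng.integers(len(train_idx)))
                    train_idx[k], test_idx[j] = test_idx[j], train_idx[k]
                    break
    return [corpus[i] for i in train_idx], [corpus[i] for i in test_idx]


def train_bilstm_crf(
    corpus: list[AnnotatedCriterion],
    config: ModelConfig | None = None,
    heldout: list[AnnotatedCriterion] | None = None,
) -> BiLstmCrfTagger:
    """Train a tagger on a gold corpus.

    The vocabulary, character set and tag inventory are built from the
    training corpus.  If ``heldout`` is given, its tags must all occur in
    ``corpus`` (otherwise :class:`LabelCoverageError` names the offender).
    """
    if not corpus:
        raise ValueError("training corpus is empty")
    config = config or ModelConfig()
    sentences = corpus_to_sentences(corpus)
    labels = sorted({lab for _, labs in sentences for lab in labs} | {"O"})
    if heldout is not None:
        heldout_labels = {lab for _, labs in corpus_to_sentences(heldout) for lab in labs}
        missing = heldout_labels - set(labels)
        if missing:
            raise LabelCoverageError(
                "labels only in the evaluation split: " + ", ".join(sorted(missing))
            )
    vocab = {UNK: 0}
    charset = {"<pad>": 0, UNK: 1}
    for surfs, _ in sentences:
        for s in surfs:
            vocab.setdefault(s.lower(), len(vocab))
            for ch in s:
                charset.setdefault(ch, len(charset))
    model = BiLstmCrfTagger(config, vocab, charset, labels)
    return model.fit(sentences)


def train_with_stopping(
    corpus_batches: list[list[AnnotatedCriterion]],
    config: ModelConfig | None = None,
    f1_threshold: float = 0.8,
) -> tuple[BiLstmCrfTagger, list[dict]]:
    """Iterative annotate-and-retrain harness.

    Batches of annotated criteria are added one at a time; after each round
    the model is retrained on the accumulated data (80/20 split per the
    configured ``train_fraction``) and evaluated on the held-out share.
    Training stops as soon as the held-out macro F1 exceeds
    ``f1_threshold``, mirroring the iterate-until-F1>0.8 stopping rule.
    Returns the final model and the per-round evaluation trace.
    """
    from .evaluation import evaluate_corpus

    config = config or ModelConfig()
    accumulated: list[AnnotatedCriterion] = []
    trace: list[dict] = []
    model: BiLstmCrfTagger | None = None
    for round_no, batch in enumerate(corpus_batches):
        accumulated.extend(batch)
        train, test = split_corpus(accumulated, config.train_fraction, config.seed)
        model = train_bilstm_crf(train, config, heldout=test)
        report = evaluate_corpus(model, test)
        trace.append(
            {
                "round": round_no,
                "n_criteria": len(accumulated),
                "macro_f1": report.macro_f1,
            }
        )
        if report.macro_f1 > f1_threshold:
            break
    assert model is not None
    return model, trace
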