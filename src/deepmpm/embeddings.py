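"""Medical-code embeddings: skip-gram pretraining, the ReLU embedding layer
and the code-correlation interpretability matrices.

Visits are treated as unordered bags of codes; the skip-gram "context" of a
code is simply the other codes recorded in the same visit, so vectors of
codes that co-occur (comorbidities, disease/treatment pairs) end up nearby.
Training is plain SGD with negative sampling over a unigram^0.75 noise
distribution, mini-batched over (centre, context) pairs for speed.  The
resulting matrix initialises the supervised embedding layer

    X_t = ReLU(W_xemb x_t + b_x)        (and P_t analogously for DRGs)

which is then fine-tuned end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ehr_data import Cohort, CodeVocabulary, build_vocab

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingParams:
    W_xemb: np.ndarray  # (d, |D|)
    b_x: np.ndarray     # (d,)
    W_pemb: np.ndarray  # (d, |L|)
    b_p: np.ndarray     # (d,)

    @property
    def d(self) -> int:
        return self.W_xemb.shape[0]

    @classmethod
    def init(cls, n_dx: int, n_drg: int, d: int = 32,
             rng: np.random.Generator | None = None,
             scale: float = 0.1) -> "EmbeddingParams":
        rng = rng or np.random.default_rng(0)
        return cls(
            W_xemb=rng.normal(0.0, scale, (d, n_dx)),
            b_x=np.zeros(d),
            W_pemb=rng.normal(0.0, scale, (d, n_drg)),
            b_p=np.zeros(d),
        )


def embed_visit(codes_multi_hot: np.ndarray, W: np.ndarray,
                b: np.ndarray) -> np.ndarray:
    """ReLU(W x + b) for one multi-hot code vector."""
    if codes_multi_hot.shape[-1] != W.shape[1]:
        raise ValueError(
            f"multi-hot length {codes_multi_hot.shape[-1]} does not match "
            f"vocabulary size {W.shape[1]}"
        )
    return np.maximum(W @ codes_multi_hot + b, 0.0)


def _visit_code_lists(cohort: Cohort, kind: str,
                      vocab: CodeVocabulary) -> list[list[int]]:
    corpus = []
    for patient in cohort:
        for v in patient.visits:
            codes = v.diagnosis_codes if kind == "diagnosis" else v.drg_codes
            idx = sorted(vocab.index[c] for c in codes if c in vocab.index)
            if len(idx) >= 1:
                corpus.append(idx)
    return corpus


def pretrain_code_embeddings(
    cohort: Cohort,
    kind: str,
    d: int = 32,
    epochs: int = 5,
    negatives: int = 5,
    seed: int = 0,
    lr: float = 0.05,
    batch_pairs: int = 512,
    vocab: CodeVocabulary | None = None,
) -> np.ndarray:
    """Skip-gram-with-negative-sampling code vectors, returned as d x |vocab|.

    Deterministic for a fixed seed.  The learning rate decays linearly to a
    tenth of its initial value over the run.  Pass ``vocab`` to align the
    columns with an externally built vocabulary (codes absent from the
    cohort keep their random initial vectors).
    """
    if d < 2:
        raise ValueError("embedding dimension must be >= 2")
    if vocab is None:
        vocab = build_vocab(cohort, kind)
    n = len(vocab)
    if n < 2:
        raise ValueError("vocabulary must contain at least 2 codes")
    rng = np.random.default_rng(seed)
    corpus = _visit_code_lists(cohort, kind, vocab)

    # all ordered (centre, context) pairs within each visit
    centres, contexts = [], []
    counts = np.zeros(n)
    for visit in corpus:
        for c in visit:
            counts[c] += 1
        if len(visit) < 2:
            continue
        arr = np.array(visit)
        for i in range(len(arr)):
            centres.extend([arr[i]] * (len(arr) - 1))
            contexts.extend(arr[np.arange(len(arr)) != i])
    if not centres:
        raise ValueError("no co-occurring code pairs in the corpus")
    centres = np.array(centres)
    contexts = np.array(contexts)
    noise = np.maximum(counts, 1.0) ** 0.75
    noise /= noise.sum()

    W_in = rng.normal(0.0, 0.5 / np.sqrt(d), (n, d))
    W_out = np.zeros((n, d))
    n_pairs = len(centres)
    total_batches = epochs * int(np.ceil(n_pairs / batch_pairs))
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch_pairs):
            idx = order[start:start + batch_pairs]
            c, o = centres[idx], contexts[idx]
            eta = lr * (1.0 - 0.9 * step / max(total_batches - 1, 1))
            step += 1
            neg = rng.choice(n, size=(len(idx), negatives), p=noise)
            vc = W_in[c]                      # (B, d)
            # positive pair: maximise sigma(vc . vo)
            vo = W_out[o]
            s = 1.0 / (1.0 + np.exp(-np.clip(np.sum(vc * vo, axis=1),
                                             -30.0, 30.0)))
            g = (s - 1.0)[:, None]            # d logloss / d score
            dvc = g * vo
            np.add.at(W_out, o, eta * -(g * vc))
            # negatives: minimise sigma(vc . vn)
            vn = W_out[neg]                   # (B, K, d)
            sn = 1.0 / (1.0 + np.exp(-np.clip(
                np.einsum("bd,bkd->bk", vc, vn), -30.0, 30.0)))
            dvc += np.einsum("bk,bkd->bd", sn, vn)
            np.add.at(W_out, neg, eta * -(sn[..., None] * vc[:, None, :]))
            np.add.at(W_in, c, -eta * dvc)
    logger.info("pretrained %s embeddings: %d codes, %d pairs, %d epochs",
                kind, n, n_pairs, epochs)
    return W_in.T.copy()  # (d, |vocab|)


def code_correlation_matrix(W: np.ndarray) -> np.ndarray:
    """Pearson correlations between embedding columns (one column per code).

    Constant columns have no defined correlation; their rows/columns are set
    to NaN (diagonal stays 1) and a warning is logged.
    """
    if W.ndim != 2 or W.shape[1] < 2:
        raise ValueError("W must be a d x |vocab| matrix with >= 2 columns")
    sd = W.std(axis=0)
    constant = sd == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(W, rowvar=False)
    if constant.any():
        logger.warning("code_correlation_matrix: %d constant column(s) "
                       "marked NaN", int(constant.sum()))
        corr[constant, :] = np.nan
        corr[:, constant] = np.nan
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def block_correlation_contrast(
    corr: np.ndarray, blocks: list[list[int]]
) -> tuple[float, float]:
    """Mean within-block vs cross-block correlation (interpretability check)."""
    n = corr.shape[0]
    members = np.full(n, -1)
    for b, idx in enumerate(blocks):
        members[np.array(idx)] = b
    within, cross = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if members[i] < 0 or members[j] < 0 or np.isnan(corr[i, j]):
                continue
            (within if members[i] == members[j] else cross).append(corr[i, j])
    return float(np.mean(within)), float(np.mean(cross))
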