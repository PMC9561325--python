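"""Training protocol, schedules, metrics, cross-validation and the
hard-positive analysis.

The protocol mirrors the reference configuration for this model family:
mini-batches of 80 patients, Adadelta with decay rho = 0.1, a slanted
triangular learning-rate schedule (linear warm-up over the first tenth of
iterations, then linear decay, ratio 32 between peak and endpoints),
L1 + L2 regularization at 1e-4 on weight matrices, and dropout with keep
probability 0.8 on the pooled status vector.  Evaluation is patient-level:
the prediction scored for a patient is the risk after their final visit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

from .ehr_data import Cohort, CodeVocabulary, build_vocab, encode_sequences, \
    EncodedSequence
from .embeddings import pretrain_code_embeddings
from .model import DeepMPMParams, forward, loss_and_grads, zero_grads, \
    _is_bias

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    batch_size: int = 80
    epochs: int = 100
    adadelta_rho: float = 0.1
    adadelta_eps: float = 1e-6
    reg_l1: float = 1e-4
    reg_l2: float = 1e-4
    dropout_keep: float = 0.8
    stlr_cut_frac: float = 0.1
    stlr_ratio: float = 32.0
    stlr_eta_max: float = 0.1
    cv_folds: int = 5
    seed: int = 0
    ablate_beta: bool = False
    d: int = 32
    hidden_alpha: int = 64
    hidden_beta: int = 64
    init_scale: float = 0.1
    pretrain_embeddings: bool = True
    pretrain_epochs: int = 3
    pretrain_negatives: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.stlr_cut_frac < 1.0:
            raise ValueError("stlr_cut_frac must be in (0, 1)")
        if self.stlr_ratio <= 1.0:
            raise ValueError("stlr_ratio must exceed 1")
        if not 0.0 < self.dropout_keep <= 1.0:
            raise ValueError("dropout_keep must be in (0, 1]")
        if not 0.0 < self.adadelta_rho < 1.0:
            raise ValueError("adadelta_rho must be in (0, 1)")


@dataclass
class EvalReport:
    auc: float
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int

    @classmethod
    def from_scores(cls, scores: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5) -> "EvalReport":
        labels = np.asarray(labels, dtype=int)
        pred = (np.asarray(scores) >= threshold).astype(int)
        tp = int(((pred == 1) & (labels == 1)).sum())
        fp = int(((pred == 1) & (labels == 0)).sum())
        fn = int(((pred == 0) & (labels == 1)).sum())
        tn = int(((pred == 0) & (labels == 0)).sum())
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        return cls(auc=rank_auc(scores, labels), precision=precision,
                   recall=recall, f1=f1, tp=tp, fp=fp, fn=fn, tn=tn)


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUROC via the rank (Mann-Whitney U) formulation, ties at half credit."""
    labels = np.asarray(labels, dtype=bool)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: only one class present")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# ---------------------------------------------------------------------------
# loss / schedule / optimizer primitives
# ---------------------------------------------------------------------------

_CLIP = 1e-7


def cross_entropy_loss(predictions, labels, visit_counts) -> float:
    """Mean over patients of the per-patient mean over visits of binary
    cross-entropy.  ``predictions``/``labels`` are flat per-visit arrays,
    ``visit_counts`` the number of visits of each patient (so the flat
    arrays concatenate the patients' visit sequences in order).
    Predictions are clipped into [1e-7, 1 - 1e-7]; never raises on
    out-of-range values.
    """
    y_hat = np.clip(np.asarray(predictions, float), _CLIP, 1.0 - _CLIP)
    y = np.asarray(labels, float)
    counts = np.asarray(visit_counts, int)
    if y_hat.shape != y.shape or counts.sum() != len(y):
        raise ValueError("predictions, labels and visit_counts disagree")
    per_visit = -(y * np.log(y_hat) + (1.0 - y) * np.log(1.0 - y_hat))
    loss = 0.0
    start = 0
    for T in counts:
        loss += per_visit[start:start + T].mean()
        start += T
    return float(loss / len(counts))


def stlr_schedule(t: float, T_total: float, cut_frac: float = 0.1,
                  ratio: float = 32.0, eta_max: float = 0.1) -> float:
    """Slanted triangular learning rate: linear rise on [0, cut] to eta_max,
    then linear decay back to eta_max/ratio at t = T_total."""
    if not 0 <= t <= T_total:
        raise ValueError(f"iteration {t} outside [0, {T_total}]")
    cut = T_total * cut_frac
    if t < cut:
        p = t / cut
    else:
        p = 1.0 - (t - cut) / (cut * (1.0 / cut_frac - 1.0))
    return eta_max * (1.0 + p * (ratio - 1.0)) / ratio


@dataclass
class AdadeltaState:
    eg2: dict[str, np.ndarray]
    edx2: dict[str, np.ndarray]

    @classmethod
    def init(cls, params: DeepMPMParams) -> "AdadeltaState":
        return cls(eg2={k: np.zeros_like(v) for k, v in
                        params.arrays().items()},
                   edx2={k: np.zeros_like(v) for k, v in
                         params.arrays().items()})


def adadelta_step(
    params: DeepMPMParams,
    grads: dict[str, np.ndarray],
    state: AdadeltaState,
    rho: float,
    eta: float = 1.0,
    eps: float = 1e-6,
) -> None:
    """In-place Adadelta update, step scaled by the schedule's eta."""
    for name, arr in params.arrays().items():
        g = grads[name]
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient for {name}")
        eg2 = state.eg2[name]
        edx2 = state.edx2[name]
        eg2 *= rho
        eg2 += (1.0 - rho) * g * g
        dx = -np.sqrt(edx2 + eps) / np.sqrt(eg2 + eps) * g
        edx2 *= rho
        edx2 += (1.0 - rho) * dx * dx
        arr += eta * dx


def apply_regularization(loss: float, params: DeepMPMParams,
                         l1: float = 1e-4, l2: float = 1e-4) -> float:
    """loss + l1*sum|w| + l2*sum w^2 over weight matrices (biases excluded)."""
    penalty = 0.0
    for name, arr in params.arrays().items():
        if _is_bias(name):
            continue
        penalty += l1 * np.abs(arr).sum() + l2 * (arr ** 2).sum()
    return loss + penalty


# ---------------------------------------------------------------------------
# training / evaluation
# ---------------------------------------------------------------------------

@dataclass
class Checkpoint:
    params: DeepMPMParams
    vocab_dx: CodeVocabulary
    vocab_drg: CodeVocabulary
    config: TrainConfig

    def save(self, path) -> None:
        payload = {
            "meta": {
                "d": self.config.d,
                "hidden_alpha": self.config.hidden_alpha,
                "hidden_beta": self.config.hidden_beta,
                "config": asdict(self.config),
                "vocab_dx": self.vocab_dx.codes,
                "vocab_drg": self.vocab_drg.codes,
            },
            "arrays": {k: v.tolist() for k, v in
                       self.params.arrays().items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with open(path) as fh:
            payload = json.load(fh)
        meta = payload["meta"]
        cfg_d = dict(meta["config"])
        config = TrainConfig(**cfg_d)
        vocab_dx = CodeVocabulary("diagnosis", meta["vocab_dx"])
        vocab_drg = CodeVocabulary("drg", meta["vocab_drg"])
        params = DeepMPMParams.init(len(vocab_dx), len(vocab_drg),
                                    d=meta["d"],
                                    hidden_alpha=meta["hidden_alpha"],
                                    hidden_beta=meta["hidden_beta"])
        for k, arr in params.arrays().items():
            arr[...] = np.array(payload["arrays"][k])
        return cls(params, vocab_dx, vocab_drg, config)


def _encode_cohort(cohort: Cohort):
    vocab_dx = build_vocab(cohort, "diagnosis")
    vocab_drg = build_vocab(cohort, "drg")
    seqs = encode_sequences(cohort, vocab_dx, vocab_drg)
    return vocab_dx, vocab_drg, seqs


def train(
    cohort: Cohort,
    config: TrainConfig,
    vocabs: tuple[CodeVocabulary, CodeVocabulary] | None = None,
) -> tuple[Checkpoint, list[dict]]:
    """Train on a cleaned cohort; returns the checkpoint and a per-epoch log.

    Deterministic for a fixed config: data order, initialization, dropout
    and pretraining all flow from config.seed.
    """
    if vocabs is None:
        vocab_dx, vocab_drg, seqs = _encode_cohort(cohort)
    else:
        vocab_dx, vocab_drg = vocabs
        seqs = encode_sequences(cohort, vocab_dx, vocab_drg)
    labels = np.array([int(s.y[s.n_visits - 1]) for s in seqs])
    if len(np.unique(labels)) < 2:
        raise ValueError("training set contains a single class")

    rng = np.random.default_rng(config.seed)
    params = DeepMPMParams.init(
        len(vocab_dx), len(vocab_drg), d=config.d,
        hidden_alpha=config.hidden_alpha, hidden_beta=config.hidden_beta,
        rng=rng, scale=config.init_scale,
    )
    if config.pretrain_embeddings:
        params.emb.W_xemb[...] = pretrain_code_embeddings(
            cohort, "diagnosis", d=config.d,
            epochs=config.pretrain_epochs,
            negatives=config.pretrain_negatives,
            seed=config.seed, vocab=vocab_dx,
        )
        params.emb.W_pemb[...] = pretrain_code_embeddings(
            cohort, "drg", d=config.d,
            epochs=config.pretrain_epochs,
            negatives=config.pretrain_negatives,
            seed=config.seed + 1, vocab=vocab_drg,
        )

    n = len(seqs)
    batches_per_epoch = int(np.ceil(n / config.batch_size))
    T_total = config.epochs * batches_per_epoch
    opt_state = AdadeltaState.init(params)
    log: list[dict] = []
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        eta = 0.0
        for b in range(batches_per_epoch):
            idx = order[b * config.batch_size:(b + 1) * config.batch_size]
            batch = [seqs[j] for j in idx]
            loss, grads = loss_and_grads(
                batch, params,
                ablate_beta=config.ablate_beta,
                dropout_keep=config.dropout_keep, rng=rng,
                l1=config.reg_l1, l2=config.reg_l2,
            )
            eta = stlr_schedule(step, T_total, config.stlr_cut_frac,
                                config.stlr_ratio, config.stlr_eta_max)
            adadelta_step(params, grads, opt_state, config.adadelta_rho,
                          eta=eta, eps=config.adadelta_eps)
            epoch_loss += loss * len(batch)
            step += 1
        entry = {"epoch": epoch, "loss": epoch_loss / n, "eta": eta}
        log.append(entry)
        logger.info("epoch %d: loss=%.5f eta=%.5f", epoch, entry["loss"], eta)
    return Checkpoint(params, vocab_dx, vocab_drg, config), log


def predict_cohort(checkpoint: Checkpoint, cohort: Cohort,
                   seqs: list[EncodedSequence] | None = None):
    """Patient-level scores (risk after the final visit) and labels."""
    if seqs is None:
        seqs = encode_sequences(cohort, checkpoint.vocab_dx,
                                checkpoint.vocab_drg)
    scores, labels, pids = [], [], []
    for s in seqs:
        out = forward(s, checkpoint.params,
                      ablate_beta=checkpoint.config.ablate_beta)
        scores.append(out.risk[s.n_visits - 1])
        labels.append(int(s.y[s.n_visits - 1]))
        pids.append(s.patient_id)
    return np.array(scores), np.array(labels), pids


def evaluate(checkpoint: Checkpoint, cohort: Cohort) -> EvalReport:
    """Patient-level metrics on a cohort sharing the model's vocabularies."""
    scores, labels, _ = predict_cohort(checkpoint, cohort)
    return EvalReport.from_scores(scores, labels)


def cross_validate(
    cohort: Cohort,
    config: TrainConfig,
    repeats: int = 1,
) -> tuple[list[EvalReport], dict[str, tuple[int, int]]]:
    """Repeated stratified k-fold CV at patient level.

    Returns per-fold reports and, for every positive patient, the pair
    (test appearances, misclassification count) across all repeats.
    """
    patients = list(cohort)
    labels = np.array([int(p.died) for p in patients])
    if len(patients) < config.cv_folds:
        raise ValueError("fewer patients than folds")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    reports: list[EvalReport] = []
    history: dict[str, tuple[int, int]] = {}
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                              random_state=(config.seed + rep) % 2 ** 31)
        for fold, (tr, te) in enumerate(skf.split(labels, labels)):
            train_cohort = Cohort([patients[j] for j in tr])
            test_cohort = Cohort([patients[j] for j in te])
            fold_cfg = TrainConfig(**{**asdict(config),
                                      "seed": config.seed + 97 * rep + fold})
            ckpt, _ = train(train_cohort, fold_cfg)
            scores, y, pids = predict_cohort(ckpt, test_cohort)
            reports.append(EvalReport.from_scores(scores, y))
            for s, yy, pid in zip(scores, y, pids):
                if yy == 1:
                    a, m = history.get(pid, (0, 0))
                    history[pid] = (a + 1, m + int(s < 0.5))
    return reports, history


def collect_hard_positives(history: dict[str, tuple[int, int]]) -> set[str]:
    """Positives misclassified in strictly more than half of their test
    appearances across repeated cross-validation."""
    return {pid for pid, (appearances, missed) in history.items()
            if missed * 2 > appearances}


def summarize_reports(reports: list[EvalReport]) -> dict[str, tuple[float, float]]:
    """Fold-wise mean and standard deviation of each metric."""
    out = {}
    for metric in ("auc", "precision", "recall", "f1"):
        vals = np.array([getattr(r, metric) for r in reports])
        out[metric] = (float(vals.mean()), float(vals.std(ddof=1)
                                                 if len(vals) > 1 else 0.0))
    return out


def holdout_auc(cohort: Cohort, config: TrainConfig,
                test_frac: float = 0.25) -> float:
    """Train/test split at patient level, returns held-out patient AUC."""
    patients = list(cohort)
    labels = np.array([int(p.died) for p in patients])
    tr, te = train_test_split(
        np.arange(len(patients)), test_size=test_frac,
        random_state=config.seed % 2 ** 31, stratify=labels,
    )
    vocab_dx = build_vocab(cohort, "diagnosis")
    vocab_drg = build_vocab(cohort, "drg")
    ckpt, _ = train(Cohort([patients[j] for j in tr]), config,
                    vocabs=(vocab_dx, vocab_drg))
    scores, y, _ = predict_cohort(ckpt, Cohort([patients[j] for j in te]))
    return rank_auc(scores, y)
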