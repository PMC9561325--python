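"""The full risk model: two-level attention over Care-LSTM states, harmonic
time weighting, pooled patient-status vector and a softmax risk head.

For a patient with visits 1..T the pipeline is, per prefix 1..i (so that a
risk estimate exists after every visit and is independent of later visits):

    g_t = Care-LSTM_alpha([X_t; P_t; m_t; delta_{t-1:t}])       (visit branch)
    e_t = Care-LSTM_beta ([X_t; P_t; m_t; delta_{t-1:t}])       (variable branch)
    alpha = softmax_t(W_alpha . g_t + b_alpha)        over visits t <= i
    beta_t = tanh(W_beta e_t + b_beta)                in [-1, 1]^d
    r_t = 1 / (m_t + ln(1 + Delta_{t:i}))             harmonic time weight
    w_t = r_t * (alpha_t + beta_t) / 2                (ablated: r_t * alpha_t)
    h_bar = (sum_t w_t * X_t) / (sum_t w_t)           elementwise
    y_hat_i = softmax(FCN(h_bar))[death]

Delta_{t:i} is the day count from visit t's admission to the prefix's last
discharge.  Alpha is a softmax ACROSS visits (a per-visit softmax of a
scalar would be identically 1).  The elementwise pooled denominator can
cancel because beta may be negative, so its magnitude is floored at 1e-8.

Gradients of the training loss with respect to every parameter are computed
by a hand-written reverse pass (verified against finite differences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import care_lstm as cl
from .care_lstm import CareLSTMParams
from .ehr_data import EncodedSequence
from .embeddings import EmbeddingParams

DENOM_EPS = 1e-8


@dataclass
class AttentionParams:
    W_alpha: np.ndarray  # (p,)
    b_alpha: np.ndarray  # (1,)
    W_beta: np.ndarray   # (d, q)
    b_beta: np.ndarray   # (d,)

    @classmethod
    def init(cls, d: int, p: int, q: int,
             rng: np.random.Generator | None = None,
             scale: float = 0.1) -> "AttentionParams":
        rng = rng or np.random.default_rng(0)
        return cls(W_alpha=rng.normal(0.0, scale, p),
                   b_alpha=np.zeros(1),
                   W_beta=rng.normal(0.0, scale, (d, q)),
                   b_beta=np.zeros(d))


@dataclass
class HeadParams:
    fcn_weight: np.ndarray  # (2, d) — logits for {discharged, death}
    fcn_bias: np.ndarray    # (2,)

    @classmethod
    def init(cls, d: int, rng: np.random.Generator | None = None,
             scale: float = 0.1) -> "HeadParams":
        rng = rng or np.random.default_rng(0)
        return cls(fcn_weight=rng.normal(0.0, scale, (2, d)),
                   fcn_bias=np.zeros(2))


@dataclass
class DeepMPMParams:
    emb: EmbeddingParams
    lstm_alpha: CareLSTMParams
    lstm_beta: CareLSTMParams
    attn: AttentionParams
    head: HeadParams

    @property
    def d(self) -> int:
        return self.emb.d

    def arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array view of every learnable tensor."""
        out: dict[str, np.ndarray] = {
            "emb.W_xemb": self.emb.W_xemb, "emb.b_x": self.emb.b_x,
            "emb.W_pemb": self.emb.W_pemb, "emb.b_p": self.emb.b_p,
        }
        for prefix, lstm in (("lstm_alpha", self.lstm_alpha),
                             ("lstm_beta", self.lstm_beta)):
            for name, arr in lstm.arrays().items():
                out[f"{prefix}.{name}"] = arr
        out.update({
            "attn.W_alpha": self.attn.W_alpha,
            "attn.b_alpha": self.attn.b_alpha,
            "attn.W_beta": self.attn.W_beta,
            "attn.b_beta": self.attn.b_beta,
            "head.fcn_weight": self.head.fcn_weight,
            "head.fcn_bias": self.head.fcn_bias,
        })
        return out

    @classmethod
    def init(cls, n_dx: int, n_drg: int, d: int = 32,
             hidden_alpha: int = 64, hidden_beta: int = 64,
             rng: np.random.Generator | None = None,
             scale: float = 0.1) -> "DeepMPMParams":
        rng = rng or np.random.default_rng(0)
        return cls(
            emb=EmbeddingParams.init(n_dx, n_drg, d, rng, scale),
            lstm_alpha=CareLSTMParams.init(d, hidden_alpha, rng, scale),
            lstm_beta=CareLSTMParams.init(d, hidden_beta, rng, scale),
            attn=AttentionParams.init(d, hidden_alpha, hidden_beta, rng,
                                      scale),
            head=HeadParams.init(d, rng, scale),
        )


@dataclass
class PredictionOutput:
    """Per-visit risks plus every attention tensor, for interpretability.

    ``risk[i]`` is the death probability after visit i computed from visits
    1..i only.  alpha/r/w/h_bar refer to the full-sequence (prefix = T)
    pass; beta is prefix-independent.
    """

    patient_id: str
    risk: np.ndarray    # (T,)
    alpha: np.ndarray   # (T,)
    beta: np.ndarray    # (T, d)
    r: np.ndarray       # (T,)
    w: np.ndarray       # (T, d)
    h_bar: np.ndarray   # (T, d) — pooled status vector of each prefix


def zero_grads(params: DeepMPMParams) -> dict[str, np.ndarray]:
    return {k: np.zeros_like(v) for k, v in params.arrays().items()}


# ---------------------------------------------------------------------------
# component operations (the library surface; forward() composes fast paths)
# ---------------------------------------------------------------------------

def visit_attention(G: np.ndarray, params: AttentionParams,
                    mask: np.ndarray | None = None) -> np.ndarray:
    """Softmax across visits of the scalar scores W_alpha . g_t + b_alpha."""
    T = G.shape[0]
    mask = np.ones(T, dtype=bool) if mask is None else np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("all visits masked in visit_attention")
    scores = G @ params.W_alpha + params.b_alpha[0]
    alpha = np.zeros(T)
    s = scores[mask]
    e = np.exp(s - s.max())
    alpha[mask] = e / e.sum()
    return alpha


def variable_attention(e_t: np.ndarray,
                       params: AttentionParams) -> np.ndarray:
    """tanh(W_beta e_t + b_beta): per-dimension weights in [-1, 1]."""
    if e_t.shape[0] != params.W_beta.shape[1]:
        raise ValueError("hidden dimension does not match W_beta")
    return np.tanh(params.W_beta @ e_t + params.b_beta)


def harmonic_weight(m_t: float, delta_to_last: float) -> float:
    """r_t = 1 / (m_t + ln(1 + Delta_{t:T})); natural logarithm, in (0, 1]."""
    if delta_to_last < 0:
        raise ValueError("delta_to_last must be non-negative")
    return 1.0 / (m_t + np.log1p(delta_to_last))


def combine_weights(alpha: np.ndarray, beta: np.ndarray,
                    r: np.ndarray) -> np.ndarray:
    """w_t = r_t * (alpha_t + beta_t) / 2, alpha broadcast across d."""
    alpha, r = np.asarray(alpha, float), np.asarray(r, float)
    if beta.shape[0] != alpha.shape[0] or r.shape[0] != alpha.shape[0]:
        raise ValueError("alpha, beta, r must agree on the visit axis")
    return r[:, None] * (alpha[:, None] + beta) / 2.0


def _guard_denominator(den: np.ndarray) -> np.ndarray:
    sign = np.where(den >= 0.0, 1.0, -1.0)
    return sign * np.maximum(np.abs(den), DENOM_EPS)


def pool_health_status(w: np.ndarray, X: np.ndarray,
                       mask: np.ndarray | None = None) -> np.ndarray:
    """Elementwise weighted average of the diagnosis embeddings."""
    T = X.shape[0]
    mask = np.ones(T, dtype=bool) if mask is None else np.asarray(mask, bool)
    wm = w[mask]
    num = (wm * X[mask]).sum(axis=0)
    den = _guard_denominator(wm.sum(axis=0))
    return num / den


def predict_risk(h_bar: np.ndarray, head: HeadParams) -> np.ndarray:
    """softmax(FCN(h_bar)) over {discharged, death}."""
    if not np.all(np.isfinite(h_bar)):
        raise ValueError("non-finite patient status vector")
    z = head.fcn_weight @ h_bar + head.fcn_bias
    e = np.exp(z - z.max())
    return e / e.sum()


# ---------------------------------------------------------------------------
# full forward / backward
# ---------------------------------------------------------------------------

def _prefix_r(seq: EncodedSequence, i: int) -> np.ndarray:
    """Harmonic weights of visits 1..i relative to the prefix's last
    discharge, so a prefix prediction never looks past visit i."""
    delta = np.maximum(seq.discharge_day[i - 1] - seq.admit_day[:i], 0.0)
    return 1.0 / (seq.m[:i] + np.log1p(delta))


def forward(
    seq: EncodedSequence,
    params: DeepMPMParams,
    ablate_beta: bool = False,
) -> PredictionOutput:
    """Inference pass: per-prefix risks plus attention tensors."""
    T = seq.n_visits
    if T == 0:
        raise ValueError("empty sequence")
    x, p = seq.x[:T], seq.p[:T]
    Zx = x @ params.emb.W_xemb.T + params.emb.b_x
    Zp = p @ params.emb.W_pemb.T + params.emb.b_p
    X = np.maximum(Zx, 0.0)
    P = np.maximum(Zp, 0.0)
    G = cl.run_sequence(X, P, seq.m[:T], seq.delta_prev[:T], params.lstm_alpha)
    E = cl.run_sequence(X, P, seq.m[:T], seq.delta_prev[:T], params.lstm_beta)
    beta = np.tanh(E @ params.attn.W_beta.T + params.attn.b_beta)
    scores = G @ params.attn.W_alpha + params.attn.b_alpha[0]

    risk = np.zeros(T)
    h_bars = np.zeros((T, params.d))
    alpha_full = None
    w_full = None
    r_full = None
    for i in range(1, T + 1):
        s = scores[:i]
        e = np.exp(s - s.max())
        alpha = e / e.sum()
        r = _prefix_r(seq, i)
        w = (r[:, None] * np.repeat(alpha[:, None], params.d, axis=1)
             if ablate_beta
             else r[:, None] * (alpha[:, None] + beta[:i]) / 2.0)
        num = (w * X[:i]).sum(axis=0)
        den = _guard_denominator(w.sum(axis=0))
        h_bar = num / den
        h_bars[i - 1] = h_bar
        risk[i - 1] = predict_risk(h_bar, params.head)[1]
        if i == T:
            alpha_full, w_full, r_full = alpha, w, r
    return PredictionOutput(
        patient_id=seq.patient_id, risk=risk, alpha=alpha_full,
        beta=beta, r=r_full, w=w_full, h_bar=h_bars,
    )


def loss_and_grads(
    seqs: list[EncodedSequence],
    params: DeepMPMParams,
    ablate_beta: bool = False,
    dropout_keep: float = 1.0,
    rng: np.random.Generator | None = None,
    l1: float = 0.0,
    l2: float = 0.0,
    compute_grads: bool = True,
) -> tuple[float, dict[str, np.ndarray] | None]:
    """Training loss (Eq.-style: mean over patients of the per-patient mean
    over visit prefixes of binary cross-entropy) and its exact gradients.

    Dropout (inverted, keep probability ``dropout_keep``) is applied to the
    pooled status vector h_bar; L1+L2 penalties cover weight matrices but
    not bias vectors.
    """
    if dropout_keep < 1.0 and rng is None:
        raise ValueError("dropout requires an rng")
    N = len(seqs)
    if N == 0:
        raise ValueError("empty batch")
    grads = zero_grads(params) if compute_grads else None
    total_loss = 0.0
    A = params.attn
    for seq in seqs:
        T = seq.n_visits
        x, p = seq.x[:T], seq.p[:T]
        Zx = x @ params.emb.W_xemb.T + params.emb.b_x
        Zp = p @ params.emb.W_pemb.T + params.emb.b_p
        X = np.maximum(Zx, 0.0)
        P = np.maximum(Zp, 0.0)
        G, cache_a = cl.run_sequence(X, P, seq.m[:T], seq.delta_prev[:T],
                                     params.lstm_alpha, return_cache=True)
        E, cache_b = cl.run_sequence(X, P, seq.m[:T], seq.delta_prev[:T],
                                     params.lstm_beta, return_cache=True)
        beta = np.tanh(E @ A.W_beta.T + A.b_beta)
        scores = G @ A.W_alpha + A.b_alpha[0]

        dG = np.zeros_like(G)
        dBeta = np.zeros_like(beta)
        dX_pool = np.zeros_like(X)
        patient_loss = 0.0
        for i in range(1, T + 1):
            s = scores[:i]
            es = np.exp(s - s.max())
            alpha = es / es.sum()
            r = _prefix_r(seq, i)
            if ablate_beta:
                w = r[:, None] * np.repeat(alpha[:, None], params.d, axis=1)
            else:
                w = r[:, None] * (alpha[:, None] + beta[:i]) / 2.0
            num = (w * X[:i]).sum(axis=0)
            den_raw = w.sum(axis=0)
            den = _guard_denominator(den_raw)
            h_bar = num / den
            if dropout_keep < 1.0:
                drop = (rng.random(params.d) < dropout_keep) / dropout_keep
                h_used = h_bar * drop
            else:
                drop = None
                h_used = h_bar
            z = params.head.fcn_weight @ h_used + params.head.fcn_bias
            zmax = z.max()
            logZ = zmax + np.log(np.exp(z - zmax).sum())
            y = int(seq.y[i - 1])
            patient_loss += logZ - z[y]
            if not compute_grads:
                continue

            prob = np.exp(z - logZ)
            dz = prob.copy()
            dz[y] -= 1.0
            dz /= N * T  # chain through the double mean now
            grads["head.fcn_weight"] += np.outer(dz, h_used)
            grads["head.fcn_bias"] += dz
            dh_used = params.head.fcn_weight.T @ dz
            dh_bar = dh_used * drop if drop is not None else dh_used
            dnum = dh_bar / den
            dden = -dh_bar * num / den ** 2
            dden_raw = np.where(np.abs(den_raw) >= DENOM_EPS, dden, 0.0)
            dw = dnum[None, :] * X[:i] + dden_raw[None, :]
            dX_pool[:i] += dnum[None, :] * w
            if ablate_beta:
                dalpha = (dw * r[:, None]).sum(axis=1)
            else:
                dalpha = (dw * r[:, None] / 2.0).sum(axis=1)
                dBeta[:i] += dw * r[:, None] / 2.0
            ds = alpha * (dalpha - float(alpha @ dalpha))
            grads["attn.W_alpha"] += G[:i].T @ ds
            grads["attn.b_alpha"][0] += ds.sum()
            dG[:i] += np.outer(ds, A.W_alpha)
        total_loss += patient_loss / T
        if not compute_grads:
            continue

        dpre_beta = dBeta * (1.0 - beta ** 2)
        grads["attn.W_beta"] += dpre_beta.T @ E
        grads["attn.b_beta"] += dpre_beta.sum(axis=0)
        dE = dpre_beta @ A.W_beta

        dX = dX_pool
        dP = np.zeros_like(P)
        sub_a = {k.split(".", 1)[1]: v for k, v in grads.items()
                 if k.startswith("lstm_alpha.")}
        sub_b = {k.split(".", 1)[1]: v for k, v in grads.items()
                 if k.startswith("lstm_beta.")}
        cl.backward_sequence(dG, cache_a, params.lstm_alpha, sub_a, dX, dP)
        cl.backward_sequence(dE, cache_b, params.lstm_beta, sub_b, dX, dP)

        dZx = dX * (Zx > 0.0)
        dZp = dP * (Zp > 0.0)
        grads["emb.W_xemb"] += dZx.T @ x
        grads["emb.b_x"] += dZx.sum(axis=0)
        grads["emb.W_pemb"] += dZp.T @ p
        grads["emb.b_p"] += dZp.sum(axis=0)

    total_loss /= N
    if l1 or l2:
        for name, arr in params.arrays().items():
            if _is_bias(name):
                continue
            total_loss += l1 * np.abs(arr).sum() + l2 * (arr ** 2).sum()
            if compute_grads:
                grads[name] += l1 * np.sign(arr) + 2.0 * l2 * arr
    return total_loss, grads


def _is_bias(name: str) -> bool:
    return name.rsplit(".", 1)[-1].startswith("b")
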