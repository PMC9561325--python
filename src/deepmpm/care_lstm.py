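"""Recurrent cells: a standard LSTM reference and the modified Care-LSTM.

The Care-LSTM augments the standard LSTM gates with clinical context:

    i_t = (1/m_t) * sigmoid(W_i X_t + U_i h_{t-1} + b_i)
    f_t = sigmoid(W_f X_t + U_f h_{t-1} + P_f P_{t-1} + Q_f q_t + b_f)
    C~_t = tanh(W_c X_t + U_c h_{t-1} + b_c)
    C_t = f_t * C_{t-1} + i_t * C~_t
    o_t = sigmoid(W_o X_t + U_o h_{t-1} + P_o P_t + b_o)
    h_t = o_t * tanh(C_t)

where X_t / P_t are the diagnosis / treatment embeddings of visit t, m_t is
the admission-type weight (1 emergency, 2 non-emergency — emergencies open
the input gate wider), and q_t rescales the day gap to the previous
discharge on three clinical time scales (60 / 180 / 365 days).  With
P_t = P_{t-1} = 0, q_t = 0 and m_t = 1 the cell reduces exactly to the
standard LSTM.  The candidate cell C~_t keeps the standard form: only the
gates receive the extra inputs.

Backward passes are hand-written (reverse-mode through the recurrence) and
are verified against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

DEFAULT_TIME_SCALES = (60.0, 180.0, 365.0)


def time_scale_vector(
    delta_days: float, scales: tuple[float, ...] = DEFAULT_TIME_SCALES
) -> np.ndarray:
    """The day gap expressed on the three clinical time scales."""
    if delta_days < 0:
        raise ValueError("delta_days must be non-negative")
    return np.array([delta_days / s for s in scales])


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class CellState:
    h: np.ndarray
    C: np.ndarray

    @classmethod
    def zeros(cls, hidden: int) -> "CellState":
        return cls(h=np.zeros(hidden), C=np.zeros(hidden))


# ---------------------------------------------------------------------------
# standard LSTM (reference cell)
# ---------------------------------------------------------------------------

@dataclass
class StandardLSTMParams:
    """Gate weights over the concatenated input [x_t, h_{t-1}]."""

    W_f: np.ndarray  # (hidden, d + hidden)
    W_i: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray  # (hidden,)
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    @classmethod
    def init(cls, d: int, hidden: int,
             rng: np.random.Generator | None = None,
             scale: float = 0.1) -> "StandardLSTMParams":
        rng = rng or np.random.default_rng(0)
        mk = lambda: rng.normal(0.0, scale, (hidden, d + hidden))
        return cls(W_f=mk(), W_i=mk(), W_c=mk(), W_o=mk(),
                   b_f=np.zeros(hidden), b_i=np.zeros(hidden),
                   b_c=np.zeros(hidden), b_o=np.zeros(hidden))


def standard_lstm_step(x: np.ndarray, state: CellState,
                       params: StandardLSTMParams) -> CellState:
    """One standard LSTM step on the concatenated input [x, h_{t-1}]."""
    hidden = params.b_f.shape[0]
    if x.shape[0] + hidden != params.W_f.shape[1]:
        raise ValueError("input/hidden dimensions do not match parameters")
    xh = np.concatenate([x, state.h])
    f = _sigmoid(params.W_f @ xh + params.b_f)
    i = _sigmoid(params.W_i @ xh + params.b_i)
    c_tilde = np.tanh(params.W_c @ xh + params.b_c)
    C = f * state.C + i * c_tilde
    o = _sigmoid(params.W_o @ xh + params.b_o)
    return CellState(h=o * np.tanh(C), C=C)


# ---------------------------------------------------------------------------
# Care-LSTM
# ---------------------------------------------------------------------------

@dataclass
class CareLSTMParams:
    W_i: np.ndarray  # (hidden, d)
    U_i: np.ndarray  # (hidden, hidden)
    b_i: np.ndarray
    W_f: np.ndarray
    U_f: np.ndarray
    P_f: np.ndarray  # (hidden, d) — previous-visit treatment into forget gate
    Q_f: np.ndarray  # (hidden, 3) — time-scale vector into forget gate
    b_f: np.ndarray
    W_c: np.ndarray
    U_c: np.ndarray
    b_c: np.ndarray
    W_o: np.ndarray
    U_o: np.ndarray
    P_o: np.ndarray  # (hidden, d) — current-visit treatment into output gate
    b_o: np.ndarray
    time_scales: tuple[float, ...] = DEFAULT_TIME_SCALES

    @property
    def hidden(self) -> int:
        return self.b_i.shape[0]

    @property
    def d(self) -> int:
        return self.W_i.shape[1]

    def arrays(self) -> dict[str, np.ndarray]:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name != "time_scales"}

    @classmethod
    def init(cls, d: int, hidden: int,
             rng: np.random.Generator | None = None,
             scale: float = 0.1,
             time_scales: tuple[float, ...] = DEFAULT_TIME_SCALES,
             ) -> "CareLSTMParams":
        rng = rng or np.random.default_rng(0)
        W = lambda: rng.normal(0.0, scale, (hidden, d))
        U = lambda: rng.normal(0.0, scale, (hidden, hidden))
        b = lambda: np.zeros(hidden)
        return cls(W_i=W(), U_i=U(), b_i=b(),
                   W_f=W(), U_f=U(), P_f=W(),
                   Q_f=rng.normal(0.0, scale, (hidden, len(time_scales))),
                   b_f=b(),
                   W_c=W(), U_c=U(), b_c=b(),
                   W_o=W(), U_o=U(), P_o=W(), b_o=b(),
                   time_scales=time_scales)


def care_lstm_step(
    X_t: np.ndarray,
    P_t: np.ndarray,
    P_prev: np.ndarray,
    m_t: float,
    delta_prev: float,
    state: CellState,
    params: CareLSTMParams,
) -> CellState:
    """One Care-LSTM step (see module docstring for the gate equations)."""
    if m_t < 1:
        raise ValueError("admission-type weight m_t must be >= 1")
    if X_t.shape[0] != params.d or P_t.shape[0] != params.d:
        raise ValueError("embedding dimension does not match parameters")
    q = time_scale_vector(delta_prev, params.time_scales)
    h, C = state.h, state.C
    i = (1.0 / m_t) * _sigmoid(params.W_i @ X_t + params.U_i @ h + params.b_i)
    f = _sigmoid(params.W_f @ X_t + params.U_f @ h + params.P_f @ P_prev
                 + params.Q_f @ q + params.b_f)
    c_tilde = np.tanh(params.W_c @ X_t + params.U_c @ h + params.b_c)
    C_new = f * C + i * c_tilde
    o = _sigmoid(params.W_o @ X_t + params.U_o @ h + params.P_o @ P_t
                 + params.b_o)
    return CellState(h=o * np.tanh(C_new), C=C_new)


@dataclass
class _SeqCache:
    """Forward intermediates needed by the backward pass, per time step."""

    X: np.ndarray          # (T, d)
    P: np.ndarray          # (T, d)
    Q: np.ndarray          # (T, 3)
    m: np.ndarray          # (T,)
    sig_i: list[np.ndarray]
    f: list[np.ndarray]
    c_tilde: list[np.ndarray]
    o: list[np.ndarray]
    C: list[np.ndarray]    # C_t, t = 1..T
    h_prev: list[np.ndarray]
    C_prev: list[np.ndarray]
    steps: list[int]       # indices of unmasked steps, in order


def run_sequence(
    X: np.ndarray,
    P: np.ndarray,
    m: np.ndarray,
    delta_prev: np.ndarray,
    params: CareLSTMParams,
    mask: np.ndarray | None = None,
    return_cache: bool = False,
):
    """Run the Care-LSTM over a visit sequence from a zero initial state.

    Returns the (T, hidden) matrix of hidden states; padded (masked-out)
    steps leave the state untouched and report the carried hidden state.
    The previous-visit treatment P_{t-1} is the zero vector at the first
    unmasked step.
    """
    T = X.shape[0]
    if T == 0:
        raise ValueError("empty visit sequence")
    if mask is None:
        mask = np.ones(T, dtype=bool)
    H = np.zeros((T, params.hidden))
    state = CellState.zeros(params.hidden)
    cache = _SeqCache(X=X, P=P, Q=np.zeros((T, len(params.time_scales))),
                      m=np.asarray(m, dtype=float),
                      sig_i=[], f=[], c_tilde=[], o=[], C=[],
                      h_prev=[], C_prev=[], steps=[])
    P_prev = np.zeros(params.d)
    for t in range(T):
        if not mask[t]:
            H[t] = state.h
            continue
        q = time_scale_vector(float(delta_prev[t]), params.time_scales)
        cache.Q[t] = q
        h, C = state.h, state.C
        sig = _sigmoid(params.W_i @ X[t] + params.U_i @ h + params.b_i)
        i = sig / m[t]
        f = _sigmoid(params.W_f @ X[t] + params.U_f @ h
                     + params.P_f @ P_prev + params.Q_f @ q + params.b_f)
        c_tilde = np.tanh(params.W_c @ X[t] + params.U_c @ h + params.b_c)
        C_new = f * C + i * c_tilde
        o = _sigmoid(params.W_o @ X[t] + params.U_o @ h + params.P_o @ P[t]
                     + params.b_o)
        state = CellState(h=o * np.tanh(C_new), C=C_new)
        H[t] = state.h
        cache.sig_i.append(sig)
        cache.f.append(f)
        cache.c_tilde.append(c_tilde)
        cache.o.append(o)
        cache.C.append(C_new)
        cache.h_prev.append(h)
        cache.C_prev.append(C)
        cache.steps.append(t)
        P_prev = P[t]
    if return_cache:
        return H, cache
    return H


def backward_sequence(
    dH: np.ndarray,
    cache: _SeqCache,
    params: CareLSTMParams,
    grads: dict[str, np.ndarray],
    dX: np.ndarray,
    dP: np.ndarray,
) -> None:
    """Reverse-mode pass through run_sequence.

    dH holds dLoss/dh_t for every step (zeros where unused); parameter
    gradients accumulate into ``grads`` (keyed like CareLSTMParams.arrays()),
    input gradients into dX / dP in place.
    """
    dh_rec = np.zeros(params.hidden)
    dC_rec = np.zeros(params.hidden)
    steps = cache.steps
    for k in range(len(steps) - 1, -1, -1):
        t = steps[k]
        sig, f = cache.sig_i[k], cache.f[k]
        c_tilde, o = cache.c_tilde[k], cache.o[k]
        C, h_prev, C_prev = cache.C[k], cache.h_prev[k], cache.C_prev[k]
        m_t = cache.m[t]
        i = sig / m_t
        tanhC = np.tanh(C)

        dh = dH[t] + dh_rec
        do = dh * tanhC
        dC = dC_rec + dh * o * (1.0 - tanhC ** 2)
        di = dC * c_tilde
        dct = dC * i
        df = dC * C_prev
        dC_rec = dC * f

        dzo = do * o * (1.0 - o)
        dzf = df * f * (1.0 - f)
        dzi = di * sig * (1.0 - sig) / m_t
        dzc = dct * (1.0 - c_tilde ** 2)

        X_t = cache.X[t]
        P_t = cache.P[t]
        P_prev = cache.P[steps[k - 1]] if k > 0 else np.zeros(params.d)
        q = cache.Q[t]

        grads["W_i"] += np.outer(dzi, X_t)
        grads["U_i"] += np.outer(dzi, h_prev)
        grads["b_i"] += dzi
        grads["W_f"] += np.outer(dzf, X_t)
        grads["U_f"] += np.outer(dzf, h_prev)
        grads["P_f"] += np.outer(dzf, P_prev)
        grads["Q_f"] += np.outer(dzf, q)
        grads["b_f"] += dzf
        grads["W_c"] += np.outer(dzc, X_t)
        grads["U_c"] += np.outer(dzc, h_prev)
        grads["b_c"] += dzc
        grads["W_o"] += np.outer(dzo, X_t)
        grads["U_o"] += np.outer(dzo, h_prev)
        grads["P_o"] += np.outer(dzo, P_t)
        grads["b_o"] += dzo

        dX[t] += (params.W_i.T @ dzi + params.W_f.T @ dzf
                  + params.W_c.T @ dzc + params.W_o.T @ dzo)
        dP[t] += params.P_o.T @ dzo
        if k > 0:
            dP[steps[k - 1]] += params.P_f.T @ dzf
        dh_rec = (params.U_i.T @ dzi + params.U_f.T @ dzf
                  + params.U_c.T @ dzc + params.U_o.T @ dzo)
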