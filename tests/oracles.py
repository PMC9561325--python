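"""Independent scalar-loop oracles for the vectorized implementation.

Everything here is written with explicit index loops and math.* scalar
functions, deliberately sharing no code with the package.
"""

import math

import numpy as np


def _sig(z: float) -> float:
    return 1.0 / (1.0 + math.exp(-z)) if z >= 0 else \
        math.exp(z) / (1.0 + math.exp(z))


def standard_lstm_step_oracle(x, h, C, params):
    hidden = len(h)
    xh = list(x) + list(h)
    def gate(W, b, fn):
        out = []
        for r in range(hidden):
            s = b[r]
            for c in range(len(xh)):
                s += W[r][c] * xh[c]
            out.append(fn(s))
        return out
    f = gate(params.W_f, params.b_f, _sig)
    i = gate(params.W_i, params.b_i, _sig)
    ct = gate(params.W_c, params.b_c, math.tanh)
    C_new = [f[r] * C[r] + i[r] * ct[r] for r in range(hidden)]
    o = gate(params.W_o, params.b_o, _sig)
    h_new = [o[r] * math.tanh(C_new[r]) for r in range(hidden)]
    return np.array(h_new), np.array(C_new)


def care_lstm_step_oracle(X, P, P_prev, m, delta, h, C, params):
    hidden = len(h)
    q = [delta / 60.0, delta / 180.0, delta / 365.0]

    def dot(M, v, r):
        return sum(M[r][c] * v[c] for c in range(len(v)))

    i, f, ct, o = [], [], [], []
    for r in range(hidden):
        i.append((1.0 / m) * _sig(dot(params.W_i, X, r)
                                  + dot(params.U_i, h, r) + params.b_i[r]))
        f.append(_sig(dot(params.W_f, X, r) + dot(params.U_f, h, r)
                      + dot(params.P_f, P_prev, r) + dot(params.Q_f, q, r)
                      + params.b_f[r]))
        ct.append(math.tanh(dot(params.W_c, X, r) + dot(params.U_c, h, r)
                            + params.b_c[r]))
        o.append(_sig(dot(params.W_o, X, r) + dot(params.U_o, h, r)
                      + dot(params.P_o, P, r) + params.b_o[r]))
    C_new = [f[r] * C[r] + i[r] * ct[r] for r in range(hidden)]
    h_new = [o[r] * math.tanh(C_new[r]) for r in range(hidden)]
    return np.array(h_new), np.array(C_new)


def combine_weights_oracle(alpha, beta, r):
    T, d = beta.shape
    w = np.zeros((T, d))
    for t in range(T):
        for j in range(d):
            w[t][j] = r[t] * (alpha[t] + beta[t][j]) / 2.0
    return w


def pool_oracle(w, X, eps=1e-8):
    T, d = X.shape
    out = np.zeros(d)
    for j in range(d):
        num = 0.0
        den = 0.0
        for t in range(T):
            num += w[t][j] * X[t][j]
            den += w[t][j]
        sign = 1.0 if den >= 0 else -1.0
        den = sign * max(abs(den), eps)
        out[j] = num / den
    return out


def adadelta_scalar_oracle(theta0, grads, rho, eta, eps=1e-6):
    """Hand-rolled Adadelta recurrence for one scalar parameter."""
    theta, eg2, edx2 = theta0, 0.0, 0.0
    trajectory = []
    for g in grads:
        eg2 = rho * eg2 + (1 - rho) * g * g
        dx = -math.sqrt(edx2 + eps) / math.sqrt(eg2 + eps) * g
        edx2 = rho * edx2 + (1 - rho) * dx * dx
        theta += eta * dx
        trajectory.append(theta)
    return trajectory
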