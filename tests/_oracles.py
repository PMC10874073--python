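"""Independent brute-force reference implementations used by the tests.

Pure-Python loops, written directly from the defining formulas; they share
no code with the package's vectorized/compiled paths.
"""

import math

import numpy as np


def softmax_adjacency_oracle(V, w, slope=0.01):
    n = len(V)
    e = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            s = sum(w[k] * abs(V[i][k] - V[j][k]) for k in range(len(w)))
            e[i, j] = s if s > 0 else slope * s
    A = np.zeros((n, n))
    for i in range(n):
        ex = [math.exp(e[i, j] - max(e[i])) for j in range(n)]
        A[i] = [v / sum(ex) for v in ex]
    return A


def loss_oracle(A, V, eta, gamma):
    n = len(V)
    total, frob = 0.0, 0.0
    for i in range(n):
        for j in range(n):
            d2 = sum((V[i][k] - V[j][k]) ** 2 for k in range(len(V[0])))
            total += math.exp(A[i][j] + eta * d2)
            frob += A[i][j] ** 2
    return total / n**2 + gamma * frob


def hidden_oracle(V, W_vih, W_vjh, b):
    n, d = len(V), len(V[0])
    H = np.zeros((n, n, d))
    for i in range(n):
        for j in range(n):
            for out in range(d):
                s = b[out]
                for k in range(d):
                    s += W_vih[out][k] * V[i][k] + W_vjh[out][k] * V[j][k]
                H[i, j, out] = max(0.0, s)
    return H


def conv_oracle(A, H, W):
    n, _, d = H.shape
    out = np.zeros((n, d))
    for i in range(n):
        agg = np.zeros(d)
        for j in range(n):
            for k in range(d):
                agg[k] += A[i][j] * H[i, j, k]
        for out_k in range(d):
            s = sum(agg[k] * W[k][out_k] for k in range(d))
            out[i, out_k] = max(0.0, s)
    return out


def mse_oracle(y, p):
    return sum((a - b) ** 2 for a, b in zip(y, p)) / len(y)


def ci_oracle(y, p):
    num, z = 0.0, 0
    for x in range(len(y)):
        for j in range(len(y)):
            if y[x] > y[j]:
                z += 1
                if p[x] > p[j]:
                    num += 1.0
                elif p[x] == p[j]:
                    num += 0.5
    return num / z


def total_loss_oracle(pred, y, gl, lam):
    return mse_oracle(y, pred) + lam * gl
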