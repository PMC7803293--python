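"""Independent loop-based reference implementations used as test oracles.

These deliberately avoid the package's vectorized/autodiff code paths:
everything is explicit Python loops over small arrays, so a bug in the
implementation cannot hide in its own oracle.
"""

import math

import numpy as np


def sigmoid(z):
    return 1.0 / (1.0 + math.exp(-z))


def conv1x1(weights, bias, vec):
    """1x1 convolution on a channel vector: out[o] = sum_c w[o,c]*v[c] + b[o]."""
    out_ch = weights.shape[0]
    return [sum(weights[o, c, 0, 0] * vec[c] for c in range(len(vec))) + bias[o]
            for o in range(out_ch)]


def global_average_pool_loop(X):
    """(H, W, C) -> list of per-channel means via explicit double loop."""
    H, W, C = X.shape
    out = []
    for c in range(C):
        s = 0.0
        for h in range(H):
            for w in range(W):
                s += X[h, w, c]
        out.append(s / (H * W))
    return out


def feature_reweight_loop(X, se):
    """Squeeze-excite recalibration of an (H, W, C) map, stepwise."""
    H, W, C = X.shape
    r = global_average_pool_loop(X)
    hidden = [max(0.0, v) for v in conv1x1(se.w1.data, se.b1.data, r)]
    gate = [sigmoid(v) for v in conv1x1(se.w2.data, se.b2.data, hidden)]
    U = np.empty_like(X)
    for h in range(H):
        for w in range(W):
            for c in range(C):
                U[h, w, c] = X[h, w, c] * gate[c]
    return U


def transfer_layer_loop(X, layer, gate_mode="combined"):
    """Two-stage gated skip connection of an (H, W, C) map, stepwise."""
    H, W, C = X.shape
    xmax = [max(X[h, w, c] for h in range(H) for w in range(W)) for c in range(C)]
    xmean = [sum(X[h, w, c] for h in range(H) for w in range(W)) / (H * W)
             for c in range(C)]
    t1 = conv1x1(layer.cmax_w.data, layer.cmax_b.data, xmax)
    t2 = conv1x1(layer.cmean_w.data, layer.cmean_b.data, xmean)
    alpha = [sigmoid(t1[c] + t2[c]) for c in range(C)]
    ax = np.empty_like(X)
    for h in range(H):
        for w in range(W):
            for c in range(C):
                ax[h, w, c] = alpha[c] * X[h, w, c]
    wsm = layer.smax_w.data[0, 0, 0, 0]
    bsm = layer.smax_b.data[0]
    wme = layer.smean_w.data[0, 0, 0, 0]
    bme = layer.smean_b.data[0]
    out_ch = layer.out_w.data.shape[0]
    Y = np.empty((H, W, out_ch))
    for h in range(H):
        for w in range(W):
            cmax = max(ax[h, w, c] for c in range(C))
            cmean = sum(ax[h, w, c] for c in range(C)) / C
            beta = sigmoid(wsm * cmax + bsm + wme * cmean + bme)
            base = ax[h, w] if gate_mode == "combined" else X[h, w]
            y = [base[c] * beta for c in range(C)]
            for o in range(out_ch):
                Y[h, w, o] = sum(layer.out_w.data[o, c, 0, 0] * y[c]
                                 for c in range(C)) + layer.out_b.data[o]
    return Y


def gradient_magnitude_loop(F):
    """Forward-difference gradient magnitude with replicate border."""
    H, W = F.shape
    out = np.empty_like(F)
    for y in range(H):
        for x in range(W):
            fxp = F[y, min(x + 1, W - 1)]
            fyp = F[min(y + 1, H - 1), x]
            out[y, x] = math.sqrt((F[y, x] - fxp) ** 2 + (F[y, x] - fyp) ** 2)
    return out


def laplacian_loop(F):
    """4-neighbour Laplacian with replicate border."""
    H, W = F.shape
    out = np.empty_like(F)
    for y in range(H):
        for x in range(W):
            out[y, x] = (F[y, min(x + 1, W - 1)] + F[y, max(x - 1, 0)]
                         + F[min(y + 1, H - 1), x] + F[max(y - 1, 0), x]
                         - 4.0 * F[y, x])
    return out


def confusion_loop(pred, truth, fov=None):
    """Per-pixel tally of (tp, tn, fp, fn) inside the FOV."""
    H, W = pred.shape
    tp = tn = fp = fn = 0
    for y in range(H):
        for x in range(W):
            if fov is not None and not fov[y, x]:
                continue
            p, t = bool(pred[y, x]), bool(truth[y, x])
            if p and t:
                tp += 1
            elif p and not t:
                fp += 1
            elif not p and t:
                fn += 1
            else:
                tn += 1
    return tp, tn, fp, fn


def auc_rank_oracle(prob, truth):
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(equal)."""
    pos = [p for p, t in zip(prob, truth) if t]
    neg = [p for p, t in zip(prob, truth) if not t]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def dilated_kernel_dense(w, rate):
    """Zero-insert a (k, k) kernel to its effective dense (K, K) form."""
    k = w.shape[0]
    K = k + (k - 1) * (rate - 1)
    dense = np.zeros((K, K))
    dense[::rate, ::rate] = w
    return dense
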