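"""Independent straight-line reference for the forward pass and importance score.

Pure-Python loops over lists — deliberately free of numpy vectorization and
of any code shared with the package — used as the oracle for the
implementation's forward computation and score arithmetic.
"""

import math


def _matvec(W, x):
    return [sum(W[r][c] * x[c] for c in range(len(x))) for r in range(len(W))]


def _relu_vec(v):
    return [max(0.0, z) for z in v]


def _softmax_list(es):
    mx = max(es)
    exps = [math.exp(e - mx) for e in es]
    s = sum(exps)
    return [e / s for e in exps]


def oracle_forward(X, cell_types, enc_W, enc_b, att_w, att_b, type_v, type_b,
                   head_w, head_b, mode="ha"):
    """Forward pass for one bag; returns (positive-class prob, logit, per-type logits).

    ``X`` is a list of feature lists, ``enc_W``/``enc_b`` lists of layer
    weights; binary sigmoid head only.  ``mode`` is "cta" or "ha".
    """
    # encoder
    H = []
    for x in X:
        h = list(x)
        for W, b in zip(enc_W, enc_b):
            h = _relu_vec([z + bb for z, bb in zip(_matvec(W, h), b)])
        H.append(h)

    present = sorted(set(cell_types))
    type_reprs = []
    for t in present:
        idx = [j for j, ct in enumerate(cell_types) if ct == t]
        if mode == "ha":
            es = [sum(w * hh for w, hh in zip(att_w, H[j])) + att_b for j in idx]
            alphas = _softmax_list(es)
        else:
            alphas = [1.0 / len(idx)] * len(idx)
        d = len(H[0])
        h_t = [sum(a * H[j][k] for a, j in zip(alphas, idx)) for k in range(d)]
        type_reprs.append(h_t)

    fs = [sum(v * hh for v, hh in zip(type_v, h_t)) + type_b for h_t in type_reprs]
    betas = _softmax_list(fs)
    d = len(type_reprs[0])
    h = [sum(b * h_t[k] for b, h_t in zip(betas, type_reprs)) for k in range(d)]

    logit = sum(w * hh for w, hh in zip(head_w, h)) + head_b
    prob = 1.0 / (1.0 + math.exp(-logit))
    per_type = {t: b * sum(w * hh for w, hh in zip(head_w, h_t))
                for t, b, h_t in zip(present, betas, type_reprs)}
    return prob, logit, per_type


def oracle_importance(type_logits_per_sample, labels, n_types):
    """kappa_i from per-sample {type: logit} dicts; absent types count as 0."""
    pos = [s for s, y in zip(type_logits_per_sample, labels) if y == 1]
    neg = [s for s, y in zip(type_logits_per_sample, labels) if y == 0]
    kappa = []
    for i in range(n_types):
        mean_pos = sum(s.get(i, 0.0) for s in pos) / len(pos)
        mean_neg = sum(s.get(i, 0.0) for s in neg) / len(neg)
        kappa.append(mean_pos - mean_neg)
    return kappa
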