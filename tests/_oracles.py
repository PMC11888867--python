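"""Independent brute-force oracles used by the test suite.

Everything here is written in the most naive style possible (plain loops,
no vectorization, no reuse of package code) so it can serve as a second,
independent route to the same quantities.
"""

import math

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

CODONS = {
    "A": 4, "C": 2, "D": 2, "E": 2, "F": 2, "G": 4, "H": 2, "I": 3,
    "K": 2, "L": 6, "M": 1, "N": 2, "P": 4, "Q": 2, "R": 6, "S": 6,
    "T": 4, "V": 4, "W": 1, "Y": 2,
}


def aac_oracle(seq):
    seq = [c for c in seq if c in RESIDUES]
    return [sum(1 for c in seq if c == r) / len(seq) for r in RESIDUES]


def dde_oracle(seq):
    pairs = []
    for i in range(len(seq) - 1):
        if seq[i] in RESIDUES and seq[i + 1] in RESIDUES:
            pairs.append(seq[i] + seq[i + 1])
    n = len(pairs)
    out = []
    for a in RESIDUES:
        for b in RESIDUES:
            dc = sum(1 for p in pairs if p == a + b) / n
            tm = (CODONS[a] / 61) * (CODONS[b] / 61)
            tv = tm * (1 - tm) / n
            out.append((dc - tm) / math.sqrt(tv))
    return out


def ctdc_oracle(seq, groups):
    seq = [c for c in seq if c in RESIDUES]
    out = []
    for attr in groups:
        for members in groups[attr]:
            out.append(sum(1 for c in seq if c in members) / len(seq))
    return out


def ctdd_oracle(seq, groups):
    seq = [c for c in seq if c in RESIDUES]
    n = len(seq)
    out = []
    for attr in groups:
        for members in groups[attr]:
            positions = [i + 1 for i, c in enumerate(seq) if c in members]
            cnt = len(positions)
            for p in (0, 25, 50, 75, 100):
                if cnt == 0:
                    out.append(0.0)
                    continue
                if p == 0:
                    k = 1
                else:
                    k = max(1, math.floor(p / 100 * cnt))
                out.append(100.0 * positions[k - 1] / n)
    return out


def apaac_oracle(seq, lam, weight, h1_scale, h2_scale):
    """Brute-force double loop over lags; scales already standardized."""
    seq = [c for c in seq if c in RESIDUES]
    n = len(seq)
    thetas = []
    for j in range(1, lam + 1):
        s1 = 0.0
        s2 = 0.0
        for i in range(n - j):
            s1 += h1_scale[seq[i]] * h1_scale[seq[i + j]]
            s2 += h2_scale[seq[i]] * h2_scale[seq[i + j]]
        thetas.append(s1 / (n - j))
        thetas.append(s2 / (n - j))
    denom = 1.0 + weight * sum(thetas)
    out = [sum(1 for c in seq if c == r) / n / denom for r in RESIDUES]
    out += [weight * t / denom for t in thetas]
    return out


def auroc_oracle(y, scores):
    """Fraction of (positive, negative) pairs correctly ordered, +1/2 ties."""
    pos = [s for s, t in zip(scores, y) if t == 1]
    neg = [s for s, t in zip(scores, y) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def metrics_oracle(tp, fp, fn, tn):
    """(balanced accuracy, MCC, F1) straight from the definitions."""
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    ba = (sens + spec) / 2
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return ba, mcc, f1


def softmax_attention_oracle(H, W_k, b_k, u_s, mask):
    """Direct-formula attention pooling on plain Python lists."""
    n = len(H)
    scores = []
    for k in range(n):
        u = [math.tanh(sum(W_k[i][j] * H[k][j] for j in range(len(H[k])))
                       + b_k[i]) for i in range(len(b_k))]
        scores.append(sum(ui * si for ui, si in zip(u, u_s)))
    exps = [math.exp(s) if m else 0.0 for s, m in zip(scores, mask)]
    z = sum(exps)
    alpha = [e / z for e in exps]
    V = [sum(alpha[k] * H[k][j] for k in range(n)) for j in range(len(H[0]))]
    return V, alpha
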