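"""Independent nested-loop reference implementations of the routing
algorithms, written directly from their defining formulas with explicit
Python loops (no shared code with the library implementations)."""

import numpy as np


def reference_squash(s: np.ndarray, variant: str) -> np.ndarray:
    norm = np.sqrt((s ** 2).sum() + 1e-9)
    if variant == "exp":
        scale = (1.0 - np.exp(-norm)) / norm
    else:
        scale = norm / (1.0 + norm ** 2)
    return scale * s


def reference_attention_routing(u, W, B, variant="exp"):
    """Single-pass self-attention routing, one scalar at a time.

    u: (batch, n_l, d_l); W: (n_l, n_next, d_l, d_next); B: (n_l, n_next).
    """
    batch, n_l, d_l = u.shape
    _, n_next, _, d_next = W.shape
    out = np.zeros((batch, n_next, d_next))
    for b in range(batch):
        u_hat = np.zeros((n_l, n_next, d_next))
        for i in range(n_l):
            for j in range(n_next):
                for e in range(d_next):
                    u_hat[i, j, e] = sum(u[b, i, d] * W[i, j, d, e]
                                         for d in range(d_l))
        # pairwise vote agreement, scaled
        a = np.zeros((n_l, n_l, n_next))
        for i in range(n_l):
            for m in range(n_l):
                for j in range(n_next):
                    a[i, m, j] = sum(u_hat[i, j, e] * u_hat[m, j, e]
                                     for e in range(d_next)) / np.sqrt(d_next)
        # couplings: softmax over output capsules of summed agreement
        c = np.zeros((n_l, n_next))
        for i in range(n_l):
            logits = np.array([sum(a[i, m, j] for m in range(n_l))
                               for j in range(n_next)])
            ex = np.exp(logits - logits.max())
            c[i] = ex / ex.sum()
        # weighted vote sum with additive bias, then squash
        for j in range(n_next):
            s = np.zeros(d_next)
            for i in range(n_l):
                s += u_hat[i, j] * (c[i, j] + B[i, j])
            out[b, j] = reference_squash(s, variant)
    return out


def reference_dynamic_routing(u, W, iterations, variant="exp"):
    """Routing-by-agreement with explicit loops."""
    batch, n_l, d_l = u.shape
    _, n_next, _, d_next = W.shape
    out = np.zeros((batch, n_next, d_next))
    for b in range(batch):
        u_hat = np.zeros((n_l, n_next, d_next))
        for i in range(n_l):
            for j in range(n_next):
                u_hat[i, j] = u[b, i] @ W[i, j]
        logits = np.zeros((n_l, n_next))
        v = np.zeros((n_next, d_next))
        for _ in range(iterations):
            c = np.zeros((n_l, n_next))
            for i in range(n_l):
                ex = np.exp(logits[i] - logits[i].max())
                c[i] = ex / ex.sum()
            for j in range(n_next):
                s = np.zeros(d_next)
                for i in range(n_l):
                    s += c[i, j] * u_hat[i, j]
                v[j] = reference_squash(s, variant)
            for i in range(n_l):
                for j in range(n_next):
                    logits[i, j] += float(u_hat[i, j] @ v[j])
        out[b] = v
    return out
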