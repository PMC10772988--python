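"""Independent nested-loop reference implementation of the bidirectional
attention equations, used to cross-check the vectorized code path.

Everything here is written with explicit Python loops over indices and
never calls the package's tensor operations.
"""

import math

import numpy as np


def _leaky(x, slope):
    return x if x > 0 else slope * x


def _softmax(v):
    m = max(v)
    e = [math.exp(x - m) for x in v]
    s = sum(e)
    return [x / s for x in e]


def loop_attention_head(V, R, Wv, Wr, U, Wa2r, Wr2a, Wp, Wc, ar2a, aa2r, slope):
    """One attention head via scalar loops.

    V: (Nv, Hc), R: (Nr, Hp); weight orientations match the package
    (features @ W).  Returns (alpha_a2r, alpha_r2a, A, h_c, h_p).
    """
    Nv, Hc = len(V), len(V[0])
    Nr, Hp = len(R), len(R[0])
    d = len(Wv[0])
    C = [[_leaky(sum(V[i][h] * Wv[h][k] for h in range(Hc)), slope)
          for k in range(d)] for i in range(Nv)]
    P = [[_leaky(sum(R[j][h] * Wr[h][k] for h in range(Hp)), slope)
          for k in range(d)] for j in range(Nr)]
    CU = [[sum(C[i][k] * U[k][l] for k in range(d)) for l in range(d)]
          for i in range(Nv)]
    A = [[math.tanh(sum(CU[i][l] * P[j][l] for l in range(d)))
          for j in range(Nr)] for i in range(Nv)]
    tC = [[math.tanh(sum(C[i][k] * Wa2r[k][l] for k in range(d)))
           for l in range(d)] for i in range(Nv)]
    I_p = [[sum(A[i][j] * tC[i][l] for i in range(Nv)) for l in range(d)]
           for j in range(Nr)]
    PWp = [[sum(P[j][k] * Wp[k][l] for k in range(d)) for l in range(d)]
           for j in range(Nr)]
    logit_r = [sum((PWp[j] + I_p[j])[k] * ar2a[k][0] for k in range(2 * d))
               for j in range(Nr)]
    alpha_r2a = _softmax(logit_r)
    tP = [[math.tanh(sum(P[j][k] * Wr2a[k][l] for k in range(d)))
           for l in range(d)] for j in range(Nr)]
    I_c = [[sum(A[i][j] * tP[j][l] for j in range(Nr)) for l in range(d)]
           for i in range(Nv)]
    CWc = [[sum(C[i][k] * Wc[k][l] for k in range(d)) for l in range(d)]
           for i in range(Nv)]
    logit_c = [sum((CWc[i] + I_c[i])[k] * aa2r[k][0] for k in range(2 * d))
               for i in range(Nv)]
    alpha_a2r = _softmax(logit_c)
    h_p = [sum(alpha_r2a[j] * P[j][k] for j in range(Nr)) for k in range(d)]
    h_c = [sum(alpha_a2r[i] * C[i][k] for i in range(Nv)) for k in range(d)]
    return (np.array(alpha_a2r), np.array(alpha_r2a), np.array(A),
            np.array(h_c), np.array(h_p))


def loop_attention_full(V, R, params, config):
    """All heads plus the head-merge projections, via the loop oracle.

    Returns dict with per-head alphas/A and merged h_c_final, h_p_final.
    """
    slope = config.leaky_slope
    a2rs, r2as, As, hcs, hps = [], [], [], [], []
    for h in range(config.attn_heads):
        g = lambda name: params[f"att{h}_{name}"].data
        a2r, r2a, A, hc, hp = loop_attention_head(
            V, R, g("Wv"), g("Wr"), g("U"), g("Wa2r"), g("Wr2a"),
            g("Wp"), g("Wc"), g("ar2a"), g("aa2r"), slope)
        a2rs.append(a2r)
        r2as.append(r2a)
        As.append(A)
        hcs.append(hc)
        hps.append(hp)
    cat_c = np.concatenate(hcs)
    cat_p = np.concatenate(hps)
    h_c_final = cat_c @ params["merge_c_W"].data + params["merge_c_b"].data
    h_p_final = cat_p @ params["merge_p_W"].data + params["merge_p_b"].data
    return {"alpha_a2r": np.stack(a2rs), "alpha_r2a": np.stack(r2as),
            "A": np.stack(As), "h_c_final": h_c_final, "h_p_final": h_p_final}
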