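"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the code paths (and, where possible, the
libraries) they check: the pooled t-test is the textbook formula, BH is
the literal step-up scan, and QC is an exhaustive per-probe rule check.
"""

import math

import numpy as np
from scipy.stats import t as t_dist


def pooled_ttest(a, b):
    """Textbook two-sample equal-variance t-test of b vs a."""
    a, b = list(map(float, a)), list(map(float, b))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    df = na + nb - 2
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    if sp2 == 0:
        if ma == mb:
            return 0.0, df, 1.0
        return math.copysign(math.inf, ma - mb), df, 0.0
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2.0 * t_dist.sf(abs(t), df)
    return t, df, p


def bh_stepup(p_values):
    """Literal Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    # running minimum from the largest rank down
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def bh_reject(p_values, alpha):
    """Index set rejected by the classical BH step-up procedure."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= alpha * i / m:
            k = i
    return set(order[:k].tolist())


def qc_survivors(ds, manifest, preset):
    """Exhaustive per-probe evaluation of the QC rules for one preset."""
    survivors = []
    for pid in ds.beta.index:
        row_detp = ds.detp.loc[pid]
        row_beads = ds.beads.loc[pid]
        ann = manifest.loc[pid]
        fails = {
            "detection_p": (row_detp > 0.01).mean() > 0.0,
            "bead_count": (row_beads < 3).mean() >= 0.05,
            "non_cpg": not ann["is_cpg"],
            "snp": bool(ann["is_snp_associated"]),
            "multimap": bool(ann["is_multimapping"]),
            "xy": ann["chrom"] in ("X", "Y"),
        }
        if preset == "raw":
            checked = []
        elif preset == "partial":
            checked = ["detection_p", "bead_count", "non_cpg"]
        else:
            checked = list(fails)
        if not any(fails[c] for c in checked):
            survivors.append(pid)
    return set(survivors)
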