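"""Per-probe differential methylation and 5-aza rescue-site calling.

For each probe a two-tailed, unpaired, equal-variance (pooled) t-test
compares the beta values of two sample groups; Benjamini-Hochberg step-up
q-values control the FDR across all surviving probes of a contrast.

A *rescue site* is a CpG that gains methylation upon Zeb1 knockdown
(Z0 - C0 > 0, significant) and loses it again under 5-azacytidine
(Z5 - Z0 < 0, significant).  Two operationalizations of "the gain is
undone" are provided: ``sign`` requires only opposite directions of the
two significant deltas, while ``strict`` additionally requires the
magnitudes to match within a relative tolerance,
|delta_Z0Z5 + delta_C0Z0| <= strict_tol * |delta_C0Z0|.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from pemt.dataset import MethylationDataset

RESULT_COLUMNS = (
    "mean_A",
    "mean_B",
    "delta_beta",
    "t_statistic",
    "degrees_of_freedom",
    "p_value",
    "q_value",
    "degenerate",
)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order
    statistics, capped at 1; significance calls at any cutoff match the
    classical step-up rejection rule.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _m_transform(beta: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    b = np.clip(beta, eps, 1 - eps)
    return np.log2(b / (1 - b))


def ttest_probes(
    ds: MethylationDataset,
    group_A: str,
    group_B: str,
    use_m_values: bool = False,
) -> pd.DataFrame:
    """Pooled t-test of group_B vs group_A for every probe.

    Returns a DataFrame indexed by probe id with columns ``mean_A``,
    ``mean_B``, ``delta_beta`` (B - A), ``t_statistic``,
    ``degrees_of_freedom`` (n_A + n_B - 2), ``p_value``, ``q_value``
    (BH across all probes of this contrast) and a ``degenerate`` flag.

    Tests run on beta values by default; ``use_m_values`` applies the
    logit (M-value) transform first while reported means/deltas stay on
    the beta scale.

    Zero pooled variance is handled by convention: equal means give
    t = 0, p = 1; unequal means with zero variance give an infinite
    t and p = 0, flagged as degenerate.
    """
    cols_a = ds.group_columns(group_A)
    cols_b = ds.group_columns(group_B)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need at least 2 replicates per group")
    a = ds.beta[cols_a].to_numpy(dtype=float)
    b = ds.beta[cols_b].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    xa, xb = ((_m_transform(a), _m_transform(b)) if use_m_values else (a, b))
    # t follows the A-vs-B direction (negative when B exceeds A), while
    # delta_beta reports B - A; two-tailed p is direction-free either way
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(xa, xb, axis=1, equal_var=True)
    df = len(cols_a) + len(cols_b) - 2

    # zero pooled variance detected as exact within-group constancy (the
    # computed variance of a constant column can be ~1e-17, not 0)
    pooled_zero = (xa == xa[:, :1]).all(axis=1) & (xb == xb[:, :1]).all(axis=1)
    equal_means = xa[:, 0] == xb[:, 0]
    t = np.where(pooled_zero & equal_means, 0.0, t)
    p = np.where(pooled_zero & equal_means, 1.0, p)
    degenerate = pooled_zero & ~equal_means
    sign = np.sign(xa.mean(axis=1) - xb.mean(axis=1))
    with np.errstate(invalid="ignore"):
        t = np.where(degenerate, sign * np.inf, t)
    p = np.where(degenerate, 0.0, p)

    return pd.DataFrame(
        {
            "mean_A": mean_a,
            "mean_B": mean_b,
            "delta_beta": mean_b - mean_a,
            "t_statistic": t,
            "degrees_of_freedom": df,
            "p_value": p,
            "q_value": bh_fdr(p),
            "degenerate": degenerate,
        },
        index=ds.probe_ids,
    )


def identify_rescue_sites(
    diff_C0Z0: pd.DataFrame,
    diff_Z0Z5: pd.DataFrame,
    fdr: float = 0.05,
    mode: str = "sign",
    strict_tol: float = 0.5,
) -> pd.DataFrame:
    """Sites hypermethylated C0->Z0 and significantly reverted Z0->Z5.

    Both differential tables must be indexed by the same surviving
    probes.  A probe is a rescue site iff q <= fdr in both contrasts,
    delta_C0Z0 > 0 and delta_Z0Z5 < 0; ``strict`` mode additionally
    requires |delta_Z0Z5 + delta_C0Z0| <= strict_tol * |delta_C0Z0|.
    """
    if mode not in ("sign", "strict"):
        raise ValueError(f"unknown rescue mode {mode!r}")
    if not 0.0 < fdr < 1.0:
        raise ValueError("fdr must lie in (0, 1)")
    if not diff_C0Z0.index.equals(diff_Z0Z5.index):
        raise ValueError("differential tables index different probe sets")
    d1 = diff_C0Z0["delta_beta"].to_numpy()
    d2 = diff_Z0Z5["delta_beta"].to_numpy()
    keep = (
        (diff_C0Z0["q_value"].to_numpy() <= fdr)
        & (diff_Z0Z5["q_value"].to_numpy() <= fdr)
        & (d1 > 0)
        & (d2 < 0)
    )
    if mode == "strict":
        keep &= np.abs(d2 + d1) <= strict_tol * np.abs(d1)
    out = pd.DataFrame(
        {
            "delta_C0Z0": d1[keep],
            "delta_Z0Z5": d2[keep],
            "q_C0Z0": diff_C0Z0["q_value"].to_numpy()[keep],
            "q_Z0Z5": diff_Z0Z5["q_value"].to_numpy()[keep],
            "mode": mode,
        },
        index=diff_C0Z0.index[keep],
    )
    out.index.name = "probe_id"
    return out


def annotate_genes(sites: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Collapse rescue sites to a deduplicated gene table.

    Every site is mapped to its manifest gene symbol (possibly empty —
    intergenic sites are retained under the empty symbol, never dropped).
    Returns one row per gene with the site count and the site ids.
    """
    missing = sites.index.difference(manifest.index)
    if len(missing) > 0:
        raise KeyError(f"probe {missing[0]!r} missing from manifest")
    genes = manifest.loc[sites.index, "gene"].fillna("")
    table = (
        pd.DataFrame({"gene": genes, "probe_id": sites.index})
        .groupby("gene", sort=True)
        .agg(n_sites=("probe_id", "size"), sites=("probe_id", ";".join))
        .reset_index()
    )
    return table
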