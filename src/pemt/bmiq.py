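"""Beta-mixture quantile (BMIQ) normalization of type II probes.

Infinium type II probes report beta values compressed toward 0.5 relative
to type I probes measured on the same sample.  BMIQ removes this design
bias sample by sample:

1. fit a three-state beta mixture (unmethylated U, hemimethylated H,
   methylated M) to the type I betas and, separately, to the type II
   betas of the sample;
2. map each type II U-state beta through its own U-component CDF and the
   inverse CDF of the type I U component (and analogously for the
   M state, using upper-tail probabilities for numerical stability near
   1);
3. map the H-state betas with a conformal shift-and-dilation onto the
   interval between the transformed U maximum and M minimum, preserving
   the gaps observed on the input scale.

Each map is monotone within its state, type I probes are untouched, and
outputs are clipped to [0, 1].

The EM fit maximises the exact mixture likelihood: the M-step optimises
each component's (a, b) against weighted sufficient statistics
(sum w*log x, sum w*log(1-x)), so the log-likelihood trace is
non-decreasing up to optimiser tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from pemt.dataset import MethylationDataset

EPS = 1e-6
STATE_NAMES = ("U", "H", "M")
_LOG_AB_BOUNDS = (np.log(1e-2), np.log(1e4))


@dataclass
class BetaMixtureFit:
    """Fitted three-state beta mixture for one probe-design distribution.

    ``weights[k]``, ``shapes[k] = (a_k, b_k)`` parametrise component k;
    components are ordered so that mean(U) < mean(H) < mean(M).
    ``states`` holds the max-posterior state index (0=U, 1=H, 2=M) per
    input value, ties broken toward H.
    """

    weights: np.ndarray
    shapes: np.ndarray
    states: np.ndarray
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def means(self) -> np.ndarray:
        a, b = self.shapes[:, 0], self.shapes[:, 1]
        return a / (a + b)

    def component(self, state: str) -> tuple[float, float]:
        k = STATE_NAMES.index(state)
        return float(self.shapes[k, 0]), float(self.shapes[k, 1])


def _clip_betas(betas: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(betas, dtype=float), EPS, 1.0 - EPS)


def _log_beta_pdf(x: np.ndarray, a: float, b: float) -> np.ndarray:
    lx, l1x = np.log(x), np.log1p(-x)
    return (a - 1.0) * lx + (b - 1.0) * l1x - special.betaln(a, b)


def _moment_estimate(x: np.ndarray) -> tuple[float, float]:
    m, v = float(x.mean()), float(x.var())
    v = max(v, 1e-6)
    common = m * (1.0 - m) / v - 1.0
    if common <= 0:
        common = 1.0
    lo, hi = np.exp(_LOG_AB_BOUNDS[0]), np.exp(_LOG_AB_BOUNDS[1])
    return (
        float(np.clip(m * common, lo, hi)),
        float(np.clip((1.0 - m) * common, lo, hi)),
    )


def _mstep_component(
    s_logx: float, s_log1x: float, w_sum: float, a0: float, b0: float
) -> tuple[float, float]:
    """Maximise the weighted beta log-likelihood via its sufficient stats."""

    def negll(theta: np.ndarray) -> tuple[float, np.ndarray]:
        a, b = np.exp(theta)
        val = -((a - 1.0) * s_logx + (b - 1.0) * s_log1x
                - w_sum * special.betaln(a, b))
        dig = special.digamma(a + b)
        ga = -(s_logx - w_sum * (special.digamma(a) - dig)) * a
        gb = -(s_log1x - w_sum * (special.digamma(b) - dig)) * b
        return float(val), np.array([ga, gb])

    x0 = np.log([a0, b0])
    res = optimize.minimize(
        negll, x0, jac=True, method="L-BFGS-B",
        bounds=[_LOG_AB_BOUNDS, _LOG_AB_BOUNDS],
    )
    # keep old parameters if the optimiser failed to improve
    if not np.isfinite(res.fun) or res.fun > negll(x0)[0] + 1e-9:
        return a0, b0
    a, b = np.exp(res.x)
    return float(a), float(b)


def fit_beta_mixture(
    betas,
    n_states: int = 3,
    tol: float = 1e-4,
    max_iter: int = 100,
    seed: int | None = None,
) -> BetaMixtureFit:
    """EM fit of an ``n_states``-component beta mixture to beta values.

    Initialisation is deterministic: values are split by thresholds
    (below 0.25 -> U, 0.25-0.75 -> H, above 0.75 -> M for three states)
    and each component starts at its method-of-moments estimate, so the
    fit is reproducible regardless of ``seed`` (accepted for interface
    symmetry with the stochastic generators).
    """
    x = _clip_betas(betas)
    if x.ndim != 1 or x.size < 100:
        raise ValueError("need a 1-D vector of at least 100 beta values")
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate input: all beta values identical")
    if n_states < 1:
        raise ValueError("n_states must be >= 1")

    edges = np.linspace(0.0, 1.0, n_states + 1)
    if n_states == 3:
        edges = np.array([0.0, 0.25, 0.75, 1.0])
    shapes = np.empty((n_states, 2))
    weights = np.empty(n_states)
    for k in range(n_states):
        sel = (x >= edges[k]) & (x < edges[k + 1] if k < n_states - 1 else x <= 1.0)
        xs = x[sel]
        if xs.size < 2 or np.ptp(xs) < 1e-9:
            shapes[k] = (2.0, 2.0)
            weights[k] = max(xs.size, 1) / x.size
        else:
            shapes[k] = _moment_estimate(xs)
            weights[k] = xs.size / x.size
    weights = np.maximum(weights, 1e-8)
    weights /= weights.sum()

    trace: list[float] = []
    converged = False
    resp = None
    for _ in range(max_iter):
        logp = np.stack(
            [
                np.log(weights[k]) + _log_beta_pdf(x, *shapes[k])
                for k in range(n_states)
            ]
        )
        logsum = special.logsumexp(logp, axis=0)
        ll = float(logsum.sum())
        resp = np.exp(logp - logsum)
        if trace and abs(ll - trace[-1]) < tol:
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        # M-step from weighted sufficient statistics
        lx, l1x = np.log(x), np.log1p(-x)
        for k in range(n_states):
            w = resp[k]
            w_sum = float(w.sum())
            if w_sum < 1e-8:  # empty component: freeze its parameters
                continue
            shapes[k] = _mstep_component(
                float(w @ lx), float(w @ l1x), w_sum, *shapes[k]
            )
        weights = np.maximum(resp.sum(axis=1) / x.size, 1e-8)
        weights /= weights.sum()
    if not converged:
        warnings.warn(
            f"beta-mixture EM hit max_iter={max_iter} without converging",
            RuntimeWarning,
            stacklevel=2,
        )

    # final responsibilities under the returned parameters
    logp = np.stack(
        [
            np.log(weights[k]) + _log_beta_pdf(x, *shapes[k])
            for k in range(n_states)
        ]
    )
    resp = np.exp(logp - special.logsumexp(logp, axis=0))

    # relabel so component means increase: U < H < M
    order = np.argsort(shapes[:, 0] / shapes.sum(axis=1))
    shapes, weights, resp = shapes[order], weights[order], resp[order]
    # max-posterior assignment, exact ties broken toward the middle (H) state
    states = resp.argmax(axis=0)
    if n_states == 3:
        states[resp[1] == resp.max(axis=0)] = 1
    return BetaMixtureFit(
        weights=weights,
        shapes=shapes,
        states=states,
        loglik_trace=trace,
        converged=converged,
    )


def _transform_type2(
    x2: np.ndarray, fit1: BetaMixtureFit, fit2: BetaMixtureFit
) -> np.ndarray:
    """Map one sample's type II betas onto the type I scale."""
    out = x2.astype(float).copy()
    u2, h2, m2 = (fit2.states == k for k in range(3))

    a1u, b1u = fit1.component("U")
    a2u, b2u = fit2.component("U")
    if u2.any():
        p = stats.beta.cdf(x2[u2], a2u, b2u)
        out[u2] = stats.beta.ppf(p, a1u, b1u)

    a1m, b1m = fit1.component("M")
    a2m, b2m = fit2.component("M")
    if m2.any():
        p = stats.beta.sf(x2[m2], a2m, b2m)
        out[m2] = stats.beta.isf(p, a1m, b1m)

    if h2.any():
        xh = x2[h2]
        min_h, max_h = float(xh.min()), float(xh.max())
        # anchor the H interval to the transformed U max / M min,
        # preserving the input-scale gaps on either side
        if u2.any() and m2.any():
            n_min = float(out[u2].max()) + (min_h - float(x2[u2].max()))
            n_max = float(out[m2].min()) - (float(x2[m2].min()) - max_h)
        elif u2.any():
            n_min = float(out[u2].max()) + (min_h - float(x2[u2].max()))
            n_max = max_h
        elif m2.any():
            n_min = min_h
            n_max = float(out[m2].min()) - (float(x2[m2].min()) - max_h)
        else:
            n_min, n_max = min_h, max_h
        if n_max <= n_min:  # degenerate gap: fall back to the raw span
            n_min, n_max = min_h, max_h
        if max_h > min_h:
            hf = (n_max - n_min) / (max_h - min_h)
            out[h2] = n_min + hf * (xh - min_h)
        else:
            out[h2] = 0.5 * (n_min + n_max)

    return np.clip(out, 0.0, 1.0)


def bmiq_normalize(
    ds: MethylationDataset,
    manifest: pd.DataFrame,
    per_sample: bool = True,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> MethylationDataset:
    """BMIQ-normalize the type II probes of every sample in a dataset.

    Type I probe rows are returned bit-identical; type II rows are mapped
    onto each sample's type I distribution.  Each sample is processed
    independently (``per_sample`` is accepted for interface clarity; the
    method is inherently per-sample).
    """
    missing = ds.probe_ids.difference(manifest.index)
    if len(missing) > 0:
        raise KeyError(f"probe {missing[0]!r} missing from manifest")
    design = manifest.loc[ds.probe_ids, "design_type"]
    is2 = (design == "II").to_numpy()
    if not is2.any():
        return ds  # nothing to normalize
    beta = ds.beta.copy()
    for sample in beta.columns:
        col = beta[sample].to_numpy(dtype=float)
        x1, x2 = _clip_betas(col[~is2]), _clip_betas(col[is2])
        try:
            fit1 = fit_beta_mixture(x1, tol=tol, max_iter=max_iter)
            fit2 = fit_beta_mixture(x2, tol=tol, max_iter=max_iter)
        except ValueError as exc:
            raise RuntimeError(
                f"beta-mixture fit failed for sample {sample!r}: {exc}"
            ) from exc
        col = col.copy()
        col[is2] = _transform_type2(x2, fit1, fit2)
        beta[sample] = col
    return MethylationDataset(
        beta=beta, detp=ds.detp, beads=ds.beads, samples=ds.samples
    )
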