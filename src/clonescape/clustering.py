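"""Mutation clustering by per-sample CCF profile.

Mutations arising on the same branch of the clone tree share a cancer cell
fraction in every region, so clustering their multi-sample CCF profiles
recovers the branches. Each variant's likelihood is binomial: the observed
alt count at depth D has success probability equal to the model-expected
VAF at the cluster's CCF under that variant's copy model,
p = t·CCF·n/c. A finite mixture of K such profiles is fit by EM with
k-means++ initialization from the point-estimate CCF matrix; K is chosen
by BIC. Clusters of any size are retained — a subclone distinguishable
from its parent by a single mutation can be biologically critical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.cluster import KMeans

from .ccf import binomial_vaf_se
from .datatypes import MutationCluster, MutationCopyModel, ReadCountMatrix
from .errors import InvalidConfigError

_P_EPS = 1e-9


def compute_ccf_matrix(
    counts: ReadCountMatrix,
    purities: dict[str, float],
    copy_models: dict[str, MutationCopyModel],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Point-estimate CCF (and standard error) per variant per sample.

    CCF = g·f and g = v·c/(t·f·n), so CCF = v·c/(t·n) regardless of f.
    Diploid contexts use c = 2. Cells without coverage are NaN, not zero.
    Values may exceed 1 before superclone resolution; negatives cannot
    occur. Variants without a resolved copy model are excluded.
    """
    samples = [s for s in counts.samples if s in purities]
    ids = [v for v in counts.variant_ids if v in copy_models]
    ccf = pd.DataFrame(np.nan, index=ids, columns=samples)
    se = pd.DataFrame(np.nan, index=ids, columns=samples)
    depth = counts.depth
    vaf = counts.vaf
    for vid in ids:
        m = copy_models[vid]
        for s in samples:
            d = int(depth.loc[vid, s])
            if d <= 0:
                continue
            t = purities[s]
            if t <= 0:
                continue
            c = 2.0 if m.segment is None else m.segment.c.get(s, 2.0)
            v = float(vaf.loc[vid, s])
            scale = c / (t * m.n)
            ccf.loc[vid, s] = v * scale
            se.loc[vid, s] = binomial_vaf_se(v, d) * scale
    return ccf, se


def _vaf_coefficients(
    counts: ReadCountMatrix,
    purities: dict[str, float],
    copy_models: dict[str, MutationCopyModel],
    ids: list[str],
    samples: list[str],
) -> np.ndarray:
    """a[i, s] with expected VAF = a[i, s] * CCF for variant i in sample s."""
    A = np.zeros((len(ids), len(samples)))
    for i, vid in enumerate(ids):
        m = copy_models[vid]
        for j, s in enumerate(samples):
            c = 2.0 if m.segment is None else m.segment.c.get(s, 2.0)
            A[i, j] = purities[s] * m.n / c
    return A


def _loglik_matrix(
    alt: np.ndarray, depth: np.ndarray, A: np.ndarray, X: np.ndarray
) -> np.ndarray:
    """Per-variant, per-cluster binomial log-likelihood (K x N)."""
    # p[k, i, s] = clip(A[i,s] * X[k,s])
    P = np.clip(A[None, :, :] * X[:, None, :], _P_EPS, 1 - _P_EPS)
    mask = depth > 0
    ll = alt[None] * np.log(P) + (depth - alt)[None] * np.log1p(-P)
    return np.where(mask[None], ll, 0.0).sum(axis=2)


def _mstep_ccf(
    w: np.ndarray, alt: np.ndarray, depth: np.ndarray, a: np.ndarray
) -> float:
    """Weighted binomial MLE of one cluster CCF in one sample.

    Maximizes sum_i w_i [alt_i log(a_i x) + (depth_i - alt_i) log(1 - a_i x)]
    over x in [0, 1]; the score is strictly decreasing so the root is unique.
    """
    use = (depth > 0) & (w > 1e-12) & (a > 0)
    if not use.any():
        return 0.0
    w, alt, depth, a = w[use], alt[use], depth[use], a[use]
    hi = min(1.0, (1.0 - 1e-6) / a.max())

    def score(x: float) -> float:
        p = a * x
        return float(np.sum(w * (alt / x - (depth - alt) * a / (1.0 - p))))

    if alt.sum() == 0:
        return 0.0
    if score(hi) >= 0:
        return hi
    if score(1e-12) <= 0:
        return 0.0
    return float(brentq(score, 1e-12, hi, xtol=1e-12))


@dataclass
class MixtureFit:
    n_clusters: int
    ccf: np.ndarray  # K x S
    weights: np.ndarray
    assignments: np.ndarray  # per-variant cluster index
    loglik: float
    bic: float
    converged: bool


def _fit_k(
    alt: np.ndarray,
    depth: np.ndarray,
    A: np.ndarray,
    ccf_init: np.ndarray,
    k: int,
    rng_seed: int,
    n_restarts: int,
    max_iter: int,
    rel_tol: float,
) -> MixtureFit:
    n, S = alt.shape
    best: MixtureFit | None = None
    # distinct k-means++ starts only: identical centers yield identical EM runs
    inits: list[np.ndarray] = []
    seen: set[bytes] = set()
    if k == 1:
        inits.append(ccf_init.mean(axis=0, keepdims=True).copy())
    else:
        for r in range(n_restarts):
            km = KMeans(n_clusters=k, n_init=1, random_state=rng_seed + r)
            km.fit(ccf_init)
            X0 = np.clip(km.cluster_centers_, 0.0, 1.0)
            key = np.round(X0[np.lexsort(X0.T[::-1])], 3).tobytes()
            if key not in seen:
                seen.add(key)
                inits.append(X0)
    for X0 in inits:
        X = X0.copy()
        pi = np.full(k, 1.0 / k)
        prev_ll, converged = -np.inf, False
        for _ in range(max_iter):
            ll_mat = _loglik_matrix(alt, depth, A, X) + np.log(pi)[:, None]
            m = ll_mat.max(axis=0)
            lse = m + np.log(np.exp(ll_mat - m).sum(axis=0))
            ll = float(lse.sum())
            W = np.exp(ll_mat - lse)  # K x N responsibilities
            pi = np.clip(W.sum(axis=1) / n, 1e-12, None)
            pi /= pi.sum()
            for kk in range(k):
                for ss in range(S):
                    X[kk, ss] = _mstep_ccf(W[kk], alt[:, ss], depth[:, ss], A[:, ss])
            if np.isfinite(prev_ll) and abs(ll - prev_ll) <= rel_tol * (abs(prev_ll) + 1):
                converged = True
                break
            prev_ll = ll
        ll_mat = _loglik_matrix(alt, depth, A, X) + np.log(pi)[:, None]
        m = ll_mat.max(axis=0)
        ll = float((m + np.log(np.exp(ll_mat - m).sum(axis=0))).sum())
        n_params = k * S + (k - 1)
        bic = -2.0 * ll + n_params * np.log(n)
        fit = MixtureFit(
            n_clusters=k,
            ccf=X.copy(),
            weights=pi.copy(),
            assignments=ll_mat.argmax(axis=0),
            loglik=ll,
            bic=float(bic),
            converged=converged,
        )
        if best is None or fit.loglik > best.loglik:
            best = fit
    assert best is not None
    return best


def cluster_mutations(
    counts: ReadCountMatrix,
    purities: dict[str, float],
    copy_models: dict[str, MutationCopyModel],
    k_range: range | None = None,
    seed: int = 0,
    n_restarts: int = 20,
    max_iter: int = 500,
    rel_tol: float = 1e-8,
) -> tuple[list[MutationCluster], MixtureFit]:
    """Cluster variants by multi-sample CCF profile; K chosen by BIC.

    Deterministic given ``seed``. Cluster ids are canonicalized by
    descending mean CCF so labels are stable across runs. Variants with
    incomplete CCF rows (uncovered samples) contribute likelihood only
    over their covered samples and are assigned by maximum likelihood.
    """
    samples = [s for s in counts.samples if s in purities]
    ids = [v for v in counts.variant_ids if v in copy_models]
    if not ids:
        raise InvalidConfigError("no variants with resolved copy models")
    if k_range is None:
        k_range = range(1, min(15, len(ids)) + 1)
    if len(k_range) == 0:
        raise InvalidConfigError("empty k_range")

    alt = counts.alt.loc[ids, samples].to_numpy(dtype=float)
    depth = counts.depth.loc[ids, samples].to_numpy(dtype=float)
    A = _vaf_coefficients(counts, purities, copy_models, ids, samples)
    ccf_pt, _ = compute_ccf_matrix(counts, purities, copy_models)
    ccf_init = ccf_pt.loc[ids, samples].to_numpy(dtype=float)
    row_mean = np.nanmean(np.where(np.isnan(ccf_init), np.nan, ccf_init), axis=1)
    row_mean = np.where(np.isnan(row_mean), 0.0, row_mean)
    inds = np.where(np.isnan(ccf_init))
    ccf_init[inds] = row_mean[inds[0]]
    ccf_init = np.clip(ccf_init, 0.0, 1.2)

    best: MixtureFit | None = None
    for k in k_range:
        if k > len(ids):
            break
        fit = _fit_k(
            alt, depth, A, ccf_init, k, seed, n_restarts, max_iter, rel_tol
        )
        if best is None or fit.bic < best.bic:
            best = fit
    assert best is not None

    order = np.argsort(-best.ccf.mean(axis=1), kind="stable")
    rank = {int(old): i for i, old in enumerate(order)}
    clusters: list[MutationCluster] = []
    for i, old in enumerate(order):
        members = [ids[j] for j in range(len(ids)) if best.assignments[j] == old]
        if not members:
            continue
        ccf_d = {s: float(best.ccf[old, jj]) for jj, s in enumerate(samples)}
        dsum = depth[[ids.index(m) for m in members]].sum(axis=0)
        se_d = {
            s: float(np.sqrt(max(ccf_d[s] * (1 - ccf_d[s]), 0.0) / d)) if d > 0 else np.nan
            for s, d in zip(samples, dsum)
        }
        clusters.append(
            MutationCluster(
                cluster_id=f"C{len(clusters) + 1}",
                members=members,
                ccf=ccf_d,
                ccf_se=se_d,
            )
        )
    # re-index assignments to canonical order for the fit report
    best.assignments = np.array([rank[int(a)] for a in best.assignments])
    best.ccf = best.ccf[order]
    best.weights = best.weights[order]
    return clusters, best
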