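"""Residual tumor detection in histologically normal samples.

A two-stage test mirrors how tumor-in-normal contamination is assessed
from deep sequencing: first the founder mutation's alt count is compared
to the site's background error rate with a one-sided exact binomial test —
only if the founder is present can any tumor cell be present — then each
mutation cluster's member sites are tested the same way, combined by
Fisher's method, and corrected across clusters by Benjamini–Hochberg. The
tumor fraction of a contaminated normal comes from the same founder-
clonality inversion used for purity (fraction = 2v at a diploid founder,
on the few-percent scale typical of invaded brain tissue), and cluster
CCFs *within* the contaminating population are obtained by treating that
fraction as the sample's purity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ccf import binomial_vaf_se
from .datatypes import MutationCluster, ReadCountMatrix
from .errors import ImpossibleModelError

DEFAULT_ERROR_FLOOR = 1e-6


@dataclass
class ErrorModel:
    """Per-site sequencing error rates from a panel of normals."""

    rates: dict[str, float]
    floor: float = DEFAULT_ERROR_FLOOR
    source: str = "panel_of_normals"

    def rate(self, variant_id: str) -> float:
        return max(self.rates.get(variant_id, self.floor), self.floor)


def build_error_model(
    normal_counts: ReadCountMatrix,
    floor: float = DEFAULT_ERROR_FLOOR,
    exclude: str | None = None,
) -> ErrorModel:
    """Per-site error rates pooled across a panel of normal samples.

    rate = (sum alt + 0.5) / (sum depth + 1) across the panel, excluding
    the tested sample when given (leave-one-out), floored globally. Sites
    with systematic artifacts get honestly high rates, protecting against
    false contamination calls there. An empty panel falls back to a fixed
    rate at the floor.
    """
    samples = [s for s in normal_counts.samples if s != exclude]
    if not samples:
        return ErrorModel(rates={}, floor=floor, source="fixed")
    alt = normal_counts.alt[samples].sum(axis=1)
    depth = normal_counts.depth[samples].sum(axis=1)
    rates = {
        vid: float((alt[vid] + 0.5) / (depth[vid] + 1.0))
        for vid in normal_counts.variant_ids
    }
    rates = {vid: max(r, floor) for vid, r in rates.items()}
    return ErrorModel(rates=rates, floor=floor)


def estimate_tumor_fraction(
    normal_counts: ReadCountMatrix,
    sample_id: str,
    founder_id: str,
    founder_model: tuple[int, int] = (2, 1),
) -> tuple[float, tuple[float, float], list[str]]:
    """Tumor fraction of a normal sample from the founder mutation's VAF.

    The purity inversion t = 2v/(n − v(M−2)) applied with the normal
    sample's founder VAF; returns (fraction, binomial 95% CI on the
    fraction, warnings). Founder depth below 100 reads attaches a
    low-confidence warning.
    """
    M, n = founder_model
    depth = int(normal_counts.depth.loc[founder_id, sample_id])
    alt = int(normal_counts.alt.loc[founder_id, sample_id])
    warnings = []
    if depth < 100:
        warnings.append(f"founder depth {depth} < 100: low-confidence estimate")
    if depth == 0:
        return 0.0, (0.0, 1.0), warnings

    def invert(v: float) -> float:
        denom = n - v * (M - 2)
        if denom <= 0:
            raise ImpossibleModelError(
                f"VAF {v} impossible under founder model (M={M}, n={n})"
            )
        return float(np.clip(2.0 * v / denom, 0.0, 1.0))

    v = alt / depth
    ci = stats.binomtest(alt, depth).proportion_ci(confidence_level=0.95)
    return invert(v), (invert(ci.low), invert(ci.high)), warnings


@dataclass
class ClusterCall:
    cluster_id: str
    combined_p: float
    q_value: float
    present: bool
    ccf_in_contaminant: dict[str, float] = field(default_factory=dict)


@dataclass
class ContaminationCall:
    sample_id: str
    founder_vaf: float
    founder_p: float
    tumor_fraction: float
    tumor_fraction_ci: tuple[float, float]
    clusters: list[ClusterCall] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": self.sample_id,
                    "tumor_fraction": self.tumor_fraction,
                    "ci_low": self.tumor_fraction_ci[0],
                    "ci_high": self.tumor_fraction_ci[1],
                    "cluster_id": c.cluster_id,
                    "combined_p": c.combined_p,
                    "q_value": c.q_value,
                    "present": c.present,
                }
                for c in self.clusters
            ]
            or [
                {
                    "sample_id": self.sample_id,
                    "tumor_fraction": self.tumor_fraction,
                    "ci_low": self.tumor_fraction_ci[0],
                    "ci_high": self.tumor_fraction_ci[1],
                    "cluster_id": "",
                    "combined_p": np.nan,
                    "q_value": np.nan,
                    "present": False,
                }
            ]
        )


def _site_p(alt: int, depth: int, rate: float) -> float:
    if depth <= 0:
        return 1.0
    return float(stats.binomtest(alt, depth, rate, alternative="greater").pvalue)


def _bh(pvals: list[float]) -> list[float]:
    """Benjamini–Hochberg q-values (monotone)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, p[idx] * m / rank)
        q[idx] = prev
    return q.tolist()


def test_presence(
    normal_counts: ReadCountMatrix,
    sample_id: str,
    founder_id: str,
    clusters: list[MutationCluster],
    error_model: ErrorModel,
    founder_model: tuple[int, int] = (2, 1),
    alpha_founder: float = 0.05,
    q_threshold: float = 0.05,
) -> ContaminationCall:
    """Two-stage tumor-in-normal test for one normal sample.

    Stage 1: one-sided exact binomial test of the founder site's alt count
    against its background error rate; a non-significant founder ends the
    assessment with tumor fraction 0 and no cluster tests. Stage 2: per
    cluster, member-site p-values combined by Fisher's method, then
    Benjamini–Hochberg across all tested clusters; clusters at
    q <= ``q_threshold`` are called present and their CCFs within the
    contaminating population computed with purity = tumor fraction.
    """
    depth = int(normal_counts.depth.loc[founder_id, sample_id])
    alt = int(normal_counts.alt.loc[founder_id, sample_id])
    founder_vaf = alt / depth if depth > 0 else 0.0
    founder_p = _site_p(alt, depth, error_model.rate(founder_id))
    if founder_p > alpha_founder:
        return ContaminationCall(
            sample_id=sample_id,
            founder_vaf=founder_vaf,
            founder_p=founder_p,
            tumor_fraction=0.0,
            tumor_fraction_ci=(0.0, 0.0),
        )

    frac, ci, warnings = estimate_tumor_fraction(
        normal_counts, sample_id, founder_id, founder_model
    )
    calls: list[ClusterCall] = []
    pvals = []
    for cl in clusters:
        site_ps = []
        for vid in cl.members:
            if vid == founder_id or vid not in normal_counts.variant_ids:
                continue
            d = int(normal_counts.depth.loc[vid, sample_id])
            a = int(normal_counts.alt.loc[vid, sample_id])
            site_ps.append(_site_p(a, d, error_model.rate(vid)))
        if not site_ps:
            continue
        combined = float(stats.combine_pvalues(site_ps, method="fisher").pvalue)
        calls.append(ClusterCall(cl.cluster_id, combined, 1.0, False))
        pvals.append(combined)
    if pvals:
        qs = _bh(pvals)
        for call, q in zip(calls, qs):
            call.q_value = float(q)
            call.present = q <= q_threshold
    cluster_by_id = {c.cluster_id: c for c in clusters}
    for call in calls:
        if not call.present or frac <= 0:
            continue
        cl = cluster_by_id[call.cluster_id]
        for vid in cl.members:
            if vid not in normal_counts.variant_ids:
                continue
            d = int(normal_counts.depth.loc[vid, sample_id])
            if d <= 0:
                continue
            v = int(normal_counts.alt.loc[vid, sample_id]) / d
            # diploid context: CCF within contaminant = v * 2 / phi
            call.ccf_in_contaminant[vid] = float(
                np.clip(v * 2.0 / frac, 0.0, 1.5)
            )
    return ContaminationCall(
        sample_id=sample_id,
        founder_vaf=founder_vaf,
        founder_p=founder_p,
        tumor_fraction=frac,
        tumor_fraction_ci=ci,
        clusters=calls,
        warnings=warnings,
    )
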