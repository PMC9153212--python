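"""Purity from the founder mutation; CNV prevalence from allelic imbalance.

Tumor purity t is estimated from the clonality of a designated founder
mutation (in diffuse midline glioma, the histone H3 K27M mutation) which is
present in every cancer cell: with the founder clonal (f = g = 1) the
forward VAF model inverts to t = 2v / (n − v·(M−2)).

Unbalanced copy change shifts the B-allele fraction of germline
heterozygous SNPs away from 0.5. For a CNV of haplotype states (a, b) at
cellular prevalence CP (fraction of all cells bearing it), the unfolded BAF
of a SNP whose B allele rides the major haplotype is

    BAF = (1·(1−CP) + a·CP) / (2·(1−CP) + M·CP),       M = a + b,

so the folded deviation (allelic imbalance) is AI = CP·d / (2c) with
d = a − b and c = 2 + CP·(M−2); inverting, CP = 4·AI / (d − 2·AI·(M−2)).
Balanced events (a = b, e.g. bi-allelic duplication) leave AI = 0 and are
resolved from the composite copy number alone: CP = (c−2)/(M−2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .ccf import FEASIBILITY_TOL, binomial_vaf_se, composite_copy
from .datatypes import CNVSegment, PurityEstimate, ReadCountMatrix, VariantSite
from .errors import ImpossibleModelError, UnresolvableSuperclone

#: Absolute tolerance on cellular-prevalence agreement when testing CNV
#: placements; array-derived CP noise dominates at this scale.
CP_AGREEMENT_TOL = 0.1

#: Haplotype states (major, minor) considered when calibrating a segment:
#: one-copy loss, CN-LOH, single gain, double gain, bi-allelic duplication.
DEFAULT_CANDIDATE_STATES: tuple[tuple[int, int], ...] = (
    (1, 0),
    (2, 0),
    (2, 1),
    (3, 1),
    (2, 2),
)

MAX_TOTAL_COPY = 8


def default_candidate_states(
    focal_major: int | None = None,
) -> list[tuple[int, int]]:
    """Default (a, b) candidates, optionally with one focal amplicon state."""
    states = list(DEFAULT_CANDIDATE_STATES)
    if focal_major is not None:
        a = min(focal_major, MAX_TOTAL_COPY - 1)
        if (a, 1) not in states:
            states.append((a, 1))
    return [s for s in states if sum(s) <= MAX_TOTAL_COPY]


def expected_baf(a: int, b: int, cp: float, b_on_major: bool = True) -> float:
    """Unfolded het-SNP BAF under a CNV of state (a, b) at prevalence cp."""
    M = a + b
    total = 2.0 * (1.0 - cp) + M * cp
    hap = a if b_on_major else b
    return (1.0 * (1.0 - cp) + hap * cp) / total


def expected_ai(a: int, b: int, cp: float) -> float:
    """Folded BAF deviation |BAF − 0.5| implied by state (a, b) at cp."""
    return abs(expected_baf(a, b, cp) - 0.5)


def estimate_purity(
    counts: ReadCountMatrix,
    founder: VariantSite | str,
    founder_model: tuple[int, int] = (2, 1),
    samples: Sequence[str] | None = None,
) -> list[PurityEstimate]:
    """Purity per sample from the clonality of the founder mutation.

    ``founder_model`` is (M, n) at the founder locus: the total copy number
    and the mutant-allele multiplicity there. The founder is assumed clonal
    and truncal (f = g = 1), so v = t·n / (2 + t·(M−2)) and
    t = 2v / (n − v·(M−2)); diploid reduces to t = 2v. Estimates above 1
    are clipped (and flagged); an observed VAF at which the model is
    mathematically impossible raises :class:`ImpossibleModelError`.
    """
    vid = founder if isinstance(founder, str) else founder.variant_id
    M, n = founder_model
    out = []
    for s in samples if samples is not None else counts.samples:
        depth = int(counts.depth.loc[vid, s])
        if depth <= 0:
            raise ImpossibleModelError(f"founder has no coverage in {s}")
        v = float(counts.alt.loc[vid, s]) / depth
        denom = n - v * (M - 2)
        if denom <= 0:
            raise ImpossibleModelError(
                f"VAF {v:.4f} impossible under founder model (M={M}, n={n}) in {s}"
            )
        t = 2.0 * v / denom
        # dt/dv = 2n / (n − v(M−2))^2
        se = abs(2.0 * n / denom**2) * binomial_vaf_se(v, depth)
        clipped = t > 1.0
        out.append(
            PurityEstimate(
                sample_id=s,
                t=float(min(t, 1.0)),
                founder_variant_id=vid,
                founder_m=M,
                founder_n=n,
                standard_error=float(se),
                clipped=clipped,
            )
        )
    return out


@dataclass
class SupercloneReport:
    adjusted_samples: dict[str, float] = field(default_factory=dict)  # sample -> factor


def check_superclone(
    ccf: pd.DataFrame,
    purities: list[PurityEstimate],
    truncal_ids: Iterable[str],
    tol: float = FEASIBILITY_TOL,
    recompute: Callable[[dict[str, float]], pd.DataFrame] | None = None,
) -> tuple[pd.DataFrame, list[PurityEstimate], SupercloneReport]:
    """Detect and repair apparent superclones (truncal CCF > 1).

    A truncal cluster or truncal CNV exceeding CCF 1 in a sample diagnoses
    underestimated purity there. The sample's purity is rescaled upward by
    its maximal truncal CCF and the CCF matrix recomputed (``recompute``
    maps adjusted purities to a fresh matrix; without it the sample's
    column is rescaled linearly, exact in the diploid case). A required
    rescale pushing t above 1 is unresolvable.
    """
    truncal_ids = [c for c in truncal_ids if c in ccf.index]
    ccf = ccf.copy()
    purities = [
        PurityEstimate(**{**p.__dict__}) for p in purities
    ]
    report = SupercloneReport()
    factors: dict[str, float] = {}
    for p in purities:
        s = p.sample_id
        if s not in ccf.columns or not truncal_ids:
            continue
        col = ccf.loc[truncal_ids, s].dropna()
        if col.empty:
            continue
        m = float(col.max())
        if m > 1.0 + tol:
            t_new = p.t * m
            if t_new > 1.0 + 1e-9:
                raise UnresolvableSuperclone(
                    f"sample {s}: purity rescale {p.t:.3f} -> {t_new:.3f} exceeds 1"
                )
            factors[s] = m
            p.t = float(min(t_new, 1.0))
            p.superclone_adjusted = True
            report.adjusted_samples[s] = m
    if factors:
        if recompute is not None:
            ccf = recompute({p.sample_id: p.t for p in purities})
        else:
            for s, m in factors.items():
                ccf[s] = ccf[s] / m
    return ccf, purities, report


def refine_purity(
    ccf: pd.DataFrame,
    purities: list[PurityEstimate],
    truncal_ids: Iterable[str],
    min_mean_ccf: float = 0.75,
) -> list[PurityEstimate]:
    """Re-anchor purity so the median truncal CCF is exactly 1.

    The founder-site estimate carries single-locus binomial noise; truncal
    variants as a group must sit at CCF 1 in every sample, so the median
    CCF of clonal truncal variants (mean CCF above ``min_mean_ccf``,
    excluding subclonal-truncal clusters) measures the residual purity
    error with the combined depth of all truncal sites. Rescaling is
    two-sided — the upward direction is the superclone correction, the
    downward direction repairs an overestimate the same way.
    """
    ids = [v for v in truncal_ids if v in ccf.index]
    ids = [v for v in ids if float(np.nanmean(ccf.loc[v])) >= min_mean_ccf]
    out = [PurityEstimate(**{**p.__dict__}) for p in purities]
    if not ids:
        return out
    for p in out:
        s = p.sample_id
        if s not in ccf.columns:
            continue
        col = ccf.loc[ids, s].dropna()
        if col.empty:
            continue
        factor = float(col.median())
        if factor <= 0:
            continue
        t_new = p.t * factor
        if t_new > 1.0:
            t_new = 1.0
            p.clipped = True
        if factor > 1.0:
            p.superclone_adjusted = True
        p.t = float(t_new)
    return out


@dataclass
class SegmentCPFit:
    """One candidate state's prevalence estimate for a segment sample."""

    major_cn: int
    minor_cn: int
    cp: float
    score: float


def infer_segment_cp(
    ai: float,
    c: float,
    candidates: Sequence[tuple[int, int]] | None = None,
    tol: float = FEASIBILITY_TOL,
) -> tuple[SegmentCPFit | None, list[SegmentCPFit]]:
    """Best (a, b, CP) explaining a segment's allelic imbalance and copy.

    Unbalanced candidates (d = a − b > 0) give CP from the AI inversion
    CP = 4·AI/(d − 2·AI·(M−2)); balanced ones give CP from c alone. Each
    retained candidate is scored by the squared mismatch between observed
    and predicted (c, AI) — AI scaled by 4 so a full one-copy imbalance
    weighs like one copy of c. Candidates whose CP falls outside
    [0, 1] ± ``tol`` are rejected. Returns (best, alternatives); best is
    None when every candidate is rejected (an unresolved segment).
    """
    if candidates is None:
        candidates = default_candidate_states()
    fits: list[SegmentCPFit] = []
    for a, b in candidates:
        M, d = a + b, a - b
        if M == 2 and d == 0:
            continue  # (1,1) is no event
        if d > 0:
            denom = d - 2.0 * ai * (M - 2)
            if denom <= 0:
                continue
            cp = 4.0 * ai / denom
        else:
            if M == 2:
                continue
            cp = (c - 2.0) / (M - 2.0)
        if not (-tol <= cp <= 1.0 + tol):
            continue
        cp = float(min(max(cp, 0.0), 1.0))
        c_pred = 2.0 + cp * (M - 2)
        ai_pred = expected_ai(a, b, cp)
        score = (c - c_pred) ** 2 + (4.0 * (ai - ai_pred)) ** 2
        fits.append(SegmentCPFit(a, b, cp, float(score)))
    fits.sort(key=lambda x: (x.score, abs(x.major_cn + x.minor_cn - 2), x.major_cn))
    if not fits:
        return None, []
    return fits[0], fits[1:]


@dataclass
class TimingFit:
    node_id: str
    residual: float
    feasible: bool
    predicted_cp: dict[str, float]


def fit_cnv_timing(
    segment: CNVSegment,
    candidate_placements: Sequence[str],
    node_ccf: pd.DataFrame,
    purities: dict[str, float],
    tol: float = CP_AGREEMENT_TOL,
) -> tuple[TimingFit | None, list[TimingFit]]:
    """Early-versus-late placement of a CNV on the clone tree.

    A placement at a tree node predicts per-sample prevalence
    CP = t · CCF(node); a truncal (early) placement predicts CP ≈ t
    everywhere. A placement is feasible when predicted and observed CP
    agree within ``tol`` in every sample with an observation; among
    feasible placements the least-squares one wins. Returns
    (best_or_None, all_fits).
    """
    fits: list[TimingFit] = []
    samples = [s for s in segment.cp if s in purities and s in node_ccf.columns]
    for node in candidate_placements:
        pred = {s: purities[s] * float(node_ccf.loc[node, s]) for s in samples}
        resid = sum((pred[s] - segment.cp[s]) ** 2 for s in samples)
        feas = all(abs(pred[s] - segment.cp[s]) <= tol for s in samples)
        fits.append(TimingFit(node, float(resid), feas, pred))
    fits.sort(key=lambda x: x.residual)
    best = next((f for f in fits if f.feasible), None)
    return best, fits


def calibrate_segments(
    observations: pd.DataFrame,
    purities: dict[str, float],
    candidates: Sequence[tuple[int, int]] | None = None,
    tol: float = FEASIBILITY_TOL,
) -> tuple[list[CNVSegment], list[str]]:
    """Calibrate per-sample cellular prevalence for each observed segment.

    ``observations`` has one row per (sample, segment) with columns
    sample_id, chrom, start, end, c, baf_dev, n_snps. One (a, b) state is
    enforced per segment across all samples of a patient: each candidate
    state is scored summed over samples and the best feasible state kept;
    segments with no feasible state are returned as unresolved ids.
    """
    if candidates is None:
        candidates = default_candidate_states()
    segments: list[CNVSegment] = []
    unresolved: list[str] = []
    for (chrom, start, end), grp in observations.groupby(
        ["chrom", "start", "end"], sort=True
    ):
        best_state, best_total, best_cps = None, np.inf, None
        for a, b in candidates:
            total, cps, ok = 0.0, {}, True
            for _, row in grp.iterrows():
                fit, _ = infer_segment_cp(
                    float(row.baf_dev), float(row.c), [(a, b)], tol=tol
                )
                if fit is None:
                    # a sample with no detectable event still fits at CP ~ 0
                    fit0, _ = infer_segment_cp(
                        float(row.baf_dev), float(row.c), [(a, b)], tol=0.5
                    )
                    if fit0 is None or fit0.cp > 0.5:
                        ok = False
                        break
                    fit = fit0
                cps[row.sample_id] = fit.cp
                total += fit.score
            if ok and total < best_total:
                best_state, best_total, best_cps = (a, b), total, cps
        seg_id = f"{chrom}:{start}-{end}"
        if best_state is None:
            unresolved.append(seg_id)
            continue
        a, b = best_state
        seg = CNVSegment(chrom=str(chrom), start=int(start), end=int(end),
                         major_cn=a, minor_cn=b)
        for _, row in grp.iterrows():
            s = row.sample_id
            cp = best_cps[s]
            seg.cp[s] = cp
            seg.ai[s] = float(row.baf_dev)
            seg.c[s] = 2.0 + cp * (seg.M - 2)
            t = purities.get(s, 0.0)
            seg.f[s] = float(min(cp / t, 1.0)) if t > 0 else 0.0
        segments.append(seg)
    return segments, unresolved
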