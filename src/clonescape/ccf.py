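"""Core algebra linking purity, CNV state, multiplicity, VAF and CCF.

A sample mixes diploid normal cells (fraction 1−t) with tumor cells
(fraction t, the purity). A fraction f of tumor cells carries a CNV of
integer state M, so the sample-average ("composite") copy number is

    c = (1−t)·2 + t·[(1−f)·2 + f·M].

A mutation carried at multiplicity n by a fraction g of the CNV-positive
cells has expected variant allele fraction

    v = t·f·g·n / c,    hence    g = v·c / (t·f·n),

and its cancer cell fraction is CCF = g·f. Both f and g must land in [0, 1];
a model that pushes either outside that interval (beyond a noise tolerance)
is infeasible and an alternative multiplicity/timing model must be
considered. Because back-mutation is vanishingly rare at somatic mutation
rates, one mutation belongs to a single lineage, so a correct model must be
feasible in every region where the mutation is detected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import (
    CNVSegment,
    MutationCopyModel,
    ReadCountMatrix,
    Timing,
)
from .errors import (
    DegenerateModelError,
    ModelInfeasibleError,
    NoTumorError,
    UndefinedStateError,
)

#: Default slack on the f, g in [0, 1] feasibility rule. Binomial sampling
#: noise at ~2500X warrants a small tolerance; values inside [-tol, 1+tol]
#: are clamped to [0, 1], values outside are rejected.
FEASIBILITY_TOL = 0.05

#: A variant counts as detected in a sample when it has at least this many
#: alt reads and at least this VAF; below that, presence is ambiguous even
#: at deep coverage.
DETECT_MIN_ALT = 3
DETECT_MIN_VAF = 0.002


def composite_copy(t: float, f: float, M: int) -> float:
    """Sample-average copy number mixing normal and tumor cells."""
    return (1.0 - t) * 2.0 + t * ((1.0 - f) * 2.0 + f * M)


def cnv_ccf(c: float, M: int, t: float, tol: float = FEASIBILITY_TOL) -> float:
    """Fraction f of tumor cells bearing a CNV, from the composite copy.

    Undefined for copy-neutral states (M = 2): CN-LOH leaves c = 2 at any
    prevalence and must be resolved from allelic imbalance instead.
    """
    if M == 2:
        raise UndefinedStateError(
            "M=2 is copy-neutral; prevalence must come from allelic imbalance"
        )
    if t <= 0:
        raise NoTumorError("purity t must be > 0 to define a tumor-cell fraction")
    f = (c - 2.0) / ((M - 2.0) * t)
    if not (-tol <= f <= 1.0 + tol):
        raise ModelInfeasibleError(
            f"CNV CCF f={f:.4g} outside [0,1] (c={c}, M={M}, t={t})", value=f
        )
    return float(min(max(f, 0.0), 1.0))


def expected_vaf(t: float, f: float, g: float, n: int, c: float) -> float:
    """Forward model: VAF of a mutation under (purity, CNV, multiplicity)."""
    if c <= 0:
        raise ValueError(f"composite copy must be positive, got {c}")
    return t * f * g * n / c


def mutation_g(
    v: float,
    c: float,
    t: float,
    f: float,
    n: int,
    tol: float = FEASIBILITY_TOL,
) -> float:
    """Fraction g of CNV-positive tumor cells carrying the mutation.

    Raises :class:`ModelInfeasibleError` when the implied g falls outside
    [0, 1] beyond ``tol``, signalling that an alternative timing or
    multiplicity model must be considered.
    """
    if t * f * n == 0:
        raise DegenerateModelError(f"t*f*n = 0 (t={t}, f={f}, n={n})")
    g = v * c / (t * f * n)
    if not (-tol <= g <= 1.0 + tol):
        raise ModelInfeasibleError(
            f"mutation fraction g={g:.4g} outside [0,1] "
            f"(v={v}, c={c}, t={t}, f={f}, n={n})",
            value=g,
        )
    return float(min(max(g, 0.0), 1.0))


def mutation_ccf(g: float, f: float) -> float:
    """Cancer cell fraction of a mutation: CCF = g·f."""
    return g * f


def is_detected(alt: int, depth: int) -> bool:
    if depth <= 0:
        return False
    return alt >= DETECT_MIN_ALT and alt / depth >= DETECT_MIN_VAF


@dataclass
class RankedCopyModel:
    """A feasible copy model with its fit quality, for reporting."""

    model: MutationCopyModel
    residual: float


def candidate_models(segment: CNVSegment | None) -> list[tuple[Timing, int]]:
    """Timing/multiplicity candidates permitted by a segment's (a, b) states.

    In a diploid context the only candidate is n=1. Inside a CNV a mutation
    may postdate the event (n=1), predate it on the duplicated haplotype
    (n=a), or predate it on the retained haplotype (n=b, only when b >= 1 —
    a mutation on a lost haplotype leaves no mutant copies to observe).
    """
    if segment is None:
        return [(Timing.DIPLOID_CONTEXT, 1)]
    cands = [(Timing.AFTER_CNV, 1)]
    if segment.major_cn >= 1 and segment.major_cn != 1:
        cands.append((Timing.BEFORE_CNV_ON_MAJOR, segment.major_cn))
    if segment.minor_cn >= 1 and segment.minor_cn not in (1, segment.major_cn):
        cands.append((Timing.BEFORE_CNV_ON_MINOR, segment.minor_cn))
    return cands


def enumerate_copy_models(
    variant_id: str,
    counts: ReadCountMatrix,
    purities: dict[str, float],
    segment: CNVSegment | None,
    tol: float = FEASIBILITY_TOL,
) -> list[RankedCopyModel]:
    """All multiplicity models consistent with the data in every region.

    One mutation belongs to a single lineage, so one (timing, n) model must
    hold across samples: a candidate is retained only when the implied g is
    feasible in every sample where the variant is detected. Retained
    candidates are ranked by the summed squared residual between observed
    and model-expected VAF; ties are broken by preferring later timing
    (after the CNV), the more parsimonious default. An empty return means
    no model fits — the variant should be flagged, not dropped.
    """
    alt = counts.alt.loc[variant_id]
    depth = counts.depth.loc[variant_id]
    vafs = counts.vaf.loc[variant_id]
    tumor_samples = [s for s in counts.samples if s in purities]
    detected = [s for s in tumor_samples if is_detected(int(alt[s]), int(depth[s]))]
    if not detected:
        return []

    timing_order = {
        Timing.AFTER_CNV: 0,
        Timing.DIPLOID_CONTEXT: 0,
        Timing.BEFORE_CNV_ON_MINOR: 1,
        Timing.BEFORE_CNV_ON_MAJOR: 2,
    }
    out: list[RankedCopyModel] = []
    for timing, n in candidate_models(segment):
        gs: dict[str, float] = {}
        residual = 0.0
        ok = True
        for s in detected:
            t = purities[s]
            if segment is None:
                f_s, c_s = 1.0, 2.0
            else:
                f_s = segment.f.get(s, 0.0)
                c_s = segment.c.get(s, composite_copy(t, f_s, segment.M))
            v = float(vafs[s])
            try:
                g = mutation_g(v, c_s, t, f_s, n, tol=tol)
            except (ModelInfeasibleError, DegenerateModelError):
                ok = False
                break
            gs[s] = g
            residual += (v - expected_vaf(t, f_s, g, n, c_s)) ** 2
        if not ok:
            continue
        out.append(
            RankedCopyModel(
                model=MutationCopyModel(
                    variant_id=variant_id,
                    segment=segment,
                    timing=timing,
                    n=n,
                    per_sample_g=gs,
                ),
                residual=float(residual),
            )
        )
    # every feasible candidate fits the per-sample VAF exactly (one free g
    # per sample), so residuals differ only through clamping at the [0,1]
    # boundary; residuals within one noise band are ties, broken toward the
    # later (more parsimonious) timing
    band = 1e-3
    out.sort(
        key=lambda r: (
            int(r.residual / band),
            timing_order[r.model.timing],
            r.residual,
        )
    )
    return out


def variant_expected_vaf(
    t: float,
    ccf: float,
    n: int,
    c: float,
) -> float:
    """Expected VAF of a mutation expressed through its CCF.

    Since CCF = g·f, the forward model v = t·f·g·n/c collapses to
    v = t·CCF·n/c, linear in the CCF — the form used by the clustering
    likelihood.
    """
    if c <= 0:
        raise ValueError(f"composite copy must be positive, got {c}")
    return t * ccf * n / c


def binomial_vaf_se(v: float, depth: int) -> float:
    """Binomial standard error of a VAF estimate at the given depth."""
    if depth <= 0:
        return np.nan
    return float(np.sqrt(max(v * (1.0 - v), 0.0) / depth))
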