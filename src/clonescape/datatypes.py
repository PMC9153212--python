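"""Core containers shared by every stage of the pipeline.

The observational substrate is a :class:`ReadCountMatrix` (per-variant,
per-sample ref/alt read counts from deep sequencing); allele-specific
copy-number calls live in :class:`CNVSegment`; inference products are
:class:`MutationCluster`, :class:`CloneTree` and :class:`RegionComposition`.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    FormatError,
    InvalidCompositionError,
    InvalidTreeError,
)


class TissueClass(str, enum.Enum):
    TUMOR = "tumor"
    NORMAL = "normal"


class VariantClass(str, enum.Enum):
    SNV = "SNV"
    INDEL = "indel"


class Timing(str, enum.Enum):
    """Mutation timing relative to an overlapping CNV.

    A mutation acquired *before* a copy change on the duplicated (major)
    haplotype is carried at multiplicity equal to the major copy number;
    before the change on the retained (minor) haplotype, at the minor copy
    number; acquired after the change, or in a diploid context, at 1.
    """

    BEFORE_CNV_ON_MAJOR = "before_cnv_on_major"
    BEFORE_CNV_ON_MINOR = "before_cnv_on_minor"
    AFTER_CNV = "after_cnv"
    DIPLOID_CONTEXT = "diploid_context"


@dataclass(frozen=True)
class VariantSite:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str | None = None
    variant_class: VariantClass = VariantClass.SNV

    def __post_init__(self):
        if self.pos < 1:
            raise FormatError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise FormatError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    patient_id: str
    tissue_class: TissueClass
    region_label: str
    spatial_position: float | None = None  # clock fraction in [0, 1)
    anatomical_site: str | None = None

    def __post_init__(self):
        if self.spatial_position is not None and not (0.0 <= self.spatial_position < 1.0):
            raise FormatError(
                f"spatial_position must lie in [0,1), got {self.spatial_position}"
            )


class ReadCountMatrix:
    """Per-variant, per-sample reference and alternate read counts.

    ``ref`` and ``alt`` are integer DataFrames indexed by variant_id with one
    column per sample. Depth 0 means "not covered": the VAF there is NaN,
    never 0, so absence of coverage is distinguishable from absence of the
    allele.
    """

    def __init__(
        self,
        variants: list[VariantSite],
        ref: pd.DataFrame,
        alt: pd.DataFrame,
        meta: list[SampleMeta] | None = None,
    ):
        ids = [v.variant_id for v in variants]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise ConsistencyError(f"duplicate variant rows: {sorted(dupes)}")
        if list(ref.index) != ids or list(alt.index) != ids:
            raise ConsistencyError("count matrices must be indexed by variant_id")
        if list(ref.columns) != list(alt.columns):
            raise ConsistencyError("ref and alt sample columns differ")
        if (ref.to_numpy() < 0).any() or (alt.to_numpy() < 0).any():
            raise FormatError("negative read counts")
        if meta is not None:
            known = {m.sample_id for m in meta}
            unknown = [s for s in ref.columns if s not in known]
            if unknown:
                raise ConsistencyError(f"samples absent from metadata: {unknown}")
        self.variants = list(variants)
        self.ref = ref.astype(np.int64)
        self.alt = alt.astype(np.int64)
        self.meta = list(meta) if meta is not None else None
        self._by_id = {v.variant_id: v for v in self.variants}

    @property
    def samples(self) -> list[str]:
        return list(self.ref.columns)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.ref.index)

    def variant(self, variant_id: str) -> VariantSite:
        return self._by_id[variant_id]

    @property
    def depth(self) -> pd.DataFrame:
        return self.ref + self.alt

    @property
    def vaf(self) -> pd.DataFrame:
        d = self.depth
        with np.errstate(invalid="ignore", divide="ignore"):
            v = self.alt / d
        return v.where(d > 0)

    def subset_samples(self, samples: list[str]) -> "ReadCountMatrix":
        return ReadCountMatrix(
            self.variants, self.ref[samples], self.alt[samples], self.meta
        )

    def concat_samples(self, other: "ReadCountMatrix") -> "ReadCountMatrix":
        if other.variant_ids != self.variant_ids:
            raise ConsistencyError("variant rows differ between matrices")
        return ReadCountMatrix(
            self.variants,
            pd.concat([self.ref, other.ref], axis=1),
            pd.concat([self.alt, other.alt], axis=1),
            (self.meta or []) + (other.meta or []) or None,
        )


@dataclass
class SegmentObservation:
    """One sample's view of one copy-number segment (SEG-style row)."""

    sample_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    c: float  # composite (sample-average) copy number
    baf_dev: float  # folded het-SNP BAF deviation |BAF - 0.5|
    n_snps: int

    def __post_init__(self):
        if self.start > self.end:
            raise FormatError(
                f"segment start > end: {self.chrom}:{self.start}-{self.end}"
            )
        if not (0.0 <= self.baf_dev <= 0.5 + 1e-9):
            raise FormatError(f"folded BAF deviation outside [0, 0.5]: {self.baf_dev}")


@dataclass
class CNVSegment:
    """Allele-specific copy-number segment with per-sample calibration.

    ``major_cn`` (a) and ``minor_cn`` (b) are the haplotype copy numbers in
    CNV-bearing tumor cells; M = a + b. Per sample the segment carries the
    composite copy number c, the folded BAF deviation (allelic imbalance),
    the cellular prevalence CP (fraction of *all* cells bearing the CNV) and,
    after purity division, the CNV cancer-cell fraction f = CP / t.
    """

    chrom: str
    start: int
    end: int
    major_cn: int
    minor_cn: int
    c: dict[str, float] = field(default_factory=dict)
    ai: dict[str, float] = field(default_factory=dict)
    cp: dict[str, float] = field(default_factory=dict)
    f: dict[str, float] = field(default_factory=dict)
    focal: bool = False

    def __post_init__(self):
        if self.minor_cn < 0 or self.major_cn < self.minor_cn:
            raise FormatError(
                f"require major_cn >= minor_cn >= 0, got ({self.major_cn},{self.minor_cn})"
            )

    @property
    def M(self) -> int:
        return self.major_cn + self.minor_cn

    @property
    def segment_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def overlaps(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class MutationCopyModel:
    """Resolved multiplicity model for one mutation.

    ``n`` is the mutant-allele multiplicity per mutation-bearing cell;
    ``per_sample_g`` the fitted fraction of CNV-positive tumor cells that
    carry the mutation, one value per sample where the variant is covered.
    """

    variant_id: str
    segment: CNVSegment | None
    timing: Timing
    n: int
    per_sample_g: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n < 1:
            raise FormatError(f"multiplicity must be >= 1, got {self.n}")
        if self.segment is not None:
            expect = {
                Timing.BEFORE_CNV_ON_MAJOR: self.segment.major_cn,
                Timing.BEFORE_CNV_ON_MINOR: self.segment.minor_cn,
                Timing.AFTER_CNV: 1,
            }.get(self.timing)
            if expect is not None and self.n != expect:
                raise ConsistencyError(
                    f"timing {self.timing.value} implies n={expect}, got n={self.n}"
                )
        elif self.timing != Timing.DIPLOID_CONTEXT or self.n != 1:
            raise ConsistencyError("variants without a segment are diploid with n=1")
        bad = {s: g for s, g in self.per_sample_g.items() if not (0.0 <= g <= 1.0)}
        if bad:
            raise ConsistencyError(f"stored g outside [0,1]: {bad}")


@dataclass
class MutationCluster:
    """A set of variants sharing a per-sample CCF profile."""

    cluster_id: str
    members: list[str]
    ccf: dict[str, float]
    ccf_se: dict[str, float] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class CloneNode:
    node_id: str
    parent_id: str | None
    cluster_id: str | None = None
    cnv_events: list[str] = field(default_factory=list)
    n_mutations: int = 0


class CloneTree:
    """Rooted tree of clones; the trunk is the founder clone.

    ``ambiguous_attachments`` maps a node to the list of alternative
    parents that were equally consistent with the sum and crossing rules.
    """

    def __init__(self, nodes: list[CloneNode]):
        self.nodes: dict[str, CloneNode] = {n.node_id: n for n in nodes}
        if len(self.nodes) != len(nodes):
            raise InvalidTreeError("duplicate node ids")
        roots = [n.node_id for n in nodes if n.parent_id is None]
        if len(roots) != 1:
            raise InvalidTreeError(f"expected exactly one root, found {roots}")
        self.root = roots[0]
        self.ambiguous_attachments: dict[str, list[str]] = {}
        # reachability + acyclicity
        seen: set[str] = set()
        for nid in self.nodes:
            path: set[str] = set()
            cur: str | None = nid
            while cur is not None:
                if cur in path:
                    raise InvalidTreeError(f"cycle through node {cur}")
                path.add(cur)
                if cur in seen:
                    break
                seen.add(cur)
                if cur not in self.nodes:
                    raise InvalidTreeError(f"parent {cur} is not a node")
                cur = self.nodes[cur].parent_id
        self._children: dict[str, list[str]] = {nid: [] for nid in self.nodes}
        for n in nodes:
            if n.parent_id is not None:
                self._children[n.parent_id].append(n.node_id)

    def children(self, node_id: str) -> list[str]:
        return list(self._children[node_id])

    def descendants(self, node_id: str) -> list[str]:
        out, stack = [], list(self._children[node_id])
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self._children[n])
        return out

    def subtree(self, node_id: str) -> list[str]:
        return [node_id] + self.descendants(node_id)

    def ancestors(self, node_id: str) -> list[str]:
        out = []
        cur = self.nodes[node_id].parent_id
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent_id
        return out

    def depth(self, node_id: str) -> int:
        return len(self.ancestors(node_id))

    def ancestry_matrix(self) -> pd.DataFrame:
        """Boolean matrix A[i, j] = node i is a strict ancestor of node j."""
        ids = sorted(self.nodes)
        A = pd.DataFrame(False, index=ids, columns=ids)
        for j in ids:
            for i in self.ancestors(j):
                A.loc[i, j] = True
        return A

    def to_dict(self) -> dict:
        return {
            "root": self.root,
            "nodes": [
                {
                    "node_id": n.node_id,
                    "parent_id": n.parent_id,
                    "cluster_id": n.cluster_id,
                    "cnv_events": list(n.cnv_events),
                    "n_mutations": n.n_mutations,
                }
                for n in self.nodes.values()
            ],
            "ambiguous_attachments": {
                k: list(v) for k, v in self.ambiguous_attachments.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CloneTree":
        tree = cls(
            [
                CloneNode(
                    node_id=n["node_id"],
                    parent_id=n["parent_id"],
                    cluster_id=n.get("cluster_id"),
                    cnv_events=list(n.get("cnv_events", [])),
                    n_mutations=int(n.get("n_mutations", 0)),
                )
                for n in d["nodes"]
            ]
        )
        tree.ambiguous_attachments = {
            k: list(v) for k, v in d.get("ambiguous_attachments", {}).items()
        }
        return tree

    def to_newick(self) -> str:
        def render(nid: str) -> str:
            kids = self._children[nid]
            label = self.nodes[nid].node_id
            length = self.nodes[nid].n_mutations
            if kids:
                inner = ",".join(render(k) for k in sorted(kids))
                return f"({inner}){label}:{length}"
            return f"{label}:{length}"

        kids = self._children[self.root]
        root_label = self.nodes[self.root].node_id
        root_len = self.nodes[self.root].n_mutations
        if kids:
            inner = ",".join(render(k) for k in sorted(kids))
            return f"(({inner}){root_label}:{root_len});"
        return f"({root_label}:{root_len});"

    def __eq__(self, other) -> bool:
        if not isinstance(other, CloneTree):
            return NotImplemented
        return json.dumps(self.to_dict(), sort_keys=True) == json.dumps(
            other.to_dict(), sort_keys=True
        )


@dataclass
class RegionComposition:
    """Per-region fractions of cancer cells assigned to each clone."""

    sample_id: str
    fractions: dict[str, float]
    inferred_only: bool = False
    multi_lineage: bool = False

    def validate(self, tol: float = 1e-6) -> None:
        if any(f < -tol for f in self.fractions.values()):
            raise InvalidCompositionError(
                f"negative clone fraction in {self.sample_id}"
            )
        total = sum(self.fractions.values())
        if total > 1 + tol:
            raise InvalidCompositionError(
                f"fractions sum to {total:.6f} > 1 in {self.sample_id}"
            )


@dataclass
class PurityEstimate:
    sample_id: str
    t: float
    founder_variant_id: str
    founder_m: int
    founder_n: int
    standard_error: float
    superclone_adjusted: bool = False
    clipped: bool = False


@dataclass
class LineageStats:
    """Summary of one major lineage (a child branch of the founder)."""

    lineage_id: str
    molecular_age: int
    average_ccf: float
    regions_excluded: list[str] = field(default_factory=list)
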