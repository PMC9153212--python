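"""Synthetic multi-region tumor cohorts with known ground truth.

Emulates the structure of a deeply sequenced, autopsy-style diffuse
midline glioma cohort: one truncal founder mutation (an H3 K27M analogue)
present in every cancer cell, a handful of mutation clusters arranged on a
random clone tree, allele-specific CNVs (losses, CN-LOH, gains, bi-allelic
duplication, focal mutant-allele amplicons) attached to branches, several
tumor regions per patient whose clonal compositions admix lineages in
about half of regions, purities centered near 0.8, deep (~2500X) coverage,
and histologically normal samples carrying 0–12% residual tumor.

The generator draws the truth first (tree, compositions, purities, copy
models) and then produces observations through exactly the forward model
the inference inverts: expected VAF v = t·f·g·n/c per variant and sample,
binomially sampled read counts with a symmetric per-read error, and
het-SNP B-allele fractions whose deviation from 0.5 encodes each CNV's
cellular prevalence. Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .datatypes import (
    CloneNode,
    CloneTree,
    CNVSegment,
    MutationCopyModel,
    ReadCountMatrix,
    RegionComposition,
    SampleMeta,
    Timing,
    TissueClass,
    VariantSite,
)
from .errors import InconsistentTruthError, InvalidConfigError
from .purity import expected_baf

_BASES = ("A", "C", "G", "T")
_SEG_SPAN = 50_000_000


@dataclass
class CNVEventSpec:
    """A requested CNV: which branch it arises on and its (a, b) state."""

    branch: int  # node index, 0 = trunk
    chrom: str
    major_cn: int
    minor_cn: int
    focal: bool = False


def default_cnv_events() -> list[CNVEventSpec]:
    """A study-like mix: truncal loss, branch gain, CN-LOH, bi-allelic dup."""
    return [
        CNVEventSpec(branch=0, chrom="17", major_cn=1, minor_cn=0),
        CNVEventSpec(branch=1, chrom="2", major_cn=2, minor_cn=1),
        CNVEventSpec(branch=0, chrom="14", major_cn=2, minor_cn=0),
        CNVEventSpec(branch=2, chrom="7", major_cn=2, minor_cn=2),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic patient.

    Defaults follow the cohort this emulates: 3–7 tumor regions (default
    5), 4–15 mutation clusters (default 6), purities drawn Beta(8, 2)
    (median ~0.82), ~2500X deep coverage with a 100X exome-like tier,
    per-read error 1e-3 after error suppression, and normal samples with
    tumor contamination on the 0–12% scale.
    """

    n_regions: int = 5
    n_normals: int = 2
    n_clusters: int = 6
    mutations_per_cluster: tuple[int, int] = (8, 15)
    founder_gene_label: str = "H3F3A"
    purity_distribution: tuple[float, float] = (8.0, 2.0)
    deep_depth: float = 2500.0
    wes_depth: float = 100.0
    # per-read error AFTER error suppression; cleaned deep sequencing has a
    # residual background on the 1e-5 scale or below
    base_error_rate: float = 1e-5
    cnv_events: list[CNVEventSpec] = field(default_factory=default_cnv_events)
    convergent_driver: str | None = None
    contamination_fractions: list[float] = field(default_factory=lambda: [0.0, 0.02])
    admixture_concentration: float = 1.5
    snps_per_segment: int = 50
    baf_noise_sd: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_regions": self.n_regions,
            "n_normals": self.n_normals,
            "n_clusters": self.n_clusters,
            "snps_per_segment": self.snps_per_segment,
        }
        for name, v in counts.items():
            if v < 1 and not (name == "n_normals" and v == 0):
                raise InvalidConfigError(f"{name} must be >= 1, got {v}")
        lo, hi = self.mutations_per_cluster
        if lo < 1 or hi < lo:
            raise InvalidConfigError(
                f"mutations_per_cluster range invalid: ({lo}, {hi})"
            )
        if not (0.0 < self.base_error_rate < 1.0):
            raise InvalidConfigError("base_error_rate must lie in (0,1)")
        if any(not (0.0 <= phi < 1.0) for phi in self.contamination_fractions):
            raise InvalidConfigError("contamination fractions must lie in [0,1)")
        if self.deep_depth < 1 or self.wes_depth < 1:
            raise InvalidConfigError("mean depths must be >= 1")
        a, b = self.purity_distribution
        if a <= 0 or b <= 0:
            raise InvalidConfigError("purity Beta parameters must be positive")
        for ev in self.cnv_events:
            if not (0 <= ev.branch < self.n_clusters):
                raise InvalidConfigError(
                    f"CNV event references branch {ev.branch}, "
                    f"but the tree has nodes 0..{self.n_clusters - 1}"
                )
            if ev.minor_cn < 0 or ev.major_cn < ev.minor_cn:
                raise InvalidConfigError(
                    f"CNV state ({ev.major_cn},{ev.minor_cn}) invalid"
                )
        if self.convergent_driver is not None and self.n_clusters < 3:
            raise InvalidConfigError(
                "a convergent driver needs >= 2 non-trunk branches "
                "(n_clusters >= 3)"
            )


@dataclass
class SimulationTruth:
    """Complete generating state for one synthetic patient."""

    config: SimulationConfig
    tree: CloneTree
    variants: list[VariantSite]
    variant_assignments: dict[str, str]  # variant_id -> node_id
    region_compositions: list[RegionComposition]
    purities: dict[str, float]
    copy_models: dict[str, MutationCopyModel]
    segments: list[CNVSegment]
    contamination: dict[str, tuple[float, dict[str, float]]]
    meta: list[SampleMeta]

    @property
    def tumor_samples(self) -> list[str]:
        return sorted(self.purities)

    @property
    def normal_samples(self) -> list[str]:
        return sorted(self.contamination)

    def node_ccf(self, node_id: str, sample_id: str) -> float:
        """Truth CCF of a node = summed clone fractions over its subtree."""
        comp = self._composition(sample_id)
        return sum(comp.get(n, 0.0) for n in self.tree.subtree(node_id))

    def _composition(self, sample_id: str) -> dict[str, float]:
        for rc in self.region_compositions:
            if rc.sample_id == sample_id:
                return rc.fractions
        if sample_id in self.contamination:
            return self.contamination[sample_id][1]
        raise InconsistentTruthError(f"unknown sample {sample_id}")

    def _cell_fraction(self, sample_id: str) -> float:
        if sample_id in self.purities:
            return self.purities[sample_id]
        if sample_id in self.contamination:
            return self.contamination[sample_id][0]
        raise InconsistentTruthError(f"unknown sample {sample_id}")

    def expected_vaf(self, variant_id: str, sample_id: str) -> float:
        """Forward model v = t·f·g·n/c = t·CCF·n/c for one cell."""
        if variant_id not in self.copy_models:
            raise InconsistentTruthError(f"no copy model for {variant_id}")
        m = self.copy_models[variant_id]
        t = self._cell_fraction(sample_id)
        node = self.variant_assignments[variant_id]
        ccf = self.node_ccf(node, sample_id)
        if m.segment is None:
            c = 2.0
        else:
            seg_node = self._segment_node(m.segment)
            cp = t * self.node_ccf(seg_node, sample_id)
            c = 2.0 + cp * (m.segment.M - 2)
        return t * ccf * m.n / c

    def _segment_node(self, segment: CNVSegment) -> str:
        for nid, node in self.tree.nodes.items():
            if segment.segment_id in node.cnv_events:
                return nid
        raise InconsistentTruthError(f"segment {segment.segment_id} not on the tree")

    def to_json(self) -> str:
        d = {
            "config": {
                **{k: v for k, v in asdict(self.config).items() if k != "cnv_events"},
                "cnv_events": [asdict(e) for e in self.config.cnv_events],
            },
            "tree": self.tree.to_dict(),
            "variants": [
                {
                    "variant_id": v.variant_id,
                    "gene": v.gene,
                    "variant_class": v.variant_class.value,
                }
                for v in self.variants
            ],
            "variant_assignments": self.variant_assignments,
            "region_compositions": [
                {"sample_id": rc.sample_id, "fractions": rc.fractions}
                for rc in self.region_compositions
            ],
            "purities": self.purities,
            "copy_models": {
                vid: {
                    "timing": m.timing.value,
                    "n": m.n,
                    "segment": None if m.segment is None else m.segment.segment_id,
                }
                for vid, m in self.copy_models.items()
            },
            "segments": [
                {
                    "segment_id": s.segment_id,
                    "major_cn": s.major_cn,
                    "minor_cn": s.minor_cn,
                }
                for s in self.segments
            ],
            "contamination": {
                s: {"phi": phi, "fractions": fr}
                for s, (phi, fr) in self.contamination.items()
            },
        }
        return json.dumps(d, sort_keys=True, indent=1)


def _random_positions(rng: np.random.Generator, chrom: str, n: int,
                      lo: int = _SEG_SPAN + 1, hi: int = 2 * _SEG_SPAN) -> list[int]:
    return sorted(int(p) for p in rng.choice(np.arange(lo, hi), size=n, replace=False))


def _make_variant(rng: np.random.Generator, chrom: str, pos: int,
                  gene: str | None = None) -> VariantSite:
    ref, alt = rng.choice(_BASES, size=2, replace=False)
    return VariantSite(chrom=chrom, pos=pos, ref=str(ref), alt=str(alt), gene=gene)


def simulate_truth(config: SimulationConfig, seed: int) -> SimulationTruth:
    """Draw a random clone tree, compositions, purities and copy models.

    The trunk carries the founder mutation; CNV events attach to the
    requested branches; a convergent driver, when configured, receives
    independent mutations (distinct positions) on at least two distinct
    non-trunk branches. Region compositions are Dirichlet draws over a
    sparse support — the trunk plus a connected subset of nodes — with
    about half of regions supporting more than one trunk-child lineage.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    K = config.n_clusters

    # --- tree topology: trunk N0, each later node attaches to a random
    # earlier node with a bias toward the trunk (broad main lineages)
    node_ids = [f"N{i}" for i in range(K)]
    parents: dict[str, str | None] = {"N0": None}
    for i in range(1, K):
        cands = node_ids[:i]
        w = np.array([2.0 if p == "N0" else 1.0 for p in cands])
        parents[node_ids[i]] = str(rng.choice(cands, p=w / w.sum()))

    # --- cluster sizes and variants
    lo, hi = config.mutations_per_cluster
    sizes = {nid: int(rng.integers(lo, hi + 1)) for nid in node_ids}
    variants: list[VariantSite] = []
    assignments: dict[str, str] = {}
    founder = _make_variant(rng, "1", 1_000_000, gene=config.founder_gene_label)
    variants.append(founder)
    assignments[founder.variant_id] = "N0"
    plain_chroms = [str(c) for c in range(3, 14)] + ["15", "16", "18", "19", "20"]
    for ki, nid in enumerate(node_ids):
        n_var = sizes[nid] - (1 if nid == "N0" else 0)
        chrom = plain_chroms[ki % len(plain_chroms)]
        for pos in _random_positions(rng, chrom, n_var):
            v = _make_variant(rng, chrom, pos)
            variants.append(v)
            assignments[v.variant_id] = nid

    if config.convergent_driver is not None:
        branches = node_ids[1:]
        chosen = rng.choice(branches, size=2, replace=False)
        for j, nid in enumerate(chosen):
            v = _make_variant(
                rng, "21", 10_000_000 + j * 1_000 + int(rng.integers(0, 999)),
                gene=config.convergent_driver,
            )
            variants.append(v)
            assignments[v.variant_id] = str(nid)
            sizes[str(nid)] += 1

    # --- CNV segments on their branches (one chromosome arm each)
    segments: list[CNVSegment] = []
    seg_node: dict[str, str] = {}
    cnv_by_node: dict[str, list[str]] = {nid: [] for nid in node_ids}
    for ev in config.cnv_events:
        seg = CNVSegment(
            chrom=ev.chrom, start=1, end=_SEG_SPAN,
            major_cn=ev.major_cn, minor_cn=ev.minor_cn, focal=ev.focal,
        )
        segments.append(seg)
        nid = node_ids[ev.branch]
        seg_node[seg.segment_id] = nid
        cnv_by_node[nid].append(seg.segment_id)

    tree = CloneTree(
        [
            CloneNode(
                node_id=nid,
                parent_id=parents[nid],
                cluster_id=nid,
                cnv_events=cnv_by_node[nid],
                n_mutations=sizes[nid],
            )
            for nid in node_ids
        ]
    )

    # --- copy models: a couple of variants per CNV cluster sit inside the
    # segment (timed before the event on the duplicated haplotype when one
    # exists), and one variant of each descendant cluster postdates it
    copy_models: dict[str, MutationCopyModel] = {
        v.variant_id: MutationCopyModel(
            variant_id=v.variant_id, segment=None,
            timing=Timing.DIPLOID_CONTEXT, n=1,
        )
        for v in variants
    }
    for seg in segments:
        nid = seg_node[seg.segment_id]
        own = [v for v in variants
               if assignments[v.variant_id] == nid and v is not founder
               and copy_models[v.variant_id].segment is None][:2]
        for j, v in enumerate(own):
            moved = VariantSite(seg.chrom, 2_000_000 + 1_000 * j + seg.start,
                                v.ref, v.alt, v.gene)
            variants[variants.index(v)] = moved
            assignments[moved.variant_id] = assignments.pop(v.variant_id)
            del copy_models[v.variant_id]
            if seg.major_cn >= 2:
                timing, n = Timing.BEFORE_CNV_ON_MAJOR, seg.major_cn
            else:
                timing, n = Timing.AFTER_CNV, 1
            copy_models[moved.variant_id] = MutationCopyModel(
                variant_id=moved.variant_id, segment=seg, timing=timing, n=n
            )
        placed = 0
        for child in tree.descendants(nid):
            sub = [v for v in variants
                   if assignments[v.variant_id] == child
                   and copy_models[v.variant_id].segment is None][:1]
            for v in sub:
                placed += 1
                moved = VariantSite(seg.chrom, 30_000_000 + 1_000 * placed
                                    + seg.start, v.ref, v.alt, v.gene)
                variants[variants.index(v)] = moved
                assignments[moved.variant_id] = assignments.pop(v.variant_id)
                del copy_models[v.variant_id]
                copy_models[moved.variant_id] = MutationCopyModel(
                    variant_id=moved.variant_id, segment=seg,
                    timing=Timing.AFTER_CNV, n=1,
                )

    # --- purities and region compositions
    a, b = config.purity_distribution
    region_ids = [f"R{i + 1}" for i in range(config.n_regions)]
    purities = {s: float(rng.beta(a, b)) for s in region_ids}
    trunk_children = tree.children("N0")

    def draw_support(multi: bool) -> list[str]:
        support = {"N0"}
        if not trunk_children:
            return ["N0"]
        if multi and len(trunk_children) >= 2:
            k = int(rng.integers(2, len(trunk_children) + 1))
        else:
            k = 1
        lineages = rng.choice(trunk_children, size=k, replace=False)
        for top in lineages:
            support.add(str(top))
            for nid in tree.descendants(str(top)):
                if tree.nodes[nid].parent_id in support and rng.random() < 0.8:
                    support.add(nid)
        return sorted(support)

    compositions: list[RegionComposition] = []
    for attempt in range(500):
        compositions = []
        for i, s in enumerate(region_ids):
            support = draw_support(multi=(i % 2 == 0))
            fr = rng.dirichlet(np.full(len(support), config.admixture_concentration))
            fractions = {nid: 0.0 for nid in node_ids}
            fractions.update({nid: float(x) for nid, x in zip(support, fr)})
            compositions.append(RegionComposition(sample_id=s, fractions=fractions))
        covered = all(
            max(
                sum(c.fractions[m] for m in tree.subtree(nid))
                for c in compositions
            ) >= 0.08
            for nid in node_ids
        )
        if covered:
            break
    else:
        raise InconsistentTruthError("could not cover every cluster in any region")

    # --- contaminated-normal compositions: trunk plus one invading lineage
    contamination: dict[str, tuple[float, dict[str, float]]] = {}
    if len(config.contamination_fractions) != config.n_normals:
        raise InvalidConfigError(
            "contamination_fractions length must equal n_normals"
        )
    for i, phi in enumerate(config.contamination_fractions):
        s = f"G{i + 1}"
        fractions = {nid: 0.0 for nid in node_ids}
        if trunk_children:
            top = str(rng.choice(trunk_children))
            fractions["N0"] = 0.4
            fractions[top] = 0.6
        else:
            fractions["N0"] = 1.0
        contamination[s] = (float(phi), fractions)

    meta = [
        SampleMeta(sample_id=s, patient_id="SIM", tissue_class=TissueClass.TUMOR,
                   region_label=s, spatial_position=float(i) / len(region_ids))
        for i, s in enumerate(region_ids)
    ] + [
        SampleMeta(sample_id=s, patient_id="SIM", tissue_class=TissueClass.NORMAL,
                   region_label=s)
        for s in contamination
    ]

    # fill truth segment calibration per tumor sample
    truth = SimulationTruth(
        config=config, tree=tree, variants=variants,
        variant_assignments=assignments, region_compositions=compositions,
        purities=purities, copy_models=copy_models, segments=segments,
        contamination=contamination, meta=meta,
    )
    for seg in segments:
        nid = seg_node[seg.segment_id]
        for s in region_ids:
            cp = purities[s] * truth.node_ccf(nid, s)
            seg.cp[s] = cp
            seg.c[s] = 2.0 + cp * (seg.M - 2)
            seg.ai[s] = abs(expected_baf(seg.major_cn, seg.minor_cn, cp) - 0.5)
            seg.f[s] = cp / purities[s] if purities[s] > 0 else 0.0
    return truth


def simulate_age_coupled_cohort(
    n_lineages: int = 10,
    n_regions: int = 5,
    seed: int = 0,
    coupling_noise: float = 0.2,
    concentration: float = 8.0,
) -> tuple[CloneTree, list[RegionComposition], dict[str, float]]:
    """A patient whose lineage expansion tracks mutation accrual.

    Major lineages (children of the trunk) that have been expanding longer
    both accrue more mutations (greater molecular age) and occupy more of
    each region on average. Each lineage's molecular age is drawn uniform
    on 5–60 mutations and its regional occupancy drawn Dirichlet with
    concentration proportional to age times a lognormal noise factor, so
    the age–CCF association is positive but noisy, as in a real tumor.
    """
    rng = np.random.default_rng(seed)
    node_ids = ["N0"] + [f"N{i + 1}" for i in range(n_lineages)]
    ages = rng.integers(5, 61, size=n_lineages)
    tree = CloneTree(
        [CloneNode("N0", None, "N0", n_mutations=int(rng.integers(2, 6)))]
        + [
            CloneNode(nid, "N0", nid, n_mutations=int(a))
            for nid, a in zip(node_ids[1:], ages)
        ]
    )
    weights = ages * rng.lognormal(0.0, coupling_noise, size=n_lineages)
    comps = []
    region_ids = [f"R{i + 1}" for i in range(n_regions)]
    for s in region_ids:
        fr = rng.dirichlet(concentration * weights / weights.mean())
        fractions = {"N0": 0.0}
        fractions.update({nid: float(x) for nid, x in zip(node_ids[1:], fr)})
        comps.append(RegionComposition(sample_id=s, fractions=fractions))
    purities = {s: float(rng.beta(8, 2)) for s in region_ids}
    return tree, comps, purities


def _draw_counts(
    rng: np.random.Generator,
    expected: np.ndarray,
    mean_depth: float,
    error_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    depth = np.maximum(rng.poisson(mean_depth, size=expected.shape), 1)
    p = expected * (1.0 - error_rate) + (1.0 - expected) * error_rate
    alt = rng.binomial(depth, p)
    return depth - alt, alt


def simulate_read_counts(
    truth: SimulationTruth,
    config: SimulationConfig,
    seed: int,
    mean_depth: float | None = None,
) -> ReadCountMatrix:
    """Binomial read counts for the tumor regions at deep coverage.

    For each variant and sample the expected VAF follows the forward model
    from the truth clone fractions, purity and copy model; the alt count
    is Binomial(depth, p) with p mixing the expected VAF and the per-read
    error symmetrically, and depth Poisson around the configured mean
    (floored at one read).
    """
    rng = np.random.default_rng(seed)
    samples = truth.tumor_samples
    exp = np.array(
        [
            [truth.expected_vaf(v.variant_id, s) for s in samples]
            for v in truth.variants
        ]
    )
    ref, alt = _draw_counts(
        rng, exp, mean_depth or config.deep_depth, config.base_error_rate
    )
    ids = [v.variant_id for v in truth.variants]
    return ReadCountMatrix(
        truth.variants,
        pd.DataFrame(ref, index=ids, columns=samples),
        pd.DataFrame(alt, index=ids, columns=samples),
        meta=truth.meta,
    )


def simulate_contaminated_normals(
    truth: SimulationTruth,
    config: SimulationConfig,
    seed: int,
    mean_depth: float | None = None,
) -> ReadCountMatrix:
    """Read counts for normal samples holding a trace tumor population.

    Each normal mixes normal tissue with a tumor fraction phi (possibly 0)
    whose clonal composition is a configured subset of the tree — the
    forward model of :func:`simulate_read_counts` with purity replaced by
    phi.
    """
    rng = np.random.default_rng(seed)
    samples = truth.normal_samples
    for s in samples:
        _, fractions = truth.contamination[s]
        for nid in fractions:
            if nid not in truth.tree.nodes:
                raise InconsistentTruthError(
                    f"contaminating clone {nid} is not on the tree"
                )
    exp = np.array(
        [
            [truth.expected_vaf(v.variant_id, s) for s in samples]
            for v in truth.variants
        ]
    )
    ref, alt = _draw_counts(
        rng, exp, mean_depth or config.deep_depth, config.base_error_rate
    )
    ids = [v.variant_id for v in truth.variants]
    return ReadCountMatrix(
        truth.variants,
        pd.DataFrame(ref, index=ids, columns=samples),
        pd.DataFrame(alt, index=ids, columns=samples),
        meta=truth.meta,
    )


def simulate_baf_segments(
    truth: SimulationTruth, config: SimulationConfig, seed: int
) -> pd.DataFrame:
    """SEG-style observations: composite copy and folded BAF deviation.

    Each segment emits ``snps_per_segment`` het-SNP BAFs per tumor sample:
    the B allele rides the duplicated or the retained haplotype with equal
    probability (unphased SNPs), Gaussian noise of sd ``baf_noise_sd`` is
    added and the value truncated to [0, 1]. The folded deviation is
    summarized with a noise-corrected quadratic estimator
    sqrt(max(0, mean((BAF−0.5)²) − sd²)) so a null segment shrinks to 0.
    """
    rng = np.random.default_rng(seed)
    rows = []
    sd = config.baf_noise_sd
    for seg in truth.segments:
        nid = truth._segment_node(seg)
        for s in truth.tumor_samples:
            cp = truth.purities[s] * truth.node_ccf(nid, s)
            on_major = rng.random(config.snps_per_segment) < 0.5
            mean = np.where(
                on_major,
                expected_baf(seg.major_cn, seg.minor_cn, cp, b_on_major=True),
                expected_baf(seg.major_cn, seg.minor_cn, cp, b_on_major=False),
            )
            baf = np.clip(mean + rng.normal(0, sd, size=mean.shape), 0.0, 1.0)
            dev2 = float(np.mean((baf - 0.5) ** 2))
            folded = float(np.sqrt(max(dev2 - sd**2, 0.0)))
            c_obs = 2.0 + cp * (seg.M - 2) + float(rng.normal(0, sd))
            rows.append(
                {
                    "sample_id": s,
                    "chrom": seg.chrom,
                    "start": seg.start,
                    "end": seg.end,
                    "c": c_obs,
                    "baf_dev": min(folded, 0.5),
                    "n_snps": config.snps_per_segment,
                }
            )
    return pd.DataFrame(rows)
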