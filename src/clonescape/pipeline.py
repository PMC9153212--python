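"""End-to-end orchestration: purity → CNV prevalence → copy models → CCF →
clusters → tree → decomposition → contamination.

One run covers one patient. The run is deterministic given the seed, and
every output is written as plain text (TSV/JSON/Newick) along with a
manifest recording the configuration hash, seed and stage warnings so a
run can be audited and reproduced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .ccf import enumerate_copy_models
from .clustering import cluster_mutations, compute_ccf_matrix
from .contamination import build_error_model, test_presence
from .datatypes import (
    CNVSegment,
    MutationCopyModel,
    ReadCountMatrix,
    SampleMeta,
    Timing,
    TissueClass,
)
from .errors import InvalidConfigError, StageError
from .phylogeny import (
    MIN_PURITY,
    build_tree,
    classification_summary,
    classify_variants,
    decompose_regions,
    lineage_stats,
    place_cnv_events,
)
from .purity import calibrate_segments, estimate_purity, refine_purity
from .synthetic import (
    SimulationConfig,
    simulate_baf_segments,
    simulate_contaminated_normals,
    simulate_read_counts,
    simulate_truth,
)


@dataclass
class PipelineConfig:
    """Inputs and thresholds for one patient run.

    Exactly one of (``counts_path`` + ``meta_path``) or ``simulation`` must
    be supplied. The founder is designated by gene label; its copy model
    (M, n) defaults to diploid heterozygous.
    """

    counts_path: str | None = None
    segments_path: str | None = None
    meta_path: str | None = None
    simulation: SimulationConfig | None = None
    founder_gene: str = "H3F3A"
    founder_model: tuple[int, int] = (2, 1)
    purity_cutoff: float = MIN_PURITY
    ccf_rule_tol: float = 0.05
    feasibility_tol: float = 0.05
    q_threshold: float = 0.05
    max_clusters: int = 10
    em_restarts: int = 20
    seed: int = 0

    def validate(self) -> None:
        real = self.counts_path is not None
        sim = self.simulation is not None
        if real == sim:
            raise InvalidConfigError(
                "supply exactly one of real inputs (counts/meta paths) "
                "or a simulation config"
            )
        if real and self.meta_path is None:
            raise InvalidConfigError("real inputs require a sample metadata table")


@dataclass
class PipelineResult:
    outdir: Path
    purities: dict[str, float]
    tree_ancestry: pd.DataFrame | None
    warnings: list[str] = field(default_factory=list)


def _segment_for(variant, segments: list[CNVSegment]) -> CNVSegment | None:
    for seg in segments:
        if seg.overlaps(variant.chrom, variant.pos):
            return seg
    return None


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    manifest: dict = {
        "seed": config.seed,
        "complete": False,
        "stages": [],
    }

    def finish_stage(name: str) -> None:
        manifest["stages"].append(name)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    # ---- stage: inputs
    try:
        if config.simulation is not None:
            sim = config.simulation
            truth = simulate_truth(sim, config.seed)
            tumor_counts = simulate_read_counts(truth, sim, config.seed + 1)
            normal_counts = simulate_contaminated_normals(truth, sim, config.seed + 2)
            seg_obs = simulate_baf_segments(truth, sim, config.seed + 3)
            meta = truth.meta
            counts = tumor_counts.concat_samples(normal_counts)
            cio.write_variant_counts(counts, outdir / "variant_counts.tsv")
            cio.write_segments(seg_obs, outdir / "segments_observed.tsv")
            cio.write_sample_meta(meta, outdir / "sample_meta.tsv")
            (outdir / "truth.json").write_text(truth.to_json())
        else:
            meta = cio.read_sample_meta(config.meta_path)
            path = Path(config.counts_path)
            if path.suffix in (".vcf", ".gz"):
                counts = cio.read_vcf_counts(path, meta)
            else:
                counts = cio.read_variant_counts(path, meta)
            seg_obs = (
                cio.segments_frame(cio.read_segments(config.segments_path))
                if config.segments_path
                else pd.DataFrame(
                    columns=["sample_id", "chrom", "start", "end", "c",
                             "baf_dev", "n_snps"]
                )
            )
    except Exception as e:  # noqa: BLE001
        raise StageError("inputs", str(e)) from e
    finish_stage("inputs")

    tumor_samples = [
        m.sample_id for m in meta if m.tissue_class == TissueClass.TUMOR
    ]
    normal_samples = [
        m.sample_id for m in meta if m.tissue_class == TissueClass.NORMAL
    ]

    # ---- stage: founder + purity
    try:
        founder_ids = [
            v.variant_id for v in counts.variants if v.gene == config.founder_gene
        ]
        if len(founder_ids) != 1:
            raise InvalidConfigError(
                f"expected exactly one {config.founder_gene} founder variant, "
                f"found {len(founder_ids)}"
            )
        founder_id = founder_ids[0]
        purity_estimates = estimate_purity(
            counts, founder_id, config.founder_model, samples=tumor_samples
        )
        purities = {p.sample_id: p.t for p in purity_estimates}
        pd.DataFrame(
            [
                {
                    "sample_id": p.sample_id, "purity": p.t,
                    "standard_error": p.standard_error,
                    "superclone_adjusted": p.superclone_adjusted,
                    "clipped": p.clipped,
                }
                for p in purity_estimates
            ]
        ).to_csv(outdir / "purity.tsv", sep="\t", index=False)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("purity", str(e)) from e
    finish_stage("purity")

    # ---- stage: CNV prevalence calibration
    try:
        segments, unresolved = ([], [])
        if len(seg_obs):
            segments, unresolved = calibrate_segments(
                seg_obs, purities, tol=config.feasibility_tol
            )
        for seg_id in unresolved:
            warnings.append(f"segments: unresolved segment {seg_id}")
        rows = []
        for seg in segments:
            for s in seg.cp:
                rows.append(
                    {
                        "segment_id": seg.segment_id, "sample_id": s,
                        "major_cn": seg.major_cn, "minor_cn": seg.minor_cn,
                        "cp": seg.cp[s], "c": seg.c[s], "f": seg.f[s],
                    }
                )
        pd.DataFrame(rows).to_csv(outdir / "segments.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("segments", str(e)) from e
    finish_stage("segments")

    # ---- stage: copy models + CCF
    try:
        copy_models: dict[str, MutationCopyModel] = {}
        for v in counts.variants:
            seg = _segment_for(v, segments)
            ranked = enumerate_copy_models(
                v.variant_id, counts, purities, seg, tol=config.feasibility_tol
            )
            if ranked:
                copy_models[v.variant_id] = ranked[0].model
            elif seg is None:
                copy_models[v.variant_id] = MutationCopyModel(
                    v.variant_id, None, Timing.DIPLOID_CONTEXT, 1
                )
            else:
                warnings.append(f"ccf: unresolved copy model for {v.variant_id}")
        ccf, ccf_se = compute_ccf_matrix(counts, purities, copy_models)
        high_purity = [
            s for s in ccf.columns if purities.get(s, 0) >= config.purity_cutoff
        ]
        truncal_guess = [
            vid
            for vid in ccf.index
            if (ccf.loc[vid, high_purity].dropna() > 0.5).all()
            and ccf.loc[vid, high_purity].notna().all()
        ]
        # anchor each sample's purity on the median truncal CCF (superclone
        # correction and its two-sided refinement in one step), then
        # recompute the matrix under the adjusted purities
        purity_estimates = refine_purity(ccf, purity_estimates, truncal_guess)
        purities = {p.sample_id: p.t for p in purity_estimates}
        ccf, _ = compute_ccf_matrix(counts, purities, copy_models)
        for p in purity_estimates:
            if p.superclone_adjusted:
                warnings.append(f"purity: superclone rescale in {p.sample_id}")
        pd.DataFrame(
            [
                {
                    "sample_id": p.sample_id, "purity": p.t,
                    "standard_error": p.standard_error,
                    "superclone_adjusted": p.superclone_adjusted,
                    "clipped": p.clipped,
                }
                for p in purity_estimates
            ]
        ).to_csv(outdir / "purity.tsv", sep="\t", index=False)
        ccf.to_csv(outdir / "ccf.tsv", sep="\t")
    except Exception as e:  # noqa: BLE001
        raise StageError("ccf", str(e)) from e
    finish_stage("ccf")

    # ---- stage: clustering
    try:
        usable = {
            s: t for s, t in purities.items() if t >= config.purity_cutoff
        }
        clusters, fit = cluster_mutations(
            counts.subset_samples(
                [s for s in counts.samples if s in usable]
            ),
            usable,
            copy_models,
            k_range=range(1, min(config.max_clusters,
                                 len(copy_models)) + 1),
            seed=config.seed,
            n_restarts=config.em_restarts,
        )
        # low-purity regions are not fit, but their compositions are still
        # inferred from the clusters established in high-purity samples
        for c in clusters:
            for s in tumor_samples:
                if s in c.ccf or s not in ccf.columns:
                    continue
                member_ccf = ccf.loc[[m for m in c.members if m in ccf.index], s]
                if member_ccf.notna().any():
                    c.ccf[s] = float(np.clip(member_ccf.mean(), 0.0, 1.0))
        pd.DataFrame(
            [
                {
                    "cluster_id": c.cluster_id, "size": c.size,
                    "members": ",".join(c.members),
                    **{f"ccf_{s}": c.ccf[s] for s in sorted(c.ccf)},
                }
                for c in clusters
            ]
        ).to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    except Exception as e:  # noqa: BLE001
        raise StageError("clustering", str(e)) from e
    finish_stage("clustering")

    # ---- stage: tree + decomposition + lineage stats
    try:
        result = build_tree(clusters, purities, tol=config.ccf_rule_tol)
        tree = result.tree
        tree, unplaced = place_cnv_events(tree, segments, purities, clusters)
        for seg_id in unplaced:
            warnings.append(f"tree: unplaced CNV {seg_id}")
        cio.write_tree(tree, outdir / "tree.json")
        comps = decompose_regions(tree, clusters, purities,
                                  tol=config.ccf_rule_tol)
        cio.write_composition(comps, purities, outdir / "composition.tsv")
        stats_rows, corr = lineage_stats(tree, comps, purities)
        pd.DataFrame(
            [
                {
                    "lineage_id": s.lineage_id,
                    "molecular_age": s.molecular_age,
                    "average_ccf": s.average_ccf,
                }
                for s in stats_rows
            ]
        ).to_csv(outdir / "lineage_stats.tsv", sep="\t", index=False)
        labels = classify_variants(counts.subset_samples(tumor_samples), purities)
        pd.DataFrame(
            [{"variant_id": k, "class": v.value} for k, v in labels.items()]
        ).to_csv(outdir / "classification.tsv", sep="\t", index=False)
        summary = {
            **classification_summary(labels),
            "n_clusters": len(clusters),
            "lineage_age_ccf_pearson": None if corr is None else corr[0],
            "multi_lineage_regions": sum(c.multi_lineage for c in comps),
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
        ancestry = tree.ancestry_matrix()
    except Exception as e:  # noqa: BLE001
        raise StageError("tree", str(e)) from e
    finish_stage("tree")

    # ---- stage: contamination
    try:
        calls = []
        for s in normal_samples:
            em = build_error_model(
                counts.subset_samples(normal_samples), exclude=s
            )
            calls.append(
                test_presence(
                    counts, s, founder_id, clusters, em,
                    founder_model=config.founder_model,
                    q_threshold=config.q_threshold,
                )
            )
        if calls:
            pd.concat([c.to_frame() for c in calls]).to_csv(
                outdir / "contamination.tsv", sep="\t", index=False
            )
        else:
            (outdir / "contamination.tsv").write_text(
                "sample_id\ttumor_fraction\tci_low\tci_high\t"
                "cluster_id\tcombined_p\tq_value\tpresent\n"
            )
    except Exception as e:  # noqa: BLE001
        raise StageError("contamination", str(e)) from e
    finish_stage("contamination")

    cfg_for_hash = asdict(config)
    manifest.update(
        {
            "complete": True,
            "config_hash": hashlib.sha256(
                json.dumps(cfg_for_hash, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "warnings": warnings,
            "numpy_version": np.__version__,
        }
    )
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return PipelineResult(
        outdir=outdir,
        purities=purities,
        tree_ancestry=ancestry,
        warnings=warnings,
    )
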