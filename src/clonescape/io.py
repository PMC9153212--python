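"""Readers and writers for the tabular formats the pipeline touches.

Variant counts travel as a TSV matrix (one ``<sample>_ref``/``<sample>_alt``
column pair per sample) or as VCF 4.x with per-sample AD fields; segments
as SEG-style TSV with 1-based inclusive coordinates; trees as JSON plus
Newick (branch lengths = mutation counts); compositions and metadata as
TSV. Readers validate strictly and reject rather than coerce: negative
counts, overlapping segments, unknown samples and duplicate variants are
all errors.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    CloneTree,
    ReadCountMatrix,
    RegionComposition,
    SampleMeta,
    SegmentObservation,
    TissueClass,
    VariantClass,
    VariantSite,
)
from .errors import ConsistencyError, FormatError, InvalidCompositionError

_VARIANT_COLS = ["variant_id", "chrom", "pos", "ref", "alt", "gene"]


def write_sample_meta(meta: list[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "patient_id": m.patient_id,
                "tissue_class": m.tissue_class.value,
                "region_label": m.region_label,
                "spatial_position": m.spatial_position,
                "anatomical_site": m.anatomical_site,
            }
            for m in meta
        ]
    ).to_csv(path, sep="\t", index=False)


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "region_label": str})
    out = []
    for _, r in df.iterrows():
        out.append(
            SampleMeta(
                sample_id=str(r.sample_id),
                patient_id=str(r.patient_id),
                tissue_class=TissueClass(r.tissue_class),
                region_label=str(r.region_label),
                spatial_position=None
                if pd.isna(r.get("spatial_position"))
                else float(r.spatial_position),
                anatomical_site=None
                if pd.isna(r.get("anatomical_site"))
                else str(r.anatomical_site),
            )
        )
    if len({m.sample_id for m in out}) != len(out):
        raise ConsistencyError("duplicate sample_id in metadata")
    return out


def write_variant_counts(counts: ReadCountMatrix, path: str | Path) -> None:
    rows = []
    for v in counts.variants:
        row = {
            "variant_id": v.variant_id,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref,
            "alt": v.alt,
            "gene": v.gene if v.gene is not None else "",
        }
        for s in counts.samples:
            row[f"{s}_ref"] = int(counts.ref.loc[v.variant_id, s])
            row[f"{s}_alt"] = int(counts.alt.loc[v.variant_id, s])
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_variant_counts(
    path: str | Path, meta: list[SampleMeta] | None = None
) -> ReadCountMatrix:
    """Read the TSV count matrix; rejects malformed rows by name."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _VARIANT_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"count matrix missing columns {missing}")
    sample_cols = [c for c in df.columns if c.endswith("_ref")]
    samples = [c[: -len("_ref")] for c in sample_cols]
    for s in samples:
        if f"{s}_alt" not in df.columns:
            raise FormatError(f"sample {s} has a ref column but no alt column")
    if df.variant_id.duplicated().any():
        dupes = df.variant_id[df.variant_id.duplicated()].tolist()
        raise ConsistencyError(f"duplicate variant rows: {dupes}")
    variants = []
    for _, r in df.iterrows():
        for s in samples:
            for kind in ("ref", "alt"):
                val = r[f"{s}_{kind}"]
                if val < 0:
                    raise FormatError(
                        f"negative {kind} count for {r.variant_id} in sample {s}"
                    )
        gene = None if pd.isna(r.gene) or r.gene == "" else str(r.gene)
        vclass = (
            VariantClass.SNV
            if len(str(r.ref)) == 1 and len(str(r.alt)) == 1
            else VariantClass.INDEL
        )
        variants.append(
            VariantSite(str(r.chrom), int(r.pos), str(r.ref), str(r.alt),
                        gene=gene, variant_class=vclass)
        )
    ids = [v.variant_id for v in variants]
    ref = pd.DataFrame(
        {s: df[f"{s}_ref"].to_numpy() for s in samples}, index=ids
    )
    alt = pd.DataFrame(
        {s: df[f"{s}_alt"].to_numpy() for s in samples}, index=ids
    )
    return ReadCountMatrix(variants, ref, alt, meta=meta)


def read_vcf_counts(
    path: str | Path, meta: list[SampleMeta] | None = None
) -> ReadCountMatrix:
    """Read a VCF 4.x with per-sample AD (ref, alt depths) fields."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants, refs, alts = [], [], []
    seen = set()
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise FormatError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS}; split first"
            )
        v = VariantSite(str(rec.CHROM), int(rec.POS), str(rec.REF), str(rec.ALT[0]),
                        gene=(rec.INFO.get("GENE") or None))
        if v.variant_id in seen:
            raise ConsistencyError(f"duplicate variant record {v.variant_id}")
        seen.add(v.variant_id)
        ad = rec.format("AD")
        if ad is None:
            raise FormatError(f"record {v.variant_id} lacks AD fields")
        ad = np.asarray(ad)
        ref_row = np.where(ad[:, 0] < 0, 0, ad[:, 0])
        alt_row = np.where(ad[:, 1] < 0, 0, ad[:, 1])
        variants.append(v)
        refs.append(ref_row)
        alts.append(alt_row)
    ids = [v.variant_id for v in variants]
    return ReadCountMatrix(
        variants,
        pd.DataFrame(np.array(refs, dtype=np.int64), index=ids, columns=samples),
        pd.DataFrame(np.array(alts, dtype=np.int64), index=ids, columns=samples),
        meta=meta,
    )


def write_segments(observations: pd.DataFrame, path: str | Path) -> None:
    cols = ["sample_id", "chrom", "start", "end", "c", "baf_dev", "n_snps"]
    observations[cols].to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> list[SegmentObservation]:
    """SEG-style per-sample segment observations, 1-based inclusive.

    Overlapping segments within one sample are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    obs = [
        SegmentObservation(
            sample_id=str(r.sample_id), chrom=str(r.chrom), start=int(r.start),
            end=int(r.end), c=float(r.c), baf_dev=float(r.baf_dev),
            n_snps=int(r.n_snps),
        )
        for _, r in df.iterrows()
    ]
    by_key: dict[tuple[str, str], list[SegmentObservation]] = {}
    for o in obs:
        by_key.setdefault((o.sample_id, o.chrom), []).append(o)
    for (sample, chrom), group in by_key.items():
        group = sorted(group, key=lambda o: o.start)
        for a, b in zip(group, group[1:]):
            if b.start <= a.end:
                raise ConsistencyError(
                    f"overlapping segments in {sample} on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )
    return obs


def segments_frame(obs: list[SegmentObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": o.sample_id, "chrom": o.chrom, "start": o.start,
                "end": o.end, "c": o.c, "baf_dev": o.baf_dev, "n_snps": o.n_snps,
            }
            for o in obs
        ]
    )


def write_tree(tree: CloneTree, path: str | Path) -> None:
    """Emit both a JSON document and a Newick string for the clone tree.

    ``path`` names the JSON file; the Newick goes to the same stem with a
    ``.nwk`` suffix. Branch lengths are per-branch mutation counts, and
    ambiguous attachments are preserved in the JSON.
    """
    path = Path(path)
    path.write_text(json.dumps(tree.to_dict(), sort_keys=True, indent=1) + "\n")
    path.with_suffix(".nwk").write_text(tree.to_newick() + "\n")


def read_tree(path: str | Path) -> CloneTree:
    return CloneTree.from_dict(json.loads(Path(path).read_text()))


def write_composition(
    comps: list[RegionComposition],
    purities: dict[str, float],
    path: str | Path,
) -> None:
    """One row per (sample, node) clone fraction, with per-sample purity."""
    rows = []
    for c in comps:
        c.validate()
        total = sum(c.fractions.values())
        if total > 1 + 1e-6:
            raise InvalidCompositionError(
                f"fractions sum to {total} > 1 in {c.sample_id}"
            )
        for node, frac in sorted(c.fractions.items()):
            rows.append(
                {
                    "sample_id": c.sample_id,
                    "node_id": node,
                    "fraction": repr(float(frac)),
                    "purity": purities.get(c.sample_id, ""),
                    "inferred_only": c.inferred_only,
                    "multi_lineage": c.multi_lineage,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_composition(path: str | Path) -> list[RegionComposition]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "node_id": str})
    out = []
    for sid, grp in df.groupby("sample_id", sort=True):
        out.append(
            RegionComposition(
                sample_id=str(sid),
                fractions={
                    str(r.node_id): float(r.fraction) for _, r in grp.iterrows()
                },
                inferred_only=bool(grp.inferred_only.iloc[0]),
                multi_lineage=bool(grp.multi_lineage.iloc[0]),
            )
        )
    for c in out:
        c.validate()
    return out


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError("config file must hold a mapping")
    return cfg
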