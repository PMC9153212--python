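"""Shared fixtures: small synthetic patients and truth-derived helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from clonescape import (
    MutationCluster,
    ReadCountMatrix,
    SimulationConfig,
    VariantSite,
    compute_ccf_matrix,
    simulate_read_counts,
    simulate_truth,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_regions=4,
        n_normals=2,
        n_clusters=4,
        mutations_per_cluster=(5, 8),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_truth(small_config, seed=11)


@pytest.fixture(scope="session")
def small_counts(small_config, small_truth):
    return simulate_read_counts(small_truth, small_config, seed=12)


def truth_clusters(truth, counts) -> list[MutationCluster]:
    """Cluster CCF estimates using the *true* variant-to-node assignment.

    Separates tree inference from clustering error: per node, the member
    variants' point CCFs (from observed counts under the true copy models)
    are averaged per sample.
    """
    ccf, _ = compute_ccf_matrix(counts, truth.purities, truth.copy_models)
    out = []
    for nid in sorted(truth.tree.nodes):
        members = [v for v, n in truth.variant_assignments.items() if n == nid]
        sub = ccf.loc[[m for m in members if m in ccf.index]]
        out.append(
            MutationCluster(
                cluster_id=nid,
                members=members,
                ccf={s: float(sub[s].mean()) for s in ccf.columns},
            )
        )
    return out


def toy_matrix(
    rows: dict[str, tuple[int, int]], samples: list[str] | None = None
) -> ReadCountMatrix:
    """A one-or-more-sample matrix from {variant_id-ish: (ref, alt)} pairs.

    Keys are 'chrom:pos'; one sample 'S1' unless counts are given as lists.
    """
    variants, refs, alts = [], [], []
    samples = samples or ["S1"]
    for key, counts in rows.items():
        chrom, pos = key.split(":")
        variants.append(VariantSite(chrom, int(pos), "A", "T"))
        if isinstance(counts[0], (tuple, list)):
            refs.append([c[0] for c in counts])
            alts.append([c[1] for c in counts])
        else:
            refs.append([counts[0]])
            alts.append([counts[1]])
    ids = [v.variant_id for v in variants]
    return ReadCountMatrix(
        variants,
        pd.DataFrame(np.array(refs), index=ids, columns=samples),
        pd.DataFrame(np.array(alts), index=ids, columns=samples),
    )
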