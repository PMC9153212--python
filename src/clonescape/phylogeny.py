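"""Clone-tree construction under the sum and crossing rules.

Two principles constrain ancestry among mutation clusters observed across
multiple tumor regions. The sum rule (pigeonhole principle): within any
sample, the CCFs of a node's children cannot sum beyond the node's own
CCF. The crossing rule: if cluster a exceeds cluster b in one sample but b
exceeds a in another, neither can be the other's ancestor — they sit on
branching lineages. The tree search enumerates rooted arborescences over
clusters that satisfy both rules in every retained sample (low-purity
samples are excluded), scores valid trees by how tightly each child nests
in its parent, and records equally-good alternative parents as ambiguous
attachments rather than forcing a resolution.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ccf import is_detected
from .datatypes import (
    CloneNode,
    CloneTree,
    CNVSegment,
    LineageStats,
    MutationCluster,
    PurityEstimate,
    RegionComposition,
)
from .errors import (
    ClassificationUndefinedError,
    IncomparableClustersError,
    InfeasiblePhylogenyError,
    InvalidCompositionError,
)
from .purity import CP_AGREEMENT_TOL, fit_cnv_timing

#: Default absolute CCF tolerance for the sum and crossing rules, matched
#: to binomial noise at ~2500X coverage.
CCF_RULE_TOL = 0.05

#: Samples below this purity are excluded from tree construction; their
#: compositions are inferred from matching clusters in high-purity samples.
MIN_PURITY = 0.05

#: A region is flagged multi-lineage when more than one child-of-founder
#: lineage holds at least this clone fraction.
CO_OCCUPANCY_MIN_FRACTION = 0.05


class Relation(enum.Enum):
    A_CAN_CONTAIN_B = "a_can_contain_b"
    B_CAN_CONTAIN_A = "b_can_contain_a"
    BRANCHING = "branching"
    AMBIGUOUS = "ambiguous"


def pairwise_relation(
    a: MutationCluster, b: MutationCluster, tol: float = CCF_RULE_TOL
) -> Relation:
    """Possible ancestry between two clusters from their CCF profiles.

    a can contain b iff CCF_a >= CCF_b − tol in every shared sample;
    branching iff each exceeds the other (beyond tol) somewhere; when both
    could contain each other within tolerance the relation is ambiguous.
    """
    shared = [
        s
        for s in a.ccf
        if s in b.ccf and not (np.isnan(a.ccf[s]) or np.isnan(b.ccf[s]))
    ]
    if not shared:
        raise IncomparableClustersError(
            f"{a.cluster_id} and {b.cluster_id} share no sample with defined CCF"
        )
    a_holds = all(a.ccf[s] >= b.ccf[s] - tol for s in shared)
    b_holds = all(b.ccf[s] >= a.ccf[s] - tol for s in shared)
    if a_holds and not b_holds:
        return Relation.A_CAN_CONTAIN_B
    if b_holds and not a_holds:
        return Relation.B_CAN_CONTAIN_A
    if a_holds and b_holds:
        return Relation.AMBIGUOUS
    return Relation.BRANCHING


def _usable_samples(
    clusters: list[MutationCluster], purities: dict[str, float]
) -> list[str]:
    samples = sorted({s for c in clusters for s in c.ccf})
    return [s for s in samples if purities.get(s, 0.0) >= MIN_PURITY]


def _sample_weights(
    clusters: list[MutationCluster], purities: dict[str, float], samples: list[str]
) -> dict[str, float]:
    """Weight each sample by purity x mean cluster CCF support.

    When ancestry decisions depend on a cluster measured in several
    samples, the sample most likely to measure CCF accurately (high purity
    and high VAF support) is weighted first.
    """
    out = {}
    for s in samples:
        vals = [c.ccf[s] for c in clusters if s in c.ccf and np.isfinite(c.ccf[s])]
        out[s] = purities.get(s, 0.0) * (float(np.mean(vals)) if vals else 0.0)
    return out


@dataclass
class TreeSearchResult:
    tree: CloneTree
    score: float
    alternatives: list[CloneTree] = field(default_factory=list)


def build_tree(
    clusters: list[MutationCluster],
    purities: dict[str, float] | list[PurityEstimate],
    tol: float = CCF_RULE_TOL,
    max_trees: int = 200_000,
) -> TreeSearchResult:
    """Infer the clone tree satisfying the sum and crossing rules.

    The root is the truncal cluster (highest support-weighted CCF, which
    must be able to contain every other cluster). All parent assignments
    consistent with the crossing rule are enumerated depth-first in
    descending-CCF order with incremental sum-rule pruning. Valid trees are
    scored by the total parent-child CCF gap (summed over samples), so each
    node attaches to the tightest container that the rules allow; among
    score-tied optima one tree is returned and the alternative parents of
    every unstable node are recorded in ``ambiguous_attachments``.

    Clusters detected in every sample with CCF uniformly in [0.5, 1) —
    subclonal-truncal clusters — are attached directly under the founder,
    and ancestry of nodes that could descend from them stays ambiguous.
    """
    if isinstance(purities, list):
        purities = {p.sample_id: p.t for p in purities}
    samples = _usable_samples(clusters, purities)
    if not samples:
        raise InfeasiblePhylogenyError("no samples at or above the purity threshold")
    weights = _sample_weights(clusters, purities, samples)

    def wmean(c: MutationCluster) -> float:
        ws = [(weights[s], c.ccf[s]) for s in samples if s in c.ccf]
        tot = sum(w for w, _ in ws)
        if tot <= 0:
            return float(np.mean([v for _, v in ws])) if ws else 0.0
        return sum(w * v for w, v in ws) / tot

    order = sorted(clusters, key=lambda c: (-wmean(c), c.cluster_id))
    root = order[0]
    rest = order[1:]
    violations = []
    for c in rest:
        rel = pairwise_relation(root, c, tol)
        if rel not in (Relation.A_CAN_CONTAIN_B, Relation.AMBIGUOUS):
            violations.append(
                f"root {root.cluster_id} cannot contain {c.cluster_id} ({rel.value})"
            )
    if violations:
        raise InfeasiblePhylogenyError(
            "no truncal cluster can contain all others", violations
        )

    # subclonal-truncal clusters: present everywhere at a flat CCF uniformly
    # below clonal. A flat profile carries no regional signal to order the
    # cluster against others, so it attaches directly under the founder and
    # downstream ambiguity is recorded rather than resolved.
    forced_root_child = set()
    for c in rest:
        if not all(s in c.ccf for s in samples):
            continue
        vals = [c.ccf[s] for s in samples]
        if (
            all(0.5 <= v < 1.0 - tol for v in vals)
            and max(vals) - min(vals) <= 2 * tol
        ):
            forced_root_child.add(c.cluster_id)

    idx = {c.cluster_id: c for c in clusters}
    ccf_arr = {
        c.cluster_id: np.array([c.ccf.get(s, np.nan) for s in samples])
        for c in clusters
    }
    zero = np.zeros(len(samples))

    def can_contain(p: str, c: str) -> bool:
        rel = pairwise_relation(idx[p], idx[c], tol)
        return rel in (Relation.A_CAN_CONTAIN_B, Relation.AMBIGUOUS)

    def candidates(ordered: bool, forced: bool) -> dict[str, list[str]] | None:
        out: dict[str, list[str]] = {}
        for i, c in enumerate(rest):
            if forced and c.cluster_id in forced_root_child:
                out[c.cluster_id] = [root.cluster_id]
                continue
            pool = [root] + (rest[:i] if ordered else
                             [r for r in rest if r is not c])
            cands = [p.cluster_id for p in pool
                     if can_contain(p.cluster_id, c.cluster_id)]
            if not cands:
                return None
            out[c.cluster_id] = cands
        return out

    # Score: valid trees all reproduce the node CCFs, so they differ only in
    # how much of the rule tolerance they consume. Trees minimizing total
    # slack usage (child-over-parent excess and sum-rule overage, both 0 for
    # the generating tree up to noise) come first; the parent-child CCF gap
    # is only a tie-break that prefers the tightest container.
    _SLACK_WEIGHT = 1e4

    def edge_cost(parent: str, child: str) -> float:
        diff = ccf_arr[parent] - ccf_arr[child]
        violation = float(np.nansum(np.maximum(-diff, 0.0)))
        gap = float(np.nansum(np.abs(diff)))
        return _SLACK_WEIGHT * violation + gap

    def run_search(
        allowed_parents: dict[str, list[str]], ordered: bool
    ) -> tuple[float, list[dict[str, str]]]:
        best_score = np.inf
        best_assignments: list[dict[str, str]] = []
        n_seen = 0
        child_sum = {c.cluster_id: zero.copy() for c in clusters}
        parent_of: dict[str, str] = {}

        def sum_ok(parent: str, child: str) -> bool:
            s = child_sum[parent] + np.nan_to_num(ccf_arr[child])
            cap = np.nan_to_num(ccf_arr[parent], nan=np.inf)
            return bool(np.all(s <= cap + tol))

        def chain_ok(parent: str, child: str) -> bool:
            # ancestors so far must contain child; no cycle through child
            cur: str | None = parent
            while cur is not None and cur != root.cluster_id:
                if cur == child:
                    return False
                cur = parent_of.get(cur)
            cur = parent_of.get(parent)
            while cur is not None:
                if not can_contain(cur, child):
                    return False
                cur = parent_of.get(cur)
            return True

        def complete_ok() -> bool:
            # in unordered mode ancestry is only fully known at the leaf
            for child in parent_of:
                cur = parent_of[child]
                seen = 0
                while cur != root.cluster_id:
                    if not can_contain(cur, child):
                        return False
                    cur = parent_of[cur]
                    seen += 1
                    if seen > len(rest):
                        return False
            return True

        def search(i: int, score: float) -> None:
            nonlocal best_score, n_seen
            if score > best_score + 1e-9 or n_seen > max_trees:
                return
            if i == len(rest):
                if not ordered and not complete_ok():
                    return
                n_seen += 1
                if score < best_score - 1e-9:
                    best_score = score
                    best_assignments.clear()
                if abs(score - best_score) <= 1e-9:
                    best_assignments.append(dict(parent_of))
                return
            child = rest[i].cluster_id
            for p in allowed_parents[child]:
                if not sum_ok(p, child) or not chain_ok(p, child):
                    continue
                cap = np.nan_to_num(ccf_arr[p], nan=np.inf)
                over_old = float(np.maximum(child_sum[p] - cap, 0.0).sum())
                parent_of[child] = p
                child_sum[p] = child_sum[p] + np.nan_to_num(ccf_arr[child])
                over_new = float(np.maximum(child_sum[p] - cap, 0.0).sum())
                search(
                    i + 1,
                    score
                    + edge_cost(p, child)
                    + _SLACK_WEIGHT * (over_new - over_old),
                )
                child_sum[p] = child_sum[p] - np.nan_to_num(ccf_arr[child])
                del parent_of[child]

        search(0, 0.0)
        return best_score, best_assignments

    # forcing first; without it if infeasible; unordered exhaustive last,
    # for near-tie profiles where a valid parent sorts below its child
    best_score, best_assignments = np.inf, []
    for ordered, forced in ((True, True), (True, False), (False, False)):
        allowed = candidates(ordered, forced)
        if allowed is None:
            continue
        best_score, best_assignments = run_search(allowed, ordered)
        if best_assignments:
            break
    if not best_assignments:
        raise InfeasiblePhylogenyError(
            "no rooted tree satisfies the sum and crossing rules",
            ["sum rule violated for every parent assignment"],
        )

    chosen = best_assignments[0]
    ambiguous: dict[str, list[str]] = {}
    for child in chosen:
        parents = sorted({a[child] for a in best_assignments})
        if len(parents) > 1:
            ambiguous[child] = [p for p in parents if p != chosen[child]]

    # A node whose re-attachment to another parent still satisfies both
    # rules is genuinely ambiguous: the data admit multiple valid trees
    # and the alternatives are reported rather than silently resolved.
    children_of: dict[str, list[str]] = {c.cluster_id: [] for c in clusters}
    for child, p in chosen.items():
        children_of[p].append(child)

    def subtree_ids(node: str) -> set[str]:
        out, stack = set(), [node]
        while stack:
            n = stack.pop()
            out.add(n)
            stack.extend(children_of[n])
        return out

    for child, pc in chosen.items():
        sub = subtree_ids(child)
        alts = set(ambiguous.get(child, []))
        for p in [root.cluster_id] + [c.cluster_id for c in rest]:
            if p == pc or p in sub or not can_contain(p, child):
                continue
            # every ancestor of the new parent must also contain the child
            ok, cur = True, p
            while cur != root.cluster_id:
                cur = chosen[cur]
                if cur != root.cluster_id and not can_contain(cur, child):
                    ok = False
                    break
            if not ok:
                continue
            # sum rule at the new parent with its existing children
            kids = [k for k in children_of[p] if k != child] + [child]
            total = np.sum(
                [np.nan_to_num(ccf_arr[k]) for k in kids], axis=0
            )
            cap = np.nan_to_num(ccf_arr[p], nan=np.inf)
            if np.all(total <= cap + tol):
                alts.add(p)
        if alts:
            ambiguous[child] = sorted(alts)

    nodes = [
        CloneNode(
            node_id=root.cluster_id,
            parent_id=None,
            cluster_id=root.cluster_id,
            n_mutations=root.size,
        )
    ]
    for c in rest:
        nodes.append(
            CloneNode(
                node_id=c.cluster_id,
                parent_id=chosen[c.cluster_id],
                cluster_id=c.cluster_id,
                n_mutations=c.size,
            )
        )
    tree = CloneTree(nodes)
    tree.ambiguous_attachments = ambiguous
    alternatives = []
    for a in best_assignments[1:21]:
        alt_nodes = [CloneNode(root.cluster_id, None, root.cluster_id,
                               n_mutations=root.size)]
        for c in rest:
            alt_nodes.append(
                CloneNode(c.cluster_id, a[c.cluster_id], c.cluster_id,
                          n_mutations=c.size)
            )
        alternatives.append(CloneTree(alt_nodes))
    return TreeSearchResult(tree=tree, score=best_score, alternatives=alternatives)


def node_ccf_frame(
    tree: CloneTree, clusters: list[MutationCluster], samples: list[str]
) -> pd.DataFrame:
    """CCF of each tree node per sample, taken from its mutation cluster."""
    idx = {c.cluster_id: c for c in clusters}
    rows = {}
    for nid, node in tree.nodes.items():
        cl = idx.get(node.cluster_id) if node.cluster_id else None
        rows[nid] = [cl.ccf.get(s, np.nan) if cl else np.nan for s in samples]
    return pd.DataFrame.from_dict(rows, orient="index", columns=samples)


def place_cnv_events(
    tree: CloneTree,
    segments: list[CNVSegment],
    purities: dict[str, float],
    clusters: list[MutationCluster],
    tol: float = CP_AGREEMENT_TOL,
) -> tuple[CloneTree, list[str]]:
    """Assign each CNV to the tree node whose CCF profile matches CP/t.

    A truncal event shows CP ~ t in every region; a lineage-specific one
    tracks its branch's CCF. Contested placements fall through to the
    early-versus-late least-squares fit; events matching no node are
    returned unplaced.
    """
    samples = [s for s in purities if purities[s] >= MIN_PURITY]
    ccf = node_ccf_frame(tree, clusters, samples)
    unplaced = []
    for seg in segments:
        best, _ = fit_cnv_timing(seg, list(tree.nodes), ccf, purities, tol=tol)
        if best is None:
            unplaced.append(seg.segment_id)
            continue
        tree.nodes[best.node_id].cnv_events.append(seg.segment_id)
    return tree, unplaced


def decompose_regions(
    tree: CloneTree,
    clusters: list[MutationCluster],
    purities: dict[str, float] | list[PurityEstimate],
    tol: float = CCF_RULE_TOL,
) -> list[RegionComposition]:
    """Per-region clone fractions from node CCFs.

    The fraction of cancer cells belonging exactly to a node's clone is its
    CCF minus the summed CCF of its children (clipped at zero within
    tolerance). A founder clone of only truncal variants absorbs whatever
    the root's descendants leave unexplained, so fractions sum to 1.
    Low-purity samples are not decomposed directly: their compositions are
    inferred from the clusters measured in high-purity samples and flagged.
    """
    if isinstance(purities, list):
        purities = {p.sample_id: p.t for p in purities}
    samples = sorted({s for c in clusters for s in c.ccf})
    high = [s for s in samples if purities.get(s, 0.0) >= MIN_PURITY]
    ccf = node_ccf_frame(tree, clusters, samples)
    root_children = tree.children(tree.root)
    out = []
    for s in samples:
        fractions: dict[str, float] = {}
        for nid in tree.nodes:
            val = ccf.loc[nid, s]
            if np.isnan(val):
                val = 0.0
            kids = sum(
                0.0 if np.isnan(ccf.loc[k, s]) else float(ccf.loc[k, s])
                for k in tree.children(nid)
            )
            frac = float(val) - kids
            if frac < -tol:
                raise InvalidCompositionError(
                    f"node {nid} in sample {s}: children CCFs exceed the node's "
                    f"by {-frac:.3f} (beyond tolerance {tol})"
                )
            fractions[nid] = max(frac, 0.0)
        non_root = sum(v for k, v in fractions.items() if k != tree.root)
        fractions[tree.root] = max(1.0 - non_root, 0.0)
        total = sum(fractions.values())
        if total > 0:
            fractions = {k: v / total for k, v in fractions.items()}
        lineage_mass = {
            ch: sum(fractions[n] for n in tree.subtree(ch)) for ch in root_children
        }
        multi = sum(m > CO_OCCUPANCY_MIN_FRACTION for m in lineage_mass.values()) > 1
        out.append(
            RegionComposition(
                sample_id=s,
                fractions=fractions,
                inferred_only=s not in high,
                multi_lineage=multi,
            )
        )
    for comp in out:
        comp.validate()
    return out


class VariantClassLabel(str, enum.Enum):
    TRUNCAL = "truncal"
    SHARED = "shared"
    PRIVATE = "private"


def classify_variants(
    counts: ReadCountMatrix,
    purities: dict[str, float],
    min_alt: int = 3,
    min_vaf: float = 0.002,
) -> dict[str, VariantClassLabel]:
    """Truncal / shared / private labels from presence across tumor regions.

    A variant is truncal when detected in all usable tumor regions, shared
    when in at least two but not all, private when in exactly one. Regions
    below the purity threshold are excluded. Variants detected nowhere are
    omitted from the result.
    """
    usable = [s for s in counts.samples if purities.get(s, 0.0) >= MIN_PURITY]
    if len(usable) < 2:
        raise ClassificationUndefinedError(
            f"need >= 2 tumor samples above purity {MIN_PURITY}, have {len(usable)}"
        )
    alt = counts.alt[usable]
    depth = counts.depth[usable]
    out: dict[str, VariantClassLabel] = {}
    for vid in counts.variant_ids:
        present = sum(
            int(alt.loc[vid, s]) >= min_alt
            and depth.loc[vid, s] > 0
            and alt.loc[vid, s] / depth.loc[vid, s] >= min_vaf
            for s in usable
        )
        if present == 0:
            continue
        if present == len(usable):
            out[vid] = VariantClassLabel.TRUNCAL
        elif present == 1:
            out[vid] = VariantClassLabel.PRIVATE
        else:
            out[vid] = VariantClassLabel.SHARED
    return out


def classification_summary(labels: dict[str, VariantClassLabel]) -> dict[str, float]:
    n = len(labels)
    counts = {
        lab.value: sum(1 for v in labels.values() if v == lab)
        for lab in VariantClassLabel
    }
    pct = {f"{k}_pct": (100.0 * v / n if n else np.nan) for k, v in counts.items()}
    return {**counts, **pct, "n_classified": n}


def lineage_stats(
    tree: CloneTree,
    comps: list[RegionComposition],
    purities: dict[str, float],
) -> tuple[list[LineageStats], tuple[float, float] | None]:
    """Molecular age and average CCF of each major lineage.

    A major lineage is a child branch of the founder. Its molecular age is
    the number of mutations from the trunk (exclusive) to its most distant
    descendant; its average CCF sums the clone fractions of all nodes in
    the lineage's subtree in each qualifying region (purity >= 5%) and
    averages over regions. Returns the per-lineage table and the Pearson
    (r, p) between age and average CCF — None when fewer than three
    lineages make the correlation undefined.
    """
    excluded = [c.sample_id for c in comps if purities.get(c.sample_id, 0) < MIN_PURITY]
    qualifying = [c for c in comps if c.sample_id not in excluded]
    stats_out: list[LineageStats] = []
    for ch in tree.children(tree.root):
        sub = tree.subtree(ch)
        ages = []
        for nid in sub:
            path = 0
            cur: str | None = nid
            while cur is not None and cur != tree.root:
                path += tree.nodes[cur].n_mutations
                cur = tree.nodes[cur].parent_id
            ages.append(path)
        avg = float(
            np.mean(
                [sum(c.fractions.get(n, 0.0) for n in sub) for c in qualifying]
            )
        ) if qualifying else np.nan
        stats_out.append(
            LineageStats(
                lineage_id=ch,
                molecular_age=int(max(ages)),
                average_ccf=avg,
                regions_excluded=list(excluded),
            )
        )
    corr = None
    if len(stats_out) >= 3:
        x = [s.molecular_age for s in stats_out]
        y = [s.average_ccf for s in stats_out]
        if np.std(x) > 0 and np.std(y) > 0:
            r, p = stats.pearsonr(x, y)
            corr = (float(r), float(p))
    return stats_out, corr
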