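"""Clonal delineation, perfect-phylogeny clone trees and the ITB index.

Regions that share somatic mutations belong to the same tumor; connected
components of the sharing graph therefore partition a patient's regions
into clonally independent tumors. Within a tumor, mutations with
identical region-presence patterns collapse into clones, and the clones
form a tree under strict containment of their region sets (a two-state
perfect phylogeny: any two presence sets must be nested or disjoint).

The intra-tumor branch-to-trunk (ITB) index summarises heterogeneity as
the mean per-region count of non-ubiquitous (branch) mutations divided by
the number of ubiquitous (trunk) mutations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .variants import MutationMatrix, _round_half_up

__all__ = [
    "TumorPartition",
    "CloneTree",
    "Clone",
    "ItbResult",
    "PerfectPhylogenyError",
    "delineate_tumors",
    "build_clone_tree",
    "classify_topology",
    "itb_index",
]


class PerfectPhylogenyError(ValueError):
    """Two mutations have overlapping but non-nested region sets."""

    def __init__(self, mut_a: str, mut_b: str):
        self.pair = (mut_a, mut_b)
        super().__init__(
            f"mutations {mut_a!r} and {mut_b!r} violate the perfect-phylogeny "
            "(two-column compatibility) condition"
        )


@dataclass
class TumorPartition:
    """Blocks of regions of shared clonal origin."""

    blocks: dict[str, list[str]]                  # tumor id -> regions
    evidence: pd.DataFrame                        # pairwise shared-mutation counts
    conflicts: list[str] = field(default_factory=list)

    @property
    def n_tumors(self) -> int:
        return len(self.blocks)

    def tumor_of(self, region: str) -> str:
        for tid, regs in self.blocks.items():
            if region in regs:
                return tid
        raise KeyError(region)

    def to_frame(self) -> pd.DataFrame:
        rows = [(r, tid) for tid, regs in self.blocks.items() for r in regs]
        return pd.DataFrame(rows, columns=["region", "tumor_id"])


def _presence_of(matrix: MutationMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(matrix, MutationMatrix):
        return matrix.somatic_mutations()
    return matrix.astype(int)


def delineate_tumors(
    matrix: MutationMatrix | pd.DataFrame,
    breakpoints: Mapping[str, float] | None = None,
    min_shared: int = 1,
    breakpoint_tol: float = 1_000_000.0,
) -> TumorPartition:
    """Partition regions into clonally independent tumors.

    Regions are graph nodes; an edge joins two regions sharing at least
    ``min_shared`` somatic mutations; blocks are the connected components.
    When per-region chromosome-3p breakpoints are supplied, blocks whose
    regions carry breakpoints further apart than ``breakpoint_tol`` bases
    are flagged as conflicts.
    """
    presence = _presence_of(matrix)
    if presence.empty:
        raise ValueError("empty mutation matrix")
    regions = list(presence.columns)
    shared = presence.T.dot(presence)  # region x region shared counts
    shared = pd.DataFrame(shared, index=regions, columns=regions)

    # union-find over regions
    parent = {r: r for r in regions}

    def find(r: str) -> str:
        while parent[r] != r:
            parent[r] = parent[parent[r]]
            r = parent[r]
        return r

    for i, a in enumerate(regions):
        for b in regions[i + 1:]:
            if shared.loc[a, b] >= min_shared:
                parent[find(a)] = find(b)

    blocks: dict[str, list[str]] = {}
    order: dict[str, int] = {}
    for r in regions:
        root = find(r)
        if root not in order:
            order[root] = len(order) + 1
        blocks.setdefault(root, []).append(r)
    named = {f"tumor_{order[root]}": regs
             for root, regs in sorted(blocks.items(), key=lambda kv: order[kv[0]])}

    conflicts: list[str] = []
    if breakpoints is not None:
        for tid, regs in named.items():
            bps = [breakpoints[r] for r in regs if r in breakpoints]
            if bps and (max(bps) - min(bps)) > breakpoint_tol:
                conflicts.append(tid)
    return TumorPartition(named, shared, conflicts)


@dataclass
class Clone:
    clone_id: str
    mutations: list[str]
    regions: frozenset[str]
    parent: str | None = None


@dataclass
class CloneTree:
    """Nested clone structure of one tumor."""

    clones: dict[str, Clone]
    regions: list[str]

    @property
    def root(self) -> Clone:
        for c in self.clones.values():
            if c.parent is None:
                return c
        raise ValueError("tree has no root")

    def children(self, clone_id: str) -> list[Clone]:
        return [c for c in self.clones.values() if c.parent == clone_id]

    @property
    def topology(self) -> str:
        return classify_topology(self)

    def trunk_mutations(self) -> list[str]:
        return list(self.root.mutations)

    def region_clone(self, region: str) -> Clone:
        """Most specific clone containing a region (leaf assignment)."""
        best = None
        for c in self.clones.values():
            if region in c.regions and (best is None or len(c.regions) < len(best.regions)):
                best = c
        if best is None:
            raise KeyError(region)
        return best

    def to_presence(self) -> pd.DataFrame:
        """Reconstruct the mutation x region presence matrix."""
        rows = {}
        for c in self.clones.values():
            for m in c.mutations:
                rows[m] = [1 if r in c.regions else 0 for r in self.regions]
        return pd.DataFrame.from_dict(rows, orient="index", columns=self.regions).astype(int)

    def parent_map(self) -> dict[str, str | None]:
        return {cid: c.parent for cid, c in self.clones.items()}

    def to_newick(self) -> str:
        from . import io as tio
        return tio.tree_to_newick(self.parent_map())

    def to_json(self) -> str:
        payload = {
            "regions": self.regions,
            "clones": [
                {"clone_id": c.clone_id, "parent": c.parent,
                 "mutations": sorted(c.mutations), "regions": sorted(c.regions)}
                for c in self.clones.values()
            ],
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CloneTree":
        payload = json.loads(text)
        clones = {
            c["clone_id"]: Clone(c["clone_id"], list(c["mutations"]),
                                 frozenset(c["regions"]), c["parent"])
            for c in payload["clones"]
        }
        return cls(clones, list(payload["regions"]))


def build_clone_tree(matrix: MutationMatrix | pd.DataFrame) -> CloneTree:
    """Build the clone tree of one tumor from its somatic mutation matrix.

    Mutations with identical region-presence patterns collapse into one
    clone; clones are ordered by strict containment of their region sets,
    with the ubiquitous mutations forming the trunk. Raises
    :class:`PerfectPhylogenyError` (naming an offending mutation pair)
    when two presence sets overlap without nesting.
    """
    presence = _presence_of(matrix)
    presence = presence.loc[presence.sum(axis=1) > 0]
    if presence.empty:
        raise ValueError("tumor matrix contains no somatic mutations")
    regions = list(presence.columns)

    # group mutations by identical presence pattern
    patterns: dict[frozenset[str], list[str]] = {}
    for mut, row in presence.iterrows():
        key = frozenset(r for r in regions if row[r])
        patterns.setdefault(key, []).append(mut)

    # pairwise compatibility: nested or disjoint
    keys = list(patterns)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            inter = a & b
            if inter and not (a <= b or b <= a):
                raise PerfectPhylogenyError(patterns[a][0], patterns[b][0])

    ordered = sorted(keys, key=lambda k: (-len(k), sorted(k)))
    all_regions = frozenset(regions)
    clones: dict[str, Clone] = {}
    virtual_root = ordered[0] != all_regions
    if virtual_root:
        clones["root"] = Clone("root", [], all_regions, None)

    key_ids: dict[frozenset[str], str] = {}
    for idx, key in enumerate(ordered):
        cid = f"clone_{idx + 1}"
        key_ids[key] = cid
        # parent: smallest strict superset among earlier clones
        parent_key = None
        for cand in ordered[:idx]:
            if key < cand and (parent_key is None or len(cand) < len(parent_key)):
                parent_key = cand
        if parent_key is not None:
            parent = key_ids[parent_key]
        else:
            parent = "root" if virtual_root else None
        clones[cid] = Clone(cid, sorted(patterns[key]), key, parent)

    return CloneTree(clones, regions)


def classify_topology(tree: CloneTree) -> str:
    """``linear`` when every clone has at most one child, else ``branched``."""
    for cid in tree.clones:
        if len(tree.children(cid)) > 1:
            return "branched"
    return "linear"


@dataclass(frozen=True)
class ItbResult:
    value: float
    n_ubiquitous: int
    mean_nonubiquitous_per_biopsy: float


def itb_index(
    matrix: MutationMatrix | pd.DataFrame,
    round_dp: int = 2,
    include_cna: bool = False,
) -> ItbResult:
    """Branch-to-trunk index of one tumor.

    Mean per-region count of non-ubiquitous somatic mutations divided by
    the number of ubiquitous (trunk) mutations, rounded half-up. By
    default only SNV/indel rows count; ``include_cna=True`` adds
    copy-number rows.
    """
    if isinstance(matrix, MutationMatrix):
        presence = matrix.somatic if include_cna else matrix.somatic_mutations()
    else:
        presence = matrix.astype(int)
    presence = presence.loc[presence.sum(axis=1) > 0]
    n_regions = presence.shape[1]
    counts = presence.sum(axis=1)
    n_ubiq = int((counts == n_regions).sum())
    if n_ubiq == 0:
        raise ValueError("ITB undefined: no ubiquitous mutations")
    branch = presence.loc[counts < n_regions]
    mean_branch = float(branch.sum(axis=0).mean()) if len(branch) else 0.0
    value = _round_half_up(mean_branch / n_ubiq, round_dp)
    return ItbResult(value, n_ubiq, mean_branch)
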