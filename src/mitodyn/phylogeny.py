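"""Neighbor-Joining phylogeny of tumor samples from mt variant profiles.

Samples of one patient (primary plus relapses) are encoded as
pseudo-sequences over the variant sites passing the permissive abundance
threshold (1%) in at least one sample: a sample's character at a site is
the alt base where the variant is present, the reference base otherwise.
Pairwise distances are Jukes-Cantor corrected proportions of differing
sites, optionally with gamma-distributed rate variation among sites
(shape 0.75 by default), in units of base substitutions per site.  Trees
are built with the classic Saitou-Nei Neighbor-Joining agglomeration and
interior branches receive site-bootstrap bipartition support.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "SaturationError",
    "VariantMatrix",
    "build_variant_matrix",
    "jc_distance",
    "jc_gamma_distance",
    "p_distance_matrix",
    "distance_matrix",
    "neighbor_joining",
    "bipartitions",
    "bootstrap_support",
    "write_newick",
]

_BASES = set("ACGT")


class SaturationError(ValueError):
    """Raised when the observed proportion of differing sites reaches the
    Jukes-Cantor saturation bound p >= 3/4, where the corrected distance
    is undefined."""


@dataclass
class VariantMatrix:
    """Character matrix over variant sites.

    ``matrix[i][j]`` is the base carried by ``sample_ids[i]`` at
    ``site_keys[j]`` (a ``(pos, ref, alt)`` tuple): the alt base where
    the sample carries the variant, the ref base otherwise.
    """

    sample_ids: list[str]
    site_keys: list[tuple[int, str, str]]
    matrix: np.ndarray  # (n_samples, n_sites) of single characters

    @property
    def n_sites(self) -> int:
        return len(self.site_keys)

    def resample_sites(self, rng: np.random.Generator) -> "VariantMatrix":
        """Bootstrap replicate: sites drawn with replacement."""
        idx = rng.integers(0, self.n_sites, size=self.n_sites)
        return VariantMatrix(
            sample_ids=self.sample_ids,
            site_keys=[self.site_keys[i] for i in idx],
            matrix=self.matrix[:, idx],
        )


def build_variant_matrix(
    samples: Mapping[str, pd.DataFrame],
    threshold: float = 0.01,
    min_depth: int = 50,
) -> VariantMatrix:
    """Encode >= 3 samples' SNVs as a character matrix.

    Only single-base substitutions enter the matrix (indels carry no
    single-character state).  A site appears if the variant passes the
    abundance threshold (and depth filter) in at least one sample; sites
    where every sample would carry the reference base cannot arise by
    construction.  Sites are ordered by genomic position, then alt base.
    Samples with no call at a site are taken as reference-covered.
    """
    if len(samples) < 3:
        raise ValueError(
            f"Neighbor-Joining needs >= 3 samples, got {len(samples)}"
        )
    sample_ids = list(samples)
    present: dict[tuple[int, str, str], set[str]] = {}
    for sid, tab in samples.items():
        for r in tab.itertuples():
            if len(r.ref) != 1 or len(r.alt) != 1:
                continue
            if r.ref not in _BASES or r.alt not in _BASES:
                continue
            if r.af >= threshold and r.dp > min_depth:
                present.setdefault((r.pos, r.ref, r.alt), set()).add(sid)
    site_keys = sorted(present)
    mat = np.empty((len(sample_ids), len(site_keys)), dtype="<U1")
    for j, key in enumerate(site_keys):
        pos, ref, alt = key
        carriers = present[key]
        for i, sid in enumerate(sample_ids):
            mat[i, j] = alt if sid in carriers else ref
    return VariantMatrix(sample_ids=sample_ids, site_keys=site_keys, matrix=mat)


# ---------------------------------------------------------------------------
# Distances


def jc_distance(p: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - 4p/3)."""
    if not 0 <= p < 0.75:
        raise SaturationError(
            f"proportion of differing sites p={p} outside [0, 3/4)"
        )
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_gamma_distance(p: float, shape: float = 0.75) -> float:
    """Jukes-Cantor distance under gamma rate variation among sites.

    d = (3a/4) [ (1 - 4p/3)^(-1/a) - 1 ] with shape parameter ``a``;
    converges to :func:`jc_distance` as a -> infinity.
    """
    if shape <= 0:
        raise ValueError("gamma shape must be > 0")
    if not 0 <= p < 0.75:
        raise SaturationError(
            f"proportion of differing sites p={p} outside [0, 3/4)"
        )
    return 0.75 * shape * ((1.0 - 4.0 * p / 3.0) ** (-1.0 / shape) - 1.0)


def p_distance_matrix(vm: VariantMatrix) -> np.ndarray:
    """Pairwise proportion of differing sites (denominator = all sites)."""
    n = len(vm.sample_ids)
    if vm.n_sites == 0:
        return np.zeros((n, n))
    diff = (vm.matrix[:, None, :] != vm.matrix[None, :, :]).mean(axis=2)
    return diff


def distance_matrix(
    vm: VariantMatrix,
    model: Literal["p", "jc", "jc_gamma"] = "jc_gamma",
    shape: float = 0.75,
) -> DistanceMatrix:
    """Evolutionary distance matrix under the chosen correction."""
    p = p_distance_matrix(vm)
    if model == "p":
        d = p
    else:
        d = np.zeros_like(p)
        it = np.nditer(p, flags=["multi_index"])
        for val in it:
            i, j = it.multi_index
            if i == j:
                continue
            d[i, j] = (
                jc_distance(float(val)) if model == "jc"
                else jc_gamma_distance(float(val), shape)
            )
    return DistanceMatrix(d, ids=vm.sample_ids)


# ---------------------------------------------------------------------------
# Neighbor-Joining


def neighbor_joining(
    dist: DistanceMatrix,
    negative_branches: Literal["clamp", "allow"] = "clamp",
) -> TreeNode:
    """Classic Saitou-Nei Neighbor-Joining.

    Iteratively joins the pair minimizing the Q criterion
    ``Q_ij = (n-2) d_ij - r_i - r_j`` (ties broken toward the lowest
    index pair), computes the branch lengths to the new interior node and
    reduces the matrix, terminating in an unrooted tree represented with
    a trifurcating root.  On an additive matrix the tree's path lengths
    reproduce the input distances exactly.

    Negative branch lengths, which NJ can produce on non-additive input,
    are by default clamped to zero with the deficit moved to the sibling
    branch so that path lengths through the join are preserved.
    """
    d = np.array(dist.data, dtype=float)
    ids = list(dist.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("Neighbor-Joining needs >= 3 taxa")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    if (d[~np.eye(n, dtype=bool)] < 0).any():
        raise ValueError("distance matrix has negative off-diagonal entries")

    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]

    def _fix_negative(li: float, lj: float) -> tuple[float, float]:
        if negative_branches == "allow":
            return li, lj
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie-break: flat argmin scans rows then columns
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = _fix_negative(li, lj)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])
        # reduced distances to the new node
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        new_d = np.empty((m - 1, m - 1))
        new_d[:-1, :-1] = d[np.ix_(keep, keep)]
        new_d[-1, :-1] = dk[keep]
        new_d[:-1, -1] = dk[keep]
        new_d[-1, -1] = 0.0
        d = new_d
        nodes = [nodes[k] for k in keep] + [parent]

    # terminal three-taxon star: solve the three-point formulas
    l0 = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    l1 = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    l2 = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    lengths = [l0, l1, l2]
    if negative_branches == "clamp":
        lengths = [max(x, 0.0) for x in lengths]
    root = TreeNode()
    for node, ln in zip(nodes, lengths):
        node.length = ln
        root.append(node)
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Canonical leaf bipartitions induced by the tree's interior branches.

    Each interior (non-root, non-tip) node's branch splits the leaves in
    two; the side not containing the alphabetically first leaf is the
    canonical representative.  Trivial splits (single leaf) are excluded.
    """
    all_tips = frozenset(t.name for t in tree.tips())
    anchor = min(all_tips)
    parts: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = all_tips - side
        if len(side) >= 2 and len(all_tips) - len(side) >= 2:
            parts.add(side)
    return parts


def bootstrap_support(
    vm: VariantMatrix,
    replicates: int = 1000,
    model: Literal["p", "jc", "jc_gamma"] = "jc_gamma",
    shape: float = 0.75,
    seed: int | None = None,
    negative_branches: Literal["clamp", "allow"] = "clamp",
) -> tuple[TreeNode, dict]:
    """NJ tree of the full matrix with site-bootstrap bipartition support.

    Site columns are resampled with replacement ``replicates`` times; a
    replicate whose distances saturate (p >= 3/4) is skipped and counted.
    Each interior branch of the full-data tree is labeled with the
    percentage of successful replicates whose tree contains the same leaf
    bipartition.  Returns the annotated tree and a run report with the
    number of skipped replicates.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    # canonical sample order so support is invariant to input permutation
    order = np.argsort(vm.sample_ids)
    vm = VariantMatrix(
        sample_ids=[vm.sample_ids[i] for i in order],
        site_keys=vm.site_keys,
        matrix=vm.matrix[order],
    )
    tree = neighbor_joining(
        distance_matrix(vm, model=model, shape=shape),
        negative_branches=negative_branches,
    )
    counts: dict[frozenset[str], int] = {b: 0 for b in bipartitions(tree)}
    rng = np.random.default_rng(seed)
    skipped = 0
    for _ in range(replicates):
        rep = vm.resample_sites(rng)
        try:
            rep_tree = neighbor_joining(
                distance_matrix(rep, model=model, shape=shape),
                negative_branches=negative_branches,
            )
        except SaturationError:
            skipped += 1
            continue
        rep_parts = bipartitions(rep_tree)
        for b in counts:
            if b in rep_parts:
                counts[b] += 1
    effective = replicates - skipped
    all_tips = frozenset(vm.sample_ids)
    anchor = min(all_tips)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = all_tips - side
        if side in counts and effective > 0:
            node.name = str(round(100.0 * counts[side] / effective))
    report = {
        "replicates": replicates,
        "skipped_saturated": skipped,
        "support": {
            "|".join(sorted(b)): (100.0 * c / effective if effective else None)
            for b, c in counts.items()
        },
    }
    if replicates and skipped > 0.1 * replicates:
        report["warning"] = (
            f"{skipped}/{replicates} bootstrap replicates were saturated "
            "and skipped; supports may be unreliable"
        )
    return tree, report


def write_newick(tree: TreeNode, sink=None) -> str:
    """Serialize a tree to Newick (branch lengths; supports as interior
    node labels).  Round-trips through any generic Newick parser."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue()
    if sink is not None:
        if hasattr(sink, "write"):
            sink.write(text)
        else:
            with open(sink, "w") as fh:
                fh.write(text)
    return text
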