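"""Phylogenies, independent contrasts, contrast correlation, FDR.

Cross-species family sizes are not independent observations: species
inherit them from common ancestors.  Felsenstein's phylogenetic
independent contrasts (PIC) transform n tip values on a rooted
bifurcating tree into n-1 standardized differences that are independent
and identically distributed under Brownian-motion evolution, so ordinary
correlation applies to the contrasts.  This module provides the tree
container (backed by dendropy for newick I/O), the PIC recursion, the
contrast correlation with its t-test, Benjamini-Hochberg FDR, and the
trait-by-family correlation screen.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from stramtf.errors import ConsistencyError, ParseError
from stramtf.rule_engine import FamilySizeMatrix

__all__ = [
    "TreeNode",
    "Phylogeny",
    "ContrastSet",
    "ContrastCorrelationResult",
    "parse_newick",
    "read_newick",
    "pic_contrasts",
    "contrast_correlation",
    "bh_fdr",
    "correlate_families",
    "read_traits",
    "write_traits",
]

DEFAULT_ZERO_LENGTH_EPSILON = 1e-8


@dataclass
class TreeNode:
    """Lightweight build-time node: label, parent-edge length, children."""

    label: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)


class Phylogeny:
    """Rooted, strictly bifurcating tree with positive branch lengths.

    Nodes are stored in postorder in flat arrays for fast traversal:
    ``left[k]``/``right[k]`` are child indices (-1 for tips), ``blen[k]``
    is the length of the edge above node k (0 for the root), and
    ``labels[k]`` names the node.  Tips keep their input labels; unnamed
    internal nodes get deterministic labels ``n1, n2, ...`` in postorder.
    """

    def __init__(
        self,
        left: np.ndarray,
        right: np.ndarray,
        blen: np.ndarray,
        labels: list[str],
    ) -> None:
        self.left = left
        self.right = right
        self.blen = blen
        self.labels = labels
        self.n_nodes = len(labels)
        self.root = self.n_nodes - 1  # postorder: root is last
        self.is_tip = left < 0
        self.tip_labels: list[str] = [labels[i] for i in np.flatnonzero(self.is_tip)]
        self.tip_index: dict[str, int] = {
            labels[i]: i for i in np.flatnonzero(self.is_tip)
        }
        self.parent = np.full(self.n_nodes, -1, dtype=np.int64)
        for k in range(self.n_nodes):
            if left[k] >= 0:
                self.parent[left[k]] = k
                self.parent[right[k]] = k

    # -- construction -------------------------------------------------

    @classmethod
    def from_node(
        cls,
        root: TreeNode,
        *,
        resolve_polytomies: bool = False,
        zero_length_epsilon: float = DEFAULT_ZERO_LENGTH_EPSILON,
        default_length: float | None = None,
    ) -> "Phylogeny":
        if resolve_polytomies:
            _resolve_polytomies(root)
        left: list[int] = []
        right: list[int] = []
        blen: list[float] = []
        labels: list[str] = []
        counter = [0]

        def visit(node: TreeNode, is_root: bool) -> int:
            nk = len(node.children)
            if nk == 1 or nk > 2:
                raise ParseError(
                    f"node {node.label or '(unnamed)'} has {nk} children; the tree "
                    "must be strictly bifurcating (set resolve_polytomies=True to "
                    "resolve arbitrarily)"
                )
            child_idx = [visit(c, False) for c in node.children]
            if is_root:
                length = 0.0
            else:
                length = node.length
                if length is None:
                    if default_length is None:
                        raise ParseError(
                            f"edge above {node.label or '(unnamed)'} has no branch "
                            "length"
                        )
                    length = default_length
                if length < 0:
                    raise ParseError(
                        f"negative branch length {length} above {node.label}"
                    )
                if length == 0:
                    warnings.warn(
                        f"zero-length branch above {node.label or '(unnamed)'} "
                        f"replaced by epsilon {zero_length_epsilon}",
                        stacklevel=2,
                    )
                    length = zero_length_epsilon
            if nk == 0:
                if not node.label:
                    raise ParseError("tip without a label")
                label = node.label
                left.append(-1)
                right.append(-1)
            else:
                counter[0] += 1
                label = node.label or f"n{counter[0]}"
                left.append(child_idx[0])
                right.append(child_idx[1])
            blen.append(float(length))
            labels.append(label)
            return len(labels) - 1

        visit(root, True)
        tips = [lab for lab, l in zip(labels, left) if l < 0]
        if len(tips) != len(set(tips)):
            dupes = sorted({t for t in tips if tips.count(t) > 1})
            raise ParseError(f"duplicate tip label(s): {dupes}")
        if len(tips) < 2:
            raise ParseError("tree must have at least 2 tips")
        return cls(
            np.asarray(left, dtype=np.int64),
            np.asarray(right, dtype=np.int64),
            np.asarray(blen, dtype=float),
            labels,
        )

    # -- properties ----------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def internal_nodes(self) -> np.ndarray:
        """Postorder indices of internal nodes."""
        return np.flatnonzero(~self.is_tip)

    def edges(self) -> list[tuple[str, str]]:
        """All (parent_label, child_label) pairs, child in postorder."""
        return [
            (self.labels[self.parent[k]], self.labels[k])
            for k in range(self.n_nodes)
            if self.parent[k] >= 0
        ]

    def node_by_label(self, label: str) -> int:
        for k, lab in enumerate(self.labels):
            if lab == label:
                return k
        raise KeyError(label)

    def tips_below(self, k: int) -> list[str]:
        if self.is_tip[k]:
            return [self.labels[k]]
        return self.tips_below(self.left[k]) + self.tips_below(self.right[k])

    def mrca(self, tip_labels: Sequence[str]) -> int:
        """Index of the most recent common ancestor of the given tips."""
        want = set(tip_labels)
        missing = want - set(self.tip_labels)
        if missing:
            raise KeyError(f"unknown tip(s): {sorted(missing)}")
        for k in range(self.n_nodes):
            if want <= set(self.tips_below(k)):
                return k
        return self.root  # unreachable: root covers all tips

    def to_newick(self, *, edge_comments: Mapping[str, str] | None = None) -> str:
        """Serialize; ``edge_comments`` maps child-node labels to a bracket
        comment placed after that edge's branch length."""

        def fmt(k: int, at_root: bool) -> str:
            if self.is_tip[k]:
                core = self.labels[k]
            else:
                core = f"({fmt(self.left[k], False)},{fmt(self.right[k], False)}){self.labels[k]}"
            if at_root:
                return core
            out = f"{core}:{self.blen[k]:.17g}"
            if edge_comments and self.labels[k] in edge_comments:
                out += f"[&{edge_comments[self.labels[k]]}]"
            return out

        return fmt(self.root, True) + ";"

    # -- covariance (used by validation and oracles) -------------------

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        d = np.zeros(self.n_nodes)
        for k in range(self.n_nodes - 2, -1, -1):  # preorder = reversed postorder
            d[k] = d[self.parent[k]] + self.blen[k]
        return d

    def bm_covariance(self) -> tuple[np.ndarray, list[str]]:
        """Brownian-motion tip covariance: V[i, j] = shared root-to-MRCA path."""
        n = self.n_tips
        depth = self.depths()
        tip_ids = [self.tip_index[t] for t in self.tip_labels]
        # ancestor sets per tip
        anc: list[set[int]] = []
        for t in tip_ids:
            s = set()
            k = t
            while k >= 0:
                s.add(k)
                k = self.parent[k]
            anc.append(s)
        V = np.empty((n, n))
        for a in range(n):
            for b in range(n):
                shared = anc[a] & anc[b]
                mrca = max(shared, key=lambda k: depth[k])
                V[a, b] = depth[mrca] if a != b else depth[tip_ids[a]]
        return V, list(self.tip_labels)


def _resolve_polytomies(node: TreeNode) -> None:
    """Arbitrarily resolve multifurcations with zero-length internal edges."""
    for child in node.children:
        _resolve_polytomies(child)
    while len(node.children) > 2:
        a = node.children.pop()
        b = node.children.pop()
        node.children.append(TreeNode(label=None, length=0.0, children=[a, b]))


def parse_newick(
    text: str,
    *,
    resolve_polytomies: bool = False,
    zero_length_epsilon: float = DEFAULT_ZERO_LENGTH_EPSILON,
    default_length: float | None = None,
) -> Phylogeny:
    """Parse a rooted newick string into a validated :class:`Phylogeny`.

    Polytomies are rejected unless ``resolve_polytomies`` (arbitrary
    resolution with epsilon-length branches); zero-length branches are
    replaced by ``zero_length_epsilon`` with a warning because contrasts
    divide by branch length.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ParseError(f"invalid newick: {exc}") from exc

    def convert(dnode: dendropy.Node) -> TreeNode:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        return TreeNode(
            label=label,
            length=dnode.edge.length,
            children=[convert(c) for c in dnode.child_nodes()],
        )

    return Phylogeny.from_node(
        convert(dtree.seed_node),
        resolve_polytomies=resolve_polytomies,
        zero_length_epsilon=zero_length_epsilon,
        default_length=default_length,
    )


def read_newick(path: str | Path, **kwargs) -> Phylogeny:
    """Read a newick file (first tree) into a :class:`Phylogeny`."""
    with open(path, "rt", encoding="utf-8") as fh:
        return parse_newick(fh.read(), **kwargs)


# ---------------------------------------------------------------------
# Phylogenetic independent contrasts
# ---------------------------------------------------------------------


@dataclass
class ContrastSet:
    """Standardized contrasts, one per internal node (postorder).

    ``node_values`` holds the working (weighted-average) value at each
    internal node and ``working_lengths`` the node's augmented parent-edge
    length after the pruning step; both are useful for auditing.
    """

    contrasts: np.ndarray
    node_ids: list[str]
    n_tips: int
    node_values: np.ndarray
    working_lengths: np.ndarray

    def __len__(self) -> int:
        return len(self.contrasts)


def pic_contrasts(tree: Phylogeny, x: Mapping[str, float]) -> ContrastSet:
    """Felsenstein's independent contrasts of a tip-valued trait.

    At each internal node k with children i, j carrying working values
    x_i, x_j and working branch lengths v_i, v_j:

    * contrast  c_k = (x_i - x_j) / sqrt(v_i + v_j)
    * working value  x_k = (x_i / v_i + x_j / v_j) / (1/v_i + 1/v_j)
    * working length of k's parent edge grows by v_i v_j / (v_i + v_j)

    Under Brownian motion the n-1 contrasts are i.i.d. Normal(0, sigma^2).
    """
    missing = set(tree.tip_labels) - set(x)
    if missing:
        raise ConsistencyError(f"missing tip value(s) for: {sorted(missing)}")
    n = tree.n_nodes
    vals = np.empty(n)
    wlen = tree.blen.astype(float).copy()
    if np.any(wlen[: n - 1] <= 0):
        bad = [tree.labels[k] for k in np.flatnonzero(wlen[: n - 1] <= 0)]
        raise ValueError(f"non-positive branch length above node(s) {bad}")
    contrasts: list[float] = []
    node_ids: list[str] = []
    node_vals: list[float] = []
    node_wlen: list[float] = []
    for k in range(n):
        if tree.is_tip[k]:
            v = float(x[tree.labels[k]])
            if not math.isfinite(v):
                raise ValueError(f"non-finite value for tip {tree.labels[k]}")
            vals[k] = v
            continue
        i, j = tree.left[k], tree.right[k]
        vi, vj = wlen[i], wlen[j]
        contrasts.append((vals[i] - vals[j]) / math.sqrt(vi + vj))
        # weighted average written so equal children stay exactly equal
        wi = (1.0 / vi) / (1.0 / vi + 1.0 / vj)
        vals[k] = vals[j] + wi * (vals[i] - vals[j])
        wlen[k] = wlen[k] + vi * vj / (vi + vj)
        node_ids.append(tree.labels[k])
        node_vals.append(vals[k])
        node_wlen.append(wlen[k])
    return ContrastSet(
        contrasts=np.asarray(contrasts),
        node_ids=node_ids,
        n_tips=tree.n_tips,
        node_values=np.asarray(node_vals),
        working_lengths=np.asarray(node_wlen),
    )


def contrast_correlation(
    cx: ContrastSet | np.ndarray,
    cy: ContrastSet | np.ndarray,
    mode: str = "through_origin",
) -> tuple[float, float]:
    """Correlate two contrast sets from the same tree.

    ``through_origin`` (default) is the statistically appropriate form for
    contrasts, whose expectation is zero by construction:
    r = sum(cx*cy) / sqrt(sum(cx^2) sum(cy^2)), tested with
    t = r sqrt((k-1)/(1-r^2)) on k-1 degrees of freedom (k contrasts).
    ``centered`` is the ordinary Pearson correlation with an intercept,
    on k-2 degrees of freedom.  Two-sided p-values.

    Returns (nan, nan) when either vector has no variation (undefined r);
    callers flag such results rather than treating them as evidence.
    """
    a = np.asarray(cx.contrasts if isinstance(cx, ContrastSet) else cx, dtype=float)
    b = np.asarray(cy.contrasts if isinstance(cy, ContrastSet) else cy, dtype=float)
    if a.shape != b.shape:
        raise ValueError("contrast vectors differ in length (different trees?)")
    k = len(a)
    if k < 2:
        raise ValueError("need at least 2 contrasts")
    if mode == "through_origin":
        sxx = float(a @ a)
        syy = float(b @ b)
        if sxx == 0.0 or syy == 0.0:
            return (math.nan, math.nan)
        r = float(a @ b) / math.sqrt(sxx * syy)
        r = max(-1.0, min(1.0, r))
        df = k - 1
    elif mode == "centered":
        if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
            return (math.nan, math.nan)
        r = float(np.corrcoef(a, b)[0, 1])
        r = max(-1.0, min(1.0, r))
        df = k - 2
        if df < 1:
            return (r, math.nan)
    else:
        raise ValueError(f"unknown correlation mode {mode!r}")
    if abs(r) >= 1.0:
        return (r, 0.0)
    t = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return (r, p)


def bh_fdr(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} m p_(j) / j over the sorted p-values, capped at 1
    and mapped back to input order.  Valid under independence or positive
    regression dependence of the tests.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------
# Trait x family correlation screen
# ---------------------------------------------------------------------


@dataclass
class ContrastCorrelationResult:
    """Correlation of one trait's contrasts with one family's contrasts."""

    trait_id: str
    family_id: str
    r: float
    p_value: float
    q_value: float
    n_contrasts: int
    significant: bool
    defined: bool = True


def correlate_families(
    tree: Phylogeny,
    traits: pd.DataFrame,
    sizes: FamilySizeMatrix,
    alpha_q: float = 0.05,
    mode: str = "through_origin",
    log10_traits: Sequence[str] = (),
) -> list[ContrastCorrelationResult]:
    """PIC-correlate every (continuous trait, family) pair with FDR control.

    Both variables are contrasted on the same tree; p-values are
    BH-corrected within each trait across families (one FDR batch per
    trait); results with q < ``alpha_q`` are flagged significant.
    Families whose sizes are constant across species produce zero
    contrasts and are reported undefined rather than significant.
    ``log10_traits`` optionally log10-transforms the named traits (useful
    for genome size / protein counts) before contrasting.
    """
    tree_sp = set(tree.tip_labels)
    trait_sp = set(traits.index)
    size_sp = set(sizes.species)
    if tree_sp != trait_sp or tree_sp != size_sp:
        raise ConsistencyError(
            "species sets disagree; "
            f"tree-only={sorted(tree_sp - (trait_sp & size_sp))}, "
            f"traits-only={sorted(trait_sp - tree_sp)}, "
            f"sizes-only={sorted(size_sp - tree_sp)}"
        )
    family_contrasts = {
        fam: pic_contrasts(tree, sizes.counts[fam].to_dict()) for fam in sizes.families
    }
    results: list[ContrastCorrelationResult] = []
    for trait in traits.columns:
        vec = traits[trait].astype(float)
        if trait in log10_traits:
            if (vec <= 0).any():
                raise ValueError(f"log10 transform of trait {trait!r}: non-positive values")
            vec = pd.Series(np.log10(vec.to_numpy()), index=vec.index)
        ct = pic_contrasts(tree, vec.to_dict())
        per_trait: list[ContrastCorrelationResult] = []
        pvals: list[float] = []
        for fam in sizes.families:
            r, p = contrast_correlation(ct, family_contrasts[fam], mode=mode)
            defined = math.isfinite(r)
            per_trait.append(
                ContrastCorrelationResult(
                    trait_id=trait,
                    family_id=fam,
                    r=r,
                    p_value=p,
                    q_value=math.nan,
                    n_contrasts=len(ct),
                    significant=False,
                    defined=defined,
                )
            )
            if defined:
                pvals.append(p)
        if pvals:
            qvals = iter(bh_fdr(pvals))
            for res in per_trait:
                if res.defined:
                    res.q_value = float(next(qvals))
                    res.significant = res.q_value < alpha_q
        results.extend(per_trait)
    return results


def correlation_results_frame(results: Sequence[ContrastCorrelationResult]) -> pd.DataFrame:
    """Tabulate correlation results (one row per trait x family)."""
    return pd.DataFrame(
        {
            "trait": [r.trait_id for r in results],
            "family": [r.family_id for r in results],
            "r": [r.r for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "n_contrasts": [r.n_contrasts for r in results],
            "significant": [r.significant for r in results],
            "defined": [r.defined for r in results],
        }
    )


# ---------------------------------------------------------------------
# Trait table I/O
# ---------------------------------------------------------------------


def read_traits(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a trait TSV with a ``#type`` annotation row.

    Layout: header ``species`` + trait names; second row ``#type`` with
    ``continuous`` or ``binary`` per trait; one row per species.  Returns
    (continuous, binary) DataFrames indexed by species.
    """
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        type_row = fh.readline().rstrip("\n").split("\t")
        if not type_row or type_row[0] != "#type":
            raise ParseError(f"{path}: expected '#type' annotation row")
        kinds = dict(zip(header[1:], type_row[1:]))
        bad = {t: k for t, k in kinds.items() if k not in ("continuous", "binary")}
        if bad:
            raise ParseError(f"{path}: unknown trait type(s) {bad}")
        species, rows = [], []
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            species.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    df = pd.DataFrame(rows, index=species, columns=header[1:])
    cont = df[[t for t, k in kinds.items() if k == "continuous"]]
    binary = df[[t for t, k in kinds.items() if k == "binary"]]
    if not binary.empty and not binary.isin([0.0, 1.0]).all().all():
        raise ParseError(f"{path}: binary traits must be 0/1")
    return cont, binary


def write_traits(
    continuous: pd.DataFrame, binary: pd.DataFrame | None, path: str | Path
) -> None:
    """Write the trait TSV dialect read by :func:`read_traits`."""
    if binary is None:
        binary = pd.DataFrame(index=continuous.index)
    cols = list(continuous.columns) + list(binary.columns)
    kinds = ["continuous"] * len(continuous.columns) + ["binary"] * len(binary.columns)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("species\t" + "\t".join(cols) + "\n")
        fh.write("#type\t" + "\t".join(kinds) + "\n")
        for sp in continuous.index:
            vals = [repr(float(continuous.loc[sp, c])) for c in continuous.columns]
            vals += [repr(float(binary.loc[sp, c])) for c in binary.columns]
            fh.write(sp + "\t" + "\t".join(vals) + "\n")
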