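"""Synthetic pipeline inputs with known ground truth.

Everything the pipeline consumes can be generated here: pure-birth (Yule)
trees, Brownian-motion traits, family-size matrices with planted
trait correlations, planted gain/loss events and planted group shifts,
and domain-hit tables whose proteins carry architectures satisfying
exactly one family rule — plus decoys (near-miss architectures or
forbidden-domain carriers at trusted scores) and sub-threshold noise
hits.  The generator keeps a ledger of every planted truth so tests can
verify recovery end to end.

Randomness is hierarchical: one global seed drives independent
per-component streams (tree, each trait, each family, hits), so adding a
family does not perturb the others.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from stramtf.domhits import DomainHit, write_hits_tsv
from stramtf.phylo import Phylogeny, TreeNode, write_traits
from stramtf.rule_engine import FamilyRule, FamilySizeMatrix, RuleSet, write_rules

__all__ = [
    "SimConfig",
    "SyntheticBundle",
    "DEFAULT_FAMILIES",
    "sim_tree",
    "sim_bm_traits",
    "sim_family_sizes",
    "gen_rules",
    "gen_domain_hits",
    "sim_groups",
    "simulate_bundle",
    "demo_config",
]

# 63 family names shaped like a Stramenopile TF/TR repertoire (38 TF + 25 TR);
# domain content attached to them here is synthetic.
_TF = [
    "C2H2", "C3H", "MYB", "MYB-related", "HSF", "CSD", "HB", "bZIP", "bHLH",
    "E2F-DP", "MADS", "GATA", "NF-YA", "NF-YB", "NF-YC", "CAMTA", "LuxR",
    "TUB", "SBP", "RWP-RK", "CPP", "Whirly", "ZF-HD", "Dof", "TCP",
    "Sigma70-like", "AP2", "WRKY", "HMG-box-TF", "Nin-like", "S1Fa-like",
    "STAT", "GeBP", "BES1", "VOZ", "NF-X1", "PLATZ", "Zn-clus",
]
_TR = [
    "GNAT", "HMG", "FHA", "LIM", "zf_A20", "SWI/SNF-BAF60b", "SWI/SNF-SNF2",
    "TFIIS", "TIG", "SET", "PHD", "Jumonji", "Bromodomain", "Chromo", "HDAC",
    "DDT", "TAZ", "BTB-POZ", "TRAF", "Sir2", "MBD", "ING", "Alba", "LUG",
    "Med6",
]
DEFAULT_FAMILIES: tuple[tuple[str, str], ...] = tuple(
    [(f, "TF") for f in _TF] + [(f, "TR") for f in _TR]
)

DEFAULT_TRAITS: dict[str, tuple[float, float]] = {
    # trait -> (root value, BM sigma per unit branch length)
    "genome_size": (100.0, 30.0),       # Mb
    "predicted_proteins": (15000.0, 3000.0),
    "n_flagella": (1.0, 0.8),
    "n_cell_types": (3.0, 1.5),
}

BINARY_TRAITS = (
    "cell_cover", "chloroplast", "pigments", "lifestyle", "cwde", "haustorium",
)


@dataclass
class SimConfig:
    """Study conditions for a synthetic dataset.

    ``planted_correlations``: (family, trait, rho) triples; the family's
    log-size latent evolves with Brownian increments correlated at rho
    with the named trait's increments.  ``planted_events``: (family, edge,
    "gain"|"loss"); an edge is a node label or a tuple of tip labels
    (edge above their MRCA).  ``planted_group_shifts``: (family, group,
    shift) adds ``shift`` within-family standard deviations to that
    group's counts.
    """

    n_tips: int = 11
    birth_rate: float = 1.0
    n_families: int = 63
    traits: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRAITS)
    )
    family_log_root: float = math.log(5.0)
    family_log_sigma: float = 0.6
    planted_correlations: tuple[tuple[str, str, float], ...] = ()
    planted_events: tuple[tuple[str, object, str], ...] = ()
    planted_group_shifts: tuple[tuple[str, str, float], ...] = ()
    decoy_fraction: float = 0.2
    noise_hits_per_species: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        if self.birth_rate <= 0:
            raise ValueError("birth_rate must be positive")
        if not (0 <= self.decoy_fraction < 1):
            raise ValueError("decoy_fraction must be in [0, 1)")
        for fam, trait, rho in self.planted_correlations:
            if not (-1 < rho < 1):
                raise ValueError(f"planted rho for {fam}/{trait} must be in (-1, 1)")
            if trait not in self.traits:
                raise ValueError(f"planted correlation names unknown trait {trait!r}")
        for _, (root, sigma) in self.traits.items():
            if sigma <= 0:
                raise ValueError("trait sigma must be positive")
        if self.family_log_sigma <= 0:
            raise ValueError("family_log_sigma must be positive")

    def family_table(self) -> list[tuple[str, str]]:
        fams = list(DEFAULT_FAMILIES[: self.n_families])
        for i in range(len(fams), self.n_families):
            fams.append((f"FAM{i + 1}", "TF" if i % 2 == 0 else "TR"))
        return fams


def _rng(cfg: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=key))


# ---------------------------------------------------------------------
# Trees and traits
# ---------------------------------------------------------------------


def sim_tree(cfg: SimConfig) -> Phylogeny:
    """Pure-birth (Yule) rooted bifurcating tree with ``n_tips`` tips.

    Starting from the root's two lineages, the waiting time to the next
    split among k extant lineages is Exponential(k * birth_rate); the tree
    is cut at the epoch when the (n+1)-th lineage would arise, so the
    expected root-to-tip depth is sum_{k=2..n} 1/(k * birth_rate).  Tip
    labels are sp01, sp02, ... in birth order; the tree is ultrametric.
    """
    rng = _rng(cfg, 0)
    n = cfg.n_tips
    # active lineages as (node, birth_time); root at time 0 with 2 children
    root = TreeNode(label=None)
    active: list[tuple[TreeNode, float]] = []
    for _ in range(2):
        child = TreeNode()
        root.children.append(child)
        active.append((child, 0.0))
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / (len(active) * cfg.birth_rate))
        idx = int(rng.integers(len(active)))
        node, born = active.pop(idx)
        node.length = t - born
        for _ in range(2):
            child = TreeNode()
            node.children.append(child)
            active.append((child, t))
    depth = t + rng.exponential(1.0 / (n * cfg.birth_rate))
    # label tips in a deterministic traversal order
    counter = [0]

    def label_tips(node: TreeNode) -> None:
        for child in node.children:
            label_tips(child)
        if not node.children and node.label is None:
            counter[0] += 1
            node.label = f"sp{counter[0]:02d}"

    for node, born in active:
        node.length = depth - born
    label_tips(root)
    return Phylogeny.from_node(root)


def sim_bm_traits(
    tree: Phylogeny, cfg: SimConfig
) -> tuple[pd.DataFrame, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Evolve each continuous trait by Brownian motion along the tree.

    Each edge above node k receives a standardized increment eps[k] ~
    N(0, 1); the child value is parent + sigma * sqrt(branch length) *
    eps[k].  Returns the tip trait table, the per-edge standardized
    increments (reused to plant correlated family latents), and all node
    values (latent states at internal nodes).
    """
    n = tree.n_nodes
    tips = tree.tip_labels
    table: dict[str, pd.Series] = {}
    eps_by_trait: dict[str, np.ndarray] = {}
    nodes_by_trait: dict[str, np.ndarray] = {}
    for ti, (trait, (root_val, sigma)) in enumerate(cfg.traits.items()):
        rng = _rng(cfg, 1, ti)
        eps = rng.standard_normal(n)
        vals = np.empty(n)
        vals[tree.root] = root_val
        for k in range(n - 2, -1, -1):  # preorder below root
            vals[k] = vals[tree.parent[k]] + sigma * math.sqrt(tree.blen[k]) * eps[k]
        table[trait] = pd.Series(
            [vals[tree.tip_index[t]] for t in tips], index=tips
        )
        eps_by_trait[trait] = eps
        nodes_by_trait[trait] = vals
    return pd.DataFrame(table), eps_by_trait, nodes_by_trait


# ---------------------------------------------------------------------
# Family sizes with planted truths
# ---------------------------------------------------------------------


def _resolve_edge(tree: Phylogeny, edge: object) -> int:
    """Resolve an edge spec (child-node label, or tip-label collection
    meaning the edge above their MRCA) to a node index."""
    if isinstance(edge, str):
        try:
            return tree.node_by_label(edge)
        except KeyError:
            raise ValueError(f"planted edge {edge!r} not in tree") from None
    try:
        return tree.mrca(list(edge))  # type: ignore[arg-type]
    except KeyError:
        raise ValueError(f"planted edge {edge!r} not in tree") from None


def sim_family_sizes(
    tree: Phylogeny,
    cfg: SimConfig,
    trait_eps: Mapping[str, np.ndarray],
    groups: Mapping[str, str] | None = None,
) -> tuple[FamilySizeMatrix, dict]:
    """Simulate the species x family count matrix with planted truths.

    Null families: counts = round(exp(latent BM)) with independent
    increments, clipped to >= 1 so that zeros arise only from planted
    losses.  Planted-correlation families share standardized increments
    with their target trait at correlation rho.  Planted gain/loss
    families evolve presence down the tree by the listed events; absent
    species get count 0.  Planted group shifts add a multiple of the
    family's count standard deviation to one ecological group.
    """
    fams = cfg.family_table()
    fam_names = [f for f, _ in fams]
    planted_corr = {fam: (trait, rho) for fam, trait, rho in cfg.planted_correlations}
    events_by_fam: dict[str, list[tuple[int, str]]] = {}
    for fam, edge, event in cfg.planted_events:
        if event not in ("gain", "loss"):
            raise ValueError(f"unknown planted event {event!r}")
        node = _resolve_edge(tree, edge)
        if node == tree.root:
            raise ValueError(f"planted event for {fam!r} resolves to the root, "
                             "which has no parent edge")
        events_by_fam.setdefault(fam, []).append((node, event))
    unknown = (set(planted_corr) | set(events_by_fam)) - set(fam_names)
    if unknown:
        raise ValueError(f"planted truth references unknown families: {sorted(unknown)}")

    n = tree.n_nodes
    tips = tree.tip_labels
    counts = pd.DataFrame(0, index=tips, columns=fam_names, dtype=int)
    latent_by_fam: dict[str, dict[str, float]] = {}
    for fi, fam in enumerate(fam_names):
        rng = _rng(cfg, 2, fi)
        z = rng.standard_normal(n)
        if fam in planted_corr:
            trait, rho = planted_corr[fam]
            eps = rho * trait_eps[trait] + math.sqrt(1 - rho * rho) * z
        else:
            eps = z
        latent = np.empty(n)
        latent[tree.root] = cfg.family_log_root
        for k in range(n - 2, -1, -1):
            latent[k] = (
                latent[tree.parent[k]]
                + cfg.family_log_sigma * math.sqrt(tree.blen[k]) * eps[k]
            )
        size = np.maximum(1, np.rint(np.exp(latent))).astype(int)
        if fam in planted_corr:
            latent_by_fam[fam] = {
                t: float(latent[tree.tip_index[t]]) for t in tips
            }

        present = np.ones(n, dtype=int)
        if fam in events_by_fam:
            ev = {node: e for node, e in events_by_fam[fam]}
            # root state: absent if the shallowest event is a gain
            depth = tree.depths()
            top_node = min(ev, key=lambda k: depth[k])
            state0 = 0 if ev[top_node] == "gain" else 1
            present[tree.root] = state0
            for k in range(n - 2, -1, -1):
                s = present[tree.parent[k]]
                if k in ev:
                    want = 1 if ev[k] == "gain" else 0
                    if want == s:
                        raise ValueError(
                            f"inconsistent planted events for {fam!r}: "
                            f"{ev[k]} on an edge already in that state"
                        )
                    s = want
                present[k] = s
        for t in tips:
            k = tree.tip_index[t]
            counts.loc[t, fam] = size[k] if present[k] else 0

    shift_ledger = []
    for fam, group, shift in cfg.planted_group_shifts:
        if groups is None:
            raise ValueError("planted_group_shifts requires a group assignment")
        if fam not in fam_names:
            raise ValueError(f"planted shift references unknown family {fam!r}")
        sd = float(counts[fam].std(ddof=1)) or 1.0
        delta = int(round(shift * sd))
        members = [s for s in tips if groups[s] == group]
        counts.loc[members, fam] = np.maximum(0, counts.loc[members, fam] + delta)
        shift_ledger.append({"family": fam, "group": group, "shift_sd": shift, "delta": delta})

    ledger = {
        "planted_correlations": [
            {"family": f, "trait": t, "rho": r} for f, t, r in cfg.planted_correlations
        ],
        "planted_events": [
            {"family": f, "edge": tree.labels[_resolve_edge(tree, e)], "event": ev}
            for f, e, ev in cfg.planted_events
        ],
        "planted_group_shifts": shift_ledger,
        "null_families": [
            f for f in fam_names if f not in planted_corr and f not in events_by_fam
        ],
        # continuous log-size latents of planted-correlation families, kept so
        # parameter recovery can be measured before integer rounding
        "latent_log_size": latent_by_fam,
    }
    return FamilySizeMatrix(counts=counts, categories=dict(fams)), ledger


# ---------------------------------------------------------------------
# Rules and domain hits
# ---------------------------------------------------------------------


def _domain_token(family: str) -> str:
    return re.sub(r"[^A-Za-z0-9]+", "_", family)


def gen_rules(cfg: SimConfig) -> RuleSet:
    """Synthesize one rule per family with unique domain content.

    Every third family requires two clauses (the second offering two
    alternative domains, like alternative DNA-binding domains); every
    family carries one forbidden domain so forbidden-carrier decoys can
    be generated.  Gathering cutoffs are drawn per domain in [20, 30) bits.
    """
    rng = _rng(cfg, 3)
    rules: list[FamilyRule] = []
    domain_ga: dict[str, float] = {}

    def ga_for(domain: str) -> None:
        domain_ga[domain] = round(float(rng.uniform(20.0, 30.0)), 1)

    for i, (fam, cat) in enumerate(cfg.family_table()):
        tok = _domain_token(fam)
        clauses: list[frozenset[str]] = [frozenset([f"DBD_{tok}"])]
        ga_for(f"DBD_{tok}")
        if i % 3 == 2:
            alts = frozenset([f"AUX1_{tok}", f"AUX2_{tok}"])
            clauses.append(alts)
            for d in alts:
                ga_for(d)
        forbidden = frozenset([f"FORB_{tok}"])
        ga_for(f"FORB_{tok}")
        rules.append(
            FamilyRule(
                family_id=fam,
                category=cat,
                required_clauses=tuple(clauses),
                forbidden=forbidden,
            )
        )
    return RuleSet(rules=rules, domain_ga=domain_ga)


def gen_domain_hits(
    sizes: FamilySizeMatrix,
    rules: RuleSet,
    cfg: SimConfig,
) -> tuple[list[DomainHit], dict[str, str]]:
    """Emit domain hits realizing a size matrix, plus decoys and noise.

    For each (species, family) count the generator writes that many
    proteins whose hits satisfy exactly that family's rule: one domain
    per required clause at a bit score GA + U(1, 20).  Decoys — a
    ``decoy_fraction`` share of all proteins — either miss one required
    clause or carry the family's forbidden domain, always at GA-passing
    scores, so they must be rejected by the classifier, not the filter.
    Sub-GA noise hits (score GA - U(1, 10)) land on real proteins and on
    otherwise-empty ones.  Returns the hits and a protein -> truth map
    (family name, "decoy" or "noise").
    """
    rng = _rng(cfg, 4)
    rule_by_fam = {r.family_id: r for r in rules}
    missing = set(sizes.families) - set(rule_by_fam)
    if missing:
        raise ValueError(f"families without a rule: {sorted(missing)}")
    hits: list[DomainHit] = []
    truth: dict[str, str] = {}
    serial: dict[str, int] = {sp: 0 for sp in sizes.species}

    def new_protein(sp: str) -> str:
        serial[sp] += 1
        return f"{sp}_g{serial[sp]:05d}"

    def ga(domain: str) -> float:
        return rules.domain_ga[domain]

    def passing(domain: str) -> float:
        return round(ga(domain) + float(rng.uniform(1.0, 20.0)), 1)

    def failing(domain: str) -> float:
        return round(ga(domain) - float(rng.uniform(1.0, 10.0)), 1)

    def emit(sp: str, pid: str, domain: str, score: float) -> None:
        hits.append(DomainHit(pid, sp, domain, score, ga(domain)))

    for fam in sizes.families:
        rule = rule_by_fam[fam]
        for sp in sizes.species:
            for _ in range(int(sizes.counts.loc[sp, fam])):
                pid = new_protein(sp)
                truth[pid] = fam
                for clause in rule.required_clauses:
                    domain = sorted(clause)[int(rng.integers(len(clause)))]
                    emit(sp, pid, domain, passing(domain))
                    if rng.random() < 0.15:  # extra copy of the same domain
                        emit(sp, pid, domain, passing(domain))

    n_planted = len(truth)
    n_decoys = int(round(cfg.decoy_fraction / (1 - cfg.decoy_fraction) * n_planted))
    fam_list = sizes.families
    for _ in range(n_decoys):
        sp = sizes.species[int(rng.integers(len(sizes.species)))]
        rule = rule_by_fam[fam_list[int(rng.integers(len(fam_list)))]]
        pid = new_protein(sp)
        truth[pid] = "decoy"
        clauses = list(rule.required_clauses)
        if len(clauses) > 1 and rng.random() < 0.5:
            # near miss: all clauses but one
            drop = int(rng.integers(len(clauses)))
            keep = [c for i, c in enumerate(clauses) if i != drop]
        else:
            # forbidden-domain carrier: full architecture plus the veto domain
            keep = clauses
            forb = sorted(rule.forbidden)[0]
            emit(sp, pid, forb, passing(forb))
        for clause in keep:
            domain = sorted(clause)[int(rng.integers(len(clause)))]
            emit(sp, pid, domain, passing(domain))

    all_domains = sorted(rules.domain_ga)
    protein_pool = sorted(truth)
    for sp in sizes.species:
        for i in range(cfg.noise_hits_per_species):
            domain = all_domains[int(rng.integers(len(all_domains)))]
            if i % 2 == 0 and protein_pool:
                pid = protein_pool[int(rng.integers(len(protein_pool)))]
                emit(sp, pid, domain, failing(domain))
            else:
                pid = new_protein(sp)
                truth.setdefault(pid, "noise")
                emit(sp, pid, domain, failing(domain))
    return hits, truth


def sim_groups(tree: Phylogeny, cfg: SimConfig) -> dict[str, str]:
    """Assign tips to autotroph/heterotroph groups.

    The split follows the root's two clades when both hold >= 2 tips
    (groups are clade-like, as in real lineages); otherwise tips
    alternate in sorted order.  The left root clade is the autotrophs.
    """
    left_tips = set(tree.tips_below(tree.left[tree.root]))
    right_tips = set(tree.tips_below(tree.right[tree.root]))
    if len(left_tips) >= 2 and len(right_tips) >= 2:
        return {
            t: ("autotroph" if t in left_tips else "heterotroph")
            for t in tree.tip_labels
        }
    ordered = sorted(tree.tip_labels)
    return {t: ("autotroph" if i % 2 == 0 else "heterotroph") for i, t in enumerate(ordered)}


def sim_binary_traits(
    tree: Phylogeny, cfg: SimConfig, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Binary mapping traits: chloroplast/pigments follow the autotroph
    group, the rest are random presence/absence."""
    rng = _rng(cfg, 5)
    tips = tree.tip_labels
    data = {}
    for trait in BINARY_TRAITS:
        if trait in ("chloroplast", "pigments"):
            data[trait] = [1.0 if groups[t] == "autotroph" else 0.0 for t in tips]
        else:
            data[trait] = rng.integers(0, 2, size=len(tips)).astype(float)
    return pd.DataFrame(data, index=tips)


# ---------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------


@dataclass
class SyntheticBundle:
    """All pipeline inputs for one simulated study, plus the truth ledger."""

    config: SimConfig
    tree: Phylogeny
    traits: pd.DataFrame
    binary_traits: pd.DataFrame
    ruleset: RuleSet
    hits: list[DomainHit]
    sizes: FamilySizeMatrix
    groups: dict[str, str]
    truth: dict[str, str]
    ledger: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every artifact in the dialect the pipeline reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "tree": outdir / "tree.nwk",
            "traits": outdir / "traits.tsv",
            "rules": outdir / "rules.tsv",
            "hits": outdir / "hits.tsv",
            "groups": outdir / "groups.tsv",
            "sizes_true": outdir / "family_sizes_true.tsv",
            "ledger": outdir / "ledger.json",
            "domtblout": outdir / "domtblout",
        }
        paths["tree"].write_text(self.tree.to_newick() + "\n", encoding="utf-8")
        write_traits(self.traits, self.binary_traits, paths["traits"])
        write_rules(self.ruleset, paths["rules"])
        write_hits_tsv(self.hits, paths["hits"])
        with open(paths["groups"], "wt", encoding="utf-8") as fh:
            fh.write("species\tgroup\n")
            for sp in self.tree.tip_labels:
                fh.write(f"{sp}\t{self.groups[sp]}\n")
        self.sizes.to_tsv(paths["sizes_true"])
        ledger = dict(self.ledger)
        ledger["truth_by_protein"] = self.truth
        ledger["seed"] = self.config.seed
        with open(paths["ledger"], "wt", encoding="utf-8") as fh:
            json.dump(ledger, fh, indent=1, sort_keys=True)
            fh.write("\n")
        paths["domtblout"].mkdir(exist_ok=True)
        for sp in self.tree.tip_labels:
            write_domtblout(
                [h for h in self.hits if h.species_id == sp],
                paths["domtblout"] / f"{sp}.domtbl",
            )
        return paths


def write_domtblout(hits: Sequence[DomainHit], path: str | Path) -> None:
    """Write hits as an HMMER3-style per-domain table (one species)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# target name        accession   tlen query name           "
                 "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
                 "i-Evalue  score  bias  from    to  from    to  from    to  "
                 "acc description of target\n#\n")
        for h in hits:
            fh.write(
                f"{h.protein_id} - 400 {h.domain_id} - 100 "
                f"1e-10 {h.bit_score:.1f} 0.1 1 1 1e-11 1e-10 {h.bit_score:.1f} 0.1 "
                f"1 100 10 110 5 115 0.95 -\n"
            )


def simulate_bundle(cfg: SimConfig) -> SyntheticBundle:
    """Generate a complete, internally consistent input bundle."""
    tree = sim_tree(cfg)
    traits, trait_eps, _ = sim_bm_traits(tree, cfg)
    groups = sim_groups(tree, cfg)
    sizes, ledger = sim_family_sizes(tree, cfg, trait_eps, groups=groups)
    ruleset = gen_rules(cfg)
    hits, truth = gen_domain_hits(sizes, ruleset, cfg)
    binary = sim_binary_traits(tree, cfg, groups)
    ledger = dict(ledger)
    ledger["groups"] = dict(groups)
    return SyntheticBundle(
        config=cfg,
        tree=tree,
        traits=traits,
        binary_traits=binary,
        ruleset=ruleset,
        hits=hits,
        sizes=sizes,
        groups=groups,
        truth=truth,
        ledger=ledger,
    )


def demo_config(seed: int = 0) -> SimConfig:
    """A paper-shaped demonstration study: 11 species, 63 families, with a
    trait-correlated family, a loss-then-regain family and a group-shifted
    family planted for the worked example.

    Event edges are resolved against the (deterministic) tree for this
    seed: the loss hits the larger root clade and the regain a sub-clade
    within it.
    """
    base = SimConfig(seed=seed)
    tree = sim_tree(base)
    left, right = tree.left[tree.root], tree.right[tree.root]
    clade = left if len(tree.tips_below(left)) >= len(tree.tips_below(right)) else right
    # regain must sit >= 2 edges below the loss so the remaining absent tips
    # are paraphyletic and the two events stay the most parsimonious account
    sub = None
    grandchildren = [
        g
        for c in (tree.left[clade], tree.right[clade])
        if c >= 0 and not tree.is_tip[c]
        for g in (tree.left[c], tree.right[c])
        if not tree.is_tip[g]
    ]
    if grandchildren:
        sub = grandchildren[0]
    events: tuple = ((("LIM", tree.labels[clade], "loss"),)
                     + ((("LIM", tree.labels[sub], "gain"),) if sub is not None else ()))
    return SimConfig(
        seed=seed,
        planted_correlations=(("C2H2", "predicted_proteins", 0.9),),
        planted_events=events,
        planted_group_shifts=(("HSF", "autotroph", 3.0),),
    )
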