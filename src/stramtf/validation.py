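"""Simulation-based calibration and recovery checks.

These routines measure, by Monte Carlo simulation against the generator's
known ground truth, the statistical properties the pipeline relies on:
the type-I error of the contrast-correlation test under independent
Brownian motion, recovery of a planted increment correlation, detection
power and false-flag rate of the trait screen under FDR control, exact
inversion of a planted size matrix by the classifier, parsimony-score
agreement with brute-force enumeration, and the calibration of the
group-abundance t-test.  The same functions back the test suite and the
reproduction script.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

from stramtf.comparative import fitch_parsimony, group_abundance_test
from stramtf.domhits import build_profiles, filter_by_ga
from stramtf.phylo import Phylogeny, contrast_correlation, pic_contrasts
from stramtf.rule_engine import FamilySizeMatrix, classify_proteome, family_size_matrix
from stramtf.simulate import (
    SimConfig,
    sim_bm_traits,
    sim_family_sizes,
    sim_tree,
    simulate_bundle,
)

__all__ = [
    "type_i_error_rate",
    "rho_recovery",
    "planted_detection",
    "bundle_inversion",
    "fitch_brute_force_check",
    "group_test_calibration",
    "whitening_check",
]

_PLANTED = ("C2H2", "predicted_proteins")


def _offset(seed: int, block: int) -> int:
    # disjoint per-measurement seed blocks, kept below 2**31
    return (seed * 1_000_003 + block * 100_000) % (2**31 - 1)


def type_i_error_rate(
    seed: int = 0,
    n_trees: int = 500,
    pairs_per_tree: int = 20,
    n_tips: int = 32,
    alpha: float = 0.05,
) -> dict:
    """Rejection rate of the contrast correlation for independent BM traits.

    Each tree contributes ``pairs_per_tree`` independent trait pairs; all
    traits evolve independently, so every p < alpha is a false positive.
    """
    base = _offset(seed, 1)
    rejected = total = 0
    traits_spec = {f"t{i}": (0.0, 1.0) for i in range(2 * pairs_per_tree)}
    for rep in range(n_trees):
        cfg = SimConfig(n_tips=n_tips, seed=base + rep, traits=traits_spec)
        tree = sim_tree(cfg)
        traits, _, _ = sim_bm_traits(tree, cfg)
        contrasts = [
            pic_contrasts(tree, traits[c].to_dict()) for c in traits.columns
        ]
        for i in range(pairs_per_tree):
            _, p = contrast_correlation(contrasts[2 * i], contrasts[2 * i + 1])
            rejected += p < alpha
            total += 1
    return {"value": rejected / total, "n": total}


def rho_recovery(
    seed: int = 0, n_reps: int = 500, n_tips: int = 64, rho: float = 0.9
) -> dict:
    """Mean through-origin contrast correlation of a planted-rho pair.

    The planted parameter is the increment correlation between the trait
    and the family's continuous log-size latent, so recovery is measured
    on the latent (the generator records it); rounding the latent to
    small integer counts is a separate, deliberate distortion whose
    effect is covered by the detection-power check.
    """
    base = _offset(seed, 2)
    fam, trait = _PLANTED
    rs = []
    for rep in range(n_reps):
        cfg = SimConfig(
            n_tips=n_tips,
            n_families=1,
            seed=base + rep,
            planted_correlations=((fam, trait, rho),),
        )
        tree = sim_tree(cfg)
        traits, eps, _ = sim_bm_traits(tree, cfg)
        _, ledger = sim_family_sizes(tree, cfg, eps)
        cx = pic_contrasts(tree, traits[trait].to_dict())
        cy = pic_contrasts(tree, ledger["latent_log_size"][fam])
        rs.append(contrast_correlation(cx, cy)[0])
    return {"value": float(np.mean(rs)), "n": n_reps}


def planted_detection(
    seed: int = 0,
    n_reps: int = 200,
    n_tips: int = 32,
    n_families: int = 50,
    rho: float = 0.9,
    alpha_q: float = 0.05,
) -> dict:
    """Power and null false-flag rate of the full trait screen.

    One family is planted at correlation ``rho`` with one trait among
    ``n_families - 1`` null families; the screen runs PIC + correlation +
    per-trait BH.  Power is the fraction of replicates flagging the
    planted (family, trait) pair at q < alpha_q; the null rate pools all
    defined null-family tests.
    """
    from stramtf.phylo import correlate_families

    base = _offset(seed, 3)
    fam, trait = _PLANTED
    detected = 0
    null_flagged = null_total = 0
    for rep in range(n_reps):
        cfg = SimConfig(
            n_tips=n_tips,
            n_families=n_families,
            seed=base + rep,
            planted_correlations=((fam, trait, rho),),
        )
        tree = sim_tree(cfg)
        traits, eps, _ = sim_bm_traits(tree, cfg)
        sizes, _ = sim_family_sizes(tree, cfg, eps)
        for res in correlate_families(tree, traits, sizes, alpha_q=alpha_q):
            if res.family_id == fam:
                if res.trait_id == trait and res.significant:
                    detected += 1
            elif res.defined:
                null_total += 1
                null_flagged += res.significant
    return {
        "power": {"value": detected / n_reps, "n": n_reps},
        "null_rate": {"value": null_flagged / null_total, "n": null_total},
    }


def bundle_inversion(seed: int = 0) -> dict:
    """Classify a paper-shaped synthetic bundle and compare with its truth.

    11 species x 63 families (~5,000 proteins), 20% decoys and sub-GA
    noise; reports whether classification reproduces the planted size
    matrix cell-for-cell and how many decoys were assigned anywhere.
    """
    cfg = SimConfig(seed=_offset(seed, 4))
    bundle = simulate_bundle(cfg)
    kept = filter_by_ga(bundle.hits)
    assignments = classify_proteome(build_profiles(kept), bundle.ruleset)
    matrix = family_size_matrix(
        assignments, bundle.tree.tip_labels, bundle.ruleset
    )
    truth = bundle.sizes.counts
    recovered = matrix.counts.loc[truth.index, truth.columns]
    decoys = {p for p, f in bundle.truth.items() if f == "decoy"}
    assigned = {a.protein_id for a in assignments}
    exact = (recovered.to_numpy() == truth.to_numpy()).mean()
    return {
        "matrix": matrix,
        "bundle": bundle,
        "cells_exact_pct": {"value": 100.0 * float(exact), "n": int(truth.size)},
        "decoys_assigned": {"value": float(len(assigned & decoys)), "n": len(decoys)},
        "n_proteins": len({a for a in bundle.truth}),
    }


def _brute_force_score(tree: Phylogeny, states: dict) -> int:
    internal = [k for k in range(tree.n_nodes) if not tree.is_tip[k]]
    fixed = {
        k: states[tree.labels[k]] for k in range(tree.n_nodes) if tree.is_tip[k]
    }
    best = math.inf
    for combo in itertools.product((0, 1), repeat=len(internal)):
        lab = dict(fixed)
        lab.update(zip(internal, combo))
        changes = sum(
            lab[k] != lab[tree.parent[k]]
            for k in range(tree.n_nodes)
            if tree.parent[k] >= 0
        )
        best = min(best, changes)
    return int(best)


def fitch_brute_force_check(seed: int = 0, n_random: int = 100) -> dict:
    """Parsimony-score agreement with exhaustive ancestral enumeration.

    All 2^6 tip patterns on a fixed 6-tip tree, plus ``n_random`` random
    8-tip instances.  Returns the fraction of agreeing instances (1.0
    expected) and the reconstructed change counts for a planted single
    loss and a planted loss-then-regain pattern.
    """
    from stramtf.phylo import parse_newick

    six = parse_newick("(((A:1,B:2):1,(C:1,D:1):2):1,(E:3,F:1):2);")
    agree = total = 0
    for bits in itertools.product((0, 1), repeat=6):
        states = dict(zip(six.tip_labels, bits))
        rec = fitch_parsimony(six, states)
        agree += rec.total_changes == _brute_force_score(six, states)
        total += 1
    rng = np.random.default_rng(_offset(seed, 5))
    for i in range(n_random):
        tree = sim_tree(SimConfig(n_tips=8, seed=_offset(seed, 6) + i))
        states = dict(zip(tree.tip_labels, rng.integers(0, 2, size=8)))
        agree += fitch_parsimony(tree, states).total_changes == _brute_force_score(
            tree, states
        )
        total += 1

    ladder = parse_newick("(((((A:1,B:1)n1:1,C:1)n2:1,D:1)n3:1,E:1)n4:1,F:1);")
    single_loss = fitch_parsimony(
        ladder, {"A": 0, "B": 0, "C": 1, "D": 1, "E": 1, "F": 1}
    ).total_changes
    loss_regain = fitch_parsimony(
        ladder, {"A": 1, "B": 1, "C": 0, "D": 0, "E": 1, "F": 1}
    ).total_changes
    return {
        "agreement": {"value": agree / total, "n": total},
        "single_loss_changes": {"value": float(single_loss), "n": 6},
        "loss_regain_changes": {"value": float(loss_regain), "n": 6},
    }


def group_test_calibration(
    seed: int = 0,
    n_reps: int = 200,
    n_null: int = 30,
    n_species: int = 12,
    shift_sd: float = 5.0,
    alpha_q: float = 0.05,
) -> dict:
    """Calibration of the group t-test + BH screen on exchangeable counts.

    Counts are i.i.d. log-normal across species (so group labels are
    exchangeable under the null); one family is shifted by ``shift_sd``
    within-family standard deviations in the autotroph group.  Reports
    how often the shifted family attains the minimal q-value and the
    pooled q < alpha_q rate among null families.
    """
    rng = np.random.default_rng(_offset(seed, 7))
    species = [f"sp{i:02d}" for i in range(n_species)]
    half = n_species // 2
    groups = {
        s: ("autotroph" if i < half else "heterotroph")
        for i, s in enumerate(species)
    }
    fams = [f"F{j}" for j in range(n_null + 1)]
    planted_min = 0
    null_flagged = null_total = 0
    for _ in range(n_reps):
        counts = np.maximum(
            1, np.rint(np.exp(rng.normal(2.5, 0.8, size=(n_species, len(fams)))))
        ).astype(int)
        df = pd.DataFrame(counts, index=species, columns=fams)
        sd = float(df["F0"].std(ddof=1)) or 1.0
        auto = [s for s in species if groups[s] == "autotroph"]
        df.loc[auto, "F0"] += int(round(shift_sd * sd))
        sizes = FamilySizeMatrix(counts=df, categories={f: "TF" for f in fams})
        results = group_abundance_test(sizes, groups)
        qs = {r.family_id: r.q_value for r in results if not r.flagged}
        if min(qs, key=qs.get) == "F0":
            planted_min += 1
        for r in results:
            if r.family_id != "F0" and not r.flagged:
                null_total += 1
                null_flagged += r.q_value < alpha_q
    return {
        "planted_min_q_rate": {"value": planted_min / n_reps, "n": n_reps},
        "null_rate": {"value": null_flagged / null_total, "n": null_total},
    }


def whitening_check(seed: int = 0, n_trees: int = 500, max_tips: int = 16) -> dict:
    """Max deviation of A V A' from the identity over random trees.

    A is the linear contrast map (recovered by probing with unit tip
    vectors), V the BM tip covariance from root-to-MRCA path lengths;
    standardized contrasts must whiten V exactly under Brownian motion.
    """
    base = _offset(seed, 8)
    worst = 0.0
    for rep in range(n_trees):
        rng = np.random.default_rng(base + rep)
        n = int(rng.integers(4, max_tips + 1))
        tree = sim_tree(SimConfig(n_tips=n, seed=base + rep))
        cols = []
        for t in tree.tip_labels:
            x = {u: (1.0 if u == t else 0.0) for u in tree.tip_labels}
            cols.append(pic_contrasts(tree, x).contrasts)
        A = np.column_stack(cols)
        V, taxa = tree.bm_covariance()
        order = [taxa.index(t) for t in tree.tip_labels]
        V = V[np.ix_(order, order)]
        dev = float(np.max(np.abs(A @ V @ A.T - np.eye(n - 1))))
        worst = max(worst, dev)
    return {"value": worst, "n": n_trees}
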