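"""End-to-end orchestration: classify, comparative analysis, simulation.

Each run writes its outputs as TSV plus a machine-readable provenance
record (``provenance.json``: configuration, package version, seed and
per-stage record counts) so results can be audited and reproduced.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import stramtf
from stramtf.comparative import (
    group_abundance_test,
    group_results_frame,
    map_all_families,
    presence_matrix,
)
from stramtf.domhits import attach_ga, build_profiles, filter_by_ga, read_domtblout, read_hits_tsv
from stramtf.errors import ConfigurationError
from stramtf.phylo import (
    correlate_families,
    correlation_results_frame,
    read_newick,
    read_traits,
)
from stramtf.rule_engine import (
    FamilySizeMatrix,
    classify_proteome,
    family_size_matrix,
    load_rules,
    relative_importance,
)
from stramtf.simulate import SimConfig, simulate_bundle

log = logging.getLogger("stramtf")

__all__ = ["RunConfig", "run_classify", "run_comparative", "run_simulate"]


@dataclass
class RunConfig:
    """Configuration for a pipeline run (mirrors the YAML config file)."""

    hits: str | None = None           # hits TSV, or directory of domtblout files
    rules: str | None = None
    tree: str | None = None
    traits: str | None = None
    groups: str | None = None
    sizes: str | None = None          # precomputed family-size matrix (TSV)
    outdir: str = "stramtf_out"
    ga_mode: str = "inclusive"        # inclusive (HMMER --cut_ga) | strict
    ambiguity_policy: str = "report_all"
    correlation_mode: str = "through_origin"
    fdr_alpha: float = 0.05
    parsimony: str = "fitch"          # fitch | dollo
    tiebreak: str = "deltran"         # deltran | acctran
    presence_threshold: int = 0
    log10_traits: list[str] = field(default_factory=list)
    species_regex: str | None = None  # species from protein ids in domtblout
    seed: int = 0                     # simulate subcommand only
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    def __post_init__(self) -> None:
        if not (0 < self.fdr_alpha <= 1):
            raise ValueError("fdr_alpha must be in (0, 1]")

    def require(self, *names: str) -> None:
        for name in names:
            path = getattr(self, name)
            if path is None:
                raise ConfigurationError(f"config is missing required path {name!r}")
            if not Path(path).exists():
                raise ConfigurationError(f"{name} path does not exist: {path}")


def _provenance(cfg: RunConfig, stage_counts: dict, outdir: Path) -> None:
    record = {
        "package": "stramtf",
        "version": stramtf.__version__,
        "config": dataclasses.asdict(cfg),
        "stage_counts": stage_counts,
    }
    with open(outdir / "provenance.json", "wt", encoding="utf-8") as fh:
        json.dump(record, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _read_hits(cfg: RunConfig) -> list:
    path = Path(cfg.hits)
    if path.is_dir():
        hits = []
        for f in sorted(path.iterdir()):
            if f.suffix in (".domtbl", ".domtblout", ".txt"):
                species = None if cfg.species_regex else f.stem
                hits.extend(
                    read_domtblout(f, species_id=species, species_regex=cfg.species_regex)
                )
        return hits
    return read_hits_tsv(path)


def run_classify(cfg: RunConfig) -> FamilySizeMatrix:
    """Hits -> GA filter -> profiles -> family assignment -> size matrix.

    Writes ``family_sizes.tsv`` and ``relative_importance.tsv`` and logs
    record counts per stage.
    """
    cfg.require("hits", "rules")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rules = load_rules(cfg.rules)
    hits = _read_hits(cfg)
    hits = attach_ga(hits, rules.domain_ga)
    kept = filter_by_ga(hits, mode=cfg.ga_mode)
    profiles = build_profiles(kept)
    assignments = classify_proteome(profiles, rules, ambiguity_policy=cfg.ambiguity_policy)
    species = sorted({h.species_id for h in hits})
    sizes = family_size_matrix(assignments, species, rules)
    counts = {
        "hits_read": len(hits),
        "hits_passing_ga": len(kept),
        "ga_mode": cfg.ga_mode,
        "proteins_profiled": len(profiles),
        "proteins_classified": len(assignments),
        "ambiguous_proteins": sum(a.ambiguous for a in assignments),
        "ambiguity_policy": cfg.ambiguity_policy,
        "families": len(rules),
        "species": len(species),
    }
    for key, value in counts.items():
        log.info("classify: %s = %s", key, value)
    sizes.to_tsv(outdir / "family_sizes.tsv")
    ri = relative_importance(sizes)
    ri.to_csv(outdir / "relative_importance.tsv", sep="\t", index_label="species")
    _provenance(cfg, counts, outdir)
    return sizes


def run_comparative(cfg: RunConfig, sizes: FamilySizeMatrix | None = None) -> dict:
    """PIC correlation screen, gain/loss mapping and group tests.

    Uses a provided/previously written size matrix, the input tree, the
    trait table and the group file.  Writes ``pic_correlations.tsv``,
    ``gain_loss_events.tsv``, ``annotated_tree.nwk``,
    ``group_tests.tsv`` and a per-trait significance summary.
    """
    cfg.require("tree", "traits")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if sizes is None:
        size_path = cfg.sizes or str(outdir / "family_sizes.tsv")
        if not Path(size_path).exists():
            raise ConfigurationError(
                f"no size matrix: run classify first or set 'sizes' ({size_path})"
            )
        sizes = FamilySizeMatrix.from_tsv(size_path)
    tree = read_newick(cfg.tree)
    continuous, _binary = read_traits(cfg.traits)

    results = correlate_families(
        tree,
        continuous,
        sizes,
        alpha_q=cfg.fdr_alpha,
        mode=cfg.correlation_mode,
        log10_traits=cfg.log10_traits,
    )
    corr = correlation_results_frame(results)
    corr.to_csv(outdir / "pic_correlations.tsv", sep="\t", index=False)
    summary = (
        corr[corr["significant"]]
        .groupby("trait")["family"]
        .apply(lambda s: ",".join(sorted(s)))
    )
    summary.to_csv(outdir / "significant_families.tsv", sep="\t", header=["families"])

    pm = presence_matrix(sizes, threshold=cfg.presence_threshold)
    recon = map_all_families(tree, pm, method=cfg.parsimony, tiebreak=cfg.tiebreak)
    with open(outdir / "gain_loss_events.tsv", "wt", encoding="utf-8") as fh:
        fh.write("family\tedge\tevent\ttotal_changes\troot_state\tambiguous_edges\n")
        for r in recon:
            amb = ",".join(r.ambiguous_edges)
            if r.events:
                for edge, event in r.events:
                    fh.write(f"{r.family_id}\t{edge}\t{event}\t{r.total_changes}\t"
                             f"{r.root_state}\t{amb}\n")
            else:
                fh.write(f"{r.family_id}\t\tnone\t0\t{r.root_state}\t{amb}\n")
    edge_tags: dict[str, list[str]] = {}
    for r in recon:
        for edge, event in r.events:
            edge_tags.setdefault(edge, []).append(f"{r.family_id}:{event}")
    comments = {edge: "events=" + "|".join(tags) for edge, tags in edge_tags.items()}
    (outdir / "annotated_tree.nwk").write_text(
        tree.to_newick(edge_comments=comments) + "\n", encoding="utf-8"
    )

    stage = {
        "tests": len(results),
        "significant": int(corr["significant"].sum()),
        "families_with_events": sum(1 for r in recon if r.events),
        "correlation_mode": cfg.correlation_mode,
        "parsimony": cfg.parsimony,
        "tiebreak": cfg.tiebreak,
    }
    group_results = None
    if cfg.groups and Path(cfg.groups).exists():
        groups = _read_groups(cfg.groups)
        group_results = group_abundance_test(sizes, groups)
        group_results_frame(group_results).to_csv(
            outdir / "group_tests.tsv", sep="\t", index=False
        )
        stage["group_tests"] = len(group_results)
    for key, value in stage.items():
        log.info("comparative: %s = %s", key, value)
    _provenance(cfg, stage, outdir)
    return {"correlations": results, "reconstructions": recon, "group_tests": group_results}


def _read_groups(path: str | Path) -> dict[str, str]:
    groups: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("species"):
            raise ConfigurationError(f"{path}: expected 'species<TAB>group' header")
        for line in fh:
            if line.strip():
                sp, grp = line.rstrip("\n").split("\t")
                groups[sp] = grp
    return groups


def run_simulate(cfg: RunConfig):
    """Generate a synthetic input bundle into the output directory."""
    sim_kwargs = dict(cfg.sim)
    sim_kwargs.setdefault("seed", cfg.seed)
    sim = SimConfig(**sim_kwargs)
    bundle = simulate_bundle(sim)
    paths = bundle.write(cfg.outdir)
    log.info(
        "simulate: %d species, %d families, %d hits -> %s",
        sim.n_tips, sim.n_families, len(bundle.hits), cfg.outdir,
    )
    return bundle, paths
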