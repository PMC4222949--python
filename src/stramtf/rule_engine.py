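"""Family rules: loading, protein classification, family-size matrices.

A TF/TR family is defined by its domain architecture: a conjunction of
required clauses (each clause an OR over alternative domains, e.g.
alternative DNA-binding domains) plus a set of forbidden domains whose
presence vetoes membership.  In the rule file every ``should`` row adds a
domain to a required clause and every ``should_not`` row adds a forbidden
domain; ``should`` rows sharing a ``clause_id`` form one OR-clause, and a
file without a ``clause_id`` column puts every required domain in its own
clause (pure AND — the strictest reading of "must appear").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from stramtf.domhits import ProteinDomainProfile
from stramtf.errors import ConsistencyError, SchemaError

__all__ = [
    "FamilyRule",
    "RuleSet",
    "FamilyAssignment",
    "FamilySizeMatrix",
    "load_rules",
    "write_rules",
    "evaluate_rule",
    "classify_proteome",
    "family_size_matrix",
    "relative_importance",
]

CATEGORIES = ("TF", "TR")


@dataclass(frozen=True)
class FamilyRule:
    """Required/forbidden domain architecture of one family.

    ``required_clauses`` is a conjunction of clauses; a profile satisfies a
    clause when it carries ANY of the clause's domains.  ``forbidden``
    domains veto membership outright.
    """

    family_id: str
    category: str  # "TF" (sequence-specific DNA binding) or "TR" (other regulators)
    required_clauses: tuple[frozenset[str], ...]
    forbidden: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.family_id}: category must be one of {CATEGORIES}")
        if not self.required_clauses or any(not c for c in self.required_clauses):
            raise ValueError(f"{self.family_id}: required clauses must be non-empty")
        required_union = frozenset().union(*self.required_clauses)
        if required_union & self.forbidden:
            raise ValueError(
                f"{self.family_id}: forbidden set overlaps required domains "
                f"{sorted(required_union & self.forbidden)}"
            )


@dataclass
class RuleSet:
    """All family rules plus an optional per-domain gathering-cutoff table."""

    rules: list[FamilyRule]
    domain_ga: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.family_id for r in self.rules]
        dupes = {f for f in ids if ids.count(f) > 1}
        if dupes:
            raise ValueError(f"duplicate family_id(s): {sorted(dupes)}")

    def __iter__(self):
        return iter(self.rules)

    def __len__(self) -> int:
        return len(self.rules)

    @property
    def family_ids(self) -> list[str]:
        return [r.family_id for r in self.rules]

    @property
    def categories(self) -> dict[str, str]:
        return {r.family_id: r.category for r in self.rules}


@dataclass
class FamilyAssignment:
    """Families a single protein was assigned to (possibly several)."""

    protein_id: str
    species_id: str
    families: tuple[str, ...]

    @property
    def ambiguous(self) -> bool:
        return len(self.families) > 1


@dataclass
class FamilySizeMatrix:
    """Species x family matrix of classified-protein counts.

    ``counts`` is a pandas DataFrame with species as the row index and
    families as columns; ``categories`` maps each family to TF or TR.
    Families with zero counts everywhere are retained so downstream
    gain/loss mapping can see absences.
    """

    counts: pd.DataFrame
    categories: dict[str, str]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.categories)
        if missing:
            raise ValueError(f"families without category label: {sorted(missing)}")

    @property
    def species(self) -> list[str]:
        return list(self.counts.index)

    @property
    def families(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        """Write counts with a category annotation row under the header."""
        with open(path, "wt", encoding="utf-8") as fh:
            fh.write("species\t" + "\t".join(self.families) + "\n")
            fh.write("#category\t" + "\t".join(self.categories[f] for f in self.families) + "\n")
            for sp in self.species:
                row = self.counts.loc[sp]
                fh.write(sp + "\t" + "\t".join(str(int(v)) for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FamilySizeMatrix":
        with open(path, "rt", encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            families = header[1:]
            cat_row = fh.readline().rstrip("\n").split("\t")
            if cat_row[0] != "#category":
                raise SchemaError(f"{path}: expected '#category' annotation row")
            categories = dict(zip(families, cat_row[1:]))
            species, rows = [], []
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                species.append(parts[0])
                rows.append([int(v) for v in parts[1:]])
        counts = pd.DataFrame(rows, index=species, columns=families)
        return cls(counts=counts, categories=categories)


_RULE_REQUIRED_COLS = ("family_id", "category", "domain_id", "type")


def load_rules(path: str | Path) -> RuleSet:
    """Load a family rule file (TSV).

    Columns: ``family_id``, ``category`` (TF/TR), ``domain_id``, ``type``
    (``should`` / ``should_not``), optional ``clause_id`` and optional
    ``ga_cutoff`` (populates the per-domain GA table).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _RULE_REQUIRED_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing rule column(s) {missing}")
    bad_types = set(df["type"]) - {"should", "should_not"}
    if bad_types:
        raise SchemaError(f"{path}: unknown type token(s) {sorted(bad_types)}")

    domain_ga: dict[str, float] = {}
    if "ga_cutoff" in df.columns:
        for _, row in df.iterrows():
            ga = row["ga_cutoff"]
            if isinstance(ga, str) and ga.strip():
                domain_ga[row["domain_id"]] = float(ga)

    rules: list[FamilyRule] = []
    for family_id, grp in df.groupby("family_id", sort=True):
        cats = sorted(set(grp["category"]))
        if len(cats) != 1:
            raise SchemaError(
                f"{path}: family {family_id!r} has conflicting categories {cats}"
            )
        should = grp[grp["type"] == "should"]
        if should.empty:
            raise SchemaError(f"{path}: family {family_id!r} has no 'should' rows")
        if "clause_id" in grp.columns and should["clause_id"].notna().all():
            clauses = tuple(
                frozenset(sub["domain_id"])
                for _, sub in should.groupby("clause_id", sort=True)
            )
        else:
            # flat file: every required domain is its own clause (pure AND)
            clauses = tuple(frozenset([d]) for d in sorted(set(should["domain_id"])))
        forbidden = frozenset(grp.loc[grp["type"] == "should_not", "domain_id"])
        rules.append(
            FamilyRule(
                family_id=str(family_id),
                category=cats[0],
                required_clauses=clauses,
                forbidden=forbidden,
            )
        )
    return RuleSet(rules=rules, domain_ga=domain_ga)


def write_rules(ruleset: RuleSet, path: str | Path) -> None:
    """Write a RuleSet back to the rule-file TSV dialect."""
    has_ga = bool(ruleset.domain_ga)
    cols = ["family_id", "category", "domain_id", "type", "clause_id"]
    if has_ga:
        cols.append("ga_cutoff")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")

        def emit(family, category, domain, typ, clause):
            row = [family, category, domain, typ, clause]
            if has_ga:
                ga = ruleset.domain_ga.get(domain)
                row.append("" if ga is None else repr(ga))
            fh.write("\t".join(row) + "\n")

        for rule in ruleset:
            for i, clause in enumerate(rule.required_clauses, start=1):
                for domain in sorted(clause):
                    emit(rule.family_id, rule.category, domain, "should", f"c{i}")
            for domain in sorted(rule.forbidden):
                emit(rule.family_id, rule.category, domain, "should_not", "")


def evaluate_rule(rule: FamilyRule, profile: ProteinDomainProfile) -> bool:
    """True iff every required clause intersects the profile and no
    forbidden domain is present."""
    if rule.forbidden & profile.domains:
        return False
    return all(clause & profile.domains for clause in rule.required_clauses)


def classify_proteome(
    profiles: Iterable[ProteinDomainProfile],
    rules: RuleSet,
    ambiguity_policy: str = "report_all",
) -> list[FamilyAssignment]:
    """Assign each protein profile to the families whose rules it satisfies.

    ``report_all`` keeps every satisfied family; ``most_specific`` keeps
    only the satisfied rule(s) with the largest number of required clauses
    (ties kept).  Proteins satisfying no rule are omitted.
    """
    if ambiguity_policy not in ("report_all", "most_specific"):
        raise ValueError(f"unknown ambiguity policy {ambiguity_policy!r}")
    assignments: list[FamilyAssignment] = []
    for profile in sorted(profiles, key=lambda p: (p.species_id, p.protein_id)):
        hits = [r for r in rules if evaluate_rule(r, profile)]
        if not hits:
            continue
        if ambiguity_policy == "most_specific" and len(hits) > 1:
            best = max(len(r.required_clauses) for r in hits)
            hits = [r for r in hits if len(r.required_clauses) == best]
        assignments.append(
            FamilyAssignment(
                protein_id=profile.protein_id,
                species_id=profile.species_id,
                families=tuple(sorted(r.family_id for r in hits)),
            )
        )
    return assignments


def family_size_matrix(
    assignments: Iterable[FamilyAssignment],
    species: Sequence[str],
    rules: RuleSet,
) -> FamilySizeMatrix:
    """Count distinct classified proteins per (species, family).

    A protein assigned to k families increments k cells.  All species in
    ``species`` and all families in ``rules`` appear even when empty.
    """
    counts = pd.DataFrame(0, index=list(species), columns=rules.family_ids, dtype=int)
    known = set(species)
    for a in assignments:
        if a.species_id not in known:
            raise ConsistencyError(
                f"assignment for {a.protein_id!r} references unknown species "
                f"{a.species_id!r}"
            )
        for fam in a.families:
            if fam not in counts.columns:
                raise ConsistencyError(f"assignment references unknown family {fam!r}")
            counts.loc[a.species_id, fam] += 1
    return FamilySizeMatrix(counts=counts, categories=rules.categories)


def relative_importance(m: FamilySizeMatrix) -> pd.DataFrame:
    """Per-species percentage contribution of each family.

    RI[s, f] = 100 * counts[s, f] / total TF+TR assignments in species s.
    Rows of species with no assignments at all are NaN (flagged, not
    fatal); every defined row sums to 100.
    """
    totals = m.counts.sum(axis=1)
    ri = 100.0 * m.counts.div(totals.where(totals > 0), axis=0)
    return ri
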