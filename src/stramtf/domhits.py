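"""Protein-domain hit tables: reading, gathering-cutoff filtering, profiles.

Hits come either from HMMER3 ``--domtblout`` output (one file per species,
or with the species parsed out of the protein identifier) or from a
simplified tab-separated dialect that carries the species column
explicitly.  Hits are filtered against each model's gathering cutoff (GA),
the curated per-model bit-score threshold above which matches are trusted,
and then collapsed into per-protein domain-presence profiles that drive
the family classification.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

from stramtf.errors import ConfigurationError, ParseError, SchemaError

__all__ = [
    "DomainHit",
    "ProteinDomainProfile",
    "read_domtblout",
    "read_hits_tsv",
    "attach_ga",
    "filter_by_ga",
    "build_profiles",
]

# 0-based positions of the fields we use in HMMER3 per-domain table rows.
# target name | target acc | tlen | query name | query acc | qlen | full E |
# full score | full bias | # | of | c-E | i-E | this-domain score | ...
_DOMTBL_TARGET = 0
_DOMTBL_QUERY = 3
_DOMTBL_DOM_SCORE = 13
_DOMTBL_MIN_FIELDS = 22


@dataclass(frozen=True)
class DomainHit:
    """One profile-HMM match of a domain model on a protein.

    ``bit_score`` is the per-domain ("this domain") score, not the
    full-sequence score; the gathering cutoff it is compared against is
    likewise the model's domain-level threshold.  ``ga_cutoff`` may be
    ``None`` until attached from a GA table (domtblout does not carry it).
    """

    protein_id: str
    species_id: str
    domain_id: str
    bit_score: float
    ga_cutoff: float | None = None

    def __post_init__(self) -> None:
        if not self.protein_id or not self.species_id or not self.domain_id:
            raise ValueError("protein_id, species_id and domain_id must be non-empty")
        if not math.isfinite(self.bit_score):
            raise ValueError(f"non-finite bit score for {self.protein_id}/{self.domain_id}")
        if self.ga_cutoff is not None and not math.isfinite(self.ga_cutoff):
            raise ValueError(f"non-finite GA cutoff for domain {self.domain_id}")


@dataclass
class ProteinDomainProfile:
    """Domain content of one protein after GA filtering.

    Classification uses the *set* of domains present; how many copies of
    each domain hit the protein is kept in ``copy_number`` for reporting
    but never consulted by the rules.
    """

    protein_id: str
    species_id: str
    domains: frozenset[str]
    copy_number: Mapping[str, int] = field(default_factory=dict)


def _species_resolver(
    species_id: str | None, species_regex: str | None
) -> Callable[[str], str]:
    if species_id is not None:
        return lambda _pid: species_id
    if species_regex is not None:
        pattern = re.compile(species_regex)

        def from_regex(pid: str) -> str:
            m = pattern.search(pid)
            if m is None:
                raise ParseError(
                    f"protein id {pid!r} does not match species regex {species_regex!r}"
                )
            return m.group(1) if m.groups() else m.group(0)

        return from_regex
    raise ConfigurationError(
        "domtblout carries no species column: pass species_id (one file per "
        "species) or species_regex (parsed from the protein id)"
    )


def read_domtblout(
    path: str | Path,
    *,
    species_id: str | None = None,
    species_regex: str | None = None,
) -> list[DomainHit]:
    """Read HMMER3 per-domain tabular output into :class:`DomainHit` records.

    Lines starting with ``#`` are comments.  The per-domain bit score
    (column 14 of the standard layout) is used.  The protein is the target
    sequence and the domain model the query, i.e. the ``hmmsearch`` of
    domain models against a proteome.

    Parameters
    ----------
    species_id:
        Species label applied to every hit (use when running one file per
        species).
    species_regex:
        Alternative: regex applied to the protein id; group 1 (or the whole
        match) becomes the species label.
    """
    resolve = _species_resolver(species_id, species_regex)
    hits: list[DomainHit] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split()
            if len(fields) < _DOMTBL_MIN_FIELDS:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {_DOMTBL_MIN_FIELDS} fields, "
                    f"got {len(fields)}"
                )
            try:
                score = float(fields[_DOMTBL_DOM_SCORE])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric domain score "
                    f"{fields[_DOMTBL_DOM_SCORE]!r}"
                ) from exc
            protein = fields[_DOMTBL_TARGET]
            hits.append(
                DomainHit(
                    protein_id=protein,
                    species_id=resolve(protein),
                    domain_id=fields[_DOMTBL_QUERY],
                    bit_score=score,
                )
            )
    return hits


_TSV_REQUIRED = ("protein_id", "species_id", "domain_id", "bit_score")


def read_hits_tsv(path: str | Path) -> list[DomainHit]:
    """Read the simplified tab-separated hit dialect.

    Header row must name ``protein_id``, ``species_id``, ``domain_id`` and
    ``bit_score``; an optional ``ga_cutoff`` column attaches the gathering
    threshold directly (otherwise it comes from the rule file's GA table).
    """
    with open(path, "rt", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise SchemaError(f"{path}: empty file")
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in _TSV_REQUIRED if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing required column(s) {missing}")
        idx = {name: header.index(name) for name in header}
        has_ga = "ga_cutoff" in idx
        hits: list[DomainHit] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            try:
                score = float(fields[idx["bit_score"]])
                ga = float(fields[idx["ga_cutoff"]]) if has_ga else None
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric score field") from exc
            hits.append(
                DomainHit(
                    protein_id=fields[idx["protein_id"]],
                    species_id=fields[idx["species_id"]],
                    domain_id=fields[idx["domain_id"]],
                    bit_score=score,
                    ga_cutoff=ga,
                )
            )
    return hits


def write_hits_tsv(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the TSV dialect (with GA column when any hit has one)."""
    hits = list(hits)
    has_ga = any(h.ga_cutoff is not None for h in hits)
    cols = list(_TSV_REQUIRED) + (["ga_cutoff"] if has_ga else [])
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for h in hits:
            row = [h.protein_id, h.species_id, h.domain_id, repr(h.bit_score)]
            if has_ga:
                row.append("" if h.ga_cutoff is None else repr(h.ga_cutoff))
            fh.write("\t".join(row) + "\n")


def attach_ga(hits: Iterable[DomainHit], domain_ga: Mapping[str, float]) -> list[DomainHit]:
    """Attach gathering cutoffs from a per-domain GA table.

    A GA already present on a hit (e.g. from the TSV dialect) wins over the
    table.  Hits whose domain is absent from both are returned with
    ``ga_cutoff=None`` and will trip :func:`filter_by_ga`.
    """
    out = []
    for h in hits:
        if h.ga_cutoff is None and h.domain_id in domain_ga:
            h = DomainHit(h.protein_id, h.species_id, h.domain_id, h.bit_score,
                          float(domain_ga[h.domain_id]))
        out.append(h)
    return out


def filter_by_ga(hits: Iterable[DomainHit], mode: str = "inclusive") -> list[DomainHit]:
    """Keep hits whose per-domain bit score clears the model's GA.

    ``inclusive`` (default) keeps score >= GA, matching HMMER's
    ``--cut_ga`` convention; ``strict`` requires score > GA.
    """
    if mode not in ("strict", "inclusive"):
        raise ValueError(f"unknown GA mode {mode!r}")
    kept: list[DomainHit] = []
    for h in hits:
        if h.ga_cutoff is None:
            raise ConfigurationError(
                f"hit {h.protein_id}/{h.domain_id}: no gathering cutoff known "
                f"for domain {h.domain_id!r}; supply a GA table"
            )
        if (h.bit_score > h.ga_cutoff) or (mode == "inclusive" and h.bit_score == h.ga_cutoff):
            kept.append(h)
    return kept


def build_profiles(hits: Iterable[DomainHit]) -> list[ProteinDomainProfile]:
    """Collapse GA-filtered hits into per-protein domain-presence profiles.

    One profile per distinct (species, protein); repeated hits of the same
    domain count once for presence, with the multiplicity retained in
    ``copy_number``.  Output order is sorted by (species, protein) so the
    result is independent of input hit order.
    """
    copies: dict[tuple[str, str], dict[str, int]] = {}
    for h in hits:
        key = (h.species_id, h.protein_id)
        dom = copies.setdefault(key, {})
        dom[h.domain_id] = dom.get(h.domain_id, 0) + 1
    return [
        ProteinDomainProfile(
            protein_id=protein,
            species_id=species,
            domains=frozenset(dom),
            copy_number=dict(sorted(dom.items())),
        )
        for (species, protein), dom in sorted(copies.items())
    ]
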