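"""Per-protein domain hits, domain architectures, and domain groups.

A domain hit records where a profile matched a protein (1-based inclusive
envelope coordinates, HMMER convention).  Architectures list a protein's
domains ordered along the sequence after resolving overlaps; a *domain
group* collects, for one domain accession, every protein and species
carrying it together with per-species copy counts.  Domain groups play
the same role for domains that families play for proteins: they are the
characters whose presence/absence and member duplications are traced on
the species tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "DomainHit",
    "Architecture",
    "DomainGroup",
    "parse_domain_hits",
    "read_domtblout",
    "architectures",
    "domain_groups",
]


class DomainTableError(ValueError):
    pass


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    domain: str
    start: int  # 1-based, inclusive
    end: int
    score: float
    evalue: float


@dataclass(frozen=True)
class Architecture:
    protein_id: str
    domains: tuple[str, ...]  # ordered by start coordinate


@dataclass(frozen=True)
class DomainGroup:
    domain: str
    proteins: frozenset[str]
    copies: dict  # species -> copy count

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.copies)


def _check_row(protein, domain, start, end, score, evalue, lineno):
    try:
        start, end = int(start), int(end)
        score, evalue = float(score), float(evalue)
    except (TypeError, ValueError) as exc:
        raise DomainTableError(f"line {lineno}: unparsable row: {exc}") from exc
    if start < 1 or end < start:
        raise DomainTableError(
            f"line {lineno}: invalid envelope {start}..{end} for {protein}"
        )
    return DomainHit(str(protein), str(domain), start, end, score, evalue)


def parse_domain_hits(
    table: pd.DataFrame, evalue_cutoff: float | str = "precomputed"
) -> list[DomainHit]:
    """Parse a 6-column domain-hit table (protein, domain, start, end,
    score, evalue), optionally filtering on independent E-value.

    ``evalue_cutoff="precomputed"`` trusts the table as already
    thresholded and keeps every row.
    """
    hits = []
    for i, row in enumerate(table.itertuples(index=False), start=1):
        hit = _check_row(row[0], row[1], row[2], row[3], row[4], row[5], i)
        if evalue_cutoff == "precomputed" or hit.evalue <= float(evalue_cutoff):
            hits.append(hit)
    return hits


def read_domain_tsv(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        names=["protein", "domain", "start", "end", "score", "evalue"],
        comment="#",
    )


def read_domtblout(path) -> pd.DataFrame:
    """Read HMMER3 --domtblout rows into the simplified 6-column layout.

    Uses the envelope coordinates (columns 20-21), the per-domain bit
    score (column 14) and the independent E-value (column 13).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            rows.append((f[0], f[3], int(f[19]), int(f[20]), float(f[13]), float(f[12])))
    return pd.DataFrame(
        rows, columns=["protein", "domain", "start", "end", "score", "evalue"]
    )


def _overlap(a: DomainHit, b: DomainHit) -> float:
    """Overlap as a fraction of the shorter envelope."""
    inter = min(a.end, b.end) - max(a.start, b.start) + 1
    if inter <= 0:
        return 0.0
    shorter = min(a.end - a.start, b.end - b.start) + 1
    return inter / shorter


def architectures(hits: list[DomainHit]) -> list[Architecture]:
    """Per-protein ordered domain lists after overlap resolution.

    Hits overlapping by more than half the shorter envelope are resolved
    by keeping the higher bit score; ties go to the lower E-value, then
    the lexicographically smaller accession.  The result is independent
    of input row order.
    """
    by_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_protein.setdefault(h.protein_id, []).append(h)
    out = []
    for protein in sorted(by_protein):
        # deterministic processing order: best hits claim their span first
        ranked = sorted(
            by_protein[protein],
            key=lambda h: (-h.score, h.evalue, h.domain, h.start, h.end),
        )
        kept: list[DomainHit] = []
        for h in ranked:
            if all(_overlap(h, k) <= 0.5 for k in kept):
                kept.append(h)
        kept.sort(key=lambda h: (h.start, h.end, h.domain))
        out.append(Architecture(protein, tuple(h.domain for h in kept)))
    return out


def domain_groups(
    hits: list[DomainHit], protein_species: dict[str, str]
) -> list[DomainGroup]:
    """One group per distinct domain accession with per-species copy counts.

    Every hit counts as one copy (tandem repeats on one protein count
    once each).  Unmapped proteins are an error.
    """
    groups: dict[str, dict] = {}
    for h in hits:
        if h.protein_id not in protein_species:
            raise KeyError(f"protein {h.protein_id!r} has no species mapping")
        g = groups.setdefault(h.domain, {"proteins": set(), "copies": {}})
        g["proteins"].add(h.protein_id)
        sp = protein_species[h.protein_id]
        g["copies"][sp] = g["copies"].get(sp, 0) + 1
    return [
        DomainGroup(d, frozenset(g["proteins"]), dict(sorted(g["copies"].items())))
        for d, g in sorted(groups.items())
    ]
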