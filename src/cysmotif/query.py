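"""Catalog queries: by protein id, by motif string, by FASTA sequence.

The FASTA query reproduces the per-cysteine report shape used for the
protein disulphide isomerase worked example: for each cysteine of the
query sequence, its k-flank motif and the catalog's total / bonded /
coefficient for that motif (zeros when the motif is absent).

Filters restrict the population of catalog records by the provenance
flags of their source proteins (engineered, mutated, DNA/RNA-linked);
an unset filter imposes no constraint, so filtered statistics are always
a contraction of the unfiltered ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .catalog import (MotifCatalog, MotifClass, MotifStats, aggregate_stats,
                      coefficient)
from .extraction import (BondScope, BondState, MotifRecord, extract_motif,
                         find_cysteines)


@dataclass(frozen=True)
class QueryFilters:
    """Provenance filters; ``None`` means no constraint on that flag."""

    engineered: bool | None = None
    mutated: bool | None = None
    nucleic_link: bool | None = None

    @property
    def unconstrained(self) -> bool:
        return self.engineered is None and self.mutated is None and self.nucleic_link is None


def apply_filters(catalog: MotifCatalog,
                  records: list[MotifRecord] | None = None,
                  filters: QueryFilters | None = None) -> list[MotifRecord]:
    """Subset of motif records whose source protein matches every set flag."""
    records = catalog.records if records is None else records
    if filters is None or filters.unconstrained:
        return list(records)
    out = []
    for rec in records:
        info = catalog.proteins.get(rec.site.protein_id)
        if info is None:
            continue
        if filters.engineered is not None and info.engineered != filters.engineered:
            continue
        if filters.mutated is not None and info.mutated != filters.mutated:
            continue
        if filters.nucleic_link is not None and info.has_nucleic_link != filters.nucleic_link:
            continue
        out.append(rec)
    return out


def _filtered_stats(catalog: MotifCatalog,
                    filters: QueryFilters | None) -> dict[tuple[str, int], MotifStats]:
    if filters is None or filters.unconstrained:
        return catalog.stats
    return aggregate_stats(apply_filters(catalog, None, filters))


# ---------------------------------------------------------------------------
# by protein id

@dataclass
class BondingSummary:
    bonded: int = 0
    free: int = 0
    intrachain: int = 0
    interchain: int = 0


@dataclass
class ProteinReport:
    protein_id: str
    found: bool
    records: list[MotifRecord] = field(default_factory=list)
    summary: BondingSummary = field(default_factory=BondingSummary)

    def record_stats(self, catalog: MotifCatalog) -> list[MotifStats]:
        return [catalog.stats[(r.motif, r.k)] for r in self.records]


def query_by_id(catalog: MotifCatalog, ids: list[str],
                filters: QueryFilters | None = None) -> list[ProteinReport]:
    """One report per requested id: its motif records, plus a bonding
    summary over its cysteines (bonded/free and intra-/inter-chain counts).
    Unknown ids are reported as not found, never fatally."""
    by_protein: dict[str, list[MotifRecord]] = {}
    for rec in apply_filters(catalog, None, filters):
        by_protein.setdefault(rec.site.protein_id, []).append(rec)

    reports = []
    for pid in ids:
        recs = by_protein.get(pid)
        if recs is None:
            reports.append(ProteinReport(pid, found=False))
            continue
        summary = BondingSummary()
        seen_sites = set()
        for rec in recs:
            key = (rec.site.chain_id, rec.site.position)
            if key in seen_sites:
                continue
            seen_sites.add(key)
            if rec.site.state is BondState.BONDED:
                summary.bonded += 1
                if rec.site.scope is BondScope.INTRACHAIN:
                    summary.intrachain += 1
                elif rec.site.scope is BondScope.INTERCHAIN:
                    summary.interchain += 1
            else:
                summary.free += 1
        reports.append(ProteinReport(pid, True, sorted(
            recs, key=lambda r: (r.site.chain_id, r.site.position, r.k)), summary))
    return reports


# ---------------------------------------------------------------------------
# by motif

@dataclass
class MotifQueryResult:
    motif: str
    k: int
    total: int
    bonded: int
    coefficient: float
    cls: MotifClass | None
    occurrences: list[MotifRecord] = field(default_factory=list)


def validate_motif(motif: str) -> int:
    """Check a query motif (odd length, central C, widths 1..5); returns k."""
    if len(motif) % 2 == 0 or not 3 <= len(motif) <= 11:
        raise ValueError(
            f"motif {motif!r}: length must be odd and between 3 and 11 "
            "(flank widths 1..5)")
    k = len(motif) // 2
    if motif[k] != "C":
        raise ValueError(f"motif {motif!r}: centre residue must be C")
    return k


def query_by_motif(catalog: MotifCatalog, motif: str,
                   filters: QueryFilters | None = None) -> MotifQueryResult:
    """Statistics and every catalog occurrence of one motif string."""
    motif = motif.upper()
    k = validate_motif(motif)
    occurrences = [r for r in apply_filters(catalog, None, filters)
                   if r.motif == motif and r.k == k]
    total = len(occurrences)
    bonded = sum(1 for r in occurrences if r.site.state is BondState.BONDED)
    if total == 0:
        return MotifQueryResult(motif, k, 0, 0, 0.0, None, [])
    stats = MotifStats(motif, k, total, bonded)
    return MotifQueryResult(motif, k, total, bonded, stats.coefficient,
                            stats.cls, occurrences)


# ---------------------------------------------------------------------------
# by FASTA sequence

@dataclass(frozen=True)
class FastaQueryRow:
    """One row per query-sequence cysteine: Position / Motif / Total /
    Bond / Coefficient (zeros when the motif is absent from the catalog)."""

    position: int
    motif: str
    total: int
    bonded: int
    coefficient: float
    cls: MotifClass | None


def query_by_fasta(catalog: MotifCatalog,
                   sequences: list[tuple[str, str]], k: int,
                   filters: QueryFilters | None = None
                   ) -> dict[str, list[FastaQueryRow]]:
    """For each FASTA record, one row per cysteine, in sequence order.

    Query motifs at the termini are '-'-padded exactly as during catalog
    construction, so the lookup keys always align."""
    if k not in catalog.k_set:
        raise ValueError(f"catalog was built without flank width {k} "
                         f"(available: {catalog.k_set})")
    stats = _filtered_stats(catalog, filters)
    results: dict[str, list[FastaQueryRow]] = {}
    for rec_id, seq in sequences:
        rows = []
        for pos in find_cysteines(seq.upper()):
            motif = extract_motif(seq.upper(), pos, k)
            s = stats.get((motif, k))
            if s is None:
                rows.append(FastaQueryRow(pos, motif, 0, 0, 0.0, None))
            else:
                rows.append(FastaQueryRow(pos, motif, s.total, s.bonded,
                                          coefficient(s.total, s.bonded), s.cls))
        results[rec_id] = rows
    return results
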