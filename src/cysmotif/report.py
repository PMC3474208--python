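"""Render query results as aligned text, CSV, or JSON lines.

Text and CSV carry identical values; JSONL adds nothing and loses
nothing either — it is the batch/API surface.
"""

from __future__ import annotations

import csv
import io
import json
from typing import Sequence

from .catalog import MotifCatalog, render_coefficient
from .query import FastaQueryRow, MotifQueryResult, ProteinReport

_FASTA_HEADER = ["Position", "Motif", "Total", "Bond", "Coefficient"]


def _fasta_row_values(row: FastaQueryRow) -> list[str]:
    return [str(row.position), row.motif, str(row.total), str(row.bonded),
            render_coefficient(row.coefficient)]


def _text_table(header: Sequence[str], rows: list[list[str]]) -> str:
    widths = [max(len(h), *(len(r[i]) for r in rows)) if rows else len(h)
              for i, h in enumerate(header)]
    fmt = "  ".join(f"{{:<{w}}}" for w in widths)
    out = [fmt.format(*header)]
    out.extend(fmt.format(*r) for r in rows)
    return "\n".join(out) + "\n"


def _csv_table(header: Sequence[str], rows: list[list[str]]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(header)
    writer.writerows(rows)
    return buf.getvalue()


def format_fasta_results(results: dict[str, list[FastaQueryRow]],
                         fmt: str = "text") -> str:
    if fmt == "jsonl":
        lines = []
        for rec_id, rows in results.items():
            for row in rows:
                lines.append(json.dumps({
                    "query": rec_id, "position": row.position, "motif": row.motif,
                    "total": row.total, "bonded": row.bonded,
                    "coefficient": float(render_coefficient(row.coefficient)),
                    "class": row.cls.value if row.cls else None,
                }, sort_keys=True))
        return "\n".join(lines) + ("\n" if lines else "")
    chunks = []
    for rec_id, rows in results.items():
        values = [_fasta_row_values(r) for r in rows]
        if fmt == "csv":
            chunks.append(_csv_table(["Query"] + _FASTA_HEADER,
                                     [[rec_id] + v for v in values]))
        else:
            chunks.append(f"# {rec_id}\n" + _text_table(_FASTA_HEADER, values))
    return "\n".join(chunks)


def format_motif_result(result: MotifQueryResult, fmt: str = "text") -> str:
    cls = result.cls.value if result.cls else ""
    if fmt == "jsonl":
        head = json.dumps({
            "motif": result.motif, "k": result.k, "total": result.total,
            "bonded": result.bonded,
            "coefficient": float(render_coefficient(result.coefficient)),
            "class": cls or None,
        }, sort_keys=True)
        occ = [json.dumps({
            "protein_id": r.site.protein_id, "chain_id": r.site.chain_id,
            "position": r.site.position, "state": r.site.state.value,
        }, sort_keys=True) for r in result.occurrences]
        return "\n".join([head] + occ) + "\n"
    header = ["Motif", "Total", "Bond", "Coefficient", "Class"]
    rows = [[result.motif, str(result.total), str(result.bonded),
             render_coefficient(result.coefficient), cls]]
    table = (_csv_table if fmt == "csv" else _text_table)(header, rows)
    occ_header = ["ProteinID", "Chain", "Position", "State"]
    occ_rows = [[r.site.protein_id, r.site.chain_id, str(r.site.position),
                 r.site.state.value] for r in result.occurrences]
    if occ_rows:
        table += "\n" + (_csv_table if fmt == "csv" else _text_table)(occ_header, occ_rows)
    return table


def format_protein_reports(reports: list[ProteinReport], catalog: MotifCatalog,
                           fmt: str = "text") -> str:
    header = ["ProteinID", "Chain", "Position", "K", "Motif", "SS", "State",
              "Scope", "Total", "Bond", "Coefficient"]
    chunks = []
    for rep in reports:
        if not rep.found:
            if fmt == "jsonl":
                chunks.append(json.dumps({"protein_id": rep.protein_id,
                                          "found": False}, sort_keys=True))
            else:
                chunks.append(f"# {rep.protein_id}: not found\n")
            continue
        rows = []
        for rec in rep.records:
            stats = catalog.stats[(rec.motif, rec.k)]
            rows.append([rep.protein_id, rec.site.chain_id, str(rec.site.position),
                         str(rec.k), rec.motif, rec.ss, rec.site.state.value,
                         rec.site.scope.value if rec.site.scope else "",
                         str(stats.total), str(stats.bonded),
                         render_coefficient(stats.coefficient)])
        s = rep.summary
        if fmt == "jsonl":
            chunks.append(json.dumps({
                "protein_id": rep.protein_id, "found": True,
                "summary": {"bonded": s.bonded, "free": s.free,
                            "intrachain": s.intrachain, "interchain": s.interchain},
                "records": [dict(zip([h.lower() for h in header], r)) for r in rows],
            }, sort_keys=True))
        elif fmt == "csv":
            chunks.append(_csv_table(header, rows))
        else:
            chunks.append(
                f"# {rep.protein_id}  bonded={s.bonded} free={s.free} "
                f"intrachain={s.intrachain} interchain={s.interchain}\n"
                + _text_table(header, rows))
    return "\n".join(chunks) + ("\n" if fmt == "jsonl" and chunks else "")
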