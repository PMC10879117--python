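"""Readers and writers for the on-disk formats.

All tabular formats are plain tab-separated text.  Allele tables follow
the CRISPResso2 allele-frequency dialect (columns ``Aligned_Sequence``,
``Reference_Sequence``, ``n_deleted``, ``n_inserted``, ``n_mutated``,
``#Reads``); the reader tolerates extra columns and accepts both the
gapped-reference convention (insertions widen the alignment) and this
package's annotation convention (ungapped reference plus an
``insertions`` column).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Iterable, Sequence

import pandas as pd
import yaml

from .sites import AlleleRow, AlleleTable, RunConfig, SiteError, TargetSite

REQUIRED_ALLELE_COLUMNS = [
    "Aligned_Sequence",
    "Reference_Sequence",
    "n_deleted",
    "n_inserted",
    "n_mutated",
    "#Reads",
]


# ---------------------------------------------------------------------------
# target sites


def read_sites(path: str | Path) -> list[TargetSite]:
    """Read target sites from TSV (or FASTA with structured headers).

    TSV columns: ``site_id``, ``editor``, ``context40`` and optionally
    ``protospacer`` (cross-checked), ``chrom``, ``start``, ``strand``,
    ``dataset``.  Malformed records raise :class:`SiteError` naming the
    offending site.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        return _read_sites_fasta(text)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("site_id", "editor", "context40"):
        if col not in df.columns:
            raise SiteError(f"sites file missing required column {col!r}")
    sites = []
    for rec in df.to_dict("records"):
        site = TargetSite(
            site_id=str(rec["site_id"]),
            editor=str(rec["editor"]),
            context40=str(rec["context40"]).upper(),
            chrom=rec.get("chrom") if pd.notna(rec.get("chrom")) else None,
            start=int(rec["start"]) if pd.notna(rec.get("start")) else None,
            strand=rec.get("strand") if pd.notna(rec.get("strand")) else "+",
            dataset=rec.get("dataset") if pd.notna(rec.get("dataset")) else "synthetic",
        )
        stated = rec.get("protospacer")
        if pd.notna(stated) and str(stated).upper() != site.protospacer:
            raise SiteError(
                f"{site.site_id}: protospacer/context mismatch "
                f"({stated} vs {site.protospacer})"
            )
        sites.append(site)
    return sites


def _read_sites_fasta(text: str) -> list[TargetSite]:
    sites = []
    header, seq = None, []
    for line in text.splitlines() + [">"]:
        line = line.strip()
        if line.startswith(">"):
            if header is not None:
                fields = dict(
                    kv.split("=", 1) for kv in header.split()[1:] if "=" in kv
                )
                sites.append(
                    TargetSite(
                        site_id=header.split()[0],
                        editor=fields.get("editor", "ABE"),
                        context40="".join(seq).upper(),
                        chrom=fields.get("chrom"),
                        start=int(fields["start"]) if "start" in fields else None,
                        strand=fields.get("strand", "+"),
                        dataset=fields.get("dataset", "synthetic"),
                    )
                )
            header, seq = line[1:] or None, []
        elif line:
            seq.append(line)
    return sites


def write_sites(sites: Iterable[TargetSite], path: str | Path) -> None:
    rows = []
    for s in sites:
        rows.append(
            {
                "site_id": s.site_id,
                "editor": s.editor,
                "protospacer": s.protospacer,
                "pam": s.pam,
                "context40": s.context40,
                "chrom": s.chrom if s.chrom is not None else "",
                "start": s.start if s.start is not None else "",
                "strand": s.strand,
                "dataset": s.dataset,
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "site_id", "editor", "protospacer", "pam", "context40",
            "chrom", "start", "strand", "dataset",
        ],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# allele tables


def _format_insertions(ins: Sequence[tuple[int, str]]) -> str:
    return ";".join(f"{i}:{s}" for i, s in ins)


def _parse_insertions(text: str) -> tuple[tuple[int, str], ...]:
    if not text or pd.isna(text):
        return ()
    out = []
    for item in str(text).split(";"):
        idx, seq = item.split(":")
        out.append((int(idx), seq))
    return tuple(out)


def _degap(aligned: str, reference: str) -> tuple[str, str, tuple[tuple[int, str], ...]]:
    """Collapse gapped-reference (insertion) columns into annotations."""
    ref_out, aln_out, insertions = [], [], []
    pending = []
    for a, r in zip(aligned, reference):
        if r == "-":
            if a != "-":
                pending.append(a)
        else:
            if pending:
                insertions.append((len(ref_out), "".join(pending)))
                pending = []
            ref_out.append(r)
            aln_out.append(a)
    if pending:
        insertions.append((len(ref_out), "".join(pending)))
    return "".join(aln_out), "".join(ref_out), tuple(insertions)


def read_allele_table(
    path: str | Path,
    site_id: str | None = None,
    replicate_id: str | None = None,
) -> AlleleTable:
    """Read one CRISPResso2-dialect allele-frequency table.

    ``site_id``/``replicate_id`` default to the file stem parsed as
    ``<site>__<replicate>`` (or the stem itself with replicate ``r1``).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_ALLELE_COLUMNS if c not in df.columns]
    if missing:
        raise SiteError(f"{path.name}: missing required column(s) {missing}")
    if len(df) == 0:
        raise SiteError(f"{path.name}: no reads")
    if (df["#Reads"] < 0).any():
        raise SiteError(f"{path.name}: negative read count")

    if site_id is None or replicate_id is None:
        stem = path.name.split(".")[0]
        parts = stem.split("__")
        site_id = site_id or parts[0]
        replicate_id = replicate_id or (parts[1] if len(parts) > 1 else "r1")

    reference = None
    rows = []
    has_ins_col = "insertions" in df.columns
    for rec in df.to_dict("records"):
        aligned = str(rec["Aligned_Sequence"]).upper()
        ref = str(rec["Reference_Sequence"]).upper()
        if "-" in ref:
            aligned, ref, insertions = _degap(aligned, ref)
        else:
            insertions = _parse_insertions(rec.get("insertions", "")) if has_ins_col else ()
        if reference is None:
            reference = ref
        elif ref != reference:
            raise SiteError(f"{path.name}: inconsistent reference sequences")
        rows.append(
            AlleleRow(
                aligned=aligned,
                n_reads=int(rec["#Reads"]),
                n_inserted=int(rec["n_inserted"]),
                n_deleted=int(rec["n_deleted"]),
                insertions=insertions,
            )
        )
    return AlleleTable(site_id=site_id, replicate_id=replicate_id, reference=reference, rows=rows)


def write_allele_table(table: AlleleTable, path: str | Path) -> None:
    rows = []
    for r in table.rows:
        n_mut = sum(
            1 for a, b in zip(r.aligned, table.reference) if a != b and a != "-"
        )
        rows.append(
            {
                "Aligned_Sequence": r.aligned,
                "Reference_Sequence": table.reference,
                "n_deleted": r.n_deleted,
                "n_inserted": r.n_inserted,
                "n_mutated": n_mut,
                "#Reads": r.n_reads,
                "insertions": _format_insertions(r.insertions),
            }
        )
    pd.DataFrame(rows, columns=REQUIRED_ALLELE_COLUMNS + ["insertions"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# generic summary records (round-trip through JSON cells)

_SCALARS = (str, int, float, bool, type(None))


def write_summary(records: Sequence[Any], path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write summary records (dataclasses or dicts) as TSV.

    Column order is deterministic: the declared field order of the first
    record.  Non-scalar fields are serialized as JSON so the matching
    reader round-trips string/int fields bit-exactly.
    """
    dicts = []
    for rec in records:
        if dataclasses.is_dataclass(rec):
            rec = dataclasses.asdict(rec)
        dicts.append(
            {
                k: (v if isinstance(v, _SCALARS) else json.dumps(v, sort_keys=True))
                for k, v in rec.items()
            }
        )
    if columns is None:
        columns = list(dicts[0].keys()) if dicts else []
    pd.DataFrame(dicts, columns=list(columns)).to_csv(path, sep="\t", index=False)


def read_summary(path: str | Path) -> list[dict]:
    """Read a TSV written by :func:`write_summary`, decoding JSON cells."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for rec in df.to_dict("records"):
        parsed = {}
        for k, v in rec.items():
            if v.startswith(("{", "[")) or v in ("null", "true", "false"):
                parsed[k] = json.loads(v)
            else:
                try:
                    parsed[k] = int(v)
                except ValueError:
                    try:
                        parsed[k] = float(v)
                    except ValueError:
                        parsed[k] = v
        out.append(parsed)
    return out


# ---------------------------------------------------------------------------
# factor tracks


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED intervals (chrom, 0-based start, half-open end)."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        out.append((f[0], int(f[1]), int(f[2])))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph-like per-base track: chrom, start, end, value."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
    )
    return df


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, header=False)


def read_expression(path: str | Path) -> dict[str, float]:
    """Two-column TSV: gene, expression (TPM)."""
    df = pd.read_csv(path, sep="\t")
    gene_col, expr_col = df.columns[:2]
    return dict(zip(df[gene_col].astype(str), df[expr_col].astype(float)))


def read_site_gene_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    a, b = df.columns[:2]
    return dict(zip(df[a].astype(str), df[b].astype(str)))


# ---------------------------------------------------------------------------
# configuration


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from JSON or YAML (decided by content, not suffix)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(data, dict):
        raise SiteError(f"config {path} does not contain a mapping")
    if "window" in data and data["window"] is not None:
        data["window"] = tuple(data["window"])
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise SiteError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    data = dataclasses.asdict(cfg)
    data["window"] = list(cfg.window)
    data["factor_channels"] = list(cfg.factor_channels)
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
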