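"""Readers and writers for the plain-text formats pathway data travels in.

Pathway collections use GMT (tab-separated gene-set format, one set per
line: id, description, genes...). The description field carries the
pathway name plus, pipe-separated, the source label and the
semicolon-joined provenance list, so merged collections round-trip
through the standard format without side files.

Annotation tables are TSV with a header row: gene -> assay sources
(";"-separated), gene -> tags, keyword -> tag, and wide compound x assay
binary activity matrices.
"""
from __future__ import annotations

import os
import tempfile
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import GmtParseError, SchemaError, ValidationError
from .model import ActivityMatrix, AssayAnnotation, AssaySource, Pathway, PathwayCollection


def _parse_description(desc: str, pathway_id: str) -> tuple[str, str, tuple[str, ...]]:
    parts = desc.split("|")
    name = parts[0].strip() or pathway_id
    source = parts[1].strip() if len(parts) > 1 and parts[1].strip() else "unknown"
    provenance: tuple[str, ...] = ()
    if len(parts) > 2 and parts[2].strip():
        provenance = tuple(p for p in parts[2].split(";") if p)
    return name, source, provenance


def read_gmt(path: str | os.PathLike) -> PathwayCollection:
    """Read a GMT file into a :class:`PathwayCollection`.

    Each line needs at least 3 tab-separated fields (id, description,
    one or more genes). Duplicate genes within a line are collapsed;
    line order is preserved; the universe is the union of all genes.

    Raises
    ------
    GmtParseError
        If a line has fewer than 3 fields (the line number is reported).
    ValidationError
        If two lines share a pathway id.
    """
    pathways: list[Pathway] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            pid = fields[0].strip()
            name, source, provenance = _parse_description(fields[1], pid)
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                raise GmtParseError(f"{path}: line {lineno}: no genes")
            pathways.append(Pathway(id=pid, name=name, genes=genes, source=source, provenance=provenance))
    return PathwayCollection(pathways)


def write_gmt(collection: PathwayCollection, path: str | os.PathLike) -> None:
    """Write a collection as GMT (UTF-8, LF endings, genes sorted per line).

    ``read_gmt(write_gmt(c))`` reproduces the ids, names, sources,
    provenance and gene sets of ``c`` exactly.
    """
    lines = []
    for p in collection:
        desc = f"{p.name}|{p.source}|{';'.join(p.provenance)}"
        lines.append("\t".join([p.id, desc, *sorted(p.genes)]))
    _atomic_write_text(path, "".join(line + "\n" for line in lines))


def _atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write via a temp file in the same directory, then rename."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _require_columns(df: pd.DataFrame, cols: list[str], path: str | os.PathLike, kind: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: {kind} table missing column(s) {missing}; found {list(df.columns)}")


def read_assay_table(path: str | os.PathLike) -> list[AssayAnnotation]:
    """Read a gene -> assay-source table (columns ``gene``, ``sources``)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    _require_columns(df, ["gene", "sources"], path, "assay")
    out = []
    for _, row in df.iterrows():
        labels = [s.strip() for s in str(row["sources"]).split(";") if s.strip()]
        sources = set()
        for lab in labels:
            try:
                sources.add(AssaySource[lab.upper()])
            except KeyError:
                raise ValidationError(
                    f"{path}: unknown assay source {lab!r} for gene {row['gene']!r} "
                    f"(expected one of {[s.name for s in AssaySource]})"
                ) from None
        out.append(AssayAnnotation(gene=row["gene"], sources=frozenset(sources)))
    return out


def read_gene_tag_table(path: str | os.PathLike) -> dict[str, frozenset[str]]:
    """Read a gene -> tags table (columns ``gene``, ``tags``; tags ";"-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    _require_columns(df, ["gene", "tags"], path, "gene_tag")
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        tags = {t.strip() for t in str(row["tags"]).split(";") if t.strip()}
        out.setdefault(row["gene"].strip(), set()).update(tags)
    return {g: frozenset(t) for g, t in out.items()}


def read_keyword_lexicon(path: str | os.PathLike) -> dict[str, frozenset[str]]:
    """Read a keyword -> tag lexicon (columns ``keyword``, ``tag``, one pair per row)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    _require_columns(df, ["keyword", "tag"], path, "keyword_lexicon")
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        kw, tag = row["keyword"].strip(), row["tag"].strip()
        if kw and tag:
            out.setdefault(kw, set()).add(tag)
    return {k: frozenset(v) for k, v in out.items()}


def read_activity_matrix(path: str | os.PathLike) -> ActivityMatrix:
    """Read a wide compound x assay activity table (first column ``compound``)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.columns[0] != "compound":
        raise SchemaError(f"{path}: activity table must start with a 'compound' column")
    assays = list(df.columns[1:])
    if not assays:
        raise SchemaError(f"{path}: activity table has no assay columns")
    vals = df[assays].to_numpy()
    try:
        arr = vals.astype(np.int64)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric activity value: {exc}") from None
    return ActivityMatrix(compounds=list(df["compound"]), assays=assays, calls=arr)


_READERS = {
    "assay": read_assay_table,
    "gene_tag": read_gene_tag_table,
    "keyword_lexicon": read_keyword_lexicon,
    "activity": read_activity_matrix,
}


def read_annotation_table(path: str | os.PathLike, kind: str):
    """Dispatch to the typed reader for ``kind``.

    ``kind`` is one of ``assay``, ``gene_tag``, ``keyword_lexicon``,
    ``activity``.
    """
    try:
        reader = _READERS[kind]
    except KeyError:
        raise ValueError(f"unknown table kind {kind!r}; expected one of {sorted(_READERS)}") from None
    return reader(path)


def write_activity_matrix(matrix: ActivityMatrix, path: str | os.PathLike) -> None:
    header = "\t".join(["compound", *matrix.assays])
    rows = (
        "\t".join([c, *map(str, row)]) for c, row in zip(matrix.compounds, matrix.calls.tolist())
    )
    _atomic_write_text(path, "".join(line + "\n" for line in [header, *rows]))


def write_tsv(path: str | os.PathLike, header: list[str], rows: list[list], comments: Mapping[str, object] | None = None) -> None:
    """Write a TSV with optional ``# key=value`` provenance header lines."""
    lines = [f"# {k}={v}" for k, v in (comments or {}).items()]
    lines.append("\t".join(header))
    lines.extend("\t".join(str(v) for v in row) for row in rows)
    _atomic_write_text(path, "".join(line + "\n" for line in lines))
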