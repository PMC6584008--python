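"""Readers and writers for search-hit tables.

Three source dialects feed the pipeline:

* NCBI BLAST tabular output (``-outfmt 6``), 12 standard columns with an
  optional 13th subject-scientific-name column;
* BOLD identification-engine exports — delimited files with per-hit rank
  columns and a similarity percentage, described by a column map;
* an archived spreadsheet workbook of study outputs, mapped sheet-by-sheet
  through a user-editable dialect config.

All of them land in the same canonical model (:class:`HitRecord` grouped
into per-query :class:`HitTable`), which also round-trips through a fixed
canonical TSV. Alignment coordinates are passed through untouched (1-based,
inclusive) and never interpreted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio import SeqIO

from .errors import ConfigError, ParseError
from .taxonomy import Lineage

logger = logging.getLogger(__name__)

DEFAULT_MAX_HITS = 10  # MegaBlast's default max_target_seqs

#: Fixed header of the canonical hit-table TSV.
CANONICAL_COLUMNS = (
    "query_id", "locus", "source_db", "run_id", "rank", "subject_id",
    "subject_label", "pident", "length", "evalue", "bitscore", "similarity",
)

_BLAST_COLS = 12  # qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore


@dataclass(frozen=True)
class HitRecord:
    """One search-result row in canonical form.

    GenBank-dialect records carry ``percent_identity``, ``evalue`` and
    ``bitscore``; BOLD-dialect records carry ``similarity``. ``lineage`` is
    optional rank context (BOLD exports include it; BLAST tabular does not).
    """

    query_id: str
    subject_id: str
    subject_label: str
    source_db: str  # "genbank" | "bold"
    run_id: str = ""
    percent_identity: float | None = None
    align_length: int | None = None
    evalue: float | None = None
    bitscore: float | None = None
    similarity: float | None = None
    lineage: Lineage | None = None

    def __post_init__(self) -> None:
        for name, v in (("percent_identity", self.percent_identity),
                        ("similarity", self.similarity)):
            if v is not None and not (0.0 <= v <= 100.0):
                raise ParseError(f"{name}={v} outside [0, 100] for query {self.query_id!r}")
        if self.evalue is not None and self.evalue < 0:
            raise ParseError(f"negative e-value {self.evalue} for query {self.query_id!r}")

    @property
    def has_genbank_stats(self) -> bool:
        return (self.percent_identity is not None and self.evalue is not None
                and self.bitscore is not None)

    @property
    def has_bold_stats(self) -> bool:
        return self.similarity is not None

    @property
    def best_similarity_stat(self) -> float | None:
        """The dialect's similarity-style statistic (pident or BOLD similarity)."""
        return self.similarity if self.source_db == "bold" else self.percent_identity


@dataclass
class HitTable:
    """All retained hits for one query, in reported order."""

    query_id: str
    locus: str = ""
    source_db: str = "genbank"
    run_id: str = ""
    records: list[HitRecord] = field(default_factory=list)
    query_length: int | None = None

    def __len__(self) -> int:
        return len(self.records)


def _parse_float(token: str, path, lineno: int, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-numeric {what} {token!r}") from None


def read_blast_tabular(
    path,
    max_hits: int = DEFAULT_MAX_HITS,
    *,
    locus: str = "",
    run_id: str = "",
) -> list[HitTable]:
    """Read BLAST ``-outfmt 6`` output into per-query hit tables.

    One :class:`HitTable` per distinct qseqid, in order of first appearance,
    each truncated to *max_hits* records. A 13th column, when present, is
    taken as the subject scientific name; otherwise the subject id doubles
    as the label.
    """
    tables: dict[str, HitTable] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) not in (_BLAST_COLS, _BLAST_COLS + 1):
                raise ParseError(
                    f"{path}:{lineno}: expected {_BLAST_COLS} or {_BLAST_COLS + 1} "
                    f"tab-separated columns, found {len(cols)}"
                )
            qid, sid = cols[0], cols[1]
            pident = _parse_float(cols[2], path, lineno, "percent identity")
            length = int(_parse_float(cols[3], path, lineno, "alignment length"))
            evalue = _parse_float(cols[10], path, lineno, "e-value")
            bitscore = _parse_float(cols[11], path, lineno, "bit score")
            label = cols[12] if len(cols) > _BLAST_COLS and cols[12].strip() else sid
            table = tables.get(qid)
            if table is None:
                table = tables[qid] = HitTable(
                    query_id=qid, locus=locus, source_db="genbank", run_id=run_id
                )
            if len(table.records) < max_hits:
                table.records.append(
                    HitRecord(
                        query_id=qid, subject_id=sid, subject_label=label,
                        source_db="genbank", run_id=run_id,
                        percent_identity=pident, align_length=length,
                        evalue=evalue, bitscore=bitscore,
                    )
                )
    return list(tables.values())


#: Default column map for BOLD-style exports (the fixture writer uses it too).
BOLD_DEFAULT_COLUMNS = {
    "query_id": "Query ID",
    "subject_id": "Subject ID",
    "similarity": "Similarity",
    "genus": "Genus",
    "species": "Species",
    # optional rank context
    "class": "Class",
    "order": "Order",
    "family": "Family",
}

_BOLD_OPTIONAL = {"subject_id", "class", "order", "family"}


def read_bold_results(
    path,
    max_hits: int = DEFAULT_MAX_HITS,
    *,
    column_map: dict[str, str] | None = None,
    locus: str = "",
    run_id: str = "",
    delimiter: str | None = None,
) -> list[HitTable]:
    """Read a BOLD identification-engine export into per-query hit tables.

    The subject label is assembled from the genus and species columns; a row
    with an empty species column yields a genus-only label, which downstream
    parsing treats as an undetermined record. A blank similarity cell marks
    an explicit "no match" row and yields an empty table for that query.
    """
    import csv as _csv

    cmap = dict(BOLD_DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = delimiter or ("\t" if "\t" in sample.splitlines()[0] else ",")
        reader = _csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        for key in ("query_id", "similarity", "genus", "species"):
            if cmap[key] not in header:
                raise ConfigError(
                    f"{path}: mapped column {cmap[key]!r} (for {key}) missing; "
                    f"header is {header}"
                )
        tables: dict[str, HitTable] = {}
        for lineno, row in enumerate(reader, start=2):
            qid = row[cmap["query_id"]].strip()
            if not qid:
                continue
            table = tables.get(qid)
            if table is None:
                table = tables[qid] = HitTable(
                    query_id=qid, locus=locus, source_db="bold", run_id=run_id
                )
            sim_cell = row[cmap["similarity"]].strip()
            if not sim_cell:  # explicit no-match row
                continue
            sim = _parse_float(sim_cell, path, lineno, "similarity")
            genus = row[cmap["genus"]].strip()
            species = row[cmap["species"]].strip()
            label = f"{genus} {species}".strip() or "unidentified"
            lineage = None
            ranks = {}
            for rank_key in ("class", "order", "family"):
                col = cmap.get(rank_key)
                if col and col in header:
                    ranks[rank_key] = row[col].strip()
            if any(ranks.values()) or genus:
                binomial = f"{genus} {species}" if genus and species else ""
                lineage = Lineage(
                    class_=ranks.get("class", ""), order=ranks.get("order", ""),
                    family=ranks.get("family", ""), genus=genus, species=binomial,
                )
            sid_col = cmap.get("subject_id")
            sid = row[sid_col].strip() if sid_col and sid_col in header else f"row{lineno}"
            if len(table.records) < max_hits:
                table.records.append(
                    HitRecord(
                        query_id=qid, subject_id=sid, subject_label=label,
                        source_db="bold", run_id=run_id, similarity=sim,
                        lineage=lineage,
                    )
                )
    return list(tables.values())


def read_query_fasta(path) -> dict[str, int]:
    """Map query id → length in bases (non-gap residues) from a FASTA file.

    Ids are the first whitespace-delimited token of each header. Duplicate
    ids and empty sequences are errors.
    """
    lengths: dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in lengths:
            raise ParseError(f"{path}: duplicate query id {rec.id!r}")
        n = sum(1 for c in str(rec.seq) if c not in "-.")
        if n == 0:
            raise ParseError(f"{path}: empty sequence for query {rec.id!r}")
        lengths[rec.id] = n
    return lengths


def read_archived_outputs(path, dialect_config: dict, max_hits: int = DEFAULT_MAX_HITS) -> list[HitTable]:
    """Read an archived study workbook through a sheet-mapping dialect config.

    ``dialect_config`` has the shape::

        {"sheets": {"<sheet name>": {
            "source_db": "genbank" | "bold",
            "locus": "COI", "run_id": "megablast", "taxon_group": "insects",
            "columns": {"query_id": "...", "subject_label": "...",
                        "pident": "...", "evalue": "...", "bitscore": "...",
                        "similarity": "...", "subject_id": "..."}}}}

    Sheets present in the workbook but absent from the config are skipped
    with a logged warning. A config naming an absent sheet or column, or
    declaring statistic columns inconsistent with its ``source_db``, raises
    :class:`ConfigError`.
    """
    from openpyxl import load_workbook

    sheets_cfg = dialect_config.get("sheets", {})
    wb = load_workbook(str(path), read_only=True, data_only=True)
    try:
        wb_sheets = set(wb.sheetnames)
        for name in sheets_cfg:
            if name not in wb_sheets:
                raise ConfigError(f"{path}: dialect maps absent sheet {name!r}")
        for name in sorted(wb_sheets - set(sheets_cfg)):
            logger.warning("workbook sheet %r not mapped by dialect config; skipped", name)

        out: list[HitTable] = []
        for name, cfg in sheets_cfg.items():
            source_db = cfg.get("source_db", "genbank")
            cols = cfg.get("columns", {})
            required = {"query_id", "subject_label"}
            required |= {"pident", "evalue", "bitscore"} if source_db == "genbank" else {"similarity"}
            wrong_db = {"similarity"} if source_db == "genbank" else {"pident", "evalue", "bitscore"}
            if wrong_db & set(cols):
                raise ConfigError(
                    f"sheet {name!r}: statistic columns {sorted(wrong_db & set(cols))} "
                    f"inconsistent with source_db={source_db!r}"
                )
            ws = wb[name]
            rows = ws.iter_rows(values_only=True)
            header = next(rows, None)
            if header is None:
                continue
            header = [str(h) if h is not None else "" for h in header]
            idx: dict[str, int] = {}
            for key, colname in cols.items():
                if colname not in header:
                    raise ConfigError(f"sheet {name!r}: mapped column {colname!r} not found")
                idx[key] = header.index(colname)
            missing = required - set(idx)
            if missing:
                raise ConfigError(f"sheet {name!r}: dialect lacks columns for {sorted(missing)}")

            tables: dict[str, HitTable] = {}
            for row in rows:
                def cell(key: str):
                    i = idx.get(key)
                    return row[i] if i is not None and i < len(row) else None

                qid = cell("query_id")
                if qid is None or str(qid).strip() == "":
                    continue
                qid = str(qid).strip()
                table = tables.get(qid)
                if table is None:
                    table = tables[qid] = HitTable(
                        query_id=qid, locus=cfg.get("locus", ""),
                        source_db=source_db, run_id=cfg.get("run_id", ""),
                    )
                label = cell("subject_label")
                if label is None or str(label).strip() == "":
                    continue  # no-match row
                kwargs: dict = {}
                if source_db == "genbank":
                    kwargs["percent_identity"] = float(cell("pident"))
                    kwargs["evalue"] = float(cell("evalue"))
                    kwargs["bitscore"] = float(cell("bitscore"))
                else:
                    kwargs["similarity"] = float(cell("similarity"))
                sid = cell("subject_id")
                if len(table.records) < max_hits:
                    table.records.append(
                        HitRecord(
                            query_id=qid,
                            subject_id=str(sid) if sid is not None else f"{name}:{qid}",
                            subject_label=str(label), source_db=source_db,
                            run_id=cfg.get("run_id", ""), **kwargs,
                        )
                    )
            out.extend(tables.values())
        return out
    finally:
        wb.close()


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_hit_tables(tables: list[HitTable], path) -> None:
    """Write hit tables to the canonical TSV (lossless round-trip)."""
    with open(path, "w") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for t in tables:
            if not t.records:
                # a header-only row preserves empty (no-match) tables
                fh.write("\t".join([t.query_id, t.locus, t.source_db, t.run_id,
                                    "0", "", "", "", "", "", "", ""]) + "\n")
            for i, r in enumerate(t.records, start=1):
                fh.write("\t".join([
                    t.query_id, t.locus, t.source_db, t.run_id, str(i),
                    r.subject_id, r.subject_label, _fmt(r.percent_identity),
                    _fmt(r.align_length), _fmt(r.evalue), _fmt(r.bitscore),
                    _fmt(r.similarity),
                ]) + "\n")


def read_hit_tables(path) -> list[HitTable]:
    """Read the canonical TSV written by :func:`write_hit_tables`."""
    tables: dict[tuple, HitTable] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != CANONICAL_COLUMNS:
            raise ParseError(f"{path}: unexpected canonical header {header}")
        for lineno, line in enumerate(fh, start=2):
            cols = line.rstrip("\n").split("\t")
            if len(cols) != len(CANONICAL_COLUMNS):
                raise ParseError(f"{path}:{lineno}: expected {len(CANONICAL_COLUMNS)} columns")
            qid, locus, source_db, run_id, rank = cols[:5]
            key = (qid, locus, source_db, run_id)
            table = tables.get(key)
            if table is None:
                table = tables[key] = HitTable(
                    query_id=qid, locus=locus, source_db=source_db, run_id=run_id
                )
            if rank == "0":
                continue  # no-match placeholder
            def opt_float(s: str) -> float | None:
                return float(s) if s != "" else None
            table.records.append(
                HitRecord(
                    query_id=qid, subject_id=cols[5], subject_label=cols[6],
                    source_db=source_db, run_id=run_id,
                    percent_identity=opt_float(cols[7]),
                    align_length=int(cols[8]) if cols[8] else None,
                    evalue=opt_float(cols[9]), bitscore=opt_float(cols[10]),
                    similarity=opt_float(cols[11]),
                )
            )
    return list(tables.values())


class TruthTable:
    """Expected lineages keyed by (specimen_id, locus), with locus fallback."""

    REQUIRED = ("specimen_id", "locus", "class", "order", "family", "genus", "species")

    def __init__(self, entries: dict[tuple[str, str], Lineage]):
        self.entries = entries

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        entries: dict[tuple[str, str], Lineage] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            missing = set(cls.REQUIRED) - set(header)
            if missing:
                raise ParseError(f"{path}: truth table missing columns {sorted(missing)}")
            ix = {c: header.index(c) for c in cls.REQUIRED}
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < len(header):
                    raise ParseError(f"{path}:{lineno}: short row")
                entries[(cols[ix["specimen_id"]], cols[ix["locus"]])] = Lineage(
                    class_=cols[ix["class"]], order=cols[ix["order"]],
                    family=cols[ix["family"]], genus=cols[ix["genus"]],
                    species=cols[ix["species"]],
                )
        return cls(entries)

    def lookup(self, specimen_id: str, locus: str = "") -> Lineage | None:
        lin = self.entries.get((specimen_id, locus))
        if lin is None:
            lin = self.entries.get((specimen_id, "*")) or self.entries.get((specimen_id, ""))
        if lin is None:
            # any-locus fallback: specimen identity does not depend on locus
            for (sid, _), v in self.entries.items():
                if sid == specimen_id:
                    return v
        return lin

    def lineages(self) -> list[Lineage]:
        return list(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)


def truncate(table: HitTable, max_hits: int) -> HitTable:
    """Return a copy keeping only the first *max_hits* records."""
    return HitTable(
        query_id=table.query_id, locus=table.locus, source_db=table.source_db,
        run_id=table.run_id, records=list(table.records[:max_hits]),
        query_length=table.query_length,
    )
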