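"""Readers and writers for every external format the pipeline touches.

FASTA goes through Biopython; tabular formats through pandas. All readers
validate eagerly and raise :class:`~lithoscreen.errors.FormatError` with the
offending id / cell / line, never returning a silently-coerced value.
Writers are atomic (temp file + rename).
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO

from ._util import atomic_write
from .errors import FormatError, ValidationError
from .records import (
    TAXONOMY_RANKS,
    BlastHit,
    ControlCollection,
    CountTable,
    GenomeAnnotation,
    GenomeType,
    PathwayDefinition,
    PcrStatus,
    SampleRecord,
    SeqStatus,
    SequenceRecord,
    TaxonomyAssignment,
    Whitelist,
    WhitelistMode,
    parse_measurement,
)

logger = logging.getLogger(__name__)


# --- FASTA -----------------------------------------------------------------


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized sequence records, order preserved.

    Wrapped and unwrapped line styles are both accepted; sequences are
    uppercased, U mapped to T, gaps stripped. Duplicate ids, empty files and
    non-IUPAC characters are hard errors.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        try:
            records.append(SequenceRecord(rec.id, str(rec.seq), desc))
        except ValidationError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    with atomic_write(path) as fh:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(f"{header}\n{rec.sequence}\n")


def read_whitelist(
    path: str | Path, match_mode: str | WhitelistMode = WhitelistMode.EXACT_SEQUENCE
) -> Whitelist:
    """Read a whitelist from FASTA (sequence entries) or a plain id list.

    A non-FASTA file (no ``>`` headers) is treated as one bare id per line and
    forces ``by_id`` matching.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        return Whitelist(read_fasta(path), WhitelistMode(match_mode))
    ids = {line.strip() for line in text.splitlines() if line.strip()}
    if not ids:
        raise FormatError(f"{path}: empty whitelist")
    return Whitelist(ids, WhitelistMode.BY_ID)


def read_controls(
    ntc: str | Path | None = None,
    drill_fluid: str | Path | None = None,
    seawater: str | Path | None = None,
) -> ControlCollection:
    """Assemble a control collection from up to three FASTA files."""
    coll = ControlCollection(
        ntc=read_fasta(ntc) if ntc else [],
        drill_fluid=read_fasta(drill_fluid) if drill_fluid else [],
        seawater=read_fasta(seawater) if seawater else [],
    )
    if coll.is_empty:
        logger.warning("control collection is empty; no hard contaminant calls possible")
    return coll


# --- count table -----------------------------------------------------------

_INT_RE = __import__("re").compile(r"^[+-]?\d+$")


def read_count_table(path: str | Path) -> CountTable:
    """Read an ASV-rows x sample-columns TSV of integer read counts.

    Integer coercion is strict: a fractional or negative cell is a hard error
    naming the ASV row and sample column. Duplicated sample or ASV ids are
    hard errors (pandas' silent header mangling is bypassed).
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty count table") from None
        sample_ids = header[1:]
        dup = _first_duplicate(sample_ids)
        if dup is not None:
            raise FormatError(f"{path}: duplicated sample id {dup!r}")
        asv_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise FormatError(
                    f"{path}: line {lineno}: expected {len(header)} columns, "
                    f"got {len(row)}"
                )
            asv_ids.append(row[0])
            vals: list[int] = []
            for sample, cell in zip(sample_ids, row[1:]):
                cell = cell.strip()
                if not _INT_RE.match(cell):
                    raise FormatError(
                        f"{path}: non-integer count {cell!r} at ASV {row[0]!r}, "
                        f"sample {sample!r}"
                    )
                v = int(cell)
                if v < 0:
                    raise FormatError(
                        f"{path}: negative count {v} at ASV {row[0]!r}, "
                        f"sample {sample!r}"
                    )
                vals.append(v)
            rows.append(vals)
    dup = _first_duplicate(asv_ids)
    if dup is not None:
        raise FormatError(f"{path}: duplicated ASV id {dup!r}")
    df = pd.DataFrame(rows, index=asv_ids, columns=sample_ids, dtype="int64")
    return CountTable(df)


def write_count_table(table: CountTable, path: str | Path) -> None:
    with atomic_write(path) as fh:
        table.df.to_csv(fh, sep="\t", index_label="asv_id")


def _first_duplicate(items) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


# --- taxonomy --------------------------------------------------------------


def read_taxonomy(path: str | Path) -> dict[str, TaxonomyAssignment]:
    """Read a TSV with columns asv_id, domain..genus; empty cells = unresolved."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "asv_id" not in df.columns:
        raise FormatError(f"{path}: missing 'asv_id' column")
    out: dict[str, TaxonomyAssignment] = {}
    for _, row in df.iterrows():
        asv_id = row["asv_id"]
        if asv_id in out:
            raise FormatError(f"{path}: duplicate taxonomy for ASV {asv_id!r}")
        ranks = {
            r: (row[r].strip() or None) if r in df.columns else None
            for r in TAXONOMY_RANKS
        }
        out[asv_id] = TaxonomyAssignment(asv_id, ranks)
    return out


# --- BLAST tabular ---------------------------------------------------------


def read_blast_tab(
    path: str | Path,
    descriptions: str | Path | Mapping[str, str] | None = None,
) -> dict[str, BlastHit]:
    """Read 12-column BLAST tabular output, keeping one best hit per query.

    Best = highest bitscore; ties broken by lexicographically smallest subject
    id. A 13th column, when present, is the subject description (``stitle``
    style); otherwise descriptions come from a sidecar id->description TSV or
    mapping. Queries absent from the file are simply absent from the result.
    """
    path = Path(path)
    desc_map: Mapping[str, str] = {}
    if isinstance(descriptions, (str, Path)):
        ddf = pd.read_csv(descriptions, sep="\t", dtype=str, header=None)
        desc_map = dict(zip(ddf[0], ddf[1].fillna("")))
    elif descriptions is not None:
        desc_map = dict(descriptions)

    best: dict[str, BlastHit] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(
                    f"{path}: line {lineno}: expected >= 12 tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                hit = BlastHit(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    subject_description=(
                        fields[12] if len(fields) > 12 else desc_map.get(fields[1], "")
                    ),
                    bitscore=float(fields[11]),
                )
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            prev = best.get(hit.query_id)
            if (
                prev is None
                or hit.bitscore > prev.bitscore
                or (hit.bitscore == prev.bitscore and hit.subject_id < prev.subject_id)
            ):
                best[hit.query_id] = hit
    return best


def read_environment_tsv(path: str | Path) -> dict[str, str]:
    """Read a two-column asv_id -> environment-description TSV (header optional)."""
    path = Path(path)
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}: line {lineno}: expected 2 columns")
            if lineno == 1 and parts[0] in ("asv_id", "query_id"):
                continue
            out[parts[0]] = parts[1]
    return out


# --- sample metadata table -------------------------------------------------

_PCR_TOKENS = {
    "+": PcrStatus.POSITIVE,
    "-": PcrStatus.NEGATIVE,
    "−": PcrStatus.NEGATIVE,  # typographic minus
    "n.c.": PcrStatus.NO_CELLS,
    "nc": PcrStatus.NO_CELLS,
}
_SEQ_TOKENS = {
    "+": SeqStatus.SUCCESS,
    "-": SeqStatus.FAILED,
    "−": SeqStatus.FAILED,
    "n.a.": SeqStatus.NOT_APPLICABLE,
    "na": SeqStatus.NOT_APPLICABLE,
}


def read_sample_table(path: str | Path) -> list[SampleRecord]:
    """Read the per-sample metadata TSV (the Table-1-style layout).

    Expected columns: sample_id, lithology, depth_mbsf, cell_density, pcr,
    seq, pfc_interior, pfc_exterior. Measurement cells accept numerics,
    "lo-hi" ranges and the sentinel tokens BMQL/BDL/ADL/n.d./n.a./n.c.
    (case-insensitive); sentinels map to typed values, never to 0.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = [
        "sample_id", "lithology", "depth_mbsf", "cell_density",
        "pcr", "seq", "pfc_interior", "pfc_exterior",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records: list[SampleRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = str(row["sample_id"]).strip()
        if sid in seen:
            raise FormatError(f"{path}: duplicate sample id {sid!r}")
        seen.add(sid)
        pcr_tok = str(row["pcr"]).strip().lower()
        if pcr_tok not in _PCR_TOKENS:
            raise FormatError(f"{path}: sample {sid!r}: unknown PCR token {row['pcr']!r}")
        pcr = _PCR_TOKENS[pcr_tok]
        seq_tok = str(row["seq"]).strip().lower()
        if seq_tok not in _SEQ_TOKENS:
            raise FormatError(f"{path}: sample {sid!r}: unknown Seq token {row['seq']!r}")
        seq = _SEQ_TOKENS[seq_tok]
        try:
            records.append(
                SampleRecord(
                    sample_id=sid,
                    lithology=str(row["lithology"]).strip(),
                    depth_mbsf=float(row["depth_mbsf"]),
                    cell_density=parse_measurement(
                        str(row["cell_density"]), context=f"{sid} cell_density"
                    ),
                    pcr_status=pcr,
                    seq_status=seq,
                    pfc_interior=parse_measurement(
                        str(row["pfc_interior"]), context=f"{sid} pfc_interior"
                    ),
                    pfc_exterior=parse_measurement(
                        str(row["pfc_exterior"]), context=f"{sid} pfc_exterior"
                    ),
                )
            )
        except ValidationError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no sample rows")
    return records


# --- genomes, pathways, markers -------------------------------------------


def read_ko_annotations(
    path: str | Path, metadata: str | Path | None = None
) -> list[GenomeAnnotation]:
    """Read genome_id/KO/copies triples, plus an optional genome-metadata TSV.

    The metadata TSV may carry genome_type, completeness, contamination,
    has_viral_evidence and has_ssu per genome; genomes missing from it default
    to an un-flagged MAG.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("genome_id", "ko", "copies"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    meta: dict[str, dict] = {}
    if metadata is not None:
        mdf = pd.read_csv(metadata, sep="\t", dtype=str)
        if "genome_id" not in mdf.columns:
            raise FormatError(f"{metadata}: missing column 'genome_id'")
        for _, row in mdf.iterrows():
            meta[row["genome_id"]] = {
                "genome_type": GenomeType(row.get("genome_type", "MAG") or "MAG"),
                "completeness_estimate": float(row.get("completeness", 0) or 0),
                "contamination_estimate": float(row.get("contamination", 0) or 0),
                "has_viral_evidence": _parse_bool(row.get("has_viral_evidence", "0")),
                "has_ssu": _parse_bool(row.get("has_ssu", "0")),
            }
    ko_maps: dict[str, dict[str, int]] = {}
    for idx, row in df.iterrows():
        gid, ko, copies = row["genome_id"], row["ko"], row["copies"]
        if not _INT_RE.match(str(copies).strip()):
            raise FormatError(
                f"{path}: row {idx + 2}: non-integer copy number {copies!r}"
            )
        bucket = ko_maps.setdefault(gid, {})
        if ko in bucket:
            raise FormatError(f"{path}: duplicate KO {ko!r} for genome {gid!r}")
        bucket[ko] = int(copies)
    genomes = []
    for gid, kos in ko_maps.items():
        try:
            genomes.append(GenomeAnnotation(gid, ko_copies=kos, **meta.get(gid, {"genome_type": GenomeType.MAG})))
        except ValidationError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    return genomes


def _parse_bool(tok) -> bool:
    return str(tok).strip().lower() in ("1", "true", "yes", "y")


def read_pathway_definitions(path: str | Path) -> list[PathwayDefinition]:
    """Read pathway_id / name / comma-separated-KO-list rows."""
    return _read_definitions(path, "pathway_id", PathwayDefinition)


def read_marker_definitions(path: str | Path) -> list[tuple[str, str, frozenset[str]]]:
    """Read marker_id / name / comma-separated-KO-list rows as plain tuples."""
    defs = _read_definitions(path, "marker_id", PathwayDefinition)
    return [(d.pathway_id, d.name, d.defining_kos) for d in defs]


def _read_definitions(path, id_col, cls) -> list[PathwayDefinition]:
    path = Path(path)
    out: list[PathwayDefinition] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if lineno == 1 and parts[0] in (id_col, "id"):
                continue
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 columns")
            pid, name, kos = parts[0], parts[1], parts[2]
            if pid in seen:
                raise FormatError(f"{path}: line {lineno}: duplicate id {pid!r}")
            seen.add(pid)
            ko_set = frozenset(k.strip() for k in kos.split(",") if k.strip())
            try:
                out.append(cls(pid, name, ko_set))
            except ValidationError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    if not out:
        raise FormatError(f"{path}: no definitions found")
    return out


def write_tsv(df: pd.DataFrame, path: str | Path, index_label: str | None = None) -> None:
    with atomic_write(path) as fh:
        df.to_csv(fh, sep="\t", index=index_label is not None, index_label=index_label)
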