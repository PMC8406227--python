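"""Core domain types for the screening pipeline.

The pipeline operates on amplicon sequence variants (ASVs) from ultra-low-biomass
subsurface samples, control sequence collections used as contamination evidence
(no-template controls, drilling-fluid "grease" and seawater sets), a whitelist of
ASVs independently established as likely indigenous, per-sample core metadata
(lithology, depth, cell density, PCR/sequencing outcome, perfluorocarbon drilling
tracer), and KO-annotated partial genomes (MAGs/SAGs).

All types validate their invariants eagerly: a constructed object is a valid one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator, Mapping

from .errors import ValidationError

# IUPAC nucleotide codes accepted after normalization (U is mapped to T).
IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")
_GAP_CHARS = ".-"

#: Taxonomic ranks tracked for family-level aggregation, coarsest first.
TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "family", "genus")


def normalize_sequence(raw: str, *, context: str = "sequence") -> str:
    """Uppercase, strip gap characters, map U->T, and validate IUPAC codes.

    Raises :class:`ValidationError` naming the 1-based position of the first
    non-IUPAC character.
    """
    seq = raw.upper().replace("U", "T")
    seq = "".join(c for c in seq if c not in _GAP_CHARS)
    for pos, c in enumerate(seq, start=1):
        if c not in IUPAC_DNA:
            raise ValidationError(
                f"{context}: non-IUPAC character {c!r} at position {pos}"
            )
    if not seq:
        raise ValidationError(f"{context}: empty sequence after normalization")
    return seq


@dataclass(frozen=True)
class SequenceRecord:
    """One DNA sequence with a unique id (an ASV, control read, or whitelist entry)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("SequenceRecord id must be nonempty")
        object.__setattr__(
            self, "sequence", normalize_sequence(self.sequence, context=self.id)
        )


def check_unique_ids(records: list[SequenceRecord], *, context: str) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValidationError(f"{context}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)


class CountTable:
    """ASV x sample integer read-count matrix backed by a pandas DataFrame.

    Rows are ASVs, columns are samples; every entry is a nonnegative integer.
    """

    def __init__(self, df) -> None:
        import pandas as pd

        if not isinstance(df, pd.DataFrame):
            raise ValidationError("CountTable requires a pandas DataFrame")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"CountTable: duplicate ASV id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValidationError(f"CountTable: duplicate sample id {dup!r}")
        try:
            coerced = df.astype("int64")
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"CountTable: non-integer counts ({exc})") from exc
        if not (coerced.values == df.values).all():
            raise ValidationError("CountTable: counts were truncated during coercion")
        if (coerced.values < 0).any():
            r, c = next(zip(*((coerced.values < 0).nonzero())))
            raise ValidationError(
                f"CountTable: negative count at ASV {coerced.index[r]!r}, "
                f"sample {coerced.columns[c]!r}"
            )
        self.df = coerced

    @property
    def asv_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.columns)

    def row_totals(self) -> "Mapping[str, int]":
        return self.df.sum(axis=1).to_dict()

    def sample_totals(self) -> "Mapping[str, int]":
        return self.df.sum(axis=0).to_dict()

    def drop_asvs(self, asv_ids) -> "CountTable":
        return CountTable(self.df.drop(index=list(asv_ids)))

    def __eq__(self, other) -> bool:
        return isinstance(other, CountTable) and self.df.equals(other.df)

    def __repr__(self) -> str:
        return f"CountTable({len(self.df)} ASVs x {self.df.shape[1]} samples)"


@dataclass(frozen=True)
class TaxonomyAssignment:
    """Rank labels for one ASV; unresolved ranks are None."""

    asv_id: str
    ranks: Mapping[str, str | None]

    def __post_init__(self) -> None:
        unknown = set(self.ranks) - set(TAXONOMY_RANKS)
        if unknown:
            raise ValidationError(
                f"TaxonomyAssignment {self.asv_id!r}: unknown ranks {sorted(unknown)}"
            )

    def family_label(self) -> str:
        """Family name, or a "(p) Phylum"-style fallback at the deepest resolved rank.

        Returns ``"unknown bacteria"`` when no rank below domain is resolved.
        """
        fam = self.ranks.get("family")
        if fam:
            return fam
        for rank in ("order", "class", "phylum"):
            name = self.ranks.get(rank)
            if name:
                return f"({rank[0]}) {name}"
        return "unknown bacteria"


@dataclass
class ControlCollection:
    """The three contamination-evidence sequence sets.

    ``ntc`` are no-template (reagent) control reads; ``drill_fluid`` are
    drilling-grease-associated sequences; ``seawater`` are water-column
    sequences from the same expedition. Ids must be unique within each set.
    An all-empty collection is permitted (the classifier then relies on the
    whitelist alone and can never emit a hard contaminant call).
    """

    ntc: list[SequenceRecord] = field(default_factory=list)
    drill_fluid: list[SequenceRecord] = field(default_factory=list)
    seawater: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, recs in self.iter_sets():
            check_unique_ids(recs, context=f"ControlCollection.{name}")

    def iter_sets(self) -> Iterator[tuple[str, list[SequenceRecord]]]:
        """Yield (control_type, records) in tie-break precedence order."""
        yield "ntc", self.ntc
        yield "drill_fluid", self.drill_fluid
        yield "seawater", self.seawater

    @property
    def is_empty(self) -> bool:
        return not (self.ntc or self.drill_fluid or self.seawater)


class WhitelistMode(str, Enum):
    EXACT_SEQUENCE = "exact_sequence"
    IDENTITY_THRESHOLD = "identity_threshold"
    BY_ID = "by_id"


@dataclass
class Whitelist:
    """ASVs independently established as likely indigenous.

    A whitelisted ASV is exempt from hard contaminant calls. Entries are either
    full sequence records (matched by exact sequence or identity threshold) or
    bare ids (matched by id membership only).
    """

    entries: list[SequenceRecord] | set[str]
    match_mode: WhitelistMode = WhitelistMode.EXACT_SEQUENCE

    def __post_init__(self) -> None:
        self.match_mode = WhitelistMode(self.match_mode)
        if isinstance(self.entries, list):
            if not self.entries:
                raise ValidationError("Whitelist: empty entry list")
            check_unique_ids(self.entries, context="Whitelist")
            if self.match_mode is WhitelistMode.BY_ID:
                raise ValidationError(
                    "Whitelist: by_id mode requires bare ids, not sequence records"
                )
        else:
            if not self.entries:
                raise ValidationError("Whitelist: empty id set")
            if self.match_mode is not WhitelistMode.BY_ID:
                raise ValidationError(
                    "Whitelist: bare-id entries cannot be used with "
                    f"{self.match_mode.value} matching"
                )

    @property
    def is_bare_ids(self) -> bool:
        return isinstance(self.entries, set)


@dataclass(frozen=True)
class BlastHit:
    """Best database hit for one query ASV, with its environment description."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    subject_description: str
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValidationError(
                f"BlastHit {self.query_id!r}: percent_identity "
                f"{self.percent_identity} outside [0, 100]"
            )
        if self.alignment_length < 1:
            raise ValidationError(
                f"BlastHit {self.query_id!r}: alignment_length must be >= 1"
            )


# --- sample metadata -------------------------------------------------------

#: canonical sentinel codes for non-numeric measurements
SENTINEL_CODES = {
    "BMQL": "below minimum quantification limit",
    "BDL": "below detection limit",
    "ADL": "above detection limit",
    "ND": "not determined",
    "NA": "not applicable",
    "NC": "no cells identified",
}


@dataclass(frozen=True)
class Sentinel:
    """Typed non-numeric measurement (never silently coerced to a number).

    ``qualifier`` carries an attached limit when present, e.g. the
    quantification limit in ``"BMQL (4.4)"`` or the bound in ``"BDL-2e2"``.
    """

    code: str
    qualifier: float | None = None

    def __post_init__(self) -> None:
        if self.code not in SENTINEL_CODES:
            raise ValidationError(f"unknown sentinel code {self.code!r}")


@dataclass(frozen=True)
class ValueRange:
    """A reported range such as a cell density of "5-16" cells per cm^3."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValidationError(f"ValueRange low {self.low} > high {self.high}")

    @property
    def midpoint(self) -> float:
        return (self.low + self.high) / 2.0


Measurement = float | ValueRange | Sentinel

_NUM = r"[0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?"
_SENT_RE = re.compile(
    rf"^(?P<code>BMQL|BDL|ADL|N\.?D\.?|N\.?A\.?|N\.?C\.?)"
    rf"(?:\s*\((?P<paren>{_NUM})\)|\s*-\s*(?P<bound>{_NUM}))?$",
    re.IGNORECASE,
)
_RANGE_RE = re.compile(rf"^(?P<lo>{_NUM})\s*[-–]\s*(?P<hi>{_NUM})$")


def parse_measurement(token: str, *, context: str = "value") -> Measurement:
    """Parse a Table-1-style measurement cell into a typed value.

    Accepts plain/scientific numerics, "lo-hi" ranges, and the sentinel tokens
    BMQL/BDL/ADL/n.d./n.a./n.c. (case-insensitive, optionally carrying a
    parenthesized limit or a trailing bound). Unknown tokens are a hard error.
    """
    tok = token.strip()
    if not tok:
        raise ValidationError(f"{context}: empty measurement cell")
    try:
        return float(tok)
    except ValueError:
        pass
    m = _RANGE_RE.match(tok)
    if m:
        return ValueRange(float(m.group("lo")), float(m.group("hi")))
    m = _SENT_RE.match(tok)
    if m:
        code = m.group("code").upper().replace(".", "")
        qual = m.group("paren") or m.group("bound")
        return Sentinel(code, float(qual) if qual is not None else None)
    raise ValidationError(f"{context}: unrecognized measurement token {token!r}")


class PcrStatus(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NO_CELLS = "no_cells"


class SeqStatus(str, Enum):
    SUCCESS = "success"
    FAILED = "failed"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class SampleRecord:
    """One core sample: lithology, depth, cell density, screening outcome, tracer.

    ``pfc_interior``/``pfc_exterior`` are perfluorocarbon drilling-tracer
    concentrations (pg per cm^3) in parallel subsamples from the core interior
    and exterior; high interior values index drilling-fluid intrusion.
    """

    sample_id: str
    lithology: str
    depth_mbsf: float
    cell_density: Measurement
    pcr_status: PcrStatus
    seq_status: SeqStatus
    pfc_interior: Measurement
    pfc_exterior: Measurement

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValidationError("SampleRecord: empty sample_id")
        if self.depth_mbsf < 0:
            raise ValidationError(
                f"SampleRecord {self.sample_id!r}: negative depth {self.depth_mbsf}"
            )
        if (
            self.pcr_status is PcrStatus.NO_CELLS
            and self.seq_status is not SeqStatus.NOT_APPLICABLE
        ):
            raise ValidationError(
                f"SampleRecord {self.sample_id!r}: no cells detected forces "
                "seq_status = not_applicable"
            )

    @property
    def is_sediment(self) -> bool:
        """Lithology heuristic: free text containing "sand" counts as sediment."""
        return "sand" in self.lithology.lower()


# --- partial genomes -------------------------------------------------------


class GenomeType(str, Enum):
    MAG = "MAG"
    SAG = "SAG"


@dataclass(frozen=True)
class GenomeAnnotation:
    """KO copy numbers and upstream QC flags for one partial genome (MAG/SAG)."""

    genome_id: str
    genome_type: GenomeType
    ko_copies: Mapping[str, int]
    completeness_estimate: float = 0.0
    contamination_estimate: float = 0.0
    has_viral_evidence: bool = False
    has_ssu: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "genome_type", GenomeType(self.genome_type))
        for ko, copies in self.ko_copies.items():
            if copies < 1:
                raise ValidationError(
                    f"GenomeAnnotation {self.genome_id!r}: KO {ko} copy number "
                    f"{copies} must be >= 1"
                )
        for name in ("completeness_estimate", "contamination_estimate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(
                    f"GenomeAnnotation {self.genome_id!r}: {name} {v} outside [0, 100]"
                )


@dataclass(frozen=True)
class PathwayDefinition:
    """A metabolic pathway defined by the KO identifiers unique to it."""

    pathway_id: str
    name: str
    defining_kos: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "defining_kos", frozenset(self.defining_kos))
        if not self.defining_kos:
            raise ValidationError(
                f"PathwayDefinition {self.pathway_id!r}: empty defining KO set"
            )
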