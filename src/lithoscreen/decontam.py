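"""The four-category ASV origin classifier and contaminant filtering.

Each ASV is assigned exactly one origin category — subsurface, possibly
subsurface, likely contaminant, or contaminant — from three evidence streams:

* a control match: >= 99% (default) global identity to a no-template-control,
  drilling-fluid or seawater sequence;
* whitelist status: membership in an independently derived "likely indigenous"
  ASV set, which exempts an ASV from hard contaminant calls;
* the environment of its closest database hit, reduced to subsurface-like /
  contaminant-like / ambiguous by a configurable keyword map (replacing the
  manual adjudication a human screener would perform).

The decision cascade is deterministic:

    R1  control match, not whitelisted               -> contaminant
    R2  control match, whitelisted:
          env subsurface-like                        -> possibly_subsurface
          env contaminant-like                       -> likely_contaminant
          env ambiguous/absent                       -> unknown_env_policy_matched
    R3  no control match:
          env contaminant-like                       -> likely_contaminant
          env subsurface-like, or whitelisted        -> subsurface
          env ambiguous/absent                       -> unknown_env_policy_unmatched

An optional abundance gate reproduces screening workflows in which only
abundant taxa (> 5,000 reads) received a database search: below the gate the
environment evidence is ignored and the ambiguous/absent branch fires.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import pandas as pd

from .errors import ValidationError
from .records import (
    BlastHit,
    ControlCollection,
    CountTable,
    SequenceRecord,
    Whitelist,
)
from .similarity import IdentityParams, MatchEvidence, best_control_match, in_whitelist

logger = logging.getLogger(__name__)


class OriginCategory(str, Enum):
    SUBSURFACE = "subsurface"
    POSSIBLY_SUBSURFACE = "possibly_subsurface"
    LIKELY_CONTAMINANT = "likely_contaminant"
    CONTAMINANT = "contaminant"


#: canonical reporting order of the four categories
CATEGORY_ORDER = (
    OriginCategory.SUBSURFACE,
    OriginCategory.POSSIBLY_SUBSURFACE,
    OriginCategory.LIKELY_CONTAMINANT,
    OriginCategory.CONTAMINANT,
)

#: environment classes
ENV_SUBSURFACE = "subsurface_like"
ENV_CONTAMINANT = "contaminant_like"
ENV_AMBIGUOUS = "ambiguous"
ENV_ABSENT = "absent"

#: the documented rule labels
RULE_LABELS = frozenset({
    "R1",
    "R2-subsurface", "R2-contaminant", "R2-default",
    "R3-contaminant", "R3-subsurface", "R3-whitelist", "R3-default",
})


@dataclass
class EnvironmentMap:
    """Keyword map classifying a best-hit environment description.

    Matching is case-insensitive substring search; if both keyword classes
    match, the contaminant class wins (discard on doubt). The two lists must
    be disjoint.
    """

    subsurface_keywords: tuple[str, ...] = (
        "subsurface", "sediment", "hydrothermal", "serpentinite",
        "aquifer", "hot spring", "borehole", "crustal fluid",
    )
    contaminant_keywords: tuple[str, ...] = (
        "skin", "human", "reagent", "laboratory", "drilling", "kit", "grease",
    )

    def __post_init__(self) -> None:
        self.subsurface_keywords = tuple(k.lower() for k in self.subsurface_keywords)
        self.contaminant_keywords = tuple(k.lower() for k in self.contaminant_keywords)
        overlap = set(self.subsurface_keywords) & set(self.contaminant_keywords)
        if overlap:
            raise ValidationError(
                f"EnvironmentMap: keyword lists overlap: {sorted(overlap)}"
            )

    def classify(self, description: str | None) -> str:
        if description is None or not description.strip():
            return ENV_ABSENT
        text = description.lower()
        if any(k in text for k in self.contaminant_keywords):
            return ENV_CONTAMINANT
        if any(k in text for k in self.subsurface_keywords):
            return ENV_SUBSURFACE
        return ENV_AMBIGUOUS


@dataclass
class ClassifierParams:
    """Tunable policy of the origin classifier.

    ``unknown_env_policy_matched`` decides whitelisted control-matchers whose
    environment is ambiguous or absent (default: likely_contaminant — discard
    on doubt); ``unknown_env_policy_unmatched`` decides non-matchers without
    environment evidence (default: possibly_subsurface). Both must be one of
    {possibly_subsurface, likely_contaminant}.
    """

    identity: IdentityParams = field(default_factory=IdentityParams)
    abundance_gate_reads: int | None = None
    unknown_env_policy_matched: OriginCategory = OriginCategory.LIKELY_CONTAMINANT
    unknown_env_policy_unmatched: OriginCategory = OriginCategory.POSSIBLY_SUBSURFACE

    def __post_init__(self) -> None:
        allowed = {OriginCategory.POSSIBLY_SUBSURFACE, OriginCategory.LIKELY_CONTAMINANT}
        for name in ("unknown_env_policy_matched", "unknown_env_policy_unmatched"):
            val = OriginCategory(getattr(self, name))
            setattr(self, name, val)
            if val not in allowed:
                raise ValidationError(
                    f"ClassifierParams.{name} must be possibly_subsurface or "
                    f"likely_contaminant, got {val.value}"
                )


@dataclass(frozen=True)
class OriginCall:
    """One ASV's category plus the evidence trail that produced it."""

    asv_id: str
    category: OriginCategory
    control_evidence: MatchEvidence | None
    whitelisted: bool
    env_class: str
    rule_fired: str

    def __post_init__(self) -> None:
        if self.rule_fired not in RULE_LABELS:
            raise ValidationError(f"undocumented rule label {self.rule_fired!r}")
        if self.category is OriginCategory.CONTAMINANT and (
            self.control_evidence is None or self.whitelisted
        ):
            raise ValidationError(
                f"{self.asv_id}: contaminant call requires control evidence and "
                "no whitelist cover"
            )
        if self.category is OriginCategory.SUBSURFACE and self.control_evidence is not None:
            raise ValidationError(
                f"{self.asv_id}: subsurface call incompatible with control evidence"
            )


def classify_asv(
    asv: SequenceRecord,
    total_reads: int,
    controls: ControlCollection,
    whitelist: Whitelist | None,
    env_class: str,
    params: ClassifierParams = None,
) -> OriginCall:
    """Run the rule cascade for one ASV. ``env_class`` is precomputed."""
    params = params or ClassifierParams()
    if controls.is_empty and whitelist is None:
        raise ValidationError(
            "classifier has no evidence basis: controls empty and no whitelist"
        )
    evidence = best_control_match(asv, controls, params.identity)
    if whitelist is not None:
        whitelisted, _ = in_whitelist(asv, whitelist, params.identity)
    else:
        whitelisted = False

    gated = (
        params.abundance_gate_reads is not None
        and total_reads <= params.abundance_gate_reads
    )
    env = ENV_ABSENT if gated else env_class

    if evidence is not None and not whitelisted:
        cat, rule = OriginCategory.CONTAMINANT, "R1"
    elif evidence is not None:  # whitelisted control-matcher
        if env == ENV_SUBSURFACE:
            cat, rule = OriginCategory.POSSIBLY_SUBSURFACE, "R2-subsurface"
        elif env == ENV_CONTAMINANT:
            cat, rule = OriginCategory.LIKELY_CONTAMINANT, "R2-contaminant"
        else:
            cat, rule = params.unknown_env_policy_matched, "R2-default"
    else:  # no control match
        if env == ENV_CONTAMINANT:
            cat, rule = OriginCategory.LIKELY_CONTAMINANT, "R3-contaminant"
        elif env == ENV_SUBSURFACE:
            cat, rule = OriginCategory.SUBSURFACE, "R3-subsurface"
        elif whitelisted:
            # likely-indigenous status read as affirmative evidence
            cat, rule = OriginCategory.SUBSURFACE, "R3-whitelist"
        else:
            cat, rule = params.unknown_env_policy_unmatched, "R3-default"
    return OriginCall(asv.id, cat, evidence, whitelisted, env, rule)


def classify_table(
    table: CountTable,
    seqs: Mapping[str, SequenceRecord] | list[SequenceRecord],
    controls: ControlCollection,
    whitelist: Whitelist | None,
    blast_map: Mapping[str, BlastHit] | Mapping[str, str] | None,
    env_map: EnvironmentMap | None = None,
    params: ClassifierParams | None = None,
) -> list[OriginCall]:
    """Classify every ASV in a count table; output order = table row order.

    ``blast_map`` maps ASV id to either a :class:`BlastHit` or directly to an
    environment description string; ASVs absent from it have no environment
    evidence. A table row without a sequence is a hard error naming the ASV.
    """
    params = params or ClassifierParams()
    env_map = env_map or EnvironmentMap()
    if not isinstance(seqs, Mapping):
        seqs = {rec.id: rec for rec in seqs}
    totals = table.row_totals()
    calls: list[OriginCall] = []
    for asv_id in table.asv_ids:
        if asv_id not in seqs:
            raise ValidationError(f"no sequence provided for table ASV {asv_id!r}")
        desc: str | None = None
        if blast_map is not None and asv_id in blast_map:
            entry = blast_map[asv_id]
            desc = entry.subject_description if isinstance(entry, BlastHit) else entry
        env_class = env_map.classify(desc)
        calls.append(
            classify_asv(
                seqs[asv_id], totals[asv_id], controls, whitelist, env_class, params
            )
        )
    return calls


@dataclass
class FilterResult:
    """A contaminant-filtered table plus the per-sample removal report."""

    table: CountTable
    report: pd.DataFrame  # sample_id, reads_before, reads_after, fraction_removed, fully_excluded


def filter_contaminants(table: CountTable, calls: list[OriginCall]) -> FilterResult:
    """Drop contaminant and likely-contaminant rows; report removed reads.

    Samples whose entire read count was removed are flagged ``fully_excluded``
    (the fate of one crustal sample in a real screen of this kind).
    """
    by_id = {c.asv_id: c for c in calls}
    missing = [a for a in table.asv_ids if a not in by_id]
    if missing:
        raise ValidationError(f"calls missing for ASVs: {missing[:5]}")
    drop = [
        a for a in table.asv_ids
        if by_id[a].category
        in (OriginCategory.CONTAMINANT, OriginCategory.LIKELY_CONTAMINANT)
    ]
    before = table.df.sum(axis=0)
    filtered = table.drop_asvs(drop)
    after = filtered.df.sum(axis=0)
    frac = ((before - after) / before.where(before > 0)).fillna(0.0)
    report = pd.DataFrame({
        "sample_id": table.sample_ids,
        "reads_before": before.values,
        "reads_after": after.values,
        "fraction_removed": frac.values,
        "fully_excluded": [(b > 0 and a == 0) for b, a in zip(before, after)],
    })
    n_excluded = int(report["fully_excluded"].sum())
    if n_excluded:
        logger.warning("%d sample(s) fully excluded by contaminant filtering", n_excluded)
    return FilterResult(filtered, report)


def calls_to_frame(calls: list[OriginCall]) -> pd.DataFrame:
    """Flatten origin calls into the output TSV layout."""
    rows = []
    for c in calls:
        ev = c.control_evidence
        rows.append({
            "asv_id": c.asv_id,
            "category": c.category.value,
            "rule_fired": c.rule_fired,
            "control_type": ev.control_type if ev else "",
            "control_seq_id": ev.control_seq_id if ev else "",
            "identity": f"{ev.identity:.6f}" if ev else "",
            "whitelisted": int(c.whitelisted),
            "env_class": c.env_class,
        })
    return pd.DataFrame(rows)
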