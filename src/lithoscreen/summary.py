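"""Post-classification reporting.

Covers the read-weighted origin-category profile per sample, the
contaminant-filtered family-level composition, the comparison of indigenous
read fraction against the perfluorocarbon drilling tracer, the
screening-success accounting over the per-sample metadata table, and the
viral-evidence tally over partial genomes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up
from .decontam import CATEGORY_ORDER, OriginCall
from .errors import ValidationError
from .records import (
    CountTable,
    GenomeAnnotation,
    GenomeType,
    PcrStatus,
    SampleRecord,
    SeqStatus,
    Sentinel,
    TaxonomyAssignment,
    ValueRange,
)

logger = logging.getLogger(__name__)

_CAT_COLS = [c.value for c in CATEGORY_ORDER]


def category_abundance(table: CountTable, calls: list[OriginCall]) -> pd.DataFrame:
    """Reads-weighted origin-category fractions per sample.

    Returns a DataFrame indexed by sample id with one column per category plus
    ``total_reads``. Zero-read samples keep NaN fractions rather than being
    divided (they are flagged by ``total_reads == 0``).
    """
    by_id = {c.asv_id: c for c in calls}
    missing = [a for a in table.asv_ids if a not in by_id]
    if missing:
        raise ValidationError(f"calls missing for ASVs: {missing[:5]}")
    cat = pd.Series({a: by_id[a].category.value for a in table.asv_ids})
    sums = table.df.groupby(cat).sum()
    sums = sums.reindex(_CAT_COLS, fill_value=0)
    totals = table.df.sum(axis=0)
    frac = (sums / totals.where(totals > 0)).T
    frac["total_reads"] = totals
    frac.index.name = "sample_id"
    return frac


def family_composition(
    filtered_table: CountTable,
    taxonomy: Mapping[str, TaxonomyAssignment],
    min_overall_fraction: float = 0.001,
) -> pd.DataFrame:
    """Family x sample relative abundances on a contaminant-filtered table.

    Families never reaching ``min_overall_fraction`` relative abundance in any
    sample are collapsed into "other family". ASVs lacking a taxonomy entry go
    to the "unknown bacteria" bucket with a logged warning. Labels fall back
    to "(p) Phylum" style where the family rank is unresolved.
    """
    labels: dict[str, str] = {}
    n_missing = 0
    for asv_id in filtered_table.asv_ids:
        tax = taxonomy.get(asv_id)
        if tax is None:
            n_missing += 1
            labels[asv_id] = "unknown bacteria"
        else:
            labels[asv_id] = tax.family_label()
    if n_missing:
        logger.warning("%d ASV(s) missing taxonomy; assigned 'unknown bacteria'", n_missing)
    fam_counts = filtered_table.df.groupby(pd.Series(labels)).sum()
    totals = fam_counts.sum(axis=0)
    frac = fam_counts / totals.where(totals > 0)
    keep = (frac >= min_overall_fraction).any(axis=1) if min_overall_fraction > 0 else frac.index == frac.index
    kept = frac[keep]
    dropped = frac[~keep] if min_overall_fraction > 0 else frac.iloc[0:0]
    if len(dropped):
        other = dropped.sum(axis=0).to_frame("other family").T
        kept = pd.concat([kept, other])
    kept = kept.fillna(0.0)
    kept.index.name = "family"
    return kept


def _exact_spearman_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p-value for the Spearman correlation.

    Enumerates all n! pairings (chunked, vectorized); intended for n <= 10.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    denom_x = math.sqrt((rx_c ** 2).sum())
    observed = abs(_rank_corr(rx, ry))
    n = len(x)
    count = 0
    total = 0
    chunk: list[tuple] = []

    def flush(chunk_perms) -> int:
        P = np.array(chunk_perms)
        py = ry[P]  # permuted rank vectors
        py_c = py - py.mean(axis=1, keepdims=True)
        denom = denom_x * np.sqrt((py_c ** 2).sum(axis=1))
        with np.errstate(invalid="ignore"):
            r = (py_c @ rx_c) / denom
        r = np.nan_to_num(r)
        return int((np.abs(r) >= observed - 1e-12).sum())

    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) >= 100_000:
            count += flush(chunk)
            total += len(chunk)
            chunk = []
    if chunk:
        count += flush(chunk)
        total += len(chunk)
    return count / total


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx_c, ry_c = rx - rx.mean(), ry - ry.mean()
    denom = math.sqrt((rx_c ** 2).sum() * (ry_c ** 2).sum())
    if denom == 0:
        return 0.0
    return float((rx_c * ry_c).sum() / denom)


def tracer_comparison(
    profiles: pd.DataFrame,
    samples: list[SampleRecord],
    tracer_field: str = "pfc_interior",
    bdl_policy: str = "exclude",
) -> dict:
    """Rank correlation of indigenous read fraction against the PFC tracer.

    The indigenous fraction is (subsurface + possibly_subsurface). Sentinel
    tracer values are excluded by default (``bdl_policy="exclude"``); with
    ``bdl_policy="zero"`` below-detection values are substituted with 0.
    Ranges contribute their midpoint. Fewer than 3 usable sample pairs yields
    an insufficient-data report and no correlation. The permutation p-value is
    exact for n <= 10, asymptotic beyond.
    """
    if bdl_policy not in ("exclude", "zero"):
        raise ValidationError(f"unknown bdl_policy {bdl_policy!r}")
    pairs: list[tuple[str, float, float]] = []
    n_excluded = 0
    for s in sorted(samples, key=lambda s: s.sample_id):
        if s.sample_id not in profiles.index:
            continue
        row = profiles.loc[s.sample_id]
        if row.get("total_reads", 1) == 0 or pd.isna(row["subsurface"]):
            n_excluded += 1
            continue
        value = getattr(s, tracer_field)
        if isinstance(value, Sentinel):
            if bdl_policy == "zero" and value.code == "BDL":
                value = 0.0
            else:
                n_excluded += 1
                continue
        elif isinstance(value, ValueRange):
            value = value.midpoint
        indig = float(row["subsurface"] + row["possibly_subsurface"])
        pairs.append((s.sample_id, indig, float(value)))
    report: dict = {
        "tracer_field": tracer_field,
        "bdl_policy": bdl_policy,
        "n_used": len(pairs),
        "n_excluded": n_excluded,
        "samples_used": [p[0] for p in pairs],
    }
    if len(pairs) < 3:
        report["status"] = "insufficient_data"
        return report
    x = np.array([p[1] for p in pairs])
    y = np.array([p[2] for p in pairs])
    rho = _rank_corr(stats.rankdata(x), stats.rankdata(y))
    if len(pairs) <= 10:
        pval = _exact_spearman_pvalue(x, y)
        method = "exact_permutation"
    else:
        pval = float(stats.spearmanr(x, y).pvalue)
        method = "asymptotic"
    report.update(status="ok", rank_correlation=rho, p_value=pval, p_method=method)
    return report


@dataclass(frozen=True)
class ScreeningSummary:
    """Screening-success accounting over the sample metadata table."""

    n_screened: int
    n_cells_detected: int
    n_pcr_positive: int
    n_sequenced: int
    n_sequenced_sediment: int
    n_sequenced_crust: int
    efficiency_percent: float

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["efficiency_percent_display"] = round_half_up(self.efficiency_percent)
        return d


def summarize_screening(samples: list[SampleRecord]) -> ScreeningSummary:
    """Count screening outcomes: cells detected, PCR-positive, sequenced.

    Cells were detected wherever the PCR status is not "no cells identified".
    The sediment/crust split of sequenced samples uses the lithology heuristic
    (free text containing "sand" counts as sediment). Efficiency is sequenced
    over screened, as a percentage.
    """
    if not samples:
        raise ValidationError("summarize_screening: empty sample list")
    n = len(samples)
    cells = [s for s in samples if s.pcr_status is not PcrStatus.NO_CELLS]
    pcr_pos = [s for s in cells if s.pcr_status is PcrStatus.POSITIVE]
    seq = [s for s in pcr_pos if s.seq_status is SeqStatus.SUCCESS]
    sed = [s for s in seq if s.is_sediment]
    return ScreeningSummary(
        n_screened=n,
        n_cells_detected=len(cells),
        n_pcr_positive=len(pcr_pos),
        n_sequenced=len(seq),
        n_sequenced_sediment=len(sed),
        n_sequenced_crust=len(seq) - len(sed),
        efficiency_percent=100.0 * len(seq) / n,
    )


def summarize_viral_evidence(genomes: list[GenomeAnnotation]) -> dict:
    """Fraction of partial genomes with viral evidence, per type and combined."""
    if not genomes:
        raise ValidationError("summarize_viral_evidence: empty genome list")
    out: dict = {}
    for gtype in (GenomeType.MAG, GenomeType.SAG):
        subset = [g for g in genomes if g.genome_type is gtype]
        flagged = sum(g.has_viral_evidence for g in subset)
        out[gtype.value] = {
            "n": len(subset),
            "n_viral": flagged,
            "fraction": flagged / len(subset) if subset else 0.0,
        }
    flagged = sum(g.has_viral_evidence for g in genomes)
    frac = flagged / len(genomes)
    out["combined"] = {
        "n": len(genomes),
        "n_viral": flagged,
        "fraction": frac,
        "percent_display": round_half_up(100.0 * frac, 1),
    }
    return out
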