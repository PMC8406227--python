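"""Seeded synthetic-data generator for end-to-end pipeline testing.

Real surveys of this kind rest on raw sequence archives and upstream tools
(denoisers, assemblers, viral detectors) that are out of scope here. The
generator instead produces every input the pipeline consumes — ASV sequences,
control collections, a whitelist, environment labels, count tables, tracer
values and KO-annotated genomes — together with recorded ground truth, so
every stage is testable offline and deterministically.

The default community is deliberately *separable*: contaminant ASVs are
verbatim copies of control sequences while indigenous ASVs stay below a 97%
identity ceiling against every control, so a correct classifier must achieve
contaminant precision and recall of exactly 1.0. The generator certifies this
regime by exhaustive pairwise identity before writing truth, so downstream
recovery tests cannot be vacuously broken by a bad draw. The no-template
control emulates the structure seen in real reagent controls, where two
contaminant taxa carry the bulk of the reads.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import atomic_write, sha256_file
from .errors import ValidationError
from .records import (
    ControlCollection,
    CountTable,
    GenomeAnnotation,
    PathwayDefinition,
    SampleRecord,
    SequenceRecord,
    Whitelist,
    WhitelistMode,
)
from .similarity import IdentityParams, best_control_match, global_identity

_BASES = np.array(list("ACGT"))

_SUBSURFACE_DESCRIPTIONS = (
    "serpentinite-hosted subsurface fluid clone",
    "deep marine sediment clone",
    "terrestrial subsurface aquifer isolate",
    "hydrothermal vent chimney clone",
    "basaltic borehole fluid clone",
)
_CONTAMINANT_DESCRIPTIONS = (
    "human skin metagenome clone",
    "laboratory reagent contaminant",
    "drilling grease isolate",
    "DNA extraction kit contaminant",
)


@dataclass
class GeneratorParams:
    """Study-condition parameters of the synthetic community.

    Defaults describe the separable test regime: 20 indigenous + 10
    contaminant ASVs of 370 nt (V4V5-amplicon-like length), 8 samples at
    50,000 reads each with planted contaminant read fractions spanning 0 to 1,
    an NTC whose entries are dominated by two contaminant taxa (110 + 21 of
    147, emulating reagent-control structure), a 14-entry drilling-fluid set
    and a 30-entry seawater set, and a whitelist covering half the indigenous
    pool. ``seed`` is mandatory.
    """

    seed: int
    n_indigenous: int = 20
    n_contaminant: int = 10
    asv_length: int = 370
    n_samples: int = 8
    read_depth: int = 50_000
    contaminant_fractions: tuple[float, ...] | None = None  # default linspace(0,1)
    lognormal_sigma: float = 1.0
    whitelist_fraction: float = 0.5
    n_whitelist_decoys: int = 0
    ntc_total: int = 147
    ntc_dominant: tuple[int, int] = (110, 21)
    n_drill_fluid: int = 14
    n_seawater: int = 30
    n_variant_contaminants: int = 0
    variant_substitutions: int = 3
    separation_ceiling: float = 0.97

    def __post_init__(self) -> None:
        if self.contaminant_fractions is None:
            self.contaminant_fractions = tuple(
                np.linspace(0.0, 1.0, self.n_samples)
            )
        self.contaminant_fractions = tuple(float(f) for f in self.contaminant_fractions)
        if len(self.contaminant_fractions) != self.n_samples:
            raise ValidationError(
                "contaminant_fractions length must equal n_samples"
            )
        if any(not 0.0 <= f <= 1.0 for f in self.contaminant_fractions):
            raise ValidationError("contaminant_fractions must lie in [0, 1]")
        if self.read_depth < 0:
            raise ValidationError("read_depth must be >= 0")
        if not 0.0 <= self.whitelist_fraction <= 1.0:
            raise ValidationError("whitelist_fraction must lie in [0, 1]")
        if sum(self.ntc_dominant) > self.ntc_total:
            raise ValidationError("ntc_dominant counts exceed ntc_total")
        if self.n_variant_contaminants > self.n_contaminant:
            raise ValidationError("more variant contaminants than contaminants")


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside generated data."""

    seed: int
    asv_origin: dict[str, str] = field(default_factory=dict)  # indigenous|contaminant
    contaminant_fractions: dict[str, float] = field(default_factory=dict)
    tracer: dict[str, float] = field(default_factory=dict)
    pathway_completeness: dict[str, dict[str, float]] = field(default_factory=dict)
    marker_copies: dict[str, dict[str, int]] = field(default_factory=dict)


@dataclass
class Community:
    asvs: list[SequenceRecord]
    controls: ControlCollection
    whitelist: Whitelist | None
    environment: dict[str, str]
    truth: SyntheticTruth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for p in pos:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return "".join(out)


def make_community(params: GeneratorParams) -> Community:
    """Generate ASVs, controls, whitelist and environment labels with truth.

    Indigenous ASVs are kept mutually below the separation ceiling and below
    it against every contaminant (rejection sampling); contaminant ASVs are
    copied verbatim into the control sets. Optionally, the last
    ``n_variant_contaminants`` contaminant ASVs are near-threshold variants:
    the sampled ASV differs from its control copy by exactly
    ``variant_substitutions`` substitutions.
    """
    rng = np.random.default_rng(params.seed)
    ident = IdentityParams()
    ceiling = params.separation_ceiling

    contaminants = [_random_seq(rng, params.asv_length) for _ in range(params.n_contaminant)]
    indigenous: list[str] = []
    for _ in range(params.n_indigenous):
        for _attempt in range(200):
            cand = _random_seq(rng, params.asv_length)
            others = indigenous + contaminants
            if all(global_identity(cand, o, ident) < ceiling for o in others):
                indigenous.append(cand)
                break
        else:
            raise ValidationError(
                "infeasible separation constraints: could not place "
                f"{params.n_indigenous} indigenous ASVs of length {params.asv_length}"
            )

    truth = SyntheticTruth(seed=params.seed)
    asvs: list[SequenceRecord] = []
    environment: dict[str, str] = {}
    for i, seq in enumerate(indigenous):
        rid = f"asv_indig_{i:04d}"
        asvs.append(SequenceRecord(rid, seq))
        truth.asv_origin[rid] = "indigenous"
        environment[rid] = _SUBSURFACE_DESCRIPTIONS[i % len(_SUBSURFACE_DESCRIPTIONS)]
    control_source: list[str] = []  # the control-side sequence per contaminant
    for i, seq in enumerate(contaminants):
        rid = f"asv_contam_{i:04d}"
        is_variant = i >= params.n_contaminant - params.n_variant_contaminants
        sample_side = (
            _mutate(rng, seq, params.variant_substitutions) if is_variant else seq
        )
        asvs.append(SequenceRecord(rid, sample_side))
        control_source.append(seq)
        truth.asv_origin[rid] = "contaminant"
        environment[rid] = _CONTAMINANT_DESCRIPTIONS[i % len(_CONTAMINANT_DESCRIPTIONS)]

    # NTC: all contaminants appear verbatim; two dominant taxa carry the bulk
    counts = np.zeros(params.n_contaminant, dtype=int)
    d0, d1 = params.ntc_dominant
    counts[0] = d0
    if params.n_contaminant > 1:
        counts[1] = d1
    else:
        counts[0] += d1
    remainder = params.ntc_total - int(counts.sum())
    for j in range(remainder):
        # spread the tail over the non-dominant taxa only
        idx = 2 + (j % (params.n_contaminant - 2)) if params.n_contaminant > 2 else 0
        counts[idx] += 1
    counts = np.maximum(counts, 1)  # every contaminant present at least once
    ntc = []
    k = 0
    for i, c in enumerate(counts):
        for _ in range(c):
            ntc.append(SequenceRecord(f"ntc_{k:04d}", control_source[i]))
            k += 1
    drill = [
        SequenceRecord(f"grease_{j:04d}", control_source[int(rng.integers(params.n_contaminant))])
        for j in range(params.n_drill_fluid)
    ]
    sea = [
        SequenceRecord(f"sw_{j:04d}", control_source[int(rng.integers(params.n_contaminant))])
        for j in range(params.n_seawater)
    ]
    controls = ControlCollection(ntc=ntc, drill_fluid=drill, seawater=sea)

    n_wl = int(round(params.whitelist_fraction * params.n_indigenous))
    wl_entries = [
        SequenceRecord(f"wl_{i:04d}", indigenous[i]) for i in range(n_wl)
    ]
    wl_entries += [
        SequenceRecord(f"wl_decoy_{i:04d}", control_source[i])
        for i in range(params.n_whitelist_decoys)
    ]
    whitelist = (
        Whitelist(wl_entries, WhitelistMode.EXACT_SEQUENCE) if wl_entries else None
    )

    community = Community(asvs, controls, whitelist, environment, truth)
    _certify_separable(community, params, ident)
    return community


def _certify_separable(
    community: Community, params: GeneratorParams, ident: IdentityParams
) -> None:
    """Verify the separable-regime guarantees before the truth is trusted."""
    unique_controls = sorted(
        {r.sequence for _, recs in community.controls.iter_sets() for r in recs}
    )
    indig = [a for a in community.asvs if community.truth.asv_origin[a.id] == "indigenous"]
    contam = [a for a in community.asvs if community.truth.asv_origin[a.id] == "contaminant"]
    for i, a in enumerate(indig):
        for b in indig[i + 1:]:
            if global_identity(a.sequence, b.sequence, ident) >= params.separation_ceiling:
                raise ValidationError(
                    f"separability certificate failed: {a.id} ~ {b.id}"
                )
        for c in unique_controls:
            if global_identity(a.sequence, c, ident) >= params.separation_ceiling:
                raise ValidationError(
                    f"separability certificate failed: {a.id} matches a control"
                )
    for a in contam:
        if best_control_match(a, community.controls, ident) is None:
            raise ValidationError(
                f"separability certificate failed: contaminant {a.id} has no "
                "control match at threshold"
            )


def sample_counts(community: Community, params: GeneratorParams) -> CountTable:
    """Draw per-sample multinomial read counts with planted contaminant mass.

    For each sample, the planted contaminant fraction is split uniformly over
    contaminant ASVs and the remainder over indigenous ASVs with log-normal
    relative abundances (drawn per sample), so the expected contaminant read
    fraction equals the planted value exactly. Zero-depth samples yield a
    zero column.
    """
    rng = np.random.default_rng([params.seed, 1])
    origin = community.truth.asv_origin
    asv_ids = [a.id for a in community.asvs]
    is_contam = np.array([origin[a] == "contaminant" for a in asv_ids])
    n_c = int(is_contam.sum())
    n_i = len(asv_ids) - n_c
    cols = {}
    for s, f in enumerate(params.contaminant_fractions):
        sid = f"S{s + 1}"
        p = np.zeros(len(asv_ids))
        if n_c:
            p[is_contam] = f / n_c
        if n_i:
            w = rng.lognormal(mean=0.0, sigma=params.lognormal_sigma, size=n_i)
            p[~is_contam] = (1.0 - f) * w / w.sum()
        if p.sum() == 0:
            counts = np.zeros(len(asv_ids), dtype=int)
        else:
            counts = rng.multinomial(params.read_depth, p / p.sum())
        cols[sid] = counts
        community.truth.contaminant_fractions[sid] = float(f)
    df = pd.DataFrame(cols, index=asv_ids)
    return CountTable(df)


def make_tracer(
    truth: SyntheticTruth, noise_sd: float = 0.0, seed: int | None = None
) -> dict[str, float]:
    """Per-sample tracer values, monotone increasing in contaminant fraction.

    The noise-free construction is strictly monotone (tracer spans 1 to 1e5,
    log-linearly in the planted fraction, the dynamic range seen in real
    perfluorocarbon tracer data); multiplicative log-normal noise of scale
    ``noise_sd`` is seeded and reproducible.
    """
    rng = np.random.default_rng(seed if seed is not None else [truth.seed, 2])
    tracer: dict[str, float] = {}
    for sid, f in sorted(truth.contaminant_fractions.items()):
        value = 10.0 ** (5.0 * f)
        if noise_sd > 0:
            value *= float(np.exp(noise_sd * rng.standard_normal()))
        tracer[sid] = value
    truth.tracer = tracer
    return tracer


# --- genomes ---------------------------------------------------------------


@dataclass
class GenomeSpec:
    """Planted truth for one synthetic genome annotation."""

    genome_id: str
    genome_type: str = "MAG"
    completeness_targets: dict[str, float] = field(default_factory=dict)
    marker_copies: dict[str, int] = field(default_factory=dict)
    has_viral_evidence: bool = False
    has_ssu: bool = False


def make_genomes(
    specs: list[GenomeSpec],
    pathways: list[PathwayDefinition],
    markers: list[tuple[str, str, frozenset[str]]] | None = None,
) -> tuple[list[GenomeAnnotation], SyntheticTruth]:
    """Construct KO annotations scoring exactly the planted completeness.

    Each target must be expressible as k/|defining KOs| of its pathway; the
    constructed KO sets are re-scored and any deviation (e.g. cross-talk from
    overlapping defining sets) is a hard error, so planted truth is exact by
    construction.
    """
    from .profiling import pathway_completeness  # local to avoid cycle

    pathway_by_id = {p.pathway_id: p for p in pathways}
    marker_by_id = {m[0]: m for m in (markers or [])}
    truth = SyntheticTruth(seed=0)
    genomes: list[GenomeAnnotation] = []
    for spec in specs:
        kos: dict[str, int] = {}
        for pid, target in spec.completeness_targets.items():
            if pid not in pathway_by_id:
                raise ValidationError(f"{spec.genome_id}: unknown pathway {pid!r}")
            defining = sorted(pathway_by_id[pid].defining_kos)
            k = target * len(defining)
            if abs(k - round(k)) > 1e-9:
                raise ValidationError(
                    f"{spec.genome_id}: target {target} for pathway {pid!r} is "
                    f"not expressible as k/{len(defining)}"
                )
            for ko in defining[: int(round(k))]:
                kos.setdefault(ko, 1)
        for mid, copies in spec.marker_copies.items():
            if mid not in marker_by_id:
                raise ValidationError(f"{spec.genome_id}: unknown marker {mid!r}")
            if copies > 0:
                first_ko = sorted(marker_by_id[mid][2])[0]
                kos[first_ko] = copies
        genome = GenomeAnnotation(
            genome_id=spec.genome_id,
            genome_type=spec.genome_type,
            ko_copies=kos,
            has_viral_evidence=spec.has_viral_evidence,
            has_ssu=spec.has_ssu,
        )
        for pid, target in spec.completeness_targets.items():
            got = pathway_completeness(genome, pathway_by_id[pid])
            if abs(got - target) > 1e-12:
                raise ValidationError(
                    f"{spec.genome_id}: pathway {pid!r} scores {got}, planted "
                    f"{target} (overlapping definitions make targets "
                    "jointly unexpressible)"
                )
        for mid, copies in spec.marker_copies.items():
            got_copies = sum(kos.get(ko, 0) for ko in marker_by_id[mid][2])
            if got_copies != copies:
                raise ValidationError(
                    f"{spec.genome_id}: marker {mid!r} sums to {got_copies}, "
                    f"planted {copies} (KO overlap with a pathway target)"
                )
        genomes.append(genome)
        truth.pathway_completeness[spec.genome_id] = dict(spec.completeness_targets)
        truth.marker_copies[spec.genome_id] = dict(spec.marker_copies)
    return genomes, truth


# --- dataset writing -------------------------------------------------------


def write_dataset(out_dir: str | Path, params: GeneratorParams) -> Path:
    """Generate a full dataset directory in the formats the readers consume.

    Writes ASV FASTA, three control FASTAs, whitelist FASTA, environment TSV,
    count table TSV, tracer TSV, truth JSON, and a manifest JSON recording
    the parameters, seed and file checksums.
    """
    from .io import write_count_table, write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    community = make_community(params)
    table = sample_counts(community, params)
    tracer = make_tracer(community.truth)

    write_fasta(community.asvs, out / "asvs.fasta")
    write_fasta(community.controls.ntc, out / "controls_ntc.fasta")
    write_fasta(community.controls.drill_fluid, out / "controls_drill_fluid.fasta")
    write_fasta(community.controls.seawater, out / "controls_seawater.fasta")
    if community.whitelist is not None:
        write_fasta(list(community.whitelist.entries), out / "whitelist.fasta")
    with atomic_write(out / "environment.tsv") as fh:
        fh.write("asv_id\tdescription\n")
        for asv_id, desc in sorted(community.environment.items()):
            fh.write(f"{asv_id}\t{desc}\n")
    write_count_table(table, out / "counts.tsv")
    with atomic_write(out / "tracer.tsv") as fh:
        fh.write("sample_id\ttracer\n")
        for sid, val in sorted(tracer.items()):
            fh.write(f"{sid}\t{val:.6g}\n")
    with atomic_write(out / "truth.json") as fh:
        json.dump(dataclasses.asdict(community.truth), fh, indent=2, sort_keys=True)
    files = sorted(p.name for p in out.iterdir() if p.suffix in (".fasta", ".tsv", ".json") and p.name != "manifest.json")
    manifest = {
        "seed": params.seed,
        "params": dataclasses.asdict(params),
        "files": {name: sha256_file(out / name) for name in files},
    }
    with atomic_write(out / "manifest.json") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def reference_sample_table() -> list[SampleRecord]:
    """The packaged 29-sample expedition metadata fixture (the worked example)."""
    from .io import read_sample_table

    with resources.as_file(
        resources.files("lithoscreen") / "data" / "expedition_samples.tsv"
    ) as path:
        return read_sample_table(path)
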