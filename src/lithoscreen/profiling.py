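"""KO-based pathway completeness and marker-gene copy matrices for partial genomes.

Pathway completeness is the fraction of a pathway's defining KO identifiers
present in a genome annotation — presence/absence semantics, so copy numbers
above one never inflate the score. Marker-gene matrices instead sum copy
numbers over each marker's KO list, for heatmaps of metabolic gene content.

Default pathway and marker definitions ship as editable TSV data
(KEGG-Decoder-style KO sets covering carbon fixation, heterotrophy,
denitrification, sulfur cycling, CO oxidation, hydrogenases and oxidases);
users can and should substitute their own definition files.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .errors import ValidationError
from .records import GenomeAnnotation, PathwayDefinition


def pathway_completeness(genome: GenomeAnnotation, pathway: PathwayDefinition) -> float:
    """|defining KOs present| / |defining KOs|; copies above 1 count once."""
    present = pathway.defining_kos & set(genome.ko_copies)
    return len(present) / len(pathway.defining_kos)


def completeness_matrix(
    genomes: list[GenomeAnnotation], pathways: list[PathwayDefinition]
) -> pd.DataFrame:
    """Genome x pathway completeness fractions (duplicate ids are errors)."""
    _check_unique([g.genome_id for g in genomes], "genome")
    _check_unique([p.pathway_id for p in pathways], "pathway")
    data = {
        g.genome_id: [pathway_completeness(g, p) for p in pathways] for g in genomes
    }
    df = pd.DataFrame(data, index=[p.pathway_id for p in pathways]).T
    df.index.name = "genome_id"
    return df


def marker_gene_matrix(
    genomes: list[GenomeAnnotation],
    markers: list[tuple[str, str, frozenset[str]]],
) -> pd.DataFrame:
    """Genome x marker total copy numbers (sum over the marker's KO list)."""
    _check_unique([g.genome_id for g in genomes], "genome")
    _check_unique([m[0] for m in markers], "marker")
    for marker_id, _, kos in markers:
        if not kos:
            raise ValidationError(f"marker {marker_id!r}: empty KO list")
    data = {
        g.genome_id: [
            sum(g.ko_copies.get(ko, 0) for ko in kos) for _, _, kos in markers
        ]
        for g in genomes
    }
    df = pd.DataFrame(data, index=[m[0] for m in markers], dtype="int64").T
    df.index.name = "genome_id"
    return df


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id {i!r}")
        seen.add(i)


def default_pathways() -> list[PathwayDefinition]:
    """The packaged pathway-definition set (editable data, not code)."""
    from .io import read_pathway_definitions

    with resources.as_file(
        resources.files("lithoscreen") / "data" / "pathways.tsv"
    ) as path:
        return read_pathway_definitions(path)


def default_markers() -> list[tuple[str, str, frozenset[str]]]:
    """The packaged marker-gene definitions (22 metabolic function genes)."""
    from .io import read_marker_definitions

    with resources.as_file(resources.files("lithoscreen") / "data" / "markers.tsv") as path:
        return read_marker_definitions(path)
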