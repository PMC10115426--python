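"""Pathway definitions and gene-set / probe-map file handling.

A pathway is defined by the set of genes transcriptionally regulated by its
transcription factor; their mRNA levels are the evidence from which pathway
activity is inferred.  Gene sets are exchanged in the GMT dialect
(``name<TAB>description<TAB>gene1<TAB>gene2...``, one set per line) and probe
maps as two-column TSV (``probe_id<TAB>gene_symbol``, header required).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayDefinition",
    "read_gmt",
    "write_gmt",
    "read_probe_map",
    "default_probe_map",
    "example_pathway_definitions",
]


@dataclass(frozen=True)
class PathwayDefinition:
    """A named pathway with its ordered transcription-factor target genes.

    Parameters
    ----------
    name:
        Pathway identifier, e.g. ``"NFKB"`` or ``"JAK-STAT1/2"``.
    target_genes:
        Ordered, duplicate-free gene symbols.
    description:
        Free-text description (GMT second column).
    probe_map:
        Mapping gene symbol -> probe identifiers on a given platform.  Genes
        absent from the map are treated as unmeasured (``missing`` evidence).
    """

    name: str
    target_genes: tuple[str, ...]
    description: str = ""
    probe_map: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("pathway name must be non-empty")
        genes = tuple(self.target_genes)
        if len(genes) == 0:
            raise ValueError(f"pathway {self.name!r} has no target genes")
        if len(set(genes)) != len(genes):
            raise ValueError(f"pathway {self.name!r} has duplicate target genes")
        object.__setattr__(self, "target_genes", genes)
        object.__setattr__(
            self,
            "probe_map",
            {g: tuple(p) for g, p in dict(self.probe_map).items()},
        )

    @property
    def n_genes(self) -> int:
        return len(self.target_genes)

    def with_probe_map(self, probe_map: Mapping[str, Sequence[str]]) -> "PathwayDefinition":
        """Return a copy whose probe map is restricted to this pathway's genes."""
        restricted = {g: tuple(probe_map[g]) for g in self.target_genes if g in probe_map}
        return PathwayDefinition(self.name, self.target_genes, self.description, restricted)


def read_gmt(path: str | Path) -> list[PathwayDefinition]:
    """Parse a GMT gene-set file into pathway definitions.

    Duplicate gene symbols within a line are collapsed (first occurrence
    kept) with a logged warning; duplicate pathway names across lines are an
    error, as is any non-empty line with fewer than three tab-separated
    fields.
    """
    path = Path(path)
    definitions: list[PathwayDefinition] = []
    seen: set[str] = set()
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line "
                    f"(expected >=3 tab-separated fields, got {len(fields)})"
                )
            name, description, *genes = fields
            genes = [g.strip() for g in genes if g.strip()]
            if name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            seen.add(name)
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                logger.warning(
                    "%s:%d: pathway %r has %d duplicate gene symbols; collapsed",
                    path, lineno, name, len(genes) - len(deduped),
                )
            definitions.append(PathwayDefinition(name, tuple(deduped), description))
    return definitions


def write_gmt(definitions: Iterable[PathwayDefinition], path: str | Path) -> None:
    with Path(path).open("w") as handle:
        for d in definitions:
            handle.write("\t".join([d.name, d.description, *d.target_genes]) + "\n")


def read_probe_map(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a probe map TSV (``probe_id<TAB>gene_symbol``; header required).

    Returns a mapping gene symbol -> tuple of probe ids, preserving file
    order within each gene.
    """
    path = Path(path)
    mapping: dict[str, list[str]] = {}
    with path.open() as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}: probe map needs 2 tab-separated columns")
        for lineno, raw in enumerate(handle, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            probe, gene = fields[0].strip(), fields[1].strip()
            mapping.setdefault(gene, []).append(probe)
    return {g: tuple(p) for g, p in mapping.items()}


def default_probe_map(definitions: Iterable[PathwayDefinition]) -> dict[str, tuple[str, ...]]:
    """One synthetic probe per gene, named ``<GENE>_at`` (simulator convention)."""
    mapping: dict[str, tuple[str, ...]] = {}
    for d in definitions:
        for g in d.target_genes:
            mapping.setdefault(g, (f"{g}_at",))
    return mapping


def example_pathway_definitions(with_probe_map: bool = True) -> list[PathwayDefinition]:
    """Load the bundled illustrative gene sets.

    These are small demonstration sets of canonical target genes per pathway
    and are **not** a calibrated assay; real analyses should supply their own
    GMT.  With ``with_probe_map`` the simulator's one-probe-per-gene map is
    attached.
    """
    ref = resources.files("stpscore.data").joinpath("example_pathways.gmt")
    with resources.as_file(ref) as p:
        definitions = read_gmt(p)
    if with_probe_map:
        pm = default_probe_map(definitions)
        definitions = [d.with_probe_map(pm) for d in definitions]
    return definitions
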