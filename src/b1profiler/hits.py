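"""Homology-search hit ingestion and tiered e-value filtering.

Consumes HMMER3 per-domain tabular output (``--domtblout``) or a plain
six-column TSV, filters hits against a :class:`~b1profiler.catalog.GeneFamilyCatalog`
with two inclusive e-value tiers (a general tier for broad annotations and a
stricter custom cutoff for verified pathway families), resolves multiple hits
per protein to the best one, and builds a genome x gene-symbol copy-count
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import math

import pandas as pd

from .catalog import GeneFamilyCatalog
from .errors import ConfigurationError, ConsistencyError, ParseError

GENERAL_EVALUE = 1e-10  # broad annotation tier
STRICT_EVALUE = 1e-15   # verified tier for B1 / nitrification / carbon-fixation families


@dataclass(frozen=True)
class GeneHit:
    """One protein-to-family homology hit."""

    protein_id: str
    genome_id: str
    family_id: str
    full_seq_evalue: float
    bit_score: float
    alignment_coords: tuple[int, int] = (1, 1)

    def __post_init__(self):
        if not self.protein_id:
            raise ConsistencyError("protein_id must be non-empty")
        if self.full_seq_evalue < 0:
            raise ConsistencyError(f"negative e-value for {self.protein_id}")
        if not math.isfinite(self.bit_score):
            raise ConsistencyError(f"non-finite bit score for {self.protein_id}")


def _genome_from_protein(protein_id: str, delimiter: str) -> str:
    if delimiter in protein_id:
        return protein_id.rsplit(delimiter, 1)[0]
    return protein_id


def parse_hit_table(
    path: str | Path,
    format: str = "domtbl",
    genome_delimiter: str = "_",
) -> list[GeneHit]:
    """Parse a hit table into :class:`GeneHit` records.

    Parameters
    ----------
    path:
        File in HMMER3 ``--domtblout`` layout (whitespace-separated, ``#``
        comments) or a 6-column TSV
        (protein_id, genome_id, family_id, evalue, bit_score, coords).
    format:
        ``"domtbl"`` or ``"tsv"``.
    genome_delimiter:
        The domtbl format carries protein ids only; the genome id is the
        protein-id prefix up to the last occurrence of this delimiter.
    """
    if format not in {"domtbl", "tsv"}:
        raise ConfigurationError(f"unknown hit-table format {format!r}")
    path = Path(path)
    if not path.exists():
        raise ParseError("file not found", path=str(path))

    hits: list[GeneHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if format == "domtbl":
                hits.append(_parse_domtbl_row(line, lineno, path, genome_delimiter))
            else:
                hits.append(_parse_tsv_row(line, lineno, path))
    return hits


def _parse_domtbl_row(line: str, lineno: int, path: Path, delim: str) -> GeneHit:
    # hmmsearch orientation: target = protein, query = HMM family.
    fields = line.split()
    if len(fields) < 22:
        raise ParseError(
            f"expected >=22 whitespace-separated columns, got {len(fields)}",
            path=str(path), line=lineno,
        )
    protein_id = fields[0]
    family_id = fields[4] if fields[4] != "-" else fields[3]
    try:
        evalue = float(fields[6])
        score = float(fields[7])
        ali_from, ali_to = int(fields[17]), int(fields[18])
    except ValueError as exc:
        raise ParseError(f"non-numeric field: {exc}", path=str(path), line=lineno)
    if evalue < 0:
        raise ParseError("negative e-value", path=str(path), line=lineno)
    return GeneHit(
        protein_id=protein_id,
        genome_id=_genome_from_protein(protein_id, delim),
        family_id=family_id,
        full_seq_evalue=evalue,
        bit_score=score,
        alignment_coords=(ali_from, ali_to),
    )


def _parse_tsv_row(line: str, lineno: int, path: Path) -> GeneHit:
    fields = line.split("\t")
    if len(fields) != 6:
        raise ParseError(
            f"expected 6 tab-separated columns, got {len(fields)}",
            path=str(path), line=lineno,
        )
    protein_id, genome_id, family_id, evalue_s, score_s, coords_s = fields
    try:
        evalue = float(evalue_s)
        score = float(score_s)
    except ValueError:
        raise ParseError(
            f"non-numeric e-value/score ({evalue_s!r}, {score_s!r})",
            path=str(path), line=lineno,
        )
    try:
        start_s, end_s = coords_s.split("-", 1)
        coords = (int(start_s), int(end_s))
    except ValueError:
        raise ParseError(f"malformed coords {coords_s!r}", path=str(path), line=lineno)
    if evalue < 0:
        raise ParseError("negative e-value", path=str(path), line=lineno)
    return GeneHit(protein_id, genome_id, family_id, evalue, score, coords)


def filter_hits(
    hits: Iterable[GeneHit],
    catalog: GeneFamilyCatalog,
    general_threshold: float = GENERAL_EVALUE,
    strict_threshold: float = STRICT_EVALUE,
) -> list[GeneHit]:
    """Apply tiered e-value filtering and best-hit-per-protein resolution.

    Families flagged ``strict_tier`` in the catalog survive only at
    ``evalue <= strict_threshold``; every other catalog family survives at
    ``evalue <= general_threshold`` (both inclusive). Hits to families the
    catalog does not know are dropped. Of multiple surviving hits on one
    protein, the best is kept: highest bit score, ties broken by lower
    e-value, then lexicographically smallest family_id.
    """
    if strict_threshold <= 0 or general_threshold <= 0:
        raise ConfigurationError("e-value thresholds must be positive")
    if general_threshold < strict_threshold:
        raise ConfigurationError(
            f"general threshold ({general_threshold}) must be >= strict "
            f"threshold ({strict_threshold})"
        )

    best: dict[str, GeneHit] = {}
    for hit in hits:
        if hit.family_id not in catalog:
            continue
        cutoff = strict_threshold if catalog.is_strict(hit.family_id) else general_threshold
        if hit.full_seq_evalue > cutoff:
            continue
        cur = best.get(hit.protein_id)
        if cur is None or _hit_rank(hit) < _hit_rank(cur):
            best[hit.protein_id] = hit
    return [best[p] for p in sorted(best)]


def _hit_rank(hit: GeneHit) -> tuple:
    return (-hit.bit_score, hit.full_seq_evalue, hit.family_id)


def build_presence_matrix(
    hits: Sequence[GeneHit],
    catalog: GeneFamilyCatalog,
    genomes: Sequence[str],
) -> pd.DataFrame:
    """Genome x gene-symbol copy-count matrix from filtered hits.

    Cell (g, s) counts distinct proteins of genome *g* whose surviving best
    hit maps to symbol *s*; multi-copy genes are preserved as counts. Genomes
    without hits appear as all-zero rows.
    """
    if len(genomes) == 0:
        raise ConsistencyError("genome list must be non-empty")
    genome_set = set(genomes)
    offenders = sorted({h.genome_id for h in hits} - genome_set)
    if offenders:
        raise ConsistencyError(
            f"hits reference genomes absent from the genome list: {offenders}"
        )
    symbols = catalog.symbols()
    matrix = pd.DataFrame(0, index=list(genomes), columns=symbols, dtype=int)
    matrix.index.name = "genome_id"
    seen: set[str] = set()
    for hit in hits:
        if hit.protein_id in seen:
            continue  # hits are best-per-protein after filtering; guard anyway
        seen.add(hit.protein_id)
        matrix.loc[hit.genome_id, catalog.symbol(hit.family_id)] += 1
    return matrix
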