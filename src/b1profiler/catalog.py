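"""Gene-family catalog: HMM/KO accessions mapped to canonical gene symbols.

The catalog controls which homology-search hits are interpretable at all, which
filtering tier applies to each family, and what functional role (de novo
synthesis, salvage, transport, or chemoautotrophy marker) each symbol plays.
A curated default ships with the package covering the thiamine pathway
vocabulary plus nitrification / sulfur-oxidation / carbon-fixation marker KOs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ConsistencyError, ParseError

#: The controlled vocabulary of canonical gene symbols.
GENE_SYMBOLS = frozenset({
    "thiC", "thiD", "thiDN", "thiE", "thiG", "thi4", "thiL", "thiK", "thiM",
    "thiN", "tenA", "thiT", "thiB", "thiP", "thiQ", "thiX", "thiY", "thiZ",
    "cytX", "ykoC", "ykoD", "ykoE", "ykoF", "omr1",
    "amoA", "nxr", "aprA", "aprB", "dsrA", "rbcL",
})

ROLES = frozenset({"synthesis", "salvage", "transport", "chemoautotrophy"})
DOMAIN_SCOPES = frozenset({"bacteria", "archaea", "both"})

#: Symbols counted as thiamine transporters in genotype calls.
TRANSPORTER_SYMBOLS = frozenset({
    "thiT", "thiB", "thiP", "thiQ", "thiX", "thiY", "thiZ",
    "cytX", "ykoC", "ykoD", "ykoE", "ykoF", "omr1",
})


@dataclass(frozen=True)
class FamilyEntry:
    family_id: str
    gene_symbol: str
    role: str
    domain_scope: str
    strict_tier: bool


class GeneFamilyCatalog:
    """Mapping of homology-model identifiers to canonical gene symbols.

    Parameters
    ----------
    entries:
        One :class:`FamilyEntry` per family_id. Each family maps to exactly
        one symbol; several families may map to the same symbol.
    """

    def __init__(self, entries: list[FamilyEntry]):
        seen: dict[str, FamilyEntry] = {}
        for e in entries:
            if e.gene_symbol not in GENE_SYMBOLS:
                raise ConsistencyError(
                    f"catalog symbol {e.gene_symbol!r} outside the controlled vocabulary"
                )
            if e.role not in ROLES:
                raise ConsistencyError(f"unknown role {e.role!r} for {e.family_id}")
            if e.domain_scope not in DOMAIN_SCOPES:
                raise ConsistencyError(
                    f"unknown domain_scope {e.domain_scope!r} for {e.family_id}"
                )
            if e.family_id in seen:
                raise ConsistencyError(f"family_id {e.family_id!r} mapped twice")
            seen[e.family_id] = e
        self._entries = seen

    def __contains__(self, family_id: str) -> bool:
        return family_id in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __getitem__(self, family_id: str) -> FamilyEntry:
        return self._entries[family_id]

    @property
    def entries(self) -> list[FamilyEntry]:
        return list(self._entries.values())

    def symbol(self, family_id: str) -> str:
        return self._entries[family_id].gene_symbol

    def is_strict(self, family_id: str) -> bool:
        return self._entries[family_id].strict_tier

    def symbols(self) -> list[str]:
        """All symbols covered by this catalog, sorted."""
        return sorted({e.gene_symbol for e in self._entries.values()})

    def families_for(self, symbol: str) -> list[str]:
        return sorted(f for f, e in self._entries.items() if e.gene_symbol == symbol)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.family_id, e.gene_symbol, e.role, e.domain_scope, e.strict_tier)
             for e in self._entries.values()],
            columns=["family_id", "gene_symbol", "role", "domain_scope", "strict_tier"],
        )

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame().copy()
        df["strict_tier"] = df["strict_tier"].map({True: "true", False: "false"})
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneFamilyCatalog":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"family_id", "gene_symbol", "role", "domain_scope", "strict_tier"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"catalog missing columns {sorted(missing)}", path=str(path))
        entries = []
        for row in df.itertuples(index=False):
            flag = str(row.strict_tier).strip().lower()
            if flag not in {"true", "false", "1", "0"}:
                raise ParseError(
                    f"strict_tier must be boolean, got {row.strict_tier!r}", path=str(path)
                )
            entries.append(FamilyEntry(
                family_id=str(row.family_id),
                gene_symbol=str(row.gene_symbol),
                role=str(row.role),
                domain_scope=str(row.domain_scope),
                strict_tier=flag in {"true", "1"},
            ))
        return cls(entries)


def default_catalog() -> GeneFamilyCatalog:
    """The catalog shipped with the package (thiamine pathway + marker KOs)."""
    ref = resources.files("b1profiler").joinpath("data/gene_families.tsv")
    with resources.as_file(ref) as path:
        return GeneFamilyCatalog.from_tsv(path)
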