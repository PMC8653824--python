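"""Taxonomic ranks, lineages and genome-to-lineage tables.

The toolkit works with seven ordered ranks, superphylum (shallowest) through
species (deepest). Superphylum participates in lineages but is excluded from
the six-rank identity-threshold system (rank normalization spans species
through phylum only).

Lineages may be truncated: ranks are assigned contiguously from the
shallowest assigned rank downward, so a lineage known only to order level
simply lacks family/genus/species. "Candidatus" name prefixes are stripped on
parsing (and flagged) so provisional and validated spellings of the same
taxon compare equal.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping

from .errors import ConfigurationError, ParseError


class Rank(enum.IntEnum):
    """The seven ranks, ordered by depth (superphylum=0 ... species=6)."""

    SUPERPHYLUM = 0
    PHYLUM = 1
    CLASS = 2
    ORDER = 3
    FAMILY = 4
    GENUS = 5
    SPECIES = 6

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "Rank":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ConfigurationError(f"unknown rank label: {label!r}") from None


#: Ranks participating in the identity-threshold system, shallow to deep.
THRESHOLD_RANKS: tuple[Rank, ...] = (
    Rank.PHYLUM,
    Rank.CLASS,
    Rank.ORDER,
    Rank.FAMILY,
    Rank.GENUS,
    Rank.SPECIES,
)

_GTDB_PREFIXES = {
    "d": None,  # domain: carried separately, not one of the seven ranks
    "p": Rank.PHYLUM,
    "c": Rank.CLASS,
    "o": Rank.ORDER,
    "f": Rank.FAMILY,
    "g": Rank.GENUS,
    "s": Rank.SPECIES,
}

_CANDIDATUS_PREFIXES = ("Candidatus ", "Ca. ", "Ca_")


def _strip_candidatus(name: str) -> tuple[str, bool]:
    for pref in _CANDIDATUS_PREFIXES:
        if name.startswith(pref):
            return name[len(pref):].strip(), True
    return name, False


@dataclass(frozen=True)
class Lineage:
    """An ordered taxonomic path, possibly truncated below some rank.

    ``names`` maps each assigned :class:`Rank` to a non-empty taxon name.
    Assigned ranks must be contiguous from the shallowest assigned rank
    downward (no internal gaps). ``domain`` preserves a GTDB ``d__`` token
    for round-tripping; it is not a rank.
    """

    names: Mapping[Rank, str] = field(default_factory=dict)
    domain: str | None = None
    source_dialect: str = "gtdb_string"
    candidatus_stripped: bool = False
    gap_truncated: bool = False

    def __post_init__(self):
        object.__setattr__(self, "names", dict(self.names))
        depths = sorted(r.value for r in self.names)
        for name in self.names.values():
            if not name:
                raise ConfigurationError("lineage names must be non-empty")
        if depths and depths != list(range(depths[0], depths[-1] + 1)):
            raise ConfigurationError(
                f"lineage ranks are not contiguous: {[Rank(d).label for d in depths]}"
            )

    def get(self, rank: Rank) -> str | None:
        return self.names.get(rank)

    def is_assigned(self, rank: Rank) -> bool:
        return rank in self.names

    @property
    def empty(self) -> bool:
        return not self.names

    @property
    def deepest_rank(self) -> Rank | None:
        return max(self.names, default=None)

    @property
    def shallowest_rank(self) -> Rank | None:
        return min(self.names, default=None)

    def truncate(self, rank: Rank) -> "Lineage":
        """Copy with all ranks deeper than ``rank`` removed.

        If this lineage is unassigned at ``rank`` the result simply ends at
        the deepest assigned rank at or above it (possibly empty, in which
        case the result's ``gap_truncated`` flag is set).
        """
        kept = {r: n for r, n in self.names.items() if r <= rank}
        return replace(self, names=kept, gap_truncated=self.gap_truncated or not kept)

    def __str__(self) -> str:
        return format_lineage(self)


def parse_lineage(text: str, dialect: str = "gtdb_string") -> Lineage:
    """Parse a lineage string.

    Dialects:

    * ``gtdb_string`` — ``d__...;p__...;c__...;o__...;f__...;g__...;s__...``;
      empty suffixes (``f__``) mean the rank is unassigned.
    * ``ncbi_columns`` — seven tab-separated fields in rank order
      superphylum..species; empty fields mean unassigned.

    Assigned ranks must be contiguous; anything below the first internal gap
    is dropped with a warning. Candidatus prefixes are stripped and flagged.
    """
    if not text or not text.strip():
        raise ParseError("empty lineage string")
    by_rank: dict[Rank, str] = {}
    domain = None
    candidatus = False

    if dialect == "gtdb_string":
        for token in text.strip().split(";"):
            token = token.strip()
            if not token:
                continue
            if len(token) < 3 or token[1:3] != "__":
                raise ParseError(f"malformed GTDB token: {token!r}")
            prefix, name = token[0], token[3:].strip()
            if prefix not in _GTDB_PREFIXES:
                raise ParseError(f"unknown GTDB rank prefix: {prefix!r}")
            if not name:
                continue
            name, was_ca = _strip_candidatus(name)
            candidatus = candidatus or was_ca
            if _GTDB_PREFIXES[prefix] is None:
                domain = name
            elif name:
                by_rank[_GTDB_PREFIXES[prefix]] = name
    elif dialect == "ncbi_columns":
        fields = [f.strip() for f in text.rstrip("\n").split("\t")]
        if len(fields) > len(Rank):
            raise ParseError(f"expected at most 7 rank fields, got {len(fields)}")
        for depth, name in enumerate(fields):
            if not name:
                continue
            name, was_ca = _strip_candidatus(name)
            candidatus = candidatus or was_ca
            if name:
                by_rank[Rank(depth)] = name
    else:
        raise ConfigurationError(f"unknown lineage dialect: {dialect!r}")

    if not by_rank:
        raise ParseError(f"no parsable ranks in lineage: {text!r}")

    # enforce contiguity: truncate at the first gap below the shallowest
    # assigned rank
    depths = sorted(r.value for r in by_rank)
    truncated = False
    keep_until = depths[-1]
    for d in range(depths[0], depths[-1] + 1):
        if Rank(d) not in by_rank:
            keep_until = d - 1
            truncated = True
            break
    if truncated:
        dropped = [Rank(d).label for d in depths if d > keep_until]
        warnings.warn(
            f"lineage has a gap; dropping ranks below {Rank(keep_until).label}: "
            f"{dropped}",
            stacklevel=2,
        )
        by_rank = {r: n for r, n in by_rank.items() if r.value <= keep_until}

    return Lineage(
        names=by_rank,
        domain=domain,
        source_dialect=dialect,
        candidatus_stripped=candidatus,
        gap_truncated=truncated,
    )


def format_lineage(lineage: Lineage, dialect: str = "gtdb_string") -> str:
    """Render a lineage as a GTDB rank-prefixed string or NCBI columns."""
    if dialect == "gtdb_string":
        tokens = []
        if lineage.domain is not None:
            tokens.append(f"d__{lineage.domain}")
        for prefix, rank in (("p", Rank.PHYLUM), ("c", Rank.CLASS),
                             ("o", Rank.ORDER), ("f", Rank.FAMILY),
                             ("g", Rank.GENUS), ("s", Rank.SPECIES)):
            tokens.append(f"{prefix}__{lineage.get(rank) or ''}")
        return ";".join(tokens)
    if dialect == "ncbi_columns":
        return "\t".join(lineage.get(Rank(d)) or "" for d in range(len(Rank)))
    raise ConfigurationError(f"unknown lineage dialect: {dialect!r}")


def lowest_shared_rank(a: Lineage, b: Lineage) -> Rank | None:
    """Deepest rank at which two lineages carry the same taxon name.

    The walk starts at the shallowest mutually assigned rank and descends
    while names agree; returns ``None`` if the lineages disagree already at
    the shallowest mutually assigned rank (or share no assigned rank at all).
    """
    shared = sorted(set(a.names) & set(b.names))
    deepest: Rank | None = None
    for rank in shared:
        if a.names[rank] == b.names[rank]:
            deepest = rank
        else:
            break
    return deepest


@dataclass
class TaxonomyTable:
    """Mapping of genome identifiers to lineages."""

    records: dict[str, Lineage] = field(default_factory=dict)

    def __getitem__(self, genome_id: str) -> Lineage:
        return self.records[genome_id]

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self.records

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, genome_id: str, default: Lineage | None = None) -> Lineage | None:
        return self.records.get(genome_id, default)

    def items(self):
        return self.records.items()

    @classmethod
    def read_tsv(cls, handle: IO[str] | str) -> "TaxonomyTable":
        """Read a taxonomy TSV.

        Two layouts are accepted (header required): ``genome_id<TAB>lineage``
        with GTDB-style strings, or ``genome_id`` plus seven named rank
        columns (superphylum..species).
        """
        close = False
        if isinstance(handle, str):
            handle = open(handle)
            close = True
        try:
            header = handle.readline().rstrip("\n").split("\t")
            if not header or header[0].strip().lower() != "genome_id":
                raise ParseError("taxonomy TSV must start with a 'genome_id' column", line=1)
            cols = [c.strip().lower() for c in header[1:]]
            records: dict[str, Lineage] = {}
            if cols == ["lineage"]:
                for lineno, line in enumerate(handle, start=2):
                    if not line.strip():
                        continue
                    parts = line.rstrip("\n").split("\t")
                    if len(parts) < 2:
                        raise ParseError("expected genome_id and lineage", line=lineno)
                    records[parts[0]] = parse_lineage(parts[1], "gtdb_string")
            else:
                try:
                    rank_order = [Rank.from_label(c) for c in cols]
                except ConfigurationError as exc:
                    raise ParseError(f"bad taxonomy header: {exc}", line=1) from None
                for lineno, line in enumerate(handle, start=2):
                    if not line.strip():
                        continue
                    parts = line.rstrip("\n").split("\t")
                    row = {}
                    for rank, value in zip(rank_order, parts[1:]):
                        if value.strip():
                            row[rank] = value.strip()
                    ordered = "\t".join(row.get(Rank(d), "") for d in range(len(Rank)))
                    records[parts[0]] = parse_lineage(ordered, "ncbi_columns")
            if len(records) == 0:
                raise ParseError("taxonomy TSV has no data rows")
            return cls(records)
        finally:
            if close:
                handle.close()

    def to_tsv(self, handle: IO[str]) -> None:
        handle.write("genome_id\tlineage\n")
        for genome_id, lineage in self.records.items():
            handle.write(f"{genome_id}\t{format_lineage(lineage)}\n")

    def subset(self, genome_ids: Iterable[str]) -> "TaxonomyTable":
        return TaxonomyTable({g: self.records[g] for g in genome_ids})
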