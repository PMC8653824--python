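"""Marker-ortholog screening from HMMER search output.

Turns ``hmmsearch --domtblout`` tables into per-genome marker hit sets:
bit-score filtering against per-marker cutoffs (e.g. 580 for the aCPSF1
model TIGR03675, or 768/516/172 for the McrA/B/G models), one-representative
selection per genome, copy-number auditing and marker-coverage statistics.

Filtering uses the full-sequence bit score, the statistic TIGRFAM trusted
cutoffs are defined on, and cutoffs are inclusive (score >= threshold keeps
the hit). Reported percentages are rounded half-up to reproduce the
conventional one-decimal presentation (95.4%, 2.9%, 78%).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import IO, Iterable, Mapping, Sequence

from .errors import ConfigurationError, ConsistencyError, ParseError
from .taxonomy import Rank, TaxonomyTable

#: Suggested full-sequence bit-score cutoffs for the shipped marker models.
DEFAULT_CUTOFFS: dict[str, float] = {
    "TIGR03675": 580.0,  # aCPSF1 (beta-CASP ribonuclease)
    "TIGR03256": 768.0,  # McrA
    "TIGR03257": 516.0,  # McrB
    "TIGR03259": 172.0,  # McrG
}

# minimum whitespace-separated fields in a domtblout data row
_DOMTBL_MIN_FIELDS = 22


@dataclass(frozen=True)
class MarkerHit:
    """One (protein, marker) hit surviving per-domain collapsing."""

    genome_id: str
    protein_id: str
    marker_id: str
    full_seq_bitscore: float
    full_seq_evalue: float
    ali_from: int
    ali_to: int
    target_len: int

    def __post_init__(self):
        if not (1 <= self.ali_from <= self.ali_to <= self.target_len):
            raise ConfigurationError(
                f"bad alignment coordinates for {self.protein_id}: "
                f"{self.ali_from}-{self.ali_to} (len {self.target_len})"
            )


@dataclass
class ScreenConfig:
    """Per-marker minimum full-sequence bit scores."""

    thresholds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))

    def __post_init__(self):
        for marker, cutoff in self.thresholds.items():
            if not cutoff > 0:
                raise ConfigurationError(f"cutoff for {marker} must be positive")

    def threshold_for(self, marker_id: str) -> float:
        try:
            return self.thresholds[marker_id]
        except KeyError:
            raise ConfigurationError(
                f"no bit-score threshold configured for marker {marker_id!r}"
            ) from None


@dataclass
class DomtbloutResult:
    hits: list[MarkerHit]
    orphans: list[str]  # protein ids that could not be mapped to a genome

    def __iter__(self):
        return iter(self.hits)

    def __len__(self):
        return len(self.hits)


def parse_domtblout(
    stream: IO[str] | Iterable[str],
    *,
    genome_map: Mapping[str, str] | None = None,
    id_split: str | None = None,
) -> DomtbloutResult:
    """Parse HMMER3 ``--domtblout`` text into collapsed marker hits.

    Rows are whitespace-delimited; ``#`` lines are comments. Multiple domain
    rows for the same (protein, marker) pair collapse to the single row with
    the highest full-sequence bit score.

    The genome for each protein comes from ``genome_map`` (protein_id ->
    genome_id) or, failing that, from splitting the protein id on
    ``id_split`` and taking the first field. Proteins mappable by neither
    rule are collected as orphans rather than failing the parse.
    """
    best: dict[tuple[str, str], MarkerHit] = {}
    orphan_ids: list[str] = []
    seen_orphans: set[str] = set()
    for lineno, line in enumerate(stream, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split()
        if len(fields) < _DOMTBL_MIN_FIELDS:
            raise ParseError(
                f"domtblout row has {len(fields)} fields, "
                f"expected >= {_DOMTBL_MIN_FIELDS}",
                line=lineno,
            )
        protein_id = fields[0]
        marker_id = fields[3]
        try:
            target_len = int(fields[2])
            evalue = float(fields[6])
            score = float(fields[7])
            ali_from = int(fields[17])
            ali_to = int(fields[18])
        except ValueError as exc:
            raise ParseError(f"bad numeric field: {exc}", line=lineno) from None

        genome_id = None
        if genome_map is not None and protein_id in genome_map:
            genome_id = genome_map[protein_id]
        elif id_split is not None and id_split in protein_id:
            genome_id = protein_id.split(id_split, 1)[0]
        if genome_id is None:
            if protein_id not in seen_orphans:
                seen_orphans.add(protein_id)
                orphan_ids.append(protein_id)
            continue

        hit = MarkerHit(
            genome_id=genome_id,
            protein_id=protein_id,
            marker_id=marker_id,
            full_seq_bitscore=score,
            full_seq_evalue=evalue,
            ali_from=ali_from,
            ali_to=ali_to,
            target_len=target_len,
        )
        key = (protein_id, marker_id)
        if key not in best or score > best[key].full_seq_bitscore:
            best[key] = hit
    return DomtbloutResult(hits=list(best.values()), orphans=orphan_ids)


def filter_hits(hits: Sequence[MarkerHit], config: ScreenConfig) -> list[MarkerHit]:
    """Keep hits whose full-sequence bit score meets the marker's cutoff.

    Cutoffs are inclusive; input order is preserved.
    """
    return [h for h in hits if h.full_seq_bitscore >= config.threshold_for(h.marker_id)]


def select_representative(hits: Sequence[MarkerHit]) -> dict[str, str]:
    """One representative protein per genome: highest bit score, ties broken
    by lexicographically smallest protein id."""
    by_genome: dict[str, MarkerHit] = {}
    for hit in hits:
        cur = by_genome.get(hit.genome_id)
        if (
            cur is None
            or hit.full_seq_bitscore > cur.full_seq_bitscore
            or (
                hit.full_seq_bitscore == cur.full_seq_bitscore
                and hit.protein_id < cur.protein_id
            )
        ):
            by_genome[hit.genome_id] = hit
    return {g: h.protein_id for g, h in sorted(by_genome.items())}


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal round-half-up (the rounding behind printed percentages)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def format_pct(value: float, decimals: int = 1) -> str:
    """Round half-up and trim a trailing '.0' (95.36 -> '95.4', 78.0 -> '78')."""
    rounded = round_half_up(value, decimals)
    text = f"{rounded:.{decimals}f}"
    if "." in text:
        text = text.rstrip("0").rstrip(".")
    return text


@dataclass
class CopyNumberReport:
    """Per-genome marker copy counts with an overall and per-group summary.

    Percentages are over genomes carrying at least one copy, rounded
    half-up to one decimal. ``per_group`` shares keep that same denominator
    so group multi-copy fractions read as shares of all marker-positive
    genomes.
    """

    per_genome: dict[str, int]
    n_genomes: int
    n_single: int
    n_double: int
    n_three_plus: int
    pct_single: float
    pct_double: float
    pct_three_plus: float
    per_group: dict[str, dict[str, float]]

    @property
    def n_multi(self) -> int:
        return self.n_double + self.n_three_plus

    @property
    def pct_multi(self) -> float:
        return round_half_up(100.0 * self.n_multi / self.n_genomes, 1)


def copy_number_audit(
    hits: Sequence[MarkerHit],
    taxonomy: TaxonomyTable | None = None,
    group_rank: Rank = Rank.CLASS,
) -> CopyNumberReport:
    """Count marker copies per genome and summarize single/multi-copy shares.

    Copies are distinct protein ids per genome (hits are expected to be
    pre-filtered). When a taxonomy is supplied, genomes are additionally
    grouped by their taxon name at ``group_rank``; genomes missing from the
    taxonomy, or unassigned at that rank, group under ``"unclassified"``.
    """
    proteins: dict[str, set[str]] = defaultdict(set)
    for hit in hits:
        proteins[hit.genome_id].add(hit.protein_id)
    per_genome = {g: len(ps) for g, ps in sorted(proteins.items())}
    n = len(per_genome)
    n_single = sum(1 for c in per_genome.values() if c == 1)
    n_double = sum(1 for c in per_genome.values() if c == 2)
    n_three = sum(1 for c in per_genome.values() if c >= 3)

    per_group: dict[str, dict[str, float]] = {}
    if n:
        groups: dict[str, list[int]] = defaultdict(list)
        for genome_id, count in per_genome.items():
            label = "unclassified"
            if taxonomy is not None:
                lineage = taxonomy.get(genome_id)
                if lineage is not None and lineage.get(group_rank):
                    label = lineage.get(group_rank)
            groups[label].append(count)
        for label, counts in sorted(groups.items()):
            n_multi = sum(1 for c in counts if c >= 2)
            per_group[label] = {
                "n_genomes": len(counts),
                "n_multi": n_multi,
                "pct_of_total": round_half_up(100.0 * len(counts) / n, 1),
                "pct_multi_of_total": round_half_up(100.0 * n_multi / n, 1),
            }

    return CopyNumberReport(
        per_genome=per_genome,
        n_genomes=n,
        n_single=n_single,
        n_double=n_double,
        n_three_plus=n_three,
        pct_single=round_half_up(100.0 * n_single / n, 1) if n else 0.0,
        pct_double=round_half_up(100.0 * n_double / n, 1) if n else 0.0,
        pct_three_plus=round_half_up(100.0 * n_three / n, 1) if n else 0.0,
        per_group=per_group,
    )


@dataclass(frozen=True)
class CoverageReport:
    n_total: int
    n_with_marker: int
    pct: float  # rounded half-up at the requested precision

    @property
    def fraction(self) -> float:
        return self.n_with_marker / self.n_total


def coverage_report(
    all_genome_ids: Iterable[str],
    hits: Sequence[MarkerHit] | Iterable[str],
    decimals: int = 0,
) -> CoverageReport:
    """Fraction of the genome universe carrying at least one marker hit.

    ``hits`` may be MarkerHit records or bare genome ids. Every hit genome
    must belong to the universe.
    """
    universe = set(all_genome_ids)
    with_marker = set()
    for item in hits:
        with_marker.add(item.genome_id if isinstance(item, MarkerHit) else item)
    stray = with_marker - universe
    if stray:
        raise ConsistencyError(
            f"{len(stray)} hit genome(s) absent from the genome universe, "
            f"e.g. {sorted(stray)[:5]}"
        )
    if not universe:
        raise ConfigurationError("empty genome universe")
    pct = round_half_up(100.0 * len(with_marker) / len(universe), decimals)
    return CoverageReport(n_total=len(universe), n_with_marker=len(with_marker), pct=pct)


def write_hits_tsv(hits: Sequence[MarkerHit], handle: IO[str]) -> None:
    handle.write(
        "genome_id\tprotein_id\tmarker_id\tbitscore\tevalue\tali_from\tali_to\ttarget_len\n"
    )
    for h in hits:
        handle.write(
            f"{h.genome_id}\t{h.protein_id}\t{h.marker_id}\t{h.full_seq_bitscore:g}\t"
            f"{h.full_seq_evalue:g}\t{h.ali_from}\t{h.ali_to}\t{h.target_len}\n"
        )
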