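"""Rank normalization: bucket pair identities by shared rank, derive thresholds.

Every unordered pair of reference sequences is assigned to the bucket of its
most specific shared rank (same genus but different species -> genus bucket),
for the six ranks phylum..species. Pairs agreeing at no rank at or below
phylum — different phyla, or lineages too shallow to decide — are discarded
and counted. The per-rank medians of the bucketed identities are the rank
normalization values; a valid threshold table is strictly increasing with
rank depth.

The shipped default table carries the published aCPSF1 normalization medians
(species 95.7, genus 87.4, family 84.9, order 84.1, class 52.9, phylum 43.2),
derived from 779 reference proteins spanning all archaeal phyla; they are
not recomputable from toolkit-internal data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import IO, Mapping

import numpy as np

from .errors import ConfigurationError, ConsistencyError
from .identity import IdentityMatrix
from .taxonomy import Rank, TaxonomyTable, lowest_shared_rank, THRESHOLD_RANKS

#: Published aCPSF1 per-rank identity medians (percent).
ACPSF1_THRESHOLDS: dict[Rank, float] = {
    Rank.SPECIES: 95.7,
    Rank.GENUS: 87.4,
    Rank.FAMILY: 84.9,
    Rank.ORDER: 84.1,
    Rank.CLASS: 52.9,
    Rank.PHYLUM: 43.2,
}


@dataclass
class RankBuckets:
    """Pair identities bucketed by most specific shared rank."""

    per_rank: dict[Rank, list[tuple[str, str, float]]]
    n_discarded: int = 0

    def sizes(self) -> dict[Rank, int]:
        return {r: len(v) for r, v in self.per_rank.items()}

    def to_long_table(self):
        """Long-format rows (rank, id_a, id_b, identity), box-plot ready."""
        import pandas as pd

        rows = [
            (rank.label, a, b, ident)
            for rank in THRESHOLD_RANKS
            for a, b, ident in self.per_rank.get(rank, [])
        ]
        return pd.DataFrame(rows, columns=["rank", "id_a", "id_b", "identity"])


def bucket_pairs(
    matrix: IdentityMatrix,
    taxonomy: TaxonomyTable,
    pool_deeper: bool = False,
) -> RankBuckets:
    """Assign each unordered pair to the bucket of its most specific shared rank.

    Pairs sharing nothing at or below phylum (different phyla, disagreement at
    the shallowest mutually assigned rank, or superphylum-only agreement) are
    counted in ``n_discarded``, as are pairs with missing identity cells.
    With ``pool_deeper`` the rank-R bucket additionally contains every pair
    from all deeper buckets (a sensitivity option; buckets then overlap).
    """
    missing = [sid for sid in matrix.ids if sid not in taxonomy]
    if missing:
        raise ConsistencyError(
            f"{len(missing)} matrix id(s) missing from taxonomy: {missing[:10]}"
        )
    per_rank: dict[Rank, list[tuple[str, str, float]]] = {
        r: [] for r in THRESHOLD_RANKS
    }
    n_discarded = 0
    ids = matrix.ids
    for a_idx in range(len(ids)):
        for b_idx in range(a_idx + 1, len(ids)):
            a, b = ids[a_idx], ids[b_idx]
            shared = lowest_shared_rank(taxonomy[a], taxonomy[b])
            if shared is None or shared == Rank.SUPERPHYLUM:
                n_discarded += 1
                continue
            ident = matrix.values[a_idx, b_idx]
            if np.isnan(ident):
                n_discarded += 1
                continue
            per_rank[shared].append((a, b, float(ident)))
    if pool_deeper:
        pooled: dict[Rank, list[tuple[str, str, float]]] = {}
        for rank in THRESHOLD_RANKS:
            pooled[rank] = [
                p for r in THRESHOLD_RANKS if r >= rank for p in per_rank[r]
            ]
        per_rank = pooled
    return RankBuckets(per_rank=per_rank, n_discarded=n_discarded)


def rank_medians(buckets: RankBuckets) -> dict[Rank, float]:
    """Median identity per non-empty bucket (even count -> mean of the two
    central values); empty buckets are absent, with a warning."""
    medians: dict[Rank, float] = {}
    for rank in THRESHOLD_RANKS:
        values = [ident for _, _, ident in buckets.per_rank.get(rank, [])]
        if not values:
            warnings.warn(f"no pairs in {rank.label} bucket; median absent",
                          stacklevel=2)
            continue
        medians[rank] = float(np.median(values))
    return medians


@dataclass
class ThresholdTable:
    """Per-rank identity cutoffs (percent), phylum..species."""

    thresholds: dict[Rank, float] = field(
        default_factory=lambda: dict(ACPSF1_THRESHOLDS)
    )
    provenance: str = "paper_default"

    def __post_init__(self):
        self.thresholds = {Rank(r): float(v) for r, v in self.thresholds.items()}
        missing = [r.label for r in THRESHOLD_RANKS if r not in self.thresholds]
        if missing:
            raise ConfigurationError(f"threshold table is missing ranks: {missing}")

    def __getitem__(self, rank: Rank) -> float:
        return self.thresholds[rank]

    def to_tsv(self, handle: IO[str]) -> None:
        handle.write("rank\tidentity_threshold\n")
        for rank in THRESHOLD_RANKS:
            handle.write(f"{rank.label}\t{self.thresholds[rank]:g}\n")

    @classmethod
    def read_tsv(cls, handle: IO[str] | str, provenance: str = "derived"):
        close = isinstance(handle, str)
        fh = open(handle) if close else handle
        try:
            header = fh.readline()
            if not header.lower().startswith("rank"):
                raise ConfigurationError("threshold TSV needs a 'rank' header")
            thresholds = {}
            for line in fh:
                if line.strip():
                    label, value = line.split("\t")[:2]
                    thresholds[Rank.from_label(label)] = float(value)
            return cls(thresholds=thresholds, provenance=provenance)
        finally:
            if close:
                fh.close()


def derive_thresholds(medians: Mapping[Rank, float]) -> ThresholdTable:
    """Promote bucket medians to a threshold table (the median IS the rank's
    normalization value; no interpolation)."""
    missing = [r.label for r in THRESHOLD_RANKS if r not in medians]
    if missing:
        raise ConfigurationError(
            f"cannot derive thresholds, ranks without medians: {missing}; "
            "fall back to the shipped default table if appropriate"
        )
    return ThresholdTable(
        thresholds={r: float(medians[r]) for r in THRESHOLD_RANKS},
        provenance="derived",
    )


def validate_thresholds(table: ThresholdTable) -> list[str]:
    """Empty list iff thresholds strictly increase with rank depth; each
    violation names the offending adjacent rank pair."""
    violations = []
    for shallow, deep in zip(THRESHOLD_RANKS, THRESHOLD_RANKS[1:]):
        if not table[deep] > table[shallow]:
            violations.append(
                f"{deep.label} ({table[deep]:g}) must exceed "
                f"{shallow.label} ({table[shallow]:g})"
            )
    return violations
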