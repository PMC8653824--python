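"""Best-hit taxonomic classification of marker sequences.

A query is aligned against labeled reference sequences; the highest-identity
reference ("the most closely related identified taxon") decides the lineage,
and the identity decides the deepest assignable rank: the deepest rank R
with identity >= threshold(R), thresholds inclusive. Queries below the
phylum threshold stay unassigned. Ties within a small tolerance are kept:
when tied references disagree, the assigned lineage is truncated to their
common part and the result is flagged.

Identity defaults to the self-contained global aligner; a precomputed
query-vs-reference identity table may be supplied instead (mirroring
MSA-derived identities).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import IO, Mapping, Sequence

from .errors import ConfigurationError
from .identity import AlignParams, global_align
from .normalize import ThresholdTable, validate_thresholds
from .taxonomy import (
    Lineage,
    Rank,
    TaxonomyTable,
    lowest_shared_rank,
    THRESHOLD_RANKS,
)

TIE_TOLERANCE = 1e-9


@dataclass
class ClassificationResult:
    query_id: str
    best_ref_ids: list[str]
    identity: float
    assigned_rank: Rank | None
    assigned_lineage: Lineage
    status: str  # assigned | unassigned_below_phylum | conflicted_ties


def best_hit(
    query_seq: str | None,
    references: Mapping[str, str],
    *,
    params: AlignParams | None = None,
    precomputed: Mapping[str, float] | None = None,
    tie_tolerance: float = TIE_TOLERANCE,
) -> tuple[list[str], float]:
    """Highest-identity reference(s) for a query.

    Identities come from ``precomputed`` (reference id -> percent identity)
    when given, otherwise from global alignment of ``query_seq`` against each
    reference. All references within ``tie_tolerance`` of the maximum are
    returned, sorted by id.
    """
    if not references:
        raise ConfigurationError("empty reference set")
    identities: dict[str, float] = {}
    if precomputed is not None:
        identities = {r: float(precomputed[r]) for r in references}
    else:
        if query_seq is None:
            raise ConfigurationError(
                "need a query sequence when identities are not precomputed"
            )
        for ref_id, ref_seq in references.items():
            _, ident, _ = global_align(query_seq, ref_seq, params)
            identities[ref_id] = ident
    top = max(identities.values())
    ties = sorted(r for r, v in identities.items() if top - v <= tie_tolerance)
    return ties, top


def assign_rank(identity: float, table: ThresholdTable) -> Rank | None:
    """Deepest rank whose (inclusive) threshold the identity meets."""
    violations = validate_thresholds(table)
    if violations:
        raise ConfigurationError(
            "refusing to classify with an invalid threshold table: "
            + "; ".join(violations)
        )
    for rank in reversed(THRESHOLD_RANKS):  # species first
        if identity >= table[rank]:
            return rank
    return None


def _common_lineage(lineages: Sequence[Lineage]) -> Lineage:
    common = lineages[0]
    for other in lineages[1:]:
        shared = lowest_shared_rank(common, other)
        if shared is None:
            return Lineage(names={})
        common = common.truncate(shared)
    return common


def classify(
    query_id: str,
    query_seq: str | None,
    references: Mapping[str, str],
    taxonomy: TaxonomyTable,
    table: ThresholdTable | None = None,
    *,
    params: AlignParams | None = None,
    precomputed: Mapping[str, float] | None = None,
    tie_tolerance: float = TIE_TOLERANCE,
) -> ClassificationResult:
    """Classify one query to its lowest supportable rank.

    References without a taxonomy entry are skipped with a warning (error if
    none remain). The assigned lineage is the best reference's lineage
    truncated at the assigned rank; conflicting ties truncate further to the
    tied references' common lineage and flag the result.
    """
    table = table or ThresholdTable()
    labeled = {r: s for r, s in references.items() if r in taxonomy}
    skipped = set(references) - set(labeled)
    if skipped:
        warnings.warn(
            f"{len(skipped)} reference(s) lack lineages and were skipped",
            stacklevel=2,
        )
    if not labeled:
        raise ConfigurationError("no reference has a taxonomy entry")

    ref_ids, identity = best_hit(
        query_seq, labeled, params=params,
        precomputed=precomputed, tie_tolerance=tie_tolerance,
    )
    rank = assign_rank(identity, table)
    if rank is None:
        return ClassificationResult(
            query_id=query_id,
            best_ref_ids=ref_ids,
            identity=identity,
            assigned_rank=None,
            assigned_lineage=Lineage(names={}),
            status="unassigned_below_phylum",
        )
    status = "assigned"
    lineage = taxonomy[ref_ids[0]].truncate(rank)
    if len(ref_ids) > 1:
        common = _common_lineage([taxonomy[r] for r in ref_ids]).truncate(rank)
        deepest = common.deepest_rank
        if deepest is None or deepest < rank:
            status = "conflicted_ties"
        lineage = common
    return ClassificationResult(
        query_id=query_id,
        best_ref_ids=ref_ids,
        identity=identity,
        assigned_rank=rank,
        assigned_lineage=lineage,
        status=status,
    )


def classify_batch(
    queries: Mapping[str, str],
    references: Mapping[str, str],
    taxonomy: TaxonomyTable,
    table: ThresholdTable | None = None,
    *,
    params: AlignParams | None = None,
    precomputed: Mapping[str, Mapping[str, float]] | None = None,
    tie_tolerance: float = TIE_TOLERANCE,
) -> tuple[list[ClassificationResult], dict[str, int]]:
    """Classify queries independently; also tally results per assigned rank.

    ``precomputed``, when given, maps query id -> (reference id -> identity).
    The tally keys are rank labels plus ``"unassigned"``.
    """
    results = []
    for query_id, seq in queries.items():
        pre = precomputed.get(query_id) if precomputed is not None else None
        results.append(
            classify(
                query_id, seq, references, taxonomy, table,
                params=params, precomputed=pre, tie_tolerance=tie_tolerance,
            )
        )
    tally = Counter(
        r.assigned_rank.label if r.assigned_rank is not None else "unassigned"
        for r in results
    )
    ordered = {r.label: tally.get(r.label, 0) for r in reversed(THRESHOLD_RANKS)}
    ordered["unassigned"] = tally.get("unassigned", 0)
    return results, ordered


def genome_call(per_copy_results: Sequence[ClassificationResult]) -> ClassificationResult:
    """Resolve multi-copy genomes: keep the deepest-rank copy result; on
    equal depth with conflicting lineages, truncate to the common lineage and
    flag the conflict."""
    if not per_copy_results:
        raise ConfigurationError("genome_call needs at least one result")
    if len(per_copy_results) == 1:
        return per_copy_results[0]

    def depth(res: ClassificationResult) -> int:
        return -1 if res.assigned_rank is None else int(res.assigned_rank)

    deepest = max(depth(r) for r in per_copy_results)
    candidates = [r for r in per_copy_results if depth(r) == deepest]
    best = max(candidates, key=lambda r: r.identity)
    if len(candidates) == 1 or deepest < 0:
        return best
    common = _common_lineage([r.assigned_lineage for r in candidates])
    if all(r.assigned_lineage.names == common.names for r in candidates):
        return best
    status = best.status
    deepest_common = common.deepest_rank
    if deepest_common is None or deepest_common < best.assigned_rank:
        status = "conflicted_ties"
    return ClassificationResult(
        query_id=best.query_id,
        best_ref_ids=sorted({rid for r in candidates for rid in r.best_ref_ids}),
        identity=best.identity,
        assigned_rank=best.assigned_rank,
        assigned_lineage=common,
        status=status,
    )


def write_results_tsv(results: Sequence[ClassificationResult], handle: IO[str]) -> None:
    handle.write(
        "query_id\tbest_refs\tidentity\tassigned_rank\tassigned_lineage\tstatus\n"
    )
    for r in results:
        rank = r.assigned_rank.label if r.assigned_rank is not None else ""
        handle.write(
            f"{r.query_id}\t{','.join(r.best_ref_ids)}\t{r.identity:.4f}\t"
            f"{rank}\t{r.assigned_lineage}\t{r.status}\n"
        )


class MarkerTaxonomyClassifier:
    """Estimator-style wrapper: fit on labeled references, predict queries.

    Parameters mirror :func:`classify`; when ``thresholds`` is None the
    shipped default table is used, or a table can be derived from a
    reference identity matrix via :func:`marktax.normalize.derive_thresholds`
    and passed in.
    """

    def __init__(
        self,
        thresholds: ThresholdTable | None = None,
        align_params: AlignParams | None = None,
        tie_tolerance: float = TIE_TOLERANCE,
    ):
        self.thresholds = thresholds
        self.align_params = align_params
        self.tie_tolerance = tie_tolerance

    def get_params(self, deep: bool = True) -> dict:
        return {
            "thresholds": self.thresholds,
            "align_params": self.align_params,
            "tie_tolerance": self.tie_tolerance,
        }

    def set_params(self, **params) -> "MarkerTaxonomyClassifier":
        for key, value in params.items():
            if key not in self.get_params():
                raise ConfigurationError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(
        self, references: Mapping[str, str], taxonomy: TaxonomyTable
    ) -> "MarkerTaxonomyClassifier":
        labeled = {r: s for r, s in references.items() if r in taxonomy}
        if not labeled:
            raise ConfigurationError("no reference has a taxonomy entry")
        self.references_ = dict(labeled)
        self.taxonomy_ = taxonomy
        self.thresholds_ = self.thresholds or ThresholdTable()
        return self

    def predict(
        self,
        queries: Mapping[str, str],
        precomputed: Mapping[str, Mapping[str, float]] | None = None,
    ) -> list[ClassificationResult]:
        if not hasattr(self, "references_"):
            raise ConfigurationError("classifier is not fitted")
        results, _ = classify_batch(
            queries, self.references_, self.taxonomy_, self.thresholds_,
            params=self.align_params, precomputed=precomputed,
            tie_tolerance=self.tie_tolerance,
        )
        return results
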