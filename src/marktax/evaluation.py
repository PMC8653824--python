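"""Self-validation experiments on synthetic data.

The central check for a rank-normalized marker taxonomy is parameter
recovery: simulate genomes with known identity strata, re-derive the rank
medians from the simulated identity matrix, and classify held-out query
genomes whose true relationship to the reference set is known by
construction.

Hold-out protocol: for each evaluated rank R, a query genome is classified
against a reference set from which its entire clade at rank R has been
removed (its genome only for species, its species for genus, its genus for
family, and so on). The query's most closely related remaining reference
then shares exactly rank R with it, so the classifier should assign rank R
and the query's own lineage truncated at R. Identities are read from the
precomputed all-vs-all matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classify import classify
from .errors import ConfigurationError
from .identity import identity_matrix
from .normalize import ThresholdTable, bucket_pairs, derive_thresholds, rank_medians
from .simulate import SimConfig, SimTruth, simulate
from .taxonomy import Rank, THRESHOLD_RANKS

#: Balanced design used by the recovery experiment: one phylum, two children
#: per internal level, six genomes per species = 192 genomes, which
#: populates all six rank buckets. The sequence length is set by a power
#: argument rather than marker realism: the narrowest inter-stratum gap
#: (family vs. order, 1 identity point) must span several standard
#: deviations of a pair identity, and that SD is sqrt(c(1-c)/L) * 100 with
#: c the match probability, so L = 2000 keeps the gap above ~4 SD and the
#: best-hit overshoot across adjacent strata negligible.
RECOVERY_DESIGN = dict(
    n_phyla=1,
    classes_per_phylum=2,
    orders_per_class=2,
    families_per_order=2,
    genera_per_family=2,
    species_per_genus=2,
    genomes_per_species=6,
    seq_length=2000,
)

#: Identity strata used for recovery runs (percent).
RECOVERY_TARGETS: dict[Rank, float] = {
    Rank.SPECIES: 96.0,
    Rank.GENUS: 88.0,
    Rank.FAMILY: 85.0,
    Rank.ORDER: 84.0,
    Rank.CLASS: 53.0,
    Rank.PHYLUM: 43.0,
}

#: Held-out queries per evaluated rank (50 in total).
DEFAULT_QUERY_PLAN: dict[Rank, int] = {
    Rank.SPECIES: 12,
    Rank.GENUS: 8,
    Rank.FAMILY: 8,
    Rank.ORDER: 8,
    Rank.CLASS: 7,
    Rank.PHYLUM: 7,
}


@dataclass
class RecoveryResult:
    truth: SimTruth
    medians: dict[Rank, float]
    thresholds: ThresholdTable
    n_queries: int
    n_correct: int
    per_rank_correct: dict[Rank, tuple[int, int]]  # rank -> (correct, total)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_queries

    @property
    def median_errors(self) -> dict[Rank, float]:
        targets = self.truth.config.target_identities
        return {r: self.medians[r] - targets[r] for r in self.medians}


def holdout_queries(
    truth: SimTruth,
    plan: dict[Rank, int],
    rng: np.random.Generator,
) -> list[tuple[str, Rank]]:
    """Pick (query genome, evaluated rank) pairs per the plan.

    Queries for a rank are drawn from distinct clades at that rank where the
    design allows, so the excluded reference clades vary across queries.
    """
    genome_ids = sorted(truth.taxonomy)
    picks: list[tuple[str, Rank]] = []
    for rank, count in plan.items():
        clades: dict[str, list[str]] = {}
        for genome_id in genome_ids:
            key = truth.taxonomy[genome_id].get(rank)
            clades.setdefault(key, []).append(genome_id)
        names = sorted(clades)
        shuffled = [names[i] for i in rng.permutation(len(names))]
        chosen_clades = [shuffled[i % len(shuffled)] for i in range(count)]
        for clade in chosen_clades:
            members = clades[clade]
            picks.append((members[int(rng.integers(len(members)))], rank))
    return picks


def _exclusion_rank(rank: Rank) -> Rank | None:
    """Clade level removed from the references for a rank-R query."""
    if rank is Rank.SPECIES:
        return None  # remove the query genome only
    return Rank(int(rank) + 1)


def rank_recovery_experiment(
    seed: int,
    targets: dict[Rank, float] | None = None,
    plan: dict[Rank, int] | None = None,
    design: dict | None = None,
) -> RecoveryResult:
    """Simulate, re-derive thresholds, classify held-out queries.

    Returns the derived medians (to compare against the configured strata)
    and hold-out classification accuracy overall and per rank.
    """
    config = SimConfig(
        **(design or RECOVERY_DESIGN),
        target_identities=dict(targets or RECOVERY_TARGETS),
        seed=int(seed) % (2**31),
    )
    truth = simulate(config)
    aln = truth.representative_alignment()
    matrix = identity_matrix(aln)
    medians = rank_medians(bucket_pairs(matrix, truth.taxonomy))
    if len(medians) < len(THRESHOLD_RANKS):
        raise ConfigurationError("recovery design left a rank bucket empty")
    thresholds = derive_thresholds(medians)

    rng = np.random.default_rng((int(seed) + 1) % (2**31))
    plan = dict(plan or DEFAULT_QUERY_PLAN)
    queries = holdout_queries(truth, plan, rng)
    index = {g: k for k, g in enumerate(matrix.ids)}
    sequences = {g: truth.proteins[g][next(iter(truth.proteins[g]))]
                 for g in matrix.ids}

    n_correct = 0
    per_rank: dict[Rank, list[int]] = {r: [0, 0] for r in plan}
    for query_id, rank in queries:
        lineage = truth.taxonomy[query_id]
        excl_rank = _exclusion_rank(rank)
        if excl_rank is None:
            excluded = {query_id}
        else:
            clade = lineage.get(excl_rank)
            excluded = {
                g for g in matrix.ids
                if truth.taxonomy[g].get(excl_rank) == clade
            }
        ref_ids = [g for g in matrix.ids if g not in excluded]
        precomputed = {
            r: matrix.values[index[query_id], index[r]] for r in ref_ids
        }
        result = classify(
            query_id,
            None,
            {r: sequences[r] for r in ref_ids},
            truth.taxonomy,
            thresholds,
            precomputed=precomputed,
        )
        expected = lineage.truncate(rank)
        ok = (
            result.assigned_rank == rank
            and result.assigned_lineage.names == expected.names
        )
        per_rank[rank][1] += 1
        if ok:
            per_rank[rank][0] += 1
            n_correct += 1

    return RecoveryResult(
        truth=truth,
        medians=medians,
        thresholds=thresholds,
        n_queries=len(queries),
        n_correct=n_correct,
        per_rank_correct={r: (c, t) for r, (c, t) in per_rank.items()},
    )
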