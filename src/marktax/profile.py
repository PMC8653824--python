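"""Marker-gene community profiling: catalog dedup, abundances, rarefaction.

The profiler consumes tabular read hits (read_id, gene_id, percent identity,
aligned length) produced by an external end-to-end read mapper, assigns each
read to its best gene hit, and aggregates assigned reads into rank-level
relative abundances via the genes' lineages. Rarefaction subsamples reads
without replacement to estimate taxon richness as a function of depth.

Default read filters are 95% nucleotide identity (a within-species proxy in
line with the ~95% ANI species boundary) and 50 bp aligned length; both are
configurable.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError
from .taxonomy import Lineage, Rank, TaxonomyTable

HIT_COLUMNS = ["read_id", "gene_id", "identity", "aligned_len"]

_NUC = set("ACGTN")


@dataclass
class GeneCatalog:
    """Nonredundant gene set: representatives plus the full id mapping."""

    genes: dict[str, tuple[str, str | None]]  # rep id -> (sequence, source genome)
    representative_of: dict[str, str]  # original id -> rep id

    def __len__(self) -> int:
        return len(self.genes)

    def representative(self, gene_id: str) -> str:
        return self.representative_of[gene_id]


def dedup_exact(
    genes: Mapping[str, str],
    sources: Mapping[str, str] | None = None,
) -> GeneCatalog:
    """Collapse byte-identical nucleotide sequences to one representative.

    Matches clustering at 100% identity and 100% coverage; no
    reverse-complement collapsing. The representative of each identical
    group is its lexicographically smallest gene id.
    """
    for gene_id, seq in genes.items():
        bad = set(seq) - _NUC
        if bad or not seq:
            raise ConfigurationError(
                f"gene {gene_id!r} has illegal nucleotide characters: "
                f"{sorted(bad) if bad else 'empty sequence'}"
            )
    groups: dict[str, list[str]] = {}
    for gene_id in sorted(genes):
        groups.setdefault(genes[gene_id], []).append(gene_id)
    catalog: dict[str, tuple[str, str | None]] = {}
    rep_of: dict[str, str] = {}
    for seq, ids in groups.items():
        rep = ids[0]  # sorted insertion -> lexicographically smallest
        catalog[rep] = (seq, sources.get(rep) if sources else None)
        for gene_id in ids:
            rep_of[gene_id] = rep
    return GeneCatalog(genes=catalog, representative_of=rep_of)


def read_hit_tsv(handle: IO[str] | str) -> pd.DataFrame:
    """Load a read-hit table (TSV with the four documented columns)."""
    table = pd.read_csv(handle, sep="\t")
    missing = [c for c in HIT_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"read-hit table is missing columns: {missing}")
    return validate_hits(table[HIT_COLUMNS])


def validate_hits(hits: pd.DataFrame) -> pd.DataFrame:
    if not ((hits["identity"] >= 0) & (hits["identity"] <= 100)).all():
        raise ConfigurationError("hit identities must lie in [0, 100]")
    if not (hits["aligned_len"] >= 1).all():
        raise ConfigurationError("aligned lengths must be >= 1")
    return hits


def sam_to_hits(path: str) -> pd.DataFrame:
    """Convert mapped SAM records to the tabular hit format.

    Identity is computed from the NM tag when present
    (100 * (1 - NM / aligned_length)); records without NM get identity 100
    with a warning. Unmapped records are skipped.
    """
    import pysam

    rows = []
    n_missing_nm = 0
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped:
                continue
            aligned = rec.query_alignment_length
            if not aligned:
                continue
            if rec.has_tag("NM"):
                nm = rec.get_tag("NM")
                ident = 100.0 * max(0.0, 1.0 - nm / aligned)
            else:
                n_missing_nm += 1
                ident = 100.0
            rows.append((rec.query_name, rec.reference_name, ident, aligned))
    if n_missing_nm:
        warnings.warn(
            f"{n_missing_nm} SAM record(s) lack NM tags; identity assumed 100",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


@dataclass
class AbundanceProfile:
    rank: Rank
    abundances: dict[str, float]  # taxon name -> fraction of assigned reads
    n_assigned: int
    n_unassigned: int
    unassigned_genes: dict[str, int] = field(default_factory=dict)

    @property
    def n_reads(self) -> int:
        return self.n_assigned + self.n_unassigned

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.abundances.items(), key=lambda kv: -kv[1]),
            columns=["taxon", "fraction"],
        )


def _best_hit_per_read(hits: pd.DataFrame) -> pd.DataFrame:
    """One row per read: highest identity, then longest alignment, then
    lexicographically smallest gene id."""
    ordered = hits.sort_values(
        ["read_id", "identity", "aligned_len", "gene_id"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates("read_id", keep="first")


def aggregate_abundance(
    hits: pd.DataFrame,
    catalog: GeneCatalog,
    gene_taxonomy: Mapping[str, Lineage] | TaxonomyTable,
    rank: Rank,
    min_identity: float = 95.0,
    min_len: int = 50,
    length_normalize: bool = False,
) -> AbundanceProfile:
    """Aggregate read hits into relative abundances at one rank.

    Gene ids are first mapped through the catalog to representatives. Each
    read contributes its single best hit. Reads failing the identity/length
    filters, or hitting genes without a lineage assigned at ``rank``, count
    as unassigned. With ``length_normalize`` the contribution of each read
    is divided by its gene's length in kb before renormalizing.
    """
    validate_hits(hits)
    unknown = set(hits["gene_id"]) - set(catalog.representative_of)
    if unknown:
        raise ConfigurationError(
            f"{len(unknown)} hit gene id(s) not in catalog, e.g. "
            f"{sorted(unknown)[:5]}"
        )
    if isinstance(gene_taxonomy, TaxonomyTable):
        gene_taxonomy = dict(gene_taxonomy.items())

    work = hits.copy()
    work["gene_id"] = work["gene_id"].map(catalog.representative_of)
    best = _best_hit_per_read(work)
    n_reads = len(best)

    passing = best[(best["identity"] >= min_identity) & (best["aligned_len"] >= min_len)]
    weights: Counter[str] = Counter()
    unassigned_genes: Counter[str] = Counter()
    n_assigned = 0
    for gene_id in passing["gene_id"]:
        lineage = gene_taxonomy.get(gene_id)
        taxon = lineage.get(rank) if lineage is not None else None
        if taxon is None:
            unassigned_genes[gene_id] += 1
            continue
        n_assigned += 1
        if length_normalize:
            weights[taxon] += 1000.0 / len(catalog.genes[gene_id][0])
        else:
            weights[taxon] += 1.0
    total = sum(weights.values())
    abundances = {t: w / total for t, w in weights.items()} if total else {}
    if unassigned_genes:
        warnings.warn(
            f"{sum(unassigned_genes.values())} read(s) hit genes without a "
            f"{rank.label}-level lineage",
            stacklevel=2,
        )
    return AbundanceProfile(
        rank=rank,
        abundances=abundances,
        n_assigned=n_assigned,
        n_unassigned=n_reads - n_assigned,
        unassigned_genes=dict(unassigned_genes),
    )


@dataclass
class RarefactionCurve:
    depths: list[int]
    mean_richness: list[float]
    sd_richness: list[float]
    n_replicates: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth": self.depths,
                "mean_richness": self.mean_richness,
                "sd_richness": self.sd_richness,
            }
        )


def rarefaction(
    read_taxa: Sequence[str],
    depths: Sequence[int],
    n_replicates: int = 100,
    seed: int | None = None,
) -> RarefactionCurve:
    """Mean (and sd) distinct-taxon count in subsamples drawn without
    replacement at each depth. Depths beyond the read count are an error
    (no extrapolation)."""
    labels = np.asarray(read_taxa)
    n = len(labels)
    if n == 0:
        raise ConfigurationError("no reads to rarefy")
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    bad = [d for d in depths if d < 1 or d > n]
    if bad:
        raise ConfigurationError(
            f"depths out of range 1..{n}: {bad} (no extrapolation)"
        )
    # integer-coded labels make np.unique cheap inside the replicate loop
    codes = pd.factorize(labels)[0]
    rng = np.random.default_rng(seed)
    means, sds = [], []
    for depth in depths:
        richness = np.empty(n_replicates)
        for rep in range(n_replicates):
            sample = rng.choice(codes, size=depth, replace=False)
            richness[rep] = len(np.unique(sample))
        means.append(float(richness.mean()))
        sds.append(float(richness.std(ddof=1)) if n_replicates > 1 else 0.0)
    return RarefactionCurve(
        depths=list(depths),
        mean_richness=means,
        sd_richness=sds,
        n_replicates=n_replicates,
    )
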