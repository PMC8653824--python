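"""Synthetic rank-structured data: taxonomies, sequences, hit tables, reads.

The generator emulates the statistical structure a marker-gene taxonomy is
built on: a balanced taxonomic hierarchy in which pairs of genomes diverging
at rank R have a calibrated expected percent identity t_R, strictly
increasing with rank depth (defaults are the shipped aCPSF1 medians).

Calibration uses a depth-block scheme. The sequence is partitioned into
contiguous site blocks, one per rank depth plus a genome-private block. The
ancestor node of a genome at depth R draws the rank-R block uniformly over
the 20 amino-acid letters, and descendants inherit it. Two genomes whose
most specific shared rank is R therefore agree exactly on blocks at depths
<= R and match with probability 1/20 elsewhere, giving expected identity
c_R + (1 - c_R)/20 with c_R the cumulative shared-block fraction. Solving
c_R = (t_R/100 - 1/20) / (1 - 1/20) makes the expectation exactly t_R; the
only calibration error is block-boundary rounding (< 0.2 points at the
default 660-residue length).

This is deliberately not a realistic evolutionary model (no rate
heterogeneity, indels, or empirical substitution preferences); it gives
exact, closed-form control of the identity strata that downstream modules
consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .identity import Alignment
from .normalize import ACPSF1_THRESHOLDS
from .taxonomy import Lineage, Rank, TaxonomyTable, THRESHOLD_RANKS

_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)
_RANDOM_MATCH = 1.0 / 20.0

#: protein id separator encoding the source genome (parse with id_split="~")
PROTEIN_SEP = "~"

_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


@dataclass
class SimConfig:
    """Study design for one synthetic data set.

    Counts give a balanced hierarchy; ``target_identities`` are the expected
    percent identities of genome pairs diverging at each rank (defaults: the
    shipped aCPSF1 medians). ``seq_length`` defaults to 660 aa, the
    approximate length of an aCPSF1 protein.
    """

    n_phyla: int = 2
    classes_per_phylum: int = 2
    orders_per_class: int = 2
    families_per_order: int = 2
    genera_per_family: int = 2
    species_per_genus: int = 2
    genomes_per_species: int = 2
    target_identities: dict[Rank, float] = field(
        default_factory=lambda: dict(ACPSF1_THRESHOLDS)
    )
    seq_length: int = 660
    multi_copy_fraction: float = 0.0
    multi_copy_identity: float = 98.0
    decoy_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        counts = (
            self.n_phyla, self.classes_per_phylum, self.orders_per_class,
            self.families_per_order, self.genera_per_family,
            self.species_per_genus, self.genomes_per_species,
        )
        if any(c < 1 for c in counts):
            raise ConfigurationError("all hierarchy counts must be >= 1")
        if self.seq_length < 50:
            raise ConfigurationError("seq_length must be >= 50")
        for frac_name in ("multi_copy_fraction", "decoy_fraction"):
            frac = getattr(self, frac_name)
            if not (0.0 <= frac < 1.0):
                raise ConfigurationError(f"{frac_name} must lie in [0, 1)")
        missing = [r.label for r in THRESHOLD_RANKS
                   if r not in self.target_identities]
        if missing:
            raise ConfigurationError(f"target identities missing ranks: {missing}")
        last = 100.0 * _RANDOM_MATCH
        for rank in THRESHOLD_RANKS:
            t = self.target_identities[rank]
            if not (last < t <= 100.0):
                raise ConfigurationError(
                    "target identities must be strictly increasing with rank "
                    f"depth and above the {last:g}% random-match floor "
                    f"(violated at {rank.label}={t:g})"
                )
            last = t

    @property
    def n_genomes(self) -> int:
        return (
            self.n_phyla * self.classes_per_phylum * self.orders_per_class
            * self.families_per_order * self.genera_per_family
            * self.species_per_genus * self.genomes_per_species
        )

    def block_boundaries(self) -> dict[Rank, int]:
        """Cumulative site index up to which a rank's blocks extend."""
        bounds: dict[Rank, int] = {}
        prev = 0
        for rank in THRESHOLD_RANKS:
            c = (self.target_identities[rank] / 100.0 - _RANDOM_MATCH) / (
                1.0 - _RANDOM_MATCH
            )
            idx = int(round(c * self.seq_length))
            if idx <= prev:
                raise ConfigurationError(
                    f"targets too close to resolve at seq_length="
                    f"{self.seq_length} (empty {rank.label} block)"
                )
            bounds[rank] = idx
            prev = idx
        if bounds[Rank.SPECIES] > self.seq_length:
            raise ConfigurationError("species target too high for seq_length")
        return bounds


@dataclass
class SimTruth:
    """Ground truth for one simulated data set."""

    config: SimConfig
    taxonomy: TaxonomyTable
    proteins: dict[str, dict[str, str]]  # genome -> protein id -> sequence
    decoys: dict[str, tuple[str, str]]  # decoy protein id -> (genome, sequence)
    root_seq: str

    @property
    def copy_counts(self) -> dict[str, int]:
        return {g: len(ps) for g, ps in self.proteins.items()}

    def representative_alignment(self) -> Alignment:
        """Gap-free alignment of the first protein copy per genome (all
        simulated sequences share one length, so the rows align column-wise)."""
        ids = sorted(self.proteins)
        rows = [self.proteins[g][f"{g}{PROTEIN_SEP}p1"] for g in ids]
        return Alignment(ids, rows)

    def protein_to_genome(self) -> dict[str, str]:
        mapping = {
            pid: g for g, ps in self.proteins.items() for pid in ps
        }
        mapping.update({pid: g for pid, (g, _) in self.decoys.items()})
        return mapping

    def gene_lineages(self) -> dict[str, Lineage]:
        """Lineage per true gene id (gene ids equal protein ids)."""
        return {
            pid: self.taxonomy[g]
            for g, ps in self.proteins.items()
            for pid in ps
        }

    def genes(self) -> dict[str, str]:
        """Reverse-translated nucleotide sequence per true protein."""
        return {
            pid: reverse_translate(seq)
            for ps in self.proteins.values()
            for pid, seq in ps.items()
        }


def reverse_translate(protein: str) -> str:
    """Deterministic reverse translation (one fixed codon per residue)."""
    return "".join(_CODON[aa] for aa in protein)


def simulate_taxonomy(config: SimConfig) -> TaxonomyTable:
    """Balanced taxonomy whose names encode their path (P01-C1-O2-...)."""
    records: dict[str, Lineage] = {}
    for p in range(config.n_phyla):
        p_name = f"P{p + 1:02d}"
        for c in range(config.classes_per_phylum):
            c_name = f"{p_name}-C{c + 1}"
            for o in range(config.orders_per_class):
                o_name = f"{c_name}-O{o + 1}"
                for f in range(config.families_per_order):
                    f_name = f"{o_name}-F{f + 1}"
                    for g in range(config.genera_per_family):
                        g_name = f"{f_name}-G{g + 1}"
                        for s in range(config.species_per_genus):
                            s_name = f"{g_name}-S{s + 1}"
                            lineage = Lineage(
                                names={
                                    Rank.PHYLUM: p_name,
                                    Rank.CLASS: c_name,
                                    Rank.ORDER: o_name,
                                    Rank.FAMILY: f_name,
                                    Rank.GENUS: g_name,
                                    Rank.SPECIES: s_name,
                                },
                                source_dialect="ncbi_columns",
                            )
                            for k in range(config.genomes_per_species):
                                records[f"{s_name}-g{k + 1}"] = lineage
    return TaxonomyTable(records)


def evolve_sequences(taxonomy: TaxonomyTable, config: SimConfig) -> SimTruth:
    """Draw calibrated marker sequences for every genome (see module docs).

    Genomes flagged multi-copy receive a second within-genome copy at
    ``multi_copy_identity`` expected identity; decoys are unrelated uniform
    sequences attached to genomes round-robin.
    """
    rng = np.random.default_rng(config.seed)
    length = config.seq_length
    bounds = config.block_boundaries()
    root = rng.choice(_AA, size=length)

    # node block letters, drawn once per (rank, node name) in sorted order
    genome_ids = sorted(taxonomy)
    node_blocks: dict[tuple[Rank, str], np.ndarray] = {}
    block_spans: dict[Rank, tuple[int, int]] = {}
    prev = 0
    for rank in THRESHOLD_RANKS:
        block_spans[rank] = (prev, bounds[rank])
        prev = bounds[rank]

    proteins: dict[str, dict[str, str]] = {}
    for genome_id in genome_ids:
        lineage = taxonomy[genome_id]
        seq = np.empty(length, dtype=np.uint8)
        for rank in THRESHOLD_RANKS:
            lo, hi = block_spans[rank]
            key = (rank, lineage.get(rank))
            if key not in node_blocks:
                node_blocks[key] = rng.choice(_AA, size=hi - lo)
            seq[lo:hi] = node_blocks[key]
        seq[bounds[Rank.SPECIES]:] = rng.choice(
            _AA, size=length - bounds[Rank.SPECIES]
        )
        proteins[genome_id] = {
            f"{genome_id}{PROTEIN_SEP}p1": seq.tobytes().decode("ascii")
        }

    # second copies: resample enough sites to hit the expected copy identity
    n_multi = int(round(config.multi_copy_fraction * len(genome_ids)))
    if n_multi:
        frac = (1.0 - config.multi_copy_identity / 100.0) / (1.0 - _RANDOM_MATCH)
        n_sites = int(round(frac * length))
        chosen = rng.choice(len(genome_ids), size=n_multi, replace=False)
        for g_idx in sorted(chosen):
            genome_id = genome_ids[g_idx]
            base = np.frombuffer(
                proteins[genome_id][f"{genome_id}{PROTEIN_SEP}p1"].encode(),
                dtype=np.uint8,
            ).copy()
            sites = rng.choice(length, size=n_sites, replace=False)
            base[sites] = rng.choice(_AA, size=n_sites)
            proteins[genome_id][f"{genome_id}{PROTEIN_SEP}p2"] = (
                base.tobytes().decode("ascii")
            )

    decoys: dict[str, tuple[str, str]] = {}
    if config.decoy_fraction > 0:
        n_true = sum(len(ps) for ps in proteins.values())
        n_decoy = int(round(
            config.decoy_fraction * n_true / (1.0 - config.decoy_fraction)
        ))
        for k in range(n_decoy):
            genome_id = genome_ids[k % len(genome_ids)]
            seq = rng.choice(_AA, size=length).tobytes().decode("ascii")
            decoys[f"{genome_id}{PROTEIN_SEP}decoy{k + 1}"] = (genome_id, seq)

    return SimTruth(
        config=config,
        taxonomy=taxonomy,
        proteins=proteins,
        decoys=decoys,
        root_seq=root.tobytes().decode("ascii"),
    )


def simulate(config: SimConfig) -> SimTruth:
    """Convenience: taxonomy + sequences in one call."""
    return evolve_sequences(simulate_taxonomy(config), config)


def _identity_to_root(seq: str, root: str) -> float:
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    b = np.frombuffer(root.encode(), dtype=np.uint8)
    return 100.0 * float((a == b).mean())


def _domtblout_row(protein_id: str, marker_id: str, length: int,
                   score: float) -> str:
    evalue = 10.0 ** (-min(300.0, score / 3.0))
    return (
        f"{protein_id} - {length} {marker_id} - {length} {evalue:.1e} "
        f"{score:.1f} 0.0 1 1 {evalue:.1e} {evalue:.1e} {score:.1f} 0.0 "
        f"1 {length} 1 {length} 1 {length} 0.99 -\n"
    )


def emit_fixtures(
    truth: SimTruth,
    outdir: str | Path,
    marker_id: str = "TIGR03675",
    cutoff: float = 580.0,
) -> dict[str, Path]:
    """Write the fixture files every consuming module reads.

    True orthologs get synthetic bit scores ``cutoff + 2 * identity-to-root``
    (always above the cutoff, increasing with identity to the root
    sequence); decoys score uniformly below the cutoff.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.config.seed + 1)
    paths = {
        "proteins": outdir / "proteins.faa",
        "taxonomy": outdir / "taxonomy.tsv",
        "domtblout": outdir / "hits.domtblout",
        "genes": outdir / "genes.fna",
        "protein_map": outdir / "protein_map.tsv",
    }

    with open(paths["proteins"], "w") as fasta, \
            open(paths["domtblout"], "w") as dom, \
            open(paths["protein_map"], "w") as pmap:
        dom.write("# synthetic hmmsearch --domtblout fixture\n")
        pmap.write("protein_id\tgenome_id\n")
        for genome_id in sorted(truth.proteins):
            for pid, seq in sorted(truth.proteins[genome_id].items()):
                fasta.write(f">{pid}\n{seq}\n")
                pmap.write(f"{pid}\t{genome_id}\n")
                score = cutoff + 2.0 * _identity_to_root(seq, truth.root_seq)
                dom.write(_domtblout_row(pid, marker_id, len(seq), score))
        for pid, (genome_id, seq) in sorted(truth.decoys.items()):
            fasta.write(f">{pid}\n{seq}\n")
            pmap.write(f"{pid}\t{genome_id}\n")
            score = float(rng.uniform(100.0, cutoff - 10.0))
            dom.write(_domtblout_row(pid, marker_id, len(seq), score))

    with open(paths["taxonomy"], "w") as fh:
        truth.taxonomy.to_tsv(fh)
    with open(paths["genes"], "w") as fh:
        for pid, gene in sorted(truth.genes().items()):
            fh.write(f">{pid}\n{gene}\n")
    return paths


def simulate_read_hits(
    truth: SimTruth,
    composition: Mapping[str, float],
    n_reads: int,
    noise: float = 1.0,
    seed: int | None = None,
    rank: Rank = Rank.SPECIES,
) -> pd.DataFrame:
    """Draw a read-hit table from a taxon composition at one rank.

    Reads are multinomial over the composition; each read hits a uniformly
    chosen gene of its taxon with identity ``100 - |N(0, noise)|`` and a
    random aligned length of 80-150 bp.
    """
    fractions = np.array(list(composition.values()), dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ConfigurationError("composition fractions must sum to 1")
    taxa = list(composition)
    genes_by_taxon: dict[str, list[str]] = {t: [] for t in taxa}
    for genome_id, ps in truth.proteins.items():
        taxon = truth.taxonomy[genome_id].get(rank)
        if taxon in genes_by_taxon:
            genes_by_taxon[taxon].extend(sorted(ps))
    empty = [t for t, genes in genes_by_taxon.items() if not genes]
    if empty:
        raise ConfigurationError(f"composition taxa without genes: {empty}")

    rng = np.random.default_rng(seed if seed is not None else truth.config.seed)
    counts = rng.multinomial(n_reads, fractions)
    rows = []
    read_no = 0
    for taxon, count in zip(taxa, counts):
        pool = genes_by_taxon[taxon]
        gene_idx = rng.integers(0, len(pool), size=count)
        idents = np.clip(100.0 - np.abs(rng.normal(0.0, noise, size=count)),
                         0.0, 100.0)
        lengths = rng.integers(80, 151, size=count)
        for k in range(count):
            read_no += 1
            rows.append(
                (f"r{read_no:07d}", pool[gene_idx[k]],
                 float(idents[k]), int(lengths[k]))
            )
    return pd.DataFrame(rows, columns=["read_id", "gene_id", "identity",
                                       "aligned_len"])
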