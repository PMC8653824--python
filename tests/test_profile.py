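"""Gene catalog dedup, read-hit aggregation and rarefaction."""

import math
import random

import numpy as np
import pandas as pd
import pytest

from marktax import (
    Lineage,
    aggregate_abundance,
    dedup_exact,
    rarefaction,
    read_hit_tsv,
)
from marktax.errors import ConfigurationError
from marktax.taxonomy import Rank


def _hits(rows):
    return pd.DataFrame(rows, columns=["read_id", "gene_id", "identity",
                                       "aligned_len"])


def _lineage(species):
    return Lineage(names={Rank.PHYLUM: "P", Rank.CLASS: "C", Rank.ORDER: "O",
                          Rank.FAMILY: "F", Rank.GENUS: "G",
                          Rank.SPECIES: species})


class TestDedupExact:
    def test_identical_sequences_collapse(self):
        catalog = dedup_exact({"g2": "ACGT", "g1": "ACGT"})
        assert len(catalog) == 1
        assert catalog.representative("g2") == "g1"  # lexicographic rep

    def test_single_base_difference_kept(self):
        catalog = dedup_exact({"g1": "ACGT", "g2": "ACGA"})
        assert len(catalog) == 2

    def test_catalog_size_equals_string_set_size(self):
        rng = random.Random(17)
        uniques = ["".join(rng.choice("ACGT") for _ in range(30))
                   for _ in range(70)]
        genes = {}
        k = 0
        for seq in uniques[:60]:
            genes[f"g{k:03d}"] = seq
            k += 1
        for seq in uniques[:10]:  # 10 groups contribute 4 extra copies each
            for _ in range(4):
                genes[f"g{k:03d}"] = seq
                k += 1
        catalog = dedup_exact(genes)
        assert len(genes) == 100
        assert len(catalog) == len(set(genes.values())) == 60
        assert set(catalog.representative_of) == set(genes)

    def test_dedup_is_idempotent(self):
        genes = {"a": "ACGT", "b": "ACGT", "c": "TTTT"}
        catalog = dedup_exact(genes)
        again = dedup_exact({r: s for r, (s, _) in catalog.genes.items()})
        assert set(again.genes) == set(catalog.genes)

    def test_illegal_nucleotide(self):
        with pytest.raises(ConfigurationError, match="illegal"):
            dedup_exact({"g1": "ACGU"})


class TestAggregateAbundance:
    def test_single_taxon_gets_everything(self):
        catalog = dedup_exact({"gene1": "ACGT"})
        hits = _hits([(f"r{k}", "gene1", 99.0, 100) for k in range(10)])
        profile = aggregate_abundance(hits, catalog, {"gene1": _lineage("sp1")},
                                      Rank.SPECIES)
        assert profile.abundances == {"sp1": 1.0}
        assert profile.n_assigned == 10 and profile.n_unassigned == 0

    def test_six_four_split(self):
        catalog = dedup_exact({"gA": "ACGT", "gB": "TTTT"})
        rows = [(f"r{k}", "gA", 99.0, 100) for k in range(6)]
        rows += [(f"r{k + 6}", "gB", 99.0, 100) for k in range(4)]
        profile = aggregate_abundance(
            _hits(rows), catalog,
            {"gA": _lineage("A"), "gB": _lineage("B")}, Rank.SPECIES,
        )
        assert profile.abundances == {"A": 0.6, "B": 0.4}

    def test_per_read_winner_matches_brute_force(self):
        rng = random.Random(23)
        genes = {f"g{k}": "".join(rng.choice("ACGT") for _ in range(20))
                 for k in range(5)}
        catalog = dedup_exact(genes)
        taxonomy = {g: _lineage(f"sp_{g}") for g in genes}
        rows = []
        for k in range(20):  # multi-hit reads with crafted identities
            read = f"r{k:02d}"
            for g in rng.sample(sorted(genes), rng.randint(1, 4)):
                rows.append((read, g, rng.choice([96.0, 97.0, 98.0]),
                             rng.choice([60, 80, 100])))
        hits = _hits(rows)
        profile = aggregate_abundance(hits, catalog, taxonomy, Rank.SPECIES)
        # brute-force winner per read: identity desc, length desc, id asc
        winners = {}
        for row in rows:
            read = row[0]
            cur = winners.get(read)
            cand = (-row[2], -row[3], row[1])
            if cur is None or cand < cur:
                winners[read] = cand
        expected = {}
        for read, (_, _, gene) in winners.items():
            taxon = f"sp_{gene}"
            expected[taxon] = expected.get(taxon, 0) + 1
        total = sum(expected.values())
        expected = {t: c / total for t, c in expected.items()}
        assert profile.abundances == pytest.approx(expected)
        assert profile.n_assigned == len(winners)

    def test_filters_send_reads_to_unassigned(self):
        catalog = dedup_exact({"gA": "ACGT"})
        rows = [("r1", "gA", 99.0, 100), ("r2", "gA", 90.0, 100),
                ("r3", "gA", 99.0, 30)]
        profile = aggregate_abundance(_hits(rows), catalog,
                                      {"gA": _lineage("A")}, Rank.SPECIES,
                                      min_identity=95.0, min_len=50)
        assert profile.n_assigned == 1 and profile.n_unassigned == 2

    def test_gene_without_taxonomy_warns_and_unassigns(self):
        catalog = dedup_exact({"gA": "ACGT", "gB": "TTTT"})
        rows = [("r1", "gA", 99.0, 100), ("r2", "gB", 99.0, 100)]
        with pytest.warns(UserWarning, match="without"):
            profile = aggregate_abundance(_hits(rows), catalog,
                                          {"gA": _lineage("A")}, Rank.SPECIES)
        assert profile.abundances == {"A": 1.0}
        assert profile.n_unassigned == 1

    def test_invariant_to_read_order_and_duplicate_relabeling(self):
        catalog = dedup_exact({"gA": "ACGT", "gA2": "ACGT", "gB": "TTTT"})
        taxonomy = {"gA": _lineage("A"), "gB": _lineage("B")}
        rows = [("r1", "gA", 99.0, 100), ("r2", "gA2", 99.0, 100),
                ("r3", "gB", 99.0, 100)]
        forward = aggregate_abundance(_hits(rows), catalog, taxonomy,
                                      Rank.SPECIES)
        backward = aggregate_abundance(_hits(rows[::-1]), catalog, taxonomy,
                                       Rank.SPECIES)
        assert forward.abundances == backward.abundances
        # duplicate gene gA2 resolved through its representative gA
        assert forward.abundances["A"] == pytest.approx(2 / 3)

    def test_round_trip_through_tsv(self, tmp_path):
        rows = [("r1", "gA", 99.0, 100)]
        path = tmp_path / "hits.tsv"
        _hits(rows).to_csv(path, sep="\t", index=False)
        assert read_hit_tsv(str(path)).shape == (1, 4)


def expected_richness(counts, depth):
    """Closed-form hypergeometric expectation of distinct taxa at a depth."""
    total = sum(counts)
    return len(counts) - sum(
        math.comb(total - c, depth) / math.comb(total, depth) for c in counts
    )


def richness_variance(counts, depth):
    """Exact variance of the distinct-taxon count via absence probabilities."""
    total = sum(counts)

    def absent(*group):
        remaining = total - sum(group)
        if remaining < depth:
            return 0.0
        return math.comb(remaining, depth) / math.comb(total, depth)

    mean_sq = 0.0
    for i, ci in enumerate(counts):
        mean_sq += 1 - absent(ci)
        for cj in counts[i + 1:]:
            both = 1 - absent(ci) - absent(cj) + absent(ci, cj)
            mean_sq += 2 * both
    return mean_sq - expected_richness(counts, depth) ** 2


class TestRarefaction:
    LABELS = (["t1"] * 40 + ["t2"] * 30 + ["t3"] * 15 + ["t4"] * 10
              + ["t5"] * 5)

    def test_full_depth_is_exact(self):
        curve = rarefaction(self.LABELS, [len(self.LABELS)], n_replicates=10,
                            seed=0)
        assert curve.mean_richness == [5.0]
        assert curve.sd_richness == [0.0]

    def test_depth_one(self):
        curve = rarefaction(self.LABELS, [1], n_replicates=200, seed=0)
        assert curve.mean_richness == [1.0]

    def test_means_match_hypergeometric_expectation(self):
        counts = [40, 30, 15, 10, 5]
        depths = [5, 10, 25, 50, 75]
        curve = rarefaction(self.LABELS, depths, n_replicates=400, seed=1)
        for depth, mean, sd in zip(curve.depths, curve.mean_richness,
                                   curve.sd_richness):
            # guard against a degenerate sample sd near saturation with the
            # exact standard error from the closed-form variance
            se = max(sd, math.sqrt(max(richness_variance(counts, depth), 0.0))
                     ) / math.sqrt(curve.n_replicates)
            assert abs(mean - expected_richness(counts, depth)) <= 3 * se

    def test_mean_nondecreasing_in_depth(self):
        depths = [1, 10, 30, 60, 100]
        curve = rarefaction(self.LABELS, depths, n_replicates=300, seed=2)
        for a, b in zip(curve.mean_richness, curve.mean_richness[1:]):
            assert b >= a - 0.15  # Monte-Carlo slack

    def test_depth_beyond_reads_is_an_error(self):
        with pytest.raises(ConfigurationError, match="no extrapolation"):
            rarefaction(self.LABELS, [101], seed=0)

    def test_seed_reproducibility(self):
        a = rarefaction(self.LABELS, [20, 40], n_replicates=50, seed=7)
        b = rarefaction(self.LABELS, [20, 40], n_replicates=50, seed=7)
        assert a.mean_richness == b.mean_richness
        assert a.sd_richness == b.sd_richness
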