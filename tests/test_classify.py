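"""Best-hit classification to the lowest supportable rank."""

import pytest

from marktax import (
    Lineage,
    MarkerTaxonomyClassifier,
    TaxonomyTable,
    ThresholdTable,
    assign_rank,
    best_hit,
    classify,
    classify_batch,
    genome_call,
)
from marktax.classify import ClassificationResult
from marktax.errors import ConfigurationError
from marktax.taxonomy import Rank

TABLE = ThresholdTable()  # shipped aCPSF1 thresholds


class TestAssignRank:
    @pytest.mark.parametrize(
        "identity,expected",
        [
            (96.0, Rank.SPECIES),
            (90.0, Rank.GENUS),   # 87.4 <= 90 < 95.7
            (85.0, Rank.FAMILY),
            (84.5, Rank.ORDER),
            (60.0, Rank.CLASS),   # 52.9 <= 60 < 84.1
            (43.2, Rank.PHYLUM),  # boundary inclusive
            (43.1, None),
        ],
    )
    def test_published_threshold_mapping(self, identity, expected):
        assert assign_rank(identity, TABLE) == expected

    def test_monotone_in_identity(self):
        previous = -1
        for identity in [x / 2 for x in range(0, 201)]:
            rank = assign_rank(identity, TABLE)
            depth = -1 if rank is None else int(rank)
            assert depth >= previous
            previous = depth

    def test_invalid_table_refuses(self):
        bad = dict(TABLE.thresholds)
        bad[Rank.SPECIES] = 10.0
        with pytest.raises(ConfigurationError, match="invalid threshold"):
            assign_rank(96.0, ThresholdTable(bad))


class TestBestHit:
    def test_identical_reference_wins_at_100(self):
        refs = {"r1": "MKVLAT", "r2": "MKVLAW"}
        ids, identity = best_hit("MKVLAT", refs)
        assert ids == ["r1"] and identity == 100.0

    def test_precomputed_identities(self):
        ids, identity = best_hit(None, {"r1": "", "r2": ""},
                                 precomputed={"r1": 92.0, "r2": 96.5})
        assert ids == ["r2"] and identity == 96.5

    def test_ties_within_tolerance_all_returned(self):
        ids, identity = best_hit(None, {"r1": "", "r2": "", "r3": ""},
                                 precomputed={"r1": 93.0, "r2": 93.0,
                                              "r3": 80.0})
        assert ids == ["r1", "r2"] and identity == 93.0

    def test_empty_reference_set(self):
        with pytest.raises(ConfigurationError):
            best_hit("MKV", {})


def _lineage(phylum="P", cls="C", order="O", family="F", genus=None,
             species=None):
    names = {Rank.PHYLUM: phylum, Rank.CLASS: cls, Rank.ORDER: order,
             Rank.FAMILY: family}
    if genus:
        names[Rank.GENUS] = genus
    if species:
        names[Rank.SPECIES] = species
    return Lineage(names={r: n for r, n in names.items() if n})


@pytest.fixture()
def reference_world():
    taxonomy = TaxonomyTable({
        "r1": _lineage(genus="G1", species="G1 s1"),
        "r2": _lineage(genus="G1", species="G1 s2"),
        "r3": _lineage(genus="G2", species="G2 s1"),
    })
    refs = {"r1": "", "r2": "", "r3": ""}
    return refs, taxonomy


class TestClassify:
    def test_species_level_assignment(self, reference_world):
        refs, taxonomy = reference_world
        result = classify("q", None, refs, taxonomy, TABLE,
                          precomputed={"r1": 97.0, "r2": 90.0, "r3": 60.0})
        assert result.assigned_rank == Rank.SPECIES
        assert result.assigned_lineage.get(Rank.SPECIES) == "G1 s1"
        assert result.status == "assigned"

    def test_mid_identity_stops_at_class(self, reference_world):
        refs, taxonomy = reference_world
        result = classify("q", None, refs, taxonomy, TABLE,
                          precomputed={"r1": 60.0, "r2": 55.0, "r3": 40.0})
        assert result.assigned_rank == Rank.CLASS
        assert result.assigned_lineage.deepest_rank == Rank.CLASS

    def test_below_phylum_is_unassigned(self, reference_world):
        refs, taxonomy = reference_world
        result = classify("q", None, refs, taxonomy, TABLE,
                          precomputed={"r1": 30.0, "r2": 20.0, "r3": 10.0})
        assert result.status == "unassigned_below_phylum"
        assert result.assigned_rank is None
        assert result.assigned_lineage.empty

    def test_conflicting_ties_truncate_to_common_lineage(self, reference_world):
        refs, taxonomy = reference_world
        # r1 and r3 share only the family; a genus-level identity cannot
        # carry genus information from conflicting ties
        result = classify("q", None, refs, taxonomy, TABLE,
                          precomputed={"r1": 90.0, "r2": 80.0, "r3": 90.0})
        assert result.assigned_rank == Rank.GENUS
        assert result.status == "conflicted_ties"
        assert result.assigned_lineage.deepest_rank == Rank.FAMILY

    def test_concordant_ties_stay_assigned(self, reference_world):
        refs, taxonomy = reference_world
        # r1 and r2 share the genus; a genus-level tie is consistent
        result = classify("q", None, refs, taxonomy, TABLE,
                          precomputed={"r1": 90.0, "r2": 90.0, "r3": 60.0})
        assert result.assigned_rank == Rank.GENUS
        assert result.status == "assigned"
        assert result.assigned_lineage.get(Rank.GENUS) == "G1"

    def test_unlabeled_references_skipped(self, reference_world):
        refs, taxonomy = reference_world
        refs = dict(refs, stranger="")
        with pytest.warns(UserWarning, match="skipped"):
            result = classify("q", None, refs, taxonomy, TABLE,
                              precomputed={"r1": 97.0, "r2": 90.0,
                                           "r3": 60.0, "stranger": 99.0})
        assert result.best_ref_ids == ["r1"]

    def test_all_unlabeled_is_an_error(self):
        with pytest.raises(ConfigurationError):
            with pytest.warns(UserWarning):
                classify("q", None, {"x": ""}, TaxonomyTable({}), TABLE,
                         precomputed={"x": 99.0})


class TestClassifyBatch:
    def test_empty_batch(self, reference_world):
        refs, taxonomy = reference_world
        results, tally = classify_batch({}, refs, taxonomy, TABLE,
                                        precomputed={})
        assert results == []
        assert sum(tally.values()) == 0

    def test_references_self_classify_to_species(self, small_truth):
        """Every reference queried against the full reference set must come
        back with its own species-level lineage at identity 100."""
        from marktax import identity_matrix

        aln = small_truth.representative_alignment()
        matrix = identity_matrix(aln)
        index = {g: k for k, g in enumerate(matrix.ids)}
        refs = {g: "" for g in matrix.ids}
        some = matrix.ids[:12]
        pre = {
            q: {r: matrix.values[index[q], index[r]] for r in matrix.ids}
            for q in some
        }
        results, tally = classify_batch(
            {q: "" for q in some}, refs, small_truth.taxonomy,
            ThresholdTable(), precomputed=pre,
        )
        assert tally["species"] == len(some)
        for res in results:
            assert res.identity == 100.0
            truth = small_truth.taxonomy[res.query_id]
            assert res.assigned_lineage.get(Rank.SPECIES) == \
                truth.get(Rank.SPECIES)

    def test_tally_counts_by_rank(self, reference_world):
        refs, taxonomy = reference_world
        pre = {
            "q1": {"r1": 97.0, "r2": 90.0, "r3": 60.0},
            "q2": {"r1": 90.0, "r2": 85.0, "r3": 60.0},
            "q3": {"r1": 30.0, "r2": 20.0, "r3": 10.0},
        }
        _, tally = classify_batch({q: "" for q in pre}, refs, taxonomy,
                                  TABLE, precomputed=pre)
        assert tally["species"] == 1
        assert tally["genus"] == 1
        assert tally["unassigned"] == 1


def _result(rank, lineage, identity=90.0, status="assigned", query="g"):
    return ClassificationResult(
        query_id=query, best_ref_ids=["r"], identity=identity,
        assigned_rank=rank, assigned_lineage=lineage, status=status,
    )


class TestGenomeCall:
    def test_deepest_rank_wins(self):
        species = _result(Rank.SPECIES, _lineage(genus="G1", species="s"), 97.0)
        genus = _result(Rank.GENUS, _lineage(genus="G1"), 90.0)
        assert genome_call([genus, species]).assigned_rank == Rank.SPECIES

    def test_conflicting_equal_depth_copies_truncate(self):
        a = _result(Rank.GENUS, _lineage(genus="G1"), 90.0)
        b = _result(Rank.GENUS, _lineage(genus="G2"), 89.5)
        call = genome_call([a, b])
        assert call.assigned_rank == Rank.GENUS
        assert call.status == "conflicted_ties"
        assert call.assigned_lineage.deepest_rank == Rank.FAMILY

    def test_single_copy_passthrough(self):
        only = _result(Rank.CLASS, _lineage())
        assert genome_call([only]) is only

    def test_empty_input_is_an_error(self):
        with pytest.raises(ConfigurationError):
            genome_call([])


class TestEstimatorWrapper:
    def test_fit_predict_round_trip(self, reference_world):
        refs, taxonomy = reference_world
        clf = MarkerTaxonomyClassifier().fit(refs, taxonomy)
        results = clf.predict(
            {"q": ""}, precomputed={"q": {"r1": 97.0, "r2": 90.0, "r3": 60.0}}
        )
        assert results[0].assigned_rank == Rank.SPECIES

    def test_params_protocol(self):
        clf = MarkerTaxonomyClassifier()
        params = clf.get_params()
        assert "thresholds" in params
        clf.set_params(tie_tolerance=1e-6)
        assert clf.tie_tolerance == 1e-6
        with pytest.raises(ConfigurationError):
            clf.set_params(nonsense=1)

    def test_predict_requires_fit(self):
        with pytest.raises(ConfigurationError, match="not fitted"):
            MarkerTaxonomyClassifier().predict({"q": "MKV"})
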