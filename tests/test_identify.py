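"""Query identification, diversity summary, family case report."""

import math

import numpy as np
import pytest

from barcotu.cluster import _finalize
from barcotu.distance import DistanceMatrix
from barcotu.identify import (
    family_case_report,
    identify_queries,
    results_frame,
    summarize_diversity,
)
from barcotu.io import BarcodeDataset, BarcodeRecord


def build_matrix(ids, pairs, default=10.0):
    n = len(ids)
    d = np.full((n, n), default)
    np.fill_diagonal(d, 0.0)
    idx = {rid: k for k, rid in enumerate(ids)}
    for (a, b), v in pairs.items():
        d[idx[a], idx[b]] = d[idx[b], idx[a]] = v
    return DistanceMatrix(list(ids), d, np.zeros((n, n), dtype=int))


IDS = ["kb", "km", "q1", "q2", "q3", "q4", "q5"]
QUERIES = ["q1", "q2", "q3", "q4", "q5"]


@pytest.fixture
def scenario():
    refs = [
        BarcodeRecord("kb", "A" * 120, genus="Karenia", species="brevis",
                      strain_id="KB1", source_class="cultured"),
        BarcodeRecord("km", "C" * 120, genus="Karenia", species="mikimotoi",
                      strain_id="KM1", source_class="cultured"),
    ]
    matrix = build_matrix(
        IDS,
        {
            ("kb", "km"): 1.2,
            ("q1", "kb"): 0.1, ("q1", "km"): 1.2,
            ("q2", "kb"): 1.0, ("q2", "km"): 1.2,
            ("q3", "kb"): 0.25,
            ("q4", "kb"): 5.0, ("q4", "km"): 5.0,
            ("q5", "kb"): 1.0, ("q5", "km"): 2.0,
        },
    )
    species = _finalize(
        "species", 0.24,
        [["kb", "q1"], ["km"], ["q2"], ["q3"], ["q4"], ["q5"]],
    )
    genus = _finalize(
        "genus", 1.4,
        [["kb", "km", "q1", "q2", "q5"], ["q3"], ["q4"]],
    )
    return refs, matrix, species, genus


def test_statuses_and_borderline(scenario):
    refs, matrix, species, genus = scenario
    results = identify_queries(
        QUERIES, refs, species, genus, matrix, genus_bounds={"Karenia": 1.4}
    )
    by_q = {r.query_id: r for r in results}
    assert by_q["q1"].status == "species_match"
    assert by_q["q1"].matched_name == "Karenia brevis"
    assert by_q["q1"].nearest_reference == "kb"
    assert by_q["q1"].nearest_pwd == pytest.approx(0.1)

    # within the genus bound of every named member of the genus OTU
    assert by_q["q2"].status == "genus_match"
    assert by_q["q2"].matched_name == "Karenia"

    # shares the genus OTU but exceeds the bound to km -> not binned
    assert by_q["q5"].status == "unidentified"
    assert not by_q["q5"].borderline

    # just above the species cut-off: flagged for scrutiny
    assert by_q["q3"].status == "unidentified"
    assert by_q["q3"].borderline
    assert by_q["q4"].status == "unidentified"
    assert not by_q["q4"].borderline


def test_unidentified_gets_eb_label_from_names(scenario):
    refs, matrix, species, genus = scenario
    q4_otu = species.assignments["q4"]
    results = identify_queries(
        QUERIES, refs, species, genus, matrix, otu_names={q4_otu: "EB1-1"}
    )
    assert {r.query_id: r.matched_name for r in results}["q4"] == "EB1-1"


def test_missing_query_raises(scenario):
    refs, matrix, species, genus = scenario
    with pytest.raises(KeyError, match="ghost"):
        identify_queries(["ghost"], refs, species, genus, matrix)


def test_no_named_references_all_unidentified(scenario):
    _, matrix, species, genus = scenario
    results = identify_queries(QUERIES, [], species, genus, matrix)
    assert all(r.status == "unidentified" for r in results)
    assert all(math.isnan(r.nearest_pwd) for r in results)


def test_results_frame_columns(scenario):
    refs, matrix, species, genus = scenario
    frame = results_frame(identify_queries(QUERIES, refs, species, genus, matrix))
    assert list(frame["query_id"]) == QUERIES
    assert set(frame.columns) >= {"status", "matched_name", "nearest_pwd", "borderline"}


def _env(rid, site="Saanich Inlet"):
    return BarcodeRecord(rid, "G" * 120, source_class="environmental",
                         site=site, season="summer")


def test_summarize_diversity_counts(scenario):
    refs, matrix, species, genus = scenario
    results = identify_queries(
        QUERIES, refs, species, genus, matrix, genus_bounds={"Karenia": 1.4}
    )
    multiplicity = {
        "q1": ["q1", "q1b"],
        "q2": ["q2"],
        "q3": ["q3"],
        "q4": ["q4", "q4b", "q4c"],
        "q5": ["q5"],
    }
    dataset = BarcodeDataset(
        [_env(r) for r in ("q1", "q1b", "q2", "q3", "q5")]
        + [_env(r, site="Gulf of Maine") for r in ("q4", "q4b", "q4c")]
    )
    s = summarize_diversity(results, species, multiplicity, dataset, refs)
    assert s.n_unique == 5
    assert s.n_total == 8
    assert s.n_species_otus == 5
    assert s.n_species_linked == 1
    assert s.n_genus_linked == 1
    # 4 of the 5 environmental species OTUs lack any named reference
    assert s.pct_unknown_species == pytest.approx(80.0)
    assert s.clone_counts == {
        "species_match": 2, "genus_match": 1, "unidentified": 5,
    }
    site = s.breakdowns["site"]
    assert site.loc["Gulf of Maine", "unidentified"] == 3
    assert s.to_dict()["n_unique"] == 5


def test_family_case_report_counts(scenario):
    refs, matrix, species, genus = scenario
    multiplicity = {"q1": ["q1", "q1b"], "q4": ["q4", "q4b", "q4c"]}
    report = family_case_report(
        species, genus, matrix, QUERIES, multiplicity,
        family_members={"kb", "km"}, anchor="kb", family_bound=1.5,
    )
    # q1 (x2), q2, q3, q5 sit within 1.5% of a family reference; q4 does not
    assert report.clones_in_family == 5
    # genus OTU of the anchor holds q1 (x2), q2, q5
    assert report.genus_level_with_anchor == 4
    assert report.species_otus_with_anchor == 3
    # only q1 shares the anchor's species OTU
    assert report.species_level_with_anchor == 2


def test_family_case_anchor_must_be_in_matrix(scenario):
    _, matrix, species, genus = scenario
    with pytest.raises(KeyError):
        family_case_report(
            species, genus, matrix, QUERIES, {}, set(), anchor="nope"
        )
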