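"""Curation cascade: boundary rules, oracle equivalence, conservation, ordering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from scatdiet.curation import (
    FilterParams,
    alignment_identity,
    annotate_taxonomy,
    filter_length,
    filter_min_reads,
    merge_taxa,
    remove_contaminants,
    remove_degenerate,
    remove_singletons,
    remove_tag_jumps,
    run_curation,
)
from scatdiet.tables import MOTUTable, ReferenceDB

from conftest import make_table, random_table

PCRS = ["A.R1", "A.R2", "A.R3", "B.R1", "B.R2", "B.R3"]
SEQ = "ACGT" * 20  # 80 bp, within length bounds


def needleman_wunsch_identity(a: str, b: str) -> float:
    """Quadratic-DP global alignment oracle: maximise matches at minimal edit cost.

    Among all unit-cost optimal alignments, picks the one with the most
    match columns, and returns 100 * matches / alignment_length.
    """
    n, m = len(a), len(b)
    INF = 10 ** 9
    # state: (cost, -matches, length) lexicographically minimal
    dp = [[(INF, 0, 0)] * (m + 1) for _ in range(n + 1)]
    dp[0][0] = (0, 0, 0)
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            cands = []
            if i > 0 and j > 0:
                c, neg, L = dp[i - 1][j - 1]
                match = a[i - 1] == b[j - 1]
                cands.append((c + (0 if match else 1), neg - (1 if match else 0), L + 1))
            if i > 0:
                c, neg, L = dp[i - 1][j]
                cands.append((c + 1, neg, L + 1))
            if j > 0:
                c, neg, L = dp[i][j - 1]
                cands.append((c + 1, neg, L + 1))
            dp[i][j] = min(cands)
    cost, neg_matches, length = dp[n][m]
    return 100.0 * (-neg_matches) / length


def test_singleton_rule_counts_dataset_total():
    t = make_table({
        "a": (SEQ, {"A.R1": 1}),                  # total 1: singleton
        "b": (SEQ, {"A.R1": 1, "B.R1": 1}),       # total 2 split over PCRs: kept
        "c": (SEQ, {"A.R2": 2}),
        "d": (SEQ, {"A.R1": 10}),
        "e": (SEQ, {"B.R3": 100}),
    }, PCRS)
    out = remove_singletons(t)
    assert list(out.counts.index) == ["b", "c", "d", "e"]


def test_degenerate_base_removal():
    t = make_table({
        "a": ("ACGNT" + SEQ, {"A.R1": 5}),
        "b": (SEQ, {"A.R1": 5}),
        "c": ("ACGR" + SEQ, {"A.R1": 5}),
        "d": ("ACGY" + SEQ, {"A.R1": 5}),
        "e": (SEQ + "TT", {"A.R1": 5}),
        "f": (SEQ, {"B.R2": 5}),
    }, PCRS)
    out = remove_degenerate(t)
    assert list(out.counts.index) == ["b", "e", "f"]


@pytest.mark.parametrize("length,kept", [(59, False), (60, True), (130, True), (131, False)])
def test_length_bounds_inclusive(length, kept):
    t = make_table({"a": ("A" * length, {"A.R1": 5})}, PCRS)
    out = filter_length(t, FilterParams())
    assert (out.n_motus == 1) is kept


@pytest.mark.parametrize("counts,kept", [
    ({"A.R1": 9, "A.R2": 9, "A.R3": 9}, False),   # 27 total but never 10 in one PCR
    ({"A.R1": 10}, True),
])
def test_min_reads_in_one_pcr(counts, kept):
    t = make_table({"a": (SEQ, counts)}, PCRS)
    out = filter_min_reads(t, FilterParams())
    assert (out.n_motus == 1) is kept


def test_filters_match_naive_recomputation():
    rng = np.random.default_rng(0)
    t = random_table(rng, 300, 10)
    params = FilterParams()
    assert set(remove_singletons(t).counts.index) == \
        {m for m in t.counts.index if t.counts.loc[m].sum() >= 2}
    assert set(remove_degenerate(t).counts.index) == \
        {m for m in t.counts.index if set(t.sequences[m]) <= set("ACGT")}
    assert set(filter_length(t, params).counts.index) == \
        {m for m in t.counts.index if 60 <= len(t.sequences[m]) <= 130}
    assert set(filter_min_reads(t, params).counts.index) == \
        {m for m in t.counts.index if t.counts.loc[m].max() >= 10}


def test_early_filters_commute():
    """Singleton, degenerate and length filters are order-independent."""
    rng = np.random.default_rng(1)
    t = random_table(rng, 150, 6)
    params = FilterParams()
    stages = {
        "s": remove_singletons,
        "d": remove_degenerate,
        "l": lambda x: filter_length(x, params),
    }
    results = []
    for order in itertools.permutations("sdl"):
        cur = t
        for key in order:
            cur = stages[key](cur)
        results.append(list(cur.counts.index))
    assert all(r == results[0] for r in results)


# -- annotation ------------------------------------------------------------

@pytest.fixture(scope="module")
def toy_db():
    rng = np.random.default_rng(4)
    base = "".join(rng.choice(list("ACGT"), size=100))
    other = "".join(rng.choice(list("ACGT"), size=100))
    return ReferenceDB(
        sequences={"Vulpes vulpes": base, "Microtus agrestis": other},
        ranks={"Vulpes vulpes": "species", "Microtus agrestis": "species"},
    )


def mutate(seq: str, k: int) -> str:
    """k isolated substitutions, spaced far apart so no indel shortcut exists."""
    out = list(seq)
    for i in range(k):
        pos = 10 + 17 * i
        out[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[pos]]
    return "".join(out)


def test_identical_sequence_gets_identity_100(toy_db):
    t = make_table({"a": (toy_db.sequences["Vulpes vulpes"], {"A.R1": 50})}, PCRS)
    out = annotate_taxonomy(t, toy_db, FilterParams())
    assert out.annotation.loc["a", "best_taxon"] == "Vulpes vulpes"
    assert out.annotation.loc["a", "identity"] == 100.0


def test_identity_boundary_five_substitutions_in_100bp(toy_db):
    """5 substitutions in 100 aligned columns = 95.0%: retained at the boundary."""
    seq = mutate(toy_db.sequences["Vulpes vulpes"], 5)
    t = make_table({"a": (seq, {"A.R1": 50})}, PCRS)
    out = annotate_taxonomy(t, toy_db, FilterParams())
    assert out.n_motus == 1
    assert out.annotation.loc["a", "identity"] == pytest.approx(95.0)
    assert out.annotation.loc["a", "identity"] == pytest.approx(
        needleman_wunsch_identity(seq, toy_db.sequences["Vulpes vulpes"]))


def test_distant_sequence_dropped(toy_db):
    seq = mutate(toy_db.sequences["Vulpes vulpes"], 6)
    # guard: the other reference must also be distant for this check
    t = make_table({"a": (seq, {"A.R1": 50})}, PCRS)
    out = annotate_taxonomy(t, toy_db, FilterParams())
    assert out.n_motus == 0


def levenshtein_oracle(a: str, b: str) -> int:
    """Plain quadratic-DP edit distance, independent of the aligner."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def test_identity_consistent_with_dp_distance_on_random_pairs(toy_db):
    """identity = 100*(1 - d/L) with d from an independent DP oracle.

    L (alignment columns) satisfies max(|a|,|b|) <= L <= max(|a|,|b|) + d,
    so the oracle bounds pin the implementation's identity from both sides.
    """
    rng = np.random.default_rng(7)
    ref = toy_db.sequences["Vulpes vulpes"]
    for _ in range(25):
        seq = list(ref)
        for _ in range(int(rng.integers(0, 8))):
            op = rng.integers(3)
            pos = int(rng.integers(len(seq)))
            if op == 0:
                seq[pos] = "ACGT"[int(rng.integers(4))]
            elif op == 1 and len(seq) > 60:
                del seq[pos]
            else:
                seq.insert(pos, "ACGT"[int(rng.integers(4))])
        query = "".join(seq)
        d = levenshtein_oracle(query, ref)
        ident = alignment_identity(query, ref)
        lmin = max(len(query), len(ref))
        assert 100.0 * (1 - d / lmin) <= ident + 1e-9
        assert ident <= 100.0 * (1 - d / (lmin + d)) + 1e-9
        if d == 0:
            assert ident == 100.0


def test_ambiguous_cross_genus_tie_dropped():
    db = ReferenceDB(
        sequences={"Vulpes vulpes": "ACGTACGTAC", "Martes martes": "ACGTACGTGG"},
        ranks={"Vulpes vulpes": "species", "Martes martes": "species"},
    )
    # equidistant from both references
    t = make_table({"a": ("ACGTACGTAG", {"A.R1": 5})}, PCRS)
    out = annotate_taxonomy(t, db, FilterParams(min_len=5, min_identity=80.0))
    assert out.n_motus == 0


def test_same_genus_tie_resolves_to_genus():
    db = ReferenceDB(
        sequences={"Microtus agrestis": "ACGTACGTAC", "Microtus arvalis": "ACGTACGTGG"},
        ranks={"Microtus agrestis": "species", "Microtus arvalis": "species"},
    )
    t = make_table({"a": ("ACGTACGTAG", {"A.R1": 5})}, PCRS)
    out = annotate_taxonomy(t, db, FilterParams(min_len=5, min_identity=80.0))
    assert out.annotation.loc["a", "best_taxon"] == "Microtus"


def test_reference_db_rejects_ambiguity_codes():
    with pytest.raises(ValueError, match="non-ACGT"):
        ReferenceDB(sequences={"X y": "ACGN"}, ranks={"X y": "species"})


# -- contaminants, tag jumps, merge ---------------------------------------

def _annotated(rows, taxa):
    t = make_table(rows, PCRS)
    t.annotation = pd.DataFrame(
        {"best_taxon": taxa, "identity": [100.0] * len(taxa)},
        index=list(rows),
    )
    return t


def test_contaminant_removal_by_annotation():
    t = _annotated(
        {"a": (SEQ, {"A.R1": 5}), "b": (SEQ, {"A.R1": 5}), "c": (SEQ, {"A.R1": 5})},
        ["Homo sapiens", "Vulpes vulpes", "Microtus agrestis"],
    )
    out = remove_contaminants(t, FilterParams())
    assert list(out.counts.index) == ["b", "c"]
    unchanged = remove_contaminants(t, FilterParams(contaminant_taxa=frozenset()))
    assert list(unchanged.counts.index) == ["a", "b", "c"]


def test_tag_jump_rule_by_hand():
    """5 reads of a 10,000-read sequence in one PCR fall below 0.1% and are zeroed."""
    t = make_table({"a": (SEQ, {"A.R1": 9995, "B.R1": 5})}, PCRS)
    out = remove_tag_jumps(t, FilterParams(tagjump_fraction=0.001))
    assert out.counts.loc["a", "B.R1"] == 0
    assert out.counts.loc["a", "A.R1"] == 9995


def test_tag_jump_fraction_zero_is_identity():
    rng = np.random.default_rng(2)
    t = random_table(rng, 50, 4)
    out = remove_tag_jumps(t, FilterParams(tagjump_fraction=0.0))
    pd.testing.assert_frame_equal(out.counts, t.counts)


def test_tag_jump_matches_naive_recomputation():
    rng = np.random.default_rng(3)
    t = random_table(rng, 200, 8)
    frac = 0.01
    out = remove_tag_jumps(t, FilterParams(tagjump_fraction=frac))
    expected = t.counts.copy()
    for m in expected.index:
        total = expected.loc[m].sum()
        for pcr in expected.columns:
            if expected.loc[m, pcr] < frac * total:
                expected.loc[m, pcr] = 0
    expected = expected[(expected.sum(axis=1) > 0) | (t.counts.sum(axis=1) == 0)]
    pd.testing.assert_frame_equal(out.counts, expected)


def test_merge_combines_same_taxon_counts():
    t = _annotated(
        {"a": (SEQ, {"A.R1": 3}), "b": (SEQ + "A", {"A.R1": 7, "A.R2": 5})},
        ["Canis lupus familiaris", "Canis lupus familiaris"],
    )
    out = merge_taxa(t)
    assert out.n_motus == 1
    assert out.counts.loc["Canis lupus familiaris", "A.R1"] == 10
    assert out.counts.loc["Canis lupus familiaris", "A.R2"] == 5
    # representative sequence comes from the highest-total member
    assert out.sequences["Canis lupus familiaris"] == SEQ + "A"


def test_merge_folds_genus_into_single_species():
    t = _annotated(
        {"a": (SEQ, {"A.R1": 3}), "b": (SEQ, {"A.R2": 4})},
        ["Microtus", "Microtus agrestis"],
    )
    out = merge_taxa(t)
    assert list(out.counts.index) == ["Microtus agrestis"]
    assert out.counts.loc["Microtus agrestis"].sum() == 7


def test_merge_keeps_genus_with_two_species():
    t = _annotated(
        {"a": (SEQ, {"A.R1": 3}), "b": (SEQ, {"A.R2": 4}), "c": (SEQ, {"A.R3": 5})},
        ["Microtus", "Microtus agrestis", "Microtus arvalis"],
    )
    out = merge_taxa(t)
    assert set(out.counts.index) == {"Microtus", "Microtus agrestis", "Microtus arvalis"}


def test_merge_conserves_per_pcr_sums():
    rng = np.random.default_rng(5)
    t = random_table(rng, 60, 5)
    taxa = rng.choice(["Vulpes vulpes", "Microtus agrestis", "Canis lupus familiaris"], 60)
    t.annotation = pd.DataFrame(
        {"best_taxon": taxa, "identity": 100.0}, index=t.counts.index)
    out = merge_taxa(t)
    pd.testing.assert_series_equal(
        out.counts.sum(axis=0), t.counts.sum(axis=0), check_names=False)


# -- full cascade ----------------------------------------------------------

def test_cascade_on_clean_synthetic_recovers_truth_taxa(small_dataset):
    ref, table, _, truth = small_dataset
    curated, log = run_curation(table, ref)
    truth_taxa = {t for t in truth.pre_artifact_counts.index
                  if truth.pre_artifact_counts.loc[t].sum() > 0
                  and t != "Homo sapiens"}
    assert set(curated.counts.index) == truth_taxa
    # attrition log is monotone in rows and reads
    assert (log["motus_out"] <= log["motus_in"]).all()
    assert (log["reads_out"] <= log["reads_in"]).all()
    assert len(log) == 8


def test_cascade_on_empty_table(reference_db):
    t = make_table({}, PCRS)
    curated, log = run_curation(t, reference_db)
    assert curated.n_motus == 0
    assert len(log) == 8
    assert (log[["motus_in", "motus_out", "reads_in", "reads_out"]] == 0).all().all()
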