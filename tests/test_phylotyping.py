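"""Pairwise identity, greedy binning, naming and count tables."""

import numpy as np
import pytest

from clonediv.phylotyping import (
    PhylotypingConfig,
    SequenceRecord,
    assign_names,
    bin_phylotypes,
    count_table,
    frequency_table,
    pairwise_identity,
)
from clonediv.simulate import SyntheticScenario, make_references, simulate_library


def rec(seq_id, residues, library=""):
    return SequenceRecord(id=seq_id, residues=residues, library=library)


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ("ACGTACGT", "ACGTACGT", 1.0),
        ("ACGT", "ACGA", 0.75),
        ("ACGTACGT", "ACGACGT", 7 / 8),  # one internal gap, 7 of 8 columns match
    ],
)
def test_pairwise_identity_known_alignments(a, b, expected):
    assert pairwise_identity(a, b) == pytest.approx(expected)
    assert pairwise_identity(b, a) == pytest.approx(expected)


def test_identity_excludes_terminal_gaps():
    # the 3' overhang should not dilute identity of the shared region
    assert pairwise_identity("ACGTACGT", "ACGTACGTTTTT") == pytest.approx(1.0)


def test_ambiguity_code_counts_as_mismatch():
    assert pairwise_identity("ACGT", "ACGN") == pytest.approx(0.75)
    assert pairwise_identity("NNNN", "NNNN") == pytest.approx(0.0)


def test_identity_rejects_empty_sequence():
    with pytest.raises(ValueError):
        pairwise_identity("ACGT", "")


def test_threshold_validation():
    with pytest.raises(ValueError):
        PhylotypingConfig(threshold=0.0)


def test_bin_empty_input():
    assert bin_phylotypes([]) == []


def test_bin_pair_above_threshold_merges():
    base = "ACGT" * 50
    variant = base[:-4] + "ACGA"  # 199/200 identical
    clusters = bin_phylotypes([rec("a", base), rec("b", variant)])
    assert len(clusters) == 1 and len(clusters[0]) == 2


def test_bin_divergent_pair_stays_split():
    rng = np.random.default_rng(7)
    a = "".join(rng.choice(list("ACGT"), 200))
    b = "".join(rng.choice(list("ACGT"), 200))
    clusters = bin_phylotypes([rec("a", a), rec("b", b)])
    assert len(clusters) == 2


def test_bin_recovers_planted_references():
    """Clones at 0.5% error around references <= 96% apart bin back exactly."""
    scenario = SyntheticScenario(
        n_references=4, seq_length=300, per_base_error=0.005, seed=11
    )
    refs = make_references(scenario)
    clones = []
    for i, ref in enumerate(refs):
        counts = np.zeros(len(refs), dtype=int)
        counts[i] = 5
        clones.extend(
            simulate_library(None, refs, scenario, library=f"lib{i}", counts=counts)
        )
    clusters = bin_phylotypes(clones)
    assert len(clusters) == len(refs)
    assert sorted(len(c) for c in clusters) == [5] * len(refs)
    # partition: every clone in exactly one cluster
    all_ids = sorted(m.id for c in clusters for m in c.members)
    assert all_ids == sorted(c.id for c in clones)


def test_assign_names_identity_and_ties():
    base = "ACGT" * 75
    near = base[:-8] + "ACGAACGA"
    clusters = bin_phylotypes([rec("clone1", base)])
    named = assign_names(clusters, [rec("Hydrogenophaga_ref", base), rec("Other_ref", near)])
    assert named[0].name == "Hydrogenophaga_ref"
    assert named[0].name_identity == pytest.approx(1.0)
    # equal-identity references: lexicographically smaller id wins
    tied = assign_names(
        bin_phylotypes([rec("clone2", base)]),
        [rec("B_ref", near), rec("A_ref", near)],
    )
    assert tied[0].name == "A_ref"


def test_assign_names_requires_references():
    with pytest.raises(ValueError):
        assign_names([], [])


def test_assign_names_records_sub_threshold_identity():
    rng = np.random.default_rng(3)
    base = "".join(rng.choice(list("ACGT"), 300))
    # ~7% substitutions: best hit falls below the species threshold
    far = list(base)
    for pos in rng.choice(300, 21, replace=False):
        far[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[far[pos]]
    clusters = assign_names(
        bin_phylotypes([rec("clone", base)]), [rec("Distant_ref", "".join(far))]
    )
    assert clusters[0].name == "Distant_ref"
    assert clusters[0].name_identity < 0.97


def build_two_library_clusters():
    a = "ACGT" * 60
    b = "TTGGCCAA" * 30
    clones = (
        [rec(f"L1_{i}", a, "L1") for i in range(24)]
        + [rec(f"L1_x{i}", b, "L1") for i in range(6)]
        + [rec(f"L2_{i}", a, "L2") for i in range(2)]
    )
    return bin_phylotypes(clones)


def test_count_table_totals_and_frequency_rendering():
    clusters = build_two_library_clusters()
    counts = count_table(clusters, libraries=["L1", "L2"])
    assert counts.sum()["L1"] == 30 and counts.sum()["L2"] == 2
    freqs = frequency_table(counts)
    assert set(freqs.loc[:, "L1"]) == {"80", "20"}
    assert "nd" in set(freqs.loc[:, "L2"])


def test_count_table_rejects_unknown_library():
    clusters = build_two_library_clusters()
    with pytest.raises(ValueError):
        count_table(clusters, libraries=["L1"])


def test_frequency_rounding_half_away_from_zero():
    import pandas as pd

    counts = pd.DataFrame({"lib": [2, 24, 2, 2]}, index=list("abcd"))
    freqs = frequency_table(counts)
    # 2/30 = 6.67% -> 7; 24/30 -> 80
    assert freqs.loc["a", "lib"] == "7"
    assert freqs.loc["b", "lib"] == "80"
    total = sum(int(v) for v in freqs["lib"])
    assert abs(total - 100) <= len(counts) / 2


def test_frequencies_sum_near_100_on_study_counts(table1_counts):
    import pandas as pd

    counts = pd.DataFrame(
        {lib: pd.Series(c) for lib, c in table1_counts.items()}
    ).fillna(0).astype(int)
    freqs = frequency_table(counts)
    for lib in counts.columns:
        total = sum(int(v) for v in freqs[lib] if v != "nd")
        s = (counts[lib] > 0).sum()
        assert abs(total - 100) <= s / 2
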