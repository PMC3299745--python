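"""Phylotype binning of 16S clone sequences at a pairwise-identity threshold.

Partial 16S rRNA clones (~900 bp) are grouped into phylotypes: sequences
sharing at least 97% base-pair identity are treated as a single operational
unit, the conventional species-level cutoff for 16S data. Identity is
measured on a global alignment with affine internal gap costs and cost-free
terminal gaps; columns that are part of a terminal gap run are also excluded
from the identity denominator, since clone inserts are partial genes with
ragged ends and a length difference should not count against identity.

Clustering is greedy centroid binning: sequences are processed in a
deterministic order (descending length, ties broken by id) and each joins the
first existing cluster whose representative it matches at or above the
threshold, else founds a new cluster. At clone-library scale (tens of clones
per library, references several percent apart) this is exact; it mirrors the
de-novo OTU pickers long used for amplicon data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align

__all__ = [
    "SequenceRecord",
    "PhylotypeCluster",
    "PhylotypingConfig",
    "pairwise_identity",
    "bin_phylotypes",
    "assign_names",
    "count_table",
    "frequency_table",
]

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class SequenceRecord:
    """A single clone (or reference) sequence with its library label."""

    id: str
    residues: str
    library: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - (_VALID_BASES | {"N"})
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-nucleotide symbols {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class PhylotypeCluster:
    """A set of clones sharing >= threshold identity with one representative."""

    phylotype_id: str
    representative: SequenceRecord
    members: list[SequenceRecord] = field(default_factory=list)
    name: str | None = None
    name_identity: float | None = None

    @property
    def member_ids(self) -> set[str]:
        return {m.id for m in self.members}

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PhylotypingConfig:
    """Identity threshold and alignment scoring for phylotype binning.

    The 0.97 default is the 16S species-level convention. Alignment scores
    are a plain affine scheme; the threshold, not the scores, carries almost
    all of the decision weight at clone-library divergences.
    """

    threshold: float = 0.97
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError(f"threshold must be in (0, 1], got {self.threshold}")

    def aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = self.match
        aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = self.gap_open
        aligner.extend_gap_score = self.gap_extend
        # terminal gaps are cost-free: clone inserts are partial genes with
        # ragged ends, and a length difference must not distort the alignment
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # attribute names before biopython 1.88
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
        return aligner


DEFAULT_CONFIG = PhylotypingConfig()


def _trim_terminal_gaps(row_a: str, row_b: str) -> tuple[str, str]:
    start = 0
    end = len(row_a)
    while start < end and (row_a[start] == "-" or row_b[start] == "-"):
        start += 1
    while end > start and (row_a[end - 1] == "-" or row_b[end - 1] == "-"):
        end -= 1
    return row_a[start:end], row_b[start:end]


def pairwise_identity(
    a: "SequenceRecord | str",
    b: "SequenceRecord | str",
    config: PhylotypingConfig = DEFAULT_CONFIG,
) -> float:
    """Fraction of matching columns on the optimal global alignment of *a*, *b*.

    Terminal gap columns are excluded from the denominator; internal gaps
    count as non-matching columns. The ambiguity code N never matches
    (conservative: an N column can only lower identity). Symmetric in its
    arguments.
    """
    seq_a = a.residues if isinstance(a, SequenceRecord) else str(a).upper()
    seq_b = b.residues if isinstance(b, SequenceRecord) else str(b).upper()
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    alignment = config.aligner().align(seq_a, seq_b)[0]
    row_a, row_b = _trim_terminal_gaps(alignment[0], alignment[1])
    matches = sum(
        1 for x, y in zip(row_a, row_b) if x == y and x in _VALID_BASES
    )
    # the denominator is never smaller than the shorter sequence, so a
    # spurious micro-overlap between unrelated sequences cannot score high
    return matches / max(len(row_a), min(len(seq_a), len(seq_b)))


def bin_phylotypes(
    sequences: list[SequenceRecord],
    config: PhylotypingConfig = DEFAULT_CONFIG,
) -> list[PhylotypeCluster]:
    """Greedy centroid clustering of clones into phylotypes.

    Deterministic for a fixed input set: sequences are visited longest first
    (ties by id); each is compared against existing representatives in
    creation order and joins the first at >= ``config.threshold`` identity.
    Every input sequence lands in exactly one cluster.
    """
    ordered = sorted(sequences, key=lambda s: (-len(s), s.id))
    clusters: list[PhylotypeCluster] = []
    for seq in ordered:
        for cluster in clusters:
            if pairwise_identity(seq, cluster.representative, config) >= config.threshold:
                cluster.members.append(seq)
                break
        else:
            clusters.append(
                PhylotypeCluster(
                    phylotype_id=f"PT{len(clusters) + 1:02d}",
                    representative=seq,
                    members=[seq],
                )
            )
    return clusters


def assign_names(
    clusters: list[PhylotypeCluster],
    references: list[SequenceRecord],
    config: PhylotypingConfig = DEFAULT_CONFIG,
) -> list[PhylotypeCluster]:
    """Name each cluster after the reference closest to its representative.

    The recorded ``name_identity`` lets a caller flag names below the
    species threshold (the analogue of a sub-97% database hit, named only to
    genus or division level). Ties go to the lexicographically smaller
    reference id. Clusters are modified in place and returned.
    """
    if not references:
        raise ValueError("assign_names requires a non-empty reference set")
    for cluster in clusters:
        best_id, best_identity = None, -1.0
        for ref in sorted(references, key=lambda r: r.id):
            ident = pairwise_identity(cluster.representative, ref, config)
            if ident > best_identity:
                best_id, best_identity = ref.id, ident
        cluster.name = best_id
        cluster.name_identity = best_identity
    return clusters


def count_table(
    clusters: list[PhylotypeCluster],
    libraries: list[str] | None = None,
) -> pd.DataFrame:
    """Phylotype-by-library clone counts.

    Row labels are the cluster names where assigned, else phylotype ids.
    If ``libraries`` is given, members carrying an unlisted label raise; the
    column order follows the given list. Otherwise columns are the labels
    seen, in first-appearance order.
    """
    seen: list[str] = []
    for cluster in clusters:
        for m in cluster.members:
            if m.library not in seen:
                seen.append(m.library)
    if libraries is None:
        libraries = seen
    else:
        unknown = [lib for lib in seen if lib not in libraries]
        if unknown:
            raise ValueError(f"members carry unknown library labels: {unknown}")
    index = [c.name or c.phylotype_id for c in clusters]
    table = pd.DataFrame(0, index=pd.Index(index, name="phylotype"), columns=libraries)
    for cluster, label in zip(clusters, index):
        for m in cluster.members:
            table.loc[label, m.library] += 1
    return table


def _round_half_away(x: float) -> int:
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


def frequency_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Whole-number percentage table; absent phylotypes rendered ``nd``.

    Frequencies are 100 * count / library total, rounded half away from
    zero. Per-library sums can drift from 100 by up to S/2 through rounding.
    """
    out = pd.DataFrame("nd", index=counts.index, columns=counts.columns)
    totals = counts.sum(axis=0)
    for lib in counts.columns:
        total = totals[lib]
        for pt in counts.index:
            c = int(counts.loc[pt, lib])
            if c > 0 and total > 0:
                out.loc[pt, lib] = str(_round_half_away(100.0 * c / total))
    return out
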