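"""Synthetic study generator: ribotypes, clone libraries, stage censuses.

The wet-lab side of the study — six treatments, three replicate wells of 50
nauplii each, one 30-clone 16S library per treatment built over eight
ribotypes — is emulated here so that every downstream stage can be exercised
without any sequence download.

Three generators share one scenario object:

* ``make_references`` draws the reference ribotypes: random sequences
  rejection-checked so that every pair sits at or below ``1 - min_divergence``
  identity (default 0.96, safely under the 0.97 phylotype threshold);
* ``simulate_library`` builds a clone library from a composition profile,
  either multinomially or with an exact count vector, and corrupts each
  clone with independent per-base substitutions (default 0.5%, i.e. roughly
  Sanger-read error scale — small against the 4% reference divergence, so
  binning is recoverable by design);
* ``simulate_experiment`` draws the stage censuses: survivors are binomial
  in ``n_start`` and copepodites binomial in the survivors, per treatment.

Determinism: each generator derives its own numpy stream from the scenario
seed via a fixed spawn key, so any call is reproducible in isolation and
streams never alias across generators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .development import StageCensus
from .phylotyping import DEFAULT_CONFIG, PhylotypingConfig, SequenceRecord, pairwise_identity

__all__ = [
    "SyntheticScenario",
    "GenerationError",
    "make_references",
    "simulate_library",
    "simulate_clone_libraries",
    "simulate_experiment",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# Stage-census probabilities (p_survive, p_metamorphose) per treatment,
# chosen to mirror the study's qualitative outcome: good survival with
# moderate-to-high metamorphosis everywhere except trimethoprim, where
# survival drops and metamorphosis is fully arrested; the acetone control
# metamorphoses fastest among controls.
DEFAULT_STAGE_MODEL: dict[str, tuple[float, float]] = {
    "Cipr": (0.85, 0.40),
    "Sulf": (0.90, 0.65),
    "Trim": (0.60, 0.00),
    "SS": (0.90, 0.60),
    "Ac": (0.90, 0.85),
    "DMSO": (0.90, 0.50),
}

# Per-library clone counts over the eight ribotypes (columns of the shipped
# count table); used as default community profiles after normalisation.
DEFAULT_LIBRARY_COUNTS: dict[str, tuple[int, ...]] = {
    "Cipr": (2, 0, 0, 0, 0, 24, 2, 2),
    "Sulf": (2, 0, 0, 0, 0, 20, 4, 4),
    "Trim": (3, 0, 0, 0, 0, 22, 2, 3),
    "SS": (15, 6, 2, 3, 4, 0, 0, 0),
    "Ac": (18, 3, 2, 2, 5, 0, 0, 0),
    "DMSO": (19, 4, 2, 0, 5, 0, 0, 0),
}

_REFERENCE_STREAM = 1
_LIBRARY_STREAM = 2
_EXPERIMENT_STREAM = 3


class GenerationError(RuntimeError):
    """Raised when a scenario cannot be satisfied within bounded retries."""


@dataclass(frozen=True)
class SyntheticScenario:
    """All knobs of the synthetic study, with the study design as defaults."""

    n_references: int = 8
    min_divergence: float = 0.04
    seq_length: int = 900
    clones_per_library: int = 30
    per_base_error: float = 0.005
    replicates: int = 3
    n_start: int = 50
    seed: int = 0
    community_counts: dict | None = None
    stage_model: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_MODEL))
    max_reference_attempts: int = 200

    def __post_init__(self) -> None:
        if not 0.0 <= self.per_base_error <= 1.0:
            raise ValueError("per_base_error must be a probability")
        if self.min_divergence <= 2 * self.per_base_error:
            raise ValueError(
                "min_divergence must exceed twice per_base_error for the "
                "planted phylotype structure to be recoverable"
            )
        for treatment, (p_s, p_m) in self.stage_model.items():
            if not (0.0 <= p_s <= 1.0 and 0.0 <= p_m <= 1.0):
                raise ValueError(f"stage probabilities for {treatment!r} not in [0,1]")
        if self.community_counts is not None:
            for lib, counts in self.community_counts.items():
                if len(counts) != self.n_references or any(c < 0 for c in counts):
                    raise ValueError(f"bad community counts for library {lib!r}")

    def with_seed(self, seed: int) -> "SyntheticScenario":
        return replace(self, seed=seed)

    @property
    def library_counts(self) -> dict[str, tuple[int, ...]]:
        """Per-library clone counts over the references.

        Defaults to the six-library study design when the scenario keeps the
        standard eight references, else to a single near-uniform library.
        """
        if self.community_counts is not None:
            return {lib: tuple(c) for lib, c in self.community_counts.items()}
        if self.n_references == len(next(iter(DEFAULT_LIBRARY_COUNTS.values()))):
            return dict(DEFAULT_LIBRARY_COUNTS)
        base, extra = divmod(self.clones_per_library, self.n_references)
        counts = tuple(
            base + (1 if i < extra else 0) for i in range(self.n_references)
        )
        return {"lib1": counts}

    def profiles(self) -> dict[str, np.ndarray]:
        """Community composition vectors (normalised counts) per library."""
        return {
            lib: np.asarray(counts, dtype=float) / sum(counts)
            for lib, counts in self.library_counts.items()
        }

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def make_references(
    scenario: SyntheticScenario,
    config: PhylotypingConfig = DEFAULT_CONFIG,
) -> list[SequenceRecord]:
    """Draw the planted reference ribotypes.

    Each candidate is accepted only if its identity to every reference drawn
    so far is at most ``1 - min_divergence``; after
    ``max_reference_attempts`` rejections a :class:`GenerationError` is
    raised (random nucleotide sequences virtually never collide at these
    divergences, so failure indicates an inconsistent scenario).
    """
    rng = scenario.rng(_REFERENCE_STREAM)
    ceiling = 1.0 - scenario.min_divergence
    refs: list[SequenceRecord] = []
    for i in range(scenario.n_references):
        for _ in range(scenario.max_reference_attempts):
            candidate = SequenceRecord(
                id=f"REF{i + 1:02d}", residues=_random_sequence(rng, scenario.seq_length)
            )
            if all(pairwise_identity(candidate, r, config) <= ceiling for r in refs):
                refs.append(candidate)
                break
        else:
            raise GenerationError(
                f"could not place reference {i + 1} below identity {ceiling}"
            )
    return refs


def _mutate(residues: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0.0:
        return residues
    arr = np.frombuffer(residues.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for pos in hits:
        choices = _BASES[_BASES != arr[pos]]
        arr[pos] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_library(
    profile,
    references: list[SequenceRecord],
    scenario: SyntheticScenario,
    library: str = "lib",
    counts=None,
    rng: np.random.Generator | None = None,
) -> list[SequenceRecord]:
    """Draw one clone library.

    ``counts`` fixes the per-reference clone counts exactly (golden-test
    mode); otherwise ``clones_per_library`` clones are drawn multinomially
    from ``profile``. Each clone is its reference with independent per-base
    substitutions at ``per_base_error``.
    """
    if rng is None:
        rng = scenario.rng(_LIBRARY_STREAM)
    if counts is None:
        p = np.asarray(profile, dtype=float)
        counts = rng.multinomial(scenario.clones_per_library, p / p.sum())
    counts = np.asarray(counts, dtype=int)
    if counts.size != len(references):
        raise ValueError("counts length must equal the number of references")
    clones: list[SequenceRecord] = []
    clone_no = 0
    for ref, k in zip(references, counts):
        for _ in range(int(k)):
            clone_no += 1
            clones.append(
                SequenceRecord(
                    id=f"{library}_clone{clone_no:03d}",
                    residues=_mutate(ref.residues, scenario.per_base_error, rng),
                    library=library,
                )
            )
    return clones


def simulate_clone_libraries(
    scenario: SyntheticScenario,
    references: list[SequenceRecord] | None = None,
    exact_counts: bool = True,
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """All libraries of the scenario: returns (references, clones).

    With ``exact_counts`` (default) each library reproduces its scenario
    count vector exactly; otherwise composition is drawn multinomially from
    the normalised profile.
    """
    if references is None:
        references = make_references(scenario)
    rng = scenario.rng(_LIBRARY_STREAM)
    clones: list[SequenceRecord] = []
    for lib, counts in scenario.library_counts.items():
        clones.extend(
            simulate_library(
                profile=np.asarray(counts, dtype=float),
                references=references,
                scenario=scenario,
                library=lib,
                counts=counts if exact_counts else None,
                rng=rng,
            )
        )
    return references, clones


def simulate_experiment(scenario: SyntheticScenario) -> list[StageCensus]:
    """Draw the stage censuses for every treatment and replicate.

    Survivors ~ Binomial(n_start, p_survive); copepodites ~ Binomial(
    survivors, p_metamorphose); nauplii are the remaining survivors.
    """
    rng = scenario.rng(_EXPERIMENT_STREAM)
    censuses: list[StageCensus] = []
    for treatment, (p_survive, p_meta) in scenario.stage_model.items():
        for rep in range(1, scenario.replicates + 1):
            survivors = int(rng.binomial(scenario.n_start, p_survive))
            copepodites = int(rng.binomial(survivors, p_meta))
            censuses.append(
                StageCensus(
                    replicate=f"{treatment}_r{rep}",
                    treatment=treatment,
                    n_start=scenario.n_start,
                    n_nauplii=survivors - copepodites,
                    n_copepodites=copepodites,
                )
            )
    return censuses


def census_frame(censuses: list[StageCensus]) -> pd.DataFrame:
    """Stage censuses as the TSV-ready tidy frame."""
    return pd.DataFrame(
        {
            "treatment": [c.treatment for c in censuses],
            "replicate": [c.replicate for c in censuses],
            "n_start": [c.n_start for c in censuses],
            "n_nauplii": [c.n_nauplii for c in censuses],
            "n_copepodites": [c.n_copepodites for c in censuses],
        }
    )
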