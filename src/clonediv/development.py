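"""Copepod development endpoints from stage censuses.

Each experimental replicate starts with a known number of nauplii and is
censused at termination for nauplii and copepodites still alive. Three
endpoints summarise the outcome:

* survivorship — percent of starting animals alive at termination;
* %Copepodites — percent of survivors that reached a copepodite stage;
* development index (DI) — a stage-weighted mean over individuals, with
  nauplii scored 1 and copepodites 2: DI = sum_i k_i * n_i / NS.

The DI is meant to fold survival and metamorphosis success into one number.
That requires a convention for the dead: by default every starting animal is
staged (NS = n_start) with dead individuals scoring 0, so mortality pulls DI
down. The alternative convention (NS = survivors only, DI then measuring
metamorphosis alone) is available via ``include_dead=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "StageCensus",
    "survivorship",
    "percent_copepodites",
    "development_index",
    "endpoint_table",
    "treatment_summary",
]

NAUPLIUS_STAGE = 1
COPEPODITE_STAGE = 2


@dataclass(frozen=True)
class StageCensus:
    """Per-replicate copepod counts by developmental stage class."""

    replicate: str
    n_start: int
    n_nauplii: int
    n_copepodites: int
    treatment: str = ""

    def __post_init__(self) -> None:
        for name in ("n_start", "n_nauplii", "n_copepodites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_nauplii + self.n_copepodites > self.n_start:
            raise ValueError(
                f"replicate {self.replicate!r}: survivors "
                f"({self.n_nauplii + self.n_copepodites}) exceed n_start ({self.n_start})"
            )

    @property
    def survivors(self) -> int:
        return self.n_nauplii + self.n_copepodites

    @property
    def n_dead(self) -> int:
        return self.n_start - self.survivors


def survivorship(census: StageCensus) -> float:
    """Percent of starting animals alive at termination."""
    if census.n_start == 0:
        raise ValueError("survivorship undefined for n_start = 0")
    return 100.0 * census.survivors / census.n_start


def percent_copepodites(census: StageCensus) -> float | None:
    """Percent of survivors that reached a copepodite stage; None if none survived."""
    if census.survivors == 0:
        return None
    return 100.0 * census.n_copepodites / census.survivors


def development_index(census: StageCensus, include_dead: bool = True) -> float:
    """Stage-weighted development index in [0, 2].

    With ``include_dead`` (default) the denominator is every starting animal
    and the dead contribute stage value 0, so DI = 2 only under full survival
    with full metamorphosis. With ``include_dead=False`` only survivors are
    staged and DI ranges over [1, 2] whenever anything survived.
    """
    score = NAUPLIUS_STAGE * census.n_nauplii + COPEPODITE_STAGE * census.n_copepodites
    if include_dead:
        if census.n_start == 0:
            raise ValueError("development index undefined for n_start = 0")
        return score / census.n_start
    if census.survivors == 0:
        raise ValueError("no survivors: survivor-only development index undefined")
    return score / census.survivors


def endpoint_table(censuses: list[StageCensus], include_dead: bool = True) -> pd.DataFrame:
    """Per-replicate endpoints as a tidy DataFrame.

    %Copepodites is NaN for replicates with no survivors.
    """
    rows = []
    for c in censuses:
        pc = percent_copepodites(c)
        rows.append(
            {
                "treatment": c.treatment,
                "replicate": c.replicate,
                "n_start": c.n_start,
                "n_nauplii": c.n_nauplii,
                "n_copepodites": c.n_copepodites,
                "survivorship": survivorship(c),
                "pct_copepodites": float("nan") if pc is None else pc,
                "DI": development_index(c, include_dead=include_dead),
            }
        )
    return pd.DataFrame(rows)


def treatment_summary(endpoints: pd.DataFrame) -> pd.DataFrame:
    """Median and range of each endpoint per treatment (reporting analogue)."""
    summaries = []
    for treatment, grp in endpoints.groupby("treatment", sort=False):
        row: dict[str, object] = {"treatment": treatment, "n_replicates": len(grp)}
        for col in ("survivorship", "pct_copepodites", "DI"):
            row[f"{col}_median"] = grp[col].median()
            row[f"{col}_min"] = grp[col].min()
            row[f"{col}_max"] = grp[col].max()
        summaries.append(row)
    return pd.DataFrame(summaries)
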