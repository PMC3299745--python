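"""End-to-end orchestration: counts -> diversity -> endpoints -> statistics.

The full analysis mirrors the study's report structure: a phylotype
count/frequency table per library, a per-library diversity table (H_B, its
bounds and evenness V), a per-replicate endpoint table with treatment
medians, and a statistics report containing

* the pooled control-vs-antibiotic t-tests on H_B and on V,
* per-antibiotic t-tests against the matched solvent control on each
  Box-Cox-transformed endpoint,
* the between-control one-way ANOVA with Tukey HSD on %Copepodites,
* Spearman rank correlations of mean treatment DI against H_B and V.

Every output starts with ``#`` provenance lines (package version, seed,
config hash); no timestamps, so a rerun with the same config and seed is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .development import endpoint_table, treatment_summary
from .diversity import diversity_table
from .io import (
    packaged_count_table,
    read_count_table,
    read_stage_census,
    write_tsv,
)
from .phylotyping import PhylotypingConfig, assign_names, bin_phylotypes, count_table, frequency_table
from .simulate import SyntheticScenario, simulate_experiment
from .stats import SampleGroup, TestResult, box_cox, one_way_anova, spearman, t_test_unpaired, tukey_hsd

__all__ = ["RunConfig", "run_full_analysis", "stats_report"]

#: antibiotic treatment -> its solvent control
DEFAULT_CONTROL_PAIRING = {"Cipr": "SS", "Sulf": "Ac", "Trim": "DMSO"}


@dataclass
class RunConfig:
    """Inputs, conventions and output location for a full run.

    With no input paths the packaged six-library count table is analysed and
    the stage censuses are simulated from the default scenario at ``seed``.
    """

    counts_tsv: str | None = None
    census_tsv: str | None = None
    clones_fasta: str | None = None
    references_fasta: str | None = None
    outdir: str = "clonediv_out"
    seed: int = 0
    identity_threshold: float = 0.97
    boxcox_lambda: "float | str" = "auto"
    di_includes_dead: bool = True
    control_pairing: dict = field(default_factory=lambda: dict(DEFAULT_CONTROL_PAIRING))

    @property
    def antibiotics(self) -> list[str]:
        return list(self.control_pairing)

    @property
    def controls(self) -> list[str]:
        return list(self.control_pairing.values())

    def digest(self) -> str:
        # outdir is excluded: where the bundle lands is not part of the
        # analysis, and identical runs must hash identically
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _provenance(config: RunConfig) -> list[str]:
    return [
        f"clonediv {__version__}",
        f"seed={config.seed}",
        f"config_hash={config.digest()}",
    ]


def _result_row(comparison: str, res: TestResult) -> dict:
    df = res.df if not isinstance(res.df, tuple) else f"{res.df[0]},{res.df[1]}"
    return {
        "comparison": comparison,
        "method": res.method,
        "statistic": res.statistic,
        "df": df,
        "p_value": res.p_value,
    }


def _boxcox_groups(named_values: list[tuple[str, list]], lmbda) -> list[SampleGroup]:
    """One Box-Cox fit on the pooled comparison data, applied to every group.

    A single lambda (and zero-shift) across the groups keeps the comparison
    on one scale. Constant pooled data (e.g. a fully arrested endpoint in
    every replicate of both groups) are passed through untransformed: any
    power transform of a constant is a constant, and the degenerate-variance
    handling of the tests takes over.
    """
    pooled = [v for _, values in named_values for v in values]
    if max(pooled) == min(pooled):
        return [SampleGroup.of(label, values) for label, values in named_values]
    fit = box_cox(pooled, lmbda)
    out = []
    start = 0
    for label, values in named_values:
        out.append(SampleGroup.of(label, fit.values[start : start + len(values)]))
        start += len(values)
    return out


def stats_report(
    diversity: pd.DataFrame,
    endpoints: pd.DataFrame,
    config: RunConfig,
) -> pd.DataFrame:
    """Assemble the statistics table from the diversity and endpoint tables."""
    rows: list[dict] = []

    controls = [c for c in config.controls if c in diversity.index]
    antibiotics = [a for a in config.antibiotics if a in diversity.index]
    for index_col in ("H_B", "V"):
        vals = diversity[index_col]
        if controls and antibiotics and not vals[controls + antibiotics].isna().any():
            res = t_test_unpaired(
                SampleGroup.of("controls", vals[controls]),
                SampleGroup.of("antibiotics", vals[antibiotics]),
            )
            rows.append(_result_row(f"{index_col}: controls vs antibiotics", res))

    by_treatment = {t: g for t, g in endpoints.groupby("treatment", sort=False)}
    endpoint_cols = ("survivorship", "pct_copepodites", "DI")
    for antibiotic, control in config.control_pairing.items():
        if antibiotic not in by_treatment or control not in by_treatment:
            continue
        for col in endpoint_cols:
            a_vals = by_treatment[antibiotic][col].dropna()
            c_vals = by_treatment[control][col].dropna()
            if len(a_vals) < 2 or len(c_vals) < 2:
                rows.append(
                    {
                        "comparison": f"{col}: {antibiotic} vs {control}",
                        "method": "skipped (fewer than 2 replicates)",
                        "statistic": math.nan,
                        "df": "",
                        "p_value": math.nan,
                    }
                )
                continue
            ga, gc = _boxcox_groups(
                [(antibiotic, list(a_vals)), (control, list(c_vals))],
                config.boxcox_lambda,
            )
            res = t_test_unpaired(ga, gc)
            rows.append(_result_row(f"{col}: {antibiotic} vs {control} (Box-Cox)", res))

    present_controls = [c for c in config.controls if c in by_treatment]
    if len(present_controls) >= 2:
        for col in endpoint_cols:
            named = [
                (c, list(by_treatment[c][col].dropna()))
                for c in present_controls
                if len(by_treatment[c][col].dropna()) >= 2
            ]
            if len(named) < 2:
                continue
            groups = _boxcox_groups(named, config.boxcox_lambda)
            res = one_way_anova(groups)
            rows.append(_result_row(f"{col}: between controls (Box-Cox)", res))
            for pair in tukey_hsd(groups):
                rows.append(
                    _result_row(f"{col}: {pair.labels[0]} vs {pair.labels[1]}", pair)
                )

    # Spearman on non-transformed data: one mean DI per treatment against
    # that treatment's library-level diversity values.
    mean_di = endpoints.groupby("treatment")["DI"].mean()
    shared = [t for t in diversity.index if t in mean_di.index]
    if len(shared) >= 3:
        for index_col in ("H_B", "V"):
            vals = diversity.loc[shared, index_col]
            if vals.isna().any():
                continue
            res = spearman(mean_di[shared].to_numpy(), vals.to_numpy())
            rows.append(_result_row(f"DI vs {index_col} (treatment-level)", res))

    return pd.DataFrame(rows)


def _load_counts(config: RunConfig) -> pd.DataFrame:
    if config.clones_fasta:
        from .io import read_fasta

        clones = read_fasta(config.clones_fasta)
        clusters = bin_phylotypes(
            clones, PhylotypingConfig(threshold=config.identity_threshold)
        )
        if config.references_fasta:
            references = read_fasta(config.references_fasta)
            assign_names(clusters, references)
        return count_table(clusters)
    if config.counts_tsv:
        return read_count_table(config.counts_tsv)
    return packaged_count_table()


def _load_endpoints(config: RunConfig) -> pd.DataFrame:
    if config.census_tsv:
        censuses = read_stage_census(config.census_tsv)
    else:
        censuses = simulate_experiment(SyntheticScenario(seed=config.seed))
    return endpoint_table(censuses, include_dead=config.di_includes_dead)


def run_full_analysis(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every stage and write the report bundle under ``config.outdir``.

    Returns the tables keyed by output stem so callers can consume them
    without re-reading the files.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = _provenance(config)

    counts = _load_counts(config)
    freqs = frequency_table(counts)
    diversity = diversity_table(counts)
    endpoints = _load_endpoints(config)
    summary = treatment_summary(endpoints)
    report = stats_report(diversity, endpoints, config)

    write_tsv(counts, outdir / "phylotype_counts.tsv", header, index=True)
    write_tsv(freqs, outdir / "phylotype_frequencies.tsv", header, index=True)
    write_tsv(
        diversity.reset_index(), outdir / "diversity.tsv", header, index=False
    )
    write_tsv(endpoints, outdir / "endpoints.tsv", header, index=False)
    write_tsv(summary, outdir / "endpoint_summary.tsv", header, index=False)
    write_tsv(report, outdir / "stats_report.tsv", header, index=False)
    _write_summary_text(outdir / "summary.txt", header, diversity, report)

    return {
        "counts": counts,
        "frequencies": freqs,
        "diversity": diversity,
        "endpoints": endpoints,
        "endpoint_summary": summary,
        "stats_report": report,
    }


def _write_summary_text(path: Path, header: list[str], diversity, report) -> None:
    lines = [f"# {h}" for h in header]
    lines.append("")
    lines.append("Per-library diversity (H_B in nats/individual):")
    for lib, row in diversity.iterrows():
        v = "undefined" if math.isnan(row["V"]) else f"{row['V']:.2f}"
        lines.append(
            f"  {lib}: N={int(row['N'])} S={int(row['S'])} "
            f"H_B={row['H_B']:.2f} V={v}"
        )
    lines.append("")
    lines.append("Key comparisons:")
    for _, row in report.iterrows():
        if isinstance(row["statistic"], float) and math.isnan(row["statistic"]):
            continue
        lines.append(
            f"  {row['comparison']}: {row['method']} statistic="
            f"{row['statistic']:.3f} df={row['df']} p={row['p_value']:.4f}"
        )
    path.write_text("\n".join(lines) + "\n")
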