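"""Cohort summary statistics: quantile group summaries and association tests.

The statistics here mirror what a clinical SPSS workflow produces: group
summaries as median (25th-75th percentile) with the HAVERAGE quantile rule
(Hyndman-Fan type 6, interpolation at rank p*(n+1)), Pearson chi-square
tests without continuity correction, and mean comparisons by t-test / ANOVA
reported alongside their rank-based counterparts (Mann-Whitney U,
Kruskal-Wallis).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

MSI_LEVELS = ("MSS", "MSI-L", "MSI-H")


@dataclass(frozen=True)
class SampleRecord:
    """One tumor's clinical covariates plus MSI status and aberration count."""

    sample: str
    age: int
    sex: str                 # M / F
    stage: int               # 1..4
    location: str            # R / L
    differentiation: str     # Well / Moderately / Poorly
    msi: str                 # MSS / MSI-L / MSI-H
    aberration_count: int

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.aberration_count < 0:
            raise ValueError("aberration_count must be non-negative")
        if self.msi not in MSI_LEVELS:
            raise ValueError(f"unknown MSI status {self.msi!r}")


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    median: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("quantiles out of order")


def load_table1() -> pd.DataFrame:
    """Load the packaged 27-tumor clinical fixture (age, sex, stage, location,
    differentiation, MSI status, total aberration count per sample)."""
    ref = importlib.resources.files("oncoclade.data") / "table1_clinical.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def quantile_type6(values, p: float) -> float:
    """Hyndman-Fan type 6 quantile (SPSS HAVERAGE): interpolate the sorted
    sample at rank h = p*(n+1), clamped to [1, n]."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("quantile of empty sequence")
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must be in (0, 1), got {p}")
    return float(np.quantile(arr, p, method="weibull"))


def group_summary(records: pd.DataFrame, group_by, variable: str) -> list[GroupSummary]:
    """Per-group n / median / quartiles of ``variable``.

    ``group_by`` is a column name or a mapping-producing callable applied to
    rows (used e.g. to collapse MSI into MSI-H vs non-MSI-H).  Empty groups
    are omitted.
    """
    df = records.copy()
    if callable(group_by):
        df["_group"] = df.apply(group_by, axis=1)
        key = "_group"
    else:
        key = group_by
    out = []
    for label, sub in df.groupby(key, sort=True, observed=True):
        vals = sub[variable].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            continue
        out.append(
            GroupSummary(
                group=str(label),
                n=int(vals.size),
                median=quantile_type6(vals, 0.5),
                q1=quantile_type6(vals, 0.25),
                q3=quantile_type6(vals, 0.75),
            )
        )
    return out


def pearson_chisq(table) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a 2-D count table.

    Empty rows/columns are dropped first; returns (statistic, df, p).
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValueError("contingency table must be 2-D")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.sum() == 0:
        raise ValueError("zero grand total")
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns after dropping empty margins")
    stat, p, dof, _ = sps.chi2_contingency(obs, correction=False)
    return float(stat), int(dof), float(p)


@dataclass
class GroupTestReport:
    """Mean- and rank-based comparisons of one variable across groups.

    Both families are reported side by side; no single p-value is
    privileged.  Skipped tests carry a reason instead of a number.
    """

    variable: str
    group_sizes: dict[str, int]
    mean_test: str | None = None        # "t-test" or "ANOVA"
    mean_p: float | None = None
    rank_test: str | None = None        # "Mann-Whitney U" or "Kruskal-Wallis"
    rank_p: float | None = None
    skipped: dict[str, str] = field(default_factory=dict)


def group_tests(records: pd.DataFrame, group_by: str, variable: str) -> GroupTestReport:
    groups = {
        str(k): sub[variable].dropna().to_numpy(dtype=float)
        for k, sub in records.groupby(group_by, observed=True)
    }
    report = GroupTestReport(variable=variable, group_sizes={k: len(v) for k, v in groups.items()})
    usable = {k: v for k, v in groups.items() if len(v) >= 2}
    for k in groups:
        if k not in usable:
            report.skipped[k] = f"group {k!r} has n<2, excluded from tests"
    arrays = list(usable.values())
    if len(arrays) < 2:
        report.skipped["_all"] = "fewer than two groups with n>=2"
        return report
    if len(arrays) == 2:
        report.mean_test = "t-test"
        report.mean_p = float(sps.ttest_ind(*arrays, equal_var=True).pvalue)
        report.rank_test = "Mann-Whitney U"
        report.rank_p = float(sps.mannwhitneyu(*arrays, alternative="two-sided").pvalue)
    else:
        report.mean_test = "ANOVA"
        report.mean_p = float(sps.f_oneway(*arrays).pvalue)
        report.rank_test = "Kruskal-Wallis"
        report.rank_p = float(sps.kruskal(*arrays).pvalue)
    return report


# ---------------------------------------------------------------------------
# Cohort tables (the shapes used in the report stage)

def msi_vs_nonmsih(row) -> str:
    return "MSI-H" if row["msi"] == "MSI-H" else "non-MSI-H"


def aberration_summary_tables(clinical: pd.DataFrame) -> dict[str, list[GroupSummary]]:
    """Aberration-count group summaries by sex, location, stage, MSI (three
    groups) and MSI-H vs rest (two groups)."""
    return {
        "sex": group_summary(clinical, "sex", "aberration_count"),
        "location": group_summary(clinical, "location", "aberration_count"),
        "stage": group_summary(clinical, "stage", "aberration_count"),
        "msi": group_summary(clinical, "msi", "aberration_count"),
        "msi2": group_summary(clinical, msi_vs_nonmsih, "aberration_count"),
    }


def msi_association_table(clinical: pd.DataFrame) -> dict:
    """Age summaries and categorical associations stratified by MSI status:
    per-group age median/quartiles, sex / location / stage tallies, and the
    Pearson chi-square p for each categorical covariate."""
    out: dict = {"age": group_summary(clinical, "msi", "age")}
    out["age_tests"] = group_tests(clinical, "msi", "age")
    for cov in ("sex", "location", "stage"):
        tab = pd.crosstab(clinical[cov], clinical["msi"])
        tab = tab.reindex(columns=[m for m in MSI_LEVELS if m in tab.columns], fill_value=0)
        out[cov] = {"table": tab}
        try:
            stat, dof, p = pearson_chisq(tab.to_numpy())
            out[cov].update(stat=stat, df=dof, p=p)
        except ValueError as exc:
            out[cov].update(stat=None, df=None, p=None, reason=str(exc))
    counts = clinical["msi"].value_counts()
    out["tally"] = {m: int(counts.get(m, 0)) for m in MSI_LEVELS}
    return out
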