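"""Promoter-methylation frequency tables for the 15-gene MSP panel.

Per-gene methylation percentages and their associations with clinical
covariates (MSI status, sex, tumor location, differentiation, age group)
are computed from long-format methylated/unmethylated calls.  NA calls are
excluded gene-wise, matching how MSP panels report.  MSI is dichotomized as
MSI-H vs the rest: an MSI-L tumor is biologically far closer to MSS than
to MSI-H in this assay context, and the stratified sample sizes of the
reference cohort only add up under that reading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import pearson_chisq
from scipy import stats as sps

GENE_PANEL = (
    "P16", "hMLH1", "SYNE1", "RNF182", "MMP2", "ICAM5", "CHD5", "CD109",
    "GPNMB", "EVL", "RET", "STARD8", "LGR6", "PTPRD", "APC2",
)
STATES = ("M", "U", "NA")

COVARIATES = ("msi", "sex", "location", "differentiation", "age_group")


@dataclass
class StratifiedFrequencyRow:
    """One gene x covariate row: per-stratum methylation percent and the
    chi-square (or Fisher) association p-value."""

    gene: str
    covariate: str
    percents: dict[str, float]       # stratum -> % methylated among evaluable
    counts: dict[str, tuple[int, int]]  # stratum -> (n methylated, n evaluable)
    p: float | None
    test: str                        # chi-square / Fisher exact / none
    note: str = ""


def _evaluable(calls: pd.DataFrame, gene: str) -> pd.DataFrame:
    sub = calls[(calls["gene"] == gene) & (calls["state"] != "NA")]
    return sub.dropna(subset=["state"])


def methylation_frequency(calls: pd.DataFrame, gene: str, subset=None) -> float:
    """Percent of evaluable samples (state M or U) with state M, to one
    decimal (round-half-even).  Returns NaN (with a warning) when no sample
    is evaluable."""
    sub = _evaluable(calls, gene)
    if subset is not None:
        sub = sub[sub["sample"].isin(set(subset))]
    n = len(sub)
    if n == 0:
        warnings.warn(f"{gene}: no evaluable samples in subset", stacklevel=2)
        return float("nan")
    return round(100.0 * (sub["state"] == "M").sum() / n, 1)


def add_age_group(clinical: pd.DataFrame, cutoff: int = 60) -> pd.DataFrame:
    out = clinical.copy()
    out["age_group"] = np.where(out["age"] < cutoff, f"<{cutoff}", f">={cutoff}")
    return out


def dichotomize_msi(clinical: pd.DataFrame) -> pd.DataFrame:
    out = clinical.copy()
    out["msi"] = np.where(out["msi"] == "MSI-H", "MSI-H", "non-MSI-H")
    return out


def stratified_association(
    calls: pd.DataFrame, clinical: pd.DataFrame, gene: str, covariate: str
) -> StratifiedFrequencyRow:
    """2 x k association of methylated/unmethylated with a categorical
    covariate.  Pearson chi-square without continuity correction; Fisher's
    exact test is substituted (and flagged) for 2x2 tables with an expected
    cell below 1; a table with no variation in state yields p = None."""
    sub = _evaluable(calls, gene).merge(
        clinical[["sample", covariate]], on="sample", how="inner"
    )
    strata = sorted(sub[covariate].astype(str).unique())
    percents, counts = {}, {}
    for s in strata:
        block = sub[sub[covariate].astype(str) == s]
        n = len(block)
        m = int((block["state"] == "M").sum())
        counts[s] = (m, n)
        percents[s] = round(100.0 * m / n, 1) if n else float("nan")
    tab = np.array([[m, n - m] for s, (m, n) in counts.items()], dtype=float).T
    row = StratifiedFrequencyRow(gene, covariate, percents, counts, None, "none")
    if tab.size == 0 or len(strata) < 2:
        row.note = "fewer than two strata"
        return row
    if tab.sum(axis=1).min() == 0:
        row.note = "no variation in methylation state"
        return row
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
    if tab.shape == (2, 2) and expected.min() < 1.0:
        row.test = "Fisher exact"
        row.note = "expected cell < 1; Fisher exact substituted"
        row.p = float(sps.fisher_exact(tab)[1])
    else:
        row.test = "chi-square"
        if expected.min() < 1.0:
            row.note = "expected cell < 1 in 2xk table; chi-square approximate"
        _, _, row.p = pearson_chisq(tab)
    return row


def methylation_table(calls: pd.DataFrame, clinical: pd.DataFrame) -> pd.DataFrame:
    """Full panel x covariate table: per-gene overall frequency plus each
    stratified association, one output row per (gene, covariate, stratum)."""
    clin = dichotomize_msi(add_age_group(clinical))
    rows = []
    genes = [g for g in GENE_PANEL if g in set(calls["gene"])]
    for gene in genes:
        overall = methylation_frequency(calls, gene)
        for cov in COVARIATES:
            if cov not in clin.columns:
                continue
            res = stratified_association(calls, clin, gene, cov)
            for stratum, pct in res.percents.items():
                m, n = res.counts[stratum]
                rows.append(
                    {"gene": gene, "overall_pct": overall, "covariate": cov,
                     "stratum": stratum, "pct_methylated": pct,
                     "n_methylated": m, "n_evaluable": n,
                     "p": res.p, "test": res.test, "note": res.note}
                )
    return pd.DataFrame(rows)


def read_methylation_calls(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "gene": str, "state": str})
    df["state"] = df["state"].fillna("NA")
    bad = set(df["state"]) - set(STATES)
    if bad:
        raise ValueError(f"bad methylation states in {path}: {sorted(bad)}")
    return df
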