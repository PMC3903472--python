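"""Synthetic colorectal-tumor cohorts with planted, recoverable structure.

The generator emulates the statistical skeleton of a 27-tumor integrative
study: MSI status drawn from cohort proportions; per-MSI-group aberration
counts (negative binomial — the observed per-tumor counts span 1 to ~800,
far too dispersed for a Poisson); right-sided location strongly enriched
in MSI-H tumors; p16/MLH1 promoter methylation concentrated in MSI-H;
chromosome X events directed by sex (amplified in males, deleted in
females); and optional planted clades of identical shared aberrations that
a parsimony analysis should recover.  Probe-level log2-ratio tracks are
emitted on a regular grid so the segmentation stage can be exercised
end-to-end.

Everything is driven by one seeded generator with per-sample substreams,
so cohorts are byte-reproducible and partially regenerable.  The planted
truth is written as a separate sidecar file that no analysis stage reads.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import CHROMOSOMES, CHROM_ORDER
from .methylation import GENE_PANEL
from .msi import PANEL as MSI_PANEL

MSI_GROUPS = ("MSS", "MSI-L", "MSI-H")

# Default per-gene methylation probabilities, (MSI-H, non-MSI-H), anchored
# to the observed stratified frequencies of the reference cohort.
DEFAULT_METHYLATION_PROB: dict[str, tuple[float, float]] = {
    "P16": (0.60, 0.045), "hMLH1": (0.80, 0.045), "SYNE1": (1.0, 1.0),
    "RNF182": (0.0, 0.0), "MMP2": (1.0, 1.0), "ICAM5": (0.20, 0.045),
    "CHD5": (0.80, 0.364), "CD109": (0.20, 0.318), "GPNMB": (0.60, 0.864),
    "EVL": (1.0, 0.773), "RET": (0.20, 0.409), "STARD8": (0.60, 0.591),
    "LGR6": (0.60, 0.273), "PTPRD": (0.80, 0.818), "APC2": (1.0, 0.864),
}

# Stage distribution per MSI group (stages 1-4), from the reference cohort.
DEFAULT_STAGE_PROBS = {
    "MSS": (3 / 18, 8 / 18, 7 / 18, 0.0),
    "MSI-L": (1 / 4, 3 / 4, 0.0, 0.0),
    "MSI-H": (2 / 5, 2 / 5, 1 / 5, 0.0),
}
DEFAULT_DIFF_PROBS = (16 / 27, 10 / 27, 1 / 27)  # Well / Moderately / Poorly
DIFF_LEVELS = ("Well", "Moderately", "Poorly")

# Group age means (years): stable tumors oldest, MSI-L notably younger.
DEFAULT_AGE_MEAN = {"MSS": 63.0, "MSI-L": 40.0, "MSI-H": 57.0}
DEFAULT_AGE_SD = 12.0


def _validate_prob(name: str, p: float) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {p}")


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    ``aberration_count_params`` maps MSI group -> (mean, dispersion); the
    negative binomial used has variance mean + mean^2 / dispersion.
    ``planted_clades`` is a list of (member sample indices, number of
    shared aberrations) pairs.
    """

    n_samples: int = 27
    msi_proportions: tuple[float, float, float] = (18 / 27, 4 / 27, 5 / 27)
    aberration_count_params: dict = field(default_factory=lambda: {
        "MSS": (37.0, 0.8), "MSI-L": (256.0, 0.8), "MSI-H": (10.0, 0.8)})
    right_side_prob_by_group: dict = field(default_factory=lambda: {
        "MSS": 1 / 18, "MSI-L": 0.0, "MSI-H": 0.8})
    methylation_prob: dict = field(
        default_factory=lambda: dict(DEFAULT_METHYLATION_PROB))
    sexlinked_X_effect: float = 0.9
    planted_clades: list = field(default_factory=list)
    probe_spacing_bp: int = 25_000
    noise_sd: float = 0.2
    interval_length_range: tuple[int, int] = (50_000, 200_000)
    gain_fold_range: tuple[float, float] = (1.3, 3.0)
    loss_fold_range: tuple[float, float] = (0.3, 0.7)
    emit_probe_tracks: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 0:
            raise ValueError(f"n_samples must be non-negative, got {self.n_samples}")
        if len(self.msi_proportions) != 3:
            raise ValueError("msi_proportions must have 3 entries (MSS, MSI-L, MSI-H)")
        if abs(sum(self.msi_proportions) - 1.0) > 1e-9:
            raise ValueError(
                f"msi_proportions must sum to 1, got {sum(self.msi_proportions)}")
        for i, p in enumerate(self.msi_proportions):
            _validate_prob(f"msi_proportions[{i}]", p)
        for g in MSI_GROUPS:
            mean, disp = self.aberration_count_params[g]
            if mean <= 0 or disp <= 0:
                raise ValueError(f"aberration_count_params[{g}] must be positive")
            _validate_prob(f"right_side_prob_by_group[{g}]",
                           self.right_side_prob_by_group[g])
        for gene, (p_h, p_rest) in self.methylation_prob.items():
            _validate_prob(f"methylation_prob[{gene}][MSI-H]", p_h)
            _validate_prob(f"methylation_prob[{gene}][rest]", p_rest)
        _validate_prob("sexlinked_X_effect", self.sexlinked_X_effect)
        if self.probe_spacing_bp <= 0:
            raise ValueError(f"probe_spacing_bp must be positive, got {self.probe_spacing_bp}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be non-negative, got {self.noise_sd}")
        for members, k in self.planted_clades:
            if k <= 0:
                raise ValueError("planted clade must share at least one aberration")
            if any(not 0 <= i < self.n_samples for i in members):
                raise ValueError("planted clade member index out of range")


@dataclass
class SyntheticCohort:
    config: CohortConfig
    samples: pd.DataFrame             # clinical covariates (+ msi, aberration_count)
    interval_reports: pd.DataFrame    # sample, chrom, start, end, fold_change, n_probes
    probe_tracks: pd.DataFrame | None  # sample, chrom, pos, log2_ratio
    msi_marker_calls: pd.DataFrame    # sample + the 5 panel markers
    methylation_calls: pd.DataFrame   # sample, gene, state
    truth: dict


def _sample_names(n: int) -> list[str]:
    return [f"S{i + 1:03d}" for i in range(n)]


def _draw_interval(rng: np.random.Generator, spacing: int,
                   length_range: tuple[int, int]) -> tuple[str, int, int]:
    chrom = CHROM_ORDER[rng.integers(len(CHROM_ORDER))]
    clen = CHROMOSOMES[chrom]
    n_probes = max(1, int(rng.integers(length_range[0] // spacing,
                                       length_range[1] // spacing + 1)))
    length = n_probes * spacing
    start = int(rng.integers(0, max(1, (clen - length) // spacing))) * spacing
    return chrom, start, start + length


def _cells(chrom: str, start: int, end: int, spacing: int):
    """Grid cells covered by a grid-aligned interval (overlap bookkeeping)."""
    return [(chrom, p) for p in range(start // spacing, end // spacing)]


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one cohort per the config; identical configs (including
    seed) yield identical cohorts."""
    config.validate()
    n = config.n_samples
    root_ss = np.random.SeedSequence(config.seed)
    master = np.random.default_rng(root_ss)
    sample_rngs = [np.random.default_rng(ss) for ss in root_ss.spawn(n)]
    names = _sample_names(n)
    spacing = config.probe_spacing_bp

    # ---- planted clade characters (shared identical intervals), drawn from
    # the master stream so they are independent of per-sample substreams
    clade_keys: list[list[tuple[str, int, int, str, float]]] = []
    clade_cells: set[tuple[str, int]] = set()
    for members, k in config.planted_clades:
        keys = []
        while len(keys) < k:
            chrom, start, end = _draw_interval(master, spacing, config.interval_length_range)
            cells = _cells(chrom, start, end, spacing)
            if any(c in clade_cells for c in cells):
                continue
            clade_cells.update(cells)
            if master.random() < 0.5:
                direction, fold = "gain", float(master.uniform(*config.gain_fold_range))
            else:
                direction, fold = "loss", float(master.uniform(*config.loss_fold_range))
            keys.append((chrom, start, end, direction, fold))
        clade_keys.append(keys)

    msi_status = [MSI_GROUPS[i] for i in master.choice(
        3, size=n, p=np.asarray(config.msi_proportions, dtype=float))]

    clinical_rows, interval_rows, marker_rows, meth_rows = [], [], [], []
    truth_samples = []

    for i, (name, rng) in enumerate(zip(names, sample_rngs)):
        group = msi_status[i]
        sex = "M" if rng.random() < 0.5 else "F"
        age = int(np.clip(round(rng.normal(DEFAULT_AGE_MEAN[group], DEFAULT_AGE_SD)), 25, 90))
        stage = int(rng.choice(4, p=DEFAULT_STAGE_PROBS[group])) + 1
        location = "R" if rng.random() < config.right_side_prob_by_group[group] else "L"
        differentiation = DIFF_LEVELS[int(rng.choice(3, p=DEFAULT_DIFF_PROBS))]

        # planted clade intervals first: members always carry all of them.
        # Background placement rejects any interval touching a grid cell
        # already occupied in this sample, or any clade cell anywhere, which
        # both keeps intervals non-overlapping and makes planted clade
        # characters exclusive to their members.
        intervals: list[tuple[str, int, int, str, float]] = []
        occupied: set[tuple[str, int]] = set(clade_cells)
        my_clades = [ci for ci, (members, _) in enumerate(config.planted_clades)
                     if i in members]
        for ci in my_clades:
            intervals.extend(clade_keys[ci])

        mean, disp = config.aberration_count_params[group]
        n_background = int(rng.negative_binomial(disp, disp / (disp + mean)))
        placed = 0
        attempts = 0
        while placed < n_background and attempts < 20 * n_background + 100:
            attempts += 1
            chrom, start, end = _draw_interval(rng, spacing, config.interval_length_range)
            cells = _cells(chrom, start, end, spacing)
            if any(c in occupied for c in cells):
                continue
            occupied.update(cells)
            if chrom == "chrX":
                amplified = (sex == "M") == (rng.random() < config.sexlinked_X_effect)
                direction = "gain" if amplified else "loss"
            else:
                direction = "gain" if rng.random() < 0.5 else "loss"
            fold = float(rng.uniform(*(config.gain_fold_range if direction == "gain"
                                       else config.loss_fold_range)))
            intervals.append((chrom, start, end, direction, fold))
            placed += 1

        for chrom, start, end, direction, fold in intervals:
            interval_rows.append(
                {"sample": name, "chrom": chrom, "start": start, "end": end,
                 "fold_change": fold, "n_probes": (end - start) // spacing})

        clinical_rows.append(
            {"sample": name, "age": age, "sex": sex, "stage": stage,
             "location": location, "differentiation": differentiation,
             "msi": group, "aberration_count": len(intervals)})

        # MSI marker calls consistent with the group
        if group == "MSI-H":
            n_unstable = 2 + int(rng.binomial(3, 0.4))
        elif group == "MSI-L":
            n_unstable = 1
        else:
            n_unstable = 0
        unstable = set(rng.choice(len(MSI_PANEL), size=n_unstable, replace=False).tolist())
        marker_rows.append(
            {"sample": name, **{m: ("unstable" if j in unstable else "stable")
                                for j, m in enumerate(MSI_PANEL)}})

        for gene in GENE_PANEL:
            p_h, p_rest = config.methylation_prob.get(gene, (0.0, 0.0))
            p = p_h if group == "MSI-H" else p_rest
            meth_rows.append({"sample": name, "gene": gene,
                              "state": "M" if rng.random() < p else "U"})

        truth_samples.append(
            {"sample": name, "msi": group, "n_intervals": len(intervals),
             "n_background_drawn": n_background, "n_background_placed": placed,
             "clades": my_clades})

    samples = pd.DataFrame(
        clinical_rows,
        columns=["sample", "age", "sex", "stage", "location",
                 "differentiation", "msi", "aberration_count"])
    interval_reports = pd.DataFrame(
        interval_rows,
        columns=["sample", "chrom", "start", "end", "fold_change", "n_probes"])
    marker_calls = pd.DataFrame(marker_rows, columns=["sample", *MSI_PANEL])
    methylation_calls = pd.DataFrame(meth_rows, columns=["sample", "gene", "state"])

    probe_tracks = None
    if config.emit_probe_tracks:
        tracks = []
        for name, rng in zip(names, sample_rngs):
            sub = interval_reports[interval_reports["sample"] == name]
            track = emit_probe_track(
                sub[["chrom", "start", "end", "fold_change"]],
                config.probe_spacing_bp, config.noise_sd,
                rng=np.random.default_rng(rng.integers(2 ** 31)))
            track.insert(0, "sample", name)
            tracks.append(track)
        probe_tracks = (pd.concat(tracks, ignore_index=True) if tracks
                        else pd.DataFrame(columns=["sample", "chrom", "pos", "log2_ratio"]))

    truth = {
        "config": _config_to_dict(config),
        "samples": truth_samples,
        "clades": [
            {"members": [names[i] for i in members],
             "characters": [
                 {"chrom": c, "start": s, "end": e, "direction": d, "fold": f}
                 for c, s, e, d, f in keys]}
            for (members, _), keys in zip(config.planted_clades, clade_keys)],
    }
    return SyntheticCohort(config, samples, interval_reports, probe_tracks,
                           marker_calls, methylation_calls, truth)


def emit_probe_track(
    intervals: pd.DataFrame,
    probe_spacing_bp: int,
    noise_sd: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Probe log2-ratios on a regular grid for one sample.

    Probes sit at multiples of the spacing on every chromosome; a probe
    inside an aberrant interval reads log2(fold_change) plus Gaussian
    noise, elsewhere noise only.  Intervals must be non-overlapping per
    chromosome.
    """
    if probe_spacing_bp <= 0:
        raise ValueError(f"probe_spacing_bp must be positive, got {probe_spacing_bp}")
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {noise_sd}")
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    by_chrom = {c: sub.sort_values("start") for c, sub in intervals.groupby("chrom")}
    for chrom, sub in by_chrom.items():
        prev_end = None
        for r in sub.itertuples(index=False):
            if prev_end is not None and r.start < prev_end:
                raise ValueError(f"overlapping intervals on {chrom}")
            prev_end = r.end
    for chrom in CHROM_ORDER:
        clen = CHROMOSOMES[chrom]
        pos = np.arange(0, clen, probe_spacing_bp, dtype=np.int64)
        log2 = (rng.normal(0.0, noise_sd, size=len(pos)) if noise_sd > 0
                else np.zeros(len(pos)))
        if chrom in by_chrom:
            for r in by_chrom[chrom].itertuples(index=False):
                covered = (pos >= r.start) & (pos < r.end)
                log2[covered] += np.log2(r.fold_change)
        rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "log2_ratio": log2}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Cohort I/O

_FILES = {
    "clinical": "clinical.tsv",
    "intervals": "intervals.tsv",
    "msi_markers": "msi_markers.tsv",
    "methylation": "methylation.tsv",
    "probes": "probe_tracks.tsv",
    "truth": "truth.json",
}


def _config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    d["planted_clades"] = [[list(m), int(k)] for m, k in config.planted_clades]
    return d


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort as tab-separated text files plus a truth sidecar
    (truth.json) that analysis stages never read.  The clinical table keeps
    only the covariate columns; MSI status and aberration counts are left
    to be re-derived from the marker calls and interval reports."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in _FILES.items()}
    clinical_cols = ["sample", "age", "sex", "stage", "location", "differentiation"]
    cohort.samples[clinical_cols].to_csv(paths["clinical"], sep="\t", index=False)
    cohort.interval_reports.to_csv(paths["intervals"], sep="\t", index=False)
    cohort.msi_marker_calls.to_csv(paths["msi_markers"], sep="\t", index=False)
    cohort.methylation_calls.to_csv(paths["methylation"], sep="\t", index=False)
    if cohort.probe_tracks is not None:
        cohort.probe_tracks.to_csv(paths["probes"], sep="\t", index=False,
                                   float_format="%.10g")
    else:
        paths.pop("probes")
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
    return paths


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Read back a written cohort (truth deliberately excluded)."""
    directory = Path(directory)
    clinical = pd.read_csv(directory / _FILES["clinical"], sep="\t",
                           dtype={"sample": str})
    intervals = pd.read_csv(directory / _FILES["intervals"], sep="\t",
                            dtype={"sample": str, "chrom": str})
    markers = pd.read_csv(directory / _FILES["msi_markers"], sep="\t",
                          dtype=str)
    methylation = pd.read_csv(directory / _FILES["methylation"], sep="\t",
                              dtype=str)
    probes_path = directory / _FILES["probes"]
    probes = (pd.read_csv(probes_path, sep="\t", dtype={"sample": str, "chrom": str})
              if probes_path.exists() else None)
    return SyntheticCohort(
        config=None, samples=clinical, interval_reports=intervals,
        probe_tracks=probes, msi_marker_calls=markers,
        methylation_calls=methylation, truth=None)


def read_truth(directory: str | Path) -> dict:
    with open(Path(directory) / _FILES["truth"]) as fh:
        return json.load(fh)
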