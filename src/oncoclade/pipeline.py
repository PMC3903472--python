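"""End-to-end orchestration: simulate/load -> call -> classify -> tabulate ->
matrix -> parsimony -> report, with a run manifest for reproducibility."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import cgh, matrix as mx, methylation as meth, msi as msimod, parsimony, stats
from .synthetic import CohortConfig, generate_cohort, read_cohort, write_cohort

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, completed: list[str], cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed after {completed}: {cause}")
        self.stage = stage
        self.completed = completed


@dataclass
class PipelineConfig:
    """Inputs are either a cohort directory (the simulator's file layout), a
    simulation config, or — for statistics-only runs — a clinical table that
    already carries MSI status and aberration counts."""

    out_dir: Path
    input_dir: Path | None = None
    simulate: CohortConfig | None = None
    clinical_table: Path | None = None        # stats-only mode
    annotation: Path | None = None            # BED gene panel (optional)
    gain_fold: float = cgh.GAIN_FOLD
    loss_fold: float = cgh.LOSS_FOLD
    window_bp: float = cgh.DEFAULT_WINDOW_BP
    z_threshold: float = cgh.DEFAULT_Z_THRESHOLD
    segment_from_probes: bool = False
    matrix_mode: str = "interval"
    merge_tolerance_bp: int = 0
    parsimony_method: str = "auto"
    parsimony_model: str = "wagner"
    seed: int = 0
    n_starts: int = 10

    def validate(self) -> None:
        if not self.loss_fold < 1.0 < self.gain_fold:
            raise ValueError("thresholds must satisfy loss_fold < 1 < gain_fold")
        modes = [self.input_dir, self.simulate, self.clinical_table]
        if sum(x is not None for x in modes) != 1:
            raise ValueError("exactly one of input_dir / simulate / clinical_table required")
        for p in (self.input_dir, self.clinical_table, self.annotation):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"input path does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    input_checksums: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    completed_stages: list = field(default_factory=list)
    skipped_stages: dict = field(default_factory=dict)
    finalized: bool = False

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=str)


def run_pipeline(config: PipelineConfig) -> Path:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = dataclasses.asdict(config)
    if config.simulate is not None:
        cfg_dict["simulate"] = dataclasses.asdict(config.simulate)
    manifest = RunManifest(config=cfg_dict)
    for p in (config.input_dir, config.clinical_table, config.annotation):
        if p is not None and Path(p).is_file():
            manifest.input_checksums[str(p)] = _sha256(Path(p))
        elif p is not None:
            for f in sorted(Path(p).glob("*")):
                if f.is_file():
                    manifest.input_checksums[str(f)] = _sha256(f)
    manifest_path = out / "manifest.json"
    manifest.write(manifest_path)

    def stage(name: str):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:
                manifest.write(manifest_path)
                raise PipelineError(name, manifest.completed_stages, exc) from exc
            manifest.completed_stages.append(name)
            return result
        return deco

    # ---- stats-only mode -------------------------------------------------
    if config.clinical_table is not None:
        @stage("load_clinical")
        def clinical():
            df = pd.read_csv(config.clinical_table, sep="\t", dtype={"sample": str})
            manifest.stage_counts["clinical_rows"] = len(df)
            return df

        @stage("cohort_tables")
        def _tables():
            return _write_cohort_tables(clinical, out)

        for s in ("cgh_calling", "msi", "methylation", "matrix", "parsimony"):
            manifest.skipped_stages[s] = "statistics-only mode: no raw CGH/marker data supplied"
            log.info("skipping stage %s: %s", s, manifest.skipped_stages[s])

        @stage("report")
        def _report():
            text = report_tables(out)
            (out / "report.txt").write_text(text)

        manifest.finalized = True
        manifest.write(manifest_path)
        return out

    # ---- full pipeline ---------------------------------------------------
    @stage("acquire")
    def cohort():
        if config.simulate is not None:
            c = generate_cohort(config.simulate)
            write_cohort(c, out / "cohort")
            return c
        return read_cohort(config.input_dir)

    @stage("cgh_calling")
    def calls():
        if config.segment_from_probes:
            if cohort.probe_tracks is None:
                raise ValueError("segment_from_probes requires probe tracks")
            raw = []
            for sample, sub in cohort.probe_tracks.groupby("sample"):
                raw.extend(cgh.segment_probes(sub, config.window_bp,
                                              config.z_threshold, sample=sample))
            fc = cgh.filter_by_fold(raw, config.gain_fold, config.loss_fold)
        else:
            fc = cgh.filter_by_fold(cohort.interval_reports,
                                    config.gain_fold, config.loss_fold)
        cgh.write_calls(fc, out / "calls.tsv")
        manifest.stage_counts["aberration_calls"] = len(fc)
        return fc

    @stage("msi")
    def statuses():
        recs = [
            msimod.MsiMarkerCalls(str(r["sample"]),
                                  {m: r[m] for m in msimod.PANEL})
            for _, r in cohort.msi_marker_calls.iterrows()
        ]
        st = [msimod.classify_msi(r) for r in recs]
        msimod.write_status_table(st, out / "msi.tsv")
        manifest.stage_counts["msi_classified"] = len(st)
        return st

    @stage("clinical_merge")
    def clinical():
        df = cohort.samples.copy()
        status = {s.sample: s.status for s in statuses}
        df["msi"] = df["sample"].astype(str).map(status)
        totals = cgh.per_sample_totals(calls, samples=df["sample"].astype(str))
        df["aberration_count"] = df["sample"].astype(str).map(totals)
        df.to_csv(out / "clinical_derived.tsv", sep="\t", index=False)
        return df

    @stage("methylation")
    def _meth():
        table = meth.methylation_table(cohort.methylation_calls, clinical)
        table.to_csv(out / "methylation_table.tsv", sep="\t", index=False)
        manifest.stage_counts["methylation_rows"] = len(table)

    if config.annotation is None:
        manifest.skipped_stages["gene_events"] = "no annotation supplied"
    else:
        @stage("gene_events")
        def _genes():
            ann = cgh.read_gene_annotation(config.annotation)
            events = cgh.intersect_genes(calls, ann)
            pd.DataFrame(
                [{"sample": e.sample, "gene": e.gene, "direction": e.direction}
                 for e in events],
                columns=["sample", "gene", "direction"],
            ).to_csv(out / "gene_events.tsv", sep="\t", index=False)
            manifest.stage_counts["gene_events"] = len(events)

    @stage("chromosome_summary")
    def _chrom():
        tab = cgh.chromosome_summary(calls, clinical)
        tab.rename_axis("chrom").to_csv(out / "chromosome_summary.tsv", sep="\t")

    @stage("cohort_tables")
    def _tables():
        _write_cohort_tables(clinical, out)

    n_samples = len(clinical)
    if n_samples < 3:
        for s in ("matrix", "parsimony"):
            manifest.skipped_stages[s] = f"only {n_samples} samples; tree inference needs >=3"
    else:
        @stage("matrix")
        def matrix_obj():
            per_sample = {s: [] for s in clinical["sample"].astype(str)}
            for c in calls:
                per_sample[str(c.sample)].append(c)
            m = mx.build_matrix(per_sample, config.merge_tolerance_bp,
                                mode=config.matrix_mode)
            mx.write_phylip_discrete(m, out / "aberrations.phy")
            mx.write_character_map(m, out / "character_map.tsv")
            manifest.stage_counts["matrix_shape"] = list(m.shape)
            return m

        @stage("parsimony")
        def _pars():
            res = parsimony.search(matrix_obj, method=config.parsimony_method,
                                   model=config.parsimony_model,
                                   seed=config.seed, n_starts=config.n_starts)
            clad = parsimony.root_and_annotate(res.exemplar(), matrix_obj,
                                               model=config.parsimony_model)
            (out / "cladogram.nwk").write_text(clad.newick() + "\n")
            clad.node_table(matrix_obj).to_csv(out / "cladogram_nodes.tsv",
                                               sep="\t", index=False)
            rooted = [parsimony.root_and_annotate(t, matrix_obj,
                                                  model=config.parsimony_model)
                      for t in res.trees]
            cons = parsimony.strict_consensus(rooted)
            parsimony.annotate_strict(cons, matrix_obj)
            (out / "consensus.nwk").write_text(cons.newick() + "\n")
            manifest.stage_counts["parsimony"] = {
                "best_length": res.best_length, "n_optimal_trees": len(res.trees),
                "method": res.method, "tree_cap_hit": res.tree_cap_hit}

    @stage("report")
    def _report():
        text = report_tables(out)
        (out / "report.txt").write_text(text)

    manifest.finalized = True
    manifest.write(manifest_path)
    return out


def _fmt(x: float) -> str:
    if x == int(x):
        return str(int(x))
    return f"{x:g}"


def _write_cohort_tables(clinical: pd.DataFrame, out: Path) -> None:
    summaries = stats.aberration_summary_tables(clinical)
    rows = []
    for key, groups in summaries.items():
        rep = stats.group_tests(
            clinical if key != "msi2" else clinical.assign(
                msi2=clinical["msi"].where(clinical["msi"] == "MSI-H", "non-MSI-H")),
            {"sex": "sex", "location": "location", "stage": "stage",
             "msi": "msi", "msi2": "msi2"}[key],
            "aberration_count")
        for g in groups:
            rows.append({"stratifier": key, "group": g.group, "n": g.n,
                         "median": g.median, "q1": g.q1, "q3": g.q3,
                         "mean_test": rep.mean_test, "mean_p": rep.mean_p,
                         "rank_test": rep.rank_test, "rank_p": rep.rank_p})
    pd.DataFrame(rows, columns=["stratifier", "group", "n", "median", "q1", "q3",
                                "mean_test", "mean_p", "rank_test", "rank_p"]
                 ).to_csv(out / "aberration_summaries.tsv", sep="\t", index=False)

    msiinfo = stats.msi_association_table(clinical)
    rows = []
    for g in msiinfo["age"]:
        rows.append({"block": "age", "group": g.group, "n": g.n,
                     "median": g.median, "q1": g.q1, "q3": g.q3,
                     "p": msiinfo["age_tests"].mean_p})
    for cov in ("sex", "location", "stage"):
        tab = msiinfo[cov]["table"]
        for level in tab.index:
            for m in tab.columns:
                rows.append({"block": cov, "group": f"{level}|{m}",
                             "n": int(tab.loc[level, m]), "p": msiinfo[cov].get("p")})
    pd.DataFrame(rows, columns=["block", "group", "n", "median", "q1", "q3", "p"]
                 ).to_csv(out / "msi_associations.tsv", sep="\t", index=False)


def report_tables(out_dir: str | Path) -> str:
    """Render the pipeline's output tables as aligned text with
    known-formatting footnotes."""
    out = Path(out_dir)
    blocks: list[str] = [f"oncoclade v{__version__} run report", ""]

    clin_path = out / "clinical_derived.tsv"
    if not clin_path.exists():
        clin_path = None
        # statistics-only runs tabulate the supplied clinical table directly

    summ_path = out / "aberration_summaries.tsv"
    if summ_path.exists():
        df = pd.read_csv(summ_path, sep="\t")
        if df.empty:
            blocks.append("Aberration counts: no samples")
        else:
            blocks.append("Aberration counts by group: median (25-75% interquantile)")
            for _, r in df.iterrows():
                blocks.append(
                    f"  {r['stratifier']:<9} {str(r['group']):<10} n={r['n']:<3} "
                    f"{_fmt(r['median'])} ({_fmt(r['q1'])}–{_fmt(r['q3'])})")
            blocks.append("")

    msi_path = out / "msi_associations.tsv"
    if msi_path.exists():
        df = pd.read_csv(msi_path, sep="\t")
        if not df.empty:
            blocks.append("MSI associations (age medians and category tallies)")
            for _, r in df.iterrows():
                if r["block"] == "age":
                    blocks.append(
                        f"  age {str(r['group']):<10} n={r['n']:<3} "
                        f"{_fmt(r['median'])} ({_fmt(r['q1'])}–{_fmt(r['q3'])})")
                else:
                    blocks.append(f"  {r['block']:<9} {str(r['group']):<14} n={int(r['n'])}")
            blocks.append("")

    chrom_path = out / "chromosome_summary.tsv"
    if chrom_path.exists():
        df = pd.read_csv(chrom_path, sep="\t")
        blocks.append("Aberrations per chromosome (total = amplifications + deletions)")
        ok = (df["total"] == df["amplifications"] + df["deletions"]).all()
        blocks.append(df.to_string(index=False))
        blocks.append(f"  row-sum check (total = amp + del): {'PASS' if ok else 'FAIL'}")
        blocks.append("")

    nwk = out / "cladogram.nwk"
    if nwk.exists():
        blocks.append("Cladogram (Newick, internal nodes labeled in preorder):")
        blocks.append("  " + nwk.read_text().strip())
        blocks.append("")

    if summ_path.exists() and pd.read_csv(summ_path, sep="\t").empty:
        pass
    elif not summ_path.exists():
        blocks.append("no samples")

    blocks.append(
        "Note: quantiles use the rank p*(n+1) interpolation rule; printed\n"
        "reference values that truncate a repeating decimal (e.g. 256 for\n"
        "256.5, 713.7 for 713.75, 148 for 148.75) are known formatting\n"
        "discrepancies, not numerical ones.")
    return "\n".join(blocks) + "\n"
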