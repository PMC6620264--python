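"""Pipeline orchestration: sequential QC with removal, outputs, config.

The wrapper :func:`sample_qc` runs the five checks in order (missing ->
sex -> inbreeding -> IBD -> population), removing flagged study samples
from the cohort between steps, and writes per-step TSVs, the problematic
sample list, and a self-contained HTML report.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import popgen, qcsteps
from .store import (CaptureRegions, MergedCohort, check_annotation_covers,
                    load_store, merge_with_benchmark, read_capture_bed,
                    read_sample_annotation, read_vcf_biallelic_snv)

#: GRCh37 X-chromosome pseudo-autosomal regions (1-based inclusive)
PAR_GRCH37 = ((60001, 2699520), (154931044, 155260560))

STEP_ORDER = qcsteps.STEP_NAMES


@dataclass
class QCConfig:
    """All tunable thresholds of the pipeline, with their defaults."""

    missing_threshold: float = 0.1
    sex_f_female_max: float = 0.2
    sex_f_male_min: float = 0.8
    inbreeding_sd_multiplier: float = 5.0
    kinship_min: float = 0.08
    pca_components: int = 4
    ld_r2: float = 0.2
    ld_window_bp: int = 500_000
    benchmark_maf_min: float = 0.01
    par_intervals: tuple = PAR_GRCH37
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.missing_threshold <= 1):
            raise ValueError("missing_threshold must be in [0, 1]")
        if not (0 < self.ld_r2 <= 1):
            raise ValueError("ld_r2 must be in (0, 1]")
        if self.sex_f_female_max >= self.sex_f_male_min:
            raise ValueError("sex F thresholds out of order")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["par_intervals"] = ";".join(
            f"{a}-{b}" for a, b in self.par_intervals)
        return d

    @classmethod
    def from_file(cls, path) -> "QCConfig":
        """Flat key=value config file; '#' starts a comment."""
        kwargs = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(
                        f"{path}: line {lineno}: expected key=value")
                key, val = (t.strip() for t in line.split("=", 1))
                if key not in fields:
                    raise ValueError(
                        f"{path}: line {lineno}: unknown option {key!r}")
                if key == "par_intervals":
                    kwargs[key] = tuple(
                        tuple(int(x) for x in part.split("-"))
                        for part in val.split(";") if part)
                elif key in ("pca_components", "ld_window_bp", "seed"):
                    kwargs[key] = int(val)
                else:
                    kwargs[key] = float(val)
        return cls(**kwargs)


@dataclass
class ProblemList:
    """Ordered list of flagged samples with the step and reason."""

    records: list = field(default_factory=list)

    def add(self, sample_id: str, step: str, reason: str,
            metric: float = np.nan):
        self.records.append({"sample_id": sample_id, "failed_step": step,
                             "reason": reason, "metric": metric})

    @property
    def sample_ids(self) -> list:
        return [r["sample_id"] for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.records,
            columns=["sample_id", "failed_step", "reason", "metric"])

    def to_tsv(self, path) -> Path:
        path = Path(path)
        df = self.to_frame()
        df["metric"] = [("" if not np.isfinite(m) else f"{m:.10g}")
                        for m in df["metric"]]
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
        return path


def _metric_for(result: qcsteps.QCStepResult, sample_id: str) -> float:
    """Pull the headline metric of a flagged sample from the step table."""
    df = result.metrics
    col = {"missing": "missing_rate", "sex": "f_x",
           "inbreeding": "f_autosomal"}.get(result.step)
    if col is not None and "sample_id" in df.columns:
        hit = df.loc[df["sample_id"] == sample_id, col]
        if len(hit):
            return float(hit.iloc[0])
    if result.step == "ibd":
        hit = df.loc[(df["id_a"] == sample_id) | (df["id_b"] == sample_id)]
        hit = hit.loc[hit["predicted_related"]]
        if len(hit):
            return float(hit["kinship"].max())
    return np.nan


def prepare_cohort(vcf_path, bed_path, annotation_path, benchmark_path,
                   study_population: str | None = None,
                   config: QCConfig | None = None) -> MergedCohort:
    """Read all inputs, merge with the benchmark, and LD-prune.

    LD pruning is run once here, on all merged samples, and recorded in
    ``Variant.pruned_in``; the per-step metrics are recomputed on the
    surviving samples at each step.
    """
    config = config or QCConfig()
    capture = read_capture_bed(bed_path)
    gm, variants = read_vcf_biallelic_snv(vcf_path, capture)
    records = read_sample_annotation(annotation_path)
    check_annotation_covers(records, gm.sample_ids)
    by_id = {r.sample_id: r for r in records}
    records = [by_id[s] for s in gm.sample_ids]
    benchmark = load_store(benchmark_path)
    if study_population is None:
        pops = [r.population for r in records if r.population != "unknown"]
        study_population = (max(set(pops), key=pops.count)
                            if pops else "unknown")
    cohort = merge_with_benchmark((gm, variants, records), benchmark,
                                  capture, study_population)
    apply_ld_pruning(cohort, config)
    return cohort


def apply_ld_pruning(cohort: MergedCohort, config: QCConfig) -> None:
    """Set ``Variant.pruned_in`` from a greedy scan on autosomes."""
    auto = np.nonzero(cohort.autosomal_mask())[0]
    keep = popgen.ld_prune(
        cohort.genotypes.values[:, auto],
        cohort.chroms[auto], cohort.positions[auto],
        r2_threshold=config.ld_r2, window_bp=config.ld_window_bp)
    for v in cohort.variants:
        v.pruned_in = False
    for j, k in zip(auto, keep):
        cohort.variants[j].pruned_in = bool(k)


def run_single_step(step_name: str, cohort: MergedCohort,
                    config: QCConfig | None = None) -> qcsteps.QCStepResult:
    """Run exactly one QC check, with no removal side effects."""
    config = config or QCConfig()
    aliases = {"missingrate": "missing", "sexcheck": "sex",
               "pca": "population", "relatedness": "ibd"}
    key = aliases.get(step_name.strip().lower().replace("_", ""),
                      step_name.strip().lower())
    if key not in qcsteps.CHECKS:
        raise ValueError(
            f"unknown QC step {step_name!r}; choose from "
            f"{', '.join(STEP_ORDER)}")
    return qcsteps.CHECKS[key](cohort, config)


def run_all_steps(cohort: MergedCohort, config: QCConfig):
    """Sequentially run all five checks, removing flagged study samples
    before each subsequent step. Returns (ProblemList, [QCStepResult])."""
    problems = ProblemList()
    results = []
    current = cohort
    for step in STEP_ORDER:
        result = qcsteps.CHECKS[step](current, config)
        results.append(result)
        for sid, reason in result.flagged:
            problems.add(sid, step, reason, _metric_for(result, sid))
        if result.flagged:
            removed = set(result.flagged_ids)
            keep = [s for s in current.sample_ids if s not in removed]
            current = current.subset_samples(keep)
    return problems, results


def sample_qc(vcf_path, bed_path, annotation_path, benchmark_path,
              out_dir, study_population: str | None = None,
              config: QCConfig | None = None):
    """End-to-end sample QC: merge, run all five checks with sequential
    removal, and write the problem list, per-step TSVs and HTML report.

    Returns ``(ProblemList, report_path)``.
    """
    from . import report as report_mod

    config = config or QCConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = prepare_cohort(vcf_path, bed_path, annotation_path,
                            benchmark_path, study_population, config)
    problems, results = run_all_steps(cohort, config)
    for result in results:
        result.to_tsv(out_dir / f"step_{result.step}.tsv")
    problems.to_tsv(out_dir / "problem_samples.tsv")
    report_path = report_mod.render_report(results, config,
                                           out_dir / "report.html")
    return problems, report_path
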