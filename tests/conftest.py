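"""Shared fixtures: small simulated cohorts and a manual cohort builder."""

import numpy as np
import pytest

from cohortqc import QCConfig, SimSpec, simulate_cohort
from cohortqc.pipeline import prepare_cohort
from cohortqc.store import (GenotypeMatrix, MergedCohort, SampleRecord,
                            Variant)

#: scaled-down study conditions for fast unit-level pipeline tests
SMALL = dict(n_study=50, n_variants=5000, n_x_variants=400)


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """One simulated cohort with all defect types planted, merged and
    pruned, reused read-only across tests."""
    out = tmp_path_factory.mktemp("sim_small")
    spec = SimSpec(seed=11, **SMALL)
    res = simulate_cohort(spec, out)
    cohort = prepare_cohort(res.vcf_path, res.bed_path,
                            res.annotation_path, res.benchmark_path,
                            config=QCConfig())
    return res, cohort


@pytest.fixture(scope="session")
def clean_sim(tmp_path_factory):
    """A defect-free simulated cohort."""
    out = tmp_path_factory.mktemp("clean_sim")
    spec = SimSpec(seed=12, n_duplicate=0, n_contaminated=0,
                   n_sex_mismatch=0, n_population_outliers=0,
                   study_related={}, **SMALL)
    res = simulate_cohort(spec, out)
    cohort = prepare_cohort(res.vcf_path, res.bed_path,
                            res.annotation_path, res.benchmark_path,
                            config=QCConfig())
    return res, cohort


def make_cohort(study_values, bench_values, chroms, positions,
                study_pops=None, study_genders=None, bench_pops=None,
                bench_relations=None, study_population="EUR"):
    """Assemble a MergedCohort directly from genotype arrays.

    ``bench_relations`` maps benchmark row index -> list of
    (other_row_index, relation).
    """
    study_values = np.asarray(study_values, dtype=np.int8)
    bench_values = np.asarray(bench_values, dtype=np.int8)
    ns, nb = study_values.shape[0], bench_values.shape[0]
    variants = [Variant(str(c), int(p), "A", "G")
                for c, p in zip(chroms, positions)]
    study_ids = [f"S{i:03d}" for i in range(ns)]
    bench_ids = [f"B{i:03d}" for i in range(nb)]
    samples = []
    for i, sid in enumerate(study_ids):
        samples.append(SampleRecord(
            sid,
            population=(study_pops[i] if study_pops else study_population),
            gender=(study_genders[i] if study_genders else "unknown"),
            cohort="study"))
    rel = bench_relations or {}
    for i, sid in enumerate(bench_ids):
        samples.append(SampleRecord(
            sid,
            population=(bench_pops[i] if bench_pops else "EUR"),
            gender="unknown", cohort="benchmark",
            known_relations=[(bench_ids[j], code)
                             for j, code in rel.get(i, [])]))
    values = np.vstack([study_values, bench_values])
    gm = GenotypeMatrix(values, study_ids + bench_ids,
                        [v.key for v in variants])
    return MergedCohort(gm, samples, variants, study_population)
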