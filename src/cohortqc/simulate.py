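"""Synthetic cohort generator with known truth.

Produces a benchmark panel (four continental populations, ~20 pedigrees
each, eight known related pairs) and a study cohort VCF/annotation with
planted defects — duplicate, five-donor contaminated sample, sex
mismatches, cross-population outliers, and cryptically related pairs —
together with a truth table for end-to-end evaluation.

Population structure follows the Balding-Nichols F-model: an ancestral
frequency p is drawn per variant, and each population's frequency is
Beta(p(1-F)/F, (1-p)(1-F)/F) so that Wright's FST between populations
equals F. Variants are mutually independent given their frequencies (no
within-population LD). Females are diploid on X; males are hemizygous
and emitted as homozygous diploid calls, which is what standard variant
callers produce and what drives the X-inbreeding sex check.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .store import (MISSING, GenotypeMatrix, MergedCohort, SampleRecord,
                    Variant, save_store)

#: benchmark pedigree plan mirroring the reference panel composition:
#: eight related pairs = 4 PO + 2 FS + 2 HF across the four populations
DEFAULT_PEDIGREES = {
    "AFR": ("PO", "PO", "FS"),
    "EAS": ("FS", "HF"),
    "EUR": ("HF",),
    "SAS": ("PO", "PO"),
}


@dataclass
class SimSpec:
    """Study conditions for one simulated cohort."""

    seed: int
    populations: tuple = ("AFR", "EAS", "EUR", "SAS")
    benchmark_pop_sizes: tuple = (22, 22, 21, 22)
    benchmark_pedigrees: dict = field(
        default_factory=lambda: dict(DEFAULT_PEDIGREES))
    fst: float = 0.1
    n_variants: int = 10_000           # autosomal, before the MAF filter
    n_x_variants: int = 500
    maf_range: tuple = (0.05, 0.5)
    benchmark_maf_min: float = 0.01
    study_population: str = "EUR"
    n_study: int = 100
    n_duplicate: int = 1
    n_contaminated: int = 1
    n_sex_mismatch: int = 2
    n_population_outliers: int = 2
    study_related: dict = field(default_factory=lambda: {"PO": 1, "FS": 1})
    missing_rate_range: tuple = (0.0, 0.05)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0 < self.fst < 1):
            raise ValueError("fst must be in (0, 1)")
        for name in ("n_variants", "n_x_variants", "n_study",
                     "n_duplicate", "n_contaminated", "n_sex_mismatch",
                     "n_population_outliers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.study_population not in self.populations:
            raise ValueError(
                f"study_population {self.study_population!r} not in "
                f"{self.populations}")
        n_planted = (2 * sum(self.study_related.values())
                     + 2 * self.n_duplicate + self.n_contaminated
                     + self.n_sex_mismatch + self.n_population_outliers
                     + 5 * self.n_contaminated)
        if n_planted > self.n_study:
            raise ValueError("defect/pedigree plan exceeds study size")

    @classmethod
    def from_file(cls, path, seed=None) -> "SimSpec":
        """Flat key=value spec file; tuple fields are comma-separated."""
        kwargs = {}
        ints = {"seed", "n_variants", "n_x_variants", "n_study",
                "n_duplicate", "n_contaminated", "n_sex_mismatch",
                "n_population_outliers"}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, val = (t.strip() for t in line.split("=", 1))
                if key in ints:
                    kwargs[key] = int(val)
                elif key == "fst":
                    kwargs[key] = float(val)
                elif key in ("maf_range", "missing_rate_range"):
                    kwargs[key] = tuple(float(x) for x in val.split(","))
                elif key == "benchmark_pop_sizes":
                    kwargs[key] = tuple(int(x) for x in val.split(","))
                elif key == "study_population":
                    kwargs[key] = val
                else:
                    raise ValueError(f"unknown spec option {key!r}")
        if seed is not None:
            kwargs["seed"] = seed
        return cls(**kwargs)


@dataclass
class TruthTable:
    """Ground truth for one simulated cohort."""

    samples: pd.DataFrame     # sample_id, true_population, true_sex, defect
    pairs: pd.DataFrame       # id_a, id_b, relation

    def defect_ids(self, defect: str) -> list:
        return list(self.samples.loc[self.samples["defect"] == defect,
                                     "sample_id"])

    @property
    def clean_ids(self) -> list:
        """Samples with no defect and no membership in a planted pair."""
        paired = set(self.pairs["id_a"]) | set(self.pairs["id_b"])
        ok = (self.samples["defect"] == "") & \
            ~self.samples["sample_id"].isin(paired)
        return list(self.samples.loc[ok, "sample_id"])

    def to_tsv(self, samples_path, pairs_path):
        self.samples.to_csv(samples_path, sep="\t", index=False,
                            lineterminator="\n")
        self.pairs.to_csv(pairs_path, sep="\t", index=False,
                          lineterminator="\n")


@dataclass
class SimResult:
    vcf_path: Path
    bed_path: Path
    annotation_path: Path
    benchmark_path: Path
    truth: TruthTable


# ---------------------------------------------------------------------------
# frequencies and genotypes
# ---------------------------------------------------------------------------

def simulate_frequencies(rng: np.random.Generator, n_variants: int,
                         n_populations: int, fst: float,
                         maf_range=(0.05, 0.5)) -> tuple:
    """Balding-Nichols population frequencies.

    Returns ``(ancestral, pop_freqs)`` with ``pop_freqs`` of shape
    (n_populations, n_variants). As fst -> 0 the population frequencies
    collapse onto the ancestral ones.
    """
    lo, hi = maf_range
    p = rng.uniform(lo, hi, size=n_variants)
    if fst < 1e-9:
        pops = np.tile(p, (n_populations, 1))
    else:
        a = p * (1.0 - fst) / fst
        b = (1.0 - p) * (1.0 - fst) / fst
        pops = rng.beta(a, b, size=(n_populations, n_variants))
    return p, np.clip(pops, 0.0, 1.0)


def sample_diploid(rng, freqs, n: int) -> np.ndarray:
    """n unrelated HWE individuals; rows samples, columns variants."""
    return rng.binomial(2, freqs, size=(n, len(freqs))).astype(np.int8)


def sample_x(rng, freqs, sexes) -> np.ndarray:
    """X genotypes: females Binomial(2, p); males hemizygous, emitted as
    homozygous diploid (0 or 2)."""
    out = np.empty((len(sexes), len(freqs)), dtype=np.int8)
    for i, sex in enumerate(sexes):
        if sex == "female":
            out[i] = rng.binomial(2, freqs)
        else:
            out[i] = 2 * rng.binomial(1, freqs).astype(np.int8)
    return out


def _transmit(rng, parent: np.ndarray) -> np.ndarray:
    """One gamete from a diploid parent (gene dropping)."""
    return rng.binomial(1, parent / 2.0).astype(np.int8)


def plant_related_pair(rng, freqs, relation: str,
                       parent: np.ndarray | None = None) -> tuple:
    """Gene-drop a related pair; returns (genotypes_a, genotypes_b).

    PO: parent plus child (one parental allele, one population allele).
    FS: two full siblings of two simulated parents. HF: half siblings
    sharing one simulated parent. DU: exact copy.
    """
    if relation == "DU":
        a = parent if parent is not None else sample_diploid(rng, freqs, 1)[0]
        return a, a.copy()
    if relation == "PO":
        a = parent if parent is not None else sample_diploid(rng, freqs, 1)[0]
        child = _transmit(rng, a) + rng.binomial(1, freqs).astype(np.int8)
        return a, child
    if relation == "FS":
        pa, pb = sample_diploid(rng, freqs, 2)
        s1 = _transmit(rng, pa) + _transmit(rng, pb)
        s2 = _transmit(rng, pa) + _transmit(rng, pb)
        return s1, s2
    if relation == "HF":
        pa, pb, pc = sample_diploid(rng, freqs, 3)
        h1 = _transmit(rng, pa) + _transmit(rng, pb)
        h2 = _transmit(rng, pa) + _transmit(rng, pc)
        return h1, h2
    raise ValueError(f"unknown relation {relation!r}")


def plant_contaminated(donors: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Genotype of a sample contaminated by five donors.

    The ten donor allele copies at each variant are pooled, as the reads
    of a DNA mixture would be, and the genotype is called from the pool:
    hom-ref when no alternate copy is present, hom-alt when no reference
    copy is present, and heterozygous otherwise. Donor-missing sites fall
    back to the remaining donors' copies; a site missing in all donors is
    missing in the contaminant. The pooled call produces the
    excess-heterozygosity (strongly negative F) signature of real
    contamination.
    """
    if donors.shape[0] != 5:
        raise ValueError("exactly 5 donor genotype vectors required")
    called = donors != MISSING
    alt = np.where(called, donors, 0).sum(axis=0)
    total = 2 * called.sum(axis=0)
    out = np.full(donors.shape[1], 1, dtype=np.int8)
    out[alt == 0] = 0
    out[(alt == total) & (total > 0)] = 2
    out[total == 0] = MISSING
    return out


def plant_sex_mismatch(annotation: pd.DataFrame, truth: pd.DataFrame,
                       sample_ids) -> tuple:
    """Flip the reported gender of the given samples; genotypes keep the
    true sex. Returns updated (annotation, truth)."""
    annotation = annotation.copy()
    truth = truth.copy()
    for sid in sample_ids:
        i = annotation.index[annotation["sample"] == sid][0]
        annotation.loc[i, "gender"] = (
            "female" if annotation.loc[i, "gender"] == "male" else "male")
        j = truth.index[truth["sample_id"] == sid][0]
        truth.loc[j, "defect"] = "sex_mismatch"
    return annotation, truth


def plant_population_outlier(annotation: pd.DataFrame,
                             truth: pd.DataFrame, sample_ids,
                             claimed_population: str) -> tuple:
    """Relabel the given (foreign-ancestry) samples as the study
    population in the annotation; truth keeps their real origin."""
    annotation = annotation.copy()
    truth = truth.copy()
    for sid in sample_ids:
        i = annotation.index[annotation["sample"] == sid][0]
        annotation.loc[i, "population"] = claimed_population
        j = truth.index[truth["sample_id"] == sid][0]
        truth.loc[j, "defect"] = "population_outlier"
    return annotation, truth


# ---------------------------------------------------------------------------
# variant layout and VCF emission
# ---------------------------------------------------------------------------

def _autosomal_layout(n: int) -> tuple:
    """Spread variants round-robin over chromosomes 1..22, 20 kb apart."""
    chroms = np.array([str(1 + (j % 22)) for j in range(n)])
    pos = np.array([100_000 + 20_000 * (j // 22) for j in range(n)],
                   dtype=np.int64)
    return chroms, pos


def _x_layout(n: int) -> tuple:
    """Non-PAR X positions (GRCh37 PAR1 ends at 2,699,520)."""
    chroms = np.array(["X"] * n)
    pos = np.array([3_000_000 + 20_000 * j for j in range(n)],
                   dtype=np.int64)
    return chroms, pos


def write_vcf(path, sample_ids, variants, values: np.ndarray) -> Path:
    """Write a minimal GT-only VCF (gzip when the name ends in .gz)."""
    path = Path(path)
    order = np.lexsort((
        np.array([v.pos for v in variants]),
        np.array([(int(v.chrom) if v.chrom.isdigit() else 100)
                  for v in variants]),
    ))
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    lines = ["##fileformat=VCFv4.2",
             "##source=cohortqc-simulator",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    seen = []
    for j in order:
        c = variants[j].chrom
        if c not in seen:
            seen.append(c)
    for c in seen:
        lines.append(f"##contig=<ID={c}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids))
    for j in order:
        v = variants[j]
        gts = "\t".join(gt_str[int(g)] for g in values[:, j])
        lines.append(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t"
                     f"PASS\t.\tGT\t{gts}")
    data = ("\n".join(lines) + "\n").encode()
    if path.suffix == ".gz":
        with gzip.open(path, "wb", mtime=0) as fh:
            fh.write(data)
    else:
        path.write_bytes(data)
    return path


def write_capture_bed(path, variants) -> Path:
    """Capture BED generously covering every simulated variant."""
    path = Path(path)
    by_chrom: dict = {}
    for v in variants:
        lo, hi = by_chrom.get(v.chrom, (v.pos, v.pos))
        by_chrom[v.chrom] = (min(lo, v.pos), max(hi, v.pos))
    def chrom_key(c):
        return (0, int(c)) if c.isdigit() else (1, c)
    lines = [f"{c}\t{max(0, lo - 1000)}\t{hi + 1000}"
             for c, (lo, hi) in sorted(by_chrom.items(),
                                       key=lambda kv: chrom_key(kv[0]))]
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _build_benchmark(rng, spec: SimSpec, auto_freqs, x_freqs):
    """Benchmark panel genotypes, sample records, per-pop MAF tables."""
    n_auto = auto_freqs.shape[1]
    samples, auto_rows, x_rows = [], [], []
    for pi, (pop, size) in enumerate(zip(spec.populations,
                                         spec.benchmark_pop_sizes)):
        pedigrees = spec.benchmark_pedigrees.get(pop, ())
        n_related = 2 * len(pedigrees)
        if n_related > size:
            raise ValueError(
                f"pedigree plan for {pop} exceeds its sample count")
        ids = [f"B{pop}{k:03d}" for k in range(size)]
        sexes = ["male" if rng.random() < 0.5 else "female"
                 for _ in range(size)]
        genos = sample_diploid(rng, auto_freqs[pi], size)
        relations: dict = {k: [] for k in range(size)}
        k = 0
        for rel in pedigrees:
            a, b = plant_related_pair(rng, auto_freqs[pi], rel,
                                      parent=genos[k].copy())
            genos[k], genos[k + 1] = a, b
            relations[k].append((ids[k + 1], rel))
            relations[k + 1].append((ids[k], rel))
            k += 2
        xg = sample_x(rng, x_freqs[pi], sexes)
        for k in range(size):
            samples.append(SampleRecord(
                ids[k], population=pop, gender=sexes[k],
                cohort="benchmark", known_relations=relations[k]))
            auto_rows.append(genos[k])
            x_rows.append(xg[k])
    auto = np.stack(auto_rows)
    xmat = np.stack(x_rows)
    return samples, auto, xmat


def _empirical_maf(values: np.ndarray, pops: np.ndarray,
                   pop_names) -> dict:
    """Per-population empirical MAF arrays keyed by population."""
    out = {}
    for pop in pop_names:
        rows = np.nonzero(pops == pop)[0]
        g = values[rows]
        called = g != MISSING
        n2 = 2.0 * called.sum(axis=0)
        alt = np.where(called, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n2 > 0, alt / n2, np.nan)
        out[pop] = np.minimum(p, 1.0 - p)
    return out


def simulate_cohort(spec: SimSpec, out_dir) -> SimResult:
    """Generate benchmark store, study VCF, annotation, BED and truth.

    Deterministic: the same spec (including seed) yields byte-identical
    output files.
    """
    rng = np.random.default_rng(spec.seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_pops = len(spec.populations)
    pop_index = {p: i for i, p in enumerate(spec.populations)}

    _, auto_freqs = simulate_frequencies(
        rng, spec.n_variants, n_pops, spec.fst, spec.maf_range)
    _, x_freqs = simulate_frequencies(
        rng, spec.n_x_variants, n_pops, spec.fst, spec.maf_range)

    bench_samples, bench_auto, bench_x = _build_benchmark(
        rng, spec, auto_freqs, x_freqs)
    bench_pops = np.array([s.population for s in bench_samples])

    # ---- study cohort ----------------------------------------------------
    si = pop_index[spec.study_population]
    n = spec.n_study
    ids = [f"S{k:04d}" for k in range(n)]
    sexes = ["male" if rng.random() < 0.5 else "female" for _ in range(n)]
    auto = sample_diploid(rng, auto_freqs[si], n)
    true_pop = [spec.study_population] * n
    defect = [""] * n
    pairs = []

    cursor = 0
    # cryptically related pairs
    for rel, count in spec.study_related.items():
        for _ in range(count):
            a, b = plant_related_pair(rng, auto_freqs[si], rel,
                                      parent=auto[cursor].copy())
            auto[cursor], auto[cursor + 1] = a, b
            pairs.append((ids[cursor], ids[cursor + 1], rel))
            defect[cursor] = defect[cursor + 1] = "related"
            cursor += 2
    # duplicate: the copy sits at cursor+1 so its ID sorts after the
    # original's
    for _ in range(spec.n_duplicate):
        auto[cursor + 1] = auto[cursor]
        pairs.append((ids[cursor], ids[cursor + 1], "DU"))
        sexes[cursor + 1] = sexes[cursor]
        defect[cursor] = defect[cursor + 1] = "duplicate"
        cursor += 2
    dup_rows = [(i, i + 1) for i in range(cursor - 2 * spec.n_duplicate,
                                          cursor, 2)]
    # contaminated sample(s): five clean donors each, taken from the end
    donor_cursor = n
    contam_rows = []
    for _ in range(spec.n_contaminated):
        donor_rows = list(range(donor_cursor - 5, donor_cursor))
        donor_cursor -= 5
        auto[cursor] = plant_contaminated(auto[donor_rows], rng)
        sexes[cursor] = "female"
        defect[cursor] = "contaminated"
        contam_rows.append((cursor, donor_rows))
        cursor += 1
    # population outliers: true ancestry from the other populations
    others = [p for p in spec.populations if p != spec.study_population]
    outlier_rows = []
    for k in range(spec.n_population_outliers):
        src = others[k % len(others)]
        auto[cursor] = sample_diploid(rng, auto_freqs[pop_index[src]], 1)[0]
        true_pop[cursor] = src
        defect[cursor] = "population_outlier"
        outlier_rows.append(cursor)
        cursor += 1
    # sex mismatches: reported gender flipped below, genotypes truthful
    mismatch_rows = list(range(cursor, cursor + spec.n_sex_mismatch))
    cursor += spec.n_sex_mismatch

    # X genotypes by true sex and true population
    xg = sample_x(rng, x_freqs[si], sexes)
    for row in outlier_rows:
        xg[row] = sample_x(rng, x_freqs[pop_index[true_pop[row]]],
                           [sexes[row]])[0]
    for row, _ in dup_rows:
        xg[row + 1] = xg[row]
    for row, donor_rows in contam_rows:
        xg[row] = plant_contaminated(xg[donor_rows], rng)

    # per-sample missing calls (study only; the reference panel is clean)
    lo, hi = spec.missing_rate_range
    rates = rng.uniform(lo, hi, size=n)
    full = np.hstack([auto, xg])
    mask = rng.random(full.shape) < rates[:, None]
    full[mask] = MISSING

    # ---- benchmark MAF restriction and variant objects -------------------
    bench_full = np.hstack([bench_auto, bench_x])
    a_chroms, a_pos = _autosomal_layout(spec.n_variants)
    x_chroms, x_pos = _x_layout(spec.n_x_variants)
    chroms = np.concatenate([a_chroms, x_chroms])
    positions = np.concatenate([a_pos, x_pos])
    maf = _empirical_maf(bench_full, bench_pops, spec.populations)
    maf_mat = np.vstack([maf[p] for p in spec.populations])
    keep = np.nanmax(maf_mat, axis=0) > spec.benchmark_maf_min

    variants = []
    for j in np.nonzero(keep)[0]:
        variants.append(Variant(
            chroms[j], int(positions[j]), "A", "G",
            maf_by_pop={p: float(maf_mat[i, j])
                        for i, p in enumerate(spec.populations)
                        if np.isfinite(maf_mat[i, j])}))
    bench_kept = bench_full[:, keep]
    study_kept = full[:, keep]

    # ---- emit files -------------------------------------------------------
    bench_gm = GenotypeMatrix(bench_kept,
                              [s.sample_id for s in bench_samples],
                              [v.key for v in variants])
    benchmark = MergedCohort(bench_gm, bench_samples, variants,
                             study_population="unknown")
    benchmark_path = save_store(benchmark, out_dir / "benchmark.cqst")
    vcf_path = write_vcf(out_dir / "study.vcf", ids, variants, study_kept)
    bed_path = write_capture_bed(out_dir / "capture.bed", variants)

    annotation = pd.DataFrame({
        "sample": ids,
        "population": [spec.study_population] * n,
        "gender": sexes,
    })
    truth_samples = pd.DataFrame({
        "sample_id": ids,
        "true_population": true_pop,
        "true_sex": sexes,
        "defect": defect,
    })
    truth_pairs = pd.DataFrame(pairs, columns=["id_a", "id_b", "relation"])

    if mismatch_rows:
        annotation, truth_samples = plant_sex_mismatch(
            annotation, truth_samples, [ids[r] for r in mismatch_rows])
    if outlier_rows:
        annotation, truth_samples = plant_population_outlier(
            annotation, truth_samples, [ids[r] for r in outlier_rows],
            spec.study_population)

    annotation_path = out_dir / "samples.tsv"
    annotation.to_csv(annotation_path, sep="\t", index=False,
                      lineterminator="\n")
    truth = TruthTable(truth_samples, truth_pairs)
    truth.to_tsv(out_dir / "truth_samples.tsv", out_dir / "truth_pairs.tsv")
    return SimResult(vcf_path, bed_path, annotation_path, benchmark_path,
                     truth)
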