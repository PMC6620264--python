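"""Cohort genotype store.

Readers for the three user-facing inputs (multi-sample VCF, capture-region
BED, sample annotation TSV), the in-memory data model (``Variant``,
``SampleRecord``, ``GenotypeMatrix``, ``MergedCohort``), study/benchmark
merging, and a compact single-file binary store.

Genotypes are coded as the count of alternate alleles: 0 (hom-ref),
1 (het), 2 (hom-alt), with :data:`MISSING` (-1) for anything that is not a
clean diploid call. Only bi-allelic single-nucleotide variants are kept.

Store file schema (format version ``cohortqc-store-1``)::

    bytes 0..5    magic  b"CQST\\x01\\n"
    bytes 6..13   little-endian uint64: length of the zlib-compressed
                  JSON metadata block
    bytes 14..21  little-endian uint64: length of the zlib-compressed
                  genotype block
    ...           the two blocks, in that order

The metadata JSON carries the format version, sample table (IDs,
population, gender, cohort, known relations), variant table (chrom, pos,
ref, alt, per-population MAF, capture/pruning flags) and the study
population label. The genotype block packs four 2-bit codes per byte
(0/1/2 as-is, 3 = missing), row-major samples x variants. Everything is
byte-deterministic: identical cohorts serialize to identical files.
"""

from __future__ import annotations

import dataclasses
import json
import math
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING: int = -1

STORE_MAGIC = b"CQST\x01\n"
STORE_FORMAT_VERSION = "cohortqc-store-1"

#: populations recognised in annotations; ASN is a study-side label that
#: matches both EAS and SAS benchmark samples
POPULATIONS = ("AFR", "EAS", "EUR", "SAS")
RELATION_CODES = ("DU", "PO", "FS", "HF", "UN")

_VALID_BASES = frozenset("ACGT")


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' so mixed-dialect VCF/BED inputs agree."""
    return chrom[3:] if chrom[:3].lower() == "chr" else chrom


def is_autosome(chrom: str) -> bool:
    c = normalize_chrom(chrom)
    return c.isdigit() and 1 <= int(c) <= 22


def is_x(chrom: str) -> bool:
    return normalize_chrom(chrom).upper() in ("X", "23")


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class Variant:
    """A bi-allelic SNV and its cohort-level summary statistics."""

    chrom: str
    pos: int                       # 1-based
    ref: str
    alt: str
    maf_by_pop: dict = field(default_factory=dict)
    in_capture: bool = True
    pruned_in: bool = True
    hwe_p: float = math.nan
    missing_rate: float = math.nan

    def __post_init__(self):
        self.chrom = normalize_chrom(str(self.chrom))
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.ref not in _VALID_BASES or self.alt not in _VALID_BASES:
            raise ValueError(f"non-SNV alleles at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SampleRecord:
    sample_id: str
    population: str = "unknown"
    gender: str = "unknown"
    cohort: str = "study"          # "study" | "benchmark"
    #: list of (other_sample_id, relation) with relation in RELATION_CODES
    known_relations: list = field(default_factory=list)


@dataclass
class GenotypeMatrix:
    """samples x variants matrix of alt-allele counts, MISSING = -1."""

    values: np.ndarray
    sample_ids: list
    variant_keys: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.sample_ids), len(self.variant_keys)):
            raise ValueError("genotype matrix shape does not match indexes")
        ok = np.isin(self.values, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("genotype codes must be in {0, 1, 2, MISSING}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]


@dataclass
class MergedCohort:
    """Study cohort merged with the benchmark panel on the benchmark's
    variant set; the unit every estimator and QC step consumes."""

    genotypes: GenotypeMatrix
    samples: list                  # list[SampleRecord], same order as rows
    variants: list                 # list[Variant], same order as columns
    study_population: str = "unknown"

    def __post_init__(self):
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample IDs in merged cohort")
        if len(self.samples) != self.genotypes.n_samples:
            raise ValueError("sample list does not match genotype rows")
        if len(self.variants) != self.genotypes.n_variants:
            raise ValueError("variant list does not match genotype columns")

    # -- convenience views -------------------------------------------------
    @property
    def sample_ids(self) -> list:
        return [s.sample_id for s in self.samples]

    @property
    def study_mask(self) -> np.ndarray:
        return np.array([s.cohort == "study" for s in self.samples])

    @property
    def populations(self) -> np.ndarray:
        return np.array([s.population for s in self.samples])

    @property
    def chroms(self) -> np.ndarray:
        return np.array([v.chrom for v in self.variants])

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def autosomal_mask(self) -> np.ndarray:
        return np.array([is_autosome(v.chrom) for v in self.variants])

    def x_mask(self) -> np.ndarray:
        return np.array([is_x(v.chrom) for v in self.variants])

    def subset_samples(self, keep_ids) -> "MergedCohort":
        """New cohort restricted to ``keep_ids`` (order preserved)."""
        keep = set(keep_ids)
        rows = [i for i, s in enumerate(self.samples) if s.sample_id in keep]
        gm = GenotypeMatrix(
            self.genotypes.values[rows].copy(),
            [self.sample_ids[i] for i in rows],
            list(self.genotypes.variant_keys),
        )
        return MergedCohort(gm, [self.samples[i] for i in rows],
                            self.variants, self.study_population)

    def matched_benchmark_populations(self) -> set:
        """Benchmark populations considered 'same population' as the study
        cohort; ASN matches both EAS and SAS."""
        pop = self.study_population
        if pop == "ASN":
            return {"EAS", "SAS"}
        if pop in POPULATIONS:
            return {pop}
        return set(POPULATIONS)

    def matched_subset_mask(self) -> np.ndarray:
        """Rows used for frequency/F reference: all study samples plus
        benchmark samples of the matched population(s)."""
        matched = self.matched_benchmark_populations()
        return np.array([
            s.cohort == "study" or s.population in matched
            for s in self.samples
        ])


# ---------------------------------------------------------------------------
# capture regions (BED)
# ---------------------------------------------------------------------------

class CaptureRegions:
    """Merged, sorted half-open 0-based intervals per chromosome."""

    def __init__(self, intervals_by_chrom: dict):
        self._iv = {}
        for chrom, iv in intervals_by_chrom.items():
            arr = np.asarray(sorted((int(a), int(b)) for a, b in iv),
                             dtype=np.int64).reshape(-1, 2)
            merged = []
            for a, b in arr:
                if merged and a <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], b)
                else:
                    merged.append([a, b])
            self._iv[normalize_chrom(chrom)] = np.asarray(merged,
                                                          dtype=np.int64)

    @property
    def intervals(self) -> dict:
        return {c: iv.copy() for c, iv in self._iv.items()}

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based VCF position."""
        iv = self._iv.get(normalize_chrom(chrom))
        if iv is None or len(iv) == 0:
            return False
        p0 = int(pos) - 1          # to 0-based
        i = np.searchsorted(iv[:, 0], p0, side="right") - 1
        return i >= 0 and p0 < iv[i, 1]

    def contains_many(self, chroms, positions) -> np.ndarray:
        return np.array([self.contains(c, p)
                         for c, p in zip(chroms, positions)])


def read_capture_bed(bed_path) -> CaptureRegions:
    """Parse a 3+ column BED file into merged capture regions.

    BED is 0-based half-open; comment/track/browser lines are skipped.
    Malformed lines raise ``ValueError`` naming the line number.
    """
    by_chrom: dict = {}
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if (not line.strip()
                    or line.startswith(("#", "track", "browser"))):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ValueError(
                    f"{bed_path}: line {lineno}: expected >=3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{bed_path}: line {lineno}: non-integer coordinates"
                ) from exc
            if end < start:
                raise ValueError(
                    f"{bed_path}: line {lineno}: end < start")
            by_chrom.setdefault(normalize_chrom(parts[0]), []).append(
                (start, end))
    return CaptureRegions(by_chrom)


# ---------------------------------------------------------------------------
# VCF reading
# ---------------------------------------------------------------------------

def read_vcf_biallelic_snv(vcf_path, capture: CaptureRegions | None = None):
    """Read a multi-sample VCF keeping bi-allelic SNVs inside capture.

    Multi-allelic records, indels and out-of-capture records are dropped.
    Diploid GT maps 0/0->0, 0/1|1/0->1, 1/1->2; any missing allele,
    half-call, or ploidy != 2 becomes MISSING. Phased separators are
    treated like unphased.

    Returns ``(GenotypeMatrix, list[Variant])``.
    """
    from cyvcf2 import VCF

    path = Path(vcf_path)
    if not path.exists():
        raise OSError(f"cannot read VCF: {path}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains no samples")

    columns = []
    variants = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        ref, alt = rec.REF, rec.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            continue
        if ref not in _VALID_BASES or alt not in _VALID_BASES:
            continue
        chrom = normalize_chrom(rec.CHROM)
        if capture is not None and not capture.contains(chrom, rec.POS):
            continue
        col = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(rec.genotypes):
            alleles = g[:-1]       # last element is the phased flag
            if len(alleles) != 2 or alleles[0] < 0 or alleles[1] < 0:
                col[i] = MISSING
            else:
                col[i] = alleles[0] + alleles[1]
        columns.append(col)
        variants.append(Variant(chrom, rec.POS, ref, alt,
                                in_capture=True))
    vcf.close()

    if columns:
        values = np.stack(columns, axis=1)
    else:
        values = np.empty((len(samples), 0), dtype=np.int8)
    gm = GenotypeMatrix(values, samples, [v.key for v in variants])
    return gm, variants


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def read_sample_annotation(tsv_path) -> list:
    """Read the sample annotation TSV (columns sample/population/gender)
    into study-cohort ``SampleRecord`` objects."""
    df = pd.read_csv(tsv_path, sep="\t", dtype=str)
    required = {"sample", "population", "gender"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{tsv_path}: annotation needs columns {sorted(required)}, "
            f"found {list(df.columns)}")
    if df["sample"].duplicated().any():
        dups = sorted(df.loc[df["sample"].duplicated(), "sample"])
        raise ValueError(f"{tsv_path}: duplicate sample IDs: {dups}")
    records = []
    for _, row in df.iterrows():
        pop = str(row["population"]).strip().upper()
        if pop not in POPULATIONS + ("ASN",):
            pop = "unknown"
        gender = str(row["gender"]).strip().lower()
        if gender not in ("male", "female"):
            gender = "unknown"
        records.append(SampleRecord(str(row["sample"]).strip(),
                                    population=pop, gender=gender,
                                    cohort="study"))
    return records


def check_annotation_covers(records, vcf_sample_ids) -> None:
    """Raise if any VCF sample lacks an annotation row."""
    annotated = {r.sample_id for r in records}
    missing = [s for s in vcf_sample_ids if s not in annotated]
    if missing:
        raise ValueError(
            f"samples in VCF without annotation rows: {missing}")


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------

def merge_with_benchmark(study, benchmark: MergedCohort,
                         capture: CaptureRegions,
                         study_population: str = "unknown") -> MergedCohort:
    """Merge a study cohort onto the benchmark panel's variant set.

    ``study`` is ``(GenotypeMatrix, list[Variant], list[SampleRecord])``.
    The merged variant set is the benchmark's; study-only variants are
    dropped. A benchmark variant absent from the study VCF gets hom-ref
    (0) study genotypes when it lies inside the capture regions and
    MISSING otherwise (the assay could not have observed it). Sites where
    the study carries a different allele pair at the same position
    (ref/alt swaps, strand flips) are dropped outright.
    """
    gm_study, study_variants, study_records = study

    study_ids = set(gm_study.sample_ids)
    collisions = [s.sample_id for s in benchmark.samples
                  if s.sample_id in study_ids]
    if collisions:
        raise ValueError(
            f"study/benchmark sample ID collision: {collisions}")

    key_to_col = {v.key: j for j, v in enumerate(study_variants)}
    pos_alleles: dict = {}
    for v in study_variants:
        pos_alleles.setdefault((v.chrom, v.pos), set()).add((v.ref, v.alt))

    n_study = gm_study.n_samples
    keep_variants = []
    study_cols = []
    bench_keep = []
    for bj, bv in enumerate(benchmark.variants):
        key = bv.key
        if key in key_to_col:
            col = gm_study.values[:, key_to_col[key]].copy()
        else:
            site = pos_alleles.get((bv.chrom, bv.pos))
            if site and (bv.ref, bv.alt) not in site:
                continue           # allele mismatch: drop the site
            inside = capture.contains(bv.chrom, bv.pos)
            col = np.full(n_study, 0 if inside else MISSING, dtype=np.int8)
        new_v = dataclasses.replace(
            bv, maf_by_pop=dict(bv.maf_by_pop),
            in_capture=capture.contains(bv.chrom, bv.pos))
        keep_variants.append(new_v)
        study_cols.append(col)
        bench_keep.append(bj)

    if study_cols:
        study_block = np.stack(study_cols, axis=1)
    else:
        study_block = np.empty((n_study, 0), dtype=np.int8)
    bench_block = benchmark.genotypes.values[:, bench_keep]
    values = np.vstack([study_block, bench_block])

    samples = list(study_records) + [dataclasses.replace(
        s, known_relations=list(s.known_relations))
        for s in benchmark.samples]
    gm = GenotypeMatrix(values,
                        gm_study.sample_ids + benchmark.sample_ids,
                        [v.key for v in keep_variants])
    cohort = MergedCohort(gm, samples, keep_variants, study_population)

    miss = (cohort.genotypes.values == MISSING).mean(axis=0)
    for v, m in zip(cohort.variants, miss):
        v.missing_rate = float(m)
    return cohort


# ---------------------------------------------------------------------------
# binary store
# ---------------------------------------------------------------------------

def _pack_genotypes(values: np.ndarray) -> bytes:
    codes = values.astype(np.int16)
    codes[codes == MISSING] = 3
    codes = codes.astype(np.uint8)
    n, m = codes.shape
    m_pad = -(-m // 4) * 4
    if m_pad != m:
        codes = np.pad(codes, ((0, 0), (0, m_pad - m)))
    c = codes.reshape(n, m_pad // 4, 4)
    packed = (c[:, :, 0] | (c[:, :, 1] << 2)
              | (c[:, :, 2] << 4) | (c[:, :, 3] << 6)).astype(np.uint8)
    return packed.tobytes()


def _unpack_genotypes(raw: bytes, n: int, m: int) -> np.ndarray:
    packed = np.frombuffer(raw, dtype=np.uint8).reshape(n, -(-m // 4))
    codes = np.empty((n, packed.shape[1] * 4), dtype=np.int8)
    for k in range(4):
        codes[:, k::4] = (packed >> (2 * k)) & 0b11
    codes = codes[:, :m]
    codes[codes == 3] = MISSING
    return codes


def _nan_to_none(x: float):
    return None if (x is None or math.isnan(x)) else float(x)


def save_store(cohort: MergedCohort, path) -> Path:
    """Serialize a cohort to the single-file binary store format."""
    meta = {
        "format_version": STORE_FORMAT_VERSION,
        "n_samples": cohort.genotypes.n_samples,
        "n_variants": cohort.genotypes.n_variants,
        "study_population": cohort.study_population,
        "samples": [
            {"sample_id": s.sample_id, "population": s.population,
             "gender": s.gender, "cohort": s.cohort,
             "known_relations": [list(t) for t in s.known_relations]}
            for s in cohort.samples
        ],
        "variants": {
            "chrom": [v.chrom for v in cohort.variants],
            "pos": [int(v.pos) for v in cohort.variants],
            "ref": [v.ref for v in cohort.variants],
            "alt": [v.alt for v in cohort.variants],
            "in_capture": [bool(v.in_capture) for v in cohort.variants],
            "pruned_in": [bool(v.pruned_in) for v in cohort.variants],
            "hwe_p": [_nan_to_none(v.hwe_p) for v in cohort.variants],
            "missing_rate": [_nan_to_none(v.missing_rate)
                             for v in cohort.variants],
            "maf_by_pop": [
                {k: float(x) for k, x in sorted(v.maf_by_pop.items())}
                for v in cohort.variants
            ],
        },
    }
    meta_blob = zlib.compress(
        json.dumps(meta, sort_keys=True,
                   separators=(",", ":")).encode("utf-8"), 6)
    geno_blob = zlib.compress(_pack_genotypes(cohort.genotypes.values), 6)
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(STORE_MAGIC)
        fh.write(struct.pack("<QQ", len(meta_blob), len(geno_blob)))
        fh.write(meta_blob)
        fh.write(geno_blob)
    return path


def load_store(path) -> MergedCohort:
    """Load a cohort saved by :func:`save_store`; round-trip identity is
    exact cell-for-cell."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(len(STORE_MAGIC))
        if magic != STORE_MAGIC:
            raise ValueError(f"{path}: not a cohortqc store file")
        header = fh.read(16)
        if len(header) != 16:
            raise ValueError(f"{path}: truncated store file")
        len_meta, len_geno = struct.unpack("<QQ", header)
        meta_blob = fh.read(len_meta)
        geno_blob = fh.read(len_geno)
    if len(meta_blob) != len_meta or len(geno_blob) != len_geno:
        raise ValueError(f"{path}: truncated store file")
    try:
        meta = json.loads(zlib.decompress(meta_blob).decode("utf-8"))
        raw = zlib.decompress(geno_blob)
    except zlib.error as exc:
        raise ValueError(f"{path}: corrupt store file") from exc
    version = meta.get("format_version")
    if version != STORE_FORMAT_VERSION:
        raise ValueError(
            f"{path}: store format version {version!r} not supported "
            f"(expected {STORE_FORMAT_VERSION!r})")

    n, m = meta["n_samples"], meta["n_variants"]
    values = _unpack_genotypes(raw, n, m)
    samples = [
        SampleRecord(s["sample_id"], s["population"], s["gender"],
                     s["cohort"],
                     [tuple(t) for t in s["known_relations"]])
        for s in meta["samples"]
    ]
    vt = meta["variants"]
    variants = []
    for j in range(m):
        variants.append(Variant(
            vt["chrom"][j], vt["pos"][j], vt["ref"][j], vt["alt"][j],
            maf_by_pop=dict(vt["maf_by_pop"][j]),
            in_capture=vt["in_capture"][j],
            pruned_in=vt["pruned_in"][j],
            hwe_p=(math.nan if vt["hwe_p"][j] is None else vt["hwe_p"][j]),
            missing_rate=(math.nan if vt["missing_rate"][j] is None
                          else vt["missing_rate"][j]),
        ))
    gm = GenotypeMatrix(values, [s.sample_id for s in samples],
                        [v.key for v in variants])
    return MergedCohort(gm, samples, variants,
                        meta.get("study_population", "unknown"))
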