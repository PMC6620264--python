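"""The five sample-QC decision rules.

Each check consumes a :class:`~cohortqc.store.MergedCohort` and a
:class:`~cohortqc.pipeline.QCConfig`, and returns a :class:`QCStepResult`
holding a per-sample (or per-pair) metric table, the thresholds applied,
and the flagged study samples with reasons. Benchmark samples appear in
the metric tables for context but are never flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import popgen
from .store import MISSING, MergedCohort

STEP_NAMES = ("missing", "sex", "inbreeding", "ibd", "population")


@dataclass
class QCStepResult:
    step: str
    metrics: pd.DataFrame
    thresholds: dict
    flagged: list = field(default_factory=list)   # (sample_id, reason)
    warnings: list = field(default_factory=list)

    @property
    def flagged_ids(self) -> list:
        return [s for s, _ in self.flagged]

    def to_tsv(self, path) -> Path:
        path = Path(path)
        df = self.metrics.copy()
        reasons = dict(self.flagged)
        key = "pair" if "id_a" in df.columns else "sample_id"
        if key == "pair":
            df["flagged"] = [
                ";".join(r for r in (reasons.get(a, ""), reasons.get(b, ""))
                         if r)
                for a, b in zip(df["id_a"], df["id_b"])]
        else:
            df["flagged"] = [reasons.get(s, "") for s in df["sample_id"]]
        # %.17g round-trips float64 exactly through the TSV
        df.to_csv(path, sep="\t", index=False, lineterminator="\n",
                  float_format="%.17g")
        return path

    @staticmethod
    def metrics_from_tsv(path) -> pd.DataFrame:
        # correctly-rounded parsing so saved metrics reload bit-exact
        return pd.read_csv(path, sep="\t", float_precision="round_trip")


def classify_sex(f_x: float, female_max: float = 0.2,
                 male_min: float = 0.8) -> str:
    """Sex call from the X inbreeding coefficient: female if F <= 0.2,
    male if F >= 0.8, ambiguous in between."""
    if not np.isfinite(f_x):
        return "ambiguous"
    if f_x <= female_max:
        return "female"
    if f_x >= male_min:
        return "male"
    return "ambiguous"


def is_related_pair(predicted: str, kinship: float,
                    kinship_min: float = 0.08) -> bool:
    """A pair counts as related only when the classifier calls a non-UN
    relationship AND the kinship coefficient clears the gate (>=)."""
    return predicted != "UN" and kinship >= kinship_min


def flag_outlier_mask(f: np.ndarray, mean: float, sd: float,
                      multiplier: float) -> np.ndarray:
    """Strictly beyond ``multiplier`` standard deviations from the mean."""
    return np.abs(f - mean) > multiplier * sd


# ---------------------------------------------------------------------------
# step 1: missing rate
# ---------------------------------------------------------------------------

def check_missing(cohort: MergedCohort, config) -> QCStepResult:
    """Flag study samples with missing rate strictly above the threshold
    (default 0.1) over all merged variants."""
    rates = popgen.sample_missing_rates(cohort.genotypes.values)
    study = cohort.study_mask
    df = pd.DataFrame({
        "sample_id": cohort.sample_ids,
        "cohort": ["study" if s else "benchmark" for s in study],
        "population": cohort.populations,
        "missing_rate": rates,
    })
    thr = config.missing_threshold
    flagged = [
        (sid, f"missing rate {r:.4g} > {thr:g}")
        for sid, r, st in zip(df["sample_id"], rates, study)
        if st and r > thr
    ]
    return QCStepResult("missing", df, {"missing_threshold": thr}, flagged)


# ---------------------------------------------------------------------------
# step 2: sex check
# ---------------------------------------------------------------------------

def check_sex(cohort: MergedCohort, config) -> QCStepResult:
    """Predict sex from the non-PAR X inbreeding coefficient and flag
    study samples whose prediction contradicts (or cannot confirm) the
    self-report."""
    x_cols = np.nonzero(cohort.x_mask())[0]
    positions = cohort.positions[x_cols]
    non_par = np.ones(len(x_cols), dtype=bool)
    for start, end in config.par_intervals:
        non_par &= ~((positions >= start) & (positions <= end))
    cols = x_cols[non_par]

    warns: list = []
    if len(cols) == 0:
        warns.append("no usable non-PAR X variants; sex check skipped")
        df = pd.DataFrame(columns=["sample_id", "cohort", "population",
                                   "reported_gender", "f_x", "pred_sex"])
        return QCStepResult("sex", df,
                            {"sex_f_female_max": config.sex_f_female_max,
                             "sex_f_male_min": config.sex_f_male_min},
                            [], warns)

    subset = cohort.matched_subset_mask()
    rows = np.nonzero(subset)[0]
    p = popgen.allele_frequencies(cohort.genotypes.values[:, cols], rows)
    usable = int((np.isfinite(p) & (p > 0) & (p < 1)).sum())
    if usable < 50:
        warns.append(f"only {usable} informative non-PAR X variants; "
                     "sex inference may be unstable")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f = popgen.inbreeding_coefficients(
            cohort.genotypes.values, rows, cols, p)

    samples = [cohort.samples[i] for i in rows]
    pred = [classify_sex(fi, config.sex_f_female_max,
                         config.sex_f_male_min) for fi in f]
    df = pd.DataFrame({
        "sample_id": [s.sample_id for s in samples],
        "cohort": [s.cohort for s in samples],
        "population": [s.population for s in samples],
        "reported_gender": [s.gender for s in samples],
        "f_x": f,
        "pred_sex": pred,
    })
    flagged = []
    for s, fi, pr in zip(samples, f, pred):
        if s.cohort != "study" or s.gender not in ("male", "female"):
            continue
        if pr == "ambiguous":
            flagged.append((s.sample_id,
                            f"ambiguous sex prediction (F_x = {fi:.4g}) "
                            f"with self-reported {s.gender}"))
        elif pr != s.gender:
            flagged.append((s.sample_id,
                            f"predicted {pr} (F_x = {fi:.4g}) but "
                            f"self-reported {s.gender}"))
    return QCStepResult("sex", df,
                        {"sex_f_female_max": config.sex_f_female_max,
                         "sex_f_male_min": config.sex_f_male_min},
                        flagged, warns)


# ---------------------------------------------------------------------------
# step 3: inbreeding check
# ---------------------------------------------------------------------------

def check_inbreeding(cohort: MergedCohort, config) -> QCStepResult:
    """Flag study samples whose autosomal inbreeding coefficient lies
    strictly beyond ``inbreeding_sd_multiplier`` standard deviations from
    the mean of the study + matched-population benchmark samples."""
    cols = np.nonzero(cohort.autosomal_mask()
                      & np.array([v.pruned_in for v in cohort.variants])
                      )[0]
    subset = cohort.matched_subset_mask()
    rows = np.nonzero(subset)[0]
    p = popgen.allele_frequencies(cohort.genotypes.values[:, cols], rows)
    f = popgen.inbreeding_coefficients(
        cohort.genotypes.values, rows, cols, p)
    samples = [cohort.samples[i] for i in rows]

    finite = np.isfinite(f)
    mean = float(np.mean(f[finite]))
    sd = float(np.std(f[finite], ddof=1)) if finite.sum() > 1 else 0.0
    mult = config.inbreeding_sd_multiplier

    df = pd.DataFrame({
        "sample_id": [s.sample_id for s in samples],
        "cohort": [s.cohort for s in samples],
        "population": [s.population for s in samples],
        "f_autosomal": f,
    })
    warns: list = []
    flagged = []
    if sd == 0.0:
        warns.append("zero variance of inbreeding coefficients; "
                     "no samples flagged")
    else:
        out = flag_outlier_mask(f, mean, sd, mult)
        for s, fi, o in zip(samples, f, out):
            if s.cohort == "study" and o and np.isfinite(fi):
                flagged.append(
                    (s.sample_id,
                     f"inbreeding coefficient {fi:.4g} beyond "
                     f"{mult:g} SD of mean ({mean:.4g} +/- {sd:.4g})"))
    return QCStepResult("inbreeding", df,
                        {"inbreeding_sd_multiplier": mult,
                         "mean": mean, "sd": sd},
                        flagged, warns)


# ---------------------------------------------------------------------------
# step 4: IBD / relatedness check
# ---------------------------------------------------------------------------

def _known_relation_map(cohort: MergedCohort) -> dict:
    rel = {}
    for s in cohort.samples:
        for other, code in s.known_relations:
            rel[frozenset((s.sample_id, other))] = code
    return rel


def check_ibd(cohort: MergedCohort, config) -> QCStepResult:
    """Detect cryptic relatedness and duplication.

    Method-of-moments (k0, k1) for every sample pair; a linear-kernel SVM
    trained on the benchmark pairs' known relationships (plus each
    benchmark sample paired with itself as a duplicate exemplar) labels
    every pair involving a study sample. Non-UN calls with kinship >=
    ``kinship_min`` define related pairs; within a study-study related
    pair the member with the higher missing rate is flagged (ties break
    to the lexicographically larger ID); in study-benchmark pairs the
    study member is flagged.
    """
    cols = np.nonzero(cohort.autosomal_mask()
                      & np.array([v.pruned_in for v in cohort.variants])
                      )[0]
    if len(cols) < 100:
        raise ValueError(
            f"only {len(cols)} pruned autosomal variants (<100); "
            "IBD estimation unstable")
    g = cohort.genotypes.values[:, cols]
    p = popgen.allele_frequencies(g)            # combined-cohort freqs
    k0, k1, k2, kin, _ = popgen.pairwise_ibd(g, p)

    ids = cohort.sample_ids
    study = cohort.study_mask
    n = len(ids)
    rel_map = _known_relation_map(cohort)
    bench_idx = np.nonzero(~study)[0]
    if not any(rel_map.get(frozenset((ids[i], ids[j]))) not in (None, "UN")
               for a, i in enumerate(bench_idx)
               for j in bench_idx[a + 1:]):
        raise ValueError("benchmark contains no known related pairs; "
                         "cannot train the relatedness classifier")

    # training set: benchmark-benchmark pairs + self-pairs as DU
    X_train, y_train = [], []
    for a, i in enumerate(bench_idx):
        X_train.append((k0[i, i], k1[i, i]))
        y_train.append("DU")
        for j in bench_idx[a + 1:]:
            X_train.append((k0[i, j], k1[i, j]))
            y_train.append(rel_map.get(frozenset((ids[i], ids[j])), "UN"))
    # standardized features keep the C = 1 margin meaningful despite the
    # overwhelming UN majority among training pairs
    svm = make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
    svm.fit(np.asarray(X_train), np.asarray(y_train))

    # pairs to evaluate: study-study and study-benchmark
    ia, ib = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if study[i] or study[j]:
                ia.append(i)
                ib.append(j)
    ia = np.asarray(ia, dtype=int)
    ib = np.asarray(ib, dtype=int)
    feats = np.column_stack([k0[ia, ib], k1[ia, ib]])
    pred = svm.predict(feats)
    kin_pair = kin[ia, ib]
    related = np.array([
        is_related_pair(pr, kv, config.kinship_min)
        for pr, kv in zip(pred, kin_pair)])

    miss = popgen.sample_missing_rates(cohort.genotypes.values)
    flagged_reasons: dict = {}
    for t in np.nonzero(related)[0]:
        i, j = int(ia[t]), int(ib[t])
        a_id, b_id = ids[i], ids[j]
        if study[i] and study[j]:
            if miss[i] > miss[j]:
                victim = a_id
            elif miss[j] > miss[i]:
                victim = b_id
            else:
                victim = max(a_id, b_id)
            other = b_id if victim == a_id else a_id
        else:
            victim = a_id if study[i] else b_id
            other = b_id if study[i] else a_id
        reason = (f"predicted {pred[t]} with {other} "
                  f"(kinship = {kin_pair[t]:.4g})")
        flagged_reasons.setdefault(victim, reason)

    df = pd.DataFrame({
        "id_a": [ids[i] for i in ia],
        "id_b": [ids[j] for j in ib],
        "k0": k0[ia, ib], "k1": k1[ia, ib], "k2": k2[ia, ib],
        "kinship": kin_pair,
        "pi_hat": k1[ia, ib] / 2.0 + k2[ia, ib],
        "known_relation": [
            rel_map.get(frozenset((ids[i], ids[j])), "unknown")
            for i, j in zip(ia, ib)],
        "predicted": pred,
        "predicted_related": related,
    })
    return QCStepResult(
        "ibd", df, {"kinship_min": config.kinship_min},
        sorted(flagged_reasons.items()))


# ---------------------------------------------------------------------------
# step 5: population outlier check
# ---------------------------------------------------------------------------

def check_population(cohort: MergedCohort, config) -> QCStepResult:
    """Flag study samples whose PCA-predicted ancestry contradicts the
    self-report.

    The eigen-decomposition includes every sample; the linear SVM is
    trained on the top-``pca_components`` eigenvectors of independent
    benchmark samples only (members of known related pairs excluded).
    A self-report of ASN matches predictions of either EAS or SAS.
    """
    bench_pops = {s.population for s in cohort.samples
                  if s.cohort == "benchmark"}
    if len(bench_pops) < 2:
        raise ValueError(
            f"population check needs >= 2 benchmark populations, "
            f"found {sorted(bench_pops)}")

    cols = np.nonzero(cohort.autosomal_mask()
                      & np.array([v.pruned_in for v in cohort.variants])
                      )[0]
    res = popgen.pca(cohort.genotypes.values, cols,
                     n_components=config.pca_components)
    ev = res.eigenvectors

    ids = cohort.sample_ids
    related_bench = {s.sample_id for s in cohort.samples
                     if s.cohort == "benchmark" and s.known_relations}
    train_rows = [i for i, s in enumerate(cohort.samples)
                  if s.cohort == "benchmark"
                  and s.sample_id not in related_bench]
    # eigenvector entries scale like 1/sqrt(n); standardize so the
    # C = 1 margin is meaningful regardless of cohort size
    svm = make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
    svm.fit(ev[train_rows], [cohort.samples[i].population
                             for i in train_rows])
    pred_all = svm.predict(ev)

    df = pd.DataFrame({
        "sample_id": ids,
        "cohort": ["study" if s.cohort == "study" else "benchmark"
                   for s in cohort.samples],
        "reported_population": cohort.populations,
        "predicted_population": pred_all,
    })
    for j in range(ev.shape[1]):
        df[f"ev{j + 1}"] = ev[:, j]

    flagged = []
    for i, s in enumerate(cohort.samples):
        if s.cohort != "study":
            continue
        reported, predicted = s.population, pred_all[i]
        if reported == "unknown":
            continue
        concordant = (predicted == reported
                      or (reported == "ASN" and predicted in ("EAS", "SAS")))
        if not concordant:
            flagged.append(
                (s.sample_id,
                 f"predicted population {predicted} discordant with "
                 f"self-reported {reported}"))
    return QCStepResult("population", df,
                        {"pca_components": config.pca_components}, flagged)


CHECKS = {
    "missing": check_missing,
    "sex": check_sex,
    "inbreeding": check_inbreeding,
    "ibd": check_ibd,
    "population": check_population,
}
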