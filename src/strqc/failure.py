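"""Genotyping-failure prediction and STR-level exclusion.

A genotyping failure is a reported allele whose true repeat size falls
outside the genotyper's confidence interval.  Failures are labelled by
visual inspection of a stratified sample of alleles, and a per-read-type
logistic GLM is trained on those labels using the continuous quality
parameters as features:

* spanning-called alleles: q_depth, q_ci, q_non
* flanking- and in-repeat-called alleles: q_ci, q_con, q_non

The fitted model is calibrated to a target training sensitivity (default
90%) so that true failures are rarely missed, predictions at or above the
cutoff are set to missing, and whole loci are excluded when more than 5% of
alleles are predicted failed or when observed failures significantly exceed
the model's prediction (one-sided chi-square, Bonferroni over loci).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import FLANKING, IN_REPEAT, SPANNING, SampleMeta
from .qc import FLAG_NAMES
from .stats import chi2_gof_1df

MODEL_FEATURES = {
    SPANNING: ("q_depth", "q_ci", "q_non"),
    FLANKING: ("q_ci", "q_con", "q_non"),
    IN_REPEAT: ("q_ci", "q_con", "q_non"),
}


@dataclass(frozen=True)
class InspectionLabel:
    """Visual-inspection verdict for one allele."""

    sample_id: str
    locus_id: str
    allele_index: int
    verdict: str  # "pass" | "fail"
    corrected_size: int | None = None

    def __post_init__(self) -> None:
        if self.verdict not in ("pass", "fail"):
            raise ValueError(f"verdict must be pass/fail, got {self.verdict!r}")
        if self.corrected_size is not None and self.verdict != "fail":
            raise ValueError("corrected_size only applies to fail verdicts")


def write_labels(labels: Sequence[InspectionLabel], path: str | Path) -> None:
    rows = [
        {
            "sample_id": l.sample_id,
            "locus_id": l.locus_id,
            "allele_index": l.allele_index,
            "verdict": l.verdict,
            "corrected_size": l.corrected_size,
        }
        for l in labels
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> list[InspectionLabel]:
    df = pd.read_csv(path, sep="\t")
    return [
        InspectionLabel(
            sample_id=str(r.sample_id),
            locus_id=str(r.locus_id),
            allele_index=int(r.allele_index),
            verdict=str(r.verdict),
            corrected_size=None if pd.isna(r.corrected_size) else int(r.corrected_size),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Inspection sampling manifest
# ---------------------------------------------------------------------------


def build_inspection_manifest(
    qc: pd.DataFrame,
    n_per_flag: int = 10,
    n_q5: int = 25,
    n_q1: int = 10,
    n_mid: int = 10,
    seed: int = 0,
) -> list[tuple[str, str, int]]:
    """Select alleles for visual inspection, per locus.

    Per locus: up to ``n_per_flag`` random alleles for each binary flag, the
    ``n_q5`` largest alleles, the ``n_q1`` smallest, and ``n_mid`` random
    alleles from each of repeat-size quintiles 2-4.  Deterministic given the
    seed; duplicates are removed.
    """
    rng = np.random.default_rng(seed)
    selected: set[tuple[str, str, int]] = set()
    key_cols = ["sample_id", "locus_id", "allele_index"]
    for locus_id, grp in qc.groupby("locus_id", sort=True):
        grp = grp.sort_values(key_cols).reset_index(drop=True)
        keys = list(grp[key_cols].itertuples(index=False, name=None))

        def sample_from(idx: np.ndarray, k: int) -> None:
            idx = np.asarray(idx)
            if len(idx) > k:
                idx = rng.choice(idx, size=k, replace=False)
            selected.update(keys[i] for i in idx)

        for flag in FLAG_NAMES:
            sample_from(np.flatnonzero(grp[flag].to_numpy()), n_per_flag)
        order = np.lexsort(
            (grp["allele_index"].to_numpy(), grp["sample_id"].to_numpy(), grp["size"].to_numpy())
        )
        selected.update(keys[i] for i in order[::-1][:n_q5])  # largest
        selected.update(keys[i] for i in order[:n_q1])  # smallest
        sizes = grp["size"].to_numpy()
        edges = np.quantile(sizes, [0.2, 0.4, 0.6, 0.8])
        for lo, hi in zip(edges[:-1], edges[1:]):  # quintiles 2, 3, 4
            sample_from(np.flatnonzero((sizes > lo) & (sizes <= hi)), n_mid)
    return sorted(selected)


# ---------------------------------------------------------------------------
# Temporal train/test split
# ---------------------------------------------------------------------------


def temporal_split(
    metas: Sequence[SampleMeta] | pd.DataFrame, cutoff_date: str = "2018-01-01"
) -> tuple[list[str], list[str]]:
    """Split samples by sequencing date: before the cutoff trains, the rest tests.

    Missing dates go to the training set (they can never leak into the
    held-out evaluation).  ISO-8601 dates compare lexicographically.
    """
    if isinstance(metas, pd.DataFrame):
        pairs = list(zip(metas["sample_id"], metas["sequencing_date"]))
    else:
        pairs = [(m.sample_id, m.sequencing_date) for m in metas]
    train, test = [], []
    for sid, date in pairs:
        if date is None or (isinstance(date, float) and np.isnan(date)) or str(date) < cutoff_date:
            train.append(sid)
        else:
            test.append(sid)
    if not test:
        warnings.warn("temporal split produced an empty test set", stacklevel=2)
    return train, test


# ---------------------------------------------------------------------------
# Failure model
# ---------------------------------------------------------------------------


@dataclass
class FailureModel:
    """Per-read-type logistic failure model plus its calibrated cutoff."""

    read_type: str
    feature_names: tuple[str, ...]
    coefficients: np.ndarray  # intercept first
    cutoff: float | None = None

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, float)
        if len(self.coefficients) != len(self.feature_names) + 1:
            raise ValueError("coefficient count must be feature count + 1 (intercept)")

    def predict_proba(self, qc: pd.DataFrame) -> np.ndarray:
        from scipy.special import expit

        X = np.column_stack(
            [np.ones(len(qc))] + [qc[f].to_numpy(float) for f in self.feature_names]
        )
        return expit(X @ self.coefficients)

    def to_dict(self) -> dict:
        return {
            "read_type": self.read_type,
            "feature_names": list(self.feature_names),
            "coefficients": self.coefficients.tolist(),
            "cutoff": self.cutoff,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FailureModel":
        return cls(
            read_type=d["read_type"],
            feature_names=tuple(d["feature_names"]),
            coefficients=np.asarray(d["coefficients"], float),
            cutoff=d.get("cutoff"),
        )


def save_models(models: dict[str, FailureModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({k: m.to_dict() for k, m in models.items()}, fh, indent=1)


def load_models(path: str | Path) -> dict[str, FailureModel]:
    with open(path) as fh:
        return {k: FailureModel.from_dict(d) for k, d in json.load(fh).items()}


def _labelled_frame(qc: pd.DataFrame, labels: Sequence[InspectionLabel]) -> pd.DataFrame:
    lab = pd.DataFrame(
        [
            {
                "sample_id": l.sample_id,
                "locus_id": l.locus_id,
                "allele_index": l.allele_index,
                "fail": 1 if l.verdict == "fail" else 0,
            }
            for l in labels
        ]
    )
    return qc.merge(lab, on=["sample_id", "locus_id", "allele_index"], how="inner")


def fit_failure_model(
    qc: pd.DataFrame, labels: Sequence[InspectionLabel], read_type: str
) -> FailureModel:
    """Fit the logistic failure GLM for one read type on labelled alleles.

    Outcome is coded fail = 1.  Zero-variance features are dropped from the
    optimization and reported with a zero slope, so a fully constant design
    degenerates to intercept = logit(fail rate).
    """
    import statsmodels.api as sm

    features = MODEL_FEATURES[read_type]
    df = _labelled_frame(qc, labels)
    df = df[df["support_type"] == read_type]
    y = df["fail"].to_numpy(float)
    if len(df) == 0 or y.min() == y.max():
        raise ValueError(
            f"cannot fit {read_type} failure model: training labels contain a single class"
        )
    cols = [df[f].to_numpy(float) for f in features]
    varying = [i for i, c in enumerate(cols) if np.ptp(c) > 0]
    X = np.column_stack([np.ones(len(df))] + [cols[i] for i in varying])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    beta = np.zeros(len(features) + 1)
    beta[0] = res.params[0]
    for j, i in enumerate(varying):
        beta[i + 1] = res.params[j + 1]
    model = FailureModel(read_type=read_type, feature_names=features, coefficients=beta)
    model.fit_bse_ = np.asarray(res.bse)  # SEs of the fitted (non-constant) terms
    model.fit_feature_idx_ = varying
    return model


def calibrate_cutoff(
    model: FailureModel, qc: pd.DataFrame, labels: Sequence[InspectionLabel],
    target_sensitivity: float = 0.90,
) -> float:
    """Choose the largest probability cutoff reaching the target sensitivity.

    Sensitivity at cutoff t is the fraction of labelled failures with
    predicted probability >= t, evaluated on the training labels.
    """
    df = _labelled_frame(qc, labels)
    df = df[df["support_type"] == model.read_type]
    fails = df[df["fail"] == 1]
    if len(fails) == 0:
        raise ValueError("cannot calibrate: no labelled failures for this read type")
    scores = np.sort(model.predict_proba(fails))[::-1]
    k = int(np.ceil(target_sensitivity * len(scores)))
    k = max(k, 1)
    cutoff = float(scores[k - 1])
    model.cutoff = cutoff
    return cutoff


def fit_and_calibrate(
    qc: pd.DataFrame,
    labels: Sequence[InspectionLabel],
    read_types: Sequence[str] = (SPANNING, FLANKING, IN_REPEAT),
    target_sensitivity: float = 0.90,
) -> dict[str, FailureModel]:
    """Fit and calibrate one failure model per read type present in the labels.

    A read type whose training labels are single-class cannot support its own
    GLM.  If a fitted model with the same feature set exists (flanking and
    in-repeat share features) it is reused; a read type labelled entirely
    ``fail`` otherwise gets a constant always-fail model.
    """
    models: dict[str, FailureModel] = {}
    single_class: dict[str, str] = {}
    for rt in read_types:
        try:
            m = fit_failure_model(qc, labels, rt)
        except ValueError:
            df = _labelled_frame(qc, labels)
            df = df[df["support_type"] == rt]
            if len(df):
                single_class[rt] = "fail" if df["fail"].iloc[0] == 1 else "pass"
            continue
        calibrate_cutoff(m, qc, labels, target_sensitivity)
        models[rt] = m
    if not models:
        raise ValueError("no read type had both pass and fail labels")
    for rt, verdict in single_class.items():
        sibling = next(
            (m for m in models.values() if MODEL_FEATURES[m.read_type] == MODEL_FEATURES[rt]),
            None,
        )
        if sibling is not None:
            models[rt] = FailureModel(rt, sibling.feature_names, sibling.coefficients.copy(),
                                      cutoff=sibling.cutoff)
        elif verdict == "fail":
            beta = np.zeros(len(MODEL_FEATURES[rt]) + 1)
            beta[0] = 20.0  # every allele of this type failed inspection
            models[rt] = FailureModel(rt, MODEL_FEATURES[rt], beta, cutoff=0.5)
    return models


def predict_failures(models: dict[str, FailureModel], qc: pd.DataFrame) -> pd.Series:
    """Predict failure for every allele in the QC table.

    An allele fails if its read-type model assigns probability >= the
    calibrated cutoff, or unconditionally if it has no attributed reads.
    Returns a boolean Series aligned to ``qc``.
    """
    fail = np.zeros(len(qc), dtype=bool)
    for rt, model in models.items():
        if model.cutoff is None:
            raise ValueError(f"{rt} model is not calibrated")
        mask = (qc["support_type"] == rt).to_numpy()
        if mask.any():
            fail[mask] = model.predict_proba(qc[mask]) >= model.cutoff
    fail |= qc["unsupported"].to_numpy(bool)
    return pd.Series(fail, index=qc.index, name="predicted_fail")


def apply_failures(genotypes, predictions: pd.DataFrame) -> int:
    """Set predicted-failure alleles to missing in-place; returns count set."""
    failed = {
        (r.sample_id, r.locus_id, r.allele_index)
        for r in predictions.itertuples()
        if r.predicted_fail
    }
    n = 0
    for g in genotypes:
        for i, allele in enumerate(g.alleles):
            if (g.sample_id, g.locus_id, i) in failed:
                allele.missing = True
                n += 1
    return n


# ---------------------------------------------------------------------------
# STR-level exclusion
# ---------------------------------------------------------------------------


@dataclass
class QcReport:
    """Per-locus genotyping-quality verdict."""

    locus_id: str
    predicted_failure_freq: float
    observed_failures: int
    inspected: int
    expected_failures: float
    chi2_p: float
    excluded: bool
    exclusion_reason: str  # none | freq_gt_5pct | observed_gt_predicted

    def __post_init__(self) -> None:
        if not 0 <= self.predicted_failure_freq <= 1:
            raise ValueError("predicted_failure_freq must lie in [0, 1]")


def str_exclusion(
    per_locus: pd.DataFrame,
    n_loci: int | None = None,
    freq_threshold: float = 0.05,
    alpha: float = 0.05,
) -> list[QcReport]:
    """Decide per-locus exclusion from the association analyses.

    ``per_locus`` needs columns locus_id, predicted_failure_freq,
    observed_failures, inspected, expected_failures.  A locus is excluded if
    its predicted failure frequency exceeds 5%, or if observed failures
    significantly exceed the model's expectation (1-df chi-square,
    Bonferroni over ``n_loci``; the test only fires in the
    observed > expected direction).
    """
    if n_loci is None:
        n_loci = len(per_locus)
    reports = []
    for r in per_locus.itertuples():
        inspected = int(r.inspected)
        if inspected > 0:
            stat, p = chi2_gof_1df(float(r.observed_failures), float(r.expected_failures), inspected)
        else:
            p = 1.0
        excluded, reason = False, "none"
        if r.predicted_failure_freq > freq_threshold:
            excluded, reason = True, "freq_gt_5pct"
        elif (
            inspected > 0
            and r.observed_failures > r.expected_failures
            and p < alpha / n_loci
        ):
            excluded, reason = True, "observed_gt_predicted"
        reports.append(
            QcReport(
                locus_id=str(r.locus_id),
                predicted_failure_freq=float(r.predicted_failure_freq),
                observed_failures=int(r.observed_failures),
                inspected=inspected,
                expected_failures=float(r.expected_failures),
                chi2_p=float(p),
                excluded=excluded,
                exclusion_reason=reason,
            )
        )
    return reports


def locus_failure_summary(
    qc: pd.DataFrame,
    predictions: pd.Series,
    models: dict[str, FailureModel],
    labels: Sequence[InspectionLabel],
) -> pd.DataFrame:
    """Aggregate per-locus predicted/observed failure statistics for str_exclusion."""
    qc = qc.copy()
    qc["predicted_fail"] = np.asarray(predictions, bool)
    lab_df = _labelled_frame(qc, labels)
    # observed vs expected is only meaningful for alleles the models can score
    lab_df = lab_df[lab_df["support_type"].isin(models)].reset_index(drop=True)
    probs = np.zeros(len(lab_df))
    for rt, model in models.items():
        mask = (lab_df["support_type"] == rt).to_numpy()
        if mask.any():
            probs[mask] = model.predict_proba(lab_df[mask])
    lab_df["fail_prob"] = probs
    rows = []
    for locus_id, grp in qc.groupby("locus_id", sort=True):
        lab_grp = lab_df[lab_df["locus_id"] == locus_id]
        rows.append(
            {
                "locus_id": locus_id,
                "predicted_failure_freq": float(grp["predicted_fail"].mean()),
                "observed_failures": int(lab_grp["fail"].sum()),
                "inspected": int(len(lab_grp)),
                "expected_failures": float(lab_grp["fail_prob"].sum()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Flag-vs-status comparison
# ---------------------------------------------------------------------------


def flags_vs_status(
    qc: pd.DataFrame,
    meta: pd.DataFrame,
    flags: Sequence[str] = FLAG_NAMES,
    include_predicted: bool = True,
) -> pd.DataFrame:
    """Test each binary flag (and predicted failure) for case/control association.

    A sample is flag-positive at a locus if any of its alleles there carries
    the flag.  Each (locus, flag) is tested with Firth logistic regression of
    case status on the indicator, adjusting for sex, country and 10 PCs.
    Returns a tidy frame with effect (OR), CI, p, and an ``untestable``
    marker where the flag does not vary.
    """
    from .design import build_design
    from .stats import ConvergenceError, firth_logistic

    flag_cols = list(flags)
    if include_predicted and "predicted_fail" in qc.columns:
        flag_cols = flag_cols + ["predicted_fail"]
    rows = []
    for locus_id, grp in qc.groupby("locus_id", sort=True):
        per_sample = grp.groupby("sample_id")[flag_cols].any()
        merged = meta.merge(per_sample, left_on="sample_id", right_index=True, how="inner")
        for flag in flag_cols:
            indicator = merged[flag].astype(float).to_numpy()
            row = {"locus_id": locus_id, "flag": flag, "untestable": False,
                   "effect": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan}
            if indicator.min() == indicator.max():
                row["untestable"] = True
            else:
                X, names = build_design(merged, predictor=indicator, predictor_name=flag)
                try:
                    fit = firth_logistic(X, merged["status"].to_numpy(), names)
                    term = fit[flag]
                    row.update(effect=term["effect"], ci_low=term["ci_low"],
                               ci_high=term["ci_high"], p=term["p"])
                except (np.linalg.LinAlgError, ConvergenceError):
                    row["untestable"] = True
            rows.append(row)
    return pd.DataFrame(rows)
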