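"""STR-disease association analyses.

Three complementary views of each locus, for three outcomes (case/control
susceptibility, survival from onset, and age at onset):

1. **Literature thresholds** — carrier status at published pathogenic and
   premutation repeat-size cutoffs, honouring the disease's inheritance mode
   (AD: one expanded allele suffices; AR: both; XR: hemizygous males, both
   alleles in females).
2. **Best-threshold scan** — every observed repeat size is tried as a
   cutoff, samples receive an allelic dosage (0/1/2 alleles at or above the
   cutoff), and the best threshold is the one with the smallest corrected
   p-value (BH-FDR across thresholds within a locus, then Bonferroni across
   loci).
3. **Repeat-size distribution** — the maximum and the sum of a sample's two
   allele sizes enter the model directly (optionally log(1+size)
   transformed).

Susceptibility uses Firth bias-reduced logistic regression, survival a Cox
proportional-hazards model, and onset ordinary linear regression; all adjust
for sex, country and 10 principal components.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import build_design
from .io import LocusDefinition, MotifCountRecord
from .stats import (
    ConvergenceError,
    bh_fdr,
    binomial_glm,
    cox_ph,
    firth_logistic,
    linear_model,
)

CARRIER = "carrier"
NON_CARRIER = "non_carrier"
MISSING = "missing"

SUSCEPTIBILITY = "susceptibility"
SURVIVAL = "survival"
ONSET = "onset"
OUTCOMES = (SUSCEPTIBILITY, SURVIVAL, ONSET)


@dataclass(frozen=True)
class ThresholdSpec:
    """One repeat-size threshold to test: [lower, upper) in repeat units."""

    locus_id: str
    kind: str  # "pathogenic" | "premutation"
    lower: float
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.lower < 1:
            raise ValueError("threshold lower bound must be >= 1")
        if self.kind not in ("pathogenic", "premutation"):
            raise ValueError(f"unknown threshold kind {self.kind!r}")
        if self.kind == "premutation" and not math.isfinite(self.upper):
            raise ValueError("premutation ranges must be bounded above by the pathogenic threshold")


@dataclass
class AssociationResult:
    """One STR x threshold x outcome association."""

    locus_id: str
    analysis: str  # literature | best_threshold | distribution_max | distribution_sum
    outcome: str
    threshold: float | None
    kind: str | None  # pathogenic / premutation / max / sum / dosage
    effect: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_fdr: float | None = None
    p_bonferroni: float | None = None
    n_carriers_case: int | None = None
    n_carriers_control: int | None = None
    untestable: bool = False


def specs_from_loci(loci: Sequence[LocusDefinition]) -> list[ThresholdSpec]:
    """Literature threshold specs (pathogenic, and premutation where defined)."""
    specs = []
    for l in loci:
        if l.pathogenic_threshold is not None:
            specs.append(ThresholdSpec(l.locus_id, "pathogenic", l.pathogenic_threshold))
            if l.premutation_threshold is not None:
                specs.append(
                    ThresholdSpec(l.locus_id, "premutation", l.premutation_threshold, l.pathogenic_threshold)
                )
    return specs


# ---------------------------------------------------------------------------
# Carrier coding
# ---------------------------------------------------------------------------


def _in_range(size, lower, upper, limited, treat_limited: bool) -> bool:
    if limited and treat_limited:
        # a fragment-length-capped call is treated as at least pathogenic-sized
        return not math.isfinite(upper)
    return lower <= size < upper


def carrier_status(
    sizes: Sequence[int | None],
    spec: ThresholdSpec,
    inheritance: str,
    sex: str | None = None,
    fragment_limited: Sequence[bool] | None = None,
    pathogenic_threshold: float | None = None,
    treat_limited_as_expanded: bool = True,
) -> str:
    """Code one sample's carrier status at a threshold under an inheritance mode.

    ``sizes`` may contain ``None`` for alleles set to missing by the failure
    model; the status is ``missing`` whenever the determination depends on a
    missing allele.  For premutation ranges, samples carrying a pathogenic
    allele are not premutation carriers (the two categories are disjoint).
    """
    if not sizes:
        return MISSING
    limited = list(fragment_limited) if fragment_limited is not None else [False] * len(sizes)
    if inheritance == "XR" and len(sizes) == 2 and sex is None:
        return MISSING

    def range_status(lower: float, upper: float) -> str:
        flags = [
            None if s is None else _in_range(s, lower, upper, l, treat_limited_as_expanded)
            for s, l in zip(sizes, limited)
        ]
        known = [f for f in flags if f is not None]
        any_missing = len(known) < len(flags)
        if inheritance == "AD" or (inheritance == "XR" and len(sizes) == 1):
            if any(known):
                return CARRIER
            return MISSING if any_missing else NON_CARRIER
        # AR, and XR in females: both alleles must lie in range
        if any(f is False for f in known):
            return NON_CARRIER
        return MISSING if any_missing else CARRIER

    if spec.kind == "pathogenic":
        return range_status(spec.lower, spec.upper)
    path_thr = pathogenic_threshold if pathogenic_threshold is not None else spec.upper
    known = [
        (s, l) for s, l in zip(sizes, limited) if s is not None
    ]
    if any(_in_range(s, path_thr, math.inf, l, treat_limited_as_expanded) for s, l in known):
        return NON_CARRIER  # pathogenic allele present
    status = range_status(spec.lower, spec.upper)
    if status == CARRIER and len(known) < len(sizes):
        return MISSING  # the missing allele could be pathogenic
    return status


def genotype_matrix(alleles: pd.DataFrame, locus_id: str) -> pd.DataFrame:
    """Wide per-sample view of one locus: size_0/size_1 (NaN = missing allele)."""
    grp = alleles[alleles["locus_id"] == locus_id]
    sizes = grp.copy()
    sizes.loc[sizes["missing"].astype(bool), "size"] = np.nan
    wide = sizes.pivot_table(index="sample_id", columns="allele_index", values="size", aggfunc="first", dropna=False)
    wide.columns = [f"size_{c}" for c in wide.columns]
    if "fragment_limited" in grp.columns:
        lim = grp.pivot_table(
            index="sample_id", columns="allele_index", values="fragment_limited",
            aggfunc="first", dropna=False,
        )
        for c in lim.columns:
            wide[f"limited_{c}"] = lim[c].fillna(False).astype(bool)
    return wide


def carrier_series(
    alleles: pd.DataFrame,
    spec: ThresholdSpec,
    inheritance: str,
    sex_by_sample: pd.Series | None = None,
    pathogenic_threshold: float | None = None,
    treat_limited_as_expanded: bool = True,
) -> pd.Series:
    """Carrier status per sample at one locus threshold (values carrier/non_carrier/missing).

    Vectorized equivalent of applying :func:`carrier_status` per sample.
    """
    grp = alleles[alleles["locus_id"] == spec.locus_id]
    sizes = grp.copy()
    sizes["size"] = sizes["size"].astype(float)
    sizes.loc[sizes["missing"].astype(bool), "size"] = np.nan
    wide = sizes.pivot_table(index="sample_id", columns="allele_index", values="size", aggfunc="first", dropna=False)
    n_called = grp.groupby("sample_id").size().reindex(wide.index).to_numpy(int)
    S = wide.to_numpy(float)
    if S.shape[1] == 1:
        S = np.column_stack([S, np.full(len(S), np.nan)])
    if "fragment_limited" in grp.columns and treat_limited_as_expanded:
        lim_raw = (
            grp.pivot_table(index="sample_id", columns="allele_index",
                            values="fragment_limited", aggfunc="first", dropna=False)
            .reindex(wide.index)
            .reindex(columns=range(S.shape[1]))
            .to_numpy()
        )
        lim = np.where(pd.isna(lim_raw), False, lim_raw).astype(bool)
    else:
        lim = np.zeros_like(S, dtype=bool)
    observed = np.isfinite(S)
    path_thr = (
        pathogenic_threshold
        if pathogenic_threshold is not None
        else (spec.lower if spec.kind == "pathogenic" else spec.upper)
    )

    def in_range_matrix(lower, upper):
        base = (S >= lower) & (S < upper)
        if math.isfinite(upper):
            return np.where(lim, False, base)  # limited calls count as pathogenic-sized
        return base | lim

    lower, upper = spec.lower, spec.upper
    in_r = in_range_matrix(lower, upper) & observed
    out_r = ~in_range_matrix(lower, upper) & observed
    any_missing = observed.sum(axis=1) < n_called

    hemi = n_called == 1
    if inheritance in ("AD",):
        dominant = np.ones(len(S), bool)
    elif inheritance == "XR":
        dominant = hemi  # hemizygous males: single allele decides
    else:
        dominant = np.zeros(len(S), bool)

    status = np.full(len(S), NON_CARRIER, dtype=object)
    # dominant-style coding
    d_car = in_r.any(axis=1)
    status[dominant & d_car] = CARRIER
    status[dominant & ~d_car & any_missing] = MISSING
    # recessive-style coding (AR; XR diploid females)
    rec = ~dominant
    r_non = out_r.any(axis=1)
    r_car = ~r_non & ~any_missing
    status[rec & r_car] = CARRIER
    status[rec & ~r_non & any_missing] = MISSING

    if inheritance == "XR" and sex_by_sample is not None:
        sex = sex_by_sample.reindex(wide.index)
        status[(~hemi) & sex.isna().to_numpy()] = MISSING

    if spec.kind == "premutation":
        path_in = ((S >= path_thr) | lim) & observed
        has_path = path_in.any(axis=1)
        status[has_path] = NON_CARRIER
        status[(~has_path) & (status == CARRIER) & any_missing] = MISSING
    return pd.Series(status, index=wide.index, name="carrier")


# ---------------------------------------------------------------------------
# Cohort filters
# ---------------------------------------------------------------------------


def cohort_filter(meta: pd.DataFrame, min_deceased_fraction: float = 0.30) -> pd.DataFrame:
    """Cases eligible for the progression (survival / onset) analyses.

    Drops cases with onset below 18 years, invalid or missing survival
    records, and all cases from countries where fewer than 30% of cases are
    deceased (a pattern of systematic misdiagnosis).
    """
    cases = meta[meta["status"] == 1].copy()
    valid = (
        cases["onset_age"].notna()
        & (cases["onset_age"] >= 18)
        & cases["survival_months"].notna()
        & (cases["survival_months"] > 0)
        & cases["event"].notna()
    )
    cases = cases[valid]
    if cases.empty:
        return cases
    deceased_frac = cases.groupby("country")["event"].mean()
    keep_countries = deceased_frac[deceased_frac >= min_deceased_fraction].index
    return cases[cases["country"].isin(keep_countries)]


# ---------------------------------------------------------------------------
# Model fitting per outcome
# ---------------------------------------------------------------------------


def _fit_predictor(
    meta: pd.DataFrame, predictor: np.ndarray, outcome: str, name: str = "predictor"
) -> dict | None:
    """Fit one predictor against one outcome with the standard covariates.

    Returns effect/ci/p on the outcome's natural scale, or None if the model
    is untestable (constant predictor, rank deficiency, non-convergence).
    """
    predictor = np.asarray(predictor, float)
    if np.ptp(predictor) == 0:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if outcome == SUSCEPTIBILITY:
                X, names = build_design(meta, predictor, name)
                fit = firth_logistic(X, meta["status"].to_numpy(), names)
            elif outcome == SURVIVAL:
                X, names = build_design(meta, predictor, name, intercept=False)
                fit = cox_ph(meta["survival_months"].to_numpy(), meta["event"].to_numpy(), X, names)
            elif outcome == ONSET:
                X, names = build_design(meta, predictor, name)
                fit = linear_model(meta["onset_age"].to_numpy(), X, names)
            else:
                raise ValueError(f"unknown outcome {outcome!r}")
        except (np.linalg.LinAlgError, ConvergenceError, ValueError):
            return None
    term = fit[name]
    return {"effect": term["effect"], "ci_low": term["ci_low"], "ci_high": term["ci_high"], "p": term["p"]}


def _outcome_meta(meta: pd.DataFrame, outcome: str, progression_meta: pd.DataFrame | None) -> pd.DataFrame:
    if outcome == SUSCEPTIBILITY:
        return meta
    return progression_meta if progression_meta is not None else cohort_filter(meta)


# ---------------------------------------------------------------------------
# (i) Literature-based thresholds
# ---------------------------------------------------------------------------


def literature_threshold_analysis(
    alleles: pd.DataFrame,
    meta: pd.DataFrame,
    loci: Sequence[LocusDefinition],
    outcome: str = SUSCEPTIBILITY,
    specs: Sequence[ThresholdSpec] | None = None,
    min_per_category: int = 5,
    inheritance_override: str | None = None,
    treat_limited_as_expanded: bool = True,
    progression_meta: pd.DataFrame | None = None,
) -> list[AssociationResult]:
    """Carrier-vs-outcome tests at the published thresholds.

    Bonferroni correction spans every (locus, threshold) pair tested for
    this outcome.  For survival and onset, thresholds with fewer than
    ``min_per_category`` observations in either carrier category are
    dropped.
    """
    loci_by_id = {l.locus_id: l for l in loci}
    if specs is None:
        specs = specs_from_loci(loci)
    target = _outcome_meta(meta, outcome, progression_meta).set_index("sample_id", drop=False)
    sex_by_sample = meta.set_index("sample_id")["sex"]
    results: list[AssociationResult] = []
    for spec in specs:
        locus = loci_by_id[spec.locus_id]
        inheritance = inheritance_override or locus.inheritance
        status = carrier_series(
            alleles, spec, inheritance, sex_by_sample,
            pathogenic_threshold=locus.pathogenic_threshold,
            treat_limited_as_expanded=treat_limited_as_expanded,
        )
        status = status[status != MISSING]
        merged = target.loc[target.index.intersection(status.index)].copy()
        merged["carrier"] = (status.loc[merged.index] == CARRIER).astype(float)
        n_car = int(merged["carrier"].sum())
        n_non = int((1 - merged["carrier"]).sum())
        res = AssociationResult(
            locus_id=spec.locus_id, analysis="literature", outcome=outcome,
            threshold=spec.lower, kind=spec.kind,
            effect=np.nan, ci_low=np.nan, ci_high=np.nan, p_raw=np.nan,
            n_carriers_case=int(merged.loc[merged["status"] == 1, "carrier"].sum()),
            n_carriers_control=int(merged.loc[merged["status"] == 0, "carrier"].sum()),
        )
        too_few = outcome != SUSCEPTIBILITY and min(n_car, n_non) < min_per_category
        if n_car == 0 or n_non == 0 or too_few:
            res.untestable = True
        else:
            fitted = _fit_predictor(merged, merged["carrier"].to_numpy(), outcome, "carrier")
            if fitted is None:
                res.untestable = True
            else:
                res.effect, res.ci_low, res.ci_high, res.p_raw = (
                    fitted["effect"], fitted["ci_low"], fitted["ci_high"], fitted["p"],
                )
        results.append(res)
    _apply_bonferroni(results)
    return results


def _apply_bonferroni(results: list[AssociationResult]) -> None:
    tested = [r for r in results if not r.untestable]
    m = len(tested)
    for r in tested:
        r.p_bonferroni = float(min(1.0, r.p_raw * m))


def sensitivity_no_inheritance(
    alleles: pd.DataFrame,
    meta: pd.DataFrame,
    loci: Sequence[LocusDefinition],
    outcome: str = SUSCEPTIBILITY,
    **kwargs,
) -> list[AssociationResult]:
    """Literature analysis rerun with every locus coded autosomal dominant."""
    return literature_threshold_analysis(
        alleles, meta, loci, outcome, inheritance_override="AD", **kwargs
    )


# ---------------------------------------------------------------------------
# (ii) Best-threshold dosage scan
# ---------------------------------------------------------------------------


def _dosage_matrix(alleles: pd.DataFrame, locus_id: str) -> tuple[pd.Index, np.ndarray, np.ndarray]:
    """Per-sample non-missing allele sizes for one locus as an (n, 2) NaN-padded array.

    Also returns the number of called alleles per sample (1 for hemizygous,
    2 otherwise) so NaNs from failure-missing alleles can be told apart from
    the absent second allele of a hemizygous genotype.
    """
    grp = alleles[alleles["locus_id"] == locus_id]
    sizes = grp.copy()
    sizes["size"] = sizes["size"].astype(float)
    sizes.loc[sizes["missing"].astype(bool), "size"] = np.nan
    wide = sizes.pivot_table(index="sample_id", columns="allele_index", values="size", aggfunc="first", dropna=False)
    n_called = grp.groupby("sample_id").size().reindex(wide.index).to_numpy(int)
    return wide.index, wide.to_numpy(float), n_called


def best_threshold_scan(
    alleles: pd.DataFrame,
    meta: pd.DataFrame,
    outcome: str = SUSCEPTIBILITY,
    min_dosage_positive: int = 5,
    progression_meta: pd.DataFrame | None = None,
) -> tuple[list[AssociationResult], dict[str, AssociationResult]]:
    """Scan every observed repeat size as a carrier threshold.

    Per sample and threshold t the predictor is the allelic dosage: the
    number of non-missing alleles of size >= t (0/1/2; 0/1 for hemizygous
    genotypes).  P-values are BH-FDR corrected across thresholds within a
    locus, then Bonferroni corrected across loci.  Returns all per-threshold
    results plus the per-locus best (smallest corrected p; ties resolved
    toward the smaller raw p, then the smaller threshold).

    Susceptibility is significant at corrected p < 0.05; for survival and
    onset the convention is stricter (p < 0.01) because the Cox and linear
    fits are sensitive to extreme repeat sizes.
    """
    target = _outcome_meta(meta, outcome, progression_meta).set_index("sample_id", drop=False)
    locus_ids = sorted(alleles["locus_id"].unique())
    all_results: list[AssociationResult] = []
    per_locus: dict[str, list[AssociationResult]] = {}
    for locus_id in locus_ids:
        index, sizes, _ = _dosage_matrix(alleles, locus_id)
        keep = index.intersection(target.index)
        sizes = sizes[index.get_indexer(keep)]
        merged = target.loc[keep]
        observed = np.unique(sizes[np.isfinite(sizes)])
        results_here: list[AssociationResult] = []
        for t in observed:
            dosage = np.nansum(sizes >= t, axis=1).astype(float)
            n_pos = int((dosage > 0).sum())
            if n_pos == 0:
                continue
            if outcome != SUSCEPTIBILITY and n_pos < min_dosage_positive:
                continue
            fitted = _fit_predictor(merged, dosage, outcome, "dosage")
            if fitted is None:
                continue
            status = merged["status"].to_numpy()
            results_here.append(
                AssociationResult(
                    locus_id=locus_id, analysis="best_threshold", outcome=outcome,
                    threshold=float(t), kind="dosage",
                    effect=fitted["effect"], ci_low=fitted["ci_low"], ci_high=fitted["ci_high"],
                    p_raw=fitted["p"],
                    n_carriers_case=int(((dosage > 0) & (status == 1)).sum()),
                    n_carriers_control=int(((dosage > 0) & (status == 0)).sum()),
                )
            )
        if results_here:
            adj = bh_fdr([r.p_raw for r in results_here])
            for r, a in zip(results_here, adj):
                r.p_fdr = float(a)
            per_locus[locus_id] = results_here
            all_results.extend(results_here)
    n_loci = len(per_locus)
    for r in all_results:
        r.p_bonferroni = float(min(1.0, r.p_fdr * n_loci))
    best = {
        locus: min(rs, key=lambda r: (r.p_bonferroni, r.p_raw, r.threshold))
        for locus, rs in per_locus.items()
    }
    return all_results, best


# ---------------------------------------------------------------------------
# (iii) Repeat-size distribution analysis
# ---------------------------------------------------------------------------


def distribution_analysis(
    alleles: pd.DataFrame,
    meta: pd.DataFrame,
    outcome: str = SUSCEPTIBILITY,
    transform: str = "identity",
    progression_meta: pd.DataFrame | None = None,
) -> list[AssociationResult]:
    """Model the repeat size itself: per locus, max(alleles) and sum(alleles).

    The sum statistic requires both alleles non-missing (the single allele
    for hemizygous genotypes); max uses whatever is observed.  ``transform``
    may be ``log`` for log(1 + size), which tames the right-skewed size
    distributions.  Susceptibility uses a binomial GLM of status on size;
    survival and onset use the Cox and linear models.
    """
    if transform not in ("identity", "log"):
        raise ValueError("transform must be 'identity' or 'log'")
    target = _outcome_meta(meta, outcome, progression_meta).set_index("sample_id", drop=False)
    results: list[AssociationResult] = []
    for locus_id in sorted(alleles["locus_id"].unique()):
        index, sizes, n_called = _dosage_matrix(alleles, locus_id)
        keep = index.intersection(target.index)
        pos = index.get_indexer(keep)
        sizes = sizes[pos]
        n_called = n_called[pos]
        merged = target.loc[keep]
        n_observed = np.isfinite(sizes).sum(axis=1)
        # max needs >= 1 observed allele; sum needs every called allele observed
        raw_max = np.nanmax(np.where(np.isfinite(sizes), sizes, -np.inf), axis=1)
        stats = {
            "max": np.where(n_observed >= 1, raw_max, np.nan),
            "sum": np.where(n_observed == n_called, np.nansum(sizes, axis=1), np.nan),
        }
        for stat_name, values in stats.items():
            mask = np.isfinite(values)
            sub = merged[mask]
            pred = values[mask]
            if transform == "log":
                pred = np.log1p(pred)
            res = AssociationResult(
                locus_id=locus_id, analysis=f"distribution_{stat_name}", outcome=outcome,
                threshold=None, kind=stat_name,
                effect=np.nan, ci_low=np.nan, ci_high=np.nan, p_raw=np.nan,
            )
            if len(sub) < 10 or np.ptp(pred) == 0:
                res.untestable = True
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    try:
                        if outcome == SUSCEPTIBILITY:
                            X, names = build_design(sub, pred, stat_name)
                            fit = binomial_glm(sub["status"].to_numpy(), X, names)
                            term = fit[stat_name]
                            fitted = {"effect": term["effect"], "ci_low": term["ci_low"],
                                      "ci_high": term["ci_high"], "p": term["p"]}
                        else:
                            fitted = _fit_predictor(sub, pred, outcome, stat_name)
                    except (np.linalg.LinAlgError, ConvergenceError, ValueError):
                        fitted = None
                if fitted is None:
                    res.untestable = True
                else:
                    res.effect, res.ci_low, res.ci_high, res.p_raw = (
                        fitted["effect"], fitted["ci_low"], fitted["ci_high"], fitted["p"],
                    )
            results.append(res)
    _apply_bonferroni(results)
    return results


# ---------------------------------------------------------------------------
# External control-panel frequency comparison
# ---------------------------------------------------------------------------


def external_frequency_comparison(
    internal: pd.DataFrame, external: pd.DataFrame, n_tests: int | None = None
) -> list[AssociationResult]:
    """Compare carrier frequencies between two control panels, adjusting for sex.

    Both frames need columns ``locus_id``, ``threshold``, ``kind``,
    ``carrier`` (0/1) and ``sex`` per sample.  Fits Firth logistic regression
    of panel membership (external = 1) on carrier status and sex, one test
    per (locus, threshold); Bonferroni over the number of tests.
    """
    keys = ["locus_id", "threshold", "kind"]
    combos = pd.concat([internal[keys], external[keys]]).drop_duplicates().sort_values(keys)
    results = []
    for _, combo in combos.iterrows():
        sel_i = internal[(internal[keys] == combo.values).all(axis=1)]
        sel_e = external[(external[keys] == combo.values).all(axis=1)]
        carrier = np.concatenate([sel_i["carrier"].to_numpy(float), sel_e["carrier"].to_numpy(float)])
        sex_male = np.concatenate(
            [(sel_i["sex"] == "male").to_numpy(float), (sel_e["sex"] == "male").to_numpy(float)]
        )
        panel = np.concatenate([np.zeros(len(sel_i)), np.ones(len(sel_e))])
        res = AssociationResult(
            locus_id=combo["locus_id"], analysis="external_comparison", outcome=SUSCEPTIBILITY,
            threshold=combo["threshold"], kind=combo["kind"],
            effect=np.nan, ci_low=np.nan, ci_high=np.nan, p_raw=np.nan,
            n_carriers_case=int(sel_e["carrier"].sum()),
            n_carriers_control=int(sel_i["carrier"].sum()),
        )
        if carrier.sum() == 0 or np.ptp(carrier) == 0:
            res.untestable = True
        else:
            cols = [np.ones(len(panel)), carrier]
            names = ["intercept", "carrier"]
            if np.ptp(sex_male) > 0:
                cols.append(sex_male)
                names.append("sex_male")
            try:
                fit = firth_logistic(np.column_stack(cols), panel, names)
                term = fit["carrier"]
                res.effect, res.ci_low, res.ci_high, res.p_raw = (
                    term["effect"], term["ci_low"], term["ci_high"], term["p"],
                )
            except (np.linalg.LinAlgError, ConvergenceError):
                res.untestable = True
        results.append(res)
    if n_tests is None:
        n_tests = sum(1 for r in results if not r.untestable)
    for r in results:
        if not r.untestable:
            r.p_bonferroni = float(min(1.0, r.p_raw * max(n_tests, 1)))
    return results


# ---------------------------------------------------------------------------
# Motif-change comparison
# ---------------------------------------------------------------------------


def motif_count_comparison(
    records: Sequence[MotifCountRecord],
    meta: pd.DataFrame,
    loci: Sequence[LocusDefinition],
    min_samples: int = 2,
) -> list[AssociationResult]:
    """Compare per-motif in-repeat read counts between cases and controls.

    Only motif regions overlapping a catalog locus are considered, and
    motifs consisting of a single repeated nucleotide are excluded (they are
    sequencing artefacts, not motif changes).  Samples without a record for
    a motif contribute a count of zero.  Firth logistic regression of status
    on read count, adjusting for sex, country and 10 PCs; Bonferroni over
    motifs.
    """
    def overlaps(rec: MotifCountRecord) -> str | None:
        for l in loci:
            if rec.contig == l.contig and rec.start < l.end and rec.end > l.start:
                return l.locus_id
        return None

    grouped: dict[tuple[str, str], dict[str, int]] = {}
    for rec in records:
        if len(set(rec.motif)) <= 1:
            continue  # single repeated nucleotide, e.g. 100% C
        locus_id = overlaps(rec)
        if locus_id is None:
            continue
        key = (locus_id, rec.motif)
        grouped.setdefault(key, {})[rec.sample_id] = (
            grouped.get(key, {}).get(rec.sample_id, 0) + rec.read_count
        )
    meta = meta.set_index("sample_id", drop=False)
    results = []
    for (locus_id, motif), counts in sorted(grouped.items()):
        res = AssociationResult(
            locus_id=locus_id, analysis="motif_counts", outcome=SUSCEPTIBILITY,
            threshold=None, kind=motif,
            effect=np.nan, ci_low=np.nan, ci_high=np.nan, p_raw=np.nan,
        )
        if len(counts) < min_samples:
            res.untestable = True
            results.append(res)
            continue
        pred = np.array([counts.get(s, 0) for s in meta.index], float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                X, names = build_design(meta, pred, "read_count")
                fit = firth_logistic(X, meta["status"].to_numpy(), names)
                term = fit["read_count"]
                res.effect, res.ci_low, res.ci_high, res.p_raw = (
                    term["effect"], term["ci_low"], term["ci_high"], term["p"],
                )
            except (np.linalg.LinAlgError, ConvergenceError):
                res.untestable = True
        results.append(res)
    _apply_bonferroni(results)
    return results


# ---------------------------------------------------------------------------
# Tidy output
# ---------------------------------------------------------------------------


def results_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    import dataclasses

    return pd.DataFrame([dataclasses.asdict(r) for r in results])
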