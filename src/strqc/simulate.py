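"""Synthetic ExpansionHunter-style cohorts with known ground truth.

The generator emulates the statistical structure that the QC and
association machinery assume: discrete right-skewed repeat-size
distributions (a common-size core plus a geometric expansion tail), planted
case/control, survival and onset effects at stated thresholds, read support
per allele (spanning reads around the true size, flanking reads bounded by
it, in-repeat reads once the repeat exceeds the read length), and planted
genotyping-failure modes that both corrupt the quality parameters and move
the reported confidence interval off the true size — so an allele is a
ground-truth failure exactly when its true size lies outside the reported
CI, mirroring how failures are adjudicated by visual inspection.

Case/control status is linked to carrier status retrospectively: given the
control carrier frequency f0 and a planted odds ratio, the case carrier
frequency is derived from the odds identity f1/(1-f1) = OR * f0/(1-f0), so
the planted OR is exactly the estimand of the logistic analysis model under
case-control sampling.  Survival times are exponential with the hazard
scaled by HR^carrier and administratively censored; onset is normal with an
additive carrier shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import (
    FLANKING,
    IN_REPEAT,
    SPANNING,
    AlleleCall,
    LocusDefinition,
    ReadSupport,
    SampleGenotype,
    SampleMeta,
    infer_support_type,
)

FAILURE_MODES = ("excess_nonconsistent", "wide_ci", "depth_imbalance", "unsupported")


class ConfigError(ValueError):
    """Infeasible simulation configuration."""


@dataclass
class LocusSim:
    """Simulation parameters for one locus.

    ``expansion_freq`` is the per-sample probability that a control carries
    at least one allele of size >= ``expansion_start`` (which defaults to
    the locus's pathogenic threshold).  ``planted_or``/``planted_hr``/
    ``planted_onset_shift`` act on that carrier indicator.
    """

    definition: LocusDefinition
    core_mean: float = 12.0
    core_sd: float = 4.0
    core_min: int = 2
    core_max: int | None = None  # default: expansion_start - 2
    expansion_freq: float = 0.0
    expansion_start: int | None = None
    expansion_geom_p: float = 0.25
    planted_or: float = 1.0
    planted_hr: float = 1.0
    planted_onset_shift: float = 0.0
    failure_modes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.expansion_start is None:
            self.expansion_start = self.definition.pathogenic_threshold or int(self.core_mean * 3)
        if self.core_max is None:
            self.core_max = max(self.core_min + 1, self.expansion_start - 2)
        bad = set(self.failure_modes) - set(FAILURE_MODES)
        if bad:
            raise ConfigError(f"unknown failure modes {sorted(bad)}")
        total = sum(self.failure_modes.values())
        if any(v < 0 for v in self.failure_modes.values()) or total > 1:
            raise ConfigError("failure-mode proportions must be in [0,1] and sum to <= 1")
        if self.expansion_freq == 0 and self.planted_or != 1.0:
            raise ConfigError(
                f"{self.definition.locus_id}: planted OR with zero expansion frequency is infeasible"
            )
        if not 0 <= self.expansion_freq < 1:
            raise ConfigError("expansion_freq must be in [0, 1)")


@dataclass
class SimulationConfig:
    """Cohort-level simulation parameters.

    Defaults mirror the regime of a large ALS case-control resource:
    5237 cases / 1746 controls with 150 bp reads, ~450 bp fragments and
    ~35x depth, sequenced over a period split roughly 81%/19% around the
    2018-01-01 training cutoff.
    """

    n_cases: int = 5237
    n_controls: int = 1746
    loci: list[LocusSim] = field(default_factory=list)
    countries: tuple[str, ...] = ("NL", "GB", "BE", "IE", "ES")
    country_weights: tuple[float, ...] = (0.3, 0.3, 0.2, 0.1, 0.1)
    male_fraction: float = 0.5
    baseline_median_survival: float = 30.0  # months
    censoring_months: float = 120.0
    onset_mean: float = 61.0
    onset_sd: float = 12.0
    read_length: float = 150.0
    fragment_length: float = 450.0
    mean_depth: float = 35.0
    pre_cutoff_fraction: float = 0.81
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ConfigError("n_cases and n_controls must be >= 1")
        if len(self.countries) != len(self.country_weights):
            raise ConfigError("countries and country_weights lengths differ")


def case_carrier_freq(f0: float, odds_ratio: float) -> float:
    """Carrier frequency among cases implied by the control frequency and OR."""
    if f0 == 0:
        return 0.0
    odds = odds_ratio * f0 / (1 - f0)
    return odds / (1 + odds)


def _allele_prob(sample_freq: float, n_alleles: int = 2) -> float:
    """Per-allele expansion probability giving the target per-sample carrier freq."""
    return 1 - (1 - sample_freq) ** (1.0 / n_alleles)


@dataclass
class Cohort:
    """A simulated cohort: metadata, per-allele table, and optional read-level genotypes."""

    config: SimulationConfig
    meta: pd.DataFrame
    alleles: pd.DataFrame
    genotypes: list[SampleGenotype] | None = None

    @property
    def loci(self) -> list[LocusDefinition]:
        return [l.definition for l in self.config.loci]

    @property
    def sample_info(self) -> dict[str, dict]:
        return {
            r.sample_id: {
                "average_depth": r.average_depth,
                "read_length": r.read_length,
                "fragment_length": r.fragment_length,
                "sex": r.sex,
            }
            for r in self.meta.itertuples()
        }

    def metas(self) -> list[SampleMeta]:
        out = []
        for r in self.meta.itertuples():
            out.append(
                SampleMeta(
                    sample_id=r.sample_id,
                    status="case" if r.status == 1 else "control",
                    sex=r.sex,
                    country=r.country,
                    pcs=tuple(getattr(r, f"pc{i}") for i in range(1, 11)),
                    sequencing_date=r.sequencing_date,
                    read_length=r.read_length,
                    fragment_length=r.fragment_length,
                    average_depth=r.average_depth,
                    onset_age=None if pd.isna(r.onset_age) else float(r.onset_age),
                    survival_months=None if pd.isna(r.survival_months) else float(r.survival_months),
                    event=None if pd.isna(r.event) else bool(r.event),
                )
            )
        return out


def _draw_core_sizes(rng, n, sim: LocusSim) -> np.ndarray:
    sizes = np.rint(rng.normal(sim.core_mean, sim.core_sd, size=n)).astype(int)
    return np.clip(sizes, sim.core_min, sim.core_max)


def _draw_expansion_sizes(rng, n, sim: LocusSim, cap: int) -> np.ndarray:
    sizes = sim.expansion_start + rng.geometric(sim.expansion_geom_p, size=n) - 1
    return np.minimum(sizes, cap)


def generate_cohort(config: SimulationConfig, with_reads: bool = True) -> Cohort:
    """Simulate a cohort; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    status = np.concatenate([np.ones(config.n_cases, int), np.zeros(config.n_controls, int)])
    width = max(5, len(str(n)))
    sample_ids = np.array([f"S{i:0{width}d}" for i in range(1, n + 1)])
    sex = np.where(rng.random(n) < config.male_fraction, "male", "female")
    weights = np.asarray(config.country_weights, float)
    country = rng.choice(list(config.countries), size=n, p=weights / weights.sum())
    pcs = rng.standard_normal((n, 10))
    depth = np.maximum(rng.normal(config.mean_depth, 3.0, size=n), 10.0)

    pre = rng.random(n) < config.pre_cutoff_fraction
    # uniform calendar days inside each era, ISO formatted
    base_pre = np.datetime64("2015-01-01")
    base_post = np.datetime64("2018-01-01")
    offs_pre = rng.integers(0, 1095, size=n)
    offs_post = rng.integers(0, 730, size=n)
    dates = np.where(pre, base_pre + offs_pre.astype("timedelta64[D]"),
                     base_post + offs_post.astype("timedelta64[D]"))
    dates = np.datetime_as_string(dates, unit="D")

    allele_rows: list[pd.DataFrame] = []
    carrier_truth = np.zeros((n, len(config.loci)))
    for j, sim in enumerate(config.loci):
        locus = sim.definition
        motif_len = locus.motif_length
        cap = int(config.fragment_length // motif_len)
        hemi = (locus.inheritance == "XR") & (sex == "male") if locus.on_chrx else np.zeros(n, bool)
        n_alleles = np.where(hemi, 1, 2)
        f1 = case_carrier_freq(sim.expansion_freq, sim.planted_or)
        q = np.where(
            status == 1,
            np.where(n_alleles == 1, f1, _allele_prob(f1)),
            np.where(n_alleles == 1, sim.expansion_freq, _allele_prob(sim.expansion_freq)),
        )
        s_idx = np.repeat(np.arange(n), n_alleles)
        total = len(s_idx)
        allele_index = np.concatenate([np.arange(k) for k in n_alleles])
        expanded = rng.random(total) < q[s_idx]
        true = np.where(
            expanded,
            _draw_expansion_sizes(rng, total, sim, cap),
            _draw_core_sizes(rng, total, sim),
        )
        mode_names = list(sim.failure_modes)
        if mode_names:
            probs = np.array([sim.failure_modes[m] for m in mode_names])
            choices = np.array(mode_names + ["none"], dtype=object)
            mode = choices[
                np.searchsorted(np.cumsum(np.append(probs, 1 - probs.sum())), rng.random(total), side="right")
            ]
        else:
            mode = np.full(total, "none", dtype=object)
        df = pd.DataFrame(
            {"s_idx": s_idx, "allele_index": allele_index, "true_size": true, "failure_mode": mode}
        )
        # ascending true sizes within each genotype
        df = df.sort_values(["s_idx", "true_size"], kind="mergesort")
        df["allele_index"] = df.groupby("s_idx").cumcount()
        df["locus_id"] = locus.locus_id
        df["sample_id"] = sample_ids[df["s_idx"]]
        # reported size and CI
        true_sizes = df["true_size"].to_numpy()
        failed = (df["failure_mode"] != "none").to_numpy()
        delta = np.maximum(3, np.rint(0.6 * true_sizes)).astype(int)
        reported = np.where(failed, true_sizes + delta, true_sizes)
        limited = reported * motif_len >= config.fragment_length - motif_len
        reported = np.minimum(reported, cap)
        span_cap = int((config.read_length - 20) // motif_len)
        spanning_callable = reported <= span_cap
        lo = np.where(spanning_callable, reported, np.maximum(0, reported - np.maximum(1, reported // 8)))
        hi = np.where(spanning_callable, reported, reported + np.maximum(2, reported // 4))
        # mild CI noise on clean spanning calls so quality is a gradient, not a step
        widen = rng.random(len(reported)) < 0.3
        hi = np.where(spanning_callable & widen, hi + rng.integers(1, 3, size=len(reported)), hi)
        shrink = rng.random(len(reported)) < 0.15
        lo = np.where(spanning_callable & shrink, np.maximum(0, lo - 1), lo)
        # failure-mode CIs keep a realistic width but exclude the true size:
        # the reported size overshoots the truth by more than the CI half-width
        lo = np.where(failed, np.maximum(0, reported - np.maximum(1, reported // 8)), lo)
        hi = np.where(failed, reported + np.maximum(2, reported // 4), hi)
        wide = (df["failure_mode"] == "wide_ci").to_numpy()
        hi = np.where(wide, reported + 2 * np.maximum(reported, 10) + 5, hi)
        lo = np.where(wide, reported, lo)
        lo = np.maximum(lo, 0)
        df["size"] = reported
        df["ci_low"] = lo
        df["ci_high"] = hi
        df["fragment_limited"] = limited
        df["fail"] = (true_sizes < lo) | (true_sizes > hi)
        df["missing"] = False
        allele_rows.append(df)
        carriers = (
            df.assign(exp=true_sizes >= sim.expansion_start)
            .groupby("s_idx")["exp"]
            .any()
            .reindex(range(n), fill_value=False)
            .to_numpy()
        )
        carrier_truth[:, j] = carriers

    alleles = pd.concat(allele_rows, ignore_index=True)
    # reported alleles must stay ascending within a genotype after corruption
    alleles = alleles.sort_values(["locus_id", "s_idx", "size", "true_size"], kind="mergesort")
    alleles["allele_index"] = alleles.groupby(["locus_id", "s_idx"]).cumcount()
    alleles = alleles.sort_values(["locus_id", "s_idx", "allele_index"]).reset_index(drop=True)

    # survival and onset for cases, driven by the planted carrier effects
    log_hr = np.zeros(n)
    onset_shift = np.zeros(n)
    for j, sim in enumerate(config.loci):
        log_hr += math.log(sim.planted_hr) * carrier_truth[:, j]
        onset_shift += sim.planted_onset_shift * carrier_truth[:, j]
    lam = math.log(2) / config.baseline_median_survival * np.exp(log_hr)
    t_event = rng.exponential(1.0 / lam)
    t_censor = rng.uniform(6.0, config.censoring_months, size=n)
    survival = np.maximum(np.minimum(t_event, t_censor), 0.5)
    event = (t_event <= t_censor).astype(float)
    onset = rng.normal(config.onset_mean, config.onset_sd, size=n) + onset_shift
    is_case = status == 1

    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "status": status,
            "sex": sex,
            "country": country,
            "sequencing_date": dates,
            "read_length": config.read_length,
            "fragment_length": config.fragment_length,
            "average_depth": depth,
            "onset_age": np.where(is_case, np.round(onset, 1), np.nan),
            "survival_months": np.where(is_case, np.round(survival, 2), np.nan),
            "event": np.where(is_case, event, np.nan),
        }
    )
    for i in range(10):
        meta[f"pc{i + 1}"] = pcs[:, i]

    cohort = Cohort(config=config, meta=meta, alleles=alleles)
    if with_reads:
        cohort.genotypes = _generate_reads(cohort, rng)
        support = {
            (g.sample_id, g.locus_id, i): a.support_type
            for g in cohort.genotypes
            for i, a in enumerate(g.alleles)
        }
        cohort.alleles["support_type"] = [
            support[(r.sample_id, r.locus_id, r.allele_index)] for r in cohort.alleles.itertuples()
        ]
    return cohort


def _generate_reads(cohort: Cohort, rng) -> list[SampleGenotype]:
    """Read-level realization of every genotype; slow path, loops per allele."""
    cfg = cohort.config
    depth_by_sample = dict(zip(cohort.meta["sample_id"], cohort.meta["average_depth"]))
    sims = {s.definition.locus_id: s for s in cfg.loci}
    genotypes = []
    for (locus_id, sample_id), grp in cohort.alleles.groupby(["locus_id", "sample_id"], sort=True):
        sim = sims[locus_id]
        motif = sim.definition.motif
        m = len(motif)
        depth = depth_by_sample[sample_id]
        grp = grp.sort_values("allele_index")
        reported = grp["size"].to_numpy(int)
        true = grp["true_size"].to_numpy(int)
        modes = grp["failure_mode"].to_numpy()
        has_unsupported = "unsupported" in modes
        counts: dict[tuple[str, int], int] = {}

        def add(read_type: str, size: int, count: int) -> None:
            if count > 0:
                key = (read_type, max(int(size), 0))
                counts[key] = counts.get(key, 0) + int(count)

        span_cap = int((cfg.read_length - 20) // m)
        flank_cap = max(int((cfg.read_length - 10) // m), 1)
        for r, s, mode in zip(reported, true, modes):
            if mode == "unsupported":
                continue  # no reads support this allele
            scale = 10.0 if mode == "depth_imbalance" else 1.0
            if s <= span_cap:
                add(SPANNING, s, max(1, rng.poisson(depth / 2 * scale)))
                if not has_unsupported:
                    for _ in range(rng.poisson(1.5)):
                        add(FLANKING, rng.integers(0, s + 1), 1)
            else:
                if not has_unsupported:
                    for _ in range(rng.poisson(depth / 3 * scale) + 1):
                        add(FLANKING, rng.integers(min(s, flank_cap) // 2, min(s, flank_cap) + 1), 1)
                if s * m >= cfg.read_length:
                    add(IN_REPEAT, int(cfg.read_length // m), rng.poisson(depth / 4 * scale) + 1)
            if mode in ("excess_nonconsistent", "depth_imbalance") and rng.random() < 0.5:
                # misaligned reads pile up at the (wrong) reported size
                add(SPANNING, r, rng.poisson(depth / 3) + 1)
            if mode == "excess_nonconsistent":
                add(FLANKING, max(reported.max(), s) + 3, rng.poisson(depth / 2) + 2)
            if mode == "none" and rng.random() < 0.12:
                # sporadic stray reads: clean calls are not pristine
                add(FLANKING, int(reported.max()) + rng.integers(1, 5), rng.integers(1, 4))
        if not counts:  # every allele unsupported: keep one placeholder read
            add(FLANKING, 0, 1)
        reads = [
            ReadSupport(rt, sz, c)
            for (rt, sz), c in sorted(counts.items(), key=lambda kv: (READ_ORDER[kv[0][0]], kv[0][1]))
        ]
        alleles = []
        for r, (_, row) in zip(reported, grp.iterrows()):
            alleles.append(
                AlleleCall(
                    size=int(r),
                    ci_low=int(row["ci_low"]),
                    ci_high=int(row["ci_high"]),
                    support_type=infer_support_type(int(r), reads, m, cfg.read_length),
                )
            )
        genotypes.append(
            SampleGenotype(
                sample_id=sample_id, locus_id=locus_id, alleles=alleles, reads=reads, motif=motif
            )
        )
    return genotypes


READ_ORDER = {SPANNING: 0, FLANKING: 1, IN_REPEAT: 2}


# ---------------------------------------------------------------------------
# ExpansionHunter-style JSON output
# ---------------------------------------------------------------------------


def _counts_string(reads: Sequence[ReadSupport], read_type: str) -> str:
    items = sorted((r.repeat_size, r.count) for r in reads if r.read_type == read_type)
    return ", ".join(f"({s}, {c})" for s, c in items) or "()"


def generate_eh_json(cohort: Cohort, outdir: str | Path) -> list[Path]:
    """Write one ExpansionHunter-style JSON per sample; round-trips via read_eh_json."""
    if cohort.genotypes is None:
        raise ValueError("cohort was generated without reads; re-run with with_reads=True")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_sample: dict[str, list[SampleGenotype]] = {}
    for g in cohort.genotypes:
        by_sample.setdefault(g.sample_id, []).append(g)
    info = cohort.sample_info
    defs = {l.locus_id: l for l in cohort.loci}
    paths = []
    import json as _json

    for sample_id in sorted(by_sample):
        meta = info[sample_id]
        locus_results = {}
        for g in sorted(by_sample[sample_id], key=lambda g: g.locus_id):
            ldef = defs[g.locus_id]
            genotype = "/".join(str(a.size) for a in g.alleles)
            ci = "/".join(f"{a.ci_low}-{a.ci_high}" for a in g.alleles)
            locus_results[g.locus_id] = {
                "AlleleCount": len(g.alleles),
                "Coverage": meta["average_depth"],
                "ReadLength": meta["read_length"],
                "FragmentLength": meta["fragment_length"],
                "LocusId": g.locus_id,
                "Variants": {
                    g.locus_id: {
                        "Genotype": genotype,
                        "GenotypeConfidenceInterval": ci,
                        "CountsOfSpanningReads": _counts_string(g.reads, SPANNING),
                        "CountsOfFlankingReads": _counts_string(g.reads, FLANKING),
                        "CountsOfInrepeatReads": _counts_string(g.reads, IN_REPEAT),
                        "ReferenceRegion": f"{ldef.contig}:{ldef.start}-{ldef.end}",
                        "RepeatUnit": ldef.motif,
                        "VariantId": g.locus_id,
                    }
                },
            }
        doc = {
            "SampleParameters": {"SampleId": sample_id, "Sex": meta["sex"]},
            "LocusResults": locus_results,
        }
        path = outdir / f"{sample_id}.json"
        with open(path, "w") as fh:
            _json.dump(doc, fh, indent=1, sort_keys=True)
        paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# Inspection labels from ground truth
# ---------------------------------------------------------------------------


def generate_inspection_labels(
    cohort: Cohort,
    manifest: Sequence[tuple[str, str, int]],
    label_noise: float | None = None,
    seed: int | None = None,
):
    """Adjudicate manifest alleles against the ground truth.

    Verdict is ``fail`` exactly when the allele's true size lies outside the
    reported confidence interval; ``label_noise`` flips a fraction of
    verdicts to emulate imperfect visual inspection.
    """
    from .failure import InspectionLabel

    if label_noise is None:
        label_noise = cohort.config.label_noise
    rng = np.random.default_rng(cohort.config.seed + 1 if seed is None else seed)
    truth = cohort.alleles.set_index(["sample_id", "locus_id", "allele_index"])
    labels = []
    for key in manifest:
        row = truth.loc[key]
        fail = bool(row["fail"])
        if label_noise and rng.random() < label_noise:
            fail = not fail
        labels.append(
            InspectionLabel(
                sample_id=key[0],
                locus_id=key[1],
                allele_index=key[2],
                verdict="fail" if fail else "pass",
                corrected_size=int(row["true_size"]) if fail else None,
            )
        )
    return labels


# ---------------------------------------------------------------------------
# Default panel
# ---------------------------------------------------------------------------


def als_panel(
    failure_rate: float = 0.0,
    planted: bool = True,
) -> list[LocusSim]:
    """A four-locus panel spanning the inheritance modes and effect regimes.

    Includes a GGCCCC hexanucleotide locus with a strong dominant
    susceptibility/survival/onset effect (OR 16 at >= 30 units, HR 1.51,
    2.4-year earlier onset; 0.47% control carriers), a CAG locus with a
    moderate premutation-range effect (OR 3.0 at >= 29 units), a recessive
    AAGGG locus and an X-linked CAG locus with no planted effects.
    """
    modes = (
        {
            "excess_nonconsistent": failure_rate * 0.4,
            "wide_ci": failure_rate * 0.3,
            "depth_imbalance": failure_rate * 0.2,
            "unsupported": failure_rate * 0.1,
        }
        if failure_rate
        else {}
    )
    c9 = LocusSim(
        definition=LocusDefinition(
            "C9L", "C9L", "GGCCCC", "chr9", 27573482, 27573544, "AD", 30, 24
        ),
        core_mean=7, core_sd=2.5, core_min=2, core_max=11,
        expansion_freq=0.0047, expansion_start=30, expansion_geom_p=0.25,
        planted_or=16.0 if planted else 1.0,
        planted_hr=1.51 if planted else 1.0,
        planted_onset_shift=-2.4 if planted else 0.0,
        failure_modes=dict(modes),
    )
    atxn2 = LocusSim(
        definition=LocusDefinition(
            "A2L", "A2L", "CAG", "chr12", 111598949, 111599018, "AD", 33, 29
        ),
        core_mean=22, core_sd=1.5, core_min=13,
        expansion_freq=0.0088, expansion_start=29, expansion_geom_p=0.6,
        planted_or=3.0 if planted else 1.0,
        failure_modes=dict(modes),
    )
    rfc1 = LocusSim(
        definition=LocusDefinition(
            "R1L", "R1L", "AAGGG", "chr4", 39348424, 39348483, "AR", 60, None
        ),
        core_mean=11, core_sd=4, core_min=2,
        expansion_freq=0.10, expansion_start=60, expansion_geom_p=0.3,
        failure_modes=dict(modes),
    )
    arx = LocusSim(
        definition=LocusDefinition(
            "XRL", "XRL", "CAG", "chrX", 67545316, 67545385, "XR", 38, 35, on_chrx=True
        ),
        core_mean=21, core_sd=3, core_min=9,
        expansion_freq=0.004, expansion_start=38, expansion_geom_p=0.5,
        failure_modes=dict(modes),
    )
    return [c9, atxn2, rfc1, arx]


def qc_panel(n_loci: int = 10, failure_freq: float = 0.03, seed: int = 0) -> list[LocusSim]:
    """A multi-locus null panel for failure-model training experiments.

    Loci alternate short motifs and expansion frequencies so every read type
    (spanning, flanking, in-repeat) is represented among both passing and
    failing alleles.
    """
    rng = np.random.default_rng(seed)
    motifs = ["CAG", "CTG", "GGCCCC", "AAGGG", "GCG", "ATTCT"]
    sims = []
    for i in range(n_loci):
        motif = motifs[i % len(motifs)]
        start = int(rng.integers(25, 45))
        sims.append(
            LocusSim(
                definition=LocusDefinition(
                    f"L{i:02d}", f"L{i:02d}", motif, f"chr{(i % 12) + 1}",
                    1_000_000 + 10_000 * i, 1_000_100 + 10_000 * i, "AD",
                    start, None,
                ),
                core_mean=float(rng.uniform(8, 22)),
                core_sd=float(rng.uniform(2, 5)),
                expansion_freq=float(rng.uniform(0.02, 0.10)),
                expansion_start=start,
                expansion_geom_p=0.2,
                failure_modes={
                    "excess_nonconsistent": failure_freq * 0.4,
                    "wide_ci": failure_freq * 0.25,
                    "depth_imbalance": failure_freq * 0.25,
                    "unsupported": failure_freq * 0.1,
                },
            )
        )
    return sims
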