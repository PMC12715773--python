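"""Per-allele quality parameters and binary QC flags.

Four continuous quality parameters, each scaled to [0, 1] so they can enter
a linear predictor directly:

* ``q_depth`` — ratio of allelic to sample-average read depth, folded so the
  value is 1 at equality and shrinks for both excess and deficit.
* ``q_ci``   — exp(-4 * CI width / repeat size); 1 for a point estimate,
  decaying as the genotyper's confidence interval grows relative to the size.
* ``q_con``  — fraction of attributed reads consistent with the allele.
* ``q_non``  — exp(-4 * non-consistent fraction); 1 when nothing contradicts
  the call.

Seven binary flags mark suspect calls: flanking-read calls, genotypes with
both alleles from in-repeat reads, fragment-length-limited sizes, a 5x
allelic/average depth imbalance, a confidence interval wider than the size,
single-consistent-read calls (J1C), and calls with fewer consistent than
non-consistent reads (LCTNC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .consistency import ConsistencyCounts, attribute_counts
from .io import FLANKING, IN_REPEAT, SampleGenotype

FLAG_NAMES = (
    "from_flanking",
    "both_in_repeat",
    "fragment_limited",
    "depth_5x",
    "ci_gt_size",
    "single_consistent_read_J1C",
    "less_consistent_than_non_LCTNC",
)


@dataclass(frozen=True)
class FlagSet:
    """The seven binary QC flags for one allele."""

    from_flanking: bool
    both_in_repeat: bool
    fragment_limited: bool
    depth_5x: bool
    ci_gt_size: bool
    single_consistent_read_J1C: bool
    less_consistent_than_non_LCTNC: bool

    def any(self) -> bool:
        return any(getattr(self, name) for name in FLAG_NAMES)


@dataclass(frozen=True)
class QcParameters:
    """The four continuous quality parameters for one allele."""

    q_depth: float
    q_ci: float
    q_con: float
    q_non: float
    unsupported: bool = False  # zero reads attributed to the allele


def q_depth(allelic_depth: float, average_depth: float) -> float:
    """Folded depth ratio: min(a, b) / max(a, b)."""
    if average_depth <= 0:
        raise ValueError("average_depth must be positive")
    if allelic_depth < 0:
        raise ValueError("allelic_depth must be non-negative")
    if allelic_depth == 0:
        return 0.0
    return min(allelic_depth, average_depth) / max(allelic_depth, average_depth)


def q_ci(ci_width: float, repeat_size: float) -> float:
    """exp(-4 * CI width / repeat size), with a continuous zero-size limit."""
    if ci_width < 0:
        raise ValueError("ci_width must be non-negative")
    if repeat_size == 0:
        return 1.0 if ci_width == 0 else 0.0
    return math.exp(-4.0 * ci_width / repeat_size)


def q_con(consistent: int, total: int) -> float:
    """Consistent-read fraction; 0 when the allele has no attributed reads."""
    if consistent < 0 or consistent > total:
        raise ValueError("need 0 <= consistent <= total")
    if total == 0:
        return 0.0
    return consistent / total


def q_non(non_consistent: int, total: int) -> float:
    """exp(-4 * non-consistent fraction of attributed reads)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if non_consistent < 0 or non_consistent > total:
        raise ValueError("need 0 <= non_consistent <= total")
    return math.exp(-4.0 * non_consistent / total)


def allele_qc(counts: ConsistencyCounts, ci_width: float, repeat_size: float,
              average_depth: float) -> QcParameters:
    """Assemble the four Q parameters for one allele from its attributed counts."""
    total = counts.total
    unsupported = total == 0
    return QcParameters(
        q_depth=q_depth(total, average_depth),
        q_ci=q_ci(ci_width, repeat_size),
        q_con=q_con(counts.consistent, total),
        q_non=q_non(counts.non_consistent, total) if total > 0 else 0.0,
        unsupported=unsupported,
    )


def binary_flags(
    genotype: SampleGenotype,
    counts: Sequence[ConsistencyCounts],
    average_depth: float,
    fragment_length: float,
    motif_length: int,
) -> list[FlagSet]:
    """Evaluate the seven binary flags for every allele of one genotype."""
    both_irr = all(a.support_type == IN_REPEAT for a in genotype.alleles)
    flags = []
    for allele, c in zip(genotype.alleles, counts):
        allelic_depth = c.total
        flags.append(
            FlagSet(
                from_flanking=allele.support_type == FLANKING,
                both_in_repeat=both_irr,
                fragment_limited=allele.size * motif_length >= fragment_length - motif_length,
                depth_5x=allelic_depth > 5 * average_depth or allelic_depth < average_depth / 5,
                ci_gt_size=allele.ci_width > allele.size,
                single_consistent_read_J1C=c.consistent == 1,
                less_consistent_than_non_LCTNC=c.consistent < c.non_consistent,
            )
        )
    return flags


def qc_table(
    genotypes: Sequence[SampleGenotype],
    sample_info: dict[str, dict],
    motif_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Build the per-allele QC table used by the failure model and manifest.

    ``sample_info`` maps sample_id to a dict with ``average_depth``,
    ``fragment_length`` (and optionally ``read_length``).  ``motif_lengths``
    maps locus_id to motif length; when absent the genotype's own motif is
    used.

    Returns one row per allele with sizes, CIs, support type, attributed
    counts, Q parameters, the seven flags, and the ``unsupported`` marker.
    """
    rows = []
    for g in genotypes:
        info = sample_info[g.sample_id]
        avg_depth = info["average_depth"]
        frag_len = info["fragment_length"]
        motif_len = (motif_lengths or {}).get(g.locus_id) or max(len(g.motif), 1)
        counts = attribute_counts(g.sizes, g.reads)
        flags = binary_flags(g, counts, avg_depth, frag_len, motif_len)
        for i, (allele, c, f) in enumerate(zip(g.alleles, counts, flags)):
            qp = allele_qc(c, allele.ci_width, allele.size, avg_depth)
            row = {
                "sample_id": g.sample_id,
                "locus_id": g.locus_id,
                "allele_index": i,
                "size": allele.size,
                "ci_low": allele.ci_low,
                "ci_high": allele.ci_high,
                "support_type": allele.support_type,
                "consistent": c.consistent,
                "non_consistent": c.non_consistent,
                "total": c.total,
                "q_depth": qp.q_depth,
                "q_ci": qp.q_ci,
                "q_con": qp.q_con,
                "q_non": qp.q_non,
                "unsupported": qp.unsupported,
            }
            for name in FLAG_NAMES:
                row[name] = getattr(f, name)
            rows.append(row)
    return pd.DataFrame(rows)
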