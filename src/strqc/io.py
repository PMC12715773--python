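"""Readers and writers for STR genotyping inputs and reports.

Handles ExpansionHunter-style per-sample genotype JSON, variant-catalog JSON,
phenotype/covariate tables, per-motif read-count tables (ExpansionHunter
Denovo-style), and tab-separated report output.

Coordinates are 0-based half-open throughout.  Repeat sizes are in repeat
units (copies of the motif), never base pairs.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

SPANNING = "spanning"
FLANKING = "flanking"
IN_REPEAT = "in_repeat"
READ_TYPES = (SPANNING, FLANKING, IN_REPEAT)

INHERITANCE_MODES = ("AD", "AR", "XR")

_MOTIF_RE = re.compile(r"^[ACGT]{1,6}$")


class ParseError(ValueError):
    """Malformed field in a genotype JSON or table."""


class SchemaError(ValueError):
    """Input table is missing required columns."""


@dataclass(frozen=True)
class LocusDefinition:
    """One STR locus: motif, location, inheritance mode, literature thresholds.

    ``pathogenic_threshold`` and ``premutation_threshold`` are repeat-unit
    cutoffs from the disease literature; premutation must be strictly below
    pathogenic when both are given.
    """

    locus_id: str
    gene: str
    motif: str
    contig: str
    start: int
    end: int
    inheritance: str
    pathogenic_threshold: int | None = None
    premutation_threshold: int | None = None
    on_chrx: bool = False

    def __post_init__(self) -> None:
        if not _MOTIF_RE.match(self.motif):
            raise ValueError(f"{self.locus_id}: motif {self.motif!r} must match [ACGT]{{1,6}}")
        if self.end <= self.start:
            raise ValueError(f"{self.locus_id}: end must exceed start")
        if self.inheritance not in INHERITANCE_MODES:
            raise ValueError(f"{self.locus_id}: inheritance {self.inheritance!r} not in {INHERITANCE_MODES}")
        if (
            self.pathogenic_threshold is not None
            and self.premutation_threshold is not None
            and not self.premutation_threshold < self.pathogenic_threshold
        ):
            raise ValueError(f"{self.locus_id}: premutation threshold must be below pathogenic")

    @property
    def motif_length(self) -> int:
        return len(self.motif)


@dataclass(frozen=True)
class ReadSupport:
    """Count of reads of one type observed at one repeat size."""

    read_type: str
    repeat_size: int
    count: int

    def __post_init__(self) -> None:
        if self.read_type not in READ_TYPES:
            raise ValueError(f"unknown read type {self.read_type!r}")
        if self.repeat_size < 0 or self.count < 1:
            raise ValueError("repeat_size must be >= 0 and count >= 1")


@dataclass
class AlleleCall:
    """One called allele: size, genotyper confidence interval, support read type."""

    size: int
    ci_low: int
    ci_high: int
    support_type: str = SPANNING
    missing: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.size <= self.ci_high):
            raise ValueError(f"CI ({self.ci_low},{self.ci_high}) must bracket size {self.size}")

    @property
    def ci_width(self) -> int:
        return self.ci_high - self.ci_low


@dataclass
class SampleGenotype:
    """Per sample x locus genotype: 1 (hemizygous) or 2 allele calls plus read support."""

    sample_id: str
    locus_id: str
    alleles: list[AlleleCall]
    reads: list[ReadSupport] = field(default_factory=list)
    motif: str = ""

    def __post_init__(self) -> None:
        if not 1 <= len(self.alleles) <= 2:
            raise ValueError("genotype must carry 1 or 2 alleles")
        self.alleles.sort(key=lambda a: a.size)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(a.size for a in self.alleles)

    @property
    def hemizygous(self) -> bool:
        return len(self.alleles) == 1


@dataclass
class SampleMeta:
    """Phenotype and sequencing covariates for one sample."""

    sample_id: str
    status: str  # "case" | "control"
    sex: str  # "male" | "female"
    country: str
    pcs: tuple[float, ...]
    sequencing_date: str | None = None  # ISO-8601; compared lexicographically
    read_length: float | None = None
    fragment_length: float | None = None
    average_depth: float | None = None
    onset_age: float | None = None
    survival_months: float | None = None
    event: bool | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.pcs) != 10:
            raise ValueError(f"{self.sample_id}: expected 10 principal components, got {len(self.pcs)}")
        if self.survival_months is not None and not self.survival_months > 0:
            raise ValueError(f"{self.sample_id}: survival_months must be positive")


@dataclass(frozen=True)
class MotifCountRecord:
    """Per-sample in-repeat read count for one motif at one region."""

    sample_id: str
    contig: str
    start: int
    end: int
    motif: str
    read_count: int

    def __post_init__(self) -> None:
        if not self.motif:
            raise ValueError("motif must be non-empty")
        if self.read_count < 0:
            raise ValueError("read_count must be non-negative")


# ---------------------------------------------------------------------------
# ExpansionHunter-style JSON
# ---------------------------------------------------------------------------

_COUNTS_PAIR_RE = re.compile(r"\(\s*(\d+)\s*,\s*(\d+)\s*\)")


def parse_counts_string(text: str, read_type: str) -> list[ReadSupport]:
    """Parse a ``"(size, count), (size, count)"`` counts field into ReadSupport entries."""
    if text is None:
        return []
    text = text.strip()
    if text in ("", "()"):
        return []
    pairs = _COUNTS_PAIR_RE.findall(text)
    stripped = _COUNTS_PAIR_RE.sub("", text).replace(",", "").strip()
    if not pairs or stripped:
        raise ParseError(f"malformed counts string {text!r}")
    return [ReadSupport(read_type, int(s), int(c)) for s, c in pairs if int(c) > 0]


def _parse_genotype(genotype: str, ci: str | Sequence[str], locus_id: str) -> list[tuple[int, int, int]]:
    """Parse genotype 'a/b' (or 'a') with CI 'l-h/l-h' into (size, lo, hi) triples."""
    try:
        sizes = [int(part) for part in str(genotype).split("/")]
    except ValueError as exc:
        raise ParseError(f"{locus_id}: malformed genotype string {genotype!r}") from exc
    if isinstance(ci, str):
        ci_parts = ci.split("/")
    else:  # per-allele list dialect
        ci_parts = [str(p) for p in ci]
    if len(ci_parts) != len(sizes):
        raise ParseError(
            f"{locus_id}: CI field has {len(ci_parts)} alleles but genotype {genotype!r} has {len(sizes)}"
        )
    out = []
    for size, part in zip(sizes, ci_parts):
        m = re.match(r"^\s*(\d+)\s*-\s*(\d+)\s*$", part)
        if not m:
            raise ParseError(f"{locus_id}: malformed confidence interval {part!r}")
        lo, hi = int(m.group(1)), int(m.group(2))
        if not lo <= size <= hi:
            raise ParseError(f"{locus_id}: CI {part!r} does not bracket size {size}")
        out.append((size, lo, hi))
    return out


def infer_support_type(
    size: int, reads: Sequence[ReadSupport], motif_length: int, read_length: float | None
) -> str:
    """Infer which read type determined an allele's size.

    Spanning reads pin a size exactly, so an allele whose size matches a
    spanning read is spanning-called.  An allele at least as long as the read
    length can only be seen via in-repeat reads; anything else was sized from
    flanking reads.
    """
    for r in reads:
        if r.read_type == SPANNING and r.repeat_size == size:
            return SPANNING
    has_irr = any(r.read_type == IN_REPEAT for r in reads)
    if has_irr and read_length is not None and size * motif_length >= read_length:
        return IN_REPEAT
    return FLANKING


def read_eh_json(path: str | Path) -> tuple[list[SampleGenotype], dict]:
    """Read one ExpansionHunter-style JSON file.

    Returns ``(genotypes, sample_info)`` where ``sample_info`` carries the
    sample-level fields (sample_id, sex, read_length, fragment_length,
    average_depth) needed downstream for QC.
    """
    with open(path) as fh:
        doc = json.load(fh)
    params = doc.get("SampleParameters", {})
    sample_id = params.get("SampleId", Path(path).stem)
    info = {
        "sample_id": sample_id,
        "sex": params.get("Sex"),
        "read_length": None,
        "fragment_length": None,
        "average_depth": None,
    }
    genotypes: list[SampleGenotype] = []
    for locus_id, locus in doc.get("LocusResults", {}).items():
        info["average_depth"] = locus.get("Coverage", info["average_depth"])
        info["read_length"] = locus.get("ReadLength", info["read_length"])
        info["fragment_length"] = locus.get("FragmentLength", info["fragment_length"])
        for variant in locus.get("Variants", {}).values():
            genotype = variant.get("Genotype")
            if genotype in (None, ""):
                continue  # no call at this locus
            triples = _parse_genotype(genotype, variant.get("GenotypeConfidenceInterval", ""), locus_id)
            reads: list[ReadSupport] = []
            for key, rtype in (
                ("CountsOfSpanningReads", SPANNING),
                ("CountsOfFlankingReads", FLANKING),
                ("CountsOfInrepeatReads", IN_REPEAT),
            ):
                reads.extend(parse_counts_string(variant.get(key, "()"), rtype))
            motif = variant.get("RepeatUnit", "")
            alleles = [
                AlleleCall(
                    size=s,
                    ci_low=lo,
                    ci_high=hi,
                    support_type=infer_support_type(s, reads, max(len(motif), 1), info["read_length"]),
                )
                for s, lo, hi in triples
            ]
            genotypes.append(
                SampleGenotype(sample_id=sample_id, locus_id=locus_id, alleles=alleles, reads=reads, motif=motif)
            )
    return genotypes, info


def read_eh_json_dir(directory: str | Path) -> tuple[list[SampleGenotype], dict[str, dict]]:
    """Read every ``*.json`` file in a directory; returns genotypes and per-sample info."""
    genotypes: list[SampleGenotype] = []
    infos: dict[str, dict] = {}
    for path in sorted(Path(directory).glob("*.json")):
        g, info = read_eh_json(path)
        genotypes.extend(g)
        infos[info["sample_id"]] = info
    return genotypes, infos


# ---------------------------------------------------------------------------
# Variant catalog
# ---------------------------------------------------------------------------

_STRUCT_RE = re.compile(r"\(([ACGT]{1,6})\)")
_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


def read_catalog(path: str | Path) -> list[LocusDefinition]:
    """Read a variant-catalog JSON (list of locus entries)."""
    with open(path) as fh:
        doc = json.load(fh)
    loci = []
    for entry in doc:
        locus_id = entry["LocusId"]
        motif = entry.get("RepeatUnit")
        if motif is None:
            m = _STRUCT_RE.search(entry.get("LocusStructure", ""))
            if not m:
                raise ParseError(f"{locus_id}: cannot extract motif from LocusStructure")
            motif = m.group(1)
        region = entry["ReferenceRegion"]
        m = _REGION_RE.match(region)
        if not m:
            raise ParseError(f"{locus_id}: malformed ReferenceRegion {region!r}")
        contig, start, end = m.group(1), int(m.group(2)), int(m.group(3))
        loci.append(
            LocusDefinition(
                locus_id=locus_id,
                gene=entry.get("Gene", locus_id),
                motif=motif,
                contig=contig,
                start=start,
                end=end,
                inheritance=entry.get("Inheritance", "AD"),
                pathogenic_threshold=entry.get("PathogenicThreshold"),
                premutation_threshold=entry.get("PremutationThreshold"),
                on_chrx=bool(entry.get("OnChrX", contig.lstrip("chr") == "X")),
            )
        )
    return loci


def write_catalog(loci: Iterable[LocusDefinition], path: str | Path) -> None:
    entries = []
    for l in loci:
        entries.append(
            {
                "LocusId": l.locus_id,
                "Gene": l.gene,
                "LocusStructure": f"({l.motif})*",
                "RepeatUnit": l.motif,
                "ReferenceRegion": f"{l.contig}:{l.start}-{l.end}",
                "Inheritance": l.inheritance,
                "PathogenicThreshold": l.pathogenic_threshold,
                "PremutationThreshold": l.premutation_threshold,
                "OnChrX": l.on_chrx,
            }
        )
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=1)


# ---------------------------------------------------------------------------
# Phenotype table
# ---------------------------------------------------------------------------

_PC_COLS = [f"pc{i}" for i in range(1, 11)]
_REQUIRED_PHENO = ["sample_id", "status", "sex", "country", *_PC_COLS]
_OPTIONAL_PHENO = ["sequencing_date", "read_length", "fragment_length", "average_depth",
                   "onset_age", "survival_months", "event"]

DEFAULT_STATUS_ALIASES = {"case": "case", "control": "control", "1": "case", "0": "control"}


def read_phenotypes(
    path: str | Path, status_aliases: Mapping[str, str] | None = None
) -> list[SampleMeta]:
    """Read a phenotype TSV into typed SampleMeta records.

    ``status_aliases`` maps raw status strings (e.g. a disease code) onto
    ``case``/``control``.  Unknown columns are preserved in ``extras``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, comment="#")
    missing = [c for c in _REQUIRED_PHENO if c not in df.columns]
    if missing:
        raise SchemaError(f"phenotype table missing required columns: {missing}")
    aliases = dict(DEFAULT_STATUS_ALIASES)
    if status_aliases:
        aliases.update({str(k).lower(): v for k, v in status_aliases.items()})
    extras_cols = [c for c in df.columns if c not in _REQUIRED_PHENO + _OPTIONAL_PHENO]
    metas = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # 1-based, after header
        status = aliases.get(str(row["status"]).lower())
        if status not in ("case", "control"):
            raise ParseError(f"line {line_no}: unrecognized status {row['status']!r}")
        try:
            pcs = tuple(float(row[c]) for c in _PC_COLS)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"line {line_no}: non-numeric principal component") from exc

        def opt_float(col):
            if col in df.columns and pd.notna(row[col]):
                return float(row[col])
            return None

        event = None
        if "event" in df.columns and pd.notna(row["event"]):
            event = bool(int(row["event"]))
        metas.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                status=status,
                sex=str(row["sex"]).lower(),
                country=str(row["country"]),
                pcs=pcs,
                sequencing_date=str(row["sequencing_date"])
                if "sequencing_date" in df.columns and pd.notna(row["sequencing_date"])
                else None,
                read_length=opt_float("read_length"),
                fragment_length=opt_float("fragment_length"),
                average_depth=opt_float("average_depth"),
                onset_age=opt_float("onset_age"),
                survival_months=opt_float("survival_months"),
                event=event,
                extras={c: row[c] for c in extras_cols},
            )
        )
    return metas


def meta_frame(metas: Sequence[SampleMeta]) -> pd.DataFrame:
    """Flatten SampleMeta records into the analysis DataFrame."""
    rows = []
    for m in metas:
        row = {
            "sample_id": m.sample_id,
            "status": 1 if m.status == "case" else 0,
            "sex": m.sex,
            "country": m.country,
            "sequencing_date": m.sequencing_date,
            "read_length": m.read_length,
            "fragment_length": m.fragment_length,
            "average_depth": m.average_depth,
            "onset_age": m.onset_age,
            "survival_months": m.survival_months,
            "event": m.event,
        }
        for i, v in enumerate(m.pcs, start=1):
            row[f"pc{i}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def write_phenotypes(metas: Sequence[SampleMeta], path: str | Path) -> None:
    df = meta_frame(metas)
    df["status"] = df["status"].map({1: "case", 0: "control"})
    cols = _REQUIRED_PHENO + [c for c in _OPTIONAL_PHENO if df[c].notna().any()]
    df[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Motif-count table (ExpansionHunter Denovo-style)
# ---------------------------------------------------------------------------


def read_motif_counts(path: str | Path) -> list[MotifCountRecord]:
    """Read an EHdn-style TSV: contig, start, end, motif, then one column per sample."""
    df = pd.read_csv(path, sep="\t")
    fixed = ["contig", "start", "end", "motif"]
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise SchemaError(f"motif-count table missing columns: {missing}")
    sample_cols = [c for c in df.columns if c not in fixed]
    records = []
    for _, row in df.iterrows():
        for s in sample_cols:
            if pd.notna(row[s]) and float(row[s]) > 0:
                records.append(
                    MotifCountRecord(
                        sample_id=str(s),
                        contig=str(row["contig"]),
                        start=int(row["start"]),
                        end=int(row["end"]),
                        motif=str(row["motif"]),
                        read_count=int(row[s]),
                    )
                )
    return records


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def write_report(results, path: str | Path, header_lines: Sequence[str] = ()) -> None:
    """Write results (DataFrame or list of dataclasses) as a TSV report.

    Columns come out in a deterministic order and numeric values round-trip
    through :func:`read_report` exactly.
    """
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        results = list(results)
        if not results:
            raise ValueError("cannot write an empty report")
        first = results[0]
        if hasattr(first, "__dataclass_fields__"):
            import dataclasses

            df = pd.DataFrame([dataclasses.asdict(r) for r in results])
        else:
            df = pd.DataFrame(results)
    if df.empty:
        raise ValueError("cannot write an empty report")
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
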