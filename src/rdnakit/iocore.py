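"""Shared data model, file readers/writers and configuration.

All genomic coordinates are 1-based inclusive.  Deletion alleles are encoded
as ``"-"``; insertions as ``"ins:<seq>"`` anchored at the position left of
the inserted sequence.  Variant names follow the ``X{pos}.{ref}.{alt}``
convention used throughout the package.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

logger = logging.getLogger("rdnakit")

SITE_COLUMNS = ["sample", "source", "position", "allele", "fwd", "rev"]

_VARIANT_NAME_RE = re.compile(r"^X(\d+)\.([ACGT\-]|ins:[ACGT]+)\.([ACGT\-]|ins:[ACGT]+)$")


class FormatError(ValueError):
    """Raised when a file does not conform to the expected layout."""


class ValidationError(ValueError):
    """Raised when file contents violate a domain invariant."""


class Source(str, Enum):
    DNA = "DNA"
    RNA = "RNA"


class CallStatus(str, Enum):
    PASS = "pass"
    BELOW_FREQUENCY = "below_frequency"
    STRAND_BIASED = "strand_biased"
    LOW_DEPTH = "low_depth"
    OUT_OF_SPAN = "out_of_span"


class SegState(str, Enum):
    HOM_A = "homA"
    HOM_B = "homB"
    HET = "het"


@dataclass(frozen=True)
class StrandCounts:
    """Strand-split read counts: (a, c) major allele, (b, d) minor allele."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"strand count {name} is negative: {v}")
        if (self.a + self.c) < (self.b + self.d):
            raise ValidationError(
                "major allele counts (a+c) must be >= minor allele counts (b+d)"
            )

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def variant_name(position: int, ref: str, alt: str) -> str:
    return f"X{position}.{ref}.{alt}"


def parse_variant_name(name: str) -> tuple[int, str, str]:
    m = _VARIANT_NAME_RE.match(name)
    if m is None:
        raise FormatError(f"not a valid variant name: {name!r}")
    return int(m.group(1)), m.group(2), m.group(3)


@dataclass(frozen=True)
class VariantCall:
    position: int
    ref: str
    alt: str
    copy_fraction: float
    sb_score: float | None
    depth: int
    status: CallStatus

    @property
    def name(self) -> str:
        return variant_name(self.position, self.ref, self.alt)

    @property
    def passed(self) -> bool:
        return self.status is CallStatus.PASS


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds governing variant calling and downstream filters.

    ``frac_inclusive`` selects whether a copy fraction exactly at
    ``min_frac`` is kept (the default) or rejected.
    """

    min_frac: float = 0.05
    sb_max: float = 0.8
    span: tuple[int, int] = (300, 8009)
    min_rna_reads: int = 25
    min_dna_reads: int = 25
    parental_min_frac: float = 0.10
    max_founder_sharing: int = 7
    frac_inclusive: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.min_frac < 1.0):
            raise ValidationError("min_frac must be in (0, 1)")
        if self.span[0] >= self.span[1]:
            raise ValidationError("span start must be < span end")
        if self.sb_max < 0:
            raise ValidationError("sb_max must be >= 0")

    def in_span(self, position: int) -> bool:
        return self.span[0] <= position <= self.span[1]

    def frac_ok(self, fraction: float) -> bool:
        if self.frac_inclusive:
            return fraction >= self.min_frac
        return fraction > self.min_frac

    @classmethod
    def from_dict(cls, d: Mapping) -> "FilterConfig":
        kwargs = dict(d)
        if "span" in kwargs:
            kwargs["span"] = tuple(kwargs["span"])
        return cls(**kwargs)

    def with_overrides(self, **kwargs) -> "FilterConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GenotypeSegment:
    chromosome: str
    start: int
    end: int
    state: SegState

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"segment start {self.start} > end {self.end} on {self.chromosome}"
            )

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class SiteCountTable:
    """Per-site, per-allele strand-split counts for one or more samples."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SITE_COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"missing columns: {missing}")
        self.data = self.data[SITE_COLUMNS].reset_index(drop=True)
        bad = self.data.index[(self.data["fwd"] < 0) | (self.data["rev"] < 0)]
        if len(bad):
            raise ValidationError(f"negative count at row {bad[0] + 1}")
        bad_src = ~self.data["source"].isin([s.value for s in Source])
        if bad_src.any():
            row = int(self.data.index[bad_src][0]) + 1
            raise ValidationError(f"unknown source at row {row}")
        dup = self.data.duplicated(subset=["sample", "source", "position", "allele"])
        if dup.any():
            row = int(self.data.index[dup][0]) + 1
            raise ValidationError(f"duplicate (sample, source, position, allele) at row {row}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample"]))

    def subset(self, sample: str | None = None, source: Source | str | None = None) -> "SiteCountTable":
        df = self.data
        if sample is not None:
            df = df[df["sample"] == sample]
        if source is not None:
            src = source.value if isinstance(source, Source) else source
            df = df[df["source"] == src]
        return SiteCountTable(df.reset_index(drop=True))

    def site_depths(self) -> pd.Series:
        """Total reads spanning each position (summed over alleles)."""
        tot = self.data["fwd"] + self.data["rev"]
        return tot.groupby(self.data["position"]).sum()


def read_site_counts(path: str | Path) -> SiteCountTable:
    """Read a strand-split site count TSV.

    The file must have the header ``sample source position allele fwd rev``.
    Malformed rows raise with the 1-based data row number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample": str, "source": str, "allele": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in ("position", "fwd", "rev"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0]) + 1
            raise ValidationError(f"{path}: non-numeric {col} at row {row}")
        if coerced.isna().any():
            row = int(df.index[coerced.isna()][0]) + 1
            raise ValidationError(f"{path}: missing {col} at row {row}")
        df[col] = coerced.astype(int)
    try:
        return SiteCountTable(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_site_counts(table: SiteCountTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def write_variant_table(
    calls_by_sample: Mapping[str, Sequence[VariantCall]], path: str | Path
) -> pd.DataFrame:
    """Write a per-sample copy-fraction matrix, one column per variant.

    Columns are ordered by position, then alternative allele; duplicate
    variant names within one sample are an error.  Samples lacking a variant
    get an empty cell.
    """
    names: dict[str, tuple[int, str]] = {}
    rows: dict[str, dict[str, float]] = {}
    for sample, calls in calls_by_sample.items():
        row: dict[str, float] = {}
        for call in calls:
            if call.name in row:
                raise ValidationError(f"duplicate variant {call.name} in sample {sample}")
            row[call.name] = call.copy_fraction
            names[call.name] = (call.position, call.alt)
        rows[sample] = row
    ordered = sorted(names, key=lambda n: (names[n][0], names[n][1]))
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=ordered)
    df.index.name = "sample"
    df.to_csv(path)
    return df


def write_segments(
    segments_by_individual: Mapping[str, Sequence[GenotypeSegment]], path: str | Path
) -> None:
    """Write genotype segments as BED-like TSV (half-open in the file only)."""
    records = []
    for indiv, segs in segments_by_individual.items():
        for seg in segs:
            records.append((seg.chromosome, seg.start - 1, seg.end, seg.state.value, indiv))
    pd.DataFrame(records, columns=["chrom", "start", "end", "state", "individual"]).to_csv(
        path, sep="\t", index=False
    )


def read_segments(path: str | Path) -> dict[str, list[GenotypeSegment]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "state": str, "individual": str})
    out: dict[str, list[GenotypeSegment]] = {}
    for rec in df.itertuples(index=False):
        out.setdefault(rec.individual, []).append(
            GenotypeSegment(rec.chrom, int(rec.start) + 1, int(rec.end), SegState(rec.state))
        )
    return out


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config root must be a mapping")
    return cfg


def filter_config_from_file(path: str | Path | None, **overrides) -> FilterConfig:
    base: dict = {}
    if path is not None:
        cfg = load_config(path)
        base = dict(cfg.get("filters", cfg))
    base.update({k: v for k, v in overrides.items() if v is not None})
    return FilterConfig.from_dict(base)


def log_filter_counts(stage: str, counts: Mapping[str, int]) -> None:
    parts = ", ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("%s: %s", stage, parts)


def read_reference_alleles(path: str | Path) -> dict[int, str]:
    """Read a two-column TSV mapping 1-based position to reference allele."""
    df = pd.read_csv(path, sep="\t", dtype={"ref": str})
    if not {"position", "ref"} <= set(df.columns):
        raise FormatError(f"{path}: expected columns (position, ref)")
    return dict(zip(df["position"].astype(int), df["ref"]))


def write_reference_alleles(ref: Mapping[int, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(ref.items()), columns=["position", "ref"]
    ).to_csv(path, sep="\t", index=False)
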