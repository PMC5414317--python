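"""Assignment of rDNA variants to the chromosome-2 or chromosome-4 cluster.

Variants are mapped by scanning their per-line copy fractions against
founder labels across the genome (one-way ANOVA per marker), requiring a
genome-wide-significant peak in exactly one rDNA top region plus agreement
between observed carrier status and the founder of origin at that locus.
Biparental crosses use parental-specific markers and perfect co-segregation
with the locus genotype instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .iocore import FilterConfig, VariantCall
from .simpop import RDNA2, RDNA2_CHROM, RDNA4, RDNA4_CHROM, GenomeMap, IndividualGenome

logger = logging.getLogger("rdnakit")

_MAX_NEGLOG10P = 300.0

CHR2_TOP = "chr2_top"
CHR4_TOP = "chr4_top"
OTHER = "other"

_REGION_TO_CLUSTER = {CHR2_TOP: RDNA2, CHR4_TOP: RDNA4}
_CLUSTER_TO_REGION = {v: k for k, v in _REGION_TO_CLUSTER.items()}


@dataclass
class MosaicMatrix:
    """Founder labels (or parental states) at every marker for every line."""

    lines: list[str]
    genome_map: GenomeMap
    labels: dict[str, np.ndarray]  # chrom -> (n_lines, n_markers)

    @classmethod
    def from_genomes(cls, genomes: Sequence[IndividualGenome], genome_map: GenomeMap) -> "MosaicMatrix":
        labels = {
            chrom: np.vstack([np.asarray(g.markers[chrom], dtype=object) for g in genomes])
            for chrom in genome_map.positions
        }
        return cls([g.id for g in genomes], genome_map, labels)

    @property
    def n_lines(self) -> int:
        return len(self.lines)


@dataclass
class LinkageScan:
    table: pd.DataFrame  # columns: chrom, position, stat, region
    peak_index: int

    @property
    def peak(self) -> pd.Series:
        return self.table.iloc[self.peak_index]

    @property
    def peak_stat(self) -> float:
        return float(self.peak["stat"])

    @property
    def peak_region(self) -> str:
        return str(self.peak["region"])

    def region_max(self, region: str) -> float:
        sub = self.table.loc[self.table["region"] == region, "stat"]
        return float(sub.max()) if len(sub) else 0.0


@dataclass(frozen=True)
class ClusterAssignment:
    variant: str
    call: str  # RDNA2 | RDNA4 | "ambiguous"
    peak_region: str
    peak_stat: float
    threshold: float
    consistency: float | None


@dataclass
class ConsistencyResult:
    fraction: float | None
    discordant_lines: list[str] = field(default_factory=list)


def founder_sharing_filter(presence: Mapping[str, bool] | Sequence[bool], max_sharing: int = 7) -> bool:
    """True iff the variant is carried by at most ``max_sharing`` founders."""
    values = list(presence.values()) if isinstance(presence, Mapping) else list(presence)
    return sum(bool(v) for v in values) <= max_sharing


def _anova_neglog10p(y: np.ndarray, codes: np.ndarray, k: int) -> np.ndarray:
    """One-way ANOVA -log10 p of y (n,) or (n, P) on integer group codes."""
    y2 = y if y.ndim == 2 else y[:, None]
    n = y2.shape[0]
    if k < 2 or n - k < 1:
        return np.zeros(y2.shape[1]) if y.ndim == 2 else np.zeros(1)[0]
    tot = y2.sum(axis=0)
    sst = (y2 ** 2).sum(axis=0) - tot ** 2 / n
    scale = np.maximum((y2 ** 2).sum(axis=0), 1.0)
    sst = np.where(sst < 1e-12 * scale, 0.0, sst)
    ssb = np.zeros_like(tot, dtype=float)
    for g in range(k):
        mask = codes == g
        n_g = int(mask.sum())
        if n_g == 0:
            continue
        s_g = y2[mask].sum(axis=0)
        ssb += s_g ** 2 / n_g
    ssb -= tot ** 2 / n
    ssb = np.clip(ssb, 0.0, sst)
    ssw = np.maximum(sst - ssb, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / (k - 1)) / (ssw / (n - k))
    out = np.zeros_like(f)
    finite = np.isfinite(f) & (f > 0)
    if finite.any():
        p = stats.f.sf(f[finite], k - 1, n - k)
        out[finite] = np.where(p > 0, -np.log10(np.maximum(p, 1e-300)), _MAX_NEGLOG10P)
    degenerate = ~np.isfinite(f) & (ssb > 1e-12)
    out[degenerate] = _MAX_NEGLOG10P
    return out if y.ndim == 2 else float(out[0])


def _region_labels(gmap: GenomeMap, chrom: str, top_fraction: float) -> np.ndarray:
    n = len(gmap.positions[chrom])
    regions = np.full(n, OTHER, dtype=object)
    top = gmap.top_indices(chrom, top_fraction)
    if chrom == RDNA2_CHROM:
        regions[top] = CHR2_TOP
    elif chrom == RDNA4_CHROM:
        regions[top] = CHR4_TOP
    return regions


def linkage_scan(
    abundance: Sequence[float] | np.ndarray,
    mosaics: MosaicMatrix,
    top_fraction: float = 0.05,
) -> LinkageScan:
    """Per-marker ANOVA of variant abundance on founder labels.

    Returns -log10 p per marker; constant abundance gives a flat scan.
    Requires at least 30 lines.
    """
    y = np.asarray(abundance, dtype=float)
    if len(y) != mosaics.n_lines:
        raise ValueError("abundance length does not match number of lines")
    if mosaics.n_lines < 30:
        raise ValueError("linkage scan requires >= 30 lines")
    frames = []
    for chrom, pos in mosaics.genome_map.positions.items():
        lab = mosaics.labels[chrom]
        stats_col = np.zeros(len(pos))
        for j in range(len(pos)):
            codes, uniques = pd.factorize(lab[:, j])
            stats_col[j] = _anova_neglog10p(y, codes, len(uniques))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "position": pos,
                    "stat": stats_col,
                    "region": _region_labels(mosaics.genome_map, chrom, top_fraction),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return LinkageScan(table, int(table["stat"].to_numpy().argmax()))


def permutation_max_stats(
    abundance: Sequence[float] | np.ndarray,
    mosaics: MosaicMatrix,
    n_perm: int = 200,
    seed: int | None = None,
) -> np.ndarray:
    """Genome-wide max -log10 p under permutation of abundance over lines."""
    rng = np.random.default_rng(seed)
    y = np.asarray(abundance, dtype=float)
    perms = np.empty((len(y), n_perm))
    for p in range(n_perm):
        perms[:, p] = y[rng.permutation(len(y))]
    maxima = np.zeros(n_perm)
    for chrom, pos in mosaics.genome_map.positions.items():
        lab = mosaics.labels[chrom]
        for j in range(len(pos)):
            codes, uniques = pd.factorize(lab[:, j])
            maxima = np.maximum(maxima, _anova_neglog10p(perms, codes, len(uniques)))
    return maxima


def permutation_threshold(max_stats: np.ndarray, alpha: float = 0.05) -> float:
    return float(np.quantile(max_stats, 1.0 - alpha))


def check_consistency(
    presence: Mapping[str, bool],
    locus_founders: Mapping[str, str],
    carrier_founders: set[str],
) -> ConsistencyResult:
    """Fraction of lines whose carrier status matches the founder of origin.

    ``presence`` maps line id to observed carrier status, ``locus_founders``
    to the line's founder at the candidate locus.  Lines missing from either
    mapping are skipped; with no informative lines the fraction is None.
    """
    match = 0
    total = 0
    discordant = []
    for line, carried in presence.items():
        founder = locus_founders.get(line)
        if founder is None:
            continue
        predicted = founder in carrier_founders
        total += 1
        if bool(carried) == predicted:
            match += 1
        else:
            discordant.append(line)
    if total == 0:
        return ConsistencyResult(None)
    return ConsistencyResult(match / total, discordant)


def flag_discordant_lines(
    discordant_by_variant: Mapping[str, Sequence[str]], min_variants: int = 2
) -> list[str]:
    """Lines discordant for >= ``min_variants`` variants (genotype-correction candidates)."""
    counts: dict[str, int] = {}
    for lines in discordant_by_variant.values():
        for line in lines:
            counts[line] = counts.get(line, 0) + 1
    return sorted(l for l, c in counts.items() if c >= min_variants)


def flag_discordant_founders(
    discordant_by_variant: Mapping[str, Sequence[str]],
    line_founders: Mapping[str, str],
    min_variants: int = 5,
) -> list[str]:
    """Founders accumulating >= ``min_variants`` discordant variants; to be dropped."""
    counts: dict[str, int] = {}
    seen: set[tuple[str, str]] = set()
    for variant, lines in discordant_by_variant.items():
        for line in lines:
            founder = line_founders.get(line)
            if founder is None or (variant, founder) in seen:
                continue
            seen.add((variant, founder))
            counts[founder] = counts.get(founder, 0) + 1
    return sorted(f for f, c in counts.items() if c >= min_variants)


def assign_cluster(
    variant: str,
    scan: LinkageScan,
    consistency: ConsistencyResult,
    threshold: float,
    consistency_min: float = 0.95,
) -> ClusterAssignment:
    """Call a cluster iff the peak is in exactly one rDNA top region,
    genome-wide significant, the other top is not significant, and the
    carrier/founder consistency is high enough; otherwise ambiguous.
    """
    region = scan.peak_region
    call = "ambiguous"
    if region in _REGION_TO_CLUSTER and scan.peak_stat >= threshold:
        other_region = CHR4_TOP if region == CHR2_TOP else CHR2_TOP
        cons = consistency.fraction
        if scan.region_max(other_region) < threshold and cons is not None and cons >= consistency_min:
            call = _REGION_TO_CLUSTER[region]
    return ClusterAssignment(
        variant, call, region, scan.peak_stat, threshold, consistency.fraction
    )


def locus_founder_labels(mosaics: MosaicMatrix, cluster: str) -> dict[str, str]:
    """Founder of origin at an rDNA locus for every line (top marker label)."""
    chrom = RDNA2_CHROM if cluster == RDNA2 else RDNA4_CHROM
    lab = mosaics.labels[chrom][:, 0]
    return {line: str(l) for line, l in zip(mosaics.lines, lab)}


def assign_variants(
    abundance: pd.DataFrame,
    mosaics: MosaicMatrix,
    founder_presence: Mapping[str, Mapping[str, bool]],
    cfg: FilterConfig | None = None,
    n_perm: int = 200,
    alpha: float = 0.05,
    consistency_min: float = 0.95,
    presence_min: float | None = None,
    seed: int | None = None,
    top_fraction: float = 0.05,
) -> dict[str, ClusterAssignment]:
    """Scan and assign every variant column of ``abundance`` (lines x variants).

    ``founder_presence`` maps variant name to per-founder DNA-pass status;
    variants shared by too many founders are skipped.
    """
    cfg = cfg or FilterConfig()
    presence_min = presence_min if presence_min is not None else cfg.min_frac
    rng = np.random.default_rng(seed)
    abundance = abundance.loc[mosaics.lines]
    out: dict[str, ClusterAssignment] = {}
    for variant in abundance.columns:
        fp = founder_presence.get(variant, {})
        if not founder_sharing_filter(fp, cfg.max_founder_sharing):
            logger.info("variant %s shared by too many founders; skipped", variant)
            continue
        y = abundance[variant].to_numpy(dtype=float)
        y = np.nan_to_num(y, nan=0.0)
        scan = linkage_scan(y, mosaics, top_fraction)
        maxima = permutation_max_stats(y, mosaics, n_perm, seed=int(rng.integers(2**32)))
        threshold = permutation_threshold(maxima, alpha)
        region = scan.peak_region
        cluster = _REGION_TO_CLUSTER.get(region)
        if cluster is not None:
            carriers = {f for f, present in fp.items() if present}
            presence = {
                line: bool(v >= presence_min) for line, v in zip(mosaics.lines, y)
            }
            cons = check_consistency(presence, locus_founder_labels(mosaics, cluster), carriers)
        else:
            cons = ConsistencyResult(None)
        out[variant] = assign_cluster(variant, scan, cons, threshold, consistency_min)
    return out


def parental_specific_markers(
    parent_a_calls: Sequence[VariantCall],
    parent_b_calls: Sequence[VariantCall],
    cfg: FilterConfig | None = None,
) -> dict[str, list[str]]:
    """Variants at >= ``parental_min_frac`` in one parent and absent
    (below the calling floor) in the other.
    """
    cfg = cfg or FilterConfig()
    frac_a = {c.name: c.copy_fraction for c in parent_a_calls}
    frac_b = {c.name: c.copy_fraction for c in parent_b_calls}
    pass_a = {c.name for c in parent_a_calls if c.passed}
    pass_b = {c.name for c in parent_b_calls if c.passed}
    out: dict[str, list[str]] = {"A": [], "B": []}
    for name in sorted(pass_a | pass_b):
        fa, fb = frac_a.get(name, 0.0), frac_b.get(name, 0.0)
        if name in pass_a and fa >= cfg.parental_min_frac and fb < cfg.min_frac:
            out["A"].append(name)
        elif name in pass_b and fb >= cfg.parental_min_frac and fa < cfg.min_frac:
            out["B"].append(name)
    return out


def assign_biparental(
    marker_parents: Mapping[str, str],
    presence: pd.DataFrame,
    locus_genotypes: Mapping[str, Mapping[str, str]],
    min_informative: int = 8,
) -> dict[str, ClusterAssignment]:
    """Assign parental markers to the locus whose genotype perfectly
    co-segregates with marker presence across lines.

    ``marker_parents`` maps variant name to "A" or "B"; ``presence`` is a
    boolean lines x variants frame; ``locus_genotypes[line][cluster]`` is in
    {"AA", "AB", "BB"}.  Lines informative for a marker are those whose
    predicted presence differs between the two loci.
    """
    out: dict[str, ClusterAssignment] = {}
    for variant, parent in marker_parents.items():
        obs = presence[variant]
        votes = {RDNA2: True, RDNA4: True}
        informative = 0
        for line in presence.index:
            genos = locus_genotypes.get(line)
            if genos is None:
                continue
            pred = {
                cluster: parent in genos[cluster] for cluster in (RDNA2, RDNA4)
            }
            if pred[RDNA2] != pred[RDNA4]:
                informative += 1
            for cluster in (RDNA2, RDNA4):
                if bool(obs[line]) != pred[cluster]:
                    votes[cluster] = False
        if informative < min_informative:
            logger.warning(
                "marker %s: only %d informative lines (<%d); ambiguous",
                variant, informative, min_informative,
            )
            call = "ambiguous"
        elif votes[RDNA2] and not votes[RDNA4]:
            call = RDNA2
        elif votes[RDNA4] and not votes[RDNA2]:
            call = RDNA4
        else:
            call = "ambiguous"
        out[variant] = ClusterAssignment(variant, call, OTHER, 0.0, 0.0, None)
    return out


def write_marker_table(assignments: Mapping[str, ClusterAssignment], path) -> None:
    pd.DataFrame(
        [
            {
                "variant": a.variant,
                "cluster": a.call,
                "peak_region": a.peak_region,
                "peak_stat": a.peak_stat,
                "threshold": a.threshold,
                "consistency": a.consistency,
            }
            for a in assignments.values()
        ]
    ).to_csv(path, index=False)
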