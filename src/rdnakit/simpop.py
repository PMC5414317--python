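"""Synthetic populations with known rDNA cluster haplotypes and silencing.

Generates cluster haplotypes (variant compositions over tandem copies),
crossing designs (inbred panel, F1, F2, multi-founder mosaics), per-haplotype
activity under a dominance rule table, and strand-split read counts with
beta-binomial noise — giving every inference stage a known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .iocore import (
    SITE_COLUMNS,
    SiteCountTable,
    ValidationError,
    parse_variant_name,
    variant_name,
)

RDNA2 = "rDNA-2"
RDNA4 = "rDNA-4"
RDNA2_CHROM = "2"
RDNA4_CHROM = "4"

_BASES = "ACGT"


def reference_allele(position: int) -> str:
    """Deterministic pseudo-reference base at a 1-based position."""
    return _BASES[position % 4]


@dataclass(frozen=True)
class ClusterHaplotype:
    """One rDNA cluster 'allele': identity, size and variant composition.

    ``composition`` maps variant name to the fraction of this haplotype's
    tandem copies carrying the variant.
    """

    id: str
    cluster: str
    copy_number: int
    composition: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cluster not in (RDNA2, RDNA4):
            raise ValidationError(f"unknown cluster {self.cluster!r}")
        if self.copy_number <= 0:
            raise ValidationError("copy_number must be > 0")
        for name, frac in self.composition.items():
            parse_variant_name(name)
            if not (0.0 <= frac <= 1.0):
                raise ValidationError(f"composition fraction out of [0,1] for {name}")


@dataclass(frozen=True)
class Founder:
    id: str
    rdna2: ClusterHaplotype
    rdna4: ClusterHaplotype

    def __post_init__(self) -> None:
        if self.rdna2.cluster != RDNA2 or self.rdna4.cluster != RDNA4:
            raise ValidationError(f"founder {self.id}: haplotype clusters mismatched")

    def haplotype(self, cluster: str) -> ClusterHaplotype:
        return self.rdna2 if cluster == RDNA2 else self.rdna4


@dataclass
class GenomeMap:
    """Marker coordinates: chromosome names and 1-based marker positions."""

    positions: dict[str, np.ndarray]

    @classmethod
    def regular(cls, n_chromosomes: int = 5, n_markers: int = 200, spacing: int = 10_000) -> "GenomeMap":
        pos = np.arange(1, n_markers + 1) * spacing
        return cls({str(c): pos.copy() for c in range(1, n_chromosomes + 1)})

    @property
    def chromosomes(self) -> list[str]:
        return list(self.positions)

    def top_indices(self, chrom: str, fraction: float = 0.05) -> np.ndarray:
        n = len(self.positions[chrom])
        k = max(1, int(np.ceil(fraction * n)))
        return np.arange(k)


@dataclass
class IndividualGenome:
    """Two-locus rDNA genotype plus background marker genotypes.

    ``markers[chrom]`` is an array of per-marker labels: founder ids for
    mosaic designs, or {"A", "H", "B"} for biparental designs.
    """

    id: str
    rdna2: tuple[str, str]
    rdna4: tuple[str, str]
    markers: dict[str, np.ndarray] = field(default_factory=dict)

    def haplotype_ids(self) -> list[str]:
        return [self.rdna2[0], self.rdna2[1], self.rdna4[0], self.rdna4[1]]

    def genotype_key(self) -> tuple[str, ...]:
        return tuple(sorted(self.haplotype_ids()))


@dataclass(frozen=True)
class SimConfig:
    coverage_dna: float = 100.0
    coverage_rna: float = 500.0
    overdispersion: float = 0.0
    strand_artifact_rate: float = 0.0
    recomb_rate: float = 1.5
    error_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage_dna <= 0 or self.coverage_rna <= 0:
            raise ValidationError("coverages must be > 0")
        if not (0.0 <= self.overdispersion < 1.0):
            raise ValidationError("overdispersion must be in [0, 1)")
        for p in (self.strand_artifact_rate, self.error_rate):
            if not (0.0 <= p <= 1.0):
                raise ValidationError("rates must be probabilities")


class DominanceRuleTable:
    """Map from an unordered four-haplotype genotype to per-haplotype activity.

    Keys are the multiset of the four haplotype ids (two per locus).  A
    ``default_activity`` callable may supply activities for genotypes
    without an explicit entry; otherwise lookup raises ``KeyError``.
    """

    def __init__(self, default: str | None = None):
        self._rules: dict[tuple[str, ...], dict[str, float]] = {}
        self.default = default  # None or "codominant"

    @staticmethod
    def _key(hap_ids: Iterable[str]) -> tuple[str, ...]:
        key = tuple(sorted(hap_ids))
        if len(key) != 4:
            raise ValidationError("genotype key must contain exactly 4 haplotype ids")
        return key

    def set_rule(self, hap_ids: Iterable[str], activities: Mapping[str, float]) -> None:
        key = self._key(hap_ids)
        acts = dict(activities)
        for hid in set(key):
            if hid not in acts:
                raise ValidationError(f"activity missing for haplotype {hid}")
            if not (0.0 <= acts[hid] <= 1.0):
                raise ValidationError("activity must lie in [0, 1]")
        if all(acts[hid] == 0.0 for hid in set(key)):
            raise ValidationError("at least one haplotype must be active per genotype")
        self._rules[key] = {hid: acts[hid] for hid in set(key)}

    def activities(self, genome: IndividualGenome) -> dict[str, float]:
        key = self._key(genome.haplotype_ids())
        if key in self._rules:
            return dict(self._rules[key])
        if self.default == "codominant":
            return {hid: 1.0 for hid in set(key)}
        raise KeyError(f"no dominance rule for genotype {key} and no default")

    def __contains__(self, hap_ids: Iterable[str]) -> bool:
        return self._key(hap_ids) in self._rules


def apply_dominance(genome: IndividualGenome, rules: DominanceRuleTable) -> dict[str, float]:
    """Per-haplotype activity fractions for this genome's two-locus genotype."""
    return rules.activities(genome)


def make_cluster_haplotype(
    hap_id: str,
    cluster: str,
    n_private_variants: int,
    copy_number: int,
    fraction_distribution=None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    span: tuple[int, int] = (300, 8009),
    exclude_positions: set[int] | None = None,
) -> ClusterHaplotype:
    """Draw a haplotype with private variants at unique positions in ``span``.

    ``fraction_distribution`` is a callable rng -> float giving the fraction
    of copies carrying each variant (default uniform on [0.2, 1.0]).
    """
    if n_private_variants < 0:
        raise ValidationError("n_private_variants must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    exclude = exclude_positions or set()
    available = [p for p in range(span[0], span[1] + 1) if p not in exclude]
    if n_private_variants > len(available):
        raise ValidationError("more variants requested than available positions")
    positions = rng.choice(len(available), size=n_private_variants, replace=False)
    if fraction_distribution is None:
        fraction_distribution = lambda r: float(r.uniform(0.2, 1.0))
    composition: dict[str, float] = {}
    for idx in sorted(int(i) for i in positions):
        pos = available[idx]
        ref = reference_allele(pos)
        alt = rng.choice([b for b in _BASES if b != ref])
        composition[variant_name(pos, ref, str(alt))] = fraction_distribution(rng)
    return ClusterHaplotype(hap_id, cluster, copy_number, composition)


def make_founder_panel(
    n_founders: int,
    n_variants_per_haplotype: int = 2,
    copy_number: int | tuple[int, int] = 200,
    fraction_distribution=None,
    seed: int | None = None,
    span: tuple[int, int] = (300, 8009),
) -> list[Founder]:
    """Founders with globally unique (founder-private) variant positions."""
    rng = np.random.default_rng(seed)
    used: set[int] = set()
    founders = []
    for i in range(n_founders):
        fid = f"P{i + 1:02d}"
        haps = {}
        for cluster, tag in ((RDNA2, "rDNA2"), (RDNA4, "rDNA4")):
            if isinstance(copy_number, tuple):
                cn = int(rng.integers(copy_number[0], copy_number[1] + 1))
            else:
                cn = copy_number
            hap = make_cluster_haplotype(
                f"{fid}.{tag}",
                cluster,
                n_variants_per_haplotype,
                cn,
                fraction_distribution=fraction_distribution,
                rng=rng,
                span=span,
                exclude_positions=used,
            )
            used.update(parse_variant_name(v)[0] for v in hap.composition)
            haps[cluster] = hap
        founders.append(Founder(fid, haps[RDNA2], haps[RDNA4]))
    return founders


def _gamete_labels(
    parent_labels: Sequence[str],
    n_markers: int,
    chrom_length: int,
    positions: np.ndarray,
    recomb_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One recombinant chromosome: Poisson crossovers, uniform placement."""
    n_x = rng.poisson(recomb_rate)
    breaks = np.sort(rng.uniform(0, chrom_length, size=n_x))
    start = int(rng.integers(len(parent_labels)))
    switches = np.searchsorted(breaks, positions)  # crossovers left of marker
    idx = (start + switches) % len(parent_labels)
    return np.asarray(parent_labels, dtype=object)[idx]


def _mosaic_labels(
    founder_ids: Sequence[str],
    chrom_length: int,
    positions: np.ndarray,
    recomb_rate: float,
    rng: np.random.Generator,
    generations: int = 4,
) -> np.ndarray:
    """A founder mosaic: each segment drawn independently among founders.

    Crossover count is Poisson with mean ``recomb_rate * generations``,
    approximating breakpoint accumulation over the intercross pedigree.
    """
    n_x = rng.poisson(recomb_rate * generations)
    breaks = np.sort(rng.uniform(0, chrom_length, size=n_x))
    seg_founders = rng.choice(founder_ids, size=n_x + 1)
    idx = np.searchsorted(breaks, positions)
    return np.asarray(seg_founders, dtype=object)[idx]


def _rdna_label(markers: dict[str, np.ndarray], chrom: str) -> str:
    return str(markers[chrom][0])


def simulate_cross(
    design: str,
    founders: Sequence[Founder],
    n_individuals: int,
    recomb_rate: float = 1.5,
    seed: int | None = None,
    genome_map: GenomeMap | None = None,
) -> list[IndividualGenome]:
    """Simulate a crossing design with the rDNA loci at the top of chr 2 and 4.

    Designs: ``inbred_panel`` (founders as homozygous lines), ``f1``, ``f2``
    (two founders), ``magic_mosaic`` (>= 3 founders; founder-labelled
    homozygous mosaics).  F2 marker labels are {"A","H","B"} with parent 1
    as "A"; mosaic labels are founder ids.
    """
    rng = np.random.default_rng(seed)
    gmap = genome_map if genome_map is not None else GenomeMap.regular()
    for chrom in (RDNA2_CHROM, RDNA4_CHROM):
        if chrom not in gmap.positions:
            raise ValidationError(f"genome map lacks chromosome {chrom}")
    by_id = {f.id: f for f in founders}

    def hap_pair(labels: tuple[str, str], cluster: str) -> tuple[str, str]:
        tag = "rdna2" if cluster == RDNA2 else "rdna4"
        return tuple(getattr(by_id[l], tag).id for l in labels)  # type: ignore[return-value]

    genomes: list[IndividualGenome] = []
    if design == "inbred_panel":
        for i in range(n_individuals):
            f = founders[i % len(founders)]
            markers = {
                c: np.full(len(p), f.id, dtype=object) for c, p in gmap.positions.items()
            }
            genomes.append(
                IndividualGenome(
                    f"{design}_{i:04d}",
                    (f.rdna2.id, f.rdna2.id),
                    (f.rdna4.id, f.rdna4.id),
                    markers,
                )
            )
        return genomes

    if design in ("f1", "f2"):
        if len(founders) != 2:
            raise ValidationError(f"design {design} requires exactly 2 founders")
        p, q = founders
        if design == "f1":
            for i in range(n_individuals):
                markers = {c: np.full(len(pos), "H", dtype=object) for c, pos in gmap.positions.items()}
                genomes.append(
                    IndividualGenome(
                        f"f1_{i:04d}",
                        (p.rdna2.id, q.rdna2.id),
                        (p.rdna4.id, q.rdna4.id),
                        markers,
                    )
                )
            return genomes
        # F2: two recombinant gametes from the F1 (labels "A" = parent p)
        for i in range(n_individuals):
            gametes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
            markers = {}
            for chrom, pos in gmap.positions.items():
                length = int(pos[-1])
                g1 = _gamete_labels(["A", "B"], len(pos), length, pos, recomb_rate, rng)
                g2 = _gamete_labels(["A", "B"], len(pos), length, pos, recomb_rate, rng)
                gametes[chrom] = (g1, g2)
                geno = np.where(g1 == g2, g1, "H")
                markers[chrom] = geno.astype(object)
            lab = {"A": p.id, "B": q.id}
            r2 = tuple(lab[str(g[0])] for g in gametes[RDNA2_CHROM])
            r4 = tuple(lab[str(g[0])] for g in gametes[RDNA4_CHROM])
            genomes.append(
                IndividualGenome(
                    f"f2_{i:04d}",
                    hap_pair(r2, RDNA2),  # type: ignore[arg-type]
                    hap_pair(r4, RDNA4),  # type: ignore[arg-type]
                    markers,
                )
            )
        return genomes

    if design == "magic_mosaic":
        if len(founders) < 3:
            raise ValidationError("magic_mosaic requires >= 3 founders")
        fids = [f.id for f in founders]
        for i in range(n_individuals):
            markers = {}
            for chrom, pos in gmap.positions.items():
                length = int(pos[-1])
                markers[chrom] = _mosaic_labels(fids, length, pos, recomb_rate, rng)
            f2l = _rdna_label(markers, RDNA2_CHROM)
            f4l = _rdna_label(markers, RDNA4_CHROM)
            genomes.append(
                IndividualGenome(
                    f"magic_{i:04d}",
                    (by_id[f2l].rdna2.id, by_id[f2l].rdna2.id),
                    (by_id[f4l].rdna4.id, by_id[f4l].rdna4.id),
                    markers,
                )
            )
        return genomes

    raise ValidationError(f"unknown design {design!r}")


def expected_fractions(
    genome: IndividualGenome,
    activities: Mapping[str, float],
    haplotypes: Mapping[str, ClusterHaplotype],
) -> pd.DataFrame:
    """Exact copy-weighted DNA and activity-weighted RNA variant fractions.

    DNA fraction of variant v = sum_i cn_i * comp_i(v) / sum_i cn_i over the
    four haplotype copies; the RNA fraction additionally weights each copy by
    its activity (silenced copies contribute no RNA reads).
    """
    copies = [haplotypes[h] for h in genome.haplotype_ids()]
    total_cn = sum(h.copy_number for h in copies)
    if total_cn == 0:
        raise ValidationError("zero total copy number")
    total_active = sum(h.copy_number * activities[h.id] for h in copies)
    variants = sorted(
        {v for h in copies for v in h.composition}, key=lambda n: parse_variant_name(n)[0]
    )
    rows = []
    for v in variants:
        dna = sum(h.copy_number * h.composition.get(v, 0.0) for h in copies) / total_cn
        if total_active > 0:
            rna = (
                sum(
                    h.copy_number * activities[h.id] * h.composition.get(v, 0.0)
                    for h in copies
                )
                / total_active
            )
        else:
            rna = float("nan")
        rows.append((v, dna, rna))
    return pd.DataFrame(rows, columns=["variant", "dna_fraction", "rna_fraction"])


def _beta_binomial(rng: np.random.Generator, n: int, p: float, rho: float) -> int:
    if n == 0:
        return 0
    p = min(max(p, 0.0), 1.0)
    if rho <= 0.0 or p in (0.0, 1.0):
        return int(rng.binomial(n, p))
    alpha = p * (1.0 - rho) / rho
    beta = (1.0 - p) * (1.0 - rho) / rho
    return int(rng.binomial(n, rng.beta(alpha, beta)))


def simulate_counts(
    genome: IndividualGenome,
    activities: Mapping[str, float],
    cfg: SimConfig,
    haplotypes: Mapping[str, ClusterHaplotype],
    rng: np.random.Generator | None = None,
) -> tuple[SiteCountTable, SiteCountTable]:
    """Strand-split DNA and RNA count tables at this genome's variant sites.

    Counts are beta-binomial around the expected fractions, split 50:50
    across strands; with probability ``strand_artifact_rate`` a variant's
    minor-allele DNA reads are collapsed onto a single strand.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    exp = expected_fractions(genome, activities, haplotypes)
    rows_dna, rows_rna = [], []
    for rec in exp.itertuples(index=False):
        pos, ref, alt = parse_variant_name(rec.variant)
        artifact = rng.random() < cfg.strand_artifact_rate
        for source, coverage, frac, rows in (
            ("DNA", cfg.coverage_dna, rec.dna_fraction, rows_dna),
            ("RNA", cfg.coverage_rna, rec.rna_fraction, rows_rna),
        ):
            depth = int(rng.poisson(coverage))
            if depth == 0:
                continue
            f = 0.0 if np.isnan(frac) else float(frac)
            n_alt = _beta_binomial(rng, depth, f, cfg.overdispersion)
            n_ref = depth - n_alt
            ref_fwd = int(rng.binomial(n_ref, 0.5)) if n_ref else 0
            if artifact and source == "DNA":
                alt_fwd = n_alt if rng.random() < 0.5 else 0
            else:
                alt_fwd = int(rng.binomial(n_alt, 0.5)) if n_alt else 0
            rows.append((genome.id, source, pos, ref, ref_fwd, n_ref - ref_fwd))
            rows.append((genome.id, source, pos, alt, alt_fwd, n_alt - alt_fwd))
    dna = SiteCountTable(pd.DataFrame(rows_dna, columns=SITE_COLUMNS))
    rna = SiteCountTable(pd.DataFrame(rows_rna, columns=SITE_COLUMNS))
    return dna, rna


def simulate_rnaseq_snp_counts(
    genomes: Sequence[IndividualGenome],
    genome_map: GenomeMap,
    depth_mean: float = 6.0,
    error_rate: float = 0.01,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-individual parental allele counts at every marker SNP.

    Depth is Poisson(``depth_mean``) truncated at 1; homozygous sites read
    from one parent up to ``error_rate``, heterozygous sites are Bernoulli
    half-and-half.  Marker labels must be in {"A", "H", "B"}.
    """
    rng = np.random.default_rng(seed)
    out = {}
    for genome in genomes:
        frames = []
        for chrom, pos in genome_map.positions.items():
            states = np.asarray(genome.markers[chrom])
            n = len(pos)
            depth = rng.poisson(depth_mean, size=n)
            depth = np.maximum(depth, 1)
            p_a = np.where(states == "A", 1.0 - error_rate, np.where(states == "B", error_rate, 0.5))
            n_a = rng.binomial(depth, p_a)
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "position": pos,
                        "nA": n_a,
                        "nB": depth - n_a,
                    }
                )
            )
        out[genome.id] = pd.concat(frames, ignore_index=True)
    return out


# --- reference dominance rule builders -------------------------------------


def codominant_rules() -> DominanceRuleTable:
    return DominanceRuleTable(default="codominant")


def inbred_silencing_rules(
    founders: Sequence[Founder], expressed_cluster: Mapping[str, str]
) -> DominanceRuleTable:
    """Homozygous-founder rules: one cluster expressed, the other silent.

    ``expressed_cluster`` maps founder id to "rDNA-2", "rDNA-4" or "both".
    """
    rules = DominanceRuleTable()
    for f in founders:
        mode = expressed_cluster[f.id]
        act2 = 1.0 if mode in (RDNA2, "both") else 0.0
        act4 = 1.0 if mode in (RDNA4, "both") else 0.0
        rules.set_rule(
            [f.rdna2.id, f.rdna2.id, f.rdna4.id, f.rdna4.id],
            {f.rdna2.id: act2, f.rdna4.id: act4},
        )
    return rules


def hierarchy_rules(
    founders: Sequence[Founder], rank: Mapping[str, float]
) -> DominanceRuleTable:
    """Rules where only haplotypes of maximal rank in a genotype are active.

    Covers every unordered two-locus genotype formable from the founders;
    ties produce co-dominance.
    """
    rules = DominanceRuleTable()
    h2 = [f.rdna2.id for f in founders]
    h4 = [f.rdna4.id for f in founders]
    for i, a2 in enumerate(h2):
        for b2 in h2[i:]:
            for j, a4 in enumerate(h4):
                for b4 in h4[j:]:
                    ids = [a2, b2, a4, b4]
                    top = max(rank[h] for h in ids)
                    rules.set_rule(ids, {h: 1.0 if rank[h] == top else 0.0 for h in set(ids)})
    return rules


def two_locus_recessive_rules(p: Founder, q: Founder) -> DominanceRuleTable:
    """F2 reference rules: p's rDNA-4 and q's rDNA-2 are always expressed;
    the reciprocal pair (p's rDNA-2, q's rDNA-4) is expressed only when both
    loci are homozygous for it.
    """
    rules = DominanceRuleTable()
    dominant = {p.rdna4.id, q.rdna2.id}
    recessive2, recessive4 = p.rdna2.id, q.rdna4.id
    r2_opts = [(p.rdna2.id, p.rdna2.id), (p.rdna2.id, q.rdna2.id), (q.rdna2.id, q.rdna2.id)]
    r4_opts = [(p.rdna4.id, p.rdna4.id), (p.rdna4.id, q.rdna4.id), (q.rdna4.id, q.rdna4.id)]
    for g2 in r2_opts:
        for g4 in r4_opts:
            ids = list(g2) + list(g4)
            double_homo = g2 == (recessive2, recessive2) and g4 == (recessive4, recessive4)
            acts = {}
            for h in set(ids):
                if h in dominant:
                    acts[h] = 1.0
                else:
                    acts[h] = 1.0 if double_homo else 0.0
            rules.set_rule(ids, acts)
    return rules


# --- truth serialization ----------------------------------------------------


def write_truth(
    genomes: Sequence[IndividualGenome],
    haplotypes: Mapping[str, ClusterHaplotype],
    path: str | Path,
    activities: Mapping[str, Mapping[str, float]] | None = None,
    genome_map: GenomeMap | None = None,
) -> None:
    """Dump ground truth (genotypes, compositions, activities) as JSON."""
    payload = {
        "genome_map": (
            {c: [int(p) for p in pos] for c, pos in genome_map.positions.items()}
            if genome_map is not None
            else None
        ),
        "haplotypes": {
            h.id: {
                "cluster": h.cluster,
                "copy_number": h.copy_number,
                "composition": dict(h.composition),
            }
            for h in haplotypes.values()
        },
        "individuals": [
            {
                "id": g.id,
                "rdna2": list(g.rdna2),
                "rdna4": list(g.rdna4),
                "markers": {c: list(map(str, m)) for c, m in g.markers.items()},
                "activities": dict(activities[g.id]) if activities else None,
            }
            for g in genomes
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> tuple[
    list[IndividualGenome],
    dict[str, ClusterHaplotype],
    GenomeMap | None,
    dict[str, dict[str, float]],
]:
    payload = json.loads(Path(path).read_text())
    haplotypes = {
        hid: ClusterHaplotype(hid, h["cluster"], h["copy_number"], h["composition"])
        for hid, h in payload["haplotypes"].items()
    }
    genomes = []
    activities: dict[str, dict[str, float]] = {}
    for rec in payload["individuals"]:
        genomes.append(
            IndividualGenome(
                rec["id"],
                tuple(rec["rdna2"]),
                tuple(rec["rdna4"]),
                {c: np.asarray(m, dtype=object) for c, m in rec["markers"].items()},
            )
        )
        if rec.get("activities"):
            activities[rec["id"]] = dict(rec["activities"])
    gmap = None
    if payload.get("genome_map"):
        gmap = GenomeMap({c: np.asarray(p) for c, p in payload["genome_map"].items()})
    return genomes, haplotypes, gmap, activities
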