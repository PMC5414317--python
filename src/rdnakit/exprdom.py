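"""Expression status of rDNA variants and dominance/epistasis summaries.

Variants act as reporters of their cluster's activity: the ratio of the
RNA-read proportion to the DNA-read proportion (rho) classifies a variant's
haplotype as silenced, partially expressed, or expressed (points on the
one-to-one DNA:RNA line).  Panels of genotypes yield a dominance partial
order over haplotypes, and F2 populations a 3x3 two-locus genotype-class
matrix of mean proportions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .iocore import VariantCall
from .pilevar import RnaQuantification

logger = logging.getLogger("rdnakit")

SILENCED = "silenced"
PARTIAL = "partial"
EXPRESSED = "expressed"
UNDEFINED = "undefined"

GENOTYPE_CLASSES = ("AA", "AB", "BB")


@dataclass(frozen=True)
class ExpressionRecord:
    variant: str
    cluster: str | None
    dna_proportions: tuple[float, ...]
    rna_proportions: tuple[float, ...]
    quantifiable: bool
    single_replicate: bool

    @property
    def dna_mean(self) -> float:
        return float(np.mean(self.dna_proportions))

    @property
    def dna_sd(self) -> float:
        return _sd(self.dna_proportions)

    @property
    def rna_mean(self) -> float | None:
        return float(np.mean(self.rna_proportions)) if self.rna_proportions else None

    @property
    def rna_sd(self) -> float | None:
        return _sd(self.rna_proportions) if self.rna_proportions else None

    @property
    def activity_ratio(self) -> float | None:
        """rho = mean RNA proportion / mean DNA proportion; None if undefined."""
        if not self.quantifiable or not self.rna_proportions:
            return None
        if self.dna_mean == 0:
            return None
        return self.rna_mean / self.dna_mean


def _sd(values: Sequence[float]) -> float:
    return float(np.std(values, ddof=1)) if len(values) >= 2 else 0.0


def build_expression_records(
    dna_calls_by_replicate: Sequence[Sequence[VariantCall]],
    rna_by_replicate: Sequence[Sequence[RnaQuantification]],
    cluster_calls: Mapping[str, str] | None = None,
) -> list[ExpressionRecord]:
    """Combine replicate DNA calls and RNA quantifications per variant.

    A variant must pass DNA filters in at least one replicate; RNA values
    come only from quantifiable replicates (sites below the RNA read cutoff
    are flagged, never zero-filled).
    """
    if not dna_calls_by_replicate:
        raise ValueError("at least one DNA replicate required")
    dna_props: dict[str, list[float]] = {}
    for calls in dna_calls_by_replicate:
        for call in calls:
            if call.passed:
                dna_props.setdefault(call.name, []).append(call.copy_fraction)
    rna_props: dict[str, list[float]] = {}
    rna_seen: set[str] = set()
    for quants in rna_by_replicate:
        for q in quants:
            rna_seen.add(q.variant)
            if q.quantifiable and q.rna_proportion is not None:
                rna_props.setdefault(q.variant, []).append(q.rna_proportion)
    records = []
    for name in sorted(dna_props):
        rna = rna_props.get(name, [])
        quantifiable = len(rna) > 0
        if name in rna_seen and not quantifiable:
            logger.info("variant %s below RNA read cutoff in all replicates", name)
        n_reps = max(len(dna_props[name]), len(rna))
        records.append(
            ExpressionRecord(
                variant=name,
                cluster=(cluster_calls or {}).get(name),
                dna_proportions=tuple(dna_props[name]),
                rna_proportions=tuple(rna),
                quantifiable=quantifiable,
                single_replicate=n_reps == 1,
            )
        )
    return records


def classify_activity(
    rho: float | ExpressionRecord | None,
    silent_max: float = 0.1,
    codominant_band: tuple[float, float] = (0.5, 2.0),
) -> str:
    """silenced iff rho < ``silent_max``; expressed iff rho reaches the
    co-dominant band or exceeds it; else partial."""
    if isinstance(rho, ExpressionRecord):
        rho = rho.activity_ratio
    if rho is None or (isinstance(rho, float) and math.isnan(rho)):
        return UNDEFINED
    if rho < silent_max:
        return SILENCED
    if rho >= codominant_band[0]:
        return EXPRESSED
    return PARTIAL


@dataclass(frozen=True)
class GenotypeObservation:
    """Expression status of each haplotype present in one genotype."""

    genotype_id: str
    status: Mapping[str, str]  # haplotype id -> status


@dataclass
class DominanceRelations:
    edges: set[tuple[str, str]] = field(default_factory=set)  # (dominant, silenced)
    codominant: set[frozenset] = field(default_factory=set)
    support: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    cycles: list[list[str]] = field(default_factory=list)


def dominance_relations(observations: Sequence[GenotypeObservation]) -> DominanceRelations:
    """Partial order over haplotypes from co-occurrence expression patterns.

    H1 > H2 whenever some genotype contains both with H1 expressed and H2
    silenced; pairs both expressed are recorded as co-dominant.  Cycles are
    reported, not resolved.
    """
    rel = DominanceRelations()
    for obs in observations:
        haps = sorted(obs.status)
        for i, h1 in enumerate(haps):
            for h2 in haps[i + 1 :]:
                s1, s2 = obs.status[h1], obs.status[h2]
                for winner, loser, sw, sl in ((h1, h2, s1, s2), (h2, h1, s2, s1)):
                    if sw == EXPRESSED and sl == SILENCED:
                        rel.edges.add((winner, loser))
                        rel.support.setdefault((winner, loser), []).append(obs.genotype_id)
                if s1 == EXPRESSED and s2 == EXPRESSED:
                    rel.codominant.add(frozenset((h1, h2)))
    rel.cycles = _find_cycles(rel.edges)
    return rel


def _find_cycles(edges: Iterable[tuple[str, str]]) -> list[list[str]]:
    """Nodes participating in directed cycles, found by Kahn elimination."""
    succ: dict[str, set[str]] = {}
    indeg: dict[str, int] = {}
    for a, b in edges:
        succ.setdefault(a, set()).add(b)
        indeg[b] = indeg.get(b, 0) + 1
        indeg.setdefault(a, 0)
    queue = [n for n, d in indeg.items() if d == 0]
    while queue:
        n = queue.pop()
        for m in succ.get(n, ()):
            indeg[m] -= 1
            if indeg[m] == 0:
                queue.append(m)
    cyclic = sorted(n for n, d in indeg.items() if d > 0)
    return [cyclic] if cyclic else []


def haplotype_status(
    records: Sequence[ExpressionRecord],
    variant_haplotypes: Mapping[str, str],
    silent_max: float = 0.1,
    codominant_band: tuple[float, float] = (0.5, 2.0),
) -> dict[str, str]:
    """Per-haplotype status from its reporter variants (mean rho per haplotype)."""
    rhos: dict[str, list[float]] = {}
    for rec in records:
        hap = variant_haplotypes.get(rec.variant)
        rho = rec.activity_ratio
        if hap is None or rho is None:
            continue
        rhos.setdefault(hap, []).append(rho)
    return {
        hap: classify_activity(float(np.mean(v)), silent_max, codominant_band)
        for hap, v in rhos.items()
    }


@dataclass(frozen=True)
class CellStats:
    n: int
    dna_mean: float | None
    dna_sd: float | None
    rna_mean: float | None
    rna_sd: float | None


@dataclass
class ClassMatrix:
    """3x3 per-genotype-class expression summary for one reporter variant."""

    variant: str
    cells: dict[tuple[str, str], CellStats]
    excluded: int

    @property
    def n_total(self) -> int:
        return sum(c.n for c in self.cells.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (g2, g4), cell in sorted(self.cells.items()):
            rows.append(
                {
                    "variant": self.variant,
                    "rdna2_genotype": g2,
                    "rdna4_genotype": g4,
                    "n": cell.n,
                    "dna_mean": cell.dna_mean,
                    "dna_sd": cell.dna_sd,
                    "rna_mean": cell.rna_mean,
                    "rna_sd": cell.rna_sd,
                }
            )
        return pd.DataFrame(rows)


def genotype_class_matrix(
    variant: str,
    genotypes: Mapping[str, tuple[str, str] | None],
    dna_proportions: Mapping[str, float],
    rna_proportions: Mapping[str, float | None],
) -> ClassMatrix:
    """Mean +/- SD of a variant's DNA and RNA proportions per two-locus class.

    ``genotypes`` maps individual id to (rDNA-2, rDNA-4) classes in
    {AA, AB, BB}; individuals with an unknown genotype at either locus are
    excluded and counted.  Empty cells report n=0 with None statistics.
    """
    buckets: dict[tuple[str, str], list[tuple[float, float | None]]] = {
        (g2, g4): [] for g2 in GENOTYPE_CLASSES for g4 in GENOTYPE_CLASSES
    }
    excluded = 0
    for ind, dna in dna_proportions.items():
        geno = genotypes.get(ind)
        if geno is None or geno[0] not in GENOTYPE_CLASSES or geno[1] not in GENOTYPE_CLASSES:
            excluded += 1
            continue
        buckets[(geno[0], geno[1])].append((dna, rna_proportions.get(ind)))
    cells = {}
    for key, vals in buckets.items():
        if not vals:
            cells[key] = CellStats(0, None, None, None, None)
            continue
        dna_vals = [v[0] for v in vals]
        rna_vals = [v[1] for v in vals if v[1] is not None]
        cells[key] = CellStats(
            n=len(vals),
            dna_mean=float(np.mean(dna_vals)),
            dna_sd=_sd(dna_vals),
            rna_mean=float(np.mean(rna_vals)) if rna_vals else None,
            rna_sd=_sd(rna_vals) if rna_vals else None,
        )
    return ClassMatrix(variant, cells, excluded)


def write_expression_table(records: Sequence[ExpressionRecord], path) -> None:
    pd.DataFrame(
        [
            {
                "variant": r.variant,
                "cluster": r.cluster,
                "dna_mean": r.dna_mean,
                "dna_sd": r.dna_sd,
                "rna_mean": r.rna_mean,
                "rna_sd": r.rna_sd,
                "activity_ratio": r.activity_ratio,
                "status": classify_activity(r),
                "n_replicates_dna": len(r.dna_proportions),
                "n_replicates_rna": len(r.rna_proportions),
                "quantifiable": r.quantifiable,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


def write_dominance_edges(rel: DominanceRelations, path) -> None:
    rows = [
        {"dominant": a, "silenced": b, "support": ";".join(rel.support.get((a, b), []))}
        for a, b in sorted(rel.edges)
    ]
    rows += [
        {"dominant": "=".join(sorted(pair)), "silenced": "", "support": "codominant"}
        for pair in sorted(rel.codominant, key=lambda p: sorted(p))
    ]
    pd.DataFrame(rows, columns=["dominant", "silenced", "support"]).to_csv(
        path, sep="\t", index=False
    )
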