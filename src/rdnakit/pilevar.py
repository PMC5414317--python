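"""Within-individual variant calling from strand-split pileup counts.

Copy fractions are alternative-read fractions per site; candidate calls are
filtered on minimum fraction, the strand-bias score, the transcribed span
and a minimum depth.  When an alternative allele outnumbers the reference,
the reference allele itself is additionally tracked as a variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .iocore import (
    CallStatus,
    FilterConfig,
    SiteCountTable,
    Source,
    StrandCounts,
    ValidationError,
    VariantCall,
    log_filter_counts,
)

logger = logging.getLogger("rdnakit")


@dataclass(frozen=True)
class SiteSummary:
    position: int
    counts: Mapping[str, tuple[int, int]]  # allele -> (fwd, rev)

    @property
    def depth(self) -> int:
        return sum(f + r for f, r in self.counts.values())

    @property
    def major_allele(self) -> str:
        return max(self.counts, key=lambda a: (sum(self.counts[a]), a))

    def fraction(self, allele: str) -> float:
        f, r = self.counts.get(allele, (0, 0))
        return (f + r) / self.depth if self.depth else 0.0


def summarize_sites(table: SiteCountTable) -> dict[int, SiteSummary]:
    out: dict[int, SiteSummary] = {}
    for (pos,), grp in table.data.groupby(["position"]):
        counts = {
            str(rec.allele): (int(rec.fwd), int(rec.rev)) for rec in grp.itertuples(index=False)
        }
        out[int(pos)] = SiteSummary(int(pos), counts)
    return out


def strand_bias_score(sc: StrandCounts) -> float:
    """|b/(a+b) - d/(c+d)| / ((b+d)/(a+b+c+d)) over major (a,c), minor (b,d).

    With no minor-allele reads the score is 0 (no evidence of bias).  A
    strand with zero total depth contributes 0 to the corresponding
    fraction term, with a warning.
    """
    if sc.total == 0:
        raise ValidationError("strand bias score undefined for all-zero counts")
    minor = sc.b + sc.d
    if minor == 0:
        return 0.0
    if sc.a + sc.b == 0 or sc.c + sc.d == 0:
        logger.warning("strand with zero depth in SB computation: %s", sc)
    fwd = sc.b / (sc.a + sc.b) if (sc.a + sc.b) > 0 else 0.0
    rev = sc.d / (sc.c + sc.d) if (sc.c + sc.d) > 0 else 0.0
    return abs(fwd - rev) / (minor / sc.total)


def _strand_counts_for(site: SiteSummary, allele: str) -> StrandCounts:
    """Major/minor strand counts for evaluating ``allele`` at a site.

    The evaluated allele is compared against the most frequent other allele;
    whichever of the two has more reads takes the major role (a, c).
    """
    e_f, e_r = site.counts.get(allele, (0, 0))
    others = {a: c for a, c in site.counts.items() if a != allele}
    if others:
        other = max(others, key=lambda a: (sum(others[a]), a))
        o_f, o_r = others[other]
    else:
        o_f, o_r = 0, 0
    if (e_f + e_r) > (o_f + o_r):
        return StrandCounts(a=e_f, b=o_f, c=e_r, d=o_r)
    return StrandCounts(a=o_f, b=e_f, c=o_r, d=e_r)


def _classify(
    position: int,
    fraction: float,
    sb: float | None,
    depth: int,
    cfg: FilterConfig,
) -> CallStatus:
    if not cfg.in_span(position):
        return CallStatus.OUT_OF_SPAN
    if depth < cfg.min_dna_reads:
        return CallStatus.LOW_DEPTH
    if not cfg.frac_ok(fraction):
        return CallStatus.BELOW_FREQUENCY
    if sb is not None and sb > cfg.sb_max:
        return CallStatus.STRAND_BIASED
    return CallStatus.PASS


def call_variants(
    table: SiteCountTable,
    cfg: FilterConfig,
    ref_alleles: Mapping[int, str],
) -> list[VariantCall]:
    """Call within-individual variants from a DNA count table.

    Every non-reference allele observed at a site yields a call; failing
    calls are retained with their filter status.  ``ref_alleles`` maps each
    position to the reference base.
    """
    if len(table) and not (table.data["source"] == Source.DNA.value).all():
        raise ValidationError("call_variants expects a DNA count table")
    sites = summarize_sites(table)
    calls: list[VariantCall] = []
    tally = {"sites_in": len(sites), "pass": 0, "below_frequency": 0,
             "strand_biased": 0, "low_depth": 0, "out_of_span": 0}
    for pos in sorted(sites):
        site = sites[pos]
        ref = ref_alleles.get(pos)
        if ref is None:
            logger.warning("no reference allele for position %d; skipping", pos)
            continue
        depth = site.depth
        for allele in sorted(site.counts):
            if allele == ref:
                continue
            frac = site.fraction(allele)
            sc = _strand_counts_for(site, allele)
            sb = strand_bias_score(sc) if sc.total > 0 else None
            status = _classify(pos, frac, sb, depth, cfg)
            tally[status.value] += 1
            calls.append(VariantCall(pos, ref, allele, frac, sb, depth, status))
    log_filter_counts("call_variants", tally)
    return calls


def flip_reference_minority(
    calls: Sequence[VariantCall],
    table: SiteCountTable,
    cfg: FilterConfig,
    ref_alleles: Mapping[int, str],
) -> list[VariantCall]:
    """Add calls tracking the reference allele where an alternative exceeds it.

    At a site where some alternative allele is strictly more frequent than
    the reference, the reference allele is reported as a variant named with
    the most frequent alternative in the reference role, subject to the same
    filters.
    """
    sites = summarize_sites(table)
    extra: list[VariantCall] = []
    by_pos: dict[int, list[VariantCall]] = {}
    for c in calls:
        by_pos.setdefault(c.position, []).append(c)
    for pos, site_calls in sorted(by_pos.items()):
        site = sites.get(pos)
        ref = ref_alleles.get(pos)
        if site is None or ref is None:
            continue
        ref_frac = site.fraction(ref)
        alts = [c.alt for c in site_calls]
        best_alt = max(alts, key=lambda a: (site.fraction(a), a))
        if site.fraction(best_alt) <= ref_frac:
            continue
        sc = _strand_counts_for(site, ref)
        sb = strand_bias_score(sc) if sc.total > 0 else None
        status = _classify(pos, ref_frac, sb, site.depth, cfg)
        extra.append(VariantCall(pos, best_alt, ref, ref_frac, sb, site.depth, status))
    return list(calls) + extra


@dataclass(frozen=True)
class RnaQuantification:
    variant: str
    rna_proportion: float | None
    rna_depth: int
    quantifiable: bool


def quantify_rna(
    table: SiteCountTable,
    dna_calls: Sequence[VariantCall],
    cfg: FilterConfig,
) -> list[RnaQuantification]:
    """RNA-level proportions for DNA-validated variants.

    Only DNA-pass calls are reported; sites with fewer spanning RNA reads
    than ``cfg.min_rna_reads`` are flagged not-quantifiable.  No strand-bias
    filter is applied at the RNA level.
    """
    if len(table) and not (table.data["source"] == Source.RNA.value).all():
        raise ValidationError("quantify_rna expects an RNA count table")
    sites = summarize_sites(table)
    out: list[RnaQuantification] = []
    skipped = 0
    for call in dna_calls:
        if not call.passed:
            skipped += 1
            logger.info("variant %s not DNA-validated; excluded from RNA report", call.name)
            continue
        site = sites.get(call.position)
        depth = site.depth if site is not None else 0
        if depth < cfg.min_rna_reads:
            out.append(RnaQuantification(call.name, None, depth, False))
            continue
        prop = site.fraction(call.alt)
        out.append(RnaQuantification(call.name, prop, depth, True))
    log_filter_counts(
        "quantify_rna",
        {"dna_calls": len(dna_calls), "reported": len(out), "not_dna_validated": skipped},
    )
    return out
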