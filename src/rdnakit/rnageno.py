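"""F2 genotyping from RNA-seq parental allele counts.

Per-SNP calls (>90% of reads from one parent => homozygous), removal of
SNPs with >10-fold hom-call imbalance across the population, classification
of non-overlapping 50-SNP windows (>85% same-parent => homozygous),
merging into segments with deterministic breakpoint refinement, and
genome-wide genotype imputation.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .iocore import GenotypeSegment, SegState

logger = logging.getLogger("rdnakit")

HOM_A = SegState.HOM_A.value
HOM_B = SegState.HOM_B.value
HET = SegState.HET.value
NOCALL = "nocall"

STATE_CODE = {HOM_A: "A", HET: "H", HOM_B: "B"}
CODE_STATE = {v: k for k, v in STATE_CODE.items()}


def call_snp(n_a: int, n_b: int, hom_frac: float = 0.90) -> str:
    """Homozygous iff strictly more than ``hom_frac`` of reads are one parent's."""
    total = n_a + n_b
    if total == 0:
        return NOCALL
    if n_a / total > hom_frac:
        return HOM_A
    if n_b / total > hom_frac:
        return HOM_B
    return HET


def call_snps(counts: pd.DataFrame, hom_frac: float = 0.90) -> pd.DataFrame:
    """Vectorized per-SNP calls; adds a ``call`` column."""
    total = counts["nA"] + counts["nB"]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_a = counts["nA"] / total
    call = np.where(
        total == 0,
        NOCALL,
        np.where(frac_a > hom_frac, HOM_A, np.where((1 - frac_a) > hom_frac, HOM_B, HET)),
    )
    out = counts.copy()
    out["call"] = call
    return out


def filter_biased_snps(
    calls_by_individual: Mapping[str, pd.DataFrame], fold: float = 10.0
) -> set[tuple[str, int]]:
    """Retain SNPs without extreme hom-call imbalance across individuals.

    A SNP is removed iff its homA call count exceeds ``fold`` times its homB
    count over all individuals, or vice versa; a zero denominator with a
    non-zero numerator counts as exceeding any fold.
    """
    if len(calls_by_individual) < 2:
        raise ValueError("filter_biased_snps requires >= 2 individuals")
    frames = []
    for df in calls_by_individual.values():
        frames.append(df[["chrom", "position", "call"]])
    allc = pd.concat(frames, ignore_index=True)
    grouped = allc.groupby(["chrom", "position"])["call"]
    n_a = grouped.apply(lambda s: int((s == HOM_A).sum()))
    n_b = grouped.apply(lambda s: int((s == HOM_B).sum()))
    retained: set[tuple[str, int]] = set()
    removed = 0
    for key in n_a.index:
        a, b = int(n_a[key]), int(n_b[key])
        biased = (a > fold * b) if b > 0 else (a > 0)
        biased = biased or ((b > fold * a) if a > 0 else (b > 0))
        if biased:
            removed += 1
        else:
            retained.add((str(key[0]), int(key[1])))
    logger.info("filter_biased_snps: removed=%d retained=%d", removed, len(retained))
    return retained


def window_classify(
    calls: Sequence[str],
    window: int = 50,
    window_frac: float = 0.85,
    min_partial: int | None = None,
) -> list[tuple[int, int, str]]:
    """Classify non-overlapping windows of usable (non-nocall) SNP calls.

    Returns (start, end, state) index triples (end exclusive).  A window is
    homozygous iff strictly more than ``window_frac`` of its calls agree on
    one parent, else heterozygous.  A final partial window of at least
    ``min_partial`` SNPs (default half the window) is classified on its own;
    a smaller remainder merges into the previous window.
    """
    if any(c == NOCALL for c in calls):
        raise ValueError("nocall SNPs must be dropped before window classification")
    min_partial = min_partial if min_partial is not None else window // 2
    n = len(calls)
    if n < min_partial:
        logger.warning("only %d usable SNPs (<%d); no windows", n, min_partial)
        return []
    bounds = list(range(0, n, window))
    spans = [(b, min(b + window, n)) for b in bounds]
    if len(spans) > 1 and spans[-1][1] - spans[-1][0] < min_partial:
        last = spans.pop()
        spans[-1] = (spans[-1][0], last[1])
    out = []
    arr = np.asarray(calls, dtype=object)
    for lo, hi in spans:
        chunk = arr[lo:hi]
        size = hi - lo
        if (chunk == HOM_A).sum() / size > window_frac:
            state = HOM_A
        elif (chunk == HOM_B).sum() / size > window_frac:
            state = HOM_B
        else:
            state = HET
        out.append((lo, hi, state))
    return out


def _refine_cut(calls: np.ndarray, lo: int, hi: int, left_state: str, right_state: str) -> int:
    """SNP index maximizing two-sided agreement within [lo, hi)."""
    chunk = calls[lo:hi]
    left_match = np.concatenate([[0], np.cumsum(chunk == left_state)])
    right_total = int((chunk == right_state).sum())
    right_match = right_total - np.concatenate([[0], np.cumsum(chunk == right_state)])
    score = left_match + right_match
    return lo + int(score.argmax())


def segment_and_refine(
    windows: Sequence[tuple[int, int, str]],
    calls: Sequence[str],
    positions: Sequence[int],
    chromosome: str,
) -> list[GenotypeSegment]:
    """Merge same-state windows and refine each breakpoint to the SNP cut
    maximizing agreement with the flanking segment states.

    ``calls`` and ``positions`` are the usable SNPs in window index space.
    The returned segments partition the SNP-covered interval and alternate
    in state.
    """
    if not windows:
        return []
    arr = np.asarray(calls, dtype=object)
    pos = np.asarray(positions)
    blocks: list[list] = []
    for lo, hi, state in windows:
        if blocks and blocks[-1][2] == state:
            blocks[-1][1] = hi
        else:
            blocks.append([lo, hi, state])
    cuts = [0]
    for i in range(1, len(blocks)):
        left = blocks[i - 1]
        right = blocks[i]
        # refine within the two windows flanking the block boundary
        flank_lo = _left_flank_start(windows, right[0])
        flank_hi = _right_flank_end(windows, right[0])
        cut = _refine_cut(arr, flank_lo, flank_hi + 1, left[2], right[2])
        cut = max(cut, cuts[-1] + 1)  # keep segments non-empty and ordered
        cuts.append(cut)
    cuts.append(len(arr))
    segments = []
    for i, block in enumerate(blocks):
        lo, hi = cuts[i], cuts[i + 1]
        if lo >= hi:
            continue
        segments.append(
            GenotypeSegment(chromosome, int(pos[lo]), int(pos[hi - 1]), SegState(block[2]))
        )
    merged: list[GenotypeSegment] = []
    for seg in segments:
        if merged and merged[-1].state == seg.state:
            merged[-1] = GenotypeSegment(chromosome, merged[-1].start, seg.end, seg.state)
        else:
            merged.append(seg)
    return merged


def _left_flank_start(windows: Sequence[tuple[int, int, str]], boundary: int) -> int:
    """Start of the window immediately left of a block boundary index."""
    for lo, hi, _ in windows:
        if hi == boundary:
            return lo
    return max(boundary - 1, 0)


def _right_flank_end(windows: Sequence[tuple[int, int, str]], boundary: int) -> int:
    """Last index of the window immediately right of a block boundary."""
    for lo, hi, _ in windows:
        if lo == boundary:
            return hi - 1
    return boundary


def impute_genotypes(
    segments: Sequence[GenotypeSegment], positions: Sequence[int]
) -> list[str]:
    """State of the containing segment for every position; edge positions
    beyond the first/last segment take the nearest segment's state."""
    if not segments:
        raise ValueError("no segments to impute from")
    segs = sorted(segments, key=lambda s: s.start)
    out = []
    for p in positions:
        state = None
        for seg in segs:
            if seg.contains(p):
                state = seg.state.value
                break
        if state is None:
            nearest = min(segs, key=lambda s: min(abs(p - s.start), abs(p - s.end)))
            state = nearest.state.value
        out.append(state)
    return out


def genotype_individual(
    counts: pd.DataFrame,
    retained: set[tuple[str, int]] | None = None,
    hom_frac: float = 0.90,
    window: int = 50,
    window_frac: float = 0.85,
) -> dict[str, list[GenotypeSegment]]:
    """Full window-genotyping of one individual; returns segments per chromosome."""
    called = call_snps(counts, hom_frac)
    out: dict[str, list[GenotypeSegment]] = {}
    for chrom, grp in called.groupby("chrom", sort=False):
        grp = grp.sort_values("position")
        if retained is not None:
            keep = [
                (str(chrom), int(p)) in retained for p in grp["position"]
            ]
            grp = grp[keep]
        usable = grp[grp["call"] != NOCALL]
        windows = window_classify(list(usable["call"]), window, window_frac)
        if not windows:
            out[str(chrom)] = []
            continue
        out[str(chrom)] = segment_and_refine(
            windows, list(usable["call"]), list(usable["position"]), str(chrom)
        )
    return out


def genotype_population(
    counts_by_individual: Mapping[str, pd.DataFrame],
    hom_frac: float = 0.90,
    fold: float = 10.0,
    window: int = 50,
    window_frac: float = 0.85,
) -> tuple[dict[str, dict[str, list[GenotypeSegment]]], pd.DataFrame]:
    """Genotype every individual and impute a positions x individuals matrix.

    The matrix holds states coded {A, H, B} and is indexed by
    (chrom, position) over all SNPs seen in the input.
    """
    called = {
        ind: call_snps(df, hom_frac) for ind, df in counts_by_individual.items()
    }
    retained = filter_biased_snps(called, fold) if len(called) >= 2 else None
    segments: dict[str, dict[str, list[GenotypeSegment]]] = {}
    any_df = next(iter(counts_by_individual.values()))
    all_positions = (
        any_df[["chrom", "position"]].drop_duplicates().sort_values(["chrom", "position"])
    )
    columns = {}
    for ind, df in counts_by_individual.items():
        segs = genotype_individual(df, retained, hom_frac, window, window_frac)
        segments[ind] = segs
        states = []
        for chrom, grp in all_positions.groupby("chrom", sort=False):
            chrom_segs = segs.get(str(chrom), [])
            if not chrom_segs:
                states.extend(["H"] * len(grp))
                continue
            states.extend(
                STATE_CODE[s] for s in impute_genotypes(chrom_segs, list(grp["position"]))
            )
        columns[ind] = states
    matrix = pd.DataFrame(
        columns,
        index=pd.MultiIndex.from_frame(all_positions.reset_index(drop=True)),
    )
    return segments, matrix
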