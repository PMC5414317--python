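"""Marker-regression QTL mapping in F2 populations.

Map reduction (duplicate-column dropping plus min-distance subsetting),
single-locus scans with additive/dominance genotype encodings, covariate
(second-QTL) scans, and permutation-based genome-wide thresholds.  The per
marker statistic is LOD = (n/2) * log10(RSS0 / RSS1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("rdnakit")

_CODE = {"A": 0, "H": 1, "B": 2}
_RSS_FLOOR = 1e-12


@dataclass
class MarkerMap:
    """Ordered markers with an individuals x markers genotype matrix.

    Genotypes are coded 0 (homA), 1 (het), 2 (homB); -1 marks missing.
    """

    info: pd.DataFrame  # columns: chrom, position
    genotypes: np.ndarray  # (n_individuals, n_markers) int8
    individuals: list[str]

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.individuals), len(self.info)):
            raise ValueError("genotype matrix shape mismatch")
        for chrom, grp in self.info.groupby("chrom", sort=False):
            if not grp["position"].is_monotonic_increasing:
                raise ValueError(f"marker positions not increasing on {chrom}")

    @classmethod
    def from_state_matrix(cls, matrix: pd.DataFrame) -> "MarkerMap":
        """Build from a (chrom, position)-indexed frame of {A,H,B} states."""
        info = matrix.index.to_frame(index=False)
        info.columns = ["chrom", "position"]
        geno = np.full((matrix.shape[1], matrix.shape[0]), -1, dtype=np.int8)
        values = matrix.to_numpy()
        for i, ind in enumerate(matrix.columns):
            geno[i] = [_CODE.get(v, -1) for v in values[:, i]]
        return cls(info, geno, list(matrix.columns))

    @property
    def n_markers(self) -> int:
        return len(self.info)

    def marker_index(self, chrom: str, position: int) -> int:
        hit = self.info.index[
            (self.info["chrom"] == chrom) & (self.info["position"] == position)
        ]
        if len(hit) != 1:
            raise KeyError(f"marker {chrom}:{position} not in map")
        return int(hit[0])

    def subset(self, keep: Sequence[int]) -> "MarkerMap":
        keep = list(keep)
        return MarkerMap(
            self.info.iloc[keep].reset_index(drop=True),
            self.genotypes[:, keep],
            list(self.individuals),
        )


@dataclass
class ScanResult:
    table: pd.DataFrame  # columns: chrom, position, lod
    model: str
    n: int
    thresholds: dict[float, float] = field(default_factory=dict)

    @property
    def peak_index(self) -> int:
        return int(self.table["lod"].to_numpy().argmax())

    @property
    def peak_lod(self) -> float:
        return float(self.table["lod"].max())


def reduce_map(markers: MarkerMap, min_distance: float = 0) -> MarkerMap:
    """Drop duplicate genotype columns (keep leftmost), then greedily keep
    markers at least ``min_distance`` apart (marker-position units) within
    each chromosome.  Idempotent: reducing a reduced map is a no-op."""
    if markers.n_markers == 0:
        raise ValueError("empty marker map")
    seen: set[bytes] = set()
    keep: list[int] = []
    for j in range(markers.n_markers):
        key = markers.genotypes[:, j].tobytes()
        if key in seen:
            continue
        seen.add(key)
        keep.append(j)
    dedup = markers.subset(keep)
    if min_distance <= 0:
        return dedup
    keep2: list[int] = []
    chroms = dedup.info["chrom"].to_numpy()
    positions = dedup.info["position"].to_numpy()
    last: dict[str, float] = {}
    for j in range(dedup.n_markers):
        chrom = str(chroms[j])
        if chrom not in last or positions[j] - last[chrom] >= min_distance:
            keep2.append(j)
            last[chrom] = positions[j]
    return dedup.subset(keep2)


def _orth(x: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing)."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
    return u[:, s > tol]


def _marker_design(codes: np.ndarray) -> np.ndarray:
    additive = codes.astype(float) - 1.0  # {-1, 0, 1}
    dominance = (codes == 1).astype(float)  # {0, 1, 0}
    return np.column_stack([additive, dominance])


def _encode_covariate(codes: np.ndarray, encoding: str) -> np.ndarray:
    if encoding == "additive":
        return (codes.astype(float) - 1.0)[:, None]
    if encoding == "dominance":
        return (codes == 1).astype(float)[:, None]
    raise ValueError(f"unknown covariate encoding {encoding!r}")


def _scan_lods(
    phenotypes: np.ndarray,
    markers: MarkerMap,
    covariate: np.ndarray | None = None,
) -> np.ndarray:
    """LOD per marker for one or many phenotype vectors.

    ``phenotypes`` is (n,) or (n, P); ``covariate`` an optional (n, c)
    design added to both null and alternative models.  Individuals with a
    missing genotype or non-finite phenotype are dropped per marker.
    """
    y = phenotypes if phenotypes.ndim == 2 else phenotypes[:, None]
    n_ind, n_pheno = y.shape
    lods = np.zeros((markers.n_markers, n_pheno))
    finite = np.isfinite(y).all(axis=1)
    for j in range(markers.n_markers):
        codes = markers.genotypes[:, j]
        mask = finite & (codes >= 0)
        n = int(mask.sum())
        if n < 3:
            continue
        yj = y[mask]
        ones = np.ones((n, 1))
        x0 = ones if covariate is None else np.column_stack([ones, covariate[mask]])
        x1 = np.column_stack([x0, _marker_design(codes[mask])])
        q0 = _orth(x0)
        q1 = _orth(x1)
        yty = (yj ** 2).sum(axis=0)
        rss0 = yty - ((q0.T @ yj) ** 2).sum(axis=0)
        rss1 = yty - ((q1.T @ yj) ** 2).sum(axis=0)
        rss0 = np.maximum(rss0, 0.0)
        rss1 = np.maximum(rss1, 0.0)
        ok = rss0 > _RSS_FLOOR
        ratio = np.ones(n_pheno)
        ratio[ok] = rss0[ok] / np.maximum(rss1[ok], _RSS_FLOOR)
        if q1.shape[1] <= q0.shape[1]:  # marker collinear with null design
            ratio[:] = 1.0
            logger.info("marker %d collinear with covariates; LOD 0", j)
        lods[j] = (n / 2.0) * np.log10(np.maximum(ratio, 1.0))
    return lods if phenotypes.ndim == 2 else lods[:, 0]


def single_scan(
    phenotype: Sequence[float] | np.ndarray, markers: MarkerMap
) -> ScanResult:
    """Single-locus marker regression with a 2-df additive+dominance model."""
    y = np.asarray(phenotype, dtype=float)
    if len(y) != len(markers.individuals):
        raise ValueError("phenotype length does not match individuals")
    n = int(np.isfinite(y).sum())
    if n < 30:
        raise ValueError("single_scan requires >= 30 phenotyped individuals")
    lods = _scan_lods(y, markers)
    table = markers.info.copy()
    table["lod"] = lods
    return ScanResult(table, "single", n)


def covariate_scan(
    phenotype: Sequence[float] | np.ndarray,
    markers: MarkerMap,
    covariate_index: int,
    encoding: str = "additive",
) -> ScanResult:
    """Scan with a second-QTL covariate in both null and alternative models."""
    y = np.asarray(phenotype, dtype=float)
    codes = markers.genotypes[:, covariate_index]
    cov = _encode_covariate(codes, encoding)
    lods = _scan_lods(y, markers, covariate=cov)
    table = markers.info.copy()
    table["lod"] = lods
    return ScanResult(table, f"{encoding}_covariate", int(np.isfinite(y).sum()))


def permutation_threshold(
    phenotype: Sequence[float] | np.ndarray,
    markers: MarkerMap,
    n_perm: int = 1000,
    alphas: Sequence[float] = (0.05, 0.10),
    seed: int | None = None,
    covariate_index: int | None = None,
    encoding: str = "additive",
) -> dict[float, float]:
    """Genome-wide LOD thresholds from phenotype permutations.

    The phenotype is permuted over individuals; threshold(alpha) is the
    empirical (1 - alpha) quantile of the per-permutation maximum LOD.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    y = np.asarray(phenotype, dtype=float)
    perms = np.empty((len(y), n_perm))
    for p in range(n_perm):
        perms[:, p] = y[rng.permutation(len(y))]
    cov = (
        _encode_covariate(markers.genotypes[:, covariate_index], encoding)
        if covariate_index is not None
        else None
    )
    lods = _scan_lods(perms, markers, covariate=cov)
    maxima = lods.max(axis=0)
    return {float(a): float(np.quantile(maxima, 1.0 - a)) for a in alphas}


def write_scan(result: ScanResult, path) -> None:
    result.table.to_csv(path, sep="\t", index=False)


def read_genotype_matrix(path) -> pd.DataFrame:
    """Read a TSV of imputed states with columns (chrom, position, <individuals>)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return df.set_index(["chrom", "position"])
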