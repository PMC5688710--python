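"""Array-level QC for remapped probes: filtering, density, replicates, clustering.

Consumes normalised beta values (methylation fractions in [0, 1]) with their
detection P values, both probes x samples.  Probes are filtered in a fixed,
reported order (sex chromosomes, listed ids, detection P), the beta
distribution is checked for the expected bimodality, replicate agreement is
scored as squared Pearson correlation and samples are clustered with
Ward-variant linkage on Euclidean distances (the ward.D2 flavour, in which
squared distances drive the Lance-Williams update).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)


@dataclass
class BetaMatrix:
    """Beta values and detection P values, probes x samples, shared axes."""

    beta: pd.DataFrame
    detection_p: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.beta.index.equals(self.detection_p.index) or not self.beta.columns.equals(
            self.detection_p.columns
        ):
            raise ValueError("beta and detection_p must share probe and sample axes")
        values = self.beta.to_numpy(float)
        finite = values[np.isfinite(values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @classmethod
    def from_tsv(cls, beta_path: str | Path, detp_path: str | Path) -> "BetaMatrix":
        beta = pd.read_csv(beta_path, sep="\t", index_col=0)
        detp = pd.read_csv(detp_path, sep="\t", index_col=0)
        return cls(beta=beta, detection_p=detp.loc[beta.index, beta.columns])

    def to_tsv(self, beta_path: str | Path, detp_path: str | Path) -> None:
        self.beta.to_csv(beta_path, sep="\t")
        self.detection_p.to_csv(detp_path, sep="\t")

    def subset(self, probe_ids: Sequence[str]) -> "BetaMatrix":
        return BetaMatrix(
            beta=self.beta.loc[probe_ids], detection_p=self.detection_p.loc[probe_ids]
        )


@dataclass
class FilterSpec:
    """Probe-filtering rules, applied in order: sex chromosomes, listed
    probe ids, detection P.

    A probe fails detection when the fraction of samples with
    ``detection_p >= cutoff`` exceeds ``max_fail_fraction`` (the default 0.0
    removes a probe failing in any sample).
    """

    drop_chroms: frozenset = frozenset({"X", "Y", "chrX", "chrY"})
    drop_probe_ids: frozenset = frozenset()
    detection_p_cutoff: float = 0.01
    max_fail_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.detection_p_cutoff <= 1:
            raise ValueError("detection_p_cutoff must be in (0, 1]")


@dataclass
class FilterReport:
    """Counts removed per rule; counts are additive in the stated order."""

    n_input: int = 0
    missing_manifest: int = 0
    sex_chrom: int = 0
    listed: int = 0
    detection_p: int = 0
    n_retained: int = 0
    validated: dict = field(default_factory=dict)  # probe_id -> bool


def filter_probes(
    matrix: BetaMatrix,
    manifest_chrom: Mapping[str, str],
    spec: FilterSpec = FilterSpec(),
) -> tuple[BetaMatrix, FilterReport]:
    """Apply the filtering rules and report per-rule removal counts.

    ``manifest_chrom`` maps probe id -> chromosome; matrix probes missing
    from it are dropped first with a warning.  Surviving probes carry a True
    validation flag in the report, removed probes False.  The operation is
    idempotent: filtering its own output removes nothing.
    """
    report = FilterReport(n_input=len(matrix.probe_ids))
    keep: list[str] = []
    detp = matrix.detection_p
    n_samples = len(matrix.sample_ids)
    for probe_id in matrix.probe_ids:
        if probe_id not in manifest_chrom:
            report.missing_manifest += 1
            report.validated[probe_id] = False
            continue
        if manifest_chrom[probe_id] in spec.drop_chroms:
            report.sex_chrom += 1
            report.validated[probe_id] = False
            continue
        if probe_id in spec.drop_probe_ids:
            report.listed += 1
            report.validated[probe_id] = False
            continue
        fails = int((detp.loc[probe_id] >= spec.detection_p_cutoff).sum())
        if n_samples and fails / n_samples > spec.max_fail_fraction:
            report.detection_p += 1
            report.validated[probe_id] = False
            continue
        report.validated[probe_id] = True
        keep.append(probe_id)
    report.n_retained = len(keep)
    if report.missing_manifest:
        log.warning("%d probes in matrix missing from manifest; dropped", report.missing_manifest)
    return matrix.subset(keep), report


@dataclass
class DensityResult:
    """KDE of beta values on [0, 1] with local maxima sorted by height."""

    grid: np.ndarray
    density: np.ndarray
    modes: list[float]  # sorted by descending density
    mode_heights: list[float]


def beta_density(
    values: BetaMatrix | pd.DataFrame | np.ndarray,
    grid: Optional[np.ndarray] = None,
) -> DensityResult:
    """Gaussian kernel density (Silverman bandwidth) of all non-missing
    beta values, with local maxima of the curve as modes."""
    if isinstance(values, BetaMatrix):
        values = values.beta
    arr = np.asarray(values, dtype=float).ravel()
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError("need at least 2 non-missing beta values")
    if grid is None:
        grid = np.linspace(0.0, 1.0, 512)
    kde = stats.gaussian_kde(arr, bw_method="silverman")
    density = kde(grid)
    interior = np.flatnonzero(
        (density[1:-1] > density[:-2]) & (density[1:-1] >= density[2:])
    ) + 1
    order = interior[np.argsort(density[interior])[::-1]]
    return DensityResult(
        grid=grid,
        density=density,
        modes=[float(grid[i]) for i in order],
        mode_heights=[float(density[i]) for i in order],
    )


def replicate_r2(
    matrix: BetaMatrix | pd.DataFrame, pairs: Sequence[tuple[str, str]]
) -> dict[tuple[str, str], float]:
    """Squared Pearson correlation between paired sample columns, over
    probes non-missing in both members of each pair."""
    beta = matrix.beta if isinstance(matrix, BetaMatrix) else matrix
    out: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        x = beta[a].to_numpy(float)
        y = beta[b].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3:
            raise ValueError(f"pair ({a}, {b}): fewer than 3 shared probes")
        r, _ = stats.pearsonr(x[ok], y[ok])
        out[(a, b)] = float(r * r)
    return out


@dataclass
class ClusterResult:
    """Sample dendrogram: scipy merge table, Newick string and leaf order."""

    sample_ids: list[str]
    merge_table: np.ndarray  # scipy linkage matrix, (n-1) x 4
    newick: str
    leaf_order: list[str]


def hierarchical_cluster(
    matrix: BetaMatrix | pd.DataFrame, pairwise_complete: bool = False
) -> ClusterResult:
    """Cluster sample columns on Euclidean distance with ward.D2-style
    linkage.

    Missing values are an error unless ``pairwise_complete`` is set, in
    which case each pairwise distance uses the probes observed in both
    samples.  Deterministic given input column order.
    """
    beta = matrix.beta if isinstance(matrix, BetaMatrix) else matrix
    samples = list(beta.columns)
    if len(samples) < 2:
        raise ValueError("clustering needs at least 2 samples")
    data = beta.to_numpy(float).T  # samples x probes
    if np.isnan(data).any():
        if not pairwise_complete:
            raise ValueError(
                "missing beta values; filter first or set pairwise_complete=True"
            )
        n = len(samples)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ok = np.isfinite(data[i]) & np.isfinite(data[j])
                if ok.sum() < 1:
                    raise ValueError(f"no shared probes between {samples[i]} and {samples[j]}")
                dist[i, j] = dist[j, i] = float(
                    np.sqrt(np.sum((data[i, ok] - data[j, ok]) ** 2))
                )
        merge = linkage(squareform(dist, checks=False), method="ward")
    else:
        merge = linkage(data, method="ward")
    tree = to_tree(merge)
    newick = _to_newick(tree, samples) + ";"
    leaf_order = [samples[i] for i in tree.pre_order(lambda leaf: leaf.id)]
    return ClusterResult(
        sample_ids=samples, merge_table=merge, newick=newick, leaf_order=leaf_order
    )


def _to_newick(node, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.left, labels)
    right = _to_newick(node.right, labels)
    bl_left = node.dist - node.left.dist
    bl_right = node.dist - node.right.dist
    return f"({left}:{bl_left:.6g},{right}:{bl_right:.6g})"
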