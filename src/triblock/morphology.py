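"""Micelle identification and shape classification.

Micelle cores are single-linkage clusters of hydrophobic (B) beads under the
minimum-image metric.  Each cluster is unwrapped across the periodic
boundaries, its gyration tensor is diagonalised, and the elongation
``e = lambda1 / ((lambda2 + lambda3)/2)`` decides between spherical,
wormlike and intermediate aggregates.  Core diameters invert the second
moments of uniform reference solids:

* sphere:  D = 2 sqrt(5/3 Rg^2)      (uniform ball, Rg^2 = 3 R^2 / 5)
* worm:    D = 4 sqrt((l2 + l3)/2)   (uniform cylinder, transverse moment R^2/4)

Diameters are core-only (the corona is excluded by construction, because
only B beads enter the clustering).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import breadth_first_order, connected_components
from scipy.spatial import cKDTree

from .errors import ClassificationError, ParameterError
from .forcefield import BEAD_B
from .simulate import minimum_image

__all__ = [
    "MorphologyConfig",
    "MicelleCluster",
    "MorphologySummary",
    "cluster_cores",
    "gyration_tensor",
    "classify_shape",
    "core_diameter",
    "diameter_ratio",
    "ratio_of_means",
    "analyze_frame",
    "summarize_trajectory",
]

SPHERICAL = "spherical"
WORMLIKE = "wormlike"
INTERMEDIATE = "intermediate"


@dataclass(frozen=True)
class MorphologyConfig:
    """Clustering / classification thresholds (all in reduced units)."""

    cutoff: float = 1.3  # single-linkage cutoff on B beads, just above LJ minimum
    e_lo: float = 2.0  # below: spherical
    e_hi: float = 5.0  # above: wormlike
    min_cluster_size: int = 10  # smaller aggregates are free chains/oligomers


@dataclass
class MicelleCluster:
    """One identified aggregate of core (B) beads."""

    indices: np.ndarray
    center_of_mass: np.ndarray
    eigenvalues: tuple  # (l1, l2, l3), descending
    shape_class: str
    diameter_spherical: float | None = None
    diameter_wormlike: float | None = None
    ambiguous: bool = False  # True for intermediate clusters (both rules reported)

    @property
    def size(self) -> int:
        return len(self.indices)

    @property
    def core_diameter(self) -> float | None:
        if self.shape_class == SPHERICAL:
            return self.diameter_spherical
        if self.shape_class == WORMLIKE:
            return self.diameter_wormlike
        return None


@dataclass
class MorphologySummary:
    """Per-trajectory morphology statistics (averaged over frames).

    ``worm_mass_fraction`` weighs the B-bead mass in wormlike clusters
    against the mass in *decisively classified* clusters (wormlike +
    spherical): intermediate clusters are ambiguous by construction and
    carry no vote in the phase call.  ``decisive_fraction`` records how much
    of the clustered mass was decisive, so a call based on little evidence
    is visible.
    """

    worm_mass_fraction: float
    mean_sphere_diameter: float | None
    mean_worm_diameter: float | None
    n_clusters: int
    decisive_fraction: float = 1.0
    per_frame: list = field(default_factory=list)

    def to_json(self, path=None) -> str:
        d = {
            "worm_mass_fraction": self.worm_mass_fraction,
            "mean_sphere_diameter": self.mean_sphere_diameter,
            "mean_worm_diameter": self.mean_worm_diameter,
            "n_clusters": self.n_clusters,
        }
        s = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def cluster_cores(positions_B: np.ndarray, box_edge: float, cutoff: float) -> list[np.ndarray]:
    """Single-linkage connected components of B beads within ``cutoff``.

    Returns a partition of all input indices (singletons included).  Pair
    inclusion uses distance <= cutoff; the cutoff is a model parameter, not
    a measured quantity, so the boundary convention is immaterial.
    """
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    n = len(positions_B)
    if n == 0:
        return []
    tree = cKDTree(positions_B % box_edge, boxsize=box_edge)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, labels = connected_components(graph, directed=False)
    return [np.flatnonzero(labels == c) for c in range(n_comp)]


def _unwrap(points: np.ndarray, box_edge: float, cutoff: float) -> np.ndarray:
    """Unwrap a connected point set across periodic boundaries (BFS)."""
    n = len(points)
    if n == 1:
        return points.copy()
    pts = points % box_edge
    tree = cKDTree(pts, boxsize=box_edge)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    ).tocsr()
    order, predecessors = breadth_first_order(graph, 0, directed=False)
    out = pts.copy()
    for node in order[1:]:
        parent = predecessors[node]
        out[node] = out[parent] + minimum_image(pts[node] - pts[parent], box_edge)
    return out


def gyration_tensor(points: np.ndarray, box_edge: float | None = None, cutoff: float = 1.3):
    """Sorted eigenvalues (descending) of the mass-weighted gyration tensor.

    When ``box_edge`` is given the point set is first unwrapped across the
    periodic boundaries (it must then be connected at ``cutoff``).
    ``Rg^2 = l1 + l2 + l3``.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 1:
        raise ParameterError("need at least one point")
    if box_edge is not None:
        points = _unwrap(points, box_edge, cutoff)
    centered = points - points.mean(axis=0)
    tensor = centered.T @ centered / len(points)
    lam = np.linalg.eigvalsh(tensor)[::-1]
    lam = np.clip(lam, 0.0, None)  # clamp tiny negative round-off
    return tuple(float(x) for x in lam)


def classify_shape(eigenvalues, e_lo: float = 2.0, e_hi: float = 5.0) -> str:
    """Spherical / wormlike / intermediate from the elongation ratio.

    ``e = l1 / ((l2 + l3)/2)``; e is 1 for an ideal ball and grows as L^2/R^2
    for elongated objects.  Collinear clusters (l2 = l3 = 0) are maximally
    elongated, hence wormlike; an all-zero tensor (single point) cannot be
    classified.
    """
    l1, l2, l3 = eigenvalues
    if l1 < 0 or l2 < 0 or l3 < 0 or not (l1 >= l2 >= l3):
        raise ParameterError("eigenvalues must be sorted non-negative")
    if l1 == 0.0:
        raise ClassificationError("all-zero gyration tensor (single point)")
    transverse = 0.5 * (l2 + l3)
    e = np.inf if transverse == 0.0 else l1 / transverse
    if e < e_lo:
        return SPHERICAL
    if e > e_hi:
        return WORMLIKE
    return INTERMEDIATE


def core_diameter(cluster: MicelleCluster) -> float:
    """Core diameter of a classified cluster of >= 4 beads (see module docs)."""
    if cluster.size < 4:
        raise ParameterError(f"cluster of {cluster.size} beads: need >= 4 for a diameter")
    d = cluster.core_diameter
    if d is None:
        raise ClassificationError(
            "intermediate cluster: both diameter rules apply (see "
            "diameter_spherical / diameter_wormlike with ambiguous=True)"
        )
    return d


def _diameters(eigenvalues):
    l1, l2, l3 = eigenvalues
    rg2 = l1 + l2 + l3
    d_sphere = 2.0 * np.sqrt(5.0 / 3.0 * rg2)
    d_worm = 4.0 * np.sqrt(0.5 * (l2 + l3))
    return float(d_sphere), float(d_worm)


def analyze_frame(
    positions: np.ndarray,
    bead_type: np.ndarray,
    box_edge: float,
    config: MorphologyConfig = MorphologyConfig(),
) -> list[MicelleCluster]:
    """Cluster the B beads of one frame and classify every cluster.

    Returns clusters sorted by decreasing size.  Indices refer to the B-bead
    subset in the original bead order.
    """
    b_idx = np.flatnonzero(np.asarray(bead_type) == BEAD_B)
    pos_b = np.asarray(positions)[b_idx]
    clusters = []
    for members in cluster_cores(pos_b, box_edge, config.cutoff):
        pts = _unwrap(pos_b[members], box_edge, config.cutoff)
        com = pts.mean(axis=0) % box_edge
        if len(members) < 2:
            clusters.append(
                MicelleCluster(
                    indices=b_idx[members],
                    center_of_mass=com,
                    eigenvalues=(0.0, 0.0, 0.0),
                    shape_class=INTERMEDIATE,
                    ambiguous=True,
                )
            )
            continue
        lam = gyration_tensor(pts)
        shape = classify_shape(lam, config.e_lo, config.e_hi)
        d_s, d_w = _diameters(lam)
        clusters.append(
            MicelleCluster(
                indices=b_idx[members],
                center_of_mass=com,
                eigenvalues=lam,
                shape_class=shape,
                diameter_spherical=d_s,
                diameter_wormlike=d_w,
                ambiguous=(shape == INTERMEDIATE),
            )
        )
    return sorted(clusters, key=lambda c: -c.size)


def summarize_trajectory(trajectory, config: MorphologyConfig = MorphologyConfig()) -> MorphologySummary:
    """Morphology statistics over the production frames of a trajectory.

    Per frame, only clusters of at least ``min_cluster_size`` beads vote
    (smaller aggregates are free chains/oligomers); the worm mass fraction
    is worm mass / (worm + sphere mass) — see :class:`MorphologySummary`
    for why intermediates abstain.  Mean diameters average over qualifying
    clusters of each class across frames.
    """
    frac, sphere_d, worm_d, decisive = [], [], [], []
    per_frame = []
    n_clusters = 0
    for fr in trajectory.frames:
        clusters = analyze_frame(fr.positions, fr.bead_type, fr.box_edge, config)
        big = [c for c in clusters if c.size >= config.min_cluster_size]
        n_clusters += len(big)
        mass = sum(c.size for c in big)
        worm_mass = sum(c.size for c in big if c.shape_class == WORMLIKE)
        sphere_mass = sum(c.size for c in big if c.shape_class == SPHERICAL)
        if worm_mass + sphere_mass > 0:
            frac.append(worm_mass / (worm_mass + sphere_mass))
            decisive.append((worm_mass + sphere_mass) / mass)
        sphere_d += [c.diameter_spherical for c in big if c.shape_class == SPHERICAL]
        worm_d += [c.diameter_wormlike for c in big if c.shape_class == WORMLIKE]
        per_frame.append(clusters)
    return MorphologySummary(
        worm_mass_fraction=float(np.mean(frac)) if frac else 0.0,
        mean_sphere_diameter=float(np.mean(sphere_d)) if sphere_d else None,
        mean_worm_diameter=float(np.mean(worm_d)) if worm_d else None,
        n_clusters=n_clusters,
        decisive_fraction=float(np.mean(decisive)) if decisive else 0.0,
        per_frame=per_frame,
    )


def ratio_of_means(sphere_diameters, worm_diameters) -> float:
    """Mean spherical diameter over mean wormlike diameter."""
    s = np.asarray(sphere_diameters, dtype=float)
    w = np.asarray(worm_diameters, dtype=float)
    if s.size == 0 or w.size == 0:
        raise ParameterError("need at least one diameter of each class")
    return float(s.mean() / w.mean())


def diameter_ratio(summaries_by_replicate) -> tuple[float, float]:
    """Sphere/worm diameter ratio, mean +/- sd over replicates.

    Each replicate is a sequence of :class:`MorphologySummary` (runs flanking
    the transition); its ratio is (mean sphere diameter over the replicate's
    runs) / (mean worm diameter).  Replicates missing a class are excluded
    with a warning; if all are excluded an error is raised.
    """
    ratios = []
    for rep, summaries in enumerate(summaries_by_replicate):
        spheres = [s.mean_sphere_diameter for s in summaries if s.mean_sphere_diameter]
        worms = [s.mean_worm_diameter for s in summaries if s.mean_worm_diameter]
        if not spheres or not worms:
            warnings.warn(
                f"replicate {rep} lacks a morphology class and is excluded",
                stacklevel=2,
            )
            continue
        ratios.append(float(np.mean(spheres) / np.mean(worms)))
    if not ratios:
        raise ParameterError("no replicate contributed both morphology classes")
    mean = float(np.mean(ratios))
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
    return mean, sd


def clusters_to_frame_table(per_frame) -> pd.DataFrame:
    """Flatten per-frame cluster lists into a tidy table (CSV-ready)."""
    rows = []
    for frame_id, clusters in enumerate(per_frame):
        for cid, c in enumerate(clusters):
            l1, l2, l3 = c.eigenvalues
            rows.append(
                {
                    "frame": frame_id,
                    "cluster": cid,
                    "size": c.size,
                    "lambda1": l1,
                    "lambda2": l2,
                    "lambda3": l3,
                    "shape": c.shape_class,
                    "diameter_spherical": c.diameter_spherical,
                    "diameter_wormlike": c.diameter_wormlike,
                }
            )
    return pd.DataFrame(rows)
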