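"""Sample clustering on the most variable cassette-exon PSI profiles.

The study's pipeline: pool every cassette-exon change observed in any mutant
versus WT into one list, keep the ``n`` events with the largest across-sample
PSI variance (default 800), pick the cluster count with the gap statistic,
then partition samples with K-means (two centers in the study).

The gap statistic follows Tibshirani's recommended variant: reference
datasets are drawn uniformly over the principal-component-aligned bounding
box of the data, Gap(k) = mean_ref[log W*_k] − log W_k with W the pooled
within-cluster sum of squared distances to centroids, and the selected k is
the smallest k with Gap(k) >= Gap(k+1) − s_{k+1}.

K-means is Lloyd's algorithm with k-means++ seeding and best-of-restarts
selection; the within-cluster objective is asserted non-increasing at every
iteration. PSI columns share the [0,1] scale so no standardization is
applied by default (a flag exists).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .io_formats import EventTable

__all__ = [
    "PsiMatrix",
    "ClusterResult",
    "top_variable_events",
    "gap_statistic",
    "kmeans_partition",
    "lloyd_kmeans",
]


@dataclass
class PsiMatrix:
    """Samples × events PSI matrix with genotype labels per sample (row)."""

    values: pd.DataFrame  # rows: samples, columns: event_ids
    genotype_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("PsiMatrix must not contain missing values")
        missing = set(self.values.index) - set(self.genotype_of)
        if missing:
            raise ValueError(f"samples without genotype label: {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


@dataclass
class ClusterResult:
    k_selected: int
    assignments: dict[str, int]
    centers: np.ndarray
    inertia: float
    gap_curve: pd.DataFrame | None = None  # columns: k, gap, sk


def top_variable_events(
    table: EventTable, n: int = 800, standardize: bool = False
) -> PsiMatrix:
    """PSI matrix restricted to the n most variable complete cassette events.

    Only SE events with a PSI value in every replicate are eligible (events
    with missing coverage are dropped, not imputed). Variance ties are broken
    by event_id lexicographic order so the selection is deterministic.
    """
    psi = table.psi_matrix()
    se_ids = [r.event_id for r in table.records if r.event_type == "SE"]
    psi = psi[se_ids].dropna(axis=1)
    if psi.shape[1] == 0:
        raise ValueError("no complete cassette events available")
    if psi.shape[1] < n:
        warnings.warn(
            f"only {psi.shape[1]} complete cassette events available "
            f"(requested {n}); using all",
            stacklevel=2,
        )
        n = psi.shape[1]
    var = psi.var(axis=0, ddof=1)
    order = sorted(psi.columns, key=lambda c: (-var[c], c))
    keep = order[:n]
    values = psi[keep]
    if standardize:
        sd = values.std(axis=0, ddof=1).replace(0.0, 1.0)
        values = (values - values.mean(axis=0)) / sd
    genotype_of = {
        rep: g for g, reps in table.sample_labels.items() for rep in reps
    }
    return PsiMatrix(values=values, genotype_of=genotype_of)


def _kpp_init(
    x: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """k-means++ seeding."""
    n = x.shape[0]
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    d2 = ((x - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total == 0:
            centers[j] = x[rng.integers(n)]
            continue
        centers[j] = x[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((x - centers[j]) ** 2).sum(axis=1))
    return centers


def lloyd_kmeans(
    x: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int = 300,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One Lloyd run from a k-means++ start: (labels, centers, inertia).

    The within-cluster objective is asserted non-increasing across
    iterations; an emptied cluster is reseeded on the point farthest from its
    center.
    """
    n = x.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    if k == 1:
        center = x.mean(axis=0, keepdims=True)
        inertia = float(((x - center) ** 2).sum())
        return np.zeros(n, dtype=int), center, inertia
    centers = _kpp_init(x, k, rng)
    prev = np.inf
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        obj = float(d2[np.arange(n), labels].sum())
        assert obj <= prev + 1e-9, "Lloyd objective increased"
        for j in range(k):
            if not np.any(labels == j):
                labels[d2[np.arange(n), labels].argmax()] = j
        obj = float(d2[np.arange(n), labels].sum())
        for j in range(k):
            centers[j] = x[labels == j].mean(axis=0)
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        inertia = float(d2[np.arange(n), labels].sum())
        if prev - inertia < tol:
            prev = inertia
            break
        prev = obj
    return labels, centers, float(prev)


def _best_kmeans(
    x: np.ndarray, k: int, rng: np.random.Generator, n_init: int
) -> tuple[np.ndarray, np.ndarray, float]:
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(n_init):
        labels, centers, inertia = lloyd_kmeans(x, k, rng)
        if best is None or inertia < best[2]:  # ties keep earliest restart
            best = (labels, centers, inertia)
    assert best is not None
    return best


def _pooled_dispersion(x: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for j in np.unique(labels):
        pts = x[labels == j]
        w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return w


def gap_statistic(
    matrix: PsiMatrix | np.ndarray,
    k_max: int = 6,
    n_ref: int = 50,
    seed: int = 0,
    n_init: int = 5,
) -> tuple[pd.DataFrame, int]:
    """Gap curve over k = 1..k_max and the selected cluster count.

    References are uniform draws over the PCA-aligned bounding box of the
    data; s_k is the reference-log-dispersion standard error inflated by
    sqrt(1 + 1/n_ref). Identical samples (zero total dispersion) short-circuit
    to k = 1.
    """
    x = matrix.matrix() if isinstance(matrix, PsiMatrix) else np.asarray(matrix, float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if k_max >= n:
        raise ValueError(f"k_max={k_max} must be below the sample count {n}")
    rng = np.random.default_rng(seed)
    if _pooled_dispersion(x, np.zeros(n, dtype=int)) == 0.0:
        curve = pd.DataFrame({"k": [1], "gap": [0.0], "sk": [0.0]})
        return curve, 1

    # PCA-aligned bounding box
    mean = x.mean(axis=0)
    xc = x - mean
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    proj = xc @ vt.T
    lo, hi = proj.min(axis=0), proj.max(axis=0)

    log_w = np.empty(k_max)
    log_w_ref = np.empty((n_ref, k_max))
    refs = [
        rng.uniform(lo, hi, size=proj.shape) @ vt + mean for _ in range(n_ref)
    ]
    eps = 1e-300
    for k in range(1, k_max + 1):
        labels, _, _ = _best_kmeans(x, k, rng, n_init)
        log_w[k - 1] = np.log(_pooled_dispersion(x, labels) + eps)
        for b, ref in enumerate(refs):
            rlab, _, _ = _best_kmeans(ref, k, rng, n_init)
            log_w_ref[b, k - 1] = np.log(_pooled_dispersion(ref, rlab) + eps)

    gap = log_w_ref.mean(axis=0) - log_w
    sk = log_w_ref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / n_ref)
    curve = pd.DataFrame({"k": np.arange(1, k_max + 1), "gap": gap, "sk": sk})
    selected = k_max
    for k in range(1, k_max):
        if gap[k - 1] >= gap[k] - sk[k]:
            selected = k
            break
    return curve, selected


def kmeans_partition(
    matrix: PsiMatrix,
    k: int = 2,
    seed: int = 0,
    n_init: int = 25,
    gap_curve: pd.DataFrame | None = None,
    k_selected: int | None = None,
) -> ClusterResult:
    """Best-of-restarts K-means partition of the samples.

    Cluster ids are relabeled by order of first appearance along the sample
    axis so that permuting samples permutes assignments identically.
    """
    x = matrix.matrix()
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds sample count {x.shape[0]}")
    rng = np.random.default_rng(seed)
    labels, centers, inertia = _best_kmeans(x, k, rng, n_init)
    # canonical ids: first-seen order
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap)
    labels = np.array([remap[lab] for lab in labels])
    order = sorted(remap, key=remap.get)
    centers = centers[order]
    return ClusterResult(
        k_selected=k_selected if k_selected is not None else k,
        assignments=dict(zip(matrix.samples, labels.tolist())),
        centers=centers,
        inertia=inertia,
        gap_curve=gap_curve,
    )
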