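"""Synthetic fixtures: 2-D geometric point clouds and scRNA-like count
matrices with planted cell types.

The expression simulator targets the one structural assumption the
clustering method makes — each pair of cell types differs in at least a
few marker genes — with a transparent generative model: log10 expression
is Gaussian around a baseline, each type's markers are shifted up by a
fixed log-fold amount, counts are the rounded back-transform, and dropout
zeroes entries independently. It deliberately omits library-size
variation, batch effects and gene-gene correlation; see the methods note
for what that implies about the tests.

All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ExpressionMatrix, LabelVector


def make_blobs_2d(
    k: int,
    n_per_blob: int,
    separation: float = 10.0,
    seed: int = 0,
    noise_sd: float = 1.0,
) -> tuple[np.ndarray, LabelVector]:
    """Isotropic 2-D Gaussian blobs with centres ``separation`` apart.

    Centres sit on an axis-aligned grid with spacing ``separation``, so
    every pair of centres is at least ``separation`` apart and each pair
    of blobs is separated along a coordinate axis. Axis alignment matters:
    the separation score examines one feature at a time (the way marker
    genes separate real cell types), so blobs split along a diagonal would
    be invisible to it — the same representation failure the concentric
    circles illustrate. Points are N(centre, noise_sd^2 I).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    centers = separation * np.column_stack(
        [np.arange(k) % 2, np.arange(k) // 2]
    ).astype(float)
    points = np.vstack([
        c + noise_sd * rng.standard_normal((n_per_blob, 2)) for c in centers
    ])
    labels = [f"blob_{t + 1}" for t in range(k) for _ in range(n_per_blob)]
    cells = [f"cell_{i + 1:04d}" for i in range(k * n_per_blob)]
    return points, LabelVector(labels=labels, cell_ids=cells)


def make_circles(
    n: int,
    radii: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, LabelVector]:
    """Concentric noisy circles, ``n`` points per circle.

    Angles are uniform; each point's radius is its circle's radius plus
    Gaussian noise. The companion :func:`radial_transform` maps points to
    their distance from the origin, the 1-D representation in which the
    circles separate perfectly.
    """
    radii = list(radii)
    if len(set(radii)) != len(radii):
        raise ValueError("radii must be distinct")
    rng = np.random.default_rng(seed)
    pts = []
    labels = []
    for ci, r in enumerate(radii):
        theta = rng.uniform(0, 2 * np.pi, size=n)
        rad = r + noise_sd * rng.standard_normal(n)
        pts.append(np.column_stack([rad * np.cos(theta), rad * np.sin(theta)]))
        labels.extend([f"circle_{ci + 1}"] * n)
    points = np.vstack(pts)
    cells = [f"cell_{i + 1:04d}" for i in range(points.shape[0])]
    return points, LabelVector(labels=labels, cell_ids=cells)


def radial_transform(points: np.ndarray, center: np.ndarray | None = None) -> np.ndarray:
    """Map each 2-D point to its distance from ``center`` (default origin),
    returned as an (n, 1) feature matrix."""
    points = np.asarray(points, dtype=float)
    if center is None:
        center = np.zeros(points.shape[1])
    return np.linalg.norm(points - center, axis=1)[:, None]


def points_to_expression(
    points: np.ndarray, cell_ids: list[str] | None = None
) -> ExpressionMatrix:
    """Wrap a 2-D (or 1-D feature) point cloud as an analysis-scale
    expression matrix, features playing the role of genes."""
    points = np.asarray(points, dtype=float)
    n, m = points.shape
    if cell_ids is None:
        cell_ids = [f"cell_{i + 1:04d}" for i in range(n)]
    gene_ids = [f"dim_{j + 1}" for j in range(m)]
    return ExpressionMatrix(
        values=points, cell_ids=cell_ids, gene_ids=gene_ids, log_transformed=True
    )


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-cell-type expression simulator.

    Each gene g has its own baseline abundance mu_g on the log10 scale,
    drawn N(baseline_mean, gene_mean_sd) — real transcriptomes span
    orders of magnitude in abundance, and the binned-dispersion gene
    filter presumes exactly that mean variation. Cell-to-cell noise is
    N(0, baseline_sd) on the log scale. Defaults: baseline_mean 1.0 with
    gene_mean_sd 0.5 (typical counts near 10, gene abundances spread over
    roughly an order of magnitude) and baseline_sd 0.4 (a ~2.5-fold
    one-sigma cell-level spread). ``marker_log_fold`` is the log10 mean
    shift of a type's markers (1.0 = tenfold up-regulation).
    ``dropout_rate`` zeroes entries independently.
    """

    n_types: int = 5
    cells_per_type: tuple[int, ...] = (100, 100, 100, 100, 100)
    n_genes: int = 500
    markers_per_type: int = 10
    marker_log_fold: float = 1.0
    baseline_mean: float = 1.0
    baseline_sd: float = 0.4
    gene_mean_sd: float = 0.5
    dropout_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 1:
            raise ValueError("n_types must be >= 1")
        if len(self.cells_per_type) != self.n_types:
            raise ValueError("cells_per_type length must equal n_types")
        if any(c < 1 for c in self.cells_per_type):
            raise ValueError("each type needs at least one cell")
        if self.n_types * self.markers_per_type > self.n_genes:
            raise ValueError("not enough genes for the requested markers")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.baseline_sd < 0 or self.gene_mean_sd < 0:
            raise ValueError("baseline_sd and gene_mean_sd must be >= 0")


def simulate_scrna(spec: SyntheticSpec) -> tuple[ExpressionMatrix, LabelVector]:
    """Simulate a count-like expression matrix with planted cell types.

    Per cell of type t: gene g's log10 expression is
    N(mu_g, baseline_sd) with per-gene baseline mu_g ~
    N(baseline_mean, gene_mean_sd); type t's marker block gets an extra
    ``marker_log_fold``; counts are round(10^log - 1) clipped at zero;
    entries then drop out independently with ``dropout_rate``. Marker
    blocks are disjoint: genes [t*k, (t+1)*k) mark type t.
    """
    rng = np.random.default_rng(spec.seed)
    n_cells = sum(spec.cells_per_type)
    gene_means = rng.normal(spec.baseline_mean, spec.gene_mean_sd, size=spec.n_genes)
    log_expr = gene_means + rng.normal(
        0.0, spec.baseline_sd, size=(n_cells, spec.n_genes)
    )
    type_of_cell = np.repeat(np.arange(spec.n_types), spec.cells_per_type)
    k = spec.markers_per_type
    for t in range(spec.n_types):
        rows = type_of_cell == t
        log_expr[np.ix_(rows, np.arange(t * k, (t + 1) * k))] += spec.marker_log_fold
    counts = np.clip(np.round(10.0**log_expr - 1.0), 0, None)
    if spec.dropout_rate > 0:
        counts[rng.random(size=counts.shape) < spec.dropout_rate] = 0.0

    cell_ids = [f"cell_{i + 1:04d}" for i in range(n_cells)]
    gene_ids = [
        f"marker_t{g // k + 1}_{g % k + 1}" if g < spec.n_types * k else f"gene_{g + 1:04d}"
        for g in range(spec.n_genes)
    ]
    X = ExpressionMatrix(values=counts, cell_ids=cell_ids, gene_ids=gene_ids)
    truth = LabelVector(
        labels=[f"type_{t + 1}" for t in type_of_cell], cell_ids=cell_ids
    )
    return X, truth
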