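"""Self-organizing-map training on gene expression profiles.

Genes are treated as points in sample space (one coordinate per sample, in
log-FC units). A rectangular grid of K = rows × cols *metagenes* is fitted to
this gene cloud with the classic online SOM rule and a Gaussian neighborhood:
at every presentation of a gene profile x the best-matching unit (BMU) b is
the metagene of minimal Euclidean distance to x, and every metagene w_k moves
by

    w_k ← w_k + α(t) · exp(−d_grid(k, b)² / 2σ(t)²) · (x − w_k)

with learning rate α and neighborhood radius σ decaying linearly over the
training steps. Each metagene ends up as a prototype of a cluster of
co-expressed genes, and neighboring metagenes carry similar profiles, so one
sample's metagene values arranged on the grid form a smooth expression
"portrait" of that sample.

After the scheduled epochs a single zero-radius batch step replaces every
populated metagene by the centroid of its assigned genes (empty metagenes
keep their weights) and recomputes the assignment. This pins the metagene
profiles to exact centroids of their gene clusters — in particular a 1×1 map
equals the global mean profile — without disturbing the learned topology.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .datatypes import ExpressionMatrix, LOGFC


@dataclass
class SOMConfig:
    """Grid geometry and training schedule.

    The default 50×50 grid suits cohort-scale matrices (tens of thousands of
    genes); smaller studies should shrink the grid so that K remains well
    below the gene count. Radius and learning rate decay linearly from their
    initial to their final value across all training steps; the defaults are
    half the larger grid dimension → 1 and 0.05 → 0.005, with every gene
    presented ten times (epochs=10).
    """

    rows: int = 50
    cols: int = 50
    epochs: int = 10
    initial_radius: float | None = None  # default: max(rows, cols) / 2
    final_radius: float = 1.0
    initial_rate: float = 0.05
    final_rate: float = 0.005
    init: str = "linear"  # "linear" (PCA plane) or "random"
    seed: int = 0

    def resolved_initial_radius(self) -> float:
        if self.initial_radius is not None:
            return float(self.initial_radius)
        return max(max(self.rows, self.cols) / 2.0, self.final_radius)

    def validate(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        r0, r1 = self.resolved_initial_radius(), self.final_radius
        a0, a1 = self.initial_rate, self.final_rate
        if min(r0, r1, a0, a1) <= 0:
            raise ValueError("radii and learning rates must be positive")
        if r1 > r0 or a1 > a0:
            raise ValueError("radii and learning rates must be non-increasing")
        if self.init not in ("linear", "random"):
            raise ValueError("init must be 'linear' or 'random'")


@dataclass
class Portrait:
    """One sample's metagene values arranged on the grid."""

    sample_id: str
    grid: np.ndarray  # rows × cols


class SOMModel:
    """Trained SOM: metadata matrix, gene→metagene assignment, geometry."""

    def __init__(
        self,
        config: SOMConfig,
        metadata: np.ndarray,           # K × M
        assignment: np.ndarray,         # N ints in [0, K)
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        quantization_errors: Sequence[float] = (),
    ):
        self.config = config
        self.metadata = np.asarray(metadata, dtype=float)
        self.assignment = np.asarray(assignment, dtype=int)
        self.gene_ids = list(gene_ids)
        self.sample_ids = list(sample_ids)
        self.quantization_errors = list(quantization_errors)
        K = config.rows * config.cols
        if self.metadata.shape != (K, len(self.sample_ids)):
            raise ValueError("metadata shape does not match grid and samples")
        if len(self.assignment) != len(self.gene_ids):
            raise ValueError("one metagene assignment per gene is required")

    # -- geometry --------------------------------------------------------------
    @property
    def n_metagenes(self) -> int:
        return self.config.rows * self.config.cols

    def grid_coordinates(self) -> np.ndarray:
        """K × 2 array of (row, col) per metagene, row-major order."""
        rows, cols = self.config.rows, self.config.cols
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()])

    def genes_of_metagene(self, k: int) -> list[str]:
        idx = np.flatnonzero(self.assignment == k)
        return [self.gene_ids[i] for i in idx]

    def genes_of_metagenes(self, ks: Sequence[int]) -> list[str]:
        mask = np.isin(self.assignment, list(ks))
        return [g for g, m in zip(self.gene_ids, mask) if m]

    # -- portraits -------------------------------------------------------------
    def portrait(self, sample_id: str) -> Portrait:
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None
        grid = self.metadata[:, j].reshape(self.config.rows, self.config.cols)
        return Portrait(sample_id=sample_id, grid=grid)

    def mean_portrait(self, sample_ids: Sequence[str]) -> Portrait:
        ids = list(sample_ids)
        if not ids:
            raise ValueError("empty sample group")
        cols = []
        for sid in ids:
            try:
                cols.append(self.sample_ids.index(sid))
            except ValueError:
                raise KeyError(f"unknown sample id: {sid!r}") from None
        grid = self.metadata[:, cols].mean(axis=1).reshape(
            self.config.rows, self.config.cols
        )
        return Portrait(sample_id=f"mean({len(ids)} samples)", grid=grid)

    # -- persistence -----------------------------------------------------------
    def save(self, path) -> None:
        """Write the model as a zip archive of TSV tables plus a JSON config."""
        with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
            header = "metagene\t" + "\t".join(self.sample_ids)
            lines = [header]
            for k in range(self.n_metagenes):
                vals = "\t".join("%.12g" % v for v in self.metadata[k])
                lines.append(f"{k}\t{vals}")
            zf.writestr("metadata.tsv", "\n".join(lines) + "\n")
            lines = ["gene_id\tmetagene"]
            for g, k in zip(self.gene_ids, self.assignment):
                lines.append(f"{g}\t{k}")
            zf.writestr("assignment.tsv", "\n".join(lines) + "\n")
            cfg = asdict(self.config)
            cfg["quantization_errors"] = self.quantization_errors
            zf.writestr("config.json", json.dumps(cfg, indent=1))

    @classmethod
    def load(cls, path) -> "SOMModel":
        with zipfile.ZipFile(path) as zf:
            cfg = json.loads(zf.read("config.json"))
            qe = cfg.pop("quantization_errors", [])
            config = SOMConfig(**cfg)
            meta_lines = zf.read("metadata.tsv").decode().strip().split("\n")
            sample_ids = meta_lines[0].split("\t")[1:]
            metadata = np.array(
                [[float(x) for x in line.split("\t")[1:]] for line in meta_lines[1:]]
            )
            asg_lines = zf.read("assignment.tsv").decode().strip().split("\n")
            gene_ids = [line.split("\t")[0] for line in asg_lines[1:]]
            assignment = np.array([int(line.split("\t")[1]) for line in asg_lines[1:]])
        return cls(config, metadata, assignment, gene_ids, sample_ids, qe)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _linear_init(X: np.ndarray, rows: int, cols: int, rng: np.random.Generator) -> np.ndarray:
    """Seed the grid on the plane of the two leading principal directions.

    Falls back to small random perturbations of the mean profile when the
    data are degenerate (fewer than two informative directions).
    """
    n, m = X.shape
    mu = X.mean(axis=0)
    K = rows * cols
    centered = X - mu
    try:
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
    except np.linalg.LinAlgError:  # pragma: no cover - numerical corner
        s, vt = np.zeros(0), np.zeros((0, m))
    # deterministic component signs: largest-magnitude loading positive
    for i in range(min(2, vt.shape[0])):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] = -vt[i]
    sd = s / np.sqrt(max(n - 1, 1))
    W = np.tile(mu, (K, 1))
    # map the longer grid axis onto the leading component
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    col_axis = np.linspace(-2, 2, cols) if cols > 1 else np.zeros(1)
    row_axis = np.linspace(-2, 2, rows) if rows > 1 else np.zeros(1)
    if cols >= rows:
        primary = col_axis[cc.ravel()]
        secondary = row_axis[rr.ravel()]
    else:
        primary = row_axis[rr.ravel()]
        secondary = col_axis[cc.ravel()]
    used = 0
    if vt.shape[0] >= 1 and sd[0] > 0:
        W += np.outer(primary, sd[0] * vt[0])
        used += 1
    if vt.shape[0] >= 2 and sd[1] > 0:
        W += np.outer(secondary, sd[1] * vt[1])
        used += 1
    if used == 0:
        scale = float(np.std(X)) or 1.0
        W += rng.normal(0.0, 0.01 * scale, size=W.shape)
    elif used == 1 and K > max(rows, cols):
        scale = sd[0] if sd.size else float(np.std(X)) or 1.0
        W += rng.normal(0.0, 1e-3 * scale, size=W.shape)
    return W


def _bmus(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Best-matching unit per gene (argmin squared Euclidean distance)."""
    # ||x - w||^2 = ||x||^2 - 2 x·w + ||w||^2 ; ||x||^2 constant per gene
    cross = X @ W.T
    w2 = np.einsum("km,km->k", W, W)
    return np.argmin(w2[None, :] - 2.0 * cross, axis=1)


def quantization_error(X: np.ndarray, W: np.ndarray) -> float:
    """Mean Euclidean distance of genes to their best-matching metagene."""
    bmu = _bmus(X, W)
    return float(np.mean(np.linalg.norm(X - W[bmu], axis=1)))


def train_som(matrix: ExpressionMatrix, config: SOMConfig) -> SOMModel:
    """Fit the metagene grid to the gene cloud of a log-FC matrix.

    Deterministic given ``config.seed``. Raises when the matrix is empty or
    has fewer genes than metagenes.
    """
    config.validate()
    if matrix.scale != LOGFC:
        raise ValueError("train_som expects a log-FC matrix (run preprocess first)")
    X = matrix.values
    n, m = X.shape
    K = config.rows * config.cols
    if n == 0 or m == 0:
        raise ValueError("empty expression matrix")
    if K > n:
        raise ValueError(f"grid has {K} metagenes but only {n} genes are available")

    rng = np.random.default_rng(config.seed)
    if config.init == "linear":
        W = _linear_init(X, config.rows, config.cols, rng)
    else:
        scale = float(np.std(X)) or 1.0
        W = X.mean(axis=0) + rng.normal(0.0, 0.1 * scale, size=(K, m))

    rr, cc = np.meshgrid(np.arange(config.rows), np.arange(config.cols), indexing="ij")
    grid_r, grid_c = rr.ravel().astype(float), cc.ravel().astype(float)

    total_steps = config.epochs * n
    r0, r1 = config.resolved_initial_radius(), config.final_radius
    a0, a1 = config.initial_rate, config.final_rate
    qe = [quantization_error(X, W)]

    step = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        for i in order:
            frac = step / max(total_steps - 1, 1)
            sigma = r0 + (r1 - r0) * frac
            alpha = a0 + (a1 - a0) * frac
            x = X[i]
            d2 = np.sum((W - x) ** 2, axis=1)
            b = int(np.argmin(d2))
            gd2 = (grid_r - grid_r[b]) ** 2 + (grid_c - grid_c[b]) ** 2
            h = np.exp(-gd2 / (2.0 * sigma * sigma))
            active = h > 1e-6
            W[active] += (alpha * h[active])[:, None] * (x - W[active])
            step += 1
        qe.append(quantization_error(X, W))

    # zero-radius batch finish: pin populated metagenes to exact centroids
    bmu = _bmus(X, W)
    for k in np.unique(bmu):
        W[k] = X[bmu == k].mean(axis=0)
    assignment = _bmus(X, W)
    qe.append(quantization_error(X, W))

    return SOMModel(
        config=config,
        metadata=W,
        assignment=assignment,
        gene_ids=matrix.gene_ids,
        sample_ids=matrix.sample_ids,
        quantization_errors=qe,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def portrait_rgba(portrait: Portrait, percentiles: tuple[float, float] = (10.0, 90.0)):
    """RGBA array of a portrait with per-sample percentile color anchoring.

    The color scale is anchored at the given low/high percentiles of the
    portrait's own values, so the darkest blue/red always mark this sample's
    strongest under-/over-expression.
    """
    import matplotlib.cm as cm
    from matplotlib.colors import Normalize

    grid = np.asarray(portrait.grid, dtype=float)
    if not np.all(np.isfinite(grid)):
        raise ValueError("portrait contains non-finite values")
    lo, hi = np.percentile(grid, percentiles)
    if hi - lo < 1e-12:  # constant portrait → uniform mid-scale color
        lo, hi = lo - 0.5, hi + 0.5
    norm = Normalize(vmin=lo, vmax=hi, clip=True)
    return cm.jet(norm(grid))


def render_portrait(portrait: Portrait, path,
                    percentiles: tuple[float, float] = (10.0, 90.0)) -> None:
    """Write a portrait as a PNG heatmap (blue = under-, red = over-expressed)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    rgba = portrait_rgba(portrait, percentiles)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(rgba, origin="upper", interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(portrait.sample_id, fontsize=10)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
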