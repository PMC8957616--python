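"""Synthetic compositional count tables with a known association network.

The generator is a logistic-normal--multinomial model, the standard
benchmark for compositionally-aware network inference: a sparse ground-truth
graph is converted to a positive-definite precision matrix, latent log
abundances are drawn from the corresponding multivariate normal, mapped
through softmax to a composition, and multinomially sampled at a per-sample
sequencing depth drawn from a truncated log-normal law.

Cohort defaults emulate a two-timepoint skin-swab 16S study: 36 baseline
and 34 post-intervention samples, read depths between ~64k and ~975k with
mean ~326k, and of the order of 100 species-level taxa after filtering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import child_rng
from .tables import CountTable

TOPOLOGIES = ("band", "scale_free", "cluster", "erdos_renyi")

#: Study-cohort depth defaults (reads per sample).
DEPTH_MEAN = 326_333
DEPTH_MIN = 63_892
DEPTH_MAX = 975_103


@dataclass
class CohortDesign:
    """Sampling design for a two-arm cohort.

    ``depth_sigma`` is the log-scale standard deviation of the log-normal
    depth law; the law is truncated to [depth_min, depth_max].
    """

    n_baseline: int = 36
    n_post: int = 34
    depth_mean: float = DEPTH_MEAN
    depth_min: int = DEPTH_MIN
    depth_max: int = DEPTH_MAX
    depth_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_baseline < 3 or self.n_post < 3:
            raise ValueError("each arm needs at least 3 samples")
        if self.depth_min <= 0 or self.depth_min > self.depth_max:
            raise ValueError("depth bounds must be positive with min <= max")


@dataclass
class TrueModel:
    """Ground truth for recovery experiments."""

    adjacency: np.ndarray
    precision: np.ndarray
    base_composition: np.ndarray
    topology_name: str
    taxon_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = self.adjacency
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.diag(a).any():
            raise ValueError("adjacency must have zero diagonal")
        p = self.precision
        if not np.allclose(p, p.T):
            raise ValueError("precision must be symmetric")
        if np.linalg.eigvalsh(p)[0] <= 0:
            raise ValueError("precision must be positive definite")
        off_support = (np.abs(p) > 1e-12) & ~np.eye(len(a), dtype=bool)
        if not np.array_equal(off_support, a.astype(bool)):
            raise ValueError("precision off-diagonal support must equal adjacency")
        if not self.taxon_ids:
            self.taxon_ids = default_taxon_ids(len(a))

    @property
    def n_taxa(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum() // 2)

    def edge_set(self) -> set[tuple[str, str]]:
        ids = self.taxon_ids
        i, j = np.triu_indices(self.n_taxa, k=1)
        mask = self.adjacency[i, j] > 0
        return {(ids[a], ids[b]) for a, b in zip(i[mask], j[mask])}

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.taxon_ids)
        g.add_edges_from(self.edge_set())
        return g


def default_taxon_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"sp{i:0{width}d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# ground-truth topologies
# ---------------------------------------------------------------------------

def generate_true_network(
    n_taxa: int,
    topology: str = "erdos_renyi",
    edge_density: float | None = None,
    band_width: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Symmetric, zero-diagonal, binary ground-truth adjacency.

    ``erdos_renyi`` realizes an *exact* edge count round(density * C(n,2))
    by sampling pairs without replacement, so realized densities are
    deterministic given the density argument. ``band`` connects each taxon
    to its ``band_width`` nearest index neighbours (width 1 is a path).
    ``scale_free`` is preferential attachment; ``cluster`` is a 3-block
    graph with edges only inside blocks.
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}; one of {TOPOLOGIES}")
    n_pairs = n_taxa * (n_taxa - 1) // 2
    adj = np.zeros((n_taxa, n_taxa), dtype=np.int8)

    if topology == "band":
        if band_width is None:
            if edge_density is None:
                raise ValueError("band topology needs band_width or edge_density")
            band_width = int(round(edge_density * (n_taxa - 1) / 2))
        if band_width == 0:
            return adj
        if band_width < 0 or band_width >= n_taxa:
            raise ValueError(
                f"band width {band_width} infeasible for {n_taxa} taxa"
            )
        for k in range(1, band_width + 1):
            idx = np.arange(n_taxa - k)
            adj[idx, idx + k] = 1
            adj[idx + k, idx] = 1
        return adj

    if edge_density is None:
        raise ValueError(f"{topology} topology needs edge_density")
    if not 0 <= edge_density < 1:
        raise ValueError("edge_density must be in [0, 1)")
    m_target = int(round(edge_density * n_pairs))
    if m_target == 0:
        return adj

    rng = child_rng(seed, "true_network", topology)
    iu, ju = np.triu_indices(n_taxa, k=1)

    if topology == "erdos_renyi":
        chosen = rng.choice(n_pairs, size=m_target, replace=False)
        adj[iu[chosen], ju[chosen]] = 1

    elif topology == "scale_free":
        m_attach = max(1, int(round(edge_density * (n_taxa - 1) / 2)))
        if m_attach >= n_taxa:
            raise ValueError(
                f"density {edge_density} infeasible for scale_free on {n_taxa} taxa"
            )
        g = nx.barabasi_albert_graph(
            n_taxa, m_attach, seed=int(rng.integers(2**31 - 1))
        )
        for a, b in g.edges():
            adj[a, b] = 1

    else:  # cluster
        blocks = np.array_split(np.arange(n_taxa), 3)
        within_pairs = sum(len(b) * (len(b) - 1) // 2 for b in blocks)
        if m_target > within_pairs:
            raise ValueError(
                f"density {edge_density} infeasible for cluster topology: "
                f"needs {m_target} edges but only {within_pairs} within-block pairs"
            )
        pool = []
        for b in blocks:
            for x in range(len(b)):
                for y in range(x + 1, len(b)):
                    pool.append((b[x], b[y]))
        chosen = rng.choice(len(pool), size=m_target, replace=False)
        for k in chosen:
            a, b = pool[k]
            adj[a, b] = 1

    adj = np.maximum(adj, adj.T)
    return adj


def _signed_couplings(
    adjacency: np.ndarray, off_diag: float, signs: str, seed: int
) -> np.ndarray:
    """Symmetric off-diagonal coupling matrix on the adjacency support.

    ``mixed`` (default) draws Rademacher signs per edge — microbial
    associations are both positive (co-occurrence) and negative
    (exclusion), and sign cancellation keeps the spectral radius of the
    coupling matrix small, so dense graphs do not force vanishing partial
    correlations the way uniformly positive couplings do.
    """
    a = np.asarray(adjacency, dtype=float)
    if signs == "positive":
        return a * off_diag
    if signs != "mixed":
        raise ValueError("signs must be 'mixed' or 'positive'")
    rng = child_rng(seed, "couplings")
    n = len(a)
    iu, ju = np.triu_indices(n, k=1)
    s = np.zeros((n, n))
    draws = rng.choice([-1.0, 1.0], size=len(iu))
    s[iu, ju] = draws
    s += s.T
    return a * s * off_diag


def _auto_shift(couplings: np.ndarray, condition_target: float) -> float:
    """Diagonal shift giving condition number ~condition_target."""
    eigs = np.linalg.eigvalsh(couplings)
    emin, emax = eigs[0], eigs[-1]
    if emax - emin < 1e-12:
        return 1.0
    return (emax - condition_target * emin) / (condition_target - 1)


def network_to_precision(
    adjacency: np.ndarray,
    condition_target: float = 10.0,
    off_diag: float = 0.3,
    diag_shift: float | None = None,
    eigen_floor: float = 1e-4,
    signs: str = "mixed",
    seed: int = 0,
) -> np.ndarray:
    """Positive-definite precision matrix with the adjacency as support.

    Off-diagonal entries get magnitude ``off_diag`` (signs per the
    ``signs`` rule) on the adjacency support; the diagonal is a uniform
    shift chosen either explicitly (``diag_shift``) or so that the
    condition number is ~``condition_target``. The smallest eigenvalue is
    floored at ``eigen_floor``, so the construction always succeeds.
    """
    b = _signed_couplings(adjacency, off_diag, signs, seed)
    eigs = np.linalg.eigvalsh(b)
    emin, emax = eigs[0], eigs[-1]
    if diag_shift is not None:
        s = float(diag_shift)
    elif emax - emin < 1e-12:  # empty graph
        s = 1.0
    else:
        c = float(condition_target)
        if c <= 1:
            raise ValueError("condition_target must be > 1")
        s = (emax - c * emin) / (c - 1)
    s = max(s, eigen_floor - emin)
    prec = b + s * np.eye(len(b))
    return prec


# ---------------------------------------------------------------------------
# logistic-normal-multinomial sampling
# ---------------------------------------------------------------------------

def default_base_composition(n_taxa: int, seed: int = 0, sigma: float = 1.0) -> np.ndarray:
    """Mildly uneven composition (log-normal offsets), normalised to sum 1."""
    rng = child_rng(seed, "base_composition")
    logits = rng.normal(0.0, sigma, size=n_taxa)
    w = np.exp(logits - logits.max())
    return w / w.sum()


def make_true_model(
    n_taxa: int,
    topology: str = "erdos_renyi",
    edge_density: float = 0.1,
    seed: int = 0,
    base_composition: np.ndarray | None = None,
    **precision_kwargs,
) -> TrueModel:
    adj = generate_true_network(n_taxa, topology, edge_density=edge_density, seed=seed)
    precision_kwargs.setdefault("seed", seed)
    prec = network_to_precision(adj, **precision_kwargs)
    if base_composition is None:
        base_composition = default_base_composition(n_taxa, seed=seed)
    base = np.asarray(base_composition, dtype=float)
    if base.shape != (n_taxa,) or (base <= 0).any():
        raise ValueError("base_composition must be a positive vector of length n_taxa")
    base = base / base.sum()
    return TrueModel(
        adjacency=adj,
        precision=prec,
        base_composition=base,
        topology_name=topology,
    )


def draw_depths(design: CohortDesign, n: int, rng: np.random.Generator) -> np.ndarray:
    """Truncated log-normal read depths matching the design's bounds."""
    sigma = design.depth_sigma
    mu = math.log(design.depth_mean) - sigma**2 / 2
    depths = np.empty(n, dtype=np.int64)
    filled = 0
    for _ in range(1000):
        draw = np.exp(rng.normal(mu, sigma, size=2 * (n - filled) + 8))
        ok = draw[(draw >= design.depth_min) & (draw <= design.depth_max)]
        take = min(len(ok), n - filled)
        depths[filled : filled + take] = ok[:take].astype(np.int64)
        filled += take
        if filled == n:
            return depths
    # pathological truncation (bounds nearly degenerate): clip instead
    draw = np.exp(rng.normal(mu, sigma, size=n - filled))
    depths[filled:] = np.clip(draw, design.depth_min, design.depth_max).astype(np.int64)
    return depths


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sample_arm(
    model: TrueModel,
    n: int,
    depths: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    cov = np.linalg.inv(model.precision)
    mu = np.log(model.base_composition)
    z = rng.multivariate_normal(mu, cov, size=n, method="cholesky")
    probs = _softmax(z)
    counts = np.empty((n, model.n_taxa), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(int(depths[i]), probs[i])
    return counts


def _assemble_table(
    counts_base: np.ndarray,
    counts_post: np.ndarray,
    taxon_ids: list[str],
) -> CountTable:
    n_b, n_p = len(counts_base), len(counts_post)
    sample_ids = [f"B{i:03d}" for i in range(1, n_b + 1)] + [
        f"P{i:03d}" for i in range(1, n_p + 1)
    ]
    subjects = [f"S{i:03d}" for i in range(1, n_b + 1)] + [
        f"S{i:03d}" for i in range(1, n_p + 1)
    ]
    timepoints = ["baseline"] * n_b + ["post"] * n_p
    counts = pd.DataFrame(
        np.vstack([counts_base, counts_post]), index=sample_ids, columns=taxon_ids
    )
    metadata = pd.DataFrame(
        {"subject": subjects, "timepoint": timepoints}, index=sample_ids
    )
    return CountTable(counts=counts, metadata=metadata)


def sample_counts(model: TrueModel, design: CohortDesign) -> CountTable:
    """Draw a full cohort (both arms) from a single true model.

    Row sums equal the drawn depths exactly; the table is a pure function
    of (model, design) including the design seed.
    """
    rng_depth = child_rng(design.seed, "depths")
    rng_counts = child_rng(design.seed, "counts")
    n = design.n_baseline + design.n_post
    depths = draw_depths(design, n, rng_depth)
    counts = _sample_arm(model, n, depths, rng_counts)
    return _assemble_table(
        counts[: design.n_baseline], counts[design.n_baseline :], model.taxon_ids
    )


def two_arm_dataset(
    n_taxa: int,
    baseline_density: float,
    post_density: float,
    design: CohortDesign,
    topology: str = "erdos_renyi",
    **model_kwargs,
) -> tuple[CountTable, TrueModel, TrueModel]:
    """Cohort whose post arm has a strictly denser true network.

    Both arms share taxon labels and base composition; only the underlying
    association graph differs.
    """
    if post_density <= baseline_density:
        raise ValueError("post_density must exceed baseline_density")
    base_comp = model_kwargs.pop(
        "base_composition", default_base_composition(n_taxa, seed=design.seed)
    )
    off_diag = model_kwargs.pop("off_diag", 0.3)
    condition_target = model_kwargs.pop("condition_target", 10.0)
    signs = model_kwargs.pop("signs", "mixed")
    seeds = (design.seed * 2 + 1, design.seed * 2 + 2)
    adjs = [
        generate_true_network(n_taxa, topology, edge_density=d, seed=s)
        for d, s in zip((baseline_density, post_density), seeds)
    ]
    couplings = [
        _signed_couplings(adj, off_diag, signs, seed=s) for adj, s in zip(adjs, seeds)
    ]
    # shared diagonal shift: both arms get the same per-edge interaction
    # strength, so the arms differ in topology only (the denser graph needs
    # the larger shift; conditioning both to it keeps the partial
    # correlations comparable rather than diluting the dense arm's edges)
    shift = max(_auto_shift(c, condition_target) for c in couplings)
    base = np.asarray(base_comp, dtype=float)
    base = base / base.sum()
    tm_base, tm_post = (
        TrueModel(
            adjacency=adj,
            precision=c + shift * np.eye(n_taxa),
            base_composition=base,
            topology_name=topology,
        )
        for adj, c in zip(adjs, couplings)
    )
    if tm_post.n_edges <= tm_base.n_edges:
        raise ValueError("post arm did not realize a denser network")
    rng_depth = child_rng(design.seed, "depths")
    rng_b = child_rng(design.seed, "counts", "baseline")
    rng_p = child_rng(design.seed, "counts", "post")
    depths = draw_depths(design, design.n_baseline + design.n_post, rng_depth)
    counts_b = _sample_arm(tm_base, design.n_baseline, depths[: design.n_baseline], rng_b)
    counts_p = _sample_arm(tm_post, design.n_post, depths[design.n_baseline :], rng_p)
    table = _assemble_table(counts_b, counts_p, tm_base.taxon_ids)
    return table, tm_base, tm_post
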