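"""Sparse association-network inference on CLR data.

Per-taxon neighbourhood selection (Meinshausen--Buhlmann): each taxon's CLR
profile is lasso-regressed on all others along a log-spaced regularization
path, and the penalty is chosen by StARS — the graph is re-estimated on
random subsamples and the sparsest penalty whose edge set is stable (mean
edge instability below a threshold) is selected. Edges are merged across
the two directed neighbourhoods by an OR (default) or AND rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path

from ._rng import child_rng
from .tables import ClrMatrix

logger = logging.getLogger(__name__)


@dataclass
class RegularizationPath:
    """Strictly decreasing lasso penalties from lambda_max down."""

    lambdas: np.ndarray
    lambda_min_ratio: float

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float)
        if lam.ndim != 1 or len(lam) < 1:
            raise ValueError("path needs at least one lambda")
        if (lam <= 0).any() or (np.diff(lam) >= 0).any():
            raise ValueError("lambdas must be positive and strictly decreasing")
        self.lambdas = lam

    @property
    def n_lambda(self) -> int:
        return len(self.lambdas)


@dataclass
class StarsResult:
    """Stability-selection summary over the regularization path."""

    path: RegularizationPath
    instability: np.ndarray          # D-bar(lambda), per path position
    monotone_instability: np.ndarray  # running max from lambda_max downward
    selection_freq: np.ndarray       # (n_lambda, p, p) symmetric edge frequencies
    selected_index: int
    n_subsamples: int
    subsample_fraction: float
    stability_threshold: float
    taxon_ids: list[str] = field(default_factory=list)
    no_stable_lambda: bool = False

    @property
    def selected_lambda(self) -> float:
        return float(self.path.lambdas[self.selected_index])

    def selected_frequencies(self) -> np.ndarray:
        return self.selection_freq[self.selected_index]


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-center and unit-scale; zero-variance columns become all-zero."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    ok = sd > 0
    z = np.zeros_like(x)
    z[:, ok] = (x[:, ok] - mu[ok]) / sd[ok]
    return z, ok


def lambda_max(values: np.ndarray) -> float:
    """Smallest penalty at which every neighbourhood regression is empty.

    On standardized columns this is the largest absolute pairwise
    correlation (the lasso KKT bound max_i |x_i' y| / n).
    """
    z, ok = _standardize(np.asarray(values, dtype=float))
    n = z.shape[0]
    s = np.abs(z.T @ z) / n
    np.fill_diagonal(s, 0.0)
    lmax = float(s.max())
    if lmax <= 0:
        raise ValueError("data have no pairwise association; lambda_max undefined")
    return lmax


def make_lambda_path(
    clr: ClrMatrix | np.ndarray,
    n_lambda: int = 20,
    lambda_min_ratio: float = 0.01,
) -> RegularizationPath:
    """Log-spaced path from the data-derived lambda_max down to
    lambda_min_ratio * lambda_max."""
    values = clr.to_array() if isinstance(clr, ClrMatrix) else np.asarray(clr, float)
    if not 0 < lambda_min_ratio < 1:
        raise ValueError("lambda_min_ratio must be in (0, 1)")
    lmax = lambda_max(values)
    lams = np.logspace(0.0, np.log10(lambda_min_ratio), n_lambda) * lmax
    return RegularizationPath(lambdas=lams, lambda_min_ratio=lambda_min_ratio)


def _neighborhood_coefs(values: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Lasso coefficients for every neighbourhood along the path.

    Returns ``coefs`` with shape (n_lambda, p, p) where ``coefs[l, i, j]``
    is the coefficient of predictor taxon i in the regression of taxon j
    at ``lambdas[l]``; the diagonal is zero. Columns are standardized
    (including the response), so coefficients are correlation-scale.
    Zero-variance taxa are excluded from both roles.
    """
    x = np.asarray(values, dtype=float)
    n, p = x.shape
    if n < 3:
        raise ValueError("need at least 3 samples")
    lambdas = np.asarray(lambdas, dtype=float)
    z, ok = _standardize(x)
    if not ok.all():
        logger.warning("excluding %d zero-variance taxa from regression", (~ok).sum())
    coefs = np.zeros((len(lambdas), p, p))
    idx = np.flatnonzero(ok)
    for j in idx:
        others = idx[idx != j]
        if len(others) == 0:
            continue
        # sklearn returns coefficients for alphas sorted descending;
        # near-threshold duality gaps at the dense path end are benign
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            alphas, path_coefs, _ = lasso_path(
                z[:, others], z[:, j], alphas=lambdas, tol=1e-6, max_iter=10_000
            )
        order = np.argsort(-alphas)
        reorder = np.argsort(np.argsort(-lambdas))
        path_coefs = path_coefs[:, order][:, reorder]
        coefs[:, others, j] = path_coefs.T
    return coefs


def neighborhood_fit(clr: ClrMatrix | np.ndarray, lam: float) -> np.ndarray:
    """Signed neighbourhood coefficient matrix at a single penalty.

    ``B[i, j]`` is the lasso coefficient of taxon i predicting taxon j;
    the diagonal is identically zero.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    values = clr.to_array() if isinstance(clr, ClrMatrix) else np.asarray(clr, float)
    return _neighborhood_coefs(values, np.array([lam]))[0]


def _symmetrize_support(coefs: np.ndarray, symmetrization: str) -> np.ndarray:
    """Boolean (n_lambda, p, p) edge indicators from directed coefficients."""
    nz = coefs != 0
    if symmetrization == "OR":
        return nz | nz.transpose(0, 2, 1)
    if symmetrization == "AND":
        return nz & nz.transpose(0, 2, 1)
    raise ValueError("symmetrization must be 'OR' or 'AND'")


def stars_select(
    clr: ClrMatrix | np.ndarray,
    path: RegularizationPath | None = None,
    n_subsamples: int = 50,
    subsample_fraction: float = 0.8,
    stability_threshold: float = 0.05,
    seed: int = 0,
    symmetrization: str = "OR",
    n_lambda: int = 20,
    lambda_min_ratio: float = 0.01,
) -> StarsResult:
    """StARS penalty selection by subsample edge stability.

    For each penalty, the network is re-estimated on ``n_subsamples``
    random subsamples (fraction ``subsample_fraction``, without
    replacement); per-edge selection frequencies theta give the mean
    instability D-bar(lambda) = mean over taxon pairs of 2 theta (1-theta),
    which lies in [0, 0.5]. Walking from lambda_max toward denser models,
    instability is monotonized by running maximum and the smallest lambda
    whose monotonized instability is <= the threshold is selected (the
    densest stable graph). If even the sparsest model is unstable, the
    sparsest lambda is returned with ``no_stable_lambda`` set.
    """
    if isinstance(clr, ClrMatrix):
        values = clr.to_array()
        taxon_ids = clr.taxon_ids
    else:
        values = np.asarray(clr, dtype=float)
        taxon_ids = [f"t{i}" for i in range(values.shape[1])]
    n, p = values.shape
    if n_subsamples < 2:
        raise ValueError("need at least 2 subsamples")
    m = int(np.floor(subsample_fraction * n))
    if m < 3:
        raise ValueError("subsample size must be >= 3")
    if path is None:
        path = make_lambda_path(values, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio)
    lambdas = path.lambdas
    rng = child_rng(seed, "stars")
    freq = np.zeros((path.n_lambda, p, p))
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=m, replace=False)
        coefs = _neighborhood_coefs(values[idx], lambdas)
        freq += _symmetrize_support(coefs, symmetrization)
    freq /= n_subsamples

    iu, ju = np.triu_indices(p, k=1)
    theta = freq[:, iu, ju]
    instability = (2.0 * theta * (1.0 - theta)).mean(axis=1)
    monotone = np.maximum.accumulate(instability)
    stable = monotone <= stability_threshold
    if stable.any():
        selected = int(np.flatnonzero(stable)[-1])
        warn = False
    else:
        selected = 0
        warn = True
        logger.warning(
            "no lambda met instability threshold %.3g; returning sparsest",
            stability_threshold,
        )
    return StarsResult(
        path=path,
        instability=instability,
        monotone_instability=monotone,
        selection_freq=freq,
        selected_index=selected,
        n_subsamples=n_subsamples,
        subsample_fraction=subsample_fraction,
        stability_threshold=stability_threshold,
        taxon_ids=list(taxon_ids),
        no_stable_lambda=warn,
    )


def network_from_coefs(
    coefs: np.ndarray,
    taxon_ids: list[str],
    symmetrization: str = "OR",
    stability: np.ndarray | None = None,
    selected_lambda: float | None = None,
) -> nx.Graph:
    """Undirected taxon graph from a directed coefficient matrix.

    Edge weight is the mean of the two directed coefficients (a missing
    direction counts as 0 under OR); stability, if given, is the StARS
    selection frequency of the edge at the selected penalty.
    """
    p = coefs.shape[0]
    if len(taxon_ids) != p:
        raise ValueError("taxon_ids length must match coefficient matrix")
    g = nx.Graph()
    g.add_nodes_from(taxon_ids)
    g.graph["symmetrization"] = symmetrization
    if selected_lambda is not None:
        g.graph["selected_lambda"] = float(selected_lambda)
    iu, ju = np.triu_indices(p, k=1)
    bij = coefs[iu, ju]
    bji = coefs[ju, iu]
    if symmetrization == "OR":
        present = (bij != 0) | (bji != 0)
    elif symmetrization == "AND":
        present = (bij != 0) & (bji != 0)
    else:
        raise ValueError("symmetrization must be 'OR' or 'AND'")
    weights = (bij + bji) / 2.0
    if not np.isfinite(weights[present]).all():
        raise ValueError("non-finite edge weight encountered")
    for i, j, w, keep in zip(iu, ju, weights, present):
        if keep:
            attrs = {"weight": float(w)}
            if stability is not None:
                attrs["stability"] = float(stability[i, j])
            g.add_edge(taxon_ids[i], taxon_ids[j], **attrs)
    return g


def infer_network(
    clr: ClrMatrix,
    stars: StarsResult | None = None,
    lam: float | None = None,
    symmetrization: str = "OR",
) -> nx.Graph:
    """Fit the neighbourhood model on the full data at the selected penalty.

    Either a :class:`StarsResult` (whose selected lambda and selection
    frequencies are used) or an explicit ``lam`` must be given.
    """
    if stars is not None:
        if stars.taxon_ids != clr.taxon_ids:
            raise ValueError("StARS result was computed on a different taxon set")
        lam = stars.selected_lambda
        stability = stars.selected_frequencies()
    elif lam is not None:
        stability = None
    else:
        raise ValueError("provide a StarsResult or an explicit lambda")
    coefs = neighborhood_fit(clr, lam)
    return network_from_coefs(
        coefs, clr.taxon_ids, symmetrization, stability=stability, selected_lambda=lam
    )
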