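"""Group-level correlation networks and density-thresholded graphs.

A *structural covariance network* has one node per brain region and, as
edge weights, the across-subject Pearson correlations of regional
grey-matter volumes computed within one group of subjects.  Confounds
(age, sex) are removed first by ordinary least-squares residualization
of each region on the covariates; correlating residuals is equivalent
to partial correlation for this design.

Binary graphs are obtained by *density thresholding*: at density ``d``
the ``k = round(d * N(N-1)/2)`` most strongly positively correlated
region pairs become edges.  Negative correlations never become edges.
Analyses run over a density grid from ``d_min`` -- the smallest grid
density at which every compared network is fully connected -- up to an
upper bound of 0.5, above which grey-matter covariance networks lose
biological specificity.

Ties in correlation rank are broken by lexicographic (row, col) order
so that thresholding is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csgraph, csr_matrix

from .errors import DataError, DensityError
from .volumes import region_columns, volume_matrix

DEFAULT_COVARIATES = ("age", "sex")
D_MAX_DEFAULT = 0.5
GRID_STEP_DEFAULT = 0.01


@dataclass(frozen=True)
class CovarianceNetwork:
    """One group's region-by-region correlation matrix."""

    region_names: tuple[str, ...]
    corr: np.ndarray
    group_label: str
    n_subjects: int

    def __post_init__(self) -> None:
        c = self.corr
        n = len(self.region_names)
        if c.shape != (n, n):
            raise DataError("correlation matrix shape does not match region names")
        if np.abs(c - c.T).max() > 1e-12:
            raise DataError("correlation matrix is not symmetric")
        if np.abs(np.diag(c) - 1.0).max() > 0:
            raise DataError("correlation matrix diagonal must be exactly 1")
        if np.abs(c).max() > 1.0:
            raise DataError("correlations must lie in [-1, 1]")

    @property
    def n_regions(self) -> int:
        return len(self.region_names)


@dataclass(frozen=True)
class DensityProfile:
    """Binary adjacency matrices of one network over a density grid."""

    density_grid: np.ndarray
    adjacency: np.ndarray  # (n_densities, N, N) boolean
    d_min: float

    def at(self, density: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.density_grid - density)))
        if abs(self.density_grid[idx] - density) > 1e-9:
            raise DensityError(f"density {density} not on the profile grid")
        return self.adjacency[idx]


def residualize(
    table: pd.DataFrame, covariate_names=DEFAULT_COVARIATES
) -> pd.DataFrame:
    """Replace each region column by its OLS residual on the covariates.

    An intercept is always included, so residual means are zero; with an
    empty covariate list this reduces to column demeaning.  Constant
    covariates are dropped with a warning (they are collinear with the
    intercept).
    """
    regions = region_columns(table)
    Y = table[regions].to_numpy(dtype=float)
    n = len(table)
    cols = [np.ones(n)]
    for name in covariate_names:
        if name not in table.columns:
            raise DataError(f"covariate {name!r} not in table")
        x = table[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"covariate {name!r} is constant; dropped", stacklevel=2)
            continue
        cols.append(x)
    X = np.column_stack(cols)
    if X.shape[1] >= n:
        raise DataError(
            f"{X.shape[1]} regressors (incl. intercept) for {n} subjects"
        )
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    out = table.copy()
    out[regions] = Y - X @ beta
    return out


def correlation_network(
    table: pd.DataFrame, group_label: str | None = None
) -> CovarianceNetwork:
    """Pearson correlation network over the rows of ``table``."""
    regions = region_columns(table)
    Y = volume_matrix(table)
    if Y.shape[0] < 3:
        raise DataError(f"need at least 3 subjects, got {Y.shape[0]}")
    sd = Y.std(axis=0)
    if (sd == 0).any():
        bad = [regions[i] for i in np.flatnonzero(sd == 0)]
        raise DataError(f"zero-variance regions: {bad}")
    corr = np.corrcoef(Y, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    if group_label is None:
        groups = table["group"].unique() if "group" in table.columns else ["?"]
        group_label = str(groups[0]) if len(groups) == 1 else "mixed"
    return CovarianceNetwork(tuple(regions), corr, group_label, Y.shape[0])


def n_edges_at_density(density: float, n_regions: int) -> int:
    """Edge count at a density: round(d * N(N-1)/2)."""
    return int(np.rint(density * n_regions * (n_regions - 1) / 2.0))


def rank_edges(corr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Positive-correlation node pairs sorted by descending correlation.

    Returns (rows, cols) index arrays of the upper triangle, strongest
    correlation first; ties broken by (row, col) lexicographic order.
    """
    n = corr.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    vals = corr[iu, ju]
    pos = vals > 0
    iu, ju, vals = iu[pos], ju[pos], vals[pos]
    order = np.lexsort((ju, iu, -vals))
    return iu[order], ju[order]


def _adjacency_from_edges(rows, cols, k: int, n: int) -> np.ndarray:
    adj = np.zeros((n, n), dtype=bool)
    adj[rows[:k], cols[:k]] = True
    adj |= adj.T
    return adj


def binarize_at_density(net: CovarianceNetwork, density: float) -> np.ndarray:
    """Binary adjacency keeping the top-k positive correlations.

    ``k = round(d * N(N-1)/2)``.  Raises :class:`DensityError` if the
    density implies no edges or exceeds the number of positive
    correlations available.
    """
    if not 0 < density <= 1:
        raise DensityError(f"density must be in (0, 1], got {density}")
    n = net.n_regions
    k = n_edges_at_density(density, n)
    if k == 0:
        raise DensityError(f"density {density} implies zero edges for N={n}")
    rows, cols = rank_edges(net.corr)
    if k > len(rows):
        d_max = len(rows) / (n * (n - 1) / 2.0)
        raise DensityError(
            f"density {density} needs {k} edges but only {len(rows)} positive "
            f"correlations exist (maximum achievable density {d_max:.4f})"
        )
    return _adjacency_from_edges(rows, cols, k, n)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))
        self.n_components = n

    def find(self, a: int) -> int:
        p = self.parent
        while p[a] != a:
            p[a] = p[p[a]]
            a = p[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb
            self.n_components -= 1


def min_connected_edge_count(rows, cols, n: int) -> int | None:
    """Smallest k such that the top-k edges span a connected graph.

    Edge sets are nested in k, so connectivity is monotone and the
    minimal k is well defined.  Returns None if even the full positive
    edge set does not connect the graph.
    """
    uf = _UnionFind(n)
    for k, (a, b) in enumerate(zip(rows, cols), start=1):
        uf.union(int(a), int(b))
        if uf.n_components == 1:
            return k
    return None


def density_grid(d_min: float, d_max: float, grid_step: float) -> np.ndarray:
    """Grid densities in [d_min, d_max] at multiples of grid_step."""
    lo = int(np.ceil(round(d_min / grid_step, 9) - 1e-9))
    hi = int(np.floor(round(d_max / grid_step, 9) + 1e-9))
    if hi < lo:
        raise DensityError(f"empty density grid: [{d_min}, {d_max}] step {grid_step}")
    return np.round(np.arange(lo, hi + 1) * grid_step, 10)


def min_connectivity_density(
    nets,
    grid_step: float = GRID_STEP_DEFAULT,
    d_max: float = D_MAX_DEFAULT,
) -> float:
    """Smallest grid density at which EVERY supplied network is connected.

    Raises :class:`DensityError` if no grid density up to ``d_max``
    connects all networks.
    """
    nets = list(nets)
    if not nets:
        raise DataError("need at least one network")
    n = nets[0].n_regions
    m = n * (n - 1) / 2.0
    k_req = 0
    for net in nets:
        rows, cols = rank_edges(net.corr)
        k_min = min_connected_edge_count(rows, cols, n)
        if k_min is None:
            raise DensityError(
                f"network {net.group_label!r} never becomes connected with "
                "positive-correlation edges only"
            )
        k_req = max(k_req, k_min)
    for d in density_grid(grid_step, d_max, grid_step):
        if n_edges_at_density(d, n) >= k_req:
            return float(d)
    raise DensityError(
        f"no grid density <= {d_max} yields full connectivity "
        f"(needs {k_req} edges, density {k_req / m:.4f})"
    )


def build_profile(
    net: CovarianceNetwork,
    d_min: float,
    d_max: float = D_MAX_DEFAULT,
    grid_step: float = GRID_STEP_DEFAULT,
) -> DensityProfile:
    """Adjacency matrices of ``net`` over the [d_min, d_max] grid."""
    if d_min > d_max:
        raise DensityError(f"d_min {d_min} exceeds d_max {d_max}")
    grid = density_grid(d_min, d_max, grid_step)
    n = net.n_regions
    rows, cols = rank_edges(net.corr)
    mats = []
    for d in grid:
        k = n_edges_at_density(float(d), n)
        if k == 0:
            raise DensityError(f"grid density {d} implies zero edges")
        if k > len(rows):
            dm = len(rows) / (n * (n - 1) / 2.0)
            raise DensityError(
                f"grid density {d} exceeds maximum achievable density {dm:.4f}"
            )
        mats.append(_adjacency_from_edges(rows, cols, k, n))
    return DensityProfile(grid, np.array(mats), float(d_min))


def is_connected(adj: np.ndarray) -> bool:
    n_comp, _ = csgraph.connected_components(csr_matrix(adj), directed=False)
    return n_comp == 1


def write_correlation_tsv(net: CovarianceNetwork, path) -> None:
    """Square correlation matrix as TSV with a region-name header."""
    df = pd.DataFrame(net.corr, columns=net.region_names)
    df.insert(0, "region", net.region_names)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_edge_list(profile: DensityProfile, region_names, path) -> None:
    """Edges as (region_a, region_b, density_first_present) TSV rows."""
    first = {}
    for d, adj in zip(profile.density_grid, profile.adjacency):
        r, c = np.nonzero(np.triu(adj, k=1))
        for a, b in zip(r, c):
            first.setdefault((int(a), int(b)), float(d))
    rows = [
        (region_names[a], region_names[b], d)
        for (a, b), d in sorted(first.items())
    ]
    pd.DataFrame(rows, columns=["region_a", "region_b", "density_first_present"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
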