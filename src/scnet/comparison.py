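"""Permutation inference on group-level network measures.

Because a structural covariance network is a *group-level* construct
(one correlation matrix per group, not per subject), group differences
cannot be tested subject-wise.  Instead, subjects are permuted between
groups and the entire network pipeline -- residualize on covariates,
correlate, threshold over the density grid, compute the measure -- is
recomputed for every relabeling.  The measure difference is summarized
by the area under its curve (AUC) across densities, making the test
robust to the choice of any single threshold.

Two designs are supported:

* **unpaired** (e.g. patients vs controls): subjects are pooled and
  reassigned uniformly at random to pseudo-groups of the original
  sizes;
* **paired** (baseline vs follow-up within one subgroup): each
  subject's baseline/follow-up labels are swapped independently with
  probability 1/2 (a sign-flip-style scheme respecting the
  within-subject pairing).

Two-tailed p-values use the ``(#{|perm| >= |observed|} + 1)/(n_perm + 1)``
convention, so p is never exactly zero.  Per-region p-values are
corrected with Benjamini-Hochberg FDR.

The minimum full-connectivity density ``d_min`` is fixed from the
*observed* data and reused in permutation replicates; a replicate whose
pseudo-network happens to be disconnected at ``d_min`` is counted (the
path length then follows the largest-component convention).
Recomputing ``d_min`` per replicate is available via
``recompute_d_min=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .errors import DataError, DensityError
from .metrics import (
    betweenness,
    characteristic_path_length,
    clustering_coefficient,
    global_metrics,
)
from .networks import (
    D_MAX_DEFAULT,
    GRID_STEP_DEFAULT,
    density_grid,
    min_connected_edge_count,
    n_edges_at_density,
    rank_edges,
)
from .volumes import BASELINE, FOLLOWUP, region_columns

GLOBAL_MEASURES = ("clustering", "path_length", "sigma")
NODAL_MEASURES = ("betweenness",)


@dataclass(frozen=True)
class ComparisonResult:
    """Permutation comparison of one network measure between two groups.

    ``observed_auc_diff``, ``p`` and ``q`` are scalars wrapped in
    length-1 arrays for global measures and length-N arrays for nodal
    measures (``region_names`` then gives the node order).  ``q`` is
    None for global measures (FDR applies across regions only).
    """

    measure: str
    grid: np.ndarray
    observed_diff_curve: np.ndarray  # (n_densities,) or (n_densities, N)
    observed_auc_diff: np.ndarray
    perm_auc_diff: np.ndarray  # (n_perm,) or (n_perm, N)
    p: np.ndarray
    q: np.ndarray | None
    n_perm: int
    seed: int
    d_min: float
    grid_step: float
    paired: bool
    region_names: tuple[str, ...] | None
    n_disconnected_replicates: int

    def metadata(self) -> dict:
        """Run conventions for the JSON metadata record."""
        return {
            "measure": self.measure,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "d_min": self.d_min,
            "d_max": float(self.grid[-1]),
            "grid_step": self.grid_step,
            "paired": self.paired,
            "p_convention": "(count+1)/(n_perm+1), two-tailed on |AUC diff|",
            "edge_rule": "top-k positive correlations, lexicographic tie-break",
            "disconnected_replicates": self.n_disconnected_replicates,
        }


def auc_over_densities(values: np.ndarray, grid: np.ndarray) -> float | np.ndarray:
    """Trapezoidal integral of a metric curve over the density grid."""
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if len(values) != len(grid):
        raise DataError(
            f"curve length {len(values)} does not match grid length {len(grid)}"
        )
    if len(grid) > 1 and not (np.diff(grid) > 0).all():
        raise DataError("density grid must be strictly increasing")
    if len(grid) == 1:
        return values[0] * 0.0 if values.ndim > 1 else 0.0
    return np.trapezoid(values, grid, axis=0)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DataError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p.ravel(), method="fdr_bh")
    return q.reshape(p.shape)


def permute_groups(
    table_a: pd.DataFrame, table_b: pd.DataFrame, seed: int, i: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool two unpaired tables and reassign rows to pseudo-groups.

    Deterministic given (seed, i); pseudo-group sizes equal the
    original sizes.  Subject sets must be disjoint.
    """
    ids_a = set(table_a["subject_id"])
    ids_b = set(table_b["subject_id"])
    if ids_a & ids_b:
        raise DataError(f"subject sets overlap: {sorted(ids_a & ids_b)[:5]}")
    pooled = pd.concat([table_a, table_b], ignore_index=True)
    rng = np.random.default_rng([seed, i])
    perm = rng.permutation(len(pooled))
    na = len(table_a)
    return (
        pooled.iloc[perm[:na]].reset_index(drop=True),
        pooled.iloc[perm[na:]].reset_index(drop=True),
    )


def permute_timepoints(paired_table: pd.DataFrame, seed: int, i: int) -> pd.DataFrame:
    """Swap baseline/follow-up labels per subject with probability 1/2.

    Every subject must have exactly one baseline and one follow-up row.
    Deterministic given (seed, i).
    """
    out = paired_table.copy()
    subjects = []
    for sid, grp in paired_table.groupby("subject_id", sort=True):
        tps = sorted(grp["timepoint"])
        if tps != [BASELINE, FOLLOWUP]:
            raise DataError(
                f"subject {sid!r} lacks a baseline/follow-up pair (has {tps})"
            )
        subjects.append(sid)
    rng = np.random.default_rng([seed, i])
    flips = rng.random(len(subjects)) < 0.5
    flip_ids = {sid for sid, f in zip(subjects, flips) if f}
    mask = out["subject_id"].isin(flip_ids)
    swapped = out.loc[mask, "timepoint"].map({BASELINE: FOLLOWUP, FOLLOWUP: BASELINE})
    out.loc[mask, "timepoint"] = swapped
    return out


# ---------------------------------------------------------------------------
# fast array-level pipeline used inside the permutation loop


def _pooled_arrays(table: pd.DataFrame, covariates) -> tuple[np.ndarray, np.ndarray]:
    """(volumes, design-with-intercept) as float arrays."""
    Y = table[region_columns(table)].to_numpy(dtype=float)
    cols = [np.ones(len(table))]
    for name in covariates:
        if name not in table.columns:
            raise DataError(f"covariate {name!r} not in table")
        cols.append(table[name].to_numpy(dtype=float))
    return Y, np.column_stack(cols)


def _residual_corr(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    E = Y - X @ beta
    sd = E.std(axis=0)
    if (sd == 0).any():
        raise DataError("zero-variance region after residualization")
    corr = np.corrcoef(E, rowvar=False)
    return np.clip(corr, -1.0, 1.0)


def _curves(
    corr: np.ndarray,
    ks: np.ndarray,
    grid: np.ndarray,
    measure,
    *,
    n_random: int,
    n_swaps_per_edge: int,
    rng_seed: int,
    allow_shortfall: bool = False,
) -> tuple[np.ndarray, bool]:
    """Measure values along the density grid, plus a degradation flag.

    The flag is True when the graph at the lowest grid density is not
    connected, or when fewer positive correlations exist than the grid
    requests (possible only in permutation replicates, since observed
    grids start at the minimum full-connectivity density; replicates
    clip the edge count with ``allow_shortfall`` instead of aborting
    the run).
    """
    n = corr.shape[0]
    rows, cols = rank_edges(corr)
    shortfall = ks[-1] > len(rows)
    if shortfall and not allow_shortfall:
        raise DensityError(
            f"network has only {len(rows)} positive correlations; "
            f"density grid needs {int(ks[-1])} edges"
        )
    k_conn = min_connected_edge_count(rows, cols, n)
    disconnected = shortfall or k_conn is None or k_conn > ks[0]
    adj = np.zeros((n, n), dtype=bool)
    prev = 0
    out = []
    for k, d in zip(ks, grid):
        k = min(int(k), len(rows))
        r, c = rows[prev:k], cols[prev:k]
        adj[r, c] = True
        adj[c, r] = True
        prev = k
        if measure == "clustering":
            out.append(clustering_coefficient(adj)[0])
        elif measure == "path_length":
            out.append(characteristic_path_length(adj))
        elif measure == "betweenness":
            out.append(betweenness(adj))
        elif measure == "sigma":
            gm = global_metrics(
                adj, float(d), n_random, n_swaps_per_edge, seed=rng_seed
            )
            out.append(gm.sigma)
        elif callable(measure):
            out.append(measure(adj))
        else:
            raise DataError(f"unknown measure {measure!r}")
    return np.asarray(out, dtype=float), disconnected


def _measure_name(measure) -> str:
    return measure if isinstance(measure, str) else getattr(measure, "__name__", "custom")


def compare(
    measure,
    data_a: pd.DataFrame,
    data_b: pd.DataFrame,
    *,
    covariates=("age", "sex"),
    n_perm: int = 1000,
    paired: bool = False,
    seed: int = 0,
    grid_step: float = GRID_STEP_DEFAULT,
    d_max: float = D_MAX_DEFAULT,
    d_min: float | None = None,
    recompute_d_min: bool = False,
    n_random: int = 20,
    n_swaps_per_edge: int = 10,
) -> ComparisonResult:
    """Permutation test of a network-measure difference between groups.

    ``measure`` is one of ``"clustering"``, ``"path_length"``,
    ``"sigma"``, ``"betweenness"``, or a callable mapping a boolean
    adjacency matrix to a scalar or per-node vector.  The observed
    difference is ``measure(data_a network) - measure(data_b network)``
    at each grid density, summarized by its AUC over
    ``[d_min, d_max]``.  For the paired design, pass the baseline rows
    as ``data_a`` and the follow-up rows as ``data_b`` (same subjects).

    With the seed fixed the result is bit-reproducible end to end.
    """
    regions_a = region_columns(data_a)
    if regions_a != region_columns(data_b):
        raise DataError("the two tables must share an identical region set")
    n_regions = len(regions_a)

    Ya, Xa = _pooled_arrays(data_a, covariates)
    Yb, Xb = _pooled_arrays(data_b, covariates)
    na = len(Ya)
    Y = np.vstack([Ya, Yb])
    X = np.vstack([Xa, Xb])

    if paired:
        subj_a = data_a["subject_id"].to_numpy()
        subj_b = data_b["subject_id"].to_numpy()
        if len(subj_a) != len(subj_b) or set(subj_a) != set(subj_b):
            raise DataError("paired design needs the same subjects in both tables")
        # canonical subject order: the relabeling pattern depends only on
        # the subject set, not on row order or argument order
        order_a = np.argsort(subj_a, kind="stable")
        order_b = np.argsort(subj_b, kind="stable")
        idx_a0 = order_a
        idx_b0 = na + order_b
        n_units = na
    else:
        ids = np.concatenate(
            [data_a["subject_id"].to_numpy(), data_b["subject_id"].to_numpy()]
        )
        # canonical pooled order for permutation reproducibility / symmetry
        pool_order = np.argsort(ids, kind="stable")
        Y = Y[pool_order]
        X = X[pool_order]
        idx_a0 = np.flatnonzero(pool_order < na)
        idx_b0 = np.flatnonzero(pool_order >= na)
        n_units = len(Y)

    def corr_pair(idx_a, idx_b):
        return (
            _residual_corr(Y[idx_a], X[idx_a]),
            _residual_corr(Y[idx_b], X[idx_b]),
        )

    obs_corr_a, obs_corr_b = corr_pair(idx_a0, idx_b0)

    def dmin_for(corrs) -> float:
        k_req = 0
        for c in corrs:
            rows, cols = rank_edges(c)
            k = min_connected_edge_count(rows, cols, n_regions)
            if k is None:
                raise DensityError("network never becomes connected")
            k_req = max(k_req, k)
        for d in density_grid(grid_step, d_max, grid_step):
            if n_edges_at_density(float(d), n_regions) >= k_req:
                return float(d)
        raise DensityError(f"no density <= {d_max} connects both networks")

    if d_min is None:
        d_min = dmin_for((obs_corr_a, obs_corr_b))
    grid = density_grid(d_min, d_max, grid_step)
    ks = np.array([n_edges_at_density(float(d), n_regions) for d in grid])

    def stat(corr_a, corr_b, rep_seed, rep_grid, rep_ks, replicate=False):
        ca, disc_a = _curves(
            corr_a, rep_ks, rep_grid, measure,
            n_random=n_random, n_swaps_per_edge=n_swaps_per_edge, rng_seed=rep_seed,
            allow_shortfall=replicate,
        )
        cb, disc_b = _curves(
            corr_b, rep_ks, rep_grid, measure,
            n_random=n_random, n_swaps_per_edge=n_swaps_per_edge, rng_seed=rep_seed + 1,
            allow_shortfall=replicate,
        )
        diff = ca - cb
        return diff, np.atleast_1d(auc_over_densities(diff, rep_grid)), disc_a or disc_b

    obs_diff, obs_auc, _ = stat(obs_corr_a, obs_corr_b, seed, grid, ks)

    perm_auc = np.empty((n_perm, len(obs_auc)))
    n_disconnected = 0
    rng_master = np.random.default_rng(seed)
    for i in range(n_perm):
        rng = np.random.default_rng([seed, i])
        if paired:
            flips = rng.random(n_units) < 0.5
            idx_a = np.where(flips, idx_b0, idx_a0)
            idx_b = np.where(flips, idx_a0, idx_b0)
        else:
            perm = rng.permutation(n_units)
            idx_a, idx_b = perm[:na], perm[na:]
        corr_a, corr_b = corr_pair(idx_a, idx_b)
        rep_grid, rep_ks = grid, ks
        if recompute_d_min:
            rep_dmin = dmin_for((corr_a, corr_b))
            rep_grid = density_grid(rep_dmin, d_max, grid_step)
            rep_ks = np.array(
                [n_edges_at_density(float(d), n_regions) for d in rep_grid]
            )
        rep_seed = int(rng_master.integers(2**31 - 2))
        _, auc_i, disc = stat(corr_a, corr_b, rep_seed, rep_grid, rep_ks, replicate=True)
        perm_auc[i] = auc_i
        n_disconnected += disc

    exceed = np.abs(perm_auc) >= np.abs(obs_auc)[None, :] - 1e-12
    p = (exceed.sum(axis=0) + 1.0) / (n_perm + 1.0)
    nodal = obs_diff.ndim == 2
    q = fdr_adjust(p) if nodal else None
    return ComparisonResult(
        measure=_measure_name(measure),
        grid=grid,
        observed_diff_curve=obs_diff,
        observed_auc_diff=obs_auc,
        perm_auc_diff=perm_auc,
        p=p,
        q=q,
        n_perm=n_perm,
        seed=seed,
        d_min=float(d_min),
        grid_step=grid_step,
        paired=paired,
        region_names=tuple(regions_a) if nodal else None,
        n_disconnected_replicates=int(n_disconnected),
    )


def result_table(result: ComparisonResult, alpha: float = 0.05) -> pd.DataFrame:
    """Per-region (or single-row global) TSV-ready result table."""
    if result.region_names is not None:
        df = pd.DataFrame(
            {
                "region": result.region_names,
                "observed_auc_diff": result.observed_auc_diff,
                "p": result.p,
                "q": result.q,
            }
        )
        df["significant_at_0.05"] = df["q"] < alpha
    else:
        df = pd.DataFrame(
            {
                "measure": [result.measure],
                "observed_auc_diff": result.observed_auc_diff,
                "p": result.p,
            }
        )
        df["significant_at_0.05"] = df["p"] < alpha
    return df
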