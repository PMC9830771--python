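"""End-to-end orchestration of the two study designs.

* **cross-sectional**: patients vs controls at baseline -- global
  metric curves, nodal betweenness comparison, hub sets per group;
* **longitudinal**: baseline vs follow-up within each clinically
  defined patient subgroup (paired permutation scheme), with hub sets
  at both timepoints reported side by side.

Patients are split into *persisting* and *decreasing* subgroups by the
change of their neurological-soft-signs (NSS) total score: subjects
whose score drop (baseline minus follow-up) exceeds the sample mean
drop form the decreasing subgroup.

All randomness flows from a single master seed, and every numeric
output directory carries a JSON metadata record (seed, grid,
conventions) enabling exact replay; reruns with an identical config
produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import comparison, metrics, networks
from .errors import DataError
from .volumes import BASELINE, FOLLOWUP, read_volume_table

log = logging.getLogger("scnet")

GLOBAL_MEASURES_DEFAULT = ("clustering", "path_length")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML/JSON-loadable).

    Defaults reproduce the reference settings: density upper bound 0.5,
    grid step 0.01, 1000 permutations, 20 random reference graphs.
    """

    input_table: str | None = None
    nss_table: str | None = None
    covariates: tuple[str, ...] = ("age", "sex")
    grid_step: float = 0.01
    d_max: float = 0.5
    n_perm: int = 1000
    n_random: int = 20
    n_swaps_per_edge: int = 10
    seed: int = 0
    paired: bool = False
    include_sigma: bool = False
    global_measures: tuple[str, ...] = GLOBAL_MEASURES_DEFAULT
    output_dir: str = "scnet-output"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        for key in ("covariates", "global_measures"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def measures(self) -> tuple[str, ...]:
        m = tuple(self.global_measures)
        if self.include_sigma and "sigma" not in m:
            m = m + ("sigma",)
        return m


def assign_nss_subgroups(nss: pd.DataFrame) -> dict[str, str]:
    """Split patients by NSS change into decreasing/persisting subgroups.

    ``nss`` needs columns subject_id, nss_baseline, nss_followup.  The
    change is baseline minus follow-up; subjects above the sample mean
    change go to ``"decreasing"``, the rest to ``"persisting"``.  Both
    subgroups must be non-empty.
    """
    for col in ("subject_id", "nss_baseline", "nss_followup"):
        if col not in nss.columns:
            raise DataError(f"NSS table lacks column {col!r}")
    missing = nss[nss[["nss_baseline", "nss_followup"]].isna().any(axis=1)]
    if len(missing):
        raise DataError(
            f"missing NSS scores for subjects: {missing['subject_id'].tolist()[:5]}"
        )
    change = nss["nss_baseline"].to_numpy(float) - nss["nss_followup"].to_numpy(float)
    mean_change = change.mean()
    labels = np.where(change > mean_change, "decreasing", "persisting")
    if len(set(labels)) < 2:
        raise DataError(
            "degenerate NSS split: all subjects fall on one side of the mean "
            "change; use an explicit cut point instead"
        )
    return dict(zip(nss["subject_id"].astype(str), labels))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _write_metadata(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _hub_table(net: networks.CovarianceNetwork, d_min: float) -> pd.DataFrame:
    adj = networks.binarize_at_density(net, d_min)
    bc = metrics.betweenness(adj)
    hubs = metrics.identify_hubs(bc, net.region_names)
    return pd.DataFrame(
        {
            "region": net.region_names,
            "density": d_min,
            "betweenness": bc,
            "is_hub": [name in hubs.names for name in net.region_names],
        }
    )


def _global_metric_table(
    net: networks.CovarianceNetwork, d_min: float, cfg: RunConfig
) -> pd.DataFrame:
    profile = networks.build_profile(net, d_min, cfg.d_max, cfg.grid_step)
    rows = []
    for d, adj in zip(profile.density_grid, profile.adjacency):
        gm = metrics.global_metrics(
            adj, float(d), cfg.n_random, cfg.n_swaps_per_edge, seed=cfg.seed
        )
        rows.append((float(d), gm.C, gm.L, gm.C_rand, gm.L_rand, gm.sigma))
    return pd.DataFrame(rows, columns=["density", "C", "L", "C_rand", "L_rand", "sigma"])


def run_cross_sectional(cfg: RunConfig, table: pd.DataFrame | None = None) -> dict:
    """Patients vs controls at baseline: full comparison bundle + report."""
    if table is None:
        table = read_volume_table(cfg.input_table)
    base = table[table["timepoint"] == BASELINE]
    groups = sorted(base["group"].unique())
    if len(groups) != 2:
        raise DataError(f"cross-sectional design needs 2 groups, found {groups}")
    g_a, g_b = groups
    tab_a = base[base["group"] == g_a].reset_index(drop=True)
    tab_b = base[base["group"] == g_b].reset_index(drop=True)
    log.info("cross-sectional: %s (n=%d) vs %s (n=%d)", g_a, len(tab_a), g_b, len(tab_b))

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict[str, comparison.ComparisonResult] = {}
    for measure in cfg.measures() + ("betweenness",):
        log.info("permutation test: %s (%d permutations)", measure, cfg.n_perm)
        res = comparison.compare(
            measure,
            tab_a,
            tab_b,
            covariates=cfg.covariates,
            n_perm=cfg.n_perm,
            seed=cfg.seed,
            grid_step=cfg.grid_step,
            d_max=cfg.d_max,
            n_random=cfg.n_random,
            n_swaps_per_edge=cfg.n_swaps_per_edge,
        )
        results[measure] = res
        _write_tsv(comparison.result_table(res), out / f"compare_{measure}.tsv")

    d_min = results["betweenness"].d_min
    nets = {}
    for label, tab in ((g_a, tab_a), (g_b, tab_b)):
        resid = networks.residualize(tab, cfg.covariates)
        net = networks.correlation_network(resid, group_label=label)
        nets[label] = net
        networks.write_correlation_tsv(net, out / f"corr_{label}.tsv")
        _write_tsv(_hub_table(net, d_min), out / f"hubs_{label}.tsv")
        _write_tsv(
            _global_metric_table(net, d_min, cfg), out / f"global_metrics_{label}.tsv"
        )
    _write_metadata(
        out / "run_metadata.json",
        {
            "design": "cross_sectional",
            "groups": [g_a, g_b],
            "n_subjects": {g_a: len(tab_a), g_b: len(tab_b)},
            "d_min": d_min,
            "config": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in asdict(cfg).items() if k != "output_dir"},
            **results["betweenness"].metadata(),
        },
    )
    return {"results": results, "networks": nets, "d_min": d_min}


def run_longitudinal(
    cfg: RunConfig,
    assignment: dict[str, str],
    table: pd.DataFrame | None = None,
) -> dict:
    """Baseline vs follow-up paired comparison within each subgroup."""
    if table is None:
        table = read_volume_table(cfg.input_table)
    patients = table[table["group"] == "patient"]
    if patients.empty:
        raise DataError("no rows with group == 'patient'")
    unassigned = set(patients["subject_id"].astype(str)) - set(assignment)
    if unassigned:
        raise DataError(f"patients without subgroup assignment: {sorted(unassigned)[:5]}")

    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, dict] = {}
    for subgroup in sorted(set(assignment.values())):
        ids = {s for s, lab in assignment.items() if lab == subgroup}
        sub = patients[patients["subject_id"].astype(str).isin(ids)]
        tab_bl = sub[sub["timepoint"] == BASELINE].reset_index(drop=True)
        tab_fu = sub[sub["timepoint"] == FOLLOWUP].reset_index(drop=True)
        if len(tab_bl) == 0 or len(tab_bl) != len(tab_fu):
            raise DataError(f"subgroup {subgroup!r} lacks complete baseline/follow-up pairs")
        log.info("longitudinal %s: n=%d pairs", subgroup, len(tab_bl))
        sub_results = {}
        for measure in cfg.measures() + ("betweenness",):
            res = comparison.compare(
                measure,
                tab_bl,
                tab_fu,
                covariates=cfg.covariates,
                n_perm=cfg.n_perm,
                paired=True,
                seed=cfg.seed,
                grid_step=cfg.grid_step,
                d_max=cfg.d_max,
                n_random=cfg.n_random,
                n_swaps_per_edge=cfg.n_swaps_per_edge,
            )
            sub_results[measure] = res
            _write_tsv(
                comparison.result_table(res),
                out / f"compare_{subgroup}_{measure}.tsv",
            )
        d_min = sub_results["betweenness"].d_min
        hubs = {}
        for tp, tab in ((BASELINE, tab_bl), (FOLLOWUP, tab_fu)):
            resid = networks.residualize(tab, cfg.covariates)
            net = networks.correlation_network(resid, group_label=f"{subgroup}-{tp}")
            hub_tab = _hub_table(net, d_min)
            hubs[tp] = hub_tab
            _write_tsv(hub_tab, out / f"hubs_{subgroup}_{tp}.tsv")
        side_by_side = hubs[BASELINE][["region"]].copy()
        side_by_side["hub_baseline"] = hubs[BASELINE]["is_hub"]
        side_by_side["hub_followup"] = hubs[FOLLOWUP]["is_hub"]
        _write_tsv(
            side_by_side[side_by_side[["hub_baseline", "hub_followup"]].any(axis=1)],
            out / f"hubs_{subgroup}_side_by_side.tsv",
        )
        bundle[subgroup] = {"results": sub_results, "d_min": d_min, "hubs": hubs}
    _write_metadata(
        out / "run_metadata.json",
        {
            "design": "longitudinal_paired",
            "subgroups": sorted(set(assignment.values())),
            "config": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in asdict(cfg).items() if k != "output_dir"},
            "d_min": {s: bundle[s]["d_min"] for s in bundle},
            "p_convention": "(count+1)/(n_perm+1), two-tailed on |AUC diff|",
        },
    )
    return bundle
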