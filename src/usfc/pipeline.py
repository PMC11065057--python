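"""End-to-end pipeline: simulate / route / build / group / coupling / metrics.

A run consumes an atlas CSV plus per-subject SC/FC matrix files named
``<subject>_sc.tsv`` / ``<subject>_fc.tsv`` (optional ``<subject>_fcmask.tsv``
significance masks) and writes every intermediate artifact under the output
directory:

    routes/<subject>.csv          efficient pathways per subject
    usfc/<subject>_usfc.tsv       per-subject edge-load matrices
    group/...                     group mean/t/q maps, outliers, networks, top edges
    coupling/...                  consistent routes and step-stratified rho table
    metrics/...                   per-subject graph metrics and comparisons
    report.json                   resolved config + per-stage summaries

Outputs carry no timestamps, so identical config + inputs reproduce
byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import coupling as cpl
from . import io as uio
from . import metrics as gmetrics
from . import synthetic as synth
from . import traffic
from .routing import (
    DEFAULT_MAX_STEPS,
    RouteTable,
    SubjectConnectome,
    euclidean_distances,
    route_all_pairs,
)

logger = logging.getLogger("usfc")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""


@dataclass(frozen=True)
class RunConfig:
    """Resolved settings of one pipeline run (all defaults as documented)."""

    atlas: str
    data_dir: str
    out_dir: str
    max_steps: int = DEFAULT_MAX_STEPS
    fc_policy: str = "auto"          # auto -> masked if masks exist, else all_nonzero
    mode: str = "absolute"           # USFC accumulation mode
    alpha: float = 0.05
    consistency_threshold: float = 0.5
    fence_k: float = 1.5
    top_k: int = 10
    normalize: str = "max"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Simulation output
# ---------------------------------------------------------------------------

def write_simulation(
    config: synth.SynthConfig, out_dir: str | Path
) -> tuple[uio.RegionAtlas, list[SubjectConnectome], synth.GroundTruth]:
    """Generate a synthetic cohort and write atlas, matrices and ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    atlas, subjects, truth = synth.generate_dataset(config)
    uio.write_atlas(atlas, out / "atlas.csv")
    for s in subjects:
        uio.write_matrix(s.sc, out / f"{s.subject_id}_sc.tsv")
        uio.write_matrix(s.fc, out / f"{s.subject_id}_fc.tsv")
    uio.write_report(
        {
            "config": asdict(config),
            "backbone_edges": sorted(list(e) for e in truth.backbone_edges),
            "fc_sign_map": {f"{i}-{j}": s for (i, j), s in sorted(truth.fc_sign_map.items())},
            "planted_routes": {
                f"{i}-{j}": list(nodes) for (i, j), nodes in sorted(truth.planted_routes.items())
            },
        },
        out / "ground_truth.json",
    )
    logger.info(
        "simulate: %d regions, %d subjects, %d backbone edges -> %s",
        atlas.n_regions, len(subjects), len(truth.backbone_edges), out,
    )
    return atlas, subjects, truth


# ---------------------------------------------------------------------------
# Input discovery
# ---------------------------------------------------------------------------

def load_cohort(atlas: uio.RegionAtlas, data_dir: str | Path) -> list[SubjectConnectome]:
    """Load all subjects from ``<subject>_sc.tsv`` / ``<subject>_fc.tsv`` pairs."""
    data = Path(data_dir)
    sc_files = sorted(data.glob("*_sc.tsv"))
    if not sc_files:
        raise StageError(f"load: no *_sc.tsv files found in {data}")
    fc_stems = {p.name[: -len("_fc.tsv")] for p in data.glob("*_fc.tsv")}
    subjects = []
    for sc_path in sc_files:
        sid = sc_path.name[: -len("_sc.tsv")]
        fc_path = data / f"{sid}_fc.tsv"
        if not fc_path.exists():
            raise StageError(f"load: subject {sid!r} is missing its FC matrix {fc_path.name}")
        fc_stems.discard(sid)
        mask_path = data / f"{sid}_fcmask.tsv"
        mask = None
        if mask_path.exists():
            df = pd.read_csv(mask_path, sep="\t", index_col=0)
            mask = df.loc[list(atlas.labels), list(atlas.labels)].to_numpy() != 0
        subjects.append(
            SubjectConnectome(
                subject_id=sid,
                sc=uio.read_matrix(sc_path, atlas, "SC"),
                fc=uio.read_matrix(fc_path, atlas, "FC"),
                fc_mask=mask,
            )
        )
    if fc_stems:
        raise StageError(
            f"load: subjects {sorted(fc_stems)} have FC matrices but no SC matrix"
        )
    return subjects


def _resolve_fc_policy(policy: str, subjects: list[SubjectConnectome]) -> str:
    if policy != "auto":
        return policy
    return "masked" if all(s.fc_mask is not None for s in subjects) else "all_nonzero"


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def route_stage(
    subjects: list[SubjectConnectome],
    atlas: uio.RegionAtlas,
    cfg: RunConfig,
    out_dir: Path,
) -> list[RouteTable]:
    out_dir.mkdir(parents=True, exist_ok=True)
    D = euclidean_distances(atlas)
    policy = _resolve_fc_policy(cfg.fc_policy, subjects)
    tables = []
    for s in subjects:
        table = route_all_pairs(s, D, max_steps=cfg.max_steps, fc_policy=policy)
        tables.append(table)
        records = [
            uio.RouteRecord(
                subject_id=s.subject_id,
                source=atlas.labels[r.nodes[0]],
                target=atlas.labels[r.nodes[-1]],
                nodes=tuple(atlas.labels[n] for n in r.nodes),
                n_steps=r.n_steps,
                total_cost=r.total_cost,
                fc=float(s.fc.values[r.pair]),
            )
            for r in (table.routes[p] for p in sorted(table.routes))
        ]
        uio.write_route_table(records, out_dir / f"{s.subject_id}.csv")
        if table.unroutable:
            logger.warning(
                "route: subject %s has %d unroutable pairs",
                s.subject_id, len(table.unroutable),
            )
    logger.info(
        "route: policy=%s, max_steps=%d, routed %s pairs per subject",
        policy, cfg.max_steps, [t.n_routed for t in tables],
    )
    return tables


def build_stage(
    subjects: list[SubjectConnectome],
    tables: list[RouteTable],
    cfg: RunConfig,
    out_dir: Path,
) -> list[traffic.USFCMatrix]:
    out_dir.mkdir(parents=True, exist_ok=True)
    usfc_list = []
    for s, table in zip(subjects, tables):
        u = traffic.accumulate_usfc(table, s.fc, mode=cfg.mode)
        usfc_list.append(u)
        uio.write_raw_matrix(u.values, u.labels, out_dir / f"{s.subject_id}_usfc.tsv")
    logger.info("build: %d per-subject USFC matrices (%s mode)", len(usfc_list), cfg.mode)
    return usfc_list


def group_stage(
    usfc_list: list[traffic.USFCMatrix],
    atlas: uio.RegionAtlas,
    cfg: RunConfig,
    out_dir: Path,
) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    group = traffic.group_usfc(usfc_list, alpha=cfg.alpha)
    uio.write_raw_matrix(group.mean, group.labels, out_dir / "group_mean.tsv")
    uio.write_raw_matrix(group.mean_masked, group.labels, out_dir / "group_mean_masked.tsv")
    uio.write_raw_matrix(group.t_stat, group.labels, out_dir / "group_t.tsv")
    uio.write_raw_matrix(group.q_value, group.labels, out_dir / "group_q.tsv")

    loads = traffic.regional_load(group.mean_masked)
    pd.DataFrame({"label": atlas.labels, "network": atlas.networks, "load": loads}).to_csv(
        out_dir / "regional_load.csv", index=False
    )
    outliers = traffic.iqr_outliers(loads, k=cfg.fence_k, labels=atlas.labels)
    uio.write_report(
        {
            "q1": outliers.q1, "q3": outliers.q3, "iqr": outliers.iqr,
            "upper_fence": outliers.upper_fence,
            "outlier_regions": list(outliers.outlier_regions),
        },
        out_dir / "outliers.json",
    )
    nets = traffic.network_summary(usfc_list, atlas, alpha=cfg.alpha)
    pd.DataFrame(
        {"network": nets.networks, "mean_load": nets.means, "sd_load": nets.sds}
    ).to_csv(out_dir / "network_summary.csv", index=False)
    if nets.q_matrix is not None:
        uio.write_raw_matrix(nets.q_matrix * (1 - np.eye(len(nets.networks))),
                             nets.networks, out_dir / "network_q.tsv")
    top = traffic.top_k_edges(group, k=cfg.top_k)
    pd.DataFrame(top, columns=["region_a", "region_b", "mean_usfc"]).to_csv(
        out_dir / "top_edges.csv", index=False
    )
    logger.info(
        "group: %d significant edges, %d outlier regions, top network %s",
        int(group.sig_mask.sum() // 2), len(outliers.outlier_regions), nets.ranking[0],
    )
    return {"group": group, "outliers": outliers, "networks": nets, "top_edges": top}


def coupling_stage(
    tables: list[RouteTable],
    subjects: list[SubjectConnectome],
    atlas: uio.RegionAtlas,
    cfg: RunConfig,
    out_dir: Path,
) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    consistent = cpl.modal_routes(tables, subjects, threshold=cfg.consistency_threshold)
    rows = [
        {
            "source": atlas.labels[r.pair[0]],
            "target": atlas.labels[r.pair[1]],
            "route": "-".join(atlas.labels[n] for n in r.modal_nodes),
            "n_steps": r.n_steps,
            "support": r.support,
            "group_fc": r.group_fc,
            "group_mean_sc": r.group_mean_sc,
        }
        for r in consistent
    ]
    pd.DataFrame(
        rows,
        columns=["source", "target", "route", "n_steps", "support", "group_fc", "group_mean_sc"],
    ).to_csv(out_dir / "consistent_routes.csv", index=False)

    result = cpl.coupling_by_step(consistent, max_steps=cfg.max_steps)
    coup_rows = []
    for (step, sign), cell in sorted(result.cells.items()):
        coup_rows.append(
            {"n_steps": step, "fc_sign": sign, "n_routes": cell.n_routes,
             "spearman_rho": cell.rho, "p_value": cell.p_value}
        )
        members = [
            r for r in consistent
            if r.n_steps == step and r.group_fc != 0 and (r.group_fc > 0) == (sign == "+")
        ]
        tag = "pos" if sign == "+" else "neg"
        pd.DataFrame(
            {
                "group_mean_sc": [r.group_mean_sc for r in members],
                "group_fc": [r.group_fc for r in members],
            }
        ).to_csv(out_dir / f"scatter_step{step}_{tag}.csv", index=False)
    pd.DataFrame(coup_rows).to_csv(out_dir / "coupling.csv", index=False)
    logger.info(
        "coupling: %d consistent routes, counts %s",
        len(consistent), {f"{k[0]}{k[1]}": v for k, v in sorted(result.counts().items())},
    )
    return {"consistent": consistent, "result": result}


def metrics_stage(
    subjects: list[SubjectConnectome],
    usfc_list: list[traffic.USFCMatrix],
    cfg: RunConfig,
    out_dir: Path,
) -> gmetrics.MetricsComparison:
    out_dir.mkdir(parents=True, exist_ok=True)
    comp = gmetrics.compare_metrics(subjects, usfc_list, normalize=cfg.normalize, alpha=cfg.alpha)
    rows = []
    for ctype in comp.types:
        for metric in gmetrics.GLOBAL_METRICS:
            for s, v in zip(subjects, comp.global_values[ctype][metric]):
                rows.append(
                    {"subject_id": s.subject_id, "type": ctype, "metric": metric, "value": v}
                )
    pd.DataFrame(rows).to_csv(out_dir / "global_metrics.csv", index=False)
    uio.write_report(
        {
            "normalize": comp.normalize,
            "global_tests": {
                f"{a}_vs_{b}": {m: {"t": t, "p": p} for m, (t, p) in tests.items()}
                for (a, b), tests in comp.global_tests.items()
            },
            "nodal_significant_counts": {
                f"{a}_vs_{b}": {m: int((q <= cfg.alpha).sum()) for m, q in qd.items()}
                for (a, b), qd in comp.nodal_q.items()
            },
        },
        out_dir / "comparison.json",
    )
    logger.info("metrics: computed for %s with normalize=%s", comp.types, cfg.normalize)
    return comp


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig) -> dict:
    """Execute route -> build -> group -> coupling -> metrics; return results.

    Any stage failure raises :class:`StageError` naming the stage; artifacts
    written before the failure are retained in the output directory.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    summaries: dict = {}

    def _stage(name, fn):
        try:
            return fn()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(f"{name}: {exc}") from exc

    atlas = _stage("load", lambda: uio.read_atlas(cfg.atlas))
    subjects = _stage("load", lambda: load_cohort(atlas, cfg.data_dir))
    summaries["load"] = {"n_regions": atlas.n_regions, "n_subjects": len(subjects)}

    tables = _stage("route", lambda: route_stage(subjects, atlas, cfg, out / "routes"))
    summaries["route"] = {
        "fc_policy": _resolve_fc_policy(cfg.fc_policy, subjects),
        "routed": [t.n_routed for t in tables],
        "unroutable": [len(t.unroutable) for t in tables],
    }

    usfc_list = _stage("build", lambda: build_stage(subjects, tables, cfg, out / "usfc"))
    results["usfc_list"] = usfc_list
    summaries["build"] = {
        "mode": cfg.mode,
        "total_load": [float(u.values.sum() / 2) for u in usfc_list],
    }

    grp = _stage("group", lambda: group_stage(usfc_list, atlas, cfg, out / "group"))
    results.update(grp)
    summaries["group"] = {
        "n_significant_edges": int(grp["group"].sig_mask.sum() // 2),
        "n_outliers": len(grp["outliers"].outlier_regions),
        "network_ranking": list(grp["networks"].ranking),
        "top_edges": [[a, b, v] for a, b, v in grp["top_edges"]],
    }

    coup = _stage(
        "coupling", lambda: coupling_stage(tables, subjects, atlas, cfg, out / "coupling")
    )
    results.update(coup)
    summaries["coupling"] = {
        "n_consistent": coup["result"].n_consistent,
        "cells": {
            f"step{k[0]}_{'pos' if k[1] == '+' else 'neg'}": {
                "n": c.n_routes, "rho": c.rho, "p": c.p_value
            }
            for k, c in sorted(coup["result"].cells.items())
        },
    }

    comp = _stage(
        "metrics", lambda: metrics_stage(subjects, usfc_list, cfg, out / "metrics")
    )
    results["metrics"] = comp
    summaries["metrics"] = {
        "global_tests": {
            f"{a}_vs_{b}": {m: list(tp) for m, tp in tests.items()}
            for (a, b), tests in comp.global_tests.items()
        }
    }

    report = {"config": cfg.to_dict(), "seed": cfg.seed, "stages": summaries}
    uio.write_report(report, out / "report.json")
    results["atlas"] = atlas
    results["subjects"] = subjects
    results["tables"] = tables
    results["report"] = report
    return results
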