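"""End-to-end analysis: load or simulate the two scenario webs, compute
empirical metrics, build null ensembles, compare, and write a report.

Randomness policy: the single global ``seed`` is expanded into independent
per-stage streams with ``numpy.random.SeedSequence([seed, stage_tag])``,
so any stage can be rerun in isolation and reproduces bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .compare import ComparisonReport, QSSComparison, chi_squared_qss, compare_ensembles
from .foodweb import FoodWeb, read_edge_list, write_edge_list
from .metrics import (
    MetricSet,
    degree_table,
    mean_trophic_level,
    omnivory,
    tl_class_fractions,
    trophic_levels,
)
from .modularity import FAST_SCHEDULE, AnnealingSchedule, find_best_partition
from .nullmodels import null_distribution
from .stability import qss
from .synthetic import sjg_like_scenario_pair

__all__ = ["run", "load_config", "DEFAULT_CONFIG", "scenario_metrics"]

log = logging.getLogger("trophicstab")

DEFAULT_CONFIG: dict = {
    "webs": {"synthetic": {"seed": 1, "s": 80, "c": 0.0625}},
    "n_null": 1000,
    "n_qss": 10000,
    "seed": 42,
    "weightings": ["unweighted", "weighted"],
    "epsilon": 1.0,
    "trades_per_node": 5,
    "annealing": "fast",
    "out_dir": None,
}

_STAGE_TAGS = {"nulls": 1, "qss": 2, "modularity": 3}


def stage_seed(seed: int, stage: str, index: int = 0) -> int:
    """Derive a per-stage substream seed (< 2**31) from the global seed."""
    ss = np.random.SeedSequence([seed, _STAGE_TAGS.get(stage, 0), index])
    return int(ss.generate_state(1)[0] % (2**31))


def load_config(path_or_dict) -> dict:
    """Read and validate a run configuration (YAML file or dict).

    Unknown keys are errors — a typo in a config silently changing nothing
    is worse than a crash.
    """
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict)
    unknown = set(raw) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = {**DEFAULT_CONFIG, **raw}
    for key in ("n_null", "n_qss", "seed", "trades_per_node"):
        cfg[key] = int(cfg[key])
    if not set(cfg["weightings"]) <= {"unweighted", "weighted"}:
        raise ValueError("weightings must be a subset of {unweighted, weighted}")
    return cfg


def _load_webs(cfg: dict) -> tuple[FoodWeb, FoodWeb]:
    webs = cfg["webs"]
    if "synthetic" in webs:
        syn = dict(webs["synthetic"])
        return sjg_like_scenario_pair(**syn)
    nonfishing = read_edge_list(
        webs["nonfishing"], webs.get("nonfishing_nodes"), name="non-fishing"
    )
    fishing = read_edge_list(webs["fishing"], webs.get("fishing_nodes"), name="fishing")
    return nonfishing, fishing


def _schedule(cfg: dict) -> AnnealingSchedule:
    return FAST_SCHEDULE if cfg["annealing"] == "fast" else AnnealingSchedule()


def scenario_metrics(
    web: FoodWeb,
    weighted: bool,
    epsilon: float = 1.0,
    n_qss: int = 10000,
    seed: int = 42,
    schedule: AnnealingSchedule | None = None,
) -> MetricSet:
    """Empirical (non-null) metric values of one web under one weighting."""
    tls = trophic_levels(web, weighted=weighted)
    mod = find_best_partition(
        web,
        weighted=weighted,
        schedule=schedule or FAST_SCHEDULE,
        seed=stage_seed(seed, "modularity"),
    )
    stability = qss(web, n=n_qss, weighted=weighted, seed=stage_seed(seed, "qss"))
    top, mid, basal = tl_class_fractions(web)
    return MetricSet(
        mTL=mean_trophic_level(tls),
        omnivory=omnivory(web, tls, weighted=weighted, epsilon=epsilon),
        modularity=mod.q,
        qss=stability.proportion_stable,
        weighted=weighted,
        extras={
            "max_TL": tls.max_tl,
            "n_nodes": web.n_nodes,
            "n_links": web.n_links,
            "tl_top_pct": top,
            "tl_intermediate_pct": mid,
            "tl_basal_pct": basal,
            "qss_n_stable": stability.n_stable,
            "qss_se": stability.se,
        },
    )


def run(config, out_dir: str | Path | None = None) -> ComparisonReport:
    """Execute the full two-scenario analysis described by ``config``.

    Writes (when an output directory is configured) per-web metrics JSON,
    one CSV per metric x weighting null ensemble, ``report.json`` /
    ``report.csv`` shaped like the scenario-comparison table plus the QSS
    rows, and a run log with versions, seeds and recipes.  Identical
    configs produce bit-identical reports.
    """
    cfg = load_config(config)
    out = Path(out_dir or cfg["out_dir"]) if (out_dir or cfg["out_dir"]) else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()

    nonfishing, fishing = _load_webs(cfg)
    log.info("webs: %s, %s", nonfishing, fishing)
    if out:
        write_edge_list(nonfishing, out / "nonfishing.csv", out / "nonfishing_nodes.csv")
        write_edge_list(fishing, out / "fishing.csv", out / "fishing_nodes.csv")

    schedule = _schedule(cfg)
    report = ComparisonReport(
        meta={
            "version": __version__,
            "config": {k: v for k, v in cfg.items() if k != "out_dir"},
        }
    )

    for weighting in cfg["weightings"]:
        weighted = weighting == "weighted"
        for web in (nonfishing, fishing):
            mset = scenario_metrics(
                web,
                weighted,
                epsilon=cfg["epsilon"],
                n_qss=cfg["n_qss"],
                seed=cfg["seed"],
                schedule=schedule,
            )
            if out:
                path = out / f"metrics_{web.name}_{weighting}.json"
                path.write_text(json.dumps(mset.as_dict(), indent=2))
                _write_tl_degree_tables(web, weighted, out, weighting)

        for metric in ("mTL", "omnivory", "modularity"):
            ensembles = []
            for i, web in enumerate((nonfishing, fishing)):
                ens = null_distribution(
                    web,
                    metric,
                    n=cfg["n_null"],
                    weighted=weighted,
                    seed=stage_seed(cfg["seed"], "nulls", index=i),
                    trades_per_node=cfg["trades_per_node"],
                    epsilon=cfg["epsilon"],
                    schedule=schedule,
                )
                ensembles.append(ens)
                if out:
                    _write_ensemble(ens, out / f"null_{metric}_{web.name}_{weighting}.csv")
            report.rows.append(compare_ensembles(*ensembles))
            log.info(
                "%s (%s): medians %.4f vs %.4f",
                metric,
                weighting,
                report.rows[-1].median_nonfishing,
                report.rows[-1].median_fishing,
            )

        qss_a = qss(
            nonfishing, n=cfg["n_qss"], weighted=weighted,
            seed=stage_seed(cfg["seed"], "qss", index=0),
        )
        qss_b = qss(
            fishing, n=cfg["n_qss"], weighted=weighted,
            seed=stage_seed(cfg["seed"], "qss", index=1),
        )
        chi2, p = chi_squared_qss(qss_a, qss_b)
        report.qss_rows.append(
            QSSComparison(
                weighted=weighted,
                prop_nonfishing=qss_a.proportion_stable,
                prop_fishing=qss_b.proportion_stable,
                chi2=chi2,
                p=p,
            )
        )

    report.meta["runtime_s"] = round(time.time() - t_start, 2)
    if out:
        (out / "report.json").write_text(json.dumps(report.as_dict(), indent=2))
        report.to_dataframe().to_csv(out / "report.csv", index=False)
        (out / "run_log.json").write_text(
            json.dumps(report.meta, indent=2, default=str)
        )
    return report


def _write_ensemble(ens, path: Path) -> None:
    header = json.dumps(ens.recipe, sort_keys=True)
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        fh.write("value\n")
        for v in ens.values:
            fh.write(f"{v:.12g}\n")


def _write_tl_degree_tables(web: FoodWeb, weighted: bool, out: Path, tag: str) -> None:
    import pandas as pd

    tls = trophic_levels(web, weighted=weighted)
    deg = degree_table(web)
    df = pd.DataFrame(
        {
            "id": list(deg),
            "degree": list(deg.values()),
            "TL": [tls.tl[i] for i in deg],
        }
    )
    df.to_csv(out / f"tl_degree_{web.name}_{tag}.csv", index=False)
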