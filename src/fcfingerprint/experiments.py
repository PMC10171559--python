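"""Experiment designs: train/test splits, grid search, stability, scan length.

All designs share one evaluation cell: fit an extractor on the
training sessions, score the training output with a train-learned
overlap threshold, then score the test output at that fixed threshold.
Parameter selection always maximizes the *training*-phase ratio of
Idiff to Overlap; test-phase values are never consulted for selection,
and no information flows from test columns into any fitted model or
threshold.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortError, CohortMatrix, RoiTimeSeries
from .connectivity import assemble_cohort, scan_to_fc_vector, truncate_scan
from .extractors import BaseExtractor, make_extractor
from .metrics import IdentifiabilityReport, evaluate_test, evaluate_train

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_GRIDS",
    "SplitPlan",
    "GridResult",
    "enumerate_splits",
    "split_cohort",
    "evaluate_extractor",
    "grid_search",
    "stability_experiment",
    "scan_length_experiment",
    "run_pipeline",
    "ConfigError",
]


class ConfigError(ValueError):
    """Invalid experiment configuration (raised before any computation)."""


#: reference hyper-parameter grids for a 10-session cohort (5 training
#: sessions): number of principal components, dictionary size k and l1
#: weight for the robust-PCA dictionary, K-SVD atoms/sparsity, COBE
#: common-component count. Scale down for smaller cohorts (the
#: constraints m <= rank, k <= columns and C <= training sessions bind
#: first).
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "pca": [{"n_components": m} for m in range(1, 190, 5)],
    "rpca": [
        {"k": k, "lam": round(lam, 2)}
        for k in range(25, 71, 5)
        for lam in np.arange(0.1, 0.51, 0.05)
    ],
    "ksvd": [
        {"k": k, "s0": s0}
        for k in range(2, 9)
        for s0 in range(2, 9)
        if s0 <= k
    ],
    "cobe": [{"n_components": c} for c in range(2, 6)],
}


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/test session subsets covering all sessions."""

    train_sessions: tuple
    test_sessions: tuple
    plan_id: str = ""

    def __post_init__(self) -> None:
        train, test = set(self.train_sessions), set(self.test_sessions)
        if not train or not test:
            raise ConfigError("both train and test must be non-empty")
        if train & test:
            raise ConfigError(
                f"train and test sessions overlap: {sorted(train & test)}"
            )


def enumerate_splits(sessions: int | Sequence, k: int) -> list[SplitPlan]:
    """All C(s, k) ways of choosing k training sessions out of s.

    ``sessions`` may be a session-id sequence or an integer count (in
    which case positional indices 0..s-1 are used). Plans come in a
    deterministic lexicographic order.
    """
    ids = tuple(range(sessions)) if isinstance(sessions, int) else tuple(sessions)
    s = len(ids)
    if not 0 < k < s:
        raise ConfigError(f"need 0 < k < s, got k={k}, s={s}")
    plans = []
    for i, train in enumerate(itertools.combinations(ids, k)):
        test = tuple(x for x in ids if x not in train)
        plans.append(
            SplitPlan(train_sessions=train, test_sessions=test, plan_id=f"plan{i:04d}")
        )
    assert len(plans) == comb(s, k)
    return plans


def _resolve_sessions(cohort: CohortMatrix, wanted: Sequence) -> list[str]:
    """Map plan entries (session ids or positional ints) onto cohort sessions."""
    sessions = cohort.sessions
    out = []
    for w in wanted:
        if isinstance(w, (int, np.integer)):
            if not 0 <= w < len(sessions):
                raise CohortError(f"session position {w} out of range")
            out.append(sessions[w])
        else:
            if str(w) not in sessions:
                raise CohortError(f"unknown session {w!r}")
            out.append(str(w))
    return out


def split_cohort(
    cohort: CohortMatrix, plan: SplitPlan
) -> tuple[CohortMatrix, CohortMatrix]:
    """Column-subset the cohort into train and test halves."""
    train_ids = _resolve_sessions(cohort, plan.train_sessions)
    test_ids = _resolve_sessions(cohort, plan.test_sessions)
    if set(train_ids) | set(test_ids) != set(cohort.sessions):
        raise CohortError("plan does not cover all sessions of the cohort")
    return cohort.select_sessions(train_ids), cohort.select_sessions(test_ids)


def evaluate_extractor(
    extractor: BaseExtractor,
    train: CohortMatrix,
    test: CohortMatrix,
) -> tuple[IdentifiabilityReport, IdentifiabilityReport]:
    """Fit on train, score train (learn threshold), score test (reuse it)."""
    extractor.fit(train)
    train_report = evaluate_train(extractor.transform(train))
    test_report = evaluate_test(extractor.transform(test), train_report.threshold)
    return train_report, test_report


@dataclass
class GridResult:
    params: dict
    train: IdentifiabilityReport | None
    test: IdentifiabilityReport | None
    selected: bool = False
    error: str | None = None


def _param_sort_key(params: dict) -> tuple:
    return tuple(params[k] for k in sorted(params))


def grid_search(
    cohort: CohortMatrix,
    algorithm: str,
    grid: Sequence[dict],
    plan: SplitPlan | None = None,
    normalization: str | None = None,
) -> list[GridResult]:
    """Evaluate every grid point; select the max training-phase ratio.

    Ties are broken toward the smallest parameter values. Per-point fit
    failures are recorded and the grid continues. ``normalization`` is
    bookkeeping only (defaults to the cohort's own tag); normalization
    itself happens at the FC-matrix stage, upstream of the cohort.
    """
    if not grid:
        raise ConfigError("empty parameter grid")
    if plan is None:
        s = cohort.s
        plan = SplitPlan(
            train_sessions=cohort.sessions[: s // 2 + s % 2],
            test_sessions=cohort.sessions[s // 2 + s % 2 :],
        )
    train, test = split_cohort(cohort, plan)
    results: list[GridResult] = []
    for params in sorted(grid, key=_param_sort_key):
        try:
            ex = make_extractor(algorithm, **params)
            tr, te = evaluate_extractor(ex, train, test)
            results.append(GridResult(params=dict(params), train=tr, test=te))
        except Exception as exc:  # recorded, grid continues
            logger.warning("grid point %s failed: %s", params, exc)
            results.append(
                GridResult(params=dict(params), train=None, test=None, error=str(exc))
            )
    scored = [r for r in results if r.train is not None]
    if scored:
        best = max(scored, key=lambda r: r.train.ratio)  # first max = smallest params
        best.selected = True
    return results


def grid_results_table(results: list[GridResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {f"param_{k}": v for k, v in r.params.items()}
        row["selected"] = r.selected
        row["error"] = r.error or ""
        for phase, rep in (("train", r.train), ("test", r.test)):
            if rep is not None:
                for k, v in rep.as_dict().items():
                    if k != "phase":
                        row[f"{phase}_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def stability_experiment(
    cohort: CohortMatrix,
    algorithm: str,
    params: dict,
    plans: Sequence[SplitPlan],
) -> tuple[pd.DataFrame, dict]:
    """Re-run one (algorithm, params) cell over many split plans.

    Returns the per-plan train/test ratio table and a dispersion
    summary (standard deviation, min, max per phase).
    """
    if len(plans) < 2:
        raise ConfigError("stability needs at least 2 split plans")
    rows = []
    for plan in plans:
        try:
            train, test = split_cohort(cohort, plan)
            tr, te = evaluate_extractor(make_extractor(algorithm, **params), train, test)
            rows.append(
                {
                    "plan_id": plan.plan_id,
                    "train_sessions": ",".join(map(str, plan.train_sessions)),
                    "train_ratio": tr.ratio,
                    "test_ratio": te.ratio,
                    "train_idiff": tr.idiff,
                    "test_idiff": te.idiff,
                    "train_overlap": tr.overlap,
                    "test_overlap": te.overlap,
                }
            )
        except Exception as exc:
            logger.warning("plan %s failed: %s", plan.plan_id, exc)
    table = pd.DataFrame(rows)
    summary = {}
    for phase in ("train", "test"):
        vals = table[f"{phase}_ratio"].to_numpy()
        summary[phase] = {
            "std": float(np.std(vals, ddof=1)),
            "min": float(np.min(vals)),
            "max": float(np.max(vals)),
            "mean": float(np.mean(vals)),
        }
    return table, summary


def scan_length_experiment(
    scans: Sequence[RoiTimeSeries],
    durations_min: Sequence[float],
    network: str | None = None,
    normalization: str = "none",
    algorithm: str = "none",
    params: dict | None = None,
    plan: SplitPlan | None = None,
) -> pd.DataFrame:
    """Ratio of Idiff to Overlap as a function of scan duration.

    For each duration (minutes): truncate every scan, recompute FC,
    normalize, assemble, split, extract and score. Durations are
    reported sorted ascending regardless of input order; a duration
    exceeding the scan length yields an error row and the table
    continues.
    """
    params = params or {}
    rows = []
    for minutes in sorted(durations_min):
        try:
            vectors = [
                (
                    ts.subject_id,
                    ts.session_id,
                    scan_to_fc_vector(
                        truncate_scan(ts, minutes), network, normalization
                    ),
                )
                for ts in scans
            ]
            cohort = assemble_cohort(
                vectors,
                network=network or "all",
                normalization=normalization if normalization != "none" else "raw",
            )
            use_plan = plan
            if use_plan is None:
                s = cohort.s
                use_plan = SplitPlan(
                    train_sessions=cohort.sessions[: s // 2 + s % 2],
                    test_sessions=cohort.sessions[s // 2 + s % 2 :],
                )
            train, test = split_cohort(cohort, use_plan)
            tr, te = evaluate_extractor(
                make_extractor(algorithm, **params), train, test
            )
            rows.append(
                {
                    "duration_min": minutes,
                    "train_ratio": tr.ratio,
                    "test_ratio": te.ratio,
                    "train_idiff": tr.idiff,
                    "test_idiff": te.idiff,
                    "train_overlap": tr.overlap,
                    "test_overlap": te.overlap,
                    "error": "",
                }
            )
        except Exception as exc:
            logger.warning("duration %s min failed: %s", minutes, exc)
            rows.append({"duration_min": minutes, "error": str(exc)})
    return pd.DataFrame(rows)


# -- end-to-end pipeline ----------------------------------------------

_REQUIRED_KEYS = {"mode", "algorithm", "normalization", "outdir"}


def _validate_config(config: dict) -> None:
    missing = _REQUIRED_KEYS - set(config)
    if missing:
        raise ConfigError(f"config is missing keys: {sorted(missing)}")
    if config["mode"] not in ("fc", "timeseries", "files"):
        raise ConfigError("mode must be 'fc', 'timeseries' or 'files'")
    if config["normalization"] not in ("none", "fisher_z", "degree"):
        raise ConfigError(
            "normalization must be one of none, fisher_z, degree"
        )
    from .extractors import EXTRACTORS

    if config["algorithm"] not in EXTRACTORS:
        raise ConfigError(f"unknown algorithm {config['algorithm']!r}")
    if config["mode"] in ("fc", "timeseries") and "cohort" not in config:
        raise ConfigError("synthetic modes need a 'cohort' section")
    if config["mode"] == "files":
        if "data_dir" not in config or "labels" not in config:
            raise ConfigError("files mode needs 'data_dir' and 'labels' paths")
    if config["mode"] == "fc" and config["normalization"] != "none":
        raise ConfigError(
            "matrix-stage normalization needs time-series input; "
            "FC-vector cohorts are generated directly in vector space"
        )


def config_hash(config: dict) -> str:
    return hashlib.sha1(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _build_cohort(config: dict) -> CohortMatrix:
    from .io import read_labels, read_timeseries
    from .synthetic import SyntheticSpec, generate_fc_cohort, generate_timeseries_cohort

    mode = config["mode"]
    network = config.get("network")
    normalization = config["normalization"]
    if mode == "fc":
        spec = SyntheticSpec(seed=config.get("seed", 0), **config["cohort"])
        return generate_fc_cohort(spec)
    if mode == "timeseries":
        spec = SyntheticSpec(seed=config.get("seed", 0), **config["cohort"])
        scans = generate_timeseries_cohort(spec)
    else:
        labels = read_labels(config["labels"])
        paths = sorted(Path(config["data_dir"]).glob("*.tsv"))
        if not paths:
            raise ConfigError(f"no .tsv scans under {config['data_dir']}")
        scans = [read_timeseries(p, labels) for p in paths]
    vectors = [
        (
            ts.subject_id,
            ts.session_id,
            scan_to_fc_vector(ts, network, normalization),
        )
        for ts in scans
    ]
    return assemble_cohort(
        vectors,
        network=network or "all",
        normalization=normalization if normalization != "none" else "raw",
    )


def run_pipeline(config: dict) -> dict:
    """Execute simulate/ingest -> FC -> normalize -> split -> fit -> score.

    Writes ``report.tsv``, the fitted model and a resolved-config JSON
    into ``outdir``; rerunning with an identical config overwrites the
    same files identically. Returns a summary dict with the report
    rows and output paths. Per-stage wall times go to the log.
    """
    from .extractors import save_model
    from .io import write_report_table

    _validate_config(config)
    chash = config_hash(config)
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)

    timings: dict[str, float] = {}
    tic = time.perf_counter()
    cohort = _build_cohort(config)
    timings["build_cohort"] = time.perf_counter() - tic

    split_cfg = config.get("split", {})
    if "train_sessions" in split_cfg:
        train_ids = [str(x) for x in split_cfg["train_sessions"]]
        test_ids = [s for s in cohort.sessions if s not in train_ids]
        plan = SplitPlan(tuple(train_ids), tuple(test_ids))
    else:
        k = int(split_cfg.get("k", cohort.s // 2 + cohort.s % 2))
        plan = SplitPlan(cohort.sessions[:k], cohort.sessions[k:])
    train, test = split_cohort(cohort, plan)

    tic = time.perf_counter()
    extractor = make_extractor(config["algorithm"], **config.get("params", {}))
    extractor.fit(train)
    timings["fit"] = time.perf_counter() - tic

    tic = time.perf_counter()
    train_report = evaluate_train(extractor.transform(train))
    test_report = evaluate_test(extractor.transform(test), train_report.threshold)
    timings["score"] = time.perf_counter() - tic

    for stage, seconds in timings.items():
        logger.info("stage %-14s %8.3f s", stage, seconds)

    rows = []
    for rep in (train_report, test_report):
        row = {
            "network": cohort.network,
            "normalization": config["normalization"],
            "algorithm": config["algorithm"],
            "params": json.dumps(config.get("params", {}), sort_keys=True),
            "config_hash": chash,
        }
        row.update(rep.as_dict())
        rows.append(row)
    report_path = outdir / "report.tsv"
    write_report_table(rows, report_path)
    model_path = outdir / "model"
    save_model(extractor, model_path, threshold=train_report.threshold)
    (outdir / "config.json").write_text(
        json.dumps({"config": config, "hash": chash}, indent=2, default=str)
    )
    return {
        "report": rows,
        "report_path": str(report_path),
        "model_path": str(model_path),
        "config_hash": chash,
        "timings": timings,
    }
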