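"""Delimited-text readers and writers.

All on-disk artifacts are plain TSV:

* cohort matrix — one scan per column, header ``subject_session``,
  plus a two-column sidecar index (``<stem>.index.tsv``) that is the
  authoritative subject/session mapping;
* ROI time series — one file per scan (T rows x n columns, header =
  node ids) with ``# key=value`` metadata comment lines;
* node labels — ``node_id<TAB>network_name``;
* reports — tidy tables, one row per scored cell.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import CohortError, CohortMatrix, RoiTimeSeries

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_timeseries",
    "read_timeseries",
    "write_labels",
    "read_labels",
    "write_report_table",
]


def write_cohort(cohort: CohortMatrix, path: str | Path) -> None:
    path = Path(path)
    header = [f"{sub}_{ses}" for sub, ses in cohort.index]
    df = pd.DataFrame(cohort.values, columns=header)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    idx = pd.DataFrame(cohort.index, columns=["subject", "session"])
    idx.insert(0, "column", header)
    idx["network"] = cohort.network
    idx["normalization"] = cohort.normalization
    idx.to_csv(_index_path(path), sep="\t", index=False)


def _index_path(path: Path) -> Path:
    return path.with_suffix(".index.tsv")


def read_cohort(path: str | Path) -> CohortMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    idx_path = _index_path(path)
    if idx_path.exists():
        idx = pd.read_csv(idx_path, sep="\t", dtype=str)
        index = tuple(zip(idx["subject"], idx["session"]))
        network = idx["network"].iloc[0] if "network" in idx else "all"
        normalization = (
            idx["normalization"].iloc[0] if "normalization" in idx else "raw"
        )
    else:  # fall back to parsing the header on the last underscore
        pairs = [c.rsplit("_", 1) for c in df.columns]
        if any(len(p) != 2 for p in pairs):
            raise CohortError(
                f"no sidecar index at {idx_path} and header of {path} is "
                "not of the form subject_session"
            )
        index = tuple((a, b) for a, b in pairs)
        network, normalization = "all", "raw"
    return CohortMatrix(
        values=df.to_numpy(dtype=float),
        index=index,
        network=network,
        normalization=normalization,
    )


def write_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# subject={ts.subject_id}\n")
        fh.write(f"# session={ts.session_id}\n")
        fh.write(f"# dt={ts.dt}\n")
        fh.write("\t".join(ts.node_ids) + "\n")
        np.savetxt(fh, ts.data, delimiter="\t", fmt="%.10g")


def read_timeseries(path: str | Path, labels: dict[str, str]) -> RoiTimeSeries:
    """Read one scan; ``labels`` maps node id to network name."""
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = value.strip()
            pos = fh.tell()
            line = fh.readline()
        node_ids = line.strip().split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    missing = [n for n in node_ids if n not in labels]
    if missing:
        raise CohortError(f"nodes {missing} missing from the labels file")
    return RoiTimeSeries(
        data=data,
        subject_id=meta.get("subject", path.stem.split("_")[0]),
        session_id=meta.get("session", path.stem.split("_")[-1]),
        dt=float(meta.get("dt", 2.0)),
        labels=tuple(labels[n] for n in node_ids),
        node_ids=tuple(node_ids),
    )


def write_labels(
    node_ids: Sequence[str], networks: Sequence[str], path: str | Path
) -> None:
    if len(node_ids) != len(networks):
        raise CohortError("node_ids and networks differ in length")
    with open(path, "w") as fh:
        for node, net in zip(node_ids, networks):
            fh.write(f"{node}\t{net}\n")


def read_labels(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise CohortError(
                f"malformed labels line {line!r}; expected node<TAB>network"
            )
        out[parts[0]] = parts[1]
    if not out:
        raise CohortError(f"labels file {path} is empty")
    return out


def write_report_table(rows: list[dict], path: str | Path) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df.to_csv(Path(path), sep="\t", index=False, float_format="%.6g")
    return df
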