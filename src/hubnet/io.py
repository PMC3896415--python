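"""Plain-text readers and writers for the pipeline's tabular artefacts.

Everything is TSV with a labelled header; time-series files carry a single
``#``-prefixed comment line recording the sampling interval and whether the
series has been conditioned.  Every writer has a matching reader that
round-trips the object.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import SyntheticSubject
from .conditioning import RegionalTimeSeries
from .network import ConnectivityMatrix, ThresholdedNetwork

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_motion",
    "read_motion",
    "write_manifest",
    "read_manifest",
    "write_cohort",
    "write_connectivity",
    "read_connectivity",
    "write_edge_list",
    "write_yaml",
    "read_yaml",
]

MOTION_COLUMNS = ["trans_x_mm", "trans_y_mm", "trans_z_mm", "rot_x_deg", "rot_y_deg", "rot_z_deg"]


def write_timeseries(ts: RegionalTimeSeries, path: str | Path) -> Path:
    path = Path(path)
    header = {"subject_id": ts.subject_id, "tr_seconds": ts.tr_seconds, "conditioned": ts.conditioned}
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        pd.DataFrame(ts.data, columns=ts.region_labels).to_csv(fh, sep="\t", index=False)
    return path


def read_timeseries(path: str | Path) -> RegionalTimeSeries:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        meta = json.loads(first.lstrip("# ")) if first.startswith("#") else {}
        frame = pd.read_csv(fh, sep="\t")
    return RegionalTimeSeries(
        subject_id=str(meta.get("subject_id", path.stem)),
        data=frame.to_numpy(dtype=float),
        region_labels=list(frame.columns),
        tr_seconds=float(meta.get("tr_seconds", 2.0)),
        conditioned=bool(meta.get("conditioned", False)),
    )


def write_motion(motion: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(np.atleast_2d(motion), columns=MOTION_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def read_motion(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def write_manifest(subjects: Iterable[SyntheticSubject], path: str | Path) -> Path:
    rows = [(s.subject_id, s.group, s.behavior_score) for s in subjects]
    pd.DataFrame(rows, columns=["subject_id", "group", "behavior_score"]).to_csv(
        path, sep="\t", index=False
    )
    return Path(path)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"subject_id": str})


def write_cohort(subjects: list[SyntheticSubject], out_dir: str | Path) -> Path:
    """Write per-subject time-series and motion TSVs plus a cohort manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for s in subjects:
        ts = RegionalTimeSeries(
            subject_id=s.subject_id,
            data=s.timeseries,
            region_labels=s.region_labels,
            tr_seconds=s.tr_seconds,
        )
        write_timeseries(ts, out / f"{s.subject_id}_timeseries.tsv")
        write_motion(s.motion, out / f"{s.subject_id}_motion.tsv")
        pd.DataFrame(s.nuisance, columns=["ventricle", "white_matter"]).to_csv(
            out / f"{s.subject_id}_nuisance.tsv", sep="\t", index=False
        )
    write_manifest(subjects, out / "manifest.tsv")
    return out


def write_connectivity(cm: ConnectivityMatrix, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# " + json.dumps({"subject_id": cm.subject_id}) + "\n")
        pd.DataFrame(cm.weights, index=cm.region_labels, columns=cm.region_labels).to_csv(
            fh, sep="\t"
        )
    return path


def read_connectivity(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        meta = json.loads(first.lstrip("# ")) if first.startswith("#") else {}
        frame = pd.read_csv(fh, sep="\t", index_col=0)
    return ConnectivityMatrix(
        subject_id=str(meta.get("subject_id", path.stem)),
        weights=frame.to_numpy(dtype=float),
        region_labels=list(frame.columns),
    )


def write_edge_list(net: ThresholdedNetwork, region_labels: list[str], path: str | Path) -> Path:
    rows = []
    for i, j in sorted(net.edges):
        w = 1.0 if net.weights_retained is None else net.weights_retained[(i, j)]
        rows.append((region_labels[i], region_labels[j], w, (i, j) in net.backbone))
    pd.DataFrame(rows, columns=["region_a", "region_b", "weight", "in_backbone"]).to_csv(
        path, sep="\t", index=False
    )
    return Path(path)


def write_yaml(obj: Mapping, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(dict(obj), fh, sort_keys=True)
    return path


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
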