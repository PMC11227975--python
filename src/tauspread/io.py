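"""Readers and writers for the plain-text interchange formats.

All tabular artifacts are CSV/TSV with a header row; square matrices carry
region ids as both header and index so they round-trip losslessly at full
double precision.  The synthetic cohort is written as:

* ``parcellation.tsv`` — region_id, network, hemisphere
* ``tau_scans.csv`` — long format: subject_id, scan_time_years, region_id, suvr
* ``subject_fc/<id>.csv`` — region x frame time-series or region x region
  correlation matrix (distinguished by an ``fc_kind.txt`` marker)
* ``covariates.csv``, ``amyloid.csv`` (subjects x regions),
  ``cognition.csv`` (long)
* ``truth.json`` — planted parameters, kept separate from analysis inputs
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .tau import RegionalScanSeries


def write_matrix_csv(values: np.ndarray, region_ids, path) -> None:
    df = pd.DataFrame(values, index=region_ids, columns=region_ids)
    df.to_csv(path, float_format="%.17g", index_label="region_id")


def read_matrix_csv(path) -> tuple[np.ndarray, list]:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    ids = [_coerce_id(c) for c in df.columns]
    return df.to_numpy(dtype=float), ids


def _coerce_id(value):
    try:
        return int(value)
    except (TypeError, ValueError):
        return value


def write_tau_scans(scans: list[RegionalScanSeries], path) -> None:
    frames = []
    for s in scans:
        for i, t in enumerate(s.times):
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": s.subject_id,
                        "scan_time_years": t,
                        "region_id": s.region_ids,
                        "suvr": s.suvr[i],
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_tau_scans(path) -> list[RegionalScanSeries]:
    df = pd.read_csv(path)
    required = {"subject_id", "scan_time_years", "region_id", "suvr"}
    if not required.issubset(df.columns):
        raise InputError(f"tau scan table must have columns {sorted(required)}")
    out = []
    for sid, g in df.groupby("subject_id", sort=True):
        wide = g.pivot_table(index="scan_time_years", columns="region_id", values="suvr", sort=True)
        out.append(
            RegionalScanSeries(
                subject_id=str(sid),
                times=wide.index.to_numpy(dtype=float),
                suvr=wide.to_numpy(dtype=float),
                region_ids=[_coerce_id(c) for c in wide.columns],
            )
        )
    return out


def write_cohort(cohort, out_dir) -> Path:
    """Write a synthetic cohort to a directory of plain-text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.parcellation.to_csv(out / "parcellation.tsv", sep="\t", index=False)
    write_tau_scans(cohort.tau_scans, out / "tau_scans.csv")
    fc_dir = out / "subject_fc"
    fc_dir.mkdir(exist_ok=True)
    (out / "fc_kind.txt").write_text(cohort.fc_kind + "\n")
    for sid, arr in cohort.subject_fc.items():
        if cohort.fc_kind == "matrix":
            write_matrix_csv(arr, cohort.region_ids, fc_dir / f"{sid}.csv")
        else:
            pd.DataFrame(arr, index=cohort.region_ids).to_csv(
                fc_dir / f"{sid}.csv", index_label="region_id", float_format="%.8g"
            )
    tmpl_dir = out / "template_timeseries"
    tmpl_dir.mkdir(exist_ok=True)
    for i, ts in enumerate(cohort.template_timeseries):
        pd.DataFrame(ts, index=cohort.region_ids).to_csv(
            tmpl_dir / f"T{i:03d}.csv", index_label="region_id", float_format="%.8g"
        )
    if cohort.covariates is not None:
        cohort.covariates.to_csv(out / "covariates.csv")
    if cohort.amyloid is not None:
        cohort.amyloid.to_csv(out / "amyloid.csv", index_label="subject_id")
    if cohort.cognition is not None:
        cohort.cognition.to_csv(out / "cognition.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
    return out


def read_template_timeseries(tmpl_dir) -> list[np.ndarray]:
    tmpl_dir = Path(tmpl_dir)
    out = []
    for path in sorted(tmpl_dir.glob("*.csv")):
        out.append(pd.read_csv(path, index_col=0).to_numpy(dtype=float))
    if not out:
        raise InputError(f"no template time-series found under {tmpl_dir}")
    return out


def read_parcellation(path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith(".tsv") else ","
    df = pd.read_csv(path, sep=sep)
    required = {"region_id", "network"}
    if not required.issubset(df.columns):
        raise InputError("parcellation needs at least region_id and network columns")
    return df


def read_subject_fc(fc_dir, kind: str) -> dict:
    fc_dir = Path(fc_dir)
    out = {}
    for path in sorted(fc_dir.glob("*.csv")):
        df = pd.read_csv(path, index_col=0)
        out[path.stem] = df.to_numpy(dtype=float)
    if not out:
        raise InputError(f"no subject FC files found under {fc_dir}")
    if kind not in ("timeseries", "matrix"):
        raise InputError(f"unknown FC kind {kind!r}")
    return out
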