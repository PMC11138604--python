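"""Readers, writers and run manifests.

Series files are CSV or TSV with one header row, rows = time points in
order, and an optional leading ``time`` column carrying 1-based integer
labels.  Missing values are a hard error: the detection method is strictly
offline-complete-data.  Omics matrices frequently ship transposed
(covariates x time); ``read_series(..., transpose=True)`` handles that.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, is_dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .pipeline import ChangePointSet, ScoreSeries, TimeSeriesMatrix
from .sampling import SamplingResult

__all__ = ["RunManifest", "read_series", "write_results"]


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a run byte-for-byte given the same inputs."""

    config: dict
    seed: int
    package_version: str
    input_digest: Optional[str]
    created: str

    @classmethod
    def create(cls, config, seed: int, input_path: "Path | None" = None) -> "RunManifest":
        from . import __version__

        digest = None
        if input_path is not None:
            digest = hashlib.sha256(Path(input_path).read_bytes()).hexdigest()
        return cls(
            config=_to_plain(config),
            seed=int(seed),
            package_version=__version__,
            input_digest=digest,
            created=datetime.now(timezone.utc).isoformat(),
        )


def _to_plain(obj):
    """Recursively render configs/dataclasses/arrays as JSON-serializable values."""
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_series(path, transpose: bool = False) -> TimeSeriesMatrix:
    """Read a CSV/TSV time-series matrix into a validated TimeSeriesMatrix.

    With ``transpose=True`` the file is covariates x time with covariate
    names in the first column, and is flipped to the internal time x
    covariates orientation.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    if not transpose and len(set(header)) != len(header):
        raise ValueError("duplicate covariate names in header")
    df = pd.read_csv(path, sep=sep, header=0)
    if transpose:
        df = df.set_index(df.columns[0]).T.reset_index(drop=True)
        df.columns.name = None
        df.columns = [str(c) for c in df.columns]

    time_index = None
    if df.columns[0].strip().lower() == "time":
        tcol = df.iloc[:, 0]
        if tcol.isna().any() or not np.array_equal(tcol, tcol.astype(int)):
            raise ValueError("time column must contain integers")
        time_index = tcol.astype(int).to_numpy()
        if (np.diff(time_index) <= 0).any():
            raise ValueError("time column must be strictly increasing")
        df = df.iloc[:, 1:]

    names = [str(c) for c in df.columns]
    if len(set(names)) != len(names):
        raise ValueError("duplicate covariate names in header")

    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-numeric or missing value at row {row + 2} (1-based, incl. header), "
                f"column {col!r}: {df[col].iloc[row]!r} — missing data are unsupported"
            )
        df[col] = numeric

    return TimeSeriesMatrix(
        values=df.to_numpy(dtype=float),
        time_index=time_index,
        covariate_names=tuple(names),
    )


def write_series(series: TimeSeriesMatrix, path) -> None:
    path = Path(path)
    df = pd.DataFrame(series.values, columns=list(series.covariate_names))
    df.insert(0, "time", series.time_index)
    df.to_csv(path, sep=_sep_for(path), index=False)


def write_results(
    out_dir,
    scores: Optional[ScoreSeries] = None,
    change_points: Optional[ChangePointSet] = None,
    sampling: Optional[SamplingResult] = None,
    manifest: Optional[RunManifest] = None,
) -> dict[str, Path]:
    """Write scores/candidates/sampling tables plus the manifest; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if scores is not None:
        p = out_dir / "scores.csv"
        pd.DataFrame({"t": scores.t, "score": scores.score}).to_csv(p, index=False)
        written["scores"] = p
    if change_points is not None:
        rows = [
            {
                "peak": c.peak_time,
                "run_start": c.run_start,
                "run_end": c.run_end,
                "score": c.peak_score,
            }
            for c in change_points.candidates
        ]
        p = out_dir / "candidates.csv"
        pd.DataFrame(rows, columns=["peak", "run_start", "run_end", "score"]).to_csv(
            p, index=False
        )
        written["candidates_csv"] = p
        pj = out_dir / "candidates.json"
        pj.write_text(
            json.dumps(
                {
                    "threshold": change_points.threshold,
                    "eta": change_points.eta,
                    "mode": change_points.mode,
                    "candidates": rows,
                },
                indent=2,
            )
        )
        written["candidates_json"] = pj
    if sampling is not None:
        p = out_dir / "frequency.csv"
        pd.DataFrame(
            {"t": sampling.t, "frequency": sampling.frequency, "mean_score": sampling.mean_score}
        ).to_csv(p, index=False)
        written["frequency"] = p
        pi = out_dir / "intervals.csv"
        pd.DataFrame(
            [
                {"start_t": iv.start_t, "end_t": iv.end_t, "peak_frequency": iv.peak_frequency}
                for iv in sampling.intervals
            ],
            columns=["start_t", "end_t", "peak_frequency"],
        ).to_csv(pi, index=False)
        written["intervals"] = pi
    if manifest is not None:
        pm = out_dir / "manifest.json"
        pm.write_text(json.dumps(_to_plain(asdict(manifest)), indent=2, sort_keys=True))
        written["manifest"] = pm
    return written
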