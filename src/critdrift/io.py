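"""CSV readers/writers and run configuration.

Interchange format: one row per trial with columns ``subject_id``,
``trial_index`` (1-based, consecutive within subject), ``response`` (0/1),
plus any number of covariate columns.  The intercept column is injected on
read, never stored.  Simulated ground truth travels in a JSON sidecar.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataValidationError, InvalidArgumentError
from .types import (
    Dataset,
    GroundTruth,
    HyperParams,
    LatentTrajectory,
    PosteriorDraws,
    SubjectData,
    SubjectParams,
)

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_ground_truth",
    "read_ground_truth",
    "write_posterior",
    "RunConfig",
]

_RESERVED = ("subject_id", "trial_index", "response")


def read_dataset(
    path,
    covariate_cols: list[str] | None = None,
    add_prev_response: bool = False,
    prev_coding: str = "pm1",
    ground_truth_path=None,
) -> Dataset:
    """Read a trial-table CSV into a validated Dataset.

    Rows are sorted by (subject_id, trial_index); an intercept column is
    injected as covariate 0.  ``covariate_cols`` defaults to every
    non-reserved column.  With ``add_prev_response`` a previous-response
    covariate is derived from the response sequence (+/-1 coding by
    default, 0 at each subject's first trial).  Validation failures name
    the offending file rows (1-based data rows, as in the file minus
    header).
    """
    path = Path(path)
    frame = pd.read_csv(path)
    for col in _RESERVED:
        if col not in frame.columns:
            raise DataValidationError(f"{path.name}: missing required column {col!r}")
    frame["_row"] = np.arange(1, len(frame) + 1)
    bad = frame[~frame["response"].isin([0, 1])]
    if len(bad):
        raise DataValidationError(
            f"{path.name}: non-binary response values at rows "
            f"{bad['_row'].tolist()[:10]} (column 'response')"
        )
    dup = frame.duplicated(subset=["subject_id", "trial_index"], keep=False)
    if dup.any():
        raise DataValidationError(
            f"{path.name}: duplicate (subject_id, trial_index) keys at rows "
            f"{frame.loc[dup, '_row'].tolist()[:10]}"
        )
    if covariate_cols is None:
        covariate_cols = [c for c in frame.columns if c not in _RESERVED + ("_row",)]
    frame = frame.sort_values(["subject_id", "trial_index"], kind="stable")
    subjects = []
    for sid, grp in frame.groupby("subject_id", sort=True):
        idx = grp["trial_index"].to_numpy()
        expected = np.arange(1, len(grp) + 1)
        if not np.array_equal(idx, expected):
            gaps = grp["_row"].to_numpy()[idx != expected][:10]
            raise DataValidationError(
                f"{path.name}: subject {sid!r} has non-consecutive trial_index "
                f"(column 'trial_index', rows {gaps.tolist()})"
            )
        y = grp["response"].to_numpy()
        cols = [np.ones(len(grp))]
        names = ["intercept"]
        for c in covariate_cols:
            cols.append(grp[c].to_numpy(dtype=float))
            names.append(c)
        if add_prev_response:
            prev = np.zeros(len(grp))
            coded = y[:-1].astype(float)
            if prev_coding == "pm1":
                coded = 2.0 * coded - 1.0
            prev[1:] = coded
            cols.append(prev)
            names.append("prev_response")
        subjects.append(
            SubjectData(
                subject_id=str(sid),
                responses=y,
                covariates=np.column_stack(cols),
                covariate_names=names,
            )
        )
    ground_truth = read_ground_truth(ground_truth_path) if ground_truth_path else None
    return Dataset(subjects=subjects, ground_truth=ground_truth)


def write_dataset(dataset: Dataset, path, ground_truth_path=None) -> None:
    """Write the trial table to CSV (and ground truth to a JSON sidecar)."""
    rows = []
    for subj in dataset.subjects:
        frame = pd.DataFrame(
            subj.covariates[:, 1:], columns=subj.covariate_names[1:]
        )
        frame.insert(0, "subject_id", subj.subject_id)
        frame.insert(1, "trial_index", np.arange(1, subj.n_trials + 1))
        frame.insert(2, "response", subj.responses)
        rows.append(frame)
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    if ground_truth_path is not None:
        if dataset.ground_truth is None:
            raise InvalidArgumentError("dataset carries no ground truth to write")
        write_ground_truth(dataset, ground_truth_path)


def write_ground_truth(dataset: Dataset, path) -> None:
    gt = dataset.ground_truth
    payload = {
        "subjects": [
            {
                "subject_id": s.subject_id,
                "weights": p.weights.tolist(),
                "ar_coef": p.ar_coef,
                "innov_var": p.innov_var,
                "trajectory": t.states.tolist(),
            }
            for s, p, t in zip(dataset.subjects, gt.params, gt.trajectories)
        ],
        "hyper": None
        if gt.hyper is None
        else {
            "weight_mean": gt.hyper.weight_mean.tolist(),
            "weight_var": gt.hyper.weight_var.tolist(),
            "ar_mean": gt.hyper.ar_mean,
            "ar_var": gt.hyper.ar_var,
            "iga_shape": gt.hyper.iga_shape,
            "iga_scale": gt.hyper.iga_scale,
        },
    }
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    params = [
        SubjectParams(
            weights=np.array(s["weights"]),
            ar_coef=s["ar_coef"],
            innov_var=s["innov_var"],
        )
        for s in payload["subjects"]
    ]
    trajectories = [
        LatentTrajectory(states=np.array(s["trajectory"])) for s in payload["subjects"]
    ]
    hyper = None
    if payload.get("hyper"):
        hyper = HyperParams(
            weight_mean=np.array(payload["hyper"]["weight_mean"]),
            weight_var=np.array(payload["hyper"]["weight_var"]),
            ar_mean=payload["hyper"]["ar_mean"],
            ar_var=payload["hyper"]["ar_var"],
            iga_shape=payload["hyper"]["iga_shape"],
            iga_scale=payload["hyper"]["iga_scale"],
        )
    return GroundTruth(params=params, trajectories=trajectories, hyper=hyper)


def _summary_rows(name, draws_2d, labels):
    rows = []
    for j, label in enumerate(labels):
        col = draws_2d[:, j]
        rows.append(
            {
                "parameter": f"{name}[{label}]" if label is not None else name,
                "mean": col.mean(),
                "sd": col.std(ddof=1),
                "q2.5": np.quantile(col, 0.025),
                "q50": np.quantile(col, 0.5),
                "q97.5": np.quantile(col, 0.975),
            }
        )
    return rows


def write_posterior(draws: PosteriorDraws, out_dir) -> dict[str, Path]:
    """Write retained draws, summaries, trajectory bands, and a manifest.

    Produces ``draws.csv`` (long format: draw, parameter, value for all
    scalar unknowns), ``summary.csv`` (mean, SD, 2.5/50/97.5% per
    parameter), ``trajectories.csv`` (per-trial posterior mean and 95%
    band per subject), and ``manifest.json`` (seed, flags, config hash,
    package version).
    """
    if draws.n_draws == 0:
        raise InvalidArgumentError("no retained draws to write")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = draws.metadata.get("subject_ids", [str(i) for i in range(draws.n_subjects)])
    cov = draws.metadata.get(
        "covariate_names", [f"cov{j}" for j in range(draws.n_covariates)]
    )
    long_rows = []
    s = draws.n_draws
    draw_idx = np.arange(s)
    def emit(param, values):
        long_rows.append(pd.DataFrame({"draw": draw_idx, "parameter": param, "value": values}))

    for i, sid in enumerate(ids):
        for j, cname in enumerate(cov):
            emit(f"weights[{sid},{cname}]", draws.weights[:, i, j])
        emit(f"ar_coef[{sid}]", draws.ar_coef[:, i])
        emit(f"innov_var[{sid}]", draws.innov_var[:, i])
    for j, cname in enumerate(cov):
        emit(f"weight_mean[{cname}]", draws.weight_mean[:, j])
        emit(f"weight_var[{cname}]", draws.weight_var[:, j])
    emit("ar_mean", draws.ar_mean)
    emit("ar_var", draws.ar_var)
    emit("iga_shape", draws.iga_shape)
    emit("iga_scale", draws.iga_scale)
    long = pd.concat(long_rows, ignore_index=True)
    draws_path = out / "draws.csv"
    long.to_csv(draws_path, index=False)

    summary = (
        long.groupby("parameter", sort=False)["value"]
        .agg(
            mean="mean",
            sd=lambda v: v.std(ddof=1),
            **{
                "q2.5": lambda v: v.quantile(0.025),
                "q50": "median",
                "q97.5": lambda v: v.quantile(0.975),
            },
        )
        .reset_index()
    )
    summary_path = out / "summary.csv"
    summary.to_csv(summary_path, index=False)

    # trajectory outputs are omitted for fluctuations-off fits (states pinned at 0)
    traj_path = None
    if draws.metadata.get("estimate_fluctuations", True):
        traj_rows = []
        for i, sid in enumerate(ids):
            mean = draws.trajectory_estimate(i)
            lo, hi = draws.trajectory_band(i, 0.95)
            traj_rows.append(
                pd.DataFrame(
                    {
                        "subject_id": sid,
                        "trial_index": np.arange(1, mean.size + 1),
                        "mean": mean,
                        "q2.5": lo,
                        "q97.5": hi,
                    }
                )
            )
        traj_path = out / "trajectories.csv"
        pd.concat(traj_rows, ignore_index=True).to_csv(traj_path, index=False)

    meta = {k: v for k, v in draws.metadata.items()}
    meta["config_hash"] = hashlib.sha256(
        json.dumps(
            {k: meta.get(k) for k in ("n_iterations", "burn_in", "thin", "seed",
                                      "estimate_fluctuations", "update_hyperpriors")},
            sort_keys=True,
        ).encode()
    ).hexdigest()[:16]
    from . import __version__

    meta["version"] = __version__
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(meta, default=str, indent=2))
    paths = {"draws": draws_path, "summary": summary_path, "manifest": manifest_path}
    if traj_path is not None:
        paths["trajectories"] = traj_path
    return paths


@dataclass
class RunConfig:
    """Structured run configuration (YAML on disk)."""

    data_path: str | None = None
    ground_truth_path: str | None = None
    out_dir: str = "critdrift_out"
    seed: int = 0
    n_iterations: int = 1000
    burn_in: int = 500
    thin: int = 1
    estimate_fluctuations: bool = True
    update_hyperpriors: bool = True
    add_prev_response: bool = False
    prev_coding: str = "pm1"
    covariate_cols: list[str] | None = None
    simulation: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("n_iterations", "burn_in", "thin"):
            if int(getattr(self, name)) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.n_iterations <= self.burn_in:
            raise ConfigurationError("n_iterations must exceed burn_in")
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")
        if self.prev_coding not in ("pm1", "01"):
            raise ConfigurationError("prev_coding must be 'pm1' or '01'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))
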