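"""Dataset I/O, pipeline orchestration and evaluation utilities.

Trials are stored either as one delimited-text matrix per trial
(rows = channels) in a directory, or as a single HDF5 container with
datasets ``/trials`` (n x c x t), ``/fs`` and optionally ``/labels``.
Labels travel in a CSV with columns ``trial_id,label``. All indices
are 0-based. ``run_pipeline`` chains preprocessing, descriptor
extraction (raw covariance or E-frames), KMDA fitting and prediction,
and emits a structured per-stage / per-iteration report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import eframes as ef
from . import kmda
from .spd_core import EEGTrial, MeanConfig, covariance

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "load_dataset",
    "save_dataset",
    "load_labels",
    "trials_to_descriptors",
    "run_pipeline",
    "cohens_kappa",
]


@dataclass
class PipelineConfig:
    """End-to-end settings: descriptor choice, preprocessing, KMDA parameters."""

    descriptor: str = "raw_covariance"  # or "eframes"
    bandpass: bool = True
    bandpass_order: int = 6
    band: tuple = (8.0, 30.0)
    window_s: float = 1.0
    overlap: float = 0.5
    layout_path: str | None = None
    params: kmda.KMDAParams = field(default_factory=kmda.KMDAParams)
    mean_cfg: MeanConfig = field(default_factory=MeanConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.descriptor not in ("raw_covariance", "eframes", "precomputed"):
            raise ValueError(
                "descriptor must be 'raw_covariance', 'eframes' or 'precomputed'"
            )


def save_dataset(path, trials: list[EEGTrial], labels=None) -> None:
    """Write trials (and optional labels) to an HDF5 container."""
    path = Path(path)
    arr = np.stack([t.data for t in trials])
    ids = [t.id or str(i) for i, t in enumerate(trials)]
    with h5py.File(path, "w") as fh:
        fh.create_dataset("trials", data=arr)
        fh.create_dataset("fs", data=float(trials[0].fs))
        fh.create_dataset("ids", data=np.array(ids, dtype="S"))
        if labels is not None:
            fh.create_dataset("labels", data=np.asarray(labels))


def _load_text_dir(path: Path) -> list[EEGTrial]:
    files = sorted(
        p
        for p in path.iterdir()
        if p.suffix in (".csv", ".txt", ".tsv") and p.stem != "labels"
    )
    if not files:
        raise FileNotFoundError(f"no trial files (*.csv/*.txt/*.tsv) in {path}")
    fs_file = path / "fs.json"
    fs = 250.0
    if fs_file.exists():
        fs = float(json.loads(fs_file.read_text())["fs"])
    trials = []
    for p in files:
        delim = "," if p.suffix == ".csv" else None
        data = np.loadtxt(p, delimiter=delim)
        trials.append(EEGTrial(data=data, fs=fs, id=p.stem))
    return trials


def load_dataset(path, labels_path=None) -> tuple[list[EEGTrial], np.ndarray | None]:
    """Load trials from an HDF5 container or a directory of text matrices.

    Trials are ordered lexicographically by id. When a labels CSV is
    given, every id it names must exist and labels are returned in
    trial order; an id mismatch raises with the offending id named.
    """
    path = Path(path)
    if path.is_dir():
        trials = _load_text_dir(path)
    else:
        with h5py.File(path, "r") as fh:
            if "trials" not in fh or "fs" not in fh:
                raise ValueError(f"{path}: missing /trials or /fs dataset")
            arr = np.asarray(fh["trials"])
            fs = float(np.asarray(fh["fs"]))
            if "ids" in fh:
                ids = [s.decode() for s in np.asarray(fh["ids"])]
            else:
                ids = [str(i) for i in range(arr.shape[0])]
        trials = [EEGTrial(data=arr[i], fs=fs, id=ids[i]) for i in range(arr.shape[0])]
    order = np.argsort([t.id for t in trials], kind="stable")
    trials = [trials[i] for i in order]

    c0 = trials[0].n_channels
    for t in trials:
        if t.n_channels != c0:
            raise ValueError(
                f"trial {t.id!r} has {t.n_channels} channels, expected {c0}"
            )

    labels = None
    if labels_path is not None:
        labels = load_labels(labels_path, [t.id for t in trials])
    return trials, labels


def load_labels(labels_path, trial_ids: list[str]) -> np.ndarray:
    """Read a trial_id,label CSV and align it to the given trial order."""
    df = pd.read_csv(labels_path, dtype={"trial_id": str})
    if not {"trial_id", "label"} <= set(df.columns):
        raise ValueError("labels CSV must have columns trial_id,label")
    table = dict(zip(df["trial_id"], df["label"]))
    missing = [i for i in table if i not in set(trial_ids)]
    if missing:
        raise ValueError(f"labels CSV names unknown trial id {missing[0]!r}")
    absent = [i for i in trial_ids if i not in table]
    if absent:
        raise ValueError(f"trial {absent[0]!r} has no label in the CSV")
    return np.asarray([table[i] for i in trial_ids])


def trials_to_descriptors(trials, config: PipelineConfig) -> list[np.ndarray]:
    """Preprocess trials and turn each into its SPD descriptor.

    With descriptor="precomputed" the inputs are taken to be SPD
    matrices already and passed through unchanged.
    """
    if config.descriptor == "precomputed":
        return [np.asarray(t, float) for t in trials]
    layout = None
    if config.descriptor == "eframes":
        layout = (
            ef.ElectrodeLayout.from_json(config.layout_path)
            if config.layout_path
            else ef.layout_22()
        )
    out = []
    for t in trials:
        if config.bandpass:
            t = ef.preprocess_bandpass(t, order=config.bandpass_order, band=config.band)
        if config.descriptor == "eframes":
            seq = ef.trial_to_frames(
                t, layout, window_s=config.window_s, overlap=config.overlap, band=config.band
            )
            out.append(ef.frames_covariance(seq))
        else:
            out.append(covariance(t))
    return out


def cohens_kappa(y_true, y_pred) -> float:
    """Chance-corrected agreement between two label vectors."""
    from sklearn.metrics import cohen_kappa_score

    return float(cohen_kappa_score(np.asarray(y_true), np.asarray(y_pred)))


def run_pipeline(
    config: PipelineConfig,
    source_trials: list[EEGTrial],
    source_labels,
    target_trials: list[EEGTrial],
    target_labels=None,
) -> dict:
    """Preprocess -> descriptor -> KMDA fit -> target predictions + report.

    When ground-truth target labels are supplied (e.g. by the
    simulator) the report also carries accuracy and Cohen's kappa.
    """
    stages = []

    def stage(name, **kv):
        rec = {"stage": name, **kv}
        stages.append(rec)
        logger.info(json.dumps(rec))

    try:
        src = trials_to_descriptors(source_trials, config)
        tgt = trials_to_descriptors(target_trials, config)
    except Exception as e:  # re-raise with stage context
        raise RuntimeError(f"descriptor stage failed: {e}") from e
    stage("descriptor", kind=config.descriptor, d=int(src[0].shape[0]),
          n_source=len(src), n_target=len(tgt))

    data = kmda.DomainDataset(target=tgt, source=src, source_labels=np.asarray(source_labels))
    try:
        model = kmda.fit(data, config.params, config.mean_cfg)
    except Exception as e:
        raise RuntimeError(f"kmda fit stage failed: {e}") from e
    for row in model.iteration_log:
        stage("kmda_iteration", **row)
    stage("fit", sigma=model.sigma, rho=model.rho, converged=model.converged,
          n_iterations=len(model.iteration_log))

    predictions = model.target_pseudo_labels
    report = {
        "stages": stages,
        "sigma": model.sigma,
        "rho": model.rho,
        "converged": model.converged,
        "n_iterations": len(model.iteration_log),
        "iteration_log": model.iteration_log,
    }
    if target_labels is not None:
        y = np.asarray(target_labels)
        acc = float(np.mean(predictions == y))
        report["accuracy"] = acc
        report["kappa"] = cohens_kappa(y, predictions)
        stage("evaluate", accuracy=acc, kappa=report["kappa"])
    return {
        "predictions": predictions,
        "target_ids": [getattr(t, "id", str(i)) for i, t in enumerate(target_trials)],
        "model": model,
        "report": report,
    }
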