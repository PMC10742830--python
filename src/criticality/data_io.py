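"""Dataset loading, synthetic data generation, HDF5/CSV export and run
configuration.

Datasets are plain numeric tables (CSV with a header row, optional label
column).  Labels never reach the network; they ride along so that class
structure can be judged after the representation is computed.  The
synthetic generator produces labelled multiclass Gaussian blobs with
controllable class separation, emulating the statistical shape of small
tabular benchmarks (a handful of positive, O(1)-magnitude attributes per
class) without shipping any data files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
import yaml

from .input_scaling import NormalisationSettings
from .network import NetworkSpec, RandomConnectivity
from .ode_engine import ClampSchedule, Trajectory
from .plasticity import HebbianSettings, ReadoutSettings
from .rcc_models import BerryParams, WuParams

__all__ = [
    "Dataset",
    "RunConfig",
    "export_hdf5",
    "load_csv",
    "load_hdf5",
    "make_blobs",
]

log = logging.getLogger("criticality")


@dataclass
class Dataset:
    """An attribute matrix with optional labels and provenance."""

    values: np.ndarray
    labels: np.ndarray | None = None
    attribute_names: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.size == 0:
            self.values = self.values.reshape(0, len(self.attribute_names))
        if not self.attribute_names:
            self.attribute_names = [f"attr{i}" for i in range(self.values.shape[1])]
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.values.shape[0]:
                raise ValueError("labels length must match number of rows")
        if np.isnan(self.values).any():
            raise ValueError("Dataset must not contain missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.values.shape[1]


def load_csv(path, label_column: str | None = None) -> Dataset:
    """Load a numeric CSV with a header row.

    Rows with missing values are dropped (and counted); the named label
    column, if any, is split off and never presented to the network.
    Non-numeric attribute cells are an error.
    """
    df = pd.read_csv(path)
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not in {list(df.columns)}")
        labels_all = df[label_column]
        df = df.drop(columns=[label_column])
    else:
        labels_all = None
    complete = df.notna().all(axis=1)
    if labels_all is not None:
        complete &= labels_all.notna()
    n_dropped = int((~complete).sum())
    if n_dropped:
        log.info("dropped %d incomplete rows from %s", n_dropped, path)
    df = df[complete]
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric attribute values in {path}: {exc}") from None
    labels = labels_all[complete].to_numpy() if labels_all is not None else None
    return Dataset(values=values, labels=labels,
                   attribute_names=list(df.columns),
                   provenance={"path": str(path), "label_column": label_column},
                   n_dropped=n_dropped)


def make_blobs(n_classes: int = 3, n_per_class: int = 40, n_features: int = 4,
               separation: float = 6.0, seed: int = 0,
               scale: float = 1.0) -> Dataset:
    """Seeded Gaussian class blobs with unit within-class spread.

    Class centroids are spaced ``separation`` within-class standard
    deviations apart along the positive diagonal, so classes are ordered by
    overall attribute magnitude — the structure of small tabular benchmarks
    like Iris, whose species differ in overall flower size, and the regime
    in which a perturbation-driven representation (whose response grows
    with the total drive) can reflect class identity.  Attributes are
    shifted so the table is nonnegative (the RCC input quotient presumes
    nonnegative data) and multiplied by ``scale``.  Deterministic given
    ``seed``.
    """
    if n_classes < 1 or n_per_class < 1 or n_features < 1:
        raise ValueError("counts must be >= 1")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    direction = np.ones(n_features) / np.sqrt(n_features)
    centroids = np.array([(c + 1) * separation * direction
                          for c in range(n_classes)])
    X = np.vstack([
        centroids[c] + rng.standard_normal((n_per_class, n_features))
        for c in range(n_classes)])
    y = np.repeat(np.arange(n_classes), n_per_class)
    X -= np.minimum(X.min(axis=0), 0.0)   # nonnegative attributes
    X *= scale
    return Dataset(values=X, labels=y,
                   provenance={"generator": "make_blobs", "seed": seed,
                               "n_classes": n_classes,
                               "n_per_class": n_per_class,
                               "n_features": n_features,
                               "separation": separation, "scale": scale})


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything needed to reproduce one representation run."""

    spec: NetworkSpec
    schedule: ClampSchedule
    input_scalars: list[float]
    shuffle_seed: int = 0
    dataset_path: str | None = None
    label_column: str | None = None
    output_csv: str | None = None
    output_hdf5: str | None = None

    def to_dict(self) -> dict:
        spec = self.spec
        weights = spec.weights
        if isinstance(weights, RandomConnectivity):
            wd = {"kind": "random", "mean": weights.mean, "sd": weights.sd}
        elif np.isscalar(weights):
            wd = {"kind": "uniform", "value": float(weights)}
        else:
            wd = {"kind": "matrix", "values": np.asarray(weights).tolist()}
        d = {
            "model": spec.model,
            "n_oscillators": spec.n_oscillators,
            "weights": wd,
            "input_map": list(spec.input_map),
            "normalisation": spec.normalisation,
            "seed": spec.seed,
            "integrator": spec.integrator,
            "reset_per_sample": spec.reset_per_sample,
            "initial_state": list(spec.initial_state),
            "params": spec.params.as_dict() if spec.params is not None else None,
            "learning": asdict(spec.learning) if spec.learning else None,
            "readout": asdict(spec.readout) if spec.readout else None,
            "steps_per_sample": self.schedule.steps_per_sample,
            "step_size": self.schedule.step_size,
            "transient_fraction": self.schedule.transient_fraction,
            "record_stride": self.schedule.record_stride,
            "input_scalars": list(map(float, self.input_scalars)),
            "shuffle_seed": self.shuffle_seed,
            "dataset_path": self.dataset_path,
            "label_column": self.label_column,
            "output_csv": self.output_csv,
            "output_hdf5": self.output_hdf5,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        wd = d.get("weights", {"kind": "uniform", "value": 0.0005})
        if wd["kind"] == "uniform":
            weights = float(wd["value"])
        elif wd["kind"] == "random":
            weights = RandomConnectivity(mean=float(wd["mean"]), sd=float(wd["sd"]))
        elif wd["kind"] == "matrix":
            weights = np.asarray(wd["values"], dtype=float)
        else:
            raise ValueError(f"unknown weight kind {wd['kind']!r}")
        model = d.get("model", "berry")
        params = d.get("params")
        if params is not None:
            params = (BerryParams.from_dict(params) if model == "berry"
                      else WuParams.from_dict(params))
        learning = d.get("learning")
        readout = d.get("readout")
        spec = NetworkSpec(
            model=model,
            n_oscillators=int(d["n_oscillators"]),
            weights=weights,
            input_map=tuple(d["input_map"]),
            normalisation=d.get("normalisation", "static"),
            learning=HebbianSettings(**learning) if learning else None,
            readout=ReadoutSettings(**readout) if readout else None,
            seed=int(d.get("seed", 0)),
            integrator=d.get("integrator", "rk4"),
            reset_per_sample=bool(d.get("reset_per_sample", False)),
            params=params,
            initial_state=tuple(d.get("initial_state", (1.0, 1.0, 1.0, 1.0))),
        )
        schedule = ClampSchedule(
            steps_per_sample=int(d.get("steps_per_sample", 50_000)),
            step_size=float(d.get("step_size", 0.1)),
            transient_fraction=float(d.get("transient_fraction", 0.5)),
            record_stride=int(d.get("record_stride", 10)),
        )
        return cls(spec=spec, schedule=schedule,
                   input_scalars=list(map(float, d["input_scalars"])),
                   shuffle_seed=int(d.get("shuffle_seed", 0)),
                   dataset_path=d.get("dataset_path"),
                   label_column=d.get("label_column"),
                   output_csv=d.get("output_csv"),
                   output_hdf5=d.get("output_hdf5"))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# HDF5 export
# ---------------------------------------------------------------------------

def export_hdf5(path, trajectory: Trajectory | None = None,
                representation: pd.DataFrame | None = None,
                config: RunConfig | dict | None = None,
                metadata: dict | None = None) -> None:
    """Write a run (trajectory, representation table, config) to HDF5.

    Layout: ``/trajectory`` (times, states, sample_boundaries,
    channel_labels), ``/representation`` (one dataset per column),
    ``/config`` (JSON-serialised run configuration and metadata).
    Arrays round-trip losslessly through :func:`load_hdf5`.
    """
    with h5py.File(path, "w") as fh:
        if trajectory is not None:
            g = fh.create_group("trajectory")
            g.create_dataset("times", data=trajectory.times)
            g.create_dataset("states", data=trajectory.states)
            g.create_dataset("sample_boundaries",
                             data=np.asarray(trajectory.sample_boundaries,
                                             dtype=np.int64).reshape(-1, 2))
            g.create_dataset("channel_labels",
                             data=np.array(trajectory.channel_labels, dtype="S"))
        if representation is not None:
            g = fh.create_group("representation")
            for col in representation.columns:
                data = representation[col].to_numpy()
                if data.dtype == object:
                    data = np.array([str(v) for v in data], dtype="S")
                g.create_dataset(str(col), data=data)
        g = fh.create_group("config")
        if config is not None:
            cd = config.to_dict() if isinstance(config, RunConfig) else dict(config)
            g.attrs["run_config"] = json.dumps(cd)
        if metadata is not None:
            g.attrs["metadata"] = json.dumps(metadata)


def load_hdf5(path) -> dict:
    """Read back a file written by :func:`export_hdf5`."""
    out: dict = {}
    with h5py.File(path, "r") as fh:
        if "trajectory" in fh:
            g = fh["trajectory"]
            out["trajectory"] = Trajectory(
                times=g["times"][()],
                states=g["states"][()],
                sample_boundaries=[tuple(b) for b in g["sample_boundaries"][()]],
                channel_labels=[s.decode() for s in g["channel_labels"][()]],
            )
        if "representation" in fh:
            g = fh["representation"]
            cols = {}
            for name in g:
                data = g[name][()]
                if data.dtype.kind == "S":
                    data = np.array([s.decode() for s in data])
                cols[name] = data
            out["representation"] = pd.DataFrame(cols)
        if "config" in fh:
            attrs = fh["config"].attrs
            if "run_config" in attrs:
                out["config"] = json.loads(attrs["run_config"])
            if "metadata" in attrs:
                out["metadata"] = json.loads(attrs["metadata"])
    return out
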