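"""Trajectory -> representation-point feature extraction.

Each clamp window, after discarding the leading transient, is summarised
into a low-dimensional point: the maxima of the network's total signals
(total M and total F for Berry, the steady-state totals for Wu), the median
frequency of the total filament oscillation, and per-unit maxima where
readout units are involved.  These points are what Criticality Analysis
hands to a downstream classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, periodogram

from .input_scaling import NormalisationSettings, shift_nonnegative, static_scale
from .network import BERRY_VARS, WU_VARS, NetworkSpec, build_network
from .ode_engine import ClampSchedule, Trajectory

__all__ = [
    "RepresentationPoint",
    "RepresentationResult",
    "grouping_report",
    "median_frequency",
    "represent",
    "totals",
    "window_features",
]

#: relative last-quartile range below which a window counts as converged
CONVERGENCE_RTOL = 1e-6


@dataclass
class RepresentationPoint:
    """Per-sample orbit summary (a row of the representation table)."""

    sample_id: int
    max_F: float = np.nan
    max_M: float = np.nan
    median_freq_F: float = np.nan
    steady_state: np.ndarray | None = None
    converged: bool = False
    label: object = None


@dataclass
class RepresentationResult:
    """Representation table plus everything needed to reproduce it."""

    table: pd.DataFrame
    metadata: dict
    trajectory: Trajectory | None = None


def totals(traj: Trajectory, variable: str,
           oscillators: Sequence[int] | None = None) -> np.ndarray:
    """Pointwise sum of one state variable across oscillators.

    ``oscillators`` restricts the sum (e.g. to the reservoir units,
    excluding readouts); default is all oscillators in the trajectory.
    """
    cols = []
    for idx, label in enumerate(traj.channel_labels):
        osc_s, var = label.split(":")
        if var != variable:
            continue
        osc = int(osc_s.removeprefix("osc"))
        if oscillators is None or osc in oscillators:
            cols.append(idx)
    if not cols:
        raise KeyError(f"no channels for variable {variable!r}")
    return traj.states[:, cols].sum(axis=1)


def _post_transient(series: np.ndarray, transient_fraction: float) -> np.ndarray:
    skip = int(np.ceil(transient_fraction * len(series)))
    out = series[skip:]
    if len(out) < 2:
        raise ValueError("post-transient window has fewer than 2 points")
    return out


def window_features(total_F: np.ndarray, total_M: np.ndarray,
                    schedule: ClampSchedule, sample_id: int = 0,
                    label=None, dt: float | None = None) -> RepresentationPoint:
    """Summarise one clamp window into a :class:`RepresentationPoint`.

    Maxima are taken over the post-transient part of the recorded window.
    A window is flagged converged (steady state rather than orbit) when the
    last quartile's range is below ``CONVERGENCE_RTOL`` of its mean level;
    the median frequency is undefined (NaN) in that case.
    """
    F = _post_transient(np.asarray(total_F, float), schedule.transient_fraction)
    M = _post_transient(np.asarray(total_M, float), schedule.transient_fraction)
    tail = M[3 * len(M) // 4:]
    scale = max(abs(float(np.mean(tail))), 1e-300)
    converged = bool(np.ptp(tail) < CONVERGENCE_RTOL * scale)
    if dt is None:
        dt = schedule.step_size * schedule.record_stride
    mf = np.nan if converged else median_frequency(F, dt)
    return RepresentationPoint(sample_id=sample_id, max_F=float(F.max()),
                               max_M=float(M.max()), median_freq_F=mf,
                               converged=converged, label=label)


def median_frequency(signal: np.ndarray, dt: float,
                     method: str = "periodogram") -> float:
    """Frequency splitting the signal's spectral power in half
    (cycles per model-time unit), computed on the mean-removed signal.

    ``method="periodogram"`` uses the cumulative periodogram;
    ``method="peak_intervals"`` returns the median of the inverse
    peak-to-peak intervals instead.  A (numerically) constant signal has no
    defined frequency and yields NaN.
    """
    if method not in ("periodogram", "peak_intervals"):
        raise ValueError(f"unknown median-frequency method {method!r}")
    x = np.asarray(signal, dtype=float)
    if len(x) < 4:
        raise ValueError("median_frequency needs at least 4 points")
    x = x - x.mean()
    if np.allclose(x, 0.0, atol=1e-12 * max(1.0, float(np.abs(signal).max()))):
        return np.nan
    if method == "peak_intervals":
        peaks, _ = find_peaks(x)
        if len(peaks) < 3:
            return np.nan
        intervals = np.diff(peaks) * dt
        return float(np.median(1.0 / intervals))
    freqs, power = periodogram(x, fs=1.0 / dt, detrend=False)
    total = power.sum()
    if total <= 0:
        return np.nan
    csum = np.cumsum(power)
    idx = int(np.searchsorted(csum, 0.5 * total))
    return float(freqs[min(idx, len(freqs) - 1)])


def represent(dataset, spec: NetworkSpec, schedule: ClampSchedule,
              input_scalars, *, shuffle_seed: int = 0,
              return_trajectory: bool = False,
              median_freq_method: str = "periodogram") -> RepresentationResult:
    """Run the full CA pipeline: scale, shuffle, clamp, extract features.

    ``dataset`` is a :class:`criticality.data_io.Dataset` (or anything with
    ``values``/``labels`` attributes).  Rows are presented in a seeded
    random order; the returned table is in presentation order and carries
    the original ``sample_id`` of each row.  Metadata records every seed and
    frozen constant needed to reproduce the table bit-identically.
    """
    values = np.atleast_2d(np.asarray(dataset.values, dtype=float))
    labels = getattr(dataset, "labels", None)
    n_samples = values.shape[0]

    meta = {
        "model": spec.model,
        "n_oscillators": spec.n_oscillators,
        "shuffle_seed": shuffle_seed,
        "network_seed": spec.seed,
        "input_scalars": np.asarray(input_scalars, float).tolist(),
        "steps_per_sample": schedule.steps_per_sample,
        "step_size": schedule.step_size,
        "transient_fraction": schedule.transient_fraction,
        "record_stride": schedule.record_stride,
        "normalisation": spec.normalisation,
    }

    if n_samples == 0:
        cols = ["sample_id", "max_F", "max_M", "median_freq_F", "label"] \
            if spec.model == "berry" else \
            ["sample_id", "max_Y", "max_Z", "max_W", "converged", "label"]
        return RepresentationResult(table=pd.DataFrame(columns=cols), metadata=meta)

    shifted, shifts = shift_nonnegative(values)
    scaled = static_scale(shifted, input_scalars)
    meta["attribute_shifts"] = shifts.tolist()

    norm = None
    if spec.normalisation == "dynamic":
        norm = NormalisationSettings.from_data(scaled)
        meta["mu_eps"] = norm.mu_eps.tolist()

    order = np.random.default_rng(shuffle_seed).permutation(n_samples)
    net = build_network(spec)
    traj = net.simulate_clamped(scaled[order], schedule, norm)

    reservoir = [i for i in range(net.n_total)
                 if net.readout_indices is None or i not in net.readout_indices]
    var_main, var_sec = ("f", "m") if spec.model == "berry" else ("z", "w")
    tot_main = totals(traj, var_main, reservoir)
    tot_sec = totals(traj, var_sec, reservoir)
    tot_y = totals(traj, "y", reservoir) if spec.model == "wu" else None
    dt = traj.dt

    rows = []
    for k, (start, end) in enumerate(traj.sample_boundaries):
        sid = int(order[k])
        lab = labels[sid] if labels is not None else None
        point = window_features(tot_main[start:end], tot_sec[start:end],
                                schedule, sample_id=sid, label=lab, dt=dt)
        if spec.model == "berry":
            row = {"sample_id": sid, "max_F": point.max_F, "max_M": point.max_M,
                   "median_freq_F": point.median_freq_F,
                   "converged": point.converged, "label": lab}
            if net.readout_indices is not None:
                for osc in range(net.n_total):
                    seg = traj.states[start:end].reshape(end - start, net.n_total, 4)
                    post = _post_transient(seg[:, osc, 1], schedule.transient_fraction)
                    row[f"f{osc}_max"] = float(post.max())
                    post_m = _post_transient(seg[:, osc, 0], schedule.transient_fraction)
                    row[f"m{osc}_max"] = float(post_m.max())
        else:
            Y = _post_transient(tot_y[start:end], schedule.transient_fraction)
            Z = _post_transient(tot_main[start:end], schedule.transient_fraction)
            Wt = _post_transient(tot_sec[start:end], schedule.transient_fraction)
            row = {"sample_id": sid, "max_Y": float(Y.max()),
                   "max_Z": float(Z.max()), "max_W": float(Wt.max()),
                   "converged": point.converged, "label": lab}
        rows.append(row)

    table = pd.DataFrame(rows)
    meta["presentation_order"] = order.tolist()
    return RepresentationResult(
        table=table, metadata=meta,
        trajectory=traj if return_trajectory else None)


def grouping_report(points: pd.DataFrame, labels, feature_cols: Sequence[str],
                    *, n_neighbors: int = 5, n_folds: int = 5,
                    seed: int = 0) -> dict:
    """Quantify how well a candidate labelling groups in feature space.

    Reports the ratio of mean between-centroid distance to mean
    within-group distance (on standardised coordinates) and a seeded
    stratified k-fold kNN accuracy — the quantitative surrogate for judging
    visual clustering of a representation.
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    X = np.asarray(points[list(feature_cols)], dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("grouping_report needs >= 2 groups of >= 2 points")

    sd = X.std(axis=0)
    Xs = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    centroids = np.array([Xs[y == c].mean(axis=0) for c in classes])
    within = np.mean([np.linalg.norm(Xs[y == c] - centroids[i], axis=1).mean()
                      for i, c in enumerate(classes)])
    between = np.mean([np.linalg.norm(centroids[i] - centroids[j])
                       for i in range(len(classes))
                       for j in range(i + 1, len(classes))])
    ratio = float(between / within) if within > 0 else np.inf

    n_folds_eff = min(n_folds, int(counts.min()))
    knn = make_pipeline(StandardScaler(),
                        KNeighborsClassifier(n_neighbors=n_neighbors))
    cv = StratifiedKFold(n_splits=n_folds_eff, shuffle=True, random_state=seed)
    scores = cross_val_score(knn, X, y, cv=cv)
    return {
        "separability_ratio": ratio,
        "knn_accuracy": float(scores.mean()),
        "knn_fold_scores": scores.tolist(),
        "n_groups": int(len(classes)),
        "group_sizes": counts.tolist(),
    }
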