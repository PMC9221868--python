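"""Irregular-series preparation: interpolation, resampling, windowing.

Two encodings turn irregular per-eye visit sequences into fixed-shape
model inputs:

* ``resampled`` — interpolate every feature onto a regular monthly grid
  (one bin = 30.44 days) and drop explicit time features;
* ``timesteps`` — keep the real visits and append the elapsed time of
  each visit (months since the first) plus the target visit's timestamp
  as ordinary features.

Windows of ``k`` consecutive visits are then cut with a stride-1
sliding window; the first ``k - 1`` visits form the input block and the
k-th visit's decimal VA is the forecasting target.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

from .records import FEATURE_NAMES, EyeSeries

__all__ = [
    "DAYS_PER_MONTH",
    "TimedValue",
    "SlidingWindowResult",
    "WindowedDataset",
    "interpolate_linear",
    "series_to_frame",
    "resample_monthly",
    "encode_timesteps_as_features",
    "sliding_window",
    "min_max_normalise",
    "impute_missing",
    "build_windowed_dataset",
    "grouped_train_val_test",
]

log = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.44  # mean Gregorian month


@dataclass(frozen=True)
class TimedValue:
    """A feature value stamped with its time in months since the first visit."""

    t: float
    y: float

    def __post_init__(self):
        if self.t < 0:
            raise ValueError("time must be >= 0 months")


def interpolate_linear(p1: TimedValue, p2: TimedValue, t: float) -> float:
    """Linear interpolation between two timed observations.

    ``y = y1 + (t - t1) * (y2 - y1) / (t2 - t1)`` for t strictly inside
    (t1, t2).
    """
    if not p1.t < t < p2.t:
        raise ValueError(f"t={t} outside the open interval ({p1.t}, {p2.t})")
    if np.isnan(p1.y) or np.isnan(p2.y):
        raise ValueError("interpolation endpoints must be non-missing")
    return p1.y + (t - p1.t) * (p2.y - p1.y) / (p2.t - p1.t)


#: Columns of a series frame that are not OCT features.
_META_COLS = ("t", "va", "treated", "observed")


def series_to_frame(series: EyeSeries) -> pd.DataFrame:
    """One row per visit: t (months since first), va, treated, 22 OCT scalars."""
    days = series.days_since_first()
    rows = {
        "t": days / DAYS_PER_MONTH,
        "va": series.va_values(),
        "treated": np.array([float(v.treated) for v in series.visits]),
        "observed": np.ones(len(series)),
    }
    feats = np.vstack([v.feature_vector() for v in series.visits])
    for j, name in enumerate(FEATURE_NAMES):
        rows[name] = feats[:, j]
    frame = pd.DataFrame(rows)
    frame.attrs["eye_id"] = series.eye_id
    frame.attrs["patient_id"] = series.patient_id
    if any(v.image_path for v in series.visits):
        frame.attrs["image_paths"] = [v.image_path for v in series.visits]
    return frame


def _month_bin(t_months: np.ndarray) -> np.ndarray:
    # t is already months; floor once more so t=0.99 months still falls in bin 0
    return np.floor(t_months + 1e-9).astype(int)


def resample_monthly(frame: pd.DataFrame) -> pd.DataFrame:
    """Resample a series frame onto the regular monthly grid.

    Bins run from month 0 to the last visit's bin. A bin containing a real
    visit takes that visit's values (on collision the later visit wins,
    logged); empty interior bins are filled feature-wise by linear
    interpolation between the nearest occupied bins. Idempotent on already
    regular frames.
    """
    if len(frame) < 2:
        raise ValueError("resampling needs a series of length >= 2")
    bins = _month_bin(frame["t"].to_numpy())
    last = int(bins[-1])
    value_cols = [c for c in frame.columns if c != "t"]
    occupied: dict[int, pd.Series] = {}
    for i, b in enumerate(bins):
        if b in occupied:
            log.info("month-bin collision at bin %d: keeping the later visit", b)
        occupied[b] = frame.iloc[i]
    grid = np.arange(last + 1)
    out = pd.DataFrame({"t": grid.astype(float)})
    occ_bins = np.array(sorted(occupied))
    for col in value_cols:
        vals = np.full(len(grid), np.nan)
        for b, row in occupied.items():
            vals[b] = row[col]
        if col == "observed":
            out[col] = np.where(np.isnan(vals), 0.0, vals)
            continue
        if col == "treated":
            # an injection only happens at a real visit
            out[col] = np.where(np.isnan(vals), 0.0, vals)
            continue
        known = occ_bins[~np.isnan(vals[occ_bins])]
        if len(known) == 0:
            out[col] = vals
            continue
        filled = vals.copy()
        for g in grid:
            if not np.isnan(filled[g]):
                continue
            lo = known[known < g]
            hi = known[known > g]
            if len(lo) and len(hi):
                filled[g] = interpolate_linear(
                    TimedValue(float(lo[-1]), vals[lo[-1]]),
                    TimedValue(float(hi[0]), vals[hi[0]]),
                    float(g),
                )
            elif len(lo):
                filled[g] = vals[lo[-1]]
            else:
                filled[g] = vals[hi[0]]
        out[col] = filled
    out.attrs = dict(frame.attrs)
    out.attrs.pop("image_paths", None)  # interpolated rows have no image
    return out


def encode_timesteps_as_features(frame: pd.DataFrame) -> pd.DataFrame:
    """Expose each visit's elapsed time (months since first) as a feature.

    Returns a copy whose ``t`` column is understood as an input feature;
    the target visit's timestamp is attached per-window at windowing time.
    """
    out = frame.copy()
    out.attrs = dict(frame.attrs)
    out["t"] = frame["t"] - frame["t"].iloc[0]
    return out


@dataclass
class SlidingWindowResult:
    """Output of the stride-1 sliding-window segmentation."""

    windows: list
    k: int
    n: int

    def __len__(self):
        return len(self.windows)


def sliding_window(ts, k: int) -> SlidingWindowResult:
    """Segment a series into all contiguous windows of length ``k``.

    Returns no windows when ``k`` exceeds the series length, the whole
    series when ``k`` equals it, and the ``n - k + 1`` stride-1 contiguous
    sub-series otherwise.
    """
    if k <= 0:
        raise ValueError("window size k must be >= 1")
    n = len(ts)
    if k > n:
        return SlidingWindowResult([], k, n)
    if k == n:
        return SlidingWindowResult([ts], k, n)
    windows = [ts[i : i + k] for i in range(n - k + 1)]
    return SlidingWindowResult(windows, k, n)


def min_max_normalise(
    train_block: np.ndarray, *apply_blocks: np.ndarray
) -> tuple[list[np.ndarray], MinMaxScaler]:
    """Min-max scale features to the training block's [min, max].

    The scaler is fitted on the training data only and reused on every
    other block; values outside the training range map outside [0, 1],
    which is permitted. A constant feature maps to 0 everywhere (logged).
    """
    train_block = np.asarray(train_block, dtype=float)
    if train_block.size == 0:
        raise ValueError("training block must be nonempty")
    scaler = MinMaxScaler(clip=False)
    scaler.fit(train_block)
    constant = scaler.data_range_ == 0
    if constant.any():
        log.info("%d constant feature(s) map to 0 under min-max scaling", int(constant.sum()))
    scaled = [scaler.transform(train_block)]
    scaled += [scaler.transform(np.asarray(b, dtype=float)) for b in apply_blocks]
    # force the constant-feature convention (x - min)/range -> 0
    for block in scaled:
        block[:, constant] = 0.0
    return scaled, scaler


def impute_missing(frame: pd.DataFrame) -> pd.DataFrame:
    """Fill missing feature values along time.

    Interior gaps are linearly interpolated between the nearest valid
    neighbours; leading/trailing gaps take the nearest valid value; an
    all-missing column is left missing and flagged in ``attrs``.
    """
    out = frame.copy()
    out.attrs = dict(frame.attrs)
    t = frame["t"].to_numpy(dtype=float)
    all_missing = []
    for col in frame.columns:
        if col in ("t", "observed"):
            continue
        y = frame[col].to_numpy(dtype=float)
        nan = np.isnan(y)
        if not nan.any():
            continue
        if nan.all():
            all_missing.append(col)
            continue
        valid = np.flatnonzero(~nan)
        filled = y.copy()
        for i in np.flatnonzero(nan):
            lo = valid[valid < i]
            hi = valid[valid > i]
            if len(lo) and len(hi):
                filled[i] = interpolate_linear(
                    TimedValue(t[lo[-1]], y[lo[-1]]), TimedValue(t[hi[0]], y[hi[0]]), t[i]
                )
            elif len(lo):
                filled[i] = y[lo[-1]]
            else:
                filled[i] = y[hi[0]]
        out[col] = filled
    out.attrs["all_missing_features"] = all_missing
    return out


@dataclass
class WindowedDataset:
    """Fixed-shape windows ready for the forecasters.

    ``inputs`` has shape (n_series, timesteps, n_features) with
    timesteps = window_size - 1; ``targets`` is the next visit's decimal
    VA; ``groups`` carries each window's patient for leakage-safe splits.
    """

    inputs: np.ndarray
    targets: np.ndarray
    groups: np.ndarray
    eye_ids: np.ndarray
    feature_names: list[str]
    encoding: str
    k: int

    def __len__(self):
        return len(self.targets)

    @property
    def timesteps(self) -> int:
        return self.inputs.shape[1]

    def flatten(self) -> tuple[np.ndarray, list[str]]:
        """Windows as flat vectors (feature x lag) for the shallow models."""
        s, t, f = self.inputs.shape
        names = [f"{name}_lag{t - i}" for i in range(t) for name in self.feature_names]
        return self.inputs.reshape(s, t * f), names

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.save(out / "inputs.npy", self.inputs)
        pd.DataFrame({"target": self.targets}).to_csv(out / "targets.csv", index=False)
        pd.DataFrame({"patient_id": self.groups, "eye_id": self.eye_ids}).to_csv(
            out / "groups.csv", index=False
        )
        (out / "meta.json").write_text(
            json.dumps(
                {"encoding": self.encoding, "k": self.k, "feature_names": self.feature_names}
            )
        )
        return out

    @classmethod
    def load(cls, in_dir: str | Path) -> "WindowedDataset":
        p = Path(in_dir)
        meta = json.loads((p / "meta.json").read_text())
        groups = pd.read_csv(p / "groups.csv")
        return cls(
            inputs=np.load(p / "inputs.npy"),
            targets=pd.read_csv(p / "targets.csv")["target"].to_numpy(),
            groups=groups["patient_id"].to_numpy(),
            eye_ids=groups["eye_id"].to_numpy(),
            feature_names=meta["feature_names"],
            encoding=meta["encoding"],
            k=meta["k"],
        )


def _resolve_feature_cols(experiment: str, frame: pd.DataFrame) -> list[str]:
    emb_cols = [c for c in frame.columns if c.startswith("emb_")]
    if experiment == "va_only":
        return ["va", "treated"]
    if experiment == "oct_numeric":
        return list(FEATURE_NAMES) + ["treated"]
    if experiment == "oct_plus_images":
        if not emb_cols:
            raise ValueError("experiment 'oct_plus_images' needs embedding columns (emb_*)")
        return list(FEATURE_NAMES) + ["treated"] + emb_cols
    if experiment == "all_features":
        if not emb_cols:
            raise ValueError("experiment 'all_features' needs embedding columns (emb_*)")
        return ["va"] + list(FEATURE_NAMES) + ["treated"] + emb_cols
    raise ValueError(f"unknown experiment {experiment!r}")


def build_windowed_dataset(
    frames: list[pd.DataFrame],
    encoding: str = "resampled",
    n_input_visits: int = 2,
    experiment: str = "oct_numeric",
    impute: bool = True,
) -> WindowedDataset:
    """Build model-ready windows from per-eye series frames.

    ``encoding`` is ``resampled`` (monthly grid) or ``timesteps`` (real
    visits with elapsed-time features); windows have
    ``k = n_input_visits + 1`` visits, the last supplying the VA target.
    """
    if encoding not in ("resampled", "timesteps"):
        raise ValueError("encoding must be 'resampled' or 'timesteps'")
    if n_input_visits not in (1, 2, 3):
        raise ValueError("n_input_visits must be 1, 2 or 3")
    k = n_input_visits + 1
    inputs, targets, groups, eye_ids = [], [], [], []
    feature_cols: list[str] | None = None
    for frame in frames:
        if encoding == "resampled":
            frame = resample_monthly(frame)
        else:
            frame = encode_timesteps_as_features(frame)
        if impute:
            frame = impute_missing(frame)
        cols = _resolve_feature_cols(experiment, frame)
        if encoding == "timesteps":
            cols = cols + ["t", "t_target"]
        if feature_cols is None:
            feature_cols = cols
        result = sliding_window(frame.index.to_numpy(), k)
        for window_idx in result.windows:
            target_row = frame.loc[window_idx[-1]]
            target = target_row["va"]
            if np.isnan(target):
                continue
            block = frame.loc[window_idx[:-1]].copy()
            if encoding == "timesteps":
                block["t_target"] = float(target_row["t"])
            x = block[cols].to_numpy(dtype=float)
            inputs.append(x)
            targets.append(float(target))
            groups.append(frame.attrs.get("patient_id", frame.attrs.get("eye_id", "?")))
            eye_ids.append(frame.attrs.get("eye_id", "?"))
    if not inputs:
        log.warning("no eligible windows (k=%d); returning an empty dataset", k)
        n_feat = len(feature_cols) if feature_cols else 0
        return WindowedDataset(
            np.zeros((0, k - 1, n_feat)),
            np.zeros(0),
            np.zeros(0, dtype=object),
            np.zeros(0, dtype=object),
            feature_cols or [],
            encoding,
            k,
        )
    return WindowedDataset(
        np.stack(inputs),
        np.array(targets),
        np.array(groups, dtype=object),
        np.array(eye_ids, dtype=object),
        feature_cols,
        encoding,
        k,
    )


def grouped_train_val_test(
    groups: np.ndarray,
    fractions: tuple[float, float, float] = (0.6, 0.3, 0.1),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Patient-grouped train/val/test index split (no patient straddles sets)."""
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    uniq = np.array(sorted(set(groups)))
    rng.shuffle(uniq)
    n = len(uniq)
    n_train = max(1, int(round(fractions[0] * n)))
    n_val = max(1, int(round(fractions[1] * n)))
    n_train = min(n_train, n - 2) if n >= 3 else n_train
    train_g = set(uniq[:n_train])
    val_g = set(uniq[n_train : n_train + n_val])
    test_g = set(uniq[n_train + n_val :])
    if not test_g and n >= 3:
        test_g = {uniq[-1]}
        val_g.discard(uniq[-1])
    idx = np.arange(len(groups))
    in_set = lambda s: np.array([g in s for g in groups])
    return idx[in_set(train_g)], idx[in_set(val_g)], idx[in_set(test_g)]
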