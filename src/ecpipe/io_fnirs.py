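"""Recording / manifest / result-matrix I/O and the fixed channel layout.

fNIRS recordings are channels x samples matrices of oxygenated-hemoglobin
concentration change (dHbO2, arbitrary concentration units).  Channels are
numbered 1..N in file-facing interfaces (as in the optode montage figures);
all in-memory indexing is 0-based.

The canonical montage covers six cortical areas with 36 channels:
channels 1-4 left prefrontal cortex (LPFC), 5-8 right prefrontal cortex
(RPFC), 9-18 left motor cortex (LMC), 19-28 right motor cortex (RMC),
29-32 left occipital lobe (LOL), 33-36 right occipital lobe (ROL).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ChannelCountError, ConfigError, ParseError

REGIONS = ("LPFC", "RPFC", "LMC", "RMC", "LOL", "ROL")

STANDARD_BLOCK_SIZES = (4, 4, 10, 10, 4, 4)


@dataclass(frozen=True)
class ChannelLayout:
    """Contiguous channel->region assignment.

    ``labels[k]`` is the region label of the k-th block and ``sizes[k]`` the
    number of consecutive channels it contains.  Channel ids are 1-based and
    run 1..n_channels in block order.
    """

    labels: tuple[str, ...] = REGIONS
    sizes: tuple[int, ...] = STANDARD_BLOCK_SIZES

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sizes):
            raise ConfigError("labels and sizes must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise ConfigError("region labels must be unique")
        if any(s < 1 for s in self.sizes):
            raise ConfigError("every region block needs >= 1 channel")

    @property
    def n_channels(self) -> int:
        return int(sum(self.sizes))

    @property
    def channel_ids(self) -> np.ndarray:
        return np.arange(1, self.n_channels + 1)

    def region_of(self, channel: int) -> str:
        """Region label of a 1-based channel id."""
        if not 1 <= channel <= self.n_channels:
            raise ValueError(
                f"channel {channel} outside 1..{self.n_channels}"
            )
        edge = 0
        for label, size in zip(self.labels, self.sizes):
            edge += size
            if channel <= edge:
                return label
        raise AssertionError("unreachable")

    def channels_in(self, region: str) -> np.ndarray:
        """1-based channel ids belonging to ``region``."""
        if region not in self.labels:
            raise ValueError(f"unknown region {region!r}")
        start = 0
        for label, size in zip(self.labels, self.sizes):
            if label == region:
                return np.arange(start + 1, start + size + 1)
            start += size
        raise AssertionError("unreachable")

    def region_index(self, region: str) -> int:
        return self.labels.index(region)


def standard_layout() -> ChannelLayout:
    """The canonical 36-channel six-region montage."""
    layout = ChannelLayout(REGIONS, STANDARD_BLOCK_SIZES)
    assert layout.n_channels == 36
    return layout


def compact_layout(n_per_region: int = 1) -> ChannelLayout:
    """A scaled-down montage with ``n_per_region`` channels per region.

    Used for fast runs; region labels and their order match the standard
    montage so region-level results are directly comparable.
    """
    return ChannelLayout(REGIONS, (n_per_region,) * len(REGIONS))


def assign_region(channel: int, layout: ChannelLayout) -> str:
    """Region label of a 1-based channel id (range-checked)."""
    return layout.region_of(channel)


@dataclass
class Recording:
    """One subject/state multichannel dHbO2 recording."""

    data: np.ndarray  # (n_channels, n_samples), float64
    fs: float
    subject_id: str = ""
    group: str = ""
    state: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ChannelCountError("recording data must be 2-D")
        if self.fs <= 0:
            raise ConfigError("sampling frequency must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ParseError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


# ---------------------------------------------------------------------------
# recordings


def load_recording(
    path: str | Path,
    layout: ChannelLayout | None = None,
    fs: float | None = None,
    subject_id: str = "",
    group: str = "",
    state: str = "",
) -> Recording:
    """Load a recording from CSV/TSV (channel-by-time) or SNIRF.

    CSV/TSV files carry one channel per row with a leading ``channel``
    column of 1-based ids; ``fs`` is required (never inferred from the
    file).  SNIRF files carry their own time vector, from which fs is read.
    """
    path = Path(path)
    layout = layout or standard_layout()
    if path.suffix.lower() == ".snirf":
        data, fs_file = _read_snirf(path)
        fs = fs_file
    else:
        if fs is None:
            raise ConfigError("fs is required for CSV/TSV recordings")
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        try:
            df = pd.read_csv(path, sep=sep, float_precision="round_trip")
        except Exception as exc:  # pragma: no cover - pandas message varies
            raise ParseError(f"{path}: {exc}") from exc
        if "channel" not in df.columns:
            raise ParseError(f"{path}: missing 'channel' id column")
        ids = df["channel"].to_numpy()
        body = df.drop(columns="channel")
        arr = body.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            for j, col in enumerate(body.columns):
                bad = pd.to_numeric(body[col], errors="coerce")
                if bad.isna().any():
                    i = int(np.flatnonzero(bad.isna())[0])
                    raise ParseError(
                        f"{path}: non-numeric cell at row {i + 2}, "
                        f"column {j + 2}"
                    )
            arr = body.astype(float).to_numpy()
        expected = layout.channel_ids
        if len(ids) != len(expected) or not np.array_equal(
            np.sort(ids), expected
        ):
            raise ChannelCountError(
                f"{path}: expected channels 1..{layout.n_channels}, "
                f"found {len(ids)} rows"
            )
        data = np.asarray(arr, dtype=float)[np.argsort(ids)]
    if data.shape[0] != layout.n_channels:
        raise ChannelCountError(
            f"{path}: {data.shape[0]} channels, layout has "
            f"{layout.n_channels}"
        )
    return Recording(
        data=data, fs=float(fs), subject_id=subject_id, group=group,
        state=state,
    )


def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write a recording to CSV/TSV (full float precision) or SNIRF."""
    path = Path(path)
    if path.suffix.lower() == ".snirf":
        _write_snirf(recording, path)
        return path
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.DataFrame(recording.data)
    df.insert(0, "channel", np.arange(1, recording.n_channels + 1))
    # default float formatting is the shortest round-trippable repr
    df.to_csv(path, sep=sep, index=False)
    return path


def _read_snirf(path: Path) -> tuple[np.ndarray, float]:
    """Minimal SNIRF reader: dataTimeSeries + time of the first data block.

    Reads only the HbO2 concentration time series the pipeline consumes;
    this is not a full SNIRF implementation.
    """
    import h5py

    with h5py.File(path, "r") as f:
        nirs = f.get("nirs") or f.get("nirs1")
        if nirs is None:
            raise ParseError(f"{path}: no /nirs group")
        data_grp = nirs.get("data1") or nirs.get("data")
        if data_grp is None:
            raise ParseError(f"{path}: no /nirs/data1 group")
        series = np.asarray(data_grp["dataTimeSeries"], dtype=float)
        time = np.asarray(data_grp["time"], dtype=float).ravel()
    if time.size == 2:  # start + sampling period form
        fs = 1.0 / float(time[1])
    else:
        fs = 1.0 / float(np.median(np.diff(time)))
    return series.T.copy(), fs  # stored time x channel


def _write_snirf(recording: Recording, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset(
            "formatVersion", data=np.bytes_("1.0")
        )
        grp = f.create_group("nirs/data1")
        grp.create_dataset(
            "dataTimeSeries", data=recording.data.T.astype(float)
        )
        t = np.arange(recording.n_samples) / recording.fs
        grp.create_dataset("time", data=t)


# ---------------------------------------------------------------------------
# manifests


MANIFEST_COLUMNS = (
    "subject_id", "group", "age", "sex", "mmse",
    "path_sitting", "path_standing",
)


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    """Check manifest invariants; adds an ``incomplete`` flag column."""
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"manifest missing columns: {missing}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ParseError(f"duplicate subject_id {dup!r}")
    mmse = pd.to_numeric(df["mmse"], errors="coerce")
    if ((mmse < 0) | (mmse > 30)).any():
        raise ParseError("MMSE scores must lie in [0, 30]")
    out = df.copy()
    out["incomplete"] = (
        df["path_sitting"].isna() | df["path_standing"].isna()
    )
    return out


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return validate_manifest(df)


def write_manifest(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# connectivity matrices


def write_connectivity(matrix, path: str | Path) -> Path:
    """Write a ConnectivityMatrix as TSV (6 significant digits, NA diagonal).

    The significance mask goes to a companion ``<stem>.mask.tsv`` file
    (1 = significant); surrogate means/SDs, when present, to
    ``<stem>.surrmean.tsv`` / ``<stem>.surrsd.tsv``.  A small JSON sidecar
    records band/subject/state metadata.
    """
    path = Path(path)
    s = matrix.strengths
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ChannelCountError(
            f"connectivity matrix must be square, got {s.shape}"
        )
    n = s.shape[0]
    ids = [str(i) for i in range(1, n + 1)]

    def _grid(values: np.ndarray, fmt) -> pd.DataFrame:
        rows = []
        for i in range(n):
            row = []
            for j in range(n):
                if i == j:
                    row.append("NA")
                else:
                    row.append(fmt(values[i, j]))
            rows.append(row)
        return pd.DataFrame(rows, index=ids, columns=ids)

    def _num(x) -> str:
        return "NA" if not np.isfinite(x) else f"{x:.6g}"

    _grid(s, _num).to_csv(path, sep="\t", index_label="source")
    if matrix.mask is not None:
        _grid(matrix.mask, lambda v: str(int(v))).to_csv(
            _companion(path, "mask"), sep="\t", index_label="source"
        )
    if matrix.surrogate_mean is not None:
        _grid(matrix.surrogate_mean, _num).to_csv(
            _companion(path, "surrmean"), sep="\t", index_label="source"
        )
    if matrix.surrogate_sd is not None:
        _grid(matrix.surrogate_sd, _num).to_csv(
            _companion(path, "surrsd"), sep="\t", index_label="source"
        )
    meta = {
        "band": matrix.band, "subject_id": matrix.subject_id,
        "state": matrix.state, "threshold_sd": matrix.threshold_sd,
        "n_channels": n,
    }
    _companion(path, "meta").with_suffix(".json").write_text(
        json.dumps(meta, indent=1, sort_keys=True)
    )
    return path


def read_connectivity(path: str | Path):
    """Read a connectivity TSV (+ companions) back into a ConnectivityMatrix."""
    from .bayesian import ConnectivityMatrix

    path = Path(path)

    def _load(p: Path) -> np.ndarray:
        df = pd.read_csv(p, sep="\t", index_col=0, na_values="NA")
        return df.to_numpy(dtype=float)

    strengths = _load(path)
    mask_path = _companion(path, "mask")
    mask = None
    if mask_path.exists():
        m = _load(mask_path)
        mask = np.where(np.isnan(m), False, m > 0.5)
    mean_path = _companion(path, "surrmean")
    sd_path = _companion(path, "surrsd")
    meta_path = _companion(path, "meta").with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ConnectivityMatrix(
        strengths=strengths,
        mask=mask,
        surrogate_mean=_load(mean_path) if mean_path.exists() else None,
        surrogate_sd=_load(sd_path) if sd_path.exists() else None,
        band=meta.get("band"),
        subject_id=meta.get("subject_id", ""),
        state=meta.get("state", ""),
        threshold_sd=meta.get("threshold_sd"),
    )


def _companion(path: Path, tag: str) -> Path:
    return path.with_name(path.stem + f".{tag}" + path.suffix)
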