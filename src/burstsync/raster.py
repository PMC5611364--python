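"""Core spike-raster data model: per-unit spike trains, binning, readers and QC.

Spike times are kept as integer milliseconds (extracellular sorters assign
spike times at sub-ms resolution; everything downstream here operates on a
1 ms grid, so times are rounded to the nearest ms on load). All intervals
and bins follow the half-open convention [start, end).
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

LAYER_GROUPS = ("L2_4", "L5_6")
UNIT_CLASSES = ("single", "multi")

__all__ = [
    "SpikeTrain",
    "BinnedRaster",
    "round_to_ms",
    "load_spike_table",
    "write_spike_table",
    "load_phy",
    "bin_spikes",
    "total_mua",
    "qc_refractory_fraction",
    "single_units",
    "LAYER_GROUPS",
    "UNIT_CLASSES",
]


def round_to_ms(times_ms: np.ndarray) -> np.ndarray:
    """Round float millisecond times to integer ms, ties away from zero.

    ``np.round`` rounds half to even; sorter output is conventionally rounded
    half up (away from zero for positive times), so 1000.5 -> 1001.
    """
    t = np.asarray(times_ms, dtype=float)
    return np.floor(t + 0.5).astype(np.int64)


@dataclass
class SpikeTrain:
    """Spike times of one sorted cluster plus its metadata labels.

    Parameters
    ----------
    unit_id : str
        Opaque cluster label.
    spike_times : ndarray of int64
        Sorted spike times in ms, each in ``[0, recording_duration)``.
        Duplicate times are permitted (they collapse on binarization).
    layer_group : {"L2_4", "L5_6"}
        Cortical layer group the cluster was localized to (an input label;
        layer identification itself is upstream of this package).
    unit_class : {"single", "multi"}
        Whether the cluster is a well-isolated single unit or multi-unit.
    recording_duration : int
        Recording length in ms.
    """

    unit_id: str
    spike_times: np.ndarray
    layer_group: str
    unit_class: str
    recording_duration: int

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=np.int64)
        if self.spike_times.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if np.any(np.diff(self.spike_times) < 0):
            self.spike_times = np.sort(self.spike_times)
        if self.layer_group not in LAYER_GROUPS:
            raise ValueError(f"unknown layer_group {self.layer_group!r}")
        if self.unit_class not in UNIT_CLASSES:
            raise ValueError(f"unknown unit_class {self.unit_class!r}")
        if self.spike_times.size and (
            self.spike_times[0] < 0
            or self.spike_times[-1] >= self.recording_duration
        ):
            raise ValueError(
                f"unit {self.unit_id}: spike times outside "
                f"[0, {self.recording_duration})"
            )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def rate_hz(self) -> float:
        if self.recording_duration == 0:
            return float("nan")
        return 1000.0 * self.n_spikes / self.recording_duration

    def with_times(self, times: np.ndarray) -> "SpikeTrain":
        """Copy of this unit with replaced spike times (sorted on entry)."""
        return replace(self, spike_times=np.sort(np.asarray(times, np.int64)))


def single_units(units: Sequence[SpikeTrain]) -> list[SpikeTrain]:
    """The good single-unit subset of a cluster collection."""
    return [u for u in units if u.unit_class == "single"]


@dataclass
class BinnedRaster:
    """Units x bins count (or binary) matrix on a regular time grid.

    Bin ``i`` covers ``[bin_origin + i*bin_width, bin_origin + (i+1)*bin_width)``
    in ms. A trailing partial bin is never represented.
    """

    matrix: np.ndarray
    bin_width: int
    unit_ids: list[str] = field(default_factory=list)
    bin_origin: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix))
        if not self.unit_ids:
            self.unit_ids = [f"u{i}" for i in range(self.matrix.shape[0])]
        if len(self.unit_ids) != self.matrix.shape[0]:
            raise ValueError("unit_ids length must match matrix rows")

    @property
    def n_units(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    def binarized(self) -> "BinnedRaster":
        """Elementwise indicator of count > 0 (lossy for multi-spike bins)."""
        return BinnedRaster(
            (self.matrix > 0).astype(np.uint8),
            self.bin_width,
            list(self.unit_ids),
            self.bin_origin,
        )

    def bin_times(self) -> np.ndarray:
        """Left edge (ms) of every bin."""
        return self.bin_origin + self.bin_width * np.arange(self.n_bins)


def bin_spikes(
    units: Sequence[SpikeTrain],
    bin_width: int,
    binarize: bool = False,
    bin_origin: int = 0,
) -> BinnedRaster:
    """Bin a spike-train collection onto a common grid.

    The grid starts at ``bin_origin`` and the last partial bin is dropped, so
    every bin covers a full ``bin_width`` ms.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1 ms")
    if not units:
        return BinnedRaster(np.zeros((0, 0), np.int64), bin_width, [], bin_origin)
    duration = max(u.recording_duration for u in units)
    n_bins = max((duration - bin_origin) // bin_width, 0)
    mat = np.zeros((len(units), n_bins), dtype=np.int64)
    hi = bin_origin + n_bins * bin_width
    for i, u in enumerate(units):
        t = u.spike_times
        t = t[(t >= bin_origin) & (t < hi)]
        idx = (t - bin_origin) // bin_width
        np.add.at(mat[i], idx, 1)
    if binarize:
        mat = (mat > 0).astype(np.uint8)
    return BinnedRaster(mat, bin_width, [u.unit_id for u in units], bin_origin)


def total_mua(units: Sequence[SpikeTrain], bin_width: int = 1) -> BinnedRaster:
    """Total multi-unit activity: the per-bin spike sum over all clusters.

    This is the tMUA signal that drives down-state detection; it pools both
    single- and multi-unit clusters.
    """
    binned = bin_spikes(units, bin_width)
    return BinnedRaster(
        binned.matrix.sum(axis=0, keepdims=True),
        bin_width,
        ["tMUA"],
        binned.bin_origin,
    )


def qc_refractory_fraction(unit: SpikeTrain, violation_ms: float = 2.0) -> float:
    """Fraction of inter-spike intervals strictly below ``violation_ms``.

    The standard cluster-quality gate: a well-isolated unit should show
    essentially no ISIs inside the refractory period; clusters are kept as
    "good" when this fraction is below 1%. Returns NaN for <2 spikes.
    """
    if unit.n_spikes < 2:
        return float("nan")
    isis = np.diff(unit.spike_times)
    return float(np.mean(isis < violation_ms))


def is_good_unit(unit: SpikeTrain, violation_ms: float = 2.0,
                 max_fraction: float = 0.01) -> bool:
    """Apply the <1% refractory-violation criterion."""
    frac = qc_refractory_fraction(unit, violation_ms)
    return bool(np.isfinite(frac) and frac < max_fraction)


# ---------------------------------------------------------------------------
# I/O: plain spike-table TSV and phy/KlustaSuite-style sorted output
# ---------------------------------------------------------------------------

_TABLE_COLUMNS = ("unit_id", "time_ms", "layer_group", "unit_class")


def load_spike_table(path: str | Path) -> list[SpikeTrain]:
    """Read the plain spike-table format.

    TSV with header ``unit_id  time_ms  layer_group  unit_class`` and an
    optional ``#duration_ms=<int>`` comment line before the header. Times may
    be fractional ms; they are rounded on load. Unparseable rows and unknown
    layer labels are hard errors reported with their line number.
    """
    path = Path(path)
    duration: int | None = None
    header: list[str] | None = None
    rows: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("duration_ms="):
                    duration = int(float(body.split("=", 1)[1]))
                continue
            parts = line.split("\t")
            if header is None:
                header = [p.strip() for p in parts]
                missing = set(_TABLE_COLUMNS) - set(header)
                if missing:
                    raise ValueError(
                        f"{path}:{lineno}: missing columns {sorted(missing)}"
                    )
                continue
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, "
                    f"got {len(parts)}"
                )
            rec = dict(zip(header, parts))
            try:
                t = float(rec["time_ms"])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad time {rec['time_ms']!r}") from exc
            if rec["layer_group"] not in LAYER_GROUPS:
                raise ValueError(
                    f"{path}:{lineno}: unknown layer label {rec['layer_group']!r}"
                )
            if rec["unit_class"] not in UNIT_CLASSES:
                raise ValueError(
                    f"{path}:{lineno}: unknown unit class {rec['unit_class']!r}"
                )
            uid = rec["unit_id"]
            entry = rows.setdefault(
                uid,
                {"times": [], "layer": rec["layer_group"], "cls": rec["unit_class"]},
            )
            if entry["layer"] != rec["layer_group"] or entry["cls"] != rec["unit_class"]:
                raise ValueError(f"{path}:{lineno}: inconsistent labels for {uid!r}")
            entry["times"].append(t)
    units = []
    for uid, entry in rows.items():
        times = round_to_ms(np.array(entry["times"], dtype=float))
        dur = duration if duration is not None else (
            int(times.max()) + 1 if times.size else 0
        )
        units.append(
            SpikeTrain(uid, np.sort(times), entry["layer"], entry["cls"], dur)
        )
    if duration is not None:
        for u in units:
            u.recording_duration = duration
    return units


def write_spike_table(path: str | Path, units: Iterable[SpikeTrain]) -> None:
    """Write the spike-table TSV (round-trips exactly with `load_spike_table`)."""
    units = list(units)
    with open(path, "w") as fh:
        if units:
            fh.write(f"#duration_ms={max(u.recording_duration for u in units)}\n")
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for u in units:
            for t in u.spike_times:
                fh.write(f"{u.unit_id}\t{int(t)}\t{u.layer_group}\t{u.unit_class}\n")


def load_phy(
    directory: str | Path,
    duration_ms: int | None = None,
) -> list[SpikeTrain]:
    """Read a phy/KlustaSuite-style sorted directory.

    Expects the two-array layout plus sidecars:

    - ``spike_times.npy``   per-spike sample index (int)
    - ``spike_clusters.npy`` per-spike cluster id (int)
    - ``cluster_group.tsv``  columns ``cluster_id  group`` with group in
      {good, mua} (noise clusters are simply absent or labelled ``noise``
      and skipped)
    - ``cluster_layers.tsv`` columns ``cluster_id  layer_group`` (L2_4/L5_6)
    - ``params.py``          must define ``sample_rate``

    Sample indices are converted to ms at the stated sampling rate and
    rounded to the nearest ms.
    """
    directory = Path(directory)
    sample_rate = _read_params_sample_rate(directory / "params.py")
    spike_samples = np.load(directory / "spike_times.npy").ravel()
    spike_clusters = np.load(directory / "spike_clusters.npy").ravel()
    if spike_samples.shape != spike_clusters.shape:
        raise ValueError("spike_times and spike_clusters length mismatch")
    groups = _read_two_col_tsv(directory / "cluster_group.tsv", "group")
    layers = _read_two_col_tsv(directory / "cluster_layers.tsv", "layer_group")
    times_ms = round_to_ms(spike_samples.astype(float) * 1000.0 / sample_rate)
    if duration_ms is None:
        duration_ms = int(times_ms.max()) + 1 if times_ms.size else 0
    class_map = {"good": "single", "mua": "multi"}
    units = []
    for cid, group in sorted(groups.items()):
        if group not in class_map:
            continue  # noise / unsorted clusters are dropped
        if cid not in layers:
            raise ValueError(f"cluster {cid} has no layer_group assignment")
        if layers[cid] not in LAYER_GROUPS:
            raise ValueError(f"cluster {cid}: unknown layer label {layers[cid]!r}")
        t = np.sort(times_ms[spike_clusters == int(cid)])
        units.append(
            SpikeTrain(str(cid), t, layers[cid], class_map[group], duration_ms)
        )
    return units


def _read_params_sample_rate(path: Path) -> float:
    for lineno, line in enumerate(open(path), start=1):
        line = line.split("#")[0].strip()
        if line.startswith("sample_rate"):
            try:
                return float(ast.literal_eval(line.split("=", 1)[1].strip()))
            except (ValueError, SyntaxError) as exc:
                raise ValueError(f"{path}:{lineno}: bad sample_rate") from exc
    raise ValueError(f"{path}: no sample_rate definition found")


def _read_two_col_tsv(path: Path, value_col: str) -> dict[int, str]:
    out: dict[int, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if "cluster_id" not in header or value_col not in header:
            raise ValueError(f"{path}: expected columns cluster_id, {value_col}")
        ci, vi = header.index("cluster_id"), header.index(value_col)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                out[int(parts[ci])] = parts[vi]
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: unparseable row") from exc
    return out
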