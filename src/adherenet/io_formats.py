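"""Delimited-text I/O, domain containers, and run configuration.

The pipeline's entry point is parcellated data: per-participant ROI time-series
matrices (rows = timepoints, columns = ROIs), a two-column ROI -> resting-state
network affiliation table, and an adherence table (homework assignments
completed out of 20, classes attended out of 4). No neuroimaging binary formats
are read; everything is comma- or tab-delimited text with the dialect sniffed
from the first line.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AffiliationCoverageError,
    ConfigError,
    DuplicateParticipantError,
    ManifestError,
    MissingTimeseriesError,
    NetworkCountError,
    NonNumericCellError,
    RaggedMatrixError,
    RoiCountMismatchError,
    UnknownRoiError,
)

logger = logging.getLogger("adherenet")

#: Canonical resting-state network names, in reporting order.
CANONICAL_NETWORKS = (
    "subcortical",
    "sensory",
    "default_mode",
    "attention_executive",
    "language_memory",
)

GROUPS = ("meditation", "writing")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoiTimeSeriesSet:
    """One participant's BOLD-like series: timepoints x ROIs with labels."""

    participant_id: str
    series: np.ndarray
    roi_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        series = np.asarray(self.series, dtype=float)
        object.__setattr__(self, "series", series)
        object.__setattr__(self, "roi_labels", tuple(self.roi_labels))
        if series.ndim != 2:
            raise ValueError("series must be a 2-D timepoints x ROI matrix")
        n_t, n_roi = series.shape
        if n_roi < 2:
            raise ValueError("need at least 2 ROIs")
        if n_t < 3:
            raise ValueError("need at least 3 timepoints")
        if len(self.roi_labels) != n_roi:
            raise ValueError("roi_labels length must match number of columns")
        if len(set(self.roi_labels)) != n_roi:
            raise ValueError("roi_labels must be unique")
        if not np.isfinite(series).all():
            raise ValueError("series contains missing/non-finite values")

    @property
    def n_roi(self) -> int:
        return self.series.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[0]


@dataclass(frozen=True)
class AffiliationVector:
    """ROI label -> resting-state network name mapping."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mapping", dict(self.mapping))

    @property
    def networks(self) -> tuple[str, ...]:
        seen: list[str] = []
        for name in self.mapping.values():
            if name not in seen:
                seen.append(name)
        return tuple(seen)

    def network_of(self, roi: str) -> str:
        try:
            return self.mapping[roi]
        except KeyError as exc:
            raise AffiliationCoverageError(f"ROI {roi!r} has no affiliation") from exc

    def labels_for(self, network: str) -> tuple[str, ...]:
        return tuple(r for r, s in self.mapping.items() if s == network)

    def indices(self, roi_labels: Sequence[str]) -> np.ndarray:
        """Integer network index per ROI, following ``self.networks`` order."""
        order = {name: i for i, name in enumerate(self.networks)}
        return np.array([order[self.network_of(r)] for r in roi_labels], dtype=int)


@dataclass(frozen=True)
class AdherenceRecord:
    """Per-participant adherence: homework completed (0-20), classes (0-4)."""

    participant_id: str
    group: str
    homework: int
    attendance: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if not 0 <= int(self.homework) <= 20:
            raise ValueError("homework must be in [0, 20]")
        if not 0 <= int(self.attendance) <= 4:
            raise ValueError("attendance must be in [0, 4]")
        object.__setattr__(self, "homework", int(self.homework))
        object.__setattr__(self, "attendance", int(self.attendance))


def default_threshold_grid() -> tuple[float, ...]:
    """The standard sparsity sweep: T = 0.05 to 0.50 in steps of 0.05."""
    return tuple(np.round(np.arange(1, 11) * 0.05, 2))


@dataclass(frozen=True)
class RunConfig:
    """Tunable analysis parameters with the study's standard defaults.

    threshold_grid : correlation cutoffs for binarization, strictly increasing,
        both endpoints included (default 0.05 ... 0.50 step 0.05).
    n_perm : permutations per correlation test (default 1000).
    fdr_q : Benjamini-Hochberg false-discovery rate (default 0.05).
    min_sig_thresholds : thresholds at which a node must stay significant after
        FDR to count as robust (default 3; set to len(threshold_grid) for the
        strict full-range rule).
    homework_cutoff : homework count above which a participant is labelled
        high-adherence (strict >, default 10).
    holdout_fraction : fraction of participants held out for classifier
        evaluation (default 0.25).
    seeds : seeds for classifier-internal randomness (default 5 seeds).
    louvain_reps : independent Louvain repetitions averaged into mean Q
        (default 150).
    """

    threshold_grid: tuple[float, ...] = field(default_factory=default_threshold_grid)
    n_perm: int = 1000
    fdr_q: float = 0.05
    min_sig_thresholds: int = 3
    homework_cutoff: int = 10
    holdout_fraction: float = 0.25
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    louvain_reps: int = 150
    absolute_threshold: bool = False
    pairwise_between: bool = False

    def __post_init__(self) -> None:
        grid = tuple(float(t) for t in self.threshold_grid)
        object.__setattr__(self, "threshold_grid", grid)
        object.__setattr__(self, "seeds", tuple(int(s) for s in self.seeds))
        if len(grid) == 0:
            raise ConfigError("threshold_grid must be non-empty")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ConfigError("threshold_grid must be strictly increasing")
        if any(t > 0.5 for t in grid):
            warnings.warn(
                "thresholds above 0.5 risk overestimating noisy, weak or "
                "physiologically insignificant connections",
                UserWarning,
                stacklevel=2,
            )
        if self.n_perm < 1:
            raise ConfigError("n_perm must be positive")
        if not 0.0 < self.fdr_q < 1.0:
            raise ConfigError("fdr_q must be in (0, 1)")
        if self.min_sig_thresholds < 1:
            raise ConfigError("min_sig_thresholds must be positive")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ConfigError("holdout_fraction must be in (0, 1)")
        if self.louvain_reps < 1:
            raise ConfigError("louvain_reps must be positive")

    def with_overrides(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Delimited parsing helpers
# ---------------------------------------------------------------------------

def _sniff_delimiter(first_line: str) -> str:
    return "\t" if "\t" in first_line else ","


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_matrix(path: str | Path) -> tuple[np.ndarray, tuple[str, ...] | None]:
    """Read a delimited numeric matrix, returning (values, header or None).

    The file may carry a single header row of column labels; the header is
    detected by the first row failing numeric conversion. Raises
    :class:`RaggedMatrixError` / :class:`NonNumericCellError` with the
    offending row and column named.
    """
    path = Path(path)
    if not path.exists():
        raise MissingTimeseriesError(f"file not found: {path}")
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise RaggedMatrixError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        fh.seek(0)
        rows = [row for row in csv.reader(fh, delimiter=delim) if row]

    header: tuple[str, ...] | None = None
    if not all(_is_number(tok) for tok in rows[0]):
        header = tuple(tok.strip() for tok in rows[0])
        rows = rows[1:]
    if not rows:
        raise RaggedMatrixError(f"{path}: no data rows")

    width = len(rows[0])
    data = np.empty((len(rows), width), dtype=float)
    for i, row in enumerate(rows):
        if len(row) != width:
            raise RaggedMatrixError(
                f"{path}: row {i + 1} has {len(row)} cells, expected {width}"
            )
        for j, tok in enumerate(row):
            try:
                data[i, j] = float(tok)
            except ValueError as exc:
                raise NonNumericCellError(
                    f"{path}: non-numeric cell at row {i + 1}, column {j + 1}: {tok!r}"
                ) from exc
    if header is not None and len(header) != width:
        raise RaggedMatrixError(f"{path}: header width differs from data width")
    return data, header


def write_matrix(path: str | Path, values: np.ndarray,
                 header: Sequence[str] | None = None, delimiter: str = "\t") -> None:
    values = np.asarray(values, dtype=float)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        if header is not None:
            writer.writerow(list(header))
        for row in values:
            writer.writerow([format(v, ".10g") for v in row])


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("participant_id", "group", "homework", "attendance", "timeseries_path")


def read_cohort(manifest_path: str | Path) -> tuple[list[RoiTimeSeriesSet], list[AdherenceRecord]]:
    """Load a cohort from a manifest table.

    The manifest columns are participant_id, group, homework, attendance and
    timeseries_path (relative paths resolved against the manifest's
    directory). ROI label order is fixed by the first file; all later files
    must match its labels (or, when headerless, its column count) exactly.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise ManifestError(f"manifest not found: {manifest_path}")
    with open(manifest_path, newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise ManifestError(f"{manifest_path}: empty manifest")
        delim = _sniff_delimiter(first)
    table = pd.read_csv(manifest_path, sep=delim, dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(table.columns)
    if missing:
        raise ManifestError(f"{manifest_path}: missing columns {sorted(missing)}")

    ids = table["participant_id"].tolist()
    dupes = {p for p in ids if ids.count(p) > 1}
    if dupes:
        raise DuplicateParticipantError(f"duplicate participant ids: {sorted(dupes)}")

    ts_sets: list[RoiTimeSeriesSet] = []
    records: list[AdherenceRecord] = []
    ref_labels: tuple[str, ...] | None = None
    for _, row in table.iterrows():
        ts_path = Path(row["timeseries_path"])
        if not ts_path.is_absolute():
            ts_path = manifest_path.parent / ts_path
        values, header = read_matrix(ts_path)
        if ref_labels is None:
            labels = header or tuple(f"ROI_{j:03d}" for j in range(values.shape[1]))
            ref_labels = labels
        else:
            if values.shape[1] != len(ref_labels):
                raise RoiCountMismatchError(
                    f"{ts_path}: {values.shape[1]} ROIs, expected {len(ref_labels)} "
                    f"(set by the first manifest entry)"
                )
            if header is not None and tuple(header) != ref_labels:
                raise RoiCountMismatchError(
                    f"{ts_path}: ROI labels differ from the first manifest entry"
                )
        try:
            ts_sets.append(RoiTimeSeriesSet(row["participant_id"], values, ref_labels))
        except ValueError as exc:
            raise NonNumericCellError(f"{ts_path}: {exc}") from exc
        records.append(
            AdherenceRecord(
                participant_id=row["participant_id"],
                group=row["group"],
                homework=int(row["homework"]),
                attendance=int(row["attendance"]),
            )
        )
    return ts_sets, records


def write_cohort(out_dir: str | Path,
                 ts_sets: Sequence[RoiTimeSeriesSet],
                 records: Sequence[AdherenceRecord],
                 affiliation: AffiliationVector | None = None) -> Path:
    """Write manifest + per-participant series (+ affiliation); returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_id = {r.participant_id: r for r in records}
    rows = []
    for ts in ts_sets:
        rec = by_id[ts.participant_id]
        fname = f"timeseries_{ts.participant_id}.tsv"
        write_matrix(out_dir / fname, ts.series, header=ts.roi_labels)
        rows.append(
            {
                "participant_id": rec.participant_id,
                "group": rec.group,
                "homework": rec.homework,
                "attendance": rec.attendance,
                "timeseries_path": fname,
            }
        )
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(manifest, sep="\t", index=False)
    if affiliation is not None:
        write_affiliations(out_dir / "affiliations.tsv", affiliation)
    return manifest


# ---------------------------------------------------------------------------
# Affiliations
# ---------------------------------------------------------------------------

def read_affiliations(path: str | Path, roi_labels: Sequence[str],
                      strict: bool = False) -> AffiliationVector:
    """Read a two-column (roi_label, network_name) table covering roi_labels.

    Exactly five networks are expected; a different count is a warning, or an
    error under ``strict``.
    """
    path = Path(path)
    if not path.exists():
        raise AffiliationCoverageError(f"affiliation file not found: {path}")
    with open(path, newline="") as fh:
        first = fh.readline()
        delim = _sniff_delimiter(first)
        fh.seek(0)
        rows = [row for row in csv.reader(fh, delimiter=delim) if row]
    if rows and rows[0] and rows[0][0].strip().lower() in {"roi", "roi_label", "label"}:
        rows = rows[1:]
    mapping: dict[str, str] = {}
    for row in rows:
        if len(row) != 2:
            raise AffiliationCoverageError(f"{path}: expected 2 columns, got {len(row)}")
        mapping[row[0].strip()] = row[1].strip()

    known = set(roi_labels)
    extra = set(mapping) - known
    if extra:
        raise UnknownRoiError(f"{path}: unknown ROIs {sorted(extra)[:5]}")
    missing = [r for r in roi_labels if r not in mapping]
    if missing:
        raise AffiliationCoverageError(
            f"{path}: ROIs without affiliation: {missing[:5]}"
        )
    n_networks = len(set(mapping.values()))
    if n_networks != 5:
        msg = f"{path}: expected 5 resting-state networks, found {n_networks}"
        if strict:
            raise NetworkCountError(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
    ordered = {r: mapping[r] for r in roi_labels}
    return AffiliationVector(ordered)


def write_affiliations(path: str | Path, affiliation: AffiliationVector) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["roi_label", "network_name"])
        for roi, network in affiliation.mapping.items():
            writer.writerow([roi, network])


# ---------------------------------------------------------------------------
# Run provenance
# ---------------------------------------------------------------------------

def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_run_record(out_dir: str | Path, cfg: RunConfig, seed: int | None,
                     inputs: Iterable[str | Path] = (), extra: dict | None = None) -> Path:
    """Persist config, seed and input digests so a run can be re-executed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "config": {
            "threshold_grid": list(cfg.threshold_grid),
            "n_perm": cfg.n_perm,
            "fdr_q": cfg.fdr_q,
            "min_sig_thresholds": cfg.min_sig_thresholds,
            "homework_cutoff": cfg.homework_cutoff,
            "holdout_fraction": cfg.holdout_fraction,
            "seeds": list(cfg.seeds),
            "louvain_reps": cfg.louvain_reps,
            "absolute_threshold": cfg.absolute_threshold,
            "pairwise_between": cfg.pairwise_between,
        },
        "seed": seed,
        "inputs": {str(p): _digest(Path(p)) for p in inputs if Path(p).exists()},
    }
    if extra:
        record.update(extra)
    path = out_dir / "run_record.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True))
    return path
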