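"""Synthetic modular BOLD cohorts with adherence coupled to network structure.

The generator plants exactly the statistical structure the downstream analysis
is meant to detect. Each participant p draws a within-module coupling weight
w_p ~ Normal(coupling_mean, coupling_sd^2) truncated at 0. Each of the five
resting-state networks gets an independent latent Gaussian series; one global
series is shared by all ROIs. ROI i in network s then follows

    x_i(t) = w_p * latent_s(t) + global_weight * global(t) + Normal(0, noise_sd^2)

so within-network correlation rises with w_p while between-network correlation
(carried only by the shared global series) falls, mirroring a brain whose
subsystems are more or less segregated. Adherence is coupled linearly to the
same scalar:

    homework_p = round(clip(a + effect_slope * w_p + eps, 0, 20)),  a = 10 - b*w_mean

and analogously for attendance on its 0-4 scale, so the expected cohort means
sit mid-scale. Rounding and clipping make ties and ceiling effects possible on
purpose; they stress the permutation machinery the way bounded counts do in
real adherence data. A null cohort sets both slopes to 0 and leaves everything
else untouched.

The cohort size defaults to 51 participants split 29 (meditation) / 22
(writing); both groups share generative parameters unless per-group slope
overrides are given.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import numpy as np

from .errors import DegenerateParamsError
from .io_formats import (
    AdherenceRecord,
    AffiliationVector,
    CANONICAL_NETWORKS,
    RoiTimeSeriesSet,
)

#: Default 131-ROI split over the five canonical resting-state networks.
DEFAULT_NETWORK_SIZES = (17, 30, 28, 30, 26)


@dataclass(frozen=True)
class SimParams:
    """Generative parameters for one synthetic cohort.

    effect_slope (homework per unit coupling) defaults to a value calibrated so
    that the pooled-cohort correlation between mean clustering and homework is
    about 0.3 at the default noise level -- the order of magnitude a real
    51-participant resting-state cohort shows for such global metrics.
    """

    n_participants: int = 51
    group_sizes: tuple[int, int] = (29, 22)
    n_roi: int = 131
    n_timepoints: int = 145
    network_sizes: tuple[int, ...] = DEFAULT_NETWORK_SIZES
    coupling_mean: float = 1.0
    coupling_sd: float = 0.3
    global_weight: float = 0.5
    noise_sd: float = 1.0
    effect_slope: float = 3.5
    effect_noise_sd: float = 3.0
    attendance_slope: float = 1.2
    attendance_noise_sd: float = 0.8
    homework_max: int = 20
    attendance_max: int = 4
    group_effect_slopes: tuple[float, float] | None = None
    coupled_networks: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "network_sizes", tuple(int(s) for s in self.network_sizes))
        if self.n_participants < 3:
            raise DegenerateParamsError("inference requires >= 3 participants")
        if sum(self.group_sizes) != self.n_participants:
            raise DegenerateParamsError("group_sizes must sum to n_participants")
        if sum(self.network_sizes) != self.n_roi:
            raise DegenerateParamsError("network_sizes must sum to n_roi")
        if any(s < 2 for s in self.network_sizes):
            raise DegenerateParamsError("every network needs >= 2 ROIs")
        for name in ("coupling_sd", "noise_sd", "effect_noise_sd", "attendance_noise_sd"):
            if getattr(self, name) < 0:
                raise DegenerateParamsError(f"{name} must be >= 0")
        if self.noise_sd == 0 and self.coupling_sd == 0:
            raise DegenerateParamsError(
                "noise_sd = 0 with coupling_sd = 0 makes all series collinear"
            )


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort plus the parameters that produced it (provenance)."""

    ts_sets: tuple[RoiTimeSeriesSet, ...]
    records: tuple[AdherenceRecord, ...]
    affiliation: AffiliationVector
    params: SimParams
    coupling: tuple[float, ...] = field(default_factory=tuple)

    def __iter__(self):
        # unpacks like the (time series, adherence, affiliation) triple
        return iter((list(self.ts_sets), list(self.records), self.affiliation))


def _roi_labels(params: SimParams) -> tuple[str, ...]:
    return tuple(f"ROI_{j:03d}" for j in range(params.n_roi))


def make_affiliation(params: SimParams) -> AffiliationVector:
    """Block assignment of ROIs to the five canonical networks."""
    labels = _roi_labels(params)
    mapping: dict[str, str] = {}
    j = 0
    for size, network in zip(params.network_sizes, CANONICAL_NETWORKS):
        for _ in range(size):
            mapping[labels[j]] = network
            j += 1
    return AffiliationVector(mapping)


def _bounded_count(rng: np.random.Generator, w: np.ndarray, slope,
                   noise_sd: float, maximum: int, expected_w: float) -> np.ndarray:
    # intercept puts the expected mean at mid-scale before rounding/clipping
    slope = np.broadcast_to(np.asarray(slope, dtype=float), w.shape)
    intercept = maximum / 2.0 - float(np.mean(slope)) * expected_w
    raw = intercept + slope * w + rng.normal(0.0, noise_sd, size=w.shape)
    return np.clip(np.rint(raw), 0, maximum).astype(int)


def simulate_cohort(params: SimParams) -> SyntheticCohort:
    """Generate a full cohort: time series, adherence records, affiliations.

    Deterministic for a given ``params.seed``. The returned object unpacks as
    the (ts_sets, records, affiliation) triple and additionally carries the
    per-participant coupling weights and the generating parameters.
    """
    rng = np.random.default_rng(params.seed)
    labels = _roi_labels(params)
    affiliation = make_affiliation(params)
    network_idx = affiliation.indices(labels)

    n = params.n_participants
    w = rng.normal(params.coupling_mean, params.coupling_sd, size=n)
    w = np.abs(w)  # truncate at zero (reflect; mass below 0 is tiny at defaults)

    groups = (["meditation"] * params.group_sizes[0] + ["writing"] * params.group_sizes[1])
    slopes = np.full(n, params.effect_slope)
    if params.group_effect_slopes is not None:
        slopes = np.where(np.array(groups) == "meditation",
                          params.group_effect_slopes[0], params.group_effect_slopes[1])

    coupled = set(range(len(params.network_sizes))
                  if params.coupled_networks is None else params.coupled_networks)

    ts_sets = []
    for p in range(n):
        latents = rng.standard_normal((len(params.network_sizes), params.n_timepoints))
        shared = rng.standard_normal(params.n_timepoints)
        noise = rng.normal(0.0, params.noise_sd, size=(params.n_timepoints, params.n_roi))
        per_roi_w = np.where(np.isin(network_idx, list(coupled)), w[p], params.coupling_mean)
        series = (per_roi_w * latents[network_idx].T
                  + params.global_weight * shared[:, None] + noise)
        ts_sets.append(RoiTimeSeriesSet(f"sub-{p + 1:03d}", series, labels))

    homework_all = _bounded_count(rng, w, slopes, params.effect_noise_sd,
                                  params.homework_max, params.coupling_mean)
    attendance = _bounded_count(rng, w, params.attendance_slope,
                                params.attendance_noise_sd, params.attendance_max,
                                params.coupling_mean)

    records = tuple(
        AdherenceRecord(ts.participant_id, grp, int(h), int(att))
        for ts, grp, h, att in zip(ts_sets, groups, homework_all, attendance)
    )
    return SyntheticCohort(tuple(ts_sets), records, affiliation, params,
                           coupling=tuple(w))


def simulate_null_cohort(params: SimParams) -> SyntheticCohort:
    """Same generative process with both adherence slopes forced to 0."""
    null_params = replace(params, effect_slope=0.0, attendance_slope=0.0,
                          group_effect_slopes=None)
    return simulate_cohort(null_params)
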