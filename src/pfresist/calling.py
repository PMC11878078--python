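"""Infection phenotyping: spot tests, growth curves, and final R/S calls.

An isolate x lytic-phage challenge is phenotyped in two stages, the way
the underlying assay works:

1. Triplicate spot test on a bacterial lawn. The spot is positive only
   when all three replicates show a spot (clear or turbid both count).
2. For spot-positive pairs only, a 24 h OD600 infection curve against an
   uninfected control. Infection is "productive" when the infected
   culture's density is significantly below the control within the
   control's exponential-growth window, by a one-sided Welch t-test on
   per-replicate window means, plus a minimum relative reduction that
   guards against trivially significant offsets.

A pair is Sensitive only when the spot is positive AND the infection is
productive; everything else (no spot, or spot without productive
infection — abortive infection / lysis-from-without) is Resistant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    AlignmentError,
    CoverageError,
    InputError,
    InsufficientReplicationError,
    NoGrowthError,
)

SpotGrade = Literal["clear", "turbid", "none"]
SPOT_GRADES: tuple[SpotGrade, ...] = ("clear", "turbid", "none")

#: Minimum sampling for a growth-curve call: at least this many time
#: points spanning at least this many hours.
MIN_POINTS = 8
MIN_SPAN_H = 12.0


@dataclass(frozen=True)
class SpotTriplicate:
    """Grades of the three spot-test replicates."""

    grades: tuple[SpotGrade, SpotGrade, SpotGrade]

    def __post_init__(self) -> None:
        if len(self.grades) != 3:
            raise InputError(f"spot test needs exactly 3 replicates, got {len(self.grades)}")
        bad = [g for g in self.grades if g not in SPOT_GRADES]
        if bad:
            raise InputError(f"invalid spot grades {bad}")


@dataclass(frozen=True)
class GrowthCurve:
    """One replicate OD600 time series for an infected or control well."""

    times: np.ndarray
    od: np.ndarray
    replicate_id: str = "rep1"
    condition: Literal["infected", "control"] = "control"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od", od)
        if times.ndim != 1 or times.shape != od.shape:
            raise InputError("times and od must be 1-D arrays of equal length")
        if len(times) >= 2 and not np.all(np.diff(times) > 0):
            raise InputError("times must be strictly increasing")
        if np.any(od < 0):
            raise InputError("OD600 values must be non-negative")


def call_spot(spots: SpotTriplicate) -> bool:
    """Positive iff every replicate shows a spot (clear or turbid)."""
    return all(g in ("clear", "turbid") for g in spots.grades)


def _common_grid(curves: Sequence[GrowthCurve]) -> tuple[np.ndarray, np.ndarray]:
    """Replicate-mean OD on the shared time grid (replicates must agree)."""
    if not curves:
        raise InputError("at least one growth curve required")
    times = curves[0].times
    for c in curves[1:]:
        if len(c.times) != len(times) or not np.allclose(c.times, times):
            raise InputError("replicate curves must share one sampling grid")
    return times, np.mean([c.od for c in curves], axis=0)


def detect_exponential_window(
    control: Sequence[GrowthCurve], threshold_frac: float = 0.5
) -> tuple[float, float]:
    """Exponential-phase time window of the uninfected control.

    The replicate-mean log-OD is smoothed with a 3-sample rolling mean
    and differentiated; the window is the contiguous interval around the
    fastest growth where the derivative stays at or above
    ``threshold_frac`` of its maximum.
    """
    if not 0 < threshold_frac <= 1:
        raise InputError("threshold_frac must be in (0, 1]")
    times, mean_od = _common_grid(control)
    if len(times) < MIN_POINTS or times[-1] - times[0] < MIN_SPAN_H:
        raise InputError(
            f"window detection needs >= {MIN_POINTS} points spanning >= {MIN_SPAN_H} h"
        )
    if mean_od.max() < 2 * mean_od[0] or mean_od[0] <= 0:
        raise NoGrowthError("control shows no growth (max OD < 2 x initial OD)")
    log_od = np.log(np.maximum(mean_od, 1e-9))
    kernel = np.ones(3) / 3
    smooth = np.convolve(log_od, kernel, mode="same")
    smooth[0], smooth[-1] = log_od[0], log_od[-1]  # edge effect of 'same' padding
    deriv = np.gradient(smooth, times)
    peak = int(np.argmax(deriv))
    cutoff = threshold_frac * deriv[peak]
    lo = peak
    while lo > 0 and deriv[lo - 1] >= cutoff:
        lo -= 1
    hi = peak
    while hi < len(times) - 1 and deriv[hi + 1] >= cutoff:
        hi += 1
    return float(times[lo]), float(times[hi])


@dataclass(frozen=True)
class ProductiveCall:
    productive: bool
    p_value: float
    mean_reduction: float


def call_productive_infection(
    infected: Sequence[GrowthCurve],
    control: Sequence[GrowthCurve],
    window: tuple[float, float],
    alpha: float = 0.05,
    min_reduction: float = 0.10,
) -> ProductiveCall:
    """Test whether infection measurably suppressed growth in the window.

    Per-replicate summaries are mean OD within ``window``; a one-sided
    unequal-variance (Welch) t-test asks whether infected < control.
    Productive requires both p <= alpha and a relative mean reduction of
    at least ``min_reduction``.
    """
    t0, t1 = window
    if t1 < t0:
        raise InputError("window end precedes window start")
    if len(infected) < 2 or len(control) < 2:
        raise InsufficientReplicationError(
            "need >= 2 replicates per condition for a significance call"
        )

    def window_means(curves: Sequence[GrowthCurve]) -> np.ndarray:
        means = []
        for c in curves:
            mask = (c.times >= t0) & (c.times <= t1)
            if not mask.any():
                raise AlignmentError(
                    f"window [{t0}, {t1}] h does not overlap curve "
                    f"{c.replicate_id} ({c.times[0]}-{c.times[-1]} h)"
                )
            means.append(float(c.od[mask].mean()))
        return np.asarray(means)

    inf_means = window_means(infected)
    ctrl_means = window_means(control)
    if np.ptp(inf_means) == 0 and np.ptp(ctrl_means) == 0 and inf_means[0] == ctrl_means[0]:
        p = 1.0  # identical constant replicates: no evidence of suppression
    else:
        p = float(
            stats.ttest_ind(
                inf_means, ctrl_means, equal_var=False, alternative="less"
            ).pvalue
        )
        if np.isnan(p):
            p = 1.0
    reduction = float(max(0.0, 1.0 - inf_means.mean() / ctrl_means.mean()))
    return ProductiveCall(
        productive=bool(p <= alpha and reduction >= min_reduction),
        p_value=p,
        mean_reduction=reduction,
    )


def final_call(spot_positive: bool, productive: Optional[bool]) -> Literal["R", "S"]:
    """Sensitive iff the spot is positive and the infection productive.

    ``productive`` must have been evaluated (non-None) whenever the spot
    was positive; a negative spot alone is Resistant.
    """
    if not spot_positive:
        return "R"
    if productive is None:
        raise InputError("spot-positive interaction requires a productive-infection call")
    return "S" if productive else "R"


@dataclass(frozen=True)
class InteractionCall:
    """Full provenance of one isolate x phage call."""

    isolate_id: str
    phage_id: str
    spot_positive: bool
    productive: Optional[bool] = None
    p_value: Optional[float] = None
    mean_reduction: Optional[float] = None
    final: Literal["R", "S"] = "R"


def call_interaction(
    isolate_id: str,
    phage_id: str,
    spots: SpotTriplicate,
    infected: Sequence[GrowthCurve] = (),
    control: Sequence[GrowthCurve] = (),
    alpha: float = 0.05,
    min_reduction: float = 0.10,
    threshold_frac: float = 0.5,
) -> InteractionCall:
    """Run the two-stage workflow for one interaction.

    Curve calling is skipped entirely (final R) when the spot is
    negative, mirroring the assay workflow where infection curves are
    run only for spot-positive combinations.
    """
    spot_positive = call_spot(spots)
    if not spot_positive:
        return InteractionCall(isolate_id, phage_id, spot_positive=False, final="R")
    window = detect_exponential_window(control, threshold_frac=threshold_frac)
    pc = call_productive_infection(
        infected, control, window, alpha=alpha, min_reduction=min_reduction
    )
    return InteractionCall(
        isolate_id,
        phage_id,
        spot_positive=True,
        productive=pc.productive,
        p_value=pc.p_value,
        mean_reduction=pc.mean_reduction,
        final=final_call(True, pc.productive),
    )


@dataclass
class ResistanceMatrix:
    """Complete isolate x phage grid of R/S calls with cell provenance."""

    data: pd.DataFrame
    provenance: dict[tuple[str, str], InteractionCall] = field(default_factory=dict)

    @property
    def isolate_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def phage_ids(self) -> list[str]:
        return list(self.data.columns)

    def counts(self) -> tuple[int, int, int]:
        """(total, resistant, sensitive) interaction counts."""
        values = self.data.to_numpy()
        n_r = int((values == "R").sum())
        n_s = int((values == "S").sum())
        return n_r + n_s, n_r, n_s

    def cell(self, isolate_id: str, phage_id: str) -> str:
        return str(self.data.at[isolate_id, phage_id])

    def to_tsv(self, path) -> None:
        self.data.rename_axis("isolate_id").to_csv(path, sep="\t", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path) -> "ResistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="isolate_id", dtype=str)
        bad = set(np.unique(df.to_numpy())) - {"R", "S"}
        if bad:
            raise InputError(f"resistance matrix contains invalid calls {sorted(bad)}")
        return cls(data=df)


def build_resistance_matrix(calls: Iterable[InteractionCall]) -> ResistanceMatrix:
    """Assemble calls into a complete matrix; reject gaps and duplicates."""
    calls = list(calls)
    if not calls:
        raise CoverageError("no interaction calls supplied")
    seen: dict[tuple[str, str], InteractionCall] = {}
    for call in calls:
        key = (call.isolate_id, call.phage_id)
        if key in seen:
            raise CoverageError(f"duplicate call for {key}")
        seen[key] = call
    isolates = sorted({k[0] for k in seen})
    phages = sorted({k[1] for k in seen})
    missing = [
        (iso, ph) for iso in isolates for ph in phages if (iso, ph) not in seen
    ]
    if missing:
        raise CoverageError(f"missing calls for {missing[:5]} (and possibly more)")
    df = pd.DataFrame(
        [[seen[(iso, ph)].final for ph in phages] for iso in isolates],
        index=pd.Index(isolates, name="isolate_id"),
        columns=phages,
    )
    return ResistanceMatrix(data=df, provenance=seen)
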