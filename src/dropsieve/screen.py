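"""Plate-scale screening logic: well aggregation, control-referenced hit
calling, screen summaries and titration tipping-point estimation.

Each well's five fields of view are collapsed to per-feature medians,
z-scored against the plate's DMSO control wells, and classified into one of
four phenotype classes: ``no_effect``, ``dissolution`` (condensates lost),
``enhancement`` (more/larger/brighter condensates), or ``other``
(shape/aggregation phenotypes detected through circularity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .segmentation import FieldSummary

__all__ = [
    "WELL_FEATURES",
    "PHENOTYPE_CLASSES",
    "WellResult",
    "ControlStats",
    "PhenotypeCall",
    "ScreenReport",
    "TitrationResult",
    "aggregate_well",
    "compute_control_stats",
    "classify_phenotype",
    "summarize_screen",
    "estimate_saturation_concentration",
    "saturation_fold_change",
]

# feature keys aggregated per well; granulometry moments ride along for QC
WELL_FEATURES = (
    "n_droplets",
    "total_droplet_intensity",
    "mean_diameter",
    "mean_circularity",
    "condensed_fraction",
    "size_mean",
    "size_variance",
    "size_skew",
    "size_kurtosis",
)

PHENOTYPE_CLASSES = ("no_effect", "dissolution", "enhancement", "other")


@dataclass
class WellResult:
    """Median-aggregated features of one well across its FOVs."""

    well: str
    n_fovs: int
    features: dict  # feature -> float (NaN when undefined in every FOV)
    qc_pass: bool = True


@dataclass
class ControlStats:
    """Per-feature mean and standard deviation over the DMSO control wells.

    Sample sd (n-1); to avoid dividing by zero when the controls are
    degenerate, the sd is floored at ``1e-6 * |mean|`` (with a tiny absolute
    floor for zero-mean features).
    """

    mean: dict
    sd: dict
    n_controls: int


@dataclass
class PhenotypeCall:
    well: str
    compound_id: str
    call: str  # one of PHENOTYPE_CLASSES
    z_scores: dict
    rationale: str


@dataclass
class ScreenReport:
    counts: dict  # class -> count
    percentages: dict  # class -> integer percent
    total_screened: int
    z_cut: float = 3.0
    withheld_wells: list = field(default_factory=list)


@dataclass
class TitrationResult:
    """Estimated saturation concentration of one titration series."""

    c_sat: Optional[float]
    reached: bool
    response_metric: str
    threshold_used: float


def _field_features(s: FieldSummary) -> dict:
    m = s.moments
    return {
        "n_droplets": float(s.n_droplets),
        "total_droplet_intensity": s.total_droplet_intensity,
        "mean_diameter": math.nan if s.mean_diameter is None else s.mean_diameter,
        "mean_circularity": math.nan if s.mean_circularity is None else s.mean_circularity,
        "condensed_fraction": s.condensed_fraction,
        "size_mean": m.mean if m is not None else math.nan,
        "size_variance": m.variance if m is not None else math.nan,
        "size_skew": m.skew if (m is not None and m.defined) else math.nan,
        "size_kurtosis": m.kurtosis if (m is not None and m.defined) else math.nan,
    }


def aggregate_well(field_summaries: Sequence[FieldSummary], well: str = "") -> WellResult:
    """Collapse a well's FOVs to per-feature medians.

    The median is robust to a single bad FOV (out of focus, dispensing
    artifact).  Features undefined in some FOVs (e.g. mean diameter of an
    empty field) are ignored in the median; a well fails QC when more than
    half of its FOVs have zero dynamic range.
    """
    if not field_summaries:
        raise ValueError("aggregate_well needs at least one field summary")
    per_fov = [_field_features(s) for s in field_summaries]
    features = {}
    for key in WELL_FEATURES:
        vals = np.array([f[key] for f in per_fov], dtype=float)
        features[key] = float(np.nanmedian(vals)) if not np.all(np.isnan(vals)) else math.nan
    n_blank = sum(1 for s in field_summaries if s.blank)
    qc_pass = n_blank <= len(field_summaries) / 2
    return WellResult(well=well, n_fovs=len(field_summaries), features=features, qc_pass=qc_pass)


def compute_control_stats(control_wells: Sequence[WellResult]) -> ControlStats:
    """Per-feature mean and sample sd over the control wells (>= 2 required)."""
    if len(control_wells) < 2:
        raise ValueError("insufficient controls: need at least 2 control wells")
    mean: dict = {}
    sd: dict = {}
    for key in WELL_FEATURES:
        vals = np.array([w.features.get(key, math.nan) for w in control_wells], dtype=float)
        vals = vals[~np.isnan(vals)]
        if len(vals) < 2:
            mean[key], sd[key] = math.nan, math.nan
            continue
        m = float(np.mean(vals))
        s = float(np.std(vals, ddof=1))
        floor = max(1e-6 * abs(m), 1e-12)
        mean[key], sd[key] = m, max(s, floor)
    return ControlStats(mean=mean, sd=sd, n_controls=len(control_wells))


def _z(well: WellResult, controls: ControlStats, key: str) -> float:
    v = well.features.get(key, math.nan)
    m, s = controls.mean.get(key, math.nan), controls.sd.get(key, math.nan)
    if any(map(math.isnan, (v, m, s))):
        return math.nan
    return (v - m) / s


def classify_phenotype(
    well: WellResult, controls: ControlStats, z_cut: float = 3.0, compound_id: str = ""
) -> PhenotypeCall:
    """Call a compound well's phenotype from control-referenced z-scores.

    Decision rules (precedence: dissolution > enhancement > other):

    * dissolution — condensed fraction z <= -z_cut, or both droplet count
      and total droplet intensity z <= -z_cut;
    * enhancement — condensed fraction z >= +z_cut, or both mean diameter
      and total droplet intensity z >= +z_cut;
    * other — neither of the above, but mean circularity z <= -z_cut
      (elongation/aggregation shape phenotypes);
    * no_effect otherwise.

    Wells that failed QC are not called here; the pipeline withholds them.
    """
    if not well.qc_pass:
        raise ValueError(f"well {well.well} failed QC; call withheld")
    z = {key: _z(well, controls, key) for key in WELL_FEATURES}

    def le(key: str, cut: float) -> bool:
        return not math.isnan(z[key]) and z[key] <= cut

    def ge(key: str, cut: float) -> bool:
        return not math.isnan(z[key]) and z[key] >= cut

    fired: list[str] = []
    # an empty well has no diameter/circularity; its condensed fraction and
    # count z-scores still fire, which is what dissolution keys on
    if le("condensed_fraction", -z_cut) or (le("n_droplets", -z_cut) and le("total_droplet_intensity", -z_cut)):
        call = "dissolution"
        if le("condensed_fraction", -z_cut):
            fired.append(f"condensed_fraction z={z['condensed_fraction']:.1f}")
        if le("n_droplets", -z_cut) and le("total_droplet_intensity", -z_cut):
            fired.append(f"n_droplets z={z['n_droplets']:.1f} & total_intensity z={z['total_droplet_intensity']:.1f}")
    elif ge("condensed_fraction", z_cut) or (ge("mean_diameter", z_cut) and ge("total_droplet_intensity", z_cut)):
        call = "enhancement"
        if ge("condensed_fraction", z_cut):
            fired.append(f"condensed_fraction z={z['condensed_fraction']:.1f}")
        if ge("mean_diameter", z_cut) and ge("total_droplet_intensity", z_cut):
            fired.append(f"mean_diameter z={z['mean_diameter']:.1f} & total_intensity z={z['total_droplet_intensity']:.1f}")
    elif le("mean_circularity", -z_cut):
        call = "other"
        fired.append(f"mean_circularity z={z['mean_circularity']:.1f}")
    else:
        call = "no_effect"
    rationale = (
        f"{call}: " + ("; ".join(fired) if fired else f"no feature beyond ±{z_cut:g} sd of controls")
    ) + " (precedence dissolution > enhancement > other)"
    return PhenotypeCall(well=well.well, compound_id=compound_id, call=call, z_scores=z, rationale=rationale)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def summarize_screen(calls: Sequence[PhenotypeCall], z_cut: float = 3.0) -> ScreenReport:
    """Tally phenotype calls into per-class counts and integer percentages."""
    if not calls:
        raise ValueError("cannot summarize an empty screen")
    counts = {c: 0 for c in PHENOTYPE_CLASSES}
    for call in calls:
        if call.call not in counts:
            raise ValueError(f"unknown phenotype class {call.call!r}")
        counts[call.call] += 1
    total = len(calls)
    percentages = {c: _round_half_away(100.0 * n / total) for c, n in counts.items()}
    return ScreenReport(counts=counts, percentages=percentages, total_screened=total, z_cut=z_cut)


_TITRATION_METRICS = ("n_droplets", "condensed_fraction", "total_droplet_intensity")


def estimate_saturation_concentration(
    series: Sequence[tuple[float, WellResult]],
    metric: str = "n_droplets",
    frac_of_max: float = 0.1,
) -> TitrationResult:
    """Estimate the tipping point of a titration series.

    The saturation concentration is snapped to the measured grid: the
    smallest tested concentration at which the chosen response metric
    reaches ``frac_of_max`` of its maximum over the series.  A series whose
    metric never rises above zero is flagged "not reached".
    """
    if metric not in _TITRATION_METRICS:
        raise ValueError(f"metric must be one of {_TITRATION_METRICS}")
    if len(series) < 3:
        raise ValueError("a titration needs at least 3 concentrations")
    conc = np.array([c for c, _ in series], dtype=float)
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    if not (0 < frac_of_max <= 1):
        raise ValueError("frac_of_max must be in (0, 1]")
    vals = np.array([w.features.get(metric, math.nan) for _, w in series], dtype=float)
    vals = np.nan_to_num(vals, nan=0.0)
    vmax = float(vals.max())
    if vmax <= 0:
        return TitrationResult(c_sat=None, reached=False, response_metric=metric, threshold_used=frac_of_max)
    idx = int(np.argmax(vals >= frac_of_max * vmax))
    return TitrationResult(
        c_sat=float(conc[idx]), reached=True, response_metric=metric, threshold_used=frac_of_max
    )


def saturation_fold_change(a: TitrationResult, b: TitrationResult) -> float:
    """Fold change ``b.c_sat / a.c_sat`` between two titration series."""
    if not (a.reached and b.reached):
        raise ValueError("fold change undefined: a tipping point was not reached")
    assert a.c_sat is not None and b.c_sat is not None
    return b.c_sat / a.c_sat
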