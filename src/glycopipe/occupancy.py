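"""MS1-based O-glycosylation site-occupancy estimation.

For each tryptic peptide region the glyco ratio is

    occupancy = sum(glycoform areas) / (sum(glycoform areas) + non-glyco area)

computed per replicate after charge states are summed within each glycoform.
When the non-glycosylated peptide is never detected the region is flagged
"High" (occupancy assumed near-complete). The xTn distribution is each
glycoform's share of the glycoform-only total. Peaks first pass an
acceptance filter on mass accuracy, isotopic dot product, retention-time
proximity and identification score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .models import GlycoformPeak, OccupancyRecord, ValidationError


@dataclass
class FilterResult:
    accepted: list[GlycoformPeak]
    rejected: list[tuple[GlycoformPeak, str]] = field(default_factory=list)

    @property
    def reject_reasons(self) -> list[str]:
        return [reason for _, reason in self.rejected]


def filter_peaks(
    peaks: Iterable[GlycoformPeak],
    ppm_window: float = 1.5,
    idotp_min: float = 0.85,
    rt_window_min: float = 5.0,
    iso_rel_abund_min: float = 20.0,
    min_id_score: float = 200.0,
) -> FilterResult:
    """Acceptance filter for MS1 glycoform peaks.

    A peak is kept when |mass error| < ppm_window (strict, matching the
    ">-1.5, <1.5" convention), idotp > idotp_min (strict), |RT delta| <
    rt_window_min, and id_score >= min_id_score. The isotopologue
    relative-abundance cutoff applies only when that value is supplied.
    Rejected peaks are returned with a reason code; an empty acceptance set
    is a valid outcome.
    """
    result = FilterResult(accepted=[])
    for peak in peaks:
        if not abs(peak.mass_error_ppm) < ppm_window:
            result.rejected.append((peak, "ppm"))
        elif not peak.idotp > idotp_min:
            result.rejected.append((peak, "idotp"))
        elif not abs(peak.rt_delta_min) < rt_window_min:
            result.rejected.append((peak, "rt"))
        elif peak.id_score < min_id_score:
            result.rejected.append((peak, "id_score"))
        elif peak.iso_rel_abund is not None and peak.iso_rel_abund <= iso_rel_abund_min:
            result.rejected.append((peak, "iso_rel_abund"))
        else:
            result.accepted.append(peak)
    return result


def compute_occupancy(peaks: Sequence[GlycoformPeak]) -> Optional[OccupancyRecord]:
    """Occupancy record for one peptide region from its accepted peaks.

    Charge states are summed within each (replicate, glycoform). Replicates
    where the non-glycosylated form is absent while it was detected in others
    are excluded from the ratio and the record flagged ``partial_detection``;
    absence in *all* replicates raises the High flag instead. xTn percentages
    are glycoform area shares pooled over replicates, rounded to integers for
    report parity (unrounded values kept alongside).

    Returns None (region skipped) when no glycoform peak is present at all.
    """
    region_keys = {p.region_key for p in peaks}
    if len(region_keys) > 1:
        raise ValidationError(f"peaks span several regions: {sorted(region_keys)}")
    if not any(p.glycoform > 0 for p in peaks):
        return None
    acc, start, end, peptide = next(iter(region_keys))

    # area[replicate][glycoform] summed over charge states
    area: dict[str, dict[int, float]] = {}
    for p in peaks:
        by_form = area.setdefault(p.replicate, {})
        by_form[p.glycoform] = by_form.get(p.glycoform, 0.0) + p.area

    tn_max = max(form for by_form in area.values() for form in by_form if form > 0)

    ratios = []
    nonglyco_seen = False
    partial = False
    for replicate, by_form in sorted(area.items()):
        glyco_total = sum(v for form, v in by_form.items() if form > 0)
        if glyco_total == 0:
            continue
        if 0 in by_form:
            nonglyco_seen = True
            ratios.append(glyco_total / (glyco_total + by_form[0]))
        else:
            partial = True
    high_flag = not nonglyco_seen

    form_totals = np.zeros(tn_max)
    for by_form in area.values():
        for form, v in by_form.items():
            if form > 0:
                form_totals[form - 1] += v
    xtn_raw = (form_totals / form_totals.sum() * 100.0).tolist()
    xtn_percent = _round_to_100(xtn_raw)

    if high_flag:
        ratio_mean: Optional[float] = None
        sd: Optional[float] = None
        n_used = len(area)
    else:
        ratio_mean = float(np.mean(ratios))
        sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else None
        n_used = len(ratios)

    return OccupancyRecord(
        accession=acc,
        region_start=start,
        region_end=end,
        peptide=peptide,
        tn_max=tn_max,
        glyco_ratio=ratio_mean,
        sd=sd,
        xtn_percent=xtn_percent,
        xtn_raw=xtn_raw,
        high_flag=high_flag,
        n_replicates=n_used,
        partial_detection=partial and not high_flag,
    )


def _round_to_100(values: Sequence[float]) -> list[int]:
    """Largest-remainder integer rounding so the percentages sum to 100."""
    floors = [int(v) for v in values]
    remainder = 100 - sum(floors)
    order = sorted(
        range(len(values)), key=lambda i: values[i] - floors[i], reverse=True
    )
    for i in order[:remainder]:
        floors[i] += 1
    return floors


def compute_occupancy_table(
    peaks: Sequence[GlycoformPeak],
) -> list[OccupancyRecord]:
    """Group accepted peaks by peptide region and compute every record."""
    by_region: dict[tuple, list[GlycoformPeak]] = {}
    for p in peaks:
        by_region.setdefault(p.region_key, []).append(p)
    records = []
    for key in sorted(by_region):
        record = compute_occupancy(by_region[key])
        if record is not None:
            records.append(record)
    return records


DEFAULT_CLASS_BOUNDS = (0.75, 0.25, 0.1, 0.001)


def classify_occupancy(
    records: Iterable[OccupancyRecord],
    bounds: tuple[float, float, float, float] = DEFAULT_CLASS_BOUNDS,
) -> dict[str, tuple[int, float]]:
    """Occupancy class counts and fractions.

    Classes: high (> 0.75, High-flag records included), medium (0.25-0.75],
    low [0.001-0.1], below_floor (< 0.001), and the 0.1-0.25 interval
    reported separately as ``gap``.
    """
    high_b, med_b, low_b, floor_b = bounds
    counts = {"high": 0, "medium": 0, "gap": 0, "low": 0, "below_floor": 0}
    total = 0
    for r in records:
        total += 1
        if r.high_flag or r.glyco_ratio > high_b:
            counts["high"] += 1
        elif r.glyco_ratio > med_b:
            counts["medium"] += 1
        elif r.glyco_ratio > low_b:
            counts["gap"] += 1
        elif r.glyco_ratio >= floor_b:
            counts["low"] += 1
        else:
            counts["below_floor"] += 1
    return {
        k: (v, v / total if total else 0.0) for k, v in counts.items()
    }


@dataclass
class RegressionReport:
    n_matched: int
    slope: float
    intercept: float
    r_squared: float
    insufficient: bool = False


def compare_conditions(
    records_a: Sequence[OccupancyRecord],
    records_b: Sequence[OccupancyRecord],
) -> RegressionReport:
    """Least-squares regression of occupancy ratios between two sources.

    Records are matched by identical peptide sequence; High-flag records
    (no numeric ratio) are excluded. Fewer than 3 matched pairs yields an
    ``insufficient`` report.
    """
    a_by_pep = {r.peptide: r for r in records_a if not r.high_flag}
    b_by_pep = {r.peptide: r for r in records_b if not r.high_flag}
    shared = sorted(set(a_by_pep) & set(b_by_pep))
    if len(shared) < 3:
        return RegressionReport(
            n_matched=len(shared), slope=float("nan"), intercept=float("nan"),
            r_squared=float("nan"), insufficient=True,
        )
    x = np.array([a_by_pep[p].glyco_ratio for p in shared])
    y = np.array([b_by_pep[p].glyco_ratio for p in shared])
    fit = stats.linregress(x, y)
    return RegressionReport(
        n_matched=len(shared),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )
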