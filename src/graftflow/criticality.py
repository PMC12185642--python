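"""Critical-area detection: percentile thresholds, masks, ROI fractions.

One patient-specific threshold per descriptor is computed on the whole
luminal surface as an area-weighted percentile of its distribution — the
33rd percentile for "low is bad" indices (TAWSS) and the 66th for "high is
bad" indices (OSI, transWSS, TSVI).  Regions beyond the threshold form the
critical mask; per-ROI critical-area percentages and pairwise Dice overlap
(the similarity index between critical maps) summarise the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LOW = "low"
HIGH = "high"


class CriticalityError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdRule:
    """Which tail of a descriptor's distribution is deemed critical."""

    descriptor: str
    direction: str  # "low": below threshold is critical; "high": above
    percentile: float | None = None  # defaults: 33 for low, 66 for high

    def __post_init__(self):
        if self.direction not in (LOW, HIGH):
            raise CriticalityError(f"direction must be 'low' or 'high', got {self.direction!r}")
        pct = self.percentile if self.percentile is not None else (33.0 if self.direction == LOW else 66.0)
        if not (0.0 < pct < 100.0):
            raise CriticalityError("percentile must lie in (0, 100)")
        object.__setattr__(self, "percentile", float(pct))


DEFAULT_RULES = (
    ThresholdRule("tawss", LOW),
    ThresholdRule("osi", HIGH),
    ThresholdRule("transwss", HIGH),
    ThresholdRule("tsvi", HIGH),
)


@dataclass
class CriticalMask:
    mask: np.ndarray  # boolean per element
    rule: ThresholdRule
    threshold: float
    support: str = "cell"  # "cell" | "node"


@dataclass
class CriticalityReport:
    """Machine-readable criticality summary: one threshold per descriptor
    and one critical-area percentage per (descriptor, ROI)."""

    thresholds: dict[str, float]
    rules: dict[str, ThresholdRule]
    area_fractions: dict[str, dict[str, float]]  # descriptor -> roi -> %
    similarity: dict[tuple[str, str], float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, per_roi in self.area_fractions.items():
            rule = self.rules[name]
            for roi, pct in per_roi.items():
                rows.append(
                    {
                        "descriptor": name,
                        "threshold": self.thresholds[name],
                        "direction": rule.direction,
                        "percentile": rule.percentile,
                        "roi": roi,
                        "pct_area": pct,
                    }
                )
        return pd.DataFrame(rows)


def percentile_threshold(values, weights, pct: float) -> float:
    """Area-weighted percentile: smallest v at which the cumulative area of
    elements with value <= v reaches pct% of the total, linearly
    interpolated between adjacent distinct values."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.size == 0:
        raise CriticalityError("empty input")
    if not np.all(np.isfinite(v)):
        raise CriticalityError("non-finite descriptor values")
    if np.any(w <= 0):
        raise CriticalityError("weights must be positive")
    if not (0.0 < pct < 100.0):
        raise CriticalityError("percentile must lie in (0, 100)")
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    target = pct / 100.0 * cum[-1]
    i = int(np.searchsorted(cum, target, side="left"))
    if i == 0:
        return float(v[0])
    if i >= len(v):
        return float(v[-1])
    c0, c1 = cum[i - 1], cum[i]
    frac = (target - c0) / (c1 - c0)
    return float(v[i - 1] + frac * (v[i] - v[i - 1]))


def critical_mask(values, threshold: float, direction: str, support: str = "cell",
                  rule: ThresholdRule | None = None) -> CriticalMask:
    """Strict-inequality mask: v < threshold (low) or v > threshold (high);
    equality is non-critical."""
    v = np.asarray(values, dtype=float)
    if not np.isfinite(threshold):
        raise CriticalityError("threshold must be finite")
    if direction == LOW:
        m = v < threshold
    elif direction == HIGH:
        m = v > threshold
    else:
        raise CriticalityError(f"unknown direction {direction!r}")
    return CriticalMask(
        mask=m,
        rule=rule or ThresholdRule("field", direction),
        threshold=float(threshold),
        support=support,
    )


def roi_area_fraction(mask: CriticalMask, roi_elements, areas) -> float:
    """Percentage of the ROI's area covered by the critical mask."""
    idx = np.asarray(roi_elements, dtype=np.int64)
    if idx.size == 0:
        raise CriticalityError("empty ROI")
    areas = np.asarray(areas, dtype=float)
    roi_area = areas[idx].sum()
    crit_area = areas[idx][mask.mask[idx]].sum()
    return float(100.0 * crit_area / roi_area)


def similarity_index(mask_a: CriticalMask, mask_b: CriticalMask, areas) -> float:
    """Area-weighted Dice overlap between two critical maps, in percent.

    100 when both masks are empty (identical by convention)."""
    a, b = mask_a.mask, mask_b.mask
    if a.shape != b.shape:
        raise CriticalityError("masks live on different surfaces")
    areas = np.asarray(areas, dtype=float)
    area_a = areas[a].sum()
    area_b = areas[b].sum()
    if area_a + area_b == 0.0:
        return 100.0
    inter = areas[a & b].sum()
    # intersection can never exceed either mask's area; the min guards the
    # upper bound against rounding so identical masks give exactly 100
    return float(100.0 * min(1.0, 2.0 * inter / (area_a + area_b)))


def criticality_report(
    fields: dict[str, np.ndarray],
    rules,
    rois: dict[str, np.ndarray],
    areas,
    with_similarity: bool = True,
    metadata: dict | None = None,
) -> CriticalityReport:
    """Assemble thresholds, per-ROI critical fractions and pairwise Dice
    similarity from per-element descriptor fields.

    Thresholds are taken over the whole-domain distribution; fractions are
    then evaluated inside each ROI.  Results compose exactly from the
    individual operations.
    """
    rules = {r.descriptor: r for r in rules}
    missing = set(rules) - set(fields)
    if missing:
        raise CriticalityError(f"missing descriptor fields: {sorted(missing)}")
    areas = np.asarray(areas, dtype=float)
    thresholds: dict[str, float] = {}
    masks: dict[str, CriticalMask] = {}
    fractions: dict[str, dict[str, float]] = {}
    for name, rule in rules.items():
        thr = percentile_threshold(fields[name], areas, rule.percentile)
        mask = critical_mask(fields[name], thr, rule.direction, rule=rule)
        thresholds[name] = thr
        masks[name] = mask
        fractions[name] = {
            roi: roi_area_fraction(mask, idx, areas) for roi, idx in rois.items()
        }
    similarity = {}
    if with_similarity:
        names = sorted(rules)
        for i, na in enumerate(names):
            for nb in names[i + 1 :]:
                similarity[(na, nb)] = similarity_index(masks[na], masks[nb], areas)
    return CriticalityReport(
        thresholds=thresholds,
        rules=rules,
        area_fractions=fractions,
        similarity=similarity,
        metadata=metadata or {},
    )
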