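"""Comparison of eDNA detections against conventional-survey checklists.

Species matching is by canonical label (case-folded, whitespace-stripped);
names absent from the checklist are surfaced in a reconciliation report
rather than silently lowering the detected count.
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = [
    "canonical", "detection_fraction", "site_by_site",
    "percent_excess_richness", "reconcile",
]


def canonical(name: str) -> str:
    return " ".join(str(name).split()).casefold()


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def detection_fraction(detected, checklist) -> tuple[int, int, int]:
    """(k, n, percent): detected-in-checklist count, checklist size, and
    the integer percentage (half away from zero)."""
    checklist = {canonical(s) for s in checklist}
    if not checklist:
        raise ValueError("checklist must be non-empty")
    detected = {canonical(s) for s in detected}
    k = len(detected & checklist)
    n = len(checklist)
    return k, n, _round_half_away(100.0 * k / n)


def reconcile(detected, checklist) -> dict[str, set]:
    """Split detections into matched and unmatched-against-checklist."""
    checklist = {canonical(s) for s in checklist}
    detected = {canonical(s) for s in detected}
    return {
        "matched": detected & checklist,
        "unmatched": detected - checklist,
        "missed": checklist - detected,
    }


def site_by_site(
    detections: dict[str, dict[str, set]], checklist
) -> pd.DataFrame:
    """Per-site and overall detection fractions for each method.

    ``detections`` maps method -> site -> detected species set. The
    overall row uses the union across sites. Returned columns are
    (method, k / n / percent) per site plus "overall".
    """
    rows = []
    for method, per_site in detections.items():
        union: set = set()
        for site, detected in per_site.items():
            union |= {canonical(s) for s in detected}
            k, n, pct = detection_fraction(detected, checklist)
            rows.append(
                {"method": method, "site": site, "k": k, "n": n, "percent": pct}
            )
        k, n, pct = detection_fraction(union, checklist)
        rows.append(
            {"method": method, "site": "overall", "k": k, "n": n, "percent": pct}
        )
    return pd.DataFrame(rows).set_index(["method", "site"])


def percent_excess_richness(a: int, b: int) -> int:
    """How much richer a is than b, as an integer percentage of b."""
    if b < 1:
        raise ValueError("reference richness must be >= 1")
    return _round_half_away(100.0 * (a - b) / b)
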