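"""Density/centralization banding and the four-type network typology.

Density and centralization are each cut into three bands —
low (<= 0.33), medium (> 0.33 and <= 0.67) and high (> 0.67) — and the band
pair maps to a network type:

* **A** — highly connected, low hierarchy (high density; fully connected
  networks, density exactly 1, are a special case),
* **B** — medium connected, medium hierarchy,
* **C** — medium connected, low hierarchy,
* **D** — lowly connected (low density; low hierarchy follows in practice).

Band combinations outside this table (e.g. medium density with high
centralization, or high density with medium centralization — both logically
possible in small networks) are labelled ``unmapped`` rather than forced into
a neighbouring type. Band boundaries carry an absolute tolerance of 1e-9 so
that exact rationals such as 2/3 = 0.6667 land in the medium band rather than
being pushed over 0.67 by floating-point representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .metrics import NetworkMetrics
from .roster import CONDITIONS, Condition

__all__ = [
    "Band",
    "NetworkType",
    "TypologyLabel",
    "band_of",
    "classify_network",
    "typology_counts",
    "BAND_TOL",
]

#: Absolute tolerance applied to the 0.33 / 0.67 band thresholds.
BAND_TOL = 1e-9

_LOW_CUT = 0.33
_HIGH_CUT = 0.67


class Band(str, Enum):
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"


class NetworkType(str, Enum):
    A = "A"
    B = "B"
    C = "C"
    D = "D"
    UNMAPPED = "unmapped"


@dataclass(frozen=True)
class TypologyLabel:
    practice_id: str
    condition: Condition
    density_band: Band
    centralization_band: Band
    network_type: NetworkType
    fully_connected: bool


def band_of(value: float) -> Band:
    """Band a metric value: low <= 0.33 < medium <= 0.67 < high."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"band_of expects a value in [0, 1], got {value}")
    if value <= _LOW_CUT + BAND_TOL:
        return Band.LOW
    if value <= _HIGH_CUT + BAND_TOL:
        return Band.MEDIUM
    return Band.HIGH


_TYPE_TABLE: dict[tuple[Band, Band], NetworkType] = {
    (Band.HIGH, Band.LOW): NetworkType.A,
    (Band.MEDIUM, Band.MEDIUM): NetworkType.B,
    (Band.MEDIUM, Band.LOW): NetworkType.C,
    (Band.LOW, Band.LOW): NetworkType.D,
    (Band.LOW, Band.MEDIUM): NetworkType.D,
    (Band.LOW, Band.HIGH): NetworkType.D,
}


def classify_network(metrics: NetworkMetrics) -> TypologyLabel:
    """Classify one network into the A-D typology by its band pair.

    Type D is defined by low density alone (a lowly connected practice can
    hardly be hierarchical in a meaningful sense); types A-C additionally
    constrain the centralization band, and undefined combinations map to
    ``unmapped``.
    """
    db = band_of(metrics.density)
    cb = band_of(metrics.centralization)
    ntype = _TYPE_TABLE.get((db, cb), NetworkType.UNMAPPED)
    return TypologyLabel(
        practice_id=metrics.practice_id,
        condition=metrics.condition,
        density_band=db,
        centralization_band=cb,
        network_type=ntype,
        fully_connected=metrics.density == 1.0,
    )


_DENSITY_NAMES = {Band.HIGH: "highly_connected", Band.MEDIUM: "medium_connected", Band.LOW: "lowly_connected"}
_CENT_NAMES = {Band.HIGH: "highly_centralized", Band.MEDIUM: "medium_centralized", Band.LOW: "lowly_centralized"}


def typology_counts(labels: list[TypologyLabel]) -> pd.DataFrame:
    """Per-condition counts and percentages of bands, types and full connection.

    Percentages are over the labelled (i.e. included) networks of each
    condition, to one decimal. An empty label list yields an all-zero table.
    """
    rows: list[dict] = []
    for condition in CONDITIONS:
        sub = [lab for lab in labels if lab.condition is condition]
        denom = len(sub)

        def add(category: str, level: str, n: int) -> None:
            pct = round(100.0 * n / denom, 1) if denom else 0.0
            rows.append(
                {
                    "condition": condition.value,
                    "category": category,
                    "level": level,
                    "n": n,
                    "pct": pct,
                    "denominator": denom,
                }
            )

        for band in (Band.HIGH, Band.MEDIUM, Band.LOW):
            add("density", _DENSITY_NAMES[band], sum(lab.density_band is band for lab in sub))
        for band in (Band.HIGH, Band.MEDIUM, Band.LOW):
            add(
                "centralization",
                _CENT_NAMES[band],
                sum(lab.centralization_band is band for lab in sub),
            )
        for ntype in NetworkType:
            add("network_type", ntype.value, sum(lab.network_type is ntype for lab in sub))
        add("fully_connected", "yes", sum(lab.fully_connected for lab in sub))
    return pd.DataFrame(rows)
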