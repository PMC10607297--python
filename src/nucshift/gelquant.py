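"""Densitometry statistics for native-gel remodeling assays and
competitive-reconstitution thermodynamics.

Band intensities enter as numbers (one lane = one mapping of band labels to
signals). Sliding extent is the slid-over-total mononucleosome signal ratio;
eviction extent is the remodeler-dependent gain in free DNA over the
starting nucleosomal signal; binding extent is bound over bound + unbound.
Per-assay values are normalized to their assay mean before pooling across
independent assays. Competitive reconstitution yields a relative
equilibrium constant (nuc/free ratio over that of a reference probe) and
the free-energy difference ddG = -R*T*ln(Keq_rel), positive for probes that
form nucleosomes less readily than the reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "LaneIntensities",
    "ThermoParams",
    "ReconstitutionMeasurement",
    "sliding_extent",
    "eviction_extent",
    "binding_extent",
    "normalize_within_assay",
    "relative_keq",
    "delta_delta_g",
]

R_KCAL = 1.987e-3  # gas constant, kcal / (mol K)


@dataclass(frozen=True)
class LaneIntensities:
    """Named band signals from one gel lane.

    Recognized band labels: ``unslid``, ``slid`` or ``slid_1..k``, ``well``,
    ``smear``, ``free_dna``, ``bound``, ``unbound``, ``nucleosomal``.
    """

    assay_id: str
    lane_id: str
    bands: Mapping[str, float]

    def __post_init__(self) -> None:
        for label, v in self.bands.items():
            if v < 0:
                raise ValueError(f"negative intensity for band {label!r}")

    def band(self, label: str) -> float:
        if label not in self.bands:
            raise KeyError(f"lane {self.lane_id!r} has no band {label!r}")
        return float(self.bands[label])

    def slid_bands(self) -> list[float]:
        return [
            float(v)
            for k, v in self.bands.items()
            if k == "slid" or k.startswith("slid_")
        ]


@dataclass(frozen=True)
class ThermoParams:
    R: float = R_KCAL  # kcal / (mol K)
    T: float = 298.15  # K

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class ReconstitutionMeasurement:
    probe_id: str
    nuc_signal: float
    free_signal: float


def sliding_extent(lane: LaneIntensities, count_smear: bool = False) -> float:
    """Slid mononucleosome signal over all mononucleosome signal in the lane.

    With ``count_smear`` the smear and loading-well signals are counted as
    remodeled species in both numerator and denominator (the alternative
    reading used when octamer-transfer intermediates are abundant). Free
    DNA never enters the denominator.
    """
    slid = sum(lane.slid_bands())
    unslid = float(lane.bands.get("unslid", 0.0))
    num = slid
    den = slid + unslid
    if count_smear:
        extra = float(lane.bands.get("smear", 0.0)) + float(lane.bands.get("well", 0.0))
        num += extra
        den += extra
    if den <= 0:
        raise ValueError("no mononucleosome signal in lane; sliding extent undefined")
    return num / den


def eviction_extent(lane_plus: LaneIntensities, lane_minus: LaneIntensities) -> float:
    """Fraction of nucleosomal DNA converted to free DNA by the remodeler.

    (free_plus - free_minus) / nucleosomal_minus. Negative values (noise)
    are returned as-is.
    """
    free_plus = lane_plus.band("free_dna")
    free_minus = lane_minus.band("free_dna")
    nuc_minus = lane_minus.band("nucleosomal")
    if nuc_minus <= 0:
        raise ValueError("nucleosomal signal absent in minus-remodeler lane")
    return (free_plus - free_minus) / nuc_minus


def binding_extent(lane: LaneIntensities) -> float:
    """Bound nucleosome signal over bound + unbound."""
    bound = lane.band("bound")
    unbound = lane.band("unbound")
    if bound + unbound <= 0:
        raise ValueError("bound + unbound signal is zero; binding extent undefined")
    return bound / (bound + unbound)


def normalize_within_assay(values: Mapping[str, Sequence[float]]) -> Dict[str, list[float]]:
    """Divide each value by its assay's mean (so each assay's mean becomes 1).

    ``values`` maps assay_id to that assay's measured extents. Values are
    normalized per assay before pooling across independent assays.
    """
    out: Dict[str, list[float]] = {}
    for assay, vals in values.items():
        vals = list(vals)
        if not vals:
            raise ValueError(f"assay {assay!r} has no values")
        mean = sum(vals) / len(vals)
        if mean == 0:
            raise ValueError(f"assay {assay!r} mean is zero; cannot normalize")
        out[assay] = [v / mean for v in vals]
    return out


def relative_keq(
    m: ReconstitutionMeasurement, ref: ReconstitutionMeasurement
) -> float:
    """Equilibrium constant of nucleosome formation relative to a reference.

    (nuc/free) of the probe over (nuc/free) of the reference (conventionally
    the 147 bp 5S rDNA positioning probe).
    """
    for x in (m, ref):
        if x.nuc_signal <= 0 or x.free_signal <= 0:
            raise ValueError(f"probe {x.probe_id!r}: signals must be positive")
    return (m.nuc_signal / m.free_signal) / (ref.nuc_signal / ref.free_signal)


def delta_delta_g(keq_rel: float, params: ThermoParams = ThermoParams()) -> float:
    """Relative free energy of nucleosome formation, -R*T*ln(Keq_rel), kcal/mol.

    Positive for destabilized probes (Keq_rel < 1).
    """
    if keq_rel <= 0:
        raise ValueError("relative Keq must be positive")
    return -params.R * params.T * math.log(keq_rel)


def lanes_from_table(table: pd.DataFrame) -> list[LaneIntensities]:
    """Group a long-format TSV table (assay_id, lane_id, band, intensity)
    into LaneIntensities objects."""
    lanes = []
    for (assay, lane), grp in table.groupby(["assay_id", "lane_id"], sort=True):
        lanes.append(
            LaneIntensities(
                assay_id=str(assay),
                lane_id=str(lane),
                bands=dict(zip(grp["band"], grp["intensity"].astype(float))),
            )
        )
    return lanes
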