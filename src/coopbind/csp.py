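"""Amide chemical-shift perturbations and peak-height competition ratios.

The combined 1H/15N perturbation for a residue observed in two conditions is

    ddelta = sqrt(0.5 * [ (ddelta_H)^2 + (0.14 * ddelta_N)^2 ])

and residues with ddelta above three standard deviations of all matched
perturbations are flagged as significant.  Peak-height ratios (after/before)
report exchange broadening: residues at a self-association interface broaden
or vanish when the interface forms and reappear when it is competed away.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PeakStatus",
    "Peak",
    "PeakList",
    "CspProfile",
    "csp",
    "csp_profile",
    "peak_height_ratio",
]

N_SCALE = 0.14  # nitrogen shift weighting relative to proton


class PeakStatus(str, enum.Enum):
    ASSIGNED = "assigned"
    OVERLAPPED = "overlapped"
    UNASSIGNED = "unassigned"
    ABSENT = "absent"


@dataclass(frozen=True)
class Peak:
    """One assigned amide resonance: residue, 1H and 15N shifts, height."""

    residue_id: int
    residue_name: str = ""
    deltaH: float = math.nan  # ppm
    deltaN: float = math.nan  # ppm
    height: float | None = None
    status: PeakStatus = PeakStatus.ASSIGNED

    def __post_init__(self) -> None:
        if self.status == PeakStatus.ASSIGNED:
            if not (math.isfinite(self.deltaH) and math.isfinite(self.deltaN)):
                raise ValueError(
                    f"assigned peak {self.residue_id} needs finite shifts"
                )
        if self.height is not None and self.height < 0:
            raise ValueError("peak height must be >= 0")


@dataclass
class PeakList:
    """Mapping residue_id -> Peak for one sample condition."""

    condition: str
    peaks: dict[int, Peak] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rid, pk in self.peaks.items():
            if pk.residue_id != rid:
                raise ValueError("peak keyed under wrong residue id")

    def add(self, peak: Peak) -> None:
        if peak.residue_id in self.peaks:
            raise ValueError(f"duplicate residue {peak.residue_id}")
        self.peaks[peak.residue_id] = peak

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(sorted(self.peaks))

    def __getitem__(self, rid: int) -> Peak:
        return self.peaks[rid]


class ExcludedResidue(ValueError):
    """A residue cannot enter the CSP calculation (unassigned/overlapped)."""


def csp(peak_a: Peak, peak_b: Peak) -> float:
    """Combined amide chemical-shift perturbation (ppm) between two peaks.

    Symmetric in its arguments; raises :class:`ExcludedResidue` if either
    peak is not cleanly assigned.
    """
    for pk in (peak_a, peak_b):
        if pk.status != PeakStatus.ASSIGNED:
            raise ExcludedResidue(
                f"residue {pk.residue_id} is {pk.status.value}; no CSP"
            )
    dH = peak_a.deltaH - peak_b.deltaH
    dN = peak_a.deltaN - peak_b.deltaN
    return math.sqrt(0.5 * (dH * dH + (N_SCALE * dN) ** 2))


@dataclass
class CspProfile:
    """Per-residue perturbations with the 3-sigma significance threshold."""

    delta: dict[int, float]  # residue -> ddelta (ppm)
    threshold: float  # 3 * SD of all matched ddelta values (ppm)
    significant: dict[int, bool]
    excluded: dict[int, str]  # residue -> reason

    @property
    def flagged(self) -> list[int]:
        return sorted(r for r, s in self.significant.items() if s)


def csp_profile(
    list_a: PeakList, list_b: PeakList, robust: bool = False
) -> CspProfile:
    """CSP for every residue assigned in both lists, with 3xSD threshold.

    The standard deviation is computed over all matched residues, perturbed
    ones included.  With ``robust=True`` the SD is replaced by the
    normal-consistent MAD (1.4826 * median absolute deviation), which resists
    a handful of large perturbations inflating the threshold.
    """
    delta: dict[int, float] = {}
    excluded: dict[int, str] = {}
    residues = set(list_a.peaks) | set(list_b.peaks)
    for rid in sorted(residues):
        pa = list_a.peaks.get(rid)
        pb = list_b.peaks.get(rid)
        if pa is None or pb is None:
            excluded[rid] = "missing in one list"
            continue
        try:
            delta[rid] = csp(pa, pb)
        except ExcludedResidue:
            bad = pa if pa.status != PeakStatus.ASSIGNED else pb
            excluded[rid] = bad.status.value
    if len(delta) < 3:
        raise ValueError(
            f"only {len(delta)} matched assigned residues; need >= 3"
        )
    values = np.array(list(delta.values()))
    if robust:
        sd = 1.4826 * float(np.median(np.abs(values - np.median(values))))
    else:
        sd = float(np.std(values, ddof=1))
    threshold = 3.0 * sd
    significant = {rid: d > threshold for rid, d in delta.items()}
    return CspProfile(
        delta=delta, threshold=threshold, significant=significant, excluded=excluded
    )


def peak_height_ratio(
    list_after: PeakList, list_before: PeakList
) -> dict[int, dict]:
    """Per-residue height ratio after/before a competition experiment.

    Returns, per residue, a record with ``ratio`` (finite float when
    height_before > 0 and the peak persists) and a ``flag``:

    - ``"reappeared"`` — absent/zero before, detectable after (interface
      residue released by the competitor);
    - ``"broadened"`` — present before, absent after (interface formed);
    - ``"omitted"`` — no usable height in either list.
    """
    out: dict[int, dict] = {}
    residues = set(list_after.peaks) | set(list_before.peaks)
    for rid in sorted(residues):
        pa = list_after.peaks.get(rid)
        pb = list_before.peaks.get(rid)
        h_after = _usable_height(pa)
        h_before = _usable_height(pb)
        if h_before is None and h_after is None:
            out[rid] = {"ratio": None, "flag": "omitted", "reason": "no heights"}
        elif (h_before in (None, 0.0)) and h_after and h_after > 0:
            out[rid] = {"ratio": None, "flag": "reappeared"}
        elif h_before and h_before > 0 and (h_after is None or h_after == 0.0):
            out[rid] = {"ratio": 0.0, "flag": "broadened"}
        elif h_before == 0.0 and (h_after in (None, 0.0)):
            out[rid] = {"ratio": None, "flag": "omitted", "reason": "both zero"}
        else:
            out[rid] = {"ratio": h_after / h_before, "flag": "ok"}
    return out


def _usable_height(peak: Peak | None) -> float | None:
    if peak is None or peak.status == PeakStatus.ABSENT:
        return None
    return peak.height
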