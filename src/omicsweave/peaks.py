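"""NMR peak filtering, quantification and assignment.

Pre-analysis rules applied to an already-normalized peak table:

* peaks with exactly one non-zero intensity ("single mass events") are
  removed;
* a peak counts as detectable only if non-zero in at least 50% of the
  samples (inclusive threshold, configurable);
* peaks are assigned to reference metabolites by nearest chemical shift
  within a +/- 0.005 ppm tolerance, ties broken toward the lower reference
  shift;
* relative abundance is the peak area — a trapezoidal integral over the
  spectral points of the peak's ppm window when one is recorded, otherwise
  the stored (already binned) intensity.

Raw FID processing, phasing, baseline correction and spectral alignment are
assumed to have happened upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import PeakTable, ReferenceShiftTable

UNASSIGNED = "unassigned"


@dataclass
class AssignedPeakTable:
    """A peak table plus per-peak metabolite assignment and per-sample
    relative abundances (peak areas)."""

    peaks: PeakTable
    assignment: pd.Series          # peak_id -> metabolite name or "unassigned"
    relative_abundance: pd.DataFrame  # samples x peaks

    def abundance_of(self, metabolite: str) -> pd.Series:
        """Per-sample abundance of a metabolite (sum over its peaks)."""
        ids = self.assignment.index[self.assignment == metabolite]
        if len(ids) == 0:
            raise KeyError(f"no peak assigned to {metabolite!r}")
        return self.relative_abundance[ids].sum(axis=1)

    @property
    def assigned_metabolites(self) -> list[str]:
        return sorted(set(self.assignment) - {UNASSIGNED})


def filter_peaks(t: PeakTable, min_detect_frac: float = 0.5,
                 detection_floor: float = 0.0) -> PeakTable:
    """Remove single-mass-event peaks and peaks detected in too few samples.

    A peak is *detected* in a sample when its intensity exceeds
    ``detection_floor`` (default 0, i.e. strictly non-zero). Peaks with
    exactly one detection are removed regardless of the fraction rule; peaks
    detected in fewer than ``min_detect_frac`` of the samples (inclusive
    boundary: exactly 50% of 6 samples survives the default) are removed.
    Sample set, peak order and retained intensities are unchanged, so the
    operation is idempotent.
    """
    if not 0.0 < min_detect_frac <= 1.0:
        raise ValueError("min_detect_frac must be in (0, 1]")
    n_samples, n_peaks = t.intensities.shape
    if n_samples == 0 or n_peaks == 0:
        raise ValueError("peak table is empty")
    detected = (t.intensities.to_numpy() > detection_floor).sum(axis=0)
    need = min_detect_frac * n_samples - 1e-9  # inclusive ">= frac" boundary
    keep = (detected != 1) & (detected >= need)
    if not keep.any():
        warnings.warn("all peaks removed by detection filtering", stacklevel=2)
    kept_ids = [p for p, k in zip(t.peak_ids, keep) if k]
    return PeakTable(
        intensities=t.intensities[kept_ids],
        ppm=t.ppm[kept_ids],
        ppm_range=t.ppm_range.loc[kept_ids] if t.ppm_range is not None else None,
    )


def peak_area(t: PeakTable, peak_id: str) -> pd.Series:
    """Per-sample relative abundance of one peak.

    With a recorded ppm window the area is the trapezoidal integral of the
    intensities of all spectral points (peaks) falling inside the window;
    a single-point window degenerates to the stored intensity.  Without a
    window the stored intensity is the (already binned) area.
    """
    if peak_id not in t.intensities.columns:
        raise KeyError(f"unknown peak id {peak_id!r}")
    if t.ppm_range is None or t.ppm_range.loc[peak_id].isna().any():
        return t.intensities[peak_id].copy()
    low, high = t.ppm_range.loc[peak_id, ["ppm_low", "ppm_high"]]
    inside = t.ppm[(t.ppm >= low) & (t.ppm <= high)].sort_values()
    if len(inside) <= 1:
        return t.intensities[peak_id].copy()
    y = t.intensities[inside.index].to_numpy()
    area = np.trapezoid(y, x=inside.to_numpy(), axis=1)
    return pd.Series(area, index=t.intensities.index, name=peak_id)


def assign_peaks(t: PeakTable, ref: ReferenceShiftTable,
                 tol_ppm: float = 0.005) -> AssignedPeakTable:
    """Assign each peak to the nearest reference shift within tolerance.

    A peak gets the reference entry minimizing ``|ppm - reference_ppm|``
    subject to the tolerance; outside tolerance it stays unassigned. Distance
    ties break toward the lower reference shift (deterministic). Assignment
    is per-peak, hence invariant to peak ordering.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    table = ref.table.sort_values(["reference_ppm", "metabolite"]).reset_index(drop=True)
    if len(table) == 0:
        warnings.warn("empty reference table: all peaks unassigned", stacklevel=2)
    names: dict[str, str] = {}
    for pid in t.peak_ids:
        shift = t.ppm[pid]
        assigned = UNASSIGNED
        if len(table):
            d = (table["reference_ppm"] - shift).abs()
            best = d.idxmin()  # first (lowest reference_ppm) among ties
            if d[best] <= tol_ppm:
                assigned = table.loc[best, "metabolite"]
        names[pid] = assigned
    abundance = pd.concat({pid: peak_area(t, pid) for pid in t.peak_ids}, axis=1)
    abundance = abundance[t.peak_ids]
    return AssignedPeakTable(
        peaks=t,
        assignment=pd.Series(names).reindex(t.peak_ids),
        relative_abundance=abundance,
    )


def total_area_normalize(t: PeakTable) -> PeakTable:
    """Optional per-sample total-area normalization (sum of peaks = 1)."""
    totals = t.intensities.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("cannot normalize samples with zero total area")
    return PeakTable(intensities=t.intensities.div(totals, axis=0),
                     ppm=t.ppm, ppm_range=t.ppm_range)
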