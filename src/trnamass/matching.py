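"""Peak-list matching, differential knockout screening and stoichiometry.

The matcher assigns observed peaks to predicted ions inside a ppm window;
the screen compares detection across a strain panel against a reference
(wild-type) strain; state quantification turns per-state fragment
intensities into fractional occupancies at one position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .masscalc import PredictedIon

__all__ = [
    "ObservedPeak",
    "PeakAssignment",
    "MatchResult",
    "DetectionMatrix",
    "CandidateGenes",
    "StateQuantification",
    "match_peaks",
    "differential_screen",
    "candidate_genes",
    "normalized_modification_ratio",
    "quantify_states",
    "read_peak_list",
    "write_peak_list",
]

DEFAULT_FRAGMENT_TOL_PPM = 10.0
DEFAULT_NUCLEOSIDE_TOL_DA = 0.5


@dataclass(frozen=True)
class ObservedPeak:
    """One entry of an LC/MS peak list."""

    mz: float
    charge: int | None = None
    intensity: float = 0.0
    retention_time: float | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"peak m/z must be > 0, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass(frozen=True)
class PeakAssignment:
    peak: ObservedPeak
    ion: PredictedIon
    error_ppm: float
    rank: int  # 0 = best candidate for this peak
    ambiguous: bool = False  # more than one candidate within tolerance


@dataclass
class MatchResult:
    assignments: list[PeakAssignment]
    unmatched_peaks: list[ObservedPeak]
    unmatched_ions: list[PredictedIon]

    def best(self) -> list[PeakAssignment]:
        return [a for a in self.assignments if a.rank == 0]


def match_peaks(
    predicted: Sequence[PredictedIon],
    observed: Sequence[ObservedPeak],
    tol_ppm: float = DEFAULT_FRAGMENT_TOL_PPM,
) -> MatchResult:
    """Assign each observed peak to all predicted ions within tolerance.

    Candidates must match the peak's charge when the peak declares one.
    Per peak, candidates are ranked by |error_ppm|, ties broken by lower
    charge; peaks with more than one candidate are flagged ambiguous.
    """
    if tol_ppm <= 0:
        raise ValueError(f"tol_ppm must be > 0, got {tol_ppm}")
    assignments: list[PeakAssignment] = []
    matched_ions: set[int] = set()
    unmatched_peaks: list[ObservedPeak] = []
    for peak in observed:
        candidates: list[tuple[float, int, int]] = []
        for ion_index, ion in enumerate(predicted):
            if peak.charge is not None and peak.charge != ion.charge:
                continue
            error_ppm = (peak.mz - ion.mz) / ion.mz * 1e6
            if abs(error_ppm) <= tol_ppm:
                candidates.append((error_ppm, ion.charge, ion_index))
        if not candidates:
            unmatched_peaks.append(peak)
            continue
        candidates.sort(key=lambda c: (abs(c[0]), c[1]))
        ambiguous = len(candidates) > 1
        for rank, (error_ppm, _, ion_index) in enumerate(candidates):
            matched_ions.add(ion_index)
            assignments.append(
                PeakAssignment(
                    peak=peak,
                    ion=predicted[ion_index],
                    error_ppm=error_ppm,
                    rank=rank,
                    ambiguous=ambiguous,
                )
            )
    unmatched_ions = [
        ion for i, ion in enumerate(predicted) if i not in matched_ions
    ]
    return MatchResult(assignments, unmatched_peaks, unmatched_ions)


# -- detection matrix and screen -------------------------------------------


@dataclass
class DetectionMatrix:
    """Strains x modified-nucleoside intensity table.

    Detection is threshold-based: a mark counts as present in a strain when
    its intensity exceeds ``floor`` (the screen calls presence/absence the
    way chromatogram inspection does).
    """

    data: pd.DataFrame  # index: strain ids; columns: nucleoside codes

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            self.data = self.data.fillna(0.0)

    @property
    def strains(self) -> list[str]:
        return list(self.data.index)

    @property
    def codes(self) -> list[str]:
        return list(self.data.columns)

    def detected(self, strain: str, code: str, floor: float = 0.0) -> bool:
        return bool(self.data.loc[strain, code] > floor)

    def detected_set(self, strain: str, floor: float = 0.0) -> set[str]:
        row = self.data.loc[strain]
        return set(row.index[row > floor])

    @classmethod
    def from_csv(cls, path: str | Path) -> "DetectionMatrix":
        return cls(pd.read_csv(path, index_col=0, comment="#"))

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path)


def differential_screen(
    matrix: DetectionMatrix,
    reference: str,
    floor: float = 0.0,
) -> dict[str, list[str]]:
    """Per strain, the modifications detected in the reference but not there."""
    if reference not in matrix.strains:
        raise KeyError(f"reference strain {reference!r} not in matrix")
    reference_set = matrix.detected_set(reference, floor)
    report: dict[str, list[str]] = {}
    for strain in matrix.strains:
        if strain == reference:
            continue
        report[strain] = sorted(reference_set - matrix.detected_set(strain, floor))
    return report


@dataclass(frozen=True)
class CandidateGenes:
    genes: frozenset[str]
    status: str  # resolved | unresolved | ambiguous

    def __iter__(self):
        return iter(sorted(self.genes))


def candidate_genes(
    region_genes: Iterable[str], single_gene_hits: Iterable[str]
) -> CandidateGenes:
    """Narrow a region-deletion hit using single-gene deletion results."""
    intersection = frozenset(region_genes) & frozenset(single_gene_hits)
    if not intersection:
        status = "unresolved"
    elif len(intersection) == 1:
        status = "resolved"
    else:
        status = "ambiguous"
    return CandidateGenes(genes=intersection, status=status)


# -- quantification --------------------------------------------------------


def normalized_modification_ratio(
    target_intensity: float,
    reference_intensity: float,
    control_ratio: float,
) -> float:
    """(target/reference) normalized to a control's target/reference ratio.

    A zero target is a valid "not detected" result and returns 0.0.
    """
    if reference_intensity <= 0:
        raise ValueError(
            f"reference intensity must be > 0, got {reference_intensity}"
        )
    if control_ratio <= 0:
        raise ValueError(f"control ratio must be > 0, got {control_ratio}")
    return (target_intensity / reference_intensity) / control_ratio


@dataclass(frozen=True)
class StateQuantification:
    """Fractional occupancy of modification states at one position."""

    fractions: Mapping[str, float]
    residual: float
    position: int | None = None

    def __post_init__(self) -> None:
        total = sum(self.fractions.values()) + self.residual
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions + residual must equal 1, got {total}")


def quantify_states(
    intensities: Mapping[str, float],
    assigned_fraction: float = 1.0,
    position: int | None = None,
) -> StateQuantification:
    """Turn per-state intensities into fractions summing (with residual) to 1.

    ``assigned_fraction`` scales the named states when they are known to
    cover only part of the molecule population; the remainder is reported
    as an explicit residual rather than forced onto named states.
    """
    if not intensities:
        raise ValueError("at least one state is required")
    if any(v < 0 for v in intensities.values()):
        raise ValueError("intensities must be >= 0")
    if not 0.0 < assigned_fraction <= 1.0:
        raise ValueError("assigned_fraction must be in (0, 1]")
    total = sum(intensities.values())
    if total == 0:
        raise ValueError("all state intensities are zero")
    fractions = {
        state: value / total * assigned_fraction
        for state, value in intensities.items()
    }
    return StateQuantification(
        fractions=fractions,
        residual=1.0 - sum(fractions.values()),
        position=position,
    )


# -- peak-list I/O ---------------------------------------------------------


def read_peak_list(path: str | Path) -> list[ObservedPeak]:
    """CSV/TSV with headers mz,charge,intensity[,rt]; '#' lines are comments."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    frame = pd.read_csv(path, sep=sep, comment="#")
    if "mz" not in frame.columns:
        raise ValueError(f"peak list {path} lacks an 'mz' column")
    peaks = []
    for row in frame.itertuples(index=False):
        charge = getattr(row, "charge", None)
        charge = int(charge) if charge is not None and pd.notna(charge) else None
        rt = getattr(row, "rt", None)
        rt = float(rt) if rt is not None and pd.notna(rt) else None
        peaks.append(
            ObservedPeak(
                mz=float(row.mz),
                charge=charge,
                intensity=float(getattr(row, "intensity", 0.0)),
                retention_time=rt,
            )
        )
    return peaks


def write_peak_list(peaks: Sequence[ObservedPeak], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "mz": [p.mz for p in peaks],
            "charge": [p.charge for p in peaks],
            "intensity": [p.intensity for p in peaks],
            "rt": [p.retention_time for p in peaks],
        }
    )
    frame.to_csv(path, index=False)
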