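"""Synthetic-data generators with known ground truth.

Every generator is driven by a :class:`SimulationConfig` seed through
``numpy.random.default_rng``, so the same config reproduces the same
records, peak lists, panels and mixtures bit for bit.

Noise model conventions: m/z jitter is Gaussian on the ppm scale,
intensities are log-normal, and peak dropout is Bernoulli — stated
stand-ins for instrument behaviour, not fitted distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .digestion import EnzymeRule, digest
from .masscalc import PredictedIon, predict_ions
from .matching import DetectionMatrix, ObservedPeak
from .registry import Registry, default_registry
from .sequence import ModifiedSequence, TRNARecord, naive_numbering

__all__ = [
    "SimulationConfig",
    "PeakTruth",
    "simulate_trnas",
    "simulate_peaklist",
    "simulate_strain_panel",
    "simulate_state_mixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for all synthetic generators; the seed fixes all randomness."""

    seed: int = 0
    n_trnas: int = 6
    trna_length: int = 76
    #: standard position -> (residue code, occupancy probability)
    modification_profile: Mapping[int, tuple[str, float]] = field(
        default_factory=lambda: {37: ("t6A", 1.0)}
    )
    mz_jitter_ppm: float = 0.0
    intensity_log_mean: float = 10.0
    intensity_log_sd: float = 1.0
    dropout: float = 0.0
    #: gene -> set of modification codes whose presence requires the gene
    strain_panel: Mapping[str, frozenset[str]] = field(default_factory=dict)
    charges: tuple[int, ...] = (1, 2)

    def __post_init__(self) -> None:
        for position, (code, prob) in self.modification_profile.items():
            if not 0.0 <= prob <= 1.0:
                raise ValueError(
                    f"occupancy probability for position {position} ({code}) "
                    f"must be in [0, 1], got {prob}"
                )
        if not 0.0 <= self.dropout <= 1.0:
            raise ValueError(f"dropout must be in [0, 1], got {self.dropout}")
        if self.mz_jitter_ppm < 0:
            raise ValueError(f"mz jitter must be >= 0, got {self.mz_jitter_ppm}")


_BASES = np.array(list("ACGU"))


def simulate_trnas(
    config: SimulationConfig, registry: Registry | None = None
) -> tuple[list[TRNARecord], dict[str, dict[int, str]]]:
    """Random tRNA-like records plus their ground-truth modification map.

    Records use naive standard numbering (position n = index n-1) over a
    random backbone; each profiled standard position is modified with its
    configured occupancy probability. The anticodon position 36 is forced
    to U so that every record is an ANN decoder unless the profile says
    otherwise.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng([config.seed, 1])
    records: list[TRNARecord] = []
    truth: dict[str, dict[int, str]] = {}
    for index in range(config.n_trnas):
        letters = rng.choice(_BASES, size=config.trna_length).tolist()
        numbering = naive_numbering(config.trna_length)
        letters[numbering[36]] = "U"
        # guarantee a cleavage anchor on each side of the anticodon loop
        letters[numbering[33]] = "G"
        letters[numbering[39]] = "G"
        planted: dict[int, str] = {}
        for position, (code, prob) in sorted(config.modification_profile.items()):
            if position not in numbering:
                raise ValueError(
                    f"profiled position {position} outside records of length "
                    f"{config.trna_length}"
                )
            if code not in registry:
                raise ValueError(f"profiled residue code {code!r} not registered")
            if rng.random() < prob:
                letters[numbering[position]] = registry.resolve(code)
                planted[position] = registry.resolve(code)
        record = TRNARecord(
            id=f"sim{index:03d}",
            organism="synthetic",
            sequence=ModifiedSequence(tuple(letters)),
            numbering_map=numbering,
        )
        records.append(record)
        truth[record.id] = planted
    return records, truth


@dataclass(frozen=True)
class PeakTruth:
    """Link between an emitted peak and the ion that generated it."""

    peak_index: int
    record_id: str
    ion: PredictedIon
    jitter_ppm: float


def simulate_peaklist(
    records: Sequence[TRNARecord],
    enzyme: EnzymeRule,
    config: SimulationConfig,
    registry: Registry | None = None,
) -> tuple[list[ObservedPeak], list[PeakTruth], list[PredictedIon]]:
    """Noisy digest peak list plus its truth table.

    Returns ``(peaks, truth, predicted)`` where ``predicted`` is the full
    noiseless ion list (one entry per fragment x charge state), ``peaks``
    carries ppm-jittered m/z with log-normal intensities after Bernoulli
    dropout, and ``truth`` links every emitted peak back to its source ion.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng([config.seed, 2])
    predicted: list[PredictedIon] = []
    origins: list[str] = []
    for record in records:
        for fragment in digest(
            record.sequence, enzyme, registry, parent_id=record.id
        ):
            for ion in predict_ions(
                fragment.sequence, charges=config.charges, registry=registry
            ):
                predicted.append(ion)
                origins.append(record.id)
    peaks: list[ObservedPeak] = []
    truth: list[PeakTruth] = []
    for ion, record_id in zip(predicted, origins):
        if rng.random() < config.dropout:
            continue
        jitter_ppm = (
            rng.normal(0.0, config.mz_jitter_ppm) if config.mz_jitter_ppm else 0.0
        )
        observed_mz = ion.mz * (1.0 + jitter_ppm * 1e-6)
        intensity = float(
            rng.lognormal(config.intensity_log_mean, config.intensity_log_sd)
        )
        truth.append(
            PeakTruth(
                peak_index=len(peaks),
                record_id=record_id,
                ion=ion,
                jitter_ppm=float(jitter_ppm),
            )
        )
        peaks.append(
            ObservedPeak(mz=observed_mz, charge=ion.charge, intensity=intensity)
        )
    return peaks, truth, predicted


def simulate_strain_panel(
    config: SimulationConfig,
    extra_marks: Sequence[str] = (),
    wild_type: str = "WT",
    base_intensity: float = 100.0,
) -> tuple[DetectionMatrix, dict[str, frozenset[str]]]:
    """Deletion-strain detection matrix plus the causal gene->marks map.

    The wild-type row detects every mark; each knockout row lacks exactly
    the marks its gene is required for, minus random dropout of the
    remaining marks.
    """
    if not config.strain_panel:
        raise ValueError("strain_panel spec is empty")
    rng = np.random.default_rng([config.seed, 3])
    causal = {gene: frozenset(marks) for gene, marks in config.strain_panel.items()}
    marks = sorted(set().union(*causal.values()) | set(extra_marks))
    unknown = [
        mark
        for gene_marks in causal.values()
        for mark in gene_marks
        if mark not in marks
    ]
    assert not unknown
    rows: dict[str, list[float]] = {wild_type: [base_intensity] * len(marks)}
    for gene in sorted(causal):
        row = []
        for mark in marks:
            if mark in causal[gene]:
                row.append(0.0)
            elif config.dropout and rng.random() < config.dropout:
                row.append(0.0)
            else:
                row.append(base_intensity)
        rows[f"Δ{gene}"] = row
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=marks)
    return DetectionMatrix(frame), causal


def simulate_state_mixture(
    fractions: Mapping[str, float],
    n_ions: int,
    config: SimulationConfig,
    intensity_noise_sd: float = 0.0,
) -> dict[str, float]:
    """Multinomial draw of n_ions across states, returned as intensities.

    ``fractions`` may sum to less than 1; the remainder is simulated as an
    unassigned pool and simply not reported (it never reaches the named
    states). Per-ion multiplicative log-normal noise is optional.
    """
    if any(v < 0 for v in fractions.values()):
        raise ValueError("fractions must be >= 0")
    total = sum(fractions.values())
    if total > 1.0 + 1e-9:
        raise ValueError(f"fractions must sum to <= 1, got {total}")
    if n_ions < 0:
        raise ValueError("n_ions must be >= 0")
    rng = np.random.default_rng([config.seed, 4])
    states = sorted(fractions)
    probs = [fractions[s] for s in states]
    remainder = max(0.0, 1.0 - total)
    counts = rng.multinomial(n_ions, probs + [remainder])
    intensities: dict[str, float] = {}
    for state, count in zip(states, counts):
        if intensity_noise_sd > 0 and count > 0:
            weights = rng.lognormal(
                -0.5 * intensity_noise_sd**2, intensity_noise_sd, size=int(count)
            )
            intensities[state] = float(weights.sum())
        else:
            intensities[state] = float(count)
    return intensities
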