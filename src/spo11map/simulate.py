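"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates what a curated Spo11-oligo experiment delivers,
without any sequence-level simulation: a truth set of non-overlapping
hot spots with heavy-tailed intensities, per-base count maps drawn
multinomially from hot-spot plus uniform-background weights, and noisy
unimodal PFGE/ChIP time courses.  Chromosome copy number multiplies a
chromosome's expected weight, and a focal chromosome can carry a
time-indexed fold boost mimicking the DSB overrepresentation that
builds on an engagement-defective chromosome late in prophase.

Everything is a pure function of (scenario, seed): repeat calls are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .genome_io import GenomeAssembly, IntegrityError, NormState, SignalMap, TimeCourse
from .kinetics import lognormal_model
from .landscape import DomainScheme, classify_interval

__all__ = [
    "SimScenario",
    "toy_assembly",
    "simulate_truth",
    "simulate_map",
    "simulate_pfge_timecourse",
    "simulate_chip_timecourse",
]


def toy_assembly(copy_number: Mapping[str, int] | None = None) -> GenomeAssembly:
    """A 4-chromosome toy genome spanning the yeast size range
    (200 kb to 1.5 Mb), centromeres mid-arm, no rDNA."""
    lengths = {"chr1": 200_000, "chr2": 500_000, "chr3": 900_000, "chr4": 1_500_000}
    cens = {c: L // 3 for c, L in lengths.items()}
    return GenomeAssembly(
        tuple(lengths), lengths, cens, None, frozenset(), dict(copy_number or {})
    )


@dataclass(frozen=True)
class SimScenario:
    """Study conditions for one simulated experiment.

    ``hotspot_density_per_kb`` defaults to 0.3/kb, the genome-wide rate
    of called hot spots in S. cerevisiae (~3600 over 12 Mb).
    Intensities are gamma distributed; shape 0.6 gives the heavy right
    tail seen in hot-spot strength spectra.  ``background_fraction`` is
    the share of reads falling outside hot spots.  ``fold_schedule``
    maps time (h) to the focal chromosome's multiplicative boost; times
    absent from the schedule get fold 1.  ``domain_modulation`` maps
    domain class names (e.g. "Tel") to weight multipliers on hot spots
    in that domain.
    """

    assembly: GenomeAssembly
    seed: int
    hotspot_density_per_kb: float = 0.3
    intensity_shape: float = 0.6
    intensity_scale: float = 1.0
    background_fraction: float = 0.15
    width_range_bp: tuple[int, int] = (50, 500)
    focal_chrom: str | None = None
    fold_schedule: Mapping[float, float] = field(default_factory=dict)
    domain_modulation: Mapping[str, float] = field(default_factory=dict)
    reads_per_timepoint: int = 1_000_000

    def __post_init__(self):
        if self.hotspot_density_per_kb < 0:
            raise IntegrityError("hotspot density must be >= 0")
        if not (0.0 <= self.background_fraction <= 1.0):
            raise IntegrityError("background_fraction must be in [0, 1]")
        if any(f <= 0 for f in self.fold_schedule.values()):
            raise IntegrityError("fold schedule must be positive")
        if any(f < 0 for f in self.domain_modulation.values()):
            raise IntegrityError("domain modulation must be >= 0")
        w0, w1 = self.width_range_bp
        if not (0 < w0 <= w1):
            raise IntegrityError("invalid width range")

    def fold_at(self, time_point: float) -> float:
        return float(self.fold_schedule.get(time_point, 1.0))


def simulate_truth(scenario: SimScenario) -> pd.DataFrame:
    """Draw the true hot-spot landscape for a scenario.

    Returns a DataFrame (chrom, start, end, intensity), 1-based closed,
    non-overlapping within each chromosome, intensities i.i.d.
    gamma(shape, scale).  Raises when the requested density cannot be
    placed without overlap.
    """
    import bisect

    rng = np.random.default_rng([scenario.seed, 0xA11])
    w0, w1 = scenario.width_range_bp
    rows = []
    for chrom in scenario.assembly.chrom_names:
        L = scenario.assembly.length_of(chrom)
        n = int(round(scenario.hotspot_density_per_kb * L / 1000.0))
        if n * w0 > L:
            raise IntegrityError(
                f"hotspot density too high to place without overlap on {chrom}"
            )
        placed: list[tuple[int, int]] = []   # sorted by start
        attempts = 0
        while len(placed) < n:
            attempts += 1
            if attempts > 200 * max(n, 1):
                raise IntegrityError(
                    f"hotspot density too high to place without overlap on {chrom}"
                )
            width = int(rng.integers(w0, w1 + 1))
            if width > L:
                continue
            start = int(rng.integers(1, L - width + 2))
            end = start + width - 1
            i = bisect.bisect_left(placed, (start, start))
            if i > 0 and placed[i - 1][1] >= start:
                continue
            if i < len(placed) and placed[i][0] <= end:
                continue
            placed.insert(i, (start, end))
        intensities = rng.gamma(
            scenario.intensity_shape, scenario.intensity_scale, size=len(placed)
        )
        for (s, e), inten in zip(placed, intensities):
            rows.append({"chrom": chrom, "start": s, "end": e,
                         "intensity": float(inten)})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "intensity"])


def _triangular(width: int) -> np.ndarray:
    """Peaked-center within-hotspot read profile, summing to 1."""
    ramp = np.minimum(np.arange(1, width + 1), np.arange(width, 0, -1))
    return ramp / ramp.sum()


def simulate_map(
    truth: pd.DataFrame,
    scenario: SimScenario,
    time_point: float = 0.0,
) -> SignalMap:
    """Draw a RAW count map from the truth at one time point.

    Reads are allocated multinomially: a ``background_fraction`` share
    uniformly over the genome, the rest over hot spots with a
    triangular within-hotspot profile.  Hot-spot mass is first split
    across chromosomes proportional to chromosome length, then within
    each chromosome proportional to intensity, so equal-length
    chromosomes have exactly equal expected totals regardless of where
    the heavy-tail intensity draws landed (a chromosome without hot
    spots spreads its share uniformly).  Chromosome weights are then
    multiplied by copy_number / 2 (diploid baseline) and the focal
    chromosome additionally by the schedule's fold at ``time_point``.
    """
    asm = scenario.assembly
    scheme = (
        DomainScheme.EAR
        if "EAR" in scenario.domain_modulation
        else DomainScheme.FIG6E
    )
    weights = {}
    for chrom in asm.chrom_names:
        L = asm.length_of(chrom)
        weights[chrom] = np.full(L, scenario.background_fraction / asm.total_length)
    hot_share = 1.0 - scenario.background_fraction
    chrom_intensity = (
        truth.groupby("chrom")["intensity"].sum() if len(truth) else {}
    )
    for chrom in asm.chrom_names:
        L = asm.length_of(chrom)
        chrom_mass = hot_share * L / asm.total_length
        total_intensity = float(chrom_intensity.get(chrom, 0.0))
        if total_intensity <= 0:
            weights[chrom] += chrom_mass / L
            continue
        for row in truth[truth["chrom"] == chrom].itertuples():
            mod = 1.0
            if scenario.domain_modulation:
                cls = classify_interval(row.chrom, row.start, row.end, asm, scheme)
                mod = float(scenario.domain_modulation.get(cls.value, 1.0))
            mass = chrom_mass * row.intensity / total_intensity * mod
            width = row.end - row.start + 1
            weights[row.chrom][row.start - 1 : row.end] += mass * _triangular(width)

    for chrom in asm.chrom_names:
        factor = asm.copies(chrom) / 2.0
        if chrom == scenario.focal_chrom:
            factor *= scenario.fold_at(time_point)
        weights[chrom] *= factor

    flat = np.concatenate([weights[c] for c in asm.chrom_names])
    total_w = flat.sum()
    if total_w <= 0:
        raise IntegrityError("zero total weight; nothing to sample")
    rng = np.random.default_rng(
        [scenario.seed, 0x3A9, int(round(time_point * 1000))]
    )
    counts = rng.multinomial(scenario.reads_per_timepoint, flat / total_w)
    data = {}
    offset = 0
    for chrom in asm.chrom_names:
        L = asm.length_of(chrom)
        data[chrom] = counts[offset : offset + L].astype(np.float64)
        offset += L
    return SignalMap(asm, data, NormState.RAW)


def simulate_pfge_timecourse(
    a: float,
    b: float,
    c: float,
    d: float,
    sigma: float,
    grid: np.ndarray,
    seed: int,
    label: str = "pfge",
) -> TimeCourse:
    """Noisy draw from the log-normal DSB timing curve on a time grid.

    Gaussian noise of SD ``sigma`` is added to each point; values are
    floored at 0 to respect the measurement domain.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if d <= 0:
        raise IntegrityError("d must be > 0")
    y = lognormal_model(grid, a, b, c, d)
    if sigma > 0:
        rng = np.random.default_rng([seed, 0x9F6E])
        y = y + rng.normal(0.0, sigma, size=grid.size)
    return TimeCourse(grid, np.maximum(y, 0.0), label)


def simulate_chip_timecourse(
    t_assoc: float,
    t_dissoc: float,
    L: float,
    k_rise: float,
    k_fall: float,
    sigma: float,
    grid: np.ndarray,
    seed: int,
    label: str = "chip",
) -> TimeCourse:
    """Rise-plateau-fall ChIP profile as a product of two logistics.

    y(t) = L * rise(t) * fall(t) with rise half-maximal at ``t_assoc``
    and fall half-maximal at ``t_dissoc``; Gaussian noise of SD
    ``sigma`` added, values floored at 0.
    """
    if not t_assoc < t_dissoc:
        raise IntegrityError("t_assoc must be < t_dissoc")
    grid = np.asarray(grid, dtype=np.float64)
    rise = 1.0 / (1.0 + np.exp(-k_rise * (grid - t_assoc)))
    fall = 1.0 / (1.0 + np.exp(k_fall * (grid - t_dissoc)))
    y = L * rise * fall
    if sigma > 0:
        rng = np.random.default_rng([seed, 0xC41])
        y = y + rng.normal(0.0, sigma, size=grid.size)
    return TimeCourse(grid, np.maximum(y, 0.0), label)
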