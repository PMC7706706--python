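"""Genome model, coordinate conventions, and on-disk formats.

Internal coordinates are 1-based closed intervals, following the SGD
convention used for the S. cerevisiae reference assemblies.  BED output
converts to 0-based half-open on write and back on read.

Per-base coverage is held in :class:`SignalMap`: one float64 array per
nuclear chromosome, index 0 holding position 1.  Maps are strand-collapsed
totals — curated Spo11-oligo maps are deposited as single tracks.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeAssembly",
    "NormState",
    "SignalMap",
    "TimeCourse",
    "Hotspot",
    "HotspotSet",
    "FormatError",
    "IntegrityError",
    "load_default_assembly",
    "read_assembly_table",
    "read_signal_map",
    "write_signal_map",
    "read_hotspots",
    "write_hotspots",
    "read_timecourse",
    "write_timecourse",
]


class FormatError(ValueError):
    """An on-disk file violates the expected dialect."""


class IntegrityError(ValueError):
    """An in-memory object violates its own invariants."""


# ---------------------------------------------------------------------------
# assembly


@dataclass(frozen=True)
class GenomeAssembly:
    """Chromosome geometry and copy-number state of one genome.

    Parameters
    ----------
    chrom_names
        Ordered chromosome identifiers (nuclear chromosomes only).
    chrom_lengths
        Length in bp per chromosome.
    centromere_mid
        Centromere midpoint (1-based bp) per chromosome.
    rdna_interval
        ``(chrom, start, end)`` of the rDNA repeat locus, 1-based closed,
        or ``None`` if the assembly has no annotated rDNA.  Signal inside
        this interval is masked out of all genome-wide totals.
    excluded_sequences
        Names of non-nuclear sequences (mitochondrion, 2-micron plasmid)
        that readers silently drop.
    copy_number
        Copies of each chromosome per cell; the diploid baseline is 2.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: Mapping[str, int]
    centromere_mid: Mapping[str, int]
    rdna_interval: tuple[str, int, int] | None = None
    excluded_sequences: frozenset[str] = frozenset()
    copy_number: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for name in self.chrom_names:
            if name not in self.chrom_lengths:
                raise IntegrityError(f"no length for chromosome {name!r}")
            L = self.chrom_lengths[name]
            if L <= 0:
                raise IntegrityError(f"non-positive length for {name!r}")
            mid = self.centromere_mid.get(name)
            if mid is not None and not (1 <= mid <= L):
                raise IntegrityError(
                    f"centromere of {name!r} at {mid} outside [1, {L}]"
                )
        if self.rdna_interval is not None:
            chrom, start, end = self.rdna_interval
            if chrom not in self.chrom_lengths:
                raise IntegrityError(f"rDNA chromosome {chrom!r} not in assembly")
            if not (1 <= start <= end <= self.chrom_lengths[chrom]):
                raise IntegrityError("rDNA interval outside chromosome bounds")
        for name, cn in self.copy_number.items():
            if cn < 1:
                raise IntegrityError(f"copy number {cn} < 1 for {name!r}")

    def length_of(self, chrom: str) -> int:
        return self.chrom_lengths[chrom]

    def copies(self, chrom: str) -> int:
        """Copy number of *chrom*; 2 (diploid) when unstated."""
        return self.copy_number.get(chrom, 2)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths[c] for c in self.chrom_names)

    @property
    def included_length(self) -> int:
        """Total nuclear length minus the masked rDNA interval."""
        total = self.total_length
        if self.rdna_interval is not None:
            _, start, end = self.rdna_interval
            total -= end - start + 1
        return total

    def with_copy_number(self, **copies: int) -> "GenomeAssembly":
        """Return a copy with updated per-chromosome copy numbers."""
        cn = dict(self.copy_number)
        cn.update(copies)
        return GenomeAssembly(
            self.chrom_names,
            self.chrom_lengths,
            self.centromere_mid,
            self.rdna_interval,
            self.excluded_sequences,
            cn,
        )


def read_assembly_table(path: str | Path) -> GenomeAssembly:
    """Read an assembly description TSV.

    Expected columns: ``chrom``, ``length``, ``cen_mid`` and optional
    ``rdna_start``/``rdna_end`` (filled on the rDNA-bearing chromosome
    only) and ``copy_number``.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "length", "cen_mid"}
    if not required.issubset(df.columns):
        raise FormatError(f"assembly table needs columns {sorted(required)}")
    names = tuple(df["chrom"].astype(str))
    lengths = dict(zip(names, df["length"].astype(int)))
    cens = {
        str(row["chrom"]): int(row["cen_mid"])
        for _, row in df.iterrows()
        if pd.notna(row["cen_mid"])
    }
    rdna = None
    if {"rdna_start", "rdna_end"}.issubset(df.columns):
        has = df.dropna(subset=["rdna_start", "rdna_end"])
        if len(has) > 1:
            raise FormatError("more than one rDNA interval in assembly table")
        if len(has) == 1:
            row = has.iloc[0]
            rdna = (str(row["chrom"]), int(row["rdna_start"]), int(row["rdna_end"]))
    copy_number = {}
    if "copy_number" in df.columns:
        copy_number = dict(zip(names, df["copy_number"].astype(int)))
    return GenomeAssembly(
        names, lengths, cens, rdna,
        frozenset({"chrM", "chrMito", "2micron"}), copy_number,
    )


def write_assembly_table(assembly: GenomeAssembly, path: str | Path) -> None:
    """Write an assembly description TSV readable by
    :func:`read_assembly_table`."""
    rows = []
    for chrom in assembly.chrom_names:
        row = {
            "chrom": chrom,
            "length": assembly.length_of(chrom),
            "cen_mid": assembly.centromere_mid.get(chrom, ""),
            "rdna_start": "",
            "rdna_end": "",
            "copy_number": assembly.copies(chrom),
        }
        if assembly.rdna_interval is not None and assembly.rdna_interval[0] == chrom:
            row["rdna_start"] = assembly.rdna_interval[1]
            row["rdna_end"] = assembly.rdna_interval[2]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_default_assembly() -> GenomeAssembly:
    """The packaged sacCer2 assembly (lengths, centromeres, rDNA)."""
    ref = resources.files("spo11map").joinpath("data/sacCer2_assembly.tsv")
    with resources.as_file(ref) as path:
        return read_assembly_table(path)


# ---------------------------------------------------------------------------
# per-base signal


class NormState(enum.Enum):
    """Normalization state of a coverage map."""

    RAW = "raw"
    RPM = "rpm"     # reads per million mapped, rDNA/mito/2-micron excluded
    NRPM = "nrpm"   # RPM after chromosome copy-number correction


@dataclass
class SignalMap:
    """Per-base non-negative coverage over one assembly."""

    assembly: GenomeAssembly
    data: dict[str, np.ndarray]
    state: NormState = NormState.RAW

    def __post_init__(self):
        for chrom in self.assembly.chrom_names:
            if chrom not in self.data:
                self.data[chrom] = np.zeros(
                    self.assembly.length_of(chrom), dtype=np.float64
                )
        for chrom, arr in self.data.items():
            if chrom not in self.assembly.chrom_lengths:
                raise IntegrityError(f"unknown chromosome {chrom!r} in map")
            arr = np.asarray(arr, dtype=np.float64)
            if arr.shape != (self.assembly.length_of(chrom),):
                raise IntegrityError(
                    f"{chrom}: array length {arr.size} != chromosome length "
                    f"{self.assembly.length_of(chrom)}"
                )
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise IntegrityError(f"{chrom}: values must be finite and >= 0")
            self.data[chrom] = arr

    @classmethod
    def zeros(cls, assembly: GenomeAssembly,
              state: NormState = NormState.RAW) -> "SignalMap":
        return cls(assembly, {}, state)

    def copy(self) -> "SignalMap":
        return SignalMap(
            self.assembly,
            {c: a.copy() for c, a in self.data.items()},
            self.state,
        )

    def masked_values(self, chrom: str) -> np.ndarray:
        """Values with the rDNA interval zeroed (view-safe copy when masked)."""
        arr = self.data[chrom]
        rdna = self.assembly.rdna_interval
        if rdna is not None and rdna[0] == chrom:
            arr = arr.copy()
            arr[rdna[1] - 1 : rdna[2]] = 0.0
        return arr

    def chrom_total(self, chrom: str, masked: bool = True) -> float:
        arr = self.masked_values(chrom) if masked else self.data[chrom]
        return float(arr.sum())

    @property
    def total_included(self) -> float:
        """Sum over nuclear chromosomes with the rDNA interval masked."""
        return sum(self.chrom_total(c) for c in self.assembly.chrom_names)


# ---------------------------------------------------------------------------
# wiggle / bedGraph

_STATE_TAG = "#spo11map-state="


def read_signal_map(path: str | Path, assembly: GenomeAssembly) -> SignalMap:
    """Read a wiggle (variableStep span=1 / fixedStep) or bedGraph file.

    Positions not listed are zero.  Sequences named in
    ``assembly.excluded_sequences`` are skipped; any other chromosome not
    in the assembly raises :class:`FormatError`.  The state is RAW unless
    a ``#spo11map-state=`` header records a prior normalization.
    """
    data = {c: np.zeros(assembly.length_of(c)) for c in assembly.chrom_names}
    state = NormState.RAW
    mode = None          # "variable" | "fixed" | "bedgraph"
    chrom = None
    skip_chrom = False
    pos = step = span = 1
    seen_bg: dict[str, list[tuple[int, int]]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(_STATE_TAG):
                state = NormState(line[len(_STATE_TAG):].strip().lower())
                continue
            if line.startswith("#"):
                continue
            if line.startswith("track"):
                if "type=bedGraph" in line:
                    mode = "bedgraph"
                continue
            if line.startswith("variableStep") or line.startswith("fixedStep"):
                fields = dict(
                    kv.split("=") for kv in line.split()[1:] if "=" in kv
                )
                chrom = fields.get("chrom")
                if chrom is None:
                    raise FormatError(f"line {lineno}: step header without chrom")
                skip_chrom = chrom in assembly.excluded_sequences
                if not skip_chrom and chrom not in assembly.chrom_lengths:
                    raise FormatError(
                        f"line {lineno}: unknown chromosome {chrom!r}"
                    )
                span = int(fields.get("span", 1))
                if line.startswith("variableStep"):
                    mode = "variable"
                    if span != 1:
                        raise FormatError(
                            f"line {lineno}: variableStep span={span} "
                            "unsupported (span=1 only)"
                        )
                else:
                    mode = "fixed"
                    pos = int(fields["start"])
                    step = int(fields.get("step", 1))
                continue

            parts = line.split()
            if mode is None and len(parts) == 4:
                mode = "bedgraph"
            if mode == "bedgraph":
                if len(parts) != 4:
                    raise FormatError(f"line {lineno}: malformed bedGraph record")
                bchrom, bstart, bend, val = (
                    parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                )
                if bchrom in assembly.excluded_sequences:
                    continue
                if bchrom not in assembly.chrom_lengths:
                    raise FormatError(
                        f"line {lineno}: unknown chromosome {bchrom!r}"
                    )
                if bend > assembly.length_of(bchrom):
                    raise FormatError(f"line {lineno}: interval beyond chromosome")
                for s, e in seen_bg.get(bchrom, ()):
                    if bstart < e and s < bend:
                        raise FormatError(
                            f"line {lineno}: overlapping bedGraph intervals "
                            f"on {bchrom}"
                        )
                seen_bg.setdefault(bchrom, []).append((bstart, bend))
                data[bchrom][bstart:bend] = val
                continue

            if chrom is None:
                raise FormatError(f"line {lineno}: data before step header")
            if mode == "variable":
                if len(parts) != 2:
                    raise FormatError(f"line {lineno}: malformed variableStep record")
                p, val = int(parts[0]), float(parts[1])
                if skip_chrom:
                    continue
                if not (1 <= p <= assembly.length_of(chrom)):
                    raise FormatError(
                        f"line {lineno}: position {p} outside {chrom}"
                    )
                data[chrom][p - 1] = val
            else:  # fixed
                val = float(parts[0])
                if not skip_chrom:
                    if not (1 <= pos <= assembly.length_of(chrom) - span + 1):
                        raise FormatError(
                            f"line {lineno}: position {pos} outside {chrom}"
                        )
                    data[chrom][pos - 1 : pos - 1 + span] = val
                pos += step

    return SignalMap(assembly, data, state)


def write_signal_map(smap: SignalMap, path: str | Path) -> None:
    """Write as variableStep span=1 wiggle, full float precision.

    Only nonzero positions are emitted; a header comment records the
    normalization state so round-trips preserve it.
    """
    with open(path, "w") as fh:
        fh.write(f"{_STATE_TAG}{smap.state.value}\n")
        fh.write('track type=wiggle_0 name="spo11map"\n')
        for chrom in smap.assembly.chrom_names:
            arr = smap.data[chrom]
            nz = np.nonzero(arr)[0]
            if nz.size == 0:
                continue
            fh.write(f"variableStep chrom={chrom} span=1\n")
            for i in nz:
                fh.write(f"{i + 1} {arr[i]:.17g}\n")


# ---------------------------------------------------------------------------
# hotspots


@dataclass(frozen=True)
class Hotspot:
    """One called hot spot, 1-based closed coordinates."""

    chrom: str
    start: int
    end: int
    total_signal: float = 0.0     # summed raw (unsmoothed) map values, nRPM
    peak_smoothed: float = 0.0    # max smoothed density inside

    def __post_init__(self):
        if self.start > self.end:
            raise IntegrityError(f"hotspot start {self.start} > end {self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "Hotspot") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class HotspotSet:
    """Sorted, non-overlapping hot spots plus calling provenance."""

    hotspots: list[Hotspot]
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.hotspots = sorted(self.hotspots, key=lambda h: (h.chrom, h.start))
        prev: Hotspot | None = None
        for h in self.hotspots:
            if prev is not None and prev.chrom == h.chrom and h.start <= prev.end:
                raise IntegrityError(
                    f"overlapping hotspots on {h.chrom}: "
                    f"[{prev.start},{prev.end}] and [{h.start},{h.end}]"
                )
            prev = h

    def __len__(self) -> int:
        return len(self.hotspots)

    def __iter__(self):
        return iter(self.hotspots)

    def on_chrom(self, chrom: str) -> list[Hotspot]:
        return [h for h in self.hotspots if h.chrom == chrom]


def write_hotspots(hs: HotspotSet, path: str | Path) -> None:
    """Write a BED6+2 file: 0-based half-open, exact strength in column 7,
    peak smoothed density in column 8.  The score column is the total
    signal clamped to the BED 0-1000 integer convention."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\ttotal_signal\tpeak_smoothed\n")
        for i, h in enumerate(hs):
            score = int(min(1000, max(0, round(h.total_signal))))
            fh.write(
                f"{h.chrom}\t{h.start - 1}\t{h.end}\ths_{i + 1}\t{score}\t.\t"
                f"{h.total_signal:.17g}\t{h.peak_smoothed:.17g}\n"
            )


def read_hotspots(path: str | Path) -> HotspotSet:
    """Read back a BED file produced by :func:`write_hotspots` (or any
    3+-column BED; strengths default to 0)."""
    hotspots = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError("BED record with fewer than 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            total = float(parts[6]) if len(parts) > 6 else 0.0
            peak = float(parts[7]) if len(parts) > 7 else 0.0
            hotspots.append(Hotspot(chrom, start + 1, end, total, peak))
    return HotspotSet(hotspots)


# ---------------------------------------------------------------------------
# time courses


@dataclass
class TimeCourse:
    """A (time, measurement) series for one locus or probe.

    Times are hours from meiotic induction, strictly increasing; values
    are percent broken DNA (PFGE) or percent-of-input (ChIP), finite and
    non-negative.
    """

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise IntegrityError("times and values must be equal-length 1-D")
        if np.any(np.diff(self.times) <= 0):
            raise IntegrityError(f"{self.label!r}: times not strictly increasing")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise IntegrityError(f"{self.label!r}: values must be finite and >= 0")

    def __len__(self) -> int:
        return self.times.size


def read_timecourse(path: str | Path) -> list[TimeCourse]:
    """Read a TSV with columns ``time_h``, ``value``, ``label`` into one
    TimeCourse per label, times sorted ascending."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"time_h", "value", "label"}
    if not required.issubset(df.columns):
        raise FormatError(f"time-course TSV needs columns {sorted(required)}")
    if df.duplicated(subset=["label", "time_h"]).any():
        raise FormatError("duplicate (label, time_h) rows")
    if (df["value"] < 0).any():
        raise FormatError("negative measurement values")
    out = []
    for label, grp in df.groupby("label", sort=True):
        grp = grp.sort_values("time_h")
        out.append(
            TimeCourse(
                grp["time_h"].to_numpy(float),
                grp["value"].to_numpy(float),
                str(label),
            )
        )
    return out


def write_timecourse(courses: Iterable[TimeCourse], path: str | Path) -> None:
    rows = [
        {"time_h": t, "value": v, "label": tc.label}
        for tc in courses
        for t, v in zip(tc.times, tc.values)
    ]
    pd.DataFrame(rows, columns=["time_h", "value", "label"]).to_csv(
        path, sep="\t", index=False
    )
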