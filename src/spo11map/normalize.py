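"""Map normalization: RPM, copy-number correction, cross-map scaling.

Normalization proceeds in up to three stages.  RPM scales a raw map so
the total over nuclear chromosomes (rDNA masked) is one million.  A copy
number correction then places aneuploid or homeologous chromosomes on a
per-homolog-pair scale (nRPM): a trisomic chromosome is multiplied by
2/3, a single-copy chromosome whose partner is absent or diverged is
either doubled or has its partner's reads summed in.  Finally two maps
being compared are cross-scaled so that their totals over the non-focal
chromosomes agree, which protects per-chromosome comparisons from the
zero-sum distortion RPM introduces when one chromosome gains reads.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .genome_io import GenomeAssembly, IntegrityError, NormState, SignalMap

__all__ = [
    "HomeologMode",
    "CopyCorrectionScheme",
    "rpm_normalize",
    "correct_copy_number",
    "cross_scale",
    "per_chromosome_totals",
    "apply_global_scale",
]


class HomeologMode(enum.Enum):
    """How to correct a chromosome whose homolog is a diverged partner.

    SUM adds the partner chromosome's reads to the native copy (used for
    per-chromosome totals); DOUBLE multiplies the native copy by two
    (used for within-chromosome profiles, where partner coordinates do
    not line up base-by-base).
    """

    SUM = "sum"
    DOUBLE = "double"


@dataclass(frozen=True)
class CopyCorrectionScheme:
    """Per-chromosome multiplicative correction factors.

    ``factors`` maps chromosome name to a positive multiplier, e.g. 2/3
    for a trisomic chromosome or 2 for a single-copy chromosome under
    DOUBLE mode.  ``from_assembly`` derives factors as 2 / copy_number
    against the diploid baseline.
    """

    factors: Mapping[str, float] = field(default_factory=dict)
    mode: HomeologMode = HomeologMode.DOUBLE
    sum_chrom: str | None = None   # chromosome receiving partner reads in SUM mode

    def __post_init__(self):
        for chrom, f in self.factors.items():
            if not f > 0:
                raise IntegrityError(f"correction factor {f} for {chrom!r} not > 0")

    @classmethod
    def from_assembly(cls, assembly: GenomeAssembly,
                      mode: HomeologMode = HomeologMode.DOUBLE,
                      sum_chrom: str | None = None) -> "CopyCorrectionScheme":
        factors = {
            c: 2.0 / assembly.copies(c)
            for c in assembly.chrom_names
            if assembly.copies(c) != 2
        }
        return cls(factors, mode, sum_chrom)


def rpm_normalize(smap: SignalMap, assembly: GenomeAssembly | None = None) -> SignalMap:
    """Scale a RAW map to reads per million mapped (RPM).

    The rDNA interval is zeroed before totaling and in the output;
    mitochondrial and plasmid sequences are absent from the nuclear
    assembly by construction.  After normalization the included total is
    exactly 1e6 and per-base proportions outside masked regions are
    unchanged.
    """
    assembly = assembly or smap.assembly
    if smap.state is not NormState.RAW:
        raise IntegrityError(f"rpm_normalize expects a RAW map, got {smap.state}")
    total = smap.total_included
    if total <= 0:
        raise IntegrityError("empty map: no signal outside masked regions")
    factor = 1e6 / total
    data = {c: smap.masked_values(c) * factor for c in assembly.chrom_names}
    return SignalMap(assembly, data, NormState.RPM)


def correct_copy_number(
    smap: SignalMap,
    scheme: CopyCorrectionScheme,
    partner_map: SignalMap | None = None,
) -> SignalMap:
    """Apply chromosome copy-number correction, producing an nRPM map.

    In DOUBLE (or plain factor) mode each listed chromosome is multiplied
    by its factor; all other chromosomes are untouched.  In SUM mode the
    per-base reads of the partner chromosome (supplied as
    ``partner_map``, restricted to ``scheme.sum_chrom``) are added to the
    native copy — appropriate only for totals, since homeologous
    coordinates do not correspond base-by-base.
    """
    if smap.state is not NormState.RPM:
        raise IntegrityError(f"correct_copy_number expects an RPM map, got {smap.state}")
    out = smap.copy()
    out.state = NormState.NRPM
    if scheme.mode is HomeologMode.SUM:
        if scheme.sum_chrom is None:
            raise IntegrityError("SUM mode requires scheme.sum_chrom")
        if partner_map is None:
            raise IntegrityError("SUM mode requires a partner_map")
        chrom = scheme.sum_chrom
        partner = partner_map.data[chrom]
        n = min(partner.size, out.data[chrom].size)
        out.data[chrom][:n] += partner[:n]
    for chrom, f in scheme.factors.items():
        out.data[chrom] = out.data[chrom] * f
    return out


def cross_scale(
    map_a: SignalMap,
    map_b: SignalMap,
    focal_chrom: str,
) -> tuple[SignalMap, SignalMap, float]:
    """Scale two maps to a common total over the non-focal chromosomes.

    The standard total is the mean of the two maps' non-focal totals;
    each map is multiplied by standard / (its own non-focal total).
    After scaling both non-focal totals equal the standard, so focal
    chromosome totals are directly comparable.
    """
    if map_a.assembly is not map_b.assembly and (
        map_a.assembly.chrom_names != map_b.assembly.chrom_names
    ):
        raise IntegrityError("cross_scale requires maps on the same assembly")

    def nonfocal_total(m: SignalMap) -> float:
        return sum(
            m.chrom_total(c) for c in m.assembly.chrom_names if c != focal_chrom
        )

    ta, tb = nonfocal_total(map_a), nonfocal_total(map_b)
    if ta <= 0 or tb <= 0:
        raise IntegrityError("non-focal total is zero; cannot cross-scale")
    standard = (ta + tb) / 2.0
    out_a, out_b = map_a.copy(), map_b.copy()
    fa, fb = standard / ta, standard / tb
    for c in out_a.assembly.chrom_names:
        out_a.data[c] = out_a.data[c] * fa
        out_b.data[c] = out_b.data[c] * fb
    return out_a, out_b, standard


def per_chromosome_totals(
    smap: SignalMap, assembly: GenomeAssembly | None = None
) -> pd.DataFrame:
    """Per-chromosome summary: length, total signal, density.

    Returns a DataFrame with columns ``chrom``, ``length``, ``total``,
    ``total_krpm`` (total / 1000) and ``density`` (total / length,
    density over the full assembly length).  The rDNA interval is masked
    from the chrXII total, matching genome-wide totals.
    """
    assembly = assembly or smap.assembly
    rows = []
    for chrom in assembly.chrom_names:
        total = smap.chrom_total(chrom)
        length = assembly.length_of(chrom)
        rows.append(
            {
                "chrom": chrom,
                "length": length,
                "total": total,
                "total_krpm": total / 1000.0,
                "density": total / length,
            }
        )
    return pd.DataFrame(rows)


def apply_global_scale(smap: SignalMap, factor: float) -> SignalMap:
    """Multiply every value by a positive factor.

    Used to place a mutant map on an absolute-DSB scale when the mutant
    makes globally more breaks than wild type (e.g. 1.8-fold for a
    zip3 deletion, 1.7-fold for an ecm11 deletion), so that per-hotspot
    ratios read as absolute fold changes rather than changes in the
    relative landscape.
    """
    if not factor > 0:
        raise IntegrityError(f"global scale factor must be > 0, got {factor}")
    out = smap.copy()
    for c in out.data:
        out.data[c] = out.data[c] * factor
    return out
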