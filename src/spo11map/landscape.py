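"""Sub-chromosomal domain classification and domain-level DSB summaries.

Chromosomal position modulates how strongly a region responds to the
feedback that shuts down DSB formation once homologs engage.  Intervals
are classified by midpoint into:

* TEL — within 20 kb of a telomere (chromosome end);
* CEN — within 10 kb of the centromere midpoint;
* RDNA — from 60 kb left of the rDNA locus to 30 kb right of it;
* EAR — end-adjacent region, (20, 110] kb from the nearer telomere
  (only under the EAR scheme);
* INTERSTITIAL — everything else.

Precedence is TEL > (EAR) > CEN > RDNA > INTERSTITIAL; the 20-kb
boundary belongs to TEL, so TEL and EAR are disjoint by construction.
"""

from __future__ import annotations

import enum

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GenomeAssembly, HotspotSet, IntegrityError, SignalMap
from .hotspots import hotspot_fold_change

__all__ = [
    "DomainClass",
    "DomainScheme",
    "classify_interval",
    "classify_hotspots",
    "domain_fold_change",
    "size_density_correlation",
]

TEL_BP = 20_000
CEN_BP = 10_000
RDNA_LEFT_BP = 60_000
RDNA_RIGHT_BP = 30_000
EAR_FAR_BP = 110_000


class DomainClass(enum.Enum):
    TEL = "Tel"
    CEN = "Cen"
    RDNA = "rDNA"
    EAR = "EAR"
    INTERSTITIAL = "Interstitial"


class DomainScheme(enum.Enum):
    """FIG6E: Tel/Cen/rDNA/Interstitial.  EAR: adds the end-adjacent
    region after Tel in precedence."""

    FIG6E = "fig6e"
    EAR = "ear"


def classify_interval(
    chrom: str,
    start: int,
    end: int,
    assembly: GenomeAssembly,
    scheme: DomainScheme = DomainScheme.FIG6E,
) -> DomainClass:
    """Classify one 1-based closed interval by its midpoint."""
    L = assembly.length_of(chrom)
    if not (1 <= start <= end <= L):
        raise IntegrityError(
            f"interval [{start},{end}] outside {chrom} bounds [1,{L}]"
        )
    mid = (start + end) / 2.0
    tel_dist = min(mid, L - mid + 1)   # distance to the nearer chromosome end
    if tel_dist <= TEL_BP:
        return DomainClass.TEL
    if scheme is DomainScheme.EAR and tel_dist <= EAR_FAR_BP:
        return DomainClass.EAR
    cen = assembly.centromere_mid.get(chrom)
    if cen is not None and abs(mid - cen) <= CEN_BP:
        return DomainClass.CEN
    if assembly.rdna_interval is not None:
        rchrom, rstart, rend = assembly.rdna_interval
        if chrom == rchrom and rstart - RDNA_LEFT_BP <= mid <= rend + RDNA_RIGHT_BP:
            return DomainClass.RDNA
    return DomainClass.INTERSTITIAL


def classify_hotspots(
    hotspots: HotspotSet,
    assembly: GenomeAssembly,
    scheme: DomainScheme = DomainScheme.FIG6E,
) -> pd.DataFrame:
    """Per-hotspot domain labels; classes partition the set."""
    rows = [
        {
            "chrom": h.chrom,
            "start": h.start,
            "end": h.end,
            "midpoint": h.midpoint,
            "domain": classify_interval(h.chrom, h.start, h.end, assembly, scheme).value,
        }
        for h in hotspots
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "midpoint", "domain"])


def domain_fold_change(
    hotspots: HotspotSet,
    map_num: SignalMap,
    map_den: SignalMap,
    assembly: GenomeAssembly,
    scheme: DomainScheme = DomainScheme.FIG6E,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distribution of per-hotspot fold changes within each domain.

    Returns ``(per_hotspot, per_domain)``.  ``per_hotspot`` is the
    :func:`hotspot_fold_change` table plus a ``domain`` column.
    ``per_domain`` has one row per domain class with ``n``, ``median``,
    ``q1``, ``q3``, ``iqr``, Tukey whiskers (the most extreme points
    within 1.5 x IQR of the box) and the outliers beyond them.
    Domains with no hot spots are reported with n = 0.
    """
    per_hotspot = hotspot_fold_change(hotspots, map_num, map_den)
    if len(per_hotspot):
        per_hotspot["domain"] = [
            classify_interval(r.chrom, r.start, r.end, assembly, scheme).value
            for r in per_hotspot.itertuples()
        ]
    else:
        per_hotspot["domain"] = pd.Series(dtype=str)

    classes = [c for c in DomainClass
               if scheme is DomainScheme.EAR or c is not DomainClass.EAR]
    rows = []
    for cls in classes:
        ratios = per_hotspot.loc[
            (per_hotspot["domain"] == cls.value) & ~per_hotspot["flagged"], "ratio"
        ].to_numpy()
        if ratios.size == 0:
            rows.append(
                {"domain": cls.value, "n": 0, "median": np.nan, "q1": np.nan,
                 "q3": np.nan, "iqr": np.nan, "whisker_lo": np.nan,
                 "whisker_hi": np.nan, "outliers": ()}
            )
            continue
        q1, med, q3 = np.percentile(ratios, [25, 50, 75])
        iqr = q3 - q1
        in_fence = ratios[(ratios >= q1 - 1.5 * iqr) & (ratios <= q3 + 1.5 * iqr)]
        outliers = ratios[(ratios < q1 - 1.5 * iqr) | (ratios > q3 + 1.5 * iqr)]
        rows.append(
            {
                "domain": cls.value,
                "n": int(ratios.size),
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "iqr": float(iqr),
                "whisker_lo": float(in_fence.min()),
                "whisker_hi": float(in_fence.max()),
                "outliers": tuple(np.sort(outliers)),
            }
        )
    return per_hotspot, pd.DataFrame(rows)


def size_density_correlation(
    summaries: pd.DataFrame,
    exclude: tuple[str, ...] = (),
) -> float:
    """Pearson r between chromosome length and break density.

    ``summaries`` is a per-chromosome table with columns ``chrom``,
    ``length`` and ``density`` (as produced by
    :func:`spo11map.normalize.per_chromosome_totals`).  Small
    chromosomes normally show elevated density (negative r); loss of
    this anticorrelation marks engagement-defective landscapes.
    Named chromosomes can be excluded, e.g. a focal aneuploid one.
    """
    df = summaries[~summaries["chrom"].isin(exclude)]
    if len(df) < 3:
        raise IntegrityError("need at least 3 chromosomes for a correlation")
    x = df["length"].to_numpy(float)
    y = df["density"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise IntegrityError("zero variance: correlation undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r)
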