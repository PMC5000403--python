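"""Post-filtering of candidate low-frequency variant sites.

Works from a strand-stratified allele-count table — per site, the number of
consensus sequences supporting each allele on the plus and minus strand —
which any downstream variant caller can emit.  From these counts the module
computes the minor allele frequency (MAF) and a strand-bias (SB) score, and
applies the standard site filters for low-frequency variant discovery:
MAF >= 0.5 %, SB < 1, and optionally a minimum depth.

The strand-bias score used is

    SB = | b/(a+b) - d/(c+d) | / ( (b+d) / (a+b+c+d) )

with a, b the major/minor counts on the plus strand and c, d on the minus
strand (Guo et al. 2012, BMC Genomics 13:666).  Perfectly balanced strands
give 0 (the ideal value); growing imbalance gives larger scores; the score
is invariant under relabelling the strands.  A site with zero depth on
either strand has undefined SB and fails the filter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

log = logging.getLogger(__name__)

SITE_COLUMNS = ("chrom", "pos", "allele", "plus", "minus")


def maf(counts: Mapping[str, int]) -> float:
    """Minor allele frequency: second-most-frequent allele count over depth.

    Ties are broken by count, then alphabetically by allele, so the result
    is deterministic.  A monoallelic site has MAF 0; zero total depth is an
    error.
    """
    depth = sum(counts.values())
    if depth <= 0:
        raise ValueError("MAF is undefined at zero depth")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(ranked) < 2:
        return 0.0
    return ranked[1][1] / depth


def strand_bias(
    major_plus: int, major_minus: int, minor_plus: int, minor_minus: int
) -> float:
    """Strand-bias score for one site (0 ideal, larger means more biased).

    Arguments are the major- and minor-allele counts on each strand.  With
    no strand coverage on either side the score is undefined (NaN); with no
    minor allele at all it is 0.
    """
    a, c, b, d = major_plus, major_minus, minor_plus, minor_minus
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b == 0 or c + d == 0:
        return math.nan
    if b + d == 0:
        return 0.0
    n = a + b + c + d
    return abs(b / (a + b) - d / (c + d)) / ((b + d) / n)


@dataclass
class SiteMetrics:
    chrom: str
    pos: int
    depth: int
    major: str
    minor: str | None
    maf: float
    sb: float


def read_allele_counts(path) -> pd.DataFrame:
    """Read a TSV of (chrom, pos, allele, plus_count, minus_count); 1-based pos."""
    df = pd.read_csv(
        path,
        sep="\t",
        names=SITE_COLUMNS,
        header=0,
        dtype={"chrom": str, "pos": int, "allele": str, "plus": int, "minus": int},
    )
    if (df[["plus", "minus"]] < 0).any().any():
        raise ValueError("negative allele counts")
    return df


def site_metrics(df: pd.DataFrame) -> list[SiteMetrics]:
    """Per-site MAF, strand bias and depth from a stranded allele-count table."""
    if "chrom" not in df.columns:
        df = df.assign(chrom="ref")
    out = []
    for (chrom, pos), grp in df.groupby(["chrom", "pos"], sort=True):
        totals = {
            row.allele: int(row.plus + row.minus) for row in grp.itertuples(index=False)
        }
        depth = sum(totals.values())
        if depth == 0:
            continue
        ranked = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
        major = ranked[0][0]
        minor = ranked[1][0] if len(ranked) > 1 else None
        by_allele = {
            row.allele: (int(row.plus), int(row.minus))
            for row in grp.itertuples(index=False)
        }
        a, c = by_allele[major]
        b, d = by_allele.get(minor, (0, 0)) if minor else (0, 0)
        out.append(
            SiteMetrics(
                chrom=str(chrom),
                pos=int(pos),
                depth=depth,
                major=major,
                minor=minor,
                maf=maf(totals),
                sb=strand_bias(a, c, b, d),
            )
        )
    return out


def filter_sites(
    sites: list[SiteMetrics],
    maf_min: float = 0.005,
    sb_max: float = 1.0,
    depth_min: int = 0,
) -> list[SiteMetrics]:
    """Keep sites with MAF >= maf_min, SB < sb_max and depth >= depth_min.

    Sites with undefined strand bias fail.  Each rejection is logged with
    the criterion that failed.
    """
    kept = []
    for s in sites:
        if s.depth < depth_min:
            log.info("site %s:%d rejected: depth %d < %d", s.chrom, s.pos, s.depth, depth_min)
            continue
        if s.maf < maf_min:
            log.info("site %s:%d rejected: MAF %.4g < %.4g", s.chrom, s.pos, s.maf, maf_min)
            continue
        if math.isnan(s.sb):
            log.info("site %s:%d rejected: strand bias undefined", s.chrom, s.pos)
            continue
        if s.sb >= sb_max:
            log.info("site %s:%d rejected: SB %.3g >= %.3g", s.chrom, s.pos, s.sb, sb_max)
            continue
        kept.append(s)
    return kept
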