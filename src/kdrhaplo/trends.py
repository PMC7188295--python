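"""Temporal haplotype-frequency trajectories within a country.

The temporal claim of interest is qualitative — kdr haplotypes sweeping up
in frequency over collection years — so the trend statistic is a rank
correlation (Spearman's rho of year vs frequency across population-year
points), classified as increasing/decreasing/flat against a configurable
threshold.  Populations lacking a haplotype contribute frequency 0 for
that point, so trajectories are comparable across haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr


@dataclass(frozen=True)
class Trajectory:
    country: str
    haplotype_name: str
    points: tuple[tuple[int, str, float], ...]  # (year, population_id, freq)
    trend_rho: float
    direction: str  # increasing / decreasing / flat


def trajectories(table: pd.DataFrame, country: str,
                 segment_id: str | None = None,
                 rho_threshold: float = 0.3) -> list[Trajectory]:
    """One frequency trajectory per haplotype observed in ``country``.

    Requires at least two distinct collection years for the country.
    """
    sub = table[table["country"] == country]
    if segment_id is not None:
        sub = sub[sub["segment_id"] == segment_id]
    if sub.empty:
        raise ValueError(f"no rows for country {country!r}")
    if sub["year"].nunique() < 2:
        raise ValueError(f"need >= 2 distinct years for {country!r}, "
                         f"found {sub['year'].nunique()}")

    out: list[Trajectory] = []
    for seg, seg_rows in sub.groupby("segment_id"):
        pops = seg_rows[["population_id", "year"]].drop_duplicates()
        freq = {(r.population_id, r.haplotype_name): r.frequency
                for r in seg_rows.itertuples()}
        for hap in sorted(seg_rows["haplotype_name"].unique()):
            points = sorted(
                (int(p.year), p.population_id, freq.get((p.population_id, hap), 0.0))
                for p in pops.itertuples())
            years = [p[0] for p in points]
            freqs = [p[2] for p in points]
            if len(set(freqs)) == 1:
                rho = 0.0
            else:
                rho = float(spearmanr(years, freqs).statistic)
                if np.isnan(rho):
                    rho = 0.0
            direction = ("increasing" if rho > rho_threshold
                         else "decreasing" if rho < -rho_threshold else "flat")
            out.append(Trajectory(country, hap, tuple(points), rho, direction))
    return out


def trajectory_table(trajs: list[Trajectory]) -> pd.DataFrame:
    rows = []
    for t in trajs:
        for year, pop, f in t.points:
            rows.append([t.country, t.haplotype_name, year, pop, f,
                         t.trend_rho, t.direction])
    return pd.DataFrame(rows, columns=[
        "country", "haplotype_name", "year", "population_id", "frequency",
        "trend_rho", "direction"])
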