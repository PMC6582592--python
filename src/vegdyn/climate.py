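"""Monthly climate series per climate region.

The driver stores, for each region and calendar year, 12 monthly mean
temperatures (°C) and 12 monthly precipitation sums (mm). Transition
predictors consume a 10-year forward window of monthly values; the
synthetic succession kernel only uses annual mean temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ClimateDriver", "make_climate"]


@dataclass
class _RegionSeries:
    year0: int
    tmean: np.ndarray  # (n_years, 12)
    precip: np.ndarray  # (n_years, 12)


class ClimateDriver:
    """Random-access monthly climate, keyed by (region, year)."""

    def __init__(self, table: pd.DataFrame) -> None:
        required = {"region", "year", "month", "tmean", "precip"}
        if not required <= set(table.columns):
            raise ValueError(f"climate table needs columns {sorted(required)}")
        self._regions: dict[int, _RegionSeries] = {}
        for region, grp in table.groupby("region"):
            grp = grp.sort_values(["year", "month"])
            years = np.sort(grp["year"].unique())
            if not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
                raise ValueError(f"region {region}: years are not contiguous")
            n_years = len(years)
            if len(grp) != n_years * 12:
                raise ValueError(f"region {region}: incomplete monthly coverage")
            tm = grp["tmean"].to_numpy(float).reshape(n_years, 12)
            pr = grp["precip"].to_numpy(float).reshape(n_years, 12)
            if not (np.isfinite(tm).all() and np.isfinite(pr).all()):
                raise ValueError(f"region {region}: non-finite climate values")
            self._regions[int(region)] = _RegionSeries(int(years[0]), tm, pr)

    @property
    def regions(self) -> tuple[int, ...]:
        return tuple(sorted(self._regions))

    def year_range(self, region: int) -> tuple[int, int]:
        """Inclusive (first, last) covered calendar year."""
        rs = self._regions[region]
        return rs.year0, rs.year0 + rs.tmean.shape[0] - 1

    def check_coverage(self, year_start: int, year_end: int) -> None:
        """Raise if any region misses a year in [year_start, year_end]."""
        for region in self._regions:
            lo, hi = self.year_range(region)
            if year_start < lo or year_end > hi:
                raise ValueError(
                    f"region {region} covers [{lo}, {hi}] but "
                    f"[{year_start}, {year_end}] is required"
                )

    def monthly_window(
        self, region: int, year: int, n_years: int = 10
    ) -> tuple[np.ndarray, np.ndarray]:
        """Monthly tmean and precip for years [year, year + n_years), each flat length 12*n_years."""
        rs = self._regions[region]
        i = year - rs.year0
        if i < 0 or i + n_years > rs.tmean.shape[0]:
            raise ValueError(
                f"region {region}: window [{year}, {year + n_years}) not covered"
            )
        return rs.tmean[i : i + n_years].ravel(), rs.precip[i : i + n_years].ravel()

    def annual_mean_temp(self, region: int, year: int) -> float:
        rs = self._regions[region]
        i = year - rs.year0
        if i < 0 or i >= rs.tmean.shape[0]:
            raise ValueError(f"region {region}: year {year} not covered")
        return float(rs.tmean[i].mean())

    def annual_mean_temp_map(self, year: int) -> dict[int, float]:
        return {r: self.annual_mean_temp(r, year) for r in self._regions}

    # -- serialization ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for region in sorted(self._regions):
            rs = self._regions[region]
            for iy in range(rs.tmean.shape[0]):
                for m in range(12):
                    rows.append(
                        (region, rs.year0 + iy, m + 1, rs.tmean[iy, m], rs.precip[iy, m])
                    )
        return pd.DataFrame(rows, columns=["region", "year", "month", "tmean", "precip"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ClimateDriver":
        return cls(pd.read_csv(path, comment="#"))


def make_climate(
    region_means: dict[int, float],
    year0: int,
    n_years: int,
    seasonal_amplitude: float = 8.0,
    temp_noise_sd: float = 0.3,
    precip_mean: float = 80.0,
    precip_noise_sd: float = 15.0,
    annual_trend: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> ClimateDriver:
    """Synthesize a monthly climate: region mean + seasonal sine + noise.

    ``annual_trend`` adds a linear warming (°C per year) to every region.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    months = np.arange(12)
    season = -seasonal_amplitude * np.cos(2.0 * np.pi * (months + 0.5) / 12.0)
    frames = []
    for region in sorted(region_means):
        base = region_means[region]
        for iy in range(n_years):
            tm = (
                base
                + annual_trend * iy
                + season
                + rng.normal(0.0, temp_noise_sd, 12)
            )
            pr = np.clip(rng.normal(precip_mean, precip_noise_sd, 12), 0.0, None)
            frames.append(
                pd.DataFrame(
                    {
                        "region": region,
                        "year": year0 + iy,
                        "month": months + 1,
                        "tmean": tm,
                        "precip": pr,
                    }
                )
            )
    return ClimateDriver(pd.concat(frames, ignore_index=True))
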