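"""Potential and realistic source-sink connectivity matrices.

Potential connectivity ``P_sd`` is the probability that a larva released
in spawning site *s* resides in destination *d* at snapshot time:
``P_sd = Q_sd / Q_s``, with ``Q_sd`` the tagged larval mass found in the
destination (summed over its cells and the full water column) and
``Q_s`` the mass released in *s*. The destinations are the 12 numbered
sectors plus the shallow (< 5 m) compartment "B" and the open ocean
"O"; with the closed mass accounting of the transport solver each
source row sums to exactly 1.

Realistic connectivity ``L_sd = P_sd * W_s`` weights each source row by
its spawner count ``W_s``, giving a theoretic larval number that depends
only on the adult stock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lagoonconnect.domain import SHALLOW_DEPTH_M, SectorPartition
from lagoonconnect.transport import TracerField

__all__ = [
    "ConnectivityMatrix",
    "potential_connectivity",
    "realistic_connectivity",
    "cumulated_connectivity",
    "connectivity_cv",
    "seasonal_connectivity",
    "SHALLOW_LABEL",
    "OCEAN_LABEL",
]

SHALLOW_LABEL = "B"
OCEAN_LABEL = "O"


@dataclass
class ConnectivityMatrix:
    """Source-by-destination connectivity table.

    ``values`` has one row per spawning site and one column per
    destination: the numbered sectors, then shallow ("B") and ocean
    ("O"). ``unit`` is "probability" (P_sd) or "larvae" (L_sd);
    ``meta`` carries scenario / wind regime / PLD / release / swim tags.
    """

    values: pd.DataFrame
    unit: str = "probability"
    meta: dict = field(default_factory=dict)

    @property
    def sites(self) -> list:
        return list(self.values.index)

    @property
    def sector_columns(self) -> list:
        return [c for c in self.values.columns if c not in (SHALLOW_LABEL, OCEAN_LABEL)]

    def row_sums(self) -> pd.Series:
        return self.values.sum(axis=1)

    def intra_lagoon(self) -> pd.DataFrame:
        """The site-by-sector block (drops B and O)."""
        return self.values[self.sector_columns]

    def to_csv(self, path) -> None:
        self.values.to_csv(path)

    @classmethod
    def read_csv(cls, path, unit: str = "probability") -> "ConnectivityMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(int)
        df.columns = [int(c) if c not in (SHALLOW_LABEL, OCEAN_LABEL) else c
                      for c in df.columns]
        return cls(values=df, unit=unit)


def potential_connectivity(snapshot: TracerField, sectors: SectorPartition,
                           meta: dict | None = None) -> ConnectivityMatrix:
    """P_sd = Q_sd / Q_s from a dispersal snapshot.

    Destination tallies integrate each sector's full water column; the
    shallow column counts mass in < 5 m cells and the ocean column the
    reservoir mass. Rows of sources with zero release are flagged NaN.
    """
    grid = snapshot.grid
    masses = snapshot.conc * grid.cell_volumes()[None]   # (n_src, nz, ny, nx)
    col_mass = masses.sum(axis=1)                        # (n_src, ny, nx)
    labels = sectors.sector_labels
    cols = labels + [SHALLOW_LABEL, OCEAN_LABEL]
    shallow = grid.wet & (grid.depth < SHALLOW_DEPTH_M)
    rows = np.zeros((snapshot.n_sources, len(cols)))
    for di, d in enumerate(labels):
        sel = sectors.mask(d) & ~shallow
        rows[:, di] = col_mass[:, sel].sum(axis=1)
    rows[:, -2] = col_mass[:, shallow].sum(axis=1)
    rows[:, -1] = snapshot.ocean_mass
    q_s = snapshot.release_total
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(q_s[:, None] > 0, rows / np.where(q_s[:, None] > 0, q_s[:, None], 1.0), np.nan)
    df = pd.DataFrame(p, index=pd.Index(snapshot.source_labels, name="site"), columns=cols)
    m = dict(meta or {})
    m.setdefault("pld_days", snapshot.elapsed_seconds / 86400.0)
    return ConnectivityMatrix(values=df, unit="probability", meta=m)


def realistic_connectivity(P: ConnectivityMatrix, w_s: pd.Series,
                           meta: dict | None = None) -> ConnectivityMatrix:
    """L_sd = P_sd * W_s (row-wise spawner weighting)."""
    w = w_s.reindex(P.values.index)
    if w.isna().any():
        raise ValueError("W_s missing for some spawning sites")
    if (w < 0).any():
        raise ValueError("W_s must be >= 0")
    vals = P.values.mul(w, axis=0)
    m = dict(P.meta)
    m.update(meta or {})
    return ConnectivityMatrix(values=vals, unit="larvae", meta=m)


def _zscore(v: np.ndarray, ddof: int = 1) -> np.ndarray:
    sd = np.std(v, ddof=ddof)
    if sd == 0:
        return np.full_like(v, np.nan)
    return (v - v.mean()) / sd


def cumulated_connectivity(M: ConnectivityMatrix, axis: str = "source",
                           ddof: int = 1) -> pd.Series:
    """Cumulated source/sink scores, standardized as z-scores.

    ``axis="source"`` sums each spawning site's row over the 12 sector
    destinations (B and O excluded from rankings); ``axis="destination"``
    sums each sector destination's column over sources. The sums are
    z-scored (sample SD by default); an all-equal vector returns NaNs.
    """
    block = M.intra_lagoon()
    if axis == "source":
        sums = block.sum(axis=1)
    elif axis == "destination":
        sums = block.sum(axis=0)
    else:
        raise ValueError("axis must be 'source' or 'destination'")
    if len(sums) < 2:
        raise ValueError("need at least 2 entries to standardize")
    return pd.Series(_zscore(sums.to_numpy(float), ddof), index=sums.index,
                     name=f"z_cumulated_{axis}")


def connectivity_cv(matrices: list[ConnectivityMatrix], ddof: int = 1) -> pd.DataFrame:
    """Per-cell coefficient of variation (%) across one factor's levels.

    CV = 100 x SD / mean over the stacked matrices (sample SD by
    default); cells with zero mean are NaN. Invariant under a uniform
    rescaling of the whole stack.
    """
    if len(matrices) < 2:
        raise ValueError("need at least 2 factor levels")
    ref = matrices[0].values
    stack = np.stack([m.values.to_numpy(float) for m in matrices])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=ddof)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean != 0, 100.0 * sd / np.where(mean != 0, mean, 1.0), np.nan)
    return pd.DataFrame(cv, index=ref.index, columns=ref.columns)


def seasonal_connectivity(L_by_regime: dict, regime_seasons: dict,
                          ddof: int = 1) -> pd.DataFrame:
    """Per-destination cumulated realistic connectivity, by season.

    ``L_by_regime`` maps regime id -> realistic connectivity matrix
    (already the sum of the reared and natural scenarios);
    ``regime_seasons`` maps regime id -> season label. Within each
    season, destination column sums are averaged over the season's
    regimes and then z-scored across destinations. Empty seasons are
    omitted.
    """
    seasons = {}
    for rid, M in L_by_regime.items():
        seasons.setdefault(regime_seasons[rid], []).append(M.intra_lagoon().sum(axis=0))
    out = {}
    for season, sums in seasons.items():
        mean_sum = pd.concat(sums, axis=1).mean(axis=1)
        out[season] = pd.Series(_zscore(mean_sum.to_numpy(float), ddof),
                                index=mean_sum.index)
    return pd.DataFrame(out)
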