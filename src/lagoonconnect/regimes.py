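"""Wind-regime classification of multi-year daily wind series.

A long daily wind record is cut into overlapping 30-day windows, each
transformed to quadratic-law wind-stress components, summarized into 15
consecutive 2-day means, and embedded in a 30-dimensional space. A PCA
on the non-standardized (mean-centred only) data preserves absolute
variability; clustering the scores with PAM (partitioning around
medoids, k-medoids) yields recurrent *wind regimes*, each represented by
the real sequence closest to its cluster barycentre. Occurrence
statistics — overall and monthly probabilities — then place every regime
in the seasonal cycle (austral winter / summer / transition).

The classifier follows the statsmodels model/results convention:
:class:`WindRegimeClassifier` is built from a :class:`~lagoonconnect.wind.WindSeries`
and ``fit()`` returns a :class:`WindRegimeResults` carrying assignments,
medoids, per-regime statistics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from lagoonconnect.wind import WindSeries, uv_to_speed_direction

__all__ = [
    "StressParams",
    "RawWindow",
    "WindSequence",
    "WindRegime",
    "WindRegimeClassifier",
    "WindRegimeResults",
    "extract_sequences",
    "wind_stress_components",
    "summarize_subsequences",
    "pca_scores",
    "cluster_regimes",
    "pam_kmedoids",
    "select_reference",
    "occurrence_statistics",
    "season_assignment",
    "circular_mean_sd",
    "WINTER_MONTHS",
    "SUMMER_MONTHS",
]

#: Austral winter months (June to October).
WINTER_MONTHS = (6, 7, 8, 9, 10)
#: Austral summer months (November to May).
SUMMER_MONTHS = (11, 12, 1, 2, 3, 4, 5)

N_SUBSEQUENCES = 15


class ZeroVarianceError(ValueError):
    """All input sequences identical; PCA is undefined."""


@dataclass(frozen=True)
class StressParams:
    """Quadratic bulk-formula parameters for surface wind stress.

    tau = rho_a * Cd * |W| * (u, v); with a constant drag coefficient the
    scaled components (|W| u, |W| v) differ from the stress only by the
    constant factor rho_a * Cd, which cannot affect a clustering.
    """

    rho_a: float = 1.2   # air density, kg/m^3
    cd: float = 0.0016   # drag coefficient (Deacon & Webb 1962)

    def __post_init__(self):
        if self.rho_a <= 0 or self.cd <= 0:
            raise ValueError("rho_a and Cd must be positive")


def wind_stress_components(u, v, params: StressParams = StressParams()):
    """Wind-stress pair (Tx, Ty) = rho_a * Cd * |W| * (u, v)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    speed = np.hypot(u, v)
    f = params.rho_a * params.cd
    return f * speed * u, f * speed * v


@dataclass
class RawWindow:
    """A full-resolution 30-day window of daily stress components."""

    start_date: pd.Timestamp
    start_index: int
    tx: np.ndarray
    ty: np.ndarray

    def __len__(self) -> int:
        return len(self.tx)


@dataclass
class WindSequence:
    """A 30-day wind sequence summarized as 15 two-day stress means."""

    start_date: pd.Timestamp
    sub_means: np.ndarray        # (15, 2): columns Tx, Ty
    parent_index: int = 0        # start offset into the parent series

    def __post_init__(self):
        self.sub_means = np.asarray(self.sub_means, dtype=float)
        if self.sub_means.shape != (N_SUBSEQUENCES, 2):
            raise ValueError(f"sub_means must be ({N_SUBSEQUENCES}, 2)")

    def flatten(self) -> np.ndarray:
        """30-vector (Tx sub-means then Ty sub-means)."""
        return np.concatenate([self.sub_means[:, 0], self.sub_means[:, 1]])


def extract_sequences(series: WindSeries, window_days: int = 30, overlap_days: int = 20,
                      params: StressParams = StressParams()) -> list[RawWindow]:
    """Cut a daily series into overlapping stress windows.

    Windows start every ``window_days - overlap_days`` days from the
    first date; only windows entirely inside the series are emitted (an
    empty list for a too-short series). A 33-year daily record
    (1979-01-01 to 2011-12-31) yields 1203 windows at the default
    30-day/20-day-overlap setting.
    """
    if overlap_days >= window_days:
        raise ValueError("overlap must be smaller than the window")
    stride = window_days - overlap_days
    tx, ty = wind_stress_components(series.u, series.v, params)
    out = []
    for s in range(0, len(series) - window_days + 1, stride):
        out.append(RawWindow(start_date=series.dates[s], start_index=s,
                             tx=tx[s:s + window_days], ty=ty[s:s + window_days]))
    return out


def summarize_subsequences(window: RawWindow) -> WindSequence:
    """Summarize a 30-day stress window into 15 consecutive 2-day means."""
    n = len(window)
    if n != 2 * N_SUBSEQUENCES:
        raise ValueError(f"window must hold {2 * N_SUBSEQUENCES} days, got {n}")
    sub = np.column_stack([
        window.tx.reshape(N_SUBSEQUENCES, 2).mean(axis=1),
        window.ty.reshape(N_SUBSEQUENCES, 2).mean(axis=1),
    ])
    return WindSequence(start_date=window.start_date, sub_means=sub,
                        parent_index=window.start_index)


def pca_scores(sequences: list[WindSequence], variance_kept: float = 0.95):
    """PCA of the flattened sequences, non-standardized (centred only).

    Returns ``(scores, loadings, explained_fraction)`` where scores has
    one row per sequence and as many columns as the smallest component
    count whose cumulative explained variance reaches ``variance_kept``.
    Variance is deliberately not scaled to 1 per column: absolute stress
    variability carries the signal that separates calm from windy
    sequences.
    """
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    if not 0 < variance_kept <= 1:
        raise ValueError("variance_kept must be in (0, 1]")
    X = np.array([s.flatten() for s in sequences])
    Xc = X - X.mean(axis=0)
    U, sing, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = sing**2
    total = var.sum()
    if total <= 0:
        raise ZeroVarianceError("all sequences are identical")
    frac = np.cumsum(var) / total
    ncomp = int(np.searchsorted(frac, variance_kept - 1e-12) + 1)
    ncomp = min(ncomp, len(sing))
    scores = U[:, :ncomp] * sing[:ncomp]
    return scores, Vt[:ncomp], var[:ncomp] / total


def pam_kmedoids(D: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning around medoids on a precomputed distance matrix.

    Deterministic BUILD (greedy) + SWAP (steepest descent) phases.
    Returns ``(medoid_indices, assignment)``.
    """
    n = D.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    # BUILD: start from the most central point, then greedily add the
    # candidate that most reduces the summed nearest-medoid distance.
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        dnear = D[:, medoids].min(axis=1)
        gains = np.maximum(dnear[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = np.asarray(medoids)

    # SWAP: repeatedly apply the single best (medoid, candidate) swap.
    for _ in range(200):
        dmat = D[:, medoids]
        if k == 1:
            d1 = dmat[:, 0]
            d2 = np.full(n, np.inf)
            nearest = np.zeros(n, dtype=int)
        else:
            order = np.argsort(dmat, axis=1)
            nearest = order[:, 0]
            d1 = dmat[np.arange(n), nearest]
            d2 = dmat[np.arange(n), order[:, 1]]
        best_delta, best_swap = -1e-12, None
        for mi in range(k):
            is_m = nearest == mi
            deltas = np.where(
                is_m[:, None],
                np.minimum(d2[:, None], D) - d1[:, None],
                np.minimum(0.0, D - d1[:, None]),
            ).sum(axis=0)
            deltas[medoids] = np.inf
            h = int(np.argmin(deltas))
            if deltas[h] < best_delta:
                best_delta, best_swap = deltas[h], (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    assignment = np.argmin(D[:, medoids], axis=1)
    return medoids, assignment


def cluster_regimes(scores: np.ndarray, k: int = 12, seed: int = 0,
                    method: str = "pam") -> tuple[np.ndarray, np.ndarray]:
    """Cluster PCA scores into ``k`` regimes.

    ``method="pam"`` (default) runs deterministic k-medoids with
    Euclidean distances and returns per-cluster medoid indices;
    ``method="kmeans"`` runs plain k-means (seeded) and reports, per
    cluster, the member closest to the centroid as its medoid.
    Returns ``(assignment, medoid_indices)``.
    """
    n = scores.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} sequences")
    if method == "pam":
        from scipy.spatial.distance import squareform, pdist

        D = squareform(pdist(scores))
        medoids, assignment = pam_kmedoids(D, k)
        return assignment, medoids
    if method == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        assignment = km.fit_predict(scores)
        medoids = np.empty(k, dtype=int)
        for c in range(k):
            members = np.nonzero(assignment == c)[0]
            d = np.linalg.norm(scores[members] - km.cluster_centers_[c], axis=1)
            medoids[c] = members[np.argmin(d)]
        return assignment, medoids
    raise ValueError(f"unknown clustering method {method!r}")


def select_reference(members: np.ndarray, scores: np.ndarray,
                     start_dates=None) -> int:
    """Cluster member closest to the cluster barycentre in score space.

    Returns the index (into ``scores``) of the reference sequence; exact
    distance ties are broken by the earliest start date when
    ``start_dates`` is given, else by the lowest index.
    """
    members = np.asarray(members)
    if members.size == 0:
        raise ValueError("empty cluster")
    bary = scores[members].mean(axis=0)
    d = np.linalg.norm(scores[members] - bary, axis=1)
    dmin = d.min()
    tied = members[np.isclose(d, dmin, rtol=0.0, atol=1e-12)]
    if start_dates is not None and len(tied) > 1:
        tied = sorted(tied, key=lambda i: (start_dates[i], i))
    return int(tied[0])


def occurrence_statistics(assignment: np.ndarray, total: int | None = None,
                          start_months: np.ndarray | None = None) -> pd.DataFrame:
    """Per-regime occurrence probabilities (%), overall and by month.

    The overall probability is 100 x member count / total sequence
    count. When ``start_months`` (month 1..12 of each sequence start) is
    given, per-month columns ``m1..m12`` hold each regime's occurrence
    mass by month (fractions summing to 1 within a regime).
    """
    assignment = np.asarray(assignment)
    if total is None:
        total = len(assignment)
    if total == 0 or len(assignment) == 0:
        raise ValueError("no assigned sequences")
    regs = np.unique(assignment)
    rows = {}
    for r in regs:
        sel = assignment == r
        n_r = int(sel.sum())
        row = {"n": n_r, "probability_pct": 100.0 * n_r / total}
        if start_months is not None:
            months = np.asarray(start_months)[sel]
            for m in range(1, 13):
                row[f"m{m}"] = float(np.count_nonzero(months == m)) / n_r
        rows[int(r)] = row
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "regime"
    return df


def season_assignment(monthly_mass: np.ndarray,
                      winter_months=WINTER_MONTHS,
                      summer_months=SUMMER_MONTHS,
                      dominance: float = 0.5,
                      enrichment: float = 1.15) -> str:
    """Label a regime winter / summer / transition from its monthly mass.

    ``monthly_mass`` holds the regime's occurrence fractions for months
    Jan..Dec (summing to 1). The regime gets a seasonal label when its
    mass inside the season's months both exceeds ``dominance`` and is
    enriched relative to the season's calendar share by at least the
    ``enrichment`` factor — so a regime spread uniformly over the year
    stays "transition" even though the 7-month summer holds most of its
    mass by construction.
    """
    monthly_mass = np.asarray(monthly_mass, dtype=float)
    if monthly_mass.shape != (12,):
        raise ValueError("monthly_mass must have 12 entries (Jan..Dec)")
    if set(winter_months) & set(summer_months):
        raise ValueError("winter and summer month sets must be disjoint")
    scores = {}
    for label, months in (("winter", winter_months), ("summer", summer_months)):
        mass = float(monthly_mass[[m - 1 for m in months]].sum())
        share = len(months) / 12.0
        scores[label] = (mass, mass / share if share > 0 else 0.0)
    candidates = [(label, mass, enr) for label, (mass, enr) in scores.items()
                  if mass >= dominance and enr >= enrichment]
    if not candidates:
        return "transition"
    return max(candidates, key=lambda t: t[2])[0]


@dataclass
class WindRegime:
    """One wind regime: a cluster of 30-day sequences and its statistics."""

    regime_id: int
    members: np.ndarray
    reference: WindSequence
    reference_index: int
    occurrence_prob: float            # percent
    mean_speed: float
    speed_sd: float
    mean_direction: float             # circular mean, degrees coming-from
    direction_sd: float               # Yamartino circular SD, degrees
    monthly_mass: np.ndarray          # occurrence fractions Jan..Dec
    season: str

    @property
    def n(self) -> int:
        return len(self.members)


def circular_mean_sd(direction_deg: np.ndarray) -> tuple[float, float]:
    """Circular mean and Yamartino standard deviation of directions (deg)."""
    rad = np.deg2rad(np.asarray(direction_deg, dtype=float))
    sa, ca = np.mean(np.sin(rad)), np.mean(np.cos(rad))
    mean = np.degrees(np.arctan2(sa, ca)) % 360.0
    eps = np.sqrt(max(0.0, 1.0 - (sa * sa + ca * ca)))
    sd = np.degrees(np.arcsin(eps) * (1.0 + (2.0 / np.sqrt(3.0) - 1.0) * eps**3))
    return float(mean), float(sd)


def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


class WindRegimeClassifier:
    """Model object: classify a daily wind series into k wind regimes.

    Parameters
    ----------
    series : WindSeries
        Gap-free daily wind record.
    window_days, overlap_days : int
        Sequence windowing (default 30-day windows, 20-day overlap).
    k : int
        Number of regimes (default 12).
    variance_kept : float
        Fraction of PCA variance retained before clustering (1.0
        reproduces full-space clustering).
    method : {"pam", "kmeans"}
    """

    def __init__(self, series: WindSeries, window_days: int = 30,
                 overlap_days: int = 20, k: int = 12,
                 variance_kept: float = 0.95,
                 stress_params: StressParams = StressParams(),
                 method: str = "pam", seed: int = 0):
        self.series = series
        self.window_days = window_days
        self.overlap_days = overlap_days
        self.k = k
        self.variance_kept = variance_kept
        self.stress_params = stress_params
        self.method = method
        self.seed = seed

    def fit(self) -> "WindRegimeResults":
        windows = extract_sequences(self.series, self.window_days,
                                    self.overlap_days, self.stress_params)
        if len(windows) < self.k:
            raise ValueError(f"only {len(windows)} sequences for k={self.k}")
        sequences = [summarize_subsequences(w) for w in windows]
        scores, loadings, explained = pca_scores(sequences, self.variance_kept)
        assignment, medoids = cluster_regimes(scores, self.k, self.seed, self.method)
        return WindRegimeResults(model=self, windows=windows, sequences=sequences,
                                 scores=scores, loadings=loadings,
                                 explained=explained, assignment=assignment,
                                 medoid_indices=medoids)


@dataclass
class WindRegimeResults:
    """Fitted wind-regime classification."""

    model: WindRegimeClassifier
    windows: list
    sequences: list
    scores: np.ndarray
    loadings: np.ndarray
    explained: np.ndarray
    assignment: np.ndarray
    medoid_indices: np.ndarray
    regimes: list = field(init=False)

    def __post_init__(self):
        self.regimes = self._build_regimes()

    def _build_regimes(self) -> list[WindRegime]:
        series = self.model.series
        total = len(self.sequences)
        start_dates = [s.start_date for s in self.sequences]
        start_months = np.array([d.month for d in start_dates])
        occ = occurrence_statistics(self.assignment, total, start_months)
        regimes = []
        for c in range(self.model.k):
            members = np.nonzero(self.assignment == c)[0]
            ref_idx = select_reference(members, self.scores, start_dates)
            # daily wind statistics pooled over the member windows
            day_idx = np.concatenate([
                np.arange(self.sequences[i].parent_index,
                          self.sequences[i].parent_index + self.model.window_days)
                for i in members
            ])
            speed = series.speed[day_idx]
            _, direction = uv_to_speed_direction(series.u[day_idx], series.v[day_idx])
            mean_dir, sd_dir = circular_mean_sd(direction)
            monthly = occ.loc[c, [f"m{m}" for m in range(1, 13)]].to_numpy(float)
            regimes.append(WindRegime(
                regime_id=c + 1,
                members=members,
                reference=self.sequences[ref_idx],
                reference_index=ref_idx,
                occurrence_prob=float(occ.loc[c, "probability_pct"]),
                mean_speed=float(speed.mean()),
                speed_sd=float(speed.std(ddof=1)) if len(speed) > 1 else 0.0,
                mean_direction=mean_dir,
                direction_sd=sd_dir,
                monthly_mass=monthly,
                season=season_assignment(monthly),
            ))
        return regimes

    @property
    def occurrence_probs(self) -> np.ndarray:
        """Occurrence probabilities (%) in regime order; sums to 100."""
        return np.array([r.occurrence_prob for r in self.regimes])

    def season_of(self, regime_id: int) -> str:
        return self.regimes[regime_id - 1].season

    def summary(self) -> pd.DataFrame:
        """Regime climatology table: id, reference start date, counts,
        occurrence probability (%, rounded half-up to one decimal), wind
        speed and circular direction statistics, and season label."""
        rows = []
        for r in self.regimes:
            rows.append({
                "regime": r.regime_id,
                "start_date": r.reference.start_date.strftime("%d/%m/%y"),
                "n_sequences": r.n,
                "probability_pct": _round_half_up(r.occurrence_prob, 1),
                "speed_mean": round(r.mean_speed, 1),
                "speed_sd": round(r.speed_sd, 1),
                "direction_mean": round(r.mean_direction, 1),
                "direction_sd": round(r.direction_sd, 1),
                "season": r.season,
            })
        return pd.DataFrame(rows).set_index("regime")

    def to_csv(self, path) -> None:
        self.summary().to_csv(path)
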