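"""Interbrain HLR correlation, shuffled-pair nulls, residualisation, Granger graphs.

Given per-second high-to-low power ratio (HLR) series from several cohorts
recorded in group and single conditions, this module computes

* lag-0 Pearson interbrain correlation for the four pair-combination
  classes (``group``: same cohort, both group condition; ``group_shuffled``:
  different cohorts, both group; ``group_single_shuffled``: same cohort, one
  group one single; ``single_shuffled``: same cohort, both single) — the
  last three are negative controls because those animals were not socially
  co-present;
* a permutation null: correlations of random distinct series pairs drawn
  from the whole pool (default 10,000 draws) summarised by mean, SD and a
  mean +- 1.96 SD band;
* locomotion-residualised correlation: over 15-min segments, the HLR
  cross-correlation is regressed on the locomotive-state cross-correlation
  and the residual isolates interbrain coupling beyond shared locomotion;
* pairwise Granger causality on the 1 Hz HLR series at lag 1 (ssr-based
  F-test), classified per unordered pair into unidirectional /
  bidirectional / none at alpha = 0.05.

The :class:`InterbrainModel` / :class:`InterbrainResults` pair bundles the
whole study in a fit-then-inspect interface; the underlying functions are
usable on their own.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import AnnotationTable
from .spectral import HlrSeries

__all__ = [
    "PairCorrelation",
    "NullDistribution",
    "ResidualCorrelation",
    "GrangerGraph",
    "COMBINATION_CLASSES",
    "STATE_ENCODING",
    "pair_correlation",
    "classify_pair",
    "build_combinations",
    "permutation_null",
    "residual_correlation",
    "granger_pvalue",
    "granger_matrix",
    "classify_directionality",
    "InterbrainModel",
    "InterbrainResults",
]

COMBINATION_CLASSES = (
    "group",
    "group_shuffled",
    "group_single_shuffled",
    "single_shuffled",
)

#: Ordinal locomotive-state encoding used for state cross-correlation;
#: preserves the mobility ordering that drives the HLR.
STATE_ENCODING = {"inactive": 0.0, "active_still": 1.0, "active": 2.0}


@dataclass
class PairCorrelation:
    subject_a: tuple[str, str, str]  # (cohort, condition, subject)
    subject_b: tuple[str, str, str]
    combination: str
    r: float
    n: int


@dataclass
class NullDistribution:
    """Permutation distribution of pairwise HLR correlations."""

    draws: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=np.float64)
        if self.draws.size < 1000:
            import warnings

            warnings.warn(
                f"only {self.draws.size} permutation draws; distribution tails "
                "will be poorly resolved",
                stacklevel=2,
            )

    @property
    def mean(self) -> float:
        return float(np.mean(self.draws))

    @property
    def sd(self) -> float:
        return float(np.std(self.draws, ddof=1))

    @property
    def band(self) -> tuple[float, float]:
        """Mean +- 1.96 SD acceptance band."""
        return (self.mean - 1.96 * self.sd, self.mean + 1.96 * self.sd)

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.draws, q))

    def percentile_of(self, value: float) -> float:
        """Empirical percentile of a query value within the null (0-100)."""
        return float(100.0 * np.mean(self.draws < value))


@dataclass
class ResidualCorrelation:
    """Per-15-min-segment pair correlations with locomotion removed."""

    segments: pd.DataFrame  # cohort, condition, pair, segment, r_loc, r_hlr, predicted, residual
    slope: float
    intercept: float
    condition_fits: dict[str, tuple[float, float]]
    pair_means: pd.DataFrame  # cohort, condition, pair, mean_residual, n_segments

    def condition_mean(self, condition: str) -> float:
        sub = self.pair_means[self.pair_means["condition"] == condition]
        return float(sub["mean_residual"].mean())


@dataclass
class GrangerGraph:
    """Directed-influence summary of one cohort at a fixed lag."""

    p_values: pd.DataFrame  # index=source, columns=target
    alpha: float
    lag: int
    pair_classes: pd.DataFrame = field(init=False)
    degrees: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        subs = list(self.p_values.index)
        rows = []
        for a, b in itertools.combinations(subs, 2):
            p_ab = self.p_values.loc[a, b]
            p_ba = self.p_values.loc[b, a]
            if np.isnan(p_ab) or np.isnan(p_ba):
                raise ValueError(f"missing p-value for pair ({a}, {b})")
            sig_ab, sig_ba = p_ab < self.alpha, p_ba < self.alpha
            if sig_ab and sig_ba:
                cls = "bidirectional"
            elif sig_ab or sig_ba:
                cls = "unidirectional"
            else:
                cls = "none"
            rows.append(
                {
                    "a": a,
                    "b": b,
                    "p_ab": p_ab,
                    "p_ba": p_ba,
                    "class": cls,
                    "direction": ("a->b" if sig_ab else "b->a") if cls == "unidirectional" else "",
                }
            )
        self.pair_classes = pd.DataFrame(rows)
        out_deg = {s: 0 for s in subs}
        in_deg = {s: 0 for s in subs}
        for _, r in self.pair_classes.iterrows():
            if r["p_ab"] < self.alpha:
                out_deg[r["a"]] += 1
                in_deg[r["b"]] += 1
            if r["p_ba"] < self.alpha:
                out_deg[r["b"]] += 1
                in_deg[r["a"]] += 1
        self.degrees = pd.DataFrame(
            {"subject_id": subs, "out_degree": [out_deg[s] for s in subs],
             "in_degree": [in_deg[s] for s in subs]}
        )

    @property
    def edges(self) -> list[tuple[str, str]]:
        """Significant directed edges (source, target)."""
        subs = list(self.p_values.index)
        return [
            (a, b)
            for a in subs
            for b in subs
            if a != b and self.p_values.loc[a, b] < self.alpha
        ]

    def class_counts(self) -> dict[str, int]:
        counts = self.pair_classes["class"].value_counts().to_dict()
        return {k: int(counts.get(k, 0)) for k in ("unidirectional", "bidirectional", "none")}


# ---------------------------------------------------------------------------
# pairwise correlation
# ---------------------------------------------------------------------------

def _overlap(a: HlrSeries, b: HlrSeries) -> tuple[np.ndarray, np.ndarray]:
    n = min(len(a), len(b))
    mask = a.valid[:n] & b.valid[:n]
    return a.values[:n][mask], b.values[:n][mask]


def classify_pair(a: HlrSeries, b: HlrSeries) -> str:
    """Combination class of a pair from its cohort/condition provenance."""
    same_cohort = a.cohort_id == b.cohort_id
    conds = {a.condition, b.condition}
    if conds == {"group"}:
        return "group" if same_cohort else "group_shuffled"
    if conds == {"group", "single"}:
        if same_cohort:
            return "group_single_shuffled"
        return "cross_cohort_mixed"
    return "single_shuffled" if same_cohort else "cross_cohort_single"


def pair_correlation(a: HlrSeries, b: HlrSeries) -> PairCorrelation:
    """Lag-0 Pearson correlation of two HLR series over jointly valid seconds."""
    xa, xb = _overlap(a, b)
    if xa.size < 2:
        raise ValueError("need at least 2 overlapping valid seconds")
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        r = np.nan  # undefined for a constant series
    else:
        r = float(np.corrcoef(xa, xb)[0, 1])
    return PairCorrelation(
        subject_a=a.key, subject_b=b.key, combination=classify_pair(a, b),
        r=r, n=int(xa.size),
    )


def lagged_correlation(
    a: HlrSeries, b: HlrSeries, max_lag_s: int = 30
) -> pd.DataFrame:
    """Pearson r of the two series at integer lags in [-max_lag_s, max_lag_s].

    Positive lag means ``a`` leads ``b``.  Exploratory utility; all default
    analyses use lag 0.
    """
    rows = []
    n = min(len(a), len(b))
    for lag in range(-max_lag_s, max_lag_s + 1):
        if lag >= 0:
            xa = a.values[: n - lag]
            xb = b.values[lag:n]
            mask = a.valid[: n - lag] & b.valid[lag:n]
        else:
            xa = a.values[-lag:n]
            xb = b.values[: n + lag]
            mask = a.valid[-lag:n] & b.valid[: n + lag]
        xa, xb = xa[mask], xb[mask]
        r = np.nan
        if xa.size >= 2 and np.ptp(xa) > 0 and np.ptp(xb) > 0:
            r = float(np.corrcoef(xa, xb)[0, 1])
        rows.append({"lag_s": lag, "r": r, "n": int(xa.size)})
    return pd.DataFrame(rows)


def build_combinations(pool: list[HlrSeries], combination: str) -> list[tuple[HlrSeries, HlrSeries]]:
    """All unordered series pairs belonging to one combination class."""
    if combination not in COMBINATION_CLASSES:
        raise ValueError(f"unknown combination class {combination!r}")
    pairs = [
        (a, b)
        for a, b in itertools.combinations(pool, 2)
        if a.key != b.key and classify_pair(a, b) == combination
    ]
    if not pairs:
        raise ValueError(f"no pairs satisfy combination class {combination!r}")
    return pairs


def permutation_null(
    pool: list[HlrSeries], n_draws: int = 10_000, seed: int = 0
) -> NullDistribution:
    """Null distribution of r from random distinct-series pairs.

    Pairs are sampled uniformly with replacement across draws (a series is
    never paired with itself within a draw).  Deterministic given ``seed``.
    """
    if len(pool) < 4:
        raise ValueError("permutation pool must contain at least 4 series")
    rng = np.random.default_rng(seed)
    m = len(pool)
    # standardise once over each series' valid seconds for fast correlation
    draws = np.empty(n_draws)
    for k in range(n_draws):
        i = int(rng.integers(m))
        j = int(rng.integers(m - 1))
        if j >= i:
            j += 1
        xa, xb = _overlap(pool[i], pool[j])
        if xa.size < 2 or np.ptp(xa) == 0 or np.ptp(xb) == 0:
            draws[k] = np.nan
            continue
        draws[k] = np.corrcoef(xa, xb)[0, 1]
    return NullDistribution(draws=draws[~np.isnan(draws)], seed=seed)


# ---------------------------------------------------------------------------
# locomotion residualisation
# ---------------------------------------------------------------------------

def _encode_states(states: np.ndarray, encoding: str = "ordinal") -> np.ndarray:
    """Numeric locomotive-state series: ordinal scalar or one-hot matrix."""
    if encoding == "ordinal":
        return np.vectorize(STATE_ENCODING.__getitem__, otypes=[float])(states)
    if encoding == "onehot":
        cats = list(STATE_ENCODING)
        return np.column_stack([(states == c).astype(float) for c in cats])
    raise ValueError(f"unknown encoding {encoding!r}")


def _state_correlation(la: np.ndarray, lb: np.ndarray) -> float:
    """Pearson r for ordinal series; mean indicator correlation for one-hot."""
    if la.ndim == 1:
        if np.ptp(la) == 0 or np.ptp(lb) == 0:
            return np.nan
        return float(np.corrcoef(la, lb)[0, 1])
    rs = []
    for k in range(la.shape[1]):
        if np.ptp(la[:, k]) > 0 and np.ptp(lb[:, k]) > 0:
            rs.append(np.corrcoef(la[:, k], lb[:, k])[0, 1])
    return float(np.mean(rs)) if rs else np.nan


def residual_correlation(
    sessions: list[tuple[list[HlrSeries], AnnotationTable]],
    segment_min: int = 15,
    scope: str = "pooled",
    encoding: str = "ordinal",
) -> ResidualCorrelation:
    """Remove the locomotion-explained part of interbrain HLR correlation.

    For every simultaneously recorded pair and every ``segment_min``-minute
    segment, compute the Pearson correlation of the two HLR series
    (``r_hlr``) and of the two ordinally encoded locomotive-state series
    (``r_loc``).  A least-squares line of ``r_hlr`` on ``r_loc`` is then
    fitted and the residual (observed minus predicted) is the
    locomotion-free interbrain correlation.

    ``scope='pooled'`` (default) fits one reference line over all segments
    of all conditions, so group-vs-single residual contrasts are measured
    against a common locomotion-to-HLR relationship; per-condition fits are
    also computed and reported.  Segments with a constant state series are
    skipped.  ``encoding`` selects the numeric state representation:
    ``"ordinal"`` (default, mobility-ordered 0/1/2) or ``"onehot"`` (mean of
    the per-state indicator correlations).
    """
    seg_len = segment_min * 60
    rows = []
    for series_list, table in sessions:
        enc = {
            s.subject_id: _encode_states(table.states(s.subject_id), encoding)
            for s in series_list
        }
        for a, b in itertools.combinations(series_list, 2):
            n = min(len(a), len(b), len(enc[a.subject_id]), len(enc[b.subject_id]))
            n_seg = n // seg_len
            for k in range(n_seg):
                sl = slice(k * seg_len, (k + 1) * seg_len)
                mask = a.valid[sl] & b.valid[sl]
                if mask.sum() < 2:
                    continue
                la, lb = enc[a.subject_id][sl][mask], enc[b.subject_id][sl][mask]
                ha, hb = a.values[sl][mask], b.values[sl][mask]
                r_loc = _state_correlation(la, lb)
                if not np.isfinite(r_loc) or np.ptp(ha) == 0 or np.ptp(hb) == 0:
                    continue
                rows.append(
                    {
                        "cohort_id": a.cohort_id,
                        "condition": a.condition,
                        "pair": f"{a.subject_id}|{b.subject_id}",
                        "segment": k,
                        "r_loc": r_loc,
                        "r_hlr": float(np.corrcoef(ha, hb)[0, 1]),
                    }
                )
    seg = pd.DataFrame(rows)
    if seg.empty:
        raise ValueError("no usable 15-min segments")
    condition_fits = {}
    for cond, sub in seg.groupby("condition"):
        if len(sub) >= 2 and np.ptp(sub["r_loc"].to_numpy()) > 0:
            sl, ic = np.polyfit(sub["r_loc"], sub["r_hlr"], 1)
            condition_fits[cond] = (float(sl), float(ic))
    if scope == "pooled":
        slope, intercept = np.polyfit(seg["r_loc"], seg["r_hlr"], 1)
        seg["predicted"] = intercept + slope * seg["r_loc"]
    elif scope == "per_condition":
        slope = intercept = np.nan
        pred = np.empty(len(seg))
        for cond, sub in seg.groupby("condition"):
            sl, ic = condition_fits[cond]
            pred[sub.index] = ic + sl * sub["r_loc"]
        seg["predicted"] = pred
    else:
        raise ValueError(f"unknown scope {scope!r}")
    seg["residual"] = seg["r_hlr"] - seg["predicted"]
    pair_means = (
        seg.groupby(["cohort_id", "condition", "pair"])["residual"]
        .agg(mean_residual="mean", n_segments="count")
        .reset_index()
    )
    return ResidualCorrelation(
        segments=seg,
        slope=float(slope),
        intercept=float(intercept),
        condition_fits=condition_fits,
        pair_means=pair_means,
    )


# ---------------------------------------------------------------------------
# Granger causality
# ---------------------------------------------------------------------------

def _contiguous_valid(a: HlrSeries, b: HlrSeries, bridge_s: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Longest jointly valid contiguous stretch, bridging gaps <= bridge_s.

    Granger regression needs contiguity; short invalid gaps are linearly
    interpolated, longer ones split the series and the longest run wins.
    """
    n = min(len(a), len(b))
    if n == 0:
        raise ValueError("series do not overlap")
    mask = a.valid[:n] & b.valid[:n]
    xa = a.values[:n].astype(float).copy()
    xb = b.values[:n].astype(float).copy()
    ok = mask.copy()
    # bridge short gaps by linear interpolation
    i = 0
    while i < n:
        if not ok[i]:
            j = i
            while j < n and not ok[j]:
                j += 1
            if 0 < i and j < n and (j - i) <= bridge_s:
                for x in (xa, xb):
                    x[i:j] = np.interp(np.arange(i, j), [i - 1, j], [x[i - 1], x[j]])
                ok[i:j] = True
            i = j
        else:
            i += 1
    # longest contiguous ok run
    best = (0, 0)
    i = 0
    while i < n:
        if ok[i]:
            j = i
            while j < n and ok[j]:
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    s = slice(*best)
    if best[1] - best[0] < 2:
        raise ValueError("no contiguous jointly valid stretch")
    return xa[s], xb[s]


def granger_pvalue(x: np.ndarray, y: np.ndarray, lag: int = 1) -> float:
    """p-value of the ssr-based F-test that ``x`` Granger-causes ``y``.

    Compares the restricted autoregression y_t ~ const + y_{t-1..t-lag}
    against the full model adding x_{t-1..t-lag}; F has (lag, n - 2*lag - 1)
    degrees of freedom.  Matches the standard ssr F-test of common Granger
    implementations.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = min(x.size, y.size)
    if n < 10 * lag + 10:
        raise ValueError(f"need at least {10 * lag + 10} observations, got {n}")
    if np.ptp(x[:n]) == 0 or np.ptp(y[:n]) == 0:
        return np.nan
    yt = y[lag:n]
    m = yt.size
    y_lags = np.column_stack([y[lag - k - 1 : n - k - 1] for k in range(lag)])
    x_lags = np.column_stack([x[lag - k - 1 : n - k - 1] for k in range(lag)])
    ones = np.ones((m, 1))
    restricted = np.hstack([ones, y_lags])
    full = np.hstack([ones, y_lags, x_lags])
    rss_r = _rss(restricted, yt)
    rss_f = _rss(full, yt)
    df_denom = m - full.shape[1]
    if rss_f <= 0 or df_denom <= 0:
        return np.nan
    f_stat = ((rss_r - rss_f) / lag) / (rss_f / df_denom)
    return float(stats.f.sf(f_stat, lag, df_denom))


def _rss(design: np.ndarray, target: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ coef
    return float(resid @ resid)


def granger_matrix(
    series: list[HlrSeries], lag: int = 1, bridge_s: int = 2
) -> pd.DataFrame:
    """p-values of the Granger test for every ordered pair of one cohort.

    Entry (i, j) is the p-value that subject i's HLR Granger-causes subject
    j's, at the given lag, on the raw (unlogged) HLR series.  Diagonal is
    NaN.
    """
    if len(series) < 2:
        raise ValueError("need at least two series")
    subs = [s.subject_id for s in series]
    p = pd.DataFrame(np.nan, index=subs, columns=subs)
    for a, b in itertools.permutations(series, 2):
        xa, xb = _contiguous_valid(a, b, bridge_s=bridge_s)
        p.loc[a.subject_id, b.subject_id] = granger_pvalue(xa, xb, lag=lag)
    return p


def classify_directionality(
    p_values: pd.DataFrame,
    alpha: float = 0.05,
    lag: int = 1,
    correction: str | None = None,
) -> GrangerGraph:
    """Unidirectional / bidirectional / none per unordered pair at ``alpha``.

    By default raw p-values are thresholded (no correction across the 12
    ordered pairs of a 4-animal cohort); ``correction`` may be
    ``"bonferroni"`` or ``"bh"`` (Benjamini-Hochberg) to adjust the
    off-diagonal p-values first.
    """
    if correction is not None:
        mat = p_values.to_numpy(dtype=float).copy()
        mask = ~np.isnan(mat)
        p = mat[mask]
        m = p.size
        if correction == "bonferroni":
            adj = np.minimum(p * m, 1.0)
        elif correction == "bh":
            order = np.argsort(p)
            ranked = p[order] * m / (np.arange(m) + 1)
            adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
            adj = np.empty(m)
            adj[order] = np.minimum(adj_sorted, 1.0)
        else:
            raise ValueError(f"unknown correction {correction!r}")
        mat[mask] = adj
        p_values = pd.DataFrame(mat, index=p_values.index, columns=p_values.columns)
    return GrangerGraph(p_values=p_values, alpha=alpha, lag=lag)


# ---------------------------------------------------------------------------
# model / results interface
# ---------------------------------------------------------------------------

class InterbrainModel:
    """Interbrain coupling study over a pool of HLR series.

    Parameters
    ----------
    sessions : list of (series_list, annotations)
        One entry per recorded session: the HLR series of its subjects and
        the per-second annotation table (may be ``None``, which disables
        residualisation for that session).  Series carry their own cohort
        and condition provenance.
    """

    def __init__(self, sessions: list[tuple[list[HlrSeries], AnnotationTable | None]]):
        if not sessions:
            raise ValueError("need at least one session")
        self.sessions = sessions
        self.pool: list[HlrSeries] = [s for series, _ in sessions for s in series]

    def fit(
        self,
        n_draws: int = 10_000,
        seed: int = 0,
        alpha: float = 0.05,
        lag: int = 1,
        segment_min: int = 15,
        residual_scope: str = "pooled",
    ) -> "InterbrainResults":
        """Run correlations, permutation null, residualisation and Granger graphs."""
        pair_rows = []
        class_pairs: dict[str, list[PairCorrelation]] = {}
        for cls in COMBINATION_CLASSES:
            try:
                pairs = build_combinations(self.pool, cls)
            except ValueError:
                continue
            pcs = [pair_correlation(a, b) for a, b in pairs]
            class_pairs[cls] = pcs
            pair_rows.extend(
                {
                    "combination": cls,
                    "cohort_a": pc.subject_a[0],
                    "subject_a": pc.subject_a[2],
                    "cohort_b": pc.subject_b[0],
                    "subject_b": pc.subject_b[2],
                    "r": pc.r,
                    "n": pc.n,
                }
                for pc in pcs
            )
        null = permutation_null(self.pool, n_draws=n_draws, seed=seed)
        with_ann = [
            (series, table) for series, table in self.sessions if table is not None
        ]
        residuals = None
        if with_ann:
            try:
                residuals = residual_correlation(
                    with_ann, segment_min=segment_min, scope=residual_scope
                )
            except ValueError:
                residuals = None
        graphs: dict[str, GrangerGraph] = {}
        for series, _ in self.sessions:
            if not series or series[0].condition != "group" or len(series) < 2:
                continue
            pmat = granger_matrix(series, lag=lag)
            graphs[series[0].cohort_id] = classify_directionality(pmat, alpha=alpha, lag=lag)
        return InterbrainResults(
            model=self,
            pair_table=pd.DataFrame(pair_rows),
            class_pairs=class_pairs,
            null=null,
            residuals=residuals,
            granger=graphs,
            alpha=alpha,
            lag=lag,
        )


@dataclass
class InterbrainResults:
    """Fitted interbrain study: correlations, null, residuals, Granger graphs."""

    model: InterbrainModel
    pair_table: pd.DataFrame
    class_pairs: dict[str, list[PairCorrelation]]
    null: NullDistribution
    residuals: ResidualCorrelation | None
    granger: dict[str, GrangerGraph]
    alpha: float
    lag: int

    def class_mean(self, combination: str) -> float:
        rs = [pc.r for pc in self.class_pairs.get(combination, []) if np.isfinite(pc.r)]
        return float(np.mean(rs)) if rs else np.nan

    def class_means(self) -> dict[str, float]:
        return {cls: self.class_mean(cls) for cls in self.class_pairs}

    def total_class_counts(self) -> dict[str, int]:
        totals = {"unidirectional": 0, "bidirectional": 0, "none": 0}
        for g in self.granger.values():
            for k, v in g.class_counts().items():
                totals[k] += v
        return totals

    def summary(self) -> str:
        lines = ["Interbrain HLR coupling study", "=" * 34]
        lines.append(f"pool: {len(self.model.pool)} series, "
                     f"{len(self.model.sessions)} sessions")
        lines.append("")
        lines.append("pair-combination class means (lag-0 Pearson r):")
        for cls, mean in self.class_means().items():
            n_pairs = len(self.class_pairs[cls])
            pct = self.null.percentile_of(mean)
            lines.append(f"  {cls:>22s}: r = {mean:+.4f} ({n_pairs} pairs, "
                         f"null percentile {pct:5.1f})")
        lo, hi = self.null.band
        lines.append(f"permutation null: {self.null.draws.size} draws, "
                     f"mean {self.null.mean:+.4f}, band [{lo:+.4f}, {hi:+.4f}]")
        if self.residuals is not None:
            lines.append("")
            lines.append("locomotion-residualised correlation (mean residual):")
            for cond in sorted(self.residuals.pair_means["condition"].unique()):
                lines.append(f"  {cond:>22s}: {self.residuals.condition_mean(cond):+.4f}")
        if self.granger:
            lines.append("")
            lines.append(f"Granger directionality (lag={self.lag}, alpha={self.alpha}):")
            for cohort, g in self.granger.items():
                c = g.class_counts()
                lines.append(
                    f"  cohort {cohort}: {c['unidirectional']} unidirectional, "
                    f"{c['bidirectional']} bidirectional, {c['none']} none"
                )
        return "\n".join(lines)
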