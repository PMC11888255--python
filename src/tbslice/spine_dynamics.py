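"""Dendritic-spine trajectory analyses.

Spine sizes are tracked per dendritic segment over an 11-point imaging
schedule (5 daily baseline scans, 5 hourly post-stimulation scans, one scan
24 h post-stimulation).  Spine IDs within a segment are ordered so that
adjacent IDs are physically closer on the dendrite.  This module implements:

* baseline (day-4) normalization of sizes and densities,
* size-binned analysis of normalized size changes,
* enlarged/shrunk classification and 2x2 transition tables,
* per-segment Pearson (or Spearman) correlation matrices of trajectories
  over the 24 h window,
* diagonal-averaged fixed-size (default 15 x 15) "unit matrices" that make
  correlation structure comparable across segments with different spine
  counts, and their elementwise variance maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .protocol import DEFAULT_SCHEDULE, ImagingSchedule

logger = logging.getLogger(__name__)


@dataclass
class SpineTrajectorySet:
    """Long-format spine sizes plus per-segment densities and conditions.

    ``sizes``: DataFrame (segment_id, spine_id, time_label, size_au); spine_id
    is the within-segment ordinal position (adjacency = physical proximity).
    ``density``: DataFrame (segment_id, time_label, spines_per_um), optional.
    ``condition``: mapping segment_id -> {"control", "stimulated"}.
    """

    sizes: pd.DataFrame
    density: pd.DataFrame | None = None
    condition: dict = field(default_factory=dict)
    schedule: ImagingSchedule = field(default_factory=lambda: DEFAULT_SCHEDULE)

    def __post_init__(self) -> None:
        req = {"segment_id", "spine_id", "time_label", "size_au"}
        if not req.issubset(self.sizes.columns):
            raise ValueError(f"sizes must have columns {sorted(req)}")
        unknown = set(self.sizes["time_label"]) - set(self.schedule.labels)
        if unknown:
            raise ValueError(f"time labels not in schedule: {sorted(unknown)}")
        base = self.sizes[self.sizes["time_label"] == self.schedule.baseline_label]
        if (base["size_au"] <= 0).any():
            raise ValueError("baseline sizes must be > 0")

    def segment_ids(self) -> list:
        return sorted(self.sizes["segment_id"].unique())

    def pivot_segment(self, segment_id, labels=None) -> pd.DataFrame:
        """Spine x time-label size matrix for one segment (rows = spine order)."""
        sub = self.sizes[self.sizes["segment_id"] == segment_id]
        mat = sub.pivot_table(index="spine_id", columns="time_label",
                              values="size_au", aggfunc="first")
        cols = [l for l in (labels or self.schedule.labels) if l in mat.columns]
        return mat.reindex(columns=cols).sort_index()


@dataclass
class CorrelationMatrix:
    """Pairwise trajectory correlations of one segment's spines.

    Undefined entries (constant trajectories) are NaN and carried as such.
    """

    values: np.ndarray
    spine_ids: list
    segment_id: object = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("correlation matrix must be square")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class UnitMatrix:
    """k x k diagonal-averaged correlation matrix with per-cell support."""

    values: np.ndarray
    support: np.ndarray
    segment_id: object = None

    @property
    def k(self) -> int:
        return self.values.shape[0]


def normalize_to_baseline(ts: SpineTrajectorySet) -> SpineTrajectorySet:
    """Divide every spine's size series by its own day-4 (baseline) size.

    The baseline entry becomes exactly 1.  Spines without a positive baseline
    value are excluded with a warning.  Density series are normalized the
    same way by each segment's baseline density.
    """
    base_label = ts.schedule.baseline_label
    sizes = ts.sizes.copy()
    base = (sizes[sizes["time_label"] == base_label]
            .set_index(["segment_id", "spine_id"])["size_au"])
    key = pd.MultiIndex.from_frame(sizes[["segment_id", "spine_id"]])
    denom = base.reindex(key).to_numpy()
    bad = ~(denom > 0)
    if bad.any():
        dropped = sizes.loc[bad, ["segment_id", "spine_id"]].drop_duplicates()
        logger.warning("excluding %d spines with missing/zero baseline", len(dropped))
        sizes = sizes.loc[~bad].copy()
        denom = denom[~bad]
    sizes["size_au"] = sizes["size_au"].to_numpy() / denom
    density = None
    if ts.density is not None:
        density = ts.density.copy()
        dbase = (density[density["time_label"] == base_label]
                 .set_index("segment_id")["spines_per_um"])
        ddenom = dbase.reindex(density["segment_id"]).to_numpy()
        density["spines_per_um"] = density["spines_per_um"].to_numpy() / ddenom
    return SpineTrajectorySet(sizes, density, dict(ts.condition), ts.schedule)


def delta_size_binned(ts: SpineTrajectorySet, t_label: str,
                      bin_edges=None) -> pd.DataFrame:
    """Per-bin mean +/- s.e.m. of baseline-normalized size change at ``t_label``.

    Delta_i = (size_i(t) - size_i(day4)) / size_i(day4); spines are binned by
    their raw day-4 size with right-closed edges (each bin labeled by its
    upper limit).  ``bin_edges=None`` uses day-4 size quantiles at
    {0.2, 0.4, 0.6, 0.8, 1.0}.  Returns a DataFrame with columns
    (bin_upper, n, mean_delta, sem_delta); empty bins appear with n = 0.
    """
    base_label = ts.schedule.baseline_label
    if t_label not in ts.schedule.labels or t_label == base_label:
        raise ValueError(f"t_label must be a non-baseline schedule label, got {t_label!r}")
    wide = ts.sizes.pivot_table(index=["segment_id", "spine_id"],
                                columns="time_label", values="size_au",
                                aggfunc="first")
    if t_label not in wide.columns:
        raise ValueError(f"no observations at {t_label!r}")
    sub = wide[[base_label, t_label]].dropna()
    s0 = sub[base_label].to_numpy()
    delta = (sub[t_label].to_numpy() - s0) / s0
    if bin_edges is None:
        qs = np.quantile(s0, [0.2, 0.4, 0.6, 0.8, 1.0])
        edges = np.concatenate([[-np.inf], qs])
    else:
        edges = np.asarray(bin_edges, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (s0 > lo) & (s0 <= hi)
        n = int(in_bin.sum())
        rows.append({
            "bin_upper": hi,
            "n": n,
            "mean_delta": float(np.mean(delta[in_bin])) if n else np.nan,
            "sem_delta": float(sstats.sem(delta[in_bin])) if n > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def classify_spines(ts: SpineTrajectorySet, t_ref_label: str,
                    t_label: str) -> pd.Series:
    """Label each spine 'enlarged' or 'shrunk' at ``t_label`` vs ``t_ref_label``.

    Enlarged iff size(t) > size(t_ref); ties count as shrunk.  Spines missing
    either observation are excluded (logged).  Returns a Series indexed by
    (segment_id, spine_id).
    """
    wide = ts.sizes.pivot_table(index=["segment_id", "spine_id"],
                                columns="time_label", values="size_au",
                                aggfunc="first")
    for lab in (t_ref_label, t_label):
        if lab not in wide.columns:
            raise ValueError(f"no observations at {lab!r}")
    sub = wide[[t_ref_label, t_label]]
    n_missing = int(sub.isna().any(axis=1).sum())
    if n_missing:
        logger.info("excluding %d spines missing a value at %s or %s",
                    n_missing, t_ref_label, t_label)
    sub = sub.dropna()
    enlarged = sub[t_label] > sub[t_ref_label]
    return enlarged.map({True: "enlarged", False: "shrunk"}).rename("label")


def transition_table(labels_early: pd.Series, labels_late: pd.Series
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """2x2 counts and row proportions of enlarged/shrunk transitions.

    Rows = early label, columns = late label, over spines observed at both
    time points.  The count total equals the number of co-observed spines.
    """
    df = pd.concat([labels_early.rename("early"), labels_late.rename("late")],
                   axis=1, join="inner")
    cats = ["enlarged", "shrunk"]
    counts = (pd.crosstab(df["early"], df["late"])
              .reindex(index=cats, columns=cats, fill_value=0))
    counts.index.name, counts.columns.name = "early", "late"
    row_tot = counts.sum(axis=1).replace(0, np.nan)
    props = counts.div(row_tot, axis=0)
    return counts, props


def correlation_matrix(ts: SpineTrajectorySet, segment_id, labels=None,
                       method: str = "pearson") -> CorrelationMatrix:
    """Pairwise correlation of spine-size time series for one segment.

    Defaults to the 24 h window (day-4 baseline through +24 h, 7 points) and
    raw sizes (correlation is scale-invariant, so baseline normalization
    would not change defined entries).  Constant series give NaN rows/columns
    (flagged-undefined), except the unit diagonal.
    """
    if labels is None:
        labels = ts.schedule.window_24h_labels
    mat = ts.pivot_segment(segment_id, labels=labels)
    if mat.shape[1] < 2:
        raise ValueError("need >= 2 time points per spine for correlation")
    x = mat.to_numpy()
    if method == "pearson":
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(x)
    elif method == "spearman":
        from scipy.stats import rankdata
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(rankdata(x, axis=1))
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r, spine_ids=list(mat.index), segment_id=segment_id)


def unit_matrix(corr: CorrelationMatrix | np.ndarray, k: int = 15,
                segment_id=None) -> UnitMatrix:
    """Average all k x k principal submatrices sliding along the diagonal.

    An n x n correlation matrix yields n - k + 1 contiguous windows (stride
    1); the unit matrix is their elementwise mean, making segments with
    different spine counts comparable.  NaN (undefined) entries are excluded
    from each cell's mean; ``support`` records how many windows contributed
    to each cell.  Requires n >= k.
    """
    if isinstance(corr, CorrelationMatrix):
        c = corr.values
        segment_id = segment_id if segment_id is not None else corr.segment_id
    else:
        c = np.asarray(corr, dtype=float)
    n = c.shape[0]
    if n < k:
        raise ValueError(f"matrix side {n} < unit-matrix size {k}")
    windows = np.stack([c[i:i + k, i:i + k] for i in range(n - k + 1)])
    support = np.sum(~np.isnan(windows), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(windows, axis=0)
    return UnitMatrix(mean, support, segment_id=segment_id)


def unit_matrices_for_set(ts: SpineTrajectorySet, k: int = 15, labels=None,
                          method: str = "pearson") -> list[UnitMatrix]:
    """Unit matrix per segment; segments with fewer than k spines are skipped."""
    out = []
    for seg in ts.segment_ids():
        corr = correlation_matrix(ts, seg, labels=labels, method=method)
        if corr.n < k:
            logger.warning("segment %r has %d spines < %d; skipped", seg, corr.n, k)
            continue
        out.append(unit_matrix(corr, k=k))
    return out


def mean_unit_matrix(mats: list[UnitMatrix]) -> np.ndarray:
    """Elementwise NaN-aware mean across unit matrices."""
    if not mats:
        raise ValueError("empty unit-matrix list")
    with np.errstate(invalid="ignore"):
        return np.nanmean(np.stack([m.values for m in mats]), axis=0)


def unit_matrix_variance(mats: list[UnitMatrix]) -> np.ndarray:
    """Elementwise sample variance (ddof=1) across a list of unit matrices."""
    if len(mats) < 2:
        raise ValueError("variance needs at least 2 unit matrices")
    stack = np.stack([m.values for m in mats])
    with np.errstate(invalid="ignore"):
        return np.nanvar(stack, axis=0, ddof=1)


def near_far_summary(u: np.ndarray, near_band: int = 2,
                     far_corner: int = 3) -> tuple[float, float]:
    """Mean of near-diagonal (|i-j| in 1..near_band) and far-corner
    (|i-j| >= k - far_corner) off-diagonal cells of a unit matrix."""
    u = np.asarray(u, dtype=float)
    k = u.shape[0]
    d = np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
    near = float(np.nanmean(u[(d >= 1) & (d <= near_band)]))
    far = float(np.nanmean(u[d >= k - far_corner]))
    return near, far
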