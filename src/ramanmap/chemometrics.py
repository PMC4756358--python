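"""PCA and nonparametric dose-response statistics on Raman spectra.

The dose-response screen works on principal-component scores: components are
ranked by the Kruskal-Wallis chi-square statistic of their scores grouped by
dose (a rank-based analog of the one-way ANOVA F statistic), the top-ranked
components are compared between dose groups with two-sided Wilcoxon rank-sum
tests, and their loadings are interpreted against a biomolecular band table
under a two-bands-per-side co-occurrence rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

from .bands import BandTable
from .dataset import SpectralDataset

__all__ = [
    "PCAModel",
    "fit_pca",
    "cumulative_evr",
    "KWResult",
    "kruskal_wallis_rank",
    "rank_components",
    "WilcoxonResult",
    "wilcoxon_rank_sum",
    "GroupScoreStats",
    "group_stats",
    "subject_segregation",
    "percentile",
    "LoadingAnnotation",
    "annotate_loading",
    "CorrelationResult",
    "correlate_loadings",
]


class ChemometricsError(ValueError):
    pass


class DegenerateVarianceError(ChemometricsError):
    pass


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    """Mean spectrum, orthonormal loadings, scores and variance fractions.

    ``scores`` is indexed by spectrum_id with columns PC1..PCk followed by
    the metadata columns (when metadata was available).  ``orientation``
    records the sign applied to each component to make the largest-magnitude
    loading element positive (deterministic output).
    """

    axis: np.ndarray
    mean_spectrum: np.ndarray
    loadings: np.ndarray  # (k, n_points)
    scores: pd.DataFrame
    evr: np.ndarray
    orientation: np.ndarray
    total_variance: float

    @property
    def k(self) -> int:
        return self.loadings.shape[0]

    def pc_names(self) -> list:
        return [f"PC{i + 1}" for i in range(self.k)]

    def score_vector(self, pc: int) -> np.ndarray:
        """Scores of component ``pc`` (1-based)."""
        return self.scores[f"PC{pc}"].to_numpy(dtype=float)

    def flip(self, pc: int):
        """Negate one component (loading, scores, orientation record)."""
        i = pc - 1
        self.loadings[i] = -self.loadings[i]
        self.scores[f"PC{pc}"] = -self.scores[f"PC{pc}"]
        self.orientation[i] = -self.orientation[i]


def fit_pca(data, k: int, metadata: pd.DataFrame | None = None,
            axis: np.ndarray | None = None, ids=None, center: bool = True) -> PCAModel:
    """Mean-centered PCA by SVD with deterministic sign orientation.

    ``data`` may be a :class:`SpectralDataset` (surviving, normalized spectra
    are used) or a plain (n, p) matrix with optional ``metadata``/``axis``/
    ``ids``.  Explained-variance fractions are taken against total centered
    variance; all-identical inputs raise ``DegenerateVarianceError``.
    """
    if isinstance(data, SpectralDataset):
        if data.state != "normalized":
            raise ChemometricsError(
                f"PCA expects a fully processed (normalized) dataset, got state {data.state!r}"
            )
        X = data.surviving_matrix()
        ids = data.surviving_ids
        metadata = data.metadata.loc[ids]
        axis = data.axis
    else:
        X = np.asarray(data, dtype=float)
        if ids is None:
            ids = [f"s{i:05d}" for i in range(X.shape[0])]
        if axis is None:
            axis = np.arange(X.shape[1], dtype=float)
    n, p = X.shape
    if k > min(n - 1, p):
        raise ChemometricsError(f"k={k} exceeds min(n-1, p) = {min(n - 1, p)}")
    mean = X.mean(axis=0) if center else np.zeros(p)
    Xc = X - mean
    total_var = float(np.sum(Xc**2))
    # relative floor: mean-subtraction rounding alone leaves O(eps^2) residue
    floor = X.size * (100 * np.finfo(float).eps) ** 2 * max(1.0, float(np.max(np.abs(X))) ** 2)
    if total_var <= floor:
        raise DegenerateVarianceError("degenerate variance: all spectra identical")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    loadings = Vt[:k].copy()
    scores = (U[:, :k] * s[:k]).copy()
    orientation = np.ones(k)
    for i in range(k):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
            orientation[i] = -1.0
    evr = (s[:k] ** 2) / total_var
    score_df = pd.DataFrame(
        scores, index=pd.Index(ids, name="spectrum_id"),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    if metadata is not None:
        score_df = score_df.join(metadata)
    return PCAModel(
        axis=np.asarray(axis, dtype=float),
        mean_spectrum=mean,
        loadings=loadings,
        scores=score_df,
        evr=evr,
        orientation=orientation,
        total_variance=total_var,
    )


def cumulative_evr(model: PCAModel, m: int) -> float:
    """Fraction of total variance captured by the first ``m`` components."""
    if m < 0 or m > model.k:
        raise ChemometricsError(f"m={m} outside [0, {model.k}]")
    return float(np.sum(model.evr[:m]))


def orient_to(model: PCAModel, reference: np.ndarray, pc: int) -> PCAModel:
    """Flip component ``pc`` so its loading correlates positively with ``reference``."""
    r = np.corrcoef(model.loadings[pc - 1], np.asarray(reference, dtype=float))[0, 1]
    if r < 0:
        model.flip(pc)
    return model


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

@dataclass
class KWResult:
    chi_square: float
    dof: int
    p_value: float
    group_sizes: dict
    all_tied: bool = False


def _split_groups(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ChemometricsError("values and labels must have equal length")
    if values.size == 0:
        raise ChemometricsError("empty sample")
    uniq = pd.unique(labels)
    groups = [values[labels == g] for g in uniq]
    return uniq, groups


def kruskal_wallis_rank(values, labels) -> KWResult:
    """Kruskal-Wallis H (chi-square statistic) of values grouped by labels.

    Midranks with tie correction; the all-tied degenerate case is defined as
    H = 0, p = 1.
    """
    uniq, groups = _split_groups(values, labels)
    if len(uniq) < 2:
        raise ChemometricsError("need at least 2 groups")
    if any(len(g) < 1 for g in groups):
        raise ChemometricsError("empty group")
    sizes = {str(g): int(len(v)) for g, v in zip(uniq, groups)}
    dof = len(uniq) - 1
    allv = np.concatenate(groups)
    if np.all(allv == allv[0]):
        return KWResult(0.0, dof, 1.0, sizes, all_tied=True)
    H, p = stats.kruskal(*groups)
    return KWResult(float(H), dof, float(p), sizes)


def rank_components(model: PCAModel, labels=None, alpha: float = 0.05) -> pd.DataFrame:
    """KW-screen every component; returns a table sorted by chi-square.

    ``labels`` defaults to the dose column of the score table.  The returned
    frame carries a ``ratio_3rd_to_2nd`` attribute (the drop-off screen used
    to decide how many components carry dose structure).
    """
    if labels is None:
        if "dose_Gy" not in model.scores.columns:
            raise ChemometricsError("no dose_Gy metadata; pass labels explicitly")
        labels = model.scores["dose_Gy"].to_numpy()
    rows = []
    for i in range(model.k):
        res = kruskal_wallis_rank(model.score_vector(i + 1), labels)
        rows.append(
            {
                "pc": i + 1,
                "chi_square": res.chi_square,
                "dof": res.dof,
                "p_value": res.p_value,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        "chi_square", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    ratio = np.nan
    if len(table) >= 3 and table["chi_square"].iloc[1] > 0:
        ratio = float(table["chi_square"].iloc[2] / table["chi_square"].iloc[1])
    table.attrs["ratio_3rd_to_2nd"] = ratio
    return table


@dataclass
class WilcoxonResult:
    statistic: float  # rank sum of the first sample
    p_two_sided: float
    method: str


def wilcoxon_rank_sum(a, b) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration p-value when both samples have n <= 10 and there are
    no ties; otherwise the normal approximation with midranks, tie-corrected
    variance and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ChemometricsError("empty sample")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size <= 10 and b.size <= 10 and not has_ties:
        method = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    W = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U -> rank sum
    return WilcoxonResult(statistic=W, p_two_sided=float(res.pvalue), method=method)


# ---------------------------------------------------------------------------
# group statistics (Tukey box-plot surface)
# ---------------------------------------------------------------------------

@dataclass
class GroupScoreStats:
    """Box-plot statistics of one group's scores.

    notch_halfwidth is the half-width of the 95% confidence interval on the
    median, 1.57 * IQR / sqrt(n) (normal approximation); whiskers sit at the
    most extreme data points within 1.5 * IQR of the quartiles.
    """

    label: str
    n: int
    median: float
    q25: float
    q75: float
    notch_halfwidth: float
    whisker_low: float
    whisker_high: float
    prop_negative: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def percentile(values, q: float) -> float:
    """Linear-interpolation quantile (same rule as group_stats)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ChemometricsError("empty sample")
    return float(np.percentile(values, q))


def _one_group_stats(label, x) -> GroupScoreStats:
    x = np.asarray(x, dtype=float)
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    iqr = q75 - q25
    in_low = x[x >= q25 - 1.5 * iqr]
    in_high = x[x <= q75 + 1.5 * iqr]
    return GroupScoreStats(
        label=str(label),
        n=int(x.size),
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        notch_halfwidth=float(1.57 * iqr / np.sqrt(x.size)),
        whisker_low=float(in_low.min()),
        whisker_high=float(in_high.max()),
        prop_negative=float(np.mean(x < 0)),
    )


def group_stats(values, labels) -> list:
    """Per-group box-plot statistics, ordered by label sort order."""
    uniq, groups = _split_groups(values, labels)
    if any(len(g) == 0 for g in groups):
        raise ChemometricsError("empty group")
    order = np.argsort([str(u) for u in uniq], kind="mergesort")
    try:  # numeric labels sort numerically
        order = np.argsort(np.asarray(uniq, dtype=float), kind="mergesort")
    except (TypeError, ValueError):
        pass
    return [_one_group_stats(uniq[i], groups[i]) for i in order]


def subject_segregation(values, subject_labels, alpha: float = 0.05) -> list:
    """Partition subjects into score-distribution equivalence classes.

    Subjects within one dose group are pairwise compared with the two-sided
    Wilcoxon rank-sum test; subjects whose scores are *not* significantly
    different (p >= alpha) are linked, and the connected components of that
    link graph are the reported classes (sorted lists of subject ids).
    """
    uniq, groups = _split_groups(values, subject_labels)
    subjects = [str(u) for u in uniq]
    n = len(subjects)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            p = wilcoxon_rank_sum(groups[i], groups[j]).p_two_sided
            if p >= alpha:
                parent[find(i)] = find(j)
    classes = {}
    for i, s in enumerate(subjects):
        classes.setdefault(find(i), []).append(s)
    return sorted(sorted(c) for c in classes.values())


# ---------------------------------------------------------------------------
# loading interpretation
# ---------------------------------------------------------------------------

@dataclass
class AnnotationEntry:
    side: str  # positive | negative | mixed | unassigned
    matched_positive: list
    matched_negative: list

    @property
    def n_matched(self) -> int:
        return len(self.matched_positive) + len(self.matched_negative)


@dataclass
class LoadingAnnotation:
    entries: dict = field(default_factory=dict)
    extrema_positive: list = field(default_factory=list)
    extrema_negative: list = field(default_factory=list)

    def side(self, entity: str) -> str:
        return self.entries[entity].side if entity in self.entries else "unassigned"


def _significant_extrema(axis, loading, quantile):
    thr = np.quantile(np.abs(loading), quantile)
    pos_idx, _ = signal.find_peaks(loading)
    neg_idx, _ = signal.find_peaks(-loading)
    pos = [float(axis[i]) for i in pos_idx if loading[i] > thr and loading[i] > 0]
    neg = [float(axis[i]) for i in neg_idx if -loading[i] > thr and loading[i] < 0]
    return pos, neg


def annotate_loading(loading, axis, table: BandTable,
                     extremum_quantile: float = 0.75) -> LoadingAnnotation:
    """Assign biomolecular entities to the sides of a loading vector.

    Local extrema whose |value| exceeds the ``extremum_quantile`` of
    |loading| are matched to band-table centers within the table tolerance.
    An entity is assigned to a side only when >= 2 of its bands match
    extrema of that sign; entities meeting that criterion on both sides are
    reported as ``mixed`` with the evidence listed.
    """
    loading = np.asarray(loading, dtype=float)
    axis = np.asarray(axis, dtype=float)
    ann = LoadingAnnotation()
    if table.entries.empty:
        return ann
    pos, neg = _significant_extrema(axis, loading, extremum_quantile)
    ann.extrema_positive = pos
    ann.extrema_negative = neg
    for entity in table.entities:
        bands = table.bands(entity)
        mpos = [float(b) for b in bands if any(abs(b - e) <= table.tolerance for e in pos)]
        mneg = [float(b) for b in bands if any(abs(b - e) <= table.tolerance for e in neg)]
        if len(mpos) >= 2 and len(mneg) >= 2:
            side = "mixed"
        elif len(mpos) >= 2:
            side = "positive"
        elif len(mneg) >= 2:
            side = "negative"
        else:
            side = "unassigned"
        ann.entries[entity] = AnnotationEntry(side, mpos, mneg)
    return ann


# ---------------------------------------------------------------------------
# cross-study correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    r: float
    overlap: tuple
    n_points: int


def correlate_loadings(a, b, axis_a=None, axis_b=None) -> CorrelationResult:
    """Pearson correlation of two loading vectors on a common grid.

    With distinct axes, ``b`` is linearly interpolated onto the points of
    ``a`` inside the overlap of the two ranges.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if axis_a is None and axis_b is None:
        if a.size != b.size:
            raise ChemometricsError("vectors differ in length and no axes given")
        av, bv = a, b
        overlap = (0.0, float(a.size - 1))
    else:
        axis_a = np.asarray(axis_a, dtype=float)
        axis_b = np.asarray(axis_b, dtype=float) if axis_b is not None else axis_a
        lo = max(axis_a[0], axis_b[0])
        hi = min(axis_a[-1], axis_b[-1])
        if hi <= lo:
            raise ChemometricsError("loading axes do not overlap")
        sel = (axis_a >= lo) & (axis_a <= hi)
        av = a[sel]
        bv = np.interp(axis_a[sel], axis_b, b)
        overlap = (float(lo), float(hi))
    r = stats.pearsonr(av, bv).statistic
    return CorrelationResult(r=float(r), overlap=overlap, n_points=int(av.size))
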