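"""Cohort-level statistics for phasic strain feature tables.

Group comparisons use the two-sided Student's t-test with pooled
variance (Welch available behind a flag), chi-square or Fisher's exact
test for categorical variables (Fisher whenever an expected count is
below 5), and a two-way mixed ANOVA for region-by-group interactions.
Discrimination is assessed with ROC analysis (rank-statistic AUC,
stratified percentile-bootstrap confidence intervals, Youden operating
point) and DeLong's test for paired AUC differences.  Unsupervised
phenotyping uses z-scored k-means with silhouette-based model selection
and a sole-member-cluster outlier rule, projected with PCA.

No multiple-testing correction is applied anywhere (alpha = 0.05 per
test); see the methods note.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult", "CategoricalTestResult", "MixedAnovaResult",
    "RocResult", "DeLongResult", "ClusterResult", "StatReport",
    "t_test", "t_test_summary", "categorical_test", "mixed_anova",
    "roc_analysis", "delong_test", "cluster_phenotypes", "chads_vasc",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

@dataclass
class TTestResult:
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    t: float
    df: float
    p: float
    test: str = "student_t_pooled"
    flag: str = ""

    def to_dict(self) -> dict:
        return asdict(self)


def t_test_summary(mean_a: float, sd_a: float, n_a: int,
                   mean_b: float, sd_b: float, n_b: int,
                   welch: bool = False) -> TTestResult:
    """Two-sided t-test from sufficient statistics (means, SDs, ns).

    Default is the pooled-variance Student's t with
    ``df = n_a + n_b - 2``; ``welch=True`` switches to the
    Welch-Satterthwaite form.  Enables reproduction of printed
    group-comparison p-values from published summary tables.
    """
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be >= 0")
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = sd_a**2, sd_b**2
    if va == 0 and vb == 0:
        if mean_a == mean_b:
            return TTestResult(mean_a, mean_b, n_a, n_b, 0.0,
                               n_a + n_b - 2, 1.0,
                               flag="zero variance, equal means")
        return TTestResult(mean_a, mean_b, n_a, n_b, np.inf,
                           n_a + n_b - 2, np.nan,
                           flag="zero variance with unequal means")
    if welch:
        se2 = va / n_a + vb / n_b
        df = se2**2 / ((va / n_a)**2 / (n_a - 1) + (vb / n_b)**2 / (n_b - 1))
        t = (mean_a - mean_b) / np.sqrt(se2)
        name = "welch_t"
    else:
        df = n_a + n_b - 2
        sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / df
        t = (mean_a - mean_b) / np.sqrt(sp2 * (1 / n_a + 1 / n_b))
        name = "student_t_pooled"
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(mean_a, mean_b, n_a, n_b, float(t), float(df),
                       float(p), test=name)


def t_test(group_a, group_b, welch: bool = False) -> TTestResult:
    """Two-sided t-test on raw samples (pooled Student by default)."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2 finite values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    return t_test_summary(a.mean(), a.std(ddof=1), len(a),
                          b.mean(), b.std(ddof=1), len(b), welch=welch)


# ---------------------------------------------------------------------------
# categorical tests
# ---------------------------------------------------------------------------

@dataclass
class CategoricalTestResult:
    p: float
    statistic: float
    test: str
    expected_min: float

    def to_dict(self) -> dict:
        return asdict(self)


def categorical_test(table, method: str = "auto") -> CategoricalTestResult:
    """Chi-square or Fisher's exact test on a 2x2 contingency table.

    ``method="auto"`` chooses Fisher's exact test whenever any expected
    cell count is below 5 (the usual "as appropriate" rule), otherwise
    the chi-square test with continuity correction.  Fisher's two-sided
    p is the sum of hypergeometric probabilities no larger than that of
    the observed table.
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("need a 2x2 table of non-negative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("empty margin in contingency table")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    use_fisher = method == "fisher" or (method == "auto" and expected.min() < 5)
    if method not in ("auto", "fisher", "chi2"):
        raise ValueError("method must be auto, fisher, or chi2")
    if use_fisher:
        odds, p = sps.fisher_exact(t, alternative="two-sided")
        return CategoricalTestResult(float(p), float(odds), "fisher_exact",
                                     float(expected.min()))
    chi2, p, _, _ = sps.chi2_contingency(t, correction=True)
    return CategoricalTestResult(float(p), float(chi2), "chi2_yates",
                                 float(expected.min()))


# ---------------------------------------------------------------------------
# mixed ANOVA
# ---------------------------------------------------------------------------

@dataclass
class MixedAnovaResult:
    f_group: float
    p_group: float
    f_within: float
    p_within: float
    p_within_gg: float
    f_interaction: float
    p_interaction: float
    p_interaction_gg: float
    gg_epsilon: float
    sphericity: bool
    table: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("table", None)
        return d


def mixed_anova(data: pd.DataFrame, dv: str, subject: str,
                between: str, within: str) -> MixedAnovaResult:
    """Two-way mixed ANOVA (between group x within region).

    Long-format input: one row per subject per within level; every
    subject must have all within levels and each group needs at least
    two subjects.  Sphericity is assessed (Mauchly) and
    Greenhouse-Geisser corrected p-values are reported alongside the
    uncorrected ones; pingouin reports the GG correction for the within
    factor, and the same epsilon is applied to the interaction.
    """
    counts = data.groupby(subject)[within].nunique()
    n_within = data[within].nunique()
    if (counts != n_within).any():
        bad = counts.index[counts != n_within].tolist()
        raise ValueError(f"subjects missing within-factor levels: {bad}")
    group_sizes = data.groupby(between)[subject].nunique()
    if (group_sizes < 2).any():
        raise ValueError("each group needs at least 2 subjects")

    import pingouin as pg  # deferred: heavy import

    aov = pg.mixed_anova(data=data, dv=dv, within=within, subject=subject,
                         between=between, correction=True)
    aov = aov.set_index("Source")
    # column naming differs across pingouin releases (p-unc vs p_unc)
    cols = {c.replace("-", "_"): c for c in aov.columns}
    p_unc, p_gg = cols["p_unc"], cols.get("p_GG_corr")
    grp = aov.loc[between]
    wit = aov.loc[within]
    inter = aov.loc["Interaction"]
    eps = float(wit.get("eps", np.nan))
    p_inter_gg = float(sps.f.sf(inter["F"], eps * inter["DF1"],
                                eps * inter["DF2"]))
    return MixedAnovaResult(
        f_group=float(grp["F"]), p_group=float(grp[p_unc]),
        f_within=float(wit["F"]), p_within=float(wit[p_unc]),
        p_within_gg=float(wit[p_gg]) if p_gg else np.nan,
        f_interaction=float(inter["F"]), p_interaction=float(inter[p_unc]),
        p_interaction_gg=p_inter_gg,
        gg_epsilon=eps,
        sphericity=bool(wit.get("sphericity", True)),
        table=aov.reset_index(),
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the midrank (Mann-Whitney) statistic; ties count 1/2."""
    ranks = sps.rankdata(scores)
    m = int(labels.sum())
    n = len(labels) - m
    return float((ranks[labels == 1].sum() - m * (m + 1) / 2) / (m * n))


def _auc_rows(score_rows: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise AUC for a (n_rows, n_subjects) score matrix."""
    ranks = sps.rankdata(score_rows, axis=1)
    m = int(labels.sum())
    n = len(labels) - m
    return (ranks[:, labels == 1].sum(axis=1) - m * (m + 1) / 2) / (m * n)


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    orientation: int          # +1: higher score predicts the event; -1: flipped
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    f1: float
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        return asdict(self)


def roc_analysis(scores, labels, n_boot: int = 2000,
                 seed: int | None = 0) -> RocResult:
    """ROC analysis of one feature against a binary outcome.

    The AUC is the rank (Mann-Whitney) statistic; the orientation is
    flipped automatically so the reported AUC is >= 0.5 (reduced strain
    magnitudes predicting events give AUC < 0.5 on the raw scale), and
    the flip is recorded.  The 95% CI is a percentile bootstrap over
    subject resampling stratified by outcome.  The operating point
    maximizes Youden's J; sensitivity, specificity, PPV and F1 are
    reported at that threshold.
    """
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(int)
    keep = ~np.isnan(s)
    if (~keep).any():
        logger.warning("excluding %d subjects with missing scores",
                       int((~keep).sum()))
        s, y = s[keep], y[keep]
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain both classes")
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    orientation = 1
    if _auc_rank(s, y) < 0.5:
        orientation, s = -1, -s
    auc = _auc_rank(s, y)

    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    bp = rng.integers(0, len(pos_idx), size=(n_boot, len(pos_idx)))
    bn = rng.integers(0, len(neg_idx), size=(n_boot, len(neg_idx)))
    boot_scores = np.concatenate([s[pos_idx][bp], s[neg_idx][bn]], axis=1)
    boot_labels = np.r_[np.ones(len(pos_idx), int), np.zeros(len(neg_idx), int)]
    boot_auc = _auc_rows(boot_scores, boot_labels)
    ci_low, ci_high = np.percentile(boot_auc, [2.5, 97.5])

    from sklearn.metrics import roc_curve

    fpr, tpr, thr = roc_curve(y, s)
    j = int(np.argmax(tpr - fpr))
    threshold = float(thr[j])
    pred = s >= threshold
    tp = int((pred & (y == 1)).sum())
    fp = int((pred & (y == 0)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    return RocResult(auc=auc, ci_low=float(ci_low), ci_high=float(ci_high),
                     n_boot=n_boot, orientation=orientation,
                     threshold=threshold, sensitivity=sens, specificity=spec,
                     ppv=ppv, f1=f1, n_pos=int(y.sum()),
                     n_neg=int((1 - y).sum()))


# ---------------------------------------------------------------------------
# DeLong's test
# ---------------------------------------------------------------------------

@dataclass
class DeLongResult:
    auc_1: float
    auc_2: float
    delta: float
    variance: float
    z: float
    p: float

    def to_dict(self) -> dict:
        return asdict(self)


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values V10 (per positive) and V01 (per negative)."""
    x = scores[labels == 1][:, None]
    yv = scores[labels == 0][None, :]
    psi = (x > yv).astype(float) + 0.5 * (x == yv)
    return psi.mean(axis=1), psi.mean(axis=0), psi.mean()


def delong_test(scores_1, scores_2, labels,
                orient: str = "auto") -> DeLongResult:
    """DeLong's test for the difference of two paired (correlated) AUCs.

    Both score vectors must be measured on the same subjects.  The
    covariance of the paired AUC estimates is obtained from the
    placement values; the p-value is a two-sided z-test on the AUC
    difference.  ``orient="auto"`` flips each score independently so
    both AUCs are >= 0.5 (matching how predictors are reported);
    ``orient="none"`` uses the raw scales.  Identical or strictly
    monotone-transformed score pairs give delta = 0 and p = 1 exactly.
    """
    s1 = np.asarray(scores_1, float)
    s2 = np.asarray(scores_2, float)
    y = np.asarray(labels).astype(int)
    if not (len(s1) == len(s2) == len(y)):
        raise ValueError("scores and labels must be paired (equal length)")
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain both classes")
    if orient == "auto":
        if _auc_rank(s1, y) < 0.5:
            s1 = -s1
        if _auc_rank(s2, y) < 0.5:
            s2 = -s2
    v10_1, v01_1, auc1 = _placements(s1, y)
    v10_2, v01_2, auc2 = _placements(s2, y)
    m, n = len(v10_1), len(v01_1)
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    var = ((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
           + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n)
    delta = auc1 - auc2
    if var <= 1e-16:
        z, p = 0.0, 1.0
        if abs(delta) > 1e-12:
            raise ValueError("zero DeLong variance with nonzero AUC difference")
    else:
        z = delta / np.sqrt(var)
        p = 2.0 * sps.norm.sf(abs(z))
    return DeLongResult(float(auc1), float(auc2), float(delta), float(var),
                        float(z), float(p))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    assignments: pd.Series = field(repr=False)
    chosen_k: int = 2
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    removed_outliers: list = field(default_factory=list)
    dropped_columns: list = field(default_factory=list)
    pca_coords: pd.DataFrame = field(repr=False, default=None)
    explained_variance_ratio: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "chosen_k": self.chosen_k,
            "silhouette_by_k": {str(k): v for k, v in self.silhouette_by_k.items()},
            "removed_outliers": list(self.removed_outliers),
            "dropped_columns": list(self.dropped_columns),
            "cluster_sizes": self.assignments.value_counts().sort_index().to_dict(),
            "explained_variance_ratio": [float(v) for v in
                                         self.explained_variance_ratio[:5]],
        }


def cluster_phenotypes(features: pd.DataFrame,
                       k_range: range | tuple = range(2, 7),
                       seed: int | None = 0,
                       n_init: int = 10,
                       max_removals: int = 5) -> ClusterResult:
    """K-means phenotype clustering on z-scored strain features.

    The number of clusters is chosen by the maximum mean silhouette over
    ``k_range``.  If the selected solution contains a cluster with
    exactly one member, that subject is removed as an outlier and the
    remaining data are re-standardized and re-clustered (iterated,
    removals logged).  The first two PCA components of the standardized
    features (with per-component explained variance) are returned for
    visualization.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score
    from sklearn.preprocessing import StandardScaler

    x = features.dropna(axis=0)
    if len(x) < len(features):
        logger.warning("excluding %d subjects with missing features",
                       len(features) - len(x))
    zero_var = x.columns[x.std(ddof=0) == 0].tolist()
    if zero_var:
        logger.warning("dropping zero-variance feature columns: %s", zero_var)
        x = x.drop(columns=zero_var)
    if x.shape[1] == 0 or len(x) < 3:
        raise ValueError("degenerate feature matrix (no variance or too few rows)")
    ks = [k for k in k_range]
    if max(ks) >= len(x):
        raise ValueError("k_range exceeds the number of subjects")

    removed: list = []
    rng_seed = seed
    for _ in range(max_removals + 1):
        z = StandardScaler().fit_transform(x.values)
        sil = {}
        labels_by_k = {}
        for k in ks:
            km = KMeans(n_clusters=k, n_init=n_init, random_state=rng_seed)
            lab = km.fit_predict(z)
            labels_by_k[k] = lab
            sil[k] = float(silhouette_score(z, lab))
        best_k = max(sil, key=lambda k: sil[k])
        lab = labels_by_k[best_k]
        sizes = np.bincount(lab)
        lone = np.flatnonzero(sizes == 1)
        if lone.size == 0:
            pca = PCA(random_state=rng_seed)
            coords = pca.fit_transform(z)
            return ClusterResult(
                assignments=pd.Series(lab, index=x.index, name="cluster"),
                chosen_k=best_k,
                silhouette_by_k=sil,
                removed_outliers=removed,
                dropped_columns=zero_var,
                pca_coords=pd.DataFrame(coords[:, :2], index=x.index,
                                        columns=["pc1", "pc2"]),
                explained_variance_ratio=pca.explained_variance_ratio_,
            )
        outlier_rows = x.index[np.isin(lab, lone)].tolist()
        logger.info("removing sole-member-cluster outliers: %s", outlier_rows)
        removed.extend(outlier_rows)
        x = x.drop(index=outlier_rows)
        if max(ks) >= len(x):
            ks = [k for k in ks if k < len(x)]
    raise RuntimeError("sole-member-cluster removal did not converge")


# ---------------------------------------------------------------------------
# CHA2DS2-VASc
# ---------------------------------------------------------------------------

def chads_vasc(chf: bool, hypertension: bool, diabetes: bool,
               stroke_tia: bool, vascular_disease: bool,
               age_y: float, female: bool) -> int:
    """CHA2DS2-VASc stroke-risk score.

    CHF +1, hypertension +1, age >= 75 +2, diabetes +1, stroke/TIA +2,
    vascular disease +1, age 65-74 +1, female sex +1.
    """
    if age_y < 0:
        raise ValueError("age must be non-negative")
    score = int(chf) + int(hypertension) + int(diabetes)
    score += 2 * int(stroke_tia) + int(vascular_disease) + int(female)
    if age_y >= 75:
        score += 2
    elif age_y >= 65:
        score += 1
    return score


# ---------------------------------------------------------------------------
# report container
# ---------------------------------------------------------------------------

@dataclass
class StatReport:
    """Named collection of test results, serializable to JSON."""

    entries: dict = field(default_factory=dict)

    def add(self, name: str, result) -> None:
        self.entries[name] = result

    def to_dict(self) -> dict:
        return {k: (v.to_dict() if hasattr(v, "to_dict") else v)
                for k, v in self.entries.items()}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)
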