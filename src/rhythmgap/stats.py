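"""Derived measures and inferential statistics for threshold data.

Implements the analysis stage: per-subject difference scores, paired t
tests with Cohen's d, Pearson correlations against battery covariates,
and the 2 (age group, between) x 3 (rhythm condition, within) x 2
(shift direction, within) split-plot ANOVA with Greenhouse-Geisser
correction on within effects involving the three-level factor.

The mixed ANOVA follows the classical multivariate-contrast approach:
for each within-subject effect the 6 cell scores are projected onto an
orthonormal contrast basis, a cell-means model over groups is fitted in
the contrast space, and the univariate F is formed from traces of the
hypothesis and residual SSCP matrices.  The Greenhouse-Geisser epsilon
is estimated from the pooled within-group covariance in contrast space.
Group (between) hypotheses are Type III, i.e. tests on unweighted group
means, which matters when group sizes differ (11 vs 10 by default).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .trials import DIRECTIONS, RHYTHM_CONDITIONS

__all__ = [
    "CELL_ORDER",
    "SubjectResult",
    "PairedTResult",
    "AnovaResult",
    "difference_scores",
    "paired_t_and_d",
    "pearson_r",
    "split_plot_anova",
    "correlation_table",
]

#: fixed column order of the 6 design cells: rhythm-major, direction-minor
CELL_ORDER = tuple(itertools.product(RHYTHM_CONDITIONS, DIRECTIONS))


@dataclass(frozen=True)
class SubjectResult:
    """Per-subject thresholds for the 6 design cells plus covariates."""

    subject_id: str
    group: str
    thresholds: dict  # (rhythm_condition, direction) -> mean threshold
    battery_scores: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CELL_ORDER if c not in self.thresholds]
        if missing:
            raise ValueError(f"missing threshold cells: {missing}")

    def cells(self) -> np.ndarray:
        """Thresholds as a vector in :data:`CELL_ORDER`."""
        return np.array([self.thresholds[c] for c in CELL_ORDER], dtype=float)

    @property
    def late_early_diff(self) -> float:
        return difference_scores(self)[0]

    @property
    def rhythm_diff(self) -> float:
        return difference_scores(self)[1]

    @property
    def mean_threshold(self) -> float:
        return float(self.cells().mean())


def difference_scores(result: SubjectResult) -> tuple[float, float]:
    """(late−early, altered−unaltered) difference scores.

    late−early: mean of the three late-onset cells minus the mean of
    the three early-onset cells (positive = better early-onset
    detection).  rhythm: mean of the four altered-rhythm cells minus
    the mean of the two unaltered cells (positive = cost of rhythm
    alteration).
    """
    th = result.thresholds
    late = np.mean([th[(r, "late")] for r in RHYTHM_CONDITIONS])
    early = np.mean([th[(r, "early")] for r in RHYTHM_CONDITIONS])
    altered = np.mean([th[(r, d)] for r in ("low_rate", "high_rate") for d in DIRECTIONS])
    unaltered = np.mean([th[("unaltered", d)] for d in DIRECTIONS])
    return float(late - early), float(altered - unaltered)


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    cohens_d: float
    degenerate: bool = False


def paired_t_and_d(x, y) -> PairedTResult:
    """Paired t test with Cohen's d = mean(diff)/sd(diff).

    A zero-variance difference vector cannot support a t statistic and
    is flagged degenerate (t and p are NaN, d is 0 when the mean
    difference is 0, else signed infinity).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        d = 0.0 if diff.mean() == 0 else float(np.sign(diff.mean()) * np.inf)
        return PairedTResult(t=float("nan"), df=n - 1, p=float("nan"),
                             cohens_d=d, degenerate=True)
    res = sps.ttest_rel(x, y)
    return PairedTResult(
        t=float(res.statistic),
        df=n - 1,
        p=float(res.pvalue),
        cohens_d=float(diff.mean() / sd),
    )


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be 1-d vectors of equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass
class AnovaResult:
    """Split-plot ANOVA table.

    ``table`` has one row per effect and per error stratum with columns
    ss, df, df_gg, ms, F, p, p_gg, epsilon, partial_eta_sq.  Effects
    with a single numerator df carry epsilon = 1 (no correction).
    """

    table: pd.DataFrame

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k, k-1) orthonormal contrast basis orthogonal to the constant."""
    basis = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1]
    return basis


def _hypothesis_ss(L: np.ndarray, B: np.ndarray, xtx_inv: np.ndarray) -> float:
    """tr of the SSCP for the general linear hypothesis L @ B = 0."""
    LB = L @ B
    middle = np.linalg.inv(L @ xtx_inv @ L.T)
    return float(np.trace(LB.T @ middle @ LB))


def split_plot_anova(thresholds: np.ndarray, groups) -> AnovaResult:
    """Mixed ANOVA for an (n_subjects, 6) threshold matrix.

    Columns must follow :data:`CELL_ORDER` (rhythm-major).  ``groups``
    is a length-n sequence of group labels (one between factor).
    Greenhouse-Geisser correction is applied to within effects with
    more than one numerator df (those involving the rhythm factor).
    """
    Y = np.asarray(thresholds, dtype=float)
    groups = np.asarray(groups)
    if Y.ndim != 2 or Y.shape[1] != len(CELL_ORDER):
        raise ValueError(f"thresholds must be n x {len(CELL_ORDER)}")
    if np.isnan(Y).any():
        raise ValueError("unbalanced within-subject design (missing cells)")
    levels = list(dict.fromkeys(groups))
    g = len(levels)
    n = Y.shape[0]
    counts = np.array([(groups == lv).sum() for lv in levels])
    if (counts < 2).any():
        raise ValueError("need at least 2 subjects per group")

    X = np.column_stack([(groups == lv).astype(float) for lv in levels])
    xtx_inv = np.diag(1.0 / counts)
    # unweighted grand mean (Type III) and group-difference hypotheses
    L_const = np.full((1, g), 1.0 / g)
    L_group = np.column_stack([np.ones(g - 1), -np.eye(g - 1)]) if g > 1 else None

    m3 = np.full((3, 1), 1.0 / np.sqrt(3.0))
    m2 = np.full((2, 1), 1.0 / np.sqrt(2.0))
    c3 = _orthonormal_contrasts(3)
    c2 = _orthonormal_contrasts(2)

    strata = {
        "between": np.kron(m3, m2),
        "rhythm": np.kron(c3, m2),
        "direction": np.kron(m3, c2),
        "rhythm_x_direction": np.kron(c3, c2),
    }

    rows: dict[str, dict] = {}
    for stratum, M in strata.items():
        Z = Y @ M
        q = M.shape[1]
        B = xtx_inv @ X.T @ Z  # group means in contrast space
        E = Z.T @ Z - B.T @ (X.T @ X) @ B
        df_e = q * (n - g)
        ss_e = float(np.trace(E))
        S = E / (n - g)
        denom = q * np.trace(S @ S)
        if q > 1 and denom > 0:
            eps = float(min(max(np.trace(S) ** 2 / denom, 1.0 / q), 1.0))
        else:
            eps = 1.0  # 1-df effect, or degenerate (zero) error covariance

        if stratum == "between":
            effects = {"age": (L_group, g - 1)}
            err_name = "error_between"
        else:
            effects = {
                stratum: (L_const, 1),
                f"age_x_{stratum}": (L_group, g - 1),
            }
            err_name = f"error_{stratum}"

        for name, (L, l_df) in effects.items():
            ss_h = _hypothesis_ss(L, B, xtx_inv)
            df_h = q * l_df
            ms_h, ms_e = ss_h / df_h, ss_e / df_e
            F = ms_h / ms_e if ms_e > 0 else (0.0 if ss_h == 0 else float("inf"))
            p = float(sps.f.sf(F, df_h, df_e)) if ms_e > 0 else float("nan")
            p_gg = (
                float(sps.f.sf(F, df_h * eps, df_e * eps)) if ms_e > 0 else float("nan")
            )
            rows[name] = dict(
                ss=ss_h, df=df_h, df_gg=df_h * eps, ms=ms_h, F=F, p=p,
                p_gg=p_gg, epsilon=eps,
                partial_eta_sq=ss_h / (ss_h + ss_e) if ss_h + ss_e > 0 else 0.0,
            )
        rows[err_name] = dict(
            ss=ss_e, df=df_e, df_gg=df_e * eps, ms=ss_e / df_e, F=np.nan,
            p=np.nan, p_gg=np.nan, epsilon=eps, partial_eta_sq=np.nan,
        )

    order = [
        "age", "error_between",
        "rhythm", "age_x_rhythm", "error_rhythm",
        "direction", "age_x_direction", "error_direction",
        "rhythm_x_direction", "age_x_rhythm_x_direction", "error_rhythm_x_direction",
    ]
    return AnovaResult(table=pd.DataFrame([rows[k] for k in order], index=order))


def correlation_table(
    results: list[SubjectResult],
    score_names: tuple[str, ...] = ("GAP", "SC", "RD", "WM"),
) -> pd.DataFrame:
    """Correlations of battery scores with mean threshold and the two
    difference scores, in the layout of the published table: one row per
    battery measure, columns (r, p) for each performance measure."""
    usable = [r for r in results if all(s in r.battery_scores for s in score_names)]
    if len(usable) < 3:
        raise ValueError("need at least 3 subjects with complete battery scores")
    perf = {
        "mean_threshold": np.array([r.mean_threshold for r in usable]),
        "late_early_diff": np.array([r.late_early_diff for r in usable]),
        "rhythm_diff": np.array([r.rhythm_diff for r in usable]),
    }
    rows = {}
    for s in score_names:
        scores = np.array([r.battery_scores[s] for r in usable])
        row = {}
        for pname, pvals in perf.items():
            r_val, p_val = pearson_r(scores, pvals)
            row[f"{pname}_r"] = r_val
            row[f"{pname}_p"] = p_val
        rows[s] = row
    return pd.DataFrame(rows).T
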