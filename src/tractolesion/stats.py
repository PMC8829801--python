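"""Group statistics: paired tests, two-way repeated-measures ANOVA, Dice.

Paired comparisons use a paired-samples t test when the paired differences
look Gaussian (Shapiro-Wilk at alpha=.05) and the Wilcoxon signed-rank test
otherwise; both are always computable directly.  The RM-ANOVA is a complete
balanced two-within-factor decomposition (e.g. timepoint x distance level)
with subject-by-factor error terms and no sphericity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedTestResult",
    "RmAnovaResult",
    "OverlapResult",
    "paired_t",
    "wilcoxon_signed_rank",
    "compare_paired",
    "rm_anova_2way",
    "dice",
]


@dataclass
class PairedTestResult:
    test: str  # "paired_t" or "wilcoxon"
    statistic: float  # t, or Wilcoxon T (min rank sum)
    df: float | None
    z: float | None
    p: float
    n: int
    normality_p: float | None = None


@dataclass
class RmAnovaResult:
    """F tests for two within-subject factors and their interaction."""

    effects: dict  # name -> dict(ss, df, ms, error_ss, error_df, F, p)
    ss_total: float
    ss_partition: float  # sum of all partitioned SS terms


@dataclass
class OverlapResult:
    dsc: float
    size_a: int
    size_b: int
    size_intersection: int


def _diffs(a, b) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1D arrays")
    if len(a) < 2:
        raise ValueError("need at least 2 pairs")
    return a - b


def paired_t(a, b) -> PairedTestResult:
    """Paired-samples t test: t = mean(d) / (sd(d)/sqrt(n)), df = n-1."""
    d = _diffs(a, b)
    if np.allclose(d.std(ddof=1), 0):
        if np.allclose(d, 0):
            # all pairs identical: t = 0 by convention, p = 1
            return PairedTestResult("paired_t", 0.0, len(d) - 1, None, 1.0, len(d))
        raise ValueError("zero-variance nonzero differences: t undefined")
    res = sps.ttest_rel(np.asarray(a, float), np.asarray(b, float))
    return PairedTestResult(
        "paired_t", float(res.statistic), float(len(d) - 1), None,
        float(res.pvalue), len(d),
    )


def wilcoxon_signed_rank(a, b) -> PairedTestResult:
    """Wilcoxon signed-rank test with normal approximation.

    Zero differences are dropped, tied absolute differences mid-ranked;
    T is the smaller signed-rank sum and z the tie-corrected standardized
    statistic.
    """
    d = _diffs(a, b)
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all paired differences are zero")
    res = sps.wilcoxon(d, zero_method="wilcox", correction=False, method="approx")
    return PairedTestResult(
        "wilcoxon", float(res.statistic), None, float(res.zstatistic),
        float(res.pvalue), len(d),
    )


def compare_paired(a, b, alpha: float = 0.05) -> PairedTestResult:
    """Paired comparison with a Shapiro-Wilk normality gate on differences.

    Gaussian-looking differences (p >= alpha) -> paired t; otherwise
    Wilcoxon signed-rank.  The normality p-value is recorded either way.
    """
    d = _diffs(a, b)
    if np.allclose(d, d[0]):
        norm_p = float("nan")  # Shapiro undefined on constant input
    else:
        norm_p = float(sps.shapiro(d).pvalue)
    if np.isnan(norm_p) or norm_p >= alpha:
        out = paired_t(a, b)
    else:
        out = wilcoxon_signed_rank(a, b)
    out.normality_p = norm_p
    return out


def _gg_epsilon(M: np.ndarray, d: int) -> float:
    """Greenhouse-Geisser epsilon from an (n, k) matrix of effect-projected
    per-subject scores; ``d`` is the effect's df (rank of the projection)."""
    if d < 2:
        return 1.0
    S = np.cov(M, rowvar=False, ddof=1)
    den = d * np.sum(S**2)
    if den <= 0:
        return 1.0
    eps = float(np.trace(S) ** 2 / den)
    return float(np.clip(eps, 1.0 / d, 1.0))


def rm_anova_2way(values: np.ndarray, correction: str | None = None) -> RmAnovaResult:
    """Two-way repeated-measures ANOVA on a complete (n, a, b) array.

    Axis 0 indexes subjects, axes 1 and 2 the two within-subject factors
    (e.g. timepoint with a=2 levels and distance with b=6 levels).  Each
    effect is tested against its own subject-interaction error term:
    F_A = MS_A / MS_{AxS} with df (a-1), (a-1)(n-1), and analogously for
    B and AxB.  By default no sphericity correction is applied;
    ``correction="gg"`` scales each effect's df pair by its
    Greenhouse-Geisser epsilon when computing the p-value (the F value
    and nominal df are reported unchanged, with ``eps`` and ``p_corr``
    added per effect).
    """
    if correction not in (None, "gg"):
        raise ValueError(f"unknown sphericity correction {correction!r}")
    y = np.asarray(values, dtype=float)
    if y.ndim != 3:
        raise ValueError("values must be (subjects, factorA levels, factorB levels)")
    if np.isnan(y).any():
        cells = np.argwhere(np.isnan(y))
        raise ValueError(f"design has missing cells at (subject, A, B) = {cells.tolist()}")
    n, a, b = y.shape
    if n < 2 or a < 2 or b < 2:
        raise ValueError("need >= 2 subjects and >= 2 levels per factor")

    gm = y.mean()
    m_s = y.mean(axis=(1, 2))  # per subject
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)  # (n, a)
    m_sb = y.mean(axis=1)  # (n, b)
    m_ab = y.mean(axis=0)  # (a, b)

    ss_subj = a * b * np.sum((m_s - gm) ** 2)
    ss_a = n * b * np.sum((m_a - gm) ** 2)
    ss_b = n * a * np.sum((m_b - gm) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + gm) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + gm) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + gm) ** 2)
    ss_total = np.sum((y - gm) ** 2)
    ss_abs = ss_total - (ss_subj + ss_a + ss_b + ss_ab + ss_as + ss_bs)

    # treat round-off-scale SS as exact zeros so degenerate designs give F=0
    tiny = 1e-12 * max(float(ss_total), 1e-300)

    def effect(name, ss, df, err_ss, err_df):
        ss = 0.0 if abs(ss) < tiny else ss
        err_ss = 0.0 if abs(err_ss) < tiny else err_ss
        ms, err_ms = ss / df, err_ss / err_df
        if err_ms == 0:
            f = 0.0 if ss == 0 else float("inf")
        else:
            f = ms / err_ms
        p = float(sps.f.sf(f, df, err_df)) if np.isfinite(f) else 0.0
        return {
            "ss": float(ss), "df": int(df), "ms": float(ms),
            "error_ss": float(err_ss), "error_df": int(err_df),
            "F": float(f), "p": p,
        }

    effects = {
        "A": effect("A", ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        "B": effect("B", ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        "AxB": effect("AxB", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    }
    if correction == "gg":
        inter = y - m_sa[:, :, None] - m_sb[:, None, :] + m_s[:, None, None]
        for name, M, d in (
            ("A", m_sa - m_s[:, None], a - 1),
            ("B", m_sb - m_s[:, None], b - 1),
            ("AxB", inter.reshape(n, a * b), (a - 1) * (b - 1)),
        ):
            e = effects[name]
            eps = _gg_epsilon(M, d)
            e["eps"] = eps
            if np.isfinite(e["F"]):
                e["p_corr"] = float(
                    sps.f.sf(e["F"], eps * e["df"], eps * e["error_df"])
                )
            else:
                e["p_corr"] = 0.0
    partition = ss_subj + ss_a + ss_b + ss_ab + ss_as + ss_bs + ss_abs
    return RmAnovaResult(effects, float(ss_total), float(partition))


def dice(a, b) -> OverlapResult:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) of two binary masks.

    Accepts VolumeImage or array input; grids must match when both carry
    one.  Two empty masks are defined as perfect overlap (DSC = 1) with a
    warning.
    """
    import warnings

    from .grids import VolumeImage

    if isinstance(a, VolumeImage) and isinstance(b, VolumeImage):
        a.grid.require_match(b.grid, "masks")
        a, b = a.data, b.data
    elif isinstance(a, VolumeImage) or isinstance(b, VolumeImage):
        a = a.data if isinstance(a, VolumeImage) else a
        b = b.data if isinstance(b, VolumeImage) else b
    am = np.asarray(a) > 0
    bm = np.asarray(b) > 0
    if am.shape != bm.shape:
        raise ValueError("masks have different shapes")
    na, nb = int(am.sum()), int(bm.sum())
    ni = int((am & bm).sum())
    if na + nb == 0:
        warnings.warn("both masks are empty; DSC defined as 1", stacklevel=2)
        return OverlapResult(1.0, 0, 0, 0)
    return OverlapResult(2.0 * ni / (na + nb), na, nb, ni)
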