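"""Repeated-measures ANOVA, paired comparisons and condition-summary reports.

The behavioural, pupil and theta outcomes are analysed with a fully
within-subject 2 (rotation angle: 30°, 150°) × 4 (session: S1–S4) design:
classic cell-means sums-of-squares decomposition, F-tests of each effect
against its effect × subject interaction, Greenhouse–Geisser sphericity
correction of the degrees of freedom (epsilon computed per effect from the
covariance of the orthonormal effect contrasts), and partial η² effect
sizes.  Post-hoc machinery: paired t-tests with paired Cohen's d
(mean difference / SD of differences) and Bonferroni adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EffectResult",
    "RMAnovaResult",
    "PairedComparison",
    "rm_anova_2x4",
    "paired_t_cohens_d",
    "bonferroni",
    "format_effect",
]


@dataclass
class EffectResult:
    name: str
    f: float
    df1: float  # GG-corrected
    df2: float
    df1_uncorrected: float
    df2_uncorrected: float
    p: float  # GG-corrected
    p_uncorrected: float
    eta_p2: float
    epsilon: float
    ss_effect: float
    ss_error: float


@dataclass
class RMAnovaResult:
    angle: EffectResult
    session: EffectResult
    interaction: EffectResult

    @property
    def effects(self) -> dict[str, EffectResult]:
        return {"angle": self.angle, "session": self.session, "angle×session": self.interaction}


@dataclass
class PairedComparison:
    t: float
    df: int
    p_raw: float
    p_adjusted: float
    cohens_d: float


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k−1) × k orthonormal contrast matrix (rows orthonormal, sum 0)."""
    helmert = np.zeros((k - 1, k))
    for i in range(k - 1):
        helmert[i, : i + 1] = 1.0
        helmert[i, i + 1] = -(i + 1.0)
        helmert[i] /= np.linalg.norm(helmert[i])
    return helmert


def _gg_epsilon(y: np.ndarray, contrasts: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon of the contrast-transformed covariance.

    ``y`` is (subjects, variables); ``contrasts`` maps the variables onto the
    effect's (df × variables) orthonormal contrast space.
    """
    z = y @ contrasts.T
    sigma = np.cov(z, rowvar=False, ddof=1)
    sigma = np.atleast_2d(sigma)
    tr = np.trace(sigma)
    eps = tr**2 / (sigma.shape[0] * np.sum(sigma**2))
    return float(min(1.0, eps))


def rm_anova_2x4(values: np.ndarray) -> RMAnovaResult:
    """Two-way fully within-subject ANOVA on (subjects, angles, sessions).

    Works for any level counts ≥ 2 per factor; the name reflects the study's
    2 angle × 4 session design.  Requires complete data (no imputation).
    """
    y = np.asarray(values, float)
    if y.ndim != 3:
        raise ValueError("values must be (subjects, angle_levels, session_levels)")
    if not np.isfinite(y).all():
        raise ValueError("missing cells are not supported")
    n, a, b = y.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))  # subject means
    m_a = y.mean(axis=(0, 2))  # angle means
    m_b = y.mean(axis=(0, 1))  # session means
    m_ab = y.mean(axis=0)  # cell means
    m_sa = y.mean(axis=2)  # subject × angle
    m_sb = y.mean(axis=1)  # subject × session

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (
        y
        - m_ab[None, :, :]
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - grand
    )
    ss_abs = np.sum(resid**2)

    c_a = _orthonormal_contrasts(a)
    c_b = _orthonormal_contrasts(b)
    y_flat = y.reshape(n, a * b)  # variables ordered (angle, session)
    # per-effect contrasts: effect contrast on its own factor, average
    # (orthonormalised) over the other factor
    eps_a = _gg_epsilon(y_flat, np.kron(c_a, np.full((1, b), 1.0 / np.sqrt(b))))
    eps_b = _gg_epsilon(y_flat, np.kron(np.full((1, a), 1.0 / np.sqrt(a)), c_b))
    eps_ab = _gg_epsilon(y_flat, np.kron(c_a, c_b))

    def effect(name, ss_eff, ss_err, df1, df2, eps):
        f = (ss_eff / df1) / (ss_err / df2)
        p_unc = float(stats.f.sf(f, df1, df2))
        p_gg = float(stats.f.sf(f, df1 * eps, df2 * eps))
        return EffectResult(
            name=name,
            f=float(f),
            df1=df1 * eps,
            df2=df2 * eps,
            df1_uncorrected=df1,
            df2_uncorrected=df2,
            p=p_gg,
            p_uncorrected=p_unc,
            eta_p2=float(ss_eff / (ss_eff + ss_err)),
            epsilon=eps,
            ss_effect=float(ss_eff),
            ss_error=float(ss_err),
        )

    return RMAnovaResult(
        angle=effect("angle", ss_a, ss_as, a - 1, (a - 1) * (n - 1), eps_a),
        session=effect("session", ss_b, ss_bs, b - 1, (b - 1) * (n - 1), eps_b),
        interaction=effect(
            "angle×session", ss_ab, ss_abs, (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1), eps_ab
        ),
    )


def paired_t_cohens_d(a: np.ndarray, b: np.ndarray, m_comparisons: int = 1) -> PairedComparison:
    """Paired t-test with paired Cohen's d and optional Bonferroni adjustment."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of the paired differences")
    t, p = stats.ttest_rel(a, b)
    return PairedComparison(
        t=float(t),
        df=a.size - 1,
        p_raw=float(p),
        p_adjusted=float(min(1.0, m_comparisons * p)),
        cohens_d=float(d.mean() / sd),
    )


def bonferroni(p_list, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: elementwise min(1, m·p)."""
    p = np.asarray(p_list, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else m
    return np.minimum(1.0, m * p)


def format_effect(e: EffectResult) -> str:
    """Human-readable line in the conventional F(df1, df2) = …, p = …, η² = … style."""
    return (
        f"{e.name}: F({e.df1:.2f},{e.df2:.2f}) = {e.f:.2f}, "
        f"p = {e.p:.3g}, eta_p^2 = {e.eta_p2:.2f} (GG epsilon = {e.epsilon:.3f})"
    )
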