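"""Per-ROI statistical battery.

Three test families, mirroring the regional analysis of paired lung-strain
studies:

(a) absolute strain change T1 vs T3: exact Wilcoxon signed-rank on
    subject-level ROI means (paired);
(b) strain progression: is the per-subject SPI different from 1.0?  The
    default is the one-sample exact signed-rank on SPI - 1 (a two-sample
    test against the constant 1.0 is degenerate: the reference "sample"
    has zero variance); a Mann-Whitney mode against a constant-1 sample
    is also provided;
(c) heterogeneity change: the Feltz-Miller asymptotic chi-square test for
    equality of coefficients of variation between the pooled per-tet
    (1 + strain) distributions at T1 and T3.

With n = 5 paired subjects the exact two-sided signed-rank p-value can
never go below 2/32 = 0.0625, so per-ROI calls at alpha = 0.05 are only
reachable one-sided; the default sidedness for progression hypotheses is
therefore "greater", and both modes are exposed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import stats as sps

from .roi import percentage_significant, spi as spi_index

EXACT_N_MAX = 25


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int | tuple[int, ...]
    alternative: str
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _signed_rank_exact_p(w_plus: float, ranks: np.ndarray, alternative: str) -> float:
    """Exact signed-rank tail probability by enumeration of sign patterns.

    Dynamic programming over doubled mid-ranks (integers even with ties)
    counts, for every achievable W+, the number of the 2^n sign
    assignments attaining it -- equivalent to full enumeration.
    """
    r2 = np.round(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts += shifted
    counts /= 2.0 ** len(r2)
    w2 = int(np.round(2 * w_plus))
    p_greater = float(counts[w2:].sum())
    p_less = float(counts[: w2 + 1].sum())
    if alternative == "greater":
        return min(p_greater, 1.0)
    if alternative == "less":
        return min(p_less, 1.0)
    return min(1.0, 2.0 * min(p_greater, p_less))


def wilcoxon_signed_rank(
    x: np.ndarray,
    y: np.ndarray | None = None,
    alternative: str = "two-sided",
) -> TestResult:
    """Wilcoxon signed-rank test, exact for n <= 25.

    ``x`` and ``y`` are paired samples (or ``x`` the differences).  Zero
    differences are dropped (Wilcoxon convention); ties in |d| get
    mid-ranks.  The exact null distribution enumerates all 2^n sign
    assignments; beyond n = 25 a normal approximation with tie correction
    is used.
    """
    d = np.asarray(x, float) - (0.0 if y is None else np.asarray(y, float))
    if y is not None and len(np.atleast_1d(x)) != len(np.atleast_1d(y)):
        raise ValueError("paired samples must have equal length")
    d = d[d != 0]
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return TestResult(0.0, 1.0, 0, alternative, "wilcoxon-signed-rank (degenerate)")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        p = _signed_rank_exact_p(w_plus, ranks, alternative)
        method = "wilcoxon-signed-rank (exact)"
    else:
        mu = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / np.sqrt(var)
        if alternative == "greater":
            p = float(sps.norm.sf(z))
        elif alternative == "less":
            p = float(sps.norm.cdf(z))
        else:
            p = float(2 * sps.norm.sf(abs(z)))
        method = "wilcoxon-signed-rank (normal approx.)"
    return TestResult(w_plus, min(p, 1.0), n, alternative, method)


def spi_vs_one_test(
    spi_values: np.ndarray,
    alternative: str = "greater",
    mode: str = "signed_rank",
) -> TestResult:
    """Is the per-subject SPI sample different from 1.0?

    mode='signed_rank' (default): one-sample exact signed-rank on
    SPI - 1.  mode='mann_whitney': Mann-Whitney U of the SPI sample
    against a same-length constant-1.0 sample.
    """
    s = np.asarray(spi_values, float)
    if s.size == 0:
        raise ValueError("empty SPI sample")
    if mode == "signed_rank":
        res = wilcoxon_signed_rank(s - 1.0, alternative=alternative)
        return TestResult(res.statistic, res.p_value, res.n, alternative, "spi-vs-1 " + res.method)
    if mode == "mann_whitney":
        ref = np.ones_like(s)
        u, p = sps.mannwhitneyu(s, ref, alternative=alternative, method="asymptotic")
        return TestResult(float(u), float(p), (len(s), len(ref)), alternative, "spi-vs-1 mann-whitney-u")
    raise ValueError(f"unknown mode {mode!r}")


def feltz_miller_cv_test(samples: list[np.ndarray]) -> TestResult:
    """Feltz-Miller asymptotic test of equal coefficients of variation.

    For k groups with sample CVs c_j = s_j / xbar_j and m_j = n_j - 1,
    the pooled CV is cbar = sum(m_j c_j) / sum(m_j) and

        D = sum_j m_j (c_j - cbar)^2 / (cbar^2 (0.5 + cbar^2))

    is referred to chi-square with k - 1 degrees of freedom.  Group means
    must be positive (inputs here are 1 + strain per tetrahedron, which
    guarantees positivity for physical deformations).
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    c, m = [], []
    for s in samples:
        s = np.asarray(s, float)
        if len(s) < 2:
            raise ValueError("each group needs n >= 2")
        mean = s.mean()
        if mean <= 0:
            raise ValueError("group mean must be positive for a CV comparison")
        c.append(np.std(s, ddof=1) / mean)
        m.append(len(s) - 1)
    c = np.asarray(c)
    m = np.asarray(m, float)
    cbar = float((m * c).sum() / m.sum())
    k = len(samples)
    if cbar == 0.0:
        warnings.warn("all groups have zero CV; p = 1", stacklevel=2)
        return TestResult(0.0, 1.0, tuple(int(mi) + 1 for mi in m), "two-sided", "feltz-miller")
    d_stat = float((m * (c - cbar) ** 2).sum() / (cbar**2 * (0.5 + cbar**2)))
    p = float(sps.chi2.sf(d_stat, k - 1))
    return TestResult(d_stat, p, tuple(int(mi) + 1 for mi in m), "two-sided", "feltz-miller")


# ----------------------------------------------------- cohort ROI testing


@dataclass
class SignificanceMap:
    """Per-cell p-values and significance flags for one test family."""

    p_values: np.ndarray  # (n, n); NaN where untestable
    flags: np.ndarray  # (n, n) bool
    testable: np.ndarray  # (n, n) bool
    alpha: float
    method: str

    @property
    def n_testable(self) -> int:
        return int(self.testable.sum())

    @property
    def n_significant(self) -> int:
        return int(self.flags.sum())

    @property
    def percentage(self) -> float:
        return percentage_significant(self.flags, self.n_testable)


@dataclass
class GroupROIData:
    """Subject-level ROI summaries for one group, both times.

    mean[time]: (n_subjects, n, n) volume-weighted ROI mean strain;
    samples[time]: per subject, dict (i, j) -> per-tet strain array
    (optionally subsampled) for distribution-level tests.
    """

    mean: dict[str, np.ndarray]
    samples: dict[str, list[dict[tuple[int, int], np.ndarray]]] = dc_field(default_factory=dict)


def _apply_alpha(p: np.ndarray, testable: np.ndarray, alpha: float, correct: bool) -> np.ndarray:
    if correct and testable.any():
        q = np.full_like(p, np.nan)
        q[testable] = sps.false_discovery_control(p[testable])
        return testable & (q < alpha)
    return testable & (p < alpha)


def roi_significance_maps(
    data: GroupROIData,
    alpha: float = 0.05,
    alternative: str = "greater",
    spi_mode: str = "signed_rank",
    fdr_correct: bool = False,
    n_grid: int = 10,
) -> dict[str, SignificanceMap]:
    """The three per-ROI test families for one group.

    A cell is testable only when occupied for every subject at both times
    and at least two subjects are available.  Family (c) additionally
    requires per-tet samples.  ``alpha = 0`` flags nothing, by
    construction of the strict comparison.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must be in [0, 1)")
    m1, m3 = data.mean["T1"], data.mean["T3"]
    if m1.shape != m3.shape:
        raise ValueError("T1/T3 ROI arrays must agree in shape")
    n_subj = m1.shape[0]
    testable = np.isfinite(m1).all(axis=0) & np.isfinite(m3).all(axis=0)
    if n_subj < 2:
        testable &= False
    out: dict[str, SignificanceMap] = {}

    p_strain = np.full((n_grid, n_grid), np.nan)
    p_spi = np.full((n_grid, n_grid), np.nan)
    for i, j in np.argwhere(testable):
        p_strain[i, j] = wilcoxon_signed_rank(
            m3[:, i, j], m1[:, i, j], alternative=alternative
        ).p_value
        cell_spi = spi_index(m1[:, i, j], m3[:, i, j])
        p_spi[i, j] = spi_vs_one_test(cell_spi, alternative=alternative, mode=spi_mode).p_value
    out["strain_t1_vs_t3"] = SignificanceMap(
        p_strain, _apply_alpha(p_strain, testable, alpha, fdr_correct), testable.copy(),
        alpha, f"wilcoxon signed-rank ({alternative})",
    )
    out["spi_vs_1"] = SignificanceMap(
        p_spi, _apply_alpha(p_spi, testable, alpha, fdr_correct), testable.copy(),
        alpha, f"spi vs 1.0, {spi_mode} ({alternative})",
    )

    if data.samples:
        p_shi = np.full((n_grid, n_grid), np.nan)
        testable_shi = testable.copy()
        for i, j in np.argwhere(testable):
            pooled = {}
            ok = True
            for t in ("T1", "T3"):
                per_subj = [s.get((i, j)) for s in data.samples[t]]
                if any(a is None for a in per_subj):
                    ok = False
                    break
                pooled[t] = 1.0 + np.concatenate(per_subj)
            if not ok or min(len(v) for v in pooled.values()) < 2:
                testable_shi[i, j] = False
                continue
            p_shi[i, j] = feltz_miller_cv_test([pooled["T1"], pooled["T3"]]).p_value
        out["shi_t1_vs_t3"] = SignificanceMap(
            p_shi, _apply_alpha(p_shi, testable_shi, alpha, fdr_correct), testable_shi,
            alpha, "feltz-miller CV equality on pooled (1 + strain)",
        )
    return out
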