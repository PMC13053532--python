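"""Statistical layer: rank tests with effect sizes, ROC/Youden thresholds,
multivariable logistic models and two-sample t-test power design.

Conventions:

* Mann–Whitney effect size is the rank-biserial coefficient
  ``r = 1 - 2U/(n1*n2)`` computed from the U statistic of the first group,
  so r = +1 when every value of group A lies below every value of group B.
* Exact p-values are used for small samples without ties
  (min(n1, n2) <= 8 for Mann–Whitney, n <= 12 non-zero pairs for the
  signed-rank test); otherwise the normal approximation with midrank tie
  correction.
* ROC direction is chosen so the positive class has the higher mean score;
  thresholds are midpoints between adjacent distinct observed scores, the
  Youden-optimal cut breaks ties toward higher specificity, and the
  reported operator is ``>=`` (higher-is-positive) or ``<=``.
* No multiple-testing adjustment is applied anywhere; every p-value is
  reported raw.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class StatTestResult:
    statistic: float
    p_value: float
    effect_r: float
    n1: int
    n2: int
    test: str = ""
    degenerate: bool = False


class RocDirection(str, enum.Enum):
    HIGHER_IS_POSITIVE = "higher_is_positive"
    LOWER_IS_POSITIVE = "lower_is_positive"


@dataclass
class RocResult:
    auc: float
    direction: RocDirection
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float

    @property
    def threshold_rule(self) -> str:
        """Printable decision rule, e.g. ``'>= 119.07'``."""
        op = ">=" if self.direction is RocDirection.HIGHER_IS_POSITIVE else "<="
        return f"{op} {self.threshold:.2f}"


@dataclass
class PredictorEffect:
    name: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class LogisticResult:
    predictors: list[PredictorEffect]
    lr_chi2: float
    df: int
    lr_p: float
    in_sample_auc: float
    coding_notes: str = ""
    separation_flag: bool = False


@dataclass(frozen=True)
class PowerSpec:
    """A-priori design of a two-sided two-sample t test."""

    effect_d: float = 0.90
    alpha: float = 0.05
    target_power: float = 0.80
    allocation: float = 1.0  # n2 / n1

    def validate(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.target_power < 1):
            raise ValueError("alpha and target_power must lie in (0, 1)")
        if self.effect_d <= 0:
            raise ValueError("effect_d must be > 0")
        if self.alpha >= self.target_power:
            raise ValueError("alpha >= target power is not a usable design")


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def mann_whitney(group_a, group_b) -> StatTestResult:
    """Two-sided Mann–Whitney U test with rank-biserial effect size.

    U is reported for ``group_a``. Exact p when min(n1, n2) <= 8 and the
    pooled sample has no ties, normal approximation (tie-corrected,
    continuity-corrected) otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    exact = min(a.size, b.size) <= 8 and not _has_ties(np.concatenate([a, b]))
    res = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="exact" if exact else "asymptotic")
    u = float(res.statistic)
    effect_r = 1.0 - 2.0 * u / (a.size * b.size)
    return StatTestResult(
        statistic=u,
        p_value=float(min(1.0, res.pvalue)),
        effect_r=float(effect_r),
        n1=a.size,
        n2=b.size,
        test="mann_whitney_u",
    )


def wilcoxon_signed_rank(paired_x, paired_y) -> StatTestResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped. The standardized statistic is
    ``Z = (W+ - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24 - tie term)`` where W+ is
    the positive-rank sum of ``x - y``, so Z < 0 when y tends to exceed x.
    Exact p for n <= 12 untied non-zero pairs, else the (tie-corrected)
    normal approximation. All-zero differences give a degenerate result
    with p = 1.
    """
    x = np.asarray(paired_x, dtype=float)
    y = np.asarray(paired_y, dtype=float)
    if x.shape != y.shape or x.size < 1:
        raise ValueError("paired samples must have equal, non-zero length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        return StatTestResult(0.0, 1.0, 0.0, x.size, x.size,
                              test="wilcoxon_signed_rank", degenerate=True)

    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    # tie correction on the variance of W+
    _, counts = np.unique(np.abs(d), return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_plus - mu) / np.sqrt(sigma2) if sigma2 > 0 else 0.0

    if n <= 12:
        # exhaustive sign-flip enumeration on the (mid)ranks; handles ties,
        # two-sided by distance of W+ from its null mean
        masks = (np.arange(1 << n)[:, None] >> np.arange(n)) & 1
        ws = masks @ ranks
        p = float(np.mean(np.abs(ws - mu) >= abs(w_plus - mu) - 1e-12))
    else:
        p = float(sps.wilcoxon(d, alternative="two-sided", method="approx").pvalue)
    # effect size: matched-pairs rank-biserial correlation
    w_minus = n * (n + 1) / 2.0 - w_plus
    effect_r = (w_plus - w_minus) / (n * (n + 1) / 2.0)
    return StatTestResult(
        statistic=float(z),
        p_value=min(1.0, p),
        effect_r=float(effect_r),
        n1=x.size,
        n2=x.size,
        test="wilcoxon_signed_rank",
    )


def spearman_correlation(x, y) -> StatTestResult:
    """Spearman rank correlation (midranks) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return StatTestResult(np.nan, np.nan, np.nan, x.size, y.size,
                              test="spearman", degenerate=True)
    res = sps.spearmanr(x, y)
    return StatTestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect_r=float(res.statistic),
        n1=x.size,
        n2=y.size,
        test="spearman",
    )


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------

def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the rank (Mann–Whitney) formulation with midrank ties."""
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = sps.rankdata(scores)
    r_pos = ranks[labels].sum()
    u_pos = r_pos - n_pos * (n_pos + 1) / 2.0
    return float(u_pos / (n_pos * n_neg))


def roc_with_youden(scores, labels) -> RocResult:
    """ROC analysis with the Youden-optimal operating threshold.

    Direction is chosen so the positive class has the higher mean score
    (ties break toward higher-is-positive). Candidate cuts are midpoints
    between adjacent distinct scores plus sentinels beyond the extremes;
    ties in J break toward higher specificity.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")

    higher = scores[labels].mean() >= scores[~labels].mean()
    direction = (RocDirection.HIGHER_IS_POSITIVE if higher
                 else RocDirection.LOWER_IS_POSITIVE)
    s = scores if higher else -scores
    auc = _rank_auc(s, labels)

    uniq = np.unique(s)
    cuts = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    best = None
    for c in cuts:
        pred = s >= c
        sens = (pred & labels).sum() / n_pos
        spec = (~pred & ~labels).sum() / n_neg
        j = sens + spec - 1.0
        # prefer larger J; on ties prefer higher specificity
        key = (round(j, 12), round(spec, 12))
        if best is None or key > best[0]:
            best = (key, c, sens, spec, j)
    _, cut, sens, spec, j = best
    threshold = cut if higher else -cut
    return RocResult(
        auc=auc,
        direction=direction,
        threshold=float(threshold),
        sensitivity=float(sens),
        specificity=float(spec),
        youden_j=float(j),
    )


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

def _expit(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))


def _ridge_logit(xmat: np.ndarray, y: np.ndarray, lam: float = 1e-2,
                 maxiter: int = 100, tol: float = 1e-8):
    """IRLS with a small ridge penalty (intercept unpenalized).

    Used when the unpenalized fit diverges (separation): keeps
    coefficients and standard errors finite so a flagged — never silent —
    result can still be reported.
    """
    n, p = xmat.shape
    pen = lam * np.eye(p)
    pen[0, 0] = 0.0
    beta = np.zeros(p)
    for _ in range(maxiter):
        mu = _expit(xmat @ beta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = xmat.T @ (y - mu) - pen @ beta
        hess = (xmat * w[:, None]).T @ xmat + pen
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.abs(step).max() < tol:
            break
    mu = _expit(xmat @ beta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    cov = np.linalg.inv((xmat * w[:, None]).T @ xmat + pen)
    bse = np.sqrt(np.diag(cov))
    llf = float(np.sum(y * np.log(np.clip(mu, 1e-12, None))
                       + (1 - y) * np.log(np.clip(1 - mu, 1e-12, None))))
    return beta, bse, llf


def logistic_model(
    design, labels, predictor_names=None, standardize: bool = True
) -> LogisticResult:
    """Multivariable logistic regression with Wald ORs and an LR test.

    ``design`` is an (n, k) matrix (no intercept column; one is added).
    Continuous predictors (> 2 distinct values) are standardized to unit
    SD when ``standardize`` is True, so their ORs are per 1 SD. Separation
    (diverging coefficients) is flagged rather than silently reported.
    """
    import statsmodels.api as sm

    x = np.asarray(design, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels, dtype=float)
    n, k = x.shape
    if n <= k:
        raise ValueError("need more observations than predictors")
    if predictor_names is None:
        predictor_names = [f"x{i}" for i in range(k)]
    if k == 0:
        # intercept-only model: LR statistic 0 by construction, chance AUC
        return LogisticResult(predictors=[], lr_chi2=0.0, df=0, lr_p=1.0,
                              in_sample_auc=0.5)

    notes = []
    xs = x.copy()
    if standardize:
        for j in range(k):
            col = x[:, j]
            if len(np.unique(col)) > 2:
                sd = col.std(ddof=1)
                if sd > 0:
                    xs[:, j] = (col - col.mean()) / sd
                    notes.append(f"{predictor_names[j]}: per 1 SD")

    xmat = sm.add_constant(xs, has_constant="add")
    separation = False
    params = bse = None
    llf = None
    try:
        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with warnings.catch_warnings():
            # a separated fit warns and overflows before we detect/flag it
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            fit = sm.Logit(y, xmat).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            separation = True
        params = np.asarray(fit.params)
        bse = np.asarray(fit.bse)
        llf = float(fit.llf)
        if not np.isfinite(bse).all():
            separation = True
    except Exception:
        separation = True
    if params is not None and np.isfinite(params).all():
        if np.abs(params).max() > 15:
            separation = True  # log-odds this large ~ separation
    else:
        # lightly ridge-penalized IRLS keeps the flagged output finite
        params, bse, llf = _ridge_logit(xmat, y, lam=1e-2)
        separation = True
    zcrit = sps.norm.ppf(0.975)
    def safe_exp(v: float) -> float:
        return float(np.exp(min(v, 700.0)))

    predictors = []
    for j in range(k):
        beta, se = params[j + 1], bse[j + 1]
        pval = 2 * sps.norm.sf(abs(beta / se)) if se > 0 else np.nan
        predictors.append(
            PredictorEffect(
                name=predictor_names[j],
                odds_ratio=safe_exp(beta),
                ci_low=safe_exp(beta - zcrit * se),
                ci_high=safe_exp(beta + zcrit * se),
                p_value=float(pval),
            )
        )

    # likelihood-ratio test against the intercept-only model
    p_bar = y.mean()
    llnull = float(n * (p_bar * np.log(p_bar) + (1 - p_bar) * np.log(1 - p_bar))) \
        if 0 < p_bar < 1 else 0.0
    lr_chi2 = max(0.0, 2 * (llf - llnull))
    lr_p = float(sps.chi2.sf(lr_chi2, k)) if k > 0 else 1.0
    fitted = _expit(xmat @ params)
    in_auc = _rank_auc(fitted, y.astype(bool)) if 0 < y.mean() < 1 else 0.5

    return LogisticResult(
        predictors=predictors,
        lr_chi2=float(lr_chi2),
        df=k,
        lr_p=lr_p,
        in_sample_auc=float(in_auc),
        coding_notes="; ".join(notes),
        separation_flag=separation,
    )


# ---------------------------------------------------------------------------
# power design
# ---------------------------------------------------------------------------

def power_two_sample_t(effect_d: float, n_per_group: int, alpha: float = 0.05) -> float:
    """Exact power of the two-sided two-sample t test via the noncentral t.

    With n per group (1:1), df = 2n - 2 and noncentrality
    ``ncp = d * sqrt(n/2)``; power = P(|T'| > t_crit).
    """
    if n_per_group < 2:
        return 0.0
    df = 2 * n_per_group - 2
    ncp = effect_d * np.sqrt(n_per_group / 2.0)
    tcrit = sps.t.ppf(1 - alpha / 2.0, df)
    return float(sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))


def sample_size_two_group_t(spec: PowerSpec) -> int:
    """Smallest n per group reaching the target power (noncentral-t search).

    Never below the closed-form normal-approximation bound
    ``2 (z_{1-a/2} + z_power)^2 / d^2``.
    """
    spec.validate()
    if spec.allocation != 1.0:
        raise NotImplementedError("only 1:1 allocation is implemented")
    z_a = sps.norm.ppf(1 - spec.alpha / 2.0)
    z_b = sps.norm.ppf(spec.target_power)
    n_lb = 2 * (z_a + z_b) ** 2 / spec.effect_d**2
    n = max(2, int(np.floor(n_lb)))
    while power_two_sample_t(spec.effect_d, n, spec.alpha) < spec.target_power:
        n += 1
        if n > 10**7:
            raise RuntimeError("sample-size search did not terminate")
    return n


def empirical_power(
    effect_d: float,
    n_per_group: int,
    alpha: float = 0.05,
    reps: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo rejection rate of the two-sided two-sample t test.

    Data are normal with unit SD and mean difference ``effect_d``. The t
    statistics for all replicates are computed in one vectorized pass.
    """
    if reps < 100:
        raise ValueError("need at least 100 replicates")
    rng = np.random.default_rng(seed)
    a = rng.normal(effect_d, 1.0, size=(reps, n_per_group))
    b = rng.normal(0.0, 1.0, size=(reps, n_per_group))
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sp = np.sqrt((va + vb) / 2.0)
    t = (a.mean(axis=1) - b.mean(axis=1)) / (sp * np.sqrt(2.0 / n_per_group))
    df = 2 * n_per_group - 2
    tcrit = sps.t.ppf(1 - alpha / 2.0, df)
    return float(np.mean(np.abs(t) > tcrit))
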