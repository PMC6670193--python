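"""Disease-association statistics for CAGs.

The testing framework is a two-stage discovery/validation design on
compositional abundance data:

1.  CAG relative abundances are mapped through the centered log-ratio
    (CLR) transform, ``clr(x)_i = log x_i - mean_j log x_j`` per sample,
    which addresses the closure constraint of relative abundances (a
    genuine decrease of much of the community would otherwise masquerade
    as an increase of the remainder).
2.  Per CAG, the mean CLR difference between samples from subjects with
    and without disease is tested in the general linear model framework;
    cohorts with repeated measures on subjects use a linear mixed model
    with a subject random intercept.  The healthy indicator is the
    regressor, so positive coefficients mean more abundant in health.
3.  Storey q-values control the FDR; CAGs with q <= 0.2 in the discovery
    cohort are "discovered", and of those, CAGs with q <= 0.2 (q-values
    recomputed within the discovered subset) and the same coefficient
    sign in an independent validation cohort are "validated".
4.  A conservative p-value for the global null of no association at all
    comes from the sign-agreement bound: if C2 of C1 discovered CAGs
    keep their coefficient sign in validation, then under the global
    null Pr(X >= C2) <= Pr(Binomial(C1, 1/2) >= C2), since each sign
    agreement is then a fair coin flip.

Helpers for the single-gene comparison (one random representative per
CAG) and Fisher / Holm-Sidak annotation enrichment round out the module.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import UnivariateSpline
from scipy.special import gammaln, logsumexp
from scipy.stats import fisher_exact, norm
from statsmodels.stats.multitest import multipletests

from .containers import CAGCatalog, AnnotationTable, ParameterError, SampleMetadata
from .cluster import CAGAbundanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "clr_transform",
    "fit_cag_association",
    "estimate_qvalues",
    "discover",
    "validate",
    "DiscoveryValidationReport",
    "SignAgreementBound",
    "sign_agreement_pvalue",
    "select_representative_genes",
    "annotation_enrichment",
    "sign_summary",
]

Q_THRESHOLD = 0.2  # FDR target of the discovery/validation design


# ---------------------------------------------------------------------------
# CLR transform


def clr_transform(
    abundance: CAGAbundanceMatrix | pd.DataFrame,
    pseudocount_policy: str = "half-min",
) -> pd.DataFrame:
    """Centered log-ratio transform, features x samples.

    Zeros are replaced per sample before taking logs.  ``"half-min"``
    (default) substitutes half the smallest nonzero value in that sample,
    the standard multiplicative replacement for compositional zeros.
    Output columns sum to zero (defining property of the CLR).
    """
    values = abundance.values if isinstance(abundance, CAGAbundanceMatrix) else abundance
    if values.shape[0] < 2:
        raise ParameterError("CLR requires at least 2 features")
    arr = values.to_numpy(dtype=float).copy()
    if (arr < 0).any():
        raise ParameterError("CLR requires nonnegative abundances")
    if pseudocount_policy != "half-min":
        raise ParameterError(f"unknown pseudocount policy {pseudocount_policy!r}")
    for j in range(arr.shape[1]):
        col = arr[:, j]
        nz = col[col > 0]
        if nz.size == 0:
            raise ParameterError(
                f"sample {values.columns[j]!r} has all-zero abundances"
            )
        col[col == 0] = nz.min() / 2.0
    logs = np.log(arr)
    clr = logs - logs.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=values.index, columns=values.columns)


# ---------------------------------------------------------------------------
# per-CAG association models


def _fit_one(
    y: np.ndarray, healthy: np.ndarray, subjects: np.ndarray | None
) -> tuple[float, float, float, str]:
    """Coefficient of the healthy indicator, its SE, Wald p, model kind."""
    X = sm.add_constant(healthy.astype(float))
    if subjects is None:
        res = sm.OLS(y, X).fit()
        coef, se, p = res.params[1], res.bse[1], res.pvalues[1]
        kind = "fixed"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.MixedLM(y, X, groups=subjects).fit(reml=True)
                coef, se, p = res.params[1], res.bse[1], res.pvalues[1]
            except (np.linalg.LinAlgError, ValueError):
                return np.nan, np.nan, np.nan, "mixed"
        kind = "mixed"
    scale = max(1.0, float(np.max(np.abs(y))))
    if not np.isfinite(se) or se <= 1e-12 * scale:
        # degenerate fit: identical responses give coef 0 and no evidence
        p = 1.0 if abs(coef) <= 1e-12 * scale else 0.0
    return float(coef), float(se), float(p), kind


def fit_cag_association(
    clr: pd.DataFrame, meta: SampleMetadata, model: str = "auto"
) -> pd.DataFrame:
    """Per-CAG disease association from CLR abundances.

    Returns a frame indexed by CAG with columns ``estimate`` (CLR
    difference associated with health: positive = more abundant in
    healthy subjects), ``se``, ``p`` (two-sided Wald), and ``model``.
    ``model="auto"`` uses a linear mixed model with a subject random
    intercept when any subject contributed more than one sample, and
    ordinary least squares otherwise.  CAGs whose fit fails are returned
    with missing p (and are excluded from q-value estimation downstream).
    """
    if model not in ("auto", "fixed", "mixed"):
        raise ParameterError(f"unknown model {model!r}")
    table = meta.table.loc[clr.columns]
    status = table["status"].to_numpy()
    healthy = 1 - status  # positive coefficient = more abundant in health
    if (status == 1).sum() < 2 or (status == 0).sum() < 2:
        raise ParameterError("need at least 2 samples in each disease group")
    use_mixed = model == "mixed" or (model == "auto" and meta.repeated_measures())
    subjects = table["subject"].to_numpy() if use_mixed else None

    rows = [
        _fit_one(clr.loc[cag].to_numpy(dtype=float), healthy, subjects)
        for cag in clr.index
    ]
    out = pd.DataFrame(
        rows, index=clr.index, columns=["estimate", "se", "p", "model"]
    )
    out.index.name = clr.index.name or "cag"
    n_failed = int(out["p"].isna().sum())
    if n_failed:
        logger.warning("%d of %d CAG fits were singular", n_failed, len(out))
    return out


# ---------------------------------------------------------------------------
# Storey q-values


def _storey_pi0(p: np.ndarray) -> float:
    """Smoother estimate of the null proportion pi0.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over a lambda grid,
    smoothed with a cubic smoothing spline and read off at the largest
    lambda, then clamped to (0, 1].
    """
    lam = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([(p > l).mean() / (1.0 - l) for l in lam])
    spline = UnivariateSpline(lam, pi0_lam, k=3)
    pi0 = float(spline(lam[-1]))
    return float(min(1.0, max(pi0, 1e-4)))


def estimate_qvalues(pvalues, pi0: float | None = None) -> np.ndarray:
    """Storey q-values (pi0 by the smoother method).

    ``q_(i) = min_{j >= i} pi0 * m * p_(j) / j`` over the sorted
    p-values, so q is monotone nondecreasing in p.  With fewer than 10
    p-values the pi0 estimate is unstable and the function falls back to
    Benjamini-Hochberg (pi0 = 1) with a warning.  Forcing ``pi0=1``
    reproduces BH exactly.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ParameterError("p-values must be one-dimensional")
    if np.isnan(p).any():
        raise ParameterError("missing p-values must be excluded before q-values")
    if ((p < 0) | (p > 1)).any():
        raise ParameterError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    if pi0 is None:
        if m < 10:
            warnings.warn(
                "fewer than 10 p-values: pi0 estimation is unstable, "
                "falling back to Benjamini-Hochberg (pi0 = 1)",
                stacklevel=2,
            )
            pi0 = 1.0
        else:
            pi0 = _storey_pi0(p)
    if not 0 < pi0 <= 1:
        raise ParameterError("pi0 must be in (0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# discovery / validation


def discover(results: pd.DataFrame, q_threshold: float = Q_THRESHOLD) -> list:
    """CAGs significant at the FDR target: q <= threshold (inclusive)."""
    if len(results) == 0 or "q" not in results.columns:
        return []
    hits = results.index[results["q"] <= q_threshold]
    return hits.tolist()


def add_qvalues(results: pd.DataFrame, pi0: float | None = None) -> pd.DataFrame:
    """Attach a ``q`` column (missing p-values get missing q)."""
    out = results.copy()
    ok = results["p"].notna()
    q = np.full(len(results), np.nan)
    q[ok.to_numpy()] = estimate_qvalues(results.loc[ok, "p"].to_numpy(), pi0=pi0)
    out["q"] = q
    return out


@dataclass
class SignAgreementBound:
    """Conservative global-null p-value from sign agreement counts.

    ``p_exact`` is Pr(Binomial(C1, 1/2) >= C2) computed in log space;
    ``p_normal`` is the printed normal approximation
    Pr(Normal(0,1) >= (C2 - C1/2) / sqrt(C1/2)).  Both are reported with
    their base-10 logarithms, which remain informative when the p-values
    underflow double precision.  Callers should report the exact bound.
    """

    c1: int
    c2: int
    p_exact: float
    log10_p_exact: float
    p_normal: float
    log10_p_normal: float


def sign_agreement_pvalue(c1: int, c2: int) -> SignAgreementBound:
    """Bound the global-null p-value for validating C2 of C1 sign matches.

    Under the global null each discovered CAG keeps its coefficient sign
    in the validation cohort with probability 1/2 independently, so
    Pr(#agreements >= C2) = Pr(Binomial(C1, 1/2) >= C2) bounds the
    probability of the observed validation outcome from above.
    """
    if c1 < 1:
        raise ParameterError("C1 must be at least 1")
    if not 0 <= c2 <= c1:
        raise ParameterError("C2 must satisfy 0 <= C2 <= C1")
    k = np.arange(c2, c1 + 1)
    log_terms = gammaln(c1 + 1) - gammaln(k + 1) - gammaln(c1 - k + 1) - c1 * np.log(2.0)
    log_p = float(min(logsumexp(log_terms), 0.0))
    z = (c2 - c1 / 2.0) / np.sqrt(c1 / 2.0)
    log_p_norm = float(norm.logsf(z))
    return SignAgreementBound(
        c1=int(c1),
        c2=int(c2),
        p_exact=float(np.exp(log_p)),
        log10_p_exact=log_p / np.log(10.0),
        p_normal=float(np.exp(log_p_norm)),
        log10_p_normal=log_p_norm / np.log(10.0),
    )


@dataclass
class DiscoveryValidationReport:
    """Outcome of the two-stage design.

    ``c1`` is the number of discovered CAGs tested in validation, ``c2``
    the number whose coefficient kept its sign; ``bound`` carries the
    conservative global-null p-value.  ``table`` holds per-discovered-CAG
    validation estimates, within-subset q-values, and flags.
    """

    discovered: list
    validated: list
    c1: int
    c2: int
    bound: SignAgreementBound | None
    table: pd.DataFrame

    @property
    def p_global_null(self) -> float:
        return self.bound.p_exact if self.bound is not None else 1.0


def validate(
    discovered: list,
    discovery_results: pd.DataFrame,
    validation_results: pd.DataFrame,
    q_threshold: float = Q_THRESHOLD,
) -> DiscoveryValidationReport:
    """Test discovered CAGs in the validation cohort.

    q-values are recomputed within the discovered subset only (only
    those hypotheses are carried forward).  A CAG validates if its
    within-subset q <= threshold and its validation coefficient has the
    same sign as its discovery coefficient.  Sign agreement over all
    testable discovered CAGs yields the conservative global-null bound.
    """
    discovered = list(discovered)
    missing = [c for c in discovered if c not in validation_results.index]
    if missing:
        raise ParameterError(
            f"discovered CAGs missing from validation results: {missing[:5]}"
        )
    sub = validation_results.loc[discovered].copy()
    d_est = discovery_results.loc[discovered, "estimate"]
    testable = sub["p"].notna() & sub["estimate"].notna() & d_est.notna()

    q = np.full(len(sub), np.nan)
    if testable.any():
        q[testable.to_numpy()] = estimate_qvalues(
            sub.loc[testable, "p"].to_numpy()
        )
    sub["q"] = q
    agree = (
        np.sign(sub["estimate"]) == np.sign(d_est)
    ) & testable
    sub["sign_agrees"] = agree
    sub["validated"] = (sub["q"] <= q_threshold) & agree

    c1 = int(testable.sum())
    c2 = int(agree.sum())
    bound = sign_agreement_pvalue(c1, c2) if c1 >= 1 else None
    return DiscoveryValidationReport(
        discovered=discovered,
        validated=sub.index[sub["validated"]].tolist(),
        c1=c1,
        c2=c2,
        bound=bound,
        table=sub,
    )


# ---------------------------------------------------------------------------
# single-gene comparison and annotation enrichment


def select_representative_genes(catalog: CAGCatalog, seed: int = 0) -> pd.Series:
    """One uniformly random member gene per CAG (deterministic given seed).

    Re-running the association pipeline on these genes instead of CAG
    abundances gives the unclustered gene-level comparison.
    """
    if len(catalog) == 0:
        raise ParameterError("catalog is empty")
    rng = np.random.default_rng(seed)
    chosen = {}
    for cag_id in np.sort(catalog.gene_to_cag.unique()):
        members = sorted(catalog.members(int(cag_id)))
        chosen[int(cag_id)] = members[rng.integers(len(members))]
    out = pd.Series(chosen, name="gene")
    out.index.name = "cag"
    return out


def annotation_enrichment(
    target_genes,
    background_genes,
    annotations: AnnotationTable,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Fisher exact enrichment of labels in a target gene set.

    For each label occurring in the background, builds the 2x2 table of
    (in/out of target) x (has/lacks label), computes the two-sided Fisher
    exact p, and applies the Holm-Sidak multiple-testing procedure at
    family-wise level ``alpha``.  Returns one row per label with the
    table counts, odds ratio, p, adjusted p, and significance flag.
    """
    target = set(map(str, target_genes))
    background = set(map(str, background_genes))
    if not target <= background:
        raise ParameterError("target gene set must be a subset of the background")
    if not background:
        raise ParameterError("background gene set is empty")

    label_genes: dict[str, set[str]] = {}
    for gene in background:
        for label in annotations.get(gene):
            label_genes.setdefault(label, set()).add(gene)
    orphan = annotations.all_labels() - set(label_genes)
    if orphan:
        logger.warning(
            "%d labels absent from the background were skipped", len(orphan)
        )
    if not label_genes:
        return pd.DataFrame(
            columns=["a", "b", "c", "d", "odds_ratio", "p", "p_adjusted", "significant"]
        )

    rows = []
    n_target, n_bg = len(target), len(background)
    for label in sorted(label_genes):
        with_label = label_genes[label]
        a = len(target & with_label)          # target, has label
        b = n_target - a                      # target, lacks label
        c = len(with_label) - a               # non-target, has label
        d = (n_bg - n_target) - c             # non-target, lacks label
        odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append((label, a, b, c, d, odds, p))
    out = pd.DataFrame(
        rows, columns=["label", "a", "b", "c", "d", "odds_ratio", "p"]
    ).set_index("label")
    with np.errstate(divide="ignore"):  # p = 1 gives log1p(-1) internally
        reject, p_adj, _, _ = multipletests(
            out["p"].to_numpy(), alpha=alpha, method="holm-sidak"
        )
    out["p_adjusted"] = p_adj
    out["significant"] = reject
    return out


def sign_summary(results: pd.DataFrame) -> float:
    """Fraction of tested CAGs with a positive (health-associated) coefficient."""
    est = results["estimate"].dropna()
    if len(est) == 0:
        raise ParameterError("no tested CAGs")
    return float((est > 0).mean())
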