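"""Single-variant association, carrier enrichment, and carrier demographics.

Per-variant association is an additive-dosage logistic regression of
case/control status on dosage plus sex, age, and ten principal components,
reporting the Wald odds ratio, 95% confidence interval, and p-value.
Separation or near-singular information is flagged (``converged=False``)
rather than corrected: extreme Wald intervals are reported as such, with a
crude allelic odds ratio as a fallback.  Complete-case analysis throughout.

Carrier enrichment uses a one-sided Fisher exact test on the 2x2
carrier/non-carrier x case/control table, reporting the conditional-MLE
odds ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from sorlscan.types import GenotypeMatrix, SampleRecord


@dataclass
class AssociationResult:
    variant_key: str
    effect_allele: str
    or_point: float
    ci_low: float
    ci_high: float
    p: float
    f_a: float
    f_u: float
    converged: bool
    bonferroni_threshold: float | None = None
    skip_reason: str | None = None

    def __post_init__(self):
        if self.converged and not (self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError(f"{self.variant_key}: CI does not bracket the point estimate")


@dataclass
class CarrierSummary:
    n_carriers: int
    n_family_history_yes: int
    n_family_history_no: int
    n_family_history_unknown: int
    pct_family_history: float
    n_with_aao: int
    n_late_onset: int
    pct_late_onset: float
    pct_female: float
    mean_age: float


def _pct(count: int, denom: int) -> float:
    """Percentage to one decimal, 0.0 for an empty denominator."""
    return round(100.0 * count / denom, 1) if denom else 0.0


def build_covariate_matrix(samples: list[SampleRecord]) -> np.ndarray:
    """Intercept + sex + age + PC1..PC10 design columns."""
    X = np.column_stack(
        [
            np.ones(len(samples)),
            [s.sex for s in samples],
            [s.age_years for s in samples],
            np.array([s.pcs for s in samples]),
        ]
    )
    for name, col in zip(["sex", "age"], [X[:, 1], X[:, 2]]):
        if np.all(np.isnan(col)):
            raise ValueError(f"covariate {name!r} is entirely missing")
    return X


def _allelic_or(f_a: float, f_u: float) -> float:
    # crude allelic odds ratio with 0/1 guards
    if f_u in (0.0,) or f_a in (1.0,):
        return math.inf
    if f_a == 0.0 or f_u == 1.0:
        return 0.0
    return (f_a / (1 - f_a)) / (f_u / (1 - f_u))


def logistic_assoc(
    matrix: GenotypeMatrix,
    samples: list[SampleRecord],
    separation_logor: float = 10.0,
) -> list[AssociationResult]:
    """Covariate-adjusted per-variant logistic association.

    Fits one maximum-likelihood logistic model per variant on complete-case
    rows.  Monomorphic variants are skipped with reason ``monomorphic``.
    Non-convergence, quasi-separation (|log OR| above
    ``separation_logor``), or a near-singular information matrix yields
    ``converged=False`` with the crude allelic odds ratio as the point
    estimate.
    """
    by_id = {s.sample_id: s for s in samples}
    kept = [s for s in matrix.sample_ids if s in by_id]
    recs = [by_id[s] for s in kept]
    y_all = np.array([1.0 if r.is_case else 0.0 for r in recs])
    if len(set(y_all)) < 2:
        raise ValueError("need both cases and controls")
    X_all = build_covariate_matrix(recs)
    idx = matrix.sample_indices(kept)
    results = []
    for j, key in enumerate(matrix.variant_keys):
        dose = matrix.dosages[idx, j]
        mask = ~np.isnan(dose) & ~np.isnan(X_all).any(axis=1)
        d, y, X = dose[mask], y_all[mask], X_all[mask]
        f_a = d[y == 1].sum() / (2 * (y == 1).sum()) if (y == 1).any() else 0.0
        f_u = d[y == 0].sum() / (2 * (y == 0).sum()) if (y == 0).any() else 0.0
        alt = key.split(":")[3]
        if np.all(d == d[0]) if d.size else True:
            results.append(
                AssociationResult(
                    key, alt, math.nan, math.nan, math.nan, math.nan,
                    f_a, f_u, converged=False, skip_reason="monomorphic",
                )
            )
            continue
        design = np.column_stack([d, X])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            beta, se = fit.params[0], fit.bse[0]
            singular = not np.isfinite(se) or se <= 0
            converged = bool(fit.mle_retvals.get("converged", False))
        except Exception:
            beta, se, singular, converged = math.nan, math.nan, True, False
        flagged = (not converged) or singular or abs(beta) > separation_logor
        if flagged:
            crude = _allelic_or(f_a, f_u)
            results.append(
                AssociationResult(
                    key, alt, crude, math.nan, math.nan, math.nan,
                    f_a, f_u, converged=False, skip_reason="separation-or-nonconvergence",
                )
            )
            continue
        z = beta / se
        p = 2 * stats.norm.sf(abs(z))
        lo, hi = math.exp(beta - 1.959963984540054 * se), math.exp(beta + 1.959963984540054 * se)
        results.append(
            AssociationResult(key, alt, math.exp(beta), lo, hi, p, f_a, f_u, converged=True)
        )
    m_tested = sum(1 for r in results if r.skip_reason is None)
    thr = bonferroni_threshold(m_tested) if m_tested else None
    for r in results:
        r.bonferroni_threshold = thr
    return results


def bonferroni_threshold(m: int) -> float:
    """Per-stratum multiple-testing threshold, alpha = 0.05 / m."""
    if m < 1:
        raise ValueError(f"need at least one tested variant, got {m}")
    return 0.05 / m


def fisher_carrier_enrichment(
    k_case: int, n_case: int, k_ctrl: int, n_ctrl: int
) -> tuple[float, float]:
    """One-sided Fisher exact test for carrier excess in cases.

    ``k`` are carrier counts, ``n`` sample totals.  Returns ``(p,
    conditional-MLE odds ratio)``; the alternative is greater-in-cases.
    """
    if n_case <= 0 or n_ctrl <= 0:
        raise ValueError("both groups must be non-empty")
    if not (0 <= k_case <= n_case and 0 <= k_ctrl <= n_ctrl):
        raise ValueError("carrier counts must lie in [0, n]")
    table = [[k_case, n_case - k_case], [k_ctrl, n_ctrl - k_ctrl]]
    _, p = stats.fisher_exact(table, alternative="greater")
    or_cmle = stats.contingency.odds_ratio(table, kind="conditional").statistic
    return float(p), float(or_cmle)


def summarize_carriers(carriers: list[SampleRecord], aao_cutoff: float) -> CarrierSummary:
    """Demographics of a carrier set.

    Family-history percentage is over all carriers; onset percentages are
    over carriers with age-at-onset available.  Late onset means AAO >=
    ``aao_cutoff`` (50 years is the convention for Parkinson's disease, 65
    for Alzheimer's disease and Lewy body dementia).
    """
    if not carriers:
        raise ValueError("carrier set is empty")
    n = len(carriers)
    fh = [c.family_history for c in carriers]
    n_yes, n_no = fh.count("yes"), fh.count("no")
    with_aao = [c for c in carriers if c.aao_years is not None]
    n_late = sum(1 for c in with_aao if c.aao_years >= aao_cutoff)
    return CarrierSummary(
        n_carriers=n,
        n_family_history_yes=n_yes,
        n_family_history_no=n_no,
        n_family_history_unknown=fh.count("unknown"),
        pct_family_history=_pct(n_yes, n),
        n_with_aao=len(with_aao),
        n_late_onset=n_late,
        pct_late_onset=_pct(n_late, len(with_aao)),
        pct_female=_pct(sum(1 for c in carriers if c.sex == 2), n),
        mean_age=float(np.mean([c.age_years for c in carriers])),
    )


def render_association_report(results: list[AssociationResult]) -> str:
    """Tab-separated association table (one row per tested variant)."""
    lines = ["variant\tA1\tP\tOR_L95_U95\tbonferroni_threshold\tF_A\tF_U\tconverged"]
    for r in results:
        if r.skip_reason == "monomorphic":
            continue
        if r.converged:
            or_s = f"{r.or_point:.2f} ({r.ci_low:.2f}-{r.ci_high:.2f})"
            p_s = f"{r.p:.3g}"
        else:
            or_s = f"{r.or_point:.2f} (crude)" if math.isfinite(r.or_point) else "NA"
            p_s = "NA"
        thr = f"{r.bonferroni_threshold:.2E}" if r.bonferroni_threshold else "NA"
        lines.append(
            f"{r.variant_key}\t{r.effect_allele}\t{p_s}\t{or_s}\t{thr}\t"
            f"{r.f_a:.3g}\t{r.f_u:.3g}\t{r.converged}"
        )
    return "\n".join(lines) + "\n"
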