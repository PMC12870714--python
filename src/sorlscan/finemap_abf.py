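"""Single-causal-variant fine-mapping from summary statistics.

Evidence for association at each variant is the approximate Bayes factor
computed from the marginal effect estimate and its standard error under a
Normal(0, W^2) effect prior:

    log ABF = 0.5 * log(V / (V + W^2)) + 0.5 * z^2 * W^2 / (V + W^2)

with V = se^2 and z = beta / se.  Assuming at most one causal variant in
the region, each variant carries prior odds p1 against the null, so the
posterior mass is proportional to p1 * ABF_k per variant and to 1 for the
no-association model; probabilities are normalized to sum to one.  The
defaults (p1 = 1e-4, W = 0.2 for case-control traits) are the conventional
single-trait choices.

A decision is reported against a 0.6 posterior threshold on both sides:
``causal-candidate`` when one variant's posterior exceeds it,
``null-favored`` when the null model's posterior exceeds it, otherwise
``inconclusive``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from sorlscan.types import SummaryStat


@dataclass
class FineMapResult:
    variant_keys: list
    log_abf: np.ndarray
    pp: np.ndarray
    pp_null: float
    lead_variant: str
    decision: str  # causal-candidate | null-favored | inconclusive

    def __post_init__(self):
        total = self.pp_null + float(np.sum(self.pp))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posterior mass {total} != 1")


def wakefield_log_abf(beta: float, se: float, prior_sd: float = 0.2) -> float:
    """Log approximate Bayes factor (association vs null) for one variant."""
    if not (math.isfinite(beta) and math.isfinite(se) and math.isfinite(prior_sd)):
        raise ValueError("non-finite input")
    if se <= 0 or prior_sd <= 0:
        raise ValueError("se and prior_sd must be positive")
    V = se * se
    W2 = prior_sd * prior_sd
    z = beta / se
    return 0.5 * math.log(V / (V + W2)) + 0.5 * z * z * W2 / (V + W2)


def finemap_region(
    stats: list[SummaryStat],
    p1: float = 1e-4,
    prior_sd: float = 0.2,
    pp_threshold: float = 0.6,
) -> FineMapResult:
    """Posterior probabilities over single-causal-variant configurations.

    Returns per-variant posteriors plus the posterior on the
    no-association model; the three-way ``decision`` compares both against
    ``pp_threshold``.
    """
    if len(stats) < 2:
        raise ValueError("need at least 2 variants to fine-map a region")
    if not (0 < p1 < 1):
        raise ValueError("p1 must lie in (0, 1)")
    keys = [s.variant_key for s in stats]
    log_abf = np.array([wakefield_log_abf(s.beta, s.se, prior_sd) for s in stats])
    if not np.isfinite(log_abf).any():
        raise ValueError("all approximate Bayes factors are non-finite")
    # log posterior weights: null gets log(1); variant k gets log(p1)+logABF_k
    log_w = np.concatenate([[0.0], math.log(p1) + log_abf])
    log_total = logsumexp(log_w)
    post = np.exp(log_w - log_total)
    pp_null = float(post[0])
    pp = post[1:]
    # exact renormalization so the invariant holds to 1e-9
    scale = pp_null + pp.sum()
    pp_null /= scale
    pp /= scale
    lead = keys[int(np.argmax(pp))]
    if pp.max() > pp_threshold:
        decision = "causal-candidate"
    elif pp_null > pp_threshold:
        decision = "null-favored"
    else:
        decision = "inconclusive"
    return FineMapResult(keys, log_abf, pp, pp_null, lead, decision)


def render_finemap_report(result: FineMapResult, stats: list[SummaryStat]) -> str:
    """Tab-separated table: variant, z, log ABF, posterior probability."""
    lines = ["variant\tz\tlog_abf\tpp"]
    for s, labf, pp in zip(stats, result.log_abf, result.pp):
        lines.append(f"{s.variant_key}\t{s.z:.3f}\t{labf:.4f}\t{pp:.6g}")
    lines.append(f"# pp_null\t{result.pp_null:.6g}")
    lines.append(f"# decision\t{result.decision}")
    lines.append(f"# lead_variant\t{result.lead_variant}")
    return "\n".join(lines) + "\n"
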