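"""Fixed-effect inverse-variance meta-analysis and bootstrap ratio summaries.

Per-cohort slopes are pooled with weights 1/se^2 (pooled se =
1/sqrt(sum of weights)); per-bin trait means are pooled the same way bin
by bin; and unitless ratios of paired effect estimates (for example the
within-sibling slope over the population slope, across many traits) are
summarised by a parametric bootstrap — each estimate is redrawn from its
normal sampling distribution, which is all that summary statistics allow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import EffectEstimate


@dataclass
class MetaResult:
    """Pooled fixed-effect estimate over k cohorts."""

    beta: float
    se: float
    z: float
    p: float
    k: int
    q_het: float         # Cochran's Q, descriptive only
    model_tag: str = ""
    trait: str = ""

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("meta-analysis needs at least one estimate")


@dataclass
class RatioSummary:
    """Bootstrap median and percentile CI of a ratio of effect estimates."""

    median: float
    lo95: float
    hi95: float
    reps: int
    seed: int
    median_weighted: float = np.nan    # precision-weighted variant

    def __post_init__(self) -> None:
        if not self.lo95 <= self.median <= self.hi95:
            raise ValueError("bootstrap CI does not bracket the median")


def ivw_meta(estimates: list[EffectEstimate]) -> MetaResult:
    """Fixed-effect inverse-variance pooling of same-class estimates."""
    if not estimates:
        raise ValueError("empty estimate list")
    tags = {e.model_tag for e in estimates}
    traits = {e.trait for e in estimates}
    if len(tags) > 1 or len(traits) > 1:
        raise ValueError(f"mixed estimate classes: tags={tags}, traits={traits}")
    beta = np.array([e.beta for e in estimates])
    se = np.array([e.se for e in estimates])
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se ** 2
    pooled = float(np.sum(w * beta) / np.sum(w))
    pooled_se = float(1.0 / np.sqrt(np.sum(w)))
    z = pooled / pooled_se
    p = 2.0 * stats.norm.sf(abs(z))
    q = float(np.sum(w * (beta - pooled) ** 2))
    return MetaResult(pooled, pooled_se, float(z), float(p), len(estimates), q,
                      model_tag=tags.pop(), trait=traits.pop())


def meta_bins(cohort_bins: list[pd.DataFrame]) -> pd.DataFrame:
    """IVW pooling of per-bin intercept-referenced trait means.

    All cohorts must have used the canonical bin bounds; a bin that is
    empty in some cohorts is pooled from the cohorts that populate it.
    """
    if not cohort_bins:
        raise ValueError("no bin summaries")
    ref = cohort_bins[0][["bin", "lo", "hi"]]
    for df in cohort_bins[1:]:
        if not np.allclose(df[["lo", "hi"]].to_numpy(),
                           ref[["lo", "hi"]].to_numpy()):
            raise ValueError("cohorts used different bin bounds")
    rows = []
    for b in ref["bin"]:
        subs = [df[df["bin"] == b].iloc[0] for df in cohort_bins]
        subs = [r for r in subs if r["n"] > 1 and np.isfinite(r["se_resid"])
                and r["se_resid"] > 0]
        if not subs:
            rows.append((b, np.nan, np.nan, np.nan, np.nan, 0, 0))
            continue
        wr = np.array([1.0 / r["se_resid"] ** 2 for r in subs])
        mr = np.array([r["mean_resid"] for r in subs])
        wf = np.array([1.0 / r["se_f"] ** 2 if np.isfinite(r["se_f"]) and r["se_f"] > 0
                       else np.nan for r in subs])
        mf = np.array([r["mean_f"] for r in subs])
        okf = np.isfinite(wf)
        pooled_f = float(np.sum(wf[okf] * mf[okf]) / np.sum(wf[okf])) if okf.any() \
            else float(np.mean(mf))
        se_f = float(1.0 / np.sqrt(np.sum(wf[okf]))) if okf.any() else np.nan
        rows.append((b, pooled_f, se_f,
                     float(np.sum(wr * mr) / np.sum(wr)),
                     float(1.0 / np.sqrt(np.sum(wr))),
                     int(sum(r["n"] for r in subs)), len(subs)))
    return pd.DataFrame(rows, columns=["bin", "mean_f", "se_f", "mean_resid",
                                       "se_resid", "n", "k"])


def ratio_bootstrap(numerators: list[EffectEstimate],
                    denominators: list[EffectEstimate],
                    reps: int = 10_000, seed: int = 0) -> RatioSummary:
    """Parametric-bootstrap median and 95% CI of paired effect ratios.

    ``numerators`` and ``denominators`` are paired by position (one pair
    per trait).  Each replicate redraws every estimate from
    N(beta, se^2), forms the per-trait ratios and pools them across
    traits; the reported median and percentile bounds summarise the
    pooled replicate distribution.  Both an unweighted (median across
    traits, the default summary) and a precision-weighted pooling are
    computed.  Denominators with appreciable mass near zero make the
    ratio unstable and are flagged.
    """
    if len(numerators) != len(denominators):
        raise ValueError("numerator and denominator lists must pair by trait")
    if reps < 1000:
        raise ValueError("use at least 1000 bootstrap replicates")
    rng = np.random.default_rng(seed)
    nb = np.array([e.beta for e in numerators])
    ns = np.array([e.se for e in numerators])
    db = np.array([e.beta for e in denominators])
    ds = np.array([e.se for e in denominators])
    if np.any(np.abs(db) < 2 * ds):
        import warnings
        warnings.warn("denominator effect within 2 se of zero; ratio unstable")
    num = rng.normal(nb, ns, size=(reps, len(nb)))
    den = rng.normal(db, ds, size=(reps, len(db)))
    ratios = num / den
    pooled = np.median(ratios, axis=1)
    wt = 1.0 / (ns ** 2 / db ** 2 + nb ** 2 * ds ** 2 / db ** 4)   # delta-method
    pooled_w = (ratios * wt).sum(axis=1) / wt.sum()
    lo, med, hi = np.percentile(pooled, [2.5, 50.0, 97.5])
    return RatioSummary(float(med), float(lo), float(hi), reps, seed,
                        median_weighted=float(np.median(pooled_w)))


def meta_table(results: list[MetaResult]) -> pd.DataFrame:
    """Long-format pooled-results table (forest-plot ready)."""
    return pd.DataFrame(
        [(r.trait, r.model_tag, r.beta, r.se, r.z, r.p, r.k, r.q_het)
         for r in results],
        columns=["trait", "model_tag", "beta", "se", "z", "p", "k", "q_het"])
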