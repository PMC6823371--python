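"""Per-cohort effect-size estimation for inbreeding-depression models.

The sequence mirrors how a cohort analysis runs: traits are first
residualized on fixed covariates (optionally with a mixed-model step that
removes polygenic family structure via REML/BLUP on a genomic relationship
matrix), then the residuals are regressed on one or more homozygosity
estimators — univariate, partitioned by ROH length class, bivariate, for
binary traits on the ln(odds-ratio) scale, within fixed F_ROH bins, and
within full-sibling families where Mendelian segregation makes the
estimator immune to all between-family confounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar

#: canonical F_ROH bin bounds shared by all cohorts
BIN_BOUNDS = (0.0, 0.002, 0.0041, 0.0067, 0.0108, 0.0186, 0.0333,
              0.06, 0.10, 0.18, 1.0)

#: convenience scale: effect at the autozygosity expected in offspring of
#: first cousins
FIRST_COUSIN_F = 0.0625

MODEL_TAGS = ("uni_froh", "uni_fsnp", "uni_fgrm",
              "part_outside", "part_lt5", "part_gt5",
              "biv_froh", "biv_fgrm",
              "binary_logit", "binary_linapprox",
              "within_sibs", "by_sex_male", "by_sex_female")


@dataclass
class EffectEstimate:
    """One (cohort, trait, model) slope with its standard error."""

    beta: float
    se: float
    n: int
    model_tag: str
    trait: str = ""
    cohort: str = ""
    mu: float = 0.0              # fitted intercept, used for bin referencing
    n_params: int = 2
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        # se = 0 only arises on degenerate exact fits; negative is a bug
        if self.se < 0 or (np.isnan(self.se) and "collinear" not in self.flags):
            raise ValueError("standard error must be non-negative")
        if self.n < self.n_params + 1:
            raise ValueError("too few samples for the model size")

    @property
    def beta_0625(self) -> float:
        """Effect at first-cousin-offspring autozygosity."""
        return FIRST_COUSIN_F * self.beta


@dataclass
class ResidualTrait:
    """Covariate-adjusted trait residuals with the fitted intercept."""

    residuals: np.ndarray
    mu: float
    design: str = "intercept"


@dataclass
class Sibship:
    """One full-sibling family inferred from pairwise relatedness."""

    family_id: str
    members: list[str]
    has_mz_like: bool = False
    flagged: bool = False


# ---------------------------------------------------------------------------
# Residualization
# ---------------------------------------------------------------------------

def _as_design(X) -> tuple[np.ndarray, list[str]]:
    if X is None:
        raise ValueError("covariate design must at least contain an intercept")
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


def residualize(y, X) -> ResidualTrait:
    """OLS residuals of a trait on its fixed covariates.

    ``X`` must be full rank and include a constant column; collinear
    columns are named in the error.
    """
    y = np.asarray(y, dtype=float)
    Xm, names = _as_design(X)
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        bad = []
        kept: list[int] = []
        for j in range(Xm.shape[1]):
            if np.linalg.matrix_rank(Xm[:, kept + [j]]) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"rank-deficient covariate design; collinear: {bad}")
    b, *_ = np.linalg.lstsq(Xm, y, rcond=None)
    resid = y - Xm @ b
    const = [j for j in range(Xm.shape[1]) if np.allclose(Xm[:, j], Xm[0, j])
             and Xm[0, j] != 0]
    mu = float(b[const[0]] * Xm[0, const[0]]) if const else 0.0
    return ResidualTrait(resid, mu, design=",".join(names))


def grammar_residuals(y, X, grm: np.ndarray, calibration: float = 1.0,
                      tol: float = 1e-8) -> tuple[ResidualTrait, dict]:
    """Mixed-model residuals y - Xb - u on a genomic relationship matrix.

    The polygenic variance ratio lambda = sigma_g^2 / sigma_e^2 is found
    by restricted maximum likelihood on the eigenrotated model (the GRM
    is eigendecomposed once, making each likelihood evaluation O(n)); the
    polygenic values u are their best linear unbiased predictions at the
    REML solution.  With ``grm`` = I, or at lambda = 0, this collapses to
    ordinary least squares.  ``calibration`` rescales the residuals
    (conventionally used to restore test-statistic calibration after BLUP
    shrinkage); the default leaves them untouched.

    Returns the residual trait plus a dict with sigma_g2, sigma_e2,
    lambda and the REML log-likelihood.
    """
    y = np.asarray(y, dtype=float)
    Xm, names = _as_design(X)
    grm = np.asarray(grm, dtype=float)
    if grm.shape != (len(y), len(y)):
        raise ValueError("GRM shape does not match the sample count")
    if not np.allclose(grm, grm.T, atol=1e-8):
        raise ValueError("GRM must be symmetric")
    d, U = np.linalg.eigh(grm)
    if d.min() < -1e-6 * max(1.0, abs(d.max())):
        raise ValueError(f"GRM not positive semi-definite (min eigenvalue {d.min():g})")
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ Xm
    n, p = Xm.shape

    def neg_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        w = lam * d + 1.0
        Xw = Xt / w[:, None]
        xtx = Xt.T @ Xw
        b = np.linalg.solve(xtx, Xw.T @ yt)
        r = yt - Xt @ b
        rss = float(r @ (r / w))
        sig_e2 = rss / (n - p)
        _, logdet_xtx = np.linalg.slogdet(xtx)
        ll = -0.5 * ((n - p) * np.log(sig_e2) + np.sum(np.log(w))
                     + logdet_xtx + (n - p))
        return -ll

    res = minimize_scalar(neg_reml, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-6})
    if not res.success:
        raise RuntimeError(f"REML did not converge: {res}")
    # prefer the boundary lambda -> 0 (pure OLS) unless the interior solution
    # is a real improvement; with an uninformative GRM (e.g. the identity)
    # the restricted likelihood is flat and u is absorbed into the noise
    lam = float(np.exp(res.x)) if res.fun < neg_reml(-30.0) - 1e-6 else 0.0

    w = lam * d + 1.0
    Xw = Xt / w[:, None]
    b = np.linalg.solve(Xt.T @ Xw, Xw.T @ yt)
    r = yt - Xt @ b
    sig_e2 = float(r @ (r / w)) / (n - p)
    sig_g2 = lam * sig_e2
    resid_rot = r / w          # (y - Xb) - BLUP(u), in the eigenbasis
    resid = U @ resid_rot * calibration
    const = [j for j in range(Xm.shape[1]) if np.allclose(Xm[:, j], Xm[0, j])
             and Xm[0, j] != 0]
    mu = float(b[const[0]] * Xm[0, const[0]]) if const else 0.0
    info = {"sigma_g2": sig_g2, "sigma_e2": sig_e2, "lambda": lam,
            "reml_loglik": -res.fun}
    return ResidualTrait(resid, mu, design=",".join(names)), info


# ---------------------------------------------------------------------------
# Regression designs
# ---------------------------------------------------------------------------

def _ols(y: np.ndarray, cols: dict[str, np.ndarray]):
    X = pd.DataFrame(cols)
    X.insert(0, "const", 1.0)
    model = sm.OLS(y, X).fit()
    return model


def fit_univariate(eps: ResidualTrait | np.ndarray, f, tag: str = "uni_froh",
                   trait: str = "", cohort: str = "") -> EffectEstimate:
    """Simple regression of trait residuals on one homozygosity estimator."""
    y = eps.residuals if isinstance(eps, ResidualTrait) else np.asarray(eps, float)
    f = np.asarray(f, dtype=float)
    ok = ~(np.isnan(y) | np.isnan(f))
    y, f = y[ok], f[ok]
    if len(y) < 3:
        raise ValueError("need at least three samples")
    if np.var(f) == 0:
        raise ValueError("homozygosity estimator has zero variance")
    m = _ols(y, {"f": f})
    return EffectEstimate(float(m.params["f"]), float(m.bse["f"]), int(m.nobs),
                          tag, trait, cohort, mu=float(m.params["const"]))


def fit_partitioned(eps, f_snp_outside, f_roh_lt5, f_roh_gt5,
                    trait: str = "", cohort: str = "") -> list[EffectEstimate]:
    """Joint regression on outside-ROH homozygosity and both ROH length classes."""
    y = eps.residuals if isinstance(eps, ResidualTrait) else np.asarray(eps, float)
    cols = {"part_outside": np.asarray(f_snp_outside, float),
            "part_lt5": np.asarray(f_roh_lt5, float),
            "part_gt5": np.asarray(f_roh_gt5, float)}
    ok = ~np.isnan(y)
    for v in cols.values():
        ok &= ~np.isnan(v)
    y = y[ok]
    cols = {k: v[ok] for k, v in cols.items()}
    X = np.column_stack([np.ones(len(y)), *cols.values()])
    rank = np.linalg.matrix_rank(X)
    flagged: list[str] = []
    if rank < X.shape[1]:
        # keep the design, flag the components that cannot be separated
        corr = pd.DataFrame(cols).corr().abs()
        for a in corr.columns:
            for b in corr.columns:
                if a < b and (np.isclose(corr.loc[a, b], 1.0)
                              or np.isnan(corr.loc[a, b])):
                    flagged += [a, b]
        for k, v in cols.items():
            if np.var(v) == 0:
                flagged.append(k)
        flagged = sorted(set(flagged))
    m = _ols(y, cols)
    out = []
    for k in cols:
        se = float(m.bse[k])
        fl = ["collinear"] if (k in flagged or not np.isfinite(se)) else []
        out.append(EffectEstimate(float(m.params[k]),
                                  se if np.isfinite(se) and se > 0 else 0.0,
                                  int(m.nobs), k, trait, cohort,
                                  mu=float(m.params["const"]), n_params=4,
                                  flags=fl))
    return out


def fit_bivariate(eps, f_roh, f_grm, trait: str = "",
                  cohort: str = "") -> list[EffectEstimate]:
    """Joint regression on F_ROH and F_GRM: the conditional effects of each."""
    y = eps.residuals if isinstance(eps, ResidualTrait) else np.asarray(eps, float)
    f1 = np.asarray(f_roh, float)
    f2 = np.asarray(f_grm, float)
    ok = ~(np.isnan(y) | np.isnan(f1) | np.isnan(f2))
    y, f1, f2 = y[ok], f1[ok], f2[ok]
    r = np.corrcoef(f1, f2)[0, 1]
    if np.isclose(abs(r), 1.0):
        raise ValueError("F_ROH and F_GRM are perfectly collinear")
    m = _ols(y, {"biv_froh": f1, "biv_fgrm": f2})
    return [EffectEstimate(float(m.params[k]), float(m.bse[k]), int(m.nobs),
                           k, trait, cohort, mu=float(m.params["const"]),
                           n_params=3)
            for k in ("biv_froh", "biv_fgrm")]


def fit_binary(y, f, X=None, method: str = "logit", trait: str = "",
               cohort: str = "") -> EffectEstimate:
    """Binary-trait effect of a homozygosity estimator, on the ln(OR) scale.

    ``method="logit"`` fits the full logistic model with f and covariates
    simultaneously; ``method="linapprox"`` scales y by 1/var(y),
    residualizes on the covariates and fits the linear model, which is
    asymptotically unbiased on the same ln(odds-ratio) scale.
    """
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if len(np.unique(y[~np.isnan(y)])) < 2:
        raise ValueError("binary trait has a single class")
    if np.nanvar(f) == 0:
        raise ValueError("homozygosity estimator has zero variance")
    if method == "logit":
        cols = {"f": f}
        if X is not None:
            Xm, names = _as_design(X)
            for j, nm in enumerate(names):
                if not np.allclose(Xm[:, j], Xm[0, j]):
                    cols[nm] = Xm[:, j]
        D = pd.DataFrame(cols)
        D.insert(0, "const", 1.0)
        ok = ~(np.isnan(y) | D.isna().any(axis=1).to_numpy())
        try:
            m = sm.Logit(y[ok], D[ok]).fit(disp=0)
        except Exception as exc:      # perfect separation and friends
            raise ValueError(f"logistic fit failed (separation?): {exc}") from exc
        if not np.isfinite(m.bse["f"]) or m.bse["f"] > 1e4 * max(1.0, abs(m.params["f"])):
            raise ValueError("perfect separation on the homozygosity estimator")
        return EffectEstimate(float(m.params["f"]), float(m.bse["f"]),
                              int(m.nobs), "binary_logit", trait, cohort,
                              mu=float(m.params["const"]),
                              n_params=D.shape[1])
    if method == "linapprox":
        vy = np.nanvar(y, ddof=0)
        ys = y / vy
        eps = residualize(ys, X) if X is not None else \
            ResidualTrait(ys - np.nanmean(ys), float(np.nanmean(ys)))
        est = fit_univariate(eps, f, tag="binary_linapprox", trait=trait,
                             cohort=cohort)
        return est
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Binned trait means
# ---------------------------------------------------------------------------

def bin_trait_means(eps, mu: float, f_roh, bounds=BIN_BOUNDS) -> pd.DataFrame:
    """Mean intercept-referenced residual and mean F_ROH in fixed bins.

    Bins are left-closed/right-open on the canonical bounds, the last bin
    closing at 1.0, so F_ROH = 0 lands in bin 1.  The residuals are
    expressed relative to the F_ROH = 0 intercept ``mu`` of the
    univariate fit so that cohorts with different mean F share a
    reference point.  Empty bins are reported with n = 0.
    """
    y = eps.residuals if isinstance(eps, ResidualTrait) else np.asarray(eps, float)
    f = np.asarray(f_roh, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("F_ROH outside [0, 1]")
    bounds = tuple(bounds)
    idx = np.searchsorted(bounds, f, side="right")
    idx = np.clip(idx, 1, len(bounds) - 1)        # F = 1.0 joins the last bin
    ref = y - mu
    rows = []
    for b in range(1, len(bounds)):
        sel = idx == b
        n = int(sel.sum())
        if n:
            rows.append((b, bounds[b - 1], bounds[b], n,
                         float(f[sel].mean()),
                         float(f[sel].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                         float(ref[sel].mean()),
                         float(ref[sel].std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan))
        else:
            rows.append((b, bounds[b - 1], bounds[b], 0,
                         np.nan, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["bin", "lo", "hi", "n", "mean_f",
                                       "se_f", "mean_resid", "se_resid"])


# ---------------------------------------------------------------------------
# Relatedness and the within-sibling design
# ---------------------------------------------------------------------------

def estimate_kinship(g, min_snps: int = 200) -> pd.DataFrame:
    """Method-of-moments pairwise kinship and IBS0 for all sample pairs.

    Kinship is the robust heterozygote-concordance estimator
    (N_het,het - 2 N_IBS0) / (N_het(i) + N_het(j)) over the pair's shared
    non-missing SNPs; IBS0 is the fraction of shared SNPs at which the
    pair are opposite homozygotes.  Duplicates/MZ pairs sit near 0.5,
    full siblings near 0.25 with IBS0 clearly above zero, parent-offspring
    near 0.25 with IBS0 near zero.
    """
    import warnings as _w
    calls = g.calls
    if calls.shape[1] < min_snps:
        _w.warn(f"kinship from only {calls.shape[1]} SNPs; estimates unstable")
    het = (calls == 1).astype(np.float32)
    hom0 = (calls == 0).astype(np.float32)
    hom2 = (calls == 2).astype(np.float32)
    obs = (calls >= 0).astype(np.float32)
    n_hethet = het @ het.T
    n_ibs0 = hom0 @ hom2.T + hom2 @ hom0.T
    n_het_i = het @ obs.T            # het sites of i observed in j
    n_shared = obs @ obs.T
    denom = n_het_i + n_het_i.T
    with np.errstate(invalid="ignore", divide="ignore"):
        kin = (n_hethet - 2.0 * n_ibs0) / denom
        ibs0 = n_ibs0 / n_shared
    ids = [str(s) for s in g.samples.sample_id]
    iu, ju = np.triu_indices(len(ids), k=1)
    return pd.DataFrame({
        "id1": [ids[i] for i in iu], "id2": [ids[j] for j in ju],
        "kinship": kin[iu, ju].astype(float),
        "ibs0": ibs0[iu, ju].astype(float),
        "n_shared": n_shared[iu, ju].astype(int),
    })


def select_full_sibs(pairs: pd.DataFrame, kin_min: float = 0.175,
                     ibs0_min: float = 0.001) -> list[Sibship]:
    """Merge qualifying relative pairs into full-sibling families.

    A pair qualifies with kinship > ``kin_min`` and IBS0 > ``ibs0_min``
    (the IBS0 floor excludes parent-offspring pairs, whose kinship is
    also ~0.25 but who can never be opposite homozygotes).  Qualifying
    pairs are merged by connected components; MZ-like pairs (kinship
    near 0.5) are retained.  A component containing a member pair that is
    clearly unrelated is flagged for review rather than dropped.
    """
    q = pairs[(pairs["kinship"] > kin_min) & (pairs["ibs0"] > ibs0_min)]
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    for a, b in zip(q["id1"], q["id2"]):
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    comps: dict[str, list[str]] = {}
    for x in parent:
        comps.setdefault(find(x), []).append(x)

    lookup = {}
    for _, row in pairs.iterrows():
        lookup[(row["id1"], row["id2"])] = (row["kinship"], row["ibs0"])
        lookup[(row["id2"], row["id1"])] = (row["kinship"], row["ibs0"])
    out = []
    for k, members in enumerate(sorted(comps.values(), key=lambda m: sorted(m)[0])):
        members = sorted(members)
        mz = False
        flagged = False
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                kin, _ = lookup.get((a, b), (np.nan, np.nan))
                if np.isfinite(kin) and kin > 0.4:
                    mz = True
                if np.isfinite(kin) and kin < kin_min / 2:
                    flagged = True
        out.append(Sibship(f"SIB{k + 1:03d}", members, has_mz_like=mz,
                           flagged=flagged))
    return out


def within_sib_effect(eps, f_roh, sibships: list[Sibship], sample_ids,
                      include_intercept: bool = False, trait: str = "",
                      cohort: str = "") -> EffectEstimate:
    """Slope of trait-residual deviations on F_ROH deviations within families.

    Each member's F_ROH and residual are centred on their family mean;
    the slope is fitted through the origin of the deviations (they sum to
    zero within every family by construction).  The naive standard error
    is returned as ``se``; a family-clustered standard error is provided
    in ``flags`` metadata via the ``se_cluster`` attribute on the result.
    """
    y = eps.residuals if isinstance(eps, ResidualTrait) else np.asarray(eps, float)
    f = np.asarray(f_roh, dtype=float)
    row = {str(s): i for i, s in enumerate(sample_ids)}
    fam_sizes = [len(s.members) for s in sibships if len(s.members) >= 2]
    if not fam_sizes:
        raise ValueError("no sibship of size >= 2")
    xd, yd, fam = [], [], []
    for s in sibships:
        idx = [row[m] for m in s.members if m in row]
        if len(idx) < 2:
            continue
        fm = f[idx].mean()
        ym = y[idx].mean()
        xd.extend(f[idx] - fm)
        yd.extend(y[idx] - ym)
        fam.extend([s.family_id] * len(idx))
    xd = np.asarray(xd)
    yd = np.asarray(yd)
    n_fam = len(set(fam))
    if np.sum(xd ** 2) == 0:
        raise ValueError("no within-family F_ROH variance (MZ-only families?)")
    if include_intercept:
        X = np.column_stack([np.ones(len(xd)), xd])
        b, *_ = np.linalg.lstsq(X, yd, rcond=None)
        beta = float(b[1])
        resid = yd - X @ b
        df = len(xd) - n_fam - 1
        sxx = float(np.sum((xd - xd.mean()) ** 2))
    else:
        sxx = float(np.sum(xd ** 2))
        beta = float(np.sum(xd * yd) / sxx)
        resid = yd - beta * xd
        df = len(xd) - n_fam - 1
    df = max(df, 1)
    s2 = float(np.sum(resid ** 2)) / df
    se = float(np.sqrt(s2 / sxx))
    fam_arr = np.asarray(fam)
    score = np.array([np.sum(xd[fam_arr == g] * resid[fam_arr == g])
                      for g in sorted(set(fam))])
    se_cluster = float(np.sqrt(np.sum(score ** 2)) / sxx)
    est = EffectEstimate(beta, se, int(len(xd)), "within_sibs", trait, cohort,
                         n_params=1 + int(include_intercept))
    est.se_cluster = se_cluster
    return est
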