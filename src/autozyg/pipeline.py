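"""End-to-end orchestration: simulate/load -> QC -> ROH -> F -> models -> meta.

A cohort run executes the full per-cohort chain and writes one
machine-readable results file (one row per trait x model, versioned
header) plus per-trait bin summaries; the meta stage pools any number of
such files.  Every stage logs counts in/out and is deterministic given
the run seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import inbreeding as inb
from . import meta as meta_mod
from . import roh as roh_mod
from .genotypes import GenotypeMatrix, qc_filter, read_genotypes, write_genotypes
from .simulate import (CohortBundle, CohortConfig, PedigreeDesign, TraitModel,
                       simulate_cohort)

log = logging.getLogger("autozyg")

SCHEMA_VERSION = "autozyg-results v1"

QUANT_MODELS = ("uni_froh", "uni_fsnp", "uni_fgrm", "partitioned", "bivariate",
                "within_sibs", "by_sex")
BINARY_MODELS = ("binary_logit", "binary_linapprox")


@dataclass
class RunConfig:
    """Serialisable description of one full run."""

    seed: int = 1
    cohorts: list[dict] = dc_field(default_factory=list)
    roh_params: dict = dc_field(default_factory=dict)
    covariates: list[str] = dc_field(default_factory=lambda: ["age", "sex"])
    bin_bounds: tuple = assoc.BIN_BOUNDS
    genome_size_bp: float | None = None       # None: use the simulated genome
    models: list[str] = dc_field(default_factory=lambda: list(QUANT_MODELS))
    outdir: str = "results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in raw.items() if k in known})

    def to_yaml(self, path: str | Path) -> None:
        data = {k: getattr(self, k) for k in self.__dataclass_fields__}
        data["bin_bounds"] = list(self.bin_bounds)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def digest(self) -> str:
        blob = json.dumps({k: str(getattr(self, k))
                           for k in self.__dataclass_fields__}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def cohort_config_from_dict(d: dict, default_name: str = "cohort") -> CohortConfig:
    """Build a simulation config from a plain (YAML-friendly) mapping."""
    d = dict(d)
    design = d.pop("design", {"unrelated": 20, "first_cousin": 20})
    offspring = d.pop("offspring_per_family", 1)
    traits = [TraitModel(**t) if not isinstance(t, TraitModel) else t
              for t in d.pop("traits", [])]
    maf = d.pop("maf_spectrum", ("uniform", 0.05, 0.5))
    return CohortConfig(
        name=d.pop("name", default_name),
        design=PedigreeDesign({k: int(v) for k, v in design.items()},
                              offspring_per_family=int(offspring)),
        trait_models=traits,
        maf_spectrum=tuple(maf),
        **d,
    )


def _trait_columns(pheno: pd.DataFrame) -> list[str]:
    reserved = {"sample_id", "family_id", "mating_type", "sex", "age", "true_f"}
    return [c for c in pheno.columns
            if c not in reserved and not c.endswith("_confounder")]


def _is_binary(values: pd.Series) -> bool:
    v = set(pd.unique(values.dropna()))
    return v <= {0, 1, 0.0, 1.0}


def _covariate_design(pheno: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    X = pd.DataFrame({"const": np.ones(len(pheno))})
    for c in covariates:
        if c in pheno.columns and pheno[c].nunique() > 1:
            X[c] = pheno[c].astype(float).to_numpy()
    return X


def analyse_cohort(g: GenotypeMatrix, pheno: pd.DataFrame, cfg: RunConfig,
                   cohort_name: str, genome_size_bp: float,
                   subset: list[str] | None = None,
                   ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Run QC, ROH calling, estimators and every configured model.

    ``subset`` optionally restricts the analysis to listed sample ids
    (the generic subgroup mechanism).  Returns the long results frame and
    per-trait bin summaries.
    """
    pheno = pheno.set_index("sample_id", drop=False).loc[
        [str(s) for s in g.samples.sample_id]].reset_index(drop=True)
    if subset is not None:
        subset = set(subset)
        missing = subset - set(pheno["sample_id"])
        if missing:
            raise ValueError(f"subset ids absent from cohort: {sorted(missing)}")
        keep = pheno["sample_id"].isin(subset).to_numpy()
        g = g.subset_samples(keep)
        pheno = pheno[keep].reset_index(drop=True)

    g_qc, report = qc_filter(g)
    log.info("%s QC: variants %d -> %d, samples %d -> %d", cohort_name,
             report.n_variants_in, report.n_variants_out,
             report.n_samples_in, report.n_samples_out)
    if g_qc.n_samples != g.n_samples:
        kept = set(str(s) for s in g_qc.samples.sample_id)
        pheno = pheno[pheno["sample_id"].isin(kept)].reset_index(drop=True)

    params = roh_mod.ROHParams(**cfg.roh_params)
    segments = roh_mod.call_roh(g_qc, params)
    summary = roh_mod.roh_sample_summary(segments, g_qc.samples.sample_id)
    profile = inb.inbreeding_profile(g_qc, segments, summary, genome_size_bp)
    log.info("%s: %d ROH segments, mean F_ROH %.4f", cohort_name, len(segments),
             profile.table["f_roh"].mean())
    t = profile.table

    sibships = None
    if "within_sibs" in cfg.models:
        fam = pheno.groupby("family_id")["sample_id"].apply(list)
        multi = fam[fam.apply(len) >= 2]
        if len(multi) >= 2:
            pairs = assoc.estimate_kinship(g_qc)
            sibships = [s for s in assoc.select_full_sibs(pairs)
                        if len(s.members) >= 2]

    rows = []
    bins_by_trait: dict[str, pd.DataFrame] = {}
    X = _covariate_design(pheno, cfg.covariates)
    for trait in _trait_columns(pheno):
        y = pheno[trait].astype(float).to_numpy()
        if _is_binary(pheno[trait]):
            for method, tag in (("logit", "binary_logit"),
                                ("linapprox", "binary_linapprox")):
                try:
                    e = assoc.fit_binary(y, t["f_roh"].to_numpy(), X,
                                         method=method, trait=trait,
                                         cohort=cohort_name)
                    rows.append(e)
                except ValueError as exc:
                    log.warning("%s %s %s skipped: %s", cohort_name, trait,
                                tag, exc)
            continue

        eps = assoc.residualize(y, X)
        uni = assoc.fit_univariate(eps, t["f_roh"], "uni_froh", trait, cohort_name)
        if "uni_froh" in cfg.models:
            rows.append(uni)
        if "uni_fsnp" in cfg.models:
            rows.append(assoc.fit_univariate(eps, t["f_snp"], "uni_fsnp",
                                             trait, cohort_name))
        if "uni_fgrm" in cfg.models:
            rows.append(assoc.fit_univariate(eps, t["f_grm"], "uni_fgrm",
                                             trait, cohort_name))
        if "partitioned" in cfg.models:
            rows.extend(assoc.fit_partitioned(
                eps, t["f_snp_outside_roh"], t["f_roh_lt5"], t["f_roh_gt5"],
                trait, cohort_name))
        if "bivariate" in cfg.models:
            rows.extend(assoc.fit_bivariate(eps, t["f_roh"], t["f_grm"],
                                            trait, cohort_name))
        if "by_sex" in cfg.models:
            for sex, tag in ((1, "by_sex_male"), (2, "by_sex_female")):
                sel = (pheno["sex"] == sex).to_numpy()
                if sel.sum() >= 10 and np.var(t["f_roh"].to_numpy()[sel]) > 0:
                    e = assoc.fit_univariate(eps.residuals[sel],
                                             t["f_roh"].to_numpy()[sel],
                                             tag, trait, cohort_name)
                    rows.append(e)
        if "within_sibs" in cfg.models and sibships:
            try:
                rows.append(assoc.within_sib_effect(
                    eps, t["f_roh"].to_numpy(), sibships,
                    g_qc.samples.sample_id, trait=trait, cohort=cohort_name))
            except ValueError as exc:
                log.warning("%s %s within-sib skipped: %s", cohort_name, trait, exc)
        bins_by_trait[trait] = assoc.bin_trait_means(
            eps, uni.mu, t["f_roh"].to_numpy(), cfg.bin_bounds)

    res = pd.DataFrame([(e.cohort, e.trait, e.model_tag, e.beta, e.se, e.n,
                         e.mu, ";".join(e.flags)) for e in rows],
                       columns=["cohort", "trait", "model_tag", "beta", "se",
                                "n", "mu", "flags"])
    return res, bins_by_trait


def write_results(res: pd.DataFrame, bins: dict[str, pd.DataFrame],
                  outdir: str | Path, cohort_name: str, provenance: dict) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / f"{cohort_name}.results.tsv"
    with open(path, "w") as fh:
        fh.write(f"# {SCHEMA_VERSION}\n")
        res.to_csv(fh, sep="\t", index=False)
    for trait, bdf in bins.items():
        bpath = outdir / f"{cohort_name}.{trait}.bins.tsv"
        with open(bpath, "w") as fh:
            fh.write(f"# {SCHEMA_VERSION}\n")
            bdf.to_csv(fh, sep="\t", index=False)
    with open(outdir / f"{cohort_name}.provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, default=str)
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        if header != SCHEMA_VERSION:
            raise ValueError(f"{path}: schema {header!r} != {SCHEMA_VERSION!r}")
        return pd.read_csv(fh, sep="\t")


def run_cohort(cfg: RunConfig, cohort_spec: dict, index: int = 0,
               ) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], CohortBundle | None]:
    """Materialise one cohort (simulate or load) and analyse it."""
    name = cohort_spec.get("name", f"cohort{index + 1}")
    bundle = None
    if "simulate" in cohort_spec:
        sim = cohort_config_from_dict(dict(cohort_spec["simulate"], name=name))
        bundle = simulate_cohort(sim, seed=int(cfg.seed) * 1000 + index)
        g, pheno = bundle.genotypes, bundle.phenotypes
        genome = cfg.genome_size_bp or sim.genetic_map().genome_size_bp
    else:
        g = read_genotypes(cohort_spec["genotypes"],
                           cohort_spec.get("dialect", "bed"))
        pheno = pd.read_csv(cohort_spec["phenotypes"], sep="\t",
                            dtype={"sample_id": str})
        genome = cfg.genome_size_bp or inb.DEFAULT_GENOME_BP
    res, bins = analyse_cohort(g, pheno, cfg, name, genome,
                               subset=cohort_spec.get("subset"))
    return res, bins, bundle


def run_meta(result_frames: list[pd.DataFrame],
             bin_frames: list[dict[str, pd.DataFrame]] | None = None,
             reps: int = 10_000, seed: int = 0) -> dict[str, pd.DataFrame]:
    """Pool per-cohort results: one IVW row per (trait, model), pooled
    bins per trait, and the within-sib : population ratio across traits."""
    all_res = pd.concat(result_frames, ignore_index=True)
    pooled = []
    for (trait, tag), grp in all_res.groupby(["trait", "model_tag"]):
        ests = [assoc.EffectEstimate(r.beta, r.se, int(r.n), tag, trait,
                                     r.cohort, n_params=1)
                for r in grp.itertuples() if r.se > 0]
        if not ests:
            log.warning("no usable estimates for %s/%s", trait, tag)
            continue
        pooled.append(meta_mod.ivw_meta(ests))
    tables = {"effects": meta_mod.meta_table(pooled)}

    if bin_frames:
        traits = set()
        for d in bin_frames:
            traits |= set(d)
        pooled_bins = []
        for trait in sorted(traits):
            frames = [d[trait] for d in bin_frames if trait in d]
            pb = meta_mod.meta_bins(frames)
            pb.insert(0, "trait", trait)
            pooled_bins.append(pb)
        tables["bins"] = pd.concat(pooled_bins, ignore_index=True)

    eff = tables["effects"]
    have = eff.pivot(index="trait", columns="model_tag", values="beta")
    if {"within_sibs", "uni_froh"} <= set(have.columns):
        ok = have[["within_sibs", "uni_froh"]].dropna().index
        if len(ok):
            num = [_row_to_est(eff, t, "within_sibs") for t in ok]
            den = [_row_to_est(eff, t, "uni_froh") for t in ok]
            rs = meta_mod.ratio_bootstrap(num, den, reps=reps, seed=seed)
            tables["ratios"] = pd.DataFrame(
                [("within_sibs:uni_froh", rs.median, rs.lo95, rs.hi95,
                  rs.median_weighted, rs.reps)],
                columns=["ratio", "median", "lo95", "hi95",
                         "median_weighted", "reps"])
    return tables


def _row_to_est(eff: pd.DataFrame, trait: str, tag: str) -> assoc.EffectEstimate:
    r = eff[(eff["trait"] == trait) & (eff["model_tag"] == tag)].iloc[0]
    return assoc.EffectEstimate(float(r["beta"]), float(r["se"]), 10, tag,
                                trait, n_params=1)


def run(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Full study: every configured cohort, then the meta stage."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames, bin_dicts = [], []
    for i, spec in enumerate(cfg.cohorts):
        res, bins, bundle = run_cohort(cfg, spec, i)
        frames.append(res)
        bin_dicts.append(bins)
        name = spec.get("name", f"cohort{i + 1}")
        write_results(res, bins, outdir, name,
                      {"config_digest": cfg.digest(), "seed": cfg.seed,
                       "schema": SCHEMA_VERSION})
        if bundle is not None and spec.get("write_genotypes"):
            write_genotypes(bundle.genotypes, outdir / f"{name}")
            bundle.phenotypes.to_csv(outdir / f"{name}.pheno.tsv", sep="\t",
                                     index=False)
            bundle.truth.segments.to_csv(outdir / f"{name}.truth.tsv", sep="\t",
                                         index=False)
    tables = run_meta(frames, bin_dicts, seed=cfg.seed)
    for key, df in tables.items():
        with open(outdir / f"meta.{key}.tsv", "w") as fh:
            fh.write(f"# {SCHEMA_VERSION}\n")
            df.to_csv(fh, sep="\t", index=False)
    return tables
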