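"""Gene-dropping simulation of consanguineous cohorts with known autozygosity.

Founder haplotypes are labelled, dropped through small fixed pedigrees
(unrelated, second-cousin, first-cousin, avuncular, full-sib and
parent-offspring unions) with Poisson recombination and no interference,
so every offspring carries exact identical-by-descent (IBD) truth
segments: spans where both transmitted haplotypes descend from one founder
haplotype.  Quantitative and binary traits are then generated under a
directional-dominance architecture — rare recessive deleterious loci whose
homozygous state tracks autozygosity — with optional covariates, per-sex
effect scaling and a family-level confounder correlated with how related
the parents are.

The closed-form inbreeding load of a trait model is
``B = sum_l |d_l| q_l (1 - q_l)``; the expected slope of the trait on the
true autozygous fraction is exactly ``-B``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, SampleTable, VariantMap

#: expected autozygosity (= parental kinship) per mating type
MATING_EXPECTED_F: dict[str, float] = {
    "unrelated": 0.0,
    "second_cousin": 1.0 / 64,
    "first_cousin": 1.0 / 16,
    "avuncular": 1.0 / 8,
    "full_sib": 1.0 / 4,
    "parent_offspring": 1.0 / 4,
}

#: fresh founders consumed per family of each mating type
_FOUNDERS_PER_FAMILY = {
    "unrelated": 2,
    "second_cousin": 6,
    "first_cousin": 4,
    "avuncular": 3,
    "full_sib": 2,
    "parent_offspring": 2,
}


@dataclass
class GeneticMap:
    """Physical chromosome lengths plus a uniform recombination rate."""

    chrom_lengths: dict[str, int]                 # bp per chromosome
    rate_cm_per_mb: float = 1.0

    def __post_init__(self) -> None:
        if any(length <= 0 for length in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.rate_cm_per_mb < 0:
            raise ValueError("recombination rate must be >= 0")

    @property
    def genome_size_bp(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    @classmethod
    def uniform(cls, n_chrom: int = 20, chrom_length_bp: int = 50_000_000,
                rate_cm_per_mb: float = 1.0) -> "GeneticMap":
        return cls({str(i + 1): chrom_length_bp for i in range(n_chrom)},
                   rate_cm_per_mb)


@dataclass
class PedigreeDesign:
    """How many families of each mating type, and sibship size."""

    n_families: dict[str, int]
    offspring_per_family: int = 1

    def __post_init__(self) -> None:
        unknown = set(self.n_families) - set(MATING_EXPECTED_F)
        if unknown:
            raise ValueError(f"unknown mating types: {sorted(unknown)}")
        if self.offspring_per_family < 1:
            raise ValueError("offspring_per_family must be >= 1")

    @property
    def n_founders_required(self) -> int:
        return sum(_FOUNDERS_PER_FAMILY[t] * k for t, k in self.n_families.items())

    @property
    def n_offspring(self) -> int:
        return sum(self.n_families.values()) * self.offspring_per_family


@dataclass
class IBDTruth:
    """True autozygous segments per offspring.

    ``segments`` has columns sample_id, chrom, start_bp, end_bp with
    half-open bp intervals [start_bp, end_bp); non-overlapping within a
    sample and chromosome.
    """

    segments: pd.DataFrame
    genome_size_bp: int

    def __post_init__(self) -> None:
        need = {"sample_id", "chrom", "start_bp", "end_bp"}
        if not need.issubset(self.segments.columns):
            raise ValueError(f"truth table needs columns {sorted(need)}")


@dataclass
class FounderPool:
    """Independent founder haplotypes over a variant map.

    ``haplotypes`` is (2 * n_founders) x n_variants of alleles in {0, 1},
    allele 1 being the counted allele with per-site frequency drawn from
    the configured spectrum.  Row index doubles as the ancestral label
    used for IBD tracking.
    """

    haplotypes: np.ndarray
    variant_map: VariantMap
    freqs: np.ndarray

    @property
    def n_founders(self) -> int:
        return self.haplotypes.shape[0] // 2


def sample_maf_spectrum(spec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw per-site counted-allele frequencies from a spectrum spec.

    ``spec`` is ("fixed", p), ("uniform", lo, hi) or ("beta", a, b); the
    beta form gives the U-shaped spectrum typical of standing variation.
    """
    kind = spec[0]
    if kind == "fixed":
        p = np.full(n, float(spec[1]))
    elif kind == "uniform":
        p = rng.uniform(float(spec[1]), float(spec[2]), n)
    elif kind == "beta":
        p = rng.beta(float(spec[1]), float(spec[2]), n)
    else:
        raise ValueError(f"unknown MAF spectrum {spec!r}")
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("spectrum produced degenerate frequencies (0 or 1)")
    return p


def simulate_founders(n: int, variant_map: VariantMap, maf_spectrum,
                      seed: int | np.random.Generator) -> FounderPool:
    """Draw ``n`` founders' haplotypes independently per site."""
    if n < 2:
        raise ValueError("need at least two founders")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = sample_maf_spectrum(maf_spectrum, len(variant_map), rng)
    haps = (rng.random((2 * n, len(variant_map))) < p).astype(np.int8)
    return FounderPool(haplotypes=haps, variant_map=variant_map, freqs=p)


# ---------------------------------------------------------------------------
# Meiosis on labelled haplotype mosaics
# ---------------------------------------------------------------------------
# A haplotype is stored per chromosome as (ends, srcs): ends[i] is the
# exclusive bp end of segment i (ends[-1] == chromosome length) and srcs[i]
# the founder haplotype row it descends from.

def _founder_person(hap_a: int, hap_b: int, gmap: GeneticMap):
    person = {}
    for c, L in gmap.chrom_lengths.items():
        person[c] = (
            (np.array([float(L)]), np.array([hap_a])),
            (np.array([float(L)]), np.array([hap_b])),
        )
    return person


def _slice(hap, a: float, b: float):
    """Segments of ``hap`` restricted to the interval (a, b]."""
    ends, srcs = hap
    out_e, out_s = [], []
    i = int(np.searchsorted(ends, a, side="right"))
    while i < len(ends) and ends[i] < b:
        out_e.append(ends[i])
        out_s.append(srcs[i])
        i += 1
    out_e.append(b)
    out_s.append(srcs[min(i, len(srcs) - 1)])
    return out_e, out_s


def _meiosis(rng, h1, h2, length: float, exp_crossovers: float):
    """One gamete: Poisson crossovers, no interference, random start phase."""
    n_xo = rng.poisson(exp_crossovers)
    cuts = np.sort(rng.uniform(0.0, length, n_xo)) if n_xo else np.empty(0)
    current = int(rng.integers(2))
    ends: list[float] = []
    srcs: list[int] = []
    prev = 0.0
    for cut in [*cuts.tolist(), length]:
        if cut <= prev:
            current ^= 1
            continue
        seg_e, seg_s = _slice(h1 if current == 0 else h2, prev, cut)
        for e, s in zip(seg_e, seg_s):
            if ends and srcs[-1] == s:
                ends[-1] = e            # coalesce same-source neighbours
            else:
                ends.append(e)
                srcs.append(s)
        prev = cut
        current ^= 1
    return np.asarray(ends), np.asarray(srcs)


def _child(rng, mother, father, gmap: GeneticMap):
    child = {}
    for c, L in gmap.chrom_lengths.items():
        exp_xo = L * gmap.rate_cm_per_mb / 1e8
        gm = _meiosis(rng, *mother[c], float(L), exp_xo)
        gp = _meiosis(rng, *father[c], float(L), exp_xo)
        child[c] = (gm, gp)
    return child


def _shared_spans(hap1, hap2, length: float):
    """Intervals where the two mosaics carry the same founder label."""
    e1, s1 = hap1
    e2, s2 = hap2
    spans = []
    i = j = 0
    prev = 0.0
    while i < len(e1) and j < len(e2):
        end = min(e1[i], e2[j])
        if s1[i] == s2[j] and end > prev:
            if spans and spans[-1][1] == prev:
                spans[-1] = (spans[-1][0], end)
            else:
                spans.append((prev, end))
        prev = end
        if e1[i] <= end:
            i += 1
        if e2[j] <= end:
            j += 1
    return spans


# ---------------------------------------------------------------------------
# Pedigree recipes
# ---------------------------------------------------------------------------

def _breed_parents(rng, mating_type: str, founders: list, gmap: GeneticMap):
    """Return the (mother, father) pair whose offspring carry the target F."""
    if mating_type == "unrelated":
        return founders[0], founders[1]
    if mating_type == "full_sib":
        a, b = founders
        return _child(rng, a, b, gmap), _child(rng, a, b, gmap)
    if mating_type == "parent_offspring":
        a, b = founders
        return _child(rng, a, b, gmap), a
    if mating_type == "avuncular":
        a, b, x = founders
        c1 = _child(rng, a, b, gmap)        # stays as uncle/aunt
        c2 = _child(rng, a, b, gmap)
        d = _child(rng, c2, x, gmap)        # niece/nephew
        return d, c1
    if mating_type == "first_cousin":
        a, b, x1, x2 = founders
        c1 = _child(rng, a, b, gmap)
        c2 = _child(rng, a, b, gmap)
        d1 = _child(rng, c1, x1, gmap)
        d2 = _child(rng, c2, x2, gmap)
        return d1, d2
    if mating_type == "second_cousin":
        a, b, x1, x2, y1, y2 = founders
        c1 = _child(rng, a, b, gmap)
        c2 = _child(rng, a, b, gmap)
        d1 = _child(rng, c1, x1, gmap)
        d2 = _child(rng, c2, x2, gmap)
        e1 = _child(rng, d1, y1, gmap)
        e2 = _child(rng, d2, y2, gmap)
        return e1, e2
    raise ValueError(f"unsupported pedigree loop for mating type {mating_type!r}")


def _genotype_offspring(person, pool: FounderPool, gmap: GeneticMap) -> np.ndarray:
    vm = pool.variant_map
    calls = np.empty(len(vm), dtype=np.int8)
    for c in gmap.chrom_lengths:
        idx = np.flatnonzero(vm.chrom == c)
        if idx.size == 0:
            continue
        pos = vm.pos_bp[idx].astype(float)
        dosage = np.zeros(idx.size, dtype=np.int8)
        for ends, srcs in person[c]:
            seg = np.searchsorted(ends, pos, side="left")
            dosage += pool.haplotypes[srcs[seg], idx]
        calls[idx] = dosage
    return calls


def gene_drop(design: PedigreeDesign, founders: FounderPool, gmap: GeneticMap,
              seed: int | np.random.Generator,
              ) -> tuple[GenotypeMatrix, IBDTruth, pd.DataFrame]:
    """Drop founder haplotypes through the designed unions.

    Returns the offspring genotype matrix over the founder pool's variant
    map, the exact IBD truth, and a metadata frame (sample_id, family_id,
    mating_type, sex, true_f).  Sibships (offspring_per_family > 1) share
    both parents.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if founders.n_founders < design.n_founders_required:
        raise ValueError(
            f"design needs {design.n_founders_required} founders, pool has "
            f"{founders.n_founders}")
    pool_iter = iter(range(founders.n_founders))

    rows, truth_rows, meta_rows = [], [], []
    genome = gmap.genome_size_bp
    fam_no = 0
    for mating_type in sorted(design.n_families):
        for _ in range(design.n_families[mating_type]):
            fam_no += 1
            fam_id = f"F{fam_no:04d}"
            k = _FOUNDERS_PER_FAMILY[mating_type]
            fam_founders = [
                _founder_person(2 * f, 2 * f + 1, gmap)
                for f in (next(pool_iter) for _ in range(k))
            ]
            mother, father = _breed_parents(rng, mating_type, fam_founders, gmap)
            for o in range(design.offspring_per_family):
                sid = f"{fam_id}_O{o + 1}"
                off = _child(rng, mother, father, gmap)
                rows.append(_genotype_offspring(off, founders, gmap))
                auto_bp = 0.0
                for c, L in gmap.chrom_lengths.items():
                    for s, e in _shared_spans(off[c][0], off[c][1], float(L)):
                        truth_rows.append((sid, c, int(np.floor(s)) + 1,
                                           int(np.floor(e)) + 1))
                        auto_bp += e - s
                meta_rows.append((sid, fam_id, mating_type,
                                  int(rng.integers(1, 3)), auto_bp / genome))

    meta = pd.DataFrame(meta_rows, columns=["sample_id", "family_id",
                                            "mating_type", "sex", "true_f"])
    calls = np.vstack(rows) if rows else np.empty((0, len(founders.variant_map)),
                                                  dtype=np.int8)
    samples = SampleTable(
        sample_id=meta["sample_id"].to_numpy(dtype=object),
        family_id=meta["family_id"].to_numpy(dtype=object),
        father_id=np.array(["0"] * len(meta), dtype=object),
        mother_id=np.array(["0"] * len(meta), dtype=object),
        sex=meta["sex"].to_numpy(),
    )
    g = GenotypeMatrix(calls, founders.variant_map, samples)
    truth = IBDTruth(
        pd.DataFrame(truth_rows, columns=["sample_id", "chrom", "start_bp", "end_bp"]),
        genome_size_bp=genome)
    return g, truth, meta


def true_autozygosity(truth: IBDTruth, sample_ids=None) -> pd.Series:
    """Per-sample autozygous genome fraction from the truth segments."""
    seg = truth.segments
    lengths = (seg["end_bp"] - seg["start_bp"]).groupby(seg["sample_id"]).sum()
    frac = lengths / truth.genome_size_bp
    if sample_ids is not None:
        frac = frac.reindex(sample_ids, fill_value=0.0)
    frac.name = "true_f"
    return frac


# ---------------------------------------------------------------------------
# Trait architecture
# ---------------------------------------------------------------------------

@dataclass
class TraitModel:
    """Directional-dominance trait architecture.

    ``recessive`` loci are (frequency q, homozygous deviation d) pairs with
    d < 0 for deleterious effects; the closed-form inbreeding load is
    ``B = sum |d| q (1 - q)`` and the expected regression of the trait on
    true autozygosity is ``-B``.  ``binary`` switches the trait to a
    Bernoulli draw from logit(p) = binary_intercept + lnor_per_unit_f * F.
    A confounder, when configured, is constant within each family and
    correlated with the expected consanguinity of the parents' union.
    """

    name: str = "trait"
    intercept: float = 0.0
    recessive: list[tuple[float, float]] = dc_field(default_factory=list)
    additive: list[tuple[float, float]] = dc_field(default_factory=list)
    covariate_effects: dict[str, float] = dc_field(default_factory=dict)
    residual_sd: float = 1.0
    sex_effect_multiplier: dict[int, float] | None = None
    binary: bool = False
    binary_intercept: float = 0.0
    lnor_per_unit_f: float = 0.0
    confounder_sd: float = 0.0
    confounder_effect: float = 0.0
    confounder_corr: float = 0.0

    def __post_init__(self) -> None:
        for q, _ in [*self.recessive, *self.additive]:
            if not 0.0 < q < 1.0:
                raise ValueError("causal locus frequencies must lie in (0, 1)")

    @property
    def load(self) -> float:
        """Theoretical inbreeding load B = sum |d| q (1 - q)."""
        return float(sum(abs(d) * q * (1 - q) for q, d in self.recessive))


def _family_confounder(model: TraitModel, meta: pd.DataFrame,
                       rng: np.random.Generator) -> pd.Series:
    """Family-constant confounder with the configured link to consanguinity."""
    fams = meta.drop_duplicates("family_id").set_index("family_id")
    exp_f = fams["mating_type"].map(MATING_EXPECTED_F).astype(float)
    noise = pd.Series(rng.normal(size=len(fams)), index=fams.index)
    rho = model.confounder_corr
    if abs(rho) > 0 and exp_f.std() > 0:
        z = rho * (exp_f - exp_f.mean()) / exp_f.std() + np.sqrt(1 - rho ** 2) * noise
    else:
        z = noise
    per_fam = model.confounder_sd * z
    return meta["family_id"].map(per_fam).rename("confounder")


def simulate_traits(causal_genotypes: np.ndarray, causal_model_index: dict,
                    truth_f: np.ndarray, meta: pd.DataFrame, model: TraitModel,
                    seed: int | np.random.Generator) -> pd.DataFrame:
    """Generate one trait column (plus its confounder) for a cohort.

    ``causal_genotypes`` holds dosages of the model's causal loci
    (columns ordered recessive then additive, per ``causal_model_index``);
    these loci are gene-dropped like array SNPs but normally withheld from
    the emitted genotype matrix, mimicking untyped rare causal variation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(meta)
    rec_cols = causal_model_index.get("recessive", [])
    add_cols = causal_model_index.get("additive", [])
    if causal_genotypes.shape[1] < len(rec_cols) + len(add_cols):
        raise ValueError("missing causal genotypes for the trait model")

    load_term = np.zeros(n)
    for col, (_, d) in zip(rec_cols, model.recessive):
        load_term += d * (causal_genotypes[:, col] == 2)
    if model.sex_effect_multiplier:
        mult = meta["sex"].map(model.sex_effect_multiplier).fillna(1.0).to_numpy()
        load_term = load_term * mult

    add_term = np.zeros(n)
    for col, (_, a) in zip(add_cols, model.additive):
        add_term += a * causal_genotypes[:, col]

    cov_term = np.zeros(n)
    for cov, eff in model.covariate_effects.items():
        cov_term += eff * meta[cov].to_numpy(dtype=float)

    conf = _family_confounder(model, meta, rng) if model.confounder_sd > 0 \
        else pd.Series(np.zeros(n), index=meta.index, name="confounder")

    out = pd.DataFrame({"sample_id": meta["sample_id"]})
    if model.binary:
        eta = (model.binary_intercept + model.lnor_per_unit_f * truth_f
               + model.confounder_effect * conf.to_numpy() + load_term + add_term)
        prob = 1.0 / (1.0 + np.exp(-eta))
        out[model.name] = (rng.random(n) < prob).astype(int)
    else:
        y = (model.intercept + load_term + add_term + cov_term
             + model.confounder_effect * conf.to_numpy()
             + rng.normal(0.0, model.residual_sd, n))
        out[model.name] = y
    out[f"{model.name}_confounder"] = conf.to_numpy()
    return out


# ---------------------------------------------------------------------------
# Cohort composition
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Everything needed to simulate one cohort deterministically."""

    name: str = "cohort"
    design: PedigreeDesign = dc_field(
        default_factory=lambda: PedigreeDesign({"unrelated": 20, "first_cousin": 20}))
    n_chrom: int = 20
    chrom_length_bp: int = 50_000_000
    snps_per_chrom: int = 1000
    rate_cm_per_mb: float = 1.0
    maf_spectrum: tuple = ("uniform", 0.05, 0.5)
    trait_models: list[TraitModel] = dc_field(default_factory=list)
    keep_causal_in_array: bool = False
    missing_rate: float = 0.0

    def genetic_map(self) -> GeneticMap:
        return GeneticMap.uniform(self.n_chrom, self.chrom_length_bp,
                                  self.rate_cm_per_mb)


@dataclass
class CohortBundle:
    """One simulated cohort with its ground truth."""

    name: str
    genotypes: GenotypeMatrix
    truth: IBDTruth
    phenotypes: pd.DataFrame
    config: CohortConfig
    seed: int

    def __post_init__(self) -> None:
        ids = set(self.genotypes.samples.sample_id)
        if set(self.phenotypes["sample_id"]) != ids:
            raise ValueError("phenotype table and genotype matrix disagree on samples")


def _array_map(cfg: CohortConfig, rng: np.random.Generator) -> VariantMap:
    chroms, poss, ids = [], [], []
    for c in range(1, cfg.n_chrom + 1):
        pos = np.sort(rng.choice(
            np.arange(1, cfg.chrom_length_bp, 50, dtype=np.int64),
            size=cfg.snps_per_chrom, replace=False))
        chroms += [str(c)] * cfg.snps_per_chrom
        poss.append(pos)
        ids += [f"snp{c}_{k}" for k in range(cfg.snps_per_chrom)]
    n = cfg.n_chrom * cfg.snps_per_chrom
    return VariantMap(np.array(chroms, dtype=object), np.concatenate(poss),
                      np.array(ids, dtype=object),
                      np.array(["A"] * n, dtype=object),
                      np.array(["B"] * n, dtype=object))


def simulate_cohort(cfg: CohortConfig, seed: int) -> CohortBundle:
    """Simulate genotypes, IBD truth and phenotypes for one cohort.

    Causal loci of every trait model are appended to the simulated variant
    set so their genotypes segregate with the same IBD process, then
    withheld from the emitted array unless ``keep_causal_in_array``.
    """
    root = np.random.SeedSequence(seed)
    s_map, s_founders, s_drop, s_traits, s_miss = root.spawn(5)
    rng_map = np.random.default_rng(s_map)

    vmap_array = _array_map(cfg, rng_map)
    # append causal loci at random positions with their configured freqs
    causal_freq, causal_chrom, causal_pos, causal_ids = [], [], [], []
    model_cols: list[dict] = []
    col = 0
    for m, model in enumerate(cfg.trait_models):
        cols = {"recessive": [], "additive": []}
        for kind in ("recessive", "additive"):
            for l, (q, _) in enumerate(getattr(model, kind)):
                causal_freq.append(q)
                causal_chrom.append(str(int(rng_map.integers(1, cfg.n_chrom + 1))))
                causal_pos.append(int(rng_map.integers(1, cfg.chrom_length_bp)))
                causal_ids.append(f"causal_m{m}_{kind[0]}{l}")
                cols[kind].append(col)
                col += 1
        model_cols.append(cols)
    n_causal = col

    chrom_all = np.concatenate([vmap_array.chrom, np.array(causal_chrom, dtype=object)])
    pos_all = np.concatenate([vmap_array.pos_bp, np.array(causal_pos, dtype=np.int64)])
    ids_all = np.concatenate([vmap_array.ids, np.array(causal_ids, dtype=object)])
    order = np.lexsort((pos_all, chrom_all.astype(str)))
    # resolve position collisions between causal loci and array SNPs
    for c in set(chrom_all.tolist()):
        m = chrom_all[order] == c
        pos_c = pos_all[order][m]
        while len(pos_c) > 1 and np.any(np.diff(pos_c) <= 0):
            dup = np.flatnonzero(np.diff(pos_c) <= 0) + 1
            pos_c[dup] = pos_c[dup - 1] + 1
        idx = order[m]
        pos_all[idx] = pos_c
    vmap_all = VariantMap(chrom_all[order], pos_all[order], ids_all[order],
                          np.array(["A"] * len(order), dtype=object),
                          np.array(["B"] * len(order), dtype=object))
    is_causal_sorted = order >= len(vmap_array)
    causal_col_of_sorted = np.full(len(order), -1)
    causal_col_of_sorted[is_causal_sorted] = order[is_causal_sorted] - len(vmap_array)

    gmap = cfg.genetic_map()
    rng_f = np.random.default_rng(s_founders)
    p_array = sample_maf_spectrum(cfg.maf_spectrum, len(vmap_array), rng_f)
    p_all = np.empty(len(vmap_all))
    p_all[~is_causal_sorted] = p_array
    if n_causal:
        p_all[is_causal_sorted] = np.array(causal_freq)[causal_col_of_sorted[is_causal_sorted]]
    n_founders = cfg.design.n_founders_required
    haps = (rng_f.random((2 * n_founders, len(vmap_all))) < p_all).astype(np.int8)
    pool = FounderPool(haps, vmap_all, p_all)

    g_all, truth, meta = gene_drop(cfg.design, pool, gmap, np.random.default_rng(s_drop))

    causal_calls = np.empty((g_all.n_samples, n_causal), dtype=np.int8)
    if n_causal:
        for j in np.flatnonzero(is_causal_sorted):
            causal_calls[:, causal_col_of_sorted[j]] = g_all.calls[:, j]
    g = g_all if cfg.keep_causal_in_array else g_all.subset_variants(~is_causal_sorted)

    rng_t = np.random.default_rng(s_traits)
    meta = meta.copy()
    meta["age"] = rng_t.normal(50.0, 10.0, len(meta)).round(1)
    pheno = meta[["sample_id", "family_id", "mating_type", "sex", "age", "true_f"]].copy()
    for model, cols in zip(cfg.trait_models, model_cols):
        tdf = simulate_traits(causal_calls, cols, meta["true_f"].to_numpy(),
                              meta, model, rng_t)
        pheno[model.name] = tdf[model.name].to_numpy()
        pheno[f"{model.name}_confounder"] = tdf[f"{model.name}_confounder"].to_numpy()

    if cfg.missing_rate > 0:
        rng_m = np.random.default_rng(s_miss)
        mask = rng_m.random(g.calls.shape) < cfg.missing_rate
        calls = g.calls.copy()
        calls[mask] = -1
        g = GenotypeMatrix(calls, g.variant_map, g.samples)

    return CohortBundle(cfg.name, g, truth, pheno, cfg, seed)
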