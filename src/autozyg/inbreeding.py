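"""Genomic inbreeding and homozygosity estimators.

Six per-sample quantities are computed:

* ``f_roh`` — fraction of the autosomal genome in called ROH, with its
  additive split into short (< 5 Mb) and long (>= 5 Mb) components;
* ``f_snp`` — method-of-moments excess homozygosity
  (O(HOM) - E(HOM)) / (N - E(HOM)) with E(HOM) = sum_i (1 - 2 p_i q_i);
* ``f_snp_outside_roh`` — the same statistic restricted to SNPs outside
  the sample's ROH, with the expectation prorated by the SNP count left;
* ``f_grm`` — the GRM-diagonal estimator
  mean_i (x_i^2 - (1 + 2 p_i) x_i + 2 p_i^2) / (2 p_i (1 - p_i)).

Expectations use in-sample allele frequencies (including the index
individual), which introduces a small O(1/n) bias in small cohorts.
Per-sample SNP counts exclude that sample's missing calls throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import AlleleFrequencies, GenotypeMatrix, allele_frequencies
from .roh import ROHSegment

DEFAULT_GENOME_BP = 3.0e9


@dataclass
class InbreedingProfile:
    """Per-sample table of all estimators (one row per sample)."""

    table: pd.DataFrame      # sample_id, f_roh, f_roh_lt5, f_roh_gt5,
    #                          f_snp, f_snp_outside_roh, f_grm

    def __post_init__(self) -> None:
        t = self.table
        if not np.allclose(t["f_roh"], t["f_roh_lt5"] + t["f_roh_gt5"],
                           rtol=0, atol=1e-12):
            raise ValueError("f_roh must equal f_roh_lt5 + f_roh_gt5 exactly")


def f_roh(summary: pd.DataFrame,
          genome_size_bp: float = DEFAULT_GENOME_BP) -> pd.DataFrame:
    """ROH-based inbreeding coefficients from per-sample ROH totals.

    ``summary`` is the frame from :func:`autozyg.roh.roh_sample_summary`.
    The denominator is the autosomal genome length, 3 Gb for the human
    genome; pass the simulated genome size for downscaled data.
    """
    if genome_size_bp <= 0:
        raise ValueError("genome size must be positive")
    kb = genome_size_bp / 1000.0
    lt5 = summary["kb_lt5"] / kb
    gt5 = summary["kb_gt5"] / kb
    out = pd.DataFrame({
        "sample_id": summary["sample_id"],
        # summed from the components so the length-class identity is bitwise
        "f_roh": lt5 + gt5,
        "f_roh_lt5": lt5,
        "f_roh_gt5": gt5,
    })
    return out


def _hom_terms(g: GenotypeMatrix, p: np.ndarray, variant_mask: np.ndarray | None = None):
    """Per-sample O(HOM), E(HOM) and N over a variant subset."""
    calls = g.calls if variant_mask is None else g.calls[:, variant_mask]
    pv = p if variant_mask is None else p[variant_mask]
    observed = calls >= 0
    hom = (calls == 0) | (calls == 2)
    exp_hom_site = 1.0 - 2.0 * pv * (1.0 - pv)
    o_hom = hom.sum(axis=1).astype(float)
    e_hom = observed @ exp_hom_site
    n = observed.sum(axis=1).astype(float)
    return o_hom, e_hom, n


def f_snp(g: GenotypeMatrix, freqs: AlleleFrequencies | None = None) -> np.ndarray:
    """Excess-homozygosity inbreeding estimate per sample.

    Undefined samples (every informative SNP monomorphic, N = E(HOM))
    come back as NaN.
    """
    if freqs is None:
        freqs = allele_frequencies(g)
    usable = freqs.n_obs > 0
    o_hom, e_hom, n = _hom_terms(g, np.nan_to_num(freqs.p), usable)
    denom = n - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(np.abs(denom) > 1e-9, (o_hom - e_hom) / denom, np.nan)
    return out


def _in_roh_mask(g: GenotypeMatrix, segments: list[ROHSegment]) -> np.ndarray:
    """Boolean samples x variants mask of SNPs inside each sample's ROH."""
    vm = g.variant_map
    sid_row = {str(s): i for i, s in enumerate(g.samples.sample_id)}
    mask = np.zeros(g.calls.shape, dtype=bool)
    for seg in segments:
        i = sid_row.get(seg.sample_id)
        if i is None:
            continue
        j = (vm.chrom == seg.chrom) & (vm.pos_bp >= seg.start_bp) & \
            (vm.pos_bp <= seg.end_bp)
        mask[i, j] = True
    return mask


def f_snp_outside_roh(g: GenotypeMatrix, segments: list[ROHSegment],
                      freqs: AlleleFrequencies | None = None) -> np.ndarray:
    """Excess homozygosity among SNPs outside each sample's called ROH.

    O'(HOM) = O(HOM) - (homozygous SNPs inside ROH);
    E'(HOM) = E(HOM) * (N - N_ROH) / N;  N' = N - N_ROH.
    NaN where N' = E'(HOM) (e.g. the whole genome inside ROH).
    """
    if freqs is None:
        freqs = allele_frequencies(g)
    usable = freqs.n_obs > 0
    p = np.nan_to_num(freqs.p)
    o_hom, e_hom, n = _hom_terms(g, p, usable)

    in_roh = _in_roh_mask(g, segments)[:, usable]
    calls = g.calls[:, usable]
    observed = calls >= 0
    hom = (calls == 0) | (calls == 2)
    n_snp_roh = (hom & in_roh).sum(axis=1).astype(float)
    n_roh = (observed & in_roh).sum(axis=1).astype(float)

    o_prime = o_hom - n_snp_roh
    with np.errstate(invalid="ignore", divide="ignore"):
        e_prime = np.where(n > 0, (n - n_roh) / n, np.nan) * e_hom
        n_prime = n - n_roh
        denom = n_prime - e_prime
        out = np.where(np.abs(denom) > 1e-9, (o_prime - e_prime) / denom, np.nan)
    return out


def f_grm(g: GenotypeMatrix, freqs: AlleleFrequencies | None = None) -> np.ndarray:
    """GRM-diagonal inbreeding estimator per sample.

    Monomorphic SNPs are excluded (the site term is undefined there);
    raises if no polymorphic SNP remains.
    """
    if freqs is None:
        freqs = allele_frequencies(g)
    poly = (freqs.n_obs > 0) & (freqs.p > 0) & (freqs.p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs for the GRM estimator")
    p = freqs.p[poly]
    calls = g.calls[:, poly]
    observed = calls >= 0
    x = np.where(observed, calls, 0).astype(float)
    site = (x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p) / (2.0 * p * (1.0 - p))
    site = np.where(observed, site, 0.0)
    n = observed.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n > 0, site.sum(axis=1) / n, np.nan)
    return out


def excess_homozygosity_by_maf(g: GenotypeMatrix, bins: list[tuple[float, float]],
                               freqs: AlleleFrequencies | None = None) -> pd.DataFrame:
    """Per-sample excess homozygosity restricted to MAF bins.

    ``bins`` are (low, high] MAF intervals.  The excess-homozygosity
    formula is evaluated on each bin's SNPs alone; bins whose SNPs are
    all monomorphic (or empty) give NaN columns and are flagged in the
    ``empty_bins`` attribute of the returned frame.
    """
    if freqs is None:
        freqs = allele_frequencies(g)
    maf = freqs.maf
    out = pd.DataFrame({"sample_id": g.samples.sample_id})
    empty = []
    for lo, hi in bins:
        col = f"f_maf_{lo:g}_{hi:g}"
        sel = (freqs.n_obs > 0) & (maf > lo) & (maf <= hi)
        if not sel.any():
            out[col] = np.nan
            empty.append((lo, hi))
            continue
        o_hom, e_hom, n = _hom_terms(g, np.nan_to_num(freqs.p), sel)
        denom = n - e_hom
        with np.errstate(invalid="ignore", divide="ignore"):
            out[col] = np.where(np.abs(denom) > 1e-9,
                                (o_hom - e_hom) / denom, np.nan)
        if np.all(np.isnan(out[col])):
            empty.append((lo, hi))
    out.attrs["empty_bins"] = empty
    return out


def inbreeding_profile(g: GenotypeMatrix, segments: list[ROHSegment],
                       summary: pd.DataFrame,
                       genome_size_bp: float = DEFAULT_GENOME_BP,
                       freqs: AlleleFrequencies | None = None) -> InbreedingProfile:
    """Assemble the full per-sample estimator table."""
    if freqs is None:
        freqs = allele_frequencies(g)
    froh = f_roh(summary, genome_size_bp).set_index("sample_id")
    order = [str(s) for s in g.samples.sample_id]
    froh = froh.reindex(order)
    table = pd.DataFrame({
        "sample_id": order,
        "f_roh": froh["f_roh"].to_numpy(),
        "f_roh_lt5": froh["f_roh_lt5"].to_numpy(),
        "f_roh_gt5": froh["f_roh_gt5"].to_numpy(),
        "f_snp": f_snp(g, freqs),
        "f_snp_outside_roh": f_snp_outside_roh(g, segments, freqs),
        "f_grm": f_grm(g, freqs),
    })
    return InbreedingProfile(table)


def cohort_f_summary(profile: InbreedingProfile) -> dict:
    """Cohort census: mean/sd of F_ROH and F_IS (mean per-sample F_SNP)."""
    t = profile.table
    if len(t) < 2:
        raise ValueError("need at least two samples for a cohort summary")
    return {
        "n": int(len(t)),
        "mean_f_roh": float(t["f_roh"].mean()),
        "sd_f_roh": float(t["f_roh"].std(ddof=1)),
        "f_is": float(np.nanmean(t["f_snp"])),
    }
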