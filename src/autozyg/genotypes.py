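"""Genotype matrices, variant maps, sample tables and array QC.

The in-memory model is a :class:`GenotypeMatrix`: an ``int8`` samples x
variants array of counted-allele dosages in {0, 1, 2} with ``-1`` marking a
missing call, plus a :class:`VariantMap` (physical map, 1-based bp) and a
:class:`SampleTable` (ids, pedigree links, sex).  I/O covers the PLINK
ped/map text dialect and the bed/bim/fam binary dialect (SNP-major).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

_AUTOSOMES = {str(i) for i in range(1, 23)}


class GenotypeFormatError(ValueError):
    """Malformed or mutually inconsistent genotype files."""


class EmptyResultError(ValueError):
    """A filter removed every variant (or every sample)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class VariantMap:
    """Physical map for the variants of a genotype matrix.

    Positions are 1-based inclusive base pairs and must be strictly
    increasing within each chromosome.  Only autosomes (or labels the
    caller declares autosomal) are admitted.
    """

    chrom: np.ndarray          # str labels, one per variant
    pos_bp: np.ndarray         # int64, 1-based
    ids: np.ndarray            # str variant identifiers
    a1: np.ndarray             # counted allele label
    a2: np.ndarray             # other allele label

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.ids = np.asarray(self.ids, dtype=object)
        self.a1 = np.asarray(self.a1, dtype=object)
        self.a2 = np.asarray(self.a2, dtype=object)
        n = len(self.chrom)
        if not (len(self.pos_bp) == len(self.ids) == len(self.a1) == len(self.a2) == n):
            raise GenotypeFormatError("variant map fields have unequal lengths")
        for c in self.chromosomes():
            pos = self.pos_bp[self.chrom == c]
            if len(pos) > 1 and not np.all(np.diff(pos) > 0):
                raise GenotypeFormatError(
                    f"positions not strictly increasing on chromosome {c}")

    def __len__(self) -> int:
        return len(self.chrom)

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        return list(dict.fromkeys(self.chrom.tolist()))

    def subset(self, mask: np.ndarray) -> "VariantMap":
        return VariantMap(self.chrom[mask], self.pos_bp[mask], self.ids[mask],
                          self.a1[mask], self.a2[mask])


@dataclass
class SampleTable:
    """Sample ids, optional pedigree links and sex.

    ``sex`` codes follow PLINK fam: 1 = male, 2 = female, 0 = unknown.
    For each sample the parent ids are either both present or both absent.
    """

    sample_id: np.ndarray
    family_id: np.ndarray
    father_id: np.ndarray
    mother_id: np.ndarray
    sex: np.ndarray            # int: 0 unknown, 1 male, 2 female

    def __post_init__(self) -> None:
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        self.family_id = np.asarray(self.family_id, dtype=object)
        self.father_id = np.asarray(self.father_id, dtype=object)
        self.mother_id = np.asarray(self.mother_id, dtype=object)
        self.sex = np.asarray(self.sex, dtype=np.int64)
        if len(set(self.sample_id)) != len(self.sample_id):
            raise GenotypeFormatError("duplicate sample ids")
        for sid, f, m in zip(self.sample_id, self.father_id, self.mother_id):
            if (f == "0") != (m == "0"):
                raise GenotypeFormatError(
                    f"sample {sid}: exactly one parent id given; need both or neither")

    def __len__(self) -> int:
        return len(self.sample_id)

    @classmethod
    def anonymous(cls, n: int, prefix: str = "S") -> "SampleTable":
        ids = np.array([f"{prefix}{i}" for i in range(n)], dtype=object)
        zeros = np.array(["0"] * n, dtype=object)
        return cls(ids, ids.copy(), zeros, zeros.copy(), np.zeros(n, dtype=np.int64))

    def subset(self, mask: np.ndarray) -> "SampleTable":
        return SampleTable(self.sample_id[mask], self.family_id[mask],
                           self.father_id[mask], self.mother_id[mask], self.sex[mask])


@dataclass
class GenotypeMatrix:
    """Samples x variants counted-allele dosages with map and sample table."""

    calls: np.ndarray
    variant_map: VariantMap
    samples: SampleTable

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise GenotypeFormatError("calls must be 2-D (samples x variants)")
        ns, nv = self.calls.shape
        if nv != len(self.variant_map):
            raise GenotypeFormatError(
                f"{nv} call columns but {len(self.variant_map)} mapped variants")
        if ns != len(self.samples):
            raise GenotypeFormatError(
                f"{ns} call rows but {len(self.samples)} samples")
        bad = ~np.isin(self.calls, (-1, 0, 1, 2))
        if bad.any():
            raise GenotypeFormatError("calls outside {0,1,2,missing}")

    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls[:, mask], self.variant_map.subset(mask),
                              self.samples)

    def subset_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls[mask], self.variant_map, self.samples.subset(mask))


@dataclass
class AlleleFrequencies:
    """Per-variant counted-allele frequency from non-missing calls only."""

    p: np.ndarray
    n_obs: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.n_obs = np.asarray(self.n_obs, dtype=np.int64)
        ok = self.n_obs > 0
        if np.any((self.p[ok] < 0) | (self.p[ok] > 1)):
            raise ValueError("allele frequency outside [0, 1]")

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.p, 1.0 - self.p)


@dataclass
class QCReport:
    """Counts removed by each QC rule, in application order."""

    n_variants_in: int
    n_samples_in: int
    n_variants_missingness: int = 0
    n_variants_maf: int = 0
    n_samples_missingness: int = 0
    n_variants_out: int = 0
    n_samples_out: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


# ---------------------------------------------------------------------------
# Frequencies and QC
# ---------------------------------------------------------------------------

def allele_frequencies(g: GenotypeMatrix) -> AlleleFrequencies:
    """Counted-allele frequency per variant, from non-missing calls.

    Variants with no non-missing call get ``n_obs == 0`` and ``p = nan``;
    downstream estimators must exclude them.
    """
    calls = g.calls
    observed = calls >= 0
    n_obs = observed.sum(axis=0)
    counts = np.where(observed, calls, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_obs > 0, counts / (2.0 * np.maximum(n_obs, 1)), np.nan)
    return AlleleFrequencies(p=p, n_obs=n_obs)


def qc_filter(g: GenotypeMatrix, max_snp_missing: float = 0.03,
              min_maf: float = 0.05, max_sample_missing: float = 0.03,
              ) -> tuple[GenotypeMatrix, QCReport]:
    """Array QC: drop poor variants first, then poor samples.

    A variant is removed when its call missingness exceeds
    ``max_snp_missing`` or its minor allele frequency is strictly below
    ``min_maf`` (a variant at exactly the threshold is kept).  Samples with
    missingness above ``max_sample_missing`` — computed on the variants
    that survived — are then removed.
    """
    for t in (max_snp_missing, min_maf, max_sample_missing):
        if not 0.0 <= t <= 1.0:
            raise ValueError("QC thresholds must lie in [0, 1]")
    report = QCReport(n_variants_in=g.n_variants, n_samples_in=g.n_samples)

    missing = g.calls < 0
    snp_miss_rate = missing.mean(axis=0) if g.n_samples else np.zeros(g.n_variants)
    freqs = allele_frequencies(g)
    with np.errstate(invalid="ignore"):
        maf = freqs.maf
    fail_miss = snp_miss_rate > max_snp_missing
    fail_maf = (freqs.n_obs == 0) | (maf < min_maf)
    report.n_variants_missingness = int(fail_miss.sum())
    report.n_variants_maf = int(fail_maf.sum())
    keep_v = ~(fail_miss | fail_maf)
    if not keep_v.any():
        raise EmptyResultError("QC removed every variant")
    g2 = g.subset_variants(keep_v)

    sample_miss_rate = (g2.calls < 0).mean(axis=1)
    keep_s = sample_miss_rate <= max_sample_missing
    report.n_samples_missingness = int((~keep_s).sum())
    if not keep_s.any():
        raise EmptyResultError("QC removed every sample")
    g3 = g2.subset_samples(keep_s)
    report.n_variants_out = g3.n_variants
    report.n_samples_out = g3.n_samples
    return g3, report


# ---------------------------------------------------------------------------
# PLINK text dialect (ped/map)
# ---------------------------------------------------------------------------

def _read_map(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if df.shape[1] == 4:
        df.columns = ["chrom", "id", "cm", "pos"]
    elif df.shape[1] == 3:
        df.columns = ["chrom", "id", "pos"]
        df["cm"] = "0"
    else:
        raise GenotypeFormatError(f"{path}: map file needs 3 or 4 columns")
    return df


def _read_ped_map(prefix: Path) -> GenotypeMatrix:
    map_df = _read_map(prefix.with_suffix(".map"))
    nv = len(map_df)
    fam_rows, geno_rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * nv:
                raise GenotypeFormatError(
                    f"ped line has {len(parts)} fields, expected {6 + 2 * nv}")
            fam_rows.append(parts[:6])
            geno_rows.append(parts[6:])
    if not fam_rows and nv == 0:
        fam_rows = []
    alleles1 = np.array([a[0::2] for a in geno_rows], dtype=object) if geno_rows \
        else np.empty((0, nv), dtype=object)
    alleles2 = np.array([a[1::2] for a in geno_rows], dtype=object) if geno_rows \
        else np.empty((0, nv), dtype=object)

    a1_labels = np.empty(nv, dtype=object)
    a2_labels = np.empty(nv, dtype=object)
    calls = np.full((len(fam_rows), nv), MISSING, dtype=np.int8)
    for j in range(nv):
        col = np.concatenate([alleles1[:, j], alleles2[:, j]]) if len(fam_rows) else np.array([])
        seen = sorted(set(col.tolist()) - {"0"})
        if len(seen) > 2:
            raise GenotypeFormatError(
                f"variant {map_df['id'][j]}: more than two alleles {seen}")
        a1 = seen[0] if seen else "A"
        a2 = seen[1] if len(seen) > 1 else a1
        a1_labels[j], a2_labels[j] = a1, a2
        if len(fam_rows):
            c1, c2 = alleles1[:, j], alleles2[:, j]
            miss = (c1 == "0") | (c2 == "0")
            calls[:, j] = (c1 == a1).astype(np.int8) + (c2 == a1).astype(np.int8)
            calls[miss, j] = MISSING

    fam = np.array(fam_rows, dtype=object).reshape(len(fam_rows), 6)
    samples = SampleTable(
        sample_id=fam[:, 1] if len(fam_rows) else np.array([], dtype=object),
        family_id=fam[:, 0] if len(fam_rows) else np.array([], dtype=object),
        father_id=fam[:, 2] if len(fam_rows) else np.array([], dtype=object),
        mother_id=fam[:, 3] if len(fam_rows) else np.array([], dtype=object),
        sex=fam[:, 4].astype(int) if len(fam_rows) else np.array([], dtype=np.int64),
    )
    vmap = VariantMap(map_df["chrom"].to_numpy(dtype=object),
                      map_df["pos"].astype(np.int64).to_numpy(),
                      map_df["id"].to_numpy(dtype=object), a1_labels, a2_labels)
    return GenotypeMatrix(calls, vmap, samples)


def _write_ped_map(g: GenotypeMatrix, prefix: Path) -> list[Path]:
    vm = g.variant_map
    map_path = prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for c, vid, pos in zip(vm.chrom, vm.ids, vm.pos_bp):
            fh.write(f"{c}\t{vid}\t0\t{pos}\n")
    ped_path = prefix.with_suffix(".ped")
    st = g.samples
    with open(ped_path, "w") as fh:
        for i in range(g.n_samples):
            fields = [str(st.family_id[i]), str(st.sample_id[i]),
                      str(st.father_id[i]), str(st.mother_id[i]),
                      str(st.sex[i]), "-9"]
            row = g.calls[i]
            for j, x in enumerate(row):
                if x < 0:
                    fields += ["0", "0"]
                elif x == 2:
                    fields += [str(vm.a1[j]), str(vm.a1[j])]
                elif x == 1:
                    fields += [str(vm.a1[j]), str(vm.a2[j])]
                else:
                    fields += [str(vm.a2[j]), str(vm.a2[j])]
            fh.write(" ".join(fields) + "\n")
    return [ped_path, map_path]


# ---------------------------------------------------------------------------
# PLINK binary dialect (bed/bim/fam), SNP-major
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b\x01"
# 2-bit codes, counted allele = A1: 00 -> 2 copies, 10 -> 1, 11 -> 0, 01 -> missing
_CODE_FROM_DOSAGE = {2: 0b00, 1: 0b10, 0: 0b11, -1: 0b01}
_DOSAGE_FROM_CODE = np.array([2, -1, 1, 0], dtype=np.int8)


def _read_bed(prefix: Path) -> GenotypeMatrix:
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"], dtype=str)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str)
    nv, ns = len(bim), len(fam)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise GenotypeFormatError("bad bed magic bytes (need SNP-major v1.00)")
    body = raw[3:]
    bytes_per_snp = (ns + 3) // 4
    if len(body) != bytes_per_snp * nv:
        raise GenotypeFormatError(
            f"bed payload {len(body)} bytes, expected {bytes_per_snp * nv}")
    if nv and ns:
        mat = body.reshape(nv, bytes_per_snp)
        shifts = np.arange(4, dtype=np.uint8) * 2
        codes = (mat[:, :, None] >> shifts[None, None, :]) & 0b11
        codes = codes.reshape(nv, bytes_per_snp * 4)[:, :ns]
        calls = _DOSAGE_FROM_CODE[codes].T.copy()
    else:
        calls = np.empty((ns, nv), dtype=np.int8)
    vmap = VariantMap(bim["chrom"].to_numpy(dtype=object),
                      bim["pos"].astype(np.int64).to_numpy(),
                      bim["id"].to_numpy(dtype=object),
                      bim["a1"].to_numpy(dtype=object),
                      bim["a2"].to_numpy(dtype=object))
    samples = SampleTable(fam["iid"].to_numpy(dtype=object),
                          fam["fid"].to_numpy(dtype=object),
                          fam["pat"].to_numpy(dtype=object),
                          fam["mat"].to_numpy(dtype=object),
                          fam["sex"].astype(int).to_numpy())
    return GenotypeMatrix(calls, vmap, samples)


def _write_bed(g: GenotypeMatrix, prefix: Path) -> list[Path]:
    vm, st = g.variant_map, g.samples
    bim_path = prefix.with_suffix(".bim")
    with open(bim_path, "w") as fh:
        for c, vid, pos, a1, a2 in zip(vm.chrom, vm.ids, vm.pos_bp, vm.a1, vm.a2):
            fh.write(f"{c}\t{vid}\t0\t{pos}\t{a1}\t{a2}\n")
    fam_path = prefix.with_suffix(".fam")
    with open(fam_path, "w") as fh:
        for i in range(g.n_samples):
            fh.write(f"{st.family_id[i]}\t{st.sample_id[i]}\t{st.father_id[i]}"
                     f"\t{st.mother_id[i]}\t{st.sex[i]}\t-9\n")
    bed_path = prefix.with_suffix(".bed")
    ns, nv = g.n_samples, g.n_variants
    bytes_per_snp = (ns + 3) // 4
    lut = np.zeros(4, dtype=np.uint8)
    for dosage, code in _CODE_FROM_DOSAGE.items():
        lut[dosage % 4] = code       # dosage -1 maps to index 3
    codes = lut[g.calls.T % 4]       # (nv, ns)
    padded = np.zeros((max(nv, 1), bytes_per_snp * 4), dtype=np.uint8)
    if nv and ns:
        padded[:, :ns] = codes
    shifts = np.arange(4, dtype=np.uint8) * 2
    packed = (padded.reshape(max(nv, 1), bytes_per_snp, 4) << shifts).sum(
        axis=2, dtype=np.uint16).astype(np.uint8)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC)
        if nv:
            packed.tofile(fh)
    return [bed_path, bim_path, fam_path]


# ---------------------------------------------------------------------------
# Public I/O
# ---------------------------------------------------------------------------

def read_genotypes(prefix: str | Path, dialect: str = "bed") -> GenotypeMatrix:
    """Read a genotype file set given its path prefix.

    ``dialect`` is ``"bed"`` (PLINK binary bed/bim/fam) or ``"ped"``
    (ped/map text).  The counted allele is A1 of the bim file, or the
    lexicographically first observed allele for the text dialect.
    """
    prefix = Path(prefix)
    if dialect == "bed":
        return _read_bed(prefix)
    if dialect == "ped":
        return _read_ped_map(prefix)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_genotypes(g: GenotypeMatrix, prefix: str | Path,
                    dialect: str = "bed") -> list[Path]:
    """Write ``g`` under ``prefix``; returns the paths written."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "bed":
        return _write_bed(g, prefix)
    if dialect == "ped":
        return _write_ped_map(g, prefix)
    raise ValueError(f"unknown dialect {dialect!r}")
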