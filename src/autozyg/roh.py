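"""Sliding-window detection of runs of homozygosity (ROH).

The caller mirrors the classic SNP-array windowed scan: a fixed-size
window of consecutive SNPs slides one SNP at a time along each
chromosome; a window is scored homozygous when it contains at most
``window_het`` heterozygous and ``window_missing`` missing calls; a SNP
becomes ROH-eligible when the proportion of homozygous windows among all
windows containing it reaches ``window_hit_threshold``; maximal runs of
eligible SNPs are split at large inter-SNP gaps, trimmed so they start
and end on a homozygous non-missing call, and kept if they satisfy the
SNP-count, length and SNP-density thresholds.

Defaults correspond to array-scale consanguinity scans: 50-SNP windows,
>= 50 SNPs and >= 1500 kb per run, <= 1000 kb gaps, <= 50 kb/SNP density,
and a 5% MAF floor applied before scanning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import AlleleFrequencies, GenotypeMatrix, allele_frequencies


@dataclass
class ROHParams:
    """Windowed ROH-scan parameters (counts in SNPs, sizes in kb)."""

    window_snp: int = 50
    min_snp: int = 50
    min_kb: float = 1500.0
    max_gap_kb: float = 1000.0
    max_density_kb_per_snp: float = 50.0
    window_missing: int = 5
    window_het: int = 1
    window_hit_threshold: float = 0.05
    maf_floor: float = 0.05

    def __post_init__(self) -> None:
        for name in ("window_snp", "min_snp", "window_missing", "window_het"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.window_hit_threshold <= 1.0:
            raise ValueError("window_hit_threshold must lie in (0, 1]")


@dataclass
class ROHSegment:
    """One called run: bp span of its first and last SNP, 1-based inclusive."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def _segment_ok(length_bp: int, n_snps: int, p: ROHParams) -> bool:
    if n_snps < p.min_snp:
        return False
    if length_bp < p.min_kb * 1000.0:
        return False
    if n_snps and length_bp / n_snps > p.max_density_kb_per_snp * 1000.0:
        return False
    return True


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of maximal True runs, stop exclusive."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, len(mask)]
    return list(zip(starts.tolist(), stops.tolist()))


def call_roh(g: GenotypeMatrix, params: ROHParams | None = None,
             freqs: AlleleFrequencies | None = None) -> list[ROHSegment]:
    """Call ROH for every sample of ``g``.

    SNPs below the MAF floor (in-sample frequencies unless ``freqs`` is
    supplied) are removed before scanning.  Chromosomes with fewer SNPs
    than one window are skipped with a warning.  Output order is by
    sample, then chromosome, then position — independent of input sample
    order.
    """
    params = params or ROHParams()
    if freqs is None:
        freqs = allele_frequencies(g)
    with np.errstate(invalid="ignore"):
        keep = freqs.maf >= params.maf_floor
    keep &= freqs.n_obs > 0
    g = g.subset_variants(keep)

    segments: list[ROHSegment] = []
    vm = g.variant_map
    w = params.window_snp
    for chrom in vm.chromosomes():
        vidx = np.flatnonzero(vm.chrom == chrom)
        pos = vm.pos_bp[vidx]
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"variant map not sorted on chromosome {chrom}")
        nv = len(vidx)
        if nv < w:
            warnings.warn(f"chromosome {chrom}: {nv} SNPs < window of {w}; skipped")
            continue
        calls = g.calls[:, vidx]
        het = calls == 1
        miss = calls < 0

        # window sums over the SNP axis (windows fully inside the chromosome)
        def wsum(x: np.ndarray) -> np.ndarray:
            c = np.cumsum(x, axis=1, dtype=np.int32)
            c = np.concatenate([np.zeros((x.shape[0], 1), np.int32), c], axis=1)
            return c[:, w:] - c[:, :-w]

        hom_win = (wsum(het) <= params.window_het) & \
                  (wsum(miss) <= params.window_missing)          # (ns, nv-w+1)
        n_win = hom_win.shape[1]
        # windows containing SNP j are those starting in [j-w+1, j], clipped
        lo = np.clip(np.arange(nv) - w + 1, 0, n_win - 1)
        hi = np.clip(np.arange(nv), 0, n_win - 1) + 1
        cwin = np.concatenate([np.zeros((hom_win.shape[0], 1), np.int32),
                               np.cumsum(hom_win, axis=1, dtype=np.int32)], axis=1)
        hits = cwin[:, hi] - cwin[:, lo]
        denom = (hi - lo).astype(float)
        eligible = hits / denom >= params.window_hit_threshold    # (ns, nv)

        gap_bp = params.max_gap_kb * 1000.0
        for s in range(g.n_samples):
            sid = str(g.samples.sample_id[s])
            for a, b in _runs(eligible[s]):
                # split at inter-SNP gaps larger than the allowance
                cut_pts = np.flatnonzero(np.diff(pos[a:b]) > gap_bp) + a + 1
                bounds = [a, *cut_pts.tolist(), b]
                for i0, i1 in zip(bounds[:-1], bounds[1:]):
                    # trim to homozygous, non-missing endpoints
                    j0, j1 = i0, i1
                    while j0 < j1 and (het[s, j0] or miss[s, j0]):
                        j0 += 1
                    while j1 > j0 and (het[s, j1 - 1] or miss[s, j1 - 1]):
                        j1 -= 1
                    n_snps = j1 - j0
                    if n_snps == 0:
                        continue
                    length = int(pos[j1 - 1] - pos[j0])
                    if _segment_ok(length, n_snps, params):
                        segments.append(ROHSegment(sid, str(chrom),
                                                   int(pos[j0]), int(pos[j1 - 1]),
                                                   n_snps))
    segments.sort(key=lambda r: (r.sample_id, r.chrom, r.start_bp))
    return segments


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    """`.hom`-style table: one row per called segment."""
    return pd.DataFrame(
        [(r.sample_id, r.chrom, r.start_bp, r.end_bp, r.length_bp / 1000.0,
          r.n_snps) for r in segments],
        columns=["sample_id", "chrom", "start_bp", "end_bp", "kb", "n_snps"])


def roh_sample_summary(segments: list[ROHSegment], sample_ids,
                       long_threshold_bp: float = 5_000_000.0) -> pd.DataFrame:
    """Per-sample totals split at the long/short boundary (default 5 Mb).

    Segments at exactly the boundary count as long.  Samples with no
    segments are reported with zeros.
    """
    rows = {str(sid): [0, 0.0, 0, 0, 0.0, 0.0] for sid in sample_ids}
    for r in segments:
        if r.sample_id not in rows:
            raise KeyError(f"segment sample {r.sample_id!r} not in sample list")
        rec = rows[r.sample_id]
        rec[0] += 1
        rec[1] += r.length_bp / 1000.0
        if r.length_bp >= long_threshold_bp:
            rec[3] += 1
            rec[5] += r.length_bp / 1000.0
        else:
            rec[2] += 1
            rec[4] += r.length_bp / 1000.0
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["n_segments", "kb_total", "n_lt5",
                                         "n_gt5", "kb_lt5", "kb_gt5"])
    df.index.name = "sample_id"
    return df.reset_index()
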