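"""Runs of homozygosity and uniparental disomy.

A run is a maximal stretch of consecutive markers in one sample satisfying
all of: span at least ``window_kb`` (5 Mb) with at least ``min_snps`` (50)
markers, at most ``max_het`` (1) heterozygote and ``max_missing`` (5) missing
calls, and no gap between consecutive markers longer than ``max_gap_kb``
(100 kb).  Runs are found by direct maximal-run search under these
constraints; het/missing budgets apply per final segment.  A chromosome whose
genotyped span is almost fully covered by runs in one sample is flagged as
candidate uniparental isodisomy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypePanel

logger = logging.getLogger(__name__)


@dataclass
class ROHSegment:
    sample: str
    chrom: int
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def _segments_for_block(
    pos: np.ndarray,
    doses: np.ndarray,
    min_bp: float,
    min_snps: int,
    max_het: int,
    max_missing: int,
) -> list[tuple[int, int]]:
    """Maximal index runs within one gap-free block under het/missing budgets."""
    n = pos.size
    het = doses == 1
    miss = np.isnan(doses)
    segments = []
    e_prev = -1
    e = -1
    n_het = n_miss = 0
    for s in range(n):
        if e < s - 1:
            e = s - 1
            n_het = n_miss = 0
        while e + 1 < n:
            nh = n_het + het[e + 1]
            nm = n_miss + miss[e + 1]
            if nh > max_het or nm > max_missing:
                break
            e += 1
            n_het, n_miss = nh, nm
        if e > e_prev:
            segments.append((s, e))
            e_prev = e
        n_het -= het[s]
        n_miss -= miss[s]
    return segments


def _trim(pos, doses, s, e):
    """Shrink a run so it starts and ends on a homozygous call."""
    hom = (doses == 0) | (doses == 2)
    while s <= e and not hom[s]:
        s += 1
    while e >= s and not hom[e]:
        e -= 1
    return s, e


def call_roh(
    panel: GenotypePanel,
    window_kb: float = 5000.0,
    min_snps: int = 50,
    max_het: int = 1,
    max_missing: int = 5,
    max_gap_kb: float = 100.0,
) -> list[ROHSegment]:
    """Detect runs of homozygosity in every sample.

    Returns non-overlapping maximal segments per sample and chromosome
    (overlapping maximal candidates are resolved greedily, longest span
    first).
    """
    chroms = panel.variants["chrom"].to_numpy()
    positions = panel.variants["pos"].to_numpy()
    min_bp = window_kb * 1000.0
    max_gap_bp = max_gap_kb * 1000.0
    out: list[ROHSegment] = []
    for j, sid in enumerate(panel.sample_ids):
        row = panel.doses[j]
        for c in pd.unique(chroms):
            idx = np.flatnonzero(chroms == c)
            pos = positions[idx]
            d = row[idx]
            # split at gaps exceeding the limit
            cuts = np.flatnonzero(np.diff(pos) > max_gap_bp)
            blocks = np.split(np.arange(pos.size), cuts + 1)
            candidates: list[tuple[int, int]] = []
            for blk in blocks:
                if blk.size < min_snps:
                    continue
                for s, e in _segments_for_block(
                    pos[blk], d[blk], min_bp, min_snps, max_het, max_missing
                ):
                    s2, e2 = _trim(pos[blk], d[blk], s, e)
                    if e2 < s2:
                        continue
                    a, b = blk[s2], blk[e2]
                    if b - a + 1 >= min_snps and pos[b] - pos[a] + 1 >= min_bp:
                        candidates.append((a, b))
            # greedy non-overlap resolution, longest span first
            candidates = sorted(
                set(candidates), key=lambda t: (-(pos[t[1]] - pos[t[0]]), t[0])
            )
            taken: list[tuple[int, int]] = []
            for a, b in candidates:
                if any(a <= tb and b >= ta for ta, tb in taken):
                    continue
                taken.append((a, b))
            for a, b in sorted(taken):
                seg = d[a : b + 1]
                out.append(
                    ROHSegment(
                        sample=sid,
                        chrom=int(c),
                        start_bp=int(pos[a]),
                        end_bp=int(pos[b]),
                        n_snps=int(b - a + 1),
                        n_het=int((seg == 1).sum()),
                        n_missing=int(np.isnan(seg).sum()),
                    )
                )
    return out


def roh_summary(segments: list[ROHSegment], sample_ids) -> pd.DataFrame:
    """Per-sample segment count and total length (kb), including zero rows."""
    df = pd.DataFrame(
        {
            "sample": [s.sample for s in segments],
            "length_kb": [s.length_bp / 1000.0 for s in segments],
        }
    )
    agg = df.groupby("sample").agg(n_segments=("length_kb", "size"), total_kb=("length_kb", "sum"))
    out = agg.reindex(sample_ids, fill_value=0.0)
    out["n_segments"] = out["n_segments"].astype(int)
    out.index.name = "sample"
    return out.reset_index()


def segments_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    """Segment table mirroring the PLINK .hom column layout."""
    return pd.DataFrame(
        {
            "FID": [s.sample for s in segments],
            "IID": [s.sample for s in segments],
            "CHR": [s.chrom for s in segments],
            "POS1": [s.start_bp for s in segments],
            "POS2": [s.end_bp for s in segments],
            "KB": [s.length_bp / 1000.0 for s in segments],
            "NSNP": [s.n_snps for s in segments],
            "NHET": [s.n_het for s in segments],
            "NMISS": [s.n_missing for s in segments],
        }
    )


def flag_upd(
    panel: GenotypePanel, segments: list[ROHSegment], min_fraction: float = 0.99
) -> list[tuple[str, int]]:
    """Flag (sample, chromosome) pairs whose genotyped span is nearly fully
    covered by runs of homozygosity — candidate uniparental isodisomy."""
    chroms = panel.variants["chrom"].to_numpy()
    positions = panel.variants["pos"].to_numpy()
    span = {}
    for c in pd.unique(chroms):
        p = positions[chroms == c]
        span[int(c)] = p.max() - p.min() + 1
    cov: dict[tuple[str, int], float] = {}
    for s in segments:
        cov[(s.sample, s.chrom)] = cov.get((s.sample, s.chrom), 0.0) + s.length_bp
    return sorted(k for k, v in cov.items() if v / span[k[1]] >= min_fraction)


def rarity_roh_regression(
    profile_frame: pd.DataFrame, roh_frame: pd.DataFrame
) -> dict[str, dict[str, float]]:
    """Least-squares fits of rarity score on ROH burden.

    Returns slope, correlation and two-sided p for score ~ total_kb and
    score ~ n_segments over the shared samples.
    """
    merged = profile_frame.merge(roh_frame, on="sample")
    if len(merged) < 3:
        raise ValueError("need at least three shared samples")
    out = {}
    for key, col in (("total_length", "total_kb"), ("n_segments", "n_segments")):
        fit = stats.linregress(merged[col].astype(float), merged["total_score"].astype(float))
        out[key] = {"slope": fit.slope, "r": fit.rvalue, "p": fit.pvalue}
    return out
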