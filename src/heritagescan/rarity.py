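"""Rare-allele scores, windowed peak calling, outlier classification and
origin assignment.

Three per-marker scores quantify how rare-allele sharing drives the
frequency-weighted relationship estimator:

* individual marker score  (x - 2p) / sqrt(2 p (1 - p))
* pair marker score        (x_j - 2p)(x_k - 2p) / (2 p (1 - p))
  (the product of the two individual scores; its mean over markers is the
  GRM off-diagonal)
* rarity score             sum over carried markers of 1 / (x * p)

The rarity score is computed with doses oriented to the minor allele, so a
single copy of an allele at frequency p contributes 1/p.  Chromosomes are cut
into non-overlapping 50-SNP windows; windows whose mean per-marker term
exceeds 50 seed "rare peaks" — candidate introgressed haplotypes — which merge
across gaps of fewer than 10 sub-threshold windows.  Individuals whose total
peak coverage exceeds the cohort mean plus three standard deviations are
classified as rare-ancestry outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import FrequencyTable, GenotypePanel, compute_freqs, orient_minor

logger = logging.getLogger(__name__)


def copy_number_cutoffs(n_samples: int, max_copies: float = 8.0, window: int = 50):
    """Cohort-size-faithful rarity thresholds anchored on allele copy number.

    With panel-derived frequencies the smallest attainable frequency is one
    copy in 2n chromosomes, so per-marker rarity terms scale with cohort
    size; absolute thresholds calibrated on one cohort do not transfer to
    another.  Two copy-number-anchored quantities do transfer:

    * the marker-selection cutoff 2n / max_copies — the score of a
      single-copy allele seen ``max_copies`` times or fewer in the cohort
      (about 2,500, i.e. p <= 0.0004, at 2n = 19,778 chromosomes);
    * the window threshold 2 x 2n / window — two cohort singletons' worth of
      rarity mass per window.  A lone singleton is indistinguishable from an
      isolated private mutation (or a genotyping error), so a window must
      carry at least two singletons' excess mass before it is treated as part
      of a rare haplotype in a small cohort.

    Returns ``(score_cutoff, window_threshold)``.
    """
    score_cutoff = 2.0 * n_samples / max_copies
    return score_cutoff, 2.0 * (2.0 * n_samples) / window


def individual_marker_score(x, p):
    """(x - 2p) / sqrt(2 p (1 - p)); undefined (NaN) where p is not in (0, 1)."""
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return np.where((p > 0) & (p < 1), out, np.nan)


def pair_marker_score(x_j, x_k, p):
    """(x_j - 2p)(x_k - 2p) / (2 p (1 - p)) — the product of the two
    individual marker scores."""
    x_j = np.asarray(x_j, dtype=float)
    x_k = np.asarray(x_k, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (x_j - 2.0 * p) * (x_k - 2.0 * p) / (2.0 * p * (1.0 - p))
    return np.where((p > 0) & (p < 1), out, np.nan)


def rarity_terms(doses, p, external_freqs: bool = False):
    """Per-marker rarity terms 1/(x*p) for carried markers, 0 where x = 0.

    ``doses`` must count the minor allele.  Markers with undefined p (outside
    (0,1)) contribute 0 and are effectively excluded; a carried allele at
    p = 0 is impossible for panel-derived frequencies and raises when
    *external_freqs* is set.
    """
    x = np.asarray(doses, dtype=float)
    p = np.asarray(p, dtype=float)
    carried = np.nan_to_num(x) > 0
    valid = (p > 0) & (p < 1)
    if external_freqs and np.any(carried & (p == 0)):
        raise ValueError("carried allele with external frequency 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = 1.0 / (x * p)
    return np.where(carried & valid, terms, 0.0)


def rarity_score(doses, p, external_freqs: bool = False):
    """Total rarity score and its per-marker terms for one sample."""
    terms = rarity_terms(doses, p, external_freqs=external_freqs)
    return float(terms.sum()), terms


@dataclass
class RarePeak:
    """A run of high-scoring windows on one chromosome for one sample.

    Coordinates span the first SNP of the first member window to the last SNP
    of the last member window, 1-based inclusive.
    """

    sample: str
    chrom: int
    start_bp: int
    end_bp: int
    first_window: int
    last_window: int
    n_windows: int
    mean_score: float

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class RarityProfile:
    """Per-sample rarity summary: total score, called peaks, coverage, flag."""

    sample: str
    total_score: float
    peaks: list[RarePeak] = field(default_factory=list)
    outlier: bool | None = None

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def coverage_bp(self) -> int:
        return int(sum(p.length_bp for p in self.peaks))


def window_rarity(
    terms: np.ndarray,
    chroms: np.ndarray,
    positions: np.ndarray,
    window: int = 50,
) -> pd.DataFrame:
    """Mean per-marker term over non-overlapping *window*-SNP windows.

    Markers must be position-sorted within chromosomes.  Zero-dose markers
    enter the mean as 0 with the window size in the denominator; the trailing
    partial window of each chromosome is averaged over its actual marker count
    and flagged ``partial``.
    """
    rows = []
    w = 0
    for c in pd.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        for s in range(0, idx.size, window):
            sl = idx[s : s + window]
            rows.append(
                {
                    "window": w,
                    "chrom": c,
                    "start_bp": int(positions[sl[0]]),
                    "end_bp": int(positions[sl[-1]]),
                    "n_markers": int(sl.size),
                    "mean_score": float(terms[sl].sum() / sl.size),
                    "partial": sl.size < window,
                }
            )
            w += 1
    return pd.DataFrame(rows)


def call_rare_peaks(
    windows: pd.DataFrame,
    sample: str = "",
    threshold: float = 50.0,
    max_gap: int = 10,
    window: int = 50,
    min_seed_markers: int = 10,
) -> list[RarePeak]:
    """Merge above-threshold windows into rare peaks.

    Windows with mean score strictly above *threshold* seed peaks; seeds on
    the same chromosome separated by fewer than *max_gap* sub-threshold
    windows merge into one peak that includes the in-between windows.
    Trailing partial windows are seeded on their rarity mass relative to the
    nominal *window* size (a lone rare allele in a short trailing window
    would otherwise be inflated by the small denominator), and partial
    windows shorter than *min_seed_markers* markers cannot seed a peak at all
    (they may still be absorbed between two seeds).
    """
    peaks: list[RarePeak] = []
    for c, grp in windows.groupby("chrom", sort=False):
        grp = grp.sort_values("window").reset_index(drop=True)
        mass_mean = grp["mean_score"] * grp["n_markers"] / window
        hot = (
            np.where(grp["partial"], mass_mean, grp["mean_score"]) > threshold
        ) & ~(grp["partial"] & (grp["n_markers"] < min_seed_markers)).to_numpy()
        hot = pd.Series(hot)
        seeds = np.flatnonzero(hot.to_numpy())
        if seeds.size == 0:
            continue
        runs: list[list[int]] = [[seeds[0], seeds[0]]]
        for s in seeds[1:]:
            if s - runs[-1][1] - 1 < max_gap:  # fewer than max_gap windows between
                runs[-1][1] = s
            else:
                runs.append([s, s])
        for a, b in runs:
            member = grp.iloc[a : b + 1]
            peaks.append(
                RarePeak(
                    sample=sample,
                    chrom=int(c),
                    start_bp=int(member.iloc[0]["start_bp"]),
                    end_bp=int(member.iloc[-1]["end_bp"]),
                    first_window=int(member.iloc[0]["window"]),
                    last_window=int(member.iloc[-1]["window"]),
                    n_windows=len(member),
                    mean_score=float(member["mean_score"].mean()),
                )
            )
    return peaks


def compute_profiles(
    panel: GenotypePanel,
    freqs: FrequencyTable | None = None,
    window: int = 50,
    threshold: float = 50.0,
    max_gap: int = 10,
) -> list[RarityProfile]:
    """Rarity profile for every sample in the panel.

    The panel is re-oriented so the counted allele is the minor allele before
    scoring (rare-allele scores are orientation-sensitive).  Frequencies
    default to the panel itself; supplying external frequencies is logged.
    """
    external = freqs is not None
    if external:
        logger.info("rarity: scoring against externally supplied frequencies")
        oriented, flipped = orient_minor(panel, freqs)
        p = np.where(flipped, 1.0 - freqs.freq, freqs.freq)
    else:
        oriented, _ = orient_minor(panel)
        p = compute_freqs(oriented).freq
    chroms = oriented.variants["chrom"].to_numpy()
    positions = oriented.variants["pos"].to_numpy()
    profiles = []
    for j, sid in enumerate(oriented.sample_ids):
        total, terms = rarity_score(oriented.doses[j], p, external_freqs=external)
        win = window_rarity(terms, chroms, positions, window=window)
        peaks = call_rare_peaks(
            win, sample=sid, threshold=threshold, max_gap=max_gap, window=window
        )
        profiles.append(RarityProfile(sample=sid, total_score=total, peaks=peaks))
    return profiles


def classify_rarity_outliers(
    profiles: list[RarityProfile], sd_mult: float = 3.0
) -> tuple[list[RarityProfile], pd.DataFrame]:
    """Flag samples whose total peak coverage exceeds mean + sd_mult * SD.

    Sets ``outlier`` on each profile in place and returns ``(profiles,
    summary)`` with a per-group summary (mean/max/min peak count and coverage)
    in the layout of the cohort peak-distribution table.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two samples to classify outliers")
    cov = np.array([p.coverage_bp for p in profiles], dtype=float)
    thresh = cov.mean() + sd_mult * cov.std()
    for p in profiles:
        p.outlier = bool(p.coverage_bp > thresh)
    rows = []
    for group, flag in (("non-outliers", False), ("outliers", True)):
        sub = [p for p in profiles if p.outlier == flag]
        n_peaks = np.array([p.n_peaks for p in sub], dtype=float)
        cvg = np.array([p.coverage_bp for p in sub], dtype=float) / 1e6
        for stat, f in (("mean", np.mean), ("max", np.max), ("min", np.min)):
            rows.append(
                {
                    "group": group,
                    "statistic": stat,
                    "n_peaks": f(n_peaks) if len(sub) else np.nan,
                    "coverage_mb": f(cvg) if len(sub) else np.nan,
                }
            )
    return profiles, pd.DataFrame(rows)


def profiles_to_frame(profiles: list[RarityProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [p.sample for p in profiles],
            "total_score": [p.total_score for p in profiles],
            "n_peaks": [p.n_peaks for p in profiles],
            "coverage_bp": [p.coverage_bp for p in profiles],
            "outlier": [p.outlier for p in profiles],
        }
    )


def peaks_to_frame(profiles: list[RarityProfile]) -> pd.DataFrame:
    """Peak table (1-based inclusive coordinates)."""
    rows = [
        {"chrom": pk.chrom, "start_bp": pk.start_bp, "end_bp": pk.end_bp,
         "sample": pk.sample, "mean_score": pk.mean_score, "n_windows": pk.n_windows}
        for p in profiles for pk in p.peaks
    ]
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "sample", "mean_score", "n_windows"])


def assign_allele_origin(
    panel: GenotypePanel,
    reference_freqs: pd.DataFrame,
    freqs: FrequencyTable | None = None,
    score_cutoff: float = 2500.0,
) -> pd.DataFrame:
    """Assign a likely origin population to high-scoring rare alleles.

    Markers whose per-marker rarity term exceeds *score_cutoff* in any sample
    are looked up in *reference_freqs* (rows indexed by marker id, one column
    per reference population, frequencies of the panel's minor allele); the
    origin is the population with the maximum frequency.  Markers missing from
    the reference are labelled "unknown".
    """
    oriented, flipped = orient_minor(panel, freqs)
    if freqs is not None:
        p = np.where(flipped, 1.0 - freqs.freq, freqs.freq)
    else:
        p = compute_freqs(oriented).freq
    max_term = np.zeros(panel.n_markers)
    for j in range(oriented.n_samples):
        terms = rarity_terms(oriented.doses[j], p)
        np.maximum(max_term, terms, out=max_term)
    selected = np.flatnonzero(max_term > score_cutoff)
    rows = []
    pops = list(reference_freqs.columns)
    for i in selected:
        mid = panel.marker_ids[i]
        if mid in reference_freqs.index:
            ref = reference_freqs.loc[mid]
            rec = {"marker": mid, "origin": ref.idxmax(), "panel_freq": p[i]}
            rec.update({f"freq_{c}": ref[c] for c in pops})
        else:
            rec = {"marker": mid, "origin": "unknown", "panel_freq": p[i]}
            rec.update({f"freq_{c}": np.nan for c in pops})
        rows.append(rec)
    return pd.DataFrame(rows)
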