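"""Genotype panels: PLINK bed/bim/fam I/O, allele frequencies, QC, LD pruning, merging.

The central container is :class:`GenotypePanel`, a samples x markers dose
matrix (copies of the counted allele, 0/1/2, NaN = missing) together with a
marker map and sample metadata.  Doses count the PLINK A1 allele as read from
disk; :func:`orient_minor` re-orients a panel so that the counted allele is the
minor allele, which the rare-allele scoring assumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

#: bed 2-bit code -> dose of the counted (A1) allele
_CODE_TO_DOSE = np.array([2.0, np.nan, 1.0, 0.0])

VARIANT_COLUMNS = ["id", "chrom", "pos", "a1", "a2"]
SAMPLE_COLUMNS = ["id", "sex", "age", "population", "lat", "lon", "residence"]

_AMBIGUOUS = {frozenset({"A", "T"}), frozenset({"C", "G"})}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class PlinkFormatError(ValueError):
    """Raised when a bed/bim/fam triple is malformed."""


def _as_variant_frame(variants: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table lacks columns {missing}")
    out = variants.reset_index(drop=True).copy()
    out["chrom"] = out["chrom"].astype(int)
    out["pos"] = out["pos"].astype(int)
    return out


def _as_sample_frame(samples: pd.DataFrame) -> pd.DataFrame:
    out = samples.reset_index(drop=True).copy()
    if "id" not in out.columns:
        raise ValueError("sample table lacks an 'id' column")
    for col in SAMPLE_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    return out


@dataclass
class GenotypePanel:
    """Samples x markers dose matrix with marker map and sample metadata.

    Parameters
    ----------
    variants : DataFrame with columns id, chrom, pos, a1, a2 (a1 = counted allele)
    samples : DataFrame with at least an id column (sex, age, population, lat,
        lon, residence are carried when present)
    doses : float array (n_samples, n_markers), entries in {0, 1, 2, NaN}
    """

    variants: pd.DataFrame
    samples: pd.DataFrame
    doses: np.ndarray

    def __post_init__(self) -> None:
        self.variants = _as_variant_frame(self.variants)
        self.samples = _as_sample_frame(self.samples)
        self.doses = np.asarray(self.doses, dtype=float)
        if self.doses.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dose matrix {self.doses.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} markers"
            )
        vals = self.doses[~np.isnan(self.doses)]
        if vals.size and not np.isin(vals, [0.0, 1.0, 2.0]).all():
            raise ValueError("doses must be 0, 1, 2 or NaN")
        if self.samples["id"].duplicated().any():
            logger.warning("duplicate sample ids present in panel")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.variants)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.samples["id"].to_numpy()

    @property
    def marker_ids(self) -> np.ndarray:
        return self.variants["id"].to_numpy()

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypePanel":
        """Return a panel restricted to the given positional indices."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypePanel(
            variants=self.variants.iloc[mi],
            samples=self.samples.iloc[si],
            doses=self.doses[np.ix_(si, mi)],
        )

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(self.variants.copy(), self.samples.copy(), self.doses.copy())


@dataclass
class FrequencyTable:
    """Per-marker counted-allele frequency with call counts.

    ``freq`` is the frequency of the counted (A1) allele over non-missing
    calls; markers with no calls have NaN frequency and are flagged in
    ``undefined``.  ``is_major`` flags markers where the counted allele is the
    major allele (candidates for re-orientation).
    """

    marker_id: np.ndarray
    freq: np.ndarray
    n_called: np.ndarray
    by_population: pd.DataFrame | None = None

    @property
    def undefined(self) -> np.ndarray:
        return self.n_called == 0

    @property
    def is_major(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.freq > 0.5

    @property
    def maf(self) -> np.ndarray:
        return np.minimum(self.freq, 1.0 - self.freq)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"id": self.marker_id, "freq": self.freq, "n_called": self.n_called}
        )
        if self.by_population is not None:
            df = df.join(self.by_population.add_prefix("freq_"))
        return df


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------

def decode_bed_bytes(raw: np.ndarray, n_samples: int) -> np.ndarray:
    """Decode SNP-major bed genotype bytes into a (n_samples, n_markers) dose matrix.

    Codes per the bed v1 format, read from the least-significant bit pair up:
    00 = two copies of A1, 01 = missing, 10 = heterozygote, 11 = zero copies.
    """
    n_bytes = (n_samples + 3) // 4
    if raw.size % n_bytes != 0:
        raise PlinkFormatError("bed payload is not a whole number of markers")
    n_markers = raw.size // n_bytes
    mat = raw.reshape(n_markers, n_bytes)
    codes = np.empty((n_markers, n_bytes * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (mat >> (2 * k)) & 0b11
    return _CODE_TO_DOSE[codes[:, :n_samples]].T


def encode_bed_bytes(doses: np.ndarray) -> bytes:
    """Encode a dose matrix as SNP-major bed genotype bytes (padding bits zero).

    Padding codes are 00; PLINK ignores them, and zeroing keeps write->read->
    write byte-stable.
    """
    n_samples, n_markers = doses.shape
    codes = np.zeros(doses.T.shape, dtype=np.uint8)
    d = doses.T
    codes[np.isnan(d)] = 1
    codes[d == 1] = 2
    codes[d == 0] = 3
    n_bytes = (n_samples + 3) // 4
    padded = np.zeros((n_markers, n_bytes * 4), dtype=np.uint8)
    padded[:, :n_samples] = codes
    out = np.zeros((n_markers, n_bytes), dtype=np.uint8)
    for k in range(4):
        out |= padded[:, k::4] << (2 * k)
    return out.tobytes()


def read_plink(prefix: str | Path) -> GenotypePanel:
    """Read a PLINK bed/bim/fam triple into a :class:`GenotypePanel`.

    Doses count the bim A1 allele.  Only v1 SNP-major bed files are accepted.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "id", "father", "mother", "sex_code", "pheno"],
        dtype={"id": str},
    )
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw.size < 3 or bytes(raw[:3]) != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes (not a v1 SNP-major bed)")
    n_samples, n_markers = len(fam), len(bim)
    payload = raw[3:]
    expected = n_markers * ((n_samples + 3) // 4)
    if payload.size != expected:
        raise PlinkFormatError(
            f"{prefix}.bed: {payload.size} genotype bytes, expected {expected}"
        )
    doses = decode_bed_bytes(payload, n_samples)
    sex = fam["sex_code"].map({1: "male", 2: "female"}).fillna("unknown")
    samples = pd.DataFrame({"id": fam["id"], "sex": sex})
    variants = bim[["id", "chrom", "pos", "a1", "a2"]]
    return GenotypePanel(variants=variants, samples=samples, doses=doses)


def write_plink(panel: GenotypePanel, prefix: str | Path) -> None:
    """Write *panel* as a bed/bim/fam triple readable by :func:`read_plink`."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    v = panel.variants
    bim = pd.DataFrame(
        {
            "chrom": v["chrom"],
            "id": v["id"],
            "cm": 0,
            "pos": v["pos"],
            "a1": v["a1"],
            "a2": v["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    s = panel.samples
    sex_code = s["sex"].map({"male": 1, "female": 2}).fillna(0).astype(int)
    fam = pd.DataFrame(
        {
            "fid": s["id"],
            "id": s["id"],
            "father": 0,
            "mother": 0,
            "sex_code": sex_code,
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(encode_bed_bytes(panel.doses))


# ---------------------------------------------------------------------------
# Frequencies
# ---------------------------------------------------------------------------

def compute_freqs(
    panel: GenotypePanel,
    subset: np.ndarray | None = None,
    by_population: bool = False,
) -> FrequencyTable:
    """Counted-allele frequency per marker over non-missing calls.

    Parameters
    ----------
    subset : optional boolean mask or index array over samples
    by_population : additionally compute frequencies within each
        ``samples.population`` label
    """
    doses = panel.doses if subset is None else panel.doses[np.asarray(subset)]
    called = ~np.isnan(doses)
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.nansum(doses, axis=0) / (2.0 * n_called)
    freq[n_called == 0] = np.nan
    by_pop = None
    if by_population:
        pops = panel.samples["population"]
        cols = {}
        for pop in pops.dropna().unique():
            mask = (pops == pop).to_numpy()
            d = panel.doses[mask]
            nc = (~np.isnan(d)).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                cols[pop] = np.nansum(d, axis=0) / (2.0 * nc)
        by_pop = pd.DataFrame(cols)
    return FrequencyTable(
        marker_id=panel.marker_ids, freq=freq, n_called=n_called, by_population=by_pop
    )


def orient_minor(panel: GenotypePanel, freqs: FrequencyTable | None = None):
    """Flip markers so the counted allele is the minor allele.

    Returns ``(panel, flipped)`` where *flipped* is a boolean mask of markers
    whose doses were mapped x -> 2 - x (and a1/a2 swapped).  Rare-allele
    scoring is orientation-sensitive and expects a minor-oriented panel.
    """
    if freqs is None:
        freqs = compute_freqs(panel)
    flip = np.asarray(freqs.is_major)
    doses = panel.doses.copy()
    doses[:, flip] = 2.0 - doses[:, flip]
    variants = panel.variants.copy()
    a1 = variants.loc[flip, "a1"].copy()
    variants.loc[flip, "a1"] = variants.loc[flip, "a2"]
    variants.loc[flip, "a2"] = a1
    return GenotypePanel(variants, panel.samples, doses), flip


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test and QC
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_hom_a1: int, n_het: int, n_hom_a2: int) -> float:
    """Plain exact Hardy-Weinberg p-value (sum of probabilities <= observed).

    Conditions on the allele counts and enumerates the exact distribution of
    the heterozygote count; no mid-p correction.
    """
    n = n_hom_a1 + n_het + n_hom_a2
    if n == 0:
        return 1.0
    rare = min(2 * n_hom_a1 + n_het, 2 * n_hom_a2 + n_het)
    if rare == 0:
        return 1.0
    # possible het counts share the parity of the rare-allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    # unnormalised log probabilities of each het count given allele counts
    from scipy.special import gammaln

    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    logp = (
        hets * np.log(2.0)
        - gammaln(hom_r + 1)
        - gammaln(hets + 1)
        - gammaln(hom_c + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def qc_filter(
    panel: GenotypePanel,
    max_missing: float = 0.02,
    hwe_p: float = 1e-6,
    sample_max_missing: float = 0.02,
):
    """Marker and sample quality control.

    Removes markers with missingness above *max_missing* or an exact
    Hardy-Weinberg p-value below *hwe_p*, then samples with missingness above
    *sample_max_missing* (computed on the retained markers).  Returns
    ``(filtered_panel, report)`` where *report* lists every exclusion with its
    reason and offending value.
    """
    if not (0 < max_missing < 1 and 0 < hwe_p < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    doses = panel.doses
    n_samples = panel.n_samples
    miss_rate = np.isnan(doses).sum(axis=0) / n_samples
    records = []
    keep_markers = np.ones(panel.n_markers, dtype=bool)
    for i in np.flatnonzero(miss_rate > max_missing):
        keep_markers[i] = False
        records.append(
            ("marker", panel.marker_ids[i], "missingness", miss_rate[i])
        )
    for i in np.flatnonzero(keep_markers):
        col = doses[:, i]
        hom1 = int((col == 2).sum())
        het = int((col == 1).sum())
        hom2 = int((col == 0).sum())
        p = hwe_exact_pvalue(hom1, het, hom2)
        if p < hwe_p:
            keep_markers[i] = False
            records.append(("marker", panel.marker_ids[i], "hwe", p))
    kept = np.flatnonzero(keep_markers)
    sub = doses[:, kept]
    if kept.size:
        sample_miss = np.isnan(sub).sum(axis=1) / kept.size
    else:
        sample_miss = np.zeros(n_samples)
    keep_samples = sample_miss <= sample_max_missing
    for j in np.flatnonzero(~keep_samples):
        records.append(
            ("sample", panel.sample_ids[j], "missingness", sample_miss[j])
        )
    report = pd.DataFrame(records, columns=["kind", "id", "reason", "value"])
    for _, row in report.iterrows():
        logger.info("qc: excluded %s %s (%s=%.3g)", row.kind, row.id, row.reason, row.value)
    out = panel.subset(np.flatnonzero(keep_samples), kept)
    return out, report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dose columns over jointly called samples."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return np.nan
    xv, yv = x[ok], y[ok]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return np.nan
    r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
    return r * r


def ld_prune(
    panel: GenotypePanel,
    window: int = 50,
    step: int = 5,
    r2: float = 0.5,
) -> np.ndarray:
    """Greedy windowed LD pruning (indep-pairwise style).

    Slides a *window*-SNP window by *step* SNPs within each chromosome; while
    any retained pair in the window has squared dose correlation above *r2*,
    the member with the lower MAF is removed (ties: the later marker).
    Monomorphic markers have undefined correlation and are always retained.
    Returns the sorted array of retained marker indices.
    """
    keep = np.ones(panel.n_markers, dtype=bool)
    freqs = compute_freqs(panel)
    maf = freqs.maf
    chroms = panel.variants["chrom"].to_numpy()
    for chrom in np.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        start = 0
        while start < len(idx):
            win = idx[start : start + window]
            retained = [i for i in win if keep[i]]
            changed = True
            while changed:
                changed = False
                for a in range(len(retained)):
                    for b in range(a + 1, len(retained)):
                        i, j = retained[a], retained[b]
                        rr = _pairwise_r2(panel.doses[:, i], panel.doses[:, j])
                        if np.isnan(rr) or rr <= r2:
                            continue
                        drop = j if (np.isnan(maf[i]) or np.isnan(maf[j]) or maf[j] <= maf[i]) else i
                        keep[drop] = False
                        retained = [m for m in retained if keep[m]]
                        changed = True
                        break
                    if changed:
                        break
            if start + window >= len(idx):
                break
            start += step
    return np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# Panel merging
# ---------------------------------------------------------------------------

def merge_panels(a: GenotypePanel, b: GenotypePanel) -> GenotypePanel:
    """Merge two panels on shared markers, aligning counted alleles.

    Markers present in both panels are kept; where the counted alleles are
    reversed the second panel's doses are mapped x -> 2 - x.  Strand-ambiguous
    A/T and C/G markers are dropped with a warning, as are markers with
    irreconcilable alleles.  Sample lists are concatenated.
    """
    b_index = {mid: k for k, mid in enumerate(b.marker_ids)}
    keep_a: list[int] = []
    b_cols: list[np.ndarray] = []
    for i, row in a.variants.iterrows():
        k = b_index.get(row["id"])
        if k is None:
            continue
        a1, a2 = str(row["a1"]).upper(), str(row["a2"]).upper()
        if frozenset({a1, a2}) in _AMBIGUOUS:
            logger.warning("merge: dropping strand-ambiguous marker %s (%s/%s)", row["id"], a1, a2)
            continue
        vb = b.variants.iloc[k]
        b1, b2 = str(vb["a1"]).upper(), str(vb["a2"]).upper()
        col = b.doses[:, k]
        if (a1, a2) == (b1, b2):
            pass
        elif (a1, a2) == (b2, b1):
            col = 2.0 - col
        elif (a1, a2) == (_COMPLEMENT.get(b1), _COMPLEMENT.get(b2)):
            pass  # opposite strand, same orientation
        elif (a1, a2) == (_COMPLEMENT.get(b2), _COMPLEMENT.get(b1)):
            col = 2.0 - col
        else:
            logger.warning(
                "merge: dropping marker %s with irreconcilable alleles %s/%s vs %s/%s",
                row["id"], a1, a2, b1, b2,
            )
            continue
        keep_a.append(i)
        b_cols.append(col)
    variants = a.variants.iloc[keep_a]
    doses = np.vstack([a.doses[:, keep_a], np.column_stack(b_cols) if b_cols else np.empty((b.n_samples, 0))])
    samples = pd.concat([a.samples, b.samples], ignore_index=True)
    return GenotypePanel(variants=variants, samples=samples, doses=doses)
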