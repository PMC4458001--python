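"""Eigenanalysis of relationship matrices and PC-based structure scans."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypePanel
from .relatedness import RelationshipMatrix

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    """Top-k eigenpairs of a relationship matrix.

    ``eigenvectors`` is samples x k with columns in descending eigenvalue
    order; raw eigenvector coordinates are used downstream (no sqrt-eigenvalue
    rescaling).  Sign convention: the largest-magnitude entry of each
    eigenvector is positive.
    """

    sample_ids: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    provenance: dict = field(default_factory=dict)

    def pc(self, index: int) -> np.ndarray:
        """1-based principal component accessor (pc(1) = top eigenvector)."""
        return self.eigenvectors[:, index - 1]


def grm_pca(grm: RelationshipMatrix, k: int = 20) -> PCAResult:
    """Top-k eigenanalysis of a relationship matrix."""
    n = grm.n
    if k > n:
        warnings.warn(f"k={k} exceeds sample count {n}; clipped")
        k = n
    w, v = np.linalg.eigh(grm.matrix)
    order = np.argsort(w)[::-1][:k]
    w, v = w[order], v[:, order]
    for j in range(v.shape[1]):
        if v[np.argmax(np.abs(v[:, j])), j] < 0:
            v[:, j] = -v[:, j]
    return PCAResult(
        sample_ids=grm.sample_ids,
        eigenvalues=w,
        eigenvectors=v,
        provenance=dict(grm.provenance),
    )


def flag_pc_outliers(
    pca: PCAResult, pcs: tuple[int, ...] = (1, 2), sd_mult: float = 6.0
) -> np.ndarray:
    """Samples lying more than *sd_mult* SDs from the mean on any listed PC.

    Moments are taken over all samples in the PCA.  A zero-variance PC flags
    nobody (degenerate guard).
    """
    flagged = np.zeros(len(pca.sample_ids), dtype=bool)
    for p in pcs:
        if p > pca.eigenvectors.shape[1]:
            raise ValueError(f"PC {p} not present (k={pca.eigenvectors.shape[1]})")
        vec = pca.pc(p)
        sd = vec.std()
        if sd == 0:
            continue
        flagged |= np.abs(vec - vec.mean()) > sd_mult * sd
    return pca.sample_ids[flagged]


def pc_snp_association(
    panel: GenotypePanel,
    pca: PCAResult,
    pc_index: int,
    covariates: pd.DataFrame | None = None,
    use_metadata_covariates: bool = True,
) -> pd.DataFrame:
    """Per-SNP linear association scan with a PC as the phenotype.

    Fits PC ~ dose + covariates by ordinary least squares for each marker in
    turn (sex, age and age^2 from the sample metadata by default when
    available) and reports one row per marker: CHR SNP BP BETA T P.
    Monomorphic markers yield NA rows.
    """
    y = pca.pc(pc_index)
    n = len(y)
    if covariates is None and use_metadata_covariates:
        covariates = _metadata_covariates(panel)
    if covariates is not None:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=float)])
    else:
        C = np.ones((n, 1))
    Q, _ = np.linalg.qr(C)
    y_res = y - Q @ (Q.T @ y)
    dof = n - C.shape[1] - 1
    betas = np.full(panel.n_markers, np.nan)
    tvals = np.full(panel.n_markers, np.nan)
    pvals = np.full(panel.n_markers, np.nan)
    X = panel.doses
    complete = ~np.isnan(X).any(axis=0)
    # fast path: no missing doses -> residualise all columns at once
    if complete.any():
        Xc = X[:, complete]
        Xr = Xc - Q @ (Q.T @ Xc)
        sxx = (Xr**2).sum(axis=0)
        poly = sxx > 1e-12
        sxy = Xr.T @ y_res
        with np.errstate(invalid="ignore", divide="ignore"):
            b = sxy / sxx
            rss = (y_res @ y_res) - b * sxy
            se = np.sqrt(rss / dof / sxx)
            t = b / se
        b[~poly] = np.nan
        t[~poly] = np.nan
        idx = np.flatnonzero(complete)
        betas[idx], tvals[idx] = b, t
        pvals[idx] = 2 * stats.t.sf(np.abs(t), dof)
    for i in np.flatnonzero(~complete):
        x = X[:, i]
        ok = ~np.isnan(x)
        if ok.sum() <= C.shape[1] + 1 or np.nanstd(x) == 0:
            continue
        D = np.column_stack([C[ok], x[ok]])
        coef, res, rank, _ = np.linalg.lstsq(D, y[ok], rcond=None)
        if rank < D.shape[1]:
            continue
        resid = y[ok] - D @ coef
        df_i = ok.sum() - D.shape[1]
        XtX_inv = np.linalg.inv(D.T @ D)
        se = np.sqrt(resid @ resid / df_i * XtX_inv[-1, -1])
        betas[i] = coef[-1]
        tvals[i] = coef[-1] / se
        pvals[i] = 2 * stats.t.sf(abs(tvals[i]), df_i)
    return pd.DataFrame(
        {
            "CHR": panel.variants["chrom"],
            "SNP": panel.variants["id"],
            "BP": panel.variants["pos"],
            "BETA": betas,
            "T": tvals,
            "P": pvals,
        }
    )


def _metadata_covariates(panel: GenotypePanel) -> pd.DataFrame | None:
    s = panel.samples
    cols = {}
    if s["sex"].notna().all() and s["sex"].nunique() > 1:
        cols["sex"] = (s["sex"] == "female").astype(float)
    if s["age"].notna().all():
        age = s["age"].astype(float)
        cols["age"] = age
        cols["age2"] = age**2
    return pd.DataFrame(cols) if cols else None


def loading_concentration(assoc: pd.DataFrame, chrom: int, start: int, end: int) -> float:
    """Ratio of mean squared association t inside a region to the genome-wide mean.

    Used to test whether a PC's marker loadings concentrate in one high-LD
    block (inversion / MHC analogue).
    """
    t2 = assoc["T"].to_numpy() ** 2
    inside = (
        (assoc["CHR"].to_numpy() == chrom)
        & (assoc["BP"].to_numpy() >= start)
        & (assoc["BP"].to_numpy() <= end)
    )
    ok = np.isfinite(t2)
    if not (inside & ok).any():
        return np.nan
    return float(np.nanmean(t2[inside & ok]) / np.nanmean(t2[ok]))


def write_eigen(pca: PCAResult, prefix: str) -> None:
    """Write GCTA-style .eigenvec (FID IID PC1..PCk) and .eigenval files."""
    df = pd.DataFrame(pca.eigenvectors, columns=[f"PC{i+1}" for i in range(pca.eigenvectors.shape[1])])
    df.insert(0, "IID", pca.sample_ids)
    df.insert(0, "FID", pca.sample_ids)
    df.to_csv(f"{prefix}.eigenvec", sep=" ", header=False, index=False)
    np.savetxt(f"{prefix}.eigenval", pca.eigenvalues)
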