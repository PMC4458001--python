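"""Genomic relationship matrices weighted by allele frequency.

The off-diagonal estimator for samples j != k is

    G_jk = (1/N) * sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))

with N the number of jointly non-missing markers for the pair; the diagonal
uses the standard companion estimator

    G_jj = 1 + (1/N) * sum_i (x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2) / (2 p_i (1 - p_i)).

Both are invariant to allele-orientation flips (x -> 2 - x, p -> 1 - p).
Because the weights blow up as p -> 0, pairs sharing rare alleles can show
strongly inflated relationship estimates; comparing a rare-marker GRM with a
common-marker GRM exposes such pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import FrequencyTable, GenotypePanel, compute_freqs

logger = logging.getLogger(__name__)


@dataclass
class RelationshipMatrix:
    """Symmetric sample x sample relationship matrix with provenance.

    ``n_matrix`` stores the per-pair count of jointly non-missing markers
    (marker count per sample on the diagonal), which makes exact pooling of
    matrices computed on disjoint marker sets possible.
    """

    sample_ids: np.ndarray
    matrix: np.ndarray
    provenance: dict = field(default_factory=dict)
    n_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("matrix shape does not match sample ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("relationship matrix is not symmetric")
        if not np.isfinite(self.matrix).all():
            raise ValueError("relationship matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return len(self.sample_ids)


def _select_markers(
    panel: GenotypePanel,
    freqs: FrequencyTable,
    maf_window: tuple[float, float] | None,
    chromosomes=None,
) -> np.ndarray:
    p = freqs.freq
    maf = np.minimum(p, 1 - p)
    with np.errstate(invalid="ignore"):
        keep = (p > 0) & (p < 1)  # monomorphic markers always excluded
    keep &= ~np.isnan(p)
    if maf_window is not None:
        low, high = maf_window
        keep &= (maf > low) & (maf <= high)
    if chromosomes is not None:
        keep &= np.isin(panel.variants["chrom"].to_numpy(), np.asarray(chromosomes))
    return np.flatnonzero(keep)


def compute_grm(
    panel: GenotypePanel,
    maf_window: tuple[float, float] | None = (0.0, 0.5),
    chromosomes=None,
    freqs: FrequencyTable | None = None,
) -> RelationshipMatrix:
    """Frequency-weighted genomic relationship matrix on a marker subset.

    ``maf_window`` is a half-open interval (low, high] on the minor allele
    frequency (None = no MAF filter); ``chromosomes`` optionally restricts to
    a chromosome subset.  Frequencies default to the panel itself; an external
    :class:`FrequencyTable` may be supplied.  Missing doses are handled by
    pairwise-complete averaging.
    """
    if freqs is None:
        freqs = compute_freqs(panel)
    idx = _select_markers(panel, freqs, maf_window, chromosomes)
    if idx.size == 0:
        raise ValueError(
            f"no polymorphic markers in MAF window {maf_window}"
            + (f" on chromosomes {chromosomes}" if chromosomes is not None else "")
        )
    X = panel.doses[:, idx]
    p = freqs.freq[idx]
    het = 2.0 * p * (1.0 - p)
    Z = (X - 2.0 * p) / np.sqrt(het)
    called = ~np.isnan(X)
    Z = np.where(called, Z, 0.0)
    M = called.astype(float)
    N = M @ M.T
    with np.errstate(invalid="ignore", divide="ignore"):
        G = (Z @ Z.T) / N
    G[N == 0] = 0.0
    # diagonal: companion estimator averaged over each sample's called markers
    diag_terms = np.where(called, (X**2 - (1 + 2 * p) * X + 2 * p**2) / het, 0.0)
    n_called = called.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        diag = 1.0 + diag_terms.sum(axis=1) / n_called
    np.fill_diagonal(G, np.where(n_called > 0, diag, 0.0))
    np.fill_diagonal(N, n_called)
    G = (G + G.T) / 2.0  # enforce exact symmetry against float noise
    return RelationshipMatrix(
        sample_ids=panel.sample_ids,
        matrix=G,
        provenance={
            "maf_window": maf_window,
            "chromosomes": tuple(chromosomes) if chromosomes is not None else None,
            "marker_count": int(idx.size),
        },
        n_matrix=N,
    )


def chromosomal_grms(
    panel: GenotypePanel, freqs: FrequencyTable | None = None
) -> dict[int, RelationshipMatrix]:
    """One GRM per autosome present in the panel, with no MAF filter."""
    if freqs is None:
        freqs = compute_freqs(panel)
    out: dict[int, RelationshipMatrix] = {}
    for c in sorted(panel.variants["chrom"].unique()):
        try:
            out[int(c)] = compute_grm(panel, maf_window=None, chromosomes=[c], freqs=freqs)
        except ValueError:
            logger.warning("chromosome %s has no polymorphic markers; skipped", c)
    return out


def combine_grms(grms: list[RelationshipMatrix]) -> RelationshipMatrix:
    """Pool GRMs computed on disjoint marker sets (count-weighted mean).

    With the per-pair counts stored in ``n_matrix`` the pooled matrix equals
    the GRM computed on the union of marker sets exactly.
    """
    if not grms:
        raise ValueError("no matrices to combine")
    ids = grms[0].sample_ids
    num = np.zeros_like(grms[0].matrix)
    den = np.zeros_like(grms[0].matrix)
    for g in grms:
        if g.n_matrix is None:
            raise ValueError("combine_grms requires n_matrix on every input")
        if not np.array_equal(g.sample_ids, ids):
            raise ValueError("sample ids differ between matrices")
        num += g.matrix * g.n_matrix
        den += g.n_matrix
    with np.errstate(invalid="ignore", divide="ignore"):
        M = num / den
    M[den == 0] = 0.0
    M = (M + M.T) / 2.0
    return RelationshipMatrix(
        sample_ids=ids,
        matrix=M,
        provenance={"combined_from": [g.provenance for g in grms],
                    "marker_count": int(sum(g.provenance.get("marker_count", 0) for g in grms))},
        n_matrix=den,
    )


def prune_related(grm: RelationshipMatrix, cutoff: float = 0.025) -> np.ndarray:
    """Iteratively drop samples until no pair exceeds *cutoff*.

    At each step the sample participating in the most above-cutoff pairs is
    removed (ties broken by sample-list order).  Returns the retained sample
    ids.
    """
    A = grm.matrix.copy()
    np.fill_diagonal(A, 0.0)
    active = np.ones(grm.n, dtype=bool)
    while True:
        over = (A > cutoff) & active[:, None] & active[None, :]
        counts = over.sum(axis=1)
        if counts.max(initial=0) == 0:
            break
        active[int(np.argmax(counts))] = False  # argmax takes the first tie
    return grm.sample_ids[active]


def find_discordant_pairs(
    grm_all: RelationshipMatrix,
    grm_common: RelationshipMatrix,
    high: tuple[float, float] = (0.17, 0.50),
    low: tuple[float, float] = (0.0, 0.08),
) -> pd.DataFrame:
    """Pairs related under all markers but unrelated under common markers only.

    Selects unordered pairs whose all-marker coefficient lies in *high* and
    whose common-marker coefficient lies in *low* (both closed intervals):
    the signature of shared rare alleles inflating the frequency-weighted
    estimator.  Sorted by the all-marker coefficient, descending.
    """
    if not np.array_equal(grm_all.sample_ids, grm_common.sample_ids):
        raise ValueError("matrices do not share sample ids")
    iu, ju = np.triu_indices(grm_all.n, k=1)
    a = grm_all.matrix[iu, ju]
    c = grm_common.matrix[iu, ju]
    sel = (a >= high[0]) & (a <= high[1]) & (c >= low[0]) & (c <= low[1])
    df = pd.DataFrame(
        {
            "sample_1": grm_all.sample_ids[iu[sel]],
            "sample_2": grm_all.sample_ids[ju[sel]],
            "grm_all": a[sel],
            "grm_common": c[sel],
        }
    )
    return df.sort_values("grm_all", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# GCTA-compatible binary I/O
# ---------------------------------------------------------------------------

def write_grm_bin(grm: RelationshipMatrix, prefix: str | Path) -> None:
    """Write the GCTA binary triple: .grm.bin, .grm.N.bin, .grm.id.

    Lower triangle (including diagonal) in row-major order, float32.
    """
    prefix = Path(prefix)
    il, jl = np.tril_indices(grm.n)
    grm.matrix[il, jl].astype("<f4").tofile(f"{prefix}.grm.bin")
    N = grm.n_matrix if grm.n_matrix is not None else np.full_like(grm.matrix, grm.provenance.get("marker_count", 0))
    N[il, jl].astype("<f4").tofile(f"{prefix}.grm.N.bin")
    pd.DataFrame({"fid": grm.sample_ids, "iid": grm.sample_ids}).to_csv(
        f"{prefix}.grm.id", sep="\t", header=False, index=False
    )


def read_grm_bin(prefix: str | Path) -> RelationshipMatrix:
    """Read a GCTA binary triple written by :func:`write_grm_bin`."""
    prefix = Path(prefix)
    ids = pd.read_csv(f"{prefix}.grm.id", sep=r"\s+", header=None)[1].to_numpy()
    n = len(ids)
    vals = np.fromfile(f"{prefix}.grm.bin", dtype="<f4").astype(float)
    if vals.size != n * (n + 1) // 2:
        raise ValueError("grm.bin size does not match id count")
    M = np.zeros((n, n))
    il, jl = np.tril_indices(n)
    M[il, jl] = vals
    M[jl, il] = vals
    Nv = np.fromfile(f"{prefix}.grm.N.bin", dtype="<f4").astype(float)
    Nmat = np.zeros((n, n))
    Nmat[il, jl] = Nv
    Nmat[jl, il] = Nv
    return RelationshipMatrix(sample_ids=ids, matrix=M, n_matrix=Nmat,
                              provenance={"source": str(prefix)})
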