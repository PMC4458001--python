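"""Synthetic admixed-cohort generation.

Builds genotype panels with the statistical structure the downstream analyses
assume: several ancestral populations diverged under the Balding-Nichols
model, a majority population into which long donor haplotypes are introgressed
in a small fraction of carriers, pedigree relatives produced by gene dropping
with crossovers, allele-frequency clines tied to geographic coordinates, and
injected homozygous segments / whole-chromosome isodisomy.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import FrequencyTable, GenotypePanel, compute_freqs

logger = logging.getLogger(__name__)

#: GRCh37 autosome lengths in bp; the simulated genome scales these by a
#: config factor so that desk-scale marker counts keep a realistic SNP density.
CHROM_LENGTHS_BP = {
    1: 249_250_621, 2: 243_199_373, 3: 198_022_430, 4: 191_154_276,
    5: 180_915_260, 6: 171_115_067, 7: 159_138_663, 8: 146_364_022,
    9: 141_213_431, 10: 135_534_747, 11: 135_006_516, 12: 133_851_895,
    13: 115_169_878, 14: 107_349_540, 15: 102_531_392, 16: 90_354_753,
    17: 81_195_210, 18: 78_077_248, 19: 59_128_983, 20: 63_025_520,
    21: 48_129_895, 22: 51_304_566,
}

#: cM per Mb used for crossover placement in gene dropping
RECOMBINATION_RATE_CM_PER_MB = 1.2


def genome_length(scale: float = 1.0) -> float:
    return sum(CHROM_LENGTHS_BP.values()) * scale


@dataclass
class PopulationModel:
    """Balding-Nichols population model.

    ``fst`` gives each population's divergence from the shared ancestral
    frequency; population frequencies are drawn Beta(p(1-F)/F, (1-p)(1-F)/F)
    around an ancestral p ~ Uniform(low, high).
    """

    n_pops: int = 2
    fst: tuple[float, ...] | float = 0.15
    n_markers: int = 10_000
    base_freq_law: tuple[float, float] = (0.05, 0.95)
    scale: float = 0.02
    seed: int = 0

    def fst_per_pop(self) -> np.ndarray:
        f = np.broadcast_to(np.atleast_1d(self.fst), (self.n_pops,)).astype(float)
        if not ((f > 0) & (f < 1)).all():
            raise ValueError("fst must lie in (0, 1) for every population")
        return f


@dataclass
class IntrogressionConfig:
    """Donor-haplotype introgression into a fraction of the cohort.

    Tract lengths are shifted-exponential with mean ``tract_mean_bp``,
    floored at ``tract_min_bp`` and truncated at ``tract_max_bp`` (long donor
    haplotypes, up to 7 Mb; sub-megabase segments reflect old admixture
    rather than a recent foreign ancestor and are not simulated); tracts are
    placed without overlap until ``genome_fraction`` of the carrier genome is
    covered (a few percent of non-majority origin).
    """

    donor_pop: str = "donor"
    carrier_fraction: float = 0.05
    tract_mean_bp: float = 3_000_000.0
    tract_max_bp: float = 7_000_000.0
    tract_min_bp: float = 1_500_000.0
    genome_fraction: float = 0.04

    def __post_init__(self) -> None:
        if not 0 <= self.carrier_fraction < 1:
            raise ValueError("carrier_fraction must lie in [0, 1)")
        if not 0 < self.genome_fraction < 1:
            raise ValueError("genome_fraction must lie in (0, 1)")


#: default region grid: Scottish-range coordinates (degrees)
_DEFAULT_REGIONS = [
    ("Aberdeen", 57.15, -2.09),
    ("Dundee", 56.46, -2.97),
    ("Edinburgh", 55.95, -3.19),
    ("Glasgow", 55.86, -4.25),
    ("Highland", 57.36, -5.10),
    ("Borders", 55.54, -2.79),
]


@dataclass
class GeoClineConfig:
    """Allele-frequency clines tied to sample coordinates.

    A ``fraction_clinal`` subset of markers has its sampling frequency shifted
    by ``cline_strength`` per degree along ``axis`` ("lon", "lat" or "both");
    shifted frequencies are clipped to (0.001, 0.999).
    """

    regions: list[tuple[str, float, float]] = field(
        default_factory=lambda: list(_DEFAULT_REGIONS)
    )
    cline_strength: float = 0.05
    fraction_clinal: float = 0.3
    axis: str = "lon"
    proportions: tuple[float, ...] | None = None


def _marker_map(n_markers: int, scale: float, rng: np.random.Generator) -> pd.DataFrame:
    """Markers spread uniformly over the 22 scaled autosomes, sorted by position."""
    lengths = np.array([CHROM_LENGTHS_BP[c] for c in range(1, 23)], dtype=float) * scale
    probs = lengths / lengths.sum()
    chroms = rng.choice(np.arange(1, 23), size=n_markers, p=probs)
    pos = np.empty(n_markers, dtype=np.int64)
    for c in range(1, 23):
        mask = chroms == c
        m = int(mask.sum())
        draw = np.unique(rng.integers(1, int(lengths[c - 1]) + 1, size=2 * m + 8))
        while draw.size < m:  # collisions are rare; top up
            extra = rng.integers(1, int(lengths[c - 1]) + 1, size=2 * m)
            draw = np.unique(np.concatenate([draw, extra]))
        pos[mask] = np.sort(rng.choice(draw, size=m, replace=False))
    order = np.lexsort((pos, chroms))
    alleles = rng.choice(["A", "C", "G", "T"], size=(n_markers, 2))
    # avoid identical ref/alt pairs
    same = alleles[:, 0] == alleles[:, 1]
    alleles[same, 1] = np.where(alleles[same, 0] == "A", "G", "A")
    return pd.DataFrame(
        {
            "id": [f"snp{i}" for i in range(n_markers)],
            "chrom": chroms[order],
            "pos": pos[order],
            "a1": alleles[:, 0],
            "a2": alleles[:, 1],
        }
    )


def simulate_cohort(
    model: PopulationModel, sizes: dict[str, int] | list[int]
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Simulate a multi-population cohort under the Balding-Nichols model.

    Returns ``(panel, pop_freqs)`` where *pop_freqs* holds each population's
    true sampling frequency per marker (columns = population labels).
    Genotypes are Binomial(2, p_pop) per marker; the marker map covers the 22
    scaled autosomes.
    """
    rng = np.random.default_rng(model.seed)
    if isinstance(sizes, dict):
        labels = list(sizes.keys())
        counts = list(sizes.values())
    else:
        labels = [f"pop{k}" for k in range(len(sizes))]
        counts = list(sizes)
    if len(labels) != model.n_pops:
        raise ValueError("sizes must give one count per population")
    fst = model.fst_per_pop()
    low, high = model.base_freq_law
    variants = _marker_map(model.n_markers, model.scale, rng)
    p_anc = rng.uniform(low, high, size=model.n_markers)
    pop_freqs = {}
    blocks = []
    sample_rows = []
    for k, (label, n) in enumerate(zip(labels, counts)):
        F = fst[k]
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_pop = rng.beta(a, b)
        pop_freqs[label] = p_pop
        blocks.append(rng.binomial(2, p_pop, size=(n, model.n_markers)).astype(float))
        sample_rows += [
            {"id": f"{label}_{j}", "sex": "female" if rng.integers(2) else "male",
             "age": float(rng.integers(18, 90)), "population": label}
            for j in range(n)
        ]
    panel = GenotypePanel(
        variants=variants,
        samples=pd.DataFrame(sample_rows),
        doses=np.vstack(blocks),
    )
    return panel, pd.DataFrame(pop_freqs)


# ---------------------------------------------------------------------------
# Introgression
# ---------------------------------------------------------------------------

def inject_introgression(
    panel: GenotypePanel,
    donor_freqs: FrequencyTable | np.ndarray,
    cfg: IntrogressionConfig,
    seed: int = 0,
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Introgress donor haplotype tracts into a random fraction of samples.

    Within each tract one implicit haplotype is redrawn from the donor
    frequencies: the new dose is one allele retained from the host genotype
    plus one Bernoulli(p_donor) donor allele.  Tracts are placed without
    overlap until ``genome_fraction`` of the genome is covered (the final
    tract is clipped to the remaining budget).  Returns the modified panel and
    a truth table (sample, chrom, start_bp, end_bp, length_bp, n_markers).
    """
    rng = np.random.default_rng(seed)
    p_donor = donor_freqs.freq if isinstance(donor_freqs, FrequencyTable) else np.asarray(donor_freqs)
    if p_donor.shape[0] != panel.n_markers:
        raise ValueError("donor frequencies must cover the panel markers")
    out = panel.copy()
    n_carriers = int(round(cfg.carrier_fraction * panel.n_samples))
    if n_carriers == 0:
        return out, pd.DataFrame(
            columns=["sample", "chrom", "start_bp", "end_bp", "length_bp", "n_markers"]
        )
    carriers = rng.choice(panel.n_samples, size=n_carriers, replace=False)
    chroms = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    chrom_span = {c: pos[chroms == c].max() for c in np.unique(chroms)}
    chrom_ids = sorted(chrom_span)
    lengths = np.array([chrom_span[c] for c in chrom_ids], dtype=float)
    total_bp = lengths.sum()
    target = cfg.genome_fraction * total_bp
    records = []
    for s in carriers:
        placed: dict[int, list[tuple[int, int]]] = {c: [] for c in chrom_ids}
        covered = 0.0
        attempts = 0
        while covered < target and attempts < 1000:
            attempts += 1
            length = min(
                cfg.tract_min_bp
                + rng.exponential(max(cfg.tract_mean_bp - cfg.tract_min_bp, 1.0)),
                cfg.tract_max_bp,
            )
            length = min(length, target - covered + 1)
            # weight chromosomes by feasible start positions so that large
            # tracts are placed uniformly over the genome, not piled onto
            # short chromosomes
            feasible = np.maximum(lengths - length, 0.0)
            if feasible.sum() == 0:
                continue
            c = chrom_ids[rng.choice(len(chrom_ids), p=feasible / feasible.sum())]
            start = int(rng.integers(1, chrom_span[c] - int(length) + 1))
            end = start + int(length) - 1
            if any(start <= e and end >= b for b, e in placed[c]):
                continue
            placed[c].append((start, end))
            covered += end - start + 1
            in_tract = (chroms == c) & (pos >= start) & (pos <= end)
            idx = np.flatnonzero(in_tract)
            host = out.doses[s, idx]
            keep = rng.binomial(1, np.clip(host / 2.0, 0, 1))
            keep = np.where(np.isnan(host), np.nan, keep)
            donor = rng.binomial(1, p_donor[idx])
            out.doses[s, idx] = keep + donor
            records.append(
                {
                    "sample": panel.sample_ids[s],
                    "chrom": c,
                    "start_bp": start,
                    "end_bp": end,
                    "length_bp": end - start + 1,
                    "n_markers": int(in_tract.sum()),
                }
            )
        if covered < target:
            logger.warning(
                "introgression: reached %.3g of %.3g bp target for sample %s",
                covered, target, panel.sample_ids[s],
            )
    truth = pd.DataFrame(records).sort_values(["sample", "chrom", "start_bp"]).reset_index(drop=True)
    return out, truth


def introgression_study(
    n_host: int = 300,
    n_donor_panel: int = 100,
    n_markers: int = 20_000,
    background_fst: float = 0.026,
    differentiated_fraction: float = 0.15,
    host_rare_mean: float = 0.0003,
    donor_common_law: tuple[float, float] = (0.35, 0.80),
    carrier_fraction: float = 0.05,
    genome_fraction: float = 0.04,
    scale: float = 0.05,
    seed: int = 0,
):
    """The canonical recent-introgression study scenario.

    Emulates the allele-frequency architecture that makes recently
    introgressed haplotypes detectable: a divergent donor population retains
    common variants that the host population has lost to drift, so alleles
    rare in the host are often common in the donor.  Most markers diverge
    symmetrically under the Balding-Nichols model (``background_fst``); a
    ``differentiated_fraction`` of markers is bottleneck-lost in the host
    (host frequency exponential with mean ``host_rare_mean``) while common in
    the donor (uniform ``donor_common_law``).  Under the defaults the
    realised pairwise host-donor FST is about 0.15.  A ``carrier_fraction``
    of host samples receives non-overlapping donor tracts totalling
    ``genome_fraction`` of their genome.

    Returns ``(panel, truth, donor_freqs, pop_freqs)``: the introgressed
    host-only panel, the tract truth table, the donor-population frequency
    table, and the true per-population sampling frequencies.
    """
    rng = np.random.default_rng(seed)
    model = PopulationModel(
        n_pops=2,
        fst=background_fst,
        n_markers=n_markers,
        scale=scale,
        seed=seed,
    )
    panel, pop_freqs = simulate_cohort(model, {"host": n_host, "donor": n_donor_panel})
    # overlay the bottleneck-lost marker class: host-rare, donor-common
    n_diff = int(round(differentiated_fraction * n_markers))
    diff = rng.choice(n_markers, size=n_diff, replace=False)
    p_host = pop_freqs["host"].to_numpy().copy()
    p_donor = pop_freqs["donor"].to_numpy().copy()
    p_host[diff] = np.clip(rng.exponential(host_rare_mean, size=n_diff), 1e-6, 0.05)
    p_donor[diff] = rng.uniform(*donor_common_law, size=n_diff)
    pop_freqs = pd.DataFrame({"host": p_host, "donor": p_donor})
    panel.doses[:n_host, diff] = rng.binomial(2, p_host[diff], size=(n_host, n_diff))
    panel.doses[n_host:, diff] = rng.binomial(2, p_donor[diff], size=(n_donor_panel, n_diff))
    host = panel.subset(sample_idx=np.arange(n_host))
    donor_freqs = FrequencyTable(
        marker_id=panel.marker_ids,
        freq=p_donor,
        n_called=np.full(n_markers, n_donor_panel),
    )
    cfg = IntrogressionConfig(
        carrier_fraction=carrier_fraction, genome_fraction=genome_fraction
    )
    injected, truth = inject_introgression(host, donor_freqs, cfg, seed=seed + 1)
    return injected, truth, donor_freqs, pop_freqs


# ---------------------------------------------------------------------------
# Pedigree gene dropping
# ---------------------------------------------------------------------------

def _split_haplotypes(doses: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Split a dose vector into two pseudo-haplotypes (het phase random)."""
    h = np.zeros((2, doses.size))
    hom2 = doses == 2
    h[:, hom2] = 1
    het = doses == 1
    pick = rng.integers(0, 2, size=int(het.sum()))
    idx = np.flatnonzero(het)
    h[pick, idx] = 1
    miss = np.isnan(doses)
    h[:, miss] = np.nan
    return h


def _gamete(
    haps: np.ndarray, chroms: np.ndarray, pos: np.ndarray, scale_back: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a gamete with Haldane crossovers at 1.2 cM/Mb (free recombination
    between chromosomes).

    ``scale_back`` maps simulated bp back to physical Mb so a scaled-down
    genome keeps a human-like crossover count.
    """
    out = np.empty(haps.shape[1])
    for c in np.unique(chroms):
        mask = chroms == c
        p = pos[mask]
        span_mb = (p.max() * scale_back) / 1e6
        morgans = span_mb * RECOMBINATION_RATE_CM_PER_MB / 100.0
        n_xo = rng.poisson(morgans)
        cuts = np.sort(rng.uniform(0, p.max(), size=n_xo))
        phase = rng.integers(0, 2)
        which = (phase + np.searchsorted(cuts, p)) % 2
        out[mask] = haps[which, mask]
    return out


def simulate_pedigree(
    panel: GenotypePanel,
    founders: dict[str, tuple[str, str]] | None = None,
    structure: str | None = None,
    founder_ids: list[str] | None = None,
    n_offspring: int = 2,
    seed: int = 0,
) -> GenotypePanel:
    """Append offspring produced by Mendelian gene dropping.

    Either pass ``founders`` mapping child id -> (mother id, father id), or a
    named ``structure`` in {"fullsib", "parent-child", "halfsib"} drawn on
    ``founder_ids``.  Crossovers follow the Haldane model at 1.2 cM/Mb;
    chromosomes assort freely.
    """
    rng = np.random.default_rng(seed)
    ids = list(panel.sample_ids)
    if founders is None:
        if structure is None or founder_ids is None:
            raise ValueError("pass either founders or (structure, founder_ids)")
        if structure == "fullsib":
            a, b = founder_ids[:2]
            founders = {f"{a}x{b}_sib{k}": (a, b) for k in range(n_offspring)}
        elif structure == "parent-child":
            a, b = founder_ids[:2]
            founders = {f"{a}x{b}_child": (a, b)}
        elif structure == "halfsib":
            a, b, c = founder_ids[:3]
            founders = {f"{a}x{b}_half0": (a, b), f"{a}x{c}_half1": (a, c)}
        else:
            raise ValueError(f"unknown structure {structure!r}")
    missing = [p for pair in founders.values() for p in pair if p not in ids]
    if missing:
        raise ValueError(f"founder ids not in panel: {sorted(set(missing))}")
    chroms = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    # infer the scale factor from the largest chromosome-1-relative span
    obs = max(pos[chroms == c].max() / CHROM_LENGTHS_BP[c] for c in np.unique(chroms))
    scale_back = 1.0 / obs
    haps = {
        sid: _split_haplotypes(panel.doses[ids.index(sid)], rng)
        for sid in {p for pair in founders.values() for p in pair}
    }
    rows = []
    new_meta = []
    for child, (mo, fa) in founders.items():
        g_m = _gamete(haps[mo], chroms, pos, scale_back, rng)
        g_f = _gamete(haps[fa], chroms, pos, scale_back, rng)
        rows.append(g_m + g_f)
        new_meta.append({"id": child, "sex": "female" if rng.integers(2) else "male"})
    samples = pd.concat([panel.samples, pd.DataFrame(new_meta)], ignore_index=True)
    doses = np.vstack([panel.doses, np.array(rows)])
    return GenotypePanel(panel.variants, samples, doses)


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------

def attach_geography(
    panel: GenotypePanel, cfg: GeoClineConfig, seed: int = 0
) -> GenotypePanel:
    """Assign samples to regions and impose allele-frequency clines.

    Samples are assigned regions (given or uniform proportions) and take their
    region's coordinates.  For the clinal marker subset, each sample's dose is
    redrawn Binomial(2, p) with p shifted by ``cline_strength`` x (coordinate -
    cohort mean coordinate) and clipped to (0.001, 0.999).
    """
    rng = np.random.default_rng(seed)
    out = panel.copy()
    n = panel.n_samples
    k = len(cfg.regions)
    props = np.full(k, 1.0 / k) if cfg.proportions is None else np.asarray(cfg.proportions, float)
    props = props / props.sum()
    assignment = rng.choice(k, size=n, p=props)
    names = [r[0] for r in cfg.regions]
    lat = np.array([cfg.regions[a][1] for a in assignment])
    lon = np.array([cfg.regions[a][2] for a in assignment])
    out.samples["residence"] = [names[a] for a in assignment]
    out.samples["lat"] = lat
    out.samples["lon"] = lon
    base = compute_freqs(panel).freq
    n_clinal = int(round(cfg.fraction_clinal * panel.n_markers))
    clinal = rng.choice(panel.n_markers, size=n_clinal, replace=False)
    if cfg.axis == "lat":
        coord = lat - lat.mean()
    elif cfg.axis == "lon":
        coord = lon - lon.mean()
    elif cfg.axis == "both":
        coord = (lat - lat.mean()) + (lon - lon.mean())
    else:
        raise ValueError(f"unknown axis {cfg.axis!r}")
    sign = rng.choice([-1.0, 1.0], size=n_clinal)
    for m, sg in zip(clinal, sign):
        p = np.clip(base[m] + sg * cfg.cline_strength * coord, 0.001, 0.999)
        out.doses[:, m] = rng.binomial(2, p).astype(float)
    return out


def inject_ld_block(
    panel: GenotypePanel,
    chrom: int,
    start_bp: int,
    end_bp: int,
    haplotype_freq: float = 0.4,
    noise: float = 0.02,
    seed: int = 0,
) -> GenotypePanel:
    """Overwrite a region with a polymorphic high-LD block (inversion analogue).

    Every marker in the span is rewritten from a single latent two-allele
    haplotype carried at ``haplotype_freq`` (each sample draws one latent
    genotype for the whole block; individual markers flip with probability
    ``noise``), producing near-perfect linkage disequilibrium across the
    block, as under a common inversion that suppresses recombination.
    """
    rng = np.random.default_rng(seed)
    out = panel.copy()
    chroms = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    idx = np.flatnonzero((chroms == chrom) & (pos >= start_bp) & (pos <= end_bp))
    latent = rng.binomial(2, haplotype_freq, size=panel.n_samples)
    block = np.repeat(latent[:, None], idx.size, axis=1).astype(float)
    flip = rng.random(block.shape) < noise
    block[flip] = rng.integers(0, 3, size=int(flip.sum()))
    out.doses[:, idx] = block
    return out


# ---------------------------------------------------------------------------
# Homozygosity injection
# ---------------------------------------------------------------------------

def inject_homozygosity(
    panel: GenotypePanel,
    roh_spec: list[tuple[str, int, int, int]] | None = None,
    upd_sample: tuple[str, int] | None = None,
    seed: int = 0,
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Inject homozygous spans and optional whole-chromosome isodisomy.

    ``roh_spec`` lists (sample_id, chrom, start_bp, end_bp) spans; overlapping
    spans for one sample are merged.  Within a span every heterozygous dose is
    replaced by a homozygous dose obtained by duplicating one randomly chosen
    allele.  ``upd_sample`` = (sample_id, chrom) makes a whole chromosome
    homozygous (uniparental isodisomy).  Returns the panel and the merged
    truth table.
    """
    rng = np.random.default_rng(seed)
    out = panel.copy()
    spans: list[tuple[str, int, int, int]] = list(roh_spec or [])
    chroms = panel.variants["chrom"].to_numpy()
    pos = panel.variants["pos"].to_numpy()
    if upd_sample is not None:
        sid, c = upd_sample
        spans.append((sid, c, 1, int(pos[chroms == c].max())))
    merged: list[list] = []
    for sid, c, start, end in sorted(spans, key=lambda t: (str(t[0]), t[1], t[2])):
        if merged and merged[-1][0] == sid and merged[-1][1] == c and start <= merged[-1][3] + 1:
            merged[-1][3] = max(merged[-1][3], end)
        else:
            merged.append([sid, c, start, end])
    ids = list(panel.sample_ids)
    for sid, c, start, end in merged:
        s = ids.index(sid)
        sel = (chroms == c) & (pos >= start) & (pos <= end)
        idx = np.flatnonzero(sel & (out.doses[s] == 1))
        out.doses[s, idx] = rng.choice([0.0, 2.0], size=idx.size)
    truth = pd.DataFrame(merged, columns=["sample", "chrom", "start_bp", "end_bp"])
    truth["is_upd"] = False
    if upd_sample is not None:
        sid, c = upd_sample
        truth.loc[(truth["sample"] == sid) & (truth["chrom"] == c), "is_upd"] = True
    return out, truth
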