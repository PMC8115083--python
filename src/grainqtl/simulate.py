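"""Synthetic structured rice-panel data with ground truth for recovery tests.

Generates, from one seed: a subdivided inbred genotype panel
(Balding-Nichols allele-frequency perturbation across subpopulations),
trait phenotypes with planted QTLs and a kinship-structured polygenic term,
starch-hydrolysis time-courses, GOPOD absorbance read-outs and toy gene
models with nonsynonymous-exonic annotation flags.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genio import (MISSING, GeneModel, GenotypeMatrix, write_gff3,
                    write_hapmap, write_vcf)
from .kinetics import DEFAULT_TIMES, GLUCOSE_TO_STARCH, first_order_model
from .traits import TRAITS

SUBPOP_NAMES = ("aro", "aus", "admix", "ind1A", "ind1B", "ind2", "ind3", "indx")

#: Published panel trait ranges used as affine-map targets and clamps.
DEFAULT_TRAIT_RANGES: dict[str, tuple[float, float]] = {
    "AC": (12.0, 33.0),
    "KL": (4.60, 7.7),
    "KB": (1.80, 3.00),
    "LBR": (1.58, 3.60),
    "ASV": (1.0, 7.0),
    "KLAC": (6.0, 12.0),
    "KBAC": (2.0, 4.5),
    "LER": (1.02, 1.96),
    "GC": (14.50, 100.0),
    "RS": (0.57, 10.00),
    "PGI": (52.91, 99.94),
}


@dataclass
class QTLSpec:
    """One planted marker effect: which SNP, which trait, how much variance."""

    snp_index: int
    trait: str
    target_pve: float
    direction: int = +1

    def __post_init__(self):
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}")
        if not 0 < self.target_pve < 100:
            raise ValueError("target_pve must be in (0, 100)")
        if self.direction not in (+1, -1):
            raise ValueError("direction must be +1 or -1")


@dataclass
class SimConfig:
    n_accessions: int = 150
    n_subpops: int = 8
    n_snps: int = 1000
    n_chromosomes: int = 1
    divergence: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    het_rate: float = 0.0
    qtls: list[QTLSpec] = field(default_factory=list)
    enforce_qc_floor: bool = True
    h2_poly: float = 0.3
    noise_scale: float = 1.0
    trait_ranges: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_RANGES))
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be >= 1")
        if self.n_subpops > self.n_accessions:
            raise ValueError("n_subpops cannot exceed n_accessions")
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0 <= self.missing_rate <= 0.2:
            raise ValueError("missing_rate must be in [0, 0.2]")
        if not 0 <= self.het_rate < 1:
            raise ValueError("het_rate must be in [0, 1)")
        if not 0 <= self.h2_poly < 1:
            raise ValueError("h2_poly must be in [0, 1)")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        self.qtls = [q if isinstance(q, QTLSpec) else QTLSpec(**q)
                     for q in self.qtls]


@dataclass
class SimTruth:
    """Ground truth retained for recovery tests and provenance."""

    subpop_labels: list[str]
    qtl_records: list[dict] = field(default_factory=list)
    polygenic: dict = field(default_factory=dict)
    kinetic_params: list[dict] = field(default_factory=list)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, list[str]]:
    """Structured inbred genotypes under a Balding-Nichols contract.

    Per SNP an ancestral frequency p is drawn uniformly from ``maf_range``;
    each subpopulation's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) with
    F = ``divergence`` (expected between-subpop variance F*p*(1-p); F = 0
    means no perturbation).  Inbred calls are a single Bernoulli draw per
    accession mapped to {0, 2}; ``het_rate`` optionally converts a fraction
    of calls to 1.  Missingness is applied uniformly at ``missing_rate``.

    With ``enforce_qc_floor`` (default) markers whose *realized* alt-allele
    frequency falls below 0.01 or realized missingness above 0.2 are redrawn
    (same ancestral frequency, fresh subpopulation draw), so the default QC
    filter is guaranteed to pass the generated panel unchanged.
    """
    rng = np.random.default_rng(config.rng_seed)
    n, m, s = config.n_accessions, config.n_snps, config.n_subpops

    pop_names = [SUBPOP_NAMES[i % len(SUBPOP_NAMES)] if i < len(SUBPOP_NAMES)
                 else f"pop{i + 1}" for i in range(s)]
    pop_of = np.arange(n) % s  # round-robin assignment
    labels = [pop_names[p] for p in pop_of]

    p_anc = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    F = config.divergence
    if F > 0:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_sub = rng.beta(a[None, :], b[None, :], size=(s, m))
    else:
        p_sub = np.broadcast_to(p_anc, (s, m)).copy()

    def draw_columns(p_cols: np.ndarray) -> np.ndarray:
        mm = p_cols.shape[1]
        alt = rng.random((n, mm)) < p_cols[pop_of, :]
        cols = np.where(alt, 2, 0).astype(np.int8)
        if config.het_rate > 0:
            cols[rng.random((n, mm)) < config.het_rate] = 1
        if config.missing_rate > 0:
            cols[rng.random((n, mm)) < config.missing_rate] = MISSING
        return cols

    calls = draw_columns(p_sub)

    if config.enforce_qc_floor:
        # redraw markers that would fail the default QC thresholds
        for _ in range(100):
            obs = calls != MISSING
            n_obs = obs.sum(axis=0)
            freq = np.where(obs, calls, 0).sum(axis=0) / np.maximum(2 * n_obs, 1)
            bad = (freq < 0.01) | (n_obs == 0) | ((~obs).mean(axis=0) > 0.2)
            if not bad.any():
                break
            idx = np.where(bad)[0]
            if F > 0:
                p_new = rng.beta(a[idx][None, :], b[idx][None, :],
                                 size=(s, idx.size))
            else:
                p_new = np.broadcast_to(p_anc[idx], (s, idx.size)).copy()
            calls[:, idx] = draw_columns(p_new)

    # spread markers over n_chromosomes pseudo-chromosomes, ~10 kb spacing
    per_chrom = int(np.ceil(m / config.n_chromosomes))
    chroms, positions = [], []
    for j in range(m):
        c = j // per_chrom + 1
        chroms.append(str(c))
        positions.append((j % per_chrom) * 10_000 + 5_000)
    bases = np.array(list("ACGT"))
    ref_i = rng.integers(0, 4, size=m)
    alt_i = (ref_i + rng.integers(1, 4, size=m)) % 4
    markers = pd.DataFrame({
        "id": [f"S{c}_{p}" for c, p in zip(chroms, positions)],
        "chrom": chroms, "pos": positions,
        "ref": bases[ref_i], "alt": bases[alt_i],
    })
    samples = [f"acc{i + 1:03d}" for i in range(n)]
    G = GenotypeMatrix(samples=samples, markers=markers, calls=calls)
    return G, labels


# ---------------------------------------------------------------------------
# phenotypes


def _realized_pve(g: np.ndarray, y: np.ndarray) -> float:
    """Regression sum-of-squares share of a single marker (percent)."""
    g = g - g.mean()
    y = y - y.mean()
    denom = float(g @ g)
    if denom == 0:
        return 0.0
    beta = float(g @ y) / denom
    return 100.0 * beta ** 2 * denom / float(y @ y)


def simulate_phenotypes(G: GenotypeMatrix, config: SimConfig,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[pd.DataFrame, SimTruth]:
    """Trait table with planted QTL effects, polygenic background and noise.

    On the latent (unit-variance) scale each trait is the sum of its QTL
    effects (variance fractions = target_pve/100), a polygenic term with
    covariance proportional to kinship (variance fraction ``h2_poly`` of the
    non-QTL remainder) and Gaussian noise.  The latent value is then
    affine-mapped so that mean +/- 3 SD spans the configured trait range and
    clamped to that range.
    """
    from .gwas import kinship

    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)
    n = G.n_samples
    qtl_by_trait: dict[str, list[QTLSpec]] = {t: [] for t in TRAITS}
    for q in config.qtls:
        if not 0 <= q.snp_index < G.n_markers:
            raise ValueError(f"QTL snp_index {q.snp_index} out of range")
        qtl_by_trait[q.trait].append(q)
    for t, qs in qtl_by_trait.items():
        if qs and sum(q.target_pve for q in qs) >= 100:
            raise ValueError(f"target PVEs for trait {t} sum to >= 100")

    K = kinship(G).values if G.n_markers > 1 else np.eye(n)
    # Cholesky of the kinship (ridge for numerical PSD) drives the polygenic draw
    L = np.linalg.cholesky(K + 1e-6 * np.eye(n))

    X = G.imputed()
    pheno = pd.DataFrame({"accession": G.samples})
    truth = SimTruth(subpop_labels=[], qtl_records=[], polygenic={})
    for trait in TRAITS:
        qs = qtl_by_trait[trait]
        f_qtl = sum(q.target_pve for q in qs) / 100.0
        rest = 1.0 - f_qtl
        var_poly = config.h2_poly * rest
        var_noise = max(rest - var_poly, 0.0) * config.noise_scale

        y = np.zeros(n)
        for q in qs:
            g = X[:, q.snp_index]
            sd = g.std()
            if sd == 0:
                raise ValueError(
                    f"QTL marker {q.snp_index} is monomorphic; cannot plant "
                    f"a {q.target_pve}% effect")
            beta = q.direction * np.sqrt(q.target_pve / 100.0) / sd
            y = y + beta * (g - g.mean())
        u = L @ rng.standard_normal(n) * np.sqrt(var_poly) if var_poly > 0 else np.zeros(n)
        e = rng.standard_normal(n) * np.sqrt(var_noise) if var_noise > 0 else np.zeros(n)
        bg = u + e
        if qs and bg.std() > 0:
            # orthogonalize the background against the QTL columns so each
            # planted variance fraction is realized exactly, not just in
            # expectation (fixed-realized-PVE design)
            Gq = X[:, [q.snp_index for q in qs]]
            Gq = Gq - Gq.mean(axis=0)
            bg = bg - Gq @ np.linalg.lstsq(Gq, bg, rcond=None)[0]
            target_sd = np.sqrt(var_poly + var_noise)
            if bg.std() > 0 and target_sd > 0:
                bg = (bg - bg.mean()) / bg.std() * target_sd
        y_lat = y + bg

        lo, hi = config.trait_ranges.get(trait, (0.0, 1.0))
        sd_lat = y_lat.std()
        if sd_lat > 0:
            z = (y_lat - y_lat.mean()) / sd_lat
        else:
            z = np.zeros(n)
        mapped = (lo + hi) / 2 + z * (hi - lo) / 6.0
        values = np.clip(mapped, lo, hi)
        if trait == "ASV":
            values = np.clip(np.rint(values), lo, hi)  # integer visual score
        pheno[trait] = values

        for q in qs:
            truth.qtl_records.append({
                "trait": trait, "snp_index": int(q.snp_index),
                "snp_id": str(G.markers["id"].iloc[q.snp_index]),
                "target_pve": float(q.target_pve),
                "direction": int(q.direction),
                "realized_pve": _realized_pve(X[:, q.snp_index], values),
            })
        truth.polygenic[trait] = [float(v) for v in u]
    return pheno, truth


# ---------------------------------------------------------------------------
# hydrolysis curves and assay read-outs


def simulate_hydrolysis_curves(n: int, calpha=None, k=None,
                               noise_sd: float = 0.0,
                               rng_seed: int | None = 0,
                               times=DEFAULT_TIMES,
                               include_t0: bool = False,
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Glucose time-courses from the first-order model plus Gaussian noise.

    glucose(t) = Calpha * (1 - e^{-kt}) / 0.9 on the sampling grid (total
    starch basis 100), noise truncated at zero.  ``calpha``/``k`` may be
    scalars, arrays of length n, or None for random draws (Calpha ~
    U(60, 100) percent, k ~ U(0.005, 0.04) /min).  Returns (curve table in
    the ``time_<min>`` layout, truth table of the generating parameters).
    """
    rng = np.random.default_rng(rng_seed)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if calpha is None:
        calpha = rng.uniform(60.0, 100.0, size=n)
    calpha = np.broadcast_to(np.asarray(calpha, dtype=float), (n,)).copy()
    if k is None:
        k = rng.uniform(0.005, 0.04, size=n)
    k = np.broadcast_to(np.asarray(k, dtype=float), (n,)).copy()
    if np.any(calpha <= 0) or np.any(k <= 0):
        raise ValueError("Calpha and k must be positive")

    grid = np.asarray(times, dtype=float)
    if include_t0:
        grid = np.concatenate([[0.0], grid])
    rows = []
    for i in range(n):
        c = first_order_model(grid, calpha[i], k[i])
        glucose = c / GLUCOSE_TO_STARCH
        if noise_sd > 0:
            glucose = glucose + rng.normal(0.0, noise_sd, size=grid.size)
        glucose = np.maximum(glucose, 0.0)
        row = {"sample": f"samp{i + 1:03d}", "total_starch": 100.0}
        row.update({f"time_{int(t)}": g for t, g in zip(grid, glucose)})
        rows.append(row)
    curves = pd.DataFrame(rows)
    truth = pd.DataFrame({"sample": curves["sample"],
                          "calpha": calpha, "k": k})
    return curves, truth


def simulate_rs_readouts(rs_true: np.ndarray, gopod_factor: float = 100.0,
                         dilution: float = 10.0, sample_mass: float = 10.0,
                         absorbance_blank: float = 0.05,
                         ) -> pd.DataFrame:
    """Invert the RS arithmetic to build GOPOD read-outs with known RS%."""
    rs_true = np.asarray(rs_true, dtype=float)
    if np.any(rs_true < 0):
        raise ValueError("RS% must be non-negative")
    glucose_ug = rs_true / 100.0 * sample_mass * 1000.0 / GLUCOSE_TO_STARCH
    net_abs = glucose_ug / (gopod_factor * dilution)
    return pd.DataFrame({
        "sample": [f"samp{i + 1:03d}" for i in range(rs_true.size)],
        "absorbance_sample": net_abs + absorbance_blank,
        "absorbance_blank": absorbance_blank,
        "gopod_factor": gopod_factor,
        "dilution": dilution,
        "sample_mass": sample_mass,
    })


# ---------------------------------------------------------------------------
# gene models


def simulate_gene_models(n_genes: int, G: GenotypeMatrix,
                         flag_rate: float = 0.3,
                         rng_seed: int | None = 0) -> list[GeneModel]:
    """Place non-overlapping single-exon genes over the marker coordinates.

    Markers are split into ``n_genes`` contiguous blocks per chromosome
    allotment; each block becomes one gene spanning its markers (with a
    small flank), and in-gene markers are flagged exonic + nonsynonymous
    with probability ``flag_rate``.  Flags are written into ``G.markers``
    in place and the gene models returned.
    """
    rng = np.random.default_rng(rng_seed)
    if not 0 <= flag_rate <= 1:
        raise ValueError("flag_rate must be in [0, 1]")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_genes > G.n_markers:
        raise ValueError("more genes than markers to place them on")

    for col in ("in_gene", "exonic", "nonsynonymous"):
        G.markers[col] = False

    genes = []
    marker_blocks = np.array_split(np.arange(G.n_markers), n_genes)
    gid = 0
    for block in marker_blocks:
        if block.size == 0:
            continue
        sub = G.markers.iloc[block]
        if sub["chrom"].nunique() > 1:  # never span a chromosome break
            sub = sub[sub["chrom"] == sub["chrom"].iloc[0]]
            block = block[: len(sub)]
        gid += 1
        start = max(int(sub["pos"].min()) - 500, 1)
        end = int(sub["pos"].max()) + 500
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(gene_id=f"gene{gid:03d}", chrom=str(sub["chrom"].iloc[0]),
                               start=start, end=end, strand=strand,
                               exons=[(start, end)]))
        G.markers.loc[G.markers.index[block], "in_gene"] = True
        flagged = rng.random(block.size) < flag_rate
        G.markers.loc[G.markers.index[block[flagged]], "exonic"] = True
        G.markers.loc[G.markers.index[block[flagged]], "nonsynonymous"] = True
    return genes


# ---------------------------------------------------------------------------
# full dataset


def simulate_dataset(config: SimConfig, outdir=None, n_genes: int = 10,
                     flag_rate: float = 0.5):
    """Generate a coherent panel: genotypes, phenotypes, gene models, truth.

    When ``outdir`` is given, writes genotypes.vcf, genotypes.hapmap.tsv,
    phenotypes.csv, genes.gff3 and truth.json there.
    """
    G, labels = simulate_genotypes(config)
    genes = simulate_gene_models(n_genes, G, flag_rate=flag_rate,
                                 rng_seed=config.rng_seed + 2)
    pheno, truth = simulate_phenotypes(G, config)
    truth.subpop_labels = labels
    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_vcf(G, outdir / "genotypes.vcf")
        write_hapmap(G, outdir / "genotypes.hapmap.tsv")
        pheno.to_csv(outdir / "phenotypes.csv", index=False)
        write_gff3(genes, outdir / "genes.gff3")
        truth.to_json(outdir / "truth.json")
    return G, labels, pheno, genes, truth
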