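"""Mixed-linear-model association scan with kinship correction.

The model per trait is  y = X b + Z g + u + e  with u ~ N(0, sg2 K) and
e ~ N(0, se2 I).  Variance components are REML-estimated once on the null
model (no marker) through the eigendecomposition of K, then held fixed for
the per-marker generalized-least-squares tests (the
population-parameters-previously-determined shortcut).  Downstream stages:
suggestive-threshold MTA calling, forward-selection multi-locus LOD
confirmation, per-marker PVE, per-allele phenotypic effects with a
favorable-allele call, and candidate-gene assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genio import MISSING, GeneModel, GenotypeMatrix
from .traits import FAVORABLE_DIRECTION

SUGGESTIVE_NEGLOG10P = 5.0
LOD_THRESHOLD = 3.0
PEAK_WINDOW_BP = 1_000_000


@dataclass
class KinshipMatrix:
    values: np.ndarray
    samples: list[str]
    estimator: str = "vanraden"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("kinship shape does not match sample count")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")


@dataclass
class MixedModelFit:
    sigma_g2: float
    sigma_e2: float
    delta: float           # se2 / sg2
    loglik: float          # REML log-likelihood at the optimum
    beta: np.ndarray       # fixed-effect estimates
    # cached spectral pieces reused by the scan
    eigvals: np.ndarray = field(repr=False, default=None)
    eigvecs: np.ndarray = field(repr=False, default=None)

    @property
    def h2(self) -> float:
        """Narrow-sense heritability implied by the variance components."""
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


def kinship(G: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden genomic relationship matrix from mean-imputed calls.

    K = W W' / (2 * sum p_j (1 - p_j)) with W the calls centered by twice
    the alt-allele frequency.  Monomorphic markers contribute nothing.
    """
    X = G.imputed()
    p = X.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all markers monomorphic; kinship undefined")
    W = X[:, poly] - 2.0 * p[poly]
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    K = W @ W.T / denom
    return KinshipMatrix(values=(K + K.T) / 2.0, samples=list(G.samples))


def structure_covariates(G: GenotypeMatrix, n_components: int = 3) -> np.ndarray:
    """Intercept plus leading principal-component scores of centered calls.

    Component signs are fixed (largest-|loading| entry positive) so output
    is deterministic; any residual sign flip leaves downstream p-values
    unchanged.
    """
    if n_components <= 0:
        raise ValueError("n_components must be positive")
    if n_components >= G.n_samples:
        raise ValueError("n_components must be < n_accessions")
    X = G.imputed()
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    for j in range(scores.shape[1]):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return np.column_stack([np.ones(G.n_samples), scores])


# ---------------------------------------------------------------------------
# REML null model (EMMA-style spectral 1-D optimization)


def _reml_pieces(delta, d, ys, Xs):
    """Weighted GLS of rotated y on rotated X at a given delta.

    Returns (beta, weighted RSS, logdet terms) for the REML criterion.
    """
    w = 1.0 / (d + delta)
    Xw = Xs * w[:, None]
    XtWX = Xs.T @ Xw
    XtWy = Xw.T @ ys
    beta = np.linalg.solve(XtWX, XtWy)
    r = ys - Xs @ beta
    rss = float(np.sum(w * r * r))
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    return beta, rss, float(np.sum(np.log(d + delta))), logdet_xwx


def _reml_loglik(delta, d, ys, Xs, logdet_xtx):
    n, p = Xs.shape
    _, rss, logdet_v, logdet_xwx = _reml_pieces(delta, d, ys, Xs)
    df = n - p
    sg2 = rss / df
    return -0.5 * (df * (np.log(2 * np.pi * sg2) + 1.0)
                   + logdet_v + logdet_xwx - logdet_xtx)


def fit_null_mlm(y: np.ndarray, Q: np.ndarray, K: KinshipMatrix) -> MixedModelFit:
    """REML fit of the no-marker mixed model via eigendecomposition of K.

    The variance ratio delta = se2/sg2 is profiled over a log-spaced grid
    (1e-5 .. 1e5) and refined with bounded scalar optimization around the
    grid optimum, so the returned likelihood is a global optimum over that
    search range.
    """
    y = np.asarray(y, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")
    n = y.size
    if Q.shape[0] != n or K.values.shape[0] != n:
        raise ValueError("dimension mismatch between y, Q and K")
    if np.linalg.matrix_rank(Q) < Q.shape[1]:
        raise ValueError("covariate matrix is singular")

    d, U = np.linalg.eigh(K.values)
    d = np.maximum(d, 0.0)
    ys = U.T @ y
    Xs = U.T @ Q
    _, logdet_xtx = np.linalg.slogdet(Q.T @ Q)

    grid = np.logspace(-5, 5, 61)
    lls = np.array([_reml_loglik(dl, d, ys, Xs, logdet_xtx) for dl in grid])
    i = int(np.argmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda t: -_reml_loglik(np.exp(t), d, ys, Xs, logdet_xtx),
        bounds=(np.log(lo), np.log(hi)), method="bounded",
        options={"xatol": 1e-10})
    delta = float(np.exp(res.x))
    ll = _reml_loglik(delta, d, ys, Xs, logdet_xtx)
    if lls[i] > ll:  # keep the grid point if refinement went sideways
        delta, ll = float(grid[i]), float(lls[i])

    beta, rss, _, _ = _reml_pieces(delta, d, ys, Xs)
    df = n - Q.shape[1]
    sg2 = rss / df
    return MixedModelFit(sigma_g2=sg2, sigma_e2=delta * sg2, delta=delta,
                         loglik=float(ll), beta=beta, eigvals=d, eigvecs=U)


# ---------------------------------------------------------------------------
# single-locus scan


def scan_mlm(G: GenotypeMatrix, y: np.ndarray, Q: np.ndarray,
             K: KinshipMatrix, null: MixedModelFit | None = None,
             ) -> pd.DataFrame:
    """Per-marker GLS test with variance parameters fixed from the null fit.

    Equivalent to whitening by the null covariance and running ordinary
    regression of y on [Q, marker] per marker; two-sided p from the t
    distribution with n - p - 1 df.  Missing calls are mean-imputed;
    monomorphic markers are skipped; a marker collinear with the covariates
    is reported with beta = 0 and p = 1 (documented contract).

    Returns a frame with columns snp, chrom, pos, beta, se, p, neglog10p,
    pve (percent of phenotypic variance, beta^2 Var(g)/Var(y)).
    """
    y = np.asarray(y, dtype=float)
    if null is None:
        null = fit_null_mlm(y, Q, K)
    d, U = null.eigvals, null.eigvecs
    w = 1.0 / (d + null.delta)
    sw = np.sqrt(w)

    yt = sw * (U.T @ y)
    Xt = sw[:, None] * (U.T @ np.asarray(Q, dtype=float))
    Qo, _ = np.linalg.qr(Xt)
    yr = yt - Qo @ (Qo.T @ yt)

    Ximp = G.imputed()
    var_g = Ximp.var(axis=0, ddof=1) if G.n_samples > 1 else np.zeros(G.n_markers)
    poly = Ximp.std(axis=0) > 0

    Gt = sw[:, None] * (U.T @ Ximp)
    Gr = Gt - Qo @ (Qo.T @ Gt)

    n, p = Xt.shape
    dof = n - p - 1
    gg = np.einsum("ij,ij->j", Gr, Gr)
    gy = Gr.T @ yr
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy / gg
        rss = yr @ yr - beta * gy
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / gg)
        tstat = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)

    collinear = poly & (gg <= 1e-10 * max(float(yr @ yr), 1.0))
    beta = np.where(collinear, 0.0, beta)
    se = np.where(collinear, np.nan, se)
    pvals = np.where(collinear, 1.0, pvals)

    var_y = y.var(ddof=1)
    pve = np.clip(100.0 * beta ** 2 * var_g / var_y, 0.0, 100.0)

    out = pd.DataFrame({
        "snp": G.markers["id"], "chrom": G.markers["chrom"],
        "pos": G.markers["pos"], "beta": beta, "se": se, "p": pvals,
        "neglog10p": -np.log10(np.maximum(pvals, np.finfo(float).tiny)),
        "pve": pve,
    })
    return out[poly].reset_index(drop=True)


def pve_of_snp(beta: float, g: np.ndarray, y: np.ndarray) -> float:
    """Percent variance explained: 100 * beta^2 Var(g) / Var(y).

    One of several GAPIT-era conventions; Var(g) is the sample variance of
    the (imputed) marker codes.
    """
    y = np.asarray(y, dtype=float)
    if y.var(ddof=1) == 0:
        raise ValueError("zero trait variance")
    return float(np.clip(
        100.0 * beta ** 2 * np.asarray(g, float).var(ddof=1) / y.var(ddof=1),
        0.0, 100.0))


def suggestive_mtas(records: pd.DataFrame,
                    threshold_neglog10p: float = SUGGESTIVE_NEGLOG10P,
                    peak_window_bp: int | None = None) -> pd.DataFrame:
    """Records with -log10(p) strictly above the suggestive threshold.

    With ``peak_window_bp`` set, associations are additionally grouped into
    per-chromosome peaks (greedy from the smallest p outward) and only the
    top record per window kept.
    """
    hits = records[records["neglog10p"] > threshold_neglog10p].copy()
    if peak_window_bp is None or hits.empty:
        return hits.reset_index(drop=True)
    kept = []
    for _, grp in hits.groupby("chrom", sort=False):
        grp = grp.sort_values("p")
        taken: list[int] = []
        for _, row in grp.iterrows():
            if all(abs(row["pos"] - grp.loc[i, "pos"]) > peak_window_bp
                   for i in taken):
                taken.append(row.name)
        kept.append(grp.loc[taken])
    return (pd.concat(kept).sort_values(["chrom", "pos"])
            .reset_index(drop=True))


# ---------------------------------------------------------------------------
# multi-locus LOD confirmation


def _ml_loglik(rss: float, n: int) -> float:
    return -0.5 * n * (np.log(2 * np.pi * rss / n) + 1.0)


@dataclass
class LodConfirm:
    """Forward-selection multi-locus confirmation stage.

    A documented stand-in for the multi-locus mixed-model family: the data
    are whitened by the null mixed-model covariance, candidate markers are
    added by forward selection (likelihood-ratio entry test at
    ``entry_alpha``), and each candidate's LOD is the log10 likelihood
    ratio of dropping it from (or adding it to) the final joint model.
    Markers with LOD strictly above ``lod_threshold`` are flagged
    confirmed.
    """

    lod_threshold: float = LOD_THRESHOLD
    entry_alpha: float = 0.01

    def run(self, y: np.ndarray, Q: np.ndarray, K: KinshipMatrix,
            G: GenotypeMatrix, candidates, null: MixedModelFit | None = None,
            ) -> pd.DataFrame:
        y = np.asarray(y, dtype=float)
        if null is None:
            null = fit_null_mlm(y, Q, K)
        d, U = null.eigvals, null.eigvecs
        sw = np.sqrt(1.0 / (d + null.delta))
        yt = sw * (U.T @ y)
        Xt = sw[:, None] * (U.T @ np.asarray(Q, dtype=float))

        candidates = list(candidates)
        Ximp = G.imputed()
        Gt = sw[:, None] * (U.T @ Ximp[:, candidates])
        n, p = Xt.shape
        max_terms = max(n - p - 2, 0)

        def rss_of(cols: list[int]) -> float:
            design = np.column_stack([Xt] + [Gt[:, c] for c in cols])
            resid = yt - design @ np.linalg.lstsq(design, yt, rcond=None)[0]
            return float(resid @ resid)

        selected: list[int] = []
        remaining = list(range(len(candidates)))
        rss_cur = rss_of([])
        while remaining and len(selected) < max_terms:
            trials = [(rss_of(selected + [c]), c) for c in remaining]
            rss_best, best = min(trials)
            lrt = 2.0 * (_ml_loglik(rss_best, n) - _ml_loglik(rss_cur, n))
            if stats.chi2.sf(max(lrt, 0.0), df=1) < self.entry_alpha:
                selected.append(best)
                remaining.remove(best)
                rss_cur = rss_best
            else:
                break

        ll_full = _ml_loglik(rss_cur, n)
        rows = []
        for c in range(len(candidates)):
            if c in selected:
                ll_red = _ml_loglik(rss_of([s for s in selected if s != c]), n)
                lrt = 2.0 * (ll_full - ll_red)
            else:
                ll_aug = _ml_loglik(rss_of(selected + [c]), n)
                lrt = 2.0 * (ll_aug - ll_full)
            lod = max(lrt, 0.0) / (2.0 * np.log(10.0))
            j = candidates[c]
            rows.append({
                "snp": G.markers["id"].iloc[j], "marker_index": j,
                "lod": lod, "in_model": c in selected,
                "confirmed": lod > self.lod_threshold,
            })
        return pd.DataFrame(rows)


def lod_confirm(y, Q, K, G, candidates, null=None,
                lod_threshold: float = LOD_THRESHOLD,
                entry_alpha: float = 0.01) -> pd.DataFrame:
    """Functional wrapper around :class:`LodConfirm`."""
    stage = LodConfirm(lod_threshold=lod_threshold, entry_alpha=entry_alpha)
    return stage.run(y, Q, K, G, candidates, null=null)


# ---------------------------------------------------------------------------
# allele effects and candidate genes


@dataclass
class AlleleEffect:
    snp: str
    trait: str
    a_ref: float
    a_alt: float
    favorable_allele: str   # "ref" or "alt"
    favorable_base: str


def allele_effect_ai(calls: np.ndarray, y: np.ndarray, trait: str,
                     snp: str = "", ref: str = "ref", alt: str = "alt",
                     ) -> AlleleEffect:
    """Per-allele phenotypic effect a_i and the favorable allele.

    a_i = mean(y over carriers of allele i) - mean(y over all scored
    accessions); heterozygotes carry both alleles.  The favorable allele is
    the one whose effect sign matches the trait's breeding direction (up
    for AC, KL, LBR, ASV, KLAC, LER, GC, RS; down for KB, KBAC, PGI).
    """
    if trait not in FAVORABLE_DIRECTION:
        raise ValueError(f"unknown trait {trait!r}")
    calls = np.asarray(calls)
    y = np.asarray(y, dtype=float)
    ok = (calls != MISSING) & np.isfinite(y)
    calls, y = calls[ok], y[ok]
    ref_car = (calls == 0) | (calls == 1)
    alt_car = (calls == 2) | (calls == 1)
    if not ref_car.any() or not alt_car.any():
        raise ValueError("marker is monomorphic among scored accessions")
    overall = y.mean()
    a_ref = float(y[ref_car].mean() - overall)
    a_alt = float(y[alt_car].mean() - overall)
    direction = FAVORABLE_DIRECTION[trait]
    fav = "ref" if direction * a_ref >= direction * a_alt else "alt"
    return AlleleEffect(snp=snp, trait=trait, a_ref=a_ref, a_alt=a_alt,
                        favorable_allele=fav,
                        favorable_base=ref if fav == "ref" else alt)


def assign_candidate_genes(chrom: str, pos: int, genes: list[GeneModel],
                           ) -> list[tuple[str, int]]:
    """Candidate gene(s) for one marker: containing gene, else both flanks.

    Returns a list of (gene_id, distance) pairs: distance 0 for a
    containing gene, otherwise one entry for the nearest gene on each side
    that exists.
    """
    on_chrom = [g for g in genes if g.chrom == str(chrom)]
    if not on_chrom:
        raise ValueError(f"no gene models on chromosome {chrom}")
    inside = [g for g in on_chrom if g.contains(str(chrom), pos)]
    if inside:
        return [(g.gene_id, 0) for g in inside[:1]]
    left = [g for g in on_chrom if g.end < pos]
    right = [g for g in on_chrom if g.start > pos]
    out = []
    if left:
        g = max(left, key=lambda g: g.end)
        out.append((g.gene_id, pos - g.end))
    if right:
        g = min(right, key=lambda g: g.start)
        out.append((g.gene_id, g.start - pos))
    return out


def genomic_inflation(pvals: np.ndarray) -> float:
    """Lambda_GC: median scan chi-square over its null median (0.4549...)."""
    pvals = np.asarray(pvals, dtype=float)
    pvals = pvals[np.isfinite(pvals) & (pvals > 0) & (pvals <= 1)]
    chi2 = stats.chi2.isf(pvals, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))
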