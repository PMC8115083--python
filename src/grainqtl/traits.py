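"""Grain-quality trait definitions, derived ratios, classification and descriptive statistics.

The panel traits are eleven grain-quality measurements:

========  =======================================  =========
code      meaning                                  units
========  =======================================  =========
AC        amylose content                          %
KL        kernel length                            mm
KB        kernel breadth                           mm
LBR       kernel length/breadth ratio              ratio
ASV       alkali spreading value                   score 1-7
KLAC      kernel length after cooking              mm
KBAC      kernel breadth after cooking             mm
LER       linear elongation ratio                  ratio
GC        gel consistency (gel flow length)        mm
RS        resistant starch                         %
PGI       predicted glycemic index                 index
========  =======================================  =========

For every trait a breeding-preferred ("favorable") direction is defined:
larger is better for all traits except KB, KBAC and PGI, which breeders
want to decrease.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

TRAITS: tuple[str, ...] = (
    "AC", "KL", "KB", "LBR", "ASV", "KLAC", "KBAC", "LER", "GC", "RS", "PGI",
)

#: +1 -> favorable allele/haplotype increases the trait, -1 -> decreases it.
FAVORABLE_DIRECTION: dict[str, int] = {
    "AC": +1, "KL": +1, "KB": -1, "LBR": +1, "ASV": +1, "KLAC": +1,
    "KBAC": -1, "LER": +1, "GC": +1, "RS": +1, "PGI": -1,
}

#: Gel-consistency bands in mm of gel flow; instrument scale bottoms out at 25.
GC_SOFT_MIN = 61.0
GC_MEDIUM_MIN = 41.0
GC_SCALE_MIN = 25.0


class BelowScaleWarning(UserWarning):
    """Gel length below the lowest calibrated band of the GC scale."""


def derive_ratios(kl, kb, klac=None):
    """Derived kernel ratios: length/breadth ratio and linear elongation ratio.

    LBR = KL / KB.  LER = KLAC / KL (cooked length relative to raw length);
    returned as NaN when ``klac`` is not provided.  Inputs may be scalars or
    array-likes; zero or negative denominators raise ``ValueError``.
    """
    kl = np.asarray(kl, dtype=float)
    kb = np.asarray(kb, dtype=float)
    if np.any(kl[~np.isnan(kl)] <= 0) or np.any(kb[~np.isnan(kb)] <= 0):
        raise ValueError("kernel dimensions must be positive")
    lbr = kl / kb
    if klac is None:
        ler = np.full_like(lbr, np.nan)
    else:
        klac = np.asarray(klac, dtype=float)
        ler = klac / kl
    if lbr.ndim == 0:
        return float(lbr), float(ler)
    return lbr, ler


def classify_gc(gel_length: float) -> str:
    """Classify a gel-consistency measurement (mm) as soft / medium / hard.

    Bands: soft >= 61 mm, medium [41, 61) mm, hard < 41 mm.  The published
    bands (61-100, 41-60, 25-40) leave gaps at 40-41 and 60-61 and say
    nothing below 25; half-open banding at 41 and 61 closes the gaps, and
    values below 25 classify as hard with a :class:`BelowScaleWarning`.
    """
    gel_length = float(gel_length)
    if not np.isfinite(gel_length) or gel_length <= 0:
        raise ValueError(f"gel length must be positive, got {gel_length}")
    if gel_length < GC_SCALE_MIN:
        warnings.warn(
            f"gel length {gel_length} mm is below the {GC_SCALE_MIN} mm scale "
            "minimum; classified as hard",
            BelowScaleWarning,
            stacklevel=2,
        )
    if gel_length >= GC_SOFT_MIN:
        return "soft"
    if gel_length >= GC_MEDIUM_MIN:
        return "medium"
    return "hard"


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlations(pheno: pd.DataFrame, traits=None, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlations among trait columns, with significance stars.

    Uses pairwise-complete observations.  Returns a long-format frame with
    columns ``trait_a, trait_b, n, r, p, stars`` covering every unordered
    pair once.  Pairs with a constant column or fewer than ``min_pairs``
    complete observations get ``r = p = NaN``.
    """
    if traits is None:
        traits = [t for t in TRAITS if t in pheno.columns]
    rows = []
    for a, b in combinations(traits, 2):
        x = pd.to_numeric(pheno[a], errors="coerce")
        y = pd.to_numeric(pheno[b], errors="coerce")
        ok = x.notna() & y.notna()
        n = int(ok.sum())
        if n < min_pairs or x[ok].nunique() < 2 or y[ok].nunique() < 2:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(x[ok], y[ok])
        rows.append({"trait_a": a, "trait_b": b, "n": n,
                     "r": float(r), "p": float(p), "stars": _stars(p)})
    return pd.DataFrame(rows)


def correlation_matrix(pheno: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Square symmetric matrix of pairwise-complete Pearson r (diagonal 1)."""
    if traits is None:
        traits = [t for t in TRAITS if t in pheno.columns]
    long = correlations(pheno, traits=traits, min_pairs=3)
    mat = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    for _, row in long.iterrows():
        mat.loc[row.trait_a, row.trait_b] = row.r
        mat.loc[row.trait_b, row.trait_a] = row.r
    return mat


def descriptives(pheno: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Per-trait mean, min, max and sample SD (n-1 denominator).

    Raises ``ValueError`` if a requested trait column has no non-missing
    values.
    """
    if traits is None:
        traits = [t for t in TRAITS if t in pheno.columns]
    rows = []
    for t in traits:
        x = pd.to_numeric(pheno[t], errors="coerce").dropna()
        if x.empty:
            raise ValueError(f"trait column {t!r} has no observed values")
        rows.append({
            "trait": t,
            "n": int(x.size),
            "mean": float(x.mean()),
            "min": float(x.min()),
            "max": float(x.max()),
            "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0,
        })
    return pd.DataFrame(rows).set_index("trait")
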