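"""Gene-level haplotype calling and haplotype-phenotype analysis.

A gene haplotype is the joint pattern of flagged (nonsynonymous exonic or
exonic indel) variant calls inside one gene span.  Accessions sharing an
identical pattern share a haplotype; labels H1, H2, ... are ordered by
descending frequency (ties by first occurrence).  Haplotype groups carried
by at least ``min_n`` lines are compared by one-way ANOVA followed by
Duncan's multiple range test, and the haplotype with the best mean in the
trait's favorable direction is flagged superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import studentized_range

from .genio import MISSING, GeneModel, GenotypeMatrix
from .traits import FAVORABLE_DIRECTION


@dataclass
class HaplotypeAssignment:
    gene_id: str
    labels: dict          # accession -> "H1", "H2", ...
    patterns: dict        # "H1" -> tuple of calls
    excluded: dict = field(default_factory=dict)  # accession -> reason

    @property
    def n_haplotypes(self) -> int:
        return len(self.patterns)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"accession": list(self.labels), "haplotype": list(self.labels.values())})


@dataclass
class HaploPhenoTable:
    gene_id: str
    trait: str
    table: pd.DataFrame   # haplotype, n, freq_pct, mean, letters, tested, superior
    anova_f: float
    anova_p: float
    mse: float
    df_error: int
    note: str = ""

    @property
    def has_letters(self) -> bool:
        return bool(self.table["letters"].astype(bool).any())


def extract_gene_variants(G: GenotypeMatrix, gene: GeneModel) -> GenotypeMatrix:
    """Markers inside the gene span that are exonic AND (nonsynonymous OR indel)."""
    m = G.markers
    in_span = ((m["chrom"] == gene.chrom)
               & (m["pos"] >= gene.start) & (m["pos"] <= gene.end))
    flagged = m["exonic"] & (m["nonsynonymous"] | m["indel"])
    return G.take_markers(np.where(in_span & flagged)[0])


def call_haplotypes(sub: GenotypeMatrix, gene_id: str = "") -> HaplotypeAssignment:
    """Group accessions by their exact call pattern over the gene's variants.

    Accessions with any missing call in the submatrix are excluded (no
    phantom haplotypes from partial patterns).  An empty submatrix puts
    every accession in H1.
    """
    if sub.n_markers == 0:
        labels = {s: "H1" for s in sub.samples}
        return HaplotypeAssignment(gene_id=gene_id, labels=labels,
                                   patterns={"H1": ()})
    groups: dict[tuple, list[str]] = {}
    order: dict[tuple, int] = {}
    excluded = {}
    for i, acc in enumerate(sub.samples):
        row = sub.calls[i]
        if np.any(row == MISSING):
            excluded[acc] = "missing call in gene"
            continue
        pat = tuple(int(c) for c in row)
        groups.setdefault(pat, []).append(acc)
        order.setdefault(pat, i)
    ranked = sorted(groups, key=lambda p: (-len(groups[p]), order[p]))
    labels, patterns = {}, {}
    for h, pat in enumerate(ranked, start=1):
        patterns[f"H{h}"] = pat
        for acc in groups[pat]:
            labels[acc] = f"H{h}"
    return HaplotypeAssignment(gene_id=gene_id, labels=labels,
                               patterns=patterns, excluded=excluded)


def haplotype_frequencies(assignment: HaplotypeAssignment) -> pd.DataFrame:
    """Counts and percent frequencies over included accessions, descending."""
    if not assignment.labels:
        raise ValueError("assignment contains no included accessions")
    counts = pd.Series(list(assignment.labels.values())).value_counts()
    n_total = int(counts.sum())
    df = pd.DataFrame({
        "haplotype": counts.index, "n": counts.to_numpy(),
        "freq_pct": 100.0 * counts.to_numpy() / n_total,
    })
    df["rank"] = df["haplotype"].str.removeprefix("H").astype(int)
    return (df.sort_values(["n", "rank"], ascending=[False, True])
            .drop(columns="rank").reset_index(drop=True))


@lru_cache(maxsize=16384)
def _duncan_q(span: int, df_error: int, alpha: float) -> float:
    """Critical studentized range at Duncan's protection level 1-(1-a)^(p-1).

    Cached: scipy's studentized_range.ppf is expensive (~0.1 s per call).
    """
    return float(studentized_range.ppf((1.0 - alpha) ** (span - 1),
                                       span, df_error))


def duncan_mrt(means, sizes, mse: float, df_error: int,
               alpha: float = 0.05) -> list[str]:
    """Duncan's multiple range test letter display.

    The shortest significant range for a span of p ordered means uses the
    studentized range at protection level alpha_p = 1 - (1-alpha)^(p-1):
    R_p = q(1-alpha_p, p, df) * sqrt(mse / n_h), with n_h the harmonic mean
    of the two group sizes compared (Kramer adjustment for unequal n).
    Groups not separated by a significant range share a letter.  Letters
    are returned in the input order of ``means``.
    """
    means = np.asarray(means, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    k = means.size
    if k < 2:
        raise ValueError("need at least 2 groups")
    if df_error < 1 or mse <= 0:
        raise ValueError("require df_error >= 1 and mse > 0")
    if np.any(sizes < 1):
        raise ValueError("group sizes must be >= 1")

    order = np.argsort(-means)  # descending
    m_sorted = means[order]
    n_sorted = sizes[order]

    qcrit = {span: _duncan_q(span, int(df_error), float(alpha))
             for span in range(2, k + 1)}

    def significant(i: int, j: int) -> bool:
        """Are sorted means i < j separated? (range test over their span)"""
        span = j - i + 1
        n_h = 2.0 / (1.0 / n_sorted[i] + 1.0 / n_sorted[j])
        rp = qcrit[span] * np.sqrt(mse / n_h)
        return (m_sorted[i] - m_sorted[j]) > rp

    def homogeneous(i: int, j: int) -> bool:
        return all(not significant(a, b)
                   for a in range(i, j + 1) for b in range(a + 1, j + 1))

    # maximal homogeneous stretches of the sorted means, one letter each
    intervals: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and homogeneous(i, j + 1):
            j += 1
        if not intervals or j > intervals[-1][1]:  # skip nested stretches
            intervals.append((i, j))

    letters_sorted = ["" for _ in range(k)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for li, (i, j) in enumerate(intervals):
        ch = alphabet[li % len(alphabet)]
        for g in range(i, j + 1):
            letters_sorted[g] += ch

    out = ["" for _ in range(k)]
    for rank, idx in enumerate(order):
        out[idx] = letters_sorted[rank]
    return out


def haplo_pheno_table(assignment: HaplotypeAssignment, pheno: pd.DataFrame,
                      trait: str, min_n: int = 2, alpha: float = 0.05,
                      ) -> HaploPhenoTable:
    """Per-haplotype trait means with ANOVA and Duncan letters.

    ``pheno`` must have an ``accession`` column and the trait column.
    Haplotypes carried by fewer than ``min_n`` scored lines are listed with
    their means but excluded from testing.  With fewer than 2 testable
    haplotypes the table is returned letter-free with a notice.
    """
    if trait not in pheno.columns:
        raise ValueError(f"trait {trait!r} not in phenotype table")
    y = pheno.set_index("accession")[trait].astype(float)

    freq = haplotype_frequencies(assignment)
    values: dict[str, np.ndarray] = {}
    for hap in freq["haplotype"]:
        accs = [a for a, h in assignment.labels.items() if h == hap]
        v = y.reindex(accs).dropna().to_numpy()
        values[hap] = v
    freq["n_scored"] = [values[h].size for h in freq["haplotype"]]
    freq["mean"] = [float(values[h].mean()) if values[h].size else np.nan
                    for h in freq["haplotype"]]
    freq["tested"] = freq["n_scored"] >= min_n

    tested = freq[freq["tested"]]["haplotype"].tolist()
    note = ""
    letters = {h: "" for h in freq["haplotype"]}
    f_stat = p_val = mse = np.nan
    df_error = 0
    if len(tested) < 2:
        note = "fewer than 2 testable haplotypes; letters omitted"
    else:
        groups = [values[h] for h in tested]
        f_stat, p_val = stats.f_oneway(*groups)
        n_tot = sum(g.size for g in groups)
        df_error = n_tot - len(groups)
        if df_error < 1:
            note = "no error degrees of freedom; letters omitted"
        else:
            mse = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups) / df_error
            if mse <= 0:
                note = "zero within-group variance; letters omitted"
            else:
                lets = duncan_mrt([values[h].mean() for h in tested],
                                  [values[h].size for h in tested],
                                  mse, df_error, alpha=alpha)
                letters.update(dict(zip(tested, lets)))
    freq["letters"] = [letters[h] for h in freq["haplotype"]]
    return HaploPhenoTable(gene_id=assignment.gene_id, trait=trait,
                           table=freq, anova_f=float(f_stat),
                           anova_p=float(p_val), mse=float(mse),
                           df_error=int(df_error), note=note)


def superior_haplotype(result: HaploPhenoTable,
                       trait: str | None = None) -> tuple[str, bool]:
    """Best-performing tested haplotype in the trait's favorable direction.

    Returns (label, separated): ties on the mean break toward larger n then
    lower label index; ``separated`` is False when the winner shares a
    letter with every other tested haplotype (no statistical separation).
    Raises on a letter-free table.
    """
    trait = trait or result.trait
    if trait not in FAVORABLE_DIRECTION:
        raise ValueError(f"unknown trait {trait!r}")
    if not result.has_letters:
        raise ValueError("table has no Duncan letters; cannot rank haplotypes")
    direction = FAVORABLE_DIRECTION[trait]
    t = result.table[result.table["tested"]].copy()
    t["rank_idx"] = t["haplotype"].str.removeprefix("H").astype(int)
    t = t.sort_values(["mean", "n_scored", "rank_idx"],
                      ascending=[direction < 0, False, True])
    best = t.iloc[0]
    others = t.iloc[1:]
    separated = True
    if len(others):
        best_letters = set(best["letters"])
        separated = not all(best_letters & set(l) for l in others["letters"])
    return str(best["haplotype"]), separated
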