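"""Genotype matrix and gene-model IO plus SNP quality-control filtering.

Genotype calls are coded per accession x marker as 0 (ref-hom), 2 (alt-hom),
1 (het, optional in inbred panels) and -1 (missing).  Coordinates are
1-based throughout, matching VCF and GFF3.  VCF reading uses cyvcf2; GFF3
reading uses gffutils; the simple text writers are local.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

#: INFO flags used to round-trip per-marker annotation through VCF.
_FLAG_INFO = {"in_gene": "INGENE", "exonic": "EXONIC",
              "nonsynonymous": "NSYN", "indel": "INDEL"}
ANNOTATION_COLUMNS = tuple(_FLAG_INFO)


@dataclass
class GenotypeMatrix:
    """Accessions x biallelic markers.

    ``markers`` is a frame with columns ``id, chrom, pos, ref, alt`` plus
    boolean annotation flags ``in_gene, exonic, nonsynonymous, indel``;
    marker ids follow the S{chrom}_{pos} convention.  ``calls`` is an int8
    array of shape (n_samples, n_markers).
    """

    samples: list[str]
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers")
        if self.markers["id"].duplicated().any():
            raise ValueError("duplicate marker ids")
        for col in ANNOTATION_COLUMNS:
            if col not in self.markers.columns:
                self.markers[col] = False
        self.markers = self.markers.reset_index(drop=True)
        for chrom, grp in self.markers.groupby("chrom", sort=False):
            if np.any(np.diff(grp["pos"].to_numpy()) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {chrom}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def alt_freq(self) -> np.ndarray:
        """Per-marker alternative-allele frequency over non-missing calls.

        Markers with no observed calls get NaN.
        """
        obs = self.calls != MISSING
        n_obs = obs.sum(axis=0)
        dosage = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, dosage / (2.0 * n_obs), np.nan)

    def missing_fraction(self) -> np.ndarray:
        return (self.calls == MISSING).mean(axis=0)

    def imputed(self) -> np.ndarray:
        """Float call matrix with missing replaced by the per-marker mean."""
        x = self.calls.astype(float)
        x[self.calls == MISSING] = np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nan_to_num(np.nanmean(x, axis=0))
        idx = np.where(np.isnan(x))
        x[idx] = means[idx[1]]
        return x

    def take_markers(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=self.markers.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index],
        )


@dataclass
class QCReport:
    n_input: int
    n_pass: int
    n_fail_maf: int
    n_fail_missing: int
    maf_min: float
    missing_max: float
    use_minor: bool = False

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


@dataclass
class GeneModel:
    """One gene span with exon intervals; 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exons: list = field(default_factory=list)

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start")
        for (s, e) in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(
                    f"{self.gene_id}: exon ({s},{e}) outside gene span "
                    f"({self.start},{self.end})")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


# ---------------------------------------------------------------------------
# reading


def read_genotypes(path, fmt: str = "vcf") -> GenotypeMatrix:
    """Read a genotype matrix from VCF or a HapMap-like TSV.

    Multi-allelic VCF records are dropped (the count is warned about);
    phased and unphased GT separators are treated identically.
    """
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "hapmap_tsv":
        return _read_hapmap(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records, call_rows = [], []
    n_multi = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        codes = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            codes[i] = a + b
        rec = {
            "id": v.ID or f"S{v.CHROM}_{v.POS}",
            "chrom": str(v.CHROM), "pos": int(v.POS),
            "ref": v.REF, "alt": v.ALT[0],
        }
        for col, tag in _FLAG_INFO.items():
            rec[col] = bool(v.INFO.get(tag) is not None)
        records.append(rec)
        call_rows.append(codes)
    vcf.close()
    if n_multi:
        warnings.warn(f"dropped {n_multi} multi-allelic site(s)", UserWarning,
                      stacklevel=3)
    markers = pd.DataFrame(records,
                           columns=["id", "chrom", "pos", "ref", "alt",
                                    *ANNOTATION_COLUMNS])
    calls = (np.array(call_rows, dtype=np.int8).T if call_rows
             else np.empty((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(samples=samples, markers=markers, calls=calls)


_HAPMAP_COLS = ["rs", "chrom", "pos", "alleles"]


def _read_hapmap(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in _HAPMAP_COLS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"hapmap file lacks columns {missing_cols}")
    samples = [c for c in df.columns if c not in _HAPMAP_COLS]
    records, call_rows = [], []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        ref, _, alt = row.alleles.partition("/")
        if not ref or not alt:
            raise ValueError(f"line {lineno}: malformed alleles {row.alleles!r}")
        codes = np.full(len(samples), MISSING, dtype=np.int8)
        for i, s in enumerate(samples):
            g = getattr(row, s) if s.isidentifier() else df.iloc[lineno - 2][s]
            g = str(g)
            if g in ("NN", "nan", "--"):
                continue
            if len(g) != 2 or any(a not in (ref, alt) for a in g):
                raise ValueError(f"line {lineno}: bad genotype {g!r} for {s}")
            codes[i] = sum(a == alt for a in g)
        records.append({"id": row.rs, "chrom": str(row.chrom),
                        "pos": int(row.pos), "ref": ref, "alt": alt})
        call_rows.append(codes)
    markers = pd.DataFrame(records, columns=["id", "chrom", "pos", "ref", "alt"])
    calls = (np.array(call_rows, dtype=np.int8).T if call_rows
             else np.empty((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(samples=samples, markers=markers, calls=calls)


def read_gene_models(path) -> list[GeneModel]:
    """Parse gene spans and exon intervals from GFF3 (1-based inclusive)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = [(e.start, e.end) for e in db.children(g, featuretype="exon",
                                                       order_by="start")]
        genes.append(GeneModel(gene_id=g.id, chrom=str(g.seqid),
                               start=g.start, end=g.end, strand=g.strand,
                               exons=exons))
    return genes


# ---------------------------------------------------------------------------
# writing


def write_vcf(G: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=grainqtl\n")
        for chrom in pd.unique(G.markers["chrom"]):
            maxpos = int(G.markers.loc[G.markers["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={maxpos + 1000}>\n")
        for col, tag in _FLAG_INFO.items():
            fh.write(f'##INFO=<ID={tag},Number=0,Type=Flag,'
                     f'Description="{col} marker">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.samples) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, m in G.markers.iterrows():
            flags = [tag for col, tag in _FLAG_INFO.items() if m[col]]
            info = ";".join(flags) if flags else "."
            gts = "\t".join(gt_map[int(c)] for c in G.calls[:, j])
            fh.write(f"{m['chrom']}\t{m['pos']}\t{m['id']}\t{m['ref']}\t"
                     f"{m['alt']}\t.\tPASS\t{info}\tGT\t{gts}\n")


def write_hapmap(G: GenotypeMatrix, path) -> None:
    rows = []
    for j, m in G.markers.iterrows():
        code_map = {0: m["ref"] * 2, 1: m["ref"] + m["alt"],
                    2: m["alt"] * 2, MISSING: "NN"}
        row = {"rs": m["id"], "chrom": m["chrom"], "pos": m["pos"],
               "alleles": f"{m['ref']}/{m['alt']}"}
        for i, s in enumerate(G.samples):
            row[s] = code_map[int(G.calls[i, j])]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_gff3(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tgrainqtl\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(f"{g.chrom}\tgrainqtl\texon\t{s}\t{e}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}.exon{i};"
                         f"Parent={g.gene_id}\n")


# ---------------------------------------------------------------------------
# QC


def filter_snps(G: GenotypeMatrix, maf_min: float = 0.01,
                missing_max: float = 0.2,
                use_minor: bool = False) -> tuple[GenotypeMatrix, QCReport]:
    """Keep markers with allele frequency >= maf_min and missingness <= missing_max.

    The frequency filtered on is the *alternative* allele frequency by
    default (taken literally from the source filter definition); set
    ``use_minor`` for a conventional minor-allele frequency filter.  A
    marker failing both rules is counted once, under the frequency rule.
    """
    if G.n_markers == 0:
        raise ValueError("empty genotype matrix")
    freq = G.alt_freq()
    if use_minor:
        freq = np.minimum(freq, 1.0 - freq)
    miss = G.missing_fraction()
    with np.errstate(invalid="ignore"):
        fail_maf = ~(freq >= maf_min)  # NaN freq (all-missing marker) fails
        fail_missing = (miss > missing_max) & ~fail_maf
    keep = ~fail_maf & ~fail_missing
    report = QCReport(
        n_input=G.n_markers, n_pass=int(keep.sum()),
        n_fail_maf=int(fail_maf.sum()), n_fail_missing=int(fail_missing.sum()),
        maf_min=maf_min, missing_max=missing_max, use_minor=use_minor,
    )
    if report.n_pass == 0:
        warnings.warn("all markers removed by QC", UserWarning, stacklevel=2)
    return G.take_markers(np.where(keep)[0]), report
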