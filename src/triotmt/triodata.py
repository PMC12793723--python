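"""Reading, validation and output of trio genotype and phenotype data.

Genotypes are coded-allele counts in {0, 1, 2} with -1 as the missing
sentinel.  The coded allele is the VCF ALT allele; signed statistics
downstream are reported relative to it.  Two on-disk genotype sources are
supported: a VCF (v4.x) plus a PLINK-style .fam pedigree defining the trios,
and a self-contained SNP-major matrix TSV used for small fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

SNP_META_COLUMNS = ["snp_id", "chrom", "pos", "coded_allele", "other_allele"]


@dataclass
class TrioGenotypeSet:
    """Aligned I x J child/mother/father genotype matrices with metadata.

    Attributes
    ----------
    G, Zm, Zp
        I x J int8 matrices of child, maternal and paternal coded-allele
        counts; -1 marks a missing genotype.
    snp_meta
        DataFrame with columns ``snp_id, chrom, pos, coded_allele,
        other_allele`` (one row per SNP).
    trio_ids
        DataFrame with columns ``child, mother, father`` (one row per trio).
    """

    G: np.ndarray
    Zm: np.ndarray
    Zp: np.ndarray
    snp_meta: pd.DataFrame
    trio_ids: pd.DataFrame

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=np.int8)
        self.Zm = np.asarray(self.Zm, dtype=np.int8)
        self.Zp = np.asarray(self.Zp, dtype=np.int8)
        self.validate()

    @property
    def n_snps(self) -> int:
        return self.G.shape[0]

    @property
    def n_trios(self) -> int:
        return self.G.shape[1]

    def validate(self) -> None:
        if not (self.G.shape == self.Zm.shape == self.Zp.shape):
            raise ValueError("G, Zm, Zp must share shape I x J")
        if len(self.snp_meta) != self.G.shape[0]:
            raise ValueError("snp_meta length must equal number of SNPs")
        if len(self.trio_ids) != self.G.shape[1]:
            raise ValueError("trio_ids length must equal number of trios")
        for name, mat in (("G", self.G), ("Zm", self.Zm), ("Zp", self.Zp)):
            bad = ~np.isin(mat, (0, 1, 2, MISSING))
            if bad.any():
                raise ValueError(f"{name} contains entries outside {{0,1,2,missing}}")
        children = self.trio_ids["child"]
        if children.duplicated().any():
            raise ValueError("duplicated child identifier in trios")
        parents = pd.concat([self.trio_ids["mother"], self.trio_ids["father"]])
        if parents.duplicated().any():
            raise ValueError("a parent appears in more than one trio")
        if set(children) & set(parents):
            raise ValueError("a sample appears both as parent and child")


@dataclass
class PhenotypeVector:
    """Child phenotypes aligned to trio order; NaN marks missing."""

    values: np.ndarray
    kind: str  # "quantitative" or "binary"
    missing: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.missing = np.isnan(self.values)
        if self.kind not in ("quantitative", "binary"):
            raise ValueError(f"unknown phenotype kind {self.kind!r}")
        if self.kind == "binary":
            obs = self.values[~self.missing]
            if not np.isin(obs, (0.0, 1.0)).all():
                raise ValueError("binary phenotype has values outside {0,1}")

    def __len__(self) -> int:
        return len(self.values)


def _read_fam(path) -> pd.DataFrame:
    fam = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype=str,
    )
    return fam


def _trios_from_fam(fam: pd.DataFrame, samples: set[str]) -> pd.DataFrame:
    """Complete trios from a .fam table, dropping those with absent parents."""
    rows = []
    for _, r in fam.iterrows():
        if r.pat in ("0", None) or r.mat in ("0", None):
            continue
        if r.iid not in samples:
            logger.warning("child %s absent from genotype source; trio dropped", r.iid)
            continue
        if r.mat not in samples or r.pat not in samples:
            logger.warning("parent of child %s missing; trio dropped", r.iid)
            continue
        rows.append({"child": r.iid, "mother": r.mat, "father": r.pat})
    trios = pd.DataFrame(rows, columns=["child", "mother", "father"])
    if trios["child"].duplicated().any():
        raise ValueError("duplicated child in pedigree")
    if len(trios) == 0:
        raise ValueError("zero complete trios in pedigree")
    return trios


def _load_vcf(vcf_path, trios: pd.DataFrame):
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    sample_idx = {s: i for i, s in enumerate(vcf.samples)}
    meta_rows, geno_rows = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        gt = np.asarray(var.gt_types, dtype=np.int8)
        gt[gt == 3] = MISSING  # cyvcf2 gts012: 3 == unknown
        meta_rows.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": var.CHROM,
                "pos": var.POS,
                "coded_allele": var.ALT[0],
                "other_allele": var.REF,
            }
        )
        geno_rows.append(gt)
    if n_skipped:
        logger.warning("skipped %d non-SNP or multi-allelic records", n_skipped)
    if not geno_rows:
        raise ValueError("no biallelic SNP records in VCF")
    geno = np.vstack(geno_rows)
    ci = [sample_idx[c] for c in trios["child"]]
    mi = [sample_idx[m] for m in trios["mother"]]
    fi = [sample_idx[f] for f in trios["father"]]
    meta = pd.DataFrame(meta_rows, columns=SNP_META_COLUMNS)
    return geno[:, ci], geno[:, mi], geno[:, fi], meta


def load_trios(genotype_source, pedigree=None) -> TrioGenotypeSet:
    """Load aligned trio genotypes from a VCF + .fam, or a matrix TSV.

    VCF genotypes are read as ALT-allele counts; phase, if present, is
    ignored.  Trios whose members are absent from the genotype source are
    dropped with a warning; zero complete trios is an error.
    """
    path = Path(genotype_source)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        if pedigree is None:
            raise ValueError("a .fam pedigree is required with a VCF source")
        trios = _trios_from_fam(_read_fam(pedigree), _vcf_samples(path))
        g, zm, zp, meta = _load_vcf(path, trios)
        return TrioGenotypeSet(G=g, Zm=zm, Zp=zp, snp_meta=meta, trio_ids=trios)
    return load_matrix_tsv(path)


def _vcf_samples(vcf_path) -> set[str]:
    from cyvcf2 import VCF

    return set(VCF(str(vcf_path)).samples)


def load_matrix_tsv(path) -> TrioGenotypeSet:
    """Load the SNP-major fixture dialect written by :func:`write_matrix_tsv`."""
    trios_rows = []
    header = None
    data_lines = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##trio\t"):
                _, child, mother, father = line.split("\t")
                trios_rows.append({"child": child, "mother": mother, "father": father})
            elif line.startswith("#"):
                header = line[1:].split("\t")
            elif line:
                data_lines.append(line.split("\t"))
    if header is None or not trios_rows:
        raise ValueError(f"{path} is not a trio matrix TSV")
    trios = pd.DataFrame(trios_rows)
    if len(data_lines) == 0:
        raise ValueError("zero SNP rows in matrix TSV")
    df = pd.DataFrame(data_lines, columns=header)
    meta = df[SNP_META_COLUMNS].copy()
    meta["pos"] = meta["pos"].astype(int)

    def col(name_fmt):
        cols = [name_fmt.format(c) for c in trios["child"]]
        return (
            df[cols].replace("NA", str(MISSING)).astype(np.int8).to_numpy()
        )

    return TrioGenotypeSet(
        G=col("{}.G"),
        Zm=col("{}.Zm"),
        Zp=col("{}.Zp"),
        snp_meta=meta.reset_index(drop=True),
        trio_ids=trios,
    )


def write_matrix_tsv(trios: TrioGenotypeSet, path) -> None:
    """Write the self-contained SNP-major fixture dialect (NA for missing)."""
    with open(path, "w") as fh:
        for _, r in trios.trio_ids.iterrows():
            fh.write(f"##trio\t{r.child}\t{r.mother}\t{r.father}\n")
        cols = list(SNP_META_COLUMNS)
        for c in trios.trio_ids["child"]:
            cols += [f"{c}.G", f"{c}.Zm", f"{c}.Zp"]
        fh.write("#" + "\t".join(cols) + "\n")
        for i in range(trios.n_snps):
            row = [str(trios.snp_meta.iloc[i][k]) for k in SNP_META_COLUMNS]
            for j in range(trios.n_trios):
                for mat in (trios.G, trios.Zm, trios.Zp):
                    v = int(mat[i, j])
                    row.append("NA" if v == MISSING else str(v))
            fh.write("\t".join(row) + "\n")


def load_phenotypes(path, trio_ids, kind: str | None = None) -> PhenotypeVector:
    """Load a two-column (id, value) TSV aligned to trio order.

    ``kind`` is auto-detected as binary iff every non-missing value is 0 or 1;
    pass ``kind`` explicitly to override.  Children absent from the file get a
    missing value with a warning; non-numeric values are a hard error naming
    the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("phenotype TSV needs an id column and a value column")
    id_col, val_col = df.columns[:2]
    mapping = {}
    for idx, row in df.iterrows():
        raw = row[val_col]
        if pd.isna(raw) or raw == "NA":
            val = np.nan
        else:
            try:
                val = float(raw)
            except ValueError:
                raise ValueError(
                    f"non-numeric phenotype {raw!r} for sample {row[id_col]!r} "
                    f"(row {idx + 2} of {path})"
                ) from None
        mapping[row[id_col]] = val
    children = trio_ids["child"] if hasattr(trio_ids, "columns") else pd.Series(trio_ids)
    values = np.full(len(children), np.nan)
    for j, child in enumerate(children):
        if child in mapping:
            values[j] = mapping[child]
        else:
            logger.warning("phenotype missing for child %s", child)
    if kind is None:
        obs = values[~np.isnan(values)]
        kind = "binary" if len(obs) and np.isin(obs, (0.0, 1.0)).all() else "quantitative"
    return PhenotypeVector(values=values, kind=kind)


def write_phenotypes(pheno: PhenotypeVector, trio_ids: pd.DataFrame, path) -> None:
    df = pd.DataFrame({"sample_id": trio_ids["child"], "value": pheno.values})
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def write_results(results: pd.DataFrame, path) -> None:
    """Write a per-SNP result table (TMT or TDT) as TSV with NA sentinels."""
    if results is None or len(results) == 0:
        raise ValueError("refusing to write an empty result table")
    results.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
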