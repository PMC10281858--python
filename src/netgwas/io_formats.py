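"""Readers and writers for genotypes, annotations, networks, phenotypes and results.

Genotypes are minor-allele dosages in {0, 1, 2}. Two on-disk genotype formats
are supported:

* PLINK binary triplets (``.bed``/``.bim``/``.fam``, SNP-major ``.bed``).
* A self-contained TSV whose first column is ``sample_id`` and whose remaining
  column headers encode the SNP coordinates as ``<chrom>:<pos>:<snp_id>``.

All genomic coordinates are 1-based inclusive (PLINK/GFF convention).
Chromosome labels are ordered by natural sort (1, 2, ..., 10 — not 1, 10, 2)
so that the circular SNP order used by the permutation null is deterministic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -9  # sentinel for a missing dosage before imputation

_PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major .bed


def natural_chrom_key(label: str):
    """Sort key ordering chromosome labels naturally: 1 < 2 < ... < 10 < 2L < X."""
    parts = re.split(r"(\d+)", str(label))
    return tuple(int(p) if p.isdigit() else p for p in parts if p != "")


@dataclass
class GenotypeDataset:
    """An n-samples x p-SNPs dosage matrix with genomic coordinates.

    Columns are sorted by (natural chromosome order, ascending position);
    this total order is what the circular permutation rotates around.
    """

    dosages: np.ndarray  # (n, p) int8, values in {0, 1, 2}
    snp_ids: np.ndarray  # (p,) str
    chrom: np.ndarray  # (p,) str
    pos: np.ndarray  # (p,) int, 1-based
    sample_ids: np.ndarray  # (n,) str

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def p(self) -> int:
        return self.dosages.shape[1]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self._validate_and_sort()

    def _validate_and_sort(self):
        n, p = self.dosages.shape
        if n < 2 or p < 1:
            raise ValueError(f"need n >= 2 samples and p >= 1 SNPs, got n={n}, p={p}")
        if not (len(self.snp_ids) == len(self.chrom) == len(self.pos) == p):
            raise ValueError("SNP metadata length does not match dosage columns")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match dosage rows")
        keys = list(zip((natural_chrom_key(c) for c in self.chrom), self.pos))
        order = sorted(range(p), key=lambda j: keys[j])
        if order != list(range(p)):
            self.dosages = self.dosages[:, order]
            self.snp_ids = self.snp_ids[order]
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
        triples = set(zip(self.chrom, self.pos, self.snp_ids))
        if len(triples) != p:
            raise ValueError("duplicate (chrom, pos, snp_id) among SNPs")

    def impute_missing(self) -> int:
        """Replace MISSING entries by the rounded per-SNP mean dosage. Returns count."""
        miss = self.dosages == MISSING
        n_miss = int(miss.sum())
        if n_miss:
            d = self.dosages.astype(float)
            d[miss] = np.nan
            col_mean = np.nanmean(d, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            fill = np.clip(np.rint(col_mean), 0, 2).astype(self.dosages.dtype)
            self.dosages = np.where(miss, fill[None, :], self.dosages)
            logger.info("imputed %d missing genotype calls to rounded per-SNP means", n_miss)
        return n_miss


@dataclass
class PhenotypeTable:
    """Continuous traits keyed by sample id; columns are trait names."""

    sample_ids: np.ndarray
    traits: pd.DataFrame  # index aligned with sample_ids

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path, format: str = "auto") -> GenotypeDataset:
    """Read genotypes from a PLINK triplet prefix or a dosage TSV.

    ``format`` is ``plink-bed``, ``tsv`` or ``auto`` (sniffed from the path).
    Missing dosages are imputed to the rounded per-SNP mean; the imputation
    count is logged.
    """
    path = Path(path)
    if format == "auto":
        if path.suffix in {".tsv", ".txt"} and path.exists():
            format = "tsv"
        else:
            format = "plink-bed"
    if format == "tsv":
        ds = _read_genotypes_tsv(path)
    elif format == "plink-bed":
        ds = _read_genotypes_plink(path)
    else:
        raise ValueError(f"unknown genotype format: {format!r}")
    ds.impute_missing()
    return ds


def _parse_snp_header(col: str, colno: int):
    parts = col.split(":")
    if len(parts) != 3:
        raise ValueError(
            f"genotype TSV column {colno} header {col!r} is not '<chrom>:<pos>:<snp_id>'"
        )
    chrom, pos, snp_id = parts
    return chrom, int(pos), snp_id


def _read_genotypes_tsv(path: Path) -> GenotypeDataset:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be 'sample_id'")
    meta = [_parse_snp_header(c, j + 1) for j, c in enumerate(df.columns[1:])]
    values = df.iloc[:, 1:].to_numpy()
    ok = np.isin(values, (0, 1, 2, MISSING))
    if not ok.all():
        i, j = np.argwhere(~ok)[0]
        raise ValueError(
            f"{path}: non-{{0,1,2}} dosage {values[i, j]!r} at row {i + 2}, column {j + 2}"
        )
    return GenotypeDataset(
        dosages=values.astype(np.int8),
        snp_ids=[m[2] for m in meta],
        chrom=[m[0] for m in meta],
        pos=[m[1] for m in meta],
        sample_ids=df["sample_id"].to_numpy(dtype=object),
    )


def write_genotypes(dataset: GenotypeDataset, path, format: str = "tsv") -> None:
    """Write genotypes as a dosage TSV or a PLINK .bed/.bim/.fam triplet."""
    path = Path(path)
    if format == "tsv":
        cols = [
            f"{c}:{p}:{s}"
            for c, p, s in zip(dataset.chrom, dataset.pos, dataset.snp_ids)
        ]
        df = pd.DataFrame(dataset.dosages, columns=cols)
        df.insert(0, "sample_id", dataset.sample_ids)
        df.to_csv(path, sep="\t", index=False)
    elif format == "plink-bed":
        _write_genotypes_plink(dataset, path)
    else:
        raise ValueError(f"unknown genotype format: {format!r}")


# PLINK .bed 2-bit codes (SNP-major): 00 = hom A1 (dosage 2 of the counted
# allele), 01 = missing, 10 = het, 11 = hom A2 (dosage 0). Samples are packed
# 4 per byte, least-significant bits first.
_BED_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_BED_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def _plink_triplet(prefix: Path):
    prefix = Path(prefix)
    if prefix.suffix == ".bed":
        prefix = prefix.with_suffix("")
    return (
        prefix.with_suffix(".bed"),
        prefix.with_suffix(".bim"),
        prefix.with_suffix(".fam"),
    )


def _read_genotypes_plink(prefix: Path) -> GenotypeDataset:
    bed_p, bim_p, fam_p = _plink_triplet(prefix)
    for f in (bed_p, bim_p, fam_p):
        if not f.exists():
            raise FileNotFoundError(f"PLINK file missing: {f}")
    bim = pd.read_csv(
        bim_p,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str},
    )
    fam = pd.read_csv(fam_p, sep=r"\s+", header=None, dtype=str)
    n, p = len(fam), len(bim)
    raw = bed_p.read_bytes()
    if raw[:3] != _PLINK_MAGIC:
        raise ValueError(f"{bed_p}: not a SNP-major PLINK .bed file (bad magic)")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * p
    if len(raw) != expected:
        raise ValueError(
            f"PLINK dimension mismatch: {bed_p} has {len(raw)} bytes but "
            f"{bim_p} ({p} SNPs) and {fam_p} ({n} samples) imply {expected}"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(p, bytes_per_snp)
    # unpack 2-bit codes, least-significant pair first
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(p, bytes_per_snp * 4)[:, :n]
    dosages = _BED_CODE_TO_DOSAGE[codes].T  # (n, p)
    return GenotypeDataset(
        dosages=np.ascontiguousarray(dosages),
        snp_ids=bim["snp_id"].to_numpy(dtype=object),
        chrom=bim["chrom"].to_numpy(dtype=object),
        pos=bim["pos"].to_numpy(),
        sample_ids=fam.iloc[:, 1].to_numpy(dtype=object),
    )


def _write_genotypes_plink(dataset: GenotypeDataset, prefix: Path) -> None:
    bed_p, bim_p, fam_p = _plink_triplet(prefix)
    n, p = dataset.n, dataset.p
    bim = pd.DataFrame(
        {
            "chrom": dataset.chrom,
            "snp_id": dataset.snp_ids,
            "cm": 0,
            "pos": dataset.pos,
            "a1": "A",
            "a2": "B",
        }
    )
    bim.to_csv(bim_p, sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": dataset.sample_ids,
            "iid": dataset.sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(fam_p, sep="\t", header=False, index=False)
    code_lut = np.empty(256, dtype=np.uint8)
    for d, c in _DOSAGE_TO_BED_CODE.items():
        code_lut[d & 0xFF] = c  # int8 sentinel wraps to its uint8 bit pattern
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((p, bytes_per_snp * 4), dtype=np.uint8)  # pad bits stay 0
    padded[:, :n] = code_lut[dataset.dosages.T.astype(np.uint8)]
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (padded.reshape(p, bytes_per_snp, 4) << shifts[None, None, :]).sum(
        axis=2, dtype=np.uint16
    ).astype(np.uint8)
    with open(bed_p, "wb") as fh:
        fh.write(_PLINK_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# annotation, network, phenotypes, covariates


def read_annotation(path) -> pd.DataFrame:
    """Read a gene annotation TSV with columns gene_id, chrom, start, end.

    Coordinates are 1-based inclusive. gene_id must be unique, start <= end.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: annotation needs columns {sorted(required)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{path}: duplicate gene_id {dup!r}")
    if (df["start"] > df["end"]).any():
        bad = df[df["start"] > df["end"]].iloc[0]
        raise ValueError(f"{path}: gene {bad['gene_id']} has start > end")
    return df[["gene_id", "chrom", "start", "end"]]


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_network(path, known_genes=None) -> list[tuple[str, str]]:
    """Read a two-column TSV edge list into a deduplicated undirected edge list.

    Self-loops are dropped and duplicate/reversed edges collapsed (simple,
    undirected graph contract); the number dropped is logged. Edges naming a
    gene absent from ``known_genes`` (when given) are kept with a warning —
    such nodes simply contribute no SNPs.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    dropped = 0
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    start = 0
    if lines and lines[0].lower().replace("\t", " ").split()[:2] in (
        ["gene_a", "gene_b"],
        ["source", "target"],
    ):
        start = 1
    unknown: set[str] = set()
    known = set(known_genes) if known_genes is not None else None
    for ln in lines[start:]:
        fields = ln.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}: edge line has fewer than two columns: {ln!r}")
        a, b = fields[0].strip(), fields[1].strip()
        if a == b:
            dropped += 1
            continue
        key = (a, b) if a < b else (b, a)
        if key in seen:
            dropped += 1
            continue
        seen.add(key)
        edges.append(key)
        if known is not None:
            unknown.update(g for g in key if g not in known)
    if dropped:
        logger.info("dropped %d self-loop/duplicate edges from %s", dropped, path)
    if unknown:
        logger.warning(
            "%d network genes absent from annotation (kept, no SNPs): %s",
            len(unknown),
            ", ".join(sorted(unknown)[:5]),
        )
    return edges


def write_network(edges, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def read_phenotypes(path) -> PhenotypeTable:
    """Read a phenotype table: TSV with a ``sample_id`` column plus one column
    per continuous trait, or a whitespace-separated FAM-style file (six
    columns, no header; trait taken from column six, sample id from the IID).
    """
    path = Path(path)
    first = path.read_text().splitlines()[0] if path.stat().st_size else ""
    if "sample_id" in first:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        traits = df.drop(columns=["sample_id"]).astype(float)
        table = PhenotypeTable(df["sample_id"].to_numpy(dtype=object), traits)
    else:
        df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
        if df.shape[1] < 6:
            raise ValueError(f"{path}: FAM-style phenotype needs >= 6 columns")
        traits = pd.DataFrame({"trait": df.iloc[:, 5].astype(float).replace(-9.0, np.nan)})
        table = PhenotypeTable(df.iloc[:, 1].to_numpy(dtype=object), traits)
    for name in table.trait_names:
        vals = table.traits[name].to_numpy()
        finite = vals[np.isfinite(vals)]
        if len(np.unique(finite)) < 2:
            raise ValueError(f"{path}: trait {name!r} has fewer than 2 distinct finite values")
    return table


def write_phenotypes(table: PhenotypeTable, path) -> None:
    df = table.traits.copy()
    df.insert(0, "sample_id", table.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: covariate table needs a 'sample_id' column")
    return df


def align_samples(dataset: GenotypeDataset, phenotypes: PhenotypeTable, covariates: pd.DataFrame | None = None):
    """Inner-join genotypes/phenotypes/covariates on sample id.

    Returns (row index into dataset, phenotype frame, covariate frame or None)
    in the genotype row order restricted to shared samples. Dropped samples
    are logged.
    """
    geno_ids = list(dataset.sample_ids)
    pheno_pos = {s: i for i, s in enumerate(phenotypes.sample_ids)}
    keep = [i for i, s in enumerate(geno_ids) if s in pheno_pos]
    cov = None
    if covariates is not None:
        cov_pos = {s: i for i, s in enumerate(covariates["sample_id"])}
        keep = [i for i in keep if geno_ids[i] in cov_pos]
        cov = covariates.drop(columns=["sample_id"]).iloc[
            [cov_pos[geno_ids[i]] for i in keep]
        ].reset_index(drop=True)
    dropped = dataset.n - len(keep)
    if dropped:
        logger.info("dropped %d samples without phenotype/covariate rows", dropped)
    if len(keep) < 2:
        raise ValueError("fewer than 2 samples shared between genotypes and phenotypes")
    pheno = phenotypes.traits.iloc[[pheno_pos[geno_ids[i]] for i in keep]].reset_index(drop=True)
    return np.asarray(keep, dtype=int), pheno, cov


# ---------------------------------------------------------------------------
# results

RESULT_COLUMNS = [
    "gene_id",
    "n_snps_in_neighborhood",
    "lrt_statistic",
    "pvalue",
    "fdr_significant",
]


def write_results(results: pd.DataFrame, path) -> None:
    """Write per-neighborhood association results as a TSV sorted by gene_id."""
    if len(results) == 0:
        raise ValueError("refusing to write an empty results table")
    missing = [c for c in RESULT_COLUMNS if c not in results.columns]
    if missing:
        raise ValueError(f"results table missing columns: {missing}")
    out = results[RESULT_COLUMNS].sort_values("gene_id").reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    df["fdr_significant"] = df["fdr_significant"].astype(bool)
    return df
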