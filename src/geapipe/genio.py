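"""Genotype and table I/O, SNP pruning, and Sambada-style genotype encoding.

Genotypes are held as a SNPs x samples dosage matrix (alt-allele counts
0/1/2, -1 for missing calls) with optional per-call allele depths, read
from biallelic VCF records.  Pruning follows the conventional
reduced-representation workflow: drop SNPs with too much missing data or
too rare a minor allele, then expand each biallelic SNP into its (at most)
three genotype-class indicator variables -- the binary unit a logistic
genotype-environment association model tests.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

GENOTYPE_CLASSES = ("hom_ref", "het", "hom_alt")


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages for a set of samples.

    ``dosage`` is an int8 array of shape (n_snps, n_samples) holding the
    alt-allele count per call (0, 1, 2) with -1 for missing.  ``ad``, when
    present, is an int32 array of shape (n_snps, n_samples, 2) with
    (ref, alt) read depths per call; positions 1-based as in VCF.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray
    ad: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.snp_ids), len(self.sample_ids)):
            raise ValueError("dosage shape inconsistent with ids")
        if self.ad is not None and self.ad.shape[:2] != self.dosage.shape:
            raise ValueError("allele-depth shape inconsistent with dosage")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.dosage != MISSING

    def missingness(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        return 1.0 - self.called().mean(axis=1)

    def alt_frequency(self) -> np.ndarray:
        """Per-SNP alt-allele frequency over called alleles only."""
        called = self.called()
        n_called = called.sum(axis=1)
        alt = np.where(called, self.dosage, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)

    def maf(self) -> np.ndarray:
        f = self.alt_frequency()
        return np.minimum(f, 1.0 - f)

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snp_ids=[self.snp_ids[i] for i in index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            dosage=self.dosage[index],
            ad=None if self.ad is None else self.ad[index],
        )


@dataclass
class GenotypeIndicators:
    """Binary genotype-class indicators, one row per (SNP, class).

    ``values`` has shape (n_indicators, n_samples) with entries in {0, 1}
    and NaN where the underlying call is missing; ``meta`` has one row per
    indicator with columns ``snp_id`` and ``genotype_class``.
    """

    values: np.ndarray
    meta: pd.DataFrame
    sample_ids: list[str] = field(default_factory=list)

    @property
    def n_indicators(self) -> int:
        return self.values.shape[0]


def read_vcf(path: str) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records are skipped with a warning.  GT is encoded as the
    alt-allele count; AD (ref, alt) is captured when present on any record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chrom, pos, ref, alt, ids = [], [], [], [], []
    dosage_rows, ad_rows = [], []
    n_multi = 0
    any_ad = False
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        gt = v.gt_types.astype(np.int8)  # 0,1,2 dosage; 3 = missing
        gt[gt == 3] = MISSING
        dosage_rows.append(gt)
        try:
            ad = v.format("AD")
        except KeyError:
            ad = None
        if ad is not None and ad.shape[1] >= 2:
            any_ad = True
            ad = np.clip(ad[:, :2].astype(np.int32), 0, None)
        else:
            ad = np.zeros((len(samples), 2), dtype=np.int32)
        ad_rows.append(ad)
    vcf.close()
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic records")
    n = len(ids)
    return GenotypeMatrix(
        sample_ids=samples,
        snp_ids=ids,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        dosage=(
            np.vstack(dosage_rows) if n else np.zeros((0, len(samples)), dtype=np.int8)
        ),
        ad=(np.stack(ad_rows) if (n and any_ad) else None),
    )


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a :class:`GenotypeMatrix` as an uncompressed VCF 4.2 file.

    Output is deterministic byte-for-byte given the same matrix.
    """
    lines = ["##fileformat=VCFv4.2", "##source=geapipe"]
    for c in sorted(set(map(str, gm.chrom))):
        lines.append(f"##contig=<ID={c}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">'
    )
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(gm.sample_ids)
    )
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    fmt = "GT:AD" if gm.ad is not None else "GT"
    for i in range(gm.n_snps):
        fields = [
            str(gm.chrom[i]),
            str(int(gm.pos[i])),
            gm.snp_ids[i],
            str(gm.ref[i]),
            str(gm.alt[i]),
            ".",
            "PASS",
            ".",
            fmt,
        ]
        for j in range(gm.n_samples):
            cell = gt_str[int(gm.dosage[i, j])]
            if gm.ad is not None:
                cell += f":{int(gm.ad[i, j, 0])},{int(gm.ad[i, j, 1])}"
            fields.append(cell)
        lines.append("\t".join(fields))
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def filter_snps(
    gm: GenotypeMatrix, md_max: float = 0.20, maf_min: float = 0.05
) -> GenotypeMatrix:
    """Prune SNPs by missing-data fraction and minor allele frequency.

    A SNP is removed when its missingness strictly exceeds ``md_max`` or
    its MAF (computed over called alleles) is strictly below ``maf_min``;
    boundary values are kept.  Returns a new matrix; before/after counts
    are logged.
    """
    for name, t in (("md_max", md_max), ("maf_min", maf_min)):
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {t}")
    if gm.n_snps == 0:
        raise ValueError("empty genotype matrix")
    md = gm.missingness()
    maf = gm.maf()
    keep = (md <= md_max) & ~np.isnan(maf) & (maf >= maf_min)
    out = gm.take_snps(np.nonzero(keep)[0])
    logger.info("filter_snps: %d SNPs -> %d SNPs", gm.n_snps, out.n_snps)
    return out


def encode_genotypes(gm: GenotypeMatrix) -> GenotypeIndicators:
    """Expand each biallelic SNP into three genotype-class indicators.

    For every called sample exactly one of the hom_ref/het/hom_alt
    indicators is 1; a missing call is missing in all three.
    """
    n = gm.n_snps * 3
    values = np.empty((n, gm.n_samples), dtype=np.float32)
    snp_col, class_col = [], []
    for c, cls in enumerate(GENOTYPE_CLASSES):
        block = (gm.dosage == c).astype(np.float32)
        block[gm.dosage == MISSING] = np.nan
        values[c::3] = block
        # interleaved rows: snp0/hom_ref, snp0/het, snp0/hom_alt, snp1/...
    order = np.arange(n)
    snp_col = [gm.snp_ids[i // 3] for i in order]
    class_col = [GENOTYPE_CLASSES[i % 3] for i in order]
    meta = pd.DataFrame({"snp_id": snp_col, "genotype_class": class_col})
    return GenotypeIndicators(values=values, meta=meta, sample_ids=list(gm.sample_ids))


def collapse_indicators(ind: GenotypeIndicators) -> np.ndarray:
    """Reconstruct the dosage matrix from genotype-class indicators."""
    n_snps = ind.n_indicators // 3
    out = np.full((n_snps, ind.values.shape[1]), MISSING, dtype=np.int8)
    for c in range(3):
        block = ind.values[c::3]
        out[block == 1.0] = c
    return out


def summarize_frequencies(gm: GenotypeMatrix) -> dict[str, pd.DataFrame]:
    """Per-SNP allele frequencies, per-sample heterozygosity, and
    per-indicator carrier frequencies.

    Heterozygosity is the proportion of het calls among a sample's called
    sites; carrier frequency is the fraction of called samples whose
    indicator is 1.
    """
    called = gm.called()
    alt = gm.alt_frequency()
    snp = pd.DataFrame(
        {
            "snp_id": gm.snp_ids,
            "alt_freq": alt,
            "maf": np.minimum(alt, 1.0 - alt),
            "missingness": gm.missingness(),
        }
    )
    n_called = called.sum(axis=0)
    het = (gm.dosage == 1).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        het_prop = np.where(n_called > 0, het / n_called, np.nan)
    sample = pd.DataFrame({"sample_id": gm.sample_ids, "heterozygosity": het_prop})
    rows = []
    for c, cls in enumerate(GENOTYPE_CLASSES):
        count = ((gm.dosage == c) & called).sum(axis=1)
        denom = called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(denom > 0, count / denom, np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "snp_id": gm.snp_ids,
                    "genotype_class": cls,
                    "carrier_freq": freq,
                }
            )
        )
    indicator = pd.concat(rows, ignore_index=True)
    return {"snp": snp, "sample": sample, "indicator": indicator}


def read_env_table(path: str) -> pd.DataFrame:
    """Read a per-sample environment table (CSV, first column sample id)."""
    df = pd.read_csv(path, index_col=0)
    if df.columns.duplicated().any():
        raise ValueError("duplicated environment variable names")
    return df


def read_sample_table(path: str) -> pd.DataFrame:
    """Read the sample table (CSV with sample_id, lon, lat, ... columns)."""
    df = pd.read_csv(path)
    required = {"sample_id", "lon", "lat"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample table must contain columns {sorted(required)}")
    return df
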