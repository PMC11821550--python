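"""Intersect SNP coordinates with gene models from a GFF3 file.

Each candidate SNP is classified against the gene features it falls in,
with precedence UTR > exon > intron (a UTR is sub-exonic, so a position
inside an annotated UTR is reported as UTR, not exon; a position inside a
gene span but outside its exons is intronic).  A SNP overlapping several
genes yields one hit per gene; a SNP outside every gene span is
intergenic.  GFF3 coordinates are 1-based inclusive and converted to
0-based half-open internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

_GENE_TYPES = {"gene", "pseudogene"}
_EXON_TYPES = {"exon"}
_UTR5 = {"five_prime_utr", "five_prime_UTR", "5'UTR"}
_UTR3 = {"three_prime_utr", "three_prime_UTR", "3'UTR"}


@dataclass
class FeatureIndex:
    """Per-sequence interval trees of genes and their sub-features."""

    genes: dict[str, IntervalTree] = field(default_factory=dict)
    # per gene id: strand, name, lists of (start0, end0) for exon/utr5/utr3
    gene_info: dict[str, dict] = field(default_factory=dict)
    n_skipped: int = 0

    @property
    def n_features(self) -> int:
        return sum(
            1 + len(g["exons"]) + len(g["utr5"]) + len(g["utr3"])
            for g in self.gene_info.values()
        )


def _gene_name(attrs: dict) -> str | None:
    for key in ("Name", "gene", "ID"):
        if key in attrs and attrs[key]:
            v = attrs[key]
            return v[0] if isinstance(v, (list, tuple)) else v
    return None


def read_gff3(path: str) -> FeatureIndex:
    """Parse a GFF3 into an interval index of genes, exons and UTRs.

    Malformed lines are skipped and counted.  A sub-feature is attributed
    to the gene whose span contains it (GBS gene models are small; no
    Parent-chain resolution is attempted beyond containment).
    """
    import gffutils

    idx = FeatureIndex()
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception:
        # empty or header-only file
        return idx
    genes = []
    for f in db.all_features():
        try:
            start0, end0 = f.start - 1, f.end  # to 0-based half-open
            ftype = f.featuretype
        except Exception:
            idx.n_skipped += 1
            continue
        if ftype in _GENE_TYPES:
            gid = f.id
            name = _gene_name(dict(f.attributes))
            idx.gene_info[gid] = {
                "name": name,
                "strand": f.strand,
                "span": (start0, end0),
                "seqid": f.seqid,
                "exons": [],
                "utr5": [],
                "utr3": [],
            }
            genes.append((f.seqid, start0, end0, gid))
    for f in db.all_features():
        ftype = f.featuretype
        if ftype in _GENE_TYPES:
            continue
        key = (
            "exons"
            if ftype in _EXON_TYPES
            else "utr5"
            if ftype in _UTR5
            else "utr3"
            if ftype in _UTR3
            else None
        )
        if key is None:
            continue
        start0, end0 = f.start - 1, f.end
        parents = list(f.attributes.get("Parent", []))
        owners = [p for p in parents if p in idx.gene_info]
        if not owners:
            # no usable Parent chain: fall back to span containment
            owners = [
                gid
                for seqid, gs, ge, gid in genes
                if seqid == f.seqid and gs <= start0 and end0 <= ge
            ]
        for gid in owners:
            idx.gene_info[gid][key].append((start0, end0))
    for seqid, gs, ge, gid in genes:
        idx.genes.setdefault(seqid, IntervalTree())[gs:ge] = gid
    return idx


def intersect_snps(
    snps: pd.DataFrame,
    index: FeatureIndex,
    require_gene_name: bool = False,
) -> pd.DataFrame:
    """Classify SNP positions against the feature index.

    ``snps`` needs columns snp_id, chrom, pos (1-based).  Returns one row
    per (SNP, overlapping gene) with feature_class in five_prime_UTR /
    three_prime_UTR / exon / intron, or a single intergenic row carrying
    no gene.  ``require_gene_name`` drops genic hits whose gene has no
    Name/gene attribute.
    """
    rows = []
    known = set(index.genes)
    unknown_seqs = set()
    for rec in snps.itertuples(index=False):
        chrom, pos1 = str(rec.chrom), int(rec.pos)
        pos0 = pos1 - 1
        if chrom not in known:
            if chrom not in unknown_seqs and index.genes:
                unknown_seqs.add(chrom)
            rows.append(
                dict(snp_id=rec.snp_id, gene_id=None, gene_name=None,
                     feature_class="intergenic", strand=None)
            )
            continue
        hits = index.genes[chrom][pos0]
        if not hits:
            rows.append(
                dict(snp_id=rec.snp_id, gene_id=None, gene_name=None,
                     feature_class="intergenic", strand=None)
            )
            continue
        for iv in sorted(hits, key=lambda iv: iv.data):
            gid = iv.data
            info = index.gene_info[gid]
            if require_gene_name and not info["name"]:
                continue
            in_any = lambda spans: any(s <= pos0 < e for s, e in spans)
            if in_any(info["utr5"]):
                cls = "five_prime_UTR"
            elif in_any(info["utr3"]):
                cls = "three_prime_UTR"
            elif in_any(info["exons"]):
                cls = "exon"
            else:
                cls = "intron"
            rows.append(
                dict(snp_id=rec.snp_id, gene_id=gid, gene_name=info["name"],
                     feature_class=cls, strand=info["strand"])
            )
    if unknown_seqs:
        logger.warning("SNPs on unknown sequences treated as intergenic: %s",
                       sorted(unknown_seqs))
    return pd.DataFrame(
        rows, columns=["snp_id", "gene_id", "gene_name", "feature_class", "strand"]
    )


def to_bed(snps: pd.DataFrame) -> pd.DataFrame:
    """Candidate SNPs as BED (0-based half-open) records."""
    return pd.DataFrame(
        {
            "chrom": snps["chrom"],
            "start": snps["pos"].astype(int) - 1,
            "end": snps["pos"].astype(int),
            "name": snps["snp_id"],
        }
    )
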