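"""Readers and writers for the external formats the pipeline touches.

One internal data model backs every format: :class:`GenotypeMatrix` holds
marker x accession dosage calls in four states (0 = homozygous reference,
1 = heterozygous, 2 = homozygous alternate, :data:`MISSING`),
:class:`MarkerRecord` carries marker metadata (chromosome, 1-based position,
selection category, alleles, optional flank sequence), and trait tables are
validated pandas DataFrames.

VCF is the canonical genotype representation; a simple marker x accession TSV
dialect (cells in {0,1,2,NA}) is provided for fixtures.  Heterozygosity in
this panel means within-accession heterogeneity of a pooled DNA sample, so a
single unphased state 1 represents it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

#: Sentinel for a no-call genotype in :attr:`GenotypeMatrix.calls`.
MISSING: int = -1

#: Selection categories: A = MAS-derived KASP markers, B = prior-GWAS hits,
#: C = GenBank-deposited genes, D = protein-changing mutations,
#: G = gap-filling high-diversity SNPs.
CATEGORIES = ("A", "B", "C", "D", "G")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class MarkerRecord:
    """Metadata for one biallelic SNP marker.

    ``pos`` is 1-based (VCF convention).  ``flank``, when present, has odd
    length with the SNP reference base at its center.
    """

    id: str
    chrom: str
    pos: int
    category: str = "G"
    ref_allele: str = "A"
    alt_allele: str = "G"
    flank: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"marker {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"marker {self.id}: ref and alt alleles are identical")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"marker {self.id}: unknown category {self.category!r}; "
                f"expected one of {CATEGORIES}"
            )
        if self.flank is not None:
            if len(self.flank) % 2 != 1:
                raise ValueError(f"marker {self.id}: flank length must be odd")
            center = self.flank[len(self.flank) // 2].upper()
            if center != self.ref_allele.upper():
                raise ValueError(
                    f"marker {self.id}: flank center base {center!r} does not "
                    f"equal ref allele {self.ref_allele!r}"
                )


@dataclass
class GenotypeMatrix:
    """Marker x accession dosage calls with an explicit missing state."""

    marker_ids: list[str]
    accession_ids: list[str]
    calls: np.ndarray  # int8, shape (n_markers, n_accessions)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D array")
        if self.calls.shape != (len(self.marker_ids), len(self.accession_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.marker_ids)} markers x {len(self.accession_ids)} accessions"
            )
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            bad = np.unique(self.calls[~valid])
            raise ValueError(f"invalid genotype codes {bad.tolist()}")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        if len(set(self.accession_ids)) != len(self.accession_ids):
            raise ValueError("duplicate accession ids")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_accessions(self) -> int:
        return len(self.accession_ids)

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def dosage(self) -> np.ndarray:
        """Calls as float with missing mapped to NaN."""
        x = self.calls.astype(float)
        x[self.calls == MISSING] = np.nan
        return x

    def subset_markers(self, keep: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            [self.marker_ids[i] for i in keep],
            list(self.accession_ids),
            self.calls[keep, :].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.marker_ids), list(self.accession_ids), self.calls.copy()
        )


# ---------------------------------------------------------------------------
# VCF

_GT_TO_CODE = {
    (0, 0): 0,
    (0, 1): 1,
    (1, 0): 1,
    (1, 1): 2,
    (None, None): MISSING,
    (None,): MISSING,
}


def read_genotype_vcf(path: str | Path) -> tuple[GenotypeMatrix, list[MarkerRecord]]:
    """Read a biallelic-SNP VCF into the internal model.

    GT fields map 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2 and ./. -> MISSING.
    Multi-allelic records are skipped with a single summary warning.  The
    marker selection category is recovered from the ``CAT`` INFO field when
    present (written by :func:`write_genotype_vcf`), defaulting to ``G``.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    accessions = list(vf.header.samples)
    marker_ids: list[str] = []
    markers: list[MarkerRecord] = []
    rows: list[list[int]] = []
    n_multiallelic = 0
    seen: set[str] = set()
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1 or len(rec.ref) != 1 or len(rec.alts[0]) != 1:
            n_multiallelic += 1
            continue
        mid = rec.id or f"{rec.chrom}_{rec.pos}"
        if mid in seen:
            raise FormatError(f"duplicate marker id {mid!r} in {path}")
        seen.add(mid)
        try:
            cat = rec.info["CAT"]
        except (KeyError, ValueError):
            cat = "G"
        if isinstance(cat, tuple):
            cat = cat[0]
        row = []
        for sample in rec.samples.values():
            gt = sample.get("GT")
            code = _GT_TO_CODE.get(tuple(gt) if gt is not None else (None, None))
            if code is None:
                code = MISSING if None in gt else min(sum(g > 0 for g in gt), 2)
            row.append(code)
        rows.append(row)
        marker_ids.append(mid)
        markers.append(
            MarkerRecord(
                id=mid,
                chrom=rec.chrom,
                pos=rec.pos,
                category=str(cat),
                ref_allele=rec.ref,
                alt_allele=rec.alts[0],
            )
        )
    vf.close()
    if n_multiallelic:
        warnings.warn(
            f"skipped {n_multiallelic} non-biallelic-SNP record(s) in {path}",
            stacklevel=2,
        )
    calls = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, len(accessions)), dtype=np.int8)
    )
    return GenotypeMatrix(marker_ids, accessions, calls), markers


_CODE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=CAT,Number=1,Type=String,Description="Marker selection category A-G">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_genotype_vcf(
    gm: GenotypeMatrix, markers: Sequence[MarkerRecord], path: str | Path
) -> None:
    """Write a VCF 4.2 file; positions are sorted within chromosome."""
    if gm.n_accessions == 0:
        raise ValueError("refusing to write a VCF with zero accessions")
    by_id = {m.id: m for m in markers}
    missing_meta = [mid for mid in gm.marker_ids if mid not in by_id]
    if missing_meta:
        raise ValueError(f"no MarkerRecord for markers {missing_meta[:5]}")
    order = sorted(
        range(gm.n_markers),
        key=lambda i: (by_id[gm.marker_ids[i]].chrom, by_id[gm.marker_ids[i]].pos),
    )
    if order != list(range(gm.n_markers)):
        warnings.warn("markers were not position-sorted; sorting on write", stacklevel=2)
    contigs = []
    for i in order:
        c = by_id[gm.marker_ids[i]].chrom
        if c not in contigs:
            contigs.append(c)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.accession_ids)
            + "\n"
        )
        for i in order:
            m = by_id[gm.marker_ids[i]]
            gts = "\t".join(_CODE_TO_GT[int(v)] for v in gm.calls[i])
            fh.write(
                f"{m.chrom}\t{m.pos}\t{m.id}\t{m.ref_allele}\t{m.alt_allele}"
                f"\t.\tPASS\tCAT={m.category}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# TSV dialects

def write_genotype_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    """Fixture dialect: markers as rows, accessions as columns, cells 0/1/2/NA."""
    df = pd.DataFrame(
        gm.calls.astype(object), index=gm.marker_ids, columns=gm.accession_ids
    )
    df = df.replace(MISSING, "NA")
    df.to_csv(path, sep="\t", index_label="marker_id")


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    calls = df.replace("NA", str(MISSING)).astype(np.int8).to_numpy()
    return GenotypeMatrix(list(df.index), list(df.columns), calls)


def write_markers_tsv(markers: Sequence[MarkerRecord], path: str | Path) -> None:
    rows = [
        {
            "id": m.id,
            "chrom": m.chrom,
            "pos": m.pos,
            "category": m.category,
            "ref": m.ref_allele,
            "alt": m.alt_allele,
            "flank": m.flank if m.flank is not None else "",
        }
        for m in markers
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_markers_tsv(path: str | Path) -> list[MarkerRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "flank": str}, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        flank = getattr(row, "flank", "") or None
        out.append(
            MarkerRecord(
                id=str(row.id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                category=str(row.category),
                ref_allele=str(row.ref),
                alt_allele=str(row.alt),
                flank=flank if flank else None,
            )
        )
    return out


TRAIT_COLUMNS = ("accession_id", "trait", "year", "value")


def validate_trait_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check the (accession, trait, year, value) long-format trait table."""
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trait table lacks columns {missing}")
    if df.duplicated(subset=["accession_id", "trait", "year"]).any():
        raise FormatError("duplicate (accession, trait, year) rows in trait table")
    if not np.isfinite(df["value"].to_numpy(dtype=float)).all():
        raise FormatError("non-finite trait values")
    return df


def read_traits_tsv(path: str | Path) -> pd.DataFrame:
    return validate_trait_table(pd.read_csv(path, sep="\t"))


def write_traits_tsv(df: pd.DataFrame, path: str | Path) -> None:
    validate_trait_table(df).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA / Newick

def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


_NEWICK_SPECIAL = set(" ()[]':;,")


def _newick_label(name: str | None) -> str:
    if not name:
        return ""
    if set(name) & _NEWICK_SPECIAL:
        return "'" + name.replace("'", "''") + "'"
    return name


def write_tree_newick(tree, path: str | Path | None = None) -> str:
    """Serialize an skbio TreeNode as Newick; labels with spaces are quoted.

    Returns the Newick string; also writes it to ``path`` when given.
    Duplicate leaf labels are rejected.
    """
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        raise ValueError("duplicate leaf labels in tree")

    def fmt(node) -> str:
        length = f":{node.length:.10g}" if node.length is not None else ""
        if node.is_tip():
            return f"{_newick_label(node.name)}{length}"
        inner = ",".join(fmt(c) for c in node.children)
        return f"({inner}){_newick_label(node.name)}{length}"

    text = fmt(tree) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
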