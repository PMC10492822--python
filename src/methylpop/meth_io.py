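"""Readers and writers for the external formats the pipeline consumes.

Per-cytosine methylation calls travel in the 7-column methylKit text dialect
(chrBase, chr, base, strand F/R, coverage, freqC, freqT).  Internally, read
counts — not percentages — are the canonical store: ``count_meth`` and
``count_unmeth`` are reconstructed once at parse time and every downstream
percentage is a derived view, which avoids accumulating rounding drift
through the filtering cascade.

Gene annotation arrives as GFF3 (1-based, inclusive), SNPs as VCF 4.x and
scaffold lengths as a FASTA ``.fai`` or two-column TSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gffutils
import numpy as np
import pandas as pd
from cyvcf2 import VCF

METHYLKIT_COLUMNS = ["chrBase", "chr", "base", "strand", "coverage", "freqC", "freqT"]

#: canonical record columns, sorted by (scaffold, position, strand)
RECORD_COLUMNS = ["scaffold", "position", "strand", "coverage", "count_meth", "count_unmeth"]


class MethParseError(ValueError):
    """Malformed methylation call file; message carries the line number."""


@dataclass
class SampleMethylome:
    """One sample's CpG cytosine calls, sorted by (scaffold, position, strand).

    ``records`` is a DataFrame with :data:`RECORD_COLUMNS`; keys are unique.
    """

    sample_id: str
    population: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        self.records = (
            self.records[RECORD_COLUMNS]
            .sort_values(["scaffold", "position", "strand"], kind="mergesort")
            .reset_index(drop=True)
        )

    @property
    def n_sites(self) -> int:
        return len(self.records)

    def percent_meth(self) -> np.ndarray:
        cov = self.records["coverage"].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.records["count_meth"].to_numpy(float) / cov


@dataclass
class Transcript:
    tx_id: str
    exons: list[tuple[int, int]] = field(default_factory=list)  # genomic order
    cds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def exon_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        """Inter-exon gaps in genomic order (may be empty)."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    def utr(self) -> list[tuple[int, int]]:
        """Exonic sub-intervals not covered by CDS (the exon-UTR class)."""
        if not self.cds:
            return list(self.exons)
        out = []
        cds = sorted(self.cds)
        for s, e in self.exons:
            pos = s
            for cs, ce in cds:
                if ce < pos or cs > e:
                    continue
                if cs > pos:
                    out.append((pos, cs - 1))
                pos = max(pos, ce + 1)
            if pos <= e:
                out.append((pos, e))
        return out


@dataclass
class GeneModel:
    gene_id: str
    scaffold: str
    strand: str  # '+' or '-'
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)
    biotype: str = "protein_coding"

    @property
    def tss(self) -> int:
        """Strand-aware transcription start: gene 5' end in transcription direction."""
        return self.start if self.strand == "+" else self.end


def read_methylkit_file(path: str, sample_id: str | None = None,
                        population: str = "") -> SampleMethylome:
    """Parse one methylKit-format call file into a :class:`SampleMethylome`.

    Counts are reconstructed as ``count_meth = round(coverage * freqC / 100)``.
    A header line is optional.  freqT may be absent (derived as 100 - freqC);
    when present, freqC + freqT must equal 100 within 0.1.
    """
    if sample_id is None:
        sample_id = os.path.splitext(os.path.basename(path))[0]
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and parts[0] == "chrBase":
                continue
            if len(parts) < 6:
                raise MethParseError(f"{path}:{lineno}: expected >= 6 columns, got {len(parts)}")
            try:
                chrom = parts[1]
                pos = int(parts[2])
                strand = parts[3]
                cov = int(parts[4])
                freq_c = float(parts[5])
                freq_t = float(parts[6]) if len(parts) > 6 else 100.0 - freq_c
            except ValueError as exc:
                raise MethParseError(f"{path}:{lineno}: {exc}") from exc
            if strand not in ("F", "R"):
                raise MethParseError(f"{path}:{lineno}: strand must be F or R, got {strand!r}")
            if abs(freq_c + freq_t - 100.0) > 0.1:
                raise MethParseError(
                    f"{path}:{lineno}: freqC + freqT = {freq_c + freq_t:g}, expected 100")
            meth = int(round(cov * freq_c / 100.0))
            rows.append((chrom, pos, strand, cov, meth, cov - meth))
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS) if rows else pd.DataFrame(
        {c: pd.Series(dtype=("int64" if c not in ("scaffold", "strand") else "object"))
         for c in RECORD_COLUMNS})
    return SampleMethylome(sample_id=sample_id, population=population, records=records)


def write_methylkit_file(methylome: SampleMethylome, path: str) -> None:
    """Write a methylKit 7-column file; freqC/freqT rounded to 2 decimals."""
    rec = methylome.records
    with open(path, "w") as fh:
        fh.write("\t".join(METHYLKIT_COLUMNS) + "\n")
        for scaffold, pos, strand, cov, meth in zip(
                rec["scaffold"], rec["position"], rec["strand"],
                rec["coverage"], rec["count_meth"]):
            freq_c = round(100.0 * meth / cov, 2) if cov else 0.0
            freq_t = round(100.0 - freq_c, 2)
            fh.write(f"{scaffold}.{pos}\t{scaffold}\t{pos}\t{strand}\t{cov}"
                     f"\t{freq_c:.2f}\t{freq_t:.2f}\n")


def _feature_children(db: gffutils.FeatureDB, parent, featuretype: str):
    return sorted(db.children(parent, featuretype=featuretype),
                  key=lambda f: (f.start, f.end))


def read_gff3(path: str):
    """Parse GFF3 into gene models plus lncRNA gene models and TE intervals.

    Returns ``(genes, lnc_genes, te_intervals)`` where ``te_intervals`` is a
    list of (scaffold, start, end).  Coordinates stay 1-based inclusive;
    orphan children are skipped by gffutils' parent resolution.
    """
    db = gffutils.create_db(path, dbfn=":memory:", force=True,
                            merge_strategy="create_unique", keep_order=True)
    genes: list[GeneModel] = []
    lnc_genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        model = GeneModel(gene_id=g.id, scaffold=g.seqid, strand=g.strand,
                          start=g.start, end=g.end,
                          biotype=g.attributes.get("gene_biotype", ["protein_coding"])[0])
        is_lnc = False
        for tx_type in ("mRNA", "lnc_RNA", "transcript"):
            for tx in _feature_children(db, g, tx_type):
                exons = [(f.start, f.end) for f in _feature_children(db, tx, "exon")]
                cds = [(f.start, f.end) for f in _feature_children(db, tx, "CDS")]
                if not exons and not cds:
                    continue
                if not exons:
                    exons = list(cds)
                model.transcripts.append(Transcript(tx_id=tx.id, exons=exons, cds=cds))
                if tx_type == "lnc_RNA":
                    is_lnc = True
        if not model.transcripts:
            continue
        if is_lnc or model.biotype == "lncRNA":
            model.biotype = "lncRNA"
            lnc_genes.append(model)
        else:
            genes.append(model)
    te_intervals = [(f.seqid, f.start, f.end)
                    for t in ("transposable_element", "repeat_region", "mobile_genetic_element")
                    for f in db.features_of_type(t)]
    return genes, lnc_genes, te_intervals


def read_vcf_sites(path: str) -> set[tuple[str, int, str, str]]:
    """Biallelic SNP positions from a VCF, 1-based; indels and multiallelic
    rows are excluded (only binary SNPs are retained)."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    sites = set()
    for v in VCF(path):
        if len(v.ALT) != 1:
            continue
        ref, alt = v.REF, v.ALT[0]
        if len(ref) == 1 and len(alt) == 1 and ref != alt:
            sites.add((v.CHROM, v.POS, ref, alt))
    return sites


def read_scaffold_lengths(path: str) -> dict[str, int]:
    """Name -> length map from a FASTA .fai or two-column TSV."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            name, length = parts[0], int(parts[1])
            if name in lengths:
                raise ValueError(f"duplicate scaffold name {name!r} in {path}")
            if length <= 0:
                raise ValueError(f"non-positive length for scaffold {name!r}")
            lengths[name] = length
    return lengths
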