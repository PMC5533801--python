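"""File formats: FASTA/FASTQ via Biopython, minimal SAM, VCF 4.2 and the
TSV tables the pipeline emits."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .capture import AlignmentRecord, ReferenceLocus
from .records import ReadPair, SampleMeta, SeqRead
from .variants import VariantSite


def _open(path: str | Path, mode: str = "rt") -> TextIO:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTA/FASTQ

def read_fasta(path: str | Path) -> dict[str, str]:
    with _open(path) as fh:
        return {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in seqs.items()]
    with _open(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def _to_biopython(read: SeqRead) -> SeqRecord:
    rec = SeqRecord(Seq(read.seq), id=read.id, description="")
    qual = read.qual if read.qual is not None else np.full(len(read.seq), 30)
    rec.letter_annotations["phred_quality"] = [int(q) for q in qual]
    return rec


def _from_biopython(rec: SeqRecord) -> SeqRead:
    qual = rec.letter_annotations.get("phred_quality")
    return SeqRead(rec.id, str(rec.seq).upper(),
                   np.array(qual, dtype=np.uint8) if qual else None)


def write_fastq(path: str | Path, reads: Iterable[SeqRead]) -> None:
    with _open(path, "wt") as fh:
        SeqIO.write((_to_biopython(r) for r in reads), fh, "fastq")


def read_fastq(path: str | Path) -> list[SeqRead]:
    with _open(path) as fh:
        return [_from_biopython(rec) for rec in SeqIO.parse(fh, "fastq")]


def write_paired_fastq(prefix: str | Path, pairs: Iterable[ReadPair],
                       gz: bool = True) -> tuple[Path, Path]:
    suffix = ".fastq.gz" if gz else ".fastq"
    p1 = Path(f"{prefix}_R1{suffix}")
    p2 = Path(f"{prefix}_R2{suffix}")
    pairs = list(pairs)
    write_fastq(p1, (p.read1 for p in pairs))
    write_fastq(p2, (p.read2 for p in pairs))
    return p1, p2


def read_paired_fastq(path1: str | Path, path2: str | Path,
                      index_of: dict[str, tuple[str, str]] | None = None
                      ) -> list[ReadPair]:
    """Zip two FASTQ files into pairs; optional per-read (i5, i7) lookup
    keyed by the mate id stem."""
    r1 = read_fastq(path1)
    r2 = read_fastq(path2)
    if len(r1) != len(r2):
        raise ValueError("R1/R2 read counts differ")
    out = []
    for a, b in zip(r1, r2):
        stem = a.id.rsplit("/", 1)[0]
        i5, i7 = (index_of or {}).get(stem, ("", ""))
        out.append(ReadPair(a, b, i5=i5, i7=i7))
    return out


# -------------------------------------------------------------- sample sheets

SHEET_COLUMNS = ["sample", "i5", "i7", "species", "year", "a260_a280",
                 "conc_ng_ul"]


def read_sample_sheet(path: str | Path
                      ) -> tuple[dict[tuple[str, str], str],
                                 dict[str, SampleMeta]]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"sample", "i5", "i7"} - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    sheet: dict[tuple[str, str], str] = {}
    meta: dict[str, SampleMeta] = {}
    for _, row in df.iterrows():
        sheet[(row["i5"], row["i7"])] = row["sample"]
        meta[row["sample"]] = SampleMeta(
            sample=row["sample"], species=row.get("species", ""),
            year=int(row["year"]) if row.get("year") else None,
            a260_a280=float(row["a260_a280"]) if row.get("a260_a280") else None,
            conc_ng_ul=float(row["conc_ng_ul"]) if row.get("conc_ng_ul") else None)
    return sheet, meta


def write_sample_sheet(path: str | Path,
                       sheet: dict[tuple[str, str], str],
                       meta: dict[str, SampleMeta] | None = None) -> None:
    rows = []
    for (i5, i7), sample in sheet.items():
        m = (meta or {}).get(sample)
        rows.append({"sample": sample, "i5": i5, "i7": i7,
                     "species": m.species if m else "",
                     "year": m.year if m else "",
                     "a260_a280": m.a260_a280 if m else "",
                     "conc_ng_ul": m.conc_ng_ul if m else ""})
    pd.DataFrame(rows, columns=SHEET_COLUMNS).to_csv(path, sep="\t",
                                                     index=False)


# ----------------------------------------------------------------------- SAM

def write_sam(path: str | Path, alignments: list[AlignmentRecord],
              reference: dict[str, str]) -> None:
    """Minimal SAM: QNAME FLAG RNAME POS MAPQ CIGAR RNEXT PNEXT TLEN SEQ
    QUAL with the standard 0x400 duplicate and 0x10 reverse flags."""
    with _open(path, "wt") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in reference.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for rec in alignments:
            flag = 0
            if rec.strand == "-":
                flag |= 0x10
            if rec.is_duplicate:
                flag |= 0x400
            qual = ("".join(chr(int(q) + 33) for q in rec.qual)
                    if rec.qual is not None else "*")
            cigar = f"{len(rec.seq)}M" if rec.seq else "*"
            fh.write("\t".join([
                rec.read_id.replace(" ", "_"), str(flag), rec.locus_id,
                str(rec.start + 1), str(rec.maq), cigar, "*", "0",
                str(rec.insert_len), rec.seq or "*", qual]) + "\n")


# ----------------------------------------------------------------------- VCF

def write_vcf(path: str | Path, sites: list[VariantSite],
              reference: dict[str, str], samples: list[str] | None = None
              ) -> None:
    """VCF 4.2 with INFO keys QD, MQ, FS, ReadPosZ and FILTER names
    matching the hard-filter rules."""
    if samples is None:
        seen: dict[str, None] = {}
        for site in sites:
            for s in site.per_sample:
                seen.setdefault(s)
        samples = list(seen)
    with _open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">\n')
        fh.write('##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">\n')
        fh.write('##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand Fisher exact p">\n')
        fh.write('##INFO=<ID=ReadPosZ,Number=1,Type=Float,Description="Alt vs ref read-position rank-sum z">\n')
        for name in ("QD", "MQ", "QUAL", "FS", "depth", "ReadPos",
                     "biallelic"):
            fh.write(f'##FILTER=<ID={name},Description="hard filter {name}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for name, seq in reference.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for site in sites:
            filt = ("PASS" if site.passed
                    else ";".join(sorted(site.filter_status)))
            info = (f"QD={site.qd:.2f};MQ={site.mq_rms:.2f};"
                    f"FS={site.fs:.2f};ReadPosZ={site.read_pos_z:.2f}")
            cols = [site.ref_id, str(site.pos + 1), ".", site.ref_base,
                    ",".join(site.alt_bases) or ".", f"{site.qual:.1f}",
                    filt, info, "GT:DP:AD:GQ"]
            for s in samples:
                call = site.per_sample.get(s)
                if call is None:
                    cols.append("./.:0:0,0:0")
                else:
                    gt = call.genotype.replace("/", "/")
                    ad = ",".join(str(d) for d in call.allele_depths)
                    cols.append(f"{gt}:{call.depth}:{ad}:{int(call.gq)}")
            fh.write("\t".join(cols) + "\n")


# ------------------------------------------------------------------ catalogue

def write_catalog(prefix: str | Path, loci) -> tuple[Path, Path]:
    """Catalogue as consensus FASTA (IUPAC codes) plus a TSV flag table."""
    fasta = Path(f"{prefix}.fasta")
    table = Path(f"{prefix}.flags.tsv")
    write_fasta(fasta, {l.locus_id: l.consensus for l in loci})
    rows = [{"locus_id": l.locus_id, "n_individuals": l.n_individuals,
             "source_assembly": l.source_assembly,
             "flags": ",".join(sorted(l.flags)) or "."}
            for l in loci]
    pd.DataFrame(rows).to_csv(table, sep="\t", index=False)
    return fasta, table


def write_reference(path: str | Path, loci: list[ReferenceLocus]) -> None:
    write_fasta(path, {l.ref_id: l.sequence for l in loci})


def write_reference_table(path: str | Path,
                          loci: list[ReferenceLocus]) -> None:
    rows = [{"ref_id": l.ref_id, "length": len(l.sequence),
             "n_supporting_reads": l.n_supporting_reads,
             "origin": l.origin, "probe_hit": l.probe_hit or ".",
             "flags": ",".join(sorted(l.flags)) or "."}
            for l in loci]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
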