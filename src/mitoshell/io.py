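"""Readers and writers for the pipeline's text formats.

FASTA/FASTQ parsing is delegated to Biopython; SAM and VCF output are
deliberately minimal (single-contig, ungapped alignments, SNP-only
records) and written directly.
"""
from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .core import N, ReferenceGenome, SequenceRead, decode, encode


def read_fasta(path) -> list:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def read_reference(path) -> ReferenceGenome:
    records = read_fasta(path)
    if not records:
        raise ValueError(f"no FASTA record in {path}")
    rid, seq = records[0]
    return ReferenceGenome(id=rid, sequence=seq, circular=True)


def read_fastq(path) -> list:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(SequenceRead(id=rec.description, bases=str(rec.seq).upper(),
                                quals=quals))
    return out


def write_sam(path, alignments, ref: ReferenceGenome) -> None:
    """Minimal single-contig SAM: FLAG 0/16, MAPQ 255, CIGAR '<len>M'.

    SEQ is reported reference-oriented, as SAM requires; unmapped reads get
    FLAG 4 with '*' placement.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{ref.id}\tLN:{len(ref)}\n")
        for aln in alignments:
            if not aln.mapped:
                fh.write(f"{aln.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t"
                         f"{decode(aln.bases)}\t*\n")
                continue
            flag = 16 if aln.strand == "-" else 0
            seq = decode(aln.ref_oriented_bases())
            fh.write(
                f"{aln.read_id}\t{flag}\t{ref.id}\t{aln.start + 1}\t255\t"
                f"{len(aln)}M\t*\t0\t0\t{seq}\t*\tNM:i:{aln.n_mismatches}\n"
            )


def write_vcf(path, consensus, ref: ReferenceGenome) -> None:
    """Per-sample VCF v4.2 with the sample's non-reference consensus calls."""
    codes = encode(consensus.sequence)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref.id},length={len(ref)}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        sites = np.where((codes != N) & (codes != ref.codes))[0]
        for pos in sites:
            fh.write(
                f"{ref.id}\t{pos + 1}\t.\t{ref.sequence[pos]}\t"
                f"{consensus.sequence[pos]}\t.\tPASS\tDP={int(consensus.depth[pos])}\n"
            )


def write_tsv(path, header, rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_newick(path, tree) -> None:
    with open(path, "w") as fh:
        fh.write(tree.as_string(schema="newick", suppress_rooting=True))


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
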