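"""File I/O: FASTA/GTF/TSV round trips and the packaged sequence fixtures."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diploid import CoordinateMap, Transcript, Variant, VariantTable


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_variants_tsv(variants: VariantTable, path) -> None:
    """Columns: chrom, pos (1-based), ref, alt, strain."""
    with open(path, "w") as f:
        f.write("chrom\tpos\tref\talt\tstrain\n")
        for v in variants:
            f.write(f"{v.chrom}\t{v.pos + 1}\t{v.ref}\t{v.alt}\t{v.strain}\n")


def read_variants_tsv(path, reference: dict[str, str] | None = None) -> VariantTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    variants = [
        Variant(r.chrom, int(r.pos) - 1, r.ref, r.alt, r.strain)
        for r in df.itertuples()
    ]
    return VariantTable(variants, reference)


def write_gtf(transcripts: list[Transcript], path) -> None:
    """Minimal GTF (1-based, closed intervals) with transcript and exon features."""
    with open(path, "w") as f:
        for tx in transcripts:
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'biotype "{tx.biotype}";'
            )
            if tx.locus:
                attrs += f' locus "{tx.locus}";'
            f.write(
                f"{tx.chrom}\ttuglocus\ttranscript\t{tx.start + 1}\t{tx.end}\t.\t"
                f"{tx.strand}\t.\t{attrs}\n"
            )
            for s, e in tx.exons:
                f.write(
                    f"{tx.chrom}\ttuglocus\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                )


def read_gtf(path) -> list[Transcript]:
    by_tx: dict[str, dict] = {}
    with open(path) as f:
        for line in f:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _, feature, start, end, _, strand, _, attr = line.rstrip("\n").split("\t")
            if feature != "exon":
                continue
            fields = {}
            for part in attr.strip().strip(";").split(";"):
                key, _, val = part.strip().partition(" ")
                fields[key] = val.strip('"')
            tid = fields["transcript_id"]
            rec = by_tx.setdefault(
                tid,
                {
                    "gene_id": fields.get("gene_id", tid),
                    "chrom": chrom,
                    "strand": strand,
                    "biotype": fields.get("biotype", "protein_coding"),
                    "locus": fields.get("locus"),
                    "exons": [],
                },
            )
            rec["exons"].append((int(start) - 1, int(end)))
    out = []
    for tid, rec in by_tx.items():
        out.append(
            Transcript(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=tuple(sorted(rec["exons"])),
                biotype=rec["biotype"],
                locus=rec["locus"],
            )
        )
    return out


def write_coordinate_map(cmap: CoordinateMap, path) -> None:
    """Chain-like TSV: chrom, src_start, src_end, offset (0-based half-open)."""
    with open(path, "w") as f:
        f.write("chrom\tsrc_start\tsrc_end\toffset\n")
        for chrom, blocks in cmap.blocks.items():
            for s, e, off in blocks:
                f.write(f"{chrom}\t{s}\t{e}\t{off}\n")


def read_coordinate_map(path) -> CoordinateMap:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    cmap = CoordinateMap()
    for r in df.itertuples():
        cmap.blocks.setdefault(r.chrom, []).append(
            (int(r.src_start), int(r.src_end), int(r.offset))
        )
    return cmap


def _data_path(name: str) -> Path:
    return Path(resources.files("tuglocus") / "data" / name)


def load_tug1_cdna() -> str:
    """The published full-length mouse Tug1 cDNA clone sequence (DNA alphabet)."""
    return next(iter(read_fasta(_data_path("tug1_cdna_mouse.fa")).values()))


def load_riboprobe() -> str:
    """The published 492-nt in situ hybridization riboprobe (RNA alphabet)."""
    return next(iter(read_fasta(_data_path("tug1_riboprobe.fa")).values()))


def load_primers() -> pd.DataFrame:
    """Published genotyping / RT-PCR / cloning / sequencing primers."""
    return pd.read_csv(_data_path("primers.tsv"), sep="\t")
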