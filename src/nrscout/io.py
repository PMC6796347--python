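"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ go through Biopython; GFF3 through gffutils; RepeatMasker
``.out``, BED, BED12, PAF and the simple VCF/TSV reports are plain-text
formats written/parsed here.  Coordinates are 0-based half-open in memory
and converted at the boundary for 1-based formats (GFF3, RepeatMasker out,
VCF).
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import AlignmentBlock
from .classify import Gene, NRSCall
from .errors import InputError
from .extract import NRSRecord, RepeatTrack
from .place import Placement


def _open(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    with _open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path: str | Path, sequences: dict[str, str], descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    records = [
        SeqRecord(Seq(seq), id=name, description=descriptions.get(name, ""))
        for name, seq in sequences.items()
    ]
    with _open(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def write_nrs_fasta(path: str | Path, records: list[NRSRecord]) -> None:
    """NRS FASTA with provenance in the description:
    ``>nrs_id source=assembly:contig:start-end``."""
    seqs = {r.nrs_id: r.sequence for r in records}
    desc = {
        r.nrs_id: f"source={r.source_assembly}:{r.source_contig}:{r.source_start}-{r.source_end}"
        for r in records
    }
    write_fasta(path, seqs, desc)


def read_nrs_fasta(path: str | Path) -> list[NRSRecord]:
    out = []
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            source = dict(
                item.split("=", 1) for item in rec.description.split() if "=" in item
            ).get("source")
            if source is None:
                raise InputError(f"{rec.id}: missing source= provenance in FASTA header")
            asm, contig, span = source.rsplit(":", 2)
            start, end = (int(x) for x in span.split("-"))
            out.append(NRSRecord(rec.id, str(rec.seq).upper(), asm, contig, start, end))
    return out


def write_paired_fastq(
    path1: str | Path, path2: str | Path, pairs: list[tuple[str, str]], prefix: str = "read"
) -> None:
    with _open(path1, "wt") as f1, _open(path2, "wt") as f2:
        for i, (r1, r2) in enumerate(pairs):
            f1.write(f"@{prefix}{i}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"@{prefix}{i}/2\n{r2}\n+\n{'I' * len(r2)}\n")


def read_paired_fastq(path1: str | Path, path2: str | Path) -> list[tuple[str, str, str, str]]:
    with _open(path1) as f1, _open(path2) as f2:
        r1 = list(SeqIO.parse(f1, "fastq"))
        r2 = list(SeqIO.parse(f2, "fastq"))
    if len(r1) != len(r2):
        raise InputError("unpaired FASTQ files: mate counts differ")
    out = []
    for a, b in zip(r1, r2):
        qa = "".join(chr(q + 33) for q in a.letter_annotations["phred_quality"])
        qb = "".join(chr(q + 33) for q in b.letter_annotations["phred_quality"])
        out.append((str(a.seq).upper(), qa, str(b.seq).upper(), qb))
    return out


# ---------------------------------------------------------------------------
# repeat tracks
# ---------------------------------------------------------------------------

def read_repeatmasker_out(path: str | Path) -> RepeatTrack:
    """RepeatMasker ``.out``: whitespace-delimited, 3 header lines, with
    1-based inclusive query coordinates in columns 6-7 and the repeat
    class/family in column 11."""
    intervals = []
    with _open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 11:
            raise InputError(f"{path}: malformed RepeatMasker line {lineno}")
        contig, qbegin, qend, cls = parts[4], parts[5], parts[6], parts[10]
        intervals.append((contig, int(qbegin) - 1, int(qend), cls))
    return RepeatTrack(intervals)


def write_repeatmasker_out(path: str | Path, track: RepeatTrack) -> None:
    header = (
        "   SW   perc perc perc  query      position in query    matching"
        "       repeat              position in repeat\n"
        "score   div. del. ins.  sequence   begin end    (left)  repeat"
        "         class/family       begin  end    (left)  ID\n\n"
    )
    with _open(path, "wt") as fh:
        fh.write(header)
        for i, (contig, s, e, cls) in enumerate(track.intervals):
            fh.write(
                f"  500    1.0  0.0  0.0  {contig} {s + 1} {e} (0) + "
                f"rep{i} {cls} 1 {e - s} (0) {i}\n"
            )


def read_repeat_bed(path: str | Path) -> RepeatTrack:
    """BED with the repeat class in column 4."""
    intervals = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise InputError(f"{path}: BED repeat track needs 4 columns (line {lineno})")
            intervals.append((parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return RepeatTrack(intervals)


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def read_gff3_genes(path: str | Path) -> list[Gene]:
    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:  # gffutils reports the offending line
        raise InputError(f"malformed GFF3 {path}: {exc}") from exc
    genes = []
    for g in db.features_of_type("gene"):
        cds = [(c.start - 1, c.end) for c in db.children(g, featuretype="CDS")]
        genes.append(Gene(g.id, g.seqid, g.start - 1, g.end, sorted(cds)))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def write_gff3_genes(path: str | Path, genes: list[Gene]) -> None:
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tnrscout\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\tID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tnrscout\tmRNA\t{g.start + 1}\t{g.end}\t.\t+\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for j, (s, e) in enumerate(g.cds):
                fh.write(
                    f"{g.chrom}\tnrscout\tCDS\t{s + 1}\t{e}\t.\t+\t0\t"
                    f"ID={g.gene_id}.cds{j};Parent={g.gene_id}.t1\n"
                )


def read_bed12_genes(path: str | Path) -> list[Gene]:
    """BED12: blocks are exons; CDS = exon pieces within thickStart/thickEnd."""
    genes = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            p = line.rstrip("\n").split("\t")
            if len(p) < 12:
                raise InputError(f"{path}: BED12 needs 12 columns (line {lineno})")
            chrom, start, end, name = p[0], int(p[1]), int(p[2]), p[3]
            thick_s, thick_e = int(p[6]), int(p[7])
            sizes = [int(x) for x in p[10].rstrip(",").split(",")]
            offs = [int(x) for x in p[11].rstrip(",").split(",")]
            cds = []
            for size, off in zip(sizes, offs):
                es, ee = start + off, start + off + size
                lo, hi = max(es, thick_s), min(ee, thick_e)
                if hi > lo:
                    cds.append((lo, hi))
            genes.append(Gene(name, chrom, start, end, cds))
    return genes


# ---------------------------------------------------------------------------
# PAF
# ---------------------------------------------------------------------------

def write_paf(path: str | Path, blocks: list[AlignmentBlock], query_lens: dict[str, int], target_lens: dict[str, int]) -> None:
    with _open(path, "wt") as fh:
        for b in blocks:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        b.query_id, query_lens[b.query_id], b.query_start, b.query_end,
                        b.strand, b.target_id, target_lens[b.target_id],
                        b.target_start, b.target_end, b.matches, b.aln_columns, 60,
                        f"NM:i:{b.aln_columns - b.matches}", f"AS:i:{int(b.score)}",
                    )
                )
                + "\n"
            )


def read_paf(path: str | Path) -> list[AlignmentBlock]:
    blocks = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            if len(p) < 12:
                raise InputError(f"{path}: PAF needs >= 12 columns (line {lineno})")
            score = 0.0
            gap_opens = 0
            for t in p[12:]:
                if t.startswith("AS:i:"):
                    score = float(t[5:])
            blocks.append(
                AlignmentBlock(
                    query_id=p[0], query_start=int(p[2]), query_end=int(p[3]),
                    strand=p[4], target_id=p[5], target_start=int(p[7]),
                    target_end=int(p[8]), matches=int(p[9]), aln_columns=int(p[10]),
                    gap_opens=gap_opens, score=score,
                )
            )
    return blocks


# ---------------------------------------------------------------------------
# placements / calls
# ---------------------------------------------------------------------------

def write_placements_bed(path: str | Path, placements: list[Placement]) -> None:
    with _open(path, "wt") as fh:
        for pl in placements:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        pl.chrom or ".",
                        pl.left_breakend if pl.left_breakend is not None else -1,
                        pl.right_breakend if pl.right_breakend is not None else -1,
                        pl.nrs_id, pl.status, int(pl.in_gap),
                    )
                )
                + "\n"
            )


def write_calls_vcf(
    path: str | Path,
    calls: list[NRSCall],
    sequences: dict[str, str],
    reference: dict[str, str],
) -> None:
    """VCF 4.2: insertions as SVTYPE=INS with the sequence in ALT; alternate
    alleles as explicit REF (reference allele) / ALT (NRS) replacements."""
    with _open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=NRSCLASS,Number=1,Type=String,Description="NRS call class">\n')
        for chrom in sorted(reference):
            fh.write(f"##contig=<ID={chrom},length={len(reference[chrom])}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for call in sorted(calls, key=lambda c: (c.chrom, c.left_breakend, c.nrs_id)):
            seq = sequences[call.nrs_id]
            chrom_seq = reference[call.chrom]
            if call.call == "insertion":
                anchor_pos = max(0, call.left_breakend - 1)
                base = chrom_seq[anchor_pos]
                fh.write(
                    f"{call.chrom}\t{anchor_pos + 1}\t{call.nrs_id}\t{base}\t{base + seq}"
                    f"\t.\tPASS\tSVTYPE=INS;NRSCLASS=insertion\n"
                )
            else:
                ref_allele = chrom_seq[call.left_breakend : call.right_breakend] or "N"
                fh.write(
                    f"{call.chrom}\t{call.left_breakend + 1}\t{call.nrs_id}\t{ref_allele}"
                    f"\t{seq}\t.\tPASS\tNRSCLASS={call.call}\n"
                )


def calls_to_frame(calls: list[NRSCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "nrs_id": c.nrs_id, "call": c.call, "chrom": c.chrom,
                "left_breakend": c.left_breakend, "right_breakend": c.right_breakend,
                "ref_allele_span": c.ref_allele_span,
                "ref_allele_identity": c.ref_allele_identity,
                "length_ratio": c.length_ratio,
            }
            for c in calls
        ]
    )


def write_truth_json(path: str | Path, records: list[dict]) -> None:
    with _open(path, "wt") as fh:
        json.dump(records, fh, indent=1, default=str)
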