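"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Biopython; GFF3 and the pileup/read TSV tables are plain
tab-separated text with strict column validation (malformed records are
rejected with their line number). SAM alignments are read through pysam and
reduced to either a read table or per-site base counts. All report tables
use 1-based inclusive coordinates; 0-based half-open conversions happen only
inside this module where a format requires them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .records import GeneAnnotation, GenomeRecord, OrfRecord, SequenceRecord

GFF_COLUMNS = 9


def read_fasta(path: Union[str, Path], circular: bool = False) -> list[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), circular))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(path: Union[str, Path], records: Iterable[SequenceRecord]) -> None:
    bio = [BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def write_orf_fasta(
    path: Union[str, Path], orfs: Iterable[OrfRecord], kind: str = "aa"
) -> None:
    bio = []
    for o in orfs:
        seq = o.aa_sequence if kind == "aa" else o.nt_sequence
        bio.append(
            BioSeqRecord(
                Seq(seq), id=o.orf_id,
                description=f"{o.contig_id}:{o.start}-{o.end}({o.strand})",
            )
        )
    SeqIO.write(bio, str(path), "fasta")


def _attr_str(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def _attr_parse(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"malformed GFF3 attribute {part!r}")
        k, v = part.split("=", 1)
        out[k] = v
    return out


def write_gff3(
    path: Union[str, Path],
    features: Iterable[GeneAnnotation],
    source: str = "orgfusion",
    feature_type: str = "gene",
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in features:
            lo, hi = g.span()
            attrs = {"ID": g.gene_id}
            if g.ortholog_id:
                attrs["ortholog"] = g.ortholog_id
            fh.write(
                "\t".join(
                    [
                        g.contig_id, source, feature_type, str(lo), str(hi),
                        ".", g.strand, ".", _attr_str(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path: Union[str, Path]) -> list[GeneAnnotation]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != GFF_COLUMNS:
                raise ValueError(
                    f"{path}:{lineno}: expected {GFF_COLUMNS} columns, "
                    f"got {len(fields)}"
                )
            contig, _, _, start, end, _, strand, _, attr_text = fields
            try:
                lo, hi = int(start), int(end)
            except ValueError as e:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from e
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: bad strand {strand!r}")
            attrs = _attr_parse(attr_text)
            if "ID" not in attrs:
                raise ValueError(f"{path}:{lineno}: feature lacks ID attribute")
            if strand == "+":
                s, e = lo, hi
            else:
                s, e = hi, lo
            out.append(
                GeneAnnotation(
                    attrs["ID"], contig, s, e, strand,
                    ortholog_id=attrs.get("ortholog"),
                )
            )
    return out


def write_orf_gff3(path: Union[str, Path], orfs: Iterable[OrfRecord]) -> None:
    feats = [
        GeneAnnotation(o.orf_id, o.contig_id, o.start, o.end, o.strand)
        for o in orfs
    ]
    write_gff3(path, feats, feature_type="ORF")


PILEUP_COLUMNS = [
    "contig", "pos", "ref_base", "count_A", "count_C", "count_G", "count_T",
    "sample_id",
]
READ_COLUMNS = ["sample_id", "contig", "start", "end"]


def read_pileup_tsv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in PILEUP_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: pileup table missing column {col!r}")
    return df


def write_pileup_tsv(path: Union[str, Path], pileup: pd.DataFrame) -> None:
    for col in PILEUP_COLUMNS:
        if col not in pileup.columns:
            raise ValueError(f"pileup table missing column {col!r}")
    pileup[PILEUP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_reads_tsv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in READ_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: read table missing column {col!r}")
    return df


def write_reads_tsv(path: Union[str, Path], reads: pd.DataFrame) -> None:
    reads.to_csv(path, sep="\t", index=False)


def write_sam(
    path: Union[str, Path],
    reads: pd.DataFrame,
    contigs: Iterable[SequenceRecord],
) -> None:
    """Write simulated reads (with sequences) as plain-text SAM."""
    import pysam

    contigs = list(contigs)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c.id, "LN": len(c)} for c in contigs],
    }
    tid = {c.id: i for i, c in enumerate(contigs)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, row in reads.iterrows():
            a = pysam.AlignedSegment()
            a.query_name = f"{row['sample_id']}_{i}"
            a.query_sequence = row["sequence"]
            a.reference_id = tid[row["contig"]]
            a.reference_start = int(row["start"]) - 1  # SAM is 0-based here
            a.cigarstring = f"{len(row['sequence'])}M"
            a.mapping_quality = 60
            a.flag = 0
            a.set_tag("RG", str(row["sample_id"]))
            out.write(a)


def sam_to_pileup(
    path: Union[str, Path],
    contigs: Iterable[SequenceRecord],
    sample_from_rg: bool = True,
) -> pd.DataFrame:
    """Per-site base counts per sample from a SAM file (pysam pileup)."""
    import pysam

    contigs = {c.id: c for c in contigs}
    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        per_sample: dict[str, dict[tuple[str, int], dict[str, int]]] = {}
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            sample = (
                aln.get_tag("RG") if sample_from_rg and aln.has_tag("RG")
                else "sample"
            )
            store = per_sample.setdefault(sample, {})
            contig = aln.reference_name
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                base = aln.query_sequence[qpos].upper()
                if base not in "ACGT":
                    continue
                key = (contig, rpos + 1)
                store.setdefault(key, {b: 0 for b in "ACGT"})[base] += 1
    for sample, store in sorted(per_sample.items()):
        for (contig, pos), counts in sorted(store.items()):
            ref = contigs[contig].sequence[pos - 1] if contig in contigs else "N"
            rows.append(
                (contig, pos, ref, counts["A"], counts["C"], counts["G"],
                 counts["T"], sample)
            )
    return pd.DataFrame(rows, columns=PILEUP_COLUMNS)


def write_json(path: Union[str, Path], obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=str)
        fh.write("\n")


def write_genome(
    outdir: Union[str, Path], genome: GenomeRecord
) -> tuple[Path, Optional[Path]]:
    """FASTA (+ GFF3 when annotated) for one genome; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / f"{genome.line_id}.{genome.organelle}.fasta"
    write_fasta(fasta, genome.contigs)
    gff = None
    if genome.genes:
        gff = outdir / f"{genome.line_id}.{genome.organelle}.gff3"
        write_gff3(gff, genome.genes)
    return fasta, gff
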