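"""Readers and writers for the file formats the pipeline touches.

GFF I/O uses a small GFF3-style dialect (9 tab-separated columns,
``key=value;`` attributes) with 1-based inclusive coordinates on disk and
0-based half-open coordinates in memory.  ``read_annotation`` /
``write_annotation`` round-trip bit-exactly for annotations this package
writes; full GFF3 compliance is out of scope.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GeneModel, GenomicInterval

__all__ = [
    "GFFParseError",
    "read_annotation",
    "write_annotation",
    "read_genome",
    "write_genome",
    "read_primers_gff",
    "write_primers_gff",
    "read_racefrags_gff",
    "write_racefrags_gff",
    "read_tsv",
    "write_tsv",
]


class GFFParseError(ValueError):
    """Malformed GFF input; carries the offending line number."""

    def __init__(self, msg: str, lineno: int):
        super().__init__(f"line {lineno}: {msg}")
        self.lineno = lineno


def _parse_attrs(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for chunk in field.rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise ValueError(f"bad attribute {chunk!r}")
        k, v = chunk.split("=", 1)
        attrs[k.strip()] = v.strip()
    return attrs


def _fmt_attrs(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def _iter_gff_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GFFParseError(f"expected 9 tab-separated fields, got {len(fields)}", lineno)
            chrom, source, ftype, start, end, score, strand, frame, attr_s = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise GFFParseError(f"non-integer coordinates {start!r}/{end!r}", lineno) from None
            if strand not in ("+", "-", "."):
                raise GFFParseError(f"bad strand {strand!r}", lineno)
            try:
                attrs = _parse_attrs(attr_s)
            except ValueError as e:
                raise GFFParseError(str(e), lineno) from None
            # GFF is 1-based inclusive; internal is 0-based half-open.
            yield lineno, chrom, source, ftype, start_i - 1, end_i, score, strand, attrs


def read_annotation(path) -> list[GeneModel]:
    """Read gene/transcript/exon/CDS records into :class:`GeneModel` objects.

    Raises :class:`GFFParseError` on malformed lines and ``ValueError`` when
    an exon falls outside its gene's locus.
    """
    genes: dict[str, dict] = {}
    tx_gene: dict[str, str] = {}
    order: list[str] = []
    for lineno, chrom, _src, ftype, start, end, _score, strand, attrs in _iter_gff_lines(path):
        if ftype == "gene":
            gid = attrs.get("ID")
            if gid is None:
                raise GFFParseError("gene record without ID", lineno)
            genes[gid] = {
                "locus": GenomicInterval(chrom, start, end, strand),
                "biotype": attrs.get("biotype", "protein_coding"),
                "tx_order": [],
                "exons": {},
                "cds": {},
            }
            order.append(gid)
        elif ftype == "transcript":
            tid, gid = attrs.get("ID"), attrs.get("Parent")
            if tid is None or gid is None or gid not in genes:
                raise GFFParseError("transcript without ID/known Parent", lineno)
            tx_gene[tid] = gid
            genes[gid]["tx_order"].append(tid)
            genes[gid]["exons"][tid] = []
            genes[gid]["cds"][tid] = []
        elif ftype in ("exon", "CDS"):
            tid = attrs.get("Parent")
            if tid is None or tid not in tx_gene:
                raise GFFParseError(f"{ftype} without known Parent transcript", lineno)
            g = genes[tx_gene[tid]]
            key = "exons" if ftype == "exon" else "cds"
            g[key][tid].append(GenomicInterval(chrom, start, end, strand))
        # unknown feature types are ignored
    out = []
    for gid in order:
        g = genes[gid]
        out.append(
            GeneModel(
                gene_id=gid,
                locus=g["locus"],
                transcripts=[sorted(g["exons"][t], key=lambda e: e.start) for t in g["tx_order"]],
                coding_spans=[sorted(g["cds"][t], key=lambda e: e.start) for t in g["tx_order"]],
                biotype=g["biotype"],
            )
        )
    return out


def write_annotation(genes: Sequence[GeneModel], path) -> None:
    lines = []
    for g in genes:
        lo = g.locus
        lines.append(
            "\t".join(
                [lo.chrom, "racenet", "gene", str(lo.start + 1), str(lo.end), ".", lo.strand, ".",
                 _fmt_attrs({"ID": g.gene_id, "biotype": g.biotype})]
            )
        )
        for i, (exons, cds) in enumerate(zip(g.transcripts, g.coding_spans), start=1):
            tid = f"{g.gene_id}.t{i}"
            tx_start = min(e.start for e in exons)
            tx_end = max(e.end for e in exons)
            lines.append(
                "\t".join(
                    [lo.chrom, "racenet", "transcript", str(tx_start + 1), str(tx_end), ".",
                     lo.strand, ".", _fmt_attrs({"ID": tid, "Parent": g.gene_id})]
                )
            )
            for ex in exons:
                lines.append(
                    "\t".join(
                        [lo.chrom, "racenet", "exon", str(ex.start + 1), str(ex.end), ".",
                         lo.strand, ".", _fmt_attrs({"Parent": tid})]
                    )
                )
            for cd in cds:
                lines.append(
                    "\t".join(
                        [lo.chrom, "racenet", "CDS", str(cd.start + 1), str(cd.end), ".",
                         lo.strand, ".", _fmt_attrs({"Parent": tid})]
                    )
                )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_genome(path) -> dict[str, str]:
    """Read a FASTA genome into a dict of upper-case sequences."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(genome: dict[str, str], path) -> None:
    recs = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()]
    SeqIO.write(recs, str(path), "fasta")


def write_primers_gff(primers, path) -> None:
    lines = []
    for p in primers:
        s = p.span
        attrs = {"ID": p.primer_id, "gene_id": p.gene_id, "race_type": p.race_type}
        lines.append(
            "\t".join([s.chrom, "racenet", "primer", str(s.start + 1), str(s.end), ".",
                       s.strand, ".", _fmt_attrs(attrs)])
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_primers_gff(path):
    from .pooling import RacePrimer

    out = []
    for lineno, chrom, _src, ftype, start, end, _score, strand, attrs in _iter_gff_lines(path):
        if ftype != "primer":
            continue
        try:
            out.append(
                RacePrimer(
                    primer_id=attrs["ID"],
                    gene_id=attrs["gene_id"],
                    span=GenomicInterval(chrom, start, end, strand),
                    race_type=attrs["race_type"],
                )
            )
        except KeyError as e:
            raise GFFParseError(f"primer record missing attribute {e}", lineno) from None
    return out


def write_racefrags_gff(frags, path) -> None:
    lines = []
    for f in frags:
        iv = f.interval
        attrs = {
            "pool_id": f.experiment.pool_id,
            "sample_id": f.experiment.sample_id,
            "n_probes": str(f.n_probes),
            "mean_intensity": f"{f.mean_intensity:.4f}",
        }
        lines.append(
            "\t".join([iv.chrom, "racenet", "RACEfrag", str(iv.start + 1), str(iv.end), ".",
                       ".", ".", _fmt_attrs(attrs)])
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_racefrags_gff(path):
    from .calling import RACEfrag
    from .core import ExperimentKey

    out = []
    for lineno, chrom, _src, ftype, start, end, _score, _strand, attrs in _iter_gff_lines(path):
        if ftype != "RACEfrag":
            continue
        try:
            out.append(
                RACEfrag(
                    interval=GenomicInterval(chrom, start, end),
                    experiment=ExperimentKey(attrs["pool_id"], attrs["sample_id"]),
                    n_probes=int(attrs["n_probes"]),
                    mean_intensity=float(attrs["mean_intensity"]),
                )
            )
        except KeyError as e:
            raise GFFParseError(f"RACEfrag record missing attribute {e}", lineno) from None
    return out


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
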