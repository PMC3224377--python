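"""Readers and writers for the standard formats the pipeline touches.

All coordinate conversions live here: internally everything is 0-based
half-open; BED and bedGraph are native, GFF3 (1-based closed) is
converted on read/write.  FASTA goes through Biopython.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigError
from .mnase import CoverageTrack, ReadAlignment
from .regions import NucleosomeCall, Region
from .synth import GeneModel

logger = logging.getLogger(__name__)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into ``{name: uppercase sequence}``."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def write_bed(records: Iterable, path) -> None:
    """Write reads, regions or nucleosome calls as BED6.

    Calls carry ``name = class`` and ``score = 1000 * height_score``;
    regions carry ``name = kind``.
    """
    with open(path, "w") as fh:
        for r in records:
            if isinstance(r, NucleosomeCall):
                name, score, strand = r.cls or ".", int(round(1000 * r.height_score)), "."
            elif isinstance(r, Region):
                name, score, strand = r.kind or ".", 0, "."
            elif isinstance(r, ReadAlignment):
                name, score, strand = ".", 0, r.strand
            else:  # generic (chrom, start, end, name, score, strand)-like
                fh.write("\t".join(str(x) for x in r) + "\n")
                continue
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t{score}\t{strand}\n")


def read_bed_regions(path, kind: str = "") -> list[Region]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(Region(chrom=f[0], start=int(f[1]), end=int(f[2]),
                              kind=kind or (f[3] if len(f) > 3 else "")))
    return out


def write_bedgraph(track, path, header: dict | None = None) -> None:
    """Write a per-bp track as run-length-merged bedGraph.

    NaN positions are omitted.  ``header`` key/values are recorded as
    '#key=value' comment lines for reproducibility.
    """
    data = track.data if isinstance(track, CoverageTrack) else track
    with open(path, "w") as fh:
        for key, value in (header or {}).items():
            fh.write(f"#{key}={value}\n")
        for chrom in data:
            v = np.asarray(data[chrom], dtype=float)
            finite = np.isfinite(v)
            # run boundaries: value changes or finite-mask changes
            change = np.flatnonzero((v[1:] != v[:-1]) & ~(np.isnan(v[1:]) & np.isnan(v[:-1])))
            bounds = np.concatenate(([0], change + 1, [len(v)]))
            for s, e in zip(bounds[:-1], bounds[1:]):
                if finite[s]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v[s]:g}\n")


def read_bedgraph(path, genome_lengths: dict[str, int] | None = None,
                  fill: float = np.nan) -> dict[str, np.ndarray]:
    """Read a bedGraph into per-chromosome arrays.

    Without ``genome_lengths`` each chromosome is sized to its last
    covered position; unspecified positions take ``fill``.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), float(f[3])))
    if not rows:
        raise ConfigError(f"{path}: empty bedGraph")
    out = {}
    lengths = genome_lengths or {}
    by_chrom: dict[str, list] = {}
    for chrom, s, e, val in rows:
        by_chrom.setdefault(chrom, []).append((s, e, val))
    for chrom, items in by_chrom.items():
        n = lengths.get(chrom, max(e for _, e, _ in items))
        v = np.full(n, fill)
        for s, e, val in items:
            v[s:e] = val
        out[chrom] = v
    return out


# GFF3 (1-based closed) <-> internal 0-based half-open

def read_gff3_genes(path) -> list[GeneModel]:
    """Gene features from a GFF3 file as 0-based half-open GeneModels."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["seqid", "source", "type", "start", "end",
                            "score", "strand", "phase", "attributes"],
                     dtype={"seqid": str})
    genes = df[df["type"] == "gene"]
    out = []
    for i, row in genes.iterrows():
        name = f"gene{i}"
        for fieldspec in str(row["attributes"]).split(";"):
            if fieldspec.startswith(("ID=", "Name=")):
                name = fieldspec.split("=", 1)[1]
                break
        out.append(GeneModel(chrom=row["seqid"], start=int(row["start"]) - 1,
                             end=int(row["end"]), strand=str(row["strand"]),
                             name=name))
    return out


def write_gff3(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(f"{g.chrom}\tnucleoflex\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.name}\n")


def read_tsv_table(path) -> pd.DataFrame:
    """Generic TSV reader (header line required, '#' comments ignored)."""
    return pd.read_csv(path, sep="\t", comment="#")


def write_profile_tsv(mean: np.ndarray, counts: np.ndarray, path,
                      flank: int | None = None) -> None:
    """Metagene profile as TSV with columns offset, mean, n."""
    if flank is None:
        flank = (len(mean) - 1) // 2
    pd.DataFrame({"offset": np.arange(-flank, flank + 1),
                  "mean": mean, "n": counts}).to_csv(path, sep="\t", index=False)
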