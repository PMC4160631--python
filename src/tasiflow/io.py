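"""Readers and writers for the formats the pipeline exchanges.

GFF3 is 1-based closed on disk (converted from the 0-based half-open
intervals used internally); BED stays 0-based half-open. FASTA goes
through Biopython; tables are plain TSV via pandas. Write-then-read is an
identity for every record type handled here.
"""

from __future__ import annotations

from pathlib import Path

import gffutils.feature
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .synth import AnnotatedGenome, Feature
from .smrna import MappedSignature, SmrnaLocus


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        first = fh.read(1)
        if first and first != ">":
            raise ValueError(f"{path}: not FASTA (line 1 does not start with '>')")
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ValueError(f"{path}: empty/truncated record {rec.id!r}")
        out[rec.id] = str(rec.seq)
    if not out:
        raise ValueError(f"{path}: no FASTA records")
    return out


# ---------------------------------------------------------------------------
# GFF3 (1-based closed intervals; feature category in the type column)
# ---------------------------------------------------------------------------

def write_gff3(features: list[Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = [f"ID={f.name}"]
            if f.mature_seq is not None:
                attrs.append(f"mature_seq={f.mature_seq}")
            if f.phase_start is not None:
                attrs.append(f"phase_start={f.phase_start}")
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        "tasiflow",
                        f.ftype,
                        str(f.start + 1),  # 1-based closed
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | Path) -> list[Feature]:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                rec = gffutils.feature.feature_from_line(line)
            except Exception as e:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 line: {e}") from e
            attrs = {k: v[0] for k, v in rec.attributes.items() if v}
            if "ID" not in attrs:
                raise ValueError(f"{path}:{lineno}: feature lacks ID attribute")
            feats.append(
                Feature(
                    name=attrs["ID"],
                    chrom=rec.seqid,
                    start=rec.start - 1,  # back to 0-based half-open
                    end=rec.end,
                    strand=rec.strand,
                    ftype=rec.featuretype,
                    mature_seq=attrs.get("mature_seq"),
                    phase_start=int(attrs["phase_start"]) if "phase_start" in attrs else None,
                )
            )
    return feats


# ---------------------------------------------------------------------------
# BED (0-based half-open)
# ---------------------------------------------------------------------------

def write_bed(loci: list[SmrnaLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, loc in enumerate(loci, start=1):
            fh.write(f"{loc.chrom}\t{loc.start}\t{loc.end}\tlocus_{i:05d}\n")


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name"])
    if (df["end"] < df["start"]).any():
        raise ValueError(f"{path}: BED end < start")
    return df


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_reads_tsv(reads_per_library: dict[str, list[str]], path: str | Path) -> None:
    """Long-format read table: library, sequence, count."""
    rows = []
    for lib, reads in reads_per_library.items():
        counts: dict[str, int] = {}
        for r in reads:
            counts[r] = counts.get(r, 0) + 1
        rows.extend((lib, seq, c) for seq, c in sorted(counts.items()))
    pd.DataFrame(rows, columns=["library", "sequence", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_reads_tsv(path: str | Path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t")
    need = {"library", "sequence", "count"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: read table needs columns {sorted(need)}")
    out: dict[str, list[str]] = {}
    for lib, sub in df.groupby("library", sort=True):
        out[str(lib)] = [
            seq for seq, c in zip(sub["sequence"], sub["count"]) for _ in range(int(c))
        ]
    return out


def write_signatures_tsv(signatures: list[MappedSignature],
                         libraries: list[str], path: str | Path) -> None:
    rows = []
    for s in signatures:
        hits = ";".join(f"{c}:{p}:{st}" for c, p, st in s.hits)
        rows.append([s.sequence, hits] + [s.counts.get(l, 0) for l in libraries])
    pd.DataFrame(rows, columns=["sequence", "hits"] + libraries).to_csv(
        path, sep="\t", index=False
    )


def write_matrix_tsv(matrix: pd.DataFrame, design: pd.DataFrame,
                     prefix: str | Path) -> tuple[Path, Path]:
    """Expression matrix plus its sample-annotation sidecar."""
    prefix = Path(prefix)
    mpath = prefix.with_suffix(".matrix.tsv")
    spath = prefix.with_suffix(".samples.tsv")
    matrix.to_csv(mpath, sep="\t")
    design.to_csv(spath, sep="\t")
    return mpath, spath


def read_matrix_tsv(prefix: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    prefix = Path(prefix)
    matrix = pd.read_csv(prefix.with_suffix(".matrix.tsv"), sep="\t", index_col=0)
    design = pd.read_csv(prefix.with_suffix(".samples.tsv"), sep="\t", index_col=0)
    return matrix, design


def write_go_sets(go_sets: dict[str, tuple[str, ...]], path: str | Path) -> None:
    rows = [(g, term) for term, genes in go_sets.items() for g in genes]
    pd.DataFrame(rows, columns=["gene", "term"]).to_csv(path, sep="\t", index=False)


def read_go_sets(path: str | Path) -> dict[str, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "term"} <= set(df.columns):
        raise ValueError(f"{path}: GO table needs gene and term columns")
    return {
        str(term): tuple(sub["gene"].astype(str))
        for term, sub in df.groupby("term", sort=True)
    }


# ---------------------------------------------------------------------------
# YAML configs
# ---------------------------------------------------------------------------

def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: YAML config must be a mapping")
    return data


def write_yaml(data: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def write_genome(genome: AnnotatedGenome, fasta: str | Path, gff3: str | Path) -> None:
    write_fasta(genome.sequences, fasta)
    write_gff3(genome.features, gff3)


def read_genome(fasta: str | Path, gff3: str | Path) -> AnnotatedGenome:
    return AnnotatedGenome(read_fasta(fasta), read_gff3(gff3))
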