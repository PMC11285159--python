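"""Readers and writers for the table and sequence formats of the pipeline.

Dialects: site tables are tab-separated with 1-based positions and allow
'#'-prefixed comment lines; window output is BED-like with 0-based
half-open coordinates; sequences are FASTA/FASTQ via Biopython. Writers
accept header comment lines so every output can carry its provenance
(producing subcommand and configuration hash).
"""

from __future__ import annotations

import hashlib
import json
import logging

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

POOLED_COLUMNS = ["CHROM", "POS", "REF",
                  "A_M", "C_M", "G_M", "T_M", "A_F", "C_F", "G_F", "T_F"]
_INTERNAL = ["chrom", "pos", "ref",
             "A_m", "C_m", "G_m", "T_m", "A_f", "C_f", "G_f", "T_f"]
CLASSIFICATION_COLUMNS = ["CHROM", "POS", "ALLELE", "FREQ_M", "FREQ_F",
                          "FST", "LABEL"]


class ParseError(ValueError):
    """Malformed input row; message carries the 1-based line number."""


def _open_lines(path):
    with open(path, "r", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_pooled_counts(path) -> pd.DataFrame:
    """Read a pooled-counts TSV (CHROM POS REF A_M..T_M A_F..T_F).

    Returns a DataFrame with internal column names (chrom, pos, ref,
    A_m..T_f). Malformed rows raise :class:`ParseError` naming the line;
    positions out of order within a chromosome only warn.
    """
    rows = []
    header = None
    last_pos = {}
    for lineno, line in _open_lines(path):
        fields = line.split("\t")
        if header is None:
            if [f.upper() for f in fields] != POOLED_COLUMNS:
                raise ParseError(
                    f"line {lineno}: header must be {' '.join(POOLED_COLUMNS)}")
            header = fields
            continue
        if len(fields) != len(POOLED_COLUMNS):
            raise ParseError(f"line {lineno}: expected "
                             f"{len(POOLED_COLUMNS)} columns, got {len(fields)}")
        chrom, pos, ref = fields[0], fields[1], fields[2]
        try:
            pos = int(pos)
            counts = [int(x) for x in fields[3:]]
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-integer field ({exc})") from exc
        if pos < 1:
            raise ParseError(f"line {lineno}: POS must be >= 1")
        if any(c < 0 for c in counts):
            raise ParseError(f"line {lineno}: negative count")
        if chrom in last_pos and pos < last_pos[chrom]:
            logger.warning("%s line %d: positions not sorted on %s",
                           path, lineno, chrom)
        last_pos[chrom] = pos
        rows.append([chrom, pos, ref] + counts)
    if header is None:
        raise ParseError("empty file: header line required")
    return pd.DataFrame(rows, columns=_INTERNAL)


def _write_tsv(df: pd.DataFrame, path, columns, header_comment=None):
    with open(path, "w") as fh:
        for line in header_comment or []:
            fh.write(f"# {line}\n")
        fh.write("\t".join(columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def write_pooled_counts(df: pd.DataFrame, path, header_comment=None):
    _write_tsv(df[_INTERNAL], path, POOLED_COLUMNS, header_comment)


def write_classifications(df: pd.DataFrame, path, header_comment=None):
    cols = ["chrom", "pos", "allele", "freq_male", "freq_female", "fst",
            "label"]
    _write_tsv(df[cols], path, CLASSIFICATION_COLUMNS, header_comment)


def read_classifications(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = ["chrom", "pos", "allele", "freq_male", "freq_female",
                  "fst", "label"]
    return df


def read_chrom_sizes(path) -> pd.DataFrame:
    """Chromosome size TSV: CHROM SIZE [ANCHORED], '#' comments allowed."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] == 2:
        df.columns = ["chrom", "size"]
        df["anchored"] = True
    else:
        df.columns = ["chrom", "size", "anchored"]
        df["anchored"] = df["anchored"].astype(bool)
    if (df["size"] <= 0).any():
        raise ParseError("chromosome sizes must be positive")
    return df


def write_windows_bed(stats_df: pd.DataFrame, path, header_comment=None):
    """BED-like window output: chrom start end n_xy n_zw log2_ratio top1."""
    cols = ["chrom", "start", "end", "n_xy", "n_zw", "log2_ratio"]
    out = stats_df.copy()
    if "top1" in out.columns:
        out["top1"] = out["top1"].astype(int)
        cols = cols + ["top1"]
    with open(path, "w") as fh:
        for line in header_comment or []:
            fh.write(f"# {line}\n")
        out[cols].to_csv(fh, sep="\t", header=False, index=False)


def read_fasta(path) -> dict:
    """FASTA as a dict name -> sequence string."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences, path):
    """Write (name, sequence) pairs or a dict to FASTA."""
    items = sequences.items() if hasattr(sequences, "items") else sequences
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def read_sequences(path) -> list:
    """FASTA or FASTQ (by extension) as (name, sequence) pairs."""
    fmt = "fastq" if str(path).endswith((".fastq", ".fq")) else "fasta"
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(params: dict) -> str:
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()[:12]


def write_manifest(path, subcommand: str, params: dict, inputs=()):
    """JSON run manifest: parameters, package version, input checksums."""
    from . import __version__
    manifest = {
        "subcommand": subcommand,
        "version": __version__,
        "parameters": params,
        "config_hash": config_hash(params),
        "inputs": {str(p): file_sha256(p) for p in inputs},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return manifest
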