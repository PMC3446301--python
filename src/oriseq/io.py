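"""Readers and writers for the standard on-disk formats.

Coordinates are 0-based half-open everywhere, matching BED/bedGraph on disk.
Reads are carried in memory as pandas DataFrames with BED6 columns
(``chrom, start, end, name, score, strand``).  Every writer prepends a small
provenance comment block (tool version, seed, config hash) that the readers
skip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .track import BinnedTrack, n_bins

__version__ = "0.1.0"

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class FormatError(ValueError):
    """Malformed input file; carries the offending line number."""


def provenance_header(seed=None, config=None) -> str:
    lines = [f"# oriseq v{__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        lines.append(f"# config-sha256: {digest}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}. Ns are preserved."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, genome: dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED6


def read_bed(path) -> pd.DataFrame:
    """Read BED (3-6 columns) into a BED6 DataFrame, validating coordinates."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start or start < 0:
                raise FormatError(
                    f"{path}:{lineno}: end <= start ({start}, {end}); "
                    "BED is 0-based half-open — 1-based input?"
                )
            name = parts[3] if len(parts) > 3 else "."
            score = parts[4] if len(parts) > 4 else "0"
            strand = parts[5] if len(parts) > 5 else "."
            rows.append((parts[0], start, end, name, score, strand))
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def write_bed(path, df: pd.DataFrame, seed=None, config=None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, config=config))
        df.to_csv(fh, sep="\t", header=False, index=False, columns=BED6_COLUMNS)


# ---------------------------------------------------------------------------
# bedGraph tracks


def write_bedgraph(path, track: BinnedTrack, seed=None, config=None) -> None:
    """Write one value per bin start (step-sized intervals); masked bins skipped."""
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, config=config))
        fh.write(f"# window: {track.window}\n# step: {track.step}\n")
        for chrom in track.chroms:
            fh.write(f"# length {chrom}: {track.chrom_lengths[chrom]}\n")
        for chrom in track.chroms:
            v, m = track.values[chrom], track.mask[chrom]
            for i in np.flatnonzero(~m):
                s = i * track.step
                fh.write(f"{chrom}\t{s}\t{s + track.step}\t{v[i]:.9g}\n")


def read_bedgraph(path) -> BinnedTrack:
    """Read a bedGraph written by :func:`write_bedgraph` back into a track.

    Bins absent from the file are restored as masked bins.
    """
    window = step = None
    lengths: dict[str, int] = {}
    data: list[tuple[str, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("window:"):
                    window = int(body.split(":")[1])
                elif body.startswith("step:"):
                    step = int(body.split(":")[1])
                elif body.startswith("length "):
                    key, val = body[len("length "):].split(":")
                    lengths[key.strip()] = int(val)
                continue
            if line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph fields")
            data.append((parts[0], int(parts[1]), float(parts[3])))
    if window is None or step is None or not lengths:
        raise FormatError(f"{path}: missing oriseq geometry header")
    track = BinnedTrack(chrom_lengths=lengths, window=window, step=step)
    for chrom in track.chroms:
        track.mask[chrom][:] = True
    for chrom, start, value in data:
        if chrom not in track.values:
            raise FormatError(f"{path}: chromosome {chrom!r} not in header")
        i = start // step
        track.values[chrom][i] = value
        track.mask[chrom][i] = False
    return track


# ---------------------------------------------------------------------------
# MEME minimal motif format


def read_meme(path) -> list:
    """Parse a MEME minimal-format motif file into Bio.motifs objects."""
    with open(path) as fh:
        return list(motifs.parse(fh, "minimal"))


def write_meme(path, pwms, background=None) -> None:
    """Write PWMs (:class:`oriseq.features.PWM`) in MEME minimal text format."""
    bg = background or {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {bg[b]:.5f}" for b in "ACGT") + "\n\n")
        for pwm in pwms:
            mat = np.asarray(pwm.matrix)
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {mat.shape[0]} "
                f"nsites= 20 E= 0\n"
            )
            for row in mat:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# misc tables


def intervals_from_bed(df: pd.DataFrame):
    """Yield (chrom, start, end) tuples from a BED6 DataFrame."""
    for row in df.itertuples(index=False):
        yield row.chrom, int(row.start), int(row.end)


def reads_from_sam(path) -> pd.DataFrame:
    """Load mapped single-end reads from a SAM file into BED6 form."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            rows.append(
                (
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,
                    aln.query_name or ".",
                    str(aln.mapping_quality),
                    "-" if aln.is_reverse else "+",
                )
            )
    return pd.DataFrame(rows, columns=BED6_COLUMNS)


def read_reads(path) -> pd.DataFrame:
    """Dispatch on extension: .sam via pysam, anything else as BED."""
    if str(path).endswith(".sam"):
        return reads_from_sam(path)
    return read_bed(path)
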