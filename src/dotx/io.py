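"""Readers and writers for the pipeline's plain-text interchange formats.

Everything round-trips through tab-delimited text (or FASTA via Biopython):
samtools-depth-style per-base depth, binned window tables, kallisto-style
abundance files, sample sheets, ortholog tables, and truth tables from the
simulator.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ABUNDANCE_COLUMNS = ["target_id", "length", "eff_length", "est_counts", "tpm"]


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_tsv(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def read_depth_text(path: str | Path) -> pd.DataFrame:
    """samtools-depth-style text: scaffold, 1-based position, depth."""
    return pd.read_csv(
        path, sep="\t", names=["scaffold", "pos", "depth"], header=None, comment="#"
    )


def write_depth_text(windows: pd.DataFrame, path: str | Path, depth_column: str) -> None:
    """Expand a window table to per-base 3-column depth text (one sex).

    Every base of a window receives the window's mean depth rounded to an
    integer read count.  Intended for small fixtures; window tables are the
    compact interchange format.
    """
    with open(path, "w") as fh:
        for row in windows.itertuples():
            depth = int(round(getattr(row, depth_column)))
            for pos in range(row.start + 1, row.end + 1):
                fh.write(f"{row.scaffold}\t{pos}\t{depth}\n")


def write_abundance_dir(
    tpm: pd.DataFrame,
    out_dir: str | Path,
    lengths: Optional[pd.Series] = None,
) -> None:
    """kallisto-style layout: ``out_dir/<sample>/abundance.tsv`` per sample."""
    out_dir = Path(out_dir)
    if lengths is None:
        lengths = pd.Series(1000, index=tpm.index)
    for sample in tpm.columns:
        sample_dir = out_dir / str(sample)
        sample_dir.mkdir(parents=True, exist_ok=True)
        frame = pd.DataFrame(
            {
                "target_id": tpm.index,
                "length": lengths.reindex(tpm.index).to_numpy(),
                "eff_length": lengths.reindex(tpm.index).to_numpy(),
                "est_counts": tpm[sample].to_numpy(),
                "tpm": tpm[sample].to_numpy(),
            }
        )
        frame.to_csv(sample_dir / "abundance.tsv", sep="\t", index=False)


def read_abundance_dir(in_dir: str | Path) -> pd.DataFrame:
    """Assemble the genes x samples TPM matrix from a kallisto-style directory."""
    in_dir = Path(in_dir)
    columns = {}
    for sample_dir in sorted(p for p in in_dir.iterdir() if p.is_dir()):
        table = pd.read_csv(sample_dir / "abundance.tsv", sep="\t")
        columns[sample_dir.name] = table.set_index("target_id")["tpm"]
    if not columns:
        raise ValueError(f"no sample subdirectories with abundance.tsv under {in_dir}")
    matrix = pd.DataFrame(columns)
    matrix.index.name = "gene"
    return matrix


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    required = {"sample", "sex", "tissue", "replicate"}
    missing = required - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet.set_index("sample")


def write_manifest(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
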