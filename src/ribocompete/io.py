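"""File I/O: TSV tables, FASTA charge profiles, JSON configs and sidecars.

All writers/readers round-trip exactly (numbers at full precision, header
row with gene_id first).  Malformed files raise :class:`FileFormatError`
naming the offending row and column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import TranscriptParams
from .pool import PolysomeProfile, PoolState
from .synthetic import OmicsExperiment, Transcriptome

__all__ = [
    "FileFormatError",
    "charge_profile_from_sequence",
    "read_fasta_charge_profiles",
    "write_fasta",
    "read_transcriptome_tsv",
    "write_transcriptome_tsv",
    "read_counts_tsv",
    "write_counts_tsv",
    "write_experiment",
    "read_experiment",
    "pool_state_to_json",
    "polysome_profile_frame",
    "write_json",
    "read_json",
]

_POSITIVE_AA = frozenset("KR")


class FileFormatError(ValueError):
    """A file violated the expected format; message names row/column."""


def charge_profile_from_sequence(seq: str) -> np.ndarray:
    """Per-residue positive-charge indicator (K/R -> 1), case-insensitive."""
    return np.fromiter(
        (1 if aa in _POSITIVE_AA else 0 for aa in seq.upper()), dtype=np.int8, count=len(seq)
    )


def read_fasta_charge_profiles(path: str | Path) -> dict[str, np.ndarray]:
    """Charge profiles keyed by record id from an amino-acid FASTA."""
    return {
        rec.id: charge_profile_from_sequence(str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=g, description="") for g, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


_TRANSCRIPTOME_COLS = ["gene_id", "ki", "ke", "m", "L", "n_codons", "class"]


def _read_tsv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}, float_precision="round_trip")
    except Exception as e:  # pandas raises many types; unify
        raise FileFormatError(f"{path}: cannot parse as TSV: {e}") from e
    na = df.isna()
    if na.to_numpy().any():
        r, c = np.argwhere(na.to_numpy())[0]
        raise FileFormatError(
            f"{path}: missing value at data row {r + 1}, column '{df.columns[c]}'"
        )
    return df


def read_transcriptome_tsv(
    path: str | Path, charge_profiles: dict[str, np.ndarray] | None = None
) -> Transcriptome:
    df = _read_tsv(path)
    missing = [c for c in _TRANSCRIPTOME_COLS if c not in df.columns]
    if missing:
        raise FileFormatError(f"{path}: missing columns {missing}")
    transcripts = []
    for _, row in df.iterrows():
        cp = charge_profiles.get(row["gene_id"]) if charge_profiles else None
        transcripts.append(
            TranscriptParams(
                gene_id=row["gene_id"], ki=float(row["ki"]), ke=float(row["ke"]),
                m=float(row["m"]), L=int(row["L"]), n_codons=int(row["n_codons"]),
                charge_profile=cp,
            )
        )
    return Transcriptome(transcripts=transcripts, class_label=list(df["class"]))


def write_transcriptome_tsv(transcriptome: Transcriptome, path: str | Path) -> None:
    # %.17g guarantees float64 round-trip through text
    transcriptome.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    if df.columns[0] != "gene_id":
        raise FileFormatError(f"{path}: first column must be gene_id, got '{df.columns[0]}'")
    df = df.set_index("gene_id")
    if not df.map(lambda v: float(v).is_integer()).to_numpy().all():
        raise FileFormatError(f"{path}: counts must be integers")
    return df.astype(np.int64)


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=True, index_label="gene_id")


def write_experiment(exp: OmicsExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write the TSV quartet (counts x2, samples, truth); returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mrna_counts": outdir / "mrna_counts.tsv",
        "fp_counts": outdir / "fp_counts.tsv",
        "samples": outdir / "samples.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_counts_tsv(exp.mrna_counts, paths["mrna_counts"])
    write_counts_tsv(exp.fp_counts, paths["fp_counts"])
    exp.sample_meta.to_csv(paths["samples"], sep="\t", index=False)
    exp.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.17g")
    return paths


def read_experiment(outdir: str | Path) -> OmicsExperiment:
    outdir = Path(outdir)
    return OmicsExperiment(
        mrna_counts=read_counts_tsv(outdir / "mrna_counts.tsv"),
        fp_counts=read_counts_tsv(outdir / "fp_counts.tsv"),
        sample_meta=_read_tsv(outdir / "samples.tsv"),
        truth=_read_tsv(outdir / "truth.tsv"),
    )


def pool_state_to_json(pool: PoolState) -> dict:
    return {"R_total": pool.R_total, "R_free": pool.R_free, "E": pool.E}


def polysome_profile_frame(
    profiles: dict[str, PolysomeProfile]
) -> pd.DataFrame:
    """Tidy table of one or more labelled polysome profiles."""
    rows = []
    for label, p in profiles.items():
        rows.append(
            {
                "condition": label,
                "free_frac": p.free_frac,
                "mono_frac": p.mono_frac,
                "light_frac": p.light_frac,
                "heavy_frac": p.heavy_frac,
                "mono_to_poly": p.mono_to_poly,
                "mono_to_poly_capped": p.mono_to_poly_capped,
            }
        )
    return pd.DataFrame(rows)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise FileFormatError(f"{path}: invalid JSON at line {e.lineno}: {e.msg}") from e
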