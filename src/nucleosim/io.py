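"""Readers/writers for the package's tabular formats and FASTA.

All tabular formats are TSV with a header row:

* ensembles   -- columns ``replica``, ``time_s``, ``dyads`` (comma-joined)
* profiles    -- ``offset_bp``, ``density``
* u_eff       -- ``gap_bp``, ``energy_kBT``
* affinity    -- ``sequence_id``, ``position``, ``energy_kBT``
* fragments   -- ``gene_id``, ``molecule_id``, ``start``, ``end``

Every simulation run can emit a JSON manifest carrying the parameters,
seeds and package version needed to reproduce it bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .kinetics import EnsembleRecord
from .lattice import LatticeSpec

__all__ = [
    "read_fasta",
    "write_ensemble",
    "read_ensemble",
    "write_profile",
    "read_profile",
    "write_u_eff",
    "read_u_eff",
    "write_fragments",
    "read_fragments",
    "write_manifest",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(id, uppercase sequence) pairs from a FASTA file (multi-record)."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_ensemble(record: EnsembleRecord, path: str | Path) -> None:
    rows = {
        "replica": record.replica_ids,
        "time_s": record.times,
        "dyads": [",".join(map(str, d)) for d in record.dyads],
    }
    header = (
        f"#lattice_length={record.lattice.length_bp}"
        f";tss_index={record.lattice.tss_index}"
        f";footprint={record.lattice.footprint_bp}"
        f";model={record.model_fingerprint};protocol={record.protocol_fingerprint}\n"
    )
    path = Path(path)
    with path.open("w") as fh:
        fh.write(header)
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_ensemble(path: str | Path) -> EnsembleRecord:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}:1: missing ensemble header line")
        meta = dict(kv.split("=", 1) for kv in header[1:].strip().split(";"))
        df = pd.read_csv(fh, sep="\t", dtype={"dyads": str}, keep_default_na=False)
    lattice = LatticeSpec(
        length_bp=int(meta["lattice_length"]),
        tss_index=int(meta["tss_index"]),
        footprint_bp=int(meta["footprint"]),
    )
    dyads = [
        np.array([int(x) for x in s.split(",")] if s else [], dtype=np.int64)
        for s in df["dyads"]
    ]
    return EnsembleRecord(
        replica_ids=df["replica"].to_numpy(np.int64),
        times=df["time_s"].to_numpy(np.float64),
        dyads=dyads,
        lattice=lattice,
        model_fingerprint=meta.get("model", ""),
        protocol_fingerprint=meta.get("protocol", ""),
    )


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed TSV: {exc}") from exc
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df[required].isna().any().any():
        bad = int(df[required].isna().any(axis=1).idxmax()) + 2  # + header line
        raise ValueError(f"{path}: line {bad}: incomplete record")
    return df


def write_profile(profile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)


def read_profile(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ["offset_bp", "density"])


def write_u_eff(table: np.ndarray, hard_core_bp: int, path: str | Path) -> None:
    gaps = hard_core_bp + np.arange(table.size)
    pd.DataFrame({"gap_bp": gaps, "energy_kBT": table}).to_csv(
        path, sep="\t", index=False
    )


def read_u_eff(path: str | Path) -> tuple[np.ndarray, int]:
    df = _read_tsv(path, ["gap_bp", "energy_kBT"])
    return df["energy_kBT"].to_numpy(np.float64), int(df["gap_bp"].iloc[0])


def write_fragments(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_fragments(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ["gene_id", "molecule_id", "start", "end"])


def write_manifest(path: str | Path, **entries) -> None:
    """JSON run manifest (parameters, seeds, versions)."""
    from . import __version__

    payload = {"nucleosim_version": __version__, **entries}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
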