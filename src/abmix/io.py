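"""Readers, writers and the versioned model container.

Sequences come in as multi-record FASTA (wrapped lines) or headerless
single-column CSV.  Numbered repertoires and score/humanization reports go
out as CSV with ``#``-prefixed metadata lines (tool version, command,
seed).  Models are stored in a single versioned HDF5 container holding the
alphabet, positions, mixture weights, emission tensor, chain type and fit
metadata; the round trip is bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from Bio import SeqIO

from . import __version__
from .mixture import CategoricalMixture
from .numbering import EncodedRepertoire, NumberedSequence
from .positions import AA_TO_CODE, ALPHABET, GAP

MODEL_FORMAT_VERSION = 1

_VALID_CHARS = set("ACDEFGHIKLMNPQRSTVWYX")


def _validate_record(seq: str, index: int, name: str, allow_gaps: bool) -> str:
    seq = seq.strip().upper()
    if not seq:
        raise ValueError(f"record {index} ({name}): empty sequence")
    valid = _VALID_CHARS | {GAP} if allow_gaps else _VALID_CHARS
    for pos, c in enumerate(seq):
        if c not in valid:
            raise ValueError(
                f"record {index} ({name}): illegal symbol {c!r} at index {pos}"
            )
    return seq


def read_sequences(
    path: str | Path, format: str | None = None, allow_gaps: bool = False
) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from FASTA or single-column CSV.

    The format is inferred from the extension unless given explicitly.
    Sequences are stripped, uppercased and validated against the amino-acid
    alphabet (X allowed; the gap symbol only with ``allow_gaps``);
    malformed records raise with their index.
    """
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() in (".csv", ".txt") else "fasta"
    if format not in ("fasta", "csv"):
        raise ValueError(f"unknown sequence format {format!r}")
    out: list[tuple[str, str]] = []
    if format == "fasta":
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
            out.append((rec.id, _validate_record(str(rec.seq), i, rec.id,
                                                 allow_gaps)))
    else:
        for i, line in enumerate(path.read_text().splitlines()):
            line = line.strip()
            if not line:
                continue
            name = f"seq_{len(out)}"
            out.append((name, _validate_record(line, i, name, allow_gaps)))
    if not out:
        raise ValueError(f"no sequence records found in {path}")
    return out


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _metadata_header(command: str, seed: int | None) -> str:
    parts = [f"# abmix {__version__}", f"# command: {command}"]
    if seed is not None:
        parts.append(f"# seed: {seed}")
    return "\n".join(parts) + "\n"


def write_csv_report(
    df: pd.DataFrame, path: str | Path, command: str, seed: int | None = None
) -> None:
    """Write a report CSV with the tool/command/seed metadata header."""
    with open(path, "w") as fh:
        fh.write(_metadata_header(command, seed))
        df.to_csv(fh, index=False, float_format="%.6f")


def read_csv_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", dtype={"sequence_id": str})


def write_numbering_csv(
    numbered: list[NumberedSequence],
    ids: list[str],
    positions: list[str],
    path: str | Path,
    command: str = "number",
    seed: int | None = None,
) -> None:
    """One row per sequence: id, chain type, percent identity, then one
    column per canonical position (gap ``-``)."""
    rows = []
    for name, ns in zip(ids, numbered):
        row = {"sequence_id": name, "chain_type": ns.chain_type,
               "percent_identity": round(ns.percent_identity, 6)}
        row.update(dict(zip(positions, ns.gapped(positions))))
        rows.append(row)
    df = pd.DataFrame(rows, columns=["sequence_id", "chain_type",
                                     "percent_identity", *positions])
    with open(path, "w") as fh:
        fh.write(_metadata_header(command, seed))
        df.to_csv(fh, index=False)


def read_numbering_csv(path: str | Path) -> tuple[list[str], EncodedRepertoire]:
    """Load a numbering CSV back into ids + an encoded repertoire."""
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    fixed = ["sequence_id", "chain_type", "percent_identity"]
    positions = [c for c in df.columns if c not in fixed]
    chains = set(df["chain_type"])
    if len(chains) > 1:
        raise ValueError(f"mixed chain types in {path}: {sorted(chains)}")
    codes = np.empty((len(df), len(positions)), dtype=np.int64)
    for j, p in enumerate(positions):
        codes[:, j] = [AA_TO_CODE[c] for c in df[p]]
    rep = EncodedRepertoire(positions=positions, codes=codes,
                            chain_type=chains.pop())
    return df["sequence_id"].tolist(), rep


def save_model(model: CategoricalMixture, path: str | Path) -> None:
    """Write the versioned single-file model container (HDF5)."""
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = "abmix-categorical-mixture"
        fh.attrs["format_version"] = MODEL_FORMAT_VERSION
        fh.attrs["package_version"] = __version__
        fh.attrs["chain_type"] = model.chain_type
        fh.attrs["meta"] = json.dumps(model.meta)
        fh.create_dataset("mixture_weights", data=model.mixture_weights)
        fh.create_dataset("emission_probs", data=model.emission_probs)
        fh.create_dataset(
            "positions", data=np.array(model.positions, dtype="S8")
        )
        fh.create_dataset("alphabet", data=np.array(model.alphabet, dtype="S1"))


def load_model(path: str | Path) -> CategoricalMixture:
    """Load and validate a model container; raises on version mismatch,
    corruption or invariant violations (no partial model is returned)."""
    try:
        with h5py.File(path, "r") as fh:
            if fh.attrs.get("format") != "abmix-categorical-mixture":
                raise ValueError(f"{path} is not an abmix model container")
            version = int(fh.attrs["format_version"])
            if version != MODEL_FORMAT_VERSION:
                raise ValueError(
                    f"model format version {version} unsupported "
                    f"(expected {MODEL_FORMAT_VERSION})"
                )
            return CategoricalMixture(
                positions=[p.decode() for p in fh["positions"][()]],
                mixture_weights=fh["mixture_weights"][()],
                emission_probs=fh["emission_probs"][()],
                chain_type=str(fh.attrs["chain_type"]),
                alphabet=tuple(a.decode() for a in fh["alphabet"][()]),
                meta=json.loads(str(fh.attrs["meta"])),
            )
    except OSError as exc:
        raise ValueError(f"cannot read model container {path}: {exc}") from exc


__all__ = [
    "read_sequences",
    "write_fasta",
    "write_csv_report",
    "read_csv_report",
    "write_numbering_csv",
    "read_numbering_csv",
    "save_model",
    "load_model",
    "MODEL_FORMAT_VERSION",
]
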