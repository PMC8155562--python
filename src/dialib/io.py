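"""Readers and writers for the tool's file formats.

MGF goes through pyteomics; FASTA is plain-header, wrapped or unwrapped;
everything else is tab-separated UTF-8 with a header row and '.' decimals.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from pyteomics import mgf as _ptmgf


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (header, sequence) records; sequence lines may be wrapped."""
    records: list[tuple[str, str]] = []
    header = None
    chunks: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(chunks)))
                header = line[1:].strip()
                chunks = []
            else:
                if header is None:
                    raise FormatError("FASTA sequence before first header")
                chunks.append(line.strip())
        if header is not None:
            records.append((header, "".join(chunks)))
    return records


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | Path, width: int = 60
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# MGF spectra


def read_mgf(path: str | Path):
    """Read an MGF file into Spectrum objects (see dialib.library)."""
    from dialib.library import Spectrum

    spectra = []
    with _ptmgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge = params.get("charge")
            charge = int(charge[0]) if charge else 0
            spectra.append(
                Spectrum(
                    id=str(params.get("title", "")),
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=charge,
                    rt=float(params.get("rtinseconds", 0.0)),
                    mz=np.asarray(entry["m/z array"], dtype=float),
                    intensity=np.asarray(entry["intensity array"], dtype=float),
                )
            )
    return spectra


def write_mgf(spectra, path: str | Path) -> None:
    entries = []
    for s in spectra:
        entries.append(
            {
                "m/z array": s.mz,
                "intensity array": s.intensity,
                "params": {
                    "title": s.id,
                    "pepmass": s.precursor_mz,
                    "charge": f"{s.precursor_charge}+",
                    "rtinseconds": s.rt,
                },
            }
        )
    _ptmgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# Generic transition list (GTL)

GTL_COLUMNS = [
    "transition_group_id",
    "PeptideSequence",
    "FullPeptideName",
    "PrecursorCharge",
    "PrecursorMz",
    "ProductMz",
    "FragmentType",
    "FragmentSeriesNumber",
    "FragmentCharge",
    "LibraryIntensity",
    "NormalizedRetentionTime",
    "ProteinName",
    "decoy",
]


def write_gtl(transitions, path: str | Path) -> None:
    """Write transitions as an OpenSWATH-compatible tsv (fixed column order,
    m/z to 6 decimals)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(GTL_COLUMNS)
        for t in transitions:
            writer.writerow(
                [
                    t.group_id,
                    t.peptide,
                    t.full_peptide_name,
                    t.precursor_charge,
                    f"{t.precursor_mz:.6f}",
                    f"{t.product_mz:.6f}",
                    t.series,
                    t.ordinal,
                    t.fragment_charge,
                    f"{t.library_intensity:.6g}",
                    f"{t.normalized_rt:.4f}",
                    t.protein_name,
                    int(t.decoy),
                ]
            )


def read_gtl(path: str | Path):
    """Read a GTL tsv back into Transition objects.

    Columns are matched by header name, so column order may differ from the
    written order. Malformed rows raise with their line number.
    """
    from dialib.library import Transition

    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        missing = set(GTL_COLUMNS) - set(header)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
        idx = {name: header.index(name) for name in GTL_COLUMNS}
        transitions = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            try:
                transitions.append(
                    Transition(
                        group_id=row[idx["transition_group_id"]],
                        peptide=row[idx["PeptideSequence"]],
                        full_peptide_name=row[idx["FullPeptideName"]],
                        precursor_charge=int(row[idx["PrecursorCharge"]]),
                        precursor_mz=float(row[idx["PrecursorMz"]]),
                        product_mz=float(row[idx["ProductMz"]]),
                        series=row[idx["FragmentType"]],
                        ordinal=int(row[idx["FragmentSeriesNumber"]]),
                        fragment_charge=int(row[idx["FragmentCharge"]]),
                        library_intensity=float(row[idx["LibraryIntensity"]]),
                        normalized_rt=float(row[idx["NormalizedRetentionTime"]]),
                        protein_name=row[idx["ProteinName"]],
                        decoy=bool(int(row[idx["decoy"]])),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed row ({exc})") from None
    return transitions


# ---------------------------------------------------------------------------
# Tabular helpers


def read_table(path: str | Path, required: Iterable[str] = ()) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(required) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_quant_matrix(path: str | Path) -> pd.DataFrame:
    """Quant matrix tsv: first column feature id, header = samples, empty
    cell = missing."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate feature ids")
    return df


def write_quant_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True, na_rep="")
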