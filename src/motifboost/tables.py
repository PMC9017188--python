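"""Tab-separated table formats, FASTA, and run manifests.

The native site-table dialect is a TSV with a versioned ``#`` header line,
one row per phosphosite, and one ``intensity_<channel>`` column per TMT
channel (0 = missing, MaxQuant convention).  A documented subset of
MaxQuant "Phospho (STY)Sites" columns is accepted through a column map,
e.g.::

    {"Protein": "protein_id", "Position": "position",
     "Amino acid": "residue", "Sequence window": "window",
     "Localization prob": "localization_prob",
     "Reporter intensity 0": "intensity_126", ...}
"""

from __future__ import annotations

import json
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .filters import INTENSITY_PREFIX, SchemaError
from .simulate import ProteinEntry

SITE_TABLE_HEADER = "# motifboost site table v1"
TRUTH_TABLE_HEADER = "# motifboost ground truth v1"

REQUIRED_SITE_COLUMNS = ("protein_id", "position", "residue", "localization_prob")


def write_site_table(frame: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(SITE_TABLE_HEADER + "\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_site_table(path, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a site table; ``column_map`` renames foreign-dialect columns.

    Non-numeric intensity cells raise a SchemaError naming the offending
    row (1-based data row) and column; zero intensities are kept as 0,
    which all downstream code treats as missing.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"protein_id": str})
    if column_map:
        frame = frame.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_SITE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required columns {missing}; "
            f"available: {sorted(frame.columns)}"
        )
    intensity_cols = [c for c in frame.columns if c.startswith(INTENSITY_PREFIX)]
    if not intensity_cols:
        raise SchemaError(f"{path}: no intensity_<channel> columns found")
    for col in intensity_cols:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise SchemaError(
                f"{path}: non-numeric value {frame[col][bad.idxmax()]!r} "
                f"in column {col!r}, data row {row}"
            )
        frame[col] = numeric.fillna(0.0)
    frame["protein_id"] = frame["protein_id"].astype(str)
    frame["position"] = frame["position"].astype(int)
    if "window" in frame.columns:
        frame["window"] = frame["window"].fillna("")
    if "is_phosphopeptide" in frame.columns:
        frame["is_phosphopeptide"] = frame["is_phosphopeptide"].astype(bool)
    return frame


def write_truth_table(frame: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(TRUTH_TABLE_HEADER + "\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_truth_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", comment="#", dtype={"protein_id": str})
    frame["direct_substrate_of"] = frame["direct_substrate_of"].fillna("")
    frame["planted_by"] = frame["planted_by"].fillna("")
    return frame


def write_fasta(proteins: list[ProteinEntry], path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[ProteinEntry]:
    return [
        ProteinEntry(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
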