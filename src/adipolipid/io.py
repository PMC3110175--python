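"""Delimited-text readers/writers and input validation.

Abundance tables are CSV/TSV with the species shorthand name in the
first column and one column per subject; the metadata table is keyed by
subject id and carries at least ``pair_id``, ``role`` and ``group``.
Validation returns actionable diagnostics rather than raising, so a
whole file's problems surface at once.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .lipids import AbundanceTable, LipidParseError, parse_lipid_name

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_fatty_acid_profile",
    "validate_inputs",
]

REQUIRED_METADATA_COLUMNS = ("pair_id", "role", "group")


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_abundance_table(data_path, metadata_path) -> AbundanceTable:
    """Load an abundance matrix and its subject metadata."""
    data = pd.read_csv(data_path, sep=_sep(data_path), index_col=0) \
        .rename_axis(None).astype(float)
    metadata = pd.read_csv(metadata_path, sep=_sep(metadata_path),
                           index_col=0).rename_axis(None)
    metadata = metadata.loc[list(data.columns)]
    return AbundanceTable(data=data, metadata=metadata)


def write_abundance_table(table: AbundanceTable, data_path,
                          metadata_path) -> None:
    table.data.to_csv(data_path, sep=_sep(data_path),
                      index_label="species", float_format="%.10g",
                      lineterminator="\n")
    table.metadata.to_csv(metadata_path, sep=_sep(metadata_path),
                          index_label="subject", float_format="%.10g",
                          lineterminator="\n")


def read_fatty_acid_profile(path) -> pd.DataFrame:
    """Subjects x fatty-acid mol% table (first column = subject id)."""
    return pd.read_csv(path, sep=_sep(path), index_col=0)


def validate_inputs(data_path, metadata_path) -> list[str]:
    """Schema and pairing diagnostics for an abundance/metadata file pair.

    Returns a list of human-readable problems (empty = well-formed).
    Checks: parseable species names, numeric non-negative concentrations
    (naming the offending cell), metadata columns, subject agreement, and
    heavy/lean completeness of each discordant pair.
    """
    diags: list[str] = []
    for p in (data_path, metadata_path):
        if not Path(p).exists():
            diags.append(f"missing file: {p}")
    if diags:
        return diags
    data = pd.read_csv(data_path, sep=_sep(data_path), index_col=0)
    metadata = pd.read_csv(metadata_path, sep=_sep(metadata_path), index_col=0)

    for name in data.index:
        try:
            parse_lipid_name(str(name))
        except LipidParseError as exc:
            diags.append(f"unparseable species name: {exc}")
    values = data.apply(pd.to_numeric, errors="coerce")
    nan_cells = np.argwhere(values.isna().to_numpy())
    for si, ci in nan_cells[:10]:
        diags.append(f"non-numeric value at species {data.index[si]!r}, "
                     f"subject {data.columns[ci]!r}")
    neg_cells = np.argwhere((values.to_numpy() < 0))
    for si, ci in neg_cells[:10]:
        diags.append(f"negative concentration at species {data.index[si]!r}, "
                     f"subject {data.columns[ci]!r}")

    missing_cols = [c for c in REQUIRED_METADATA_COLUMNS
                    if c not in metadata.columns]
    if missing_cols:
        diags.append(f"metadata lacks required columns: {missing_cols}")
        return diags
    unknown = set(data.columns) - set(metadata.index)
    if unknown:
        diags.append(f"subjects without metadata: {sorted(unknown)}")
    disc = metadata[metadata["group"] == "discordant"]
    for pair_id, sub in disc.groupby("pair_id"):
        roles = sorted(sub["role"])
        if roles != ["heavy", "lean"]:
            diags.append(f"discordant pair {pair_id!r} has roles {roles}; "
                         "expected exactly one heavy and one lean")
    return diags
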