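"""Lipid species nomenclature, classification, and abundance tables.

Lipid species are named in the usual shorthand dialect, e.g.
``PC(16:1/18:0)`` for a diacyl phosphatidylcholine, ``PE(P-16:0/20:4)``
for an ethanolamine plasmalogen (vinyl-ether linked 16:0 at *sn*-1,
arachidonoyl at *sn*-2), ``PC(O-18:1/16:0)`` for an alkyl-ether lipid,
``SM(d18:1/24:0)`` for a sphingomyelin, or a class-level sum composition
such as ``PC(34:1)``. Both ``:`` and the typographic ``∶`` separator are
accepted; parsing is reversible onto the canonical ``:`` dialect.

Abundance tables hold a species x subject concentration matrix together
with per-subject metadata (twin pair id, heavy/lean role, group, BMI,
fat cell size). Relative compositional analysis normalizes each subject
column by that subject's total phospholipid signal.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LipidSpecies",
    "LipidClassification",
    "AbundanceTable",
    "LipidParseError",
    "parse_lipid_name",
    "format_lipid_name",
    "classify_species",
    "normalize_total_pl",
    "PHOSPHOLIPID_HEADGROUPS",
]

#: Headgroup classes counted as phospholipids for total-PL normalization
#: (the classes detected in positive-ion-mode lipidomics).
PHOSPHOLIPID_HEADGROUPS = ("PC", "PE", "SM")

_KNOWN_HEADGROUPS = ("PC", "PE", "SM", "TG")

_CHAIN_RE = re.compile(r"^(?P<prefix>P-|O-|d|t)?(?P<c>\d+):(?P<db>\d+)$")
_NAME_RE = re.compile(r"^(?P<head>[A-Za-z][A-Za-z0-9]*)\((?P<chains>[^()]+)\)$")


class LipidParseError(ValueError):
    """Raised when a lipid shorthand name cannot be parsed."""


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed lipid species.

    ``sn1_linkage`` is ``"alkenyl_ether"`` for plasmalogen-class ("P-")
    species, ``"alkyl_ether"`` for "O-" species, ``"acyl"`` for ordinary
    ester lipids, and ``"n/a"`` for chainless class-level names such as
    cholesterol.
    """

    raw_name: str
    headgroup: str  # PC, PE, SM, TG, Cholesterol, other
    sn1_linkage: str  # acyl | alkenyl_ether | alkyl_ether | n/a
    chains: tuple[tuple[int, int], ...]  # (carbons, double_bonds) per chain
    sum_composition: bool = False

    @property
    def total_carbons(self) -> int:
        return sum(c for c, _ in self.chains)

    @property
    def total_double_bonds(self) -> int:
        return sum(db for _, db in self.chains)

    def __str__(self) -> str:
        return format_lipid_name(self)


@dataclass(frozen=True)
class LipidClassification:
    """Boolean classification flags for one species."""

    is_phospholipid: bool
    is_ether: bool
    is_plasmalogen_class: bool
    is_pufa_containing: bool
    is_short_saturated: bool


def parse_lipid_name(raw_name: str) -> LipidSpecies:
    """Parse a shorthand lipid name into a :class:`LipidSpecies`.

    Accepts ``HEAD(chain[/chain...])`` with an optional ``P-``/``O-``
    prefix on the first chain, sphingoid ``d``/``t`` prefixes, both ``:``
    and ``∶`` separators, and the chainless class name ``Cholesterol``.
    Unknown headgroups are classified ``other`` with a warning. Raises
    :class:`LipidParseError` naming the offending token on malformed input.
    """
    if not isinstance(raw_name, str) or not raw_name.strip():
        raise LipidParseError(f"empty or non-string lipid name: {raw_name!r}")
    name = raw_name.strip().replace("∶", ":")

    if name.lower() == "cholesterol":
        return LipidSpecies(raw_name=raw_name, headgroup="Cholesterol",
                            sn1_linkage="n/a", chains=())

    m = _NAME_RE.match(name)
    if m is None:
        raise LipidParseError(
            f"malformed lipid name {raw_name!r}: expected HEAD(chain[/chain...])")
    head = m.group("head")
    if head not in _KNOWN_HEADGROUPS:
        warnings.warn(f"unknown headgroup {head!r} in {raw_name!r}; "
                      "classified as 'other'", stacklevel=2)
        headgroup = "other"
    else:
        headgroup = head

    chain_tokens = m.group("chains").split("/")
    chains: list[tuple[int, int]] = []
    sn1_linkage = "acyl"
    for pos, tok in enumerate(chain_tokens):
        cm = _CHAIN_RE.match(tok.strip())
        if cm is None:
            raise LipidParseError(
                f"malformed chain token {tok!r} in lipid name {raw_name!r}")
        prefix = cm.group("prefix")
        if prefix in ("P-", "O-"):
            if pos != 0:
                raise LipidParseError(
                    f"ether prefix {prefix!r} only allowed on the first chain "
                    f"({raw_name!r})")
            sn1_linkage = "alkenyl_ether" if prefix == "P-" else "alkyl_ether"
        carbons = int(cm.group("c"))
        double_bonds = int(cm.group("db"))
        if carbons <= 0:
            raise LipidParseError(
                f"non-positive carbon count in chain {tok!r} of {raw_name!r}")
        chains.append((carbons, double_bonds))

    # single C:D token on a glycerolipid headgroup = class-level sum composition
    sum_comp = len(chains) == 1 and headgroup in ("PC", "PE", "SM", "TG", "other")
    return LipidSpecies(raw_name=raw_name, headgroup=headgroup,
                        sn1_linkage=sn1_linkage, chains=tuple(chains),
                        sum_composition=sum_comp)


def format_lipid_name(sp: LipidSpecies) -> str:
    """Canonical shorthand for a species (``:`` dialect, no whitespace)."""
    if sp.headgroup == "Cholesterol":
        return "Cholesterol"
    head = sp.headgroup if sp.headgroup != "other" else sp.raw_name.split("(")[0]
    toks = []
    for i, (c, db) in enumerate(sp.chains):
        prefix = ""
        if i == 0:
            if sp.sn1_linkage == "alkenyl_ether":
                prefix = "P-"
            elif sp.sn1_linkage == "alkyl_ether":
                prefix = "O-"
        toks.append(f"{prefix}{c}:{db}")
    return f"{head}({'/'.join(toks)})"


def classify_species(sp: LipidSpecies, pufa_threshold: int = 2,
                     short_carbon_max: int = 32,
                     saturated_db_max: int = 1) -> LipidClassification:
    """Classify a parsed species into the membrane-remodeling categories.

    A species is PUFA-containing when any single chain carries at least
    ``pufa_threshold`` double bonds (default 2). "Short saturated" means
    at most ``saturated_db_max`` double bonds in total and no more than
    ``short_carbon_max`` total carbons — the species class depleted in
    heavy co-twins. Sum compositions (single pseudo-chain names) are
    excluded from the chain-specific PUFA/short-saturated calls.
    """
    is_pl = sp.headgroup in PHOSPHOLIPID_HEADGROUPS
    is_ether = sp.sn1_linkage in ("alkenyl_ether", "alkyl_ether")
    is_plasmalogen = sp.sn1_linkage == "alkenyl_ether"
    if sp.sum_composition or not sp.chains:
        is_pufa = False
        is_short_sat = False
    else:
        is_pufa = any(db >= pufa_threshold for _, db in sp.chains)
        is_short_sat = (sp.total_double_bonds <= saturated_db_max
                        and sp.total_carbons <= short_carbon_max)
    return LipidClassification(
        is_phospholipid=is_pl,
        is_ether=is_ether,
        is_plasmalogen_class=is_plasmalogen,
        is_pufa_containing=is_pufa,
        is_short_saturated=is_short_sat,
    )


_METADATA_ROLES = ("heavy", "lean", "none")


@dataclass
class AbundanceTable:
    """A species x subject lipid concentration matrix with twin metadata.

    ``data`` is indexed by species raw name (rows) with subject id columns.
    ``metadata`` is indexed by subject id and carries at least ``pair_id``,
    ``role`` (heavy/lean/none) and ``group`` (discordant, concordant_high,
    concordant_low, morbid); clinical covariates such as ``bmi`` and
    ``fcs`` ride along as extra columns.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame
    species: list[LipidSpecies] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self) -> None:
        if not self.species:
            self.species = [parse_lipid_name(n) for n in self.data.index]
        self.validate()

    def validate(self) -> None:
        if len(self.species) != self.data.shape[0]:
            raise ValueError("species list does not match data rows")
        if list(self.data.columns) != list(self.metadata.index):
            missing = set(self.data.columns) ^ set(self.metadata.index)
            raise ValueError(f"subject mismatch between data and metadata: {missing}")
        if (self.data.values < 0).any():
            bad = np.argwhere(self.data.values < 0)[0]
            raise ValueError(
                f"negative concentration at species {self.data.index[bad[0]]!r}, "
                f"subject {self.data.columns[bad[1]]!r}")
        bad_roles = set(self.metadata["role"]) - set(_METADATA_ROLES)
        if bad_roles:
            raise ValueError(f"unknown roles {bad_roles}")
        disc = self.metadata[self.metadata["group"] == "discordant"]
        for pair_id, sub in disc.groupby("pair_id"):
            roles = sorted(sub["role"])
            if roles != ["heavy", "lean"]:
                raise ValueError(
                    f"discordant pair {pair_id!r} must have exactly one heavy "
                    f"and one lean subject, got {list(sub['role'])}")

    @property
    def subjects(self) -> list[str]:
        return list(self.data.columns)

    def classifications(self, **kwargs) -> pd.DataFrame:
        """Per-species classification flags as a boolean DataFrame."""
        rows = {sp.raw_name: vars(classify_species(sp, **kwargs))
                for sp in self.species}
        return pd.DataFrame.from_dict(rows, orient="index").loc[self.data.index]

    def phospholipid_mask(self,
                          headgroups: tuple[str, ...] = PHOSPHOLIPID_HEADGROUPS
                          ) -> np.ndarray:
        return np.array([sp.headgroup in headgroups for sp in self.species])

    def discordant_pairs(self) -> pd.DataFrame:
        """Pair table: index pair_id, columns heavy/lean subject ids."""
        disc = self.metadata[self.metadata["group"] == "discordant"]
        out = {}
        for pair_id, sub in disc.groupby("pair_id"):
            heavy = sub.index[sub["role"] == "heavy"][0]
            lean = sub.index[sub["role"] == "lean"][0]
            out[pair_id] = {"heavy": heavy, "lean": lean}
        return pd.DataFrame.from_dict(out, orient="index").sort_index()


def normalize_total_pl(table: AbundanceTable,
                       headgroups: tuple[str, ...] = PHOSPHOLIPID_HEADGROUPS
                       ) -> AbundanceTable:
    """Express every species as a fraction of the subject's total phospholipid.

    Each subject column is divided by that subject's summed signal over the
    phospholipid classes (default PC, PE, SM). Non-phospholipid species
    (triacylglycerols, cholesterol) become fractions of total PL and may
    exceed 1. Raises if any subject has zero total phospholipid signal.
    """
    mask = table.phospholipid_mask(headgroups)
    if not mask.any():
        raise ValueError("no phospholipid species in table")
    totals = table.data.values[mask].sum(axis=0)
    zero = np.flatnonzero(totals <= 0)
    if zero.size:
        raise ValueError(
            "zero total phospholipid signal for subject(s): "
            + ", ".join(table.data.columns[i] for i in zero))
    data = table.data / totals
    return AbundanceTable(data=data, metadata=table.metadata.copy(),
                          species=list(table.species), normalized=True)
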