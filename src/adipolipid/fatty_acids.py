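"""Fatty-acid desaturation/elongation activity indices.

The activity of an enzymatic step (e.g. SCD-catalyzed Delta-9
desaturation 16:0 -> 16:1n7, or ELOVL6 elongation 16:0 -> 18:0) is
estimated by the product-to-substrate concentration ratio on mol%
fatty-acid profiles. These ratios are indices of pathway activity, not
kinetic rates. The default step table is shipped as a package data file
(``data/fatty_acid_steps.tsv``) covering the Delta-9, n-6 and n-3 routes
up to arachidonic acid and DHA; it is editable without code changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .diffstats import paired_frame_analysis

__all__ = [
    "PathwayStep",
    "default_step_table",
    "step_ratio",
    "ratio_table",
    "compare_ratios_paired",
    "validate_profile",
]


@dataclass(frozen=True)
class PathwayStep:
    """One enzymatic step estimated by a product/substrate ratio."""

    name: str
    enzyme: str
    substrate_fa: str
    product_fa: str
    series: str  # n-3 | n-6 | n-7 | n-9 | saturated

    def __post_init__(self) -> None:
        if self.substrate_fa == self.product_fa:
            raise ValueError(f"step {self.name!r}: substrate equals product")


def default_step_table() -> list[PathwayStep]:
    """The packaged desaturation/elongation step set.

    Covers Delta-9 desaturation (16:0->16:1n7, 18:0->18:1n9), ELOVL6
    elongations (16:0->18:0, 16:1n7->18:1n7), the n-6 route
    18:2n6->18:3n6->20:3n6->20:4n6 plus 20:4n6->22:4n6, and the n-3
    route 18:3n3->18:4n3->20:4n3->20:5n3->22:5n3->22:6n3.
    """
    src = resources.files("adipolipid").joinpath("data/fatty_acid_steps.tsv")
    with resources.as_file(src) as path:
        df = pd.read_csv(path, sep="\t")
    return [PathwayStep(**row) for row in df.to_dict(orient="records")]


def validate_profile(profile: pd.DataFrame, tol: float = 1e-6) -> None:
    """Check a subjects x fatty-acid mol% frame for basic sanity."""
    if (profile.values < 0).any():
        raise ValueError("mol% values must be non-negative")
    over = profile.sum(axis=1) > 100 + tol
    if over.any():
        raise ValueError(
            f"per-subject mol% sums exceed 100: {list(profile.index[over])}")


def step_ratio(profile: pd.DataFrame, step: PathwayStep) -> pd.Series:
    """Product/substrate mol% ratio per subject for one step.

    Subjects with zero substrate get NaN with a warning rather than a
    division blow-up. Raises KeyError when a label is missing from the
    profile columns.
    """
    for label in (step.substrate_fa, step.product_fa):
        if label not in profile.columns:
            raise KeyError(
                f"fatty acid {label!r} of step {step.name!r} not in profile")
    sub = profile[step.substrate_fa].to_numpy(float)
    prod = profile[step.product_fa].to_numpy(float)
    out = np.full(len(profile), np.nan)
    ok = sub > 0
    if not ok.all():
        bad = list(profile.index[~ok])
        warnings.warn(f"zero substrate {step.substrate_fa!r} for subject(s) "
                      f"{bad}; ratio set to NaN", stacklevel=2)
    out[ok] = prod[ok] / sub[ok]
    return pd.Series(out, index=profile.index, name=step.name)


def ratio_table(profile: pd.DataFrame,
                steps: list[PathwayStep] | None = None) -> pd.DataFrame:
    """All step ratios: rows = subjects, columns = step names."""
    if steps is None:
        steps = default_step_table()
    return pd.concat([step_ratio(profile, s) for s in steps], axis=1)


def compare_ratios_paired(profile: pd.DataFrame, metadata: pd.DataFrame,
                          steps: list[PathwayStep] | None = None,
                          method: str = "t",
                          log_transform: bool = True) -> pd.DataFrame:
    """Paired heavy-vs-lean comparison of every step ratio.

    ``metadata`` follows the abundance-table schema (pair_id, role,
    group). Delegates to the paired test machinery on the per-subject
    ratios; reports per-step statistic, p-value, Storey q-value and
    heavy-vs-lean direction.
    """
    if steps is None:
        steps = default_step_table()
    ratios = ratio_table(profile, steps)
    if ratios.isna().any().any():
        dropped = list(ratios.columns[ratios.isna().any()])
        warnings.warn(f"steps with missing ratios dropped: {dropped}",
                      stacklevel=2)
        ratios = ratios.dropna(axis=1)
    res = paired_frame_analysis(ratios.T.loc[:, metadata.index], metadata,
                                method=method, log_transform=log_transform)
    res.index.name = "step"
    return res.rename(columns={"mean_heavy": "mean_ratio_heavy",
                               "mean_lean": "mean_ratio_lean"})
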