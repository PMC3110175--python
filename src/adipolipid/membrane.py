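"""Membrane biophysical properties from bilayer trajectories.

Computes the quantities used to compare simulated bilayer systems:

* **area per lipid (APL)** — lateral box area divided by the number of
  lipids in one leaflet; a proxy for packing/fluidity (smaller area =
  less fluid).
* **bilayer thickness** — separation of the mean z of the two leaflets'
  head-reference atoms.
* **molecular order parameter** S_mol(i) = <(3 cos^2 theta - 1)/2>,
  where theta is the angle between the chain segment vector at carbon i
  and the bilayer normal (fixed to z). The segment vector at interior
  carbon i is C(i+1) - C(i-1); segments are numbered from the linkage
  end, and the terminal carbons carry no value. S_mol is 1 for chains
  perfectly ordered along the normal, 0 for isotropic orientations and
  -0.5 for chains lying in the membrane plane.

Frames before a configured equilibration time are discarded prior to
averaging. Standard errors use block averaging (default 5 blocks) since
consecutive frames are autocorrelated.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .lipids import LipidSpecies, parse_lipid_name

__all__ = [
    "LipidTopology",
    "BilayerTrajectory",
    "MembraneProperties",
    "MixtureDesign",
    "area_per_lipid",
    "apl_series",
    "smol_profile",
    "thickness",
    "discard_equilibration",
    "design_mixture",
    "compare_systems",
    "analyze_trajectory",
    "write_trajectory",
    "read_trajectory",
]


@dataclass(frozen=True)
class LipidTopology:
    """One lipid's atoms: leaflet, head reference, ordered chain carbons."""

    leaflet: str  # "upper" | "lower"
    head_index: int
    chains: tuple[tuple[int, ...], ...]  # atom indices, linkage -> terminal methyl


@dataclass
class BilayerTrajectory:
    """Frames of box dimensions and coordinates plus chain topology.

    ``boxes`` is (n_frames, 3) in nm, ``coords`` (n_frames, n_atoms, 3) in
    nm, ``times`` (n_frames,) in ns. All frames share the topology.
    """

    boxes: np.ndarray
    coords: np.ndarray
    times: np.ndarray
    lipids: list[LipidTopology]

    def __post_init__(self) -> None:
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.boxes.shape != (self.n_frames, 3):
            raise ValueError("boxes must be (n_frames, 3)")
        if self.coords.ndim != 3 or self.coords.shape[0] != self.n_frames:
            raise ValueError("coords must be (n_frames, n_atoms, 3)")
        leaflets = {lip.leaflet for lip in self.lipids}
        if not leaflets <= {"upper", "lower"}:
            raise ValueError(f"unknown leaflet labels {leaflets}")
        for lip in self.lipids:
            for chain in lip.chains:
                if max(chain, default=-1) >= self.n_atoms:
                    raise ValueError("chain atom index beyond coordinate array")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def n_lipids(self) -> int:
        return len(self.lipids)

    def leaflet_count(self, leaflet: str) -> int:
        return sum(1 for lip in self.lipids if lip.leaflet == leaflet)


@dataclass
class MembraneProperties:
    """Summary of one analyzed bilayer system."""

    apl_series: np.ndarray  # nm^2 per analyzed frame
    apl_mean: float
    apl_sem: float
    thickness_mean: float
    thickness_sem: float
    smol_profile: pd.DataFrame  # columns: segment, smol, sem
    smol_saturated_mean: float
    fluidity_index: float  # 1 / mean S_mol over saturated segments
    analyzed_window: tuple[float, float]  # (t_start, t_end) ns
    label: str = ""


@dataclass
class MixtureDesign:
    """Integer per-leaflet lipid counts realizing target mole fractions."""

    components: list[tuple[LipidSpecies, float]]
    n_lipids_total: int
    per_leaflet_counts: list[int]
    realized_fractions: list[float]


def _block_sem(series: np.ndarray, n_blocks: int = 5) -> float:
    """Standard error of the mean by block averaging over n_blocks blocks."""
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n < 2:
        return float("nan")
    n_blocks = min(n_blocks, n)
    blocks = np.array_split(series, n_blocks)
    means = np.array([b.mean() for b in blocks])
    return float(means.std(ddof=1) / math.sqrt(n_blocks))


def area_per_lipid(box: np.ndarray, n_leaflet_lipids: int) -> float:
    """Lateral area Lx*Ly divided by the per-leaflet lipid count (nm^2)."""
    if n_leaflet_lipids <= 0:
        raise ValueError("n_leaflet_lipids must be positive")
    box = np.asarray(box, dtype=float)
    if (box[:2] <= 0).any():
        raise ValueError("box dimensions must be positive")
    return float(box[0] * box[1] / n_leaflet_lipids)


def apl_series(traj: BilayerTrajectory) -> np.ndarray:
    """Per-frame area per lipid of the upper leaflet (nm^2)."""
    n_up = traj.leaflet_count("upper")
    n_lo = traj.leaflet_count("lower")
    if n_up != n_lo:
        raise ValueError(f"unequal leaflet populations ({n_up} vs {n_lo})")
    return traj.boxes[:, 0] * traj.boxes[:, 1] / n_up


def smol_profile(traj: BilayerTrajectory, chain_selector=None,
                 n_blocks: int = 5) -> pd.DataFrame:
    """Per-segment molecular order parameter profile.

    ``chain_selector`` restricts which chains enter the average: ``None``
    (all chains), an int (chain position within each lipid, 0 = sn-1), or
    a callable ``(lipid_index, chain_index) -> bool``. Returns a DataFrame
    with columns ``segment`` (1-based interior carbon number counted from
    the linkage end), ``smol``, ``sem``.
    """
    chains = []
    for li, lip in enumerate(traj.lipids):
        for ci, chain in enumerate(lip.chains):
            if chain_selector is None:
                keep = True
            elif callable(chain_selector):
                keep = chain_selector(li, ci)
            else:
                keep = ci == int(chain_selector)
            if keep:
                if len(chain) < 3:
                    raise ValueError(
                        f"chain {ci} of lipid {li} has fewer than 3 carbons")
                chains.append(chain)
    if not chains:
        raise ValueError("chain selector matched no chains")
    n_carbons = len(chains[0])
    if any(len(c) != n_carbons for c in chains):
        raise ValueError("selected chains have differing carbon counts")

    idx = np.array(chains)  # (n_chains, n_carbons)
    # segment vector at interior carbon i: C(i+1) - C(i-1)
    coords = traj.coords  # (F, N, 3)
    fwd = coords[:, idx[:, 2:], :]   # (F, n_chains, n_carbons-2, 3)
    bwd = coords[:, idx[:, :-2], :]
    seg = fwd - bwd
    norm = np.linalg.norm(seg, axis=-1)
    if (norm == 0).any():
        raise ValueError("zero-length segment vector encountered")
    cos2 = (seg[..., 2] / norm) ** 2
    p2 = 1.5 * cos2 - 0.5  # (F, n_chains, n_segments)
    per_frame = p2.mean(axis=1)  # (F, n_segments)
    rows = []
    for s in range(per_frame.shape[1]):
        rows.append({
            "segment": s + 1,
            "smol": float(per_frame[:, s].mean()),
            "sem": _block_sem(per_frame[:, s], n_blocks),
        })
    return pd.DataFrame(rows)


def thickness(traj: BilayerTrajectory) -> np.ndarray:
    """Per-frame head-plane separation: mean z(upper heads) - mean z(lower)."""
    up = [lip.head_index for lip in traj.lipids if lip.leaflet == "upper"]
    lo = [lip.head_index for lip in traj.lipids if lip.leaflet == "lower"]
    if not up or not lo:
        raise ValueError("a leaflet has no head-reference atoms")
    z_up = traj.coords[:, up, 2].mean(axis=1)
    z_lo = traj.coords[:, lo, 2].mean(axis=1)
    return z_up - z_lo


def discard_equilibration(traj: BilayerTrajectory,
                          t_equil: float) -> BilayerTrajectory:
    """Drop frames with time < ``t_equil`` (ns)."""
    if t_equil <= 0:
        return traj
    keep = traj.times >= t_equil
    if not keep.any():
        raise ValueError(
            f"t_equil = {t_equil} ns discards the whole trajectory "
            f"(duration {traj.times[-1]} ns)")
    return BilayerTrajectory(boxes=traj.boxes[keep], coords=traj.coords[keep],
                             times=traj.times[keep], lipids=traj.lipids)


def analyze_trajectory(traj: BilayerTrajectory, t_equil: float = 0.0,
                       chain_selector=None, saturated_segments=None,
                       n_blocks: int = 5, label: str = "") -> MembraneProperties:
    """Full property summary after discarding the equilibration window.

    ``saturated_segments`` names the 1-based segment numbers entering the
    saturated-segment average whose inverse is reported as the fluidity
    index; default is all segments (appropriate for the geometric
    synthetic fixtures, which carry no per-segment saturation labels).
    """
    analyzed = discard_equilibration(traj, t_equil)
    apl = apl_series(analyzed)
    thick = thickness(analyzed)
    prof = smol_profile(analyzed, chain_selector, n_blocks=n_blocks)
    if saturated_segments is None:
        sat = prof
    else:
        sat = prof[prof["segment"].isin(saturated_segments)]
    sat_mean = float(sat["smol"].mean())
    return MembraneProperties(
        apl_series=apl,
        apl_mean=float(apl.mean()),
        apl_sem=_block_sem(apl, n_blocks),
        thickness_mean=float(thick.mean()),
        thickness_sem=_block_sem(thick, n_blocks),
        smol_profile=prof,
        smol_saturated_mean=sat_mean,
        fluidity_index=float(1.0 / sat_mean) if sat_mean != 0 else float("inf"),
        analyzed_window=(float(analyzed.times[0]), float(analyzed.times[-1])),
        label=label,
    )


def design_mixture(components, n_lipids: int) -> MixtureDesign:
    """Integer per-leaflet counts for a lipid mixture by largest remainder.

    ``components`` is a list of (species-or-name, target mole fraction);
    fractions must sum to 1 and ``n_lipids`` must be even. Counts are
    assigned per leaflet symmetrically: quotas fraction * (n_lipids/2)
    are floored, and leftover slots go to the largest fractional
    remainders. Warns when a component rounds to zero.
    """
    comps = []
    for sp, frac in components:
        if isinstance(sp, str):
            sp = parse_lipid_name(sp)
        comps.append((sp, float(frac)))
    total = sum(f for _, f in comps)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mole fractions sum to {total}, expected 1")
    if n_lipids % 2:
        raise ValueError("n_lipids must be even (two equal leaflets)")
    per_leaflet = n_lipids // 2
    quotas = [f * per_leaflet for _, f in comps]
    counts = [math.floor(q) for q in quotas]
    leftover = per_leaflet - sum(counts)
    order = sorted(range(len(comps)), key=lambda i: (quotas[i] - counts[i], -i),
                   reverse=True)
    for i in order[:leftover]:
        counts[i] += 1
    for (sp, _), c in zip(comps, counts):
        if c == 0:
            warnings.warn(f"component {sp} rounds to zero lipids per leaflet",
                          stacklevel=2)
    realized = [c / per_leaflet for c in counts]
    return MixtureDesign(components=comps, n_lipids_total=n_lipids,
                         per_leaflet_counts=counts, realized_fractions=realized)


def compare_systems(props: list[MembraneProperties],
                    labels: list[str] | None = None) -> pd.DataFrame:
    """Rank analyzed systems by mean APL (descending fluidity).

    All systems must share the analyzed time window. Returns a DataFrame
    with one row per system ordered by decreasing apl_mean, including the
    APL difference to the next-ranked system with propagated sem.
    """
    if len(props) < 2:
        raise ValueError("need at least two systems to compare")
    if labels is not None:
        props = [replace(p, label=lb) for p, lb in zip(props, labels)]
    windows = {p.analyzed_window for p in props}
    if len(windows) > 1:
        raise ValueError(f"mismatched analysis windows: {windows}")
    ranked = sorted(props, key=lambda p: (-p.apl_mean, p.label))
    rows = []
    for rank, p in enumerate(ranked):
        row = {
            "rank": rank + 1,
            "label": p.label,
            "apl_mean": p.apl_mean,
            "apl_sem": p.apl_sem,
            "thickness_mean": p.thickness_mean,
            "thickness_sem": p.thickness_sem,
            "fluidity_index": p.fluidity_index,
        }
        if rank + 1 < len(ranked):
            nxt = ranked[rank + 1]
            row["apl_diff_to_next"] = p.apl_mean - nxt.apl_mean
            row["apl_diff_sem"] = math.hypot(p.apl_sem, nxt.apl_sem)
        else:
            row["apl_diff_to_next"] = np.nan
            row["apl_diff_sem"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Minimal text trajectory format
#
#   TOPOLOGY <n_lipids>
#   LIPID <leaflet> <head_index> <chain1 indices comma-sep> [<chain2 ...>]
#   ...
#   FRAME <time_ns> <Lx> <Ly> <Lz>
#   <x> <y> <z>          (one line per atom, nm)
#   ...
# ---------------------------------------------------------------------------

def write_trajectory(traj: BilayerTrajectory, path) -> None:
    """Write a trajectory in the package's minimal text format."""
    with open(path, "w") as fh:
        fh.write(f"TOPOLOGY {traj.n_lipids}\n")
        for lip in traj.lipids:
            chains = " ".join(",".join(str(i) for i in ch) for ch in lip.chains)
            fh.write(f"LIPID {lip.leaflet} {lip.head_index} {chains}\n")
        for f in range(traj.n_frames):
            b = traj.boxes[f]
            fh.write(f"FRAME {traj.times[f]:.6f} {b[0]:.9f} {b[1]:.9f} {b[2]:.9f}\n")
            for atom in traj.coords[f]:
                fh.write(f"{atom[0]:.9f} {atom[1]:.9f} {atom[2]:.9f}\n")


def read_trajectory(path) -> BilayerTrajectory:
    """Read a trajectory written by :func:`write_trajectory`."""
    lipids: list[LipidTopology] = []
    boxes, times, frames = [], [], []
    current: list[list[float]] | None = None
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "TOPOLOGY":
                continue
            if parts[0] == "LIPID":
                chains = tuple(tuple(int(i) for i in tok.split(","))
                               for tok in parts[3:])
                lipids.append(LipidTopology(leaflet=parts[1],
                                            head_index=int(parts[2]),
                                            chains=chains))
            elif parts[0] == "FRAME":
                if current is not None:
                    frames.append(current)
                times.append(float(parts[1]))
                boxes.append([float(parts[2]), float(parts[3]), float(parts[4])])
                current = []
            else:
                if current is None:
                    raise ValueError(f"coordinate line before any FRAME: {line!r}")
                current.append([float(parts[0]), float(parts[1]), float(parts[2])])
    if current is not None:
        frames.append(current)
    return BilayerTrajectory(boxes=np.array(boxes), coords=np.array(frames),
                             times=np.array(times), lipids=lipids)
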