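"""Synthetic data with known ground truth for every pipeline stage.

Three generator families:

* :func:`simulate_cohort` — a monozygotic-twin lipidomics cohort
  (default 13 BMI-discordant + 9 concordant pairs, ~300 species) with
  planted multiplicative effects: PUFA-containing ether phospholipids
  elevated and short saturated species depleted in heavy co-twins, plus
  a pair-level random effect producing within-pair correlation. A
  ``morbid`` scenario applies a global depletion of PUFA-ether species.
* :func:`simulate_network_data` — multivariate normal samples from a
  given precision matrix; the true conditional-dependence edges are the
  non-zero off-diagonal precision entries.
* :func:`simulate_trajectory` — idealized bilayer trajectories whose
  area per lipid, head-plane thickness and per-segment orientational
  order are prescribed exactly in expectation, for membrane-analysis
  parameter-recovery tests.

All generators are deterministic given their spec (which includes the
seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lipids import AbundanceTable, classify_species, parse_lipid_name
from .membrane import BilayerTrajectory, LipidTopology

__all__ = [
    "CohortSpec",
    "TrajectorySpec",
    "simulate_cohort",
    "simulate_fatty_acid_profiles",
    "simulate_network_data",
    "chain_precision",
    "random_sparse_precision",
    "simulate_trajectory",
    "build_species_catalog",
]

# Additional log2 shift applied to PUFA-ether species for every subject in
# the morbid-obesity scenario (ether-lipid remodeling broken down).
MORBID_ETHER_LOG2_SHIFT = -1.5


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic twin lipidomics cohort.

    Defaults mirror the study conditions: 13 discordant + 9 concordant
    pairs, 300 species of which 10% are PUFA-ether (planted up 1 log2
    unit in heavy co-twins) and 10% short saturated (planted down 1 log2
    unit), measurement noise sd 0.2 on the log2 scale and within-pair
    correlation 0.5.
    """

    n_discordant_pairs: int = 13
    n_concordant_pairs: int = 9
    n_species: int = 300
    fraction_ether_pufa: float = 0.1
    fraction_short_sat: float = 0.1
    effect_log2_up: float = 1.0
    effect_log2_down: float = -1.0
    within_pair_corr: float = 0.5
    noise_sd_log: float = 0.2
    seed: int = 0
    scenario: str = "healthy_obese"

    def __post_init__(self) -> None:
        if self.n_discordant_pairs < 1 or self.n_concordant_pairs < 0:
            raise ValueError("pair counts must be positive")
        if not 0 <= self.fraction_ether_pufa <= 1:
            raise ValueError("fraction_ether_pufa must lie in [0, 1]")
        if not 0 <= self.within_pair_corr < 1:
            raise ValueError("within_pair_corr must lie in [0, 1)")
        if self.noise_sd_log <= 0:
            raise ValueError("noise_sd_log must be positive")
        if self.scenario not in ("healthy_obese", "morbid"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.fraction_ether_pufa > 0 and \
                round(self.fraction_ether_pufa * self.n_species) < 1:
            raise ValueError("fraction_ether_pufa * n_species < 1")


def build_species_catalog(n_species: int, n_ether_pufa: int,
                          n_short_sat: int) -> tuple[list[str], pd.DataFrame]:
    """Deterministic species name catalog with planted-category labels.

    Returns (names, truth frame with column ``category`` in
    {ether_pufa, short_sat, null}). Names are valid shorthand and their
    parsed classifications agree with the assigned category.
    """
    ether_pool = [
        f"{head}(P-{sn1}/{sn2})"
        for head in ("PE", "PC")
        for sn1 in ("16:0", "18:0", "16:1", "18:1")
        for sn2 in ("20:4", "22:6", "20:3", "22:5", "18:2", "22:4")
    ] + [
        f"{head}(O-{sn1}/{sn2})"
        for head in ("PE", "PC")
        for sn1 in ("16:0", "18:1")
        for sn2 in ("20:4", "22:6", "20:3")
    ]
    short_pool = [
        f"{head}({sn1}/{sn2})"
        for head in ("PC", "PE")
        for sn1 in ("12:0", "14:0", "16:0")
        for sn2 in ("14:0", "16:0", "16:1", "14:1")
    ] + [f"SM(d16:{db}/{c}:0)" for db in (0, 1) for c in (12, 14, 16)]
    null_pool = [
        f"{head}({sn1}/{sn2})"
        for head in ("PC", "PE")
        for sn1 in ("16:0", "18:0", "18:1", "16:1")
        for sn2 in ("18:1", "18:2", "20:4", "22:6", "20:1")
    ] + [f"SM(d18:1/{c}:{db})" for c in (18, 20, 22, 24) for db in (0, 1)] \
      + [f"TG({c}:{db})" for c in range(44, 60, 2) for db in range(0, 7)] \
      + ["Cholesterol"]

    if n_ether_pufa > len(ether_pool):
        raise ValueError(f"at most {len(ether_pool)} ether-PUFA species available")
    if n_short_sat > len(short_pool):
        raise ValueError(f"at most {len(short_pool)} short saturated species available")
    n_null = n_species - n_ether_pufa - n_short_sat
    if n_null < 0:
        raise ValueError("planted categories exceed n_species")
    if n_null > len(null_pool):
        # pad with distinct sum compositions (excluded from chain-specific
        # classification, so never PUFA/short-saturated calls)
        null_pool = null_pool + [f"{head}({c}:{db})" for head in ("PC", "PE")
                                 for c in range(30, 48) for db in range(0, 10)]
    if n_null > len(null_pool):
        raise ValueError(f"species catalog exhausted (need {n_null} null)")
    names = (ether_pool[:n_ether_pufa] + short_pool[:n_short_sat]
             + null_pool[:n_null])
    cats = (["ether_pufa"] * n_ether_pufa + ["short_sat"] * n_short_sat
            + ["null"] * n_null)
    truth = pd.DataFrame({"category": cats}, index=names)
    # sanity: planted categories must classify as intended
    for name, cat in zip(names, cats):
        cl = classify_species(parse_lipid_name(name))
        if cat == "ether_pufa":
            assert cl.is_ether and cl.is_pufa_containing, name
        elif cat == "short_sat":
            assert cl.is_short_saturated, name
    return names, truth


def simulate_cohort(spec: CohortSpec) -> tuple[AbundanceTable, pd.DataFrame]:
    """Generate a twin cohort abundance table plus the planted truth.

    Log2 abundance of species *s* in subject *j* of pair *p* is
    ``mu_s + a_{p,s} + e_{j,s} + delta_{s,j}`` with species baseline
    ``mu_s ~ N(0, 1.5^2)``, pair effect variance chosen so the within-pair
    correlation of the log abundances equals ``within_pair_corr``,
    residual sd ``noise_sd_log``, and planted effect ``delta`` applied to
    heavy co-twins of discordant pairs (``effect_log2_up`` on PUFA-ether
    species, ``effect_log2_down`` on short saturated species). The truth
    frame carries per-species ``category`` and signed ``planted_log2``.
    """
    rng = np.random.default_rng(spec.seed)
    n_up = round(spec.fraction_ether_pufa * spec.n_species)
    n_down = round(spec.fraction_short_sat * spec.n_species)
    names, truth = build_species_catalog(spec.n_species, n_up, n_down)

    planted = np.zeros(spec.n_species)
    planted[truth["category"] == "ether_pufa"] = spec.effect_log2_up
    planted[truth["category"] == "short_sat"] = spec.effect_log2_down
    truth = truth.assign(planted_log2=planted)

    n_pairs = spec.n_discordant_pairs + spec.n_concordant_pairs
    rho = spec.within_pair_corr
    pair_sd = spec.noise_sd_log * math.sqrt(rho / (1 - rho))

    mu = rng.normal(0.0, 1.5, size=spec.n_species)
    subjects, meta_rows = [], []
    cols = np.empty((spec.n_species, 2 * n_pairs))
    morbid = spec.scenario == "morbid"
    ether_mask = (truth["category"] == "ether_pufa").to_numpy()

    col = 0
    for p in range(n_pairs):
        discordant = p < spec.n_discordant_pairs
        pair_id = f"pair{p + 1:02d}"
        pair_eff = rng.normal(0.0, pair_sd, size=spec.n_species)
        bmi_base = rng.normal(25.0, 1.5)
        fcs_base = rng.normal(90.0, 8.0)
        for role_idx, role in enumerate(("lean", "heavy") if discordant
                                        else ("a", "b")):
            log2x = mu + pair_eff + rng.normal(0.0, spec.noise_sd_log,
                                               size=spec.n_species)
            if discordant and role == "heavy" and not morbid:
                log2x = log2x + planted
            if morbid:
                log2x = log2x + MORBID_ETHER_LOG2_SHIFT * ether_mask
            sid = f"{pair_id}_{role}"
            subjects.append(sid)
            cols[:, col] = np.exp2(log2x)
            col += 1
            if morbid:
                group, out_role = "morbid", "none"
                bmi = bmi_base + rng.normal(25.0, 3.0)  # BMI ~ 47-60
                fcs = fcs_base + rng.normal(0.0, 10.0)
            elif discordant:
                group, out_role = "discordant", role
                bmi = bmi_base + (5.3 if role == "heavy" else 0.0) \
                    + rng.normal(0.0, 0.5)
                fcs = fcs_base * (1.17 if role == "heavy" else 1.0) \
                    + rng.normal(0.0, 3.0)
            else:
                high = p % 2 == 0  # alternate concordant-high/low pairs
                group = "concordant_high" if high else "concordant_low"
                out_role = "none"
                bmi = bmi_base + (3.0 if high else -1.0) + rng.normal(0.0, 0.5)
                fcs = fcs_base + rng.normal(0.0, 3.0)
            meta_rows.append({"subject": sid, "pair_id": pair_id,
                              "role": out_role, "group": group,
                              "bmi": round(bmi, 2), "fcs": round(fcs, 2)})

    data = pd.DataFrame(cols, index=names, columns=subjects)
    metadata = pd.DataFrame(meta_rows).set_index("subject")
    table = AbundanceTable(data=data, metadata=metadata)
    return table, truth


# Typical adipose-tissue fatty acid composition (mol%), used as the baseline
# of the synthetic profiles; heavy-vs-lean log2 effects mirror the direction
# of the observed remodeling (palmitoleic/arachidonic up; stearic, linoleic,
# alpha-linolenic down).
_FA_BASELINE = {
    "14:0": 3.0, "16:0": 21.0, "16:1n7": 5.5, "18:0": 4.5, "18:1n9": 43.0,
    "18:1n7": 2.0, "18:2n6": 13.0, "18:3n6": 0.1, "18:3n3": 1.1,
    "18:4n3": 0.05, "20:3n6": 0.35, "20:4n6": 0.45, "20:4n3": 0.05,
    "20:5n3": 0.1, "22:4n6": 0.15, "22:5n3": 0.25, "22:6n3": 0.3,
}
_FA_HEAVY_LOG2 = {
    "16:1n7": 0.45, "20:4n6": 0.4, "18:0": -0.3, "18:2n6": -0.25,
    "18:3n3": -0.3, "22:5n3": -0.2,
}


def simulate_fatty_acid_profiles(metadata: pd.DataFrame, seed: int = 0,
                                 noise_sd_log: float = 0.15,
                                 within_pair_corr: float = 0.5,
                                 heavy_effects_log2: dict | None = None
                                 ) -> pd.DataFrame:
    """Fatty-acid mol% profiles (subjects x FA labels) for a cohort.

    Subjects and pairing are taken from an AbundanceTable metadata frame;
    heavy co-twins receive the configured log2 effects before per-subject
    renormalization to 100 mol%.
    """
    if heavy_effects_log2 is None:
        heavy_effects_log2 = _FA_HEAVY_LOG2
    rng = np.random.default_rng(seed)
    labels = list(_FA_BASELINE)
    base = np.log2(np.array([_FA_BASELINE[l] for l in labels]))
    eff = np.array([heavy_effects_log2.get(l, 0.0) for l in labels])
    rho = within_pair_corr
    pair_sd = noise_sd_log * math.sqrt(rho / (1 - rho))

    rows = {}
    for pair_id, sub in metadata.groupby("pair_id", sort=True):
        pair_eff = rng.normal(0.0, pair_sd, size=len(labels))
        for sid in sorted(sub.index):
            log2x = base + pair_eff + rng.normal(0.0, noise_sd_log,
                                                 size=len(labels))
            if sub.loc[sid, "role"] == "heavy":
                log2x = log2x + eff
            x = np.exp2(log2x)
            rows[sid] = 100.0 * x / x.sum()
    prof = pd.DataFrame.from_dict(rows, orient="index", columns=labels)
    return prof.loc[list(metadata.index)]


def simulate_network_data(precision: np.ndarray, n: int, seed: int = 0,
                          var_names: list[str] | None = None
                          ) -> tuple[pd.DataFrame, set[tuple[str, str]]]:
    """Multivariate normal samples with a given precision matrix.

    Returns (samples frame, true edge set). True edges are the variable
    pairs with non-zero off-diagonal precision entries (|omega_ij| >
    1e-12). Raises on non-positive-definite input.
    """
    precision = np.asarray(precision, dtype=float)
    p = precision.shape[0]
    if precision.shape != (p, p) or not np.allclose(precision, precision.T):
        raise ValueError("precision matrix must be square symmetric")
    try:
        np.linalg.cholesky(precision)
    except np.linalg.LinAlgError as exc:
        raise ValueError("precision matrix is not positive definite") from exc
    if var_names is None:
        var_names = [f"X{i + 1}" for i in range(p)]
    cov = np.linalg.inv(precision)
    rng = np.random.default_rng(seed)
    samples = rng.multivariate_normal(np.zeros(p), cov, size=n,
                                      method="cholesky")
    edges = {tuple(sorted((var_names[i], var_names[j])))
             for i in range(p) for j in range(i + 1, p)
             if abs(precision[i, j]) > 1e-12}
    return pd.DataFrame(samples, columns=var_names), edges


def chain_precision(p: int, strength: float = 0.45) -> np.ndarray:
    """Tridiagonal chain precision matrix X1 - X2 - ... - Xp."""
    if not 0 < strength < 0.5:
        raise ValueError("strength must lie in (0, 0.5) for positive definiteness")
    omega = np.eye(p)
    for i in range(p - 1):
        omega[i, i + 1] = omega[i + 1, i] = -strength
    return omega


def random_sparse_precision(p: int, density: float = 0.1, seed: int = 0,
                            strength: tuple[float, float] = (0.2, 0.3)
                            ) -> np.ndarray:
    """Random sparse symmetric positive-definite precision matrix.

    Off-diagonal support is Bernoulli(density) on the upper triangle with
    magnitudes uniform in ``strength`` and random signs; the diagonal is
    inflated to 1.1x the row absolute sum (strict diagonal dominance)
    and the matrix rescaled to unit diagonal. The default strength range
    places direct partial correlations in the regime where they are
    detectable at a few hundred samples while two-step indirect
    correlations (of order strength squared) stay below detectability —
    the regime where conditional-independence structure recovery is
    informative.
    """
    rng = np.random.default_rng(seed)
    omega = np.zeros((p, p))
    iu = np.triu_indices(p, 1)
    mask = rng.random(len(iu[0])) < density
    vals = rng.uniform(*strength, size=mask.sum()) * \
        rng.choice([-1.0, 1.0], size=mask.sum())
    omega[iu[0][mask], iu[1][mask]] = vals
    omega = omega + omega.T
    rowsum = np.abs(omega).sum(axis=1)
    np.fill_diagonal(omega, np.maximum(1.0, 1.1 * rowsum))
    d = np.sqrt(np.diag(omega))
    return omega / np.outer(d, d)


@dataclass(frozen=True)
class TrajectorySpec:
    """Design of an idealized bilayer trajectory.

    ``target_smol_profile`` is a scalar or per-segment list of target
    orientational order values in [-0.5, 1]. ``orientation_mode``:
    ``"mixture"`` draws each segment from a mix of perfectly aligned
    (weight S, for S >= 0; in-plane with weight -2S for S < 0) and
    isotropic orientations, giving the target in expectation;
    ``"fixed_angle"`` uses the deterministic polar angle
    ``arccos(sqrt((2S + 1)/3))`` so every single segment attains the
    target exactly (noise-free limit, e.g. the magic angle 54.7356 deg
    for S = 0). If ``volume_coupling`` is set, the head-plane thickness
    is 2 V_lipid / APL each frame with the fixed molecular volume
    ``v_lipid`` (nm^3), so thickness x APL is constant by construction
    and thickness falls as the membrane spreads laterally; otherwise the
    thickness is ``thickness0`` in every frame.
    """

    n_lipids: int = 128
    n_chain_carbons: int = 16
    chains_per_lipid: int = 2
    target_apl: float = 0.60  # nm^2
    target_smol_profile: float | tuple = 0.3
    thickness0: float = 4.0  # nm
    volume_coupling: bool = False
    v_lipid: float = 1.2  # nm^3, used only with volume_coupling
    n_frames: int = 50
    frame_jitter_sd: float = 0.0  # relative sd of the per-frame box area
    time_per_frame: float = 1.0  # ns
    orientation_mode: str = "mixture"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lipids % 2:
            raise ValueError("n_lipids must be even (two equal leaflets)")
        if self.n_chain_carbons < 3:
            raise ValueError("chains need at least 3 carbons for a segment")
        if self.orientation_mode not in ("mixture", "fixed_angle"):
            raise ValueError(f"unknown orientation_mode {self.orientation_mode!r}")
        prof = self.segment_targets()
        if ((prof < -0.5) | (prof > 1.0)).any():
            raise ValueError("target S_mol values must lie in [-0.5, 1]")

    def segment_targets(self) -> np.ndarray:
        n_seg = self.n_chain_carbons - 2
        prof = np.asarray(self.target_smol_profile, dtype=float)
        if prof.ndim == 0:
            return np.full(n_seg, float(prof))
        if len(prof) != n_seg:
            raise ValueError(
                f"target_smol_profile needs {n_seg} per-segment values")
        return prof


def _segment_vectors(rng: np.random.Generator, s_target: float, size: int,
                     mode: str) -> np.ndarray:
    """Unit segment vectors whose expected P2(cos theta) equals s_target."""
    if mode == "fixed_angle":
        cos_t = math.sqrt((2.0 * s_target + 1.0) / 3.0)
        sin_t = math.sqrt(max(0.0, 1.0 - cos_t ** 2))
        phi = rng.uniform(0.0, 2.0 * math.pi, size=size)
        return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi),
                                np.full(size, cos_t)])
    # mixture mode
    u = rng.random(size)
    z = rng.uniform(-1.0, 1.0, size=size)
    phi = rng.uniform(0.0, 2.0 * math.pi, size=size)
    r = np.sqrt(1.0 - z ** 2)
    vec = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])  # isotropic
    if s_target >= 0:
        aligned = u < s_target
        vec[aligned] = [0.0, 0.0, 1.0]
    else:
        planar = u < (-2.0 * s_target)
        phi_p = rng.uniform(0.0, 2.0 * math.pi, size=int(planar.sum()))
        vec[planar] = np.column_stack([np.cos(phi_p), np.sin(phi_p),
                                       np.zeros_like(phi_p)])
    return vec


def simulate_trajectory(spec: TrajectorySpec) -> BilayerTrajectory:
    """Build an idealized bilayer trajectory realizing the spec targets.

    Chains are interleaved segment walks: carbon positions are laid down
    so that the measured segment vector C(i+1) - C(i-1) at interior
    carbon *i* is exactly the drawn orientation vector (times the 0.25 nm
    segment length), pointed from the head plane toward the bilayer
    center. The lateral box realizes ``target_apl`` per leaflet lipid
    (with optional per-frame area jitter) and head planes sit at
    +-thickness/2.
    """
    rng = np.random.default_rng(spec.seed)
    n_leaflet = spec.n_lipids // 2
    n_seg = spec.n_chain_carbons - 2
    targets = spec.segment_targets()
    seg_len = 0.25  # nm

    n_atoms_per_lipid = 1 + spec.chains_per_lipid * spec.n_chain_carbons
    n_atoms = spec.n_lipids * n_atoms_per_lipid

    # per-frame box / thickness
    jitter = (rng.normal(0.0, spec.frame_jitter_sd, size=spec.n_frames)
              if spec.frame_jitter_sd > 0 else np.zeros(spec.n_frames))
    jitter = np.clip(jitter, -0.5, 0.5)
    apl_frames = spec.target_apl * (1.0 + jitter)
    area_frames = apl_frames * n_leaflet
    if spec.volume_coupling:
        thick_frames = 2.0 * spec.v_lipid / apl_frames
    else:
        thick_frames = np.full(spec.n_frames, spec.thickness0)
    lx = np.sqrt(area_frames)
    lz = thick_frames + 2.0 * seg_len * spec.n_chain_carbons
    boxes = np.column_stack([lx, lx, lz])

    lipids: list[LipidTopology] = []
    atom = 0
    for li in range(spec.n_lipids):
        leaflet = "upper" if li < n_leaflet else "lower"
        head = atom
        atom += 1
        chains = []
        for _ in range(spec.chains_per_lipid):
            chains.append(tuple(range(atom, atom + spec.n_chain_carbons)))
            atom += spec.n_chain_carbons
        lipids.append(LipidTopology(leaflet=leaflet, head_index=head,
                                    chains=tuple(chains)))

    coords = np.zeros((spec.n_frames, n_atoms, 3))
    n_chains_total = spec.n_lipids * spec.chains_per_lipid
    for f in range(spec.n_frames):
        half = thick_frames[f] / 2.0
        # segment vectors for all chains: (n_chains_total, n_seg, 3)
        segs = np.empty((n_chains_total, n_seg, 3))
        for s in range(n_seg):
            segs[:, s, :] = _segment_vectors(rng, targets[s], n_chains_total,
                                             spec.orientation_mode) * seg_len
        heads_xy = rng.uniform(0.0, lx[f], size=(spec.n_lipids, 2))
        ci = 0
        for li, lip in enumerate(lipids):
            sign = -1.0 if lip.leaflet == "upper" else 1.0  # toward center
            head_z = half if lip.leaflet == "upper" else -half
            coords[f, lip.head_index] = [heads_xy[li, 0], heads_xy[li, 1],
                                         head_z]
            for chain in lip.chains:
                pos = np.zeros((spec.n_chain_carbons, 3))
                pos[0] = coords[f, lip.head_index] + [0.0, 0.0,
                                                      sign * 0.5 * seg_len]
                pos[1] = pos[0] + [0.05, 0.0, sign * 0.5 * seg_len]
                sv = segs[ci] * np.array([1.0, 1.0, sign])
                for i in range(1, spec.n_chain_carbons - 1):
                    pos[i + 1] = pos[i - 1] + sv[i - 1]
                coords[f, chain[0]:chain[-1] + 1] = pos
                ci += 1
    times = np.arange(spec.n_frames, dtype=float) * spec.time_per_frame
    return BilayerTrajectory(boxes=boxes, coords=coords, times=times,
                             lipids=lipids)
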