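"""Synthetic multi-domain fixtures with known ground truth.

Ideal-geometry backbones (textbook bond lengths/angles, trans peptide
bonds) are grown residue by residue from phi/psi profiles: canonical
helix/strand torsions inside domains, seeded random coil torsions in the
linkers. Because every fixture is generated from internal coordinates, the
true inter-domain transforms, the linker torsions and the domain layout are
all known exactly — the oracle interaction map of a fixture scores the
fixture itself at zero ACD, which anchors the whole engine's tests.

These toys emulate the *geometry* of multi-domain proteins (rigid compact
units joined by flexible linkers), not their sequences, side chains or
packing quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import GenerationError, ValidationError
from .geometry import place_atom
from .interactions import (DEFAULT_BLUR, BinScheme, discretize_targets,
                           oracle_targets_from_structure, write_interactions)
from .kinematics import (IDEAL_ANG_C_N_CA, IDEAL_ANG_CA_C_N,
                         IDEAL_ANG_N_CA_C, IDEAL_C_N, IDEAL_CA_C,
                         IDEAL_N_CA, OMEGA_TRANS, apply_torsions,
                         linker_residues)
from .structure import (BackboneStructure, Domain, DomainLayout,
                        virtual_cbeta)

IDEAL_C_O = 1.231
IDEAL_ANG_CA_C_O = np.deg2rad(120.8)

#: Canonical (phi, psi) in degrees per secondary-structure kind.
CANONICAL_TORSIONS = {"helix": (-57.0, -47.0), "strand": (-120.0, 120.0)}
#: Per-residue torsion jitter (degrees) keeping domains individual but regular.
DOMAIN_JITTER_DEG = 6.0
#: Minimum inter-domain CA-CA distance for an acceptable target.
CLASH_MIN_CA = 3.5


def build_chain_from_torsions(phi: np.ndarray, psi: np.ndarray,
                              chain: str = "A", start_resnum: int = 1,
                              res_name: str = "ALA") -> BackboneStructure:
    """Grow an ideal-geometry backbone (with O and CB) from torsions.

    ``phi[0]`` is unused (no preceding carbonyl); ``psi[-1]`` only orients
    the final carbonyl oxygen. All omegas are trans.
    """
    phi = np.deg2rad(np.asarray(phi, dtype=float))
    psi = np.deg2rad(np.asarray(psi, dtype=float))
    L = len(phi)
    if len(psi) != L:
        raise ValidationError("phi and psi must have equal length")
    coords = np.full((L, 5, 3), np.nan)
    # first residue in the xy-plane
    coords[0, 0] = (0.0, 0.0, 0.0)                       # N
    coords[0, 1] = (IDEAL_N_CA, 0.0, 0.0)                # CA
    ang = IDEAL_ANG_N_CA_C
    coords[0, 2] = coords[0, 1] + IDEAL_CA_C * np.array(
        [-np.cos(ang), np.sin(ang), 0.0])                # C
    for i in range(1, L):
        n0, ca0, c0 = coords[i - 1, 0], coords[i - 1, 1], coords[i - 1, 2]
        n1 = place_atom(n0, ca0, c0, IDEAL_C_N, IDEAL_ANG_CA_C_N, psi[i - 1])
        ca1 = place_atom(ca0, c0, n1, IDEAL_N_CA, IDEAL_ANG_C_N_CA,
                         OMEGA_TRANS)
        c1 = place_atom(c0, n1, ca1, IDEAL_CA_C, IDEAL_ANG_N_CA_C, phi[i])
        coords[i, 0], coords[i, 1], coords[i, 2] = n1, ca1, c1
        coords[i - 1, 3] = place_atom(n0, ca0, c0, IDEAL_C_O,
                                      IDEAL_ANG_CA_C_O, psi[i - 1] - np.pi)
    coords[L - 1, 3] = place_atom(coords[L - 1, 0], coords[L - 1, 1],
                                  coords[L - 1, 2], IDEAL_C_O,
                                  IDEAL_ANG_CA_C_O, psi[L - 1] - np.pi)
    coords[:, 4] = virtual_cbeta(coords[:, 0], coords[:, 1], coords[:, 2])
    return BackboneStructure(
        np.array([chain] * L, dtype=object),
        np.arange(start_resnum, start_resnum + L),
        np.array([res_name] * L, dtype=object), coords)


def make_ideal_domain(kind: str, length: int, seed: int = 0,
                      chain: str = "A",
                      start_resnum: int = 1) -> BackboneStructure:
    """Single compact domain: 'helix', 'strand' or 'mixed' (helix then
    strand halves). A small seeded torsion jitter keeps domains from being
    literal repeats while preserving the secondary structure."""
    if length < 8:
        raise ValidationError("domain length must be >= 8")
    if kind == "mixed":
        half = length // 2
        prof = ([CANONICAL_TORSIONS["helix"]] * half
                + [CANONICAL_TORSIONS["strand"]] * (length - half))
    elif kind in CANONICAL_TORSIONS:
        prof = [CANONICAL_TORSIONS[kind]] * length
    else:
        raise ValidationError(f"unknown domain kind {kind!r}")
    rng = np.random.default_rng(seed)
    prof = np.asarray(prof, dtype=float)
    prof = prof + rng.uniform(-DOMAIN_JITTER_DEG, DOMAIN_JITTER_DEG,
                              prof.shape)
    return build_chain_from_torsions(prof[:, 0], prof[:, 1], chain=chain,
                                     start_resnum=start_resnum)


# ---------------------------------------------------------------------------
# Multi-domain targets


@dataclass
class ChainSpec:
    """Domains (kind, length) of one chain plus linker lengths between
    consecutive domains."""
    domains: list[tuple[str, int]]
    linkers: list[int] = field(default_factory=list)

    def __post_init__(self):
        if len(self.linkers) != max(0, len(self.domains) - 1):
            raise ValidationError("need one linker length per junction")
        for _, n in self.domains:
            if n < 8:
                raise ValidationError("domain lengths must be >= 8")

    @property
    def length(self) -> int:
        return sum(n for _, n in self.domains) + sum(self.linkers)


@dataclass
class FixtureSpec:
    """Recipe for one synthetic multi-domain / multi-chain target."""
    chains: list[ChainSpec]
    rng_seed: int = 0
    perturbation_deg: float = 60.0

    def __post_init__(self):
        if not self.chains:
            raise ValidationError("at least one chain required")
        total = sum(c.length for c in self.chains)
        if total > 500:
            raise ValidationError("fixtures are capped at 500 residues")


def _chain_torsion_profile(cspec: ChainSpec, rng: np.random.Generator
                           ) -> tuple[np.ndarray, np.ndarray]:
    phis: list[float] = []
    psis: list[float] = []
    for d, (kind, length) in enumerate(cspec.domains):
        canon = (CANONICAL_TORSIONS[kind] if kind != "mixed"
                 else CANONICAL_TORSIONS["helix"])
        for i in range(length):
            if kind == "mixed" and i >= length // 2:
                canon = CANONICAL_TORSIONS["strand"]
            phis.append(canon[0] + rng.uniform(-DOMAIN_JITTER_DEG,
                                               DOMAIN_JITTER_DEG))
            psis.append(canon[1] + rng.uniform(-DOMAIN_JITTER_DEG,
                                               DOMAIN_JITTER_DEG))
        if d < len(cspec.linkers):
            for _ in range(cspec.linkers[d]):
                phis.append(rng.uniform(-160.0, -50.0))  # coil region
                psis.append(rng.uniform(90.0, 180.0))
    return np.asarray(phis), np.asarray(psis)


def _chain_layout_ranges(cspec: ChainSpec) -> list[tuple[int, int]]:
    """Domain ranges with each linker split evenly between its flanks."""
    ranges = []
    pos = 1
    extra_prev = 0
    for d, (_, length) in enumerate(cspec.domains):
        start = pos
        span = extra_prev + length
        if d < len(cspec.linkers):
            lead = cspec.linkers[d] // 2 + cspec.linkers[d] % 2
            span += lead
            extra_prev = cspec.linkers[d] - lead
        else:
            extra_prev = 0
        ranges.append((start, start + span - 1))
        pos = start + span
    return ranges


def _min_cross_distance(ca_a: np.ndarray, ca_b: np.ndarray) -> float:
    d = np.linalg.norm(ca_a[:, None, :] - ca_b[None, :, :], axis=2)
    return float(d.min())


def make_multidomain_target(spec: FixtureSpec
                            ) -> tuple[BackboneStructure, DomainLayout]:
    """Clash-free multi-domain target with layout; retries linker torsions
    (and chain poses) up to 100 times before giving up."""
    rng = np.random.default_rng(spec.rng_seed)
    chain_names = [chr(ord("A") + k) for k in range(len(spec.chains))]

    domains: list[Domain] = []
    for cname, cspec in zip(chain_names, spec.chains):
        for k, (lo, hi) in enumerate(_chain_layout_ranges(cspec)):
            domains.append(Domain(f"{cname}{k + 1}", cname, [(lo, hi)]))
    layout = DomainLayout(chain_names, domains)

    for _attempt in range(100):
        chains: list[BackboneStructure] = []
        ok = True
        for cname, cspec in zip(chain_names, spec.chains):
            phis, psis = _chain_torsion_profile(cspec, rng)
            st = build_chain_from_torsions(phis, psis, chain=cname)
            # intra-chain inter-domain clash check
            labels = np.empty(len(st), dtype=object)
            for i, rn in enumerate(st.res_nums):
                labels[i] = layout.domain_of(cname, int(rn))
            ca = st.ca
            d = np.linalg.norm(ca[:, None] - ca[None, :], axis=2)
            inter = labels[:, None] != labels[None, :]
            near = np.abs(np.subtract.outer(np.arange(len(st)),
                                            np.arange(len(st)))) <= 1
            if np.any(inter & ~near & (d < CLASH_MIN_CA)):
                ok = False
                break
            chains.append(st)
        if not ok:
            continue
        # place extra chains at a random contacting, clash-free pose
        placed = [chains[0]]
        for st in chains[1:]:
            pose_ok = False
            for _ in range(100):
                cand = _random_chain_pose(st, placed, rng)
                if cand is not None:
                    placed.append(cand)
                    pose_ok = True
                    break
            if not pose_ok:
                ok = False
                break
        if not ok:
            continue
        full = BackboneStructure(
            np.concatenate([c.chain_ids for c in placed]),
            np.concatenate([c.res_nums for c in placed]),
            np.concatenate([c.res_names for c in placed]),
            np.concatenate([c.coords for c in placed]))
        return layout.attach(full), layout
    raise GenerationError("could not generate a clash-free target in "
                          "100 attempts")


def _random_chain_pose(st: BackboneStructure,
                       placed: list[BackboneStructure],
                       rng: np.random.Generator
                       ) -> BackboneStructure | None:
    from scipy.spatial.transform import Rotation
    anchor_ca = np.concatenate([p.ca for p in placed])
    anchor_centroid = anchor_ca.mean(axis=0)
    r_anchor = float(np.max(np.linalg.norm(anchor_ca - anchor_centroid,
                                           axis=1)))
    own = st.ca - st.ca.mean(axis=0)
    r_own = float(np.max(np.linalg.norm(own, axis=1)))
    R = Rotation.random(random_state=rng).as_matrix()
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    dist = (r_anchor + r_own) * rng.uniform(0.55, 0.9) + 4.0
    cand = st.copy()
    cand.coords = ((st.coords - st.ca.mean(axis=0)) @ R.T
                   + anchor_centroid + direction * dist)
    dmin = _min_cross_distance(anchor_ca, cand.ca)
    if CLASH_MIN_CA <= dmin <= 9.0:  # clash-free but in contact
        return cand
    return None


def perturbed_start(target: BackboneStructure, layout: DomainLayout,
                    magnitude_deg: float, seed: int,
                    width: int = 8) -> tuple[BackboneStructure, np.ndarray]:
    """Perturb the linker windows (and chain poses) by uniform offsets of
    at most ``magnitude_deg``; returns the structure and the applied gene
    vector (negate it to restore the target exactly)."""
    if magnitude_deg < 0:
        raise ValidationError("magnitude must be >= 0")
    spec = linker_residues(layout, width=width)
    rng = np.random.default_rng(seed)
    mag = np.deg2rad(magnitude_deg)
    genes = np.zeros(spec.n_genes)
    genes[:spec.n_torsion_genes] = rng.uniform(-mag, mag,
                                               spec.n_torsion_genes)
    for s in range(len(spec.chain_slots)):
        g = spec.n_torsion_genes + 6 * s
        genes[g: g + 3] = rng.uniform(-mag, mag, 3)
        genes[g + 3: g + 6] = rng.uniform(-magnitude_deg / 15.0,
                                          magnitude_deg / 15.0, 3)
    return apply_torsions(target, spec, genes), genes


# ---------------------------------------------------------------------------
# Fixture catalogue


def standard_fixture_specs(seed: int = 0) -> dict[str, FixtureSpec]:
    """The fixed three-target catalogue used throughout the test suite."""
    return {
        "two_domain": FixtureSpec(
            [ChainSpec([("helix", 28), ("helix", 28)], [8])],
            rng_seed=seed * 1000 + 1),
        "three_domain": FixtureSpec(
            [ChainSpec([("helix", 22), ("strand", 14), ("helix", 22)],
                       [8, 8])],
            rng_seed=seed * 1000 + 2),
        "two_chain": FixtureSpec(
            [ChainSpec([("helix", 26)]), ChainSpec([("helix", 26)])],
            rng_seed=seed * 1000 + 3),
    }


def fixture_suite(out_dir, seed: int = 0,
                  r_max: float = 40.0) -> dict[str, dict[str, Path]]:
    """Write the catalogue: PDB + layout JSON + oracle interactions in both
    mode and blurred dist dialects per target. Regeneration with the same
    seed is bit-identical for the TSV/JSON artifacts."""
    from .structure import write_pdb
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scheme = BinScheme.default(r_max=r_max)
    written: dict[str, dict[str, Path]] = {}
    for name, fspec in standard_fixture_specs(seed).items():
        target, layout = make_multidomain_target(fspec)
        oracle = oracle_targets_from_structure(target, layout, r_max=r_max)
        blurred = discretize_targets(oracle, scheme, DEFAULT_BLUR)
        paths = {
            "pdb": out_dir / f"{name}.pdb",
            "layout": out_dir / f"{name}.layout.json",
            "mode": out_dir / f"{name}.mode.tsv",
            "dist": out_dir / f"{name}.dist.tsv",
        }
        write_pdb(target, paths["pdb"])
        layout.to_file(paths["layout"])
        write_interactions(oracle, paths["mode"])
        write_interactions(blurred, paths["dist"])
        written[name] = paths
    return written
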