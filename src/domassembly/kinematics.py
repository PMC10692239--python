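"""Torsion-space kinematics: map decision variables to coordinates.

Domains are rigid bodies; the only degrees of freedom are phi/psi offsets
of the linker residues around each domain junction (default window: eight
residues, four on each side) plus, for multi-chain inputs, one rigid 6-DoF
slot per non-anchor chain. A phi offset rotates everything C-terminal of
the residue's CA about its N-CA axis (including the residue's own C, O and
CB, which keeps the residue internally rigid); a psi offset rotates
everything past C about the CA-C axis (carrying O along so the carbonyl
stays in the peptide plane). The N-terminal domain of the first chain is
the fixed reference.

Offsets are a group action on conformations: applying v then w equals
applying v + w (angles wrapped), and the zero vector is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import LayoutError, ValidationError
from .frames import (build_frame, compose, invert, rotations_from_euler,
                     wrap_angle)
from .geometry import dihedral, place_atom, rotation_about_axis
from .structure import (BackboneStructure, DomainLayout,
                        C_, CA_, CB_, N_, O_)

# Ideal peptide geometry used to build inter-domain junctions.
IDEAL_C_N = 1.329
IDEAL_N_CA = 1.458
IDEAL_CA_C = 1.525
IDEAL_C_O = 1.231
IDEAL_ANG_CA_C_N = np.deg2rad(116.2)
IDEAL_ANG_C_N_CA = np.deg2rad(121.7)
IDEAL_ANG_N_CA_C = np.deg2rad(111.0)
IDEAL_ANG_CA_C_O = np.deg2rad(120.8)
OMEGA_TRANS = np.pi

# Junction torsions of the deterministic base conformation (extended-ish;
# individuals store offsets relative to these).
BASE_PHI = np.deg2rad(-120.0)
BASE_PSI = np.deg2rad(140.0)


@dataclass
class LinkerSpec:
    """Movable torsions and rigid chain slots for one layout.

    ``torsions`` lists ``(chain, residue number, "phi"|"psi")`` in N->C
    order; ``chain_slots`` lists non-anchor chains, each contributing six
    genes (three rotation angles about the chain centroid, three
    translations in Angstrom) after the torsion genes.
    """

    torsions: list[tuple[str, int, str]]
    chain_slots: list[str] = field(default_factory=list)
    width: int = 8

    @property
    def n_torsion_genes(self) -> int:
        return len(self.torsions)

    @property
    def n_genes(self) -> int:
        return len(self.torsions) + 6 * len(self.chain_slots)

    def angle_gene_mask(self) -> np.ndarray:
        """True for genes that are angles (torsions + slot rotations)."""
        mask = np.ones(self.n_genes, dtype=bool)
        for s in range(len(self.chain_slots)):
            base = self.n_torsion_genes + 6 * s
            mask[base + 3: base + 6] = False
        return mask

    def window_residues(self) -> set[tuple[str, int]]:
        return {(c, r) for c, r, _ in self.torsions}


def linker_residues(layout: DomainLayout, width: int = 8) -> LinkerSpec:
    """Movable windows: ``width/2`` residues on each side of every junction
    between sequence-adjacent domains of a chain."""
    if width < 2 or width % 2:
        raise ValidationError("linker width must be an even integer >= 2")
    half = width // 2
    torsions: list[tuple[str, int, str]] = []
    claimed: dict[str, set[int]] = {}
    for chain, up_id, down_id, junction in layout.boundaries():
        down = next(d for d in layout.domains if d.id == down_id)
        up = next(d for d in layout.domains if d.id == up_id)
        start_next = min(a for a, _ in down.ranges)
        window = list(range(junction - half + 1, junction + 1)) + \
            list(range(start_next, start_next + half))
        for rn in window[:half]:
            if not up.contains(rn):
                raise LayoutError(
                    f"linker window escapes domain {up_id} (residue {rn})")
        for rn in window[half:]:
            if not down.contains(rn):
                raise LayoutError(
                    f"linker window escapes domain {down_id} (residue {rn})")
        seen = claimed.setdefault(chain, set())
        if seen & set(window):
            raise LayoutError(
                f"linker windows overlap on chain {chain}; "
                "domains too short for this width")
        seen.update(window)
        for rn in window:
            torsions.append((chain, rn, "phi"))
            torsions.append((chain, rn, "psi"))
    return LinkerSpec(torsions, chain_slots=list(layout.chains[1:]),
                      width=width)


# ---------------------------------------------------------------------------
# Applying a torsion vector


class TorsionPlan:
    """Precompiled bookkeeping binding a LinkerSpec to one base structure
    (row indices, downstream slices, chain-slot blocks), so that repeated
    torsion application inside the optimizer skips all lookups.

    Valid only while the base's residue ordering is unchanged; chains must
    occupy contiguous row blocks (guaranteed by layout attachment).
    """

    def __init__(self, base: BackboneStructure, spec: LinkerSpec):
        self.spec = spec
        index = base.residue_index()
        chain_rows = {c: base.chain_slice(c) for c in base.chains()}
        for c, rows in chain_rows.items():
            if len(rows) and not np.array_equal(
                    rows, np.arange(rows[0], rows[-1] + 1)):
                raise ValidationError(
                    f"chain {c} rows are not contiguous; attach the layout "
                    "before building a torsion plan")
        self.torsion_ops: list[tuple[int, str, int]] = []
        for chain, resnum, kind in spec.torsions:
            key = (chain, resnum)
            if key not in index:
                raise ValidationError(
                    f"residue {chain}{resnum} absent from base")
            row = index[key]
            if not np.all(np.isfinite(base.coords[row, (N_, CA_, C_), :])):
                raise ValidationError(
                    f"residue {chain}{resnum} misses backbone atoms")
            chain_end = int(chain_rows[chain][-1])
            self.torsion_ops.append((row, kind, chain_end))
        self.slot_blocks: list[tuple[int, int, np.ndarray]] = []
        for chain in spec.chain_slots:
            rows = chain_rows[chain]
            centroid = np.nanmean(base.coords[rows, CA_], axis=0)
            self.slot_blocks.append((int(rows[0]), int(rows[-1]) + 1,
                                     centroid))


def apply_torsions(base: BackboneStructure, spec: LinkerSpec,
                   v: np.ndarray, plan: TorsionPlan | None = None
                   ) -> BackboneStructure:
    """Return a new conformation with the offsets of ``v`` applied to
    ``base``. Bond lengths/angles and all geometry outside the movable
    windows are preserved exactly."""
    v = np.asarray(v, dtype=float)
    if v.shape != (spec.n_genes,):
        raise ValidationError(
            f"torsion vector length {v.shape} != ({spec.n_genes},)")
    if not np.all(np.isfinite(v)):
        raise ValidationError("non-finite gene in torsion vector")
    if plan is None:
        plan = TorsionPlan(base, spec)
    out = base.copy()
    coords = out.coords

    for g, (row, kind, chain_end) in enumerate(plan.torsion_ops):
        offset = wrap_angle(v[g])
        if offset == 0.0:
            continue
        if kind == "phi":
            pivot = coords[row, CA_]
            axis = pivot - coords[row, N_]
            own = (C_, O_, CB_)
        else:
            pivot = coords[row, C_]
            axis = pivot - coords[row, CA_]
            own = (O_,)
        R = rotation_about_axis(axis, float(offset))
        block = coords[row + 1: chain_end + 1].reshape(-1, 3)
        coords[row + 1: chain_end + 1] = (
            (block - pivot) @ R.T + pivot).reshape(-1, 5, 3)
        for k in own:
            xyz = coords[row, k]
            if xyz[0] == xyz[0]:  # fast NaN check on x
                coords[row, k] = R @ (xyz - pivot) + pivot

    for s, (start, stop, centroid) in enumerate(plan.slot_blocks):
        gbase = spec.n_torsion_genes + 6 * s
        rot = wrap_angle(v[gbase: gbase + 3])
        trans = v[gbase + 3: gbase + 6]
        if np.all(rot == 0.0) and np.all(trans == 0.0):
            continue
        R = rotations_from_euler(rot[None])[0]
        block = coords[start:stop].reshape(-1, 3)
        coords[start:stop] = ((block - centroid) @ R.T + centroid
                              + trans).reshape(-1, 5, 3)
    return out


def measure_torsions(structure: BackboneStructure,
                     spec: LinkerSpec) -> np.ndarray:
    """Current phi/psi values (radians) of the spec's movable torsions."""
    index = structure.residue_index()
    coords = structure.coords
    chain_rows = {c: structure.chain_slice(c) for c in structure.chains()}
    out = np.empty(spec.n_torsion_genes)
    for g, (chain, resnum, kind) in enumerate(spec.torsions):
        row = index[(chain, resnum)]
        rows = chain_rows[chain]
        pos = np.searchsorted(rows, row)
        if kind == "phi":
            if pos == 0:
                raise ValidationError(
                    f"phi of first residue {chain}{resnum} undefined")
            prev = rows[pos - 1]
            out[g] = dihedral(coords[prev, C_], coords[row, N_],
                              coords[row, CA_], coords[row, C_])
        else:
            if pos == len(rows) - 1:
                raise ValidationError(
                    f"psi of last residue {chain}{resnum} undefined")
            nxt = rows[pos + 1]
            out[g] = dihedral(coords[row, N_], coords[row, CA_],
                              coords[row, C_], coords[nxt, N_])
    return out


def recovery_genes(base: BackboneStructure, target: BackboneStructure,
                   spec: LinkerSpec) -> np.ndarray:
    """Gene vector that carries ``base`` onto ``target`` when both share the
    same rigid-domain internal geometry (the oracle-optimum test helper)."""
    from .metrics import kabsch_rmsd  # local import to avoid a cycle
    genes = np.zeros(spec.n_genes)
    genes[:spec.n_torsion_genes] = wrap_angle(
        measure_torsions(target, spec) - measure_torsions(base, spec))
    if spec.chain_slots:
        moved = apply_torsions(base, spec, genes)
        t_index = target.residue_index()
        for s, chain in enumerate(spec.chain_slots):
            rows = moved.chain_slice(chain)
            t_rows = np.array([t_index[(chain, int(moved.res_nums[r]))]
                               for r in rows])
            sup = kabsch_rmsd(moved.coords[rows, CA_],
                              target.coords[t_rows, CA_])
            centroid = np.nanmean(base.coords[base.chain_slice(chain), CA_],
                                  axis=0)
            from .frames import eulers_from_rotations
            gbase = spec.n_torsion_genes + 6 * s
            genes[gbase: gbase + 3] = eulers_from_rotations(sup.rotation)[0]
            genes[gbase + 3: gbase + 6] = (
                sup.rotation @ centroid + sup.translation - centroid)
    return genes


# ---------------------------------------------------------------------------
# Full-length construction


def _junction_place(up_coords: np.ndarray, phi: float, psi: float
                    ) -> np.ndarray:
    """Ideal-geometry N/CA/C of the residue following ``up_coords``
    (one residue's atom block), given the junction psi and phi."""
    n0, ca0, c0 = up_coords[N_], up_coords[CA_], up_coords[C_]
    n1 = place_atom(n0, ca0, c0, IDEAL_C_N, IDEAL_ANG_CA_C_N, psi)
    ca1 = place_atom(ca0, c0, n1, IDEAL_N_CA, IDEAL_ANG_C_N_CA, OMEGA_TRANS)
    c1 = place_atom(c0, n1, ca1, IDEAL_CA_C, IDEAL_ANG_N_CA_C, phi)
    return np.stack([n1, ca1, c1])


def _superpose_domain(domain: BackboneStructure,
                      target_nca_c: np.ndarray) -> BackboneStructure:
    """Rigidly move a domain so its first residue's N/CA/C frame lands on
    the given triple."""
    first = domain.coords[0]
    f_dom = build_frame(first[N_], first[CA_], first[C_])
    f_tgt = build_frame(*target_nca_c)
    move = compose(f_tgt, invert(f_dom))
    out = domain.copy()
    out.coords = out.coords @ move.R.T + move.t
    return out


def build_base_full_length(domains: list[BackboneStructure],
                           layout: DomainLayout) -> BackboneStructure:
    """Deterministic full-length conformation: domains concatenated N->C
    per chain with ideal peptide junctions (C-N 1.329 A, omega 180 deg) at
    fixed reference torsions; chains laid side by side along +x.

    ``domains`` must follow ``layout.domains`` order; torsion vectors are
    interpreted as offsets from this conformation.
    """
    if len(domains) != len(layout.domains):
        raise LayoutError(
            f"{len(domains)} domain structures for "
            f"{len(layout.domains)} layout domains")
    by_id: dict[str, BackboneStructure] = {}
    for dom_struct, dom in zip(domains, layout.domains):
        expected = dom.residue_numbers()
        got = [int(r) for r in dom_struct.res_nums]
        if got != expected:
            raise LayoutError(
                f"domain {dom.id}: residue numbers {got[:3]}... do not "
                f"match layout ranges")
        by_id[dom.id] = dom_struct

    chain_structs: list[BackboneStructure] = []
    for chain in layout.chains:
        parts = layout.domains_in_chain(chain)
        assembled = by_id[parts[0].id].copy()
        for nxt in parts[1:]:
            placed = _junction_place(assembled.coords[-1],
                                     BASE_PHI, BASE_PSI)
            # re-idealize the junction carbonyl O to the base psi so that
            # a psi offset carries it exactly onto any rebuilt target
            last = assembled.coords[-1]
            assembled.coords[-1, O_] = place_atom(
                last[N_], last[CA_], last[C_], IDEAL_C_O,
                IDEAL_ANG_CA_C_O, BASE_PSI - np.pi)
            moved = _superpose_domain(by_id[nxt.id], placed)
            assembled = BackboneStructure(
                np.concatenate([assembled.chain_ids, moved.chain_ids]),
                np.concatenate([assembled.res_nums, moved.res_nums]),
                np.concatenate([assembled.res_names, moved.res_names]),
                np.concatenate([assembled.coords, moved.coords]))
        assembled.chain_ids = np.array([chain] * len(assembled),
                                       dtype=object)
        chain_structs.append(assembled)

    # lay chains side by side; rigid slots move them during optimization
    placed_chains = [chain_structs[0]]
    offset_x = float(np.max(chain_structs[0].ca[:, 0]))
    for cs in chain_structs[1:]:
        gap = 10.0
        shift = np.array([offset_x + gap - float(np.min(cs.ca[:, 0])),
                          0.0, 0.0])
        cs = cs.copy()
        cs.coords = cs.coords + shift
        offset_x = float(np.max(cs.ca[:, 0]))
        placed_chains.append(cs)

    full = BackboneStructure(
        np.concatenate([c.chain_ids for c in placed_chains]),
        np.concatenate([c.res_nums for c in placed_chains]),
        np.concatenate([c.res_names for c in placed_chains]),
        np.concatenate([c.coords for c in placed_chains]))
    return layout.attach(full)


def initial_full_length(domains: list[BackboneStructure],
                        layout: DomainLayout, rng_seed: int,
                        width: int = 8) -> BackboneStructure:
    """Random initial full-length model: the deterministic base with linker
    phi/psi drawn uniformly from [-pi, pi) and non-anchor chains placed with
    a random rigid transform inside a 30 A margin around the anchor."""
    base = build_base_full_length(domains, layout)
    spec = linker_residues(layout, width=width)
    if spec.n_genes == 0:
        return base
    rng = np.random.default_rng(rng_seed)
    genes = sample_initial_genes(base, spec, rng)
    return apply_torsions(base, spec, genes)


def sample_initial_genes(base: BackboneStructure, spec: LinkerSpec,
                         rng: np.random.Generator) -> np.ndarray:
    """One random decision vector (shared by initial models and the
    optimizer's initial population)."""
    genes = np.empty(spec.n_genes)
    genes[:spec.n_torsion_genes] = rng.uniform(-np.pi, np.pi,
                                               spec.n_torsion_genes)
    if spec.chain_slots:
        anchor_rows = base.chain_slice(base.chains()[0])
        centroid = np.mean(base.coords[anchor_rows, CA_], axis=0)
        radius = float(np.max(np.linalg.norm(
            base.coords[anchor_rows, CA_] - centroid, axis=1))) + 30.0
        for s in range(len(spec.chain_slots)):
            g = spec.n_torsion_genes + 6 * s
            genes[g: g + 3] = rng.uniform(-np.pi, np.pi, 3)
            genes[g + 3: g + 6] = rng.uniform(-radius, radius, 3)
    return genes
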